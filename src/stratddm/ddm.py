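"""Two-boundary Wiener diffusion: first-passage density, survival,
absorption probability, an exact (inverse-survival) sampler, and a
brute-force Euler-Maruyama path simulator used as the test oracle.

The diffusion coefficient is fixed at 1; scale is absorbed into the
threshold and drift.  The upper boundary codes the correct response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _wfpt


@dataclass(frozen=True)
class DiffusionSpec:
    """Constant-drift Wiener process between absorbing boundaries.

    v: drift (evidence/s); a: threshold separation (> 0); w: relative
    start point in (0, 1), measured toward the upper (correct) boundary.
    """

    v: float
    a: float
    w: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("threshold a must be > 0")
        if not 0 < self.w < 1:
            raise ValueError("start point w must lie in (0, 1)")


def wfpt_density(u, boundary: str, spec: DiffusionSpec):
    """First-passage density at time(s) ``u > 0`` for the given boundary."""
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    upper = boundary == "upper"
    arr = np.asarray(u, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("u must be > 0")
    if arr.ndim == 0:
        return float(_wfpt.pdf_boundary(float(arr), spec.v, spec.a, spec.w, upper))
    return _wfpt.pdf_boundary_arr(np.ascontiguousarray(arr.ravel()),
                                  spec.v, spec.a, spec.w, upper).reshape(arr.shape)


def wfpt_survival(u, spec: DiffusionSpec):
    """P(neither boundary reached by time u); 1 at u = 0, monotone down."""
    arr = np.asarray(u, dtype=float)
    if np.any(arr < 0):
        raise ValueError("u must be >= 0")
    if arr.ndim == 0:
        return float(_wfpt.survival(float(arr), spec.v, spec.a, spec.w))
    return _wfpt.survival_arr(np.ascontiguousarray(arr.ravel()),
                              spec.v, spec.a, spec.w).reshape(arr.shape)


def absorption_prob(spec: DiffusionSpec) -> float:
    """Probability of eventual upper-boundary absorption (closed form,
    continuous at v = 0 where it equals w)."""
    return float(_wfpt.prob_upper(spec.v, spec.a, spec.w))


def simulate_ddm_path(spec: DiffusionSpec, dt: float = 1e-4,
                      max_time: float = 10.0, seed: int = 0):
    """Single Euler-Maruyama path; returns (boundary or None, time).

    Deterministic given the seed; part of the brute-force oracle, not of
    the fitting path.
    """
    if dt <= 0 or max_time <= 0:
        raise ValueError("dt and max_time must be > 0")
    codes, times = _wfpt.em_paths(spec.v, spec.a, spec.w, dt, max_time, 1, seed)
    code = int(codes[0])
    boundary = {1: "upper", -1: "lower", 0: None}[code]
    return boundary, float(times[0])


def simulate_ddm_paths(spec: DiffusionSpec, dt: float, max_time: float,
                       n: int, seed: int):
    """n Euler-Maruyama paths; returns (codes in {1,-1,0}, times)."""
    if dt <= 0 or max_time <= 0:
        raise ValueError("dt and max_time must be > 0")
    return _wfpt.em_paths(spec.v, spec.a, spec.w, dt, max_time, n, seed)


def em_boundary_correction(spec: DiffusionSpec, dt: float) -> DiffusionSpec:
    """Effective spec seen by a discrete Euler-Maruyama walk.

    A discrete walk overshoots the continuous boundaries by about
    0.5826*sqrt(dt) (the Riemann-zeta constant of the Gaussian random
    walk), i.e. it behaves like a continuous diffusion with boundaries
    pushed outward by that amount.  Oracle comparisons at finite dt use
    this corrected spec as the analytic reference.
    """
    h = 0.5826 * np.sqrt(dt)
    a_eff = spec.a + 2.0 * h
    w_eff = (spec.w * spec.a + h) / a_eff
    return DiffusionSpec(spec.v, a_eff, w_eff)


def sample_ddm(spec: DiffusionSpec, n: int, seed: int, horizon: float | None = None):
    """n seeded draws of (boundary code, time) from the exact first-passage
    law, by bisecting the survival function.

    Boundary codes: 1 upper, -1 lower, 0 unabsorbed by ``horizon``.  With
    the default horizon the unabsorbed probability is below 1e-12.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if horizon is None:
        horizon = 1.0
        while _wfpt.survival(horizon, spec.v, spec.a, spec.w) > 1e-12:
            horizon *= 2.0
            if horizon > 1e6:
                break
    return _wfpt.sample_fpt_many(spec.v, spec.a, spec.w, float(horizon), n, seed)
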