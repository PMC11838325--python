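"""Parameter containers and scale transforms.

Individual-level parameters (natural scale):

========= ======================= ==========================================
name      units                   role
========= ======================= ==========================================
alpha     evidence units (> 0)    decision threshold (boundary separation)
kappa     evidence / s            counting drift base ("counting boost")
tau       seconds (>= 0)          non-decision time
delta     evidence / s            retrieval drift base (retrieval efficiency)
beta      proportion in (0, 1)    start-point bias toward the correct bound
mu        log-odds                retrieval propensity at the switch point
omega     s per difficulty unit   switching sensitivity (>= 0)
gamma     seconds (> 0)           baseline switching time
========= ======================= ==========================================

The hierarchical model works on transformed scales: log for the positive
parameters (alpha, kappa, tau, delta, omega, gamma), logit for beta and
identity for mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PARAM_NAMES = ("alpha", "kappa", "tau", "delta", "beta", "mu", "omega", "gamma")

#: transform code per parameter: "log", "logit" or "id"
TRANSFORMS = ("log", "log", "log", "log", "logit", "id", "log", "log")


def to_transformed(values: np.ndarray) -> np.ndarray:
    """Natural -> transformed scale along the last axis (length 8)."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    out[..., :4] = np.log(v[..., :4])
    out[..., 4] = np.log(v[..., 4] / (1.0 - v[..., 4]))
    out[..., 5] = v[..., 5]
    out[..., 6:8] = np.log(v[..., 6:8])
    return out


def to_natural(values: np.ndarray) -> np.ndarray:
    """Transformed -> natural scale along the last axis (length 8)."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    out[..., :4] = np.exp(v[..., :4])
    out[..., 4] = 1.0 / (1.0 + np.exp(-v[..., 4]))
    out[..., 5] = v[..., 5]
    out[..., 6:8] = np.exp(v[..., 6:8])
    return out


def lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (location, scale) of a log-normal with the given
    natural-scale mean and SD."""
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def logit_moments(mean: float, sd: float) -> tuple[float, float]:
    """Delta-method logit-scale (location, scale) for a proportion with the
    given natural-scale mean and SD."""
    return math.log(mean / (1.0 - mean)), sd / (mean * (1.0 - mean))


@dataclass(frozen=True)
class PersonParams:
    """The eight individual-level parameters on their natural scale."""

    alpha: float
    kappa: float
    tau: float
    delta: float
    beta: float
    mu: float
    omega: float
    gamma: float

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PersonParams":
        arr = np.asarray(arr, dtype=float)
        return cls(**dict(zip(PARAM_NAMES, arr)))


@dataclass
class GroupParams:
    """Population-level parameters.

    ``loc``/``scale`` are the between-person location and scale of each of
    the eight parameters on its transformed scale; ``sess_scale`` the
    within-person between-session scale on the same scale.  Extras:

    - ``nu``: log-odds of decomposition among non-retrieval switches,
    - ``lam``: difficulty coefficient on the procedural (counting) drift,
    - ``Delta``: drift decrement of decomposition relative to counting,
    - ``sigma_d``: scale of the item difficulty distribution.
    """

    loc: np.ndarray
    scale: np.ndarray
    sess_scale: np.ndarray
    nu: float
    lam: float
    Delta: float
    sigma_d: float

    def __post_init__(self):
        self.loc = np.asarray(self.loc, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.sess_scale = np.asarray(self.sess_scale, dtype=float)
        for name in ("loc", "scale", "sess_scale"):
            if getattr(self, name).shape != (8,):
                raise ValueError(f"{name} must have shape (8,)")
        if np.any(self.scale < 0) or np.any(self.sess_scale < 0):
            raise ValueError("scales must be >= 0")
        if self.lam < 0 or self.Delta < 0:
            raise ValueError("lam and Delta must be >= 0")
        if not self.sigma_d > 0:
            raise ValueError("sigma_d must be > 0")

    def typical_person(self) -> PersonParams:
        """The median person: inverse-transformed group locations."""
        return PersonParams.from_array(to_natural(self.loc))
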