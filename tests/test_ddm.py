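"""Wiener first-passage numerics against quadrature, closed forms and the
brute-force path oracle."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from stratddm import _wfpt
from stratddm.ddm import (DiffusionSpec, absorption_prob,
                          em_boundary_correction, sample_ddm,
                          simulate_ddm_path, wfpt_density, wfpt_survival)

from conftest import ANCHOR_SPEC

RNG = np.random.default_rng(42)
RANDOM_SPECS = [
    DiffusionSpec(v=float(RNG.uniform(-4, 4)), a=float(RNG.uniform(0.8, 6)),
                  w=float(RNG.uniform(0.15, 0.85)))
    for _ in range(8)
]


@pytest.mark.parametrize("spec", RANDOM_SPECS)
def test_density_normalizes_to_one(spec):
    mass = sum(
        quad(lambda t: wfpt_density(t, b, spec), 0, np.inf, limit=200)[0]
        for b in ("upper", "lower")
    )
    assert mass == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("spec", RANDOM_SPECS[:4])
def test_absorption_prob_equals_upper_density_mass(spec):
    mass_up = quad(lambda t: wfpt_density(t, "upper", spec), 0, np.inf,
                   limit=200)[0]
    assert absorption_prob(spec) == pytest.approx(mass_up, abs=1e-6)


def test_driftless_symmetry_and_absorption():
    spec = DiffusionSpec(v=0.0, a=2.5, w=0.5)
    for u in (0.1, 0.5, 1.3, 3.0):
        assert wfpt_density(u, "upper", spec) == pytest.approx(
            wfpt_density(u, "lower", spec), rel=1e-12
        )
    assert absorption_prob(spec) == 0.5
    assert absorption_prob(DiffusionSpec(0.0, 3.91, 0.54)) == 0.54


def test_strong_drift_absorbs_upper():
    assert absorption_prob(DiffusionSpec(10.0, 3.91, 0.54)) >= 0.999


def test_density_vanishes_at_zero_plus():
    for spec in RANDOM_SPECS[:4]:
        assert wfpt_density(1e-8, "upper", spec) < 1e-12
    with pytest.raises(ValueError):
        wfpt_density(0.0, "upper", ANCHOR_SPEC)


def test_small_and_large_time_series_agree_at_crossover():
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(100):
        a = rng.uniform(0.5, 8)
        w = rng.uniform(0.05, 0.95)
        tt = rng.uniform(0.05, 1.0)  # normalized time around the switch
        d_small = _wfpt.fw_density(tt, w, 1)
        d_large = _wfpt.fw_density(tt, w, 2)
        worst = max(worst, abs(d_small - d_large))
    assert worst < 1e-8


def test_densities_finite_nonnegative_over_parameter_box():
    for v in (-6.0, -2.0, 0.0, 3.0, 6.0):
        for a in (0.5, 2.0, 8.0):
            for w in (0.05, 0.5, 0.95):
                spec = DiffusionSpec(v, a, w)
                vals = wfpt_density(np.array([0.05, 0.5, 2.0, 6.0]), "upper",
                                    spec)
                surv = wfpt_survival(np.array([0.0, 0.5, 2.0, 6.0]), spec)
                assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
                assert np.all(np.isfinite(surv))
                assert np.all((surv >= 0) & (surv <= 1))


def test_survival_matches_integrated_density_and_monotone():
    spec = ANCHOR_SPEC
    prev = 1.0
    assert wfpt_survival(0.0, spec) == 1.0
    for u in (0.2, 0.81, 1.5, 3.0, 5.0):
        s = wfpt_survival(u, spec)
        integral = 1.0 - quad(
            lambda t: wfpt_density(t, "upper", spec)
            + wfpt_density(t, "lower", spec), 0, u, limit=200,
        )[0]
        assert s == pytest.approx(integral, abs=1e-6)
        assert s <= prev + 1e-12
        prev = s
    assert wfpt_survival(60.0, spec) < 1e-9
    with pytest.raises(ValueError):
        wfpt_survival(-0.1, spec)


def test_exact_sampler_reproducible_and_symmetric():
    spec = DiffusionSpec(0.0, 2.0, 0.5)
    c1, t1 = sample_ddm(spec, 5, seed=9)
    c2, t2 = sample_ddm(spec, 5, seed=9)
    assert np.array_equal(c1, c2) and np.array_equal(t1, t2)
    codes, _ = sample_ddm(spec, 20000, seed=1)
    frac = (codes == 1).mean()
    se = np.sqrt(0.25 / 20000)
    assert abs(frac - 0.5) < 3 * se


def test_exact_sampler_matches_integrated_cdf():
    spec = ANCHOR_SPEC
    codes, times = sample_ddm(spec, 20000, seed=3)
    up = times[codes == 1]
    p_up = absorption_prob(spec)

    def cdf(ts):
        return np.array(
            [_wfpt.cdf_lower(t, -spec.v, spec.a, 1 - spec.w) for t in
             np.atleast_1d(ts)]
        ) / p_up

    res = kstest(up, cdf)
    assert res.pvalue > 0.01


def test_em_path_determinism_and_strong_drift_limit():
    spec = DiffusionSpec(40.0, 2.0, 0.25)
    b1, t1 = simulate_ddm_path(spec, dt=1e-5, max_time=2.0, seed=5)
    b2, t2 = simulate_ddm_path(spec, dt=1e-5, max_time=2.0, seed=5)
    assert (b1, t1) == (b2, t2)
    assert b1 == "upper"
    # deterministic limit: time to cover a(1-w) at drift v
    assert t1 == pytest.approx(spec.a * (1 - spec.w) / spec.v, rel=0.25)


def test_em_oracle_upper_fraction(em_reference):
    """Cross-oracle: path-simulation absorption fraction vs the closed form
    evaluated at the boundary-corrected effective spec."""
    codes = em_reference["codes"]
    n = em_reference["n"]
    frac = (codes == 1).mean()
    p = absorption_prob(em_boundary_correction(em_reference["spec"],
                                               em_reference["dt"]))
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se
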