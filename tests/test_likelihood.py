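"""Mixture trial likelihood: component arithmetic, mass closure,
responsibilities and the likelihood-crossing RT."""

import numpy as np
import pandas as pd
import pytest

from stratddm import _wfpt
from stratddm.errors import DataValidationError, DegenerateTrialError
from stratddm.likelihood import (TrialLikelihoodContext, dataset_loglik,
                                 likelihood_crossing_rt, outcome_masses,
                                 procedural_drifts, responsibilities_table,
                                 retrieval_drift, selection_probs,
                                 switch_time, trial_loglik,
                                 trial_responsibilities,
                                 trial_strategy_components)
from stratddm.params import PersonParams
from stratddm.readwrite import RunConfig, TrialRecord
from stratddm.simulate import default_group_params, simulate_cohort

GROUP = default_group_params()
TYPICAL = PersonParams(alpha=3.91, kappa=3.06, tau=0.66, delta=1.49,
                       beta=0.54, mu=-0.83, omega=0.51, gamma=0.81)


def ctx_for(person=TYPICAL, d=0.0, deadline=5.0):
    return TrialLikelihoodContext(person, d, GROUP.nu, GROUP.lam, GROUP.Delta,
                                  deadline)


def test_drift_and_switch_arithmetic():
    assert retrieval_drift(1.49, 0.0) == 1.49
    assert retrieval_drift(1.49, 1.0) == pytest.approx(0.49)
    assert procedural_drifts(3.06, 1.0, 0.5, 1.0) == pytest.approx((2.56, 1.56))
    v_c, v_d = procedural_drifts(3.06, 0.3, 0.0, 2.0)
    assert v_c == 3.06          # lam = 0: counting ignores difficulty
    assert v_d < v_c
    assert switch_time(0.81, 0.51, 1.0) == pytest.approx(1.32)
    assert switch_time(0.81, 0.0, 5.0) == pytest.approx(0.81)
    assert switch_time(0.1, 0.51, -2.0) == pytest.approx(1e-3)  # clamp


def test_retrieval_drift_mean_over_centered_bank():
    d = np.array([-1.2, -0.3, 0.1, 1.4])
    d = d - d.mean()
    assert np.mean(retrieval_drift(1.49, d)) == pytest.approx(1.49)


def test_selection_probs():
    assert selection_probs(0.0, 0.0, 0.0) == pytest.approx((0.5, 0.25, 0.25))
    p_ret, p_count, p_dec = selection_probs(-0.83, 0.0, GROUP.nu)
    assert p_ret == pytest.approx(1 / (1 + np.exp(0.83)), abs=1e-9)
    assert p_ret + p_count + p_dec == pytest.approx(1.0)
    assert selection_probs(-0.83, 50.0, 0.0)[0] < 1e-12  # hard-item limit


@pytest.mark.parametrize("d", [-0.8, 0.0, 1.1])
def test_outcome_mass_closes_to_one(d):
    masses = outcome_masses(ctx_for(d=d))
    assert masses.to_numpy().sum() == pytest.approx(1.0, abs=1e-5)
    assert (masses.to_numpy() >= 0).all()


def test_structural_censoring_reduces_to_retrieval_survival():
    # switch time beyond the deadline: the censor mass is pure retrieval
    person = PersonParams(alpha=3.91, kappa=3.06, tau=0.66, delta=1.49,
                          beta=0.54, mu=-0.83, omega=0.0, gamma=10.0)
    ctx = ctx_for(person)
    trial = TrialRecord("p", "s", "i", None, "none")
    expect = _wfpt.survival(5.0 - 0.66, 1.49, 3.91, 0.54)
    assert trial_loglik(trial, ctx) == pytest.approx(np.log(expect), abs=1e-10)


def test_rt_before_tau_flags_minus_inf_without_raising():
    trial = TrialRecord("p", "s", "i", 0.3, "correct")  # below tau = 0.66
    assert trial_loglik(trial, ctx_for()) == -np.inf


def test_answered_rt_at_deadline_rejected():
    trial = TrialRecord("p", "s", "i", 5.0, "correct")
    with pytest.raises(DataValidationError, match="censored"):
        trial_loglik(trial, ctx_for())


def test_responsibilities_structural_and_normalized():
    ctx = ctx_for()
    fast = TrialRecord("p", "s", "i", 0.9, "correct")  # u = 0.24 < s = 0.81
    r = trial_responsibilities(fast, ctx)
    assert (r.p_retrieval, r.p_counting, r.p_decomposition) == (1.0, 0.0, 0.0)
    assert r.entropy_nat == 0.0
    slow = TrialRecord("p", "s", "i", 3.1, "correct")
    r2 = trial_responsibilities(slow, ctx)
    comps = np.array(trial_strategy_components(slow, ctx))
    manual = comps / comps.sum()
    assert np.allclose([r2.p_retrieval, r2.p_counting, r2.p_decomposition],
                       manual, atol=1e-12)
    assert 0.0 <= r2.entropy_nat <= np.log(3) + 1e-12


def test_degenerate_trial_raises_named_error():
    trial = TrialRecord("p", "s", "i", 0.3, "correct")
    with pytest.raises(DegenerateTrialError):
        trial_responsibilities(trial, ctx_for())


def test_mean_retrieval_responsibility_tracks_generative_fraction():
    """Self-consistency: averaged posterior retrieval responsibility over
    simulated trials matches the ground-truth retrieval rate."""
    from stratddm import _kernels

    n = 10000
    P = np.tile(TYPICAL.to_array(), (n, 1))
    d = np.zeros(n)
    rts, resps, strat, _ = _kernels.simulate_trials(
        P, d, GROUP.nu, GROUP.lam, GROUP.Delta, 5.0, 99
    )
    trials = pd.DataFrame({
        "person_id": "p", "session_id": "s", "item_id": "i",
        "rt": rts, "response": np.select([resps == 1, resps == -1],
                                         ["correct", "incorrect"], "none"),
    })
    params = pd.DataFrame([{"person_id": "p", "session_id": "s",
                            **dict(zip(("alpha", "kappa", "tau", "delta",
                                        "beta", "mu", "omega", "gamma"),
                                       TYPICAL.to_array()))}])
    items = pd.DataFrame({"item_id": ["i"], "d": [0.0]})
    tab = responsibilities_table(trials, params, items, RunConfig(),
                                 GROUP.nu, GROUP.lam, GROUP.Delta)
    true_frac = (strat == 0).mean()
    est_frac = tab["p_retrieval"].mean()
    se = np.sqrt(true_frac * (1 - true_frac) / n)
    assert abs(est_frac - true_frac) < 3 * se


def test_crossing_rt_properties():
    ctx = ctx_for()
    cross = likelihood_crossing_rt(ctx)
    s = switch_time(TYPICAL.gamma, TYPICAL.omega, 0.0)
    assert cross is not None
    assert TYPICAL.tau + s < cross < 5.0
    # retrieval dominates below the crossing, non-retrieval above
    for rt, expect_ret in ((cross - 0.3, True), (cross + 0.5, False)):
        r = trial_responsibilities(TrialRecord("p", "s", "i", rt, "correct"),
                                   ctx)
        assert (r.p_retrieval > r.p_counting + r.p_decomposition) == expect_ret
    # no retrieval branch -> no crossing
    never = PersonParams(alpha=3.91, kappa=3.06, tau=0.66, delta=1.49,
                         beta=0.54, mu=-60.0, omega=0.51, gamma=0.81)
    assert likelihood_crossing_rt(ctx_for(never)) is None


def test_profile_loglik_peaks_near_generating_delta():
    cohort = simulate_cohort(n_persons=1, n_sessions=1,
                             trials_per_session=4000, seed=77)
    person = cohort.sessions.iloc[0]
    params = cohort.sessions.copy()
    lls = {}
    for shift in (-0.6, -0.3, 0.0, 0.3, 0.6):
        p = params.copy()
        p["delta"] = person["delta"] + shift
        ll, _ = dataset_loglik(cohort.observed(), p, cohort.items,
                               RunConfig(), cohort.group.nu, cohort.group.lam,
                               cohort.group.Delta)
        lls[shift] = ll
    assert max(lls, key=lls.get) == 0.0


def test_dataset_loglik_contracts(small_cohort):
    cfg = RunConfig()
    g = small_cohort.group
    obs = small_cohort.observed()
    total, flags = dataset_loglik(obs, small_cohort.sessions,
                                  small_cohort.items, cfg, g.nu, g.lam, g.Delta)
    assert np.isfinite(total) and flags == 0
    assert dataset_loglik(obs.iloc[0:0], small_cohort.sessions,
                          small_cohort.items, cfg, g.nu, g.lam, g.Delta) == (0.0, 0)
    single, _ = dataset_loglik(obs.iloc[[3]], small_cohort.sessions,
                               small_cohort.items, cfg, g.nu, g.lam, g.Delta)
    row = obs.iloc[3]
    sess = small_cohort.sessions
    prow = sess[(sess.person_id == row.person_id)
                & (sess.session_id == row.session_id)].iloc[0]
    ctx = TrialLikelihoodContext(
        PersonParams(*[prow[n] for n in ("alpha", "kappa", "tau", "delta",
                                         "beta", "mu", "omega", "gamma")]),
        float(small_cohort.items.set_index("item_id").loc[row.item_id, "d"]),
        g.nu, g.lam, g.Delta, cfg.deadline,
    )
    assert single == pytest.approx(trial_loglik(row, ctx), rel=1e-12)
    # permutation invariance
    shuffled = obs.sample(frac=1.0, random_state=0)
    total2, _ = dataset_loglik(shuffled, small_cohort.sessions,
                               small_cohort.items, cfg, g.nu, g.lam, g.Delta)
    assert total2 == pytest.approx(total, rel=1e-12)
    # missing parameter set -> lookup error naming the key
    with pytest.raises(KeyError, match="p000"):
        dataset_loglik(obs, small_cohort.sessions[
            small_cohort.sessions.person_id != "p000"],
            small_cohort.items, cfg, g.nu, g.lam, g.Delta)
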