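"""Generative simulator: anchored defaults, item banks, determinism, and
agreement with the analytic outcome masses."""



import numpy as np
import pytest
from scipy.stats import kendalltau

from stratddm import _kernels
from stratddm.likelihood import TrialLikelihoodContext, outcome_masses
from stratddm.params import PARAM_NAMES, to_natural
from stratddm.readwrite import write_trials
from stratddm.simulate import (ANCHOR_MEANS, default_group_params,
                               make_item_bank, simulate_cohort,
                               simulate_trial)


def test_default_locations_match_reported_summaries():
    g = default_group_params()
    nat = to_natural(g.loc)
    # log-normal locations are moment-matched: implied natural mean equals
    # the reported mean
    for k, name in enumerate(PARAM_NAMES):
        mean, sd = ANCHOR_MEANS[name]
        if name == "mu":
            implied = nat[k]
        elif name == "beta":
            implied = nat[k]  # logit location maps back to the mean proportion
        else:
            implied = float(np.exp(g.loc[k] + 0.5 * g.scale[k] ** 2))
        assert implied == pytest.approx(mean, rel=0.01)
    assert nat[0] == pytest.approx(3.91, rel=0.02)   # alpha anchor
    assert nat[4] == pytest.approx(0.54, rel=0.01)   # beta anchor
    frac = 0.07 / 0.67
    assert g.nu == pytest.approx(np.log(frac / (1 - frac)))
    assert np.allclose(g.sess_scale, 0.1 * g.scale)


def test_item_bank_construction():
    bank = make_item_bank(n_items=30, seed=5)
    assert bank["d"].mean() == pytest.approx(0.0, abs=1e-12)
    assert ((bank["sum"] >= 3) & (bank["sum"] <= 14)).all()
    assert (bank["operand_a"] + bank["operand_b"] == bank["sum"]).all()
    assert (bank["operand_a"] >= 1).all() and (bank["operand_b"] >= 1).all()
    tau = kendalltau(bank["d"], bank["sum"]).statistic
    assert tau >= 0.5
    pd0 = make_item_bank(n_items=30, seed=5)
    assert pd0.equals(bank)


def test_easy_items_easier_across_seeds():
    gaps = []
    for seed in range(100):
        bank = make_item_bank(n_items=20, seed=seed)
        easy = bank.loc[bank["difficulty_class"] == "easy", "d"]
        hard = bank.loc[bank["difficulty_class"] == "hard", "d"]
        if len(easy) and len(hard):
            gaps.append(hard.mean() - easy.mean())
    assert np.all(np.array(gaps) > 0)


def test_cohort_byte_identical_for_same_seed(tmp_path):
    a = simulate_cohort(n_persons=4, n_sessions=2, trials_per_session=10,
                        seed=9)
    b = simulate_cohort(n_persons=4, n_sessions=2, trials_per_session=10,
                        seed=9)
    fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_trials(a.observed(), fa)
    write_trials(b.observed(), fb)
    assert fa.read_bytes() == fb.read_bytes()


def test_simulate_trial_limits():
    g = default_group_params()
    p = g.typical_person()
    # mu -> +inf: every switch continues retrieval
    ctx = TrialLikelihoodContext(
        type(p)(**{**p.__dict__, "mu": 60.0}), 0.0, g.nu, g.lam, g.Delta, 5.0
    )
    for seed in range(40):
        t = simulate_trial(ctx, seed)
        assert t.true_strategy == "retrieval"
    # omega = 0, gamma beyond the deadline: no trial ever switches
    ctx2 = TrialLikelihoodContext(
        type(p)(**{**p.__dict__, "omega": 0.0, "gamma": 10.0}),
        0.0, g.nu, g.lam, g.Delta, 5.0,
    )
    for seed in range(40):
        t = simulate_trial(ctx2, seed)
        assert not t.true_switch_happened
        assert t.true_strategy == "retrieval"


def test_simulated_cells_match_analytic_masses():
    g = default_group_params()
    p = g.typical_person()
    n = 20000
    P = np.tile(p.to_array(), (n, 1))
    d = np.full(n, 0.4)
    rts, resps, strat, _ = _kernels.simulate_trials(P, d, g.nu, g.lam,
                                                    g.Delta, 5.0, 17)
    ctx = TrialLikelihoodContext(p, 0.4, g.nu, g.lam, g.Delta, 5.0)
    masses = outcome_masses(ctx).to_numpy()
    obs = np.zeros((3, 3))
    col = {1: 0, -1: 1, 0: 2}
    for s_i, r_i in zip(strat, resps):
        obs[s_i, col[r_i]] += 1
    obs /= n
    se = np.sqrt(masses * (1 - masses) / n)
    assert np.all(np.abs(obs - masses) <= 3 * se + 1e-9)


def test_no_answered_rt_at_or_beyond_deadline():
    cohort = simulate_cohort(n_persons=20, n_sessions=1,
                             trials_per_session=60, seed=2)
    answered = cohort.trials[cohort.trials["response"] != "none"]
    assert (answered["rt"] < cohort.deadline).all()
    assert (answered["rt"] > 0).all()
    censored = cohort.trials[cohort.trials["response"] == "none"]
    assert censored["rt"].isna().all()


def test_retrieval_truth_only_before_switch():
    cohort = simulate_cohort(n_persons=10, n_sessions=1,
                             trials_per_session=60, seed=4)
    pre_switch = cohort.trials[~cohort.trials["true_switch_happened"]]
    assert (pre_switch["true_strategy"] == "retrieval").all()
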