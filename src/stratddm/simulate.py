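"""Seeded generative simulator: item banks, population and session-level
parameter draws, and trial generation with ground-truth latent strategies.

Defaults emulate the study conditions: ~105 children, 3 sessions, addition
verification items with sums 3-14 (easy = sum <= 10), and group-level
parameter locations/scales anchored to the reported individual-level
posterior summaries (alpha 3.91/0.70, kappa 3.06/0.43, tau 0.66/0.32,
delta 1.49/0.44, beta 0.54/0.03, mu -0.83/1.29, omega 0.51/0.29,
gamma 0.81/0.37), mapped onto the transformed scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


from . import _kernels
from .likelihood import TrialLikelihoodContext
from .params import (GroupParams, PARAM_NAMES, lognormal_moments,
                     logit_moments, to_natural)

#: reported individual-level (mean, SD) pairs, natural scale
ANCHOR_MEANS = {
    "alpha": (3.91, 0.70),
    "kappa": (3.06, 0.43),
    "tau": (0.66, 0.32),
    "delta": (1.49, 0.44),
    "beta": (0.54, 0.03),
    "mu": (-0.83, 1.29),
    "omega": (0.51, 0.29),
    "gamma": (0.81, 0.37),
}

#: average strategy-use proportions the defaults are anchored to
USE_DECOMPOSITION = 0.07
USE_NON_RETRIEVAL = 0.67  # counting 0.60 + decomposition 0.07

STRATEGY_NAMES = ("retrieval", "counting", "decomposition")
_RESP_NAME = {1: "correct", -1: "incorrect", 0: "none"}


def default_group_params(session_jitter: float = 0.1) -> GroupParams:
    """Group-level defaults anchored to the reported parameter summaries.

    Locations/scales are the natural-scale means/SDs above mapped onto the
    transformed scales (moment-matched log-normal / delta-method logit);
    session scales default to ``session_jitter`` times the between-person
    scale.  Extras: nu is the log-odds of decomposition among
    non-retrieval use (0.07 of 0.67); lam (procedural difficulty
    coefficient), Delta (decomposition drift decrement) and sigma_d (item
    difficulty scale) are generator defaults calibrated so that simulated
    strategy-split behaviour reproduces the reported qualitative pattern
    (RT: retrieval < counting < decomposition; accuracy: counting >
    retrieval > decomposition; larger easy/hard RT gap for counting).
    """
    loc = np.empty(8)
    scale = np.empty(8)
    for k, name in enumerate(PARAM_NAMES):
        mean, sd = ANCHOR_MEANS[name]
        if name == "beta":
            loc[k], scale[k] = logit_moments(mean, sd)
        elif name == "mu":
            loc[k], scale[k] = mean, sd
        else:
            loc[k], scale[k] = lognormal_moments(mean, sd)
    frac = USE_DECOMPOSITION / USE_NON_RETRIEVAL
    nu = float(np.log(frac / (1.0 - frac)))
    return GroupParams(
        loc=loc,
        scale=scale,
        sess_scale=session_jitter * scale,
        nu=nu,
        lam=0.5,
        Delta=2.5,
        sigma_d=0.8,
    )


def make_item_bank(n_items: int = 24, seed: int = 0,
                   sigma_d: float | None = None,
                   size_weight: float = 0.82) -> pd.DataFrame:
    """Random addition-verification item bank with sums in 3..14.

    Item difficulty d is centered (mean exactly 0), has SD sigma_d, and is
    rank-correlated with the problem sum through ``size_weight`` (the
    share of the difficulty signal carried by problem size).
    """
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if sigma_d is None:
        sigma_d = default_group_params().sigma_d
    rng = np.random.default_rng(seed)
    sums = rng.integers(3, 15, size=n_items)
    operand_a = np.array([rng.integers(1, s) for s in sums])
    operand_b = sums - operand_a
    z_sum = (sums - sums.mean()) / max(sums.std(), 1e-12)
    raw = size_weight * z_sum + np.sqrt(1.0 - size_weight ** 2) * rng.standard_normal(
        n_items
    )
    d = sigma_d * (raw - raw.mean()) / max(raw.std(), 1e-12)
    return pd.DataFrame(
        {
            "item_id": [f"i{k:03d}" for k in range(n_items)],
            "operand_a": operand_a,
            "operand_b": operand_b,
            "sum": sums,
            "difficulty_class": np.where(sums <= 10, "easy", "hard"),
            "d": d,
        }
    )


def draw_cohort_params(group: GroupParams, n_persons: int, n_sessions: int,
                       rng: np.random.Generator):
    """Draw person- and session-level parameters on the transformed scales;
    returns (persons, sessions) DataFrames with natural-scale columns."""
    th_person = group.loc + group.scale * rng.standard_normal((n_persons, 8))
    th_sess = (
        th_person[:, None, :]
        + group.sess_scale * rng.standard_normal((n_persons, n_sessions, 8))
    )
    person_ids = [f"p{k:03d}" for k in range(n_persons)]
    session_ids = [f"s{k + 1}" for k in range(n_sessions)]
    persons = pd.DataFrame(to_natural(th_person), columns=list(PARAM_NAMES))
    persons.insert(0, "person_id", person_ids)
    rows = []
    for i, pid in enumerate(person_ids):
        for j, sid in enumerate(session_ids):
            rows.append((pid, sid, *to_natural(th_sess[i, j])))
    sessions = pd.DataFrame(rows, columns=["person_id", "session_id", *PARAM_NAMES])
    return persons, sessions


@dataclass
class SimulatedCohort:
    """A simulated dataset plus its ground truth."""

    trials: pd.DataFrame       # observed columns + true_strategy, true_switch_happened
    persons: pd.DataFrame      # person-level natural-scale truth
    sessions: pd.DataFrame     # session-level natural-scale truth
    items: pd.DataFrame        # item bank with difficulty d
    group: GroupParams
    seed: int
    deadline: float

    def observed(self) -> pd.DataFrame:
        """The trial table as a fitting routine would see it."""
        return self.trials[
            ["person_id", "session_id", "item_id", "rt", "response"]
        ].copy()


def simulate_cohort(group: GroupParams | None = None, n_persons: int = 105,
                    n_sessions: int = 3, item_bank: pd.DataFrame | None = None,
                    trials_per_session: int = 60, seed: int = 0,
                    deadline: float = 5.0) -> SimulatedCohort:
    """Simulate a full cohort; reproducible to the byte given the seed."""
    if min(n_persons, n_sessions, trials_per_session) < 1:
        raise ValueError("all counts must be >= 1")
    if group is None:
        group = default_group_params()
    rng = np.random.default_rng(seed)
    if item_bank is None:
        item_bank = make_item_bank(
            seed=int(rng.integers(2 ** 31)), sigma_d=group.sigma_d
        )
    persons, sessions = draw_cohort_params(group, n_persons, n_sessions, rng)
    n_ps = n_persons * n_sessions
    n_trials = n_ps * trials_per_session
    item_idx = rng.integers(0, len(item_bank), size=n_trials)
    P_nat = np.repeat(
        sessions[list(PARAM_NAMES)].to_numpy(dtype=float), trials_per_session, axis=0
    )
    d_tr = item_bank["d"].to_numpy()[item_idx]
    kernel_seed = int(rng.integers(2 ** 31))
    rts, resps, strat, switched = _kernels.simulate_trials(
        np.ascontiguousarray(P_nat), d_tr, group.nu, group.lam, group.Delta,
        deadline, kernel_seed,
    )
    ids = sessions[["person_id", "session_id"]].to_numpy()
    trials = pd.DataFrame(
        {
            "person_id": np.repeat(ids[:, 0], trials_per_session),
            "session_id": np.repeat(ids[:, 1], trials_per_session),
            "item_id": item_bank["item_id"].to_numpy()[item_idx],
            "rt": rts,
            "response": [_RESP_NAME[c] for c in resps],
            "true_strategy": [STRATEGY_NAMES[s] for s in strat],
            "true_switch_happened": switched.astype(bool),
        }
    )
    return SimulatedCohort(
        trials=trials, persons=persons, sessions=sessions, items=item_bank,
        group=group, seed=seed, deadline=deadline,
    )


def simulate_trials_from_sessions(sessions: pd.DataFrame,
                                  item_bank: pd.DataFrame,
                                  trials_per_session: int, seed: int,
                                  deadline: float = 5.0,
                                  group: GroupParams | None = None
                                  ) -> pd.DataFrame:
    """Generate trials for explicitly given session-level parameters
    (natural scale), e.g. to inject exact parameter changes between
    timepoints.  Returns a trial table with ground-truth columns."""
    if group is None:
        group = default_group_params()
    rng = np.random.default_rng(seed)
    n_ps = len(sessions)
    n_trials = n_ps * trials_per_session
    item_idx = rng.integers(0, len(item_bank), size=n_trials)
    P_nat = np.repeat(
        sessions[list(PARAM_NAMES)].to_numpy(dtype=float), trials_per_session,
        axis=0,
    )
    d_tr = item_bank["d"].to_numpy()[item_idx]
    rts, resps, strat, switched = _kernels.simulate_trials(
        np.ascontiguousarray(P_nat), d_tr, group.nu, group.lam, group.Delta,
        deadline, int(rng.integers(2 ** 31)),
    )
    ids = sessions[["person_id", "session_id"]].to_numpy()
    return pd.DataFrame(
        {
            "person_id": np.repeat(ids[:, 0], trials_per_session),
            "session_id": np.repeat(ids[:, 1], trials_per_session),
            "item_id": item_bank["item_id"].to_numpy()[item_idx],
            "rt": rts,
            "response": [_RESP_NAME[c] for c in resps],
            "true_strategy": [STRATEGY_NAMES[s] for s in strat],
            "true_switch_happened": switched.astype(bool),
        }
    )


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated trial with its latent ground truth."""

    rt: float            # NaN when censored
    response: str
    true_strategy: str
    true_switch_happened: bool


def simulate_trial(ctx: TrialLikelihoodContext, seed: int) -> SimulatedTrial:
    """Simulate a single trial under a likelihood context."""
    P = ctx.person.to_array()[None, :]
    d = np.array([ctx.item_d])
    rts, resps, strat, switched = _kernels.simulate_trials(
        P, d, ctx.nu, ctx.lam, ctx.Delta, ctx.deadline, seed
    )
    return SimulatedTrial(
        rt=float(rts[0]),
        response=_RESP_NAME[int(resps[0])],
        true_strategy=STRATEGY_NAMES[int(strat[0])],
        true_switch_happened=bool(switched[0]),
    )
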