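"""Validation machinery at desk scale: supervised RT-cutoff benchmarking,
rank-consistency statistics between strategy-use profiles, the
crossing-vs-cutoff comparison, the reliability (ICC) pattern study, and
the end-to-end parameter-recovery harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, pearsonr

from .errors import DataValidationError
from .likelihood import TrialLikelihoodContext, likelihood_crossing_rt
from .measures import behavioural_session_summaries, icc
from .params import PARAM_NAMES
from .readwrite import RunConfig
from .simulate import simulate_cohort


def optimal_rt_cutoff(rts, labels) -> tuple[float, float]:
    """Supervised RT threshold: trials with rt below the threshold are
    called retrieval; returns (threshold, error_rate) minimizing
    misclassification.

    Candidate thresholds are the midpoints between adjacent sorted
    distinct RTs (plus open ends); ties are broken by the midpoint of the
    optimal threshold interval.
    """
    rts = np.asarray(rts, dtype=float)
    lab = np.asarray(labels)
    is_ret = lab == "retrieval" if lab.dtype.kind in "UO" else lab.astype(bool)
    if is_ret.all() or (~is_ret).all():
        raise DataValidationError("both labels must be present")
    distinct = np.unique(rts)
    if len(distinct) > 1:
        inner = 0.5 * (distinct[:-1] + distinct[1:])
        gap = np.median(np.diff(distinct))
    else:
        inner = np.empty(0)
        gap = 1.0
    cands = np.concatenate([[distinct[0] - gap], inner, [distinct[-1] + gap]])
    errs = np.array([np.sum((rts < c) != is_ret) for c in cands])
    best = errs.min()
    ok = np.flatnonzero(errs == best)
    runs = np.split(ok, np.flatnonzero(np.diff(ok) > 1) + 1)
    longest = max(runs, key=len)
    thr = 0.5 * (cands[longest[0]] + cands[longest[-1]])
    return float(thr), float(best / len(rts))


def rank_consistency(profile_a, profile_b) -> tuple[float, float]:
    """(Kendall tau-b, MSE) between two retrieval-use profiles over the
    same units (pandas Series aligned on index, or equal-length arrays)."""
    if isinstance(profile_a, pd.Series) and isinstance(profile_b, pd.Series):
        if set(profile_a.index) != set(profile_b.index):
            raise DataValidationError("profiles cover different units")
        profile_b = profile_b.reindex(profile_a.index)
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise DataValidationError("profiles must share >= 2 units")
    tau = kendalltau(a, b).statistic
    mse = float(np.mean((a - b) ** 2))
    return float(tau), mse


@dataclass
class CrossingCutoffReport:
    crossing_rt: float | None       # trial-weighted median over items
    cutoff_rt: float | None
    cutoff_error: float | None
    difference: float | None
    per_item_crossing: dict = field(default_factory=dict)
    notes: str = ""


def crossing_vs_cutoff(cohort, params=None, deadline: float | None = None
                       ) -> CrossingCutoffReport:
    """Compare the model's likelihood-crossing RT with the supervised
    optimal RT cutoff on a simulated cohort with ground-truth strategies.

    ``params`` defaults to the cohort's group-typical person (its
    generating group locations); per-item crossings are aggregated as the
    answered-trial-weighted median.
    """
    group = cohort.group
    person = group.typical_person() if params is None else params
    deadline = cohort.deadline if deadline is None else deadline
    per_item = {}
    for row in cohort.items.itertuples(index=False):
        ctx = TrialLikelihoodContext(person, row.d, group.nu, group.lam,
                                     group.Delta, deadline)
        per_item[row.item_id] = likelihood_crossing_rt(ctx)
    ans = cohort.trials[cohort.trials["response"] != "none"]
    notes = []
    crossings = ans["item_id"].map(per_item).dropna()
    crossing = float(np.median(crossings)) if len(crossings) else None
    if crossing is None:
        notes.append("no-crossing flag on every item")
    labels = ans["true_strategy"] == "retrieval"
    if labels.all() or (~labels).all():
        cutoff = err = None
        notes.append("cutoff undefined: only one strategy class present")
    else:
        cutoff, err = optimal_rt_cutoff(ans["rt"].to_numpy(), labels.to_numpy())
    diff = (abs(crossing - cutoff)
            if crossing is not None and cutoff is not None else None)
    return CrossingCutoffReport(crossing, cutoff, err, diff, per_item,
                                "; ".join(notes))


def reliability_pattern(n_cohorts: int = 50, n_persons: int = 20,
                        n_sessions: int = 3, trials_per_session: int = 40,
                        seed: int = 0) -> pd.DataFrame:
    """Between-session consistency ICC of the metacognitive parameters
    (mu, gamma, omega; session-level ground truth) versus model-free
    behavioural summaries (median RT, accuracy) on the same simulated
    cohorts.  One row per cohort."""
    rows = []
    for rep in range(n_cohorts):
        cohort = simulate_cohort(
            n_persons=n_persons, n_sessions=n_sessions,
            trials_per_session=trials_per_session,
            seed=int(np.random.default_rng([seed, rep]).integers(2 ** 31)),
        )
        row = {"cohort": rep}
        for par in ("mu", "gamma", "omega"):
            wide = cohort.sessions.pivot(index="person_id",
                                         columns="session_id", values=par)
            row[f"icc_{par}"] = icc(wide.to_numpy(), "consistency")
        beh = behavioural_session_summaries(cohort.observed())
        for meas in ("median_rt", "accuracy"):
            wide = beh.pivot(index="person_id", columns="session_id",
                             values=meas)
            row[f"icc_{meas}"] = icc(wide.to_numpy(), "consistency")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Parameter-recovery results: per-parameter aggregate correlation,
    bias and RMSE plus per-replicate detail and any stage failures."""

    per_parameter: pd.DataFrame
    per_replicate: pd.DataFrame
    failures: list = field(default_factory=list)


def parameter_recovery(n_persons: int = 20, n_sessions: int = 3,
                       trials_per_session: int = 60, seeds=(0, 1, 2, 3, 4),
                       config: RunConfig | None = None) -> RecoveryReport:
    """Simulate -> fit -> compare person-level posterior means to truth,
    aggregated across replicate seeds (median of per-seed correlations).
    A failure in one replicate is recorded and the loop continues."""
    from .inference import fit_hierarchical

    if config is None:
        config = RunConfig()
    detail = []
    failures = []
    for seed in seeds:
        try:
            cohort = simulate_cohort(
                n_persons=n_persons, n_sessions=n_sessions,
                trials_per_session=trials_per_session, seed=seed,
                deadline=config.deadline,
            )
            cfg = RunConfig(**{**config.__dict__, "seed": int(seed) + 1})
            samples, _ = fit_hierarchical(
                cohort.observed(), cohort.items[["item_id"]], cfg
            )
            est = samples.person_natural()
            m = cohort.persons.merge(est, on="person_id",
                                     suffixes=("_true", "_est"))
            for par in PARAM_NAMES:
                t = m[f"{par}_true"].to_numpy()
                e = m[f"{par}_est"].to_numpy()
                detail.append({
                    "seed": seed, "parameter": par,
                    "r": float(pearsonr(t, e).statistic),
                    "bias": float(np.mean(e - t)),
                    "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
                    "n_persons": n_persons, "n_sessions": n_sessions,
                    "trials_per_session": trials_per_session,
                })
        except Exception as exc:  # keep the harness running
            failures.append({"seed": seed, "error": repr(exc)})
    per_rep = pd.DataFrame(detail)
    if len(per_rep):
        agg = per_rep.groupby("parameter", sort=False).agg(
            r_median=("r", "median"), r_mean=("r", "mean"),
            bias=("bias", "mean"), rmse=("rmse", "mean"),
        ).reset_index()
        order = {p: i for i, p in enumerate(PARAM_NAMES)}
        agg = agg.sort_values(by="parameter", key=lambda s: s.map(order))
    else:
        agg = pd.DataFrame(
            columns=["parameter", "r_median", "r_mean", "bias", "rmse"]
        )
    return RecoveryReport(per_parameter=agg.reset_index(drop=True),
                          per_replicate=per_rep, failures=failures)
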