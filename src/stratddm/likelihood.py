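"""The mixture trial likelihood: retrieval-first accumulation, a
difficulty-dependent switching time, probabilistic three-way strategy
selection at the switch point, deadline censoring, and trial-level
posterior strategy responsibilities.

Generative structure of one trial (decision clock starts after the
non-decision time tau):

1. A retrieval accumulator (drift ``delta - d``, threshold alpha, start
   bias beta) runs from time 0.
2. If it is unresolved at the switching time ``s = max(gamma + omega*d,
   1 ms)``, a strategy is selected with probabilities from
   :func:`selection_probs`: continue retrieval (the same accumulator keeps
   running), or restart a fresh accumulator with the counting or
   decomposition drift.
3. Any trial whose accumulator has not resolved by the deadline is
   censored (``response = none``).

The likelihood of an answered trial at decision time u > s is therefore

    p_r * f_R(u) + S_R(s) * [p_c * f_C(u - s) + p_d * f_D(u - s)]

where S_R(s), the probability that retrieval is still unresolved at the
switch point, gates the restarted branches (for the continue-retrieval
branch the conditioning survival cancels: S_R(s) * f_R(u)/S_R(s)).
Censored trials contribute the analogous survival mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import expit

from . import _kernels, _wfpt
from .errors import DataValidationError, DegenerateTrialError
from .params import PARAM_NAMES, PersonParams
from .readwrite import RunConfig, TrialRecord

_RESP_CODE = {"correct": 1, "incorrect": -1, "none": 0}


@dataclass(frozen=True)
class TrialLikelihoodContext:
    """Everything needed to score one trial: the person's parameters, the
    item difficulty, the group-level extras and the deadline."""

    person: PersonParams
    item_d: float
    nu: float
    lam: float
    Delta: float
    deadline: float

    def __post_init__(self):
        if self.lam < 0 or self.Delta < 0:
            raise ValueError("lam and Delta must be >= 0")
        if not self.deadline > 0:
            raise ValueError("deadline must be > 0")


@dataclass(frozen=True)
class StrategyResponsibilities:
    """Posterior probability that a trial was solved by each strategy,
    and the entropy (nats) of that distribution."""

    p_retrieval: float
    p_counting: float
    p_decomposition: float
    entropy_nat: float


def retrieval_drift(delta: float, d: float) -> float:
    """Retrieval accumulator drift: base efficiency minus a linear
    difficulty penalty (unit coefficient on d, the identification
    convention)."""
    return delta - d


def procedural_drifts(kappa: float, d: float, lam: float, Delta: float):
    """(counting, decomposition) drifts: kappa - lam*d and the same minus
    the decomposition decrement Delta."""
    if lam < 0 or Delta < 0:
        raise ValueError("lam and Delta must be >= 0")
    v_count = kappa - lam * d
    return v_count, v_count - Delta


def switch_time(gamma: float, omega: float, d: float) -> float:
    """Switching latency from accumulation onset: gamma + omega*d, clamped
    at 1 ms."""
    if not gamma > 0 or omega < 0:
        raise ValueError("gamma must be > 0 and omega >= 0")
    return max(gamma + omega * d, _kernels.SWITCH_EPS)


def selection_probs(mu: float, d: float, nu: float):
    """(retrieval, counting, decomposition) selection probabilities at the
    switch point: logistic(mu - d) for retrieval; the remainder split by
    logistic(nu) toward decomposition."""
    p_ret = float(expit(mu - d))
    p_dec = (1.0 - p_ret) * float(expit(nu))
    p_count = (1.0 - p_ret) - p_dec
    return p_ret, p_count, p_dec


def _trial_args(trial, ctx: TrialLikelihoodContext):
    if isinstance(trial, TrialRecord):
        rt, response = trial.rt, trial.response
    else:  # namedtuple / dataframe row
        rt, response = trial.rt, trial.response
    code = _RESP_CODE[response]
    if code != 0:
        if rt is None or (isinstance(rt, float) and math.isnan(rt)):
            raise DataValidationError("answered trial without rt")
        if rt >= ctx.deadline:
            raise DataValidationError(
                f"answered trial with rt {rt} >= deadline {ctx.deadline}; "
                "it should have been censored"
            )
        rt = float(rt)
    else:
        rt = np.nan
    p = ctx.person
    return (
        rt, code,
        p.alpha, p.kappa, p.tau, p.delta, p.beta, p.mu, p.omega, p.gamma,
        ctx.item_d, ctx.nu, ctx.lam, ctx.Delta, ctx.deadline,
    )


def trial_loglik(trial, ctx: TrialLikelihoodContext) -> float:
    """Log-likelihood of one trial; -inf (never an exception) for trials
    with rt <= tau."""
    return float(_kernels.trial_loglik(*_trial_args(trial, ctx)))


def trial_strategy_components(trial, ctx: TrialLikelihoodContext):
    """Unnormalized (retrieval, counting, decomposition) component masses;
    their sum is the trial likelihood."""
    return _kernels.trial_components(*_trial_args(trial, ctx))


def _entropy_nat(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() + 0.0)


def trial_responsibilities(trial, ctx: TrialLikelihoodContext,
                           mode: str = "posterior") -> StrategyResponsibilities:
    """Posterior strategy responsibilities for one trial.

    mode="posterior" (default) normalizes the likelihood components given
    the observed RT and accuracy; mode="prior" uses the selection
    probabilities at the switch point instead (still accounting for
    resolution before the switch).
    """
    if mode == "prior":
        comps = np.array(_prior_components(trial, ctx))
    else:
        comps = np.array(trial_strategy_components(trial, ctx))
    tot = comps.sum()
    if tot <= 0:
        raise DegenerateTrialError(
            f"all strategy components vanished for trial {trial!r}"
        )
    p = comps / tot
    return StrategyResponsibilities(p[0], p[1], p[2], _entropy_nat(p))


def _prior_components(trial, ctx):
    """Pre-data strategy probabilities: resolution before the switch or
    selection at it."""
    p = ctx.person
    s = switch_time(p.gamma, p.omega, ctx.item_d)
    v_r = retrieval_drift(p.delta, ctx.item_d)
    surv_s = _wfpt.survival(s, v_r, p.alpha, p.beta)
    p_ret, p_count, p_dec = selection_probs(p.mu, ctx.item_d, ctx.nu)
    return (
        (1.0 - surv_s) + surv_s * p_ret,
        surv_s * p_count,
        surv_s * p_dec,
    )


def likelihood_crossing_rt(ctx: TrialLikelihoodContext, boundary: str = "upper",
                           tol: float = 1e-4):
    """Smallest rt > tau + s at which the retrieval and non-retrieval
    likelihood components are equal, or None if their difference never
    changes sign before the deadline."""
    p = ctx.person
    s = switch_time(p.gamma, p.omega, ctx.item_d)
    U = ctx.deadline - p.tau
    if U <= s:
        return None
    p_ret, p_count, p_dec = selection_probs(p.mu, ctx.item_d, ctx.nu)
    if p_ret < 1e-12:  # structurally absent retrieval branch
        return None
    v_r = retrieval_drift(p.delta, ctx.item_d)
    v_c, v_d = procedural_drifts(p.kappa, ctx.item_d, ctx.lam, ctx.Delta)
    surv_s = _wfpt.survival(s, v_r, p.alpha, p.beta)
    upper = boundary == "upper"

    def gap(u):
        f_r = _wfpt.pdf_boundary(u, v_r, p.alpha, p.beta, upper)
        f_c = _wfpt.pdf_boundary(u - s, v_c, p.alpha, p.beta, upper)
        f_d = _wfpt.pdf_boundary(u - s, v_d, p.alpha, p.beta, upper)
        return p_ret * f_r - surv_s * (p_count * f_c + p_dec * f_d)

    grid = np.linspace(s + 1e-6, U, 400)
    vals = np.array([gap(u) for u in grid])
    sign = np.sign(vals)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(changes) == 0:
        return None
    lo, hi = grid[changes[0]], grid[changes[0] + 1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(lo) * gap(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return float(p.tau + 0.5 * (lo + hi))


def dataset_loglik(trials: pd.DataFrame, params: pd.DataFrame,
                   items: pd.DataFrame, config: RunConfig,
                   nu: float, lam: float, Delta: float):
    """Total log-likelihood of a tidy trial table.

    ``params`` has one row per person(-session) with the eight parameter
    columns; ``items`` carries item_id and difficulty d.  Returns
    (total, n_flagged); flagged (-inf) trials propagate without raising.
    """
    if len(trials) == 0:
        return 0.0, 0
    key_cols = ["person_id"] + (
        ["session_id"] if "session_id" in params.columns else []
    )
    merged = trials.merge(params, on=key_cols, how="left", validate="many_to_one")
    if merged[list(PARAM_NAMES)].isna().any(axis=None):
        bad = merged.loc[merged[PARAM_NAMES[0]].isna(), key_cols].iloc[0].tolist()
        raise KeyError(f"no parameters for {tuple(zip(key_cols, bad))}")
    merged = merged.merge(items[["item_id", "d"]], on="item_id", how="left",
                          validate="many_to_one")
    if merged["d"].isna().any():
        bad = merged.loc[merged["d"].isna(), "item_id"].iloc[0]
        raise KeyError(f"no item difficulty for item_id {bad!r}")
    answered = merged["response"] != "none"
    if (merged.loc[answered, "rt"] >= config.deadline).any():
        raise DataValidationError("answered trial with rt >= deadline")
    rt = merged["rt"].to_numpy(dtype=float)
    resp = merged["response"].map(_RESP_CODE).to_numpy(dtype=np.int64)
    P = np.ascontiguousarray(merged[list(PARAM_NAMES)].to_numpy(dtype=float))
    d_tr = merged["d"].to_numpy(dtype=float)
    out = np.empty(len(merged))
    total, n_flag = _kernels.ll_rows(
        rt, resp, P, d_tr, float(nu), float(lam), float(Delta),
        float(config.deadline), out,
    )
    return float(total), int(n_flag)


def responsibilities_table(trials: pd.DataFrame, params: pd.DataFrame,
                           items: pd.DataFrame, config: RunConfig,
                           nu: float, lam: float, Delta: float,
                           mode: str = "posterior") -> pd.DataFrame:
    """Per-trial strategy responsibilities and entropy for a trial table."""
    key_cols = ["person_id"] + (
        ["session_id"] if "session_id" in params.columns else []
    )
    merged = trials.merge(params, on=key_cols, how="left", validate="many_to_one")
    merged = merged.merge(items[["item_id", "d"]], on="item_id", how="left",
                          validate="many_to_one")
    if merged[list(PARAM_NAMES) + ["d"]].isna().any(axis=None):
        raise KeyError("missing parameters or item difficulty for some trials")
    if mode == "posterior":
        rt = merged["rt"].to_numpy(dtype=float)
        resp = merged["response"].map(_RESP_CODE).to_numpy(dtype=np.int64)
        P = np.ascontiguousarray(merged[list(PARAM_NAMES)].to_numpy(dtype=float))
        d_tr = merged["d"].to_numpy(dtype=float)
        comps = _kernels.components_rows(
            rt, resp, P, d_tr, float(nu), float(lam), float(Delta),
            float(config.deadline),
        )
    else:
        comps = np.array(
            [
                _prior_components(
                    row,
                    TrialLikelihoodContext(
                        PersonParams.from_array(
                            np.array([getattr(row, n) for n in PARAM_NAMES])
                        ),
                        row.d, nu, lam, Delta, config.deadline,
                    ),
                )
                for row in merged.itertuples(index=False)
            ]
        )
    tot = comps.sum(axis=1)
    if np.any(tot <= 0):
        bad = merged.iloc[int(np.flatnonzero(tot <= 0)[0])]
        raise DegenerateTrialError(
            f"all strategy components vanished for trial {bad.to_dict()!r}"
        )
    p = comps / tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1) + 0.0
    out = trials.reset_index(drop=True).copy()
    out["p_retrieval"] = p[:, 0]
    out["p_counting"] = p[:, 1]
    out["p_decomposition"] = p[:, 2]
    out["entropy_nat"] = ent
    return out


def outcome_masses(ctx: TrialLikelihoodContext) -> pd.DataFrame:
    """Analytic probability of each strategy x outcome cell, by adaptive
    quadrature of the mixture components.  Rows: retrieval, counting,
    decomposition; columns: correct, incorrect, none.  Sums to 1."""
    p = ctx.person
    s = switch_time(p.gamma, p.omega, ctx.item_d)
    U = ctx.deadline - p.tau
    v_r = retrieval_drift(p.delta, ctx.item_d)
    v_c, v_d = procedural_drifts(p.kappa, ctx.item_d, ctx.lam, ctx.Delta)
    p_ret, p_count, p_dec = selection_probs(p.mu, ctx.item_d, ctx.nu)
    cells = np.zeros((3, 3))
    if U <= 0:
        cells[0, 2] = 1.0
    elif U <= s:
        for col, upper in ((0, True), (1, False)):
            cells[0, col] = quad(
                lambda t: _wfpt.pdf_boundary(t, v_r, p.alpha, p.beta, upper),
                0, U, limit=200,
            )[0]
        cells[0, 2] = _wfpt.survival(U, v_r, p.alpha, p.beta)
    else:
        surv_s = _wfpt.survival(s, v_r, p.alpha, p.beta)
        for col, upper in ((0, True), (1, False)):
            pre = quad(
                lambda t: _wfpt.pdf_boundary(t, v_r, p.alpha, p.beta, upper),
                0, s, limit=200,
            )[0]
            post = quad(
                lambda t: _wfpt.pdf_boundary(t, v_r, p.alpha, p.beta, upper),
                s, U, limit=200,
            )[0]
            cells[0, col] = pre + p_ret * post
            cells[1, col] = surv_s * p_count * quad(
                lambda t: _wfpt.pdf_boundary(t, v_c, p.alpha, p.beta, upper),
                0, U - s, limit=200,
            )[0]
            cells[2, col] = surv_s * p_dec * quad(
                lambda t: _wfpt.pdf_boundary(t, v_d, p.alpha, p.beta, upper),
                0, U - s, limit=200,
            )[0]
        cells[0, 2] = p_ret * _wfpt.survival(U, v_r, p.alpha, p.beta)
        cells[1, 2] = surv_s * p_count * _wfpt.survival(U - s, v_c, p.alpha, p.beta)
        cells[2, 2] = surv_s * p_dec * _wfpt.survival(U - s, v_d, p.alpha, p.beta)
    return pd.DataFrame(
        cells,
        index=["retrieval", "counting", "decomposition"],
        columns=["correct", "incorrect", "none"],
    )
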