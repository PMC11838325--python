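"""Hierarchical Bayesian estimation by blocked adaptive Metropolis.

Model (transformed scales: log for the positive parameters, logit for the
start bias, identity for the retrieval propensity):

    group location  M_k   ~ Normal(0, loc_prior_sd)          k = 1..8
    group scale     S_k   ~ half-Normal(scale_prior_sd)
    session scale sess_k  ~ half-Normal(scale_prior_sd)
    person level  th_p,k  ~ Normal(M_k, S_k)
    session level th_ps,k ~ Normal(th_p,k, sess_k)
    item scale  sigma_d   ~ half-Normal(scale_prior_sd)
    item difficulty d_i   ~ Normal(0, sigma_d)
    extras: nu ~ Normal(0, extras_prior_sd); lambda, Delta half-Normal
    trials: the mixture likelihood of :mod:`stratddm.likelihood`

The sampler is gradient-free, robust to the likelihood's kink at the
switching time: Metropolis-within-Gibbs with one random-walk block per
person-session, one per item, one for the group extras, conjugate Gibbs
steps for person-level means and group locations, and log-scale random
walks for the scale parameters.  Proposal steps follow Robbins-Monro
adaptation toward an acceptance rate of 0.3 during warmup only; all
tuning is frozen before retained draws.  With a single session per person
the session layer is dropped and persons are sampled directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .errors import DataValidationError, StratDDMError
from .params import PARAM_NAMES, to_natural
from .readwrite import RunConfig

_RESP_CODE = {"correct": 1, "incorrect": -1, "none": 0}

#: static proposal scales per transformed parameter (used when the session
#: layer is absent; with sessions the session scale bounds the step)
_BASE_STEP = np.array([0.05, 0.05, 0.04, 0.08, 0.08, 0.5, 0.3, 0.1])

_TARGET_ACC = 0.3


def _rm_rate(t: int) -> float:
    return (t + 1.0) ** -0.7


@dataclass
class PosteriorSamples:
    """Post-warmup draws on the transformed scales.

    ``draws`` maps names to arrays with leading (chain, draw) axes:
    theta_ps (.., n_ps, 8), theta_person (.., n_person, 8; only with a
    session layer), M, S, sess_sd (.., 8), d (.., n_items), extras
    (.., 3: nu, log lambda, log Delta), sigma_d (..,).
    """

    draws: dict
    person_ids: list
    session_keys: list            # (person_id, session_id) per ps block
    item_ids: list
    use_sessions: bool
    fixed_item_d: Optional[np.ndarray]
    seed: int
    warmup: int
    acceptance: dict
    priors: dict

    def person_natural(self) -> pd.DataFrame:
        """Posterior-mean person-level parameters on the natural scale."""
        key = "theta_person" if self.use_sessions else "theta_ps"
        arr = self.draws[key]
        nat = to_natural(arr).mean(axis=(0, 1))
        out = pd.DataFrame(nat, columns=list(PARAM_NAMES))
        out.insert(0, "person_id", self.person_ids)
        return out

    def session_natural(self) -> pd.DataFrame:
        """Posterior-mean person-session parameters on the natural scale."""
        nat = to_natural(self.draws["theta_ps"]).mean(axis=(0, 1))
        out = pd.DataFrame(nat, columns=list(PARAM_NAMES))
        out.insert(0, "person_id", [k[0] for k in self.session_keys])
        out.insert(1, "session_id", [k[1] for k in self.session_keys])
        return out

    def item_d(self) -> pd.DataFrame:
        if self.fixed_item_d is not None:
            d = self.fixed_item_d
            fixed = True
        else:
            d = self.draws["d"].mean(axis=(0, 1))
            fixed = False
        return pd.DataFrame({"item_id": self.item_ids, "d": d, "fixed": fixed})

    def extras_mean(self) -> tuple:
        ex = self.draws["extras"].mean(axis=(0, 1))
        return float(ex[0]), float(math.exp(ex[1])), float(math.exp(ex[2]))


@dataclass
class FitReport:
    """Posterior summaries and convergence diagnostics per parameter."""

    summary: pd.DataFrame         # name, mean, sd, q2.5, q97.5, rhat, ess, flag
    priors: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def flagged(self) -> pd.DataFrame:
        return self.summary[self.summary["flag"] != ""]


def log_prior(theta_ps, theta_person, M, S, sess_sd, d, sigma_d, extras,
              config: RunConfig, use_sessions: bool = True) -> float:
    """Joint log-density of all levels above the likelihood (unnormalized
    only by constants).  -inf when a scale is non-positive with
    non-degenerate lower levels."""
    def norm(x, m, s):
        x = np.asarray(x, dtype=float)
        if np.any(s <= 0):
            dev = np.asarray(x - m)
            return -np.inf if np.any(dev != 0) else np.inf
        return float(np.sum(-np.log(s) - 0.5 * ((x - m) / s) ** 2))

    lp = norm(M, 0.0, config.loc_prior_sd)
    for s in np.atleast_1d(S):
        lp += -0.5 * (s / config.scale_prior_sd) ** 2 if s > 0 else -np.inf
    lp += norm(theta_person, M, S) if use_sessions else 0.0
    if use_sessions:
        for s in np.atleast_1d(sess_sd):
            lp += -0.5 * (s / config.scale_prior_sd) ** 2 if s > 0 else -np.inf
        lp += norm(theta_ps, theta_person[..., None, :]
                   if theta_person.ndim == 2 and theta_ps.ndim == 3
                   else theta_person, sess_sd)
    else:
        lp += norm(theta_ps, M, S)
    lp += -0.5 * (sigma_d / config.scale_prior_sd) ** 2 if sigma_d > 0 else -np.inf
    lp += norm(d, 0.0, sigma_d)
    nu, llam, ldec = extras
    lp += norm(nu, 0.0, config.extras_prior_sd)
    lp += -0.5 * (math.exp(llam) / config.extras_prior_sd) ** 2 + llam
    lp += -0.5 * (math.exp(ldec) / config.extras_prior_sd) ** 2 + ldec
    return float(lp)


def _prepare_arrays(trials: pd.DataFrame, items: pd.DataFrame):
    """Sort trials into contiguous person-session blocks and CSR item lists."""
    t = trials.copy()
    answered = t["response"] != "none"
    t["_resp"] = t["response"].map(_RESP_CODE)
    if t["_resp"].isna().any():
        raise DataValidationError("unknown response code in trials")
    person_ids = sorted(t["person_id"].unique())
    keys = (
        t[["person_id", "session_id"]]
        .drop_duplicates()
        .sort_values(["person_id", "session_id"])
    )
    session_keys = list(map(tuple, keys.to_numpy()))
    ps_index = {k: j for j, k in enumerate(session_keys)}
    t["_ps"] = [ps_index[(p, s)] for p, s in zip(t["person_id"], t["session_id"])]
    item_ids = list(items["item_id"])
    item_index = {k: m for m, k in enumerate(item_ids)}
    unknown = set(t["item_id"]) - set(item_ids)
    if unknown:
        raise DataValidationError(f"trial item_id(s) not in item table: {sorted(unknown)}")
    t["_item"] = t["item_id"].map(item_index)
    t = t.sort_values(["_ps"], kind="stable").reset_index(drop=True)
    rt = t["rt"].to_numpy(dtype=float)
    resp = t["_resp"].to_numpy(dtype=np.int64)
    ps = t["_ps"].to_numpy(dtype=np.int64)
    n_ps = len(session_keys)
    ps_start = np.searchsorted(ps, np.arange(n_ps), side="left").astype(np.int64)
    ps_end = np.searchsorted(ps, np.arange(n_ps), side="right").astype(np.int64)
    item_of_trial = t["_item"].to_numpy(dtype=np.int64)
    order = np.argsort(item_of_trial, kind="stable")
    counts = np.bincount(item_of_trial, minlength=len(item_ids))
    item_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    item_trials = order.astype(np.int64)
    person_of_ps = np.array(
        [person_ids.index(k[0]) for k in session_keys], dtype=np.int64
    )
    # ps blocks are sorted by person, so each person's blocks are contiguous
    n_person = len(person_ids)
    pp_start = np.searchsorted(person_of_ps, np.arange(n_person)).astype(np.int64)
    pp_end = np.searchsorted(
        person_of_ps, np.arange(n_person), side="right"
    ).astype(np.int64)
    return (t, rt, resp, ps_start, ps_end, item_ptr, item_trials,
            person_of_ps, pp_start, pp_end, person_ids, session_keys,
            item_ids, item_of_trial)


def _scale_mh(cur, ss, n, prior_sd, step, rng):
    """Vectorized log-random-walk update for scale parameters given the
    sum of squared deviations ``ss`` over ``n`` terms each."""
    cur = np.atleast_1d(np.asarray(cur, dtype=float))
    prop = cur * np.exp(step * rng.standard_normal(cur.shape))

    def logp(s):
        return (-n * np.log(s) - ss / (2.0 * s ** 2)
                - 0.5 * (s / prior_sd) ** 2 + np.log(s))

    lacc = logp(prop) - logp(cur)
    acc = np.log(rng.random(cur.shape)) < lacc
    return np.where(acc, prop, cur), acc


def fit_hierarchical(trials: pd.DataFrame, items: pd.DataFrame,
                     config: RunConfig, fixed_item_d: bool = False):
    """Fit the hierarchical model; returns (PosteriorSamples, FitReport).

    With ``fixed_item_d`` the item difficulties are taken from the ``d``
    column of ``items`` and held constant (the longitudinal refit mode).
    """
    (t, rt, resp, ps_start, ps_end, item_ptr, item_trials, person_of_ps,
     pp_start, pp_end, person_ids, session_keys, item_ids,
     item_of_trial) = _prepare_arrays(trials, items)
    if (t.loc[t["_resp"] != 0, "rt"] >= config.deadline).any():
        raise DataValidationError("answered trial with rt >= deadline")
    n_ps = len(session_keys)
    n_person = len(person_ids)
    n_items = len(item_ids)
    n_sessions_per_person = np.bincount(person_of_ps, minlength=n_person)
    use_sessions = bool(np.any(n_sessions_per_person > 1))
    update_items = not fixed_item_d
    if fixed_item_d:
        if "d" not in items.columns:
            raise StratDDMError("fixed_item_d requires a d column in items")
        d_fixed = items["d"].to_numpy(dtype=float).copy()

    n_chains = config.chains
    n_keep = config.draws
    total_sweeps = config.warmup + n_keep * config.thin
    tmax = float(config.deadline)

    draws = {
        "theta_ps": np.empty((n_chains, n_keep, n_ps, 8)),
        "M": np.empty((n_chains, n_keep, 8)),
        "S": np.empty((n_chains, n_keep, 8)),
        "extras": np.empty((n_chains, n_keep, 3)),
    }
    if use_sessions:
        draws["theta_person"] = np.empty((n_chains, n_keep, n_person, 8))
        draws["sess_sd"] = np.empty((n_chains, n_keep, 8))
    if update_items:
        draws["d"] = np.empty((n_chains, n_keep, n_items))
        draws["sigma_d"] = np.empty((n_chains, n_keep))
    acc_stats = {}

    # data-informed non-decision floor: tau must sit below each block's
    # fastest answered RT for the likelihood to be finite
    min_rt = np.full(n_ps, tmax)
    for j in range(n_ps):
        blk = rt[ps_start[j]:ps_end[j]]
        blk = blk[np.isfinite(blk)]
        if len(blk):
            min_rt[j] = blk.min()

    from .simulate import default_group_params

    anchor = default_group_params()

    for chain in range(n_chains):
        rng = np.random.default_rng([config.seed, chain])
        theta_ps = None
        for attempt in range(100):
            # domain-anchored, overdispersed initialization: group
            # locations near the package's default anchor, persons spread
            # with the anchor scale, non-decision time floored by each
            # block's fastest answered RT
            M = anchor.loc + 2.0 * config.init_jitter * rng.standard_normal(8)
            S = anchor.scale.copy()
            sess_sd = np.maximum(config.session_jitter * anchor.scale, 0.01)
            theta_person = M + S * rng.standard_normal((n_person, 8))
            theta_ps = (
                theta_person[person_of_ps]
                + 0.5 * sess_sd * rng.standard_normal((n_ps, 8))
            )
            theta_ps[:, 2] = np.minimum(
                theta_ps[:, 2],
                np.log(np.maximum(0.8 * (0.8 ** attempt) * min_rt, 1e-3)),
            )
            theta_person = np.empty((n_person, 8))
            for p in range(n_person):
                theta_person[p] = theta_ps[person_of_ps == p].mean(axis=0)
            d = (np.zeros(n_items) if update_items else d_fixed.copy())
            ex = np.array([anchor.nu, math.log(anchor.lam), math.log(anchor.Delta)])
            ex += config.init_jitter * rng.standard_normal(3)
            P_nat = np.empty((len(rt), 8))
            ll_tr = np.empty(len(rt))
            d_tr = d[item_of_trial].astype(float)
            tot = _kernels.init_cache(
                theta_ps, ps_start, ps_end, rt, resp, d_tr,
                ex[0], math.exp(ex[1]), math.exp(ex[2]), tmax, P_nat, ll_tr,
            )
            if np.isfinite(tot):
                break
        else:
            raise StratDDMError(
                "non-finite log-posterior at initialization after 100 restarts"
            )
        sigma_d = 1.0

        log_step_ps = np.zeros(n_ps)
        log_step_person = np.zeros(n_person)
        log_step_item = np.full(n_items, math.log(0.2))
        # covariance-adaptive proposals: start diagonal, switch to the
        # warmup empirical covariance (Cholesky) once enough sweeps accrue
        L_ps = np.tile(np.diag(_BASE_STEP), (n_ps, 1, 1))
        L_person = np.tile(np.diag(_BASE_STEP), (n_person, 1, 1))
        cov_t = 0
        mean_ps = np.zeros((n_ps, 8))
        C_ps = np.zeros((n_ps, 8, 8))
        mean_person = np.zeros((n_person, 8))
        C_person = np.zeros((n_person, 8, 8))
        _COV_START, _COV_USE, _COV_EVERY = 150, 400, 50
        log_step_ex = math.log(0.05)
        log_step_S = np.full(8, math.log(0.2))
        log_step_sess = np.full(8, math.log(0.2))
        log_step_sigd = math.log(0.2)
        acc_ps = np.zeros(n_ps, dtype=np.int64)
        acc_person = np.zeros(n_person, dtype=np.int64)
        acc_item = np.zeros(n_items, dtype=np.int64)
        acc_ps_tot = np.zeros(n_ps)
        acc_ex_tot = 0.0

        keep_i = 0
        for sweep_i in range(total_sweeps):
            warm = sweep_i < config.warmup
            eps_ps = rng.standard_normal((n_ps, 8))
            u_ps = rng.random(n_ps)
            eps_person = rng.standard_normal((n_person, 8))
            u_person = rng.random(n_person)
            jump_u = rng.random(n_person)
            jump_coord = rng.integers(0, 11, n_person)
            jump_z = rng.standard_normal((n_person, 3))
            eps_item = rng.standard_normal(n_items)
            u_item = rng.random(n_items)
            eps_ex = rng.standard_normal(3)
            u_ex = rng.random()
            acc_ex = _kernels.sweep(
                theta_ps, person_of_ps, theta_person, sess_sd, use_sessions,
                M, S, d, sigma_d, ex,
                rt, resp, d_tr, P_nat, ll_tr,
                ps_start, ps_end, item_ptr, item_trials,
                pp_start, pp_end,
                np.exp(log_step_ps), L_ps, np.exp(log_step_person),
                L_person, np.exp(log_step_item), math.exp(log_step_ex),
                eps_ps, u_ps, eps_person, u_person, jump_u, jump_coord,
                jump_z, eps_item, u_item, eps_ex, u_ex,
                tmax, update_items, True,
                acc_ps, acc_person, acc_item,
            )
            # --- conjugate and scale updates (no likelihood terms) ------
            if use_sessions:
                sums = np.zeros((n_person, 8))
                np.add.at(sums, person_of_ps, theta_ps)
                prec = 1.0 / S ** 2 + n_sessions_per_person[:, None] / sess_sd ** 2
                mean = (M / S ** 2 + sums / sess_sd ** 2) / prec
                theta_person = mean + rng.standard_normal((n_person, 8)) / np.sqrt(prec)
                level = theta_person
            else:
                level = theta_ps
            n_level = level.shape[0]
            prec = 1.0 / config.loc_prior_sd ** 2 + n_level / S ** 2
            mean = level.sum(axis=0) / S ** 2 / prec
            M = mean + rng.standard_normal(8) / np.sqrt(prec)
            ssq = ((level - M) ** 2).sum(axis=0)
            S, acc_S = _scale_mh(S, ssq, n_level, config.scale_prior_sd,
                                 np.exp(log_step_S), rng)
            if use_sessions:
                dev = theta_ps - theta_person[person_of_ps]
                ssq = (dev ** 2).sum(axis=0)
                sess_sd, acc_sess = _scale_mh(
                    sess_sd, ssq, n_ps, config.scale_prior_sd,
                    np.exp(log_step_sess), rng,
                )
            if update_items:
                sig_arr, acc_sig = _scale_mh(
                    np.array([sigma_d]), (d ** 2).sum(), n_items,
                    config.scale_prior_sd, math.exp(log_step_sigd), rng,
                )
                sigma_d = float(sig_arr[0])
            # --- warmup-only covariance and Robbins-Monro adaptation ----
            if warm:
                if sweep_i >= _COV_START:
                    cov_t += 1
                    dev = theta_ps - mean_ps
                    mean_ps += dev / cov_t
                    C_ps += dev[:, :, None] * (theta_ps - mean_ps)[:, None, :]
                    devp = theta_person - mean_person
                    mean_person += devp / cov_t
                    C_person += (
                        devp[:, :, None] * (theta_person - mean_person)[:, None, :]
                    )
                if (
                    sweep_i >= _COV_USE
                    and cov_t > 30
                    and (sweep_i - _COV_USE) % _COV_EVERY == 0
                ):
                    reg = 1e-6 * np.eye(8)
                    try:
                        L_ps = np.linalg.cholesky(C_ps / (cov_t - 1) + reg)
                        L_person = np.linalg.cholesky(
                            C_person / (cov_t - 1) + reg
                        )
                        if sweep_i == _COV_USE:
                            scale = 2.38 / math.sqrt(8.0)
                            log_step_ps[:] = math.log(scale)
                            log_step_person[:] = math.log(scale)
                    except np.linalg.LinAlgError:
                        pass
                rate = _rm_rate(sweep_i)
                if use_sessions:
                    log_step_ps += rate * (acc_ps - _TARGET_ACC)
                else:
                    rw_ps = jump_u >= 0.2
                    log_step_ps[rw_ps] += rate * (acc_ps[rw_ps] - _TARGET_ACC)
                if use_sessions:
                    # adapt person steps only on random-walk proposals;
                    # prior-jump sweeps carry no step information
                    rw = jump_u >= 0.2
                    log_step_person[rw] += rate * (acc_person[rw] - _TARGET_ACC)
                log_step_item += rate * (acc_item - _TARGET_ACC)
                log_step_ex += rate * (acc_ex - _TARGET_ACC)
                log_step_S += rate * (acc_S - _TARGET_ACC)
                if use_sessions:
                    log_step_sess += rate * (acc_sess - _TARGET_ACC)
                if update_items:
                    log_step_sigd += rate * (float(acc_sig[0]) - _TARGET_ACC)
            else:
                acc_ps_tot += acc_ps
                acc_ex_tot += acc_ex
                k = sweep_i - config.warmup
                if (k + 1) % config.thin == 0 and keep_i < n_keep:
                    draws["theta_ps"][chain, keep_i] = theta_ps
                    draws["M"][chain, keep_i] = M
                    draws["S"][chain, keep_i] = S
                    draws["extras"][chain, keep_i] = ex
                    if use_sessions:
                        draws["theta_person"][chain, keep_i] = theta_person
                        draws["sess_sd"][chain, keep_i] = sess_sd
                    if update_items:
                        draws["d"][chain, keep_i] = d
                        draws["sigma_d"][chain, keep_i] = sigma_d
                    keep_i += 1
        acc_stats[f"chain{chain}"] = {
            "ps_accept_mean": float(
                (acc_ps_tot / max(n_keep * config.thin, 1)).mean()
            ),
            "extras_accept": float(acc_ex_tot / max(n_keep * config.thin, 1)),
        }

    priors = {
        "group_location": f"Normal(0, {config.loc_prior_sd}) on transformed scale",
        "group_scale": f"half-Normal({config.scale_prior_sd})",
        "session_scale": f"half-Normal({config.scale_prior_sd})",
        "item_difficulty": "Normal(0, sigma_d), sigma_d ~ half-Normal"
                           f"({config.scale_prior_sd})",
        "extras": f"nu ~ Normal(0, {config.extras_prior_sd}); lambda, Delta ~ "
                  f"half-Normal({config.extras_prior_sd})",
    }
    samples = PosteriorSamples(
        draws=draws, person_ids=person_ids, session_keys=session_keys,
        item_ids=item_ids, use_sessions=use_sessions,
        fixed_item_d=d_fixed if fixed_item_d else None,
        seed=config.seed, warmup=config.warmup, acceptance=acc_stats,
        priors=priors,
    )
    return samples, diagnostics(samples)


def _flatten_draws(samples: PosteriorSamples):
    """Yield (name, (chains, draws) array) scalar series."""
    for key, arr in samples.draws.items():
        if key == "theta_ps":
            for j, (p, s) in enumerate(samples.session_keys):
                for k, pname in enumerate(PARAM_NAMES):
                    yield f"theta[{p},{s},{pname}]", arr[:, :, j, k]
        elif key == "theta_person":
            for j, p in enumerate(samples.person_ids):
                for k, pname in enumerate(PARAM_NAMES):
                    yield f"theta[{p},{pname}]", arr[:, :, j, k]
        elif key in ("M", "S", "sess_sd"):
            for k, pname in enumerate(PARAM_NAMES):
                yield f"{key}[{pname}]", arr[:, :, k]
        elif key == "d":
            for m, iid in enumerate(samples.item_ids):
                yield f"d[{iid}]", arr[:, :, m]
        elif key == "extras":
            for k, name in enumerate(("nu", "log_lambda", "log_Delta")):
                yield name, arr[:, :, k]
        else:
            yield key, arr


def diagnostics(samples: PosteriorSamples) -> FitReport:
    """Split rank-normalized R-hat and bulk ESS per scalar parameter,
    flagging R-hat > 1.05 and degenerate (constant) chains."""
    import warnings

    import arviz as az

    if samples.draws["theta_ps"].shape[0] < 2:
        raise StratDDMError("diagnostics require >= 2 chains")
    rows = []
    for name, series in _flatten_draws(samples):
        mean = float(series.mean())
        sd = float(series.std(ddof=1))
        lo, hi = np.quantile(series, [0.025, 0.975])
        if np.allclose(series, series.ravel()[0]):
            rhat = np.nan
            ess = np.nan
            flag = "degenerate"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(series.copy()))
                ess = float(az.ess(series.copy()))
            flag = "rhat>1.05" if rhat > 1.05 else ""
        rows.append((name, mean, sd, float(lo), float(hi), rhat, ess, flag))
    if samples.fixed_item_d is not None:
        for iid, dval in zip(samples.item_ids, samples.fixed_item_d):
            rows.append((f"d[{iid}]", float(dval), 0.0, float(dval), float(dval),
                         np.nan, np.nan, "fixed"))
    summary = pd.DataFrame(
        rows,
        columns=["name", "mean", "sd", "q2.5", "q97.5", "rhat", "ess", "flag"],
    )
    return FitReport(summary=summary, priors=samples.priors, seed=samples.seed)


@dataclass
class LongitudinalResult:
    report_t1: FitReport
    report_t2: FitReport
    changes: pd.DataFrame         # person_id, parameter, mean_change, lo, hi
    samples_t1: PosteriorSamples
    samples_t2: PosteriorSamples


def fit_longitudinal(trials_t1: pd.DataFrame, trials_t2: pd.DataFrame,
                     items: pd.DataFrame, config: RunConfig) -> LongitudinalResult:
    """Two-timepoint procedure: fit T1 fully, freeze item difficulties at
    their T1 posterior means, refit persons/sessions/group on T2 with the
    items fixed, and tabulate per-person natural-scale parameter changes."""
    missing = set(trials_t2["item_id"]) - set(trials_t1["item_id"])
    if missing:
        raise DataValidationError(
            f"T2 items absent from the T1 bank: {sorted(missing)}"
        )
    samples1, report1 = fit_hierarchical(trials_t1, items, config)
    items_fixed = items.merge(
        samples1.item_d()[["item_id", "d"]], on="item_id", how="inner",
        suffixes=("_drop", ""),
    )
    items_fixed = items_fixed[[c for c in items_fixed.columns
                               if not c.endswith("_drop")]]
    cfg2 = RunConfig(**{**config.__dict__, "seed": config.seed + 1})
    samples2, report2 = fit_hierarchical(
        trials_t2, items_fixed, cfg2, fixed_item_d=True
    )
    key = "theta_person" if samples1.use_sessions else "theta_ps"
    ids1 = (samples1.person_ids if samples1.use_sessions
            else [k[0] for k in samples1.session_keys])
    key2 = "theta_person" if samples2.use_sessions else "theta_ps"
    ids2 = (samples2.person_ids if samples2.use_sessions
            else [k[0] for k in samples2.session_keys])
    common = [p for p in ids1 if p in ids2]
    nat1 = to_natural(samples1.draws[key])
    nat2 = to_natural(samples2.draws[key2])
    n_use = min(nat1.shape[1], nat2.shape[1])
    rows = []
    for p in common:
        i1 = ids1.index(p)
        i2 = ids2.index(p)
        diff = nat2[:, :n_use, i2, :] - nat1[:, :n_use, i1, :]
        for k, pname in enumerate(PARAM_NAMES):
            dk = diff[:, :, k]
            lo, hi = np.quantile(dk, [0.025, 0.975])
            rows.append((p, pname, float(dk.mean()), float(lo), float(hi),
                         bool(lo <= 0 <= hi)))
    changes = pd.DataFrame(
        rows,
        columns=["person_id", "parameter", "mean_change", "lo", "hi",
                 "covers_zero"],
    )
    return LongitudinalResult(report1, report2, changes, samples1, samples2)


def sbc_reduced(n_reps: int, n_trials: int = 60, draws: int = 2000,
                warmup: int = 800, thin: int = 10, seed: int = 0,
                deadline: float = 5.0):
    """Simulation-based calibration on the one-person reduced model.

    Group-level quantities are held at their defaults; per replicate a
    person is drawn from the group prior, trials are simulated, the
    8-parameter block is sampled with the same kernel as the full fitter,
    and the rank of the truth among thinned retained draws is recorded.
    Returns (ranks, n_ranks): ranks has shape (n_reps, 8), each entry in
    0..n_ranks inclusive.
    """
    from .simulate import default_group_params, make_item_bank

    group = default_group_params()
    rng_master = np.random.default_rng(seed)
    bank = make_item_bank(seed=int(rng_master.integers(2 ** 31)),
                          sigma_d=group.sigma_d)
    d_items = bank["d"].to_numpy()
    n_keep = draws // thin
    ranks = np.empty((n_reps, 8), dtype=np.int64)
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        truth = group.loc + group.scale * rng.standard_normal(8)
        item_idx = rng.integers(0, len(bank), size=n_trials)
        d_tr = d_items[item_idx].astype(float)
        P = np.tile(to_natural(truth), (n_trials, 1))
        rts, resps, _, _ = _kernels.simulate_trials(
            np.ascontiguousarray(P), d_tr, group.nu, group.lam, group.Delta,
            deadline, int(rng.integers(2 ** 31)),
        )
        theta = np.zeros((1, 8))
        kept = _sample_single_block(
            rts, resps, d_tr, group, theta, warmup, draws, thin, deadline, rng
        )
        ranks[rep] = (kept < truth[None, :]).sum(axis=0)
    return ranks, n_keep


def _sample_single_block(rts, resps, d_tr, group, theta, warmup, draws, thin,
                         deadline, rng):
    """Adaptive 8-dim Metropolis for one person with a fixed group prior."""
    n = len(rts)
    ps_start = np.array([0], dtype=np.int64)
    ps_end = np.array([n], dtype=np.int64)
    person_of_ps = np.array([0], dtype=np.int64)
    theta_person = np.zeros((1, 8))
    M = group.loc.copy()
    S = group.scale.copy()
    sess = np.full(8, 1.0)
    P_nat = np.empty((n, 8))
    ll_tr = np.empty(n)
    fin = rts[np.isfinite(rts)]
    theta[0] = M + 0.1 * rng.standard_normal(8)
    theta[0, 2] = math.log(min(0.8 * (fin.min() if len(fin) else 1.0), 1.0))
    ex = np.array([group.nu, math.log(group.lam), math.log(group.Delta)])
    tot = _kernels.init_cache(
        theta, ps_start, ps_end, rts, resps, d_tr,
        ex[0], group.lam, group.Delta, deadline, P_nat, ll_tr,
    )
    if not np.isfinite(tot):
        theta[0, 2] = math.log(0.1)
        _kernels.init_cache(theta, ps_start, ps_end, rts, resps, d_tr,
                            ex[0], group.lam, group.Delta, deadline, P_nat, ll_tr)
    log_step = np.zeros(1)
    acc = np.zeros(1, dtype=np.int64)
    acc_i = np.zeros(0, dtype=np.int64)
    d_empty = np.zeros(0)
    item_ptr = np.array([0], dtype=np.int64)
    item_trials = np.zeros(0, dtype=np.int64)
    n_keep = draws // thin
    kept = np.empty((n_keep, 8))
    L = np.diag(_BASE_STEP)[None, :, :].copy()
    mean_w = np.zeros(8)
    C_w = np.zeros((8, 8))
    cov_t = 0
    k = 0
    for sweep_i in range(warmup + draws):
        jump_u = rng.random(1)
        _kernels.sweep(
            theta, person_of_ps, theta_person, sess, False,
            M, S, d_empty, 1.0, ex,
            rts, resps, d_tr, P_nat, ll_tr,
            ps_start, ps_end, item_ptr, item_trials,
            np.array([0], dtype=np.int64), np.array([1], dtype=np.int64),
            np.exp(log_step), L, np.ones(1), L,
            np.zeros(0), 0.0,
            rng.standard_normal((1, 8)), rng.random(1),
            np.zeros((1, 8)), rng.random(1),
            jump_u, rng.integers(0, 11, 1), rng.standard_normal((1, 3)),
            np.zeros(0), np.zeros(0), np.zeros(3), 1.0,
            deadline, False, False,
            acc, np.zeros(1, dtype=np.int64), acc_i,
        )
        if sweep_i < warmup:
            if sweep_i >= 100:
                cov_t += 1
                dev = theta[0] - mean_w
                mean_w += dev / cov_t
                C_w += np.outer(dev, theta[0] - mean_w)
            if sweep_i >= 250 and cov_t > 30 and (sweep_i - 250) % 50 == 0:
                try:
                    L = np.linalg.cholesky(
                        C_w / (cov_t - 1) + 1e-6 * np.eye(8)
                    )[None, :, :]
                    if sweep_i == 250:
                        log_step[:] = math.log(2.38 / math.sqrt(8.0))
                except np.linalg.LinAlgError:
                    pass
            if jump_u[0] >= 0.2:
                log_step += _rm_rate(sweep_i) * (acc - _TARGET_ACC)
        else:
            j = sweep_i - warmup
            if (j + 1) % thin == 0 and k < n_keep:
                kept[k] = theta[0]
                k += 1
    return kept
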