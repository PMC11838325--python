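"""Numba kernels for the mixture trial likelihood, cohort simulation and
the blocked Metropolis sweep.

Parameter vector convention (one person-session, natural scale):
index 0 alpha, 1 kappa, 2 tau, 3 delta, 4 beta, 5 mu, 6 omega, 7 gamma.
Transformed scale uses log for all positive parameters, logit for beta,
identity for mu.

Response coding: 1 correct (upper boundary), -1 incorrect (lower), 0 none
(censored at the deadline).
"""

import math

import numpy as np
from numba import njit

from ._wfpt import pdf_lower, sample_fpt, survival

# positivity clamp for the switch time, seconds
SWITCH_EPS = 1e-3

# transformed-scale hyperprior scales
LOC_PRIOR_SD = 2.0
SCALE_PRIOR_SD = 1.0
EXTRAS_PRIOR_SD = 2.0


@njit(cache=True)
def expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def to_natural(th):
    out = np.empty(8)
    for k in range(8):
        if k == 4:
            out[k] = expit(th[k])
        elif k == 5:
            out[k] = th[k]
        else:
            out[k] = math.exp(th[k])
    return out


@njit(cache=True)
def trial_components(rt, resp, al, ka, ta, de, be, mu, om, ga,
                     d, nu, lam, dec, tmax):
    """Unnormalized strategy component masses (retrieval, counting,
    decomposition) for one trial.  Their sum is the trial likelihood."""
    U = tmax - ta
    s = ga + om * d
    if s < SWITCH_EPS:
        s = SWITCH_EPS
    vr = de - d
    pr = expit(mu - d)
    pdec = expit(nu)
    pc = (1.0 - pr) * (1.0 - pdec)
    pd = (1.0 - pr) * pdec
    if resp == 0:
        if U <= 0.0:
            # structurally censored: no decision time available at all
            return 1.0, 0.0, 0.0
        if U <= s:
            return survival(U, vr, al, be), 0.0, 0.0
        vc = ka - lam * d
        vd = vc - dec
        s_r_s = survival(s, vr, al, be)
        return (
            pr * survival(U, vr, al, be),
            s_r_s * pc * survival(U - s, vc, al, be),
            s_r_s * pd * survival(U - s, vd, al, be),
        )
    if U <= 0.0:
        return 0.0, 0.0, 0.0
    u = rt - ta
    if u <= 0.0:
        return 0.0, 0.0, 0.0
    upper = resp == 1
    if upper:
        vr_b = -vr
        w_b = 1.0 - be
    else:
        vr_b = vr
        w_b = be
    if u <= s:
        return pdf_lower(u, vr_b, al, w_b, 0), 0.0, 0.0
    vc = ka - lam * d
    vd = vc - dec
    if upper:
        vc_b = -vc
        vd_b = -vd
    else:
        vc_b = vc
        vd_b = vd
    s_r_s = survival(s, vr, al, be)
    return (
        pr * pdf_lower(u, vr_b, al, w_b, 0),
        s_r_s * pc * pdf_lower(u - s, vc_b, al, w_b, 0),
        s_r_s * pd * pdf_lower(u - s, vd_b, al, w_b, 0),
    )


@njit(cache=True)
def trial_loglik(rt, resp, al, ka, ta, de, be, mu, om, ga, d, nu, lam, dec, tmax):
    cr, cc, cd = trial_components(
        rt, resp, al, ka, ta, de, be, mu, om, ga, d, nu, lam, dec, tmax
    )
    L = cr + cc + cd
    if L <= 0.0:
        return -np.inf
    return math.log(L)


@njit(cache=True)
def ll_fill_range(i0, i1, rt, resp, nat, d_tr, nu, lam, dec, tmax, out):
    """Per-trial log-likelihood for a contiguous block sharing one
    natural-scale parameter vector; writes out[i0:i1], returns the sum."""
    tot = 0.0
    for i in range(i0, i1):
        v = trial_loglik(
            rt[i], resp[i],
            nat[0], nat[1], nat[2], nat[3], nat[4], nat[5], nat[6], nat[7],
            d_tr[i], nu, lam, dec, tmax,
        )
        out[i] = v
        tot += v
    return tot


@njit(cache=True)
def init_cache(theta_ps, ps_start, ps_end, rt, resp, d_tr, nu, lam, dec, tmax,
               P_nat, ll_tr):
    tot = 0.0
    for j in range(theta_ps.shape[0]):
        nat = to_natural(theta_ps[j])
        tot += ll_fill_range(
            ps_start[j], ps_end[j], rt, resp, nat, d_tr, nu, lam, dec, tmax, ll_tr
        )
        for i in range(ps_start[j], ps_end[j]):
            for k in range(8):
                P_nat[i, k] = nat[k]
    return tot


@njit(cache=True)
def sweep(theta_ps, person_of_ps, theta_person, sess_sd, use_sessions,
          M, S, d, sigma_d, ex,
          rt, resp, d_tr, P_nat, ll_tr,
          ps_start, ps_end, item_ptr, item_trials,
          pp_start, pp_end,
          step_ps, L_ps, step_person, L_person, step_item, step_ex,
          eps_ps, u_ps, eps_person, u_person, jump_u, jump_coord, jump_z,
          eps_item, u_item, eps_ex, u_ex,
          tmax, update_items, update_extras,
          acc_ps, acc_person, acc_item):
    """One blocked Metropolis sweep over person-session, item and
    group-extra blocks.  Updates state and the per-trial likelihood
    cache in place; returns 1 if the extras block was accepted."""
    n_trials = rt.shape[0]
    tmp = np.empty(n_trials)
    nu = ex[0]
    lam = math.exp(ex[1])
    dec = math.exp(ex[2])

    # --- person-session blocks ---------------------------------------
    n_ps = theta_ps.shape[0]
    thp = np.empty(8)
    for j in range(n_ps):
        # with a session layer the block conditional is dominated by the
        # tight session prior, so a diagonal proposal scaled by the
        # CURRENT session scale stays well calibrated as that scale
        # moves (scaling by other state components keeps the conditional
        # kernel symmetric); without sessions the block is person-level
        # and uses the adapted covariance factor
        ps_jump = False
        if use_sessions:
            for k in range(8):
                sk = sess_sd[k]
                if sk < 0.004:
                    sk = 0.004
                thp[k] = theta_ps[j, k] + step_ps[j] * sk * eps_ps[j, k]
        else:
            # person-level block (one session per person): mixture of a
            # covariance random walk and Metropolized prior draws for the
            # coordinates whose posterior can be bimodal
            ps_jump = jump_u[j] < 0.2
            for k in range(8):
                thp[k] = theta_ps[j, k]
            if ps_jump:
                if jump_coord[j] == 8:      # switching trio mu, omega, gamma
                    for idx in range(3):
                        k = 5 + idx
                        thp[k] = M[k] + S[k] * jump_z[j, idx]
                elif jump_coord[j] == 9:    # kappa-gamma trade-off
                    for idx, k in enumerate((1, 7)):
                        thp[k] = M[k] + S[k] * jump_z[j, idx]
                elif jump_coord[j] == 10:   # tau-gamma trade-off
                    for idx, k in enumerate((2, 7)):
                        thp[k] = M[k] + S[k] * jump_z[j, idx]
                else:
                    k = jump_coord[j]
                    thp[k] = M[k] + S[k] * jump_z[j, 0]
            else:
                for k in range(8):
                    move = 0.0
                    for l in range(k + 1):
                        move += L_ps[j, k, l] * eps_ps[j, l]
                    thp[k] = theta_ps[j, k] + step_ps[j] * move
        nat = to_natural(thp)
        news = ll_fill_range(
            ps_start[j], ps_end[j], rt, resp, nat, d_tr, nu, lam, dec, tmax, tmp
        )
        cur = 0.0
        for i in range(ps_start[j], ps_end[j]):
            cur += ll_tr[i]
        dpr = 0.0
        if use_sessions:
            p = person_of_ps[j]
            for k in range(8):
                an = thp[k] - theta_person[p, k]
                bn = theta_ps[j, k] - theta_person[p, k]
                dpr += (bn * bn - an * an) / (2.0 * sess_sd[k] * sess_sd[k])
        elif not ps_jump:
            for k in range(8):
                an = thp[k] - M[k]
                bn = theta_ps[j, k] - M[k]
                dpr += (bn * bn - an * an) / (2.0 * S[k] * S[k])
        lacc = news - cur + dpr
        if lacc >= 0.0 or math.log(u_ps[j]) < lacc:
            for k in range(8):
                theta_ps[j, k] = thp[k]
            for i in range(ps_start[j], ps_end[j]):
                ll_tr[i] = tmp[i]
                for k in range(8):
                    P_nat[i, k] = nat[k]
            acc_ps[j] = 1
        else:
            acc_ps[j] = 0

    # --- joint person shifts (person mean + all its sessions) ----------
    # the centered hierarchy makes person-level moves through individual
    # session blocks very slow when the session scale is small; shifting
    # a person's mean together with all its session values restores
    # likelihood-scale mixing at the person level
    if use_sessions:
        shift = np.empty(8)
        for p in range(pp_start.shape[0]):
            # mixture proposal: mostly covariance-scaled random-walk
            # shifts; occasionally a Metropolized draw from the
            # hierarchical prior for one coordinate or for the
            # switching-related trio (mu, omega, gamma), whose posterior
            # can be bimodal per person.  For prior draws the prior and
            # proposal terms cancel, so acceptance is the likelihood
            # ratio and mode jumps stay possible.
            prior_jump = jump_u[p] < 0.2
            if prior_jump:
                for k in range(8):
                    shift[k] = 0.0
                if jump_coord[p] == 8:
                    for idx in range(3):
                        k = 5 + idx
                        shift[k] = M[k] + S[k] * jump_z[p, idx] - theta_person[p, k]
                elif jump_coord[p] == 9:
                    for idx, k in enumerate((1, 7)):
                        shift[k] = M[k] + S[k] * jump_z[p, idx] - theta_person[p, k]
                elif jump_coord[p] == 10:
                    for idx, k in enumerate((2, 7)):
                        shift[k] = M[k] + S[k] * jump_z[p, idx] - theta_person[p, k]
                else:
                    k = jump_coord[p]
                    shift[k] = M[k] + S[k] * jump_z[p, 0] - theta_person[p, k]
            else:
                for k in range(8):
                    move = 0.0
                    for l in range(k + 1):
                        move += L_person[p, k, l] * eps_person[p, l]
                    shift[k] = step_person[p] * move
            news = 0.0
            cur = 0.0
            bad = False
            for j in range(pp_start[p], pp_end[p]):
                for k in range(8):
                    thp[k] = theta_ps[j, k] + shift[k]
                nat = to_natural(thp)
                news += ll_fill_range(
                    ps_start[j], ps_end[j], rt, resp, nat, d_tr,
                    nu, lam, dec, tmax, tmp,
                )
                for i in range(ps_start[j], ps_end[j]):
                    cur += ll_tr[i]
                if news == -np.inf:
                    bad = True
                    break
            if prior_jump:
                dpr = 0.0
            else:
                dpr = 0.0
                for k in range(8):
                    an = theta_person[p, k] + shift[k] - M[k]
                    bn = theta_person[p, k] - M[k]
                    dpr += (bn * bn - an * an) / (2.0 * S[k] * S[k])
            lacc = news - cur + dpr
            if (not bad) and (lacc >= 0.0 or math.log(u_person[p]) < lacc):
                for k in range(8):
                    theta_person[p, k] += shift[k]
                for j in range(pp_start[p], pp_end[p]):
                    for k in range(8):
                        theta_ps[j, k] += shift[k]
                    nat = to_natural(theta_ps[j])
                    ll_fill_range(
                        ps_start[j], ps_end[j], rt, resp, nat, d_tr,
                        nu, lam, dec, tmax, ll_tr,
                    )
                    for i in range(ps_start[j], ps_end[j]):
                        for k in range(8):
                            P_nat[i, k] = nat[k]
                acc_person[p] = 1
            else:
                acc_person[p] = 0

    # --- item blocks ---------------------------------------------------
    if update_items:
        for m in range(d.shape[0]):
            dp = d[m] + step_item[m] * eps_item[m]
            news = 0.0
            cur = 0.0
            for q in range(item_ptr[m], item_ptr[m + 1]):
                i = item_trials[q]
                v = trial_loglik(
                    rt[i], resp[i],
                    P_nat[i, 0], P_nat[i, 1], P_nat[i, 2], P_nat[i, 3],
                    P_nat[i, 4], P_nat[i, 5], P_nat[i, 6], P_nat[i, 7],
                    dp, nu, lam, dec, tmax,
                )
                tmp[q] = v
                news += v
                cur += ll_tr[i]
            dpr = (d[m] * d[m] - dp * dp) / (2.0 * sigma_d * sigma_d)
            lacc = news - cur + dpr
            if lacc >= 0.0 or math.log(u_item[m]) < lacc:
                d[m] = dp
                for q in range(item_ptr[m], item_ptr[m + 1]):
                    i = item_trials[q]
                    ll_tr[i] = tmp[q]
                    d_tr[i] = dp
                acc_item[m] = 1
            else:
                acc_item[m] = 0

    # --- group extras (nu, log lambda, log Delta) ----------------------
    if not update_extras:
        return 0
    nup = ex[0] + step_ex * eps_ex[0]
    llamp = ex[1] + step_ex * eps_ex[1]
    ldecp = ex[2] + step_ex * eps_ex[2]
    lamp = math.exp(llamp)
    decp = math.exp(ldecp)
    news = 0.0
    cur = 0.0
    for i in range(n_trials):
        v = trial_loglik(
            rt[i], resp[i],
            P_nat[i, 0], P_nat[i, 1], P_nat[i, 2], P_nat[i, 3],
            P_nat[i, 4], P_nat[i, 5], P_nat[i, 6], P_nat[i, 7],
            d_tr[i], nup, lamp, decp, tmax,
        )
        tmp[i] = v
        news += v
        cur += ll_tr[i]
    es2 = EXTRAS_PRIOR_SD * EXTRAS_PRIOR_SD
    dpr = (ex[0] * ex[0] - nup * nup) / (2.0 * es2)
    dpr += (lam * lam - lamp * lamp) / (2.0 * es2) + (llamp - ex[1])
    dpr += (dec * dec - decp * decp) / (2.0 * es2) + (ldecp - ex[2])
    lacc = news - cur + dpr
    acc_ex = 0
    if lacc >= 0.0 or math.log(u_ex) < lacc:
        ex[0] = nup
        ex[1] = llamp
        ex[2] = ldecp
        for i in range(n_trials):
            ll_tr[i] = tmp[i]
        acc_ex = 1
    return acc_ex


@njit(cache=True)
def ll_rows(rt, resp, P_nat, d_tr, nu, lam, dec, tmax, out):
    """Per-trial log-likelihoods for per-trial parameter rows.

    Returns (total, n_flagged): flagged trials have -inf log-likelihood;
    they make the total -inf but never raise.
    """
    tot = 0.0
    n_flag = 0
    for i in range(rt.shape[0]):
        v = trial_loglik(
            rt[i], resp[i],
            P_nat[i, 0], P_nat[i, 1], P_nat[i, 2], P_nat[i, 3],
            P_nat[i, 4], P_nat[i, 5], P_nat[i, 6], P_nat[i, 7],
            d_tr[i], nu, lam, dec, tmax,
        )
        out[i] = v
        tot += v
        if v == -np.inf:
            n_flag += 1
    return tot, n_flag


@njit(cache=True)
def components_rows(rt, resp, P_nat, d_tr, nu, lam, dec, tmax):
    """Per-trial strategy component masses (n, 3)."""
    n = rt.shape[0]
    out = np.empty((n, 3))
    for i in range(n):
        cr, cc, cd = trial_components(
            rt[i], resp[i],
            P_nat[i, 0], P_nat[i, 1], P_nat[i, 2], P_nat[i, 3],
            P_nat[i, 4], P_nat[i, 5], P_nat[i, 6], P_nat[i, 7],
            d_tr[i], nu, lam, dec, tmax,
        )
        out[i, 0] = cr
        out[i, 1] = cc
        out[i, 2] = cd
    return out


@njit(cache=True)
def simulate_trials(P_nat, d_tr, nu, lam, dec, tmax, seed):
    """Generate trials for pre-drawn per-trial parameters.

    Returns (rts, resps, strategies, switched): rt is NaN for censored
    trials; strategy 0 retrieval, 1 counting, 2 decomposition; switched
    marks trials whose retrieval attempt reached the switch point.
    """
    np.random.seed(seed)
    n = P_nat.shape[0]
    rts = np.full(n, np.nan)
    resps = np.zeros(n, np.int64)
    strat = np.zeros(n, np.int64)
    switched = np.zeros(n, np.int64)
    for i in range(n):
        al = P_nat[i, 0]
        ka = P_nat[i, 1]
        ta = P_nat[i, 2]
        de = P_nat[i, 3]
        be = P_nat[i, 4]
        mu = P_nat[i, 5]
        om = P_nat[i, 6]
        ga = P_nat[i, 7]
        di = d_tr[i]
        U = tmax - ta
        if U <= 0.0:
            continue  # structurally censored retrieval trial
        s = ga + om * di
        if s < SWITCH_EPS:
            s = SWITCH_EPS
        vr = de - di
        b, t = sample_fpt(vr, al, be, U, np.random.random(), np.random.random())
        if b != 0 and t <= s:
            rts[i] = ta + t
            resps[i] = b
            continue
        if U <= s:
            continue  # censored while still retrieving, before any switch
        # retrieval unresolved at the switch point: probabilistic selection
        switched[i] = 1
        pr = expit(mu - di)
        pdec = expit(nu)
        u1 = np.random.random()
        if u1 < pr:
            # continue with the running retrieval accumulator
            if b != 0:
                rts[i] = ta + t
                resps[i] = b
            continue
        if u1 < pr + (1.0 - pr) * (1.0 - pdec):
            strat[i] = 1
            v2 = ka - lam * di
        else:
            strat[i] = 2
            v2 = ka - lam * di - dec
        b2, t2 = sample_fpt(v2, al, be, U - s, np.random.random(), np.random.random())
        if b2 != 0:
            rts[i] = ta + s + t2
            resps[i] = b2
    return rts, resps, strat, switched
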