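"""Low-level Wiener first-passage-time numerics (numba kernels).

Conventions: diffusion coefficient fixed at 1, absorbing boundaries at 0
(lower / error) and ``a`` (upper / correct), relative start ``w`` in (0,1)
so the process starts at ``w*a``, constant drift ``v``.

The first-passage density uses the classical dual series representation:
a small-time expansion in image terms and a large-time eigenfunction
expansion.  Per evaluation the representation needing fewer terms for a
truncation error below ~1e-12 is selected (the standard crossover rule).
The CDF/survival uses the analytically integrated large-time series,
which converges for every t > 0 when enough terms are taken.
"""

import math

import numpy as np
from numba import njit

# truncation error target for the series (well inside the 1e-9 contract)
_SERIES_ERR = 1e-12


@njit(cache=True)
def fw_density(tt, w, mode):
    """Standardized lower-boundary FPT density at normalized time tt = t/a^2
    for unit threshold and zero drift.  mode: 0 auto, 1 force small-time
    series, 2 force large-time series (modes 1/2 exist for testing the
    crossover agreement)."""
    if tt <= 0.0:
        return 0.0
    # terms needed by the small-time series
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * _SERIES_ERR < 1.0:
        ks = 2.0 + math.sqrt(
            -2.0 * tt * math.log(2.0 * _SERIES_ERR * math.sqrt(2.0 * math.pi * tt))
        )
        lb = math.sqrt(tt) + 1.0
        if ks < lb:
            ks = lb
    else:
        ks = 2.0
    # terms needed by the large-time series
    if math.pi * tt * _SERIES_ERR < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * _SERIES_ERR) / (math.pi ** 2 * tt))
        lb = 1.0 / (math.pi * math.sqrt(tt))
        if kl < lb:
            kl = lb
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    use_small = ks < kl
    if mode == 1:
        use_small = True
    elif mode == 2:
        use_small = False
    if use_small:
        K = int(math.ceil(ks))
        half = K // 2
        acc = 0.0
        for k in range(-half, half + 1):
            z = w + 2.0 * k
            acc += z * math.exp(-z * z / (2.0 * tt))
        val = acc / math.sqrt(2.0 * math.pi * tt ** 3)
    else:
        K = int(math.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += (
                k
                * math.exp(-0.5 * k * k * math.pi * math.pi * tt)
                * math.sin(k * math.pi * w)
            )
        val = math.pi * acc
    if val < 0.0:
        val = 0.0
    return val


@njit(cache=True)
def pdf_lower(t, v, a, w, mode):
    """Density of absorption at the LOWER boundary at time t."""
    if t <= 0.0:
        return 0.0
    g = math.exp(-v * a * w - 0.5 * v * v * t) / (a * a)
    return g * fw_density(t / (a * a), w, mode)


@njit(cache=True)
def pdf_boundary(t, v, a, w, upper):
    """Density of absorption at the chosen boundary at time t."""
    if upper:
        return pdf_lower(t, -v, a, 1.0 - w, 0)
    return pdf_lower(t, v, a, w, 0)


@njit(cache=True)
def prob_upper(v, a, w):
    """Probability of eventual absorption at the upper boundary
    (closed form for constant drift; continuous at v = 0)."""
    x = 2.0 * v * a
    if abs(x) < 1e-10:
        return w
    return math.expm1(-x * w) / math.expm1(-x)


@njit(cache=True)
def cdf_lower(t, v, a, w):
    """P(absorbed at the lower boundary by time t)."""
    if t <= 1e-7:
        return 0.0
    plo = 1.0 - prob_upper(v, a, w)
    c = math.pi / (a * a) * math.exp(-v * a * w)
    acc = 0.0
    k = 1
    while k <= 100000:
        lam = 0.5 * v * v + 0.5 * k * k * math.pi * math.pi / (a * a)
        acc += k * math.sin(k * math.pi * w) * math.exp(-lam * t) / lam
        # terms decay like k*exp(-c k^2 t); stop once the envelope is tiny
        if k >= 4 and c * k * math.exp(-lam * t) / lam < 1e-14:
            break
        k += 1
    val = plo - c * acc
    if val < 0.0:
        val = 0.0
    elif val > plo:
        val = plo
    return val


@njit(cache=True)
def survival(t, v, a, w):
    """P(neither boundary reached by time t)."""
    if t <= 0.0:
        return 1.0
    s = 1.0 - cdf_lower(t, v, a, w) - cdf_lower(t, -v, a, 1.0 - w)
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    return s


@njit(cache=True)
def sample_fpt(v, a, w, horizon, u_time, u_bound):
    """Draw (boundary, time) by inverting the survival function.

    u_time, u_bound are iid U(0,1).  Returns (code, t) with code 1 for the
    upper boundary, -1 for the lower, 0 if unabsorbed by ``horizon``
    (then t = horizon).  Exact up to the 1e-6 s bisection tolerance.
    """
    s_h = survival(horizon, v, a, w)
    if u_time < s_h:
        return 0, horizon
    lo = 0.0
    hi = horizon
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if survival(mid, v, a, w) > u_time:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    fl = pdf_lower(t, v, a, w, 0)
    fu = pdf_lower(t, -v, a, 1.0 - w, 0)
    tot = fl + fu
    code = 1
    if tot > 0.0 and u_bound < fl / tot:
        code = -1
    return code, t


@njit(cache=True)
def em_paths(v, a, w, dt, max_time, n, seed):
    """Euler-Maruyama brute-force path oracle.

    Returns (codes, times): code 1 upper, -1 lower, 0 unabsorbed by
    max_time (time then equals max_time).  Deterministic given seed.
    """
    np.random.seed(seed)
    codes = np.zeros(n, np.int64)
    times = np.full(n, max_time)
    sq = math.sqrt(dt)
    nstep = int(max_time / dt)
    for i in range(n):
        x = w * a
        for j in range(1, nstep + 1):
            x += v * dt + sq * np.random.standard_normal()
            if x >= a:
                codes[i] = 1
                times[i] = j * dt
                break
            if x <= 0.0:
                codes[i] = -1
                times[i] = j * dt
                break
    return codes, times


@njit(cache=True)
def pdf_boundary_arr(ts, v, a, w, upper):
    out = np.empty(ts.shape[0])
    for i in range(ts.shape[0]):
        out[i] = pdf_boundary(ts[i], v, a, w, upper)
    return out


@njit(cache=True)
def survival_arr(ts, v, a, w):
    out = np.empty(ts.shape[0])
    for i in range(ts.shape[0]):
        out[i] = survival(ts[i], v, a, w)
    return out


@njit(cache=True)
def sample_fpt_many(v, a, w, horizon, n, seed):
    """n seeded draws from sample_fpt."""
    np.random.seed(seed)
    codes = np.empty(n, np.int64)
    times = np.empty(n)
    for i in range(n):
        c, t = sample_fpt(v, a, w, horizon, np.random.random(), np.random.random())
        codes[i] = c
        times[i] = t
    return codes, times
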