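"""Derived per-person cognitive and metacognitive summaries.

From trial-level strategy responsibilities this module computes, per
person: mean strategy-selection entropy (Omega, nats), the SD of that
entropy across trials (Sigma), adaptivity (psi: the across-trial
correlation between retrieval drift and retrieval responsibility), and
mean strategy-use proportions.  Between-session reliability of any
per-person measure is quantified with two-way ANOVA intraclass
correlations (consistency ICC(3,1) and absolute-agreement ICC(2,1)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .errors import DataValidationError
from .likelihood import retrieval_drift

LN3 = float(np.log(3.0))


def entropy_summary(entropies) -> tuple[float, float]:
    """(Omega, Sigma): mean and population SD of per-trial entropy,
    pooled across all of a person's trials."""
    e = np.asarray(entropies, dtype=float)
    if len(e) < 2:
        raise DataValidationError("entropy summary needs >= 2 trials")
    return float(e.mean()), float(e.std(ddof=0))


def adaptivity(drifts, p_retrieval, method: str = "pearson") -> float:
    """Correlation between trial-level retrieval drift and retrieval
    responsibility.  NaN (undefined-adaptivity flag) when either side has
    zero variance."""
    x = np.asarray(drifts, dtype=float)
    y = np.asarray(p_retrieval, dtype=float)
    if len(x) < 3:
        raise DataValidationError("adaptivity needs >= 3 trials")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    return float(pearsonr(x, y).statistic)


def strategy_proportions(resp_matrix) -> np.ndarray:
    """Mean responsibility vector (retrieval, counting, decomposition)
    across a person's trials; sums to 1."""
    m = np.asarray(resp_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise DataValidationError("need at least one trial")
    return m.mean(axis=0)


def metacog_summary(resp_table: pd.DataFrame, params: pd.DataFrame,
                    items: pd.DataFrame) -> pd.DataFrame:
    """Per-person summary from a responsibilities table (the output of
    :func:`stratddm.likelihood.responsibilities_table`).

    ``params`` supplies each person's delta (person-level, natural scale)
    and ``items`` the difficulty d, for the adaptivity correlation.
    """
    merged = resp_table.merge(items[["item_id", "d"]], on="item_id")
    merged = merged.merge(
        params[["person_id", "delta"]].drop_duplicates("person_id"),
        on="person_id",
    )
    merged["retrieval_v"] = retrieval_drift(merged["delta"], merged["d"])
    rows = []
    for pid, g in merged.groupby("person_id", sort=True):
        omega_m, sigma_m = entropy_summary(g["entropy_nat"])
        psi = adaptivity(g["retrieval_v"], g["p_retrieval"])
        props = strategy_proportions(
            g[["p_retrieval", "p_counting", "p_decomposition"]].to_numpy()
        )
        rows.append((pid, omega_m, sigma_m, psi, *props))
    return pd.DataFrame(
        rows,
        columns=["person_id", "Omega", "Sigma", "psi",
                 "use_retrieval", "use_counting", "use_decomposition"],
    )


def per_session_measures(resp_table: pd.DataFrame) -> pd.DataFrame:
    """Session-level Omega/Sigma and strategy proportions (for ICC)."""
    rows = []
    for (pid, sid), g in resp_table.groupby(["person_id", "session_id"],
                                            sort=True):
        omega_m, sigma_m = entropy_summary(g["entropy_nat"])
        props = strategy_proportions(
            g[["p_retrieval", "p_counting", "p_decomposition"]].to_numpy()
        )
        rows.append((pid, sid, omega_m, sigma_m, *props))
    return pd.DataFrame(
        rows,
        columns=["person_id", "session_id", "Omega", "Sigma",
                 "use_retrieval", "use_counting", "use_decomposition"],
    )


def icc(matrix, variant: str = "consistency") -> float:
    """Two-way mixed-effects single-rater intraclass correlation of a
    persons x sessions value matrix.

    ``consistency`` is ICC(3,1) and ``agreement`` ICC(2,1), both from the
    standard two-way ANOVA decomposition.  Returns NaN (degenerate flag)
    when the total variance is zero; raises on missing cells.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DataValidationError("icc needs >= 2 persons and >= 2 sessions")
    if np.isnan(m).any():
        raise DataValidationError("icc input has missing cells")
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        return float("nan")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "consistency":
        denom = msr + (k - 1) * mse
    elif variant == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("variant must be 'consistency' or 'agreement'")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_table(values: pd.DataFrame, measures: list[str]) -> pd.DataFrame:
    """Both ICC variants for each measure column of a tidy person x
    session table (columns person_id, session_id, <measures>)."""
    rows = []
    for meas in measures:
        wide = values.pivot(index="person_id", columns="session_id",
                            values=meas)
        if wide.isna().any(axis=None):
            raise DataValidationError(f"missing cells for measure {meas!r}")
        rows.append((meas,
                     icc(wide.to_numpy(), "consistency"),
                     icc(wide.to_numpy(), "agreement")))
    return pd.DataFrame(rows, columns=["measure", "icc_consistency",
                                       "icc_agreement"])


def behavioural_session_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Model-free per-session summaries: median RT on answered trials,
    accuracy on answered trials, and no-response rate."""
    rows = []
    for (pid, sid), g in trials.groupby(["person_id", "session_id"],
                                        sort=True):
        answered = g[g["response"] != "none"]
        rows.append((
            pid, sid,
            float(answered["rt"].median()) if len(answered) else np.nan,
            float((answered["response"] == "correct").mean())
            if len(answered) else np.nan,
            float((g["response"] == "none").mean()),
        ))
    return pd.DataFrame(
        rows, columns=["person_id", "session_id", "median_rt", "accuracy",
                       "nr_rate"],
    )
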