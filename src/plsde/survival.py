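"""Per-feature survival stratification: exact 1-D 2-means, Kaplan-Meier
curves and the two-group log-rank test.

For each selected feature the samples are split into a low and a high
expression stratum with k-means (k = 2).  In one dimension the optimal
2-means partition is always a contiguous threshold split, so it is found
exactly by scanning the n - 1 thresholds between consecutive sorted values
— no random initialization is involved.  Stratum separation in survival is
then tested with the standard log-rank chi-square (1 df); curves use the
product-limit estimator.  Kaplan-Meier estimation and the log-rank test are
delegated to :mod:`lifelines`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateStatisticError
from .normalization import ExpressionMatrix

DEFAULT_ALPHA = 0.05


def kmeans_split_1d(values: Sequence[float]) -> np.ndarray:
    """Exact 2-means split of 1-D values into 'low'/'high' strata.

    Scans every contiguous threshold of the sorted values and returns the
    assignment minimizing the within-cluster sum of squares; samples tied
    with the boundary value go to the lower cluster.  Raises
    :class:`DataError` when all values are identical (no valid split).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise DataError("need >= 2 samples to stratify")
    s = np.sort(x)
    if s[0] == s[-1]:
        raise DataError("constant expression: no valid stratification")
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    total_sum, total_sq = csum[-1], csq[-1]
    best_wcss, best_k = np.inf, -1
    for k in range(1, n):  # low cluster = s[:k]
        if s[k - 1] == s[k]:
            continue  # ties never straddle the boundary
        low = csq[k - 1] - csum[k - 1] ** 2 / k
        high = (total_sq - csq[k - 1]) - (total_sum - csum[k - 1]) ** 2 / (n - k)
        wcss = low + high
        if wcss < best_wcss - 1e-12:
            best_wcss, best_k = wcss, k
    threshold = s[best_k - 1]
    return np.where(x > threshold, "high", "low")


@dataclass(eq=False)
class KMCurve:
    """Product-limit curve over the distinct event times of one stratum."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "at_risk": self.at_risk,
            "events": self.events, "survival": self.survival,
        })


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored observations leave the risk set without contributing events.
    Returned rows cover the distinct *event* times only (S = 1 before the
    first event by construction).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    t = table.index.to_numpy(dtype=float)[mask]
    return KMCurve(
        event_times=t,
        at_risk=table["at_risk"].to_numpy(dtype=int)[mask],
        events=table["observed"].to_numpy(dtype=int)[mask],
        survival=kmf.survival_function_at_times(t).to_numpy(dtype=float),
    )


def logrank_test(times: Sequence[float], events: Sequence[int],
                 strata: Sequence[str]) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value.

    Raises :class:`DegenerateStatisticError` when the statistic is
    undefined (no events, one stratum empty, or zero variance).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    strata = np.asarray(strata)
    groups = np.unique(strata)
    if len(groups) != 2:
        raise DataError(f"log-rank needs exactly two strata, got {list(groups)}")
    if events.sum() < 1:
        raise DegenerateStatisticError("no events observed in either stratum")
    m = strata == groups[0]
    res = _ll_logrank(times[m], times[~m], event_observed_A=events[m],
                      event_observed_B=events[~m])
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat) or not np.isfinite(p):
        raise DegenerateStatisticError("log-rank variance is zero; statistic undefined")
    return stat, p


def survival_screen(matrix: ExpressionMatrix, features: Sequence[str],
                    phenotype: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Stratify each feature by exact 2-means and log-rank test the strata.

    ``phenotype`` must carry sample, time, event columns aligned with the
    matrix samples.  Per-feature failures (constant expression, degenerate
    statistic) are recorded in the ``note`` column, never fatal.  The
    ``p_bh`` column is an informational Benjamini-Hochberg adjustment; the
    ``significant`` flag uses the raw p at ``alpha`` as in the original
    screen design.
    """
    pheno = phenotype.set_index("sample").loc[matrix.sample_ids]
    times = pheno["time"].to_numpy(dtype=float)
    events = pheno["event"].to_numpy(dtype=int)
    if (times <= 0).any():
        raise DataError("follow-up times must be positive")

    rows = []
    curves: dict[str, dict[str, KMCurve]] = {}
    for feat in features:
        if feat not in matrix.values.index:
            raise DataError(f"feature {feat!r} not in expression matrix")
        rec = {"feature": feat, "n_low": 0, "n_high": 0,
               "logrank_stat": np.nan, "p": np.nan, "note": ""}
        try:
            strata = kmeans_split_1d(matrix.values.loc[feat].to_numpy())
            rec["n_low"] = int((strata == "low").sum())
            rec["n_high"] = int((strata == "high").sum())
            stat, p = logrank_test(times, events, strata)
            rec["logrank_stat"], rec["p"] = stat, p
            curves[feat] = {
                s: km_curve(times[strata == s], events[strata == s])
                for s in ("low", "high")
            }
        except (DataError, DegenerateStatisticError) as exc:
            rec["note"] = str(exc)
        rows.append(rec)

    out = pd.DataFrame(rows, columns=["feature", "n_low", "n_high",
                                      "logrank_stat", "p", "note"])
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = ok & (out["p"] < alpha)
    out.attrs["km_curves"] = curves
    return out
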