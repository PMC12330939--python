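"""Quartile expression grouping, Kaplan-Meier estimation and the log-rank test.

All three pieces are implemented from first principles (product-limit
estimator; Mantel-Haenszel log-rank with the hypergeometric variance and
the simultaneous-event tie convention) so their arithmetic can be checked
against hand-worked tables and permutation oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# quartile grouping
# ---------------------------------------------------------------------------

def quartile_groups(expr_vector: pd.Series | np.ndarray) -> pd.DataFrame:
    """Assign low / medium / high by expression quartiles.

    Cut points are the rank-interpolated (type-7) first and third
    quartiles; values <= Q1 go to "low", values > Q3 to "high", the rest to
    "medium", so ties at a cut always fall to the lower group.
    """
    if isinstance(expr_vector, pd.Series):
        ids = list(expr_vector.index)
        x = expr_vector.to_numpy(dtype=float)
    else:
        x = np.asarray(expr_vector, dtype=float)
        ids = list(range(len(x)))
    if len(x) < 8:
        raise ValueError("need n >= 8 samples for quartile grouping")
    if np.all(x == x[0]):
        raise ValueError("constant expression vector: quartiles undefined")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # numpy default = type-7 interpolation
    group = np.where(x <= q1, "low", np.where(x > q3, "high", "medium"))
    return pd.DataFrame({"sample_id": ids, "expression": x, "group": group})


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, sorted
    at_risk: np.ndarray  # n_i just before each event time
    events: np.ndarray  # d_i events at each time
    survival: np.ndarray  # S(t_i)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Product-limit estimator: S(t) = prod over event times <= t of (1 - d_i/n_i).

    Censored observations (event == 0) leave the risk set without
    contributing an event; ties are handled by pooling all events at a
    distinct time into a single factor.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty group")
    if (times <= 0).any():
        raise ValueError("times must be > 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    n = len(times)
    at_risk, d, surv = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(t_sorted >= t))
        d_i = int(np.sum((t_sorted == t) & (e_sorted == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        d.append(d_i)
        surv.append(s)
    return KMCurve(event_times, np.array(at_risk), np.array(d), np.array(surv))


# ---------------------------------------------------------------------------
# log-rank (Mantel-Haenszel) test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi2: float
    df: int
    pvalue: float
    observed: np.ndarray  # events per group
    expected: np.ndarray
    groups: list


def logrank_statistic(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> LogRankResult:
    """Log-rank chi-square over >= 2 groups.

    At each distinct event time the observed events per group are compared
    with the hypergeometric expectation given the risk sets; for two groups
    chi2 = (O1 - E1)^2 / V1, generalized via the covariance matrix of the
    first g-1 groups otherwise.  Zero total events -> undefined (NaN).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    g = len(uniq)
    if g < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() == 0:
        return LogRankResult(np.nan, g - 1, np.nan, np.zeros(g), np.zeros(g), list(uniq))
    event_times = np.unique(times[events == 1])
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g - 1, g - 1))
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        d_j = int(np.sum((times == t) & (events == 1)))
        n_gj = np.array([np.sum(at_risk & (groups == u)) for u in uniq], dtype=float)
        d_gj = np.array([np.sum((times == t) & (events == 1) & (groups == u)) for u in uniq], dtype=float)
        O += d_gj
        E += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            mult = d_j * (n_j - d_j) / (n_j - 1)
            for a in range(g - 1):
                for b in range(g - 1):
                    if a == b:
                        V[a, b] += mult * frac[a] * (1 - frac[a])
                    else:
                        V[a, b] -= mult * frac[a] * frac[b]
    diff = (O - E)[: g - 1]
    if g == 2:
        v = V[0, 0]
        chi2 = float(diff[0] ** 2 / v) if v > 0 else 0.0
    else:
        chi2 = float(diff @ np.linalg.pinv(V) @ diff)
    p = float(stats.chi2.sf(chi2, df=g - 1))
    return LogRankResult(chi2, g - 1, p, O, E, list(uniq))


def logrank_test(times, events, groups) -> LogRankResult:
    return logrank_statistic(np.asarray(times), np.asarray(events), np.asarray(groups))


# ---------------------------------------------------------------------------
# per-RBP survival screen
# ---------------------------------------------------------------------------

def survival_screen(
    rbp_list: list[str],
    expr_matrix: pd.DataFrame,
    survival_meta: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Quartile-group each RBP, drop "medium", log-rank low vs high.

    ``expr_matrix`` is RBPs x samples; ``survival_meta`` needs columns
    sample_id, survival_time, event covering the screened samples.  Both
    raw and BH-adjusted p-values are reported; the significance call
    follows the raw p at ``alpha``.
    """
    meta = survival_meta.set_index("sample_id")
    shared = [s for s in expr_matrix.columns if s in meta.index and not pd.isna(meta.loc[s, "survival_time"])]
    if len(shared) < 8:
        raise ValueError("need >= 8 samples with survival data")
    rows = []
    for rbp in rbp_list:
        if rbp not in expr_matrix.index:
            continue
        grouping = quartile_groups(expr_matrix.loc[rbp, shared])
        keep = grouping[grouping["group"].isin(["low", "high"])]
        ids = keep["sample_id"].tolist()
        res = logrank_test(
            meta.loc[ids, "survival_time"].to_numpy(dtype=float),
            meta.loc[ids, "event"].to_numpy(dtype=int),
            keep["group"].to_numpy(),
        )
        rows.append(
            {
                "rbp_name": rbp,
                "n_low": int((keep["group"] == "low").sum()),
                "n_high": int((keep["group"] == "high").sum()),
                "chi2": res.chi2,
                "pvalue": res.pvalue,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no screened RBP present in the expression matrix")
    ok = ~df["pvalue"].isna()
    df["fdr"] = np.nan
    if ok.any():
        df.loc[ok, "fdr"] = multipletests(df.loc[ok, "pvalue"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["pvalue"] < alpha
    return df
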