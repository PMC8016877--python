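"""Phenotype statistics: insulin-tolerance AUC, ANOVA, and Kaplan-Meier /
log-rank comparison of tumor incidence.

The glucose AUC uses the trapezoid rule over the ITT sampling schedule
(0, 3, 6, 9, 12, 30 min).  The two-way ANOVA is the classical fixed-effects
decomposition for a balanced complete (group x time) design; the log-rank
test and KM estimator are computed from the risk tables directly so each
step is checkable by hand.  The unspecified post-hoc procedure is
Holm-adjusted pairwise Welch tests.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, ParameterError


def trapezoid_auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Area under a glucose-time curve by the trapezoid rule (mg/dL * min)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ParameterError("times and values must have equal length")
    if t.size < 2:
        raise ParameterError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ContractError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F and p."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0.0:  # all observations identical: F := 0, p := 1
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def twoway_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-way fixed-effects ANOVA (group, time, interaction).

    ``data`` columns: value, group, time.  Every (group, time) cell must
    hold the same number (>= 2) of observations; unbalanced designs raise.
    Returns a frame indexed by effect with sum_sq, df, F and p.
    """
    for col in ("value", "group", "time"):
        if col not in data.columns:
            raise ParameterError(f"data must have a {col!r} column")
    cells = data.groupby(["group", "time"], observed=True)["value"]
    sizes = cells.size()
    a = data["group"].nunique()
    b = data["time"].nunique()
    if len(sizes) != a * b or sizes.nunique() != 1:
        raise ParameterError("design must be complete and balanced")
    r = int(sizes.iloc[0])
    if r < 2:
        raise ParameterError("need >= 2 replicates per cell")

    y = data["value"].astype(float)
    grand = y.mean()
    cell_mean = cells.mean()
    g_mean = data.groupby("group", observed=True)["value"].mean()
    t_mean = data.groupby("time", observed=True)["value"].mean()

    ss_a = b * r * ((g_mean - grand) ** 2).sum()
    ss_b = a * r * ((t_mean - grand) ** 2).sum()
    inter = (
        cell_mean
        - g_mean.reindex(cell_mean.index.get_level_values(0)).to_numpy()
        - t_mean.reindex(cell_mean.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = r * (inter ** 2).sum()
    resid = y.to_numpy() - cells.transform("mean").to_numpy()
    ss_e = float((resid ** 2).sum())

    df_a, df_b = a - 1, b - 1
    df_ab, df_e = df_a * df_b, a * b * (r - 1)
    ms_e = ss_e / df_e

    def f_and_p(ss: float, df: int) -> tuple[float, float]:
        if ms_e == 0.0:  # noiseless cells: effect present iff its SS > 0
            return (np.inf, 0.0) if ss > 1e-12 else (0.0, 1.0)
        f = (ss / df) / ms_e
        return f, float(stats.f.sf(f, df, df_e))

    rows = {}
    for name, ss, df in [("group", ss_a, df_a), ("time", ss_b, df_b),
                         ("group:time", ss_ab, df_ab)]:
        f, p = f_and_p(float(ss), df)
        rows[name] = {"sum_sq": float(ss), "df": df, "F": f, "p_value": p}
    rows["residual"] = {"sum_sq": ss_e, "df": df_e, "F": np.nan, "p_value": np.nan}
    return pd.DataFrame(rows).T


def posthoc_pairwise(
    groups: Sequence[Sequence[float]], labels: Sequence[str]
) -> pd.DataFrame:
    """Holm-adjusted pairwise Welch t-tests (the post-hoc procedure)."""
    if len(groups) != len(labels):
        raise ParameterError("labels must match groups")
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(groups), 2):
        t, p = stats.ttest_ind(np.asarray(gi, float), np.asarray(gj, float),
                               equal_var=False)
        rows.append((labels[i], labels[j], float(t), float(p)))
    out = pd.DataFrame(rows, columns=["group_1", "group_2", "t", "p_value"])
    if len(out):
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier estimator and two-group log-rank test
# ---------------------------------------------------------------------------

def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier estimate with right censoring.

    ``records`` columns: time, event (1 = tumor detected, 0 = censored).
    Returns one row per distinct event time with n_risk, n_event, survival
    (product-limit S(t)) and incidence (1 - S(t)).
    """
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    if np.any(t <= 0):
        raise ParameterError("times must be > 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ParameterError("event must be 0 or 1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n = t.size
    for tt in np.unique(t[e == 1]):
        at_risk = int((t >= tt).sum())
        d = int(((t == tt) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((float(tt), at_risk, d, surv, 1.0 - surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival", "incidence"])


def logrank(records: pd.DataFrame, group_A: str, group_B: str) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p from the risk tables.

    At each distinct event time t the observed events in group A are
    compared with their hypergeometric expectation given the pooled risk
    set; chi2 = (O - E)^2 / V summed over event times.
    """
    present = set(records["group"])
    for g in (group_A, group_B):
        if g not in present:
            raise KeyError(f"unknown group {g!r}")
    sub = records[records["group"].isin([group_A, group_B])]
    t = sub["time"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=int)
    in_a = (sub["group"] == group_A).to_numpy()
    if e.sum() == 0:
        raise ParameterError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        risk = t >= tt
        n = int(risk.sum())
        n1 = int((risk & in_a).sum())
        d = int(((t == tt) & (e == 1)).sum())
        d1 = int(((t == tt) & (e == 1) & in_a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
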