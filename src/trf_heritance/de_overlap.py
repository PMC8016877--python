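"""TPM normalization, two-condition differential expression, cross-generation
overlap and composition summaries for tRF count matrices.

Expression is normalized to TPM (columns sum to 1e6).  Because all tRFs in a
30-45 nt gel slice have nearly the same length, the default skips the
per-kilobase rate and is a counts-per-million of weighted counts; classic
length-normalized TPM is available by flag.

The differential test defaults to a two-sided Welch t-test on log2(TPM+1)
with Benjamini-Hochberg correction; at the design's n = 3-4 replicates an
exact label-permutation test on the mean log2 difference is provided as an
assumption-free alternative.  The cross-generation overlap is the set of
species significant in both comparisons with the same direction of change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, ParameterError

TPM_SCALE = 1e6


@dataclass
class ExpressionMatrix:
    """TPM values (species x samples) plus the sample -> group map."""

    values: pd.DataFrame
    groups: dict[str, str]

    def samples_in(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.groups.get(s) == group]
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return cols


@dataclass
class OverlapReport:
    """Species significant in two comparisons with consistent direction."""

    species: list[str]
    directions: dict[str, str]
    n_up_shared: int
    n_down_shared: int


def tpm_normalize(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    lengths: Mapping[str, float] | None = None,
    length_normalize: bool = False,
) -> ExpressionMatrix:
    """Scale each sample column to 1e6.

    With ``length_normalize`` the count of each species is first divided by
    its length in kb (classic TPM); otherwise columns are plain
    counts-per-million.  All-zero columns stay zero, with a warning.
    """
    if (counts.values < 0).any():
        raise ParameterError("counts must be non-negative")
    rates = counts.astype(float)
    if length_normalize:
        if lengths is None:
            raise KeyError("lengths required when length_normalize=True")
        missing = [s for s in counts.index if s not in lengths]
        if missing:
            raise KeyError(f"missing lengths for species: {missing}")
        kb = pd.Series({s: lengths[s] / 1000.0 for s in counts.index})
        if (kb <= 0).any():
            raise ParameterError("species lengths must be > 0")
        rates = rates.div(kb, axis=0)
    sums = rates.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"all-zero count column(s): {list(sums.index[zero])}")
        sums = sums.replace(0, 1.0)
    tpm = rates.div(sums, axis=1) * TPM_SCALE
    return ExpressionMatrix(tpm, dict(groups or {}))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_permutation_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p for the difference of group means."""
    pooled = np.concatenate([a, b])
    n_a = a.size
    obs = abs(b.mean() - a.mean())
    idx = range(pooled.size)
    total = hits = 0
    for comb in combinations(idx, n_a):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        d = abs(pooled[~mask].mean() - pooled[mask].mean())
        hits += d >= obs - 1e-12
        total += 1
    return hits / total


def de_test(
    expr: ExpressionMatrix,
    group_A: str,
    group_B: str,
    alpha: float = 0.05,
    method: str = "welch_log",
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Per-species differential expression of group_B relative to group_A.

    Returns a frame indexed by species with mean_A/mean_B (TPM),
    log2_fold_change (difference of group means of log2(TPM+1)), p_value,
    q_value (BH), significant and direction.  Significance is q < alpha by
    default, or raw p < alpha with ``use_raw_p``.
    """
    if method not in ("welch_log", "exact_permutation"):
        raise ParameterError(f"unknown method {method!r}")
    cols_a = expr.samples_in(group_A)
    cols_b = expr.samples_in(group_B)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ParameterError("each group needs >= 2 samples")

    log_a = np.log2(expr.values[cols_a].to_numpy() + 1.0)
    log_b = np.log2(expr.values[cols_b].to_numpy() + 1.0)
    mean_a = expr.values[cols_a].mean(axis=1)
    mean_b = expr.values[cols_b].mean(axis=1)
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)

    pvals = np.empty(len(expr.values.index))
    for i in range(pvals.size):
        a, b = log_a[i], log_b[i]
        if a.var() == 0.0 and b.var() == 0.0:
            pvals[i] = 1.0 if a.mean() == b.mean() else 0.0
        elif method == "welch_log":
            pvals[i] = stats.ttest_ind(b, a, equal_var=False).pvalue
        else:
            pvals[i] = _exact_permutation_p(a, b)
    qvals = bh_adjust(pvals)
    sig = (pvals < alpha) if use_raw_p else (qvals < alpha)
    direction = np.where(~sig | (lfc == 0), "none", np.where(lfc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "significant": sig,
            "direction": direction,
        },
        index=expr.values.index,
    )


def overlap_analysis(de_F0: pd.DataFrame, de_F1: pd.DataFrame) -> OverlapReport:
    """Species significant in both comparisons with identical direction."""
    if set(de_F0.index) != set(de_F1.index):
        raise ContractError("the two comparisons cover different species universes")
    shared, directions = [], {}
    for sp in de_F0.index:
        r0, r1 = de_F0.loc[sp], de_F1.loc[sp]
        if r0["significant"] and r1["significant"] and r0["direction"] == r1["direction"] \
                and r0["direction"] != "none":
            shared.append(sp)
            directions[sp] = r0["direction"]
    shared.sort()
    n_up = sum(1 for s in shared if directions[s] == "up")
    return OverlapReport(shared, directions, n_up, len(shared) - n_up)


@dataclass
class CompositionSummary:
    species: list[str]  # the top_k species, by mean abundance
    per_sample: pd.Series  # combined fraction of those species per sample
    group_mean: pd.Series  # combined fraction averaged within each group
    overall_mean: float


def composition_summary(expr: ExpressionMatrix, top_k: int) -> CompositionSummary:
    """Combined abundance fraction of the ``top_k`` most abundant species.

    Top species are ranked by mean fraction across samples, ties broken by
    label; fractions are TPM / 1e6 per sample.
    """
    n_species = len(expr.values.index)
    if top_k < 1 or top_k > n_species:
        raise ParameterError(f"top_k must lie in [1, {n_species}]")
    frac = expr.values / TPM_SCALE
    order = (
        frac.mean(axis=1)
        .to_frame("mean")
        .assign(label=lambda d: d.index)
        .sort_values(["mean", "label"], ascending=[False, True])
    )
    top = list(order.index[:top_k])
    per_sample = frac.loc[top].sum(axis=0)
    if expr.groups:
        group_mean = per_sample.groupby(per_sample.index.map(expr.groups)).mean()
    else:
        group_mean = pd.Series({"all": per_sample.mean()})
    return CompositionSummary(top, per_sample, group_mean, float(per_sample.mean()))


def scatter_table(expr: ExpressionMatrix, group_A: str, group_B: str) -> pd.DataFrame:
    """Per-species group means on the log10(TPM+1) scale (scatterplot axes)."""
    cols_a = expr.samples_in(group_A)
    cols_b = expr.samples_in(group_B)
    return pd.DataFrame(
        {
            "mean_A": np.log10(expr.values[cols_a] + 1.0).mean(axis=1),
            "mean_B": np.log10(expr.values[cols_b] + 1.0).mean(axis=1),
        },
        index=expr.values.index,
    )
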