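"""Target prediction for tRFs and hypergeometric term enrichment.

A gene is called a target of a tRF only if it passes two independent
predictors, the intersect-two-tools strategy common in small-RNA target
screens:

1. a seed-match scan for exact antiparallel Watson-Crick complements of the
   tRF 5' seed (positions 2-7 = 6mer, 2-8 = 7mer, 7mer with a site-adjacent
   A = 8mer) in the 3'UTR; a gene qualifies with at least one 7mer/8mer site;
2. a simplified miRanda-style duplex scorer: the best ungapped antiparallel
   pairing of the tRF against the UTR with match +5, G:U wobble +1, mismatch
   -3 (seed positions 2-8 weighted x2), and an additive pair energy of
   G:C -3, A:T -2, G:U -1 kcal/mol; a gene qualifies when some site reaches
   score >= 150 AND energy <= -20.

The scorer's constants are explicit and its thresholds configurable; its
absolute scale is not comparable to the original miRanda tool's.  Enrichment
of the final gene list is a one-sided hypergeometric over-representation
test per term with BH correction, reported below a configurable FDR cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de_overlap import bh_adjust
from .errors import ContractError, FormatError, ParameterError

MATCH_SCORE = 5.0
WOBBLE_SCORE = 1.0
MISMATCH_SCORE = -3.0
SEED_WEIGHT = 2.0
SEED_SPAN = (1, 8)  # 0-based half-open: tRF positions 2-8, 1-based

PAIR_ENERGY = {"GC": -3.0, "AT": -2.0, "GU": -1.0}

DEFAULT_SCORE_MIN = 150.0
DEFAULT_ENERGY_MAX = -20.0

# column layout of the enrichment result frame (one row per term)
ENRICHMENT_COLUMNS = ["term_id", "k", "K", "n", "N", "p_value", "fdr"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _clean(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s or set(s) - set("ACGT"):
        raise FormatError(f"{what} contains non-ACGT(U) symbols: {seq[:30]!r}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetHit:
    trf_id: str
    gene_id: str
    site_start: int  # 0-based UTR offset of the best seed site
    seed_type: str  # "6mer" | "7mer" | "8mer"
    duplex_score: float
    duplex_energy: float


def seed_sites(trf_sequence: str, utr_sequence: str) -> list[tuple[int, str]]:
    """All seed-complementary sites in a UTR, strongest type per site.

    The 7mer site sequence is the reverse complement of tRF positions 2-8;
    an 8mer additionally has an A immediately 3' of the site (opposite tRF
    position 1).  6mer sites (complement of positions 2-7) are reported only
    where they are not part of a 7mer site.
    """
    trf = _clean(trf_sequence, "tRF")
    utr = _clean(utr_sequence, "UTR")
    if len(trf) < 8:
        raise ParameterError("tRF must be at least 8 nt for a seed scan")
    site7 = revcomp(trf[SEED_SPAN[0]:SEED_SPAN[1]])  # 7 nt
    site6 = revcomp(trf[SEED_SPAN[0]:SEED_SPAN[1] - 1])  # 6 nt == site7[1:]
    found: list[tuple[int, str]] = []
    pos = utr.find(site7)
    while pos >= 0:
        kind = "8mer" if pos + 7 < len(utr) and utr[pos + 7] == "A" else "7mer"
        found.append((pos, kind))
        pos = utr.find(site7, pos + 1)
    sevens = {p for p, _ in found}
    pos = utr.find(site6)
    while pos >= 0:
        if pos - 1 not in sevens:
            found.append((pos, "6mer"))
        pos = utr.find(site6, pos + 1)
    return sorted(found)


_SCORE_LUT = np.full((4, 4), MISMATCH_SCORE)
_ENERGY_LUT = np.zeros((4, 4))
_IDX = {b: i for i, b in enumerate("ACGT")}
for _a, _b, _e in [("G", "C", "GC"), ("C", "G", "GC"), ("A", "T", "AT"), ("T", "A", "AT")]:
    _SCORE_LUT[_IDX[_a], _IDX[_b]] = MATCH_SCORE
    _ENERGY_LUT[_IDX[_a], _IDX[_b]] = PAIR_ENERGY[_e]
for _a, _b in [("G", "T"), ("T", "G")]:
    _SCORE_LUT[_IDX[_a], _IDX[_b]] = WOBBLE_SCORE
    _ENERGY_LUT[_IDX[_a], _IDX[_b]] = PAIR_ENERGY["GU"]


def _encode(seq: str) -> np.ndarray:
    return np.array([_IDX[c] for c in seq], dtype=np.int64)


def _scan_pairings(trf: str, target: str) -> tuple[float, float, int]:
    """Best ungapped antiparallel pairing of ``trf`` against any stretch of
    ``target``; returns (score, energy, 0-based target offset of the paired
    stretch).  tRF position i pairs with stretch position len-1-i."""
    t = _encode(trf)
    n = len(trf)
    g = _encode(target)
    if g.size < n:
        raise ParameterError("target shorter than the tRF")
    windows = np.lib.stride_tricks.sliding_window_view(g, n)[:, ::-1]
    weights = np.ones(n)
    weights[SEED_SPAN[0]:SEED_SPAN[1]] = SEED_WEIGHT
    pair_scores = _SCORE_LUT[t[None, :], windows]
    scores = (pair_scores * weights[None, :]).sum(axis=1)
    top = scores.max()
    # score ties are broken by the most stable (lowest) duplex energy
    candidates = np.nonzero(scores == top)[0]
    energies = _ENERGY_LUT[t[None, :], windows[candidates]].sum(axis=1)
    pick = int(candidates[int(np.argmin(energies))])
    return float(top), float(energies.min()), pick


def duplex_score(trf_sequence: str, utr_window: str) -> tuple[float, float]:
    """Score and energy of the best pairing register of a tRF in a window.

    The window must be between the tRF length and tRF length + 10; every
    register of the (ungapped, antiparallel) duplex is evaluated and the
    best-scoring one is returned.
    """
    trf = _clean(trf_sequence, "tRF")
    window = _clean(utr_window, "window")
    if not len(trf) <= len(window) <= len(trf) + 10:
        raise ParameterError(
            f"window length {len(window)} outside [{len(trf)}, {len(trf) + 10}]"
        )
    score, energy, _ = _scan_pairings(trf, window)
    return score, energy


def predict_targets(
    trfs: Mapping[str, str],
    utr_db: Mapping[str, str] | Iterable[tuple[str, str]],
    score_min: float = DEFAULT_SCORE_MIN,
    energy_max: float = DEFAULT_ENERGY_MAX,
) -> list[TargetHit]:
    """Genes passing BOTH predictors for each tRF.

    seed predictor: >= one 7mer/8mer seed site in the UTR;
    duplex predictor: best pairing with score >= score_min and energy <=
    energy_max.  Returns one TargetHit per (tRF, gene) pair that passes.
    """
    if not np.isfinite(score_min) or not np.isfinite(energy_max):
        raise ParameterError("thresholds must be finite")
    utr_items = list(utr_db.items()) if isinstance(utr_db, Mapping) else list(utr_db)
    if not utr_items:
        raise ParameterError("empty UTR database")
    hits = []
    for trf_id, trf_seq in trfs.items():
        trf = _clean(trf_seq, f"tRF {trf_id}")
        for gene_id, utr_seq in utr_items:
            utr = _clean(utr_seq, f"UTR {gene_id}")
            if len(utr) < len(trf):
                continue
            sites = [s for s in seed_sites(trf, utr) if s[1] in ("7mer", "8mer")]
            if not sites:
                continue
            score, energy, _ = _scan_pairings(trf, utr)
            if score >= score_min and energy <= energy_max:
                # strongest site, earliest position on ties
                best_site = max(sites, key=lambda s: (s[1] == "8mer", -s[0]))
                hits.append(TargetHit(trf_id, gene_id, best_site[0], best_site[1],
                                      score, energy))
    return hits


def enrich(
    query_genes: Iterable[str],
    annotation: pd.DataFrame,
    universe: Iterable[str],
    fdr_max: float | None = 0.25,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, BH-corrected.

    ``annotation`` has columns gene_id, term_id.  Rows with fdr < ``fdr_max``
    are returned sorted by p-value; pass ``fdr_max=None`` for the full table.
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        raise ContractError(f"query genes outside the universe: {sorted(outside)}")
    ann = annotation[annotation["gene_id"].isin(universe)]
    N, n = len(universe), len(query)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        members = set(genes)
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    table = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"])
        table = table.sort_values(["p_value", "term_id"]).reset_index(drop=True)
        if fdr_max is not None:
            table = table[table["fdr"] < fdr_max].reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table
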