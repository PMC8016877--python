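"""Alignment of cleaned tRF tags to a tRNA reference and weighted-read
counting.

tRF quantification is complicated by isoacceptor families whose members are
nearly identical: many tags align equally well to several reference tRNAs.
Reads are therefore split into *unique* reads (best hits on exactly one
reference) and *shared* reads (ties across several), and per-reference
abundance is computed as weighted reads::

    weighted reads = unique reads + alignment score % * shared reads

where the alignment score percent of a hit is 100 * matches / read_length of
an ungapped sense-strand alignment.  Two readings of the formula are
implemented:

* ``literal`` — each shared read adds score%/100 to every reference in its
  shared set (the formula applied verbatim; total mass of a shared read may
  exceed 1);
* ``normalized`` — each shared read's contributions are rescaled to sum to
  exactly 1, so per-sample weighted totals equal the number of mapped reads.

Alignment is ungapped, sense strand only (small-RNA libraries are stranded),
scanning every offset of every reference; per reference only the
best-scoring offset is kept, ties broken by the smallest start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .preprocess import ReadRecord
from .simgen import TRNAReference

MIN_READ_LEN = 15
DEFAULT_MIN_SCORE_PERCENT = 85.0

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_id: str
    start: int  # 0-based offset on the reference
    matches: int
    score_percent: float


@dataclass(frozen=True)
class ReadAssignment:
    """Mapping status of one read: unmapped, unique (one reference) or shared
    (>= 2 references with per-reference score percents)."""

    read_id: str
    status: str  # "unmapped" | "unique" | "shared"
    ref_id: str | None = None
    scores: dict[str, float] | None = None  # shared only: ref_id -> score %


@dataclass
class TRFCountTable:
    """Per-reference unique/shared/weighted counts for one sample."""

    counts: pd.DataFrame  # index ref_id; columns unique, shared_contrib, weighted
    totals: dict[str, int]  # n_mapped, n_unique, n_shared
    sample: str | None = None
    mode: str = "literal"


class ReferenceIndex:
    """Window bank over a tRNA reference for vectorised ungapped alignment.

    For each read length L the index holds every length-L window of every
    reference as one uint8 matrix, so scoring a read against all offsets of
    all references is a single numpy comparison.
    """

    def __init__(self, ref: TRNAReference):
        self.ref = ref
        self.ref_ids = [e.ref_id for e in ref.entries]
        self._enc = [_encode(e.sequence) for e in ref.entries]
        self._banks: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _bank(self, L: int):
        """(windows (n,L), segments, start (n,)) for read length L, where
        segments is a list of (ref_index, lo, hi) window slices, windows
        being concatenated in reference order and start-ordered within."""
        if L not in self._banks:
            wins, starts, segments = [], [], []
            pos = 0
            for i, enc in enumerate(self._enc):
                n_off = enc.size - L + 1
                if n_off <= 0:
                    continue
                wins.append(np.lib.stride_tricks.sliding_window_view(enc, L))
                starts.append(np.arange(n_off))
                segments.append((i, pos, pos + n_off))
                pos += n_off
            if wins:
                self._banks[L] = (
                    np.ascontiguousarray(np.concatenate(wins)),
                    segments,
                    np.concatenate(starts),
                )
            else:
                self._banks[L] = (np.empty((0, L), dtype=np.uint8), [], np.empty(0, dtype=int))
        return self._banks[L]

    def match_counts(self, reads_enc: np.ndarray):
        """Match counts of each read (rows) against every window of length
        reads_enc.shape[1]; returns (matches, segments, start)."""
        L = reads_enc.shape[1]
        wins, segments, starts = self._bank(L)
        if wins.shape[0] == 0 or reads_enc.shape[0] == 0:
            return np.empty((reads_enc.shape[0], 0), dtype=np.int64), segments, starts
        out = np.empty((reads_enc.shape[0], wins.shape[0]), dtype=np.int64)
        # chunk reads to cap the (reads x windows x L) comparison buffer
        step = max(1, int(4e7 // max(1, wins.shape[0] * L)))
        for lo in range(0, reads_enc.shape[0], step):
            chunk = reads_enc[lo : lo + step]
            out[lo : lo + step] = (chunk[:, None, :] == wins[None, :, :]).sum(axis=2)
        return out, segments, starts

    def best_scores(self, reads_enc: np.ndarray):
        """Best match count per (read, reference): returns (best (n_reads,
        n_segments) array, reference indices of the segments)."""
        matches, segments, _ = self.match_counts(reads_enc)
        if not segments:
            return np.empty((reads_enc.shape[0], 0), dtype=np.int64), []
        bounds = np.array([lo for _, lo, _ in segments])
        best = np.maximum.reduceat(matches, bounds, axis=1)
        return best, [i for i, _, _ in segments]


def align_read(
    read: ReadRecord | str,
    ref: TRNAReference | ReferenceIndex,
    min_score_percent: float = DEFAULT_MIN_SCORE_PERCENT,
) -> list[AlignmentHit]:
    """All ungapped sense-strand alignments of a read with score percent >=
    ``min_score_percent``; one best-offset hit per reference, score ties
    within a reference broken by the smallest start."""
    if isinstance(read, str):
        read = ReadRecord("read", read, "I" * len(read))
    if len(read) < MIN_READ_LEN:
        raise ParameterError(f"read {read.read_id!r}: length {len(read)} < {MIN_READ_LEN}")
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    enc = _encode(read.sequence)[None, :]
    matches, segments, starts = index.match_counts(enc)
    return _hits_for_read(read.read_id, len(read), matches[0], segments, starts,
                          index.ref_ids, min_score_percent)


def _hits_for_read(
    read_id: str,
    read_len: int,
    matches: np.ndarray,
    segments: list[tuple[int, int, int]],
    starts: np.ndarray,
    ref_ids: Sequence[str],
    min_score_percent: float,
) -> list[AlignmentHit]:
    hits = []
    for i, lo, hi in segments:
        m = matches[lo:hi]
        best = int(m.max())
        score = 100.0 * best / read_len
        if score >= min_score_percent:
            # windows are start-ordered, argmax returns the smallest start
            start = int(starts[lo:hi][int(np.argmax(m))])
            hits.append(AlignmentHit(read_id, ref_ids[i], start, best, score))
    return hits


def classify(hits: list[AlignmentHit], best_margin_percent: float = 0.0) -> ReadAssignment:
    """Partition one read's hits into unmapped / unique / shared.

    Shared sets contain every reference scoring within ``best_margin_percent``
    of the best hit; if the margin rule leaves a single eligible reference
    the read counts as unique to it.
    """
    if not hits:
        return ReadAssignment("", "unmapped")
    ids = {h.read_id for h in hits}
    if len(ids) != 1:
        raise ContractError(f"classify() received hits from multiple reads: {sorted(ids)}")
    read_id = hits[0].read_id
    best = max(h.score_percent for h in hits)
    eligible = [h for h in hits if h.score_percent >= best - best_margin_percent]
    if len(eligible) == 1:
        return ReadAssignment(read_id, "unique", ref_id=eligible[0].ref_id)
    return ReadAssignment(
        read_id, "shared", scores={h.ref_id: h.score_percent for h in eligible}
    )


def assign_reads(
    reads: Iterable[ReadRecord],
    ref: TRNAReference | ReferenceIndex,
    min_score_percent: float = DEFAULT_MIN_SCORE_PERCENT,
    best_margin_percent: float = 0.0,
) -> list[ReadAssignment]:
    """Align and classify a whole sample, memoising per distinct sequence."""
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    reads = list(reads)
    # bucket distinct sequences by length for one vectorised pass per length
    by_len: dict[int, dict[str, None]] = {}
    for rec in reads:
        if len(rec) >= MIN_READ_LEN:
            by_len.setdefault(len(rec), {})[rec.sequence] = None
    cache: dict[str, tuple[str, str | None, dict[str, float] | None]] = {}
    for L, seqmap in by_len.items():
        seqs = list(seqmap)
        enc = np.stack([_encode(s) for s in seqs])
        best, seg_refs = index.best_scores(enc)
        scores = 100.0 * best / L if best.size else best.astype(float)
        passing = scores >= min_score_percent
        ref_ids = index.ref_ids
        for row, seq in enumerate(seqs):
            cols = np.nonzero(passing[row])[0] if scores.size else []
            if len(cols) == 0:
                cache[seq] = ("unmapped", None, None)
                continue
            hits = [
                AlignmentHit("x", ref_ids[seg_refs[c]], 0, int(best[row, c]),
                             float(scores[row, c]))
                for c in cols
            ]
            a = classify(hits, best_margin_percent)
            cache[seq] = (a.status, a.ref_id, a.scores)
    out = []
    for rec in reads:
        entry = cache.get(rec.sequence)
        if entry is None:
            out.append(ReadAssignment(rec.read_id, "unmapped"))
        else:
            status, rid, scores = entry
            out.append(ReadAssignment(rec.read_id, status, ref_id=rid,
                                      scores=dict(scores) if scores else None))
    return out


def weighted_counts(
    assignments: Iterable[ReadAssignment],
    mode: str = "literal",
    sample: str | None = None,
) -> TRFCountTable:
    """Accumulate unique/shared/weighted counts for one sample.

    literal:    shared read adds score%/100 to each reference in its set.
    normalized: shared read's contributions are rescaled to total exactly 1.
    """
    if mode not in ("literal", "normalized"):
        raise ParameterError(f"unknown mode {mode!r}")
    unique: dict[str, int] = {}
    shared: dict[str, float] = {}
    n_unique = n_shared = 0
    for a in assignments:
        if a.status == "unique":
            unique[a.ref_id] = unique.get(a.ref_id, 0) + 1
            n_unique += 1
        elif a.status == "shared":
            n_shared += 1
            if mode == "literal":
                for r, s in a.scores.items():
                    shared[r] = shared.get(r, 0.0) + s / 100.0
            else:
                total = sum(a.scores.values())
                for r, s in a.scores.items():
                    shared[r] = shared.get(r, 0.0) + s / total
        elif a.status != "unmapped":
            raise ContractError(f"unknown assignment status {a.status!r}")
    refs = sorted(set(unique) | set(shared))
    df = pd.DataFrame(
        {
            "unique": [unique.get(r, 0) for r in refs],
            "shared_contrib": [shared.get(r, 0.0) for r in refs],
        },
        index=pd.Index(refs, name="ref_id"),
    )
    df["weighted"] = df["unique"] + df["shared_contrib"]
    totals = {"n_mapped": n_unique + n_shared, "n_unique": n_unique, "n_shared": n_shared}
    return TRFCountTable(df, totals, sample=sample, mode=mode)


def count_matrix(
    samples: Sequence[TRFCountTable],
    ref: TRNAReference,
    collapse: str = "by_ref",
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Weighted-count matrix (rows = species, columns = samples).

    ``by_isoacceptor`` sums family members; species absent from a sample get
    0.  Every counted reference must belong to ``ref``.
    """
    if collapse not in ("by_ref", "by_isoacceptor"):
        raise ParameterError(f"unknown collapse {collapse!r}")
    if sample_names is None:
        sample_names = [t.sample or f"S{i + 1}" for i, t in enumerate(samples)]
    if len(sample_names) != len(samples):
        raise ParameterError("sample_names must match samples")
    by_id = ref.by_id
    cols = {}
    for name, table in zip(sample_names, samples):
        extra = set(table.counts.index) - set(by_id)
        if extra:
            raise ContractError(f"sample {name!r} counts unknown references: {sorted(extra)}")
        cols[name] = table.counts["weighted"]
    mat = pd.DataFrame(cols, index=pd.Index(list(by_id), name="ref_id")).fillna(0.0)
    if collapse == "by_isoacceptor":
        iso = pd.Series({r: by_id[r].isoacceptor for r in mat.index})
        mat = mat.groupby(iso.reindex(mat.index)).sum()
        mat.index.name = "isoacceptor"
    return mat


def quantify_sample(
    reads: Iterable[ReadRecord],
    ref: TRNAReference | ReferenceIndex,
    mode: str = "literal",
    min_score_percent: float = DEFAULT_MIN_SCORE_PERCENT,
    best_margin_percent: float = 0.0,
    sample: str | None = None,
) -> TRFCountTable:
    """align -> classify -> weighted counts for one cleaned library."""
    assignments = assign_reads(reads, ref, min_score_percent, best_margin_percent)
    return weighted_counts(assignments, mode=mode, sample=sample)


def assignments_frame(assignments: Iterable[ReadAssignment]) -> pd.DataFrame:
    """Tidy per-read assignment table (for the TSV report)."""
    rows = []
    for a in assignments:
        if a.status == "shared":
            refs = ";".join(sorted(a.scores))
            scores = ";".join(f"{a.scores[r]:.2f}" for r in sorted(a.scores))
        elif a.status == "unique":
            refs, scores = a.ref_id, ""
        else:
            refs, scores = "", ""
        rows.append((a.read_id, a.status, refs, scores))
    return pd.DataFrame(rows, columns=["read_id", "status", "refs", "score_percents"])
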