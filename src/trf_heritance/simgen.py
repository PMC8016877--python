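"""Ground-truth simulator for sperm small-RNA (tRF) sequencing studies.

The generator emulates the statistical structure the downstream pipeline
assumes, at desk scale:

* a closed tRNA reference of isoacceptor families whose members are mutated
  copies of a family ancestor, so that 5' fragments of different members are
  often identical -> multi-mapping ("shared") reads;
* libraries of 5'-anchored tRNA fragments, 30-45 nt before the 3' adapter,
  with a composition dominated by two species (GlyGCC + GluCTC = 70% in the
  packaged study fixture) and planted fold-changes on a small set of species
  shared between two generations;
* multinomial sequencing of that composition with optional Dirichlet
  replicate overdispersion and i.i.d. substitution errors;
* synthetic 3'UTR / gene-term annotation databases for target prediction,
  and phenotype tables (insulin-tolerance glucose series, tumor onset times)
  for the phenotype statistics.

Every emitted read carries a truth row (source reference, fragment
coordinates), which is what the recovery tests are scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import DEFAULT_ADAPTER, ReadRecord

BASES = "ACGT"

# Isoacceptor labels used for generated families, in assignment order.  The
# first seven are the species tracked in the packaged study fixture.
ISOACCEPTOR_NAMES = [
    "GlyGCC", "GluCTC", "ValTAC", "SerCGA", "ArgCCG", "ArgTCG", "SeCTCA",
    "LysCTT", "HisGTG", "AspGTC", "ProAGG", "ThrTGT", "AlaAGC", "LeuCAA",
]

# Packaged study fixture: two dominant species summing to exactly 70%, and
# five perturbed species whose planted fold-changes are mass-balanced
# (+2*0.03*3 = -3*0.08*0.75 = 0.18), so renormalisation leaves non-target
# species with zero compositional fold-change.
STUDY_COMPOSITION: dict[str, float] = {
    "GlyGCC": 0.38,
    "GluCTC": 0.32,
    "ValTAC": 0.03,
    "SerCGA": 0.03,
    "ArgCCG": 0.08,
    "ArgTCG": 0.08,
    "SeCTCA": 0.08,
}
STUDY_EFFECTS: dict[str, float] = {
    "ValTAC": 4.0,
    "SerCGA": 4.0,
    "ArgCCG": 0.25,
    "ArgTCG": 0.25,
    "SeCTCA": 0.25,
}
STUDY_REF_SEED = 101


def child_rng(seed: int, *counters: int) -> np.random.Generator:
    """Child generator for (master seed, counter...) — the documented seed
    scheme: each library gets SeedSequence([master, generation, condition,
    replicate]) so adding libraries never perturbs earlier ones."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, counters)]))


# ---------------------------------------------------------------------------
# tRNA reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefEntry:
    ref_id: str
    isoacceptor: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TRNAReference:
    """Named tRNA sequences grouped into isoacceptor families."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ParameterError("reference ref_ids must be unique")
        for e in self.entries:
            if not e.sequence or set(e.sequence) - set(BASES):
                raise ParameterError(f"{e.ref_id}: sequence must be non-empty over ACGT")
            if not 60 <= e.length <= 100:
                raise ParameterError(f"{e.ref_id}: length {e.length} outside [60, 100]")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def by_id(self) -> dict[str, RefEntry]:
        return {e.ref_id: e for e in self.entries}

    @property
    def isoacceptors(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.isoacceptor, None)
        return list(seen)

    def members(self, isoacceptor: str) -> list[RefEntry]:
        return [e for e in self.entries if e.isoacceptor == isoacceptor]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.ref_id} isoacceptor={e.isoacceptor}\n{e.sequence}\n")

    @classmethod
    def read_fasta(cls, path) -> "TRNAReference":
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            iso = None
            for tok in rec.description.split():
                if tok.startswith("isoacceptor="):
                    iso = tok.split("=", 1)[1]
            if iso is None:
                iso = rec.id.rsplit("-", 1)[0]
            entries.append(RefEntry(rec.id, iso, str(rec.seq).upper().replace("U", "T")))
        return cls(entries)


def _mutation_rate(identity: float) -> float:
    # Members are independent mutants of a family ancestor; two members match
    # at a position with probability (1-m)^2 + m^2/3 (mutations pick one of
    # the three other bases).  Solve that for the requested pairwise identity;
    # below the random-sequence floor of 1/4 use the maximal rate 3/4.
    if identity >= 1.0:
        return 0.0
    if identity < 0.25:
        return 0.75
    return (3.0 - math.sqrt(9.0 - 12.0 * (1.0 - identity))) / 4.0


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        cur = np.zeros(arr.size, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            cur[arr == b] = i
        shift = rng.integers(1, 4, size=int(hit.sum()))  # to one of the 3 other bases
        arr[hit] = lut[(cur[hit] + shift) % 4]
    return arr.tobytes().decode()


def make_reference(
    n_families: int,
    members_per_family: int,
    within_family_identity: float,
    length_range: tuple[int, int] = (70, 90),
    seed: int = 0,
    isoacceptors: Sequence[str] | None = None,
) -> TRNAReference:
    """Generate a family-structured tRNA reference.

    Each family has a random ancestor; members are independent per-base
    mutants of it, calibrated so expected pairwise identity within a family
    matches ``within_family_identity``.
    """
    if n_families < 1 or members_per_family < 1:
        raise ParameterError("n_families and members_per_family must be >= 1")
    if not 0.0 <= within_family_identity <= 1.0:
        raise ParameterError("within_family_identity must lie in [0, 1]")
    lo, hi = length_range
    if not (60 <= lo <= hi <= 100):
        raise ParameterError("length_range must satisfy 60 <= min <= max <= 100")
    if isoacceptors is None:
        isoacceptors = [
            ISOACCEPTOR_NAMES[i] if i < len(ISOACCEPTOR_NAMES) else f"Iso{i + 1:02d}"
            for i in range(n_families)
        ]
    elif len(isoacceptors) != n_families:
        raise ParameterError("need one isoacceptor label per family")

    rng = child_rng(seed, 0)
    rate = _mutation_rate(within_family_identity)
    entries = []
    for iso in isoacceptors:
        length = int(rng.integers(lo, hi + 1))
        ancestor = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        for k in range(members_per_family):
            entries.append(RefEntry(f"{iso}-{k + 1}", iso, _mutate(ancestor, rate, rng)))
    return TRNAReference(entries)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design and noise parameters for one simulated experiment.

    Defaults are the packaged desk-scale study conditions: 4 replicates per
    condition per generation, 10^4 reads per library, 30-45 nt fragments,
    GlyGCC+GluCTC at a combined 70%, and mass-balanced 4x / 0.25x planted
    fold-changes on the five species perturbed in the treatment condition.
    """

    n_families: int = 7
    members_per_family: int = 3
    within_family_identity: float = 0.95
    composition: dict[str, float] = field(default_factory=lambda: dict(STUDY_COMPOSITION))
    depth: int = 10_000
    length_window: tuple[int, int] = (30, 45)
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.005
    effects: dict[str, float] = field(default_factory=lambda: dict(STUDY_EFFECTS))
    replicates: int = 4
    seed: int = 0
    treatment: str = "OID"
    overdispersion: float | None = 1000.0
    fragment_mode: str = "five_prime"  # or "uniform"
    partial_adapter: bool = False

    def validate(self) -> None:
        total = sum(self.composition.values())
        if min(self.composition.values(), default=0.0) < 0 or abs(total - 1.0) > 1e-9:
            raise ParameterError("composition proportions must be >= 0 and sum to 1")
        if any(fc <= 0 for fc in self.effects.values()):
            raise ParameterError("fold-changes must be > 0")
        if self.depth < 0:
            raise ParameterError("depth must be >= 0")
        lo, hi = self.length_window
        if not (15 <= lo <= hi <= 60):
            raise ParameterError("length_window must satisfy 15 <= min <= max <= 60")
        if not 0.0 <= self.error_rate < 1.0:
            raise ParameterError("error_rate must lie in [0, 1)")
        if self.fragment_mode not in ("five_prime", "uniform"):
            raise ParameterError("fragment_mode must be 'five_prime' or 'uniform'")


@dataclass
class TruthTable:
    """Per-read source records plus realized composition and planted effects."""

    reads: pd.DataFrame  # read_id, source_ref_id, source_isoacceptor, fragment_start, fragment_length
    composition: dict[str, float]
    effects: dict[str, float]

    def isoacceptor_fractions(self) -> pd.Series:
        if len(self.reads) == 0:
            return pd.Series(dtype=float)
        return self.reads["source_isoacceptor"].value_counts(normalize=True).sort_index()


def effective_composition(
    composition: Mapping[str, float], effects: Mapping[str, float] | None
) -> dict[str, float]:
    """Composition after applying fold-changes, renormalized to sum 1."""
    probs = {k: v * (effects or {}).get(k, 1.0) for k, v in composition.items()}
    total = sum(probs.values())
    if total <= 0:
        raise ParameterError("effective composition has zero mass")
    return {k: v / total for k, v in probs.items()}


def simulate_library(
    ref: TRNAReference,
    config: SimConfig,
    condition: str,
    seed: int,
    read_prefix: str = "r",
) -> tuple[list[ReadRecord], TruthTable]:
    """Simulate one library: reads are contiguous reference fragments with the
    3' adapter appended and substitution errors applied to the full read.

    The planted fold-changes in ``config.effects`` act only when ``condition``
    equals ``config.treatment``.  Base qualities are constant (Q37): the
    substitution error model is the only sequence noise.
    """
    config.validate()
    iso_set = set(ref.isoacceptors)
    unknown = set(config.composition) - iso_set
    if unknown:
        raise KeyError(f"composition references unknown isoacceptors: {sorted(unknown)}")

    effects = config.effects if condition == config.treatment else {}
    probs = effective_composition(config.composition, effects)
    isos = sorted(probs)
    p = np.array([probs[i] for i in isos], dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    if config.overdispersion is not None and math.isfinite(config.overdispersion):
        p = rng.dirichlet(np.maximum(config.overdispersion * p, 1e-6))

    depth = config.depth
    if depth == 0:
        truth = TruthTable(
            pd.DataFrame(
                columns=["read_id", "source_ref_id", "source_isoacceptor",
                         "fragment_start", "fragment_length"]
            ),
            composition={}, effects=dict(effects),
        )
        return [], truth

    members = {iso: ref.members(iso) for iso in isos}
    src = rng.choice(len(isos), size=depth, p=p / p.sum())
    member_idx = rng.integers(0, [len(members[isos[s]]) for s in src])
    lo, hi = config.length_window
    lengths = rng.integers(lo, hi + 1, size=depth)

    records: list[ReadRecord] = []
    rows = []
    adapter = config.adapter
    err = config.error_rate
    # vectorised pre-draws for speed
    if config.partial_adapter and adapter:
        ad_lens = rng.integers(max(1, len(adapter) // 4), len(adapter) + 1, size=depth)
    else:
        ad_lens = np.full(depth, len(adapter), dtype=int)
    for i in range(depth):
        iso = isos[src[i]]
        entry = members[iso][member_idx[i]]
        L = min(int(lengths[i]), entry.length)
        if config.fragment_mode == "five_prime":
            start = 0
        else:
            start = int(rng.integers(0, entry.length - L + 1))
        frag = entry.sequence[start : start + L]
        seq = frag + adapter[: int(ad_lens[i])]
        if err > 0:
            k = rng.binomial(len(seq), err)
            if k:
                arr = list(seq)
                for pos in rng.choice(len(seq), size=k, replace=False):
                    cur = arr[pos]
                    arr[pos] = BASES[(BASES.index(cur) + int(rng.integers(1, 4))) % 4]
                seq = "".join(arr)
        rid = f"{read_prefix}{i:06d}"
        records.append(ReadRecord(rid, seq, "F" * len(seq)))
        rows.append((rid, entry.ref_id, iso, start, L))

    reads_df = pd.DataFrame(
        rows, columns=["read_id", "source_ref_id", "source_isoacceptor",
                       "fragment_start", "fragment_length"]
    )
    realized = reads_df["source_isoacceptor"].value_counts(normalize=True).to_dict()
    return records, TruthTable(reads_df, composition=realized, effects=dict(effects))


def simulate_experiment(
    ref: TRNAReference,
    config: SimConfig,
    seed: int,
    generations: Sequence[str] = ("F0", "F1"),
    conditions: Sequence[str] = ("CO", "OID"),
) -> dict[tuple[str, str, int], tuple[list[ReadRecord], TruthTable]]:
    """Simulate the full factorial design generation x condition x replicate.

    Library seeds follow the documented counter scheme
    SeedSequence([seed, generation_index, condition_index, replicate]).
    """
    out = {}
    for gi, gen in enumerate(generations):
        for ci, cond in enumerate(conditions):
            for rep in range(1, config.replicates + 1):
                lib_seed = np.random.SeedSequence([int(seed), gi, ci, rep])
                # materialise a plain integer seed so the library is
                # reproducible in isolation
                lib_int = int(lib_seed.generate_state(1, np.uint32)[0])
                prefix = f"{gen}_{cond}_{rep}_"
                out[(gen, cond, rep)] = simulate_library(
                    ref, config, cond, seed=lib_int, read_prefix=prefix
                )
    return out


def study_reference(seed: int = STUDY_REF_SEED) -> TRNAReference:
    """The packaged study fixture's reference space: seven isoacceptor
    families, three members each, 95% within-family identity."""
    return make_reference(
        n_families=7,
        members_per_family=3,
        within_family_identity=0.95,
        length_range=(70, 90),
        seed=seed,
        isoacceptors=list(STUDY_COMPOSITION),
    )


# ---------------------------------------------------------------------------
# Annotation database (3'UTRs + gene->term table)
# ---------------------------------------------------------------------------

def make_annotation_db(
    n_genes: int,
    n_terms: int,
    genes_per_term_range: tuple[int, int],
    utr_length: int,
    planted: Mapping[str, Iterable[str]] | None = None,
    planted_sites: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Synthetic 3'UTR FASTA records and a gene->term membership table.

    ``planted`` forces given genes into given terms; ``planted_sites`` splices
    a given sequence (e.g. the reverse complement of a tRF seed) into a
    gene's UTR at a random interior position.
    """
    if n_genes < 1 or n_terms < 1 or utr_length < 1:
        raise ParameterError("n_genes, n_terms and utr_length must be positive")
    lo, hi = genes_per_term_range
    if not 1 <= lo <= hi <= n_genes:
        raise ParameterError("genes_per_term_range must satisfy 1 <= min <= max <= n_genes")

    rng = child_rng(seed, 7)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_set = set(genes)
    for src, mapping in (("planted", planted), ("planted_sites", planted_sites)):
        if mapping:
            items = set(mapping) if src == "planted_sites" else {
                g for gs in mapping.values() for g in gs
            }
            missing = items - gene_set
            if missing:
                raise KeyError(f"{src} references genes outside the universe: {sorted(missing)}")

    utrs = []
    for g in genes:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=utr_length))
        site = (planted_sites or {}).get(g)
        if site:
            site = site.upper().replace("U", "T")
            if len(site) > utr_length:
                raise ParameterError(f"planted site for {g} longer than the UTR")
            pos = int(rng.integers(0, utr_length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        utrs.append((g, seq))

    membership: dict[str, set[str]] = {}
    for t in range(n_terms):
        term = f"T{t + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        membership[term] = set(rng.choice(genes, size=size, replace=False))
    for term, gs in (planted or {}).items():
        membership.setdefault(term, set()).update(gs)
    rows = [(g, term) for term in membership for g in sorted(membership[term])]
    annot = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    return utrs, annot


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

ITT_TIMES_MIN = (0, 3, 6, 9, 12, 30)
# Fractional progress toward the glucose nadir at each ITT timepoint:
# monotone fall to the nadir at 12 min, partial rebound by 30 min.
_ITT_PROFILE = (0.0, 0.35, 0.60, 0.80, 1.00, 0.55)

DEFAULT_ITT_PARAMS = {"baseline": 120.0, "nadir_frac": 0.45, "noise_sd": 8.0}
DEFAULT_SURVIVAL_PARAMS = {"median_weeks": 14.0}


def simulate_phenotypes(
    groups: Sequence[str],
    n_per_group: int,
    itt_curve_params: Mapping[str, Mapping[str, float]] | None = None,
    survival_params: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    follow_up_weeks: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Glucose time-series (insulin tolerance test schedule 0/3/6/9/12/30 min)
    and tumor-onset records (exponential onset, right-censored at the end of
    the follow-up window), per animal.

    ``itt_curve_params[group]`` keys: baseline (mg/dL), nadir_frac (glucose at
    the nadir as a fraction of baseline; 1.0 = flat curve), noise_sd (mg/dL).
    ``survival_params[group]`` keys: median_weeks (median onset time).
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    rng = child_rng(seed, 13)
    times = np.array(ITT_TIMES_MIN, dtype=float)
    profile = np.array(_ITT_PROFILE)

    glu_rows, surv_rows = [], []
    for group in groups:
        ipar = {**DEFAULT_ITT_PARAMS, **dict((itt_curve_params or {}).get(group, {}))}
        spar = {**DEFAULT_SURVIVAL_PARAMS, **dict((survival_params or {}).get(group, {}))}
        rate = math.log(2.0) / float(spar["median_weeks"])
        for a in range(1, n_per_group + 1):
            animal = f"{group}_{a:03d}"
            mean = ipar["baseline"] * (1.0 - (1.0 - ipar["nadir_frac"]) * profile)
            values = np.maximum(mean + rng.normal(0.0, ipar["noise_sd"], size=times.size), 0.0)
            for t, v in zip(times, values):
                glu_rows.append((animal, group, t, float(v)))
            onset = rng.exponential(1.0 / rate)
            if onset <= follow_up_weeks:
                surv_rows.append((animal, group, float(onset), 1))
            else:
                surv_rows.append((animal, group, float(follow_up_weeks), 0))

    glucose = pd.DataFrame(glu_rows, columns=["animal_id", "group", "time_min", "glucose_mg_dl"])
    survival = pd.DataFrame(surv_rows, columns=["animal_id", "group", "time_weeks", "event"])
    return glucose, survival
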