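# Methods

This note documents the models, parameter choices and numerical conventions
behind each stage, what the simulator does and does not emulate, and the
design decisions taken where the underlying procedure was open.

## Simulator

**Reference model.** A tRNA reference is a set of isoacceptor families.
Each family has a random ancestor sequence (60–100 nt; default draw 70–90)
and `members_per_family` independent per-base mutants of it.  The per-member
mutation rate *m* is calibrated so the expected pairwise identity between two
members equals the requested `within_family_identity` *d*: two members agree
at a position with probability (1−m)² + m²/3 (mutations choose one of the
three other bases), giving m = (3 − √(9 − 12(1−d)))/4 for d ≥ 0.25.  Below
the random-sequence floor of 25% identity the maximal rate 3/4 is used.
Family similarity is what produces multi-mapping ("shared") reads: at the
packaged identity of 0.95, roughly half of 30–45 nt 5′ fragments are
identical between two members.

**Libraries.** Each read is a contiguous fragment of one reference sequence
— 5′-anchored by default, because sperm tRFs are predominantly 5′ halves
(`fragment_mode="uniform"` gives uniform start positions) — with length
uniform in the 30–45 nt window, the 3′ sequencing adapter appended (TruSeq
small-RNA sequence), and i.i.d. substitution errors applied to the whole
read (default rate 0.005/base).  There are no indels, which keeps the
ungapped aligner an exact model of the data; this is a documented
simplification, not a property of real libraries.  Base qualities are
constant (Q37); the substitution model is the only sequence noise, and the
quality filter is exercised by constructed reads in the tests instead.
A `partial_adapter` flag emits truncated adapters to exercise trimming
edge cases.

**Composition and planted effects.** The source isoacceptor of each read is
drawn from the configured composition; in the treatment condition each
species' proportion is multiplied by its planted fold-change and the vector
renormalized.  Replicate variability beyond multinomial sampling is modelled
as a Dirichlet jitter of the per-library composition with concentration
1000 (per-species CV of roughly 3–25% depending on abundance) — a moderate,
fixed choice in the absence of a stated replicate-noise figure.  The
packaged study fixture is

| species | CO proportion | treatment fold-change |
|---|---|---|
| GlyGCC | 0.38 | – |
| GluCTC | 0.32 | – |
| ValTAC | 0.03 | 4× |
| SerCGA | 0.03 | 4× |
| ArgCCG | 0.08 | 0.25× |
| ArgTCG | 0.08 | 0.25× |
| SeCTCA | 0.08 | 0.25× |

The dominant pair sums to exactly 70%.  The planted effects are
mass-balanced (+2·0.03·3 = −3·0.08·0.75 = 0.18), so renormalization leaves
unperturbed species with zero compositional fold-change; without this
balance, closed (compositional) data would induce spurious opposite-sign
fold-changes on every null species.  Default design: 2 generations × 2
conditions × 4 replicates, 10⁴ reads per library (desk scale; real
libraries run ≥10⁷).  Master seed → per-library seeds via
`SeedSequence([seed, generation, condition, replicate])`, so adding
libraries never perturbs existing ones, and identical configurations are
byte-identical.

**What the simulator does not model:** RNA modifications (a major real-world
confounder of tRF sequencing), ligation bias, PCR duplication, indels,
genomic background beyond the tRNA space, 3′ tRF species, or quality decay.
Passing recovery tests therefore demonstrates the pipeline's correctness on
data satisfying its own assumptions, not robustness to these artefacts.

## Read cleaning

Adapter trimming removes the longest 3′ suffix matching a prefix of the
adapter with ≥ `min_overlap` (default 3) bases and mismatch fraction ≤
`max_mismatch_rate` (default 0.1); candidate suffixes are scanned left to
right so the longest qualifying suffix wins.  The quality filter requires
every sliding window (default 4 bases) to have mean Phred ≥ 15 and the read
to be ≥ 15 nt; windows shorter than 4 (short reads) are judged on the
whole-read mean.  These defaults are small-RNA conventions; the contract
(trim, filter, select) is reproduced rather than any one trimming tool's
exact algorithm.  Size selection keeps 30–45 nt inclusive on both ends,
mirroring the gel excision window.  Reads are never trimmed from the 5′
end.  Per-library statistics satisfy the accounting identity
`n_input = n_quality_failed + (size-rejected) + n_size_selected`.

## Alignment and weighted counts

Alignment is ungapped, sense strand only (small-RNA libraries are stranded;
no reverse complement search), scoring every offset of every reference and
keeping, per reference, the best match count (ties → smallest start).  The
alignment score percent is 100 × matches / read length; hits below
`min_score_percent` (default 85) are discarded.  Internally all coordinates
are 0-based half-open.  The implementation encodes every reference window
of a given read length as one uint8 matrix, so scoring a batch of distinct
read sequences is a single vectorised comparison; a brute-force
offset-by-offset oracle in the tests pins the semantics.

Reads are classified unmapped / unique / shared.  The shared set contains
all references within `best_margin_percent` (default 0: exact ties) of the
best score; if the margin prunes the set to one reference the read counts
as unique there.

Weighted counts implement both readings of the formula
`weighted = unique + score% × shared`:

* **literal** — each shared read adds score/100 to *every* reference in its
  set.  A shared read's total contribution is ≈ its set size, so per-family
  totals are inflated by the family's internal sharing rate.  Because that
  rate varies between families (random ancestors), literal-mode
  isoacceptor *fractions* are biased when sharing is heterogeneous — a
  structural property of the formula, demonstrated in the tests, not a bug.
* **normalized** — contributions are rescaled so each shared read
  contributes total mass exactly 1; per-sample weighted totals then equal
  the mapped-read count exactly, and isoacceptor fractions recover the
  truth composition within binomial tolerance.

`literal` is the default (it applies the formula verbatim); composition-type
analyses use `normalized`, and every run manifest records the mode.

## Expression and differential testing

TPM scales each sample column to 10⁶.  Since all tRFs in a 30–45 nt gel
slice have nearly equal length, the default skips the per-kilobase rate
(counts-per-million of weighted counts); classic length-normalized TPM is a
flag, using the parent tRNA length.  All-zero columns stay zero with a
warning.

The differential test defaults to a two-sided Welch t-test on log₂(TPM+1)
— the +1 guards zeros, the log stabilises multiplicative noise — with
Benjamini–Hochberg correction across species, significance at q < α
(default 0.05; a `use_raw_p` switch exists because "p < 0.05 with
correction" is ambiguous in common usage).  Because n = 3–4 per group makes
t-distribution assumptions fragile, an exact permutation test on the
difference of group means of log₂(TPM+1) is provided; at 3v3 it enumerates
all 20 relabelings (the observed labelling is included, so p ≥ 1/20).
Species with zero variance in both groups get p = 1 when means are equal.
Direction is defined on group B relative to group A as given by the caller
(treatment vs control in the fixtures), and `none` for non-significant
species.  The cross-generation overlap is the set of species significant in
both comparisons with identical direction.

Calibration, measured by the tests and the acceptance script: under the
global null (Dirichlet-jittered multinomial libraries, no effects) the
fraction of datasets with any BH discovery at α = 0.05 stays at a few
percent; planted 4×/0.25× effects at n = 4/group are recovered with the
correct sign essentially always at the packaged noise level.

## Target prediction and enrichment

The seed is transplanted from the microRNA convention: tRF positions 2–7
(6mer) and 2–8 (7mer), counted 1-based from the 5′ end; a 7mer site with an
A immediately 3′ in the UTR is an 8mer.  Which end of a tRF drives target
recognition is unsettled; the 5′ seed is the documented default.  T and U
are equivalent on input.

The duplex scorer is an explicit stand-in for an unpublished "modified
miRanda" scorer: best ungapped antiparallel register with match +5, G:U
wobble +1, mismatch −3, seed positions ×2, plus an additive pair-energy sum
(G:C −3, A:T −2, G:U −1 kcal/mol).  Score ties between registers are broken
toward the most stable (lowest) energy.  The thresholds (score ≥ 150,
energy ≤ −20) are exposed as configuration and are calibrated to *this*
scorer's scale — they are not comparable to the original tool's units.
A gene is a predicted target only if it passes both the seed predictor
(≥ 7mer site) and the duplex predictor; prediction is monotone in both
thresholds.

Enrichment is the one-sided hypergeometric over-representation test per
term with BH correction across terms, reported below FDR 0.25 (a
conventional permissive cutoff for exploratory ontology screens).

## Phenotype statistics

AUC uses the trapezoid rule over the insulin-tolerance schedule
{0, 3, 6, 9, 12, 30} min.  One-way ANOVA is the classical between/within F;
the all-identical corner case returns F = 0, p = 1.  Two-way ANOVA is the
balanced complete-design decomposition (group, time, interaction) by
explicit sums of squares — unbalanced designs are rejected rather than
approximated, a documented limitation; with zero residual variance, effects
with positive SS get p = 0 and null effects p = 1.  The unspecified
post-hoc procedure is Holm-adjusted pairwise Welch tests (conservative,
distribution-table-free).  The log-rank test and Kaplan–Meier estimator are
computed from explicit risk tables (events-only steps, variance term
skipped when the risk set has one member), cross-checked against an
independent survival library in the tests; tumor incidence is modelled as
time-to-first-tumor per animal with right censoring at the end of
follow-up.  The phenotype simulator draws exponential onset times (group
medians configurable) and glucose curves as a fixed fall-and-rebound
profile scaled by baseline and nadir fraction with Gaussian noise.

## Problem sizes

The packaged analyses use 10⁴ reads per library (2 × 10⁴ for the
composition check), 4 replicates per condition per generation, 7
isoacceptor families × 3 members, 200 datasets for the null-FDR rate, and
20 reseeds for the overlap-recovery check — sizes chosen so every recovery
property is measurable at binomial tolerance while the full suite runs in
a couple of minutes on one CPU.
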