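"""Alignment, unique/shared classification and weighted-read counting."""

import numpy as np
import pytest

from trf_heritance import simgen
from trf_heritance.align_assign import (
    AlignmentHit,
    align_read,
    assign_reads,
    classify,
    count_matrix,
    quantify_sample,
    weighted_counts,
)
from trf_heritance.errors import ContractError, ParameterError
from trf_heritance.preprocess import ReadRecord


def brute_force_hits(read_seq, ref, min_score):
    """Independent oracle: exhaustive offset-by-offset ungapped scoring."""
    hits = {}
    for e in ref.entries:
        best, best_start = -1, None
        for start in range(len(e.sequence) - len(read_seq) + 1):
            m = sum(a == b for a, b in zip(read_seq, e.sequence[start:]))
            if m > best:
                best, best_start = m, start
        if best >= 0 and 100.0 * best / len(read_seq) >= min_score:
            hits[e.ref_id] = (best_start, best)
    return hits


def make_read(seq, rid="r1"):
    return ReadRecord(rid, seq, "I" * len(seq))


class TestAlignRead:
    def test_exact_unique_substring_scores_100(self, small_ref):
        entry = small_ref.entries[0]
        hits = align_read(make_read(entry.sequence[5:40]), small_ref, 85)
        exact = [h for h in hits if h.score_percent == 100.0]
        assert len(exact) >= 1
        assert any(h.ref_id == entry.ref_id and h.start == 5 for h in exact)

    def test_identical_family_members_force_multi_mapping(self):
        ref = simgen.make_reference(1, 2, 1.0, length_range=(70, 70), seed=4)
        frag = ref.entries[0].sequence[:35]
        hits = align_read(make_read(frag), ref, 85)
        assert {h.ref_id for h in hits if h.score_percent == 100.0} == \
            {e.ref_id for e in ref.entries}

    def test_matches_exhaustive_offset_scan(self):
        ref = simgen.make_reference(5, 2, 0.85, length_range=(60, 90), seed=8)
        rng = np.random.default_rng(17)
        for trial in range(30):
            if trial % 2:
                read_seq = "".join(rng.choice(list("ACGT"), size=35))
            else:  # reads derived from the reference hit more often
                e = ref.entries[rng.integers(len(ref))]
                start = rng.integers(0, e.length - 35 + 1)
                read_seq = e.sequence[start:start + 35]
            expected = brute_force_hits(read_seq, ref, 80)
            got = {h.ref_id: (h.start, h.matches)
                   for h in align_read(make_read(read_seq), ref, 80)}
            assert got == expected

    def test_short_read_rejected(self, small_ref):
        with pytest.raises(ParameterError):
            align_read(make_read("ACGTACGT"), small_ref)


class TestClassify:
    def test_no_hits_is_unmapped(self):
        assert classify([]).status == "unmapped"

    def test_single_hit_is_unique(self):
        a = classify([AlignmentHit("r", "A", 0, 35, 100.0)])
        assert (a.status, a.ref_id) == ("unique", "A")

    def test_margin_rule_selects_near_best_hits(self):
        hits = [AlignmentHit("r", "A", 0, 35, 100.0),
                AlignmentHit("r", "B", 3, 35, 100.0),
                AlignmentHit("r", "C", 1, 30, 85.0)]
        a = classify(hits, best_margin_percent=5.0)
        assert a.status == "shared" and set(a.scores) == {"A", "B"}

    def test_margin_pruning_to_single_ref_is_unique(self):
        hits = [AlignmentHit("r", "A", 0, 35, 100.0),
                AlignmentHit("r", "C", 1, 30, 85.0)]
        a = classify(hits, best_margin_percent=5.0)
        assert (a.status, a.ref_id) == ("unique", "A")

    def test_mixed_read_ids_rejected(self):
        hits = [AlignmentHit("r1", "A", 0, 35, 100.0),
                AlignmentHit("r2", "B", 0, 35, 100.0)]
        with pytest.raises(ContractError):
            classify(hits)


class TestWeightedCounts:
    def test_literal_formula_direct_application(self):
        assigns = [*({"status": "unique"},) * 0]
        assigns = [classify([AlignmentHit(f"u{i}", "A", 0, 35, 100.0)])
                   for i in range(10)]
        assigns.append(classify([AlignmentHit("s", "A", 0, 28, 80.0),
                                 AlignmentHit("s", "B", 0, 28, 80.0)]))
        table = weighted_counts(assigns, mode="literal")
        assert table.counts.loc["A", "weighted"] == pytest.approx(10.8)
        assert table.counts.loc["B", "weighted"] == pytest.approx(0.8)

    def test_normalized_mode_splits_symmetric_shared_read_evenly(self):
        a = classify([AlignmentHit("s", "A", 0, 35, 100.0),
                      AlignmentHit("s", "B", 0, 35, 100.0)])
        table = weighted_counts([a], mode="normalized")
        assert table.counts.loc["A", "weighted"] == pytest.approx(0.5)
        assert table.counts.loc["B", "weighted"] == pytest.approx(0.5)

    def test_matches_per_read_accumulation_oracle_both_modes(self, small_ref):
        cfg = simgen.SimConfig(depth=500,
                               composition={"GlyGCC": 0.6, "GluCTC": 0.4},
                               effects={}, adapter="", error_rate=0.01)
        reads, _ = simgen.simulate_library(small_ref, cfg, "CO", seed=21)
        assigns = assign_reads(reads, small_ref)
        for mode in ("literal", "normalized"):
            table = weighted_counts(assigns, mode=mode)
            expect: dict[str, float] = {}
            for a in assigns:
                if a.status == "unique":
                    expect[a.ref_id] = expect.get(a.ref_id, 0.0) + 1.0
                elif a.status == "shared":
                    denom = 100.0 if mode == "literal" else sum(a.scores.values())
                    for r, s in a.scores.items():
                        expect[r] = expect.get(r, 0.0) + s / denom
            for r, v in expect.items():
                assert table.counts.loc[r, "weighted"] == pytest.approx(v)

    def test_normalized_mode_conserves_mapped_reads(self, small_ref):
        cfg = simgen.SimConfig(depth=2000,
                               composition={"GlyGCC": 0.6, "GluCTC": 0.4},
                               effects={}, adapter="")
        reads, _ = simgen.simulate_library(small_ref, cfg, "CO", seed=31)
        table = quantify_sample(reads, small_ref, mode="normalized")
        assert table.counts["weighted"].sum() == pytest.approx(
            table.totals["n_mapped"], abs=1e-9)

    def test_literal_mode_totals_within_bounds(self, small_ref):
        cfg = simgen.SimConfig(depth=2000,
                               composition={"GlyGCC": 0.6, "GluCTC": 0.4},
                               effects={}, adapter="")
        reads, _ = simgen.simulate_library(small_ref, cfg, "CO", seed=31)
        assigns = assign_reads(reads, small_ref)
        table = weighted_counts(assigns, mode="literal")
        total = table.counts["weighted"].sum()
        upper = table.totals["n_unique"] + sum(
            len(a.scores) for a in assigns if a.status == "shared")
        assert table.totals["n_unique"] <= total <= upper

    def test_adding_a_read_never_decreases_counts(self, small_ref):
        cfg = simgen.SimConfig(depth=50, composition={"GlyGCC": 1.0}, effects={},
                               adapter="")
        reads, _ = simgen.simulate_library(small_ref, cfg, "CO", seed=41)
        assigns = assign_reads(reads, small_ref)
        for mode in ("literal", "normalized"):
            prev = weighted_counts(assigns[:-1], mode=mode).counts["weighted"]
            full = weighted_counts(assigns, mode=mode).counts["weighted"]
            aligned = full.reindex(prev.index.union(full.index), fill_value=0.0)
            prev = prev.reindex(aligned.index, fill_value=0.0)
            assert (aligned >= prev - 1e-12).all()


class TestCountMatrix:
    def test_single_sample_single_species(self):
        ref = simgen.make_reference(1, 1, 1.0, seed=1)
        a = classify([AlignmentHit("r", ref.entries[0].ref_id, 0, 35, 100.0)])
        mat = count_matrix([weighted_counts([a])], ref)
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == 1.0

    def test_isoacceptor_collapse_sums_members(self, small_ref):
        ids = [e.ref_id for e in small_ref.members("GlyGCC")][:2]
        assigns = (
            [classify([AlignmentHit(f"a{i}", ids[0], 0, 35, 100.0)]) for i in range(3)]
            + [classify([AlignmentHit(f"b{i}", ids[1], 0, 35, 100.0)])
               for i in range(4)]
        )
        table = weighted_counts(assigns)
        by_ref = count_matrix([table], small_ref, collapse="by_ref")
        by_iso = count_matrix([table], small_ref, collapse="by_isoacceptor")
        assert by_iso.loc["GlyGCC"].iloc[0] == pytest.approx(
            by_ref.loc[ids].iloc[:, 0].sum()) == 7.0

    def test_row_sums_match_per_sample_recount(self, small_ref):
        cfg = simgen.SimConfig(depth=400,
                               composition={"GlyGCC": 0.5, "GluCTC": 0.5},
                               effects={}, adapter="")
        tables = []
        for s in range(8):
            reads, _ = simgen.simulate_library(small_ref, cfg, "CO", seed=100 + s)
            tables.append(quantify_sample(reads, small_ref, sample=f"S{s}"))
        mat = count_matrix(tables, small_ref)
        for i, t in enumerate(tables):
            assert mat.iloc[:, i].sum() == pytest.approx(t.counts["weighted"].sum())

    def test_unknown_reference_in_table_rejected(self, small_ref):
        a = classify([AlignmentHit("r", "Ghost-1", 0, 35, 100.0)])
        with pytest.raises(ContractError):
            count_matrix([weighted_counts([a])], small_ref)


class TestRecovery:
    def test_normalized_fractions_recover_truth_composition(self, study_ref):
        """By-isoacceptor normalized weighted fractions track the truth table
        at 1e4 depth even with heterogeneous within-family sharing."""
        cfg = simgen.SimConfig(depth=10_000, error_rate=0.0, adapter="",
                               overdispersion=None)
        reads, truth = simgen.simulate_library(study_ref, cfg, "CO", seed=55)
        table = quantify_sample(reads, study_ref, mode="normalized")
        mat = count_matrix([table], study_ref, collapse="by_isoacceptor")
        frac = mat.iloc[:, 0] / mat.iloc[:, 0].sum()
        expected = truth.isoacceptor_fractions()
        for iso in expected.index:
            assert frac[iso] == pytest.approx(expected[iso], abs=0.02)

    def test_literal_fractions_recover_under_uniform_sharing(self):
        """The literal formula multiple-counts each shared read once per
        family member, so isoacceptor fractions are only recovered when the
        sharing structure is uniform across families (here: identical
        members, so every read is shared by exactly 3 references)."""
        ref = simgen.make_reference(4, 3, 1.0, length_range=(70, 80), seed=6,
                                    isoacceptors=["GlyGCC", "GluCTC", "ValTAC",
                                                  "SerCGA"])
        comp = {"GlyGCC": 0.4, "GluCTC": 0.3, "ValTAC": 0.2, "SerCGA": 0.1}
        cfg = simgen.SimConfig(depth=10_000, composition=comp, effects={},
                               error_rate=0.0, adapter="", overdispersion=None)
        reads, truth = simgen.simulate_library(ref, cfg, "CO", seed=56)
        for mode in ("literal", "normalized"):
            table = quantify_sample(reads, ref, mode=mode)
            mat = count_matrix([table], ref, collapse="by_isoacceptor")
            frac = mat.iloc[:, 0] / mat.iloc[:, 0].sum()
            expected = truth.isoacceptor_fractions()
            for iso in expected.index:
                assert frac[iso] == pytest.approx(expected[iso], abs=0.02)

    def test_identity_one_makes_every_read_ambiguous(self):
        ref = simgen.make_reference(2, 2, 1.0, length_range=(70, 70), seed=12)
        cfg = simgen.SimConfig(depth=100,
                               composition={ref.isoacceptors[0]: 1.0}, effects={},
                               error_rate=0.0, adapter="")
        reads, _ = simgen.simulate_library(ref, cfg, "CO", seed=13)
        assigns = assign_reads(reads, ref)
        assert all(a.status == "shared" for a in assigns)
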