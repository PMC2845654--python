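"""ORF scanning, cross-species CDS projection, disablers and enablers."""

import numpy as np
import pytest

from conftest import random_orf_locus
from denovogene.orf import (
    Orf,
    OrthologAlignment,
    classify_variation,
    detect_disablers,
    infer_enablers,
    project_cds,
    scan_orfs,
)


class TestScanOrfs:
    def test_minimal_orf(self):
        (hit,) = scan_orfs("ATGAAATGA", 1)
        assert (hit.start, hit.n_codons, hit.cds_len_bp) == (0, 2, 9)

    def test_no_start_codon(self):
        assert scan_orfs("CCCCCC", 1) == []

    def test_unterminated_orf_excluded(self):
        assert scan_orfs("ATGAAAAAA", 1) == []

    def test_ambiguous_orf_excluded_by_default(self):
        seq = "ATGANATGA"
        assert scan_orfs(seq, 1) == []
        (hit,) = scan_orfs(seq, 1, include_ambiguous=True)
        assert hit.ambiguous

    def test_sorted_longest_first_then_five_prime(self):
        # two ORFs of equal length in different frames plus a longer one
        seq = "ATG" + "AAA" * 10 + "TGA"
        longer = scan_orfs(seq, 1)[0]
        assert longer.n_codons == 11
        hits = scan_orfs("ATGAAATGACATGAAATGA", 1)
        assert hits[0].n_codons >= hits[-1].n_codons
        starts = [h.start for h in hits if h.n_codons == hits[0].n_codons]
        assert starts == sorted(starts)

    def test_planted_orf_recovered(self, rng):
        seq, start = random_orf_locus(rng, n_codons=194)
        top = scan_orfs(seq, 50)[0]
        assert (top.start, top.n_codons) == (start, 194)
        assert top.cds_len_bp == 585

    def test_nested_internal_atg_also_reported(self):
        seq = "ATGATGAAATAA"
        hits = scan_orfs(seq, 1)
        assert [(h.start, h.n_codons) for h in hits] == [(0, 3), (3, 2)]


def _aln(ref_row, other_rows, names=None):
    species = ["human"] + (names or [f"sp{i}" for i in range(1, len(other_rows) + 1)])
    return OrthologAlignment(tuple(species), (ref_row, *other_rows), "human")


class TestProjectCds:
    def test_identity_projection(self):
        seq = "ATGAAACCCTGA"
        aln = _aln(seq, [seq])
        orf = Orf(0, 3, 12)
        proj = project_cds(aln, orf)
        for codon in proj.codons["sp1"]:
            assert codon.bases == codon.ref_codon
            assert codon.insertions == ()

    def test_insertion_recorded_at_codon(self):
        # reference gapped where the other species carries an extra base
        ref = "ATGG-AATGA"
        oth = "ATGGGAATGA"
        aln = _aln(ref, [oth])
        proj = project_cds(aln, Orf(0, 2, 9))
        codon2 = proj.codons["sp1"][1]
        assert codon2.insertions == ((0, "G"),)
        assert codon2.render() == "GGAA"

    def test_all_gap_species_flagged_missing(self):
        aln = _aln("ATGAAATGA", ["---------"])
        proj = project_cds(aln, Orf(0, 2, 9))
        assert "sp1" in proj.missing

    def test_orf_outside_alignment_rejected(self):
        aln = _aln("ATGAAATGA", ["ATGAAATGA"])
        with pytest.raises(ValueError):
            project_cds(aln, Orf(3, 2, 9))

    def test_ungapped_base_count_preserved(self):
        ref = "ATGAAA---CCCTGA"
        oth = "ATGAA-GGGCC-TGA"
        aln = _aln(ref, [oth])
        proj = project_cds(aln, Orf(0, 3, 12))
        total = sum(
            sum(1 for b in c.bases if b != "-") + sum(len(s) for _, s in c.insertions)
            for c in proj.codons["sp1"]
        )
        assert total == sum(1 for b in oth if b != "-")


class TestDetectDisablers:
    def test_reference_projection_always_clean(self, rng):
        seq, start = random_orf_locus(rng, 60)
        aln = _aln(seq, [seq, seq])
        proj = project_cds(aln, Orf(start, 60, 183))
        assert detect_disablers(proj)["human"] == []

    def test_premature_stop_at_codon_28(self, rng):
        seq, start = random_orf_locus(rng, 60)
        other = seq[: start + 81] + "TAG" + seq[start + 84 :]
        aln = _aln(seq, [other])
        proj = project_cds(aln, Orf(start, 60, 183))
        (event,) = detect_disablers(proj)["sp1"]
        assert (event.kind, event.codon_index, event.detail) == (
            "premature_stop",
            28,
            "TAG",
        )

    def test_one_base_insertion_is_frameshift(self, rng):
        seq, start = random_orf_locus(rng, 60)
        p = start + 3 * 39 + 1  # after first base of codon 40
        ref = seq[:p] + "-" + seq[p:]
        oth = seq[:p] + "G" + seq[p:]
        aln = _aln(ref, [oth])
        proj = project_cds(aln, Orf(start, 60, 183))
        (event,) = detect_disablers(proj)["sp1"]
        assert (event.kind, event.codon_index) == ("frameshift", 40)
        assert not event.compensated

    def test_stops_after_frameshift_suppressed_until_compensation(self, rng):
        seq, start = random_orf_locus(rng, 60)
        oth = list(seq)
        oth[start + 3 * 9 + 2] = "-"  # 1-bp deletion in codon 10
        oth[start + 3 * 19] = "T"  # would-be TAG at codon 20, frame shifted
        oth[start + 3 * 19 + 1] = "A"
        oth[start + 3 * 19 + 2] = "G"
        oth[start + 3 * 29 + 2] = "-"  # second deletion: codon 30, net -2
        oth[start + 3 * 30 + 2] = "-"  # third: codon 31, net -3 == 0 mod 3
        oth = "".join(oth)
        aln = _aln(seq, [oth])
        proj = project_cds(aln, Orf(start, 60, 183))
        events = detect_disablers(proj)["sp1"]
        kinds = [(e.kind, e.codon_index) for e in events]
        assert ("premature_stop", 20) not in kinds
        assert [k for k, _ in kinds] == ["frameshift", "frameshift", "frameshift"]
        assert all(e.compensated for e in events)

    def test_identical_species_has_no_events(self, rng):
        seq, start = random_orf_locus(rng, 40)
        aln = _aln(seq, [seq])
        proj = project_cds(aln, Orf(start, 40, 123))
        assert detect_disablers(proj)["sp1"] == []


class TestInferEnablers:
    def _fixture(self, rng, anc_codon="TAG", foc_codon="TGG", codon=28, n=60):
        seq, start = random_orf_locus(rng, n)
        p = start + 3 * (codon - 1)
        focal = seq[:p] + foc_codon + seq[p + 3 :]
        anc = seq[:p] + anc_codon + seq[p + 3 :]
        aln = OrthologAlignment(
            ("human", "chimp", "gorilla", "orangutan", "rhesus"),
            (focal, anc, anc, anc, anc),
            "human",
        )
        proj = project_cds(aln, Orf(start, n, 3 * (n + 1)))
        return aln, proj

    def test_stop_escape_reported(self, rng):
        aln, proj = self._fixture(rng)
        (en,) = infer_enablers(aln, proj, "human")
        assert (en.codon_index, en.ancestral, en.derived, en.removes) == (
            28,
            "TAG",
            "TGG",
            "premature_stop",
        )

    def test_plain_substitution_not_an_enabler(self, rng):
        aln, proj = self._fixture(rng, anc_codon="AAA", foc_codon="AAG")
        assert infer_enablers(aln, proj, "human") == []

    def test_two_outgroup_tie_skipped(self, rng):
        seq, start = random_orf_locus(rng, 60)
        p = start + 81
        focal = seq[:p] + "TGG" + seq[p + 3 :]
        stop = seq[:p] + "TAG" + seq[p + 3 :]
        aln = OrthologAlignment(
            ("human", "chimp", "gorilla"), (focal, stop, seq), "human"
        )
        proj = project_cds(aln, Orf(start, 60, 183))
        assert infer_enablers(aln, proj, "human") == []

    def test_all_outgroups_missing_rejected(self, rng):
        seq, start = random_orf_locus(rng, 40)
        gaps = "-" * len(seq)
        aln = OrthologAlignment(
            ("human", "chimp", "gorilla"), (seq, gaps, gaps), "human"
        )
        proj = project_cds(aln, Orf(start, 40, 123))
        with pytest.raises(ValueError):
            infer_enablers(aln, proj, "human")


class TestClassifyVariation:
    @pytest.mark.parametrize(
        "ref_codon,other_codon,kind",
        [("TTT", "TTC", "synonymous"), ("TTT", "TTA", "nonsynonymous")],
    )
    def test_point_differences(self, rng, ref_codon, other_codon, kind):
        seq, start = random_orf_locus(rng, 40)
        p = start + 3 * 10
        ref = seq[:p] + ref_codon + seq[p + 3 :]
        oth = seq[:p] + other_codon + seq[p + 3 :]
        aln = _aln(ref, [oth])
        table = classify_variation(aln, Orf(start, 40, 123))
        row = table[table.codon_index == 11].iloc[0]
        assert row.kind == kind

    def test_identical_rows_produce_empty_table(self, rng):
        seq, start = random_orf_locus(rng, 40)
        aln = _aln(seq, [seq])
        assert classify_variation(aln, Orf(start, 40, 123)).empty

    def test_multi_hit_codon_with_aa_change_is_nonsynonymous(self, rng):
        seq, start = random_orf_locus(rng, 40)
        p = start + 3 * 5
        ref = seq[:p] + "TTT" + seq[p + 3 :]
        oth = seq[:p] + "CTC" + seq[p + 3 :]  # two hits, Phe -> Leu
        aln = _aln(ref, [oth])
        table = classify_variation(aln, Orf(start, 40, 123))
        assert table[table.codon_index == 6].iloc[0].kind == "nonsynonymous"


class TestOrthologAlignmentInvariants:
    def test_ragged_rows_rejected_with_offender_named(self):
        with pytest.raises(ValueError, match="sp1"):
            OrthologAlignment(("human", "sp1"), ("ACGTACGTAC", "ACGTACGTA"), "human")

    def test_reference_must_be_present(self):
        with pytest.raises(ValueError):
            OrthologAlignment(("a", "b"), ("AC", "GT"), "zz")
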