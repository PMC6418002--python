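"""Coordinate conversion, translation services, intervals, trees, fixtures."""

import pytest
from hypothesis import given, settings, strategies as st

from microevo.codons import revcomp, translate
from microevo.genome_io import (
    Feature,
    FeatureKind,
    HomologContext,
    LabeledRootedTree,
    StrainAnnotation,
    noncoding_intervals,
    read_strain_annotation,
    read_table1_fixture,
    six_frame_translate,
    write_strain_annotation,
)

DNA = st.text(alphabet="ACGT", min_size=3, max_size=300)


def write_inputs(tmp_path, seq, gff_rows):
    fasta = tmp_path / "s.fasta"
    fasta.write_text(">strainX\n" + seq + "\n")
    gff = tmp_path / "s.gff3"
    gff.write_text("##gff-version 3\n" + "".join(r + "\n" for r in gff_rows))
    return fasta, gff


class TestGffReading:
    def test_one_based_inclusive_converts_to_half_open(self, tmp_path):
        fasta, gff = write_inputs(
            tmp_path, "ATGAAATAG" * 10, ["strainX\t.\tCDS\t1\t6\t.\t+\t0\tID=g1"]
        )
        ann = read_strain_annotation(fasta, gff)
        assert (ann.features[0].start, ann.features[0].end) == (0, 6)

    def test_phase_trims_coding_start(self, tmp_path):
        # 1-based [10,18] with phase 2 on + strand -> 0-based [11,18)
        fasta, gff = write_inputs(
            tmp_path, "A" * 30, ["strainX\t.\tCDS\t10\t18\t.\t+\t2\tID=g1"]
        )
        with pytest.warns(UserWarning):  # 7 nt after trimming: flagged, kept
            ann = read_strain_annotation(fasta, gff)
        f = ann.features[0]
        assert (f.start, f.end) == (11, 18)

    def test_phase_trimming_keeps_frame_clean_cds(self, tmp_path):
        # 1-based [10,18] phase 0 is 9 nt: [9,18), a clean codon interval
        fasta, gff = write_inputs(
            tmp_path, "A" * 30, ["strainX\t.\tCDS\t10\t18\t.\t+\t0\tID=g1"]
        )
        ann = read_strain_annotation(fasta, gff)
        f = ann.features[0]
        assert (f.start, f.end) == (9, 18)
        assert not f.pseudogenized

    def test_empty_gff_is_valid(self, tmp_path):
        fasta, gff = write_inputs(tmp_path, "ACGTACGTACGT", [])
        ann = read_strain_annotation(fasta, gff)
        assert ann.features == [] and ann.length == 12

    def test_duplicate_feature_ids_rejected(self, tmp_path):
        fasta, gff = write_inputs(
            tmp_path,
            "A" * 30,
            [
                "strainX\t.\tCDS\t1\t6\t.\t+\t0\tID=g1",
                "strainX\t.\tCDS\t7\t12\t.\t+\t0\tID=g1",
            ],
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_strain_annotation(fasta, gff)

    def test_frameshifted_cds_flagged_pseudogenized(self, tmp_path):
        fasta, gff = write_inputs(
            tmp_path, "A" * 30, ["strainX\t.\tCDS\t1\t8\t.\t+\t0\tID=g1"]
        )
        with pytest.warns(UserWarning, match="pseudogenized"):
            ann = read_strain_annotation(fasta, gff)
        assert ann.features[0].pseudogenized

    def test_round_trip_preserves_everything(self, tmp_path):
        ann = StrainAnnotation(
            "strainX",
            "ATGAAATAG" + "ACGT" * 10 + "ATGCCCTAA",
            [
                Feature("g1", FeatureKind.CDS, 0, 9, "+", median_coverage=42.0),
                Feature("n1", FeatureKind.NCRNA, 12, 40, "-"),
                Feature("g2", FeatureKind.CDS, 49, 58, "-"),
            ],
        )
        write_strain_annotation(ann, tmp_path / "o.fasta", tmp_path / "o.gff3")
        back = read_strain_annotation(tmp_path / "o.fasta", tmp_path / "o.gff3")
        assert back.sequence == ann.sequence
        assert [
            (f.feature_id, f.kind, f.start, f.end, f.strand, f.median_coverage)
            for f in back.features
        ] == [
            (f.feature_id, f.kind, f.start, f.end, f.strand, f.median_coverage)
            for f in ann.features
        ]


class TestSixFrameTranslate:
    def test_known_frames(self):
        frames = six_frame_translate("ATGAAA")
        assert frames[1] == "MK"
        assert frames[-1] == "FH"  # revcomp TTTCAT -> F H

    def test_ambiguity_yields_x(self):
        assert six_frame_translate("ATGNAA")[1] == "MX"

    @settings(max_examples=50, derandomize=True, database=None)
    @given(DNA)
    def test_reverse_frames_equal_forward_frames_of_revcomp(self, seq):
        frames = six_frame_translate(seq)
        rc_frames = six_frame_translate(revcomp(seq)) if len(seq) >= 3 else {}
        for k in (1, 2, 3):
            assert frames[-k] == rc_frames[k]


class TestNoncodingIntervals:
    def mk(self, length, cds):
        feats = [
            Feature(f"g{i}", FeatureKind.CDS, s, e, "+")
            for i, (s, e) in enumerate(cds)
        ]
        return StrainAnnotation("s", "A" * length, feats)

    def test_single_cds(self):
        ann = self.mk(99, [(10, 40)])
        assert noncoding_intervals(ann) == [(0, 10), (40, 99)]

    def test_overlapping_cds_unioned(self):
        ann = self.mk(99, [(10, 40), (30, 60)])
        assert noncoding_intervals(ann) == [(0, 10), (60, 99)]

    def test_no_cds_returns_whole_genome(self):
        ann = self.mk(50, [])
        assert noncoding_intervals(ann) == [(0, 50)]

    @settings(max_examples=50, derandomize=True, database=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 80), st.integers(1, 20)), min_size=0, max_size=8
        )
    )
    def test_tiles_genome_with_cds_union(self, raw):
        length = 120
        cds = [(s, min(s + 3 * ((w // 3) + 1), length)) for s, w in raw]
        cds = [(s, e) for s, e in cds if (e - s) % 3 == 0 and e <= length and s < e]
        ann = self.mk(length, cds)
        nc = noncoding_intervals(ann)
        # disjoint and sorted
        for (s1, e1), (s2, e2) in zip(nc, nc[1:]):
            assert e1 < s2
        covered = sum(e - s for s, e in nc)
        union_cds = set()
        for s, e in cds:
            union_cds.update(range(s, e))
        assert covered + len(union_cds) == length


class TestLabeledRootedTree:
    def test_fixture_tree_labels_and_mrca(self, tree):
        assert tree.root_label == 1
        assert sorted(tree.internal_labels) == list(range(1, 10))
        assert tree.mrca(["p_quercus", "p_celtis"]) == 9
        assert tree.mrca(["p_quercus", "p_celtis", "p_inopinatum"]) == 8
        assert tree.mrca(["p_celtis", "p_braziliensis"]) == 5
        assert tree.mrca(["p_celtis", "p_salinus"]) == 2
        assert tree.mrca(["p_celtis", "p_neocaledonia"]) == 1

    def test_leaves_below(self, tree):
        assert tree.leaves_below(9) == {"p_quercus", "p_celtis"}
        assert tree.leaves_below(8) == {"p_inopinatum", "p_quercus", "p_celtis"}

    def test_duplicate_internal_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            LabeledRootedTree.from_newick("((a:1,b:1)2:1,(c:1,d:1)2:1)1;")

    def test_ancestor_path(self, tree):
        assert tree.ancestor_labels("p_celtis") == [1, 2, 4, 5, 8, 9, "p_celtis"]


class TestTable1Fixture:
    def test_spot_checked_rows(self, table1):
        by_id = {r.gene_id: r for r in table1}
        r = by_id["pclt_cds_11"]
        assert (r.length_aa, r.most_ancestral_detection, r.predicted_dna_binding) == (
            69,
            5,
            True,
        )
        assert by_id["pqer_cds_350"].most_ancestral_detection is None
        assert by_id["pclt_cds_1081"].median_coverage == 12090
        assert by_id["pclt_cds_308"].homolog_context is HomologContext.NCRNA
        assert by_id["pqer_cds_685"].homolog_context is HomologContext.ALTERNATIVE_FRAME
        assert by_id["pqer_cds_143"].homolog_context is HomologContext.ANTISENSE_UTR5

    def test_every_context_row_parses(self, table1):
        assert all(isinstance(r.homolog_context, HomologContext) for r in table1)

    def test_row_count_enforced(self, tmp_path, table1):
        src = "\n".join(
            [
                "gene_id\tsize_aa\tmost_ancestral_detection\thomolog_in_partner\tpredicted_dna_binding\tmedian_coverage",
                "pclt_cds_11\t69\tSince node 5\tNone\tYes\t704",
            ]
        )
        bad = tmp_path / "bad.tsv"
        bad.write_text(src + "\n")
        with pytest.raises(ValueError, match="30"):
            read_table1_fixture(bad)
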