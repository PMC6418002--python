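"""Translated non-coding search, Karlin-Altschul statistics, MRCA dating."""

import math

import numpy as np
import pytest

from microevo.ancestry_tracing import (
    HitContext,
    TraceHit,
    TranslatedSearcher,
    assign_creation_node,
    classify_hit_context,
    karlin_altschul_evalue,
    summarize_node_distribution,
    translated_noncoding_search,
)
from microevo.codons import GENETIC_CODE, revcomp
from microevo.genome_io import Feature, FeatureKind, LabeledRootedTree, StrainAnnotation

AA_TO_CODON = {}
for codon, aa in GENETIC_CODE.items():
    AA_TO_CODON.setdefault(aa, codon)


def back_translate(pep):
    return "".join(AA_TO_CODON[a] for a in pep)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(rng, n):
    aas = [a for a in set(GENETIC_CODE.values()) if a != "*"]
    return "".join(rng.choice(sorted(aas), size=n))


class TestKarlinAltschul:
    def test_zero_score_closed_form(self):
        assert karlin_altschul_evalue(0, 10, 100) == pytest.approx(0.13 * 10 * 100)

    def test_linearity_in_subject_length(self):
        e1 = karlin_altschul_evalue(30, 100, 1000)
        e2 = karlin_altschul_evalue(30, 100, 2000)
        assert e2 == pytest.approx(2 * e1)

    def test_direct_evaluation(self):
        # E = K m n exp(-lambda S), evaluated independently
        expect = 0.13 * 100 * 10**6 * math.exp(-0.318 * 50)
        assert karlin_altschul_evalue(50, 100, 10**6) == pytest.approx(expect)


class TestTranslatedSearch:
    def test_planted_query_found_in_intergenic_dna(self, rng):
        query = random_protein(rng, 60)
        genome = random_dna(rng, 5000) + back_translate(query) + random_dna(rng, 5000)
        ann = StrainAnnotation("subj", genome, [])
        hits = translated_noncoding_search(query, ann, query_id="q")
        assert hits, "planted trace must be found"
        top = hits[0]
        assert top.evalue < 1e-10
        assert top.start <= 5000 + 5 and top.end >= 5000 + 3 * 60 - 5
        assert top.context is HitContext.INTERGENIC

    def test_planted_on_reverse_strand_found(self, rng):
        query = random_protein(rng, 60)
        genome = random_dna(rng, 3000) + revcomp(back_translate(query)) + random_dna(rng, 3000)
        hits = translated_noncoding_search(query, StrainAnnotation("s", genome, []))
        assert hits and hits[0].frame < 0

    def test_hit_inside_same_frame_cds_masked(self, rng):
        query = random_protein(rng, 60)
        planted = back_translate(query)
        left = random_dna(rng, 3000)
        pad = (3 - len(left) % 3) % 3
        left = left + "A" * pad  # CDS starts in frame +1
        genome = left + planted + random_dna(rng, 3000)
        cds = Feature("g1", FeatureKind.CDS, len(left), len(left) + len(planted), "+")
        ann = StrainAnnotation("s", genome, [cds])
        hits = translated_noncoding_search(query, ann)
        assert hits == []

    def test_false_positive_rate_matches_evalue_theory(self, rng):
        """Random queries vs random DNA: total hit count stays within ~3x
        of the Karlin-Altschul expectation E_max * n_queries."""
        subject = StrainAnnotation("s", random_dna(rng, 100_000), [])
        searcher = TranslatedSearcher(subject)
        e_max = 0.05
        total = 0
        n_q = 100
        for _ in range(n_q):
            total += len(searcher.search(random_protein(rng, 100), e_max=e_max))
        assert total <= 3 * e_max * n_q

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            translated_noncoding_search("MKVL", StrainAnnotation("s", "ACGTACGTACGT", []))


class TestClassifyHitContext:
    def mk_ann(self, feats, n=1000):
        return StrainAnnotation("s", "A" * n, feats)

    def hit(self, start, end, frame=1):
        return TraceHit("q", "s", start, end, frame, 100.0, 1e-9)

    def test_between_genes_is_intergenic(self):
        ann = self.mk_ann([Feature("g", FeatureKind.CDS, 0, 300, "+")])
        assert classify_hit_context(self.hit(400, 500), ann) is HitContext.INTERGENIC

    def test_opposite_strand_cds_is_antisense(self):
        ann = self.mk_ann([Feature("g", FeatureKind.CDS, 300, 600, "-")])
        assert classify_hit_context(self.hit(350, 450), ann) is HitContext.ANTISENSE_CDS

    def test_same_strand_cds_other_frame_is_alternative_frame(self):
        ann = self.mk_ann([Feature("g", FeatureKind.CDS, 300, 600, "+")])
        # frame +2 over a frame-+1 CDS
        assert (
            classify_hit_context(self.hit(350, 450, frame=2), ann)
            is HitContext.ALTERNATIVE_FRAME
        )

    def test_utr_and_ncrna_contexts(self):
        ann = self.mk_ann(
            [
                Feature("u5", FeatureKind.UTR5, 100, 200, "+"),
                Feature("nc", FeatureKind.NCRNA, 500, 700, "+"),
            ]
        )
        assert classify_hit_context(self.hit(120, 180), ann) is HitContext.UTR5
        assert classify_hit_context(self.hit(550, 650), ann) is HitContext.NCRNA_OVERLAP


def random_labeled_tree(rng, n_leaves=10):
    """Random rooted binary topology with integer internal labels."""
    leaves = [f"L{i}" for i in range(n_leaves)]
    nodes = [f"{name}:1" for name in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    newick = nodes[0]
    # relabel internal nodes with unique integers in preorder
    import dendropy

    t = dendropy.Tree.get(data=newick + ";", schema="newick", preserve_underscores=True)
    for k, node in enumerate(t.preorder_internal_node_iter(), 1):
        node.label = str(k)
    return LabeledRootedTree(
        dendropy.Tree.get(
            data=t.as_string(schema="newick", suppress_rooting=True),
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    )


def oracle_mrca(tree, leaves):
    """Deepest common label of all root-to-leaf paths (path intersection)."""
    paths = [tree.ancestor_labels(leaf) for leaf in leaves]
    common = None
    for depth in range(min(len(p) for p in paths)):
        labels = {p[depth] for p in paths}
        if len(labels) == 1:
            common = labels.pop()
        else:
            break
    return common


class TestAssignCreationNode:
    def test_no_evidence_gives_none(self, tree):
        a = assign_creation_node(tree, "p_celtis", [])
        assert a.node is None

    def test_partner_evidence_gives_node_nine(self, tree):
        a = assign_creation_node(tree, "p_celtis", ["p_quercus"])
        assert a.node == 9

    def test_unknown_evidence_leaf_rejected(self, tree):
        with pytest.raises(KeyError):
            assign_creation_node(tree, "p_celtis", ["p_nonexistent"])

    def test_monotone_toward_root_as_evidence_grows(self, tree):
        order = ["p_quercus", "p_inopinatum", "p_braziliensis", "p_salinus", "p_pampulha"]
        depth = {1: 0, 2: 1, 4: 2, 5: 3, 8: 4, 9: 5}
        prev = 10
        for k in range(1, len(order) + 1):
            node = assign_creation_node(tree, "p_celtis", order[:k]).node
            assert depth[node] <= prev
            prev = depth[node]

    def test_matches_path_intersection_oracle_on_random_trees(self, rng):
        for rep in range(100):
            t = random_labeled_tree(rng)
            leaves = t.leaves
            k = int(rng.integers(1, 5))
            focal = leaves[int(rng.integers(len(leaves)))]
            evidence = list(rng.choice([l for l in leaves if l != focal], size=k, replace=False))
            got = assign_creation_node(t, focal, evidence).node
            assert got == oracle_mrca(t, [focal, *evidence])

    def test_full_clade_variant_requires_all_descendants(self, tree):
        # evidence covers the quercus side only: strict variant stays at 9
        strict = assign_creation_node(
            tree, "p_celtis", ["p_quercus", "p_braziliensis"], require_full_clade=True
        )
        assert strict.node == 9
        loose = assign_creation_node(tree, "p_celtis", ["p_quercus", "p_braziliensis"])
        assert loose.node == 5


class TestSummarizeNodeDistribution:
    def test_table_counts(self, table1):
        counts = summarize_node_distribution(
            r.most_ancestral_detection for r in table1
        )
        assert counts == {9: 5, 8: 8, 5: 4, 2: 6, None: 7}

    def test_empty(self):
        assert summarize_node_distribution([]) == {}
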