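"""Genome, annotation, tree and table I/O plus coordinate/translation services.

All internal coordinates are 0-based half-open ``[start, end)``. GFF3's
1-based inclusive convention is converted at the I/O boundary only.
Genomes are linear (pandoravirus chromosomes are linear contigs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import revcomp, translate


class FeatureKind(str, Enum):
    CDS = "CDS"
    NCRNA = "ncRNA"
    UTR5 = "UTR5"
    UTR3 = "UTR3"


_GFF_TYPE_TO_KIND = {
    "CDS": FeatureKind.CDS,
    "ncRNA": FeatureKind.NCRNA,
    "five_prime_UTR": FeatureKind.UTR5,
    "three_prime_UTR": FeatureKind.UTR3,
}
_KIND_TO_GFF_TYPE = {v: k for k, v in _GFF_TYPE_TO_KIND.items()}


@dataclass
class Feature:
    """One typed genomic feature in internal 0-based half-open coordinates."""

    feature_id: str
    kind: FeatureKind
    start: int
    end: int
    strand: str
    median_coverage: float | None = None
    pseudogenized: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.feature_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class StrainAnnotation:
    """One strain's genome sequence with its typed features."""

    strain_id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature id {f.feature_id!r} in {self.strain_id}")
            seen.add(f.feature_id)
            if f.end > self.length:
                raise ValueError(
                    f"{f.feature_id}: interval [{f.start},{f.end}) exceeds genome length {self.length}"
                )
            if f.kind is FeatureKind.CDS and not f.pseudogenized and f.length % 3:
                raise ValueError(f"{f.feature_id}: CDS length {f.length} not a multiple of 3")

    def features_of_kind(self, kind: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind is kind]

    def cds_features(self, include_pseudogenized: bool = False) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind is FeatureKind.CDS and (include_pseudogenized or not f.pseudogenized)
        ]

    def feature_by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def feature_sequence(self, feature: Feature | str) -> str:
        """Coding/transcribed-strand sequence of a feature."""
        if isinstance(feature, str):
            feature = self.feature_by_id(feature)
        seg = self.sequence[feature.start : feature.end]
        return seg if feature.strand == "+" else revcomp(seg)

    def protein_sequence(self, feature: Feature | str) -> str:
        """Translation of a CDS, terminal stop stripped."""
        pep = translate(self.feature_sequence(feature))
        return pep[:-1] if pep.endswith("*") else pep


def read_strain_annotation(fasta_path: str | Path, gff_path: str | Path) -> StrainAnnotation:
    """Load a one-sequence FASTA plus a flat GFF3 into a StrainAnnotation.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    CDS phase > 0 trims the 5' end of the coding interval to restore frame.
    A CDS whose length is still not a multiple of 3 is kept but flagged
    pseudogenized, with a warning.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one sequence, found {len(records)}")
    strain_id = records[0].id
    sequence = str(records[0].seq).upper()

    features: list[Feature] = []
    with open(gff_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff_path}:{line_no}: expected 9 columns, got {len(cols)}")
            _, _, ftype, start1, end1, _, strand, phase, attrs = cols
            kind = _GFF_TYPE_TO_KIND.get(ftype)
            if kind is None:
                continue
            start, end = int(start1) - 1, int(end1)
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            fid = attr_map.get("ID", f"{strain_id}_feat_{line_no}")
            coverage = attr_map.get("median_coverage")
            pseudo = False
            if kind is FeatureKind.CDS:
                ph = int(phase) if phase not in (".", "") else 0
                if ph:
                    if strand == "+":
                        start += ph
                    else:
                        end -= ph
                if (end - start) % 3:
                    warnings.warn(
                        f"{fid}: CDS length {end - start} not a multiple of 3 after phase "
                        "adjustment; flagging as pseudogenized"
                    )
                    pseudo = True
            features.append(
                Feature(
                    feature_id=fid,
                    kind=kind,
                    start=start,
                    end=end,
                    strand=strand,
                    median_coverage=float(coverage) if coverage is not None else None,
                    pseudogenized=pseudo,
                )
            )
    return StrainAnnotation(strain_id=strain_id, sequence=sequence, features=features)


def write_strain_annotation(
    annotation: StrainAnnotation, fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write FASTA (60-column wrap) and GFF3 (1-based inclusive, version pragma)."""
    rec = SeqRecord(Seq(annotation.sequence), id=annotation.strain_id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.strain_id} 1 {annotation.length}\n")
        for f in annotation.features:
            attrs = f"ID={f.feature_id}"
            if f.median_coverage is not None:
                attrs += f";median_coverage={f.median_coverage:g}"
            if f.pseudogenized:
                attrs += ";pseudogenized=true"
            fh.write(
                "\t".join(
                    [
                        annotation.strain_id,
                        "microevo",
                        _KIND_TO_GFF_TYPE[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind is FeatureKind.CDS else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate all six reading frames.

    Keys are +1, +2, +3, -1, -2, -3. Frame -k is the forward translation of
    the reverse complement offset by k-1. Stops render as '*', ambiguous
    codons as 'X'.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    rc = revcomp(seq)
    out: dict[int, str] = {}
    for k in (1, 2, 3):
        out[k] = translate(seq[k - 1 :])
        out[-k] = translate(rc[k - 1 :])
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def noncoding_intervals(annotation: StrainAnnotation) -> list[tuple[int, int]]:
    """Strand-agnostic complement of the union of CDS intervals."""
    cds = merge_intervals(
        (f.start, f.end) for f in annotation.cds_features(include_pseudogenized=True)
    )
    out: list[tuple[int, int]] = []
    prev = 0
    for s, e in cds:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < annotation.length:
        out.append((prev, annotation.length))
    return out


class LabeledRootedTree:
    """Rooted phylogeny with string leaf names and integer internal labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    @classmethod
    def from_newick(cls, source: str | Path) -> "LabeledRootedTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True, rooting="force-rooted"
        )
        return cls(tree)

    def _validate(self) -> None:
        labels = [self._label(n) for n in self._tree.preorder_internal_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("internal node labels are not unique")
        if any(lab is None for lab in labels):
            raise ValueError("every internal node must carry a label")

    @staticmethod
    def _label(node: dendropy.Node) -> int | str | None:
        if node.is_leaf():
            return node.taxon.label if node.taxon else None
        if node.label is None:
            return None
        try:
            return int(node.label)
        except ValueError:
            return node.label

    @property
    def leaves(self) -> list[str]:
        return [t.label for t in self._tree.taxon_namespace]

    @property
    def root_label(self) -> int | str:
        return self._label(self._tree.seed_node)

    @property
    def internal_labels(self) -> list[int | str]:
        return [self._label(n) for n in self._tree.preorder_internal_node_iter()]

    def _node_by_label(self, label: int | str) -> dendropy.Node:
        for n in self._tree.preorder_node_iter():
            if self._label(n) == label:
                return n
        raise KeyError(f"no node labeled {label!r}")

    def mrca(self, leaf_names: Sequence[str]) -> int | str:
        """Label of the most recent common ancestor of the given leaves."""
        names = sorted(set(leaf_names))
        if not names:
            raise ValueError("mrca of an empty leaf set")
        missing = set(names) - set(self.leaves)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        if len(names) == 1:
            return names[0]
        node = self._tree.mrca(taxon_labels=names)
        return self._label(node)

    def leaves_below(self, label: int | str) -> set[str]:
        node = self._node_by_label(label)
        return {lf.taxon.label for lf in node.leaf_iter()}

    def ancestor_labels(self, leaf: str) -> list[int | str]:
        """Labels on the root-to-leaf path, root first, leaf last."""
        node = self._node_by_label(leaf)
        path = [self._label(node)]
        while node.parent_node is not None:
            node = node.parent_node
            path.append(self._label(node))
        return path[::-1]

    def branches(self) -> list[tuple[int | str, int | str, float]]:
        """(parent_label, child_label, length) in preorder; root excluded."""
        out = []
        for n in self._tree.preorder_node_iter():
            if n.parent_node is None:
                continue
            out.append(
                (self._label(n.parent_node), self._label(n), float(n.edge.length or 0.0))
            )
        return out

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


class HomologContext(str, Enum):
    """Where a unique gene's remote homolog lies in the partner genome."""

    NONE = "none"
    INTERGENIC = "intergenic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    ANTISENSE_UTR5 = "antisense_utr5"
    ANTISENSE_CDS = "antisense_cds"
    ALTERNATIVE_FRAME = "alternative_frame"
    NCRNA = "ncRNA"


@dataclass
class UniqueGeneRecord:
    """One strain-unique protein-coding gene and its homology context."""

    gene_id: str
    length_aa: int
    most_ancestral_detection: int | None
    homolog_context: HomologContext
    homolog_detail: str
    predicted_dna_binding: bool
    median_coverage: float

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError(f"{self.gene_id}: length_aa must be positive")

    @property
    def strain_prefix(self) -> str:
        return self.gene_id.split("_", 1)[0]


def _parse_context(text: str) -> HomologContext:
    t = text.replace("′", "'").strip()
    low = t.lower()
    if low == "none":
        return HomologContext.NONE
    if "ncrna" in low:
        return HomologContext.NCRNA
    if low.startswith("anti 5'utr"):
        return HomologContext.ANTISENSE_UTR5
    if low.startswith("antisense"):
        return HomologContext.ANTISENSE_CDS
    if low.startswith("alternative frame"):
        return HomologContext.ALTERNATIVE_FRAME
    if low.startswith("3'utr"):
        return HomologContext.UTR3
    if low.startswith("5'utr"):
        return HomologContext.UTR5
    if low.startswith("intergenic"):
        return HomologContext.INTERGENIC
    raise ValueError(f"unrecognized homolog context: {text!r}")


def read_table1_fixture(tsv_path: str | Path | None = None) -> list[UniqueGeneRecord]:
    """Load the bundled 30-row unique-gene table (or a compatible TSV)."""
    if tsv_path is None:
        src = resources.files("microevo.data").joinpath("table1_unique_genes.tsv")
        lines = src.read_text().splitlines()
    else:
        lines = Path(tsv_path).read_text().splitlines()
    header = lines[0].split("\t")
    expected = [
        "gene_id",
        "size_aa",
        "most_ancestral_detection",
        "homolog_in_partner",
        "predicted_dna_binding",
        "median_coverage",
    ]
    if header != expected:
        raise ValueError(f"unexpected header {header}")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        gene_id, size_aa, anc, homolog, binding, cov = line.split("\t")
        node = None if anc.strip().lower() == "none" else int(anc.strip().rsplit(" ", 1)[-1])
        records.append(
            UniqueGeneRecord(
                gene_id=gene_id,
                length_aa=int(size_aa),
                most_ancestral_detection=node,
                homolog_context=_parse_context(homolog),
                homolog_detail=homolog,
                predicted_dna_binding=binding.strip().lower() == "yes",
                median_coverage=float(cov.replace(",", "")),
            )
        )
    if len(records) != 30:
        raise ValueError(f"fixture must contain exactly 30 records, found {len(records)}")
    return records


def load_fixture_tree() -> LabeledRootedTree:
    """The bundled 10-strain labeled pandoravirus phylogeny."""
    src = resources.files("microevo.data").joinpath("pandoravirus_tree.nwk")
    tree = dendropy.Tree.get(
        data=src.read_text(), schema="newick", preserve_underscores=True, rooting="force-rooted"
    )
    return LabeledRootedTree(tree)
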