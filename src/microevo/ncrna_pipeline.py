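"""Expression validation, ncRNA calling/classification and cross-strain
ncRNA matching.

One expression floor is used throughout: a transcript is validated when
its median read coverage exceeds 5 (strict). ncRNA candidate regions are
maximal expressed runs on a strand that do not overlap a same-strand CDS;
a call is antisense when more than half of its length lies opposite a
protein-coding transcript, intergenic otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .codons import revcomp
from .genome_io import Feature, FeatureKind, StrainAnnotation

EXPRESSION_THRESHOLD = 5.0
MIN_NCRNA_LENGTH = 200
MATCH_MIN_IDENTITY = 0.8
MATCH_MIN_COVERAGE = 0.5


def validate_gene_expression(
    features: Iterable[Feature], threshold: float = EXPRESSION_THRESHOLD
) -> dict[str, list[Feature]]:
    """Partition features into kept / rejected / unevaluated.

    Kept iff median_coverage > threshold (strictly); features without a
    coverage value are routed to "unevaluated"."""
    out: dict[str, list[Feature]] = {"kept": [], "rejected": [], "unevaluated": []}
    for f in features:
        if f.median_coverage is None:
            out["unevaluated"].append(f)
        elif f.median_coverage > threshold:
            out["kept"].append(f)
        else:
            out["rejected"].append(f)
    return out


@dataclass
class NcRnaCall:
    call_id: str
    start: int
    end: int
    strand: str
    median_coverage: float
    ncrna_class: str | None = None  # "antisense" | "intergenic"
    homolog_in_partner: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Per-base coverage array from a (0-based half-open) bedGraph file."""
    cov = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _chrom, start, end, value = line.split()[:4]
            cov[int(start) : int(end)] = float(value)
    return cov


def call_ncrna_regions(
    coverage_plus: np.ndarray,
    coverage_minus: np.ndarray,
    annotation: StrainAnnotation,
    threshold: float = EXPRESSION_THRESHOLD,
    min_len: int = MIN_NCRNA_LENGTH,
) -> list[NcRnaCall]:
    """Maximal expressed runs per strand, excluding runs that overlap a
    same-strand CDS, shorter than ``min_len``, or (after the CDS check)
    below the median threshold."""
    calls: list[NcRnaCall] = []
    cds = annotation.cds_features(include_pseudogenized=True)
    counter = 0
    for strand, cov in (("+", coverage_plus), ("-", coverage_minus)):
        above = np.asarray(cov) > threshold
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        runs = list(zip(edges[::2], edges[1::2]))
        for s, e in runs:
            if e - s < min_len:
                continue
            if any(f.strand == strand and f.overlap(s, e) > 0 for f in cds):
                continue
            med = float(np.median(cov[s:e]))
            if med <= threshold:
                continue
            counter += 1
            calls.append(
                NcRnaCall(
                    call_id=f"{annotation.strain_id}_ncRNA_{counter}",
                    start=s,
                    end=e,
                    strand=strand,
                    median_coverage=med,
                )
            )
    for c in calls:
        c.ncrna_class = classify_ncrna(c, annotation)
    return calls


def classify_ncrna(call: NcRnaCall, annotation: StrainAnnotation) -> str:
    """"antisense" iff opposite-strand CDS overlap exceeds half the call
    length (strictly); "intergenic" otherwise."""
    opposite = [
        f
        for f in annotation.cds_features(include_pseudogenized=True)
        if f.strand != call.strand
    ]
    overlap = sum(f.overlap(call.start, call.end) for f in opposite)
    return "antisense" if overlap > call.length / 2 else "intergenic"


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _nt_identity(a: str, b: str) -> tuple[float, float]:
    """Local-alignment identity and coverage (vs the shorter sequence)."""
    if not a or not b:
        return 0.0, 0.0
    alns = _local_aligner().align(a.upper(), b.upper())
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    aligned = ident = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            aligned += 1
            if x == y:
                ident += 1
    return (ident / aligned if aligned else 0.0, aligned / min(len(a), len(b)))


def match_ncrna_across_strains(
    calls_a: Sequence[NcRnaCall],
    calls_b: Sequence[NcRnaCall],
    genome_a: str | StrainAnnotation,
    genome_b: str | StrainAnnotation,
    min_identity: float = MATCH_MIN_IDENTITY,
    min_coverage: float = MATCH_MIN_COVERAGE,
    mode: str = "sequence",
) -> dict:
    """Reciprocal-best pairing of ncRNA calls between two strains.

    ``mode="sequence"`` (default) pairs by nucleotide local-alignment
    identity/coverage; ``mode="position"`` pairs by reciprocal coordinate
    overlap >= 50% (appropriate for collinear genomes). Returns pairs plus
    per-strain unmatched call ids.
    """
    seq_a = genome_a.sequence if isinstance(genome_a, StrainAnnotation) else genome_a
    seq_b = genome_b.sequence if isinstance(genome_b, StrainAnnotation) else genome_b

    def call_seq(call: NcRnaCall, genome: str) -> str:
        seg = genome[call.start : call.end]
        return seg if call.strand == "+" else revcomp(seg)

    score: dict[tuple[str, str], float] = {}
    for ca in calls_a:
        for cb in calls_b:
            if mode == "position":
                ov = max(0, min(ca.end, cb.end) - max(ca.start, cb.start))
                ok = (
                    ca.strand == cb.strand
                    and ov > 0.5 * ca.length
                    and ov > 0.5 * cb.length
                )
                score[(ca.call_id, cb.call_id)] = float(ov) if ok else 0.0
            else:
                ident, cover = _nt_identity(call_seq(ca, seq_a), call_seq(cb, seq_b))
                score[(ca.call_id, cb.call_id)] = (
                    ident if (ident >= min_identity and cover >= min_coverage) else 0.0
                )
    ids_a = sorted(c.call_id for c in calls_a)
    ids_b = sorted(c.call_id for c in calls_b)
    pairs: list[tuple[str, str]] = []
    if ids_a and ids_b:
        best_a = {a: min(ids_b, key=lambda b: (-score[(a, b)], b)) for a in ids_a}
        best_b = {b: min(ids_a, key=lambda a: (-score[(a, b)], a)) for b in ids_b}
        pairs = [
            (a, b)
            for a, b in best_a.items()
            if score[(a, b)] > 0 and best_b[b] == a
        ]
    matched_a = {a for a, _ in pairs}
    matched_b = {b for _, b in pairs}
    return {
        "pairs": pairs,
        "unmatched_a": [i for i in ids_a if i not in matched_a],
        "unmatched_b": [i for i in ids_b if i not in matched_b],
    }
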