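"""Date strain-unique gene creation from traces in relatives' non-coding DNA.

A newborn gene that arose from a protogene leaves drifting homologous
sequence in the non-coding regions of related strains. Each unique protein
is searched against all six reading-frame translations of relatives'
genomes (seeded, ungapped, BLOSUM62; Karlin-Altschul E-values), hits are
masked to the non-coding moiety, and the creation node is the MRCA of the
focal strain and every strain with evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices

from .genome_io import Feature, FeatureKind, LabeledRootedTree, StrainAnnotation, six_frame_translate

SEED_LENGTH = 4
XDROP = 20.0
KA_LAMBDA = 0.318  # ungapped BLOSUM62 Karlin-Altschul parameters
KA_K = 0.13
E_MAX = 1e-3

_BLOSUM = substitution_matrices.load("BLOSUM62")
_B62: dict[tuple[str, str], float] = {}
for _i, _a in enumerate(_BLOSUM.alphabet):
    for _j, _b in enumerate(_BLOSUM.alphabet):
        _B62[(_a, _b)] = float(_BLOSUM[_i, _j])


def _score(a: str, b: str) -> float:
    return _B62.get((a, b), -4.0)


class HitContext(str, Enum):
    INTERGENIC = "intergenic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    ANTISENSE_CDS = "antisense_cds"
    ALTERNATIVE_FRAME = "alternative_frame"
    NCRNA_OVERLAP = "ncRNA_overlap"


@dataclass
class TraceHit:
    query_id: str
    subject_strain: str
    start: int  # genomic, 0-based half-open
    end: int
    frame: int  # +1..+3, -1..-3
    score: float
    evalue: float
    context: HitContext | None = None


def karlin_altschul_evalue(
    score: float,
    query_len: int,
    subject_len: int,
    lam: float = KA_LAMBDA,
    K: float = KA_K,
) -> float:
    """Ungapped local-alignment E-value: E = K * m * n * exp(-lambda * S)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return K * query_len * subject_len * math.exp(-lam * score)


class TranslatedSearcher:
    """Seeded six-frame protein-vs-genome search against one subject.

    The subject's frame translations and the exact ``SEED_LENGTH``-mer seed
    index are built once and reused across queries.
    """

    def __init__(self, subject: StrainAnnotation):
        if subject.length < 3:
            raise ValueError("subject shorter than one codon")
        self.subject = subject
        self.frames = six_frame_translate(subject.sequence)
        self._index: dict[str, list[tuple[int, int]]] = {}
        for frame, pep in self.frames.items():
            for i in range(len(pep) - SEED_LENGTH + 1):
                word = pep[i : i + SEED_LENGTH]
                if "*" in word or "X" in word:
                    continue
                self._index.setdefault(word, []).append((frame, i))
        self._same_frame_cds = self._cds_frame_map()

    def _cds_frame_map(self) -> dict[int, list[tuple[int, int]]]:
        """Genomic CDS intervals grouped by the search frame they occupy."""
        n = self.subject.length
        by_frame: dict[int, list[tuple[int, int]]] = {f: [] for f in (1, 2, 3, -1, -2, -3)}
        for f in self.subject.cds_features(include_pseudogenized=True):
            if f.strand == "+":
                frame = f.start % 3 + 1
            else:
                frame = -((n - f.end) % 3 + 1)
            by_frame[frame].append((f.start, f.end))
        return by_frame

    def aa_to_genomic(self, frame: int, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map a frame-translation peptide interval to genomic coordinates."""
        n = self.subject.length
        k = abs(frame) - 1
        if frame > 0:
            return k + 3 * aa_start, k + 3 * aa_end
        return n - (k + 3 * aa_end), n - (k + 3 * aa_start)

    def _extend(self, query: str, pep: str, qpos: int, spos: int) -> tuple[int, int, float]:
        """Ungapped X-drop extension around a seed; returns (q_start, q_end, score)."""
        seed_score = sum(_score(query[qpos + k], pep[spos + k]) for k in range(SEED_LENGTH))
        # right extension
        best = run = seed_score
        best_right = SEED_LENGTH
        k = SEED_LENGTH
        while qpos + k < len(query) and spos + k < len(pep):
            run += _score(query[qpos + k], pep[spos + k])
            k += 1
            if run > best:
                best, best_right = run, k
            if best - run > XDROP:
                break
        # left extension
        run = best
        best_left = 0
        k = 1
        while qpos - k >= 0 and spos - k >= 0:
            run += _score(query[qpos - k], pep[spos - k])
            if run > best:
                best, best_left = run, k
            if best - run > XDROP:
                break
            k += 1
        return qpos - best_left, qpos - best_left + (best_right + best_left), best

    def search(
        self,
        query: str,
        query_id: str = "query",
        e_max: float = E_MAX,
        min_noncoding_frac: float = 0.5,
    ) -> list[TraceHit]:
        """All non-coding hits with E <= e_max, sorted by E-value.

        A hit is discarded when more than ``1 - min_noncoding_frac`` of it
        overlaps a same-strand, same-frame CDS (i.e. it merely rediscovers
        an annotated coding region); UTR, antisense and alternative-frame
        overlaps are kept, mirroring the contexts the analysis reports.
        """
        query = query.upper()
        if len(query) < 20:
            raise ValueError("query shorter than 20 aa")
        best_by_diag: dict[tuple[int, int], tuple[int, int, float]] = {}
        for qpos in range(len(query) - SEED_LENGTH + 1):
            word = query[qpos : qpos + SEED_LENGTH]
            for frame, spos in self._index.get(word, ()):
                diag = spos - qpos
                pep = self.frames[frame]
                qs, qe, score = self._extend(query, pep, qpos, spos)
                prev = best_by_diag.get((frame, diag))
                if prev is None or score > prev[2]:
                    best_by_diag[(frame, diag)] = (qs, qe, score)
        hits: list[TraceHit] = []
        n = self.subject.length
        for (frame, diag), (qs, qe, score) in best_by_diag.items():
            if score <= 0:
                continue
            e = karlin_altschul_evalue(score, len(query), n)
            if e > e_max:
                continue
            g_start, g_end = self.aa_to_genomic(frame, qs + diag, qe + diag)
            cds_ov = sum(
                max(0, min(g_end, ce) - max(g_start, cs))
                for cs, ce in self._same_frame_cds[frame]
            )
            if (g_end - g_start) and 1 - cds_ov / (g_end - g_start) < min_noncoding_frac:
                continue
            hits.append(
                TraceHit(
                    query_id=query_id,
                    subject_strain=self.subject.strain_id,
                    start=g_start,
                    end=g_end,
                    frame=frame,
                    score=score,
                    evalue=e,
                )
            )
        hits = _dedupe_overlapping(hits)
        for h in hits:
            h.context = classify_hit_context(h, self.subject)
        hits.sort(key=lambda h: (h.evalue, h.start))
        return hits


def _dedupe_overlapping(hits: list[TraceHit]) -> list[TraceHit]:
    """Keep the best-scoring hit among genomically overlapping ones."""
    kept: list[TraceHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.start)):
        if all(
            h.end <= k.start or h.start >= k.end or h.frame != k.frame for k in kept
        ):
            kept.append(h)
    return kept


def translated_noncoding_search(
    query: str,
    subject: StrainAnnotation,
    e_max: float = E_MAX,
    query_id: str = "query",
) -> list[TraceHit]:
    """One-shot wrapper around :class:`TranslatedSearcher`."""
    return TranslatedSearcher(subject).search(query, query_id=query_id, e_max=e_max)


def classify_hit_context(hit: TraceHit, annotation: StrainAnnotation) -> HitContext:
    """Context of a hit interval, by priority: alternative frame on a
    same-strand CDS > antisense CDS > 5'/3' UTR > ncRNA overlap >
    intergenic. A category needs to cover at least half the hit."""
    strand = "+" if hit.frame > 0 else "-"
    length = hit.end - hit.start
    n = annotation.length

    def frac(features: Iterable[Feature]) -> float:
        ov = 0
        for f in features:
            ov += f.overlap(hit.start, hit.end)
        return min(ov / length, 1.0) if length else 0.0

    cds = annotation.cds_features(include_pseudogenized=True)
    same = [f for f in cds if f.strand == strand]
    # same-strand CDS overlap here is necessarily in a different frame:
    # same-frame hits were masked out during the search
    if frac(same) > 0.5:
        return HitContext.ALTERNATIVE_FRAME
    anti = [f for f in cds if f.strand != strand]
    if frac(anti) > 0.5:
        return HitContext.ANTISENSE_CDS
    if frac(f for f in annotation.features_of_kind(FeatureKind.UTR5)) > 0.5:
        return HitContext.UTR5
    if frac(f for f in annotation.features_of_kind(FeatureKind.UTR3)) > 0.5:
        return HitContext.UTR3
    if frac(f for f in annotation.features_of_kind(FeatureKind.NCRNA)) > 0.5:
        return HitContext.NCRNA_OVERLAP
    return HitContext.INTERGENIC


@dataclass
class AncestryAssignment:
    gene_id: str
    node: int | str | None
    supporting_strains: list[str]


def assign_creation_node(
    tree: LabeledRootedTree,
    focal_leaf: str,
    strains_with_evidence: Iterable[str],
    gene_id: str = "",
    require_full_clade: bool = False,
) -> AncestryAssignment:
    """MRCA of the focal leaf and all evidence leaves; None without evidence.

    With ``require_full_clade`` the assignment is instead the deepest
    ancestor of the focal leaf whose every other descendant carries
    evidence (the stricter all-descendants reading).
    """
    evidence = sorted(set(strains_with_evidence) - {focal_leaf})
    if focal_leaf not in tree.leaves:
        raise KeyError(f"focal leaf {focal_leaf!r} not in tree")
    missing = set(evidence) - set(tree.leaves)
    if missing:
        raise KeyError(f"evidence leaves not in tree: {sorted(missing)}")
    if not evidence:
        return AncestryAssignment(gene_id=gene_id, node=None, supporting_strains=[])
    if not require_full_clade:
        node = tree.mrca([focal_leaf, *evidence])
    else:
        node = None
        for label in tree.ancestor_labels(focal_leaf)[:-1]:  # root..parent
            others = tree.leaves_below(label) - {focal_leaf}
            if others and others <= set(evidence):
                node = label
                break
    return AncestryAssignment(gene_id=gene_id, node=node, supporting_strains=evidence)


def summarize_node_distribution(
    assignments: Iterable[AncestryAssignment | int | None],
) -> dict[int | str | None, int]:
    """Multiset count of assigned creation nodes (None = no trace)."""
    counts: dict[int | str | None, int] = {}
    for a in assignments:
        node = a.node if isinstance(a, AncestryAssignment) else a
        counts[node] = counts.get(node, 0) + 1
    return counts
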