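"""Forward genome-evolution simulator with de novo gene birth.

Genomes are alternating CDS/intergenic segments evolved down a labeled
rooted tree. Coding segments evolve under a Goldman-Yang-style codon model
(transition bias kappa, nonsynonymous scaling omega); intergenic DNA under
an HKY-like nucleotide model with short indels. Gene birth inserts a
protogene-derived ORF (intergenic composition) on the drawn branch; gene
death drops the annotation but keeps the sequence drifting as non-coding
DNA, so traces of dead or never-activated genes remain findable.

Compositional defaults mirror the pandoravirus contrast between coding
(G+C ~ 64.4%) and intergenic (~57.5%) DNA. Birth/death rates are
illustrative: no empirical estimates exist for them.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from scipy.linalg import expm

from .codons import (
    CODON_INDEX,
    GENETIC_CODE,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    revcomp,
    split_codons,
)
from .genome_io import Feature, FeatureKind, LabeledRootedTree, StrainAnnotation


@dataclass
class SimParams:
    """Generator settings; rates are per branch (expected events) unless noted."""

    coding_gc: float = 0.644
    intergenic_gc: float = 0.575
    omega_ancestral: float = 0.3
    omega_new: float = 0.8
    kappa: float = 2.0
    birth_rate: float = 1.0
    death_rate: float = 0.05
    gene_length_aa: tuple[float, float] = (5.5, 0.45)  # lognormal (mu, sigma) of aa length
    new_gene_length_aa: tuple[float, float] = (4.8, 0.35)
    indel_rate: float = 0.002  # events/site per unit branch length, intergenic only
    n_ancestral_genes: int = 20
    intergenic_len: int = 400
    n_ncrna: int = 8
    ncrna_switch: float = 0.3  # per-branch on/off toggle probability
    ncrna_antisense_frac: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for gc in (self.coding_gc, self.intergenic_gc):
            if not 0 < gc < 1:
                raise ValueError("GC fractions must lie in (0, 1)")
        for r in (self.birth_rate, self.death_rate, self.indel_rate, self.kappa):
            if r < 0:
                raise ValueError("rates must be non-negative")


def _nt_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _conditional_nonstop_gc(base_gc: float) -> float:
    """Mean G+C of iid-nucleotide codons conditioned on not being a stop."""
    p = _nt_probs(base_gc)
    idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    tot = gc_sum = 0.0
    for c in SENSE_CODONS:
        pc = p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]]
        tot += pc
        gc_sum += pc * sum(x in "GC" for x in c) / 3.0
    return gc_sum / tot


@lru_cache(maxsize=None)
def _gc_base_for_target(target_gc: float) -> float:
    """Base nucleotide GC whose stop-free codon distribution realizes the
    target G+C (stop rejection enriches G+C by ~1 point otherwise)."""
    from scipy.optimize import brentq

    return float(brentq(lambda g: _conditional_nonstop_gc(g) - target_gc, 0.05, 0.95))


# ---------------------------------------------------------------------------
# codon-level evolution


def _codon_stationary(gc: float | None) -> np.ndarray:
    if gc is None:
        return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    p = _nt_probs(_gc_base_for_target(gc))
    idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    pi = np.array([p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] for c in SENSE_CODONS])
    return pi / pi.sum()


@lru_cache(maxsize=32)
def _codon_rate_matrix(omega: float, kappa: float, gc: float | None = None) -> np.ndarray:
    """Goldman-Yang-style generator over the 61 sense codons.

    With ``gc`` set, target-frequency factors (F1x4 flavour) make the
    coding composition stationary, so genomes keep their G+C along deep
    branches.
    """
    n = len(SENSE_CODONS)
    nt_pi = _nt_probs(_gc_base_for_target(gc)) if gc is not None else np.full(4, 0.25)
    nt_idx = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == ci[pos]:
                    continue
                cj = ci[:pos] + nt + ci[pos + 1 :]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                rate = nt_pi[nt_idx[nt]] * (kappa if is_transition(ci[pos], nt) else 1.0)
                if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                    rate *= omega
                Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # one expected substitution per nucleotide site per unit time at
    # stationarity (3 nt sites per codon)
    pi = _codon_stationary(gc)
    mean_rate = -float(pi @ np.diag(Q))
    if mean_rate > 0:
        Q /= mean_rate / 3.0
    return Q


def _transition_matrix(omega: float, kappa: float, t: float, gc: float | None) -> np.ndarray:
    return expm(_codon_rate_matrix(omega, kappa, gc) * t)


def evolve_codon_sequence(
    seq: str,
    t: float,
    omega: float,
    kappa: float = 2.0,
    rng: np.random.Generator | int | None = None,
    gc: float | None = None,
) -> str:
    """Evolve a coding sequence for branch length ``t`` (substitutions per
    nucleotide site) under the codon model. A terminal stop is preserved;
    internal stops are rejected."""
    rng = np.random.default_rng(rng)
    codons = split_codons(seq.upper())
    stop = ""
    if codons and codons[-1] in STOP_CODONS:
        stop = codons[-1]
        codons = codons[:-1]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("internal stop codon")
    if t < 0:
        raise ValueError("negative branch length")
    if t == 0 or not codons:
        return seq.upper()
    P = _transition_matrix(omega, kappa, t, gc)
    idx = np.array([CODON_INDEX[c] for c in codons])
    out = [
        SENSE_CODONS[rng.choice(len(SENSE_CODONS), p=P[i])]
        for i in idx
    ]
    return "".join(out) + stop


# ---------------------------------------------------------------------------
# intergenic evolution


def _nt_rate_matrix(kappa: float, gc: float) -> np.ndarray:
    pi = _nt_probs(gc)
    Q = np.zeros((4, 4))
    for i, a in enumerate(NUCLEOTIDES):
        for j, b in enumerate(NUCLEOTIDES):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if is_transition(a, b) else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(pi * np.diag(Q))
    if mu > 0:
        Q /= mu
    return Q


def evolve_intergenic(
    seq: str,
    t: float,
    params: SimParams,
    rng: np.random.Generator,
) -> str:
    """HKY-like substitution plus geometric-length indels (p=0.5, max 10 nt)."""
    if t == 0 or not seq:
        return seq
    P = expm(_nt_rate_matrix(params.kappa, params.intergenic_gc) * t)
    code = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    idx = np.array([code.get(c, 0) for c in seq.upper()])
    new_idx = idx.copy()
    for i in range(4):
        mask = idx == i
        if mask.any():
            new_idx[mask] = rng.choice(4, size=int(mask.sum()), p=P[i])
    out = "".join(NUCLEOTIDES[i] for i in new_idx)
    n_events = rng.poisson(params.indel_rate * t * len(out))
    for _ in range(n_events):
        length = min(int(rng.geometric(0.5)), 10)
        pos = int(rng.integers(0, max(1, len(out))))
        if rng.random() < 0.5 and len(out) > length:
            out = out[:pos] + out[pos + length :]
        else:
            ins = "".join(rng.choice(list(NUCLEOTIDES), size=length, p=_nt_probs(params.intergenic_gc)))
            out = out[:pos] + ins + out[pos:]
    return out


# ---------------------------------------------------------------------------
# sequence sampling


def _sample_codons(
    n: int, gc: float, rng: np.random.Generator, no_stop: bool = True
) -> list[str]:
    probs = _nt_probs(_gc_base_for_target(gc) if no_stop else gc)
    out: list[str] = []
    while len(out) < n:
        c = "".join(rng.choice(list(NUCLEOTIDES), size=3, p=probs))
        if no_stop and c in STOP_CODONS:
            continue
        out.append(c)
    return out


def sample_protogene(
    params: SimParams,
    length_aa: int,
    rng: np.random.Generator | int | None = None,
) -> str:
    """A stop-free ORF (ATG ... stop) drawn from the intergenic composition.

    The G+C of the body follows ``params.intergenic_gc``, not the coding
    model: protogenes look like the non-coding DNA they came from.
    """
    if length_aa < 30:
        raise ValueError("protogenes must encode at least 30 aa")
    rng = np.random.default_rng(rng)
    body = _sample_codons(length_aa - 1, params.intergenic_gc, rng)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    return "ATG" + "".join(body) + stop


def sample_gene(
    params: SimParams, length_aa: int, rng: np.random.Generator
) -> str:
    """An established gene: coding composition, ATG ... stop."""
    body = _sample_codons(length_aa - 1, params.coding_gc, rng)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    return "ATG" + "".join(body) + stop


def sample_intergenic(params: SimParams, length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length, p=_nt_probs(params.intergenic_gc)))


# ---------------------------------------------------------------------------
# family simulation


@dataclass
class GeneTruth:
    gene_id: str
    birth_branch: int | str  # child label of the branch carrying the birth
    death_branches: list[int | str] = field(default_factory=list)
    omega: float = 0.3
    origin: str = "ancestral_core"  # ancestral_core | protogene_birth | insertion
    strand: str = "+"


@dataclass
class SimTruthTable:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    ncrna_states: dict[str, dict[str, bool]] = field(default_factory=dict)  # id -> leaf -> on
    ncrna_class: dict[str, str] = field(default_factory=dict)  # id -> antisense|intergenic

    def presence_matrix(self, tree: LabeledRootedTree) -> dict[str, dict[str, bool]]:
        """Gene x leaf presence implied by births and deaths on the tree."""
        out: dict[str, dict[str, bool]] = {}
        for gid, g in self.genes.items():
            born_below = (
                tree.leaves_below(g.birth_branch)
                if g.birth_branch in tree.internal_labels
                else {g.birth_branch}
            )
            dead: set[str] = set()
            for d in g.death_branches:
                dead |= (
                    tree.leaves_below(d) if d in tree.internal_labels else {d}
                )
            out[gid] = {leaf: (leaf in born_below and leaf not in dead) for leaf in tree.leaves}
        return out


@dataclass
class _Segment:
    kind: str  # "intergenic" | "gene"
    seq: str  # coding-strand codons for genes, genomic for intergenic
    gene_id: str = ""
    strand: str = "+"
    omega: float = 0.3


@dataclass
class ScriptedBirth:
    """A planted birth: protogene sequence arises on the branch into
    ``origin_node`` and is annotated as a CDS only in ``active_leaves``
    (drifting as non-coding DNA in every other descendant)."""

    origin_node: int | str
    active_leaves: tuple[str, ...]
    length_aa: int = 120


def simulate_family(
    tree: LabeledRootedTree,
    params: SimParams,
    scripted_births: Iterable[ScriptedBirth] = (),
) -> tuple[dict[str, StrainAnnotation], SimTruthTable]:
    """Evolve a root genome down the tree; returns per-leaf annotations and
    the ground-truth table consistent with them."""
    if len(tree.leaves) < 2:
        raise ValueError("tree must have at least two leaves")
    if params.n_ancestral_genes < 1 and params.birth_rate == 0 and not scripted_births:
        raise ValueError("parameters yield zero genes")
    rng = np.random.default_rng(params.seed)
    truth = SimTruthTable()

    segments: list[_Segment] = [
        _Segment("intergenic", sample_intergenic(params, params.intergenic_len, rng))
    ]
    for k in range(params.n_ancestral_genes):
        mu, sigma = params.gene_length_aa
        length_aa = max(60, int(rng.lognormal(mu, sigma)))
        gid = f"gene_{k + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        omega = params.omega_ancestral
        segments.append(
            _Segment("gene", sample_gene(params, length_aa, rng), gid, strand, omega)
        )
        segments.append(
            _Segment("intergenic", sample_intergenic(params, params.intergenic_len, rng))
        )
        truth.genes[gid] = GeneTruth(
            gene_id=gid, birth_branch=tree.root_label, omega=omega, strand=strand
        )

    # ncRNA loci anchored to ancestral genes (antisense) or intergenic gaps
    for k in range(params.n_ncrna):
        nid = f"ncrna_{k + 1:03d}"
        truth.ncrna_class[nid] = (
            "antisense" if rng.random() < params.ncrna_antisense_frac else "intergenic"
        )
        truth.ncrna_states[nid] = {}
    ncrna_anchor: dict[str, int] = {}
    gene_positions = [i for i, s in enumerate(segments) if s.kind == "gene"]
    inter_positions = [i for i, s in enumerate(segments) if s.kind == "intergenic"]
    for nid, klass in truth.ncrna_class.items():
        pool = gene_positions if klass == "antisense" else inter_positions
        ncrna_anchor[nid] = int(rng.choice(pool))

    scripted = list(scripted_births)
    birth_counter = [0]

    leaf_genomes: dict[str, list[_Segment]] = {}

    def descend(
        node_label: int | str,
        genome: list[_Segment],
        ncrna_on: dict[str, bool],
        child_branches: list,
    ) -> None:
        for parent, child, t in child_branches:
            if parent != node_label:
                continue
            # stable per-branch substream: adding a leaf elsewhere does not
            # perturb this branch's draws
            child_rng = np.random.default_rng(
                np.random.SeedSequence(
                    [params.seed, zlib.crc32(str(child).encode())]
                )
            )
            g = [replace(s) for s in genome]
            # scripted genes with no active leaf below this branch revert to
            # plain drifting non-coding DNA (the trace the search recovers)
            below = (
                tree.leaves_below(child) if child in tree.internal_labels else {child}
            )
            for s in g:
                if s.kind != "gene" or not s.gene_id.startswith("planted_"):
                    continue
                active = getattr(truth.genes[s.gene_id], "_active_leaves", set())
                if not (active & below):
                    truth.genes[s.gene_id].death_branches.append(child)
                    genomic = s.seq if s.strand == "+" else revcomp(s.seq)
                    s.kind, s.seq, s.gene_id = "intergenic", genomic, ""
            # substitutions
            for s in g:
                if s.kind == "gene":
                    s.seq = evolve_codon_sequence(
                        s.seq, t, s.omega, params.kappa, child_rng, gc=params.coding_gc
                    )
                else:
                    s.seq = evolve_intergenic(s.seq, t, params, child_rng)
            # deaths: annotation lost, sequence keeps drifting as intergenic
            if params.death_rate > 0:
                for s in list(g):
                    if s.kind != "gene" or truth.genes[s.gene_id].origin == "scripted":
                        continue
                    if child_rng.random() < 1 - math.exp(-params.death_rate):
                        truth.genes[s.gene_id].death_branches.append(child)
                        genomic = s.seq if s.strand == "+" else revcomp(s.seq)
                        s.kind, s.seq, s.gene_id = "intergenic", genomic, ""
            # stochastic births
            for _ in range(child_rng.poisson(params.birth_rate)):
                birth_counter[0] += 1
                gid = f"newgene_{birth_counter[0]:04d}"
                mu, sigma = params.new_gene_length_aa
                length_aa = max(30, int(child_rng.lognormal(mu, sigma)))
                seq = sample_protogene(params, length_aa, child_rng)
                strand = "+" if child_rng.random() < 0.5 else "-"
                pos = int(child_rng.integers(0, len(g)))
                g.insert(pos, _Segment("gene", seq, gid, strand, params.omega_new))
                truth.genes[gid] = GeneTruth(
                    gene_id=gid,
                    birth_branch=child,
                    omega=params.omega_new,
                    origin="protogene_birth",
                    strand=strand,
                )
            # scripted births materialize on their origin branch
            for sb in scripted:
                if sb.origin_node == child:
                    birth_counter[0] += 1
                    gid = f"planted_{birth_counter[0]:04d}"
                    seq = sample_protogene(params, sb.length_aa, child_rng)
                    pos = int(child_rng.integers(0, len(g)))
                    g.insert(pos, _Segment("gene", seq, gid, "+", params.omega_new))
                    gt = GeneTruth(
                        gene_id=gid,
                        birth_branch=child,
                        omega=params.omega_new,
                        origin="scripted",
                    )
                    gt._active_leaves = set(sb.active_leaves)  # type: ignore[attr-defined]
                    truth.genes[gid] = gt
            # ncRNA on/off toggling
            child_on = dict(ncrna_on)
            for nid in child_on:
                if child_rng.random() < params.ncrna_switch:
                    child_on[nid] = not child_on[nid]
            if child in tree.leaves:
                for nid, on in child_on.items():
                    truth.ncrna_states[nid][child] = on
                leaf_genomes[child] = g
            else:
                descend(child, g, child_on, child_branches)

    root_on = {nid: True for nid in truth.ncrna_class}
    descend(tree.root_label, segments, root_on, tree.branches())

    annotations = {
        leaf: _emit_annotation(leaf, genome, truth, ncrna_anchor, rng)
        for leaf, genome in sorted(leaf_genomes.items())
    }
    if not any(a.cds_features() for a in annotations.values()):
        raise ValueError("parameters yield zero genes in every leaf")
    return annotations, truth


def _emit_annotation(
    leaf: str,
    genome: list[_Segment],
    truth: SimTruthTable,
    ncrna_anchor: dict[str, int],
    rng: np.random.Generator,
) -> StrainAnnotation:
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    seg_index_of_gene: dict[str, tuple[int, int]] = {}
    anchor_intervals: dict[int, tuple[int, int]] = {}
    for i, s in enumerate(genome):
        if s.kind == "gene":
            g = truth.genes[s.gene_id]
            active = getattr(g, "_active_leaves", None)
            genomic = s.seq if s.strand == "+" else revcomp(s.seq)
            if active is None or leaf in active:
                features.append(
                    Feature(
                        feature_id=f"{leaf}|{s.gene_id}",
                        kind=FeatureKind.CDS,
                        start=pos,
                        end=pos + len(genomic),
                        strand=s.strand,
                    )
                )
            elif leaf not in g.death_branches:
                g.death_branches.append(leaf)
            anchor_intervals[i] = (pos, pos + len(genomic))
            parts.append(genomic)
            pos += len(genomic)
        else:
            anchor_intervals[i] = (pos, pos + len(s.seq))
            parts.append(s.seq)
            pos += len(s.seq)
    # ncRNA features at their anchors, on the opposite strand for antisense
    for nid, states in truth.ncrna_states.items():
        if not states.get(leaf, False):
            continue
        anchor = ncrna_anchor[nid]
        if anchor >= len(genome):
            continue
        a_start, a_end = anchor_intervals.get(anchor, (0, 0))
        if a_end - a_start < 60:
            continue
        seg = genome[anchor]
        if truth.ncrna_class[nid] == "antisense" and seg.kind == "gene":
            strand = "-" if seg.strand == "+" else "+"
            start, end = a_start, a_end
        else:
            strand = "+"
            span = a_end - a_start
            length = max(60, int(span * 0.6))
            start = a_start + (span - length) // 2
            end = start + length
        features.append(
            Feature(
                feature_id=f"{leaf}|{nid}",
                kind=FeatureKind.NCRNA,
                start=start,
                end=end,
                strand=strand,
            )
        )
    return StrainAnnotation(strain_id=leaf, sequence="".join(parts), features=features)


# ---------------------------------------------------------------------------
# expression / coverage


def simulate_coverage(
    annotation: StrainAnnotation,
    on_fraction: float,
    rng: np.random.Generator | int | None = None,
    on_median: float = 300.0,
    on_sigma: float = 1.2,
) -> dict[str, float]:
    """Per-feature median coverage: expressed features draw from a high
    log-normal regime (median a few hundred), silent ones stay below the
    validation threshold of 5."""
    if not 0 <= on_fraction <= 1:
        raise ValueError("on_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    out: dict[str, float] = {}
    for f in annotation.features:
        if rng.random() < on_fraction:
            out[f.feature_id] = max(10.0, float(rng.lognormal(math.log(on_median), on_sigma)))
        else:
            out[f.feature_id] = float(rng.uniform(0.0, 4.5))
    return out


def simulate_base_coverage(
    annotation: StrainAnnotation,
    feature_medians: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
    background: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Stranded per-base coverage tracks (plus, minus) with Poisson noise
    around each feature's median and a low background elsewhere."""
    rng = np.random.default_rng(rng)
    plus = rng.poisson(background, annotation.length).astype(float)
    minus = rng.poisson(background, annotation.length).astype(float)
    for f in annotation.features:
        level = feature_medians.get(f.feature_id)
        if level is None:
            continue
        track = plus if f.strand == "+" else minus
        track[f.start : f.end] += rng.poisson(max(level, 0.0), f.end - f.start)
    return plus, minus
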