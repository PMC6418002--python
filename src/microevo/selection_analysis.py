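"""Pairwise dN/dS estimation for ortholog pairs, with node-level aggregation.

The estimator is Nei-Gojobori (1986) pathway counting with Jukes-Cantor
correction: synonymous/nonsynonymous site counts per codon, averaged
difference counts over all shortest stop-free mutational pathways, then
d = -(3/4) ln(1 - 4p/3) per class. A transition/transversion-weighted
site-counting variant (YN00-flavoured) is available via ``method="kappa"``.

Pairs are screened with the filters dN > 0, dS > 0, dS <= 2 and
dN/dS <= 10 before aggregation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .codons import (
    GENETIC_CODE,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    split_codons,
    translate,
)

MAX_DS = 2.0
MAX_OMEGA = 10.0


@dataclass
class CodonPairAlignment:
    """Gap-free aligned codon columns for one ortholog pair."""

    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("unequal codon row lengths")
        for c in itertools.chain(self.codons_a, self.codons_b):
            if c in STOP_CODONS:
                raise ValueError("stop codon inside alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class DnDsEstimate:
    gene_a: str
    gene_b: str
    dN: float | None
    dS: float | None
    omega: float | None
    N_sites: float
    S_sites: float
    passed_filters: bool


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def codon_align_via_protein(
    nt_a: str, nt_b: str, gene_a: str = "a", gene_b: str = "b"
) -> CodonPairAlignment:
    """Globally align the translations, back-map codons, drop gapped columns."""
    rows: list[list[str]] = []
    peps: list[str] = []
    for seq in (nt_a, nt_b):
        codons = split_codons(seq.upper())
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        pep = "".join(GENETIC_CODE[c] if c in GENETIC_CODE else "X" for c in codons)
        if "*" in pep:
            raise ValueError("internal stop codon; refuse to align a pseudogene")
        rows.append(codons)
        peps.append(pep)
    aln = _protein_aligner().align(peps[0], peps[1])[0]
    a_idx = b_idx = 0
    cod_a: list[str] = []
    cod_b: list[str] = []
    for col_a, col_b in zip(*aln):
        if col_a != "-" and col_b != "-":
            cod_a.append(rows[0][a_idx])
            cod_b.append(rows[1][b_idx])
        if col_a != "-":
            a_idx += 1
        if col_b != "-":
            b_idx += 1
    return CodonPairAlignment(gene_a=gene_a, gene_b=gene_b, codons_a=cod_a, codons_b=cod_b)


def ng86_sites(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """(S_sites, N_sites) for one sense codon.

    Per position, the fraction of single-nucleotide changes that are
    synonymous, with stop-producing changes excluded from that position's
    denominator; S + N = 3 exactly. ``kappa`` != 1 weights transition
    changes, giving the ts/tv-aware site counts used by the YN00-style
    variant.
    """
    codon = codon.upper()
    if codon not in GENETIC_CODE or codon in STOP_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    s_sites = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], nt) else 1.0
            tot_w += w
            if GENETIC_CODE[mutant] == aa:
                syn_w += w
        s_sites += syn_w / tot_w if tot_w else 0.0
    return s_sites, 3.0 - s_sites


def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(S_diffs, N_diffs) between two sense codons.

    Averages the synonymous/nonsynonymous step counts over all shortest
    mutational pathways whose intermediates are sense codons, each pathway
    weighted equally. If every pathway crosses a stop codon, all pathways
    are used (stop-crossing steps counted as nonsynonymous).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c not in GENETIC_CODE or c in STOP_CODONS:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool) -> tuple[float, float] | None:
        cur = a
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if GENETIC_CODE.get(cur, "*") == GENETIC_CODE.get(nxt, "*") and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                s += 1
            else:
                n += 1
            cur = nxt
        return float(s), float(n)

    paths = [walk(order, allow_stops=False) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, allow_stops=True) for order in itertools.permutations(diff_pos)]
    s_mean = sum(p[0] for p in valid) / len(valid)
    n_mean = sum(p[1] for p in valid) / len(valid)
    return s_mean, n_mean


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds_pair(
    aln: CodonPairAlignment,
    min_codons: int = 30,
    method: str = "ng86",
    kappa: float = 2.0,
) -> DnDsEstimate:
    """NG86 dN/dS with Jukes-Cantor correction and the screening filters.

    ``method="kappa"`` uses transition/transversion-weighted site counts
    (difference counting is pathway-based in both variants).
    """
    if aln.n_codons < min_codons:
        raise ValueError(f"alignment has {aln.n_codons} codons; need >= {min_codons}")
    site_kappa = kappa if method == "kappa" else 1.0
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sa, na = ng86_sites(ca, site_kappa)
        sb, nb = ng86_sites(cb, site_kappa)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, nd = ng86_diffs(ca, cb)
        s_diffs += sd
        n_diffs += nd
    pS = s_diffs / s_sites if s_sites else 0.0
    pN = n_diffs / n_sites if n_sites else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    passed = (
        dN is not None
        and dS is not None
        and dN > 0
        and dS > 0
        and dS <= MAX_DS
        and omega is not None
        and omega <= MAX_OMEGA
    )
    return DnDsEstimate(
        gene_a=aln.gene_a,
        gene_b=aln.gene_b,
        dN=dN,
        dS=dS,
        omega=omega,
        N_sites=n_sites,
        S_sites=s_sites,
        passed_filters=passed,
    )


def aggregate_by_node(
    estimates: Iterable[DnDsEstimate],
    node_of_pair: Mapping[tuple[str, str], int | str],
) -> pd.DataFrame:
    """Mean/sd/n of omega per creation node over filter-passing pairs.

    ``node_of_pair`` maps (gene_a, gene_b) to the label of the node dating
    the pair (the MRCA of the strains carrying the gene cluster). Nodes
    with no passing pair are omitted.
    """
    rows: dict[int | str, list[float]] = {}
    for est in estimates:
        if not est.passed_filters:
            continue
        key = (est.gene_a, est.gene_b)
        node = node_of_pair.get(key, node_of_pair.get((est.gene_b, est.gene_a)))
        if node is None:
            raise KeyError(f"no node assignment for pair {key}")
        rows.setdefault(node, []).append(est.omega)
    records = [
        {
            "node": node,
            "mean_omega": float(np.mean(vals)),
            "sd_omega": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": len(vals),
        }
        for node, vals in sorted(rows.items(), key=lambda kv: str(kv[0]))
    ]
    return pd.DataFrame.from_records(records, columns=["node", "mean_omega", "sd_omega", "n"])
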