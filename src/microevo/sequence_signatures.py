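"""Compositional signatures of newborn genes: CAI, G+C, length, residue chi2.

Newly created genes inherit the composition of the non-coding regions they
arose from, so they separate from the bulk proteome on codon adaptation
(CAI, Sharp & Li relative adaptiveness), G+C fraction, protein length and
amino-acid composition. This module computes those statistics and the
associated tests (Wilcoxon rank-sum per metric, pooled-residue Pearson
chi-square with df = 19).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .codons import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, SYNONYMOUS_FAMILIES, split_codons
from .genome_io import UniqueGeneRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CodonUsage:
    """Sense-codon counts of a reference gene set."""

    counts: dict[str, int] = field(default_factory=dict)
    source: str = ""

    @classmethod
    def from_genes(cls, genes: Iterable[str], source: str = "") -> "CodonUsage":
        counts: Counter[str] = Counter()
        for gene in genes:
            for codon in split_codons(gene.upper()):
                if codon in GENETIC_CODE and codon not in STOP_CODONS:
                    counts[codon] += 1
        if not counts:
            raise ValueError("empty codon usage")
        return cls(counts=dict(counts), source=source)


def relative_adaptiveness(usage: CodonUsage, floor: float = 0.01) -> dict[str, float]:
    """Sharp-Li w: each codon's count over the max count in its synonymous
    family; zero (or all-zero-family) codons floored at ``floor``."""
    w: dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        mx = max(usage.counts.get(c, 0) for c in family)
        for c in family:
            w[c] = max(usage.counts.get(c, 0) / mx, floor) if mx else floor
    return w


def cai(gene: str, w: dict[str, float]) -> float:
    """Codon Adaptation Index: geometric mean of w over the gene's codons.

    The terminal stop is dropped; an internal stop raises (pseudogene
    guard); codons containing ambiguity are skipped.
    """
    codons = split_codons(gene.upper())
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    logs = []
    for codon in codons:
        if codon in STOP_CODONS:
            raise ValueError("internal stop codon")
        if codon in GENETIC_CODE:
            logs.append(math.log(w[codon]))
    if not logs:
        raise ValueError("no scorable codons")
    return math.exp(sum(logs) / len(logs))


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases excluded from the denominator."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return gc / (gc + at)


def composition_chi_square(
    set_a: Sequence[str], set_b: Sequence[str]
) -> dict[str, float]:
    """Pearson chi-square comparing pooled amino-acid composition.

    Expected counts for set_a come from set_b's residue frequencies scaled
    to set_a's total; df is fixed at 19 (20 residue classes). Residues
    absent from set_b get a 0.5 pseudocount in both sets.
    """
    if not set_a or not set_b:
        raise ValueError("both protein sets must be non-empty")

    def pooled(proteins: Sequence[str]) -> np.ndarray:
        c = Counter("".join(p.upper() for p in proteins))
        return np.array([c.get(aa, 0) for aa in AMINO_ACIDS], dtype=float)

    obs = pooled(set_a)
    ref = pooled(set_b)
    zero = ref == 0
    if zero.any():
        obs = obs + 0.5 * zero
        ref = ref + 0.5 * zero
    expected = ref / ref.sum() * obs.sum()
    keep = expected > 0
    statistic = float(((obs[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    df = 19
    return {"statistic": statistic, "df": df, "p": float(stats.chi2.sf(statistic, df))}


def signature_report(
    novel_genes: Sequence[str],
    background_genes: Sequence[str],
    reference_w: dict[str, float] | None = None,
) -> dict[str, dict[str, float | None]]:
    """Per-set means and Wilcoxon rank-sum p for CAI, G+C and protein length.

    ``reference_w`` defaults to relative adaptiveness computed from the
    background set. Lengths are in amino acids (codons minus terminal stop).
    p-values use the normal approximation with tie correction; sets smaller
    than 2 get p = None.
    """
    if not novel_genes or not background_genes:
        raise ValueError("both gene sets must be non-empty")
    if reference_w is None:
        reference_w = relative_adaptiveness(CodonUsage.from_genes(background_genes))

    def metrics(genes: Sequence[str]) -> dict[str, list[float]]:
        out = {"CAI": [], "GC": [], "length": []}
        for g in genes:
            codons = split_codons(g.upper())
            n_aa = len(codons) - (1 if codons and codons[-1] in STOP_CODONS else 0)
            out["CAI"].append(cai(g, reference_w))
            out["GC"].append(gc_content(g))
            out["length"].append(float(n_aa))
        return out

    a, b = metrics(novel_genes), metrics(background_genes)
    report: dict[str, dict[str, float | None]] = {}
    for key in ("CAI", "GC", "length"):
        x, y = np.asarray(a[key]), np.asarray(b[key])
        if len(x) >= 2 and len(y) >= 2:
            p = float(
                stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            )
        else:
            p = None
        report[key] = {
            "novel_mean": float(x.mean()),
            "background_mean": float(y.mean()),
            "p": p,
        }
    return report


def summarize_unique_gene_table(records: Sequence[UniqueGeneRecord]) -> dict:
    """Exact arithmetic over a unique-gene table (counts, mean length,
    DNA-binding calls, creation-node distribution)."""
    if not records:
        return {
            "n_total": 0,
            "n_per_strain": {},
            "mean_length_aa": 0.0,
            "n_dna_binding": 0,
            "node_distribution": {},
            "n_no_trace": 0,
        }
    per_strain: Counter[str] = Counter(r.strain_prefix for r in records)
    nodes: Counter[int | None] = Counter(r.most_ancestral_detection for r in records)
    return {
        "n_total": len(records),
        "n_per_strain": dict(per_strain),
        "mean_length_aa": round(sum(r.length_aa for r in records) / len(records), 1),
        "n_dna_binding": sum(r.predicted_dna_binding for r in records),
        "node_distribution": dict(nodes),
        "n_no_trace": nodes.get(None, 0),
    }
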