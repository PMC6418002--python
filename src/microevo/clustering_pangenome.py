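"""Protein clustering across strains and pan/core-genome accumulation curves.

Clusters are single-linkage connected components of the similarity graph
with edges where global identity >= 30% and coverage >= 50% of the shorter
protein (thresholds configurable). Accumulation curves enumerate pan and
core cluster counts over all C(G, g) genome combinations, exactly up to
G = 12 and by seeded sampling beyond.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

MIN_IDENTITY = 0.30
MIN_COVERAGE = 0.50
EXHAUSTIVE_MAX_GENOMES = 12

Protein = tuple[str, str, str]  # (strain_id, gene_id, peptide)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def pairwise_protein_identity(a: str, b: str) -> dict[str, float]:
    """Global-alignment identity and coverage between two peptides.

    identity = identical columns / columns where both rows are residues;
    coverage = those columns / length of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("empty peptide")
    aln = _aligner().align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    aligned = ident = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            aligned += 1
            if x == y:
                ident += 1
    return {
        "identity": ident / aligned if aligned else 0.0,
        "coverage": aligned / min(len(a), len(b)),
    }


@dataclass
class ProteinClusterSet:
    """Partition of all proteins into clusters with per-strain presence."""

    strains: list[str]
    clusters: list[dict] = field(default_factory=list)  # {cluster_id, members}

    def presence_matrix(self) -> pd.DataFrame:
        mat = pd.DataFrame(
            False,
            index=[c["cluster_id"] for c in self.clusters],
            columns=self.strains,
        )
        for c in self.clusters:
            for strain, _gene in c["members"]:
                mat.loc[c["cluster_id"], strain] = True
        return mat

    def clusters_of_strain(self, strain: str) -> set[str]:
        return {
            c["cluster_id"]
            for c in self.clusters
            if any(s == strain for s, _ in c["members"])
        }

    def core_cluster_ids(self) -> set[str]:
        all_strains = set(self.strains)
        return {
            c["cluster_id"]
            for c in self.clusters
            if {s for s, _ in c["members"]} == all_strains
        }

    def cluster_of_gene(self, strain: str, gene_id: str) -> str:
        for c in self.clusters:
            if (strain, gene_id) in c["members"]:
                return c["cluster_id"]
        raise KeyError((strain, gene_id))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster_id": c["cluster_id"], "strain": s, "gene_id": g}
            for c in self.clusters
            for s, g in c["members"]
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "strain", "gene_id"])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_proteins(
    proteins: Sequence[Protein],
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
) -> ProteinClusterSet:
    """Single-linkage clustering of proteins across strains.

    Deterministic: items are processed in sorted (strain, gene) order and
    cluster ids are numbered by each cluster's lexicographically smallest
    member. Pairs whose length ratio already caps coverage below the
    threshold are skipped without aligning.
    """
    items = sorted(proteins, key=lambda p: (p[0], p[1]))
    strains = sorted({p[0] for p in items})
    if not strains:
        raise ValueError("no proteins given")
    uf = _UnionFind(len(items))
    for i, j in itertools.combinations(range(len(items)), 2):
        a, b = items[i][2], items[j][2]
        res = pairwise_protein_identity(a, b)
        if res["identity"] >= min_identity and res["coverage"] >= min_coverage:
            uf.union(i, j)
    comps: dict[int, list[Protein]] = {}
    for idx in range(len(items)):
        comps.setdefault(uf.find(idx), []).append(items[idx])
    ordered = sorted(comps.values(), key=lambda ms: (ms[0][0], ms[0][1]))
    clusters = [
        {
            "cluster_id": f"cluster_{k:05d}",
            "members": [(s, g) for s, g, _ in ms],
        }
        for k, ms in enumerate(ordered, 1)
    ]
    return ProteinClusterSet(strains=strains, clusters=clusters)


@dataclass
class AccumulationCurve:
    """Pan/core cluster counts over genome combinations, per subset size."""

    pan: dict[int, list[int]]
    core: dict[int, list[int]]
    exhaustive: bool

    @property
    def n_genomes(self) -> int:
        return max(self.pan)

    def summary(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.pan):
            for name, vals in (("pan", self.pan[g]), ("core", self.core[g])):
                arr = np.asarray(vals)
                rows.append(
                    {
                        "g": g,
                        "set": name,
                        "n_combinations": len(arr),
                        "median": float(np.median(arr)),
                        "q1": float(np.percentile(arr, 25)),
                        "q3": float(np.percentile(arr, 75)),
                        "min": int(arr.min()),
                        "max": int(arr.max()),
                        "mean": float(arr.mean()),
                    }
                )
        return pd.DataFrame(rows)


def accumulation_curves(
    pcs: ProteinClusterSet,
    sample: int | None = None,
    seed: int = 0,
) -> AccumulationCurve:
    """Pan/core sizes for every genome combination at every subset size.

    Exhaustive up to 12 genomes; beyond that an explicit ``sample`` count
    is required (seeded random combinations).
    """
    strains = pcs.strains
    G = len(strains)
    if G > EXHAUSTIVE_MAX_GENOMES and sample is None:
        raise ValueError(
            f"{G} genomes exceeds the exhaustive limit {EXHAUSTIVE_MAX_GENOMES}; "
            "use sampling (pass sample=...)"
        )
    sets = {s: pcs.clusters_of_strain(s) for s in strains}
    rng = np.random.default_rng(seed)
    pan: dict[int, list[int]] = {}
    core: dict[int, list[int]] = {}
    for g in range(1, G + 1):
        if sample is None:
            combos = itertools.combinations(strains, g)
        else:
            combos = (
                tuple(rng.choice(strains, size=g, replace=False)) for _ in range(sample)
            )
        pan[g], core[g] = [], []
        for combo in combos:
            union: set[str] = set()
            inter: set[str] | None = None
            for s in combo:
                union |= sets[s]
                inter = sets[s] if inter is None else inter & sets[s]
            pan[g].append(len(union))
            core[g].append(len(inter or set()))
    return AccumulationCurve(pan=pan, core=core, exhaustive=sample is None)


def pan_increment(curve: AccumulationCurve) -> float:
    """Mean pan-genome growth contributed by the G-th genome:
    mean pan(G) minus mean pan(G-1)."""
    G = curve.n_genomes
    if G < 2:
        raise ValueError("need at least two genomes")
    return float(np.mean(curve.pan[G]) - np.mean(curve.pan[G - 1]))


def reciprocal_best_pairs(
    proteins_a: Mapping[str, str], proteins_b: Mapping[str, str]
) -> list[tuple[str, str]]:
    """Reciprocal-best-identity ortholog pairing between two gene sets.

    (a, b) is reported iff b is a's highest-identity partner and vice
    versa; ties break toward the lexicographically smallest gene id.
    """
    if not proteins_a or not proteins_b:
        return []
    ids_a, ids_b = sorted(proteins_a), sorted(proteins_b)
    ident = {
        (ga, gb): pairwise_protein_identity(proteins_a[ga], proteins_b[gb])["identity"]
        for ga in ids_a
        for gb in ids_b
    }
    # ties break toward the smallest gene id: minimize (-identity, id)
    best_for_a = {
        ga: min(ids_b, key=lambda gb: (-ident[(ga, gb)], gb)) for ga in ids_a
    }
    best_for_b = {
        gb: min(ids_a, key=lambda ga: (-ident[(ga, gb)], ga)) for gb in ids_b
    }
    return [
        (ga, gb)
        for ga, gb in best_for_a.items()
        if best_for_b[gb] == ga
    ]
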