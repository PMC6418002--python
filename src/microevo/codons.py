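"""Genetic-code tables and small nucleotide utilities shared across modules.

Standard genetic code only (translation table 1); the viruses studied here
use the standard code.
"""

from __future__ import annotations

import itertools

NUCLEOTIDES = "ACGT"

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GENETIC_CODE: dict[str, str] = {}
for _c, _aa in zip(
    ("".join(t) for t in itertools.product("TCAG", repeat=3)),
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
):
    GENETIC_CODE[_c] = _aa

STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

# synonymous families keyed by amino acid, stop codons excluded
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(GENETIC_CODE[_c], ())
for _aa in SYNONYMOUS_FAMILIES:
    SYNONYMOUS_FAMILIES[_aa] = tuple(c for c in SENSE_CODONS if GENETIC_CODE[c] == _aa)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True for A<->G or C<->T substitutions."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any ambiguity (N etc.) yields 'X'."""
    return GENETIC_CODE.get(codon.upper(), "X")


def translate(seq: str) -> str:
    """Translate in frame +1, truncating a trailing partial codon; stops as '*'."""
    n = len(seq) - len(seq) % 3
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, n, 3))


def split_codons(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]
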