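"""Large-scale structural features: dotplot collinearity, terminal
palindrome, and TIR-flanked (hAT-style) transposon candidates.

Everything here is exact-word based: shared words between the two
sequences (both orientations) merged into collinear segments; a terminal
palindrome is the longest prefix whose first half matches the reverse
complement of its second half within a mismatch budget; a transposon
candidate is an interval flanked by terminal inverted repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


@dataclass
class MatchSegment:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # "direct" | "inverted"
    word: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


def dotplot_matches(seq_a: str, seq_b: str, word: int = 15) -> list[MatchSegment]:
    """All exact shared words in both orientations, merged into maximal
    collinear segments on the same (anti)diagonal."""
    if word < 8:
        raise ValueError("word length must be >= 8")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - word + 1):
        index.setdefault(seq_a[i : i + word], []).append(i)

    direct: dict[int, list[int]] = {}  # diagonal j-i -> sorted a-starts
    inverted: dict[int, list[int]] = {}  # antidiagonal i+j -> a-starts
    rc_b = revcomp(seq_b)
    nb = len(seq_b)
    for j in range(nb - word + 1):
        w = seq_b[j : j + word]
        for i in index.get(w, ()):
            direct.setdefault(j - i, []).append(i)
        wrc = rc_b[j : j + word]  # forward match in rc(B): inverted in B
        for i in index.get(wrc, ()):
            # position in B of the inverted match: B[nb-j-word : nb-j]
            b_start = nb - j - word
            inverted.setdefault(i + b_start, []).append(i)

    segments: list[MatchSegment] = []
    for diag, starts in direct.items():
        for run_s, run_e in _merge_runs(sorted(set(starts)), word):
            segments.append(
                MatchSegment(run_s, run_e + word, run_s + diag, run_e + word + diag, "direct", word)
            )
    for anti, starts in inverted.items():
        for run_s, run_e in _merge_runs(sorted(set(starts)), word):
            # a in [run_s, run_e+word); matching b interval mirrors on the antidiagonal
            segments.append(
                MatchSegment(
                    run_s,
                    run_e + word,
                    anti - run_e,
                    anti - run_s + word,
                    "inverted",
                    word,
                )
            )
    segments.sort(key=lambda s: (s.a_start, s.b_start, s.orientation))
    return segments


def _merge_runs(starts: list[int], word: int) -> list[tuple[int, int]]:
    """Merge word-start positions within ``word`` of each other into runs;
    returns (first_start, last_start) pairs."""
    runs: list[tuple[int, int]] = []
    for s in starts:
        if runs and s - runs[-1][1] <= word:
            runs[-1] = (runs[-1][0], s)
        else:
            runs.append((s, s))
    return runs


def find_terminal_palindrome(
    seq: str,
    search_window: int = 50_000,
    min_len: int = 1000,
    max_mismatch_frac: float = 0.05,
) -> tuple[int, int] | None:
    """Longest even-length prefix [0, 2h) whose first half matches the
    reverse complement of its second half within the mismatch budget."""
    from scipy.signal import fftconvolve

    x = _encode(seq[: min(len(seq), search_window)])
    comp = np.full(256, 255, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    z = comp[x]
    h_max = len(x) // 2
    h_min = max(1, min_len // 2)
    if h_min > h_max:
        return None
    # the prefix [0, 2h) is palindromic iff seq[k] pairs with comp(seq[2h-1-k]);
    # the number of matching pairs for every h at once is a correlation of the
    # per-base indicator channels, evaluated at lag 2h-1 (each pair counted twice)
    corr = np.zeros(2 * len(x) - 1)
    for c in b"ACGT":
        a_ind = (x == c).astype(np.float64)
        b_ind = (z == c).astype(np.float64)
        corr += fftconvolve(a_ind, b_ind)
    hs = np.arange(h_min, h_max + 1)
    matches = np.rint(corr[2 * hs - 1] / 2.0)
    mismatches = hs - matches
    passing = hs[mismatches <= max_mismatch_frac * hs]
    if passing.size == 0:
        return None
    h = int(passing.max())
    return (0, 2 * h)


@dataclass
class TransposonCandidate:
    start: int
    end: int
    tir_length: int
    tir_mismatches: int
    cargo_gene_ids: list[str]

    @property
    def length(self) -> int:
        return self.end - self.start


def _verify_tir(seq: str, start: int, end: int, L: int) -> int:
    """Mismatch count between the left TIR and the revcomp of the right TIR."""
    left = seq[start : start + L]
    right_rc = revcomp(seq[end - L : end])
    return sum(a != b for a, b in zip(left, right_rc))


def find_tir_segments(
    seq: str,
    tir_min: int = 15,
    tir_max_mismatch: int = 2,
    seg_min: int = 2000,
    seg_max: int = 15000,
    seed_word: int = 8,
    annotation=None,
) -> list[TransposonCandidate]:
    """Intervals [i, j) whose termini are inverted repeats of each other.

    Seeded by exact shared ``seed_word``-mers between the sequence and its
    reverse complement at a separation within [seg_min, seg_max]; each seed
    is extended greedily under the mismatch budget. Overlapping candidates
    resolve by longest TIR, then leftmost. If an annotation is supplied,
    cargo gene ids are CDS features contained in the interval.
    """
    seq = seq.upper()
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - seed_word + 1):
        index.setdefault(seq[i : i + seed_word], []).append(i)

    raw: list[tuple[int, int, int, int]] = []  # (start, end, tir_len, mism)
    seen: set[tuple[int, int]] = set()
    rc = revcomp(seq)
    for p in range(n - seed_word + 1):
        w = rc[p : p + seed_word]
        # rc[p:p+k] corresponds to seq[n-p-k : n-p]
        right_end = n - p
        for i in index.get(w, ()):
            if i >= right_end:
                continue
            span = right_end - i
            if not (seg_min <= span <= seg_max):
                continue
            # extend the inverted repeat outward/inward from the seed
            L, mism = _extend_ir(seq, i, right_end, seed_word, tir_max_mismatch)
            if L < tir_min:
                continue
            key = (i, right_end)
            if key in seen:
                continue
            seen.add(key)
            raw.append((i, right_end, L, mism))

    raw.sort(key=lambda t: (-t[2], t[0]))
    chosen: list[tuple[int, int, int, int]] = []
    for cand in raw:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda t: t[0])

    out = []
    for start, end, L, mism in chosen:
        cargo: list[str] = []
        if annotation is not None:
            cargo = [
                f.feature_id
                for f in annotation.cds_features(include_pseudogenized=True)
                if f.start >= start and f.end <= end
            ]
        out.append(TransposonCandidate(start, end, L, mism, cargo))
    return out


def _extend_ir(
    seq: str, start: int, end: int, seed: int, budget: int
) -> tuple[int, int]:
    """Grow the terminal inverted repeat inward from a seed anchored at the
    segment termini; returns (length, mismatches)."""
    L = seed
    mism = _verify_tir(seq, start, end, L)
    best = (L, mism) if mism <= budget else (0, 0)
    limit = (end - start) // 2
    while L < limit:
        a = seq[start + L]
        b = revcomp(seq[end - L - 1])
        L += 1
        if a != b:
            mism += 1
            if mism > budget:
                break
        best = (L, mism)
    return best
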