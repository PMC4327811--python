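"""Spaced-word extraction and match counting.

The central statistic is N, the number of *P-matches* between two
sequences summed over a pattern set: a P-match at (i, j) means the two
windows starting at i in S1 and j in S2 agree at every match position of
P.  N equals the inner product of the per-pattern spaced-word count
vectors of the two sequences, so it is computed in O((L1+L2)*m*k) by
projecting every window to its length-k spaced word and aggregating in
hash tables — never by scanning position pairs.

A *binary* variant counts each spaced-word type once per pattern,
regardless of how often it occurs: repeats then contribute a single
shared word instead of a product of their copy numbers, which makes the
downstream distance estimator robust to repetitive sequences.

Windows whose match positions touch a non-ACGT character (N runs,
ambiguity codes) contribute no spaced word; the number of valid window
start positions per pattern is recorded so the model layer can use it as
the effective (L - l + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .patterns import Pattern, PatternSet

__all__ = [
    "DnaSequence",
    "MatchCounts",
    "SequenceError",
    "spaced_word_at",
    "count_matches",
    "count_matches_rc",
    "brute_force_count",
    "list_matches",
    "reverse_complement",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")

# byte -> 2-bit code for A/C/G/T, 255 for anything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_BRUTE_FORCE_GUARD = 10**7


class SequenceError(ValueError):
    """Raised for invalid nucleotide sequences or window coordinates."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated, uppercased nucleotide sequence with an identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        foreign = set(self.residues) - _IUPAC
        if foreign:
            raise SequenceError(
                f"sequence {self.id!r} contains non-IUPAC characters "
                f"{sorted(foreign)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """2-bit codes (A=0, C=1, G=2, T=3), 255 for ambiguity letters."""
        raw = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return _CODE[raw]


def reverse_complement(seq: DnaSequence) -> DnaSequence:
    """Reverse-complement, mapping ambiguity codes to their IUPAC complements."""
    return DnaSequence(seq.id, str(Seq(seq.residues).reverse_complement()))


@dataclass(frozen=True)
class MatchCounts:
    """Per-pattern and total spaced-word match counts for a sequence pair.

    ``valid_starts1``/``valid_starts2`` record, per pattern, how many
    window start positions in each sequence yielded a valid spaced word
    (i.e. no ambiguity character under a match position); for pure-ACGT
    sequences this is exactly L - l + 1.  In reverse-complement mode the
    start counts refer to the forward strands.
    """

    per_pattern: dict[Pattern, int]
    mode: str  # "full" | "binary"
    rc_mode: bool = False
    valid_starts1: dict[Pattern, int] = field(default_factory=dict)
    valid_starts2: dict[Pattern, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        """Total match count over all patterns."""
        return sum(self.per_pattern.values())


def spaced_word_at(seq: DnaSequence, i: int, pattern: Pattern) -> str | None:
    """The spaced word of ``pattern`` starting at 1-based position ``i``.

    Returns the length-k projection of the window onto the match
    positions, or ``None`` if any projected character is not one of
    A/C/G/T.  Raises for out-of-range ``i``.
    """
    n_windows = len(seq) - pattern.length + 1
    if not 1 <= i <= n_windows:
        raise SequenceError(
            f"window start {i} out of range 1..{n_windows} for sequence "
            f"{seq.id!r} (L={len(seq)}) and pattern length {pattern.length}"
        )
    word = "".join(seq.residues[i + pos - 2] for pos in pattern.match_positions)
    return word if set(word) <= set("ACGT") else None


def _word_codes(enc: np.ndarray, pattern: Pattern) -> np.ndarray:
    """Integer codes of the valid spaced words of one pattern, per window."""
    n = enc.shape[0] - pattern.length + 1
    if n < 1:
        raise SequenceError(
            f"sequence of length {enc.shape[0]} shorter than pattern "
            f"length {pattern.length}"
        )
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for off in pattern.offsets:
        c = enc[off : off + n]
        valid &= c != 255
        codes = (codes << np.uint64(2)) | c.astype(np.uint64)
    return codes[valid]


def _pair_count(codes1: np.ndarray, codes2: np.ndarray, mode: str) -> int:
    u1, c1 = np.unique(codes1, return_counts=True)
    u2, c2 = np.unique(codes2, return_counts=True)
    _, i1, i2 = np.intersect1d(u1, u2, assume_unique=True, return_indices=True)
    if mode == "binary":
        return int(i1.shape[0])
    return int(np.sum(c1[i1] * c2[i2]))


def _check_mode(mode: str) -> None:
    if mode not in ("full", "binary"):
        raise ValueError(f"mode must be 'full' or 'binary', got {mode!r}")


def count_matches(
    s1: DnaSequence, s2: DnaSequence, pset: PatternSet, mode: str = "full"
) -> MatchCounts:
    """Count spaced-word matches between ``s1`` and ``s2``.

    In ``full`` mode the per-pattern count is the number of position
    pairs (i, j) with a P-match, computed as the inner product
    sum_w c1(w) * c2(w) of the spaced-word occurrence counts.  In
    ``binary`` mode it is the number of distinct spaced words occurring
    at least once in both sequences.
    """
    _check_mode(mode)
    for s in (s1, s2):
        if len(s) < pset.length:
            raise SequenceError(
                f"sequence {s.id!r} (L={len(s)}) is shorter than the pattern "
                f"length {pset.length}"
            )
    enc1, enc2 = s1.encoded(), s2.encoded()
    per_pattern: dict[Pattern, int] = {}
    v1: dict[Pattern, int] = {}
    v2: dict[Pattern, int] = {}
    for p in pset:
        codes1 = _word_codes(enc1, p)
        codes2 = _word_codes(enc2, p)
        v1[p] = codes1.shape[0]
        v2[p] = codes2.shape[0]
        per_pattern[p] = _pair_count(codes1, codes2, mode)
    return MatchCounts(per_pattern, mode, False, v1, v2)


def count_matches_rc(
    s1: DnaSequence, s2: DnaSequence, pset: PatternSet, mode: str = "full"
) -> MatchCounts:
    """Strand-aware match count: S1 against both strands of S2.

    Forward and reverse-complement counts are computed separately and
    combined (full mode: summed; binary mode: a word is shared if it
    occurs in S1 and on either strand of S2), which avoids the artifact
    windows a literal concatenation of S2 with its reverse complement
    would create at the junction.
    """
    _check_mode(mode)
    for s in (s1, s2):
        if len(s) < pset.length:
            raise SequenceError(
                f"sequence {s.id!r} (L={len(s)}) is shorter than the pattern "
                f"length {pset.length}"
            )
    s2rc = reverse_complement(s2)
    enc1, enc2f, enc2r = s1.encoded(), s2.encoded(), s2rc.encoded()
    per_pattern: dict[Pattern, int] = {}
    v1: dict[Pattern, int] = {}
    v2: dict[Pattern, int] = {}
    for p in pset:
        codes1 = _word_codes(enc1, p)
        codes2f = _word_codes(enc2f, p)
        codes2r = _word_codes(enc2r, p)
        v1[p] = codes1.shape[0]
        v2[p] = codes2f.shape[0]
        if mode == "full":
            per_pattern[p] = _pair_count(codes1, codes2f, "full") + _pair_count(
                codes1, codes2r, "full"
            )
        else:
            both = np.union1d(codes2f, codes2r)
            per_pattern[p] = _pair_count(codes1, both, "binary")
    return MatchCounts(per_pattern, mode, True, v1, v2)


def list_matches(
    s1: DnaSequence, s2: DnaSequence, pattern: Pattern
) -> list[tuple[int, int]]:
    """All 1-based position pairs (i, j) with a P-match, by exhaustive scan.

    Quadratic; intended for worked examples and as a test oracle.
    """
    if len(s1) * len(s2) > _BRUTE_FORCE_GUARD:
        raise SequenceError(
            f"exhaustive scan refused: L1*L2 = {len(s1) * len(s2)} exceeds "
            f"the guard {_BRUTE_FORCE_GUARD}"
        )
    acgt = set("ACGT")
    n1 = len(s1) - pattern.length + 1
    n2 = len(s2) - pattern.length + 1
    out: list[tuple[int, int]] = []
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            ok = True
            for pos in pattern.match_positions:
                a = s1.residues[i + pos - 2]
                b = s2.residues[j + pos - 2]
                if a != b or a not in acgt:
                    ok = False
                    break
            if ok:
                out.append((i, j))
    return out


def brute_force_count(
    s1: DnaSequence, s2: DnaSequence, pset: PatternSet, mode: str = "full"
) -> MatchCounts:
    """Quadratic-time oracle realizing the match indicators directly.

    Full mode enumerates every position pair (i, j) and compares
    characters at the match positions; binary mode intersects the sets
    of spaced-word strings extracted from each sequence.  Guarded to
    small inputs; must agree with :func:`count_matches` everywhere.
    """
    _check_mode(mode)
    if len(s1) * len(s2) > _BRUTE_FORCE_GUARD:
        raise SequenceError(
            f"brute force refused: L1*L2 = {len(s1) * len(s2)} exceeds "
            f"the guard {_BRUTE_FORCE_GUARD}"
        )
    per_pattern: dict[Pattern, int] = {}
    v1: dict[Pattern, int] = {}
    v2: dict[Pattern, int] = {}
    for p in pset:
        words1 = [
            spaced_word_at(s1, i, p) for i in range(1, len(s1) - p.length + 2)
        ]
        words2 = [
            spaced_word_at(s2, j, p) for j in range(1, len(s2) - p.length + 2)
        ]
        v1[p] = sum(w is not None for w in words1)
        v2[p] = sum(w is not None for w in words2)
        if mode == "full":
            per_pattern[p] = len(list_matches(s1, s2, p))
        else:
            shared = {w for w in words1 if w is not None} & {
                w for w in words2 if w is not None
            }
            per_pattern[p] = len(shared)
    return MatchCounts(per_pattern, mode, False, v1, v2)
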