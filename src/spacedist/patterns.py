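"""Binary match/don't-care patterns for spaced-word matching.

A *pattern* is a word over ``{0,1}``: a ``1`` marks a *match position*
(where two sequences must agree), a ``0`` a *don't-care position* (which
is ignored).  The number of match positions is the pattern's *weight* k;
its total length is l.  A spaced word is the projection of a sequence
window onto the match positions of a pattern.

Patterns are kept in a canonical form whose first character is ``1``: a
leading don't-care would merely shift every occurrence by a constant and
generate duplicate-equivalent patterns.  Trailing don't-cares are
allowed; they change l and hence the number of valid window start
positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from math import comb
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Pattern",
    "PatternSet",
    "PatternError",
    "parse_pattern",
    "random_pattern_set",
    "n_overlap",
    "load_patterns",
    "save_patterns",
]


class PatternError(ValueError):
    """Raised when a pattern or pattern set violates its constraints."""


@dataclass(frozen=True)
class Pattern:
    """A binary match/don't-care mask.

    Parameters
    ----------
    text : str
        The mask as a string over ``{0,1}``, e.g. ``"1101"``.  Must be
        nonempty, contain at least one ``1`` and start with ``1``.
    """

    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise PatternError("pattern text must be nonempty")
        if set(self.text) - {"0", "1"}:
            raise PatternError(
                f"pattern text must contain only '0'/'1', got {self.text!r}"
            )
        if "1" not in self.text:
            raise PatternError("pattern must have at least one match position")
        if self.text[0] != "1":
            raise PatternError(
                "pattern must start with a match position (canonical form); "
                f"got {self.text!r}"
            )

    @property
    def length(self) -> int:
        """Total pattern length l."""
        return len(self.text)

    @property
    def weight(self) -> int:
        """Number of match positions k."""
        return self.text.count("1")

    @cached_property
    def match_positions(self) -> tuple[int, ...]:
        """1-based positions of the match positions, sorted ascending."""
        return tuple(i + 1 for i, c in enumerate(self.text) if c == "1")

    @cached_property
    def offsets(self) -> tuple[int, ...]:
        """0-based offsets of the match positions (for array indexing)."""
        return tuple(i for i, c in enumerate(self.text) if c == "1")

    @property
    def is_contiguous(self) -> bool:
        return self.weight == self.length

    def __str__(self) -> str:
        return self.text


def parse_pattern(text: str) -> Pattern:
    """Parse a binary string such as ``"1101"`` into a :class:`Pattern`."""
    return Pattern(text)


@dataclass(frozen=True)
class PatternSet:
    """An ordered set of pairwise-distinct patterns sharing one (l, k).

    All patterns must have the same length and the same weight; the
    closed-form expectation and variance of the match count N assume
    this.
    """

    patterns: tuple[Pattern, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise PatternError("pattern set must be nonempty")
        object.__setattr__(self, "patterns", tuple(self.patterns))
        lengths = {p.length for p in self.patterns}
        weights = {p.weight for p in self.patterns}
        if len(lengths) > 1 or len(weights) > 1:
            raise PatternError(
                "all patterns in a set must share the same length and weight; "
                f"got lengths {sorted(lengths)} and weights {sorted(weights)}"
            )
        if len({p.text for p in self.patterns}) != len(self.patterns):
            raise PatternError("patterns in a set must be pairwise distinct")

    @property
    def m(self) -> int:
        """Number of patterns."""
        return len(self.patterns)

    @property
    def length(self) -> int:
        return self.patterns[0].length

    @property
    def weight(self) -> int:
        return self.patterns[0].weight

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, i: int) -> Pattern:
        return self.patterns[i]


def random_pattern_set(
    weight: int, length: int, m: int, seed: int | None = None
) -> PatternSet:
    """Draw ``m`` distinct random patterns of the given weight and length.

    Each pattern has position 1 as a match position; the remaining
    ``weight - 1`` match positions are drawn uniformly without
    replacement from positions 2..length.  Duplicates are rejected and
    redrawn so the set is pairwise distinct.  The same seed always
    yields the same set.
    """
    if weight < 1:
        raise PatternError("weight must be >= 1")
    if weight > length:
        raise PatternError(f"weight {weight} exceeds pattern length {length}")
    n_canonical = comb(length - 1, weight - 1)
    if not 1 <= m <= n_canonical:
        raise PatternError(
            f"cannot draw {m} distinct canonical patterns of weight {weight} "
            f"and length {length}; only {n_canonical} exist"
        )
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    patterns: list[Pattern] = []
    while len(patterns) < m:
        free = rng.choice(np.arange(1, length), size=weight - 1, replace=False)
        mask = np.zeros(length, dtype=np.uint8)
        mask[0] = 1
        mask[free] = 1
        text = "".join("1" if b else "0" for b in mask)
        if text not in seen:
            seen.add(text)
            patterns.append(Pattern(text))
    return PatternSet(tuple(patterns), seed=seed)


def n_overlap(p: Pattern, p_prime: Pattern, s: int) -> int:
    """Size of the union of p's match positions with p'-shifted-by-s's.

    ``n(P, P', s) = |P-hat  U  P'-hat + s|`` counts the sequence
    positions constrained when the windows of P and of P' shifted s
    positions to the right overlap; it governs the covariance between
    the corresponding spaced-word match indicators.  Negative shifts are
    allowed and satisfy ``n(P, P', -s) == n(P', P, s)``.
    """
    shifted = {pos + s for pos in p_prime.match_positions}
    return len(set(p.match_positions) | shifted)


def load_patterns(path: str | Path) -> PatternSet:
    """Read a pattern set from a plain-text file, one binary string per line."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise PatternError(f"no patterns found in {path}")
    return PatternSet(tuple(Pattern(ln) for ln in lines))


def save_patterns(pset: PatternSet | Sequence[Pattern], path: str | Path) -> None:
    """Write patterns to a plain-text file, one binary string per line."""
    Path(path).write_text("".join(f"{p.text}\n" for p in pset))
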