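"""Model-based evolutionary distances from spaced-word match counts.

Under a gap-free model with independent sites, uniform substitution
rates and match probability p at homologous positions (q = sum_a q_a^2
at background positions), the expected total match count for a pattern
set of m patterns with common length l and weight k over sequences of
length L is

    E(N) = m * [ (L - l + 1) * p^k  +  (L - l) * (L - l + 1) * q^k ].

Inverting this gives an estimator of p,

    p_hat = ( N / (m * (L - l + 1))  -  (L - l) * q^k )^(1/k),

and the Jukes-Cantor transform d = -(3/4) * ln((4/3) * p_hat - 1/3)
turns p_hat into substitutions per site.  Variants cover a single local
homology of known length (d_loc), homologies on either strand via
reverse-complement counting (d_RC), and repeat-robust binary counts
(each shared spaced-word type counted once).

The variance of N follows from the covariances of overlapping match
indicators: two windows shifted by s share n(P, P', s) constrained
positions, so

    Var(N) ~ (L-l+1)     * sum_{P,P'} sum_s (p^n(P,P',s) - p^2k)
           + (L-l+1)(L-l) * sum_{P,P'} sum_s (q^n(P,P',s) - q^2k),

with s ranging over -l+1 .. l-1 and (P, P') over ordered pairs.  The
derivation assumes uniform nucleotide composition (q = 0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .counting import (
    DnaSequence,
    MatchCounts,
    count_matches,
    count_matches_rc,
)
from .patterns import PatternSet, n_overlap

__all__ = [
    "EvoModelParams",
    "DistanceResult",
    "background_q",
    "expected_N",
    "estimate_p",
    "jc_distance",
    "jc_match_probability",
    "distance_dN",
    "distance_dloc",
    "distance_dRC",
    "variance_N",
    "variance_N_normalized",
]

#: statuses a distance computation can end in
STATUS_OK = "ok"
STATUS_RADICAND = "radicand_nonpositive"
STATUS_JC = "jc_domain_violation"
STATUS_SATURATED = "saturated"


@dataclass
class EvoModelParams:
    """Closed-form model parameters.

    ``L`` is the common length for the global model; ``L1 <= L2`` the
    two lengths for the strand-aware (rc) model; ``L_hom`` the homology
    length for the local model.  Lengths may be non-integral because the
    counting layer substitutes per-pattern effective window counts for
    L - l + 1 when sequences contain ambiguity characters.
    """

    p: float | None = None
    q: float = 0.25
    k: int = 9
    length: int = 15  # pattern length l
    m: int = 1
    L: float | None = None
    L1: float | None = None
    L2: float | None = None
    L_hom: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"background match probability q={self.q} not in (0,1]")
        if self.p is not None and not self.q <= self.p <= 1.0:
            raise ValueError(
                f"homologous match probability p={self.p} must satisfy "
                f"q <= p <= 1 (q={self.q})"
            )

    @property
    def L_star(self) -> float:
        """Background position count of the local model."""
        if self.L1 is None or self.L2 is None or self.L_hom is None:
            raise ValueError("L1, L2 and L_hom are required for the local model")
        ell = self.length
        return (self.L1 - ell + 1) * (self.L2 - ell + 1) - self.L_hom


@dataclass
class DistanceResult:
    """An estimated distance with its diagnostics.

    ``d`` is in substitutions per site and ``None`` unless status is
    ``ok`` or ``saturated``; ``saturated`` means the estimated match
    probability exceeded 1 and was capped (d = 0), while
    ``radicand_nonpositive`` / ``jc_domain_violation`` mark pairs whose
    match count is indistinguishable from (or below) background.
    """

    d: float | None
    p_hat: float | None
    N_used: int
    mode: str  # e.g. "dN/full", "dRC/binary"
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def background_q(frequencies: Iterable[float] | None = None, fixed: float | None = None) -> float:
    """Background match probability q = sum_a q_a^2.

    Either pass nucleotide ``frequencies`` (must sum to 1) or a
    ``fixed`` constant, which is returned unchanged.
    """
    if fixed is not None:
        return float(fixed)
    if frequencies is None:
        raise ValueError("either frequencies or fixed must be given")
    f = np.asarray(list(frequencies), dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {f.sum()!r}")
    return float(np.sum(f**2))


def expected_N(params: EvoModelParams, model: str = "global") -> float:
    """Expected total spaced-word match count under the chosen model."""
    p, q, k, ell, m = params.p, params.q, params.k, params.length, params.m
    if p is None:
        raise ValueError("p is required to evaluate E(N)")
    if model == "global":
        if params.L is None:
            raise ValueError("L is required for the global model")
        L = params.L
        return m * ((L - ell + 1) * p**k + (L - ell) * (L - ell + 1) * q**k)
    if model == "rc":
        if params.L1 is None or params.L2 is None:
            raise ValueError("L1 and L2 are required for the rc model")
        return m * (
            (params.L1 - ell + 1) * p**k
            + 2 * (params.L1 - ell + 1) * (params.L2 - ell) * q**k
        )
    if model == "local":
        if params.L_hom is None:
            raise ValueError("L_hom is required for the local model")
        return m * ((params.L_hom - ell + 1) * p**k + params.L_star * q**k)
    raise ValueError(f"unknown model {model!r}")


def _root_k(radicand: float, k: int) -> tuple[float | None, str]:
    """Real k-th root on the strictly positive branch, with status."""
    if radicand <= 0:
        return None, STATUS_RADICAND
    p_hat = math.exp(math.log(radicand) / k)
    if p_hat > 1.0:
        return 1.0, STATUS_SATURATED
    return p_hat, STATUS_OK


def estimate_p(N: float, params: EvoModelParams, model: str = "global") -> tuple[float | None, str]:
    """Estimate the homologous match probability p from a match count.

    Global model (equal lengths, same strand):
    ``p_hat = (N / (m (L1 - l + 1)) - (L2 - l) q^k)^(1/k)``; with equal
    lengths L1 = L2 = L this is the exact inverse of E(N).  For unequal
    lengths the homologous term uses the shorter sequence and the
    background term the longer one.  The rc model doubles the
    background term to account for both strands of S2.

    Returns ``(p_hat, status)``: status ``radicand_nonpositive`` (p_hat
    None) when the background-corrected count is nonpositive, and
    ``saturated`` (p_hat capped at 1) when the root exceeds 1.
    """
    q, k, ell, m = params.q, params.k, params.length, params.m
    if model in ("global", "rc"):
        L1 = params.L1 if params.L1 is not None else params.L
        L2 = params.L2 if params.L2 is not None else params.L
        if L1 is None or L2 is None:
            raise ValueError("sequence lengths are required to estimate p")
        if L1 > L2:
            L1, L2 = L2, L1
        bg_factor = 2.0 if model == "rc" else 1.0
        radicand = N / (m * (L1 - ell + 1)) - bg_factor * (L2 - ell) * q**k
        return _root_k(radicand, k)
    if model == "local":
        if params.L_hom is None:
            raise ValueError("L_hom is required for the local model")
        radicand = (N / m - params.L_star * q**k) / (params.L_hom - ell + 1)
        return _root_k(radicand, k)
    raise ValueError(f"unknown model {model!r}")


def jc_distance(p_hat: float) -> tuple[float | None, str]:
    """Jukes-Cantor distance from a match probability.

    ``d = -(3/4) ln((4/3) p_hat - 1/3)``, defined for p_hat > 1/4; at or
    below 1/4 the sequences are saturated and the distance undefined.
    """
    if p_hat <= 0.25:
        return None, STATUS_JC
    return -0.75 * math.log(4.0 / 3.0 * p_hat - 1.0 / 3.0), STATUS_OK


def jc_match_probability(d: float) -> float:
    """Match probability at Jukes-Cantor distance d: 1/4 + 3/4 e^(-4d/3)."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


def _mean(values: Iterable[float]) -> float:
    vals = list(values)
    return sum(vals) / len(vals)


def _effective_lengths(counts: MatchCounts) -> tuple[float, float]:
    """Mean valid window counts, ordered (shorter, longer)."""
    e1 = _mean(counts.valid_starts1.values())
    e2 = _mean(counts.valid_starts2.values())
    return (e1, e2) if e1 <= e2 else (e2, e1)


def _finish(
    N: float, params: EvoModelParams, model: str, mode_label: str
) -> DistanceResult:
    p_hat, status = estimate_p(N, params, model)
    if p_hat is None:
        return DistanceResult(None, None, int(N), mode_label, status)
    d, jc_status = jc_distance(p_hat)
    if d is None:
        return DistanceResult(None, p_hat, int(N), mode_label, jc_status)
    final = STATUS_SATURATED if status == STATUS_SATURATED else STATUS_OK
    return DistanceResult(d, p_hat, int(N), mode_label, final)


def distance_dN(
    s1: DnaSequence,
    s2: DnaSequence,
    pset: PatternSet,
    mode: str = "full",
    q: float = 0.25,
) -> DistanceResult:
    """Global-homology distance d_N (same strand, whole sequences).

    Counts spaced-word matches, corrects for the expected background
    count, and applies the Jukes-Cantor transform.  ``mode='binary'``
    uses the repeat-robust count of distinct shared spaced words.
    Window counts with ambiguity characters excluded stand in for
    L - l + 1.
    """
    counts = count_matches(s1, s2, pset, mode)
    eff1, eff2 = _effective_lengths(counts)
    params = EvoModelParams(
        q=q, k=pset.weight, length=pset.length, m=pset.m,
        L1=eff1 + pset.length - 1, L2=eff2 + pset.length - 1,
    )
    return _finish(counts.N, params, "global", f"dN/{mode}")


def distance_dRC(
    s1: DnaSequence,
    s2: DnaSequence,
    pset: PatternSet,
    mode: str = "full",
    q: float = 0.25,
) -> DistanceResult:
    """Strand-aware distance d_RC: matches against both strands of S2,
    with the background term doubled accordingly."""
    counts = count_matches_rc(s1, s2, pset, mode)
    eff1, eff2 = _effective_lengths(counts)
    params = EvoModelParams(
        q=q, k=pset.weight, length=pset.length, m=pset.m,
        L1=eff1 + pset.length - 1, L2=eff2 + pset.length - 1,
    )
    return _finish(counts.N, params, "rc", f"dRC/{mode}")


def distance_dloc(
    s1: DnaSequence,
    s2: DnaSequence,
    pset: PatternSet,
    L_hom: float,
    mode: str = "full",
    q: float = 0.25,
) -> DistanceResult:
    """Local-homology distance d_loc for a shared region of known length.

    The background position count is L* = (L1-l+1)(L2-l+1) - L_hom and
    the homologous term spans L_hom - l + 1 windows.
    """
    ell = pset.length
    if not ell <= L_hom <= min(len(s1), len(s2)):
        raise ValueError(
            f"L_hom={L_hom} must lie between the pattern length {ell} and "
            f"the shorter sequence length {min(len(s1), len(s2))}"
        )
    counts = count_matches(s1, s2, pset, mode)
    eff1, eff2 = _effective_lengths(counts)
    params = EvoModelParams(
        q=q, k=pset.weight, length=ell, m=pset.m,
        L1=eff1 + ell - 1, L2=eff2 + ell - 1, L_hom=L_hom,
    )
    return _finish(counts.N, params, "local", f"dloc/{mode}")


def variance_N(p: float, q: float, pset: PatternSet, L: float) -> float:
    """Analytic variance of the total match count N (gap-free, uniform
    composition).

    Sums the covariances of match indicators over ordered pattern pairs
    (P, P') and window shifts s in [-l+1, l-1], using the overlap count
    n(P, P', s); the homologous term scales with L - l + 1, the
    background term with (L - l + 1)(L - l).
    """
    if not 0.0 < q <= p <= 1.0:
        raise ValueError(f"require 0 < q <= p <= 1, got p={p}, q={q}")
    ell, k = pset.length, pset.weight
    hom = 0.0
    bg = 0.0
    for pa in pset:
        for pb in pset:
            for s in range(-ell + 1, ell):
                n = n_overlap(pa, pb, s)
                hom += p**n - p ** (2 * k)
                bg += q**n - q ** (2 * k)
    return (L - ell + 1) * hom + (L - ell + 1) * (L - ell) * bg


def variance_N_normalized(p: float, q: float, pset: PatternSet, L: float) -> float:
    """Variance of the normalized count N/m."""
    return variance_N(p, q, pset, L) / pset.m**2
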