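"""Reproductive-isolation index formulas.

All functions here operate on pure numbers and are independent of data
ingestion.  The central quantity is the RI index

    RI = 1 - 2 * H / (H + C)

where ``C`` is conspecific and ``H`` heterospecific reproductive success
(counts, rates or proportions — the index is scale-invariant).  RI = 1
means complete isolation (no heterospecific success), RI = 0 no isolation
(equal success), and negative values indicate heterospecific advantage.

Phenological isolation uses the one-sided variant

    RI_pheno = 1 - S / (S + U)

with ``S`` and ``U`` the shared and unshared proportions of the focal
species' flowering time, so RI_pheno lies in [0, 1].

Per-barrier indices combine sequentially: each barrier only acts on what
earlier barriers let through,

    RI[1,i] = RI[1,i-1] + RI_i * (1 - RI[1,i-1]),

and each barrier's absolute contribution to total isolation is the
telescoping difference AC_i = RI[1,i] - RI[1,i-1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import UndefinedConstancyError, UndefinedIndexError

#: Canonical life-cycle order of the six barriers handled by the cascade.
BARRIER_ORDER = ("phenology", "ethological", "style", "ovary", "fruit", "seed")

#: Barrier labels legal on a BarrierCounts record (post-phenology stages).
COUNT_BARRIERS = ("ethological", "style", "ovary", "fruit", "seed")


@dataclass(frozen=True)
class BarrierCounts:
    """Conspecific (C) and heterospecific (H) success for one barrier
    and one cross direction (maternal species, paternal species)."""

    conspecific_C: float
    heterospecific_H: float
    barrier_label: str = "ethological"
    direction: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.conspecific_C < 0 or self.heterospecific_H < 0:
            raise ValueError(
                f"counts must be non-negative, got C={self.conspecific_C}, "
                f"H={self.heterospecific_H}"
            )
        if self.barrier_label not in COUNT_BARRIERS:
            raise ValueError(
                f"unknown barrier label {self.barrier_label!r}; "
                f"expected one of {COUNT_BARRIERS}"
            )


@dataclass(frozen=True)
class PhenologyOverlap:
    """Shared (S) and unshared (U) flowering proportions of a focal
    species relative to a partner species."""

    shared_S: float
    unshared_U: float
    focal_species: str = "focal"
    partner_species: str = "partner"

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_S <= 1.0 and 0.0 <= self.unshared_U <= 1.0):
            raise ValueError(
                f"S and U must lie in [0, 1], got S={self.shared_S}, U={self.unshared_U}"
            )


@dataclass(frozen=True)
class ConstancyInputs:
    """Inputs of the constancy index: c is the observed proportion of
    conspecific (intraspecific) transitions, p the proportion of visits
    to one of the two array species.  The random-foraging expectation is
    e = p^2 + (1-p)^2, which lies in [1/2, 1]."""

    c: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError(f"c and p must lie in [0, 1], got c={self.c}, p={self.p}")

    @property
    def e(self) -> float:
        return self.p * self.p + (1.0 - self.p) * (1.0 - self.p)


@dataclass(frozen=True)
class TotalRIInputs:
    """Components of the flowering-weighted total RI: end-to-end
    heterospecific/conspecific success during the shared (Hs, Cs) and
    unshared (Hu, Cu) flowering periods, weighted by S and U.

    By default Hu = 0: a partner species cannot sire seed outside the
    period in which it flowers."""

    S: float
    U: float
    Hs: float
    Cs: float
    Hu: float = 0.0
    Cu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S", "U", "Hs", "Cs", "Hu", "Cu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CascadeResult:
    """Per-barrier RI values assembled into the sequential cascade."""

    barrier_order: tuple[str, ...]
    per_barrier_RI: tuple[float, ...]
    cumulative_RI: tuple[float, ...]
    contributions_AC: tuple[float, ...]
    total_RI: float
    asymmetry: tuple[float, ...] = field(default=())


def ri_from_counts(counts: BarrierCounts | None = None, *,
                   H: float | None = None, C: float | None = None,
                   barrier: str = "?", direction: str = "?") -> float:
    """RI = 1 - 2*H/(H+C).

    Accepts either a :class:`BarrierCounts` or keyword ``H``/``C``.
    Equals 1 iff H = 0, 0 iff H = C, and -1 iff C = 0.

    Raises
    ------
    UndefinedIndexError
        If C + H = 0; the message names the barrier and direction.
    """
    if counts is not None:
        C, H = counts.conspecific_C, counts.heterospecific_H
        barrier, direction = counts.barrier_label, "x".join(counts.direction)
    if C is None or H is None:
        raise TypeError("provide either a BarrierCounts or both H= and C=")
    if C < 0 or H < 0:
        raise ValueError("H and C must be non-negative")
    total = H + C
    if total == 0:
        raise UndefinedIndexError(
            f"RI undefined for barrier {barrier!r}, direction {direction!r}: "
            "no conspecific and no heterospecific success observed (C + H = 0)"
        )
    return 1.0 - 2.0 * H / total


def ri_phenology(overlap: PhenologyOverlap | None = None, *,
                 S: float | None = None, U: float | None = None) -> float:
    """Phenological RI = 1 - S/(S+U): 1 for disjoint flowering, 0 for
    complete overlap of the focal window."""
    if overlap is not None:
        S, U = overlap.shared_S, overlap.unshared_U
    if S is None or U is None:
        raise TypeError("provide either a PhenologyOverlap or both S= and U=")
    if S < 0 or U < 0:
        raise ValueError("S and U must be non-negative")
    if S + U == 0:
        raise UndefinedIndexError("phenological RI undefined: S + U = 0")
    return 1.0 - S / (S + U)


def constancy_index(inputs: ConstancyInputs | None = None, *,
                    c: float | None = None, p: float | None = None) -> float:
    """Constancy index CI = (c - e) / (c + e - 2ce), e = p^2 + (1-p)^2.

    CI = 1 for complete constancy, 0 when the observed conspecific
    proportion matches the random expectation, -1 for perfect
    alternation.  The denominator c(1-e) + e(1-c) vanishes only at
    c = e = 1 (e >= 1/2 always); that limit is defined as 1, matching a
    forager that never leaves one species in a single-species sequence.
    """
    if inputs is not None:
        c, e = inputs.c, inputs.e
    else:
        if c is None or p is None:
            raise TypeError("provide either ConstancyInputs or both c= and p=")
        e = p * p + (1.0 - p) * (1.0 - p)
    denom = c + e - 2.0 * c * e
    if denom == 0.0:
        if c == 1.0:
            return 1.0
        raise UndefinedConstancyError(
            f"constancy index undefined: zero denominator with c={c}, e={e}"
        )
    return (c - e) / denom


def total_ri(inputs: TotalRIInputs) -> float:
    """Flowering-weighted total RI.

    RI_total = 1 - 2*(S*Hs + U*Hu) / [(S*Hs + U*Hu) + (S*Cs + U*Cu)]

    With U = 0 this degenerates exactly to ``ri_from_counts(H=Hs, C=Cs)``.
    """
    het = inputs.S * inputs.Hs + inputs.U * inputs.Hu
    con = inputs.S * inputs.Cs + inputs.U * inputs.Cu
    if het + con == 0:
        raise UndefinedIndexError(
            "total RI undefined: weighted success is zero in both arms"
        )
    return 1.0 - 2.0 * het / (het + con)


def cumulative_ri(per_barrier: Sequence[float]) -> list[float]:
    """Sequential cumulative isolation RI[1,i].

    RI[1,1] = RI_1 and RI[1,i] = RI[1,i-1] + RI_i * (1 - RI[1,i-1]):
    each barrier removes a fraction RI_i of the heterospecific gene flow
    that survived the earlier barriers.  Once a barrier has RI_i = 1 the
    cumulative value is exactly 1.0 and stays there.

    The raw recurrence can fall below -1 when several strong
    heterospecific-advantage barriers compound (the index cannot
    represent more than complete advantage), so the cumulative value is
    floored at -1, the bottom of the index's defined range.
    """
    out: list[float] = []
    acc = 0.0
    for i, r in enumerate(per_barrier):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"per-barrier RI out of [-1, 1] at position {i}: {r}")
        acc = 1.0 if r == 1.0 else max(-1.0, acc + r * (1.0 - acc))
        out.append(acc)
    return out


def absolute_contributions(cumulative: Sequence[float]) -> list[float]:
    """AC_i = RI[1,i] - RI[1,i-1] with RI[1,0] = 0.

    The sum of contributions telescopes exactly to the final cumulative
    value.
    """
    out: list[float] = []
    prev = 0.0
    for v in cumulative:
        out.append(v - prev)
        prev = v
    return out


def asymmetry(ri_forward: float, ri_reverse: float) -> float:
    """Absolute difference between the RI values of the two reciprocal
    cross directions of a species pair."""
    for v in (ri_forward, ri_reverse):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"RI value out of [-1, 1]: {v}")
    return math.fabs(ri_forward - ri_reverse)
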