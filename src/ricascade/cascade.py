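"""Sequential barrier cascade: cumulative RI, totals, contributions.

Per-barrier RI values for one directed species pair are assembled in
life-cycle order (phenology, ethological, style, ovary, fruit, seed) and
combined sequentially — each barrier acts only on the heterospecific
gene flow that survived the earlier barriers.  The module reports two
totals side by side:

* the recurrence total, the final cumulative value of
  RI[1,i] = RI[1,i-1] + RI_i (1 - RI[1,i-1]), which is the total the
  absolute contributions AC_i telescope to; and
* the flowering-weighted total, which down-weights post-phenology
  heterospecific success by the shared flowering proportion S and
  credits conspecific success over the whole season (Hu = 0, Cu = Cs).

For all-non-negative ladders the recurrence total equals
1 - prod(1 - RI_i) exactly, and is therefore order-invariant; with
negative entries (heterospecific advantage) order matters and the
life-cycle order is the meaningful one.

Barriers that could not be estimated are skipped, not imputed as zero:
zero-filling would silently understate the contribution of every later
barrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crosses, foraging
from .errors import EmptyInputError, NotEstimable, UndefinedIndexError
from .ri_core import (BARRIER_ORDER, CascadeResult, PhenologyOverlap,
                      TotalRIInputs, absolute_contributions, asymmetry,
                      cumulative_ri, total_ri)


@dataclass(frozen=True)
class LadderEntry:
    barrier: str
    ri: float | None
    estimable: bool


@dataclass(frozen=True)
class BarrierLadder:
    """All barrier strengths of one directed species pair, in canonical
    life-cycle order, with non-estimable entries flagged."""

    direction: tuple[str, str]
    entries: tuple[LadderEntry, ...]
    phenology_overlap: PhenologyOverlap | None = None

    def estimable_entries(self) -> list[LadderEntry]:
        return [e for e in self.entries if e.estimable]


def assemble_ladder(direction: tuple[str, str],
                    barrier_ris: Mapping[str, float | None],
                    overlap: PhenologyOverlap | None = None,
                    order: Sequence[str] = BARRIER_ORDER) -> BarrierLadder:
    """Build a ladder from a {barrier: RI} mapping.

    Barriers absent from the mapping, or mapped to None/NaN, are flagged
    not estimable.  At least one estimable barrier is required.
    """
    entries = []
    for barrier in order:
        ri = barrier_ris.get(barrier)
        if ri is None or (isinstance(ri, float) and math.isnan(ri)):
            entries.append(LadderEntry(barrier=barrier, ri=None, estimable=False))
        else:
            if not -1.0 <= ri <= 1.0:
                raise ValueError(f"{barrier}: RI {ri} out of [-1, 1]")
            entries.append(LadderEntry(barrier=barrier, ri=float(ri), estimable=True))
    ladder = BarrierLadder(direction=tuple(direction), entries=tuple(entries),
                           phenology_overlap=overlap)
    if not ladder.estimable_entries():
        raise EmptyInputError(
            f"no estimable barrier for direction {direction[0]} x {direction[1]}"
        )
    return ladder


def run_cascade(ladder: BarrierLadder,
                reverse_ladder: BarrierLadder | None = None) -> CascadeResult:
    """Cumulative RI, absolute contributions and total for one ladder.

    The total is exactly 1.0 whenever any estimable barrier has RI = 1.
    If the reverse-direction ladder is supplied, per-barrier asymmetry
    |RI_ab - RI_ba| is attached (NaN where either side is missing).
    """
    est = ladder.estimable_entries()
    ris = [e.ri for e in est]
    cum = cumulative_ri(ris)
    acs = absolute_contributions(cum)
    asym: tuple[float, ...] = ()
    if reverse_ladder is not None:
        rev = {e.barrier: e.ri for e in reverse_ladder.entries if e.estimable}
        asym = tuple(
            asymmetry(e.ri, rev[e.barrier]) if e.barrier in rev else float("nan")
            for e in est
        )
    return CascadeResult(
        barrier_order=tuple(e.barrier for e in est),
        per_barrier_RI=tuple(ris),
        cumulative_RI=tuple(cum),
        contributions_AC=tuple(acs),
        total_RI=cum[-1],
        asymmetry=asym,
    )


def total_ri_weighted(ladder: BarrierLadder,
                      overlap: PhenologyOverlap | None = None,
                      successes: Mapping[str, tuple[float, float]] | None = None
                      ) -> float:
    """Flowering-weighted total RI.

    Post-phenology barriers are compounded into end-to-end success
    proportions for the shared flowering period: Hs and Cs are the
    products of per-stage heterospecific and conspecific successes.
    Outside the shared period the partner cannot pollinate (Hu = 0)
    while conspecific reproduction proceeds unimpeded (Cu = Cs).

    ``successes`` optionally supplies per-barrier (C, H) success
    proportions; otherwise each stage's proportions are recovered from
    its RI via (C, H) = ((1+RI)/2, (1-RI)/2), which preserves the only
    quantity the total depends on, the ratio H/C = (1-RI)/(1+RI).
    """
    overlap = overlap or ladder.phenology_overlap
    if overlap is None:
        raise ValueError("phenology overlap required for the weighted total")
    hs = cs = 1.0
    for entry in ladder.estimable_entries():
        if entry.barrier == "phenology":
            continue
        if successes is not None and entry.barrier in successes:
            c, h = successes[entry.barrier]
        else:
            c, h = (1.0 + entry.ri) / 2.0, (1.0 - entry.ri) / 2.0
        hs *= h
        cs *= c
    return total_ri(TotalRIInputs(S=overlap.shared_S, U=overlap.unshared_U,
                                  Hs=hs, Cs=cs, Hu=0.0, Cu=cs))


def cascade_table(result: CascadeResult, direction: tuple[str, str]) -> pd.DataFrame:
    """Long-format per-barrier table (cumulative-contribution plot data)."""
    rows = []
    for i, barrier in enumerate(result.barrier_order):
        rows.append({
            "maternal": direction[0], "paternal": direction[1],
            "barrier": barrier,
            "RI": result.per_barrier_RI[i],
            "cumulative_RI": result.cumulative_RI[i],
            "AC": result.contributions_AC[i],
            "asymmetry": result.asymmetry[i] if result.asymmetry else float("nan"),
        })
    return pd.DataFrame(rows)


MIN_STABLE_ARM = 5  # resampling an arm smaller than this is flagged unstable


def bootstrap_ci(direction: tuple[str, str], *,
                 bouts: Sequence[foraging.ForagingBout] | None = None,
                 array_species: tuple[str, str] | None = None,
                 pistils: Sequence[crosses.PistilAssay] | None = None,
                 fruits: Sequence[crosses.FruitRecord] | None = None,
                 seeds: Sequence[crosses.SeedAssay] | None = None,
                 phenology_ri: float | None = None,
                 B: int = 2000, seed: int | None = None,
                 mode: str = "proportions") -> dict:
    """Nonparametric bootstrap intervals per barrier and for total RI.

    Raw observations are resampled with replacement *within arm* (bouts
    as wholes; pistils, flowers and fruits within the intraspecific and
    interspecific arms separately), the whole ladder is recomputed per
    replicate, and 2.5/97.5 percentile intervals are reported.  The
    phenological RI, if supplied, is held fixed (it is a population-level
    window statistic, not an exchangeable observation).  Arms with fewer
    than five observations are flagged unstable.  Results are
    bit-reproducible under a fixed seed.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible bootstrap intervals")
    rng = np.random.default_rng(seed)
    maternal, paternal = direction

    def split_arms(records, is_intra):
        intra = [r for r in records if is_intra(r)]
        inter = [r for r in records
                 if r.treatment == "inter_cross" and r.maternal_species == maternal
                 and r.paternal_species == paternal]
        return intra, inter

    pist_arms = flower_arms = seed_arms = None
    if pistils is not None:
        pist_arms = split_arms(pistils, lambda r: r.treatment == "intra_cross"
                               and r.maternal_species == maternal
                               and r.paternal_species == maternal)
    if fruits is not None:
        intra, inter = split_arms(fruits, lambda r: r.treatment == "intra_cross"
                                  and r.maternal_species == maternal
                                  and r.paternal_species == maternal)
        # expand batches to per-flower Bernoulli outcomes for resampling
        def expand(arm):
            out = []
            for r in arm:
                out.extend([1] * r.fruits_set + [0] * (r.flowers_treated - r.fruits_set))
            return out
        flower_arms = (expand(intra), expand(inter))
    if seeds is not None:
        seed_arms = split_arms(seeds, lambda r: r.treatment == "intra_cross"
                               and r.maternal_species == maternal
                               and r.maternal_species == r.paternal_species)

    unstable = []
    if bouts is not None and len(bouts) < MIN_STABLE_ARM:
        unstable.append("ethological")
    for name, arms in (("pistil", pist_arms), ("fruit", flower_arms),
                       ("seed", seed_arms)):
        if arms is not None and (len(arms[0]) < MIN_STABLE_ARM
                                 or len(arms[1]) < MIN_STABLE_ARM):
            unstable.append(name)

    def resample(arm):
        idx = rng.integers(0, len(arm), size=len(arm))
        return [arm[i] for i in idx]

    barrier_draws: dict[str, list[float]] = {b: [] for b in BARRIER_ORDER}
    total_draws: list[float] = []
    for _ in range(B):
        ris: dict[str, float | None] = {}
        if phenology_ri is not None:
            ris["phenology"] = phenology_ri
        if bouts is not None:
            try:
                table = foraging.count_transitions(resample(bouts), *array_species)
                ris["ethological"] = foraging.ethological_ri(table, maternal)
            except (UndefinedIndexError, EmptyInputError):
                ris["ethological"] = None
        if pist_arms is not None:
            boot = resample(pist_arms[0]) + resample(pist_arms[1])
            for stage in ("style", "ovary"):
                try:
                    succ = crosses.stage_success(boot, stage, direction, mode=mode)
                    ris[stage] = crosses.stage_ri(succ)
                except (NotEstimable, UndefinedIndexError):
                    ris[stage] = None
        if flower_arms is not None:
            c = sum(resample(flower_arms[0]))
            h = sum(resample(flower_arms[1]))
            try:
                ris["fruit"] = crosses.stage_ri(crosses.StageSuccess(
                    stage="fruit", direction=direction,
                    conspecific_value=float(c), heterospecific_value=float(h)))
            except UndefinedIndexError:
                ris["fruit"] = None
        if seed_arms is not None:
            boot = resample(seed_arms[0]) + resample(seed_arms[1])
            try:
                succ = crosses.stage_success(boot, "seed", direction)
                ris["seed"] = crosses.stage_ri(succ)
            except (NotEstimable, UndefinedIndexError):
                ris["seed"] = None
        try:
            ladder = assemble_ladder(direction, ris)
        except EmptyInputError:
            continue
        result = run_cascade(ladder)
        for barrier, ri in zip(result.barrier_order, result.per_barrier_RI):
            barrier_draws[barrier].append(ri)
        total_draws.append(result.total_RI)

    def interval(draws):
        if not draws:
            return None
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return (float(lo), float(hi))

    return {
        "direction": direction,
        "B": B,
        "seed": seed,
        "barriers": {b: interval(d) for b, d in barrier_draws.items() if d},
        "total": interval(total_draws),
        "unstable": unstable,
    }
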