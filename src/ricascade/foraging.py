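"""Pollinator foraging bouts, ethological isolation and constancy.

A foraging bout is one pollinator's uninterrupted, ordered sequence of
flower visits in a two-species choice array.  Consecutive visits define
transitions; pooled transition counts give the ethological RI, and
within-bout transition structure gives each forager's constancy index.

Orientation convention for the ethological RI of a focal species:
C = conspecific transitions into the focal species (focal -> focal) and
H = heterospecific transitions into it (other -> focal) — the pollen
arriving on focal stigmas.  Both directed RI values of a pair come from
the same pooled table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .errors import EmptyInputError, NotEstimable, SchemaError, UndefinedIndexError
from .ri_core import constancy_index, ri_from_counts


@dataclass(frozen=True)
class ForagingBout:
    """One pollinator's ordered visit sequence."""

    bout_id: str
    pollinator: str
    visits: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.visits) < 1:
            raise ValueError(f"bout {self.bout_id!r}: empty visit sequence")

    @property
    def n_transitions(self) -> int:
        return len(self.visits) - 1


@dataclass(frozen=True)
class TransitionTable:
    """Pairwise transition counts between the two array species a and b;
    x -> y means a consecutive visit from an x flower to a y flower."""

    species_a: str
    species_b: str
    n_aa: int = 0
    n_bb: int = 0
    n_ab: int = 0
    n_ba: int = 0

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_bb, self.n_ab, self.n_ba) < 0:
            raise ValueError("transition counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_aa + self.n_bb + self.n_ab + self.n_ba

    @property
    def intraspecific(self) -> int:
        return self.n_aa + self.n_bb

    @property
    def interspecific(self) -> int:
        return self.n_ab + self.n_ba

    def into(self, species: str) -> tuple[int, int]:
        """(conspecific, heterospecific) transition counts INTO a species."""
        if species == self.species_a:
            return self.n_aa, self.n_ba
        if species == self.species_b:
            return self.n_bb, self.n_ab
        raise ValueError(
            f"species {species!r} is not in the array "
            f"({self.species_a!r}, {self.species_b!r})"
        )


def count_transitions(bouts: Iterable[ForagingBout], species_a: str,
                      species_b: str) -> TransitionTable:
    """Pool consecutive-visit transitions over bouts.

    Single-visit bouts contribute zero transitions.  Visit labels
    outside the two array species raise a validation error naming the
    offending bout.
    """
    bouts = list(bouts)
    if not bouts:
        raise EmptyInputError("no foraging bouts supplied")
    valid = {species_a, species_b}
    counts = {"aa": 0, "bb": 0, "ab": 0, "ba": 0}
    for bout in bouts:
        for visit in bout.visits:
            if visit not in valid:
                raise SchemaError(
                    f"bout {bout.bout_id!r}: unknown plant species {visit!r} "
                    f"(array species are {species_a!r}, {species_b!r})"
                )
        for prev, nxt in zip(bout.visits, bout.visits[1:]):
            key = ("a" if prev == species_a else "b") + ("a" if nxt == species_a else "b")
            counts[key] += 1
    return TransitionTable(species_a=species_a, species_b=species_b,
                           n_aa=counts["aa"], n_bb=counts["bb"],
                           n_ab=counts["ab"], n_ba=counts["ba"])


def ethological_ri(table: TransitionTable, focal: str) -> float:
    """Ethological RI of the focal species from pooled transitions.

    Only the pooled table matters — the result is invariant to how the
    visits were segmented into bouts.
    """
    C, H = table.into(focal)
    if C + H == 0:
        raise UndefinedIndexError(
            f"ethological RI undefined for {focal!r}: no transitions into it"
        )
    return ri_from_counts(H=H, C=C, barrier="ethological", direction=focal)


def bout_constancy(bout: ForagingBout, species_a: str, species_b: str) -> float:
    """Constancy index of a single bout.

    c is the bout's proportion of conspecific transitions; p is the
    proportion of its visits made to the first array species.  Bouts of
    fewer than two visits carry no transition information.
    """
    if bout.n_transitions < 1:
        raise NotEstimable(
            f"bout {bout.bout_id!r} has a single visit; constancy not estimable"
        )
    for visit in bout.visits:
        if visit not in (species_a, species_b):
            raise SchemaError(
                f"bout {bout.bout_id!r}: unknown plant species {visit!r}"
            )
    conspecific = sum(prev == nxt for prev, nxt in zip(bout.visits, bout.visits[1:]))
    c = conspecific / bout.n_transitions
    p = sum(v == species_a for v in bout.visits) / len(bout.visits)
    return constancy_index(c=c, p=p)


def pollinator_constancy_summary(bouts: Iterable[ForagingBout], pollinator: str,
                                 species_a: str, species_b: str) -> dict:
    """Mean +/- sample SD of the constancy index over one pollinator's
    estimable bouts.

    A single estimable bout has no sample SD; by the conventional table
    format it is reported as 0.0 and flagged with n = 1 in the output.
    """
    cis = []
    for bout in bouts:
        if bout.pollinator != pollinator:
            continue
        try:
            cis.append(bout_constancy(bout, species_a, species_b))
        except NotEstimable:
            continue
    if not cis:
        raise NotEstimable(
            f"no estimable bouts (>= 2 visits) for pollinator {pollinator!r}"
        )
    n = len(cis)
    mean = sum(cis) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in cis) / (n - 1)) if n > 1 else 0.0
    return {"pollinator": pollinator, "n_bouts": n, "mean_CI": mean, "sd_CI": sd}


def g_test_transitions(intra: int, inter: int) -> tuple[float, int, float]:
    """Likelihood-ratio G-test of intra- vs interspecific transition
    counts against equal expected counts.

    G = 2 * sum O * ln(O/E) with E = (intra + inter) / 2 and df = 1;
    the p-value comes from the chi-square distribution.  Zero cells
    contribute 0 to the sum (O ln O -> 0 as O -> 0).  No continuity
    correction is applied.

    The equal-count null is a modelling convention for a balanced
    two-species array, not a claim about relative flower availability.
    """
    if intra < 0 or inter < 0:
        raise ValueError("counts must be non-negative")
    total = intra + inter
    if total == 0:
        raise EmptyInputError("G-test undefined: both counts are zero")
    expected = total / 2.0
    g = 2.0 * (xlogy(intra, intra / expected) + xlogy(inter, inter / expected))
    p = float(chi2.sf(g, df=1))
    return float(g), 1, p


def read_bouts_csv(path: str | Path) -> list[ForagingBout]:
    """Read foraging bouts from CSV, one row per visit.

    Expected columns: bout_id, pollinator, visit_order, plant_species.
    Visits are ordered within bout by visit_order.
    """
    df = pd.read_csv(path)
    required = {"bout_id", "pollinator", "visit_order", "plant_species"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bouts = []
    for bout_id, grp in df.groupby("bout_id", sort=True):
        pollinators = grp["pollinator"].unique()
        if len(pollinators) != 1:
            raise SchemaError(
                f"{path}: bout {bout_id!r} lists multiple pollinators {list(pollinators)}"
            )
        grp = grp.sort_values("visit_order")
        bouts.append(ForagingBout(
            bout_id=str(bout_id),
            pollinator=str(pollinators[0]),
            visits=tuple(str(s) for s in grp["plant_species"]),
        ))
    if not bouts:
        raise EmptyInputError(f"{path}: no bouts found")
    return bouts


def transition_table_frame(table: TransitionTable) -> pd.DataFrame:
    """Transition table as a tidy one-row DataFrame for CSV export."""
    a, b = table.species_a, table.species_b
    return pd.DataFrame([{
        f"{a}->{a}": table.n_aa, f"{b}->{b}": table.n_bb,
        f"{a}->{b}": table.n_ab, f"{b}->{a}": table.n_ba,
        "intraspecific": table.intraspecific,
        "interspecific": table.interspecific,
    }])


def constancy_summary_table(bouts: Sequence[ForagingBout], species_a: str,
                            species_b: str) -> pd.DataFrame:
    """Per-pollinator constancy summary for all pollinators in the data."""
    pollinators = sorted({b.pollinator for b in bouts})
    rows = []
    for pol in pollinators:
        try:
            rows.append(pollinator_constancy_summary(bouts, pol, species_a, species_b))
        except NotEstimable:
            rows.append({"pollinator": pol, "n_bouts": 0,
                         "mean_CI": float("nan"), "sd_CI": float("nan")})
    return pd.DataFrame(rows)
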