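"""Flowering-phenology windows and temporal isolation.

Per-individual flowering records (first and last flowering day) are
aggregated into species-level windows — the union of closed day
intervals over individuals — from which shared/unshared proportions and
the phenological RI are computed for each directed species pair.

Day resolution is integer day-of-year: field phenology surveys are
typically run at multi-day intervals, so sub-day precision would be
spurious.  Both endpoints of an individual's flowering interval count as
flowering days (closed intervals).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyInputError, SchemaError
from .ri_core import PhenologyOverlap, ri_phenology

PHENOLOGY_COLUMNS = ("individual_id", "species", "site",
                     "first_flower_day", "last_flower_day")


@dataclass(frozen=True)
class FloweringRecord:
    """One individual's flowering interval, in day-of-year units."""

    individual_id: str
    species: str
    site: str
    first_flower_day: int
    last_flower_day: int

    def __post_init__(self) -> None:
        if self.first_flower_day > self.last_flower_day:
            raise ValueError(
                f"individual {self.individual_id!r}: first_flower_day "
                f"{self.first_flower_day} > last_flower_day {self.last_flower_day}"
            )
        if not (1 <= self.first_flower_day and self.last_flower_day <= 366):
            raise ValueError(
                f"individual {self.individual_id!r}: days must fall within "
                "one calendar year (1..366)"
            )


@dataclass(frozen=True)
class SpeciesWindow:
    """Population-level flowering window: the set of days on which at
    least one individual of the species was flowering."""

    species: str
    flowering_days: frozenset[int]

    def __len__(self) -> int:
        return len(self.flowering_days)


def _to_day_of_year(value) -> int:
    """Accept integer day-of-year or an ISO-8601 date string."""
    if isinstance(value, (int,)) and not isinstance(value, bool):
        return int(value)
    if isinstance(value, float) and value == int(value):
        return int(value)
    if isinstance(value, str):
        s = value.strip()
        if s.lstrip("+-").isdigit():
            return int(s)
        try:
            return _dt.date.fromisoformat(s).timetuple().tm_yday
        except ValueError as err:
            raise SchemaError(f"cannot parse day value {value!r}: {err}") from err
    raise SchemaError(f"cannot parse day value {value!r}")


def read_phenology_csv(path: str | Path) -> list[FloweringRecord]:
    """Read per-individual flowering records from CSV.

    Expected columns: individual_id, species, site, first_flower_day,
    last_flower_day.  Dates may be ISO-8601 or integer day-of-year.
    """
    df = pd.read_csv(path)
    missing = set(PHENOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(FloweringRecord(
                individual_id=str(row["individual_id"]),
                species=str(row["species"]),
                site=str(row["site"]),
                first_flower_day=_to_day_of_year(row["first_flower_day"]),
                last_flower_day=_to_day_of_year(row["last_flower_day"]),
            ))
        except (ValueError, SchemaError) as err:
            raise SchemaError(f"{path}, row {i + 2}: {err}") from err
    return records


def build_window(records: Iterable[FloweringRecord], species: str,
                 site: str | None = None) -> SpeciesWindow:
    """Union of the closed flowering intervals of all individuals of one
    species, optionally restricted to one site."""
    days: set[int] = set()
    n = 0
    for rec in records:
        if rec.species != species:
            continue
        if site is not None and rec.site != site:
            continue
        n += 1
        days.update(range(rec.first_flower_day, rec.last_flower_day + 1))
    if n == 0:
        where = f" at site {site!r}" if site is not None else ""
        raise EmptyInputError(f"no flowering records for species {species!r}{where}")
    return SpeciesWindow(species=species, flowering_days=frozenset(days))


def overlap_proportions(focal: SpeciesWindow, partner: SpeciesWindow) -> PhenologyOverlap:
    """Shared and unshared proportions of the focal window.

    S = |focal ∩ partner| / |focal|,  U = |focal \\ partner| / |focal|;
    S + U = 1 exactly because both are proportions of the focal window.
    """
    if not focal.flowering_days or not partner.flowering_days:
        raise EmptyInputError("overlap undefined for an empty flowering window")
    n_focal = len(focal.flowering_days)
    n_shared = len(focal.flowering_days & partner.flowering_days)
    return PhenologyOverlap(
        shared_S=n_shared / n_focal,
        unshared_U=(n_focal - n_shared) / n_focal,
        focal_species=focal.species,
        partner_species=partner.species,
    )


def phenology_ri_pair(records: Sequence[FloweringRecord], species_a: str,
                      species_b: str, site: str | None = None
                      ) -> tuple[float, float]:
    """Directed phenological RI values (a as focal, b as focal).

    The two directions generally differ when the windows differ in
    length: RI_pheno is the unshared fraction of the *focal* window.
    """
    win_a = build_window(records, species_a, site=site)
    win_b = build_window(records, species_b, site=site)
    ri_ab = ri_phenology(overlap_proportions(win_a, win_b))
    ri_ba = ri_phenology(overlap_proportions(win_b, win_a))
    return ri_ab, ri_ba


def phenology_table(records: Sequence[FloweringRecord],
                    pairs: Sequence[tuple[str, str]],
                    site: str | None = None) -> pd.DataFrame:
    """Tidy per-direction table of (focal, partner, S, U, RI_pheno)."""
    rows = []
    for a, b in pairs:
        for focal, partner in ((a, b), (b, a)):
            ov = overlap_proportions(build_window(records, focal, site=site),
                                     build_window(records, partner, site=site))
            rows.append({
                "focal": focal, "partner": partner,
                "S": ov.shared_S, "U": ov.unshared_U,
                "RI_pheno": ri_phenology(ov),
            })
    return pd.DataFrame(rows)
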