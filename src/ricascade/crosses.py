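"""Hand-pollination experiments: pistil assays, fruit set, embryo scoring.

Three record types summarise a crossing design into per-stage barrier
strengths:

* pistil assays — per-pistil pollen-tube counts at the stigma, style and
  ovary (the nested counts satisfy ovary <= style <= stigma);
* fruit records — flowers treated vs dense, turgid fruits set;
* seed assays — per-fruit embryo category counts (large, small, aborted,
  empty), with the large-embryo rate as the viability measure.

Each post-pollination stage (style, ovary, fruit, seed) compares the
intraspecific-cross arm (C) with the interspecific arm (H) of one
direction (maternal x paternal) and feeds RI = 1 - 2H/(H+C).
Self-pollination assays measure compatibility, not isolation, and are
excluded from interspecific RI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import NotEstimable, SchemaError
from .ri_core import ri_from_counts

TREATMENTS = ("self", "intra_cross", "inter_cross")
STAGES = ("style", "ovary", "fruit", "seed")
EMBRYO_CATEGORIES = ("n_large", "n_small", "n_aborted", "n_empty")


@dataclass(frozen=True)
class PistilAssay:
    pistil_id: str
    maternal_species: str
    paternal_species: str
    treatment: str
    tubes_on_stigma: int
    tubes_in_style: int
    tubes_in_ovary: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not (0 <= self.tubes_in_ovary <= self.tubes_in_style <= self.tubes_on_stigma):
            raise ValueError(
                f"pistil {self.pistil_id!r}: tube counts must nest "
                "(ovary <= style <= stigma)"
            )


@dataclass(frozen=True)
class FruitRecord:
    maternal_species: str
    paternal_species: str
    treatment: str
    flowers_treated: int
    fruits_set: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not 0 <= self.fruits_set <= self.flowers_treated:
            raise ValueError("need 0 <= fruits_set <= flowers_treated")


@dataclass(frozen=True)
class SeedAssay:
    fruit_id: str
    maternal_species: str
    paternal_species: str
    treatment: str
    n_large: int
    n_small: int
    n_aborted: int
    n_empty: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if min(self.n_large, self.n_small, self.n_aborted, self.n_empty) < 0:
            raise ValueError("embryo category counts must be non-negative")

    @property
    def total_scored(self) -> int:
        return self.n_large + self.n_small + self.n_aborted + self.n_empty


@dataclass(frozen=True)
class StageSuccess:
    """Conspecific vs heterospecific success at one post-pollination
    stage for one cross direction."""

    stage: str
    direction: tuple[str, str]
    conspecific_value: float
    heterospecific_value: float
    n_conspecific: int = 0
    n_heterospecific: int = 0


def fruit_call(turgid: bool) -> bool:
    """Fruit-set indicator: a dense, turgid capsule counts as a fruit;
    soft, hollow capsules do not (they are retained for seed-assay
    linkage but score zero here)."""
    return bool(turgid)


def _pistil_arm(assays: Iterable[PistilAssay], direction: tuple[str, str],
                treatment: str) -> list[PistilAssay]:
    maternal, paternal = direction
    if treatment == "intra_cross":
        return [a for a in assays
                if a.treatment == "intra_cross" and a.maternal_species == maternal
                and a.paternal_species == maternal]
    return [a for a in assays
            if a.treatment == "inter_cross" and a.maternal_species == maternal
            and a.paternal_species == paternal]


def _mean_proportion(assays: Sequence[PistilAssay], stage: str,
                     mode: str) -> tuple[float, int]:
    """Stage success of one arm.

    ``mode="proportions"`` averages per-pistil proportions
    (style/stigma, ovary/style); pistils with a zero denominator carry
    no information about that conditional stage and are skipped.
    ``mode="counts"`` pools raw tube counts across pistils.
    """
    if mode == "counts":
        if stage == "style":
            num = sum(a.tubes_in_style for a in assays)
            den = sum(a.tubes_on_stigma for a in assays)
        else:
            num = sum(a.tubes_in_ovary for a in assays)
            den = sum(a.tubes_in_style for a in assays)
        if den == 0:
            raise NotEstimable(f"{stage}: no pollen tubes in the denominator pool")
        return num / den, len(assays)
    props = []
    for a in assays:
        if stage == "style":
            if a.tubes_on_stigma > 0:
                props.append(a.tubes_in_style / a.tubes_on_stigma)
        else:
            if a.tubes_in_style > 0:
                props.append(a.tubes_in_ovary / a.tubes_in_style)
    if not props:
        raise NotEstimable(f"{stage}: no pistil with a nonzero denominator")
    return sum(props) / len(props), len(props)


def stage_success(assays: Sequence[PistilAssay] | Sequence[FruitRecord]
                  | Sequence[SeedAssay],
                  stage: Literal["style", "ovary", "fruit", "seed"],
                  direction: tuple[str, str],
                  mode: str = "proportions") -> StageSuccess:
    """Summarise one stage of one cross direction into C and H values.

    style / ovary : mean per-pistil tube proportions (or pooled counts
                    with ``mode="counts"``) from :class:`PistilAssay`.
    fruit         : fruit counts from :class:`FruitRecord`.
    seed          : pooled large-embryo rate over fruits (weights =
                    seeds scored) from :class:`SeedAssay`.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    maternal, paternal = direction
    if stage in ("style", "ovary"):
        intra = _pistil_arm(assays, direction, "intra_cross")
        inter = _pistil_arm(assays, direction, "inter_cross")
        if not intra or not inter:
            raise NotEstimable(
                f"{stage} stage not estimable for {maternal} x {paternal}: "
                "need both an intraspecific and an interspecific arm"
            )
        c_val, n_c = _mean_proportion(intra, stage, mode)
        h_val, n_h = _mean_proportion(inter, stage, mode)
    elif stage == "fruit":
        intra = [r for r in assays if r.treatment == "intra_cross"
                 and r.maternal_species == maternal and r.paternal_species == maternal]
        inter = [r for r in assays if r.treatment == "inter_cross"
                 and r.maternal_species == maternal and r.paternal_species == paternal]
        if not intra or not inter:
            raise NotEstimable(
                f"fruit stage not estimable for {maternal} x {paternal}"
            )
        c_val = float(sum(r.fruits_set for r in intra))
        h_val = float(sum(r.fruits_set for r in inter))
        n_c = sum(r.flowers_treated for r in intra)
        n_h = sum(r.flowers_treated for r in inter)
    else:  # seed
        intra = [a for a in assays if a.treatment == "intra_cross"
                 and a.maternal_species == maternal and a.paternal_species == maternal]
        inter = [a for a in assays if a.treatment == "inter_cross"
                 and a.maternal_species == maternal and a.paternal_species == paternal]
        if not intra or not inter:
            raise NotEstimable(
                f"seed stage not estimable for {maternal} x {paternal}"
            )
        tot_c = sum(a.total_scored for a in intra)
        tot_h = sum(a.total_scored for a in inter)
        if tot_c == 0 or tot_h == 0:
            raise NotEstimable("seed stage: no seeds scored in one arm")
        c_val = sum(a.n_large for a in intra) / tot_c
        h_val = sum(a.n_large for a in inter) / tot_h
        n_c, n_h = len(intra), len(inter)
    return StageSuccess(stage=stage, direction=direction,
                        conspecific_value=c_val, heterospecific_value=h_val,
                        n_conspecific=n_c, n_heterospecific=n_h)


def stage_ri(success: StageSuccess) -> float:
    """RI of one post-pollination stage from its C and H values."""
    return ri_from_counts(H=success.heterospecific_value,
                          C=success.conspecific_value,
                          barrier=success.stage,
                          direction="x".join(success.direction))


def stage_table(pistils: Sequence[PistilAssay], fruits: Sequence[FruitRecord],
                seeds: Sequence[SeedAssay], directions: Sequence[tuple[str, str]],
                mode: str = "proportions") -> pd.DataFrame:
    """Per-stage StageSuccess and RI for each direction, long format.

    Non-estimable stages appear with NaN values and estimable=False.
    """
    source = {"style": pistils, "ovary": pistils, "fruit": fruits, "seed": seeds}
    rows = []
    for direction in directions:
        for stage in STAGES:
            row = {"maternal": direction[0], "paternal": direction[1],
                   "stage": stage}
            try:
                succ = stage_success(source[stage], stage, direction, mode=mode)
                row.update(C=succ.conspecific_value, H=succ.heterospecific_value,
                           n_C=succ.n_conspecific, n_H=succ.n_heterospecific,
                           RI=stage_ri(succ), estimable=True)
            except NotEstimable:
                row.update(C=float("nan"), H=float("nan"), n_C=0, n_H=0,
                           RI=float("nan"), estimable=False)
            rows.append(row)
    return pd.DataFrame(rows)


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_pistils_csv(path: str | Path) -> list[PistilAssay]:
    df = _read_csv(path, {"pistil_id", "maternal_species", "paternal_species",
                          "treatment", "tubes_on_stigma", "tubes_in_style",
                          "tubes_in_ovary"})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(PistilAssay(
                pistil_id=str(row["pistil_id"]),
                maternal_species=str(row["maternal_species"]),
                paternal_species=str(row["paternal_species"]),
                treatment=str(row["treatment"]),
                tubes_on_stigma=int(row["tubes_on_stigma"]),
                tubes_in_style=int(row["tubes_in_style"]),
                tubes_in_ovary=int(row["tubes_in_ovary"]),
            ))
        except ValueError as err:
            raise SchemaError(f"{path}, row {i + 2}: {err}") from err
    return out


def read_fruits_csv(path: str | Path) -> list[FruitRecord]:
    df = _read_csv(path, {"maternal_species", "paternal_species", "treatment",
                          "flowers_treated", "fruits_set"})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(FruitRecord(
                maternal_species=str(row["maternal_species"]),
                paternal_species=str(row["paternal_species"]),
                treatment=str(row["treatment"]),
                flowers_treated=int(row["flowers_treated"]),
                fruits_set=int(row["fruits_set"]),
            ))
        except ValueError as err:
            raise SchemaError(f"{path}, row {i + 2}: {err}") from err
    return out


def read_seeds_csv(path: str | Path) -> list[SeedAssay]:
    df = _read_csv(path, {"fruit_id", "maternal_species", "paternal_species",
                          "treatment", *EMBRYO_CATEGORIES})
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SeedAssay(
                fruit_id=str(row["fruit_id"]),
                maternal_species=str(row["maternal_species"]),
                paternal_species=str(row["paternal_species"]),
                treatment=str(row["treatment"]),
                n_large=int(row["n_large"]), n_small=int(row["n_small"]),
                n_aborted=int(row["n_aborted"]), n_empty=int(row["n_empty"]),
            ))
        except ValueError as err:
            raise SchemaError(f"{path}, row {i + 2}: {err}") from err
    return out
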