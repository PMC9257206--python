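"""Synthetic field datasets with the statistical structure the analysis
assumes, plus the packaged reference dataset.

Three generators emulate the three record types of a reproductive-
isolation field study:

* flowering schedules — per-individual start days drawn from a rounded
  normal, durations from a truncated rounded normal (at least one day);
* pollinator foraging bouts — a one-parameter Markov visit model in
  which the next visit stays conspecific with probability
  kappa + (1 - kappa) * abundance(current species); kappa interpolates
  between abundance-random foraging (kappa = 0, ethological RI ~ 0) and
  perfect constancy (kappa = 1, RI = CI = 1);
* hand-pollination outcomes — nested binomial pollen-tube counts per
  pistil, Bernoulli fruit set per flower, and multinomial embryo
  categories per fruit (~300 seeds scored per fruit, the conventional
  assay size).

All generators are deterministic under a fixed seed and emit exactly
the record types the ingestion modules validate, so the pipeline can be
exercised end to end without any field data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .crosses import FruitRecord, PistilAssay, SeedAssay
from .errors import ConfigError
from .foraging import ForagingBout, TransitionTable
from .phenology import FloweringRecord

_FIXTURE_RESOURCE = "habenaria_choice_arrays.json"

#: Barrier order actually measured in the reference study: a single
#: pollinia-pistil value (pollen tubes reaching the ovary) was published,
#: so the ladder has no separate style entry.
REFERENCE_BARRIER_ORDER = ("phenology", "ethological", "ovary", "fruit", "seed")


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PhenologySpeciesConfig:
    """Flowering-schedule parameters for one species (days of year)."""

    species: str
    n_individuals: int
    mean_start: float
    sd_start: float
    mean_duration: float
    sd_duration: float
    site: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ConfigError(f"{self.species}: n_individuals must be >= 0")
        if self.sd_start < 0 or self.sd_duration < 0:
            raise ConfigError(f"{self.species}: standard deviations must be >= 0")


@dataclass(frozen=True)
class ForagingConfig:
    """Choice-array foraging parameters for one species pair.

    ``kappa`` is the constancy parameter in [0, 1]; ``abundance_a`` the
    relative abundance of the first species; ``mean_visits`` the mean
    bout length (shifted-geometric, so bouts of a single visit occur).
    """

    species_a: str
    species_b: str
    n_bouts: int
    kappa: float
    abundance_a: float = 0.5
    mean_visits: float = 3.0
    pollinator: str = "sim_moth"

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ConfigError(f"kappa must lie in [0, 1], got {self.kappa}")
        if not 0.0 < self.abundance_a < 1.0:
            raise ConfigError("abundance_a must lie strictly in (0, 1)")
        if self.mean_visits <= 1.0:
            raise ConfigError("mean_visits must exceed 1")
        if self.n_bouts < 0:
            raise ConfigError("n_bouts must be >= 0")


@dataclass(frozen=True)
class CrossArmConfig:
    """Outcome rates for one pollination arm (intra- or interspecific)."""

    n_pistils: int = 30
    lambda_stigma: float = 20.0
    p_style: float = 0.8
    p_ovary: float = 0.6
    n_flowers: int = 50
    p_fruit: float = 0.9
    embryo_probs: tuple[float, float, float, float] = (0.8, 0.1, 0.05, 0.05)
    seeds_per_fruit: int = 300

    def __post_init__(self) -> None:
        for name in ("p_style", "p_ovary", "p_fruit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.embryo_probs) - 1.0) > 1e-9 or min(self.embryo_probs) < 0:
            raise ConfigError("embryo_probs must be non-negative and sum to 1")
        if self.lambda_stigma <= 0:
            raise ConfigError("lambda_stigma must be positive")
        if self.n_pistils < 0 or self.n_flowers < 0 or self.seeds_per_fruit < 1:
            raise ConfigError("sample sizes must be positive")


@dataclass(frozen=True)
class CrossConfig:
    """A reciprocal-cross design arm pair for one direction."""

    maternal: str
    paternal: str
    intra: CrossArmConfig = field(default_factory=CrossArmConfig)
    inter: CrossArmConfig = field(default_factory=CrossArmConfig)


@dataclass(frozen=True)
class SimConfig:
    """Full synthetic-study configuration."""

    rng_seed: int
    phenology: tuple[PhenologySpeciesConfig, ...] = ()
    foraging: tuple[ForagingConfig, ...] = ()
    crosses: tuple[CrossConfig, ...] = ()


def default_config(seed: int = 0) -> SimConfig:
    """A three-species study emulating the canonical field design.

    Two late-flowering species with broadly overlapping schedules and
    weak post-pollination barriers between them, and one species
    flowering about two weeks earlier that shares one array with the
    first species and is fully intersterile with both (no interspecific
    fruit).  Sample sizes mirror a single-season field campaign
    (~30 individuals per species, ~10 bouts per array, ~30 pistils and
    ~50 flowers per arm).
    """
    weak = CrossArmConfig()
    blocked = CrossArmConfig(p_ovary=0.1, p_fruit=0.0,
                             embryo_probs=(0.01, 0.04, 0.2, 0.75))
    return SimConfig(
        rng_seed=seed,
        phenology=(
            PhenologySpeciesConfig("lim", 30, 205.0, 4.0, 30.0, 5.0),
            PhenologySpeciesConfig("dav", 27, 207.0, 4.0, 30.0, 5.0),
            PhenologySpeciesConfig("del", 34, 191.0, 4.0, 25.0, 5.0),
        ),
        foraging=(
            ForagingConfig("lim", "dav", n_bouts=11, kappa=0.85),
            ForagingConfig("lim", "del", n_bouts=9, kappa=0.80),
        ),
        crosses=(
            CrossConfig("lim", "dav", intra=weak, inter=weak),
            CrossConfig("dav", "lim", intra=weak, inter=weak),
            CrossConfig("lim", "del", intra=weak, inter=blocked),
            CrossConfig("del", "lim", intra=weak, inter=blocked),
            CrossConfig("dav", "del", intra=weak, inter=blocked),
            CrossConfig("del", "dav", intra=weak, inter=blocked),
        ),
    )


# ---------------------------------------------------------------------------
# generators

def simulate_phenology(configs: Sequence[PhenologySpeciesConfig],
                       rng: np.random.Generator) -> list[FloweringRecord]:
    """Per-individual flowering records: rounded-normal start days and
    truncated rounded-normal durations (>= 1 day)."""
    records = []
    for cfg in configs:
        starts = np.rint(rng.normal(cfg.mean_start, cfg.sd_start,
                                    cfg.n_individuals)).astype(int)
        durations = np.maximum(
            1, np.rint(rng.normal(cfg.mean_duration, cfg.sd_duration,
                                  cfg.n_individuals)).astype(int))
        for i, (s, d) in enumerate(zip(starts, durations)):
            s = int(np.clip(s, 1, 366))
            last = int(np.clip(s + d - 1, s, 366))
            records.append(FloweringRecord(
                individual_id=f"{cfg.species}_{i:03d}", species=cfg.species,
                site=cfg.site, first_flower_day=s, last_flower_day=last))
    return records


def simulate_bouts(config: ForagingConfig, rng: np.random.Generator
                   ) -> list[ForagingBout]:
    """Markov foraging bouts in a two-species array.

    The first visit follows the abundance weights; each later visit
    stays on the current species with probability
    kappa + (1 - kappa) * abundance(current), else switches.  Bout
    length is 1 + Geometric(p) with p chosen so the mean equals
    ``mean_visits``.
    """
    species = (config.species_a, config.species_b)
    abundance = (config.abundance_a, 1.0 - config.abundance_a)
    p_len = 1.0 / (config.mean_visits - 1.0)
    p_len = min(1.0, p_len)
    bouts = []
    for b in range(config.n_bouts):
        length = 1 + int(rng.geometric(p_len))
        current = int(rng.random() >= abundance[0])
        visits = [species[current]]
        for _ in range(length - 1):
            p_stay = config.kappa + (1.0 - config.kappa) * abundance[current]
            if rng.random() >= p_stay:
                current = 1 - current
            visits.append(species[current])
        bouts.append(ForagingBout(bout_id=f"{config.species_a}-{config.species_b}-{b:03d}",
                                  pollinator=config.pollinator,
                                  visits=tuple(visits)))
    return bouts


def simulate_crosses(config: CrossConfig, rng: np.random.Generator,
                     skip_intra: bool = False
                     ) -> tuple[list[PistilAssay], list[FruitRecord], list[SeedAssay]]:
    """Hand-pollination outcomes for one direction, both arms.

    Pollen-tube counts nest by construction: stigma ~ Poisson (>= 1),
    style ~ Binomial(stigma, p_style), ovary ~ Binomial(style, p_ovary).
    Fruit set is Bernoulli per flower; each fruit that set is scored
    for ~300 seeds with multinomial embryo categories.

    ``skip_intra`` omits the intraspecific arm — used when several
    directions share a maternal species, which in a real crossing design
    shares a single intraspecific control.
    """
    pistils: list[PistilAssay] = []
    fruits: list[FruitRecord] = []
    seeds: list[SeedAssay] = []
    arms = [("intra_cross", config.intra, config.maternal),
            ("inter_cross", config.inter, config.paternal)]
    if skip_intra:
        arms = arms[1:]
    for treatment, arm, paternal in arms:
        tag = f"{config.maternal}x{paternal}_{treatment}"
        for i in range(arm.n_pistils):
            stigma = 0
            while stigma == 0:
                stigma = int(rng.poisson(arm.lambda_stigma))
            style = int(rng.binomial(stigma, arm.p_style))
            ovary = int(rng.binomial(style, arm.p_ovary))
            pistils.append(PistilAssay(
                pistil_id=f"{tag}_p{i:03d}",
                maternal_species=config.maternal, paternal_species=paternal,
                treatment=treatment, tubes_on_stigma=stigma,
                tubes_in_style=style, tubes_in_ovary=ovary))
        set_flags = rng.random(arm.n_flowers) < arm.p_fruit
        for i, flag in enumerate(set_flags):
            fruits.append(FruitRecord(
                maternal_species=config.maternal, paternal_species=paternal,
                treatment=treatment, flowers_treated=1, fruits_set=int(flag)))
            if flag:
                cats = rng.multinomial(arm.seeds_per_fruit, arm.embryo_probs)
                seeds.append(SeedAssay(
                    fruit_id=f"{tag}_f{i:03d}",
                    maternal_species=config.maternal, paternal_species=paternal,
                    treatment=treatment,
                    n_large=int(cats[0]), n_small=int(cats[1]),
                    n_aborted=int(cats[2]), n_empty=int(cats[3])))
    return pistils, fruits, seeds


def simulate_dataset(config: SimConfig) -> dict:
    """Run all generators of a :class:`SimConfig` under its seed.

    Returns a dict with keys ``phenology``, ``bouts``, ``pistils``,
    ``fruits``, ``seeds`` holding record lists.
    """
    rng = np.random.default_rng(config.rng_seed)
    phen = simulate_phenology(config.phenology, rng)
    bouts: list[ForagingBout] = []
    for fcfg in config.foraging:
        bouts.extend(simulate_bouts(fcfg, rng))
    pistils: list[PistilAssay] = []
    fruits: list[FruitRecord] = []
    seeds: list[SeedAssay] = []
    seen_intra: set[str] = set()
    for ccfg in config.crosses:
        p, f, s = simulate_crosses(ccfg, rng,
                                   skip_intra=ccfg.maternal in seen_intra)
        seen_intra.add(ccfg.maternal)
        pistils.extend(p)
        fruits.extend(f)
        seeds.extend(s)
    return {"phenology": phen, "bouts": bouts, "pistils": pistils,
            "fruits": fruits, "seeds": seeds}


# ---------------------------------------------------------------------------
# packaged reference dataset

def load_reference_study() -> dict:
    """The packaged reference dataset: choice-array transition counts
    per pollinator and the published per-barrier RI ladder for each
    directed species pair of the three-Habenaria system."""
    with resources.files("ricascade.data").joinpath(_FIXTURE_RESOURCE).open() as fh:
        return json.load(fh)


def reference_transition_tables() -> dict[str, TransitionTable]:
    """Pooled transition tables of the two choice arrays, keyed
    'lim_dav' and 'lim_del'."""
    study = load_reference_study()
    out = {}
    for key, arr in study["arrays"].items():
        a, b = arr["species"]
        t = arr["total"]
        out[key] = TransitionTable(species_a=a, species_b=b,
                                   n_aa=t["n_aa"], n_bb=t["n_bb"],
                                   n_ab=t["n_ab"], n_ba=t["n_ba"])
    return out


def reference_ladders() -> dict[str, dict[str, float | None]]:
    """Published per-barrier RI values keyed by direction
    ('maternal x paternal'); None marks a barrier that could not be
    measured (no shared pollinator)."""
    return load_reference_study()["published_ladders"]
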