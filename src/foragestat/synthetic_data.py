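"""Beta-binomial generator of plate-level assay datasets.

Emulates the statistical structure of the foraging-risk assay — bounded counts
of 10 worms per plate, skewed and overdispersed percent-exiting values, and
genotype × feeding-condition effects — without any mechanistic model of worm
behavior.  Exit propensity is additive on the logit scale:

    logit p = baseline + strain_effect + condition_effect·[fd] + interaction·[fd]

Plate counts are binomial(worms, p) when the intra-plate correlation rho is 0,
and beta-binomial with mean p and intra-class correlation rho otherwise
(worms on a plate influence one another, inflating between-plate variance by
the factor 1 + (worms-1)·rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit, logit

from .assay_data import Assay, Condition, ExperimentTable, PlateRecord

__all__ = ["StrainSpec", "GeneratorConfig", "SimulatedDataset",
           "simulate_plate", "generate_dataset", "true_effect"]


@dataclass(frozen=True)
class StrainSpec:
    """One strain's logit effects relative to the wild-type fed baseline.

    ``interaction_logit`` applies only when food-deprived, so it moves the
    strain's effect of food deprivation without moving its fed behavior.
    """

    name: str
    strain_logit: float = 0.0
    interaction_logit: float = 0.0
    control_group: str = "cohort1"


@dataclass(frozen=True)
class GeneratorConfig:
    """Effect model and sampling plan for a simulated experiment.

    Defaults mirror the assay's structure: 10-worm plates, a wild-type fed
    exit probability around 20% and a strong (~40 percent-point) response to
    one hour of food deprivation, with mild overdispersion.
    """

    strains: tuple[StrainSpec, ...] = (StrainSpec("WT"),)
    baseline_logit: float = float(logit(0.2))
    condition_effect: float = float(logit(0.6) - logit(0.2))
    rho: float = 0.05
    plates_per_cell: int = 20
    worms_per_plate: int = 10
    fructose_molarity: float = 3.0
    deprivation_minutes: float = 60.0
    assay: Assay = Assay.MULTISENSORY
    batch_effects: tuple[float, ...] = (0.0,)  # per-batch logit shifts, cycled
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.plates_per_cell < 1:
            raise ValueError("plates_per_cell must be >= 1")
        if self.worms_per_plate < 1:
            raise ValueError("worms_per_plate must be >= 1")
        if len({s.name for s in self.strains}) != len(self.strains):
            raise ValueError("duplicate strain names")

    def strain(self, name: str) -> StrainSpec:
        for s in self.strains:
            if s.name == name:
                return s
        raise KeyError(f"unknown strain {name!r}")

    def exit_probability(self, strain: str, condition: Condition) -> float:
        s = self.strain(strain)
        eta = self.baseline_logit + s.strain_logit
        if condition is Condition.FOOD_DEPRIVED:
            eta += self.condition_effect + s.interaction_logit
        return float(expit(eta))

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["assay"] = self.assay.value
        payload["strains"] = [asdict(s) for s in self.strains]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload["strains"] = tuple(StrainSpec(**s) for s in payload["strains"])
        payload["assay"] = Assay(payload["assay"])
        payload["batch_effects"] = tuple(payload["batch_effects"])
        return cls(**payload)


@dataclass
class SimulatedDataset:
    """Generated plates plus the ground truth the estimators target."""

    table: ExperimentTable
    truth: "pd.DataFrame"  # strain, p_fed, p_fd, true_effect (percent points)
    config: GeneratorConfig

    def truth_to_csv(self, path) -> None:
        self.truth.to_csv(path, index=False, float_format="%r")


def simulate_plate(
    p: float, rho: float, worms: int, rng: np.random.Generator
) -> int:
    """Exit count for one plate: binomial at rho=0, beta-binomial otherwise.

    The beta-binomial uses mean p and intra-class correlation rho, i.e. the
    latent per-plate probability is Beta(p·t, (1-p)·t) with t = (1-rho)/rho.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho {rho} outside [0, 1)")
    if p in (0.0, 1.0):
        return int(round(p * worms))
    if rho == 0.0:
        return int(rng.binomial(worms, p))
    theta = (1.0 - rho) / rho
    p_plate = rng.beta(p * theta, (1.0 - p) * theta)
    return int(rng.binomial(worms, p_plate))


def true_effect(config: GeneratorConfig, strain: str) -> float:
    """True effect of food deprivation for a strain, in percent points:
    100 × (p_food_deprived − p_fed) from the logit model."""
    p_fed = config.exit_probability(strain, Condition.FED)
    p_fd = config.exit_probability(strain, Condition.FOOD_DEPRIVED)
    return 100.0 * (p_fd - p_fed)


def generate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """One plate record per (strain, condition, replicate); deterministic
    under a fixed seed.  Batches cycle across replicate plates and may carry
    an optional logit shift for robustness experiments (zero by default)."""
    import pandas as pd

    rng = np.random.Generator(np.random.PCG64(config.seed))
    records: list[PlateRecord] = []
    truth_rows = []
    for strain in config.strains:
        for condition in (Condition.FED, Condition.FOOD_DEPRIVED):
            eta_base = logit(config.exit_probability(strain.name, condition))
            for rep in range(config.plates_per_cell):
                b = rep % len(config.batch_effects)
                p = float(expit(eta_base + config.batch_effects[b]))
                exits = simulate_plate(
                    p, config.rho, config.worms_per_plate, rng
                )
                records.append(
                    PlateRecord(
                        plate_id=f"{strain.name}-{condition.value}-{rep:03d}",
                        strain=strain.name,
                        control_group=strain.control_group,
                        condition=condition,
                        assay=config.assay,
                        worms_placed=config.worms_per_plate,
                        worms_remaining=config.worms_per_plate - exits,
                        fructose_molarity=config.fructose_molarity,
                        deprivation_minutes=(
                            config.deprivation_minutes
                            if condition is Condition.FOOD_DEPRIVED
                            else 0.0
                        ),
                        batch=f"batch{b}",
                    )
                )
        truth_rows.append(
            {
                "strain": strain.name,
                "p_fed": config.exit_probability(strain.name, Condition.FED),
                "p_fd": config.exit_probability(
                    strain.name, Condition.FOOD_DEPRIVED
                ),
                "true_effect": true_effect(config, strain.name),
            }
        )
    return SimulatedDataset(
        table=ExperimentTable(records),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
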