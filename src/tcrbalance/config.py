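"""Run configuration: validated settings for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .burden import BalanceParams
from .errors import ConfigError
from .repertoire import KEY_RECIPES
from .units import parse_duration


class FilterSettings(BaseModel):
    """Thresholds of the two clonotype filters."""

    min_reads: int = Field(2, ge=1)
    min_fraction: float = Field(0.01, gt=0, lt=1)
    renormalize: bool = True
    top_n: int = Field(100, ge=1)


class BalanceSettings(BaseModel):
    """Balance-model parameters and the sweep grids to export."""

    params: dict = Field(default_factory=dict)
    b_series: list[float] = Field(
        default_factory=lambda: [1e-1, 1e-2, 1e-3, 1e-4, 1e-5]
    )
    tau_values: list[str] = Field(
        default_factory=lambda: ["90 min", "4 hours", "12 hours"]
    )
    vaf_axis: list[float] = Field(
        default_factory=lambda: [round(0.02 * i, 2) for i in range(26)]
    )

    def base_params(self) -> BalanceParams:
        raw = dict(self.params)
        if "tau" in raw:
            raw["tau"] = parse_duration(raw["tau"])
        return BalanceParams(**raw)

    def tau_days(self) -> list[float]:
        return [parse_duration(t) for t in self.tau_values]


class SimulatedElispot(BaseModel):
    label: str
    rate_background: float = Field(ge=0)
    rate_effect: float = Field(ge=0)


class ElispotSettings(BaseModel):
    multiplier: Literal[1, 2] = 2
    alpha: float = Field(0.05, gt=0, lt=1)
    resamples: int = Field(10_000, ge=100)
    wells_csv: Optional[str] = None
    simulated: list[SimulatedElispot] = Field(
        default_factory=lambda: [
            SimulatedElispot(label="responder", rate_background=5.0, rate_effect=45.0),
            SimulatedElispot(label="non_responder", rate_background=5.0, rate_effect=0.0),
        ]
    )


class CohortScenario(BaseModel):
    """Fully synthetic cohort: four patients, both chains, paired timepoints.

    Defaults emulate the study scale: thousands of clonotypes per bulk
    bone-marrow sample sequenced to 1e6 reads, near-monoclonal cultures, and
    end-of-trial spike-ins of order 0.02% total frequency.  One patient
    (``unspiked_patient``) receives no spikes, giving exact-0% rows.
    """

    n_patients: int = Field(4, ge=1)
    loci: list[str] = Field(default_factory=lambda: ["alpha", "beta"])
    n_clonotypes: int = Field(3000, ge=10)
    read_depth: int = Field(1_000_000, ge=1000)
    retention: float = Field(0.9, ge=0, le=1)
    clone_size_exponent: float = Field(2.0, gt=1)
    n_dominant: int = Field(5, ge=1)
    dominant_fraction: float = Field(0.9, gt=0, le=1)
    culture_background_n: int = Field(100, ge=1)
    culture_read_depth: int = Field(100_000, ge=1000)
    n_spiked: int = Field(3, ge=0)
    spike_total_frequency: float = Field(2.2e-4, ge=0, lt=1)
    unspiked_patient: int | None = 2

    @model_validator(mode="after")
    def _check(self):
        if self.n_spiked > self.n_dominant:
            raise ValueError("n_spiked cannot exceed n_dominant")
        bad = [l for l in self.loci if l not in ("alpha", "beta")]
        if bad:
            raise ValueError(f"unknown loci {bad}")
        return self


class SampleInputs(BaseModel):
    """File-based inputs for one (patient, chain)."""

    patient_id: str
    locus: str
    baseline: str
    end_of_trial: str
    culture: str
    dialect: Literal["airr", "minimal_tsv"] = "airr"

    def paths(self) -> dict[str, str]:
        return {
            "baseline_bm": self.baseline,
            "end_of_trial_bm": self.end_of_trial,
            "specific_culture": self.culture,
        }


class RunConfig(BaseModel):
    """Everything one reproducible pipeline run needs."""

    seed: int = Field(0, ge=0, lt=2**31)
    output_dir: str = "runs"
    key_recipe: str = "aa_v"
    filters: FilterSettings = Field(default_factory=FilterSettings)
    balance: BalanceSettings = Field(default_factory=BalanceSettings)
    elispot: ElispotSettings = Field(default_factory=ElispotSettings)
    scenario: Optional[CohortScenario] = None
    inputs: list[SampleInputs] = Field(default_factory=list)

    @field_validator("key_recipe")
    @classmethod
    def _known_recipe(cls, value):
        if value not in KEY_RECIPES:
            raise ValueError(f"unknown key recipe {value!r}; choose from {sorted(KEY_RECIPES)}")
        return value

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.scenario is None) == (not self.inputs):
            raise ValueError("provide exactly one of 'scenario' or 'inputs'")
        for inp in self.inputs:
            for path in inp.paths().values():
                if not Path(path).exists():
                    raise ValueError(f"input file not found: {path}")
        return self

    def key_fields(self) -> tuple[str, ...]:
        return KEY_RECIPES[self.key_recipe]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError -> package error
        raise ConfigError(f"invalid run config {path}: {exc}") from exc


def demo_config(output_dir: str = "runs", seed: int = 7) -> RunConfig:
    """The fully synthetic demo cohort (four patients, both chains)."""
    return RunConfig(seed=seed, output_dir=output_dir, scenario=CohortScenario())
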