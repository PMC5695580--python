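"""Schema-validated pipeline configuration (YAML).

Unknown keys are rejected.  Embedded defaults are the study conventions:
pools of 8 individuals, 20x minimum coverage, 12.5% minimum variant
frequency (one individual's share of the pool).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import types as t

__all__ = [
    "LocusSpec",
    "DesignSpec",
    "ScenarioSpec",
    "SequencingSpec",
    "CallerSpec",
    "PipelineConfig",
    "load_config",
    "default_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LocusSpec(_Strict):
    locus_id: str
    length: int = Field(gt=0)
    sequence: Optional[str] = None
    intra_individual_variants: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check_sequence(self) -> "LocusSpec":
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length does not match length field")
        return self

    def build(self, seed: int) -> t.ReferenceLocus:
        if self.sequence is not None:
            return t.ReferenceLocus(
                self.locus_id, self.sequence, self.intra_individual_variants
            )
        return t.ReferenceLocus.random(
            self.locus_id, self.length, seed, self.intra_individual_variants
        )


class DesignSpec(_Strict):
    #: region -> catchment -> list of sites
    hierarchy: dict[str, dict[str, list[str]]]
    pool_size: int = Field(default=8, ge=1)

    def build(self) -> t.SamplingDesign:
        catchments: dict[str, str] = {}
        sites: dict[str, str] = {}
        for region, catchment_map in self.hierarchy.items():
            for catchment, site_list in catchment_map.items():
                catchments[catchment] = region
                for site in site_list:
                    if site in sites:
                        raise ValueError(f"site {site!r} appears twice")
                    sites[site] = catchment
        return t.SamplingDesign(
            regions=tuple(self.hierarchy),
            catchments=catchments,
            sites=sites,
            pool_size=self.pool_size,
        )


class ScenarioSpec(_Strict):
    scenario: Literal["founder_expansion", "persistence"]
    n_founder_lineages: int = Field(default=1, ge=1)
    founder_age: float = Field(default=0.0, ge=0)
    lineage_divergence: float = Field(default=0.0, ge=0)
    mutation_rate: float = Field(default=0.0, ge=0)
    rng_seed: int = 0

    def build(self) -> t.ScenarioConfig:
        return t.ScenarioConfig(
            scenario=self.scenario,
            n_founder_lineages=self.n_founder_lineages,
            founder_age=self.founder_age,
            lineage_divergence=self.lineage_divergence,
            mutation_rate=self.mutation_rate,
            rng_seed=self.rng_seed,
        )


class SequencingSpec(_Strict):
    mean_depth: float = Field(default=50.0, gt=0)
    error_rate: float = Field(default=0.002, ge=0, lt=0.25)
    strand_prob: float = Field(default=0.5, gt=0, lt=1)

    def build(self) -> t.SequencingModel:
        return t.SequencingModel(
            mean_depth=self.mean_depth,
            error_rate=self.error_rate,
            strand_prob=self.strand_prob,
        )


class CallerSpec(_Strict):
    min_coverage: int = Field(default=20, ge=1)
    min_variant_frequency: float = Field(default=0.125, gt=0, le=0.5)
    require_both_strands: bool = True

    def build(self):
        from .caller import PoolCallerConfig

        return PoolCallerConfig(
            min_coverage=self.min_coverage,
            min_variant_frequency=self.min_variant_frequency,
            require_both_strands=self.require_both_strands,
        )


class PipelineConfig(_Strict):
    design: DesignSpec
    loci: list[LocusSpec]
    #: region label -> scenario
    scenarios: dict[str, ScenarioSpec]
    sequencing: SequencingSpec = SequencingSpec()
    caller: CallerSpec = CallerSpec()
    seed: int = 0
    outdir: str = "poolskim_out"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_scenarios(self) -> "PipelineConfig":
        for region in self.design.hierarchy:
            if region not in self.scenarios:
                raise ValueError(f"region {region!r} has no scenario")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a mapping")
    return PipelineConfig.model_validate(data)


def default_config(
    seed: int = 0,
    cp_length: int = t.CP_LOCUS_LENGTH,
    nr_length: int = t.NR_LOCUS_LENGTH,
    error_rate: float = 0.0,
) -> PipelineConfig:
    """The built-in 12-site study: a persistence region of three
    long-diverged catchments and a founder-expansion region of three
    catchments sharing one recent founding lineage.

    Rates and times are illustrative (plastid-like mutation rate of 1e-9
    substitutions/site/generation), not estimates for any real species.
    """
    hierarchy = {
        "AWT": {
            "Daintree": ["CTBH"],
            "Mulgrave-Russell": ["CF"],
            "Johnstone": ["GCK"],
        },
        "NNSW": {
            "Tweed": ["HS"],
            "Richmond": ["BS", "Booy", "BH", "VP"],
            "Clarence": ["RAM", "OG", "CC", "OW"],
        },
    }
    return PipelineConfig(
        design=DesignSpec(hierarchy=hierarchy, pool_size=8),
        loci=[
            LocusSpec(locus_id="cpDNA", length=cp_length),
            LocusSpec(locus_id="nrDNA", length=nr_length, intra_individual_variants=2.0),
        ],
        scenarios={
            "AWT": ScenarioSpec(
                scenario="persistence",
                n_founder_lineages=3,
                founder_age=2_000,
                lineage_divergence=2_000_000,
                mutation_rate=1e-9,
            ),
            "NNSW": ScenarioSpec(
                scenario="founder_expansion",
                n_founder_lineages=1,
                founder_age=2_000,
                lineage_divergence=2_000_000,
                mutation_rate=1e-9,
            ),
        },
        sequencing=SequencingSpec(mean_depth=60.0, error_rate=error_rate),
        caller=CallerSpec(),
        seed=seed,
    )
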