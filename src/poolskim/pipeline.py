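"""End-to-end orchestration: simulate -> call -> classify -> report -> tree.

Thin glue over the library modules, shared by the command-line interface
and by scripted analyses.
"""
from __future__ import annotations

from dataclasses import dataclass

from .caller import PoolConsensus, call_study
from .catalog import SNPRecord, build_alignment, classify_snps
from .config import PipelineConfig
from .diversity import (
    DiversityReport,
    build_report,
    collapse_to_catchments,
    distance_matrix,
)
from .simulate import StudyBundle, generate_study
from .tree import RelationshipTree, nj_tree
from .types import ReferenceLocus, SamplingDesign

__all__ = ["PipelineResult", "run_pipeline", "analyse"]


@dataclass(frozen=True)
class PipelineResult:
    design: SamplingDesign
    loci: tuple[ReferenceLocus, ...]
    study: StudyBundle | None
    consensuses_by_locus: dict[str, list[PoolConsensus]]
    records_by_locus: dict[str, list[SNPRecord]]
    report: DiversityReport
    trees: dict[str, RelationshipTree]


def analyse(
    design: SamplingDesign,
    loci: list[ReferenceLocus],
    consensuses_by_locus: dict[str, list[PoolConsensus]],
    study: StudyBundle | None = None,
) -> PipelineResult:
    """Classify, summarise and build trees from called consensuses."""
    records_by_locus: dict[str, list[SNPRecord]] = {}
    for locus in loci:
        consensuses = consensuses_by_locus.get(locus.locus_id, [])
        if not consensuses:
            continue
        alignment = build_alignment(consensuses)
        variants_by_site = {c.site: list(c.variants) for c in consensuses}
        records_by_locus[locus.locus_id] = classify_snps(
            alignment, variants_by_site, design
        )
    report = build_report(records_by_locus, consensuses_by_locus, design, loci)
    trees: dict[str, RelationshipTree] = {}
    for locus in loci:
        consensuses = consensuses_by_locus.get(locus.locus_id, [])
        if not consensuses:
            continue
        catchment_matrix = collapse_to_catchments(
            distance_matrix(consensuses, locus.length), design
        )
        if len(catchment_matrix.labels) >= 3:
            trees[locus.locus_id] = nj_tree(catchment_matrix)
    return PipelineResult(
        design=design,
        loci=tuple(loci),
        study=study,
        consensuses_by_locus=consensuses_by_locus,
        records_by_locus=records_by_locus,
        report=report,
        trees=trees,
    )


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> PipelineResult:
    """Simulate a study from the config and analyse it end to end."""
    run_seed = config.seed if seed is None else seed
    design = config.design.build()
    loci = [spec.build(seed=run_seed + 1000 + i) for i, spec in enumerate(config.loci)]
    scenario_by_region = {r: s.build() for r, s in config.scenarios.items()}
    model = config.sequencing.build()
    study = generate_study(design, loci, scenario_by_region, model, seed=run_seed)

    caller_config = config.caller.build()
    references = {locus.locus_id: locus.sequence for locus in loci}
    consensuses_by_locus: dict[str, list[PoolConsensus]] = {}
    for locus in loci:
        pileups = [study.pileups[(site, locus.locus_id)] for site in design.site_labels]
        consensuses_by_locus[locus.locus_id] = call_study(
            pileups, caller_config, references
        )
    return analyse(design, loci, consensuses_by_locus, study=study)
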