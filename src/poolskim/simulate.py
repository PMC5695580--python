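"""Synthetic study generator for the two competing dispersal regimes.

Haplotypes evolve by point substitution along a star-shaped lineage tree:
founding lineages diverge independently from the reference ancestor for
``lineage_divergence`` generations, each site descends from its founding
lineage for ``founder_age`` generations, and the pooled individuals at a
site are clones of the site haplotype (maternal, non-recombining
inheritance).  Multi-copy loci may additionally carry per-individual
intra-genomic variants.  Pools are then "sequenced": per-position depth is
Poisson, reads are drawn uniformly from pool members, miscalled with the
model's error rate and assigned a strand — yielding the per-position,
per-strand base counts the caller consumes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import PoolPileup
from .types import (
    BASES,
    FOUNDER_EXPANSION,
    PERSISTENCE,
    Haplotype,
    ReferenceLocus,
    SamplingDesign,
    ScenarioConfig,
    SequencingModel,
    codes_to_seq,
)

__all__ = [
    "simulate_haplotypes",
    "simulate_pool_pileup",
    "generate_study",
    "StudyBundle",
]


def _mutate(
    codes: np.ndarray,
    rate: float,
    generations: float,
    rng: np.random.Generator,
    events: list | None,
    **labels,
) -> np.ndarray:
    """Apply a Poisson(rate * generations * L) number of point substitutions.

    Repeat hits at a position are allowed (the later substitution wins), so
    for short branches the expected pairwise difference between two branches
    of length T is ~ 2 * rate * T * L.
    """
    length = codes.size
    n_events = rng.poisson(rate * generations * length)
    out = codes.copy()
    for _ in range(n_events):
        pos = int(rng.integers(length))
        old = int(out[pos])
        new = (old + 1 + int(rng.integers(3))) % 4
        out[pos] = new
        if events is not None:
            events.append({"position": pos, "from_base": BASES[old], "to_base": BASES[new], **labels})
    return out


def _simulate_region(
    design: SamplingDesign,
    region: str,
    locus: ReferenceLocus,
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    events: list | None,
) -> list[Haplotype]:
    ref = locus.codes
    k = scenario.n_founder_lineages
    lineages = [
        _mutate(
            ref,
            scenario.mutation_rate,
            scenario.lineage_divergence,
            rng,
            events,
            locus=locus.locus_id,
            region=region,
            level="lineage",
            lineage=i,
        )
        for i in range(k)
    ]

    # founder_expansion: sites are exchangeable descendants of the founding
    # lineage(s); persistence: each catchment carries its own lineage.
    catchments = design.catchments_in_region(region)
    if scenario.scenario == PERSISTENCE:
        lineage_of_catchment = {c: i % k for i, c in enumerate(catchments)}
        lineage_of_site = {
            s: lineage_of_catchment[c]
            for c in catchments
            for s in design.sites_in_catchment(c)
        }
    else:
        sites = design.sites_in_region(region)
        lineage_of_site = {s: i % k for i, s in enumerate(sites)}

    haplotypes: list[Haplotype] = []
    for site in design.sites_in_region(region):
        lineage_idx = lineage_of_site[site]
        site_codes = _mutate(
            lineages[lineage_idx],
            scenario.mutation_rate,
            scenario.founder_age,
            rng,
            events,
            locus=locus.locus_id,
            region=region,
            level="site",
            lineage=lineage_idx,
            site=site,
        )
        for i in range(design.pool_size):
            ind_codes = site_codes
            if locus.intra_individual_variants > 0:
                n_private = rng.poisson(locus.intra_individual_variants)
                ind_codes = site_codes.copy()
                for _ in range(n_private):
                    pos = int(rng.integers(locus.length))
                    old = int(ind_codes[pos])
                    new = (old + 1 + int(rng.integers(3))) % 4
                    ind_codes[pos] = new
                    if events is not None:
                        events.append(
                            {
                                "position": pos,
                                "from_base": BASES[old],
                                "to_base": BASES[new],
                                "locus": locus.locus_id,
                                "region": region,
                                "level": "individual",
                                "lineage": lineage_idx,
                                "site": site,
                                "individual": f"{site}|{i + 1}",
                            }
                        )
            haplotypes.append(
                Haplotype(
                    individual_id=f"{site}|{i + 1}",
                    site=site,
                    locus_id=locus.locus_id,
                    sequence=codes_to_seq(ind_codes),
                )
            )
    return haplotypes


def simulate_haplotypes(
    design: SamplingDesign,
    locus: ReferenceLocus,
    scenario: ScenarioConfig,
    seed: int | np.random.SeedSequence | None = None,
    events: list | None = None,
) -> list[Haplotype]:
    """Simulate one haplotype per individual per site under one scenario.

    The scenario is applied to every region in the design, each region
    evolving independently.  ``seed`` overrides ``scenario.rng_seed`` (used
    by :func:`generate_study` to derive child streams).
    """
    rng = np.random.default_rng(scenario.rng_seed if seed is None else seed)
    haplotypes: list[Haplotype] = []
    for region in design.regions:
        haplotypes.extend(_simulate_region(design, region, locus, scenario, rng, events))
    return haplotypes


def simulate_pool_pileup(
    haplotypes: list[Haplotype],
    model: SequencingModel,
    seed: int | np.random.SeedSequence,
) -> PoolPileup:
    """Sequence one site's pool of haplotypes into per-strand base counts.

    Per position the read count is Poisson(``mean_depth``); each read takes
    its base from a uniformly chosen pool member, miscalled with probability
    ``error_rate`` (uniform over the other 3 bases), and lands on the
    forward strand with probability ``strand_prob``.  Sampling is done in
    aggregate (multinomial over the induced per-base read probabilities),
    which is distributionally identical to per-read simulation.
    """
    if not haplotypes:
        raise ValueError("empty haplotype set")
    sites = {h.site for h in haplotypes}
    loci = {h.locus_id for h in haplotypes}
    if len(sites) != 1 or len(loci) != 1:
        raise ValueError("haplotypes must share one site and one locus")
    rng = np.random.default_rng(seed)

    matrix = np.stack([h.codes for h in haplotypes])  # (n, L)
    n, length = matrix.shape
    pool_freq = np.zeros((length, 4))
    for b in range(4):
        pool_freq[:, b] = (matrix == b).sum(axis=0) / n
    e = model.error_rate
    read_prob = pool_freq * (1.0 - e) + (1.0 - pool_freq) * (e / 3.0)

    depth = rng.poisson(model.mean_depth, size=length)
    base_counts = rng.multinomial(depth, read_prob)
    forward = rng.binomial(base_counts, model.strand_prob)
    counts = np.stack([forward, base_counts - forward], axis=-1)
    return PoolPileup(site=sites.pop(), locus_id=loci.pop(), counts=counts)


@dataclass(frozen=True)
class StudyBundle:
    """Everything one simulated study produced, plus its ground truth.

    ``truth`` has one row per (locus, position) where at least one simulated
    haplotype differs from the reference: the reference base, the
    alternative alleles with their carriers, and whether the column
    segregates (>= 2 distinct alleles among the sampled haplotypes).
    ``events`` is the raw substitution log with lineage of origin.
    """

    design: SamplingDesign
    loci: tuple[ReferenceLocus, ...]
    scenario_by_region: dict[str, ScenarioConfig]
    model: SequencingModel
    haplotypes: dict[str, list[Haplotype]]
    pileups: dict[tuple[str, str], PoolPileup]
    truth: pd.DataFrame
    events: pd.DataFrame

    def haplotypes_for(self, site: str, locus_id: str) -> list[Haplotype]:
        return [h for h in self.haplotypes[locus_id] if h.site == site]


_EVENT_COLUMNS = [
    "locus", "region", "level", "lineage", "site", "individual",
    "position", "from_base", "to_base",
]
_TRUTH_COLUMNS = [
    "locus", "position", "ref_allele", "alt_alleles", "carriers",
    "n_carriers", "segregating",
]


def _build_truth(loci, haplotypes_by_locus) -> pd.DataFrame:
    rows = []
    for locus in loci:
        haps = haplotypes_by_locus[locus.locus_id]
        matrix = np.stack([h.codes for h in haps])
        ref = locus.codes
        diff_cols = np.nonzero((matrix != ref).any(axis=0))[0]
        for pos in diff_cols:
            column = matrix[:, pos]
            alts = sorted({BASES[int(c)] for c in column if c != ref[pos]})
            carriers = [
                haps[i].individual_id for i in np.nonzero(column != ref[pos])[0]
            ]
            rows.append(
                {
                    "locus": locus.locus_id,
                    "position": int(pos),
                    "ref_allele": BASES[int(ref[pos])],
                    "alt_alleles": ",".join(alts),
                    "carriers": ",".join(carriers),
                    "n_carriers": len(carriers),
                    "segregating": len(np.unique(column)) > 1,
                }
            )
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def generate_study(
    design: SamplingDesign,
    loci: list[ReferenceLocus],
    scenario_by_region: dict[str, ScenarioConfig],
    model: SequencingModel,
    seed: int,
) -> StudyBundle:
    """Simulate the full study: haplotypes, pileups, and ground truth.

    Deterministic given ``seed``: all child random streams are spawned from
    one ``SeedSequence`` in a fixed order (loci outer, regions / site-locus
    pairs inner).
    """
    for region in design.regions:
        if region not in scenario_by_region:
            raise ValueError(f"no scenario configured for region {region!r}")

    root = np.random.SeedSequence(seed)
    n_hap_streams = len(loci) * len(design.regions)
    n_pileup_streams = len(design.sites) * len(loci)
    children = root.spawn(n_hap_streams + n_pileup_streams)
    stream = iter(children)

    events: list = []
    haplotypes_by_locus: dict[str, list[Haplotype]] = {}
    for locus in loci:
        haps: list[Haplotype] = []
        for region in design.regions:
            rng = np.random.default_rng(next(stream))
            haps.extend(
                _simulate_region(
                    design, region, locus, scenario_by_region[region], rng, events
                )
            )
        haplotypes_by_locus[locus.locus_id] = haps

    pileups: dict[tuple[str, str], PoolPileup] = {}
    for site in design.site_labels:
        for locus in loci:
            site_haps = [
                h for h in haplotypes_by_locus[locus.locus_id] if h.site == site
            ]
            pileups[(site, locus.locus_id)] = simulate_pool_pileup(
                site_haps, model, next(stream)
            )

    truth = _build_truth(loci, haplotypes_by_locus)
    events_df = pd.DataFrame(events, columns=_EVENT_COLUMNS)
    return StudyBundle(
        design=design,
        loci=tuple(loci),
        scenario_by_region=dict(scenario_by_region),
        model=model,
        haplotypes=haplotypes_by_locus,
        pileups=pileups,
        truth=truth,
        events=events_df,
    )
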