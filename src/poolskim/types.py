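"""Core domain types shared across the pipeline.

The pipeline models a pooled genome-skimming study: at each sampling site a
fixed number of individuals (default 8) are pooled into one sequencing
library, and high-copy loci (a chloroplast genome and a nuclear ribosomal
repeat) are deeply covered.  Sites are nested in catchments (river drainage
basins), catchments in regions — the hierarchy along which SNP privacy and
diversity statistics are later attributed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: integer code used for masked/ambiguous positions in consensus matrices
N_CODE = 4

#: default assembled locus lengths (bp) for the two high-copy fractions
CP_LOCUS_LENGTH = 124_678
NR_LOCUS_LENGTH = 5_813

FOUNDER_EXPANSION = "founder_expansion"
PERSISTENCE = "persistence"


def seq_to_codes(sequence: str) -> np.ndarray:
    """Encode an ACGT(N) string as uint8 codes (A=0..T=3, N=4)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    lut[ord("N")] = N_CODE
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = lut[raw]
    if (codes == 255).any():
        bad = sequence[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    alphabet = np.frombuffer((BASES + "N").encode("ascii"), dtype=np.uint8)
    return alphabet[codes].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT string, e.g. for a synthetic reference locus."""
    return codes_to_seq(rng.integers(0, 4, size=length).astype(np.uint8))


@dataclass(frozen=True)
class ReferenceLocus:
    """A reference locus against which haplotypes and pileups are defined.

    Parameters
    ----------
    locus_id : str
        Label, conventionally ``cpDNA`` or ``nrDNA``.
    sequence : str
        Reference sequence over {A, C, G, T}.
    intra_individual_variants : float, default 0
        Mean number of intra-genomic variant positions carried by each
        individual, emulating heterogeneity among the tandem copies of a
        multi-copy locus (nrDNA).  Single-copy organellar loci use 0.
    """

    locus_id: str
    sequence: str
    intra_individual_variants: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("locus sequence must be non-empty")
        if self.intra_individual_variants < 0:
            raise ValueError("intra_individual_variants must be >= 0")
        seq_to_codes(self.sequence)  # alphabet check

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return seq_to_codes(self.sequence)

    @classmethod
    def random(
        cls,
        locus_id: str,
        length: int,
        seed: int | np.random.Generator,
        intra_individual_variants: float = 0.0,
    ) -> "ReferenceLocus":
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        return cls(locus_id, random_sequence(length, rng), intra_individual_variants)


def default_loci(seed: int = 0) -> list[ReferenceLocus]:
    """Two synthetic reference loci at the default assembled lengths.

    cpDNA: 124,678 bp single-copy plastid genome; nrDNA: 5,813 bp multi-copy
    ribosomal repeat with mild intra-individual copy heterogeneity.
    """
    rng = np.random.default_rng(seed)
    return [
        ReferenceLocus.random("cpDNA", CP_LOCUS_LENGTH, rng),
        ReferenceLocus.random("nrDNA", NR_LOCUS_LENGTH, rng, intra_individual_variants=2.0),
    ]


@dataclass(frozen=True)
class SamplingDesign:
    """The region -> catchment -> site hierarchy and pool size.

    ``catchments`` maps each catchment to its region; ``sites`` maps each
    site to its catchment.  Ordering of the mappings is preserved and used
    for all deterministic output ordering.
    """

    regions: tuple[str, ...]
    catchments: dict[str, str]
    sites: dict[str, str]
    pool_size: int = 8

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region labels")
        for catchment, region in self.catchments.items():
            if region not in self.regions:
                raise ValueError(f"catchment {catchment!r} maps to unknown region {region!r}")
        for site, catchment in self.sites.items():
            if catchment not in self.catchments:
                raise ValueError(f"site {site!r} maps to unknown catchment {catchment!r}")

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(self.sites)

    @property
    def catchment_labels(self) -> tuple[str, ...]:
        return tuple(self.catchments)

    def catchment_of(self, site: str) -> str:
        return self.sites[site]

    def region_of_site(self, site: str) -> str:
        return self.catchments[self.sites[site]]

    def sites_in_catchment(self, catchment: str) -> tuple[str, ...]:
        if catchment not in self.catchments:
            raise KeyError(f"unknown catchment {catchment!r}")
        return tuple(s for s, c in self.sites.items() if c == catchment)

    def catchments_in_region(self, region: str) -> tuple[str, ...]:
        if region not in self.regions:
            raise KeyError(f"unknown region {region!r}")
        return tuple(c for c, r in self.catchments.items() if r == region)

    def sites_in_region(self, region: str) -> tuple[str, ...]:
        return tuple(
            s for c in self.catchments_in_region(region) for s in self.sites_in_catchment(c)
        )

    @property
    def n_individuals(self) -> int:
        return len(self.sites) * self.pool_size

    @classmethod
    def default(cls) -> "SamplingDesign":
        """The 12-site, 96-individual design: 3 AWT catchments (1 site each)
        and 3 NNSW catchments (1 + 4 + 4 sites), 8 individuals per pool."""
        return cls(
            regions=("AWT", "NNSW"),
            catchments={
                "Daintree": "AWT",
                "Mulgrave-Russell": "AWT",
                "Johnstone": "AWT",
                "Tweed": "NNSW",
                "Richmond": "NNSW",
                "Clarence": "NNSW",
            },
            sites={
                "CTBH": "Daintree",
                "CF": "Mulgrave-Russell",
                "GCK": "Johnstone",
                "HS": "Tweed",
                "BS": "Richmond",
                "Booy": "Richmond",
                "BH": "Richmond",
                "VP": "Richmond",
                "RAM": "Clarence",
                "OG": "Clarence",
                "CC": "Clarence",
                "OW": "Clarence",
            },
            pool_size=8,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for one dispersal regime.

    ``founder_expansion`` models rapid recent spread from few maternal
    founders: every site in a region descends from one of
    ``n_founder_lineages`` (typically 1) lineages, and accumulates private
    mutations only over the short ``founder_age``.  ``persistence`` models
    long local history and/or multiple founders: each catchment carries its
    own founding lineage, and lineages have diverged for
    ``lineage_divergence`` generations — much longer than ``founder_age``.

    Times are in generations; ``mutation_rate`` is substitutions per site
    per generation.
    """

    scenario: str
    n_founder_lineages: int = 1
    founder_age: float = 0.0
    lineage_divergence: float = 0.0
    mutation_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (FOUNDER_EXPANSION, PERSISTENCE):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_founder_lineages < 1:
            raise ValueError("n_founder_lineages must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.founder_age < 0 or self.lineage_divergence < 0:
            raise ValueError("times must be >= 0")


@dataclass(frozen=True)
class Haplotype:
    """One individual's maternal haplotype at one locus."""

    individual_id: str
    site: str
    locus_id: str
    sequence: str

    @property
    def codes(self) -> np.ndarray:
        return seq_to_codes(self.sequence)


@dataclass(frozen=True)
class SequencingModel:
    """Shotgun sequencing digest: per-position depth is Poisson with mean
    ``mean_depth``; each read miscalls its base with probability
    ``error_rate`` (uniform over the 3 other bases) and is assigned to the
    forward strand with probability ``strand_prob``."""

    mean_depth: float = 50.0
    error_rate: float = 0.002
    strand_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if not 0 < self.strand_prob < 1:
            raise ValueError("strand_prob must be in (0, 1)")
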