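"""Within-pool variant detection and masked consensus building.

A pooled library of ``pool_size`` individuals is reduced to, per position,
base counts split by strand.  Calling follows three rules: positions with
total depth below ``min_coverage`` (default 20x) are masked to N; the
consensus is the plurality base; a non-consensus base is reported as a
within-pool variant when its frequency (over all reads at the position)
reaches ``min_variant_frequency`` — default 1/pool_size = 12.5%, one
individual's contribution to the pool — and, if ``require_both_strands``,
it is seen on at least one forward and one reverse read.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import BASES, BASE_INDEX, N_CODE

__all__ = [
    "PoolPileup",
    "PoolCallerConfig",
    "MinorAllele",
    "VariantCall",
    "PoolConsensus",
    "call_pool",
    "call_study",
]


@dataclass(frozen=True)
class PoolPileup:
    """Per-position, per-strand base counts for one site-pool at one locus.

    ``counts`` has shape (L, 4, 2): position x base (ACGT order) x strand
    (forward, reverse).
    """

    site: str
    locus_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.shape[1:] != (4, 2):
            raise ValueError("counts must have shape (L, 4, 2)")
        if (counts < 0).any():
            raise ValueError("negative read counts")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        """Total reads per position (both strands, all bases)."""
        return self.counts.sum(axis=(1, 2))


@dataclass(frozen=True)
class PoolCallerConfig:
    min_coverage: int = 20
    min_variant_frequency: float = 0.125
    require_both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_variant_frequency <= 0.5:
            raise ValueError("min_variant_frequency must be in (0, 0.5]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(frozen=True)
class MinorAllele:
    base: str
    frequency: float
    forward_support: bool
    reverse_support: bool


@dataclass(frozen=True)
class VariantCall:
    """A position with at least one confirmed within-pool minor allele.

    ``position`` is a 0-based locus coordinate (1-based only in exported
    tables)."""

    position: int
    major_allele: str
    minor_alleles: tuple[MinorAllele, ...]
    depth: int


@dataclass(frozen=True)
class PoolConsensus:
    """Masked consensus plus within-pool variant calls for one site-pool."""

    site: str
    locus_id: str
    sequence: str
    variants: tuple[VariantCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        for v in self.variants:
            if self.sequence[v.position] == "N":
                raise ValueError(
                    f"variant at masked position {v.position} in pool {self.site!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def variant_positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.variants)

    @property
    def masked(self) -> np.ndarray:
        return np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8) == ord("N")


def call_pool(
    pileup: PoolPileup,
    config: PoolCallerConfig = PoolCallerConfig(),
    reference: str | None = None,
) -> PoolConsensus:
    """Apply the coverage / frequency / strand rules to one pileup.

    ``reference`` (optional, same length as the pileup) only breaks exact
    plurality ties: the reference base wins if it is among the tied maxima,
    otherwise the alphabetically first tied base is chosen and the other is
    still eligible as a minor allele.
    """
    totals = pileup.counts.sum(axis=2)  # (L, 4)
    depth = totals.sum(axis=1)
    masked = depth < config.min_coverage

    # plurality consensus; np.argmax resolves ties to the lowest base index,
    # i.e. alphabetically first
    consensus_idx = np.argmax(totals, axis=1)
    if reference is not None:
        if len(reference) != pileup.length:
            raise ValueError("reference length mismatch")
        ref_idx = np.array([BASE_INDEX.get(b, N_CODE) for b in reference])
        valid_ref = ref_idx < 4
        max_count = totals.max(axis=1)
        ref_count = np.where(valid_ref, totals[np.arange(len(ref_idx)), np.minimum(ref_idx, 3)], -1)
        ref_wins = valid_ref & (ref_count == max_count)
        consensus_idx = np.where(ref_wins, ref_idx, consensus_idx)

    seq_codes = np.where(masked, N_CODE, consensus_idx).astype(np.uint8)
    alphabet = np.frombuffer((BASES + "N").encode("ascii"), dtype=np.uint8)
    sequence = alphabet[seq_codes].tobytes().decode("ascii")

    # candidate minor alleles: unmasked positions, non-consensus base with
    # frequency >= threshold (denominator = all reads at the position)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth[:, None] > 0, totals / np.maximum(depth, 1)[:, None], 0.0)
    is_consensus = np.zeros_like(totals, dtype=bool)
    is_consensus[np.arange(pileup.length), consensus_idx] = True
    candidate = (
        ~masked[:, None]
        & ~is_consensus
        & (totals > 0)
        & (freq >= config.min_variant_frequency - 1e-12)
    )
    if config.require_both_strands:
        candidate &= (pileup.counts[:, :, 0] > 0) & (pileup.counts[:, :, 1] > 0)

    variants: list[VariantCall] = []
    for pos in np.nonzero(candidate.any(axis=1))[0]:
        minors = tuple(
            MinorAllele(
                base=BASES[b],
                frequency=float(totals[pos, b] / depth[pos]),
                forward_support=bool(pileup.counts[pos, b, 0] > 0),
                reverse_support=bool(pileup.counts[pos, b, 1] > 0),
            )
            for b in np.nonzero(candidate[pos])[0]
        )
        variants.append(
            VariantCall(
                position=int(pos),
                major_allele=BASES[int(consensus_idx[pos])],
                minor_alleles=minors,
                depth=int(depth[pos]),
            )
        )
    return PoolConsensus(
        site=pileup.site, locus_id=pileup.locus_id, sequence=sequence, variants=tuple(variants)
    )


def call_study(
    pileups: list[PoolPileup],
    config: PoolCallerConfig = PoolCallerConfig(),
    references: dict[str, str] | None = None,
) -> list[PoolConsensus]:
    """Call every pileup independently; order of the input is preserved.

    ``references`` optionally maps locus_id to a reference sequence used for
    consensus tie-breaking.  Duplicate (site, locus) pileups are rejected.
    """
    seen: set[tuple[str, str]] = set()
    out: list[PoolConsensus] = []
    for pileup in pileups:
        key = (pileup.site, pileup.locus_id)
        if key in seen:
            raise ValueError(f"duplicate pileup for site/locus {key}")
        seen.add(key)
        ref = references.get(pileup.locus_id) if references else None
        out.append(call_pool(pileup, config, reference=ref))
    return out
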