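"""Consensus alignment and SNP classification along the sampling hierarchy.

Site consensuses for one locus share reference coordinates, so "alignment"
is positional stacking — no realignment.  Columns masked (N) in any site are
excluded from analysis everywhere, mirroring the removal of low-coverage
areas before annotation.  Each analysable polymorphic column becomes one
SNP record, classified as:

* ``fixed_difference`` — consensus bases differ between sites and no pool
  shows a within-pool variant at the column;
* ``within_pool_only`` — consensuses agree but at least one pool is
  internally polymorphic at the column;
* ``mixed`` — both at once (consensuses differ *and* some pool is
  internally polymorphic); these columns are excluded from fixed-difference
  counting, the conservative reading.

Privacy is assessed on minority-allele carriers: a SNP is private to a
group (site, catchment or region) when every site carrying a non-majority
allele lies in that group and at least one scored site lies outside it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caller import PoolConsensus, VariantCall
from .types import BASES, N_CODE, SamplingDesign, seq_to_codes

__all__ = [
    "ConsensusAlignment",
    "SNPRecord",
    "FIXED_DIFFERENCE",
    "WITHIN_POOL_ONLY",
    "MIXED",
    "build_alignment",
    "classify_snps",
    "count_unique_fixed",
    "count_between",
]

FIXED_DIFFERENCE = "fixed_difference"
WITHIN_POOL_ONLY = "within_pool_only"
MIXED = "mixed"


@dataclass(frozen=True)
class ConsensusAlignment:
    """Positional alignment of site consensuses for one locus.

    ``codes`` is a (n_sites, L) uint8 matrix (A=0..T=3, N=4);
    ``analysable`` flags columns unmasked in every site.
    """

    locus_id: str
    sites: tuple[str, ...]
    codes: np.ndarray
    analysable: np.ndarray

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def analysable_columns(self) -> np.ndarray:
        return np.nonzero(self.analysable)[0]

    @property
    def analysable_length(self) -> int:
        return int(self.analysable.sum())

    def row(self, site: str) -> np.ndarray:
        return self.codes[self.sites.index(site)]


def build_alignment(consensuses: list[PoolConsensus]) -> ConsensusAlignment:
    """Stack same-locus consensuses into a shared-coordinate alignment."""
    if not consensuses:
        raise ValueError("no consensuses to align")
    loci = {c.locus_id for c in consensuses}
    if len(loci) != 1:
        raise ValueError(f"consensuses span multiple loci: {sorted(loci)}")
    lengths = {c.length for c in consensuses}
    if len(lengths) != 1:
        raise ValueError(f"consensus length mismatch: {sorted(lengths)}")
    codes = np.stack([seq_to_codes(c.sequence) for c in consensuses])
    analysable = (codes != N_CODE).all(axis=0)
    return ConsensusAlignment(
        locus_id=loci.pop(),
        sites=tuple(c.site for c in consensuses),
        codes=codes,
        analysable=analysable,
    )


@dataclass(frozen=True)
class SNPRecord:
    """One polymorphic analysable column with its hierarchy attribution."""

    locus_id: str
    position: int
    alleles_by_site: dict[str, str]
    kind: str
    majority_allele: str
    minority_sites: frozenset[str]
    within_pool_sites: frozenset[str]
    private_to_site: str | None = None
    private_to_catchment: str | None = None
    private_to_region: str | None = None


def _privacy(
    minority_sites: frozenset[str],
    all_sites: tuple[str, ...],
    design: SamplingDesign,
) -> tuple[str | None, str | None, str | None]:
    """Finest group containing every minority carrier, with at least one
    scored site outside the group at each level."""
    if not minority_sites:
        return None, None, None
    site = next(iter(minority_sites)) if len(minority_sites) == 1 else None
    if site is not None and not (set(all_sites) - {site}):
        site = None

    catchments = {design.catchment_of(s) for s in minority_sites}
    catchment = catchments.pop() if len(catchments) == 1 else None
    if catchment is not None and not any(
        design.catchment_of(s) != catchment for s in all_sites
    ):
        catchment = None

    regions = {design.region_of_site(s) for s in minority_sites}
    region = regions.pop() if len(regions) == 1 else None
    if region is not None and not any(
        design.region_of_site(s) != region for s in all_sites
    ):
        region = None
    return site, catchment, region


def classify_snps(
    alignment: ConsensusAlignment,
    variants_by_site: dict[str, list[VariantCall]],
    design: SamplingDesign,
) -> list[SNPRecord]:
    """Turn every analysable polymorphic column into one classified record.

    A column is polymorphic when site consensuses disagree and/or any pool
    has a within-pool variant call there.  The classification partitions the
    polymorphic analysable columns.
    """
    unknown = set(alignment.sites) - set(design.sites)
    if unknown:
        raise ValueError(f"alignment sites not in design: {sorted(unknown)}")

    site_index = {s: i for i, s in enumerate(alignment.sites)}
    within_at: dict[int, set[str]] = {}
    for site, calls in variants_by_site.items():
        if site not in site_index:
            continue
        row = alignment.codes[site_index[site]]
        for call in calls:
            if row[call.position] == N_CODE:
                raise ValueError(
                    f"within-pool variant reported at masked column {call.position} "
                    f"of site {site!r}"
                )
            within_at.setdefault(call.position, set()).add(site)

    codes = alignment.codes
    differing = np.zeros(alignment.length, dtype=bool)
    differing[alignment.analysable] = (
        codes[:, alignment.analysable] != codes[0, alignment.analysable]
    ).any(axis=0)

    positions = set(np.nonzero(differing)[0].tolist())
    positions.update(p for p in within_at if alignment.analysable[p])
    records: list[SNPRecord] = []
    for pos in sorted(positions):
        column = codes[:, pos]
        alleles_by_site = {s: BASES[int(column[i])] for i, s in enumerate(alignment.sites)}
        has_fixed = bool(differing[pos])
        pool_sites = frozenset(within_at.get(pos, set()))
        if has_fixed and pool_sites:
            kind = MIXED
        elif has_fixed:
            kind = FIXED_DIFFERENCE
        else:
            kind = WITHIN_POOL_ONLY

        # majority allele by site count; ties to the alphabetically first base
        counts = np.bincount(column, minlength=4)
        majority = int(np.argmax(counts))
        minority_sites = frozenset(
            s for i, s in enumerate(alignment.sites) if column[i] != majority
        )
        private_site, private_catchment, private_region = _privacy(
            minority_sites, alignment.sites, design
        )
        records.append(
            SNPRecord(
                locus_id=alignment.locus_id,
                position=int(pos),
                alleles_by_site=alleles_by_site,
                kind=kind,
                majority_allele=BASES[majority],
                minority_sites=minority_sites,
                within_pool_sites=pool_sites,
                private_to_site=private_site,
                private_to_catchment=private_catchment,
                private_to_region=private_region,
            )
        )
    return records


def count_unique_fixed(
    records: list[SNPRecord], catchment: str, design: SamplingDesign
) -> int:
    """Fixed SNPs whose minority allele is confined to one catchment."""
    if catchment not in design.catchments:
        raise KeyError(f"unknown catchment {catchment!r}")
    return sum(
        1
        for r in records
        if r.kind == FIXED_DIFFERENCE and r.private_to_catchment == catchment
    )


def count_between(
    records: list[SNPRecord],
    alignment: ConsensusAlignment,
    group_a: set[str],
    group_b: set[str],
) -> int:
    """Fixed differences separating two site groups.

    Counts analysable columns where all of ``group_a`` share one base, all
    of ``group_b`` share a different base, and no member pool has a
    within-pool variant at the column.  Symmetric in its group arguments.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    missing = (group_a | group_b) - set(alignment.sites)
    if missing:
        raise ValueError(f"sites not in alignment: {sorted(missing)}")

    members = group_a | group_b
    n = 0
    for r in records:
        if r.locus_id != alignment.locus_id:
            continue
        if r.within_pool_sites & members:
            continue
        a_bases = {r.alleles_by_site[s] for s in group_a}
        b_bases = {r.alleles_by_site[s] for s in group_b}
        if len(a_bases) == 1 and len(b_bases) == 1 and a_bases != b_bases:
            n += 1
    return n
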