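"""Hierarchical diversity statistics and distance summaries.

Reporting conventions: per-bp SNP rates divide by the *full* assembled
locus length (not the unmasked length) — this is what makes printed
(count, rate) pairs mutually checkable as rate = count / L — with
unmasked-length variants available as supplementary values.  Display
rounding is 2 significant figures in the ``1.3x10-3`` style; raw floats are
always retained in machine output.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .caller import PoolConsensus
from .catalog import SNPRecord, build_alignment, count_unique_fixed
from .types import N_CODE, ReferenceLocus, SamplingDesign, seq_to_codes

__all__ = [
    "format_rate",
    "snp_per_bp",
    "percent_polymorphic",
    "count_differences",
    "pairwise_distance",
    "DistanceMatrix",
    "distance_matrix",
    "collapse_to_catchments",
    "group_average_distance",
    "avg_within_pool_variants",
    "DiversityReport",
    "build_report",
]


def format_rate(value: float) -> str:
    """2-significant-figure scientific string in the ``1.3x10-3`` style."""
    if value == 0:
        return "0"
    if value < 0:
        raise ValueError("rate must be >= 0")
    exponent = math.floor(math.log10(value))
    mantissa = round(value / 10**exponent, 1)
    if mantissa >= 10.0:  # rounding pushed into the next decade
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.1f}x10{exponent}"


def snp_per_bp(count: int, locus_length: int) -> tuple[float, str]:
    """SNPs per base pair over the full assembled locus length."""
    if locus_length <= 0:
        raise ValueError("locus_length must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    rate = count / locus_length
    return rate, format_rate(rate)


def percent_polymorphic(count: int, locus_length: int) -> tuple[float, str]:
    """Percentage of the locus that is polymorphic, rounded to 2 decimals."""
    if locus_length <= 0:
        raise ValueError("locus_length must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    pct = round(100.0 * count / locus_length, 2)
    return pct, f"{pct:.2f}%"


def count_differences(a: PoolConsensus, b: PoolConsensus) -> int:
    """Columns unmasked in both consensuses where the bases differ."""
    if a.locus_id != b.locus_id:
        raise ValueError(f"locus mismatch: {a.locus_id!r} vs {b.locus_id!r}")
    if a.length != b.length:
        raise ValueError("consensus length mismatch")
    ca, cb = seq_to_codes(a.sequence), seq_to_codes(b.sequence)
    both = (ca != N_CODE) & (cb != N_CODE)
    return int((ca[both] != cb[both]).sum())


def pairwise_distance(a: PoolConsensus, b: PoolConsensus, locus_length: int) -> float:
    """p-distance per bp of full locus length: differing columns / L."""
    if locus_length <= 0:
        raise ValueError("locus_length must be > 0")
    return count_differences(a, b) / locus_length


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric per-bp distance matrix over site or catchment labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(values, values.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        if (values < -1e-15).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    consensuses: list[PoolConsensus], locus_length: int
) -> DistanceMatrix:
    """Site-level pairwise p-distance matrix, in input order."""
    labels = tuple(c.site for c in consensuses)
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = pairwise_distance(consensuses[i], consensuses[j], locus_length)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def collapse_to_catchments(
    matrix: DistanceMatrix, design: SamplingDesign
) -> DistanceMatrix:
    """Catchment-level matrix: unweighted mean over cross-catchment site
    pairs (catchments appear in design order)."""
    catchments = [
        c for c in design.catchment_labels
        if any(s in matrix.labels for s in design.sites_in_catchment(c))
    ]
    idx = {s: i for i, s in enumerate(matrix.labels)}
    n = len(catchments)
    values = np.zeros((n, n))
    for a, b in combinations(range(n), 2):
        pairs = [
            (idx[sa], idx[sb])
            for sa in design.sites_in_catchment(catchments[a])
            if sa in idx
            for sb in design.sites_in_catchment(catchments[b])
            if sb in idx
        ]
        d = float(np.mean([matrix.values[i, j] for i, j in pairs]))
        values[a, b] = values[b, a] = d
    return DistanceMatrix(labels=tuple(catchments), values=values)


def group_average_distance(
    matrix: DistanceMatrix,
    groups: dict[str, str],
    locus_length: int,
) -> dict[tuple, tuple[float, int]]:
    """Unweighted within- and between-group means over label pairs.

    ``groups`` maps each matrix label (catchment) to its group (region).
    Returns ``{("within", g): (mean_distance, snp_count), ("between", g1,
    g2): ...}`` where the SNP count is mean distance x locus length rounded
    to the nearest integer.  Within-group entries need >= 2 members.
    """
    missing = set(matrix.labels) - set(groups)
    if missing:
        raise ValueError(f"ungrouped labels: {sorted(missing)}")
    by_group: dict[str, list[str]] = {}
    for label in matrix.labels:
        by_group.setdefault(groups[label], []).append(label)

    out: dict[tuple, tuple[float, int]] = {}
    for g, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has < 2 members for a within-group mean")
        dists = [matrix[a, b] for a, b in combinations(members, 2)]
        mean = float(np.mean(dists))
        out[("within", g)] = (mean, int(round(mean * locus_length)))
    for g1, g2 in combinations(by_group, 2):
        dists = [matrix[a, b] for a in by_group[g1] for b in by_group[g2]]
        mean = float(np.mean(dists))
        out[("between", g1, g2)] = (mean, int(round(mean * locus_length)))
    return out


def avg_within_pool_variants(
    consensuses_by_catchment: dict[str, list[PoolConsensus]],
) -> dict[str, float]:
    """Mean within-pool variant-position count per catchment (may be
    fractional, e.g. 9.5)."""
    out: dict[str, float] = {}
    for catchment, consensuses in consensuses_by_catchment.items():
        if not consensuses:
            raise ValueError(f"catchment {catchment!r} has no sites")
        out[catchment] = float(np.mean([len(c.variants) for c in consensuses]))
    return out


@dataclass(frozen=True)
class DiversityReport:
    """Machine-readable diversity summary: one row per catchment plus
    within-/between-region group rows, per locus."""

    catchment_rows: list[dict] = field(default_factory=list)
    group_rows: list[dict] = field(default_factory=list)
    locus_lengths: dict[str, int] = field(default_factory=dict)
    analysable_lengths: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "locus_lengths": self.locus_lengths,
            "analysable_lengths": self.analysable_lengths,
            "catchments": self.catchment_rows,
            "groups": self.group_rows,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def catchment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.catchment_rows)

    def group_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.group_rows)

    @property
    def n_rows(self) -> int:
        return len(self.catchment_rows) + len(self.group_rows)


def build_report(
    records_by_locus: dict[str, list[SNPRecord]],
    consensuses_by_locus: dict[str, list[PoolConsensus]],
    design: SamplingDesign,
    loci: list[ReferenceLocus],
) -> DiversityReport:
    """Assemble the full diversity report from classified SNPs and
    consensuses.

    Catchment rows carry, per locus: the unique (catchment-private) fixed
    SNP count with its per-bp rate, the per-analysable-bp rate as a
    supplementary value, and the mean within-pool variant count.  Group
    rows carry within-region and between-region mean catchment distances
    with the implied SNP counts.
    """
    locus_lengths = {l.locus_id: l.length for l in loci}
    for locus_id in records_by_locus:
        if locus_id not in locus_lengths:
            raise ValueError(f"records for unknown locus {locus_id!r}")

    alignments = {
        locus_id: build_alignment(consensuses)
        for locus_id, consensuses in consensuses_by_locus.items()
    }
    analysable_lengths = {
        locus_id: aln.analysable_length for locus_id, aln in alignments.items()
    }

    catchment_rows: list[dict] = []
    for catchment in design.catchment_labels:
        sites = design.sites_in_catchment(catchment)
        row: dict = {
            "catchment": catchment,
            "region": design.catchments[catchment],
            "n_sites": len(sites),
            "n_individuals": len(sites) * design.pool_size,
        }
        for locus in loci:
            lid = locus.locus_id
            records = records_by_locus.get(lid, [])
            unique = count_unique_fixed(records, catchment, design)
            rate, disp = snp_per_bp(unique, locus.length)
            row[f"{lid}_unique_fixed"] = unique
            row[f"{lid}_per_bp"] = rate
            row[f"{lid}_per_bp_display"] = disp
            analysable = analysable_lengths.get(lid, locus.length)
            row[f"{lid}_per_analysable_bp"] = (
                unique / analysable if analysable else float("nan")
            )
            pool = [
                c for c in consensuses_by_locus.get(lid, []) if c.site in sites
            ]
            row[f"{lid}_avg_within_pool_variants"] = (
                float(np.mean([len(c.variants) for c in pool])) if pool else float("nan")
            )
        catchment_rows.append(row)

    region_of_catchment = dict(design.catchments)
    group_rows: list[dict] = []
    group_keys: list[tuple] = [("within", r) for r in design.regions]
    group_keys += [
        ("between", a, b) for a, b in combinations(design.regions, 2)
    ]
    per_locus_group: dict[str, dict] = {}
    for locus in loci:
        lid = locus.locus_id
        consensuses = consensuses_by_locus.get(lid)
        if not consensuses:
            continue
        site_matrix = distance_matrix(consensuses, locus.length)
        catchment_matrix = collapse_to_catchments(site_matrix, design)
        per_locus_group[lid] = group_average_distance(
            catchment_matrix, region_of_catchment, locus.length
        )
    for key in group_keys:
        if key[0] == "within":
            label, n_sites = key[1], len(design.sites_in_region(key[1]))
        else:
            label = f"{key[1]} vs {key[2]}"
            n_sites = len(design.sites_in_region(key[1])) + len(
                design.sites_in_region(key[2])
            )
        row = {
            "comparison": key[0],
            "group": label,
            "n_sites": n_sites,
            "n_individuals": n_sites * design.pool_size,
        }
        for locus in loci:
            lid = locus.locus_id
            if lid not in per_locus_group or key not in per_locus_group[lid]:
                continue
            mean, snps = per_locus_group[lid][key]
            row[f"{lid}_distance"] = mean
            row[f"{lid}_distance_display"] = format_rate(mean)
            row[f"{lid}_n_snps"] = snps
        group_rows.append(row)

    return DiversityReport(
        catchment_rows=catchment_rows,
        group_rows=group_rows,
        locus_lengths=locus_lengths,
        analysable_lengths=analysable_lengths,
    )
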