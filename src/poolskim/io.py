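"""Text formats: pileup TSV, FASTA, variant TSV, SNP table, report files.

All outputs are UTF-8, LF, deterministically ordered (sites in design
order, positions ascending).  Positions are 0-based internally and 1-based
in every exported table.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import MinorAllele, PoolConsensus, PoolPileup, VariantCall
from .catalog import SNPRecord
from .types import BASES, BASE_INDEX, Haplotype

__all__ = [
    "write_pileup_tsv",
    "read_pileup_tsv",
    "write_haplotypes_fasta",
    "read_haplotypes_fasta",
    "write_consensus_fasta",
    "read_consensus_fasta",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_snp_table",
]

PILEUP_COLUMNS = ["locus", "pos", "A_f", "A_r", "C_f", "C_r", "G_f", "G_r", "T_f", "T_r"]


def write_pileup_tsv(pileup: PoolPileup, path: str | Path) -> None:
    """One row per position: locus, pos (1-based), then per-base
    forward/reverse counts.  The site label travels in a ``# site=`` header
    comment so the round-trip is lossless."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# site={pileup.site}\n")
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        counts = pileup.counts
        for pos in range(pileup.length):
            cells = [pileup.locus_id, str(pos + 1)]
            for b in range(4):
                cells.append(str(int(counts[pos, b, 0])))
                cells.append(str(int(counts[pos, b, 1])))
            fh.write("\t".join(cells) + "\n")


def read_pileup_tsv(path: str | Path, site: str | None = None) -> PoolPileup:
    """Parse a pileup TSV; file pos 1 maps to internal position 0."""
    path = Path(path)
    rows: list[list[int]] = []
    locus_id = ""
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("# ")
                if stripped.startswith("site="):
                    site = site or stripped[len("site="):]
                continue
            cells = line.split("\t")
            if not header_seen:
                if cells != PILEUP_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: bad header {cells!r}")
                header_seen = True
                continue
            if len(cells) != len(PILEUP_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(PILEUP_COLUMNS)} columns, "
                    f"got {len(cells)}"
                )
            try:
                pos = int(cells[1])
                counts = [int(c) for c in cells[2:]]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            if pos != len(rows) + 1:
                raise ValueError(
                    f"{path}:{lineno}: positions must be contiguous 1-based "
                    f"(got {pos}, expected {len(rows) + 1})"
                )
            locus_id = locus_id or cells[0]
            if cells[0] != locus_id:
                raise ValueError(f"{path}:{lineno}: mixed loci in one pileup file")
            rows.append(counts)
    if not rows:
        warnings.warn(f"empty pileup file {path}", stacklevel=2)
        return PoolPileup(
            site=site or "", locus_id=locus_id, counts=np.zeros((0, 4, 2), dtype=int)
        )
    counts = np.array(rows, dtype=np.int64).reshape(len(rows), 4, 2)
    return PoolPileup(site=site or "", locus_id=locus_id, counts=counts)


def write_haplotypes_fasta(haplotypes: list[Haplotype], path: str | Path) -> None:
    """One record per individual, id ``site|individual``."""
    records = [
        SeqRecord(Seq(h.sequence), id=h.individual_id, description=h.locus_id)
        for h in haplotypes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_haplotypes_fasta(path: str | Path, locus_id: str) -> list[Haplotype]:
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        site = record.id.split("|")[0]
        out.append(
            Haplotype(
                individual_id=record.id,
                site=site,
                locus_id=locus_id,
                sequence=str(record.seq),
            )
        )
    return out


def write_consensus_fasta(consensuses: list[PoolConsensus], path: str | Path) -> None:
    """One record per site-pool, id ``site|locus``, N for masked."""
    records = [
        SeqRecord(Seq(c.sequence), id=f"{c.site}|{c.locus_id}", description="")
        for c in consensuses
    ]
    SeqIO.write(records, str(path), "fasta")


def read_consensus_fasta(path: str | Path) -> list[PoolConsensus]:
    """Read consensuses (without their variant calls — see
    :func:`read_variants_tsv` to reattach them)."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        site, _, locus_id = record.id.partition("|")
        out.append(
            PoolConsensus(site=site, locus_id=locus_id, sequence=str(record.seq))
        )
    return out


VARIANT_COLUMNS = ["CHROM", "SITE", "POS", "REF", "ALT", "AF", "DP", "FWD", "REV"]


def write_variants_tsv(consensuses: list[PoolConsensus], path: str | Path) -> None:
    """Minimal VCF-like table: CHROM=locus, POS 1-based, REF=consensus base,
    one row per (position, minor allele)."""
    rows = []
    for c in consensuses:
        for v in c.variants:
            for m in v.minor_alleles:
                rows.append(
                    {
                        "CHROM": c.locus_id,
                        "SITE": c.site,
                        "POS": v.position + 1,
                        "REF": v.major_allele,
                        "ALT": m.base,
                        "AF": f"{m.frequency:.6f}",
                        "DP": v.depth,
                        "FWD": int(m.forward_support),
                        "REV": int(m.reverse_support),
                    }
                )
    frame = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_variants_tsv(path: str | Path) -> dict[tuple[str, str], list[VariantCall]]:
    """Variant calls keyed by (site, locus), rebuilt from the table."""
    frame = pd.read_csv(path, sep="\t", dtype={"SITE": str, "CHROM": str})
    out: dict[tuple[str, str], list[VariantCall]] = {}
    if frame.empty:
        return out
    grouped = frame.groupby(["SITE", "CHROM", "POS"], sort=True)
    for (site, locus, pos), group in grouped:
        minors = tuple(
            MinorAllele(
                base=row.ALT,
                frequency=float(row.AF),
                forward_support=bool(row.FWD),
                reverse_support=bool(row.REV),
            )
            for row in group.itertuples()
        )
        call = VariantCall(
            position=int(pos) - 1,
            major_allele=group.iloc[0]["REF"],
            minor_alleles=minors,
            depth=int(group.iloc[0]["DP"]),
        )
        out.setdefault((site, locus), []).append(call)
    for calls in out.values():
        calls.sort(key=lambda v: v.position)
    return out


def write_snp_table(records: list[SNPRecord], path: str | Path) -> None:
    """Classified SNP records as TSV (POS 1-based; alleles as
    ``site:base`` pairs)."""
    rows = []
    for r in sorted(records, key=lambda r: (r.locus_id, r.position)):
        rows.append(
            {
                "locus": r.locus_id,
                "pos": r.position + 1,
                "kind": r.kind,
                "majority_allele": r.majority_allele,
                "alleles": ",".join(f"{s}:{b}" for s, b in r.alleles_by_site.items()),
                "minority_sites": ",".join(sorted(r.minority_sites)),
                "within_pool_sites": ",".join(sorted(r.within_pool_sites)),
                "private_to_site": r.private_to_site or "",
                "private_to_catchment": r.private_to_catchment or "",
                "private_to_region": r.private_to_region or "",
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "locus", "pos", "kind", "majority_allele", "alleles",
            "minority_sites", "within_pool_sites",
            "private_to_site", "private_to_catchment", "private_to_region",
        ],
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
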