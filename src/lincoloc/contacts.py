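"""4C contact post-processing: replicate intersection, low-complexity
exclusion, extension to the assay's resolution, projection onto genes and
the read-count filter.

The canonical stage order is fixed:

    intersect replicates → exclude low-complexity → extend → assign → filter

Intersection first establishes which contact regions are reproducible;
exclusion then removes reads that live entirely inside repeat/low-complexity
annotation; extension widens each surviving contact to the fragment-level
resolution of a 6-cutter 4C assay (±2.5 kb around the contact center);
assignment credits every gene whose body the extended contact touches; and
the filter keeps genes whose summed supporting reads strictly exceed the
threshold (default 100).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .intervals import GeneAnnotation, GenomicInterval, Track

__all__ = [
    "ContactRecord",
    "GeneContactTable",
    "read_contacts_bed",
    "write_contacts_bed",
    "intersect_replicates",
    "exclude_low_complexity",
    "extend_contacts",
    "assign_contacts_to_genes",
    "filter_contact_genes",
    "quantify_contacts",
]


@dataclass(frozen=True)
class ContactRecord:
    """One mapped 4C contact region and the read count supporting it."""

    interval: GenomicInterval
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError(f"contact read count must be >= 1, got {self.reads}")


def _contacts_to_pr(contacts: Sequence[ContactRecord]) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [c.interval.chrom for c in contacts],
                "Start": [c.interval.start for c in contacts],
                "End": [c.interval.end for c in contacts],
                "reads": [c.reads for c in contacts],
            }
        )
    )


def read_contacts_bed(path: str | Path) -> list[ContactRecord]:
    """Read contacts from a 5-column BED (chrom start end name reads)."""
    recs: list[ContactRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: contacts BED needs a read count in column 5"
                )
            iv = GenomicInterval(
                fields[0], int(fields[1]), int(fields[2]),
                fields[3] if fields[3] != "." else None,
            )
            recs.append(ContactRecord(iv, int(float(fields[4]))))
    return sorted(recs, key=lambda r: r.interval)


def write_contacts_bed(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(contacts, key=lambda r: r.interval):
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t{c.reads}\n")


def intersect_replicates(
    rep1: Sequence[ContactRecord], rep2: Sequence[ContactRecord]
) -> list[ContactRecord]:
    """Keep the merged genomic regions supported by both replicates.

    Each surviving region carries the summed reads of every record (from
    either replicate) overlapping it, so total evidence is preserved and
    counts are monotone in the inputs. Disjoint replicates yield an empty
    list with a warning rather than an error.
    """
    if not rep1 or not rep2:
        raise ValueError("both replicates must be non-empty")
    g1, g2 = _contacts_to_pr(rep1), _contacts_to_pr(rep2)
    regions = g1.intersect(g2)
    if regions.empty:
        warnings.warn("replicate intersection is empty", stacklevel=2)
        return []
    regions = regions.merge()
    both = pr.PyRanges(pd.concat([g1.df, g2.df], ignore_index=True))
    joined = regions.join(both)  # region × overlapping source records
    out: list[ContactRecord] = []
    for (chrom, start, end), grp in joined.df.groupby(
        ["Chromosome", "Start", "End"], observed=True
    ):
        out.append(
            ContactRecord(GenomicInterval(str(chrom), int(start), int(end)), int(grp.reads.sum()))
        )
    return sorted(out, key=lambda r: r.interval)


def exclude_low_complexity(
    contacts: Sequence[ContactRecord], regions: Track
) -> list[ContactRecord]:
    """Drop contacts *fully contained* (100% of their span) within any single
    low-complexity region; partial overlaps survive. Mirrors an intersection
    with a minimum overlap fraction of 1.0 on the contact side."""
    if not contacts or len(regions) == 0:
        return list(contacts)
    g = _contacts_to_pr(contacts)
    kept = g.overlap(regions.to_pyranges(), how="containment", invert=True)
    if kept.empty:
        return []
    keep_keys = {
        (str(c), int(s), int(e))
        for c, s, e in zip(kept.df.Chromosome, kept.df.Start, kept.df.End)
    }
    return [
        c
        for c in contacts
        if (c.interval.chrom, c.interval.start, c.interval.end) in keep_keys
    ]


def extend_contacts(
    contacts: Sequence[ContactRecord],
    target_length: int = 5000,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[ContactRecord]:
    """Widen each contact to ``target_length`` bp, symmetric about its center.

    The replacement interval is [center − target/2, center + target/2),
    truncated at coordinate 0 (and at the chromosome end when a sizes map is
    supplied — without one the right end is unknowable). Contacts already at
    least ``target_length`` long are left untouched.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    out: list[ContactRecord] = []
    for c in contacts:
        iv = c.interval
        if iv.length >= target_length:
            out.append(c)
            continue
        center = iv.center
        start = int(math.floor(center - target_length / 2.0))
        end = start + target_length
        if start < 0:
            start = 0
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        out.append(ContactRecord(GenomicInterval(iv.chrom, start, end, iv.id), c.reads))
    return out


@dataclass
class GeneContactTable:
    """Per-gene 4C read totals with their filter state.

    ``table`` columns: gene_id, gene_name, contact_reads, passes_filter.
    ``passes_filter`` is maintained as ``contact_reads > threshold``.
    """

    table: pd.DataFrame
    threshold: int = 100

    def __post_init__(self) -> None:
        required = {"gene_id", "gene_name", "contact_reads"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gene contact table missing columns {missing}")
        self.table = self.table.copy()
        self.table["passes_filter"] = self.table["contact_reads"] > self.threshold

    @property
    def passing(self) -> pd.DataFrame:
        """Filter-passing genes, ranked by read count (descending)."""
        sub = self.table[self.table.passes_filter]
        return sub.sort_values(
            ["contact_reads", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)

    @property
    def passing_gene_ids(self) -> list[str]:
        return list(self.passing.gene_id)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.sort_values(
            ["contact_reads", "gene_id"], ascending=[False, True]
        ).to_csv(path, sep="\t", index=False)


def assign_contacts_to_genes(
    contacts: Sequence[ContactRecord],
    genes: Sequence[GeneAnnotation],
    threshold: int = 100,
) -> GeneContactTable:
    """Project contacts onto gene bodies: every gene overlapped by >= 1 bp of
    a contact is credited with that contact's full read count (a contact
    spanning several genes credits each of them). Genes with no overlapping
    contact appear with zero reads."""
    base = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_name": [g.gene_name for g in genes],
            "contact_reads": 0,
        }
    )
    if contacts and len(genes) > 0:
        gpr = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": [g.interval.chrom for g in genes],
                    "Start": [g.interval.start for g in genes],
                    "End": [g.interval.end for g in genes],
                    "gene_id": [g.gene_id for g in genes],
                }
            )
        )
        joined = gpr.join(_contacts_to_pr(contacts))
        if not joined.empty:
            sums = joined.df.groupby("gene_id", observed=True).reads.sum()
            base["contact_reads"] = (
                base.gene_id.map(sums).fillna(0).astype(int)
            )
    return GeneContactTable(base, threshold=threshold)


def filter_contact_genes(table: GeneContactTable, threshold: int = 100) -> GeneContactTable:
    """Re-threshold a gene contact table; strict inequality (a gene at
    exactly the threshold is dropped)."""
    return GeneContactTable(table.table.drop(columns=["passes_filter"]), threshold=threshold)


def quantify_contacts(
    rep1: Sequence[ContactRecord],
    rep2: Sequence[ContactRecord],
    genes: Sequence[GeneAnnotation],
    exclude_regions: Optional[Track] = None,
    target_length: int = 5000,
    threshold: int = 100,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> GeneContactTable:
    """The full canonical chain over two replicates of mapped contacts."""
    merged = intersect_replicates(rep1, rep2)
    if exclude_regions is not None:
        merged = exclude_low_complexity(merged, exclude_regions)
    extended = extend_contacts(merged, target_length=target_length, chrom_sizes=chrom_sizes)
    return assign_contacts_to_genes(extended, genes, threshold=threshold)
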