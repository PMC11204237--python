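"""Genomic interval and track primitives shared by every pipeline stage.

All coordinates are 0-based half-open, BED-style. GTF input (1-based,
inclusive) is converted at ingest and never seen downstream. Chromosome
names are compared by exact string equality; a ``chr1`` vs ``1`` mismatch
surfaces as zero overlaps/pairs rather than being silently aliased.

Interval set arithmetic (intersection, merge, containment, overlap counting)
is delegated to :mod:`pyranges`; this module only fixes the conventions and
the validated dataclasses around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pyranges as pr

__all__ = [
    "GenomicInterval",
    "Track",
    "GeneAnnotation",
    "BedParseError",
    "GtfParseError",
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "genes_to_track",
    "center_and_length",
    "overlap_fraction",
    "intersect_tracks",
]

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Malformed BED input; the message names the offending line."""


class GtfParseError(ValueError):
    """Malformed or incomplete GTF input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval anchored to a chromosome.

    ``start`` is inclusive, ``end`` exclusive; zero-length intervals are
    rejected because a stretch with no extent has no defined overlap index.
    """

    chrom: str
    start: int
    end: int
    id: Optional[str] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        """Midpoint as a real number; never rounded (a ±0.5 bp rounding bias
        would propagate into every center distance)."""
        return (self.start + self.end) / 2.0


def center_and_length(iv: GenomicInterval) -> tuple[float, int]:
    """Return ``(center, length)`` of an interval, center as an exact real."""
    return iv.center, iv.length


@dataclass
class Track:
    """An ordered collection of intervals, sorted by (chrom, start, end).

    Duplicate records are permitted: read-level tracks legitimately carry
    many identical intervals.
    """

    name: str = "track"
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def add(self, iv: GenomicInterval) -> None:
        import bisect

        bisect.insort(self.intervals, iv)

    @property
    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def to_pyranges(self) -> pr.PyRanges:
        if not self.intervals:
            return pr.PyRanges()
        df = pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in self.intervals],
                "Start": [iv.start for iv in self.intervals],
                "End": [iv.end for iv in self.intervals],
            }
        )
        return pr.PyRanges(df)

    @classmethod
    def from_pyranges(cls, granges: pr.PyRanges, name: str = "track") -> "Track":
        if granges.empty:
            return cls(name=name)
        df = granges.df
        ivs = [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(df.Chromosome, df.Start, df.End)
        ]
        return cls(name=name, intervals=ivs)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body: stable identifier, display symbol, and its interval."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval


def read_bed(path: str | Path, name: Optional[str] = None) -> Track:
    """Read a 3+ column BED file into a sorted :class:`Track`.

    Column 4 (if present) becomes the record id, column 6 the strand.
    ``track``/``browser``/``#`` lines are skipped. Coordinates are kept
    exactly as written (BED is already 0-based half-open).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            rec_id = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, rec_id, strand))
            except ValueError as exc:
                raise BedParseError(f"{path.name}:{lineno}: {exc}") from exc
    return Track(name=name or path.stem, intervals=intervals)


def write_bed(track: Track, path: str | Path) -> None:
    """Write a track as BED; round-trips coordinates bit-exactly."""
    with open(path, "w") as fh:
        for iv in track:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.strand is not None:
                cols.append(iv.id if iv.id is not None else ".")
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_gtf_genes(path: str | Path, collapse_warn: bool = True) -> list[GeneAnnotation]:
    """Extract gene-level records from an Ensembl-dialect GTF.

    1-based inclusive GTF coordinates are converted to 0-based half-open
    (``start-1``, ``end``). A gene feature without a ``gene_id`` attribute
    or a duplicated ``gene_id`` raises :class:`GtfParseError`; a file with
    no gene features returns an empty list with a warning (transcript-only
    GTFs are a common user error and should be loud).
    """
    import gffutils

    path = str(path)
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",  # duplicates surface via the gene_id check below
    )
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise GtfParseError(f"gene feature at {feat.seqid}:{feat.start} lacks gene_id")
        gene_id = gene_ids[0]
        if gene_id in seen:
            raise GtfParseError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        names = feat.attributes.get("gene_name")
        strand = feat.strand if feat.strand in _VALID_STRANDS else None
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, gene_id, strand)
        genes.append(GeneAnnotation(gene_id, names[0] if names else gene_id, iv))
    if not genes and collapse_warn:
        warnings.warn(f"{path}: GTF contains no gene features", stacklevel=2)
    return genes


def genes_to_track(genes: Sequence[GeneAnnotation], name: str = "genes") -> Track:
    """Project gene annotations onto a plain interval track (ids retained)."""
    return Track(
        name=name,
        intervals=[replace(g.interval, id=g.gene_id) for g in genes],
    )


def overlap_fraction(genes: Track, features: Track) -> float:
    """Fraction of gene records overlapped (>=1 bp) by at least one feature.

    Invariant to record order and to splitting a feature into adjacent
    pieces, since only the covered/not-covered state of each gene counts.
    """
    if len(genes) == 0:
        raise ValueError("gene track is empty")
    if len(features) == 0:
        return 0.0
    counts = genes.to_pyranges().count_overlaps(features.to_pyranges())
    return float((counts.df.NumberOverlaps > 0).mean())


def intersect_tracks(a: Track, b: Track) -> Track:
    """Base-pair-level intersection of two tracks, merged.

    Equivalent to intersecting the covered base sets of ``a`` and ``b`` and
    reporting the maximal runs, i.e. ``bedtools intersect`` followed by
    ``merge``.
    """
    if len(a) == 0 or len(b) == 0:
        return Track(name=f"{a.name}&{b.name}")
    out = a.to_pyranges().intersect(b.to_pyranges())
    if not out.empty:
        out = out.merge()
    return Track.from_pyranges(out, name=f"{a.name}&{b.name}")
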