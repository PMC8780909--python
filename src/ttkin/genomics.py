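"""Peak-set genomics: region assignment, target overlaps, metagene profiles.

Coordinates are 0-based half-open throughout (BED convention).  A transcript
model is three ordered block lists — 5'UTR, CDS, 3'UTR — in transcript
orientation (5'→3'); on the minus strand the 5'UTR therefore sits genomically
rightmost.  Peaks are reduced to their midpoint base for region assignment
and metagene mapping (the MetaPlotR convention): the midpoint is located in
transcript coordinates, its region determined by half-open block membership
(a region boundary belongs to the downstream region), and for metagene
profiles its position within the region is rescaled to unit length so the
5'UTR, CDS and 3'UTR occupy [0,1), [1,2) and [2,3) respectively.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

REGIONS = ("utr5", "cds", "utr3")
_REGION_OFFSET = {"utr5": 0.0, "cds": 1.0, "utr3": 2.0}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Midpoint base (floor of the arithmetic mean of the bounds)."""
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """A named collection of peaks (e.g. one CLIP/meRIP factor)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    name: str = "peaks"

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                score = int(iv.score) if float(iv.score).is_integer() else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "PeakSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValidationError(f"{path}: BED line with <3 fields: {line!r}")
                intervals.append(
                    GenomicInterval(
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        name=f[3] if len(f) > 3 else ".",
                        score=float(f[4]) if len(f) > 4 else 0.0,
                        strand=f[5] if len(f) > 5 else "+",
                    )
                )
        return cls(intervals=intervals, name=name or Path(path).stem)


@dataclass
class TranscriptModel:
    """One gene's transcript structure as 5'UTR / CDS / 3'UTR exonic blocks.

    Blocks are ordered 5'→3' in transcript orientation and must not overlap.
    """

    gene_id: str
    chrom: str
    strand: str
    utr5: tuple[GenomicInterval, ...] = ()
    cds: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        self.utr5 = tuple(self.utr5)
        self.cds = tuple(self.cds)
        self.utr3 = tuple(self.utr3)
        if self.region_length("cds") <= 0:
            raise ValidationError(f"{self.gene_id}: CDS length must be > 0")
        for region in REGIONS:
            prev_end = None
            for b in self.blocks(region):
                if b.chrom != self.chrom:
                    raise ValidationError(f"{self.gene_id}: block on wrong chromosome")
                # 5'->3' order means genomically ascending on +, descending on -
                key = b.start if self.strand == "+" else -b.start
                if prev_end is not None and key <= prev_end:
                    raise ValidationError(f"{self.gene_id}: {region} blocks out of order")
                prev_end = key

    def blocks(self, region: str) -> tuple[GenomicInterval, ...]:
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}[region]

    def region_length(self, region: str) -> int:
        return sum(len(b) for b in self.blocks(region))

    @property
    def total_length(self) -> int:
        return sum(self.region_length(r) for r in REGIONS)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) envelope over all blocks."""
        starts = [b.start for r in REGIONS for b in self.blocks(r)]
        ends = [b.end for r in REGIONS for b in self.blocks(r)]
        return min(starts), max(ends)

    def locate(self, pos: int) -> tuple[str, int] | None:
        """Map a genomic base to (region, offset-within-region, 5'→3').

        Returns None when the base falls in an intron or outside the model.
        """
        for region in REGIONS:
            acc = 0
            for b in self.blocks(region):
                if b.start <= pos < b.end:
                    off = pos - b.start if self.strand == "+" else b.end - 1 - pos
                    return region, acc + off
                acc += len(b)
        return None


# ---------------------------------------------------------------------------
# transcript model TSV dialect
# ---------------------------------------------------------------------------

def _fmt_blocks(blocks: Sequence[GenomicInterval]) -> str:
    return ",".join(f"{b.start}-{b.end}" for b in blocks) or "."


def _parse_blocks(text: str, chrom: str, strand: str) -> tuple[GenomicInterval, ...]:
    if text == ".":
        return ()
    out = []
    for part in text.split(","):
        s, e = part.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return tuple(out)


def write_transcript_models(models: Iterable[TranscriptModel], path: str | Path) -> None:
    rows = []
    for m in models:
        rows.append(
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "utr5_blocks": _fmt_blocks(m.utr5),
                "cds_blocks": _fmt_blocks(m.cds),
                "utr3_blocks": _fmt_blocks(m.utr3),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcript_models(path: str | Path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = []
    for _, r in df.iterrows():
        models.append(
            TranscriptModel(
                gene_id=r["gene_id"],
                chrom=r["chrom"],
                strand=r["strand"],
                utr5=_parse_blocks(r["utr5_blocks"], r["chrom"], r["strand"]),
                cds=_parse_blocks(r["cds_blocks"], r["chrom"], r["strand"]),
                utr3=_parse_blocks(r["utr3_blocks"], r["chrom"], r["strand"]),
            )
        )
    return models


# ---------------------------------------------------------------------------
# peak -> transcript operations
# ---------------------------------------------------------------------------

def assign_peak_region(peak: GenomicInterval, tx: TranscriptModel) -> str:
    """Region ('utr5'|'cds'|'utr3'|'none') containing the peak midpoint."""
    if peak.chrom != tx.chrom:
        raise ValidationError(
            f"chromosome mismatch: peak on {peak.chrom}, transcript on {tx.chrom}"
        )
    hit = tx.locate(peak.midpoint)
    return "none" if hit is None else hit[0]


def metagene_coordinate(peak: GenomicInterval, tx: TranscriptModel) -> float | None:
    """Peak midpoint on the metagene axis [0,3), or None when unmapped.

    Position within the containing region is rescaled to unit length and
    offset by 0/1/2 for 5'UTR/CDS/3'UTR.
    """
    if peak.chrom != tx.chrom:
        raise ValidationError(
            f"chromosome mismatch: peak on {peak.chrom}, transcript on {tx.chrom}"
        )
    hit = tx.locate(peak.midpoint)
    if hit is None:
        return None
    region, off = hit
    length = tx.region_length(region)
    return _REGION_OFFSET[region] + off / length


class _TxIndex:
    """Per-chromosome interval index over transcript spans."""

    def __init__(self, txs: Sequence[TranscriptModel]):
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for tx in txs:
            s, e = tx.span
            self.trees[tx.chrom][s:e] = tx

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        hits = self.trees[chrom][pos] if chrom in self.trees else ()
        return sorted((h.data for h in hits), key=lambda t: t.gene_id)


def genes_with_region_peaks(
    peaks: PeakSet,
    txs: Sequence[TranscriptModel],
    region: str = "any",
) -> set[str]:
    """Gene ids with at least one peak whose midpoint maps to ``region``.

    ``region`` may be 'utr5'/'cds'/'utr3' or 'any' (any exonic region).  A
    peak whose midpoint falls inside several genes' models counts for each.
    """
    if region not in REGIONS and region != "any":
        raise ValidationError(f"unknown region {region!r}")
    index = _TxIndex(txs)
    hit_genes: set[str] = set()
    for peak in peaks:
        for tx in index.overlapping(peak.chrom, peak.midpoint):
            r = assign_peak_region(peak, tx)
            if r != "none" and (region == "any" or r == region):
                hit_genes.add(tx.gene_id)
    return hit_genes


def overlap_partition(a: set, b: set, c: set) -> dict[str, int]:
    """Counts of the 7 exclusive regions of a three-set Venn diagram."""
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab_only": len((a & b) - c),
        "ac_only": len((a & c) - b),
        "bc_only": len((b & c) - a),
        "abc": len(a & b & c),
    }


def cobinding_fraction(reader_genes: set, ago2_genes: set) -> float:
    """Percentage of reader-bound genes also bound by AGO2."""
    if not reader_genes:
        raise ValidationError("reader gene set is empty")
    return 100.0 * len(reader_genes & ago2_genes) / len(reader_genes)


@dataclass
class MetageneProfile:
    """Density histogram of peak midpoints on the [0,3) metagene axis."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n_peaks_mapped: int
    n_peaks_unmapped: int

    def region_mass(self, region: str) -> float:
        """Fraction of density mass in one region's unit interval."""
        lo = _REGION_OFFSET[region]
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        width = self.bin_edges[1] - self.bin_edges[0]
        sel = (centers >= lo) & (centers < lo + 1)
        return float(np.sum(self.densities[sel]) * width)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "density": self.densities,
            }
        ).to_csv(path, sep="\t", index=False)


def metagene_profile(
    peaks: PeakSet, txs: Sequence[TranscriptModel], n_bins: int = 90
) -> MetageneProfile:
    """Histogram of metagene coordinates over all mappable (peak, gene) pairs."""
    if n_bins < 3 or n_bins % 3:
        raise ValidationError("n_bins must be >= 3 and divisible by 3")
    index = _TxIndex(txs)
    coords: list[float] = []
    unmapped = 0
    for peak in peaks:
        found = False
        for tx in index.overlapping(peak.chrom, peak.midpoint):
            x = metagene_coordinate(peak, tx)
            if x is not None:
                coords.append(x)
                found = True
        if not found:
            unmapped += 1
    edges = np.linspace(0.0, 3.0, n_bins + 1)
    if coords:
        dens, _ = np.histogram(coords, bins=edges, density=True)
    else:
        dens = np.zeros(n_bins)
    return MetageneProfile(
        bin_edges=edges,
        densities=dens,
        n_peaks_mapped=len(coords),
        n_peaks_unmapped=unmapped,
    )
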