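"""Genomic intervals, fixed-size bins and peak sets.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Two intervals overlap iff they share at least one base,
i.e. ``a.start < b.end and b.start < a.end``; a zero-length touch at a
boundary does not count as overlap.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "make_fixed_bins",
    "read_chrom_sizes",
    "read_bed",
    "HG19_CHROM_SIZES",
]

#: Reference chromosome lengths for the hg19 human assembly (UCSC), used for
#: whole-genome fixed-size binning.
HG19_CHROM_SIZES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
    "chrM": 16571,
}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakSet:
    """An ordered collection of genomic intervals defining matrix columns.

    ``kind`` is ``"fixed_bin"`` for a regular tiling of the genome (with
    ``bin_size`` set) or ``"called"`` for arbitrary called peaks.
    Intervals are kept sorted by ``(chrom, start)``; the column order of any
    matrix built over the set is exactly ``self.intervals`` order.
    """

    intervals: list[GenomicInterval]
    kind: str = "called"
    bin_size: int | None = None

    # per-chromosome index, built lazily
    _index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_bin", "called"):
            raise ValueError(f"unknown peak-set kind {self.kind!r}")
        if self.kind == "fixed_bin" and not self.bin_size:
            raise ValueError("fixed_bin peak set requires bin_size")
        ordered = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if ordered != list(self.intervals):
            self.intervals = ordered

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return (
            self.intervals == other.intervals
            and self.kind == other.kind
            and self.bin_size == other.bin_size
        )

    def _build_index(self) -> dict:
        """Per-chromosome arrays (starts, ends, cummax_end, global column ids)."""
        if self._index is None:
            idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
            by_chrom: dict[str, list[int]] = {}
            for j, iv in enumerate(self.intervals):
                by_chrom.setdefault(iv.chrom, []).append(j)
            for chrom, cols in by_chrom.items():
                cols_arr = np.asarray(cols, dtype=np.int64)
                starts = np.asarray([self.intervals[j].start for j in cols], dtype=np.int64)
                ends = np.asarray([self.intervals[j].end for j in cols], dtype=np.int64)
                idx[chrom] = (starts, ends, np.maximum.accumulate(ends), cols_arr)
            object.__setattr__(self, "_index", idx)
        return self._index

    def overlapping_columns(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global column indices of every peak overlapping ``[start, end)``.

        Works for arbitrary (possibly overlapping) called peaks; intervals on
        a chromosome are sorted by start, and the cumulative-maximum end
        bounds the leftmost candidate.
        """
        idx = self._build_index()
        if chrom not in idx:
            return np.empty(0, dtype=np.int64)
        starts, ends, cummax, cols = idx[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        lo = int(np.searchsorted(cummax, start, side="right"))
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        sel = ends[lo:hi] > start
        return cols[lo:hi][sel]

    def fingerprint(self) -> str:
        """Stable digest of the peak regions (count + hashed interval list).

        Two matrices are feature-compatible for train/predict iff their peak
        sets share this fingerprint.
        """
        h = hashlib.sha256()
        h.update(f"{self.kind}:{self.bin_size}:{len(self.intervals)}".encode())
        for iv in self.intervals:
            h.update(f"{iv.chrom}:{iv.start}-{iv.end};".encode())
        return h.hexdigest()

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")

    @classmethod
    def from_bed(cls, path: str | Path, kind: str = "called",
                 bin_size: int | None = None) -> "PeakSet":
        intervals = read_bed(path)
        if kind == "fixed_bin" and bin_size is None:
            sizes = {iv.end - iv.start for iv in intervals}
            bin_size = max(sizes) if sizes else None
        return cls(intervals, kind=kind, bin_size=bin_size)


def make_fixed_bins(chrom_sizes: Mapping[str, int], bin_size: int) -> PeakSet:
    """Tile every chromosome into consecutive ``bin_size`` windows.

    Bins start at position 0; the final bin of a chromosome may be shorter.
    The number of bins is ``sum(ceil(length / bin_size))`` over chromosomes.
    """
    if not chrom_sizes:
        raise ValueError("no chromosomes")
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    intervals: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        length = int(chrom_sizes[chrom])
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom}")
        for k in range(math.ceil(length / bin_size)):
            start = k * bin_size
            intervals.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return PeakSet(intervals, kind="fixed_bin", bin_size=bin_size)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) chromosome-sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected 'name\\tlength'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of intervals (extra columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected at least 3 BED columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out
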