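"""Binary cell-peak matrices and their on-disk representation.

The central container is :class:`CellPeakMatrix`: a sparse binary matrix of
``n`` cells (rows) by ``m`` peaks (columns) together with the barcode list
and the :class:`~svmatac.genome.PeakSet` that defines the columns.  scATAC
signal is near-binary (two copies of each locus), so a value records only
whether any fragment of that cell overlapped the peak.

All-zero columns are deliberately retained: training and prediction matrices
must live in the same feature space, and a column that is empty in one
dataset may carry signal in another.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .genome import GenomicInterval, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "CellPeakMatrix",
    "GroupAssignment",
    "build_matrix",
    "apply_blacklist",
    "filter_small_populations",
    "read_matrix",
    "write_matrix",
    "read_fragments",
]


def _as_binary_csr(values) -> sp.csr_matrix:
    X = sp.csr_matrix(values)
    X.eliminate_zeros()
    if X.nnz and not np.isin(X.data, (0, 1)).all():
        raise ValueError("cell-peak matrix must be binary (values in {0, 1})")
    X = X.astype(np.int8)
    return X


@dataclass
class CellPeakMatrix:
    """Binary cells x peaks matrix with barcode and peak metadata."""

    values: sp.csr_matrix
    barcodes: list[str]
    peaks: PeakSet

    def __post_init__(self) -> None:
        self.values = _as_binary_csr(self.values)
        self.barcodes = list(self.barcodes)
        if self.values.shape[0] != len(self.barcodes):
            raise ValueError(
                f"matrix has {self.values.shape[0]} rows but {len(self.barcodes)} barcodes"
            )
        if self.values.shape[1] != len(self.peaks):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but {len(self.peaks)} peaks"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def with_values(self, values) -> "CellPeakMatrix":
        """Same barcodes/peaks, new values (shape-checked)."""
        return CellPeakMatrix(values, self.barcodes, self.peaks)

    def subset_rows(self, idx: np.ndarray) -> "CellPeakMatrix":
        idx = np.asarray(idx)
        return CellPeakMatrix(
            self.values[idx], [self.barcodes[i] for i in idx], self.peaks
        )

    def equals(self, other: "CellPeakMatrix") -> bool:
        return (
            self.barcodes == other.barcodes
            and self.peaks == other.peaks
            and (self.values != other.values).nnz == 0
        )


class GroupAssignment:
    """A barcode -> group-label mapping (cell types or cluster identifiers)."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping: dict[str, str] = {str(k): str(v) for k, v in mapping.items()}

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, barcode: str) -> str:
        return self.mapping[barcode]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.mapping

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupAssignment) and self.mapping == other.mapping

    def labels(self) -> list[str]:
        """Distinct labels in sorted order."""
        return sorted(set(self.mapping.values()))

    def labels_for(self, barcodes: Iterable[str]) -> np.ndarray:
        """Label array aligned to ``barcodes``; missing barcodes are an error."""
        out = []
        for b in barcodes:
            if b not in self.mapping:
                raise KeyError(f"barcode {b!r} has no group label")
            out.append(self.mapping[b])
        return np.asarray(out, dtype=object)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.mapping.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def subset(self, barcodes: Iterable[str]) -> "GroupAssignment":
        return GroupAssignment({b: self.mapping[b] for b in barcodes})

    @classmethod
    def from_arrays(cls, barcodes: Iterable[str], labels: Iterable) -> "GroupAssignment":
        return cls(dict(zip(barcodes, (str(l) for l in labels))))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroupAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"],
                         dtype=str)
        if df["label"].isna().any():
            raise ValueError(f"{path}: expected two tab-separated columns (barcode, label)")
        return cls.from_arrays(df["barcode"], df["label"])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for b, lab in self.mapping.items():
                fh.write(f"{b}\t{lab}\n")


def read_fragments(path: str | Path) -> Iterator[tuple[GenomicInterval, str]]:
    """Stream a 10x-style fragments TSV (chrom, start, end, barcode[, count]).

    Accepts plain or gzip/bgzip-compressed files.  Malformed records raise
    with the offending line number; comment lines are skipped.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{line_no}: expected >=4 tab-separated fields, got {len(fields)}"
                )
            chrom, start, end, barcode = fields[0], fields[1], fields[2], fields[3]
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: {exc}") from exc
            yield iv, barcode


def build_matrix(
    fragments: Iterable[tuple[GenomicInterval, str]],
    peaks: PeakSet,
    barcodes: list[str],
) -> CellPeakMatrix:
    """Binary detection matrix: 1 iff any fragment of the cell overlaps the peak.

    A fragment spanning a bin boundary marks every overlapped bin.  Fragments
    whose barcode is not in ``barcodes`` are skipped (real fragment files
    contain non-cell barcodes); the skip count is logged.
    """
    if not barcodes:
        raise ValueError("barcodes must be non-empty")
    row_of = {b: i for i, b in enumerate(barcodes)}
    rows: list[int] = []
    cols: list[int] = []
    skipped = 0
    for iv, barcode in fragments:
        i = row_of.get(barcode)
        if i is None:
            skipped += 1
            continue
        for j in peaks.overlapping_columns(iv.chrom, iv.start, iv.end):
            rows.append(i)
            cols.append(int(j))
    if skipped:
        logger.info("build_matrix: skipped %d fragments with unknown barcodes", skipped)
    shape = (len(barcodes), len(peaks))
    if not rows:
        return CellPeakMatrix(sp.csr_matrix(shape, dtype=np.int8), barcodes, peaks)
    data = np.ones(len(rows), dtype=np.int8)
    X = sp.coo_matrix((data, (rows, cols)), shape=shape).tocsr()
    X.data[:] = 1  # duplicates collapse to 1: binary detection
    return CellPeakMatrix(X, barcodes, peaks)


def apply_blacklist(
    matrix: CellPeakMatrix, blacklist: Iterable[GenomicInterval]
) -> CellPeakMatrix:
    """Zero every column whose peak overlaps a blacklist region.

    Columns are zeroed, never dropped, so the feature space is unchanged.
    """
    bad = np.zeros(matrix.n_peaks, dtype=bool)
    for iv in blacklist:
        bad[matrix.peaks.overlapping_columns(iv.chrom, iv.start, iv.end)] = True
    if not bad.any():
        return matrix.with_values(matrix.values.copy())
    X = matrix.values.tocsc(copy=True)
    col_of_entry = np.repeat(np.arange(X.shape[1]), np.diff(X.indptr))
    X.data[bad[col_of_entry]] = 0
    X.eliminate_zeros()
    return matrix.with_values(X.tocsr())


def filter_small_populations(
    matrix: CellPeakMatrix,
    groups: GroupAssignment,
    min_size: int = 10,
) -> tuple[CellPeakMatrix, GroupAssignment]:
    """Drop all cells of any group with fewer than ``min_size`` members.

    The bound is strict: groups of exactly ``min_size`` survive.  Surviving
    rows are untouched and keep their relative order.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    labels = groups.labels_for(matrix.barcodes)
    sizes: dict[str, int] = {}
    for lab in labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    keep = np.asarray([sizes[lab] >= min_size for lab in labels])
    if not keep.any():
        raise ValueError("no cells survive population filter")
    if keep.all():
        return matrix.subset_rows(np.arange(matrix.n_cells)), groups.subset(matrix.barcodes)
    idx = np.flatnonzero(keep)
    sub = matrix.subset_rows(idx)
    return sub, groups.subset(sub.barcodes)


def write_matrix(matrix: CellPeakMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx + peaks.bed + barcodes.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), matrix.values.tocoo(), field="integer")
    matrix.peaks.to_bed(outdir / "peaks.bed")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for b in matrix.barcodes:
            fh.write(b + "\n")
    meta = outdir / "peaks.meta"
    with open(meta, "w") as fh:
        fh.write(f"kind\t{matrix.peaks.kind}\n")
        if matrix.peaks.bin_size:
            fh.write(f"bin_size\t{matrix.peaks.bin_size}\n")


def read_matrix(
    mtx_path: str | Path,
    peaks_bed_path: str | Path,
    barcodes_path: str | Path,
) -> CellPeakMatrix:
    """Read an MTX + peaks BED + barcodes TSV triple.

    Any nonzero value is binarized to 1 with a warning.  Dimension mismatches
    between the MTX header and the sidecar files are an error naming all
    three files.
    """
    X = sp.csr_matrix(mmread(str(mtx_path)))
    with open(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    meta_path = Path(peaks_bed_path).with_suffix(".meta")
    kind, bin_size = "called", None
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            key, _, val = line.partition("\t")
            if key == "kind":
                kind = val
            elif key == "bin_size":
                bin_size = int(val)
    peaks = PeakSet.from_bed(peaks_bed_path, kind=kind, bin_size=bin_size)
    if X.shape[0] != len(barcodes) or X.shape[1] != len(peaks):
        raise ValueError(
            f"dimension mismatch: {mtx_path} declares {X.shape}, but "
            f"{barcodes_path} has {len(barcodes)} barcodes and "
            f"{peaks_bed_path} has {len(peaks)} peaks"
        )
    X.eliminate_zeros()
    if X.nnz and (X.data != 1).any():
        warnings.warn(
            f"{mtx_path}: non-binary values binarized to 1", UserWarning, stacklevel=2
        )
        X.data = np.ones_like(X.data)
    return CellPeakMatrix(X, barcodes, peaks)
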