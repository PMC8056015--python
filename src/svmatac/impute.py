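"""Co-accessibility-driven signal imputation.

Co-accessible peak pairs (e.g. enhancer-promoter pairs scored by Cicero)
carry cell-type regulatory structure.  Within each cell group, a peak that
is *distinct* — non-zero in every cell of the group after enhancement,
``sum_j C_kj = n`` — propagates its signal to any partner peak linked to it
with co-accessibility score ``L_ik >= c_int`` (recommended cutoff 0.25): the
partner column is set to all ones for that group.

Links are scored between *called* peaks but applied to the fixed-bin matrix;
a called peak overlapping several bins is assigned to the leftmost
(lowest-start) overlapping bin.  Propagation is evaluated in a single pass
against the pre-imputation state: a column saturated by imputation does not
itself trigger further propagation unless ``cascade=True``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .enhance import _check_binary, _saturate_columns
from .genome import GenomicInterval, PeakSet
from .matrix import CellPeakMatrix, GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "CoAccessLinkTable",
    "BinLinkMap",
    "CoAccessImputer",
    "read_links",
    "map_links_to_bins",
    "impute",
    "impute_group",
    "score_coaccessibility",
    "DEFAULT_C_INT",
]

#: Recommended co-accessibility score cutoff for imputation.
DEFAULT_C_INT = 0.25

# "chr1_100_600" or "chr1:100-600"
_PEAK_RE = re.compile(r"^(?P<chrom>[^:_]+)[:_](?P<start>\d+)[-_](?P<end>\d+)$")


def parse_peak_string(text: str) -> GenomicInterval:
    """Parse a peak string in either underscore or colon-dash dialect."""
    m = _PEAK_RE.match(str(text).strip())
    if not m:
        raise ValueError(f"unparseable peak string: {text!r}")
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


@dataclass
class CoAccessLinkTable:
    """Scored pairs of called peaks, as emitted by Cicero."""

    links: list[tuple[GenomicInterval, GenomicInterval, float]]

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("Peak1,Peak2,coaccess\n")
            for a, b, s in self.links:
                fh.write(
                    f"{a.chrom}_{a.start}_{a.end},{b.chrom}_{b.start}_{b.end},{s:g}\n"
                )


@dataclass
class BinLinkMap:
    """Unordered bin-index pairs with their (maximum) co-accessibility score."""

    pairs: dict[tuple[int, int], float]

    def __len__(self) -> int:
        return len(self.pairs)

    def items(self):
        return self.pairs.items()

    def scoring_pairs(self, c_int: float) -> list[tuple[int, int]]:
        return [pair for pair, s in self.pairs.items() if s >= c_int]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (i, k), s in sorted(self.pairs.items()):
                fh.write(f"{i}\t{k}\t{s:g}\n")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[int, int, float]]
    ) -> "BinLinkMap":
        out: dict[tuple[int, int], float] = {}
        for i, k, s in pairs:
            if i == k:
                continue
            key = (min(i, k), max(i, k))
            if key not in out or s > out[key]:
                out[key] = float(s)
        return cls(out)


def read_links(path: str | Path) -> CoAccessLinkTable:
    """Read a Cicero-dialect link table (CSV or TSV: Peak1, Peak2, coaccess).

    Rows with a missing (NA) score are dropped and counted; both the
    ``chr1_100_600`` and ``chr1:100-600`` peak dialects are accepted.
    """
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    try:
        p1, p2, sc = cols["peak1"], cols["peak2"], cols["coaccess"]
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns Peak1, Peak2, coaccess; got {list(df.columns)}"
        ) from exc
    n_na = int(df[sc].isna().sum())
    if n_na:
        logger.info("read_links: dropped %d rows with NA coaccess score", n_na)
        df = df.dropna(subset=[sc])
    links = [
        (parse_peak_string(a), parse_peak_string(b), float(s))
        for a, b, s in zip(df[p1], df[p2], df[sc])
    ]
    return CoAccessLinkTable(links)


def _leftmost_bin(peak: GenomicInterval, bins: PeakSet) -> int | None:
    cols = bins.overlapping_columns(peak.chrom, peak.start, peak.end)
    if cols.size == 0:
        return None
    return int(cols.min())


def map_links_to_bins(table: CoAccessLinkTable, bins: PeakSet) -> BinLinkMap:
    """Map called-peak links onto fixed-bin column indices.

    Each called peak is assigned to its leftmost overlapping bin; links whose
    endpoints land in the same bin are dropped as self-links; duplicate and
    reciprocal pairs collapse to one unordered pair keeping the maximum
    score.  Peaks overlapping no bin (e.g. an unknown chromosome) drop their
    link with a warning.
    """
    if bins.kind != "fixed_bin":
        raise ValueError("map_links_to_bins requires a fixed_bin peak set")
    mapped: list[tuple[int, int, float]] = []
    n_unmapped = 0
    for a, b, s in table:
        i = _leftmost_bin(a, bins)
        k = _leftmost_bin(b, bins)
        if i is None or k is None:
            n_unmapped += 1
            continue
        mapped.append((i, k, s))
    if n_unmapped:
        logger.warning(
            "map_links_to_bins: dropped %d links with peaks overlapping no bin",
            n_unmapped,
        )
    return BinLinkMap.from_pairs(mapped)


class CoAccessImputer(BaseEstimator, TransformerMixin):
    """Propagate saturated columns across strong co-accessibility links.

    Group-conditional like :class:`~svmatac.enhance.SignalEnhancer`: group
    labels are passed as ``y`` (one per row, all cells one group if absent).
    The input is expected to be the *enhanced* matrix of each group.

    Parameters
    ----------
    link_map : BinLinkMap
        Unordered bin pairs with scores, from :func:`map_links_to_bins`.
    c_int : float, default 0.25
        Score cutoff; only pairs with score >= ``c_int`` propagate.
    cascade : bool, default False
        When True, iterate propagation to a fixed point instead of the
        single pass evaluated against the input state.
    """

    def __init__(self, link_map: BinLinkMap, c_int: float = DEFAULT_C_INT,
                 cascade: bool = False):
        self.link_map = link_map
        self.c_int = c_int
        self.cascade = cascade

    def fit(self, X, y=None) -> "CoAccessImputer":
        X = _check_binary(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _propagate(self, sat: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
        """Columns newly saturated by one pass over ``pairs`` given state ``sat``."""
        new = np.zeros_like(sat)
        for i, k in pairs:
            if sat[k]:
                new[i] = True
            if sat[i]:
                new[k] = True
        return new & ~sat

    def transform(self, X, y=None) -> sp.csr_matrix:
        X = _check_binary(X)
        n, m = X.shape
        if n == 0:
            raise ValueError("cannot impute an empty matrix")
        if y is None:
            y = np.zeros(n, dtype=object)
        y = np.asarray(y, dtype=object)
        if y.shape[0] != n:
            raise ValueError(f"{n} rows but {y.shape[0]} group labels")
        pairs = [
            (i, k) for i, k in self.link_map.scoring_pairs(self.c_int)
            if i < m and k < m
        ]
        out = X
        for g in np.unique(y):
            rows = np.flatnonzero(y == g)
            col_sums = np.asarray(X[rows].sum(axis=0)).ravel()
            sat = col_sums == rows.size
            new = self._propagate(sat, pairs)
            if self.cascade:
                state = sat | new
                while True:
                    extra = self._propagate(state, pairs)
                    if not extra.any():
                        break
                    new |= extra
                    state |= extra
            out = _saturate_columns(out, rows, np.flatnonzero(new))
        return out if out is not X else X.copy()

    def fit_transform(self, X, y=None, **fit_params) -> sp.csr_matrix:
        return self.fit(X, y).transform(X, y)


def impute_group(
    submatrix: CellPeakMatrix,
    link_map: BinLinkMap,
    c_int: float = DEFAULT_C_INT,
    cascade: bool = False,
) -> CellPeakMatrix:
    """Impute a single-group (enhanced) matrix."""
    X = CoAccessImputer(link_map, c_int=c_int, cascade=cascade).fit_transform(
        submatrix.values
    )
    return submatrix.with_values(X)


def impute(
    matrix: CellPeakMatrix,
    groups: GroupAssignment,
    link_map: BinLinkMap,
    c_int: float = DEFAULT_C_INT,
    cascade: bool = False,
) -> CellPeakMatrix:
    """Per-group imputation of an enhanced matrix; row order preserved."""
    y = groups.labels_for(matrix.barcodes)
    X = CoAccessImputer(link_map, c_int=c_int, cascade=cascade).fit_transform(
        matrix.values, y
    )
    return matrix.with_values(X)


def score_coaccessibility(
    matrix: CellPeakMatrix,
    max_distance: int = 500_000,
    min_cells: int = 5,
) -> CoAccessLinkTable:
    """Approximate co-accessibility scorer (stand-in for Cicero).

    Scores every within-chromosome peak pair whose midpoints lie within
    ``max_distance`` and whose columns are each non-zero in at least
    ``min_cells`` cells, with the Pearson correlation of the two binary
    columns clamped to [0, 1].  This is correlation, not Cicero's
    regularized partial-correlation model; supplying a real Cicero output
    file is the canonical path, this scorer is plumbing for pipelines
    without one.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    X = matrix.values.tocsc()
    n, m = X.shape
    peaks = matrix.peaks.intervals
    col_sums = np.asarray(X.sum(axis=0)).ravel().astype(float)
    eligible = col_sums >= min_cells
    mids = np.asarray([(iv.start + iv.end) / 2 for iv in peaks])
    chroms = np.asarray([iv.chrom for iv in peaks], dtype=object)

    links: list[tuple[GenomicInterval, GenomicInterval, float]] = []
    Xd = X.astype(np.float64)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero((chroms == chrom) & eligible)
        if cols.size < 2:
            continue
        order = cols[np.argsort(mids[cols], kind="stable")]
        sub = Xd[:, order]
        gram = (sub.T @ sub).toarray()
        s = col_sums[order]
        sub_mids = mids[order]
        for a in range(order.size):
            for b in range(a + 1, order.size):
                if sub_mids[b] - sub_mids[a] > max_distance:
                    break
                cov = n * gram[a, b] - s[a] * s[b]
                var_a = n * s[a] - s[a] ** 2
                var_b = n * s[b] - s[b] ** 2
                if var_a <= 0 or var_b <= 0:
                    score = 0.0  # constant column: correlation undefined
                else:
                    score = cov / np.sqrt(var_a * var_b)
                score = float(min(max(score, 0.0), 1.0))
                links.append((peaks[order[a]], peaks[order[b]], score))
    links.sort(key=lambda t: -t[2])
    return CoAccessLinkTable(links)
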