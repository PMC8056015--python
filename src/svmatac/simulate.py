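"""Synthetic scATAC-seq cell-peak data with planted ground truth.

The generator emulates the data regime the pipeline targets: a binary
cell-peak matrix over fixed 5 kb bins of one synthetic chromosome ("chrS"),
several cell types each with a disjoint block of signature peaks, severe
per-cell detection dropout (a cell detects each of its own signature peaks
with probability ``detection_rate``, default 0.05 — the middle of the 1-10%
per-peak detectability typical of the assay), a low background rate
everywhere else, and a co-accessibility link table connecting same-type
signature-peak pairs (plus an equal number of sub-threshold decoy links that
a correct pipeline must ignore).

Everything planted is recorded in a truth manifest, and outputs are
bit-reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .genome import GenomicInterval, make_fixed_bins
from .impute import CoAccessLinkTable
from .matrix import CellPeakMatrix, GroupAssignment, write_matrix

__all__ = ["SyntheticSpec", "generate", "batch_shift", "write_fixture"]

_BIN = 5000
_CHROM = "chrS"


@dataclass
class SyntheticSpec:
    """Parameters of the planted world (defaults are the reference scenario)."""

    n_types: int = 3
    cells_per_type: int = 100
    m_peaks: int = 2000
    signature_peaks_per_type: int = 40
    background_rate: float = 0.002
    detection_rate: float = 0.05
    n_links: int = 60
    link_score_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    def validate(self) -> None:
        if self.n_types * self.signature_peaks_per_type > self.m_peaks:
            raise ValueError("signature blocks exceed the number of peaks")
        for name in ("background_rate", "detection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.link_score_range
        if not lo <= hi:
            raise ValueError("link_score_range must be (low, high) with low <= high")
        if min(self.n_types, self.cells_per_type, self.m_peaks,
               self.signature_peaks_per_type) < 1 or self.n_links < 0:
            raise ValueError("counts must be positive")


def _link_peak(bin_index: int) -> GenomicInterval:
    """A small called peak inside a bin (exercises leftmost-bin mapping)."""
    start = bin_index * _BIN + 1000
    return GenomicInterval(_CHROM, start, start + 400)


def generate(
    spec: SyntheticSpec,
) -> tuple[CellPeakMatrix, GroupAssignment, CoAccessLinkTable, dict]:
    """Draw one synthetic dataset; returns (matrix, groups, links, manifest)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_types * spec.cells_per_type
    m = spec.m_peaks

    type_names = [f"type{t}" for t in range(spec.n_types)]
    sig_cols = {
        type_names[t]: list(
            range(t * spec.signature_peaks_per_type,
                  (t + 1) * spec.signature_peaks_per_type)
        )
        for t in range(spec.n_types)
    }

    dense = (rng.random((n, m)) < spec.background_rate).astype(np.int8)
    labels = np.repeat(type_names, spec.cells_per_type)
    for t, name in enumerate(type_names):
        rows = slice(t * spec.cells_per_type, (t + 1) * spec.cells_per_type)
        cols = sig_cols[name]
        dense[rows, cols[0]:cols[-1] + 1] = (
            rng.random((spec.cells_per_type, len(cols))) < spec.detection_rate
        ).astype(np.int8)

    barcodes = [f"cell{i:04d}" for i in range(n)]
    peaks = make_fixed_bins({_CHROM: m * _BIN}, _BIN)
    matrix = CellPeakMatrix(sp.csr_matrix(dense), barcodes, peaks)
    groups = GroupAssignment.from_arrays(barcodes, labels)

    true_links: list[tuple[GenomicInterval, GenomicInterval, float]] = []
    lo, hi = spec.link_score_range
    for _ in range(spec.n_links):
        name = type_names[int(rng.integers(spec.n_types))]
        i, k = rng.choice(sig_cols[name], size=2, replace=False)
        score = float(rng.uniform(lo, hi))
        true_links.append((_link_peak(int(i)), _link_peak(int(k)), score))
    decoy_links: list[tuple[GenomicInterval, GenomicInterval, float]] = []
    for _ in range(spec.n_links):
        i, k = rng.choice(m, size=2, replace=False)
        score = float(rng.uniform(0.02, 0.24))
        decoy_links.append((_link_peak(int(i)), _link_peak(int(k)), score))
    links = CoAccessLinkTable(true_links + decoy_links)

    manifest = {
        "spec": asdict(spec),
        "chrom": _CHROM,
        "bin_size": _BIN,
        "type_names": type_names,
        "signature_columns": sig_cols,
        "true_links": [
            [int(a.start // _BIN), int(b.start // _BIN), s] for a, b, s in true_links
        ],
        "decoy_links": [
            [int(a.start // _BIN), int(b.start // _BIN), s] for a, b, s in decoy_links
        ],
    }
    return matrix, groups, links, manifest


def batch_shift(
    matrix: CellPeakMatrix,
    delta_detection: float,
    seed: int,
    manifest: dict,
) -> CellPeakMatrix:
    """Shift the effective signature detection rate by ``delta_detection``.

    Emulates a batch/technical effect between datasets.  Negative deltas
    thin existing detections (each signature-position 1 is kept with
    probability ``(r + delta) / r``); positive deltas add Bernoulli ones at
    planted-signature positions only, at the rate needed to lift ``r`` to
    ``r + delta``.  Background positions are never touched and thinning
    never creates new ones.
    """
    r = float(manifest["spec"]["detection_rate"])
    target = r + delta_detection
    if not 0.0 <= target <= 1.0:
        raise ValueError(
            f"shifted detection rate {target} outside [0, 1]"
        )
    if delta_detection == 0:
        return matrix.with_values(matrix.values.copy())
    rng = np.random.default_rng(seed)
    cells_per_type = int(manifest["spec"]["cells_per_type"])
    type_names = manifest["type_names"]
    dense = np.asarray(matrix.values.todense(), dtype=np.int8)
    for t, name in enumerate(type_names):
        rows = slice(t * cells_per_type, (t + 1) * cells_per_type)
        cols = np.asarray(manifest["signature_columns"][name], dtype=int)
        block = dense[rows][:, cols]
        if delta_detection < 0:
            keep_p = target / r if r > 0 else 0.0
            block = block * (rng.random(block.shape) < keep_p)
        else:
            # P(new one) on current zeros so the overall rate reaches target
            add_p = delta_detection / (1.0 - r) if r < 1.0 else 0.0
            add = (block == 0) & (rng.random(block.shape) < add_p)
            block = block | add
        sub = dense[rows]
        sub[:, cols] = block.astype(np.int8)
        dense[rows] = sub
    return matrix.with_values(sp.csr_matrix(dense))


def write_fixture(
    outdir: str | Path,
    spec: SyntheticSpec,
) -> tuple[CellPeakMatrix, GroupAssignment, CoAccessLinkTable, dict]:
    """Generate and write the full fixture file set the pipeline consumes.

    Emits matrix.mtx/peaks.bed/barcodes.tsv, labels.tsv, links.csv and
    truth_manifest.json into ``outdir``; returns the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, groups, links, manifest = generate(spec)
    write_matrix(matrix, outdir)
    groups.write_tsv(outdir / "labels.tsv")
    links.to_csv(outdir / "links.csv")
    (outdir / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))
    return matrix, groups, links, manifest
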