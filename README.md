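# svmatac

Cell-type classification for single-cell ATAC-seq, built around repairing
the signal before classifying it.

scATAC-seq cell-peak matrices are near-binary and dominated by dropout:
only ~1–10% of a cell's truly accessible peaks are detected, so a
classifier trained on the raw matrix confuses related cell types. `svmatac`
implements a three-step pipeline:

1. **Group-based enhancement** — within each cell group (type or cluster)
   of `n` cells, a peak whose detection fraction reaches the cutoff
   (`c_enh ≤ Σ_j C_ij / n`, default `c_enh = 0.1`) is set to 1 in every
   cell of the group: its zeros are dropout, not closed chromatin.
2. **Co-accessibility imputation** — peak pairs with Cicero co-accessibility
   score `L_ik ≥ c_int` (default 0.25) are significantly connected; within a
   group, if one peak of such a pair is *distinct* (non-zero in all cells,
   `Σ_j C_kj = n`) the partner column is set to 1 as well. Called peaks are
   mapped to fixed 5 kb genome bins by the leftmost-overlap rule.
3. **Linear SVM** — a one-vs-rest linear-kernel SVM trained on the repaired
   matrix; prediction-time data is clustered first (enhancement and
   imputation are group-based), then repaired and classified.

Evaluation follows per-class precision/recall/F1 with macro-mean F1, a
row-normalized confusion heatmap, stratified k-fold cross-validation, and a
cross-dataset (train on A, predict B) design.

Intended users: computational epigenomics groups annotating scATAC-seq
datasets from a labeled reference, and anyone benchmarking imputation-aware
classifiers on sparse binary matrices.

## Worked example

Everything below runs offline on the bundled synthetic generator, which
plants 3 cell types × 100 cells over 2,000 five-kb bins with 40 signature
peaks per type, a 5% per-peak detection rate, 0.2% background, and 60 true
co-accessibility links (plus 60 sub-threshold decoys):

```python
from svmatac import (SyntheticSpec, generate, map_links_to_bins, enhance,
                     impute, run_intra)

matrix, groups, links, _ = generate(SyntheticSpec(seed=1))
print("cells x peaks:", matrix.shape, "| nonzero entries:", matrix.values.nnz)

link_map = map_links_to_bins(links, matrix.peaks)
enhanced = enhance(matrix, groups)              # c_enh = 0.1
imputed = impute(enhanced, groups, link_map)    # c_int = 0.25
print("ones raw -> enhanced -> imputed:",
      matrix.values.nnz, "->", enhanced.values.nnz, "->", imputed.values.nnz)

baseline, pipeline = run_intra(matrix, groups, link_map, k=5, seed=1)
print(f"baseline macro F1: {baseline.mean_f1:.4f}")
print(f"svmATAC  macro F1: {pipeline.mean_f1:.4f}")
print(pipeline.per_class.round(3))
```

prints

```
cells x peaks: (300, 2000) | nonzero entries: 1799
ones raw -> enhanced -> imputed: 1799 -> 2062 -> 2348
baseline macro F1: 0.8768
svmATAC  macro F1: 1.0000
       precision  recall   f1
type0        1.0     1.0  1.0
type1        1.0     1.0  1.0
type2        1.0     1.0  1.0
```

Reading it: enhancement saturates the few signature peaks whose within-type
detection fraction clears 0.1 (1799 → 2062 ones), imputation propagates
those saturated peaks across strong links (→ 2348 ones), and the repaired
matrix separates the three types perfectly in fivefold CV while the
raw-matrix SVM baseline reaches only 0.88 macro-F1. The ones-count deltas
are also logged by the CLI at each stage — added signal is added noise, so
watch them when tuning cutoffs.

The same estimators compose in scikit-learn style:
`SignalEnhancer(c_enh=0.1)` and `CoAccessImputer(link_map, c_int=0.25)` are
transformers (group labels passed as `y`), and `SvmAtacClassifier` is a
fit/predict classifier with `get_params`/`set_params`.

## Command line

```bash
svmatac simulate --seed 1 --outdir sim/                # synthetic fixture
svmatac build --fragments frags.tsv.gz --chrom-sizes hg19.sizes \
              --barcodes cells.txt --blacklist blacklist.bed --outdir mat/
svmatac train --matrix-dir mat/ --labels labels.tsv --links cicero.csv \
              --model-out model/
svmatac predict --matrix-dir new/ --model model/ --links cicero.csv \
                --k-clusters 8 --out predictions.tsv
svmatac cv --matrix-dir mat/ --labels labels.tsv --links cicero.csv \
           --outdir report/
```

Matrices are exchanged as MatrixMarket `matrix.mtx` + `peaks.bed` +
`barcodes.tsv`; labels and clusters as two-column TSV; links as Cicero-style
CSV (`Peak1,Peak2,coaccess`, either `chr1_100_600` or `chr1:100-600` peak
dialect). Every command echoes its effective configuration to
`run_config.json` in the output directory.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch — it simulates the default synthetic dataset, maps the link table to
bins, runs the enhance→impute→SVM pipeline inside stratified fivefold CV
against the raw-SVM baseline, prints both macro-F1 scores, and writes its
results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
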