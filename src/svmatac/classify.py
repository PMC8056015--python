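"""Linear-SVM cell-type classification over enhanced+imputed matrices.

The classifier is a one-vs-rest linear SVM.  Binary detection matrices are
already on a common scale, so no feature scaling is applied.  A fitted model
is bound to the peak set it was trained on via a fingerprint; predicting on
a matrix with a different peak set is an error, because train and predict
matrices must share the same peak regions for the learned weights to be
meaningful.

Prediction-time data is unlabeled, but enhancement and imputation are
group-based, so unlabeled cells are first clustered; :func:`cluster_cells`
provides a standard TF-IDF / LSI / k-means recipe for this.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.svm import LinearSVC

from .enhance import DEFAULT_C_ENH, SignalEnhancer
from .impute import DEFAULT_C_INT, BinLinkMap, CoAccessImputer
from .matrix import CellPeakMatrix, GroupAssignment

__all__ = ["SvmAtacClassifier", "train", "predict", "cluster_cells",
           "save_model", "load_model"]

_MODEL_FORMAT_VERSION = 1


def _extract(X):
    """Accept a CellPeakMatrix or a raw (sparse/dense) binary matrix."""
    if isinstance(X, CellPeakMatrix):
        return X.values, X.peaks.fingerprint(), X.barcodes
    return sp.csr_matrix(X), None, None


def _extract_groups(y, barcodes):
    if isinstance(y, GroupAssignment):
        if barcodes is None:
            raise ValueError("group assignment requires a CellPeakMatrix input")
        return y.labels_for(barcodes)
    return np.asarray(y, dtype=object)


class SvmAtacClassifier(BaseEstimator, ClassifierMixin):
    """One-vs-rest linear SVM with built-in enhancement and imputation.

    ``fit`` enhances and imputes the training matrix using the true labels
    as groups (both steps are group-based), then trains the SVM.  ``predict``
    applies the same preprocessing to the test matrix using supplied groups
    (cluster identifiers for unlabeled data) before scoring; with
    ``groups=None`` and ``preprocess=True`` cells are clustered into
    ``len(classes_)`` groups automatically.

    Parameters
    ----------
    C : float, default 1.0
        SVM regularization strength.
    c_enh : float, default 0.1
        Enhancement cutoff (fraction of non-zero cells in a group).
    c_int : float, default 0.25
        Co-accessibility score cutoff for imputation.
    link_map : BinLinkMap or None
        Bin-level co-accessibility links; imputation is skipped when None.
    preprocess : bool, default True
        Apply enhancement+imputation inside fit/predict.  False gives the
        raw-matrix SVM baseline.
    cascade : bool, default False
        Iterate imputation to a fixed point (off matches the single-pass
        definition).
    random_state : int, default 0
        Seed for the SVM solver and prediction-time clustering.

    Attributes
    ----------
    classes_ : ndarray of str
        Ordered class labels; decision-value ties resolve to the first.
    coef_, intercept_ : ndarray
        Per-class linear weights and intercepts (one row for binary).
    feature_fingerprint_ : str or None
        Digest of the training peak set (None when fitted on a bare matrix).
    """

    def __init__(
        self,
        C: float = 1.0,
        c_enh: float = DEFAULT_C_ENH,
        c_int: float = DEFAULT_C_INT,
        link_map: BinLinkMap | None = None,
        preprocess: bool = True,
        cascade: bool = False,
        random_state: int = 0,
    ):
        self.C = C
        self.c_enh = c_enh
        self.c_int = c_int
        self.link_map = link_map
        self.preprocess = preprocess
        self.cascade = cascade
        self.random_state = random_state

    # -- preprocessing ----------------------------------------------------
    def _enhance_impute(self, X: sp.csr_matrix, y: np.ndarray) -> sp.csr_matrix:
        X = SignalEnhancer(c_enh=self.c_enh).fit_transform(X, y)
        if self.link_map is not None and len(self.link_map):
            X = CoAccessImputer(
                self.link_map, c_int=self.c_int, cascade=self.cascade
            ).fit_transform(X, y)
        return X

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y) -> "SvmAtacClassifier":
        values, fingerprint, barcodes = _extract(X)
        labels = _extract_groups(y, barcodes)
        if labels.shape[0] != values.shape[0]:
            raise ValueError(
                f"{values.shape[0]} cells but {labels.shape[0]} labels"
            )
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires at least 2 classes")
        if self.preprocess:
            values = self._enhance_impute(values, labels)
        self._svm_ = LinearSVC(C=self.C, random_state=self.random_state)
        self._svm_.fit(values, labels)
        self.classes_ = self._svm_.classes_
        self.coef_ = self._svm_.coef_
        self.intercept_ = self._svm_.intercept_
        self.n_features_in_ = values.shape[1]
        self.feature_fingerprint_ = fingerprint
        return self

    def _check_features(self, values, fingerprint):
        mismatch = values.shape[1] != self.n_features_in_ or (
            fingerprint is not None
            and self.feature_fingerprint_ is not None
            and fingerprint != self.feature_fingerprint_
        )
        if mismatch:
            raise ValueError(
                "feature space mismatch: train and predict matrices must "
                "share the same peak regions"
            )

    def decision_function(self, X) -> np.ndarray:
        values, fingerprint, _ = _extract(X)
        self._check_features(values, fingerprint)
        return self._svm_.decision_function(values)

    def predict(self, X, groups=None, k_clusters: int | None = None):
        """Predict one label per cell.

        ``groups`` (array or GroupAssignment) drives prediction-time
        enhancement+imputation; when omitted and preprocessing is on, cells
        are clustered into ``k_clusters`` (default: the number of classes)
        with :func:`cluster_cells`.  Returns a GroupAssignment when ``X`` is
        a CellPeakMatrix, else an ndarray of labels.
        """
        values, fingerprint, barcodes = _extract(X)
        self._check_features(values, fingerprint)
        if self.preprocess:
            if groups is None:
                k = k_clusters or len(self.classes_)
                groups = _cluster_values(values, k, self.random_state)
            else:
                groups = _extract_groups(groups, barcodes)
            values = self._enhance_impute(values, groups)
        # LinearSVC breaks decision ties by first class, matching the
        # fixed-class-order contract.
        labels = self._svm_.predict(values)
        if barcodes is not None:
            return GroupAssignment.from_arrays(barcodes, labels)
        return labels

    def score(self, X, y, **kwargs) -> float:
        pred = self.predict(X, **kwargs)
        if isinstance(pred, GroupAssignment):
            _, _, barcodes = _extract(X)
            pred = pred.labels_for(barcodes)
        truth = _extract_groups(y, _extract(X)[2])
        return float(np.mean(pred == truth))


def _cluster_values(X: sp.csr_matrix, k: int, seed: int) -> np.ndarray:
    """TF-IDF -> truncated SVD (first component dropped) -> k-means."""
    n, m = X.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if k < 2:
        raise ValueError("k must be >= 2")
    X = X.astype(np.float64).tocsr()
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    row_sums[row_sums == 0] = 1.0
    tf = sp.diags(1.0 / row_sums) @ X
    col_sums = np.asarray(X.sum(axis=0)).ravel()
    idf = np.log(1.0 + n / np.maximum(col_sums, 1.0))
    tfidf = tf @ sp.diags(idf)
    # n-1 cap keeps the decomposition well-posed on tiny inputs
    n_comp = min(30, m - 1, n - 1)
    if n_comp >= 2:
        svd = TruncatedSVD(n_components=n_comp, random_state=seed)
        emb = svd.fit_transform(tfidf)[:, 1:]  # drop depth-correlated PC1
    else:
        emb = tfidf.toarray()
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(emb)


def cluster_cells(matrix: CellPeakMatrix, k: int, seed: int) -> GroupAssignment:
    """Cluster unlabeled cells into ``k`` groups ("c0".."c{k-1}").

    TF-IDF weighting of the binary matrix, truncated SVD to
    ``min(30, m-1)`` components with the first (sequencing-depth) component
    dropped, then k-means with a fixed seed.  Deterministic given the seed.
    """
    ids = _cluster_values(matrix.values, k, seed)
    return GroupAssignment.from_arrays(matrix.barcodes, [f"c{int(i)}" for i in ids])


# -- thin functional wrappers ------------------------------------------------

def train(
    matrix: CellPeakMatrix,
    groups: GroupAssignment,
    regularization: float = 1.0,
    link_map: BinLinkMap | None = None,
    c_enh: float = DEFAULT_C_ENH,
    c_int: float = DEFAULT_C_INT,
    preprocess: bool = True,
    random_state: int = 0,
) -> SvmAtacClassifier:
    """Fit a one-vs-rest linear SVM bound to the matrix's peak set."""
    clf = SvmAtacClassifier(
        C=regularization, c_enh=c_enh, c_int=c_int, link_map=link_map,
        preprocess=preprocess, random_state=random_state,
    )
    return clf.fit(matrix, groups)


def predict(
    model: SvmAtacClassifier,
    matrix: CellPeakMatrix,
    groups: GroupAssignment | None = None,
    k_clusters: int | None = None,
) -> GroupAssignment:
    """Predict cell types for every barcode of ``matrix``."""
    return model.predict(matrix, groups=groups, k_clusters=k_clusters)


# -- portable model archive --------------------------------------------------

def save_model(model: SvmAtacClassifier, outdir: str | Path) -> None:
    """Write a portable model archive: model.json + weights.npz."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _MODEL_FORMAT_VERSION,
        "multiclass": "one-vs-rest",
        "classes": [str(c) for c in model.classes_],
        "n_features": int(model.n_features_in_),
        "feature_fingerprint": model.feature_fingerprint_,
        "params": {
            "C": model.C,
            "c_enh": model.c_enh,
            "c_int": model.c_int,
            "preprocess": model.preprocess,
            "cascade": model.cascade,
            "random_state": model.random_state,
        },
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(outdir / "weights.npz", coef=model.coef_, intercept=model.intercept_)


def load_model(path: str | Path, link_map: BinLinkMap | None = None) -> SvmAtacClassifier:
    """Rebuild a classifier from :func:`save_model` output."""
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version in {path}")
    arrays = np.load(path / "weights.npz")
    clf = SvmAtacClassifier(link_map=link_map, **meta["params"])
    svm = LinearSVC(C=clf.C, random_state=clf.random_state)
    svm.classes_ = np.asarray(meta["classes"], dtype=object)
    svm.coef_ = arrays["coef"]
    svm.intercept_ = arrays["intercept"]
    svm.n_features_in_ = int(meta["n_features"])
    clf._svm_ = svm
    clf.classes_ = svm.classes_
    clf.coef_ = svm.coef_
    clf.intercept_ = svm.intercept_
    clf.n_features_in_ = int(meta["n_features"])
    clf.feature_fingerprint_ = meta["feature_fingerprint"]
    return clf
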