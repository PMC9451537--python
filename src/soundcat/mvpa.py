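"""Eight-way multivoxel pattern decoding and searchlight mapping.

The decoder is an sklearn-style estimator combining training-set-only
feature selection (top-k voxels by one-way ANOVA F across the eight
categories, k = 40 by default) with a one-vs-one linear support vector
machine (C = 1). Cross-validation is leave-one-run-out: every run's 24
stimulus β-patterns are one sample each, labelled by their 8-way
category, so the default five-run design gives 5 folds of 96 training
and 24 test samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import warnings

from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import f_classif
from sklearn.svm import SVC

from .stimuli import CATEGORIES, N_STIMULI
from .synth import BetaArray
from .univariate import ROIMask

DEFAULT_K = 40
CHANCE_8WAY = 1.0 / 8.0


def select_features(train_patterns: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Top-k voxels by one-way ANOVA F across the classes.

    Deterministic: ties (and NaN scores from zero-variance voxels,
    treated as 0) break toward the lowest voxel index. Selection must be
    computed on training folds only; this function never sees test data.
    """
    X = np.asarray(train_patterns, dtype=float)
    y = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes to score features")
    if k >= X.shape[1]:
        if k > X.shape[1]:
            warnings.warn(
                f"k={k} exceeds {X.shape[1]} voxels; returning all voxels",
                RuntimeWarning,
                stacklevel=2,
            )
        return np.arange(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.inf)
    order = np.lexsort((np.arange(F.size), -F))
    return np.sort(order[:k])


class EightWayDecoder(BaseEstimator, ClassifierMixin):
    """ANOVA-F voxel selection + one-vs-one linear SVM.

    Parameters
    ----------
    k : number of voxels retained by training-set feature selection.
    C : SVM regularisation (fixed, no search).
    """

    def __init__(self, k: int = DEFAULT_K, C: float = 1.0):
        self.k = k
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training fold lacks class diversity")
        self.selected_voxels_ = select_features(X, y, self.k)
        self.svc_ = SVC(kernel="linear", C=self.C, decision_function_shape="ovo")
        self.svc_.fit(X[:, self.selected_voxels_], y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.svc_.predict(X[:, self.selected_voxels_])

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class DecodingResult:
    subject_id: str
    roi: str
    fold_accuracies: list[float]
    selected_voxels: list[np.ndarray]
    n_classes: int = 8

    @property
    def accuracy(self) -> float:
        """Mean decoding accuracy (DA) over folds."""
        return float(np.mean(self.fold_accuracies))


def samples_from_runs(
    subject_betas: np.ndarray, labels_24: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten (runs, 24, voxels) β into samples, labels and run ids."""
    B = np.asarray(subject_betas, dtype=float)
    n_runs, n_cond, n_vox = B.shape
    if labels_24 is None:
        if n_cond != N_STIMULI:
            raise ValueError("default labels require 24 conditions")
        labels_24 = np.repeat(np.arange(len(CATEGORIES)), N_STIMULI // len(CATEGORIES))
    X = B.reshape(n_runs * n_cond, n_vox)
    y = np.tile(np.asarray(labels_24), n_runs)
    runs = np.repeat(np.arange(n_runs), n_cond)
    return X, y, runs


def decode_loro(
    subject_betas: np.ndarray,
    labels_24: np.ndarray | None = None,
    k: int = DEFAULT_K,
    C: float = 1.0,
    subject_id: str = "",
    roi: str = "",
) -> DecodingResult:
    """Leave-one-run-out eight-way decoding for one subject.

    Per fold: feature-select on the training runs only, fit the linear
    SVM, score on the held-out run.
    """
    B = np.asarray(subject_betas, dtype=float)
    if B.ndim != 3 or B.shape[0] < 2:
        raise ValueError("need (runs>=2, conditions, voxels) β array")
    X, y, runs = samples_from_runs(B, labels_24)
    fold_acc, fold_sel = [], []
    for r in range(B.shape[0]):
        tr, te = runs != r, runs == r
        clf = EightWayDecoder(k=k, C=C).fit(X[tr], y[tr])
        fold_acc.append(clf.score(X[te], y[te]))
        fold_sel.append(clf.selected_voxels_)
    return DecodingResult(
        subject_id=subject_id,
        roi=roi,
        fold_accuracies=fold_acc,
        selected_voxels=fold_sel,
        n_classes=len(np.unique(y)),
    )


def decode_eightway(
    betas: BetaArray, roi: ROIMask | None = None, k: int = DEFAULT_K, C: float = 1.0
) -> list[DecodingResult]:
    """LORO decoding for every subject of a BetaArray, optionally ROI-masked."""
    out = []
    for sid in betas.subject_ids:
        B = betas.subject(sid)
        roi_name = betas.roi
        if roi is not None:
            B = B[:, :, roi.voxel_indices]
            roi_name = roi.name
        out.append(decode_loro(B, k=k, C=C, subject_id=sid, roi=roi_name))
    return out


def decoding_table(results: list[DecodingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for f, acc in enumerate(r.fold_accuracies):
            rows.append(
                {"subject": r.subject_id, "roi": r.roi, "fold": f, "accuracy": acc}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Searchlight
# ---------------------------------------------------------------------------

@dataclass
class SearchlightMap:
    """Per-voxel statistic over a 3-D mask."""

    values: np.ndarray  # flat, one value per in-mask voxel
    mask: np.ndarray  # boolean 3-D grid
    radius: float
    statistic: str = ""

    def to_volume(self) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.values
        return vol


def sphere_neighbors(
    grid_shape: tuple[int, int, int],
    center: tuple[int, int, int],
    radius: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Flat indices of in-mask voxels within Euclidean ``radius`` of center."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    if not mask[center]:
        raise ValueError(f"center {center} lies outside the mask")
    r = int(np.floor(radius))
    offs = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(offs, offs, offs, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2 + 1e-12
    pts = np.stack([dx[keep], dy[keep], dz[keep]], axis=1) + np.asarray(center)
    ok = np.all((pts >= 0) & (pts < np.asarray(grid_shape)), axis=1)
    pts = pts[ok]
    flat = np.ravel_multi_index(tuple(pts.T), grid_shape)
    return np.sort(flat[mask.reshape(-1)[flat]])


def run_searchlight(
    patterns: np.ndarray,
    mask: np.ndarray,
    radius: float,
    map_fn,
    statistic: str = "",
) -> SearchlightMap:
    """Evaluate ``map_fn`` on each voxel's spherical neighborhood.

    ``patterns`` has voxels on the last axis in *grid flat order*
    restricted to the mask (i.e. ``patterns[..., i]`` is the i-th True
    voxel of ``mask`` in C order). ``map_fn`` receives the pattern array
    restricted to a neighborhood and returns a scalar.
    """
    mask = np.asarray(mask, dtype=bool)
    in_mask_flat = np.flatnonzero(mask.reshape(-1))
    pos_of_flat = {int(f): i for i, f in enumerate(in_mask_flat)}
    if patterns.shape[-1] != len(in_mask_flat):
        raise ValueError("patterns last axis must match the in-mask voxel count")
    values = np.empty(len(in_mask_flat))
    centers = np.argwhere(mask)
    for i, c in enumerate(centers):
        nb_flat = sphere_neighbors(mask.shape, tuple(c), radius, mask)
        cols = [pos_of_flat[int(f)] for f in nb_flat]
        try:
            values[i] = float(map_fn(patterns[..., cols]))
        except Exception as e:  # annotate with voxel context
            raise RuntimeError(f"searchlight map_fn failed at voxel {tuple(c)}") from e
    return SearchlightMap(values=values, mask=mask, radius=radius, statistic=statistic)


def searchlight_decoding_statistic(k: int = DEFAULT_K, C: float = 1.0):
    """map_fn factory: LORO decoding accuracy within a neighborhood."""

    def fn(local_patterns: np.ndarray) -> float:
        kk = min(k, local_patterns.shape[-1])
        return decode_loro(local_patterns, k=kk, C=C).accuracy

    return fn


def searchlight_stability_statistic():
    """map_fn factory: split-half pattern stability within a neighborhood."""
    from .rsa import split_half_stability

    return lambda local: split_half_stability(local)


__all__ = [
    "EightWayDecoder",
    "DecodingResult",
    "SearchlightMap",
    "DEFAULT_K",
    "CHANCE_8WAY",
    "select_features",
    "samples_from_runs",
    "decode_loro",
    "decode_eightway",
    "decoding_table",
    "sphere_neighbors",
    "run_searchlight",
    "searchlight_decoding_statistic",
    "searchlight_stability_statistic",
]
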