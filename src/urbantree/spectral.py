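"""Spectral false-positive filtering (stage 2B).

Around every candidate a 50 cm buffer is drawn on a seven-band ortho stack
(RGB from two acquisition years plus a near-infrared band) and per-band zonal
statistics (mean and population standard deviation) form a 14-dimensional
feature vector.  A binary TREE / NOT-TREE classifier trained on labelled
sample points then decides which candidates are vegetation; candidates whose
TREE posterior falls below the decision threshold are discarded.

Feature selection is a single-step permutation-importance ranking from a
seeded random forest.  Four classifiers are exposed behind one interface —
random forest (default), a single-hidden-layer neural network, and linear and
radial SVMs — with repeated k-fold cross-validated accuracy reported at
training time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import Raster, TreeCandidate
from .merge import MergeParams, merge_candidates

__all__ = [
    "BAND_NAMES",
    "FEATURE_NAMES",
    "OrthoStack",
    "ClassifierSpec",
    "SpectralModel",
    "zonal_features",
    "feature_table",
    "select_features",
    "train_classifier",
    "filter_candidates",
    "FeatureExtractionError",
]

logger = logging.getLogger(__name__)

#: canonical band order: 2014 RGB, 2017 RGB, 2017 near-infrared
BAND_NAMES = ("R14", "G14", "B14", "R17", "G17", "B17", "NIR17")
#: fixed feature order: mean then sd, band-major
FEATURE_NAMES = tuple(f"{b}_{s}" for b in BAND_NAMES for s in ("mean", "sd"))

TREE, NOT_TREE = "TREE", "NOT_TREE"


class FeatureExtractionError(ValueError):
    """Buffer entirely off-raster or covering only nodata pixels."""


@dataclass
class OrthoStack:
    """Seven co-registered ortho bands on one shared grid."""

    bands: dict[str, Raster]

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise ValueError(f"missing bands: {missing}")
        ref = self.bands[BAND_NAMES[0]]
        for name in BAND_NAMES:
            r = self.bands[name]
            if (
                r.origin != ref.origin
                or r.cell_size != ref.cell_size
                or r.values.shape != ref.values.shape
            ):
                raise ValueError(f"band {name} not on the shared grid")

    @property
    def grid(self) -> Raster:
        return self.bands[BAND_NAMES[0]]


@dataclass
class ClassifierSpec:
    """Which classifier to train and how to cross-validate it.

    algorithm: RF | ANN | SVM_LINEAR | SVM_RADIAL.
    cv_repeats: replicates of the k-fold cross-validation (default 3).
    cv_folds: folds per replicate (default 10).
    decision_threshold: minimum TREE posterior to keep a candidate.
    """

    algorithm: str = "RF"
    cv_repeats: int = 3
    cv_folds: int = 10
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("RF", "ANN", "SVM_LINEAR", "SVM_RADIAL"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")


@dataclass
class SpectralModel:
    """A fitted TREE/NOT-TREE classifier with its feature schema."""

    estimator: object
    feature_names: tuple[str, ...]
    cv_accuracy: float
    spec: ClassifierSpec

    def tree_posterior(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        tree_col = list(self.estimator.classes_).index(TREE)
        return proba[:, tree_col]


def _buffer_pixels(point: tuple[float, float], grid: Raster, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ii, jj) of cells whose centers lie within radius of point."""
    x, y = point
    c = grid.cell_size
    x0, y0 = grid.origin
    rc = int(np.ceil(radius / c)) + 1
    ci, cj = grid.index_of(x, y)
    i0, i1 = max(0, ci - rc), min(grid.n_rows, ci + rc + 1)
    j0, j1 = max(0, cj - rc), min(grid.n_cols, cj + rc + 1)
    if i0 >= i1 or j0 >= j1:
        return np.empty(0, int), np.empty(0, int)
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    cx, cy = grid.cell_center(ii, jj)
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
    return ii[inside], jj[inside]


def zonal_features(
    point: tuple[float, float], stack: OrthoStack, buffer_radius: float = 0.5
) -> np.ndarray:
    """14-feature vector (per-band mean and population sd) around ``point``.

    The zone is the set of pixels whose centers lie within ``buffer_radius``
    of the point.  Standard deviation uses the population (n) divisor — with
    only ~12 pixels in a 50 cm buffer the n vs n-1 choice is material, so it
    is fixed and documented here.  Raises FeatureExtractionError when the
    buffer misses the raster or covers only nodata.
    """
    if buffer_radius <= 0:
        raise ValueError("buffer_radius must be positive")
    ii, jj = _buffer_pixels(point, stack.grid, buffer_radius)
    if ii.size == 0:
        raise FeatureExtractionError("buffer entirely off-raster")
    feats = np.empty(len(FEATURE_NAMES))
    for k, band in enumerate(BAND_NAMES):
        vals = stack.bands[band].values[ii, jj]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise FeatureExtractionError(f"buffer covers only nodata in band {band}")
        feats[2 * k] = vals.mean()
        feats[2 * k + 1] = vals.std(ddof=0)
    return feats


def feature_table(
    points: Sequence[tuple[float, float]],
    stack: OrthoStack,
    buffer_radius: float = 0.5,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Feature vectors for many points as a DataFrame (one row per point).

    Points without spectral coverage (off-raster or all-nodata buffers) are
    skipped with a logged count; their labels are skipped with them.
    """
    rows, kept_labels = [], []
    dropped = 0
    for k, p in enumerate(points):
        try:
            rows.append(zonal_features(p, stack, buffer_radius))
        except FeatureExtractionError:
            dropped += 1
            continue
        if labels is not None:
            kept_labels.append(labels[k])
    if dropped:
        logger.info("feature_table: dropped %d points without spectral coverage", dropped)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        df["label"] = kept_labels
    return df


def select_features(
    train: pd.DataFrame,
    keep_fraction: Optional[float] = None,
    importance_threshold: Optional[float] = None,
    seed: int = 0,
) -> list[str]:
    """Rank features by permutation importance and keep a subset.

    A seeded random forest is fit on the full table, features are ranked by
    permutation importance, and either the top ``keep_fraction`` of them or
    those above ``importance_threshold`` are retained.  The subset is never
    empty: the top-ranked feature is always kept.
    """
    feats = [c for c in train.columns if c != "label"]
    if len(feats) < 2:
        raise ValueError("need at least 2 features to select from")
    y = train["label"]
    if y.nunique() < 2:
        raise ValueError("training set must contain both classes")
    X = train[feats].to_numpy()
    rf = RandomForestClassifier(n_estimators=100, random_state=seed)
    rf.fit(X, y)
    imp = permutation_importance(rf, X, y, n_repeats=5, random_state=seed)
    order = np.argsort(-imp.importances_mean, kind="stable")
    ranked = [feats[i] for i in order]
    if keep_fraction is not None:
        n_keep = max(1, int(round(keep_fraction * len(feats))))
        kept = ranked[:n_keep]
    elif importance_threshold is not None:
        kept = [f for f, i in zip(ranked, imp.importances_mean[order]) if i >= importance_threshold]
        if not kept:
            kept = ranked[:1]
    else:
        kept = ranked
    return kept


def _make_estimator(spec: ClassifierSpec):
    if spec.algorithm == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=spec.seed)
    if spec.algorithm == "ANN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000, random_state=spec.seed),
        )
    kernel = "linear" if spec.algorithm == "SVM_LINEAR" else "rbf"
    # calibrated SVM so filtering can threshold a TREE posterior
    return make_pipeline(
        StandardScaler(),
        CalibratedClassifierCV(SVC(kernel=kernel, random_state=spec.seed), ensemble=False),
    )


def train_classifier(
    train: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    features: Optional[Sequence[str]] = None,
) -> SpectralModel:
    """Fit a TREE/NOT-TREE classifier with repeated-CV accuracy reporting.

    ``train`` holds one row per labelled point with feature columns and a
    'label' column in {TREE, NOT_TREE}; ``features`` restricts the model to a
    selected subset (defaults to all feature columns).
    """
    spec = spec or ClassifierSpec()
    feats = list(features) if features is not None else [c for c in train.columns if c != "label"]
    y = train["label"].to_numpy()
    for cls in (TREE, NOT_TREE):
        if (y == cls).sum() < 10:
            raise ValueError(f"need >= 10 examples of class {cls}")
    X = train[feats].to_numpy()
    est = _make_estimator(spec)
    n_splits = min(spec.cv_folds, int(np.bincount(pd.factorize(y)[0]).min()))
    cv = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=spec.cv_repeats, random_state=spec.seed
    )
    scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
    est.fit(X, y)
    return SpectralModel(
        estimator=est,
        feature_names=tuple(feats),
        cv_accuracy=float(scores.mean()),
        spec=spec,
    )


def filter_candidates(
    candidates: Sequence[TreeCandidate],
    model: SpectralModel,
    stack: OrthoStack,
    buffer_radius: float = 0.5,
    merge_params: Optional[MergeParams] = None,
) -> list[TreeCandidate]:
    """Keep candidates the classifier calls TREE at the decision threshold.

    Candidates whose buffer misses the rasters (or hits only nodata) are
    dropped with a logged count, since no spectral evidence exists for them.
    Positions and ids are preserved; when ``merge_params`` is given the kept
    set is additionally merged (grouping survivors closer than 4 m), matching
    the pipeline's merge-after-every-stage rule.
    """
    kept: list[TreeCandidate] = []
    rows = []
    usable: list[TreeCandidate] = []
    dropped = 0
    for cand in candidates:
        try:
            feats = zonal_features(cand.position, stack, buffer_radius)
        except FeatureExtractionError:
            dropped += 1
            continue
        usable.append(cand)
        rows.append(feats)
    if dropped:
        logger.info("filter_candidates: dropped %d candidates without spectral coverage", dropped)
    if usable:
        table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
        X = table[list(model.feature_names)].to_numpy()
        post = model.tree_posterior(X)
        kept = [c for c, p in zip(usable, post) if p >= model.spec.decision_threshold]
    if merge_params is not None:
        kept = merge_candidates(kept, merge_params)
    return kept
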