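"""PCA-based Quality of Care Index scoring.

The QCI of a stratum is the first principal component of its four
care-quality ratio indices, rescaled to a 0-100 scale where higher means
better care.  The construction is:

1. *Orient* the features so that larger always means better care:
   ``prev_inc`` is kept as-is; ``mir``, ``daly_prev`` and ``yll_yld`` are
   negated (all three grow when care worsens).
2. Drop zero-variance features (recorded on the fitted model).
3. Z-score each remaining feature (mean 0, unit sample variance), i.e. the
   PCA operates on the correlation matrix — the four indices live on
   incommensurate scales, so covariance-PCA would let the widest-ranged
   index dominate.
4. Take the leading eigenvector of the correlation matrix as the loading
   vector, with its sign fixed so the loading sum is positive (the leading
   eigenvector is only defined up to sign; with the orientation of step 1
   this makes "higher score = better care" a testable contract).
5. Min-max rescale the projection to [0, 100] over the fitting pool
   (optionally with percentile bounds); strata scored outside the pool's
   range are clipped.

Strata with any missing index are excluded from fitting and scored as
missing — imputation would manufacture quality signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .indices import INDEX_COLS
from .io import STRATUM_COLS

__all__ = [
    "GOOD_FEATURES",
    "BAD_FEATURES",
    "QCIScorer",
    "orient_features",
    "principal_axis",
    "fit_qci",
    "score_qci",
    "model_to_yaml",
    "model_from_yaml",
]

#: indices where larger values indicate better care
GOOD_FEATURES = ("prev_inc",)
#: indices where larger values indicate worse care (negated before PCA)
BAD_FEATURES = ("mir", "daly_prev", "yll_yld")

_ZERO_VAR_RTOL = 1e-12


def orient_features(table: pd.DataFrame) -> pd.DataFrame:
    """Flip the sign of the "bad" indices so larger = better care on every
    column; returns a copy restricted to the four index columns."""
    out = table[list(INDEX_COLS)].astype(float).copy()
    for col in BAD_FEATURES:
        out[col] = -out[col]
    return out


def principal_axis(matrix) -> tuple[np.ndarray, float]:
    """Leading principal axis of an n x k matrix of z-scored features.

    Returns the unit loading vector of the first principal component —
    the top eigenvector of the sample correlation matrix — with its sign
    fixed so the loading sum is positive (tie-break: first nonzero loading
    positive), and the explained variance ratio (top eigenvalue / k).

    Raises ValueError when the matrix carries no variance.
    """
    Z = np.asarray(matrix, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2 or Z.shape[1] < 1:
        raise ValueError("need an n x k matrix with n >= 2, k >= 1")
    if not np.isfinite(Z).all():
        raise ValueError("matrix must be finite")
    if np.allclose(Z.std(axis=0, ddof=1), 0.0):
        raise ValueError("zero total variance: all rows identical")

    pca = PCA(n_components=1, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_[0]
    loadings = _fix_sign(loadings)
    # columns are z-scored (unit sample variance) so total variance == k
    evr = float(pca.explained_variance_[0] / Z.shape[1])
    return loadings, evr


def _fix_sign(loadings: np.ndarray) -> np.ndarray:
    s = loadings.sum()
    if abs(s) > 1e-12:
        return loadings if s > 0 else -loadings
    nz = loadings[np.abs(loadings) > 1e-12]
    if len(nz) and nz[0] < 0:
        return -loadings
    return loadings


class QCIScorer(BaseEstimator, TransformerMixin):
    """Fit the correlation-PCA care-quality score and map strata to 0-100.

    Parameters
    ----------
    lower_q, upper_q : float in [0, 1]
        Percentile bounds of the raw first-component score used as the 0
        and 100 anchors of the scale.  Defaults (0, 1) give a true min-max
        rescaling over the fitting pool.

    Attributes (after ``fit``)
    --------------------------
    feature_order_ : list of the four index names, fixed order.
    kept_features_ : features entering the PCA (positive variance).
    dropped_features_ : zero-variance features excluded from the PCA.
    means_, sds_ : per-kept-feature oriented means / sample SDs.
    loadings_ : unit loading vector over kept features, oriented so the
        loading sum is positive.
    explained_variance_ratio_ : top eigenvalue / number of kept features.
    score_min_, score_max_ : raw-score anchors of the 0-100 scale.
    fit_pool_size_ : number of strata in the fitting pool.
    """

    def __init__(self, lower_q: float = 0.0, upper_q: float = 1.0):
        self.lower_q = lower_q
        self.upper_q = upper_q

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        if not (0.0 <= self.lower_q < self.upper_q <= 1.0):
            raise ValueError("need 0 <= lower_q < upper_q <= 1")
        F = self._as_features(X)
        if np.isnan(F.to_numpy()).any():
            raise ValueError("fitting pool contains missing indices; drop flagged strata first")
        if len(F) < 2:
            raise ValueError("need at least 2 complete strata to fit")

        oriented = orient_features(F)
        means = oriented.mean(axis=0)
        sds = oriented.std(axis=0, ddof=1)
        scale = np.maximum(np.abs(means), 1.0)
        keep = sds.to_numpy() > _ZERO_VAR_RTOL * scale.to_numpy()
        if not keep.any():
            raise ValueError("zero total variance: all strata identical")

        self.feature_order_ = list(INDEX_COLS)
        self.kept_features_ = [f for f, k in zip(INDEX_COLS, keep) if k]
        self.dropped_features_ = [f for f, k in zip(INDEX_COLS, keep) if not k]
        self.means_ = means[self.kept_features_].to_numpy()
        self.sds_ = sds[self.kept_features_].to_numpy()

        Z = (oriented[self.kept_features_].to_numpy() - self.means_) / self.sds_
        self.loadings_, self.explained_variance_ratio_ = principal_axis(Z)

        raw = Z @ self.loadings_
        lo = float(np.quantile(raw, self.lower_q))
        hi = float(np.quantile(raw, self.upper_q))
        if not hi > lo:
            raise ValueError("degenerate score range on the fitting pool")
        self.score_min_, self.score_max_ = lo, hi
        self.fit_pool_size_ = int(len(F))
        return self

    # -- scoring -----------------------------------------------------------

    def raw_score(self, X) -> np.ndarray:
        """Projection on the oriented first principal axis (unscaled);
        NaN for strata with any missing index."""
        check_is_fitted(self, "loadings_")
        F = self._as_features(X)
        oriented = orient_features(F)
        Z = (oriented[self.kept_features_].to_numpy() - self.means_) / self.sds_
        return Z @ self.loadings_

    def transform(self, X) -> np.ndarray:
        """QCI on the 0-100 scale (clipped); NaN for incomplete strata."""
        raw = self.raw_score(X)
        qci = 100.0 * (raw - self.score_min_) / (self.score_max_ - self.score_min_)
        return np.clip(qci, 0.0, 100.0)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "feature_order": self.feature_order_,
            "kept_features": self.kept_features_,
            "dropped_features": self.dropped_features_,
            "means": [float(v) for v in self.means_],
            "sds": [float(v) for v in self.sds_],
            "loadings": [float(v) for v in self.loadings_],
            "explained_variance_ratio": float(self.explained_variance_ratio_),
            "score_min": self.score_min_,
            "score_max": self.score_max_,
            "fit_pool_size": self.fit_pool_size_,
            "scale_bounds": [self.lower_q, self.upper_q],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCIScorer":
        model = cls(lower_q=d["scale_bounds"][0], upper_q=d["scale_bounds"][1])
        model.feature_order_ = list(d["feature_order"])
        model.kept_features_ = list(d["kept_features"])
        model.dropped_features_ = list(d["dropped_features"])
        model.means_ = np.asarray(d["means"], dtype=float)
        model.sds_ = np.asarray(d["sds"], dtype=float)
        model.loadings_ = np.asarray(d["loadings"], dtype=float)
        model.explained_variance_ratio_ = float(d["explained_variance_ratio"])
        model.score_min_ = float(d["score_min"])
        model.score_max_ = float(d["score_max"])
        model.fit_pool_size_ = int(d["fit_pool_size"])
        return model

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _as_features(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in INDEX_COLS if c not in X.columns]
            if missing:
                raise ValueError(f"feature mismatch: missing index columns {missing}")
            return X[list(INDEX_COLS)].astype(float)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(INDEX_COLS):
            raise ValueError(f"expected {len(INDEX_COLS)} feature columns {list(INDEX_COLS)}")
        return pd.DataFrame(arr, columns=list(INDEX_COLS))


# -- functional wrappers ----------------------------------------------------

def fit_qci(index_table: pd.DataFrame, lower_q: float = 0.0, upper_q: float = 1.0) -> QCIScorer:
    """Fit a :class:`QCIScorer` on the complete strata of an IndexTable."""
    pool = _complete_rows(index_table)
    if len(pool) < 2:
        raise ValueError("need at least 2 complete strata to fit")
    return QCIScorer(lower_q=lower_q, upper_q=upper_q).fit(pool)


def score_qci(model: QCIScorer, index_table: pd.DataFrame) -> pd.DataFrame:
    """Score an IndexTable; returns a QCITable.

    Output columns: the stratum key, ``raw_score`` and ``qci`` (0-100,
    missing where the stratum was flagged in the IndexTable).
    """
    key_cols = [c for c in STRATUM_COLS if c in index_table.columns]
    out = index_table[key_cols].copy()
    complete = _complete_mask(index_table)
    raw = np.full(len(index_table), np.nan)
    qci = np.full(len(index_table), np.nan)
    if complete.any():
        sub = index_table.loc[complete]
        raw[complete.to_numpy()] = model.raw_score(sub)
        qci[complete.to_numpy()] = model.transform(sub)
    out["raw_score"] = raw
    out["qci"] = qci
    return out


def _complete_mask(index_table: pd.DataFrame) -> pd.Series:
    mask = ~index_table[list(INDEX_COLS)].isna().any(axis=1)
    if "missing_reason" in index_table.columns:
        mask &= index_table["missing_reason"].fillna("none") == "none"
    return mask


def _complete_rows(index_table: pd.DataFrame) -> pd.DataFrame:
    return index_table.loc[_complete_mask(index_table)]


def model_to_yaml(model: QCIScorer, path) -> None:
    """Serialize a fitted model to human-readable, round-trippable YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def model_from_yaml(path) -> QCIScorer:
    with open(path) as fh:
        return QCIScorer.from_dict(yaml.safe_load(fh))
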