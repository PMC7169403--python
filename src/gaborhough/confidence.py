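"""SVM confidence scoring on accumulator-space features.

A marking is only clinically useful if the operator knows when to trust it.
Following the idea of training a support vector machine on the Hough
accumulator space, this module summarizes an accumulator into a fixed-length
feature vector and fits an SVM with a cubic (degree-3 polynomial) kernel and
an automatically chosen kernel scale.  The signed margin is squashed to a
confidence in [0, 1] (0.5 at the decision boundary).

Features are summary statistics of the vote distribution rather than the
flattened raw array, so the feature length is independent of the search-grid
resolution:

    [max rate, mean, variance, peak-to-second-peak ratio, vote entropy,
     argmax pose coordinates normalized to their grid ranges (Sx, Sy, theta,
     y, x), fraction of votes within the suppression radius of the peak]

The "automatic kernel scale" is the median pairwise Euclidean distance
between the standardized training vectors — a standard deterministic reading
of that phrase; the cubic kernel is ``(x . x' / s^2 + 1)^3``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import SVC

from .ght import Accumulator

__all__ = [
    "FEATURE_NAMES",
    "DegenerateAccumulatorError",
    "featurize",
    "MarkingConfidenceSVC",
    "train_confidence",
    "score_confidence",
]

FEATURE_NAMES = (
    "max_rate",
    "mean_votes",
    "var_votes",
    "peak_ratio",
    "entropy",
    "argmax_sx",
    "argmax_sy",
    "argmax_theta",
    "argmax_y",
    "argmax_x",
    "peak_vote_fraction",
)

PEAK_RATIO_CAP = 1e6


class DegenerateAccumulatorError(ValueError):
    """Raised when an all-zero accumulator is featurized."""


def _norm_axis(values: np.ndarray, idx: int) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return 0.5
    return (float(values[idx]) - lo) / (hi - lo)


def featurize(acc: Accumulator, suppression_radius: float = 5.0) -> np.ndarray:
    """Summarize an accumulator into the fixed feature vector.

    Scale-free features (entropy, peak ratio, normalized argmax, peak vote
    fraction) are invariant to multiplying all votes by a positive constant;
    max and mean scale linearly with it.
    """
    v = np.asarray(acc.votes, dtype=float)
    total = v.sum()
    if total <= 0:
        raise DegenerateAccumulatorError("all-zero accumulator has no features")
    mx = v.max()
    mean = v.mean()
    var = v.var()
    p = (v / total).ravel()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    isx, isy, it, iy, ix = np.unravel_index(int(v.argmax()), v.shape)
    g = acc.grid
    h, w = v.shape[3], v.shape[4]

    # peak neighborhood in (x, y): votes near the peak, and the best rival cell
    yy, xx = np.mgrid[0:h, 0:w]
    near = (xx - ix) ** 2 + (yy - iy) ** 2 <= suppression_radius ** 2
    frac = float(v[:, :, :, near].sum() / total)
    far = ~near
    second = float(v[:, :, :, far].max()) if far.any() else 0.0
    ratio = mx / second if second > 0 else PEAK_RATIO_CAP
    ratio = min(ratio, PEAK_RATIO_CAP)

    return np.array(
        [
            mx,
            mean,
            var,
            ratio,
            entropy,
            _norm_axis(g.sx, isx),
            _norm_axis(g.sy, isy),
            _norm_axis(g.theta, it),
            iy / (h - 1) if h > 1 else 0.5,
            ix / (w - 1) if w > 1 else 0.5,
            frac,
        ]
    )


class MarkingConfidenceSVC:
    """Cubic-kernel SVM over accumulator features, sklearn-estimator style.

    Parameters
    ----------
    C : float
        SVM regularization strength.
    seed : int
        Seed recorded in the metadata; the fit itself is deterministic.

    Attributes (after :meth:`fit`)
    ------------------------------
    kernel_scale_ : float
        Median pairwise distance between standardized training vectors.
    mean_, std_ : ndarray
        Per-feature standardization statistics.
    support_vectors_, dual_coef_, intercept_ : ndarray
        The fitted decision function, stored explicitly so that scoring is
        bit-stable across serialization.
    """

    degree = 3

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C, "seed": self.seed}

    def set_params(self, **params) -> "MarkingConfidenceSVC":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarkingConfidenceSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("exactly two classes are required")
        if min(np.sum(y == c) for c in classes) < 2:
            raise ValueError("at least two samples per class are required")

        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.std_ = std
        Z = (X - self.mean_) / self.std_

        d = pdist(Z)
        s = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        self.kernel_scale_ = s

        svc = SVC(
            kernel="poly",
            degree=self.degree,
            gamma=1.0 / s ** 2,
            coef0=1.0,
            C=self.C,
        )
        svc.fit(Z, y)
        self.classes_ = svc.classes_
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_.copy()
        self.intercept_ = svc.intercept_.copy()
        self.n_features_in_ = X.shape[1]
        self.metadata_ = {"n_samples": int(len(y)), "seed": int(self.seed)}
        return self

    # -- scoring -----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "support_vectors_"):
            raise RuntimeError("model is not fitted")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed margin; positive values favor ``classes_[1]`` (correct)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} != trained {self.n_features_in_}"
            )
        Z = (X - self.mean_) / self.std_
        g = 1.0 / self.kernel_scale_ ** 2
        K = (g * (Z @ self.support_vectors_.T) + 1.0) ** self.degree
        return (K @ self.dual_coef_.ravel()) + self.intercept_[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        df = self.decision_function(X)
        return np.where(df > 0, self.classes_[1], self.classes_[0])

    def confidence(self, X: np.ndarray) -> np.ndarray:
        """Monotone map of the margin into [0, 1]; 0.5 at the boundary."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def loocv_accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        """Leave-one-out cross-validated accuracy of this configuration."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        hits = 0
        for train, test in LeaveOneOut().split(X):
            if np.unique(y[train]).size < 2:
                continue
            m = MarkingConfidenceSVC(C=self.C, seed=self.seed).fit(
                X[train], y[train]
            )
            hits += int(m.predict(X[test])[0] == y[test][0])
        return hits / len(y)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format_version": 1,
            "params": self.get_params(),
            "kernel_scale": self.kernel_scale_,
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
            "classes": self.classes_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "n_features_in": self.n_features_in_,
            "metadata": self.metadata_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkingConfidenceSVC":
        m = cls(**d["params"])
        m.kernel_scale_ = float(d["kernel_scale"])
        m.mean_ = np.array(d["mean"], dtype=float)
        m.std_ = np.array(d["std"], dtype=float)
        m.classes_ = np.array(d["classes"])
        m.support_vectors_ = np.array(d["support_vectors"], dtype=float)
        m.dual_coef_ = np.array(d["dual_coef"], dtype=float)
        m.intercept_ = np.array(d["intercept"], dtype=float)
        m.n_features_in_ = int(d["n_features_in"])
        m.metadata_ = dict(d["metadata"])
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MarkingConfidenceSVC":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_confidence(
    samples: np.ndarray, labels: np.ndarray, seed: int = 0
) -> tuple[MarkingConfidenceSVC, float]:
    """Fit the confidence SVM and report its leave-one-out accuracy."""
    model = MarkingConfidenceSVC(seed=seed).fit(samples, labels)
    return model, model.loocv_accuracy(samples, labels)


def score_confidence(model: MarkingConfidenceSVC, f: np.ndarray) -> float:
    """Confidence in [0, 1] for one feature vector."""
    return float(model.confidence(np.atleast_2d(f))[0])
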