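"""Discrete AdaBoost over decision stumps, for false-positive region removal.

Binary boosting with labels in {+1, -1}: each round fits the weighted-error
minimizing depth-1 stump (exhaustive search over feature/threshold pairs,
thresholds at midpoints of consecutive distinct values), weights it by
``alpha = 0.5 * ln((1 - eps) / eps)`` and reweights samples by
``w <- w * exp(-alpha * y * h(x))`` followed by renormalization — after
which, by the classical identity, the misclassified samples carry exactly
half of the total weight. Training stops early when a stump is perfect
(eps = 0, recorded with a capped alpha) or when no stump beats chance
(eps >= 0.5).

The strong classifier scores ``sum_t alpha_t h_t(x)`` and labels by sign
(ties map to +1). Candidate PED regions predicted negative are deleted in
whole from the mask. Implemented from scratch: the boosting loop and its
reweighting identity are part of the method's contract and are oracle-
tested against hand-computed rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import RegionMask

__all__ = [
    "Stump",
    "StrongClassifier",
    "TrainingError",
    "train",
    "predict",
    "predict_batch",
    "filter_regions",
    "make_labels",
]

_EPS_ERR = 1e-12


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class Stump:
    """h(x) = polarity if x[feature] > threshold else -polarity."""

    feature: int
    threshold: float
    polarity: int  # +1 or -1

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.where(X[:, self.feature] > self.threshold, self.polarity,
                        -self.polarity)


@dataclass
class StrongClassifier:
    """Weighted ensemble of decision stumps."""

    stumps: list[Stump] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        s = np.zeros(X.shape[0])
        for stump, alpha in zip(self.stumps, self.alphas):
            s += alpha * stump(X)
        return s

    def to_json(self, path) -> None:
        payload = {
            "stumps": [
                {"feature": s.feature, "threshold": s.threshold,
                 "polarity": s.polarity}
                for s in self.stumps
            ],
            "alphas": list(self.alphas),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StrongClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            stumps=[Stump(int(s["feature"]), float(s["threshold"]),
                          int(s["polarity"])) for s in payload["stumps"]],
            alphas=[float(a) for a in payload["alphas"]],
        )


def _best_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray
                ) -> tuple[Stump, float]:
    """Exhaustive weighted-error-minimizing stump.

    Ties break toward the lowest feature index, then the lowest threshold,
    then polarity +1.
    """
    m, d = X.shape
    best: tuple[float, int, float, int] | None = None  # (err, feat, thr, pol)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        wy = (w * y)[order]
        # err(+1 pol, threshold after i) = P[y=+1, x<=thr] + P[y=-1, x>thr]
        wpos_cum = np.concatenate([[0.0], np.cumsum(np.where(wy > 0, wy, 0.0))])
        wneg_cum = np.concatenate([[0.0], np.cumsum(np.where(wy < 0, -wy, 0.0))])
        wneg_tot = wneg_cum[-1]
        # candidate cut positions: before all points, and between distinct values
        cuts = [0] + [i + 1 for i in range(m - 1) if xs[i] < xs[i + 1]]
        for i in cuts:
            thr = xs[0] - 1.0 if i == 0 else 0.5 * (xs[i - 1] + xs[i])
            err_pos = wpos_cum[i] + (wneg_tot - wneg_cum[i])
            for pol, err in ((1, err_pos), (-1, 1.0 - err_pos)):
                cand = (err, j, thr, pol)
                if best is None or (
                    err < best[0] - _EPS_ERR
                    or (abs(err - best[0]) <= _EPS_ERR and cand[1:] < best[1:])
                ):
                    best = cand
    assert best is not None
    err, j, thr, pol = best
    return Stump(j, float(thr), pol), float(max(err, 0.0))


def train(X: np.ndarray, y: np.ndarray, n_rounds: int = 50,
          weights: np.ndarray | None = None) -> StrongClassifier:
    """Train a discrete AdaBoost ensemble.

    ``X`` is (m, n_features), ``y`` in {+1, -1} with both classes present,
    ``weights`` optional initial sample weights (uniform by default).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if n_rounds < 1:
        raise TrainingError("n_rounds must be >= 1")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("feature matrix and labels disagree in length")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise TrainingError("training needs both classes present")
    m = X.shape[0]
    w = np.full(m, 1.0 / m) if weights is None else np.asarray(weights, float)
    w = w / w.sum()

    clf = StrongClassifier()
    for _ in range(n_rounds):
        stump, eps = _best_stump(X, y, w)
        if eps >= 0.5:
            break
        alpha = 0.5 * np.log((1.0 - eps) / max(eps, _EPS_ERR))
        clf.stumps.append(stump)
        clf.alphas.append(float(alpha))
        if eps <= _EPS_ERR:
            break
        h = stump(X)
        w = w * np.exp(-alpha * y * h)
        w = w / w.sum()
    if not clf.stumps:
        raise TrainingError("no weak classifier beat chance on round 1")
    return clf


def predict(clf: StrongClassifier, fv: np.ndarray) -> tuple[float, int]:
    """Score and sign-label one feature vector (score 0 maps to +1)."""
    score = float(clf.score(np.atleast_2d(fv))[0])
    return score, (1 if score >= 0 else -1)


def predict_batch(clf: StrongClassifier, X: np.ndarray) -> np.ndarray:
    return np.where(clf.score(X) >= 0, 1, -1)


def make_labels(regions, truth_mask: np.ndarray,
                overlap_threshold: float = 0.5) -> np.ndarray:
    """+1 for regions with ``|region & truth| / |region| >= threshold``, else -1."""
    labels = np.empty(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        xs, zs = region.pixels[:, 0], region.pixels[:, 1]
        inside = truth_mask[xs, region.bscan, zs].sum()
        labels[i] = 1 if inside / region.size >= overlap_threshold else -1
    return labels


def filter_regions(mask: RegionMask, regions, features: np.ndarray,
                   clf: StrongClassifier) -> RegionMask:
    """Keep only regions the classifier labels positive; drop others whole."""
    if len(regions) != len(features):
        raise TrainingError("every region needs a feature vector")
    out = np.zeros_like(mask.mask)
    if len(regions):
        keep = predict_batch(clf, np.asarray(features)) > 0
        for region, k in zip(regions, keep):
            if k:
                out[region.pixels[:, 0], region.bscan, region.pixels[:, 1]] = True
    return RegionMask(out)
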