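"""Face-verification distance: normalization, chi-square components,
learned feature weights, and per-dyad averaging.

The face of each picture is a nonnegative feature vector (in the real
study, post-ReLU activations of a deep network; here, synthetic
embeddings). Verification works on the per-feature chi-square components
of picture pairs: a linear max-margin classifier separates same- from
different-individual pairs, its (nonnegative-clipped) coefficients become
feature weights, and the weighted chi-square distance between pictures is
averaged over all cross picture pairs of each unordered dyad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingSet",
    "VerificationModel",
    "normalize_features",
    "chi2_components",
    "learn_verification_weights",
    "kfold_verification_accuracy",
    "weighted_chi2_distance",
    "sample_verification_pairs",
    "dyad_facial_distances",
]


class EmbeddingSet:
    """Per-picture nonnegative feature vectors with ids and ages.

    ``features`` is ``(n_pictures, d)``; rows belong to
    ``individual_ids`` and were taken at ``ages`` (days).
    """

    def __init__(
        self,
        features: np.ndarray,
        individual_ids: Sequence[str],
        ages: np.ndarray,
    ):
        features = np.asarray(features, dtype=float)
        if features.ndim != 2:
            raise ValueError("features must be 2-D (pictures x features)")
        if np.any(features < 0):
            raise ValueError("features must be nonnegative")
        if len(individual_ids) != len(features) or len(ages) != len(features):
            raise ValueError("ids/ages length must match number of pictures")
        self.features = features
        self.individual_ids = np.asarray(individual_ids, dtype=object)
        self.ages = np.asarray(ages, dtype=float)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.features, columns=[f"f_{j}" for j in range(self.dim)]
        )
        df.insert(0, "age_days", self.ages)
        df.insert(0, "individual_id", self.individual_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EmbeddingSet":
        cols = [c for c in df.columns if c.startswith("f_")]
        return cls(
            df[cols].to_numpy(float),
            df["individual_id"].astype(str).to_numpy(),
            df["age_days"].to_numpy(float),
        )

    @classmethod
    def read_csv(cls, path) -> "EmbeddingSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class VerificationModel:
    """Learned per-feature weights and the verification accuracy."""

    weights: np.ndarray
    training_accuracy: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not np.any(self.weights > 0):
            raise ValueError("at least one weight must be positive")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"feature": np.arange(len(self.weights)), "weight": self.weights}
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, training_accuracy: float = float("nan")):
        df = pd.read_csv(path)
        return cls(df["weight"].to_numpy(float), training_accuracy)


def normalize_features(v: np.ndarray) -> np.ndarray:
    """L1-normalize nonnegative feature vector(s) to unit sum.

    Accepts a single vector or a matrix (rows normalized independently).
    An all-zero vector is an error: it carries no face information and
    the chi-square distance is undefined for it.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("features must be nonnegative")
    s = v.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot normalize an all-zero feature vector")
    return v / s


def chi2_components(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature chi-square components ``(x_i - y_i)^2 / (x_i + y_i)``.

    Symmetric in (x, y); the 0/0 case (both features vanish) is the limit
    of the formula and yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(
            f"length mismatch: {x.shape[-1]} vs {y.shape[-1]} features"
        )
    denom = x + y
    num = (x - y) ** 2
    out = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=float)
    np.divide(num, denom, out=out, where=denom > 0)
    return out


def learn_verification_weights(
    same_pairs: np.ndarray,
    diff_pairs: np.ndarray,
    C: float = 1.0,
) -> VerificationModel:
    """Learn chi-square feature weights with a linear max-margin classifier.

    ``same_pairs`` / ``diff_pairs`` are matrices of per-feature chi-square
    components for same- and different-individual picture pairs. Inputs
    are standardized and a primal linear SVM (squared hinge, C=1 default)
    is fit with response 1 for same and 0 for different pairs. Since a
    *large* component signals a *different* pair, the raw coefficients of
    the same-class are negative for informative features; weights are the
    magnitudes of the discriminating direction on the raw component
    scale, with wrong-signed (negative) weights clipped to 0 so that the
    weighted distance remains a valid dissimilarity.

    Returns the model with its held-in training accuracy.
    """
    same_pairs = np.atleast_2d(np.asarray(same_pairs, dtype=float))
    diff_pairs = np.atleast_2d(np.asarray(diff_pairs, dtype=float))
    if len(same_pairs) == 0 or len(diff_pairs) == 0:
        raise ValueError("both same- and different-individual pairs are required")
    if same_pairs.shape[1] != diff_pairs.shape[1]:
        raise ValueError("same/diff pair components differ in length")
    X = np.vstack([same_pairs, diff_pairs])
    y = np.concatenate([np.ones(len(same_pairs)), np.zeros(len(diff_pairs))])
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / scale
    clf = LinearSVC(C=C, dual=False)
    clf.fit(Xs, y)
    acc = float(clf.score(Xs, y))
    # coef is for class "same" (1); informative components push towards
    # "different", so the distance weights are the negated coefficients,
    # mapped back to the raw component scale.
    w = -clf.coef_.ravel() / scale
    w = np.clip(w, 0.0, None)
    if not np.any(w > 0):
        raise ValueError(
            "degenerate training set: no feature discriminates the classes"
        )
    return VerificationModel(weights=w, training_accuracy=acc)


def kfold_verification_accuracy(
    same_pairs: np.ndarray,
    diff_pairs: np.ndarray,
    k: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> float:
    """Cross-validated verification accuracy (honest counterpart of the
    held-in training accuracy)."""
    X = np.vstack([np.atleast_2d(same_pairs), np.atleast_2d(diff_pairs)])
    y = np.concatenate(
        [np.ones(len(np.atleast_2d(same_pairs))),
         np.zeros(len(np.atleast_2d(diff_pairs)))]
    )
    pipe = make_pipeline(StandardScaler(), LinearSVC(C=C, dual=False))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(pipe, X, y, cv=cv)))


def weighted_chi2_distance(
    x: np.ndarray, y: np.ndarray, model: VerificationModel
) -> float:
    """Weighted chi-square distance ``sum_i w_i (x_i-y_i)^2/(x_i+y_i)``."""
    comps = chi2_components(x, y)
    if comps.shape[-1] != len(model.weights):
        raise ValueError(
            f"dimension mismatch: {comps.shape[-1]} components vs "
            f"{len(model.weights)} weights"
        )
    return float(comps @ model.weights)


def sample_verification_pairs(
    embeddings: EmbeddingSet,
    n_pairs_per_class: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced same/different picture pairs as chi-square components.

    Samples up to ``n_pairs_per_class`` pairs per class (bounded by the
    number of distinct pairs available) from L1-normalized features.
    """
    feats = normalize_features(embeddings.features)
    ids = embeddings.individual_ids
    n = len(feats)
    same, diff = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (same if ids[i] == ids[j] else diff).append((i, j))
    if not same or not diff:
        raise ValueError("need both same- and different-individual pairs")

    def _take(pairs, k):
        idx = rng.choice(len(pairs), size=min(k, len(pairs)), replace=False)
        ii = np.array([pairs[t][0] for t in idx])
        jj = np.array([pairs[t][1] for t in idx])
        return chi2_components(feats[ii], feats[jj])

    return _take(same, n_pairs_per_class), _take(diff, n_pairs_per_class)


def dyad_facial_distances(
    embeddings: EmbeddingSet, model: VerificationModel
) -> pd.DataFrame:
    """Mean weighted chi-square distance for every unordered dyad.

    For each pair of distinct individuals, averages the weighted
    chi-square distance over all cross picture pairs (pictures of one
    against pictures of the other) and records the pair count and the
    mean absolute age difference over the same picture pairs. Individuals
    without pictures are skipped with a logged warning.
    """
    feats = normalize_features(embeddings.features)
    if feats.shape[1] != len(model.weights):
        raise ValueError("embedding dimension does not match model weights")
    ids = embeddings.individual_ids
    uniq = list(dict.fromkeys(ids))
    groups = {u: np.flatnonzero(ids == u) for u in uniq}
    empties = [u for u, g in groups.items() if len(g) == 0]
    for u in empties:
        logger.warning("individual %s has no pictures; skipped", u)
        del groups[u]
    uniq = [u for u in uniq if u in groups]
    if len(uniq) < 2:
        raise ValueError("need at least two individuals with pictures")

    w = model.weights
    ages = embeddings.ages
    rows = []
    for a_pos in range(len(uniq)):
        ga = groups[uniq[a_pos]]
        fa = feats[ga]
        for b_pos in range(a_pos + 1, len(uniq)):
            gb = groups[uniq[b_pos]]
            fb = feats[gb]
            x = fa[:, None, :]
            ycol = fb[None, :, :]
            denom = x + ycol
            comp = np.zeros_like(denom)
            np.divide((x - ycol) ** 2, denom, out=comp, where=denom > 0)
            dmat = comp @ w
            age_diff = np.abs(ages[ga][:, None] - ages[gb][None, :])
            id_a, id_b = sorted((uniq[a_pos], uniq[b_pos]))
            rows.append(
                {
                    "id_a": id_a,
                    "id_b": id_b,
                    "mean_distance": float(dmat.mean()),
                    "n_picture_pairs": int(dmat.size),
                    "mean_age_distance": float(age_diff.mean()),
                }
            )
    return pd.DataFrame(rows)
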