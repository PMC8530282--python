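"""Model interpretation: saliency importance, FSL weights, top-fraction selection.

Saliency scores a feature by the mean absolute gradient of the pre-sigmoid
logit with respect to that input, averaged over samples (the pre-sigmoid
output avoids gradient saturation).  When the model carries a Feature
Selection Layer, its learned non-negative weights are an alternative,
directly interpretable importance measure.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .netlayers import Network, NetworkError

__all__ = [
    "saliency_importance",
    "fsl_importance",
    "top_fraction",
    "importance_summary",
]


def _feature_ids(model: Network, n: int, feature_ids: Sequence[str] | None) -> list[str]:
    if feature_ids is not None:
        ids = list(feature_ids)
    elif model.feature_ids is not None:
        ids = list(model.feature_ids)
    else:
        ids = [f"feature_{i}" for i in range(n)]
    if len(ids) != n:
        raise NetworkError(f"{len(ids)} feature ids for {n} input features")
    return ids


def saliency_importance(
    model: Network, X: np.ndarray, feature_ids: Sequence[str] | None = None
) -> dict[str, float]:
    """Mean |d logit / d x_k| over the rows of ``X``, keyed by feature id.

    Dropout is disabled; scores are finite and non-negative, and a feature
    whose every path to the output is masked out scores exactly 0.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a nonempty samples x features matrix")
    grads = model.input_gradients(X)
    scores = np.abs(grads).mean(axis=0)
    ids = _feature_ids(model, X.shape[1], feature_ids)
    return dict(zip(ids, scores.tolist()))


def fsl_importance(
    model: Network, feature_ids: Sequence[str] | None = None
) -> dict[str, float]:
    """The learned non-negative FSL weight per input feature."""
    fsl = model.fsl
    if fsl is None:
        raise NetworkError("model has no feature selection layer")
    ids = _feature_ids(model, fsl.w.size, feature_ids)
    return dict(zip(ids, fsl.w.tolist()))


def top_fraction(importance: Mapping[str, float], q: float = 0.2) -> set[str]:
    """The ceil(q * n) features with the highest scores.

    Ties at the cutoff break by lexicographic feature id.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if not importance:
        raise ValueError("empty importance mapping")
    k = math.ceil(q * len(importance))
    ordered = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    return {fid for fid, _ in ordered[:k]}


def importance_summary(importance: Mapping[str, float]) -> dict:
    """Count/fraction of strictly positive scores plus log10 scores for plotting."""
    scores = np.array(list(importance.values()), dtype=float)
    positive = scores[scores > 0]
    return {
        "n_features": int(scores.size),
        "n_nonzero": int(positive.size),
        "fraction_nonzero": float(positive.size / scores.size) if scores.size else 0.0,
        "log10_scores": np.log10(positive).tolist(),
    }
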