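"""Five-class linear Bayesian (Gaussian LDA) per-pixel classification.

Each pixel's stain-feature vector x is scored against five tissue classes
(macrophage, darkly stained tumor, lightly stained tumor, vessel, stroma)
with the linear discriminant

    delta_k(x) = x' S^-1 m_k - 1/2 m_k' S^-1 m_k + log pi_k

where m_k is the class mean, S the shared (pooled) covariance and pi_k the
prior. Shared covariance makes every decision boundary linear. Training is
done once from annotated label masks and the model is then frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["LabelScheme", "ClassifierModel", "train", "classify", "train_from_masks"]

SCHEME_VERSION = 1


class LabelScheme(IntEnum):
    """Stable integer codes for the five pixel classes."""

    MACROPHAGE = 0
    TUMOR_DARK = 1
    TUMOR_LIGHT = 2
    VESSEL = 3
    STROMA = 4


@dataclass
class ClassifierModel:
    """Frozen Gaussian-LDA model: class means, pooled covariance, priors."""

    means: np.ndarray        # (n_classes, n_features)
    covariance: np.ndarray   # (n_features, n_features), SPD after regularization
    priors: np.ndarray       # (n_classes,), >= 0, sums to 1
    channel_names: tuple[str, ...]
    n_per_class: tuple[int, ...]
    scheme_version: int = SCHEME_VERSION

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        self.priors = np.asarray(self.priors, dtype=np.float64)
        if (self.priors < 0).any() or not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must be nonnegative and sum to 1")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        # positive-definiteness check via Cholesky
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance is not positive definite") from exc

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def discriminant_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear weights W (n_classes, n_features) and biases b so that
        delta_k(x) = W[k] @ x + b[k]."""
        siginv_mu = np.linalg.solve(self.covariance, self.means.T).T
        bias = -0.5 * np.sum(siginv_mu * self.means, axis=1) + np.log(self.priors)
        return siginv_mu, bias

    def save(self, path: str | Path) -> None:
        payload = {
            "scheme_version": self.scheme_version,
            "classes": [c.name for c in LabelScheme],
            "channels": list(self.channel_names),
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "n_per_class": list(self.n_per_class),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            means=np.array(payload["means"]),
            covariance=np.array(payload["covariance"]),
            priors=np.array(payload["priors"]),
            channel_names=tuple(payload["channels"]),
            n_per_class=tuple(payload["n_per_class"]),
            scheme_version=int(payload["scheme_version"]),
        )


def train(
    labeled_samples: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    regularization: float = 1e-6,
    priors: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ClassifierModel:
    """Fit class means and a pooled covariance from per-class samples.

    ``labeled_samples`` maps each class code of :class:`LabelScheme` to an
    (n_k, d) array of feature vectors; every class needs >= 2 samples. The
    pooled covariance is regularized by ``regularization * mean-variance``
    times the identity. Priors default to uniform — the annotations come
    from pathologist-guided sampling, which is not frequency-representative.
    """
    if not isinstance(labeled_samples, Mapping):
        labeled_samples = dict(enumerate(labeled_samples))
    codes = sorted(int(c) for c in LabelScheme)
    missing = [c for c in codes if c not in labeled_samples]
    if missing:
        raise ValueError(f"missing training samples for classes {missing}")
    arrays = [np.atleast_2d(np.asarray(labeled_samples[c], dtype=np.float64)) for c in codes]
    for c, a in zip(codes, arrays):
        if a.shape[0] < 2:
            raise ValueError(f"class {c} needs >= 2 samples, got {a.shape[0]}")
    d = arrays[0].shape[1]
    means = np.stack([a.mean(axis=0) for a in arrays])
    n_total = sum(a.shape[0] for a in arrays)
    k = len(codes)
    scatter = np.zeros((d, d))
    for a, mu in zip(arrays, means):
        dev = a - mu
        scatter += dev.T @ dev
    pooled = scatter / max(n_total - k, 1)
    # trace-scaled ridge so the regularization is unit free
    scale = np.trace(pooled) / d if np.trace(pooled) > 0 else 1.0
    pooled = pooled + regularization * scale * np.eye(d)
    if priors is None:
        pri = np.full(k, 1.0 / k)
    else:
        pri = np.asarray(priors, dtype=np.float64)
        pri = pri / pri.sum()
    try:
        np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is degenerate; increase regularization"
        ) from exc
    names = tuple(channel_names) if channel_names else tuple(f"ch{i}" for i in range(d))
    return ClassifierModel(
        means=means,
        covariance=pooled,
        priors=pri,
        channel_names=names,
        n_per_class=tuple(a.shape[0] for a in arrays),
    )


def classify(stack, model: ClassifierModel) -> np.ndarray:
    """Assign every pixel of a FeatureStack (or (H, W, d) array) to the class
    with the highest linear discriminant score; ties go to the lowest class
    code (np.argmax takes the first maximum). Returns an (H, W) uint8 map.
    """
    channels = getattr(stack, "channels", None)
    if channels is None:
        channels = np.asarray(stack)
    h, w, d = channels.shape
    if d != model.n_features:
        raise ValueError(
            f"feature stack has {d} channels but model expects {model.n_features}"
        )
    weights, bias = model.discriminant_weights()
    scores = channels.reshape(-1, d).astype(np.float64) @ weights.T + bias
    return scores.argmax(axis=1).astype(np.uint8).reshape(h, w)


def train_from_masks(
    feature_stacks: Sequence,
    label_masks: Sequence[np.ndarray],
    regularization: float = 1e-6,
    max_per_class: int = 20000,
    seed: int = 0,
) -> ClassifierModel:
    """Train from paired feature stacks and per-pixel label masks.

    Pixels are pooled per class across all images; if a class has more than
    ``max_per_class`` pixels a deterministic subsample is used.
    """
    rng = np.random.default_rng(seed)
    per_class: dict[int, list[np.ndarray]] = {int(c): [] for c in LabelScheme}
    names: tuple[str, ...] | None = None
    for stack, mask in zip(feature_stacks, label_masks):
        channels = getattr(stack, "channels", None)
        if channels is None:
            channels = np.asarray(stack)
        if names is None:
            names = getattr(stack, "channel_names", None)
        flat = channels.reshape(-1, channels.shape[2])
        labels = np.asarray(mask).ravel()
        for c in per_class:
            sel = flat[labels == c]
            if sel.size:
                per_class[c].append(sel)
    samples: dict[int, np.ndarray] = {}
    for c, chunks in per_class.items():
        if not chunks:
            raise ValueError(f"no training pixels for class {LabelScheme(c).name}")
        arr = np.concatenate(chunks, axis=0)
        if arr.shape[0] > max_per_class:
            idx = rng.choice(arr.shape[0], size=max_per_class, replace=False)
            arr = arr[np.sort(idx)]
        samples[c] = arr
    return train(samples, regularization=regularization, channel_names=names)
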