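"""Stain separation: RGB -> per-stain contrast channels.

The three chromogens (Vector Blue for CD31+ endothelium, DAB for CD68+
macrophages, Fast Red for pan-Mena tumor cells) and the light-green
counterstain combine approximately additively in optical-density (OD)
space (Beer-Lambert). Each stain is modeled as a unit direction in OD
space; per-pixel concentrations are recovered by least squares and then
median-filtered to suppress speckle before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

__all__ = ["StainMatrix", "FeatureStack", "rgb_to_od", "extract_features"]

# Reference chromogen colors (RGB 0-255). These defaults are fitted to the
# synthetic renderer's palette; for real slides supply measured colors via
# the config file.
DEFAULT_STAIN_COLORS: dict[str, tuple[int, int, int]] = {
    "vessel": (70, 90, 200),        # Vector Blue (CD31)
    "macrophage": (120, 80, 30),    # DAB (CD68)
    "tumor": (210, 100, 130),       # Fast Red (pan-Mena), mid-tone
    "counterstain": (200, 230, 200),  # light green
}


def rgb_to_od(raster: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to optical density.

    ``od = -log10((v + 1) / 256)`` per channel, so white maps to ~0 and
    darker pixels to larger OD. Output is float32, always >= 0.
    """
    v = np.asarray(raster, dtype=np.float32)
    return -np.log10((v + 1.0) / 256.0)


def _color_to_od_unit(rgb: tuple[int, int, int]) -> np.ndarray:
    od = rgb_to_od(np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3)).ravel()
    norm = np.linalg.norm(od)
    if norm == 0:
        raise ValueError(f"stain color {rgb} has zero optical density (white)")
    return od / norm


@dataclass
class StainMatrix:
    """Unit OD direction per stain, columns ordered as ``names``."""

    names: tuple[str, ...]
    od_vectors: np.ndarray  # shape (3, n_stains), unit columns

    def __post_init__(self) -> None:
        self.od_vectors = np.asarray(self.od_vectors, dtype=np.float64)
        if self.od_vectors.shape != (3, len(self.names)):
            raise ValueError("od_vectors must be 3 x n_stains")
        if (self.od_vectors < -1e-9).any():
            raise ValueError("stain OD vectors must be nonnegative")
        norms = np.linalg.norm(self.od_vectors, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain OD vectors must be unit norm")
        if np.linalg.matrix_rank(self.od_vectors) < min(3, len(self.names)):
            raise ValueError("stain matrix is rank deficient")

    @classmethod
    def from_colors(cls, colors: dict[str, tuple[int, int, int]] | None = None) -> "StainMatrix":
        """Build from named RGB reference colors (the config representation)."""
        colors = dict(colors or DEFAULT_STAIN_COLORS)
        names = tuple(colors)
        vecs = np.stack([_color_to_od_unit(tuple(colors[n])) for n in names], axis=1)
        return cls(names, vecs)

    def to_colors(self) -> dict[str, list[float]]:
        return {n: self.od_vectors[:, i].tolist() for i, n in enumerate(self.names)}


@dataclass
class FeatureStack:
    """Per-pixel stain-concentration channels (arbitrary units, >= 0)."""

    channels: np.ndarray  # (H, W, n_stains) float32
    channel_names: tuple[str, ...]
    median_radius: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (H*W, n_channels) view for classification."""
        return self.channels.reshape(-1, self.n_channels)


def _nnls_by_support(od_flat: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Nonnegative least-squares unmixing, vectorized over pixels.

    With a handful of stains the NNLS solution can be found exactly by
    enumerating column supports: for each nonempty subset of stains solve
    the unconstrained least squares on that subset, keep solutions with all
    coefficients nonnegative, and per pixel take the feasible support with
    the smallest residual, preferring fewer stains on ties (so a pure-stain
    pixel loads only its own channel). Deterministic; falls back to the
    clipped minimum-norm solution for pixels with no feasible support.
    """
    n_px = od_flat.shape[0]
    n_stains = vectors.shape[1]
    best = np.clip(od_flat @ np.linalg.pinv(vectors).T, 0.0, None)
    best_res = np.full(n_px, np.inf, dtype=np.float64)
    supports = sorted(
        (s for r in range(1, n_stains + 1) for s in combinations(range(n_stains), r)),
        key=lambda s: (len(s), s),
    )
    for support in supports:
        sub = vectors[:, support]
        coef = od_flat @ np.linalg.pinv(sub).T  # (n_px, |support|)
        resid = np.einsum("ij,ij->i", od_flat - coef @ sub.T, od_flat - coef @ sub.T)
        feasible = (coef >= -1e-9).all(axis=1)
        win = feasible & (resid < best_res - 1e-12)
        if win.any():
            best_res[win] = resid[win]
            best[win] = 0.0
            best[np.ix_(win, support)] = np.clip(coef[win], 0.0, None)
    return best


def extract_features(
    raster: np.ndarray,
    stain_matrix: StainMatrix | None = None,
    median_radius: int = 1,
) -> FeatureStack:
    """Unmix an RGB image into per-stain channels and median-filter them.

    Per pixel, OD is decomposed onto the stain directions by nonnegative
    least squares (see :func:`_nnls_by_support`), then each channel is
    smoothed with a square median filter of the given radius
    (``median_radius = 0`` disables filtering).
    """
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")
    stain_matrix = stain_matrix or StainMatrix.from_colors()
    od = rgb_to_od(raster)  # (H, W, 3)
    conc = _nnls_by_support(
        od.reshape(-1, 3).astype(np.float64), stain_matrix.od_vectors
    ).astype(np.float32)
    h, w = od.shape[:2]
    stack = conc.reshape(h, w, -1)
    if median_radius > 0:
        size = 2 * median_radius + 1
        stack = np.stack(
            [ndimage.median_filter(stack[..., i], size=size) for i in range(stack.shape[2])],
            axis=-1,
        )
    return FeatureStack(
        channels=np.ascontiguousarray(stack, dtype=np.float32),
        channel_names=stain_matrix.names,
        median_radius=median_radius,
    )
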