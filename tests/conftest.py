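import numpy as np
import pytest

from tmemdp.config import RunConfig
from tmemdp.evaluation import train_default_model
from tmemdp.slide_io import CalibrationParams


@pytest.fixture(scope="session")
def default_model():
    """Pixel classifier trained once per session on generated fields."""
    return train_default_model(RunConfig(), seed=0)


@pytest.fixture(scope="session")
def calib_1um():
    """Calibration used by the synthetic renderer: 1 um/px, 300x400 um HPF."""
    return CalibrationParams(microns_per_pixel=1.0)


# ---------------------------------------------------------------------------
# brute-force oracles shared across test modules


def brute_point_in_polygon(px: float, py: float, poly: list[tuple[float, float]]) -> bool:
    """Crossing-number point-in-polygon (strict interior for generic points)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def brute_boundary_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Object pixels with >= 1 non-object 8-neighbor (image edge counts)."""
    h, w = mask.shape
    out = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            boundary = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        boundary = True
            if boundary:
                out.append((r, c))
    return out


def brute_contact_fraction(obj_mask: np.ndarray, neighbor_mask: np.ndarray) -> float:
    """Per-pixel adjacency count oracle for perimeter-contact fractions."""
    h, w = obj_mask.shape
    boundary = brute_boundary_pixels(obj_mask)
    if not boundary:
        return 0.0
    touching = 0
    for r, c in boundary:
        hit = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and neighbor_mask[rr, cc] and not obj_mask[rr, cc]:
                    hit = True
        if hit:
            touching += 1
    return touching / len(boundary)
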