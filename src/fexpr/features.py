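"""Frame-level feature extraction.

One frame (49 landmarks + grayscale raster) becomes a 1617-dimensional
vector: 1176 geometric features (all pairwise landmark distances,
normalised by the inter-ocular distance for in-plane rotation and scale
invariance) and 441 appearance features (a reduced landmark-local
histogram-of-oriented-gradients descriptor: 9 gradient maps per landmark,
each pooled to one scalar).

Feature naming is fixed forever: ``dist_i_j`` for landmark pairs i < j in
lexicographic order, then ``hog_l_k`` for landmark l and map k in 0..8
(landmark-major). Importance aggregation relies on this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .corpus import Corpus, FrameRecord
from .landmarks import LEFT_EYE, N_LANDMARKS, RIGHT_EYE

N_MAPS = 9
N_GEOMETRIC = N_LANDMARKS * (N_LANDMARKS - 1) // 2   # 1176
N_APPEARANCE = N_LANDMARKS * N_MAPS                  # 441
N_FEATURES = N_GEOMETRIC + N_APPEARANCE              # 1617

#: fraction of the IOD used as the side of the landmark-local window
WINDOW_IOD_FRACTION = 0.2


@lru_cache(maxsize=1)
def feature_names() -> tuple[str, ...]:
    """The 1617 feature names, in extraction order."""
    geo = tuple(f"dist_{i}_{j}"
                for i in range(N_LANDMARKS) for j in range(i + 1, N_LANDMARKS))
    app = tuple(f"hog_{l}_{k}" for l in range(N_LANDMARKS) for k in range(N_MAPS))
    return geo + app


@lru_cache(maxsize=1)
def feature_types() -> tuple[str, ...]:
    """Per-feature type tag, aligned with :func:`feature_names`."""
    return ("geometric",) * N_GEOMETRIC + ("appearance",) * N_APPEARANCE


@dataclass(frozen=True)
class FeatureVector:
    """A named 1617-dimensional frame descriptor."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values")

    @property
    def names(self) -> tuple[str, ...]:
        return feature_names()

    @property
    def types(self) -> tuple[str, ...]:
        return feature_types()

    @property
    def geometric(self) -> np.ndarray:
        return self.values[:N_GEOMETRIC]

    @property
    def appearance(self) -> np.ndarray:
        return self.values[N_GEOMETRIC:]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def interocular_distance(landmarks: np.ndarray) -> float:
    """Distance between the two eye centroids (6 landmarks each), pixels."""
    pts = np.asarray(landmarks, dtype=float)
    if pts.shape != (N_LANDMARKS, 2) or not np.isfinite(pts).all():
        raise ValueError("expected a finite (49, 2) landmark array")
    left = pts[list(LEFT_EYE)].mean(axis=0)
    right = pts[list(RIGHT_EYE)].mean(axis=0)
    iod = float(np.linalg.norm(left - right))
    if iod <= 0:
        raise ValueError("degenerate face: coincident eye centroids")
    return iod


def geometric_features(landmarks: np.ndarray, iod: float | None = None) -> np.ndarray:
    """IOD-normalised pairwise distances, lexicographic pair order (i < j).

    ``iod`` may be forced (e.g. for sub-configurations in testing);
    otherwise it is computed from the eye landmarks of the 49-point set.
    """
    pts = np.asarray(landmarks, dtype=float)
    if iod is None:
        iod = interocular_distance(pts)
    if iod <= 0:
        raise ValueError("IOD must be strictly positive")
    return pdist(pts) / iod


def _window_bounds(center: tuple[float, float], side: int,
                   shape: tuple[int, int]) -> tuple[int, int, int, int]:
    cx, cy = int(round(center[0])), int(round(center[1]))
    half = side // 2
    x0, x1 = max(0, cx - half), min(shape[1], cx + half + 1)
    y0, y1 = max(0, cy - half), min(shape[0], cy + half + 1)
    if x0 >= x1 or y0 >= y1:
        raise ValueError(f"window around ({center[0]}, {center[1]}) is empty "
                         "after clipping to the image")
    return x0, x1, y0, y1


def gradient_maps(image: np.ndarray, center: tuple[float, float],
                  window_side: int) -> np.ndarray:
    """Nine gradient maps over a square window centred at ``center`` (x, y).

    Central-difference gradients with edge replication are computed over
    the window (clipped to the image). Map 0 is the per-pixel gradient
    magnitude; maps 1-8 hold the magnitude where the signed gradient
    orientation (atan2, [0, 360) degrees) falls in the corresponding
    45-degree bin, zero elsewhere — a hard assignment, so map 0 equals
    the pixel-wise sum of maps 1-8 exactly.
    """
    img = np.asarray(image, dtype=float)
    if img.dtype != float:
        img = img.astype(float)
    if image.dtype == np.uint8:
        img = img / 255.0
    x0, x1, y0, y1 = _window_bounds(center, window_side, img.shape)
    win = img[y0:y1, x0:x1]
    padded = np.pad(win, 1, mode="edge")
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    angle = np.degrees(np.arctan2(gy, gx)) % 360.0
    bins = np.minimum((angle // 45.0).astype(int), 7)
    maps = np.zeros((N_MAPS,) + win.shape)
    maps[0] = mag
    for k in range(8):
        maps[k + 1] = np.where(bins == k, mag, 0.0)
    return maps


def window_side(iod: float, fraction: float = WINDOW_IOD_FRACTION) -> int:
    """Window side: ``fraction * IOD`` rounded to the nearest odd int >= 3."""
    target = fraction * iod
    side = 2 * int(np.round((target - 1) / 2.0)) + 1
    return max(3, side)


def appearance_features(image: np.ndarray, landmarks: np.ndarray,
                        iod: float | None = None) -> np.ndarray:
    """441 landmark-local gradient scalars, landmark-major, map-minor.

    For each landmark the 9 gradient maps over its IOD-scaled window are
    each pooled to one scalar: the map sum divided by the window pixel
    count (a mean, robust to border clipping).
    """
    pts = np.asarray(landmarks, dtype=float)
    if iod is None:
        iod = interocular_distance(pts)
    side = window_side(iod)
    out = np.empty(N_APPEARANCE)
    for l, (x, y) in enumerate(pts):
        maps = gradient_maps(image, (x, y), side)
        out[l * N_MAPS:(l + 1) * N_MAPS] = (
            maps.reshape(N_MAPS, -1).sum(axis=1) / maps[0].size)
    return out


def extract(frame: FrameRecord) -> FeatureVector:
    """Full 1617-feature descriptor of one frame (geometric then appearance)."""
    if frame.image is None:
        raise ValueError(f"{frame.video_id}: frame has no image")
    iod = interocular_distance(frame.landmarks)
    geo = geometric_features(frame.landmarks, iod=iod)
    app = appearance_features(frame.image, frame.landmarks, iod=iod)
    return FeatureVector(values=np.concatenate([geo, app]))


def feature_matrix(corpus: Corpus) -> pd.DataFrame:
    """Extract every frame of a corpus; rows indexed by video_id."""
    rows = {f.video_id: extract(f).values for f in corpus.frames}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(feature_names()))


def write_features(table: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a feature matrix as CSV with a sidecar JSON of parameters."""
    import json
    from pathlib import Path

    path = Path(path)
    table.to_csv(path, index_label="video_id")
    sidecar = {"n_features": table.shape[1],
               "window_iod_fraction": WINDOW_IOD_FRACTION}
    sidecar.update(params or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
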