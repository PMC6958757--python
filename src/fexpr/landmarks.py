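"""Canonical 49-point facial landmark layout.

The package works throughout in the common 49-point tracker convention,
with image coordinates: x grows rightward, y grows downward, origin at the
top-left, units are pixels on a 256 x 256 canonical canvas.

Region indexing (fixed forever; feature naming and importance aggregation
depend on it):

======== ======= ========================================================
region   indices layout
======== ======= ========================================================
brows    0-9     5 left-brow points (0-4, lateral to medial) then 5
                 right-brow points (5-9, medial to lateral)
nose     10-18   4 bridge points (10-13, top to bottom) then 5 points
                 along the nostril line (14-18, left to right)
eyes     19-30   6 left-eye points (19-24) then 6 right-eye points
                 (25-30); each eye is outer corner, two upper-lid points,
                 inner corner, two lower-lid points (a closed hexagon)
mouth    31-48   12 outer-lip points (31-42: left corner, 5 upper-lip,
                 right corner, 5 lower-lip) then 6 inner-lip points
                 (43-48: left corner, 2 upper, right corner, 2 lower)
======== ======= ========================================================

"left"/"right" are in image terms (smaller/larger x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Emotion classes, in the fixed label order used everywhere in the package.
EMOTIONS: tuple[str, ...] = ("neutral", "happiness", "anger", "sadness")

N_LANDMARKS = 49
CANVAS_SIZE = 256
MIDLINE_X = CANVAS_SIZE / 2.0

REGIONS: dict[str, tuple[int, int]] = {
    "brows": (0, 10),
    "nose": (10, 19),
    "eyes": (19, 31),
    "mouth": (31, 49),
}

LEFT_EYE = tuple(range(19, 25))
RIGHT_EYE = tuple(range(25, 31))

# Mirror partner of each landmark under reflection about the vertical
# midline (self-partners sit on the midline).
MIRROR_INDEX = np.array(
    [9, 8, 7, 6, 5, 4, 3, 2, 1, 0,               # brows
     10, 11, 12, 13, 18, 17, 16, 15, 14,          # nose
     25, 26, 27, 28, 29, 30, 19, 20, 21, 22, 23, 24,  # eyes
     37, 36, 35, 34, 33, 32, 31, 42, 41, 40, 39, 38,  # outer mouth
     46, 45, 44, 43, 48, 47],                     # inner mouth
    dtype=int,
)

_TEMPLATE = np.array(
    [
        # left brow 0-4
        (76, 96), (87, 92), (98, 90), (109, 92), (120, 95),
        # right brow 5-9
        (136, 95), (147, 92), (158, 90), (169, 92), (180, 96),
        # nose bridge 10-13
        (128, 112), (128, 124), (128, 136), (128, 148),
        # nostril line 14-18
        (108, 160), (118, 164), (128, 166), (138, 164), (148, 160),
        # left eye 19-24
        (78, 120), (88, 114), (98, 114), (108, 120), (98, 126), (88, 126),
        # right eye 25-30
        (178, 120), (168, 114), (158, 114), (148, 120), (158, 126), (168, 126),
        # outer mouth 31-42
        (98, 190), (106, 184), (116, 180), (128, 178), (140, 180), (150, 184),
        (158, 190), (150, 196), (140, 200), (128, 202), (116, 200), (106, 196),
        # inner mouth 43-48
        (106, 190), (117, 186), (139, 186), (150, 190), (139, 194), (117, 194),
    ],
    dtype=float,
)

#: side of each landmark relative to the midline: -1 left, 0 midline, +1 right
SIDE = np.sign(_TEMPLATE[:, 0] - MIDLINE_X).astype(int)

#: landmark chains drawn by the renderer; (indices, closed)
DRAW_CHAINS: tuple[tuple[tuple[int, ...], bool], ...] = (
    (tuple(range(0, 5)), False),      # left brow
    (tuple(range(5, 10)), False),     # right brow
    (tuple(range(10, 14)), False),    # nose bridge
    (tuple(range(14, 19)), False),    # nostril line
    (LEFT_EYE, True),
    (RIGHT_EYE, True),
    (tuple(range(31, 43)), True),     # outer lips
    (tuple(range(43, 49)), True),     # inner lips
)


@dataclass(frozen=True)
class LandmarkTemplate:
    """The canonical neutral-face landmark configuration.

    Attributes
    ----------
    points
        ``(49, 2)`` array of (x, y) coordinates in canonical pixels.
    region_index
        Length-49 array of region labels ("brows", "nose", "eyes", "mouth").
    """

    points: np.ndarray
    region_index: np.ndarray

    @property
    def interocular_distance(self) -> float:
        left = self.points[list(LEFT_EYE)].mean(axis=0)
        right = self.points[list(RIGHT_EYE)].mean(axis=0)
        return float(np.linalg.norm(left - right))


def region_labels() -> np.ndarray:
    """Per-landmark region label array in index order."""
    labels = np.empty(N_LANDMARKS, dtype=object)
    for name, (lo, hi) in REGIONS.items():
        labels[lo:hi] = name
    return labels


def make_template() -> LandmarkTemplate:
    """Return the fixed canonical 49-point template.

    Deterministic; the layout is mirror-symmetric about ``x = 128`` to
    machine precision and has a strictly positive inter-ocular distance.
    """
    return LandmarkTemplate(points=_TEMPLATE.copy(), region_index=region_labels())


def mirror_points(points: np.ndarray) -> np.ndarray:
    """Reflect a 49-point configuration about the vertical midline.

    Point ``i`` of the result is the reflection of point ``MIRROR_INDEX[i]``,
    so a symmetric face maps onto itself.
    """
    pts = np.asarray(points, dtype=float)
    out = pts[MIRROR_INDEX].copy()
    out[:, 0] = 2 * MIDLINE_X - out[:, 0]
    return out
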