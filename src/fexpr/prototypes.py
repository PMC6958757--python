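"""Emotion displacement prototypes.

Each prototype is a 49 x 2 vector field (canonical pixels at intensity 1)
added to a subject's neutral configuration to produce an expression. The
numbers below are fixture data chosen to caricature the standard facial
action patterns, not measurements:

* happiness — mouth corners pulled up and outward, lower lip raised,
  lower eyelids raised (eye narrowing); the strongest prototype, since
  smiles are the most recognisable posed expression.
* anger — inner brow ends pulled down and together, lips compressed
  vertically and corners drawn inward, slight upper-lid lowering.
* sadness — inner brow ends raised, mouth corners pulled down, upper
  eyelids drooping.
* neutral — the zero field.

Prototypes are built from a left-side/midline specification and mirrored,
so they are exactly symmetric; asymmetry is injected later by the
generator's per-side scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import EMOTIONS, MIRROR_INDEX, N_LANDMARKS


@dataclass(frozen=True)
class EmotionPrototype:
    """A named displacement field applied at expression intensity 1."""

    emotion: str
    displacement: np.ndarray  # (49, 2), canonical pixels
    description: str


def _symmetric_field(left_spec: dict[int, tuple[float, float]]) -> np.ndarray:
    """Expand a left-side/midline displacement spec into a symmetric field.

    For every specified landmark i, the mirror partner receives the
    x-negated displacement; midline points may be specified directly.
    """
    field = np.zeros((N_LANDMARKS, 2))
    for i, (dx, dy) in left_spec.items():
        field[i] = (dx, dy)
        j = int(MIRROR_INDEX[i])
        if j != i:
            field[j] = (-dx, dy)
    return field


_HAPPINESS = _symmetric_field({
    # outer lips: corner up/out, neighbours follow
    31: (-6.0, -8.0), 32: (-3.0, -5.0), 33: (-1.0, -2.0), 34: (0.0, -1.5),
    42: (-5.0, -6.0), 41: (-2.0, -3.0), 40: (0.0, -2.0),
    # inner lips
    43: (-5.0, -6.0), 44: (-2.0, -3.0), 48: (-2.0, -4.0),
    # eye narrowing: lower lids up, upper lids slightly down
    23: (0.0, -3.0), 24: (0.0, -3.0), 20: (0.0, 1.5), 21: (0.0, 1.5),
})

_ANGER = _symmetric_field({
    # inner brow ends down and toward the midline
    4: (3.0, 5.0), 3: (2.0, 3.5), 2: (1.0, 2.0),
    # lip compression: corners in, upper lip down, lower lip up
    31: (2.0, 0.0), 32: (0.0, 2.0), 33: (0.0, 2.0), 34: (0.0, 2.0),
    42: (0.0, -2.0), 41: (0.0, -2.0), 40: (0.0, -2.0),
    43: (1.5, 0.0), 44: (0.0, 2.5), 48: (0.0, -2.5),
    # glare: upper lids lowered
    20: (0.0, 1.0), 21: (0.0, 1.0),
})

_SADNESS = _symmetric_field({
    # inner brow ends raised and slightly together
    4: (1.0, -5.0), 3: (0.5, -3.0),
    # mouth corners pulled down
    31: (-2.0, 5.0), 32: (-1.0, 3.0), 42: (-1.0, 3.0), 43: (-1.0, 3.0),
    # drooping upper lids
    20: (0.0, 2.0), 21: (0.0, 2.0),
})

PROTOTYPES: dict[str, EmotionPrototype] = {
    "neutral": EmotionPrototype(
        "neutral", np.zeros((N_LANDMARKS, 2)), "relaxed face, zero displacement"),
    "happiness": EmotionPrototype(
        "happiness", _HAPPINESS, "smile: mouth corners up/out, eyes narrowed"),
    "anger": EmotionPrototype(
        "anger", _ANGER, "frown: inner brows down/in, lips compressed"),
    "sadness": EmotionPrototype(
        "sadness", _SADNESS, "inner brows raised, mouth corners down"),
}

assert tuple(PROTOTYPES) == EMOTIONS


def get_prototype(emotion: str) -> EmotionPrototype:
    try:
        return PROTOTYPES[emotion]
    except KeyError:
        raise ValueError(
            f"unknown emotion {emotion!r}; expected one of {EMOTIONS}") from None
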