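"""Landmark-level attribution of forest feature importance.

A trained forest's impurity-decrease importances (which sum to 1 over the
1617 named features) are aggregated two ways:

* by feature type — the geometric vs appearance contribution split, in
  percent;
* by landmark — each ``hog_l_k`` importance accrues to landmark ``l``;
  each ``dist_i_j`` importance accrues half to ``i`` and half to ``j``;
  weights are renormalised within each type.

The *effective landmark count* (smallest number of top-ranked landmarks
holding a given importance mass, default 90%) operationalises "how many
landmarks the classifier needs".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .landmarks import N_LANDMARKS

_DIST = re.compile(r"^dist_(\d+)_(\d+)$")
_HOG = re.compile(r"^hog_(\d+)_(\d+)$")

FEATURE_TYPES = ("geometric", "appearance")


def _as_named_importances(model_or_importances, names=None) -> pd.Series:
    """Accept a ClassificationResults, Series, or (values, names) pair."""
    obj = model_or_importances
    if hasattr(obj, "importances"):          # ClassificationResults
        return obj.importances()
    if isinstance(obj, pd.Series):
        return obj
    if hasattr(obj, "feature_importances_"):  # fitted sklearn forest
        if names is None:
            raise ValueError("a bare sklearn model needs feature names")
        return pd.Series(obj.feature_importances_, index=list(names))
    if names is None:
        raise ValueError("importance values need feature names")
    return pd.Series(np.asarray(obj, dtype=float), index=list(names))


def type_contributions(model_or_importances, names=None) -> tuple[float, float]:
    """(geometric %, appearance %) share of total importance."""
    imp = _as_named_importances(model_or_importances, names)
    total = imp.sum()
    if total <= 0:
        raise ValueError("importances sum to zero")
    geo = imp[[n for n in imp.index if _DIST.match(n)]].sum()
    app = imp[[n for n in imp.index if _HOG.match(n)]].sum()
    if not np.isclose(geo + app, total):
        raise ValueError("unnamed or unrecognised features in importance vector")
    return 100.0 * geo / total, 100.0 * app / total


def landmark_importance(model_or_importances, feature_type: str,
                        names=None) -> np.ndarray:
    """Per-landmark weights (length 49, summing to 1) for one feature type.

    Appearance importance accrues to the window's landmark; geometric
    importance is split half/half between the pair's endpoints.
    """
    if feature_type not in FEATURE_TYPES:
        raise ValueError(f"feature_type must be one of {FEATURE_TYPES}")
    imp = _as_named_importances(model_or_importances, names)
    weights = np.zeros(N_LANDMARKS)
    for name, value in imp.items():
        if feature_type == "geometric":
            m = _DIST.match(name)
            if m:
                i, j = int(m.group(1)), int(m.group(2))
                weights[i] += value / 2.0
                weights[j] += value / 2.0
        else:
            m = _HOG.match(name)
            if m:
                weights[int(m.group(1))] += value
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"no {feature_type} importance to attribute")
    return weights / total


def effective_landmark_count(weights: Sequence[float], mass: float = 0.9) -> int:
    """Smallest number of top-ranked landmarks with cumulative weight >= mass.

    Ties are broken by landmark index (lower index ranked first).
    """
    w = np.asarray(weights, dtype=float)
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    order = np.lexsort((np.arange(len(w)), -w))
    cum = np.cumsum(w[order])
    return int(np.searchsorted(cum, mass - 1e-12) + 1)


@dataclass(frozen=True)
class ImportanceProfile:
    """Aggregated importance view of one trained regime."""

    per_feature: pd.Series
    type_contribution: tuple[float, float]   # (geometric %, appearance %)
    landmark_weights: dict[str, np.ndarray]  # per feature type, length 49
    effective_counts: dict[str, int]         # per feature type, at `mass`
    mass: float = 0.9

    @classmethod
    def from_results(cls, results, mass: float = 0.9) -> "ImportanceProfile":
        imp = _as_named_importances(results)
        lw = {t: landmark_importance(imp, t) for t in FEATURE_TYPES}
        return cls(
            per_feature=imp,
            type_contribution=type_contributions(imp),
            landmark_weights=lw,
            effective_counts={t: effective_landmark_count(w, mass)
                              for t, w in lw.items()},
            mass=mass,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-landmark table (landmark, type, weight)."""
        rows = [{"landmark": l, "type": t, "weight": w[l]}
                for t, w in self.landmark_weights.items()
                for l in range(N_LANDMARKS)]
        return pd.DataFrame(rows)


def render_importance_map(template, weights_by_type: dict[str, np.ndarray],
                          out_path, max_area: float = 600.0,
                          min_area: float = 8.0) -> None:
    """Write a PNG plotting the template landmarks with marker area
    proportional to importance weight, one panel per feature type.

    Zero-weight landmarks are still plotted at the minimum marker size.
    Renderer settings are fixed so identical inputs give identical bytes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pts = template.points if hasattr(template, "points") else np.asarray(template)
    n_panels = len(weights_by_type)
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 4), dpi=100)
    if n_panels == 1:
        axes = [axes]
    for ax, (ftype, w) in zip(np.atleast_1d(axes), weights_by_type.items()):
        w = np.asarray(w, dtype=float)
        area = np.maximum(min_area, max_area * w / max(w.max(), 1e-12))
        ax.scatter(pts[:, 0], pts[:, 1], s=area, c="tab:blue", alpha=0.8)
        ax.set_title(ftype)
        ax.set_xlim(0, 256)
        ax.set_ylim(256, 0)   # image convention: y downward
        ax.set_aspect("equal")
        ax.axis("off")
    fig.savefig(out_path, metadata={"Software": "fexpr"})
    plt.close(fig)
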