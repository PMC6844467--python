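"""Normalized mean deviation product (nMDP) reference method and comparison.

nMDP assigns each voxel the product of its per-channel deviations from the
mean, normalized by the deviations of the maxima:

    nMDP_i = (x_i - x_mean)(y_i - y_mean) / ((x_max - x_mean)(y_max - y_mean))

Positive values are read as colocalised, negative as not-colocalised.  Unlike
the regression-adjusted mapping, nMDP is evaluated wherever *either* channel
is above its background threshold, so structures carrying only one
fluorophore still receive a colour — the main qualitative difference probed
by the classification comparison below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import ChannelPair
from .regression import ColocThresholds, ColocalisationError
from .core import ScoreVolume

__all__ = [
    "NmdpResult",
    "DifferenceMap",
    "DegenerateNormalizerError",
    "nmdp",
    "classify",
    "nmdp_render",
    "LABEL_NEITHER",
    "LABEL_AGREE",
    "LABEL_RACC_ONLY",
    "LABEL_NMDP_ONLY",
]

LABEL_NEITHER = 0
LABEL_AGREE = 1
LABEL_RACC_ONLY = 2
LABEL_NMDP_ONLY = 3


class DegenerateNormalizerError(ColocalisationError):
    """A channel maximum equals its mean, so the nMDP normalizer vanishes."""


@dataclass
class NmdpResult:
    """Per-voxel nMDP values with the region where they are defined.

    ``values`` is meaningful only where ``defined`` is True (at least one
    channel above threshold); elsewhere it is 0 by convention.
    """

    values: np.ndarray
    defined: np.ndarray
    mean_x: float
    mean_y: float
    max_x: float
    max_y: float
    display_min: float = -1.0
    display_max: float = 1.0


@dataclass
class DifferenceMap:
    """Voxel-wise agreement between the two methods' colocalised sets."""

    labels: np.ndarray  # LABEL_* codes
    percent_different: float


def nmdp(
    pair: ChannelPair, thr: ColocThresholds, max_scope: str = "roi"
) -> NmdpResult:
    """Evaluate nMDP over the union ROI of above-threshold voxels.

    Means are always taken over the ROI.  ``max_scope`` selects whether the
    normalizing maxima are taken within the ROI (``"roi"``, default — the
    natural reading once manual thresholding performs the background
    removal) or over the entire image (``"global"``).
    """
    thr.validate(pair.i_max)
    if max_scope not in ("roi", "global"):
        raise ValueError("max_scope must be 'roi' or 'global'")
    ch1 = pair.ch1.astype(np.float64)
    ch2 = pair.ch2.astype(np.float64)
    roi = (ch1 > thr.t_ch1) | (ch2 > thr.t_ch2)
    if not roi.any():
        raise ColocalisationError("no voxel is above either channel threshold")
    mean_x = float(ch1[roi].mean())
    mean_y = float(ch2[roi].mean())
    if max_scope == "roi":
        max_x = float(ch1[roi].max())
        max_y = float(ch2[roi].max())
    else:
        max_x = float(ch1.max())
        max_y = float(ch2.max())
    denom = (max_x - mean_x) * (max_y - mean_y)
    if denom == 0.0:
        raise DegenerateNormalizerError(
            "a channel maximum equals its mean; nMDP is undefined"
        )
    values = np.zeros(pair.shape, dtype=float)
    values[roi] = (ch1[roi] - mean_x) * (ch2[roi] - mean_y) / denom
    return NmdpResult(
        values=values,
        defined=roi,
        mean_x=mean_x,
        mean_y=mean_y,
        max_x=max_x,
        max_y=max_y,
    )


def classify(racc: ScoreVolume, nm: NmdpResult) -> DifferenceMap:
    """Label each voxel by which method(s) call it colocalised.

    RACC-colocalised: the score volume's visualised mask (both channels above
    threshold and within the distance threshold).  nMDP-colocalised: defined
    and strictly positive.  ``percent_different`` is the percentage of all
    voxels on which the two classifications disagree.
    """
    if racc.coloc.shape != nm.values.shape:
        raise ValueError("score volume and nMDP grids are not aligned")
    racc_set = racc.coloc
    nmdp_set = nm.defined & (nm.values > 0.0)
    labels = np.full(racc_set.shape, LABEL_NEITHER, dtype=np.int8)
    labels[racc_set & nmdp_set] = LABEL_AGREE
    labels[racc_set & ~nmdp_set] = LABEL_RACC_ONLY
    labels[~racc_set & nmdp_set] = LABEL_NMDP_ONLY
    n_diff = int((labels == LABEL_RACC_ONLY).sum() + (labels == LABEL_NMDP_ONLY).sum())
    percent = 100.0 * n_diff / labels.size
    return DifferenceMap(labels=labels, percent_different=percent)


def _nmdp_colormap():
    """Diverging map: blues for negative values, red-to-yellow for positive,
    with a deliberate discontinuity at zero (the colocalised / not-colocalised
    boundary)."""
    from matplotlib.colors import LinearSegmentedColormap

    return LinearSegmentedColormap.from_list(
        "nmdp",
        [
            (0.0, "#00004c"),
            (0.5, "#99ccff"),
            (0.5, "#cc0000"),
            (1.0, "#ffff00"),
        ],
    )


def nmdp_render(
    result: NmdpResult,
    display_min: float | None = None,
    display_max: float | None = None,
) -> np.ndarray:
    """Map nMDP values to an RGB volume (float in [0, 1], shape (..., 3)).

    Values are scaled linearly between the display bounds (defaults carried
    on the result, conventionally -1 and 1) and clipped outside; voxels where
    nMDP is undefined are rendered black.
    """
    lo = result.display_min if display_min is None else display_min
    hi = result.display_max if display_max is None else display_max
    if not lo < hi:
        raise ValueError("display_min must be < display_max")
    cmap = _nmdp_colormap()
    norm = np.clip((result.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = cmap(norm)[..., :3]
    rgb[~result.defined] = 0.0
    return rgb
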