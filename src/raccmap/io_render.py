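"""Volume I/O and rendering: TIFF stacks, RGB colour mapping, MIPs, fluorograms.

Volumes are stored z-major (TIFF pages are z-slices), coordinates 0-based.
The colocalisation score is rendered with a perceptually uniform colourmap
(Magma by default, black at 0 to bright yellow at 1); channel overlays
default to red/green so coincident signal appears yellow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile
from matplotlib import colormaps
from matplotlib.colors import LogNorm

from .phantoms import ChannelPair
from .regression import ColocThresholds
from .core import RaccModel, ScoreVolume
from .nmdp import (
    DifferenceMap,
    LABEL_AGREE,
    LABEL_NMDP_ONLY,
    LABEL_RACC_ONLY,
)

__all__ = [
    "RenderSpec",
    "read_pair",
    "write_volume",
    "render_racc",
    "overlay_channels",
    "overlay_mask",
    "render_difference",
    "mip",
    "scatter_plot",
]


@dataclass
class RenderSpec:
    """Rendering options; the default colourmap is perceptually uniform."""

    colourmap_name: str = "magma"
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ch1_colour: tuple[float, float, float] = (1.0, 0.0, 0.0)
    ch2_colour: tuple[float, float, float] = (0.0, 1.0, 0.0)
    mip_axis: int | None = 0


_I_MAX_BY_DTYPE = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def _load_volume(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D image or a 3D stack, got shape {arr.shape}")
    return arr


def read_pair(path_ch1, path_ch2=None, i_max: float | None = None) -> ChannelPair:
    """Read a two-channel volume from one TIFF per channel, or from a single
    TIFF whose first or second axis has length 2.

    ``i_max`` defaults to the bit-depth ceiling (255 for 8-bit, 65535 for
    16-bit).  2D images become single-slice volumes.
    """
    if path_ch2 is not None:
        ch1 = _load_volume(path_ch1)
        ch2 = _load_volume(path_ch2)
        if ch1.shape != ch2.shape:
            raise ValueError(
                f"channel stacks do not align: {ch1.shape} vs {ch2.shape}"
            )
        if ch1.dtype != ch2.dtype:
            raise ValueError(
                f"channel bit depths differ: {ch1.dtype} vs {ch2.dtype}"
            )
    else:
        arr = tifffile.imread(path_ch1)
        if arr.ndim == 3 and arr.shape[0] == 2:  # (2, Y, X)
            ch1, ch2 = arr[0][None], arr[1][None]
        elif arr.ndim == 4 and arr.shape[0] == 2:  # (2, Z, Y, X)
            ch1, ch2 = arr[0], arr[1]
        elif arr.ndim == 4 and arr.shape[1] == 2:  # (Z, 2, Y, X)
            ch1, ch2 = arr[:, 0], arr[:, 1]
        else:
            raise ValueError(
                f"{path_ch1}: cannot locate a length-2 channel axis in shape {arr.shape}"
            )
    if i_max is None:
        try:
            i_max = _I_MAX_BY_DTYPE[ch1.dtype]
        except KeyError:
            raise ValueError(
                f"cannot infer i_max for dtype {ch1.dtype}; pass it explicitly"
            ) from None
    return ChannelPair(ch1=ch1, ch2=ch2, i_max=float(i_max))


def write_volume(path, volume: np.ndarray) -> None:
    """Write a volume as a multi-page TIFF, one page per z-slice.

    A trailing length-3 axis is stored as interleaved RGB, anything else as
    single-sample grayscale pages.
    """
    volume = np.asarray(volume)
    photometric = "rgb" if volume.ndim >= 3 and volume.shape[-1] == 3 else "minisblack"
    tifffile.imwrite(path, volume, photometric=photometric)


def render_racc(score: ScoreVolume, spec: RenderSpec | None = None) -> np.ndarray:
    """Colour the score volume: colourmap(c) on visualised voxels, background
    elsewhere.  Returns float RGB in [0, 1], shape (..., 3)."""
    spec = spec or RenderSpec()
    cmap = colormaps[spec.colourmap_name]
    rgb = cmap(np.clip(score.c, 0.0, 1.0))[..., :3]
    rgb[~score.coloc] = spec.background
    return rgb


def overlay_channels(pair: ChannelPair, spec: RenderSpec | None = None) -> np.ndarray:
    """Additive two-colour overlay of the raw channels (red/green default)."""
    spec = spec or RenderSpec()
    c1 = np.asarray(spec.ch1_colour, dtype=float)
    c2 = np.asarray(spec.ch2_colour, dtype=float)
    rgb = (
        pair.ch1[..., None].astype(float) / pair.i_max * c1
        + pair.ch2[..., None].astype(float) / pair.i_max * c2
    )
    return np.clip(rgb, 0.0, 1.0)


def overlay_mask(
    pair: ChannelPair, mask: np.ndarray, spec: RenderSpec | None = None
) -> np.ndarray:
    """Channel overlay with the masked (colocalised) voxels painted white."""
    rgb = overlay_channels(pair, spec)
    rgb[mask] = 1.0
    return rgb


_DIFFERENCE_COLOURS = {
    LABEL_AGREE: (1.0, 1.0, 1.0),  # both methods agree: white
    LABEL_RACC_ONLY: (1.0, 0.0, 1.0),  # magenta: RACC only
    LABEL_NMDP_ONLY: (1.0, 1.0, 0.0),  # yellow: nMDP only
}


def render_difference(diff: DifferenceMap) -> np.ndarray:
    """Colour the classification difference map (neither-method voxels black)."""
    rgb = np.zeros(diff.labels.shape + (3,), dtype=float)
    for label, colour in _DIFFERENCE_COLOURS.items():
        rgb[diff.labels == label] = colour
    return rgb


def mip(volume: np.ndarray, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along one axis (per component for RGB)."""
    return np.max(volume, axis=axis)


def scatter_plot(
    pair: ChannelPair,
    thr: ColocThresholds,
    model: RaccModel | None = None,
    path=None,
    bins: int = 64,
):
    """Fluorogram: 2D histogram of joint intensities with model overlays.

    Brightness encodes the frequency of voxels at each joint intensity (log
    scale).  Overlays: the regression line (red), the channel thresholds
    (green dashes), the distance-threshold band around the line (white), the
    colourmap maximum point (orange) and the per-channel mean intensities of
    the union ROI used by nMDP (red marker).

    Returns ``(fig, counts, xedges, yedges)``; if ``path`` is given the
    figure is also saved there and closed.
    """
    x = pair.ch1.astype(float).ravel()
    y = pair.ch2.astype(float).ravel()
    bearing = (x > 0) | (y > 0)
    fig, ax = plt.subplots(figsize=(5, 5))
    counts, xedges, yedges, _ = ax.hist2d(
        x[bearing],
        y[bearing],
        bins=bins,
        range=[[0, pair.i_max], [0, pair.i_max]],
        cmap="magma",
        norm=LogNorm(),
    )
    ax.axvline(thr.t_ch1, color="lime", ls="--", lw=1)
    ax.axhline(thr.t_ch2, color="lime", ls="--", lw=1)

    roi = (x > thr.t_ch1) | (y > thr.t_ch2)
    if roi.any():
        ax.plot(x[roi].mean(), y[roi].mean(), "ro", ms=6, label="channel means")

    if model is not None:
        fit = model.fit
        xs = np.array([0.0, pair.i_max])
        ax.plot(xs, fit.beta0 + fit.beta1 * xs, "r-", lw=1.5, label="regression line")
        # Distance-threshold band: two parallels at perpendicular offset
        # d_t * i_max from the line.
        direction = (model.p1 - model.p0) / np.linalg.norm(model.p1 - model.p0)
        normal = np.array([-direction[1], direction[0]])
        offset = model.d_t * pair.i_max * normal
        for sgn in (+1, -1):
            a = model.p0 + sgn * offset
            b = model.p1 + sgn * offset
            ax.plot([a[0], b[0]], [a[1], b[1]], color="white", lw=1)
        # Colourmap maximum: a short perpendicular tick at p_max.
        tick = 0.06 * pair.i_max * normal
        ax.plot(
            [model.p_max[0] - tick[0], model.p_max[0] + tick[0]],
            [model.p_max[1] - tick[1], model.p_max[1] + tick[1]],
            color="orange",
            lw=2,
            label="p_max",
        )
    ax.set_xlim(0, pair.i_max)
    ax.set_ylim(0, pair.i_max)
    ax.set_xlabel("channel 1 intensity")
    ax.set_ylabel("channel 2 intensity")
    ax.set_facecolor("black")
    if path is not None:
        fig.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig, counts, xedges, yedges
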