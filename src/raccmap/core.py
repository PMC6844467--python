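"""Core RACC model: project voxels onto the regression line and map to [0, 1].

The fitted regression line is treated as a 1D subspace of the joint-intensity
plane.  Two anchor points delimit the usable span: ``p0``, where the line
crosses the background-threshold boundary, and ``p1``, where it meets the
intensity ceiling ``i_max``.  Each above-threshold voxel's intensity pair is
projected perpendicularly onto the line; its position along the ``p0 -> p_max``
segment gives the base colourmap value, which is then attenuated linearly in
the normalized perpendicular distance ``d`` with slope ``tan(theta)`` and cut
off entirely beyond an automatic distance threshold ``d_t``.

``d_t`` and ``p_max`` are each chosen (independently, by nearest-rank
percentile) to include 99% of the above-threshold voxels, so outliers are
suppressed and the full colourmap span is used even when intensities are low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import ChannelPair
from .regression import (
    ColocThresholds,
    DemingFit,
    coloc_mask,
    fit_deming,
    sample_stats,
)

__all__ = [
    "RaccModel",
    "ScoreVolume",
    "intersect_p0",
    "intersect_p1",
    "project",
    "nearest_rank_percentile",
    "auto_distance_threshold",
    "auto_pmax",
    "colourmap_value",
    "score_volume",
]

#: Fraction of above-threshold voxels that the automatic distance threshold
#: and the colourmap maximum point each include.
INCLUSION_FRACTION = 0.99


@dataclass(frozen=True)
class RaccModel:
    """Everything needed to evaluate the colourmap value of a voxel."""

    fit: DemingFit
    p0: np.ndarray  # (x, y) where the line crosses the threshold boundary
    p1: np.ndarray  # (x, y) where the line meets the intensity ceiling
    p_max: np.ndarray  # colourmap saturation point on the line
    t_max: float  # p_max as a fraction of the p0 -> p1 segment, in (0, 1]
    d_t: float  # normalized perpendicular distance threshold
    theta: float  # penalization angle, degrees, [0, 90)
    rescale: bool
    i_max: float


@dataclass
class ScoreVolume:
    """Per-voxel colourmap values with the visualised-voxel mask.

    ``c`` is zero wherever ``coloc`` is False.  ``distances`` holds the
    normalized perpendicular distance ``d`` for above-threshold voxels and
    NaN elsewhere (diagnostic).
    """

    c: np.ndarray
    coloc: np.ndarray
    distances: np.ndarray


def _check_positive_slope(fit: DemingFit) -> None:
    if not fit.beta1 > 0:
        raise ValueError("the model requires a positive regression slope")


def intersect_p0(fit: DemingFit, thr: ColocThresholds) -> np.ndarray:
    """Intersection of the regression line with the threshold boundary.

    The line must cross one of the two threshold lines ``x = t_ch1`` /
    ``y = t_ch2``; the feasible crossing (the one on the boundary of the
    above-both-thresholds quadrant) is returned.
    """
    _check_positive_slope(fit)
    y_at_t1 = thr.t_ch1 * fit.beta1 + fit.beta0
    if thr.t_ch2 <= y_at_t1:
        return np.array([thr.t_ch1, y_at_t1], dtype=float)
    return np.array([(thr.t_ch2 - fit.beta0) / fit.beta1, thr.t_ch2], dtype=float)


def intersect_p1(fit: DemingFit, i_max: float) -> np.ndarray:
    """Intersection of the regression line with the intensity ceiling.

    Whichever of ``y = i_max`` / ``x = i_max`` the line reaches first (at the
    smaller x) delimits the representable span.
    """
    _check_positive_slope(fit)
    if fit.beta0 >= i_max * (1.0 - fit.beta1):
        return np.array([(i_max - fit.beta0) / fit.beta1, i_max], dtype=float)
    return np.array([i_max, i_max * fit.beta1 + fit.beta0], dtype=float)


def project(
    q: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perpendicular projection of intensity pairs onto the line p0 -> p1.

    Parameters
    ----------
    q : array of shape (..., 2)
        Joint intensity pairs.

    Returns
    -------
    p_i : (..., 2) projected points on the line
    t : (...) scalar position along the segment (0 at p0, 1 at p1)
    d_raw : (...) perpendicular distance in intensity units
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p = p1 - p0
    pp = float(p @ p)
    if pp == 0.0:
        raise ValueError("p0 and p1 coincide; the line span is empty")
    qv = np.asarray(q, dtype=float) - p0
    t = (qv @ p) / pp
    p_i = t[..., None] * p + p0
    d_raw = np.linalg.norm(np.asarray(q, dtype=float) - p_i, axis=-1)
    return p_i, t, d_raw


def nearest_rank_percentile(values: np.ndarray, fraction: float = INCLUSION_FRACTION) -> float:
    """Nearest-rank percentile: the smallest sample value v such that at
    least ``fraction`` of the samples are <= v (rank = ceil(fraction * n))."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    rank = int(np.ceil(fraction * n))
    return float(v[max(rank, 1) - 1])


def auto_distance_threshold(distances: np.ndarray) -> float:
    """Distance threshold including 99% of the above-threshold voxels."""
    return nearest_rank_percentile(distances, INCLUSION_FRACTION)


def auto_pmax(
    t: np.ndarray, p0: np.ndarray, p1: np.ndarray, rescale: bool = True
) -> tuple[np.ndarray, float]:
    """Colourmap saturation point including 99% of the projections.

    With ``rescale`` off, ``p1`` is retained (``t_max = 1``).  The returned
    ``t_max`` is clamped to (0, 1] so the colourmap span never exceeds the
    intensity ceiling nor collapses.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if not rescale:
        return p1.copy(), 1.0
    t_max = nearest_rank_percentile(t, INCLUSION_FRACTION)
    t_max = float(min(max(t_max, np.finfo(float).tiny), 1.0))
    return p0 + t_max * (p1 - p0), t_max


def colourmap_value(q: np.ndarray, model: RaccModel) -> np.ndarray:
    """Final colourmap value in [0, 1] for intensity pairs ``q`` (..., 2).

    The base value is the projection position along ``p0 -> p_max`` (clamped:
    beyond ``p_max`` saturates at 1, below ``p0`` at 0), attenuated by
    ``d * tan(theta)`` and zeroed where ``d`` exceeds the distance threshold.
    Callers are expected to mask to above-threshold voxels first.
    """
    _, t, d_raw = project(q, model.p0, model.p1)
    d = d_raw / model.i_max
    # Position along p0 -> p_max, via the projection parameter (identical to
    # the x-coordinate ratio for any finite positive slope, but stable when
    # the slope is large).
    u = t / model.t_max
    pen = d * np.tan(np.deg2rad(model.theta))
    c = np.where(u >= 1.0, 1.0 - pen, u - pen)
    c = np.where((d > model.d_t) | (u <= pen), 0.0, c)
    return np.clip(c, 0.0, 1.0)


def _validate_theta(theta: float) -> None:
    if not 0.0 <= theta < 90.0:
        raise ValueError("theta must lie in [0, 90) degrees")


def score_volume(
    pair: ChannelPair,
    thr: ColocThresholds,
    theta: float = 45.0,
    lam: float = 1.0,
    rescale: bool = True,
    roi: tuple[slice, slice, slice] | None = None,
) -> tuple[ScoreVolume, RaccModel]:
    """Run the full pipeline over a volume and return scores plus the model.

    mask -> sample moments -> Deming fit -> p0/p1 -> per-voxel projection ->
    automatic d_t and p_max -> per-voxel colourmap value.  All model
    parameters are estimated over the whole volume (or over ``roi``, a
    bounding box of slices, in which case the returned grids cover the ROI
    only — regional analyses should refit rather than reuse a global model).
    """
    _validate_theta(theta)
    if roi is not None:
        pair = ChannelPair(pair.ch1[roi], pair.ch2[roi], pair.i_max)
    mask = coloc_mask(pair, thr)
    stats = sample_stats(pair, mask)
    fit = fit_deming(stats, lam)
    p0 = intersect_p0(fit, thr)
    p1 = intersect_p1(fit, pair.i_max)
    if not p0[0] < p1[0]:
        raise ValueError(
            "thresholds leave no intensity span below the ceiling; "
            "lower the thresholds"
        )

    q = np.stack(
        [pair.ch1[mask].astype(float), pair.ch2[mask].astype(float)], axis=-1
    )
    _, t, d_raw = project(q, p0, p1)
    d = d_raw / pair.i_max
    d_t = auto_distance_threshold(d)
    p_max, t_max = auto_pmax(t, p0, p1, rescale=rescale)
    model = RaccModel(
        fit=fit,
        p0=p0,
        p1=p1,
        p_max=p_max,
        t_max=t_max,
        d_t=d_t,
        theta=float(theta),
        rescale=rescale,
        i_max=pair.i_max,
    )

    c = np.zeros(pair.shape, dtype=float)
    c[mask] = colourmap_value(q, model)
    coloc = np.zeros(pair.shape, dtype=bool)
    coloc[mask] = d <= d_t
    c[~coloc] = 0.0
    distances = np.full(pair.shape, np.nan)
    distances[mask] = d
    return ScoreVolume(c=c, coloc=coloc, distances=distances), model
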