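"""Representational-geometry statistics over state axes.

Pairwise axis angles (folded to [0, 90] degrees, axes being directionless),
a bootstrap surrogate null for the angle between statistically independent
axes, hierarchical clustering of the angle matrix, the Spatial-Distribution
Index, five-area-group d' coordinates, continuous two-segment piecewise
fits of d' ramps, and the pixel-wise decoding negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .axes import DPrimeCurve, area_dprime_curve, dprime, dprime_curve

__all__ = [
    "axis_angle",
    "angle_matrix",
    "surrogate_angle_null",
    "cluster_axes",
    "sdi",
    "AREA_GROUPS",
    "group_dprime_5d",
    "PiecewiseFit",
    "piecewise_fit",
    "pixelwise_dprime",
]

#: Five broad area groups for the 5-D d' space; V1 is excluded because it
#: contributes a near-uniform d' to every separation.
AREA_GROUPS = {
    "dorsal": ("PM", "AM"),
    "ventral": ("L",),
    "parietal": ("A", "AL", "RL"),
    "somatosensory": ("SSt", "SSb"),
    "retrosplenial": ("RS",),
}


def axis_angle(a1: np.ndarray, a2: np.ndarray) -> float:
    """Angle between two axes in degrees, folded to [0, 90].

    Axes are directionless, so the absolute cosine is used.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n1, n2 = np.linalg.norm(a1), np.linalg.norm(a2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    c = np.clip(np.abs(a1 @ a2) / (n1 * n2), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_matrix(axes: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of pairwise angles between named axes."""
    labels = list(axes)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = axis_angle(axes[labels[i]], axes[labels[j]])
    return labels, m


def surrogate_angle_null(
    axis: np.ndarray, n_surrogates: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Bootstrap null for the angle between independent axes.

    Surrogate axes are built by resampling the axis entries with
    replacement (matched dimensionality and weight distribution) and
    renormalizing; the 2.5/97.5 percentiles of the angle to the original
    axis form the null confidence interval.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size < 2:
        raise ValueError("axis dimension must be >= 2")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, axis.size, size=(n_surrogates, axis.size))
    surr = axis[picks]
    angles = np.array([axis_angle(axis, s) for s in surr if np.linalg.norm(s) > 0])
    lo, hi = np.percentile(angles, [2.5, 97.5])
    return float(lo), float(hi)


def cluster_axes(labels: list[str], angles: np.ndarray):
    """Average-linkage hierarchical clustering on the angle distance matrix.

    Returns the scipy linkage matrix and the leaf order as labels.
    """
    condensed = squareform(np.asarray(angles, dtype=float), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    return link, order


def sdi(global_dprime: float, area_dprimes) -> float:
    """Spatial-Distribution Index: ``(d'_global / max(d'_i) - 1) * 100`` percent.

    0% when a single area carries all the discriminative signal; larger when
    pooling across areas beats the best single area.
    """
    area_dprimes = np.asarray(area_dprimes, dtype=float)
    peak = np.max(area_dprimes)
    if peak <= 0:
        raise ValueError("max area d' must be positive")
    return float((global_dprime / peak - 1.0) * 100.0)


def group_dprime_5d(
    grp_a: np.ndarray,
    grp_b: np.ndarray,
    component_area: np.ndarray,
    area_names: tuple[str, ...],
    frame_rate: float,
    window: tuple[float, float],
    **kwargs,
) -> dict[str, float]:
    """Peak |d'| per broad area group (dorsal, ventral, parietal,
    somatosensory, retrosplenial), each from the components of that group."""
    out = {}
    for gname, members in AREA_GROUPS.items():
        ids = [area_names.index(m) + 1 for m in members]
        comp_idx = np.flatnonzero(np.isin(component_area, ids))
        if comp_idx.size == 0:
            raise ValueError(f"area group '{gname}' has no components")
        curve = area_dprime_curve(grp_a, grp_b, comp_idx, frame_rate, window, **kwargs)
        out[gname] = curve.peak
    return out


@dataclass
class PiecewiseFit:
    """Two-segment continuous linear fit of a d' ramp."""

    pre_slope: float  # d'/s before the knot
    post_slope: float  # d'/s after the knot
    knot_time: float  # s relative to alignment (movement onset)
    fit_window: tuple[float, float]
    sse: float
    degenerate: bool = False


def _two_segment_lsq(t: np.ndarray, y: np.ndarray, knot: float):
    """Closed-form least squares for a continuous two-piece line with a fixed knot."""
    basis = np.column_stack([np.ones_like(t), t - knot, np.maximum(t - knot, 0.0)])
    coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
    pred = basis @ coef
    sse = float(np.sum((y - pred) ** 2))
    pre = coef[1]
    post = coef[1] + coef[2]
    return pre, post, sse


def piecewise_fit(
    curve: DPrimeCurve,
    window_start: float = -1.0,
    peak_fraction: float = 0.95,
) -> PiecewiseFit:
    """Fit a continuous two-slope line to a movement-aligned d' curve.

    The fit window runs from ``window_start`` up to the earliest time the
    curve reaches ``peak_fraction`` of its post-movement maximum.  The knot
    is found by scanning every interior sample and refining with a bounded
    golden-section search; the knot time is the slope-change time.  A flat
    curve (dynamic range below 1e-9) is flagged degenerate with zero slopes.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.dprime, dtype=float)
    post = t >= 0
    if not post.any():
        raise ValueError("curve does not cover the post-movement period")
    post_max = np.nanmax(y[post])
    reach = np.flatnonzero((t >= 0) & (y >= peak_fraction * post_max))
    t_end = t[reach[0]] if reach.size else t[-1]
    sel = (t >= window_start) & (t <= t_end)
    if sel.sum() < 4:
        raise ValueError("degenerate fit window")
    ts, ys = t[sel], y[sel]

    if np.ptp(ys) < 1e-9:
        return PiecewiseFit(0.0, 0.0, float("nan"), (float(ts[0]), float(ts[-1])), 0.0, True)

    candidates = ts[1:-1]
    sses = np.array([_two_segment_lsq(ts, ys, k)[2] for k in candidates])
    k0 = candidates[int(np.argmin(sses))]
    from scipy.optimize import minimize_scalar

    lo = max(ts[1], k0 - 2 * (ts[1] - ts[0]))
    hi = min(ts[-2], k0 + 2 * (ts[1] - ts[0]))
    if hi > lo:
        res = minimize_scalar(
            lambda k: _two_segment_lsq(ts, ys, k)[2], bounds=(lo, hi), method="bounded"
        )
        knot = float(res.x)
    else:
        knot = float(k0)
    pre, post_slope, sse = _two_segment_lsq(ts, ys, knot)
    return PiecewiseFit(
        pre_slope=float(pre),
        post_slope=float(post_slope),
        knot_time=knot,
        fit_window=(float(ts[0]), float(ts[-1])),
        sse=sse,
    )


def pixelwise_dprime(
    data: np.ndarray,
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    align_a: np.ndarray,
    align_b: np.ndarray,
    window: tuple[float, float],
    frame_rate: float,
) -> np.ndarray:
    """Per-pixel, per-time d' between two trial groups, no spatial pooling.

    ``data`` is the session tensor (trials, x, y, t); the result has shape
    (x, y, W).  This is the negative control showing that a weak signal
    distributed over many pixels is invisible without spatial integration.
    """
    n_frames = data.shape[-1]
    w0 = int(round(window[0] * frame_rate))
    w1 = int(round(window[1] * frame_rate))
    offsets = np.arange(w0, w1 + 1)

    def stack(trials, aligns):
        out = np.empty((trials.size, *data.shape[1:3], offsets.size), dtype=float)
        for i, (tr, af) in enumerate(zip(trials, aligns)):
            frames = np.clip(np.round(af + offsets).astype(int), 0, n_frames - 1)
            out[i] = data[tr][..., frames]
        return out

    a = stack(np.asarray(trials_a), np.asarray(align_a))
    b = stack(np.asarray(trials_b), np.asarray(align_b))
    mu = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.sqrt(0.5 * (a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)))
    pooled = np.where(pooled == 0, np.nan, pooled)
    return mu / pooled
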