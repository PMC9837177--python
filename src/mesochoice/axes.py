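"""State axes and cross-validated d' discriminability in component space.

A state axis is a unit vector over temporal components along which two
trial groups A and B separate maximally in a variance-weighted sense: per
component, the difference of group means divided by the pooled standard
deviation ``sqrt((sigma_A^2 + sigma_B^2) / 2)``, the resulting vector
normalized to unit length.  Projections are plain dot products (no
mean-centering in time), and discriminability is
``d' = (<P_A> - <P_B>) / pooled SD of the projections``, reported on
held-out trials via 5-fold cross-validation in which only 20% of trials
define the axis and the remaining 80% are scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialGroupPair",
    "DPrimeCurve",
    "build_group_pair",
    "extract_aligned",
    "state_axis",
    "project",
    "dprime",
    "dprime_curve",
    "axis_stability",
    "area_dprime_curve",
    "orthogonalized_dprime",
]

GROUP_VARIABLES = ("stimulus", "contra_orientation", "wheel", "saccade", "attention", "choice")


@dataclass
class TrialGroupPair:
    """Balanced trial groups with per-trial alignment frames.

    ``align_a`` / ``align_b`` are frame indices (one per trial) to which the
    analysis window is referenced.  For the stimulus variable the same
    trials appear in both groups with shifted alignment (signal window vs.
    the preceding no-stimulus window); for every other variable the groups
    are disjoint.
    """

    variable: str
    trials_a: np.ndarray
    trials_b: np.ndarray
    align_a: np.ndarray
    align_b: np.ndarray
    window: tuple[float, float]  # seconds relative to alignment

    def __post_init__(self) -> None:
        if len(self.trials_a) != len(self.trials_b):
            raise ValueError("groups must be balanced")
        if self.variable != "stimulus" and np.intersect1d(self.trials_a, self.trials_b).size:
            raise ValueError("groups must be disjoint")


def _balance(a: np.ndarray, b: np.ndarray, rng: np.random.Generator):
    n = min(a.size, b.size)
    if a.size > n:
        a = rng.choice(a, size=n, replace=False)
    if b.size > n:
        b = rng.choice(b, size=n, replace=False)
    return np.sort(a), np.sort(b)


def _no_event_before(times, t_event: float, guard: float) -> bool:
    times = np.asarray(times, dtype=float)
    return not np.any((times >= t_event - guard) & (times < t_event))


def build_group_pair(
    table: pd.DataFrame,
    variable: str,
    frame_rate: float,
    seed: int = 0,
    window: tuple[float, float] = (-0.5, 0.5),
) -> TrialGroupPair:
    """Build the balanced trial groups for one task variable.

    Inclusion rules:

    * ``stimulus``: all trials; group A aligned to stimulus onset (window
      around onset), group B the same trials shifted 0.5 s earlier so the
      window covers the pre-stimulus second.
    * ``wheel``: A = first movement at least 0.5 s after onset with no
      saccade in the preceding 0.5 s, aligned to movement; B = no movement
      during the first 5 s (or the trial, if shorter), aligned to a random
      frame in the same span.
    * ``saccade``: symmetric to wheel with the roles of saccades and wheel
      movements swapped.
    * ``attention``: A/B = top/bottom tertile of the z-scored pupil change,
      aligned to stimulus onset.
    * ``choice``: the wheel-A inclusion rule, split by the direction of the
      first movement (A = right choice, B = left choice), aligned to
      movement.
    * ``contra_orientation``: A/B = contralateral (left) stimulus closer to
      horizontal / vertical, aligned to stimulus onset.

    The larger group is subsampled at random to balance.  An empty group
    raises with the name of the failed rule.
    """
    rng = np.random.default_rng(seed)
    stim = table["stim_onset"].to_numpy()
    n_frames = int(table["n_frames"].iloc[0])
    idx = np.arange(len(table))
    move_t = table["first_move_time"].to_numpy(dtype=float)
    has_move = np.isfinite(move_t)

    def fail(name, arr, rule):
        if arr.size == 0:
            raise ValueError(f"empty group for {name}: no trial satisfies '{rule}'")

    if variable == "stimulus":
        a, b = idx, idx
        align_a = stim.astype(float)
        align_b = stim - 0.5 * frame_rate
        return TrialGroupPair(variable, a, b, align_a, align_b[b], window)

    if variable in ("wheel", "choice"):
        sac_ok = np.array(
            [
                (not has_move[i])
                or _no_event_before(table["saccade_times"].iloc[i], move_t[i], 0.5)
                for i in idx
            ]
        )
        group_a = idx[has_move & (move_t >= 0.5) & sac_ok]
        align_of = stim + move_t * frame_rate
        if variable == "wheel":
            fail("wheel A", group_a, "movement >= 0.5 s after onset, no saccade 0.5 s before")
            span = (n_frames - stim[0]) / frame_rate
            lim = min(5.0, span)
            no_move = idx[~has_move | (move_t > lim)]
            fail("wheel B", no_move, "no movement in the first 5 s")
            a, b = _balance(group_a, no_move, rng)
            align_b = stim[b] + rng.uniform(0.5, lim, size=b.size) * frame_rate
            return TrialGroupPair(variable, a, b, align_of[a], align_b, window)
        # choice: split qualifying movement trials by first-movement direction
        dirs = table["first_move_dir"].to_numpy(dtype=object)
        right = group_a[dirs[group_a] == "ccw"]
        left = group_a[dirs[group_a] == "cw"]
        fail("choice A", right, "right-choice trials with qualifying movement")
        fail("choice B", left, "left-choice trials with qualifying movement")
        a, b = _balance(right, left, rng)
        return TrialGroupPair(variable, a, b, align_of[a], align_of[b], window)

    if variable == "saccade":
        first_sac = np.array(
            [
                next((t for t in table["saccade_times"].iloc[i] if t >= 0.5), np.nan)
                for i in idx
            ]
        )
        has_sac = np.isfinite(first_sac)
        move_ok = np.array(
            [
                (not has_sac[i])
                or (not has_move[i])
                or not (first_sac[i] - 0.5 <= move_t[i] < first_sac[i])
                for i in idx
            ]
        )
        group_a = idx[has_sac & move_ok]
        fail("saccade A", group_a, "saccade >= 0.5 s after onset, no wheel movement 0.5 s before")
        span = (n_frames - stim[0]) / frame_rate
        lim = min(5.0, span)
        n_sac = np.array([len(table["saccade_times"].iloc[i]) for i in idx])
        no_sac = idx[n_sac == 0]
        fail("saccade B", no_sac, "no saccade in the first 5 s")
        a, b = _balance(group_a, no_sac, rng)
        align_a = stim[a] + first_sac[a] * frame_rate
        align_b = stim[b] + rng.uniform(0.5, lim, size=b.size) * frame_rate
        return TrialGroupPair(variable, a, b, align_a, align_b, window)

    if variable == "attention":
        if "attention" not in table:
            raise ValueError("attention labels missing; run label_attention first")
        att = table["attention"].to_numpy()
        hi, lo = idx[att == "high"], idx[att == "low"]
        fail("attention A", hi, "top tertile of pupil change")
        fail("attention B", lo, "bottom tertile of pupil change")
        a, b = _balance(hi, lo, rng)
        return TrialGroupPair(variable, a, b, stim[a].astype(float), stim[b].astype(float), window)

    if variable == "contra_orientation":
        la = table["left_angle"].to_numpy()
        horiz = idx[np.abs(la) > 60.0]
        vert = idx[np.abs(la) < 30.0]
        fail("contra A", horiz, "left stimulus near horizontal")
        fail("contra B", vert, "left stimulus near vertical")
        a, b = _balance(horiz, vert, rng)
        return TrialGroupPair(variable, a, b, stim[a].astype(float), stim[b].astype(float), window)

    raise ValueError(f"unknown variable {variable!r}; expected one of {GROUP_VARIABLES}")


def extract_aligned(
    temporal: np.ndarray,
    trials: np.ndarray,
    align_frames: np.ndarray,
    window: tuple[float, float],
    frame_rate: float,
) -> np.ndarray:
    """Cut per-trial windows (trials, K, W) around per-trial alignment frames.

    Windows falling partially outside the trial are clipped to the trial
    bounds (edge frames repeat), keeping trial counts balanced.
    """
    k, n_frames = temporal.shape[1], temporal.shape[2]
    w0 = int(round(window[0] * frame_rate))
    w1 = int(round(window[1] * frame_rate))
    offsets = np.arange(w0, w1 + 1)
    out = np.empty((trials.size, k, offsets.size), dtype=temporal.dtype)
    for i, (tr, af) in enumerate(zip(trials, align_frames)):
        frames = np.clip(np.round(af + offsets).astype(int), 0, n_frames - 1)
        out[i] = temporal[tr][:, frames]
    return out


def window_times(window: tuple[float, float], frame_rate: float) -> np.ndarray:
    w0 = int(round(window[0] * frame_rate))
    w1 = int(round(window[1] * frame_rate))
    return np.arange(w0, w1 + 1) / frame_rate


def _axis_ratio(grp_a: np.ndarray, grp_b: np.ndarray) -> np.ndarray:
    """Per-component (mean_A - mean_B) / pooled SD, shape (K, W)."""
    mu = grp_a.mean(axis=0) - grp_b.mean(axis=0)
    pooled = np.sqrt(0.5 * (grp_a.var(axis=0, ddof=1) + grp_b.var(axis=0, ddof=1)))
    zero = pooled == 0
    if zero.any():
        warnings.warn("zero pooled SD in some components; entries set to 0", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(zero, 0.0, mu / np.where(zero, 1.0, pooled))
    return ratio


def state_axis(
    grp_a: np.ndarray, grp_b: np.ndarray, mode: str = "per_time"
) -> np.ndarray:
    """State axis from two aligned group tensors (trials, K, W).

    ``mode='per_time'`` returns S(t) of shape (K, W), each column unit norm;
    ``mode='window'`` averages the per-component ratio over the window
    before normalizing and returns a single (K,) unit vector.
    """
    if grp_a.shape[0] < 2 or grp_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 trials")
    ratio = _axis_ratio(grp_a, grp_b)
    if mode == "window":
        v = ratio.mean(axis=1)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("all-zero state axis (identical group statistics)")
        return v / n
    if mode == "per_time":
        norms = np.linalg.norm(ratio, axis=0)
        if np.all(norms == 0):
            raise ValueError("all-zero state axis (identical group statistics)")
        norms = np.where(norms == 0, 1.0, norms)
        return ratio / norms
    raise ValueError("mode must be 'per_time' or 'window'")


def project(axis: np.ndarray, temporal: np.ndarray) -> np.ndarray:
    """Project trials onto an axis: ``P_i(t) = S(t) . C_i(t)``.

    ``axis`` is (K,) or (K, W); ``temporal`` is (trials, K, W).  No
    mean-centering is applied.
    """
    temporal = np.asarray(temporal)
    axis = np.asarray(axis)
    if axis.ndim == 1:
        if axis.shape[0] != temporal.shape[1]:
            raise ValueError("axis dimension does not match component count")
        return np.einsum("k,nkt->nt", axis, temporal)
    if axis.shape != temporal.shape[1:]:
        raise ValueError("axis (K, W) does not match temporal window")
    return np.einsum("kt,nkt->nt", axis, temporal)


def dprime(proj_a: np.ndarray, proj_b: np.ndarray) -> np.ndarray:
    """Signed d' per time point: (mean_A - mean_B) / pooled SD."""
    mu = proj_a.mean(axis=0) - proj_b.mean(axis=0)
    pooled = np.sqrt(0.5 * (proj_a.var(axis=0, ddof=1) + proj_b.var(axis=0, ddof=1)))
    pooled = np.where(pooled == 0, np.nan, pooled)
    return mu / pooled


@dataclass
class DPrimeCurve:
    """Cross-validated discriminability trace."""

    times: np.ndarray  # s relative to alignment
    dprime: np.ndarray  # (W,) fold-averaged
    per_fold: np.ndarray  # (folds, W)

    @property
    def peak(self) -> float:
        return float(np.nanmax(np.abs(self.dprime)))


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def dprime_curve(
    grp_a: np.ndarray,
    grp_b: np.ndarray,
    frame_rate: float,
    window: tuple[float, float],
    cv_folds: int = 5,
    train_frac: float = 0.2,
    seed: int = 0,
    axis_mode: str = "per_time",
    baseline_zero: bool = False,
) -> DPrimeCurve:
    """Cross-validated d'(t) between two aligned group tensors.

    Per fold, the state axis is defined from a ``train_frac`` subset of each
    group (one fold when ``train_frac = 1 / cv_folds``) and d' is computed
    from the projections of the remaining trials; the curve is the mean over
    folds.  ``baseline_zero`` subtracts the first-frame value from the
    curve, pinning discriminability to zero at window start (used for the
    sustained-attention variable).
    """
    n = grp_a.shape[0]
    rng = np.random.default_rng(seed)
    folds_a = _fold_indices(n, cv_folds, rng)
    folds_b = _fold_indices(grp_b.shape[0], cv_folds, rng)
    w = grp_a.shape[2]
    per_fold = np.empty((cv_folds, w))
    for f in range(cv_folds):
        tr_a, tr_b = folds_a[f], folds_b[f]
        if train_frac != 1.0 / cv_folds:
            n_tr = max(2, int(round(train_frac * n)))
            tr_a, tr_b = folds_a[f][:n_tr], folds_b[f][:n_tr]
        te_a = np.setdiff1d(np.arange(n), tr_a)
        te_b = np.setdiff1d(np.arange(grp_b.shape[0]), tr_b)
        if te_a.size < 2 or te_b.size < 2 or tr_a.size < 2 or tr_b.size < 2:
            raise ValueError("not enough trials for the requested split")
        axis = state_axis(grp_a[tr_a], grp_b[tr_b], mode=axis_mode)
        pa = project(axis, grp_a[te_a])
        pb = project(axis, grp_b[te_b])
        if axis.ndim == 1 and pa.ndim == 2:
            per_fold[f] = dprime(pa, pb)
        else:
            per_fold[f] = dprime(pa, pb)
    curve = per_fold.mean(axis=0)
    if baseline_zero:
        curve = curve - curve[0]
        per_fold = per_fold - per_fold[:, :1]
    return DPrimeCurve(times=window_times(window, frame_rate), dprime=curve, per_fold=per_fold)


def smooth_axes_backward(s_t: np.ndarray, smoothing: int = 3) -> np.ndarray:
    """Backward moving average of a time-resolved axis S(t), (K, T)."""
    k, t = s_t.shape
    out = np.empty_like(s_t, dtype=float)
    for i in range(t):
        out[:, i] = s_t[:, max(0, i - smoothing + 1) : i + 1].mean(axis=1)
    return out


def axis_stability(s_t: np.ndarray, smoothing: int = 3) -> np.ndarray:
    """Cosine-similarity matrix R(S(t), S(t')) of a smoothed axis sequence.

    Entries involving a zero-norm axis are masked as NaN; the diagonal is 1
    wherever defined.
    """
    if s_t.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    s = smooth_axes_backward(np.asarray(s_t, dtype=float), smoothing)
    norms = np.linalg.norm(s, axis=0)
    valid = norms > 0
    sn = np.where(valid, norms, 1.0)
    u = s / sn
    r = u.T @ u
    r[~valid, :] = np.nan
    r[:, ~valid] = np.nan
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    return r


def stable_window_center(r: np.ndarray, threshold: float = 0.8) -> int:
    """Index t* at the center of the longest run with mean off-diagonal R > threshold."""
    t = r.shape[0]
    mean_off = np.array(
        [np.nanmean(np.delete(r[i], i)) if t > 1 else np.nan for i in range(t)]
    )
    good = mean_off > threshold
    best_len, best_start, run_start = 0, 0, None
    for i in range(t + 1):
        if i < t and good[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len == 0:
        return int(np.nanargmax(mean_off))
    return best_start + best_len // 2


def area_dprime_curve(
    grp_a: np.ndarray,
    grp_b: np.ndarray,
    component_idx: np.ndarray,
    frame_rate: float,
    window: tuple[float, float],
    **kwargs,
) -> DPrimeCurve:
    """d' curve using only a subset of components (one area or area group)."""
    component_idx = np.asarray(component_idx, dtype=int)
    if component_idx.size == 0:
        raise ValueError("area has no components")
    return dprime_curve(
        grp_a[:, component_idx], grp_b[:, component_idx], frame_rate, window, **kwargs
    )


def orthogonalize(target: np.ndarray, nuisance: list[np.ndarray]) -> np.ndarray:
    """Project nuisance axes out of a target axis and renormalize.

    Gram-Schmidt on the nuisance set, then removal of its span from the
    target.  A target inside the nuisance span raises.
    """
    basis: list[np.ndarray] = []
    for v in nuisance:
        u = np.asarray(v, dtype=float).copy()
        for b in basis:
            u -= (u @ b) * b
        n = np.linalg.norm(u)
        if n > 1e-12:
            basis.append(u / n)
    t = np.asarray(target, dtype=float).copy()
    for b in basis:
        t -= (t @ b) * b
    n = np.linalg.norm(t)
    if n < 1e-10:
        raise ValueError("target axis lies in the nuisance span")
    return t / n


def orthogonalized_dprime(
    grp_a: np.ndarray,
    grp_b: np.ndarray,
    nuisance_axes: list[np.ndarray],
    frame_rate: float,
    window: tuple[float, float],
    cv_folds: int = 5,
    train_frac: float = 0.2,
    seed: int = 0,
) -> DPrimeCurve:
    """Held-out d' along the target axis after removing nuisance directions.

    Per fold, the window-averaged target axis is fit on the training split,
    orthogonalized against the (label-independent) nuisance axes,
    renormalized, and scored on held-out trials.
    """
    n = grp_a.shape[0]
    rng = np.random.default_rng(seed)
    folds_a = _fold_indices(n, cv_folds, rng)
    folds_b = _fold_indices(grp_b.shape[0], cv_folds, rng)
    w = grp_a.shape[2]
    per_fold = np.empty((cv_folds, w))
    for f in range(cv_folds):
        tr_a, tr_b = folds_a[f], folds_b[f]
        te_a = np.setdiff1d(np.arange(n), tr_a)
        te_b = np.setdiff1d(np.arange(grp_b.shape[0]), tr_b)
        axis = state_axis(grp_a[tr_a], grp_b[tr_b], mode="window")
        axis = orthogonalize(axis, nuisance_axes)
        per_fold[f] = dprime(project(axis, grp_a[te_a]), project(axis, grp_b[te_b]))
    return DPrimeCurve(
        times=window_times(window, frame_rate),
        dprime=per_fold.mean(axis=0),
        per_fold=per_fold,
    )
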