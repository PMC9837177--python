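"""Seeded, localization-penalized matrix factorization of imaging tensors.

The decomposition approximates the concatenated dF/F tensor as a sum of
separable spatial-temporal components, ``F[x, y, t] ~ sum_k A[x, y, k] *
C[k, t]``, with each component anchored to one of the 10 atlas regions by a
per-pixel localization penalty.  Spatial maps are nonnegative; temporal
components are unconstrained (dF/F is signed).

Pipeline: SVD compression to 99% variance, seed-mask construction
(distance field D = 1 inside a region, exponential decay outside, penalty
1 - D), then a greedy rank line search that adds components to the region
with the largest residual variance until the explained-variance target is
met, re-fitting with warm-started HALS updates.  Every retained component
must keep at least the localization threshold of its spatial energy inside
its seed support (D > 0.5); components failing the check are re-fit with a
stronger penalty.

The factorization itself runs entirely in the compressed temporal basis:
with ``X ~ U S V^T`` (V orthonormal), fitting ``A W`` to ``U S`` is
equivalent to fitting ``A (W V^T)`` to the reconstruction, so the time
dimension never enters the inner loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synth import AreaAtlas

__all__ = [
    "SVDBasis",
    "SeedMask",
    "Decomposition",
    "svd_compress",
    "make_seed_masks",
    "loca_nmf",
    "explained_variance",
]


@dataclass
class SVDBasis:
    """Truncated SVD of the pixels x time data matrix."""

    u: np.ndarray  # (pixels, rank)
    s: np.ndarray  # (rank,)
    vt: np.ndarray  # (rank, time)
    ev: float  # explained fraction of squared Frobenius norm
    rank: int

    def reconstruct(self) -> np.ndarray:
        return (self.u * self.s) @ self.vt


def _centered_ev_by_rank(u: np.ndarray, s: np.ndarray, vt: np.ndarray, total_var: float):
    """Cumulative per-rank explained temporal variance of the reconstruction.

    Uses orthonormality of the rows of ``vt``: for the rank-r reconstruction
    the per-pixel sum of squares is the row norm of ``(u s)[:, :r]`` and the
    per-pixel temporal mean is its dot product with the column mean of
    ``vt``.
    """
    m = u * s
    n_time = vt.shape[1]
    vbar = vt.mean(axis=1)
    ssq_cum = np.cumsum(m**2, axis=1)
    mean_cum = np.cumsum(m * vbar, axis=1)
    var_by_rank = (ssq_cum / n_time - mean_cum**2).sum(axis=0)
    return var_by_rank / total_var


def svd_compress(x: np.ndarray, ev: float = 0.99, max_rank: int | None = None) -> SVDBasis:
    """Smallest-rank SVD basis whose reconstruction retains ``ev`` of the
    temporal variance.

    ``x`` is pixels x time (trials concatenated along time).  The basis is
    computed on the raw (uncentered) matrix, so per-pixel offsets stay
    representable, but the retention criterion is the summed per-pixel
    temporal variance of the rank-r reconstruction relative to that of the
    data — a pure DC offset costs no rank budget.  For matrices over ~1200
    rows/columns a randomized solver with adaptive rank doubling is used.
    ``max_rank`` caps the basis size even when the target is not reached.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not np.any(x != 0):
        raise ValueError("all-zero input")
    total_var = float(np.sum(np.var(x, axis=1)))
    n = min(x.shape)
    cap = n if max_rank is None else min(max_rank, n)

    if n <= 1200:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        ev_cum = _centered_ev_by_rank(u, s, vt, total_var) if total_var > 0 else np.ones(n)
    else:
        from sklearn.utils.extmath import randomized_svd

        k = min(64, cap)
        while True:
            u, s, vt = randomized_svd(x, n_components=k, random_state=0)
            ev_cum = _centered_ev_by_rank(u, s, vt, total_var) if total_var > 0 else np.ones(k)
            if ev_cum[-1] >= ev or k >= cap:
                break
            k = min(2 * k, cap)
    rank = int(np.searchsorted(ev_cum, ev) + 1)
    rank = min(rank, cap, len(s))
    return SVDBasis(
        u=np.ascontiguousarray(u[:, :rank]),
        s=s[:rank].copy(),
        vt=np.ascontiguousarray(vt[:rank]),
        ev=float(ev_cum[rank - 1]),
        rank=rank,
    )


@dataclass
class SeedMask:
    """Per-region distance field and localization penalty.

    ``distance`` is 1 exactly on region pixels and decays as
    ``exp(-dist / decay_length)`` outside; ``penalty = 1 - distance``.
    ``support`` is the D > 0.5 set used to score localization.
    """

    area_id: int
    distance: np.ndarray
    penalty: np.ndarray = field(init=False)
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.penalty = 1.0 - self.distance
        self.support = self.distance > 0.5


def make_seed_masks(atlas: AreaAtlas, decay_length: float | None = None) -> list[SeedMask]:
    """Build a seed mask per atlas region.

    ``decay_length`` is in pixels; the default is ~15% of the typical area
    diameter, approximately matching the spatial correlation length the
    seeding is meant to respect.
    """
    if decay_length is None:
        area_px = np.mean([atlas.area_mask(k).sum() for k in range(1, atlas.n_areas + 1)])
        decay_length = 0.15 * 2.0 * np.sqrt(area_px / np.pi)
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    masks = []
    for k in range(1, atlas.n_areas + 1):
        inside = atlas.area_mask(k)
        dist = ndimage.distance_transform_edt(~inside)
        d = np.where(inside, 1.0, np.exp(-dist / decay_length))
        masks.append(SeedMask(area_id=k, distance=d))
    return masks


@dataclass
class Decomposition:
    """Spatial maps, per-trial temporal components, and area assignments."""

    spatial: np.ndarray  # (x, y, K), nonnegative, unit-norm maps
    temporal: np.ndarray  # (trials, K, frames)
    component_area: np.ndarray  # (K,) area ids 1..N
    area_names: tuple[str, ...]
    ev_total: float
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.spatial.shape[-1]

    def concat_temporal(self) -> np.ndarray:
        """(K, trials * frames) temporal matrix."""
        tr, k, t = self.temporal.shape
        return np.moveaxis(self.temporal, 1, 0).reshape(k, tr * t)

    def components_of(self, area: int | str) -> np.ndarray:
        if isinstance(area, str):
            area = self.area_names.index(area) + 1
        return np.flatnonzero(self.component_area == area)

    def localization(self, masks: list[SeedMask]) -> np.ndarray:
        """Fraction of each component's spatial L2 energy inside its seed support."""
        flat = self.spatial.reshape(-1, self.n_components)
        out = np.empty(self.n_components)
        for k in range(self.n_components):
            m = masks[self.component_area[k] - 1].support.ravel()
            e = np.sum(flat[:, k] ** 2)
            out[k] = np.sum(flat[m, k] ** 2) / e if e > 0 else 0.0
        return out


def _hals_fit(
    y: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    penalties: np.ndarray,
    beta: np.ndarray,
    n_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating updates for A >= 0 (penalized) and unconstrained W.

    Minimizes ``||y - a w||^2 + sum_k beta_k * sum_p penalty[k, p] a[p, k]^2``
    where ``y`` is the compressed data (pixels x rank).
    """
    eps = 1e-12
    for _ in range(n_iter):
        gram = a.T @ a + 1e-10 * np.eye(a.shape[1])
        w = np.linalg.solve(gram, a.T @ y)
        yw = y @ w.T  # (pixels, K)
        ww = w @ w.T  # (K, K)
        for k in range(a.shape[1]):
            num = yw[:, k] - a @ ww[:, k] + a[:, k] * ww[k, k]
            den = ww[k, k] + beta[k] * penalties[k]
            a[:, k] = np.maximum(0.0, num / (den + eps))
        norms = np.linalg.norm(a, axis=0)
        dead = norms < eps
        if dead.any():  # revive numerically dead components
            a[:, dead] = eps
    return a, w


def _var_sum(m: np.ndarray, vbar: np.ndarray, n_time: int, rows=None) -> float:
    """Summed per-pixel temporal variance of ``m @ vt`` without forming it.

    ``m`` is (pixels, rank) coefficients in an orthonormal temporal basis
    ``vt`` whose column mean is ``vbar``.
    """
    if rows is not None:
        m = m[rows]
    ssq = np.sum(m**2, axis=1)
    mean = m @ vbar
    return float(np.sum(ssq / n_time - mean**2))


def _init_component(residual: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Seed a spatial map from the dominant residual pattern inside a support."""
    r = residual * support.ravel()[:, None]
    v = r.sum(axis=0)
    nv = np.linalg.norm(v)
    v = v / nv if nv > 0 else np.ones(r.shape[1]) / np.sqrt(r.shape[1])
    for _ in range(5):
        u = r @ v
        nu = np.linalg.norm(u)
        if nu == 0:
            break
        u /= nu
        v = r.T @ u
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    u = np.abs(r @ v)
    u *= support.ravel()
    n = np.linalg.norm(u)
    return u / n if n > 0 else support.ravel().astype(float) / np.sqrt(support.sum())


def loca_nmf(
    x: np.ndarray,
    masks: list[SeedMask],
    atlas: AreaAtlas,
    n_trials: int,
    loc_threshold: float = 0.75,
    ev_target: float = 0.99,
    max_per_area: int = 4,
    penalty_weight: float = 1.0,
    n_iter: int = 25,
    svd_ev: float = 0.99,
    svd_max_rank: int | None = None,
    seed: int = 0,
) -> Decomposition:
    """Greedy-rank localized NMF of a pixels x time matrix.

    ``x`` is (pixels, trials * frames) with pixels in row-major atlas order.
    The data is first SVD-compressed (``svd_ev`` variance, optionally capped
    at ``svd_max_rank``); the factorization and all variance accounting then
    target the compressed reconstruction, i.e. the structured part of the
    signal rather than per-pixel sensor noise.

    The line search starts with one component per region and repeatedly adds
    a component to the region whose seed support holds the largest residual
    variance, until ``ev_target`` is reached or every region is at
    ``max_per_area`` (then the best fit is returned with ``converged=False``
    and a warning).
    """
    x = np.asarray(x, dtype=float)
    if svd_max_rank is None:
        svd_max_rank = max(2 * max_per_area * len(masks), 20)
    basis = svd_compress(x, ev=svd_ev, max_rank=svd_max_rank)
    y = basis.u * basis.s  # (pixels, rank)
    vt = basis.vt
    n_time = x.shape[1]
    vbar = vt.mean(axis=1)

    n_pix = y.shape[0]
    supports = [m.support.ravel() for m in masks]
    penalties_flat = [m.penalty.ravel() for m in masks]
    total_var = _var_sum(y, vbar, n_time)

    comp_area: list[int] = []
    a = np.zeros((n_pix, 0))
    w = np.zeros((0, y.shape[1]))

    def add_component(area_idx: int):
        nonlocal a, w, comp_area
        residual = y - a @ w
        new_a = _init_component(residual, masks[area_idx].support)
        a = np.column_stack([a, new_a])
        w = np.vstack([w, new_a @ residual])
        comp_area.append(area_idx + 1)

    def loc_scores() -> np.ndarray:
        out = np.empty(len(comp_area))
        for k, ai in enumerate(comp_area):
            e = np.sum(a[:, k] ** 2)
            out[k] = np.sum(a[supports[ai - 1], k] ** 2) / e if e > 0 else 1.0
        return out

    def refit(iters: int):
        nonlocal a, w
        pen = np.stack([penalties_flat[ai - 1] for ai in comp_area])
        beta = np.full(len(comp_area), penalty_weight)
        scale = float(np.mean(np.sum(w**2, axis=1))) if w.size else 1.0
        a, w = _hals_fit(y, a, w, pen, beta * scale, iters)
        for _ in range(4):  # strengthen penalties on under-localized components
            bad = loc_scores() < loc_threshold
            if not bad.any():
                break
            beta[bad] *= 4.0
            scale = float(np.mean(np.sum(w**2, axis=1)))
            a, w = _hals_fit(y, a, w, pen, beta * scale, max(5, iters // 2))

    def recon_ev() -> float:
        return _var_sum(a @ w, vbar, n_time) / total_var if total_var > 0 else 0.0

    for i in range(len(masks)):
        add_component(i)
    refit(n_iter)
    ev = recon_ev()
    converged = ev >= ev_target
    while not converged:
        counts = np.bincount(comp_area, minlength=len(masks) + 1)[1:]
        residual = y - a @ w
        res_var = np.array(
            [
                _var_sum(residual, vbar, n_time, rows=supports[i])
                if counts[i] < max_per_area
                else -np.inf
                for i in range(len(masks))
            ]
        )
        if not np.isfinite(res_var).any() or res_var.max() <= 0:
            break
        add_component(int(np.argmax(res_var)))
        refit(n_iter)
        ev = recon_ev()
        converged = ev >= ev_target

    if not converged:
        warnings.warn(
            f"explained-variance target {ev_target} unreachable at max rank "
            f"(reached {ev:.4f}); returning best decomposition",
            RuntimeWarning,
        )

    # drop near-duplicate spatial maps within an area: collinear columns make
    # the temporal unmixing ill-conditioned (large anti-correlated noise in
    # the duplicated components) without adding explanatory power
    keep = np.ones(len(comp_area), dtype=bool)
    norms0 = np.linalg.norm(a, axis=0)
    norms0[norms0 == 0] = 1.0
    unit = a / norms0
    for i in range(len(comp_area)):
        if not keep[i]:
            continue
        for j in range(i + 1, len(comp_area)):
            if keep[j] and comp_area[i] == comp_area[j] and unit[:, i] @ unit[:, j] > 0.95:
                keep[j] = False
    if not keep.all():
        a = a[:, keep]
        w = w[keep]
        comp_area = [ai for ai, k in zip(comp_area, keep) if k]
        pen = np.stack([penalties_flat[ai - 1] for ai in comp_area])
        beta = np.full(len(comp_area), penalty_weight)
        scale = float(np.mean(np.sum(w**2, axis=1)))
        a, w = _hals_fit(y, a, w, pen, beta * scale, max(5, n_iter // 2))
        ev = recon_ev()

    norms = np.linalg.norm(a, axis=0)
    norms[norms == 0] = 1.0
    a = a / norms
    c = (w * norms[:, None]) @ vt

    order = np.argsort(comp_area, kind="stable")
    a = a[:, order]
    c = c[order]
    comp_area_arr = np.asarray(comp_area)[order]

    h, w_px = atlas.shape
    n_frames = n_time // n_trials
    temporal = np.moveaxis(c.reshape(len(comp_area), n_trials, n_frames), 0, 1)
    return Decomposition(
        spatial=a.reshape(h, w_px, -1),
        temporal=temporal,
        component_area=comp_area_arr,
        area_names=atlas.area_names,
        ev_total=ev,
        converged=converged,
    )


def explained_variance(
    decomp: Decomposition, subset: np.ndarray | list[int], x: np.ndarray
) -> float:
    """Explained variance of a component subset against the original matrix.

    Per pixel, the variance over concatenated time of the partial
    reconstruction is summed over pixels and divided by the summed variance
    of the original signal.  An empty subset yields 0.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return 0.0
    flat_a = decomp.spatial.reshape(-1, decomp.n_components)[:, subset]
    c = decomp.concat_temporal()[subset]
    recon = flat_a @ c
    var_x = np.sum(np.var(np.asarray(x, dtype=float), axis=1))
    return float(np.sum(np.var(recon, axis=1)) / var_x) if var_x > 0 else 0.0
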