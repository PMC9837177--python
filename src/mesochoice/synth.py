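"""Synthetic mesoscale imaging sessions, behavior, and psychometric choices.

This module generates everything the downstream analysis consumes: a
10-region cortical atlas, per-trial dF/F image tensors with planted
low-dimensional signals (stimulus, wheel movement, saccades, sustained
attention, and a sparse distributed choice signal), a per-trial behavior
table, and input/target sequences for the recurrent decision model.

The generator encodes the statistical structure the analysis assumes:

* choices follow a lapse-logistic psychometric curve of the signed
  orientation difference theta,
  ``P_left(theta) = sigmoid(alpha * theta) * (1 - lambda) + lambda / 2``,
  with a steeper slope in high-attention trials;
* each task variable contributes a separable spatial map x temporal kernel
  to the image tensor, with per-trial amplitude jitter along the same
  spatial pattern (this jitter, not the per-pixel sensor noise, sets the
  trial-to-trial discriminability of the variable);
* the choice signal is sparse and distributed across all areas, with an
  amplitude a fraction of the stimulus response;
* sustained attention is a session-state variable: a latent per-trial
  level drives both the pupil-area change and a sustained cortical offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AREA_NAMES",
    "AreaAtlas",
    "PsychometricParams",
    "PlantedSignal",
    "SignalSpec",
    "SessionParams",
    "SessionTensor",
    "RNNDataset",
    "make_atlas",
    "psychometric_prob",
    "simulate_choices",
    "expected_fraction_correct",
    "simulate_session",
    "gaussian_component_trials",
    "make_rnn_dataset",
    "default_signal_spec",
]

#: The ten posterior-cortex seeding regions, in canonical order.
AREA_NAMES = ("V1", "PM", "AM", "A", "SSt", "RL", "SSb", "AL", "L", "RS")


@dataclass(frozen=True)
class AreaAtlas:
    """Labeled cortical map on a pixel grid.

    ``label_map`` holds 0 outside the imaging window and 1..N inside, where
    N is the number of areas.  ``pixel_size`` is the pixel edge in microns.
    """

    label_map: np.ndarray
    area_names: tuple[str, ...] = AREA_NAMES
    pixel_size: float = 65.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.label_map)
        n = len(self.area_names)
        present = set(np.unique(labels)) - {0}
        if present != set(range(1, n + 1)):
            raise ValueError(
                f"label_map must contain exactly areas 1..{n}, got {sorted(present)}"
            )

    @property
    def n_areas(self) -> int:
        return len(self.area_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def area_id(self, name: str) -> int:
        return self.area_names.index(name) + 1

    def area_mask(self, area: int | str) -> np.ndarray:
        if isinstance(area, str):
            area = self.area_id(area)
        return self.label_map == area


def make_atlas(
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 65.0,
    jitter: float = 0.12,
    seed: int = 0,
) -> AreaAtlas:
    """Procedurally draw a 10-region Voronoi map inside a circular window.

    Site centers sit on a jittered two-ring layout; each labeled pixel is
    assigned to its nearest site, so every region is convex (hence
    contiguous), disjoint, and nonempty.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.48 * min(h, w)
    # 10 sites: 3 inner + 7 outer ring.
    sites = []
    for i in range(3):
        ang = 2 * np.pi * i / 3 + 0.3
        sites.append((cy + 0.35 * radius * np.sin(ang), cx + 0.35 * radius * np.cos(ang)))
    for i in range(7):
        ang = 2 * np.pi * i / 7
        sites.append((cy + 0.8 * radius * np.sin(ang), cx + 0.8 * radius * np.cos(ang)))
    sites = np.asarray(sites)
    sites += rng.normal(0.0, jitter * radius, size=sites.shape)

    yy, xx = np.mgrid[0:h, 0:w]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    d2 = (yy[..., None] - sites[:, 0]) ** 2 + (xx[..., None] - sites[:, 1]) ** 2
    labels = np.where(inside, np.argmin(d2, axis=-1) + 1, 0).astype(np.int32)
    # Voronoi cells of in-window sites are always nonempty (site pixel itself
    # lies inside); assert defensively in case jitter pushed a site out.
    for k in range(1, 11):
        if not np.any(labels == k):
            raise RuntimeError(f"atlas generation produced an empty area {k}")
    return AreaAtlas(label_map=labels, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Psychometric choice generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricParams:
    """Lapse-logistic psychometric parameters.

    ``lapse`` is the difficulty-independent error floor; ``slope_low`` and
    ``slope_high`` are the logistic slopes (per degree) in low and high
    sustained-attention states.
    """

    lapse: float = 0.2
    slope_low: float = 2.0 / 90.0
    slope_high: float = 5.0 / 90.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        if self.slope_low <= 0 or self.slope_high <= 0:
            raise ValueError("slopes must be positive")

    def slope(self, attention: str) -> float:
        if attention == "high":
            return self.slope_high
        if attention == "low":
            return self.slope_low
        raise ValueError(f"attention must be 'high' or 'low', got {attention!r}")


def psychometric_prob(theta, params: PsychometricParams, attention: str):
    """Probability of a left choice at signed angle difference ``theta``.

    ``P_left = sigmoid(alpha * theta) * (1 - lapse) + lapse / 2``; bounded in
    [lapse/2, 1 - lapse/2] and strictly increasing in theta.
    """
    alpha = params.slope(attention)
    theta = np.asarray(theta, dtype=float)
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(-alpha * theta))
    return sig * (1.0 - params.lapse) + params.lapse / 2.0


def standard_difficulties(n_levels: int = 13, max_angle: float = 90.0) -> np.ndarray:
    """Signed angle-difference levels uniformly spanning [-max, +max]."""
    return np.linspace(-max_angle, max_angle, n_levels)


def simulate_choices(
    difficulties,
    n_per_level: int,
    params: PsychometricParams,
    attention: str,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, float]:
    """Draw Bernoulli L/R choices from the psychometric curve.

    Returns a per-trial table (theta, choice, correct) and the fraction of
    correct trials.  A trial is correct when the choice matches sign(theta);
    at theta = 0 the rewarded side is a fair virtual coin.
    """
    difficulties = np.asarray(difficulties, dtype=float)
    if difficulties.size == 0:
        raise ValueError("difficulties must be nonempty")
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    theta = np.repeat(difficulties, n_per_level)
    p_left = psychometric_prob(theta, params, attention)
    left = rng.random(theta.size) < p_left
    rewarded_left = np.where(
        theta > 0, True, np.where(theta < 0, False, rng.random(theta.size) < 0.5)
    )
    correct = left == rewarded_left
    df = pd.DataFrame(
        {
            "theta": theta,
            "choice": np.where(left, "left", "right"),
            "correct": correct,
        }
    )
    return df, float(correct.mean())


def expected_fraction_correct(
    difficulties, params: PsychometricParams, attention: str
) -> float:
    """Closed-form expectation of ``simulate_choices`` fraction correct."""
    theta = np.asarray(difficulties, dtype=float)
    p_left = psychometric_prob(theta, params, attention)
    p_correct = np.where(theta > 0, p_left, np.where(theta < 0, 1.0 - p_left, 0.5))
    return float(p_correct.mean())


def fit_psychometric(theta, left, slope0: float = 0.02, lapse0: float = 0.1):
    """Maximum-likelihood fit of the lapse-logistic model.

    Returns ``(alpha, lapse)`` maximizing the Bernoulli likelihood of the
    observed left/right choices over the signed difficulty ``theta``.
    """
    from scipy.optimize import minimize

    theta = np.asarray(theta, dtype=float)
    left = np.asarray(left, dtype=bool)

    def nll(x):
        alpha, lapse = x
        with np.errstate(over="ignore"):
            sig = 1.0 / (1.0 + np.exp(-alpha * theta))
        p = sig * (1.0 - lapse) + lapse / 2.0
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(np.where(left, np.log(p), np.log1p(-p)))

    res = minimize(
        nll,
        x0=[slope0, lapse0],
        method="L-BFGS-B",
        bounds=[(1e-5, 10.0), (0.0, 1.0)],
    )
    return float(res.x[0]), float(res.x[1])


def fit_psychometric_curve(theta, p_left, slope0: float = 0.02, lapse0: float = 0.1):
    """Least-squares fit of the lapse-logistic model to a probability curve.

    Unlike :func:`fit_psychometric` this fits measured choice probabilities
    (e.g. a model's output curve) rather than binary trials.  Returns
    ``(alpha, lapse)``.
    """
    from scipy.optimize import minimize

    theta = np.asarray(theta, dtype=float)
    p_left = np.asarray(p_left, dtype=float)

    def sse(x):
        alpha, lapse = x
        with np.errstate(over="ignore"):
            pred = (1.0 / (1.0 + np.exp(-alpha * theta))) * (1.0 - lapse) + lapse / 2.0
        return np.sum((pred - p_left) ** 2)

    res = minimize(
        sse, x0=[slope0, lapse0], method="L-BFGS-B", bounds=[(1e-5, 10.0), (0.0, 1.0)]
    )
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# Imaging-session generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSignal:
    """One planted task variable: spatial footprint and temporal kernel.

    ``amplitude`` is the per-carrier-pixel dF/F amplitude of the signal;
    ``trial_noise_sd`` is the SD of per-trial amplitude jitter applied along
    the same spatial pattern.  The jitter is what limits single-trial
    discriminability: after spatial pooling the expected d' of a two-sided
    signal is approximately ``2 * amplitude / trial_noise_sd``.
    """

    carrier_areas: tuple[str, ...]
    amplitude: float
    trial_noise_sd: float
    spatial_sparsity: float = 1.0
    temporal_profile: str = "transient"  # step | transient | ramp | constant

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 < self.spatial_sparsity <= 1.0:
            raise ValueError("spatial_sparsity must be in (0, 1]")


@dataclass(frozen=True)
class SignalSpec:
    """Amplitudes and footprints of all planted variables plus noise terms."""

    stimulus: PlantedSignal
    wheel: PlantedSignal
    saccade: PlantedSignal
    attention: PlantedSignal
    choice: PlantedSignal
    noise_sd: float = 0.01
    global_fluct_sd: float = 0.003


def default_signal_spec() -> SignalSpec:
    """Study-condition defaults.

    Amplitude-to-jitter ratios are set so cross-validated d' of each
    variable lands in the 0.5-1.5 range observed for mesoscale task
    variables; the choice signal is sparse (20% of pixels) across all 10
    areas with amplitude one fifth of the stimulus response.
    """
    return SignalSpec(
        stimulus=PlantedSignal(
            carrier_areas=("V1", "L", "AL"),
            amplitude=0.020,
            trial_noise_sd=0.020,
            temporal_profile="transient",
        ),
        wheel=PlantedSignal(
            carrier_areas=("A", "AM", "RL", "PM"),
            amplitude=0.015,
            trial_noise_sd=0.012,
            temporal_profile="step",
        ),
        saccade=PlantedSignal(
            carrier_areas=("AM", "A"),
            amplitude=0.015,
            trial_noise_sd=0.010,
            temporal_profile="transient",
        ),
        attention=PlantedSignal(
            carrier_areas=("AM", "A", "RS", "PM"),
            amplitude=0.008,
            trial_noise_sd=0.004,
            temporal_profile="constant",
        ),
        choice=PlantedSignal(
            carrier_areas=AREA_NAMES,
            amplitude=0.004,
            trial_noise_sd=0.008,
            spatial_sparsity=0.2,
            temporal_profile="ramp",
        ),
    )


@dataclass(frozen=True)
class SessionParams:
    """Trial timing and behavioral statistics of a simulated session."""

    frame_rate: float = 30.0
    pre_stim: float = 1.0  # s before stimulus onset
    open_loop: float = 1.5  # s of open-loop after onset
    closed_loop: float = 1.0  # s of closed-loop retained in the tensor
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    n_levels: int = 13
    max_angle: float = 90.0
    p_move: float = 0.8  # fraction of trials with a detected wheel movement
    move_delay_mean: float = 0.5  # s, exponential delay added to the 0.5 s floor
    saccade_rate: float = 0.15  # events / s

    @property
    def trial_duration(self) -> float:
        return self.pre_stim + self.open_loop + self.closed_loop

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))

    @property
    def stim_frame(self) -> int:
        return int(round(self.pre_stim * self.frame_rate))


@dataclass
class SessionTensor:
    """Per-trial dF/F image stack with timing metadata."""

    data: np.ndarray  # (trials, x, y, t)
    frame_rate: float
    pre_stim: float
    open_loop: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.data.ndim != 4:
            raise ValueError("data must be (trials, x, y, t)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def stim_frame(self) -> int:
        return int(round(self.pre_stim * self.frame_rate))


def _temporal_kernel(
    profile: str, n_frames: int, event_frame: float, frame_rate: float
) -> np.ndarray:
    """Unit-amplitude kernel aligned to ``event_frame``."""
    t = (np.arange(n_frames) - event_frame) / frame_rate
    if profile == "constant":
        return np.ones(n_frames)
    if profile == "step":
        return (t >= 0).astype(float)
    if profile == "transient":
        tau = 0.2
        k = np.where(t >= 0, (t / tau) * np.exp(1.0 - t / tau), 0.0)
        return k
    if profile == "ramp":
        # linear rise over the 0.3 s before the event, sustained after
        rise = 0.3
        return np.clip((t + rise) / rise, 0.0, 1.0)
    raise ValueError(f"unknown temporal profile {profile!r}")


def _spatial_map(
    atlas: AreaAtlas, sig: PlantedSignal, rng: np.random.Generator
) -> np.ndarray:
    mask = np.zeros(atlas.shape, dtype=bool)
    for name in sig.carrier_areas:
        mask |= atlas.area_mask(name)
    if sig.spatial_sparsity < 1.0:
        idx = np.flatnonzero(mask.ravel())
        keep = rng.choice(idx, size=max(1, int(round(sig.spatial_sparsity * idx.size))), replace=False)
        mask = np.zeros(atlas.shape, dtype=bool).ravel()
        mask[keep] = True
        mask = mask.reshape(atlas.shape)
    return mask.astype(float)


def simulate_behavior(
    params: SessionParams, n_trials: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate the per-trial behavior table (no imaging).

    Attention is driven by a latent per-trial level z ~ N(0,1): the pupil
    change is z plus measurement noise, the slope of the psychometric curve
    is high for z > 0, and the planted attention signal is proportional to z.
    Attention labels are the top/bottom tertiles of the z-scored pupil
    change, as in the analysis.
    """
    fps = params.frame_rate
    n_frames = params.n_frames
    stim_frame = params.stim_frame
    post_dur = params.open_loop + params.closed_loop

    latent = rng.normal(0.0, 1.0, n_trials)
    pupil_raw = latent + rng.normal(0.0, 0.4, n_trials)
    pupil_change = (pupil_raw - pupil_raw.mean()) / pupil_raw.std()

    levels = standard_difficulties(params.n_levels, params.max_angle)
    theta = rng.choice(levels, size=n_trials)
    left_angle = rng.uniform(-90.0, 90.0, n_trials)
    right_angle = left_angle - theta

    att_state = np.where(latent > 0, "high", "low")
    p_left = np.array(
        [
            psychometric_prob(th, params.psychometric, att)
            for th, att in zip(theta, att_state)
        ]
    )
    chose_left = rng.random(n_trials) < p_left

    moves = rng.random(n_trials) < params.p_move
    max_move = post_dur - 0.25
    move_time = 0.5 + rng.exponential(params.move_delay_mean, n_trials)
    move_time = np.minimum(move_time, max_move)
    move_time[~moves] = np.nan

    choice = np.where(moves, np.where(chose_left, "left", "right"), "timeout")
    first_move_dir = np.where(moves, np.where(chose_left, "cw", "ccw"), None)

    rewarded_left = np.where(
        theta > 0, True, np.where(theta < 0, False, rng.random(n_trials) < 0.5)
    )
    correct = moves & (chose_left == rewarded_left)

    saccade_times = []
    for i in range(n_trials):
        n_sac = rng.poisson(params.saccade_rate * post_dur)
        times = np.sort(rng.uniform(0.05, post_dur - 0.1, n_sac))
        saccade_times.append(times)

    return pd.DataFrame(
        {
            "stim_onset": np.full(n_trials, stim_frame, dtype=int),
            "left_angle": left_angle,
            "right_angle": right_angle,
            "theta": theta,
            "difficulty": np.abs(theta),
            "choice": choice,
            "correct": correct,
            "first_move_time": move_time,
            "first_move_dir": first_move_dir,
            "saccade_times": saccade_times,
            "pupil_change": pupil_change,
            "attention_latent": latent,
            "n_frames": np.full(n_trials, n_frames, dtype=int),
        }
    )


def label_attention(table: pd.DataFrame) -> pd.DataFrame:
    """Add tertile attention labels from the z-scored pupil change."""
    pa = table["pupil_change"].to_numpy()
    lo, hi = np.percentile(pa, [100 / 3, 200 / 3])
    label = np.where(pa >= hi, "high", np.where(pa <= lo, "low", "mid"))
    out = table.copy()
    out["attention"] = label
    return out


def simulate_session(
    atlas: AreaAtlas,
    spec: SignalSpec,
    params: SessionParams,
    n_trials: int,
    seed: int = 0,
) -> tuple[SessionTensor, pd.DataFrame]:
    """Generate a full imaging session: dF/F tensor plus behavior table.

    The tensor is the sum over planted variables of
    ``spatial map x temporal kernel x (signed amplitude + trial jitter)``,
    plus iid per-pixel Gaussian noise and a shared global fluctuation.
    Bit-reproducible for a fixed ``(seed, atlas, spec, params)``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    fps = params.frame_rate
    n_frames = params.n_frames
    stim_frame = params.stim_frame

    table = simulate_behavior(params, n_trials, rng)
    table = label_attention(table)

    h, w = atlas.shape
    data = rng.normal(0.0, spec.noise_sd, size=(n_trials, h, w, n_frames)).astype(
        np.float32
    )

    # shared global fluctuation: smooth in time, uniform in space
    if spec.global_fluct_sd > 0:
        g = rng.normal(0.0, 1.0, size=(n_trials, n_frames))
        kern = np.ones(5) / 5.0
        g = np.apply_along_axis(lambda x: np.convolve(x, kern, mode="same"), 1, g)
        g *= spec.global_fluct_sd / max(g.std(), 1e-12)
        data += g[:, None, None, :].astype(np.float32)

    maps = {
        name: _spatial_map(atlas, getattr(spec, name), rng)
        for name in ("stimulus", "wheel", "saccade", "attention", "choice")
    }

    move_frames = table["first_move_time"].to_numpy() * fps + stim_frame
    chose_left = table["choice"].to_numpy() == "left"
    latent = table["attention_latent"].to_numpy()

    for i in range(n_trials):
        tk = np.zeros((h, w, n_frames), dtype=np.float32)

        def add(sig: PlantedSignal, m: np.ndarray, event_frame: float, scale: float):
            amp = scale * sig.amplitude + rng.normal(0.0, sig.trial_noise_sd)
            k = _temporal_kernel(sig.temporal_profile, n_frames, event_frame, fps)
            tk[m > 0] += (amp * k).astype(np.float32)

        add(spec.stimulus, maps["stimulus"], stim_frame, 1.0)
        add(spec.attention, maps["attention"], 0, latent[i])
        if np.isfinite(move_frames[i]):
            add(spec.wheel, maps["wheel"], move_frames[i], 1.0)
            sgn = 1.0 if chose_left[i] else -1.0
            add(spec.choice, maps["choice"], move_frames[i], sgn)
        for t_s in table["saccade_times"].iloc[i]:
            add(spec.saccade, maps["saccade"], t_s * fps + stim_frame, 1.0)
        data[i] += tk

    tensor = SessionTensor(
        data=data, frame_rate=fps, pre_stim=params.pre_stim, open_loop=params.open_loop
    )
    return tensor, table


def gaussian_component_trials(
    delta: float,
    n_trials: int,
    n_components: int = 2,
    n_frames: int = 20,
    noise_sd: float = 1.0,
    signal_component: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class Gaussian clouds in component space, the d' oracle fixture.

    Groups differ by ``delta`` along one component with unit (``noise_sd``)
    isotropic noise, constant over frames, so the closed-form population d'
    equals ``delta / noise_sd`` along the planted axis.

    Returns ``(temporal, labels)`` with ``temporal`` of shape
    (trials, components, frames) and boolean ``labels`` (True = group A).
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_trials, dtype=bool)
    labels[: n_trials // 2] = True
    means = np.zeros((n_trials, n_components))
    means[labels, signal_component] = delta / 2.0
    means[~labels, signal_component] = -delta / 2.0
    noise = rng.normal(0.0, noise_sd, size=(n_trials, n_components, n_frames))
    temporal = means[:, :, None] + noise
    return temporal, labels


def planted_sparse_choice_session(
    atlas: AreaAtlas,
    per_pixel_dprime: float = 0.12,
    n_carrier: int = 400,
    n_trials: int = 3000,
    n_frames: int = 3,
    pixel_noise_sd: float = 0.01,
    background_sd: float = 2.5e-3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class session with a weak choice signal spread over many pixels.

    The carrier set is a random subset of labeled pixels distributed across
    all areas; these pixels model the sparse functional population that
    carries both ongoing activity and the choice signal.  Per area, an
    independent background fluctuation of SD ``background_sd`` modulates the
    area's carrier pixels coherently (so each area owns a compressible,
    localized activity mode, as in real data), and on top of it every
    carrier pixel's mean separates by
    ``sep = per_pixel_dprime * sqrt(pixel_noise_sd^2 + background_sd^2)``
    between the classes — single-pixel discriminability ``per_pixel_dprime``.

    Pooling the N carriers averages away the independent pixel noise and,
    across the 10 mutually independent area backgrounds, most of the
    background as well:
    ``d'_pop ~ sqrt(N) * sep / sqrt((N / 10) * background_sd^2 +
    pixel_noise_sd^2)``, about 1.3 at the defaults — an order of magnitude
    above the per-pixel value.

    Returns ``(data (trials, x, y, frames), labels, carrier_mask)``.
    """
    rng = np.random.default_rng(seed)
    flat_labels = atlas.label_map.ravel()
    labeled = np.flatnonzero(flat_labels > 0)
    carriers = rng.choice(labeled, size=n_carrier, replace=False)
    mask = np.zeros(flat_labels.size, dtype=bool)
    mask[carriers] = True
    mask = mask.reshape(atlas.shape)

    labels = np.zeros(n_trials, dtype=bool)
    labels[: n_trials // 2] = True
    sep = per_pixel_dprime * np.sqrt(pixel_noise_sd**2 + background_sd**2)
    amp = np.where(labels, sep / 2, -sep / 2)
    data = rng.normal(0.0, pixel_noise_sd, size=(n_trials, *atlas.shape, n_frames))
    data += amp[:, None, None, None] * mask[None, :, :, None]
    for area in range(1, atlas.n_areas + 1):
        area_carriers = mask & atlas.area_mask(area)
        if not area_carriers.any():
            continue
        bg = rng.normal(0.0, background_sd, size=(n_trials, 1, 1, n_frames))
        data += bg * area_carriers[None, :, :, None]
    return data, labels, mask


# ---------------------------------------------------------------------------
# RNN training data
# ---------------------------------------------------------------------------


@dataclass
class RNNDataset:
    """Input/target sequences for the recurrent decision model.

    ``inputs``: (trials, frames, 3) — left stimulus, right stimulus, and a
    binary attention channel.  ``targets``: (trials, 2, 3) one-hot rows for
    the stimulus-presentation frame (no-choice class) and the final frame
    (left or right per the simulated choice).  ``meta`` records theta,
    attention, and the drawn choice per trial.
    """

    inputs: np.ndarray
    targets: np.ndarray
    stim_frame: int
    meta: pd.DataFrame


def make_rnn_dataset(
    params: PsychometricParams,
    n_per_level: int,
    difficulties=None,
    attention_levels=("low", "high"),
    n_frames: int = 25,
    stim_onset_frame: int = 10,
    input_noise_sd: float = 0.1,
    seed: int = 0,
) -> RNNDataset:
    """Build the psychometrically labeled training set.

    Stimulus channels are zero for the first ``stim_onset_frame`` frames and
    constant at angle/90 afterwards; Gaussian noise (SD ``input_noise_sd``)
    is added to the stimulus channels on every frame.  The attention channel
    is a noiseless constant 0/1.  theta is the left minus right channel
    level, so the left-choice label frequency per level follows
    ``P_left(theta)``.
    """
    if difficulties is None:
        difficulties = standard_difficulties()
    difficulties = np.asarray(difficulties, dtype=float)
    if np.any(np.abs(difficulties) > 90.0):
        raise ValueError("difficulties must lie within [-90, 90] degrees")
    rng = np.random.default_rng(seed)

    thetas, att_labels = [], []
    for att in attention_levels:
        for th in difficulties:
            thetas.extend([th] * n_per_level)
            att_labels.extend([att] * n_per_level)
    theta = np.asarray(thetas)
    att = np.asarray(att_labels)
    n = theta.size
    order = rng.permutation(n)
    theta, att = theta[order], att[order]

    # orientation pair with the given signed difference; absolute level is
    # task-irrelevant and drawn uniformly within range
    left = np.empty(n)
    for i in range(n):
        lo, hi = max(-90.0, theta[i] - 90.0), min(90.0, theta[i] + 90.0)
        left[i] = rng.uniform(lo, hi)
    right = left - theta

    x = np.zeros((n, n_frames, 3), dtype=np.float32)
    x[:, stim_onset_frame:, 0] = (left / 90.0)[:, None]
    x[:, stim_onset_frame:, 1] = (right / 90.0)[:, None]
    x[:, :, :2] += rng.normal(0.0, input_noise_sd, size=(n, n_frames, 2)).astype(
        np.float32
    )
    x[:, :, 2] = (att == "high").astype(np.float32)[:, None]

    p_left = np.where(
        att == "high",
        psychometric_prob(left - right, params, "high"),
        psychometric_prob(left - right, params, "low"),
    )
    chose_left = rng.random(n) < p_left

    targets = np.zeros((n, 2, 3), dtype=np.float32)
    targets[:, 0, 2] = 1.0  # no-choice at stimulus presentation
    targets[chose_left, 1, 0] = 1.0
    targets[~chose_left, 1, 1] = 1.0

    meta = pd.DataFrame(
        {
            "theta": left - right,
            "attention": att,
            "choice": np.where(chose_left, "left", "right"),
        }
    )
    return RNNDataset(inputs=x, targets=targets, stim_frame=stim_onset_frame, meta=meta)
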