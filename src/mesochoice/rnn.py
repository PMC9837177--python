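"""Recurrent decision model trained on psychometrically generated choices.

A single Elman recurrent layer of 50 ReLU units receives three inputs
(left stimulus, right stimulus, binary attention), followed by a batch
normalization layer over the recurrent output sequence and a 3-class
softmax head (left, right, no-choice).  The loss is categorical cross
entropy at two frames only: the stimulus-presentation frame (target
no-choice, which pins the output before evidence arrives) and the final
frame (target equal to the psychometrically drawn choice).  Training uses
Adam for 25 epochs with batch size 640.

The network, batch normalization, backpropagation through time, and the
Adam optimizer are implemented directly in numpy: the model is tiny (about
3,000 parameters) and full-batch gradients are checked against finite
differences in the test suite.

For the representational analyses, the model's "choice" on a trial is its
own response (the argmax of the left/right output at the final frame), in
the same way the animal's choice is its recorded response; hidden-unit
time series then play the role of the temporal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import axes as _axes
from .geometry import axis_angle
from .synth import RNNDataset, PsychometricParams, make_rnn_dataset

__all__ = [
    "RNNConfig",
    "DecisionRNN",
    "build_rnn",
    "train_rnn",
    "rnn_psychometric",
    "hidden_traces",
    "rnn_choice_axes",
    "choice_axis_angles",
]

_EPS = 1e-5


@dataclass
class RNNConfig:
    n_units: int = 50
    n_frames: int = 25
    stim_onset_frame: int = 10
    n_inputs: int = 3
    n_outputs: int = 3
    epochs: int = 25
    batch_size: int = 640
    learning_rate: float = 1e-3
    input_noise_sd: float = 0.1
    bn_momentum: float = 0.99

    def __post_init__(self) -> None:
        if min(self.n_units, self.n_frames, self.n_inputs, self.n_outputs) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.stim_onset_frame < self.n_frames:
            raise ValueError("stim_onset_frame must lie within the trial")


class DecisionRNN:
    """Elman RNN + batch norm + softmax head, all parameters in numpy arrays."""

    PARAM_NAMES = ("wx", "wh", "b", "gamma", "beta", "wo", "bo")

    def __init__(self, config: RNNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        n, i, o = config.n_units, config.n_inputs, config.n_outputs
        q, _ = np.linalg.qr(rng.normal(size=(n, n)))
        self.params = {
            "wx": rng.normal(0.0, 1.0 / np.sqrt(i), size=(i, n)),
            "wh": 0.9 * q,
            "b": np.zeros(n),
            "gamma": np.ones(n),
            "beta": np.zeros(n),
            "wo": rng.normal(0.0, 1.0 / np.sqrt(n), size=(n, o)),
            "bo": np.zeros(o),
        }
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward -----------------------------------------------------------

    def _recur(self, x: np.ndarray):
        """Run the recurrence; returns pre-activations z and hidden states h."""
        bsz, t, _ = x.shape
        n = self.config.n_units
        z = np.empty((bsz, t, n))
        h = np.empty((bsz, t, n))
        prev = np.zeros((bsz, n))
        wx, wh, b = self.params["wx"], self.params["wh"], self.params["b"]
        for j in range(t):
            z[:, j] = x[:, j] @ wx + prev @ wh + b
            prev = np.maximum(z[:, j], 0.0)
            h[:, j] = prev
        return z, h

    def forward(self, x: np.ndarray, train: bool = False):
        """Return (softmax outputs (B, T, O), cache for backward)."""
        z, h = self._recur(x)
        g, be = self.params["gamma"], self.params["beta"]
        if train:
            mu = h.mean(axis=(0, 1))
            var = h.var(axis=(0, 1))
            m = self.config.bn_momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + _EPS)
        xhat = (h - mu) / std
        hn = g * xhat + be
        logits = hn @ self.params["wo"] + self.params["bo"]
        ex = np.exp(logits - logits.max(axis=-1, keepdims=True))
        probs = ex / ex.sum(axis=-1, keepdims=True)
        cache = {"x": x, "z": z, "h": h, "xhat": xhat, "std": std, "probs": probs, "train": train}
        return probs, cache

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, targets: np.ndarray, stim_frame: int):
        """Cross entropy at the stimulus frame and the final frame, plus grads.

        ``targets`` is (B, 2, O): row 0 for the stimulus frame, row 1 for the
        last frame.
        """
        probs, cache = self.forward(x, train=True)
        bsz, t, o = probs.shape
        frames = (stim_frame, t - 1)
        loss = 0.0
        dlogits = np.zeros_like(probs)
        for r, f in enumerate(frames):
            p = np.clip(probs[:, f], 1e-12, None)
            loss -= np.mean(np.sum(targets[:, r] * np.log(p), axis=-1))
            dlogits[:, f] = (probs[:, f] - targets[:, r]) / bsz

        g = self.params["gamma"]
        hn_grad = dlogits @ self.params["wo"].T
        xhat = cache["xhat"]
        flat = lambda a: a.reshape(-1, a.shape[-1])
        dwo = flat(g * xhat + self.params["beta"]).T @ flat(dlogits)
        dbo = flat(dlogits).sum(axis=0)

        # batch-norm backward over the (batch, time) sample axis
        m = bsz * t
        dgamma = (hn_grad * xhat).sum(axis=(0, 1))
        dbeta = hn_grad.sum(axis=(0, 1))
        dxhat = hn_grad * g
        s1 = dxhat.sum(axis=(0, 1))
        s2 = (dxhat * xhat).sum(axis=(0, 1))
        dh = (dxhat - s1 / m - xhat * s2 / m) / cache["std"]

        # backpropagation through time
        wx, wh = self.params["wx"], self.params["wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(self.params["b"])
        dz_next = None
        for j in range(t - 1, -1, -1):
            dh_j = dh[:, j].copy()
            if dz_next is not None:
                dh_j += dz_next @ wh.T
            dz = dh_j * (cache["z"][:, j] > 0)
            dwx += x[:, j].T @ dz
            db += dz.sum(axis=0)
            if j > 0:
                dwh += cache["h"][:, j - 1].T @ dz
            dz_next = dz

        grads = {"wx": dwx, "wh": dwh, "b": db, "gamma": dgamma, "beta": dbeta, "wo": dwo, "bo": dbo}
        return float(loss), grads, probs


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)  # end-of-trial categorical accuracy


def build_rnn(config: RNNConfig | None = None, seed: int = 0) -> DecisionRNN:
    """Freshly initialized decision RNN; identical weights for identical seeds."""
    return DecisionRNN(config or RNNConfig(), seed=seed)


def train_rnn(
    model: DecisionRNN, dataset: RNNDataset, seed: int = 0, verbose: bool = False
) -> TrainHistory:
    """Adam training on the psychometrically labeled dataset.

    End-of-trial categorical accuracy is reported per epoch; because the
    labels are stochastic, it converges to the generator's label
    consistency (the mean of max(P_left, 1 - P_left)), not to 1.
    """
    cfg = model.config
    rng = np.random.default_rng(seed)
    x, y = dataset.inputs.astype(float), dataset.targets.astype(float)
    n = x.shape[0]
    mstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    vstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            if sel.size < 2:
                continue
            loss, grads, probs = model.loss_and_grads(x[sel], y[sel], dataset.stim_frame)
            if not np.isfinite(loss):
                raise RuntimeError(f"divergent loss at epoch {epoch}; aborting")
            step += 1
            for k in model.params:
                mstate[k] = b1 * mstate[k] + (1 - b1) * grads[k]
                vstate[k] = b2 * vstate[k] + (1 - b2) * grads[k] ** 2
                mhat = mstate[k] / (1 - b1**step)
                vhat = vstate[k] / (1 - b2**step)
                model.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            losses.append(loss)
            pred = probs[:, -1].argmax(axis=-1)
            correct += int((pred == y[sel, 1].argmax(axis=-1)).sum())
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(correct / n)
        if verbose:
            print(f"epoch {epoch + 1}: loss {history.loss[-1]:.4f} acc {history.accuracy[-1]:.3f}")
    return history


def end_accuracy(model: DecisionRNN, dataset: RNNDataset) -> float:
    """Final-frame categorical accuracy against the dataset labels (eval mode)."""
    probs, _ = model.forward(dataset.inputs.astype(float), train=False)
    pred = probs[:, -1].argmax(axis=-1)
    return float((pred == dataset.targets[:, 1].argmax(axis=-1)).mean())


def model_choices(model: DecisionRNN, inputs: np.ndarray) -> np.ndarray:
    """The model's own L/R response per trial: argmax of (L, R) at the final frame."""
    probs, _ = model.forward(np.asarray(inputs, dtype=float), train=False)
    return np.where(probs[:, -1, 0] >= probs[:, -1, 1], "left", "right")


def rnn_psychometric(
    model: DecisionRNN,
    thetas,
    attention_values=(0.0, 1.0),
    n_trials: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Choice-probability curve of the trained model.

    For each (theta, attention input level), the reported ``p_left`` is the
    model's mean final-frame output probability of left among left/right,
    ``P(L) / (P(L) + P(R))``.  Cross entropy against stochastically drawn
    labels makes this output converge to the generator's psychometric
    probability, so a lapse-logistic fit of the curve recovers the training
    lapse and slopes.  ``frac_left`` additionally reports the fraction of
    argmax responses, which is much steeper (the argmax washes out the
    learned probability).

    Inputs are generated exactly as in training (noisy stimulus channels,
    constant attention channel), but the attention level may be any scalar,
    including values never seen in training, to probe generalization.
    """
    cfg = model.config
    rng = np.random.default_rng(seed)
    rows = []
    for att in attention_values:
        for th in np.asarray(thetas, dtype=float):
            lo, hi = max(-90.0, th - 90.0), min(90.0, th + 90.0)
            left = rng.uniform(lo, hi, size=n_trials)
            right = left - th
            x = np.zeros((n_trials, cfg.n_frames, 3), dtype=float)
            x[:, cfg.stim_onset_frame :, 0] = (left / 90.0)[:, None]
            x[:, cfg.stim_onset_frame :, 1] = (right / 90.0)[:, None]
            x[:, :, :2] += rng.normal(0.0, cfg.input_noise_sd, size=(n_trials, cfg.n_frames, 2))
            x[:, :, 2] = att
            probs, _ = model.forward(x, train=False)
            p_lr = probs[:, -1, 0] / (probs[:, -1, 0] + probs[:, -1, 1])
            frac = float((probs[:, -1, 0] >= probs[:, -1, 1]).mean())
            rows.append(
                {"theta": th, "attention": att, "p_left": float(p_lr.mean()), "frac_left": frac}
            )
    return pd.DataFrame(rows)


def hidden_traces(model: DecisionRNN, inputs: np.ndarray) -> np.ndarray:
    """Hidden-unit activations (trials, units, frames), ReLU so nonnegative."""
    _, h = model._recur(np.asarray(inputs, dtype=float))
    return np.moveaxis(h, 1, 2)


def rnn_choice_axes(
    model: DecisionRNN,
    dataset: RNNDataset,
    by: str = "difficulty",
    window_frames: tuple[int, int] | None = None,
) -> dict:
    """Choice state axes of the hidden units, split by difficulty or attention.

    The choice on each trial is the model's own response.  Axes are
    window-averaged over the post-stimulus frames (by default from 3 frames
    after stimulus onset to the final frame), exactly as for the imaging
    components.  Returns a dict mapping the condition (difficulty level or
    attention label) to a unit-norm axis over hidden units.
    """
    cfg = model.config
    h = hidden_traces(model, dataset.inputs)
    choice = model_choices(model, dataset.inputs)
    if window_frames is None:
        window_frames = (cfg.stim_onset_frame + 3, cfg.n_frames - 1)
    f0, f1 = window_frames
    h = h[:, :, f0 : f1 + 1]

    meta = dataset.meta
    out = {}
    if by == "difficulty":
        keys = np.round(np.abs(meta["theta"].to_numpy()), 6)
    elif by == "attention":
        keys = meta["attention"].to_numpy()
    else:
        raise ValueError("by must be 'difficulty' or 'attention'")
    for key in np.unique(keys):
        sel = keys == key
        left = sel & (choice == "left")
        right = sel & (choice == "right")
        if left.sum() < 2 or right.sum() < 2:
            continue
        out[key] = _axes.state_axis(h[left], h[right], mode="window")
    return out


def choice_axis_angles(axes_by_condition: dict) -> pd.DataFrame:
    """Pairwise angles between per-condition choice axes."""
    keys = list(axes_by_condition)
    rows = []
    for i, ki in enumerate(keys):
        for kj in keys[i + 1 :]:
            rows.append(
                {
                    "a": ki,
                    "b": kj,
                    "angle_deg": axis_angle(axes_by_condition[ki], axes_by_condition[kj]),
                }
            )
    return pd.DataFrame(rows)
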