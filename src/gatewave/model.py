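"""The weighted gate layer autoencoder (WGLAE).

A single-hidden-layer under-complete autoencoder with a logistic sigmoid on
both layers. Each training sample is one EEG segment flattened channel-major
(channels x samples). A binary gate is applied to the input by element-wise
multiplication, zeroing the blocked (DV) channels:

    x_gated = x (*) theta
    x_hat   = sigmoid(W_ho . sigmoid(W_ih . x_gated + b_h) + b_o)

The loss is a per-feature weighted squared error against the ORIGINAL,
ungated sample, so the network must infer the blocked channels from the
remaining ones:

    wLoss = (1/Nv) sum_k omega_k (x_hat_k - x_k)^2

The weights omega emphasise the blocked channels early in training and decay
exponentially to a floor, so that DV estimation is prioritised first and the
overall reconstruction dominates later. Training follows the
curriculum/session/lesson schedule from :mod:`gatewave.gates`: within each
minibatch the gradient is accumulated over every lesson's mask and applied
as a single optimiser step, so the model learns all its sessions
simultaneously and every (sample, lesson) pair is visited once per epoch.

Gradients and the Adam optimiser are implemented directly in numpy; the
analytic gradients are validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .gates import CurriculumConfig, GateMask, lessons_per_session
from .io import SegmentSet, normalize_segments
from .montage import ElectrodeMontage, build_montage

__all__ = [
    "WGLAE",
    "WeightSchedule",
    "TrainConfig",
    "TrainingDivergence",
    "gate_input",
    "forward",
    "weighted_loss",
    "weights_at_epoch",
    "train",
    "reconstruct",
]


class TrainingDivergence(RuntimeError):
    """Raised when the loss or activations become non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class WeightSchedule:
    """Exponential decay of the DV error weight toward a floor.

    DV channels start at ``dv_weight_initial`` and decay with time constant
    ``decay_time_constant`` (epochs) toward ``floor_weight``; IDV channels
    keep the fixed ``idv_weight``.
    """

    dv_weight_initial: float = 2.0
    idv_weight: float = 1.0
    decay_time_constant: float = 100.0
    floor_weight: float = 1.0

    def __post_init__(self) -> None:
        if min(self.dv_weight_initial, self.idv_weight,
               self.decay_time_constant, self.floor_weight) <= 0:
            raise ValueError("all schedule parameters must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the full-scale study
    configuration: Adam, lr 1e-5, 10000 epochs, batch 1024)."""

    learning_rate: float = 1e-5
    epochs: int = 10000
    batch_size: int = 1024
    optimiser: str = "adam"
    validation_fraction: float = 0.2
    weight_seed: int = 0
    shuffle_seed: int = 0
    early_keep_best: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# functional core


def gate_input(x: np.ndarray, mask: GateMask) -> np.ndarray:
    """Apply the binary gate channel-wise: DV channels are zeroed.

    ``x`` has a channel axis of length ``len(mask.labels)``: either
    (..., channels) or (..., channels, samples).
    """
    x = np.asarray(x, dtype=np.float64)
    theta = mask.theta.astype(np.float64)
    if x.ndim >= 2 and x.shape[-2] == len(mask.labels):
        return x * theta[..., :, None]
    if x.shape[-1] == len(mask.labels):
        return x * theta
    raise ValueError(
        f"input channel axis does not match mask ({len(mask.labels)} channels)"
    )


def _forward_flat(x_flat: np.ndarray, W_ih, b_h, W_ho, b_o):
    h = expit(x_flat @ W_ih + b_h)
    y = expit(h @ W_ho + b_o)
    return h, y


def forward(model: "WGLAE", gated_x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass of a fitted model on flattened gated input."""
    gated_x = np.atleast_2d(np.asarray(gated_x, dtype=np.float64))
    if gated_x.shape[1] != model.n_features_in_:
        raise ValueError(
            f"input width {gated_x.shape[1]} != model width {model.n_features_in_}"
        )
    _, y = _forward_flat(gated_x, model.W_ih_, model.b_h_, model.W_ho_, model.b_o_)
    return y


def weighted_loss(x: np.ndarray, x_hat: np.ndarray, omega: np.ndarray) -> float:
    """(1/Nv) sum_k omega_k (x_hat_k - x_k)^2, averaged over rows if batched."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=np.float64))
    omega = np.asarray(omega, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have equal shapes")
    if omega.shape[-1] != x.shape[-1]:
        raise ValueError("omega width must match feature width")
    if (omega < 0).any():
        raise ValueError("omega must be non-negative")
    per_row = (omega * (x_hat - x) ** 2).sum(axis=-1) / x.shape[-1]
    return float(per_row.mean())


def weights_at_epoch(schedule: WeightSchedule, mask: GateMask, epoch: int) -> np.ndarray:
    """Per-channel error weights at a given epoch under the decay schedule."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    dv_w = schedule.floor_weight + (
        schedule.dv_weight_initial - schedule.floor_weight
    ) * np.exp(-epoch / schedule.decay_time_constant)
    return np.where(mask.theta == 0, dv_w, schedule.idv_weight).astype(np.float64)


def _loss_and_grads(params, x, x_gated, omega):
    """Weighted loss and analytic gradients for one minibatch.

    ``params`` = (W_ih, b_h, W_ho, b_o); ``omega`` is a per-feature weight
    row. The loss matches :func:`weighted_loss` of the forward output against
    the ungated ``x``.
    """
    W_ih, b_h, W_ho, b_o = params
    h, y = _forward_flat(x_gated, W_ih, b_h, W_ho, b_o)
    n, nf = x.shape
    diff = y - x
    loss = float((omega * diff ** 2).sum() / (nf * n))
    d = (2.0 / (nf * n)) * omega * diff
    dz2 = d * y * (1.0 - y)
    gW_ho = h.T @ dz2
    gb_o = dz2.sum(axis=0)
    dh = dz2 @ W_ho.T
    dz1 = dh * h * (1.0 - h)
    gW_ih = x_gated.T @ dz1
    gb_h = dz1.sum(axis=0)
    return loss, (gW_ih, gb_h, gW_ho, gb_o)


class _Adam:
    """Plain Adam with bias correction."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


# ---------------------------------------------------------------------------
# estimator


class WGLAE(BaseEstimator, TransformerMixin):
    """Weighted gate layer autoencoder for missing-channel EEG reconstruction.

    Parameters
    ----------
    montage : str or ElectrodeMontage, default="10-20-19ch"
        Electrode layout; gate sequences are derived from its geometry.
    mechanism : {"order", "partition", "hemisphere_rotation", "random", None}
        Gate control mechanism. ``None`` disables gating and weighting
        entirely, reducing the model to a plain under-complete autoencoder.
    n_dv : int, default=1
        Number of simultaneously blocked channels per lesson.
    hidden_width : int or None
        Hidden layer width; default ``floor(n_features / 2)`` of the
        flattened (channels x samples) input.
    learning_rate, epochs, batch_size :
        Adam settings. Defaults follow the full-scale study configuration
        (1e-5, 10000, 1024); reduced-scale runs should lower ``epochs`` and
        raise ``learning_rate`` accordingly.
    validation_fraction : float, default=0.2
        Seeded fraction of the fit data held out to track validation loss.
    dv_weight_initial, idv_weight, decay_time_constant, floor_weight :
        Error-weight schedule; ``decay_time_constant=None`` means
        ``epochs / 10``.
    early_keep_best : bool, default=True
        Keep the weights with minimal validation loss.
    normalize : bool, default=True
        Per-channel min-max scale the training data to [0, 1] and store the
        statistics for inference. When False the input must already be in
        [0, 1].
    use_bias : bool, default=True
        Include per-layer bias offsets.
    lesson_update : {"aggregate", "interleave"}, default="aggregate"
        How lessons enter each optimiser step. ``aggregate`` accumulates the
        gradient over every lesson per minibatch (stationary objective,
        order-invariant — the recommended default); ``interleave`` takes one
        sequential step per lesson in the gate sequence's order, so the
        ordering of the gate control mechanism influences the dynamics (used
        when the ordering itself is the experimental variable).
    gate_seed, data_seed :
        Seeds for the random gate permutation and the per-epoch sample order.
    random_state :
        Seed for weight initialisation (and defaults for the other seeds).

    Attributes
    ----------
    W_ih_, b_h_, W_ho_, b_o_ : ndarray
        Fitted weights (input->hidden, hidden->output).
    loss_curve_, val_loss_curve_ : ndarray
        Per-epoch weighted training loss and masked validation MSE.
    labels_ : tuple of str
        Channel order the model was fitted with.
    norm_lo_, norm_hi_ : ndarray
        Per-channel normalisation statistics.
    """

    def __init__(
        self,
        montage="10-20-19ch",
        mechanism: str | None = "partition",
        n_dv: int = 1,
        hidden_width: int | None = None,
        learning_rate: float = 1e-5,
        epochs: int = 10000,
        batch_size: int = 1024,
        validation_fraction: float = 0.2,
        dv_weight_initial: float = 2.0,
        idv_weight: float = 1.0,
        decay_time_constant: float | None = None,
        floor_weight: float = 1.0,
        early_keep_best: bool = True,
        normalize: bool = True,
        use_bias: bool = True,
        lesson_update: str = "aggregate",
        gate_seed: int | None = None,
        data_seed: int | None = None,
        random_state: int | None = None,
    ):
        self.montage = montage
        self.mechanism = mechanism
        self.n_dv = n_dv
        self.hidden_width = hidden_width
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.dv_weight_initial = dv_weight_initial
        self.idv_weight = idv_weight
        self.decay_time_constant = decay_time_constant
        self.floor_weight = floor_weight
        self.early_keep_best = early_keep_best
        self.normalize = normalize
        self.use_bias = use_bias
        self.lesson_update = lesson_update
        self.gate_seed = gate_seed
        self.data_seed = data_seed
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _resolve_montage(self) -> ElectrodeMontage:
        if isinstance(self.montage, ElectrodeMontage):
            return self.montage
        return build_montage(self.montage)

    def _as_array(self, X) -> tuple[np.ndarray, tuple[str, ...], float | None]:
        """Coerce input to (n, C, T) in the montage channel order."""
        if isinstance(X, SegmentSet):
            data, labels, fs = X.data, X.labels, X.fs
        else:
            data = np.asarray(X, dtype=np.float64)
            labels, fs = None, None
        if data.ndim != 3:
            raise ValueError("expected segments shaped (n_segments, channels, samples)")
        mont = self._resolve_montage()
        if labels is not None:
            if set(labels) != set(mont.labels):
                raise ValueError(
                    f"SegmentSet channels {sorted(set(labels) ^ set(mont.labels))} "
                    "do not match the montage"
                )
            order = [labels.index(l) for l in mont.labels]
            data = data[:, order, :]
        elif data.shape[1] != len(mont):
            raise ValueError(
                f"array has {data.shape[1]} channels but montage has {len(mont)}"
            )
        return data, tuple(mont.labels), fs

    def _schedule(self) -> WeightSchedule:
        tau = self.decay_time_constant
        if tau is None:
            tau = max(self.epochs / 10.0, 1.0)
        return WeightSchedule(self.dv_weight_initial, self.idv_weight,
                              tau, self.floor_weight)

    def _expand(self, per_channel: np.ndarray) -> np.ndarray:
        """Repeat a per-channel vector across each channel's time samples."""
        return np.repeat(per_channel, self.n_samples_)

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        data, labels, _fs = self._as_array(X)
        n, C, T = data.shape
        mont = self._resolve_montage()
        self.labels_ = labels
        self.n_samples_ = T

        rng = np.random.default_rng(self.random_state)

        # validation split at segment granularity (seeded)
        n_val = int(np.floor(n * self.validation_fraction))
        perm = np.random.default_rng(
            self.random_state if self.random_state is not None else 0
        ).permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) < 1:
            raise ValueError("not enough segments to fit")

        if self.normalize:
            lo = data[tr_idx].min(axis=(0, 2))
            hi = data[tr_idx].max(axis=(0, 2))
            span = np.where(hi > lo, hi - lo, 1.0)
            data = np.clip((data - lo[None, :, None]) / span[None, :, None], 0.0, 1.0)
            self.norm_lo_, self.norm_hi_ = lo, hi
        else:
            if data.min() < -1e-6 or data.max() > 1 + 1e-6:
                raise ValueError(
                    "input must be normalised to [0, 1] (or pass normalize=True)"
                )
            self.norm_lo_ = np.zeros(C)
            self.norm_hi_ = np.ones(C)

        Xf = data.reshape(n, C * T)
        nf = C * T
        self.n_features_in_ = nf
        hidden = self.hidden_width if self.hidden_width is not None else nf // 2
        self.hidden_width_ = int(hidden)

        # curriculum masks (flattened per-feature gates)
        if self.mechanism is not None:
            data_seed = self.data_seed
            if data_seed is None:
                data_seed = self.random_state if self.random_state is not None else 0
            gate_seed = self.gate_seed
            if gate_seed is None and self.mechanism == "random":
                gate_seed = data_seed
            curriculum = CurriculumConfig(
                montage=mont, mechanism=self.mechanism, n_dv=self.n_dv,
                data_seed=int(data_seed), gate_seed=gate_seed,
            )
            masks = curriculum.masks()
            self.curriculum_ = curriculum
        else:
            full = GateMask(theta=np.ones(C, dtype=np.int8), dv_labels=(), labels=labels)
            masks, data_seed = [full], (self.data_seed or 0)
            self.curriculum_ = None
        self.masks_ = masks
        schedule = self._schedule()

        theta_f = [self._expand(m.theta.astype(np.float64)) for m in masks]
        L = len(masks)

        # Glorot-uniform initialisation
        lim1 = np.sqrt(6.0 / (nf + hidden))
        lim2 = np.sqrt(6.0 / (hidden + nf))
        params = [
            rng.uniform(-lim1, lim1, size=(nf, hidden)),
            np.zeros(hidden),
            rng.uniform(-lim2, lim2, size=(hidden, nf)),
            np.zeros(nf),
        ]
        adam = _Adam(params, lr=self.learning_rate)
        bias_free = not self.use_bias

        X_tr, X_val = Xf[tr_idx], Xf[val_idx]
        n_tr = len(tr_idx)
        bs = min(self.batch_size, n_tr)

        loss_curve = np.empty(self.epochs)
        val_curve = np.full(self.epochs, np.nan)
        best_val, best_params = np.inf, None

        for epoch in range(self.epochs):
            if self.mechanism is None:
                omega_f = [np.ones(nf)]
            else:
                omega_f = [self._expand(weights_at_epoch(schedule, m, epoch))
                           for m in masks]
            order = np.random.default_rng((int(data_seed), epoch)).permutation(n_tr)
            batches = [order[i:i + bs] for i in range(0, n_tr, bs)]
            losses = []
            for b, batch in enumerate(batches):
                xb = X_tr[batch]
                if self.lesson_update == "aggregate":
                    # one optimiser step per batch, gradients accumulated over
                    # all lessons: the model learns its sessions simultaneously
                    # and the objective stays stationary across steps
                    acc = None
                    for l in range(L):
                        loss, grads = _loss_and_grads(
                            params, xb, xb * theta_f[l], omega_f[l]
                        )
                        acc = (grads if acc is None
                               else tuple(a + g for a, g in zip(acc, grads)))
                        losses.append(loss)
                    acc = tuple(a / L for a in acc)
                    if bias_free:
                        acc = (acc[0], np.zeros_like(acc[1]),
                               acc[2], np.zeros_like(acc[3]))
                    params = adam.step(params, acc)
                elif self.lesson_update == "interleave":
                    # sequential per-lesson steps in the mechanism's order,
                    # rotated round-robin across batches; the lesson ORDER of
                    # the gate sequence matters in this mode
                    for j in range(L):
                        l = (b + j) % L
                        loss, grads = _loss_and_grads(
                            params, xb, xb * theta_f[l], omega_f[l]
                        )
                        if bias_free:
                            grads = (grads[0], np.zeros_like(grads[1]),
                                     grads[2], np.zeros_like(grads[3]))
                        params = adam.step(params, grads)
                        losses.append(loss)
                else:
                    raise ValueError(
                        f"unknown lesson_update {self.lesson_update!r}; "
                        "choose 'aggregate' or 'interleave'"
                    )
            loss_curve[epoch] = float(np.mean(losses))
            if not np.isfinite(loss_curve[epoch]):
                raise TrainingDivergence(epoch)
            if n_val:
                vloss = 0.0
                for tf in theta_f:
                    _, yv = _forward_flat(X_val * tf, *params)
                    vloss += float(((yv - X_val) ** 2).mean())
                val_curve[epoch] = vloss / L
                if self.early_keep_best and val_curve[epoch] < best_val:
                    best_val = val_curve[epoch]
                    best_params = [p.copy() for p in params]

        if self.early_keep_best and best_params is not None:
            params = best_params
        self.W_ih_, self.b_h_, self.W_ho_, self.b_o_ = params
        self.loss_curve_ = loss_curve
        self.val_loss_curve_ = val_curve
        return self

    # -- inference --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "W_ih_"):
            raise RuntimeError("model is not fitted")

    def normalize_input(self, X) -> np.ndarray:
        """Apply the stored per-channel normalisation; returns (n, C, T)."""
        self._check_fitted()
        data, _, _ = self._as_array(X)
        span = np.where(self.norm_hi_ > self.norm_lo_,
                        self.norm_hi_ - self.norm_lo_, 1.0)
        return np.clip(
            (data - self.norm_lo_[None, :, None]) / span[None, :, None], 0.0, 1.0
        )

    def reconstruct(
        self,
        X,
        missing: list[str] | None = None,
        mask: GateMask | None = None,
    ) -> np.ndarray:
        """Reconstruct segments with the given channels blocked.

        Blocked channels are zeroed on input; their reconstructed values are
        the model's imputation. Returns (n, C, T) on the normalised [0, 1]
        scale, in montage channel order.
        """
        self._check_fitted()
        if mask is not None and missing is not None:
            raise ValueError("give either missing labels or a mask, not both")
        if mask is None:
            dv = tuple(missing) if missing else ()
            unknown = [d for d in dv if d not in self.labels_]
            if unknown:
                raise ValueError(f"missing labels not in montage: {unknown}")
            theta = np.array([0 if l in dv else 1 for l in self.labels_], dtype=np.int8)
            mask = GateMask(theta=theta, dv_labels=dv, labels=self.labels_)
        data = self.normalize_input(X)
        n, C, T = data.shape
        gated = gate_input(data, mask)
        y = forward(self, gated.reshape(n, C * T))
        return y.reshape(n, C, T)

    def transform(self, X) -> np.ndarray:
        """Plain autoencoder reconstruction (no channels blocked)."""
        return self.reconstruct(X)

    def inverse_normalize(self, data: np.ndarray) -> np.ndarray:
        """Map [0, 1]-scale reconstructions back to the original signal scale."""
        self._check_fitted()
        span = np.where(self.norm_hi_ > self.norm_lo_,
                        self.norm_hi_ - self.norm_lo_, 1.0)
        return data * span[None, :, None] + self.norm_lo_[None, :, None]

    # -- persistence ------------------------------------------------------

    CHECKPOINT_SCHEMA = 1

    def save(self, path: str | Path) -> None:
        """Write a checkpoint archive (weights, normalisation, metadata)."""
        self._check_fitted()
        meta = {k: v for k, v in self.get_params().items()
                if not isinstance(v, ElectrodeMontage)}
        if isinstance(self.montage, ElectrodeMontage):
            mont = self.montage
            meta["montage"] = {
                "system_name": mont.system_name,
                "labels": list(mont.labels),
                "positions": {l: list(mont.positions[l]) for l in mont.labels},
                "lobes": dict(mont.lobes),
                "hemispheres": dict(mont.hemispheres),
            }
        np.savez_compressed(
            Path(path),
            schema_version=np.array(self.CHECKPOINT_SCHEMA),
            W_ih=self.W_ih_, b_h=self.b_h_, W_ho=self.W_ho_, b_o=self.b_o_,
            norm_lo=self.norm_lo_, norm_hi=self.norm_hi_,
            labels=np.array(self.labels_),
            n_samples=np.array(self.n_samples_),
            loss_curve=self.loss_curve_,
            val_loss_curve=self.val_loss_curve_,
            params=np.array(json.dumps(meta, default=str)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "WGLAE":
        with np.load(Path(path), allow_pickle=False) as z:
            if int(z["schema_version"]) != cls.CHECKPOINT_SCHEMA:
                raise IOError(f"unsupported checkpoint schema {int(z['schema_version'])}")
            meta = json.loads(str(z["params"]))
            for key in ("hidden_width", "decay_time_constant", "gate_seed",
                        "data_seed", "random_state"):
                if meta.get(key) == "None":
                    meta[key] = None
            for key in ("n_dv", "epochs", "batch_size"):
                if key in meta:
                    meta[key] = int(meta[key])
            if meta.get("mechanism") == "None":
                meta["mechanism"] = None
            if isinstance(meta.get("montage"), dict):
                d = meta["montage"]
                meta["montage"] = ElectrodeMontage(
                    system_name=d["system_name"],
                    labels=tuple(d["labels"]),
                    positions={l: tuple(p) for l, p in d["positions"].items()},
                    lobes=d["lobes"],
                    hemispheres=d["hemispheres"],
                )
            model = cls(**{k: v for k, v in meta.items() if k in cls().get_params()})
            model.W_ih_ = z["W_ih"]
            model.b_h_ = z["b_h"]
            model.W_ho_ = z["W_ho"]
            model.b_o_ = z["b_o"]
            model.norm_lo_ = z["norm_lo"]
            model.norm_hi_ = z["norm_hi"]
            model.labels_ = tuple(str(l) for l in z["labels"])
            model.n_samples_ = int(z["n_samples"])
            model.n_features_in_ = model.W_ih_.shape[0]
            model.hidden_width_ = model.W_ih_.shape[1]
            model.loss_curve_ = z["loss_curve"]
            model.val_loss_curve_ = z["val_loss_curve"]
        return model


def train(
    segments: SegmentSet,
    curriculum: CurriculumConfig,
    config: TrainConfig = TrainConfig(),
    schedule: WeightSchedule | None = None,
) -> WGLAE:
    """Fit a WGLAE from explicit curriculum/train configurations."""
    sched = schedule or WeightSchedule(
        decay_time_constant=max(config.epochs / 10.0, 1.0)
    )
    model = WGLAE(
        montage=curriculum.montage,
        mechanism=curriculum.mechanism,
        n_dv=curriculum.n_dv,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        validation_fraction=config.validation_fraction,
        dv_weight_initial=sched.dv_weight_initial,
        idv_weight=sched.idv_weight,
        decay_time_constant=sched.decay_time_constant,
        floor_weight=sched.floor_weight,
        early_keep_best=config.early_keep_best,
        gate_seed=curriculum.gate_seed,
        data_seed=curriculum.data_seed,
        random_state=config.weight_seed,
    )
    return model.fit(segments)


def reconstruct(model: WGLAE, segments, mask: GateMask) -> np.ndarray:
    """Functional alias of :meth:`WGLAE.reconstruct` with an explicit mask."""
    return model.reconstruct(segments, mask=mask)
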