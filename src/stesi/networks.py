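"""Learned inverse operators: wide 1D-CNN, bi-LSTM, and a deepSIF-style
spatio-temporal network, trained with a cosine-similarity loss.

All three map an EEG window (Ne x T) to a source estimate (Ns x T):

* ``cnn1d`` - one temporal convolution bank whose kernel spans all
  electrodes and 5 time steps (same-padded), ReLU, then a dense map to the
  sources applied per time step.
* ``lstm`` - two bidirectional LSTM layers (hidden 85 per direction,
  dropout between layers), ReLU, dense 2*hidden -> Ns per time step.
* ``deepsif`` - a spatial module of two residual fully-connected blocks
  with ELU activations (the second lifts the electrode dimension to a
  500-wide feature space, with a dense skip path), a dense 500 -> 500,
  then a temporal module of three stacked LSTMs whose hidden state is the
  source dimension.

Because the cosine loss scores only the shape of the source pattern at
each instant, amplitudes are restored after inference by global-field-
power (GFP) rescaling: each time column is scaled so its re-projection
through the leadfield matches the measured EEG's spatial standard
deviation.  Training pairs are normalized by the EEG max-abs, which
preserves the linear forward relation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, clip_global_norm, concat
from .inverse import InverseSolution

__all__ = ["ArchitectureSpec", "TrainConfig", "NormalizedPair",
           "normalize_pair", "cosine_loss", "gfp_rescale", "build_model",
           "train", "predict"]

from dataclasses import dataclass, field


@dataclass
class ArchitectureSpec:
    kind: str                       # "cnn1d" | "lstm" | "deepsif"
    n_electrodes: int
    n_sources: int
    cnn_filters: int = 2048
    cnn_kernel_t: int = 5
    lstm_hidden: int = 85
    lstm_layers: int = 2
    lstm_dropout: float = 0.2
    deepsif_feature_dim: int = 500

    def __post_init__(self):
        if self.kind not in ("cnn1d", "lstm", "deepsif"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if min(self.n_electrodes, self.n_sources, self.cnn_filters,
               self.cnn_kernel_t, self.lstm_hidden, self.deepsif_feature_dim) <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.lstm_dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class TrainConfig:
    batch_size: int = 8
    max_epochs: int = 500
    early_stop_patience: int = 20
    learning_rate: float = 1e-3
    grad_clip_norm: float = 1.0     # applied when the model kind is lstm
    rng_seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class NormalizedPair:
    X_tilde: np.ndarray
    Y_tilde: np.ndarray
    alpha: float                    # V


def normalize_pair(X: np.ndarray, Y: np.ndarray) -> NormalizedPair:
    """Divide both members of a pair by alpha = max|Y|."""
    alpha = float(np.max(np.abs(Y)))
    if alpha == 0:
        raise ValueError("cannot normalize an all-zero EEG matrix")
    return NormalizedPair(X_tilde=X / alpha, Y_tilde=Y / alpha, alpha=alpha)


def cosine_loss(X: np.ndarray, X_hat: np.ndarray,
                return_guarded: bool = False):
    """Negative mean per-column cosine similarity, in [-1, 1].

    Columns where either argument has zero norm contribute 0 (guarded);
    the number of guarded columns is available via ``return_guarded``.
    """
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError("shape mismatch")
    num = np.sum(X * X_hat, axis=0)
    na = np.linalg.norm(X, axis=0)
    nb = np.linalg.norm(X_hat, axis=0)
    ok = (na > 0) & (nb > 0)
    cos = np.zeros(X.shape[1])
    cos[ok] = num[ok] / (na[ok] * nb[ok])
    loss = -float(np.mean(cos))
    if return_guarded:
        return loss, int(np.sum(~ok))
    return loss


def gfp_rescale(X_hat_tilde: np.ndarray, Y: np.ndarray, L: np.ndarray):
    """Restore amplitudes by matching per-instant global field power.

    Each column is scaled by std(Y[:, t]) / std((L X)[:, t]) (std over
    electrodes).  Columns whose re-projection has zero variance keep scale
    1 and are flagged.  Returns (X_hat, flagged_columns).
    """
    Y_proj = L @ X_hat_tilde
    s_y = Y.std(axis=0)
    s_p = Y_proj.std(axis=0)
    flagged = np.flatnonzero(s_p == 0).tolist()
    scale = np.ones_like(s_p)
    ok = s_p > 0
    scale[ok] = s_y[ok] / s_p[ok]
    return X_hat_tilde * scale[None, :], flagged


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out, shape, dtype=np.float64):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class _Dense:
    def __init__(self, rng, n_in, n_out, dtype=np.float64):
        self.W = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out), dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:  # x (..., n_in)
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class _LSTMLayer:
    """Single-direction LSTM; gates in i, f, g, o order, forget bias 1."""

    def __init__(self, rng, n_in, hidden, dtype=np.float64):
        self.h = hidden
        self.dtype = dtype
        self.Wx = Tensor(_glorot(rng, n_in, hidden, (n_in, 4 * hidden), dtype),
                         requires_grad=True)
        self.Wh = Tensor(_glorot(rng, hidden, hidden, (hidden, 4 * hidden), dtype),
                         requires_grad=True)
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden:2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def run(self, xs, reverse=False):
        """xs: list of (B, n_in) tensors; returns list of (B, h) tensors."""
        B = xs[0].shape[0]
        h = Tensor(np.zeros((B, self.h), dtype=self.dtype))
        c = Tensor(np.zeros((B, self.h), dtype=self.dtype))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out = [None] * len(xs)
        H = self.h
        for t in order:
            z = xs[t] @ self.Wx + h @ self.Wh + self.b
            i = z[:, 0:H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            out[t] = h
        return out

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]


class _BiLSTMLayer:
    def __init__(self, rng, n_in, hidden, dtype=np.float64):
        self.fwd = _LSTMLayer(rng, n_in, hidden, dtype)
        self.bwd = _LSTMLayer(rng, n_in, hidden, dtype)

    def run(self, xs):
        hf = self.fwd.run(xs)
        hb = self.bwd.run(xs, reverse=True)
        return [concat([a, b], axis=1) for a, b in zip(hf, hb)]

    @property
    def params(self):
        return self.fwd.params + self.bwd.params


class Model:
    """A learnable Ne x T -> Ns x T inverse operator."""

    def __init__(self, spec: ArchitectureSpec, rng_seed: int = 0,
                 dtype=np.float64):
        self.spec = spec
        self.dtype = np.dtype(dtype).type
        self.rng = np.random.default_rng(rng_seed)
        self.training = False
        self._build(self.rng)

    # construction ------------------------------------------------------
    def _build(self, rng):
        s = self.spec
        dt = self.dtype
        if s.kind == "cnn1d":
            # kernel spans all electrodes x cnn_kernel_t steps
            self.conv_W = Tensor(
                _glorot(rng, s.n_electrodes * s.cnn_kernel_t, s.cnn_filters,
                        (s.n_electrodes * s.cnn_kernel_t, s.cnn_filters), dt),
                requires_grad=True)
            self.conv_b = Tensor(np.zeros(s.cnn_filters, dtype=dt),
                                 requires_grad=True)
            self.head = _Dense(rng, s.cnn_filters, s.n_sources, dt)
            self._params = [self.conv_W, self.conv_b] + self.head.params
        elif s.kind == "lstm":
            self.layers = []
            n_in = s.n_electrodes
            for _ in range(s.lstm_layers):
                self.layers.append(_BiLSTMLayer(rng, n_in, s.lstm_hidden, dt))
                n_in = 2 * s.lstm_hidden
            self.head = _Dense(rng, 2 * s.lstm_hidden, s.n_sources, dt)
            self._params = sum((l.params for l in self.layers), []) + self.head.params
        else:  # deepsif
            ne, fd, ns = s.n_electrodes, s.deepsif_feature_dim, s.n_sources
            self.b1a = _Dense(rng, ne, ne, dt)
            self.b1b = _Dense(rng, ne, ne, dt)
            self.b2a = _Dense(rng, ne, fd, dt)
            self.b2b = _Dense(rng, fd, fd, dt)
            self.b2skip = _Dense(rng, ne, fd, dt)
            self.mid = _Dense(rng, fd, fd, dt)
            self.tlayers = [_LSTMLayer(rng, fd, ns, dt),
                            _LSTMLayer(rng, ns, ns, dt),
                            _LSTMLayer(rng, ns, ns, dt)]
            self._params = (self.b1a.params + self.b1b.params + self.b2a.params
                            + self.b2b.params + self.b2skip.params + self.mid.params
                            + sum((l.params for l in self.tlayers), []))

    @property
    def params(self):
        return self._params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def layer_summary(self) -> list:
        return [f"{self.spec.kind}: {self.n_parameters()} parameters",
                f"Ne={self.spec.n_electrodes} Ns={self.spec.n_sources}"]

    # state -------------------------------------------------------------
    def get_weights(self):
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p.data = w.copy()

    # forward -----------------------------------------------------------
    def forward(self, Y: np.ndarray | Tensor) -> Tensor:
        """Y: (B, Ne, T) -> (B, Ns, T)."""
        x = Y if isinstance(Y, Tensor) else Tensor(np.asarray(Y, dtype=self.dtype))
        s = self.spec
        if s.kind == "cnn1d":
            T = x.shape[-1]
            if T < s.cnn_kernel_t:
                raise ValueError("input shorter than the temporal kernel span")
            half = s.cnn_kernel_t // 2
            xp = x.pad_last(half, s.cnn_kernel_t - 1 - half)
            cols = xp.unfold_last(s.cnn_kernel_t)   # (B, Ne*k, T)
            B = cols.shape[0]
            flat = cols.transpose(0, 2, 1).reshape(B * T, -1)  # (B*T, Ne*k)
            h = (flat @ self.conv_W + self.conv_b).relu()      # (B*T, F)
            out = self.head(h)                                 # (B*T, Ns)
            return out.reshape(B, T, s.n_sources).transpose(0, 2, 1)
        if s.kind == "lstm":
            T = x.shape[-1]
            xs = [x[:, :, t] for t in range(T)]
            for li, layer in enumerate(self.layers):
                xs = layer.run(xs)
                if self.training and s.lstm_dropout > 0 and li < len(self.layers) - 1:
                    keep = 1.0 - s.lstm_dropout
                    xs = [h * Tensor((self.rng.binomial(1, keep, h.shape) / keep)
                                     .astype(self.dtype)) for h in xs]
            cols = [self.head(h.relu()).reshape(h.shape[0], s.n_sources, 1)
                    for h in xs]
            return concat(cols, axis=2)
        # deepsif
        T = x.shape[-1]
        h = x.transpose(0, 2, 1)                     # (B, T, Ne)
        r = self.b1b(self.b1a(h).elu())
        h = (r + h).elu()
        r = self.b2b(self.b2a(h).elu())
        h = (r + self.b2skip(h)).elu()               # (B, T, F)
        h = self.mid(h)
        xs = [h[:, t, :] for t in range(T)]
        for layer in self.tlayers:
            xs = layer.run(xs)
        cols = [c.reshape(c.shape[0], s.n_sources, 1) for c in xs]
        return concat(cols, axis=2)

    def predict_numpy(self, Y: np.ndarray) -> np.ndarray:
        """Inference on a single (Ne, T) window; returns (Ns, T)."""
        self.training = False
        return self.forward(Y[None]).data[0]


def build_model(spec: ArchitectureSpec, rng_seed: int = 0,
                dtype=np.float64) -> Model:
    """Instantiate a learnable inverse operator; logs its parameter count."""
    model = Model(spec, rng_seed=rng_seed, dtype=dtype)
    import logging
    logging.getLogger(__name__).info("built %s", "; ".join(model.layer_summary()))
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _cosine_loss_ad(pred: Tensor, target: np.ndarray) -> Tensor:
    """Autodiff cosine loss over a batch (B, Ns, T); guarded columns -> 0."""
    tgt = np.asarray(target, dtype=float)
    n_t = np.linalg.norm(tgt, axis=1)                       # (B, T)
    mask = (n_t > 0).astype(float)
    denom_t = np.where(n_t > 0, n_t, 1.0)
    num = (pred * Tensor(tgt)).sum(axis=1)                  # (B, T)
    n_p = ((pred * pred).sum(axis=1) + 1e-24).sqrt()
    cos = num / (n_p * Tensor(denom_t)) * Tensor(mask)
    return -cos.mean()


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def train(model: Model, dataset, cfg: TrainConfig):
    """Fit the model by minimizing the cosine loss on normalized pairs.

    ``dataset`` is a Dataset (train/validation split by index).  Each pair
    is normalized by its own EEG max-abs.  Early stopping restores the
    best validation weights after ``early_stop_patience`` epochs without
    improvement; LSTM-kind models use global-norm gradient clipping.
    Returns (model, history dict).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    pairs_tr = [normalize_pair(s.X, s.Y) for s in dataset.train]
    pairs_va = [normalize_pair(s.X, s.Y) for s in dataset.validation]
    if not pairs_tr or not pairs_va:
        raise ValueError("dataset must contain both train and validation samples")
    dt = model.dtype
    Xtr = np.stack([p.X_tilde for p in pairs_tr]).astype(dt)
    Ytr = np.stack([p.Y_tilde for p in pairs_tr]).astype(dt)
    Xva = np.stack([p.X_tilde for p in pairs_va]).astype(dt)
    Yva = np.stack([p.Y_tilde for p in pairs_va]).astype(dt)

    opt = Adam(model.params, lr=cfg.learning_rate)
    clip = model.spec.kind in ("lstm", "deepsif")
    history = {"train_loss": [], "val_loss": []}
    best = np.inf
    best_weights = model.get_weights()
    stale = 0
    for epoch in range(cfg.max_epochs):
        model.training = True
        losses = []
        for bidx in _batches(len(Xtr), cfg.batch_size, rng):
            opt.zero_grad()
            pred = model.forward(Ytr[bidx])
            loss = _cosine_loss_ad(pred, Xtr[bidx])
            if not np.isfinite(loss.item()):
                model.set_weights(best_weights)
                raise FloatingPointError("training diverged (non-finite loss)")
            loss.backward()
            if clip:
                clip_global_norm(model.params, cfg.grad_clip_norm)
            opt.step()
            losses.append(loss.item())
        model.training = False
        val_losses = []
        for i in range(0, len(Xva), max(cfg.batch_size, 16)):
            pred = model.forward(Yva[i:i + max(cfg.batch_size, 16)])
            val_losses.append(
                _cosine_loss_ad(pred, Xva[i:i + max(cfg.batch_size, 16)]).item())
        tr_loss = float(np.mean(losses))
        va_loss = float(np.mean(val_losses))
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        if cfg.verbose:
            print(f"epoch {epoch:3d}  train {tr_loss:+.4f}  val {va_loss:+.4f}")
        if va_loss < best - 1e-9:
            best = va_loss
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    history["best_val_loss"] = best
    history["epochs_run"] = len(history["train_loss"])
    return model, history


def predict(model: Model, Y: np.ndarray, L: np.ndarray) -> InverseSolution:
    """Normalize, apply the network, and GFP-rescale back to input units."""
    alpha = float(np.max(np.abs(Y)))
    if alpha == 0:
        return InverseSolution(X_hat=np.zeros((model.spec.n_sources, Y.shape[1])),
                               method=model.spec.kind,
                               config={"degenerate": "all-zero input"})
    X_tilde = model.predict_numpy(Y / alpha)
    X_hat, flagged = gfp_rescale(X_tilde, Y, L)
    return InverseSolution(X_hat=X_hat, method=model.spec.kind,
                           config={"alpha": alpha},
                           flagged_sources=flagged)
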