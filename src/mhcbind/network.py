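"""The peptide-MHC binding network and its building blocks.

Architecture (single pair input -> scalar output):

* a 2D-CNN branch reads the concatenated peptide+pseudo-sequence one-hot
  matrix as a 1-channel image, followed by a convolutional block
  attention module (CBAM: channel attention, then spatial attention);
* a 1D-CNN-BiLSTM branch reads the same matrix as a sequence of residue
  vectors, extracting local patterns (1D convolution) and long-range
  order (bidirectional LSTM, last hidden states of both directions);
* a BLOSUM62 skip branch flattens the substitution-score encoding of
  the peptide through one dense layer;
* the branch outputs are concatenated and reduced by an MLP head to one
  value: a raw score for regression on log-affinity targets, or a logit
  (sigmoid on predict) for binder classification.

Each branch can be ablated independently (``use_cbam``,
``use_1dcnn_bilstm``, ``use_blosum``); the 2D-CNN trunk is always on.

The module-level functions (:func:`conv1d_forward`, :func:`lstm_step`,
:func:`cbam_apply`, ...) are plain-NumPy single-instance references for
the same arithmetic the batched training graph performs; the test suite
holds both against scalar oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from ._autodiff import Tensor
from .encoding import encode_dataset


# =====================================================================
# reference ops (single instance, plain NumPy)
# =====================================================================

def _apply_activation(y, activation):
    return y if activation is None else activation(y)


def conv1d_forward(X, W, b=0.0, activation=None):
    """Valid 1D convolution: y_i = act(sum_j W_j . X_{i+j} + b).

    ``X`` may be a 1D signal ``(L,)`` or channelled ``(L, C)``; ``W`` a
    single kernel of matching shape ``(m,)`` / ``(m, C)``.
    """
    X = np.asarray(X, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    m = W.shape[0]
    if m > X.shape[0]:
        raise ValueError(f"kernel size {m} exceeds input length {X.shape[0]}")
    Lo = X.shape[0] - m + 1
    windows = np.stack([X[i : i + m] for i in range(Lo)])  # (Lo, m[, C])
    y = np.tensordot(windows, W, axes=W.ndim) + b
    return _apply_activation(y, activation)


def conv2d_forward(x, w, b=0.0, activation=None):
    """Valid 2D convolution: y_ij = act(sum_kl w_kl x_{i+k,j+l} + b)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    K, L = w.shape
    H, W_ = x.shape
    if K > H or L > W_:
        raise ValueError(f"kernel {K}x{L} exceeds input {H}x{W_}")
    Ho, Wo = H - K + 1, W_ - L + 1
    y = np.empty((Ho, Wo), dtype=np.float64)
    for i in range(Ho):
        for j in range(Wo):
            y[i, j] = np.sum(w * x[i : i + K, j : j + L]) + b
    return _apply_activation(y, activation)


@dataclass
class LSTMCellParams:
    """Gate weights acting on the concatenation [h_{t-1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray


@dataclass
class LSTMState:
    f_t: np.ndarray
    i_t: np.ndarray
    o_t: np.ndarray
    c_tilde: np.ndarray
    C_t: np.ndarray
    h_t: np.ndarray


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_step(x_t, h_prev, C_prev, params: LSTMCellParams) -> LSTMState:
    """One LSTM cell update.

    f_t = sigmoid(W_f . [h_{t-1}, x_t] + b_f), analogously i_t / o_t;
    c~_t = tanh(W_c . [h, x] + b_c); C_t = f_t*C_{t-1} + i_t*c~_t;
    h_t = o_t * tanh(C_t).
    """
    hx = np.concatenate([np.asarray(h_prev, dtype=np.float64),
                         np.asarray(x_t, dtype=np.float64)])
    for name in ("W_f", "W_i", "W_o", "W_c"):
        W = getattr(params, name)
        if W.shape[1] != hx.shape[0]:
            raise ValueError(
                f"{name} expects input of size {W.shape[1]}, got {hx.shape[0]}"
            )
    f = _sigmoid(params.W_f @ hx + params.b_f)
    i = _sigmoid(params.W_i @ hx + params.b_i)
    o = _sigmoid(params.W_o @ hx + params.b_o)
    ct = np.tanh(params.W_c @ hx + params.b_c)
    C = f * np.asarray(C_prev, dtype=np.float64) + i * ct
    h = o * np.tanh(C)
    return LSTMState(f_t=f, i_t=i, o_t=o, c_tilde=ct, C_t=C, h_t=h)


@dataclass
class CBAMParams:
    """Shared channel-MLP weights and the spatial convolution kernel."""

    mlp_w1: np.ndarray  # (C, C//r)
    mlp_b1: np.ndarray
    mlp_w2: np.ndarray  # (C//r, C)
    mlp_b2: np.ndarray
    spatial_w: np.ndarray  # (2, ks, ks): [avg-map, max-map] channels
    spatial_b: float = 0.0


def _channel_mlp(s, p: CBAMParams):
    return np.maximum(s @ p.mlp_w1 + p.mlp_b1, 0.0) @ p.mlp_w2 + p.mlp_b2


def cbam_channel_attention(F, params: CBAMParams):
    """Channel weights Mc = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F))).

    Pooling is global over all spatial positions, per channel.
    F: (C, H, W) -> Mc: (C,), each entry in (0, 1).
    """
    F = np.asarray(F, dtype=np.float64)
    avg = F.mean(axis=(1, 2))
    mx = F.max(axis=(1, 2))
    return _sigmoid(_channel_mlp(avg, params) + _channel_mlp(mx, params))


def cbam_spatial_attention(F, params: CBAMParams):
    """Spatial weights Ms = sigmoid(Conv([AvgPool(F); MaxPool(F)])).

    Pooling is across the channel dimension; the two pooled maps are
    concatenated and convolved with one kernel, zero-padded so the
    output keeps the input's spatial shape.  F: (C, H, W) -> Ms: (H, W).
    """
    F = np.asarray(F, dtype=np.float64)
    pooled = np.stack([F.mean(axis=0), F.max(axis=0)])  # (2, H, W)
    _, ks, _ = params.spatial_w.shape
    pad = ks // 2
    padded = np.pad(pooled, ((0, 0), (pad, pad), (pad, pad)))
    H, W = F.shape[1], F.shape[2]
    out = np.empty((H, W), dtype=np.float64)
    for i in range(H):
        for j in range(W):
            out[i, j] = np.sum(params.spatial_w * padded[:, i : i + ks, j : j + ks])
    return _sigmoid(out + params.spatial_b)


def cbam_apply(F, params: CBAMParams):
    """Full CBAM: channel attention first, then spatial attention.

    F' = Mc(F) (x) F  (broadcast over channels);
    F'' = Ms(F') (x) F'  (broadcast over spatial positions).
    """
    F = np.asarray(F, dtype=np.float64)
    mc = cbam_channel_attention(F, params)
    f1 = mc[:, None, None] * F
    ms = cbam_spatial_attention(f1, params)
    return ms[None, :, :] * f1


# =====================================================================
# configuration
# =====================================================================

@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the published training recipe (AdamW, learning rate
    1e-4, cosine annealing with T_max=30, 30 epochs, batch 40000 for
    class I / 20000 for class II); layer sizes are desk-scale defaults
    and freely configurable.
    """

    task: str = "classification"  # or "regression"
    mhc_class: int = 1
    max_pep_len: int = 14  # 21 for class II
    use_cbam: bool = True
    use_1dcnn_bilstm: bool = True
    use_blosum: bool = True
    n_filters_1d: int = 64
    kernel_1d: int = 3
    n_filters_2d: int = 32
    kernel_2d: int = 3
    lstm_hidden: int = 64
    cbam_reduction: int = 8
    spatial_kernel: int = 7
    blosum_dense: int = 32
    mlp_hidden: tuple = (128,)
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    epochs: int = 30
    t_max: int = 30
    batch_size: int = 40000
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mhc_class == 2 and self.batch_size == 40000:
            self.batch_size = 20000
        self.mlp_hidden = tuple(self.mlp_hidden)
        for name in ("n_filters_1d", "n_filters_2d", "lstm_hidden",
                     "kernel_1d", "kernel_2d", "blosum_dense", "batch_size",
                     "epochs", "t_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def fusion_dim(config: ModelConfig, pseudo_len: int) -> int:
    """Length of the concatenated feature vector entering the MLP head.

    The 2D trunk output is 2x2 max-pooled (odd edges cropped) before
    CBAM and flattening.
    """
    H = config.max_pep_len + pseudo_len
    W = 21
    hp = (H - config.kernel_2d + 1) // 2
    wp = (W - config.kernel_2d + 1) // 2
    d = config.n_filters_2d * hp * wp
    if config.use_1dcnn_bilstm:
        d += 2 * config.lstm_hidden
    if config.use_blosum:
        d += config.blosum_dense
    return d


# =====================================================================
# estimator
# =====================================================================

def _as_pairs(X):
    """Normalise X to (peptides, alleles) lists.

    Accepts a DataFrame with peptide/allele columns, a 2-column array,
    or an iterable of (peptide, allele) tuples.
    """
    if hasattr(X, "columns"):
        return list(X["peptide"]), list(X["allele"])
    pairs = [tuple(row) for row in X]
    return [p for p, _ in pairs], [a for _, a in pairs]


class PanMHCNet(BaseEstimator):
    """CNN-BiLSTM-CBAM binding predictor, sklearn estimator interface.

    Parameters
    ----------
    config : ModelConfig
        Architecture and training hyper-parameters.
    pseudo_sequences : dict
        Mapping allele name -> fixed-length pseudo-sequence.

    After :meth:`fit`: ``params_`` (parameter arrays), ``fusion_dim_``,
    ``train_loss_history_``, ``val_loss_history_``, ``best_epoch_``.
    """

    def __init__(self, config: ModelConfig = None, pseudo_sequences: dict = None):
        self.config = config
        self.pseudo_sequences = pseudo_sequences

    # -- parameters ----------------------------------------------------
    def _pseudo_len(self) -> int:
        lens = {len(v) for v in self.pseudo_sequences.values()}
        if len(lens) != 1:
            raise ValueError("pseudo-sequences must share one length")
        return lens.pop()

    def _init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        pl = self._pseudo_len()

        def glorot(*shape):
            fan_in, fan_out = shape[0], shape[-1]
            lim = math.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        p = {}
        k2 = cfg.kernel_2d
        p["w2d"] = glorot(cfg.n_filters_2d, 1, k2, k2)
        p["b2d"] = zeros(cfg.n_filters_2d)
        if cfg.use_cbam:
            cr = max(cfg.n_filters_2d // cfg.cbam_reduction, 1)
            p["c_w1"] = glorot(cfg.n_filters_2d, cr)
            p["c_b1"] = zeros(cr)
            p["c_w2"] = glorot(cr, cfg.n_filters_2d)
            p["c_b2"] = zeros(cfg.n_filters_2d)
            ks = cfg.spatial_kernel
            p["s_w"] = glorot(1, 2, ks, ks)
            p["s_b"] = zeros(1)
        if cfg.use_1dcnn_bilstm:
            p["w1d"] = glorot(cfg.n_filters_1d, cfg.kernel_1d, 21)
            p["b1d"] = zeros(cfg.n_filters_1d)
            H = cfg.lstm_hidden
            for d in ("fw", "bw"):
                for g in ("f", "i", "o", "c"):
                    p[f"lstm_{d}_Wx{g}"] = glorot(cfg.n_filters_1d, H)
                    p[f"lstm_{d}_Wh{g}"] = glorot(H, H)
                    p[f"lstm_{d}_b{g}"] = zeros(H)
        if cfg.use_blosum:
            p["bl_w"] = glorot(cfg.max_pep_len * 20, cfg.blosum_dense)
            p["bl_b"] = zeros(cfg.blosum_dense)
        d_in = fusion_dim(cfg, pl)
        for li, h in enumerate(cfg.mlp_hidden):
            p[f"mlp_w{li}"] = glorot(d_in, h)
            p[f"mlp_b{li}"] = zeros(h)
            d_in = h
        p["out_w"] = glorot(d_in, 1)
        p["out_b"] = zeros(1)
        return p

    # -- forward -------------------------------------------------------
    def _lstm_direction(self, seq: Tensor, params: dict, direction: str) -> Tensor:
        cfg = self.config
        B, T, _ = seq.shape
        H = cfg.lstm_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = range(T) if direction == "fw" else range(T - 1, -1, -1)
        g = lambda name: params[f"lstm_{direction}_{name}"]
        for t in order:
            x = seq.index_step(t)
            f = (x @ g("Wxf") + h @ g("Whf") + g("bf")).sigmoid()
            i = (x @ g("Wxi") + h @ g("Whi") + g("bi")).sigmoid()
            o = (x @ g("Wxo") + h @ g("Who") + g("bo")).sigmoid()
            ct = (x @ g("Wxc") + h @ g("Whc") + g("bc")).tanh()
            c = f * c + i * ct
            h = o * c.tanh()
        return h

    def _cbam(self, feat: Tensor, params: dict) -> Tensor:
        B, C = feat.shape[0], feat.shape[1]
        avg = feat.mean(axis=(2, 3))
        mx = feat.amax(axis=(2, 3))

        def mlp(s):
            return (s @ params["c_w1"] + params["c_b1"]).relu() @ params["c_w2"] + params["c_b2"]

        mc = (mlp(avg) + mlp(mx)).sigmoid()
        f1 = feat * mc.reshape(B, C, 1, 1)
        s_avg = f1.mean(axis=1, keepdims=True)
        s_max = f1.amax(axis=1, keepdims=True)
        sp = ad.concat([s_avg, s_max], axis=1)
        pad = self.config.spatial_kernel // 2
        ms = ad.conv2d(ad.pad2d(sp, pad), params["s_w"], params["s_b"]).sigmoid()
        return f1 * ms

    def _forward(self, params: dict, onehot: np.ndarray, blosum: np.ndarray) -> Tensor:
        cfg = self.config
        B = onehot.shape[0]
        feat = ad.conv2d(Tensor(onehot[:, None, :, :]), params["w2d"], params["b2d"]).relu()
        feat = ad.maxpool2d(feat)
        if cfg.use_cbam:
            feat = self._cbam(feat, params)
        branches = [feat.reshape(B, -1)]
        if cfg.use_1dcnn_bilstm:
            seq = ad.conv1d(Tensor(onehot), params["w1d"], params["b1d"]).relu()
            hf = self._lstm_direction(seq, params, "fw")
            hb = self._lstm_direction(seq, params, "bw")
            branches.append(ad.concat([hf, hb], axis=1))
        if cfg.use_blosum:
            fb = (Tensor(blosum.reshape(B, -1)) @ params["bl_w"] + params["bl_b"]).relu()
            branches.append(fb)
        h = ad.concat(branches, axis=1) if len(branches) > 1 else branches[0]
        for li in range(len(cfg.mlp_hidden)):
            h = (h @ params[f"mlp_w{li}"] + params[f"mlp_b{li}"]).relu()
        out = h @ params["out_w"] + params["out_b"]
        return out.reshape(B)

    # -- training ------------------------------------------------------
    def _encode(self, X):
        peptides, alleles = _as_pairs(X)
        return encode_dataset(peptides, alleles, self.pseudo_sequences,
                              self.config.max_pep_len)

    def _loss(self, params, onehot, blosum, y, weights=None) -> Tensor:
        logits = self._forward(params, onehot, blosum)
        if self.config.task == "regression":
            return ad.mse_loss(logits, y)
        return ad.bce_with_logits(logits, y, weights)

    def fit(self, X, y, validation=None):
        """Train on (peptide, allele) pairs.

        ``y``: log-affinity scores (regression) or 0/1 labels
        (classification; per-class weights balance the loss).  If
        ``validation=(X_val, y_val)`` is given, the parameters with the
        lowest validation loss across epochs are kept, otherwise the
        final epoch's.
        """
        onehot, blosum = self._encode(X)
        encoded_val = None
        if validation is not None:
            Xv, yv = validation
            encoded_val = (self._encode(Xv), np.asarray(yv, dtype=np.float64))
        return self.fit_encoded(onehot, blosum, y, validation=encoded_val)

    def fit_encoded(self, onehot, blosum, y, validation=None):
        """Train from pre-encoded arrays (see :func:`encode_dataset`);
        ``validation`` is ``((onehot_v, blosum_v), y_v)``."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        y = np.asarray(y, dtype=np.float64)
        n = len(y)

        weights = None
        if cfg.task == "classification":
            n_pos = int(y.sum())
            n_neg = n - n_pos
            if n_pos == 0 or n_neg == 0:
                raise ValueError("classification needs both classes")
            w = {1: n / (2.0 * n_pos), 0: n / (2.0 * n_neg)}
            weights = np.where(y == 1, w[1], w[0])

        val = None
        if validation is not None:
            (v_onehot, v_blosum), yv = validation
            yv = np.asarray(yv, dtype=np.float64)
            v_weights = None
            if weights is not None:
                v_weights = np.where(yv == 1,
                                     n / (2.0 * max(y.sum(), 1)),
                                     n / (2.0 * max(n - y.sum(), 1)))
            val = (v_onehot, v_blosum, yv, v_weights)

        params = self._init_params(rng)
        mstate = {k: np.zeros_like(p.data) for k, p in params.items()}
        vstate = {k: np.zeros_like(p.data) for k, p in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.train_loss_history_ = []
        self.val_loss_history_ = []
        best_val = np.inf
        best_params = None
        self.best_epoch_ = None

        for epoch in range(cfg.epochs):
            lr = 0.5 * cfg.learning_rate * (
                1.0 + math.cos(math.pi * min(epoch, cfg.t_max) / cfg.t_max)
            )
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                loss = self._loss(params, onehot[idx], blosum[idx], y[idx],
                                  None if weights is None else weights[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch offset {lo}: "
                        f"{float(loss.data)!r}"
                    )
                loss.backward()
                step += 1
                for k, p in params.items():
                    g = p.grad
                    mstate[k] = beta1 * mstate[k] + (1 - beta1) * g
                    vstate[k] = beta2 * vstate[k] + (1 - beta2) * g * g
                    mhat = mstate[k] / (1 - beta1 ** step)
                    vhat = vstate[k] / (1 - beta2 ** step)
                    p.data -= lr * (mhat / (np.sqrt(vhat) + eps)
                                    + cfg.weight_decay * p.data)
                epoch_loss += float(loss.data) * len(idx)
            self.train_loss_history_.append(epoch_loss / n)

            if val is not None:
                vl = self._eval_loss(params, *val)
                self.val_loss_history_.append(vl)
                if vl < best_val:
                    best_val = vl
                    best_params = {k: p.data.copy() for k, p in params.items()}
                    self.best_epoch_ = epoch

        if best_params is not None:
            for k, p in params.items():
                p.data = best_params[k]
        self.params_ = params
        self.fusion_dim_ = fusion_dim(cfg, self._pseudo_len())
        return self

    def _eval_loss(self, params, onehot, blosum, y, weights) -> float:
        const = {k: Tensor(p.data) for k, p in params.items()}
        total = 0.0
        n = len(y)
        for lo in range(0, n, 8192):
            hi = min(lo + 8192, n)
            loss = self._loss(const, onehot[lo:hi], blosum[lo:hi], y[lo:hi],
                              None if weights is None else weights[lo:hi])
            total += float(loss.data) * (hi - lo)
        return total / n

    # -- inference -----------------------------------------------------
    def _predict_encoded(self, onehot, blosum) -> np.ndarray:
        const = {k: Tensor(p.data) for k, p in self.params_.items()}
        outs = []
        for lo in range(0, onehot.shape[0], 8192):
            z = self._forward(const, onehot[lo : lo + 8192], blosum[lo : lo + 8192])
            outs.append(z.data)
        z = np.concatenate(outs)
        if self.config.task == "classification":
            return _sigmoid(z)
        return z

    def predict(self, X) -> np.ndarray:
        """Scores: binding probability in [0, 1] (classification) or
        log-affinity score (regression)."""
        onehot, blosum = self._encode(X)
        return self._predict_encoded(onehot, blosum)

    def predict_proba(self, X) -> np.ndarray:
        if self.config.task != "classification":
            raise ValueError("predict_proba requires the classification task")
        p = self.predict(X)
        return np.column_stack([1.0 - p, p])


def save_checkpoint(path, model: PanMHCNet) -> None:
    """Write parameters + config as a versioned .npz archive."""
    arrays = {f"param::{k}": p.data for k, p in model.params_.items()}
    import json

    arrays["meta"] = np.frombuffer(
        json.dumps({"format_version": 1, "config": model.config.to_dict()}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_checkpoint(path, pseudo_sequences: dict) -> PanMHCNet:
    import json

    with np.load(path) as arc:
        meta = json.loads(bytes(arc["meta"]).decode())
        model = PanMHCNet(ModelConfig.from_dict(meta["config"]), pseudo_sequences)
        model.params_ = {
            k[len("param::"):]: Tensor(arc[k], requires_grad=True)
            for k in arc.files if k.startswith("param::")
        }
    model.fusion_dim_ = fusion_dim(model.config, model._pseudo_len())
    return model
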