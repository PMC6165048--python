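"""The multi-timescale drowsiness temporal CNN.

The network maps a 1-min bilateral eyelid-distance sequence (1800 x 2 at
30 Hz) to four drowsiness probabilities, one per timescale (5/15/30/60 s).

Architecture
------------
* **Trunk** — two temporal convolutions (width ``W``, receptive field 15,
  stride 1, zero padding 7, ReLU then batch-norm), densely connected (the
  input of each is concatenated to its output), with one max-pooling layer
  (field 3, stride 3) in between.  At the printed width ``W = 32`` the two
  trunk outputs have depths 34 and 66, and the pooled sequence length is
  600 (an effective rate of 10 positions per second).
* **Branches** — four branches, one per timescale: a convolution (width
  ``W``, field 31, padding 15, ReLU then batch-norm, no skip), a global
  pooling, a dense head.  Branches 1-3 pool with *temporal
  sigmoid-weighted pooling*: normalized weights
  ``w_n \\propto sigmoid(slope * (n - 600 + 10 * n0 - 0.5))`` concentrate the
  mass on the most recent ``n0`` seconds (5, 15, 30 s) while decaying
  smoothly; branch 4 (60 s) uses a plain global average.  The half-sample
  offset places the cutoff between positions so the infinite-slope limit
  is exactly the mean of the last ``10 * n0`` positions.
* **Multi-timescale context** — the four head embeddings are concatenated,
  passed through a shared dense layer, and the result is concatenated back
  into every branch before its final 2-way softmax.  The ablation
  (``with_context=False``) removes the shared pathway and doubles the head
  width to keep the parameter count comparable.

Training follows the recipe the ground-truth design calls for: the loss is
the average of four binary relative entropies between the predicted and
ternary target probabilities, epochs are stratified (equal quotas from the
five 470 ms strata), inputs are centered by the training-set mean eyelid
distance, left/right channels are swapped with probability 0.5, and model
selection uses a class-weighted validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ground_truth import (
    STRATUM_THRESHOLD_MS,
    compute_validation_frequencies,
    validation_weights,
)
from .nn import Adam, BatchNorm1D, Conv1D, Dense, Dropout, MaxPool1D, Param, ReLU
from .session import PVTSession

__all__ = [
    "SequenceSample",
    "NetConfig",
    "TrainConfig",
    "DrowsinessNet",
    "sigmoid_pool_weights",
    "sigmoid_pool",
    "drowsiness_loss",
    "make_epoch",
    "augment_swap",
    "train_fold",
]

EPS_CLAMP = 1e-7


@dataclass
class SequenceSample:
    """A labeled 1-min sequence ending at ``t_end`` of one session.

    ``p`` holds the four target probabilities in {0, 0.5, 1} (NaN when the
    median RT is undefined); ``m`` the median RTs themselves, used for
    strata and validation weighting.  The 1800 x 2 matrix is extracted
    lazily from the session to keep sample pools light.
    """

    session: PVTSession
    t_end: float
    p: np.ndarray
    m: np.ndarray
    stratum: int | None

    @property
    def subject_id(self) -> str:
        return self.session.subject_id

    def matrix(self, seq_len: int = 1800) -> np.ndarray:
        i_end = int(round(self.t_end * self.session.fps))
        if i_end < seq_len or i_end > len(self.session.left_dist):
            raise ValueError(f"t_end={self.t_end} leaves no full {seq_len}-sample window")
        sl = slice(i_end - seq_len, i_end)
        return np.stack([self.session.left_dist[sl], self.session.right_dist[sl]], axis=1)


@dataclass
class NetConfig:
    """Architecture hyper-parameters (defaults are the printed values)."""

    width: int = 32  # conv depth of trunk and branch layers
    head_width: int = 16  # first dense layer and context layer depth
    trunk_kernel: int = 15
    branch_kernel: int = 31
    pool_stride: int = 3
    seq_len: int = 1800
    rate_after_pool: float = 10.0  # positions per second after the stride-3 pool
    pool_cutoffs_s: tuple[float, float, float] = (5.0, 15.0, 30.0)
    slope: float = 1.5  # sigmoid-pooling slope (per position)
    dropout: tuple[float, float, float] = (0.35, 0.7, 0.35)
    with_context: bool = True

    @property
    def pooled_len(self) -> int:
        return self.seq_len // self.pool_stride

    @property
    def trunk_depths(self) -> tuple[int, int]:
        return (2 + self.width, 2 + 2 * self.width)


@dataclass
class TrainConfig:
    """Optimization settings (Adam coefficients and LR as printed)."""

    learning_rate: float = 0.0016029
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    stratum_quota: int = 256
    swap_prob: float = 0.5
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    val_subsample: int | None = None  # cap on validation samples per epoch


def sigmoid_pool_weights(
    n0_s: float, slope: float, length: int = 600, rate: float = 10.0
) -> np.ndarray:
    """Normalized attention weights over sequence positions 1..length.

    ``w_n \\propto sigmoid(slope * (n - length + rate * n0 - 0.5))``; weights
    sum to one and are nondecreasing in ``n``, so the most recent ``n0``
    seconds dominate.  As ``slope -> inf`` this converges to the plain mean
    of the last ``rate * n0`` positions (the half-sample offset puts the
    cutoff between positions).
    """
    n = np.arange(1, length + 1, dtype=float)
    arg = slope * (n - length + rate * n0_s - 0.5)
    w = np.empty_like(arg)  # numerically stable sigmoid, branch by sign
    pos = arg >= 0
    w[pos] = 1.0 / (1.0 + np.exp(-arg[pos]))
    e = np.exp(arg[~pos])
    w[~pos] = e / (1.0 + e)
    return w / w.sum()


def sigmoid_pool(v: np.ndarray, n0_s: float, slope: float, rate: float = 10.0) -> np.ndarray:
    """Pool a (..., C, L) sequence into (..., C) with sigmoid attention weights."""
    v = np.asarray(v)
    if v.shape[-1] != 600:
        raise ValueError(f"expected pooled sequence length 600, got {v.shape[-1]}")
    w = sigmoid_pool_weights(n0_s, slope, length=v.shape[-1], rate=rate)
    return v @ w


def drowsiness_loss(
    p_hat: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Average of four binary relative entropies between p_hat and p.

    ``L = -(1/4) sum_i [ p_i ln(p̂_i/p_i) + (1-p_i) ln((1-p̂_i)/(1-p_i)) ]``
    with the convention ``0 ln(0/0) = 0``.  ``p_hat`` is clamped to
    ``[1e-7, 1 - 1e-7]``.  Optional ``weights`` (same shape) multiply each
    timescale term, which is how validation samples are class-balanced.
    Inputs are (4,) or (N, 4); the mean over samples is returned.
    """
    p_hat = np.clip(np.atleast_2d(np.asarray(p_hat, dtype=float)), EPS_CLAMP, 1.0 - EPS_CLAMP)
    p = np.atleast_2d(np.asarray(p, dtype=float))
    w = np.ones_like(p) if weights is None else np.atleast_2d(np.asarray(weights, dtype=float))
    term_pos = np.where(p > 0, p * np.log(p_hat / np.where(p > 0, p, 1.0)), 0.0)
    q = 1.0 - p
    term_neg = np.where(q > 0, q * np.log((1.0 - p_hat) / np.where(q > 0, q, 1.0)), 0.0)
    per_sample = -(w * (term_pos + term_neg)).sum(axis=1) / 4.0
    return float(per_sample.mean())


def augment_swap(x: np.ndarray) -> np.ndarray:
    """Exchange the left and right eyelid-distance columns."""
    return x[:, ::-1]


def make_epoch(
    pool: dict[int, list[int]], quota: int, rng: np.random.Generator
) -> np.ndarray:
    """One stratified training epoch: ``quota`` draws per stratum, shuffled.

    ``pool`` maps each stratum 0..4 to the indices of its samples; draws
    are with replacement within stratum.  Every stratum must be populated.
    """
    indices = []
    for stratum in range(5):
        members = pool.get(stratum, [])
        if not members:
            raise ValueError(
                f"training stratum {stratum} is empty; enlarge or diversify the cohort"
            )
        indices.append(rng.choice(members, size=quota, replace=True))
    epoch = np.concatenate(indices)
    rng.shuffle(epoch)
    return epoch


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DrowsinessNet:
    """Four-branch temporal CNN over 1-min eyelid-distance sequences."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = config or NetConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        w, h = cfg.width, cfg.head_width
        self.center = 0.0  # training-set mean eyelid distance, set by train_fold

        self.conv1 = Conv1D(2, w, cfg.trunk_kernel, rng)
        self.relu1, self.bn1 = ReLU(), BatchNorm1D(w)
        self.pool = MaxPool1D(cfg.pool_stride)
        self.conv2 = Conv1D(2 + w, w, cfg.trunk_kernel, rng)
        self.relu2, self.bn2 = ReLU(), BatchNorm1D(w)
        self.drop_trunk = Dropout(cfg.dropout[0], rng)

        head_in = h if cfg.with_context else 2 * h
        # the four branch convolutions share their input, so they are fused
        # into one convolution of depth 4W whose output is split per branch
        self.branches_conv = Conv1D(2 + 2 * w, 4 * w, cfg.branch_kernel, rng)
        self.branches_relu = ReLU()
        self.branch_bn = []
        self.branch_drop_pool, self.branch_fc1, self.branch_fc1_relu = [], [], []
        self.branch_drop_head, self.branch_fc2 = [], []
        self.pool_weights = []
        for i in range(4):
            self.branch_bn.append(BatchNorm1D(w))
            self.branch_drop_pool.append(Dropout(cfg.dropout[1], rng))
            self.branch_fc1.append(Dense(w, head_in, rng))
            self.branch_fc1_relu.append(ReLU())
            self.branch_drop_head.append(Dropout(cfg.dropout[2], rng))
            self.branch_fc2.append(Dense(2 * h, 2, rng))
            if i < 3:
                wv = sigmoid_pool_weights(
                    cfg.pool_cutoffs_s[i], cfg.slope, cfg.pooled_len, cfg.rate_after_pool
                )
            else:  # 60 s branch: global average pooling
                wv = np.full(cfg.pooled_len, 1.0 / cfg.pooled_len)
            self.pool_weights.append(wv.astype(np.float32))
        if cfg.with_context:
            self.context_fc = Dense(4 * h, h, rng)
            self.context_relu = ReLU()
        else:
            self.context_fc = None

        self._layers = [
            self.conv1, self.bn1, self.conv2, self.bn2, self.drop_trunk,
            self.branches_conv, *self.branch_bn, *self.branch_drop_pool,
            *self.branch_fc1, *self.branch_drop_head, *self.branch_fc2,
        ]
        if self.context_fc is not None:
            self._layers.append(self.context_fc)

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def train_mode(self, flag: bool) -> None:
        for layer in self._layers:
            layer.train_mode(flag)

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def context_parameter_count(self) -> int:
        """Parameters of the shared context pathway (0 without context)."""
        if self.context_fc is None:
            return 0
        return int(sum(p.value.size for p in self.context_fc.params()))

    def state_dict(self) -> dict:
        state = {f"param_{i}": p.value.copy() for i, p in enumerate(self.params())}
        for i, layer in enumerate(self._layers):
            if isinstance(layer, BatchNorm1D):
                state[f"bn_{i}_mean"] = layer.running_mean.copy()
                state[f"bn_{i}_var"] = layer.running_var.copy()
        state["center"] = np.array(self.center)
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, layer in enumerate(self._layers):
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = state[f"bn_{i}_mean"]
                layer.running_var[...] = state[f"bn_{i}_var"]
        self.center = float(state["center"])

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability of the drowsy class per timescale, shape (N, 4).

        ``x`` is (N, 1800, 2) in the column order (left, right), already
        centered by the caller (see :meth:`predict_proba` for the inference
        path that applies the stored centering constant).
        """
        cfg = self.config
        if x.ndim != 3 or x.shape[1] != cfg.seq_len or x.shape[2] != 2:
            raise ValueError(f"expected input (N, {cfg.seq_len}, 2), got {x.shape}")
        self.train_mode(train)
        xc = np.ascontiguousarray(x.transpose(0, 2, 1), dtype=np.float32)  # (N, 2, L)

        h1 = self.bn1.forward(self.relu1.forward(self.conv1.forward(xc)))
        out1 = np.concatenate([xc, h1], axis=1)  # densely connected: depth 2 + W
        pooled = self.pool.forward(out1)
        h2 = self.bn2.forward(self.relu2.forward(self.conv2.forward(pooled)))
        out2 = np.concatenate([pooled, h2], axis=1)  # depth 2 + 2W
        out2 = self.drop_trunk.forward(out2)
        self._cache_shapes = (out1.shape, h1.shape[1])

        hb_all = self.branches_relu.forward(self.branches_conv.forward(out2))
        w_ = self.config.width
        heads = []
        for i in range(4):
            hb = self.branch_bn[i].forward(hb_all[:, i * w_ : (i + 1) * w_, :])
            a = hb @ self.pool_weights[i]  # (N, W)
            a = self.branch_drop_pool[i].forward(a)
            heads.append(self.branch_fc1_relu[i].forward(self.branch_fc1[i].forward(a)))
        if self.context_fc is not None:
            ctx = self.context_relu.forward(self.context_fc.forward(np.concatenate(heads, axis=1)))
            zs = [np.concatenate([heads[i], ctx], axis=1) for i in range(4)]
        else:
            zs = heads
        self._head_width = heads[0].shape[1]
        logits = []
        for i in range(4):
            z = self.branch_drop_head[i].forward(zs[i])
            logits.append(self.branch_fc2[i].forward(z))
        self._probs = np.stack([_softmax(l) for l in logits], axis=1)  # (N, 4, 2)
        return self._probs[:, :, 1]

    def backward(self, p: np.ndarray, weights: np.ndarray | None = None) -> None:
        """Accumulate gradients of the (weighted) relative-entropy loss.

        Must follow a ``forward(..., train=True)`` call on the same batch.
        """
        n = self._probs.shape[0]
        w = np.ones((n, 4)) if weights is None else np.asarray(weights, dtype=float)
        dout2 = None
        dheads = [None] * 4
        dctx_sum = None
        for i in range(4):
            target = np.stack([1.0 - p[:, i], p[:, i]], axis=1)
            dlogits = (self._probs[:, i, :] - target) * w[:, i : i + 1] / (4.0 * n)
            dz = self.branch_drop_head[i].backward(self.branch_fc2[i].backward(dlogits.astype(np.float32)))
            if self.context_fc is not None:
                dheads[i] = dz[:, : self._head_width]
                dctx_sum = dz[:, self._head_width :] if dctx_sum is None else dctx_sum + dz[:, self._head_width :]
            else:
                dheads[i] = dz
        if self.context_fc is not None:
            dctx_in = self.context_fc.backward(self.context_relu.backward(dctx_sum))
            hwidth = self._head_width
            for i in range(4):
                dheads[i] = dheads[i] + dctx_in[:, i * hwidth : (i + 1) * hwidth]
        w_ = self.config.width
        dhb_all = np.empty((n, 4 * w_, self.config.pooled_len), dtype=np.float32)
        for i in range(4):
            da = self.branch_fc1[i].backward(self.branch_fc1_relu[i].backward(dheads[i]))
            da = self.branch_drop_pool[i].backward(da)
            dv = da[:, :, None] * self.pool_weights[i][None, None, :]
            dhb_all[:, i * w_ : (i + 1) * w_, :] = self.branch_bn[i].backward(dv)
        dout2 = self.branches_conv.backward(self.branches_relu.backward(dhb_all))
        dout2 = self.drop_trunk.backward(dout2)
        out1_shape, w_depth = self._cache_shapes
        dpooled = dout2[:, : 2 + self.config.width, :].copy()
        dh2 = dout2[:, 2 + self.config.width :, :]
        dpooled += self.conv2.backward(self.relu2.backward(self.bn2.backward(dh2)))
        dout1 = self.pool.backward(dpooled)
        dh1 = dout1[:, 2:, :]
        self.conv1.backward(self.relu1.backward(self.bn1.backward(dh1)))

    # -- inference --------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Centered, batched inference; returns drowsy probabilities (N, 4)."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size] - self.center, train=False))
        return np.concatenate(out, axis=0)


def _sample_weight_matrix(samples: list[SequenceSample], vw: np.ndarray) -> np.ndarray:
    """Per-sample per-timescale validation weights from the (4, 2) table."""
    m = np.stack([s.m for s in samples])
    side = (m >= STRATUM_THRESHOLD_MS).astype(int)
    return vw[np.arange(4)[None, :], side]


def train_fold(
    train_samples: list[SequenceSample],
    val_samples: list[SequenceSample],
    net_config: NetConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[DrowsinessNet, list[dict]]:
    """Train one cross-validation fold and return (model, history).

    The training pool must populate all five strata.  The model with the
    lowest class-weighted validation loss is returned; the input-centering
    constant (training-set mean eyelid distance) is stored on the model.
    Training and validation subject sets must be disjoint.
    """
    net_config = net_config or NetConfig()
    tc = train_config or TrainConfig()
    if {s.subject_id for s in train_samples} & {s.subject_id for s in val_samples}:
        raise ValueError("train and validation subject sets overlap")

    rng = np.random.default_rng(tc.seed)
    net = DrowsinessNet(net_config, seed=int(rng.integers(0, 2**31 - 1)))
    center = float(
        np.mean(
            [np.mean(s.session.left_dist) + np.mean(s.session.right_dist) for s in
             {id(s.session): s for s in train_samples}.values()]
        )
        / 2.0
    )
    net.center = center

    pool: dict[int, list[int]] = {}
    for idx, s in enumerate(train_samples):
        if s.stratum is not None:
            pool.setdefault(int(s.stratum), []).append(idx)

    vw = validation_weights(compute_validation_frequencies(np.stack([s.m for s in val_samples])))
    if tc.val_subsample is not None and len(val_samples) > tc.val_subsample:
        keep = np.random.default_rng(tc.seed + 1).choice(
            len(val_samples), size=tc.val_subsample, replace=False
        )
        val_samples = [val_samples[i] for i in keep]
    val_w = _sample_weight_matrix(val_samples, vw)
    val_p = np.stack([s.p for s in val_samples])
    val_x = np.stack([s.matrix(net_config.seq_len) for s in val_samples]).astype(np.float32)

    opt = Adam(net.params(), lr=tc.learning_rate, beta1=tc.beta1, beta2=tc.beta2)
    history: list[dict] = []
    best_loss, best_state, since_best = np.inf, None, 0
    for epoch in range(tc.max_epochs):
        order = make_epoch(pool, tc.stratum_quota, rng)
        train_losses = []
        for start in range(0, len(order), tc.batch_size):
            batch_idx = order[start : start + tc.batch_size]
            xs, ps = [], []
            for i in batch_idx:
                x = train_samples[i].matrix(net_config.seq_len)
                if rng.random() < tc.swap_prob:
                    x = augment_swap(x)
                xs.append(x)
                ps.append(train_samples[i].p)
            xb = np.stack(xs).astype(np.float32) - center
            pb = np.stack(ps)
            p_hat = net.forward(xb, train=True)
            loss = drowsiness_loss(p_hat, pb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}; "
                    "inspect learning rate and input scaling"
                )
            train_losses.append(loss)
            opt.zero_grad()
            net.backward(pb)
            opt.step()

        val_hat = net.predict_proba(val_x)  # predict_proba applies the centering
        val_loss = drowsiness_loss(val_hat, val_p, weights=val_w)
        accs = []
        for i in range(4):
            definite = np.isin(val_p[:, i], (0.0, 1.0))
            if definite.any():
                accs.append(float(np.mean((val_hat[definite, i] >= 0.5) == (val_p[definite, i] == 1.0))))
            else:
                accs.append(np.nan)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": float(val_loss),
                **{f"val_acc_{ts}": accs[i] for i, ts in enumerate((5, 15, 30, 60))},
            }
        )
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, since_best = val_loss, net.state_dict(), 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.train_mode(False)
    return net, history
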