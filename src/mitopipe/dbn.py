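"""Restricted Boltzmann machines, CD-1, and the deep belief network classifier.

An RBM over binary visible units v (length n) and hidden units h (length m)
assigns energy

    E(v, h; theta) = -v^T omega h - b_vis . v - c_hid . h

with theta = {omega, b_vis, c_hid}. The joint is p(v, h) = exp(-E)/Z with
partition function Z = sum over all configurations; the bipartite structure
makes the conditionals factorise into logistic sigmoids. Training uses
one-step contrastive divergence: hidden states are Bernoulli samples, the
visible reconstruction is mean-field, and each parameter moves by the
learning rate times the difference between data and reconstruction
expectations (batch means).

A DBN is a greedy layer-wise stack of RBMs (layer k trains on layer k-1's
hidden probabilities) that is then fine-tuned end to end with a softmax
output layer and backpropagation. Real-valued features scaled to [0, 1] are
treated as visible activation probabilities, the standard relaxation that
keeps the binary RBM equations unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

MAX_ENUMERATION_UNITS = 20


@dataclass
class RBMParams:
    """theta = {omega (n x m), b_vis (n), c_hid (m)}."""

    omega: np.ndarray
    b_vis: np.ndarray
    c_hid: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.b_vis = np.asarray(self.b_vis, dtype=float)
        self.c_hid = np.asarray(self.c_hid, dtype=float)
        n, m = self.omega.shape
        if self.b_vis.shape != (n,) or self.c_hid.shape != (m,):
            raise ValueError("bias lengths must match the weight matrix")
        if not (np.isfinite(self.omega).all() and np.isfinite(self.b_vis).all()
                and np.isfinite(self.c_hid).all()):
            raise ValueError("parameters must be finite")

    @property
    def n_visible(self):
        return self.omega.shape[0]

    @property
    def n_hidden(self):
        return self.omega.shape[1]

    def copy(self):
        return RBMParams(self.omega.copy(), self.b_vis.copy(), self.c_hid.copy())


def init_rbm(n_visible: int, n_hidden: int, rng, weight_sd: float = 0.01
             ) -> RBMParams:
    """Small zero-mean Gaussian weights, zero biases."""
    return RBMParams(rng.normal(0.0, weight_sd, size=(n_visible, n_hidden)),
                     np.zeros(n_visible), np.zeros(n_hidden))


@dataclass(frozen=True)
class RBMTrainConfig:
    epsilon: float = 0.1
    epochs: int = 50
    batch_size: int = 32
    cd_steps: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if min(self.epochs, self.batch_size, self.cd_steps) < 1:
            raise ValueError("epochs, batch_size, cd_steps must be >= 1")


@dataclass(frozen=True)
class DBNConfig:
    layer_sizes: tuple[int, ...] = (256, 128)
    rbm_train: RBMTrainConfig = RBMTrainConfig()
    finetune_lr: float = 0.01
    finetune_epochs: int = 100
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if len(self.layer_sizes) < 1 or min(self.layer_sizes) < 1:
            raise ValueError("need at least one hidden layer of width >= 1")


# ---------------------------------------------------------------------------
# exact model quantities (small RBMs; these are the correctness oracles)


def energy(v, h, params: RBMParams) -> float:
    """-v^T omega h - b_vis . v - c_hid . h."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("v/h lengths must match the parameter shapes")
    return float(-v @ params.omega @ h - params.b_vis @ v - params.c_hid @ h)


def p_hidden_given_visible(v, params: RBMParams) -> np.ndarray:
    """sigmoid(c_hid + omega^T v), elementwise over hidden units."""
    v = np.asarray(v, dtype=float)
    return expit(params.c_hid + v @ params.omega)


def p_visible_given_hidden(h, params: RBMParams) -> np.ndarray:
    """sigmoid(b_vis + omega h), elementwise over visible units."""
    h = np.asarray(h, dtype=float)
    return expit(params.b_vis + h @ params.omega.T)


def _all_states(k: int) -> np.ndarray:
    bits = np.arange(2 ** k)[:, None] >> np.arange(k)[None, ::-1] & 1
    return bits.astype(float)


def partition_function(params: RBMParams) -> float:
    """Exact Z by exhaustive enumeration; refuses when n + m > 20."""
    n, m = params.n_visible, params.n_hidden
    if n + m > MAX_ENUMERATION_UNITS:
        raise ValueError(
            f"exhaustive enumeration limited to n + m <= {MAX_ENUMERATION_UNITS}"
        )
    vs = _all_states(n)
    hs = _all_states(m)
    # energies for all (v, h): -(v omega h + b v + c h)
    e = -(vs @ params.omega @ hs.T + (vs @ params.b_vis)[:, None]
          + (hs @ params.c_hid)[None, :])
    return float(np.exp(-e).sum())


def exact_log_likelihood(data, params: RBMParams) -> float:
    """Mean log p(v) over rows of ``data`` via the exact partition function."""
    n, m = params.n_visible, params.n_hidden
    if n + m > MAX_ENUMERATION_UNITS:
        raise ValueError(
            f"exhaustive enumeration limited to n + m <= {MAX_ENUMERATION_UNITS}"
        )
    v = np.asarray(data, dtype=float)
    # log p(v) = b.v + sum_j softplus(c_j + (v omega)_j) - log Z
    act = v @ params.omega + params.c_hid
    free = v @ params.b_vis + np.logaddexp(0.0, act).sum(axis=1)
    return float(free.mean() - np.log(partition_function(params)))


# ---------------------------------------------------------------------------
# contrastive divergence


def cd1_update(batch, params: RBMParams, config: RBMTrainConfig, rng,
               sample_hidden=None, reconstruct_visible=None) -> RBMParams:
    """One CD-1 parameter update in place; returns ``params``.

    Hidden states are Bernoulli draws from p(h|v); the visible
    reconstruction is mean-field (probabilities). The two hooks exist for
    tests that force a particular sample or reconstruction.
    """
    v0 = np.asarray(batch, dtype=float)
    if v0.ndim == 1:
        v0 = v0[None]
    if v0.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    if v0.min() < 0 or v0.max() > 1:
        raise ValueError("visible data must lie in [0, 1]")

    ph0 = p_hidden_given_visible(v0, params)
    h0 = sample_hidden(ph0) if sample_hidden else (rng.random(ph0.shape) < ph0)
    h0 = np.asarray(h0, dtype=float)
    v1 = (reconstruct_visible(h0) if reconstruct_visible
          else p_visible_given_hidden(h0, params))
    ph1 = p_hidden_given_visible(v1, params)

    n = v0.shape[0]
    eps = config.epsilon
    params.omega += eps * (v0.T @ ph0 - v1.T @ ph1) / n
    params.c_hid += eps * (ph0.mean(axis=0) - ph1.mean(axis=0))
    params.b_vis += eps * (v0.mean(axis=0) - v1.mean(axis=0))
    return params


def train_rbm(data, n_hidden: int, config: RBMTrainConfig):
    """CD training over epochs; returns (params, reconstruction-error trace)."""
    v = np.asarray(data, dtype=float)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("data must be a non-empty 2-D array")
    rng = np.random.default_rng(config.seed)
    params = init_rbm(v.shape[1], n_hidden, rng)
    trace = []
    n = v.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = v[order[start:start + config.batch_size]]
            for _ in range(config.cd_steps):
                cd1_update(batch, params, config, rng)
        ph = p_hidden_given_visible(v, params)
        recon = p_visible_given_hidden(ph, params)
        trace.append(float(((v - recon) ** 2).mean()))
    return params, trace


def pretrain_dbn(features, config: DBNConfig):
    """Greedy layer-wise pretraining; returns the list of RBMParams.

    Layer k's training input is layer k-1's hidden activation probabilities.
    """
    x = np.asarray(features, dtype=float)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("features must be scaled to [0, 1] before pretraining")
    stack = []
    for k, width in enumerate(config.layer_sizes):
        cfg = replace(config.rbm_train, seed=config.rbm_train.seed + k)
        params, _ = train_rbm(x, width, cfg)
        stack.append(params)
        x = p_hidden_given_visible(x, params)
    return stack


# ---------------------------------------------------------------------------
# supervised fine-tuning


class DBNClassifier:
    """Pretrained sigmoid layers + softmax head, fine-tuned end to end."""

    def __init__(self, stack: list[RBMParams], config: DBNConfig):
        self.config = config
        self.weights = [p.omega.copy() for p in stack]
        self.biases = [p.c_hid.copy() for p in stack]
        rng = np.random.default_rng(config.seed + 7919)
        m = stack[-1].n_hidden
        self.w_out = rng.normal(0.0, 0.01, size=(m, config.n_classes))
        self.b_out = np.zeros(config.n_classes)

    def _forward(self, x):
        acts = [np.asarray(x, dtype=float)]
        for w, c in zip(self.weights, self.biases):
            acts.append(expit(acts[-1] @ w + c))
        logits = acts[-1] @ self.w_out + self.b_out
        return acts, logits

    def predict_proba(self, features) -> np.ndarray:
        _, logits = self._forward(features)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, features) -> np.ndarray:
        return self.predict_proba(features).argmax(axis=1)

    def finetune(self, features, labels, freeze_pretrained: bool = False):
        """Mini-batch backprop with Adam-style adaptive steps on cross-entropy.

        Adaptive per-parameter scaling keeps fine-tuning effective across
        the wide learning-rate range the hyperparameter search explores.
        Returns the per-epoch loss trace.
        """
        x = np.asarray(features, dtype=float)
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("fine-tuning needs at least two classes present")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 104729)
        n = x.shape[0]
        batch = min(32, n)
        params = ([self.w_out, self.b_out]
                  + ([] if freeze_pretrained
                     else [a for pair in zip(self.weights, self.biases)
                           for a in pair]))
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, adam_eps = 0.9, 0.999, 1e-8
        step = 0
        trace = []
        for _ in range(cfg.finetune_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                acts, logits = self._forward(x[idx])
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                p = e / e.sum(axis=1, keepdims=True)
                nb = len(idx)
                epoch_loss -= np.log(p[np.arange(nb), y[idx]] + 1e-12).sum()
                d = p.copy()
                d[np.arange(nb), y[idx]] -= 1.0
                d /= nb
                grads = [acts[-1].T @ d, d.sum(axis=0)]
                g = d @ self.w_out.T
                if not freeze_pretrained:
                    for k in range(len(self.weights) - 1, -1, -1):
                        a = acts[k + 1]
                        g = g * a * (1.0 - a)
                        # keep grads aligned with params order [w0,b0,w1,b1,..]
                        grads.insert(2, g.sum(axis=0))
                        grads.insert(2, acts[k].T @ g)
                        g = g @ self.weights[k].T
                step += 1
                c1 = 1 - b1 ** step
                c2 = 1 - b2 ** step
                for i, (p_arr, g_arr) in enumerate(zip(params, grads)):
                    m[i] = b1 * m[i] + (1 - b1) * g_arr
                    v[i] = b2 * v[i] + (1 - b2) * g_arr * g_arr
                    p_arr -= cfg.finetune_lr * (m[i] / c1) / (
                        np.sqrt(v[i] / c2) + adam_eps)
            trace.append(epoch_loss / n)
        return trace


def finetune_and_predict(stack, features, labels, config: DBNConfig,
                         freeze_pretrained: bool = False) -> DBNClassifier:
    """Append a softmax layer, backpropagate through the stack, return it."""
    clf = DBNClassifier(stack, config)
    clf.finetune(features, labels, freeze_pretrained=freeze_pretrained)
    return clf


def fit_dbn(features, labels, config: DBNConfig) -> DBNClassifier:
    """Pretrain + fine-tune in one call (features already in [0, 1])."""
    stack = pretrain_dbn(features, config)
    return finetune_and_predict(stack, features, labels, config)


def min_max_scale(features, lo=None, span=None):
    """Per-dimension min-max scaling to [0, 1]; returns (scaled, lo, span)."""
    x = np.asarray(features, dtype=float)
    if lo is None:
        lo = x.min(axis=0)
        span = x.max(axis=0) - lo
        span = np.where(span == 0, 1.0, span)
    return np.clip((x - lo) / span, 0.0, 1.0), lo, span
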