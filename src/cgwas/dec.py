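"""Deep embedded clustering (DEC).

DEC jointly learns a latent representation and cluster centroids:

1. Pretrain a symmetric autoencoder on mean squared reconstruction error.
2. Initialize k centroids by k-means on the latent codes.
3. Refine: soft-assign points to centroids with a Student-t kernel
   (one degree of freedom), ``q_ij \\propto (1 + ||z_i - mu_j||^2)^-1``,
   build the sharpened target ``p_ij \\propto q_ij^2 / f_j`` (``f_j`` the
   soft cluster frequency), and take mini-batch gradient steps on
   ``KL(P || Q)`` with respect to both the encoder and the centroids.

Training stops when the fraction of points whose hard label changed between
consecutive target refreshes drops below ``tolerance``, or at
``max_iterations`` mini-batch steps. Everything is seeded and runs on CPU;
the networks are plain NumPy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .features import FeatureMatrix


@dataclass
class DECHyperparams:
    """DEC settings; the defaults are the emulated study's published ones
    (k=40, batch 256, 300 pretraining epochs, 400 maximum iterations,
    update interval 30, stopping tolerance 0.001)."""

    k: int = 40
    batch_size: int = 256
    pretrain_epochs: int = 300
    max_iterations: int = 400
    update_interval: int = 30
    tolerance: float = 0.001
    encoder_dims: tuple = (500, 500, 2000)  # hidden widths, canonical DEC
    latent_dim: int = 10
    pretrain_lr: float = 1e-3
    refine_lr: float = 0.01
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must be in (0, 1)")
        for name in ("batch_size", "pretrain_epochs", "max_iterations", "update_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Minimal MLP with ReLU hidden layers and a linear output


class _MLP:
    def __init__(self, dims, rng):
        self.dims = list(dims)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self):
        return self.W + self.b

    def forward(self, X, cache=None):
        a = X
        if cache is not None:
            cache.append(a)
        last = len(self.W) - 1
        for l, (W, b) in enumerate(zip(self.W, self.b)):
            a = a @ W + b
            if l != last:
                a = np.maximum(a, 0.0)
            if cache is not None:
                cache.append(a)
        return a

    def backward(self, dout, cache):
        """Gradients for all parameters plus dL/dinput; ``cache`` from forward."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        last = len(self.W) - 1
        for l in range(last, -1, -1):
            a_in, a_out = cache[l], cache[l + 1]
            if l != last:
                delta = delta * (a_out > 0)
            gW[l] = a_in.T @ delta
            gb[l] = delta.sum(axis=0)
            delta = delta @ self.W[l].T
        return gW + gb, delta


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGDMomentum:
    def __init__(self, params, lr, momentum):
        self.lr, self.mom = lr, momentum
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        for p, g, v in zip(params, grads, self.v):
            v *= self.mom
            v -= self.lr * g
            p += v


# ---------------------------------------------------------------------------
# DEC proper


@dataclass
class DECModel:
    encoder: _MLP
    centroids: np.ndarray  # (k, latent_dim)
    hyper: DECHyperparams
    kl_history: list = field(default_factory=list)

    def transform(self, X) -> np.ndarray:
        return self.encoder.forward(np.asarray(X, dtype=float))

    def predict_soft(self, X) -> np.ndarray:
        return soft_assign(self.transform(X), self.centroids)


@dataclass
class ClusterAssignment:
    """Soft assignment matrix Q plus derived hard labels."""

    Q: np.ndarray  # (n, k), rows sum to 1
    labels: np.ndarray  # argmax per row (ties -> lowest index)
    sample_ids: list = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def k(self) -> int:
        return self.Q.shape[1]

    @property
    def n_nonempty(self) -> int:
        return len(np.unique(self.labels))

    def members(self) -> dict:
        """cluster label -> list of sample ids (non-empty clusters only)."""
        if self.sample_ids is None:
            raise ValueError("assignment carries no sample ids")
        out: dict = {}
        for sid, lab in zip(self.sample_ids, self.labels):
            out.setdefault(int(lab), []).append(sid)
        return out


def soft_assign(Z: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Student-t (df=1) soft assignment, rows normalized to 1."""
    Z = np.asarray(Z, dtype=float)
    d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = 1.0 / (1.0 + d2)
    return u / u.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened target P: p_ij = (q_ij^2 / f_j) / sum_j'(q_ij'^2 / f_j').

    Columns with zero soft frequency f_j contribute nothing (no division
    error on empty clusters).
    """
    f = Q.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(f > 0, Q**2 / f, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def _kl(P, Q):
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], 1e-300))))


def _as_array(X):
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.X, dtype=float), X.sample_ids
    return np.asarray(X, dtype=float), None


def _build_autoencoder(d_in, hyper, rng):
    enc_dims = [d_in, *hyper.encoder_dims, hyper.latent_dim]
    dec_dims = enc_dims[::-1]
    return _MLP(enc_dims, rng), _MLP(dec_dims, rng)


def pretrain_autoencoder(X, hyper: DECHyperparams):
    """Train a symmetric autoencoder on MSE; returns (encoder, decoder, history).

    ``history`` holds the full-data reconstruction error before and after
    training. Batch size is clipped to n when the data are smaller than one
    batch.
    """
    Xa, _ = _as_array(X)
    if not np.all(np.isfinite(Xa)):
        raise ValueError("feature matrix contains non-finite values")
    n, d = Xa.shape
    rng = np.random.default_rng(hyper.seed)
    enc, dec = _build_autoencoder(d, hyper, rng)
    opt = _Adam(enc.params + dec.params, hyper.pretrain_lr)
    bs = min(hyper.batch_size, n)

    def full_mse():
        rec = dec.forward(enc.forward(Xa))
        return float(np.mean((rec - Xa) ** 2))

    history = {"initial_mse": full_mse()}
    for _epoch in range(hyper.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb = Xa[idx]
            c_enc, c_dec = [], []
            z = enc.forward(xb, c_enc)
            rec = dec.forward(z, c_dec)
            dL = 2.0 * (rec - xb) / rec.size
            g_dec, dz = dec.backward(dL, c_dec)
            g_enc, _ = enc.backward(dz, c_enc)
            opt.step(enc.params + dec.params, g_enc + g_dec)
    history["final_mse"] = full_mse()
    return enc, dec, history


def _init_centroids(Z, k, seed, rng):
    n = Z.shape[0]
    if n < k:
        warnings.warn(f"n={n} < k={k}; extra centroids are jittered copies")
    k_eff = min(k, n)
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=int(seed) % (2**31))
    km.fit(Z)
    centroids = km.cluster_centers_
    if k_eff < k:
        extra = Z[rng.integers(0, n, size=k - k_eff)] + 1e-3 * rng.standard_normal(
            (k - k_eff, Z.shape[1])
        )
        centroids = np.vstack([centroids, extra])
    return centroids


def fit_dec(X, hyper: DECHyperparams):
    """Full DEC pipeline; returns (DECModel, ClusterAssignment).

    Deterministic given the hyperparameter seed. Clusters may end up empty
    (hard labels simply never select them); downstream consumers see only
    the non-empty ones.
    """
    Xa, sample_ids = _as_array(X)
    n = Xa.shape[0]
    if n < hyper.k:
        warnings.warn(f"fewer samples ({n}) than clusters ({hyper.k})")
    enc, _dec, _hist = pretrain_autoencoder(Xa, hyper)
    rng = np.random.default_rng(hyper.seed + 1)
    Z = enc.forward(Xa)
    centroids = _init_centroids(Z, hyper.k, hyper.seed, rng)

    bs = min(hyper.batch_size, n)
    opt = _SGDMomentum(enc.params + [centroids], hyper.refine_lr, hyper.momentum)
    kl_history = []
    last_labels = None
    P = None
    order = rng.permutation(n)
    cursor = 0
    for it in range(hyper.max_iterations):
        if it % hyper.update_interval == 0:
            Z = enc.forward(Xa)
            Q = soft_assign(Z, centroids)
            P = target_distribution(Q)
            kl = _kl(P, Q)
            if not np.isfinite(kl):
                raise FloatingPointError(f"divergent KL objective at iteration {it}")
            kl_history.append(kl)
            labels = Q.argmax(axis=1)
            if last_labels is not None:
                changed = float(np.mean(labels != last_labels))
                last_labels = labels
                if changed < hyper.tolerance:
                    break
            else:
                last_labels = labels
        # mini-batch KL(P||Q) step
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + bs]
        cursor += bs
        cache = []
        zb = enc.forward(Xa[idx], cache)
        diff = zb[:, None, :] - centroids[None, :, :]  # (b, k, d)
        u = 1.0 / (1.0 + (diff**2).sum(axis=2))
        qb = u / u.sum(axis=1, keepdims=True)
        pb = P[idx]
        coef = 2.0 * u * (pb - qb) / len(idx)  # (b, k)
        dz = (coef[:, :, None] * diff).sum(axis=1)
        dmu = -(coef[:, :, None] * diff).sum(axis=0)
        g_enc, _ = enc.backward(dz, cache)
        opt.step(enc.params + [centroids], g_enc + [dmu])

    Z = enc.forward(Xa)
    Q = soft_assign(Z, centroids)
    kl_history.append(_kl(target_distribution(Q), Q))
    labels = Q.argmax(axis=1)
    model = DECModel(enc, centroids, hyper, kl_history)
    return model, ClusterAssignment(Q, labels, sample_ids)
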