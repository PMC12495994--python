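"""Two-layer high-order graph convolution and link scoring.

Propagation rule:  H = A_h . LeakyReLU(A_e . H0 . W1) . W2, where A_e is
the similarity-enhanced adjacency (first layer: immediate neighbors) and
A_h the triangle-motif adjacency (second layer: higher-order context).
A triplet (lncRNA, miRNA, mRNA) is embedded either through a two-layer
perceptron on the concatenated node embeddings or as a learned convex
combination; the probability of a triplet-disease link is a bilinear form
passed through a sigmoid.  Training minimizes binary cross-entropy with
Adam; all tensors are NumPy arrays and gradients are computed in closed
form, which keeps the model exactly reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .hetnet import BlockMatrix

__all__ = [
    "ModelParams",
    "TrainConfig",
    "TrainedModel",
    "init_params",
    "propagate",
    "triplet_embedding",
    "link_probability",
    "train_model",
]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the experimental setup)."""

    epochs: int = 300
    learning_rate: float = 0.001
    dropout: float = 0.5
    hidden: int = 128
    embed: int = 64
    d0: int = 64
    train_ratio: float = 0.8
    seed: int = 0
    triplet_mode: str = "mlp"  # or "weighted"
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.train_ratio < 1):
            raise ValueError("train_ratio must be in (0, 1)")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("epochs", "hidden", "embed", "d0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.triplet_mode not in ("mlp", "weighted"):
            raise ValueError("triplet_mode must be 'mlp' or 'weighted'")


@dataclass
class ModelParams:
    """All trainable arrays of the model."""

    H0: np.ndarray  # (Nv, d0) initial node embeddings
    W1: np.ndarray  # (d0, hidden)
    W2: np.ndarray  # (hidden, d)
    Wp: np.ndarray  # (d, d) bilinear score matrix
    M1: np.ndarray  # (3d, d) triplet MLP layer 1
    b1: np.ndarray  # (d,)
    M2: np.ndarray  # (d, d) triplet MLP layer 2
    b2: np.ndarray  # (d,)
    alpha_logits: np.ndarray  # (3,) weighted-mode mixing logits
    triplet_mode: str = "mlp"

    def mixing_weights(self) -> np.ndarray:
        """Softmax-normalized (alpha1, alpha2, alpha3)."""
        e = np.exp(self.alpha_logits - self.alpha_logits.max())
        return e / e.sum()

    def trainable(self) -> dict:
        out = {"H0": self.H0, "W1": self.W1, "W2": self.W2, "Wp": self.Wp}
        if self.triplet_mode == "mlp":
            out.update(M1=self.M1, b1=self.b1, M2=self.M2, b2=self.b2)
        else:
            out.update(alpha_logits=self.alpha_logits)
        return out


def init_params(n_nodes: int, cfg: TrainConfig, rng: np.random.Generator) -> ModelParams:
    d0, h, d = cfg.d0, cfg.hidden, cfg.embed

    def glorot(fan_in, fan_out):
        s = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.standard_normal((fan_in, fan_out)) * s

    return ModelParams(
        H0=rng.standard_normal((n_nodes, d0)) / np.sqrt(d0),
        W1=glorot(d0, h),
        W2=glorot(h, d),
        Wp=glorot(d, d) * 0.1,
        M1=glorot(3 * d, d),
        b1=np.zeros(d),
        M2=glorot(d, d),
        b2=np.zeros(d),
        alpha_logits=np.zeros(3),
        triplet_mode=cfg.triplet_mode,
    )


def _as_csr(A):
    if isinstance(A, BlockMatrix):
        A = A.matrix
    return sp.csr_matrix(A)


def _lrelu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _lrelu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def propagate(
    A_e,
    A_h,
    params: ModelParams,
    leaky_slope: float = 0.2,
    dropout: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Forward pass of the two-layer propagation rule.

    Dropout (inverted scaling) is applied to the hidden layer only when
    ``dropout > 0`` and an RNG is supplied, i.e. during training.
    """
    Ae, Ah = _as_csr(A_e), _as_csr(A_h)
    n = Ae.shape[0]
    if Ae.shape != (n, n) or Ah.shape != (n, n) or params.H0.shape[0] != n:
        raise ValueError("A_e, A_h and H0 disagree on the number of nodes")
    if params.H0.shape[1] != params.W1.shape[0]:
        raise ValueError("H0 / W1 dimension mismatch")

    P = Ae @ params.H0
    Z1 = P @ params.W1
    U = _lrelu(Z1, leaky_slope)
    if dropout > 0 and dropout_rng is not None:
        mask = (dropout_rng.random(U.shape) >= dropout) / (1.0 - dropout)
        Ud = U * mask
    else:
        mask = None
        Ud = U
    Z2 = Ah @ Ud
    H = Z2 @ params.W2
    if return_cache:
        return H, {"Ae": Ae, "Ah": Ah, "P": P, "Z1": Z1, "mask": mask, "Z2": Z2}
    return H


def triplet_embedding(
    h_lnc: np.ndarray,
    h_mi: np.ndarray,
    h_mr: np.ndarray,
    params: ModelParams,
    mode: str | None = None,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Embed one triplet from its three node embeddings.

    mode="mlp": two-layer perceptron on the concatenation, output dim d.
    mode="weighted": softmax-normalized convex combination.
    """
    mode = params.triplet_mode if mode is None else mode
    h_lnc, h_mi, h_mr = (np.asarray(v, float) for v in (h_lnc, h_mi, h_mr))
    if not (h_lnc.shape == h_mi.shape == h_mr.shape):
        raise ValueError("triplet member embeddings must share a dimension")
    if mode == "weighted":
        w = params.mixing_weights()
        return w[0] * h_lnc + w[1] * h_mi + w[2] * h_mr
    c = np.concatenate([h_lnc, h_mi, h_mr])
    if c.shape[0] != params.M1.shape[0]:
        raise ValueError("concatenated dimension does not match MLP input")
    u = _lrelu(c @ params.M1 + params.b1, leaky_slope)
    return u @ params.M2 + params.b2


def link_probability(h_triplet: np.ndarray, h_disease: np.ndarray, Wp: np.ndarray) -> float:
    """sigmoid(h_triplet . Wp . h_disease)."""
    h_t = np.atleast_1d(np.asarray(h_triplet, float))
    h_d = np.atleast_1d(np.asarray(h_disease, float))
    Wp = np.atleast_2d(np.asarray(Wp, float))
    s = float(np.clip(h_t @ Wp @ h_d, -500, 500))
    return float(1.0 / (1.0 + np.exp(-s)))


# ---------------------------------------------------------------------------
# batched forward/backward used by training


def _forward_scores(H: np.ndarray, params: ModelParams, samples: np.ndarray, slope: float):
    """Scores for (n, 4) index rows [lnc, mi, mr, dis]; returns cache."""
    l, m, r, d = (samples[:, k] for k in range(4))
    Hl, Hm, Hr, Hd = H[l], H[m], H[r], H[d]
    cache = {"idx": (l, m, r, d), "Hd": Hd}
    if params.triplet_mode == "mlp":
        c = np.concatenate([Hl, Hm, Hr], axis=1)
        a1 = c @ params.M1 + params.b1
        u1 = _lrelu(a1, slope)
        t = u1 @ params.M2 + params.b2
        cache.update(c=c, a1=a1, u1=u1)
    else:
        w = params.mixing_weights()
        t = w[0] * Hl + w[1] * Hm + w[2] * Hr
        cache.update(w=w, Hl=Hl, Hm=Hm, Hr=Hr)
    s = np.clip(np.einsum("bi,ij,bj->b", t, params.Wp, Hd), -500, 500)
    cache["t"] = t
    yhat = 1.0 / (1.0 + np.exp(-s))
    return yhat, cache


def score_samples(H: np.ndarray, params: ModelParams, samples: np.ndarray, slope: float = 0.2):
    """Link probabilities for an (n, 4) array of node-index quadruples."""
    yhat, _ = _forward_scores(H, params, np.asarray(samples, dtype=int), slope)
    return yhat


def _backward(
    H_shape,
    params: ModelParams,
    cache: dict,
    gcn_cache: dict,
    ds: np.ndarray,
    slope: float,
):
    """Closed-form gradients of mean BCE w.r.t. every trainable array."""
    grads: dict = {}
    l, m, r, d = cache["idx"]
    t, Hd = cache["t"], cache["Hd"]

    grads["Wp"] = (t * ds[:, None]).T @ Hd
    dt = ds[:, None] * (Hd @ params.Wp.T)
    dHd = ds[:, None] * (t @ params.Wp)

    dH = np.zeros(H_shape)
    if params.triplet_mode == "mlp":
        u1, a1, c = cache["u1"], cache["a1"], cache["c"]
        grads["M2"] = u1.T @ dt
        grads["b2"] = dt.sum(axis=0)
        du1 = dt @ params.M2.T
        da1 = du1 * _lrelu_grad(a1, slope)
        grads["M1"] = c.T @ da1
        grads["b1"] = da1.sum(axis=0)
        dc = da1 @ params.M1.T
        dsz = H_shape[1]
        np.add.at(dH, l, dc[:, :dsz])
        np.add.at(dH, m, dc[:, dsz : 2 * dsz])
        np.add.at(dH, r, dc[:, 2 * dsz :])
    else:
        w = cache["w"]
        np.add.at(dH, l, w[0] * dt)
        np.add.at(dH, m, w[1] * dt)
        np.add.at(dH, r, w[2] * dt)
        dw = np.array(
            [
                float(np.sum(dt * cache["Hl"])),
                float(np.sum(dt * cache["Hm"])),
                float(np.sum(dt * cache["Hr"])),
            ]
        )
        grads["alpha_logits"] = (np.diag(w) - np.outer(w, w)) @ dw
    np.add.at(dH, d, dHd)

    Z2, Z1, P = gcn_cache["Z2"], gcn_cache["Z1"], gcn_cache["P"]
    grads["W2"] = Z2.T @ dH
    dZ2 = dH @ params.W2.T
    dUd = gcn_cache["Ah"].T @ dZ2
    if gcn_cache["mask"] is not None:
        dUd = dUd * gcn_cache["mask"]
    dZ1 = dUd * _lrelu_grad(Z1, slope)
    grads["W1"] = P.T @ dZ1
    dP = dZ1 @ params.W1.T
    grads["H0"] = gcn_cache["Ae"].T @ dP
    return grads


@dataclass
class TrainedModel:
    """A fitted model: parameters, final (eval-mode) embeddings, history."""

    params: ModelParams
    cfg: TrainConfig
    H: np.ndarray
    loss_history: list = field(default_factory=list)

    def scores(self, samples: np.ndarray) -> np.ndarray:
        return score_samples(self.H, self.params, samples, self.cfg.leaky_slope)


def train_model(
    A_e,
    A_h,
    positives: np.ndarray,
    negatives: np.ndarray | None,
    cfg: TrainConfig,
    neg_sampler=None,
) -> TrainedModel:
    """Full-batch Adam training of the propagation + scoring model.

    ``positives``/``negatives`` are (n, 4) integer arrays of node indices
    [lnc, mi, mr, disease].  Each epoch uses all positives and a 1:1 draw
    of negatives — taken from ``neg_sampler(rng, n)`` when provided (fresh
    negatives per epoch), otherwise subsampled from the fixed ``negatives``
    pool.  Loss is mean binary cross-entropy; everything is deterministic
    under ``cfg.seed``.
    """
    positives = np.asarray(positives, dtype=int)
    if positives.size == 0:
        raise ValueError("no positive samples")
    if negatives is None and neg_sampler is None:
        raise ValueError("need negatives or a neg_sampler")
    if negatives is not None:
        negatives = np.asarray(negatives, dtype=int)

    rng = np.random.default_rng(cfg.seed)
    n_nodes = _as_csr(A_e).shape[0]
    params = init_params(n_nodes, cfg, rng)
    n_pos = len(positives)

    # Adam state
    tensors = params.trainable()
    mom = {k: np.zeros_like(v) for k, v in tensors.items()}
    vel = {k: np.zeros_like(v) for k, v in tensors.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    losses = []
    for epoch in range(cfg.epochs):
        if neg_sampler is not None:
            neg = np.asarray(neg_sampler(rng, n_pos), dtype=int)
        elif len(negatives) > n_pos:
            neg = negatives[rng.choice(len(negatives), size=n_pos, replace=False)]
        else:
            neg = negatives
        batch = np.vstack([positives, neg])
        y = np.concatenate([np.ones(n_pos), np.zeros(len(neg))])

        H, gcn_cache = propagate(
            A_e,
            A_h,
            params,
            cfg.leaky_slope,
            dropout=cfg.dropout,
            dropout_rng=rng,
            return_cache=True,
        )
        yhat, cache = _forward_scores(H, params, batch, cfg.leaky_slope)
        yhat = np.clip(yhat, 1e-12, 1 - 1e-12)
        loss = float(-np.mean(y * np.log(yhat) + (1 - y) * np.log(1 - yhat)))
        losses.append(loss)

        ds = (yhat - y) / len(y)
        grads = _backward(H.shape, params, cache, gcn_cache, ds, cfg.leaky_slope)

        t_adam = epoch + 1
        tensors = params.trainable()
        for k, g in grads.items():
            mom[k] = beta1 * mom[k] + (1 - beta1) * g
            vel[k] = beta2 * vel[k] + (1 - beta2) * g * g
            mhat = mom[k] / (1 - beta1**t_adam)
            vhat = vel[k] / (1 - beta2**t_adam)
            tensors[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    H_final = propagate(A_e, A_h, params, cfg.leaky_slope)
    return TrainedModel(params=params, cfg=cfg, H=H_final, loss_history=losses)
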