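"""Distribution-agnostic optimal-transport autoencoder for dropout recovery.

The model is a deterministic encoder/decoder pair trained on log-normalized
expression with the relaxed optimal-transport objective

    L = E ||x - x_hat||^2  +  lambda * MMD_imq(Q(Z), P(Z))
                           +  beta * KL(P(bulk_agg) || Q(recon_agg)),

where Q(Z) is the empirical distribution of encoder codes, P(Z) an isotropic
Gaussian prior N(0, sigma_z^2 I), the MMD uses the inverse-multiquadratics
kernel k(u, v) = C / (C + ||u - v||^2) with C = 2 * d_z * sigma_z^2, and the
optional KL term matches the per-gene mean of the reconstructions to the
per-gene mean of a matched bulk table, both renormalized to probability
vectors over genes.

Everything — forward pass, analytic gradients of the three loss terms, and
the Adam optimizer — is implemented directly on numpy arrays in float64, so
training is bit-reproducible from a seed on a fixed platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import ExpressionMatrix

__all__ = [
    "BisConfig",
    "LatentBatch",
    "TrainHistory",
    "BisModel",
    "imq_kernel",
    "sample_prior",
    "mmd_penalty",
    "reconstruction_cost",
    "aggregate_to_distribution",
    "bulk_consistency_kl",
    "total_loss",
    "train",
    "impute",
    "encode",
    "decode",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BisConfig:
    """Model and training hyperparameters.

    ``kernel_const`` defaults to 2 * bottleneck_dim * sigma_z**2, the
    expected squared distance between two independent prior draws, which
    keeps the IMQ kernel well-scaled for the prior.
    """

    encoder_widths: tuple[int, ...] = (512, 128)
    bottleneck_dim: int = 32
    decoder_widths: tuple[int, ...] = (128, 512)
    sigma_z: float = 1.0
    kernel_const: float | None = None
    lam: float = 0.01
    beta: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 512
    epochs: int = 300
    seed: int = 0
    fill_zeros_only: bool = False
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not self.encoder_widths or not self.decoder_widths:
            raise ValueError("layer width lists must be nonempty")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2 (the MMD needs >= 2 points)")
        if self.sigma_z <= 0 or self.bottleneck_dim < 1:
            raise ValueError("sigma_z must be positive and bottleneck_dim >= 1")
        if self.C <= 0:
            raise ValueError("kernel_const must be positive")
        if self.lam < 0 or self.beta < 0:
            raise ValueError("lam and beta must be nonnegative")

    @property
    def C(self) -> float:
        if self.kernel_const is not None:
            return float(self.kernel_const)
        return 2.0 * self.bottleneck_dim * self.sigma_z**2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_widths"] = list(self.encoder_widths)
        d["decoder_widths"] = list(self.decoder_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BisConfig":
        d = dict(d)
        d["encoder_widths"] = tuple(d["encoder_widths"])
        d["decoder_widths"] = tuple(d["decoder_widths"])
        return cls(**d)


@dataclass
class LatentBatch:
    """A batch of latent codes, from the encoder or the prior."""

    codes: np.ndarray
    source: str = "encoder"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (n x d_z)")
        if not np.all(np.isfinite(self.codes)):
            raise ValueError("codes contain non-finite values")
        if self.source not in ("encoder", "prior"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def d(self) -> int:
        return self.codes.shape[1]


@dataclass
class TrainHistory:
    """Per-epoch loss components; total = recon + lam*mmd + beta*kl."""

    reconstruction_loss: list[float] = field(default_factory=list)
    mmd_loss: list[float] = field(default_factory=list)
    kl_loss: list[float] = field(default_factory=list)
    total_loss: list[float] = field(default_factory=list)

    def append(self, recon: float, mmd: float, kl: float, total: float) -> None:
        self.reconstruction_loss.append(recon)
        self.mmd_loss.append(mmd)
        self.kl_loss.append(kl)
        self.total_loss.append(total)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# loss primitives


def imq_kernel(u: np.ndarray, v: np.ndarray, C: float) -> float:
    """Inverse-multiquadratics kernel C / (C + ||u - v||^2) for two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("imq_kernel requires equal dimensions")
    return float(C / (C + np.sum((u - v) ** 2)))


def _imq_gram(a: np.ndarray, b: np.ndarray, C: float) -> np.ndarray:
    d2 = np.sum(a**2, axis=1)[:, None] + np.sum(b**2, axis=1)[None, :] - 2.0 * a @ b.T
    np.maximum(d2, 0.0, out=d2)
    return C / (C + d2)


def sample_prior(n: int, cfg: BisConfig, rng: np.random.Generator | None = None) -> LatentBatch:
    """Draw n i.i.d. codes from the prior N(0, sigma_z^2 I)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    codes = rng.normal(0.0, cfg.sigma_z, size=(n, cfg.bottleneck_dim))
    return LatentBatch(codes, source="prior")


def mmd_penalty(zq: LatentBatch, zp: LatentBatch, C: float) -> float:
    """Biased (V-statistic) squared-MMD estimate with the IMQ kernel.

    mean of all within-pairs of ``zq`` + mean of all within-pairs of ``zp``
    - 2 * mean of all cross pairs.  Nonnegative, and exactly zero on
    identical point sets.
    """
    if zq.n == 0 or zp.n == 0:
        raise ValueError("mmd_penalty requires nonempty batches")
    if zq.d != zp.d:
        raise ValueError("latent dimension mismatch")
    a, b = zq.codes, zp.codes
    val = (
        _imq_gram(a, a, C).mean()
        + _imq_gram(b, b, C).mean()
        - 2.0 * _imq_gram(a, b, C).mean()
    )
    return float(val)


def _mmd_grad_zq(zq: np.ndarray, zp: np.ndarray, C: float) -> np.ndarray:
    """d/d zq of the V-statistic MMD (zp treated as constant)."""
    n, m = zq.shape[0], zp.shape[0]

    def sqd(a, b):
        d2 = np.sum(a**2, 1)[:, None] + np.sum(b**2, 1)[None, :] - 2.0 * a @ b.T
        return np.maximum(d2, 0.0)

    # dk/du = -2C (u - v) / (C + ||u-v||^2)^2
    wqq = -2.0 * C / (C + sqd(zq, zq)) ** 2
    wqp = -2.0 * C / (C + sqd(zq, zp)) ** 2
    grad_qq = (wqq.sum(axis=1)[:, None] * zq - wqq @ zq) * (2.0 / n**2)
    grad_qp = (wqp.sum(axis=1)[:, None] * zq - wqp @ zp) * (-2.0 / (n * m))
    return grad_qq + grad_qp


def reconstruction_cost(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over cells of the squared Euclidean reconstruction distance."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("shape mismatch between input and reconstruction")
    return float(np.sum((x - x_hat) ** 2) / x.shape[0])


def aggregate_to_distribution(values: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-gene mean across rows, eps-smoothed and renormalized to sum 1."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if np.any(values < 0):
        raise ValueError("aggregate_to_distribution requires nonnegative values")
    mean = values.mean(axis=0) + eps
    total = mean.sum()
    if total <= 0:
        raise ValueError("all-zero matrix cannot be normalized without smoothing")
    return mean / total


def bulk_consistency_kl(p_bulk: np.ndarray, q_sc: np.ndarray) -> float:
    """KL(P || Q) = sum_k P_k ln(P_k / Q_k), with 0 ln 0 = 0."""
    p = np.asarray(p_bulk, dtype=float)
    q = np.asarray(q_sc, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distribution length mismatch")
    support = p > 0
    if np.any(q[support] <= 0):
        raise ValueError("Q must be positive wherever P is positive")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def total_loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    zq: LatentBatch,
    zp: LatentBatch,
    p_bulk: np.ndarray | None,
    cfg: BisConfig,
) -> tuple[float, dict[str, float]]:
    """Weighted objective and its three addends.

    The KL addend is computed between ``p_bulk`` and the aggregated
    reconstruction; when ``p_bulk`` is None it is reported as 0 and the
    beta term drops out.
    """
    recon = reconstruction_cost(x, x_hat)
    mmd = mmd_penalty(zq, zp, cfg.C)
    if p_bulk is None:
        kl = 0.0
    else:
        kl = bulk_consistency_kl(p_bulk, aggregate_to_distribution(x_hat, cfg.eps))
    total = recon + cfg.lam * mmd + cfg.beta * kl
    return total, {"reconstruction": recon, "mmd": mmd, "kl": kl, "total": total}


# ---------------------------------------------------------------------------
# network


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def _softplus(a: np.ndarray) -> np.ndarray:
    # overflow-safe log(1 + e^a)
    return np.logaddexp(0.0, a)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class BisModel:
    """Encoder/decoder with ReLU hidden layers.

    The bottleneck layer is linear (codes live on all of R^{d_z}, matching
    the Gaussian prior); the output layer is softplus so reconstructed
    log-normalized expression is strictly nonnegative.
    """

    def __init__(self, n_genes: int, cfg: BisConfig):
        self.cfg = cfg
        self.n_genes = n_genes
        widths = (
            [n_genes]
            + list(cfg.encoder_widths)
            + [cfg.bottleneck_dim]
            + list(cfg.decoder_widths)
            + [n_genes]
        )
        self._widths = widths
        self._enc_layers = len(cfg.encoder_widths) + 1  # up to and incl. bottleneck
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.trained = False
        self.gene_ids: list[str] | None = None

    # -- forward -----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
        """Return (codes, reconstruction, cache for backprop)."""
        cache = []
        h = x
        n_layers = len(self.W)
        z = None
        for li in range(n_layers):
            a = h @ self.W[li] + self.b[li]
            if li == self._enc_layers - 1:
                out = a                     # linear bottleneck
                kind = "linear"
            elif li == n_layers - 1:
                out = _softplus(a)          # nonnegative output
                kind = "softplus"
            else:
                out = _relu(a)
                kind = "relu"
            cache.append((h, a, kind))
            h = out
            if li == self._enc_layers - 1:
                z = out
        return z, h, cache

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        if h.ndim != 2 or h.shape[0] == 0:
            raise ValueError("encode expects a nonempty 2-D batch")
        if h.shape[1] != self.n_genes:
            raise ValueError(
                f"gene dimension {h.shape[1]} does not match model input {self.n_genes}"
            )
        for li in range(self._enc_layers):
            a = h @ self.W[li] + self.b[li]
            h = a if li == self._enc_layers - 1 else _relu(a)
        return h

    def decode_array(self, z: np.ndarray) -> np.ndarray:
        h = np.asarray(z, dtype=float)
        if h.ndim != 2:
            raise ValueError("decode expects a 2-D batch of codes")
        if h.shape[1] != self.cfg.bottleneck_dim:
            raise ValueError(
                f"code dimension {h.shape[1]} does not match bottleneck "
                f"{self.cfg.bottleneck_dim}"
            )
        n_layers = len(self.W)
        for li in range(self._enc_layers, n_layers):
            a = h @ self.W[li] + self.b[li]
            h = _softplus(a) if li == n_layers - 1 else _relu(a)
        return h

    # -- backward ----------------------------------------------------------

    def _backward(
        self,
        cache: list,
        z: np.ndarray,
        d_xhat: np.ndarray,
        d_z_direct: np.ndarray,
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Backprop given dL/d x_hat and the direct dL/dz (from the MMD)."""
        n_layers = len(self.W)
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(bb) for bb in self.b]
        grad = d_xhat
        for li in range(n_layers - 1, -1, -1):
            h, a, kind = cache[li]
            if kind == "softplus":
                da = grad * (1.0 / (1.0 + np.exp(-a)))
            elif kind == "relu":
                da = grad * (a > 0)
            else:  # linear bottleneck
                da = grad + d_z_direct
            gW[li] = h.T @ da
            gb[li] = da.sum(axis=0)
            grad = da @ self.W[li].T
        return gW, gb


# ---------------------------------------------------------------------------
# operations on the model


def encode(x: ExpressionMatrix | np.ndarray, model: BisModel) -> LatentBatch:
    """Map a batch of log-normalized cells to latent codes."""
    vals = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    return LatentBatch(model.encode_array(vals), source="encoder")


def decode(z: LatentBatch, model: BisModel, col_ids: list[str] | None = None) -> np.ndarray:
    """Map latent codes back to (nonnegative) expression space."""
    return model.decode_array(z.codes)


def train(
    x: ExpressionMatrix,
    y_bulk: ExpressionMatrix | None,
    cfg: BisConfig,
) -> tuple[BisModel, TrainHistory]:
    """Mini-batch Adam training of the full objective.

    Per step: encode the batch, decode, draw a fresh prior batch of equal
    size, and descend ``recon + lam * MMD + beta * KL``.  The bulk target
    distribution is computed once from ``y_bulk``; the single-cell side of
    the KL is the aggregated reconstruction of the current batch.  When
    ``y_bulk`` is None the beta term is dropped (reported as a zero KL).
    History records per-epoch means of each component.
    """
    if x.layer_tag != "log_normalized":
        raise ValueError("train expects log-normalized input")
    xv = x.values
    n, g = xv.shape
    p_bulk = None
    if y_bulk is not None:
        if list(y_bulk.col_ids) != list(x.col_ids):
            raise ValueError("bulk genes are not aligned to single-cell genes; run align_genes first")
        p_bulk = aggregate_to_distribution(y_bulk.values, cfg.eps)

    model = BisModel(g, cfg)
    model.gene_ids = list(x.col_ids)
    params = model.W + model.b
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A17]))
    history = TrainHistory()
    C = cfg.C

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        comps = np.zeros(3)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:
                continue  # MMD undefined on a single point
            xb = xv[idx]
            z, xhat, cache = model._forward(xb)
            zp = rng.normal(0.0, cfg.sigma_z, size=(idx.size, cfg.bottleneck_dim))

            b = idx.size
            recon = float(np.sum((xb - xhat) ** 2) / b)
            mmd = mmd_penalty(LatentBatch(z), LatentBatch(zp, "prior"), C)
            d_xhat = 2.0 * (xhat - xb) / b
            d_z = cfg.lam * _mmd_grad_zq(z, zp, C)

            if p_bulk is not None:
                m_plus = xhat.mean(axis=0) + cfg.eps
                s = m_plus.sum()
                q = m_plus / s
                kl = bulk_consistency_kl(p_bulk, q)
                # d KL / d xhat_{ig} = (1 - p_g / q_g) / (s * b)
                d_xhat = d_xhat + cfg.beta * (1.0 - p_bulk / q)[None, :] / (s * b)
            else:
                kl = 0.0

            total = recon + cfg.lam * mmd + cfg.beta * kl
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {_epoch}: recon={recon}, mmd={mmd}, kl={kl}"
                )
            gW, gb = model._backward(cache, z, d_xhat, d_z)
            opt.step(params, gW + gb)
            comps += (recon, mmd, kl)
            n_batches += 1
        recon_e, mmd_e, kl_e = comps / max(n_batches, 1)
        history.append(recon_e, mmd_e, kl_e, recon_e + cfg.lam * mmd_e + cfg.beta * kl_e)

    model.trained = True
    return model, history


def impute(model: BisModel, x: ExpressionMatrix, cfg: BisConfig | None = None) -> ExpressionMatrix:
    """Reconstruct a full expression matrix through the trained model.

    With ``fill_zeros_only`` the observed nonzero entries are copied through
    unchanged and only zeros receive reconstructed values.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    cfg = cfg if cfg is not None else model.cfg
    xhat = model.decode_array(model.encode_array(x.values))
    if cfg.fill_zeros_only:
        xhat = np.where(x.values > 0, x.values, xhat)
    return x.with_values(xhat, layer_tag="imputed")


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: BisModel, path: str) -> None:
    """Persist weights, config and gene list to a single .npz archive."""
    arrays = {f"W{i}": w for i, w in enumerate(model.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.b)})
    arrays["meta"] = np.array(
        json.dumps(
            {
                "config": model.cfg.to_dict(),
                "n_genes": model.n_genes,
                "gene_ids": model.gene_ids,
                "trained": model.trained,
            }
        )
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> BisModel:
    """Restore a model saved by :func:`save_checkpoint`."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = BisConfig.from_dict(meta["config"])
    model = BisModel(meta["n_genes"], cfg)
    model.W = [data[f"W{i}"] for i in range(len(model.W))]
    model.b = [data[f"b{i}"] for i in range(len(model.b))]
    model.trained = bool(meta["trained"])
    model.gene_ids = meta["gene_ids"]
    return model
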