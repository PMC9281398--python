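"""Energy-weighted variational auto-encoder over normalized dihedral angles.

Architecture: the encoder takes the concatenation of the normalized
dihedral vector x (length D) and the scaled energy E*, passes it through
two fully connected ReLU layers of equal width (``layersize``), and emits
the mean mu and log-variance of a diagonal Gaussian in a d-dimensional
latent space.  The decoder maps a latent vector back through two ReLU
layers to dihedrals only — the energy is an encoder input, never a decoder
output.

The loss is

    delta_total = delta_rec + lambda * delta_kld
    delta_rec   = (1/N) sum_i exp(beta * E*_i) * Diff(x_i_in, x_i_out)
    Diff        = mean absolute difference over the D normalized dihedrals
    delta_kld   = (1/N) sum_i 0.5 * sum_j (mu_ij^2 + s2_ij - 1 - ln s2_ij)

A negative energy weight beta down-weights high-energy structures, biasing
the latent space toward the low-energy region of the torsional landscape.
Training is full-batch Adam with plateau-based early stopping; everything
is seeded and reproducible.  Implemented directly in numpy: the networks
are small (two layers, <=128 units) and the training sets are at most a
few thousand records, so explicit backpropagation is fast and dependency
free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "VAEConfig",
    "VAEModel",
    "kl_divergence",
    "weighted_reconstruction_loss",
    "total_loss",
    "reparameterize",
    "train_vae",
    "reconstruction_mae",
]


@dataclass
class VAEConfig:
    input_dim: int
    layersize: int = 80
    latent_dim: int = 2
    lambda_: float = 0.01
    beta: float = 0.0
    epochs: int = 100_000
    seed: int = 0
    learning_rate: float = 1e-3
    early_stop_tol: float = 1e-5
    early_stop_patience: int = 1000

    def __post_init__(self) -> None:
        if self.layersize < 1 or self.latent_dim < 1:
            raise ValueError("layersize and latent_dim must be >= 1")
        if self.lambda_ <= 0 and self.lambda_ != 0.0:
            raise ValueError("lambda_ must be >= 0")
        if self.beta > 0:
            raise ValueError("energy weight beta must be <= 0")


# -- loss pieces (pure functions, used by training and by tests) ------------


def kl_divergence(mu: np.ndarray, sigma2: np.ndarray) -> float:
    """Batch-mean closed-form KL( N(mu, diag sigma2) || N(0, I) )."""
    mu = np.atleast_2d(mu)
    sigma2 = np.atleast_2d(sigma2)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma^2 must be positive")
    per_sample = 0.5 * np.sum(mu**2 + sigma2 - 1.0 - np.log(sigma2), axis=1)
    return float(per_sample.mean())


def weighted_reconstruction_loss(
    x_in: np.ndarray, x_out: np.ndarray, e_star: np.ndarray, beta: float
) -> float:
    """delta_rec: exp(beta*E*)-weighted mean absolute reconstruction error."""
    x_in = np.atleast_2d(x_in)
    x_out = np.atleast_2d(x_out)
    e_star = np.atleast_1d(e_star)
    if x_in.shape != x_out.shape or len(e_star) != x_in.shape[0]:
        raise ValueError("batch shapes do not match")
    diff = np.abs(x_in - x_out).mean(axis=1)
    return float(np.mean(np.exp(beta * e_star) * diff))


def total_loss(delta_rec: float, delta_kld: float, lambda_: float) -> float:
    return float(delta_rec + lambda_ * delta_kld)


def reparameterize(
    mu: np.ndarray, sigma2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """z = mu + sigma * eps, eps ~ N(0, I).  Training-time only."""
    eps = rng.standard_normal(mu.shape)
    return mu + np.sqrt(sigma2) * eps


# -- model ------------------------------------------------------------------


def _init_layer(rng, n_in, n_out):
    # He initialization, appropriate for ReLU hidden layers
    w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
    return w, np.zeros(n_out)


class VAEModel:
    """Encoder/decoder weights plus their hyperparameters.

    Parameter layout: encoder ``e1, e2`` (ReLU), heads ``mu``, ``lv``
    (log-variance, linear); decoder ``d1, d2`` (ReLU), output ``out``
    (linear).  The log-variance head guarantees positive sigma^2.
    """

    _LAYERS = ("e1", "e2", "mu", "lv", "d1", "d2", "out")

    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H, d = config.input_dim, config.layersize, config.latent_dim
        self.params: dict[str, np.ndarray] = {}
        for name, (n_in, n_out) in {
            "e1": (D + 1, H),
            "e2": (H, H),
            "mu": (H, d),
            "lv": (H, d),
            "d1": (d, H),
            "d2": (H, H),
            "out": (H, D),
        }.items():
            w, b = _init_layer(rng, n_in, n_out)
            self.params[f"{name}_w"] = w
            self.params[f"{name}_b"] = b

    # forward passes -------------------------------------------------------

    def encode(self, x: np.ndarray, e_star: np.ndarray):
        """Deterministic encoder pass -> (mu, sigma2), both (N, d)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        e_star = np.atleast_1d(np.asarray(e_star, dtype=float))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim} features, got {x.shape[1]}"
            )
        inp = np.concatenate([x, e_star[:, None]], axis=1)
        p = self.params
        h1 = np.maximum(inp @ p["e1_w"] + p["e1_b"], 0.0)
        h2 = np.maximum(h1 @ p["e2_w"] + p["e2_b"], 0.0)
        mu = h2 @ p["mu_w"] + p["mu_b"]
        logvar = h2 @ p["lv_w"] + p["lv_b"]
        return mu, np.exp(logvar)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        p = self.params
        g1 = np.maximum(z @ p["d1_w"] + p["d1_b"], 0.0)
        g2 = np.maximum(g1 @ p["d2_w"] + p["d2_b"], 0.0)
        return g2 @ p["out_w"] + p["out_b"]

    def latent_points(self, x: np.ndarray, e_star: np.ndarray) -> np.ndarray:
        """Post-training latent data: z = mu (variances are discarded)."""
        mu, _ = self.encode(x, e_star)
        return mu

    # full differentiable pass --------------------------------------------

    def _forward_backward(self, x, e_star, eps):
        """One full-batch loss + gradient evaluation.

        Returns (delta_total, delta_rec, delta_kld, grads).  Gradients of
        the L1 reconstruction term use the sign subgradient; the KL term
        and the reparameterized sample are differentiated exactly.
        """
        p = self.params
        cfg = self.config
        N, D = x.shape
        w_i = np.exp(cfg.beta * e_star)  # (N,)

        inp = np.concatenate([x, e_star[:, None]], axis=1)
        a1 = inp @ p["e1_w"] + p["e1_b"]
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ p["e2_w"] + p["e2_b"]
        h2 = np.maximum(a2, 0.0)
        mu = h2 @ p["mu_w"] + p["mu_b"]
        logvar = h2 @ p["lv_w"] + p["lv_b"]
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * eps
        a3 = z @ p["d1_w"] + p["d1_b"]
        g1 = np.maximum(a3, 0.0)
        a4 = g1 @ p["d2_w"] + p["d2_b"]
        g2 = np.maximum(a4, 0.0)
        x_out = g2 @ p["out_w"] + p["out_b"]

        resid = x_out - x
        diff = np.abs(resid).mean(axis=1)
        delta_rec = float(np.mean(w_i * diff))
        delta_kld = 0.5 * float(
            np.mean(np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1))
        )
        delta = total_loss(delta_rec, delta_kld, cfg.lambda_)

        grads = {}
        # reconstruction head
        d_xout = np.sign(resid) * (w_i / (N * D))[:, None]
        grads["out_w"] = g2.T @ d_xout
        grads["out_b"] = d_xout.sum(0)
        d_g2 = (d_xout @ p["out_w"].T) * (a4 > 0)
        grads["d2_w"] = g1.T @ d_g2
        grads["d2_b"] = d_g2.sum(0)
        d_g1 = (d_g2 @ p["d2_w"].T) * (a3 > 0)
        grads["d1_w"] = z.T @ d_g1
        grads["d1_b"] = d_g1.sum(0)
        d_z = d_g1 @ p["d1_w"].T
        # reparameterization + KL
        d_mu = d_z + cfg.lambda_ * mu / N
        d_logvar = (
            d_z * eps * 0.5 * sigma
            + cfg.lambda_ * 0.5 * (np.exp(logvar) - 1.0) / N
        )
        grads["mu_w"] = h2.T @ d_mu
        grads["mu_b"] = d_mu.sum(0)
        grads["lv_w"] = h2.T @ d_logvar
        grads["lv_b"] = d_logvar.sum(0)
        d_h2 = (d_mu @ p["mu_w"].T + d_logvar @ p["lv_w"].T) * (a2 > 0)
        grads["e2_w"] = h1.T @ d_h2
        grads["e2_b"] = d_h2.sum(0)
        d_h1 = (d_h2 @ p["e2_w"].T) * (a1 > 0)
        grads["e1_w"] = inp.T @ d_h1
        grads["e1_b"] = d_h1.sum(0)
        return delta, delta_rec, delta_kld, grads

    # persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing JSON checkpoint: config plus flat weight lists."""
        blob = {
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "VAEModel":
        blob = json.loads(Path(path).read_text())
        model = cls(VAEConfig(**blob["config"]))
        for k, v in blob["params"].items():
            model.params[k] = np.asarray(v, dtype=float)
        return model


def train_vae(
    config: VAEConfig,
    x: np.ndarray,
    e_star: np.ndarray,
    model: VAEModel | None = None,
) -> tuple[VAEModel, dict]:
    """Train (or warm-start) the VAE by full-batch Adam.

    Parameters
    ----------
    x, e_star : the VAE-included subset of the pool — normalized dihedrals
        in [-1, 1]^D and their scaled energies.
    model : pass an existing model to warm-start; by default the network is
        re-initialized from ``config.seed``.

    Returns the trained model and a history dict with per-epoch
    ``total`` / ``rec`` / ``kld`` losses.  Stops early once the running
    minimum of the total loss improves by less than ``early_stop_tol``
    (relative) over ``early_stop_patience`` epochs.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    e_star = np.atleast_1d(np.asarray(e_star, dtype=float))
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if model is None:
        model = VAEModel(config)
    rng = np.random.default_rng(config.seed + 1)

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    b1, b2, lr, eps_adam = 0.9, 0.999, config.learning_rate, 1e-8

    history = {"total": [], "rec": [], "kld": []}
    running_min: list[float] = []
    for epoch in range(1, config.epochs + 1):
        eps = rng.standard_normal((x.shape[0], config.latent_dim))
        delta, d_rec, d_kld, grads = model._forward_backward(x, e_star, eps)
        history["total"].append(delta)
        history["rec"].append(d_rec)
        history["kld"].append(d_kld)
        for k, g in grads.items():
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1**epoch)
            vhat = v[k] / (1 - b2**epoch)
            model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps_adam)
        best = delta if not running_min else min(running_min[-1], delta)
        running_min.append(best)
        if epoch > config.early_stop_patience:
            prev = running_min[-config.early_stop_patience - 1]
            if prev - best < config.early_stop_tol * max(abs(prev), 1e-12):
                break
    return model, history


def reconstruction_mae(
    model: VAEModel, x: np.ndarray, e_star: np.ndarray, ranges=None
) -> float:
    """Deterministic input->output MAE, reported in degrees.

    Encodes with z = mu (no sampling), decodes, and averages the absolute
    difference over records and dimensions.  Each normalized unit spans
    half the dimension's declared range; without ``ranges`` a full 360 deg
    circle is assumed (1 unit = 180 deg).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_out = model.decode(model.latent_points(x, e_star))
    err = np.abs(x - x_out)
    if ranges is None:
        return float(err.mean() * 180.0)
    half_span = np.array([(hi - lo) / 2.0 for lo, hi, *_ in ranges])
    return float((err * half_span).mean())
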