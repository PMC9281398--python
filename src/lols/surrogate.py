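"""Real-space energy model: Gaussian-process regression over torsions.

The covariance is the standard periodic (exp-sine-squared) kernel with one
period and one lengthscale per dimension,

    k(x, x') = s2 * exp( - sum_d 2 sin^2(pi (x_d - x'_d)/p_d) / l_d^2 ),

fitted to scaled energies E* against dihedrals normalized to [-1, 1] (so
p_d = 2 on every periodic dimension; aperiodic dimensions fall back to a
squared-exponential factor).  Observation noise is held fixed during the
fit (0.001 eV by default, the accuracy scale of a good quantum-chemistry
single point).  The constant mean is profiled out by generalized least
squares at every likelihood evaluation — an uninformative prior on the GP
mean.  Signal variance and lengthscales are chosen by maximum a
posteriori: log marginal likelihood plus weak inverse-gamma priors that
keep lengthscales in a physically sensible band (roughly 5-120 degrees).

Local minima of the posterior mean are extracted by conjugate-gradient
descent started from every training input, with coordinates wrapped into
their periodic spans, then merged: candidates closer than 15 degrees mean
circular dihedral distance are grouped (single linkage) and only the
lowest-energy member of each group survives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .energy_backend import _dedup_minima
from .preprocessing import DataPool, denormalize_angles, normalize_angles

__all__ = [
    "EnergyModel",
    "fit_energy_model",
    "predict_energy",
    "extract_local_minima",
    "merge_similar",
]

logger = logging.getLogger(__name__)

# inverse-gamma hyperpriors (shape, scale) on lengthscale and signal
# variance, in normalized units where the full angle range spans 2
_ELL_PRIOR = (3.0, 1.2)  # mode 0.3 ~ 54 deg on a 360 deg dimension
_SF2_PRIOR = (2.0, 1.0)

MAX_STARTS = 5000  # CG start-point thinning bound


@dataclass
class EnergyModel:
    """A fitted periodic-kernel GP over normalized dihedrals."""

    ranges: list
    X: np.ndarray  # (n, D) normalized training inputs
    y: np.ndarray  # (n,) training targets (E* by default)
    noise: float
    log_sf2: float
    log_ell: np.ndarray  # (D,)
    mean_const: float
    alpha: np.ndarray  # K_y^{-1} (y - mean)
    _cho: tuple

    @property
    def periodic(self) -> np.ndarray:
        return np.array([bool(r[2]) for r in self.ranges])

    def _cross_kernel(self, Xs: np.ndarray) -> np.ndarray:
        return _kernel(
            Xs, self.X, np.exp(self.log_sf2), np.exp(self.log_ell),
            self.periodic,
        )

    def predict_normalized(self, Xs: np.ndarray):
        """(posterior mean, sd) at normalized inputs."""
        Xs = np.atleast_2d(Xs)
        Ks = self._cross_kernel(Xs)
        mean = self.mean_const + Ks @ self.alpha
        v = cho_solve(self._cho, Ks.T)
        var = np.exp(self.log_sf2) - np.einsum("ij,ji->i", Ks, v)
        return mean, np.sqrt(np.maximum(var, 0.0))

    def predict_mean_normalized(self, x: np.ndarray) -> float:
        """Posterior mean only (no variance solve) at one normalized point."""
        k = self._cross_kernel(np.atleast_2d(x))[0]
        return float(self.mean_const + k @ self.alpha)

    def mean_gradient_normalized(self, x: np.ndarray) -> np.ndarray:
        """Analytic gradient of the posterior mean at one normalized point."""
        x = np.asarray(x, dtype=float)
        k = self._cross_kernel(x[None, :])[0]  # (n,)
        ell2 = np.exp(2.0 * self.log_ell)
        grad = np.zeros_like(x)
        delta = x[None, :] - self.X  # (n, D)
        for d in range(len(x)):
            if self.periodic[d]:
                # d/dx of -2 sin^2(pi delta / 2) / l^2, period 2
                dk = -(np.pi / ell2[d]) * np.sin(np.pi * delta[:, d])
            else:
                dk = -delta[:, d] / ell2[d]
            grad[d] = np.sum(self.alpha * k * dk)
        return grad


def _kernel(A, B, sf2, ell, periodic):
    """Periodic / squared-exponential product kernel matrix."""
    expo = np.zeros((A.shape[0], B.shape[0]))
    for d in range(A.shape[1]):
        delta = A[:, d, None] - B[None, :, d]
        if periodic[d]:
            expo += 2.0 * np.sin(np.pi * delta / 2.0) ** 2 / ell[d] ** 2
        else:
            expo += 0.5 * delta**2 / ell[d] ** 2
    return sf2 * np.exp(-expo)


def _neg_log_posterior(theta, X, y, noise, periodic):
    """Negative (profiled-mean) log marginal likelihood + priors, w/ grad."""
    n, D = X.shape
    sf2 = np.exp(theta[0])
    ell = np.exp(theta[1:])
    K = _kernel(X, X, sf2, ell, periodic)
    if not np.all(np.isfinite(K)):
        return 1e12, np.zeros_like(theta)
    Ky = K + (noise**2) * np.eye(n)
    try:
        cho = cho_factor(Ky, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("degenerate kernel matrix: adding jitter")
        Ky += 1e-8 * sf2 * np.eye(n)
        try:
            cho = cho_factor(Ky, lower=True)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
    ones = np.ones(n)
    Kinv_y = cho_solve(cho, y)
    Kinv_1 = cho_solve(cho, ones)
    c = (ones @ Kinv_y) / (ones @ Kinv_1)
    r = y - c
    alpha = cho_solve(cho, r)
    nll = 0.5 * r @ alpha + np.sum(np.log(np.diag(cho[0]))) \
        + 0.5 * n * np.log(2.0 * np.pi)
    # inverse-gamma priors: -log p(x) = (a+1) log x + b / x  (+ const)
    a_l, b_l = _ELL_PRIOR
    nll += np.sum((a_l + 1.0) * np.log(ell) + b_l / ell)
    a_s, b_s = _SF2_PRIOR
    nll += (a_s + 1.0) * np.log(sf2) + b_s / sf2

    # gradient via the trace identity; profiled mean is enveloped out
    Kinv = cho_solve(cho, np.eye(n))
    W = Kinv - np.outer(alpha, alpha)
    grad = np.empty_like(theta)
    grad[0] = 0.5 * np.sum(W * K) + (a_s + 1.0) - b_s / sf2
    for d in range(D):
        delta = X[:, d, None] - X[None, :, d]
        if periodic[d]:
            s2 = 2.0 * np.sin(np.pi * delta / 2.0) ** 2
        else:
            s2 = 0.5 * delta**2
        dK_dlog_ell = K * (2.0 * s2 / ell[d] ** 2)
        grad[1 + d] = 0.5 * np.sum(W * dK_dlog_ell) \
            + (a_l + 1.0) - b_l / ell[d]
    return nll, grad


def fit_energy_model(
    pool: DataPool | tuple,
    noise: float = 0.001,
    use_scaled: bool = True,
    seed: int = 0,
    n_restarts: int = 2,
) -> EnergyModel:
    """Fit the GP energy model to the full data pool (MAP hyperparameters).

    All pool records participate, including those excluded from VAE
    training by the alpha-cutoff.  ``use_scaled`` selects E* (default) or
    raw E as the regression target; the monotone scaling preserves every
    minimum location, so the choice only affects conditioning.
    """
    if isinstance(pool, DataPool):
        X = pool.normalized_angles()
        y = pool.scaled_energies() if use_scaled else pool.energies()
        ranges = pool.ranges
    else:
        X, y, ranges = pool
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
    n, D = X.shape
    if n < 2 * D:
        raise ValueError(f"need at least {2 * D} records, got {n}")
    periodic = np.array([bool(r[2]) for r in ranges])

    y_center = y - y.mean()
    y_sd = max(float(y_center.std()), 1e-8)
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.concatenate([[np.log(y_sd**2)], np.full(D, np.log(0.3))])]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(
            np.concatenate(
                [
                    [np.log(y_sd**2) + rng.normal(0, 0.5)],
                    np.log(rng.uniform(0.1, 0.8, D)),
                ]
            )
        )
    # bounds keep the optimizer away from degenerate kernels (lengthscale
    # collapse / variance blow-up) where the Cholesky factorization fails
    bounds = [(np.log(y_sd**2) - 8.0, np.log(y_sd**2) + 8.0)] + [
        (np.log(1e-3), np.log(50.0))
    ] * D
    for theta0 in starts:
        res = optimize.minimize(
            _neg_log_posterior,
            theta0,
            args=(X, y, noise, periodic),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    sf2, ell = np.exp(theta[0]), np.exp(theta[1:])
    K = _kernel(X, X, sf2, ell, periodic)
    Ky = K + (noise**2) * np.eye(n)
    cho = cho_factor(Ky, lower=True)
    ones = np.ones(n)
    c = (ones @ cho_solve(cho, y)) / (ones @ cho_solve(cho, ones))
    alpha = cho_solve(cho, y - c)
    return EnergyModel(
        ranges=list(ranges),
        X=X,
        y=y,
        noise=noise,
        log_sf2=float(theta[0]),
        log_ell=theta[1:].copy(),
        mean_const=float(c),
        alpha=alpha,
        _cho=cho,
    )


def predict_energy(model: EnergyModel, angles) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, sd) at dihedral vectors given in degrees."""
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    lows = np.array([r[0] for r in model.ranges])
    spans = np.array([r[1] - r[0] for r in model.ranges])
    periodic = model.periodic
    wrapped = angles.copy()
    wrapped[:, periodic] = (
        lows[periodic]
        + np.mod(angles[:, periodic] - lows[periodic], spans[periodic])
    )
    X = normalize_angles(wrapped, model.ranges)
    return model.predict_normalized(X)


def _wrap_normalized(x: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[periodic] = np.mod(x[periodic] + 1.0, 2.0) - 1.0
    return out


def extract_local_minima(
    model: EnergyModel,
    starts: np.ndarray | None = None,
    gtol: float = 1e-5,
    seed: int = 0,
) -> list[tuple[np.ndarray, float]]:
    """Conjugate-gradient minima of the posterior mean from every training point.

    Returns (angles_degrees, predicted E*) for each converged endpoint
    (posterior-mean gradient norm <= ``gtol`` in normalized units).
    Non-converged starts are skipped with a log entry.  When the pool
    exceeds 5000 records the starts are subsampled (uniform, seeded).
    """
    X0 = model.X if starts is None else np.atleast_2d(starts)
    if X0.shape[0] > MAX_STARTS:
        idx = np.random.default_rng(seed).choice(
            X0.shape[0], MAX_STARTS, replace=False
        )
        X0 = X0[idx]
    periodic = model.periodic
    out = []
    for i, x0 in enumerate(X0):
        res = optimize.minimize(
            model.predict_mean_normalized,
            x0,
            jac=model.mean_gradient_normalized,
            method="CG",
            options={"gtol": gtol, "maxiter": 500},
        )
        grad_norm = float(np.linalg.norm(
            model.mean_gradient_normalized(res.x)
        ))
        if grad_norm > gtol * 10:
            logger.debug("start %d did not converge (|g|=%.2e)", i, grad_norm)
            continue
        x_min = _wrap_normalized(res.x, periodic)
        angles = denormalize_angles(x_min, model.ranges)
        out.append((angles, float(res.fun)))
    return out


def merge_similar(
    candidates, ranges, threshold: float = 15.0
) -> list[tuple[np.ndarray, float]]:
    """Purge duplicate minima: single-linkage groups under mean circular
    dihedral distance < ``threshold`` degrees keep only their lowest-energy
    member; ties break by lexicographic angle order.  Sorted by energy."""
    return _dedup_minima(list(candidates), ranges, threshold)
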