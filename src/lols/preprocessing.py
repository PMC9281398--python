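"""Feature normalization, energy scaling and the high-energy VAE cutoff.

Dihedral angles are mapped linearly from their declared ranges onto
[-1, 1].  Raw backend energies E (eV) are shifted by a per-molecule
threshold E0 and compressed logarithmically above it:

    E* = E - E0                 for E <= E0
    E* = ln(1 + (E - E0))       for E >  E0

The transform is continuous and strictly increasing, keeps energies near
E0 close to zero, and above E0 never expands raw energy increments —
high-energy structure is flattened so it cannot dominate model fitting,
while the energy ordering (and hence every minimum location) is preserved.

Records whose scaled energy exceeds mean(E*) + alpha * std(E*) are
excluded from VAE training but stay in the pool for the energy model.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "normalize_angles",
    "denormalize_angles",
    "scale_energy",
    "vae_cutoff",
    "DataPool",
]


def _bounds(ranges) -> tuple[np.ndarray, np.ndarray]:
    lows = np.array([r[0] for r in ranges], dtype=float)
    highs = np.array([r[1] for r in ranges], dtype=float)
    return lows, highs


def normalize_angles(angles: np.ndarray, ranges) -> np.ndarray:
    """Map degrees in [low, high] linearly onto [-1, 1] per dimension."""
    angles = np.asarray(angles, dtype=float)
    lows, highs = _bounds(ranges)
    if np.any(angles < lows - 1e-9) or np.any(angles > highs + 1e-9):
        raise ValueError("angle outside its declared range")
    return 2.0 * (angles - lows) / (highs - lows) - 1.0


def denormalize_angles(x: np.ndarray, ranges) -> np.ndarray:
    """Exact inverse of :func:`normalize_angles`."""
    x = np.asarray(x, dtype=float)
    lows, highs = _bounds(ranges)
    return lows + (x + 1.0) * (highs - lows) / 2.0


def scale_energy(E, E0: float):
    """Scaled energy E*: linear shift below E0, ln(1 + dE) above it."""
    E = np.asarray(E, dtype=float)
    dE = E - E0
    out = np.where(dE <= 0.0, dE, np.log1p(np.maximum(dE, 0.0)))
    return float(out) if out.ndim == 0 else out


class DataPool:
    """The growing training set of the active-learning loop.

    Backed by a pandas DataFrame with columns ``angle_1 .. angle_D``
    (degrees), ``energy_eV``, ``scaled_energy``, ``vae_included``,
    ``iteration`` and ``run_id``.  Raw energies are the source of truth:
    scaled energies are recomputed whenever E0 changes.
    """

    def __init__(self, ranges, E0: float | None = None):
        self.ranges = list(ranges)
        self.D = len(self.ranges)
        self._E0 = E0
        cols = self.angle_columns + [
            "energy_eV",
            "scaled_energy",
            "vae_included",
            "iteration",
            "run_id",
        ]
        self.frame = pd.DataFrame(columns=cols).astype(
            {"vae_included": bool, "iteration": int}
        )

    @property
    def angle_columns(self) -> list[str]:
        return [f"angle_{i + 1}" for i in range(self.D)]

    @property
    def E0(self) -> float | None:
        return self._E0

    def set_E0(self, E0: float) -> None:
        """Fix the threshold energy and rescale every stored record."""
        self._E0 = float(E0)
        if len(self.frame):
            self.frame["scaled_energy"] = scale_energy(
                self.frame["energy_eV"].to_numpy(), self._E0
            )

    def add(self, angles: np.ndarray, energies: np.ndarray,
            iteration: int = 0, run_id: str = "run0") -> None:
        angles = np.atleast_2d(np.asarray(angles, dtype=float))
        energies = np.atleast_1d(np.asarray(energies, dtype=float))
        if angles.shape != (len(energies), self.D):
            raise ValueError("angles / energies shape mismatch")
        if self._E0 is None:
            # default threshold: the minimum energy seen in the initial data
            self._E0 = float(energies.min())
        block = pd.DataFrame(angles, columns=self.angle_columns)
        block["energy_eV"] = energies
        block["scaled_energy"] = scale_energy(energies, self._E0)
        block["vae_included"] = True
        block["iteration"] = int(iteration)
        block["run_id"] = run_id
        frames = [df for df in (self.frame, block) if len(df)]
        self.frame = pd.concat(frames, ignore_index=True)

    def __len__(self) -> int:
        return len(self.frame)

    # -- views ------------------------------------------------------------

    def angles(self) -> np.ndarray:
        return self.frame[self.angle_columns].to_numpy(dtype=float)

    def normalized_angles(self) -> np.ndarray:
        return normalize_angles(self.angles(), self.ranges)

    def energies(self) -> np.ndarray:
        return self.frame["energy_eV"].to_numpy(dtype=float)

    def scaled_energies(self) -> np.ndarray:
        return self.frame["scaled_energy"].to_numpy(dtype=float)

    def vae_subset(self) -> tuple[np.ndarray, np.ndarray]:
        """(normalized angles, E*) of the records kept for VAE training."""
        mask = self.frame["vae_included"].to_numpy(dtype=bool)
        return self.normalized_angles()[mask], self.scaled_energies()[mask]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, ranges, E0: float | None = None) -> "DataPool":
        pool = cls(ranges, E0=E0)
        pool.frame = pd.read_csv(path)
        if E0 is not None:
            pool.set_E0(E0)
        elif len(pool.frame):
            pool._E0 = float(pool.frame["energy_eV"].min())
            pool.set_E0(pool._E0)
        return pool


def vae_cutoff(pool: DataPool, alpha: float = 2.0) -> float:
    """Flag records with E* above mean + alpha * std as excluded from the VAE.

    The threshold uses the population standard deviation over the whole
    pool.  Exclusion is strict (ties at the threshold are retained) and the
    flagged records stay in the pool for the energy model.  Returns the
    threshold E*_max.  Idempotent: the flags are a pure function of the
    stored scaled energies.
    """
    if not len(pool):
        raise ValueError("empty data pool")
    estar = pool.scaled_energies()
    emax = float(estar.mean() + alpha * estar.std())
    pool.frame["vae_included"] = estar <= emax
    return emax
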