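"""Pluggable energy oracles.

The production workflow treats the energy source as a black box mapping a
dihedral vector to a raw energy in eV (or to "invalid" when the structure
is unphysical or the engine fails).  Three backends are provided:

* :class:`SyntheticPES` — a periodic multi-well test landscape over D
  torsions whose local minima can be enumerated exactly by brute force.
  It is the desk-scale stand-in for a quantum-chemistry engine and the
  ground truth for all benchmarks.
* :class:`CallableBackend` — wraps any ``f(angles) -> eV`` python callable.
* :class:`ExternalBackend` — a templated-command stub for real engines:
  writes an XYZ file, runs the command, parses one energy in eV from its
  output.  No engine is bundled.

Synthetic PES closed form, with u_d = 2*pi*(theta_d - low_d)/span_d:

    E(theta) = base + sum_d [ A_d cos(c_d u_d + phi_d)
                              + eps_d cos(u_d + psi_d) ]
             + cs * sum_{d<e} B_de cos(u_d - u_e + chi_de)

The dominant harmonic of order c_d carves c_d wells along dimension d (the
per-dimension counts multiply to roughly the requested total number of
wells); the weak order-1 "tilt" term breaks the well degeneracy so the
landscape has a unique global minimum; the pairwise cosine couplings (cs =
``coupling_strength``) correlate neighbouring torsions the way real
torsional profiles do.  The function is smooth and exactly periodic in
every dimension.
"""

from __future__ import annotations

import re
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage, optimize

from .molecule import (
    Conformation,
    MoleculeSpec,
    apply_dihedrals,
    detect_clash,
    dihedral_distance,
    write_xyz,
)

__all__ = [
    "SyntheticPES",
    "make_synthetic_pes",
    "evaluate",
    "bruteforce_minima",
    "CallableBackend",
    "ExternalBackend",
    "MolecularBackend",
]

_TWO_PI = 2.0 * np.pi


def _well_counts(dim: int, n_wells: int) -> list[int]:
    """Distribute ~n_wells minima over dimensions as per-axis well counts.

    Factorizes n_wells into primes and multiplies them onto the axes round
    robin, so the product of the counts equals n_wells whenever it fits
    (each axis is capped at 6 wells to keep the landscape resolvable).
    """
    factors = []
    rem = n_wells
    p = 2
    while rem > 1:
        while rem % p == 0:
            factors.append(p)
            rem //= p
        p += 1
    counts = [1] * dim
    for f in sorted(factors, reverse=True):
        axis = int(np.argmin(counts))
        if counts[axis] * f <= 6:
            counts[axis] *= f
    return counts


@dataclass
class SyntheticPES:
    """Parameters of the periodic multi-well test energy function."""

    dim: int
    counts: list[int]
    amplitudes: np.ndarray  # A_d, eV
    phases: np.ndarray  # phi_d
    tilt_amps: np.ndarray  # eps_d, eV
    tilt_phases: np.ndarray  # psi_d
    couplings: list[tuple[int, int, float, float]]  # (d, e, B_de, chi_de)
    coupling_strength: float
    base_energy: float
    seed: int
    lows: np.ndarray = field(default=None)
    spans: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.lows is None:
            self.lows = np.zeros(self.dim)
        if self.spans is None:
            self.spans = np.full(self.dim, 360.0)
        for name in ("amplitudes", "phases", "tilt_amps", "tilt_phases",
                     "lows", "spans"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def ranges(self) -> list[tuple[float, float, bool]]:
        return [
            (float(lo), float(lo + sp), True)
            for lo, sp in zip(self.lows, self.spans)
        ]

    # -- energy and analytic gradient -------------------------------------

    def _u(self, angles: np.ndarray) -> np.ndarray:
        return _TWO_PI * (angles - self.lows) / self.spans

    def energy(self, angles: np.ndarray) -> np.ndarray:
        """Vectorized energy (eV); ``angles`` is (..., dim) in degrees."""
        angles = np.asarray(angles, dtype=float)
        u = self._u(angles)
        e = np.full(u.shape[:-1], self.base_energy)
        for d in range(self.dim):
            e = e + self.amplitudes[d] * np.cos(
                self.counts[d] * u[..., d] + self.phases[d]
            )
            e = e + self.tilt_amps[d] * np.cos(u[..., d] + self.tilt_phases[d])
        for d, j, B, chi in self.couplings:
            e = e + self.coupling_strength * B * np.cos(
                u[..., d] - u[..., j] + chi
            )
        return e

    def gradient(self, angles: np.ndarray) -> np.ndarray:
        """Analytic dE/dtheta, eV per degree, shape (..., dim)."""
        angles = np.asarray(angles, dtype=float)
        u = self._u(angles)
        dedu = np.zeros_like(u)
        for d in range(self.dim):
            dedu[..., d] = -self.amplitudes[d] * self.counts[d] * np.sin(
                self.counts[d] * u[..., d] + self.phases[d]
            ) - self.tilt_amps[d] * np.sin(u[..., d] + self.tilt_phases[d])
        for d, j, B, chi in self.couplings:
            s = self.coupling_strength * B * np.sin(u[..., d] - u[..., j] + chi)
            dedu[..., d] -= s
            dedu[..., j] += s
        return dedu * (_TWO_PI / self.spans)

    def evaluate(self, conf: Conformation | np.ndarray) -> float | None:
        angles = conf.angles if isinstance(conf, Conformation) else conf
        return float(self.energy(np.asarray(angles, dtype=float)))

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "counts": list(map(int, self.counts)),
            "amplitudes": self.amplitudes.tolist(),
            "phases": self.phases.tolist(),
            "tilt_amps": self.tilt_amps.tolist(),
            "tilt_phases": self.tilt_phases.tolist(),
            "couplings": [
                [int(d), int(e), float(b), float(c)]
                for d, e, b, c in self.couplings
            ],
            "coupling_strength": float(self.coupling_strength),
            "base_energy": float(self.base_energy),
            "seed": int(self.seed),
            "lows": self.lows.tolist(),
            "spans": self.spans.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticPES":
        data = dict(data)
        data["couplings"] = [tuple(c) for c in data["couplings"]]
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticPES":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_synthetic_pes(
    dim: int,
    n_wells: int,
    coupling_strength: float = 0.05,
    seed: int = 0,
    base_energy: float = -2.0e4,
) -> SyntheticPES:
    """Deterministically build a periodic multi-well PES for a seed.

    Well depths are drawn in 0.12-0.25 eV (typical torsional barrier
    scale), the symmetry-breaking tilt at 4-8% of the main amplitude, and
    every torsion pair is coupled with a random phase.  The base energy
    defaults to -20,000 eV to exercise the absolute-energy-shift pathway
    the way a real total-energy engine would.
    """
    rng = np.random.default_rng(seed)
    counts = _well_counts(dim, n_wells)
    amplitudes = rng.uniform(0.12, 0.25, dim)
    phases = rng.uniform(0.0, _TWO_PI, dim)
    tilt_amps = rng.uniform(0.04, 0.08, dim) * amplitudes
    tilt_phases = rng.uniform(0.0, _TWO_PI, dim)
    couplings = []
    for d in range(dim):
        for e in range(d + 1, dim):
            couplings.append(
                (d, e, float(rng.uniform(0.5, 1.0)), float(rng.uniform(0.0, _TWO_PI)))
            )
    return SyntheticPES(
        dim=dim,
        counts=counts,
        amplitudes=amplitudes,
        phases=phases,
        tilt_amps=tilt_amps,
        tilt_phases=tilt_phases,
        couplings=couplings,
        coupling_strength=coupling_strength,
        base_energy=base_energy,
        seed=seed,
    )


def evaluate(backend, conf) -> float | None:
    """Raw backend energy of a conformation, or None when invalid."""
    return backend.evaluate(conf)


def _wrap(angles: np.ndarray, pes: SyntheticPES) -> np.ndarray:
    return pes.lows + np.mod(angles - pes.lows, pes.spans)


def bruteforce_minima(
    pes: SyntheticPES, grid_points_per_dim: int = 24
) -> list[tuple[np.ndarray, float]]:
    """Enumerate all local minima of a synthetic PES exactly.

    Scans the full periodic grid, keeps points that are minimal within
    their 3^D wrap-around neighbourhood, polishes each by gradient-based
    local minimization, merges duplicates (mean circular dihedral distance
    < 15 deg, lowest energy kept) and returns the list sorted by energy.
    This enumeration is the reference oracle for every benchmark.
    """
    n = grid_points_per_dim
    if n < 3 * max(pes.counts):
        warnings.warn(
            f"grid of {n} points/dim may be too coarse for "
            f"{max(pes.counts)} wells along one dimension"
        )
    axes = [
        pes.lows[d] + pes.spans[d] * np.arange(n) / n for d in range(pes.dim)
    ]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    energies = pes.energy(mesh)
    local_min = energies <= ndimage.minimum_filter(
        energies, size=3, mode="wrap"
    )
    starts = mesh[local_min]

    polished = []
    for start in starts:
        res = optimize.minimize(
            lambda a: pes.energy(a),
            start,
            jac=lambda a: pes.gradient(a),
            method="CG",
            options={"gtol": 1e-10},
        )
        polished.append((_wrap(res.x, pes), float(res.fun)))
    return _dedup_minima(polished, pes.ranges)


def _dedup_minima(candidates, ranges, threshold: float = 15.0):
    """Single-linkage merge under mean circular distance; keep lowest E."""
    if not candidates:
        return []
    m = len(candidates)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            mean_d, _ = dihedral_distance(
                candidates[i][0], candidates[j][0], ranges
            )
            if mean_d < threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(candidates[i])
    kept = []
    for members in groups.values():
        members.sort(key=lambda t: (t[1], tuple(np.round(t[0], 9))))
        kept.append(members[0])
    kept.sort(key=lambda t: (t[1], tuple(np.round(t[0], 9))))
    return kept


# -- backends for real molecules -------------------------------------------


class CallableBackend:
    """Adapter: any ``f(angles_degrees) -> energy_eV`` callable."""

    def __init__(self, func, gradient=None):
        self._func = func
        if gradient is not None:
            # only expose the attribute when a gradient exists, so callers
            # can probe with hasattr and fall back to finite differences
            self.gradient = lambda a: gradient(np.asarray(a, dtype=float))

    def evaluate(self, conf) -> float | None:
        angles = conf.angles if isinstance(conf, Conformation) else conf
        try:
            e = self._func(np.asarray(angles, dtype=float))
        except Exception:
            return None
        return None if e is None or not np.isfinite(e) else float(e)


class ExternalBackend:
    """Command-template stub for external quantum-chemistry engines.

    ``command`` is a shell template containing ``{xyz}``, e.g.
    ``"my_engine --geom {xyz}"``.  The engine must print a single energy in
    eV matched by ``energy_regex`` (default: last float on a line starting
    with 'energy').  A non-zero exit status or an unparsable output marks
    the conformation invalid.
    """

    def __init__(
        self,
        spec: MoleculeSpec,
        command: str,
        energy_regex: str = r"energy[^-\d]*(-?\d+\.?\d*(?:[eE][+-]?\d+)?)",
        workdir: str | Path = ".",
        clash_scale: float = 0.7,
    ):
        self.spec = spec
        self.command = command
        self.energy_regex = re.compile(energy_regex, re.IGNORECASE)
        self.workdir = Path(workdir)
        self.clash_scale = clash_scale

    def evaluate(self, conf) -> float | None:
        if not isinstance(conf, Conformation) or conf.coords is None:
            angles = conf.angles if isinstance(conf, Conformation) else conf
            conf = apply_dihedrals(self.spec, np.asarray(angles, dtype=float))
        if detect_clash(conf, self.spec, self.clash_scale):
            return None
        xyz = self.workdir / "lols_input.xyz"
        write_xyz(xyz, self.spec.symbols, conf.coords, comment=self.spec.name)
        try:
            out = subprocess.run(
                self.command.format(xyz=xyz),
                shell=True,
                capture_output=True,
                text=True,
                check=True,
            ).stdout
        except subprocess.CalledProcessError:
            return None
        match = None
        for match in self.energy_regex.finditer(out):
            pass
        return float(match.group(1)) if match else None


class MolecularBackend:
    """Clash-checking wrapper around a torsion-space energy callable.

    Realizes the Cartesian structure, rejects steric clashes (non-bonded
    pair closer than ``clash_scale`` times the covalent-radius sum) and
    only then calls the energy function — mirroring how failed engine
    single points mark a sample invalid.
    """

    def __init__(self, spec: MoleculeSpec, func, clash_scale: float = 0.7):
        self.spec = spec
        self._func = func
        self.clash_scale = clash_scale

    def evaluate(self, conf) -> float | None:
        if not isinstance(conf, Conformation) or conf.coords is None:
            angles = conf.angles if isinstance(conf, Conformation) else conf
            conf = apply_dihedrals(self.spec, np.asarray(angles, dtype=float))
        if detect_clash(conf, self.spec, self.clash_scale):
            return None
        e = self._func(conf.angles)
        return None if e is None or not np.isfinite(e) else float(e)
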