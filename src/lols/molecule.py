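"""Flexible-molecule representation for torsion-space conformer search.

A molecule is a rigid skeleton (reference Cartesian geometry, all bond
lengths and bond angles frozen) plus an ordered list of rotatable dihedral
angles.  The free dihedrals are the search coordinates; everything here is
in degrees and angstroms, with 0-based atom indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Dihedral",
    "MoleculeSpec",
    "Conformation",
    "measure_dihedral",
    "apply_dihedrals",
    "detect_clash",
    "dihedral_distance",
    "read_xyz",
    "write_xyz",
    "write_multi_xyz",
    "load_molecule_spec",
]

# Cordero covalent radii, angstrom.  Enough elements for organic molecules;
# unknown symbols fall back to 0.75 A.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_DEFAULT_RADIUS = 0.75

# factor applied to the radius sum when inferring bonds from geometry
BOND_FACTOR = 1.2


class TopologyError(ValueError):
    """Raised when a rotatable bond lies inside a ring or indices are bad."""


@dataclass(frozen=True)
class Dihedral:
    """One searchable torsion: four atom indices (a, b, c, d) and its range.

    The rotation axis is the bond b-c; setting the torsion rotates the
    subtree on the d-side.  ``periodic`` marks dimensions whose range is a
    full (or symmetry-halved) period, so distances wrap with span
    ``high - low``.
    """

    indices: tuple[int, int, int, int]
    low: float = 0.0
    high: float = 360.0
    periodic: bool = True

    @property
    def span(self) -> float:
        return self.high - self.low


@dataclass
class MoleculeSpec:
    """Skeleton geometry plus the ordered list of free dihedrals.

    Parameters
    ----------
    symbols : list of element symbols
    coords : (n_atoms, 3) reference Cartesian coordinates, angstrom
    dihedrals : free (searchable) torsions; their count is the search
        dimensionality ``D``
    fixed_dihedrals : torsions clamped to a value (e.g. trans peptide bonds
        at 180 deg); they are verified, never rotated
    bonds : optional explicit bond list overriding covalent-radius inference
    """

    symbols: list[str]
    coords: np.ndarray
    dihedrals: list[Dihedral]
    fixed_dihedrals: list[tuple[tuple[int, int, int, int], float]] = field(
        default_factory=list
    )
    name: str = "molecule"
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.symbols)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        for dih in self.dihedrals:
            idx = dih.indices
            if len(set(idx)) != 4:
                raise TopologyError(f"dihedral indices not distinct: {idx}")
            if min(idx) < 0 or max(idx) >= n:
                raise TopologyError(f"dihedral index out of bounds: {idx}")
            if not (0.0 <= dih.low < dih.high <= 360.0):
                raise ValueError(f"bad dihedral range [{dih.low}, {dih.high}]")
        if self.D < 1:
            raise ValueError("need at least one free dihedral")
        if self.bonds is None:
            self.bonds = infer_bonds(self.symbols, self.coords)
        self._adjacency = _adjacency(len(self.symbols), self.bonds)
        self._bond_set = {frozenset(b) for b in self.bonds}
        # precompute, per free dihedral, the set of atoms rotated with it
        self._rotating = [
            _rotating_atoms(self._adjacency, d.indices) for d in self.dihedrals
        ]

    @property
    def D(self) -> int:
        """Search dimensionality: number of free dihedrals."""
        return len(self.dihedrals)

    @property
    def ranges(self) -> list[tuple[float, float, bool]]:
        """Per-dimension (low, high, periodic) tuples, for distance/kernels."""
        return [(d.low, d.high, d.periodic) for d in self.dihedrals]

    def reference_angles(self) -> np.ndarray:
        """Measure the free dihedrals on the reference geometry (degrees)."""
        return np.array(
            [measure_dihedral(self.coords, *d.indices) for d in self.dihedrals]
        )


@dataclass
class Conformation:
    """A point in torsion space, optionally realized in Cartesian space.

    ``energy`` is the raw backend energy E (eV); ``scaled_energy`` is E*
    after the logarithmic high-energy compression.  Invalid conformations
    (steric clashes, failed backend calls) carry no energy.
    """

    angles: np.ndarray
    coords: np.ndarray | None = None
    energy: float | None = None
    scaled_energy: float | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if not self.valid and self.energy is not None:
            raise ValueError("invalid conformation cannot carry an energy")


def infer_bonds(symbols: list[str], coords: np.ndarray) -> list[tuple[int, int]]:
    """Infer the bond graph: pairs closer than 1.2x the covalent-radius sum."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([COVALENT_RADII.get(s, _DEFAULT_RADIUS) for s in symbols])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    cutoff = BOND_FACTOR * (radii[:, None] + radii[None, :])
    i, j = np.nonzero(np.triu(dist < cutoff, k=1))
    return [(int(a), int(b)) for a, b in zip(i, j)]


def _adjacency(n: int, bonds: list[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _component(adj: list[set[int]], start: int, blocked_edge: frozenset) -> set[int]:
    """Connected component of ``start`` with one edge removed."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if frozenset((u, v)) == blocked_edge or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def _rotating_atoms(
    adj: list[set[int]], indices: tuple[int, int, int, int]
) -> np.ndarray:
    """Atoms on the d-side of bond b-c; errors out if b-c sits in a ring."""
    a, b, c, d = indices
    if c not in adj[b]:
        raise TopologyError(f"axis atoms {b}-{c} are not bonded")
    comp_c = _component(adj, c, frozenset((b, c)))
    if b in comp_c:
        raise TopologyError(f"rotatable bond {b}-{c} lies inside a ring")
    if d not in comp_c or a in comp_c:
        raise TopologyError(f"dihedral {indices} does not straddle bond {b}-{c}")
    comp_c.discard(c)  # c is on the axis: it never moves
    return np.fromiter(sorted(comp_c), dtype=int)


def measure_dihedral(coords: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Torsion angle a-b-c-d in degrees, mapped to [0, 360).

    Uses the atan2 convention: the signed angle between the plane (a, b, c)
    and the plane (b, c, d), viewed along b->c.
    """
    p = np.asarray(coords, dtype=float)
    b1 = p[b] - p[a]
    b2 = p[c] - p[b]
    b3 = p[d] - p[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(m1 @ n2, n1 @ n2))
    return float(angle % 360.0)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit ``axis`` by ``angle_deg``."""
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def apply_dihedrals(spec: MoleculeSpec, angles: np.ndarray) -> Conformation:
    """Realize a torsion vector as Cartesian coordinates.

    Each free dihedral (a, b, c, d) is driven to its target by rotating the
    d-side subtree about the b-c bond.  Because the rotation axis passes
    through both b and c, previously set torsions — and all fixed torsions,
    bond lengths and bond angles — are untouched, so the dihedrals may be
    applied in any order on an acyclic rotor tree.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (spec.D,):
        raise ValueError(f"expected {spec.D} angles, got shape {angles.shape}")
    for val, dih in zip(angles, spec.dihedrals):
        if not (dih.low - 1e-9 <= val <= dih.high + 1e-9):
            raise ValueError(
                f"angle {val} outside declared range [{dih.low}, {dih.high}]"
            )
    coords = spec.coords.copy()
    for target, dih, movers in zip(angles, spec.dihedrals, spec._rotating):
        a, b, c, d = dih.indices
        current = measure_dihedral(coords, a, b, c, d)
        delta = target - current
        if abs(delta) < 1e-13:
            continue
        # rotating the d-side by +t about the b->c axis decreases the
        # measured torsion by t under the atan2 convention used here
        axis = coords[c] - coords[b]
        rot = _rotation_matrix(axis, -delta)
        coords[movers] = (coords[movers] - coords[c]) @ rot.T + coords[c]
    return Conformation(angles=angles.copy(), coords=coords)


def detect_clash(
    conf: Conformation, spec: MoleculeSpec, scale: float = 0.7
) -> bool:
    """True if any non-bonded pair sits closer than scale x radius sum.

    Stands in for a failing quantum-chemistry single point: clashing
    structures are flagged invalid and never enter the data pool.
    """
    if conf.coords is None:
        raise ValueError("conformation has no coordinates")
    coords = conf.coords
    radii = np.array(
        [COVALENT_RADII.get(s, _DEFAULT_RADIUS) for s in spec.symbols]
    )
    n = len(spec.symbols)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    cutoff = scale * (radii[:, None] + radii[None, :])
    close = dist < cutoff
    for i in range(n):
        close[i, i] = False
    for pair in spec._bond_set:
        i, j = tuple(pair)
        close[i, j] = close[j, i] = False
    return bool(close.any())


def circular_diff(a: np.ndarray, b: np.ndarray, ranges) -> np.ndarray:
    """Per-dimension dihedral difference: wrapped on periodic dims."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("angle vectors differ in length")
    delta = np.abs(a - b)
    for k, (low, high, periodic) in enumerate(ranges):
        if periodic:
            span = high - low
            delta[..., k] = np.minimum(delta[..., k], span - delta[..., k])
    return delta


def dihedral_distance(a, b, ranges) -> tuple[float, float]:
    """(mean, max) absolute dihedral difference, circular on periodic dims."""
    delta = circular_diff(a, b, ranges)
    return float(delta.mean()), float(delta.max())


# ---------------------------------------------------------------------------
# file formats


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a single-frame XYZ file -> (symbols, coords)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.array(coords)


def write_xyz(path, symbols, coords, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_xyz_block(symbols, coords, comment))


def write_multi_xyz(path, symbols, frames, comments=None) -> None:
    """Write a conformer ensemble as a multi-frame XYZ file."""
    comments = comments or ["" for _ in frames]
    with open(path, "w") as fh:
        for coords, comment in zip(frames, comments):
            fh.write(_xyz_block(symbols, coords, comment))


def _xyz_block(symbols, coords, comment: str) -> str:
    lines = [str(len(symbols)), comment.replace("\n", " ")]
    for s, (x, y, z) in zip(symbols, np.asarray(coords)):
        lines.append(f"{s:2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(lines) + "\n"


def load_molecule_spec(path: str | Path) -> MoleculeSpec:
    """Load a molecule definition from a YAML spec file.

    Layout::

        name: cysteine
        xyz: reference.xyz            # relative to the spec file
        dihedrals:
          - indices: [0, 1, 2, 3]
            range: [0, 360]           # optional, default full circle
            periodic: true            # optional, default true
        fixed_dihedrals:
          - indices: [4, 5, 6, 7]
            value: 180.0
        bonds: [[0, 1], [1, 2]]       # optional override
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    symbols, coords = read_xyz(path.parent / data["xyz"])
    dihedrals = []
    for entry in data["dihedrals"]:
        low, high = entry.get("range", [0.0, 360.0])
        dihedrals.append(
            Dihedral(
                indices=tuple(entry["indices"]),
                low=float(low),
                high=float(high),
                periodic=bool(entry.get("periodic", True)),
            )
        )
    fixed = [
        (tuple(e["indices"]), float(e["value"]))
        for e in data.get("fixed_dihedrals", [])
    ]
    bonds = data.get("bonds")
    if bonds is not None:
        bonds = [tuple(b) for b in bonds]
    return MoleculeSpec(
        symbols=symbols,
        coords=coords,
        dihedrals=dihedrals,
        fixed_dihedrals=fixed,
        name=data.get("name", path.stem),
        bonds=bonds,
    )
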