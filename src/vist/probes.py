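"""Molecules and labelled probe points for NICS evaluation.

NICS tensors are evaluated at virtual points: ring centres (NICS(0)),
points 1 or 2 A above a ring plane (NICS(1)/NICS(2)), bond midpoints and
their offsets, line scans through a macrocycle, and planar grids for 2D
maps.  This module builds those probe sets from a molecular geometry.

Coordinates are Angstrom everywhere; conversion to bohr happens only in
file readers/writers that need it (see ``vist.qcio``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "Probe",
    "ProbeSet",
    "ring_centroid_normal",
    "ring_probes",
    "bond_probes",
    "line_scan",
    "plane_grid",
]

MIN_ATOM_SEPARATION = 0.1  # A


@dataclass
class Molecule:
    """Atoms with Cartesian positions (A); ghosts carry probe positions."""

    atoms: list[tuple[str, np.ndarray]]
    ghosts: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("molecule needs at least one atom")
        self.atoms = [(sym, np.asarray(pos, dtype=float).reshape(3)) for sym, pos in self.atoms]
        self.ghosts = [np.asarray(g, dtype=float).reshape(3) for g in self.ghosts]
        coords = self.coords
        if len(coords) > 1:
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_ATOM_SEPARATION:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"atoms {i} and {j} are {d.min():.3f} A apart "
                    f"(< {MIN_ATOM_SEPARATION} A)"
                )

    @property
    def coords(self) -> np.ndarray:
        return np.array([pos for _, pos in self.atoms])

    @property
    def symbols(self) -> list[str]:
        return [sym for sym, _ in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Probe:
    label: str
    position: np.ndarray
    normal: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.normal is not None:
            self.normal = np.asarray(self.normal, dtype=float).reshape(3)


@dataclass
class ProbeSet:
    """Labelled probe points, optionally with a reference ring normal each."""

    probes: list[Probe]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.probes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate probe labels: {dupes}")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.probes]).reshape(-1, 3)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.probes]

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __add__(self, other: "ProbeSet") -> "ProbeSet":
        return ProbeSet(self.probes + other.probes)


def ring_centroid_normal(
    mol: Molecule, indices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and best-fit-plane unit normal of a ring of atoms.

    The normal is the direction of least coordinate variance of the centred
    ring atoms (smallest principal component of the positions), which for a
    puckered ring is the natural best-fit plane.  Its orientation follows
    the right-hand rule over the atom ordering, so listing a planar ring
    counterclockwise (seen from +z) gives the +z normal.
    """
    indices = list(indices)
    if len(indices) < 3:
        raise ValueError("need at least 3 atoms to define a ring plane")
    coords = mol.coords[indices]
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    # least-variance direction = eigenvector of smallest covariance eigenvalue
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)
    scale = max(evals[-1], 1e-30)
    if evals[1] / scale < 1e-10:
        raise ValueError("ring atoms are collinear or degenerate; no plane defined")
    normal = evecs[:, 0]
    # right-hand rule over the ordering fixes the sign
    winding = np.zeros(3)
    for i in range(len(centred)):
        winding += np.cross(centred[i], centred[(i + 1) % len(centred)])
    if winding @ normal < 0:
        normal = -normal
    return centroid, normal


def _require_unit(normal: Sequence[float]) -> np.ndarray:
    n = np.asarray(normal, dtype=float).reshape(3)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("normal must be a unit vector")
    return n


def ring_probes(
    centre: Sequence[float],
    normal: Sequence[float],
    offsets: Iterable[float],
    both_sides: bool = False,
    prefix: str = "ring",
) -> ProbeSet:
    """Probes at centre + offset * normal for each offset (A).

    Offset 0 is the NICS(0) position; 1 and 2 A give NICS(1)/NICS(2).
    ``both_sides`` mirrors every non-zero offset to -offset, since for
    non-planar systems the two faces of a ring are inequivalent.
    """
    centre = np.asarray(centre, dtype=float).reshape(3)
    n = _require_unit(normal)
    offs: list[float] = []
    for o in offsets:
        offs.append(float(o))
        if both_sides and o != 0.0:
            offs.append(-float(o))
    probes = [
        Probe(label=f"{prefix}_{o:+g}", position=centre + o * n, normal=n.copy())
        for o in offs
    ]
    return ProbeSet(probes)


def bond_probes(
    mol: Molecule,
    i: int,
    j: int,
    offsets: Iterable[float],
    normal: Sequence[float],
    both_sides: bool = False,
    prefix: str = "bond",
) -> ProbeSet:
    """Probes above the midpoint of bond i-j, displaced along a ring normal."""
    if i == j:
        raise ValueError("bond requires two distinct atoms")
    coords = mol.coords
    mid = 0.5 * (coords[i] + coords[j])
    return ring_probes(mid, normal, offsets, both_sides=both_sides, prefix=f"{prefix}_{i}_{j}")


def line_scan(
    p_start: Sequence[float],
    p_end: Sequence[float],
    n: int,
    prefix: str = "scan",
) -> ProbeSet:
    """n equally spaced probes from p_start to p_end, endpoints included.

    Labels carry the fractional position along the line, so the output is a
    ready-made 1D NICS scan (e.g. across a macrocycle from one ring centre
    to the opposite one).
    """
    if n < 2:
        raise ValueError("line scan needs at least 2 points")
    a = np.asarray(p_start, dtype=float).reshape(3)
    b = np.asarray(p_end, dtype=float).reshape(3)
    if np.linalg.norm(b - a) < 1e-12:
        raise ValueError("line scan endpoints coincide")
    fractions = np.linspace(0.0, 1.0, n)
    probes = [
        Probe(label=f"{prefix}_{f:.4f}", position=(1.0 - f) * a + f * b)
        for f in fractions
    ]
    return ProbeSet(probes)


def plane_grid(
    centre: Sequence[float],
    normal: Sequence[float],
    half_extent: float,
    spacing: float,
    prefix: str = "grid",
) -> ProbeSet:
    """Square grid of probes in the plane through centre orthogonal to normal.

    Produces (2*floor(half_extent/spacing)+1)^2 points, for 2D NICS maps.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    centre = np.asarray(centre, dtype=float).reshape(3)
    n = _require_unit(normal)
    # orthonormal in-plane basis: pick the Cartesian axis least aligned with n
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(n)))] = 1.0
    e1 = seed - (seed @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    k = int(np.floor(half_extent / spacing + 1e-12))
    probes = []
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            pos = centre + i * spacing * e1 + j * spacing * e2
            probes.append(Probe(label=f"{prefix}_{i:+d}_{j:+d}", position=pos, normal=n.copy()))
    return ProbeSet(probes)
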