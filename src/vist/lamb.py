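"""Diamagnetic (Lamb) shielding from an electron-density grid.

With the gauge origin placed at the probe point, the diamagnetic part of
the shielding tensor is a positive-semidefinite functional of the electron
density alone:

    sigma_dia(gamma, beta) = (alpha^2 / 2) * Int [ (r^2 d_gb - r_g r_b) / r^3 ] rho(r) dr

with r measured from the probe, alpha the fine-structure constant and
d_gb the Kronecker delta.  The zz element reduces to the textbook Lamb
expression (alpha^2/2) Int (x^2+y^2)/r^3 rho dr >= 0: the shielding along
any direction is produced by density in the plane perpendicular to it,
which is why in-plane ring currents show up as a pronounced out-of-plane
tensor component.

The integral is evaluated by midpoint (voxel-centred) quadrature over a
cube-format grid; the voxel containing the probe is excluded, since the
integrand is O(1/r) there and the excluded mass vanishes with resolution.
Only the diamagnetic term is computed — paramagnetic deshielding requires
excited-state wavefunctions and is out of scope — and the dia/para split
itself is gauge-dependent, so the result is meaningful only under the
probe-at-gauge-origin convention used here.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .qcio import BOHR_TO_ANGSTROM, DensityGrid
from .tensor_core import ShieldingTensor

__all__ = ["ALPHA2_PPM", "diamagnetic_tensor"]

# alpha^2 * 1e6 with fine-structure constant 1/137.035999: converts the
# dimensionless atomic-unit shielding to ppm
ALPHA2_PPM = 53.2514


def diamagnetic_tensor(
    grid: DensityGrid, probe: Sequence[float], probe_unit: str = "angstrom"
) -> ShieldingTensor:
    """Diamagnetic shielding tensor (ppm) at a probe point from a density grid.

    Parameters
    ----------
    grid
        Electron density on a regular grid, bohr / electrons-per-bohr^3
        (the cube-file convention).  All values must be non-negative.
    probe
        Probe position; Angstrom by default (the toolkit-wide unit),
        ``probe_unit="bohr"`` to pass grid-native coordinates.

    Returns
    -------
    ShieldingTensor
        Symmetric tensor with non-negative diagonal, anchored at the probe
        (origin stored in Angstrom); the tensor is also recorded as its own
        ``dia`` component.
    """
    if np.any(grid.values < 0):
        raise ValueError("electron density grid contains negative values")
    probe = np.asarray(probe, dtype=float).reshape(3)
    if probe_unit == "angstrom":
        probe_bohr = probe / BOHR_TO_ANGSTROM
        origin_ang = probe
    elif probe_unit == "bohr":
        probe_bohr = probe
        origin_ang = probe * BOHR_TO_ANGSTROM
    else:
        raise ValueError(f"probe_unit must be 'angstrom' or 'bohr', got {probe_unit!r}")

    d = grid.points().reshape(-1, 3) - probe_bohr  # bohr, from the probe
    rho = grid.values.reshape(-1)

    # exclude the voxel containing the probe: nearest grid point in the
    # grid's own (possibly skewed) basis, only if the probe is inside bounds
    frac = np.linalg.solve(grid.axes.T, probe_bohr - grid.origin)
    idx = np.rint(frac).astype(int)
    mask = np.ones(len(d), dtype=bool)
    if np.all(idx >= 0) and np.all(idx < grid.shape):
        mask[np.ravel_multi_index(tuple(idx), grid.shape)] = False

    d = d[mask]
    rho = rho[mask]
    r2 = np.einsum("ij,ij->i", d, d)
    r3 = r2 ** 1.5
    w = rho / r3 * grid.voxel_volume
    # Int (r^2 I - d d^T)/r^3 rho dV, voxel sums
    outer = np.einsum("i,ij,ik->jk", w, d, d)
    sigma = 0.5 * ALPHA2_PPM * (np.eye(3) * np.sum(w * r2) - outer)
    sigma = 0.5 * (sigma + sigma.T)  # symmetric up to round-off; enforce
    return ShieldingTensor(origin=origin_ang, sigma=sigma, label="dia", dia=sigma.copy())
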