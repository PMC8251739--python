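"""Shielding-tensor data model, principal-axis decomposition and NICS extraction.

The chemical shielding tensor sigma is the mixed second derivative of the
molecular energy with respect to an external magnetic field component
(index beta) and a nuclear magnetic-moment component (index gamma).  It is a
generally *non-symmetric* real 3x3 matrix, in ppm.  Evaluated at a virtual
(nucleus-free) point it yields the nucleus-independent chemical shift

    NICS = -sigma_iso = -(sigma_xx + sigma_yy + sigma_zz) / 3,

negative at the centre of an aromatic ring, positive for an antiaromatic one.

The decomposition implemented here constructs the principal axes of the
tensor as its eigenvectors, in analogy to the principal axes of the moment
of inertia: sigma q(i) = t(i) q(i).  Because sigma need not be symmetric,
two modes are offered:

``symmetrized``
    Eigendecomposition of (sigma + sigma^T)/2.  Eigenvalues are guaranteed
    real, axes orthogonal.  The antisymmetric part of sigma never
    contributes to the isotropic average, so all scalar NICS values are
    unaffected.  This is the default.

``right-eigen``
    Right eigenvectors of the raw matrix.  Faithful to the unsymmetrized
    problem; eigenvalues may come in complex-conjugate pairs, which are
    reported via ``complex_flag`` with real parts retained (the imaginary
    magnitude is recorded, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ShieldingTensor",
    "VISTResult",
    "symmetrize",
    "vist_decompose",
    "nics_iso",
    "nics_component",
]

_MODES = ("symmetrized", "right-eigen")


@dataclass
class ShieldingTensor:
    """A 3x3 chemical shielding matrix (ppm) anchored at a point in space (A).

    ``sigma`` is indexed ``(gamma, beta)`` with gamma the nuclear-moment
    component and beta the field component.  ``dia`` / ``para`` optionally
    carry the diamagnetic/paramagnetic split as metadata; note the split is
    gauge-origin dependent and only the total is physical.
    """

    origin: np.ndarray
    sigma: np.ndarray
    label: str = ""
    dia: Optional[np.ndarray] = None
    para: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(self.origin)):
            raise ValueError(f"tensor {self.label!r}: non-finite origin")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError(f"tensor {self.label!r}: non-finite sigma entries")
        for name in ("dia", "para"):
            part = getattr(self, name)
            if part is not None:
                setattr(self, name, np.asarray(part, dtype=float).reshape(3, 3))

    @property
    def trace(self) -> float:
        return float(np.trace(self.sigma))

    @property
    def isotropic(self) -> float:
        """sigma_iso = trace/3 (ppm)."""
        return self.trace / 3.0


@dataclass
class VISTResult:
    """Principal-axis decomposition of a shielding tensor.

    Eigenvalues ``t(1), t(2), t(3)`` are sorted by descending absolute value
    (the dominant component first); ``axes[i]`` is the unit principal axis
    q(i).  ``nics_components`` are -t(i) and ``nics_iso`` their mean, so a
    negative component is shielded/aromatic along that axis.
    """

    eigenvalues: np.ndarray
    axes: np.ndarray  # rows are q(1), q(2), q(3)
    mode: str
    complex_flag: bool
    nics_iso: float
    nics_components: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""
    imag_magnitude: float = 0.0


def symmetrize(t: ShieldingTensor) -> ShieldingTensor:
    """Return (sigma + sigma^T)/2 anchored at the same origin. Idempotent."""
    return ShieldingTensor(
        origin=t.origin.copy(),
        sigma=0.5 * (t.sigma + t.sigma.T),
        label=t.label,
        dia=None if t.dia is None else 0.5 * (t.dia + t.dia.T),
        para=None if t.para is None else 0.5 * (t.para + t.para.T),
    )


def _fix_axis_sign(axis: np.ndarray) -> np.ndarray:
    """Flip the axis so its largest-magnitude Cartesian entry is positive."""
    k = int(np.argmax(np.abs(axis)))
    return -axis if axis[k] < 0 else axis


def _sort_order(vals: np.ndarray, axes: np.ndarray) -> list[int]:
    # descending |t|; ties by descending signed t, then axis closest to +z
    return sorted(
        range(3),
        key=lambda i: (-abs(vals[i]), -vals[i], -axes[i, 2]),
    )


def vist_decompose(t: ShieldingTensor, mode: str = "symmetrized") -> VISTResult:
    """Principal axes and eigenvalues of a shielding tensor.

    Parameters
    ----------
    t
        The tensor to decompose.
    mode
        ``"symmetrized"`` (default) diagonalises (sigma + sigma^T)/2;
        ``"right-eigen"`` takes right eigenvectors of the raw matrix and
        flags complex-conjugate eigenvalue pairs via ``complex_flag``.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    sigma = t.sigma
    complex_flag = False
    imag_mag = 0.0
    if mode == "symmetrized":
        vals, vecs = np.linalg.eigh(0.5 * (sigma + sigma.T))
        vals = vals.astype(float)
        axes = vecs.T.astype(float)  # rows = eigenvectors
    else:
        vals_c, vecs_c = np.linalg.eig(sigma)
        imag_mag = float(np.max(np.abs(vals_c.imag)))
        # scale-aware test: a conjugate pair on a ppm-sized tensor
        scale = max(float(np.max(np.abs(vals_c))), 1.0)
        complex_flag = imag_mag > 1e-10 * scale
        vals = vals_c.real.astype(float)
        axes = np.empty((3, 3))
        for i in range(3):
            v = vecs_c[:, i].real
            n = np.linalg.norm(v)
            if n < 1e-12:  # purely imaginary eigenvector component
                v = vecs_c[:, i].imag
                n = np.linalg.norm(v)
            axes[i] = v / n
    axes = np.array([_fix_axis_sign(a) for a in axes])
    order = _sort_order(vals, axes)
    vals, axes = vals[order], axes[order]
    return VISTResult(
        eigenvalues=vals,
        axes=axes,
        mode=mode,
        complex_flag=complex_flag,
        nics_iso=-float(np.sum(vals)) / 3.0,
        nics_components=-vals,
        origin=t.origin.copy(),
        label=t.label,
        imag_magnitude=imag_mag,
    )


def nics_iso(t: ShieldingTensor) -> float:
    """NICS = -sigma_iso = -trace(sigma)/3, in ppm."""
    return -t.trace / 3.0


def nics_component(t: ShieldingTensor, u: Sequence[float]) -> float:
    """Directional NICS component -(u^T sigma u) along unit vector u.

    For u along the normal of a planar ring this is the out-of-plane
    component NICS_zz, the part that reflects in-plane ring currents.
    """
    u = np.asarray(u, dtype=float).reshape(3)
    if abs(np.linalg.norm(u) - 1.0) > 1e-8:
        raise ValueError(f"direction must be a unit vector, got |u|={np.linalg.norm(u)}")
    return -float(u @ t.sigma @ u)
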