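"""Dumb-bell glyph scenes: the 3D visual encoding of a decomposed tensor.

Each principal component of a shielding tensor becomes a dumb-bell — a rod
with two spherical end-lobes — centred at the probe point and oriented
along the principal axis.  Size and length grow with the magnitude of the
eigenvalue |t(i)|; the colour encodes the sign of the NICS component -t(i):
negative (shielded, aromatic) contributions are blue, positive (deshielded,
antiaromatic) red.  Components flagged as complex by the right-eigen
decomposition are rendered semi-transparent — visible but visually
distinct, never hidden.

Scenes are emitted as VMD draw-command scripts (TCL), as triangulated OBJ
meshes, or as lossless JSON records; all outputs use fixed 6-decimal
coordinate formatting and LF endings, so identical scenes give identical
bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .probes import Molecule
from .tensor_core import VISTResult

__all__ = [
    "Glyph",
    "Scene",
    "build_glyphs",
    "scene_from_results",
    "render_tcl",
    "export_scene",
    "scene_from_json",
    "DEFAULT_SCALE",
    "DEFAULT_THRESHOLD",
]

DEFAULT_SCALE = 0.04  # A per ppm: benzene's -29.5 ppm component renders ~1.2 A
DEFAULT_THRESHOLD = 1.0  # ppm; weaker components are dropped as visual noise
DEFAULT_MAX_LENGTH = 4.0  # A cap so extreme antiaromatic values stay on screen
LOBE_RADIUS_FRACTION = 0.25  # lobe radius = 0.25 x half-length
ROD_RADIUS_FRACTION = 0.08  # rod radius as a fraction of length

COLOR_SHIELDED = "shielded-blue"
COLOR_DESHIELDED = "deshielded-red"


@dataclass
class Glyph:
    """One oriented dumb-bell: a principal component of one tensor."""

    origin: np.ndarray
    axis: np.ndarray
    nics_value: float  # -t(i), ppm
    length: float  # A
    lobe_radius: float  # A
    color: str  # COLOR_SHIELDED or COLOR_DESHIELDED
    complex_marker: bool = False

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        if self.length < 0:
            raise ValueError("glyph length must be non-negative")


@dataclass
class Scene:
    molecule: Optional[Molecule]
    glyphs: list[Glyph]
    scale: float = DEFAULT_SCALE
    threshold: float = DEFAULT_THRESHOLD


def build_glyphs(
    v: VISTResult,
    origin: Optional[Sequence[float]] = None,
    scale: float = DEFAULT_SCALE,
    threshold: float = DEFAULT_THRESHOLD,
    max_length: float = DEFAULT_MAX_LENGTH,
) -> list[Glyph]:
    """Dumb-bells for the (up to three) principal components of one tensor.

    length = scale * |t(i)| capped at ``max_length``; components with
    |t(i)| < threshold are omitted; colour follows the sign of the NICS
    component -t(i) (negative = blue/shielded).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    origin = np.asarray(origin if origin is not None else v.origin, dtype=float)
    glyphs = []
    for t_i, axis in zip(v.eigenvalues, v.axes):
        if abs(t_i) < threshold:
            continue
        length = min(scale * abs(t_i), max_length)
        nics = -float(t_i)
        glyphs.append(
            Glyph(
                origin=origin.copy(),
                axis=axis.copy(),
                nics_value=nics,
                length=length,
                lobe_radius=LOBE_RADIUS_FRACTION * 0.5 * length,
                color=COLOR_SHIELDED if nics < 0 else COLOR_DESHIELDED,
                complex_marker=v.complex_flag,
            )
        )
    return glyphs


def scene_from_results(
    results: Sequence[VISTResult],
    molecule: Optional[Molecule] = None,
    scale: float = DEFAULT_SCALE,
    threshold: float = DEFAULT_THRESHOLD,
    max_length: float = DEFAULT_MAX_LENGTH,
) -> Scene:
    glyphs: list[Glyph] = []
    for v in results:
        glyphs.extend(build_glyphs(v, scale=scale, threshold=threshold, max_length=max_length))
    return Scene(molecule=molecule, glyphs=glyphs, scale=scale, threshold=threshold)


# ------------------------------------------------------------- TCL output

_F = "{:.6f}".format  # fixed formatting => byte-deterministic output


def _vec(p: np.ndarray) -> str:
    return "{" + " ".join(_F(x) for x in p) + "}"


_TCL_HEADER = """\
# VIST dumb-bell glyph scene (VMD draw commands)
# blue = shielded/aromatic (NICS component < 0), red = deshielded/antiaromatic
color change rgb 23 0.100000 0.100000 0.900000
color change rgb 24 0.900000 0.100000 0.100000
material add copy Opaque
material rename Material23 VistSolid
material add copy Transparent
material rename Material24 VistComplex
material change opacity VistComplex 0.500000
draw delete all
"""


def render_tcl(scene: Scene, resolution: int = 24) -> str:
    """Emit a self-contained VMD draw script for a scene.

    Each glyph becomes one cylinder plus two end-lobe spheres, oriented
    along its principal axis and coloured by sign class; complex-flagged
    glyphs use a semi-transparent material.
    """
    out = [_TCL_HEADER]
    for g in scene.glyphs:
        half = 0.5 * g.length * g.axis
        a, b = g.origin - half, g.origin + half
        rod_r = ROD_RADIUS_FRACTION * g.length
        out.append(f"draw material {'VistComplex' if g.complex_marker else 'VistSolid'}")
        out.append(f"draw color {23 if g.color == COLOR_SHIELDED else 24}")
        out.append(
            f"draw cylinder {_vec(a)} {_vec(b)} radius {_F(rod_r)} "
            f"resolution {resolution} filled yes"
        )
        out.append(f"draw sphere {_vec(a)} radius {_F(g.lobe_radius)} resolution {resolution}")
        out.append(f"draw sphere {_vec(b)} radius {_F(g.lobe_radius)} resolution {resolution}")
    return "\n".join(out) + "\n"


# ------------------------------------------------------------ JSON / OBJ


def export_scene(
    scene: Scene, format: str = "json", n_ring: int = 16, sphere_stacks: int = 8
) -> str:
    """Serialise a scene: ``json`` is lossless and round-trippable, ``obj``
    is a triangulated mesh (one group per glyph)."""
    if format == "json":
        return _scene_to_json(scene)
    if format == "obj":
        return _scene_to_obj(scene, n_ring=n_ring, sphere_stacks=sphere_stacks)
    raise ValueError(f"unknown scene format {format!r}; expected 'json' or 'obj'")


def _scene_to_json(scene: Scene) -> str:
    mol = None
    if scene.molecule is not None:
        mol = {
            "atoms": [[sym, pos.tolist()] for sym, pos in scene.molecule.atoms],
            "ghosts": [g.tolist() for g in scene.molecule.ghosts],
        }
    doc = {
        "molecule": mol,
        "scale": scene.scale,
        "threshold": scene.threshold,
        "glyphs": [
            {
                "origin": g.origin.tolist(),
                "axis": g.axis.tolist(),
                "nics_value": g.nics_value,
                "length": g.length,
                "lobe_radius": g.lobe_radius,
                "color": g.color,
                "complex_marker": g.complex_marker,
            }
            for g in scene.glyphs
        ],
    }
    return json.dumps(doc, indent=2)


def scene_from_json(text: str) -> Scene:
    doc = json.loads(text)
    mol = None
    if doc.get("molecule") is not None:
        mol = Molecule(
            atoms=[(sym, np.asarray(pos)) for sym, pos in doc["molecule"]["atoms"]],
            ghosts=[np.asarray(g) for g in doc["molecule"]["ghosts"]],
        )
    glyphs = [
        Glyph(
            origin=np.asarray(g["origin"]),
            axis=np.asarray(g["axis"]),
            nics_value=g["nics_value"],
            length=g["length"],
            lobe_radius=g["lobe_radius"],
            color=g["color"],
            complex_marker=g["complex_marker"],
        )
        for g in doc["glyphs"]
    ]
    return Scene(molecule=mol, glyphs=glyphs, scale=doc["scale"], threshold=doc["threshold"])


def sphere_vertex_count(n_ring: int, sphere_stacks: int) -> int:
    """Vertices of one UV sphere at the export resolution."""
    return (sphere_stacks - 1) * n_ring + 2


def glyph_vertex_count(n_ring: int, sphere_stacks: int) -> int:
    """Vertices of one dumb-bell: 2 cylinder rings + 2 end-lobe spheres."""
    return 2 * n_ring + 2 * sphere_vertex_count(n_ring, sphere_stacks)


def _frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(axis)))] = 1.0
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def _scene_to_obj(scene: Scene, n_ring: int, sphere_stacks: int) -> str:
    out = ["# VIST dumb-bell glyph mesh"]
    base = 1  # OBJ indices are 1-based
    for gi, g in enumerate(scene.glyphs):
        out.append(f"g glyph_{gi}")
        verts: list[np.ndarray] = []
        faces: list[tuple[int, int, int]] = []
        axis = g.axis / np.linalg.norm(g.axis)
        e1, e2 = _frame(axis)
        half = 0.5 * g.length * axis
        ends = (g.origin - half, g.origin + half)
        rod_r = ROD_RADIUS_FRACTION * g.length
        # cylinder: two rings of n_ring vertices, side quads split in triangles
        for end in ends:
            for k in range(n_ring):
                th = 2.0 * np.pi * k / n_ring
                verts.append(end + rod_r * (np.cos(th) * e1 + np.sin(th) * e2))
        for k in range(n_ring):
            k2 = (k + 1) % n_ring
            faces.append((k, n_ring + k, n_ring + k2))
            faces.append((k, n_ring + k2, k2))
        # two UV spheres (poles + (stacks-1) rings of n_ring vertices each)
        for end in ends:
            pole_s = len(verts)
            verts.append(end + g.lobe_radius * axis)
            ring_start = len(verts)
            for s in range(1, sphere_stacks):
                phi = np.pi * s / sphere_stacks
                c, r = np.cos(phi), np.sin(phi)
                for k in range(n_ring):
                    th = 2.0 * np.pi * k / n_ring
                    verts.append(
                        end
                        + g.lobe_radius
                        * (c * axis + r * (np.cos(th) * e1 + np.sin(th) * e2))
                    )
            pole_n = len(verts)
            verts.append(end - g.lobe_radius * axis)
            for k in range(n_ring):
                k2 = (k + 1) % n_ring
                faces.append((pole_s, ring_start + k, ring_start + k2))
                last = ring_start + (sphere_stacks - 2) * n_ring
                faces.append((pole_n, last + k2, last + k))
                for s in range(sphere_stacks - 2):
                    r0 = ring_start + s * n_ring
                    r1 = r0 + n_ring
                    faces.append((r0 + k, r1 + k, r1 + k2))
                    faces.append((r0 + k, r1 + k2, r0 + k2))
        for v in verts:
            out.append(f"v {_F(v[0])} {_F(v[1])} {_F(v[2])}")
        for f in faces:
            out.append(f"f {base + f[0]} {base + f[1]} {base + f[2]}")
        base += len(verts)
    return "\n".join(out) + "\n"
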