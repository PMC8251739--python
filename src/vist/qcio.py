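"""File formats connecting the toolkit to quantum-chemistry engines.

Native readers/writers for:

* XYZ geometries (standard 2-header-line dialect, Angstrom);
* NMR job input decks with ghost "Bq" centres at the probe points;
* shielding-tensor log blocks in the Gaussian dialect
  (``Magnetic shielding tensor (ppm):`` followed by per-centre
  ``XX= .. YX= .. ZX= ..`` lines);
* cube volumetric grids (bohr; z fastest) for electron densities;
* tensor tables as CSV/JSON (the neutral interchange format — any other
  log dialect enters the toolkit through these).

Tensor entry labels in logs are mapped as printed with the first letter as
the row (nuclear-moment) index, so the line ``XX= a  YX= b  ZX= c`` fills
the first *column* of sigma.  The symmetrized decomposition default makes
downstream results robust to a transposed reading; the raw matrix is
preserved for right-eigen mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .probes import Molecule, Probe, ProbeSet
from .tensor_core import ShieldingTensor

__all__ = [
    "ParseError",
    "DensityGrid",
    "read_xyz",
    "write_xyz",
    "parse_shielding_log",
    "write_shielding_log",
    "write_nmr_input",
    "read_cube",
    "write_cube",
    "tensors_to_table",
    "table_to_tensors",
    "write_tensor_csv",
    "read_tensor_csv",
    "write_tensor_json",
    "read_tensor_json",
]

BOHR_TO_ANGSTROM = 0.52917721  # cube files are bohr by convention

SHIELDING_MARKER = "Magnetic shielding tensor (ppm)"

_ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe",
]
_Z_FROM_SYMBOL = {s: z for z, s in enumerate(_ELEMENTS)}
_Z_FROM_SYMBOL["Bq"] = 0


class ParseError(ValueError):
    """A structured text input could not be parsed."""


# ---------------------------------------------------------------- XYZ


def read_xyz(text: str) -> Molecule:
    """Parse an XYZ file: count line, comment line, then ``El x y z`` rows."""
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ file")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"bad XYZ atom-count line: {lines[0]!r}") from exc
    if len(lines) < 2 + natoms:
        raise ParseError(f"XYZ file truncated: expected {natoms} atom lines")
    atoms = []
    ghosts = []
    for k, line in enumerate(lines[2 : 2 + natoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {k}: expected 'El x y z', got {line!r}")
        try:
            pos = np.array([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise ParseError(f"line {k}: malformed coordinate in {line!r}") from exc
        if parts[0] in ("Bq", "X"):
            ghosts.append(pos)
        else:
            atoms.append((parts[0], pos))
    return Molecule(atoms=atoms, ghosts=ghosts)


def write_xyz(mol: Molecule, comment: str = "") -> str:
    n = len(mol.atoms) + len(mol.ghosts)
    out = [str(n), comment.replace("\n", " ")]
    for sym, pos in mol.atoms:
        out.append(f"{sym:<3s} {pos[0]:15.8f} {pos[1]:15.8f} {pos[2]:15.8f}")
    for g in mol.ghosts:
        out.append(f"{'Bq':<3s} {g[0]:15.8f} {g[1]:15.8f} {g[2]:15.8f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------- shielding log blocks

_TENSOR_ROW_LABELS = (("XX", "YX", "ZX"), ("XY", "YY", "ZY"), ("XZ", "YZ", "ZZ"))
_IDX = {"X": 0, "Y": 1, "Z": 2}


def parse_shielding_log(
    text: str, orientation: str = "standard"
) -> list[ShieldingTensor]:
    """Extract per-centre shielding tensors from a quantum-chemistry log.

    One tensor is returned per centre, in file order; ghost centres are
    labelled ``Bq<n>``, real atoms ``<El><n>``.  Positions are taken from
    the requested geometry block when present (``orientation`` chooses
    between the ``Standard orientation`` and ``Input orientation`` tables,
    which may be rotated relative to each other), else left at the origin.
    """
    lines = text.splitlines()
    positions = _parse_orientation_block(lines, orientation)
    start = None
    for i, line in enumerate(lines):
        if SHIELDING_MARKER in line:
            start = i + 1
            break
    if start is None:
        raise ParseError(f"no shielding block found; expected marker {SHIELDING_MARKER!r}")
    tensors: list[ShieldingTensor] = []
    i = start
    while i < len(lines):
        parts = lines[i].split()
        # centre header: " <idx>  <El>   Isotropic =  ...  Anisotropy = ..."
        if len(parts) >= 3 and parts[0].isdigit() and "Isotropic" in lines[i]:
            idx = int(parts[0])
            element = parts[1]
            sigma = np.zeros((3, 3))
            for r in range(3):
                i += 1
                if i >= len(lines):
                    raise ParseError(f"line {i + 1}: truncated tensor block for centre {idx}")
                row = lines[i].replace("=", "= ").split()
                expected = _TENSOR_ROW_LABELS[r]
                if len(row) < 6:
                    raise ParseError(f"line {i + 1}: malformed tensor row {lines[i]!r}")
                for lab_pos in range(3):
                    lab = row[2 * lab_pos].rstrip("=")
                    if lab != expected[lab_pos]:
                        raise ParseError(
                            f"line {i + 1}: expected entry {expected[lab_pos]}, got {lab!r}"
                        )
                    try:
                        val = float(row[2 * lab_pos + 1])
                    except ValueError as exc:
                        raise ParseError(
                            f"line {i + 1}: malformed numeric field "
                            f"{row[2 * lab_pos + 1]!r}"
                        ) from exc
                    # first letter = row (moment index), second = column (field)
                    sigma[_IDX[lab[0]], _IDX[lab[1]]] = val
            origin = positions.get(idx, np.zeros(3))
            tensors.append(
                ShieldingTensor(origin=origin, sigma=sigma, label=f"{element}{idx}")
            )
        elif tensors and parts and not lines[i].startswith(" "):
            break  # left the shielding section
        i += 1
    if not tensors:
        raise ParseError("shielding block contained no centres")
    return tensors


def _parse_orientation_block(lines: list[str], orientation: str) -> dict[int, np.ndarray]:
    marker = {"standard": "Standard orientation:", "input": "Input orientation:"}.get(
        orientation
    )
    if marker is None:
        raise ValueError(f"orientation must be 'standard' or 'input', got {orientation!r}")
    positions: dict[int, np.ndarray] = {}
    for i, line in enumerate(lines):
        if marker in line:
            j = i + 5  # skip the table rule lines
            while j < len(lines) and not lines[j].strip().startswith("---"):
                parts = lines[j].split()
                if len(parts) >= 6:
                    try:
                        positions[int(parts[0])] = np.array(
                            [float(parts[3]), float(parts[4]), float(parts[5])]
                        )
                    except ValueError:
                        pass
                j += 1
    return positions


def write_shielding_log(
    tensors: Sequence[ShieldingTensor],
    elements: Optional[Sequence[str]] = None,
    with_geometry: bool = True,
) -> str:
    """Synthesise a log file in the dialect ``parse_shielding_log`` reads.

    Used to round-trip tensors through the parser in tests and to mock the
    output of an external engine; ``elements`` defaults to all-ghost
    ("Bq") centres.
    """
    if elements is None:
        elements = ["Bq"] * len(tensors)
    out = [" Entering NMR module.", ""]
    if with_geometry:
        out += [
            "                         Standard orientation:",
            " " + "-" * 69,
            " Center     Atomic      Atomic             Coordinates (Angstroms)",
            " Number     Number       Type             X           Y           Z",
            " " + "-" * 69,
        ]
        for k, (t, el) in enumerate(zip(tensors, elements), start=1):
            z = _Z_FROM_SYMBOL.get(el, 0)
            out.append(
                f" {k:6d} {z:10d} {0:11d}    "
                f"{t.origin[0]:11.6f} {t.origin[1]:11.6f} {t.origin[2]:11.6f}"
            )
        out.append(" " + "-" * 69)
    out.append(" SCF GIAO " + SHIELDING_MARKER + ":")
    for k, (t, el) in enumerate(zip(tensors, elements), start=1):
        iso = t.isotropic
        out.append(f" {k:6d}  {el:<2s}   Isotropic = {iso:9.4f}   Anisotropy = {0.0:9.4f}")
        s = t.sigma
        for labels in _TENSOR_ROW_LABELS:
            entries = []
            for lab in labels:
                entries.append(f"{lab}= {s[_IDX[lab[0]], _IDX[lab[1]]]:10.4f}")
            out.append("   " + "   ".join(entries))
    out.append(" End of NMR computation.")
    return "\n".join(out) + "\n"


# ------------------------------------------------------- NMR input decks


def write_nmr_input(
    mol: Molecule,
    probes: ProbeSet,
    route: str = "#P PBE1PBE/Def2SVP NMR=GIAO SCF=Tight",
    charge: int = 0,
    multiplicity: int = 1,
    title: str = "NICS probe job",
    warn=None,
) -> str:
    """Write an NMR job input deck: real atoms first, then ghost "Bq" centres.

    A probe closer than 0.1 A to an atom triggers a warning via ``warn``
    (default: ``warnings.warn``) but is still written — the engine, not the
    deck writer, decides whether that is fatal.  Output is byte-deterministic
    for fixed inputs.
    """
    if len(probes) == 0:
        raise ValueError("probe set is empty; nothing to compute")
    if warn is None:
        import warnings

        warn = warnings.warn
    coords = mol.coords
    out = [route, "", title, "", f"{charge} {multiplicity}"]
    for sym, pos in mol.atoms:
        out.append(f"{sym:<3s} {pos[0]:14.8f} {pos[1]:14.8f} {pos[2]:14.8f}")
    for p in probes:
        d = np.linalg.norm(coords - p.position, axis=1).min()
        if d < 0.1:
            warn(f"probe {p.label!r} lies {d:.3f} A from an atom")
        out.append(
            f"{'Bq':<3s} {p.position[0]:14.8f} {p.position[1]:14.8f} {p.position[2]:14.8f}"
        )
    out.append("")
    return "\n".join(out) + "\n"


# ------------------------------------------------------------- cube files


@dataclass
class DensityGrid:
    """A volumetric scalar field on a regular (possibly skewed) grid.

    ``origin`` and ``axes`` are in bohr (cube convention); ``values`` has
    shape (n1, n2, n3) with the third index fastest in file order, in
    electrons/bohr^3 for electron densities.  ``atoms`` are
    (atomic number, charge, position bohr) records.
    """

    origin: np.ndarray
    axes: np.ndarray  # 3x3, row i = step vector of axis i
    values: np.ndarray
    atoms: list[tuple[int, float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """|det(axes)| in bohr^3."""
        return abs(float(np.linalg.det(self.axes)))

    def points(self) -> np.ndarray:
        """Grid-point positions, shape (n1, n2, n3, 3), bohr."""
        n1, n2, n3 = self.shape
        i, j, k = np.meshgrid(
            np.arange(n1), np.arange(n2), np.arange(n3), indexing="ij"
        )
        idx = np.stack([i, j, k], axis=-1).astype(float)
        return self.origin + idx @ self.axes


def read_cube(text: str) -> DensityGrid:
    """Parse a cube file (2 comment lines, counts/axes header, z-fastest values).

    MO cubes (negative atom count, extra DSET line) are rejected with a
    clear message — this reader handles scalar fields only.
    """
    lines = text.splitlines()
    if len(lines) < 6:
        raise ParseError("cube file too short for a valid header")
    try:
        parts = lines[2].split()
        natoms = int(parts[0])
        origin = np.array([float(v) for v in parts[1:4]])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"bad cube header line 3: {lines[2]!r}") from exc
    if natoms < 0:
        raise ParseError(
            "negative atom count: this is an MO cube (multiple datasets), "
            "which is not supported; export a single scalar field instead"
        )
    counts = np.zeros(3, dtype=int)
    axes = np.zeros((3, 3))
    for a in range(3):
        try:
            parts = lines[3 + a].split()
            counts[a] = int(parts[0])
            axes[a] = [float(v) for v in parts[1:4]]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"bad cube axis line {4 + a}: {lines[3 + a]!r}") from exc
    if np.any(counts < 1):
        raise ParseError(f"cube axis counts must be >= 1, got {counts.tolist()}")
    atoms = []
    for a in range(natoms):
        parts = lines[6 + a].split()
        if len(parts) < 5:
            raise ParseError(f"bad cube atom line {7 + a}: {lines[6 + a]!r}")
        atoms.append(
            (int(parts[0]), float(parts[1]), np.array([float(v) for v in parts[2:5]]))
        )
    raw = " ".join(lines[6 + natoms :]).split()
    expected = int(np.prod(counts))
    if len(raw) != expected:
        raise ParseError(
            f"cube grid truncated or oversized: expected {expected} values, found {len(raw)}"
        )
    try:
        values = np.array([float(v) for v in raw]).reshape(tuple(counts))
    except ValueError as exc:
        raise ParseError("malformed numeric value in cube grid") from exc
    return DensityGrid(origin=origin, axes=axes, values=values, atoms=atoms)


def write_cube(grid: DensityGrid, comment: str = "generated cube") -> str:
    n1, n2, n3 = grid.shape
    out = [comment, "scalar field, z fastest"]
    out.append(
        f"{len(grid.atoms):5d} {grid.origin[0]:11.6f} {grid.origin[1]:11.6f} {grid.origin[2]:11.6f}"
    )
    for a in range(3):
        c = (n1, n2, n3)[a]
        out.append(
            f"{c:5d} {grid.axes[a, 0]:11.6f} {grid.axes[a, 1]:11.6f} {grid.axes[a, 2]:11.6f}"
        )
    for z, q, pos in grid.atoms:
        out.append(f"{z:5d} {q:11.6f} {pos[0]:11.6f} {pos[1]:11.6f} {pos[2]:11.6f}")
    flat = grid.values.reshape(-1)
    for start in range(0, len(flat), 6):
        out.append(" ".join(f"{v:16.8E}" for v in flat[start : start + 6]))
    return "\n".join(out) + "\n"


# --------------------------------------------------------- tensor tables

_TABLE_COLUMNS = [
    "label", "x", "y", "z",
    "s_xx", "s_xy", "s_xz",
    "s_yx", "s_yy", "s_yz",
    "s_zx", "s_zy", "s_zz",
]


def tensors_to_table(tensors: Sequence[ShieldingTensor]) -> pd.DataFrame:
    rows = []
    for t in tensors:
        rows.append(
            [t.label, *t.origin.tolist(), *t.sigma.reshape(-1).tolist()]
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def table_to_tensors(df: pd.DataFrame) -> list[ShieldingTensor]:
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"tensor table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        sigma = np.array([row[c] for c in _TABLE_COLUMNS[4:]], dtype=float).reshape(3, 3)
        out.append(
            ShieldingTensor(
                origin=np.array([row["x"], row["y"], row["z"]], dtype=float),
                sigma=sigma,
                label=str(row["label"]),
            )
        )
    return out


def write_tensor_csv(tensors: Sequence[ShieldingTensor], path_or_buf) -> None:
    tensors_to_table(tensors).to_csv(path_or_buf, index=False)


def read_tensor_csv(path_or_buf) -> list[ShieldingTensor]:
    return table_to_tensors(pd.read_csv(path_or_buf))


def write_tensor_json(tensors: Sequence[ShieldingTensor]) -> str:
    records = [
        {
            "label": t.label,
            "origin": t.origin.tolist(),
            "sigma": t.sigma.tolist(),
        }
        for t in tensors
    ]
    return json.dumps(records, indent=2)


def read_tensor_json(text: str) -> list[ShieldingTensor]:
    try:
        records = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"bad tensor JSON: {exc}") from exc
    return [
        ShieldingTensor(
            origin=np.asarray(r["origin"]), sigma=np.asarray(r["sigma"]), label=r.get("label", "")
        )
        for r in records
    ]
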