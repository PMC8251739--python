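# vist — visualisation of chemical shielding tensors

`vist` is a toolkit for analysing aromaticity and antiaromaticity through
the full 3×3 chemical shielding tensor rather than a single scalar. It is
aimed at computational chemists who already run NICS (nucleus-independent
chemical shift) calculations and want to see *where* and *in which
direction* a molecule shields or deshields — essential for non-planar
macrocycles, stacked π-systems and anything with competing ring currents in
different planes.

## The method

The chemical shielding tensor σ is the mixed second derivative of the
energy with respect to an external field component B<sub>β</sub> and a
nuclear-moment component μ<sub>γ</sub>; evaluated at a virtual point it
gives the NICS value

&nbsp;&nbsp;&nbsp;&nbsp;NICS = −σ<sub>iso</sub> = −(σ<sub>xx</sub> + σ<sub>yy</sub> + σ<sub>zz</sub>)/3,

negative at aromatic ring centres, positive at antiaromatic ones. The core
operation here constructs the principal axes of σ as its eigenvectors,
σ q⃗<sup>(i)</sup> = t<sup>(i)</sup> q⃗<sup>(i)</sup>, and renders each
component as an oriented dumb-bell whose length tracks |t<sup>(i)</sup>|
and whose colour encodes the sign of −t<sup>(i)</sup> (blue = shielded /
aromatic, red = deshielded / antiaromatic). Because σ is generally
non-symmetric, the default decomposition symmetrizes it (real eigenvalues,
orthogonal axes; the antisymmetric part never affects any isotropic value),
with a `right-eigen` mode that keeps the raw matrix and flags complex
eigenvalue pairs.

Around that core the package provides:

* **probes** — ring centroids/normals, NICS(0)/(1)/(2) offsets, bond
  probes, line scans and planar grids, exportable as ghost-atom ("Bq")
  NMR input decks;
* **qcio** — readers/writers for XYZ, Gaussian-dialect shielding logs,
  cube densities, and CSV/JSON tensor tables;
* **lamb** — numerical integration of the diamagnetic (Lamb) shielding
  tensor from a density grid, gauge origin at the probe;
* **ring_sim** — classical current-loop models (point-dipole and
  Biot–Savart) that generate physically structured tensor fields for
  testing and teaching;
* **glyphs** — dumb-bell scenes as VMD draw scripts, OBJ meshes or JSON.

## Worked example

```python
import numpy as np
from vist import ShieldingTensor, nics_iso, vist_decompose

t = ShieldingTensor(origin=[0, 0, 0], sigma=np.diag([6.7, 6.7, 13.3]))
v = vist_decompose(t)
print(f"isotropic NICS(0):  {nics_iso(t):6.1f} ppm")
print(f"dominant component: {v.nics_components[0]:6.1f} ppm along {v.axes[0]}")
```

prints

```
isotropic NICS(0):    -8.9 ppm
dominant component:  -13.3 ppm along [0. 0. 1.]
```

— the benzene ring centre: every axis is shielded, the dominant −13.3 ppm
out-of-plane component reflects the in-plane ring current, and the three
components average to the familiar isotropic NICS(0) of −8.9 ppm. The
scripts in `examples/` walk through the other capabilities (axial scans
and parameter recovery, the Lamb integrator against its closed form, glyph
rendering, and the probe → input deck → log → table round trip); the CLI
(`vist probe|analyze|render|simulate|lamb`) wires the same steps together
from the shell.

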