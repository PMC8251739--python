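# Methods

## Shielding tensors and NICS

The package stores the chemical shielding tensor σ as a real 3×3 matrix in
ppm, indexed (γ, β) with γ the nuclear-moment component and β the field
component, anchored at a probe point in Å. Physically σ is the mixed second
derivative of the energy with respect to field and moment; it is generally
non-symmetric, and only its total (not the diamagnetic/paramagnetic split,
which is gauge-origin dependent) is observable. NICS values are sign
conventions on top of σ: NICS = −trace(σ)/3, and the directional component
along a unit vector u is −uᵀσu, so negative values mean shielding
(aromatic) and positive deshielding (antiaromatic).

## Principal-axis decomposition

`vist_decompose` diagonalises the tensor and returns eigenvalues
t⁽¹⁾…t⁽³⁾ with unit axes q⁽¹⁾…q⁽³⁾. Two modes exist because the matrix is
non-symmetric:

* **symmetrized** (default): eigendecomposition of (σ + σᵀ)/2 via a
  symmetric solver. Eigenvalues are guaranteed real and axes orthogonal,
  and every scalar NICS quantity is unchanged because the antisymmetric
  part is traceless and vanishes in uᵀσu. This is the mode all rendering
  defaults to.
* **right-eigen**: right eigenvectors of the raw matrix. Eigenvalues can
  occur as complex-conjugate pairs; when they do, the real parts are
  retained, `complex_flag` is set, and the maximum imaginary magnitude is
  stored. The flag propagates into glyphs, which are drawn
  semi-transparent, so a complex pair is visible rather than silently
  truncated. Left eigenvectors differ from right ones in this regime; the
  package exposes the right-eigenvector convention and the symmetrized
  mode rather than privileging one presentation of the non-normal case.

Ordering and orientation are made deterministic for testing and rendering:
components sort by descending |t|, ties break by descending signed t and
then by the axis closest to +z; each axis is flipped so its
largest-magnitude Cartesian entry is positive. For exactly degenerate
eigenvalues the axes within the degenerate subspace are an arbitrary
orthonormal basis of it (the solver's choice); tests therefore compare
degenerate axes only up to that freedom.

## Probe generation

Ring planes are defined by the least-variance direction of the centred
ring atoms — equivalent to the best-fit plane, and the natural
generalisation for puckered rings. The normal's sign follows the
right-hand rule over the supplied atom ordering, and "above" a ring means
the positive side of that normal. Because the two faces of a ring in a
non-planar molecule are inequivalent, offset probes can optionally be
mirrored to both sides. Line scans place n equally spaced points labelled
by fractional position; planar grids use an orthonormal in-plane basis
seeded from the Cartesian axis least aligned with the normal. All
user-facing coordinates are Å; only the cube reader/writer converts to
bohr (0.52917721 Å/bohr).

## File formats

The shielding-log parser reads the dialect in which per-centre blocks
follow a "Magnetic shielding tensor (ppm)" marker with rows labelled
XX/YX/ZX, XY/YY/ZY, XZ/YZ/ZZ. Labels are mapped as printed with the first
letter as the row index, so the first printed line fills the first column
of σ; a writer for the same dialect exists so the mapping is pinned by a
round-trip test, and the symmetrized default makes all scalar results
robust to a transposed reading in any case. Positions come from the
standard- or input-orientation table (selectable, since engines may rotate
the frame between them). Cube files use the standard layout (two comment
lines, counts and axis vectors, atoms, values with z fastest); negative
atom counts signal multi-dataset MO cubes and are rejected explicitly.
Any other engine's output enters through the CSV/JSON tensor tables
(columns label, x, y, z, s_xx…s_zz row-major).

## Diamagnetic (Lamb) integrator

With the gauge origin at the probe, the diamagnetic tensor is
σ_dia(γβ) = (α²/2)∫(r²δ_γβ − r_γ r_β)/r³ ρ(r) dr with r measured from the
probe; the diagonal reduces to the textbook Lamb form and is non-negative
for any non-negative density. The general-component form is the standard
tensor extension of that diagonal expression. The conversion constant
α²×10⁶ = 53.2514 ppm uses α = 1/137.035999. Quadrature is midpoint
(voxel-centred) with the voxel containing the probe excluded: the
integrand is O(1/r) there, so the excluded mass vanishes with resolution,
and the scheme's error is controlled empirically by a voxel-halving
convergence test rather than by a singular-kernel correction. On a unit
Gaussian density (exponent 1 bohr⁻², box ±5 bohr) the integrator is within
0.45% of the closed form σ_iso = (α²/3)·2√(a/π) at h = 0.1 bohr and
changes by 0.34% on halving h — those grid sizes (101³ and 201³ voxels)
are the ones the tests and the acceptance script use. Only the
diamagnetic term is computed; paramagnetic deshielding needs
excited-state wavefunctions and is out of scope, so the module makes no
claim beyond the probe-at-gauge-origin convention.

## Ring-current simulator

The simulator is the package's synthetic-data generator and physics
oracle. A ring is a circular loop (centre, unit normal n̂, radius a,
strength κ in ppm·Å³) whose current responds linearly to the normal
component of the applied field only — a flat ring has no in-plane
response. That minimal model produces exactly the anisotropy the glyphs
display: the point-dipole form σ = κ(3d̂d̂ᵀ − I)n̂n̂ᵀ/|d|³ gives +2κ/z³
along the normal on-axis (shielded for diatropic κ > 0) and −κ/d³ at
distant in-plane points (deshielded), with the pattern reversed for
paratropic κ < 0. The Biot–Savart variant discretises the loop into
segments with the current scaled so the far-field dipole moment equals κ
(unit system μ₀/4π = 1); it matches the on-axis closed form
σ_nn = 2κ/(a²+z²)^{3/2} to better than 0.1% at 512 segments and the
dipole model to better than 1% beyond 20 radii. Superposition over loops
is exact by linearity.

One structural consequence of the normal-only response is worth stating:
σ = κ·b·n̂ᵀ has only its n̂-column nonzero, so coaxial flat loops produce
*no* in-plane diagonal components anywhere on their axis. In-plane
shielding at the mid-gap of a stacked antiaromatic pair — the
through-space aromaticity signature — therefore requires representing the
through-space current itself as a loop in a vertical plane, which is how
the stacked-pair test and example are built. Default study conditions for
the recovery test mimic a benzene-like ring: a = 1.39 Å, κ = 75 ppm·Å³
(chosen so the NICS(1)-position component is ≈ −30 ppm), a 21-point axial
scan on z ∈ [0.5, 4.5] Å with 0.1 ppm Gaussian noise and an explicit seed;
a scipy least-squares fit of the closed form recovers both parameters
within 1%, comfortably inside the 5% tolerance asserted.

What the simulator does *not* emulate: real electron-density effects
(σ-framework shielding near nuclei and bonds), paramagnetic terms beyond
an effective negative κ, non-circular current paths, and any quantitative
correspondence to DFT/GIAO ppm values. Passing tests therefore demonstrate
correct tensor algebra, sign structure and field geometry — not agreement
with quantum-chemical shieldings, which must come from an external engine
through the log/table interfaces.

## Glyph encoding

Each retained component becomes a dumb-bell: a rod of length
scale × |t⁽ⁱ⁾| (default 0.04 Å/ppm, capped at 4 Å) along q⁽ⁱ⁾ with end
lobes of radius 0.25 × half-length, blue when the NICS component −t⁽ⁱ⁾ is
negative (shielded/aromatic) and red when positive. Components below the
display threshold (default 1 ppm) are omitted. The exact primitive and the
size mapping are display conventions, kept fully parameterised; the
defaults make a benzene-like −29.5 ppm component about 1.2 Å long. TCL
(VMD draw commands), OBJ (16-gon cylinders, 8-stack UV spheres) and JSON
outputs use fixed 6-decimal formatting and LF endings so identical scenes
are byte-identical; JSON is the lossless round-trip format.

## Degenerate and error cases

Non-finite tensor entries, non-unit normals/directions, coincident scan
endpoints, collinear ring atoms, negative densities, probes at loop
centres or on the wire, truncated or mislabelled log/cube payloads all
raise typed errors naming the offending quantity. Probes closer than
0.1 Å to an atom when writing input decks warn but do not fail, since
some engines tolerate near-coincident ghosts.

## Problem sizes

The test-suite and acceptance computations use 1000 random tensors for
trace/oracle checks, 200 random rotations, 512-segment loops, 101³/201³
Lamb grids and 21-point scans — sizes at which every numerical claim above
is at least an order of magnitude inside its stated tolerance while the
whole suite runs in well under a minute.
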