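"""Axial NICS scan over a simulated aromatic ring current, then recover the
loop parameters from the noisy scan.

A diatropic loop (radius 1.39 A, strength 75 ppm*A^3 — benzene-like) is
scanned along its axis with the Biot-Savart model; the scan is then
refitted to check that strength and radius come back.
"""

import numpy as np

from vist import (
    CurrentLoop,
    field_scan,
    fit_axial_scan,
    line_scan,
    nics_component,
    noisy_axial_scan,
)

loop = CurrentLoop(centre=[0, 0, 0], normal=[0, 0, 1], radius=1.39, strength=75.0)

probes = line_scan([0, 0, 0.5], [0, 0, 4.5], 9, prefix="axial")
tensors = field_scan([loop], probes, model="biot_savart")
print("  z (A)   NICS_zz (ppm)")
for p, t in zip(probes, tensors):
    print(f"  {p.position[2]:5.2f}   {nics_component(t, [0, 0, 1]):8.2f}")
print("Negative NICS_zz all along the axis: the loop is diatropic (aromatic),")
print("strongest near the ring and decaying with distance.\n")

z = np.linspace(0.5, 4.5, 21)
scan = noisy_axial_scan(loop, z, noise_sigma=0.1, seed=2021)
kappa, a = fit_axial_scan(z, scan, kappa0=10.0, a0=1.0)
print(f"recovered strength kappa = {kappa:6.2f} ppm*A^3  (true 75.00)")
print(f"recovered radius   a     = {a:6.3f} A         (true 1.390)")
print("A 21-point scan with 0.1 ppm noise pins both loop parameters to <1%.")
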