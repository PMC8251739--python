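"""Ring-current models: algebraic limits, oracle agreement, sign structure."""

import numpy as np
import pytest

from vist import (
    CurrentLoop,
    ProbeSet,
    Probe,
    SingularityError,
    axial_nics_closed_form,
    field_scan,
    fit_axial_scan,
    line_scan,
    loop_tensor_biot_savart,
    loop_tensor_dipole,
    loops_from_config,
    nics_component,
    noisy_axial_scan,
)


def diatropic(radius=1.39, strength=75.0, centre=(0, 0, 0), normal=(0, 0, 1)):
    return CurrentLoop(centre=np.array(centre, float), normal=np.array(normal, float),
                       radius=radius, strength=strength)


class TestDipoleModel:
    def test_on_axis_value(self):
        loop = diatropic(strength=10.0)
        t = loop_tensor_dipole(loop, [0, 0, 2.0])
        # sigma_nn = 2 kappa / z^3; transverse columns vanish
        assert t.sigma[2, 2] == pytest.approx(2 * 10.0 / 8.0)
        assert np.allclose(t.sigma[:, :2], 0.0, atol=1e-15)
        # shielded along the normal for a diatropic loop
        assert nics_component(t, [0, 0, 1]) < 0

    def test_in_plane_deshielded(self):
        loop = diatropic(strength=10.0)
        t = loop_tensor_dipole(loop, [3.0, 0, 0])
        assert t.sigma[2, 2] == pytest.approx(-10.0 / 27.0)
        assert nics_component(t, [0, 0, 1]) > 0  # deshielded outside the ring

    def test_zero_strength(self):
        t = loop_tensor_dipole(diatropic(strength=0.0), [1.0, 1.0, 1.0])
        assert np.allclose(t.sigma, 0.0)

    def test_centre_is_singular(self):
        with pytest.raises(SingularityError):
            loop_tensor_dipole(diatropic(), [0, 0, 0])

    def test_off_axis_tensor_is_nonsymmetric(self):
        t = loop_tensor_dipole(diatropic(), [2.0, 0.5, 1.5])
        assert not np.allclose(t.sigma, t.sigma.T)


class TestBiotSavart:
    def test_on_axis_closed_form(self):
        """Finite-loop axial field ~ a^2/(a^2+z^2)^(3/2), 0.1% at 512 segments."""
        loop = diatropic()
        for z in (0.5, 1.0, 2.0, 5.0):
            t = loop_tensor_biot_savart(loop, [0, 0, z], n_segments=512)
            exact = -axial_nics_closed_form(loop, z)
            assert t.sigma[2, 2] == pytest.approx(exact, rel=1e-3)

    def test_matches_dipole_far_field(self):
        loop = diatropic()
        d = 20 * loop.radius
        for point in ([0, 0, d], [d, 0, 0], [d / np.sqrt(2), 0, d / np.sqrt(2)]):
            tb = loop_tensor_biot_savart(loop, point, n_segments=512)
            td = loop_tensor_dipole(loop, point)
            scale = np.max(np.abs(td.sigma))
            assert np.max(np.abs(tb.sigma - td.sigma)) < 0.01 * scale

    def test_segment_convergence(self):
        loop = diatropic()
        point = [0.8, 0.6, 3 * loop.radius]
        t1 = loop_tensor_biot_savart(loop, point, n_segments=512)
        t2 = loop_tensor_biot_savart(loop, point, n_segments=1024)
        assert np.max(np.abs(t1.sigma - t2.sigma)) < 1e-4 * np.max(np.abs(t2.sigma))

    def test_wire_is_singular(self):
        with pytest.raises(SingularityError, match="wire"):
            loop_tensor_biot_savart(diatropic(radius=1.0), [1.0, 0, 0], n_segments=4096)

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError, match="8 segments"):
            loop_tensor_biot_savart(diatropic(), [0, 0, 1.0], n_segments=4)


class TestSignStructure:
    def test_diatropic_pattern(self):
        """Aromatic loop: NICS < 0 along the normal on-axis, > 0 at distant
        in-plane points."""
        loop = diatropic()
        for z in (0.5, 1.0, 2.0, 4.0):
            t = loop_tensor_biot_savart(loop, [0, 0, z], n_segments=128)
            assert nics_component(t, [0, 0, 1]) < 0
        for d in (2.5, 4.0, 8.0):
            t = loop_tensor_biot_savart(loop, [d, 0, 0], n_segments=128)
            assert nics_component(t, [0, 0, 1]) > 0

    def test_paratropic_pattern_reversed(self):
        """Antiaromatic loop: dominant positive NICS component along the normal."""
        from vist import vist_decompose

        loop = diatropic(strength=-75.0)
        t = loop_tensor_dipole(loop, [0, 0, 1.0])
        v = vist_decompose(t)
        assert v.nics_components[0] > 0
        assert abs(v.axes[0] @ np.array([0, 0, 1.0])) > 0.99

    def test_through_space_signature_in_stacked_antiaromatic_pair(self):
        """Stacked antiaromatic rings bridged by a through-space (vertical-
        plane) diatropic loop show, at the mid-gap point, in-plane shielding
        of opposite sign to the out-of-plane deshielding; an isolated flat
        ring, responding only along its own normal, produces no in-plane
        component there at all."""
        h = 1.7
        top = diatropic(strength=-75.0, centre=(0, 0, h))
        probes = ProbeSet([Probe("mid", [0, 0, 0])])
        single = field_scan([top], probes, model="biot_savart")[0]
        assert nics_component(single, [1, 0, 0]) == pytest.approx(0.0, abs=1e-12)
        through_space = CurrentLoop(centre=[0, 0, 0], normal=[1, 0, 0],
                                    radius=h, strength=40.0)
        stacked = [top, diatropic(strength=-75.0, centre=(0, 0, -h)), through_space]
        t = field_scan(stacked, probes, model="biot_savart")[0]
        assert nics_component(t, [0, 0, 1]) > 0  # residual antiaromaticity
        assert nics_component(t, [1, 0, 0]) < 0  # through-space aromaticity


class TestFieldScan:
    def test_superposition_two_parallel_loops(self):
        h = 2.0
        loops = [diatropic(strength=10.0, centre=(0, 0, h)),
                 diatropic(strength=10.0, centre=(0, 0, -h))]
        t = field_scan(loops, ProbeSet([Probe("mid", [0, 0, 0])]))[0]
        assert t.sigma[2, 2] == pytest.approx(2 * (2 * 10.0 / h**3))

    def test_axial_decay_monotonic(self):
        loop = diatropic()
        ps = line_scan([0, 0, 1.0], [0, 0, 8.0], 15)
        tensors = field_scan([loop], ps, model="biot_savart")
        mags = [abs(t.sigma[2, 2]) for t in tensors]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_empty_loop_list(self):
        tensors = field_scan([], line_scan([0, 0, 1], [0, 0, 2], 3))
        assert all(np.allclose(t.sigma, 0.0) for t in tensors)

    def test_singularity_names_pair(self):
        with pytest.raises(SingularityError, match="loop 0 at probe 'mid'"):
            field_scan([diatropic()], ProbeSet([Probe("mid", [0, 0, 0])]))


class TestParameterRecovery:
    def test_recover_kappa_and_radius(self):
        """kappa and a of a single loop come back within 5% from a noisy
        21-point axial scan (noise 0.1 ppm, fixed seed)."""
        loop = diatropic(radius=1.39, strength=75.0)
        z = np.linspace(0.5, 4.5, 21)
        nics = noisy_axial_scan(loop, z, noise_sigma=0.1, seed=2021)
        kappa, a = fit_axial_scan(z, nics, kappa0=10.0, a0=1.0)
        assert kappa == pytest.approx(75.0, rel=0.05)
        assert a == pytest.approx(1.39, rel=0.05)

    def test_scan_reproducible_for_fixed_seed(self):
        loop = diatropic()
        z = np.linspace(0.5, 4.5, 21)
        assert np.array_equal(noisy_axial_scan(loop, z, seed=7), noisy_axial_scan(loop, z, seed=7))


class TestConfig:
    def test_loops_from_config(self):
        cfg = {"loops": [{"centre": [0, 0, 0], "normal": [0, 0, 2], "radius": 1.4,
                          "strength": -30.0}]}
        (loop,) = loops_from_config(cfg)
        assert np.allclose(loop.normal, [0, 0, 1])
        assert loop.strength == -30.0

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown keys"):
            loops_from_config({"loops": [{"centre": [0, 0, 0], "normal": [0, 0, 1],
                                          "radius": 1.0, "strength": 1.0, "turns": 2}]})

    def test_invalid_loop_geometry_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            CurrentLoop(centre=[0, 0, 0], normal=[0, 0, 1], radius=-1.0, strength=1.0)
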