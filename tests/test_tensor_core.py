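"""Principal-axis decomposition, NICS extraction and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vist import ShieldingTensor, nics_component, nics_iso, symmetrize, vist_decompose

from conftest import random_rotation


def tensor(sigma, **kw):
    return ShieldingTensor(origin=[0.0, 0.0, 0.0], sigma=np.asarray(sigma, float), **kw)


def char_poly_roots(sigma):
    """Independent eigenvalue oracle: roots of det(sigma - t I) via np.roots
    on explicitly expanded characteristic-polynomial coefficients."""
    s = np.asarray(sigma, float)
    c2 = -np.trace(s)
    c1 = 0.5 * (np.trace(s) ** 2 - np.trace(s @ s))
    c0 = -np.linalg.det(s)
    return np.roots([1.0, c2, c1, c0])


class TestSymmetrize:
    def test_idempotent_on_symmetric(self):
        s = np.array([[1.0, 2.0, 3.0], [2.0, 5.0, 6.0], [3.0, 6.0, 9.0]])
        assert np.array_equal(symmetrize(tensor(s)).sigma, s)

    def test_forced_by_definition(self):
        s = np.zeros((3, 3))
        s[0, 1] = 4.0
        out = symmetrize(tensor(s)).sigma
        assert out[0, 1] == out[1, 0] == 2.0

    def test_removed_part_is_antisymmetric(self, rng):
        s = rng.normal(size=(3, 3)) * 10
        diff = symmetrize(tensor(s)).sigma - s
        assert np.allclose(diff, -diff.T, atol=1e-12)


class TestDecompose:
    def test_diagonal_tensor(self):
        v = vist_decompose(tensor(np.diag([20.0, -5.0, -5.0])))
        assert np.allclose(sorted(v.eigenvalues), [-5, -5, 20])
        assert v.eigenvalues[0] == 20.0
        # axes are the coordinate axes; dominant axis is x
        assert np.allclose(v.axes[0], [1, 0, 0], atol=1e-12)
        assert np.allclose(np.sort(np.abs(v.axes).argmax(axis=1)), [0, 1, 2])

    def test_benzene_dominant_out_of_plane(self):
        """Ring-centre principal shieldings 13.3/6.7/6.7 ppm: the dominant
        NICS component is -13.3 ppm along the ring normal (z)."""
        v = vist_decompose(tensor(np.diag([6.7, 6.7, 13.3])))
        assert v.nics_components[0] == pytest.approx(-13.3)
        assert np.allclose(np.abs(v.axes[0]), [0, 0, 1], atol=1e-12)

    def test_eigenvalues_match_char_poly_oracle(self, rng):
        from vist import CurrentLoop, loop_tensor_dipole

        loop = CurrentLoop(centre=[0, 0, 0], normal=[0, 0, 1], radius=1.39, strength=60.0)
        t = loop_tensor_dipole(loop, [1.8, 0.4, 1.2])  # off-axis, non-symmetric
        sym = 0.5 * (t.sigma + t.sigma.T)
        v = vist_decompose(t, mode="symmetrized")
        assert np.allclose(
            sorted(v.eigenvalues), sorted(char_poly_roots(sym).real), atol=1e-8
        )

    def test_mode_validation(self):
        with pytest.raises(ValueError, match="mode"):
            vist_decompose(tensor(np.eye(3)), mode="left-eigen")

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            tensor(np.full((3, 3), np.nan))

    def test_symmetric_tensor_same_in_both_modes(self, rng):
        s = rng.normal(size=(3, 3))
        s = s + s.T
        v1 = vist_decompose(tensor(s), mode="symmetrized")
        v2 = vist_decompose(tensor(s), mode="right-eigen")
        assert np.allclose(v1.eigenvalues, v2.eigenvalues, atol=1e-10)
        assert not v2.complex_flag

    def test_complex_pair_flagged_not_dropped(self):
        # strong antisymmetric part forces a conjugate eigenvalue pair
        s = np.array([[0.0, 10.0, 0.0], [-10.0, 0.0, 0.0], [0.0, 0.0, 3.0]])
        v = vist_decompose(tensor(s), mode="right-eigen")
        assert v.complex_flag
        assert v.imag_magnitude == pytest.approx(10.0, rel=1e-8)
        # real parts retained; their sum still matches the trace
        assert np.sum(v.eigenvalues) == pytest.approx(np.trace(s), rel=1e-8)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_trace_conservation_both_modes(self, seed):
        s = np.random.default_rng(seed).normal(size=(3, 3)) * 50
        for mode in ("symmetrized", "right-eigen"):
            v = vist_decompose(tensor(s), mode=mode)
            tr = np.trace(s)
            assert np.sum(v.eigenvalues) == pytest.approx(tr, rel=1e-8, abs=1e-8)

    def test_trace_conservation_bulk(self, rng):
        for _ in range(1000):
            s = rng.normal(size=(3, 3)) * 30
            for mode in ("symmetrized", "right-eigen"):
                v = vist_decompose(tensor(s), mode=mode)
                assert abs(np.sum(v.eigenvalues) - np.trace(s)) <= 1e-8 * max(
                    1.0, abs(np.trace(s))
                )

    def test_sorted_by_descending_magnitude(self, rng):
        for _ in range(50):
            s = rng.normal(size=(3, 3)) * 20
            v = vist_decompose(tensor(s))
            mags = np.abs(v.eigenvalues)
            assert mags[0] >= mags[1] >= mags[2]

    def test_axes_unit_and_orthogonal_in_symmetrized_mode(self, rng):
        for _ in range(50):
            s = rng.normal(size=(3, 3)) * 20
            v = vist_decompose(tensor(s))
            assert np.allclose(np.linalg.norm(v.axes, axis=1), 1.0, atol=1e-10)
            gram = v.axes @ v.axes.T - np.eye(3)
            assert np.max(np.abs(gram)) <= 1e-8

    def test_rotation_equivariance(self, rng):
        for _ in range(25):
            s = rng.normal(size=(3, 3)) * 15
            s = s + s.T
            R = random_rotation(rng)
            v = vist_decompose(tensor(s))
            vr = vist_decompose(tensor(R @ s @ R.T))
            assert np.allclose(v.eigenvalues, vr.eigenvalues, atol=1e-8)
            # axes rotate along (up to sign; skip degenerate spectra)
            gaps = np.abs(np.subtract.outer(v.eigenvalues, v.eigenvalues))
            if np.min(gaps[~np.eye(3, dtype=bool)]) > 1e-6:
                for q, qr in zip(v.axes, vr.axes):
                    assert min(
                        np.linalg.norm(qr - R @ q), np.linalg.norm(qr + R @ q)
                    ) < 1e-8

    def test_complex_flag_false_for_symmetric(self, rng):
        for _ in range(100):
            s = rng.normal(size=(3, 3))
            s = s + s.T
            assert not vist_decompose(tensor(s), mode="right-eigen").complex_flag


class TestNics:
    def test_zero_tensor(self):
        assert nics_iso(tensor(np.zeros((3, 3)))) == 0.0

    def test_benzene_isotropic(self):
        """Principal components -13.3/-6.7/-6.7 ppm average to NICS -8.9."""
        t = tensor(np.diag([13.3, 6.7, 6.7]))
        assert nics_iso(t) == pytest.approx(-8.9)

    def test_equals_minus_mean_of_eigenvalues(self, rng):
        for mode in ("symmetrized", "right-eigen"):
            s = rng.normal(size=(3, 3)) * 25
            t = tensor(s)
            v = vist_decompose(t, mode=mode)
            assert nics_iso(t) == pytest.approx(-np.mean(v.eigenvalues), abs=1e-10)

    def test_component_out_of_plane(self):
        t = tensor(np.diag([13.3, 6.7, 6.7]))
        assert nics_component(t, [1.0, 0.0, 0.0]) == pytest.approx(-13.3)

    def test_component_axis_average_is_iso(self, rng):
        s = rng.normal(size=(3, 3)) * 10
        t = tensor(s)
        avg = np.mean([nics_component(t, e) for e in np.eye(3)])
        assert avg == pytest.approx(nics_iso(t), abs=1e-12)

    def test_component_rotation_equivariance(self, rng):
        s = rng.normal(size=(3, 3)) * 10
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        R = random_rotation(rng)
        assert nics_component(tensor(R @ s @ R.T), R @ u) == pytest.approx(
            nics_component(tensor(s), u), abs=1e-9
        )

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            nics_component(tensor(np.eye(3)), [1.0, 1.0, 0.0])
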