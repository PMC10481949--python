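"""Unit tests for the truncated multipole (VSH) field model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import sph_harm_y

from megarray.basis import (
    BasisComponent,
    BasisPart,
    MultipoleBasisSpec,
    basis_field,
    basis_field_matrix,
    basis_matrix,
    basis_row,
    component_count,
    components,
    field_at,
    internal_mask,
    selector_matrix,
)
from megarray.geometry import HelmetSurface, radial_array

from conftest import random_surface_array


def reference_potential(part: str, l: int, m: int, p: np.ndarray) -> float:
    """Independent scalar potential: real orthonormal harmonic times the
    internal/external radial factor (built directly on scipy, not on the
    package's field code)."""
    r = np.linalg.norm(p)
    theta = np.arccos(p[2] / r)
    phi = np.arctan2(p[1], p[0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        yr = y.real
    elif m > 0:
        yr = np.sqrt(2) * (-1) ** m * y.real
    else:
        yr = np.sqrt(2) * (-1) ** abs(m) * y.imag
    return yr / r ** (l + 1) if part == "internal" else r**l * yr


class TestComponentCount:
    @pytest.mark.parametrize(
        "l_int, l_ext, expected",
        [(10, 3, 135), (1, 1, 6), (2, 0, 8), (8, 3, 95), (4, 2, 32)],
    )
    def test_closed_form(self, l_int, l_ext, expected):
        assert component_count(l_int, l_ext) == expected
        spec = MultipoleBasisSpec(l_int, l_ext)
        assert spec.n_components == expected
        assert len(components(spec)) == expected

    @pytest.mark.parametrize("l_int, l_ext", [(0, 3), (-1, 2), (3, -1)])
    def test_invalid_cutoffs_rejected(self, l_int, l_ext):
        with pytest.raises(ValueError):
            component_count(l_int, l_ext)

    def test_canonical_ordering_internal_first(self):
        spec = MultipoleBasisSpec(2, 1)
        comps = components(spec)
        assert [c.column for c in comps] == list(range(spec.n_components))
        internal = [c for c in comps if c.part is BasisPart.INTERNAL]
        assert len(internal) == spec.n_internal
        # l ascending, m ascending within l
        assert [(c.degree, c.order) for c in internal] == [
            (1, -1), (1, 0), (1, 1),
            (2, -2), (2, -1), (2, 0), (2, 1), (2, 2),
        ]


class TestBasisField:
    @pytest.mark.parametrize("l", [1, 3, 7])
    @pytest.mark.parametrize("part", [BasisPart.INTERNAL, BasisPart.EXTERNAL])
    def test_radial_homogeneity(self, l, part):
        """Internal fields scale as r^-(l+2) along a ray, external as r^(l-1)."""
        comp = BasisComponent(part, l, 1, 0)
        p = np.array([0.07, -0.11, 0.13])
        ratio = np.linalg.norm(basis_field(comp, 2 * p)) / np.linalg.norm(
            basis_field(comp, p)
        )
        expected = 2.0 ** -(l + 2) if part is BasisPart.INTERNAL else 2.0 ** (l - 1)
        assert ratio == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        l=st.integers(1, 9),
        m=st.integers(-9, 9),
        part=st.sampled_from([BasisPart.INTERNAL, BasisPart.EXTERNAL]),
        scale=st.floats(0.5, 3.0),
    )
    def test_homogeneity_property(self, l, m, part, scale):
        """|B(c*r)| / |B(r)| follows the radial power law for any scale c."""
        if abs(m) > l:
            m = m % (l + 1)
        comp = BasisComponent(part, l, m, 0)
        p = np.array([0.04, -0.09, 0.11])
        ratio = np.linalg.norm(basis_field(comp, scale * p)) / np.linalg.norm(
            basis_field(comp, p)
        )
        power = -(l + 2) if part is BasisPart.INTERNAL else l - 1
        assert ratio == pytest.approx(scale**power, rel=1e-10)

    def test_field_is_negative_gradient_of_potential(self, rng):
        """Analytic field equals the central-difference gradient of the
        harmonic potential to < 1e-6 relative error."""
        for _ in range(25):
            l = int(rng.integers(1, 9))
            m = int(rng.integers(-l, l + 1))
            part = str(rng.choice(["internal", "external"]))
            p = rng.normal(size=3)
            p *= rng.uniform(0.1, 0.3) / np.linalg.norm(p)
            comp = BasisComponent(BasisPart(part), l, m, 0)
            B = basis_field(comp, p)
            h = 1e-6
            grad = np.zeros(3)
            for i in range(3):
                dp = np.zeros(3)
                dp[i] = h
                grad[i] = -(
                    reference_potential(part, l, m, p + dp)
                    - reference_potential(part, l, m, p - dp)
                ) / (2 * h)
            assert np.linalg.norm(B - grad) < 1e-6 * np.linalg.norm(grad)

    def test_divergence_and_curl_free(self, rng):
        """Numerically estimated div B and curl B vanish for every component
        family (finite differences, relative to the field magnitude)."""
        h = 1e-6
        for part, l, m in [("internal", 2, -1), ("internal", 6, 4), ("external", 3, -2)]:
            comp = BasisComponent(BasisPart(part), l, m, 0)
            p = rng.normal(size=3)
            p *= 0.2 / np.linalg.norm(p)
            J = np.zeros((3, 3))  # J[i, j] = dB_i / dx_j
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = h
                J[:, j] = (basis_field(comp, p + dp) - basis_field(comp, p - dp)) / (
                    2 * h
                )
            scale = np.abs(J).max()
            assert abs(J.trace()) < 1e-4 * scale
            curl = np.array(
                [J[2, 1] - J[1, 2], J[0, 2] - J[2, 0], J[1, 0] - J[0, 1]]
            )
            assert np.linalg.norm(curl) < 1e-4 * scale

    def test_origin_evaluation_rejected(self):
        comp = BasisComponent(BasisPart.INTERNAL, 1, 0, 0)
        with pytest.raises(ValueError):
            basis_field(comp, np.zeros(3))

    def test_near_axis_evaluation_is_continuous(self):
        """Points on and just off the polar axis give consistent fields."""
        comp = BasisComponent(BasisPart.INTERNAL, 3, 1, 0)
        on_axis = basis_field(comp, np.array([0.0, 0.0, 0.2]))
        off_axis = basis_field(comp, np.array([1e-8, 0.0, 0.2]))
        assert np.linalg.norm(off_axis - on_axis) < 1e-6 * np.linalg.norm(on_axis)


class TestSelectors:
    def test_completeness_and_orthogonality(self):
        spec = MultipoleBasisSpec(3, 2)
        i_int = selector_matrix(spec, BasisPart.INTERNAL)
        i_ext = selector_matrix(spec, BasisPart.EXTERNAL)
        assert np.array_equal(i_int + i_ext, np.eye(spec.n_components))
        assert np.array_equal(i_int @ i_ext, np.zeros((spec.n_components,) * 2))

    def test_coefficient_split(self, rng):
        spec = MultipoleBasisSpec(2, 2)
        x = rng.normal(size=spec.n_components)
        mask = internal_mask(spec)
        assert np.array_equal(x * mask + x * ~mask, x)


class TestRowsAndMatrices:
    def test_row_matches_componentwise_fields(self, rng):
        spec = MultipoleBasisSpec(3, 2)
        r = np.array([0.05, 0.1, 0.12])
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        row = basis_row(r, e, spec)
        expected = [
            e @ basis_field(c, r, origin=spec.origin) for c in components(spec)
        ]
        assert np.allclose(row, expected, rtol=1e-12)

    def test_directional_functional_linear_in_orientation(self, rng):
        """e -> e . B_j(r) is linear before unit normalization."""
        spec = MultipoleBasisSpec(2, 1)
        r = np.array([0.0, 0.11, 0.14])
        F = basis_field_matrix(r, spec)[0]
        u, v = rng.normal(size=3), rng.normal(size=3)
        a, b = 0.7, -1.3
        assert np.allclose((a * u + b * v) @ F, a * (u @ F) + b * (v @ F), rtol=1e-12)

    def test_non_unit_orientation_rejected(self):
        spec = MultipoleBasisSpec(1, 0)
        with pytest.raises(ValueError):
            basis_row(np.array([0.1, 0, 0.1]), np.array([1.0, 1.0, 0.0]), spec)

    def test_matrix_rows_are_sensor_rows(self, surface, rng):
        spec = MultipoleBasisSpec(2, 1)
        arr = random_surface_array(surface, 5, rng)
        S = basis_matrix(arr, spec)
        assert S.shape == (5, spec.n_components)
        for i in range(5):
            assert np.allclose(
                S[i], basis_row(arr.positions[i], arr.orientations[i], spec)
            )

    def test_duplicated_sensor_duplicates_row(self, surface, rng):
        spec = MultipoleBasisSpec(2, 0)
        arr = random_surface_array(surface, 4, rng)
        dup = arr.concatenate(arr.subset([0]))
        S = basis_matrix(dup, spec)
        assert np.array_equal(S[0], S[4])
        assert np.linalg.matrix_rank(S) == np.linalg.matrix_rank(S[:4])

    def test_field_at_consistency(self, rng):
        spec = MultipoleBasisSpec(3, 1)
        x = rng.normal(size=spec.n_components)
        r = np.array([0.12, -0.03, 0.08])
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        assert e @ field_at(x, r, spec) == pytest.approx(
            float(basis_row(r, e, spec) @ x), rel=1e-12
        )

    def test_field_at_trivial_cases(self):
        spec = MultipoleBasisSpec(2, 1)
        r = np.array([0.1, 0.02, 0.1])
        assert np.array_equal(field_at(np.zeros(spec.n_components), r, spec), np.zeros(3))
        x = np.zeros(spec.n_components)
        x[4] = 2.5
        comp = components(spec)[4]
        assert np.allclose(field_at(x, r, spec), 2.5 * basis_field(comp, r))


class TestCrossValidation:
    def test_matches_established_sss_basis_up_to_column_scale(self, rng):
        """Sensor matrices agree with MNE-Python's SSS basis up to a fixed
        per-column scale factor (different normalization conventions)."""
        from mne.preprocessing.maxwell import _sss_basis

        m = 40
        pos = rng.normal(size=(m, 3))
        pos *= rng.uniform(0.12, 0.25, (m, 1)) / np.linalg.norm(
            pos, axis=1, keepdims=True
        )
        ori = rng.normal(size=(m, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)

        class _Arr:
            positions = pos
            orientations = ori

        spec = MultipoleBasisSpec(4, 3)
        S_ours = basis_matrix(_Arr, spec)
        S_ref = _sss_basis(
            dict(origin=np.zeros(3), int_order=4, ext_order=3),
            (pos.copy(), ori.copy(), np.arange(m), m),
        )
        assert S_ref.shape == S_ours.shape
        for j in range(S_ours.shape[1]):
            a, b = S_ours[:, j], S_ref[:, j]
            scale = (a @ b) / (b @ b)
            assert np.linalg.norm(a - scale * b) < 1e-10 * np.linalg.norm(a)
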