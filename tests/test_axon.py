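"""Axon paths, driver profiles, activating function, normalization."""

import numpy as np
import pytest

import olftes as ot
from olftes.errors import (
    DegeneratePathError,
    InsufficientSamplesError,
    NormalizationError,
    OutOfDomainError,
)
from olftes.solver import PotentialField

from conftest import uniform_ef


def grid_phantom(n=20, spacing=1.0):
    """Minimal grid container exposing coordinate geometry for sampling."""
    labels = np.ones((n, n, n), dtype=np.int16)
    return ot.VoxelPhantom(
        labels=labels, spacing=spacing, origin=np.zeros(3),
        fiducials={"nasion": np.array([n / 2, n - 1.0, n / 2]),
                   "inion": np.array([n / 2, 0.0, n / 2]),
                   "left_preauricular": np.array([0.0, n / 2, n / 2]),
                   "right_preauricular": np.array([n - 1.0, n / 2, n / 2]),
                   "vertex": np.array([n / 2, n / 2, n - 1.0])},
    )


def potential_from(fn, n=20, spacing=1.0):
    x = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    return PotentialField(values=fn(X, Y, Z), mask=np.ones((n, n, n), bool),
                          spacing=spacing, iterations=1, relative_residual=0.0)


class TestMakeAxon:
    def test_straight_segment_sample_count(self):
        path = ot.make_axon([[0, 0, 0], [10, 0, 0]], ds_mm=0.5)
        assert len(path.points) == 21
        assert np.allclose(np.diff(path.arc_length), 0.5)

    def test_l_shape_total_length(self):
        path = ot.make_axon([[0, 0, 0], [5, 0, 0], [5, 7, 0]], ds_mm=0.25)
        assert path.arc_length[-1] == pytest.approx(12.0, abs=0.25)

    def test_uniform_resampling_increments(self):
        path = ot.make_axon([[0, 0, 0], [3, 4, 0], [3, 4, 6]], ds_mm=0.1)
        seg = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
        assert np.allclose(seg, 0.1, atol=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegeneratePathError):
            ot.make_axon([[1, 1, 1], [1, 1, 1]], ds_mm=0.1)

    def test_text_and_json_round_trip(self, tmp_path):
        path = ot.make_axon([[0, 0, 0], [4, 2, 1]], ds_mm=0.2, roi_name="demo")
        path.to_json(tmp_path / "a.json")
        back = ot.AxonPath.from_json(tmp_path / "a.json")
        assert np.allclose(back.points, path.points)
        assert back.roi_name == "demo"
        path.to_text(tmp_path / "a.txt")
        pts = np.loadtxt(tmp_path / "a.txt")
        assert np.allclose(pts, path.points, atol=1e-6)


class TestSampling:
    def test_constant_potential(self):
        ph = grid_phantom()
        pot = potential_from(lambda X, Y, Z: np.full_like(X, 0.25))
        path = ot.make_axon([[2, 5, 5], [15, 5, 5]], ds_mm=0.5)
        ve = ot.potential_along_axon(pot, path, ph)
        assert np.allclose(ve, 0.25)

    def test_linear_potential_slope(self):
        ph = grid_phantom()
        pot = potential_from(lambda X, Y, Z: 0.002 * X)
        path = ot.make_axon([[2, 5, 5], [15, 5, 5]], ds_mm=0.5)
        ve = ot.potential_along_axon(pot, path, ph)
        slope = np.diff(ve) / 0.5
        assert np.allclose(slope, 0.002, atol=1e-12)

    def test_trilinear_midpoint(self):
        ph = grid_phantom(4)
        V = np.zeros((4, 4, 4))
        V[2:] = 1.0  # step between x-index 1 and 2
        pot = PotentialField(values=V, mask=np.ones((4, 4, 4), bool), spacing=1.0,
                             iterations=1, relative_residual=0.0)
        path = ot.make_axon([[1.0, 1, 1], [2.0, 1, 1]], ds_mm=0.25)
        ve = ot.potential_along_axon(pot, path, ph)
        assert ve[2] == pytest.approx(0.5)  # midpoint between voxel centers

    def test_out_of_domain_rejected(self):
        ph = grid_phantom(8)
        pot = potential_from(lambda X, Y, Z: X, n=8)
        pot.mask[5:] = False
        pot.values[5:] = np.nan
        path = ot.make_axon([[1, 3, 3], [7, 3, 3]], ds_mm=0.5)
        with pytest.raises(OutOfDomainError):
            ot.potential_along_axon(pot, path, ph)


class TestTangentialField:
    def test_parallel_uniform_field(self):
        ph = grid_phantom()
        ef = uniform_ef((20, 20, 20), (1.0, 0.0, 0.0))
        path = ot.make_axon([[2, 5, 5], [15, 5, 5]], ds_mm=0.5)
        et = ot.ef_along_axon(ef, path, ph)
        assert np.allclose(et, 1.0)

    def test_perpendicular_field_zero(self):
        ph = grid_phantom()
        ef = uniform_ef((20, 20, 20), (0.0, 0.0, 0.7))
        path = ot.make_axon([[2, 5, 5], [15, 5, 5]], ds_mm=0.5)
        assert np.allclose(ot.ef_along_axon(ef, path, ph), 0.0, atol=1e-12)

    def test_reversal_flips_sign(self):
        """A path doubling back reverses the sign of Et in a uniform field."""
        ph = grid_phantom()
        ef = uniform_ef((20, 20, 20), (1.0, 0.0, 0.0))
        path = ot.make_axon([[2, 5, 5], [15, 5, 5], [3, 5.02, 5]], ds_mm=0.5)
        et = ot.ef_along_axon(ef, path, ph)
        assert et[2] > 0.9 and et[-2] < -0.9

    def test_projection_bound_on_solved_field(self, solved_small_pair):
        """|Et| <= |E| pointwise for a real solved field."""
        ef = solved_small_pair["ef"]
        ph = solved_small_pair["stamped"]
        path = ot.make_axon([[0, -12, 0], [0, 12, 0]], ds_mm=0.25)
        et = ot.ef_along_axon(ef, path, ph)
        from olftes.axon import _filled_interpolator

        mag = _filled_interpolator(ef.magnitude, ef.mask, ph)(path.points)
        assert np.all(np.abs(et) <= mag + 1e-12)

    def test_et_matches_minus_dve_ds(self, solved_small_pair):
        """Et equals -dVe/ds along a straight path (two sampling routes)."""
        ef = solved_small_pair["ef"]
        pot = solved_small_pair["potential"]
        ph = solved_small_pair["stamped"]
        path = ot.make_axon([[0, -12, 0], [0, 12, 0]], ds_mm=0.25)
        et = ot.ef_along_axon(ef, path, ph)
        ve = ot.potential_along_axon(pot, path, ph)
        dve = -np.gradient(ve, 0.25e-3)  # volts per meter
        inner = slice(4, -4)
        scale = np.max(np.abs(et[inner]))
        assert np.allclose(et[inner], dve[inner], atol=0.12 * scale)


class TestActivatingFunction:
    def test_linear_ve_zero(self):
        ve = np.linspace(0.0, 1.0, 30)
        f = ot.activating_function(ve, ds_mm=0.5)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_quadratic_exact(self):
        """Ve = a s^2 has activating function 2a (units V/m^2)."""
        a = 3.0  # volts per mm^2
        s = np.arange(40) * 0.25
        f = ot.activating_function(a * s**2, ds_mm=0.25)
        a_si = a / (1e-3) ** 2  # volts per m^2
        assert np.allclose(f[1:-1], 2 * a_si, rtol=1e-9)
        # endpoint convention copies the neighboring one-sided value
        assert f[0] == f[1] and f[-1] == f[-2]

    def test_telescoping_identity(self):
        """Sum of interior second differences telescopes to the end slopes."""
        rng = np.random.default_rng(11)
        ve = rng.standard_normal(25)
        ds = 0.5
        f = ot.activating_function(ve, ds_mm=ds)
        ds_m = ds * 1e-3
        lhs = np.sum(f[1:-1]) * ds_m
        rhs = (ve[-1] - ve[-2]) / ds_m - (ve[1] - ve[0]) / ds_m
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            ot.activating_function(np.array([0.0, 1.0]), ds_mm=0.5)

    def test_af_peak_colocates_with_et_extremum_transition(self):
        """On a quadratic Ve along the path, the constant AF equals the slope
        of -Et, whose zero crossing sits at the Ve minimum (co-location)."""
        path = ot.make_axon([[2, 10, 10], [18, 10, 10]], ds_mm=0.25)
        s = path.arc_length
        ve = 1e-4 * (s - 8.0) ** 2
        f = ot.activating_function(ve, path.ds_mm)
        a_si = 1e-4 / (1e-3) ** 2
        assert np.allclose(f[1:-1], 2 * a_si, rtol=1e-9)
        et = -np.gradient(ve, 0.25e-3)
        assert abs(s[np.argmin(np.abs(et))] - 8.0) <= 0.25


class TestNormalization:
    def _profile(self, mid, scale):
        s = np.arange(20) * 0.5
        return ot.DrivingProfiles(
            s_mm=s, ve_v=scale * np.sin(s), et_v_per_m=scale * np.cos(s),
            af_v_per_m2=scale * np.sin(2 * s), montage_id=mid, roi_name="OE_anterior",
        )

    def test_global_peak_becomes_one(self):
        profiles = [self._profile("A", 2.0), self._profile("B", 0.5)]
        out = ot.normalize_profiles(profiles)
        peak = max(np.max(np.abs(p.et_v_per_m)) for p in out)
        assert peak == pytest.approx(1.0)
        ref = out[0].normalization["et_v_per_m"]["reference_profile"]
        assert ref[0] == "A"

    def test_identical_profiles_identical_outputs(self):
        out = ot.normalize_profiles([self._profile("A", 1.0), self._profile("B", 1.0)])
        assert np.allclose(out[0].et_v_per_m, out[1].et_v_per_m)
        assert np.allclose(out[0].af_v_per_m2, out[1].af_v_per_m2)

    def test_argmax_preserved(self):
        p = self._profile("A", 1.7)
        out = ot.normalize_profiles([p])[0]
        assert np.argmax(np.abs(out.et_v_per_m)) == np.argmax(np.abs(p.et_v_per_m))

    def test_all_zero_rejected(self):
        p = self._profile("A", 0.0)
        with pytest.raises(NormalizationError):
            ot.normalize_profiles([p])

    def test_empty_set_rejected(self):
        with pytest.raises(NormalizationError):
            ot.normalize_profiles([])


class TestDefaultAxons:
    def test_one_axon_per_third_posterior_shortest(self, head_and_rois):
        phantom, rois = head_and_rois
        axons = ot.default_oe_axons(phantom, rois, ds_mm=0.2)
        assert set(axons) == {"OE_anterior", "OE_middle", "OE_posterior"}
        lengths = {k: v.arc_length[-1] for k, v in axons.items()}
        assert lengths["OE_posterior"] < lengths["OE_anterior"]
        assert lengths["OE_posterior"] < lengths["OE_middle"]

    def test_axons_inside_oe(self, head_and_rois):
        phantom, rois = head_and_rois
        axons = ot.default_oe_axons(phantom, rois, ds_mm=0.2)
        for path in axons.values():
            ijk = np.round(phantom.world_to_voxel(path.points)).astype(int)
            assert rois["OE"][ijk[:, 0], ijk[:, 1], ijk[:, 2]].all()
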