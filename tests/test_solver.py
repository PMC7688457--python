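"""Finite-volume assembly, PCG solve, derived fields, quasi-static helpers."""

import numpy as np
import pytest

import olftes as ot
from olftes import units
from olftes.errors import (
    InvalidParameterError,
    SingularSystemError,
    StateError,
)
from olftes.montage import BoundaryConditions, ElectrodeFaces
from olftes.solver import PotentialField, _FACE_OFFSETS


def bar_system(n=12, sigma=0.5, spacing=2.0, current_ma=1.0):
    """Homogeneous 1-voxel-thick bar: flux on one end, ground at the other."""
    sig = np.full((n, 1, 1), sigma)
    face_area = units.mm_to_m(spacing) ** 2
    src = ElectrodeFaces(
        name="src", role=ot.ANTERIOR_SOURCE,
        faces=np.array([[0, 0, 0, 0]]), voxels=np.array([[0, 0, 0]]),
    )
    gnd = ElectrodeFaces(
        name="gnd", role=ot.POSTERIOR_GROUND,
        faces=np.array([[n - 1, 0, 0, 1]]), voxels=np.array([[n - 1, 0, 0]]),
    )
    bc = BoundaryConditions(
        electrodes=[src, gnd],
        jn_a_per_m2=units.ma_to_a(current_ma) / face_area,
        total_current_ma=current_ma, face_area_m2=face_area,
    )
    return ot.assemble_system(sig, bc, spacing), sig


class TestAssembly:
    def test_matrix_symmetric_and_conservative(self):
        system, _ = bar_system()
        A = system.A
        assert (A - A.T).nnz == 0 or abs(A - A.T).max() < 1e-15
        # interior rows (not touching flux or ground) sum to zero
        rowsums = np.asarray(A.sum(axis=1)).ravel()
        assert np.allclose(rowsums[1:-1], 0.0, atol=1e-18)

    def test_harmonic_mean_face_conductance(self):
        """Scalp/skull face conductance uses the harmonic mean of the pair."""
        got = ot.harmonic_mean_conductivity(0.465, 0.01)
        assert got == pytest.approx(2.0 / (1.0 / 0.465 + 1.0 / 0.01))
        assert got == pytest.approx(0.01958, rel=2e-3)

    def test_zero_sigma_rejected(self):
        sig = np.full((4, 1, 1), 1.0)
        sig[1, 0, 0] = 0.0
        system, _ = bar_system(4)
        with pytest.raises(InvalidParameterError):
            ot.assemble_system(sig, system.bc, 2.0)

    def test_no_ground_rejected(self):
        system, sig3 = bar_system(4)
        bc = BoundaryConditions(
            electrodes=[e for e in system.bc.electrodes if e.role == ot.ANTERIOR_SOURCE],
            jn_a_per_m2=system.bc.jn_a_per_m2,
            total_current_ma=1.0, face_area_m2=system.bc.face_area_m2,
        )
        with pytest.raises(SingularSystemError):
            ot.assemble_system(np.full((4, 1, 1), 1.0), bc, 2.0)

    def test_spd_positive_diagonal(self):
        system, _ = bar_system()
        assert (system.A.diagonal() > 0).all()


class TestSolve:
    def test_ohms_law_on_bar(self):
        """V at the source end equals J*L/sigma for a homogeneous bar."""
        n, sigma, spacing, I = 12, 0.5, 2.0, 1.0
        system, _ = bar_system(n, sigma, spacing, I)
        pot = ot.solve_potential(system)
        h = units.mm_to_m(spacing)
        J = units.ma_to_a(I) / h**2
        expected = J * (n - 1) * h / sigma  # center-to-center distance
        assert pot.values[0, 0, 0] == pytest.approx(expected, rel=1e-7)
        assert pot.values[-1, 0, 0] == pytest.approx(0.0, abs=1e-12)
        # linear profile in between
        profile = pot.values[:, 0, 0]
        assert np.allclose(np.diff(profile), profile[1] - profile[0], rtol=1e-6)

    def test_doubling_sigma_halves_potential(self):
        s1, _ = bar_system(sigma=0.4)
        s2, _ = bar_system(sigma=0.8)
        v1 = ot.solve_potential(s1).values[0, 0, 0]
        v2 = ot.solve_potential(s2).values[0, 0, 0]
        assert v1 == pytest.approx(2.0 * v2, rel=1e-7)

    def test_zero_current_gives_zero_field(self):
        system, _ = bar_system(current_ma=1.0)
        system.b[:] = 0.0
        pot = ot.solve_potential(system)
        assert np.nanmax(np.abs(pot.values)) == 0.0
        assert pot.relative_residual == 0.0

    def test_linearity_alpha_10(self, solved_small_pair, table):
        """Scaling the injected current by 10 scales V pointwise by 10."""
        base = solved_small_pair
        montage10 = ot.Montage(
            id="pair10",
            electrodes=[
                ot.Electrode("circle", "nasion", (0.0, 0.0), ot.ANTERIOR_SOURCE, name="src"),
                ot.Electrode("circle", "inion", (0.0, 0.0), ot.POSTERIOR_GROUND, name="gnd"),
            ],
            total_current_ma=10.0,
        )
        stamped, bc = ot.apply_montage(base["phantom"], montage10, table)
        system = ot.assemble_system(ot.conductivity_volume(stamped, table), bc, 2.0)
        v10 = ot.solve_potential(system).values
        v1 = base["potential"].values
        mask = base["potential"].mask
        denom = np.abs(v1[mask])
        dev = np.abs(v10[mask] - 10.0 * v1[mask])
        scale = np.nanmax(denom)
        assert np.nanmax(dev) / scale < 1e-7

    def test_superposition_of_sources(self, solved_small_pair):
        """b_A + b_B solves to V_A + V_B on the same stamped system."""
        system = solved_small_pair["system"]
        b_full = system.b.copy()
        rng = np.random.default_rng(7)
        split = rng.random(len(b_full)) < 0.5
        bA = np.where(split, b_full, 0.0)
        bB = np.where(~split, b_full, 0.0)
        import copy

        sysA = copy.copy(system)
        sysA.b = bA
        sysB = copy.copy(system)
        sysB.b = bB
        vA = ot.solve_potential(sysA).values
        vB = ot.solve_potential(sysB).values
        v = solved_small_pair["potential"].values
        mask = solved_small_pair["potential"].mask
        err = np.nanmax(np.abs(vA[mask] + vB[mask] - v[mask]))
        assert err < 1e-7 * np.nanmax(np.abs(v[mask]))

    def test_maximum_principle(self, solved_small_pair):
        """Potential extrema occur at the electrodes (max at source, min at ground)."""
        pot = solved_small_pair["potential"]
        bc = solved_small_pair["bc"]
        src = next(e for e in bc.electrodes if e.role == ot.ANTERIOR_SOURCE)
        v_src = pot.values[src.voxels[:, 0], src.voxels[:, 1], src.voxels[:, 2]]
        vmax = np.nanmax(pot.values)
        assert np.nanmax(v_src) >= vmax * (1 - 1e-6)
        assert np.nanmin(pot.values) >= -1e-9 * vmax  # ground pins the minimum at 0

    def test_closed_box_conservation(self, solved_small_pair):
        """Net current through a box not intersecting electrodes is ~0."""
        pot = solved_small_pair["potential"]
        n = pot.values.shape[0]
        c = n // 2
        net = ot.box_net_current(pot, (c - 4, c - 4, c - 4), (c + 4, c + 4, c + 4))
        assert abs(net) < 1e-6 * 1.0  # relative to 1 mA injected


class TestElectrodeCurrents:
    def test_flux_recovery_small_pair(self, solved_small_pair):
        currents = ot.net_electrode_currents(solved_small_pair["potential"])
        assert currents["src"] == pytest.approx(1.0, rel=1e-3)
        assert currents["gnd"] == pytest.approx(-1.0, rel=1e-3)

    def test_unsolved_state_rejected(self):
        pot = PotentialField(values=np.zeros((2, 2, 2)), mask=np.ones((2, 2, 2), bool),
                             spacing=1.0, iterations=0, relative_residual=0.0, system=None)
        with pytest.raises(StateError):
            ot.net_electrode_currents(pot)


class TestElectricField:
    def _linear_potential(self, slope_per_mm=-0.001, n=8):
        x = np.arange(n) * 1.0
        V = np.broadcast_to(slope_per_mm * x[:, None, None], (n, n, n)).copy()
        return PotentialField(values=V, mask=np.ones((n, n, n), bool), spacing=1.0,
                              iterations=1, relative_residual=0.0)

    def test_gradient_of_linear_potential(self):
        """V = -0.001*x volts (x in mm) gives a uniform 1 V/m field along +x."""
        ef = ot.electric_field(self._linear_potential())
        assert np.allclose(ef.vectors[..., 0], 1.0)
        assert np.allclose(ef.vectors[..., 1:], 0.0)
        assert np.allclose(ef.magnitude, 1.0)

    def test_constant_potential_zero_field(self):
        pot = self._linear_potential(slope_per_mm=0.0)
        ef = ot.electric_field(pot)
        assert np.allclose(ef.magnitude, 0.0)

    def test_magnitude_is_norm(self, solved_small_pair):
        ef = solved_small_pair["ef"]
        assert np.allclose(ef.magnitude, np.linalg.norm(ef.vectors, axis=-1))

    def test_unsolved_input_rejected(self):
        with pytest.raises(StateError):
            ot.electric_field(None)


class TestQuasiStatic:
    def test_first_zero_crossings(self):
        assert ot.first_zero_crossing_khz(ot.PulseSpec(0.5)) == pytest.approx(2.0)
        assert ot.first_zero_crossing_khz(ot.PulseSpec(0.25)) == pytest.approx(4.0)
        assert ot.first_zero_crossing_khz(ot.PulseSpec(2.0)) == pytest.approx(0.5)

    def test_analysis_frequency_is_half(self):
        assert ot.analysis_frequency_khz(ot.PulseSpec(0.5)) == pytest.approx(1.0)

    def test_spectrum_zero_and_dc(self):
        pulse = ot.PulseSpec(0.5, amplitude_ma=2.0)
        f = np.array([0.0, 1000.0, 2000.0, 4000.0])
        mag = ot.pulse_spectrum(pulse, f)
        assert mag[0] == pytest.approx(2.0 * 0.5e-3)  # pulse area
        assert mag[2] == pytest.approx(0.0, abs=1e-15)  # first zero at 2 kHz
        assert mag[3] == pytest.approx(0.0, abs=1e-15)

    def test_invalid_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            ot.PulseSpec(0.0)

    def test_reactive_ratio_values(self):
        eps = units.EPSILON_0 * 1e5
        got = ot.reactive_ratio(0.276, eps, 1000.0)
        assert got == pytest.approx(2 * np.pi * 1000 * eps / 0.276)
        assert got == pytest.approx(0.0202, rel=0.01)
        assert ot.reactive_ratio(0.276, eps, 0.0) == 0.0
        # linear in frequency
        assert ot.reactive_ratio(0.276, eps, 2000.0) == pytest.approx(2 * got)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            ot.reactive_ratio(0.0, 1e-10, 100.0)
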