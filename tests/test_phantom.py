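"""Phantom construction, conductivity table, OE partitioning, NIfTI round trip."""

import numpy as np
import pytest
import yaml
from scipy import ndimage

import olftes as ot
from olftes.errors import (
    EmptyRoiError,
    InvalidGeometryError,
    InvalidParameterError,
    ResolutionError,
    UnknownTissueError,
)


class TestLayeredSphere:
    def test_shell_volumes_match_analytic(self, sphere_phantom):
        """Voxel counts per shell track the analytic shell volumes within 3%."""
        sp = sphere_phantom.spacing
        shells = {
            "Scalp": (80.0, 75.0),
            "Skull": (75.0, 71.0),
            "CSF": (71.0, 69.0),
            "Gray matter": (69.0, 0.0),
        }
        for tissue, (r1, r2) in shells.items():
            lab = ot.TISSUE_LABELS[tissue]
            v_voxel = float((sphere_phantom.labels == lab).sum()) * sp**3
            v_true = 4.0 / 3.0 * np.pi * (r1**3 - r2**3)
            assert abs(v_voxel - v_true) / v_true < 0.03

    def test_homogeneous_ball_single_label(self):
        ph = ot.build_layered_sphere([40.0], ["Gray matter"], 2.0)
        inside = ph.labels[ph.tissue_mask()]
        assert (inside == ot.TISSUE_LABELS["Gray matter"]).all()

    def test_nondecreasing_radii_rejected(self):
        with pytest.raises(InvalidGeometryError):
            ot.build_layered_sphere([80.0, 85.0], ["Scalp", "Skull"], 2.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(InvalidParameterError):
            ot.build_layered_sphere([80.0], ["Scalp"], 0.0)

    def test_fiducials_on_surface(self, sphere_phantom):
        for point in sphere_phantom.fiducials.values():
            assert abs(np.linalg.norm(point) - 80.0) < 1e-9

    @pytest.mark.parametrize("spacing", [4.0, 2.0])
    def test_shell_volume_error_shrinks_with_spacing(self, spacing):
        """Voxelized volume error roughly halves when the spacing halves."""
        ph = ot.build_layered_sphere([40.0, 35.0], ["Scalp", "Gray matter"], spacing)
        v_true = 4.0 / 3.0 * np.pi * (40.0**3 - 35.0**3)
        v_voxel = float((ph.labels == ot.TISSUE_LABELS["Scalp"]).sum()) * spacing**3
        err = abs(v_voxel - v_true) / v_true
        assert err < 0.02 * spacing  # ~linear in spacing with a small constant


class TestConductivityTable:
    def test_reference_values(self, table):
        assert table["Skull"] == 0.01
        assert table["Olfactory epithelium and olfactory mucosa"] == 0.0004
        assert table["Gray matter"] == 0.276
        assert table["Electrode (material)"] == 5.8e7
        assert table["Air"] == 1e-7

    def test_has_seventeen_entries(self, table):
        assert len(table) == 17

    def test_unknown_tissue_raises(self, table):
        with pytest.raises(UnknownTissueError):
            table["unobtainium"]

    def test_yaml_round_trip_bit_exact(self, table, tmp_path):
        path = tmp_path / "table.yaml"
        table.to_yaml(path)
        assert ot.ConductivityTable.from_yaml(path) == table

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            ot.ConductivityTable({"Scalp": 0.0})


class TestConductivityVolume:
    def test_uniform_ball(self, table):
        ph = ot.build_layered_sphere([30.0], ["Gray matter"], 2.0)
        sigma = ot.conductivity_volume(ph, table)
        assert np.allclose(sigma[ph.tissue_mask()], 0.276)
        assert np.isnan(sigma[~ph.tissue_mask()]).all()

    def test_two_shells_two_values(self, table):
        ph = ot.build_layered_sphere([30.0, 25.0], ["Scalp", "Skull"], 2.0)
        sigma = ot.conductivity_volume(ph, table)
        vals = np.unique(sigma[~np.isnan(sigma)])
        assert len(vals) == 2

    def test_missing_label_reported(self, table):
        ph = ot.build_layered_sphere([30.0], ["Gray matter"], 2.0)
        ph.registry[99] = "mystery tissue"
        ph.labels[ph.shape[0] // 2, ph.shape[1] // 2, ph.shape[2] // 2] = 99
        with pytest.raises(UnknownTissueError, match="99"):
            ot.conductivity_volume(ph, table)

    def test_background_as_air(self, table):
        ph = ot.build_layered_sphere([30.0], ["Gray matter"], 2.0)
        sigma = ot.conductivity_volume(ph, table, background="air")
        assert np.allclose(sigma[~ph.tissue_mask()], 1e-7)


class TestOlfactoryHead:
    def test_required_tissues_present(self, head_and_rois):
        phantom, _ = head_and_rois
        for tissue in ("Scalp", "Skull", "CSF", "Gray matter", "White matter",
                       "Air", "Mucosa", "Olfactory bulb", "Eye",
                       "Olfactory epithelium and olfactory mucosa"):
            assert (phantom.labels == ot.TISSUE_LABELS[tissue]).any(), tissue

    def test_oe_adjacent_to_cavity_and_plate(self, head_and_rois):
        phantom, rois = head_and_rois
        grown = ndimage.binary_dilation(
            rois["OE"], ndimage.generate_binary_structure(3, 3)
        )
        assert (grown & (phantom.labels == ot.TISSUE_LABELS["Air"])).any()
        assert (grown & (phantom.labels == ot.TISSUE_LABELS["Skull"])).any()

    def test_ob_two_components(self, head_and_rois):
        _, rois = head_and_rois
        assert ndimage.label(rois["OB"])[1] == 2

    def test_deep_rois_inside_tissue(self, head_and_rois):
        phantom, rois = head_and_rois
        for name in ("hippocampus", "basal_ganglia"):
            assert rois[name].any()
            assert not (rois[name] & ~phantom.tissue_mask()).any()

    def test_cavity_is_internal(self, head_and_rois):
        """The air channel never touches exterior background."""
        phantom, _ = head_and_rois
        air = phantom.labels == ot.TISSUE_LABELS["Air"]
        grown = ndimage.binary_dilation(air, ndimage.generate_binary_structure(3, 1))
        assert not (grown & (phantom.labels == ot.BACKGROUND)).any()

    def test_coarse_spacing_rejected(self):
        with pytest.raises(ResolutionError):
            ot.build_olfactory_head(5.0)

    def test_nifti_round_trip(self, head_and_rois, tmp_path):
        phantom, rois = head_and_rois
        phantom.to_nifti(tmp_path / "head.nii")
        back = ot.VoxelPhantom.from_nifti(tmp_path / "head.nii")
        assert np.array_equal(back.labels, phantom.labels)
        assert back.spacing == phantom.spacing
        for k, v in phantom.fiducials.items():
            assert np.allclose(back.fiducials[k], v)
        rois.to_nifti(tmp_path / "rois", phantom)
        rois_back = ot.RoiSet.from_nifti(tmp_path / "rois")
        assert np.array_equal(rois_back["OE"], rois["OE"])


class TestPartitionThirds:
    def _slab(self, length, axis=1):
        shape = [4, 4, 4]
        shape[axis] = length + 4
        mask = np.zeros(shape, bool)
        sl = [slice(1, 3)] * 3
        sl[axis] = slice(2, 2 + length)
        mask[tuple(sl)] = True
        return mask

    @pytest.mark.parametrize("length,expected", [(30, (10, 10, 10)), (31, (10, 10, 11))])
    def test_slab_layer_counts(self, length, expected):
        """Anterior and middle take floor(L/3); the posterior absorbs the rest."""
        mask = self._slab(length)
        thirds = ot.partition_oe_thirds(mask, anterior_axis=1)
        per_voxel = mask[1, 2, 1]  # slab cross-section is 2x2
        counts = tuple(int(t.sum()) // 4 for t in thirds)
        assert counts == expected

    def test_partition_property(self, head_and_rois):
        _, rois = head_and_rois
        a, m, p = ot.partition_oe_thirds(rois["OE"])
        assert not (a & m).any() and not (a & p).any() and not (m & p).any()
        assert np.array_equal(a | m | p, rois["OE"])

    def test_anterior_is_high_y(self, head_and_rois):
        """With +y anterior, the anterior third has the largest y coordinates."""
        _, rois = head_and_rois
        a, _, p = ot.partition_oe_thirds(rois["OE"], anterior_axis=1, anterior_positive=True)
        assert np.argwhere(a)[:, 1].min() > np.argwhere(p)[:, 1].max()

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyRoiError):
            ot.partition_oe_thirds(np.zeros((4, 4, 4), bool))
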