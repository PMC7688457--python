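"""Shared fixtures: small phantoms and one solved montage, reused across tests."""

import numpy as np
import pytest

import olftes as ot


@pytest.fixture(scope="session")
def sphere_phantom():
    """4-layer validation sphere at 2 mm."""
    return ot.build_layered_sphere(
        [80.0, 75.0, 71.0, 69.0], ["Scalp", "Skull", "CSF", "Gray matter"], 2.0
    )


@pytest.fixture(scope="session")
def small_sphere():
    """3-layer miniature sphere for fast solver tests."""
    return ot.build_layered_sphere([30.0, 27.0, 24.0], ["Scalp", "Skull", "Gray matter"], 2.0)


@pytest.fixture(scope="session")
def head_and_rois():
    """Olfactory head at 2 mm with its ROI set."""
    return ot.build_olfactory_head(2.0)


@pytest.fixture(scope="session")
def table():
    return ot.default_conductivity_table()


@pytest.fixture(scope="session")
def solved_montage1(head_and_rois, table):
    """Montage 1 applied and solved on the 2 mm olfactory head."""
    phantom, rois = head_and_rois
    stamped, bc = ot.apply_montage(phantom, ot.standard_montage(1), table)
    sigma = ot.conductivity_volume(stamped, table)
    system = ot.assemble_system(sigma, bc, stamped.spacing)
    potential = ot.solve_potential(system)
    ef = ot.electric_field(potential)
    return {"phantom": phantom, "rois": rois, "stamped": stamped, "bc": bc,
            "sigma": sigma, "system": system, "potential": potential, "ef": ef}


@pytest.fixture(scope="session")
def solved_small_pair(small_sphere, table):
    """Two-electrode solve on the miniature sphere (fast, reused)."""
    ph = small_sphere
    montage = ot.Montage(
        id="pair",
        electrodes=[
            ot.Electrode("circle", "nasion", (0.0, 0.0), ot.ANTERIOR_SOURCE, name="src"),
            ot.Electrode("circle", "inion", (0.0, 0.0), ot.POSTERIOR_GROUND, name="gnd"),
        ],
        total_current_ma=1.0,
    )
    stamped, bc = ot.apply_montage(ph, montage, table)
    sigma = ot.conductivity_volume(stamped, table)
    system = ot.assemble_system(sigma, bc, stamped.spacing)
    potential = ot.solve_potential(system)
    ef = ot.electric_field(potential)
    return {"phantom": ph, "stamped": stamped, "bc": bc, "sigma": sigma,
            "system": system, "potential": potential, "ef": ef}


def uniform_ef(shape, vector, mask=None):
    """EFField with a spatially uniform vector field (test helper)."""
    vectors = np.zeros(shape + (3,))
    vectors[...] = np.asarray(vector, float)
    if mask is None:
        mask = np.ones(shape, bool)
    vectors[~mask] = 0.0
    return ot.EFField(vectors=vectors, magnitude=np.linalg.norm(vectors, axis=-1),
                      mask=mask, spacing=1.0)
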