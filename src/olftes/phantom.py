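"""Synthetic head phantoms and tissue conductivity assignment.

The licensed anatomical model used in the original montage screen is replaced
here by parameterized voxel phantoms: concentric layered spheres (used for
solver validation against the analytic series solution) and a stylized
"olfactory head" carrying the structures that matter for olfactory-targeted
stimulation — a layered scalp/skull/CSF/gray/white head, an internal nasal
air cavity lined with mucosa, a thin high-resistivity olfactory-epithelium
(OE) sheet at the cavity roof, two olfactory-bulb (OB) bodies above a thin
bone plate (cribriform stand-in), eye spheres, a neck, and deep ellipsoidal
regions of interest standing in for hippocampus and basal ganglia.

Conductivities are the DC/low-frequency isotropic literature values used for
quasi-static stimulation modeling (S/m); the default table is exposed by
:func:`default_conductivity_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    EmptyRoiError,
    InvalidGeometryError,
    InvalidParameterError,
    ResolutionError,
    UnknownTissueError,
)

#: reserved background label (exterior air, outside the computational domain)
BACKGROUND = 0

#: canonical tissue / material names with their integer labels
TISSUE_LABELS = {
    "Background": BACKGROUND,
    "Scalp": 1,
    "Muscle": 2,
    "Skull": 3,
    "CSF": 4,
    "Gray matter": 5,
    "White matter": 6,
    "Fat": 7,
    "Blood": 8,
    "Eye": 9,
    "Air": 10,
    "Conductive gel": 11,
    "Electrode (material)": 12,
    "Cartilage": 13,
    "Intestines": 14,
    "Mucosa": 15,
    "Olfactory bulb": 16,
    "Olfactory epithelium and olfactory mucosa": 17,
}

_NAME_BY_LABEL = {v: k for k, v in TISSUE_LABELS.items()}

#: DC electrical conductivities in S/m for each tissue compartment and
#: electrode material (17 entries).
DEFAULT_CONDUCTIVITIES = {
    "Scalp": 0.465,
    "Muscle": 0.35,
    "Skull": 0.01,
    "CSF": 1.65,
    "Gray matter": 0.276,
    "White matter": 0.126,
    "Fat": 0.04,
    "Blood": 0.7,
    "Eye": 1.65,
    "Air": 1e-7,
    "Conductive gel": 0.3,
    "Electrode (material)": 5.8e7,
    "Cartilage": 1.01,
    "Intestines": 0.164,
    "Mucosa": 0.0004,
    "Olfactory bulb": 0.126,
    "Olfactory epithelium and olfactory mucosa": 0.0004,
}


class ConductivityTable:
    """Mapping tissue name -> conductivity sigma in S/m.

    All values must be strictly positive.  Unknown lookups raise
    :class:`UnknownTissueError`.
    """

    def __init__(self, values: dict[str, float]):
        for name, sigma in values.items():
            if not sigma > 0:
                raise InvalidParameterError(
                    f"conductivity for {name!r} must be > 0, got {sigma}"
                )
        self._values = dict(values)

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise UnknownTissueError(f"unknown tissue {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ConductivityTable) and self._values == other._values

    def items(self):
        return self._values.items()

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"conductivities_S_per_m": self.as_dict()}, sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "ConductivityTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(data["conductivities_S_per_m"])


def default_conductivity_table() -> ConductivityTable:
    """Return the default DC conductivity table (17 entries, S/m)."""
    return ConductivityTable(DEFAULT_CONDUCTIVITIES)


@dataclass
class VoxelPhantom:
    """A labeled voxel volume with physical geometry.

    Attributes
    ----------
    labels : int16 array, shape (nx, ny, nz)
        Tissue label per voxel; ``BACKGROUND`` marks exterior air outside the
        computational domain.
    spacing : float
        Isotropic voxel edge length in mm.
    origin : (3,) array
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    fiducials : dict
        Named anatomical landmarks in physical mm: nasion, inion,
        left/right preauricular, vertex.
    registry : dict
        label integer -> tissue name for every label present.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray
    fiducials: dict[str, np.ndarray]
    registry: dict[int, str] = field(default_factory=lambda: dict(_NAME_BY_LABEL))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        self.fiducials = {k: np.asarray(v, dtype=float) for k, v in self.fiducials.items()}
        if self.spacing <= 0:
            raise InvalidParameterError(f"spacing must be > 0, got {self.spacing}")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.registry)
        if missing:
            raise InvalidGeometryError(
                f"labels {sorted(missing)} missing from the tissue registry"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def tissue_mask(self) -> np.ndarray:
        """Boolean mask of non-background voxels."""
        return self.labels != BACKGROUND

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (possibly fractional) to physical mm."""
        return self.origin + self.spacing * np.asarray(ijk, dtype=float)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map physical mm to fractional voxel indices."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def coordinate_grids(self):
        """Physical coordinates of voxel centers along each axis (1-D arrays)."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a]) for a in range(3)
        )

    def surface_mask(self) -> np.ndarray:
        """Tissue voxels with at least one face-neighbor outside the tissue."""
        t = self.tissue_mask()
        interior = np.ones_like(t)
        for axis in range(3):
            fwd = np.roll(t, 1, axis=axis)
            bwd = np.roll(t, -1, axis=axis)
            # grid edges count as exterior
            sl = [slice(None)] * 3
            sl[axis] = 0
            fwd[tuple(sl)] = False
            sl[axis] = -1
            bwd[tuple(sl)] = False
            interior &= fwd & bwd
        return t & ~interior

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            labels=self.labels.copy(),
            spacing=self.spacing,
            origin=self.origin.copy(),
            fiducials={k: v.copy() for k, v in self.fiducials.items()},
            registry=dict(self.registry),
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path, registry_path=None) -> None:
        """Write the label volume as NIfTI plus a YAML tissue registry sidecar."""
        import nibabel as nib

        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        nib.save(img, str(path))
        if registry_path is None:
            registry_path = str(path).replace(".nii.gz", "").replace(".nii", "") + ".yaml"
        meta = {
            "registry": {int(k): v for k, v in self.registry.items()},
            "fiducials_mm": {k: [float(x) for x in v] for k, v in self.fiducials.items()},
        }
        Path(registry_path).write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def from_nifti(cls, path, registry_path=None) -> "VoxelPhantom":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        sp = affine[np.arange(3), np.arange(3)]
        if not np.allclose(sp, sp[0]) or not np.allclose(
            affine[:3, :3], np.diag(sp)
        ):
            raise InvalidGeometryError("phantom NIfTI must have an isotropic diagonal affine")
        if registry_path is None:
            registry_path = str(path).replace(".nii.gz", "").replace(".nii", "") + ".yaml"
        meta = yaml.safe_load(Path(registry_path).read_text())
        return cls(
            labels=np.asanyarray(img.dataobj).astype(np.int16),
            spacing=float(sp[0]),
            origin=affine[:3, 3].copy(),
            fiducials={k: np.array(v, float) for k, v in meta["fiducials_mm"].items()},
            registry={int(k): v for k, v in meta["registry"].items()},
        )


class RoiSet:
    """Named boolean voxel masks over a phantom grid."""

    def __init__(self, masks: dict[str, np.ndarray]):
        self._masks = {k: np.asarray(v, bool) for k, v in masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._masks[name]
        except KeyError:
            raise EmptyRoiError(f"no ROI named {name!r}") from None

    def __contains__(self, name):
        return name in self._masks

    def names(self):
        return list(self._masks)

    def items(self):
        return self._masks.items()

    def to_nifti(self, directory, phantom: VoxelPhantom) -> None:
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag([phantom.spacing] * 3 + [1.0])
        affine[:3, 3] = phantom.origin
        for name, mask in self._masks.items():
            img = nib.Nifti1Image(mask.astype(np.uint8), affine)
            nib.save(img, str(directory / f"roi_{name}.nii"))

    @classmethod
    def from_nifti(cls, directory) -> "RoiSet":
        import nibabel as nib

        masks = {}
        for p in sorted(Path(directory).glob("roi_*.nii*")):
            name = p.name[len("roi_"):].split(".nii")[0]
            masks[name] = np.asanyarray(nib.load(str(p)).dataobj).astype(bool)
        return cls(masks)


# ---------------------------------------------------------------------------
# Layered sphere phantom (validation geometry)
# ---------------------------------------------------------------------------

def build_layered_sphere(radii, tissues, spacing, margin_voxels=2) -> VoxelPhantom:
    """Build a concentric-shell sphere phantom.

    Parameters
    ----------
    radii : sequence of float
        Strictly decreasing shell outer radii in mm (outermost first).
    tissues : sequence of str
        Tissue names outer -> inner, same length as ``radii``.
    spacing : float
        Isotropic voxel size in mm.

    The grid is sized symmetrically so the sphere center falls on a voxel
    center; fiducials are placed at the surface poles (nasion +y, inion -y,
    preauriculars +/-x, vertex +z).
    """
    radii = [float(r) for r in radii]
    if spacing is None or spacing <= 0:
        raise InvalidParameterError(f"spacing must be > 0, got {spacing}")
    if len(radii) != len(tissues):
        raise InvalidGeometryError("radii and tissues must have equal length")
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])) or radii[0] <= 0:
        raise InvalidGeometryError(f"radii must be strictly decreasing and positive: {radii}")
    unknown = [t for t in tissues if t not in TISSUE_LABELS]
    if unknown:
        raise UnknownTissueError(f"unknown tissue names {unknown}")

    R = radii[0]
    half = int(np.ceil(R / spacing)) + margin_voxels
    n = 2 * half + 1
    origin = np.array([-half * spacing] * 3)
    ax = np.arange(n) * spacing - half * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = X * X + Y * Y + Z * Z

    labels = np.zeros((n, n, n), dtype=np.int16)
    for radius, tissue in zip(radii, tissues):  # outer -> inner overwrites
        labels[r2 <= radius * radius] = TISSUE_LABELS[tissue]

    fiducials = {
        "nasion": np.array([0.0, R, 0.0]),
        "inion": np.array([0.0, -R, 0.0]),
        "left_preauricular": np.array([-R, 0.0, 0.0]),
        "right_preauricular": np.array([R, 0.0, 0.0]),
        "vertex": np.array([0.0, 0.0, R]),
    }
    return VoxelPhantom(labels=labels, spacing=spacing, origin=origin, fiducials=fiducials)


# ---------------------------------------------------------------------------
# Olfactory head phantom
# ---------------------------------------------------------------------------

@dataclass
class OlfactoryHeadParams:
    """Geometry parameters of the stylized olfactory head (all mm).

    The head is a nested set of ellipsoids (scalp outermost) whose layer
    thicknesses approximate adult scalp/skull/CSF/cortex; the coordinate
    frame is x lateral (+x subject-right), y anterior, z superior, with the
    head center at the physical origin.
    """

    # outer scalp ellipsoid semi-axes (x, y, z)
    scalp_semiaxes: tuple = (70.0, 85.0, 78.0)
    scalp_thickness: float = 6.0
    skull_thickness: float = 7.0
    csf_thickness: float = 4.0
    gray_thickness: float = 8.0

    # neck cylinder (skin-covered muscle), axis parallel to z
    neck_center_xy: tuple = (0.0, -15.0)
    neck_radius: float = 42.0
    neck_top_z: float = -50.0
    neck_bottom_z: float = -118.0
    neck_skin_thickness: float = 5.0

    # eyes
    eye_centers: tuple = ((-24.0, 60.0, 5.0), (24.0, 60.0, 5.0))
    eye_radius: float = 8.0

    # nasal block: a mucosa-filled region (turbinate stand-in) carrying a
    # narrow internal air channel.  Keeping the walls tissue rather than air
    # preserves the resistive conduction pathway nose -> mucosa -> OE ->
    # cribriform plate -> OB that anterior montages exploit; a pure air box
    # would insulate the OE and move the voltage drop into the air gap.
    # the block reaches almost to the anterior surface: only skin and a thin
    # bone sliver separate it from the nose-bridge electrodes, mirroring the
    # short skin/nasal-bone path of the real nose
    nasal_halfwidth_x: float = 13.5
    nasal_y: tuple = (40.0, 78.5)
    nasal_z: tuple = (-26.5, 6.5)
    air_halfwidth_x: float = 3.0
    air_y: tuple = (44.0, 75.0)
    air_z: tuple = (-22.0, 4.0)

    # olfactory epithelium sheet at the cavity roof.  The sheet extent along
    # the cavity roof is a free parameter (the anatomical boundary of the OE
    # is not sharply defined); thickness is exaggerated relative to real
    # epithelium so the sheet stays resolvable at ~1 mm grids.
    oe_halfwidth_x: float = 10.0
    oe_y: tuple = (42.0, 74.0)
    oe_thickness: float = 2.0

    # thin bone plate (cribriform stand-in) above the OE
    plate_halfwidth_x: float = 12.0
    plate_y: tuple = (40.0, 76.0)
    plate_thickness: float = 2.0

    # olfactory bulbs: two ellipsoids sitting on the plate
    ob_center_offset_x: float = 6.0
    ob_center_y: float = 56.0
    ob_semiaxes: tuple = (4.0, 9.0, 3.5)

    # deep ROI ellipsoids at plausible fractional head positions
    hippocampus_centers: tuple = ((-30.0, -12.0, -2.0), (30.0, -12.0, -2.0))
    hippocampus_semiaxes: tuple = (7.0, 16.0, 7.0)
    basal_ganglia_centers: tuple = ((-17.0, 6.0, 8.0), (17.0, 6.0, 8.0))
    basal_ganglia_semiaxes: tuple = (9.0, 13.0, 10.0)

    def as_dict(self) -> dict:
        return asdict(self)


def _ellipsoid_mask(X, Y, Z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (
        ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
    ) <= 1.0


def build_olfactory_head(spacing=1.0, params: OlfactoryHeadParams | None = None):
    """Build the synthetic olfactory head.

    Returns ``(phantom, rois)`` where the ROI set exposes masks ``OB``,
    ``OE``, ``hippocampus`` and ``basal_ganglia`` (plus left/right variants
    for the deep ROIs).

    Raises
    ------
    ResolutionError
        If the voxel spacing cannot realize the OE sheet with at least one
        voxel layer.
    """
    if spacing is None or spacing <= 0:
        raise InvalidParameterError(f"spacing must be > 0, got {spacing}")
    p = params or OlfactoryHeadParams()

    n_oe = int(round(p.oe_thickness / spacing))
    if n_oe < 1:
        raise ResolutionError(
            f"spacing {spacing} mm cannot resolve the {p.oe_thickness} mm OE sheet "
            "(sheet would be 0 voxels thick)"
        )

    ax0, ay0, az0 = p.scalp_semiaxes
    pad = 2 * spacing
    xmin, xmax = -ax0 - pad, ax0 + pad
    ymin, ymax = -ay0 - pad, ay0 + pad
    zmin, zmax = p.neck_bottom_z - pad, az0 + pad

    nx = int(np.ceil((xmax - xmin) / spacing)) + 1
    ny = int(np.ceil((ymax - ymin) / spacing)) + 1
    nz = int(np.ceil((zmax - zmin) / spacing)) + 1
    # centre the grid so that x=0 falls on a voxel center (mirror symmetry)
    if nx % 2 == 0:
        nx += 1
    origin = np.array([-(nx - 1) / 2 * spacing, ymin, zmin])
    gx = origin[0] + spacing * np.arange(nx)
    gy = origin[1] + spacing * np.arange(ny)
    gz = origin[2] + spacing * np.arange(nz)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")

    L = TISSUE_LABELS
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    # neck first (head overwrites in the overlap)
    ncx, ncy = p.neck_center_xy
    neck_r2 = (X - ncx) ** 2 + (Y - ncy) ** 2
    in_neck_z = (Z >= p.neck_bottom_z) & (Z <= p.neck_top_z)
    labels[(neck_r2 <= p.neck_radius**2) & in_neck_z] = L["Scalp"]
    inner_r = p.neck_radius - p.neck_skin_thickness
    labels[(neck_r2 <= inner_r**2) & in_neck_z] = L["Muscle"]

    # nested head ellipsoids, outer -> inner
    t_cum = np.cumsum(
        [0.0, p.scalp_thickness, p.skull_thickness, p.csf_thickness, p.gray_thickness]
    )
    layer_tissues = ["Scalp", "Skull", "CSF", "Gray matter", "White matter"]
    for t, tissue in zip(t_cum, layer_tissues):
        semi = (ax0 - t, ay0 - t, az0 - t)
        labels[_ellipsoid_mask(X, Y, Z, (0, 0, 0), semi)] = L[tissue]

    # eyes
    for c in p.eye_centers:
        labels[_ellipsoid_mask(X, Y, Z, c, (p.eye_radius,) * 3)] = L["Eye"]

    # mucosa-filled nasal block, then the internal air channel through it
    mucosa = (
        (np.abs(X) <= p.nasal_halfwidth_x)
        & (Y >= p.nasal_y[0])
        & (Y <= p.nasal_y[1])
        & (Z >= p.nasal_z[0])
        & (Z <= p.nasal_z[1])
    )
    labels[mucosa] = L["Mucosa"]
    cavity = (
        (np.abs(X) <= p.air_halfwidth_x)
        & (Y >= p.air_y[0])
        & (Y <= p.air_y[1])
        & (Z >= p.air_z[0])
        & (Z <= p.air_z[1])
    )
    labels[cavity] = L["Air"]

    # OE sheet at the channel roof: exactly n_oe voxel layers starting at the
    # first voxel layer whose center lies above the air-channel roof, wider
    # than the channel so it rests on mucosa laterally and air centrally
    k_roof = int(np.searchsorted(gz, p.air_z[1], side="right"))
    k_oe = slice(k_roof, min(k_roof + n_oe, nz))
    oe_xy = (
        (np.abs(X[:, :, 0]) <= p.oe_halfwidth_x)
        & (Y[:, :, 0] >= p.oe_y[0])
        & (Y[:, :, 0] <= p.oe_y[1])
    )
    oe_mask = np.zeros_like(labels, dtype=bool)
    oe_mask[:, :, k_oe] = oe_xy[:, :, None]
    labels[oe_mask] = L["Olfactory epithelium and olfactory mucosa"]

    # bone plate directly above the OE sheet
    k_plate0 = k_roof + n_oe
    n_plate = max(1, int(round(p.plate_thickness / spacing)))
    k_plate = slice(k_plate0, min(k_plate0 + n_plate, nz))
    plate_xy = (
        (np.abs(X[:, :, 0]) <= p.plate_halfwidth_x)
        & (Y[:, :, 0] >= p.plate_y[0])
        & (Y[:, :, 0] <= p.plate_y[1])
    )
    plate_mask = np.zeros_like(labels, dtype=bool)
    plate_mask[:, :, k_plate] = plate_xy[:, :, None]
    labels[plate_mask] = L["Skull"]

    # olfactory bulbs sitting on the plate
    ob_z = gz[min(k_plate0 + n_plate, nz - 1)] + p.ob_semiaxes[2] * 0.7
    ob_mask = np.zeros_like(labels, dtype=bool)
    for sx in (-1.0, 1.0):
        c = (sx * p.ob_center_offset_x, p.ob_center_y, ob_z)
        ob_mask |= _ellipsoid_mask(X, Y, Z, c, p.ob_semiaxes)
    labels[ob_mask] = L["Olfactory bulb"]
    oe_mask &= labels == L["Olfactory epithelium and olfactory mucosa"]

    # deep ROIs: masks only; tissue labels remain gray/white matter
    rois = {}
    for prefix, centers, semi in (
        ("hippocampus", p.hippocampus_centers, p.hippocampus_semiaxes),
        ("basal_ganglia", p.basal_ganglia_centers, p.basal_ganglia_semiaxes),
    ):
        union = np.zeros_like(labels, dtype=bool)
        for c, side in zip(centers, ("left", "right")):
            mask = _ellipsoid_mask(X, Y, Z, c, semi)
            mask &= labels > BACKGROUND
            rois[f"{prefix}_{side}"] = mask
            union |= mask
        rois[prefix] = union

    rois["OE"] = oe_mask
    rois["OB"] = ob_mask

    fiducials = {
        "nasion": np.array([0.0, ay0, 0.0]),
        "inion": np.array([0.0, -ay0, 0.0]),
        "left_preauricular": np.array([-ax0, 0.0, 0.0]),
        "right_preauricular": np.array([ax0, 0.0, 0.0]),
        "vertex": np.array([0.0, 0.0, az0]),
    }
    phantom = VoxelPhantom(labels=labels, spacing=spacing, origin=origin, fiducials=fiducials)
    return phantom, RoiSet(rois)


# ---------------------------------------------------------------------------
# Conductivity assignment and OE partitioning
# ---------------------------------------------------------------------------

def conductivity_volume(
    phantom: VoxelPhantom,
    table: ConductivityTable,
    background: str = "exclude",
) -> np.ndarray:
    """Map the phantom's labels to a conductivity volume in S/m.

    Background voxels are set to NaN (outside the computational domain) by
    default, or to the table's "Air" value with ``background="air"`` when the
    simulation domain should include exterior air.  Raises
    :class:`UnknownTissueError` naming any label without a table entry.
    """
    if background not in ("exclude", "air"):
        raise InvalidParameterError(f"background must be 'exclude' or 'air', got {background!r}")
    present = np.unique(phantom.labels)
    lut = np.full(int(present.max()) + 1, np.nan)
    missing = []
    for lab in present.tolist():
        if lab == BACKGROUND:
            lut[lab] = table["Air"] if background == "air" else np.nan
            continue
        name = phantom.registry.get(lab)
        if name is None or name not in table:
            missing.append(lab)
        else:
            lut[lab] = table[name]
    if missing:
        raise UnknownTissueError(
            f"labels {missing} have no conductivity entry"
        )
    return lut[phantom.labels]


def partition_oe_thirds(oe_mask: np.ndarray, anterior_axis: int = 1,
                        anterior_positive: bool = True):
    """Split an OE mask into (anterior, middle, posterior) thirds.

    The bounding extent of the mask along ``anterior_axis`` is divided into
    three intervals measured from the anterior end: the anterior segment
    takes ``floor(L/3)`` voxel layers, the middle ``floor(2L/3) - floor(L/3)``,
    and the posterior segment the remainder.  ``anterior_positive`` states
    whether the anterior direction is toward increasing indices.

    Returns three masks that partition the input (pairwise disjoint, union
    equal to the input).
    """
    oe_mask = np.asarray(oe_mask, bool)
    if not oe_mask.any():
        raise EmptyRoiError("OE mask is empty")
    proj = np.any(oe_mask, axis=tuple(a for a in range(3) if a != anterior_axis))
    idx = np.nonzero(proj)[0]
    lo, hi = int(idx[0]), int(idx[-1])
    length = hi - lo + 1
    n1 = length // 3
    n2 = (2 * length) // 3 - n1

    # layer offsets measured from the anterior end
    if anterior_positive:
        edges = [hi + 1, hi + 1 - n1, hi + 1 - n1 - n2, lo]
        slices = [slice(edges[1], edges[0]), slice(edges[2], edges[1]), slice(edges[3], edges[2])]
    else:
        edges = [lo, lo + n1, lo + n1 + n2, hi + 1]
        slices = [slice(edges[0], edges[1]), slice(edges[1], edges[2]), slice(edges[2], edges[3])]

    out = []
    for sl in slices:
        m = np.zeros_like(oe_mask)
        indexer = [slice(None)] * 3
        indexer[anterior_axis] = sl
        m[tuple(indexer)] = oe_mask[tuple(indexer)]
        out.append(m)
    return tuple(out)
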