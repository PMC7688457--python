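"""Electrode montages: landmark-anchored placement, stamping, boundary conditions.

Six candidate montages for olfactory-targeted stimulation are provided by
:func:`standard_montage`.  Electrodes are circular (6 mm diameter) or oval
(25 x 20 mm) conductor disks, each interfaced to the scalp through a 1 mm
conductive-gel layer; anterior electrodes act as current sources (uniform
inward normal current density Jn over their exposed surfaces) and posterior
electrodes as grounds (V = 0 on their exposed surfaces).

Anchors are named landmarks (cranial fiducials or supported 10-10 positions)
plus a tangential offset in cm: first component lateral (+ = subject right),
second component "up" along the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from . import units
from .errors import (
    GeometryConflictError,
    InvalidParameterError,
    PlacementError,
    UnknownLandmarkError,
    UnknownMontageError,
)
from .phantom import BACKGROUND, TISSUE_LABELS, VoxelPhantom

ANTERIOR_SOURCE = "anterior-source"
POSTERIOR_GROUND = "posterior-ground"

#: fractional arc positions of supported 10-10 labels.  Midline labels are
#: fractions of the nasion->vertex->inion arc; lateral labels (P9/P10) are
#: fractions of the nasion->preauricular->inion circumferential arc on their
#: side, placed just behind/below the ear.
MIDLINE_FRACTIONS = {"Fpz": 0.1, "Fz": 0.3, "Cz": 0.5, "Pz": 0.7, "POz": 0.8,
                     "Oz": 0.9, "Iz": 1.0}
LATERAL_FRACTIONS = {"P9": ("left", 0.75), "P10": ("right", 0.75)}

FIDUCIAL_ALIASES = {
    "nasion": "nasion",
    "inion": "inion",
    "vertex": "vertex",
    "left_preauricular": "left_preauricular",
    "right_preauricular": "right_preauricular",
    "lpa": "left_preauricular",
    "rpa": "right_preauricular",
}


@dataclass
class Electrode:
    """A single stimulation electrode (conductor disk + gel layer)."""

    shape: str  # "circle" | "oval"
    anchor: str  # landmark name
    offset_cm: tuple = (0.0, 0.0)  # (lateral, up) tangential offset in cm
    role: str = ANTERIOR_SOURCE
    diameter: float = 6.0  # mm, circles
    long_axis: float = 25.0  # mm, ovals (horizontal)
    short_axis: float = 20.0  # mm, ovals
    thickness: float = 1.0  # mm conductor
    gel_thickness: float = 1.0  # mm
    name: str = ""

    def __post_init__(self):
        if self.shape not in ("circle", "oval"):
            raise InvalidParameterError(f"unknown electrode shape {self.shape!r}")
        if self.role not in (ANTERIOR_SOURCE, POSTERIOR_GROUND):
            raise InvalidParameterError(f"unknown electrode role {self.role!r}")

    @property
    def half_axes(self) -> tuple[float, float]:
        """Tangential half-axes (u=lateral, v=up) of the footprint, mm."""
        if self.shape == "circle":
            return self.diameter / 2.0, self.diameter / 2.0
        return self.long_axis / 2.0, self.short_axis / 2.0


def circle(anchor, offset_cm=(0.0, 0.0), role=ANTERIOR_SOURCE, name="", diameter=6.0):
    return Electrode("circle", anchor, offset_cm, role, diameter=diameter, name=name)


def oval(anchor, offset_cm=(0.0, 0.0), role=POSTERIOR_GROUND, name=""):
    return Electrode("oval", anchor, offset_cm, role)


@dataclass
class Montage:
    """A named electrode arrangement with a total injected current."""

    id: object  # 1..6 or "custom"
    electrodes: list
    total_current_ma: float = 1.0

    def __post_init__(self):
        if not self.total_current_ma > 0:
            raise InvalidParameterError("total_current_ma must be > 0")
        roles = {e.role for e in self.electrodes}
        if ANTERIOR_SOURCE not in roles or POSTERIOR_GROUND not in roles:
            raise InvalidParameterError(
                "montage needs at least one anterior-source and one posterior-ground electrode"
            )

    def to_yaml(self, path) -> None:
        data = {
            "id": self.id,
            "total_current_ma": self.total_current_ma,
            "electrodes": [asdict(e) for e in self.electrodes],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "Montage":
        data = yaml.safe_load(Path(path).read_text())
        electrodes = []
        for e in data["electrodes"]:
            e = dict(e)
            e["offset_cm"] = tuple(e.get("offset_cm", (0.0, 0.0)))
            electrodes.append(Electrode(**e))
        return cls(id=data["id"], electrodes=electrodes,
                   total_current_ma=float(data.get("total_current_ma", 1.0)))


@dataclass
class ElectrodeFaces:
    """Exposed boundary faces of one electrode's conductor.

    ``faces`` is an (M, 4) int array of (i, j, k, face_code); face codes
    0..5 are -x,+x,-y,+y,-z,+z of the owning voxel (i, j, k).
    """

    name: str
    role: str
    faces: np.ndarray
    voxels: np.ndarray  # (K, 3) conductor voxel indices


@dataclass
class BoundaryConditions:
    """Flux/ground boundary specification for the potential solve.

    A single uniform inward normal current density ``jn_a_per_m2`` is applied
    over the union of all source exposed faces so that
    ``jn * total source area = total current``; ground faces receive V = 0.
    """

    electrodes: list  # list[ElectrodeFaces]
    jn_a_per_m2: float
    total_current_ma: float
    face_area_m2: float

    @property
    def source_faces(self) -> np.ndarray:
        fs = [e.faces for e in self.electrodes if e.role == ANTERIOR_SOURCE]
        return np.concatenate(fs) if fs else np.empty((0, 4), int)

    @property
    def ground_faces(self) -> np.ndarray:
        fs = [e.faces for e in self.electrodes if e.role == POSTERIOR_GROUND]
        return np.concatenate(fs) if fs else np.empty((0, 4), int)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def _head_center(phantom: VoxelPhantom) -> np.ndarray:
    f = phantom.fiducials
    return np.mean(
        [f["nasion"], f["inion"], f["left_preauricular"], f["right_preauricular"]], axis=0
    )


def _surface_point_along(phantom: VoxelPhantom, center, direction) -> np.ndarray:
    """Outermost tissue point along a ray from ``center`` in ``direction``."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    extent = np.linalg.norm(np.array(phantom.shape) * phantom.spacing)
    ts = np.arange(0.0, extent, phantom.spacing / 2.0)
    pts = center + ts[:, None] * direction
    ijk = np.round(phantom.world_to_voxel(pts)).astype(int)
    ok = np.all((ijk >= 0) & (ijk < np.array(phantom.shape)), axis=1)
    inside = np.zeros(len(ts), bool)
    inside[ok] = phantom.labels[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]] != BACKGROUND
    if not inside.any():
        raise PlacementError("ray from head center does not intersect tissue")
    t_surf = ts[np.nonzero(inside)[0][-1]]
    return center + t_surf * direction


def _slerp(a, b, t):
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    ang = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if ang < 1e-12:
        return a
    return (np.sin((1 - t) * ang) * a + np.sin(t * ang) * b) / np.sin(ang)


def _arc_point(phantom, center, via_dirs, fraction, samples=400) -> np.ndarray:
    """Point at a fractional arc length along the surface polyline traced by
    sweeping directions through ``via_dirs`` (list of unit vectors)."""
    ts = np.linspace(0.0, 1.0, samples)
    nseg = len(via_dirs) - 1
    pts = []
    for t in ts:
        seg = min(int(t * nseg), nseg - 1)
        local = t * nseg - seg
        d = _slerp(via_dirs[seg], via_dirs[seg + 1], local)
        pts.append(_surface_point_along(phantom, center, d))
    pts = np.array(pts)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    target = fraction * cum[-1]
    i = int(np.searchsorted(cum, target))
    i = min(max(i, 1), len(pts) - 1)
    w = (target - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-12)
    return pts[i - 1] * (1 - w) + pts[i] * w


def landmark_position(phantom: VoxelPhantom, name: str) -> np.ndarray:
    """Physical position (mm) of a fiducial or supported 10-10 landmark.

    Midline 10-10 labels are placed at their fractional arc length along the
    nasion -> vertex -> inion surface arc; P9/P10 along the lateral
    circumferential arcs through the preauricular points.
    """
    key = name.strip()
    lower = key.lower()
    if lower in FIDUCIAL_ALIASES:
        return phantom.fiducials[FIDUCIAL_ALIASES[lower]].copy()

    c = _head_center(phantom)
    f = phantom.fiducials
    if key in MIDLINE_FRACTIONS:
        dirs = [f["nasion"] - c, f["vertex"] - c, f["inion"] - c]
        return _arc_point(phantom, c, dirs, MIDLINE_FRACTIONS[key])
    if key in LATERAL_FRACTIONS:
        side, frac = LATERAL_FRACTIONS[key]
        pa = f[f"{side}_preauricular"] - c
        dirs = [f["nasion"] - c, pa, f["inion"] - c]
        return _arc_point(phantom, c, dirs, frac)
    raise UnknownLandmarkError(f"unknown landmark {name!r}")


# ---------------------------------------------------------------------------
# Standard montages
# ---------------------------------------------------------------------------

#: lateral offset (cm) of the two nose-bridge electrodes from the nasion;
#: the source description gives no number ("immediate right and left of the
#: nose bridge"), so this is configurable.
NOSE_BRIDGE_OFFSET_CM = 0.8

#: lateral half-spacing (cm) of the posterior oval pair of montages 4 and 6
#: (stated only as "similar location to Montage 3", which uses 4 cm spacing).
M46_POSTERIOR_HALFSPACING_CM = 2.0


def _nose_bridge_pair():
    return [
        circle("nasion", (-NOSE_BRIDGE_OFFSET_CM, 0.0), ANTERIOR_SOURCE, "nose_bridge_left"),
        circle("nasion", (+NOSE_BRIDGE_OFFSET_CM, 0.0), ANTERIOR_SOURCE, "nose_bridge_right"),
    ]


def _forehead_triplet():
    # 1 cm above the nasion, 1.5 cm apart, central electrode on the midline
    return [
        circle("nasion", (-1.5, 1.0), ANTERIOR_SOURCE, "forehead_left"),
        circle("nasion", (0.0, 1.0), ANTERIOR_SOURCE, "forehead_mid"),
        circle("nasion", (+1.5, 1.0), ANTERIOR_SOURCE, "forehead_right"),
    ]


def _m46_posterior_pair():
    h = M46_POSTERIOR_HALFSPACING_CM
    return [
        Electrode("oval", "Iz", (-h, -4.5), POSTERIOR_GROUND, name="neck_left"),
        Electrode("oval", "Iz", (+h, -4.5), POSTERIOR_GROUND, name="neck_right"),
    ]


def standard_montage(montage_id: int, total_current_ma: float = 1.0) -> Montage:
    """Return one of the six candidate montages.

    1. Nose bridge + upper posterior: two 6 mm circles flanking the nose
       bridge; two ovals 1 cm left/right of the midline at POz level.
    2. Upper forehead + lower posterior: two circles 3 cm above the nasion,
       1.5 cm apart; two circles 1 cm left/right of midline at inion level.
    3. Lower forehead + neck posterior: three circles 1 cm above the nasion,
       1.5 cm apart; four ovals 4.5 cm below Iz, 4 cm apart.
    4. Montage 3's forehead triplet + Montage 1's nose-bridge pair; two ovals
       at Montage 3's posterior location.
    5. Montage 3's forehead triplet; circles at P9/P10 (behind the ears).
    6. One midline lower-forehead circle + nose-bridge pair; two posterior
       ovals as in Montage 4.
    """
    if montage_id == 1:
        # "1 cm left/right of the midline" is read as the clearance between
        # the oval's inner edge and the midline: a 25 mm long-axis oval
        # centered 1 cm off-midline would overlap its mirror twin, so the
        # centers sit at +/- (1 cm + long_axis/2).
        off = 1.0 + 2.5 / 2.0
        electrodes = _nose_bridge_pair() + [
            Electrode("oval", "POz", (-off, 0.0), POSTERIOR_GROUND, name="posterior_left"),
            Electrode("oval", "POz", (+off, 0.0), POSTERIOR_GROUND, name="posterior_right"),
        ]
    elif montage_id == 2:
        electrodes = [
            circle("nasion", (-0.75, 3.0), ANTERIOR_SOURCE, "upper_forehead_left"),
            circle("nasion", (+0.75, 3.0), ANTERIOR_SOURCE, "upper_forehead_right"),
            circle("inion", (-1.0, 0.0), POSTERIOR_GROUND, "lower_posterior_left"),
            circle("inion", (+1.0, 0.0), POSTERIOR_GROUND, "lower_posterior_right"),
        ]
    elif montage_id == 3:
        electrodes = _forehead_triplet() + [
            Electrode("oval", "Iz", (x, -4.5), POSTERIOR_GROUND, name=f"neck_{i}")
            for i, x in enumerate((-6.0, -2.0, 2.0, 6.0))
        ]
    elif montage_id == 4:
        electrodes = _forehead_triplet() + _nose_bridge_pair() + _m46_posterior_pair()
    elif montage_id == 5:
        electrodes = _forehead_triplet() + [
            circle("P9", (0.0, 0.0), POSTERIOR_GROUND, "behind_ear_left"),
            circle("P10", (0.0, 0.0), POSTERIOR_GROUND, "behind_ear_right"),
        ]
    elif montage_id == 6:
        electrodes = [circle("nasion", (0.0, 1.0), ANTERIOR_SOURCE, "forehead_mid")]
        electrodes += _nose_bridge_pair() + _m46_posterior_pair()
    else:
        raise UnknownMontageError(f"unknown montage {montage_id!r} (standard ids are 1..6)")
    return Montage(id=montage_id, electrodes=electrodes, total_current_ma=total_current_ma)


# ---------------------------------------------------------------------------
# Stamping and boundary conditions
# ---------------------------------------------------------------------------

_FACE_OFFSETS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]], int
)


def _tangent_frame(normal: np.ndarray):
    """Orthonormal (u=lateral, v=up) tangent basis for an outward normal."""
    n = normal / np.linalg.norm(normal)
    xhat = np.array([1.0, 0.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    u = xhat - (xhat @ n) * n
    if np.linalg.norm(u) < 0.2:  # normal nearly lateral: fall back to y for u
        u = np.array([0.0, 1.0, 0.0]) - (n[1]) * n
    u /= np.linalg.norm(u)
    v = zhat - (zhat @ n) * n - (zhat @ u) * u
    if np.linalg.norm(v) < 0.2:  # near the vertex: derive v from n x u
        v = np.cross(n, u)
    v /= np.linalg.norm(v)
    return n, u, v


class _SurfaceSnapper:
    """Nearest-surface-voxel lookup with local outward-normal estimation."""

    def __init__(self, phantom: VoxelPhantom):
        self.phantom = phantom
        surf = phantom.surface_mask()
        self.surf_ijk = np.argwhere(surf)
        if len(self.surf_ijk) == 0:
            raise PlacementError("phantom has no tissue surface")
        self.surf_xyz = phantom.voxel_to_world(self.surf_ijk)
        self.tree = cKDTree(self.surf_xyz)
        self.tissue = phantom.tissue_mask()
        self.tissue_ijk = np.argwhere(self.tissue)
        self.tissue_tree = cKDTree(phantom.voxel_to_world(self.tissue_ijk))

    def snap(self, point, max_dist_mm=20.0):
        """Nearest surface voxel center, with a tie-break that commutes with
        x-mirroring so left/right-symmetric queries snap to mirrored voxels."""
        k = min(12, len(self.surf_xyz))
        d, i = self.tree.query(point, k=k)
        d = np.atleast_1d(d)
        i = np.atleast_1d(i)
        if d[0] > max_dist_mm:
            raise PlacementError(
                f"anchor point {np.round(point, 1)} is {d[0]:.1f} mm from the surface"
            )
        ties = i[d <= d[0] + 1e-9]
        if len(ties) == 1:
            return self.surf_xyz[ties[0]]
        cand = self.surf_xyz[ties]
        s = 1.0 if point[0] >= -1e-12 else -1.0
        order = np.lexsort((cand[:, 2], cand[:, 1], -s * cand[:, 0]))
        return cand[order[0]]

    def normal(self, surface_point, radius_mm=None):
        """Outward normal estimated from the local tissue centroid.

        The centroid uses exact (order-independent) summation so that
        mirror-symmetric neighborhoods produce exactly mirrored normals."""
        import math

        radius = radius_mm or 6.0 * self.phantom.spacing
        idx = self.tissue_tree.query_ball_point(surface_point, radius)
        pts = self.phantom.voxel_to_world(self.tissue_ijk[idx])
        centroid = np.array([math.fsum(pts[:, a]) for a in range(3)]) / len(pts)
        n = surface_point - centroid
        norm = np.linalg.norm(n)
        if norm < 1e-9:
            raise PlacementError("cannot estimate surface normal (degenerate neighborhood)")
        return n / norm


def _walk_surface(snapper, start, component, arc_mm, step_mm=3.0):
    """Walk an arc length along the surface in the local u (component=0) or
    v (component=1) tangent direction, re-snapping at every step."""
    p = start
    remaining = abs(arc_mm)
    sgn = np.sign(arc_mm)
    while remaining > 1e-9:
        n = snapper.normal(p)
        _, u, v = _tangent_frame(n)
        d = u if component == 0 else v
        s = min(step_mm, remaining)
        p = snapper.snap(p + sgn * s * d)
        remaining -= s
    return p


def resolve_anchor(phantom: VoxelPhantom, electrode: Electrode,
                   snapper: _SurfaceSnapper | None = None):
    """Resolve an electrode's anchor to (surface point, outward normal, u, v).

    The tangential offset is applied as an arc length along the surface
    (lateral first, then vertical), so large offsets follow the curved
    scalp/neck rather than a flat tangent plane.
    """
    snapper = snapper or _SurfaceSnapper(phantom)
    base = landmark_position(phantom, electrode.anchor)
    p = snapper.snap(base)
    off = np.asarray(electrode.offset_cm, float) * 10.0  # cm -> mm
    if abs(off[0]) > 0:
        p = _walk_surface(snapper, p, 0, off[0])
    if abs(off[1]) > 0:
        p = _walk_surface(snapper, p, 1, off[1])
    n = snapper.normal(p)
    n, u, v = _tangent_frame(n)
    return p, n, u, v


def apply_montage(phantom: VoxelPhantom, montage: Montage, table=None):
    """Stamp electrode + gel geometry into a copy of the phantom.

    For each electrode a gel layer conforming to the stair-stepped voxel
    surface (morphological dilation of the tissue) and a conductor disk on
    top of it are written with the "Conductive gel" and
    "Electrode (material)" labels.  Returns ``(stamped_phantom,
    BoundaryConditions)`` with a uniform inward normal current density over
    the union of source exposed faces integrating to the montage's total
    current.
    """
    out = phantom.copy()
    spacing = out.spacing
    snapper = _SurfaceSnapper(phantom)
    tissue0 = phantom.tissue_mask()
    shape = np.array(out.shape)

    gel_label = TISSUE_LABELS["Conductive gel"]
    el_label = TISSUE_LABELS["Electrode (material)"]
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

    claimed = np.zeros(out.shape, bool)  # voxels stamped by any electrode
    electrode_voxels = []

    for electrode in montage.electrodes:
        anchor, n, u, v = resolve_anchor(phantom, electrode, snapper)
        ha_u, ha_v = electrode.half_axes
        n_gel = max(1, int(round(electrode.gel_thickness / spacing)))
        n_el = max(1, int(round(electrode.thickness / spacing)))
        reach = (n_gel + n_el + 2) * spacing

        # local bounding box
        rad = max(ha_u, ha_v) + reach
        lo = np.maximum(np.floor(out.world_to_voxel(anchor - rad)).astype(int), 0)
        hi = np.minimum(np.ceil(out.world_to_voxel(anchor + rad)).astype(int) + 1, shape)
        box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

        sub_t = tissue0[box]
        gi = np.meshgrid(*[np.arange(s.start, s.stop) for s in box], indexing="ij")
        pts = out.voxel_to_world(np.stack([g.ravel() for g in gi], axis=1))
        d = pts - anchor
        tu = d @ u
        tv = d @ v
        tn = d @ n
        foot = ((tu / ha_u) ** 2 + (tv / ha_v) ** 2 <= 1.0) & (
            tn >= -0.5 * spacing
        ) & (tn <= reach)
        foot = foot.reshape(sub_t.shape)

        dil1 = ndimage.binary_dilation(sub_t, structure=struct, iterations=n_gel)
        dil2 = ndimage.binary_dilation(dil1, structure=struct, iterations=n_el)
        gel_vox = dil1 & ~sub_t & foot
        cond_vox = dil2 & ~dil1 & foot
        if not gel_vox.any() or not cond_vox.any():
            raise PlacementError(
                f"electrode {electrode.name or electrode.anchor!r} produced an empty stamp"
            )

        stamp = gel_vox | cond_vox
        if (claimed[box] & stamp).any():
            raise GeometryConflictError(
                f"electrode {electrode.name or electrode.anchor!r} overlaps a previously "
                "stamped electrode footprint"
            )
        claimed[box] |= stamp
        out.labels[box][gel_vox] = gel_label
        out.labels[box][cond_vox] = el_label

        ijk = np.argwhere(cond_vox) + lo
        electrode_voxels.append((electrode, ijk))

    # exposed faces: conductor voxel faces adjacent to background
    domain = out.tissue_mask()
    faces_per_electrode = []
    for electrode, ijk in electrode_voxels:
        faces = []
        for code, off in enumerate(_FACE_OFFSETS):
            nb = ijk + off
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            outside = np.ones(len(ijk), bool)
            outside[ok] = ~domain[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
            sel = ijk[outside]
            if len(sel):
                faces.append(np.column_stack([sel, np.full(len(sel), code)]))
        if not faces:
            raise PlacementError(
                f"electrode {electrode.name or electrode.anchor!r} has no exposed surface"
            )
        faces_per_electrode.append(
            ElectrodeFaces(
                name=electrode.name or f"{electrode.anchor}{electrode.offset_cm}",
                role=electrode.role,
                faces=np.concatenate(faces),
                voxels=ijk,
            )
        )

    face_area = units.mm_to_m(spacing) ** 2
    n_src = sum(len(e.faces) for e in faces_per_electrode if e.role == ANTERIOR_SOURCE)
    jn = units.ma_to_a(montage.total_current_ma) / (n_src * face_area)
    bc = BoundaryConditions(
        electrodes=faces_per_electrode,
        jn_a_per_m2=jn,
        total_current_ma=montage.total_current_ma,
        face_area_m2=face_area,
    )
    return out, bc
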