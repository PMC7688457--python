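"""Drivers of axonal polarization along exemplary axon paths.

Under extracellular stimulation, a finite axon is polarized by the electric
field component along its local direction (Et) and, for long fibers, by the
activating function — the second spatial difference of the extracellular
potential along the path, f(s) = d^2 Ve / d s^2, evaluated here as a central
second difference over a uniform arc-length grid.  Profiles across montages
are normalized to the largest absolute value in the set so different
montages can be compared on one axis.

Paths are piecewise-linear control polygons resampled at uniform arc-length
steps; potential and field are sampled by trilinear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from . import units
from .errors import (
    DegeneratePathError,
    InsufficientSamplesError,
    InvalidParameterError,
    NormalizationError,
    OutOfDomainError,
)
from .solver import EFField, PotentialField

#: default resampling step, mm (sub-voxel so second differences stay smooth
#: on 0.5–1 mm grids)
DEFAULT_DS_MM = 0.1


@dataclass
class AxonPath:
    """Uniformly resampled axon path."""

    points: np.ndarray  # (N, 3) physical mm
    ds_mm: float
    roi_name: str = ""

    @property
    def arc_length(self) -> np.ndarray:
        return self.ds_mm * np.arange(len(self.points))

    @property
    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points, self.ds_mm, axis=0)
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        return t / np.where(norms > 0, norms, 1.0)

    def to_text(self, path) -> None:
        np.savetxt(path, self.points, fmt="%.6f",
                   header="x_mm y_mm z_mm", comments="# ")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "roi_name": self.roi_name,
            "ds_mm": self.ds_mm,
            "points_mm": self.points.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "AxonPath":
        d = json.loads(Path(path).read_text())
        return cls(points=np.array(d["points_mm"], float), ds_mm=float(d["ds_mm"]),
                   roi_name=d.get("roi_name", ""))


def make_axon(control_points, ds_mm: float = DEFAULT_DS_MM, roi_name: str = "") -> AxonPath:
    """Resample a piecewise-linear control polygon at uniform arc length."""
    pts = np.atleast_2d(np.asarray(control_points, float))
    if ds_mm is None or ds_mm <= 0:
        raise InvalidParameterError(f"ds must be > 0, got {ds_mm}")
    if len(pts) < 2:
        raise DegeneratePathError("need at least 2 control points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.all(seg < 1e-12):
        raise DegeneratePathError("control points are coincident")
    keep = np.concatenate([[True], seg > 1e-12])
    pts = pts[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = int(np.floor(total / ds_mm + 1e-9)) + 1
    s = ds_mm * np.arange(n)
    out = np.column_stack([np.interp(s, cum, pts[:, a]) for a in range(3)])
    if len(out) < 3:
        raise DegeneratePathError(
            f"path of length {total:.3g} mm yields fewer than 3 samples at ds={ds_mm}"
        )
    return AxonPath(points=out, ds_mm=ds_mm, roi_name=roi_name)


def _filled_interpolator(values: np.ndarray, mask: np.ndarray, phantom):
    """Trilinear interpolator over the grid with exterior voxels filled by
    their nearest in-domain value (keeps interpolation clean at the domain
    boundary)."""
    filled = values
    if not mask.all():
        idx = ndimage.distance_transform_edt(
            ~mask, return_distances=False, return_indices=True
        )
        filled = values[tuple(idx)]
    grids = phantom.coordinate_grids() if hasattr(phantom, "coordinate_grids") else phantom
    rgi = RegularGridInterpolator(grids, filled, method="linear",
                                  bounds_error=False, fill_value=np.nan)

    def interp(points_mm):
        out = rgi(np.atleast_2d(points_mm))
        return out

    return interp


def _check_inside(mask: np.ndarray, phantom, points_mm):
    ijk = np.round(phantom.world_to_voxel(points_mm)).astype(int)
    shape = np.array(mask.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    ok = np.zeros(len(ijk), bool)
    ok[inside] = mask[ijk[inside, 0], ijk[inside, 1], ijk[inside, 2]]
    if not ok.all():
        bad = int(np.argmin(ok))
        raise OutOfDomainError(
            f"axon sample at s = {bad} * ds (point {np.round(points_mm[bad], 2)}) "
            "lies outside the solved domain"
        )


def potential_along_axon(potential: PotentialField, path: AxonPath, phantom) -> np.ndarray:
    """Extracellular potential Ve(s) in volts by trilinear interpolation."""
    _check_inside(potential.mask, phantom, path.points)
    interp = _filled_interpolator(potential.values, potential.mask, phantom)
    return interp(path.points)


def ef_along_axon(ef: EFField, path: AxonPath, phantom) -> np.ndarray:
    """Signed tangential field Et(s) = E(s) . t(s) in V/m.

    Positive when the field points along increasing arc length."""
    _check_inside(ef.mask, phantom, path.points)
    comps = [
        _filled_interpolator(ef.vectors[..., a], ef.mask, phantom)(path.points)
        for a in range(3)
    ]
    E = np.column_stack(comps)
    return np.einsum("ij,ij->i", E, path.tangents)


def activating_function(ve: np.ndarray, ds_mm: float) -> np.ndarray:
    """Second difference of Ve over ds^2, in V/m^2.

    Interior points use the central second difference; endpoints copy the
    one-sided second difference of their nearest interior neighbor, keeping
    the output the same length as the input.
    """
    ve = np.asarray(ve, float)
    if len(ve) < 3:
        raise InsufficientSamplesError("activating function needs >= 3 samples")
    if ds_mm is None or ds_mm <= 0:
        raise InvalidParameterError(f"ds must be > 0, got {ds_mm}")
    ds_m = units.mm_to_m(ds_mm)
    f = np.empty_like(ve)
    f[1:-1] = (ve[:-2] - 2 * ve[1:-1] + ve[2:]) / ds_m**2
    f[0] = f[1]
    f[-1] = f[-2]
    return f


@dataclass
class DrivingProfiles:
    """Arc-length profiles of the polarization drivers for one montage/axon."""

    s_mm: np.ndarray
    ve_v: np.ndarray
    et_v_per_m: np.ndarray
    af_v_per_m2: np.ndarray
    montage_id: object = None
    roi_name: str = ""
    #: set by normalize_profiles: per-quantity global reference values and
    #: the id of the profile that supplied them
    normalization: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "s_mm": self.s_mm, "ve_v": self.ve_v,
            "et_v_per_m": self.et_v_per_m, "af_v_per_m2": self.af_v_per_m2,
        })
        for key in ("et_v_per_m", "af_v_per_m2"):
            ref = self.normalization.get(key)
            if ref:
                df[key.split("_")[0] + "_normalized"] = df[key] / ref["reference_value"]
        df.to_csv(path, index=False)


def compute_profiles(potential: PotentialField, ef: EFField, path: AxonPath,
                     phantom, montage_id=None) -> DrivingProfiles:
    """All three drivers (Ve, Et, activating function) along one axon."""
    ve = potential_along_axon(potential, path, phantom)
    et = ef_along_axon(ef, path, phantom)
    af = activating_function(ve, path.ds_mm)
    return DrivingProfiles(
        s_mm=path.arc_length, ve_v=ve, et_v_per_m=et, af_v_per_m2=af,
        montage_id=montage_id, roi_name=path.roi_name,
    )


def normalize_profiles(profiles) -> list:
    """Normalize Et and activating-function profiles across a set.

    Each quantity is divided by the global maximum absolute value of that
    quantity over the whole set; the profile supplying the reference is
    recorded.  Returns new profiles with ``normalization`` filled and the
    quantity arrays scaled.
    """
    profiles = list(profiles)
    if not profiles:
        raise NormalizationError("empty profile set")
    out = []
    refs = {}
    for key, attr in (("et_v_per_m", "et_v_per_m"), ("af_v_per_m2", "af_v_per_m2")):
        peak, ref_profile = 0.0, None
        for p in profiles:
            m = float(np.max(np.abs(getattr(p, attr))))
            if m > peak:
                peak, ref_profile = m, (p.montage_id, p.roi_name)
        if peak == 0.0:
            raise NormalizationError(f"all-zero quantity {key}: cannot normalize")
        refs[key] = {"reference_value": peak, "reference_profile": ref_profile}
    for p in profiles:
        out.append(
            DrivingProfiles(
                s_mm=p.s_mm.copy(),
                ve_v=p.ve_v.copy(),
                et_v_per_m=p.et_v_per_m / refs["et_v_per_m"]["reference_value"],
                af_v_per_m2=p.af_v_per_m2 / refs["af_v_per_m2"]["reference_value"],
                montage_id=p.montage_id,
                roi_name=p.roi_name,
                normalization=refs,
            )
        )
    return out


def default_oe_axons(phantom, rois, ds_mm: float = DEFAULT_DS_MM) -> dict:
    """One exemplary straight axon per OE third, oriented along the OE sheet
    (anterior-posterior), derived from the phantom's OE geometry.

    The posterior axon is shortened (the sheet narrows toward the back), so
    it is the shortest of the three.
    """
    from .phantom import partition_oe_thirds

    thirds = partition_oe_thirds(rois["OE"], anterior_axis=1, anterior_positive=True)
    names = ("OE_anterior", "OE_middle", "OE_posterior")
    # fraction of each third's AP extent spanned by its axon
    spans = (0.8, 0.8, 0.5)
    axons = {}
    for name, mask, span in zip(names, thirds, spans):
        ijk = np.argwhere(mask)
        if len(ijk) == 0:
            continue
        xyz = phantom.voxel_to_world(ijk)
        x_mid = np.median(xyz[:, 0])
        z_mid = np.median(xyz[:, 2])
        y_lo, y_hi = xyz[:, 1].min(), xyz[:, 1].max()
        extent = y_hi - y_lo
        margin = (1.0 - span) / 2.0 * extent + phantom.spacing
        # keep at least a few samples even on coarse grids
        min_span = max(4.0 * ds_mm, phantom.spacing)
        margin = min(margin, max(0.0, (extent - min_span) / 2.0))
        p0 = np.array([x_mid, y_lo + margin, z_mid])
        p1 = np.array([x_mid, y_hi - margin, z_mid])
        axons[name] = make_axon([p0, p1], ds_mm=ds_mm, roi_name=name)
    return axons
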