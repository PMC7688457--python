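"""End-to-end screening workflow: configuration, fixtures, two-stage screen.

Stage 1 solves every configured montage on the phantom and ranks them by the
olfactory-epithelium volume fraction above the reference threshold; stage 2
reruns the top-ranked subset with OE-third summaries, deep-ROI summaries,
cross-sections and axonal driving profiles.  Every output file is
accompanied by provenance metadata (config hash, package version, solver
residuals); a run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from importlib.metadata import version as _pkg_version
from .axon import compute_profiles, default_oe_axons, normalize_profiles
from .errors import ConfigurationError, PipelineError, UnknownMontageError
from .metrics import (
    REFERENCE_THRESHOLD,
    montage_report,
    oe_thirds_summary,
    render_cross_section,
    roi_summary,
)
from .phantom import (
    OlfactoryHeadParams,
    RoiSet,
    VoxelPhantom,
    build_layered_sphere,
    build_olfactory_head,
    default_conductivity_table,
    partition_oe_thirds,
)

log = logging.getLogger("olftes.pipeline")


@dataclass
class RunConfig:
    """Fully serializable description of one screening run."""

    phantom_kind: str = "olfactory_head"  # or "nifti"
    spacing_mm: float = 1.0
    phantom_path: str | None = None  # NIfTI label volume (phantom_kind="nifti")
    registry_path: str | None = None
    roi_dir: str | None = None
    phantom_params: dict = field(default_factory=dict)
    montage_ids: tuple = (1, 2, 3, 4, 5, 6)
    total_current_ma: float = 1.0
    rel_tol: float = 1e-8
    threshold_max_v_per_m: float = 1.0
    threshold_count: int = 101
    reference_threshold: float = REFERENCE_THRESHOLD
    top_k: int = 3
    axon_ds_mm: float = 0.1
    outdir: str = "olftes_run"
    seed: int = 0

    def thresholds(self) -> np.ndarray:
        return np.linspace(0.0, self.threshold_max_v_per_m, self.threshold_count)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["montage_ids"] = tuple(data.get("montage_ids", (1, 2, 3, 4, 5, 6)))
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def build_phantom(config: RunConfig):
    """Materialize the configured phantom and its ROI set."""
    if config.phantom_kind == "olfactory_head":
        params = OlfactoryHeadParams(**config.phantom_params)
        return build_olfactory_head(config.spacing_mm, params)
    if config.phantom_kind == "nifti":
        if not config.phantom_path:
            raise ConfigurationError("phantom_kind='nifti' requires phantom_path")
        phantom = VoxelPhantom.from_nifti(config.phantom_path, config.registry_path)
        rois = RoiSet.from_nifti(config.roi_dir) if config.roi_dir else RoiSet({})
        return phantom, rois
    raise ConfigurationError(f"unknown phantom kind {config.phantom_kind!r}")


def _provenance(config: RunConfig, extra=None) -> dict:
    out = {
        "config_digest": config.digest(),
        "olftes_version": _pkg_version("olftes"),
        "config": asdict(config),
    }
    if extra:
        out.update(extra)
    return out


def run_screening(config: RunConfig):
    """Execute the two-stage montage screen; returns the report bundle dict.

    Stage failures abort with a :class:`PipelineError` naming the stage and
    montage; outputs produced so far are retained next to a failure
    manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = default_conductivity_table()
    bundle = {"stage1": None, "stage2": {}, "provenance": _provenance(config)}

    def fail(stage, montage_id, exc):
        manifest = {
            "failed_stage": stage,
            "montage": montage_id,
            "error": f"{type(exc).__name__}: {exc}",
        }
        (outdir / "failure_manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(
            f"stage {stage!r} failed for montage {montage_id}: {exc}"
        ) from exc

    log.info("building phantom kind=%s spacing=%g", config.phantom_kind, config.spacing_mm)
    try:
        phantom, rois = build_phantom(config)
    except Exception as exc:  # noqa: BLE001 - manifest then re-raise
        fail("phantom", None, exc)

    # validate montage ids before any heavy work
    for mid in config.montage_ids:
        if isinstance(mid, int) and not 1 <= mid <= 6:
            err = UnknownMontageError(f"unknown montage {mid}")
            fail("montage-definition", mid, err)

    # ---------------------------------------------------------------- stage 1
    try:
        report = montage_report(
            phantom, rois, list(config.montage_ids),
            total_current_ma=config.total_current_ma,
            thresholds=config.thresholds(), table=table,
            rel_tol=config.rel_tol,
            reference_threshold=config.reference_threshold,
            keep_fields=True,
        )
    except Exception as exc:  # noqa: BLE001
        fail("stage1-screen", None, exc)

    report.to_frame().to_csv(outdir / "stage1_summaries.csv", index=False)
    report.curves_frame().to_csv(outdir / "stage1_focality_curves.csv", index=False)
    ranking = report.ranking()
    bundle["stage1"] = {
        "ranking": ranking,
        "reference_threshold_v_per_m": config.reference_threshold,
        "residuals": {
            str(r.montage_id): r.solver_report["relative_residual"] for r in report.results
        },
    }
    log.info("stage 1 ranking by OE fraction above %.2f V/m: %s",
             config.reference_threshold, ranking)

    # ---------------------------------------------------------------- stage 2
    top = ranking[: config.top_k]
    thirds = None
    if "OE" in rois:
        thirds = partition_oe_thirds(rois["OE"], anterior_axis=1, anterior_positive=True)
    axons = default_oe_axons(phantom, rois, config.axon_ds_mm) if "OE" in rois else {}

    profiles_by_montage = {}
    for result in report.results:
        mid = result.montage_id
        if mid not in top:
            continue
        sub = outdir / f"montage_{mid}"
        sub.mkdir(exist_ok=True)
        try:
            rows = []
            if thirds is not None:
                for s in oe_thirds_summary(result.ef, thirds, phantom.spacing):
                    rows.append(s.as_dict())
            for roi in ("OB", "hippocampus", "basal_ganglia"):
                if roi in rois:
                    rows.append(roi_summary(result.ef, rois[roi], phantom.spacing, roi).as_dict())
            import pandas as pd

            pd.DataFrame(rows).to_csv(sub / "deep_dive_summaries.csv", index=False)

            # coronal (fixed-y) cross sections through the deep ROIs
            for roi in ("hippocampus", "basal_ganglia"):
                if roi in rois and rois[roi].any():
                    yidx = int(np.round(np.argwhere(rois[roi])[:, 1].mean()))
                    render_cross_section(
                        result.ef, axis=1, index=yidx,
                        overlay_masks={roi: rois[roi]},
                        path=sub / f"coronal_{roi}.png",
                    )

            profs = []
            for name, path in axons.items():
                prof = compute_profiles(result.potential, result.ef, path, phantom, mid)
                profs.append(prof)
            profiles_by_montage[mid] = profs
            bundle["stage2"][str(mid)] = {
                "folder": str(sub),
                "solver_relative_residual": result.solver_report["relative_residual"],
            }
        except Exception as exc:  # noqa: BLE001
            fail("stage2-deep-dive", mid, exc)

    # cross-montage normalization of the driving profiles
    if profiles_by_montage:
        try:
            flat = [p for profs in profiles_by_montage.values() for p in profs]
            normalized = normalize_profiles(flat)
            for prof in normalized:
                sub = outdir / f"montage_{prof.montage_id}"
                prof.to_csv(sub / f"axon_{prof.roi_name}.csv")
            bundle["normalization"] = {
                k: {"reference_value": v["reference_value"],
                    "reference_profile": list(v["reference_profile"])}
                for k, v in normalized[0].normalization.items()
            }
        except Exception as exc:  # noqa: BLE001
            fail("stage2-normalize", None, exc)

    (outdir / "report.json").write_text(json.dumps(bundle, indent=1, default=str))
    config.to_yaml(outdir / "config.yaml")
    return bundle


def generate_fixtures(seed: int, outdir) -> dict:
    """Write the standard fixture set; deterministic given the seed.

    Produces the 4-layer validation sphere, the olfactory head at 2 mm with
    its ROI masks, the default exemplary axon paths, and a miniature
    smoke-test phantom (< 64^3 voxels) with ROI masks.
    """
    rng = np.random.default_rng(seed)  # reserved for future randomized fixtures
    del rng
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    sphere = build_layered_sphere(
        [80.0, 75.0, 71.0, 69.0], ["Scalp", "Skull", "CSF", "Gray matter"], 2.0
    )
    sphere.to_nifti(outdir / "sphere_4layer_2mm.nii")
    written["sphere"] = str(outdir / "sphere_4layer_2mm.nii")

    head, rois = build_olfactory_head(2.0)
    head.to_nifti(outdir / "olfactory_head_2mm.nii")
    rois.to_nifti(outdir / "rois_2mm", head)
    written["olfactory_head"] = str(outdir / "olfactory_head_2mm.nii")

    axons = default_oe_axons(head, rois)
    for name, path in axons.items():
        path.to_json(outdir / f"axon_{name}.json")
        path.to_text(outdir / f"axon_{name}.txt")
    written["axons"] = sorted(str(p) for p in outdir.glob("axon_*.json"))

    smoke = build_layered_sphere([28.0, 25.0, 22.0], ["Scalp", "Skull", "Gray matter"], 2.0)
    smoke.to_nifti(outdir / "smoke_sphere_2mm.nii")
    written["smoke"] = str(outdir / "smoke_sphere_2mm.nii")

    def rel(entry):
        if isinstance(entry, list):
            return [rel(e) for e in entry]
        return str(Path(entry).relative_to(outdir))

    (outdir / "fixtures_manifest.json").write_text(
        json.dumps({"seed": seed,
                    "files": {k: rel(v) for k, v in written.items()}}, indent=1)
    )
    return written
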