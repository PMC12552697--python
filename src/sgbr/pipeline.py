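"""End-to-end orchestration: design, homogenize, grow, fracture, segment,
report — with a provenance manifest.

A run is a directory of stage outputs plus ``manifest.json`` recording the
config hash, seeds, and a SHA-256 checksum of every file each stage wrote.
Reruns of the same config produce identical checksums for the
deterministic stages; :func:`verify_run` detects corrupted intermediates
and names the offending stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml

from .image import ImageVolume, write_nifti
from . import geometry, ctseg
from .geometry import ScaffoldSpec
from .materials import DEFAULT_MATERIALS
from .homogenize import build_property_table, EffectivePropertyTable
from .growth import GrowthConfig, run_scenarios, REFERENCE_GROWTH_LOAD
from .synthetic import (PhantomSpec, make_phantom, make_load_case,
                        make_ct_phantom, make_ct)
from .voxfem import propagate_crack
from .stats import linreg, scenario_summary

log = logging.getLogger("sgbr.pipeline")

STAGES = ("design", "homogenize", "phantom", "growth", "fracture",
          "segment", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    scaffold: dict = dc_field(default_factory=lambda: dict(
        family="gyroid", unit_cell_size=3.5, target_volume_fraction=0.5,
        voxel_spacing=3.5 / 16))
    phantom: dict = dc_field(default_factory=lambda: dict(screw_patches=0))
    growth: dict = dc_field(default_factory=dict)
    growth_load_n: float = REFERENCE_GROWTH_LOAD
    table_samples: int = 6
    fracture_schedule: list = dc_field(
        default_factory=lambda: [float(x)
                                 for x in np.linspace(100.0, 2000.0, 8)])
    ct_roi_mm: float = 4.0
    scenarios: list = dc_field(default_factory=lambda: ["excluded"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Each stage consumes only the previous stages' files within the run
    directory; any failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"config_sha256": config.digest(), "seed": config.seed,
                "stages": {}}

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "seconds": round(time.time() - t0, 3),
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    # --- design ---------------------------------------------------------
    t0 = time.time()
    try:
        spec = ScaffoldSpec(**config.scaffold)
        mask, iso = geometry.generate_scaffold(spec)
        vf = geometry.volume_fraction(mask)
        pore, perc = geometry.pore_size(mask)
        strut = geometry.strut_size(mask)
        write_nifti(mask, out / "scaffold_cell.nii.gz")
        with open(out / "design_metrics.json", "w") as fh:
            json.dump({"iso_level": iso, "volume_fraction": vf,
                       "pore_size_mm": pore, "pore_percolates": perc,
                       "strut_size_mm": strut}, fh, indent=2)
        design_files = [out / "scaffold_cell.nii.gz",
                        out / "design_metrics.json"]
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("design", str(e)) from e
    record("design", design_files, t0)

    # --- homogenize -----------------------------------------------------
    t0 = time.time()
    try:
        table = build_property_table(
            mask, {1: DEFAULT_MATERIALS["ls_pek"],
                   2: DEFAULT_MATERIALS["new_bone"]},
            n_samples=config.table_samples, scaffold_label=1,
            new_bone_label=2, descriptor=str(config.scaffold))
        table.to_json(out / "property_table.json")
    except Exception as e:
        raise PipelineError("homogenize", str(e)) from e
    record("homogenize", [out / "property_table.json"], t0)

    # --- phantom --------------------------------------------------------
    t0 = time.time()
    try:
        ph = make_phantom(PhantomSpec(seed=config.seed, **config.phantom))
        write_nifti(ph.labels, out / "phantom_labels.nii.gz")
    except Exception as e:
        raise PipelineError("phantom", str(e)) from e
    record("phantom", [out / "phantom_labels.nii.gz"], t0)

    # --- growth ---------------------------------------------------------
    t0 = time.time()
    try:
        table = EffectivePropertyTable.from_json(out / "property_table.json")
        case = make_load_case(ph, config.growth_load_n, "bonded")
        cfg = GrowthConfig(**config.growth)
        res = run_scenarios(ph.labels, cfg, table, case,
                            scenarios=tuple(config.scenarios))
        growth_files = []
        rows = ["scenario,week,mass_g"]
        for sc, r in res["scenarios"].items():
            for w, snap in sorted(r["state"].snapshots.items()):
                f = out / f"density_{sc}_week{int(w)}.nii.gz"
                write_nifti(ImageVolume(snap, ph.labels.spacing), f)
                growth_files.append(f)
            for w, m in sorted(r["mass_at_checkpoint"].items()):
                rows.append(f"{sc},{w},{m}")
        (out / "mass_history.csv").write_text("\n".join(rows) + "\n")
        with open(out / "growth_summary.json", "w") as fh:
            json.dump({str(w): v for w, v in res["summary"].items()}, fh,
                      indent=2)
        growth_files += [out / "mass_history.csv", out / "growth_summary.json"]
        growth_res = res
    except Exception as e:
        raise PipelineError("growth", str(e)) from e
    record("growth", growth_files, t0)

    # --- fracture -------------------------------------------------------
    t0 = time.time()
    try:
        case_fr = make_load_case(ph, 1.0, "bonded")
        crack = propagate_crack(ph.labels, _label_materials(), case_fr,
                                config.fracture_schedule)
        with open(out / "fracture.json", "w") as fh:
            json.dump({
                "failure_load_n": crack.failure_load,
                "arrested_levels": list(crack.arrested_levels),
                "crack_path": [list(map(int, ijk)) for ijk in crack.path],
            }, fh, indent=2)
    except Exception as e:
        raise PipelineError("fracture", str(e)) from e
    record("fracture", [out / "fracture.json"], t0)

    # --- segment --------------------------------------------------------
    t0 = time.time()
    try:
        ctph = make_ct_phantom(seed=config.seed, roi_mm=config.ct_roi_mm)
        scan, truth = make_ct(ctph.labels, seed=config.seed)
        seg = ctseg.segment_scan(
            scan,
            ImageVolume(ctph.masks["frame"], ctph.labels.spacing),
            ImageVolume(ctph.masks["lattice_envelope"], ctph.labels.spacing),
            ImageVolume(ctph.masks["native_bone"], ctph.labels.spacing))
        truth_cm3 = float((truth.values == 4).sum()
                          * ctph.labels.voxel_volume / 1000.0)
        with open(out / "segmentation.json", "w") as fh:
            json.dump({"volumes_cm3": seg.volumes_cm3,
                       "truth_cm3": truth_cm3,
                       "thresholds": seg.thresholds}, fh, indent=2)
    except Exception as e:
        raise PipelineError("segment", str(e)) from e
    record("segment", [out / "segmentation.json"], t0)

    # --- report ---------------------------------------------------------
    t0 = time.time()
    try:
        masses = {sc: r["mass_at_checkpoint"]
                  for sc, r in growth_res["scenarios"].items()}
        any_sc = next(iter(masses.values()))
        weeks = sorted(any_sc)
        if len(weeks) >= 3:
            rep = linreg(weeks, [any_sc[w] for w in weeks])
            mass_vs_time = {"slope_g_per_week": rep.slope,
                            "r_squared": rep.r_squared,
                            "F": rep.F, "df": list(rep.df), "p": rep.p}
        else:  # too few checkpoints for a regression
            mass_vs_time = {"slope_g_per_week": None, "r_squared": None,
                            "F": None, "df": None, "p": None}
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # single-scenario SD warning
            summary = scenario_summary(masses)
        with open(out / "report.json", "w") as fh:
            json.dump({
                "mass_vs_time": mass_vs_time,
                "scenario_summary": {str(w): v for w, v in summary.items()},
            }, fh, indent=2)
    except Exception as e:
        raise PipelineError("report", str(e)) from e
    record("report", [out / "report.json"], t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _label_materials() -> dict:
    from .image import LABELS
    return {LABELS["host_bone"]: DEFAULT_MATERIALS["bone"],
            LABELS["scaffold_solid"]: DEFAULT_MATERIALS["ls_pek"],
            LABELS["tcp_lattice"]: DEFAULT_MATERIALS["btcp"],
            LABELS["screw"]: DEFAULT_MATERIALS["screw"]}


def verify_run(run_dir) -> None:
    """Check every manifest checksum; raise PipelineError naming the stage
    of the first mismatching or missing file."""
    run = Path(run_dir)
    with open(run / "manifest.json") as fh:
        manifest = json.load(fh)
    for stage, info in manifest["stages"].items():
        for name, digest in info["files"].items():
            path = run / name
            if not path.exists():
                raise PipelineError(stage, f"missing output {name}")
            if _sha256(path) != digest:
                raise PipelineError(stage, f"checksum mismatch in {name}")
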