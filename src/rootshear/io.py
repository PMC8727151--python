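"""Readers, writers, configuration and the end-to-end pipeline.

File conventions (one declared unit system, as printed in lab reports):
lengths mm, soil stresses kPa, root stiffness MPa, angles degrees.

* Root table CSV: header ``label,x_mm,y_mm,diameter_mm,E_MPa``.
* Specimen config JSON: ``phi_deg, tau_prime_kpa, Z_min_mm, Z_max_mm,
  D_tube_mm, growth{u_step3_mm, u_final_mm, f_step3}, baseline_csv``.
* Stress record CSV: ``u_mm,S_kpa``.
* Zone-map CSV: ``x_mm,y_mm,thickness_mm,z_lower_mm,z_upper_mm,ok``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import presets
from .backanalysis import assumption_check, fit_tau_prime
from .field import read_field, write_field  # noqa: F401  (re-exported surface)
from .model import (
    GrowthSchedule,
    InterfaceParams,
    Root,
    ShearTestRecord,
    ShearZoneModel,
    SoilParams,
    Specimen,
    predict_stress_curve,
)
from .synthetic import (
    FieldGenConfig,
    RootMapConfig,
    generate_field,
    generate_root_map,
    generate_stress_record,
)
from .trilinear import FitSettings
from .zonemap import ShearZoneMap, thickness_map

logger = logging.getLogger(__name__)

__all__ = [
    "read_root_table",
    "write_root_table",
    "read_record",
    "write_record",
    "read_specimen_config",
    "load_specimen",
    "write_map_csv",
    "read_map_csv",
    "RunConfig",
    "run_pipeline",
]

ROOT_COLUMNS = ["label", "x_mm", "y_mm", "diameter_mm", "E_MPa"]


def read_root_table(path) -> list[Root]:
    """Read the per-root CSV; validation errors name the offending row."""
    df = pd.read_csv(path)
    missing = [c for c in ROOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    roots = []
    for idx, row in df.iterrows():
        try:
            roots.append(
                Root(
                    x_mm=float(row["x_mm"]),
                    y_mm=float(row["y_mm"]),
                    diameter_mm=float(row["diameter_mm"]),
                    e_mpa=float(row["E_MPa"]),
                    label=str(row["label"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {idx + 1}: {exc}") from exc
    return roots


def write_root_table(path, roots: list[Root]) -> None:
    pd.DataFrame(
        {
            "label": [r.label for r in roots],
            "x_mm": [r.x_mm for r in roots],
            "y_mm": [r.y_mm for r in roots],
            "diameter_mm": [r.diameter_mm for r in roots],
            "E_MPa": [r.e_mpa for r in roots],
        }
    ).to_csv(path, index=False)


def read_record(path, label: str = "") -> ShearTestRecord:
    df = pd.read_csv(path)
    for col in ("u_mm", "S_kpa"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return ShearTestRecord(
        df["u_mm"].to_numpy(float), df["S_kpa"].to_numpy(float), label=label
    )


def write_record(path, record: ShearTestRecord) -> None:
    record.to_frame().to_csv(path, index=False)


def read_specimen_config(path) -> dict:
    with open(path) as f:
        cfg = json.load(f)
    required = ["phi_deg", "tau_prime_kpa", "Z_min_mm", "Z_max_mm", "D_tube_mm"]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ValueError(f"{path}: missing key(s) {missing}")
    return cfg


def load_specimen(
    config_path, roots_path=None, label: str = "", baseline_dir=None
) -> Specimen:
    """Assemble a specimen from a config JSON and an optional root CSV.

    ``baseline_csv`` in the config is resolved relative to ``baseline_dir``
    (default: the config file's directory).
    """
    cfg = read_specimen_config(config_path)
    roots = read_root_table(roots_path) if roots_path else []
    growth = None
    if "growth" in cfg and cfg["growth"]:
        g = cfg["growth"]
        growth = GrowthSchedule(
            u_step3_mm=float(g["u_step3_mm"]),
            u_final_mm=float(g["u_final_mm"]),
            f_step3=float(g.get("f_step3", 0.8)),
        )
    zone = ShearZoneModel(
        z_min_mm=float(cfg["Z_min_mm"]),
        z_max_mm=float(cfg["Z_max_mm"]),
        d_tube_mm=float(cfg["D_tube_mm"]),
        growth=growth,
    )
    baseline_u = baseline_s = None
    source = "unspecified"
    if cfg.get("baseline_csv"):
        base = Path(baseline_dir) if baseline_dir else Path(config_path).parent
        bpath = base / cfg["baseline_csv"]
        rec = read_record(bpath)
        baseline_u, baseline_s = rec.u_mm, rec.s_kpa
        source = f"csv:{cfg['baseline_csv']}"
    soil = SoilParams(
        phi_deg=float(cfg["phi_deg"]),
        baseline_u_mm=baseline_u,
        baseline_s_kpa=baseline_s,
        baseline_source=source,
    )
    spec = Specimen(
        roots=tuple(roots),
        soil=soil,
        interface=InterfaceParams(tau_prime_kpa=float(cfg["tau_prime_kpa"])),
        zone=zone,
        label=label or cfg.get("label", ""),
    )
    logger.info("loaded specimen %r: %d roots, RAR %.4f%%",
                spec.label, len(spec.roots), 100.0 * spec.rar)
    return spec


def write_map_csv(path, zmap: ShearZoneMap) -> None:
    zmap.to_frame().to_csv(path, index=False)


def read_map_csv(path, step_index: int = 0) -> ShearZoneMap:
    return ShearZoneMap.from_frame(pd.read_csv(path), step_index=step_index)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """End-to-end synthetic run: field -> maps -> Z_max -> model -> tau' fit.

    ``schedule`` names one of the study step schedules; the shear-zone
    geometry and root population are drawn from the synthetic generators at
    reduced resolution (``pitch_mm``/``extent_mm``) unless overridden.
    """

    out_dir: str
    seed: int = 0
    schedule: str = "Willow C"
    target_rar: float = presets.RAR_PERCENT["Willow C"] / 100.0
    pitch_mm: float = 1.5
    extent_mm: float = 42.0
    z_max_mm: float = presets.Z_MAX_MM
    tau_prime_true_kpa: float = presets.TAU_PRIME_FITTED_KPA
    phi_deg: float = presets.PHI_DEG
    e_mpa: float = presets.E_ROOT_MPA["willow"]
    noise_sigma_mm: float = presets.DVC_NOISE_MM
    stress_noise_kpa: float = 0.0
    baseline_s_ult_kpa: float = 4.0
    baseline_u_ref_mm: float = 2.0


def _config_hash(cfg: RunConfig) -> str:
    fields = asdict(cfg)
    fields.pop("out_dir")  # the science, not the destination, keys the run
    payload = json.dumps(fields, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic workflow and write its artifacts.

    Steps: generate a root map and displacement fields at the third and
    final load steps; fit thickness maps; take the estimated peak thickness
    as the model's Z_max; forward-model a stress record at the configured
    true tau'; back-fit tau' from that record; check the no-breakage /
    no-pull-out assumptions. Writes maps, curves and a JSON report into
    ``out_dir`` and returns the report dict. Idempotent for fixed config.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = presets.STEP_SCHEDULES_MM[cfg.schedule]
    u_final = schedule[-1]

    if cfg.target_rar > 0:
        roots = generate_root_map(
            RootMapConfig(target_rar=cfg.target_rar, e_mpa=cfg.e_mpa, seed=cfg.seed)
        )
    else:
        roots = []  # fallow configuration
    write_root_table(out / "roots.csv", roots)

    bumps = tuple()
    fcfg = FieldGenConfig(
        extent_mm=cfg.extent_mm,
        pitch_mm=cfg.pitch_mm,
        z_max_mm=cfg.z_max_mm,
        bumps=bumps,
        schedule_mm=tuple(schedule),
        noise_sigma_mm=cfg.noise_sigma_mm,
        seed=cfg.seed,
    )
    settings3 = FitSettings(noise_sigma_mm=max(cfg.noise_sigma_mm * 3, 1e-12))
    settings7 = FitSettings(noise_sigma_mm=max(cfg.noise_sigma_mm * 7, 1e-12))
    map3 = thickness_map(generate_field(fcfg, 3), settings3)
    map7 = thickness_map(generate_field(fcfg, 7), settings7)
    write_map_csv(out / "map_step3.csv", map3)
    write_map_csv(out / "map_step7.csv", map7)
    z_max_est = float(np.nanmax(map7.thickness_mm)) if map7.n_ok else float("nan")

    growth = GrowthSchedule(u_step3_mm=schedule[2], u_final_mm=u_final)
    zone = ShearZoneModel(
        z_min_mm=presets.Z_GAP_MM,
        z_max_mm=z_max_est if np.isfinite(z_max_est) else cfg.z_max_mm,
        d_tube_mm=presets.D_TUBE_MM,
        growth=growth,
    )
    base_u, base_s = _hyperbolic(cfg, u_final)
    soil = SoilParams(
        phi_deg=cfg.phi_deg,
        baseline_u_mm=base_u,
        baseline_s_kpa=base_s,
        baseline_source="fitted hyperbolic",
    )
    spec = Specimen(
        roots=tuple(roots),
        soil=soil,
        interface=InterfaceParams(tau_prime_kpa=cfg.tau_prime_true_kpa),
        zone=zone,
        label=cfg.schedule,
    )

    u_grid = np.concatenate([[0.0], np.asarray(schedule)])
    record = generate_stress_record(
        spec, u_grid, noise_sigma_kpa=cfg.stress_noise_kpa, seed=cfg.seed + 1
    )
    write_record(out / "record.csv", record)
    pred = predict_stress_curve(spec, u_grid)
    pred.to_frame().to_csv(out / "prediction.csv", index=False)
    pred.diagnostics.to_csv(out / "diagnostics.csv", index=False)

    if spec.roots:
        fit = fit_tau_prime(record, spec)
        tau_fit = fit.tau_prime_kpa
        fit_block = {
            "tau_prime_kpa": tau_fit,
            "residual_kpa": fit.residual_kpa,
            "target": fit.target,
            "u_target_mm": fit.u_target_mm,
        }
    else:
        fit_block = {"tau_prime_kpa": None, "note": "fallow: tau' unidentifiable"}

    report_check = assumption_check(spec, u_final)
    ds_final = float(pred.delta_s_kpa[-1])
    report = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "schedule": cfg.schedule,
        "n_roots": len(roots),
        "rar_percent": 100.0 * spec.rar,
        "zone_map": {
            "z_max_estimated_mm": z_max_est,
            "columns_ok_step3": map3.n_ok,
            "columns_ok_step7": map7.n_ok,
        },
        "model": {
            "tau_prime_true_kpa": cfg.tau_prime_true_kpa,
            "delta_s_final_kpa": ds_final,
            "total_final_kpa": float(pred.record.s_kpa[-1]),
        },
        "fit": fit_block,
        "assumptions": {
            "no_breakage": report_check.no_breakage,
            "no_pullout": report_check.no_pullout,
            "max_sigma_axial_mpa": float(
                report_check.table["sigma_axial_MPa"].max()
            ) if len(report_check.table) else 0.0,
            "max_stressed_length_mm": float(
                report_check.table["l_mm"].max()
            ) if len(report_check.table) else 0.0,
        },
    }
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    return report


def _hyperbolic(cfg: RunConfig, u_final: float):
    from .model import hyperbolic_baseline

    return hyperbolic_baseline(
        cfg.baseline_s_ult_kpa, cfg.baseline_u_ref_mm, u_final * 1.05
    )
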