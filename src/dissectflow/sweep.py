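"""Orchestration of the multi-case re-entry-location experiment.

Runs every configured case at the configured resolution, applies the full
post-processing chain, and emits tidy comparison tables plus a plain-text
trend report.  The whole pipeline is deterministic: identical configs give
bit-identical outputs, and the report is keyed by the config hash.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import (build_bc, build_case_geometry, build_fluid,
                     build_numerics, config_hash, load_config)
from .geometry import case_spec
from .post import (RecirculationMetric, peak_velocity_location,
                   recirculation_extent, regional_summary, tear_flux,
                   wall_shear_stress)
from .solver import Diagnostics, simulate

__all__ = ["CaseResult", "SweepResult", "run_sweep", "compare_cases",
           "trend_label", "render_report"]

log = logging.getLogger(__name__)

PHASE_NAMES = ("systole", "diastole")


@dataclass
class CaseResult:
    case_id: int
    re_entry_distance: Optional[float]
    diagnostics: Diagnostics
    summaries: pd.DataFrame                 # 12 rows x n_phases
    recirculation: list[RecirculationMetric]
    tear_fluxes: pd.DataFrame               # phase x (entry, re_entry) m^2/s
    peak_velocity: pd.DataFrame             # phase, speed, region, label


@dataclass
class SweepResult:
    cases: dict[int, CaseResult]
    config: dict
    config_hash: str
    failures: dict[int, str] = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    @property
    def summaries(self) -> pd.DataFrame:
        if not self.cases:
            return pd.DataFrame()
        return pd.concat([c.summaries for c in self.cases.values()],
                         ignore_index=True)


def _case_cache_path(out_dir: Path, cid: int, chash: str) -> Path:
    return out_dir / "cases" / f"case{cid}_{chash}.json"


def _save_case(path: Path, c: CaseResult) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "case_id": c.case_id,
        "re_entry_distance": c.re_entry_distance,
        "diagnostics": c.diagnostics.__dict__,
        "summaries": c.summaries.to_json(orient="split"),
        "recirculation": [m.__dict__ for m in c.recirculation],
        "tear_fluxes": c.tear_fluxes.to_json(orient="split"),
        "peak_velocity": c.peak_velocity.to_json(orient="split"),
    }
    path.write_text(json.dumps(payload))


def _load_case(path: Path) -> CaseResult:
    import io as _io

    d = json.loads(path.read_text())
    return CaseResult(
        case_id=d["case_id"],
        re_entry_distance=d["re_entry_distance"],
        diagnostics=Diagnostics(**d["diagnostics"]),
        summaries=pd.read_json(_io.StringIO(d["summaries"]), orient="split"),
        recirculation=[RecirculationMetric(**m) for m in d["recirculation"]],
        tear_fluxes=pd.read_json(_io.StringIO(d["tear_fluxes"]),
                                 orient="split"),
        peak_velocity=pd.read_json(_io.StringIO(d["peak_velocity"]),
                                   orient="split"),
    )


def run_sweep(config: Optional[dict] = None,
              out_dir: Optional[str | Path] = None,
              case_ids: Optional[list[int]] = None,
              resume: bool = False) -> SweepResult:
    """Simulate every configured case and post-process both phase snapshots.

    Per-case failures are recorded and skipped; the sweep raises only when
    every case fails.  With ``out_dir`` the tidy CSV tables, the trend
    report and a JSON run manifest are written there, plus a per-case store
    keyed by the config hash from which ``resume=True`` reloads completed
    cases instead of re-simulating them.
    """
    cfg = config if config is not None else load_config()
    chash = config_hash(cfg)
    if case_ids is None:
        case_ids = list(cfg.get("cases", range(1, 12)))
    fluid = build_fluid(cfg)
    bc = build_bc(cfg)
    numerics = build_numerics(cfg)
    ncfg = cfg.get("numerics", {})
    spacing = ncfg.get("spacing_mm", 1.0)
    n_cycles = ncfg.get("n_cycles", 4)
    phases = tuple(ncfg.get("snapshot_phases_s", (0.25, 0.47)))
    post_cfg = cfg.get("post", {})
    thr = post_cfg.get("recirculation_threshold", 0.01)
    ref = post_cfg.get("reference_speed", 1.0)

    cases: dict[int, CaseResult] = {}
    failures: dict[int, str] = {}
    for cid in case_ids:
        t0 = time.perf_counter()
        if resume and out_dir is not None:
            cache = _case_cache_path(Path(out_dir), cid, chash)
            if cache.exists():
                cases[cid] = _load_case(cache)
                log.info("case %d reloaded from %s", cid, cache)
                continue
        try:
            geom = build_case_geometry(cfg, cid)
            res = simulate(geom, spacing, bc, fluid, n_cycles=n_cycles,
                           snapshot_phases=phases, numerics=numerics,
                           case_id=cid)
            summaries, recirc, flux_rows, peak_rows = [], [], [], []
            for snap, pname in zip(res.snapshots, PHASE_NAMES):
                wss = wall_shear_stress(snap, res.grid, fluid, geom)
                summaries.append(regional_summary(
                    snap, res.grid, geom, pname, fluid, wss=wss, case_id=cid))
                recirc.append(recirculation_extent(
                    snap, res.grid, geom, pname, threshold=thr,
                    reference_speed=ref, case_id=cid))
                fluxes = {"case_id": cid, "phase": pname,
                          "entry_flux_m2s": tear_flux(snap, res.grid, geom,
                                                      "entry")}
                fluxes["re_entry_flux_m2s"] = (
                    tear_flux(snap, res.grid, geom, "re_entry")
                    if geom.re_entry is not None else np.nan)
                flux_rows.append(fluxes)
                speed, region, label = peak_velocity_location(snap, res.grid,
                                                              geom)
                peak_rows.append({"case_id": cid, "phase": pname,
                                  "peak_speed_ms": speed, "region": region,
                                  "location": label})
            cases[cid] = CaseResult(
                case_id=cid,
                re_entry_distance=case_spec(cid).re_entry_distance,
                diagnostics=res.diagnostics,
                summaries=pd.concat(summaries, ignore_index=True),
                recirculation=recirc,
                tear_fluxes=pd.DataFrame(flux_rows),
                peak_velocity=pd.DataFrame(peak_rows),
            )
            log.info("case %d done in %.1f s (%d steps)", cid,
                     time.perf_counter() - t0, res.diagnostics.n_steps)
            if out_dir is not None:
                _save_case(_case_cache_path(Path(out_dir), cid, chash),
                           cases[cid])
        except Exception as exc:
            failures[cid] = str(exc)
            log.error("case %d failed: %s", cid, exc)
    if not cases:
        raise RuntimeError(f"all cases failed: {failures}")

    result = SweepResult(cases, cfg, chash, failures,
                         provenance={"dissectflow_version": __version__,
                                     "timestamp": time.strftime(
                                         "%Y-%m-%dT%H:%M:%S")})
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SweepResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.summaries.to_csv(out / "regional_summaries.csv", index=False)
    pd.concat([c.tear_fluxes for c in result.cases.values()],
              ignore_index=True).to_csv(out / "tear_fluxes.csv", index=False)
    pd.DataFrame([m.__dict__ for c in result.cases.values()
                  for m in c.recirculation]).to_csv(
        out / "recirculation.csv", index=False)
    pd.concat([c.peak_velocity for c in result.cases.values()],
              ignore_index=True).to_csv(out / "peak_velocity.csv", index=False)
    blocks = compare_cases(result)
    (out / "trend_report.txt").write_text(render_report(blocks))
    for name in ("pressure_gaps", "fl_minus_case1", "recirculation_trend",
                 "tear_flux_signs"):
        df = blocks.get(name)
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "config_hash": result.config_hash,
        "cases": sorted(result.cases),
        "failures": result.failures,
        **result.provenance,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def trend_label(values) -> str:
    """Monotonicity annotation for a numeric series."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size < 2:
        return "insufficient data"
    d = np.diff(v)
    if np.all(d == 0):
        return "constant"
    if np.all(d <= 0):
        return "decreasing"
    if np.all(d >= 0):
        return "increasing"
    return "non-monotonic"


def compare_cases(result: SweepResult) -> dict:
    """Trend report blocks across completed cases (descriptive annotations,
    not assertions):

    a. systolic true-lumen region-1 minus region-6 pressure gap per case;
    b. per-region systolic false-lumen pressure/WSS of each re-entry case
       minus the entry-only baseline;
    c. recirculation extent versus re-entry distance;
    d. tear-flux signs per phase.
    """
    if len(result.cases) < 1:
        raise ValueError("need at least one completed case")
    ordered = [result.cases[cid] for cid in sorted(result.cases)]

    def sys_rows(c: CaseResult) -> pd.DataFrame:
        return c.summaries[c.summaries.phase == "systole"]

    gap_rows = []
    for c in ordered:
        s = sys_rows(c)
        tl = s[s.lumen == "true"].set_index("region").pressure_median_kpa
        gap_rows.append({
            "case_id": c.case_id,
            "re_entry_distance_mm": c.re_entry_distance,
            "tl_region1_minus_region6_kpa": float(
                tl.get(1, np.nan) - tl.get(tl.index.max(), np.nan)),
        })
    gaps = pd.DataFrame(gap_rows)

    base = next((c for c in ordered if c.case_id == 1), None)
    fl_rows = []
    if base is not None:
        b = sys_rows(base)
        b_fl = b[b.lumen == "false"].set_index("region")
        for c in ordered:
            if c.case_id == 1:
                continue
            s = sys_rows(c)
            fl = s[s.lumen == "false"].set_index("region")
            for r in fl.index:
                fl_rows.append({
                    "case_id": c.case_id,
                    "region": r,
                    "fl_pressure_minus_case1_kpa": float(
                        fl.pressure_median_kpa[r]
                        - b_fl.pressure_median_kpa[r]),
                    "fl_wss_median_minus_case1_pa": float(
                        fl.wss_median_pa[r] - b_fl.wss_median_pa[r]),
                })
    fl_cmp = pd.DataFrame(fl_rows)

    rec_rows = []
    for c in ordered:
        for m in c.recirculation:
            if m.phase != "systole":
                continue
            rec_rows.append({
                "case_id": c.case_id,
                "re_entry_distance_mm": c.re_entry_distance,
                "area_fraction_reversed": m.area_fraction_reversed,
                "reversed_area_mm2": m.reversed_area_mm2,
                "reversed_area_sign_mm2": m.reversed_area_sign_mm2,
                "zone_area_mm2": m.zone_area_mm2,
            })
    rec = pd.DataFrame(rec_rows)

    flux = pd.concat([c.tear_fluxes for c in ordered], ignore_index=True)
    flux["re_entry_direction"] = np.select(
        [flux.re_entry_flux_m2s > 0, flux.re_entry_flux_m2s < 0],
        ["FL->TL", "TL->FL"], default="n/a")

    re_cases = rec[rec.case_id != 1]
    annotations = {
        "pressure_gap_trend": trend_label(
            gaps[gaps.case_id != 1].tl_region1_minus_region6_kpa),
        "recirculation_area_trend_with_distance": trend_label(
            re_cases.sort_values("re_entry_distance_mm")
            .reversed_area_sign_mm2),
    }
    return {
        "pressure_gaps": gaps,
        "fl_minus_case1": fl_cmp,
        "recirculation_trend": rec,
        "tear_flux_signs": flux,
        "annotations": annotations,
        "config_hash": result.config_hash,
    }


def render_report(blocks: dict) -> str:
    lines = [
        "dissectflow trend report",
        f"config hash: {blocks['config_hash']}",
        "",
        "[a] systolic TL region-1 minus region-6 pressure gap (kPa)",
        blocks["pressure_gaps"].to_string(index=False),
        "",
        "[b] systolic FL pressure / WSS minus entry-only baseline",
        (blocks["fl_minus_case1"].to_string(index=False)
         if len(blocks["fl_minus_case1"]) else "  (no re-entry cases)"),
        "",
        "[c] recirculation below the re-entry tear (systole)",
        blocks["recirculation_trend"].to_string(index=False),
        "",
        "[d] tear flux directions (positive = FL->TL)",
        blocks["tear_flux_signs"].to_string(index=False),
        "",
        "annotations (descriptive, not assertions):",
    ]
    lines += [f"  {k}: {v}" for k, v in blocks["annotations"].items()]
    return "\n".join(lines) + "\n"
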