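"""End-to-end campaign orchestration.

Stages run in order — enumerate, track, tsa, ic50 — over synthetic inputs
generated from the config's scenario section, and the results are folded
into a single machine-readable campaign report.  A stage error
short-circuits the remaining stages; the partial report records the failed
stage.  All stage outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

from . import chem, doseresponse, synthesis, simulate, tsa

log = logging.getLogger("clickscreen.pipeline")

__all__ = ["run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "library": {
        "label": "4",
        "n_azide": 3,
        "n_alkyne": 2,
        "n_acid": 3,
        "sulfonamide_carrier": "alkyne",
    },
    "synthesis": {"ssr_true": 75.0, "yield_mean": 56.0, "yield_sd": 15.0},
    "tsa": {
        "k": 3.0,
        "floor": 0.5,
        "rsd_constant": 1.4826,
        "method": "boltzmann",
        "shifters": [[5, 3.0], [10, -2.0]],
        "n_null": 85,
        "null_sd": 0.15,
        "noise_pct": 2.0,
    },
    "dose": {
        "top_uM": 200.0,
        "factor": 3.0,
        "points": 10,
        "n_replicates": 4,
        "noise_pct": 5.0,
        "planted_ic50s": [0.2, 1.1, 6.07, 8.74],
        "planted_hill": 1.0,
    },
}


def load_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def _stage_enumerate(cfg: dict[str, Any], report: dict[str, Any], out_dir: Path | None):
    lib = cfg["library"]
    spec = simulate.ScenarioSpec(
        seed=cfg["seed"],
        n_azide=lib["n_azide"],
        n_alkyne=lib["n_alkyne"],
        n_acid=lib["n_acid"],
        sulfonamide_carrier=lib.get("sulfonamide_carrier", "alkyne"),
    )
    azides, alkynes, acids = simulate.gen_building_blocks(spec)
    design = chem.LibraryDesign(
        library_label=lib.get("label", "4"),
        azides=azides,
        alkynes=alkynes,
        acids=acids,
        sulfonamide_carrier=spec.sulfonamide_carrier,
    )
    failures: list[chem.FailedMember] = []
    members = list(chem.enumerate_library(design, failures=failures))
    theo = chem.count_theoretical(design)
    log.info(
        "enumerate: sizes=(%d,%d,%d) theoretical=%d members=%d failed=%d",
        len(azides), len(alkynes), len(acids), theo, len(members), len(failures),
    )
    report["library"] = {
        "label": design.library_label,
        "set_sizes": [len(azides), len(alkynes), len(acids)],
        "theoretical_space": theo,
        "enumerated_members": len(members),
        "failed_triples": len(failures),
        "duplicate_products": sum(m.duplicate_of is not None for m in members),
    }
    if out_dir is not None:
        chem.write_members_csv(members, out_dir / "members.csv")
        chem.write_members_sdf(members, out_dir / "members.sdf")
    return spec, members, theo


def _stage_track(cfg, report, spec, members, theo, out_dir):
    syn = cfg["synthesis"]
    spec2 = simulate.ScenarioSpec(
        seed=cfg["seed"],
        ssr_true=syn["ssr_true"],
        yield_mean=syn["yield_mean"],
        yield_sd=syn["yield_sd"],
    )
    outcomes = simulate.gen_outcomes(spec2, [m.member_id for m in members])
    lib_report = synthesis.build_report(report["library"]["label"], outcomes, theo)
    log.info(
        "track: planned=%d isolated=%d ssr=%d%%",
        lib_report.planned_count, lib_report.isolated_count, lib_report.ssr_percent,
    )
    report["synthesis"] = json.loads(lib_report.to_json())
    if out_dir is not None:
        synthesis.write_outcomes_csv(outcomes, out_dir / "outcomes.csv")
    return outcomes


def _stage_tsa(cfg, report, out_dir):
    t = cfg["tsa"]
    spec = simulate.ScenarioSpec(
        seed=cfg["seed"],
        shifters=tuple((int(n), float(s)) for n, s in t["shifters"]),
        n_null=int(t["n_null"]),
        null_sd=float(t["null_sd"]),
        melt_noise_pct=float(t.get("noise_pct", 2.0)),
    )
    plate, truth = simulate.gen_melt_plate(spec)
    table = tsa.analyze_plate(
        tsa.curves_from_frame(plate),
        method=t.get("method", "boltzmann"),
        k=float(t["k"]),
        floor=float(t["floor"]),
        c=float(t.get("rsd_constant", 1.4826)),
    )
    pos, neg = table.hit_ids("positive"), table.hit_ids("negative")
    log.info(
        "tsa: plate=%s med=%.3f rsd=%.3f threshold=%.3f hits=%d (+%d/-%d)",
        table.plate_id, table.med, table.rsd, table.threshold,
        len(pos) + len(neg), len(pos), len(neg),
    )
    report["tsa"] = {
        "plate": table.plate_id,
        "med_C": table.med,
        "rsd_C": table.rsd,
        "threshold_C": table.threshold,
        "k": table.k,
        "floor_C": table.floor,
        "n_hits": len(pos) + len(neg),
        "positive_hits": pos,
        "negative_hits": neg,
        "excluded_wells": table.excluded,
        "planted_truth": {cid: s for cid, s in truth.items() if s != 0.0},
    }
    if out_dir is not None:
        tsa.shift_table_frame(table).to_csv(out_dir / "shift_table.csv", index=False)
    return pos + neg


def _stage_ic50(cfg, report, hits, out_dir):
    d = cfg["dose"]
    planted = list(d["planted_ic50s"])
    fits = []
    for idx, cid in enumerate(hits):
        potent = idx < len(planted)
        spec = simulate.ScenarioSpec(
            seed=cfg["seed"] + idx + 1,
            ic50_uM=planted[idx] if potent else 1.0,
            hill=float(d.get("planted_hill", 1.0)),
            top_pct=100.0 if potent else 0.0,
            bottom_pct=0.0,
            dose_noise_pct=float(d["noise_pct"]),
            n_replicates=int(d["n_replicates"]),
            dilution_top_uM=float(d["top_uM"]),
            dilution_factor=float(d["factor"]),
            dilution_points=int(d["points"]),
        )
        traces_df, truth = simulate.gen_dose_kinetics(spec, compound_id=cid)
        traces = [
            doseresponse.KineticTrace(
                well=w["well"].iloc[0],
                compound_id=w["compound_id"].iloc[0],
                concentration_uM=float(w["concentration_uM"].iloc[0]),
                times=w["time_s"].to_numpy(),
                absorbance=w["absorbance"].to_numpy(),
                role=w["role"].iloc[0],
            )
            for _, w in traces_df.groupby("well", sort=False)
        ]
        dr = doseresponse.reduce_traces(traces)[cid]
        fit = doseresponse.fit_ic50(dr)
        log.info("ic50: %s %s", cid, fit.report_potency(spec.dilution_top_uM))
        fits.append(
            {
                "compound_id": cid,
                "converged": fit.converged,
                "ic50_uM": fit.ic50_uM if fit.converged else None,
                "hill": fit.hill if fit.converged else None,
                "potency": fit.report_potency(spec.dilution_top_uM),
                "planted_ic50_uM": truth["ic50_uM"] if potent else None,
            }
        )
    confirmed = [f for f in fits if f["converged"]]
    report["ic50"] = {
        "n_tested": len(fits),
        "n_confirmed": len(confirmed),
        "fits": fits,
    }
    if out_dir is not None:
        (out_dir / "ic50_fits.json").write_text(json.dumps(fits, indent=2))


def run_pipeline(
    config: dict[str, Any], out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run every stage over the synthetic campaign described by *config*.

    Returns the campaign report dict (also written to ``report.json`` when
    *out_dir* is given).  Rerunning with the same config yields an
    identical report.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config, "stages_completed": []}
    try:
        spec, members, theo = _stage_enumerate(config, report, out_dir)
        report["stages_completed"].append("enumerate")
        if members:
            _stage_track(config, report, spec, members, theo, out_dir)
            report["stages_completed"].append("track")
        else:
            report["skipped"] = "no members enumerated; downstream stages skipped"
            return _finish(report, out_dir)
        hits = _stage_tsa(config, report, out_dir)
        report["stages_completed"].append("tsa")
        _stage_ic50(config, report, hits, out_dir)
        report["stages_completed"].append("ic50")
    except Exception as exc:  # short-circuit with a partial report
        report["failed_stage"] = {
            "after": report["stages_completed"][-1] if report["stages_completed"] else None,
            "error": f"{type(exc).__name__}: {exc}",
        }
        log.error("pipeline aborted: %s", exc)
    return _finish(report, out_dir)


def _finish(report, out_dir):
    if out_dir is not None:
        (Path(out_dir) / "report.json").write_text(json.dumps(report, indent=2))
    return report
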