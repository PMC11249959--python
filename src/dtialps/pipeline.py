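"""End-to-end orchestration: simulate -> alps -> stats.

Each stage is deterministic for a fixed configuration and seed, writes
its outputs under the configured directory, and records them in a run
manifest (config hash, per-stage seeds, file inventory with content
hashes, QC exclusion summary).  The manifest is written even when a
stage fails part-way.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .alps import compute_alps
from .cohort import make_cohort, make_longitudinal, nc_reference
from .config import PipelineConfig
from .phantom import make_phantom
from .rois import ROISet
from .stats import (MUTATION_STAGE_FAMILY, STAGE_FAMILY, add_stage4,
                    adjusted_group_comparison, association_model,
                    describe_cohort, lmm_progression, stratify_alps)

log = logging.getLogger("dtialps")

EXIT_OK = 0
EXIT_FATAL = 1
EXIT_PARTIAL = 2


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    qc_summary: dict = field(default_factory=dict)
    status: str = "running"

    def record(self, path: Path) -> None:
        self.outputs[path.name] = _hash_file(path)

    def write(self, out_dir: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "outputs": dict(sorted(self.outputs.items())),
            "qc_summary": self.qc_summary,
            "status": self.status,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _manifest(config: PipelineConfig) -> RunManifest:
    return RunManifest(
        config_hash=_config_hash(config),
        seeds={s: config.stage_seed(s)
               for s in ("phantom", "cohort", "longitudinal", "dwi")},
    )


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.record(path)


def _write_json(obj, path: Path, manifest: RunManifest) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
    manifest.record(path)


def cmd_simulate(config: PipelineConfig) -> int:
    """Generate phantom NIfTI volumes, ground-truth sidecars and cohort tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    try:
        base_seed = config.stage_seed("phantom")
        rois = config.roi_set()
        for i in range(config.phantom.n_subjects):
            spec = config.phantom_spec(seed=(base_seed + i) % (2 ** 31))
            tensor, fa, gt, default_rois = make_phantom(spec)
            if rois is None:
                rois = default_rois
            stem = out / f"phantom_{i:03d}"
            dio.write_tensor(tensor, f"{stem}_tensor.nii.gz")
            dio.write_scalar(fa, f"{stem}_fa.nii.gz")
            with open(f"{stem}_truth.json", "w") as fh:
                json.dump({"ground_truth": gt, "seed": spec.seed,
                           "rois": default_rois.to_dict()}, fh, indent=2, sort_keys=True)
            for suffix in ("_tensor.nii.gz", "_fa.nii.gz", "_truth.json"):
                manifest.record(Path(f"{stem}{suffix}"))
        _write_json({"rois": rois.to_dict()}, out / "rois.json", manifest)

        cohort = make_cohort(config.cohort_spec())
        _write_csv(cohort, out / "cohort.csv", manifest)
        visits = make_longitudinal(cohort, config.longitudinal_spec())
        _write_csv(visits, out / "visits.csv", manifest)
        log.info("simulated %d phantoms, %d subjects, %d visits",
                 config.phantom.n_subjects, len(cohort), len(visits))
        manifest.status = "ok"
        return EXIT_OK
    except Exception:
        manifest.status = "failed"
        raise
    finally:
        manifest.write(out)


def cmd_alps(tensor_paths, config: PipelineConfig,
             rois: ROISet | None = None) -> int:
    """Compute per-subject ALPS indices from tensor volumes.

    Writes one CSV row per subject plus a QC JSON; unreadable or
    failing subjects are recorded and the run continues (exit code 2).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    if rois is None:
        rois = config.roi_set()
    rois_file = out / "rois.json"
    if rois is None and rois_file.exists():
        with open(rois_file) as fh:
            rois = ROISet.from_dict(json.load(fh)["rois"])
    if rois is None:
        manifest.status = "failed"
        manifest.write(out)
        raise ValueError("no ROI definition: provide a 'rois' config block")

    thresholds = config.qc_thresholds()
    rows, qc_all, failures = [], {}, []
    for path in tensor_paths:
        subject = Path(path).name.replace("_tensor.nii.gz", "").replace(".nii.gz", "").replace(".nii", "")
        try:
            tensor = dio.read_tensor(path)
            result = compute_alps(tensor, rois, thresholds)
            rows.append({
                "subject": subject,
                "alps_left": result.alps_left,
                "alps_right": result.alps_right,
                "alps_mean": result.alps_mean,
                "qc_pass": result.qc.passed,
                "qc_reasons": "; ".join(result.qc.reasons),
            })
            qc_all[subject] = result.qc.to_dict()
        except Exception as exc:
            log.warning("subject %s failed: %s", subject, exc)
            failures.append({"subject": subject, "error": str(exc)})
    _write_csv(pd.DataFrame(rows), out / "alps.csv", manifest)
    n_fail = sum(1 for s in qc_all.values() if not s["passed"])
    manifest.qc_summary = {
        "n_subjects": len(rows) + len(failures),
        "n_qc_fail": n_fail,
        "n_unreadable": len(failures),
        "failures": failures,
        "excluded": [s for s, r in qc_all.items() if not r["passed"]],
    }
    _write_json(qc_all, out / "alps_qc.json", manifest)
    manifest.status = "ok" if not failures else "partial"
    manifest.write(out)
    return EXIT_OK if not failures else EXIT_PARTIAL


def run_stats(cohort: pd.DataFrame, visits: pd.DataFrame | None,
              config: PipelineConfig) -> dict:
    """The study's statistics battery on a cohort (+ optional visits) table."""
    analysis = config.analysis
    covars = list(analysis.covariates)
    report: dict = {}

    staged = add_stage4(cohort)
    desc = describe_cohort(
        staged, "stage4",
        variables=["age", "sex", "education", "cdr_ftld", "nfl", "gfap",
                   "alps_mean", "alps_left", "alps_right"])
    report["descriptives"] = desc.to_dict(orient="records")

    report["comparison_stage"] = adjusted_group_comparison(
        staged, "alps_mean", "stage4", covars, family=STAGE_FAMILY).to_dict()
    report["comparison_mutation_stage"] = adjusted_group_comparison(
        staged, "alps_mean", "group", covars,
        family=MUTATION_STAGE_FAMILY).to_dict()

    carriers = cohort[cohort["mutation"] != "NC"]
    presym = carriers[carriers["stage"] == "presymptomatic"]
    report["associations"] = {
        "cdr_ftld": association_model(
            carriers, "cdr_ftld_latent", "alps_mean", covars).to_dict(),
        "years_to_onset": association_model(
            presym, "years_to_onset", "alps_mean", covars).to_dict(),
        "nfl": association_model(
            carriers, "nfl", "alps_mean", list(analysis.plasma_covariates),
            log_transform_y=True).to_dict(),
        "gfap": association_model(
            carriers, "gfap", "alps_mean", list(analysis.plasma_covariates),
            log_transform_y=True).to_dict(),
    }

    if visits is not None and len(visits):
        nc_mean, nc_sd = nc_reference(cohort)
        if "stratum" not in visits.columns:
            strat = pd.Series(
                stratify_alps(cohort["alps_mean"].to_numpy(), nc_mean, nc_sd),
                index=cohort.index)
            visits = visits.merge(
                cohort[["id"]].assign(stratum=strat), on="id", how="left")
        report["longitudinal"] = lmm_progression(
            visits, cohort, covariates=covars).to_dict()
        report["strata_reference"] = {"nc_mean": nc_mean, "nc_sd": nc_sd}
    else:
        log.warning("no visits provided; longitudinal section skipped")
        report["longitudinal"] = None
    return report


def cmd_stats(cohort_csv, visits_csv, config: PipelineConfig) -> int:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    try:
        cohort = pd.read_csv(cohort_csv)
        missing = {"id", "mutation", "stage", "alps_mean"} - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
        visits = None
        if visits_csv is not None and Path(visits_csv).exists():
            visits = pd.read_csv(visits_csv)
            if len(visits):
                vmissing = {"id", "time"} - set(visits.columns)
                if vmissing:
                    raise ValueError(f"visits table is missing columns: {sorted(vmissing)}")
        report = run_stats(cohort, visits, config)
        _write_json(report, out / "stats_report.json", manifest)
        _write_human_tables(report, out, manifest)
        manifest.status = "ok"
        return EXIT_OK
    except Exception:
        manifest.status = "failed"
        raise
    finally:
        manifest.write(out)


def _write_human_tables(report: dict, out: Path, manifest: RunManifest) -> None:
    lines = ["# Cohort statistics report", ""]
    for key in ("comparison_stage", "comparison_mutation_stage"):
        block = report[key]
        lines.append(f"## {key} (outcome {block['outcome']})")
        for g, e in block["emms"].items():
            lines.append(f"  {g}: EMM {e['emm']:.3f} +/- {e['se']:.3f} (n={e['n']})")
        for c in block["contrasts"]:
            tag = "*" if c["significant"] else " "
            lines.append(f"  {c['a']} vs {c['b']}: diff {c['estimate']:+.3f}, "
                         f"p={c['p_raw']:.4f}, p_fdr={c['p_fdr']:.4f} {tag}")
        lines.append("")
    lines.append("## associations (beta on ALPS)")
    for name, a in report["associations"].items():
        lines.append(f"  {name}: beta={a['beta']:+.3f} (se {a['se']:.3f}), "
                     f"p={a['p']:.4f}, n={a['n']}")
    if report.get("longitudinal"):
        lines.append("")
        lines.append("## longitudinal progression (CDR-FTLD/year by baseline ALPS stratum)")
        for s, d in report["longitudinal"]["stratum_slopes"].items():
            lines.append(f"  {s}: slope {d['slope']:+.3f} "
                         f"[{d['ci_low']:+.3f}, {d['ci_high']:+.3f}], p={d['p']:.4f}")
        for c in report["longitudinal"]["slope_contrasts"]:
            lines.append(f"  {c['a']} vs {c['b']}: diff {c['estimate']:+.3f}, p={c['p']:.4f}")
    path = out / "stats_report.txt"
    path.write_text("\n".join(lines) + "\n")
    manifest.record(path)


def run_all(config: PipelineConfig) -> int:
    """simulate -> alps (on the generated phantoms) -> stats."""
    code = cmd_simulate(config)
    out = Path(config.output_dir)
    tensors = sorted(out.glob("phantom_*_tensor.nii.gz"))
    code = max(code, cmd_alps([os.fspath(p) for p in tensors], config))
    code = max(code, cmd_stats(out / "cohort.csv", out / "visits.csv", config))
    return code
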