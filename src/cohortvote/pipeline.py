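"""End-to-end orchestration: simulate -> rank -> integrate -> calibrate ->
validate, as one configured, seeded, logged run.

A run directory contains per-cohort differential tables (``de/``), the ranked
signature (``signature.tsv``), the null calibration (``calibration.json``),
the clinical validation report (``validation.json``), the ground truth when
simulated (``truth.tsv``), a structured log, and the fully resolved
configuration (``resolved_config.yaml``) from which the run can be reproduced
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, integration, io, nulls, simulate, survival

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "summarize"]

STAGE_FILES = {
    "differential": "de",
    "integration": "signature.tsv",
    "calibration": "calibration.json",
    "validation": "validation.json",
    "config": "resolved_config.yaml",
}


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Defaults mirror the published procedure: ``top_n = 1000`` genes per
    cohort list and ``min_duplication = 5`` (strictly more than four cohorts).
    Either ``simulation`` or explicit cohort paths must be supplied.
    """

    simulation: simulate.SimulationConfig | None = None
    cohort_paths: list[dict] = field(default_factory=list)
    top_n: int = 1000
    min_duplication: int = 5
    fc_scope: str = "top"
    pseudocount: float = 0.0
    permutation_B: int = 0  # 0 disables the permutation null
    validation_marker_effect: float = 1.5
    validation_n: int = 400
    validation_endpoint: str = "OS"
    validation_cutoff: str | float = "median"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        config = cls(**raw)
        if sim is not None:
            config.simulation = simulate.SimulationConfig(**sim)
        return config

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
            for key in ("cases_per_cohort", "effect_fc_range",
                        "baseline_log2_range"):
                out["simulation"][key] = list(out["simulation"][key])
        return out


def _load_cohorts(config: PipelineConfig):
    if config.simulation is not None:
        return simulate.generate_multi_cohort(config.simulation)
    if not config.cohort_paths:
        raise ValueError("config needs a simulation block or cohort_paths")
    cohorts = []
    for entry in config.cohort_paths:
        matrix = io.read_expression_matrix(
            entry["matrix"], entry.get("scale_hint", "auto")
        )
        if "probe_map" in entry:
            matrix = io.collapse_probes(
                matrix, io.read_probe_map(entry["probe_map"])
            )
        ann = io.read_sample_annotation(entry["annotation"])
        cohorts.append(io.assemble_cohort(entry["cohort_id"], matrix, ann))
    return cohorts, None


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write all outputs under ``out_dir``.

    Returns the run directory.  Stage failures propagate with the stage name
    prefixed.  Re-running with an identical config produces byte-identical
    signature and calibration files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        logger.info(line)
        log_lines.append(line)

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # --- simulate / load ---------------------------------------------------
    cohorts, truth = run_stage("cohorts", lambda: _load_cohorts(config))
    log("cohorts", f"{len(cohorts)} cohorts, "
        f"sizes {[len(c.sample_ids) for c in cohorts]}")
    if truth is not None:
        simulate.write_truth(out / "truth.tsv", truth)

    # --- differential ------------------------------------------------------
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    fc_tables: dict[str, pd.DataFrame] = {}
    universes: dict[str, set] = {}
    top_lists: dict[str, set] = {}

    def differential_stage():
        for cohort in cohorts:
            fc = differential.median_fold_change(cohort, config.pseudocount)
            table = differential.select_top_n(fc, n=config.top_n)
            fc_tables[cohort.cohort_id] = table
            universes[cohort.cohort_id] = set(cohort.gene_ids)
            top_lists[cohort.cohort_id] = differential.top_n_set(table)
            table.reset_index().to_csv(
                de_dir / f"{cohort.cohort_id}.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n",
            )

    run_stage("differential", differential_stage)
    log("differential", f"top-{config.top_n} lists, sizes "
        f"{[len(top_lists[c.cohort_id]) for c in cohorts]}")

    # --- integration -------------------------------------------------------
    def integration_stage():
        dup = integration.count_duplication(top_lists, universes)
        return integration.build_signature(
            dup, fc_tables, min_duplication=config.min_duplication,
            fc_scope=config.fc_scope,
        )

    signature = run_stage("integration", integration_stage)
    log("integration", f"signature size {len(signature)} at "
        f"min_duplication={config.min_duplication}")

    # --- calibration -------------------------------------------------------
    def calibration_stage():
        sizes = {cid: len(u) for cid, u in universes.items()}
        uniform = len(set(sizes.values())) == 1
        universe_arg = next(iter(sizes.values())) if uniform else sizes
        sig = nulls.calibrate_signature(signature, config.top_n, universe_arg)
        report = {
            "top_n": config.top_n,
            "universe_sizes": dict(sorted(sizes.items())),
            "expected_signature_size_null": (
                nulls.expected_count(
                    len(cohorts), config.top_n, max(sizes.values()),
                    config.min_duplication,
                )
                if config.min_duplication <= len(cohorts)
                else 0.0  # threshold unreachable: no gene can pass by chance
            ),
            "signature_size": int(len(sig)),
        }
        if config.permutation_B > 0:
            perm = nulls.permutation_null(
                cohorts, top_n=config.top_n, B=config.permutation_B,
                seed=config.seed,
            )
            report["permutation"] = {
                "B": perm.B,
                "mean_counts_per_duplication": [
                    round(x, 6) for x in perm.mean_counts.tolist()
                ],
            }
        return sig, report

    signature, calib_report = run_stage("calibration", calibration_stage)
    io.write_signature(out / "signature.tsv", signature)
    (out / "calibration.json").write_text(
        json.dumps(calib_report, indent=2, sort_keys=True) + "\n"
    )

    # --- validation --------------------------------------------------------
    def validation_stage():
        sim = config.simulation or simulate.SimulationConfig()
        clinical = simulate.generate_clinical(
            sim, config.validation_marker_effect,
            seed=config.seed + 1, n_samples=config.validation_n,
            endpoint=config.validation_endpoint,
        )
        groups = survival.dichotomize(
            clinical["marker_expression"], config.validation_cutoff
        )
        high = clinical[groups == "high"]
        low = clinical[groups == "low"]
        lr = survival.logrank_test(
            (high["time"], high["event"]), (low["time"], low["event"])
        )
        jt_stat, jt_p = survival.ordinal_trend_test(
            clinical["marker_expression"], clinical["grade"], method="normal"
        )
        marker = truth.marker_gene if truth is not None else None
        return {
            "marker_gene": marker,
            "endpoint": clinical.attrs["endpoint"],
            "n_samples": int(len(clinical)),
            "group_sizes": {"high": int(len(high)), "low": int(len(low))},
            "logrank_statistic": lr.statistic,
            "logrank_p": lr.p_value,
            "trend_statistic": jt_stat,
            "trend_p": jt_p,
        }

    validation = run_stage("validation", validation_stage)
    (out / "validation.json").write_text(
        json.dumps(validation, indent=2, sort_keys=True) + "\n"
    )
    log("validation", f"log-rank p={validation['logrank_p']:.3g}, "
        f"trend p={validation['trend_p']:.3g}")

    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def summarize(run_dir: str | Path) -> str:
    """Render a completed run directory as a Markdown summary."""
    run = Path(run_dir)
    missing = [
        name for name in ("signature.tsv", "calibration.json",
                          "validation.json", "resolved_config.yaml")
        if not (run / name).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"incomplete run directory {run}: missing {missing}"
        )
    signature = io.read_signature(run / "signature.tsv")
    calib = json.loads((run / "calibration.json").read_text())
    validation = json.loads((run / "validation.json").read_text())

    lines = [
        "# cohortvote run summary",
        "",
        f"- signature size: {len(signature)}",
    ]
    if len(signature):
        top = signature.iloc[0]
        lines.append(
            f"- top gene: {top['gene']} "
            f"(duplication {top['duplication_times']}/"
            f"{top['cohorts_measured']}, "
            f"median FC {top['median_fold_change']:.3g})"
        )
    else:
        lines.append("- top gene: none (empty signature)")
    lines += [
        f"- expected signature size under the binomial null: "
        f"{calib['expected_signature_size_null']:.3g}",
        f"- validation ({validation['endpoint']}, n={validation['n_samples']}):"
        f" log-rank p = {validation['logrank_p']:.3g}, "
        f"trend p = {validation['trend_p']:.3g}",
    ]
    return "\n".join(lines) + "\n"
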