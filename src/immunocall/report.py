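"""Pipeline orchestration and report rendering.

:func:`run_pipeline` chains the stages — optional simulation, antigen
overexpression calling, response calling, synergy scoring — and writes
machine-readable outputs plus a run log stamping the configuration hash
and seed, so a run is reproducible byte for byte from its embedded
config. :func:`render_responder_table` turns a cohort summary into the standard
responder-proportion table (one ``n/denominator`` and percent per pool
plus an at-least-one column).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as iomod
from .expression import call_overexpression, compute_thresholds, transform_expression
from .response import (
    build_response_matrix,
    call_observations,
    response_matrix_frame,
    stratify_by_subtype,
    summarize_cohort,
)
from .synergy import score_synergy, summarize_synergy, synergy_frame
from .synthetic import (
    ExpressionSimConfig,
    FlowSimConfig,
    default_antigen_pools,
    default_gene_panel,
    gen_expression_cohort,
    gen_flow_cohort,
    write_fixture_bundle,
)
from .types import (
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_LOD,
    DEFAULT_SD_MULTIPLIER,
    CohortSummary,
)

log = logging.getLogger("immunocall")


def fmt_percent(value: float) -> str:
    """Mixed display style: one decimal below 20%, integer otherwise."""
    if math.isnan(value):
        return "N/A"
    if value < 20.0:
        return f"{value:.1f}%"
    return f"{value:.0f}%"


def render_responder_table(summary: CohortSummary) -> pd.DataFrame:
    """Responder-proportion table: per pool ``n/denominator`` and percent.

    Regenerable from the machine-readable cohort summary alone; the
    at-least-one column uses the full cohort denominator.
    """
    pools = list(summary.pool_tallies)
    cols = pools + ["At least one"]
    tallies = [summary.pool_tallies[p] for p in pools] + [summary.at_least_one]
    counts = [f"{n}/{d}" for n, d in tallies]
    percents = [fmt_percent(100.0 * n / d) if d else "N/A" for n, d in tallies]
    return pd.DataFrame([counts, percents], index=["responders", "percent"], columns=cols)


def summary_payload(summary: CohortSummary) -> dict[str, Any]:
    """JSON-serializable view of a cohort summary (full precision)."""
    return {
        "cohort_size": summary.cohort_size,
        "pool_tallies": {p: list(t) for p, t in summary.pool_tallies.items()},
        "pool_proportions": summary.pool_proportions,
        "at_least_one": list(summary.at_least_one),
        "at_least_one_proportion": summary.at_least_one_proportion,
        "mean_pools_per_patient": summary.mean_pools_per_patient,
        "breadth": {str(k): v for k, v in (summary.breadth or {}).items()},
        "control_tallies": {p: list(t) for p, t in summary.control_tallies.items()},
    }


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Collects the assay constants (0.01% LOD, 2-SD overexpression cutoff,
    2-fold synergy threshold), the seed, and the input/output locations.
    When ``simulate`` is true the input files are generated under the
    output directory before the calling stages run.
    """

    out_dir: str = "results/pipeline"
    lod: float = DEFAULT_LOD
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    seed: int = 0
    simulate: bool = True
    expr_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    flow_path: str | None = None
    cohort_path: str | None = None

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")
        if not self.simulate:
            needed = [self.expr_path, self.samples_path, self.genes_path, self.flow_path]
            if any(p is None for p in needed):
                raise ValueError("without simulation, expression and flow input paths are required")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> Path:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run simulate → overexpression → responses → synergy → report.

    Returns a manifest mapping output file names to sha256 digests. Every
    output carries full-precision values; display rounding happens only
    in the rendered table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d config=%s", config.seed, config.config_hash())

    if config.simulate:
        inputs = out / "inputs"
        expr_cfg = ExpressionSimConfig(genes=default_gene_panel(), seed=config.seed)
        cohort, _expr_truth = gen_expression_cohort(expr_cfg)
        write_fixture_bundle(cohort, _expr_truth, inputs)
        flow_cfg = FlowSimConfig(
            antigen_pools=default_antigen_pools(), include_ici=True, seed=config.seed + 1
        )
        observations, _flow_truth = gen_flow_cohort(flow_cfg)
        write_fixture_bundle(observations, _flow_truth, inputs)
        cohort_table = pd.DataFrame(
            {"histology": ["AC"] * len({o.patient_id for o in observations})},
            index=pd.Index(sorted({o.patient_id for o in observations}), name="patient_id"),
        )
        iomod.write_cohort_table(cohort_table, inputs / "cohort.tsv")
        expr_path = inputs / "expression.tsv"
        samples_path = inputs / "samples.tsv"
        genes_path = inputs / "genes.tsv"
        flow_path = inputs / "flow.csv"
        cohort_path = inputs / "cohort.tsv"
    else:
        expr_path = Path(config.expr_path)
        samples_path = Path(config.samples_path)
        genes_path = Path(config.genes_path)
        flow_path = Path(config.flow_path)
        cohort_path = Path(config.cohort_path) if config.cohort_path else None

    files: list[Path] = []

    # expression stage
    cohort = iomod.read_expression_bundle(expr_path, samples_path, genes_path)
    logm = transform_expression(cohort)
    thresholds = compute_thresholds(logm, cohort, config.sd_multiplier)
    summary = call_overexpression(logm, thresholds, cohort)
    p = out / "overexpression_summary.csv"
    summary.to_csv(p, index=False, lineterminator="\n")
    files.append(p)
    log.info("overexpression: %d gene x subtype calls", len(summary))

    # response stage
    observations = iomod.read_flow_csv(flow_path)
    cohort_table = iomod.read_cohort_table(cohort_path) if cohort_path else None
    calls = call_observations(observations, lod=config.lod, ici=False)
    matrix = build_response_matrix(calls, cohort_table)
    p = out / "response_matrix.csv"
    response_matrix_frame(matrix).to_csv(p, index=False, lineterminator="\n")
    files.append(p)
    cohort_summary = summarize_cohort(matrix)
    payload = summary_payload(cohort_summary)
    if cohort_table is not None and "histology" in matrix.metadata.columns:
        payload["by_subtype"] = {
            s: summary_payload(m) for s, m in stratify_by_subtype(matrix).items()
        }
    files.append(_write_json(out / "cohort_summary.json", payload))
    log.info(
        "responses: %d/%d patients with >=1 response, mean %.2f pools/patient",
        cohort_summary.at_least_one[0],
        cohort_summary.at_least_one[1],
        cohort_summary.mean_pools_per_patient,
    )

    # synergy stage
    syn_calls = score_synergy(observations, lod=config.lod, fold_threshold=config.fold_threshold)
    p = out / "synergy_summary.csv"
    synergy_frame(syn_calls).to_csv(p, index=False, lineterminator="\n")
    files.append(p)
    syn_summary = summarize_synergy(syn_calls, cohort_size=len(matrix.patients))
    files.append(_write_json(out / "synergy_patients.json", syn_summary))
    log.info(
        "synergy: %d/%d patients with >=%.1f-fold amplification",
        syn_summary["n_synergy_patients"],
        syn_summary["n_patients"],
        config.fold_threshold,
    )

    # report stage
    p = out / "responder_table.csv"
    render_responder_table(cohort_summary).to_csv(p, lineterminator="\n")
    files.append(p)

    manifest = {f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(files)}
    run_log = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "outputs": manifest,
    }
    _write_json(out / "run_log.json", run_log)
    return manifest
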