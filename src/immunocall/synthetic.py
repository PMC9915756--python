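"""Synthetic cohorts with known planted truth.

Two generators stand in for data that cannot ship with the package:

* :func:`gen_expression_cohort` emulates bulk transcriptomic cohorts
  (tumor/normal lung expression matrices plus a normal-tissue reference
  panel). Per gene, normal samples draw from a Gaussian background in
  log2 space; each tumor sample is ectopically activated with a planted
  per-subtype probability, shifting its mean upward. Ubiquitous genes
  are expressed in every tumor/normal sample, with a designated
  non-expressing subset of the reference panel carrying the background
  level used for threshold calibration. FPKM-platform values are
  returned on the linear scale (the inverse of the log2(1+x) transform
  applied downstream).

* :func:`gen_flow_cohort` emulates multimer immunomonitoring: per
  patient × antigen pool, a responder flag is drawn, responders carry a
  post-expansion frequency drawn log-uniformly from a configured range
  while non-responders stay at the precursor frequency, and the
  multimer-positive event count is binomial in the tube's CD8+ events.
  Paired ±ICI tubes share the responder status; when the ICI effect is
  drawn, the ICI tube's true frequency is multiplied by a fold effect.

Every draw is recorded in a truth object so downstream callers can be
checked for parameter recovery. All randomness flows through a single
integer seed via :class:`numpy.random.Generator`; no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    CLASS_TISSUE_RESTRICTED,
    CLASS_UBIQUITOUS,
    GENE_CLASSES,
    PLATFORM_MICROARRAY,
    PLATFORM_RNASEQ,
    PLATFORMS,
    SUBTYPE_AC,
    SUBTYPE_SCC,
    ExpressionCohort,
    FlowObservation,
    pool_label,
)

# ---------------------------------------------------------------------------
# expression cohorts


@dataclass(frozen=True)
class GeneSpec:
    """Generating parameters for one gene.

    ``background_mean``/``background_sd`` describe the non-expressing
    level in log2 units; ``activation_shift`` is added to the mean when a
    sample expresses the gene. For tissue-restricted genes the per-subtype
    ``activation_fraction`` governs ectopic activation in tumors; for
    ubiquitous genes every tumor and normal sample is expressed and the
    fraction is ignored.
    """

    gene_id: str
    gene_class: str
    activation_fraction: Mapping[str, float]
    background_mean: float = 5.0
    background_sd: float = 0.5
    activation_shift: float = 3.0

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        for sub, f in self.activation_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"activation_fraction[{sub}] must lie in [0, 1]")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if self.activation_shift < 0:
            raise ValueError("activation_shift must be non-negative")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Study design for a synthetic expression cohort.

    Defaults mirror a microarray lung cohort of 14 normal lungs, 86
    adenocarcinomas and 60 squamous carcinomas, with a 48-tissue
    reference panel for calibrating ubiquitous genes.
    """

    genes: tuple[GeneSpec, ...]
    n_normal: int = 14
    n_tumor_per_subtype: Mapping[str, int] = field(
        default_factory=lambda: {SUBTYPE_AC: 86, SUBTYPE_SCC: 60}
    )
    platform: str = PLATFORM_MICROARRAY
    n_reference: int = 48
    reference_nonexpressing_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 2:
            raise ValueError("n_normal must be >= 2 so an SD is defined")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if not 0.0 <= self.reference_nonexpressing_fraction <= 1.0:
            raise ValueError("reference_nonexpressing_fraction must lie in [0, 1]")
        if any(n < 0 for n in self.n_tumor_per_subtype.values()):
            raise ValueError("tumor counts must be non-negative")
        for spec in self.genes:
            missing = set(self.n_tumor_per_subtype) - set(spec.activation_fraction)
            if spec.gene_class == CLASS_TISSUE_RESTRICTED and missing:
                raise ValueError(
                    f"{spec.gene_id}: no activation_fraction for subtypes {sorted(missing)}"
                )


@dataclass
class ExpressionTruth:
    """Ground truth for a generated expression cohort.

    ``fractions`` maps (gene, subtype) to the planted activation
    fraction; ``activated`` is a tumor-sample × gene boolean frame of the
    realized activation flags; ``gene_params`` maps gene →
    (background_mean, background_sd, activation_shift, gene_class);
    ``reference_nonexpressing`` maps ubiquitous genes to the reference
    sample ids designated non-expressing.
    """

    fractions: dict[tuple[str, str], float]
    activated: pd.DataFrame
    gene_params: dict[str, tuple[float, float, float, str]]
    sample_subtype: dict[str, str]
    reference_nonexpressing: dict[str, list[str]]

    def activated_flags(self, gene_id: str, subtype: str) -> list[bool]:
        ids = [s for s, sub in self.sample_subtype.items() if sub == subtype]
        return list(self.activated.loc[ids, gene_id])

    def to_json(self) -> str:
        payload = {
            "fractions": [[g, s, f] for (g, s), f in sorted(self.fractions.items())],
            "activated": {
                "samples": list(self.activated.index),
                "genes": list(self.activated.columns),
                "flags": self.activated.astype(int).to_numpy().tolist(),
            },
            "gene_params": {g: list(p) for g, p in sorted(self.gene_params.items())},
            "sample_subtype": dict(sorted(self.sample_subtype.items())),
            "reference_nonexpressing": {
                g: v for g, v in sorted(self.reference_nonexpressing.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExpressionTruth":
        d = json.loads(text)
        act = pd.DataFrame(
            np.asarray(d["activated"]["flags"], dtype=bool),
            index=d["activated"]["samples"],
            columns=d["activated"]["genes"],
        )
        return cls(
            fractions={(g, s): f for g, s, f in d["fractions"]},
            activated=act,
            gene_params={g: tuple(p) for g, p in d["gene_params"].items()},
            sample_subtype=d["sample_subtype"],
            reference_nonexpressing=d["reference_nonexpressing"],
        )


def default_gene_panel() -> tuple[GeneSpec, ...]:
    """A 14-antigen panel shaped like an NSCLC tumor-antigen study.

    Cancer-germline genes carry subtype-skewed activation fractions
    (higher in squamous carcinoma), survivin is activated in most tumors
    of both subtypes, and HER2/MUC1 are ubiquitously expressed.
    """

    def tr(gene: str, ac: float, scc: float) -> GeneSpec:
        return GeneSpec(gene, CLASS_TISSUE_RESTRICTED, {SUBTYPE_AC: ac, SUBTYPE_SCC: scc})

    return (
        tr("MAGE-A1", 0.10, 0.40),
        tr("MAGE-A2", 0.12, 0.40),
        tr("MAGE-A3", 0.12, 0.45),
        tr("MAGE-A4", 0.10, 0.35),
        tr("MAGE-A9", 0.10, 0.30),
        tr("MAGE-A10", 0.10, 0.35),
        tr("NY-ESO-1", 0.08, 0.30),
        tr("CAMEL", 0.05, 0.35),
        tr("GLULD1", 0.35, 0.05),
        tr("SURVIVIN", 0.85, 0.99),
        tr("WT-1", 0.15, 0.20),
        GeneSpec("HER2", CLASS_UBIQUITOUS, {}),
        GeneSpec("MUC-1", CLASS_UBIQUITOUS, {}),
        tr("MAGE-A3.2", 0.12, 0.45),
    )


def gen_expression_cohort(
    config: ExpressionSimConfig,
) -> tuple[ExpressionCohort, ExpressionTruth]:
    """Draw a seeded expression cohort and its planted truth."""
    rng = np.random.default_rng(config.seed)
    subtypes = list(config.n_tumor_per_subtype)

    normal_ids = [f"N{i:03d}" for i in range(1, config.n_normal + 1)]
    tumor_ids: dict[str, list[str]] = {}
    for sub in subtypes:
        n = config.n_tumor_per_subtype[sub]
        tumor_ids[sub] = [f"T{sub}{i:03d}" for i in range(1, n + 1)]
    ref_ids = [f"R{i:03d}" for i in range(1, config.n_reference + 1)]
    all_tumors = [s for sub in subtypes for s in tumor_ids[sub]]
    columns = normal_ids + all_tumors + ref_ids

    n_nonexpr = int(round(config.reference_nonexpressing_fraction * config.n_reference))
    nonexpr_ref = ref_ids[:n_nonexpr]

    log_rows = []
    fractions: dict[tuple[str, str], float] = {}
    activated = pd.DataFrame(False, index=all_tumors, columns=[g.gene_id for g in config.genes])
    gene_params: dict[str, tuple[float, float, float, str]] = {}
    ref_designation: dict[str, list[str]] = {}

    for spec in config.genes:
        mu, sd, shift = spec.background_mean, spec.background_sd, spec.activation_shift
        gene_params[spec.gene_id] = (mu, sd, shift, spec.gene_class)
        ubiq = spec.gene_class == CLASS_UBIQUITOUS

        normal_mu = mu + shift if ubiq else mu
        vals_normal = rng.normal(normal_mu, sd, size=config.n_normal)

        vals_tumor = []
        for sub in subtypes:
            n = config.n_tumor_per_subtype[sub]
            if ubiq:
                frac = 1.0
                flags = np.ones(n, dtype=bool)
            else:
                frac = spec.activation_fraction[sub]
                flags = rng.random(n) < frac
            fractions[(spec.gene_id, sub)] = frac
            activated.loc[tumor_ids[sub], spec.gene_id] = flags
            vals_tumor.append(rng.normal(mu + shift * flags, sd))

        if ubiq:
            ref_mu = np.full(config.n_reference, mu + shift)
            ref_mu[:n_nonexpr] = mu
            ref_designation[spec.gene_id] = list(nonexpr_ref)
        else:
            ref_mu = np.full(config.n_reference, mu)
        vals_ref = rng.normal(ref_mu, sd)

        log_rows.append(np.concatenate([vals_normal, *vals_tumor, vals_ref]))

    log_matrix = pd.DataFrame(
        log_rows,
        index=pd.Index([g.gene_id for g in config.genes], name="gene_id"),
        columns=columns,
    )
    if config.platform == PLATFORM_RNASEQ:
        values = np.maximum(np.exp2(log_matrix.to_numpy()) - 1.0, 0.0)
        matrix = pd.DataFrame(values, index=log_matrix.index, columns=log_matrix.columns)
    else:
        matrix = log_matrix

    sample_rows = (
        [(s, "normal", "NA") for s in normal_ids]
        + [(s, "tumor", sub) for sub in subtypes for s in tumor_ids[sub]]
        + [(s, "reference", "NA") for s in ref_ids]
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "group", "subtype"]
    ).set_index("sample_id")
    samples["platform"] = config.platform
    genes = pd.DataFrame(
        {"gene_class": [g.gene_class for g in config.genes]},
        index=pd.Index([g.gene_id for g in config.genes], name="gene_id"),
    )

    cohort = ExpressionCohort(values=matrix, samples=samples, genes=genes)
    sample_subtype = {s: sub for sub in subtypes for s in tumor_ids[sub]}
    truth = ExpressionTruth(
        fractions=fractions,
        activated=activated,
        gene_params=gene_params,
        sample_subtype=sample_subtype,
        reference_nonexpressing=ref_designation,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# flow cohorts


@dataclass(frozen=True)
class FlowSimConfig:
    """Study design for a synthetic multimer immunomonitoring experiment.

    Defaults follow the measured biology: circulating tumor-specific
    precursors near 0.001% of CD8+ cells, post-expansion frequencies
    spanning 0.026%–3.82%, a 0.01%-of-CD8 detection limit implying
    ~50,000 gated events per tube, and a threefold ICI amplification in
    5/8 of responding patients.
    """

    antigen_pools: tuple[frozenset[str], ...]
    n_patients: int = 26
    cd8_events_per_tube: int = 50_000
    precursor_freq: float = 1e-5
    expanded_freq_range: tuple[float, float] = (2.6e-4, 3.82e-2)
    responder_prob: float | Mapping[str, float] = 0.5
    include_ici: bool = False
    ici_fold_effect: float = 3.0
    ici_effect_prob: float = 0.625
    ici_responders_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.expanded_freq_range
        if not 0.0 < self.precursor_freq < low < high < 1.0:
            raise ValueError("need 0 < precursor_freq < expanded low < expanded high < 1")
        if self.cd8_events_per_tube <= 0:
            raise ValueError("cd8_events_per_tube must be positive")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.antigen_pools or any(not p for p in self.antigen_pools):
            raise ValueError("antigen pools must be non-empty")
        probs = (
            self.responder_prob.values()
            if isinstance(self.responder_prob, Mapping)
            else [self.responder_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("responder_prob must lie in [0, 1]")
        if not 0.0 <= self.ici_effect_prob <= 1.0:
            raise ValueError("ici_effect_prob must lie in [0, 1]")
        if self.ici_fold_effect < 1.0:
            raise ValueError("ici_fold_effect must be >= 1")

    def pool_responder_prob(self, pool: str) -> float:
        if isinstance(self.responder_prob, Mapping):
            return self.responder_prob[pool]
        return self.responder_prob


def default_antigen_pools() -> tuple[frozenset[str], ...]:
    """Singleton pools for the 14-antigen panel plus the Melan-A control."""
    names = [g.gene_id for g in default_gene_panel() if g.gene_id != "MAGE-A3.2"]
    return tuple(frozenset({n}) for n in names + ["Melan-A"])


@dataclass
class FlowTruth:
    """Planted truth per patient × pool: responder flag, true post-expansion
    frequency (fraction of CD8+ events) and the realized ICI multiplier."""

    responder: dict[tuple[str, str], bool]
    true_freq: dict[tuple[str, str], float]
    ici_multiplier: dict[tuple[str, str], float]

    def responder_fraction(self, pool: str) -> float:
        flags = [r for (p, q), r in self.responder.items() if q == pool]
        return sum(flags) / len(flags) if flags else float("nan")

    def to_json(self) -> str:
        keys = sorted(self.responder)
        payload = {
            "records": [
                {
                    "patient_id": p,
                    "pool": q,
                    "responder": bool(self.responder[(p, q)]),
                    "true_freq": self.true_freq[(p, q)],
                    "ici_multiplier": self.ici_multiplier[(p, q)],
                }
                for p, q in keys
            ]
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FlowTruth":
        d = json.loads(text)
        responder, freq, mult = {}, {}, {}
        for rec in d["records"]:
            key = (rec["patient_id"], rec["pool"])
            responder[key] = rec["responder"]
            freq[key] = rec["true_freq"]
            mult[key] = rec["ici_multiplier"]
        return cls(responder, freq, mult)


def gen_flow_cohort(config: FlowSimConfig) -> tuple[list[FlowObservation], FlowTruth]:
    """Draw a seeded multimer immunomonitoring cohort and its truth."""
    rng = np.random.default_rng(config.seed)
    low, high = config.expanded_freq_range
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]

    observations: list[FlowObservation] = []
    responder: dict[tuple[str, str], bool] = {}
    true_freq: dict[tuple[str, str], float] = {}
    ici_mult: dict[tuple[str, str], float] = {}

    for patient in patients:
        for pool_set in config.antigen_pools:
            label = pool_label(pool_set)
            key = (patient, label)
            is_resp = rng.random() < config.pool_responder_prob(label)
            if is_resp:
                # log-uniform across the configured range: post-expansion
                # frequencies span two decades
                freq = float(np.exp(rng.uniform(np.log(low), np.log(high))))
            else:
                freq = config.precursor_freq
            responder[key] = bool(is_resp)
            true_freq[key] = freq

            k = int(rng.binomial(config.cd8_events_per_tube, freq))
            observations.append(
                FlowObservation(patient, pool_set, False, config.cd8_events_per_tube, k)
            )

            if config.include_ici:
                eligible = is_resp or not config.ici_responders_only
                boosted = eligible and rng.random() < config.ici_effect_prob
                mult = config.ici_fold_effect if boosted else 1.0
                ici_mult[key] = mult
                freq_ici = min(freq * mult, 0.99)
                k_ici = int(rng.binomial(config.cd8_events_per_tube, freq_ici))
                observations.append(
                    FlowObservation(patient, pool_set, True, config.cd8_events_per_tube, k_ici)
                )
            else:
                ici_mult[key] = 1.0

    return observations, FlowTruth(responder, true_freq, ici_mult)


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixture_bundle(
    obj,
    truth,
    directory: str | Path,
) -> dict[str, str]:
    """Write a cohort (expression or flow) plus its truth to disk.

    Returns a manifest mapping file name → sha256 hex digest. Files
    round-trip losslessly through the readers in :mod:`immunocall.io`.
    """
    import hashlib

    from . import io as iomod

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    if isinstance(obj, ExpressionCohort):
        files += iomod.write_expression_bundle(obj, directory)
        truth_path = directory / "expression_truth.json"
        truth_path.write_text(truth.to_json() + "\n")
        files.append(truth_path)
    elif isinstance(obj, list) and all(isinstance(o, FlowObservation) for o in obj):
        files.append(iomod.write_flow_csv(obj, directory / "flow.csv"))
        truth_path = directory / "flow_truth.json"
        truth_path.write_text(truth.to_json() + "\n")
        files.append(truth_path)
    else:
        raise TypeError("expected an ExpressionCohort or a list of FlowObservation")

    manifest = {}
    for path in sorted(files):
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
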