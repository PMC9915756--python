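"""Core record types shared across the pipeline stages.

The pipeline moves through three representations:

* expression — a gene × sample matrix with sample/gene annotations
  (:class:`ExpressionCohort`), per-gene cutoffs (:class:`GeneThreshold`)
  and per-gene × subtype call rates (an overexpression summary frame);
* immune monitoring — per-tube multimer counts (:class:`FlowObservation`)
  censored into :class:`ResponseCall` records and assembled into a
  :class:`ResponseMatrix` with cohort metadata;
* checkpoint synergy — paired ±ICI frequencies scored as
  :class:`SynergyCall`.

All frequencies are expressed as percent of gated CD8+ events; all
expression thresholds live on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

GROUP_NORMAL = "normal"
GROUP_TUMOR = "tumor"
GROUP_REFERENCE = "reference"
GROUPS = (GROUP_NORMAL, GROUP_TUMOR, GROUP_REFERENCE)

SUBTYPE_AC = "AC"
SUBTYPE_SCC = "SCC"

PLATFORM_MICROARRAY = "microarray_rma"
PLATFORM_RNASEQ = "rnaseq_fpkm"
PLATFORMS = (PLATFORM_MICROARRAY, PLATFORM_RNASEQ)

CLASS_TISSUE_RESTRICTED = "tissue_restricted"
CLASS_UBIQUITOUS = "ubiquitous"
GENE_CLASSES = (CLASS_TISSUE_RESTRICTED, CLASS_UBIQUITOUS)

REGIME_NORMAL_MEAN_2SD = "normal_mean_plus_2sd"
REGIME_FIXED_REFERENCE = "fixed_reference_calibrated"

#: limit of detection for multimer-positive cells, percent of gated CD8+ events
DEFAULT_LOD = 0.01
#: number of standard deviations above the normal mean for overexpression
DEFAULT_SD_MULTIPLIER = 2.0
#: minimum fold increase in ASTC frequency to call checkpoint synergy
DEFAULT_FOLD_THRESHOLD = 2.0
#: assay positive-control specificity, excluded from breadth statistics
DEFAULT_CONTROL_POOLS = frozenset({"Melan-A"})


def pool_label(antigens: Iterable[str]) -> str:
    """Canonical label for a dextramer pool: sorted, semicolon-joined."""
    names = sorted(set(antigens))
    if not names:
        raise ValueError("antigen pool must be non-empty")
    return ";".join(names)


@dataclass
class ExpressionCohort:
    """Gene × sample expression values with sample and gene annotations.

    ``values`` is platform-native: linear FPKM for RNA-seq, log2 intensities
    for RMA-processed microarrays. ``samples`` is indexed by sample id with
    columns ``group``/``subtype``/``platform``; ``genes`` is indexed by
    gene id with column ``gene_class``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing annotations: {sorted(missing)[:5]}")
        bad_groups = set(self.samples["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown sample groups: {sorted(bad_groups)}")
        platforms = set(self.samples.loc[list(self.values.columns), "platform"])
        if len(platforms) != 1:
            raise ValueError(f"cohort must use a single platform, got {sorted(platforms)}")
        (self.platform,) = platforms
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform tag: {self.platform!r}")
        if self.platform == PLATFORM_RNASEQ and (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values are not allowed")
        bad_classes = set(self.genes["gene_class"]) - set(GENE_CLASSES)
        if bad_classes:
            raise ValueError(f"unknown gene classes: {sorted(bad_classes)}")

    def sample_ids(self, group: str, subtype: str | None = None) -> list[str]:
        ann = self.samples.loc[list(self.values.columns)]
        mask = ann["group"] == group
        if subtype is not None:
            mask &= ann["subtype"] == subtype
        return list(ann.index[mask])

    @property
    def tumor_subtypes(self) -> list[str]:
        ann = self.samples.loc[list(self.values.columns)]
        sub = ann.loc[ann["group"] == GROUP_TUMOR, "subtype"].dropna()
        return sorted(s for s in sub.unique() if s != "NA")


@dataclass(frozen=True)
class GeneThreshold:
    """Per-gene log2-scale expression cutoff and the regime that set it."""

    gene_id: str
    threshold: float
    regime: str
    n_reference_samples: int
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER

    def __post_init__(self) -> None:
        if not pd.notna(self.threshold) or abs(self.threshold) == float("inf"):
            raise ValueError(f"threshold for {self.gene_id} is not finite")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.regime not in (REGIME_NORMAL_MEAN_2SD, REGIME_FIXED_REFERENCE):
            raise ValueError(f"unknown regime: {self.regime!r}")


@dataclass(frozen=True)
class FlowObservation:
    """One patient × pool × condition multimer measurement.

    ``cd8_events`` counts gated CD8-positive living single cells;
    ``multimer_events`` counts the multimer-positive subset.
    """

    patient_id: str
    antigen_pool: frozenset[str]
    ici: bool
    cd8_events: int
    multimer_events: int

    def __post_init__(self) -> None:
        if not self.antigen_pool:
            raise ValueError("antigen_pool must be non-empty")
        if self.cd8_events <= 0:
            raise ValueError("cd8_events must be positive")
        if not 0 <= self.multimer_events <= self.cd8_events:
            raise ValueError("multimer_events must lie in [0, cd8_events]")

    @property
    def pool(self) -> str:
        return pool_label(self.antigen_pool)


@dataclass(frozen=True)
class ResponseCall:
    """LOD-censored frequency and detection call for one measurement."""

    raw_frequency: float
    censored_frequency: float
    detected: bool
    lod: float = DEFAULT_LOD

    def __post_init__(self) -> None:
        if self.raw_frequency < 0:
            raise ValueError("frequency must be non-negative")
        if self.lod <= 0:
            raise ValueError("lod must be positive")


@dataclass
class ResponseMatrix:
    """Patient × pool grid of response calls with cohort metadata.

    ``calls`` maps ``(patient_id, pool)`` to a :class:`ResponseCall`;
    untested cells are absent, never recorded as negative. ``patients``
    is the full cohort (denominator for breadth statistics); per-pool
    denominators count patients with an observation for that pool.
    """

    calls: dict[tuple[str, str], ResponseCall]
    patients: list[str]
    pools: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    control_pools: frozenset[str] = DEFAULT_CONTROL_POOLS

    def pool_denominator(self, pool: str) -> int:
        return sum(1 for (p, q) in self.calls if q == pool)

    def detected_pools(self, patient: str, include_controls: bool = False) -> list[str]:
        out = []
        for (p, q), call in self.calls.items():
            if p != patient or not call.detected:
                continue
            if not include_controls and q in self.control_pools:
                continue
            out.append(q)
        return sorted(out)


@dataclass
class CohortSummary:
    """Cohort-level responder statistics.

    ``pool_tallies`` maps pool → (n responders, n tested); proportions are
    on [0, 1]. ``breadth`` maps k → number of patients detected on ≥ k
    pools (control pools excluded); ``mean_pools_per_patient`` divides the
    total detected calls by the full cohort size.
    """

    cohort_size: int
    pool_tallies: dict[str, tuple[int, int]]
    at_least_one: tuple[int, int]
    mean_pools_per_patient: float
    breadth: dict[int, int] | None = None
    control_tallies: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def pool_proportions(self) -> dict[str, float]:
        return {p: (n / d if d else float("nan")) for p, (n, d) in self.pool_tallies.items()}

    @property
    def at_least_one_proportion(self) -> float:
        n, d = self.at_least_one
        return n / d if d else float("nan")


@dataclass(frozen=True)
class SynergyCall:
    """Paired ±ICI frequencies with LOD-aware fold change and flags.

    ``fold_change`` divides the censored ICI-arm frequency by the censored
    control-arm frequency, so sub-LOD control arms give finite folds.
    ``synergy`` requires both fold ≥ threshold and a detected ICI arm;
    ``de_novo`` marks responses present only with the ICI.
    """

    patient_id: str
    pool: str
    freq_no_ici: float
    freq_ici: float
    fold_change: float
    synergy: bool
    de_novo: bool
    lod: float = DEFAULT_LOD
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
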