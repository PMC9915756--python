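"""Antigen-specific T-cell response calling from multimer counts.

The frequency of multimer-positive cells among gated CD8+ events is
censored at a limit of detection (0.01% of CD8+ events by default):
non-detections are reported AT the LOD, and a response is called only
when the raw frequency strictly exceeds it. Cohort summaries cover
per-pool responder proportions (with per-pool denominators, since not
every patient is tested on every pool), breadth (patients responding to
at least k specificities) and the mean number of responses per patient.
The Melan-A positive control is tallied separately and never counts
toward breadth.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    DEFAULT_CONTROL_POOLS,
    DEFAULT_LOD,
    CohortSummary,
    FlowObservation,
    ResponseCall,
    ResponseMatrix,
)


def compute_frequency(obs: FlowObservation) -> float:
    """Multimer-positive frequency as percent of gated CD8+ events."""
    return 100.0 * obs.multimer_events / obs.cd8_events


def censor_and_call(frequency: float, lod: float = DEFAULT_LOD) -> ResponseCall:
    """Censor a frequency at the LOD and call detection.

    The censored frequency is ``max(frequency, lod)``; detection requires
    the raw frequency to strictly exceed the LOD (values at the LOD are
    indistinguishable from non-detections). Idempotent on censored values.
    """
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    if lod <= 0:
        raise ValueError("lod must be positive")
    return ResponseCall(
        raw_frequency=frequency,
        censored_frequency=max(frequency, lod),
        detected=frequency > lod,
        lod=lod,
    )


def call_observations(
    observations: Iterable[FlowObservation],
    lod: float = DEFAULT_LOD,
    ici: bool = False,
) -> list[tuple[str, str, ResponseCall]]:
    """Censored calls for every observation in one condition (±ICI)."""
    out = []
    seen = set()
    for obs in observations:
        if obs.ici != ici:
            continue
        key = (obs.patient_id, obs.pool)
        if key in seen:
            raise ValueError(f"duplicate observation for {key} in one condition")
        seen.add(key)
        out.append((obs.patient_id, obs.pool, censor_and_call(compute_frequency(obs), lod)))
    return out


def build_response_matrix(
    calls: Sequence[tuple[str, str, ResponseCall]],
    cohort: pd.DataFrame | None = None,
    control_pools: frozenset[str] = DEFAULT_CONTROL_POOLS,
) -> ResponseMatrix:
    """Assemble per-patient × pool calls into a matrix.

    ``cohort`` is the patient metadata table (indexed by patient id); when
    given, every observed patient must appear in it and the cohort defines
    the breadth denominator. Untested cells stay absent.
    """
    grid: dict[tuple[str, str], ResponseCall] = {}
    for patient, pool, call in calls:
        key = (patient, pool)
        if key in grid:
            raise ValueError(f"duplicate call for {key}")
        grid[key] = call
    observed_patients = sorted({p for p, _ in grid})
    if cohort is not None:
        unknown = set(observed_patients) - set(cohort.index)
        if unknown:
            raise ValueError(f"patients absent from cohort table: {sorted(unknown)}")
        patients = list(cohort.index)
        metadata = cohort
    else:
        patients = observed_patients
        metadata = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    pools = sorted({q for _, q in grid})
    return ResponseMatrix(
        calls=grid,
        patients=patients,
        pools=pools,
        metadata=metadata,
        control_pools=control_pools,
    )


def summarize_cohort(matrix: ResponseMatrix) -> CohortSummary:
    """Cohort-level responder statistics from a response matrix.

    Per-pool proportions use per-pool tested denominators; breadth, the
    at-least-one tally and the mean responses per patient use the full
    cohort denominator. Control pools are tallied separately.
    """
    if not matrix.calls:
        raise ValueError("empty response matrix")
    n_cohort = len(matrix.patients)

    pool_tallies: dict[str, tuple[int, int]] = {}
    control_tallies: dict[str, tuple[int, int]] = {}
    for pool in matrix.pools:
        tested = [
            call for (p, q), call in matrix.calls.items() if q == pool and p in set(matrix.patients)
        ]
        tally = (sum(c.detected for c in tested), len(tested))
        if pool in matrix.control_pools:
            control_tallies[pool] = tally
        else:
            pool_tallies[pool] = tally

    per_patient = {p: len(matrix.detected_pools(p)) for p in matrix.patients}
    total = sum(per_patient.values())
    max_k = max(per_patient.values(), default=0)
    breadth = {k: sum(1 for v in per_patient.values() if v >= k) for k in range(1, max_k + 1)}

    return CohortSummary(
        cohort_size=n_cohort,
        pool_tallies=pool_tallies,
        at_least_one=(breadth.get(1, 0), n_cohort),
        mean_pools_per_patient=total / n_cohort if n_cohort else float("nan"),
        breadth=breadth,
        control_tallies=control_tallies,
    )


def summarize_pool_tallies(
    tallies: Mapping[str, tuple[int, int]],
    cohort_size: int,
    at_least_one: tuple[int, int] | None = None,
) -> CohortSummary:
    """Cohort summary from marginal per-pool tallies alone.

    Used when only numerator/denominator pairs are available (no
    per-patient grid). The mean responses per patient is the sum of the
    numerators over the cohort size; breadth cannot be derived from
    marginals and is left unset.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    for pool, (n, d) in tallies.items():
        if not 0 <= n <= d:
            raise ValueError(f"{pool}: numerator must lie in [0, denominator]")
        if d > cohort_size:
            raise ValueError(f"{pool}: denominator exceeds cohort size")
    total = sum(n for n, _ in tallies.values())
    return CohortSummary(
        cohort_size=cohort_size,
        pool_tallies=dict(tallies),
        at_least_one=at_least_one if at_least_one is not None else (0, 0),
        mean_pools_per_patient=total / cohort_size,
        breadth=None,
    )


def stratify_by_subtype(
    matrix: ResponseMatrix,
    histology_column: str = "histology",
    major_subtypes: Sequence[str] = ("AC", "SCC"),
) -> dict[str, CohortSummary]:
    """Per-histology cohort summaries.

    Patients outside the major subtypes (e.g. carcinoid, large-cell
    neuroendocrine) form an ``other`` stratum. Each stratum's summary is
    computed on the restricted matrix with that stratum as the cohort.
    """
    if histology_column not in matrix.metadata.columns:
        raise ValueError(f"metadata lacks a {histology_column!r} column")
    histology = matrix.metadata[histology_column]
    strata: dict[str, list[str]] = {s: [] for s in major_subtypes}
    strata["other"] = []
    for patient in matrix.patients:
        h = histology.get(patient)
        strata[h if h in major_subtypes else "other"].append(patient)

    out: dict[str, CohortSummary] = {}
    for name, members in strata.items():
        if not members:
            continue
        sub_calls = {k: v for k, v in matrix.calls.items() if k[0] in set(members)}
        if not sub_calls:
            out[name] = CohortSummary(
                cohort_size=len(members),
                pool_tallies={},
                at_least_one=(0, len(members)),
                mean_pools_per_patient=0.0,
            )
            continue
        sub = ResponseMatrix(
            calls=sub_calls,
            patients=members,
            pools=sorted({q for _, q in sub_calls}),
            metadata=matrix.metadata.loc[members],
            control_pools=matrix.control_pools,
        )
        out[name] = summarize_cohort(sub)
    return out


def histology_fractions(
    cohort: pd.DataFrame,
    histology_column: str = "histology",
    major_subtypes: Sequence[str] = ("AC", "SCC"),
) -> dict[str, tuple[int, int]]:
    """Tally of patients per histology stratum, as (count, cohort size)."""
    n = len(cohort)
    counts = cohort[histology_column].value_counts()
    out = {s: (int(counts.get(s, 0)), n) for s in major_subtypes}
    out["other"] = (n - sum(c for c, _ in out.values()), n)
    return out


def response_matrix_frame(matrix: ResponseMatrix) -> pd.DataFrame:
    """Long-format frame of the matrix: one row per (patient, pool) call."""
    rows = [
        {
            "patient_id": p,
            "antigen_pool": q,
            "raw_freq": call.raw_frequency,
            "censored_freq": call.censored_frequency,
            "detected": call.detected,
        }
        for (p, q), call in sorted(matrix.calls.items())
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "antigen_pool", "raw_freq", "censored_freq", "detected"]
    )
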