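"""Checkpoint-inhibitor synergy scoring by LOD-aware fold change.

For each patient × pool measured with and without anti-PD-1, both
frequencies are censored at the limit of detection before dividing, so a
control arm below the LOD yields a conservative, finite fold rather than
an infinite one. Synergy is called when the fold change reaches the
threshold (a doubling by default) AND the ICI arm itself is detected —
amplification of sub-LOD noise never counts. A response detected only in
the ICI arm is additionally flagged de novo.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_LOD,
    FlowObservation,
    SynergyCall,
)
from .response import censor_and_call, compute_frequency


def fold_change(
    freq_ici: float,
    freq_no_ici: float,
    lod: float = DEFAULT_LOD,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    patient_id: str = "",
    pool: str = "",
) -> SynergyCall:
    """Score one paired ±ICI measurement.

    Frequencies are percent of gated CD8+ events, raw (uncensored);
    censoring at ``lod`` is applied here. Two sub-LOD arms give fold 1.
    """
    if freq_ici < 0 or freq_no_ici < 0:
        raise ValueError("frequencies must be non-negative")
    call_ici = censor_and_call(freq_ici, lod)
    call_ctrl = censor_and_call(freq_no_ici, lod)
    fold = call_ici.censored_frequency / call_ctrl.censored_frequency
    return SynergyCall(
        patient_id=patient_id,
        pool=pool,
        freq_no_ici=call_ctrl.censored_frequency,
        freq_ici=call_ici.censored_frequency,
        fold_change=fold,
        synergy=fold >= fold_threshold and call_ici.detected,
        de_novo=call_ici.detected and not call_ctrl.detected,
        lod=lod,
        fold_threshold=fold_threshold,
    )


def score_synergy(
    observations: Iterable[FlowObservation],
    lod: float = DEFAULT_LOD,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> list[SynergyCall]:
    """Pair ±ICI tubes per patient × pool and score each pair.

    Unpaired observations (missing either arm) are skipped.
    """
    arms: dict[tuple[str, str], dict[bool, FlowObservation]] = defaultdict(dict)
    for obs in observations:
        key = (obs.patient_id, obs.pool)
        if obs.ici in arms[key]:
            raise ValueError(f"duplicate {'+ICI' if obs.ici else 'control'} tube for {key}")
        arms[key][obs.ici] = obs
    calls = []
    for (patient, pool), pair in sorted(arms.items()):
        if len(pair) < 2:
            continue
        calls.append(
            fold_change(
                freq_ici=compute_frequency(pair[True]),
                freq_no_ici=compute_frequency(pair[False]),
                lod=lod,
                fold_threshold=fold_threshold,
                patient_id=patient,
                pool=pool,
            )
        )
    return calls


def summarize_synergy(calls: Sequence[SynergyCall], cohort_size: int | None = None) -> dict:
    """Patient-level synergy tally.

    Counts patients with at least one synergistic pool (each patient once,
    however many pools respond), de-novo responders, and reports the
    per-call fold distribution and the maximum fold observed.
    """
    patients = sorted({c.patient_id for c in calls})
    n = cohort_size if cohort_size is not None else len(patients)
    synergy_patients = sorted({c.patient_id for c in calls if c.synergy})
    de_novo_patients = sorted({c.patient_id for c in calls if c.de_novo})
    folds = [c.fold_change for c in calls]
    return {
        "n_patients": n,
        "n_calls": len(calls),
        "synergy_patients": synergy_patients,
        "n_synergy_patients": len(synergy_patients),
        "synergy_patient_fraction": len(synergy_patients) / n if n else float("nan"),
        "de_novo_patients": de_novo_patients,
        "n_de_novo_patients": len(de_novo_patients),
        "max_fold": max(folds) if folds else float("nan"),
        "median_fold": float(np.median(folds)) if folds else float("nan"),
    }


def synergy_frame(calls: Sequence[SynergyCall]) -> pd.DataFrame:
    """Long-format frame: one row per scored patient × pool pair."""
    rows = [
        {
            "patient_id": c.patient_id,
            "antigen_pool": c.pool,
            "freq_no_ici": c.freq_no_ici,
            "freq_ici": c.freq_ici,
            "fold_change": c.fold_change,
            "synergy": c.synergy,
            "de_novo": c.de_novo,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "antigen_pool",
            "freq_no_ici",
            "freq_ici",
            "fold_change",
            "synergy",
            "de_novo",
        ],
    )
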