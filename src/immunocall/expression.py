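"""Tumor-antigen mRNA overexpression calling.

Two thresholding regimes are supported, mirroring how ectopically
activated cancer-germline genes and ubiquitously expressed genes are
handled in bulk transcriptomics:

* tissue-restricted genes (MAGE family, NY-ESO-1, ...): the cutoff is the
  mean log2 expression in normal-lung samples plus ``sd_multiplier``
  standard deviations — an outlier threshold against the normal
  background;
* ubiquitous genes (HER2, MUC1): a fixed cutoff calibrated on a
  reference panel of tissues designated as non-expressing, using the
  same mean + k·SD statistic for regime symmetry.

A tumor sample is called overexpressed when its log2 value is strictly
greater than the gene's threshold; per-gene × subtype call rates are the
primary output.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CLASS_UBIQUITOUS,
    DEFAULT_SD_MULTIPLIER,
    GROUP_NORMAL,
    GROUP_REFERENCE,
    GROUP_TUMOR,
    PLATFORM_MICROARRAY,
    PLATFORM_RNASEQ,
    REGIME_FIXED_REFERENCE,
    REGIME_NORMAL_MEAN_2SD,
    ExpressionCohort,
    GeneThreshold,
)


def transform_expression(
    cohort: ExpressionCohort, microarray_already_log2: bool = True
) -> pd.DataFrame:
    """Bring platform-native values onto the log2 scale used for calling.

    RNA-seq FPKM values map through log2(1 + FPKM). RMA-processed
    microarray intensities are already log2 by construction and pass
    through unchanged unless ``microarray_already_log2`` is False, in
    which case a plain log2 is applied.
    """
    if cohort.platform == PLATFORM_RNASEQ:
        vals = cohort.values.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative FPKM values are not allowed")
        return pd.DataFrame(
            np.log2(1.0 + vals), index=cohort.values.index, columns=cohort.values.columns
        )
    if cohort.platform == PLATFORM_MICROARRAY:
        if microarray_already_log2:
            return cohort.values.astype(float).copy()
        return pd.DataFrame(
            np.log2(cohort.values.to_numpy(dtype=float)),
            index=cohort.values.index,
            columns=cohort.values.columns,
        )
    raise ValueError(f"unknown platform tag: {cohort.platform!r}")


def _mean_plus_k_sd(values: Sequence[float], k: float) -> tuple[float, int]:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("at least 2 values are required to estimate an SD")
    # sample SD (n-1 denominator): standard for small normal cohorts
    return float(arr.mean() + k * arr.std(ddof=1)), int(arr.size)


def threshold_tissue_restricted(
    normal_values: Sequence[float],
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    gene_id: str = "",
) -> GeneThreshold:
    """Outlier threshold: mean + k·SD of log2 expression in normal samples."""
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    thr, n = _mean_plus_k_sd(normal_values, sd_multiplier)
    return GeneThreshold(gene_id, thr, REGIME_NORMAL_MEAN_2SD, n, sd_multiplier)


def threshold_ubiquitous(
    reference_values: Sequence[float],
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    gene_id: str = "",
) -> GeneThreshold:
    """Fixed threshold calibrated on designated non-expressing reference samples."""
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    thr, n = _mean_plus_k_sd(reference_values, sd_multiplier)
    return GeneThreshold(gene_id, thr, REGIME_FIXED_REFERENCE, n, sd_multiplier)


def compute_thresholds(
    log_matrix: pd.DataFrame,
    cohort: ExpressionCohort,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    reference_designation: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, GeneThreshold]:
    """Per-gene thresholds, picking the regime from the gene class.

    Tissue-restricted genes calibrate on normal-group samples; ubiquitous
    genes calibrate on reference-group samples. ``reference_designation``
    optionally restricts a ubiquitous gene's panel to an explicit list of
    non-expressing reference sample ids; by default the whole reference
    group is used.
    """
    normals = cohort.sample_ids(GROUP_NORMAL)
    reference = cohort.sample_ids(GROUP_REFERENCE)
    out: dict[str, GeneThreshold] = {}
    for gene_id, cls in cohort.genes["gene_class"].items():
        if gene_id not in log_matrix.index:
            raise KeyError(f"gene {gene_id} missing from expression matrix")
        if cls == CLASS_UBIQUITOUS:
            panel = list(reference)
            if reference_designation and gene_id in reference_designation:
                panel = [s for s in reference_designation[gene_id] if s in log_matrix.columns]
            if len(panel) < 2:
                raise ValueError(
                    f"{gene_id}: ubiquitous calling needs >=2 non-expressing reference samples"
                )
            out[gene_id] = threshold_ubiquitous(
                log_matrix.loc[gene_id, panel], sd_multiplier, gene_id
            )
        else:
            if len(normals) < 2:
                raise ValueError(
                    f"{gene_id}: tissue-restricted calling needs >=2 normal samples"
                )
            out[gene_id] = threshold_tissue_restricted(
                log_matrix.loc[gene_id, normals], sd_multiplier, gene_id
            )
    return out


def call_overexpression(
    log_matrix: pd.DataFrame,
    thresholds: Mapping[str, GeneThreshold],
    cohort: ExpressionCohort,
    subtypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene × subtype overexpression call rates.

    Counts tumor samples whose log2 value is strictly greater than the
    gene's threshold. Samples with missing values are excluded from both
    numerator and denominator. Subtypes with no tumors are reported with
    ``n_tumors`` 0 and NaN percent (not applicable).

    Returns a frame with columns ``gene_id, subtype, regime, threshold,
    n_tumors, n_above, percent`` (full precision; rounding is display-only).
    """
    if subtypes is None:
        subtypes = cohort.tumor_subtypes
    rows = []
    for gene_id in cohort.genes.index:
        if gene_id not in thresholds:
            raise KeyError(f"no threshold for gene {gene_id}")
        thr = thresholds[gene_id]
        for subtype in subtypes:
            samples = cohort.sample_ids(GROUP_TUMOR, subtype)
            vals = log_matrix.loc[gene_id, samples].to_numpy(dtype=float) if samples else np.array([])
            vals = vals[~np.isnan(vals)]
            n = int(vals.size)
            n_above = int((vals > thr.threshold).sum())
            rows.append(
                {
                    "gene_id": gene_id,
                    "subtype": subtype,
                    "regime": thr.regime,
                    "threshold": thr.threshold,
                    "n_tumors": n,
                    "n_above": n_above,
                    "percent": 100.0 * n_above / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def expected_call_rate(
    activated: Sequence[bool],
    threshold: float,
    background_mean: float,
    background_sd: float,
    activation_shift: float,
) -> float:
    """Expected fraction of tumor samples called, given planted truth.

    Each sample's value is Gaussian around the background mean, shifted by
    ``activation_shift`` when activated; the probability of exceeding the
    realized threshold is a Gaussian upper tail per sample.
    """
    flags = np.asarray(list(activated), dtype=bool)
    if flags.size == 0:
        return float("nan")
    mu = background_mean + activation_shift * flags
    p = 1.0 - stats.norm.cdf((threshold - mu) / background_sd)
    return float(p.mean())


def recover_activation(
    summary: pd.DataFrame,
    truth: "ExpressionTruth",
    thresholds: Mapping[str, GeneThreshold],
) -> pd.DataFrame:
    """Validation harness: compare call rates against the planted truth.

    For each gene × subtype, reports the planted activation fraction, the
    called percent, the truth-implied expected percent (activated and
    non-activated samples each contribute their Gaussian tail beyond the
    realized threshold), the absolute error between called and planted
    percents, and a coverage flag: whether the observed count lies within
    a 95% binomial interval around the expected rate.
    """
    from .synthetic import ExpressionTruth  # local import to avoid a cycle

    if not isinstance(truth, ExpressionTruth):
        raise TypeError("truth must be an ExpressionTruth")
    rows = []
    for _, rec in summary.iterrows():
        key = (rec["gene_id"], rec["subtype"])
        if key not in truth.fractions:
            raise KeyError(f"no planted truth for gene/subtype {key}")
        planted = truth.fractions[key]
        mean, sd, shift, _cls = truth.gene_params[rec["gene_id"]]
        flags = truth.activated_flags(rec["gene_id"], rec["subtype"])
        thr = thresholds[rec["gene_id"]].threshold
        p_exp = expected_call_rate(flags, thr, mean, sd, shift)
        n = int(rec["n_tumors"])
        p_obs = rec["n_above"] / n if n else float("nan")
        if n and not math.isnan(p_exp):
            half = 1.96 * math.sqrt(max(p_exp * (1.0 - p_exp), 1e-12) / n)
            covered = abs(p_obs - p_exp) <= half
        else:
            covered = False
        rows.append(
            {
                "gene_id": rec["gene_id"],
                "subtype": rec["subtype"],
                "planted_fraction": planted,
                "called_percent": rec["percent"],
                "expected_percent": 100.0 * p_exp,
                "abs_error_percent": abs(rec["percent"] - 100.0 * planted),
                "covered_95": covered,
            }
        )
    return pd.DataFrame(rows)
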