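# Methods

## Overexpression calling

Expression values are analyzed on the log2 scale. RNA-seq input is linear
FPKM and is transformed as log2(1 + FPKM); RMA-processed microarray
intensities are treated as already log2 (a flag applies a plain log2 for
matrices declared linear). Negative FPKM values are rejected at cohort
construction.

Two threshold regimes share one statistic, mean + *k*·SD with *k* = 2 by
default:

* **tissue-restricted** (cancer-germline antigens, survivin, WT-1,
  GLULD1): calibrated on the normal-lung samples of the same cohort. This
  is an outlier test against the normal background — under a Gaussian
  null with tumors i.i.d. with normals, the expected call rate is the
  upper tail mass 100·(1 − Φ(*k*)) ≈ 2.275% at *k* = 2, which the test
  suite verifies by simulation.
* **fixed reference-calibrated** (HER2, MUC-1, which normal tissues
  express broadly): calibrated on a reference panel of samples designated
  non-expressing. The statistic for this regime was a genuinely open
  choice (a "signal level in reference tissues" pins down no estimator);
  we reuse mean + *k*·SD over the designated panel for symmetry between
  regimes, and the designation is explicit — by default the entire
  reference group, overridable per gene.

The SD is the sample SD (n − 1 denominator), standard for small normal
cohorts (n = 14 is typical for microarray lung series); at least two
calibration samples are required. A tumor sample is called overexpressed
when its value is **strictly greater** than the threshold — ties fall
below, the conservative reading of "over a threshold". Samples with
missing values are excluded from both numerator and denominator; subtypes
with no tumors are reported as not applicable rather than 0%. Percentages
are kept at full precision internally; the mixed display style (one
decimal below 20%, integer otherwise) applies only to rendered tables.

## Response calling

The ASTC frequency is 100·(multimer-positive events)/(gated CD8+ events),
in percent. Censoring at the limit of detection (LOD, default 0.01% of
CD8+ events) maps frequencies to max(*f*, LOD); detection requires
*f* > LOD with strict inequality, because values at the LOD are
indistinguishable from non-detections that are reported at the LOD.
Censoring is idempotent and commutes with detection.

Responses are called on the post-expansion frequency alone, with no
baseline subtraction: pre-culture precursor frequencies (~0.001% of CD8+
cells) sit an order of magnitude below the LOD and are generally not
measurable. Pooled dextramers sharing a fluorochrome resolve only the
pool, so calls attach to pools (canonical label: sorted, semicolon-joined
antigen names) and are never attributed to individual antigens within a
pool.

Cohort summaries use two denominators deliberately: per-pool responder
proportions divide by the number of patients actually tested on that pool
(peptide mixes differ between patients), while breadth (patients
responding to ≥ *k* pools) and the mean responses per patient divide by
the full cohort. Untested patient × pool cells are absent, never counted
as negative. The Melan-A specificity is an assay positive control: it is
tallied separately and excluded from breadth and means. Histology strata
are AC, SCC and "other" (carcinoid, large-cell neuroendocrine).

## Synergy scoring

For a patient × pool measured with and without anti-PD-1, both arms are
censored at the LOD before dividing, so a control arm below the LOD gives
a conservative finite fold instead of an infinite one; two sub-LOD arms
give exactly fold 1. Synergy requires fold ≥ 2 (a doubling; the boundary
counts) **and** a detected ICI arm, so a 2-fold wobble below the LOD can
never be called. De-novo responses — detected only with the ICI — are
flagged separately rather than folded into the ratio. Patient-level
tallies count each patient once however many of their pools respond.
Fold change is monotone in both arms and anti-symmetric (swapping arms
inverts the fold) whenever both arms exceed the LOD.

## Synthetic cohorts

The expression generator draws, per gene, a Gaussian background in log2
space for normal samples; each tumor sample is activated with a planted
per-subtype probability, which shifts its mean by a configured amount.
Ubiquitous genes are expressed (shifted) in every tumor and normal
sample; the reference panel carries a configurable non-expressing subset
(default: the whole panel, emulating calibration tissues chosen because
they do not express the genes), recorded in the truth file. For the FPKM
platform the generator emits linear values via 2^x − 1 (clamped at 0), the
exact inverse of the downstream transform, so calling is
platform-symmetric. Default design: 14 normals, 86 AC and 60 SCC tumors,
a 48-sample reference panel, background SD 0.5 log2 units, activation
shift 3 log2 units (an ~8-fold induction), and per-gene activation
fractions skewed toward SCC for the cancer-germline antigens with
survivin high in both subtypes — the qualitative pattern reported for
NSCLC cohorts.

The flow generator draws, per patient × pool, a responder flag
(probability 0.5 by default, configurable per pool); responders carry a
post-expansion frequency drawn **log-uniformly** from 0.026%–3.82% (the
observed range spans more than two decades, so a log-uniform spread is
the natural one-parameter-free choice), non-responders stay at the
precursor frequency (default 0.001% of CD8+ cells). Observed counts are
binomial in the tube's CD8+ events (default 50,000, consistent with a
0.01% LOD corresponding to a ~5-event floor). Paired ±ICI tubes share
the responder flag and base frequency; with probability 0.625 (5/8, the
observed synergy rate) a responder's ICI tube is multiplied by the fold
effect (default 3, within the observed two-to-nine-fold range). By
default only responders can be boosted; de-novo responses arise when a
responder's control-arm draw lands below the LOD. All draws flow through
one `numpy.random.Generator` seeded from a single integer; identical
configs and seeds are byte-reproducible, including written fixture
bundles (verified by sha256 manifest).

What the generators do **not** emulate: probe-level microarray noise and
normalization artifacts, batch effects, correlated co-activation of
antigens within a patient, event-level flow cytometry (gating,
compensation, viability), or inter-tube variation in gated CD8+ counts.
Passing recovery tests therefore show that the callers read back what the
generative model planted under idealized Gaussian/binomial noise — not
that the thresholds are optimal for real cohorts.

## Parameter recovery and numerical choices

The recovery harness compares called rates to the **truth-implied
expectation**, not to the raw planted fraction: with an activation shift
of 4 SD and a 2-SD cutoff, the expected call rate is
*f*·Φ(shift/σ − *k*) + (1 − *f*)·(1 − Φ(*k*)) — the background tail
inflates low fractions (~2.3 points at *f* = 0) and detection misses
deflate high ones (*f* = 0.99 yields ≈ 96.8%). Per gene × subtype the
harness computes the expected rate from the realized threshold and the
planted flags and checks the observed count against a 95% binomial
interval around it; because the count is Poisson-binomial, the binomial
interval at the mean rate is conservative. Acceptance-level checks assert
nominal coverage across planted fractions {0, 0.2, 0.4, 0.85, 0.99} × 20
seeds (200 tumors, 50 normals each).

Other conventions: thresholds must be finite (degenerate all-equal
calibration values give SD 0 and threshold = mean, which is valid);
duplicate patient × pool × condition observations are rejected rather
than averaged; unpaired ±ICI tubes are skipped by the synergy scorer;
empty response matrices are an error for summarization. Problem sizes in
the acceptance script (10⁴ samples for the null calibration, 200
tumors × 20 seeds for activation recovery, 100 patients × 10 seeds for
responder recovery, 200 patients for the ICI recovery) were chosen so
Monte-Carlo standard errors sit well inside the assertion tolerances.

## Known limitations

* The per-patient response grid behind published breadth percentages
  (e.g. the share of patients with ≥2 or ≥4 responses) is generally not
  recoverable from marginal per-antigen tallies; `summarize_pool_tallies`
  therefore reports only marginal-derivable statistics, and breadth is
  computed only when a full response matrix is available.
* The fixed-reference regime's estimator is a design choice (see above);
  with a different convention (e.g. a percentile of the reference
  distribution) ubiquitous-gene percentages would shift.
* Fold changes near the LOD are noisy: with true 3-fold amplification at
  the low end of the expansion range, binomial counting noise pushes a
  few percent of pairs below the 2-fold cut, a small negative bias the
  synergy-recovery tests account for explicitly.
* The pipeline consumes tabulated event counts; gating from raw FCS
  files, phenotyping and functional readouts are out of scope.
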