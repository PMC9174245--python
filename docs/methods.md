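# Methods

This note documents the models, conventions and design choices behind
`btcmeth`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Coordinates and data model

Genomic intervals are 0-based half-open internally; all user-facing CGI
labels are 1-based inclusive UCSC style (`chr2:176993479-176995557`),
and the parser/renderer round-trip exactly. CGI intervals come from a
4-column BED and must be disjoint within a chromosome — the loader
rejects overlaps rather than resolving ties, so a probe belongs to at
most one island. Strand is ignored throughout: β-values are
strand-symmetric at the CpG level. β matrices are probes × samples TSV
with `NA` for missing; probes missing in more than 20% of samples are
dropped with a logged count before analysis.

## Synthetic cohort model

The generator emulates the statistical structure of an FFPE tumour /
normal methylation-array study at island resolution. Its defaults are
the package's reference study conditions and are chosen once:

| parameter | default | meaning |
|---|---|---|
| `n_tumour`, `n_normal` | 50, 10 | discovery-style design |
| `n_cgis` | 200 | islands in the desk-scale universe |
| `probes_per_cgi` | 4–10 | probes averaged per island |
| `n_hyper`, `n_hypo` | 20, 2 | planted alterations (≈10:1 hyper:hypo, the imbalance seen in biliary tumours) |
| `delta` | 0.35 | CGI-level effect in β units (middle of the relevant 0.2–0.5 range) |
| `normal_mean_range` | 0.03–0.15 | baseline β of candidate (hypermethylatable) islands |
| `background_mean_range` | 0.03–0.97 | support of the null background |
| `kappa` | 50 | Beta concentration of probe noise |
| `purity_range` | 0.6–1.0 | tumour cell fraction |
| `n_ffpe_degraded` | 0 | samples corrupted by the FFPE model |

Generation proceeds per island: a normal-tissue mean is drawn
(uniformly in `normal_mean_range` for planted hyper islands; uniformly
in roughly 0.5–0.9 for planted hypo islands, so there is room to lose
`delta`; from a sharply U-shaped Beta(0.2, 0.2) rescaled to
`background_mean_range` for the null background, because array β
distributions are strongly bimodal with only ~10–15% of probes at
intermediate methylation). Per-probe means jitter around the island
mean on the logit scale (sd 0.3), drawn once per probe — this mimics
the probe-to-probe variation visible in per-CpG profiles. A planted
island shifts the **tumour-cell** mean by ±`delta`; the observed tumour
mean is the purity-weighted mixture

    μ_obs = purity · μ_tumour-cell + (1 − purity) · μ_normal,

linear in β because β is a fraction of methylated alleles over a
mixture of cell populations. Observed values are drawn
Beta(μκ, (1−μ)κ). Everything is deterministic given the seed.

FFPE degradation is phenomenological, reproducing only the QC-relevant
symptom (aberrant, intermediate-heavy β distributions): selected
samples' values are shrunk toward 0.5 by the severity factor plus
Gaussian noise (sd = 0.08 · severity), which provably inflates the
intermediate-β fraction monotonically in severity. Degraded samples
are drawn from the tumours first — FFPE tumour blocks are the
degradation-prone material — spilling into normals only when the
requested count exceeds the tumour count. It does not model
bisulfite-conversion chemistry, crosslinking, batch effects,
SNP-affected probes or copy-number interactions — so passing QC tests
demonstrates that the filter catches this *kind* of aberration, not
that it reproduces any particular laboratory failure mode.

Multi-cohort generation shares one CGI/probe universe: replication
cohorts reuse the discovery cohort's planted labels; other-cancer
cohorts receive a chosen fraction of the discovery hyper set (the
shared gastrointestinal alterations the specificity filter must
remove) plus their own private alterations drawn from the null pool.
The ground truth records which planted islands are disease-specific.

ddPCR tables are simulated from the same Poisson physics the caller
assumes: positive-droplet counts are Binomial(accepted, 1 − e^(−λ))
with class-specific mean copies per droplet λ, and the multiplexed
control channel is always positive-rich.

## Sample QC

The published filtering step that reduced the discovery cohort is not
described beyond its effect, so the rule here is a declared surrogate:
exclude a sample when its intermediate-β fraction (share of probes
with 0.3 < β < 0.7) exceeds **0.35**, or its bimodality coefficient
falls below **5/9 ≈ 0.556** (the uniform distribution's value; good
bisulfite arrays are strongly bimodal and score well above it, while
shrunk-to-0.5 degradation scores below). Both thresholds are
configurable and every exclusion is reported with its scores; a
matched normal is never auto-excluded when its tumour fails. The score
nominally requires ≥1,000 non-missing probes; the pipeline relaxes
this to the available probe count on small simulated panels. QC runs
on probe-level values, before island aggregation.

## Differential methylation

Probe β are averaged (missing ignored) per island and sample; islands
with fewer than 3 probes are dropped. Δβ is the difference of
island-level group means. "Combined P" is Fisher's combination of
per-probe two-sided Welch t-tests (default), with Stouffer's method
and a single Welch t-test on island means as alternatives; p-values
are clamped to [1e-300, 1]. BH adjustment runs across all islands and
both nominal and adjusted values are reported — small discovery
cohorts typically retain nothing after FDR, and the working criterion
is the nominal Δβ > 0.20, P < 0.05 pair. Matched pairing is ignored by
the tests (groups are pooled); pair ids are kept for reporting.

Fisher's method assumes independent probe-level tests; within-island
probe correlation would inflate the statistic. In the generator,
probes are conditionally independent given their means, and the
measured null rate of `combined_p < 0.05` is calibrated (the suite
asserts the pooled rate over 100 null seeds lies in [0.02, 0.10]). On
real arrays with correlated probes the combined P is anti-conservative
and should be read as a ranking score, as in the nominal analysis it
reproduces.

The somatic-change matrix is per-tumour: β(tumour) minus the average
normal β per island; its tumour-wise mean equals Δβ by construction.

## Marker selection and panel search

The filter chain (hyper + normal-low → replication → cross-cancer
specificity) is set-monotone, and each `MarkerSet` carries provenance
tags. Markers absent from a replication cohort are counted
*untestable* and reported, never silently kept; markers absent from an
other-cancer cohort cannot be excluded by it (logged). Replication
overlap is scored by the upper-tail hypergeometric probability
P(X ≥ k), computed via the survival function in log space.

The proprietary panel-ranking tool used in the original study is not
published; `btcmeth` implements its observable contract as a
transparent exhaustive search. Per-marker positivity thresholds are
fit on training data only, by Youden's index (best-accuracy optional),
with candidate thresholds at midpoints between consecutive distinct
scores; ties break toward the higher (more specific) threshold, and
an all-tied score vector yields +∞ ("call everything negative"). A
panel calls a sample positive if any member exceeds its threshold
(OR rule); its continuous ROC score is the maximum member β (mean
optional). Panels are ranked by (fully-evaluated first, mean
validation AUC, mean sensitivity, mean specificity, smaller size,
lexicographic marker ids) — a total order, so the ranking is
deterministic and independent of candidate input order. The search is
exhaustive over combinations of size ≤ 3 from at most 40 candidates;
the pipeline caps candidates at the 15 largest discovery Δβ by
default. The fitted panel is exposed as a scikit-learn estimator
(`MarkerPanelClassifier`).

## Clustering and clinical association

Samples are clustered on island-level matrices with Euclidean distance
and Ward linkage (the standard choice for methylation heatmaps;
configurable), after imputing missing islands with column means.
Cluster–clinical association uses the two-sided Fisher exact test on
2×2 tables built from the study's own dichotomies: stage I–II vs
III–IV, and clusters containing normals ("mixed") vs tumour-only
clusters.

## ddPCR calling and quantification

Target molecules distribute over droplets approximately Poisson, so
λ = −ln(1 − positives/accepted) and concentration = λ / droplet
volume; the droplet volume defaults to 0.85 nL (QX200 convention,
configurable). Saturated wells (every droplet positive) are an error.
A sample is *invalid* when its multiplexed control channel shows fewer
than 1 positive droplet; invalid samples are excluded from
sensitivity/specificity denominators and reported separately, the
convention matching the exclusion of a both-assays-negative tumour in
the validation series. Positivity uses a threshold on target
positive-droplet counts: fixed at 3 droplets by default, or derived
from ROC on the counts with the Youden (default) or best-accuracy
criterion — the two criteria can disagree on borderline samples (a
benign sample with three positive droplets flips between them), which
is why both are exposed. Assay AUC uses the raw positive-droplet
counts as scores. Panels combine by OR; a sample is invalid only when
all member assays are invalid.

## Power

The canonical calculation is the two-sided two-sample normal
approximation with known σ:

    z = Δ / (σ √(1/n₁ + 1/n₂)),   power = Φ(z − z₁₋α/₂) + Φ(−z − z₁₋α/₂),

which returns exactly α at Δ = 0. σ defaults to 0.09, the
90th-percentile probe SD observed in normal tissue of public
cholangiocarcinoma array data (median 0.02) — any σ ≤ 0.127 yields a
display value of 100% at the 50 vs 10 discovery design, so the
headline power claim is robust to this choice. The Monte-Carlo
cross-check draws groups from Normal(0.5 ∓ Δ/2, σ) clipped to [0, 1]
(means symmetric around 0.5 keep truncation negligible at realistic
σ; the truncation rate is reported) and applies either the Welch
t-test (default — the test a practitioner would run) or the
known-variance z-test. The z-test simulation matches the analytic
formula within Monte-Carlo error; the Welch t-test sits slightly below
it at small, unbalanced designs (up to ~5 percentage points at
n = 30 vs 10 with small effects, a small-sample property of the
normal approximation), converging at the designs of interest.

## Pipeline determinism and problem sizes

The run config carries a single seed; each stage derives a child seed
by stable hashing of its name, so stages can be re-run in isolation
and whole runs are byte-identical given the same config. All
thresholds default to the working criteria above (Δβ 0.20, P 0.05,
normal-β 0.20). Test and demonstration cohorts use desk-scale problem
sizes — tens of samples, 30–200 islands of 3–10 probes — chosen so
that planted effects at Δβ = 0.4 and κ ≈ 80–100 are comfortably
detectable and full multi-seed property checks (50–100 replicates)
remain quick; the statistical structure, not the scale, is what the
checks exercise.

## Known limitations

* The QC rule, the probe-combination method and the panel-search
  internals are declared surrogates for unpublished procedures; all
  are configurable and their defaults documented above.
* The generator does not model probe correlation within islands,
  batch/chip effects, cell-type composition or copy-number aberration,
  so calibration results transfer to real arrays only qualitatively.
* Region-growing DMR detection, array normalisation and IDAT parsing
  are out of scope: the pipeline starts from a normalised β matrix.
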