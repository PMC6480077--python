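# Methods

## Data model and conventions

Raw qPCR panel data are sample × assay grids of quantification cycles
(Cq). Every absent or undetermined measurement is carried as NaN from
parsing onward; no imputation happens anywhere in the pipeline. All
quantities are in PCR cycles unless noted.

**Detection filter.** A target that does not cross the amplification
threshold within `max_cycles` (default 40) carries no abundance
information. The cutoff is inclusive: a reported Cq of exactly 40 is read
as "did not reach threshold within 40 cycles" and masked. The filter is
idempotent; assays detected in zero samples are retained in the matrix but
listed in an exclusion report so downstream panels can drop them.

**ΔCq direction.** ΔCq = Cq(target) − mean Cq(reference). This is the only
direction under which "higher −ΔCq = more abundant miRNA" holds (lower Cq
means more template), and it is the convention the packaged reference
cohort requires; descriptions of the normalization that subtract the
target from the controls circulate as well, but they are inconsistent with
that sign convention and we treat them as errata. The reference is the
mean over *detected* internal-control assays only (five defaults:
miR-425-5p, miR-423-5p, miR-103a-3p, miR-191-5p, miR-93-5p); a sample with
zero detected controls is a hard per-sample error, never silently imputed.
Global-mean normalization (reference = mean of all detected assays in the
sample) is available as an alternative. Both are shift-invariant: adding a
constant to every Cq of a sample leaves its ΔCq row unchanged.

## Differential testing and marker selection

ΔΔCq = ΔCq(24 h) − ΔCq(0 h) per subject and assay; only complete pairs
contribute. Each assay gets a paired (one-sample) t-test of ΔΔCq against
zero, two-sided — sidedness is not dictated by the design, and two-sided
is the conservative choice. BH q-values are computed within each drug's
panel separately (each study is tested on its own), over all assays with
≥ 2 complete pairs. Degenerate zero-variance differences are reported with
p = 0 (nonzero mean) or p = 1 (all-zero) plus a `degenerate` flag instead
of crashing, so a pathological assay cannot abort a 179-assay run.

The common signature across two drugs takes assays with q < 0.05 in both
and the same direction in both; significant assays with conflicting
directions are excluded and reported. "Clearest change" for the final
panel is operationalized as largest |mean ΔΔCq| in the reference drug's
result, with ties broken by smaller q and then assay id so selection is
deterministic. The shipped default panel is the fixed 4-up/4-down set
(up: miR-423-3p, let-7a-5p, miR-26a-5p, let-7f-5p; down: miR-144-3p,
miR-451a, miR-215, miR-363-3p).

## MOR signal score and stratification

score = −Σ ΔCq(up) + Σ ΔCq(down). The score is a sum, not a mean, so it is
defined only when all eight markers are present; patients with incomplete
rows get NaN scores and the label `unassigned`, and flow through all
reports as such rather than aborting the cohort. Swapping the up and down
lists negates every score exactly.

**Clustering.** Patients are stratified by agglomerative clustering of the
eight-marker ΔCq rows, cut at k = 2. Defaults: **correlation distance,
complete linkage**. This was a genuinely open design point and we chose by
behaviour, not convention: the two biological classes are mirror images of
each other in profile shape (up markers high / down markers low, and vice
versa), while the dominant Euclidean structure in marker space is the
per-patient abundance offset and the large fixed between-marker baseline
differences (e.g. miR-451a sits ~10 cycles from miR-215 in every patient).
Euclidean/average-linkage clustering of the reference cohort therefore
degenerates to a 24-vs-1 outlier split; correlation distance with complete
linkage recovers a 17/8 partition that is exactly monotone in the score,
and on synthetic mirrored cohorts (separation 2.0 cycles, within-class SD
0.7) recovers the planted classes with mean adjusted Rand index ≈ 1.0.
Euclidean, cityblock, cosine distances and average/complete/Ward/single
linkage remain selectable via `ClusteringSpec`. No feature scaling is
applied (all markers share cycle units). Cluster labels are oriented
deterministically: the cluster with the higher mean score is class 1, so
the output is invariant to patient order and dendrogram orientation. The
merge list (scipy linkage matrix) is exposed for inspection. Fewer than 3
complete rows, or all rows identical, is a classification error.

## Efficacy and association

Baseline VAS = mean over available days {−3, −2, −1, 1}; treatment VAS =
mean over available days {2, 3, 4}; ΔVAS = treatment − baseline (mm,
negative = improvement). Windows average whatever days are present —
requiring complete windows would discard patients that the reference
analysis evidently kept — and the contributing-day counts are always
emitted so a stricter policy can be audited; an empty window makes ΔVAS
missing.

Spearman rho uses mid-ranks; its two-sided p uses the t-approximation
t = rho·√((n−2)/(1−rho²)) on n−2 df, which is standard at the cohort sizes
involved (n ≈ 23). An exhaustive-permutation p is computed alongside
whenever n ≤ 10. Fisher's exact test on class × (ΔVAS > 0 vs ΔVAS ≤ 0) —
ΔVAS = 0 counts as "not improved" because the enrichment hypothesis is
about ΔVAS strictly > 0 — uses the two-sided convention of summing
hypergeometric probabilities of tables no more probable than the observed
one. The reported odds ratio is the sample cross-product ratio, with the
Haldane 0.5 correction applied for display only when a cell is zero. The
0.01 significance threshold is a report annotation, not a gate: all
p-values are always emitted.

## Synthetic data

The healthy-subject generator emulates paired single-dose panels: 6
subjects × 179 assays by default. Each assay draws a baseline Cq (controls
near 22 and stable, targets spread around 28); each subject draws a
loading offset shared by both timepoints, which normalization must cancel;
measurement noise is Gaussian on the Cq scale with SD 0.5 cycles (log-scale
measurement error is approximately Gaussian in cycles), and internal
controls receive only 0.1-cycle drift. Planted effects default to 1.0
cycle on the eight default markers, lowering post-treatment Cq for
up-regulated assays.

The patient-cohort generator draws a latent class per patient
(default 25 patients, 0.68/0.32 — the composition of the reference
cohort), mirrored marker profiles 2.0 cycles apart with within-class SD
0.7 on Table-2-like per-assay baselines, and daily VAS with patient-level
baseline 14 ± 10 mm, day noise 5 mm and a class-dependent post-switch
shift of ±`dvas_effect`/2 (default 4 mm between class means — the
class-mean ΔVAS gap observed in the reference cohort). VAS is clipped to
[0, 100] after noise and the clipping rate is reported so configurations
stay in the linear regime. Days are dropped at `missing_day_rate`
(default 5%). Truth tables (latent class, expected ΔVAS, planted effects)
are always emitted; tests compare against truth files, never against
generator internals. Randomness: one `numpy` Generator seeded from
`(seed, stream)` per call — same seed, byte-identical outputs; the drug
label hashes (CRC-32) into the stream so two drugs give independent panels
under one seed.

What the generator does *not* emulate: PCR efficiency differences,
inter-plate calibration, heavy-tailed contamination or platelet-derived
confounding of plasma miRNA, circadian or comorbidity effects on
expression, and any pharmacokinetic dose–response structure. Passing the
simulation suite therefore shows the statistical machinery behaves
correctly under the stated noise model, not that the eight-marker score is
clinically valid on new data.

## Numerical and reporting choices

Internal computation is full precision; scores and marker values are
rounded to 1 decimal only at report boundaries, where marker values are
presented in −ΔCq units as reference tables print them. Ranked reports
sort by descending score with ties broken by patient id and missing scores
last. The paired-difference recovery property is evaluated at the level of
the ΔΔCq observations themselves (shift 1.0, SD 0.5, n = 6): the noise
there is the noise of the quantity the t-test sees, independent of how it
decomposes into per-measurement and reference-average components.

## Problem sizes

The simulation checks use 200 replicates for null-panel FDR control and
marker recovery, 100 for cohort class recovery, and 500 null cohorts
(n = 23) for the level of the association tests; Fisher-oracle equivalence
enumerates every 2×2 table with all margins ≤ 30, and exact-permutation
Spearman equivalence enumerates all orderings at n ≤ 7. These sizes give
stable estimates for the thresholds being checked while keeping the whole
suite fast on one CPU.

## Known limitations

The reference cohort ships with published, rounded (1 dp) −ΔCq inputs, so
recomputed scores can differ from the published score column by up to 0.2
cycles; five rows reproduce exactly and are asserted as such. The true
class boundary of the published stratification is not recoverable from the
published material (no class column is printed), so the enrichment test is
additionally asserted under every score-monotone split with a boundary
between ranks 12 and 17. The healthy-subject differential results
themselves (4 commonly up- and 16 commonly down-regulated miRNAs) are not
reproducible here because the raw panel data were never deposited; the
selection machinery is validated on synthetic re-enactments instead.
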