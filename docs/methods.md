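# Methods

This note documents the statistical conventions, the synthetic-data model,
and the design choices made where more than one reasonable reading existed.

## Percentile normalization

**Model.** For each marker gene and cycle day (LH+6..LH+11), the reference
distribution of expression is summarized by its empirical quantile
function. ΔCt values (Ct(target) − Ct(L19)) are negated into expression
scores before ranking, so a higher percentile always means higher
expression; this orientation is what makes the defect rules (low SCARA5
percentile = failed decidualization) meaningful. uNK percentages enter the
same machinery unnegated.

**Interpolation.** Percentiles use Hazen plotting positions
p_i = 100·(i − ½)/n on the sorted scores, midrank-averaged within tie
groups, with linear interpolation between distinct scores and clamping to
0/100 outside the reference range. Consequences worth knowing:

* the smallest reference score maps to 50/n, not 0 — only queries strictly
  below the range clamp to 0;
* self-assigned reference percentiles are uniform up to a 0.5/n
  discrepancy, which is what the calibration tests check with a
  Kolmogorov–Smirnov statistic;
* the mapping is monotone non-decreasing in expression by construction.

The exact centile convention used to draw the original reference graphs is
not published; Hazen positions were chosen as a standard, continuous
convention and are recorded in the curve metadata.

**Sparse days.** `min_per_day` (default 20 observations) guards curve
quality. A day below the minimum is pooled with its nearest neighbouring
days (distance ties resolved toward the earlier day) until the minimum is
reached; pooling is recorded in curve metadata and an error is raised if
the whole reference cannot reach the minimum. The motivating reference had
30–46 samples per day, so pooling is a guarded extension, not a modelled
behaviour.

**uNK quantification.** uNK abundance is the number of CD56⁺ cells per 100
stromal cells averaged over three images; any image with a zero stromal
count is an error rather than a silent skip.

## Defect rules, binning and cohort tests

Thresholds follow the printed inequalities literally: ≤ 30th and ≥ 70th
percentile are inclusive; the uNK rule requires both markers strictly
inside (30, 70). The three defect regions are mutually exclusive by
construction (the two marker-low rules split on DIO2; the uNK rule
requires SCARA5 > 30), and everything else — including combinations the
rules do not name, such as SCARA5 ≤ 30 with mid-range DIO2 — is `none`.
An exhaustive scan of the integer percentile grid is part of the test
suite.

The cohort bin score is SCARA5 + uNK percentile (DIO2 participates in
classification but not in the bin sum). How the original four bins were
bounded is not recoverable from the published occupancies (they exclude
equal-frequency quartiles), so the default is four equal-width bins on
[0, 200] with edges 50/100/150, half-open except the closed top bin, and
fully configurable.

2×2 contingency tables are tested with Fisher's exact test, two-sided by
hypergeometric tail summation (all tables at most as probable as the
observed one — the scipy convention). Larger tables use χ² without
continuity correction; the per-defect 2×2 χ² comparisons reported by
`screen_cohort` keep the Yates correction, since small defect counts are
the rule there. Degenerate tables (an absent category) skip the test
rather than fabricate a p-value.

## Synthetic cohorts

The generator emulates the case/control study design: per subject a group,
a biopsy day uniform on LH+6..11, marker ΔCt values, and three
CD56⁺/stromal image-count pairs.

* **ΔCt model.** Normal per (gene, day), with day-varying means — SCARA5
  induced across the window (mean ΔCt 7.0 → 4.2, sd 1.2), DIO2 rising
  toward menstruation (9.0 → 5.8, sd 1.5). Typical qPCR scales for
  moderately expressed transcripts; the true across-subject distribution
  of ΔCt is not published, and Normality is a stand-in chosen for exact
  quantile inversion. Values are clipped at zero (≥4 sd away at the
  defaults).
* **Latent classes.** Each subject carries a class in {normal,
  decid_failure, excess_senescence, unk_deficiency}. Class prevalences are
  planted *exactly* — largest-remainder apportionment of n·p per group,
  order shuffled by the seed — so recovery tests measure pipeline error,
  not the generator's own sampling noise. Default prevalences produce an
  aberrant response in 44% of the RPL arm and 14% of controls, dominated
  by senescence and uNK deficiency, matching the published cohort.
* **Percentile-space realization.** A class is realized by drawing
  percentiles uniformly inside its rule region (e.g. decidualization
  failure: both markers on [0, 30]) — normals by rejection from the
  complement — and inverting through the generative day-specific quantile
  functions. Scored back against those quantiles, planted classes are
  recovered by construction; `generative_curves()` exports them as a
  dense-grid `CentileCurveSet` (4001 quantile knots, interpolation error
  well under 0.1 percentile points).
* **uNK image counts.** The latent uNK percentage (Normal(10, 2)
  reference) is converted to three image pairs with stromal fields of
  150–250 cells and cd56 = round(pct · stromal/100). The rounding is the
  only image-level noise: through a Normal(10, 2) reference the percentile
  axis is steep (~17 points per percentage point), so binomial per-image
  sampling would translate into tens of percentile points and planted
  classes would stop being recoverable. Real image counts are noisier than
  this; the generator trades that realism for a sharp end-to-end test.

What passing these tests shows: the centile/screening machinery is
self-consistent and recovers planted truth exactly. What it does not show:
robustness to the quantile-estimation noise of a finite empirical
reference (a ~40-per-day reference has ~7-percentile standard error near
the 30th percentile — subjects near a rule boundary genuinely flip), nor
to assay-level noise in ΔCt or uNK counts.

## Synthetic count matrices and barcode reads

Count matrices are negative binomial (size = `nb_dispersion`, default 2)
around state-specific means, then zeroed by independent Bernoulli dropout
(default rate 0.3). Baseline gene weights are log-normal; module genes
(defaults: 30 DC-like, 30 snDC-like of 200) are elevated 8-fold in their
own state; per-state weights are renormalized so the expected library size
(default 2000 counts) is state-independent. Branch proportions default to
0.78 DC / 0.13 snDC / 0.09 trunk, the day-6 composition of the decidual
time course. Not modelled: doublets, batch effects, ambient contamination
of real cells, gene–gene correlation beyond module membership.

Barcode reads are log-normal: real barcodes (σ = 0.25) above an ambient
population (σ = 0.5), means on the natural scale, floor of one read.

## Cell calling, QC, imputation, marker partitioning

* **Knee point.** Barcodes are ranked by descending reads (identifier as
  deterministic tiebreak); the knee is the point of maximum perpendicular
  distance between the cumulative-read-fraction curve and the chord
  joining its endpoints, both axes normalized. If that distance is below
  10⁻³ of the chord length the input is flagged knee-less and every
  barcode is returned. The statistic needs a bimodal read distribution:
  a single smooth population (no ambient background) has genuine curvature
  and will yield a knee somewhere inside it — a documented limitation, not
  a bug.
* **QC order.** (1) cells by detected-gene bounds (≥200 kept, >4500
  removed — "more than" is exclusive on both the gene and the 5%
  mitochondrial rule), (2) cells by mitochondrial fraction computed on the
  full gene set, (3) genes by support in the surviving cells (≥3). The
  source toolkit applies these jointly; the order here is fixed for
  reproducibility and makes the filter idempotent on typical data
  (re-filtering can in principle remove a cell whose detected-gene count
  was propped up by discarded genes).
* **Normalization.** Per-cell scaling to the median library size, then
  log1p. The upstream publication delegates this step to a toolkit
  default, so the choice is explicit and configurable here.
* **Imputation.** A deliberately simple graph diffusion rather than the
  adaptive-kernel original: symmetric union k-NN affinity with self loops
  (k = 15), row-normalized to a Markov matrix, t = 3 diffusion steps
  applied to expression. t = 0 is the identity; constant genes are fixed
  points; on a complete graph the transition is doubly stochastic and
  gene means are preserved. The contract served — graph smoothing before
  thresholding marker expression — is the same, and the linear operator
  has a closed-form oracle (explicit matrix powers) used in the tests.
* **Marker partitioning.** "Midpoint of the expression levels" is read as
  the midpoint of each gene's min–max range on the imputed matrix (the
  most literal reading; median or mean would also be defensible). Cells
  strictly above one marker's midpoint and strictly below the other's are
  assigned to the corresponding enriched/reduced class; everything else is
  intermediate; a zero-range gene is an error.
* **Rank-sum tests.** Exact two-sided Mann–Whitney p-values for tie-free
  groups up to 25; otherwise a tie-corrected normal approximation without
  continuity correction, so identical groups give p = 1 exactly.
  Bonferroni adjustment over the tested genes.

## Co-expression modules and congruency

* **Correlation k-means.** Distance 1 − Pearson, implemented as spherical
  k-means on row-standardized profiles — assignment and the normalized-
  mean centroid update both monotonically decrease the objective, which
  the tests assert. Initialization is k-means++-style in correlation
  distance; the best of 5 restarts (within the 50-iteration cap) is kept,
  deterministically given the seed. Constant-profile genes have undefined
  correlation and go to a reserved "flat" module (−1), excluded from the
  objective and reported by warning.
* **Figure of merit.** Yeung's leave-one-condition-out formulation: for
  each left-out condition, genes are clustered on the rest and the FOM is
  the RMS deviation of the left-out values from their cluster means,
  averaged over folds and divided by √((n − k)/n). The suggested k is the
  elbow — the interior k with the largest second difference. FOM operates
  on raw expression values, so per-gene scale differences inflate it even
  when profiles correlate perfectly; "distinct patterns" for recovery
  tests are therefore constructed mutually uncorrelated (orthogonalized
  centered profiles), which is what distinctness means to this metric.
* **Congruency.** For each unordered pair of the supplied branch genes,
  the Pearson correlation across cells is computed in each dataset and
  summed (range −2..+2); |sum| > 1 is congruent. Self-pairs are reported
  (sum exactly 2) but excluded from enrichment; pairs touching a
  zero-variance gene are undefined, excluded and counted. Evaluating two
  in vivo days means running the statistic per day and intersecting the
  congruent sets. The default enrichment null permutes gene identities of
  the second dataset (equivalently, symmetric permutation of its
  correlation matrix), with p = (1 + #{null ≥ observed})/(1 + n_perm);
  the add-one estimator makes the p-value conservative (super-uniform
  under the null), which the calibration tests verify. A hypergeometric
  variant exists but requires explicit urn parameters — the original
  test's parameterization is unstated, so none is silently assumed.
* **Marker filters.** Sequential: stromal enrichment (significant rank-sum
  vs *every* other cell type with log2 fold change ≥ 1, Bonferroni-adjusted
  p ≤ 0.05), epithelial non-regulation (max/min temporal fold change
  ≤ 1.5), and a required direction of late-luteal change in stroma
  (sign of last minus first condition). The published criteria are
  qualitative; all three thresholds are config-exposed, and the audit
  records which filter removed each gene. The ranking of "top branch
  genes" is an input — trajectory modelling is out of scope — with a
  convenience ranking by absolute between-state mean difference for
  synthetic data.

## Problem sizes used in the checks

The shipped tests and the acceptance script run on deliberately small
instances: 10-gene/20-cell congruency oracles, 200-replicate null
calibrations at 199 permutations, 250-sample percentile references,
500-subjects-per-arm recovery cohorts, 1000–8000-barcode knee curves, and
70-gene/9-condition FOM scans over k = 1..12 with 20 seeded repeats.
These sizes make every check exact or tightly calibrated while keeping a
full run in seconds; all of them are parameters, not limits of the
implementation.

## Known limitations

* The Normal-per-day ΔCt model and the rounded uNK image counts are
  stand-ins; no claim is made that they match real assay noise.
* The empirical reference machinery is exercised with synthetic
  references; the historic 1997-biopsy uNK reference and day handling
  outside LH+6..11 are external and not reproduced.
* Knee calling presumes an ambient background below the real-cell
  population.
* The hypergeometric congruency test is an interpretation that the caller
  must parameterize.
* Alignment, barcode error correction, clustering/embedding, trajectory
  inference, deconvolution and GO enrichment are out of scope; branch gene
  lists are inputs.
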