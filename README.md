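# decidua

Screening tools for decidual-pathway defects in cycling human endometrium,
plus the single-cell computations that underpin the marker choice.

## The problem

During the luteal phase, endometrial stromal cells (EnSC) decidualize and
then diverge into two fates: stress-resistant decidual cells (DC) and
senescent decidual cells (snDC). Uterine natural killer (uNK) cells are
thought to clear the senescent subset; failure anywhere along this pathway
— too little decidualization, too much senescence, or too few uNK cells —
is a candidate mechanism for recurrent pregnancy loss (RPL). Because
marker expression and uNK abundance change day by day across the
implantation window (LH+6..LH+11), raw measurements are only comparable
after normalizing to the day of the cycle.

`decidua` implements that analysis as a reusable, tested pipeline:

* **Percentile reference curves** (`decidua.centiles`). Per gene and cycle
  day, an empirical quantile function built from a reference cohort of
  RT-qPCR ΔCt values (ΔCt = Ct(target) − Ct(L19); lower ΔCt = higher
  expression). A new biopsy's ΔCt maps to a 0–100 expression percentile
  via Hazen plotting positions ((i − ½)/n, midrank ties, linear
  interpolation, clamped at 0/100). uNK abundance — CD56⁺ cells per 100
  stromal cells, averaged over three images — is normalized the same way.
* **Defect classification** (`decidua.screening`). With S, D, U the
  SCARA5, DIO2 and uNK percentiles:
  decidualization failure = S ≤ 30 ∧ D ≤ 30;
  excessive decidual senescence = S ≤ 30 ∧ D ≥ 70;
  uNK-cell deficiency = U ≤ 30 ∧ 30 < S < 70 ∧ 30 < D < 70;
  otherwise none. The three regions are provably disjoint. Cohorts are
  additionally binned on S + U ∈ [0, 200] (four equal-width bins by
  default) and group differences tested with Fisher's exact test (2×2)
  or χ².
* **Single-cell support** (`decidua.preprocess`, `decidua.network`).
  Knee-point cell calling on the barcode rank curve, QC filters
  (≥200 / ≤4500 genes per cell, ≤5% mitochondrial reads, ≥3-cell gene
  support), median-library log normalization, k-NN Markov-diffusion
  imputation, midpoint marker partitioning
  (SCARA5-enriched/DIO2-reduced cells vs the converse), rank-sum marker
  tests with Bonferroni correction, FOM-guided k-means co-expression
  modules (Pearson metric), and the gene-pair *congruency* statistic:
  for a gene pair, the sum of its Pearson correlations in two datasets
  (range −2..+2), congruent when |sum| > 1, with permutation or
  hypergeometric enrichment tests.
* **Synthetic data with planted truth** (`decidua.simulate`). Cohorts with
  latent defect classes realized in percentile space and inverted through
  day-specific quantile functions; branch-structured negative-binomial
  count matrices with DC-like and snDC-like gene modules; barcode read
  distributions with ambient background; planted co-regulation patterns.

## Worked example

Simulate the default study design (90 control and 89 RPL subjects with the
published defect mix), score every subject against the day-specific
reference curves, and screen:

```python
import decidua as dc
from decidua.centiles import score_cohort

cfg = dc.CohortSimConfig(seed=1)            # 90 control / 89 RPL
cohort, truth = dc.generate_cohort(cfg)
curves = dc.generative_curves(cfg)
per_subject, summary = dc.screen_cohort(score_cohort(cohort, curves))

print(summary["defect_counts"])
for grp, inc in summary["aberrant_incidence"].items():
    print(f"{grp}: {100*inc:.1f}% aberrant")
print(f"Fisher exact p = {summary['aberrant_test']['p_value']:.2g}")
```

```
group              RPL  control
defect
decid_failure        6        5
excess_senescence   20        4
unk_deficiency      13        3
none                50       78
RPL: 43.8% aberrant
control: 13.3% aberrant
Fisher exact p = 6.2e-06
```

An aberrant decidual response is roughly three times as frequent in the
RPL arm (44% vs 13%), dominated by excessive senescence and uNK
deficiency, and the group difference is decisive. The same steps are
available from the shell:

```sh
decidua simulate cohort --seed 1 --out sim/
decidua screen --percentiles percentiles.tsv --out screen/
```

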