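# riborestore

Integrative analysis of **translational compensation of copy-number
imbalance** in paired transcriptome / translatome profiles.

Aggressive tumors such as high-risk neuroblastoma carry few point
mutations but many segmental copy-number alterations (CNAs).  A gene whose
locus is gained or lost changes its transcript abundance roughly linearly
with copy number — yet its protein output may stay unchanged, because
translation can buffer the imbalance.  Measuring both the transcriptome
(total mRNA) and the translatome (polysome-engaged mRNA) in the same
samples exposes this buffering through the **translational efficiency**

> TE(g, i) = log2 TL(g, i) − log2 TC(g, i)

for gene *g* in sample *i*.  Combining per-gene TE direction with the
collinear CNA direction yields a four-class taxonomy:

| CNA \ TE  | up (polysome-enriched) | down (polysome-depleted) |
|-----------|------------------------|--------------------------|
| **loss**  | RESTORE_UP (compensation) | ENHANCE_DOWN (magnification) |
| **gain**  | ENHANCE_UP (magnification) | RESTORE_DOWN (compensation) |

`riborestore` implements the full pipeline around this classification:

* **CNA calling** — circular-binary-segmentation-style changepoint search
  with permutation significance, modal re-centering, threshold calling,
  a count-based recurrent-aberration test with a rotation null, and a
  sign-unanimity consensus direction per gene.
* **Expression/TE** — probe QC filtering, quantile normalization,
  first-quartile detectability, log2 TE with per-sample distribution
  summaries, profile clustering (Pearson distance / Ward, k-means, PCA),
  delta-CT qPCR normalization.
* **Differential representation** — rank product (permutation PFP),
  paired t (BH), and a SAM-style moderated statistic (sign-flip
  permutation FDR), with a Venn consensus; the rank-product selection is
  the primary set.
* **RESTORE statistics** — exact binomial prevalence of RESTORE over
  ENHANCE, Fisher enrichment of compensatory TE inside CNAs, per-line
  one-sided Wilcoxon dosage-shift tests, breadth correlation, generic
  category enrichment, and a pan-cancer alteration-frequency bootstrap
  with genome-wide and CNA-background nulls.
* **Stoichiometry** — histone-family linear-scale sums, a coefficient-of-
  variation coordination metric (CV_TC / CV_TL), protein-complex
  membership statistics with a bootstrap null.
* **Prognosis** — Kaplan–Meier / log-rank concordance scoring: is each
  RESTORE gene associated with worse outcome in the expression state that
  would trigger its compensation?
* **Synthetic data** — a generator that plants all of the above structure
  (recurrent CNAs, compensation classes, histone stoichiometry with a
  compensation-disabled control line, prognostic cohort, complex catalog,
  pan-cancer table) with known ground truth.

## Worked example

```python
from riborestore import SimulationConfig
from riborestore.config import RunConfig
from riborestore.pipeline import run_synthetic

dataset, summary = run_synthetic(SimulationConfig(seed=7), RunConfig())
r = summary["restore"]
print(r["n_restore"], r["n_enhance"], round(r["prevalence_p"], 5))
print(summary["recovery"]["restore_recovery_fraction"])
print(summary["stoichiometry"]["n_lines_ratio_above_1"], "/ 13")
```

prints

```
120 75 0.00156
1.0
12 / 13
```

120 RESTORE vs 75 ENHANCE calls (the compensating classes dominate,
exact binomial p ≈ 0.0016), all 120 planted RESTORE genes recovered with
their exact class, and the translatome is the coordinated level
(CV_TC / CV_TL > 1) in all 12 compensating lines while the
compensation-disabled control line sits at ratio ≈ 1.

The same stages are exposed as a CLI:

```bash
riborestore simulate --seed 7 --outdir data/
riborestore segment --probes data/probes.tsv --outdir out/seg
riborestore run-all --seed 7 --outdir out/full
```

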