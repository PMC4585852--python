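# Methods

## The generative model behind the synthetic panel

The generator emulates a panel of `n_lines = 13` cell lines profiled at
three levels.  Copy state is an integer offset from neutral per gene and
line: loss −1, neutral 0, gain +1, amplification +2.  Probe log-ratios are
the segment mean for the state (−1, 0, +0.58, +2 log2 by default — the
single-copy loss/gain ratios for a diploid background, with amplification
as a high-level gain) plus N(0, σ_probe), σ_probe = 0.1.

Expression follows a linear dosage model with an additive compensation
term in log2 space:

    TC(g,i) = μ_g + β·cn(g,i) + ε          ε  ~ N(0, σ)
    TL(g,i) = TC(g,i) + δ(g,i) + ε′        ε′ ~ N(0, σ)

with δ = −γ·β·cn for RESTORE genes, +γ·β·cn for ENHANCE genes, 0
otherwise.  Defaults: β = 1 log2/copy-step, γ = 1 (full compensation),
σ = 0.25 log2.  With γ = 1 and σ → 0 a RESTORE gene's translatome is flat
at its baseline while its transcriptome carries the full dosage shift —
the zero-noise limits are tested exactly.

Planted structure, defaults: 2000 genes on 10 chromosomes; 12 recurrent
regions of 20 genes (half loss, half gain, one gain region amplified),
each altered with a shared direction in 8–13 lines; 60 RESTORE_UP +
40 ENHANCE_DOWN genes inside loss regions, 60 RESTORE_DOWN +
40 ENHANCE_UP inside gain regions.  Regions recurrent in most lines
mirror the biology being emulated (the large segmental aberrations of
high-risk neuroblastoma — 1p/11q deletion, 17q gain — occur in the
majority of MYCN-amplified lines) and give every affected line enough
altered genes for the per-line shift tests to be informative.

Baselines μ_g are N(8, 1.5) log2; planted-class and histone genes draw
their baseline from the upper 65 % of that distribution, because the
compensation phenomenon is defined over detectable loci (the analysis
classifies genes that survive the first-quartile detectability filter)
and histones are abundantly transcribed.

**Histone stoichiometry.**  Five families (3/12/16/5/9 members, the
replication-dependent H1/H2A/H2B/H3/H4 family sizes).  Transcription is
deliberately imbalanced: each family gets per-line log2 shifts spanning
±1 (so TC family sums vary ≥ 4-fold across lines), while the translatome
is rescaled per line so every family's linear-scale sum equals one common
target — the direct encoding of nucleosome equimolarity.  One line
(`control_line_index`, a KELLY-like control) skips the rescaling.  Small
multiplicative noise (σ = 0.05 log2) keeps sums within ~5 % of target.

**Cohort.**  A latent binary risk group multiplies an exponential
baseline hazard (0.1) by exp(1.2).  A fraction (0.7) of planted RESTORE
genes express the risk group in their adverse direction (high expression
for RESTORE_DOWN, low for RESTORE_UP, 2 log2 units apart, unit noise);
censoring is independent with probability 0.2.

**What the generator does not emulate:** probe-level microarray physics
(dye bias, spatial artifacts), miRNA-target regulation, correlated noise
between genes, subclonal CNAs, or heterogeneous per-line compensation
strength (γ is global).  Passing the recovery tests therefore shows the
pipeline's statistics behave correctly under the stated model, not that
real microarray data would yield the same counts.  In particular the
per-line "breadth correlation" has no planted signal here (all lines
share γ), so its value on synthetic runs is noise around zero.

## Analysis procedures and numerical choices

**Coordinates.**  0-based half-open everywhere inside the package; SEG
and 1-based dialects are converted at the I/O boundary only.

**Segmentation.**  Recursive changepoint search with the circular
two-endpoint statistic: the arc [i, j) maximising the two-sample t
against its complement, with both parts ≥ `min_probes` (3).  The arc form
(not a single binary cut) is what gives power against an interior
aberration flanked by normal copy number.  Significance by within-segment
permutation (100 shuffles, add-one p, accepted when p < α = 0.01); an
exact zero-variance separation (infinite t) is accepted outright.  The
permutation loop stops early once enough exceedances make significance
impossible — a pure optimisation that cannot change the decision.
Preceded by winsorization of probes beyond 4 scaled MADs of their
5-probe neighbourhood median.  Re-centering subtracts the probe-weighted
Gaussian-kernel mode (bandwidth 0.1 log2) of the segment means.  Calling
thresholds on re-centered means: loss < −0.2, gain > +0.2,
amplification > +1.0 — fixed thresholds rather than a mixture model,
because they are transparent, config-exposed, and sufficient for the
downstream binary direction.

**Recurrence.**  Per gene, the count of lines sharing a non-neutral
direction (amplification counts as gain).  Null: cyclic rotation of each
line's genome-ordered call track (500 rotations), which preserves each
line's run-length structure — independent shuffles would overstate the
significance of long segments.  Add-one empirical p, BH across genes;
flagged genes need count ≥ 3 and q ≤ 0.05; adjacent same-direction
flagged genes merge into regions.

**Gene-level CNA direction.**  Sign-unanimity across lines: any mix of
gain and loss calls for one gene is "conflict" and excluded from
classification.  The rule is deliberately conservative; how a source
study would collapse opposing per-line calls is not derivable, so
exclusion avoids fabricating a direction.

**Quantile normalization** replaces each sample's order statistics by
their across-sample mean; ties receive the average of the values they
span; missing-aware fallback maps ranks through a mean-quantile
reference.  Cross-checked against `limma::normalizeQuantiles` in the
test suite.

**Detectability.**  A gene is detectable at a level when its median
across samples reaches the first quartile (linear-interpolation
convention, pinned in config) of all gene medians; the union across the
two levels is kept, so a gene translationally silenced at one level
remains analyzable.

**TE** is carried in log2 (TL − TC); "breadth" of a sample's TE
distribution is its IQR.  A per-sample summary also reports median and
the tail fractions beyond ±1 log2.

**Differential representation.**  Unit of analysis: the paired fold
change fc = TL − TC per line (identical to log2 TE).  Rank product:
average-tie ranks per sample (descending for "up", ascending for
"down"), RP = geometric mean of ranks; the null re-draws each sample's
rank vector independently (1000 permutations); E[false positives] at a
gene's RP is the pooled-null count below it divided by the permutation
count, and PFP divides by the gene's rank position (clipped to [0, 1]).
Up and down are evaluated separately; a gene significant in both is
impossible and asserted.  Paired t: one-sample t against zero, BH across
genes; zero-variance genes with nonzero mean get the smallest
representable p and a degenerate flag.  SAM: d = mean/(se + s0) with s0
chosen by the standard coefficient-of-variation minimisation over
percentiles of the standard errors (10 quantile bins; median of s when
fewer than 20 genes); the null sign-flips whole samples (the
exchangeability of a paired design); FDR(Δ) = median null exceedance
count over observed exceedance count; the smallest Δ with FDR ≤ 0.05 is
selected.  The primary set for classification is the rank-product
selection at PFP ≤ 0.05 — the most conservative of the three — with its
direction labels.

**Classification** intersects the primary diffrep set with genes whose
consensus CNA direction is loss or gain; the TE direction is the diffrep
label, not a per-line vote.  Prevalence is the exact symmetric two-sided
binomial (p0 = 0.5) on RESTORE vs ENHANCE counts.  Enrichment tests are
two-sided Fisher exact; per-line shift tests are one-sided
Mann-Whitney (lost > neutral; gained < neutral), exact for small strata,
tie-corrected normal approximation otherwise, with optional BH across
lines (off by default, matching per-line reporting).

**Bootstraps.**  All empirical p-values use the add-one convention
(1 + #null ≥ observed)/(n + 1), so p = 0 is impossible.  The pan-cancer
statistic is the unweighted mean concordant alteration frequency over
tumor types (deletion frequency for RESTORE_UP sets, gain frequency for
RESTORE_DOWN); nulls draw same-size gene sets from the genome-wide
background or from CNA-region genes excluding the tested set.  The
complex statistic is the number of set members in ≥ 1 complex; a complex
counts as "half covered" when at least half (ties included) of its
members are in the set.

**Stoichiometry metric.**  Family signals are linear-scale (2^x) member
sums per line and level; "averaged by family" is implemented as
sum-within-family per line, then across-line mean for display, because
per-line sums keep the statistic testable.  Coordination is the
coefficient of variation (sample SD / mean) of family sums across
families within a line; the ratio CV_TC / CV_TL > 1 marks the translatome
as the coordinated level.

**Prognosis.**  Product-limit estimator and two-group log-rank
implemented in-package (the signed observed-minus-expected term drives
the direction-of-risk call; both are cross-checked against lifelines in
the tests).  Genes are dichotomized at the cohort median — deterministic
and conventional, unlike an optimal-cutoff scan — and a RESTORE gene is
concordant when the adverse group for its class is significantly worse
at unadjusted α = 0.05 (BH optional in config).

## Reported sizes

The default study analysed by the tests and by `scripts/acceptance.py`
uses 2000 genes × 13 lines, 1000 rank-product permutations, 200 SAM
permutations, 500 recurrence rotations, 1000 bootstrap draws and a
200-patient cohort; calibration suites use 60–200 replicates at reduced
matrix sizes.  These sizes give stable Monte-Carlo estimates (PFP and
empirical p resolution ≤ 0.005) while keeping a full run around a
minute on one core.

## Known limitations

* Calling by fixed thresholds assumes a mostly diploid background; no
  ploidy or purity correction.
* The recurrence test is count-based; it does not weight by segment
  amplitude or use a kernel over genomic distance.
* The prevalence binomial treats RESTORE/ENHANCE as exchangeable under
  the null; if gains and losses differ strongly in breadth the symmetric
  null is only an approximation.
* Concordance uses a median split; genes whose prognostic signal lives
  in an extreme quantile may be missed.
* Missing values are excluded pairwise by the statistics but the
  rank-product path requires complete rows; the pipeline drops
  incomplete genes before testing.
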