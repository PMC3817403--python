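# Methods

`eptlmap` implements a pipeline for mapping *expression probabilistic trait
loci* (ePTLs): genetic loci that change the cell-to-cell variability of a
gene's expression rather than (or in addition to) its mean. The motivating
system is the BY/RM pair of *S. cerevisiae* strains carrying a
P_met17-GFP reporter of the methionine pathway, phenotyped by flow
cytometry, but every stage is generic.

## Phenotype definition

Single-cell fluorescence (FL1) scales with cell size and granulometry, so
FL1 is first conditioned on log(FSC) and log(SSC) by an ordinary
least-squares regression fitted within each acquisition sample; the
corrected value is the residual plus the sample mean (mean-preserving, and
exactly orthogonal to both covariates within the fitted sample). Cell-to-
cell variability is the coefficient of variation, CV = s.d./mean, of the
corrected intensities, with the sample s.d. using the n−1 denominator.
The conditioning is linear; a nonparametric (binned) conditioning would
also be defensible, but linear is the minimal model that removes the
planted coupling of the synthetic generator exactly in expectation, and a
pooled-across-samples fit is available behind a flag.

## The CV-gain statistic

CV declines with mean expression (low-abundance regimes are intrinsically
noisier), so raw CV differences confound mean effects. The pipeline
removes the dependence with a linear reference model, `cv = a + b·mean`,
fitted by OLS on samples of a reference strain across induction
conditions. The **CV gain** of any sample is its observed CV minus the
model prediction at its mean. Gains of reference samples average exactly
zero (an OLS identity); departure of a test strain's gains from zero is
assessed with a one-sample, one-tailed Student t-test, pooling samples
across methionine concentrations by default (a per-condition mode exists).
Samples whose mean falls outside the fitted range are scored by
extrapolation with a warning.

## Linkage testing on conditioned residuals

To test whether a segregating locus affects variability and not merely
mean, CV is regressed on mean across **all** spores of a cross (not the
reference subset), and the residuals are the quantitative trait. The two
genotype groups are compared with a two-sided Wilcoxon Mann–Whitney test.
When both groups have ≤ 10 spores the exact null distribution is obtained
by enumerating all C(n+m, n) group assignments of the midranked pooled
values (correct under ties); larger panels use the tie-corrected normal
approximation with continuity correction. Two-sided exact P is
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Under the null the genotype labels
are independent of the residuals, so the test is distribution-free
regardless of how the residuals were constructed; the simulation suite
confirms a 5% type-I error within binomial error over 1,000 null panels.

Candidate loci are flagged at raw P < α (default 0.05) with **no**
multiple-testing correction, matching the validation logic the pipeline
reproduces; this is a caveat for larger candidate sets, and a Bonferroni
option exists. The additivity diagnostic reports the combined-locus gain
minus the sum of single-locus gains.

## Synthetic data generator

No raw cytometry or sequencing data are available for the original
experiment, so the generator produces every input with known ground truth.

* **Cells.** log FSC and log SSC are normal (defaults: 5.5 ± 0.25 and
  5.0 ± 0.35). The expression component is lognormal, moment-matched to a
  target mean m and target CV `c(m) = a₀ + b₀·m + Δc`, where Δc is the
  planted ePTL (CV-gain) effect and an additive mean shift plays the eQTL
  role; a requested negative CV is rejected, never clipped. FL1 adds
  `k·(log FSC − E[log FSC])` with k = 20 a.u. per log unit, so linear
  conditioning removes it exactly in expectation. The lognormal is a
  choice, not an observation: right-skewed intensity distributions are
  typical of cytometry, but the original single-cell distribution shape is
  unknown. Baseline CV law defaults: a₀ = 0.25, b₀ = −0.001 per a.u.,
  giving CV ≈ 0.15–0.24 over the simulated mean range, comparable to
  reporter CVs in this regime. Default 10,000 cells per sample, the
  acquisition size of the emulated experiment.
* **Dose response.** Mean expression under methionine repression follows a
  decreasing Hill function `floor + (max − floor)/(1 + (c/K)^h)` with
  defaults max = 150, floor = 10 a.u., K = 50 µM, h = 1.5, evaluated over
  the standard 7-point series {0, 5, 20, 50, 100, 150, 200 µM} (1 mM is
  the repressive pre-culture). The true functional form is unknown; a Hill
  curve is the standard monotone saturating choice.
* **Spore panels.** Each spore is donor/recipient at the tested locus with
  probability 1/2 (Mendelian backcross segregation); donor spores receive
  the planted CV gain. Default panel size 40 spores, the pool size used
  per selection step in the emulated design.
* **Pileups.** Depth per SNP is Poisson(coverage), reads carry the true
  allele with probability 1 − ε (symmetric error); defaults 45× and
  ε = 0.01. SNP grids default to one site per ~300 bp, matching the
  ~42,800 SNPs distinguishing the two backgrounds over a ~12 Mb genome.

All generators take an explicit integer seed (fixed seed ⇒ bitwise
identical output) and never touch global RNG state.

What the generator does **not** emulate: cytometer artifacts (doublets,
debris, saturation), gating, day effects or culture-to-culture variation,
correlated sequencing errors, alignment artifacts, and any epistasis —
locus effects are additive by construction. Passing tests therefore show
the statistics are correctly calibrated under a clean additive model, not
that the pipeline is robust to every failure mode of real cytometry data.

## Introgression simulation

Genomes are haploid lists of donor/recipient intervals in genetic-map (cM)
coordinates over 16 chromosomes. The default map uses S288c chromosome
sizes with a uniform 0.36 cM/kb, giving a ~4,350 cM genome; cM↔bp are
proportional within a chromosome. Meiosis follows the Haldane model:
Poisson(L/100) crossovers per chromosome, positions uniform, alternating
parental copies from a fair-coin start. Yeast's substantial crossover
interference is deliberately ignored — it affects segment-length variance,
not the expectations the pipeline relies on — and the meiosis function is
the single hook where an interference model could be substituted.

A lineage starts from the fully heterozygous F1: generation 1 sporulates
the F1 (expected donor share 1/2) and each later generation crosses the
selected spore to the recipient, halving the expectation, so the expected
donor fraction after g generations is 2⁻ᵍ (~0.8% at g = 7) without
selection. Selection is phenotypic, not marker-assisted: each spore gets a
simulated CV gain (sum of effects at donor-carried target loci plus
Gaussian noise, default s.d. 0.005) and a mean shift (noise s.d. 2 a.u.);
among spores whose |mean shift| is within a tolerance (default ±10 a.u.,
i.e. ±10% of the default recipient mean) the highest CV gain wins. If no
spore passes the mean filter the nearest-mean spore is taken with a
warning. Selection at k loci adds linkage drag of roughly 2·(100/g) cM per
selected locus, which is why selected seven-generation lineages retain
~1–2% donor genome rather than 0.8%.

`retention_prob(k) = 2⁻ᵏ` is the chance a single spore keeps donor alleles
at k unlinked heterozygous loci — the drift argument for why independent
lineages retain different locus subsets.

## Region detection

Sites are called donor (recipient) when that allele's read frequency is
≥ 0.9 at depth ≥ 5, ambiguous otherwise; at 45× with 1% error this gives a
per-site miscall probability below 10⁻⁶. Maximal runs of donor calls per
chromosome become regions bounded by the outermost donor SNP positions
(1-based inclusive, matching how such tables are printed; BED export is
0-based half-open). Ambiguous calls inside a run are bridged and do not
count as donor support; recipient calls split runs unless `max_bridge > 0`
(default 0 — no bridging of discordant calls). Single-SNP regions are
filtered (min_snps = 2) as probable sequencing errors before validation.
Region length is reported as the boundary difference in kb; the off-by-one
between span and inclusive length is far below rounding resolution.

## Fine mapping

A region flanked by two selectable genes supports a double-selection
recombinant screen: keeping spores that are donor at the left flank and
recipient at the right retains exactly the viability-selected recombinant
class (expected frequency r(d)/2 under Haldane). Survivors are genotyped
at an ordered marker panel; a **perfect discriminator** is a marker whose
genotype partitions the low-/high-variability classes with zero
misclassification (either polarity). The candidate interval runs from the
nearest non-discriminating marker left of the perfect block to the nearest
one on its right (panel edges bound it otherwise); with adjacent tied
perfect markers, all are reported and the interval uses the outermost
non-discriminating flanks. Quantitative CV gains are binarised by an exact
1-D 2-means split by default, since the original classification was
visual; the split is configurable.

## Numerical and testing choices

* OLS everywhere via `numpy.linalg.lstsq`; degenerate designs (constant
  covariates, identical means) are rejected or fall back to identity with
  a warning rather than silently regularised.
* Exact Mann–Whitney enumeration is limited to ≤ 10 per group
  (C(20,10) ≈ 1.8×10⁵ assignments); tests cross-check it against an
  independent brute-force enumerator and against `scipy` on tie-free
  inputs.
* The t-test on gains returns P = 0.5 for identically-zero gains and
  refuses zero-variance nonzero gains.
* Simulation suite sizes: 10,000 meioses for the Haldane check, 200
  lineages for the 2⁻ᵍ decay, 1,000 null panels (40 spores × 100 cells)
  for type-I calibration, a 3×3 grid × 150 replicates for power
  monotonicity, 50,000 cells for moment recovery. These sizes put
  Monte-Carlo error well inside the 3-s.e. acceptance bands used by the
  tests.

## Known limitations

* No crossover interference and a uniform cM/kb map (no hotspots,
  centromere or telomere effects).
* Additive locus effects only; the emulated experiment itself shows
  epistasis (background-dependent effect sizes), which the generator does
  not reproduce.
* Linear CV~mean conditioning can misestimate gains if the true CV–mean
  relationship is strongly curved over the observed range.
* Haploid genetics throughout: no diploid phenotypes, aneuploidy, or
  mitotic recombination.
* No multiple-testing correction by default in candidate classification.
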