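# eptlmap

Mapping **expression probabilistic trait loci (ePTLs)** — genetic loci that
change the *cell-to-cell variability* of gene expression rather than its
mean — from flow-cytometry phenotypes and backcross-introgression genetics
in yeast.

Most expression QTL methods treat the mean expression of a genotype as the
trait. But isogenic cells vary around that mean, and the *width* of the
single-cell distribution is itself heritable: loci can raise or lower the
coefficient of variation (CV = s.d./mean) of a reporter at a fixed mean.
Detecting such loci is confounded by the strong negative CV~mean
dependence of gene expression — a locus that lowers mean expression raises
CV trivially. `eptlmap` implements the statistics and simulations needed
to separate the two, for geneticists mapping variance/noise QTL with
cytometry reporters:

* **Size conditioning** — single-cell fluorescence (FL1) is regressed on
  log(FSC) and log(SSC) per sample and replaced by the mean-preserving
  residual, removing cell-size effects.
* **CV gain** — a linear reference model `cv = a + b·mean` is fitted on a
  reference strain across induction conditions; a sample's gain is
  `cv_obs − (a + b·mean_obs)`, tested against zero by a one-tailed t-test.
* **Linkage on conditioned residuals** — across the spores of a cross, CV
  is regressed on mean and the residuals are compared between genotype
  groups with a Wilcoxon Mann–Whitney test (exact by enumeration for small
  groups, tie-corrected normal approximation otherwise).
* **Backcross-introgression simulation** — Haldane meioses over a
  16-chromosome yeast map with per-generation phenotypic spore selection;
  expected donor-genome fraction decays as 2⁻ᵍ without selection and shows
  linkage drag with it.
* **Introgressed-region detection** — donor/recipient genotype calls from
  per-SNP pileup allele counts, segmentation into regions bounded by the
  outermost donor SNPs, and filtering of single-SNP (likely error) calls.
* **Fine mapping** — double-selection recombinant screens and
  perfect-discriminator marker analysis to localise a causal polymorphism
  to a marker interval.
* **Synthetic data** — generators for every input (cell tables, dose
  series, spore panels, pileups, genotype tracks) with planted ground
  truth, since the motivating experiment's raw data were never deposited.

## Worked example

Simulate a strain carrying a single variability locus (planted CV gain
0.018 at fixed mean) alongside its reference background over the
methionine induction series, then recover the gain:

```python
import eptlmap as e
from eptlmap.cytometry import sample_stats

dose = e.DoseResponse()                      # mean: 150 a.u. (0 uM) -> 10 a.u. (repressed)
by   = e.PopulationParams(strain="BY", n_cells=10_000)
eptl = e.PopulationParams(strain="ePTL8", cv_gain_effect=0.018, n_cells=10_000)

ref_stats  = [sample_stats(e.size_correct(t))
              for t in e.methionine_series(by, dose, seed=1)]
test_stats = [sample_stats(e.size_correct(t))
              for t in e.methionine_series(eptl, dose, seed=2)]

model = e.fit_cv_mean(ref_stats, reference="BY")
gains = e.cv_gain(test_stats, model).gains
print(f"cv = {model.intercept:.4f} + {model.slope:.2e} * mean")
print(f"mean CV gain = {gains.mean():.4f}")
print(f"one-tailed P = {e.gain_ttest(gains, 'greater'):.2e}")
```

Output:

```
cv = 0.2503 + -1.00e-03 * mean
mean CV gain = 0.0175
one-tailed P = 3.98e-07
```

The reference model recovers the generator's baseline CV law (intercept
0.25, slope −0.001 per a.u.), and the estimated gain of 0.0175 matches the
planted 0.018: the locus raises variability at every induction level
without the estimate being contaminated by its (zero) mean effect, and the
t-test rejects no departure from zero decisively. (A warning notes that two
samples have means marginally outside the reference model's fitted range —
sampling noise around the shared 150 a.u. induction ceiling — so their
gains are extrapolations; that is expected and harmless here.)

The same analyses are available from the shell:

```sh
eptlmap simulate --seed 1 --series --out cells.tsv
eptlmap correct cells.tsv --out corrected.tsv
eptlmap stats corrected.tsv --out stats.tsv
eptlmap gain stats.tsv --reference BY --out gains.tsv
eptlmap linkage stats.tsv genotypes.tsv --out linkage.tsv
eptlmap introgress --generations 7 --replicates 200 --seed 1 --out lineages.tsv
eptlmap regions pileup.tsv --out regions.tsv --bed regions.bed
eptlmap finemap panel.tsv --out finemap.tsv
eptlmap scenario --name validate_candidates --seed 1 --out report.tsv
```

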