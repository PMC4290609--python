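# Methods

## Model and procedure

The analysis treats a platform as a probes × samples real matrix: log
intensities for expression arrays, β fractions in [0, 1] for methylation
arrays. The matrix is decomposed by thin SVD, by default **uncentered**.
Uncentered decomposition is deliberate: on array data every probe has a
large positive baseline, so the leading component is a near-constant
sample-independent profile absorbing the bulk of the variance, and the
between-condition contrasts appear as small later components. Probe scores
are the left singular vectors scaled by their singular values; sample
contributions are the (unit-norm) right singular vectors; a component's
contribution fraction is its squared singular value over the sum of all
squared singular values. Because the sign of a singular-vector pair is
arbitrary, it is fixed so that the mean of each sample-contribution vector
is ≥ 0 (ties broken by the first nonzero element), which makes outputs
identical across linear-algebra backends.

Each component is characterized against the 2×2 cell-line × metastasis
design. Contributions are averaged within the four categories (fixed order
A549−, A549+, HTB56−, HTB56+). A component is *flat* when the coefficient
of variation of all its sample contributions falls below `flat_cv`
(default 0.1). Otherwise three contrasts are scaled by the pooled
within-category standard deviation `s` of replicate contributions:

* `e_cell = |mean(A549) − mean(HTB56)| / s`
* `e_metA = |A549− − A549+| / s`
* `e_metH = |HTB56− − HTB56+| / s`

and the largest effect exceeding `z_threshold` (default 2.0) names the
component; ties or no exceedance give *other*. When no category has two
replicates the rule degrades to ranking the raw contrasts (logged). These
two thresholds formalize what is otherwise a by-eye reading of
contribution plots; there is no canonical numeric rule, so both are
configurable and echoed in every run summary.

Components are paired across platforms by the Pearson correlation of their
4-long category-mean vectors; with 4 points the two-sided P-value uses the
t transform with 2 degrees of freedom. All (k, l) candidates up to
`max_pc = 6` are scored and exported; candidates need `p < alpha = 0.05`
and the *same* characterization label on both platforms; each component is
used at most once, assigned greedily by decreasing |r|. Gene selection then
runs only on pairings with a biological label (cell_line or a metastasis
contrast) — flat or unlabeled pairings distinguish nothing worth selecting
on.

For a pairing, the `n_top = 100` most extreme probes are taken from each
tail of each platform's component, ties at the cutoff expanding the set
(logged). Tails are matched by the sign rule encoding the expected
anticorrelation of expression and promoter methylation: positively
correlated components pair opposite tails (expression-high with
methylation-low and vice versa), negatively correlated components pair the
same tails. Probes map to RefSeq genes through the annotation tables
(multi-gene probes contribute all their genes, unannotated probes
nothing); the overlap count x is the number of genes common to the two
selections, and its significance is the upper binomial tail
`P[X ≥ x]` with `X ~ Binomial(n, n/y)`. The observed overlap is included
in its own tail (`1 − CDF(x − 1)`, so x = 0 gives 1); the exclusive
variant `1 − CDF(x)` sits behind a flag. The overlap is *counted* at gene
level — gene lists are the reported unit — while the universe `y` is the
per-platform probe count the binomial formula calls for; since the two
platforms differ in size, each tail pairing reports one P-value per
universe. Both tail pairings are always reported, and the final gene list
is the union of their gene sets over all biologically labeled pairings.

## Promoter methylation from site-level calls

A RefSeq transcript's promoter is the strand-aware window from 1500 bp
upstream to 500 bp downstream of its TSS: for a + strand gene with 0-based
`tx_start`, the 1-based window `[tx_start + 1 − 1500, tx_start + 1 + 500]`;
for a − strand gene the mirror image around `tx_end`. Windows are inclusive
on both ends (no open/closed rule is forced by the definition; inclusive is
the simplest testable choice) and clipped at position 1. The gene-level
value is the **unweighted mean of per-site β values** inside the window;
count-form sites are converted per site (methylated/total) before
averaging. The alternative pooled ratio Σmethylated/Σtotal — which differs
whenever site coverages differ — is available behind a flag. Multi-locus
RefSeq IDs get one window per locus and the gene value averages the locus
means. Sites are summed in sorted order so the mean is exactly invariant
to site ordering and to coordinate reflection. Genes whose windows contain
no sites are reported missing rather than erroring. Whether replicate
sequencing runs are pooled before aggregation is left to the caller; the
per-sample table keeps them separate.

## Baseline statistics

* Per-probe t-tests between metastasis groups use Welch's unequal-variance
  statistic (the pooled Student variant is a flag); probes with zero
  variance in both groups get p = 1 and a flag. P-values are
  Benjamini–Hochberg adjusted (step-up: sort ascending,
  `q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1, returned in input order).
* Paired probe correlations collect every (expression probe, methylation
  probe) pair sharing a RefSeq ID, average replicates within the four
  design categories on each platform — replicate counts differ across
  platforms, so raw samples cannot be paired — and correlate the 4 paired
  means (df = 2), with BH over all pairs. Pairs with fewer than 3 distinct
  category means on either side are skipped and counted.
* Directional validation uses both one-sided two-sample Kolmogorov–Smirnov
  P-values (is A stochastically greater than B, and the reverse),
  asymptotic by default with the exact small-sample distribution behind a
  flag; a warning is logged when more than 10% of pooled values are tied.

## Synthetic data

The generator emulates the paired study the analysis is built for: four
conditions (A549/HTB56 × with/without metastasis), 3 expression and 2
methylation replicates per condition, 2000 genes with 1–2 expression
probes and 1 methylation probe each. Per gene and condition the signal is

```
baseline + cell·1[HTB56] + metH·1[HTB56 ∧ met] + metA·1[A549 ∧ met] + noise
```

with defaults: expression baseline N(8, 2²) log units, noise sd 0.3,
cell-line effect +2.0 on 150 genes, metastasis effect +1.5 on 30
HTB56-specific and 20 A549-specific genes; methylation baseline
N(0.5, 0.15²), noise sd 0.05, cell-line effect +0.15, metastasis effect
−0.15 (anticorrelated with expression, the default; a same-sign mode
exercises the other tail-pairing branch). β values are simulated on the
raw scale and clipped to [0, 1] — clipping is rare at these sizes and is
logged. All randomness flows from one integer seed through a single
generator. The site-level companion lays the same genes on a toy
two-chromosome genome (alternating strands, 20 kb spacing), places 20
uniformly positioned sites per promoter with β = gene value + N(0, 0.1²)
site noise, plus decoy sites outside every window, and records the
per-gene truth.

What the generator does not emulate: array noise spectra, probe GC or
affinity effects, batch structure, spatially correlated methylation, CpG
density. Passing recovery tests therefore demonstrates the pipeline's
mechanics and statistical calibration, not robustness to real array
artefacts.

### A detectability limit worth knowing about

With the default methylation parameters the HTB56-metastasis component is
intentionally hard: 30 probes × effect 0.15 against a 2000 × 8 noise
matrix at σ = 0.05 puts the planted eigenvalue (~0.7 after the
non-orthogonal cell-line pattern absorbs part of the effect — the two
contrasts share the HTB56+ samples) just above the Marchenko–Pastur noise
edge, in the regime where the leading eigenvector is only partially
aligned with the planted direction. The expression platform recovers all
30 planted genes in its top-100 tail; the methylation top-100 typically
holds 50–90% of them depending on seed, and the gene-level intersection is
capped by the methylation side. At seed 0 the pipeline recovers 16/30
planted genes with overlap P ≈ 2×10⁻⁷ against the expression universe
(the acceptance script reports the corresponding numbers for its own
seed). This mirrors the method's real use case — the methylation array is
the noisier platform — and is a property of the study conditions, not of
the implementation.

## Numerical choices

* SVD via LAPACK (`numpy.linalg.svd`); BH via statsmodels; t, KS, binomial
  and t-transform tails via scipy. Contribution fractions use all thin
  components, so they sum to 1 regardless of how many are retained.
* Ties: outlier cutoff ties expand the selection (logged); greedy PC
  matching breaks |r| ties by component index; equal top characterization
  effects give *other*.
* Degenerate inputs: zero-variance category-mean vectors make a
  correlation undefined — such candidates are skipped in matching and
  raise in direct calls; probes with missing values are dropped (with
  count) before decomposition, since the decomposition has no missing-data
  mechanism.
* Coordinates are normalized at the reader boundary only: gene tables stay
  0-based half-open (refGene dialect), site tables are 1-based after read
  (a 0-based `start` column is shifted).

## Known limitations

* The binomial overlap model treats the two top-100 selections as
  independent draws with replacement; the exact null is hypergeometric.
  The difference is negligible for y ≫ n (the Monte-Carlo acceptance test
  bounds it) but the binomial form is kept as the method's defining
  statistic.
* Characterization assumes the 2×2 design; other designs need their own
  contrast set.
* The df = 2 correlation P-values are exact only under normality of the
  category means; with 4 points they are best read as ranking scores, and
  the alpha gate as a heuristic filter.
* Probe-level annotation ambiguity (multi-gene probes) slightly inflates
  gene universes; the universe size y deliberately stays the probe count.
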