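# Methods

`cladecall` implements a phenotype-to-genotype pipeline for experimentally
evolved *Saccharomyces cerevisiae*: from raw qRT-PCR cycle-threshold (Ct)
values of a five-gene glucose-inducible panel (*HXT2*, *HXT3*, *HXT4*,
*HXT6/7*, *SUC2*; *ACT1* reference), through ancestor-relative log2
expression profiles, to hierarchical clades, driver-mutation predictions,
a discriminant-analysis contrast of mutation versus ploidy grouping, and
exact binomial tests for parallel evolution.  This note records the models,
the defaults and why they were chosen, and the limits of what the synthetic
cohorts can demonstrate.

## Relative quantification

The quantity analysed everywhere downstream is the efficiency-corrected
log2 expression ratio of an evolved clone over the diploid ancestor,
internally normalized to *ACT1*:

    log2 R = dCt_ref * log2(1 + E_ref) - dCt_gene * log2(1 + E_gene),

with `dCt_x = Ct_x(clone) - Ct_x(ancestor)` and `E` the primer pair's
amplification efficiency (`E = 1` is perfect doubling; then the expression
reduces to the classical 2^-ddCt).  Efficiencies come either from user
input or from dilution-series standard curves fit by ordinary least squares
of Ct on log10(dilution) (`E = 10^(-1/slope) - 1`); a non-negative slope is
flagged as an invalid curve rather than silently used, and the reported
linear range is the widest contiguous dilution window whose own fit reaches
r² ≥ 0.99.

Replicate handling: technical replicates are averaged first; ratios are
formed per biological replicate (clone replicate *b* against ancestor
replicate *b*, falling back to the pooled ancestor mean when unmatched) and
the reported value is their mean with the standard error over biological
replicates (the common qPCR convention).  A quadrature mode that propagates
the four per-term Ct standard errors instead is provided for comparison.
With a single biological replicate the SEM is undefined and reported as 0.
When the Ct table carries a `batch` column, clones are normalized against
the ancestor processed in the same batch, matching the experimental
practice of co-processing each clone with an ancestor aliquot.

## Clustering and clade-count selection

Clones are clustered by agglomerative **complete linkage** on Euclidean
distances between panel log2 profiles (correlation distance is available).
The agglomeration is implemented directly (O(n³); trivially fast at cohort
scale) so that ties between equal inter-cluster distances are broken
deterministically — among tied pairs, the one whose sorted pair of smallest
leaf labels is lexicographically least merges first — making the dendrogram
a pure function of the input regardless of row order.  Complete linkage
yields monotone merge heights and hence an ultrametric cophenetic matrix;
dendrograms export to Newick with branch lengths equal to height
differences.

The clade count is chosen from the within-group sum of squares (WGSS)
curve over cuts k = 1..k_max (default 10).  Two explicit elbow rules are
computed and emitted in the selection trace:

* **`curvature` (default)** — the largest second forward difference of
  `log WGSS(k)`.  WGSS decays roughly geometrically over uninformative k on
  data with structure at several scales, so the *raw* WGSS curve is convex
  everywhere and its absolute curvature is maximal at k = 2 almost
  regardless of the true structure.  On the log scale the curve is
  near-linear while cuts still separate real clades and kinks where further
  cuts only split clades internally; the maximum of the log-curvature is
  the standard scale-invariant automation of "inspect within-group variance
  against model complexity".
* **`second_diff`** — the largest raw second forward difference
  `WGSS(k-1) - 2 WGSS(k) + WGSS(k+1)`, kept selectable for comparison
  precisely because its small-k bias is instructive.

The full trace (k, WGSS, both statistics) is always written so a human can
override the cut (`k=` in the API, `--k` on the CLI).  In the degenerate
noise-free case WGSS reaches exactly zero; values are floored at 1e-6 of
WGSS(1) before taking logs, which leaves the location of the kink
untouched.

## Driver prediction

Genotyped clones label the clades by majority vote; an unlabelled clone
inherits its clade's label with a support fraction (agreeing labelled
members / labelled members).  Ties and empty clades abstain and the
prediction is reported UNDETERMINED, never guessed.

Because distinct drivers can co-inhabit a primary clade (a loss-of-function
*MTH1* sub-clade sits inside the moderate-*SNF3* clade; *RGT2* and *IPT1*
share the minimal-response clade; the few *MOT3* mutants neighbour the
*HXT6/7*-amplified clones), a plain k-clade vote cannot resolve them.
`predict_refined` formalizes how a reader resolves this on the dendrogram:
ascend from the query clone's leaf toward its clade root and vote over the
first enclosing subtree that contains genotyped clones and yields an untied
majority — i.e. label by the nearest genotyped neighbours in tree topology.
For clades whose genotyped members agree this reduces exactly to the clade
vote; the pipeline and the acceptance analysis use the refined mode.
Leave-one-out cross-validation over the genotyped clones is provided
(`loocv`); clustering itself never depends on labels, so only the vote is
recomputed.

## Class separation (Fisher LDA)

Fisher's construction is specified explicitly so results are
implementation-independent: with between-class scatter `Sb` and pooled
within-class scatter `Sw`, the axes solve `Sb w = λ Sw w`, ordered by
decreasing λ, at most `min(genes, classes−1)` informative axes.  `Sw` is
ridge-regularized by `λ_r · trace(Sw)/p · I` (default `λ_r = 1e-6`) so that
small classes on a five-gene panel cannot make the problem singular; the
ridge slightly breaks exact affine equivariance of the scores (at the 1e-5
level), which the tests tolerate explicitly.  Classification uses the
Gaussian rule with pooled covariance `Sw/(n−K)` and class-proportional
priors (uniform optional); cross-validation is leave-one-out, which is
deterministic at this scale.  Note that LOOCV is mildly pessimistic under
a permutation null — removing a sample shifts its own class mean away — so
the permutation test in the suite checks one-sidedly that no signal
survives label permutation.

95% confidence ellipses on the first two discriminant scores use the
chi-square (known-covariance) scaling `sqrt(χ²₂(0.95)) ≈ 2.4477` by
default, matching the common plotting convention; the F-based Hotelling
scaling for small samples is available by flag and is always wider.
Pairwise ellipse overlap areas are computed by grid integration over the
intersection of bounding boxes (400×400 default).  `separation_report`
contrasts the same matrix grouped by driver mutation versus by ancestral
ploidy: LOOCV accuracies per grouping, overlap areas, and a flag set when
every mutation-class accuracy exceeds every ploidy-class accuracy.

## Recurrence (parallel evolution) tests

For a gene hit in k **distinct** clones (multiple hits inside one clone
count once), the null probability of at least k hits is the exact binomial
upper tail `P(X ≥ k)`, `X ~ Bin(n, p_hit)`, under one of two nulls:
`per_mutation` (default; n = total mutations in the cohort,
`p_hit = gene_length / target_length`) or `per_clone` (n = clones,
`p_hit = 1 − (1 − gene_length/target_length)^m` with m the mean mutation
count per clone).  Only genes hit in ≥ 2 distinct clones are tested;
p-values are Benjamini–Hochberg adjusted across tested genes (Bonferroni
optional).  Because the distinct-clone count never exceeds the raw hit
count, the per-mutation construction is conservative, and the Monte-Carlo
suite verifies type-I control at or below nominal.  The package
deliberately does not claim to reproduce any particular published p-value
for recurrent genes: the trial counts and effective target sizes behind
such numbers are inputs the user must supply.

## Synthetic cohorts

The generator emulates the study design rather than any real dataset:
evolved clones from three ancestral ploidies (default 27 haploid-, 32
diploid-, 33 tetraploid-derived; ids 1xx/2xx/3xx), each measured on panel
plus reference in triplicate reactions for each of two biological
replicates, alongside an ancestor processed identically.  Per clone, gene
and biological replicate a true log2 ratio is drawn from
`Normal(mean_log2[class], sd_log2)` (ancestor-like class: mean 0, forced by
the ratio definition); it converts to cycles through the efficiency model
`Ct = baseline − z / log2(1+E)` plus a per-(clone, replicate) cDNA-loading
offset in cycles that hits all genes equally (and therefore cancels under
*ACT1* normalization, as in the real assay) and independent technical noise
per reaction.  Defaults: technical SD 0.15 cycles, biological SD 0.2 log2
units, loading SD 0.3 cycles, efficiencies 0.90–0.97 — mid-range values for
a well-run SYBR assay.  A seed fully determines every output.

Class signatures are package defaults, not published measurements (the
source of the qualitative tiers is a heatmap).  They encode: *HXT2/3/4*
activation tiers high > moderate > low > minimal for the Snf3/Rgt2/Mth1
signalling mutants, with *SUC2* as the secondary separator — invertase
derepression is strongest under weak glucose signalling and repressed under
constitutive high-glucose (Rgt2) signalling; an *HXT6/7* gain with mild
down-regulation elsewhere for the amplified clones; and a *MOT3* profile
with *HXT3*/*HXT6/7* up and *HXT2*/*HXT4*/*SUC2* down next to them.  The
magnitudes are calibrated so that (a) classes documented to share a clade
stay within ~1.1 log2 of each other and co-cluster, and (b) each successive
clade split removes a comparable fraction of the within-group variance, so
the five-clade structure is resolvable at every scale of the merge tree.
Under these defaults the elbow selection returns five clades and the
21-clone hold-out validation is reproduced across seeds.

The mutation-table generator draws per-clone mutation counts from a Poisson
(optionally per-ploidy means; tetraploids default higher) and places each
mutation in a gene with probability proportional to length × selection
weight, or in the remaining intergenic target; positions are uniform within
the gene and (clone, gene, position) records are unique.

**What passing these simulations does and does not show.**  The cohorts
have Gaussian noise, exactly class-determined expression, no batch drift,
no plate effects, no failed reactions, no clones with genuinely novel
drivers, and signature tiers chosen to be resolvable.  Passing therefore
demonstrates that the pipeline's logic is correct and that the published
workflow is coherent end-to-end at realistic noise levels — not that real
clones of unknown genotype will always be predicted correctly; the original
study itself required targeted sequencing to confirm each prediction.

## Numerical and scale choices

Monte-Carlo sizes are chosen to keep the full suite comfortably inside a
routine CI run while leaving the statistical checks sharp: ellipse coverage
at 100 000 samples (±0.005 band), recurrence type-I control over 400
neutral cohorts × 20 genes, detection power over 200 selected cohorts,
permutation null at 200 permutations of 45 clones, hold-out validation on
the 92-clone cohort.  Tolerances: exact-arithmetic binomial oracle at
1e-12 (n ≤ 50); qPCR ratio oracle at 1e-12; linkage versus scipy at 1e-10;
LDA eigen-oracle at 1e-8; Newick round-trip at 1e-9 (branch lengths are
written with 17 significant digits).

## Known limitations

* Prediction resolution is bounded by expression distinguishability:
  classes with identical signatures are only resolvable to their shared
  clade, mirroring the need for sequencing/copy-number confirmation in
  practice.
* The WGSS elbow, like any automatic model-complexity rule, can be
  ambiguous when clade separations span very different scales; the trace is
  always emitted and a forced `k` is a first-class option.
* The recurrence nulls treat mutations as independent uniform events on a
  length-weighted target; they ignore mutational spectra, hotspots and
  clonal relatedness.
* No absolute quantification, no amplification-curve fitting, no multi-
  plate calibrator normalization beyond the batch rule.
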