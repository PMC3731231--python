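# Methods

`eqtlcre` implements an integrative cis-eQTL / cis-regulatory-element (CRE)
analysis as a reusable pipeline, validated end-to-end on synthetic data with
planted truth. This note documents the statistical models, the synthetic
data the tests run on, the numerical choices, and the limitations.

## Association model and Bayes factors

For a residual expression trait `y` (standard-normal quantiles after
normalization) and a mean genotype dosage `g` in [0, 2], association is
scored by the Bayes factor of the conjugate Bayesian linear regression

    y = mu + a g + d h(g) + eps,   eps ~ N(0, sigma^2),

against the null (`a = d = 0`), where `h(g) = min(g, 2 - g)` encodes
dominance (the heterozygote indicator on hard calls, extended linearly to
imputed mean dosages). Priors: `mu` flat, `sigma^2` Jeffreys, and effects
scaled by the residual standard deviation, `a ~ N(0, sigma_a^2 sigma^2)`,
`d ~ N(0, sigma_d^2 sigma^2)`. With flat-prior covariates projected out and
`A = Xc'Xc + D^{-1}`,

    BF = |D A|^{-1/2} (S1 / S0)^{-(n - q)/2},

with `S0 = yc'yc`, `S1 = S0 - yc'Xc A^{-1} Xc'yc`, and `q` the number of
flat-prior covariates. The BF is averaged over a grid of effect scales
`sigma_a in {0.05, 0.1, 0.2, 0.4}` with `sigma_d = sigma_a / 4` and uniform
weights; averaging happens in log space via log-sum-exp. Because the prior
scales with `sigma`, the BF is invariant to shifting or rescaling the trait,
and the symmetric prior makes it exactly invariant to allele relabeling
(`g -> 2 - g`).

A Monte-Carlo oracle (`mc_univariate_log10bf`) validates the closed form: it
draws standardized effects from the prior, integrates the intercept
analytically and the residual scale numerically on a log-sigma grid (the
Jeffreys measure is flat in log sigma), sharing no matrix identity with the
production path. Agreement is within a few thousandths of a log10 unit at
10^6 draws.

### Conditional (multivariate) Bayes factors

The conditional evidence for a focal SNP given previously accepted SNPs is
the marginal-likelihood ratio of the model with and without the focal SNP,
where the accepted SNPs' additive and dominance coefficients are nuisance
covariates with flat priors — they are integrated out exactly by projection,
the same treatment the intercept receives, and the effect-scale grid applies
to the focal SNP only. Consequences that the tests pin down: with an empty
conditioning set the conditional BF equals the univariate BF exactly; a
focal SNP orthogonal to the conditioning set keeps its univariate evidence
(up to sampling noise); a near-duplicate of an accepted SNP collapses to no
evidence. A joint-grid formulation (one shared scale across all SNPs) was
rejected because the grid couples the SNPs and biases the conditional BF
downward by ~0.2 log10 units even for orthogonal SNPs. Linearly dependent
nuisance columns (dominance duplicates additive when no minor-allele
homozygotes exist) are dropped by rank-revealing QR before projection.

## Expression preparation

The normalization pipeline mirrors standard array practice: log2 transform
with non-positive intensities floored at half the array's minimum positive
value; k-nearest-neighbour imputation of missing entries (k = 10 by default;
neighbours are trait columns ranked by mean squared difference over jointly
observed samples); per-array quantile transform to the average empirical
distribution; per-trait transform to standard-normal quantiles,
`Phi^-1((rank - 0.5)/n)` with average ranks at ties. Constant traits are
dropped with a warning before the cross-array step (afterwards they are no
longer detectable as constant).

Latent structure is removed by principal components: PVE is computed per
component, and PCs 1..k are regressed out where k counts the leading
components whose drop to the next PVE is at least `pve_delta` (default
0.01). Residuals are re-quantile-normalized per trait, so the association
input is exactly a standard-normal quantile set whenever ties are absent
(always true for generic residuals). The tie-sensitive caveat: the
cross-array quantile step can tie two samples at a trait when both rank it
identically within their arrays; such columns carry average-rank ties
rather than the exact quantile set.

Probes of the same gene are collapsed to probe-cluster traits by a Gaussian
mixture on the probes-by-samples matrix (embedded on up to three principal
components; spherical covariance; component count 1..3 chosen by BIC); each
cluster's trait is the per-sample mean of member probes. Multi-population
studies are handled by per-population inverse-normal transformation after
the cross-array step, then pooled.

Genotype QC: samples below a call-rate threshold are removed first, then
SNPs below a SNP call-rate threshold are dropped (reference-panel imputation
is out of scope, so a fully missing SNP cannot be rescued), then SNPs
failing a 1-df Hardy–Weinberg chi-square test at `hwe_alpha` (default 1e-4)
on rounded genotypes; remaining sporadic missing dosages are mean-imputed
per SNP.

## Tiers, allelic heterogeneity, and permutation FDR

LD blocks are delimited by inter-SNP intervals whose recombination rate
reaches `rate_threshold` (default 0.9 cM/Mb, config-exposed). Per gene and
probe cluster, the best SNP per block by univariate BF is a candidate; tier
1 is the top candidate, and tiers 2..4 are accepted greedily by conditional
BF given all accepted SNPs, each required to occupy a distinct block and to
meet the admission floor. Ties for best-in-block break to the lowest genomic
coordinate. Records are unioned across probe clusters; a gene with two or
more significant tiers exhibits allelic heterogeneity.

FDR is estimated from a single shared permutation of expression sample
labels (identical across genes, preserving the gene–gene correlation
structure): per tier and cutoff `c`, `FDR(c) = min(1, N_perm(c)/N_obs(c))`,
monotonized to be non-increasing in `c`; cutoffs with no observed
associations report FDR 1 (undefined). The significance cutoff for a target
FDR (default 10%) is the smallest `c` whose estimate drops below the target,
per tier; a tier-t record is kept only if every lower tier of its cluster
was kept, since its conditional BF conditions on them. More permutations are
supported (counts averaged), one is the default.

Forward-stepwise selection with BIC is the independent check on allelic
heterogeneity: each step adds the SNP (additive + dominance, two
parameters) that most improves BIC, stopping at no improvement. Under the
null with m candidate SNPs this greedy search selects at least one SNP with
probability about `1 - P(chi2_2 < 2 ln n)^m` (~0.22 at n = 200, m = 50) —
an inherent selection effect, not a bug. Because stepwise may pick several
tag SNPs inside one LD block while the tier scan is block-constrained,
method agreement is measured on the number of *independent signals*:
stepwise selections are collapsed to distinct LD blocks before comparing
counts.

## Bivariate (two-cell-type) model and the integrated Bayes factor

For a gene–SNP pair with paired traits in cell types A and B, five models
are scored against the joint null: A-not-B (`BF_A`), B-not-A (`BF_B`),
A-and-B (independent effects, `BF_A * BF_B`), stable (one shared effect on
the stacked data with per-cell-type intercepts), and A-opposite-B (shared
magnitude, sign-flipped dosage in B; the dominance column is not
sign-flipped since it encodes a deviation magnitude). Residuals are treated
as independent across cell types — the paired-sample residual correlation is
ignored in the likelihood (a documented approximation). The integrated
Bayes factor is

    iBF = log10( mean(BF_AnotB, BF_BnotA, BF_AandB, BF_AoppB) / BF_stable ),

i.e. a uniform prior over the four differential configurations against the
stable one; a pair is flagged differential when iBF > 0 strictly, and
flagged pairs are labeled by the largest differential BF. Label swap is an
exact symmetry: it exchanges A-not-B and B-not-A and fixes the other three.

Two behaviors worth knowing. First, power differs by model: A-and-B with a
dominant shared component is frequently absorbed by the stable model (the
confusion is one-sided and expected). Second, under the joint null the iBF
concentrates near zero, so the strict iBF > 0 flag behaves like a fair coin
on no-signal pairs; this is why the pipeline classifies only discovered
eQTLs, where at least one cell type carries real evidence.

## CRE overlap and enrichment

All intervals are 0-based, half-open; SNPs are points. A SNP overlaps an
element if its position lies in `[start - pad, end + pad)` with pad 500 bp
by default; replicate tracks are merged by interval union with half-open
adjacency (`[a,b) + [b,c) = [a,c)`). An insulator intervenes between a SNP
and a TSS when its midpoint `floor((start+end)/2)` lies strictly between
them; the degenerate SNP-at-TSS span is false. Every interval operation is
tested against an all-pairs brute-force oracle.

The background SNP set contains every SNP cis to at least one gene (within
1 Mb of TSS/TES, which contains the gene body), each assigned uniformly at
random to one of its cis genes. Four logistic regressions (fitted by IRLS
through statsmodels GLM; distances rescaled to Mb; Z = beta/SE with normal
two-tailed p) quantify: CRE overlap of eQTL vs background SNPs controlling
for signed/absolute TSS distance and expression level; within-cell-type
replication vs CRE overlap controlling for position, conditional BF and
tier; overlap across the background/tier-1/tier-2 grouping with a Wald test
of the tier-1 minus tier-2 contrast; and intervening-insulator presence for
tier-1/tier-2 pairs vs random cis pairs controlling for inter-SNP distance,
pair positions, and intervening hotspots/TSSs. Separation (unbounded
estimates) raises an error in direct use; the pipeline catches it and skips
the affected model, since sparse classes at small problem sizes can
legitimately separate.

Paired and unpaired categorical contrasts use exact tests: McNemar as the
exact two-sided binomial on discordant counts, Fisher via the
hypergeometric two-sided rule, both verified against exhaustive oracles on
all small tables. Binned replication curves use equal-width bins with
Wilson 95% intervals (empty bins flagged, not dropped).

## Replication and specificity prediction

A discovery association is replicated in a target study when the target's
univariate log10 BF is at least `bf_threshold` (default 1.0); pairs absent
from the target, or with MAF below `maf_min` (default 0.05) in either study,
are untested and excluded from denominators. A cell-type-specific eQTL
replicates within cell type but not between.

The random-forest classifier predicts the within / between / cell-specific
replication outcomes from discovery statistics (log10 BF, effect size,
signed and absolute TSS distance, expression) plus per-track CRE overlap
flags. Validation is stratified 10-fold cross-validation with pooled
out-of-fold probabilities; AUC uses the Mann–Whitney rank formulation
(equal to trapezoidal ROC integration); accuracy is thresholded at 0.5;
permutation importance is the mean held-out accuracy drop when one feature
column is permuted. The CRE ablation refits on identical folds without CRE
columns and reports the AUC gap. Forest size defaults to 500 trees.

For GWAS annotation transfer, a forest is trained on a reduced,
cell-portable feature set (activating / repressive / insulator overlap
flags only) to separate top eQTL SNPs from never-associated background
SNPs, then applied to a GWAS SNP list twice — with features computed from
the matched (disease-relevant) cell type's tracks and from an unmatched
cell type's — and the per-SNP probability shift is tested by the two-sided
Wilcoxon signed-rank test (identical feature sets short-circuit to p = 1).

## Synthetic data: what it emulates and what it does not

The generator is first-class, tested code; its defaults are the package's
study conditions (200 genes, 50 cis SNPs per gene, two cell types, 200
samples per study).

* **Genotypes.** One gene per chromosome with 50 SNPs at 2 kb spacing;
  recombination hotspots every 10th interval (2.0 vs 0.1 cM/Mb) delimit LD
  blocks. Haplotypes follow a block-exchangeable copying model: within a
  block each haplotype carries a backbone uniform which each SNP copies
  with probability `sqrt(within_block_r2)`, giving pairwise dosage
  correlation equal to the parameter at equal MAFs (attenuated when MAFs
  differ, drawn U(0.05, 0.5) per SNP) and exact independence across blocks.
  Monomorphic draws are resampled a bounded number of times. This is not a
  coalescent: no recombination gradients within blocks, no allele-frequency
  spectrum realism, no population structure.
* **Expression.** Traits are sums of planted additive effects, shared
  Gaussian confounders (three by default, contributing 30% of non-genetic
  variance, with loadings scaled exactly per gene) and Gaussian noise,
  emitted as array-like intensities `2^(y+8)` with 2% missingness so the
  normalization pipeline has real work. Planted effects are specified as
  variance explained (default R^2 = 0.15 per causal SNP) and realized per
  SNP from its dosage variance; tier-2 SNPs occupy different blocks than
  tier 1. Each eQTL gene carries one of the five bivariate classes
  (default mix 60/20/10/5/5% stable / A-not-B / B-not-A / A-and-B /
  A-opposite-B; A-and-B realizes a half-magnitude effect in B).
* **Studies.** Three studies: discovery and an independent replication
  cohort of cell type A (disjoint samples from one genotype pool, so the
  SNP panel and MAFs match), and a paired cell-type-B study sharing the
  discovery donors (as when two tissues are sampled from the same
  individuals) — which is what makes the bivariate model's paired-trait
  requirement satisfiable.
* **CRE tracks.** Activating / repressive / insulator interval tracks per
  cell type. Background intervals (200–600 bp) are seeded on non-causal SNP
  positions at rate 0.15; each causal SNP gets one coverage draw at
  `eqtl_enrichment`-fold that rate for activating (default 3x) and
  1/fold for repressive (a planted depletion); a covered causal interval
  exists in all of the SNP's matched cell types and leaks into unmatched
  ones only when not cell-type specific (`specific_fraction`, default
  0.3). Insulators are placed independently of SNPs. Discovered eQTLs are
  tag SNPs, not always the causal SNP, so measured enrichments are
  attenuated relative to the planted rates — the same conservatism real
  tag-SNP analyses face.
* **GWAS list.** A synthetic SNP list enriched (70%) inside the matched
  cell type's activating CREs stands in for a curated GWAS catalog.

Passing tests on these data demonstrate internal correctness and
calibration — recovery of planted structure, null behavior of the FDR
machinery, oracle agreement — not performance on real cohorts, where LD,
expression noise, probe artifacts and CRE boundary error are all harder.

## Numerical and reproducibility choices

Log-sum-exp for all BF grid averaging; `S1` clamped at the smallest
positive double before logs; rank-revealing QR for nuisance projections;
distances rescaled to Mb inside logistic fits. Every stochastic operation
takes an explicit seed; the pipeline derives per-stage streams from one
config seed, and two runs with the same config produce byte-identical
output files (fixed float formats in all writers). Problem sizes in the
test suite and the acceptance script (25–250 genes, 100–300 samples) were
chosen once as desk-scale conditions with adequate statistical resolution
for each check.

## Known limitations

The bivariate likelihood ignores paired-residual correlation; the iBF
threshold 0 is a convention (a positive threshold would trade recall for a
cleaner null); the copying LD model understates LD heterogeneity; the
stepwise null selection rate is inherent to greedy BIC; trans effects,
interaction models, multi-tissue (>2) sharing, genotype imputation to
reference panels and probe re-annotation are out of scope.
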