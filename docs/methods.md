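# Methods

This note documents the statistical models the package implements, the
choices made where the methodology leaves room, and what the synthetic
study design does and does not emulate.

## Differential expression and meta-analysis

The design is 2 groups (case/control) × 2 challenges
(allergen/diluent). Cultures may be paired (the pairing id is carried
in the sample annotations) but the analysis treats arms as unpaired,
matching the common situation where quality control breaks the pairing.
For log2-scale intensities the log2 ratio of arm means is the
difference of arm means; for linear-scale input it is
log2(mean₁/mean₂) with a delta-method standard error
`sqrt(v₁/(n₁m₁²) + v₂/(n₂m₂²))/ln 2`. The test is Welch's t
(unequal variances, Welch–Satterthwaite df); the optional permutation
p-value shuffles arm labels and recomputes t, two-sided with the
(b+1)/(B+1) add-one correction used for every permutation p in the
package. Cross-study pooling is fixed-effect inverse-variance on the
log2 ratios (weights 1/se²; pooled SE (Σw)^(−1/2); normal p). A gene is
*reproducibly* differentially expressed when its meta-analysis p is
strictly smaller than both its discovery p and the Bonferroni family
level α/m — strict inequalities, so a gene exactly at either boundary
fails.

## Gene-set enrichment

The hypergeometric test is one-sided (upper tail) on the 2×2 split of
the universe by significance and set membership; the default
significance rule is q < 0.05 and |log2 ratio| > 1, both exposed. Odds
ratios use the Haldane–Anscombe 0.5 correction when any cell is zero.
GSEA uses the weighted running sum (hits advance by
|score|^w normalized within the set, default w = 1; misses retreat by
1/(N−K)); the enrichment score is the signed maximum deviation. The
permutation null redraws K gene labels uniformly — phenotype
permutation is impractical at the sample sizes this design has — and
the p-value is one-sided in the observed direction **against the
same-signed part of the null only**: conditioning on the sign of the
maximum deviation and comparing against the full null makes null
p-values stochastically too small (observed mean ≈ 0.27 under pure
noise in our calibration), while the same-signed comparison restores
uniformity. Benjamini–Hochberg q-values are computed per test family
and the consensus rule requires both q's ≤ the FDR level (inclusive).
Mantel–Haenszel pooling of enrichment tables uses the statsmodels
stratified-table machinery; heterogeneity is Woolf's chi-square of
Haldane-corrected log odds ratios, flagged at p ≤ 0.2.

## GWAS pathway enrichment

Genes are scored by the minimum SNP p within ±50 kb of the gene span
(BED input is 0-based half-open; eligibility is
`start+1−w ≤ pos ≤ end+w`, inclusive). Genes without a window SNP are
excluded from both the observed statistic and the null. A set's
statistic is the number of member genes whose −log10 score reaches the
95th percentile of all scored genes (the cutoff quantile is a
parameter; the 75th percentile gives a less discrete count statistic
and is what the calibration suite exercises). The null draws equally
sized gene sets uniformly from the scored genes. The full MAGENTA
procedure additionally regresses gene scores on gene size, SNP density
and LD structure; the synthetic design has none of those confounders,
so the correction is omitted — on real data this makes long genes
over-score and is a known limitation.

## Co-enrichment and Pareto selection

The expression-side objective for a pathway is the **maximum** of its
GSEA and hypergeometric p-values (a pathway must pass both); the
GWAS-side objective is its permutation enrichment p. The combined
global p-value treats the pathway as significant only if every
component null is rejected: `1 − Π(1−p_k)` under independence, or the
conservative Šidák-corrected maximum `1 − (1 − max p)^K` (the default
for cross-dataset inference, since expression and GWAS cohorts can
share structure). Pareto efficiency is standard non-domination under
minimization of both objectives — no other pathway weakly better in
both and strictly better in one; duplicates do not dominate each other
— restricted to pathways with both p-values inside the nominal bound.
Ranking is by global p ascending with the expression odds ratio
breaking ties (larger effect first); raw p-values populate the
objective space while q-values govern the upstream consensus filter.

## Inter-pathway network

Given pathways A and B, the network members are the genes incident to
at least one **direct** interaction with one endpoint in A and one in
B; indirect edges never qualify, within-pathway edges never change
membership, and a gene annotated to both pathways may play either role
(it is kept once with a dual label). Connectivity is tested against a
degree-aware null: background nodes are assigned to log2-spaced degree
bins (bins merged upward until each holds ≥ 5 nodes), and each
permutation replaces the member set with a uniform draw from the same
bin profile. The direct statistic is the edge count among members; the
indirect statistic counts member pairs sharing a non-member neighbour;
per-node p-values compare each member's direct degree into the member
set with its degree into the sampled sets. This replaces
rewiring-based nulls with a simpler scheme that honours the same
contract (degree control) at desk scale. The drug view is a bipartite
graph from a (drug, gene, effect) table restricted to members, with
the modal effect tag per drug as consensus (ties are `ambiguous`).

## Coordination statistics

Correlation enrichment compares absolute Spearman correlations of
within-set gene pairs against set×rest pairs (or, for a response
vector, set genes vs remaining genes against the response; "rest"
always means all measured genes outside the set). Group means are
compared by Welch's t and by permuting set membership; the AUC is the
rank-sum probability that an in-group |ρ| exceeds a null |ρ| (ties
count half), with a Mann–Whitney p and a Hanley–McNeil 95% CI.

Dysregulated coordination: per gene pair, Spearman ρ is computed in
the case and control arms and their difference tested with Fisher's z,
`z = (atanh ρ₁ − atanh ρ₂)/sqrt(1/(n₁−3) + 1/(n₂−3))`, two-sided,
with |ρ| clipped to 1−10⁻¹⁰. The two-sided choice for both the
per-pair test and the excess test is the variant consistent with all
reference values of the excess analysis. The excess test counts pairs
with p < α (strict), reports the expectation N·α rounded half-up, and
computes an exact two-sided binomial test (minimum-likelihood
definition, as in `scipy.stats.binomtest`) on the raw count. No
multiplicity correction is applied to per-pair p-values: the statistic
deliberately counts *nominal* significances. The sign test for
cross-method superiority is P(X ≥ s), X ~ Binomial(n, ½), ties
dropped.

## Predictive regression

Q² uses k-fold cross-validation (default 7 folds with seeded fold
assignment; leave-one-out supported, since both conventions are common
for this panel size): per fold, predictors are standardized on the
training samples only, OLS is fitted (with a small fixed ridge penalty
of 10⁻³ only when predictors ≥ training samples), and
Q² = 1 − PRESS/TSS with TSS about training-fold means. The model p is
the overall F test of the full-data fit; the Q² permutation p permutes
the response. For a multivariate panel, Λ = det(E)/det(E+H) with E the
residual SSCP and H the hypothesis SSCP; 1 − Λ is reported as
multivariate R² with Rao's F approximation for the model p (verified
against an independent response-permutation null and against the
statsmodels MANOVA implementation in the tests). Out of sample, E is
accumulated from cross-validated residuals and E+H from held-out
deviations about training-fold response means. Coefficient
bi-clustering uses correlation distance with average linkage on the
standardized coefficient matrix; cluster support is the fraction of
sample-bootstrap refits in which a subtree's exact leaf set reappears,
significant at ≥ 0.95.

## Synthetic study design

Defaults emulate a small allergen-challenge microarray study: 300
genes, six disjoint pathways covering 160 of them, 20 samples per arm,
Gaussian noise (sd 0.5) on the log2 scale — the conventional noise
model for log-intensity microarray data. Planted signals:

* **Differential expression** on one pathway in the case-allergen arm,
  magnitudes uniform on [0.3, 2.7] (the reported fold-change range for
  pathways of this kind), signs negative with probability 0.8 —
  challenged pathways respond directionally coherently, and a
  signed-ranking GSEA can only detect coherent shifts.
* **Co-expression** as equicorrelated multivariate-normal blocks
  (ρ = 0.3 within the two named pathways).
* **Correlation disruption**: 15 *disjoint* gene pairs (each gene in
  at most one pair) whose correlation in the case-allergen arm is
  shifted by −0.6. Disjointness matters: for disjoint deltas inside an
  equicorrelated block the smallest eigenvalue of the target matrix is
  bounded below by (1−ρ)−|δ| > 0, whereas overlapping pairs readily
  make the matrix indefinite, and the nearest-PSD repair (eigenvalue
  clipping with unit-diagonal rescaling) then silently erodes the
  planted deltas. If the repair moves any planted correlation by more
  than 0.1 the generator raises an error naming the pairs.
* **GWAS signal**: 5000 null SNPs with Uniform(0,1) p-values at
  uniform positions on one chromosome (genes tiled 150 kb apart so
  50 kb windows never overlap); half the planted pathway's genes get
  one mid-gene SNP with p ~ Beta(0.1, 1).
* **Interactions**: Erdős–Rényi background (density 0.01) drawn over
  all gene pairs *except* the stratum crossing the two designated
  pathways, plus 10 planted direct crossing edges — so the planted
  edges are exactly the inter-pathway signal and extraction can be
  checked for exact recovery.
* **Protein response**: a linear mix of five network genes
  (coefficients |U(0.5, 1.5)|, random sign) plus Gaussian noise at
  half the signal sd.

Everything planted is serialized in the truth record; recovery tests
consume the truth, never regenerate it. Determinism: all generators
derive their streams from (seed, stream-id) pairs, so identical
configurations reproduce byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium and
uneven SNP density, probe-level artefacts and batch effects, scale-free
interaction topology, heavy-tailed expression noise, and overlapping
pathway annotations. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under its stated
assumptions, not that effect sizes on real data will match.

## Test-scale choices

The calibration suite checks uniformity of every p-value family on 20
simulated null studies (KS at α = 0.01) using a 150-gene, 15-per-arm
design, and recovery rates on 50 studies at the default design; these
sizes give recovery margins well clear of the pass thresholds while
keeping the whole suite in the low minutes on a single core.
Permutation counts in tests (100–500) are the smallest that leave the
add-one p-value floor below the decision thresholds in play.

## Known limitations

* The best-SNP gene score is not corrected for gene length or SNP
  density (see GWAS section); fine for the synthetic design, biased on
  real data.
* The binomial excess test assumes pair-level independence; pairs
  sharing genes are positively dependent, so its p-values on dense
  pair sets are approximate (the reference analyses share this
  property).
* Fisher's z on Spearman ρ uses the 1/(n−3) variance, which is
  slightly anticonservative for rank correlations at small n
  (the exact variance is ≈ 1.06/(n−3)).
* The degree-binned connectivity null controls the degree profile but
  not higher-order structure (clustering, communities).
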