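# Methods

## The model

`sumgene` performs gene-based (region-based) association testing from
GWAS summary statistics. For a gene with m variants the inputs are the
vector of per-variant z-scores **z**, the m×m Pearson genotype
correlation (LD) matrix **R** estimated on the analysis sample or an
ancestry-matched reference panel, and a non-negative weight vector
**w**. Under the null hypothesis of no association and large n,

  **z** ~ N(0, **R**),

so any quadratic or linear statistic in **z** has a known null
distribution given **R**, and the classical individual-level score tests
can be recomputed without genotypes. The six tests:

| test  | statistic | null distribution |
|-------|-----------|-------------------|
| burden (BT) | (wᵀz)² / (wᵀRw) | χ²₁ |
| SKAT  | Σ w²ₖz²ₖ | Σ λₖχ²₁, λ = eig(WRW) |
| SKAT-O | min-p over Q_ρ = (1−ρ)Q_SKAT + ρQ_BT | one-dimensional integral over the conditional mixture |
| ACAT-V | Σ ωₖ tan((0.5−pₖ)π) / Σ ωₖ | standard Cauchy |
| FLM   | uᵀΣ⁻¹u, u = BᵀWz, Σ = BᵀWRWB | χ²_K |
| PCA   | Σ over leading PCs of (projected score)²/λ | χ²_k |

**Weight scale.** Weights act on the standardized-genotype scale: z and
R are the sufficient statistics, and both are invariant to per-variant
dosage scaling, so this is the natural scale for a summary-statistics
formulation. The classical raw-dosage weighting is recovered by
multiplying w by the per-variant dosage standard deviations. BT, SKAT,
SKAT-O and PCA p-values are invariant to positive rescaling of w.

**The omnibus grid.** No single test is uniformly most powerful; which
one wins depends on the gene's unknown architecture (effect direction
consistency, sparsity, positional smoothness). Each selected method is
therefore evaluated for every combination of beta-density MAF weighting
function (i ∈ [1, I]; defaults Beta(1,25) and Beta(1,1)) and
causal-probability annotation channel (j ∈ [0, J]; j = 0 = no
annotation, probabilities multiply the weights). The p-value lattice is
combined by a two-level Cauchy (ACAT) scheme — first across the (i, j)
cells within a method, then across methods. Cells that fail
preconditions (e.g. the FLM collinearity filter) are omitted from the
combination rather than imputed at p = 1, which would bias the Cauchy
sum toward the null.

## Quadratic-form p-values

Tail probabilities of Σ λₖχ²₁ are computed by Imhof's numerical
inversion of the characteristic function (adaptive quadrature on the
oscillatory integrand), with two exact shortcuts (single eigenvalue;
all eigenvalues equal) and a Kuonen saddlepoint (Lugannani–Rice) fallback
whenever the inversion integral returns p ≤ 1e-9, a non-probability, or
a large error estimate. The engine is validated against closed-form
chi-square cases and a frozen 10⁷-draw Monte-Carlo value.

SKAT-O follows the standard optimal-test construction: per-ρ p-values
from the mixture spectra of M_ρ^{1/2}ΦM_ρ^{1/2} (Φ = WRW), the minimum
p referred to its null distribution through the one-dimensional
conditioning integral on the burden direction, with the small-sample
variance adjustment and a moment-matched (Liu) quantile for the per-ρ
thresholds. The conditional mixture survival is evaluated at 30 nodes
and interpolated on the log scale before the outer expectation is taken
on a dense grid — the absolute interpolation error is far below the
Monte-Carlo validation tolerance. ρ grid default
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; ρ ≥ 0.999 is capped inside
the integral (the ρ = 1 component is exactly the burden test). The
result is clamped to [min-p, min-p × grid size] (Bonferroni bound).

## FLM and PCA specifics

FLM expands the genetic-effect function over K basis functions (cubic
B-splines with uniform clamped knots by default, Fourier as an
alternative; K = 25) evaluated at variant positions rescaled to [0,1].
The collinearity filter rejects the cell when m ≤ K or when the
basis-projected covariance has condition number above 1e8 — strongly
dispersed weights (Beta(1,25) over a wide MAF range) trip this filter
often, which is the intended behavior. PCA keeps the smallest set of
leading eigencomponents of WRW whose cumulative eigenvalue share
reaches `pca_var_prop` (default 0.85).

ACAT-V uses Cauchy weights ωₖ = wₖ²·MAFₖ(1−MAFₖ) (mirroring the
variance of a standardized per-variant score), switchable to plain wₖ².
Very rare variants are not pooled into a mini-burden — per-variant MAC
is not reliably available from summary statistics; the recommended
MAC ≥ 5 input filter handles that upstream.

## Large-gene approximation

Kernel tests cost O(m³). For genes with more than `trigger_m` = 500
variants (strictly greater), SKAT, SKAT-O, PCA and FLM route through a
split approximation: variants are divided by their weighted p-values
p*ₖ = two-sided tail of zₖwₖ into a low group (p* ≤ t, default
t = 0.8) and a high group; the exact test runs on the low group with
the matching principal submatrix of R (a principal submatrix of a PSD
matrix is PSD, so no re-repair); the high group contributes the plain
arithmetic mean of its p*; the two are ACAT-combined. At t = 1 the high
group is empty and the approximation is exactly the base test. BT and
ACAT-V are linear-time and never approximated.

**Why the weighted z is not renormalized.** The split must not select
variants on their observed z — a subgroup selected for large |z| and
referred to its unconditional sub-spectrum null is anti-conservative,
increasingly so with m. On the natural beta-density scale the flat
function Beta(1,1) is identically 1 (so constant weights reproduce the
ordinary p, and under the null a threshold t retains a fraction t of
variants — the source of the 1/t³ ≈ 2 expected speed-up for cubic-cost
tests at t = 0.8), while dispersed functions such as Beta(1,25) take
values ≫ 1 at low MAF: up-weighted variants then have small weighted p
regardless of z, and the variants relegated to the high group are
precisely those whose weight — hence whose contribution to both the
statistic and its null spectrum — is negligible. Renormalizing by
max(w) destroys this property (we measured R² = 0.79 and inflated
deviance two orders of magnitude above the conservative one at
m = 500–2000); the raw scale gives R² ≈ 0.99 with the conservative
deviance dominating, and raising the threshold makes the approximation
more conservative and inflation rarer — the trade-off that motivates
the 0.8 default.

The evaluation harness (`threshold_scan`) reports, per threshold, the
determination coefficient R² between −log10 p of original and
approximated tests and the two deviances
dev = Σᵢ (log10 P_Aᵢ − log10 P_Oᵢ)², summed separately over genes where
the approximation is conservative (P_A > P_O) and inflated (P_A < P_O).

## Polygene pruning

A genome-wide-significant hit just outside a gene leaks into the
gene-based statistic through LD. Pruning removes every within-gene
variant with r² ≥ 0.5 (configurable) against any outside variant with
p < 5e-8 within a 1 Mb flank. The thresholds are deliberately mandatory
configuration with logged values: they are GWAS-convention defaults,
not calibrated constants. When cross-correlations between gene variants
and outside hits are unavailable, pruning is skipped with a prominent
warning rather than silently passing.

## Synthetic data and what it does (not) show

Genotypes follow a latent-Gaussian threshold model: two haplotype
layers of an AR(1) latent field with correlation exp(−ld_decay·|a−b|)
(default decay 0.1, adjacent-variant latent r ≈ 0.90), thresholded at
the normal quantile of each variant's MAF (log-uniform on
[0.005, 0.5] by default) and summed — Hardy–Weinberg dosages with
tunable LD and exact target frequencies in expectation. Quantitative
phenotypes add N(0, effect_sd²) effects on standardized dosages for a
`causal_frac` share of variants to unit-variance noise; binary traits
threshold the latent value at the target prevalence.

`gwas()` emits score-test z-scores (null residual variance shared
across variants) rather than per-variant Wald z. The two agree to
O(z²/n), but the score form makes the summary-level tests *exactly*
equal to the individual-level score tests when the LD panel is the
analysis sample — the equivalence suite asserts agreement within 1e-3
on −log10 p and observes ~1e-12.

For the large-gene suites, genes are drawn directly at the summary
level, z ~ N(Rδ, R) with analytic AR(1) R — valid because the quantity
under study is a deterministic function of (z, R, w). The gene
landscape emulates a biobank-scale polygenic trait: half the genes
null, the rest carrying round(0.005·m) causal variants with
non-centrality δ ~ N(0, 3.5²), spreading −log10 p from 0 to ≈ 30.
Problem sizes in the shipped suites (equivalence at n = 5000,
m ≤ 100; 200 genes of 500–2000 variants; 1000 null genes at
n = 10,000, m = 60) are the package's chosen desk-scale designs. The
null study uses n = 10,000 so the rarest simulated variants
(MAF 0.005, expected MAC ≈ 100) have effectively Gaussian score
statistics — the regime the z ~ N(0, R) premise assumes and that
biobank GWAS exceed by one to two orders of magnitude; at much smaller
n the skew of rare-variant score statistics, not the region tests,
dominates calibration error.

Not emulated: imputation noise and INFO-score error, population
stratification, relatedness, case-control imbalance (binary z-scores
are plain logistic score statistics without saddlepoint correction and
are documented as valid for reasonably balanced designs only),
multi-allelic sites, and strand ambiguity in the generator itself
(alignment handles it for real inputs). Passing tests therefore
demonstrate internal correctness and calibration under idealized LD
and well-behaved z-scores, not robustness to those artifacts.

## Numerical choices and degenerate inputs

- p-values from z use erfc (accurate past |z| = 8); −log10 p via
  `log_ndtr` for p below 1e-300.
- ACAT: p = 1 inputs perturbed to 1 − 1/d; p < 1e-15 handled by the
  tan asymptote 1/(pπ); p floored at 1e-308 before the transform;
  Cauchy survival computed via arctan(1/T) in the tails.
- Burden with wᵀRw ≤ 1e-12 (after scaling w to max 1), all-zero
  effective weights, or an all-nonpositive spectrum raise typed
  degenerate-test errors; the omnibus logs and omits such cells.
- LD repair clips negative eigenvalues at zero and rescales to unit
  diagonal (minimal, deterministic perturbation); repair is a no-op for
  matrices already PSD within 1e-10.
- Monomorphic panel variants are excluded from LD with a warning;
  variants in the statistics but absent from the panel are excluded
  from the gene (no correlation information exists for them).
- Ambiguous-strand variants (A/T, C/G) are dropped during alignment by
  default — a silent sign error corrupts burden-type tests.

## Known limitations

- The Cauchy combination's validity under dependence is a *tail*
  property. Over a grid of strongly positively dependent cells the
  combined null p is close to nominal at conventional significance
  levels (measured type-I 0.04–0.06 at α = 0.05 across cells, omnibus
  tail fractions 0.014 at 0.01) but conservative through the middle of
  the distribution (ECDF ≈ 0.41 at p = 0.5): a combined p near 1
  requires all dependent cells to be simultaneously null-extreme. The
  omnibus p is therefore *valid* for significance testing but not
  KS-uniform under the null — a goodness-of-fit test on thousands of
  null genes will reject uniformity without implying inflated error
  rates.
- SKAT-O's one-dimensional integral is itself an approximation; like
  the reference construction it is least accurate for large p (center
  of the distribution), where accuracy is inconsequential.
- The large-gene approximation's mean-p arm makes null genes mildly
  conservative (combined p pulled toward 1), visible as the dominant
  deviance term at t = 0.8.
- Annotation probabilities enter multiplicatively on the weight scale;
  other functional forms (e.g. on the squared-weight scale) would
  change the lattice but not the machinery.
- Cross-population LD mixing is the user's responsibility; the package
  performs no ancestry checks.
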