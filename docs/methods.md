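# Methods

`shortscale` builds and evaluates short forms of hierarchical ordinal
trait inventories: from a pool of Likert-type items organised as items →
facets → domains, it selects a fixed number of items per facet (two, by
default) so that the resulting instrument jointly optimises model fit,
model-based reliability, and part–whole validity, and it then evaluates
the shortened instrument the way a psychometric validation study would:
fit indices, multi-group measurement invariance, reliability, and
criterion-validity contrasts. The concrete default templates mirror a
34-item short form of a 220-item maladaptive-trait inventory (17 facets,
6 domains, 4 response categories), but every component is generic.

## Measurement model

The latent-response model is a second-order factor model on the probit
scale. Each ordinal response X_i arises by thresholding a standard-normal
item latent y*_i at increasing thresholds τ_i:

    y*_i = λ_i η_f(i) + ε_i          (items on facets)
    η_f  = γ_f ξ_d(f) + ζ_f          (facets on domains)
    corr(ξ_d, ξ_e) = Φ_de            (domains correlate freely)

with all latent variables standardized in the reference population, so
the implied polychoric correlation between items i and j is
λ_i λ_j · corr(η_f(i), η_f(j)), where corr(η_f, η_g) = γ_f γ_g Φ_de for
different facets and 1 within a facet.

Two identification modes are supported:

* **Essential tau-equivalence** (default): all unstandardized first- and
  second-order loadings fixed to 1; domain variances ψ_d, facet
  disturbances ζ_f and domain covariances free. On the correlation
  metric the implied matrix is then *block-constant* — same facet:
  ψ_d + ζ_f; same domain: ψ_d; across domains: c_de.
* **Congeneric**: loadings free with latent variances fixed to 1 (an
  identity rescaling of marker-fixing).

## Estimation

Estimation is two-step DWLS. Step 1: item thresholds from the probit of
the univariate cumulative category proportions (zero-frequency
categories are merged into their lower neighbour and logged). Step 2:
each pairwise polychoric correlation maximizes the bivariate-normal cell
likelihood with thresholds fixed, via bounded one-dimensional search
(estimates clamped to ±0.999). The bivariate normal CDF uses the exact
single-integral (Drezner–Wesolowsky) identity evaluated by 48-node
Gauss–Legendre quadrature; this is deterministic and accurate to ~1e-12.
Missing data are handled by pairwise deletion.

The structural model minimizes the diagonally weighted least-squares
discrepancy F(θ) = Σ_j (s_j − σ_j(θ))² / w_j over the non-redundant
polychorics. The weights w_j are asymptotic variances estimated from
per-respondent influence functions of the two-step estimator; the
influence function includes the propagated effect of threshold
estimation, which matters (ignoring it underestimates the variance by
~20% and mis-calibrates the test statistic). The full influence matrix
is retained so that the scaled statistic below can use the complete
asymptotic covariance without ever materializing it.

For the tau-equivalent mode the discrepancy separates by parameter
(every correlation belongs to exactly one block), so the exact global
minimizer is a set of weighted block means computed in closed form — no
iteration, bitwise deterministic. The congeneric mode is fitted by
bounded L-BFGS-B with an analytic gradient (verified against finite
differences to 1e-9); starts are fixed (loadings 0.7, domain
correlations 0.2) with one fallback restart at 0.4, so fits are
reproducible. Negative variances are *not* clipped during estimation;
they surface as Heywood flags (negative disturbance, standardized
loading above 1, latent correlation outside [−1, 1]).

### Test statistic and fit indices

T = (n−1)·F is mean-scaled by c = tr(U Γ)/df, with U the
residual-projection weight implied by the DWLS fit and Γ the asymptotic
covariance of the fitted statistics (full covariance via the influence
matrix when available, diagonal otherwise). With influence-based Γ the
mean of T_s/df over replications of a well-specified model at n = 500 is
within a few percent of 1. CFI uses a zero-correlation independence
baseline; RMSEA = √(max(T_s − df, 0)/(df (n−1))) with a 90% CI by
noncentral-χ² inversion; SRMR is the root mean square correlation
residual. Inside search loops a fast mode uses the diagonal-Γ shortcut
(T_s = F exactly, since the fitting weights are the acov diagonal) and
defers the RMSEA CI; this preserves the ordering of candidates and is
never used for reported fits.

## Reliability

McDonald's ω on the latent-response metric:
ω = (Σλ)²/((Σλ)² + Σ(1−λ²)) per facet. For domains both variants are
reported: ω_hierarchical counts only domain-factor variance (item
loading λ_i γ_f), ω_total also counts facet-specific variance, computed
from the model-implied composite variance. ω_total is the headline
domain figure, consistent with published domain reliabilities of the
same magnitude as facet reliabilities. For two-item tau-equivalent
facets, ω equals the Spearman–Brown-corrected inter-item polychoric
exactly.

## Item selection (MAX–MIN ant system)

Candidate short forms pick 2 items per facet. Each item carries a
pheromone level; an ant samples a pair per facet sequentially with
probability proportional to pheromone; the sampled model is fitted
(tau-equivalent, closed form) and scored by a weighted sum of
logistic-transformed statistics:

* Objective A: CFI (b=.95, a=100, ↑), RMSEA (b=.05, a=100, ↓),
  SRMR (b=.06, a=100, ↓), mean facet+domain ω (b=.70, a=30, ↑).
* Objective B: CFI, RMSEA, mean ω as above, minimum first-/second-order
  standardized loading (b=.50, a=20, ↑), and the mean part–whole
  correlation between the 2-item facet score and the full-pool facet
  score (b=.80, a=30, ↑).

After each iteration pheromone decays by ρ = 0.95 and the best solution
deposits its objective value on its items; levels are clamped to
[φ_min, φ_max] with φ_max = best/(1−ρ). The pheromone floor follows the
standard MAX–MIN schedule: φ_min is set per facet so that a fully
converged state reconstructs the incumbent with probability
p_best = 0.05. (The simpler φ_max/(2·pool) floor is available but cannot
concentrate on 17-facet problems: the probability of re-sampling the
incumbent falls to ~1e-4, so improvements are never retained.) On
stagnation (no meaningful improvement — more than 1e-3 — within the
stagnation window) pheromones are re-initialized and the next deposits
follow the new restart's own best; the overall best across restarts is
returned. Defaults: 16 ants, 300 iterations, stagnation window 30, two
restarts; `ACOConfig.scaled_for(pool)` lengthens the budget
proportionally for large pools (the 141-item template gets 2800
iterations, window 240, three restarts).

Non-converged fits score 0. Heywood-flagged fits are scored normally but
flagged; the inadmissibility exclusion is applied at the final ranking,
not inside the search. This matters: on a pool with strong planted items
among weak distractors, every selection mixing strong and weak facets
within a domain has a genuinely negative facet disturbance, so
zero-scoring Heywood solutions would wall off the optimum from every
search path.

### End-to-end pipeline

Stratified 70/30 train/test split (largest-remainder allocation per
stratum). Both objectives are run three times each on the training
split; all six solutions are re-fitted on the test split and sorted by
test CFI, then RMSEA, then SRMR. Among the best three, facet pairs
replicated at least twice are fixed; the remaining facets are enumerated
exhaustively over the candidate items occurring in the top solutions
(capped at 1e5 models; if the cap would be exceeded the consensus
tightens to the top two and then the single best solution). Candidates
are ranked on the test split — CFI, then RMSEA, then mean facet ω —
after dropping any with test-split Heywood flags. The content-validity
judgment among leading candidates is deliberately left to the user.

On the planted-pool template, recovery is driven by objective B: its
part–whole and minimum-loading components discriminate along the whole
ascent, whereas objective A's components barely rank pure-block
selections (they all fit essentially perfectly, and the ω logistic is
flat below ~.55). A-runs therefore tend to converge to distractor
regions; the consensus of the B-runs carries the final selection.

## Screening

Per respondent: missing fraction; average longstring (mean length of
maximal runs of identical consecutive responses; missing breaks runs);
squared Mahalanobis distance on mean-imputed item scores with ridge
1e-6·trace/p; even–odd consistency (Pearson correlation across facets of
even- vs odd-positioned half scores, Spearman–Brown corrected, clamped
to [−1, 1]). Inclusion requires <10% missing items and every index
within 2.5 reference SDs. On 34 four-category items the longstring and
even–odd indices are markedly skewed, so about 5% of perfectly clean
simulated respondents fall outside 2.5 SDs (a normal tail would predict
0.6%); variance-stabilizing transforms do not remove this. The rule is
kept literal; its clean-data retention (~95%) is consistent with
published retention rates of 90–93% that include real careless
responders.

## Measurement invariance

Four nested multi-group models are fitted to each group's polychorics
*and* thresholds jointly (thresholds weighted by their own
influence-function variances): (1) configural — per-group congeneric
fits, thresholds saturated; (2) equal thresholds and latent intercepts —
one shared threshold vector, non-reference groups gain item scale
factors and latent domain means; (3) + equal loadings in the reference
group's metric, non-reference groups gain free latent (co)variances;
(4) + equal item residual variances (scale factors become
model-implied). Degrees of freedom are statistics minus free parameters
under this parameterization. Levels 2–4 are optimized jointly by
L-BFGS-B after a cheap threshold-block staging pass that supplies warm
starts; nesting (F non-decreasing up the ladder) is checked on every
run. A level passes relative to its predecessor iff ΔCFI < .01,
ΔSRMR < .01 and the RMSEA 90% CIs overlap. No partial-invariance search
is attempted.

## Validation statistics

Correlations pool across samples on the Fisher-z scale (unweighted by
default, (n−3)-weighted optionally). Differences between two dependent
overlapping correlations get the Zou-style CI built from the individual
Fisher CIs and the estimated correlation between the two estimates;
simulated coverage at n=200 is nominal to within ~1%. Cohen's d uses the
pooled-SD form with a noncentral-t CI. Convergent short-vs-long
correlations are computed on overlapping items, which inflates them —
reports carry that caveat. Profile tables give per-group z-means and
quartiles against reference norms, between-group d with CI, and
within-group short-vs-long d.

## Synthetic data

The generator draws domain factors from N(0, Φ), facet factors as
γ·domain + disturbance, item latents as λ·facet + uniqueness, and
discretizes at per-item thresholds — exactly the estimation model, so
parameter recovery is a sharp self-consistency test. Defaults emulate
the study conditions: Φ has off-diagonal entries from .06 to .48
averaging .32; γ = λ = .80; thresholds (−0.2, 0.6, 1.4), right-skewed as
typical of maladaptive-trait items (a symmetric option exists). The
`pid5bfplus` template is the 34-item short form; `pid5pool` is the
141-item pool (facet pool sizes 7, 9, 7, 10, 7, 6, 5, 10, 6, 7, 6, 9,
8, 13, 12, 9, 10) with exactly two λ=.80 items planted per facet among
λ=.40 distractors. Groups can deviate by threshold shifts, loading
scaling, or domain-mean shifts; careless responders (constant or
uniform-random rows) and MCAR missingness can be injected.

What the generator does *not* emulate: item wording effects, correlated
residuals, acquiescence or other response styles, non-normal latent
traits, and real diagnostic-group mixtures. Passing tests therefore
demonstrate internal consistency of the machinery under its own model,
not robustness to violations of it.

## Problem sizes used in tests and the acceptance script

Replication counts and sample sizes were chosen so each check has clear
resolving power at desk scale: oracle equivalence on the enumerable
{4,4,5,5} pool (3,600 selections, 20 seeded runs); planted recovery on
the full 141-item pool at n=2,000 with one pipeline run; calibration
over 200 replications at n=500 on a 12-item model; ladder operating
characteristics on a 16-item, 4-domain instrument at n=1,500 per group
(20 shift replications in the test suite, 10 in the acceptance script);
Zou coverage over 2,000 replications at n=200. The acceptance script
derives every random stream from the single `--seed` argument.

## Known limitations

* Objective A cannot recover planted structure on its own (see above);
  this reflects its information content, not a search defect.
* The scaled statistic uses mean (not mean-and-variance) scaling.
* Invariance levels 2–4 rely on numerical optimization; the nesting
  check guards against (rare) incomplete convergence.
* Standard errors of structural parameters are not computed — the
  pipeline consumes only fit statistics and point estimates.
* The Bayesian re-estimation sometimes used when DWLS produces Heywood
  cases in validation samples is out of scope; such fits are flagged and
  left to the analyst.
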