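# Methods

## Model

`lcasub` fits a finite mixture over K latent classes to mixed-type
indicator data under local independence: given class membership, all
indicators are independent. Nominal and ordinal indicators follow
class-conditional multinomials θ_jkc; continuous indicators are normal
with class means μ_jk and a variance σ²_j that is pooled across classes by
default (fewer parameters, stabler EM) or class-specific via
`variance_mode="class_specific"`. Class weights π_k complete the
parameter set; the free-parameter count is
(K−1) + Σ_cat K(C_j−1) + Σ_cont (K+1) (pooled) or 2K (class-specific).

Ordinal indicators are deliberately modelled as unordered multinomials.
No adjacent-category or proportional-odds structure is imposed, because no
particular ordinal parameterisation is canonical for this kind of
questionnaire data and an unordered fit never biases the class-conditional
response probabilities. The ordering is used only downstream: conditional
means via equidistant integer scores in summaries, and min–max scaling in
profile matrices. A consequence is that BIC values are not comparable with
software that scores ordinal items inside the likelihood.

Missingness is assumed ignorable. A missing cell simply drops out of the
within-class product, so patients with partial data contribute exactly the
likelihood of their observed cells; nothing is imputed. Rows missing on
*every* variable carry no information and are rejected at dataset
construction (with identifiers), mirroring the usual exclusion of
completely missing patients.

## Estimation

EM from a seed-determined random initialisation: per-row responsibilities
are drawn from a symmetric Dirichlet(1), followed by an M-step. Iteration
stops when the relative log-likelihood change falls below `tol` (default
1e-8) or after `max_iter` (default 1000) iterations; non-convergence
returns the fit with `converged=False` and a warning. The log-likelihood
history is retained on every fit so the EM monotonicity guarantee is
assertable (tolerance 1e-8; the probability/variance floors below can in
principle perturb an update by that order).

Numerical guards: every multinomial cell is floored at 1e-6 and
renormalised after each M-step; each continuous variance is floored at
1e-6 times the variable's sample variance; E-step densities are computed
in log space with `logsumexp`. A class whose total posterior weight falls
below 1e-6 raises a class-collapse error rather than being silently
renormalised — the restart driver excludes that run and only fails if all
restarts collapse. Returned models are canonicalised by sorting classes in
descending π (stable sort), which breaks label switching across restarts;
modal assignment breaks posterior ties toward the lowest class index.

## Model search

For each K, `n_restarts` (default 10) EM runs start from seeds
`base_seed + index`. One fit is retained by the **BIC consistency rule**:
BICs rounded to two decimals are tallied; if a unique modal value with
multiplicity ≥ 2 exists, the best-log-likelihood fit among those attaining
it is retained — deliberately even when a lone restart reports a lower
BIC, since a recurring optimum is better evidence of the global one than a
single lucky run. Otherwise (all values distinct, or tied maximal
multiplicity) the minimum-BIC fit is retained. Two decimals was chosen as
the coarsest rounding that still separates genuinely different optima at
realistic likelihood scales. Note the rule's known failure mode: a *bad*
local optimum that recurs can outvote a better singleton, which is one
reason searches default to ten restarts.

The **starting model** walks K = 2, 3, … while
BIC(K) ≤ BIC(K−1) − 0.01·|BIC(K−1)| and returns the last K reached,
capped at the global BIC argmin (relevant when BIC is non-monotone beyond
the walk). Selecting a *preferred* model larger than the starting model is
a human, consensus-based judgement; the package stops at the starting
model plus the reports that inform that judgement.

**Loadings** quantify variable–subgroup association on a [0, 1] scale:
Cramér's V (from the χ² of the variable × modal-class table) for nominal
variables, and the correlation ratio η (between-class over total sum of
squares, square-rooted) for ordinal (integer-scored) and continuous
variables. These are scale-free stand-ins for the loosely specified
"correlation between each variable and the identified subgroups";
constant variables score 0 with a warning.

## Two-stage pipeline

Stage one fits a separate LCA inside each health domain (fixed per-domain
K, or searched) and assigns each patient to the domain category with their
largest posterior. Stage two runs the ordinary search on the derived
dataset of one nominal variable per domain. Design points: the derived
dataset is complete by construction (modal assignment is total); levels
never assigned remain declared (logged); assignment certainty is *not*
carried forward — hard assignment is the method's defining
information-loss trade-off, which is why second-stage posterior certainty
can only match or trail a single-stage fit on the same cohort. No
minimum-posterior screen is applied between stages.

## Diagnostics

- **Posterior summary**: median and IQR of per-patient maximum posteriors;
  counts of maxima strictly below 0.70 and of patients with posteriors
  strictly above one third for more than one class. Both thresholds are
  strict, so boundary rows (exactly 0.70 / exactly 1/3) are excluded; the
  multi-membership cut is one third, the natural "shared between classes"
  bound conventionally printed as 0.33.
- **Profile matrix**: per variable, class-conditional severity scores in
  [0, 1]. Continuous: mean scaled by the declared range (fallback: span of
  class means). Ordinal: integer-scored conditional mean over C−1.
  Nominal: score-weighted mean when the recode map carries numeric
  severity scores, else the probability of a designated severe level;
  without either the variable is excluded with a warning. `lower_worse`
  variables are reversed (x → 1−x, an involution) so higher always means
  more severe.
- **Features**: variables with ≥ 30% spread between their highest- and
  lowest-scoring classes, grouped greedily in descending spread; a
  variable joins the first group with which its class-score vector has
  Spearman rank correlation ≥ 0.6 against every member (tolerating minor
  profile crossings). A group is *quantitative* when no member pair orders
  two classes oppositely, else *qualitative*. The rank-correlation
  criterion replaces what is otherwise a visual judgement.
- **Subgroup sizes**: modal-assignment shares; classes below 5% are
  flagged, classes in [3%, 5%) pass conditionally when their
  distinguishing high-spread variables include declared
  under-represented characteristics, classes below 3% always flag.
- **Cross-tabulation**: joint modal counts with per-cell flags at
  precedence a (row maximum) > b (column maximum) > c (> 10% of row) >
  d (> 10% of column only). The flag definitions in circulating printed
  tables overlap contradictorily (cells flagged both "largest" and "not
  largest"); this precedence reproduces the unambiguous cells and is
  applied uniformly. Agreement reporting: per-row/column spread and
  concentration, greedy one-to-one matched percent agreement, and the
  adjusted Rand index computed from the contingency table (so it is
  available when only counts, not assignment vectors, exist); prevalence
  percentages round half away from zero.

## Synthetic cohorts

The generator emulates the study design the methodology targets, not any
real cohort's marginals. Default template: six domains, 112 variables
(mixed binary/multi-level nominal, ordinal 0–5/0–10 scales, three
continuous demographics), n = 928, planted per-domain category counts
(7, 7, 7, 7, 6, 8), three global classes with equal weights, separation
0.8, 5% MCAR missingness — calibrated so ≥ 95% of rows are > 86% complete.

Structure is layered: global class → domain category → indicators. The
class-to-category coupling ships in three regimes: `identity` (category =
class; requires per-domain categories = number of classes; indicators are
then an exact locally independent LCA), `noisy` (δ-mixture of a
class-preferred category and a uniform), `independent` (null). Categorical
indicators interpolate θ(δ) = (1−δ)·uniform + δ·point-mass at a
category-dependent preferred level ((category + variable index) mod C);
continuous indicators get δ-scaled equally spaced mean offsets (sd = 15%
of the declared range, draws clipped to it). Because preferred levels
alias when C is smaller than the category count, single binary items
cannot separate all categories — realistic for questionnaire items, and
the reason "maximal separation" checks use δ = 1 and multi-restart fits.
MCAR is the only missingness mechanism; masks that would empty a row are
redrawn.

What passing recovery tests on these cohorts shows: the estimator, search
rules and pipelines behave correctly when the data-generating process
matches the model (and degrade gracefully under the null). What they do
not show: robustness to violations real cohorts exhibit — within-domain
residual dependence beyond the planted coupling, non-ignorable
missingness, ordinal response styles, or unequal domain informativeness.

## Simulation-study sizes

Repeatable studies (`lcasub.experiments`) use a compact six-domain design:
4 variables per domain (24 total), 3 planted categories per domain,
identity coupling, n = 1000, separation 0.85, 5% missingness, EM tolerance
1e-7 with 5 restarts (a scaled-down version of the 10 used for real
searches), 20 generator seeds per study. With these sizes a full study
battery (weight recovery, class-count recovery over K = 1..6, two-stage
recovery and certainty comparison) completes in minutes on one CPU.
Fitted-vs-true class matching uses the Hungarian algorithm on the
confusion matrix; class-count recovery means the BIC argmin equals the
planted count.

## Known limitations

- No covariates on class membership, no ordinal logit parameterisations,
  no Bayesian estimation, no bootstrap likelihood-ratio tests.
- BIC values are not comparable with commercial LCA software whose ordinal
  and variance parameterisations differ; equivalence is not claimed.
- The consensus step that promotes a preferred model beyond the starting
  model is intentionally not automated.
- Pooling and recoding decisions are declarative codebook rules; the
  clinically motivated judgement of *which* items to pool cannot be
  automated and is not.
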