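# Methods

## The model

`censherit` fits a Bayesian multi-trait animal model to populations in which
one trait — growth rate at a target body weight (`GR_SW`, g/day) — is
recorded longitudinally under sequential threshold harvesting, while the
remaining traits are cross-sectional. The linear model is

    y = Xb + Za + Mc + [0; Sr] + e,

with breeding values `a ~ N(0, A ⊗ G0)` over the pedigree's numerator
relationship matrix `A`, common-fullsib effects `c ~ N(0, I ⊗ C0)` (one
vector per fullsib family; non-genetic variation shared by sibs reared
together), a scalar permanent effect `r ~ N(0, σr²)` per fish carrying
repeated growth records, and residuals that are correlated within a
cross-sectional block (the four same-age traits; the three slaughter-quality
traits) but independent across blocks and independent per record for the
longitudinal trait (variance `σe8²`). Residual covariance between `GR_SW`
and the other traits is structurally zero — the longitudinal trait has many
residuals per fish where the quality traits have one, so such covariances
are not estimable, and the block-diagonal residual structure encodes that.

A fish alive at event `j` with body weight below the threshold contributes a
left-censored record: its growth rate is known only to satisfy
`y ≤ TW_j / t_ij` (threshold weight over age in days from first feeding,
because body weight = growth rate × age under the linear-growth definition of
the trait). Inside the Gibbs sampler these records are augmented from the
truncated normal located at the fish's current linear predictor. Because the
record's fixed effects include the sampling group (event × year class), the
per-event means of the augmented-plus-observed values estimate the growth of
*all* fish alive at the event, undoing the harvest selection.

Fixed effects: each cross-sectional block carries one combined factor
(year-class × tank × sex by default); the longitudinal trait carries additive
factors, the first (sampling group) holding the level means and the rest
(sex) corner-point constrained. Levels are built from the data, so an empty
level cannot arise silently; an explicit estimability check rejects factors
with empty levels. When a tank factor is collinear with sampling group (one
grow-out tank per year class), it is simply omitted from the default factor
list.

## Gibbs sampler

One sweep updates, in fixed order:

1. **Censored growth records** — truncated-normal draws at the current
   predictor, bounded by `TW_j/t_ij`. The sampler uses the inverse-CDF method
   down to five standard deviations below the mean and a translated
   exponential rejection sampler beyond, so bounds arbitrarily far into the
   tail are handled exactly (verified eight standard deviations out).
2. **Missing cross-sectional traits** — conditional Gaussians within their
   residual block, vectorized by missingness pattern.
3. **Location effects** in the order fixed effects, breeding values, fullsib
   effects, permanent effects. All updates are conditionally independent
   across units except the breeding-value sweep, where `A⁻¹` couples
   relatives; that single step is a sequential numba kernel, everything else
   is vectorized numpy.
4. **Variance components** — inverse-Wishart full conditionals for `G0`
   (scale `a'A⁻¹a` plus prior scale, df = animals + prior df), `C0` and the
   residual blocks, and scaled inverse-chi-square conditionals for `σe8²`
   and `σr²`.

### Blocked updates for slow directions

Single-site Gibbs mixes extremely slowly in animal models because the data
constrain only sums of effects: each record sees `a_i + c_f (+ r_i)`, and a
founder is seen only through its progeny. Production samplers historically
compensate with chain lengths in the millions. To make desk-scale chains
usable, three exact blocked updates replace or follow the single-site ones:

* each family's fullsib vector `c_f` is drawn **jointly with a common shift
  of its members' breeding values** (a 2T-dimensional Gaussian whose data
  part acts on the sum direction and whose pedigree/family priors break the
  degeneracy);
* each fish's permanent effect is drawn jointly with its own breeding value
  for the longitudinal trait (2×2 conditionals);
* each sire's and each dam's breeding value is drawn jointly with a common
  shift of its offspring (founders have no records, so their values are
  otherwise dragged along by progeny one site at a time).

Groups are disjoint given the fixed parents, so each move is one vectorized
batch. Members that are themselves parents would bring their own progeny
terms into the conditional; such groups fall back to the unblocked update
(irrelevant for two-generation data, where phenotyped animals have no
progeny). The whole transition kernel — augmentation, locations, blocked
moves, variances, with multi-trait blocks, censoring and the permanent
effect — was verified by successive-conditional (``getting it right'')
simulation: iterating data-step and kernel-step leaves the prior invariant,
and the sampled quantiles match direct prior Monte Carlo.

### Priors and starting values

Priors are weak and configurable: inverse-Wishart with df = dimension + 2
and diagonal scale matrices set to 30% (G0), 10% (C0) and 60% (residual
blocks; 50% for the longitudinal residual, 10% for the permanent variance,
df 4.1) of the method-of-moments phenotypic variances, so each prior mean
matches the corresponding share of phenotypic variance while contributing
the weight of only a handful of observations. Fixed effects carry flat
priors.

Starting values matter at desk-scale chain lengths. When the pedigree
contains enough paternal halfsib structure (at least ten sires, five with
two or more dams), `G0` and `C0` start from the classical moment
decomposition — fullsib covariances estimate `G0/2 + C0`, halfsib
covariances `G0/4` — projected to positive definiteness, with residual
blocks taking the remainder of the within-animal covariance and the
permanent variance the remainder of the longitudinal variance after the
within-fish residual estimate. Otherwise initialization falls back to a
fixed 30/10/10/remainder split of the phenotypic variances. Effects start at
zero, fixed effects at level means, and censored records at level means
clipped below their bounds.

## Synthetic populations

The generator reproduces the statistical structure the model assumes, plus
the harvest protocol:

* **Mating design**: `n_dams ≥ n_sires`, one sire per dam, at most two dams
  per sire (surplus dams become second mates). Defaults: 120 sires, 206
  dams ≈ the scale of the source breeding program, split over two year
  classes, with 12 SA + 14 SW offspring per family (the study used 10–15).
* **Genetic structure**: founders drawn from `N(0, G0)`; offspring as parent
  average plus a Mendelian deviation scaled by parental inbreeding, so
  `A ⊗ G0` is realized without factorizing `A`. The default true components
  use the published heritabilities (0.23, 0.11, 0.37, 0.33, 0.20, 0.16,
  0.35, 0.35), fullsib proportions, and full genetic / fullsib / residual
  correlation matrices (both printed correlation matrices are positive
  definite and are used unmodified); phenotypic variances are chosen to
  match the published trait means and CVs (e.g. filet fat SD ≈ 1.8%, growth
  rate SD ≈ 1 g/day). Of the non-genetic, non-fullsib share of `GR_SW`
  variance, 70% is permanent — a fish's growth rank is highly stable
  between events.
* **Growth and slaughter**: growth is linear from first feeding
  (BW = GR × age) — the minimal model consistent with the trait definition;
  no growth curve beyond that is imposed. Each SW fish receives a fresh
  latent growth rate per event (fixed effects with a mild 0.05 g/day
  per-event decline, plus a + c + r + event residual). The schedule defaults
  to the published year-class-1 ages (baseline weighing at 700 d, events at
  805–958 d) with thresholds 4.2 kg then 4.4 kg and a slaughter-everyone
  final event; a fish exactly at the threshold is harvested. Harvested fish
  acquire the three quality traits with the SW residual covariance. Of the
  unharvested fish within 5% below the threshold, 30% get an ordinary
  observed (not slaughtered) record — a stand-in for the study's
  ``subjectively sampled'' near-threshold weighings, whose true rule is not
  documented. Everyone else contributes a censored row. Mortality removes a
  random 5% of fish at a random event (the study lost 4–8%); dead fish keep
  their earlier records and get no phantom rows afterwards.
* **SA group**: all four traits at one common age per year class, residual
  covariance `R_SA`; around 0.5% of trait values are missing at random.

One independent child RNG stream per component (pedigree, genetics,
residuals, mortality, missingness) derives from the design seed.

What the generator does **not** emulate: nonlinear growth, feed intake,
temperature effects, genotype-by-environment structure, and any
non-Gaussian trait behaviour. Passing parameter-recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to their violation in real data.

## Verification strategy and problem sizes

The test suite verifies each operation against an independent oracle:
relationship matrices against a top-down recursive-expectation oracle and
dense inversion; the truncated-normal sampler against closed-form moments
and scipy's implementation; location conditionals against closed-form
shrinkage and dense GLS; variance conditionals against inverse-Wishart
moments; the reduced (single-trait, uncensored) model against a dense REML
oracle; and the Raftery–Lewis diagnostic against its closed-form minimum
sample size.

The end-to-end recovery study uses 200 families (100 sires × 2 dams, the
arrangement that maximizes halfsib information) with 20 SW + 10 SA offspring
each, and a 5,000-iteration chain (burn-in 1,000, thinning 5). Two caveats
discovered while validating, both quantified by the suite:

* **Realization noise dominates h² recovery at this scale.** The additive /
  fullsib split is identified by halfsib covariances, which with 100 sire
  groups have a relative standard deviation of roughly 40% of `G0/4`; the
  implied per-trait standard deviation of realized heritability around its
  generating value is about 0.08–0.10 for the high-h² traits. Long-chain
  (40,000-iteration) posteriors coincide with the 5,000-iteration ones and
  with the realized moment estimates of each simulated dataset, so the
  sampler is unbiased and converged — but a tolerance of ±0.15 on *all
  eight* heritabilities simultaneously is exceeded by realization noise for
  a substantial fraction of data seeds, typically by one or two traits at
  0.15–0.25.
* **Informative near-threshold sampling slightly biases event means.** The
  generator's band rule observes the *largest* of the censored fish, while
  the model treats censored rows as full truncated normals; the remaining
  censored fish are therefore depleted just below the bound and the
  estimated per-event means sit about 0.04–0.08 g/day (≈1.5%) above the
  all-fish truth at intermediate events. With the band rule disabled the
  estimates are unbiased (verified); the bias is the price of emulating the
  study's informal extra weighings while keeping the model exactly as
  specified.

## Numerical choices

* Truncated-normal sampling: inverse CDF for bounds above −5 SD, Robert's
  translated-exponential rejection below; draws clipped to the bound against
  round-off.
* Non-positive-definite inverse-Wishart draws (numerical) retry with
  escalating diagonal jitter and a logged warning; the per-animal Cholesky
  in the numba kernel does the same.
* Chains are bitwise reproducible: one `numpy.random.Generator` drives every
  draw, with the numba kernel consuming pre-drawn normals.
* Retention rule: iteration `t` is retained iff `t > burn_in` and
  `t % thinning == 0`, giving `floor(n/thin) − floor(burn/thin)` samples —
  matching the published protocol's arithmetic (2,017,200 iterations,
  burn-in 10,000, interval 100 → 20,072 retained). The published burn-in
  wording is ambiguous between samples and iterations; the retained count
  implies iterations, which is the reading adopted.
* Dense `A` is refused above 5,000 animals; the sparse inverse (Henderson
  rules with Meuwissen–Luo inbreeding-corrected Mendelian variances) has no
  such limit. Inbreeding is always accounted for in `A⁻¹`.
* Posterior "±" values are posterior standard deviations over retained
  draws, derived per draw and then averaged (never ratios of averages).
* Raftery–Lewis thinning search is capped at 50.

## Limitations

Only upper (left-) censoring with a single bound per record is supported; no
genomic relationships; no REML; the blocked founder/family updates assume
phenotyped animals without progeny of their own for full effect (deeper
pedigrees remain correct but fall back to slower unblocked moves); and the
pre-correction module implements exactly the printed linear adjustment
(slope only, intercept kept, per year class) rather than any multi-covariate
generalization.
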