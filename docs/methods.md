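# Methods

## Model and assumptions

`painapc` fits a Poisson age–period–cohort model to a Lexis table of survey
counts, one stratum (gender) at a time — strata are never pooled implicitly;
gender-combined descriptives require explicit aggregation. Per cell,
`y ~ Poisson(n λ)` with `log λ = μ + α_i + β_j + γ_k (+ z_ij)`. Treating a
bounded proportion as a Poisson rate is the standard approximation in this
methodology; it is accurate for rates well below 1 and is the model actually
being projected, so the synthetic generator mirrors it exactly (with a logged
post-hoc cap `y ← min(y, n)` protecting table validity in the rare cells
where a Poisson draw overshoots the at-risk count).

The cohort diagonal of cell `(i, j)` is `k = M(I − i) + j`, with `i = 1` the
youngest age group so larger `k` means later birth. `M` (age width / period
width) must be a positive integer for cohort-indexed operations; tables whose
widths do not divide (e.g. 20-year descriptive age classes over one pooled
25-year period) are fully supported for age/period/total margins and simply
have no cohort margin. One deliberate relaxation: the **last** age group may
be wider than the rest, because published descriptive tables routinely use an
open-ended top class (">70"); interior groups must share one width.
Overlapping cohort diagonals are additionally grouped into disjoint 10-year
birth intervals by assigning each diagonal to the decade containing the
midpoint of its birth span, anchored at the earliest birth year on the grid —
for the reference 14 × 5 grid this yields the nine decades 1891–1900 through
1971–1980.

## Priors

Each included effect vector `u` (length m, RW order o ∈ {1, 2}) carries the
intrinsic Gaussian random-walk prior with density kernel
`τ^(r/2) exp(−τ/2 Σ(Δ^o u)²)`, rank `r = m − o`. The "log-gamma (1, 0.00005)"
hyperprior of the source methodology is implemented as Gamma(shape 1, rate
0.00005) on each precision τ (equivalently log-gamma on log τ), the stock
vague default of Bayesian APC software; the overdispersion precision gets
Gamma(1, 0.005). Overdispersion `z_ij` is iid Normal(0, 1/τ_z) per cell and is
included by default in the full model. Normalising constants are retained in
all densities so log posteriors are comparable across specifications; the
intercept is flat. DIC itself depends only on the likelihood, so model
comparison is unaffected by prior constants either way.

## Identifiability

Age, period and cohort are linearly dependent (`cohort = period − age` up to
interval bookkeeping), so the model is identified by constraints, not by the
likelihood. Two mechanisms are used, both likelihood- and prior-invariant
reparametrisations applied after every sweep:

1. **Sum-to-zero recentring** of each effect vector, the subtracted mean
   absorbed into `μ`. This pins the overall level.
2. **Zero-linear-trend normalisation of γ**, applied only when the model is
   full APC with RW2 priors on all three effects. In that configuration the
   posterior is exactly flat along the direction
   `(α_i + gMi, β_j − gj, γ_k + gk)` — RW2 penalises no linear trend and the
   likelihood cannot see the shift — so without a section choice the chain is
   sampling an improper distribution and per-level effect estimates are
   arbitrary. Each retained state is projected onto the canonical section
   where γ has zero least-squares linear trend. Any RW1 component breaks the
   flatness, so mixed-order models are left untouched. The consequence, shared
   by all APC methods: individual effect *trends* are identified only relative
   to this convention, while fitted and projected rates are unaffected by it.
   The synthetic truths place γ on the same section (symmetric parabola, zero
   linear trend) so recovery experiments compare like with like.

## Sampler

Metropolis-within-Gibbs: conjugate Gamma draws for each RW precision
(`Gamma(shape + r/2, rate + q/2)` with `q` the RW quadratic form) and for the
overdispersion precision; Gaussian random-walk Metropolis for `μ` and for each
effect level (single-site, with an incrementally maintained exposure cache
`E = n·exp(η)` so one update costs one row/column/diagonal); a vectorised
Metropolis sweep for `z`, whose cells are conditionally independent. Proposal
scales adapt every 50 burn-in iterations toward ~30% acceptance and are frozen
after burn-in, preserving detailed balance for the retained draws. Chains
start from centred marginal log rates (not zeros: a zero start makes the
initial RW quadratic forms vanish and the conjugate precision update then
pins the effects at implausibly high precision). Defaults: 2 chains, 50,000
iterations, 10,000 burn-in, thinning 10 — all configurable; tests and the
replicate experiments run 1 chain × 2,000–3,000 iterations, which the
convergence diagnostics (split-R̂ < 1.05 on μ and all precisions via arviz)
support on tables of this size. Identical seed and inputs reproduce draws
bitwise.

DIC is `D̄ + pD` with `pD = D̄ − D(θ̄)`, deviance `D = −2·loglik`, `θ̄` the
element-wise posterior mean (re-centred). `pD` can be negative on pathological
fits and is reported as computed. Model selection takes the minimum-DIC
candidate, except that a full-APC/RW2 candidate within 2 DIC points of the
minimum (a conventional "effectively tied" margin, configurable) is preferred
as the natural smoothing target. Failed candidate fits are flagged with a
warning and excluded.

## Projection

Per posterior draw, the period effect is extended `H` periods ahead and the
cohort effect by the `H` new diagonals entering the extended grid (max index
`M(I−1)+J+H`), each by its fitted-order RW predictive:
`Normal(u_last, 1/τ)` for RW1, `Normal(2u_last − u_prev, 1/τ)` for RW2. The
extension uses each draw's own precision, is not re-centred (the constraint
binds on the observed range), and fresh overdispersion draws
`z ~ Normal(0, 1/τ_z)` are added by default so predictive bands reflect all
modelled variability (a structural-only option excludes them). Rates per
(age, future period) cell are the per-draw `exp(η)`; bands are central
quantile intervals at 10/25/50/75/95% by default — "10% CI" meaning the
narrow 45th–55th-percentile band around the median — and are nested by
construction as order statistics of one draw set. At-risk counts are carried
forward from the last observed period (user-supplied future counts are
accepted). Default horizon H = 2 five-year periods, i.e. a 10-year
projection window. Band levels require at least 5 draws beyond each tail
(e.g. ≥ 200 draws for a 95% band), otherwise the projection refuses with the
minimum named.

## Synthetic data

`default_truth` encodes the structure the analysis assumes: 14 five-year age
groups (31–100), 5 periods (1991–2015), 18 cohort diagonals; female intercept
log 0.44 vs male log 0.36; a mildly increasing age effect (log range 0.22); a
log-linear rising period effect (slope 0.045 per period); a symmetric
parabolic cohort effect (amplitude 0.18, peak mid-range, i.e. births around
the 1930s–40s); overdispersion SD 0.03; at-risk counts of 1,000–11,700 per
cell concentrated at ages 51–70, for ~300,000–400,000 observations per
stratum. Implied cell rates span 0.26–0.55, higher among females. These
magnitudes were fixed once, by construction, to land in that target range.
What the generator does **not** emulate: the composition of a harmonised
multi-study dataset (study heterogeneity, attrition, missingness, item
wording), binomial sampling of a bounded proportion, or unequal cell
exposure over periods. Passing recovery tests therefore demonstrate that the
machinery is correct under its own assumptions, not that those assumptions
hold in any particular survey.

## Numerical choices and degenerate inputs

Rates are computed from exact integer sums and divided only for display;
empty margin levels give NaN, never 0. Cells with `n = 0, y = 0` contribute
nothing to the likelihood; `n = 0, y > 0` is rejected. The exposure cache is
refreshed from scratch every 1,000 iterations to stop multiplicative
round-off drift. `rw_quadratic_form` requires length ≥ order + 1 and its
shift invariances (constant for both orders, linear for RW2) hold to 1e−10.
Effect draws satisfy sum-to-zero to 1e−10. Quantile-based summaries
(medians, bands) commute with exp, so RR summaries are computed per draw and
then summarised.

## Known limitations

- Effect-level estimates in the full RW2 model are canonical-section
  quantities (see Identifiability); comparisons with other software must use
  the same convention or compare identifiable functionals (fitted rates,
  second differences).
- DIC is the only comparison criterion implemented, matching the methodology
  this package follows; no WAIC/LOO.
- Single-site Metropolis mixes slowly on very large grids; the defaults are
  tuned for tables of order 14 × 5, not registry-scale grids.
- The Poisson approximation deteriorates as rates approach 1; the generator's
  validity cap then triggers more often and predictive rates are no longer
  guaranteed below 1.
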