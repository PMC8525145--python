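# Methods

## The liability model

Developmental mode is treated as a threshold trait. Each individual
carries a latent liability

ℓ = µ + β·1[high salinity] + a + m + d + pe,   clutch liability = ℓ + e,

with a ~ N(0, V_a A) the additive genetic value over the relationship
matrix A, m a maternal-family effect (V_m), d a rearing-dish effect
(V_dish), pe a permanent-environment effect of the individual (V_id), and
e ~ N(0, V_e) a clutch-level residual redrawn for every egg mass. A clutch
develops lecithotrophically when its liability is positive; an
individual's binary score comes from its mean capsule diameter with the
150 µm boundary assigned to lecithotrophy. Because repeated clutches share
everything except e, egg-mass-type "switching" by an individual emerges
from residual noise near the threshold (an optional Markov flip rate can
add environment-dependent switching on top).

Latent-scale heritability is h² = V_a / (V_a + ΣV_other + V_link) with
V_link = 1 for the probit link. Observed-scale heritability follows the
standard GLMM conversion: with ℓ ~ N(µ, V) over the population,
p̄ = E[Φ(ℓ)] = Φ(µ/√(1+V)), Ψ = E[φ(ℓ)], and
h²_obs = Ψ²V_a / (p̄(1−p̄)). Expectations are evaluated with 64-node
Gauss–Hermite quadrature; a Monte-Carlo integrator is kept as an
independent cross-check and the two agree within Monte-Carlo error on a
grid of (µ, V).

## Relationship matrices

The pedigree route is the tabular method,
a_xy = ½(a_{x,sire(y)} + a_{x,dam(y)}), a_xx = 1 + ½a_{sire(x),dam(x)},
which handles self-fertilization (dam = sire) and accumulating inbreeding
automatically: a selfed offspring of an outbred parent has F = 0.5, its
selfed offspring F = 0.75. Field-collected clutches have unknown
paternity, so assumption-based matrices fill within-family blocks with
0.25 (maternal half-sibs, the conservative default), 0.5 (outcrossed full
sibs), off-diagonal 1.0 with diagonal 1.5 (progeny of one selfing parent),
or a seeded per-clutch mixture. Tests verify the pedigree route against an
independent recursive-kinship implementation on exhaustive small
pedigrees.

## Samplers

All three animal models are blocked Gibbs samplers. Location effects have
multivariate-normal full conditionals; the animal term is sampled per
connected component of A with batched Cholesky factorizations, which keeps
a 600-individual fit at 20,000 iterations around ten seconds. Variance
components have inverse-gamma full conditionals; fixed effects get
N(0, 1) priors for the Gaussian response and N(0, 1000) for threshold and
categorical responses; the link variance is fixed at 1 for non-Gaussian
responses (identification). Binary and categorical responses use
truncated-normal data augmentation. The categorical model uses two latent
dimensions (one per non-reference category; the reference is
planktotrophy) with independent unit link residuals: an observation is the
reference category when both latents are negative and otherwise the
category of the largest latent. Under this parameterization equal latent
intercepts make the two non-reference categories equiprobable; exact
1/3–1/3–1/3 frequencies occur at µ = Φ⁻¹(1−1/√3)-type symmetric points
rather than at µ = 0, which differs from parameterizations that treat all
three categories symmetrically.

Chain defaults are 603,000 iterations, 10,000 burn-in, thinning 10
(config-scalable; tests and the acceptance suite run 20,000/2,000/10).
pMCMC for a fixed effect is 2·min(P(β>0), P(β<0)) with a 1/n_draws floor.
DIC is D̄ + p_D with p_D = D̄ − D(θ̄), the deviance at the posterior mean
predictors. Effective sample sizes come from the autocorrelation-based
estimator in arviz, flagged below 1000.

### Identifiability of threshold models, priors, and the marginal sampler

With one binary record per individual and a block-structured A, the
likelihood identifies only the ratio of family-shared variance to total
latent variance: the individual-specific (Mendelian) part of the additive
effect is indistinguishable from extra link residual. Along that
weakly identified "latent scale" direction the usual weakly-informative
priors are dangerous: an inverse-gamma(0.001, 0.001) or even a
half-Cauchy SD prior leaves the augmented posterior asymptotically flat
(the prior tail is cancelled by the measure of the latents), so chains
drift to absurd scales. Three design choices address this:

1. **Marginalization.** When each individual contributes one record and A
   is equicorrelated within families (all clutch assumptions), the
   Mendelian part of the animal effect is absorbed analytically into the
   link residual, whose variance becomes 1 + (diag−off)·V_a; only the
   family-shared component s_f ~ N(0, off·V_a) is sampled, and V_a itself
   is updated by univariate slice sampling of its full conditional.
2. **A scale anchor.** The additive SD gets a half-normal(1) prior by
   default in threshold and categorical models. On a probit latent scale
   with link variance 1, additive SDs beyond ~3 imply near-deterministic
   liabilities, so this is weakly informative in the scientifically
   meaningful range while its light tail keeps the posterior proper along
   the scale direction. Half-Cauchy and inverse-gamma options remain
   available for sensitivity analysis.
3. **A joint scale move.** A Metropolis step proposes rescaling every
   latent-scale quantity by a common factor, traversing the weakly
   identified direction in one step instead of a slow random walk. The
   category rule of the L/P/M model is invariant to a common positive
   rescaling, so the move applies jointly across both latent dimensions.

The other random terms (family, dish, family-by-site) use parameter
expansion (working effects times a scalar with a normal prior), which
amounts to a half-Cauchy(1) prior on each SD and improves mixing near
zero variance. Gaussian fits are fully identified and keep plain
inverse-gamma(0.001, 0.001) variance priors. For general (non-block)
pedigrees or repeated binary records the explicit animal-effect sampler is
used; it is exact but mixes slowly over the latent scale for single-record
binary data, which is why the per-individual binary coding plus clutch
assumptions is the supported configuration at scale.

The binary recovery check in the acceptance suite uses 20 outcrossed
full-sib families of 30 with the extra 0.1 variance on dishes and a base
rate near 0.5. Those choices maximize what the design identifies: full-sib
clutches put half of V_a in the family-shared (identified) part, dishes
are nested within families and so are separable from both the family
block and the animal term, one clutch per individual makes the
per-individual score exactly one liability draw, and a balanced incidence
maximizes the information per binary observation. Even so the posterior
for a single replicate is wide — with 20 families the family-shared
variance carries sampling error of order 30% — so recovery is asserted on
the average posterior mean across 20 replicate fits (within ±0.15 of the
generative 0.45) together with ≥85% credible-interval coverage.

## Selection response

For the threshold trait, a proportion q of lecithotrophic layers maps to
liability mean u = Φ⁻¹(q) (unit-variance liability, threshold at zero).
Selecting exactly the upper tail gives S = φ(Φ⁻¹(q))/q; the response is
the change in u across generations; realized h² is R/S per step and
ΣR/ΣS summed, with missing generations simply shortening the sum. For
capsule size, S and R are plain mean differences computed in µm; the
reporting scale is mm (so a 20 µm response prints as 0.02), consistent
with selected-parent means sitting near the lecithotrophic capsule mode.

## The synthetic generator: what it emulates and what it does not

Defaults follow the study system: 17 maternal families with ~13
individuals per family per salinity, capsule modes 113/182 µm with
within-mode SD 9.7 µm applied to both modes (the data do not separate
them), egg sizes 105 ± 5 / 68 ± 4 µm, ~6.5% mixed clutches drawing from
both modes 50:50, survival 0.63 (16 ppt) / 0.81 (32 ppt), a Poisson(4.5)
clutch count with minimum 1, and µ and β calibrated so the expected
egg-mass proportions of lecithotrophy are 17.6% (low) and 25.7% (high).
Variance defaults (V_a = 1.2, V_m = 0.2, V_dish = 0.05, V_id = 0.2,
V_e = 1) put latent h² at 0.45. Selection propagates exactly the
lecithotrophic layers by selfing: offspring breeding value is the parent's
plus a Mendelian deviation of variance ½V_a(1−F_parent), and
F_child = ½(1+F_parent). A salinity line with no lecithotrophic layers
terminates with a logged event.

Not emulated: temperature and photoperiod effects, seasonal field
structure, partial fertilization of selfed clutches, measurement error in
ImageJ capsule calls, and between-mode differences in within-mode SD.
Passing tests therefore show that the estimators recover the parameters of
this liability world, not that real *A. willowi* data satisfy its
assumptions (in particular, real clutch paternity is an unknown mixture,
which is why the relatedness assumption is a switch).

## Numerical choices and limitations

- 150 µm boundary assigned to lecithotrophy at both the capsule and the
  individual-mean level.
- Capsule draws truncated at zero (practically at 1 µm); CSV output uses
  fixed one-decimal formatting so write–read–write is byte-stable.
- Quadrature: 64 Hermite nodes for scale conversion; 32 for categorical
  likelihoods. Numerical derivatives for categorical Ψ integrate the
  *other* dimension's residual by quadrature so the differentiated
  variable enters smoothly.
- Slice sampler: log-scale stepping-out with unit width, capped at 50
  expansions and 100 shrinkage steps.
- The cross-environment correlation regresses family proportion in low
  salinity on high salinity (the direction used for predicting correlated
  responses) and reports the direction-free Pearson correlation alongside.
- Proportions are analyzed untransformed (family-mean method), an
  intentional fidelity-over-optimality choice; no control-line correction
  is applied because the design has no control lineages.
- Realized-heritability sums over whatever consecutive generations are
  available; with a lost lineage the low-salinity sum rests on a single
  step.
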