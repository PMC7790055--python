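# Methods

## Model

`hbewa` implements experience-weighted attraction (EWA) learning for
two-player normal-form investment games, with the Patent Race (prize
q = 10, weak/strong endowments 4/5) as the packaged default. Participant
*i* in session *j* chooses an investment `Y_ij(t)` in round *t* from the
role's action space `0..(4 + r_ij)` with categorical probabilities

    p_ijk(t) = exp(λ_ij V_ijk(t-1)) / Σ_l exp(λ_ij V_ijl(t-1)),

where attractions and the experience weight evolve as

    N_ij(t)   = ρ_ij N_ij(t-1) + 1
    V_ijk(t)  = [ φ_ij N_ij(t-1) V_ijk(t-1) + f_ijk(t) ] / N_ij(t)
    f_ijk(t)  = { δ_ij + (1 - δ_ij) I(Y_ij(t) = k) } π(k, Y*_ij(t))
    π(k, y)   = endowment(r_ij) + q I(k > y) - k.

δ = 0 is pure reinforcement learning, δ = 1 pure belief learning
(fictitious play). Sampling uses the algebraically equivalent closed
forms

    N(t) = ρ^t N(0) + (1 - ρ^t)/(1 - ρ)
    V_k(t) = [ φ^t V_k(0) N(0) + Σ_{l=1..t} f_k(l) φ^(t-l) ] / N(t)

vectorised over rounds (the φ-convolution runs through a linear IIR
filter); the recursion is retained as an independent oracle and every fit
spot-checks one evaluation of each path against the other.

### Hierarchy

Each family f ∈ {δ, λ, φ, ρ} is modelled on a link scale (logit for the
unit-interval parameters, natural log for λ):

    q_f(param_ij) = x_i'β^f + z_ij'γ^f + θ_i^f + ε_ij^f,
    ε_ij^f ~ N(0, σ_f²),  θ_i ~ MVN(0₄, Σ).

x_i = (intercept, mean-centred age in years, sex with 1 = male);
z_ij = (strong-role indicator, session-1 indicator). Priors:
β, γ ~ N(0, 100²); σ_f ~ Uniform(0, 1000); Σ⁻¹ ~ Wishart(I₄, df 5). For
a 4×4 matrix, df = dimension + 1 is the smallest df making the implied
prior correlations marginally uniform on (−1, 1); the package verifies
this property by simulation. Two reference alternatives bracket the
hierarchy: a shared model (one quadruple for everyone) and a unique model
(an independent quadruple per participant-session), both under
δ, φ, ρ ~ Uniform(0, 1) and λ ~ Gamma(0.01, 0.01) (shape/rate, so prior
mean 1); the shared model's priors are not pinned down by any external
constraint, so the unique model's weak priors are reused once.

### Initial conditions

V(0) is estimated before sampling, exogenously to the hierarchy, by a
multinomial softmax MLE on the pooled first five rounds of all players
sharing a (session, role) group; N(0) = 1 (one observation-equivalent of
prior experience, so the initial attractions wash out quickly). Because
λ·V(0) is not jointly identifiable, λ is fixed at 1 for this step and
V(0) is anchored to mean zero, giving the closed form
`V0_k = ln(n_k + c) − mean_k ln(n_k + c)` with additive smoothing
c = 0.5 so never-chosen strategies stay finite. The likelihood omits the
first five rounds of each session by default (configurable `start`), but
the attraction state still evolves through them, so round-6 probabilities
reflect the full history.

## Sampler

Metropolis-within-Gibbs on link-transformed parameters:

* session-level link parameters η_ij^f: scalar random-walk Metropolis,
  one proposal per session/family per sweep, with per-parameter step
  sizes adapted toward ~0.3 acceptance during burn-in only and frozen
  afterwards (so the post-burn-in kernel is exactly invariant);
* β, γ and θ: exact conjugate Gaussian conditional draws (a Metropolis
  step with acceptance one) — given η the regression layer is linear
  Gaussian, so there is no reason to random-walk it;
* interweaved non-centred (ancillarity) moves: proposals that shift a
  whole coefficient row — or a participant's θ_i — together with the
  affected sessions' η, holding residuals fixed, accepted by likelihood
  × prior ratio.  Without these the population level freezes whenever a
  σ_f collapses: the centred Gibbs layer can then no longer move the
  level against the likelihood.  On alternating sweeps the intercepts
  additionally receive heavy-tailed (Cauchy) independence proposals,
  per family and jointly across the four families: mode-hopping kernels
  whose reverse density decays only polynomially, so chains can move
  between the interpretable region and the saturated-link plateau (see
  Known limitations) instead of random-walking across it;
* σ_f: random-walk Metropolis on log σ with the Uniform(0, 1000) support
  enforced, plus a joint (σ, residual) rescaling move every tenth sweep
  that multiplies the session residuals by σ′/σ.  The rescaling cancels
  the Gaussian terms exactly, leaving acceptance equal to the likelihood
  ratio, and lets the scale hierarchy traverse its prior range instead
  of being trapped in the (σ, ε) funnel.  In prior-only mode a uniform
  independence version of the same move runs every sweep (it traverses
  the prior exactly; against a likelihood it would manufacture transient
  huge-σ states, so there it is disabled);
* Σ: conjugate draw, Σ⁻¹ | θ ~ Wishart(5 + n, (I₄ + Σᵢθᵢθᵢ′)⁻¹), so every
  stored Σ is positive definite by construction.

Proposal-scale caps differ by sampler: the weak-prior (shared/unique)
samplers allow steps up to 300 because the Gamma(0.01, 0.01) sensitivity
prior spans hundreds of log-units, while the hierarchical sampler caps
steps at 2 — in saturated-link regions the likelihood is flat, acceptance
stays high at any scale, and an uncapped step lets chains leap
arbitrarily deep into the plateau.

The unique-model sampler updates every session from its own seeded
random stream keyed by (participant, session), so a session's inference
is bit-identical whether it is fitted alone or with the rest of the
dataset. All fits support a `prior_only` mode that disables the
likelihood; the retained draws are then checked against the stated priors
(Kolmogorov–Smirnov at α = 0.01 on 10,000 draws) in the test suite,
including the marginally uniform Σ-correlation property.

Default schedule: two chains of 500,000 post-burn-in iterations after
100,000 burn-in, thinned by 50 (20,000 retained draws, 10,000 per chain).
Simulation studies and the acceptance pipeline use a desk-scale schedule
— one chain, 20,000 post-burn-in after 4,000 burn-in, thinned by 10 — on
12 participants × 2 sessions × 60 rounds, the package's own reduced
rendition of the full 42 × 2 × ~80 design. Convergence is monitored by
the Geweke diagnostic (first 10% vs last 50% of a chain, variances from
Bartlett-windowed spectral densities at zero) and by an effective sample
size using Geyer's initial-positive-sequence truncation (the
autocorrelation sum stops at the first negative consecutive pair).

## Model comparison

WAIC on the deviance scale with the variance-based penalty:
`lppd = Σ_points ln mean_draws(likelihood)` (log-sum-exp based),
`p_waic = Σ_points var_draws(log-likelihood)`,
`waic = −2(lppd − p_waic)`. A "point" is one participant-session-round
choice, the grain at which the categorical likelihood factorises exactly.
Models are ranked by ascending WAIC over identical point sets.

## Simulator

The generator reproduces the study design: participants with ages
~N(22.3, 5.9) clipped to 18–47 and a one-third male share, roles
alternating across participants and swapping between a participant's two
sessions, opponents drawn from an exogenous categorical pool over the
opposing role's action space (the experimental protocol matched players
against pre-recorded opponent choices; an EWA self-play mode is
available as an alternative). The pool is block-wise nonstationary —
four distributions per session drifting from near-uniform exploratory
play toward the strongly bimodal drop-out/all-in pattern that investment
games equilibrate to. The drift matters beyond realism: belief learning
updates foregone payoffs the moment opponent behaviour shifts while
reinforcement learning only learns through realised payoffs, so a
stationary pool leaves δ nearly unidentified (a few nats over a whole
reduced-scale dataset). Simulated players start from "greedy prior"
attractions — half the expected payoff of each strategy against a
uniformly mixing opponent, mean-centred — rather than indifference;
instructed participants reason about payoffs before round 1, and a
non-trivial V(0) decaying through N(t) is one of the few channels that
separates ρ from λ. Choices are drawn from the softmax at the current
attraction state; the state evolves by the same recursion the likelihood
uses; everything is reproducible byte-for-byte from one seed.

Ground truth comes in two regimes. The homogeneous scenario uses a single
shared quadruple, default (δ, λ, φ, ρ) = (0.35, 0.6, 0.90, 0.88). The
sensitivity keeps play decisive but stochastic (observed-choice
probability ≈0.6 on average): much larger values make play deterministic
and λ unidentified from above, much smaller values bury the δ signal in
choice noise. The two decays sit high and close together, the regime
fitted investment-game play actually occupies (φ ≈ ρ keeps attractions
bounded by the game's payoffs, and empirical posteriors put the φ–ρ
correlation near 1); this matters for estimability, because once N(t)
reaches its steady state only the product λ(1−ρ) enters the dynamics —
at ρ = 0.88 the experience-weight transient spans the likelihood window,
whereas for ρ ≲ 0.8 it is over before the likelihood starts and the
entire lower range of ρ becomes likelihood-flat. The heterogeneous
scenario draws each session's quadruple from the hierarchy with
intercepts at the links of the shared truth, small per-year age slopes,
moderate sex contrasts, role contrasts making the strong role more
belief-driven but less payoff-sensitive and faster-forgetting
(γ_role = 1.54, −0.69, −1.35, −1.20 on the link scale), mild session-1
contrasts, random-effect scales (0.5, 0.25, 0.5, 0.5) with the
characteristic correlation pattern (φ–ρ ≈ 0.97, both strongly negative
with δ; verified positive definite), and residual scales
(0.25, 0.15, 0.25, 0.25).

What the simulator does not emulate: real opponent pools with
session-specific composition, within-session nonstationarity of human
strategies beyond the block drift (fatigue, experimentation), and
dropout/missingness. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own generative
assumptions, not robustness to misspecified human data.

## Numerical choices

* Softmax computed with max subtraction; overflowing λ·V yields −inf
  log-likelihood (with a warning at the API surface), never an exception.
* ρ within 1e−12 of 1 uses the N(0) + t limit of the experience-weight
  closed form; the core accepts the closed intervals δ, φ, ρ ∈ [0, 1] and
  λ ≥ 0 so the named limits are exactly representable, while the links
  keep hierarchical parameters strictly interior.
* Closed form and recursion agree to 1e−10 relative tolerance over
  1,000 randomised cases (asserted in the tests).
* Initialisation: link-scale start near (δ, λ, φ, ρ) ≈ (0.5, 1, 0.6, 0.6)
  with small jitter; a non-finite starting likelihood triggers
  re-initialisation up to 10 times before erroring.
* MAE is reported ×100; coverage uses equal-tailed quantile intervals;
  session-effect recovery R² is computed about the identity line (not an
  OLS fit), so it can be negative when estimated within-participant
  changes are worse than predicting no change.
* The printed form of the correlation conversion uses the standard
  corr_ij = Σ_ij/√(Σ_ii Σ_jj).

## Known limitations

* Hierarchical collapse at reduced scale. On logit/log link scales the
  likelihood is exactly flat once a parameter saturates (δ below ~0.002
  maps to the whole half-line η < −6), and the hyperpriors are extremely
  diffuse (coefficients N(0, 100²), residual scales Uniform(0, 1000)).
  When the data carry only ~10 nats of information about a family's
  population level — which is what 24 sessions × 55 choice rounds yield
  for δ, whose reinforcement-vs-belief signal is intrinsically weak —
  the saturated plateau acquires posterior mass comparable to or
  exceeding the interpretable region: the likelihood penalty (~e⁻¹²,
  with the other families' levels compensating) is offset by the
  enormous prior volume of the plateau relative to the narrow
  interpretable basin. The hierarchical sampler then legitimately spends
  most of its time with that family collapsed (level driven to ±100 on
  the link scale, σ_f inflated), producing biased session estimates with
  far-below-nominal interval coverage, while the shared and unique
  models — whose Uniform(0,1)/Gamma priors have no such plateau — behave
  well. This is a property of the stated model at small information
  volumes, not of the sampler: the mode-hopping kernels transition
  between the regions, and the collapse disappears when the data volume
  grows (full-scale designs carry several times the information). The
  end-to-end recovery suite runs at the reduced scale and reports this
  honestly where it bites.
* The Metropolis sweeps update one session-family scalar at a time;
  strongly correlated posteriors (φ with ρ) mix more slowly than a joint
  proposal would. The schedule defaults compensate with thinning.
* The unique model inherits the boundary-fit pathology it is meant to
  illustrate: with ~55 informative rounds per session, λ can drift large
  wherever a session's choices happen to track the running argmax.
* ρ is separately identified from λ only through the experience-weight
  transient and the decay of the initial attractions; with the first
  five rounds excluded from the likelihood, ρ values small enough for
  N(t) to equilibrate before round 6 are not estimable in practice.
* V(0), N(0) are fixed, not estimated; in short sessions their influence
  is not negligible.
* Games are limited to two roles with finite contiguous integer action
  spaces.
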