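# Methods

## Model and assumptions

The dynamics is a discrete-time Markov jump process on population
compositions **n** = (n_γ), Σ n_γ = N, for a finite set of K organism
types. One generation applies variation, reproduction and selection at
once: the transition kernel is the multinomial

    W[n ← n′] = N! Π_γ (1/n_γ!) [ f_γ (π n′)_γ / Σ_{γ″γ′} f_{γ″} π_{γ″←γ′} n′_{γ′} ]^{n_γ},

where π is the column-stochastic variation kernel (π[γ, γ′] = probability
that a γ′ organism becomes γ within one generation) and f the vector of
reproduction rates. Standing assumptions, inherited by every module:

* **Constant N** — resources abundant but limiting; population-size
  fluctuations are ignored. No finite-N correction is attempted.
* **Non-interacting organisms** — f and π do not depend on **n**; no
  composition-dependent (pair/recombination) variation channels.
* **Constant environment** — f and π do not depend on the generation.
* **Reversible variation support** — π[γ, γ′] > 0 ⇔ π[γ′, γ] > 0; the
  magnitudes may still be arbitrarily asymmetric.
* **Dimensionless rates** — only ratios of f matter for the dynamics.
  Under f → c·f, selection probabilities and the directionality F are
  invariant while ψ and φ shift by the additive constant 2N ln c (growth
  and expected-growth terms each contribute N ln c).

## Force decomposition

The directionality F = ln(W[n←n′]/W[n′←n]) is always computed from the
log transition probabilities (log-gamma + x·log y with the conventions
0·ln 0 = 0 and x⁰ = 1), while ψ = Σ n ln f − Σ ln n! + φ,
φ = N ln Σ f_γ π[γ,γ′] n_γ′ and
ζ = Σ_γ [n_γ ln(πn′)_γ − n′_γ ln(πn)_γ] are computed from their raw
defining sums. Because the two routes share no code path, the identity
F = Δψ + ζ is a genuine cross-check; the measured residual stays below
1e-9 (typically 1e-13) on randomized models, and this is enforced in the
tests rather than assumed.

One-way pairs (one direction impossible) leave F undefined: operations
raise a typed `OneWayTransitionError`, with an opt-in `allow_infinite`
escape hatch that returns signed infinity for exploratory use.

## Sensitivity and the restricted regime

ω_γ is the variation-weighted mean relative fitness loss of γ's variants.
It is a 0/0 for types that never vary (μ_γ = 0) and is reported as NaN
(undefined), never as 0. The identity
φ = N ln(F_n − Σ μ_γ ω_γ f_γ n_γ) is used as a second, independent route
to φ and is tested at 1e-10 relative tolerance. The strong-selection
first-order form φ ≈ −Σ μ_γ ω_γ n_γ + const reports its constant
explicitly as N ln(N f_high), the value obtained by substituting
f_γ = f_high everywhere, so the approximation is testable as an equality
with an explicit error term.

The population sensitivity Ω_n = (F_n − F_π,n)/F_n is defined only in the
common-μ regime; heterogeneous μ_γ (beyond a relative tolerance of 1e-6)
is refused with a `RestrictedRegimeError` rather than silently
generalized. K = 1 is treated as the formal limit (no variation channel;
Ω ≡ 1, zero variance).

## The μ-scaled family and the fluctuation relation

The one-parameter kernel family π(μ) = (1−μ)I + μQ, with Q a
zero-diagonal column-stochastic conditional variant kernel, is the
package's canonical way to vary the variation probability. Under this
family μ_γ = μ exactly for every type and — crucially — F_π and Ω do not
depend on μ, so the restricted potential
ψ = Σ n ln f − Σ ln n! + N ln F_n − μNΩ_n is *linear* in μ and the
Boltzmann ensemble is a one-parameter exponential family in Ω. The
fluctuation relation −(1/N) d⟨Ω⟩/dμ = var(Ω) then holds as an exact
identity, limited only by finite-difference error; measured agreement is
~1e-13 at δμ = 1e-4. For any other μ-dependence the relation is
approximate, and the scan reports the discrepancy instead of hiding it.

Susceptibilities use central differences with default step
δμ = max(1e-4, μ/100), one step-halving, a Richardson-extrapolated value
and a convergence flag; a second route through d² ln Z/dμ² is available
as an independent check.

Two empirical caveats established during development and reflected in the
tests:

* The Boltzmann ensemble (exact or restricted ψ) approximates the true
  stationary law only where ζ is negligible. The Monte-Carlo sampler
  follows the exact chain, so its long-run Ω average is validated against
  the exact stationary eigenvector (agreement within sampling error); the
  gap to the Boltzmann average is itself a diagnostic that shrinks as μ
  grows and as selection strengthens. The total-variation diagnostic
  (`boltzmann_vs_exact`) decreases with rate spread only in the
  strong-selection tail; at weak selection it is non-monotone.
* "Fluctuations shrink as the mean plateaus" presupposes a plateau. The
  two-type family reaches none even at μ = 0.95 (var grows
  monotonically with μ there); the plateau implication is exhibited by
  the grid landscape, whose sampled SD of Ω falls steadily across
  μ ∈ [0.02, 0.3].

## Numerical choices

* Composition spaces are enumerated in lexicographic descending order of
  (n_1, n_2, …); deterministic across runs. Enumeration refuses spaces
  beyond 200,000 states (configurable) with a clear error.
* Transition matrices use the destination-row/source-column convention
  W[dest, source]; columns sum to 1 within 1e-10 (validated at
  construction).
* Multinomial probabilities are evaluated in log space; exact zeros arise
  only when a required selection probability is exactly zero.
* Stationary vectors: power iteration to an L1 residual of 1e-12 (default
  cap 10⁶ iterations), with a dense eigensolve under `method="dense"`.
  Reducible chains (e.g. identity kernels) raise a
  `ReducibleChainError` carrying *all* recurrent classes instead of
  returning an arbitrary stationary vector.
* Ensembles are normalized through log-sum-exp; potentials spanning
  hundreds of nats do not overflow.
* Kernel validation tolerates |column sum − 1| ≤ 1e-10; renormalization
  happens only on explicit request (`VariationKernel.renormalized`).

## Simulation

Each generation is one multinomial draw with the current selection
probabilities — distributionally identical to per-organism variation
followed by resampling, and verified against the exact kernel column by
chi-square tests (α = 0.01, 10⁵ draws). One NumPy generator per
trajectory; replicate seeds derived by `SeedSequence.spawn`. Occupancy
estimates use a default burn-in of T/10 and moving-block bootstrap
standard errors (block length 100 generations, 200 resamples) to respect
autocorrelation.

## Synthetic study conditions and their defaults

The package generates all of its own inputs; no external data exist for
this model class.

* **Two-type model**: f = (2, 1), symmetric μ = 0.1, N = 3 — the smallest
  composition space (4 states) exhibiting all three force classes; N = 10
  for ensemble work.
* **Random models** (property tests): log-uniform rates in [0.5, 2],
  per-type μ uniform in [0.05, 0.3], symmetrized sparse variation support
  augmented with a ring so every type can vary. These spans cover weak to
  ~4-fold selection and realistic per-generation variation pressure while
  keeping every generated model valid and ergodic.
* **Grid landscape**: 12×12 lattice, one type per site, hops to
  4-neighbors with per-neighbor probability μ̄/deg so that μ_γ = μ̄ exactly
  at every site including boundaries (the μ̄/4 convention is available via
  a flag). Defaults f_fast/f_slow = 2, μ̄ = 0.4, N = 50, T = 4×10⁴
  generations. The high μ̄ is deliberate: robustness enaptation is a
  high-variation-pressure phenomenon, and at low μ̄ the slow sea becomes
  impermeable at desk scale — fast-site groups outside the starting
  island are then never visited, and their steady-state probabilities
  (which can drop below 10⁻¹⁰) are not estimable by direct sampling. At
  the chosen defaults the connectivity ordering (island interior > strip
  > isolated) resolves reproducibly across seeds with ~5–10× separation
  between strip and isolated occupancies.

What passing tests on these conditions do **not** show: behavior under
composition-dependent rates or kernels, fluctuating N, changing
environments, continuous type spaces, or the true magnitude of rare-event
depletion probabilities on weakly-connected landscapes (only their
ordering at permeable parameters). Real populations also violate the
non-interaction and constant-environment assumptions in ways these
synthetic conditions cannot probe.

## Known limitations

* Boltzmann-approximation quality has no rigorous error bound here; the
  TV diagnostic is empirical.
* The strong-selection constant is the leading-order choice; higher-order
  corrections are not modeled.
* `zeta_small_mu_scaling` certifies boundedness of ζ + ln μ only on the
  requested grid; it is a numerical certificate, not a proof.
* Full-matrix operations are dense; spaces beyond ~10⁴ states are better
  served by the simulation module.
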