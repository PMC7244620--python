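# Methods

## Model and assumptions

The object of study is a time-homogeneous, synchronously updated Markov
process on a product of finite state sets: a system block S and an
environment block E, with next-state kernels φ(e, s; s′) for the system and
ψ(s, e; e′) for the environment, both reading the same time-n pair. The
joint one-step law therefore factorises, P(s′, e′ | s, e) = φ·ψ, which is
equivalent to the conditional independence I(S_{n+1}; E_{n+1} | S_n, E_n) = 0.
`check_markov_structure` verifies this and the first-order Markov property
numerically on three-time joints; a worked counterexample (a hidden coin
shared by S_{n+1} and E_{n+1}) shows what a violated product form looks
like.

All information quantities are *exact* finite sums in base-2 logarithms
(bits); there is no estimation error, only floating-point rounding. The
only estimator in the package is the plug-in `empirical_lagged_joint`
(counts of consecutive state pairs), which is deliberately bias-uncorrected:
measures on empirical joints are reported as-is.

## Reference distribution

Every measure is a functional of the lagged joint
P(S_n, E_n, S_{n+1}, E_{n+1}), which requires a time-n distribution. The
default is the **stationary distribution** of the joint chain: it is the
only choice that makes a parameter sweep a function of the parameters
alone, and for strictly positive kernels it exists and is unique. A
user-supplied μ is accepted everywhere for the non-stationary case (and is
*required* for reducible chains, where the solver refuses to pick among
multiple fixed points). H_sys is the entropy of the time-n system marginal
of whichever base is in force.

The stationary solver takes the null space of Tᵀ − I (SVD-based), rejects
dimension ≠ 1, and polishes the fixed point by power iteration until the
∞-norm residual is below 1e-10. Periodic irreducible chains have a unique
fixed point and are accepted.

## The measures

With Total_MI = I(S_{n+1}; S_n, E_n):

* organismal individuality A\* = I(S_{n+1}; S_n);
* colonial individuality A = I(S_{n+1}; S_n | E_n);
* environmental determination nC = I(S_{n+1}; E_n | S_n);
* environmental coding NTIC = A\* − A.

Total_MI = A\* + nC = A + I(S_{n+1}; E_n) are exact chain-rule identities
and are exercised on random batteries rather than assumed. "Mutual
information between two time steps" is deliberately read as the
predictability expression I(S_{n+1}; S_n, E_n); the alternative two-step
joint reading I((S,E)_{n+1}; (S,E)_n) is computed as well and exposed as
the `two_step_MI` field, but is never the headline column.

NTIC is computed PID-free as a co-information, so the headline measures do
not depend on any choice of partial information decomposition. The PID
module implements Williams–Beer I_min — redundancy as the target-state
expectation of the minimum specific information across the two sources —
because it is the canonical first proposal and yields non-negative
components; the decomposition is a pluggable strategy (`PID_METHODS`)
precisely because no single PID is consensual, and only the optional
four-term report depends on it. Zero-probability target states carry zero
weight in the redundancy expectation; specific-information ties need no
tie-break (the min is well defined).

## Two-spin logistic model

Both units have states {−1, +1} and update via logistic rules with logit
2·next·(δ + α·own + β·other + γ·own·other); α is self-memory, β
cross-coupling, γ the pairwise-interaction coupling and δ a bias. The 4×4
joint transition matrix is built two independent ways (direct product of
the eight named conditional probabilities a_S…d_E, and kernel assembly
through the generic machinery) and the two constructions are required to
agree entrywise to 1e-12. Row/column order is (s,e) = (+1,+1), (−1,+1),
(+1,−1), (−1,−1); generically, joint states are enumerated with the
environment as the slow index.

Sweep defaults: α_S, β_S ∈ {−5, −4.5, …, 5}, γ_S ∈ {0, 1, 2, 3, 5},
δ_S = δ_E = 0, with a *random* environment (α_E = β_E = γ_E = 0) or a
*correlated* one (α_E = 2). Only the γ endpoints and α_E = 2 are externally
fixed; the axis ranges and intermediate γ values are configuration choices
exposed through `SweepGrid`. δ = 0 is the symmetric choice and reproduces
the unbiased-coin baseline at zero couplings.

### Operationalising the qualitative sweep claims

The published claims about these sweeps are qualitative; `sweep_claims_report`
turns them into orderings with explicit margins, and the operationalisations
were fixed from the model's analytic structure before being wired into
tests:

* **Entropy reduction by γ.** At δ = 0 the γ_S = 0 chain is invariant under
  a global spin flip, so H_sys = 1 exactly there; γ breaks the symmetry.
  The check is therefore one-sided: H_sys(γ=5) ≤ H_sys(γ=0) + 1e-9 at every
  matched (α_S, β_S), with a strict decrease (> 1e-3 bits) somewhere on the
  grid. The decrease is ~1e-6 bits near the origin and approaches 1 bit at
  strong coupling.
* **Total_MI reversal.** Mean Total_MI over the low-coupling region
  (|α_S|, |β_S| ≤ 1) must be minimal at γ_S = 0 and maximal at γ_S = 5
  among the swept γ values.
* **A ≈ A\* at high coupling (random environment, γ = 0).** Exactly on the
  |α_S| = |β_S| diagonal the logit can cancel (e.g. α·s + β·e = 0 for one
  of the four conditioning pairs), leaving residual noise and synergy, so
  the literal grid corner is not representative. The check evaluates the
  point of the high-coupling region (|α_S|, |β_S| ≥ 4) where both measures
  are simultaneously largest — arg max of min(A, A\*) — and requires a
  relative gap below 0.1 (measured: ≈ 0.077 at (−5, −4)); the corner's
  absolute gap is reported alongside.
* **Correlated environment.** At γ_S = 0, α_S = 0 and the largest |β_S|,
  A\* must exceed both A and nC (measured ≈ 0.87 vs ≈ 0 and ≈ 0.13): the
  environment's regularity is internalised rather than counted as inflow.

## Boundary expansion

`FactoredProcess` holds per-unit kernels conditioned on the full previous
product state; any split of units into blocks is then an *exact* coupled
process (`coarse_grain`), because no conditioning information is discarded.
Before/after measures for internalising a block ΔS are computed from block
marginals of one and the same full-chain lagged joint at its stationary
distribution, so the comparison isolates the boundary move. The three
expansion identities (for nC′, A′\*, A′ — the latter in both printed
forms, also checked against each other) are exact chain-rule algebra; they
are verified by computing every side independently by direct summation,
with residuals required below 1e-8.

Since the correction terms for A and A\* are conditional mutual
informations, both measures are monotone non-decreasing under expansion;
they cannot locate a boundary alone. `greedy_expand` therefore maximises
penalised gain Δmeasure − λ·log2(|unit alphabet|): the λ·log2 form charges
a unit by its coding capacity, the simplest size cost consistent with
"maximise prediction while minimising coding capacity"; it is exposed as a
hook. Expansion stops when the best penalised gain drops below −1e-9 — the
small negative threshold absorbs rounding in the monotone gains, so an
unpenalised (λ = 0) expansion provably runs to the full unit set, while a
dominating penalty stops it immediately. Ties break to the lowest unit
index (arbitrary, documented). The default cap of 5 units keeps the
product space ≤ 32 states and the six-variable lagged joints ≤ 1024 cells,
so everything stays exact; the cap is a module constant. Exhaustive or
provably optimal partition search is out of scope by design.

## Synthetic fixtures and what tests show

`iti.fixtures` generates the random instances all batteries run on:
kernels and joint tables are drawn uniformly with a 1e-3 floor before row
normalisation, so every generated chain is strictly positive — irreducible,
aperiodic, with a unique stationary distribution. Battery sizes (500 random
joints and processes, 200 three-unit chains, 10⁶-step simulation, the
21×21×5 default sweep grid) are chosen so the full suite runs in seconds
while exercising state-space sizes from 4 to 32.

These fixtures emulate *generic* well-mixed finite chains. They do not
emulate: near-reducible chains (metastability, slow mixing), deterministic
or sparse kernels (except where tests construct them explicitly),
non-stationary regimes, large alphabets, or finite-sample estimation noise
— the analytic route is exact, and the plug-in route inherits the usual
small-sample entropy bias uncorrected. Passing tests therefore certify the
algebra and the implementation, not the behaviour of the measures on short
empirical recordings.

## Numerical conventions

* log base 2 everywhere; all outputs labelled bits.
* 0·log 0 := 0 via support-only summation.
* Information values in [−1e-9, 0) are clamped to 0; below −1e-9 an
  internal-consistency error is raised rather than silently clamped.
* Probability normalisation tolerance 1e-9; identity residual budget 1e-8;
  stationary residual 1e-10; matrix comparisons 1e-12. All collected in
  `iti.tolerances.TOL` and adjustable there.
* Simulation draws the system state (via φ) before the environment state
  (via ψ) within a step; both read the same time-n pair, so the order has
  no distributional effect and matters only for seed-level reproducibility.
* TSV serialisation writes probabilities with `repr`, making write→read→
  write round trips byte-identical.

## Known limitations

* Two-source PID only; the full redundancy lattice for more sources and
  optimisation-based PIDs (e.g. BROJA) are extension points, not built.
* Continuous state spaces, continuous time, and asynchronous updating are
  out of scope.
* Model-file schema errors name the offending key; only YAML parse errors
  carry line numbers.
* The greedy expansion is a heuristic: it makes no optimality claim about
  the boundary it returns.
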