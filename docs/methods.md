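# Methods

This note records the modelling assumptions behind `varsel`, the parameters
that matter, the numerical choices, and the limitations a user should know
about before reading anything into a simulation.

## Particular flows (`varsel.langevin`)

The fast scale is a Langevin system ẋ = (Q − Γ)∇ℑ(x) + ω with fluctuation
variance 2Γ.  The drift is constructed, not estimated: the user supplies
the surprisal ℑ directly, and the Helmholtz form then guarantees that ℑ is
the stationary potential.  Three structural assumptions:

* **Quadratic default.**  ℑ(x) = ½xᵀΠx with Π symmetric positive definite.
  This buys analytic access to everything the package asserts: the NESS
  density is N(0, Π⁻¹); the Lyapunov relation JΣ + ΣJᵀ + 2Γ = 0 holds
  identically for Σ = Π⁻¹; conditioning on the blanket reduces to a Schur
  complement, so blanket independence is a statement about the η–μ block
  of Π.  A callable-potential variant exists for nonlinear demos but
  carries no analytic guarantees and no sparsity validation.
* **State-independent Q and Γ.**  The solenoidal operator and fluctuation
  amplitude are constant matrices.  State-dependent versions would break
  the equivalence between the quadratic potential and a Gaussian NESS.
* **Stability before stationarity.**  Any NESS claim first checks that
  every eigenvalue of J = (Q − Γ)Π has negative real part; with Γ ≻ 0 and
  Π ≻ 0 this holds automatically, and `stationary_covariance` raises
  `UnstableFlow` otherwise (e.g. Γ = 0, pure circulation).

A *particular partition* is enforced at construction: the drift Jacobian
must have zero blocks J[η,μ], J[μ,η], J[s,μ], J[a,η] — external states
never drive internal states directly and vice versa, sensory states are
not driven by internal states, active states are not driven by external
ones.  Validation is exact (tolerance 1e−10 on the assembled Jacobian).

**Integration** is Euler–Maruyama with fixed step (default dt = 0.01 in
the time units of the flow; relaxation times in the fixtures are order 1,
so the step is 1% of the fastest timescale).  Per-step noise is
N(0, 2Γ·dt) through a symmetric PSD square root.  One seeded generator per
run; the seed is recorded in every `Trajectory` and output artefact.  A
divergence guard aborts when ‖x‖∞ exceeds a configurable bound (default
1e6).  Euler–Maruyama biases the sampled stationary variance of an OU
process by a factor 1/(1 − r/2) where r is the per-step contraction; at
the default steps this is below 1%, well inside the Monte-Carlo tolerances
the tests use.

**Blanket diagnostics.**  Conditional independence of η and μ given the
blanket is checked two ways: analytically (Schur complement of the NESS
covariance; the check is |Σ[η,μ|b]| < 1e−8) and empirically (partial
correlation of sampled η and μ residuals after regressing out b, with a
block-permutation p-value — blocks, not single rows, because trajectory
samples are autocorrelated).  For linear flows with solenoidal coupling,
*instantaneous* conditional independence given the instantaneous blanket
state is equivalent to the potential having no η–μ block; the package
asserts the analytic statement only in that case and otherwise reports,
rather than asserts, the empirical path-wise statistic.  (Path-wise
independence given the whole blanket path is the stronger statement the
sparse coupling licenses; the state-wise version can fail even for valid
flows, which is why the fixtures keep Π[η,μ] = 0.)

## Generalised filtering and free energy (`varsel.filtering`)

Generalised coordinates truncate a path at order n (default 3): a state,
its velocity, acceleration, …, with the shift operator D moving each order
up and zeroing the top.  The Lagrangian of a generalised state is

    L(x→) = ½[ ln|Γ̃| + (Dx→ − f(x→))ᵀ (2Γ̃)⁻¹ (Dx→ − f(x→)) + ∇·f ],

the precision-weighted squared residual of the flow, plus a log-normaliser
and the flow divergence.  Two conventions had to be fixed:

* The quadratic form is weighted by (2Γ̃)⁻¹ — the inverse of the
  fluctuation covariance — which makes L the exact negative log density of
  the generalised residual up to constants (the test suite checks this
  against an independently assembled Gaussian density).
* The divergence correction ∇·f (= tr J for linear flows) is included by
  default and can be dropped with a switch; it reflects one
  stochastic-calculus convention for the change of measure from
  fluctuations to states, and nothing downstream depends on which
  convention is active because it is path-independent for linear flows.

Generalised fluctuations are smooth, with Gaussian autocorrelation of
width `roughness` (default 0.5 time units): the cross-order covariance is
the standard derivative-of-kernel matrix, diag(1, 1/σ², 3/σ⁴, …) with the
known odd-order zeros.

**Paths of least action.**  For linear-Gaussian models the discretised
action is a convex quadratic in the whole state path, so the stationarity
condition ∇L = 0 — the fixed point of the moving-frame gradient descent
ẋ→ = Dx→ − κ∇L — is solved exactly in one sparse (block-tridiagonal)
Newton step, and the terminal gradient norm is reported (machine precision
in practice, against a contract of 1e−6).  On the same Euler
discretisation this path equals the posterior mean of a discrete Kalman
smoother, which the tests verify against an independently written RTS
smoother.  The descent rate κ therefore never influences the answer, only
the (skipped) iteration; it is kept as a configuration constant (default
1) for the online active-inference step below.

**The free-energy stack.**  The variational density is Gaussian
throughout (Laplace assumption), which makes all six decomposition terms —
energy, entropy, complexity, accuracy, divergence, log evidence — exact
closed forms.  Each term is computed from its own formula, *not* by
rearranging F, so the three identities

    F = energy − entropy = complexity − accuracy = divergence − log evidence

are genuine cross-checks (enforced at 1e−8 on every construction) rather
than tautologies.  The ELBO bound F ≥ −log evidence holds with equality
exactly when the variational density equals the posterior.

**Active inference** takes one Euler step of α̇→ = Dα→ − ∇F per call:
internal states descend F through the belief (perception), active states
descend F through the sensory channel using a supplied reflex sensitivity
ds/da (action).  In the closed-loop thermostat fixture the coupled linear
system has a unique stable fixed point at which the sensed variable equals
the prior mean — homeostasis at the genetically specified set point — and
the tests check convergence to it at 1e−6.

## Renormalisation (`varsel.renorm`)

The grouping operator G has no canonical algorithm, so the package defines
one and guards it with an oracle.  A partition of states into particles is
*valid* when (i) cut edges induce consistent roles — a state receiving
influence from outside its particle is sensory, one that only transmits is
active, the rest are internal; (ii) active and internal states receive no
outside edges; and (iii) every particle owns at least one internal state
(a thing needs states of its own; without this requirement the all-
singletons partition would always win).  `group` returns the *finest*
valid partition.  On graphs of ≤ 10 nodes this is found by exhaustive
enumeration of set partitions, which doubles as the test oracle and also
reports how many alternative finest partitions exist (the finest-first
rule is a choice, and the count makes the ambiguity visible).  Larger
graphs use a deterministic heuristic: nodes whose removal disconnects the
influence graph are candidate blanket states; the components left after
removing them are internal cores; each blanket node joins the core it
shares most edges with.  The result is machine-checked against the
invariants and falls back to the trivial single particle if invalid.

The reduction operator R is deliberately simple: declared parameters and
initial states pass through unchanged (they are constants of the
lifetime), and any simulated state whose path variance over the lifetime,
normalised by its NESS variance, falls below ε = 0.05 is flagged as slow.
The threshold is a convention, not an estimate: an OU state with
relaxation time 200× the lifetime accumulates ~1% of its stationary
variance over the window, a unit-rate state ~100%, so any ε in a wide
band separates them; 0.05 marks "slow" as ≥ 20× timescale separation.
Partitions are re-evaluated only at generation boundaries, matching the
selection protocol's cadence, although in principle they may wander.

Coupling at the next scale is estimated by finite-difference
cross-sensitivity of one particle's action to another's genotype;
`renormalise` then reapplies G to the genotype-level graph, which is what
makes the construction recursive (particles of particles).

## Selection (`varsel.selection`)

Variational fitness is defined, not derived: the action of a phenotypic
lifetime *is* the negative fitness of its genotype.  (The proportionality
between genotype likelihood and phenotypic path likelihood that underlies
this reading is a modelling postulate; the package exposes it as the
definition of the fitness functional and claims no generality beyond it.)
Lifetimes that diverge numerically are scored as +∞ action with a
diagnostic — the phenotype strayed from the path — rather than aborting
the generation.

Gradients of the action with respect to the genotype use central finite
differences with common random numbers (the same lifetime seed on both
sides of the difference), step h = 1e−3 relative.  CRN matters: it cancels
the shared stochasticity of the lifetime so the difference estimates the
derivative of the realised action, which the tests confirm against the
closed-form derivative of accumulated negative log evidence in the
linear-Gaussian environment.

The slow update is θ ← θ + (Q_slow − Γ_slow)∇A·dt + N(0, 2Γ_slow·dt),
with Q_slow = 0 by default (an optional antisymmetric matrix mixes the
descent without changing the stationary law).  Because drift mobility and
noise variance share Γ_slow, the stationary density is exp(−A(θ))
regardless of Γ_slow — the discrete-time (Euler) bias on the stationary
variance is r/2 where r = Γ_slow·dt_slow is the per-generation contraction,
so study configurations keep r ≤ 0.1.  Only the products Γ_slow·dt_slow
enter; both are reported together in every config.  The
Kolmogorov–Smirnov comparison against exp(−A) on the quadratic stub uses
10⁴ samples thinned at four relaxation times per draw (residual
autocorrelation e⁻⁴), taken after a ten-relaxation-time burn-in.

Bayesian model reduction for Gaussians: with posterior precision P, prior
precision P₀ and reduced-prior precision P_r, the reduced posterior has
precision P_p = P + P_r − P₀ and the evidence change is

    ΔF = ½[ln|P_r| − ln|P₀| + ln|P| − ln|P_p|]
       + ½[bᵀP_p⁻¹b − mᵀPm − m_rᵀP_r m_r + m₀ᵀP₀m₀],   b = Pm + P_r m_r − P₀m₀.

The formula is oracle-anchored: every test compares it against evidence
differences computed from conjugate closed forms, at 1e−6.  Greedy
structure selection tries candidates one at a time in insertion order;
candidates are callables mapping the *current* prior to a reduced prior,
so that earlier accepted reductions stay in force along the greedy chain
(with absolute reduced priors a later candidate would silently restore a
pruned component).  On orthogonal (diagonal) components the greedy deltas
sum to the joint reduction's evidence change exactly.

## The synaptic demo (`varsel.synaptic`)

The demo instantiates the whole stack on a neuron whose dendrite must
discover where its synapses belong.  The environment is n_pools = 20
presynaptic pools firing Gaussian bumps at phases k/n_pools of each wave;
the wave train is periodic, so every pool's curve is an exact
time-translate and carries exactly `waves_per_lifetime` bumps.  The cell's
generative model is a travelling wave along its own dendrite: slot j
expects the bump of phase j/n_slots.  With n_slots = n_pools the identity
assignment is the unique global optimum, and an exhaustive check confirms
it beats every single-swap neighbour in action.

Per-channel free energy is ½[ln 2π − λ_j + e^{λ_j}ε_j²] plus a weak
Gaussian prior on the log precision λ_j (variance 16); λ_j follows a
gradient flow on F with learning rate 2.0, clipped to [−5, 5].  The fixed
point is λ_j ≈ −ln⟨ε_j²⟩: matched synapses (ε from sensory noise only)
saturate high, mismatched ones settle low — precision *is* the evidence
summary that drives selection, as required.

Key geometric choice: the bump width is a quarter of the inter-pool
spacing.  At half the spacing, adjacent pools' bumps correlate at e⁻¹ ≈
0.37, an adjacent-mismatched synapse then carries genuine signal, model
reduction correctly keeps it, and relocation deadlocks short of the
optimum; at a quarter spacing the correlation is e⁻⁴ ≈ 0.02 and pools are
temporally resolvable.  This is an identifiability requirement of the
design, not a tuning knob.

Structure selection runs per generation on per-synapse channel gains: each
slot's input is modelled as y_j = g_j·pred_j + noise with prior
g_j ~ N(0, 1); a lifetime of data gives a conjugate Gaussian posterior
over g_j under the learned precision, and the reduction candidate pins
g_j to zero (prior variance 1e−6).  Accepted removals relocate the slot to
a pool drawn uniformly from the pools other than its current one, and the
slot's precision restarts at its initial value.  Every decision is logged
with its evidence delta, and the demo's decisions are bit-reproducible
given the config seed.

Default study conditions: 5 segments × 4 synapses (20 slots, one pool per
slot), lifetime 120 time units, 2 waves per lifetime, 64 generations,
sensory noise s.d. 0.1 (10% of bump amplitude — mild but non-negligible
channel noise), dt = 0.25 (bump width 0.75 time units, so three samples
per bump s.d.).

**What the generator does and does not emulate.**  It produces the timed,
spatially ordered input statistics that make dendritic ordering
identifiable, with stationary wave timing, identical bump shapes, and
white Gaussian channel noise.  It does not emulate biophysical membrane
dynamics, spike timing, conduction delays, synaptic facilitation or
depression, or nonstationary environments.  Passing tests therefore show
that the *selection mechanics* — precision learning, evidence-based
pruning, random relocation — find the generative structure when one
exists and is identifiable; they say nothing about robustness to model
mismatch between the cell's generative model and a real neuropil.

## Problem sizes

The test and reproduction runs use: 10⁶ Euler–Maruyama steps per NESS
check (five random flows); 500-step filtering traces; 100 random models
for the free-energy and reduction checks; 50 chains × 16 200 generations
(10⁴ thinned samples) for the stationary-law comparison; 50 genotypes ×
100 generations × lifetime 100 for parameter recovery; and 10 seeds each
for the synaptic demo at default and reduced size.  These sizes put the
Monte-Carlo error of every estimate well inside the asserted tolerance
bands while keeping a full reproduction run to a few minutes on one core.

## Known limitations

* Everything analytic rests on the linear-Gaussian (quadratic-potential,
  Laplace) assumptions; the callable-potential and nonlinear escape
  hatches run but are not covered by the guarantees.
* State-dependent diffusion, Fokker–Planck density solvers, and
  thermodynamic (heat/work) accounting are out of scope.
* Selection has no recombination, crossover or explicit replicator
  dynamics; genotypes evolve independently given the environment, and
  populations interact only through the fitness functional.
* The grouping heuristic beyond 10 nodes is deterministic and validated
  per run, but is not guaranteed to find the finest partition.
* Discrete-state (POMDP-style) active inference and hierarchical deep
  models are not implemented.
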