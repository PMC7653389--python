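# Methods

## Thermodynamic mass-action kinetics and the steady state

Reactions are modelled in the Marcelin form: the net rate of reaction *j*
is proportional to the difference between the exponentiated forward and
reverse affinities, `J_j = c_j (K_j Q_j⁻¹ − K_j⁻¹ Q_j)`, with the reaction
quotient `Q_j` built from molar activities of *all* species (boundary
included) against a 1 M standard state. We set the timescale factor
`c_j ≡ 1` for every reaction: all fluxes are therefore in odds-difference
units per common unit timescale, and flux *ratios*, odds and free energies
— the quantities the analyses rest on — are unaffected by this choice.
Under a shared timescale, the steady state is the maximum path-entropy
solution: net driving forces equalise along linear segments and distribute
in proportion to stoichiometry at branch points.

Regulation enters as an activity coefficient `α_j ∈ [0, 1]` multiplying
the net driving force (`J_j = α_j (K_j Q_j⁻¹ − K_j⁻¹ Q_j)`). This is a
rheostat, deliberately distinct from *gating*, which scales forward and
reverse mass-action rate constants identically and therefore cancels from
the odds; `gated_steady_state` implements the gating control to make the
contrast testable.

### Solver

The optimisation problem `‖S_V (α ∘ (KQ⁻ − K⁻Q))‖² = 0` is solved over
`x = ln n_V`:

* positivity is built in and the residual is log-concave in `x`;
* the analytic Jacobian is `−S_V diag(α_j (f_j + 1/f_j)) S_V^T` with
  `f_j = K_j/Q_j` — symmetric and (for α > 0) negative definite, so
  Levenberg–Marquardt converges in a handful of iterations;
* exponents are clipped at ±300 to guard overflow far from the solution
  (inactive at any solution of interest);
* default start: the state's variable concentrations (1 mM for the
  biological models); on failure, up to 10 seeded restarts perturbed by
  ±2 natural-log units;
* convergence: squared residual norm ≤ 1e-10 (configurable). In practice
  the analytic-Jacobian solves land at machine precision, giving
  `‖S_V J‖∞` of 1e-12 or better on the 27-variable model.

Flat directions (zero-flux branches, species untouched by any active
reaction) are detected from the singular values of the Jacobian at the
solution and reported in `null_direction_report`, never silently pinned.
Closed systems (no boundary species) are underdetermined in the sense
`M_V > Z`; construction rejects them by default but accepts
`check_determined=False` for equilibrium studies, where the solver
converges to *a* point on the equilibrium manifold (`Q = K`, all fluxes
zero) whose concentration ratios follow the Boltzmann weights
`exp(−μ°_i/R_gT)` when standard potentials are supplied.

Rate constants can be back-calculated from a converged solution via
`k_j = J_j / (Π n_i^{ν} (1 − K_j⁻¹Q_j))`, `k_{−j} = k_j / K_j`; reactions
within 1e-6 of unit odds leave `k` undefined (reported, not guessed).
Integrating the resulting mass-action ODEs reproduces the optimiser's
fixed point, which the tests use as an independent cross-check.

## Scoring

* Free energies: `ΔG_j = −R_gT ln(K_jQ_j⁻¹)`;
  `ΔG_j^eff = ΔG_j − R_gT ln α_j` (undefined at α = 0, returned as NaN).
* Dissipation: `dG/dt = −R_gT Σ_j α_j (r_j − r_{−j}) ln(K_jQ_j⁻¹)` with
  the Marcelin rates `r_j = K_jQ_j⁻¹`, `r_{−j} = K_j⁻¹Q_j`; the entropy
  production rate is `EPR = −dG/dt ≥ 0` (each term is a flux times its
  own affinity, so every summand is non-negative). The energy dissipation
  rate keeps only the K-dependent part,
  `dE/dt = −R_gT Σ_j α_j (r_j − r_{−j}) ln K_j`; it vanishes identically
  when all K = 1 regardless of flux. Both the signed value and the
  per-reaction contributions are reported.
* Calibre: `L_i = ln(ñ_i/n_i)` per variable metabolite; stopping loss
  `L = Σ max(L_i, 0)`; "in calibre" means every `L_i ≤ 0` with an
  absolute slack of 1e-9 to absorb solver noise. Predictions *below*
  target are acceptable because the model tracks free pools while
  measurements include enzyme-bound metabolite. The RL loss is
  `Λ = ln(Σ_i ñ_i/n_i)`, which weights the worst violators most.
* Adenylate energy charge `(ATP + ADP/2)/(ATP + ADP + AMP)` is computed
  as a readout only; no band is enforced anywhere.

## MCA regulation

Concentration control coefficients `C_{i,j} = ∂ln n_i/∂ln α_j` are
one-sided downward finite differences (activities cannot exceed 1) with a
full re-solve per probe, warm-started from the base solution; the default
relative step is 0.01, and 1e-3 is used where coefficients are compared
with closed forms. α-scale invariance of the steady state implies the
summation theorem `Σ_j C_{i,j} = 0` per variable species, which the tests
verify to 1e-4. Boundary species have identically zero coefficients.

The loop: compute the violating set M′, score each eligible reaction by
`ΔL_j = Σ_{i∈M′} −ln(1 − C_{i,j} δ)` (arguments capped at 1e-12 when a
step would overshoot a concentration to zero), regulate the argmax (ties
break to the lowest reaction index) by a multiplicative decrement
`α ← α(1 − δ)` with δ = 0.05, and re-solve. The final step is refined by
bisection so L lands at zero without overshoot — minimal regulation on a
continuous α. Terminal reasons are `in_calibre`, `stalled` (no positive
estimated reduction, solver failure, or the iteration cap of 1000) and
`flux_collapse` (max |J| below 1e-6 of its unregulated value) — the last
reproduces the known failure mode where chasing an unreachable target
throttles the whole network. Eligibility is every active reaction
(unrestricted mode) or only reactions with an immediate product — a
species with positive signed coefficient in the reaction's net-flux
direction at the unregulated base — in M′ (local mode).

## RL regulation

The MDP: states are activity vectors on the lattice `{k·Δα}`, actions
choose a reaction, transitions deterministically decrement the chosen
activity by Δα = 0.05 and re-solve (results cached by lattice point, which
makes toy-model training cheap). Reward: `(Λ(s) − Λ(s′))/η`, plus
`EPR(s′)` when the move reaches L = 0 (terminal). Defaults: discount
γ = 0.9; η = Λ(s₀)/10 so intermediate rewards are O(1); ε-greedy policy
with one-step lookahead `argmax_a R(s,a,s′) + γV(s′)`, initial ε = 0.5 for
Z ≤ 12 (0.2 above), halved every 25 episodes; 350 episodes per agent;
value function a single-hidden-layer tanh network (width 64) trained by
SGD on the squared n-step-return error, n-step SARSA with truncation at
terminals. None of γ, η, Δα or the width is pinned by the study
conditions; all are configurable and logged with results. Each agent uses
one seeded generator; sweeps (default 6 n-values × 3 learning rates × 10
agents = 180 runs) spawn child seeds deterministically and select the
agent with the largest cumulative reward averaged over its last 50
terminal states. The terminal-state population (activities, L, Λ, EPR,
dE/dt per terminal) is retained so the dissipation spread across schemes
can be inspected.

## The E. coli models

Three builders: gluconeogenesis (10 reactions), glycolysis–TCA (21) and
glycolysis–PPP–TCA (29 reactions: upper/lower glycolysis, oxidative and
non-oxidative PPP, the TCA cycle and the NADH-dependent GOGAT reaction
that ties 2-oxoglutarate to the fixed glutamate/glutamine pools). The
largest model has 47 metabolites: 27 variable intermediates and 20 fixed
boundary pools. Eleven boundary values are the stated glucose-fed
concentrations (glucose 1 mM, ATP 9.6 mM, ADP 0.56 mM, Pi 20 mM,
NAD⁺ 2.6 mM, NADH 0.083 mM — NAD/NADH = 31.3 — glutamate 0.096 mM,
glutamine 3.81 mM, CO₂ 0.1 mM, CoA 1.4 mM, H₂O 55.5 M). The boundary set
is completed to 20 by the cofactor pairs the reaction roster implies:
NADP⁺/NADPH for the oxidative PPP (NADPH clamped at the NADH level and
NADP⁺ set from the condition ratio, 0.02 or 31.3 — only the ratio is
constrained), the ubiquinone pair for succinate dehydrogenase (1 mM each),
and a mitochondrial-side pool (NAD_m/NADH_m, CoA_m, CO₂_m, H₂O_m,
mirroring the cytosolic values) implied by the explicit pyruvate
transporter PYRt2m, which is itself modelled as pure translocation with
K = 1 unless an energy is supplied. PDH draws the cytosolic CoA pool
(imported with pyruvate); the TCA proper uses the matrix pool. The
gluconeogenesis roster runs pyruvate → G6P through PC, PPCK and the
reversed glycolytic chain with FBP; glucose 6-phosphatase is folded into
the fixed G6P product pool to keep the canonical 10-reaction count while
retaining PC and FBP. Protons are not explicit species — supplied ΔG°'
must be transformed (pH-adjusted) values; water is explicit at 55.5 M.
Concentrations are held internally in molar; all file interfaces are mM.

## Synthetic data

`generate_synthetic_thermo` samples per-reaction standard free-energy
drops uniformly from [1, 10] kJ/mol (numerically benign odds), fits
per-metabolite standard chemical potentials by least squares
(`S^T μ = ΔG°'`) so the K set is path-independent on branched and cyclic
topologies (the thermodynamic consistency a real free-energy database
guarantees), and rescales so the realised drops sum to the requested
overall favourability — equal to the source→sink standard drop on a linear
chain. The analyses use 260–300 kJ/mol overall for the 21–29-reaction
models, i.e. roughly 9–10 kJ/mol of drive per reaction, enough that every
segment's odds are far from 1. `generate_targets` sets targets to a
fraction of the unregulated prediction (guaranteeing a non-empty violating
set) with the 1.0 mM default elsewhere.

What synthetic thermodynamics do and do not show: every *stoichiometric*
consequence (the PPP:glucose flux ratio of 3 with PFK off, the factor-two
odds split between upper and lower glycolysis, mass balance, the summation
theorem, regulation pushing reactions from equilibrium) is independent of
the individual K values and is exercised honestly. The *identity* of the
regulated set beyond the entry-point pattern, and printed per-reaction
free-energy values, depend on the real reaction energetics and on measured
metabolite targets; reproducing those requires user-supplied transformed
reaction energies (e.g. eQuilibrator at pH 7.0, I = 0.15) and measured
concentrations via the TSV interfaces. With synthetic energies and the
uniform 1 mM target, the unrestricted search still concentrates regulation
at the pathway entry (HEX1 carries the largest summed control coefficient)
but selects its second site in the TCA segment rather than at GAPD.

## Problem sizes and determinism

The shipped analyses use the full 29-reaction model for solving and MCA
(a regulation run is ~500 steps × 30 warm-started re-solves, tens of
seconds) and the 2-reaction chain for RL training (150-episode agents,
5 seeds, seconds with the transition cache); the full 180-run sweep on the
29-reaction model is supported but is hours of compute and is exercised
as a scaled-down configuration. All stochastic components (multi-start
perturbations, ε-greedy exploration, weight initialisation, synthetic
drops) draw from seeded generators; identical seeds give bit-identical
traces and files.

## Known limitations

* No enzyme saturation: the Marcelin form has no K_M or V_max, so
  kinetic (V-type) regulation is outside the model; the activity
  coefficient is a purely thermodynamic (K-type-like) rheostat.
* The shared-timescale assumption fixes relative fluxes by thermodynamics
  alone; absolute fluxes are in arbitrary units until rate constants are
  back-calculated.
* The local-MCA eligibility rule uses net-flux direction at the
  unregulated base; pathways whose flux direction flips under regulation
  would need re-evaluation per step.
* The MCA loss model is linear in ln α per step; strongly coupled
  violations can make the greedy argmax path-dependent (the deterministic
  tie-break keeps it reproducible).
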