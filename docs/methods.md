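# Methods

## Model and assumptions

`ecmkit` treats metabolic fluxes as given data (measured or computed
elsewhere; stationarity is not assumed) and predicts metabolite and enzyme
concentrations from an optimality principle: the cell realizes the fluxes
with the enzyme profile of minimal total cost. The key modeling move is to
express enzyme demand as a function of metabolite log-concentrations
x = ln(c/1 mM) through separable reversible rate laws,

E_l = v_l / (kcat⁺_l · η_rev,l · η_sat,l · η_reg,l),

and to minimize the burden-weighted total q = Σ h_El E_l over the metabolite
polytope P, the set of x satisfying the concentration bounds and
Θ_l = ln K_eq,l − Σ_i n_il x_i ≥ ε for every active oriented reaction.
Each −ln η term is convex in x, so q is convex on P and the optimum is found
reliably by local methods. Assumptions worth keeping in mind:

- All active reactions are enzymatic and oriented along their flux; zero-flux
  reactions are dropped from the cost and impose no driving-force
  constraint (the inactive sub-network is not modeled).
- Boundary metabolites with fixed concentrations isolate the pathway from
  the rest of the network; predictions are only as meaningful as those
  boundary choices.
- The burden is linear by default (q = Σ h E); a user-supplied convex h(E)
  is accepted and preserves convexity.

## Cost tiers

| Tier | η_rev | η_sat | needs | notes |
|------|-------|-------|-------|-------|
| EMC0 | – | – | fluxes | q = Σ v, constant in x |
| EMC1 | – | – | h, kcat⁺ | q = Σ h v/kcat⁺, constant in x |
| EMC2S | ✓ | – | + K_eq | depends on x only through Θ |
| EMC2SP | ✓ | S/(S+P) | + kcat⁻ | η_sat = 1/(1+e^(−Θ)·kcat⁺/kcat⁻) via the Haldane substitution |
| EMC3S | ✓ | S/(1+S) | + K_M | |
| EMC3SP | ✓ | S/(1+S+P) | + K_M | |
| EMC4CM | ✓ | common modular | + K_M | equals EMC3SP for 1:1 reactions |

S = Π(s_i/K_M,i)^{|n|}, P = Π(p_j/K_M,j)^{|n|}; stoichiometric coefficients
enter with exponent |n_il| (this generalizes the unimolecular law; explicit
cooperativity beyond stoichiometry is not modeled). The common modular
denominator is Π(1+s/K)^{|n|} + Π(1+p/K)^{|n|} − 1. Each tier lower-bounds
the next within its S/SP family. Allosteric regulation is implemented as the
noncompetitive prefactor η_reg = 1/(1 + c_I/K_I); other mechanisms can be
injected as user callables with the contract 0 < η ≤ 1 and −ln η convex
(required to keep the program convex).

EMC2SP is stated in some summaries as needing only {h, kcat⁺, K_eq}, but its
S/(S+P) denominator requires the kcat⁺/kcat⁻ ratio; we expose kcat⁻
explicitly (it is derivable from the Haldane relationship in a balanced
parameter set).

## Units, parameters, defaults

- Concentrations mM, fluxes mM/s, catalytic constants 1/s; x is natural-log
  mM (standard concentration 1 mM); K_eq unitless at that standard;
  RT = 2.4790 kJ/mol (25 °C) converts Gibbs energies to RT units.
- ε (driving-force margin): 1e-9. The cost itself diverges at Θ → 0 and acts
  as a natural barrier; ε only makes the LP feasibility strict. Per-reaction
  minimal driving forces can be set by the user.
- Missing K_M values are filled with 0.1 mM (geometric mid-range of typical
  values), given low weight in balancing, and flagged
  (`km_default_mask`) so saturation-based results can be audited.
- Burden modes: per-reaction h_E from the parameter table (default 1,
  i.e. uniform), protein mass in Da (cost = mg protein/l; pathway specific
  activity A_pw = v_pw/q then comes out in mmol s⁻¹ mg⁻¹), or mass divided
  by the median mass (a chain-length proxy). Amino-acid-composition costing
  is out of scope.
- Default concentration bounds when a compound row gives none: 1e-6–100 mM.
- kcat∞ = 1e8 1/s is carried as a constant for the optional diffusion-limit
  decomposition kcat⁺ = kcat∞ η_cat.

## Parameter balancing

Measured kinetic constants are made mutually consistent by a weighted least
squares fit in log-parameter space over the free basis (per-metabolite
formation energies g_i in RT units, ln K_M, ln kcat⁺); ln K_eq = −Σ n g and
ln kcat⁻ follow from the basis, so Haldane relationships and Wegscheider
cycle conditions hold exactly by construction, and the procedure is
deterministic and idempotent. This is a deliberate simplification of full
Bayesian balancing: there are no prior distributions or posterior samples,
only optional weak prior rows (`prior_weight`) that regularize
under-determined systems; genuinely undetermined outputs raise an error
instead of being silently imputed. The same free basis is used for
Monte-Carlo parameter sampling (independent log-normal perturbations;
defaults log10-sd 0.2 for K_M and kcat⁺, 0.05 RT for formation energies),
which is a simplification of sampling from a balanced posterior — sampled
sets are exactly Haldane-consistent but their correlations beyond that are
not calibrated to any measurement error model.

## Optimization

- Variables: free metabolite log-concentrations only; fixed metabolites are
  folded into constraint offsets.
- Solver: scipy's trust-region constrained method with analytic gradients,
  BFGS curvature, E-face constraints and bounds kept feasible at every
  iterate; start point is the MDF profile (the interior point maximizing the
  minimum driving-force slack — reusing an operation the method needs
  anyway, instead of a Chebyshev center). Convergence at projected gradient
  < 1e-9; a seeded multi-start is the fallback if the first run fails.
- Regularizer: λ‖x − x̂‖² with defaults λ = 1e-6 × (cost at the MDF point)
  and x̂ the midpoint of the log-bounds. The squared norm was chosen for
  smoothness and strict convexity; it uniquely pins the flat tiers
  (EMC0/EMC1, and the Θ-only EMC2 family along its null directions) while
  perturbing strictly convex tiers negligibly. λ is configurable; no
  canonical value is claimed.
- Infeasibility: an empty polytope raises an error carrying an irreducible
  infeasible subset of driving-force constraints (deletion filter over the
  feasibility LP). The CLI maps this to exit code 3.
- Tolerance ranges at cost slack α (default 0.01): metabolite endpoints by
  bisection on the coordinate against the convex check
  min{q : x ∈ P, x_j = t} ≤ (1+α)q_opt, with the pinned coordinate
  eliminated from the subproblem; enzyme lower endpoints minimize the convex
  demand under the cost constraint (exact); enzyme upper endpoints maximize
  a convex function and are therefore only a heuristic — maximum over the
  metabolite-endpoint profiles plus local ascent — and are tagged as such.

## Synthetic data

The toy pathway (X ⇌ A ⇌ B ⇌ Y, all constants 1, flux 1 mM/s) fixes its
boundary levels at 1 mM and 0.01 mM; these are not canonical values — they
were chosen once to give a comfortably feasible polytope (total force
ln 100) spanning the concentration decades of interest, and are
configurable. The random-model generator draws formation energies first
(normal, sd 1.5 RT), derives K_eq, draws K_M log-normally around 0.1 mM and
kcat⁺ around 10 1/s (log10-sd 0.5), sets kcat⁻ by Haldane, and redraws
boundary concentrations until the polytope is nonempty with margin. It
emulates thermodynamically consistent chain/branched pathways only: no
cofactor coupling, no moiety conservation, no shared metabolites between
distant reactions, uniform burdens. Passing tests on these models therefore
demonstrate correctness of the machinery, not predictive accuracy on real
networks. Synthetic "measurements" are the model's own predictions times
log-normal noise; the cost-optimality recovery experiment (optimum predicts
such data better than broadly sampled profiles) checks internal consistency
of the optimality test, again not biology.

Flux samples that would flip a sign are rejected and redrawn (orientation
must be preserved); fixed boundary levels are perturbed uniformly in a
relative range (default ±5%); flux noise is relative (default 15%); local
metabolite sampling uses ln-sd 0.05 with rejection against the polytope, and
broad sampling uses flat (symmetric Dirichlet, concentration 1) convex
combinations of the 2m coordinate-wise extreme points — the mixing
distribution over the polytope is a design choice, not canonical.

## Problem sizes and numerical checks in the test suite

Tests run on the toy model (2 free metabolites) and seeded random chains of
5–6 metabolites; convexity is checked on ≥1000 random feasible segments
across all seven tiers, optimizer correctness against a 200×200 grid search
(1e-3 relative cost) and 2000 sampled feasible points per variant, gradients
against central finite differences (1e-5 relative), the inverse-rate-law
round trip to 1e-9 relative, and the recovery experiment over 20 seeded
repetitions with 1000 broad profiles each. These sizes keep the full suite
fast while exercising every code path; larger problems run through the same
code unchanged.

## Known limitations

- Only the common modular law is implemented as an EMC4 instance; other
  modular variants (direct binding etc.) are not.
- No preemptive enzyme expression across conditions, no non-enzymatic or
  dilution reactions, no control-coefficient/Hessian-based tolerance
  approximations, no embedding into FBA or elementary-flux-mode screening.
- No SBML import/export and no database (BRENDA/eQuilibrator) retrieval;
  models arrive as SBtab-dialect TSV.
- Enzyme upper tolerance endpoints are heuristic (see above).
- The scaled reactant elasticity appears in control-coefficient theory only
  and has no representation here.
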