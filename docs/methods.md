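# Methods

## Model and simulation scheme

The engine implements dynamic flux balance analysis in the static
optimisation approach (SOA): the extracellular environment evolves on a
fixed grid t = 0, Δt, 2Δt, …, and at every grid point one linear program

    max  c·v   s.t.   S v = 0,   lb ≤ v ≤ ub

is solved over the intracellular steady-state polytope. Between solutions,
biomass B (gDW/L) and the tracked medium concentrations X (mmol/L) are
integrated analytically under the assumption that the flux vector is
constant over the step:

    μ  = v_biomass                      (1/h, the *biomass reaction* flux)
    B' = B e^{μΔt}
    X' = X + v_ex · B (e^{μΔt} − 1)/μ   (Euler form X + v_ex·B·Δt for |μ| ≤ 1e−9)

where v_ex is the metabolite's exchange flux (positive = secretion). Growth
is deliberately read from the biomass reaction, never from the LP objective,
so the objective can be any flux — including one that competes with growth,
as in overproduced protein secretion. The biomass reaction is resolved from
an explicit argument, else by a case-insensitive "biomass" id/name match,
else the first reaction with a nonzero objective coefficient is used and a
warning issued.

What makes the engine *adaptive* is that at any step, before the LP is
solved, the run can be steered:

1. a **bounds schedule** (columns `<reaction>[low]` / `<reaction>[upp]`)
   overwrites reaction limits at matching times; sparse schedules are
   densified by linear interpolation between knots (no extrapolation) or,
   with `interpolate_schedules=False`, must carry a row for every grid time;
2. a **bounds callback** `f(model, concentrations, last_fluxes, Δt) →
   {reaction: (lb, ub)}` implements feedback logic on reaction limits;
3. a **concentration schedule** adds differential amounts to the medium
   (zero means no change, positive adds, negative removes);
4. a **concentration callback** `g(concentrations) → concentrations`
   replaces medium values, e.g. a fed-batch sensor/actor rule.

The order is fixed as listed so that callbacks observe scheduled changes.

### Substrate conventions

Initial concentrations may name any subset of exchanged metabolites in any
order. Zero marks an absent substrate (its uptake is clamped to zero until
it is produced); a negative value marks a substrate in unlimited EXCESS —
it is never clamped, its concentration is not integrated, and its
cumulative exchange is logged instead. Exchanged metabolites not mentioned
default to EXCESS with a warning. A callback may later convert an EXCESS
metabolite into a tracked one by assigning it a non-negative concentration;
until then the sentinel is sticky.

### Availability clamp

To prevent consuming substrate that is not there, the lower bound of every
exchange reaction that is *currently* an uptake reaction (lb < 0 after the
step's interventions — eligibility is read from the bounds in force, not
the initial ones, because exchanges may legitimately switch direction) is
tightened to

    lb ← max(lb, −X / (B Δt)).

The clamp is ephemeral: it modifies only the bounds used for this step's
LP, so when a concentration recovers the bound relaxes back to the limit
currently in force, never beyond. Because the realised consumption follows
the exponential integral B(e^{μΔt}−1)/μ, which exceeds the linear B·Δt for
μ > 0, the engine re-tightens against the realised μ and re-solves until no
bound moves (tightening uptake can only lower μ, so this converges; in
practice one extra solve at an exhaustion step). This guarantees tracked
concentrations never fall below −1e−9 by construction; a violation raises
an integration-consistency error rather than being silently clipped.

### LP solution

FBA is solved by HiGHS (through SciPy) behind a single backend surface.
Because FBA optima are often degenerate, two refinements are available:

* **MTF** (minimisation of total flux, the parsimonious-FBA construction):
  each flux is split into non-negative forward/reverse parts and Σ|v_i| is
  minimised subject to c·v ≥ γ·Z* with Z* the FBA optimum (γ = 1 by
  default). The L1 norm via variable splitting is the standard choice.
* **Per-step FVA** at objective fraction γ records min/max flux brackets;
  it multiplies the per-step LP count by 2n and is off by default.

Alternate LP backends can return different optimal vertices; the test suite
therefore pins exact flux values only where the optimum is provably unique
and otherwise asserts objective values and feasibility. Numerical
tolerances: feasibility 1e−9, optimality comparisons 1e−6, schedule time
matching 1e−9 h; all fixed constants surfaced in `lp_core`/`dynamics`.

An infeasible step LP terminates the run early and returns the partial
trajectory with a termination reason — premature termination (e.g. forced
secretion after carbon exhaustion) is a simulation result, not an error.
A degenerate all-zero objective is rejected at validation rather than
silently treated as "optimise nothing".

## Statistical pipeline

Trajectory variables (concentrations and fluxes per time point) are mined
as follows. Normality is screened per variable with Shapiro-Wilk and
Anderson-Darling; when both reject at α = 0.05 the rank-based branch is
recommended. All-pairs association uses Pearson, Spearman, and curvilinear
(quadratic/cubic) regression; for the curvilinear sweep, entry (i, j) is
the R² of regressing variable i on a polynomial in variable j — a
directional quantity, so only the Pearson/Spearman matrices are symmetric.

Feature selection offers forward and backward stepwise OLS scored by AICc
(the small-sample corrected AIC; the stopping rule is "no candidate step
improves AICc") and a grouped Boruta: candidates are batched in groups of
20, each group receives a shadow-feature random-forest pass (each iteration
appends independently permuted copies of every feature, a *hit* is an
importance above the best shadow, and hit counts are tested against a
Binomial(n, ½) at α = 0.05), survivors (confirmed + tentative) are pooled
and re-grouped until at most one group of ≤ 20 remains, which receives the
final pass; its confirmed set is the selection. Random forests are
regression forests (500 trees by default; outcomes here are continuous
fluxes/concentrations) and every stochastic element derives from one seed,
making results bit-reproducible.

Timeline comparison between two simulations computes per shared variable
ANOVA, Kruskal-Wallis, Welch t and Mann-Whitney U over the whole grid or a
time window. The Mann-Whitney column is the primary artifact (trajectory
variables are essentially never normal); raw p-values are reported, with a
Benjamini-Hochberg-adjusted column added as a clearly labelled extra. The
output table is heatmap-ready TSV; rendering is left to any plotting layer.

Time trends are fitted as polynomials of order 1–3 in t (or in a
transformed time axis such as √t). Non-nested specifications of the same
response are compared with the Cox test and the Davidson-MacKinnon J test;
a small p-value in `compare_nonnested(a, b)` is evidence against `b`.
Nested pairs (one regressor span containing the other) are rejected with a
pointer to the F-test; exact fits (zero residuals) flag the comparison as
degenerate instead of fabricating statistics.

## Toy scenarios

The fixture generator produces ≤ 25-reaction networks whose qualitative
behaviour is guaranteed by construction, standing in for genome-scale
fermentation scenarios:

* **diauxic** (defaults: glucose 10 mmol/L, O₂ uptake cap 4 mmol/gDW/h in
  EXCESS supply, biomass yields 0.05/0.20/0.06 per fermentation, glucose
  respiration, by-product respiration): the optimum ferments glucose
  (excreting the by-product) while respiring at the O₂ cap, then switches
  to respiring the accumulated by-product — a two-phase growth curve with
  exactly one sign change of the by-product exchange, the
  overflow/re-uptake motif (the acetate switch, or L-alanine excretion and
  later consumption in *Streptomyces* fermentations).
* **secretion-conflict** (ATP cost 2 per protein, biomass drain 20
  precursor + 20 ATP per unit growth): protein synthesis drains the same
  precursor/ATP pools as growth, so an unforced optimum never secretes;
  forcing a secretion floor starves the culture and ends the run early.
* **minimal-chain**, **futile-cycle**, **parallel-paths** exercise the LP
  layer: a unique vertex, an MTF-silenced loop, and genuinely alternate
  optima.

Default initial biomass is 0.05 gDW/L (documented range 0.01–0.1). The
synthetic statistical tables are standard-normal decoys with an optionally
planted linear signal plus Gaussian noise. These fixtures reproduce the
*mechanisms* (resource competition, overflow metabolism, feedback feeding)
but none of the stoichiometric detail, biomass composition or yields of a
real genome-scale network — passing tests demonstrate correctness of the
algorithmic machinery, not predictive accuracy for any organism.

## Problem sizes and defaults

The default step is 1 h (the usual fermentation-scale choice); the bundled
scenarios use 0.25–0.5 h to resolve their faster toy kinetics. Statistical
checks use 40–60 time points and up to 46 variables, with 500-tree forests
by default (tests and the reproduction script use 40–60 trees and 8–10
shadow iterations, ample at the planted effect sizes). The brute-force LP
oracle in the test suite enumerates vertices only for networks of ≤ 6
reactions.

## Known limitations

* SOA with a fixed step: no dynamic step-size control and no whole-horizon
  (DOA/collocation) formulation; stiff transitions should be resolved by a
  smaller Δt.
* Bounds callbacks may edit bounds only, not stoichiometry.
* Michaelis-Menten-style uptake kinetics are not built in, but are
  expressible as a bounds callback.
* The curvilinear R² sweep is directional (documented above).
* Boruta group batching follows input column order; a different ordering
  can change group composition (not selection outcomes at realistic effect
  sizes).
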