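# Methods

This note documents the models implemented in `comgem`, their assumptions,
the numerical choices behind the solvers, what the bundled synthetic
community does and does not emulate, and the design decisions taken where
the problem was genuinely open.

## Single-species layer

A model is a stoichiometric matrix S (metabolites × reactions) with flux
bounds, a biomass reaction (flux in hr⁻¹, the standard biomass-reaction
convention identifying its flux with specific growth rate) and an ATP
maintenance reaction. Flux balance analysis solves `max c·v s.t. S v = 0,
lb ≤ v ≤ ub`; flux variability analysis reports per-reaction min/max at a
required fraction of the optimum. All LPs — FBA, FVA, and every community
program below — are assembled sparse and solved with HiGHS (scipy), primal/
dual feasibility tolerance 1e-9. LPs generally have alternate optima; the
toolkit treats only the objective value and FVA-certified-unique fluxes as
meaningful, and the test suite cross-checks FBA objectives against an
independent solver stack (cobra/GLPK).

Maintenance energy: GAM (growth-associated, mmol ATP·gDCW⁻¹) is folded into
the biomass reaction as `gam ×` the maintenance reaction's own stoichiometry;
NGAM (mmol ATP·gDCW⁻¹·hr⁻¹) is the maintenance reaction's lower bound.
`set_maintenance` replaces the previously recorded GAM contribution, so for
SBML imports whose biomass reaction already embeds an unknown GAM the
adjustment is relative to the recorded attribute (0 on import).

Blocked-reaction removal opens every boundary reaction to ±1000
mmol·gDCW⁻¹·hr⁻¹ (the COBRA "wide open" convention — the removal is meant to
hold under *any* condition, which needs a concrete bound), removes reactions
whose FVA range is (0,0) within 1e-9, and iterates to a fixed point. Since
removing zero-flux reactions cannot alter the remaining flux space, the
iteration is a safety net rather than a mathematical necessity. The biomass
and maintenance reactions are never removed, because a model without them is
structurally invalid here.

## Community construction

Member models are harmonized (canonical extracellular names via a synonym
map, then species prefixes M1, C1, …) and merged around a shared community
compartment `[u]`. Each whitelisted extracellular metabolite gets, per
species that declares it, one reversible transport `[e] ⇌ [u]` with open
bounds — exchange directionality is an *outcome* of the LP, never an input —
plus a single community exchange reaction on `[u]` carrying the policy
bounds (uptake negative). Member-level exchange reactions on `[e]` are
removed: everything must pass through the community accounting. Exclusion
from exchange is implemented by omission (no `[u]` counterpart at all), so a
species obligated to excrete an excluded metabolite renders the model
infeasible rather than leaking it — the solver status is reported verbatim
in that case. Light is treated as a `[u]` "metabolite" with an uptake-style
community exchange, because photon supply is constrained exactly like a
substrate. Six named inclusion/exclusion presets over central-carbon acids
(`setup1`…`setup6`) ship as `ExchangePolicy` constructors.

## SteadyCom

Variables are aggregate fluxes `V_jk` (mmol per gDCW of *total* community
biomass per hr) and biomass fractions `X_k`. Species bounds scale with
abundance (`lb_j X_k ≤ V_jk ≤ ub_j X_k`), growth couples as `V_bio,k = μ_k
X_k`, and community exchange bounds are absolute — they represent measured
community-basis rates and are valid at Σ X_k = 1.

*Equal-growth solve.* At fixed μ the program `max Σ X_k` is linear; μ* is
the largest μ at which Σ X_k = 1 is attainable. Because measured rates may
enter as equalities (e.g. net CO₂ uptake fixed at 0.680), μ = 0 can itself
be infeasible — nothing is consumed without growth — so the feasible μ set
is an interior interval. The solver therefore (1) tests μ = 0, falling back
to a geometric+linear seed grid to find any feasible point (error
"constraints inconsistent" if none); (2) brackets and bisects the upper
endpoint (default tolerance 1e-6 hr⁻¹, 60 iterations); (3) polishes by the
fixed-point iteration μ ← μ · Σ X*(μ), exact when the uncapped
abundance optimum scales as c/μ (it does whenever an absolute community
bound is the binding constraint), which resolves μ* — and hence the
abundances — far beyond the bisection tolerance; (4) re-solves at μ* with a
parsimonious secondary objective.

*Fixed-composition solve.* Abundances and per-species growth rates are
prescribed (they may differ — the unequal-growth relaxation that the
dynamic coupling requires), optionally with per-species specific-rate
constraints on the `[u]` transports, scaled by `X_k` internally. A relative
slack ε widens growth coupling and equality-like rate bounds, since kinetic
yields and GEM stoichiometry never agree to machine precision; ε defaults
to 1%. On infeasibility an elastic relaxation of the metabolite balances
(growth coupling stays hard) reports which mass balances cannot close —
e.g. a deliberate 20% yield mismatch is flagged on the carbon species.

*Uniqueness.* The community LP's flux degeneracy is broken by minimizing
total |transport flux| through `[u]` ("parsimonious cross-feeding") at the
fixed optimum. This tie-break is a design choice of this package, not a
property of the formulation; tests assert only tie-break-stable quantities.
Cross-feeding extraction decomposes each shared metabolite's transports
into producer/consumer records (the environment appearing via the community
exchange), splitting producers over consumers proportionally, with the sign
convention: positive = produced by the methanotroph.

## Dynamic FBA

Static-optimization stepping: at each step, dissolved concentrations set
uptake caps via Michaelis–Menten terms (the methanotroph's CH₄ cap is
multiplied by an O₂ Monod factor — a multiplicative dual-substrate closure,
chosen because methane oxidation requires both), a lexicographic LP
sequence per species yields unique exchange fluxes (each attained optimum is
pinned within 1e-9 before the next level; the default priority list is max
biomass, then minimal uptake of each tracked substrate in declared order),
and the reactor advances by explicit Euler (default dt 0.1 hr):
`dX_k/dt = μ_k X_k`, `dS_i/dt = Σ_k ν_ik X_k (+ transfer)`. Negative
concentration crossings clamp to zero, which shuts the uptake cap next step.
The step-halving convergence test bounds the discretization risk of choosing
Euler over a DAE embedding. There is no community compartment: with gas
coupling on, phototroph O₂ and methanotroph CO₂ enter the shared pools
within the step; with it off they are vented — the comparison quantifies
what in-situ gas exchange buys under O₂ limitation.

## Semi-structured kinetics

State: biomass X_C, X_M (gDCW/L), dissolved CH₄/O₂/CO₂ (mmol/L), headspace
partial pressures (bar, ideal gas, inert N₂). Closure:

    μ_M = μmax_M · C_CH4/(K_CH4+C_CH4) · C_O2/(K_O2+C_O2)
    μ_C = μmax_C · C_CO2/(K_CO2+C_CO2) · I/(K_I+I)
    q_CH4 = μ_M/Y_M,  q_O2 = r_O2/CH4 · q_CH4,  q_CO2↑ = r_CO2/CH4 · q_CH4
    q_CO2 = μ_C/Y_C,  q_O2↑ = PQ · q_CO2
    dC_i/dt = kLa_i (H_i p_i − C_i) + Σ_k ν_ik X_k
    dp_i/dt = −kLa_i (H_i p_i − C_i) · V_L R T / V_G

Product-of-Monod limitation is the default; a minimum-law switch exists
because the field uses both and the choice is not decidable from first
principles here. Light is a constant saturation factor (no self-shading).
Refeeds are instantaneous headspace resets (liquid untouched), integrated
piecewise with LSODA (rtol 1e-8, atol 1e-10); trajectory queries are
right-continuous at events. Yields in the bundled scenarios are matched to
the toy stoichiometry (Y_M = 1/40 gDCW/mmol CH₄, r_O2/CH4 = 1.3,
r_CO2/CH4 = 0.3, Y_C = 1/45, PQ = 1), making the closed-system carbon audit
exact: headspace + dissolved + biomass carbon (28 and 45 mmol C/gDCW via the
biomass pseudo-formulas) is conserved to integrator precision.

Default scenario conditions: 60/30/10 CH₄/CO₂/N₂ headspace at 1 bar, 0.4 L
liquid / 0.6 L headspace at 303 K, kLa 6 hr⁻¹ per gas, Henry constants
(mmol·L⁻¹·bar⁻¹) 1.3/1.1/27 for CH₄/O₂/CO₂ (~30 °C values), μmax 0.20 and
0.06 hr⁻¹ for the methanotroph and phototroph — magnitudes typical of
gas-fed methanotroph and *Arthrospira*-type cultures, chosen once for the
fixture, not fitted to any dataset.

*Parameter recovery.* `fit_growth_params` refits (μmax, K) from biomass
observations by multi-start relative least squares (the (μmax, K) surface
has a correlation ridge; multi-start avoids its local minima). The
dedicated identifiability design (`make_recovery_design`: liquid batch, 30
samples over 40 h, initial CH₄ at 10·K so the run traverses the whole
Monod-sensitive range) recovers both parameters within 10% at 2%
multiplicative noise for the suite's frozen seeds. A caveat stated plainly:
with biomass-only data at this noise level, K's sampling variability is of
the same order as that 10% — arbitrary noise realizations can exceed it,
which the acceptance script reports as median and max errors rather than
hiding.

## DynamiCom coupling

At each output time of a kinetic trajectory, the per-species specific rates
(CH₄, O₂, CO₂ by default) and normalized biomass fractions become
constraints of a fixed-composition SteadyCom solve; recorded exchanges form
a time-indexed series, normalizable per CH₄ uptake (dimensionless
mmol/mmol) or per total growth (mmol/gDCW). Contracts held by construction
and enforced by tests: the kinetic trajectory is read-only
(unidirectionality — no feedback from the LP layer); LP growth equals
kinetic growth within ε; output frequency does not change values at shared
times; per-time infeasibilities are recorded in-series (status + missing
value) and only a majority-infeasible run raises.

Two honest limitations of the toy-scale coupling. First, with net O₂
exchange closed *and* kinetic rate equalities, many time points are
legitimately infeasible: dissolved O₂ and gas transfer buffer the two
species' instantaneous rates, so strict in-situ balance holds only where
the trajectory happens to balance — the closed-O₂ audit therefore asserts
producer=consumer equality at the feasible times. Second, the toy
stoichiometry cannot reproduce a time-resolved nitrate→ammonium switch: at
tight ε the methanotroph can never afford its nitrate route (it costs extra
CH₄ the rate equality forbids), and at loose ε the parsimonious tie-break
prefers the nitrate route outright; what the toy does reproduce robustly is
the emergent ammonium cross-feed itself (negative-signed series, majority
N-route) and its growth-optimality (blocking it lowers μ*).

## The synthetic community

The toy pair stands in for a curated methanotroph/phototroph GEM pair at
minimal scale: methanotroph biomass `40 CH₄ + 52 O₂ + 8 N → biomass +
12 CO₂` with ammonium (free) and nitrate (costing 0.25 CH₄ + 0.5 O₂ per N)
assimilation routes, a respiration/ATP cycle for maintenance; phototroph
biomass `45 CO₂ + 400 photon + 6 NH₄ → biomass + 45 O₂` with photon-driven
nitrate reduction and photophosphorylation. Coefficients are frozen
integers chosen so the headline optima are exact rationals (μ* =
0.680·97/1800, composition 45:52, forced-nitrate μ = 0.680·101/1980),
hand-checkable and asserted at 1e-6 relative. Photon and the fixed-N
bookkeeping species are declared massless; the nitrate route's 0.25 CH₄ is
lumped oxidation bookkeeping exempted from the per-reaction carbon audit.
What passing these tests shows: the LP formulations, the couplings and the
conservation/uniqueness machinery are correct. What it does not show:
anything about real organisms' metabolite-level predictions — genome-scale
models bring alternate optima at far larger scale, thermodynamically
infeasible loops, and curation noise the toy does not emulate; the toolkit
loads such models from SBML but makes no claims for them.

## Degenerate inputs and edge behavior

Empty exchange whitelists yield disconnected species (zero growth is then
the only community solution); a whitelisted metabolite absent from every
species warns and is skipped; zero total biomass is an error for the
coupling layer while single-species extinction (X_k = 0) forces that
species' fluxes to zero smoothly; zero normalization denominators produce
missing values, not exceptions; infeasible LPs return status objects (with
elastic diagnoses where informative) rather than raising, except where a
whole run is meaningless.
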