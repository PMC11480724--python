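"""Dynamic FBA: Michaelis-Menten uptake caps, lexicographic LP, reactor loop.

Each species is an independent stoichiometric model (no shared community
compartment). At every step the dissolved substrate concentrations set
uptake caps through Michaelis-Menten terms (optionally multiplied by
co-substrate Monod factors, e.g. the methanotroph's CH4 uptake also requires
O2), a lexicographic sequence of LPs yields unique exchange fluxes, and the
bioreactor state is advanced by explicit Euler stepping:

    dX_k/dt = mu_k X_k        dS_i/dt = sum_k v_ik X_k (+ gas transfer)

Interspecies coupling is purely environmental: with ``couple_gases`` on, O2
excreted by the phototroph and CO2 excreted by the methanotroph enter the
shared liquid pools within the same step; with it off those products are
vented and each species only sees externally supplied gas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lp import OPTIMAL
from .model import FluxSolution, StoichModel, fba


def mm_uptake(s: float, vmax: float, km: float) -> float:
    """Michaelis-Menten specific uptake rate vmax*S/(Km+S)."""
    if s < 0:
        raise ValueError("substrate concentration must be non-negative")
    if vmax < 0 or km <= 0:
        raise ValueError("vmax must be >= 0 and Km > 0")
    return vmax * s / (km + s)


@dataclass
class MMTerm:
    vmax: float  # mmol/gDCW/hr
    km: float  # mmol/L
    #: co-substrate -> half-saturation constant; each multiplies the cap
    modifiers: dict[str, float] = field(default_factory=dict)

    def cap(self, conc: dict[str, float], substrate: str) -> float:
        v = mm_uptake(max(conc.get(substrate, 0.0), 0.0), self.vmax, self.km)
        for co, km in self.modifiers.items():
            s = max(conc.get(co, 0.0), 0.0)
            v *= s / (km + s)
        return v


@dataclass
class UptakeKinetics:
    """Per species and substrate Michaelis-Menten uptake parameters."""

    terms: dict[str, dict[str, MMTerm]]  # species -> substrate -> term

    @classmethod
    def from_dict(cls, doc: dict) -> "UptakeKinetics":
        terms = {
            sp: {
                sub: MMTerm(d["vmax"], d["km"], dict(d.get("modifiers", {})))
                for sub, d in subs.items()
            }
            for sp, subs in doc.items()
        }
        return cls(terms)


@dataclass
class LexicographicProgram:
    """Ordered (reaction id, sense) objectives; the first must be biomass."""

    objectives: list[tuple[str, str]]

    def __post_init__(self):
        if not self.objectives:
            raise ValueError("lexicographic program must be non-empty")
        rids = [r for r, _ in self.objectives]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reactions in lexicographic program")
        for _, sense in self.objectives:
            if sense not in ("max", "min"):
                raise ValueError(f"objective sense must be max/min, got {sense!r}")

    @classmethod
    def default(cls, model: StoichModel, substrates: list[str], products: list[str] = ()):
        """[max biomass, min each substrate uptake, max each product excretion].

        Substrate/product names refer to exchange reactions ``EX_<name>``;
        "min uptake" is expressed as maximizing the signed exchange flux
        (uptake is negative).
        """
        objs = [(model.biomass_id, "max")]
        objs += [(f"EX_{s}", "max") for s in substrates if f"EX_{s}" in model.reaction_ids]
        objs += [(f"EX_{p}", "max") for p in products if f"EX_{p}" in model.reaction_ids]
        return cls(objs)


#: absolute window used to fix each attained optimum before the next level
LEX_FIX_TOL = 1e-9


def lexicographic_fba(
    model: StoichModel,
    program: LexicographicProgram,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Solve the objectives in order, pinning each optimum as a constraint.

    The fluxes of programmed reactions are unique (up to LEX_FIX_TOL) no
    matter how the solver breaks ties elsewhere. Infeasibility at any level
    is reported with the level's reaction named.
    """
    bounds = dict(extra_bounds or {})
    sol = None
    for level, (rid, sense) in enumerate(program.objectives):
        sol = fba(model, objective=rid, extra_bounds=bounds, sense=sense)
        if sol.status != OPTIMAL:
            return FluxSolution(
                status=sol.status,
                message=f"lexicographic level {level} ({rid}, {sense}): {sol.status}",
            )
        opt = sol.objective_value
        bounds[rid] = (opt - LEX_FIX_TOL, opt + LEX_FIX_TOL)
    # re-report the first objective's value as the headline objective
    first = program.objectives[0][0]
    return FluxSolution(
        status=OPTIMAL, objective_value=sol.fluxes[first], fluxes=sol.fluxes
    )


@dataclass
class ReactorTrajectory:
    times: np.ndarray
    biomass: pd.DataFrame  # columns per species, gDCW/L
    concentrations: pd.DataFrame  # columns per substrate, mmol/L
    growth_rates: pd.DataFrame  # per species, 1/hr
    exchange_fluxes: pd.DataFrame  # columns (species, substrate), mmol/gDCW/hr
    status: str = "ok"
    message: str = ""

    def final_biomass(self, species: str | None = None) -> float:
        if species is None:
            return float(self.biomass.iloc[-1].sum())
        return float(self.biomass[species].iloc[-1])


@dataclass
class GasTransfer:
    """First-order transfer toward a saturation concentration (reservoir)."""

    kla: float  # 1/hr
    c_sat: float  # mmol/L


def dfba_simulate(
    models: dict[str, StoichModel],
    kinetics: UptakeKinetics,
    init_biomass: dict[str, float],
    init_conc: dict[str, float],
    dt: float = 0.1,
    t_end: float = 48.0,
    programs: dict[str, LexicographicProgram] | None = None,
    couple_gases: bool = True,
    transfer: dict[str, GasTransfer] | None = None,
    exchange_id=lambda substrate: f"EX_{substrate}",
) -> ReactorTrajectory:
    """Static-optimization dynamic FBA over a shared liquid phase.

    ``models`` maps species label to its stoichiometric model;
    ``init_conc`` declares the tracked substrates. Products of tracked
    substrates accumulate in the pool (subject to ``couple_gases``; O2
    produced by a phototroph and CO2 produced by a methanotroph are the
    coupled gases). A negative-concentration crossing is clamped to zero,
    which shuts the corresponding uptake cap off at the next step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, x in init_biomass.items():
        if x < 0:
            raise ValueError(f"negative initial biomass for {name}")
    if any(v < 0 for v in init_conc.values()):
        raise ValueError("negative initial concentration")
    programs = programs or {}
    transfer = transfer or {}
    species = list(models)
    substrates = list(init_conc)

    times = [0.0]
    X = {k: [init_biomass.get(k, 0.0)] for k in species}
    S = {s: [init_conc[s]] for s in substrates}
    mu_hist = {k: [] for k in species}
    flux_hist: dict[tuple[str, str], list[float]] = {
        (k, s): [] for k in species for s in substrates
    }
    status, message = "ok", ""

    n_steps = int(round(t_end / dt))
    for _step in range(n_steps):
        conc = {s: S[s][-1] for s in substrates}
        sols: dict[str, FluxSolution] = {}
        failed = None
        for k in species:
            model = models[k]
            bounds: dict[str, tuple[float, float]] = {}
            for sub, term in kinetics.terms.get(k, {}).items():
                rid = exchange_id(sub)
                if rid in model.reaction_ids:
                    cap = term.cap(conc, sub)
                    r = model.reaction(rid)
                    bounds[rid] = (max(r.lb, -cap), r.ub)
            program = programs.get(k) or LexicographicProgram.default(model, substrates)
            sol = lexicographic_fba(model, program, extra_bounds=bounds)
            if sol.status != OPTIMAL:
                failed = f"species {k} at t={times[-1]:.3f}: {sol.message or sol.status}"
                break
            sols[k] = sol
        if failed is not None:  # terminate with the partial trajectory
            status, message = "infeasible", failed
            break
        dS = {s: 0.0 for s in substrates}
        for k in species:
            model = models[k]
            mu = sols[k].fluxes[model.biomass_id]
            for s in substrates:
                v = sols[k].fluxes.get(exchange_id(s), 0.0)
                pooled = 0.0 if (not couple_gases and v > 0 and _is_coupled_gas(s)) else v
                dS[s] += pooled * X[k][-1]
                flux_hist[(k, s)].append(v)
            X[k].append(X[k][-1] * (1.0 + dt * mu))
            mu_hist[k].append(mu)
        for s, tr in transfer.items():
            dS[s] += tr.kla * (tr.c_sat - conc[s])
        for s in substrates:
            S[s].append(max(0.0, conc[s] + dt * dS[s]))
        times.append(times[-1] + dt)

    n = len(times)
    biomass = pd.DataFrame({k: X[k][:n] for k in species}, index=times)
    conc_df = pd.DataFrame({s: S[s][:n] for s in substrates}, index=times)
    mu_df = pd.DataFrame({k: mu_hist[k] for k in species}, index=times[1:])
    flux_df = (
        pd.DataFrame({key: vals for key, vals in flux_hist.items()}, index=times[1:])
        if n > 1
        else pd.DataFrame()
    )
    return ReactorTrajectory(
        times=np.array(times),
        biomass=biomass,
        concentrations=conc_df,
        growth_rates=mu_df,
        exchange_fluxes=flux_df,
        status=status,
        message=message,
    )


def _is_coupled_gas(substrate: str) -> bool:
    return substrate in ("o2", "co2")
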