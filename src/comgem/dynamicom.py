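"""Kinetically constrained community FBA over time (DynamiCom).

A validated kinetic trajectory fully determines the reactor dynamics; at
each output time its per-species specific rates and biomass fractions are
converted into constraints for a fixed-composition community solve, and the
predicted interspecies exchange fluxes are recorded. The coupling is
strictly unidirectional: nothing computed here feeds back into the kinetic
trajectory, which is treated as read-only, so the constraint times can be
chosen at any frequency without changing the values at shared times.

Sign convention for the recorded series: positive = produced by the
methanotroph, negative = produced by the phototroph (community-basis fluxes,
mmol per gDCW of total biomass per hr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityModel
from .kinetics import KineticRates, KineticTrajectory
from .steadycom import SteadyComSolution, solve_fixed_composition

#: gases whose kinetic rates constrain the community LP by default
DEFAULT_CONSTRAINED = ("ch4", "o2", "co2")


def constraints_from_rates(
    rates: KineticRates,
    biomass: dict[str, float],
    eps: float = 0.01,
    constrain: tuple[str, ...] = DEFAULT_CONSTRAINED,
) -> dict:
    """Translate kinetic outputs into fixed-composition solve arguments.

    ``biomass`` holds the kinetic biomass of each species (gDCW/L); it is
    normalized to abundance fractions. Each constrained specific rate q
    becomes the transport bound pair (q, q) — an equality that the solver
    widens by the relative slack ``eps`` to absorb small kinetic/GEM yield
    mismatch. Growth rates are passed through and receive the same slack.
    """
    total = sum(biomass.values())
    if total <= 0:
        raise ValueError("zero total biomass")
    abundances = {k: x / total for k, x in biomass.items()}
    growth = {}
    rate_bounds: dict[tuple[str, str], tuple[float, float]] = {}
    for k, per in rates.per_species.items():
        growth[k] = max(per.get("growth", 0.0), 0.0)
        for met in constrain:
            if met in per:
                q = per[met]
                rate_bounds[(k, met)] = (q, q)
    return {
        "abundances": abundances,
        "growth_rates": growth,
        "rate_constraints": rate_bounds,
        "eps": eps,
    }


@dataclass
class ExchangeSeries:
    """Time-indexed signed cross-feeding fluxes per shared metabolite."""

    times: np.ndarray
    #: metabolite -> signed community-basis flux per time (NaN when infeasible)
    values: pd.DataFrame
    #: per-time solver status
    status: list[str]
    #: (species, metabolite) -> transport flux per time (+ export to [u])
    transport: dict[tuple[str, str], np.ndarray]
    #: |community CH4 uptake| per time (normalization denominator)
    ch4_uptake: np.ndarray
    #: total community growth rate per time (1/hr)
    total_growth: np.ndarray
    #: species -> LP-realized specific growth rate per time (1/hr)
    lp_growth: dict[str, np.ndarray] = field(default_factory=dict)
    normalization: str = "raw"  # raw | per_CH4 | per_growth
    positive_species: str = ""

    @property
    def feasible_fraction(self) -> float:
        return float(np.mean([s == "optimal" for s in self.status]))

    def to_frame(self) -> pd.DataFrame:
        long = self.values.reset_index().melt(
            id_vars="index", var_name="metabolite", value_name="signed_flux"
        )
        long = long.rename(columns={"index": "time"})
        long["normalization"] = self.normalization
        status_map = dict(zip(self.times, self.status))
        long["status"] = long["time"].map(status_map)
        return long


def run_dynamicom(
    trajectory: KineticTrajectory,
    community: CommunityModel,
    exchange_bounds: dict[str, tuple[float, float]] | None = None,
    eps: float = 0.01,
    times: np.ndarray | None = None,
    constrain: tuple[str, ...] = DEFAULT_CONSTRAINED,
    max_infeasible_fraction: float = 0.5,
) -> ExchangeSeries:
    """Fixed-composition community solves along a kinetic trajectory.

    Per-time infeasibilities are recorded in the series (status + NaN row),
    not raised; only when more than ``max_infeasible_fraction`` of the times
    fail does the run itself error out. The kinetic trajectory is never
    modified.
    """
    params = trajectory.params
    label = {params.species_M: "X_M", params.species_C: "X_C"}
    missing = [k for k in label if k not in community.members]
    if missing:
        raise ValueError(
            f"kinetic species {missing} not among community members {community.members}"
        )
    if times is None:
        times = np.asarray(trajectory.times)
        # drop duplicated event samples; keep the post-event one
        keep = np.append(np.diff(times) > 0, True)
        times = times[keep]
    mets = sorted(community.exchanges)
    n = len(times)
    data = {m: np.full(n, np.nan) for m in mets}
    transport = {
        (k, m): np.full(n, np.nan) for (k, m) in community.transports
    }
    status: list[str] = []
    ch4_up = np.full(n, np.nan)
    growth_tot = np.full(n, np.nan)
    lp_growth = {k: np.full(n, np.nan) for k in label}
    pos = params.species_M

    for i, t in enumerate(times):
        state = trajectory.state_at(float(t))
        rates = trajectory.rates_at(float(t))
        biomass = {params.species_M: state.X_M, params.species_C: state.X_C}
        if sum(biomass.values()) <= 0:
            status.append("no_biomass")
            continue
        kwargs = constraints_from_rates(rates, biomass, eps=eps, constrain=constrain)
        sol = solve_fixed_composition(
            community,
            kwargs["abundances"],
            kwargs["growth_rates"],
            rate_constraints=kwargs["rate_constraints"],
            eps=kwargs["eps"],
            exchange_bounds=exchange_bounds,
        )
        status.append(sol.status)
        if not sol.ok:
            continue
        for m in mets:
            data[m][i] = _signed_flux(sol, m, pos)
        for key in transport:
            transport[key][i] = sol.transport[key[0]].get(key[1], 0.0)
        ch4_up[i] = abs(min(sol.exchange.get("ch4", 0.0), 0.0))
        growth_tot[i] = sum(
            kwargs["growth_rates"][k] * kwargs["abundances"][k] for k in kwargs["growth_rates"]
        )
        for k in lp_growth:
            x_k = kwargs["abundances"][k]
            if x_k > 0:
                lp_growth[k][i] = sol.fluxes[community.biomass_ids[k]] / x_k

    frac_bad = np.mean([s != "optimal" for s in status]) if status else 1.0
    if frac_bad > max_infeasible_fraction:
        raise RuntimeError(
            f"{frac_bad:.0%} of time points infeasible; kinetic rates and community "
            "stoichiometry disagree beyond eps"
        )
    return ExchangeSeries(
        times=np.asarray(times, dtype=float),
        values=pd.DataFrame(data, index=np.asarray(times, dtype=float)),
        status=status,
        transport=transport,
        ch4_uptake=ch4_up,
        total_growth=growth_tot,
        lp_growth=lp_growth,
        normalization="raw",
        positive_species=pos,
    )


def _signed_flux(sol: SteadyComSolution, met: str, positive_species: str) -> float:
    """Community-basis signed flux: the positive species' net export to [u];
    for metabolites it does not touch, minus the partner's net export."""
    if met in sol.transport.get(positive_species, {}):
        return sol.transport[positive_species][met]
    others = [d.get(met) for k, d in sol.transport.items() if k != positive_species and met in d]
    return -others[0] if others else 0.0


def normalize_series(series: ExchangeSeries, mode: str) -> ExchangeSeries:
    """Normalize fluxes by CH4 uptake (per_CH4) or total growth (per_growth).

    Times with a zero denominator get missing values rather than raising.
    """
    if series.normalization != "raw":
        raise ValueError("normalize_series expects a raw series")
    if mode == "per_CH4":
        denom = series.ch4_uptake.copy()
    elif mode == "per_growth":
        denom = series.total_growth.copy()
    else:
        raise ValueError("mode must be per_CH4 or per_growth")
    denom[~np.isfinite(denom)] = np.nan
    denom[denom <= 0] = np.nan
    values = series.values.div(pd.Series(denom, index=series.values.index), axis=0)
    return ExchangeSeries(
        times=series.times,
        values=values,
        status=list(series.status),
        transport=dict(series.transport),
        ch4_uptake=series.ch4_uptake,
        total_growth=series.total_growth,
        lp_growth=dict(series.lp_growth),
        normalization=mode,
        positive_species=series.positive_species,
    )
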