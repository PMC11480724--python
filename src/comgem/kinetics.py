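"""Semi-structured kinetic model of the methanotroph-phototroph coculture.

Monod growth on liquid-phase substrates, yield-linked gas uptake/excretion,
two-film gas-liquid mass transfer with Henry equilibrium, an ideal-gas
headspace mole balance, and explicit O2/CO2 cross-feeding through the shared
liquid phase. Refeed events reset the headspace composition instantaneously
(liquid unchanged). The model is "semi-structured" in that the only
intracellular detail it carries is the stoichiometric linkage between growth
and gas exchange; everything else is lumped into Monod terms.

State (``ReactorState``): biomass X_C, X_M (gDCW/L); dissolved CH4, O2, CO2
(mmol/L); headspace partial pressures (bar). Specific rates are reported
with uptake negative and excretion positive (mmol/gDCW/hr).

Growth laws::

    mu_M = mu_max_M * f(C_CH4; K_ch4) (*|min) f(C_O2; K_o2)
    mu_C = mu_max_C * f(C_CO2; K_co2) * I/(K_I + I)

with f(S; K) = S/(K+S); product-of-Monod limitation is the default, a
minimum-law switch is available. Uptakes follow from yields: q_CH4 = mu_M /
Y_M, q_O2 = r_O2/CH4 * q_CH4, q_CO2(excreted) = r_CO2/CH4 * q_CH4 for the
methanotroph; q_CO2 = mu_C / Y_C and q_O2(excreted) = PQ * q_CO2 for the
phototroph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

#: gas constant, L*bar/(mmol*K)
R_GAS = 0.0831446 / 1000.0

GASES = ("ch4", "o2", "co2")


@dataclass
class KineticParams:
    mu_max_M: float
    K_ch4: float
    K_o2: float
    mu_max_C: float
    K_co2: float
    light: float
    K_light: float
    Y_M: float  # gDCW per mmol CH4
    Y_C: float  # gDCW per mmol CO2
    r_o2_ch4: float  # mol O2 consumed per mol CH4 (methanotroph)
    r_co2_ch4: float  # mol CO2 excreted per mol CH4 (methanotroph)
    pq: float  # photosynthetic quotient, mol O2 per mol CO2
    kla: dict[str, float]  # 1/hr per gas
    henry: dict[str, float]  # mmol/L/bar per gas
    V_L: float  # L
    V_G: float  # L
    temperature: float  # K
    limitation: str = "product"  # or "minimum"
    species_M: str = "M1"
    species_C: str = "C1"

    def __post_init__(self):
        for name in ("mu_max_M", "K_ch4", "K_o2", "mu_max_C", "K_co2", "light", "K_light"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Y_M <= 0 or self.Y_C <= 0 or self.pq <= 0:
            raise ValueError("yields and PQ must be positive")
        if self.limitation not in ("product", "minimum"):
            raise ValueError("limitation must be 'product' or 'minimum'")

    @property
    def biomass_carbon_M(self) -> float:
        """mmol C per gDCW of methanotroph biomass implied by the yields."""
        return (1.0 - self.r_co2_ch4) / self.Y_M

    @property
    def biomass_carbon_C(self) -> float:
        return 1.0 / self.Y_C

    @classmethod
    def from_dict(cls, doc: dict) -> "KineticParams":
        return cls(**doc)


@dataclass
class ReactorState:
    t: float
    X_C: float
    X_M: float
    c: dict[str, float]  # dissolved, mmol/L
    p: dict[str, float]  # partial pressures, bar (includes inert n2)

    def validate(self):
        if self.X_C < 0 or self.X_M < 0:
            raise ValueError("negative biomass")
        if any(v < -1e-9 for v in self.c.values()) or any(v < -1e-9 for v in self.p.values()):
            raise ValueError("negative concentration or pressure")


@dataclass
class KineticRates:
    """Specific rates per species at one time point (uptake < 0)."""

    t: float
    #: species label -> {"growth": 1/hr, gas: mmol/gDCW/hr signed}
    per_species: dict[str, dict[str, float]]


_STATE_FIELDS = ("X_C", "X_M", "c_ch4", "c_o2", "c_co2", "p_ch4", "p_o2", "p_co2")


def _pack(state: ReactorState) -> np.ndarray:
    return np.array(
        [
            state.X_C,
            state.X_M,
            state.c["ch4"],
            state.c["o2"],
            state.c["co2"],
            state.p["ch4"],
            state.p["o2"],
            state.p["co2"],
        ]
    )


def _unpack(t: float, y: np.ndarray, p_n2: float) -> ReactorState:
    y = np.maximum(y, 0.0)
    return ReactorState(
        t=t,
        X_C=y[0],
        X_M=y[1],
        c={"ch4": y[2], "o2": y[3], "co2": y[4]},
        p={"ch4": y[5], "o2": y[6], "co2": y[7], "n2": p_n2},
    )


def _monod(s: float, k: float) -> float:
    s = max(s, 0.0)
    return s / (k + s) if (k + s) > 0 else 0.0


def species_rates(state: ReactorState, params: KineticParams) -> KineticRates:
    """Specific growth/uptake/excretion rates at a state (pure function)."""
    f_ch4 = _monod(state.c["ch4"], params.K_ch4)
    f_o2 = _monod(state.c["o2"], params.K_o2)
    if params.limitation == "product":
        mu_M = params.mu_max_M * f_ch4 * f_o2
    else:
        mu_M = params.mu_max_M * min(f_ch4, f_o2)
    q_ch4 = mu_M / params.Y_M
    mu_C = (
        params.mu_max_C
        * _monod(state.c["co2"], params.K_co2)
        * _monod(params.light, params.K_light)
    )
    q_co2_C = mu_C / params.Y_C
    return KineticRates(
        t=state.t,
        per_species={
            params.species_M: {
                "growth": mu_M,
                "ch4": -q_ch4,
                "o2": -params.r_o2_ch4 * q_ch4,
                "co2": params.r_co2_ch4 * q_ch4,
            },
            params.species_C: {
                "growth": mu_C,
                "co2": -q_co2_C,
                "o2": params.pq * q_co2_C,
            },
        },
    )


def kinetic_rhs(state: ReactorState, params: KineticParams) -> dict[str, float]:
    """Time derivatives of every state field (per hr)."""
    rates = species_rates(state, params)
    rM = rates.per_species[params.species_M]
    rC = rates.per_species[params.species_C]
    out = {
        "X_C": rC["growth"] * state.X_C,
        "X_M": rM["growth"] * state.X_M,
    }
    gas_to_liquid_factor = params.V_L * R_GAS * params.temperature / params.V_G
    for gas in GASES:
        transfer = params.kla[gas] * (params.henry[gas] * state.p[gas] - state.c[gas])
        bio = rM.get(gas, 0.0) * state.X_M + rC.get(gas, 0.0) * state.X_C
        out[f"c_{gas}"] = transfer + bio
        # headspace: moles leaving the gas phase = moles entering the liquid
        out[f"p_{gas}"] = -transfer * gas_to_liquid_factor
    return out


@dataclass
class KineticTrajectory:
    times: np.ndarray
    states: list[ReactorState]
    rates: list[KineticRates]
    params: KineticParams
    #: times at which refeed events fired (grid points are right-continuous there)
    event_times: tuple[float, ...] = ()

    def state_at(self, t: float) -> ReactorState:
        i = self._bracket(t)
        if self.times[i] == t:
            return self.states[i]
        j = i + 1
        w = (t - self.times[i]) / (self.times[j] - self.times[i])
        a, b = self.states[i], self.states[j]
        return ReactorState(
            t=t,
            X_C=(1 - w) * a.X_C + w * b.X_C,
            X_M=(1 - w) * a.X_M + w * b.X_M,
            c={g: (1 - w) * a.c[g] + w * b.c[g] for g in a.c},
            p={g: (1 - w) * a.p[g] + w * b.p[g] for g in a.p},
        )

    def rates_at(self, t: float) -> KineticRates:
        """Linearly interpolated specific rates (right-continuous at events)."""
        i = self._bracket(t)
        if self.times[i] == t:
            return self.rates[i]
        j = i + 1
        w = (t - self.times[i]) / (self.times[j] - self.times[i])
        a, b = self.rates[i], self.rates[j]
        per = {}
        for k in a.per_species:
            per[k] = {
                key: (1 - w) * a.per_species[k].get(key, 0.0) + w * b.per_species[k].get(key, 0.0)
                for key in set(a.per_species[k]) | set(b.per_species[k])
            }
        return KineticRates(t=t, per_species=per)

    def _bracket(self, t: float) -> int:
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(f"t={t} outside trajectory range")
        # right-continuous convention: at a duplicated event time take the
        # post-event sample (the later index with equal time)
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return max(0, min(i, len(self.times) - 1))

    def carbon_total(self, state: ReactorState) -> float:
        """Total carbon (mmol) in headspace + liquid + biomass at a state."""
        p = self.params
        n_gas = lambda gas: state.p[gas] * p.V_G / (R_GAS * p.temperature)
        return (
            n_gas("ch4")
            + n_gas("co2")
            + (state.c["ch4"] + state.c["co2"]) * p.V_L
            + (p.biomass_carbon_M * state.X_M + p.biomass_carbon_C * state.X_C) * p.V_L
        )


def simulate_kinetics(
    params: KineticParams,
    init: ReactorState,
    t_grid: np.ndarray,
    refeeds: list[tuple[float, dict[str, float]]] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> KineticTrajectory:
    """Integrate the reactor ODEs over ``t_grid`` with refeed events.

    ``refeeds`` is a list of (time, new headspace partial pressures); each
    event discontinuously resets the listed pressures (liquid untouched).
    Event times are inserted into the output grid twice (pre and post state)
    so interpolation stays exact on both sides.
    """
    init.validate()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    refeeds = sorted(refeeds or [], key=lambda e: e[0])
    for tev, _ in refeeds:
        if not (t_grid[0] < tev < t_grid[-1]):
            raise ValueError(f"refeed time {tev} outside the simulation range")

    p_n2 = init.p.get("n2", 0.0)

    def rhs(t, y):
        d = kinetic_rhs(_unpack(t, y, p_n2), params)
        return np.array([d[f] for f in _STATE_FIELDS])

    times: list[float] = []
    states: list[ReactorState] = []
    y = _pack(init)
    breakpoints = [t_grid[0]] + [tev for tev, _ in refeeds] + [t_grid[-1]]
    event_times = tuple(tev for tev, _ in refeeds)
    for seg_idx in range(len(breakpoints) - 1):
        a, b = breakpoints[seg_idx], breakpoints[seg_idx + 1]
        t_eval = t_grid[(t_grid >= a) & (t_grid <= b)]
        if len(t_eval) == 0 or t_eval[0] > a:
            t_eval = np.insert(t_eval, 0, a)
        if t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else a}: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            times.append(float(tt))
            states.append(_unpack(float(tt), yy, p_n2))
        y = sol.y[:, -1].copy()
        if seg_idx < len(breakpoints) - 2:  # apply the refeed, duplicate the grid point
            _, reset = refeeds[seg_idx]
            post = _unpack(b, y, reset.get("n2", p_n2))
            for gas, pressure in reset.items():
                if gas == "n2":
                    p_n2 = pressure
                else:
                    post.p[gas] = pressure
            y = _pack(post)
            times.append(float(b))
            states.append(post)

    times_arr = np.array(times)
    rates = [species_rates(s, params) for s in states]
    return KineticTrajectory(
        times=times_arr, states=states, rates=rates, params=params, event_times=event_times
    )


def rates_at(trajectory: KineticTrajectory, t: float) -> KineticRates:
    return trajectory.rates_at(t)


# ---------------------------------------------------------------------------
# scenario plumbing and parameter fitting
# ---------------------------------------------------------------------------

def scenario_params(scenario: dict) -> KineticParams:
    return KineticParams.from_dict(scenario["params"])


def scenario_init(scenario: dict) -> ReactorState:
    init = scenario["init"]
    return ReactorState(t=0.0, X_C=init["X_C"], X_M=init["X_M"], c=dict(init["c"]), p=dict(init["p"]))


def run_scenario(scenario: dict, t_grid: np.ndarray | None = None) -> KineticTrajectory:
    params = scenario_params(scenario)
    if t_grid is None:
        t_grid = np.arange(0.0, scenario["t_end"] + 1e-9, scenario.get("output_interval", 1.0))
    refeeds = [(e["time"], dict(e["p"])) for e in scenario.get("refeeds", [])]
    return simulate_kinetics(params, scenario_init(scenario), t_grid, refeeds)


def fit_growth_params(
    t_obs: np.ndarray,
    x_obs: np.ndarray,
    scenario: dict,
    which: str = "M",
    x0: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares recovery of (mu_max, K_substrate) from biomass data.

    Refits the named species' maximum growth rate and primary-substrate
    half-saturation constant by simulating the scenario and minimizing
    relative residuals against observed biomass. Used to check parameter
    identifiability of the kinetic closure.
    """
    from scipy.optimize import least_squares

    base = dict(scenario["params"])
    mu_key = f"mu_max_{which}"
    k_key = "K_ch4" if which == "M" else "K_co2"

    def residuals(theta):
        p = dict(base)
        p[mu_key], p[k_key] = abs(theta[0]), abs(theta[1])
        sc = dict(scenario)
        sc["params"] = p
        traj = run_scenario(sc, t_grid=np.asarray(t_obs))
        sim = np.array(
            [traj.state_at(t).X_M if which == "M" else traj.state_at(t).X_C for t in t_obs]
        )
        return (sim - x_obs) / np.maximum(x_obs, 1e-12)

    if x0 is not None:
        starts = [x0]
    else:
        # the (mu_max, K) surface has a correlation ridge; a small multistart
        # avoids settling into its local minima
        mu0, k0 = base[mu_key], base[k_key]
        starts = [(mu0 * a, k0 * b) for a in (0.6, 1.5) for b in (0.3, 1.0, 3.0)]
    best = None
    for start in starts:
        fit = least_squares(residuals, x0=start, method="lm")
        if best is None or fit.cost < best.cost:
            best = fit
    return abs(best.x[0]), abs(best.x[1])
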