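"""Steady-state community FBA with abundance-scaled bounds (SteadyCom).

The community LP treats the aggregate flux V_jk of reaction j in species k
(mmol per gDCW of *total* community biomass per hr) and the biomass fraction
X_k of each species as variables. Species-level bounds scale with abundance
(lb_j X_k <= V_jk <= ub_j X_k), growth is coupled through V_bio,k = mu_k X_k,
and community exchange reactions carry absolute bounds (measured rates per
gDCW of total biomass, valid at sum(X) = 1).

Two solve modes are provided:

* :func:`solve_steadycom` — the equal-growth formulation: find the largest
  community growth rate mu at which total abundance 1 is feasible, by
  bisection on the feasibility of the abundance-maximization LP followed by
  a fixed-point refinement mu <- mu * sum(X*(mu)).
* :func:`solve_fixed_composition` — abundances and per-species growth rates
  are given (they may differ between species), optionally with per-species
  specific-rate constraints; a parsimonious secondary objective (minimal
  total transport flux through [u]) picks a unique exchange pattern among
  alternate optima.

Because measured community rates may enter as equality bounds, zero growth
can itself be infeasible (nothing is consumed at mu = 0); the feasible mu
set is then an interior interval and the solver searches a seeded mu grid
for a feasible starting point before bracketing the upper endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._lp import INFEASIBLE, OPTIMAL, solve_lp
from .community import CommunityModel
from .model import ModelError

#: fluxes below this magnitude are treated as zero when reporting exchanges
FLUX_EPS = 1e-9


class ConstraintsInconsistentError(ModelError):
    """No community growth rate satisfies the imposed constraints."""


@dataclass
class SteadyComSolution:
    status: str
    mu: float | None = None
    #: per-species biomass fraction (gDCW_k per gDCW_community)
    abundances: dict[str, float] = field(default_factory=dict)
    #: per-species growth rates (equal to mu in the equal-growth mode)
    growth_rates: dict[str, float] = field(default_factory=dict)
    #: aggregate fluxes V_jk, mmol/gDCW_community/hr
    fluxes: dict[str, float] = field(default_factory=dict)
    #: community exchange flux per [u] metabolite (+ secretion, - uptake)
    exchange: dict[str, float] = field(default_factory=dict)
    #: species -> met -> transport flux into [u] (+ export, - uptake)
    transport: dict[str, dict[str, float]] = field(default_factory=dict)
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class CrossFeedingRecord:
    metabolite: str
    producer: str  # species prefix or "environment"
    consumer: str  # species prefix or "environment"
    flux: float  # magnitude, mmol/gDCW_community/hr
    signed: float  # + when produced by the designated positive species


class _CommunityLP:
    """Index bookkeeping and row assembly for the community LP."""

    def __init__(self, community: CommunityModel):
        self.community = community
        self.rids = community.reaction_ids
        self.ridx = {r: j for j, r in enumerate(self.rids)}
        self.species = community.members
        self.kidx = {k: len(self.rids) + i for i, k in enumerate(self.species)}
        self.n = len(self.rids) + len(self.species)
        self.S = community.stoichiometric_matrix()

    def assemble(
        self,
        growth_rates: dict[str, float],
        exchange_bounds: dict[str, tuple[float, float]] | None = None,
        rate_bounds: dict[tuple[str, str], tuple[float, float]] | None = None,
        fixed_X: dict[str, float] | None = None,
        eps: float = 0.0,
        cap: float = 1.0,
    ):
        """Build (A_eq, b_eq, A_ub, b_ub, bounds) for the LP at given growth rates.

        ``eps`` is a relative slack applied to the growth coupling and to any
        equality-like rate bounds. ``rate_bounds`` are per-species specific
        rates (mmol/gDCW_k/hr) on transport reactions, scaled by X_k inside
        the LP.
        """
        com = self.community
        exchange_bounds = exchange_bounds or {}
        rate_bounds = rate_bounds or {}
        eq_rows, eq_b = [], []
        ub_rows, ub_b = [], []

        # steady state of every metabolite (species compartments and [u])
        m = self.S.shape[0]
        eq = sp.hstack([self.S, sp.csr_matrix((m, len(self.species)))], format="csr")
        eq_rows.append(eq)
        eq_b.append(np.zeros(m))
        self._eq_row_names = list(com.metabolite_ids)

        def _row(pairs):
            cols = np.array([c for c, _ in pairs])
            vals = np.array([v for _, v in pairs])
            return sp.csr_matrix((vals, (np.zeros(len(pairs), dtype=int), cols)), shape=(1, self.n))

        # growth coupling V_bio,k = mu_k X_k (with optional relative slack)
        for k in self.species:
            j = self.ridx[com.biomass_ids[k]]
            xk = self.kidx[k]
            mu_k = growth_rates[k]
            if eps == 0.0:
                eq_rows.append(_row([(j, 1.0), (xk, -mu_k)]))
                eq_b.append(np.zeros(1))
                self._eq_row_names.append(f"growth[{k}]")
            else:
                lo, hi = sorted((mu_k * (1 - eps), mu_k * (1 + eps)))
                ub_rows.append(_row([(j, 1.0), (xk, -hi)]))
                ub_b.append(np.zeros(1))
                ub_rows.append(_row([(j, -1.0), (xk, lo)]))
                ub_b.append(np.zeros(1))

        # abundance-scaled bounds for species-owned reactions
        for r in self.community.reactions:
            if r.species is None:
                continue
            j, xk = self.ridx[r.id], self.kidx[r.species]
            ub_rows.append(_row([(j, 1.0), (xk, -r.ub)]))
            ub_b.append(np.zeros(1))
            ub_rows.append(_row([(j, -1.0), (xk, r.lb)]))
            ub_b.append(np.zeros(1))

        # kinetic specific-rate constraints, scaled by abundance
        self._rate_row_names = []
        for (k, met), (lo, hi) in rate_bounds.items():
            tid = com.transports.get((k, met))
            if tid is None:
                raise KeyError(f"no transport for species {k!r}, metabolite {met!r}")
            j, xk = self.ridx[tid], self.kidx[k]
            if eps > 0.0:
                lo, hi = min(lo * (1 - eps), lo * (1 + eps)), max(hi * (1 - eps), hi * (1 + eps))
            ub_rows.append(_row([(j, 1.0), (xk, -hi)]))
            ub_b.append(np.zeros(1))
            self._rate_row_names.append(f"rate[{k},{met}]<=")
            ub_rows.append(_row([(j, -1.0), (xk, lo)]))
            ub_b.append(np.zeros(1))
            self._rate_row_names.append(f"rate[{k},{met}]>=")

        # variable bounds
        bounds: list[tuple[float | None, float | None]] = [(None, None)] * len(self.rids)
        for r in com.reactions:
            if r.species is None:  # community exchange: absolute bounds
                lb, ub = exchange_bounds.get(r.id, (r.lb, r.ub))
                bounds[self.ridx[r.id]] = (lb, ub)
        for k in self.species:
            if fixed_X is not None:
                bounds.append((fixed_X[k], fixed_X[k]))
            else:
                bounds.append((0.0, cap))
        if fixed_X is None:
            # sum(X) <= cap
            cols = np.array([self.kidx[k] for k in self.species])
            row = sp.csr_matrix(
                (np.ones(len(cols)), (np.zeros(len(cols), dtype=int), cols)), shape=(1, self.n)
            )
            ub_rows.append(row)
            ub_b.append(np.array([cap]))

        A_eq = sp.vstack(eq_rows, format="csr")
        b_eq = np.concatenate(eq_b)
        A_ub = sp.vstack(ub_rows, format="csr")
        b_ub = np.concatenate(ub_b)
        return A_eq, b_eq, A_ub, b_ub, bounds

    # -- objectives ------------------------------------------------------
    def abundance_objective(self) -> np.ndarray:
        c = np.zeros(self.n)
        for k in self.species:
            c[self.kidx[k]] = 1.0
        return c

    def solve_parsimonious(self, A_eq, b_eq, A_ub, b_ub, bounds):
        """Minimize total |transport flux| over the feasible set (tie-break)."""
        tcols = [self.ridx[tid] for tid in self.community.transports.values()]
        naux = len(tcols)
        n = self.n
        # aux t_i >= |v_tcol_i|
        A_eq2 = sp.hstack([A_eq, sp.csr_matrix((A_eq.shape[0], naux))], format="csr")
        rows, extra_b = [sp.hstack([A_ub, sp.csr_matrix((A_ub.shape[0], naux))], format="csr")], [b_ub]
        for i, j in enumerate(tcols):
            for sgn in (1.0, -1.0):
                r = sp.csr_matrix(
                    (np.array([sgn, -1.0]), (np.array([0, 0]), np.array([j, n + i]))),
                    shape=(1, n + naux),
                )
                rows.append(r)
                extra_b.append(np.zeros(1))
        A_ub2 = sp.vstack(rows, format="csr")
        b_ub2 = np.concatenate(extra_b)
        bounds2 = list(bounds) + [(0.0, None)] * naux
        c = np.zeros(n + naux)
        c[n:] = 1.0
        res = solve_lp(c, A_eq2, b_eq, A_ub2, b_ub2, bounds2, sense="min")
        if res.status == OPTIMAL:
            res.x = res.x[:n]
        return res

    def diagnose(self, A_eq, b_eq, A_ub, b_ub, bounds) -> str:
        """Elastic relaxation of the metabolite balances naming the violation.

        Adds +/- slack to every metabolite steady-state row (growth coupling
        stays hard), minimizes total slack, and reports the metabolites
        needing nonzero slack — i.e. which mass balances the constraint set
        cannot close.
        """
        m = self.S.shape[0]
        n_eq = A_eq.shape[0]
        Ipos = sp.vstack(
            [sp.identity(m, format="csr"), sp.csr_matrix((n_eq - m, m))], format="csr"
        )
        A_eq2 = sp.hstack([A_eq, Ipos, -Ipos], format="csr")
        A_ub2 = sp.hstack([A_ub, sp.csr_matrix((A_ub.shape[0], 2 * m))], format="csr")
        bounds2 = list(bounds) + [(0.0, None)] * (2 * m)
        c = np.concatenate([np.zeros(self.n), np.ones(2 * m)])
        res = solve_lp(c, A_eq2, b_eq, A_ub2, b_ub, bounds2, sense="min")
        if res.status != OPTIMAL:
            return "infeasible (elastic diagnosis also failed)"
        slack = res.x[self.n : self.n + m] + res.x[self.n + m :]
        bad = [
            f"{self._eq_row_names[i]} ({slack[i]:.3g})"
            for i in np.argsort(slack)[::-1]
            if slack[i] > 1e-6
        ]
        if not bad:
            return "infeasible (no single balance identified)"
        return "balances violated: " + ", ".join(bad[:5])

    # -- solution extraction --------------------------------------------
    def extract(self, x: np.ndarray, growth_rates: dict[str, float]) -> SteadyComSolution:
        com = self.community
        abundances = {k: float(x[self.kidx[k]]) for k in self.species}
        fluxes = {rid: float(x[self.ridx[rid]]) for rid in self.rids}
        exchange = {met: fluxes[eid] for met, eid in com.exchanges.items()}
        transport: dict[str, dict[str, float]] = {k: {} for k in self.species}
        for (k, met), tid in com.transports.items():
            transport[k][met] = fluxes[tid]
        return SteadyComSolution(
            status=OPTIMAL,
            mu=None,
            abundances=abundances,
            growth_rates=dict(growth_rates),
            fluxes=fluxes,
            exchange=exchange,
            transport=transport,
        )


def steadycom_lp_at_mu(
    community: CommunityModel,
    mu: float,
    exchange_bounds: dict[str, tuple[float, float]] | None = None,
    cap: float = 1.0,
) -> tuple[float, SteadyComSolution]:
    """Maximize total abundance at a fixed community growth rate.

    Returns ``(max sum X, solution)``; infeasibility gives ``(0.0, solution
    with status 'infeasible')``. ``exchange_bounds`` maps community exchange
    reaction ids to (lb, ub) overrides.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    lp = _CommunityLP(community)
    growth = {k: mu for k in lp.species}
    A_eq, b_eq, A_ub, b_ub, bounds = lp.assemble(growth, exchange_bounds, cap=cap)
    res = solve_lp(lp.abundance_objective(), A_eq, b_eq, A_ub, b_ub, bounds, sense="max")
    if res.status != OPTIMAL:
        return 0.0, SteadyComSolution(status=res.status, mu=mu)
    sol = lp.extract(res.x, growth)
    sol.mu = mu
    return float(res.objective), sol


def _exchange_override_by_rid(community, bounds_by_met):
    if not bounds_by_met:
        return None
    return {community.exchanges[m]: b for m, b in bounds_by_met.items()}


def solve_steadycom(
    community: CommunityModel,
    exchange_bounds: dict[str, tuple[float, float]] | None = None,
    tol: float = 1e-6,
    mu_hi: float = 10.0,
    max_iter: int = 60,
    parsimonious: bool = True,
) -> SteadyComSolution:
    """Largest equal growth rate at total abundance 1, with its composition.

    ``exchange_bounds`` maps community metabolite base names to (lb, ub)
    overrides of the community exchange bounds. Bisection (to ``tol`` on mu)
    brackets the upper endpoint of the feasible mu interval; a fixed-point
    pass mu <- mu * sum(X*(mu)) then polishes mu so that abundances are
    resolved well beyond the bisection tolerance. Among alternate optima a
    parsimonious (minimal total transport) solution is reported.
    """
    ex = _exchange_override_by_rid(community, exchange_bounds)

    def total_at(mu: float) -> float:
        # uncapped total abundance (cap far above 1 so the optimum is interior)
        t, _ = steadycom_lp_at_mu(community, mu, ex, cap=100.0)
        return t

    def feasible(mu: float) -> bool:
        return total_at(mu) >= 1.0 - 1e-9

    # find a feasible starting point
    lo = None
    if feasible(0.0):
        lo = 0.0
    else:
        for mu in _seed_grid(mu_hi):
            if feasible(mu):
                lo = mu
                break
    if lo is None:
        raise ConstraintsInconsistentError(
            "constraints inconsistent: no feasible community growth rate found "
            f"(searched 0..{mu_hi})"
        )

    hi = max(lo, tol) * 2.0
    for _ in range(60):
        if not feasible(hi):
            break
        lo = hi
        hi *= 2.0
    else:
        raise ModelError("community growth appears unbounded")

    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid

    # fixed-point polish: total abundance scales ~ c/mu near the optimum
    mu_star = lo
    last_good = lo
    for _ in range(50):
        t = total_at(mu_star)
        if t <= 0.0:  # stepped past the feasible interval; keep the last good mu
            mu_star = last_good
            break
        last_good = mu_star
        if abs(t - 1.0) <= 1e-11:
            break
        nxt = mu_star * t
        if not np.isfinite(nxt) or nxt <= 0 or nxt > hi * 1.5:
            break
        mu_star = nxt

    total, sol = steadycom_lp_at_mu(community, mu_star, ex, cap=1.0)
    if not sol.ok or total < 1.0 - 1e-7:
        mu_star = lo  # numerical edge: fall back to the certified feasible point
        total, sol = steadycom_lp_at_mu(community, mu_star, ex, cap=1.0)
        if not sol.ok:
            raise ModelError(f"final solve failed at mu={mu_star}: {sol.status}")

    if parsimonious:
        lp = _CommunityLP(community)
        growth = {k: mu_star for k in lp.species}
        A_eq, b_eq, A_ub, b_ub, bounds = lp.assemble(
            growth, ex, fixed_X=sol.abundances
        )
        res = lp.solve_parsimonious(A_eq, b_eq, A_ub, b_ub, bounds)
        if res.status == OPTIMAL:
            sol = lp.extract(res.x, growth)
    sol.mu = mu_star
    sol.growth_rates = {k: mu_star for k in community.members}
    return sol


def _seed_grid(mu_hi: float):
    """Geometric then linear mu candidates for locating a feasible interval."""
    geo = [mu_hi * 2.0**-k for k in range(1, 41)]
    lin = list(np.linspace(mu_hi / 256.0, mu_hi, 256))
    return geo + lin


def solve_fixed_composition(
    community: CommunityModel,
    abundances: dict[str, float],
    growth_rates: dict[str, float],
    rate_constraints: dict[tuple[str, str], tuple[float, float]] | None = None,
    eps: float = 0.0,
    exchange_bounds: dict[str, tuple[float, float]] | None = None,
    parsimonious: bool = True,
) -> SteadyComSolution:
    """Community solve at a prescribed composition and per-species growth.

    ``abundances`` must sum to 1; growth rates may differ between species
    (the modified, unequal-growth form used when kinetic predictions drive
    the community model). ``rate_constraints`` maps (species, base met) to
    per-species specific-rate bounds (mmol/gDCW_k/hr, uptake negative) on the
    species' transport with [u]; they are multiplied by X_k internally.
    ``eps`` is a relative slack applied to growth coupling and rate bounds.
    On infeasibility the returned solution's message names the mass balances
    that cannot close.
    """
    total = sum(abundances.values())
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1 (got {total})")
    for k, mu_k in growth_rates.items():
        if mu_k < 0:
            raise ValueError(f"negative growth rate for {k}")
    lp = _CommunityLP(community)
    ex = _exchange_override_by_rid(community, exchange_bounds)
    A_eq, b_eq, A_ub, b_ub, bounds = lp.assemble(
        growth_rates,
        ex,
        rate_bounds=rate_constraints,
        fixed_X=abundances,
        eps=eps,
    )
    if parsimonious:
        res = lp.solve_parsimonious(A_eq, b_eq, A_ub, b_ub, bounds)
    else:
        res = solve_lp(np.zeros(lp.n), A_eq, b_eq, A_ub, b_ub, bounds, sense="min")
    if res.status != OPTIMAL:
        msg = lp.diagnose(A_eq, b_eq, A_ub, b_ub, bounds) if res.status == INFEASIBLE else ""
        return SteadyComSolution(status=res.status, message=msg, abundances=dict(abundances))
    sol = lp.extract(res.x, growth_rates)
    sol.abundances = dict(abundances)
    sol.mu = float(sum(growth_rates[k] * abundances[k] for k in growth_rates))
    return sol


def extract_crossfeeding(
    solution: SteadyComSolution,
    positive_species: str | None = None,
    tol: float = FLUX_EPS,
) -> list[CrossFeedingRecord]:
    """Decompose [u] transport fluxes into producer/consumer records.

    For each shared metabolite, species exporting to [u] (transport > 0) and
    the environment (community uptake) are producers; species importing and
    the environment (community secretion) are consumers. Producer totals are
    split over consumers proportionally. Records are sorted by flux
    magnitude; ``signed`` is +flux when the producer is ``positive_species``
    (default: the first community member, the methanotroph in the bundled
    coculture) and -flux otherwise.
    """
    if not solution.ok:
        raise ValueError("cross-feeding extraction requires an optimal solution")
    if positive_species is None:
        positive_species = next(iter(solution.transport), None)
    mets = sorted({m for d in solution.transport.values() for m in d})
    records: list[CrossFeedingRecord] = []
    for met in mets:
        producers: list[tuple[str, float]] = []
        consumers: list[tuple[str, float]] = []
        for k, d in solution.transport.items():
            f = d.get(met, 0.0)
            if f > tol:
                producers.append((k, f))
            elif f < -tol:
                consumers.append((k, -f))
        ex = solution.exchange.get(met, 0.0)
        if ex < -tol:
            producers.append(("environment", -ex))
        elif ex > tol:
            consumers.append(("environment", ex))
        tot_cons = sum(f for _, f in consumers)
        if tot_cons <= tol:
            continue
        for prod, pf in producers:
            for cons, cf in consumers:
                flux = pf * cf / tot_cons
                if flux <= tol:
                    continue
                records.append(
                    CrossFeedingRecord(
                        metabolite=met,
                        producer=prod,
                        consumer=cons,
                        flux=flux,
                        signed=flux if prod == positive_species else -flux,
                    )
                )
    records.sort(key=lambda r: r.flux, reverse=True)
    return records
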