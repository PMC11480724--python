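"""Stoichiometric model container, I/O, FBA/FVA and blocked-reaction removal.

The in-memory representation is deliberately small: a model is a list of
metabolites with compartment tags, a list of reactions given as sparse
stoichiometric columns with flux bounds, plus the identities of the biomass
and ATP-maintenance reactions and the two maintenance-energy parameters
(GAM, growth-associated, mmol ATP/gDCW folded into the biomass reaction;
NGAM, non-growth-associated, mmol ATP/gDCW/hr enforced as the maintenance
reaction's lower bound).

Units follow the COBRA convention: fluxes in mmol/gDCW/hr, the biomass
reaction flux in 1/hr, uptake negative and excretion positive on exchange
(boundary) reactions.

Models round-trip through a flat JSON dialect; SBML Level 3 files are read
through cobra/libsbml and converted into this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._lp import OPTIMAL, solve_lp

#: widest exchange bound assumed when probing "any conditions" (COBRA convention)
OPEN_BOUND = 1000.0

#: |flux| below this is treated as zero when classifying blocked reactions
BLOCKED_TOL = 1e-9


class ModelError(Exception):
    """Base class for model construction/IO problems."""


class ParseError(ModelError):
    """Raised when a model file cannot be parsed; names the offending element."""


class ValidationError(ModelError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str  # 'c' intracellular, 'e' extracellular, 'u' community


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = -OPEN_BOUND
    ub: float = OPEN_BOUND
    species: str | None = None  # owner species in a community model

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub, self.species)

    @property
    def is_boundary(self) -> bool:
        """True for exchange/demand reactions touching a single metabolite."""
        return len(self.stoich) == 1


@dataclass
class StoichModel:
    """One species' metabolic network (or a merged community network)."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    maintenance_id: str
    gam: float = 0.0
    ngam: float = 0.0
    species: str = ""

    VALID_COMPARTMENTS = ("c", "e", "u")

    def __post_init__(self):
        self.validate()

    # -- bookkeeping -----------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for m in self.metabolites:
            if m.compartment not in self.VALID_COMPARTMENTS:
                raise ValidationError(
                    f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
                )
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {sorted(missing)}"
                )
            if r.lb > r.ub:
                raise ValidationError(f"reaction {r.id!r}: lb {r.lb} > ub {r.ub}")
        for rid, what in ((self.biomass_id, "biomass"), (self.maintenance_id, "maintenance")):
            if rid not in set(rxn_ids):
                raise ValidationError(f"{what} reaction {rid!r} not in model")
        if self.gam < 0 or self.ngam < 0:
            raise ValidationError("gam and ngam must be non-negative")

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    @property
    def boundary_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_boundary]

    def copy(self) -> "StoichModel":
        return StoichModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_id=self.biomass_id,
            maintenance_id=self.maintenance_id,
            gam=self.gam,
            ngam=self.ngam,
            species=self.species,
        )

    def stoichiometric_matrix(self) -> sp.csr_matrix:
        """S with metabolites as rows, reactions as columns."""
        midx = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoich.items():
                rows.append(midx[met])
                cols.append(j)
                vals.append(coef)
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | ...
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def model_to_dict(model: StoichModel) -> dict:
    return {
        "species": model.species,
        "metabolites": [
            {"id": m.id, "compartment": m.compartment} for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "stoich": dict(r.stoich), "lb": r.lb, "ub": r.ub}
            for r in model.reactions
        ],
        "biomass_id": model.biomass_id,
        "maintenance_id": model.maintenance_id,
        "gam": model.gam,
        "ngam": model.ngam,
    }


def model_from_dict(doc: dict) -> StoichModel:
    try:
        mets = [Metabolite(m["id"], m["compartment"]) for m in doc["metabolites"]]
        rxns = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoich"].items()},
                float(r.get("lb", -OPEN_BOUND)),
                float(r.get("ub", OPEN_BOUND)),
            )
            for r in doc["reactions"]
        ]
        return StoichModel(
            metabolites=mets,
            reactions=rxns,
            biomass_id=doc["biomass_id"],
            maintenance_id=doc["maintenance_id"],
            gam=float(doc.get("gam", 0.0)),
            ngam=float(doc.get("ngam", 0.0)),
            species=doc.get("species", ""),
        )
    except KeyError as exc:
        raise ParseError(f"model document missing required field {exc}") from exc


def write_model(model: StoichModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)


def read_model(
    path,
    format: str | None = None,
    biomass_id: str | None = None,
    maintenance_id: str | None = None,
) -> StoichModel:
    """Read a model from the JSON dialect or an SBML Level 3 file.

    ``format`` is inferred from the extension when omitted. For SBML the
    biomass/maintenance reactions are taken from ``biomass_id`` /
    ``maintenance_id`` when given, otherwise guessed from the objective and
    from conventional id patterns ('biomass', 'ATPM').
    """
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: not valid JSON at line {exc.lineno}") from exc
        return model_from_dict(doc)
    if format == "sbml":
        return _read_sbml(path, biomass_id, maintenance_id)
    raise ValueError(f"unknown format {format!r}")


def _read_sbml(path, biomass_id, maintenance_id) -> StoichModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # libsbml raises a zoo of error types
        raise ParseError(f"{path}: SBML parse failed ({exc})") from exc

    def _guess(patterns, given, what):
        if given is not None:
            if given not in [r.id for r in cm.reactions]:
                raise ValidationError(f"{what} reaction {given!r} not in SBML model")
            return given
        for r in cm.reactions:
            if any(p in r.id.lower() for p in patterns):
                return r.id
        raise ValidationError(f"could not identify a {what} reaction in {path}")

    if biomass_id is None and cm.objective is not None:
        obj_rxns = [
            r.id for r in cm.reactions if abs(r.objective_coefficient) > 0
        ]
        if len(obj_rxns) == 1:
            biomass_id = obj_rxns[0]
    biomass_id = _guess(("biomass", "growth"), biomass_id, "biomass")
    maintenance_id = _guess(("atpm", "maintenance", "ngam"), maintenance_id, "maintenance")

    comp_map = {}
    for cid in cm.compartments:
        tag = cid.lower().strip("_")[-1]
        comp_map[cid] = tag if tag in StoichModel.VALID_COMPARTMENTS else "c"
    mets = [Metabolite(m.id, comp_map.get(m.compartment, "c")) for m in cm.metabolites]
    rxns = [
        Reaction(
            r.id,
            {m.id: coef for m, coef in r.metabolites.items()},
            float(max(r.lower_bound, -OPEN_BOUND)),
            float(min(r.upper_bound, OPEN_BOUND)),
        )
        for r in cm.reactions
    ]
    return StoichModel(
        metabolites=mets,
        reactions=rxns,
        biomass_id=biomass_id,
        maintenance_id=maintenance_id,
        species=cm.id or "",
    )


# ---------------------------------------------------------------------------
# Maintenance energy
# ---------------------------------------------------------------------------

def set_maintenance(model: StoichModel, gam: float, ngam: float) -> StoichModel:
    """Return a copy with maintenance energies set.

    The GAM contribution is ``gam`` times the maintenance reaction's own
    stoichiometry, folded into the biomass reaction (replacing whatever GAM
    the model carried before, tracked through ``model.gam``); NGAM becomes
    the maintenance reaction's lower bound. For models loaded from SBML whose
    biomass reaction already embeds an unknown GAM, this therefore adjusts
    relative to the recorded ``gam`` attribute (0 by default).
    """
    if gam < 0 or ngam < 0:
        raise ValidationError("gam and ngam must be non-negative")
    out = model.copy()
    maint = out.reaction(out.maintenance_id)
    bio = out.reaction(out.biomass_id)
    delta = gam - model.gam
    for met, coef in maint.stoich.items():
        new = bio.stoich.get(met, 0.0) + delta * coef
        if abs(new) < 1e-12:
            bio.stoich.pop(met, None)
        else:
            bio.stoich[met] = new
    maint.lb = ngam
    maint.ub = max(maint.ub, ngam)
    out.gam = gam
    out.ngam = ngam
    out.validate()
    return out


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

def _merged_bounds(model: StoichModel, extra_bounds) -> list[tuple[float, float]]:
    bounds = []
    extra = extra_bounds or {}
    for r in model.reactions:
        lb, ub = r.lb, r.ub
        if r.id in extra:
            lb, ub = extra[r.id]
            if lb > ub:
                raise ValidationError(f"extra bound for {r.id!r}: lb {lb} > ub {ub}")
        bounds.append((lb, ub))
    return bounds


def fba(
    model: StoichModel,
    objective: str | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction flux subject to S.v = 0.

    ``extra_bounds`` override the model's bounds reaction-by-reaction without
    mutating the model. Alternate optima are possible; only the objective
    value (and fluxes shown unique by FVA) should be relied upon.
    """
    objective = objective or model.biomass_id
    rids = model.reaction_ids
    if objective not in rids:
        raise KeyError(f"objective reaction {objective!r} not in model")
    S = model.stoichiometric_matrix()
    c = np.zeros(len(rids))
    c[rids.index(objective)] = 1.0
    res = solve_lp(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_merged_bounds(model, extra_bounds),
        sense=sense,
    )
    if res.status != OPTIMAL:
        return FluxSolution(status=res.status)
    return FluxSolution(
        status=OPTIMAL,
        objective_value=res.objective,
        fluxes=dict(zip(rids, res.x)),
    )


def fva(
    model: StoichModel,
    reactions: list[str] | None = None,
    frac_opt: float = 0.0,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability: per-reaction (min, max) at >= frac_opt of the optimum."""
    if not 0.0 <= frac_opt <= 1.0:
        raise ValueError("frac_opt must lie in [0, 1]")
    rids = model.reaction_ids
    reactions = reactions if reactions is not None else rids
    bounds = _merged_bounds(model, extra_bounds)
    S = model.stoichiometric_matrix()
    b_eq = np.zeros(S.shape[0])
    A_ub = None
    b_ub = None
    if frac_opt > 0.0:
        base = fba(model, extra_bounds=extra_bounds)
        if not base.ok:
            raise ModelError(f"base model not solvable for FVA: {base.status}")
        j = rids.index(model.biomass_id)
        row = sp.csr_matrix(
            (np.array([-1.0]), (np.array([0]), np.array([j]))), shape=(1, len(rids))
        )
        A_ub, b_ub = row, np.array([-frac_opt * base.objective_value])
    out = {}
    for rid in reactions:
        c = np.zeros(len(rids))
        c[rids.index(rid)] = 1.0
        lo = solve_lp(c, A_eq=S, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds, sense="min")
        hi = solve_lp(c, A_eq=S, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds, sense="max")
        if lo.status != OPTIMAL or hi.status != OPTIMAL:
            raise ModelError(f"FVA subproblem for {rid!r} returned {lo.status}/{hi.status}")
        out[rid] = (lo.objective, hi.objective)
    return out


# ---------------------------------------------------------------------------
# Blocked (dead-end) reaction removal
# ---------------------------------------------------------------------------

def remove_blocked_reactions(model: StoichModel):
    """Drop reactions that can carry no flux under any exchange conditions.

    All boundary reactions are opened to +/-OPEN_BOUND, FVA at frac_opt=0
    classifies reactions with a (0, 0) range as blocked, and the removal is
    iterated to a fixed point. The biomass and maintenance reactions are
    never removed (a model without them is structurally invalid). Metabolites
    left unreferenced are dropped as well. Returns ``(reduced_model,
    removed_reaction_ids)``.
    """
    work = model.copy()
    protected = set(getattr(work, "protected_ids", (work.biomass_id, work.maintenance_id)))
    removed: list[str] = []
    while True:
        open_bounds = {r.id: (-OPEN_BOUND, OPEN_BOUND) for r in work.reactions if r.is_boundary}
        ranges = fva(work, frac_opt=0.0, extra_bounds=open_bounds)
        dead = [
            rid
            for rid, (lo, hi) in ranges.items()
            if abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL and rid not in protected
        ]
        if not dead:
            break
        removed.extend(dead)
        work.reactions = [r for r in work.reactions if r.id not in set(dead)]
        used = {m for r in work.reactions for m in r.stoich}
        work.metabolites = [m for m in work.metabolites if m.id in used]
        work.validate()
    return work, removed


# ---------------------------------------------------------------------------
# cobra bridge (SBML writing and cross-validation)
# ---------------------------------------------------------------------------

def to_cobra(model: StoichModel):
    """Convert to a cobra.Model (used for SBML export and cross-checks)."""
    import cobra

    cm = cobra.Model(model.species or "model")
    comp_name = {"c": "c", "e": "e", "u": "u"}
    cmets = {
        m.id: cobra.Metabolite(m.id, compartment=comp_name[m.compartment])
        for m in model.metabolites
    }
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cm.add_reactions([cr])
        cr.add_metabolites({cmets[m]: coef for m, coef in r.stoich.items()})
    cm.objective = model.biomass_id
    return cm
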