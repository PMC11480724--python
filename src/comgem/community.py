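"""Merging species models into a compartmentalized community model.

Each member species keeps its own intracellular [c] and extracellular [e]
compartments under a species prefix (M1, C1, ...). A shared community
compartment [u] is added; every whitelisted extracellular metabolite gets one
reversible transport reaction per species that declares it (species [e] <->
[u], "move freely in and out") and a single community exchange reaction on
[u] whose bounds come from the exchange policy. Metabolites excluded from
exchange simply have no [u] counterpart: their member-level exchange
reactions are removed and no transport is added, so any obligatory
production of them renders the community model infeasible rather than
leaking past the community accounting.

Sign conventions: transport flux > 0 means the species exports to [u];
community exchange flux > 0 means net secretion to the environment, < 0 net
uptake by the community (so a fixed net CO2 consumption of 0.680 is the
bound pair (-0.680, -0.680)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import Metabolite, Reaction, StoichModel, ValidationError, OPEN_BOUND


class PolicyError(Exception):
    """Invalid exchange-policy request."""


@dataclass
class ExchangePolicy:
    """Which metabolites may enter the community compartment, with bounds.

    ``bounds`` maps a community metabolite base name to (lb, ub) for its
    community exchange reaction, in mmol per gDCW of total community biomass
    per hr; metabolites without an entry get the wide-open default.
    """

    whitelist: tuple[str, ...]
    blacklist: tuple[str, ...] = ()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.whitelist = tuple(self.whitelist)
        self.blacklist = tuple(self.blacklist)
        overlap = set(self.whitelist) & set(self.blacklist)
        if overlap:
            raise PolicyError(f"metabolites both whitelisted and blacklisted: {sorted(overlap)}")
        for met, (lb, ub) in self.bounds.items():
            if met in self.blacklist:
                raise PolicyError(f"bound requested for blacklisted metabolite {met!r}")
            if met not in self.whitelist:
                raise PolicyError(f"bound requested for non-whitelisted metabolite {met!r}")
            if lb > ub:
                raise PolicyError(f"bound for {met!r}: lb {lb} > ub {ub}")


#: gases/nutrients always shared in the coculture setups
BASE_SHARED = ("ch4", "o2", "co2", "photon", "nh4", "no3")

#: the six published in-silico setups: (included organics, excluded organics)
TABLE3_SETUPS = {
    "setup1": (("mal", "pyr"), ("succ", "oaa", "fum", "akg")),
    "setup2": (("pyr",), ("succ", "mal", "oaa", "fum", "akg")),
    "setup3": (("pyr", "succ"), ("mal", "oaa", "fum", "akg")),
    "setup4": (("succ",), ("pyr", "mal", "oaa", "fum", "akg")),
    "setup5": (("mal", "succ"), ("pyr", "oaa", "fum", "akg")),
    "setup6": (("mal", "akg"), ("succ", "oaa", "fum", "pyr")),
}


def make_setup_policy(
    name: str,
    base_shared: tuple[str, ...] = BASE_SHARED,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> ExchangePolicy:
    """One of the six named central-carbon exchange setups as a policy."""
    if name not in TABLE3_SETUPS:
        raise PolicyError(f"unknown setup {name!r}; choose from {sorted(TABLE3_SETUPS)}")
    included, excluded = TABLE3_SETUPS[name]
    return ExchangePolicy(
        whitelist=tuple(base_shared) + included,
        blacklist=excluded,
        bounds=bounds or {},
    )


@dataclass
class CommunityModel(StoichModel):
    """N species plus a shared [u] compartment; see module docstring."""

    members: list[str] = field(default_factory=list)
    biomass_ids: dict[str, str] = field(default_factory=dict)
    maintenance_ids: dict[str, str] = field(default_factory=dict)
    #: (species, base met) -> transport reaction id
    transports: dict[tuple[str, str], str] = field(default_factory=dict)
    #: base met -> community exchange reaction id
    exchanges: dict[str, str] = field(default_factory=dict)
    policy: ExchangePolicy | None = None

    @property
    def protected_ids(self) -> tuple[str, ...]:
        return tuple(self.biomass_ids.values()) + tuple(self.maintenance_ids.values())

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_id=self.biomass_id,
            maintenance_id=self.maintenance_id,
            gam=self.gam,
            ngam=self.ngam,
            species=self.species,
            members=list(self.members),
            biomass_ids=dict(self.biomass_ids),
            maintenance_ids=dict(self.maintenance_ids),
            transports=dict(self.transports),
            exchanges=dict(self.exchanges),
            policy=self.policy,
        )


def harmonize_ids(
    models: list[StoichModel],
    synonym_map: dict[str, str] | None = None,
    prefixes: list[str] | None = None,
) -> list[StoichModel]:
    """Apply canonical metabolite names and species prefixes.

    ``synonym_map`` sends raw metabolite ids to canonical base names so that
    extracellular metabolites meant to be shared end up with the same base
    name in every species. All metabolite and reaction ids are then prefixed
    with the species prefix (derived from the species label, e.g. 'M1').
    """
    synonym_map = synonym_map or {}
    if prefixes is None:
        counts: dict[str, int] = {}
        prefixes = []
        for m in models:
            letter = m.species[:1].upper() if m.species else "S"
            counts[letter] = counts.get(letter, 0) + 1
            prefixes.append(f"{letter}{counts[letter]}")
    if len(set(prefixes)) != len(prefixes):
        raise ValidationError(f"species prefixes not disjoint: {prefixes}")
    out = []
    for model, prefix in zip(models, prefixes):
        canon = {m.id: synonym_map.get(m.id, m.id) for m in model.metabolites}
        seen: dict[str, str] = {}
        for raw, base in canon.items():
            if base in seen:
                raise ValidationError(
                    f"species {model.species!r}: metabolites {seen[base]!r} and {raw!r} "
                    f"both map to canonical name {base!r}"
                )
            seen[base] = raw
        mets = [Metabolite(f"{prefix}_{canon[m.id]}", m.compartment) for m in model.metabolites]
        rxns = [
            Reaction(
                f"{prefix}_{r.id}",
                {f"{prefix}_{canon[m]}": c for m, c in r.stoich.items()},
                r.lb,
                r.ub,
                species=prefix,
            )
            for r in model.reactions
        ]
        out.append(
            StoichModel(
                metabolites=mets,
                reactions=rxns,
                biomass_id=f"{prefix}_{model.biomass_id}",
                maintenance_id=f"{prefix}_{model.maintenance_id}",
                gam=model.gam,
                ngam=model.ngam,
                species=prefix,
            )
        )
    return out


def _base_name(met_id: str, prefix: str) -> str:
    return met_id[len(prefix) + 1 :] if met_id.startswith(prefix + "_") else met_id


def build_community(models: list[StoichModel], policy: ExchangePolicy) -> CommunityModel:
    """Merge harmonized species models around a shared [u] compartment."""
    if len(models) == 1 and isinstance(models[0], CommunityModel):
        return models[0].copy()
    prefixes = [m.species for m in models]
    if len(set(prefixes)) != len(prefixes) or any(not p for p in prefixes):
        raise ValidationError("models must be harmonized (disjoint non-empty species prefixes)")

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    extracellular: dict[str, set[str]] = {p: set() for p in prefixes}
    for model in models:
        prefix = model.species
        metabolites.extend(model.metabolites)
        for m in model.metabolites:
            if m.compartment == "e":
                extracellular[prefix].add(_base_name(m.id, prefix))
        for r in model.reactions:
            if r.is_boundary:
                (mid,) = r.stoich
                if model.metabolite(mid).compartment == "e":
                    continue  # member-level exchange: replaced by the [u] route
            rr = r.copy()
            rr.species = prefix
            reactions.append(rr)

    transports: dict[tuple[str, str], str] = {}
    exchanges: dict[str, str] = {}
    shared: list[str] = []
    for base in policy.whitelist:
        holders = [p for p in prefixes if base in extracellular[p]]
        if not holders:
            warnings.warn(f"whitelisted metabolite {base!r} absent from all species; skipped")
            continue
        shared.append(base)
        metabolites.append(Metabolite(base, "u"))
        for p in holders:
            tid = f"TR_{p}_{base}"
            transports[(p, base)] = tid
            reactions.append(
                Reaction(tid, {f"{p}_{base}": -1.0, base: 1.0}, -OPEN_BOUND, OPEN_BOUND, species=p)
            )
        eid = f"EX_u_{base}"
        exchanges[base] = eid
        lb, ub = policy.bounds.get(base, (-OPEN_BOUND, OPEN_BOUND))
        reactions.append(Reaction(eid, {base: -1.0}, lb, ub, species=None))

    return CommunityModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=models[0].biomass_id,
        maintenance_id=models[0].maintenance_id,
        species="+".join(prefixes),
        members=prefixes,
        biomass_ids={m.species: m.biomass_id for m in models},
        maintenance_ids={m.species: m.maintenance_id for m in models},
        transports=transports,
        exchanges=exchanges,
        policy=policy,
    )


def set_exchange_policy(
    community: CommunityModel, bounds: dict[str, tuple[float, float]]
) -> CommunityModel:
    """Return a copy with updated community exchange bounds.

    Setting a metabolite to (0, 0) closes its net exchange with the
    environment, forcing any production to be consumed in situ.
    """
    out = community.copy()
    for met, (lb, ub) in bounds.items():
        if met not in out.exchanges:
            raise PolicyError(f"no community exchange for metabolite {met!r}")
        if lb > ub:
            raise PolicyError(f"bound for {met!r}: lb {lb} > ub {ub}")
        rxn = out.reaction(out.exchanges[met])
        rxn.lb, rxn.ub = lb, ub
    return out
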