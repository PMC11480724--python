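"""Deterministic toy coculture ("toybin-1") and kinetic scenario generator.

The toy community stands in for a genome-scale methanotroph/phototroph pair
so every algorithm in the toolkit is exercisable without external model
downloads. Coefficients are frozen integers/simple rationals chosen so the
headline community optima are exact by hand:

methanotroph (species label "M")
    BIO_M:   40 ch4 + 52 o2 + 8 nx -> biomass + 12 co2     (flux in 1/hr)
    R_NH4:   nh4 -> nx                                      (ammonium assimilation)
    R_NO3:   no3 + 0.25 ch4 + 0.5 o2 -> nx                  (nitrate reduction)
    RESP_M:  ch4 + 2 o2 + 10 adp -> co2 + 10 atp            (maintenance fuel)
    ATPM_M:  atp -> adp                                      (NGAM floor)
    exchanges for ch4, o2, co2, nh4, no3

phototroph (species label "C")
    BIO_C:   45 co2 + 400 photon + 6 nh4 -> biomass + 45 o2
    R_NO3C:  no3 + 2 photon -> nh4                           (nitrate reduction)
    PSATP_C: 5 photon + adp -> atp                           (photophosphorylation)
    ATPM_C:  atp -> adp
    exchanges for co2, o2, photon, nh4, no3

nx (fixed nitrogen) and photon are massless bookkeeping species; R_NO3's
0.25 CH4 is lumped oxidation bookkeeping and is exempt from the carbon
audit (see :func:`elemental_audit`). Biomass pseudo-formulas carry
28 mmol C/gDCW (methanotroph) and 45 mmol C/gDCW (phototroph).

Hand optima used throughout the tests (net O2 exchange closed, net CO2
uptake fixed at 0.680 mmol/gDCW/hr, everything else open):

* ammonium mode (optimal): X_M = 45/97, X_C = 52/97,
  mu* = 0.680 * 97/1800, community CH4 uptake = 0.680,
  nh4 cross-feed = 8 mu* X_M.
* forced-nitrate mode (nh4 transport blocked): X_M = 45/101,
  mu = 0.680 * 101/1980 < mu*.
"""

from __future__ import annotations

import numpy as np

from .model import Metabolite, Reaction, StoichModel

#: carbon content of the biomass pseudo-formulas, mmol C per gDCW
BIOMASS_CARBON = {"M": 28.0, "C": 45.0}

#: carbon atoms per molecule for the audited metabolites
CARBON = {"ch4": 1.0, "co2": 1.0}
#: nitrogen atoms per molecule
NITROGEN = {"nh4": 1.0, "no3": 1.0, "nx": 1.0}
#: bookkeeping species exempt from the elemental audit
MASSLESS = ("photon",)
#: reactions whose carbon imbalance is declared (lumped oxidation bookkeeping)
CARBON_EXEMPT_REACTIONS = ("R_NO3",)


def make_toybin1() -> tuple[StoichModel, StoichModel]:
    """The frozen binary community (methanotroph, phototroph); bit-identical
    on every call."""
    met_m = [
        Metabolite("ch4", "e"),
        Metabolite("o2", "e"),
        Metabolite("co2", "e"),
        Metabolite("nh4", "e"),
        Metabolite("no3", "e"),
        Metabolite("nx", "c"),
        Metabolite("atp", "c"),
        Metabolite("adp", "c"),
    ]
    rxn_m = [
        Reaction("BIO_M", {"ch4": -40.0, "o2": -52.0, "nx": -8.0, "co2": 12.0}, 0.0, 1000.0),
        Reaction("R_NH4", {"nh4": -1.0, "nx": 1.0}, 0.0, 1000.0),
        Reaction("R_NO3", {"no3": -1.0, "ch4": -0.25, "o2": -0.5, "nx": 1.0}, 0.0, 1000.0),
        Reaction("RESP_M", {"ch4": -1.0, "o2": -2.0, "adp": -10.0, "co2": 1.0, "atp": 10.0}, 0.0, 1000.0),
        Reaction("ATPM_M", {"atp": -1.0, "adp": 1.0}, 0.0, 1000.0),
        Reaction("EX_ch4", {"ch4": -1.0}, -1000.0, 1000.0),
        Reaction("EX_o2", {"o2": -1.0}, -1000.0, 1000.0),
        Reaction("EX_co2", {"co2": -1.0}, -1000.0, 1000.0),
        Reaction("EX_nh4", {"nh4": -1.0}, -1000.0, 1000.0),
        Reaction("EX_no3", {"no3": -1.0}, -1000.0, 1000.0),
    ]
    methanotroph = StoichModel(
        metabolites=met_m,
        reactions=rxn_m,
        biomass_id="BIO_M",
        maintenance_id="ATPM_M",
        species="M",
    )

    met_c = [
        Metabolite("co2", "e"),
        Metabolite("o2", "e"),
        Metabolite("photon", "e"),
        Metabolite("nh4", "e"),
        Metabolite("no3", "e"),
        Metabolite("atp", "c"),
        Metabolite("adp", "c"),
    ]
    rxn_c = [
        Reaction("BIO_C", {"co2": -45.0, "photon": -400.0, "nh4": -6.0, "o2": 45.0}, 0.0, 1000.0),
        Reaction("R_NO3C", {"no3": -1.0, "photon": -2.0, "nh4": 1.0}, 0.0, 1000.0),
        Reaction("PSATP_C", {"photon": -5.0, "adp": -1.0, "atp": 1.0}, 0.0, 1000.0),
        Reaction("ATPM_C", {"atp": -1.0, "adp": 1.0}, 0.0, 1000.0),
        Reaction("EX_co2", {"co2": -1.0}, -1000.0, 1000.0),
        Reaction("EX_o2", {"o2": -1.0}, -1000.0, 1000.0),
        Reaction("EX_photon", {"photon": -1.0}, -1000.0, 1000.0),
        Reaction("EX_nh4", {"nh4": -1.0}, -1000.0, 1000.0),
        Reaction("EX_no3", {"no3": -1.0}, -1000.0, 1000.0),
    ]
    phototroph = StoichModel(
        metabolites=met_c,
        reactions=rxn_c,
        biomass_id="BIO_C",
        maintenance_id="ATPM_C",
        species="C",
    )
    return methanotroph, phototroph


def perturb_toybin1(seed: int, scale: float = 0.1) -> tuple[StoichModel, StoichModel]:
    """Structure-preserving random variant of the toy pair.

    The major biomass coefficients are multiplied by independent factors in
    [1-scale, 1+scale] (seeded), keeping every sign and the network topology,
    so community optima move but all solver invariants must still hold.
    """
    rng = np.random.default_rng(seed)
    m, c = make_toybin1()

    def jitter(model, rid, mets):
        r = model.reaction(rid)
        for met in mets:
            r.stoich[met] *= 1.0 + scale * (2.0 * rng.random() - 1.0)

    jitter(m, "BIO_M", ["ch4", "o2", "co2", "nx"])
    jitter(c, "BIO_C", ["co2", "photon", "o2", "nh4"])
    return m, c


def elemental_audit(model: StoichModel) -> dict[str, float]:
    """Per-reaction carbon and nitrogen imbalance bookkeeping.

    Exchanges and other boundary reactions are skipped (they are sources and
    sinks by construction), massless species contribute nothing, the biomass
    reaction is balanced against the declared biomass pseudo-formula, and
    reactions in ``CARBON_EXEMPT_REACTIONS`` are excluded from the carbon
    check. Returns {reaction id: max |imbalance| over audited elements}.
    """
    out = {}
    for r in model.reactions:
        if r.is_boundary:
            continue
        imbalances = []
        for element, content in (("C", CARBON), ("N", NITROGEN)):
            if element == "C" and r.id in CARBON_EXEMPT_REACTIONS:
                continue
            total = sum(content.get(met, 0.0) * coef for met, coef in r.stoich.items())
            if r.id == model.biomass_id and element == "C":
                total += BIOMASS_CARBON.get(model.species, 0.0)
            if r.id == model.biomass_id and element == "N":
                # biomass N is whatever fixed nitrogen it consumed
                total -= sum(
                    NITROGEN.get(met, 0.0) * coef for met, coef in r.stoich.items()
                )
            imbalances.append(abs(total))
        out[r.id] = max(imbalances) if imbalances else 0.0
    return out


# ---------------------------------------------------------------------------
# Kinetic scenarios
# ---------------------------------------------------------------------------

#: headspace composition of the emulated batch experiments (CH4/CO2/N2)
BATCH_HEADSPACE = {"ch4": 0.60, "co2": 0.30, "n2": 0.10, "o2": 0.0}


def make_scenario(name: str, seed: int = 0) -> dict:
    """Named kinetic scenario configs (plain dicts, YAML/JSON serializable).

    * ``batch_default`` — closed bottle, 60/30/10 CH4/CO2/N2 headspace,
      kinetic yields matched to the toy stoichiometry.
    * ``refeed`` — batch_default plus one headspace reset at 72 h.
    * ``o2_limited`` — tiny O2 transfer and low dissolved O2 so phototroph-
      produced O2 is the binding resource for the methanotroph.

    All randomness (none at present beyond downstream perturbations) is
    seeded; the same (name, seed) always returns an identical config.
    """
    if name not in ("batch_default", "refeed", "o2_limited"):
        raise ValueError(f"unknown scenario {name!r}")
    params = {
        # growth kinetics
        "mu_max_M": 0.20,  # 1/hr
        "K_ch4": 0.05,  # mmol/L
        "K_o2": 0.02,  # mmol/L
        "mu_max_C": 0.06,  # 1/hr
        "K_co2": 0.20,  # mmol/L
        "light": 150.0,  # umol photons/m2/s, constant
        "K_light": 40.0,
        # yields matched to the toy stoichiometry
        "Y_M": 1.0 / 40.0,  # gDCW per mmol CH4
        "Y_C": 1.0 / 45.0,  # gDCW per mmol CO2
        "r_o2_ch4": 52.0 / 40.0,
        "r_co2_ch4": 12.0 / 40.0,
        "pq": 1.0,  # photosynthetic quotient, mol O2 per mol CO2
        # gas-liquid transfer (per-gas kLa in 1/hr; Henry in mmol/L/bar at ~30 C)
        "kla": {"ch4": 6.0, "o2": 6.0, "co2": 6.0},
        "henry": {"ch4": 1.3, "o2": 1.1, "co2": 27.0},
        "V_L": 0.4,  # liquid volume, L
        "V_G": 0.6,  # headspace volume, L
        "temperature": 303.15,  # K
        "limitation": "product",  # or "minimum"
        "species_M": "M1",
        "species_C": "C1",
    }
    init = {
        "X_M": 0.010,  # gDCW/L
        "X_C": 0.030,
        "c": {"ch4": 0.0, "o2": 0.0, "co2": 0.0},
        "p": dict(BATCH_HEADSPACE),
    }
    scenario = {
        "name": name,
        "seed": int(seed),
        "params": params,
        "init": init,
        "t_end": 96.0,
        "output_interval": 1.0,
        "refeeds": [],
        "dfba": {
            "dt": 0.1,
            "couple_gases": True,
            # Michaelis-Menten uptake caps per species/substrate, with
            # multiplicative co-substrate factors for the methanotroph
            "uptake": {
                "M1": {
                    "ch4": {"vmax": 8.0, "km": 0.05, "modifiers": {"o2": 0.02}},
                    "o2": {"vmax": 10.4, "km": 0.02},
                },
                "C1": {"co2": {"vmax": 2.7, "km": 0.20}},
            },
        },
    }
    if name == "refeed":
        scenario["refeeds"] = [{"time": 72.0, "p": dict(BATCH_HEADSPACE)}]
    if name == "o2_limited":
        scenario["params"]["kla"] = {"ch4": 6.0, "o2": 0.0, "co2": 6.0}
        scenario["init"]["c"]["o2"] = 0.02
        scenario["init"]["c"]["ch4"] = 0.5  # dissolved CH4 already present
        scenario["t_end"] = 48.0
    return scenario


def make_recovery_design() -> tuple[dict, np.ndarray]:
    """Monoculture design for checking Monod parameter identifiability.

    A liquid-batch methanotroph monoculture (no gas transfer, O2 in excess)
    in which dissolved CH4 traverses the whole Monod-sensitive range: the
    early near-saturated phase pins mu_max while the gradual approach to
    depletion pins K. Returns (scenario, observation times): 30 samples over
    40 h, c_CH4(0) = 10 K_CH4. With only 2% multiplicative noise on biomass,
    designs that deplete CH4 abruptly (high kLa, small K) leave K poorly
    identified; this one recovers both parameters to within 10%.
    """
    scenario = make_scenario("batch_default")
    scenario["name"] = "recovery_design"
    scenario["init"]["X_M"] = 0.01
    scenario["init"]["X_C"] = 0.0
    scenario["init"]["c"] = {"ch4": 20.0, "o2": 500.0, "co2": 0.0}
    scenario["init"]["p"] = {"ch4": 0.0, "o2": 0.0, "co2": 0.0, "n2": 1.0}
    scenario["params"]["kla"] = {"ch4": 0.0, "o2": 0.0, "co2": 0.0}
    scenario["params"]["K_ch4"] = 2.0
    scenario["t_end"] = 40.0
    t_obs = np.linspace(0.0, 40.0, 30)
    return scenario, t_obs
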