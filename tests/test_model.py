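"""Stoichiometric model container, I/O, FBA/FVA and blocked-reaction removal."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import comgem as cg
from comgem.model import (
    Metabolite,
    Reaction,
    model_from_dict,
    model_to_dict,
    to_cobra,
)


class TestIO:
    def test_json_round_trip_is_lossless(self, toy_pair, tmp_path):
        for model in toy_pair:
            path = tmp_path / f"{model.species}.json"
            cg.write_model(model, path)
            back = cg.read_model(path)
            assert model_to_dict(back) == model_to_dict(model)

    def test_toy_methanotroph_counts(self, toy_pair):
        m, _ = toy_pair
        assert len(m.reactions) == 10
        assert len(m.metabolites) == 8

    def test_malformed_json_names_problem(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(cg.ParseError, match="JSON"):
            cg.read_model(bad)

    def test_missing_biomass_is_validation_error(self, toy_pair):
        doc = model_to_dict(toy_pair[0])
        doc["biomass_id"] = "NO_SUCH"
        with pytest.raises(cg.ValidationError, match="biomass"):
            model_from_dict(doc)

    def test_inverted_bounds_rejected(self, toy_pair):
        doc = model_to_dict(toy_pair[0])
        doc["reactions"][0]["lb"], doc["reactions"][0]["ub"] = 5.0, -5.0
        with pytest.raises(cg.ValidationError, match="lb"):
            model_from_dict(doc)

    def test_undeclared_metabolite_rejected(self, toy_pair):
        doc = model_to_dict(toy_pair[0])
        doc["reactions"][0]["stoich"]["ghost"] = 1.0
        with pytest.raises(cg.ValidationError, match="ghost"):
            model_from_dict(doc)

    def test_sbml_round_trip_preserves_optimum(self, toy_pair, tmp_path):
        import cobra.io

        m, _ = toy_pair
        path = tmp_path / "m.xml"
        cobra.io.write_sbml_model(to_cobra(m), str(path))
        back = cg.read_model(path, biomass_id="BIO_M", maintenance_id="ATPM_M")
        assert sorted(back.reaction_ids) == sorted(m.reaction_ids)
        mu_a = cg.fba(m, extra_bounds={"EX_ch4": (-40, 0)}).objective_value
        mu_b = cg.fba(back, extra_bounds={"EX_ch4": (-40, 0)}).objective_value
        assert mu_b == pytest.approx(mu_a, rel=1e-9)


class TestMaintenance:
    @pytest.mark.parametrize(
        "gam,ngam",
        [(23.0, 10.6), (23.0, 5.6), (60.0, 0.6), (40.0, 0.05)],
    )
    def test_published_maintenance_settings_apply(self, toy_pair, gam, ngam):
        """GAM lands in the biomass ATP coefficient, NGAM in the floor."""
        m = cg.set_maintenance(toy_pair[0], gam, ngam)
        assert m.reaction(m.maintenance_id).lb == ngam
        assert m.reaction(m.biomass_id).stoich["atp"] == -gam

    def test_zero_maintenance_leaves_optimum_unchanged(self, toy_pair):
        m = toy_pair[0]
        m0 = cg.set_maintenance(m, 0.0, 0.0)
        cap = {"EX_ch4": (-40, 0)}
        assert cg.fba(m0, extra_bounds=cap).objective_value == pytest.approx(
            cg.fba(m, extra_bounds=cap).objective_value
        )

    def test_negative_values_rejected(self, toy_pair):
        with pytest.raises(cg.ValidationError):
            cg.set_maintenance(toy_pair[0], -1.0, 0.0)
        with pytest.raises(cg.ValidationError):
            cg.set_maintenance(toy_pair[0], 0.0, -1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=30.0), st.floats(min_value=0.0, max_value=30.0))
    def test_higher_ngam_never_raises_optimum(self, toy_pair, ngam_lo, ngam_hi):
        """Maintenance is a pure burden: growth is monotone non-increasing in NGAM."""
        ngam_lo, ngam_hi = sorted((ngam_lo, ngam_hi))
        m = toy_pair[0]
        cap = {"EX_ch4": (-40, 0)}
        mu = [
            cg.fba(cg.set_maintenance(m, 0.0, ngam), extra_bounds=cap).objective_value
            for ngam in (ngam_lo, ngam_hi)
        ]
        assert mu[1] <= mu[0] + 1e-9


class TestFBA:
    def test_methane_limited_growth(self, toy_pair):
        sol = cg.fba(toy_pair[0], extra_bounds={"EX_ch4": (-40, 0)})
        assert sol.ok
        assert sol.objective_value == pytest.approx(1.0, rel=1e-9)

    def test_oxygen_becomes_limiting(self, toy_pair):
        sol = cg.fba(
            toy_pair[0], extra_bounds={"EX_ch4": (-40, 0), "EX_o2": (-26, 0)}
        )
        assert sol.objective_value == pytest.approx(0.5, rel=1e-9)

    def test_agrees_with_independent_solver(self, toy_pair):
        """Dual-route check: the HiGHS-based FBA against cobra/GLPK."""
        m, c = toy_pair
        for model, caps in (
            (m, {"EX_ch4": (-40, 0), "EX_o2": (-30, 0)}),
            (c, {"EX_co2": (-45, 0)}),
        ):
            ours = cg.fba(model, extra_bounds=caps).objective_value
            cm = to_cobra(model)
            for rid, (lb, ub) in caps.items():
                rxn = cm.reactions.get_by_id(rid)
                rxn.lower_bound, rxn.upper_bound = lb, ub
            theirs = cm.optimize().objective_value
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_no_carbon_source_no_growth(self, toy_pair):
        for model in toy_pair:
            closed = {rid: (0.0, 1000.0) for rid in model.boundary_ids}
            sol = cg.fba(model, extra_bounds=closed)
            assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_and_bounds_hold_at_optimum(self, toy_pair):
        model = toy_pair[0]
        extra = {"EX_ch4": (-40, 0)}
        sol = cg.fba(model, extra_bounds=extra)
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        assert np.abs(model.stoichiometric_matrix() @ v).max() <= 1e-6
        for r in model.reactions:
            lb, ub = extra.get(r.id, (r.lb, r.ub))
            assert lb - 1e-8 <= sol.fluxes[r.id] <= ub + 1e-8

    def test_infeasible_and_unbounded_status(self, toy_pair):
        m = toy_pair[0]
        # NGAM demands ATP but every carbon/energy source is shut
        burdened = cg.set_maintenance(m, 0.0, 5.0)
        closed = {rid: (0.0, 0.0) for rid in burdened.boundary_ids}
        assert cg.fba(burdened, extra_bounds=closed).status == "infeasible"
        wide = {
            "RESP_M": (0.0, np.inf),
            "ATPM_M": (0.0, np.inf),
            "EX_ch4": (-np.inf, 0),
            "EX_o2": (-np.inf, 0),
            "EX_co2": (0, np.inf),
        }
        sol = cg.fba(m, objective="RESP_M", extra_bounds=wide)
        assert sol.status == "unbounded"

    def test_unknown_objective_raises(self, toy_pair):
        with pytest.raises(KeyError):
            cg.fba(toy_pair[0], objective="NOPE")


class TestFVA:
    def test_blocked_sink_has_zero_range(self, toy_pair):
        m = toy_pair[0].copy()
        m.metabolites = m.metabolites + [Metabolite("orphan", "c")]
        m.reactions = m.reactions + [Reaction("SINK", {"orphan": -1.0}, 0.0, 1000.0)]
        lo, hi = cg.fva(m, ["SINK"])["SINK"]
        assert (lo, hi) == (0.0, 0.0)

    def test_optimum_pins_biomass_range(self, toy_pair):
        m = toy_pair[0]
        cap = {"EX_ch4": (-40, 0)}
        mu = cg.fba(m, extra_bounds=cap).objective_value
        lo, hi = cg.fva(m, [m.biomass_id], frac_opt=1.0, extra_bounds=cap)[m.biomass_id]
        assert lo == pytest.approx(mu, abs=1e-6)
        assert hi == pytest.approx(mu, abs=1e-6)

    def test_both_nitrogen_routes_can_carry_flux(self, toy_pair):
        ranges = cg.fva(toy_pair[0], ["R_NH4", "R_NO3"], frac_opt=0.0)
        for rid in ("R_NH4", "R_NO3"):
            assert ranges[rid][1] > 1e-6

    def test_fva_brackets_fba_fluxes_at_optimum(self, toy_pair):
        m = toy_pair[0]
        cap = {"EX_ch4": (-40, 0)}
        sol = cg.fba(m, extra_bounds=cap)
        ranges = cg.fva(m, frac_opt=1.0, extra_bounds=cap)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6
        assert lo <= hi

    def test_bad_frac_opt_rejected(self, toy_pair):
        with pytest.raises(ValueError):
            cg.fva(toy_pair[0], frac_opt=1.5)


class TestBlockedRemoval:
    def _with_dead_ends(self, model):
        m = model.copy()
        m.metabolites = m.metabolites + [Metabolite("orp1", "c"), Metabolite("orp2", "c")]
        m.reactions = m.reactions + [
            Reaction("DEAD1", {"orp1": 1.0}, 0.0, 1000.0),
            Reaction("DEAD2", {"orp1": -1.0, "orp2": 1.0}, 0.0, 1000.0),
            Reaction("DEAD3", {"orp2": -1.0, "atp": 1.0}, 0.0, 0.0),
        ]
        return m

    def test_injected_dead_ends_are_exactly_removed(self, toy_pair):
        m = self._with_dead_ends(toy_pair[0])
        reduced, removed = cg.remove_blocked_reactions(m)
        assert sorted(removed) == ["DEAD1", "DEAD2", "DEAD3"]
        assert sorted(reduced.reaction_ids) == sorted(toy_pair[0].reaction_ids)
        assert not any(met.id.startswith("orp") for met in reduced.metabolites)

    def test_clean_model_unchanged(self, toy_pair):
        for model in toy_pair:
            reduced, removed = cg.remove_blocked_reactions(model)
            assert removed == []
            assert model_to_dict(reduced) == model_to_dict(model)

    def test_optimum_invariant_under_reduction(self, toy_pair):
        m = self._with_dead_ends(toy_pair[0])
        reduced, _ = cg.remove_blocked_reactions(m)
        cap = {"EX_ch4": (-40, 0)}
        assert cg.fba(reduced, extra_bounds=cap).objective_value == pytest.approx(
            cg.fba(m, extra_bounds=cap).objective_value, rel=1e-9
        )
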