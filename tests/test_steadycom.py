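"""SteadyCom: bisection LP, fixed-composition solves, cross-feeding extraction."""

import numpy as np
import pytest

import comgem as cg
from conftest import (
    CH4_UPTAKE_STAR,
    MEASURED_BOUNDS,
    MU_MODE_B,
    MU_STAR,
    NH4_CROSSFEED_STAR,
    X_C_STAR,
    X_M_STAR,
)


class TestLPAtMu:
    def test_zero_growth_caps_at_one(self, open_community):
        total, sol = cg.steadycom_lp_at_mu(open_community, 0.0)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert sol.ok

    def test_abundance_just_below_one_near_optimum(self, toy_community):
        # at mu slightly above the optimum the fixed CO2 demand cannot be met
        # by a full unit of biomass: max total abundance = mu*/mu < 1
        total, _ = cg.steadycom_lp_at_mu(toy_community, 0.0367)
        assert total == pytest.approx(MU_STAR / 0.0367, rel=1e-7)
        assert total < 1.0

    def test_unreachable_growth_is_infeasible(self, toy_community):
        total, sol = cg.steadycom_lp_at_mu(toy_community, 10.0)
        assert total == 0.0
        assert sol.status == "infeasible"

    def test_negative_mu_rejected(self, toy_community):
        with pytest.raises(ValueError):
            cg.steadycom_lp_at_mu(toy_community, -0.1)


class TestSolve:
    def test_hand_oracle_optimum(self, steadycom_solution):
        """Frozen hand linear-algebra solution of the measured-rate setup."""
        sol = steadycom_solution
        assert sol.ok
        assert sol.mu == pytest.approx(MU_STAR, rel=1e-6)
        assert sol.abundances["M1"] == pytest.approx(X_M_STAR, rel=1e-6)
        assert sol.abundances["C1"] == pytest.approx(X_C_STAR, rel=1e-6)
        assert sum(sol.abundances.values()) == pytest.approx(1.0, abs=1e-6)
        assert -sol.exchange["ch4"] == pytest.approx(CH4_UPTAKE_STAR, rel=1e-6)

    def test_single_species_reduces_to_fba(self, toy_pair):
        """A one-member 'community' with a fixed CO2 uptake equals monoculture
        FBA at that uptake."""
        _, c = toy_pair
        (ch,) = cg.harmonize_ids([c])
        com = cg.build_community(
            [ch],
            cg.ExchangePolicy(
                whitelist=("co2", "o2", "photon", "nh4", "no3"),
                bounds={"co2": (-45.0, 0.0)},
            ),
        )
        sol = cg.solve_steadycom(com)
        mono = cg.fba(c, extra_bounds={"EX_co2": (-45.0, 0.0)})
        assert sol.mu == pytest.approx(mono.objective_value, rel=1e-6)

    def test_inconsistent_constraints_error(self, toy_pair):
        """A fixed CO2 uptake with no light to fix it is unsatisfiable at
        every growth rate."""
        m, c = toy_pair
        com = cg.build_community(
            cg.harmonize_ids([m, c]),
            cg.ExchangePolicy(
                whitelist=("ch4", "o2", "co2", "photon", "nh4", "no3"),
                bounds={"co2": (-0.680, -0.680), "photon": (0.0, 0.0)},
            ),
        )
        with pytest.raises(cg.ConstraintsInconsistentError, match="inconsistent"):
            cg.solve_steadycom(com)

    def test_feasibility_is_monotone_below_optimum(self, toy_pair):
        """With the CO2 constraint as a capacity (not an equality), any mu
        below the optimum stays feasible and any mu above fails."""
        m, c = toy_pair
        com = cg.build_community(
            cg.harmonize_ids([m, c]),
            cg.ExchangePolicy(
                whitelist=("ch4", "o2", "co2", "photon", "nh4", "no3"),
                bounds={"o2": (0.0, 0.0), "co2": (-0.680, 0.0), "nh4": (0.0, 1000.0)},
            ),
        )
        for mu in np.linspace(0.0, MU_STAR * 0.999, 7):
            total, _ = cg.steadycom_lp_at_mu(com, mu, cap=100.0)
            assert total >= 1.0 - 1e-9, f"feasible mu {mu} reported infeasible"
        for mu in (MU_STAR * 1.001, MU_STAR * 1.5, 1.0):
            total, _ = cg.steadycom_lp_at_mu(com, mu, cap=100.0)
            assert total < 1.0 - 1e-9, f"infeasible mu {mu} reported feasible"


class TestFixedComposition:
    def test_reproduces_equal_growth_optimum(self, toy_community, steadycom_solution):
        sol = steadycom_solution
        fixed = cg.solve_fixed_composition(
            toy_community,
            sol.abundances,
            {k: sol.mu for k in toy_community.members},
        )
        assert fixed.ok
        for k in sol.transport:
            for met, v in sol.transport[k].items():
                assert fixed.transport[k][met] == pytest.approx(v, abs=1e-6)

    def test_dormant_community_has_zero_fluxes(self, open_community):
        fixed = cg.solve_fixed_composition(
            open_community,
            {"M1": 0.5, "C1": 0.5},
            {"M1": 0.0, "C1": 0.0},
            rate_constraints={
                ("M1", "ch4"): (0.0, 0.0),
                ("M1", "o2"): (0.0, 0.0),
                ("C1", "co2"): (0.0, 0.0),
            },
        )
        assert fixed.ok
        assert max(abs(v) for v in fixed.fluxes.values()) <= 1e-9

    def test_nitrogen_shortfall_names_the_balance(self, toy_pair):
        """With every nitrogen source closed, growth demands cannot close the
        N balances and the diagnosis says which."""
        m, c = toy_pair
        com = cg.build_community(
            cg.harmonize_ids([m, c]),
            cg.ExchangePolicy(
                whitelist=("ch4", "o2", "co2", "photon", "nh4", "no3"),
                bounds={"nh4": (0.0, 0.0), "no3": (0.0, 0.0)},
            ),
        )
        fixed = cg.solve_fixed_composition(
            com, {"M1": 0.5, "C1": 0.5}, {"M1": 0.05, "C1": 0.05}
        )
        assert fixed.status == "infeasible"
        assert any(tag in fixed.message for tag in ("nh4", "no3", "nx"))

    def test_bad_abundances_rejected(self, open_community):
        with pytest.raises(ValueError, match="sum to 1"):
            cg.solve_fixed_composition(
                open_community, {"M1": 0.7, "C1": 0.7}, {"M1": 0.0, "C1": 0.0}
            )


class TestCrossFeeding:
    def test_optimum_records_nh4_o2_co2_mutualism(self, steadycom_solution):
        records = cg.extract_crossfeeding(steadycom_solution, positive_species="M1")
        by_pair = {(r.metabolite, r.producer, r.consumer): r for r in records}
        nh4 = by_pair[("nh4", "C1", "M1")]
        assert nh4.flux == pytest.approx(NH4_CROSSFEED_STAR, rel=1e-6)
        assert nh4.signed == pytest.approx(-NH4_CROSSFEED_STAR, rel=1e-6)
        o2 = by_pair[("o2", "C1", "M1")]
        assert o2.flux == pytest.approx(52.0 * MU_STAR * X_M_STAR, rel=1e-6)
        assert ("co2", "M1", "C1") in by_pair  # methanotroph CO2 feeds the phototroph
        assert by_pair[("co2", "M1", "C1")].signed > 0

    def test_closed_exchange_producer_equals_consumer(self, steadycom_solution):
        """Net O2 exchange is (0,0): phototroph production must exactly match
        methanotroph consumption."""
        sol = steadycom_solution
        assert sol.transport["C1"]["o2"] == pytest.approx(
            -sol.transport["M1"]["o2"], abs=1e-9
        )

    def test_empty_whitelist_gives_no_records(self, toy_pair):
        com = cg.build_community(
            cg.harmonize_ids(list(toy_pair)), cg.ExchangePolicy(whitelist=())
        )
        sol = cg.solve_fixed_composition(com, {"M1": 0.5, "C1": 0.5}, {"M1": 0.0, "C1": 0.0})
        assert cg.extract_crossfeeding(sol) == []

    def test_environment_consumer_convention(self, toy_pair):
        """A metabolite excreted to [u] and leaving the system is recorded
        with consumer = environment."""
        _, c = toy_pair
        (ch,) = cg.harmonize_ids([c])
        com = cg.build_community(
            [ch],
            cg.ExchangePolicy(whitelist=("co2", "o2", "photon", "nh4", "no3")),
        )
        sol = cg.solve_fixed_composition(com, {"C1": 1.0}, {"C1": 0.01})
        records = cg.extract_crossfeeding(sol, positive_species="M1")
        o2 = [r for r in records if r.metabolite == "o2"]
        assert o2 and o2[0].producer == "C1" and o2[0].consumer == "environment"
        assert o2[0].signed < 0


class TestEmergentNitrogenExchange:
    def test_blocking_ammonium_transport_lowers_growth(self, toy_community):
        """The optimal community routes the methanotroph's nitrogen through
        phototroph-produced ammonium; forcing the nitrate route strictly
        lowers the optimum to the hand-computed forced-nitrate value."""
        blocked = toy_community.copy()
        tr = blocked.reaction(blocked.transports[("M1", "nh4")])
        tr.lb = tr.ub = 0.0
        sol_b = cg.solve_steadycom(blocked)
        assert sol_b.mu == pytest.approx(MU_MODE_B, rel=1e-6)
        assert sol_b.mu < MU_STAR
        assert sol_b.abundances["M1"] == pytest.approx(45.0 / 101.0, rel=1e-6)

    def test_bisection_matches_brute_force_on_perturbed_instances(self):
        """Seeded random perturbations: the bisection optimum agrees with a
        brute-force feasibility scan over mu."""
        tol = 1e-6
        for seed in range(5):
            m, c = cg.fixtures.perturb_toybin1(seed)
            com = cg.build_community(
                cg.harmonize_ids([m, c]),
                cg.ExchangePolicy(
                    whitelist=("ch4", "o2", "co2", "photon", "nh4", "no3"),
                    bounds={
                        "o2": (0.0, 0.0),
                        "co2": (-0.680, 0.0),
                        "nh4": (0.0, 1000.0),
                    },
                ),
            )
            sol = cg.solve_steadycom(com, tol=tol)
            step = 1e-5
            grid = np.arange(sol.mu - 30 * step, sol.mu + 30 * step, step)
            feasible = [
                mu
                for mu in grid
                if mu >= 0 and cg.steadycom_lp_at_mu(com, mu, cap=100.0)[0] >= 1.0 - 1e-9
            ]
            assert feasible, f"seed {seed}: nothing feasible near bisection optimum"
            scan_max = max(feasible)
            assert abs(scan_max - sol.mu) <= step + tol, f"seed {seed}"
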