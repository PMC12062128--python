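"""FBA / pFBA / FVA / sampling engine, checked against hand LPs, a
brute-force vertex oracle and cobrapy as an independent implementation."""

import numpy as np
import pytest

from egflux import fba_engine as fe
from egflux import model_core as mc

from conftest import make_toy_model


def _cs(model, rates):
    return fe.apply_measured_rates(model, rates)


GLC_RATES = {"EX_glc__D_e": -1.0, "EX_eg_e": -0.2, "EX_glyclt_e": 0.2,
             "EX_xyl__D_e": 0.0}


class TestConstraints:
    def test_fixed_rate_sets_two_sided_bound(self, core_model):
        cs = _cs(core_model, {"EX_eg_e": -1.0})
        assert cs.bounds["EX_eg_e"] == (-1.0, -1.0)
        assert cs.provenance["EX_eg_e"] == "measured"

    def test_empty_rates_keep_model_defaults(self, core_model):
        cs = _cs(core_model, {})
        resolved = cs.resolved(core_model)
        for rid, rxn in core_model.reactions.items():
            assert resolved[rid] == (rxn.lower_bound, rxn.upper_bound)

    def test_unknown_reaction_rejected(self, core_model):
        with pytest.raises(KeyError, match="nope"):
            _cs(core_model, {"nope": 1.0})


class TestFBA:
    def test_toy_chain_objective_is_uptake_capacity(self, toy_chain):
        sol = fe.solve_fba(toy_chain)
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_blocked_transport_zeroes_objective(self, toy_chain):
        cs = fe.FluxConstraintSet({"T_a": (0.0, 0.0)})
        sol = fe.solve_fba(toy_chain, cs)
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_contradictory_fixed_constraint_is_infeasible(self, toy_chain):
        # the exchange only allows uptake (ub 0); forcing secretion +1
        cs = fe.FluxConstraintSet({"EX_a": (1.0, 1.0), "T_a": (0.0, 0.0)})
        sol = fe.solve_fba(toy_chain, cs)
        assert sol.status == "infeasible"

    def test_steady_state_within_tolerance(self, core_model):
        sol = fe.solve_fba(core_model, _cs(core_model, GLC_RATES))
        S, met_ids, rxn_ids = core_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r] for r in rxn_ids])
        assert np.max(np.abs(S @ v)) < fe.FEASIBILITY_TOL

    def test_matches_vertex_enumeration_oracle(self, vertex_oracle,
                                               toy_chain, toy_parallel):
        """On tiny networks the LP optimum must equal the best vertex of
        the exhaustively enumerated flux polytope."""
        for model in (toy_chain, toy_parallel):
            S, _, rxn_ids = model.stoichiometric_matrix()
            lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
            ub = np.array([min(model.reactions[r].upper_bound, 50.0)
                           for r in rxn_ids])
            cs = fe.FluxConstraintSet(
                {r: (l, u) for r, l, u in zip(rxn_ids, lb, ub)})
            vertices = vertex_oracle(S, lb, ub)
            assert vertices, "oracle found no vertices"
            iobj = rxn_ids.index(model.objective_id)
            best = max(v[iobj] for v in vertices)
            sol = fe.solve_fba(model, cs)
            assert sol.objective_value == pytest.approx(best, abs=1e-7)


class TestPFBA:
    def test_diamond_takes_one_step_route(self, toy_diamond):
        """Brute force over the two route assignments: pushing 10 via the
        direct arc costs total flux 30 (uptake+transport+route), via the
        two-arc detour 40; parsimony must choose the direct arc."""
        sol = fe.solve_pfba(toy_diamond)
        assert sol.ok
        assert sol.fluxes["DIRECT"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["VIA1"] == pytest.approx(0.0, abs=1e-6)
        assert sol.fluxes["VIA2"] == pytest.approx(0.0, abs=1e-6)

    def test_growth_matches_fba_within_1e9(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        fba = fe.solve_fba(core_model, cs)
        pfba = fe.solve_pfba(core_model, cs)
        assert pfba.objective_value == pytest.approx(
            fba.objective_value, rel=1e-9, abs=1e-12)

    def test_total_flux_not_above_sampled_points(self, core_model):
        """pFBA total |flux| is minimal among feasible points at the same
        growth: every sampled alternate optimum carries at least as much."""
        cs = _cs(core_model, GLC_RATES)
        pfba = fe.solve_pfba(core_model, cs)
        cs_fixed = fe.apply_measured_rates(
            core_model, {"BIOMASS": pfba.objective_value}, base=cs)
        summary = fe.sample_solution_space(core_model, cs_fixed, n=50,
                                           growth_fraction=1.0, seed=11,
                                           return_points=True)
        total_pfba = sum(abs(v) for v in pfba.fluxes.values())
        totals = np.abs(summary.points).sum(axis=1)
        assert np.all(totals >= total_pfba - 1e-5)

    def test_glucose_condition_routes_all_eg_through_nadp(self, core_model):
        """With glucose fixed and EG/GA exchanges fixed equimolar, the
        NADPH demand of biomass makes the NADP-dependent dehydrogenase
        carry all EG-oxidation flux."""
        sol = fe.solve_pfba(core_model, _cs(core_model, GLC_RATES))
        frac = fe.route_fraction(sol, ["EGDH_NADP"],
                                 ["EGDH_NAD", "EGDH_NADP"])
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_infeasibility_propagates(self, toy_chain):
        cs = fe.FluxConstraintSet({"EX_a": (1.0, 1.0), "T_a": (0.0, 0.0)})
        sol = fe.solve_pfba(toy_chain, cs)
        assert sol.status == "infeasible"


class TestFVA:
    def test_fixed_reaction_interval_collapses(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        fva = fe.flux_variability(core_model, cs, reactions=["EX_glc__D_e"])
        assert fva["EX_glc__D_e"][0] == pytest.approx(-1.0, abs=1e-8)
        assert fva["EX_glc__D_e"][1] == pytest.approx(-1.0, abs=1e-8)

    def test_parallel_routes_range_zero_to_demand(self, toy_parallel):
        cs = fe.FluxConstraintSet({"BIO": (10.0, 10.0)})
        fva = fe.flux_variability(toy_parallel, cs, growth_fraction=1.0,
                                  reactions=["R1", "R2"])
        for rid in ("R1", "R2"):
            assert fva[rid][0] == pytest.approx(0.0, abs=1e-8)
            assert fva[rid][1] == pytest.approx(10.0, abs=1e-8)

    def test_no_gah_from_xylose_without_xylulose1p_route(self):
        """Without the xylulose-1P aldolase and without EG, no reaction
        can produce cytosolic glycolaldehyde from xylose carbon."""
        m = mc.build_core_model(("NAD", "NADP"), xylulose1p_route=False)
        cs = fe.apply_measured_rates(m, {"EX_xyl__D_e": -1.0,
                                         "EX_eg_e": 0.0,
                                         "EX_glc__D_e": 0.0})
        fva = fe.flux_variability(m, cs, growth_fraction=0.0,
                                  reactions=["EGDH_NAD", "EGDH_NADP", "GRE2R"])
        # GAH producers: the EG dehydrogenases (forward); all stuck at 0
        for rid in ("EGDH_NAD", "EGDH_NADP"):
            assert fva[rid][1] == pytest.approx(0.0, abs=1e-8)

    def test_gah_from_xylose_with_route_enabled(self):
        m = mc.build_core_model(("NAD", "NADP"), xylulose1p_route=True)
        cs = fe.apply_measured_rates(m, {"EX_xyl__D_e": -1.0,
                                         "EX_eg_e": 0.0,
                                         "EX_glc__D_e": 0.0})
        fva = fe.flux_variability(m, cs, growth_fraction=0.0,
                                  reactions=["XU1PA"])
        assert fva["XU1PA"][1] > 0.1


class TestSampling:
    def test_same_seed_reproduces_summary(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        a = fe.sample_solution_space(core_model, cs, n=60, seed=7)
        b = fe.sample_solution_space(core_model, cs, n=60, seed=7)
        assert a == b

    def test_different_seed_differs(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        a = fe.sample_solution_space(core_model, cs, n=60, seed=7)
        b = fe.sample_solution_space(core_model, cs, n=60, seed=8)
        assert a != b

    def test_samples_feasible_and_within_fva(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        summary = fe.sample_solution_space(core_model, cs, n=80, seed=3,
                                           return_points=True)
        S, _, rxn_ids = core_model.stoichiometric_matrix()
        residual = np.max(np.abs(summary.points @ S.T))
        assert residual < fe.FEASIBILITY_TOL
        opt = fe.solve_fba(core_model, cs).objective_value
        growth = summary.points[:, summary.reaction_ids.index("BIOMASS")]
        assert np.all(growth >= 0.9 * opt - 1e-6)
        fva = fe.flux_variability(core_model, cs)
        for j, rid in enumerate(summary.reaction_ids):
            lo, hi = fva[rid]
            col = summary.points[:, j]
            assert col.min() >= lo - 1e-6
            assert col.max() <= hi + 1e-6

    def test_fixed_flux_reaction_has_zero_sd(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        summary = fe.sample_solution_space(core_model, cs, n=40, seed=5)
        med, sd, lo, hi = summary.stats["EX_glc__D_e"]
        assert med == pytest.approx(-1.0, abs=1e-8)
        assert sd == pytest.approx(0.0, abs=1e-8)

    def test_median_between_min_and_max(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        summary = fe.sample_solution_space(core_model, cs, n=40, seed=5)
        for med, sd, lo, hi in summary.stats.values():
            assert lo - 1e-12 <= med <= hi + 1e-12

    def test_seed_required(self, core_model):
        with pytest.raises(ValueError, match="seed"):
            fe.sample_solution_space(core_model, _cs(core_model, GLC_RATES),
                                     n=10, seed=None)

    def test_too_few_samples_rejected(self, core_model):
        with pytest.raises(ValueError):
            fe.sample_solution_space(core_model, _cs(core_model, GLC_RATES),
                                     n=1, seed=1)


class TestReporting:
    def test_normalize_identity_at_unit_uptake(self):
        out = fe.normalize_by_uptake({"EX_s": -1.0, "R": 0.46}, "EX_s")
        assert out["R"] == pytest.approx(0.46)

    def test_normalize_scales_to_figure_labels(self):
        # 0.46 mmol/gCDW/h over 2.0 uptake -> normalized flux 0.23
        out = fe.normalize_by_uptake({"EX_s": -2.0, "ICLp": 0.46}, "EX_s")
        assert out["ICLp"] == pytest.approx(0.23)

    def test_normalize_zero_uptake_raises(self):
        with pytest.raises(ZeroDivisionError):
            fe.normalize_by_uptake({"EX_s": 0.0}, "EX_s")

    def test_route_fraction_examples(self):
        assert fe.route_fraction({"a": 1.0, "b": 0.0}, ["a"], ["a", "b"]) == 1.0
        assert fe.route_fraction({"a": 0.92, "b": 0.08}, ["a"], ["a", "b"]) \
            == pytest.approx(0.92)
        with pytest.raises(ZeroDivisionError):
            fe.route_fraction({"a": 0.0}, ["a"], ["a"])

    def test_route_fraction_subset_bounded_by_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fluxes = {f"r{i}": float(v)
                      for i, v in enumerate(rng.normal(size=5))}
            frac = fe.route_fraction(fluxes, ["r0", "r1"], list(fluxes))
            assert 0.0 <= frac <= 1.0 + 1e-12

    def test_rate_table_roundtrip(self, tmp_path):
        p = tmp_path / "rates.tsv"
        p.write_text("reaction\tvalue\nEX_glc__D_e\t-1.5\nEX_eg_e\t-0.2\n")
        rates = fe.read_rate_table(p)
        assert rates == {"EX_glc__D_e": -1.5, "EX_eg_e": -0.2}


class TestAgainstCobra:
    """cobrapy (GLPK) as an independent implementation on the same
    network; our engine is scipy/HiGHS, so agreement is a genuine
    cross-check, not self-comparison."""

    @staticmethod
    def to_cobra(model):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("core")
        mets = {mid: cobra.Metabolite(mid, compartment=m.compartment)
                for mid, m in model.metabolites.items()}
        rxns = []
        for rid, r in model.reactions.items():
            cr = cobra.Reaction(rid, lower_bound=r.lower_bound,
                                upper_bound=r.upper_bound)
            rxns.append(cr)
        cm.add_reactions(rxns)
        for rid, r in model.reactions.items():
            cm.reactions.get_by_id(rid).add_metabolites(
                {mets[mid]: c for mid, c in r.stoichiometry.items()})
        cm.objective = model.objective_id
        return cm

    def test_fba_optimum_matches_cobra(self, core_model):
        cs = _cs(core_model, GLC_RATES)
        ours = fe.solve_fba(core_model, cs)
        cm = self.to_cobra(core_model)
        for rid, value in GLC_RATES.items():
            cm.reactions.get_by_id(rid).bounds = (value, value)
        theirs = cm.optimize()
        assert theirs.status == "optimal"
        assert ours.objective_value == pytest.approx(
            theirs.objective_value, rel=1e-6)

    def test_pfba_total_flux_matches_cobra(self, core_model):
        from cobra.flux_analysis import pfba as cobra_pfba
        cs = _cs(core_model, GLC_RATES)
        ours = fe.solve_pfba(core_model, cs)
        cm = self.to_cobra(core_model)
        for rid, value in GLC_RATES.items():
            cm.reactions.get_by_id(rid).bounds = (value, value)
        theirs = cobra_pfba(cm)
        total_ours = sum(abs(v) for v in ours.fluxes.values())
        total_theirs = sum(abs(v) for v in theirs.fluxes)
        assert total_ours == pytest.approx(total_theirs, rel=1e-4)
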