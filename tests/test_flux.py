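"""Expression-constrained FBA, LP oracles, differential flux."""

import numpy as np
import pandas as pd
import pytest

from omicsflux import flux as fx
from omicsflux.expression import DETable, compute_rpkm, differential_expression
from omicsflux.model_io import FluxDistribution, parse_gpr
from omicsflux.synthetic_data import (make_toy_network, random_feasible_model,
                                      simulate_study)


def group_map(columns):
    return {c: c.rsplit("_", 1)[0] for c in columns}


# ---------------------------------------------------------------------------
# GPR aggregation
# ---------------------------------------------------------------------------

class TestAggregateGpr:
    def test_and_takes_the_scarcest_subunit(self):
        assert fx.aggregate_gpr_expression(
            parse_gpr("g1 and g2"), {"g1": 3.0, "g2": 7.0}) == 3.0

    def test_or_sums_isozymes(self):
        assert fx.aggregate_gpr_expression(
            parse_gpr("g1 or g2"), {"g1": 3.0, "g2": 7.0}) == 10.0

    def test_single_leaf_passes_through(self):
        assert fx.aggregate_gpr_expression(parse_gpr("g1"), {"g1": 5.0}) == 5.0

    def test_missing_gene_zeroes_an_and(self):
        assert fx.aggregate_gpr_expression(
            parse_gpr("g1 and gX"), {"g1": 9.0}) == 0.0

    def test_missing_gene_ignored_under_or(self):
        assert fx.aggregate_gpr_expression(
            parse_gpr("g1 or gX"), {"g1": 9.0}) == 9.0

    def test_nested_rule(self):
        # min(4, 2 + 5) over OR of gX (absent -> skipped) and gY
        expr = parse_gpr("gA and (gB or gC)")
        assert fx.aggregate_gpr_expression(
            expr, {"gA": 4.0, "gB": 2.0, "gC": 5.0}) == 4.0


# ---------------------------------------------------------------------------
# Expression-derived bounds
# ---------------------------------------------------------------------------

class TestExpressionToBounds:
    def test_zero_expression_closes_the_reaction(self, toy_model):
        bounds = fx.expression_to_bounds(toy_model, {"g1": 0.0}, k=1.0)
        assert (bounds.lower["R1"], bounds.upper["R1"]) == (0.0, 0.0)

    def test_cap_is_k_times_expression(self, toy_model):
        bounds = fx.expression_to_bounds(toy_model, {"g1": 5.0}, k=1.0)
        assert bounds.upper["R1"] == 5.0

    def test_doubling_k_doubles_binding_caps(self, toy_model):
        e = {"g1": 5.0, "g2a": 2.0, "g2b": 1.0}
        b1 = fx.expression_to_bounds(toy_model, e, k=1.0)
        b2 = fx.expression_to_bounds(toy_model, e, k=2.0)
        for rid, agg in b1.provenance.items():
            if b1.upper[rid] < toy_model.reaction(rid).upper_bound:
                assert b2.upper[rid] == pytest.approx(2 * b1.upper[rid])

    def test_gprless_reactions_untouched(self, toy_model):
        bounds = fx.expression_to_bounds(toy_model, {}, k=1.0)
        assert bounds.upper["EX_A"] == 10.0
        assert "EX_A" not in bounds.provenance

    def test_reversible_reaction_gets_symmetric_bounds(self, toy_model):
        toy_model.reaction("R1").lower_bound = -1000.0
        bounds = fx.expression_to_bounds(toy_model, {"g1": 4.0}, k=1.0)
        assert (bounds.lower["R1"], bounds.upper["R1"]) == (-4.0, 4.0)

    def test_nonpositive_k_rejected(self, toy_model):
        with pytest.raises(ValueError):
            fx.expression_to_bounds(toy_model, {}, k=0.0)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

class TestFba:
    def test_chain_biomass_equals_binding_enzymatic_cap(self, chain_model):
        sol = fx.fba(chain_model)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-8)
        assert sol.fluxes["R1"] == pytest.approx(5.0, abs=1e-6)

    def test_closed_uptake_means_no_growth(self, chain_model):
        chain_model.reaction("EX_A").upper_bound = 0.0
        sol = fx.fba(chain_model)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_diamond_tie_break_is_deterministic_and_shares_load(self, diamond_model):
        """Total demand 4 over two routes capped at 3: the vertex solutions
        are (1,3) and (3,1); after L1 + lexicographic tie-breaking both
        routes carry >= 1 and repeated solves are bit-identical."""
        sol1 = fx.fba(diamond_model)
        sol2 = fx.fba(diamond_model)
        assert (sol1.fluxes == sol2.fluxes).all()
        assert sol1.fluxes["Ra"] + sol1.fluxes["Rb"] == pytest.approx(4.0, abs=1e-6)
        assert sol1.fluxes["Ra"] >= 1.0 - 1e-6
        assert sol1.fluxes["Rb"] >= 1.0 - 1e-6

    def test_steady_state_and_bounds_hold(self, toy_model):
        sol = fx.fba(toy_model)
        S = toy_model.stoichiometric_matrix()
        v = sol.fluxes.to_numpy()
        assert np.abs(S @ v).max() <= 1e-6
        for rxn in toy_model.reactions:
            assert rxn.lower_bound - 1e-9 <= sol.fluxes[rxn.id] <= rxn.upper_bound + 1e-9

    def test_infeasible_bounds_reported(self, chain_model):
        # force consumption of A with no production possible
        chain_model.reaction("EX_A").upper_bound = 0.0
        chain_model.reaction("biomass").lower_bound = 1.0
        with pytest.raises(fx.InfeasibleModelError):
            fx.fba(chain_model)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_models(self, seed):
        """The HiGHS-based solver and the exhaustive vertex-enumeration
        oracle agree to 1e-8 on random small feasible models, and each
        solution is balanced to 1e-6."""
        model = random_feasible_model(seed)
        sol = fx.fba(model)
        oracle = fx.brute_force_fba_objective(model)
        assert oracle is not None
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)
        S = model.stoichiometric_matrix()
        assert np.abs(S @ sol.fluxes.to_numpy()).max() <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_relaxing_an_upper_bound_never_hurts(self, seed):
        model = random_feasible_model(seed)
        base = fx.fba(model).objective_value
        for rxn in model.reactions:
            relaxed = model.copy()
            relaxed.reaction(rxn.id).upper_bound += 5.0
            assert fx.fba(relaxed).objective_value >= base - 1e-8

    def test_cobra_cross_check_on_cycle_toy(self):
        """Independent solver route: cobra's FBA optimum on the translated
        cycle toy matches ours."""
        cobra = pytest.importorskip("cobra")
        model = make_toy_network(3, with_cycle_motif=True, seed=5)
        cm = cobra.Model("toy")
        mets = {m: cobra.Metabolite(m, compartment="c")
                for m in model.metabolite_ids}
        rxns = []
        for r in model.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound,
                                upper_bound=r.upper_bound)
            cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
            rxns.append(cr)
        cm.add_reactions(rxns)
        cm.objective = model.objective_reaction
        assert fx.fba(model).objective_value == pytest.approx(
            cm.optimize().objective_value, abs=1e-6)


# ---------------------------------------------------------------------------
# auto_k
# ---------------------------------------------------------------------------

class TestAutoK:
    def test_pins_95th_percentile_cap_to_target(self):
        study = simulate_study(seed=1)
        expr = compute_rpkm(study.counts, study.gene_lengths,
                            sample_groups=study.sample_groups)
        k = fx.auto_k(study.model, expr, target_cap=10.0)
        aggs = []
        for s in expr.values.columns:
            emap = expr.sample_expression(s)
            for rxn in study.model.reactions:
                if rxn.gpr is not None and not rxn.exchange:
                    aggs.append(fx.aggregate_gpr_expression(rxn.gpr, emap))
        assert k * np.percentile([a for a in aggs if a > 0], 95) == \
            pytest.approx(10.0)

    def test_all_zero_expression_rejected(self, toy_model):
        vals = pd.DataFrame(0.0, index=["g1", "g2a", "g2b"],
                            columns=["c_1", "c_2"])
        expr = compute_rpkm(vals + 0, pd.Series(1000.0, index=vals.index),
                            totals=pd.Series(1e6, index=vals.columns),
                            sample_groups={"c_1": "c", "c_2": "c"})
        with pytest.raises(ValueError):
            fx.auto_k(toy_model, expr)


# ---------------------------------------------------------------------------
# Differential flux
# ---------------------------------------------------------------------------

def _dist(values: dict[str, list[float]], side: str) -> list[FluxDistribution]:
    rids = list(values)
    n = len(next(iter(values.values())))
    out = []
    for i in range(n):
        fluxes = pd.Series({r: values[r][i] for r in rids})
        out.append(FluxDistribution(fluxes, fluxes.iloc[-1], f"{side}_{i}"))
    return out


class TestDifferentialFlux:
    def test_identical_constant_groups_not_significant(self):
        case = _dist({"R": [1.0, 1.0, 1.0]}, "a")
        ctrl = _dist({"R": [1.0, 1.0, 1.0]}, "b")
        table = fx.differential_flux(case, ctrl).table
        assert not table.at["R", "significant"]
        assert table.at["R", "p_value"] == 1.0

    def test_constant_but_different_groups_are_exact_calls(self):
        case = _dist({"R": [2.0, 2.0, 2.0]}, "a")
        ctrl = _dist({"R": [1.0, 1.0, 1.0]}, "b")
        table = fx.differential_flux(case, ctrl).table
        assert table.at["R", "p_value"] == 0.0
        assert table.at["R", "significant"]

    def test_min_diff_gates_tiny_changes(self):
        case = _dist({"R": [1.0005, 1.0005, 1.0005]}, "a")
        ctrl = _dist({"R": [1.0, 1.0, 1.0]}, "b")
        table = fx.differential_flux(case, ctrl).table
        assert table.at["R", "p_value"] == 0.0
        assert not table.at["R", "significant"]  # |diff| = 5e-4 < 1e-3

    def test_all_zero_reactions_are_not_tested(self):
        case = _dist({"R": [0.0, 0.0, 0.0], "S": [1.0, 1.1, 0.9]}, "a")
        ctrl = _dist({"R": [0.0, 0.0, 0.0], "S": [1.0, 1.0, 1.0]}, "b")
        table = fx.differential_flux(case, ctrl).table
        assert "R" not in table.index and "S" in table.index

    def test_needs_two_replicates(self):
        case = _dist({"R": [1.0]}, "a")
        ctrl = _dist({"R": [1.0, 1.0]}, "b")
        with pytest.raises(ValueError):
            fx.differential_flux(case, ctrl)


# ---------------------------------------------------------------------------
# Replicate solves and flux-controlling genes
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def study():
    return simulate_study(seed=1)


@pytest.fixture(scope="module")
def expr(study):
    return compute_rpkm(study.counts, study.gene_lengths,
                        sample_groups=study.sample_groups)


class TestReplicateFluxes:
    def test_one_distribution_per_replicate(self, study, expr):
        k = fx.auto_k(study.model, expr)
        dists = fx.replicate_fluxes(study.model, expr, "control", k)
        assert len(dists) == 3
        assert [d.sample_id for d in dists] == ["control_1", "control_2",
                                                "control_3"]

    def test_identical_expression_gives_identical_fluxes(self, study, expr):
        k = fx.auto_k(study.model, expr)
        twice = [fx.replicate_fluxes(study.model, expr, "control", k)
                 for _ in range(2)]
        for a, b in zip(*twice):
            assert (a.fluxes == b.fluxes).all()

    def test_throttled_group_grows_slower(self, study, expr):
        """The planted knock-down of the cycle gene lowers the malignant
        groups' mean biomass flux below the control's."""
        k = fx.auto_k(study.model, expr)
        ctrl = fx.replicate_fluxes(study.model, expr, "control", k)
        mal = fx.replicate_fluxes(study.model, expr, "lineA", k)
        mean = lambda ds: np.mean([d.fluxes["biomass"] for d in ds])
        assert mean(mal) < mean(ctrl)

    def test_planted_reaction_and_gene_are_recovered(self, study, expr):
        """End-to-end on the cycle toy, seed 1: the throttled reaction is
        differentially used and its gene is emitted as flux-controlling."""
        det = differential_expression(expr, "lineA", "control")
        k = fx.auto_k(study.model, expr)
        diff = fx.differential_flux(
            fx.replicate_fluxes(study.model, expr, "lineA", k),
            fx.replicate_fluxes(study.model, expr, "control", k))
        assert study.truth.limited_reaction in diff.significant_reactions
        pairs = fx.flux_controlling_genes(diff, det, study.model)
        assert any(p.reaction_id == study.truth.limited_reaction
                   and p.gene_id == "g_cyc_2" and p.gene_call == "down"
                   for p in pairs)


class TestFluxControllingGenes:
    def _diff(self, sig: dict[str, bool]) -> fx.DiffFluxTable:
        table = pd.DataFrame({
            "q_value": [0.01 if s else 0.9 for s in sig.values()],
            "significant": list(sig.values()),
        }, index=list(sig))
        return fx.DiffFluxTable(table)

    def test_pair_emitted_for_de_gene_of_significant_reaction(self, toy_model):
        de = DETable(pd.DataFrame({"call": ["down"]}, index=["g1"]), "a", "b")
        pairs = fx.flux_controlling_genes(self._diff({"R1": True}), de, toy_model)
        assert [(p.reaction_id, p.gene_id, p.gene_call) for p in pairs] == \
            [("R1", "g1", "down")]

    def test_no_pair_without_de_support(self, toy_model):
        de = DETable(pd.DataFrame({"call": []}), "a", "b")
        assert fx.flux_controlling_genes(self._diff({"R1": True}), de,
                                         toy_model) == []

    def test_non_significant_reactions_are_skipped(self, toy_model):
        de = DETable(pd.DataFrame({"call": ["up"]}, index=["g1"]), "a", "b")
        assert fx.flux_controlling_genes(self._diff({"R1": False}), de,
                                         toy_model) == []
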