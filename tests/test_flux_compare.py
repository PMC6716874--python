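import itertools

import numpy as np
import pandas as pd
import pytest

import _oracles
from contextflux.flux_compare import (InfeasibleModelError, add_biomass,
                                      apply_medium, classify_one,
                                      classify_status, consensus_status,
                                      derive_condition_model, fba, fva,
                                      genes_from_reactions)
from contextflux.model_io import (MetabolicModel, Metabolite, Reaction,
                                  parse_gpr)
from contextflux.synthetic_data import (ExpressionSimSpec, TRP_BRANCH_GENES,
                                        TRP_BRANCH_REACTIONS,
                                        plant_pathway_downregulation,
                                        simulate_expression)
from contextflux.expression import differential_expression


def linear_chain(yield_=1.0, uptake=10.0):
    """EX_A (uptake) -> A_e -> A -> B -> EX_B with the given yield."""
    mets = [Metabolite(m, compartment="c") for m in ("A_e", "A", "B")]
    rxns = [
        Reaction("EX_A", stoichiometry={"A_e": -1}, lower_bound=-uptake),
        Reaction("T", stoichiometry={"A_e": -1, "A": 1}),
        Reaction("R", stoichiometry={"A": -1, "B": yield_}),
        Reaction("EX_B", stoichiometry={"B": -1}),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                          objective_id="EX_B", id="chain")


def two_path_motif():
    """Parallel redundant routes A -> B (p1, p2), uptake 10."""
    mets = [Metabolite(m, compartment="c") for m in ("A_e", "A", "B")]
    rxns = [
        Reaction("EX_A", stoichiometry={"A_e": -1}, lower_bound=-10),
        Reaction("T", stoichiometry={"A_e": -1, "A": 1}),
        Reaction("p1", stoichiometry={"A": -1, "B": 1}),
        Reaction("p2", stoichiometry={"A": -1, "B": 1}),
        Reaction("EX_B", stoichiometry={"B": -1}),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                          objective_id="EX_B", id="two_path")


class TestAddBiomass:
    def test_sets_objective_and_grows(self, toy_model_no_branch):
        m = toy_model_no_branch.subset(
            [r.id for r in toy_model_no_branch.reactions if r.id != "biomass"])
        m.objective_id = None
        m2 = add_biomass(m, {"atp_c": -2, "g6p_c": -1, "oaa_c": -0.5, "adp_c": 2})
        assert m2.objective_id == "biomass"
        opt, _ = fba(m2)
        assert opt > 0

    def test_unknown_metabolite_rejected(self, toy_model):
        m = toy_model.subset([r.id for r in toy_model.reactions
                              if r.id != "biomass"])
        with pytest.raises(ValueError, match="ghost"):
            add_biomass(m, {"ghost": -1})

    def test_pure_production_rejected(self, toy_model):
        m = toy_model.subset([r.id for r in toy_model.reactions
                              if r.id != "biomass"])
        with pytest.raises(ValueError, match="consume"):
            add_biomass(m, {"atp_c": 1})


class TestApplyMedium:
    def test_closing_glucose_kills_sugar_only_growth(self, toy_model_no_branch):
        """Without the trp branch, g6p comes from glucose only; biomass needs
        g6p, so closing glucose uptake sends the optimum to zero... the branch
        model is already dead, so use a biomass without the NAD demand."""
        m = toy_model_no_branch.subset(
            [r.id for r in toy_model_no_branch.reactions if r.id != "biomass"])
        m.objective_id = None
        m = add_biomass(m, {"atp_c": -2, "g6p_c": -1, "oaa_c": -0.5, "adp_c": 2})
        assert fba(m)[0] > 0
        closed = apply_medium(m, {"EX_glc": 0.0, "EX_o2": -20.0})
        assert fba(closed)[0] == pytest.approx(0.0, abs=1e-9)

    def test_open_policy_leaves_unlisted_untouched(self, toy_model):
        m = apply_medium(toy_model, {}, default_policy="open")
        assert m.get_reaction("EX_glc").lower_bound == -10

    def test_closed_policy_zeroes_unlisted(self, toy_model):
        m = apply_medium(toy_model, {"EX_glc": -10.0})
        assert m.get_reaction("EX_o2").lower_bound == 0.0
        assert m.get_reaction("EX_glc").lower_bound == -10.0
        # secretion bounds untouched
        assert m.get_reaction("EX_co2").upper_bound == 1000.0

    def test_positive_uptake_bound_rejected(self, toy_model):
        with pytest.raises(ValueError, match="<= 0"):
            apply_medium(toy_model, {"EX_glc": 5.0})

    def test_non_exchange_rejected(self, toy_model):
        with pytest.raises(ValueError, match="HEX"):
            apply_medium(toy_model, {"HEX": -1.0})


class TestFBA:
    def test_linear_chain_hand_optimum(self):
        assert fba(linear_chain())[0] == pytest.approx(10.0)
        assert fba(linear_chain(yield_=0.5))[0] == pytest.approx(5.0)

    def test_blocked_objective_gives_zero(self):
        m = linear_chain()
        m.get_reaction("T").upper_bound = 0.0
        assert fba(m)[0] == pytest.approx(0.0)

    def test_matches_independent_lp_oracle(self, toy_model):
        opt, _ = fba(toy_model)
        assert opt == pytest.approx(_oracles.fba_oracle(toy_model), abs=1e-6)


class TestFVA:
    def test_chain_at_fraction_one_collapses(self):
        intervals = fva(linear_chain(), objective_fraction=1.0)
        for rid in ("T", "R", "EX_B"):
            assert intervals.loc[rid, "vmin"] == pytest.approx(10.0, abs=1e-6)
            assert intervals.loc[rid, "vmax"] == pytest.approx(10.0, abs=1e-6)

    def test_two_path_motif_analytic_intervals(self):
        intervals = fva(two_path_motif(), objective_fraction=0.9)
        for rid in ("p1", "p2"):
            assert intervals.loc[rid, "vmin"] == pytest.approx(0.0, abs=1e-6)
            assert intervals.loc[rid, "vmax"] == pytest.approx(10.0, abs=1e-6)
        assert intervals.loc["EX_A", "vmax"] == pytest.approx(-9.0, abs=1e-6)
        assert intervals.loc["EX_A", "vmin"] == pytest.approx(-10.0, abs=1e-6)

    def test_fraction_zero_respects_bounds(self, toy_model):
        intervals = fva(toy_model, objective_fraction=0.0)
        for r in toy_model.reactions:
            assert intervals.loc[r.id, "vmin"] >= r.lower_bound - 1e-6
            assert intervals.loc[r.id, "vmax"] <= r.upper_bound + 1e-6

    def test_matches_brute_force_lp_oracle(self, toy_model):
        intervals = fva(toy_model, objective_fraction=0.9)
        oracle = _oracles.fva_oracle(toy_model, objective_fraction=0.9)
        for rid, (lo, hi) in oracle.items():
            assert intervals.loc[rid, "vmin"] == pytest.approx(lo, abs=1e-6)
            assert intervals.loc[rid, "vmax"] == pytest.approx(hi, abs=1e-6)

    def test_bad_fraction_rejected(self, toy_model):
        with pytest.raises(ValueError):
            fva(toy_model, objective_fraction=1.5)


# ---------------------------------------------------------------------------
# condition models
# ---------------------------------------------------------------------------

def fake_de(rows: dict[str, tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"logFC": [v[0] for v in rows.values()],
         "p_value": [v[1] for v in rows.values()],
         "adj_p": [v[1] for v in rows.values()]},
        index=list(rows))


class TestDeriveConditionModel:
    def gpr_toy(self):
        mets = [Metabolite("A", compartment="c"), Metabolite("B", compartment="c")]
        rxns = [
            Reaction("OR2", stoichiometry={"A": -1, "B": 1},
                     gpr=parse_gpr("g1 or g2")),
            Reaction("AND2", stoichiometry={"A": -1, "B": 1},
                     gpr=parse_gpr("g1 and g2")),
            Reaction("bare", stoichiometry={"A": -1, "B": 1}),
        ]
        return MetabolicModel(metabolites=mets, reactions=rxns,
                              genes=["g1", "g2"])

    def test_or_redundancy_survives(self):
        de = fake_de({"g1": (-2.0, 0.001), "g2": (0.0, 0.9)})
        m = derive_condition_model(self.gpr_toy(), de, "naive", 1.0)
        assert m.get_reaction("OR2").upper_bound > 0
        assert m.get_reaction("AND2").upper_bound == 0
        assert m.get_reaction("bare").upper_bound > 0

    def test_direction_of_silencing(self):
        de = fake_de({"g1": (2.0, 0.001), "g2": (2.0, 0.001)})
        naive_m = derive_condition_model(self.gpr_toy(), de, "naive", 1.0)
        primed_m = derive_condition_model(self.gpr_toy(), de, "primed", 1.0)
        # up in naive == down in primed: silenced only in the primed model
        assert naive_m.get_reaction("AND2").upper_bound > 0
        assert primed_m.get_reaction("AND2").upper_bound == 0

    def test_padj_gate(self):
        de = fake_de({"g1": (-2.0, 0.5), "g2": (-2.0, 0.5)})
        m = derive_condition_model(self.gpr_toy(), de, "naive", 1.0)
        assert m.get_reaction("AND2").upper_bound > 0

    def test_any_mode_over_deletes(self):
        de = fake_de({"g1": (-2.0, 0.001), "g2": (0.0, 0.9)})
        m = derive_condition_model(self.gpr_toy(), de, "naive", 1.0, mode="any")
        assert m.get_reaction("OR2").upper_bound == 0

    def test_threshold_monotonicity(self, toy_model):
        """Loosening the logFC cutoff (1.0 -> 0.7) never silences fewer genes."""
        rng_de = fake_de({g: (-0.9, 0.001) for g in TRP_BRANCH_GENES})
        zeroed = {}
        for thr in (1.0, 0.85, 0.7):
            m = derive_condition_model(toy_model, rng_de, "naive", thr)
            zeroed[thr] = {r.id for r in m.reactions if r.upper_bound == 0
                           and r.lower_bound == 0}
        assert zeroed[1.0] <= zeroed[0.85] <= zeroed[0.7]
        assert set(TRP_BRANCH_REACTIONS) <= zeroed[0.7]
        assert not zeroed[1.0]


# ---------------------------------------------------------------------------
# status classification
# ---------------------------------------------------------------------------

class TestClassifyStatus:
    @pytest.mark.parametrize("n,p,want", [
        ((2, 3), (0, 1), "A"),
        ((0, 1), (2, 3), "B"),
        ((1, 5), (0, 4), "C"),
        ((0, 4), (1, 5), "D"),
        ((0, 5), (0, 5), "E"),
        ((0, 0), (0, 0), "F"),
        ((0, 5), (1, 4), "E"),     # mutually covering: no shift call
    ])
    def test_hand_cases(self, n, p, want):
        assert classify_one(n, p) == want

    def test_exhaustive_endpoint_orderings_match_oracle(self):
        values = [0.0, 1.0, 2.0, 3.0]
        for a_n, b_n, a_p, b_p in itertools.product(values, repeat=4):
            if a_n > b_n or a_p > b_p:
                continue
            got = classify_one((a_n, b_n), (a_p, b_p))
            want = _oracles.status_oracle((a_n, b_n), (a_p, b_p))
            assert got == want, (a_n, b_n, a_p, b_p)

    def test_antisymmetry_under_model_swap(self):
        swap = {"A": "B", "B": "A", "C": "D", "D": "C", "E": "E", "F": "F"}
        values = [0.0, 1.0, 2.5, 4.0]
        for a_n, b_n, a_p, b_p in itertools.product(values, repeat=4):
            if a_n > b_n or a_p > b_p:
                continue
            direct = classify_one((a_n, b_n), (a_p, b_p))
            swapped = classify_one((a_p, b_p), (a_n, b_n))
            assert swapped == swap[direct]

    def test_missing_reaction_is_zero_interval(self):
        naive = pd.DataFrame({"vmin": [2.0], "vmax": [3.0]}, index=["R"])
        primed = pd.DataFrame({"vmin": [], "vmax": []})
        out = classify_status(naive, primed)
        assert out.loc["R", "status"] == "A"

    def test_every_reaction_gets_exactly_one_status(self, toy_model):
        intervals = fva(toy_model, 0.9)
        out = classify_status(intervals, intervals)
        assert set(out.index) == set(toy_model.reaction_ids())
        assert out["status"].isin(list("ABCDEF")).all()
        assert (out["status"] != "A").all() and (out["status"] != "B").all()


class TestConsensus:
    def call(self, status_by_thr):
        return {
            thr: pd.DataFrame({"status": [s], "direction_flip": [False]},
                              index=["R"])
            for thr, s in status_by_thr.items()
        }

    def test_all_A_is_robust_naive(self):
        up_n, up_p = consensus_status(self.call({1.0: "A", 0.85: "A", 0.7: "C"}))
        assert up_n == ["R"] and up_p == []

    def test_one_E_breaks_robustness(self):
        up_n, up_p = consensus_status(self.call({1.0: "A", 0.85: "A", 0.7: "E"}))
        assert up_n == [] and up_p == []

    def test_mismatched_universes_rejected(self):
        calls = self.call({1.0: "A", 0.85: "A"})
        calls[0.7] = pd.DataFrame({"status": ["A"], "direction_flip": [False]},
                                  index=["other"])
        with pytest.raises(ValueError):
            consensus_status(calls)


class TestGenesFromReactions:
    def test_union_of_gprs(self, toy_model):
        genes = genes_from_reactions(toy_model, ["HEX", "PYK"])
        assert genes == {"g_hk1", "g_hk2", "g_pyk", "g_eno"}

    def test_empty_gpr_contributes_nothing(self):
        m = linear_chain()
        assert genes_from_reactions(m, ["R"]) == set()

    def test_unknown_reaction_rejected(self, toy_model):
        with pytest.raises(KeyError):
            genes_from_reactions(toy_model, ["nope"])

    def test_branch_reactions_give_branch_genes(self, toy_model):
        genes = genes_from_reactions(toy_model, list(TRP_BRANCH_REACTIONS))
        assert genes == set(TRP_BRANCH_GENES)
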