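"""Constraint-based target scoring: pFBA solves, score arithmetic, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trpml.gsm import (
    DEFAULT_FRACTIONS,
    FluxDistribution,
    InfeasibleModelError,
    Reaction,
    StoichiometricModel,
    gene_scores,
    pathway_enrichment,
    reaction_scores,
    regime_overlap,
    score_targets,
    solve_pfba,
    suboptimal_scan,
)
from tests.conftest import random_feasible_model

TOL = 1e-6


def _mass_balance_residual(model, dist):
    S = model.stoichiometric_matrix()
    v = np.array([dist.fluxes[r.id] for r in model.reactions])
    return np.max(np.abs(S @ v))


class TestPfba:
    def test_all_carbon_to_growth_at_full_fraction(self, toy_chain):
        d = solve_pfba(toy_chain, growth_fraction=1.0)
        assert d["growth"] == pytest.approx(10.0, abs=1e-6)
        assert d["trp"] == pytest.approx(0.0, abs=1e-6)

    def test_conservation_forces_remainder_to_target(self, toy_chain):
        d = solve_pfba(toy_chain, growth_fraction=0.5)
        assert d["growth"] == pytest.approx(5.0, abs=1e-6)
        assert d["trp"] == pytest.approx(5.0, abs=1e-6)

    @pytest.mark.parametrize("fraction", [0.3, 0.55, 0.8, 1.0])
    def test_mass_balance_and_bounds(self, model_factory, fraction):
        model = model_factory(np.random.default_rng(42))
        d = solve_pfba(model, fraction)
        assert _mass_balance_residual(model, d) < TOL
        for r in model.reactions:
            assert r.lb - TOL <= d.fluxes[r.id] <= r.ub + TOL

    def test_matches_cobra_pfba_oracle(self, model_factory):
        """Total parsimonious flux agrees with an independent COBRA/glpk solve."""
        cobra = pytest.importorskip("cobra")
        from cobra.flux_analysis import pfba as cobra_pfba

        for seed in (1, 2, 3):
            model = model_factory(np.random.default_rng(seed))
            mine = solve_pfba(model, 0.5)

            cm = cobra.Model("oracle")
            mets = {m: cobra.Metabolite(m) for m in model.metabolites}
            for r in model.reactions:
                cr = cobra.Reaction(r.id)
                cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
                cr.bounds = (r.lb, r.ub)
                cm.add_reactions([cr])
            cm.objective = model.objective
            mu = cm.optimize().objective_value
            cm.reactions.get_by_id(model.objective).bounds = (0.5 * mu, 0.5 * mu)
            cm.objective = model.target
            t = cm.optimize().objective_value
            cm.reactions.get_by_id(model.target).bounds = (t, t)
            sol = cobra_pfba(cm)
            oracle_total = float(sol.fluxes.abs().sum())
            assert mine.total_flux == pytest.approx(oracle_total, abs=1e-4)

    def test_parsimony_never_beaten_by_feasible_alternative(self, model_factory):
        """pFBA total |flux| is minimal among solutions with the same growth/target."""
        cobra = pytest.importorskip("cobra")
        model = model_factory(np.random.default_rng(7))
        mine = solve_pfba(model, 0.6)
        # alternative feasible solution: plain FBA (no parsimony) at same fixings
        cm = cobra.Model("alt")
        mets = {m: cobra.Metabolite(m) for m in model.metabolites}
        for r in model.reactions:
            cr = cobra.Reaction(r.id)
            cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
            cr.bounds = (r.lb, r.ub)
            cm.add_reactions([cr])
        cm.objective = model.objective
        mu = cm.optimize().objective_value
        cm.reactions.get_by_id(model.objective).bounds = (0.6 * mu, 0.6 * mu)
        cm.objective = model.target
        sol = cm.optimize()
        assert mine.fluxes[model.target] == pytest.approx(sol.objective_value, abs=1e-5)
        assert mine.total_flux <= float(sol.fluxes.abs().sum()) + 1e-5

    def test_infeasible_model_names_stage(self):
        m = StoichiometricModel(
            metabolites=["A"],
            reactions=[
                Reaction("in", {"A": 1}, 2, 10),  # forced inflow
                Reaction("growth", {"A": -1}, 0, 1),
                Reaction("trp", {"A": -1}, 0, 0.5),  # cannot drain the forced inflow
            ],
            objective="growth",
            target="trp",
        )
        with pytest.raises(InfeasibleModelError) as exc:
            solve_pfba(m, 1.0)
        assert exc.value.stage

    def test_bad_fraction_rejected(self, toy_chain):
        for f in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                solve_pfba(toy_chain, f)


class TestScan:
    def test_default_grid_has_11_conditions(self, toy_chain):
        scan = suboptimal_scan(toy_chain)
        assert len(scan) == 11
        assert scan[0].growth_fraction == pytest.approx(0.30)
        assert scan[-1].growth_fraction == pytest.approx(0.80)

    def test_single_full_fraction_equals_reference(self, toy_chain):
        ref = solve_pfba(toy_chain, 1.0)
        (only,) = suboptimal_scan(toy_chain, [1.0])
        assert only.fluxes == pytest.approx(ref.fluxes, abs=1e-9)

    def test_target_flux_decreases_with_growth_fraction(self, toy_chain):
        scan = suboptimal_scan(toy_chain)
        trp = [d["trp"] for d in scan]
        assert all(a > b for a, b in zip(trp, trp[1:]))

    def test_empty_fractions_rejected(self, toy_chain):
        with pytest.raises(ValueError):
            suboptimal_scan(toy_chain, [])


def _dist(fluxes, f=0.5):
    return FluxDistribution(fluxes=fluxes, growth_fraction=f)


class TestScores:
    def test_doubling_flux_scores_two(self):
        ref = _dist({"r": 2.0}, 1.0)
        scan = [_dist({"r": 4.0}, f) for f in (0.3, 0.5, 0.8)]
        s = reaction_scores(scan, ref)
        assert s.loc["r", "score"] == pytest.approx(2.0, rel=1e-3)

    def test_identical_flux_scores_one(self):
        ref = _dist({"r": 3.3}, 1.0)
        s = reaction_scores([_dist({"r": 3.3}, 0.5)], ref)
        assert s.loc["r", "score"] == pytest.approx(1.0)

    def test_zero_reference_uses_pseudo_flux_formula(self):
        delta = 1e-4
        ref = _dist({"r": 0.0}, 1.0)
        scan = [_dist({"r": v}, f) for v, f in [(1.0, 0.3), (2.0, 0.5)]]
        s = reaction_scores(scan, ref, pseudo_flux=delta)
        expected = np.mean([(1.0 + delta) / delta, (2.0 + delta) / delta])
        assert s.loc["r", "score"] == pytest.approx(expected)

    def test_doubly_zero_reaction_is_unscored(self):
        ref = _dist({"r": 0.0}, 1.0)
        s = reaction_scores([_dist({"r": 0.0}, 0.5)], ref)
        assert not s.loc["r", "scored"]
        assert np.isnan(s.loc["r", "score"])

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValueError, match="r2"):
            reaction_scores([_dist({"r1": 1.0, "r2": 1.0})], _dist({"r1": 1.0}))

    def test_reference_vs_itself_scores_one_everywhere(self, model_factory):
        model = model_factory(np.random.default_rng(5))
        ref = solve_pfba(model, 1.0)
        s = reaction_scores([ref], ref)
        scored = s[s["scored"]]
        assert np.allclose(scored["score"], 1.0)

    def test_gene_score_is_mean_of_reaction_scores(self, toy_chain):
        rxn = pd.DataFrame(
            {"score": [2.0, 1.0], "scored": [True, True], "sign_change": [False, False]},
            index=pd.Index(["uptake", "conv"], name="reaction"),
        )
        m = StoichiometricModel(
            metabolites=toy_chain.metabolites,
            reactions=[
                Reaction("uptake", {"A": 1}, 0, 10, ("g1",)),
                Reaction("conv", {"A": -1, "B": 1}, 0, 1000, ("g1",)),
                Reaction("growth", {"B": -1}, 0, 1000, ()),
                Reaction("trp", {"B": -1}, 0, 1000, ()),
            ],
            objective="growth",
            target="trp",
        )
        g = gene_scores(rxn, m)
        assert g.loc["g1", "score"] == pytest.approx(1.5)
        assert g.loc["g1", "classification"] == "overexpress"

    def test_all_unit_scores_classified_neutral(self):
        rxn = pd.DataFrame(
            {"score": [1.0], "scored": [True], "sign_change": [False]},
            index=pd.Index(["uptake"], name="reaction"),
        )
        m = StoichiometricModel(
            metabolites=["A"],
            reactions=[
                Reaction("uptake", {"A": 1}, 0, 10, ("g1",)),
                Reaction("growth", {"A": -1}, 0, 1000),
                Reaction("trp", {"A": -1}, 0, 1000),
            ],
            objective="growth",
            target="trp",
        )
        assert gene_scores(rxn, m).loc["g1", "classification"] == "neutral"

    def test_gene_scores_match_groupby_oracle(self, model_factory):
        model = model_factory(np.random.default_rng(11))
        ref = solve_pfba(model, 1.0)
        scan = suboptimal_scan(model, [0.4, 0.6])
        rxn = reaction_scores(scan, ref)
        genes = gene_scores(rxn, model)
        # independent oracle: explode gene-reaction pairs and groupby-average
        pairs = [(g, r.id) for r in model.reactions for g in r.genes]
        df = pd.DataFrame(pairs, columns=["gene", "reaction"]).merge(
            rxn.reset_index(), on="reaction"
        )
        oracle = df[df["scored"]].groupby("gene")["score"].mean()
        for gene, expected in oracle.items():
            assert genes.loc[gene, "score"] == pytest.approx(expected)

    def test_classification_invariant_under_reaction_reordering(self, model_factory):
        model = model_factory(np.random.default_rng(3))
        base = score_targets(model, [0.4, 0.7])
        shuffled = StoichiometricModel(
            metabolites=model.metabolites,
            reactions=list(reversed(model.reactions)),
            objective=model.objective,
            target=model.target,
        )
        other = score_targets(shuffled, [0.4, 0.7])
        merged = base.join(other, lsuffix="_a", rsuffix="_b")
        assert (merged["classification_a"] == merged["classification_b"]).all()

    def test_regime_overlap_intersects_classified_sets(self, model_factory):
        m1 = model_factory(np.random.default_rng(8))
        s1 = score_targets(m1, [0.4, 0.7])
        ov = regime_overlap(s1, s1)
        assert ov["overexpress"] == set(s1.index[s1["classification"] == "overexpress"])


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities ≤ P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
            if 0 <= k <= r1 and 0 <= c1 - k <= r2
            else 0.0
        )

    p_obs = prob(a)
    return sum(p for k in range(0, min(r1, c1) + 1) if (p := prob(k)) <= p_obs * (1 + 1e-9))


class TestEnrichment:
    def test_symmetric_table_gives_p_one(self):
        df = pathway_enrichment(
            {"g1", "g2", "g5", "g6"},
            {"pw": {"g1", "g2", "g3", "g4"}},
            {f"g{i}" for i in range(1, 9)},
        )
        assert df.loc["pw", "p_two_sided"] == pytest.approx(1.0)

    def test_known_table_three_one(self):
        # targets {g1,g2,g3,g5}, pathway {g1,g2,g3,g4}: table [[3,1],[1,3]]
        df = pathway_enrichment(
            {"g1", "g2", "g3", "g5"},
            {"pw": {"g1", "g2", "g3", "g4"}},
            {f"g{i}" for i in range(1, 9)},
        )
        assert df.loc["pw", "p_two_sided"] == pytest.approx(34 / 70, rel=1e-9)

    def test_strong_enrichment_significant_and_matches_oracle(self):
        universe = {f"g{i}" for i in range(1, 25)}
        pathway = {f"g{i}" for i in range(1, 7)}
        targets = pathway | {"g7"}
        df = pathway_enrichment(targets, {"pw": pathway}, universe)
        p = df.loc["pw", "p_two_sided"]
        assert p < 0.05
        a, b, c, d = (int(df.loc["pw", k]) for k in "abcd")
        assert p == pytest.approx(_fisher_enumeration(a, b, c, d), rel=1e-6)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment(set(), {}, set())

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.tuples(*[st.integers(0, 6)] * 4))
    def test_fisher_agrees_with_enumeration(self, table):
        a, b, c, d = table
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        universe = (
            [f"pi{i}" for i in range(a)] + [f"po{i}" for i in range(b)]
            + [f"oi{i}" for i in range(c)] + [f"oo{i}" for i in range(d)]
        )
        targets = {g for g in universe if g.startswith("pi") or g.startswith("oi")}
        pathway = {g for g in universe if g.startswith("p")}
        df = pathway_enrichment(targets, {"pw": pathway}, set(universe))
        assert df.loc["pw", "p_two_sided"] == pytest.approx(
            _fisher_enumeration(a, b, c, d), rel=1e-6
        )


def test_model_json_round_trip(tmp_path, toy_chain):
    p = tmp_path / "model.json"
    toy_chain.to_json(p)
    back = StoichiometricModel.from_json(p)
    assert back.to_dict() == toy_chain.to_dict()


def test_model_validation_rejects_bad_inputs():
    with pytest.raises(ValueError, match="undeclared"):
        StoichiometricModel(
            metabolites=["A"],
            reactions=[
                Reaction("r", {"A": 1, "Z": -1}, 0, 1),
                Reaction("growth", {"A": -1}, 0, 1),
                Reaction("trp", {"A": -1}, 0, 1),
            ],
            objective="growth",
            target="trp",
        )
    with pytest.raises(ValueError, match="lb > ub"):
        StoichiometricModel(
            metabolites=["A"],
            reactions=[
                Reaction("r", {"A": 1}, 5, 1),
                Reaction("growth", {"A": -1}, 0, 1),
                Reaction("trp", {"A": -1}, 0, 1),
            ],
            objective="growth",
            target="trp",
        )
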