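"""Wilcoxon/BH differential expression, consistent-DEG intersection, Spearman
seed networks and the hypergeometric over-representation test."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from reosig import (
    ExpressionMatrix,
    GeneSetCollection,
    SyntheticCohortConfig,
    coexpression_network,
    consistent_degs,
    generate_cohort,
    hypergeom_enrich,
    localize_inflammation_genes,
    wilcoxon_deg,
)


def bh_oracle(pvals):
    """Brute-force step-up: smallest q at which each hypothesis is rejected."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        k = m - rank_from_top  # 1-based rank of this p-value
        running_min = min(running_min, pvals[idx] * m / k)
        adjusted[idx] = running_min
    return adjusted


class TestBenjaminiHochberg:
    def test_step_up_arithmetic_example(self):
        adjusted = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_all_small_permutations(self):
        base = [0.001, 0.012, 0.2, 0.04, 0.9, 0.5]
        for perm in permutations(base):
            got = multipletests(list(perm), method="fdr_bh")[1]
            np.testing.assert_allclose(got, bh_oracle(np.array(perm)), atol=1e-12)


class TestWilcoxonDeg:
    def test_planted_de_recovered_with_correct_directions(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=300, n_samples_per_class=(40, 40),
            n_de_genes=50, de_log_fold_change=3.0, rng_seed=10,
        ))
        table = wilcoxon_deg(cohort.matrix, cohort.labels, fdr_cutoff=0.01)
        truth = {e["gene"]: e["sign"] for e in cohort.truth["de_genes"]}
        for gene, sign in truth.items():
            assert table.loc[gene, "significant"]
            want = "up_in_case" if sign > 0 else "down_in_case"
            assert table.loc[gene, "direction"] == want

    def test_null_cohort_nearly_no_hits(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=500, n_samples_per_class=(30, 30), rng_seed=12,
        ))
        table = wilcoxon_deg(cohort.matrix, cohort.labels, fdr_cutoff=0.01)
        assert table["significant"].mean() < 0.005

    def test_constant_gene_has_p_one_and_stays(self):
        frame = pd.DataFrame(
            [[1.0] * 8, [1, 5, 2, 6, 3, 7, 4, 8]], index=["flat", "vary"],
            columns=[f"s{j}" for j in range(8)], dtype=float,
        )
        labels = pd.Series(["case"] * 4 + ["control"] * 4, index=frame.columns)
        table = wilcoxon_deg(ExpressionMatrix(frame), labels)
        assert table.loc["flat", "p_value"] == 1.0
        assert table.loc["flat", "direction"] == "none"

    def test_fdr_never_below_p(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=100, n_samples_per_class=(15, 15), n_de_genes=10,
            de_log_fold_change=2.0, rng_seed=14,
        ))
        table = wilcoxon_deg(cohort.matrix, cohort.labels)
        assert (table["fdr"] >= table["p_value"] - 1e-12).all()

    def test_small_class_is_error(self):
        frame = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        labels = pd.Series(["case", "control"], index=["s1", "s2"])
        with pytest.raises(ValueError):
            wilcoxon_deg(ExpressionMatrix(frame), labels)


class TestConsistentDegs:
    def make_table(self, entries):
        idx = [e[0] for e in entries]
        return pd.DataFrame(
            {
                "significant": [e[1] for e in entries],
                "direction": [e[2] for e in entries],
            },
            index=idx,
        )

    def test_direction_agreement_required(self):
        a = self.make_table([("g1", True, "up_in_case"), ("g2", True, "up_in_case")])
        b = self.make_table([("g1", True, "down_in_case"), ("g2", True, "up_in_case")])
        assert consistent_degs(a, b) == ["g2"]

    def test_direction_none_excluded(self):
        a = self.make_table([("g1", True, "none")])
        b = self.make_table([("g1", True, "none")])
        assert consistent_degs(a, b) == []

    def test_shared_planted_de_across_two_cohorts(self):
        tables = []
        shared_truth = None
        for seed in (21, 22):
            cohort = generate_cohort(SyntheticCohortConfig(
                n_genes=200, n_samples_per_class=(40, 40),
                n_de_genes=30, de_log_fold_change=3.0, rng_seed=seed,
            ))
            tables.append(wilcoxon_deg(cohort.matrix, cohort.labels))
            truth = {e["gene"]: e["sign"] for e in cohort.truth["de_genes"]}
            shared_truth = truth if shared_truth is None else {
                g: s for g, s in shared_truth.items() if truth.get(g) == s
            }
        shared = consistent_degs(tables[0], tables[1])
        # every strongly planted gene with the same sign in both cohorts is found
        assert set(shared_truth) <= set(shared)


class TestCoexpressionNetwork:
    def test_copy_of_seed_gives_edge_with_rho_one(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.lognormal(2, 0.5, (5, 30)),
                             index=[f"g{i}" for i in range(5)],
                             columns=[f"s{j}" for j in range(30)])
        frame.loc["g1"] = frame.loc["g0"].values
        edges = coexpression_network(ExpressionMatrix(frame), ["g0"], ["g1", "g2"])
        hit = edges[edges["partner_gene"] == "g1"]
        assert len(hit) == 1 and hit["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_yields_no_edges(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=300, n_samples_per_class=(50, 50), rng_seed=30,
        ))
        genes = cohort.matrix.gene_ids
        edges = coexpression_network(cohort.matrix, genes[:3], genes[3:])
        assert len(edges) == 0

    def test_planted_module_recovered(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=120, n_samples_per_class=(50, 50), n_correlated_modules=1,
            module_size=11, module_correlation=0.8, rng_seed=31,
        ))
        module = cohort.truth["modules"][0]["genes"]
        seed, partners = module[0], module[1:]
        background = [g for g in cohort.matrix.gene_ids if g not in module][:50]
        edges = coexpression_network(cohort.matrix, [seed], partners + background)
        recovered = set(edges["partner_gene"]) & set(partners)
        assert len(recovered) >= 8  # >= 8/10 planted partners at n=100
        assert set(edges["partner_gene"]) <= set(partners)  # no background edge

    def test_seed_equal_candidate_skipped(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.lognormal(2, 0.5, (3, 20)),
                             index=["g0", "g1", "g2"],
                             columns=[f"s{j}" for j in range(20)])
        edges = coexpression_network(ExpressionMatrix(frame), ["g0"], ["g0", "g1"])
        tested = edges.attrs["tested"]
        assert "g0" not in set(tested["partner_gene"])

    def test_vectorised_spearman_matches_scipy(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.lognormal(2, 0.5, (6, 25)),
                             index=[f"g{i}" for i in range(6)],
                             columns=[f"s{j}" for j in range(25)])
        edges = coexpression_network(ExpressionMatrix(frame), ["g0"], [f"g{i}" for i in range(1, 6)],
                                     rho_cutoff=0.0, fdr_cutoff=1.1,
                                     within_sample_ranks=False)
        tested = edges.attrs["tested"]
        for row in tested.itertuples(index=False):
            rho, p = stats.spearmanr(frame.loc["g0"], frame.loc[row.partner_gene])
            assert row.rho == pytest.approx(rho, abs=1e-12)
            assert row.p_value == pytest.approx(p, rel=1e-9)

    def test_relaxing_fdr_only_adds_edges(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=60, n_samples_per_class=(30, 30), n_correlated_modules=1,
            module_size=8, module_correlation=0.7, rng_seed=33,
        ))
        module = cohort.truth["modules"][0]["genes"]
        background = [g for g in cohort.matrix.gene_ids if g not in module]
        strict = coexpression_network(cohort.matrix, [module[0]], module[1:] + background,
                                      rho_cutoff=0.6, fdr_cutoff=0.01)
        loose = coexpression_network(cohort.matrix, [module[0]], module[1:] + background,
                                     rho_cutoff=0.6, fdr_cutoff=0.5)
        strict_keys = set(map(tuple, strict[["seed_gene", "partner_gene"]].values))
        loose_keys = set(map(tuple, loose[["seed_gene", "partner_gene"]].values))
        assert strict_keys <= loose_keys


class TestHypergeomEnrich:
    def test_single_term_tail(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection({"S": universe[:5]})
        table = hypergeom_enrich(universe[:5], sets, universe)
        assert table.loc[0, "p_value"] == pytest.approx(1 / 252)

    def test_zero_overlap_p_bounded_by_one(self):
        universe = [f"u{i}" for i in range(10)]
        sets = GeneSetCollection({"S": universe[:2]})
        table = hypergeom_enrich(universe[5:7], sets, universe)
        assert table.loc[0, "overlap_count"] == 0
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_outside_universe_is_error(self):
        sets = GeneSetCollection({"S": ["a"]})
        with pytest.raises(ValueError, match="outside universe"):
            hypergeom_enrich(["zz"], sets, ["a", "b"])

    def test_set_disjoint_from_universe_skipped_with_warning(self):
        sets = GeneSetCollection({"S": ["far", "away"], "T": ["a"]})
        with pytest.warns(UserWarning, match="skipped"):
            table = hypergeom_enrich(["a"], sets, ["a", "b"])
        assert list(table["set_name"]) == ["T"]

    def test_uniform_p_under_random_queries(self):
        rng = np.random.default_rng(9)
        universe = [f"u{i}" for i in range(200)]
        sets = GeneSetCollection({"S": universe[:40]})
        pvals = []
        for _ in range(400):
            query = list(rng.choice(universe, size=20, replace=False))
            pvals.append(hypergeom_enrich(query, sets, universe).loc[0, "p_value"])
        # discrete stochastic dominance: P(p <= t) <= t at a grid of thresholds
        pvals = np.asarray(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            assert (pvals <= t).mean() <= t + 3 * np.sqrt(t * (1 - t) / 400)


class TestInflammationTags:
    def make_deg(self):
        return pd.DataFrame(
            {
                "direction": ["up_in_case", "down_in_case"],
                "fdr": [0.001, 0.002],
                "significant": [True, True],
            },
            index=["gA", "gB"],
        )

    def test_multi_category_gene_gets_both_tags(self):
        sets = GeneSetCollection({"chemokine": ["gA"], "cytokine": ["gA", "gB"]})
        table = localize_inflammation_genes(self.make_deg(), sets)
        tags = dict(zip(table["gene"], table["categories"]))
        assert tags["gA"] == "chemokine;cytokine"
        assert tags["gB"] == "cytokine"

    def test_untagged_gene_retained(self):
        sets = GeneSetCollection({"chemokine": ["gZ"]})
        table = localize_inflammation_genes(self.make_deg(), sets)
        assert set(table["gene"]) == {"gA", "gB"}
        assert (table["categories"] == "").all()

    def test_planted_de_gene_tagged_with_direction(self):
        cohort = generate_cohort(SyntheticCohortConfig(
            n_genes=100, n_samples_per_class=(30, 30), n_de_genes=5,
            de_log_fold_change=3.0, rng_seed=40,
        ))
        table = wilcoxon_deg(cohort.matrix, cohort.labels)
        entry = cohort.truth["de_genes"][0]
        sets = GeneSetCollection({"inflammatory response": [entry["gene"]]})
        tagged = localize_inflammation_genes(table.loc[table["significant"]], sets)
        row = tagged[tagged["gene"] == entry["gene"]].iloc[0]
        assert row["categories"] == "inflammatory response"
        want = "up_in_case" if entry["sign"] > 0 else "down_in_case"
        assert row["direction"] == want
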