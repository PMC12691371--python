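import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualscreen import ValidationError, build_dual_design, make_synthetic_library
from dualscreen import simulate as sim
from dualscreen import sl


@pytest.fixture(scope="module")
def noiseless_parts(noiseless_cdko):
    lib, dual, design, counts, truth = noiseless_cdko
    lfc = sl.construct_lfc(counts, design, dual, pseudocount=0)
    fitness = sl.single_gene_fitness(lfc, dual, lib)
    return lib, dual, design, counts, truth, lfc, fitness


class TestConstructLfc:
    def test_equal_timepoints_give_zero(self, tiny_library):
        dual = build_dual_design(tiny_library)
        truth = sim.make_cdko_truth(
            tiny_library, n_planted=0, gene_fitness_sd=0.0, tau=0.0,
            sigma_construct=0.0, dropout_fraction=0.0, seed=0,
        )
        counts, design, _ = sim.simulate_cdko_screen(dual, truth, seed=0, noiseless=True)
        lfc = sl.construct_lfc(counts, design, dual, pseudocount=0)
        assert np.allclose(lfc["lfc"], 0.0, atol=1e-12)

    def test_noiseless_lfc_equals_generative_model(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, _ = noiseless_parts
        assert np.allclose(
            lfc["lfc"].reindex(truth.construct_lfc_true.index),
            truth.construct_lfc_true,
            atol=1e-9,
        )

    def test_replicate_order_invariance(self, noisy_cdko_small):
        lib, dual, design, counts, truth = noisy_cdko_small
        lfc1 = sl.construct_lfc(counts, design, dual)
        shuffled = design.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        design2 = type(design)(shuffled)
        lfc2 = sl.construct_lfc(counts, design2, dual)
        assert np.allclose(lfc1["lfc"], lfc2["lfc"].reindex(lfc1.index))

    def test_missing_constructs_treated_as_zero(self, tiny_library):
        dual = build_dual_design(tiny_library)
        truth = sim.make_cdko_truth(tiny_library, n_planted=0, seed=0)
        counts, design, _ = sim.simulate_cdko_screen(dual, truth, seed=0)
        trimmed = counts.frame.iloc[:-3]
        lfc = sl.construct_lfc(trimmed, design, dual)
        assert len(lfc) == dual.n_constructs
        assert np.isfinite(lfc["lfc"]).all()


class TestSingleFitness:
    def test_noiseless_fitness_recovered_exactly(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        aligned = truth.guide_fitness.reindex(fitness.guide.index)
        assert np.allclose(fitness.guide, aligned, atol=1e-9)

    def test_safe_guides_have_null_fitness(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        for guide in lib.safe_guides:
            assert abs(fitness.guide[guide]) < 1e-9

    def test_fitness_is_linear_in_planted_effects(self):
        lib = make_synthetic_library(4, 2, 2)
        dual = build_dual_design(lib)
        truth = sim.make_cdko_truth(
            lib, n_planted=0, tau=0.0, sigma_construct=0.0,
            dropout_fraction=0.0, seed=3,
        )
        counts1, design, _ = sim.simulate_cdko_screen(dual, truth, seed=1, noiseless=True)
        doubled = truth
        doubled.guide_fitness = 2.0 * truth.guide_fitness
        counts2, _, _ = sim.simulate_cdko_screen(dual, doubled, seed=1, noiseless=True)
        f1 = sl.single_gene_fitness(
            sl.construct_lfc(counts1, design, dual, 0), dual, lib
        )
        f2 = sl.single_gene_fitness(
            sl.construct_lfc(counts2, design, dual, 0), dual, lib
        )
        assert np.allclose(2.0 * f1.gene, f2.gene, atol=1e-9)


class TestScoresNoiseless:
    def test_all_scale_scores_recover_gamma_exactly(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        planted = list(truth.gamma_true.index)
        h = sl.sl_score_horlbeck(lfc, fitness, dual)
        m_b = sl.sl_score_median(lfc, fitness, dual, background_normalize=True)
        m_nb = sl.sl_score_median(lfc, fitness, dual, background_normalize=False)
        s_b = sl.sl_score_sgrna_derived(lfc, fitness, dual, background_normalize=True)
        for table in (h, m_b, m_nb, s_b):
            assert np.allclose(table.loc[planted, "score"], -2.0, atol=1e-9)
            assert table.drop(planted)["score"].abs().max() < 1e-9

    def test_rank_aggregation_puts_planted_pairs_first(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        r = sl.sl_score_rank_agg(lfc, fitness, dual)
        top2 = set(r.sort_values("score").index[:2])
        assert top2 == set(truth.gamma_true.index)

    def test_horlbeck_equals_explicit_18_construct_enumeration(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        pair = truth.gamma_true.index[0]
        gene_a, gene_b = pair.split("__")
        guides_a = lib.frame.loc[lib.frame["gene"] == gene_a, "guide_id"]
        guides_b = lib.frame.loc[lib.frame["gene"] == gene_b, "guide_id"]
        values = lfc["lfc"]
        deltas = []
        for ga, gb in itertools.product(guides_a, guides_b):
            for cid in (f"{ga}~{gb}", f"{gb}~{ga}"):
                deltas.append(
                    values[cid] - fitness.gene[gene_a] - fitness.gene[gene_b]
                )
        assert len(deltas) == 18
        h = sl.sl_score_horlbeck(lfc, fitness, dual)
        assert h.loc[pair, "score"] == pytest.approx(np.mean(deltas), abs=1e-12)

    def test_sgrna_score_equals_horlbeck_for_homogeneous_guides(self, noiseless_parts):
        # tau = 0 -> guide-level and gene-level fitness coincide
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        h = sl.sl_score_horlbeck(lfc, fitness, dual)
        s = sl.sl_score_sgrna_derived(lfc, fitness, dual, background_normalize=False)
        assert np.allclose(h["score"], s["score"].reindex(h.index), atol=1e-9)

    def test_guide_level_correction_removes_outlier_guide_bias(self):
        # one guide with deviant efficiency: the guide-resolution score stays
        # exact while the gene-median version keeps a bias
        lib = make_synthetic_library(3, 3, 3)
        dual = build_dual_design(lib)
        truth = sim.make_cdko_truth(
            lib, n_planted=1, gamma=-2.0, tau=0.0, sigma_construct=0.0,
            dropout_fraction=0.0, seed=4, planted_pairs=["G001__G002"],
        )
        truth.guide_fitness["G001_g3"] += 1.5  # outlier guide
        counts, design, truth = sim.simulate_cdko_screen(dual, truth, seed=4, noiseless=True)
        lfc = sl.construct_lfc(counts, design, dual, pseudocount=0)
        fitness = sl.single_gene_fitness(lfc, dual, lib)
        s = sl.sl_score_sgrna_derived(lfc, fitness, dual, background_normalize=False)
        h = sl.sl_score_horlbeck(lfc, fitness, dual)
        assert s.loc["G001__G002", "score"] == pytest.approx(-2.0, abs=1e-9)
        assert abs(h.loc["G001__G002", "score"] + 2.0) > 0.1


class TestScoreInvariances:
    def test_background_variant_absorbs_global_shift(self, noiseless_parts):
        lib, dual, design, counts, truth, lfc, fitness = noiseless_parts
        shift = 0.7
        lfc_shifted = lfc.copy()
        lfc_shifted["lfc"] = lfc["lfc"] + shift
        fit_shifted = sl.single_gene_fitness(lfc_shifted, dual, lib)
        for background in (True, False):
            m0 = sl.sl_score_median(lfc, fitness, dual, background)
            m1 = sl.sl_score_median(lfc_shifted, fit_shifted, dual, background)
            if background:
                assert np.allclose(m0["score"], m1["score"], atol=1e-9)
            else:
                # the shift propagates through the two fitness terms, so the
                # non-normalized deltas move by -shift
                assert np.allclose(m1["score"] - m0["score"], -shift, atol=1e-9)

    def test_orientation_relabeling_leaves_scores_unchanged(self, noiseless_cdko):
        lib, dual, design, counts, truth = noiseless_cdko
        sep = "~"
        swapped_ids = {
            cid: f"{cid.split(sep)[1]}{sep}{cid.split(sep)[0]}"
            for cid in counts.frame.index
        }
        swapped = counts.frame.rename(index=swapped_ids)
        s1 = sl.score_sl_table(
            sl.construct_lfc(counts, design, dual, 0), dual, lib,
            methods=("horlbeck", "median", "sgrna"),
        )
        s2 = sl.score_sl_table(
            sl.construct_lfc(type(counts)(swapped), design, dual, 0), dual, lib,
            methods=("horlbeck", "median", "sgrna"),
        )
        for col in ("horlbeck", "median", "sgrna"):
            assert np.allclose(s1[col], s2[col].reindex(s1.index), atol=1e-9)

    def test_stronger_planted_interaction_ranks_higher(self):
        lib = make_synthetic_library(10, 3, 4)
        dual = build_dual_design(lib)
        ranks = {m: [] for m in ("horlbeck", "median", "sgrna", "rra")}
        for gamma in (-0.5, -1.0, -2.0):
            truth = sim.make_cdko_truth(
                lib, n_planted=1, gamma=gamma, seed=6,
                planted_pairs=["G003__G007"],
            )
            counts, design, truth = sim.simulate_cdko_screen(dual, truth, seed=6)
            lfc = sl.construct_lfc(counts, design, dual)
            scores = sl.score_sl_table(lfc, dual, lib)
            for m in ranks:
                order = scores[m].rank(method="min")
                ranks[m].append(order["G003__G007"])
        for m, series in ranks.items():
            assert series[0] >= series[1] >= series[2], (m, series)
            assert series[2] == 1


class TestRankAggregation:
    def test_rho_matches_brute_force_order_statistic(self):
        rng = np.random.default_rng(9)
        ranks = np.sort(rng.random((5, 4)), axis=1)
        rho = sl._rra_rho(ranks)
        for row, expected in zip(ranks, rho):
            brute = min(
                stats.beta.cdf(row[k - 1], k, 4 - k + 1) for k in range(1, 5)
            )
            assert expected == pytest.approx(brute, abs=1e-12)

    def test_dominant_pair_wins(self, noiseless_cdko):
        lib, dual, design, counts, truth = noiseless_cdko
        lfc = sl.construct_lfc(counts, design, dual, pseudocount=0)
        fitness = sl.single_gene_fitness(lfc, dual, lib)
        # force one pair's deltas far below everything else
        pair_rows = dual.frame.loc[dual.frame["pair"] == "G002__G006", "construct_id"]
        lfc.loc[pair_rows, "lfc"] -= 5.0
        r = sl.sl_score_rank_agg(lfc, fitness, dual)
        assert r["score"].idxmin() == "G002__G006"

    def test_permutation_p_uniform_on_random_ranks(self, noiseless_cdko):
        lib, dual, design, counts, truth = noiseless_cdko
        rng = np.random.default_rng(2)
        lfc = sl.construct_lfc(counts, design, dual, pseudocount=0)
        lfc["lfc"] = rng.normal(size=len(lfc))
        fitness = sl.single_gene_fitness(lfc, dual, lib)
        r = sl.sl_score_rank_agg(lfc, fitness, dual, n_permutations=500, seed=0)
        ks = stats.kstest(r["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestConsensus:
    def make_scores(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 4)),
            columns=["horlbeck", "median", "sgrna", "rra"],
            index=[f"A{i:02d}__B{i:02d}" for i in range(n)],
        )

    def test_identical_rankings_reproduce_shared_decile(self):
        scores = self.make_scores()
        for col in scores.columns[1:]:
            scores[col] = scores["horlbeck"]
        flagged, _ = sl.consensus_sl_pairs(scores, top_fraction=0.10, min_methods=3)
        expected = set(scores["horlbeck"].nsmallest(4).index)
        assert set(flagged.index[flagged["consensus"]]) == expected

    def test_three_of_four_hits_required_by_default(self):
        scores = self.make_scores(seed=1)
        target = scores.index[0]
        # push the target to the extreme top in exactly 3 methods
        for col in ("horlbeck", "median", "sgrna"):
            scores.loc[target, col] = -100.0
        scores.loc[target, "rra"] = 100.0
        flagged, _ = sl.consensus_sl_pairs(scores)
        assert flagged.loc[target, "consensus"]
        scores.loc[target, "sgrna"] = 100.0  # now only 2 of 4
        flagged, _ = sl.consensus_sl_pairs(scores)
        assert not flagged.loc[target, "consensus"]

    def test_consensus_monotone_in_min_methods(self):
        scores = self.make_scores(seed=2)
        sets = []
        for mm in (1, 2, 3, 4):
            flagged, _ = sl.consensus_sl_pairs(scores, min_methods=mm)
            sets.append(set(flagged.index[flagged["consensus"]]))
        for small, large in zip(sets[1:], sets[:-1]):
            assert small <= large

    def test_venn_counts_cover_all_flagged_pairs(self):
        scores = self.make_scores(seed=3)
        flagged, venn = sl.consensus_sl_pairs(scores)
        n_flagged_any = int((flagged["n_methods_hit"] > 0).sum())
        assert sum(venn.values()) == n_flagged_any

    def test_invalid_top_fraction_rejected(self):
        with pytest.raises(ValidationError):
            sl.consensus_sl_pairs(self.make_scores(), top_fraction=0.0)


class TestCandidateSelection:
    def test_expression_threshold_is_strict(self):
        hallmark = ["A", "B"]
        expr = {"A": 49.0, "B": 51.0}
        beta = pd.Series({"A": 0.0, "B": 0.0})
        selected, _ = sl.select_cdko_candidates(hallmark, expr, beta)
        assert selected == ["B"]

    def test_venn_regions_track_failed_criteria(self):
        hallmark = ["A", "B"]
        expr = {"A": 100.0, "B": 100.0, "C": 100.0}
        beta = pd.Series({"A": 0.5, "B": 0.5, "C": 0.5})
        selected, venn = sl.select_cdko_candidates(hallmark, expr, beta)
        assert selected == ["A", "B"]
        # C is expressed and non-essential but not a hallmark gene
        assert venn["expressed&nonessential"] == 1
        assert venn["hallmark&expressed&nonessential"] == 2

    def test_engineered_intersection_of_65_genes(self):
        genes = [f"G{i:03d}" for i in range(150)]
        hallmark = genes[:80]
        expr = {g: (100.0 if g in genes[10:120] else 1.0) for g in genes}
        beta = pd.Series(
            {g: (0.2 if g in genes[5:75] else 3.0) for g in genes}
        )
        selected, venn = sl.select_cdko_candidates(hallmark, expr, beta)
        assert len(selected) == 65  # genes[10:75]
        assert venn["hallmark&expressed&nonessential"] == 65

    def test_beta_table_input_accepted(self):
        beta = pd.DataFrame(
            {"gene": ["A", "B"], "condition": ["control", "control"],
             "beta": [0.0, 2.0]}
        )
        selected, _ = sl.select_cdko_candidates(["A", "B"], {"A": 60, "B": 60}, beta)
        assert selected == ["A"]


class TestNetwork:
    def test_star_graph_has_single_hub(self):
        pairs = [("HUB", f"G{i}") for i in range(12)]
        net = sl.sl_network_hubs(pairs, hub_threshold=10)
        assert net.hubs == ["HUB"]
        assert net.degrees["HUB"] == 12

    def test_empty_pair_list(self):
        net = sl.sl_network_hubs([])
        assert net.hubs == [] and len(net.degrees) == 0

    def test_degrees_match_brute_force_count_on_random_graphs(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i:02d}" for i in range(40)]
        for _ in range(3):
            edges = set()
            while len(edges) < 242:
                a, b = rng.choice(40, size=2, replace=False)
                edges.add((genes[min(a, b)], genes[max(a, b)]))
            net = sl.sl_network_hubs(sorted(edges), hub_threshold=10)
            counts = {}
            for a, b in edges:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            for gene, deg in counts.items():
                assert net.degrees[gene] == deg
            assert sorted(net.hubs) == sorted(
                g for g, d in counts.items() if d >= 10
            )
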