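"""Sex-bias scoring, consistency calling and gene-set statistics."""

import numpy as np
import pandas as pd
import pytest

from chronovae import (
    consistent_bias_genes,
    geneset_shift_test,
    hypergeometric_enrichment,
    ppi_odds_ratio_test,
)
from chronovae.sexbias import compute_sexbias_table
from chronovae.stats import auroc, differential_expression


def _bias_table(scores_by_time, n_cells=100, gene="g1", expr=10.0):
    rows = []
    for tp, score in scores_by_time.items():
        rows.append({"gene": gene, "cell_type": "ct", "time_days": tp,
                     "score": score, "n_cells": n_cells, "n_pooled": 3 * n_cells,
                     "mean_expr_F": expr, "mean_expr_M": expr})
    return pd.DataFrame(rows)


class TestConsistentBias:
    def test_consistently_high_scores_are_female_biased(self):
        tbl = pd.concat([_bias_table({1: 0.7, 2: 0.8, 3: 0.65}),
                         _bias_table({1: 0.5, 2: 0.5, 3: 0.5}, gene="g2", expr=1.0)])
        female, male = consistent_bias_genes(tbl, "ct")
        assert female == {"g1"} and male == set()

    def test_one_crossing_score_excludes(self):
        tbl = pd.concat([_bias_table({1: 0.7, 2: 0.45}),
                         _bias_table({1: 0.2, 2: 0.3}, gene="g2", expr=1.0)])
        female, male = consistent_bias_genes(tbl, "ct")
        assert "g1" not in female and "g1" not in male

    def test_low_expression_excluded_despite_scores(self):
        # g1 is bottom-half by expression at time 2 -> excluded
        t1 = pd.concat([_bias_table({1: 0.9}, expr=10.0),
                        _bias_table({1: 0.9}, gene="g2", expr=5.0),
                        _bias_table({1: 0.1}, gene="g3", expr=1.0),
                        _bias_table({1: 0.1}, gene="g4", expr=0.5)])
        t2 = pd.concat([_bias_table({2: 0.9}, expr=0.1),
                        _bias_table({2: 0.9}, gene="g2", expr=5.0),
                        _bias_table({2: 0.1}, gene="g3", expr=1.0),
                        _bias_table({2: 0.1}, gene="g4", expr=0.5)])
        female, male = consistent_bias_genes(pd.concat([t1, t2]), "ct")
        assert "g1" not in female and "g2" in female

    def test_too_few_cells_warns_empty(self):
        tbl = _bias_table({1: 0.9}, n_cells=10)
        with pytest.warns(UserWarning, match="qualifying"):
            female, male = consistent_bias_genes(tbl, "ct")
        assert female == set() and male == set()


class TestGenesetShift:
    def test_exact_enumeration_small_sets(self):
        scores = {"a1": 0.9, "a2": 0.8, "b1": 0.2, "b2": 0.1}
        p = geneset_shift_test(scores, {"a1", "a2"}, {"b1", "b2"})
        assert p == pytest.approx(1 / 6)

    def test_identical_score_multisets_near_half(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=100)
        scores = {f"a{i}": v for i, v in enumerate(vals)}
        scores.update({f"b{i}": v for i, v in enumerate(vals)})
        a = {f"a{i}" for i in range(100)}
        b = {f"b{i}" for i in range(100)}
        assert geneset_shift_test(scores, a, b) == pytest.approx(0.5, abs=0.01)

    def test_one_sided_complement_small_n(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            vals = rng.normal(size=7)
            scores = {f"g{i}": v for i, v in enumerate(vals)}
            a = {f"g{i}" for i in range(3)}
            b = {f"g{i}" for i in range(3, 7)}
            p_ab = geneset_shift_test(scores, a, b)
            p_ba = geneset_shift_test(scores, b, a)
            # P(W_a >= w) + P(W_b >= w') = 1 + tie mass >= 1
            assert p_ab + p_ba >= 1.0 - 1e-12

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            geneset_shift_test({"g1": 0.5}, {"x"}, {"g1"})


class TestPpiOddsRatio:
    def test_hand_computed_corrected_odds_ratio(self):
        edges = [("a1", "x1")]
        with pytest.warns(UserWarning, match="skipped"):
            orr, p = ppi_odds_ratio_test(edges, {"a1", "a2"}, {"x1"},
                                         {"a1", "a2", "b1", "b2"}, seed=0)
        # 2x2 with 0.5 correction: (1.5/1.5) / (0.5/2.5) = 5.0
        assert orr == pytest.approx(5.0)
        assert np.isnan(p)

    def test_null_calibration(self):
        """Candidate sets drawn from the null rarely reach small p."""
        rng = np.random.default_rng(0)
        autosomal = [f"a{i}" for i in range(30)]
        xlinked = [f"x{i}" for i in range(10)]
        edges = [(a, x) for a in autosomal for x in xlinked if rng.random() < 0.3]
        assert len(edges) >= 50
        hits = 0
        for rep in range(20):
            cand = set(rng.choice(autosomal, size=8, replace=False))
            _, p = ppi_odds_ratio_test(edges, cand, set(xlinked),
                                       set(autosomal), n_perm=100, seed=rep)
            hits += p > 0.05
        assert hits >= 18  # >= 90% of null replicates non-significant

    def test_enriched_candidates_detected(self):
        autosomal = [f"a{i}" for i in range(40)]
        xlinked = [f"x{i}" for i in range(5)]
        cand = set(autosomal[:8])
        edges = [(a, x) for a in autosomal[:8] for x in xlinked]  # dense block
        edges += [(f"a{10 + i}", f"x{i % 5}") for i in range(25)]  # sparse background
        orr, p = ppi_odds_ratio_test(edges, cand, set(xlinked), set(autosomal),
                                     n_perm=100, seed=0)
        assert orr > 1
        assert p < 0.05

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            ppi_odds_ratio_test([], {"g"}, {"g"}, {"g"})


class TestHypergeometricEnrichment:
    def test_direct_combinatorics(self):
        universe = [f"g{i}" for i in range(10)]
        study = universe[:5]
        out = hypergeometric_enrichment(study, {"term": universe[:4]}, universe)
        assert out.loc[0, "p"] == pytest.approx(6 / 252)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = hypergeometric_enrichment(universe[:5], {"term": universe[10:12]}, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_study_equals_universe_degenerate(self):
        universe = [f"g{i}" for i in range(8)]
        out = hypergeometric_enrichment(universe, {"t1": universe[:3],
                                                   "t2": universe[3:]}, universe)
        assert np.allclose(out["p"], 1.0)

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"zz"}, {"t": {"a"}}, {"a", "b"})


class TestDifferentialExpression:
    def test_detects_planted_mean_shift(self):
        rng = np.random.default_rng(0)
        Xa = rng.poisson(5.0, size=(150, 30)).astype(float)
        Xb = rng.poisson(5.0, size=(150, 30)).astype(float)
        Xa[:, :5] *= 3  # up in group a
        de = differential_expression(Xa, Xb)
        assert (de.loc[:4, "q"] < 0.05).all()
        assert (de.loc[:4, "t"] > 0).all()
        # depth normalization makes the remaining genes compositionally
        # lower in group a; none should come out significantly up
        assert not ((de.loc[5:, "q"] < 0.05) & (de.loc[5:, "t"] > 0)).any()

    def test_rarely_expressed_genes_excluded(self):
        rng = np.random.default_rng(1)
        Xa = rng.poisson(5.0, size=(100, 3)).astype(float)
        Xb = rng.poisson(5.0, size=(100, 3)).astype(float)
        Xa[:, 0] = 0
        Xb[:, 0] = 0
        Xb[:3, 0] = 1  # expressed in 1.5% of cells
        de = differential_expression(Xa, Xb)
        assert not de.loc[0, "kept"]
        assert np.isnan(de.loc[0, "p"])


class TestSexbiasTable:
    def test_scores_complement_under_sex_relabel(self, rna_ensemble, tiny_sim):
        """Swapping which sex is 'female' maps score -> 1 - score."""
        _, data, _ = tiny_sim
        model, _, _ = rna_ensemble[1]
        t1 = compute_sexbias_table([model], data, pool_neighbors=False)
        t2 = compute_sexbias_table([model], data, female="M", male="F",
                                   pool_neighbors=False)
        s1, s2 = t1["score"].to_numpy(), t2["score"].to_numpy()
        ok = np.isfinite(s1) & np.isfinite(s2)
        assert ok.any()
        assert np.allclose(s1[ok], 1.0 - s2[ok])

    def test_invariant_to_cell_order(self, rna_ensemble, tiny_sim):
        _, data, _ = tiny_sim
        model, _, _ = rna_ensemble[1]
        rng = np.random.default_rng(0)
        shuffled = data.subset(rng.permutation(data.n_cells))
        t1 = compute_sexbias_table([model], data, pool_neighbors=False)
        t2 = compute_sexbias_table([model], shuffled, pool_neighbors=False)
        key = ["gene", "cell_type", "time_days"]
        m = t1.merge(t2, on=key, suffixes=("_a", "_b"))
        ok = np.isfinite(m["score_a"]) & np.isfinite(m["score_b"])
        assert np.allclose(m.loc[ok, "score_a"], m.loc[ok, "score_b"])

    def test_small_pool_gives_missing_score(self, rna_ensemble, tiny_sim):
        _, data, _ = tiny_sim
        model, _, _ = rna_ensemble[1]
        tbl = compute_sexbias_table([model], data, pool_neighbors=False,
                                    min_pooled_cells=10**6)
        assert tbl["score"].isna().all()

    def test_unknown_sex_level_rejected(self, rna_ensemble, tiny_sim):
        _, data, _ = tiny_sim
        model, _, _ = rna_ensemble[1]
        with pytest.raises(ValueError, match="unknown"):
            compute_sexbias_table([model], data, female="Q")


class TestValidationProcedure:
    def test_model_scores_beat_nearest_time_de_baseline(self, sex_heldout_models,
                                                        tiny_sim):
        """With the male sample held out at one time point, sex-bias scores
        rank that time point's planted female-biased genes better than DE
        carried over from the nearest sex-matched time point, in >= 2 of
        3 seeds (time-specific switch genes penalize the carry-over)."""
        spec, data, truth = tiny_sim
        G = spec.n_genes
        eval_t, near_t = 8.5, 8.25
        rna = data.modality_mask("RNA")
        t = data.time_days
        cond = data.obs["condition"].to_numpy()
        genes = list(truth.genes.index)
        labels = (truth.sex_lfc_at(genes, eval_t) > 0).astype(int)
        Xa = data.counts[rna & np.isclose(t, near_t) & (cond == "F")].toarray()[:, :G]
        Xb = data.counts[rna & np.isclose(t, near_t) & (cond == "M")].toarray()[:, :G]
        de = differential_expression(Xa, Xb)
        base_auroc = auroc(np.nan_to_num(de["t"].to_numpy(), nan=0.0), labels)
        wins = 0
        for model in sex_heldout_models:
            tbl = compute_sexbias_table([model], data, pool_neighbors=False)
            sub = tbl[np.isclose(tbl["time_days"], eval_t)].dropna(subset=["score"])
            med = sub.groupby("gene")["score"].median().reindex(genes)
            model_auroc = auroc(np.nan_to_num(med.to_numpy(), nan=0.5), labels)
            wins += model_auroc > base_auroc
        assert wins >= 2
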