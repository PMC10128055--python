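"""Trade-off scores, strategy clustering, and cluster characterization."""

import numpy as np
import pandas as pd
import pytest

from siptraits import (
    ClusterModel,
    FeatureCensus,
    InvestmentScores,
    characterize_clusters,
    fit_clusters,
    investment_scores,
    label_strategies,
    predict,
    scores_from_counts,
)
from siptraits.lifehistory import strategy_taxon_table
from siptraits.errors import UndefinedStatisticError, ValidationError


def make_census(tf=120, se=35, sm=25, overlap=10, mt=100, genes=4000):
    return FeatureCensus(
        unit_id="u",
        n_genes=genes,
        counts={"MCP": 0, "MT": mt, "ADH": 0, "TF": tf, "OSM": 0, "DOR": 0, "SE": se},
        smbc_count=2,
        smbc_gene_count=sm,
        smbc_se_overlap=overlap,
    )


class TestInvestmentScores:
    def test_frozen_examples(self):
        s = investment_scores(make_census())
        assert s.tf_per_gene == pytest.approx(120 / 4000)  # 0.03
        assert s.acquisition_ratio == pytest.approx((35 + 25 - 10) / 100)  # 0.5

    def test_overlap_subtracted_once(self):
        s0 = investment_scores(make_census(overlap=0))
        s10 = investment_scores(make_census(overlap=10))
        assert s0.acquisition_ratio - s10.acquisition_ratio == pytest.approx(0.1)

    def test_overlap_above_components_rejected(self):
        with pytest.raises(ValidationError):
            investment_scores(make_census(), overlap=30)  # > min(SE, SM genes)

    def test_zero_transporters_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            investment_scores(make_census(mt=0))

    def test_scores_from_counts_matches_and_excludes(self, caplog):
        df = pd.DataFrame(
            {
                "TF": [120, 50],
                "SE": [35, 5],
                "MT": [100, 0],
                "n_genes": [4000, 3000],
                "smbc_genes": [25, 0],
                "se_overlap": [10, 0],
            },
            index=pd.Index(["G1", "G2"], name="genome_id"),
        )
        with caplog.at_level("WARNING", logger="siptraits"):
            scores = scores_from_counts(df)
        assert [s.unit_id for s in scores] == ["G1"]
        assert scores[0].tf_per_gene == pytest.approx(0.03)
        assert scores[0].acquisition_ratio == pytest.approx(0.5)
        assert any("G2" in r.message for r in caplog.records)


def blob_scores(rng, center, n, sd=0.02, prefix="u"):
    """Tight Gaussian blob in (tf_per_gene, acquisition_ratio) space."""
    tf = np.clip(rng.normal(center[0], sd * center[0] + 1e-4, n), 1e-4, 0.99)
    acq = np.clip(rng.normal(center[1], sd * center[1] + 1e-3, n), 1e-3, None)
    return [
        InvestmentScores(f"{prefix}{i}", float(t), float(a))
        for i, (t, a) in enumerate(zip(tf, acq))
    ]


# well-separated archetype centroids: S lowest tf; C vs R split on acquisition
CENTERS = {"C": (0.030, 0.50), "S": (0.012, 0.20), "R": (0.032, 0.05)}


def three_blob_training(seed=0, n=15):
    rng = np.random.default_rng(seed)
    scores, truth = [], {}
    for strat, center in CENTERS.items():
        blob = blob_scores(rng, center, n, prefix=strat)
        scores.extend(blob)
        truth.update({s.unit_id: strat for s in blob})
    return scores, truth


class TestClustering:
    def test_recovers_planted_strategies(self):
        scores, truth = three_blob_training()
        model = fit_clusters(scores, seed=1)
        assigned = {a.unit_id: a.strategy for a in predict(model, scores)}
        assert assigned == truth

    def test_training_assignments_consistent_with_predict(self):
        scores, _ = three_blob_training()
        model = fit_clusters(scores, seed=1)
        again = predict(model, scores)
        assert all(
            model.training_assignments[a.unit_id] == a.cluster for a in again
        )

    def test_seeded_fit_is_deterministic(self):
        scores, _ = three_blob_training()
        m1 = fit_clusters(scores, seed=42)
        m2 = fit_clusters(scores, seed=42)
        np.testing.assert_allclose(m1.centroids, m2.centroids)
        assert m1.training_assignments == m2.training_assignments

    def test_axis_scale_invariance_of_partition(self):
        # multiplying one raw axis by a constant must not change the
        # partition because axes are z-scored before clustering
        scores, _ = three_blob_training()
        scaled = [
            InvestmentScores(s.unit_id, s.tf_per_gene, s.acquisition_ratio * 7.0)
            for s in scores
        ]
        p1 = {a.unit_id: a.cluster for a in predict(fit_clusters(scores, seed=3),
                                                    scores)}
        p2 = {a.unit_id: a.cluster for a in predict(fit_clusters(scaled, seed=3),
                                                    scaled)}
        # compare as partitions (cluster ids may permute)
        groups1 = {}
        groups2 = {}
        for u in p1:
            groups1.setdefault(p1[u], set()).add(u)
            groups2.setdefault(p2[u], set()).add(u)
        assert {frozenset(g) for g in groups1.values()} == {
            frozenset(g) for g in groups2.values()
        }

    def test_prediction_uses_training_scaling(self):
        scores, truth = three_blob_training(seed=0)
        model = fit_clusters(scores, seed=1)
        # a lone new point near the S centroid must land in S even though
        # rescaling on the singleton set would be impossible/meaningless
        new = [InvestmentScores("new", 0.012, 0.20)]
        assert predict(model, new)[0].strategy == "S"

    def test_too_few_units_rejected(self):
        with pytest.raises(ValidationError):
            fit_clusters(blob_scores(np.random.default_rng(0), (0.03, 0.5), 2))

    def test_zero_variance_axis_rejected(self):
        flat = [InvestmentScores(f"u{i}", 0.03, float(i) / 10 + 0.1) for i in range(6)]
        with pytest.raises(ValidationError):
            fit_clusters(flat)

    def test_k1_centroid_at_origin_of_scaled_space(self):
        scores, _ = three_blob_training()
        model = fit_clusters(scores, k=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], [0.0, 0.0], atol=1e-12)
        assert model.cluster_to_strategy == {}

    def test_model_round_trip(self, tmp_path):
        scores, _ = three_blob_training()
        model = fit_clusters(scores, seed=5)
        p = tmp_path / "model.json"
        model.to_json(p)
        again = ClusterModel.from_json(p)
        np.testing.assert_allclose(model.centroids, again.centroids)
        assert again.cluster_to_strategy == model.cluster_to_strategy
        assert again.training_assignments == model.training_assignments
        a1 = predict(model, scores)
        a2 = predict(again, scores)
        assert [(x.unit_id, x.cluster) for x in a1] == [
            (x.unit_id, x.cluster) for x in a2
        ]


class TestLabelStrategies:
    def model_with_centroids(self, raw):
        raw = np.asarray(raw, dtype=float)
        mean = np.zeros(2)
        sd = np.ones(2)
        return ClusterModel(mean=mean, sd=sd, centroids=raw, k=len(raw), seed=0)

    def test_labeling_rule(self):
        m = self.model_with_centroids([[0.03, 0.5], [0.012, 0.2], [0.032, 0.05]])
        assert label_strategies(m) == {0: "C", 1: "S", 2: "R"}

    def test_tie_on_tf_goes_to_lowest_index(self, caplog):
        m = self.model_with_centroids([[0.01, 0.5], [0.01, 0.2], [0.03, 0.05]])
        with caplog.at_level("WARNING", logger="siptraits"):
            labels = label_strategies(m)
        assert labels[0] == "S"
        assert any("tie" in r.message for r in caplog.records)

    def test_k_not_three_gives_empty_map(self):
        m = self.model_with_centroids([[0.01, 0.5], [0.03, 0.05]])
        assert label_strategies(m) == {}


class TestCharacterizeClusters:
    def test_separated_groups_flagged_with_dunn_pairs(self):
        scores, truth = three_blob_training(seed=2, n=10)
        model = fit_clusters(scores, seed=1)
        assignments = predict(model, scores)
        rng = np.random.default_rng(0)
        shift = {"C": 0.0, "S": 0.0, "R": 4.0}
        values = pd.DataFrame(
            {"max_lfc": [shift[truth[s.unit_id]] + rng.normal(0, 0.5)
                         for s in scores]},
            index=[s.unit_id for s in scores],
        )
        res = characterize_clusters(assignments, values)
        assert len(res) == 1 and res[0].p < 0.05
        assert len(res[0].pairs) == 3
        rs = [p for p in res[0].pairs if "R" in (p.group_i, p.group_j)
              and "S" in (p.group_i, p.group_j)]
        assert rs and rs[0].p_adj < 0.05

    def test_null_column_gets_no_pairs(self):
        scores, _ = three_blob_training(seed=3, n=10)
        model = fit_clusters(scores, seed=1)
        assignments = predict(model, scores)
        values = pd.DataFrame(
            {"flat": np.zeros(len(scores))}, index=[s.unit_id for s in scores]
        )
        res = characterize_clusters(assignments, values)
        assert res[0].p == 1.0 and res[0].pairs == ()

    def test_degenerate_sizes_skipped(self, caplog):
        scores, _ = three_blob_training(seed=4, n=10)
        model = fit_clusters(scores, seed=1)
        assignments = predict(model, scores)[:1]  # single unit
        values = pd.DataFrame({"x": [1.0]}, index=[assignments[0].unit_id])
        with caplog.at_level("WARNING", logger="siptraits"):
            assert characterize_clusters(assignments, values) == []


def test_strategy_taxon_table():
    scores, truth = three_blob_training(seed=5, n=5)
    model = fit_clusters(scores, seed=1)
    assignments = predict(model, scores)
    taxa = {s.unit_id: ("Proteobacteria" if truth[s.unit_id] == "C" else "Firmicutes")
            for s in scores}
    table = strategy_taxon_table(assignments, taxa)
    c_rows = table[table["strategy"] == "C"]
    assert set(c_rows["taxon"]) == {"Proteobacteria"}
    assert c_rows["n_units"].sum() == 5
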