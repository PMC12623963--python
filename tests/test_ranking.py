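import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from foldrank import (
    Conformation,
    DecoyPoolSpec,
    FAST_POOL_PARAMS,
    ScoreTable,
    SelectionConfig,
    aggregate_scores,
    cluster_models,
    diversity_select,
    make_decoys,
    make_reference_chain,
    order_models,
    pairwise_matrix,
    pss,
    select_top,
)
from foldrank.errors import ArgumentError, ConfigError


def table_of(**columns) -> ScoreTable:
    n = len(next(iter(columns.values())))
    return ScoreTable([f"m{i}" for i in range(n)],
                      {k: np.asarray(v, float) for k, v in columns.items()})


@pytest.fixture(scope="module")
def two_conformation_pool():
    """90/10 pool: dominant wrong conformation, minority correct one."""
    ref = make_reference_chain(40, "helix", rng_seed=42)
    spec = DecoyPoolSpec(
        n_models=60,
        sigma_grid=(0.8,),
        conformations=(Conformation(weight=0.9, hinge_angle_deg=120.0),
                       Conformation(weight=0.1, hinge_angle_deg=0.0)),
        rng_seed=42,
    )
    models, truth = make_decoys(ref, spec)
    sim = pairwise_matrix(models, params=FAST_POOL_PARAMS)
    return models, truth, sim


class TestPss:
    def test_all_ones(self):
        assert pss(np.ones((4, 4))).tolist() == [1.0] * 4

    def test_hand_arithmetic(self):
        sim = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
        values = pss(sim)
        assert values[0] == pytest.approx(0.55)
        assert values[2] == pytest.approx(0.2)
        assert values[0] > values[2]

    def test_permutation_equivariance(self, rng):
        sim = rng.uniform(0.2, 1.0, (5, 5))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        perm = rng.permutation(5)
        assert pss(sim[np.ix_(perm, perm)]) == pytest.approx(pss(sim)[perm])

    def test_singleton_rejected(self):
        with pytest.raises(ArgumentError):
            pss(np.ones((1, 1)))

    def test_duplicating_a_model_never_lowers_its_pss(self):
        # consensus bias: copies of a model raise its mean similarity
        base = np.array([[1.0, 0.4, 0.3],
                         [0.4, 1.0, 0.5],
                         [0.3, 0.5, 1.0]])
        p0 = pss(base)[0]
        for k in (1, 2, 4):
            n = 3 + k
            sim = np.ones((n, n))
            sim[:3, :3] = base
            for extra in range(3, n):  # extras are near-copies of model 0
                sim[extra, 1:3] = sim[1:3, extra] = base[0, 1:3]
                sim[extra, 0] = sim[0, extra] = 0.99
            pk = pss(sim)[0]
            assert pk >= p0 - 1e-12
            p0 = pk


class TestAggregate:
    def test_single_column_preserves_ranking(self):
        t = table_of(gate=[0.1, 0.9, 0.4])
        agg = aggregate_scores(t, ["gate"])
        assert np.argsort(agg).tolist() == np.argsort(t.column("gate")).tolist()

    def test_two_opposed_columns_tie_broken_lexicographically(self):
        t = table_of(a=[1.0, 0.0], b=[0.0, 1.0])
        agg = aggregate_scores(t, ["a", "b"])
        assert agg == pytest.approx([0.5, 0.5])
        assert order_models(t, agg) == ["m0", "m1"]

    def test_constant_column_contributes_half(self):
        t = table_of(c=[7.0, 7.0, 7.0])
        assert aggregate_scores(t, ["c"]) == pytest.approx([0.5, 0.5, 0.5])

    def test_unknown_column_is_lookup_error(self):
        with pytest.raises(ConfigError, match="nope"):
            aggregate_scores(table_of(a=[1.0, 2.0]), ["nope"])

    def test_model_missing_all_scores_ranked_last(self):
        t = table_of(a=[0.9, np.nan, 0.1], b=[0.8, np.nan, 0.2])
        agg = aggregate_scores(t, ["a", "b"])
        assert np.isnan(agg[1])
        assert order_models(t, agg)[-1] == "m1"

    def test_mixed_scales_normalised(self):
        # plDDT on 0-100 must not drown a 0-1 score after normalisation
        t = table_of(plddt_global=[90.0, 50.0], gate=[0.0, 1.0])
        agg = aggregate_scores(t, ["plddt_global", "gate"])
        assert agg == pytest.approx([0.5, 0.5])


class TestClustering:
    def test_planted_partition_recovered(self, two_conformation_pool):
        models, truth, sim = two_conformation_pool
        table = ScoreTable([m.model_id for m in models],
                           {"gate": truth["plddt_global"].to_numpy()})
        config = SelectionConfig(strategy="multicom_gate", n_clusters=2, rng_seed=0)
        out = cluster_models(sim, table, config)
        ari = adjusted_rand_score(truth["conformation"].to_numpy(), out.labels)
        assert ari == pytest.approx(1.0)

    def test_degenerate_pool_collapses_to_one_cluster(self):
        sim = np.ones((6, 6))
        table = table_of(gate=np.linspace(0, 1, 6))
        out = cluster_models(sim, table, SelectionConfig(strategy="multicom_gate"))
        assert set(out.labels) == {0}
        assert out.representatives == ["m5"]  # highest gate
        assert out.cluster_sizes == [6]

    def test_same_seed_reproducible(self, two_conformation_pool, rng):
        models, truth, sim = two_conformation_pool
        table = ScoreTable([m.model_id for m in models],
                           {"gate": truth["plddt_global"].to_numpy()})
        config = SelectionConfig(strategy="multicom_gate", rng_seed=7)
        a = cluster_models(sim, table, config)
        b = cluster_models(sim, table, config)
        assert np.array_equal(a.labels, b.labels)
        assert a.representatives == b.representatives


class TestDiversitySelect:
    def test_degenerate_identical_pool_falls_back_to_rank_order(self):
        n = 10
        sim = np.ones((n, n))
        ids = [f"m{i}" for i in range(n)]
        ranked = sorted(ids, key=lambda m: int(m[1:]))
        out = diversity_select(ranked, sim, ids,
                               SelectionConfig(require_af3=False))
        assert out == ranked[:5]

    def test_five_mutually_dissimilar_selected_in_rank_order(self):
        n = 8
        sim = np.full((n, n), 0.95)
        np.fill_diagonal(sim, 1.0)
        ids = [f"m{i}" for i in range(n)]
        diverse = [0, 2, 4, 5, 7]
        for a in diverse:
            for b in diverse:
                if a != b:
                    sim[a, b] = 0.3
        ranked = ids  # rank order m0..m7
        out = diversity_select(ranked, sim, ids,
                               SelectionConfig(require_af3=False))
        assert out == [f"m{i}" for i in diverse]

    def test_af3_slot_guarantee(self):
        n = 6
        sim = np.full((n, n), 0.2)
        np.fill_diagonal(sim, 1.0)
        ids = [f"m{i}" for i in range(n)]
        generators = {m: "af2" for m in ids}
        generators["m5"] = "af3"
        out = diversity_select(ids, sim, ids, SelectionConfig(), generators)
        assert out[-1] == "m5"
        assert len(out) == 5


class TestSelectTop:
    def _pool(self, rng):
        n = 12
        sim = rng.uniform(0.3, 0.9, (n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        table = table_of(
            plddt_global=rng.uniform(50, 95, n),
            gate=rng.uniform(0, 1, n),
            af3_ranking=rng.uniform(0, 1, n),
            gcpnet_ema=rng.uniform(0, 1, n),
            enqa=rng.uniform(0, 1, n),
            pss=rng.uniform(0, 1, n),
        )
        generators = {m: ("af3" if i % 3 == 0 else "af2")
                      for i, m in enumerate(table.model_ids)}
        return sim, table, generators

    def test_multicom_ai_equals_diversity_select_over_plddt(self, rng):
        sim, table, generators = self._pool(rng)
        config = SelectionConfig(strategy="multicom_ai")
        got = select_top(sim, table, config, generators)
        ranked = order_models(table, aggregate_scores(table, ["plddt_global"]))
        assert got == diversity_select(ranked, sim, table.model_ids, config,
                                       generators)

    def test_multicom_llm_top1_is_af3_ranking_argmax(self, rng):
        sim, table, generators = self._pool(rng)
        got = select_top(sim, table, SelectionConfig(strategy="multicom_llm"),
                         generators)
        expected = table.model_ids[int(np.argmax(table.column("af3_ranking")))]
        assert got[0] == expected

    def test_multicom_human_top1_is_normalised_mean_argmax(self):
        # gate and plddt disagree; the normalised mean decides
        table = table_of(gate=[0.95, 0.2, 0.6], plddt_global=[10.0, 90.0, 80.0])
        sim = np.full((3, 3), 0.5)
        np.fill_diagonal(sim, 1.0)
        got = select_top(sim, table, SelectionConfig(strategy="multicom_human",
                                                     n_select=3))
        norm_mean = (np.array([1.0, 0.0, 8 / 15]) + np.array([0.0, 1.0, 7 / 8])) / 2
        assert got[0] == table.model_ids[int(np.argmax(norm_mean))]

    def test_missing_column_names_strategy_and_column(self):
        table = table_of(plddt_global=[80.0, 70.0])
        sim = np.ones((2, 2))
        with pytest.raises(ConfigError, match="multicom_gate.*gate"):
            select_top(sim, table, SelectionConfig(strategy="multicom_gate"))

    @pytest.mark.parametrize("strategy", ["multicom_ai", "multicom_gate",
                                          "multicom_llm", "multicom",
                                          "multicom_human"])
    def test_every_strategy_returns_n_distinct_ids(self, strategy, rng):
        sim, table, generators = self._pool(rng)
        got = select_top(sim, table, SelectionConfig(strategy=strategy),
                         generators)
        assert len(got) == 5
        assert len(set(got)) == 5
        assert set(got) <= set(table.model_ids)

    def test_override_forced_to_front(self, rng):
        sim, table, generators = self._pool(rng)
        got = select_top(sim, table, SelectionConfig(strategy="multicom_ai"),
                         generators, override=["m7", "m3"])
        assert got[:2] == ["m7", "m3"]
        assert len(set(got)) == 5

    def test_unknown_override_model_rejected(self, rng):
        sim, table, generators = self._pool(rng)
        with pytest.raises(ConfigError, match="ghost"):
            select_top(sim, table, SelectionConfig(strategy="multicom_ai"),
                       generators, override=["ghost"])


class TestRareClusterRescue:
    def test_gate_clustering_rescues_minority_but_pss_picks_majority(
        self, two_conformation_pool
    ):
        models, truth, sim = two_conformation_pool
        minority = set(truth.loc[truth["conformation"] == 1, "model_id"])
        consensus = pss(sim)
        table = ScoreTable([m.model_id for m in models], {"gate": consensus})
        # pure consensus ranking: top-1 sits in the dominant cluster
        pss_top1 = order_models(table, consensus)[0]
        assert pss_top1 not in minority
        # clustering-based selection still carries a minority representative
        got = select_top(sim, table,
                         SelectionConfig(strategy="multicom_gate",
                                         require_af3=False))
        assert set(got) & minority
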