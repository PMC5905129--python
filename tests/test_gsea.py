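import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from spheretrace import synthetic
from spheretrace.gsea import (
    ExpressionDataset,
    ModuleEnrichment,
    NodeSetCollection,
    RankedNodeList,
    collapse_to_nodes,
    cross_dataset_concordance,
    enrichment_score,
    filter_modules,
    permutation_nes,
    score_collection,
    snr_metric,
)


def brute_force_es(metrics, hits, weight_exponent):
    """Independent step-by-step prefix-walk oracle (pure Python)."""
    n = len(metrics)
    n_hit = sum(hits)
    assert n_hit > 0
    if n_hit == n:
        return 1.0
    wsum = sum(abs(m) ** weight_exponent for m, h in zip(metrics, hits) if h)
    run, best = 0.0, 0.0
    for m, h in zip(metrics, hits):
        if h:
            run += abs(m) ** weight_exponent / wsum
        else:
            run -= 1.0 / (n - n_hit)
        if abs(run) > abs(best):
            best = run
    return best


class TestSNR:
    def test_identical_groups_zero(self):
        x = np.array([1.3, 0.2, -0.5])
        assert snr_metric(x, x) == 0.0

    def test_antisymmetry(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.5, 0.1, 0.2])
        assert snr_metric(a, b) == pytest.approx(-snr_metric(b, a))

    def test_constant_groups_hand_oracle(self):
        # [DERIVED] floored formula by direct arithmetic:
        # sd_a -> max(0, 0.2*1, 0.005) = 0.2 ; sd_b -> max(0, 0, 0.005) = 0.005
        a = np.array([1.0, 1.0, 1.0])
        b = np.array([0.0, 0.0, 0.0])
        assert snr_metric(a, b) == pytest.approx(1.0 / 0.205, abs=1e-12)

    def test_short_vectors_raise(self):
        with pytest.raises(ValueError):
            snr_metric(np.array([1.0]), np.array([1.0, 2.0]))

    @given(
        a=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        b=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
    )
    @settings(max_examples=50)
    def test_antisymmetry_property(self, a, b):
        a, b = np.array(a), np.array(b)
        assert snr_metric(a, b) == pytest.approx(-snr_metric(b, a), abs=1e-12)


class TestCollapse:
    def test_max_abs_metric_retained_with_sign(self, tiny_dataset):
        ranked = collapse_to_nodes(tiny_dataset)
        metrics = ranked.as_series()
        # EC 1.1.1.1 has candidates p1, p2: retained value must be the one
        # with larger |SNR|, sign preserved
        mask = tiny_dataset.class_mask
        per_probe = {
            p: snr_metric(
                tiny_dataset.values.loc[p][mask], tiny_dataset.values.loc[p][~mask]
            )
            for p in ["p1", "p2"]
        }
        expected = max(per_probe.values(), key=abs)
        assert metrics["1.1.1.1"] == pytest.approx(expected)

    def test_single_probe_identity(self, tiny_dataset):
        ranked = collapse_to_nodes(tiny_dataset)
        mask = tiny_dataset.class_mask
        expected = snr_metric(
            tiny_dataset.values.loc["p4"][mask], tiny_dataset.values.loc["p4"][~mask]
        )
        assert ranked.as_series()["3.3.3.3"] == pytest.approx(expected)

    def test_multi_ec_gene_contributes_to_each(self, tiny_dataset):
        ranked = collapse_to_nodes(tiny_dataset)
        assert {"1.1.1.1", "2.2.2.2", "3.3.3.3"} == set(ranked.nodes)

    def test_row_order_invariance(self, tiny_dataset):
        ranked = collapse_to_nodes(tiny_dataset)
        shuffled = ExpressionDataset(
            values=tiny_dataset.values.iloc[::-1],
            labels=tiny_dataset.labels,
            probe_to_gene=tiny_dataset.probe_to_gene,
            gene_to_ec=tiny_dataset.gene_to_ec,
            classes=tiny_dataset.classes,
        )
        ranked2 = collapse_to_nodes(shuffled)
        np.testing.assert_array_equal(ranked.nodes, ranked2.nodes)
        np.testing.assert_allclose(ranked.metrics, ranked2.metrics)

    def test_empty_annotation_raises(self, tiny_dataset):
        with pytest.raises(ValueError, match="annotation"):
            collapse_to_nodes(
                ExpressionDataset(
                    values=tiny_dataset.values,
                    labels=tiny_dataset.labels,
                    probe_to_gene={},
                    gene_to_ec={},
                    classes=tiny_dataset.classes,
                )
            )

    def test_constant_matrix_no_error(self, tiny_dataset):
        const = ExpressionDataset(
            values=tiny_dataset.values * 0 + 1.0,
            labels=tiny_dataset.labels,
            probe_to_gene=tiny_dataset.probe_to_gene,
            gene_to_ec=tiny_dataset.gene_to_ec,
            classes=tiny_dataset.classes,
        )
        ranked = collapse_to_nodes(const)
        assert np.isfinite(ranked.metrics).all()

    def test_planted_nodes_rank_higher(self, node_sets, planted_dataset):
        # [DERIVED] simulation: planted module nodes occupy higher mean rank
        ranked = collapse_to_nodes(planted_dataset)
        planted = node_sets["M0000"]
        pos = {n: i for i, n in enumerate(ranked.nodes)}
        planted_ranks = [pos[n] for n in planted]
        other_ranks = [pos[n] for n in ranked.nodes if n not in planted]
        p = mannwhitneyu(planted_ranks, other_ranks, alternative="less").pvalue
        assert p < 0.01


class TestEnrichmentScore:
    def test_prefix_set_gives_one(self):
        ranked = RankedNodeList(
            nodes=np.array(list("abcde")), metrics=np.array([5.0, 4, 3, 2, 1])
        )
        assert enrichment_score(ranked, {"a", "b"}, weight_exponent=0) == pytest.approx(1.0)

    def test_worked_five_node_example(self):
        # [DERIVED] brute-force running-sum oracle over all 5 steps:
        # hits at ranks 1 and 4, w=1: steps 5/7, -1/3, -1/3, +2/7, -1/3
        ranked = RankedNodeList(
            nodes=np.array(list("abcde")), metrics=np.array([5.0, 4, 3, 2, 1])
        )
        expected = brute_force_es([5, 4, 3, 2, 1], [1, 0, 0, 1, 0], 1.0)
        assert expected == pytest.approx(5 / 7)
        assert enrichment_score(ranked, {"a", "d"}) == pytest.approx(expected, abs=1e-12)

    def test_all_nodes_degenerate_one(self):
        ranked = RankedNodeList(nodes=np.array(list("abc")), metrics=np.array([3.0, 2, 1]))
        assert enrichment_score(ranked, {"a", "b", "c"}) == 1.0

    def test_empty_intersection_raises(self):
        ranked = RankedNodeList(nodes=np.array(list("abc")), metrics=np.array([3.0, 2, 1]))
        with pytest.raises(ValueError, match="not represented"):
            enrichment_score(ranked, {"z"})

    @given(st.data())
    @settings(max_examples=200)
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(3, 50))
        metrics = np.sort(
            np.array(data.draw(st.lists(
                st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n
            )))
        )[::-1]
        k = data.draw(st.integers(1, n))
        hit_idx = data.draw(st.permutations(range(n)))[:k]
        hits = np.zeros(n, dtype=bool)
        hits[list(hit_idx)] = True
        wexp = data.draw(st.sampled_from([0.0, 0.5, 1.0, 2.0]))
        ranked = RankedNodeList(
            nodes=np.array([f"n{i:02d}" for i in range(n)]), metrics=metrics
        )
        node_set = set(ranked.nodes[hits])
        es = enrichment_score(ranked, node_set, weight_exponent=wexp)
        oracle = brute_force_es(list(metrics), list(hits), wexp)
        assert es == pytest.approx(oracle, abs=1e-12)
        assert -1 - 1e-12 <= es <= 1 + 1e-12

    def test_shift_invariance_at_weight_zero(self):
        rng = np.random.default_rng(3)
        metrics = np.sort(rng.normal(size=20))[::-1]
        nodes = np.array([f"n{i}" for i in range(20)])
        node_set = set(nodes[[1, 5, 9]])
        a = enrichment_score(RankedNodeList(nodes, metrics), node_set, 0.0)
        b = enrichment_score(RankedNodeList(nodes, metrics + 7.5), node_set, 0.0)
        assert a == pytest.approx(b, abs=1e-12)


class TestPermutationNES:
    def test_sign_preservation_and_determinism(self, node_sets, planted_dataset):
        r1 = permutation_nes(
            planted_dataset, node_sets["M0000"], n_perm=150, seed=7, mode="phenotype"
        )
        r2 = permutation_nes(
            planted_dataset, node_sets["M0000"], n_perm=150, seed=7, mode="phenotype"
        )
        assert np.sign(r1.nes) == np.sign(r1.es)
        assert (r1.es, r1.nes, r1.p) == (r2.es, r2.nes, r2.p)

    def test_planted_module_detected(self, node_sets, planted_dataset):
        # [DERIVED] power: effect size 2, planted module -> strong positive NES
        res = permutation_nes(
            planted_dataset, node_sets["M0000"], n_perm=300, seed=1, mode="phenotype"
        )
        assert res.nes > 1.2
        assert res.p < 0.05
        assert res.enriched_in == planted_dataset.classes[0]

    def test_small_classes_use_node_permutation(self, tiny_dataset):
        res = permutation_nes(tiny_dataset, {"1.1.1.1", "2.2.2.2"}, n_perm=120, seed=0)
        assert 0 <= res.p <= 1

    def test_phenotype_mode_rejected_for_small_classes(self, tiny_dataset):
        with pytest.raises(ValueError, match=">= 7 samples"):
            permutation_nes(
                tiny_dataset, {"1.1.1.1"}, n_perm=120, seed=0, mode="phenotype"
            )

    def test_n_perm_floor(self, node_sets, planted_dataset):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_nes(planted_dataset, node_sets["M0000"], n_perm=10, seed=0)


class TestFilterModules:
    def _ranked(self, n):
        return RankedNodeList(
            nodes=np.array([f"n{i}" for i in range(n)]),
            metrics=np.arange(n, 0, -1, dtype=float),
        )

    def test_boundaries(self):
        ranked = self._ranked(600)
        collection = NodeSetCollection(
            sets={
                "two": frozenset(["n0", "n1"]),
                "three": frozenset(["n0", "n1", "n2"]),
                "big": frozenset(f"n{i}" for i in range(501)),
                "max": frozenset(f"n{i}" for i in range(500)),
            }
        )
        kept = filter_modules(collection, ranked)
        assert set(kept.sets) == {"three", "max"}

    def test_represented_means_present_in_ranking(self):
        ranked = self._ranked(5)
        collection = NodeSetCollection(
            sets={"m": frozenset(["n0", "n1", "zz", "yy"])}  # only 2 represented
        )
        assert len(filter_modules(collection, ranked)) == 0

    def test_idempotent(self, node_sets):
        ranked = self._ranked(100)
        big = NodeSetCollection(
            sets={"a": frozenset(["n1", "n2", "n3"]), "b": frozenset(["n1"])}
        )
        once = filter_modules(big, ranked)
        twice = filter_modules(once, ranked)
        assert once.sets == twice.sets


def _make_enrich(nes_by_module):
    return [
        ModuleEnrichment(
            module_id=m, n_nodes=5, es=np.sign(v) * 0.5, nes=v, p=0.01,
            enriched_in="A" if v >= 0 else "B",
        )
        for m, v in nes_by_module.items()
    ]


class TestConcordance:
    def test_identity(self):
        a = _make_enrich({"m1": 2.0, "m2": -1.5, "m3": 0.3, "m4": 1.3})
        res = cross_dataset_concordance(a, a, tau=1.2)
        assert res.pearson == pytest.approx(1.0)
        assert res.shared_up == ["m1", "m4"]
        assert res.shared_down == ["m2"]

    def test_antisymmetry(self):
        a = _make_enrich({"m1": 2.0, "m2": -1.5, "m3": 0.3})
        b = _make_enrich({"m1": -2.0, "m2": 1.5, "m3": -0.3})
        res = cross_dataset_concordance(a, b, tau=1.2)
        assert res.pearson == pytest.approx(-1.0)
        assert res.shared_up == [] and res.shared_down == []

    def test_too_few_common_modules(self):
        a = _make_enrich({"m1": 1.0, "m2": 2.0})
        b = _make_enrich({"m3": 1.0, "m4": 2.0})
        with pytest.raises(ValueError, match=">= 3 modules"):
            cross_dataset_concordance(a, b)

    def test_planted_modules_in_shared_list(self):
        # [DERIVED] simulation (single replicate; acceptance covers 50)
        node_sets = synthetic.gen_node_sets(12, 8, seed=3)
        planted = {"M0000": 1, "M0001": 1}
        results = []
        for seed in (101, 202):
            truth = synthetic.ExpressionTruth(
                planted_modules=planted, effect_size=2.0, seed=seed
            )
            ds = synthetic.gen_expression_dataset(120, (15, 15), node_sets, truth)
            results.append(
                score_collection(ds, node_sets, n_perm=150, seed=seed, mode="phenotype")
            )
        res = cross_dataset_concordance(results[0], results[1], tau=1.2)
        assert set(planted) <= set(res.shared_up)


class TestScoreCollection:
    def test_q_values_attached_and_filterd(self, node_sets, planted_dataset):
        results = score_collection(
            planted_dataset, node_sets, n_perm=120, seed=0, mode="phenotype"
        )
        assert results
        for r in results:
            assert 0 <= r.p <= 1
            assert 0 <= r.q <= 1
            assert 3 <= r.n_nodes <= 500
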