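"""Consensus ranking: gate, top-decile ranks, Venn classes, confusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htsumd.analysis import ConformationCluster
from htsumd.energetics import HBondRecord
from htsumd.errors import ConfigError, ValidationError
from htsumd.ranking import (VennClass, confusion_metrics, hbond_gate,
                            hit_list, rank_pipeline, top_decile_count,
                            top_decile_ranks, venn_classify)


def make_cluster(uid, fragment="F1", size=50, dg_ave=-5.0, hyd_ave=5.0,
                 occupancies=(50.0,), dg_best=None, hyd_best=None):
    hb = [HBondRecord(0, 0, "PK1", occ) for occ in occupancies]
    dg_best = dg_ave - 1.0 if dg_best is None else dg_best
    hyd_best = hyd_ave + 1.0 if hyd_best is None else hyd_best
    return ConformationCluster(
        cluster_id=uid, fragment_id=fragment, replica_id=0,
        members=np.arange(size), size=size, population_pct=10.0,
        representative=0, dg_best=dg_best, dg_ave=dg_ave,
        hyd_best=hyd_best, hyd_ave=hyd_ave, hbonds=hb)


class TestHbondGate:
    def test_occupied_cluster_kept(self):
        assert len(hbond_gate([make_cluster(0, occupancies=(50.0,))])) == 1

    def test_cluster_without_records_removed(self):
        assert hbond_gate([make_cluster(0, occupancies=())]) == []

    def test_mixed_set_count(self):
        clusters = [make_cluster(i) for i in range(3)] + \
            [make_cluster(i, occupancies=()) for i in range(3, 5)]
        assert len(hbond_gate(clusters)) == 3

    def test_below_threshold_removed(self):
        clusters = [make_cluster(0, occupancies=(5.0,))]
        assert hbond_gate(clusters, min_occupancy=10.0) == []

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=0,
                    max_size=6),
           st.floats(min_value=0, max_value=100))
    @settings(max_examples=50)
    def test_monotone_in_threshold(self, occupancies, threshold):
        clusters = [make_cluster(0, occupancies=tuple(occupancies))]
        low = hbond_gate(clusters, min_occupancy=threshold / 2)
        high = hbond_gate(clusters, min_occupancy=threshold)
        assert len(high) <= len(low)


class TestTopDecileRanks:
    @pytest.mark.parametrize("n,k", [(30, 3), (681, 68), (5, 1), (1, 1),
                                     (100, 10)])
    def test_retained_count(self, n, k):
        assert top_decile_count(n) == k

    def test_ordering_directions(self):
        clusters = [make_cluster(0, size=10, dg_ave=-2.0, hyd_ave=1.0),
                    make_cluster(1, size=30, dg_ave=-9.0, hyd_ave=9.0),
                    make_cluster(2, size=20, dg_ave=-5.0, hyd_ave=5.0)]
        ranks = top_decile_ranks(clusters)
        assert ranks["SIZE_clust"].ordered == (1, 2, 0)
        assert ranks["HYD_clust"].ordered == (1, 2, 0)
        assert ranks["MMGBSA_clust"].ordered == (1, 2, 0)
        assert all(len(r.retained) == 1 for r in ranks.values())

    def test_tie_breaks_by_energy_then_uid(self):
        clusters = [make_cluster(0, size=20, dg_ave=-3.0),
                    make_cluster(1, size=20, dg_ave=-8.0),
                    make_cluster(2, size=20, dg_ave=-8.0)]
        ranks = top_decile_ranks(clusters)
        assert ranks["SIZE_clust"].ordered == (1, 2, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            top_decile_ranks([])


class TestVennClassify:
    def _clusters(self):
        # 10 clusters so k = 1 per rank; cluster 0 dominates everything
        clusters = [make_cluster(0, fragment="Fwin", size=100, dg_ave=-9.0,
                                 hyd_ave=9.0)]
        for i in range(1, 10):
            clusters.append(make_cluster(i, fragment=f"F{i}", size=10 + i % 3,
                                         dg_ave=-1.0 - 0.1 * i,
                                         hyd_ave=1.0 + 0.1 * i))
        return clusters

    def test_triple_membership_is_first_choice(self):
        clusters = self._clusters()
        ranks = top_decile_ranks(clusters)
        cluster_classes, calls = venn_classify(ranks, clusters)
        assert cluster_classes[0] == VennClass.FIRST_CHOICE
        assert calls["Fwin"].venn_class == VennClass.FIRST_CHOICE

    def test_pairwise_membership(self):
        clusters = [
            make_cluster(0, fragment="Fa", size=100, dg_ave=-2.0,
                         hyd_ave=9.0),     # HYD + SIZE
            make_cluster(1, fragment="Fb", size=10, dg_ave=-9.0,
                         hyd_ave=8.0),     # HYD + MMGBSA would need top-1...
        ] + [make_cluster(i, fragment=f"F{i}", size=50, dg_ave=-5.0,
                          hyd_ave=1.0) for i in range(2, 10)]
        ranks = top_decile_ranks(clusters)
        cluster_classes, _ = venn_classify(ranks, clusters)
        assert cluster_classes[0] == VennClass.HYD_SIZE

    def test_fragment_inherits_best_class(self):
        clusters = self._clusters()
        # second cluster of the winning fragment, mediocre everywhere
        clusters.append(make_cluster(10, fragment="Fwin", size=11,
                                     dg_ave=-1.0, hyd_ave=1.0))
        ranks = top_decile_ranks(clusters)
        _, calls = venn_classify(ranks, clusters)
        assert calls["Fwin"].venn_class == VennClass.FIRST_CHOICE
        assert calls["Fwin"].best_cluster_uid == 0

    def test_classes_partition_the_gated_set(self):
        rng = np.random.default_rng(0)
        clusters = [make_cluster(i, fragment=f"F{i % 7}",
                                 size=int(rng.integers(10, 200)),
                                 dg_ave=float(rng.uniform(-12, -1)),
                                 hyd_ave=float(rng.uniform(0, 30)))
                    for i in range(40)]
        ranks = top_decile_ranks(clusters)
        cluster_classes, _ = venn_classify(ranks, clusters)
        assert sorted(cluster_classes) == list(range(40))  # each exactly once
        k = top_decile_count(40)
        n_retained = {name: sum(1 for uid in cluster_classes
                                if uid in ranks[name].retained)
                      for name in ranks}
        assert all(v == k for v in n_retained.values())


class TestHitList:
    def _calls(self):
        clusters = [
            make_cluster(0, fragment="Fa", size=200, dg_ave=-9.0, hyd_ave=30),
            make_cluster(1, fragment="Fb", size=150, dg_ave=-2.0, hyd_ave=25),
            make_cluster(2, fragment="Fc", size=12, dg_ave=-8.0, hyd_ave=20),
        ] + [make_cluster(i, fragment=f"F{i}", size=15, dg_ave=-3.0,
                          hyd_ave=2.0) for i in range(3, 30)]
        ranks = top_decile_ranks(clusters)
        _, calls = venn_classify(ranks, clusters)
        return calls

    def test_first_choice_policy(self):
        calls = self._calls()
        assert hit_list(calls, "first_choice") == ["Fa"]

    def test_extended_adds_hyd_pairs(self):
        calls = self._calls()
        hits = hit_list(calls, "extended")
        assert hits == ["Fa", "Fb", "Fc"]

    def test_first_choice_subset_of_extended(self):
        calls = self._calls()
        assert set(hit_list(calls, "first_choice")) <= set(
            hit_list(calls, "extended"))

    def test_unknown_policy(self):
        with pytest.raises(ConfigError):
            hit_list(self._calls(), "bogus")

    def test_empty_classification(self):
        assert hit_list({}, "extended") == []


class TestConfusionMetrics:
    def test_screen_worked_example(self):
        """100 fragments, 16 true binders, 14 predictions of which 12
        correct: TP 12, FP 2, FN 4, TN 82, accuracy 94%."""
        truth = {f"F{i}" for i in range(16)}
        predicted = {f"F{i}" for i in range(12)} | {"X1", "X2"}
        counts = confusion_metrics(predicted, truth, total=100)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (12, 2, 4, 82)
        assert counts.accuracy == pytest.approx(0.94)

    def test_perfect_prediction(self):
        truth = {"a", "b"}
        counts = confusion_metrics(truth, truth, total=10)
        assert counts.accuracy == 1.0

    def test_predict_everything(self):
        universe = {f"F{i}" for i in range(100)}
        truth = {f"F{i}" for i in range(16)}
        counts = confusion_metrics(universe, truth, total=100)
        assert counts.accuracy == pytest.approx(0.16)

    def test_identity_total(self):
        counts = confusion_metrics({"a"}, {"b"}, total=5)
        assert counts.tp + counts.fp + counts.fn + counts.tn == 5

    def test_universe_too_small(self):
        with pytest.raises(ValidationError):
            confusion_metrics({"a", "b"}, {"c"}, total=2)


def test_rank_pipeline_smoke():
    clusters = [make_cluster(i, fragment=f"F{i % 5}", size=10 + i,
                             dg_ave=-1.0 - i * 0.3, hyd_ave=i * 0.5)
                for i in range(20)]
    clusters += [make_cluster(20 + i, fragment="Fnone", occupancies=())
                 for i in range(3)]
    report = rank_pipeline(clusters)
    assert len(report["gated"]) == 20
    assert "Fnone" not in report["calls"]
    assert isinstance(report["hits"], list)
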