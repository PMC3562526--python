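"""Chord-distance clustering, direction partition, bin enrichment, Venn cells."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from xspecies.chip_model import AnnotationMap, AnnotationRecord, DETable
from xspecies.postanalysis import (
    chord_distance,
    compare_up_sets,
    hcluster,
    partition_direction,
    wilcoxon_bin_enrichment,
)


class TestChordDistance:
    def test_orthogonal_unit_vectors(self):
        assert chord_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(np.sqrt(2))

    def test_scale_invariance(self):
        assert chord_distance(np.array([2.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_hand_value_sqrt_2_minus_sqrt2(self):
        d = chord_distance(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert d == pytest.approx(np.sqrt(2 - np.sqrt(2)), abs=1e-12)
        assert d == pytest.approx(0.76537, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            chord_distance(np.zeros(3), np.ones(3))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_equals_cosine_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=5)
        cos = x @ y / (np.linalg.norm(x) * np.linalg.norm(y))
        expected = np.sqrt(max(0.0, 2 - 2 * cos))
        assert chord_distance(x, y) == pytest.approx(expected, abs=1e-12)


class TestHcluster:
    def test_two_separable_direction_groups(self):
        """All-up vs all-down noiseless profiles split exactly at k=2."""
        up = np.tile([1.0, 1.0, 1.0, 2.0, 2.0, 2.0], (5, 1)) * np.arange(1, 6)[:, None]
        down = np.tile([2.0, 2.0, 2.0, 1.0, 1.0, 1.0], (5, 1)) * np.arange(1, 6)[:, None]
        ids = [f"u{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        res = hcluster(np.vstack([up, down]), ids, k=2)
        labels_up = {res.labels[i] for i in range(5)}
        labels_down = {res.labels[i] for i in range(5, 10)}
        assert len(labels_up) == 1 and len(labels_down) == 1 and labels_up != labels_down

    def test_k_equals_n_gives_singletons(self, rng):
        rows = rng.normal(size=(6, 4))
        res = hcluster(rows, [f"s{i}" for i in range(6)], k=6)
        assert sorted(res.labels) == [1, 2, 3, 4, 5, 6]

    def test_k_one_single_cluster(self, rng):
        rows = rng.normal(size=(5, 3))
        res = hcluster(rows, [f"s{i}" for i in range(5)], k=1)
        assert set(res.labels) == {1}

    def test_merge_heights_non_decreasing(self, rng):
        rows = rng.normal(size=(20, 6))
        res = hcluster(rows, [f"s{i}" for i in range(20)], k=4)
        heights = [h for _, _, h in res.merge_history]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="k"):
            hcluster(rng.normal(size=(3, 2)), ["a", "b", "c"], k=4)


class TestPartitionDirection:
    def _de(self):
        return DETable(pd.DataFrame({
            "log2fc": [1.738, -1.228, 0.1, 2.0],
            "p_raw": [0.0358, 0.0408, 0.9, 0.001],
            "p_adj": [0.04, 0.045, 0.95, 0.004],
            "direction": ["up", "down", "flat", "up"],
            "selected": [True, True, False, True],
        }, index=["FRUCT", "PL", "X", "Y"]))

    def test_reported_style_rows_partition(self):
        up, down = partition_direction(self._de())
        assert "FRUCT" in up and "PL" in down

    def test_union_is_selection(self):
        de = self._de()
        up, down = partition_direction(de)
        assert up | down == set(de.selected_ids) and not up & down

    def test_empty_selection(self):
        de = self._de()
        de.frame["selected"] = False
        up, down = partition_direction(de)
        assert up == set() and down == set()


def annotation_of(bins_by_id: dict[str, list[str]]) -> AnnotationMap:
    amap = AnnotationMap()
    for ps_id, bins in bins_by_id.items():
        amap[ps_id] = AnnotationRecord(gene_id=ps_id, bins=bins)
    return amap


class TestWilcoxonEnrichment:
    def test_exact_worked_fixture_p_2_over_35(self):
        """Members hold the top 3 of 7 ranks: two-sided exact p = 2/35."""
        fc = {"m1": 2.0, "m2": 1.8, "m3": 1.5, "o1": 0.1, "o2": -0.2, "o3": 0.0, "o4": 0.2}
        amap = annotation_of({k: (["hot"] if k.startswith("m") else ["cold"]) for k in fc})
        res = {r.bin: r for r in wilcoxon_bin_enrichment(fc, amap, min_bin_size=3)}
        assert res["hot"].p_raw == pytest.approx(2 / 35, abs=1e-12)
        assert res["hot"].direction == "up"

    def test_label_swap_flips_direction_preserves_p(self):
        fc = {"a": 2.0, "b": 1.8, "c": 1.5, "d": 0.1, "e": -0.2, "f": 0.0, "g": 0.2}
        hot = annotation_of({k: (["X"] if k in "abc" else ["Y"]) for k in fc})
        swapped = annotation_of({k: (["Y"] if k in "abc" else ["X"]) for k in fc})
        r1 = {r.bin: r for r in wilcoxon_bin_enrichment(fc, hot, 3)}
        r2 = {r.bin: r for r in wilcoxon_bin_enrichment(fc, swapped, 3)}
        assert r1["X"].p_raw == pytest.approx(r2["X"].p_raw, abs=1e-12)
        assert r1["X"].direction == "up" and r2["X"].direction == "down"

    def test_permutation_calibration(self, rng):
        """Null labels: rejection rate at 0.05 stays near or below nominal."""
        values = rng.normal(size=40)
        rejections = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(40)
            fc = {f"g{i}": float(values[perm[i]]) for i in range(40)}
            amap = annotation_of({f"g{i}": (["bin"] if i < 10 else []) for i in range(40)})
            (res,) = wilcoxon_bin_enrichment(fc, amap, min_bin_size=3)
            rejections += res.p_raw <= 0.05
        assert rejections / n_perm <= 0.06

    def test_exact_close_to_normal_at_boundary(self, rng):
        """n1 = 8 boundary: exact and asymptotic p agree within 0.02."""
        for _ in range(20):
            mv = rng.normal(0.5, 1, 8)
            ov = rng.normal(0, 1, 30)
            p_exact = stats.mannwhitneyu(mv, ov, alternative="two-sided", method="exact").pvalue
            p_norm = stats.mannwhitneyu(mv, ov, alternative="two-sided", method="asymptotic",
                                        use_continuity=True).pvalue
            assert abs(p_exact - p_norm) <= 0.02

    def test_bin_containing_everything_rejected(self):
        fc = {"a": 1.0, "b": 2.0, "c": 3.0}
        amap = annotation_of({k: ["all"] for k in fc})
        with pytest.raises(ValueError, match="every"):
            wilcoxon_bin_enrichment(fc, amap, min_bin_size=3)


class TestCompareUpSets:
    def test_identical_tables(self):
        t = {"g1": 1.0, "g2": 0.5, "g3": 0.1}
        res = compare_up_sets({"papaya": t, "tomato": dict(t)}, 0.3)
        assert res.cells[("papaya", "tomato")] == 2
        assert res.exclusive("papaya") == 0 and res.exclusive("tomato") == 0

    def test_disjoint_namespaces_warn(self):
        with pytest.warns(UserWarning, match="shared"):
            res = compare_up_sets({"a": {"x": 1.0}, "b": {"y": 1.0}}, 0.3)
        assert res.cells[("a", "b")] == 0
        assert res.exclusive("a") == 1 and res.exclusive("b") == 1

    def test_constructed_three_way_venn(self):
        """10 genes shared by all three; known exclusive and pairwise cells."""
        shared = {f"s{i}": 1.0 for i in range(10)}
        pap = dict(shared, **{f"p{i}": 1.0 for i in range(4)}, **{"pt": 0.8})
        tom = dict(shared, **{f"t{i}": 1.0 for i in range(3)}, **{"pt": 0.9})
        gra = dict(shared, **{f"v{i}": 1.0 for i in range(5)}, low=0.1)
        res = compare_up_sets({"papaya": pap, "tomato": tom, "grape": gra}, 0.3)
        assert res.cells[("papaya", "tomato", "grape")] == 10
        assert res.cells[("papaya", "tomato")] == 1  # the "pt" gene
        assert res.exclusive("papaya") == 4
        assert res.exclusive("tomato") == 3
        assert res.exclusive("grape") == 5  # "low" is below threshold
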