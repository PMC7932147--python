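"""Hierarchical clustering and group-segregation scoring."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from posthypoxia.cluster import hier_cluster, segregation_score
from posthypoxia.preprocess import average_duplicates, chex_normalize
from posthypoxia.screen import run_screen
from posthypoxia.simulate import SimConfig, simulate_luminex_plate


def line_points(xs, labels):
    return pd.DataFrame({"x": xs}, index=labels)


class TestHierCluster:
    def test_identical_samples_merge_first_at_height_zero(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]],
            index=["a", "b", "c"], columns=["A", "B"],
        )
        res = hier_cluster(df, log_transform=False, zscore=False)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        first = {res.labels[int(res.linkage[0, 0])], res.labels[int(res.linkage[0, 1])]}
        assert first == {"a", "b"}

    @pytest.mark.parametrize(
        "method, heights",
        [
            ("single", [1.0, 2.0, 4.0]),
            ("average", [1.0, 2.0, 5.5]),
        ],
    )
    def test_hand_computed_line_dendrogram(self, method, heights):
        # points 0, 1, 5, 7 on a line: pairs merge at 1 and 2; the two
        # clusters then join at min distance 4 (single) or mean 5.5 (average)
        df = line_points([0.0, 1.0, 5.0, 7.0], ["p1", "p2", "p3", "p4"])
        res = hier_cluster(df, log_transform=False, zscore=False, method=method)
        assert np.allclose(sorted(res.linkage[:, 2]), heights)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.lognormal(size=(10, 6)),
                          index=[f"s{i}" for i in range(10)])
        perm = rng.permutation(10)
        a = hier_cluster(df)
        b = hier_cluster(df.iloc[perm])
        assert np.allclose(sorted(a.linkage[:, 2]), sorted(b.linkage[:, 2]))
        cut_a = a.cut(2)
        cut_b = b.cut(2)
        part_a = {frozenset(cut_a.index[cut_a == k]) for k in (1, 2)}
        part_b = {frozenset(cut_b.index[cut_b == k]) for k in (1, 2)}
        assert part_a == part_b

    def test_constant_analyte_dropped_with_warning(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [4.0, 4.0, 4.0]},
                          index=["a", "b", "c"])
        with pytest.warns(RuntimeWarning, match="constant"):
            res = hier_cluster(df, log_transform=False)
        assert res.descriptor["n_features"] == 1

    def test_affine_rescaling_invariance_after_zscore(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.lognormal(size=(8, 5)))
        scaled = df * [2.0, 0.5, 7.0, 1.0, 3.0]
        a = hier_cluster(df, log_transform=True, zscore=True)
        b = hier_cluster(scaled, log_transform=True, zscore=True)
        assert np.allclose(a.linkage[:, 2], b.linkage[:, 2])

    def test_newick_export_contains_all_leaves(self):
        df = line_points([0.0, 1.0, 5.0], ["x", "y", "z"])
        res = hier_cluster(df, log_transform=False, zscore=False)
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk


class TestSegregationScore:
    def test_perfect_separation_scores_one(self):
        cfg = SimConfig(noise_cv=0.0, well_scale_sd=0.0, duplicate_cv=0.0,
                        affected_analytes=tuple((j, "post1h", 4.0) for j in range(10)))
        m = chex_normalize(average_duplicates(simulate_luminex_plate(cfg)))
        res = hier_cluster(m, axis="samples")
        assert segregation_score(res, m.meta["group"], "post1h") == 1.0

    def test_single_group_scores_one_by_convention(self):
        df = line_points([0.0, 1.0, 5.0], ["a", "b", "c"])
        res = hier_cluster(df, log_transform=False, zscore=False)
        labels = {"a": "g", "b": "g", "c": "g"}
        assert segregation_score(res, labels, "g") == 1.0

    def test_missing_labels_rejected(self):
        df = line_points([0.0, 1.0], ["a", "b"])
        res = hier_cluster(df, log_transform=False, zscore=False)
        with pytest.raises(ValueError, match="labels missing"):
            segregation_score(res, {"a": "g"}, "g")

    def test_random_labels_match_enumerated_null_expectation(self):
        """With labels independent of the tree, the score's null law is the
        hypergeometric placement of targets across the 2-cluster cut."""

        def expected_score(n, t, a):
            total, acc = comb(n, t), 0.0
            for j in range(max(0, t - (n - a)), min(t, a) + 1):
                w = comb(a, j) * comb(n - a, t - j)
                s1 = (j + (n - a) - (t - j)) / n
                s2 = ((t - j) + a - j) / n
                if j > t - j:
                    s = s1
                elif t - j > j:
                    s = s2
                else:
                    s = max(s1, s2)
                acc += w * s
            return acc / total

        rng = np.random.default_rng(123)
        n, t = 15, 5
        observed, expected = [], []
        for _ in range(1000):
            df = pd.DataFrame(rng.lognormal(size=(n, 8)),
                              index=[f"s{i}" for i in range(n)])
            res = hier_cluster(df)
            targets = rng.choice(n, size=t, replace=False)
            labels = {f"s{i}": ("hit" if i in targets else "rest") for i in range(n)}
            observed.append(segregation_score(res, labels, "hit"))
            a = int((res.cut(2) == 1).sum())
            expected.append(expected_score(n, t, a))
        observed, expected = np.asarray(observed), np.asarray(expected)
        assert observed.mean() < 1.0
        se = observed.std(ddof=1) / np.sqrt(len(observed))
        assert abs(observed.mean() - expected.mean()) < 3 * se


def test_reference_plasma_one_hour_group_segregates(reference_matrices):
    """The 1h samples cluster away from controls on the stand-in plasma
    panel, as seen in the study's sample dendrograms."""
    m = reference_matrices["plasma"]
    res = hier_cluster(m, axis="samples")
    assert segregation_score(res, m.meta["group"], "post1h") == 1.0


def test_reference_retina_hits_segregate_one_hour_group(reference_matrices):
    """Clustering the retina samples on the significant analytes only (as
    the study does for its 4 retinal hits) separates the 1h group."""
    from dataclasses import replace

    m = reference_matrices["retina"]
    hits = sorted(run_screen(m, "post1h").primary_hits)
    sub = replace(m, values=m.values[hits])
    res = hier_cluster(sub, axis="samples")
    assert segregation_score(res, m.meta["group"], "post1h") == 1.0
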