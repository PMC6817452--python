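"""Normalization, differential expression, BH adjustment and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mircna.expression import (
    NormalizationError,
    bh_adjust,
    differential_expression,
    hierarchical_cluster,
    normalize,
)


def _raw_matrix(endo: dict[str, list[float]], n_pos=3, n_neg=3, n_hk=2,
                pos=None, neg=None, hk=None):
    """Assemble a raw count matrix with controls from per-sample endo counts."""
    samples = sorted({s for vals in endo.values() for s in range(len(vals))})
    n = len(next(iter(endo.values())))
    rows, classes, index = [], [], []
    for name, vals in endo.items():
        rows.append(vals)
        classes.append("endogenous")
        index.append(name)
    for i in range(n_hk):
        rows.append(hk[i] if hk else [1000.0] * n)
        classes.append("housekeeping")
        index.append(f"HK{i}")
    for i in range(n_pos):
        rows.append(pos[i] if pos else [float(2 ** (10 - i))] * n)
        classes.append("positive")
        index.append(f"POS{i}")
    for i in range(n_neg):
        rows.append(neg[i] if neg else [0.0] * n)
        classes.append("negative")
        index.append(f"NEG{i}")
    frame = pd.DataFrame(rows, index=index, columns=[f"s{j}" for j in range(n)])
    frame.insert(0, "probe_class", classes)
    return frame


class TestNormalize:
    def test_identical_samples_stay_identical(self):
        raw = _raw_matrix({"m1": [100, 100], "m2": [40, 40]})
        norm = normalize(raw)
        pd.testing.assert_series_equal(
            norm["s0"], norm["s1"], check_names=False
        )

    def test_doubled_sample_restored_by_positive_controls(self):
        base = _raw_matrix({"m1": [100, 200], "m2": [40, 80]},
                           pos=[[1024, 2048], [512, 1024], [256, 512]],
                           hk=[[1000, 2000], [500, 1000]])
        norm = normalize(base)
        np.testing.assert_allclose(norm["s0"], norm["s1"], rtol=1e-12)

    def test_zero_positive_control_names_sample(self):
        raw = _raw_matrix({"m1": [100, 100]}, pos=[[0, 1024], [512, 512], [256, 256]])
        with pytest.raises(NormalizationError, match="s0"):
            normalize(raw)

    def test_idempotent_when_controls_flat_and_negatives_zero(self):
        raw = _raw_matrix({"m1": [300, 90], "m2": [12, 700]})
        first = normalize(raw)
        # rebuild a raw matrix whose endogenous counts equal 2^first - 1
        again = _raw_matrix(
            {m: list(2.0 ** first.loc[m] - 1.0) for m in first.index}
        )
        second = normalize(again)
        np.testing.assert_allclose(second.to_numpy(), first.to_numpy(), atol=1e-9)

    def test_requires_all_control_classes(self):
        raw = _raw_matrix({"m1": [10, 10]}, n_hk=0)
        with pytest.raises(ValueError, match="housekeeping"):
            normalize(raw)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.07], [0.07]),
            # hand-applied step-up: q_(i) = min_{j>=i} p_(j) m / j
            ([0.005, 0.30, 0.05], [0.015, 0.30, 0.075]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_monotone_in_sorted_p_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDifferentialExpression:
    @staticmethod
    def _labels(n_a, n_b):
        labels = {f"a{i}": "TNBC" for i in range(n_a)}
        labels.update({f"b{i}": "non-TNBC" for i in range(n_b)})
        return labels

    def test_equal_means_not_significant(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(8, 1, size=6)
        norm = pd.DataFrame(
            [np.concatenate([shared, shared])],
            index=["m1"],
            columns=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
        )
        de = differential_expression(norm, self._labels(6, 6), "TNBC", "non-TNBC")
        assert de.loc[0, "log2fc"] == pytest.approx(0.0)
        assert not de.loc[0, "significant"]

    def test_zero_variance_equal_means_p_one(self):
        norm = pd.DataFrame(
            [[5.0] * 8], index=["m1"],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        de = differential_expression(norm, self._labels(4, 4), "TNBC", "non-TNBC")
        assert de.loc[0, "p"] == 1.0 and de.loc[0, "t"] == 0.0

    def test_log2fc_sign_convention(self):
        norm = pd.DataFrame(
            [[9.0] * 4 + [7.0] * 4, [6.0] * 4 + [8.0] * 4],
            index=["up_in_a", "down_in_a"],
            columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        de = differential_expression(norm, self._labels(4, 4), "TNBC", "non-TNBC")
        de = de.set_index("mirna")
        assert de.loc["up_in_a", "direction"] == "up"
        assert de.loc["down_in_a", "direction"] == "down"

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(2)
        cols = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        norm = pd.DataFrame(rng.normal(8, 1, (6, 10)),
                            index=[f"m{i}" for i in range(6)], columns=cols)
        de1 = differential_expression(norm, self._labels(5, 5), "TNBC", "non-TNBC")
        shuffled = norm.iloc[::-1, ::-1]
        de2 = differential_expression(shuffled, self._labels(5, 5), "TNBC", "non-TNBC")
        merged = de1.set_index("mirna").join(
            de2.set_index("mirna"), lsuffix="_1", rsuffix="_2"
        )
        np.testing.assert_allclose(merged["p_1"], merged["p_2"], rtol=1e-10)
        np.testing.assert_allclose(merged["log2fc_1"], merged["log2fc_2"], rtol=1e-10)

    def test_planted_effects_recovered_at_stated_thresholds(self):
        """Planted |log2FC| = 2 miRNAs are recovered and nulls controlled."""
        rng = np.random.default_rng(3)
        n_planted, n_null, n_per_group, n_sims = 20, 80, 20, 25
        recovered, false_pos = 0, 0
        for _ in range(n_sims):
            a = rng.normal(8, 0.5, (n_planted + n_null, n_per_group))
            b = rng.normal(8, 0.5, (n_planted + n_null, n_per_group))
            a[:n_planted] += 2.0
            cols = [f"a{i}" for i in range(n_per_group)] + [
                f"b{i}" for i in range(n_per_group)
            ]
            norm = pd.DataFrame(
                np.hstack([a, b]), columns=cols,
                index=[f"m{i}" for i in range(n_planted + n_null)],
            )
            de = differential_expression(
                norm, self._labels(n_per_group, n_per_group), "TNBC", "non-TNBC"
            )
            sig = de[de["significant"]]["mirna"]
            planted_names = {f"m{i}" for i in range(n_planted)}
            recovered += len(planted_names & set(sig))
            false_pos += len(set(sig) - planted_names)
        assert recovered / (n_sims * n_planted) >= 0.90
        # false discoveries among significances stay near the FDR bound
        total_sig = recovered + false_pos
        assert false_pos / max(total_sig, 1) <= 0.25 + 0.05


def brute_force_average_linkage(dist):
    """Oracle: greedy average-linkage agglomeration on a distance matrix."""
    clusters = {i: [i] for i in range(len(dist))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i][j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), d))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


class TestHierarchicalCluster:
    def test_duplicate_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 10)
        data = pd.DataFrame(
            {"x": base, "x_copy": base, "y": rng.normal(0, 1, 10),
             "z": rng.normal(0, 1, 10)}
        )
        result = hierarchical_cluster(data, axis="columns")
        first = result.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_distance_two(self):
        x = np.arange(10.0)
        data = pd.DataFrame({"x": x, "neg": -x})
        result = hierarchical_cluster(data, axis="columns")
        # the single x / -x merge happens at height 2 (1 - (-1))
        assert result.linkage_matrix[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_merge_heights_match_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame(rng.normal(0, 1, (12, 5)),
                            columns=list("abcde"))
        result = hierarchical_cluster(data, axis="columns")
        mat = data.to_numpy().T
        dist = 1 - np.corrcoef(mat)
        oracle = brute_force_average_linkage(dist)
        np.testing.assert_allclose(
            sorted(result.linkage_matrix[:, 2]),
            sorted(m[2] for m in oracle),
            atol=1e-10,
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(rng.normal(0, 1, (15, 4)), columns=list("wxyz"))
        r1 = hierarchical_cluster(data)
        r2 = hierarchical_cluster(data * 3.5 + 11.0)
        np.testing.assert_allclose(
            r1.linkage_matrix[:, 2], r2.linkage_matrix[:, 2], atol=1e-10
        )
        assert r1.leaf_order == r2.leaf_order

    def test_zero_variance_profile_named(self):
        data = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(data, axis="columns")

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(0, 1, (10, 4)), columns=list("pqrs"))
        newick = hierarchical_cluster(data).to_newick()
        assert newick.endswith(";")
        for leaf in "pqrs":
            assert leaf in newick
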