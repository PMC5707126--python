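import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from hervex.domain_discrimination import (DomainProfile, cluster_specimens,
                                          domain_hit_rates, log2_center,
                                          split_and_test, _pearson_distance)


class TestDomainHitRates:
    def test_binning_arithmetic(self):
        counts = {"s1": {"GAG_U1": 3, "GAG_U2": 7}}
        rates = domain_hit_rates(counts, {"GAG_U1": "GAG", "GAG_U2": "GAG"},
                                 {"s1": 10**6})
        assert rates.loc["GAG", "s1"] == pytest.approx(1e-5)

    def test_empty_domain_zero(self):
        rates = domain_hit_rates({"s1": {"GAG_U1": 3}},
                                 {"GAG_U1": "GAG", "ENV_U1": "ENV"},
                                 {"s1": 100})
        assert rates.loc["ENV", "s1"] == 0.0

    def test_conservation(self):
        counts = {"s1": {"GAG_U1": 3, "ENV_U1": 4, "ENV_U2": 5}}
        rates = domain_hit_rates(counts,
                                 {"GAG_U1": "GAG", "ENV_U1": "ENV",
                                  "ENV_U2": "ENV"}, {"s1": 1000})
        assert (rates["s1"] * 1000).sum() == pytest.approx(12)

    def test_unmapped_entry_is_error(self):
        with pytest.raises(KeyError):
            domain_hit_rates({"s1": {"X_U1": 1}}, {}, {"s1": 10})


class TestLog2Center:
    def test_constant_row_centers_to_zero(self):
        rates = pd.DataFrame([[2e-5, 2e-5, 2e-5]], index=["GAG"],
                             columns=["a", "b", "c"])
        prof = log2_center(rates, pseudocount=1e-12)
        assert prof.values == pytest.approx(np.zeros((1, 3)), abs=1e-9)

    def test_fourfold_row_gives_plus_minus_one(self):
        eps = 1e-12
        rates = pd.DataFrame([[4e-3, 1e-3]], index=["GAG"], columns=["a", "b"])
        prof = log2_center(rates, pseudocount=eps)
        assert prof.values[0] == pytest.approx([1.0, -1.0], abs=1e-6)

    def test_domain_scaling_invariance(self):
        rng = np.random.default_rng(30)
        base = rng.uniform(1e-6, 1e-4, size=(3, 6))
        r1 = pd.DataFrame(base, index=list("XYZ"), columns=list("abcdef"))
        r2 = r1.copy()
        r2.loc["Y"] *= 2.0  # scaling a whole domain row cancels in centering
        p1 = log2_center(r1, pseudocount=1e-15)
        p2 = log2_center(r2, pseudocount=1e-15)
        assert p2.values == pytest.approx(p1.values, abs=1e-9)

    def test_centering_idempotent(self):
        rng = np.random.default_rng(31)
        rates = pd.DataFrame(rng.uniform(1e-6, 1e-4, size=(4, 5)))
        prof = log2_center(rates, pseudocount=1e-9)
        # feed the centered matrix back through as if rates, pseudocount folded
        again = prof.values - prof.values.mean(axis=1, keepdims=True)
        assert again == pytest.approx(prof.values)

    def test_default_pseudocount_needs_hq(self):
        rates = pd.DataFrame([[1e-5]])
        with pytest.raises(ValueError):
            log2_center(rates)


def _profile(values, specimens=None):
    values = np.asarray(values, dtype=float)
    values = values - values.mean(axis=1, keepdims=True)
    specimens = specimens or [f"s{i}" for i in range(values.shape[1])]
    return DomainProfile(specimens, [f"d{i}" for i in range(values.shape[0])],
                         values)


class TestCluster:
    def test_identical_specimens_merge_first_at_zero(self):
        rng = np.random.default_rng(32)
        col = rng.normal(size=4)
        other = rng.normal(size=(4, 2))
        prof = _profile(np.column_stack([col, col, other[:, 0], other[:, 1]]))
        merges = cluster_specimens(prof)
        assert merges[0][:2] == (0, 1)
        assert merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        col = np.array([1.0, -1.0, 2.0, -2.0])
        prof = _profile(np.column_stack([col, -col]))
        dist = _pearson_distance(prof.values)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_zero_variance_column_warns(self):
        vals = np.column_stack([np.zeros(3), [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            _pearson_distance(vals - vals.mean(axis=1, keepdims=True) * 0)

    def test_matches_scipy_average_linkage_oracle(self):
        rng = np.random.default_rng(33)
        for trial in range(5):
            vals = rng.normal(size=(5, 6))
            prof = _profile(vals)
            merges = cluster_specimens(prof)
            ref = linkage(squareform(_pearson_distance(prof.values),
                                     checks=False), method="average")
            assert [m[2] for m in merges] == pytest.approx(
                ref[:, 2].tolist(), abs=1e-9)
            # cluster sizes along the agglomeration agree too
            sizes = []
            leaf_count = {i: 1 for i in range(6)}
            for i, (a, b, _) in enumerate(merges):
                leaf_count[6 + i] = leaf_count[a] + leaf_count[b]
                sizes.append(leaf_count[6 + i])
            assert sizes == ref[:, 3].astype(int).tolist()

    def test_too_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            cluster_specimens(_profile(np.zeros((1, 5))))
        with pytest.raises(ValueError):
            cluster_specimens(_profile(np.zeros((3, 1))))


class TestSplitAndTest:
    def _two_cluster_profile(self, n_left, n_right, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = -a
        cols, names = [], []
        for i in range(n_left):
            cols.append(a + rng.normal(scale=0.05, size=4))
            names.append(f"L{i}")
        for i in range(n_right):
            cols.append(b + rng.normal(scale=0.05, size=4))
            names.append(f"R{i}")
        return _profile(np.column_stack(cols), names)

    def test_reported_membership_table(self):
        # 9 of 10 case specimens in one node, 12 of 16 controls in the other
        prof = self._two_cluster_profile(13, 13)
        groups = {}
        left = [f"L{i}" for i in range(13)]
        right = [f"R{i}" for i in range(13)]
        for s in left[:9] + right[:1]:
            groups[s] = "demyelination"
        for s in left[9:] + right[1:]:
            groups[s] = "control"
        design = pd.DataFrame({"specimen_id": list(groups),
                               "group": list(groups.values())})
        merges = cluster_specimens(prof)
        split = split_and_test(merges, prof.specimens, design)
        assert sorted(split.left_members) == sorted(left)
        assert split.contingency == [[9, 1], [4, 12]]
        assert split.fisher.p_value == pytest.approx(0.0036, abs=2e-4)
        assert round(split.fisher.p_value, 3) == 0.004

    def test_balanced_split_p_one(self):
        prof = self._two_cluster_profile(10, 10, seed=1)
        groups = {}
        for i in range(10):
            groups[f"L{i}"] = "demyelination" if i < 5 else "control"
            groups[f"R{i}"] = "demyelination" if i < 5 else "control"
        design = pd.DataFrame({"specimen_id": list(groups),
                               "group": list(groups.values())})
        split = split_and_test(cluster_specimens(prof), prof.specimens, design)
        assert split.contingency in ([[5, 5], [5, 5]],)
        assert split.fisher.p_value == pytest.approx(1.0)

    def test_perfect_split_minimal_p(self):
        prof = self._two_cluster_profile(10, 16, seed=2)
        groups = {f"L{i}": "demyelination" for i in range(10)}
        groups |= {f"R{i}": "control" for i in range(16)}
        design = pd.DataFrame({"specimen_id": list(groups),
                               "group": list(groups.values())})
        split = split_and_test(cluster_specimens(prof), prof.specimens, design)
        assert split.contingency == [[10, 0], [0, 16]]
        # hypergeometric tail: minimal achievable p for these margins
        from scipy.stats import hypergeom
        p_min = hypergeom.pmf(10, 26, 10, 10) * 2
        assert split.fisher.p_value <= p_min + 1e-12

    def test_absent_group_is_error(self):
        prof = self._two_cluster_profile(3, 3, seed=3)
        design = pd.DataFrame({"specimen_id": prof.specimens,
                               "group": ["control"] * 6})
        with pytest.raises(ValueError, match="absent"):
            split_and_test(cluster_specimens(prof), prof.specimens, design)

    def test_excluded_group_ignored(self):
        prof = self._two_cluster_profile(4, 4, seed=4)
        groups = {f"L{i}": "demyelination" for i in range(4)}
        groups |= {f"R{i}": "control" for i in range(3)} | {"R3": "OND"}
        design = pd.DataFrame({"specimen_id": list(groups),
                               "group": list(groups.values())})
        split = split_and_test(cluster_specimens(prof), prof.specimens, design)
        assert sum(split.contingency[0]) + sum(split.contingency[1]) == 7
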