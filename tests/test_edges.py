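import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import richclubnet as r


def _toy_atlas(flags):
    n = len(flags)
    hemis = ["left", "right"] * (n // 2) + ["left"] * (n % 2)
    return r.make_atlas(
        [f"n{i}" for i in range(n)], [f"r{i}" for i in range(n)],
        hemis, flags,
    )


def _graph(edges, n):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return r.make_connectome(w)


class TestClassify:
    def test_definition(self):
        # rich set {A,B}; A-B rich, A-C feeder, C-D local
        atlas = _toy_atlas([1, 1, 0, 0])
        c = _graph([(0, 1, 3), (0, 2, 2), (2, 3, 1)], 4)
        cls = r.classify_edges(c, atlas)
        got = {
            (int(i), int(j)): lab
            for i, j, lab in zip(cls.edge_i, cls.edge_j, cls.labels)
        }
        assert got == {(0, 1): "rich", (0, 2): "feeder", (2, 3): "local"}

    def test_all_flagged_every_edge_rich(self):
        atlas = _toy_atlas([1, 1, 1, 1])
        c = _graph([(0, 1, 1), (1, 2, 1), (2, 3, 1)], 4)
        cls = r.classify_edges(c, atlas)
        assert (cls.labels == "rich").all()

    def test_partition_on_random_graph(self):
        rng = np.random.default_rng(0)
        n = 20
        a = np.triu(rng.random((n, n)) < 0.3, 1)
        w = np.where(a, rng.uniform(0.1, 2, (n, n)), 0.0)
        c = r.make_connectome(w + w.T)
        atlas = _toy_atlas(list(rng.integers(0, 2, n)))
        cls = r.classify_edges(c, atlas)
        assert sum(cls.counts().values()) == c.n_edges

    def test_node_count_mismatch(self):
        atlas = _toy_atlas([1, 0])
        with pytest.raises(ValueError, match="nodes"):
            r.classify_edges(_graph([(0, 1, 1)], 3), atlas)

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(1)
        n = 10
        a = np.triu(rng.random((n, n)) < 0.4, 1)
        w = np.where(a, rng.uniform(0.1, 2, (n, n)), 0.0)
        w = w + w.T
        flags = list(rng.integers(0, 2, n))
        perm = rng.permutation(n)
        counts = r.classify_edges(
            r.make_connectome(w), _toy_atlas(flags)).counts()
        counts_p = r.classify_edges(
            r.make_connectome(w[np.ix_(perm, perm)]),
            _toy_atlas([flags[i] for i in perm])).counts()
        assert counts == counts_p


class TestClassStrengths:
    def test_hand_sums(self):
        atlas = _toy_atlas([1, 1, 0, 0])
        c = _graph([(0, 1, 3), (0, 2, 2), (2, 3, 1)], 4)
        s = r.class_strengths(c, r.classify_edges(c, atlas))
        assert s.as_dict() == {"rich": 3.0, "feeder": 2.0, "local": 1.0}

    def test_empty_class_is_zero(self):
        atlas = _toy_atlas([1, 1, 0, 0])
        c = _graph([(0, 1, 3)], 4)
        s = r.class_strengths(c, r.classify_edges(c, atlas))
        assert s.feeder_strength == 0.0 and s.local_strength == 0.0

    def test_linearity_and_conservation(self):
        rng = np.random.default_rng(2)
        n = 16
        a = np.triu(rng.random((n, n)) < 0.4, 1)
        w = np.where(a, rng.uniform(0.1, 2, (n, n)), 0.0)
        c = r.make_connectome(w + w.T)
        atlas = _toy_atlas([1] * 4 + [0] * 12)
        s = r.class_strengths(c, r.classify_edges(c, atlas))
        total = s.rich_strength + s.feeder_strength + s.local_strength
        assert total == pytest.approx(c.total_weight(), rel=1e-9)
        c2 = r.make_connectome(2 * c.weights)
        s2 = r.class_strengths(c2, r.classify_edges(c2, atlas))
        for lab in ("rich", "feeder", "local"):
            assert s2.as_dict()[lab] == pytest.approx(2 * s.as_dict()[lab])


class TestRegionStrength:
    @pytest.fixture
    def bilateral(self):
        # regions a,b rich; c not; nodes [a_L, a_R, b_L, b_R, c_L, c_R]
        atlas = r.make_atlas(
            ["a_L", "a_R", "b_L", "b_R", "c_L", "c_R"],
            ["a", "a", "b", "b", "c", "c"],
            ["left", "right"] * 3,
            [1, 1, 1, 1, 0, 0],
        )
        c = _graph(
            [(0, 2, 2),   # a_L-b_L rich
             (0, 1, 4),   # a_L-a_R rich (homotopic)
             (1, 4, 1),   # a_R-c_L feeder
             (2, 5, 3),   # b_L-c_R feeder
             (4, 5, 5)],  # c_L-c_R local
            6,
        )
        return c, atlas

    def test_rich_counts_both_endpoints(self, bilateral):
        c, atlas = bilateral
        # a_L rich edges: b_L(2) + a_R(4) = 6; a_R: a_L(4) = 4 -> mean 5
        assert r.region_class_strength(c, atlas, "a", "rich") == 5.0
        # shared a_L-b_L edge also contributes to region b: (2 + 0)/2
        assert r.region_class_strength(c, atlas, "b", "rich") == 1.0

    def test_feeder_hemisphere_average(self, bilateral):
        c, atlas = bilateral
        assert r.region_class_strength(c, atlas, "a", "feeder") == 0.5
        assert r.region_class_strength(c, atlas, "b", "feeder") == 1.5

    def test_symmetric_hemispheres(self):
        atlas = r.make_atlas(
            ["t_L", "t_R", "x_L", "x_R"], ["t", "t", "x", "x"],
            ["left", "right"] * 2, [1, 1, 0, 0],
        )
        c = _graph([(0, 2, 4), (1, 3, 4)], 4)  # L and R feeder weight 4
        assert r.region_class_strength(c, atlas, "t", "feeder") == 4.0

    def test_unbalanced_hemispheres_average(self):
        atlas = r.make_atlas(
            ["t_L", "t_R", "x_L", "x_R"], ["t", "t", "x", "x"],
            ["left", "right"] * 2, [1, 1, 0, 0],
        )
        c = _graph([(0, 2, 2), (1, 3, 6)], 4)
        assert r.region_class_strength(c, atlas, "t", "feeder") == 4.0

    def test_non_rich_region_rejected(self, bilateral):
        c, atlas = bilateral
        with pytest.raises(ValueError, match="not a rich-club region"):
            r.region_class_strength(c, atlas, "c", "feeder")


class TestZScore:
    def _cohort(self, groups):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(groups))],
            "group": groups,
        })

    def test_hand_values(self):
        table = self._cohort(["CU", "CU", "CU", "ADdementia"])
        vals = pd.Series([1, 2, 3, 3.0], index=table.subject_id)
        z = r.zscore_vs_reference(vals, table, "CU")
        assert z.z["s3"] == pytest.approx(1.0)
        assert z.reference_mean == 2.0 and z.reference_sd == 1.0

    def test_target_at_reference_mean_is_zero(self):
        table = self._cohort(["CU", "CU", "ADdementia"])
        vals = pd.Series([0, 10, 5.0], index=table.subject_id)
        z = r.zscore_vs_reference(vals, table, "CU")
        assert z.z["s2"] == pytest.approx(0.0)
        # n-1 denominator: sd({0,10}) = 7.0711
        assert z.reference_sd == pytest.approx(7.0710678, rel=1e-6)
        assert (10 - z.reference_mean) / z.reference_sd == pytest.approx(
            0.70710678, rel=1e-6)

    def test_reference_members_standardized(self):
        rng = np.random.default_rng(0)
        table = self._cohort(["CU"] * 20 + ["ADdementia"] * 10)
        vals = pd.Series(rng.normal(5, 2, 30), index=table.subject_id)
        z = r.zscore_vs_reference(vals, table, "CU")
        ref = z.z[table.subject_id[:20]]
        assert abs(ref.mean()) < 1e-9
        assert abs(ref.std(ddof=1) - 1) < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        shift=hst.floats(-100, 100, allow_nan=False),
        scale=hst.floats(0.01, 50, allow_nan=False),
    )
    def test_affine_invariance(self, shift, scale):
        table = self._cohort(["CU"] * 5 + ["prodromalAD"] * 3)
        vals = pd.Series(
            [1.0, 2, 4, 8, 16, 3, 5, 7], index=table.subject_id)
        z1 = r.zscore_vs_reference(vals, table, "CU").z
        z2 = r.zscore_vs_reference(scale * vals + shift, table, "CU").z
        np.testing.assert_allclose(z1, z2, atol=1e-7)

    def test_zero_sd_rejected(self):
        table = self._cohort(["CU", "CU", "ADdementia"])
        vals = pd.Series([3, 3, 5.0], index=table.subject_id)
        with pytest.raises(ValueError, match="zero SD"):
            r.zscore_vs_reference(vals, table, "CU")
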