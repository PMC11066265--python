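import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import estasm
from estasm import CountTable, NullConfig, ValidationError
from oracles import brute_beta_mntd, classify_oracle


class TestBetaMntd:
    def test_identical_communities_zero(self, toy_tree):
        x = [3, 1, 2, 5]
        assert estasm.beta_mntd(x, x, toy_tree,
                                taxon_ids=list("ABCD")) == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self, toy_tree):
        # {A} vs {B}: nearest-taxon distance is d(A,B) = 1 + 1 = 2
        got = estasm.beta_mntd([5, 0, 0, 0], [0, 3, 0, 0], toy_tree,
                               taxon_ids=list("ABCD"))
        assert got == pytest.approx(2.0)

    def test_symmetry_and_nonnegativity(self, toy_tree):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 6, size=4)
            y = rng.integers(0, 6, size=4)
            if x.sum() == 0 or y.sum() == 0:
                continue
            a = estasm.beta_mntd(x, y, toy_tree, taxon_ids=list("ABCD"))
            b = estasm.beta_mntd(y, x, toy_tree, taxon_ids=list("ABCD"))
            assert a == b >= 0

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_bruteforce_on_random_trees(self, weighted):
        rng = np.random.default_rng(42)
        for seed in range(5):
            tree = estasm.simulate_tree(20, seed=seed)
            ids = [t.name for t in tree.tips()]
            dist = tree.tip_tip_distances().filter(ids).data
            x = rng.integers(0, 5, size=20)
            y = rng.integers(0, 5, size=20)
            x[rng.integers(0, 20)] += 1  # never empty
            y[rng.integers(0, 20)] += 1
            got = estasm.beta_mntd(x, y, tree, taxon_ids=ids,
                                   weighted=weighted)
            want = brute_beta_mntd(x, y, dist, weighted=weighted)
            assert got == pytest.approx(want, abs=1e-12)

    def test_taxon_missing_from_tree(self, toy_tree):
        with pytest.raises(ValidationError, match="absent"):
            estasm.beta_mntd([1, 1], [1, 1], toy_tree, taxon_ids=["A", "Z"])


class TestBntiMatrix:
    def test_star_tree_null_is_degenerate(self):
        # equal pairwise distances: every shuffle gives the same betaMNTD
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        t = CountTable(["S1", "S2"], list("ABCD"),
                       np.array([[4, 4, 0, 0], [0, 0, 4, 4]]))
        with pytest.warns(UserWarning, match="degenerate"):
            res = estasm.bnti_matrix(t, star, NullConfig(n_null=99, seed=0))
        assert np.isnan(res.bnti.iloc[0, 1])

    def test_identical_support_pair_is_degenerate(self):
        """Shared-support pairs have betaMNTD 0 under every relabeling, so
        the null collapses and betaNTI is flagged missing."""
        tree = estasm.simulate_tree(8, seed=1)
        ids = [t.name for t in tree.tips()]
        row = np.array([3, 1, 4, 1, 5, 9, 2, 6])
        t = CountTable(["S1", "S2"], ids, np.vstack([row, row * 2]))
        with pytest.warns(UserWarning, match="degenerate"):
            res = estasm.bnti_matrix(t, tree, NullConfig(n_null=99, seed=0))
        assert np.isnan(res.bnti.iloc[0, 1])

    def test_n_null_floor(self, bundle):
        with pytest.raises(ValidationError, match="99"):
            NullConfig(n_null=50)

    def test_reproducible_under_seed(self):
        cfg = estasm.SimConfig(n_taxa=30, n_samples=6, depth=300, seed=3)
        b = estasm.simulate_dataset(cfg)
        r1 = estasm.bnti_matrix(b.table, b.tree, NullConfig(n_null=99, seed=5))
        r2 = estasm.bnti_matrix(b.table, b.tree, NullConfig(n_null=99, seed=5))
        pd.testing.assert_frame_equal(r1.bnti, r2.bnti)


class TestRcBray:
    @staticmethod
    def _pool_table(counts):
        return CountTable([f"S{i}" for i in range(len(counts))],
                          [f"T{j}" for j in range(counts.shape[1])], counts)

    def test_bounds(self):
        cfg = estasm.SimConfig(n_taxa=40, n_samples=8, depth=400, seed=9)
        b = estasm.simulate_dataset(cfg)
        rc = estasm.rc_bray_matrix(b.table, NullConfig(n_null=99, seed=0))
        off = rc.to_numpy()[~np.eye(8, dtype=bool)]
        assert (off >= -1).all() and (off <= 1).all()

    def test_identical_samples_push_rc_to_minus_one(self):
        # obs BC = 0 while null pairs are almost surely dissimilar
        rng = np.random.default_rng(1)
        row = rng.integers(1, 10, size=12)
        counts = np.vstack([row, row, rng.integers(0, 10, size=12)])
        rc = estasm.rc_bray_matrix(self._pool_table(counts),
                                   NullConfig(n_null=199, seed=2))
        assert rc.iloc[0, 1] < -0.95

    def test_maximally_dissimilar_pair_pushes_rc_up(self):
        # disjoint supports (obs BC = 1) against a well-mixed null
        counts = np.array([
            [5, 5, 5, 0, 0, 0],
            [0, 0, 0, 5, 5, 5],
            [2, 2, 2, 2, 2, 2],
            [3, 1, 2, 3, 1, 2],
        ])
        rc = estasm.rc_bray_matrix(self._pool_table(counts),
                                   NullConfig(n_null=199, seed=3))
        assert rc.iloc[0, 1] > 0.9

    def test_null_preserves_richness_and_depth(self):
        """Null communities keep each sample's observed richness and reads."""
        rng = np.random.default_rng(0)
        from estasm.assembly import _null_community

        occ = np.array([3.0, 2.0, 1.0, 4.0, 1.0])
        ab = np.array([0.5, 0.2, 0.1, 0.15, 0.05])
        for _ in range(50):
            c = _null_community(rng, occ, ab, richness=3, depth=40)
            assert (c > 0).sum() == 3
            assert c.sum() == 40

    def test_reproducible(self):
        cfg = estasm.SimConfig(n_taxa=25, n_samples=5, depth=200, seed=4)
        b = estasm.simulate_dataset(cfg)
        r1 = estasm.rc_bray_matrix(b.table, NullConfig(n_null=99, seed=7))
        r2 = estasm.rc_bray_matrix(b.table, NullConfig(n_null=99, seed=7))
        pd.testing.assert_frame_equal(r1, r2)


class TestClassify:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, 0.0, "heterogeneous_selection"),
        (-2.5, 0.99, "homogeneous_selection"),
        (1.0, 0.99, "dispersal_limitation"),
        (1.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.0, "drift"),
        (2.0, 0.99, "dispersal_limitation"),   # ties fall through
        (-2.0, -0.99, "homogenizing_dispersal"),
        (1.0, 0.95, "drift"),
        (1.0, -0.95, "drift"),
        (np.nan, 0.0, "undetermined"),
        (1.0, np.nan, "undetermined"),
    ])
    def test_rules(self, bnti, rc, expected):
        assert estasm.classify_pair(bnti, rc) == expected

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(6)
        n = 6
        b = rng.normal(0, 3, size=(n, n))
        r = rng.uniform(-1, 1, size=(n, n))
        b = (b + b.T) / 2
        r = (r + r.T) / 2
        ids = [f"s{i}" for i in range(n)]
        calls = estasm.classify_processes(pd.DataFrame(b, index=ids, columns=ids),
                                          pd.DataFrame(r, index=ids, columns=ids))
        for i in range(n):
            for j in range(i + 1, n):
                assert calls.iloc[i, j] == classify_oracle(b[i, j], r[i, j])

    def test_shape_mismatch(self):
        b = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        r = pd.DataFrame(np.zeros((4, 4)), index=list("wxyz"), columns=list("wxyz"))
        with pytest.raises(ValidationError):
            estasm.classify_processes(b, r)


class TestProcessFractions:
    @staticmethod
    def _calls_from_pairs(labels):
        """Symmetric call matrix whose upper triangle is ``labels``."""
        n_pairs = len(labels)
        n = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
        m = np.full((n, n), "", dtype=object)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = labels[k]
                k += 1
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(m, index=ids, columns=ids)

    def test_all_drift(self):
        calls = self._calls_from_pairs(["drift"] * 6)
        fr = estasm.process_fractions(calls)
        assert fr.loc["overall", "drift"] == pytest.approx(100.0)

    def test_counting_example(self):
        labels = (["heterogeneous_selection"] * 4
                  + ["homogeneous_selection"] * 2
                  + ["dispersal_limitation"] * 2 + ["drift"] * 2)
        fr = estasm.process_fractions(self._calls_from_pairs(labels))
        row = fr.loc["overall"]
        assert row["heterogeneous_selection"] == pytest.approx(40.0)
        assert row["homogeneous_selection"] == pytest.approx(20.0)
        assert row["dispersal_limitation"] == pytest.approx(20.0)
        assert row["drift"] == pytest.approx(20.0)
        assert row["homogenizing_dispersal"] == pytest.approx(0.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        labels = list(rng.choice(estasm.assembly.PROCESSES[:-1], size=45))
        fr = estasm.process_fractions(self._calls_from_pairs(labels))
        procs = list(estasm.assembly.PROCESSES[:-1])
        assert fr.loc["overall", procs].sum() == pytest.approx(100.0, abs=0.01)

    def test_group_pairs_and_skip_warning(self):
        labels = ["drift"] * 6
        calls = self._calls_from_pairs(labels)
        groups = ["g1", "g1", "g2", "g2"]
        fr = estasm.process_fractions(calls, groups=groups)
        assert fr.loc["g1", "n_pairs"] == 1
        with pytest.warns(UserWarning, match="skipped"):
            estasm.process_fractions(calls, groups=["g1", "g1", "g1", "solo"])
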