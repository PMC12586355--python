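import numpy as np
import pandas as pd
import pytest
import scipy.stats
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim, mantel as skbio_mantel

from mycolink.community import (
    anosim,
    bray_curtis,
    euclidean_1d,
    mantel,
    mantel_many,
    one_way_anova,
    prevalence_filter,
    rarefy,
    relative_abundance,
    response_ratio,
    tukey_hsd,
    venn_partition,
)


class TestRarefy:
    def test_full_sample_returned_unchanged(self):
        t = pd.DataFrame({"a": [3, 2, 5]}, index=["x", "y", "z"])
        out = rarefy(t, depth=10, seed=0)
        assert (out["a"] == t["a"]).all()

    def test_column_sums_equal_depth(self, toy_counts):
        out = rarefy(toy_counts, depth=30, seed=1)
        assert (out.sum(axis=0) == 30).all()

    def test_shallow_samples_dropped_with_warning(self, caplog):
        t = pd.DataFrame({"deep": [50, 50], "shallow": [1, 1]}, index=["x", "y"])
        with caplog.at_level("WARNING"):
            out = rarefy(t, depth=60, seed=0)
        assert list(out.columns) == ["deep"]
        assert "shallow" in caplog.text

    def test_depth_unreachable_raises(self, toy_counts):
        with pytest.raises(ValueError, match="depth"):
            rarefy(toy_counts, depth=10 ** 9)

    def test_hypergeometric_expectation(self):
        # per-ASV expected retained count = depth * count/total
        col = np.array([40, 25, 20, 10, 5])
        t = pd.DataFrame({"s": col}, index=list("abcde"))
        depth = 50
        draws = np.stack([
            rarefy(t, depth=depth, seed=s)["s"].to_numpy() for s in range(1000)
        ])
        expected = depth * col / col.sum()
        # multivariate hypergeometric variance per component
        n_tot = col.sum()
        var = depth * (col / n_tot) * (1 - col / n_tot) * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / 1000)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9).all()


class TestPrevalenceFilter:
    def make(self, n_present, n_samples=33):
        row = [1] * n_present + [0] * (n_samples - n_present)
        return pd.DataFrame([row], index=["asv"],
                            columns=[f"s{i}" for i in range(n_samples)])

    def test_strict_boundary(self):
        assert len(prevalence_filter(self.make(7))) == 1   # 21.2% > 20%
        assert len(prevalence_filter(self.make(6))) == 0   # 18.2%
        assert len(prevalence_filter(self.make(0))) == 0

    def test_idempotent(self, toy_counts):
        once = prevalence_filter(toy_counts)
        assert prevalence_filter(once).equals(once)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = pd.DataFrame({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0], "c": [0, 0, 3, 1]},
                         index=list("wxyz"))
        d = bray_curtis(relative_abundance(t))
        assert d["a", "b"] == pytest.approx(0.0)
        assert d["a", "c"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = pd.DataFrame({"x": [0.5, 0.5, 0.0], "y": [0.25, 0.25, 0.5]})
        d = bray_curtis(t)
        assert d["x", "y"] == pytest.approx(0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.uniform(0, 1, size=(12, 8)),
                         columns=[f"s{i}" for i in range(8)])
        d = bray_curtis(t)
        for i in range(8):
            for j in range(8):
                a, b = t.iloc[:, i], t.iloc[:, j]
                ref = np.abs(a - b).sum() / (a + b).sum()
                assert d[f"s{i}", f"s{j}"] == pytest.approx(ref, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        t = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(t)


def _random_dm(rng, n, ids=None):
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _random_dm(np.random.default_rng(0), 12)
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        d = _random_dm(np.random.default_rng(1), 10)
        d2 = DistanceMatrix(2.5 * np.asarray(d.data) + (1 - np.eye(10)), ids=d.ids)
        r, _ = mantel(d, d2, n_perm=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(2)
        d1, d2 = _random_dm(rng, 15), _random_dm(rng, 15)
        r_ours, p_ours = mantel(d1, d2, n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio_mantel(d1, d2, permutations=999,
                                       alternative="greater", seed=0)
        assert r_ours == pytest.approx(float(r_ref), abs=1e-12)
        assert p_ours == pytest.approx(float(p_ref), abs=0.05)

    def test_mismatched_ids_error(self):
        d1 = _random_dm(np.random.default_rng(0), 5)
        d2 = _random_dm(np.random.default_rng(0), 5, ids=list("abcde"))
        with pytest.raises(ValueError, match="different sample"):
            mantel(d1, d2)

    def test_shared_permutations_reproducible(self):
        rng = np.random.default_rng(3)
        d1 = _random_dm(rng, 12)
        others = [_random_dm(rng, 12) for _ in range(3)]
        r1, p1 = mantel_many(d1, others, n_perm=199, seed=5)
        r2, p2 = mantel_many(d1, others, n_perm=199, seed=5)
        assert (r1 == r2).all() and (p1 == p2).all()
        assert ((p1 > 0) & (p1 <= 1)).all()


class TestAnosim:
    def test_perfect_separation_gives_R_one(self):
        # two tight clusters far apart: all between > all within
        pts = np.vstack([np.random.default_rng(0).normal(0, 0.1, (4, 2)),
                         np.random.default_rng(1).normal(100, 0.1, (4, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(8)]
        labels = pd.Series(["g1"] * 4 + ["g2"] * 4, index=ids)
        r, p = anosim(DistanceMatrix(d, ids=ids), labels, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_exchangeable_groups_give_R_near_zero(self):
        rng = np.random.default_rng(4)
        d = _random_dm(rng, 16)
        labels = pd.Series(["a", "b"] * 8, index=d.ids)
        r, _ = anosim(d, labels, n_perm=99, seed=0)
        assert abs(r) < 0.3

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        d = _random_dm(rng, 18)
        labels = pd.Series(rng.choice(["a", "b", "c"], size=18), index=d.ids)
        r_ours, _ = anosim(d, labels, n_perm=99, seed=0)
        ref = skbio_anosim(d, labels.to_numpy(), permutations=99, seed=0)
        assert r_ours == pytest.approx(float(ref["test statistic"]), abs=1e-12)

    def test_single_group_error(self):
        d = _random_dm(np.random.default_rng(0), 6)
        with pytest.raises(ValueError, match="2 groups"):
            anosim(d, pd.Series(["g"] * 6, index=d.ids))


class TestVenn:
    def test_identical_groups(self):
        t = pd.DataFrame({"s1": [1, 1, 0], "s2": [2, 1, 0]}, index=list("abc"))
        out = venn_partition({"g1": t, "g2": t.copy()})
        assert out["shared"] == 2
        assert all(v == 0 for v in out["unique"].values())

    def test_disjoint_groups(self):
        t1 = pd.DataFrame({"s1": [1, 0]}, index=list("ab"))
        t2 = pd.DataFrame({"s2": [0, 5]}, index=list("ab"))
        out = venn_partition({"g1": t1, "g2": t2})
        assert out["shared"] == 0
        assert out["unique"] == {"g1": 1, "g2": 1}

    def test_three_groups_match_set_algebra(self):
        rng = np.random.default_rng(6)
        asvs = [f"a{i}" for i in range(40)]
        tables, present = {}, {}
        for g in ("g1", "g2", "g3"):
            mask = rng.random(40) < 0.5
            tables[g] = pd.DataFrame({"s": mask.astype(int)}, index=asvs)
            present[g] = {a for a, m in zip(asvs, mask) if m}
        out = venn_partition(tables)
        assert out["shared"] == len(present["g1"] & present["g2"] & present["g3"])
        for g in present:
            others = set().union(*(present[h] for h in present if h != g))
            assert out["unique"][g] == len(present[g] - others)


class TestResponseRatio:
    def test_equal_means_zero(self):
        rr, _ = response_ratio([2, 2, 2], [2, 2, 2])
        assert rr == 0.0

    def test_e_fold_change_is_one(self):
        rr, _ = response_ratio([np.e * 3.0] * 3, [3.0] * 3)
        assert rr == pytest.approx(1.0)

    def test_se_close_to_bootstrap(self):
        rng = np.random.default_rng(7)
        t = rng.normal(10, 2, size=3)
        c = rng.normal(8, 2, size=3)
        _, se = response_ratio(t, c)
        boots = []
        for _ in range(10_000):
            bt = rng.choice(t, size=3, replace=True)
            bc = rng.choice(c, size=3, replace=True)
            if bt.mean() > 0 and bc.mean() > 0:
                boots.append(np.log(bt.mean() / bc.mean()))
        assert se == pytest.approx(np.std(boots), rel=0.35)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            response_ratio([1.0, -3.0], [1.0, 1.0])


class TestAnovaTukey:
    def test_two_groups_match_pooled_t_test(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.2, 1, 8)])
        labs = ["a"] * 8 + ["b"] * 8
        _, p_anova = one_way_anova(vals, labs)
        t_p = scipy.stats.ttest_ind(vals[:8], vals[8:]).pvalue
        assert p_anova == pytest.approx(t_p, rel=1e-9)
        tk = tukey_hsd(vals, labs, alpha=0.05)
        assert bool(tk.pairwise["reject"].iloc[0]) == (t_p < 0.05)

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(0.2, 1, 6),
                               rng.normal(30, 1, 6)])
        labs = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        tk = tukey_hsd(vals, labs)
        assert tk.letters["c"] not in (tk.letters["a"], tk.letters["b"])
        assert set(tk.letters["a"]) & set(tk.letters["b"])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])

    def test_letters_cover_every_group(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 1, 20)
        labs = list("abcd") * 5
        tk = tukey_hsd(vals, labs)
        assert set(tk.letters) == set("abcd")
        assert all(tk.letters.values())


def test_relative_abundance_columns_sum_to_one(toy_counts):
    rel = relative_abundance(rarefy(toy_counts, depth=30, seed=0))
    assert np.allclose(rel.sum(axis=0), 1.0)


def test_euclidean_1d_matches_abs_difference():
    s = pd.Series([1.0, 4.0, 6.0], index=["a", "b", "c"])
    d = euclidean_1d(s)
    assert d["a", "b"] == pytest.approx(3.0)
    assert d["a", "c"] == pytest.approx(5.0)
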