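"""Gene Set Z-score: running moments, scoring, permutation and EVD p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylgsz.dataset import DataError
from methylgsz.genesets import GeneSetCollection
from methylgsz.gsz import (GeneSetZTest, GszParams, empirical_pvalue,
                           evd_pvalue, gsz_score, intersect_universe,
                           permutation_null, running_moments)


def moments_by_enumeration(scores, m):
    """Oracle: exact running mean/variance over all C(N,m) memberships."""
    N = len(scores)
    sums = []
    for member in itertools.combinations(range(N), m):
        x = np.zeros(N)
        x[list(member)] = np.asarray(scores, float)[list(member)]
        sums.append(np.cumsum(x))
    sums = np.array(sums)
    return sums.mean(axis=0), sums.var(axis=0)


class TestRunningMoments:
    def test_small_worked_example(self):
        E, V = running_moments([3, 2, 1, 0], 2)
        assert E[1] == pytest.approx(2.5)   # k=2
        assert V[1] == pytest.approx(2.25)

    def test_constant_scores_have_deterministic_total(self):
        E, V = running_moments([2.0] * 6, 3)
        assert E[-1] == pytest.approx(6.0)  # X_N = m*c always
        assert V[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("N", range(3, 9))
    def test_matches_enumeration_for_all_small_sizes(self, N):
        rng = np.random.default_rng(N)
        scores = rng.normal(size=N)
        for m in range(2, N):
            E, V = running_moments(scores, m)
            E0, V0 = moments_by_enumeration(scores, m)
            assert np.allclose(E, E0, atol=1e-10)
            assert np.allclose(V, V0, atol=1e-10)

    def test_complement_size_matches_enumeration(self):
        rng = np.random.default_rng(77)
        scores = rng.normal(size=7)
        E, V = running_moments(scores, 6)  # m = N-1
        E0, V0 = moments_by_enumeration(scores, 6)
        assert np.allclose(E, E0) and np.allclose(V, V0)

    def test_rejects_degenerate_sizes(self):
        for m in (0, 1, 4, 9):
            with pytest.raises(DataError):
                running_moments([1.0, 2.0, 3.0, 4.0], m)


def gsz_reference(scores: pd.Series, members, params: GszParams) -> float:
    """Independent O(N^2)-ish reference: enumeration moments + same
    smoothing/floor, max over both ranking directions, floored at 0."""
    vals = scores.to_numpy(float)
    genes = scores.index.to_numpy()
    pooled = np.var(vals)
    floor = params.var_floor_frac * pooled
    best = -np.inf
    for direction in ("desc", "asc"):
        order = np.lexsort((genes, -vals)) if direction == "desc" else \
            np.lexsort((genes, -vals))[::-1]
        s = vals[order]
        member_mask = np.isin(genes[order], list(members))
        E, V = moments_by_enumeration(s, int(member_mask.sum()))
        Vs = [V[0]]
        for k in range(1, len(s)):
            Vs.append(params.var_smooth * V[k] + (1 - params.var_smooth) * Vs[-1])
        X = np.cumsum(np.where(member_mask, s, 0.0))
        Z = (X - E) / np.sqrt(np.array(Vs) + floor)
        best = max(best, Z.max())
    return max(best, 0.0)


class TestGszScore:
    def test_equal_scores_give_zero(self):
        scores = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            g, direction, _ = gsz_score(scores, ["g0", "g1", "g2"])
        assert g == 0.0

    def test_top_heavy_set_detected_at_high_end(self):
        scores = pd.Series(np.arange(20, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(20)])
        g, direction, profile = gsz_score(scores, ["g0", "g1", "g2", "g3"])
        assert direction == "high" and g > 0
        assert profile.argmax() == 3  # deviation peaks right after the members

    def test_bottom_heavy_set_detected_at_low_end(self):
        scores = pd.Series(np.arange(20, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(20)])
        g, direction, _ = gsz_score(scores, ["g16", "g17", "g18", "g19"])
        assert direction == "low" and g > 0

    def test_mean_shifted_set_direction_follows_shift_sign(self):
        """A set whose members all score above the universe mean is 'high'
        even when the ascending profile's terminal deviation (which carries
        the same mean shift) happens to exceed the descending maximum."""
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=200),
                           index=[f"g{i:03d}" for i in range(200)])
        members = [f"g{i:03d}" for i in range(0, 40, 2)]
        scores.loc[members] = rng.normal(2.0, 0.5, len(members))
        _, direction, _ = gsz_score(scores, members)
        assert direction == "high"
        neg = scores * -1
        _, direction, _ = gsz_score(neg, members)
        assert direction == "low"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_reference(self, seed):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=8), index=[f"g{i}" for i in range(8)])
        members = list(rng.choice(scores.index, size=3, replace=False))
        params = GszParams()
        g, _, _ = gsz_score(scores, members, params)
        assert g == pytest.approx(gsz_reference(scores, members, params), abs=1e-9)


class TestPermutationNull:
    def test_pvalue_bounds(self):
        null = np.arange(100, dtype=float)
        assert empirical_pvalue(1e6, null) == pytest.approx(1 / 101)
        assert empirical_pvalue(-1.0, null) == pytest.approx(1.0)

    def test_null_scores_reproducible_and_nonnegative(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        members = list(scores.index[:8])
        params = GszParams(n_permutations=50, seed=5)
        a = permutation_null(scores, members, params)
        b = permutation_null(scores, members, params)
        assert np.array_equal(a, b) and (a >= 0).all()

    def test_requires_enough_permutations(self):
        with pytest.raises(DataError):
            GszParams(n_permutations=5)


class TestEvdPvalue:
    def test_gumbel_cdf_at_location(self):
        rng = np.random.default_rng(0)
        null = stats.gumbel_r.rvs(loc=2.0, scale=1.0, size=4000, random_state=rng)
        loc, scale = stats.gumbel_r.fit(null)
        p = evd_pvalue(loc, null, family="gumbel")
        assert p == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_extreme_observations(self):
        rng = np.random.default_rng(1)
        null = stats.gumbel_r.rvs(size=200, random_state=rng)
        assert evd_pvalue(-50.0, null, family="gumbel") == pytest.approx(1.0)
        assert evd_pvalue(1e9, null) >= np.finfo(float).eps

    def test_gumbel_parameter_recovery(self):
        rng = np.random.default_rng(2)
        null = stats.gumbel_r.rvs(loc=2.0, scale=1.0, size=5000, random_state=rng)
        sd = null.std()
        scale0 = sd * np.sqrt(6) / np.pi
        loc, scale = stats.gumbel_r.fit(null, loc=null.mean() - 0.5772 * scale0,
                                        scale=scale0)
        assert loc == pytest.approx(2.0, rel=0.05)
        assert scale == pytest.approx(1.0, rel=0.05)

    def test_degenerate_null_falls_back_to_empirical(self):
        with pytest.warns(UserWarning):
            p = evd_pvalue(1.0, np.zeros(30))
        assert p == pytest.approx(1 / 31)


class TestIntersectUniverse:
    def _scores(self, n=50):
        return pd.Series(np.linspace(1, -1, n), index=[f"g{i}" for i in range(n)])

    def test_out_of_universe_set_excluded(self):
        sets = GeneSetCollection({"out": ["x1", "x2", "x3", "x4", "x5"],
                                  "ok": [f"g{i}" for i in range(8)]})
        kept = intersect_universe(sets, self._scores())
        assert list(kept.sets) == ["ok"]

    def test_whole_universe_set_retained_within_bounds(self):
        scores = self._scores(30)
        sets = GeneSetCollection({"all": list(scores.index)})
        kept = intersect_universe(sets, scores, GszParams(max_set_size=30))
        assert "all" in kept.sets
        with pytest.raises(DataError):
            intersect_universe(sets, scores, GszParams(max_set_size=29))

    def test_default_bounds_keep_published_sizes(self):
        # analyzed sizes of the reported significant sets span 5..725
        published_sizes = [8, 5, 657, 321, 9, 7, 45, 725, 7, 22, 17, 7, 138]
        params = GszParams()
        assert all(params.min_set_size <= s <= params.max_set_size
                   for s in published_sizes)


class TestGeneSetZTest:
    def _fixture(self, n_sets=20, seed=3, N=400):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=N), index=[f"g{i}" for i in range(N)])
        sets = {f"s{i}": list(rng.choice(scores.index, size=10, replace=False))
                for i in range(n_sets)}
        return scores, GeneSetCollection(sets)

    def test_single_set_q_equals_p_asym(self):
        scores, _ = self._fixture()
        sets = GeneSetCollection({"only": list(scores.index[:10])})
        table = GeneSetZTest(scores, sets, GszParams(seed=1)).fit().table
        assert table["q"].iloc[0] == pytest.approx(table["p_asym"].iloc[0])

    def test_set_order_invariance(self):
        scores, coll = self._fixture()
        rev = GeneSetCollection(dict(reversed(list(coll.sets.items()))))
        a = GeneSetZTest(scores, coll, GszParams(seed=2)).fit().table
        b = GeneSetZTest(scores, rev, GszParams(seed=2)).fit().table
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_deterministic_output_bytes(self, tmp_path):
        scores, coll = self._fixture()
        paths = []
        for run in (1, 2):
            res = GeneSetZTest(scores, coll, GszParams(seed=9)).fit()
            path = tmp_path / f"run{run}.tsv"
            res.to_tsv(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_per_category_fdr(self):
        scores, coll = self._fixture(n_sets=10)
        cats = {name: ("A" if i < 5 else "B") for i, name in enumerate(coll.sets)}
        coll = GeneSetCollection(coll.sets, categories=cats)
        res = GeneSetZTest(scores, coll, GszParams(seed=4)).fit()
        tab = res.table
        from methylgsz.ewas import bh_adjust
        for cat in ("A", "B"):
            sub = tab[tab.category == cat]
            assert np.allclose(sub["q"], bh_adjust(sub["p_asym"].to_numpy(), len(sub)))

    def test_pvalue_rank_concordance(self):
        """Asymptotic and empirical p-values rank sets almost identically."""
        rng = np.random.default_rng(21)
        N = 1000
        scores = pd.Series(rng.normal(size=N), index=[f"g{i}" for i in range(N)])
        sets = {f"s{i}": list(rng.choice(scores.index,
                                         size=rng.integers(8, 30), replace=False))
                for i in range(100)}
        table = GeneSetZTest(scores, GeneSetCollection(sets),
                             GszParams(n_permutations=200, seed=6)).fit().table
        rho = stats.spearmanr(table["p_asym"], table["p_perm"]).statistic
        assert rho >= 0.9
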