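"""Mass-univariate ANOVA, TFCE enhancement, and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saccerp.tfce import (
    cluster_summary,
    mask_components,
    permutation_test,
    rm_anova_map,
    tfce_enhance,
)

CHAIN4 = [(0, 1), (1, 2), (2, 3)]
CHAIN6 = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]


def brute_force_tfce(stat, pairs, E, H, dh):
    """Independent per-threshold connected-component enumerator (BFS)."""
    n_ch, n_t = stat.shape
    heights = np.arange(1, int(np.floor(stat.max() / dh)) + 1) * dh
    out = np.zeros_like(stat)
    nbrs = {c: set() for c in range(n_ch)}
    for a, b in pairs:
        nbrs[a].add(b)
        nbrs[b].add(a)
    for h in heights:
        sup = stat >= h
        seen = np.zeros_like(sup)
        for c in range(n_ch):
            for t in range(n_t):
                if sup[c, t] and not seen[c, t]:
                    comp, stack = [], [(c, t)]
                    seen[c, t] = True
                    while stack:
                        cc, tt = stack.pop()
                        comp.append((cc, tt))
                        moves = [(cc, tt - 1), (cc, tt + 1)] + [(nb, tt) for nb in nbrs[cc]]
                        for c2, t2 in moves:
                            if 0 <= t2 < n_t and sup[c2, t2] and not seen[c2, t2]:
                                seen[c2, t2] = True
                                stack.append((c2, t2))
                    add = (len(comp) ** E) * (h**H) * dh
                    for cc, tt in comp:
                        out[cc, tt] += add
    return out


class TestRmAnova:
    def test_identical_conditions_give_zero(self):
        x = np.tile(np.arange(4.0)[:, None, None, None], (1, 3, 2, 5))
        assert np.all(rm_anova_map(x) == 0.0)

    def test_additive_hand_dataset_has_zero_error_variance(self):
        # rows {1,2,3},{2,3,4},{3,4,5}: pure subject+condition effects, so
        # MS_err = 0 and F is flagged infinite
        x = np.array([[1.0, 2, 3], [2, 3, 4], [3, 4, 5]])[:, :, None, None]
        f = rm_anova_map(x)
        assert np.isinf(f[0, 0])

    def test_hand_decomposition_with_interaction(self):
        x = np.array([[1.0, 2, 4], [2, 3, 4], [3, 5, 5]])
        s, c = 3, 3
        grand = x.mean()
        ss_cond = s * np.sum((x.mean(axis=0) - grand) ** 2)
        resid = x - x.mean(axis=0) - x.mean(axis=1)[:, None] + grand
        ss_err = np.sum(resid**2)
        expected = (ss_cond / 2) / (ss_err / 4)
        f = rm_anova_map(x[:, :, None, None])[0, 0]
        assert f == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal((6, 3, 1, 1))
        f = rm_anova_map(x)[0, 0]
        df = pd.DataFrame(
            {
                "y": x.ravel(),
                "subj": np.repeat(np.arange(6), 3),
                "cond": np.tile(np.arange(3), 6),
            }
        )
        ref = pingouin.rm_anova(data=df, dv="y", within="cond", subject="subj")
        assert f == pytest.approx(ref["F"].iloc[0], rel=1e-9)

    def test_null_distribution_ks(self, rng):
        x = rng.standard_normal((10, 3, 10000))
        f = rm_anova_map(x)
        p = stats.kstest(f.ravel(), stats.f(2, 18).cdf).pvalue
        assert p > 0.01

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            rm_anova_map(np.zeros((1, 3, 4)))


class TestTfceEnhance:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            stat = rng.random((4, 20)) * 5.0
            dh = stat.max() / 100.0
            mine = tfce_enhance(stat, CHAIN4, dh=dh)
            brute = brute_force_tfce(stat, CHAIN4, 0.666, 1.0, dh)
            rel = np.abs(mine - brute) / np.maximum(np.abs(brute), 1e-30)
            assert rel.max() < 1e-6

    def test_single_cell_analytic_limit(self):
        stat = np.zeros((4, 7))
        stat[2, 3] = 3.0
        approx = [tfce_enhance(stat, CHAIN4, dh=3.0 / n)[2, 3] for n in (100, 1000, 10000)]
        target = 3.0**2 / 2.0
        errors = np.abs(np.array(approx) - target)
        assert np.all(np.diff(errors) < 0)  # converges as dh -> 0
        assert errors[-1] / target < 1e-3

    def test_uniform_map_enhances_symmetrically(self):
        stat = np.full((4, 6), 2.0)
        e = tfce_enhance(stat, CHAIN4, dh=0.02)
        assert np.allclose(e, e[0, 0])

    def test_monotone_under_scaling(self, rng):
        stat = rng.random((4, 12)) * 3.0
        e1 = tfce_enhance(stat, CHAIN4, dh=stat.max() / 100)
        e2 = tfce_enhance(2.5 * stat, CHAIN4, dh=2.5 * stat.max() / 100)
        assert np.all(e2 >= e1 - 1e-12)

    def test_empty_adjacency_warns(self):
        stat = np.ones((3, 4))
        with pytest.warns(UserWarning, match="adjacency"):
            tfce_enhance(stat, [], dh=0.01)

    def test_negative_map_rejected(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.array([[-1.0, 0.0]]), [], dh=0.1)


class TestPermutationTest:
    def test_threshold_is_null_95th_percentile(self, rng):
        maps = rng.standard_normal((8, 3, 4, 10))
        res = permutation_test(maps, CHAIN4, n_perm=200, seed=1)
        thresh = np.quantile(res.null_max, 0.95)
        # cells significant at alpha=0.05 exceed ~the 95th percentile of null maxima
        if res.mask.any():
            assert res.enhanced[res.mask].min() >= thresh - 1e-9
        assert np.all(res.enhanced[~res.mask] <= np.max(res.null_max))

    def test_p_values_in_unit_interval_and_mask_consistent(self, rng):
        maps = rng.standard_normal((6, 3, 4, 8))
        res = permutation_test(maps, CHAIN4, n_perm=150, seed=2)
        assert np.all(res.p_map > 0) and np.all(res.p_map <= 1)
        assert np.array_equal(res.mask, res.p_map < res.alpha)
        assert len(res.null_max) == 150

    def test_fixed_seed_bit_identical(self, rng):
        maps = rng.standard_normal((7, 3, 4, 8))
        r1 = permutation_test(maps, CHAIN4, n_perm=120, seed=9)
        r2 = permutation_test(maps, CHAIN4, n_perm=120, seed=9)
        assert np.array_equal(r1.p_map, r2.p_map)
        assert np.array_equal(r1.null_max, r2.null_max)

    def test_tiny_cohort_uses_exact_enumeration(self, rng):
        maps = rng.standard_normal((2, 3, 2, 4))
        with pytest.warns(UserWarning, match="exact"):
            res = permutation_test(maps, [(0, 1)], n_perm=100, seed=0)
        assert res.exact and len(res.null_max) == 36  # (3!)^2

    def test_strong_effect_is_detected(self, rng):
        maps = 0.3 * rng.standard_normal((10, 3, 4, 20))
        maps[:, 2, 2:4, 8:14] += 3.0  # one condition departs on a patch
        res = permutation_test(maps, CHAIN4, n_perm=300, seed=3)
        assert res.mask[2:4, 8:14].mean() > 0.8


class TestClusterSummary:
    def _result(self, mask, enhanced=None):
        from saccerp.tfce import TfceResult

        enhanced = np.where(mask, 5.0, 0.0) if enhanced is None else enhanced
        return TfceResult(
            f_map=enhanced, enhanced=enhanced, null_max=np.ones(100),
            p_map=np.where(mask, 0.01, 0.5), mask=mask, alpha=0.05,
            E=0.666, H=1.0, dh=0.1,
        )

    def test_single_cell_cluster(self, rng):
        mask = np.zeros((4, 10), bool)
        mask[1, 3] = True
        maps = rng.standard_normal((5, 3, 4, 10))
        clusters, contrib = cluster_summary(
            self._result(mask), maps, CHAIN4, np.arange(10) / 500.0
        )
        assert len(clusters) == 1 and clusters[0]["n_cells"] == 1
        assert set(contrib["contrast"]) == {"background-body", "background-head", "body-head"}

    def test_two_disjoint_regions_two_clusters(self, rng):
        mask = np.zeros((4, 10), bool)
        mask[0, 0:2] = True
        mask[3, 7:9] = True
        comp, n = mask_components(mask, CHAIN4)
        assert n == 2
        clusters, _ = cluster_summary(
            self._result(mask), rng.standard_normal((4, 3, 4, 10)), CHAIN4, np.arange(10) / 500.0
        )
        assert len(clusters) == 2

    def test_empty_mask_empty_summary(self, rng):
        mask = np.zeros((4, 10), bool)
        clusters, contrib = cluster_summary(
            self._result(mask), rng.standard_normal((4, 3, 4, 10)), CHAIN4, np.arange(10) / 500.0
        )
        assert clusters == [] and contrib.empty

    def test_contrast_peak_is_argmax_of_mean_difference(self, rng):
        mask = np.ones((2, 6), bool)
        maps = rng.standard_normal((6, 3, 2, 6))
        res = self._result(mask)
        _, contrib = cluster_summary(res, maps, [(0, 1)], np.arange(6) / 500.0, labels=("a", "b"))
        row = contrib[(contrib["contrast"] == "background-head") & (contrib["channel"] == "a")]
        diff = (maps[:, 0, 0] - maps[:, 2, 0]).mean(axis=0)
        assert row["time_ms"].iloc[0] == pytest.approx(np.argmax(np.abs(diff)) / 500.0 * 1000)
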