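"""Static metrics: confidence binning, SDT tabulation, meta-d', type-II AUC."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from vratio.metrics import (
    SDTTable,
    bin_confidence,
    build_sdt_table,
    fit_meta_d,
    type2_auc,
)


class TestBinConfidence:
    def test_eight_values_four_bins(self):
        labels = bin_confidence([1, 2, 3, 4, 5, 6, 7, 8], 4)
        _, counts = np.unique(labels, return_counts=True)
        assert list(counts) == [2, 2, 2, 2]

    def test_all_identical(self):
        np.testing.assert_array_equal(bin_confidence([3.0] * 10, 4), np.ones(10))

    def test_order_preserved(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        labels = bin_confidence(vals, 4)
        for lo, hi in [(1.0, 2.0), (2.0, 3.0), (3.0, 4.0)]:
            assert labels[vals == lo].max() <= labels[vals == hi].min()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=200)
        np.testing.assert_array_equal(bin_confidence(vals, 4), bin_confidence(np.exp(vals), 4))


class TestBuildSDTTable:
    def test_hand_tabulated_eight_trials(self):
        # stimulus, choice, confidence level (2 levels)
        stim = [-1, -1, -1, -1, 1, 1, 1, 1]
        choice = [-1, -1, 1, 1, -1, 1, 1, 1]
        conf = [2, 1, 1, 2, 1, 1, 2, 2]
        t = build_sdt_table(stim, choice, conf, n_levels=2)
        # layout: [S1resp conf2, S1resp conf1, S2resp conf1, S2resp conf2]
        np.testing.assert_array_equal(t.counts_s1, [1, 1, 1, 1])
        np.testing.assert_array_equal(t.counts_s2, [0, 1, 1, 2])

    def test_counts_conserved(self, small_dataset):
        _, ds = small_dataset
        labels = bin_confidence(ds.confidence, 4)
        t = build_sdt_table(ds.trials["stimulus"], ds.trials["choice"], labels, 4)
        assert t.counts_s1.sum() + t.counts_s2.sum() == len(ds)

    def test_relabel_symmetry(self):
        rng = np.random.default_rng(11)
        stim = rng.choice([-1, 1], 400)
        choice = rng.choice([-1, 1], 400)
        conf = rng.integers(1, 5, 400)
        a = build_sdt_table(stim, choice, conf, 4)
        b = build_sdt_table(-stim, -choice, conf, 4)
        np.testing.assert_array_equal(a.counts_s1, b.counts_s2[::-1])
        np.testing.assert_array_equal(a.counts_s2, b.counts_s1[::-1])

    def test_single_stimulus_class_rejected(self):
        with pytest.raises(ValueError):
            build_sdt_table([1, 1], [1, -1], [1, 2], 2)


def _ideal_observer_table(d: float, n: int, seed: int, n_levels: int = 4):
    """SDT observer whose confidence is the distance from the criterion."""
    rng = np.random.default_rng(seed)
    stim = rng.choice([-1, 1], n)
    x = rng.normal(stim * d / 2.0, 1.0)
    choice = np.where(x >= 0, 1, -1)
    conf = bin_confidence(np.abs(x), n_levels)
    return build_sdt_table(stim, choice, conf, n_levels)


class TestFitMetaD:
    def test_ideal_observer_meta_d_matches_d(self):
        t = _ideal_observer_table(d=1.5, n=20000, seed=31)
        res = fit_meta_d(t)
        assert res.d_prime == pytest.approx(1.5, abs=0.05)
        assert res.meta_d_prime == pytest.approx(res.d_prime, abs=0.1)
        assert res.m_ratio == pytest.approx(1.0, abs=0.07)

    def test_shuffled_confidence_destroys_meta_d(self):
        rng = np.random.default_rng(37)
        stim = rng.choice([-1, 1], 20000)
        x = rng.normal(stim * 1.5 / 2.0, 1.0)
        choice = np.where(x >= 0, 1, -1)
        conf = bin_confidence(rng.permutation(np.abs(x)), 4)
        res = fit_meta_d(build_sdt_table(stim, choice, conf, 4))
        assert abs(res.meta_d_prime) < 0.15

    def test_negative_d_prime_flagged(self):
        t = SDTTable(2, np.array([1.0, 2.0, 10.0, 10.0]), np.array([10.0, 10.0, 2.0, 1.0]))
        res = fit_meta_d(t)
        assert math.isnan(res.m_ratio)
        assert not res.converged

    def test_unequal_variance_scale(self):
        # with s != 1, d' uses the RMS-scaled convention
        t = _ideal_observer_table(d=1.5, n=20000, seed=41)
        r1 = fit_meta_d(t, s_ratio=1.0)
        r2 = fit_meta_d(t, s_ratio=0.8)
        assert r1.d_prime != pytest.approx(r2.d_prime, abs=1e-6)
        assert r2.s_ratio_used == 0.8
        assert math.isfinite(r2.m_ratio)

    def test_grid_search_oracle(self):
        """Independent brute-force fit of the same conditional type-2 likelihood."""
        table = SDTTable(
            2,
            np.array([44.0, 25.0, 20.0, 11.0]),
            np.array([12.0, 18.0, 28.0, 42.0]),
        )
        res = fit_meta_d(table)
        pt = table.padded()
        k = 2
        n1, n2 = pt.counts_s1.sum(), pt.counts_s2.sum()
        far = pt.counts_s1[k:].sum() / n1
        hr = pt.counts_s2[k:].sum() / n2
        d1 = norm.ppf(hr) - norm.ppf(far)
        c1 = -0.5 * (norm.ppf(hr) + norm.ppf(far))
        counts = np.vstack([pt.counts_s1, pt.counts_s2])

        def nll(meta_d):
            """Profile NLL: the conditional likelihood factorizes across the two
            sides of the type-1 criterion, so each type-2 criterion is searched
            on its own dense grid."""
            mc = meta_d * c1 / d1
            mu = np.array([-meta_d / 2.0, meta_d / 2.0])
            p_s1 = norm.cdf(mc - mu)  # P("S1" response | stimulus)
            g = np.linspace(1e-3, 4.0, 4000)
            # below mc: cells (-inf, mc-g) and (mc-g, mc), denominator p_s1
            lo_edge = norm.cdf(mc - g[:, None] - mu[None, :])
            cells_lo = np.stack([lo_edge, p_s1[None, :] - lo_edge], axis=2)
            cond_lo = np.clip(cells_lo / p_s1[None, :, None], 1e-300, None)
            # counts for (stim, [conf2, conf1]) on the "S1"-response side
            c_lo = np.stack([counts[:, 0], counts[:, 1]], axis=1)
            nll_lo = -np.einsum("gsc,sc->g", np.log(cond_lo), c_lo)
            # above mc: cells (mc, mc+g) and (mc+g, inf), denominator 1 - p_s1
            hi_edge = norm.cdf(mc + g[:, None] - mu[None, :])
            cells_hi = np.stack([hi_edge - p_s1[None, :], 1.0 - hi_edge], axis=2)
            cond_hi = np.clip(cells_hi / (1.0 - p_s1)[None, :, None], 1e-300, None)
            c_hi = np.stack([counts[:, 2], counts[:, 3]], axis=1)
            nll_hi = -np.einsum("gsc,sc->g", np.log(cond_hi), c_hi)
            return nll_lo.min() + nll_hi.min()

        md_grid = np.arange(0.05, 3.0, 0.01)
        coarse = np.array([nll(md) for md in md_grid])
        md0 = md_grid[int(np.argmin(coarse))]
        md_fine = np.arange(md0 - 0.02, md0 + 0.02, 0.0005)
        fine = np.array([nll(md) for md in md_fine])
        best_md = md_fine[int(np.argmin(fine))]
        meta_d1_opt = res.meta_d_prime  # s=1 so the scale factor is 1
        assert meta_d1_opt == pytest.approx(best_md, abs=1e-3)
        assert res.nll <= fine.min() + 1e-4


class TestType2AUC:
    def test_constant_confidence_is_chance(self):
        acc = np.array([True, False, True, False])
        assert type2_auc(acc, np.ones(4)) == pytest.approx(0.5)

    def test_perfect_separation(self):
        acc = np.array([True, True, False, False])
        assert type2_auc(acc, [4.0, 3.0, 2.0, 1.0]) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(43)
        acc = rng.random(300) < 0.7
        conf = rng.normal(acc.astype(float), 1.0)
        a = type2_auc(acc, conf)
        b = type2_auc(acc, np.exp(conf))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            type2_auc([True, True], [1.0, 2.0])


def test_padding_perturbs_d_prime_only_slightly():
    t = _ideal_observer_table(d=1.2, n=5000, seed=47)
    r_small = fit_meta_d(t, pad=1e-6)
    r_default = fit_meta_d(t)
    assert abs(r_small.d_prime - r_default.d_prime) < 0.01
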