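"""Measurement stack: segmentation, CoV, SSIM, polar maps, TPD, ROC/DeLong."""

from itertools import product

import numpy as np
import pytest

from spect_bench.evaluation import (
    NormalDB,
    PolarMap,
    RatingSet,
    build_normal_db,
    cov,
    delong_test,
    paired_t_test,
    polar_map,
    roc_auc,
    segment_myocardium,
    ssim_region,
    tpd,
)
from spect_bench.volume import Volume


def _vol(values, voxel=4.8):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return Volume(arr, voxel)


def _mask_like(vol):
    return Volume(np.ones(vol.shape), vol.voxel_mm)


class TestSegmentation:
    def test_truth_mode_passes_mask_through(self, small_phantom):
        out = segment_myocardium(small_phantom.activity, mode="truth",
                                 truth_mask=small_phantom.myo_mask)
        assert out is small_phantom.myo_mask

    def test_all_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            segment_myocardium(Volume(np.zeros((16, 16, 16)), 4.8))

    def test_threshold_mode_recovers_wall_on_clean_reconstruction(self):
        """Dice >= 0.8 against truth on a noise-free reconstruction that
        resolves the wall (3 mm grid, converged OSEM, no post-filter)."""
        from spect_bench.geometry import SystemGeometry
        from spect_bench.phantom import PhantomSpec, make_phantom
        from spect_bench.projector import forward_project
        from spect_bench.recon import OsemConfig, osem

        spec = PhantomSpec(grid_shape=(64,) * 3, voxel_mm=3.0,
                           body_mm=(88.0, 70.0), seed=3)
        ph = make_phantom(spec)
        geom = SystemGeometry(n_views=64, det_rows=64, det_cols=64, pixel_mm=3.0)
        proj = forward_project(ph.activity, ph.attn, geom)
        rec = osem(proj, ph.attn, geom,
                   OsemConfig(n_iterations=20, postfilter_fwhm_mm=0.0))
        seg = segment_myocardium(rec)
        truth = ph.myo_mask.data
        dice = 2 * (seg.data * truth).sum() / (seg.data.sum() + truth.sum())
        assert dice >= 0.8


class TestCov:
    def test_constant_region_has_zero_cov(self):
        vol = _vol([3.0] * 10)
        assert cov(vol, _mask_like(vol)) == 0.0

    def test_hand_computed_sample_sd_over_mean(self):
        vol = _vol([1.0, 2.0, 3.0])
        assert cov(vol, _mask_like(vol)) == pytest.approx(50.0)  # 100 * 1 / 2

    def test_scale_invariance(self, rng):
        vol = Volume(rng.uniform(1, 5, (6, 6, 6)), 4.8)
        mask = _mask_like(vol)
        base = cov(vol, mask)
        for c in (0.1, 7.3):
            assert cov(vol.like(vol.data * c), mask) == pytest.approx(base, rel=1e-12)

    def test_zero_mean_rejected(self):
        vol = _vol([0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            cov(vol, _mask_like(vol))


class TestSsim:
    def test_self_similarity_is_exactly_one(self, rng):
        vol = Volume(rng.uniform(0.5, 2.0, (8, 8, 8)), 4.8)
        assert ssim_region(vol, vol, _mask_like(vol)) == 1.0

    def test_reversed_sequence_gives_minus_one(self):
        f, r = _vol([1, 2, 3]), _vol([3, 2, 1])
        assert ssim_region(f, r, _mask_like(f)) == pytest.approx(-1.0)

    def test_scaled_copy_matches_brute_force_formula(self, rng):
        f = Volume(rng.uniform(0.5, 2.0, (6, 6, 6)), 4.8)
        mask = _mask_like(f)
        prev_gap = None
        for c in (2.0, 1.5, 1.1, 1.01):
            r = f.like(c * f.data)
            v = f.data.ravel()
            mu_f, mu_r = v.mean(), c * v.mean()
            var_f = v.var(ddof=1)
            var_r = (c * v).var(ddof=1)
            cov_fr = np.cov(v, c * v, ddof=1)[0, 1]
            brute = (2 * mu_f * mu_r / (mu_f**2 + mu_r**2)) * (
                2 * cov_fr / (var_f + var_r)
            )
            got = ssim_region(f, r, mask)
            assert got == pytest.approx(brute, rel=1e-10)
            gap = 1.0 - got
            if prev_gap is not None:
                assert gap < prev_gap  # approaches 1 as c -> 1
            prev_gap = gap

    def test_ssim_never_exceeds_one(self, rng):
        mask = Volume(np.ones((5, 5, 5)), 4.8)
        for _ in range(20):
            a = Volume(rng.uniform(0, 3, (5, 5, 5)), 4.8)
            b = Volume(rng.uniform(0, 3, (5, 5, 5)), 4.8)
            assert ssim_region(a, b, mask) <= 1.0 + 1e-12

    def test_degenerate_regions_rejected(self):
        flat = _vol([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="variances"):
            ssim_region(flat, flat, _mask_like(flat))


class TestPolarMap:
    def test_uniform_phantom_is_flat(self, small_phantom):
        pm = polar_map(small_phantom.activity, small_phantom.myo_mask)
        assert np.all(np.abs(pm.samples - 1.0) <= 0.10)

    def test_shape_contract(self, small_phantom):
        pm = polar_map(small_phantom.activity, small_phantom.myo_mask,
                       n_rings=10, n_angles=24)
        assert pm.samples.shape == (10, 24)

    def test_invariant_to_global_scaling(self, small_phantom):
        a = polar_map(small_phantom.activity, small_phantom.myo_mask)
        scaled = small_phantom.activity.like(small_phantom.activity.data * 17.0)
        b = polar_map(scaled, small_phantom.myo_mask)
        np.testing.assert_allclose(a.samples, b.samples, rtol=1e-12)

    def test_empty_mask_rejected(self, small_phantom):
        empty = Volume(np.zeros(small_phantom.activity.shape), 4.8)
        with pytest.raises(ValueError, match="empty"):
            polar_map(small_phantom.activity, empty)


class TestNormalDB:
    @staticmethod
    def _pm(samples):
        return PolarMap(samples=np.asarray(samples, dtype=float), norm_factor=1.0)

    def test_identical_maps_hit_sd_floor(self):
        maps = [self._pm(np.ones((12, 36))) for _ in range(4)]
        db = build_normal_db(maps)
        assert np.allclose(db.sd, NormalDB.SD_FLOOR_FRACTION * 1.0)

    def test_hand_computed_mean_and_sd(self):
        a = np.ones((12, 36))
        b = np.ones((12, 36))
        a[3, 5], b[3, 5] = 0.9, 1.1
        db = build_normal_db([self._pm(a), self._pm(b)])
        assert db.mean[3, 5] == pytest.approx(1.0)
        assert db.sd[3, 5] == pytest.approx(np.sqrt(2) * 0.1, rel=1e-6)

    def test_needs_two_maps(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_normal_db([self._pm(np.ones((12, 36)))])


class TestTpd:
    def _db(self):
        return NormalDB(mean=np.ones((12, 36)), sd=np.full((12, 36), 0.05),
                        n_studies=10)

    def test_nominal_study_scores_zero(self):
        db = self._db()
        pm = PolarMap(samples=db.mean.copy(), norm_factor=1.0)
        assert tpd(pm, db) == 0.0

    def test_single_saturated_sample_closed_form(self):
        """One of 432 samples at z = z0 + zcap contributes 100/432 %."""
        db = self._db()
        samples = db.mean.copy()
        samples[4, 7] -= (3.0 + 4.0) * db.sd[4, 7]
        pm = PolarMap(samples=samples, norm_factor=1.0)
        assert tpd(pm, db) == pytest.approx(100.0 / 432.0, rel=1e-9)

    def test_deeper_defect_never_lowers_tpd(self):
        db = self._db()
        samples = db.mean.copy()
        prev = tpd(PolarMap(samples.copy(), 1.0), db)
        for depth in (0.1, 0.2, 0.4, 0.6):
            s = db.mean.copy()
            s[2:5, 6:12] -= depth
            cur = tpd(PolarMap(s, 1.0), db)
            assert cur >= prev
            prev = cur


def _auc_brute(pos, neg):
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p, n in product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        rs = RatingSet(np.array([1, 2, 5, 6.0]), np.array([0, 0, 1, 1], bool))
        assert roc_auc(rs).auc == 1.0

    def test_tied_case_matches_pair_enumeration(self):
        rs = RatingSet(np.array([1, 2, 2, 3.0]), np.array([0, 0, 1, 1], bool))
        assert roc_auc(rs).auc == pytest.approx(0.875)  # (1+1+0.5+1)/4

    def test_random_toys_match_exhaustive_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            scores = rng.integers(0, 6, 10).astype(float)
            truth = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], bool)
            res = roc_auc(RatingSet(scores, truth))
            assert res.auc == pytest.approx(_auc_brute(scores[truth], scores[~truth]))
            assert res.auc == pytest.approx(roc_auc_score(truth, scores))

    def test_uninformative_ratings_sit_near_half(self, rng):
        scores = rng.standard_normal(600)
        truth = np.repeat([False, True], 300)
        assert roc_auc(RatingSet(scores, truth)).auc == pytest.approx(0.5, abs=0.07)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(RatingSet(np.array([1.0, 2.0]), np.array([1, 1], bool)))


def _delong_brute(scores_a, scores_b, truth):
    """Placement-value computation written out longhand (independent loops)."""
    pos = np.where(truth)[0]
    neg = np.where(~truth)[0]
    m, n = len(pos), len(neg)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    def placements(scores):
        v10 = [sum(psi(scores[i], scores[j]) for j in neg) / n for i in pos]
        v01 = [sum(psi(scores[i], scores[j]) for i in pos) / m for j in neg]
        return np.array(v10), np.array(v01)

    v10a, v01a = placements(scores_a)
    v10b, v01b = placements(scores_b)
    auc_a, auc_b = v10a.mean(), v10b.mean()

    def cov(u, v):
        return ((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1)

    var = (
        cov(v10a, v10a) + cov(v10b, v10b) - 2 * cov(v10a, v10b)
    ) / m + (cov(v01a, v01a) + cov(v01b, v01b) - 2 * cov(v01a, v01b)) / n
    return auc_a - auc_b, var


class TestDeLong:
    TOY_A = np.array([3.1, 2.2, 1.5, 4.0, 2.8, 5.1, 4.4, 3.9, 6.0, 5.5])
    TOY_B = np.array([2.0, 2.9, 1.1, 3.3, 3.0, 4.9, 3.1, 5.2, 4.1, 6.1])
    TRUTH = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], bool)

    def test_self_comparison_is_null(self):
        rs = RatingSet(self.TOY_A, self.TRUTH)
        delta, z, p = delong_test(rs, rs)
        assert delta == 0.0
        assert p == 1.0

    def test_fixed_toy_matches_placement_oracle(self):
        rs_a = RatingSet(self.TOY_A, self.TRUTH)
        rs_b = RatingSet(self.TOY_B, self.TRUTH)
        delta, z, p = delong_test(rs_a, rs_b)
        d_ref, var_ref = _delong_brute(self.TOY_A, self.TOY_B, self.TRUTH)
        assert delta == pytest.approx(d_ref, abs=1e-12)
        assert z == pytest.approx(d_ref / np.sqrt(var_ref), rel=1e-9)
        from scipy.stats import norm

        assert p == pytest.approx(2 * norm.sf(abs(z)), rel=1e-9)

    def test_internal_auc_equals_roc_auc(self, rng):
        scores_a = rng.normal(size=14)
        scores_b = scores_a + rng.normal(scale=0.3, size=14)
        truth = np.repeat([False, True], 7)
        rs_a, rs_b = RatingSet(scores_a, truth), RatingSet(scores_b, truth)
        delta, _, _ = delong_test(rs_a, rs_b)
        assert delta == pytest.approx(roc_auc(rs_a).auc - roc_auc(rs_b).auc,
                                      abs=1e-12)

    def test_unpaired_inputs_rejected(self):
        rs_a = RatingSet(self.TOY_A, self.TRUTH)
        rs_b = RatingSet(self.TOY_B[:8], self.TRUTH[:8])
        with pytest.raises(ValueError, match="paired"):
            delong_test(rs_a, rs_b)


class TestPairedT:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = paired_t_test(x, x)
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_t_statistic(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.zeros(3)
        t, p = paired_t_test(x, y)
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), rel=1e-9)  # 3.4641
        assert p == pytest.approx(0.07418, abs=1e-3)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        t1, p1 = paired_t_test(x, y)
        t2, p2 = paired_t_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_constant_shift_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        t, p = paired_t_test(x + 0.5, x)
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test(np.ones(3), np.ones(4))
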