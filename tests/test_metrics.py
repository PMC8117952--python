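"""Agreement metrics against independent brute-force oracles."""
import numpy as np
import pytest

from mbfseg import metrics as mx
from mbfseg.core import Contour
from mbfseg.errors import (EmptyReference, SingularCovariance, ZeroVariance)
from mbfseg.geometry import disk_contour, resample_closed


# --------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)
# --------------------------------------------------------------------------

def brute_confusion(auto, ref):
    tp = fp = fn = tn = 0
    for a, r in zip(np.asarray(auto).ravel(), np.asarray(ref).ravel()):
        if a and r:
            tp += 1
        elif a and not r:
            fp += 1
        elif not a and r:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_kappa(auto, ref):
    tp, fp, fn, tn = brute_confusion(auto, ref)
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    p_auto = (tp + fp) / n
    p_ref = (tp + fn) / n
    pe = p_auto * p_ref + (1 - p_auto) * (1 - p_ref)
    return (po - pe) / (1 - pe)


def brute_nn_distances(pts_a, pts_b):
    out = []
    for p in pts_a:
        out.append(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in pts_b))
    return np.asarray(out)


def brute_u_statistic(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def random_masks(rng, shape=(12, 12)):
    auto = rng.random(shape) > 0.6
    ref = rng.random(shape) > 0.6
    ref[0, 0] = True  # never empty
    auto[1, 1] = True
    return auto, ref


def random_contour(rng, n=20):
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(5, 10, n)
    return Contour(np.column_stack([16 + r * np.sin(theta),
                                    16 + r * np.cos(theta)]))


class TestAreaAgreementOracle:
    def test_identical_masks(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:6, 3:7] = True
        a = mx.area_agreement(m, m)
        assert a.dice == 1.0 and a.kappa == pytest.approx(1.0)
        assert a.volume_overlap_error == 0.0
        assert a.relative_volume_difference == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[:2, :2] = True
        b[10:12, 10:12] = True
        agg = mx.area_agreement(a, b)
        assert agg.dice == 0.0

    def test_shifted_square_counts(self):
        # 2x2 auto square overlapping ref by 2 px on a 10x10 grid
        auto = np.zeros((10, 10), dtype=bool)
        ref = np.zeros((10, 10), dtype=bool)
        auto[2:4, 2:4] = True
        ref[2:4, 3:5] = True
        agg = mx.area_agreement(auto, ref)
        assert agg.dice == pytest.approx(0.5)
        assert agg.kappa == pytest.approx(brute_kappa(auto, ref), abs=1e-12)

    def test_empty_reference_raises(self):
        auto = np.ones((4, 4), dtype=bool)
        with pytest.raises(EmptyReference):
            mx.area_agreement(auto, np.zeros((4, 4), dtype=bool))

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            auto, ref = random_masks(rng)
            tp, fp, fn, tn = brute_confusion(auto, ref)
            n = tp + fp + fn + tn
            agg = mx.area_agreement(auto, ref)
            assert agg.dice == pytest.approx(2 * tp / (2 * tp + fp + fn),
                                             abs=1e-9)
            assert agg.kappa == pytest.approx(brute_kappa(auto, ref),
                                              abs=1e-9)
            assert agg.accuracy == pytest.approx((tp + tn) / n, abs=1e-9)
            assert agg.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-9)
            assert agg.specificity == pytest.approx(tn / (tn + fp), abs=1e-9)
            assert agg.ppv == pytest.approx(tp / (tp + fp), abs=1e-9)
            assert agg.volume_overlap_error == pytest.approx(
                1 - tp / (tp + fp + fn), abs=1e-9)
            assert agg.relative_volume_difference == pytest.approx(
                ((tp + fp) - (tp + fn)) / (tp + fn), abs=1e-9)


class TestBorderDistances:
    def test_identical_contours_all_zero(self):
        c = Contour(disk_contour((16, 16), 8.0, 64))
        assert mx.rms_nn_border_distance(c, c) == 0.0
        assert mx.hausdorff(c, c) == 0.0
        assert mx.assd(c, c) == 0.0

    def test_concentric_circles_give_ring_gap(self):
        a = Contour(disk_contour((32, 32), 12.0, 256))
        r = Contour(disk_contour((32, 32), 10.0, 256))
        assert mx.rms_nn_border_distance(a, r) == pytest.approx(2.0,
                                                                abs=0.05)
        assert mx.hausdorff(a, r) == pytest.approx(2.0, abs=0.05)
        assert mx.assd(a, r) == pytest.approx(2.0, abs=0.05)

    def test_distances_scale_linearly_with_spacing(self):
        a = Contour(disk_contour((32, 32), 12.0, 256))
        r = Contour(disk_contour((32, 32), 10.0, 256))
        assert mx.rms_nn_border_distance(a, r, (2.0, 2.0)) == pytest.approx(
            4.0, abs=0.1)
        assert mx.hausdorff(a, r, (2.0, 2.0)) == pytest.approx(4.0, abs=0.1)

    def test_matches_brute_force_on_random_contours(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = random_contour(rng)
            r = random_contour(rng)
            pa = resample_closed(a.points, spacing=0.5)
            pr = resample_closed(r.points, spacing=0.5)
            d_ar = brute_nn_distances(pa, pr)
            d_ra = brute_nn_distances(pr, pa)
            assert mx.rms_nn_border_distance(a, r) == pytest.approx(
                np.sqrt((d_ar ** 2).mean()), abs=1e-9)
            assert mx.hausdorff(a, r) == pytest.approx(
                max(d_ar.max(), d_ra.max()), abs=1e-9)
            assert mx.assd(a, r) == pytest.approx(
                np.concatenate([d_ar, d_ra]).mean(), abs=1e-9)

    def test_symmetry_of_hausdorff_and_assd_not_rms(self):
        rng = np.random.default_rng(2)
        a, r = random_contour(rng), random_contour(rng)
        assert mx.hausdorff(a, r) == pytest.approx(mx.hausdorff(r, a),
                                                   abs=1e-12)
        assert mx.assd(a, r) == pytest.approx(mx.assd(r, a), abs=1e-12)
        # the RMS nearest-neighbour distance is directed by definition
        assert mx.rms_nn_border_distance(a, r) != pytest.approx(
            mx.rms_nn_border_distance(r, a), abs=1e-6)


class TestMahalanobis:
    def test_translated_congruent_clouds_match_closed_form(self):
        rng = np.random.default_rng(3)
        base = rng.multivariate_normal([0, 0], [[4, 1], [1, 2]], 200)
        a = Contour(base + np.array([30, 30]))
        r = Contour(base + np.array([33, 31]))
        # identical covariances: pooled == individual; closed form on the
        # centroid difference
        pa = resample_closed(a.points, spacing=0.5)
        pr = resample_closed(r.points, spacing=0.5)
        diff = pa.mean(axis=0) - pr.mean(axis=0)
        na, nr = len(pa), len(pr)
        pooled = ((na - 1) * np.cov(pa.T) + (nr - 1) * np.cov(pr.T)) / (
            na + nr - 2)
        expected = float(np.sqrt(diff @ np.linalg.inv(pooled) @ diff))
        assert mx.mahalanobis(a, r) == pytest.approx(expected, abs=1e-9)

    def test_collinear_sets_raise(self):
        line = np.column_stack([np.linspace(0, 10, 20), np.zeros(20)])
        with pytest.raises(SingularCovariance):
            mx.mahalanobis(Contour(line), Contour(line + [0, 0]))


class TestPairedStatistics:
    def test_identical_sequences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = mx.bland_altman(x, x)
        assert ba.bias == 0.0 and ba.sd == 0.0
        assert mx.pearson(x, x) == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = mx.bland_altman(x + 0.1, x)
        assert ba.bias == pytest.approx(0.1)
        assert ba.loa_low == pytest.approx(ba.bias - 1.96 * ba.sd)
        assert ba.loa_high == pytest.approx(ba.bias + 1.96 * ba.sd)
        assert mx.pearson(x + 0.1, x) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVariance):
            mx.pearson(np.ones(5), np.arange(5.0))

    def test_u_statistic_matches_rank_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 20, 10).astype(float)
            y = rng.integers(0, 20, 10).astype(float)
            assert mx.mann_whitney_u(x, y) == pytest.approx(
                brute_u_statistic(x, y), abs=1e-9)

    def test_icc_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        truth = rng.normal(2, 0.8, 30)
        auto = truth + rng.normal(0.05, 0.15, 30)
        ref = truth + rng.normal(0, 0.15, 30)
        ours = mx.icc(auto, ref)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(30), 2),
            "raters": np.repeat(["a", "r"], 30),
            "scores": np.concatenate([auto, ref]),
        })
        table = pingouin.intraclass_corr(df, targets="targets",
                                         raters="raters", ratings="scores")
        # ICC(A,1): two-way random, absolute agreement, single measures
        icc2 = float(table.loc[table["Type"] == "ICC2", "ICC"].iloc[0]
                     if (table["Type"] == "ICC2").any()
                     else table["ICC"].iloc[1])
        assert ours == pytest.approx(icc2, abs=1e-9)


class TestDiceKappaProximity:
    def test_near_identical_on_background_dominated_masks(self,
                                                          noisy_study):
        """With a dominant background the chance-corrected kappa tracks
        Dice closely — the behaviour reported for full-image masks."""
        from mbfseg.core import SliceLocation

        tr = noisy_study.truth[SliceLocation.BASE]
        rng = np.random.default_rng(6)
        # perturb the truth annulus to emulate an imperfect segmentation
        noisy_mask = tr.myo_mask ^ (rng.random(tr.myo_mask.shape) < 0.01)
        agg = mx.area_agreement(noisy_mask, tr.myo_mask)
        assert abs(agg.dice - agg.kappa) <= 0.05
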