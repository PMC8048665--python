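"""Challenge metric suite: identities, oracles, and invariances."""

import numpy as np
import pytest
from scipy import ndimage

from qsmphantom.metrics import (
    calc_moment,
    calc_streak,
    deviation_from_linear_slope,
    evaluate_all,
    nrmse,
    rmse_detrended,
)


@pytest.fixture()
def truth_mask():
    rng = np.random.default_rng(0)
    truth = rng.normal(0.0, 0.05, size=(24, 24, 24))
    mask = np.zeros((24, 24, 24), bool)
    mask[2:22, 2:22, 2:22] = True
    return truth, mask


class TestNrmse:
    def test_identity_and_offset(self, truth_mask):
        truth, mask = truth_mask
        assert nrmse(truth, truth, mask) == 0.0
        assert nrmse(truth + 0.7, truth, mask) < 1e-10

    def test_antipodal_scores_200(self, truth_mask):
        truth, mask = truth_mask
        truth = truth - truth[mask].mean()
        np.testing.assert_allclose(nrmse(-truth, truth, mask), 200.0, rtol=1e-9)

    def test_constant_truth_rejected(self):
        mask = np.ones((4, 4, 4), bool)
        with pytest.raises(ValueError, match="constant"):
            nrmse(np.zeros((4, 4, 4)), np.full((4, 4, 4), 2.0), mask)


class TestRmseDetrended:
    def test_pure_scaling_detrends_to_zero(self, truth_mask):
        truth, mask = truth_mask
        score, flagged = rmse_detrended(2.0 * truth, truth, mask)
        assert score < 1e-10 and flagged
        score, _ = rmse_detrended(truth, truth, mask)
        assert score < 1e-12

    def test_noise_level_recovered(self):
        """recon = truth + noise(sd sigma): score ~ 100 sigma / SD(truth)."""
        rng = np.random.default_rng(1)
        truth = rng.normal(0.0, 0.05, size=(30, 30, 30))
        noise = rng.normal(0.0, 0.01, size=truth.shape)
        mask = np.ones(truth.shape, bool)
        score, _ = rmse_detrended(truth + noise, truth, mask)
        expected = 100.0 * 0.01 / truth.std()
        assert abs(score - expected) / expected < 0.10

    def test_negative_slope_flagged_not_detrended(self, truth_mask):
        truth, mask = truth_mask
        score, detrended = rmse_detrended(-truth, truth, mask)
        assert not detrended
        assert score > 100.0

    def test_scale_invariance_contrast_with_nrmse(self, truth_mask):
        truth, mask = truth_mask
        scaled = 3.0 * truth
        assert nrmse(scaled, truth, mask) > 1.0
        score, _ = rmse_detrended(scaled, truth, mask)
        assert score < 1e-9


class TestLinearitySlope:
    def _regions(self):
        masks, means = {}, {}
        vol = np.zeros((20, 20, 20))
        presc = {"a": 0.044, "b": 0.131, "c": 0.038, "d": 0.1, "e": 0.152, "f": 0.111}
        for i, (name, chi) in enumerate(presc.items()):
            m = np.zeros((20, 20, 20), bool)
            m[3 * i : 3 * i + 2, :3, :3] = True
            masks[name] = m
            vol[m] = chi
        return vol, masks, presc

    def test_exact_means_score_zero(self):
        vol, masks, presc = self._regions()
        assert deviation_from_linear_slope(vol, masks, presc) < 1e-12

    def test_global_scaling_detected(self):
        vol, masks, presc = self._regions()
        np.testing.assert_allclose(
            deviation_from_linear_slope(0.8 * vol, masks, presc), 0.2, atol=1e-12
        )

    def test_offset_case_matches_regression_oracle(self):
        """A constant offset changes the through-origin slope exactly as an
        independently coded least-squares fit predicts."""
        vol, masks, presc = self._regions()
        out = deviation_from_linear_slope(vol + 0.05, masks, presc)
        x = np.array([presc[n] for n in sorted(masks)])
        y = x + 0.05
        slope_oracle = np.linalg.lstsq(x[:, None], y, rcond=None)[0][0]
        np.testing.assert_allclose(out, abs(slope_oracle - 1.0), atol=1e-12)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="two"):
            deviation_from_linear_slope(np.zeros((4, 4, 4)), {"a": np.ones((4, 4, 4), bool)}, {"a": 1.0})


class TestCalcMetrics:
    def _calc_setup(self, n=40, radius=3.0):
        x, y, z = np.meshgrid(*[np.arange(n) - n / 2 + 0.5] * 3, indexing="ij")
        r = np.sqrt(x * x + y * y + z * z)
        calc = r <= radius
        return calc

    def test_streak_identities(self):
        calc = self._calc_setup()
        rng = np.random.default_rng(2)
        truth = rng.normal(size=calc.shape)
        assert calc_streak(truth, truth, calc) == 0.0
        assert calc_streak(truth + 1.3, truth, calc) < 1e-12

    def test_streak_matches_enumerated_voxel_oracle(self):
        """Hollow-box SD agrees with a brute-force voxel enumeration."""
        calc = self._calc_setup()
        rng = np.random.default_rng(3)
        truth = rng.normal(size=calc.shape)
        recon = truth + rng.normal(scale=0.5, size=calc.shape)
        got = calc_streak(recon, truth, calc)
        # oracle: explicit loop over the shell between the two expanded boxes
        coords = np.argwhere(calc)
        lo, hi = coords.min(0), coords.max(0)
        vals = []
        n = calc.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    inside_outer = all(lo[a] - 8 <= (i, j, k)[a] <= hi[a] + 8 for a in range(3))
                    inside_inner = all(lo[a] - 2 <= (i, j, k)[a] <= hi[a] + 2 for a in range(3))
                    if inside_outer and not inside_inner:
                        vals.append(recon[i, j, k] - truth[i, j, k])
        np.testing.assert_allclose(got, np.std(vals), rtol=1e-12)

    def test_streak_requires_single_component(self):
        calc = self._calc_setup()
        calc[0, 0, 0] = True
        with pytest.raises(ValueError, match="connected"):
            calc_streak(np.zeros(calc.shape), np.zeros(calc.shape), calc)

    def test_moment_of_digitized_sphere(self):
        """Moment equals chi * voxel volume * voxel count exactly."""
        calc = self._calc_setup(radius=3.0)
        region = ndimage.binary_dilation(calc, iterations=2)
        chi = np.where(calc, -3.3, 0.0)
        got = calc_moment(chi, region, voxel_volume=1.0)
        np.testing.assert_allclose(got, -3.3 * calc.sum(), rtol=1e-12)
        # continuum value for a 3 mm sphere is -3.3 * (4/3) pi 27 = -373.2
        assert abs(got - (-373.2)) / 373.2 < 0.25  # digitization-level agreement

    def test_moment_invariant_to_redistribution(self):
        calc = self._calc_setup(radius=2.0)
        region = ndimage.binary_dilation(calc, iterations=2)
        rng = np.random.default_rng(4)
        chi = np.where(region, rng.normal(size=calc.shape), 0.0)
        shuffled = chi.copy()
        vals = shuffled[region]
        rng.shuffle(vals)
        shuffled[region] = vals
        np.testing.assert_allclose(
            calc_moment(chi, region), calc_moment(shuffled, region), rtol=1e-12
        )

    def test_zero_reconstruction_zero_moment(self):
        calc = self._calc_setup(radius=2.0)
        assert calc_moment(np.zeros(calc.shape), calc) == 0.0


def test_full_report_on_self_is_clean(head128, gt128, table1):
    """Scoring the ground truth against itself zeroes every error metric."""
    from qsmphantom.synth import LABELS

    model, params, rois = head128
    _, chi_l, _ = gt128
    presc = {n: float(table1.row(LABELS[n])["chi_mean"]) for n in rois["dgm_regions"]}
    masks = dict(rois)
    report = evaluate_all(chi_l.chi, chi_l.chi, masks, presc, voxel_volume=1.0)
    assert report.nrmse < 1e-9
    assert report.rmse_detrend_tissue < 1e-6
    assert report.calc_streak == 0.0
    assert report.calc_moment_deviation == 0.0
    assert report.calc_moment < -50.0  # strongly diamagnetic calcification
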