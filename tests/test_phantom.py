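"""Susceptibility composition: modulation law, partial voluming, blending."""

import numpy as np
import pytest
from scipy import ndimage

from qsmphantom.phantom import (
    FWHM_TO_SIGMA,
    ParameterMaps,
    SusceptibilityVolume,
    TissueParamTable,
    compose_chi,
    gradient_reliability_blend,
    localize_chi,
    partial_volume_maps,
    tissue_chi_map,
)


def _params(shape=(8, 8, 8), r1=0.9, r2s=38.0):
    return ParameterMaps(
        m0=np.ones(shape), r1=np.full(shape, r1), r2star=np.full(shape, r2s)
    )


class TestTissueChiMap:
    def test_globus_pallidus_at_reference_rates(self, table1):
        """At R2*=ref, R1=ref the map returns the mean susceptibility exactly."""
        p = _params(r1=0.9, r2s=70.0)
        lab = table1.label_of("globus_pallidus")
        chi = tissue_chi_map(p, table1, lab, (70.0, 0.9))
        assert np.all(chi == 0.131)

    def test_caudate_r2star_deviation_arithmetic(self, table1):
        """A unit R2* excess adds a_tissue ppm: 0.044 - 0.012 = 0.032."""
        p = _params(r1=0.9, r2s=36.0)
        lab = table1.label_of("caudate")
        chi = tissue_chi_map(p, table1, lab, (35.0, 0.9))
        np.testing.assert_allclose(chi, 0.032, atol=1e-12)

    def test_piecewise_constant_tissue_is_flat(self, table1):
        rng = np.random.default_rng(0)
        p = ParameterMaps(
            m0=np.ones((6, 6, 6)),
            r1=rng.uniform(0.1, 2, (6, 6, 6)),
            r2star=rng.uniform(5, 80, (6, 6, 6)),
        )
        chi = tissue_chi_map(p, table1, table1.label_of("bone"), (40.0, 1.0))
        assert np.all(chi == -2.1)

    def test_missing_label_reports_id(self, table1):
        with pytest.raises(KeyError, match="99"):
            tissue_chi_map(_params(), table1, 99, (0.0, 0.0))

    def test_modulation_is_linear_in_rate_deviation(self, table1):
        """Scaling the R2* deviation by k scales that term's contribution by k."""
        lab = table1.label_of("thalamus")
        base = tissue_chi_map(_params(r2s=40.0), table1, lab, (38.0, 0.9))
        scaled = tissue_chi_map(_params(r2s=44.0), table1, lab, (38.0, 0.9))
        chi0 = float(table1.row(lab)["chi_mean"])
        np.testing.assert_allclose(scaled - chi0, 3.0 * (base - chi0), rtol=1e-12)

    def test_deviation_clip_bounds_extrapolation(self, table1):
        lab = table1.label_of("gray_matter")
        chi = tissue_chi_map(_params(r2s=130.0), table1, lab, (30.0, 0.9), dev_clip=(5.0, 0.1))
        expected = 0.02 + (-0.095) * 5.0
        np.testing.assert_allclose(chi, expected, atol=1e-12)


class TestPartialVolume:
    def test_interior_probability_is_one(self):
        labels = np.zeros((16, 16, 16), dtype=int)
        labels[4:12, 4:12, 4:12] = 1
        labels[labels == 0] = 2
        probs = partial_volume_maps(labels, {1: True, 2: True})
        assert abs(probs[1][8, 8, 8] - 1.0) < 1e-3

    def test_half_space_interface_probability(self):
        """Two half-spaces meeting at a plane split 50/50 at the interface."""
        labels = np.ones((16, 16, 16), dtype=int)
        labels[8:] = 2
        probs = partial_volume_maps(labels, {1: True, 2: True})
        # the continuum plane lies between voxels 7 and 8
        centre = 0.5 * (probs[1][7, 8, 8] + probs[1][8, 8, 8])
        assert abs(centre - 0.5) < 1e-6
        np.testing.assert_allclose(probs[1][7, 8, 8], probs[2][8, 8, 8], atol=1e-9)

    def test_sums_to_one_and_matches_direct_convolution(self):
        """Gaussian smoothing agrees with an explicit spatial convolution."""
        rng = np.random.default_rng(3)
        labels = rng.integers(1, 4, size=(16, 16, 16))
        probs = partial_volume_maps(labels, {1: True, 2: True, 3: False})
        total = sum(probs.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

        # brute-force oracle: sampled Gaussian kernel, direct triple loop
        sigma = 1.2 * FWHM_TO_SIGMA
        rad = int(4.0 * sigma + 0.5)
        offs = np.arange(-rad, rad + 1)
        g1 = np.exp(-0.5 * (offs / sigma) ** 2)
        g1 /= g1.sum()
        mask = (labels == 1).astype(float)
        padded = np.pad(mask, rad)
        out = np.zeros_like(mask)
        for i, gi in zip(offs, g1):
            for j, gj in zip(offs, g1):
                for k, gk in zip(offs, g1):
                    out += (
                        gi * gj * gk
                        * padded[
                            rad + i : rad + i + 16,
                            rad + j : rad + j + 16,
                            rad + k : rad + k + 16,
                        ]
                    )
        smooth2 = ndimage.gaussian_filter(
            (labels == 2).astype(float), sigma, mode="constant", truncate=4.0
        )
        hard3 = (labels == 3).astype(float)
        expected = out / (out + smooth2 + hard3)
        np.testing.assert_allclose(probs[1], expected, atol=1e-6)

    def test_empty_mask_warns(self):
        labels = np.ones((4, 4, 4), dtype=int)
        with pytest.warns(UserWarning, match="all-zero"):
            probs = partial_volume_maps(labels, {1: True, 2: True})
        assert probs[2].max() == 0.0


class TestGradientBlend:
    def test_limits_and_midpoint(self):
        full = np.full((4, 4, 4), 1.0)
        noa = np.full((4, 4, 4), 3.0)
        grad = np.zeros((4, 4, 4))
        np.testing.assert_array_equal(gradient_reliability_blend(full, noa, grad), full)
        grad[:] = 0.5
        np.testing.assert_array_equal(gradient_reliability_blend(full, noa, grad), noa)
        grad[:] = 0.5 * (0.08 + 0.3)
        np.testing.assert_allclose(gradient_reliability_blend(full, noa, grad), 2.0)

    def test_inverted_thresholds_rejected(self):
        z = np.zeros((2, 2, 2))
        with pytest.raises(ValueError, match="g_lo"):
            gradient_reliability_blend(z, z, z, g_lo=0.3, g_hi=0.08)


class TestCompose:
    def test_single_tissue_identity(self):
        chi_t = np.random.default_rng(0).normal(size=(6, 6, 6))
        p = {1: np.ones((6, 6, 6))}
        out = compose_chi({1: chi_t}, p, np.ones((6, 6, 6), bool))
        np.testing.assert_array_equal(out.chi, chi_t)

    def test_two_tissue_weighting(self):
        shape = (4, 4, 4)
        probs = {1: np.full(shape, 0.25), 2: np.full(shape, 0.75)}
        out = compose_chi({1: 0.0, 2: 0.1}, probs, np.ones(shape, bool))
        np.testing.assert_allclose(out.chi, 0.075, atol=1e-12)

    def test_shape_mismatch_fails(self):
        with pytest.raises(ValueError, match="shape"):
            compose_chi({1: 0.0}, {1: np.ones((4, 4, 4))}, np.ones((5, 5, 5), bool))

    def test_uncovered_voxels_get_air(self):
        shape = (4, 4, 4)
        p = np.zeros(shape)
        p[0, 0, 0] = 1.0
        out = compose_chi({1: 0.1}, {1: p}, np.ones(shape, bool))
        assert out.chi[1, 1, 1] == 9.2

    def test_piecewise_constant_limit_is_label_lookup(self, table1):
        """Binary probabilities + a=b=0 reproduce a label-lookup map exactly."""
        rng = np.random.default_rng(5)
        labels = rng.integers(12, 16, size=(10, 10, 10))  # piecewise tissues
        flags = {lab: False for lab in np.unique(labels)}
        flags[12] = True  # keep at least one "brain" flag for the API
        probs = {
            lab: (labels == lab).astype(float) for lab in np.unique(labels)
        }
        per_tissue = {
            lab: float(table1.row(lab)["chi_mean"]) for lab in np.unique(labels)
        }
        out = compose_chi(per_tissue, probs, np.ones(labels.shape, bool))
        lookup = np.vectorize(lambda l: per_tissue[l])(labels)
        np.testing.assert_array_equal(out.chi, lookup)


class TestLocalize:
    def test_constant_inside_mask_vanishes(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        vol = SusceptibilityVolume(np.full((8, 8, 8), 3.7), "whole_head", mask)
        out = localize_chi(vol, mask)
        np.testing.assert_allclose(out.chi, 0.0, atol=1e-12)

    def test_zero_mean_and_idempotent(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((8, 8, 8), bool)
        mask[1:7, 1:7, 1:7] = True
        vol = SusceptibilityVolume(rng.normal(size=(8, 8, 8)), "whole_head", mask)
        out = localize_chi(vol, mask)
        assert abs(out.chi[mask].mean()) < 1e-9
        assert np.all(out.chi[~mask] == 0.0)
        out2 = localize_chi(out, mask)
        np.testing.assert_allclose(out2.chi, out.chi, atol=1e-15)

    def test_empty_mask_fails(self):
        vol = SusceptibilityVolume(np.zeros((4, 4, 4)), "whole_head", np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="empty"):
            localize_chi(vol, np.zeros((4, 4, 4), bool))


def test_shipped_tables_have_paper_extremes(table1):
    """Air and bone rows carry the fixed literature susceptibilities."""
    assert float(table1.row(table1.label_of("air"))["chi_mean"]) == 9.2
    assert float(table1.row(table1.label_of("bone"))["chi_mean"]) == -2.1
    model2 = TissueParamTable.model2()
    assert float(model2.row(model2.label_of("white_matter"))["chi_mean"]) == 0.005
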