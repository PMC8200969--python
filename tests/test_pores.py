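"""Pore pipeline tests, including the independent shape-score oracle."""

import math

import numpy as np
import pytest
from conftest import as_calibrated
from scipy.stats import spearmanr

from dermaflux.core_io import ROI
from dermaflux.pores import (
    PoreParams,
    binarize,
    detect_pores,
    enhance_edges,
    luminance,
    pore_area,
)
from dermaflux.synthetic import PatchParams, generate_patch

# ---------------------------------------------------------------------------
# Independent perimeter/circularity oracle: a from-scratch reimplementation
# of the weighted border-pixel estimator, computed with python sets (no
# ndimage machinery shared with the implementation under test).
# ---------------------------------------------------------------------------

_W = {
    5: 1.0,
    7: 1.0,
    15: 1.0,
    17: 1.0,
    25: 1.0,
    27: 1.0,
    21: math.sqrt(2),
    33: math.sqrt(2),
    13: (1 + math.sqrt(2)) / 2,
    23: (1 + math.sqrt(2)) / 2,
}


def oracle_perimeter(pixels: set[tuple[int, int]]) -> float:
    border = {
        (r, c)
        for (r, c) in pixels
        if not all(p in pixels for p in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)))
    }
    total = 0.0
    for r, c in border:
        n4 = sum(p in border for p in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)))
        nd = sum(
            p in border
            for p in ((r - 1, c - 1), (r - 1, c + 1), (r + 1, c - 1), (r + 1, c + 1))
        )
        total += _W.get(1 + 2 * n4 + 10 * nd, 0.0)
    return total


def oracle_circularity(pixels: set[tuple[int, int]]) -> float:
    p = oracle_perimeter(pixels)
    return min(1.0, 4 * math.pi * len(pixels) / p**2)


def disk_mask(radius, shape=(64, 64), center=(32, 32)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestEnhanceEdges:
    def test_constant_raster_zero_response(self):
        resp = enhance_edges(np.full((64, 64), 0.37))
        np.testing.assert_allclose(resp, 0.0, atol=1e-12)

    def test_dark_disk_peak_at_center(self):
        # disk radius ~ sigma_small * sqrt(2); response maximal at the center
        lum = np.full((96, 96), 0.6)
        lum[disk_mask(2.1, (96, 96), (48, 48))] = 0.4
        resp = enhance_edges(lum)
        assert np.unravel_index(np.argmax(resp), resp.shape) == (48, 48)
        assert resp[48, 48] > 0

    def test_center_response_grows_then_decays_over_radius_grid(self):
        # numeric evaluation of the DoG radial response over a radius grid
        centers = []
        for r in [1, 2, 3, 4, 6, 10, 16, 24]:
            lum = np.full((192, 192), 0.6)
            lum[disk_mask(r, (192, 192), (96, 96))] = 0.4
            centers.append(enhance_edges(lum)[96, 96])
        peak = int(np.argmax(centers))
        assert 0 < peak < len(centers) - 1  # interior maximum: band-pass in size

    def test_dc_offset_invariance(self):
        rng = np.random.default_rng(0)
        lum = rng.uniform(0.2, 0.6, (64, 64))
        np.testing.assert_allclose(
            enhance_edges(lum), enhance_edges(np.clip(lum + 0.3, 0, 1)), atol=1e-10
        )

    def test_too_small_raster(self):
        with pytest.raises(ValueError, match="sigma_large"):
            enhance_edges(np.zeros((20, 20)))


class TestBinarize:
    def test_all_zero_response_empty_mask(self):
        assert not binarize(np.zeros((32, 32))).any()

    def test_single_extreme_blob_isolated(self):
        rng = np.random.default_rng(3)
        resp = rng.uniform(-0.01, 0.01, (64, 64))
        blob = disk_mask(3)
        resp[blob] = 1.0
        mask = binarize(resp, k=3.0)
        np.testing.assert_array_equal(mask, blob)

    def test_k_infinity_empty(self):
        rng = np.random.default_rng(4)
        resp = rng.normal(0, 1, (64, 64))
        assert not binarize(resp, k=1e12).any()


class TestDetectPores:
    def test_empty_mask_empty_list(self):
        assert detect_pores(np.zeros((64, 64), bool), np.full((64, 64), 0.5)) == []

    def test_disk_accepted_with_high_circularity(self):
        mask = disk_mask(6)
        lum = np.full((64, 64), 0.5)
        lum[mask] = 0.4
        cands = detect_pores(mask, lum)
        assert len(cands) == 1
        assert cands[0].circularity >= 0.85
        assert cands[0].area_px == int(mask.sum())

    def test_rectangle_rejected_by_circularity(self):
        mask = np.zeros((64, 64), bool)
        mask[17:47, 30:34] = True  # 30x4, axis ratio 7.5
        pixels = {(r, c) for r, c in zip(*np.nonzero(mask))}
        assert oracle_circularity(pixels) < 0.6  # oracle agrees it must fail
        lum = np.full((64, 64), 0.5)
        lum[mask] = 0.3
        assert detect_pores(mask, lum, PoreParams(circularity_min=0.6)) == []

    def test_circularity_matches_oracle(self):
        rng = np.random.default_rng(11)
        mask = np.zeros((128, 128), bool)
        for _ in range(6):
            r = rng.integers(3, 8)
            cy, cx = rng.integers(15, 113, 2)
            mask |= disk_mask(r, (128, 128), (cy, cx))
        lum = np.where(mask, 0.3, 0.6)
        cands = detect_pores(mask, lum, PoreParams(circularity_min=0.01, min_contrast=0.0))
        assert cands
        from skimage.measure import label as cc_label

        labels = cc_label(mask, connectivity=2)
        comps = {}
        for r, c in zip(*np.nonzero(labels)):
            comps.setdefault(labels[r, c], set()).add((int(r), int(c)))
        by_area = {len(v): v for v in comps.values()}
        for cand in cands:
            pixels = by_area[cand.area_px]
            assert cand.circularity == pytest.approx(oracle_circularity(pixels), abs=1e-9)
            assert cand.perimeter_px == pytest.approx(oracle_perimeter(pixels), abs=1e-9)

    def test_border_touching_discarded(self):
        mask = disk_mask(6, center=(3, 32))  # clipped by the top edge
        lum = np.where(mask, 0.3, 0.6)
        assert detect_pores(mask, lum, PoreParams(circularity_min=0.01)) == []

    def test_contrast_gate(self):
        mask = disk_mask(6)
        lum = np.full((64, 64), 0.5)
        lum[mask] = 0.495  # contrast ~ 0.005 < default 0.02
        assert detect_pores(mask, lum) == []

    def test_sorted_by_area_desc(self):
        mask = disk_mask(4, (128, 128), (30, 30)) | disk_mask(7, (128, 128), (90, 90))
        lum = np.where(mask, 0.3, 0.6)
        cands = detect_pores(mask, lum)
        areas = [c.area_px for c in cands]
        assert areas == sorted(areas, reverse=True)


class TestPoreArea:
    ROI_FULL = ROI(0, 512, 0, 512, label="cheek")

    def _patch(self, **kw):
        img, truth = generate_patch(PatchParams(**kw))
        return as_calibrated(img), truth

    def test_pore_free_patch_zero(self):
        img, _ = self._patch(n_pores=0, illum_gradient=0.05, seed=1)
        assert pore_area(img, self.ROI_FULL).total_area_au == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_disk_recovery_within_5pct(self, seed):
        # full 10-seed sweep lives in the acceptance suite
        img, _ = self._patch(
            n_pores=25, pore_radius_mean=5, pore_contrast=0.15, texture_rms=0.02, seed=seed
        )
        res = pore_area(img, self.ROI_FULL)
        expected = 1000 * 25 * np.pi * 25 / 512**2
        assert res.total_area_au == pytest.approx(expected, rel=0.05)

    def test_low_contrast_disks_gated_to_zero(self):
        img, _ = self._patch(n_pores=25, pore_radius_mean=5, pore_contrast=0.03, seed=2)
        assert pore_area(img, self.ROI_FULL).total_area_au == 0.0

    def test_requires_calibrated(self):
        img, _ = generate_patch(PatchParams(seed=0))
        with pytest.raises(ValueError, match="calibrated"):
            pore_area(img, self.ROI_FULL)

    def test_requires_cheek_label(self):
        img, _ = self._patch(seed=0)
        with pytest.raises(ValueError, match="cheek"):
            pore_area(img, ROI(0, 512, 0, 512, label="eye_to_cheek"))

    def test_total_area_matches_candidate_sum(self):
        img, _ = self._patch(
            n_pores=25, pore_radius_mean=5, pore_contrast=0.15, texture_rms=0.02, seed=4
        )
        res = pore_area(img, self.ROI_FULL)
        assert res.total_area_au == pytest.approx(
            1000 * sum(c.area_px for c in res.candidates) / res.roi_area_px
        )

    def test_radius_monotonicity_spearman_one(self):
        radii = [3, 4, 5, 6, 7, 8, 9]
        means = []
        for r in radii:
            vals = [
                pore_area(
                    self._patch(
                        n_pores=12,
                        pore_radius_mean=r,
                        pore_contrast=0.15,
                        texture_rms=0.02,
                        seed=seed,
                    )[0],
                    self.ROI_FULL,
                ).total_area_au
                for seed in range(4)
            ]
            means.append(np.mean(vals))
        rho, _ = spearmanr(radii, means)
        assert rho == pytest.approx(1.0)

    def test_border_disks_contribute_zero(self):
        # clean patch (no texture -> no false positives); ROI cuts the disk
        img, truth = self._patch(n_pores=1, pore_radius_mean=8, pore_contrast=0.2, seed=9)
        row, col, r = truth.pores[0]
        # ROI whose edge crosses the disk -> candidate touches border -> dropped
        r0 = int(row) - 2
        roi = ROI(max(0, r0), min(512, r0 + 300), 0, 512, label="cheek")
        res = pore_area(img, roi)
        assert res.total_area_au == 0.0


class TestLuminance:
    def test_rec709_weights(self):
        px = np.zeros((2, 2, 3))
        px[0, 0] = (1.0, 0.0, 0.0)
        px[0, 1] = (0.0, 1.0, 0.0)
        px[1, 0] = (0.0, 0.0, 1.0)
        lum = luminance(px)
        assert lum[0, 0] == pytest.approx(0.2126)
        assert lum[0, 1] == pytest.approx(0.7152)
        assert lum[1, 0] == pytest.approx(0.0722)
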