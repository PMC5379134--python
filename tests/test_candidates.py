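"""Multiscale correlation filtering, region growing, vessel/size filtering."""

import numpy as np
import pytest

import madetect as md
from madetect.candidates import (
    CandidateRegion,
    adaptive_threshold,
    correlation_map,
    extract_candidates,
    filter_by_size,
    gaussian_template,
    multiscale_max,
    region_grow,
    threshold_candidates,
    vessel_mask,
)
from madetect.errors import ShapeError

from conftest import implant_gaussian


def brute_force_pearson(values, sigma, invert=True):
    """Literal per-pixel Pearson correlation with the Gaussian template."""
    tmpl = gaussian_template(sigma)
    h = tmpl.shape[0] // 2
    y = 1.0 - values if invert else values
    pad = np.pad(y, h, mode="symmetric")
    xc = tmpl - tmpl.mean()
    sxx = (xc ** 2).sum()
    out = np.zeros_like(values, dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            win = pad[i:i + 2 * h + 1, j:j + 2 * h + 1]
            yc = win - win.mean()
            den = np.sqrt(sxx * (yc ** 2).sum())
            out[i, j] = 0.0 if den <= 1e-12 else (xc * yc).sum() / den
    return np.clip(out, 0.0, 1.0)


class TestCorrelationMap:
    def test_affine_copy_of_template_scores_one(self):
        tmpl = gaussian_template(1.2)
        size = 41
        vals = np.full((size, size), 0.8)
        h = tmpl.shape[0] // 2
        c = size // 2
        # dark blob: inverted window is an affine copy a*G+b with a>0
        vals[c - h:c + h + 1, c - h:c + h + 1] -= 0.3 * tmpl
        r = correlation_map(vals, 1.2)
        assert r[c, c] == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_maps_to_zero(self):
        r = correlation_map(np.full((16, 16), 0.5), 1.1)
        np.testing.assert_array_equal(r, 0.0)

    @pytest.mark.parametrize("sigma", [1.1, 1.3, 1.5])
    def test_matches_brute_force_oracle(self, sigma, rng):
        img = rng.random((32, 32))
        fast = correlation_map(img, sigma)
        slow = brute_force_pearson(img, sigma)
        assert np.max(np.abs(fast - slow)) < 1e-10

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ShapeError):
            correlation_map(np.zeros((5, 5)), 1.5)

    def test_bright_blob_suppressed_by_polarity(self):
        vals = np.full((41, 41), 0.4)
        tmpl = gaussian_template(1.3)
        h = tmpl.shape[0] // 2
        vals[20 - h:20 + h + 1, 20 - h:20 + h + 1] += 0.3 * tmpl
        assert correlation_map(vals, 1.3)[20, 20] == 0.0


class TestMultiscale:
    def test_zero_maps_stay_zero(self):
        assert np.all(multiscale_max([np.zeros((4, 4))] * 5) == 0.0)

    def test_pixelwise_maximum(self):
        maps = [np.full((1, 1), v) for v in (0.2, 0.5, 0.4, 0.1, 0.3)]
        assert multiscale_max(maps)[0, 0] == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            multiscale_max([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_max_dominates_each_single_scale(self, rng):
        maps = [rng.random((16, 16)) for _ in range(5)]
        final = multiscale_max(maps)
        for m in maps:
            assert np.all(final >= m)

    def test_matched_scale_wins_at_blob_center(self):
        size, sigma_true = 64, 1.3
        vals = np.full((size, size), 0.7)
        implant_gaussian(vals, (32, 32), sigma_true, 0.3)
        center_scores = {s: correlation_map(vals, s)[32, 32]
                         for s in (1.1, 1.2, 1.3, 1.4, 1.5)}
        assert center_scores[1.3] >= max(
            v for s, v in center_scores.items() if s != 1.3) - 1e-12


class TestVesselMask:
    def _curve_and_blob(self):
        vals = np.full((128, 128), 0.6)
        rr = np.arange(10, 118)
        cc = (64 + 20 * np.sin(rr / 18)).astype(int)
        for r, c in zip(rr, cc):        # long dark curve, ~3 px wide
            vals[r, c - 1:c + 2] -= 0.25
        implant_gaussian(vals, (30, 20), 1.3, 0.3)   # small dark MA-like blob
        return md.GrayImage(values=vals), rr, cc

    def test_curve_kept_blob_removed(self):
        gray, rr, cc = self._curve_and_blob()
        mask = vessel_mask(gray)
        on_curve = mask[rr[len(rr) // 2], cc[len(cc) // 2]]
        assert on_curve
        assert not mask[30, 20]

    def test_vessel_free_image_nearly_empty(self, rng):
        vals = 0.6 + 0.01 * rng.standard_normal((128, 128))
        for center in [(30, 40), (90, 80)]:
            implant_gaussian(vals, center, 1.2, 0.25)
        mask = vessel_mask(md.GrayImage(values=vals))
        assert mask.mean() < 0.01

    def test_supplied_mask_passes_through(self, rng):
        gray = md.GrayImage(values=rng.random((64, 64)))
        supplied = np.zeros((64, 64), bool)
        out = vessel_mask(gray, supplied=supplied)
        assert out is not supplied or np.array_equal(out, supplied)
        assert not out.any()

    def test_supplied_mask_shape_checked(self, rng):
        gray = md.GrayImage(values=rng.random((64, 64)))
        with pytest.raises(ShapeError):
            vessel_mask(gray, supplied=np.zeros((32, 32), bool))


class TestThresholdCandidates:
    def test_inclusive_boundary(self):
        resp = np.zeros((8, 8))
        resp[1, 1], resp[3, 3], resp[5, 5] = 0.59, 0.60, 0.61
        comps = threshold_candidates(resp, 0.6)
        kept = {tuple(c[0]) for c in comps}
        assert kept == {(3, 3), (5, 5)}

    def test_blob_on_vessel_removed(self):
        resp = np.zeros((16, 16))
        resp[4:7, 4:7] = 0.9
        vessels = np.zeros((16, 16), bool)
        vessels[3:8, 3:8] = True
        assert threshold_candidates(resp, 0.6, vessels=vessels) == []

    def test_two_separate_blobs_two_components(self):
        resp = np.zeros((64, 64))
        resp[10:13, 10:13] = 0.8
        resp[10:13, 33:36] = 0.8     # 20 px away
        comps = threshold_candidates(resp, 0.6)
        assert len(comps) == 2

    def test_monotone_in_threshold(self, rng):
        # blob-like response map (the MSCF regime): isolated unimodal peaks
        resp = np.zeros((128, 128))
        for _ in range(12):
            r, c = rng.integers(10, 118, 2)
            peak = rng.uniform(0.3, 1.0)
            yy, xx = np.mgrid[0:128, 0:128].astype(float)
            resp = np.maximum(
                resp, peak * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / 8.0))
        counts = [len(threshold_candidates(resp, t))
                  for t in (0.3, 0.5, 0.7, 0.9)]
        # raising the threshold never increases the seed-region count
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # and retained pixel sets shrink monotonically in any regime
        noisy = rng.random((64, 64))
        masks = [noisy >= t for t in (0.3, 0.5, 0.7, 0.9)]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(lo[hi])


class TestAdaptiveThreshold:
    def test_direct_substitution(self):
        # I_darkest=0.2 at the component; background window mean 0.6
        vals = np.full((64, 64), 0.6)
        vals[32, 32] = 0.2
        cfg = md.PipelineConfig(beta=0.5, bg_mean_window=25, seed_dilation=0)
        t, seed = adaptive_threshold(vals, np.array([[32, 32]]), cfg)
        assert seed == (32, 32)
        i_bg = vals[20:45, 20:45].mean()
        assert t == pytest.approx(0.2 - 0.5 * (0.2 - i_bg))

    @pytest.mark.parametrize("beta,expected", [(0.0, "darkest"), (1.0, "bg")])
    def test_limit_cases(self, beta, expected):
        vals = np.full((64, 64), 0.6)
        vals[32, 32] = 0.2
        cfg = md.PipelineConfig(beta=beta, seed_dilation=0)
        t, seed = adaptive_threshold(vals, np.array([[32, 32]]), cfg)
        if expected == "darkest":
            assert t == pytest.approx(0.2)
        else:
            assert t == pytest.approx(vals[20:45, 20:45].mean())

    def test_seed_is_darkest_in_dilated_locality(self):
        vals = np.full((64, 64), 0.6)
        vals[30, 30] = 0.3
        vals[31, 31] = 0.1           # darkest just outside the raw component
        cfg = md.PipelineConfig(seed_dilation=2)
        _, seed = adaptive_threshold(vals, np.array([[30, 30]]), cfg)
        assert seed == (31, 31)


def oracle_flood_fill(values, seed, t):
    """Independent stack-based 8-connected flood fill of pixels <= t."""
    if values[seed] > t:
        return set()
    seen = {seed}
    stack = [seed]
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                q = (r + dr, c + dc)
                if (q not in seen and 0 <= q[0] < values.shape[0]
                        and 0 <= q[1] < values.shape[1] and values[q] <= t):
                    seen.add(q)
                    stack.append(q)
    return seen


class TestRegionGrow:
    def test_dark_disk_grown_exactly(self):
        vals = np.full((64, 64), 0.8)
        yy, xx = np.mgrid[0:64, 0:64]
        disk = np.hypot(yy - 30, xx - 30) <= 3.3    # 37 pixels
        vals[disk] = 0.1
        assert disk.sum() == 37
        region = region_grow(vals, (30, 30), t=0.4)
        assert region.area == 37
        assert set(map(tuple, region.pixels)) == set(map(tuple, np.argwhere(disk)))

    def test_isolated_seed_gives_singleton(self):
        vals = np.full((32, 32), 0.9)
        vals[16, 16] = 0.1
        region = region_grow(vals, (16, 16), t=0.4)
        assert region.area == 1 and region.seed == (16, 16)

    def test_bridge_joins_two_disks(self):
        vals = np.full((64, 64), 0.8)
        yy, xx = np.mgrid[0:64, 0:64]
        d1 = np.hypot(yy - 30, xx - 20) <= 3
        d2 = np.hypot(yy - 30, xx - 40) <= 3
        vals[d1 | d2] = 0.1
        vals[30, 20:41] = 0.1                      # 1-px bridge
        region = region_grow(vals, (30, 20), t=0.4)
        expected = oracle_flood_fill(vals, (30, 20), 0.4)
        assert set(map(tuple, region.pixels)) == expected

    def test_seed_above_threshold_signals_empty(self):
        vals = np.full((32, 32), 0.9)
        assert region_grow(vals, (16, 16), t=0.4) is None

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_flood_fill_oracle_on_random_blobs(self, trial):
        rng = np.random.default_rng(500 + trial)
        vals = 0.7 + 0.05 * rng.standard_normal((48, 48))
        n_blobs = rng.integers(1, 4)
        centers = rng.integers(10, 38, size=(n_blobs, 2))
        for r, c in centers:
            implant_gaussian(vals, (int(r), int(c)), rng.uniform(1.0, 2.5),
                             rng.uniform(0.3, 0.5))
        seed = tuple(int(v) for v in centers[0])
        t = float(vals[seed] + 0.15)
        region = region_grow(vals, seed, t)
        expected = oracle_flood_fill(vals, seed, t)
        assert set(map(tuple, region.pixels)) == expected


class TestSizeFilter:
    @staticmethod
    def _region(area):
        pixels = np.argwhere(np.ones((area, 1), bool))
        return CandidateRegion(pixels=pixels, seed=(0, 0), area=area)

    def test_area_121_discarded_120_kept(self):
        regions = [self._region(120), self._region(121)]
        kept = filter_by_size(regions, max_area=120)
        assert [r.area for r in kept] == [120]

    def test_empty_input(self):
        assert filter_by_size([], 120) == []

    def test_oversized_flag_discards(self):
        r = self._region(5)
        r.oversized = True
        assert filter_by_size([r], 120) == []


class TestEndToEnd:
    def test_implanted_blobs_recovered(self):
        size = 256
        rng = np.random.default_rng(9)
        vals = 0.55 + 0.02 * np.sin(np.linspace(0, 4, size))[None, :]
        vals = np.broadcast_to(vals, (size, size)).copy()
        vals += 0.005 * rng.standard_normal((size, size))
        centers = [(60, 60), (60, 190), (190, 60), (190, 190), (128, 128)]
        for ctr in centers:
            implant_gaussian(vals, ctr, 1.3, 0.25)
        fov = np.ones((size, size), bool)
        image = md.GrayImage(values=np.clip(vals, 0, 1), fov=fov)
        regions, _ = extract_candidates(image, md.PipelineConfig())
        found = np.array([r.centroid for r in regions])
        for r, c in centers:
            assert np.min(np.hypot(found[:, 0] - r, found[:, 1] - c)) <= 3
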