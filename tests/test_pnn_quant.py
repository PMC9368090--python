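"""WFA+ cell detection, PL classification and fold-change statistics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from coronalstack import (
    PnnQuant,
    PnnSliceRecord,
    RoiSpec,
    classify_pl_regions,
    detect_wfa_cells,
    fold_change_analysis,
    make_dapi_mask,
    outer_contour,
    pair_threshold,
    quantify_slice,
)
from coronalstack.synthdata import ROI_IBA1_NEG, ROI_IBA1_POS, SynthParams, simulate_roi_patches


def disc_image(discs, shape=(120, 120), value=200.0, background=10.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (r, c, rad) in discs:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = value
    return img


class TestDetectWfaCells:
    def test_blank_roi_counts_zero(self):
        _, n, vals = detect_wfa_cells(np.zeros((50, 50)), (0, 0, 50, 50), threshold=10)
        assert n == 0 and vals == []

    def test_min_size_filter_on_enumerated_discs(self):
        # radii 7, 9, 11 px -> ~149, 253, 377 px: only the last two pass 200
        img = disc_image([(20, 20, 7), (60, 60, 9), (95, 30, 11)])
        masks, n, vals = detect_wfa_cells(img, (0, 0, 120, 120), threshold=100,
                                          min_size_px=200)
        assert n == 2
        assert all(v == pytest.approx(200.0) for v in vals)

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError, match="roi"):
            detect_wfa_cells(np.zeros((10, 10)), (0, 0, 20, 20), threshold=1)

    def test_counts_within_poisson_band_of_density(self):
        """Total detected count over 50 simulated ROI fields falls inside
        the central 95% band of the Poisson law implied by the density."""
        params = SynthParams(
            microns_per_pixel=4.0, wfa_density_per_mm2=8.0, wfa_retention_iba1pos=1.0
        )
        rng = np.random.default_rng(42)
        total, lam_total = 0, 0.0
        pad_area_rect = None
        for _ in range(50):
            patches = simulate_roi_patches(params, rng, "iba1_neg")
            r0, c0, r1, c1 = patches["roi_px"]
            thr = pair_threshold(patches["contra"], (r0, c0, r1, c1))
            _, n, _ = detect_wfa_cells(patches["ipsi"], (r0, c0, r1, c1), thr,
                                       min_size_px=50)
            total += n
            lam_total += params.wfa_density_per_mm2 * ROI_IBA1_NEG.area_mm2
        band = stats.poisson.interval(0.95, lam_total)
        assert band[0] <= total <= band[1]


class TestClassifyPlRegions:
    def _slice(self, pnn_brain, lesioned=True):
        params, stacks, gt = pnn_brain
        ids = stacks["DAPI"].slice_ids
        for img, iba, sid in zip(stacks["DAPI"].slices, stacks["Iba1"].slices, ids):
            if (gt.true_lesion_area_mm2[sid] > 0) == lesioned:
                return params, img, iba, sid, gt

    def test_empty_iba1_mask_gives_whole_band_negative(self, pnn_brain):
        params, img, _, sid, _ = self._slice(pnn_brain)
        cal = params.calibration
        m = make_dapi_mask(img, sid)
        c = outer_contour(m, cal)
        pos, neg = classify_pl_regions(np.zeros_like(m.binary), m, c, cal)
        assert pos.sum() == 0
        assert neg.sum() > 0

    def test_full_iba1_mask_gives_whole_band_positive(self, pnn_brain):
        params, img, _, sid, _ = self._slice(pnn_brain)
        cal = params.calibration
        m = make_dapi_mask(img, sid)
        c = outer_contour(m, cal)
        pos, neg = classify_pl_regions(np.ones_like(m.binary), m, c, cal)
        assert neg.sum() == 0
        assert pos.sum() > 0

    def test_intact_slice_warns_and_returns_empty(self, small_brain):
        params, stacks, gt = small_brain
        cal = params.calibration
        sid = gt.true_order[0]
        idx = stacks["DAPI"].slice_ids.index(sid)
        m = make_dapi_mask(stacks["DAPI"].slices[idx], sid)
        c = outer_contour(m, cal)
        with pytest.warns(UserWarning, match="no lesion"):
            pos, neg = classify_pl_regions(np.zeros_like(m.binary), m, c, cal)
        assert pos.sum() == 0 and neg.sum() == 0

    def test_halo_band_intersection_within_ten_percent(self, pnn_brain):
        """The Iba1+ PL recovered from the images matches the analytic
        halo-and-band intersection area."""
        import math

        from skimage import filters as skf

        from coronalstack.stereology import contralateral_threshold

        params, img, iba, sid, gt = self._slice(pnn_brain)
        cal = params.calibration
        m = make_dapi_mask(img, sid)
        c = outer_contour(m, cal)
        blurred = skf.gaussian(iba.astype(float), 5, preserve_range=True)
        iba1_mask = blurred >= contralateral_threshold(blurred)
        band_mm = 0.5
        pos, neg = classify_pl_regions(iba1_mask, m, c, cal, band_width_mm=band_mm)
        r = params.lesion_radius_mm
        w = min(params.iba1_halo_width_mm, band_mm)
        expected = 0.5 * math.pi * ((r + w) ** 2 - r**2)  # ventral half-annulus
        assert pos.sum() * cal.mm2_per_px == pytest.approx(expected, rel=0.10)


class TestFoldChangeAnalysis:
    def rec(self, sid, cls, ni, nc):
        return PnnSliceRecord(sid, cls, ni, nc, 100.0, 100.0)

    def test_identical_counts_give_unit_folds_and_degenerate_t(self):
        q = PnnQuant(
            [self.rec(s, c, 10, 10) for s in "abc" for c in ("iba1_pos", "iba1_neg")]
        )
        with pytest.warns(UserWarning, match="zero variance"):
            s = fold_change_analysis(q)
        assert s.mean_fold == {"iba1_pos": 1.0, "iba1_neg": 1.0}
        assert np.isnan(s.t_statistic)

    def test_hand_checkable_constant_folds(self):
        q = PnnQuant(
            [self.rec(s, "iba1_pos", 2, 10) for s in "abc"]
            + [self.rec(s, "iba1_neg", 10, 10) for s in "abc"]
        )
        with pytest.warns(UserWarning, match="zero variance"):
            s = fold_change_analysis(q)
        assert s.mean_fold["iba1_pos"] == pytest.approx(0.2)
        assert s.mean_fold["iba1_neg"] == pytest.approx(1.0)

    def test_zero_contralateral_slice_excluded_with_warning(self):
        q = PnnQuant(
            [self.rec(s, "iba1_pos", 3, 9) for s in "abc"]
            + [self.rec(s, "iba1_neg", 8, 9) for s in "ab"]
            + [self.rec("c", "iba1_neg", 8, 0)]
        )
        with pytest.warns(UserWarning, match="excluded"):
            s = fold_change_analysis(q)
        assert s.n_pairs == 2

    def test_single_class_rejected(self):
        q = PnnQuant([self.rec(s, "iba1_pos", 3, 9) for s in "abc"])
        with pytest.raises(ValueError, match="2 region classes"):
            fold_change_analysis(q)

    def test_paired_t_matches_scipy_on_noisy_folds(self, rng):
        folds_pos = rng.uniform(0.1, 0.4, 8)
        folds_neg = rng.uniform(0.8, 1.2, 8)
        q = PnnQuant()
        for i, (fp, fn) in enumerate(zip(folds_pos, folds_neg)):
            q.records.append(self.rec(f"s{i}", "iba1_pos", int(fp * 100), 100))
            q.records.append(self.rec(f"s{i}", "iba1_neg", int(fn * 100), 100))
        s = fold_change_analysis(q)
        x = np.array([r.fold_change_count for r in q.records if r.region_class == "iba1_neg"])
        y = np.array([r.fold_change_count for r in q.records if r.region_class == "iba1_pos"])
        t_ref, p_ref = stats.ttest_rel(y, x)
        assert s.t_statistic == pytest.approx(t_ref)
        assert s.p_value == pytest.approx(p_ref)


def _patch_brain_folds(params, rng, n_slices=12):
    """Fold changes of one simulated brain from rendered ROI patches."""
    q = PnnQuant()
    for s in range(n_slices):
        for cls in ("iba1_pos", "iba1_neg"):
            patches = simulate_roi_patches(params, rng, cls)
            r0, c0, r1, c1 = patches["roi_px"]
            rect = (int(r0), int(c0), int(r1), int(c1))
            thr = pair_threshold(patches["contra"], rect)
            _, ni, _ = detect_wfa_cells(patches["ipsi"], rect, thr, min_size_px=50)
            _, nc, _ = detect_wfa_cells(patches["contra"], rect, thr, min_size_px=50)
            q.records.append(PnnSliceRecord(f"s{s}", cls, ni, nc, 1.0, 1.0))
    return fold_change_analysis(q)


def test_recovered_reduction_monotone_in_generated_retention():
    """Mean recovered Iba1+ fold change increases with the generated
    retention fraction over {0.2, 0.5, 0.8}."""
    rng = np.random.default_rng(7)
    means = []
    for retention in (0.2, 0.5, 0.8):
        params = SynthParams(microns_per_pixel=4.0, wfa_retention_iba1pos=retention)
        folds = [
            _patch_brain_folds(params, rng, n_slices=8).mean_fold["iba1_pos"]
            for _ in range(4)
        ]
        means.append(np.mean(folds))
    assert means[0] < means[1] < means[2]


def test_counts_invariant_under_global_intensity_scaling(rng):
    """With the threshold re-derived from the contralateral ROI, a global
    intensity rescale leaves all counts unchanged."""
    params = SynthParams(microns_per_pixel=4.0)
    patches = simulate_roi_patches(params, rng, "iba1_neg")
    r0, c0, r1, c1 = (int(v) for v in patches["roi_px"])
    rect = (r0, c0, r1, c1)
    counts = {}
    for k in (1.0, 2.5):
        ipsi = patches["ipsi"].astype(np.float64) * k
        contra = patches["contra"].astype(np.float64) * k
        thr = pair_threshold(contra, rect)
        _, ni, _ = detect_wfa_cells(ipsi, rect, thr, min_size_px=50)
        _, nc, _ = detect_wfa_cells(contra, rect, thr, min_size_px=50)
        counts[k] = (ni, nc)
    assert counts[1.0] == counts[2.5]


def test_quantify_slice_on_rendered_brain(pnn_brain):
    """End-to-end per-slice quantification with generator ROIs shows the
    suppressed Iba1+ region and the preserved Iba1- region."""
    params, stacks, gt = pnn_brain
    mpp = params.microns_per_pixel
    shape = stacks["WFA"].shape
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0

    def rect_px(rect):
        return (
            int(round(cy + rect.y0 * 1000 / mpp)),
            int(round(cx + rect.x0 * 1000 / mpp)),
            int(round(cy + rect.y1 * 1000 / mpp)),
            int(round(cx + rect.x1 * 1000 / mpp)),
        )

    q = PnnQuant()
    for img, sid in zip(stacks["WFA"].slices, stacks["WFA"].slice_ids):
        if gt.true_lesion_area_mm2[sid] <= 0:
            continue
        specs = [
            RoiSpec(sid, "iba1_pos", rect_px(ROI_IBA1_POS), rect_px(ROI_IBA1_POS.mirrored())),
            RoiSpec(sid, "iba1_neg", rect_px(ROI_IBA1_NEG), rect_px(ROI_IBA1_NEG.mirrored())),
        ]
        q.records.extend(quantify_slice(img, specs, min_size_px=50))
    s = fold_change_analysis(q)
    assert s.mean_fold["iba1_pos"] < 0.6
    assert 0.6 < s.mean_fold["iba1_neg"] < 1.6
    assert s.mean_fold["iba1_pos"] < s.mean_fold["iba1_neg"]
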