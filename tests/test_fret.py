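"""Tests of the acceptor-photobleaching FRET quantification pipeline."""

import math

import numpy as np
import pytest
from scipy.special import betainc

from spbfret import (SimConfig, SpotROI, background_correct,
                     classify_fret_pair, detect_spots, get_fixture,
                     measure_roi_mean, normalize_to_donor_median,
                     percent_increase, quantify_image_set, quantify_table,
                     simulate_fret_image_set)


def _phi(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestDetectSpots:
    def test_single_spot_found_within_one_pixel(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 1.0, (64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        img += 50.0 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 1.3**2))
        spots = detect_spots(img)
        assert len(spots) == 1
        r, c = spots[0].center_px
        assert abs(r - 32) <= 1 and abs(c - 32) <= 1

    def test_constant_image_yields_no_spots(self):
        assert detect_spots(np.full((32, 32), 7.0)) == []

    def test_two_separated_spots(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100.0, 1.0, (64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        for r0, c0 in ((26, 32), (38, 32)):  # 12 px apart
            img += 50.0 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                 / (2 * 1.3**2))
        spots = detect_spots(img, min_separation_px=5)
        assert len(spots) == 2


class TestMeasureRoiMean:
    def test_constant_box(self):
        img = np.full((5, 5), 7.0)
        assert measure_roi_mean(img, SpotROI((2, 2), 1)) == 7.0

    def test_mean_of_0_to_8(self):
        img = np.arange(9, dtype=float).reshape(3, 3)
        assert measure_roi_mean(img, SpotROI((1, 1), 1)) == 4.0

    def test_out_of_bounds_names_the_cell(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="cell_X"):
            measure_roi_mean(img, SpotROI((0, 0), 2), cell_id="cell_X")

    def test_noiseless_simulator_spot_matches_analytic_integral(self):
        """ROI mean of a noiseless simulated spot equals the closed-form
        pixel-integrated Gaussian (product of normal-CDF differences)."""
        cfg = SimConfig(n_cells_DA=1, n_cells_D=1, n_cells_bg=1,
                        image_shape_px=(48, 48), seed=5).noiseless()
        cell = simulate_fret_image_set(cfg).by_class("D")[0]
        img = cell.images["donor_pre"]
        r0, c0 = cell.true_center
        center = (int(round(r0)), int(round(c0)))
        h = 2
        measured = measure_roi_mean(img, SpotROI(center, h))
        total = 0.0
        for r in range(center[0] - h, center[0] + h + 1):
            for c in range(center[1] - h, center[1] + h + 1):
                fr = (_phi((r + 0.5 - r0) / cfg.psf_sigma_px)
                      - _phi((r - 0.5 - r0) / cfg.psf_sigma_px))
                fc = (_phi((c + 0.5 - c0) / cfg.psf_sigma_px)
                      - _phi((c - 0.5 - c0) / cfg.psf_sigma_px))
                total += (cfg.donor_amplitude * fr * fc
                          + cfg.cyto_background + cfg.camera_offset)
        assert measured == pytest.approx(total / (2 * h + 1) ** 2, abs=1e-6)


class TestEquations:
    @pytest.mark.parametrize("fl,bg,expected", [(100, 20, 80), (20, 20, 0),
                                                (15, 20, -5)])
    def test_background_correction(self, fl, bg, expected):
        assert background_correct(fl, bg) == expected

    @pytest.mark.parametrize("pre,post,expected", [(80, 92, 15.0),
                                                   (80, 80, 0.0),
                                                   (80, 76, -5.0)])
    def test_percent_increase(self, pre, post, expected):
        assert percent_increase(pre, post) == pytest.approx(expected)

    def test_percent_increase_rejects_nonpositive_pre(self):
        with pytest.raises(ValueError):
            percent_increase(0.0, 50.0)

    def test_normalization_subtracts_donor_median(self):
        da, d, med = normalize_to_donor_median([15, 16, 17], [1, 2, 3])
        assert med == 2.0
        assert list(da) == [13, 14, 15]
        assert list(d) == [-1, 0, 1]
        assert np.median(d) == 0.0

    def test_normalization_identity_and_noop_cases(self):
        da, d, _ = normalize_to_donor_median([1, 2, 3], [1, 2, 3])
        assert np.array_equal(da, d)
        da, d, med = normalize_to_donor_median([5, 6], [0, 0, 0])
        assert med == 0.0 and list(da) == [5, 6]

    def test_normalization_requires_donor_control(self):
        with pytest.raises(ValueError):
            normalize_to_donor_median([1, 2], [])

    def test_normalized_donor_median_is_zero(self):
        """Exact 0 for odd n (the median is a data value); for even n the
        averaging of the two middle values leaves at most one ulp."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            d = rng.normal(0, 5, n)
            _, nd, _ = normalize_to_donor_median(rng.normal(10, 3, 10), d)
            if n % 2 == 1:
                assert np.median(nd) == 0.0
            else:
                assert abs(np.median(nd)) < 1e-12


class TestClassifyPair:
    def test_shifted_distribution_is_positive(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0, 3, 30)
        da = rng.normal(14, 3, 30)
        res = classify_fret_pair(da, d)
        assert res.positive and res.p_value < 0.01
        # oracle: equal-variance Student t through the incomplete beta
        na, nb = da.size, d.size
        sp2 = (((na - 1) * da.var(ddof=1) + (nb - 1) * d.var(ddof=1))
               / (na + nb - 2))
        t = (da.mean() - d.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        p_oracle = betainc(df / 2.0, 0.5, df / (df + t * t))
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_groups_negative(self):
        x = np.arange(10.0)
        assert not classify_fret_pair(x, x).positive

    def test_directionality_enforced(self):
        rng = np.random.default_rng(1)
        d = rng.normal(10, 1, 30)
        da = rng.normal(0, 1, 30)   # significantly *below* the control
        res = classify_fret_pair(da, d)
        assert res.p_value < 0.01 and not res.positive

    def test_insufficient_n_flags_instead_of_crashing(self):
        res = classify_fret_pair([1.0, 2.0], [0.0, 1.0, 2.0])
        assert not res.positive and res.flags


class TestQuantifyImageSet:
    def test_noiseless_recovery_is_exact(self):
        cfg = SimConfig(apparent_efficiency_pct=14.0, n_cells_DA=5,
                        n_cells_D=5, n_cells_bg=3, image_shape_px=(48, 48),
                        seed=2).noiseless()
        res = quantify_image_set(simulate_fret_image_set(cfg))
        assert res.mean_DA == pytest.approx(14.0, abs=1e-6)

    def test_donor_only_as_both_classes_is_negative(self):
        cfg = get_fixture("donor_only", seed=8,
                          n_cells_DA=15, n_cells_D=15, n_cells_bg=8,
                          image_shape_px=(48, 48))
        res = quantify_image_set(simulate_fret_image_set(cfg))
        assert not res.positive

    def test_gain_and_offset_invariance(self, tiny_noiseless_set):
        base = quantify_image_set(tiny_noiseless_set)
        for transform in (lambda im: im * 3.7, lambda im: im + 55.0):
            scaled = tiny_noiseless_set
            import copy
            scaled = copy.deepcopy(tiny_noiseless_set)
            for cell in scaled.cells:
                for page in cell.images:
                    cell.images[page] = transform(cell.images[page])
            res = quantify_image_set(scaled)
            assert res.efficiencies_DA_pct == pytest.approx(
                base.efficiencies_DA_pct, abs=1e-9)

    def test_missing_class_raises(self, tiny_noiseless_set):
        import copy
        broken = copy.deepcopy(tiny_noiseless_set)
        broken.cells = [c for c in broken.cells if c.sample_class != "D"]
        with pytest.raises(ValueError, match="donor-only sample required"):
            quantify_image_set(broken)

    def test_monotone_recovery_across_efficiencies(self):
        means = []
        for e in (5.0, 10.0, 20.0, 30.0):
            cfg = SimConfig(apparent_efficiency_pct=e, n_cells_DA=50,
                            n_cells_D=20, n_cells_bg=10, seed=31)
            means.append(quantify_image_set(
                simulate_fret_image_set(cfg)).mean_DA)
        assert means == sorted(means)

    def test_matches_spreadsheet_style_recomputation(self):
        """Independent plain-numpy recomputation on a small noiseless set."""
        cfg = SimConfig(apparent_efficiency_pct=20.0, n_cells_DA=4,
                        n_cells_D=4, n_cells_bg=3, image_shape_px=(48, 48),
                        seed=13).noiseless()
        iset = simulate_fret_image_set(cfg)
        res = quantify_image_set(iset)

        h = 2
        def box_mean(img, r, c):
            return img[r - h:r + h + 1, c - h:c + h + 1].mean()

        bgs = {"pre": [], "post": []}
        for cell in iset.by_class("bg"):
            for fr, fc in ((0.25, 0.25), (0.25, 0.75), (0.5, 0.5),
                           (0.75, 0.25), (0.75, 0.75)):
                r, c = int(fr * 48), int(fc * 48)
                bgs["pre"].append(box_mean(cell.images["donor_pre"], r, c))
                bgs["post"].append(box_mean(cell.images["donor_post"], r, c))
        bg_pre, bg_post = np.mean(bgs["pre"]), np.mean(bgs["post"])

        e_vals = {"DA": [], "D": []}
        for cell in iset.cells:
            if cell.sample_class == "bg":
                continue
            img = cell.images["donor_pre"]
            r, c = np.unravel_index(np.argmax(img), img.shape)
            pre = box_mean(img, r, c) - bg_pre
            post = box_mean(cell.images["donor_post"], r, c) - bg_post
            e_vals[cell.sample_class].append(100.0 * (post - pre) / pre)
        med = np.median(e_vals["D"])
        expected_da = np.asarray(e_vals["DA"]) - med
        assert res.efficiencies_DA_pct == pytest.approx(expected_da, abs=1e-9)

    def test_bootstrap_ci_recovery_of_fixture_ground_truth(self):
        """Estimated mean efficiency lies inside its bootstrap 99% CI of the
        configured value for both shipped FRET fixtures."""
        for name, truth in (("spc42_cnm67", 14.0), ("tandem_bfa1", 26.0)):
            cfg = get_fixture(name, seed=21)
            res = quantify_image_set(simulate_fret_image_set(cfg))
            e = res.efficiencies_DA_pct
            rng = np.random.default_rng(1)
            boot = [np.mean(rng.choice(e, e.size)) for _ in range(2000)]
            lo, hi = np.percentile(boot, [0.5, 99.5])
            assert lo <= truth <= hi, name


class TestQuantifyTable:
    def test_premeasured_table_route(self):
        import pandas as pd
        rows = [("da1", "DA", 100.0, 112.0), ("da2", "DA", 90.0, 100.5),
                ("da3", "DA", 110.0, 123.5),
                ("d1", "D", 100.0, 100.0), ("d2", "D", 95.0, 95.0),
                ("d3", "D", 105.0, 105.0),
                ("b1", "bg", 20.0, 20.0), ("b2", "bg", 20.0, 20.0)]
        df = pd.DataFrame(rows, columns=["cell_id", "class", "FL_pre",
                                         "FL_post"])
        res = quantify_table(df)
        # (112-20)/(100-20) - 1 = 15%, donor-only all exactly 0
        assert res.mean_DA == pytest.approx(15.0, abs=1e-9)

    def test_unknown_class_label_lists_allowed(self):
        import pandas as pd
        df = pd.DataFrame([("x", "XX", 1.0, 2.0)],
                          columns=["cell_id", "class", "FL_pre", "FL_post"])
        with pytest.raises(ValueError, match="DA"):
            quantify_table(df)
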