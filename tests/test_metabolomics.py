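"""Density maps, hotspot pairing, ion extraction and paired statistics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, t as tdist

from imdkit import simulate as sim
from imdkit.geometry import ValidationError
from imdkit.metabolomics import (
    HotspotROI,
    IonImage,
    PairedMetabolomicsModel,
    density_map,
    detect_hotspots,
    extract_ion_counts,
    opposite_trend,
    pair_rois,
    paired_stats,
    signature_matrix,
)
from tests.conftest import random_cells


def blank_image(nx=40, ny=40, px=125.0, channels=("c0",)):
    counts = np.zeros((len(channels), ny, nx))
    return IonImage(pixel_size=px, counts=counts, channels=list(channels))


def cells_at(points, marker="CD8"):
    pts = np.asarray(points, float)
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(pts)),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "tumor_id": "t",
            "CD3": True,
            "CD8": marker == "CD8",
            "FOXP3": marker == "FOXP3",
            "nucleus": True,
        }
    )


class TestDensityMap:
    def test_single_cell_mass_conserved(self):
        grid = blank_image()
        cells = cells_at([(2500.0, 2500.0)])
        dens = density_map(cells, "CD8", grid)
        px_area = grid.pixel_size**2 / 1e6
        assert dens.sum() * px_area == pytest.approx(1.0)

    def test_two_far_cells_two_modes(self):
        grid = blank_image()
        cells = cells_at([(1000.0, 1000.0), (4000.0, 4000.0)])
        dens = density_map(cells, "CD8", grid, bandwidth=150)
        # local maxima at both cell pixels
        j1, i1 = int(1000 // 125), int(1000 // 125)
        j2, i2 = int(4000 // 125), int(4000 // 125)
        assert dens[j1, i1] > dens[j1, i1 + 5]
        assert dens[j2, i2] > dens[j2, i2 - 5]

    def test_matches_bruteforce_kernel(self):
        """Binned KDE agrees with direct per-pixel Gaussian evaluation."""
        rng = np.random.default_rng(2)
        grid = blank_image()
        cells = random_cells(rng, 200, (0, 0, 5000, 5000))
        bw = 250.0
        dens = density_map(cells, "CD8", grid, bandwidth=bw)
        X, Y = grid.pixel_centers()
        oracle = np.zeros_like(X)
        for _, c in cells.iterrows():
            oracle += np.exp(-((X - c.x) ** 2 + (Y - c.y) ** 2) / (2 * bw**2))
        oracle /= 2 * np.pi * bw**2  # cells/um^2
        oracle *= 1e6  # cells/mm^2
        px_area = grid.pixel_size**2 / 1e6
        assert dens.sum() * px_area == pytest.approx(200, rel=1e-6)
        # pointwise agreement up to binning error, away from the edges where
        # the oracle (untruncated Gaussian) loses mass off-grid
        interior = np.zeros_like(oracle, dtype=bool)
        m = int(np.ceil(3 * bw / grid.pixel_size))
        interior[m:-m, m:-m] = True
        mask = interior & (oracle > oracle.max() * 0.05)
        rel = np.abs(dens[mask] - oracle[mask]) / oracle[mask]
        assert np.median(rel) < 0.1
        assert pearsonr(dens[interior], oracle[interior])[0] > 0.99

    def test_no_positive_cells_warns_zero_map(self):
        grid = blank_image()
        cells = cells_at([(100.0, 100.0)], marker="FOXP3")
        with pytest.warns(UserWarning):
            dens = density_map(cells, "CD8", grid)
        assert (dens == 0).all()

    def test_bad_bandwidth(self):
        with pytest.raises(ValidationError):
            density_map(cells_at([(0, 0)]), "CD8", blank_image(), bandwidth=0)


class TestDetectHotspots:
    def test_single_planted_cluster_recovered(self):
        grid = blank_image(80, 80)
        rng = np.random.default_rng(0)
        pts = rng.normal([5000, 5000], 200, size=(80, 2))
        dens = density_map(cells_at(pts), "CD8", grid)
        spots = detect_hotspots(dens, grid, cells_at(pts), "CD8")
        assert len(spots) == 1
        assert math.hypot(spots[0].center[0] - 5000, spots[0].center[1] - 5000) < 250

    def test_uniform_map_no_hotspots(self):
        grid = blank_image(80, 80)
        spots = detect_hotspots(np.ones(grid.shape), grid, cells_at([(0, 0)]), "CD8")
        assert spots == []

    def test_generator_ground_truth_count(self, cd8_hotspot_section):
        image, cells = cd8_hotspot_section
        dens = density_map(cells, "CD8", image)
        spots = detect_hotspots(dens, image, cells, "CD8")
        assert len(spots) == 6

    def test_bad_quantile(self):
        grid = blank_image()
        with pytest.raises(ValidationError):
            detect_hotspots(np.ones(grid.shape), grid, cells_at([(0, 0)]), "CD8", quantile=1.5)


class TestPairROIs:
    def _scene(self, n_high=40, n_low=20):
        """One marker-rich disc at the centre, uniform low field elsewhere."""
        grid = blank_image(80, 80)
        rng = np.random.default_rng(4)
        high = rng.normal([5000, 5000], 150, size=(n_high, 2))
        bg = rng.uniform(0, 10000, size=(n_low, 2))
        cells = cells_at(np.vstack([high, bg]))
        hs = HotspotROI(0, "CD8", (5000.0, 5000.0), 400.0, n_high)
        return grid, cells, hs

    def test_sufficient_fold_accepted(self):
        grid, cells, hs = self._scene(40, 60)  # sparse bg -> low candidate counts
        pairs = pair_rois([hs], cells, grid)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.count_log2fc >= 0.5
        assert not p.high.overlaps(p.low)
        assert p.area_ratio == pytest.approx(1.0)

    def test_insufficient_fold_rejected(self):
        # cells on a regular lattice: every equal-area disc holds ~the same
        # count, so no candidate can satisfy the 0.5 log2-unit fold rule
        grid = blank_image(40, 40)
        xs = np.arange(50.0, 5000.0, 100.0)
        bg = np.array([(x, y) for x in xs for y in xs])
        cells = cells_at(bg)
        n_high = int(
            ((bg[:, 0] - 2500) ** 2 + (bg[:, 1] - 2500) ** 2 <= 400**2).sum()
        )
        hs = HotspotROI(0, "CD8", (2500.0, 2500.0), 400.0, n_high)
        with pytest.warns(UserWarning):
            pairs = pair_rois([hs], cells, grid)
        assert pairs == []

    def test_fold_rule_arithmetic(self):
        # 40 vs 20 -> log2(40.5/20.5) ~ 0.98 >= 0.5; 40 vs 35 -> 0.19 < 0.5
        assert np.log2(40.5 / 20.5) >= 0.5
        assert np.log2(40.5 / 35.5) < 0.5

    def test_emitted_pairs_satisfy_all_constraints(self, cd8_hotspot_section):
        """Every pair re-checked against the four pairing constraints."""
        image, cells = cd8_hotspot_section
        res = PairedMetabolomicsModel(image, cells, "CD8").fit()
        taken = list(res.hotspots)
        for p in res.pairs:
            assert p.area_ratio == pytest.approx(1.0)
            assert p.count_log2fc >= 0.5
            assert p.separation <= 4000.0
            for other in taken:
                if other is not p.high:
                    assert not p.low.overlaps(other)
            taken.append(p.low)


class TestExtractIonCounts:
    def test_small_roi_totals(self):
        counts = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        img = IonImage(pixel_size=100.0, counts=counts, channels=["c"])
        roi = HotspotROI(0, "CD8", (100.0, 100.0), 150.0, 0)
        res = extract_ion_counts(img, roi)
        assert res["total"].iloc[0] == 10.0
        assert res["mean"].iloc[0] == 2.5

    def test_single_pixel_roi(self):
        counts = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        img = IonImage(pixel_size=100.0, counts=counts, channels=["c"])
        roi = HotspotROI(0, "CD8", (50.0, 50.0), 40.0, 0)
        assert extract_ion_counts(img, roi)["total"].iloc[0] == 1.0

    def test_matches_pixel_center_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(50, size=(3, 30, 30)).astype(float)
        img = IonImage(pixel_size=100.0, counts=counts, channels=["a", "b", "c"])
        roi = HotspotROI(0, "CD8", (1234.0, 1911.0), 517.0, 0)
        res = extract_ion_counts(img, roi)
        # exhaustive per-pixel oracle
        for ci in range(3):
            total = 0.0
            npx = 0
            for j in range(30):
                for i in range(30):
                    cx, cy = (i + 0.5) * 100, (j + 0.5) * 100
                    if (cx - 1234) ** 2 + (cy - 1911) ** 2 <= 517**2:
                        total += counts[ci, j, i]
                        npx += 1
            assert res["total"].iloc[ci] == total
            assert res["n_pixels"].iloc[ci] == npx

    def test_offgrid_roi_rejected(self):
        img = IonImage(pixel_size=100.0, counts=np.zeros((1, 2, 2)), channels=["c"])
        roi = HotspotROI(0, "CD8", (10000.0, 10000.0), 100.0, 0)
        with pytest.raises(ValidationError):
            extract_ion_counts(img, roi)


class TestPairedStats:
    def _pairs(self, img, centers):
        return [
            (
                HotspotROI(i, "CD8", hi, 300.0, 40),
                HotspotROI(100 + i, "CD8", lo, 300.0, 10),
            )
            for i, (hi, lo) in enumerate(centers)
        ]

    def test_identical_counts_null(self):
        counts = np.full((2, 40, 40), 100.0)
        img = IonImage(pixel_size=125.0, counts=counts, channels=["a", "b"])
        from imdkit.metabolomics import ROIPair

        pairs = [
            ROIPair(h, l, "CD8")
            for h, l in self._pairs(img, [((1000, 1000), (3000, 3000)), ((1000, 4000), (4000, 1000))])
        ]
        st = paired_stats(pairs, img)
        assert st["mean_log2fc"].abs().max() == 0.0
        assert (st["p_value"] == 1.0).all()

    def test_matches_closed_form_one_sample_t(self):
        """t on a fixed pair-difference vector equals the textbook formula."""
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, size=(1, 60, 60)).astype(float)
        img = IonImage(pixel_size=125.0, counts=counts, channels=["m"])
        from imdkit.metabolomics import ROIPair

        centers = [
            ((1000, 1000), (3000, 3000)),
            ((1000, 5000), (5000, 1000)),
            ((6000, 6000), (3000, 6000)),
            ((6000, 3000), (1000, 6500)),
        ]
        pairs = [ROIPair(h, l, "CD8") for h, l in self._pairs(img, centers)]
        st = paired_stats(pairs, img)
        fcs = []
        for p in pairs:
            mh = extract_ion_counts(img, p.high)["mean"].iloc[0]
            ml = extract_ion_counts(img, p.low)["mean"].iloc[0]
            fcs.append(math.log2((mh + 0.5) / (ml + 0.5)))
        fcs = np.array(fcs)
        t_manual = fcs.mean() / (fcs.std(ddof=1) / math.sqrt(len(fcs)))
        p_manual = 2 * tdist.sf(abs(t_manual), len(fcs) - 1)
        assert st["t_statistic"].iloc[0] == pytest.approx(t_manual)
        assert st["p_value"].iloc[0] == pytest.approx(p_manual)

    def test_too_few_pairs_rejected(self, cd8_hotspot_section):
        image, _ = cd8_hotspot_section
        with pytest.raises(ValidationError):
            paired_stats([], image)

    def test_cd8_preset_flags_planted_metabolites(self, cd8_hotspot_section):
        image, cells = cd8_hotspot_section
        res = PairedMetabolomicsModel(image, cells, "CD8").fit()
        st = res.stats.set_index("metabolite")
        for m in ("glutathione", "N-acetyl-cysteine"):
            assert st.loc[m, "significant"]
            assert st.loc[m, "mean_log2fc"] > 0


class TestSignatureMatrix:
    def test_duplicated_channel_perfect_correlation(self):
        rng = np.random.default_rng(5)
        v = rng.poisson(100, 10).astype(float)
        ab = pd.DataFrame({"a": v, "a_dup": v, "b": rng.poisson(100, 10)})
        corr, cats = signature_matrix(ab)
        assert corr.loc["a", "a_dup"] == pytest.approx(1.0)

    def test_inverse_pattern_anticorrelated(self):
        x = np.linspace(1, 100, 12)
        ab = pd.DataFrame({"up": x, "down": x[::-1]})
        corr, _ = signature_matrix(ab, log_transform=False)
        assert corr.loc["up", "down"] == pytest.approx(-1.0, abs=1e-6)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(6)
        ab = pd.DataFrame(rng.poisson(80, size=(15, 4)).astype(float), columns=list("abcd"))
        corr, _ = signature_matrix(ab)
        logv = np.log2(ab + 0.5)
        for i in "abcd":
            for j in "abcd":
                r = pearsonr(logv[i], logv[j])[0]
                assert corr.loc[i, j] == pytest.approx(r)

    def test_constant_metabolite_missing(self):
        ab = pd.DataFrame({"const": [5.0] * 6, "var": np.arange(6.0)})
        corr, _ = signature_matrix(ab)
        assert np.isnan(corr.loc["const", "var"])

    def test_tertile_categories(self):
        ab = pd.DataFrame(
            {"lo": [1.0] * 5, "mid": [100.0] * 5, "hi": [10000.0] * 5},
        )
        _, cats = signature_matrix(ab)
        assert cats["lo"] == "low" and cats["mid"] == "intermediate" and cats["hi"] == "high"

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValidationError):
            signature_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestOppositeTrend:
    def _stats(self, rows):
        return pd.DataFrame(
            rows, columns=["metabolite", "mean_log2fc", "significant"]
        )

    def test_opposite_significant_included(self):
        a = self._stats([("m", 1.0, True)])
        b = self._stats([("m", -1.0, True)])
        assert opposite_trend(a, b) == ["m"]

    def test_concordant_excluded(self):
        a = self._stats([("m", 1.0, True)])
        b = self._stats([("m", 0.5, True)])
        assert opposite_trend(a, b) == []

    def test_nonsignificant_excluded(self):
        a = self._stats([("m", 1.0, True)])
        b = self._stats([("m", -1.0, False)])
        assert opposite_trend(a, b) == []

    def test_disjoint_namespaces_warn_empty(self):
        a = self._stats([("m1", 1.0, True)])
        b = self._stats([("m2", -1.0, True)])
        with pytest.warns(UserWarning):
            assert opposite_trend(a, b) == []


class TestSignRecovery:
    def test_planted_sign_recovery_at_twenty_pairs(self):
        """>= 95 % of planted |log2FC| = 1 effects recover their sign with
        >= 20 matched pairs."""
        correct = total = 0
        for seed in range(3):
            effects = {f"met_{i:02d}": (1.0 if i % 2 == 0 else -1.0) for i in range(10)}
            sc = sim.MetabolomicsScenario(
                name="SIGN",
                hotspot_marker="CD8",
                metabolite_effects=effects,
                n_hotspots=20,
                grid_extent=(20000.0, 20000.0),
                seed=seed,
            )
            img, cells = sim.gen_ion_image(sc)
            res = PairedMetabolomicsModel(img, cells, "CD8").fit()
            assert len(res.pairs) >= 20
            st = res.stats.set_index("metabolite")
            for m, eff in effects.items():
                total += 1
                if np.sign(st.loc[m, "mean_log2fc"]) == np.sign(eff):
                    correct += 1
        assert correct / total >= 0.95
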