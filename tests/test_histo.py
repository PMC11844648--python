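"""Concentric-ring binning, intensity normalization, neuron density."""

import numpy as np
import pandas as pd
import pytest

from imeqc import (
    HistoSimConfig,
    RadialBinning,
    bin_intensity,
    neuron_density,
    normalize_profile,
    radial_bins,
    radial_profile,
    simulate_histology,
)
from imeqc.histo import BEYOND_LABEL, HOLE_LABEL


def _circular_hole(shape=(1800, 1800), center=(900, 900), radius_px=200):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius_px


class TestRadialBins:
    def test_circular_hole_geometry(self):
        hole = _circular_hole()
        labels = radial_bins(hole, um_per_px=1.0)
        # pixel ~30 um past the edge -> bin 0; ~60 um -> bin 1
        assert labels[900, 900 + 230] == 0
        assert labels[900, 900 + 260] == 1
        assert labels[900, 900] == HOLE_LABEL
        assert labels[900, 900 + 200 + 680] == BEYOND_LABEL

    def test_half_open_boundary(self):
        # single-pixel hole gives exact integer distances along the axis
        hole = np.zeros((201, 201), bool)
        hole[100, 100] = True
        labels = radial_bins(hole, um_per_px=1.0)
        assert labels[100, 150] == 1          # d = 50 exactly -> bin 1
        assert labels[100, 149] == 0          # d = 49 -> bin 0
        assert labels[100, 199] == 1          # d = 99
        assert labels[100, 200] == 2          # d = 100 -> bin 2

    def test_annulus_areas_match_analytic(self):
        hole = _circular_hole()
        labels = radial_bins(hole, um_per_px=1.0)
        r0 = 200.0
        for k in range(13):
            n = (labels == k).sum()
            expected = np.pi * ((r0 + 50 * (k + 1)) ** 2
                                - (r0 + 50 * k) ** 2)
            assert n == pytest.approx(expected, rel=0.02)

    def test_pixel_partition_is_exhaustive(self):
        hole = _circular_hole()
        labels = radial_bins(hole, um_per_px=1.0)
        n_bins = (labels >= 0).sum()
        n_hole = (labels == HOLE_LABEL).sum()
        n_beyond = (labels == BEYOND_LABEL).sum()
        assert n_bins + n_hole + n_beyond == labels.size

    def test_empty_hole_rejected(self):
        with pytest.raises(ValueError):
            radial_bins(np.zeros((10, 10), bool), 1.0)


class TestBinIntensity:
    def test_uniform_image(self):
        hole = _circular_hole((900, 900), (450, 450), 100)
        labels = radial_bins(hole, 1.0)
        prof = bin_intensity(np.full((900, 900), 123.0), labels)
        assert np.allclose(prof["mean_intensity"].dropna(), 123.0)

    def test_artifact_pixels_excluded(self):
        hole = _circular_hole((900, 900), (450, 450), 100)
        labels = radial_bins(hole, 1.0)
        img = np.full((900, 900), 500.0)
        clean = bin_intensity(img, labels)
        art = np.zeros((900, 900), bool)
        art[400:420, 600:650] = True
        img2 = img.copy()
        img2[art] = 65535.0
        masked = bin_intensity(img2, labels, art)
        np.testing.assert_allclose(masked["mean_intensity"],
                                   clean["mean_intensity"])

    def test_linear_gradient_matches_annulus_average(self):
        # oracle: numeric integration of profile(d) over each annulus
        hole = _circular_hole()
        labels = radial_bins(hole, 1.0)
        rr, cc = np.mgrid[0:1800, 0:1800]
        d = np.maximum(np.hypot(rr - 900, cc - 900) - 200.0, 0.0)
        img = 1000.0 + 2.0 * d
        prof = bin_intensity(img, labels)
        r0 = 200.0
        for k in range(13):
            b1, b2 = 50.0 * k, 50.0 * (k + 1)
            r = np.linspace(r0 + b1, r0 + b2, 2000)
            w = 2 * np.pi * r
            expected = np.trapezoid((1000 + 2 * (r - r0)) * w, r) / \
                np.trapezoid(w, r)
            assert prof["mean_intensity"][k] == pytest.approx(expected,
                                                              rel=0.01)


class TestNormalizeProfile:
    def _profile(self, bg=1000.0, k_val=None):
        rows = [{"bin": k, "inner_um": 50 * k, "outer_um": 50 * (k + 1),
                 "n_pixels": 100, "mean_intensity": bg} for k in range(13)]
        df = pd.DataFrame(rows)
        if k_val is not None:
            df.loc[0, "mean_intensity"] = k_val
        return df

    def test_constitutive_marker_background_is_one(self):
        out = normalize_profile(self._profile(), factor=1.0)
        assert out.loc[out["bin"] == 12, "normalized"].iloc[0] == 1.0

    def test_absent_marker_background_is_zero(self):
        out = normalize_profile(self._profile(), factor=0.0)
        assert out.loc[out["bin"] == 12, "normalized"].iloc[0] == 0.0

    def test_double_background_formula(self):
        prof = self._profile(k_val=2000.0)
        assert normalize_profile(prof, 1.0)["normalized"][0] == 2.0
        assert normalize_profile(prof, 0.0)["normalized"][0] == 1.0

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(self._profile(bg=0.0), 1.0)


class TestNeuronDensity:
    def test_homogeneous_process_normalizes_to_one(self):
        cfg = HistoSimConfig(shape_px=(1800, 1800), hole_center_px=(900, 900),
                             hole_radius_um=200.0,
                             neuron_density_profile=lambda d: np.full_like(
                                 d, 800.0),
                             seed=3)
        _, hole, _, cents = simulate_histology(cfg)
        labels = radial_bins(hole, 1.0)
        df = neuron_density(cents, labels, 1.0)
        # Poisson error per bin: counts ~ 800 * area(mm^2)
        for _, row in df.iterrows():
            expect = 800.0 * row["area_mm2"]
            assert abs(row["n_neurons"] - expect) < 4 * np.sqrt(expect)
        assert np.all(np.abs(df["normalized"] - 1.0) < 0.3)

    def test_empty_bin_zero_density(self):
        hole = _circular_hole((900, 900), (450, 450), 100)
        labels = radial_bins(hole, 1.0)
        pts = np.array([[450.0 + 125.0, 450.0]])  # single point in bin 0
        df = neuron_density(pts, labels, 1.0)
        assert df.loc[1, "n_neurons"] == 0
        assert df.loc[1, "density_per_mm2"] == 0.0

    def test_scale_covariance(self):
        hole = _circular_hole((900, 900), (450, 450), 100)
        pts = np.array([[600.0, 450.0], [640.0, 450.0], [700.0, 450.0],
                        [1020.0, 450.0]])
        bin2 = RadialBinning(bin_width_um=100.0, max_distance_um=1300.0,
                             background_bin_um=(1200.0, 1300.0))
        d1 = neuron_density(pts, radial_bins(hole, 1.0), 1.0)
        d2 = neuron_density(pts, radial_bins(hole, 2.0, bin2), 2.0,
                            binning=bin2)
        # doubling um/px with the same pixel content: same counts per
        # (rescaled) bin, x4 area, /4 density
        assert d2["n_neurons"].sum() == d1["n_neurons"].sum()
        k = d1.loc[2, "n_neurons"]
        assert d2.loc[2, "n_neurons"] == k
        assert d2.loc[2, "area_mm2"] == pytest.approx(
            4 * d1.loc[2, "area_mm2"])

    def test_zero_background_warns(self):
        hole = _circular_hole((900, 900), (450, 450), 100)
        labels = radial_bins(hole, 1.0)
        pts = np.array([[575.0, 450.0]])
        with pytest.warns(UserWarning):
            df = neuron_density(pts, labels, 1.0)
        assert "normalized" not in df.columns


class TestEndToEndProfiles:
    def test_simulated_profile_shape_recovered(self):
        # configured exponential-decay-to-background marker profile should
        # be recovered with correlation >= 0.99 at zero noise
        prof_fn = lambda d: 1000.0 + 3000.0 * np.exp(-d / 150.0)
        cfg = HistoSimConfig(shape_px=(1800, 1800), hole_center_px=(900, 900),
                             hole_radius_um=200.0, marker_profile=prof_fn,
                             noise_sd=0.0, seed=0)
        img, hole, art, _ = simulate_histology(cfg)
        prof = radial_profile(img, hole, "GFAP", 1.0, art)
        centers = (prof["inner_um"] + prof["outer_um"]) / 2
        expected = prof_fn(centers.to_numpy())
        r = np.corrcoef(prof["mean_intensity"], expected)[0, 1]
        assert r >= 0.99

    def test_rotation_invariance(self):
        prof_fn = lambda d: 1000.0 + 2000.0 * np.exp(-d / 100.0)
        cfg = HistoSimConfig(shape_px=(1400, 1400), hole_center_px=(700, 700),
                             hole_radius_um=150.0, marker_profile=prof_fn,
                             noise_sd=20.0, seed=4)
        img, hole, art, _ = simulate_histology(cfg)
        p1 = radial_profile(img, hole, "GFAP", 1.0)
        p2 = radial_profile(np.rot90(img), np.rot90(hole), "GFAP", 1.0)
        ratio = p2["mean_intensity"] / p1["mean_intensity"]
        assert np.all(np.abs(ratio - 1.0) < 0.01)

    def test_unknown_marker_rejected(self):
        hole = _circular_hole((900, 900), (450, 450), 100)
        with pytest.raises(ValueError):
            radial_profile(np.ones((900, 900)), hole, "XYZ", 1.0)
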