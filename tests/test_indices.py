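"""Vegetation-index registry: formulas, symmetries and the feature table."""

import math

import numpy as np
import pandas as pd
import pytest

from wheatn.indices import (
    ASD_ALIASES,
    REGISTRY,
    DualexReading,
    FluorescenceReading,
    build_feature_table,
    compute_asd_vis,
    compute_multiplex_vis,
    compute_rgb_vis,
    dualex_features,
    family_names,
    red_edge_max_derivative,
    red_edge_position,
    rep_reflectance,
)
from wheatn.spectra import ReflectanceSpectrum, RGBPlotStats, band

from conftest import make_spectrum

NORMALIZED_DIFFS = ["NDCI", "NDRE", "NDVI_(670,780)", "NDWI", "NDII", "NDIopt", "PPR", "PVR", "PRI", "TBI2"]
SIMPLE_RATIOS = ["SR_(700,670)", "SR_(418,450)", "VOGa", "SR_(553,537)", "SR_(750,700)", "WI"]


def rgb_stats(R, G, B):
    return RGBPlotStats(
        mean_dn={"R": R, "G": G, "B": B},
        white_dn={"R": 255, "G": 255, "B": 255},
        black_dn={"R": 0, "G": 0, "B": 0},
        calibrated=True,
    )


class TestRegistry:
    def test_family_counts(self):
        assert len(family_names("asd")) == 28
        assert len(family_names("multiplex")) == 9
        assert len(family_names("rgb")) == 14
        assert len(family_names("dualex")) == 3

    def test_names_unique(self):
        names = list(REGISTRY)
        assert len(names) == len(set(names)) == 28 + 9 + 14 + 3

    def test_aliases_share_band_math(self, small_dataset):
        vis = compute_asd_vis(small_dataset.spectrum(0, "Feekes5"))
        for alias, target in ASD_ALIASES.items():
            assert alias in REGISTRY[target].aliases
            assert target in vis


class TestASDIndices:
    def test_flat_spectrum_symmetry(self, flat_spectrum):
        vis = compute_asd_vis(flat_spectrum)
        for name in NORMALIZED_DIFFS:
            assert vis[name] == pytest.approx(0.0, abs=1e-12), name
        for name in SIMPLE_RATIOS:
            assert vis[name] == pytest.approx(1.0, rel=1e-12), name
        assert vis["REFD"] == pytest.approx(0.0, abs=1e-15)
        assert math.isnan(vis["REP"])  # zero red-edge slope

    def test_ndvi_example(self):
        s = make_spectrum({780: 0.5, 670: 0.1})
        assert compute_asd_vis(s)["NDVI_(670,780)"] == pytest.approx(0.4 / 0.6, rel=1e-6)

    def test_rep_four_point_example(self):
        s = make_spectrum({670: 0.05, 700: 0.1, 740: 0.4, 780: 0.5})
        rep = red_edge_position(s)
        assert rep == pytest.approx(700 + 40 * (0.275 - 0.1) / 0.3, rel=1e-12)
        assert rep == pytest.approx(723.33, abs=0.01)
        assert rep_reflectance(s) == pytest.approx(band(s, rep), rel=1e-12)

    def test_refd_equals_slope_for_linear_red_edge(self):
        wl = np.arange(350, 2501)
        vals = np.full(wl.size, 0.1)
        lin = (wl >= 660) & (wl <= 800)
        vals[lin] = 0.1 + 0.002 * (wl[lin] - 660)
        s = ReflectanceSpectrum(wavelengths=wl, values=vals)
        assert red_edge_max_derivative(s) == pytest.approx(0.002, rel=1e-9)

    def test_tbi2_strict_mode_is_degenerate_constant(self, small_dataset):
        s = small_dataset.spectrum(1, "Feekes5")
        assert compute_asd_vis(s, strict=True)["TBI2"] == pytest.approx(1.0)
        assert compute_asd_vis(s)["TBI2"] != pytest.approx(1.0)

    def test_scale_invariance_of_ratio_indices(self, small_dataset):
        s = small_dataset.spectrum(2, "Feekes11")
        scaled = ReflectanceSpectrum(wavelengths=s.wavelengths, values=0.5 * s.values)
        v1, v2 = compute_asd_vis(s), compute_asd_vis(scaled)
        for name in NORMALIZED_DIFFS + SIMPLE_RATIOS + ["mND705", "TBI1"]:
            assert v2[name] == pytest.approx(v1[name], rel=1e-9), name

    def test_incomplete_coverage_rejected(self):
        s = ReflectanceSpectrum(wavelengths=np.arange(400, 901), values=np.full(501, 0.2))
        with pytest.raises(ValueError):
            compute_asd_vis(s)


class TestMultiplexIndices:
    def test_unit_channels_identity(self):
        vis = compute_multiplex_vis(FluorescenceReading(1, 1, 1, 1, 1, 1))
        for name in ("SFR_G", "SFR_R", "BRR_FRF", "FER_RUV", "FER_RG", "NBI_G", "NBI_R"):
            assert vis[name] == 1.0
        assert vis["FLAV"] == 0.0 and vis["ANTH"] == 0.0

    def test_flav_is_log10_of_fer_ruv(self):
        vis = compute_multiplex_vis(FluorescenceReading(1, 1, 1, 1, 2, 1))
        assert vis["FER_RUV"] == 2.0
        assert vis["FLAV"] == pytest.approx(math.log10(2), rel=1e-12)

    def test_sfr_g_ratio(self):
        vis = compute_multiplex_vis(FluorescenceReading(1, 1, 3, 2, 1, 1))
        assert vis["SFR_G"] == 1.5

    def test_nonpositive_channel_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceReading(1, 0, 1, 1, 1, 1)


class TestRGBIndices:
    def test_grey_point(self):
        vis = compute_rgb_vis(rgb_stats(120, 120, 120))
        for name in ("ExG", "GRVI", "NDI", "NPCI", "CVI1", "CVI2"):
            assert vis[name] == pytest.approx(0.0, abs=1e-12), name
        assert vis["r"] == pytest.approx(1 / 3)
        assert vis["g"] == pytest.approx(1 / 3)
        assert vis["b"] == pytest.approx(1 / 3)
        assert math.isnan(vis["CVI3"])  # r == g

    def test_exr_example(self):
        # chromatic coordinates r=0.5, g=0.3, b=0.2
        vis = compute_rgb_vis(rgb_stats(125, 75, 50))
        assert vis["r"] == pytest.approx(0.5)
        assert vis["ExR"] == pytest.approx(1.4 * 0.5 - 0.2, rel=1e-12)

    def test_zero_blue_boundary(self):
        vis = compute_rgb_vis(rgb_stats(100, 100, 0))
        assert vis["NDI"] == pytest.approx(-1.0)

    def test_chromatic_closure(self, small_dataset):
        for key in small_dataset.keys():
            vis = compute_rgb_vis(small_dataset.rgb_stats(*key))
            assert vis["r"] + vis["g"] + vis["b"] == pytest.approx(1.0, rel=1e-12)


class TestDualexFeatures:
    def test_identity_pass_through(self):
        vals = dualex_features(DualexReading(NBI=30, Chl=35, Flav=1.2))
        assert vals == {"NBI": 30.0, "Chl": 35.0, "Flav": 1.2}

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            DualexReading(NBI=30, Chl=0, Flav=1.2)

    def test_generated_nbi_is_chl_over_flav(self, small_dataset):
        d = small_dataset.dualex
        assert np.allclose(d["NBI"], d["Chl"] / d["Flav"], rtol=1e-9)


class TestFeatureTable:
    def test_shapes_and_targets(self, small_dataset):
        tab = build_feature_table(small_dataset, families=("asd",))
        n = len(small_dataset.keys())
        assert len(tab) == n
        assert set(family_names("asd")) <= set(tab.columns)
        assert {"LNC", "PNC", "NNI"} <= set(tab.columns)

    def test_two_stages_concatenate(self, small_dataset):
        tab = build_feature_table(small_dataset, families=("dualex",))
        per_stage = tab.groupby("stage").size()
        assert per_stage.sum() == len(tab) == 24

    def test_duplicate_records_rejected(self, small_dataset):
        dup = small_dataset.plant_samples.copy()
        dup = pd.concat([dup, dup.iloc[[0]]], ignore_index=True)
        broken = type(small_dataset)(
            config=small_dataset.config,
            latent=small_dataset.latent,
            spectra_values=small_dataset.spectra_values,
            wavelengths=small_dataset.wavelengths,
            fluorescence=small_dataset.fluorescence,
            dualex=small_dataset.dualex,
            rgb=small_dataset.rgb,
            plant_samples=dup,
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(broken, families=("dualex",))

    def test_unknown_family_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            build_feature_table(small_dataset, families=("sentinel2",))
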