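"""Septal ROI, transmural HA quantification, E2A mobility and consensus QC."""

from dataclasses import replace

import numpy as np
import pytest

from cdtikit.metrics_report import (
    SummaryMetrics,
    TransmuralProfile,
    e2a_mobility,
    ha_transmurality,
    normal_range_qc,
    segment_partition,
    septal_roi,
    summarize_roi,
    transmural_profile,
)
from cdtikit.pipeline import run_pipeline
from cdtikit.synthetic_phantom import PhantomSpec, make_annulus, make_phantom


class TestSeptalRoi:
    def test_spans_arc_between_landmarks(self, noiseless_phantom, default_spec):
        _, _, truth = noiseless_phantom
        roi = septal_roi(truth.contours, truth.mask, default_spec.pixel_spacing)
        c = default_spec.grid_center
        xs = np.arange(default_spec.matrix_size) * default_spec.pixel_spacing
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        theta = np.degrees(np.arctan2(yy - c[1], xx - c[0]))
        assert np.all(np.abs(theta[roi]) <= 60.0 + 1e-9)
        # expected share of the annulus: 120 of 360 degrees
        assert roi.sum() / truth.mask.sum() == pytest.approx(1 / 3, abs=0.05)
        # full transmural extent
        r = np.hypot(xx - c[0], yy - c[1])
        assert r[roi].min() < default_spec.r_endo + 1.0
        assert r[roi].max() > default_spec.r_epi - 1.0

    def test_trabeculation_excluded(self, default_spec):
        contours, mask = make_annulus(default_spec)
        c = default_spec.grid_center
        blob = np.array(
            [[c[0] + 10, c[1] - 1], [c[0] + 12, c[1] - 1],
             [c[0] + 12, c[1] + 1], [c[0] + 10, c[1] + 1]]
        )
        from cdtikit.dwi_io import LVContours
        with_trab = LVContours(
            endo=contours.endo, epi=contours.epi,
            rv_insertion=contours.rv_insertion, trabeculation=blob,
        )
        roi_plain = septal_roi(contours, mask, default_spec.pixel_spacing)
        roi_trab = septal_roi(with_trab, mask, default_spec.pixel_spacing)
        removed = roi_plain & ~roi_trab
        assert removed.sum() > 0
        xs = np.arange(default_spec.matrix_size) * default_spec.pixel_spacing
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        assert np.all((xx[removed] >= c[0] + 10) & (xx[removed] <= c[0] + 12))

    def test_missing_landmarks_rejected(self, default_spec):
        contours, mask = make_annulus(default_spec)
        from cdtikit.dwi_io import LVContours
        bare = LVContours(endo=contours.endo, epi=contours.epi)
        with pytest.raises(ValueError, match="landmark"):
            septal_roi(bare, mask, default_spec.pixel_spacing)

    def test_tiny_roi_rejected(self, noiseless_phantom, default_spec):
        _, _, truth = noiseless_phantom
        with pytest.raises(ValueError, match="voxels"):
            septal_roi(truth.contours, truth.mask, default_spec.pixel_spacing,
                       min_voxels=10_000)

    def test_six_segments(self, noiseless_phantom, default_spec):
        _, _, truth = noiseless_phantom
        labels = segment_partition(truth.contours, truth.mask,
                                   default_spec.pixel_spacing)
        present = set(np.unique(labels[truth.mask]))
        assert present == {1, 2, 3, 4, 5, 6}
        assert np.all(labels[~truth.mask] == 0)


class TestTransmuralProfile:
    def test_phantom_bins_on_prescribed_line(self, noiseless_phantom, noiseless_result):
        _, _, truth = noiseless_phantom
        res = noiseless_result
        profile = transmural_profile(res.angles.ha, res.frames.depth, res.septal)
        expected = 50.0 - profile.bin_depth  # ha_endo +50 -> ha_epi -50
        assert np.max(np.abs(profile.bin_ha - expected)) < 0.5

    def test_constant_ha_gives_flat_profile(self, noiseless_result):
        res = noiseless_result
        flat = np.where(np.isfinite(res.angles.ha), 17.0, np.nan)
        profile = transmural_profile(flat, res.frames.depth, res.septal)
        assert np.allclose(profile.bin_ha, 17.0, atol=1e-9)

    def test_wrap_crossing_profile_unwrapped(self):
        """A profile running 70->110 deg (folded to [-90,90)) unwraps monotone."""
        depth = np.tile(np.linspace(2, 98, 200), (3, 1))
        true = 70.0 + 0.4 * depth  # crosses +90
        folded = np.where(true >= 90.0, true - 180.0, true)
        roi = np.ones_like(depth, bool)
        profile = transmural_profile(folded, depth, roi)
        jumps = np.abs(np.diff(profile.bin_ha))
        assert np.all(jumps < 20.0)  # no 180-degree discontinuities
        # hand unwrap: bins match the true line modulo a global 180 shift
        expected = 70.0 + 0.4 * profile.bin_depth
        offset = np.round((profile.bin_ha - expected).mean() / 180.0) * 180.0
        assert np.max(np.abs(profile.bin_ha - expected + offset)) < 1.0

    def test_too_few_bins_rejected(self):
        depth = np.full((10, 10), 50.0)
        ha = np.zeros_like(depth)
        with pytest.raises(ValueError, match="populated"):
            transmural_profile(ha, depth, np.ones_like(depth, bool))


class TestHat:
    def _profile(self, slope, intercept=50.0, n=10):
        d = np.linspace(5, 95, n)
        return TransmuralProfile(
            bin_centers=d, bin_depth=d, bin_ha=intercept + slope * d,
            counts=np.full(n, 20), empty_bins=np.array([], int),
        )

    def test_consensus_slope(self, noiseless_result):
        res = noiseless_result
        profile = transmural_profile(res.angles.ha, res.frames.depth, res.septal)
        hat = ha_transmurality(profile, 7.0)
        assert hat.slope_deg_per_pct == pytest.approx(-1.0, abs=0.06)
        assert 95.0 <= hat.ha_range <= 110.0

    def test_constant_profile(self):
        hat = ha_transmurality(self._profile(0.0), 7.0)
        assert hat.slope_deg_per_pct == pytest.approx(0.0, abs=1e-9)
        assert hat.ha_range == pytest.approx(0.0, abs=1e-9)

    def test_offset_invariance(self):
        a = ha_transmurality(self._profile(-1.0, intercept=50.0), 7.0)
        b = ha_transmurality(self._profile(-1.0, intercept=20.0), 7.0)
        assert a.slope_deg_per_pct == pytest.approx(b.slope_deg_per_pct)

    def test_per_mm_identity(self):
        for thickness in (5.0, 7.0, 12.0):
            hat = ha_transmurality(self._profile(-1.0), thickness)
            assert hat.slope_deg_per_mm * thickness == pytest.approx(
                hat.slope_deg_per_pct * 100.0
            )

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            ha_transmurality(self._profile(-1.0, n=2), 7.0)


class TestE2aMobility:
    def test_consensus_pair(self):
        mobility, reduced = e2a_mobility(62.0, 13.0)
        assert mobility == pytest.approx(49.0)
        assert not reduced

    def test_identical_phases(self):
        mobility, reduced = e2a_mobility(40.0, 40.0)
        assert mobility == 0.0
        assert not reduced

    def test_reduced_mobility_flag(self):
        mobility, reduced = e2a_mobility(20.0, 30.0)
        assert mobility == pytest.approx(-10.0)
        assert reduced


class TestNormalRangeQc:
    def test_steam_systole_fa_in_range(self):
        s = SummaryMetrics(fa_mean=0.47)
        flags = {f.metric: f for f in normal_range_qc(s, "STEAM", "systole")}
        assert flags["fa"].status == "in_range"

    def test_free_water_hard_flag(self):
        s = SummaryMetrics(md_mean=3.2e-3)
        flags = {f.metric: f for f in normal_range_qc(s, "STEAM", "systole")}
        assert flags["md"].status == "hard_flag"

    def test_sequences_never_cross_compared(self):
        s = SummaryMetrics(fa_mean=0.36)
        mcse = {f.metric: f for f in normal_range_qc(s, "MCSE", "systole")}
        steam = {f.metric: f for f in normal_range_qc(s, "STEAM", "systole")}
        assert mcse["fa"].status == "in_range"
        assert steam["fa"].status == "out_of_range"

    def test_hat_uses_mean_2sd_rule(self):
        s = SummaryMetrics(hat_deg_per_pct=-1.05)
        flags = {f.metric: f for f in normal_range_qc(s, "STEAM", "systole")}
        assert flags["hat"].status == "in_range"
        assert "2SD" in flags["hat"].rule

    def test_unknown_sequence_rejected(self):
        with pytest.raises(ValueError):
            normal_range_qc(SummaryMetrics(), "EPI", "systole")


class TestSummaries:
    def test_noiseless_summary_matches_prescription(self, noiseless_result):
        s = noiseless_result.summary
        assert s.md_mean == pytest.approx(1.03e-3, rel=1e-9)
        assert s.fa_mean == pytest.approx(0.46476, abs=1e-5)
        assert s.e2a_median == pytest.approx(62.0, abs=1e-9)

    def test_noisy_summaries_inside_typical_ranges(self):
        """At SNR 20 with range-centre prescriptions, MD/FA stay in range."""
        from cdtikit.synthetic_phantom import eigenvalues_for_md_fa
        lam = eigenvalues_for_md_fa(1.0e-3, 0.47)
        in_md, in_fa = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = PhantomSpec(eigenvalues=lam, snr=20.0, seed=seed)
            stack, table, truth = make_phantom(spec)
            res = run_pipeline(stack, table, truth.contours, mask=truth.mask,
                               register=False)
            in_md += 0.8e-3 <= res.summary.md_mean <= 1.2e-3
            in_fa += 0.43 <= res.summary.fa_mean <= 0.51
        assert in_md >= 9
        assert in_fa >= 9
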