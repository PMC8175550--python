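"""Generator ground truth: designed quantities must be exactly what is rendered."""

import numpy as np
import pandas as pd
import pytest

from zfo import synthetic as syn
from zfo.oct import COMPARTMENTS, DEFAULT_REFRACTIVE_INDICES
from zfo.photorefraction import estimate_slope


class TestBScanPhantom:
    def test_optical_extent_is_thickness_times_index(self):
        # a 500 µm lens at n=1.4 spans 700 µm of optical path = 350 pixels of 2 µm
        spec = syn.EyePhantomSpec()
        _, truth = syn.generate_bscan(spec)
        lens_row = truth.set_index("compartment").loc["lens"]
        assert lens_row["extent_px"] == 350
        assert lens_row["optical_um"] == pytest.approx(700.0)

    def test_unit_indices_make_optical_equal_physical(self):
        spec = syn.EyePhantomSpec(indices={c: 1.0 for c in COMPARTMENTS})
        _, truth = syn.generate_bscan(spec)
        assert np.allclose(truth["optical_um"], truth["physical_um"])

    def test_optical_total_is_sum_of_thickness_times_index(self):
        spec = syn.EyePhantomSpec()
        _, truth = syn.generate_bscan(spec)
        expected = sum(
            spec.thicknesses_um[c] * DEFAULT_REFRACTIVE_INDICES[c]
            for c in COMPARTMENTS
        )
        assert truth.attrs["optical_total_um"] == pytest.approx(expected)

    def test_quantized_roundtrip_within_one_pixel(self):
        # rendered pixel extent / n maps back to physical thickness +- 1 px
        spec = syn.EyePhantomSpec()
        _, truth = syn.generate_bscan(spec)
        for _, row in truth.iterrows():
            recovered = row["extent_px"] * spec.pixel_depth_um / row["refractive_index"]
            assert abs(recovered - row["physical_um"]) <= spec.pixel_depth_um

    def test_rpe_is_brightest_band(self):
        bscan, truth = syn.generate_bscan(syn.EyePhantomSpec())
        rpe_start = truth.attrs["boundaries_px"][-2]
        assert np.argmax(bscan.image.mean(axis=1)) >= rpe_start

    def test_subpixel_compartment_rejected(self):
        thick = dict(syn.WT_THICKNESSES_UM, anterior_chamber=0.5)
        with pytest.raises(syn.DegeneratePhantomError):
            syn.generate_bscan(syn.EyePhantomSpec(thicknesses_um=thick))

    def test_seeded_regeneration_is_bit_identical(self):
        spec = syn.EyePhantomSpec(speckle=0.05, seed=7)
        a, _ = syn.generate_bscan(spec)
        b, _ = syn.generate_bscan(spec)
        assert np.array_equal(a.image, b.image)


class TestPupilProfiles:
    def test_zero_refraction_is_flat(self):
        prof = syn.generate_pupil_profile(0.0, 1.924)
        slope, _ = estimate_slope(prof)
        assert slope == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "refraction, factor, expected_slope",
        [(-4.0, 2.0, -2.0), (1.924, 1.924, 1.0), (10.0, 1.924, 10.0 / 1.924)],
    )
    def test_designed_slope(self, refraction, factor, expected_slope):
        prof = syn.generate_pupil_profile(refraction, factor)
        slope, r2 = estimate_slope(prof)
        assert slope == pytest.approx(expected_slope, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_pupil_profile(1.0, 1.924, n_points=2)

    def test_zero_factor_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_pupil_profile(1.0, 0.0)


class TestOkrTraces:
    def test_perfect_gain_slope_equals_drum_velocity(self):
        tr = syn.generate_okr_trace(syn.OkrTraceSpec(gain=1.0, noise_sd_deg=0.0))
        # slope within any reset-free second of the trace
        v = np.diff(tr.angle_deg[:90]) * tr.frame_rate
        assert np.allclose(v, 20.0)

    def test_zero_gain_is_flat(self):
        tr = syn.generate_okr_trace(syn.OkrTraceSpec(gain=0.0))
        assert np.allclose(tr.angle_deg, 0.0)
        assert tr.meta["reset_times_s"] == []

    def test_segment_slopes_match_designed_velocity(self):
        spec = syn.OkrTraceSpec(gain=0.6, duration_s=10.0, noise_sd_deg=0.0)
        tr = syn.generate_okr_trace(spec)
        resets = [int(round(t * spec.frame_rate)) for t in tr.meta["reset_times_s"]]
        edges = [0] + resets + [tr.angle_deg.size]
        for s, e in zip(edges[:-1], edges[1:]):
            seg_t, seg_a = tr.time_s[s:e], tr.angle_deg[s:e]
            slope = np.polyfit(seg_t, seg_a, 1)[0]
            assert slope == pytest.approx(12.0, rel=1e-9)

    def test_excessive_saccade_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_okr_trace(syn.OkrTraceSpec(saccade_rate_hz=40.0))


class TestErgTraces:
    def test_template_maximum_equals_designed_b_amplitude(self):
        spec = syn.ErgTraceSpec(b_amplitude_uv=200.0, baseline_offset_uv=50.0)
        t = np.arange(0.0, spec.template_support_ms, 1.0)
        tmpl = syn.erg_template(spec, t)
        assert tmpl.max() == pytest.approx(200.0, abs=1e-9)

    def test_zero_amplitudes_give_pure_noise(self):
        spec = syn.ErgTraceSpec(
            a_amplitude_uv=0.0, b_amplitude_uv=0.0, noise_sd_uv=1.0, seed=3
        )
        tr = syn.generate_erg_trace(spec)
        assert abs(tr.voltage_uv.mean()) < 0.5
        assert tr.voltage_uv.std() == pytest.approx(1.0, rel=0.1)

    def test_responses_to_both_stimuli_identical_when_noiseless(self):
        tr = syn.generate_erg_trace(syn.ErgTraceSpec())
        i0 = np.searchsorted(tr.time_ms, tr.onsets_ms[0])
        i1 = np.searchsorted(tr.time_ms, tr.onsets_ms[1])
        n = 900
        assert np.allclose(tr.voltage_uv[i0 : i0 + n], tr.voltage_uv[i1 : i1 + n])

    def test_overlapping_stimuli_rejected(self):
        with pytest.raises(ValueError):
            syn.ErgTraceSpec(inter_stimulus_ms=500.0, template_support_ms=1000.0)

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError):
            syn.ErgTraceSpec(pre_stimulus_ms=20.0)


class TestLensImages:
    def test_no_rings_means_zero_opaque_fraction(self):
        _, mask = syn.generate_lens_image(syn.LensImageSpec())
        assert mask.sum() == 0

    def test_target_fraction_hit_up_to_quantization(self):
        spec = syn.LensImageSpec(target_opaque_fraction=0.25)
        img, mask = syn.generate_lens_image(spec)
        n = spec.image_size_px
        yy, xx = np.mgrid[0:n, 0:n]
        disk = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) <= spec.lens_radius_px
        frac = mask.sum() / disk.sum()
        assert frac == pytest.approx(0.25, abs=0.01)

    def test_single_ring_fraction_matches_analytic_annulus_area(self):
        spec = syn.LensImageSpec(rings=[(0.5, 6.0, 0.3)], lens_radius_px=50.0)
        _, mask = syn.generate_lens_image(spec)
        r_in, r_out = 0.5 * 50 - 3, 0.5 * 50 + 3
        analytic = (r_out**2 - r_in**2) / 50.0**2
        n = spec.image_size_px
        yy, xx = np.mgrid[0:n, 0:n]
        disk = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) <= 50.0
        assert mask.sum() / disk.sum() == pytest.approx(analytic, rel=0.05)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_lens_image(
                syn.LensImageSpec(rings=[(0.9, 1.0, 0.3)], target_opaque_fraction=0.95)
            )


class TestCohorts:
    def test_noiseless_cohort_differences_equal_effect(self):
        spec = syn.CohortSpec(between_fish_sd=0.0, residual_sd=0.0,
                              genotype_effect=-47.0)
        df = syn.generate_cohort(spec)
        wt = df.loc[df.genotype == "WT", "value"]
        mut = df.loc[df.genotype == "mutant", "value"]
        assert np.all(mut.to_numpy()[:, None] - wt.to_numpy() == -47.0)

    def test_two_rows_per_fish(self):
        df = syn.generate_cohort(syn.CohortSpec(n_fish_per_group=5))
        assert (df.groupby("fish_id").size() == 2).all()
        assert df.groupby("fish_id")["genotype"].nunique().max() == 1

    def test_seeded_regeneration_is_bit_identical(self):
        a = syn.generate_cohort(syn.CohortSpec(seed=11))
        b = syn.generate_cohort(syn.CohortSpec(seed=11))
        pd.testing.assert_frame_equal(a, b)
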