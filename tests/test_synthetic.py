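"""Generator correctness: closed forms, ground truth, seeded purity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fishheart import synthetic as syn
from fishheart.exceptions import InvalidParameterError, PackingError, RenderingError
from fishheart.stats import compute_ucrit


class TestBeatingHeartVideo:
    def test_seeded_reproducibility(self):
        p = syn.CardiacSimParams(noise_sd=5.0, seed=7, duration=1.5)
        v1, _ = syn.gen_beating_heart_video(p)
        v2, _ = syn.gen_beating_heart_video(p)
        np.testing.assert_array_equal(v1.plane_long, v2.plane_long)
        np.testing.assert_array_equal(v1.plane_short, v2.plane_short)

    def test_truth_volume_extremes_match_edv_esv(self, clean_masks_video):
        _, truth = clean_masks_video
        assert truth["volume"].max() == pytest.approx(4.0, abs=0)
        assert truth["volume"].min() >= 2.0

    def test_ground_truth_ef_is_half_for_4_over_2(self, noiseless_video):
        _, truth = noiseless_video
        assert truth["ef"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(esv=5.0),  # ESV >= EDV
            dict(esv=0.0),
            dict(heart_rate=0.0),
            dict(frame_rate=3.0),  # below 2x heart rate
            dict(duration=1.0),  # fewer than 3 cycles
            dict(noise_sd=-1.0),
        ],
    )
    def test_invalid_params_raise(self, bad):
        with pytest.raises(InvalidParameterError):
            syn.gen_beating_heart_video(syn.CardiacSimParams(**bad))

    def test_oversized_heart_raises_rendering_error(self):
        with pytest.raises(RenderingError):
            syn.gen_beating_heart_video(syn.CardiacSimParams(image_shape=(40, 40)))


class TestMyofibrilTrace:
    def test_activation_approaches_f_max(self):
        # a long activation phase ends within 0.1% of the plateau force
        p = syn.MyofibrilSimParams(
            noise_sd=0.0, event_times=(0.5, 4.0, 4.1, 5.0), duration=6.0
        )
        trace, _ = syn.gen_myofibril_trace(p)
        stop = np.searchsorted(trace.time, p.event_times[1])
        assert abs(trace.force[stop - 1] - p.f_max) < 1e-3 * p.f_max

    def test_noiseless_activation_matches_closed_form(self):
        p = syn.MyofibrilSimParams(noise_sd=0.0)
        trace, _ = syn.gen_myofibril_trace(p)
        sel = (trace.time >= p.event_times[0]) & (trace.time < p.event_times[1])
        t = trace.time[sel] - p.event_times[0]
        expected = p.f_passive + (p.f_max - p.f_passive) * (1 - np.exp(-p.k_act * t))
        np.testing.assert_allclose(trace.force[sel], expected, rtol=1e-9)

    def test_zero_tlin_relaxation_is_pure_exponential(self):
        p = syn.MyofibrilSimParams(t_lin=0.0, noise_sd=0.0)
        trace, truth = syn.gen_myofibril_trace(p)
        sel = trace.time >= p.event_times[3]
        t = trace.time[sel] - p.event_times[3]
        f_r = truth["f_relax_onset"]
        expected = p.f_passive + (f_r - p.f_passive) * np.exp(-p.k_rel * t)
        np.testing.assert_allclose(trace.force[sel], expected, rtol=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(k_act=0.0),
            dict(t_lin=-0.1),
            dict(f_passive=600.0),  # passive above max
            dict(event_times=(0.5, 2.5, 2.4, 4.5)),  # out of order
            dict(event_times=(0.5, 2.5, 2.6, 7.0)),  # beyond trace
        ],
    )
    def test_invalid_params_raise(self, bad):
        with pytest.raises(InvalidParameterError):
            syn.gen_myofibril_trace(syn.MyofibrilSimParams(**bad))

    def test_seeded_reproducibility(self):
        p = syn.MyofibrilSimParams(noise_sd=0.05, seed=3)
        t1, _ = syn.gen_myofibril_trace(p)
        t2, _ = syn.gen_myofibril_trace(p)
        np.testing.assert_array_equal(t1.force, t2.force)


class TestDopplerWaveform:
    def test_noiseless_maxima_equal_stated_peaks(self):
        p = syn.DopplerSimParams(e_peak=10.0, a_peak=5.0, noise_sd=0.0)
        wave, truth = syn.gen_doppler_waveform(p)
        assert truth["e_over_a"] == pytest.approx(2.0)
        assert wave.velocity.max() == pytest.approx(10.0, rel=1e-3)

    def test_equal_peaks_give_unit_ratio(self):
        _, truth = syn.gen_doppler_waveform(syn.DopplerSimParams(e_peak=8.0, a_peak=8.0))
        assert truth["e_over_a"] == pytest.approx(1.0)

    def test_timing_invariant_violation_raises(self):
        with pytest.raises(InvalidParameterError):
            syn.gen_doppler_waveform(syn.DopplerSimParams(ivct=0.2, ivrt=0.2, et=0.2))


class TestSwimCohort:
    def test_round_trip_recovers_true_ucrit(self):
        params = syn.CohortSimParams(n_per_group=20, seed=11)
        table, truth = syn.gen_swim_cohort(params)
        for row, u_true in zip(table.itertuples(), truth["true_ucrit"]):
            res = compute_ucrit(
                row.exhaustion_time, row.initial_speed, row.speed_increment,
                row.stage_duration,
            )
            assert res.ucrit == pytest.approx(u_true, abs=1e-9)

    def test_boundary_ucrit_exhausts_at_stage_end(self):
        p = syn.SwimProtocol()
        # true Ucrit exactly one increment above the initial speed
        u = p.initial_speed + p.speed_increment
        params = syn.CohortSimParams(
            n_per_group=1, true_ucrit_mean=u, true_ucrit_sd=0.0, seed=0
        )
        table, _ = syn.gen_swim_cohort(params)
        assert table.exhaustion_time.iloc[0] == pytest.approx(2 * p.stage_duration)

    def test_zero_sd_gives_identical_exhaustion_times(self):
        params = syn.CohortSimParams(n_per_group=5, true_ucrit_sd=0.0, seed=0)
        table, _ = syn.gen_swim_cohort(params)
        assert table.exhaustion_time.nunique() == 1


class TestSurvivalCohort:
    def test_zero_hazard_censors_everything(self):
        params = syn.CohortSimParams(hazard_per_group=(0.0, 0.0), n_per_group=10)
        table, _ = syn.gen_survival_cohort(params)
        assert (table.event == 0).all()
        assert (table.time == params.censor_time).all()

    def test_seeded_reproducibility(self):
        params = syn.CohortSimParams(seed=5)
        t1, _ = syn.gen_survival_cohort(params)
        t2, _ = syn.gen_survival_cohort(params)
        assert t1.equals(t2)


class TestLabeledImages:
    def test_area_fraction_exact_pixel_count(self):
        img, truth = syn.gen_labeled_image(
            "area_fraction", syn.LabelImageSpec(shape=(100, 100), target_fraction=0.25)
        )
        assert img.sum() == 2500
        assert truth["fraction"] == pytest.approx(0.25)

    def test_zero_positive_nuclei(self):
        (_, pos), truth = syn.gen_labeled_image(
            "nuclei", syn.LabelImageSpec(n_objects=10, n_positive=0)
        )
        assert truth["percent_positive"] == 0.0
        assert np.ptp(pos) == 0  # positive channel is flat background

    def test_single_square_cell_area(self):
        labels, truth = syn.gen_labeled_image(
            "cells", syn.LabelImageSpec(n_cells=1, cell_side=20, pixel_size=1.0)
        )
        assert truth["areas_um2"][0] == pytest.approx(400.0)
        assert (labels == 1).sum() == 400

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            syn.gen_labeled_image(
                "nuclei", syn.LabelImageSpec(shape=(30, 30), n_objects=100, n_positive=0)
            )


class TestForcePca:
    def test_midpoint_and_tail(self):
        table, _ = syn.gen_force_pca(5.75, 2.0, 45.0, np.array([5.75, 10.0, 5.5, 6.0]))
        assert table.tension.iloc[0] == pytest.approx(22.5)
        assert table.tension.iloc[1] < 1e-6 * 45.0

    def test_noiseless_closed_form(self):
        pca = np.arange(5.5, 6.01, 0.1)
        table, _ = syn.gen_force_pca(5.75, 2.0, 45.0, pca)
        expected = 45.0 / (1.0 + 10.0 ** (2.0 * (pca - 5.75)))
        np.testing.assert_allclose(table.tension.to_numpy(), expected, rtol=1e-9)


@given(u=st.floats(min_value=9.0, max_value=120.0))
def test_swim_generator_inverts_ucrit_for_any_speed(u):
    """Exhaustion-time encoding of a true Ucrit is exactly inverted by the
    Brett-form computation for any speed at or above the protocol start."""
    params = syn.CohortSimParams(n_per_group=1, true_ucrit_mean=u, true_ucrit_sd=0.0)
    table, _ = syn.gen_swim_cohort(params)
    row = table.iloc[0]
    res = compute_ucrit(
        row.exhaustion_time, row.initial_speed, row.speed_increment, row.stage_duration
    )
    assert res.ucrit == pytest.approx(u, rel=1e-12)
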