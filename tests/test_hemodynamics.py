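"""IOS inversion, illumination correction, epoch averaging and the standard
fractional-response pipeline."""

import numpy as np
import pytest

from widefield import hemodynamics as hd
from widefield import synthetic
from widefield.core_io import EventTable, FrameStack


def _stack(data, times, channel="IOS_GREEN", exposure=50.0):
    return FrameStack(np.asarray(data, float), times, channel, exposure)


class TestInvertIOS:
    def test_definition_with_frame_max(self):
        out = hd.invert_ios(np.array([[0.0, 10.0], [5.0, 10.0]]))
        np.testing.assert_array_equal(out, [[10.0, 0.0], [5.0, 0.0]])

    def test_linearity_of_range(self):
        frame = np.array([[1.0, 4.0], [2.0, 3.0]])
        assert np.ptp(hd.invert_ios(2 * frame)) == pytest.approx(2 * np.ptp(hd.invert_ios(frame)))

    def test_dark_vessel_maps_to_high_absorption(self):
        parenchyma = np.full((32, 32), 100.0)
        parenchyma[:, 15:18] = 40.0  # dark vessel (strong absorber)
        inv = hd.invert_ios(parenchyma)
        assert inv[:, 15:18].min() > inv[:, :10].max()

    def test_constant_frame_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="dynamic range"):
            out = hd.invert_ios(np.full((4, 4), 2.0))
        np.testing.assert_array_equal(out, 0.0)


class TestIlluminationCorrect:
    def test_flat_field_identity(self):
        rng = np.random.default_rng(0)
        field = 1.0 + 0.3 * rng.random((32, 32))
        stack = _stack(3.7 * np.repeat(field[None], 5, axis=0), np.arange(5.0) * 10)
        out = hd.illumination_correct(stack, hd.IlluminationField(field, 100))
        # a stack that IS the illumination pattern becomes spatially constant
        assert np.ptp(out.data) / out.data.mean() < 1e-12 * 10 + 1e-9

    def test_constant_field_is_identity(self):
        data = np.random.default_rng(1).random((4, 8, 8))
        stack = _stack(data, np.arange(4.0))
        out = hd.illumination_correct(stack, hd.IlluminationField(np.full((8, 8), 2.0), 100))
        np.testing.assert_allclose(out.data, data)

    def test_vignetting_removed_from_flat_phantom(self):
        rr, cc = np.mgrid[:64, :64]
        d = np.hypot(rr - 31.5, cc - 31.5)
        vignette = 1.0 - 0.3 * (d / d.max()) ** 2
        stack = _stack(100.0 * np.repeat(vignette[None], 3, axis=0), np.arange(3.0) * 10)
        # kernel scaled as in acquisition practice: ~1/6 of the FoV
        field = hd.estimate_illumination(stack, kernel_px=10)
        out = hd.illumination_correct(stack, field)
        cv = out.data[0].std() / out.data[0].mean()
        assert cv < 0.01

    def test_nonpositive_field_rejected(self):
        stack = _stack(np.ones((2, 4, 4)), [0, 10])
        with pytest.raises(ValueError):
            hd.illumination_correct(stack, hd.IlluminationField(np.zeros((4, 4)), 100))


class TestEpochAverage:
    def _session(self, n_epochs=5, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dt, epoch_ms = 20.0, 2000.0
        times = np.arange(0, n_epochs * epoch_ms, dt)
        signal = np.sin(2 * np.pi * (times % epoch_ms) / epoch_ms)
        data = 100 + 10 * signal[:, None, None] * np.ones((times.size, 4, 4))
        if noise_sd:
            data = data + rng.normal(0, noise_sd, data.shape)
        events = EventTable(np.arange(n_epochs) * epoch_ms + 500.0, ["s"] * n_epochs)
        spec = hd.EpochSpec(epoch_s=2.0, stim_onset_s=0.5, n_epochs=n_epochs,
                            baseline_window_s=(0.1, 0.4))
        return _stack(data, times), events, spec

    def test_identical_epochs_average_to_single_epoch(self):
        stack, events, spec = self._session()
        avg = hd.epoch_average(stack, events, spec, dt_ms=20.0)
        single = hd.epoch_average(stack, EventTable(events.times_ms[:1], ["s"]), spec, dt_ms=20.0)
        np.testing.assert_allclose(avg.data, single.data, rtol=1e-10)

    def test_noise_reduced_by_epoch_count(self):
        """Averaging n independent-noise epochs cuts noise variance ~n-fold."""
        stack_clean, events, spec = self._session(n_epochs=30)
        stack_noisy, _, _ = self._session(n_epochs=30, noise_sd=5.0, seed=7)
        avg_c = hd.epoch_average(stack_clean, events, spec, dt_ms=20.0)
        avg_n = hd.epoch_average(stack_noisy, events, spec, dt_ms=20.0)
        resid_var = np.var(avg_n.data - avg_c.data)
        assert resid_var == pytest.approx(25.0 / 30, rel=0.35)

    def test_excluded_trial_bookkeeping(self):
        stack, events, spec = self._session(n_epochs=4)
        # corrupt epoch 2 massively; excluding it must restore the clean mean
        data = stack.data.copy()
        sel = (stack.timestamps_ms >= 4000) & (stack.timestamps_ms < 6000)
        data[sel] += 1e6
        corrupted = _stack(data, stack.timestamps_ms)
        avg_all = hd.epoch_average(corrupted, events, spec, dt_ms=20.0)
        avg_excl = hd.epoch_average(corrupted, events, spec, dt_ms=20.0, exclude=(2,))
        clean = hd.epoch_average(stack, events, spec, dt_ms=20.0)
        assert np.abs(avg_all.data - clean.data).max() > 1e4
        np.testing.assert_allclose(avg_excl.data, clean.data, rtol=1e-10)

    def test_event_too_close_to_edge_rejected(self):
        stack, events, spec = self._session()
        bad = EventTable([100.0], ["s"])  # epoch would start before recording
        with pytest.raises(ValueError, match="full epoch"):
            hd.epoch_average(stack, bad, spec, dt_ms=20.0)


class TestComputeResponse:
    def _avg(self, course):
        times = np.arange(0, 10_000.0, 100.0)
        return _stack(course(times)[:, None, None] * np.ones((times.size, 2, 2)), times)

    def test_null_response(self):
        avg = self._avg(lambda t: np.full(t.size, 100.0))
        resp = hd.compute_response(avg, hd.EpochSpec())
        np.testing.assert_allclose(resp.r, 0.0, atol=1e-12)

    def test_ten_percent_excursion(self):
        course = lambda t: np.where((t >= 5000) & (t < 6000), 110.0, 100.0)
        resp = hd.compute_response(self._avg(course), hd.EpochSpec())
        peak = resp.r[(resp.time_s >= 5.0) & (resp.time_s < 6.0)]
        np.testing.assert_allclose(peak, 0.10)

    def test_scale_invariance(self):
        course = lambda t: 100.0 + 5 * np.sin(t / 800.0)
        r1 = hd.compute_response(self._avg(course), hd.EpochSpec()).r
        r2 = hd.compute_response(self._avg(lambda t: 7.3 * course(t)), hd.EpochSpec()).r
        np.testing.assert_allclose(r1, r2, rtol=1e-10)

    def test_nonpositive_baseline_invalid(self):
        avg = self._avg(lambda t: np.full(t.size, -1.0))
        resp = hd.compute_response(avg, hd.EpochSpec())
        assert not resp.valid.any()


class TestStandardPipeline:
    def test_constant_input_yields_zero_response_calcium(self):
        times = np.arange(0, 30_100.0, 66.0)
        stack = _stack(np.full((times.size, 16, 16), 50.0), times, channel="FL")
        events = EventTable([3000.0, 13_000.0, 23_000.0], ["s"] * 3)
        resp = hd.standard_response_pipeline(stack, events, hd.EpochSpec(), "Ca")
        np.testing.assert_allclose(np.nan_to_num(resp.r), 0.0, atol=1e-9)

    def test_static_spatial_pattern_yields_zero_response_hbt(self):
        rng = np.random.default_rng(3)
        pattern = 50.0 + 20.0 * rng.random((16, 16))
        times = np.arange(0, 30_100.0, 66.0)
        stack = _stack(np.repeat(pattern[None], times.size, axis=0), times)
        events = EventTable([3000.0, 13_000.0, 23_000.0], ["s"] * 3)
        resp = hd.standard_response_pipeline(stack, events, hd.EpochSpec(), "HbT")
        assert np.nanmax(np.abs(resp.r)) < 1e-9

    def test_pipeline_scale_invariance(self, quiet_session, epoch_spec):
        stacks, events, _ = quiet_session
        r1 = hd.standard_response_pipeline(stacks["HbT"], events, epoch_spec, "HbT")
        scaled = stacks["HbT"].replace(data=stacks["HbT"].data * 3.5)
        r2 = hd.standard_response_pipeline(scaled, events, epoch_spec, "HbT")
        np.testing.assert_allclose(np.nan_to_num(r1.r), np.nan_to_num(r2.r), atol=1e-7)

    def test_routing_contract(self, quiet_session, epoch_spec):
        stacks, events, _ = quiet_session
        ca = hd.standard_response_pipeline(stacks["Ca"], events, epoch_spec, "Ca")
        hbt = hd.standard_response_pipeline(stacks["HbT"], events, epoch_spec, "HbT")
        assert not any("invert" in s for s in ca.steps)
        assert any("invert" in s for s in hbt.steps)
        assert not any("mean2d" in s for s in hbt.steps)

    def test_dhb_gets_extra_mean_filter(self):
        cfg = synthetic.SessionConfig(
            fov_px=(32, 32), n_epochs=3, channels=("dHb",),
            territories=[synthetic.Territory((16, 16), 6, {"dHb": -0.01}, "stim")],
            seed=5,
        )
        stacks, events, _ = synthetic.simulate_neurovascular_session(cfg)
        resp = hd.standard_response_pipeline(stacks["dHb"], events, hd.EpochSpec(), "dHb")
        assert any("mean2d" in s for s in resp.steps)

    def test_dhb_sign_convention(self):
        """An oxygenation increase (red reflectance up, dHb washout) must give
        a negative dHb response."""
        cfg = synthetic.SessionConfig(
            fov_px=(48, 48), n_epochs=6, channels=("dHb",),
            territories=[synthetic.Territory((24, 24), 10, {"dHb": -0.02}, "stim")],
            seed=5,
        )
        stacks, events, truth = synthetic.simulate_neurovascular_session(cfg)
        resp = hd.standard_response_pipeline(stacks["dHb"], events, hd.EpochSpec(), "dHb")
        window = resp.window(4.0, 7.0)
        centre_course = np.nanmean(resp.r[:, 22:27, 22:27], axis=(1, 2))
        assert centre_course[window].min() < -0.005

    def test_known_response_amplitude_and_timing(self, quiet_session, epoch_spec):
        """Noise-free 2% HbT response: the pipeline peak must match the
        analytically box-smoothed response kernel, at the programmed time."""
        stacks, events, truth = quiet_session
        resp = hd.standard_response_pipeline(stacks["HbT"], events, epoch_spec, "HbT")
        rin = np.where(truth.cortex_mask[None], resp.r, np.nan)
        ti, ri, ci = np.unravel_index(np.nanargmax(rin), rin.shape)
        # oracle: programmed gamma-variate kernel convolved with the 1.01 s box
        t = np.arange(0, 10, 0.01)
        kern = synthetic._hemo_kernel(t - 3.0, 1.0)
        w = 101
        smoothed = np.convolve(kern, np.ones(w) / w, mode="same")
        expected_peak = 0.02 * smoothed.max()
        expected_time = t[smoothed.argmax()]
        assert np.nanmax(rin) == pytest.approx(expected_peak, rel=0.05)
        assert resp.time_s[ti] == pytest.approx(expected_time, abs=0.25)
        assert (ri, ci) == (32, 32)

    def test_raw_response_recovers_programmed_amplitude(self, quiet_session, epoch_spec):
        """Before temporal smoothing, the fractional response equals the
        programmed 2% amplitude."""
        stacks, events, truth = quiet_session
        from widefield.hemodynamics import (
            _invert_stack,
            compute_response,
            epoch_average,
            estimate_illumination,
            illumination_correct,
        )

        work = _invert_stack(stacks["HbT"])
        field = estimate_illumination(work, kernel_px=64, t_window_ms=(0.0, 3000.0))
        work = illumination_correct(work, field)
        avg = epoch_average(work, events, epoch_spec, dt_ms=10.0)
        resp = compute_response(avg, epoch_spec)
        assert np.nanmax(resp.r[:, 32, 32]) == pytest.approx(0.02, rel=0.03)
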