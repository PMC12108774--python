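"""Phantom builder and MGE acquisition simulator."""

import numpy as np
import pytest

from retrogate import (
    DynamicModulation,
    HeartbeatModel,
    PhantomSpec,
    ProtocolSpec,
    TriggerTrain,
    Vial,
    build_phantom,
    default_phantom_spec,
    detect_triggers,
    simulate_pulseox,
    simulate_triggers,
    synthesize_mge,
    vial_masks,
)
from retrogate.fourier import image_to_kspace, kspace_to_image


class TestBuildPhantom:
    def test_default_vials_span_4_to_20_ms(self):
        _, t2 = build_phantom(default_phantom_spec())
        inside = t2[t2 > 0]
        assert inside.min() == 4.0 and inside.max() == 20.0
        assert set(np.unique(inside)) == {4.0, 6.0, 9.0, 12.0, 16.0, 20.0}

    def test_empty_vial_list_gives_zero_images(self):
        s0, t2 = build_phantom(PhantomSpec(grid=(32, 32)))
        assert not s0.any() and not t2.any()

    def test_full_grid_vial_is_uniform(self):
        spec = PhantomSpec(
            grid=(32, 32), vials=(Vial(center=(15.5, 15.5), radius=40.0, s0=100.0, t2star=10.0),)
        )
        s0, _ = build_phantom(spec)
        assert np.all(s0 == 100.0)

    def test_overlapping_vials_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(
                grid=(64, 64),
                vials=(
                    Vial(center=(30, 30), radius=10, s0=1, t2star=5),
                    Vial(center=(35, 30), radius=10, s0=1, t2star=8),
                ),
            )


class TestSimulateTriggers:
    def test_constant_rr(self):
        model = HeartbeatModel(distribution="constant", rr_mean=120.0)
        train = simulate_triggers(model, 1200.0)
        assert train.trigger_times.tolist() == list(np.arange(0.0, 1200.0, 120.0))

    def test_uniform_rr_mean(self):
        # R-R ~ U[80, 160]: sample mean within 3 SE of 120 ms
        model = HeartbeatModel(distribution="uniform", rr_mean=120.0, rr_spread=40.0, seed=11)
        train = simulate_triggers(model, 130_000.0)
        rr = train.rr_intervals
        assert rr.size >= 1000
        se = 80.0 / np.sqrt(12.0) / np.sqrt(rr.size)
        assert abs(rr.mean() - 120.0) < 3 * se
        assert rr.min() >= 80.0 and rr.max() <= 160.0

    def test_failure_rate_doubles_intervals(self):
        base = HeartbeatModel(distribution="constant", rr_mean=120.0, seed=3)
        failed = HeartbeatModel(
            distribution="constant", rr_mean=120.0, failure_rate=0.1, seed=3
        )
        n = 1000
        duration = n * 120.0 + 60.0
        train = simulate_triggers(failed, duration)
        rr = train.rr_intervals
        n_multi = int((rr > 180.0).sum())  # merged (>= double-length) intervals
        # dropping each trigger independently with p=0.1 merges ~10% of beats;
        # allow a generous binomial band
        p = 0.1
        expect = p * n
        sd = np.sqrt(n * p * (1 - p))
        assert expect - 4 * sd < n_multi < expect + 4 * sd
        assert simulate_triggers(base, duration).n_triggers > train.n_triggers

    def test_replay_from_file_cycles_values(self):
        model = HeartbeatModel(
            distribution="replay_from_file", rr_mean=100.0, rr_values=(90.0, 110.0, 100.0)
        )
        train = simulate_triggers(model, 1000.0)
        assert train.rr_intervals[:3].tolist() == [90.0, 110.0, 100.0]

    def test_determinism(self):
        model = HeartbeatModel(distribution="gaussian", rr_mean=120.0, rr_spread=5.0, seed=9)
        a = simulate_triggers(model, 10_000.0)
        b = simulate_triggers(model, 10_000.0)
        assert np.array_equal(a.trigger_times, b.trigger_times)


class TestSimulatePulseox:
    def test_noiseless_peaks_at_trigger_times(self):
        train = TriggerTrain(50.0 + np.arange(10) * 120.0)
        fs = 1000.0
        trace = simulate_pulseox(train, fs)
        for tk in train.trigger_times:
            lo, hi = int((tk - 30) * fs / 1000), int((tk + 30) * fs / 1000)
            peak = lo + np.argmax(trace[lo:hi])
            assert abs(peak * 1000.0 / fs - tk) <= 1000.0 / fs

    def test_roundtrip_recovers_train(self):
        train = TriggerTrain(80.0 + np.cumsum(np.full(40, 130.0)))
        det = detect_triggers(simulate_pulseox(train, 1000.0), 1000.0)
        assert det.n_triggers == train.n_triggers
        assert np.abs(det.trigger_times - train.trigger_times).max() <= 1.0

    def test_quantization_error_bound_halves_with_sampling_rate(self):
        # beat times deliberately off the sample grid
        train = TriggerTrain(100.0 + np.cumsum(np.full(30, 120.37)))
        for fs in (250.0, 500.0):
            det = detect_triggers(simulate_pulseox(train, fs), fs, smooth_ms=0.0)
            err = np.abs(det.trigger_times[None] - train.trigger_times[:, None]).min(axis=1)
            # sub-sample refinement keeps errors within the half-sample bound
            assert err.max() <= 0.5 * 1000.0 / fs


class TestSynthesizeMGE:
    def test_first_echo_kspace_inverts_to_decay_weighted_image(self, small_sim, small_phantom):
        s0, t2 = build_phantom(small_phantom)
        proto = small_sim.kspace.protocol
        sel = small_sim.kspace.meas_index == 0
        order = np.argsort(small_sim.kspace.pe_index[sel])
        k = small_sim.kspace.data[sel][order][:, 0, :]  # first echo, rows in pe order
        img = np.abs(kspace_to_image(k))
        ideal = s0 * np.exp(-proto.te1 / np.where(t2 > 0, t2, np.inf))
        assert np.abs(img - ideal).max() < 1e-10 * ideal.max()

    def test_default_echo_times(self):
        te = ProtocolSpec().echo_times
        assert np.allclose(te, [1.5, 3.1, 4.7, 6.3, 7.9, 9.5, 11.1])

    def test_line_timestamps_follow_ttl_and_tr(self, small_sim):
        proto = small_sim.kspace.protocol
        for m in (0, 7, proto.n_measurements - 1):
            sel = small_sim.kspace.meas_index == m
            ts = np.sort(small_sim.kspace.timestamps_ms[sel])
            start = small_sim.ttl.measurement_start_times[m]
            assert np.allclose(ts, start + np.arange(proto.n_pe) * proto.tr)

    def test_total_duration_is_continuous(self, small_sim):
        proto = small_sim.kspace.protocol
        assert small_sim.ttl.measurement_end_times[-1] == pytest.approx(proto.duration)
        gaps = small_sim.ttl.measurement_start_times[1:] - small_sim.ttl.measurement_end_times[:-1]
        assert np.allclose(gaps, 0.0)

    def test_static_measurements_identical(self, small_sim):
        proto = small_sim.kspace.protocol
        d = small_sim.kspace.data
        m0 = d[small_sim.kspace.meas_index == 0]
        m5 = d[small_sim.kspace.meas_index == 5]
        assert np.array_equal(m0, m5)

    def test_seed_determinism(self, small_phantom, small_protocol, constant_train):
        a = synthesize_mge(small_phantom, small_protocol, constant_train, noise_sd=2.0, seed=4)
        b = synthesize_mge(small_phantom, small_protocol, constant_train, noise_sd=2.0, seed=4)
        assert np.array_equal(a.kspace.data, b.kspace.data)

    def test_noise_sd_calibration(self, small_phantom, small_protocol, constant_train):
        clean = synthesize_mge(small_phantom, small_protocol, constant_train)
        noisy = synthesize_mge(small_phantom, small_protocol, constant_train, noise_sd=3.0, seed=8)
        diff = noisy.kspace.data - clean.kspace.data
        assert diff.size >= 10**5
        assert diff.real.std() == pytest.approx(3.0, rel=0.02)
        assert diff.imag.std() == pytest.approx(3.0, rel=0.02)

    def test_dynamic_modulation_scales_decay(self, small_phantom, constant_train):
        proto = ProtocolSpec(matrix=(32, 32), n_measurements=2)
        mod = DynamicModulation.sinusoid(0.2)
        sim = synthesize_mge(small_phantom, proto, constant_train, modulation=mod)
        # oracle: rebuild one line's k-space row from the pixelwise model
        s0, t2 = build_phantom(small_phantom)
        i = 17
        line = np.flatnonzero((sim.kspace.meas_index == 1) & (sim.kspace.pe_index == i))[0]
        t = sim.kspace.timestamps_ms[line]
        times = constant_train.trigger_times
        k = np.searchsorted(times, t, side="right") - 1
        u = (t - times[k]) / (times[k + 1] - times[k])
        f = 1.0 + 0.2 * np.sin(2 * np.pi * u)
        for e, te in enumerate(proto.echo_times):
            img = s0 * np.exp(-te / np.where(t2 > 0, t2 * f, np.inf))
            expected = image_to_kspace(img)[i]
            assert np.abs(sim.kspace.data[line, e] - expected).max() < 1e-10

    def test_modulation_outside_train_errors(self, small_phantom):
        proto = ProtocolSpec(matrix=(32, 32), n_measurements=2)
        short_train = TriggerTrain([0.0, 120.0])  # does not cover the acquisition
        with pytest.raises(ValueError, match="modulation undefined"):
            synthesize_mge(
                small_phantom, proto, short_train, modulation=DynamicModulation.sinusoid(0.1)
            )
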