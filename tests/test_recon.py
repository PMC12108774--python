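"""Binning reconstruction: phase correction, averaging, Fourier inversion."""

import numpy as np
import pytest
from dataclasses import replace

from retrogate import (
    HeartbeatModel,
    assign_phases,
    bin_and_average,
    build_phantom,
    filter_rr,
    nema_snr,
    phase_correct,
    reconstruct,
    reconstruct_reference,
    simulate_triggers,
    synthesize_mge,
)
from retrogate.physio import DiscardReason, PhaseAssignment
from retrogate.recon import REFERENCE, ReconError


def _uniform_assignment(lines, n_phases=4, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_phases, lines.n_lines)
    reasons = np.zeros(lines.n_lines, dtype=int)
    return PhaseAssignment(labels=labels, reasons=reasons, n_phases=n_phases)


class TestPhaseCorrect:
    def test_identity_on_static_noiseless_data(self, small_sim):
        out = phase_correct(small_sim.kspace, reference_measurement=0)
        assert np.abs(out.data - small_sim.kspace.data).max() < 1e-12

    def test_removes_constant_phase_offset(self, small_sim):
        data = small_sim.kspace.data.copy()
        bad = small_sim.kspace.meas_index == 3
        data[bad] *= np.exp(1j * 0.3)
        corrupted = replace(small_sim.kspace, data=data)
        out = phase_correct(corrupted, reference_measurement=0)
        ref = small_sim.kspace.data[bad]
        assert np.abs(out.data[bad] - ref).max() < 1e-9 * np.abs(ref).max()

    def test_removes_linear_phase_ramp(self, small_sim):
        # a linear phase ramp in k-space is a readout shift (Fourier shift theorem)
        n_ro = small_sim.kspace.n_readout
        ramp = np.exp(1j * 2 * np.pi * (np.arange(n_ro) - n_ro // 2) / n_ro)
        data = small_sim.kspace.data.copy()
        bad = small_sim.kspace.meas_index == 3
        data[bad] *= ramp
        out = phase_correct(replace(small_sim.kspace, data=data), reference_measurement=0)
        ref = small_sim.kspace.data[bad]
        assert np.abs(out.data[bad] - ref).max() < 1e-6 * np.abs(ref).max()

    def test_missing_reference_lines_error(self, small_sim):
        keep = ~(
            (small_sim.kspace.meas_index == 0) & (small_sim.kspace.pe_index == 5)
        )
        truncated = replace(
            small_sim.kspace,
            data=small_sim.kspace.data[keep],
            pe_index=small_sim.kspace.pe_index[keep],
            meas_index=small_sim.kspace.meas_index[keep],
            timestamps_ms=small_sim.kspace.timestamps_ms[keep],
        )
        with pytest.raises(ReconError, match="missing"):
            phase_correct(truncated, reference_measurement=0)

    def test_idempotent_on_corrected_data(self, small_sim):
        data = small_sim.kspace.data.copy()
        rng = np.random.default_rng(2)
        for m in range(small_sim.kspace.protocol.n_measurements):
            sel = small_sim.kspace.meas_index == m
            data[sel] *= np.exp(1j * rng.uniform(-0.5, 0.5))
        once = phase_correct(replace(small_sim.kspace, data=data), 0)
        twice = phase_correct(once, 0)
        assert np.abs(twice.data - once.data).max() < 1e-9


class TestBinAndAverage:
    def test_static_bins_equal_global_mean(self, small_sim):
        a = _uniform_assignment(small_sim.kspace)
        binned = bin_and_average(small_sim.kspace, a)
        # all lines of one (pe) are identical, so every non-empty bin equals it
        proto = small_sim.kspace.protocol
        first = small_sim.kspace.data[small_sim.kspace.meas_index == 0]
        pe_first = small_sim.kspace.pe_index[small_sim.kspace.meas_index == 0]
        for p in range(a.n_phases):
            for pe in range(proto.n_pe):
                if binned.counts[p, 0, pe] > 0:
                    expected = first[pe_first == pe][0]
                    scale = np.abs(expected).max()
                    assert np.abs(binned.data[p, :, pe, :] - expected).max() < 1e-12 * scale

    def test_count_conservation(self, small_sim, constant_train):
        f = filter_rr(constant_train)
        a = assign_phases(small_sim.kspace.timestamps_ms, constant_train, f, 10)
        binned = bin_and_average(small_sim.kspace, a)
        proto = small_sim.kspace.protocol
        total = binned.counts.sum(axis=0) + binned.discarded
        assert np.all(total == proto.n_measurements)

    def test_counts_match_gating_oracle(self, small_sim, constant_train):
        f = filter_rr(constant_train)
        a = assign_phases(small_sim.kspace.timestamps_ms, constant_train, f, 10)
        binned = bin_and_average(small_sim.kspace, a)
        # exhaustive enumeration over all lines
        expected = np.zeros((10, small_sim.kspace.protocol.n_pe), dtype=int)
        for label, pe in zip(a.labels, small_sim.kspace.pe_index):
            if label >= 0:
                expected[label, pe] += 1
        assert np.array_equal(binned.counts[:, 0, :], expected)


class TestReconstruct:
    def test_zero_kspace_gives_zero_image(self, small_sim):
        a = _uniform_assignment(small_sim.kspace, n_phases=1)
        binned = bin_and_average(small_sim.kspace, a)
        zeroed = replace(binned, data=np.zeros_like(binned.data))
        series = reconstruct(zeroed, 0)
        assert np.abs(series.images).max() == 0.0

    def test_linearity(self, small_sim):
        a = _uniform_assignment(small_sim.kspace, n_phases=1)
        binned = bin_and_average(small_sim.kspace, a)
        doubled = replace(binned, data=2.5 * binned.data)
        img1 = reconstruct(binned, 0).images
        img2 = reconstruct(doubled, 0).images
        assert np.abs(img2 - 2.5 * img1).max() < 1e-12 * np.abs(img1).max()

    def test_missing_line_equals_subtracted_contribution(self, small_sim):
        from retrogate.fourier import kspace_to_image

        a = _uniform_assignment(small_sim.kspace, n_phases=1)
        binned = bin_and_average(small_sim.kspace, a)
        gap = replace(binned, data=binned.data.copy(), counts=binned.counts.copy())
        gap.data[0, :, 7, :] = 0.0
        gap.counts[0, :, 7] = 0
        full = reconstruct(binned, 0).images
        partial = reconstruct(gap, 0, allow_partial=True).images
        only_line = np.zeros_like(binned.data[0])
        only_line[:, 7, :] = binned.data[0, :, 7, :]
        assert np.abs(partial - (full - kspace_to_image(only_line))).max() < 1e-12

    def test_low_fill_raises_unless_allowed(self, small_sim):
        a = _uniform_assignment(small_sim.kspace, n_phases=1)
        binned = bin_and_average(small_sim.kspace, a)
        sparse = replace(binned, counts=binned.counts.copy())
        sparse.counts[0, :, :16] = 0  # half the pe rows empty
        with pytest.raises(ReconError, match="fill fraction"):
            reconstruct(sparse, 0)
        with pytest.warns(RuntimeWarning, match="zero-filled"):
            series = reconstruct(sparse, 0, allow_partial=True)
        assert series.fill_fraction == 0.5


class TestReference:
    def test_reference_equals_single_phase_binning(self, small_sim):
        ref = reconstruct_reference(small_sim.kspace)
        labels = np.zeros(small_sim.kspace.n_lines, dtype=int)
        a = PhaseAssignment(labels=labels, reasons=labels.copy(), n_phases=1)
        binned = bin_and_average(small_sim.kspace, a)
        series = reconstruct(binned, 0)
        assert np.array_equal(ref.images, series.images)
        assert ref.phase_label == REFERENCE

    def test_noiseless_reference_independent_of_n_measurements(
        self, small_phantom, small_protocol, constant_train
    ):
        from retrogate import ProtocolSpec

        short = ProtocolSpec(matrix=(32, 32), n_measurements=3)
        sim_short = synthesize_mge(small_phantom, short, constant_train)
        sim_long = synthesize_mge(small_phantom, small_protocol, constant_train)
        a = reconstruct_reference(sim_short.kspace).images
        b = reconstruct_reference(sim_long.kspace).images
        assert np.abs(a - b).max() < 1e-12

    def test_per_phase_equals_reference_for_static_noiseless(self, small_sim, constant_train):
        f = filter_rr(constant_train)
        a = assign_phases(small_sim.kspace.timestamps_ms, constant_train, f, 5)
        binned = bin_and_average(small_sim.kspace, a)
        ref = reconstruct_reference(small_sim.kspace)
        for p in range(5):
            series = reconstruct(binned, p, allow_partial=True)
            assert np.abs(series.magnitude - ref.magnitude).max() < 1e-9

    def test_reference_snr_scales_with_sqrt_n_measurements(self, small_phantom):
        # SNR of the averaged reference image grows as sqrt(n_measurements)
        from retrogate import ProtocolSpec

        noise_sd = 5.0
        snrs = {}
        for n_meas in (30, 300):
            proto = ProtocolSpec(matrix=(32, 32), n_measurements=n_meas)
            train = simulate_triggers(
                HeartbeatModel(distribution="constant", rr_mean=119.0, seed=0),
                proto.duration + 300.0,
            )
            sim = synthesize_mge(small_phantom, proto, train, noise_sd=noise_sd, seed=13)
            mag = reconstruct_reference(sim.kspace).magnitude[0]
            s0, _ = build_phantom(small_phantom)
            signal_roi = s0 > 0
            bg = np.zeros_like(signal_roi)
            bg[:4, :] = True
            bg[-4:, :] = True
            snrs[n_meas] = nema_snr(mag, signal_roi, bg)
        ratio = snrs[300] / snrs[30]
        assert ratio == pytest.approx(np.sqrt(10.0), rel=0.15)
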