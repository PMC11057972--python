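"""Spike detection, clustering, spike-triggered averaging, morphology."""

import math

import numpy as np
import pytest

from myospect import (
    EmgSignal,
    MotorUnitModel,
    MuapWaveform,
    cluster_muaps,
    count_phases,
    dedupe_waveforms,
    detect_spikes,
    measure_duration,
    median_frequency,
    periodogram,
    spike_triggered_average,
    waveform_snr,
)
from myospect.muap_estimation import TriggerSet
from myospect.synthetic_data import _unit_kernel, surface_template

from conftest import FS


def _train_signal(kernel, spike_idx, n, noise_sd, rng):
    """Place a kernel at known sample indices plus white noise."""
    x = np.zeros(n)
    half = (len(kernel) - 1) // 2
    for c in spike_idx:
        x[c - half : c - half + len(kernel)] += kernel
    if noise_sd:
        x += rng.normal(0, noise_sd, n)
    return EmgSignal(x, FS)


@pytest.fixture
def template_kernel():
    # order-2: unambiguous central extremum for alignment checks
    return _unit_kernel(MotorUnitModel(2, 1.0, 2.5, 8.0, 0.1), FS)


class TestDetectSpikes:
    def test_all_zero_gives_empty(self):
        sig = EmgSignal(np.zeros(int(2 * FS)), FS)
        assert len(detect_spikes(sig)) == 0

    def test_recall_precision_at_snr10(self, template_kernel, rng):
        spacing = int(0.1 * FS)
        spike_idx = np.arange(20, 400) * spacing
        n = spike_idx[-1] + spacing
        noise_sd = np.max(np.abs(template_kernel)) / 10
        sig = _train_signal(template_kernel, spike_idx, n, noise_sd, rng)
        triggers = detect_spikes(sig)
        det = np.round(triggers.times * FS).astype(int)
        d = np.abs(det[:, None] - spike_idx[None, :])
        tol = round(1e-3 * FS)
        precision = (d.min(axis=1) <= tol).mean()
        recall = (d.min(axis=0) <= tol).mean()
        assert precision >= 0.95 and recall >= 0.95

    def test_peak_alignment_at_snr20(self, rng):
        # sharp intramuscular-style spike: the extremum is steep enough
        # that noise cannot move the detected peak more than one sample
        kernel = _unit_kernel(MotorUnitModel(2, 1.0, 0.3, 8.0, 0.1), FS)
        spacing = int(0.1 * FS)
        spike_idx = np.arange(20, 200) * spacing
        noise_sd = np.max(np.abs(kernel)) / 20
        sig = _train_signal(kernel, spike_idx, spike_idx[-1] + spacing, noise_sd, rng)
        det = np.round(detect_spikes(sig).times * FS).astype(int)
        d = det[:, None] - spike_idx[None, :]
        nearest = np.abs(d).min(axis=1)
        matched = nearest[nearest <= 5]
        # kernel extremum is at the spike index: alignment within 1 sample
        assert np.quantile(matched, 0.95) <= 1


class TestClusterMuaps:
    def test_two_distinct_templates_fully_separated(self, rng):
        k1 = _unit_kernel(MotorUnitModel(1, 1.0, 2.0, 8.0, 0.1), FS)
        k2 = _unit_kernel(MotorUnitModel(2, 1.0, 4.0, 8.0, 0.1), FS)
        spacing = int(0.1 * FS)
        idx = np.arange(20, 80) * spacing
        x = np.zeros(idx[-1] + spacing)
        labels = np.tile([0, 1], len(idx) // 2)
        for c, lab in zip(idx, labels):
            k = k1 if lab == 0 else k2
            half = (len(k) - 1) // 2
            x[c - half : c - half + len(k)] += k
        x += rng.normal(0, 0.01, len(x))
        sig = EmgSignal(x, FS)
        triggers = TriggerSet(idx / FS)
        clusters = cluster_muaps(sig, triggers)
        assert len(clusters) == 2
        # purity: each cluster maps to one generating label
        for cl in clusters:
            cl_idx = np.round(cl.times * FS).astype(int)
            got = labels[np.searchsorted(idx, cl_idx)]
            assert len(set(got.tolist())) == 1

    def test_single_template_single_cluster(self, template_kernel, rng):
        spacing = int(0.1 * FS)
        idx = np.arange(20, 60) * spacing
        sig = _train_signal(template_kernel, idx, idx[-1] + spacing, 0.01, rng)
        clusters = cluster_muaps(sig, TriggerSet(idx / FS))
        assert len(clusters) == 1
        assert len(clusters[0]) == len(idx)

    def test_amplitude_is_a_grouping_feature(self, template_kernel, rng):
        spacing = int(0.1 * FS)
        idx = np.arange(20, 80) * spacing
        x = np.zeros(idx[-1] + spacing)
        half = (len(template_kernel) - 1) // 2
        for j, c in enumerate(idx):
            scale = 1.0 if j % 2 == 0 else 3.0
            x[c - half : c - half + len(template_kernel)] += scale * template_kernel
        sig = EmgSignal(x + rng.normal(0, 0.005, len(x)), FS)
        clusters = cluster_muaps(sig, TriggerSet(idx / FS))
        assert len(clusters) == 2


class TestSpikeTriggeredAverage:
    def test_noise_free_recovery_is_exact(self, template_kernel):
        spacing = int(0.1 * FS)
        idx = np.arange(20, 140) * spacing
        sig = _train_signal(template_kernel, idx, idx[-1] + spacing, 0.0, None)
        wf = spike_triggered_average(sig, TriggerSet(idx / FS))
        expected = np.zeros(1500)
        half = (len(template_kernel) - 1) // 2
        center = (1500 - 1) // 2
        expected[center - half : center - half + len(template_kernel)] = template_kernel
        np.testing.assert_array_almost_equal(wf.samples, expected, decimal=12)
        assert wf.n_windows == len(idx)

    def test_rmse_within_standard_error_bound(self, template_kernel, rng):
        sigma = 0.1
        spacing = int(0.1 * FS)
        idx = np.arange(20, 420) * spacing  # 400 triggers
        sig = _train_signal(template_kernel, idx, idx[-1] + spacing, sigma, rng)
        wf = spike_triggered_average(sig, TriggerSet(idx / FS))
        expected = np.zeros(1500)
        half = (len(template_kernel) - 1) // 2
        center = (1500 - 1) // 2
        expected[center - half : center - half + len(template_kernel)] = template_kernel
        rmse = np.sqrt(np.mean((wf.samples - expected) ** 2))
        assert rmse <= 2 * sigma / math.sqrt(400)

    def test_convergence_rate_one_over_sqrt_n(self, template_kernel, rng):
        sigma = 0.1
        spacing = int(0.08 * FS)
        rmses = []
        ns = [100, 400, 1600]
        for n_triggers in ns:
            vals = []
            for _ in range(3):
                idx = np.arange(10, 10 + n_triggers) * spacing
                sig = _train_signal(template_kernel, idx, idx[-1] + spacing, sigma, rng)
                wf = spike_triggered_average(sig, TriggerSet(idx / FS))
                expected = np.zeros(1500)
                half = (len(template_kernel) - 1) // 2
                center = (1500 - 1) // 2
                expected[center - half : center - half + len(template_kernel)] = template_kernel
                vals.append(np.sqrt(np.mean((wf.samples - expected) ** 2)))
            rmses.append(np.mean(vals))
        slope = np.polyfit(np.log(ns), np.log(rmses), 1)[0]
        assert abs(slope - (-0.5)) < 0.1

    def test_insufficient_triggers_error_names_count(self, template_kernel):
        spacing = int(0.1 * FS)
        idx = np.arange(20, 70) * spacing  # 50 triggers
        sig = _train_signal(template_kernel, idx, idx[-1] + spacing, 0.0, None)
        with pytest.raises(ValueError, match="50"):
            spike_triggered_average(sig, TriggerSet(idx / FS))

    def test_sign_flip_flips_recovery(self, template_kernel):
        spacing = int(0.1 * FS)
        idx = np.arange(20, 140) * spacing
        sig = _train_signal(template_kernel, idx, idx[-1] + spacing, 0.0, None)
        flipped = sig.with_samples(-sig.samples)
        wf = spike_triggered_average(sig, TriggerSet(idx / FS))
        wf_flipped = spike_triggered_average(flipped, TriggerSet(idx / FS))
        np.testing.assert_array_equal(wf_flipped.samples, -wf.samples)


class TestWaveformSnr:
    def test_zero_baseline_gives_inf(self):
        wf = surface_template(MotorUnitModel(1, 1.0, 2.0, 8.0, 0.1), fs=FS)
        assert waveform_snr(wf) == math.inf

    def test_constructed_snr_near_20(self, rng):
        base = surface_template(MotorUnitModel(1, 1.0, 2.0, 8.0, 0.1), fs=FS)
        p2p = np.ptp(base.samples)
        noisy = MuapWaveform(base.samples + rng.normal(0, p2p / 20, len(base.samples)), FS)
        assert waveform_snr(noisy) == pytest.approx(20.0, rel=0.25)

    def test_pure_noise_flagged_for_discard(self, rng):
        # Gaussian range statistics: p2p of 1500 samples / edge SD ~ 6-8,
        # but the discard decision is about the absence of a dominant peak
        snrs = []
        for _ in range(20):
            wf = MuapWaveform(rng.normal(0, 1.0, 1500), FS)
            snrs.append(waveform_snr(wf))
        assert np.median(snrs) < 9.0  # far below any clean MUAP


class TestDedupe:
    def test_keeps_highest_snr_copy(self, rng):
        base = surface_template(MotorUnitModel(1, 1.0, 2.0, 8.0, 0.1), fs=FS)
        lo = MuapWaveform(base.samples + rng.normal(0, 0.02, 1500), FS, snr=10.0, unit_id="lo")
        hi = MuapWaveform(base.samples + rng.normal(0, 0.005, 1500), FS, snr=30.0, unit_id="hi")
        kept = dedupe_waveforms([lo, hi])
        assert len(kept) == 1 and kept[0].unit_id == "hi"

    def test_distinct_waveforms_both_kept(self):
        a = surface_template(MotorUnitModel(1, 1.0, 2.0, 8.0, 0.1), fs=FS)
        b = surface_template(MotorUnitModel(2, 1.0, 4.0, 8.0, 0.1), fs=FS)
        a.snr, b.snr = 10.0, 12.0
        assert len(dedupe_waveforms([a, b])) == 2

    def test_empty_input(self):
        assert dedupe_waveforms([]) == []


class TestMorphology:
    def test_duration_matches_threshold_scan_oracle(self):
        wf = surface_template(MotorUnitModel(1, 1.0, 4.0, 8.0, 0.1), fs=FS)
        measured = measure_duration(wf)
        # brute-force oracle: first/last sample with |h| above the 1%-of-peak
        # relative floor used for noise-free waveforms
        thr = 0.01 * np.max(np.abs(wf.samples))
        above = np.flatnonzero(np.abs(wf.samples) > thr)
        oracle_ms = (above[-1] - above[0]) / FS * 1000.0
        assert measured == pytest.approx(oracle_ms, abs=0.1)
        assert wf.duration_ms == measured

    def test_doubling_lambda_doubles_duration(self):
        d1 = measure_duration(surface_template(MotorUnitModel(1, 1.0, 3.0, 8.0, 0.1), fs=FS))
        d2 = measure_duration(surface_template(MotorUnitModel(1, 1.0, 6.0, 8.0, 0.1), fs=FS))
        assert d2 == pytest.approx(2 * d1, abs=2000.0 / FS)

    def test_all_zero_waveform_rejected(self):
        wf = MuapWaveform(np.zeros(1500), FS)
        with pytest.raises(ValueError):
            measure_duration(wf)

    def test_phase_counts_match_lobe_structure(self):
        t = np.arange(1500)
        mono = MuapWaveform(np.exp(-(((t - 750) / 60.0) ** 2)), FS)
        assert count_phases(mono) == 1
        biphasic = surface_template(MotorUnitModel(1, 1.0, 4.0, 8.0, 0.1), fs=FS)
        assert count_phases(biphasic) == 2
        triphasic = surface_template(MotorUnitModel(2, 1.0, 4.0, 8.0, 0.1), fs=FS)
        assert count_phases(triphasic) == 3


class TestPipelineSelfConsistency:
    def test_sta_waveform_mdf_matches_template(self, rng):
        unit = MotorUnitModel(1, 1.0, 2.5, 8.0, 0.1)
        kernel = _unit_kernel(unit, FS)
        spacing = int(0.1 * FS)
        idx = np.arange(20, 240) * spacing  # N >= 200
        noise_sd = np.ptp(kernel) / 10
        sig = _train_signal(kernel, idx, idx[-1] + spacing, noise_sd, rng)
        wf = spike_triggered_average(sig, TriggerSet(idx / FS))
        template = surface_template(unit, fs=FS)
        ps = periodogram(template)
        mdf_t = median_frequency(ps, band=(20.0, 1000.0))
        mdf_w = median_frequency(periodogram(wf), band=(20.0, 1000.0))
        assert abs(mdf_w - mdf_t) <= ps.delta_f
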