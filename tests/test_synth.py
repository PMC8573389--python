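import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram

from megfc.connectivity import pair_correlation
from megfc.io import read_events, read_study
from megfc.preprocess import band_by_name, bandpass_array
from megfc.synth import (
    CouplingSpec,
    SimulationConfig,
    StudyConfig,
    SwdSpec,
    default_region_scheme,
    gamma_recovery_design,
    gen_background,
    gen_swd,
    inject_coupling,
    seizure_plan,
    simulate_recording,
    simulate_study,
)
from megfc.datasets import cae_clinical_table


class TestBackground:
    def test_deterministic_for_fixed_seed(self):
        a = gen_background(3, 2.0, 1200, slope=1.0, seed=42)
        b = gen_background(3, 2.0, 1200, slope=1.0, seed=42)
        assert np.array_equal(a.data, b.data)

    def test_seed_changes_output(self):
        a = gen_background(3, 2.0, 1200, seed=1)
        b = gen_background(3, 2.0, 1200, seed=2)
        assert not np.array_equal(a.data, b.data)

    def test_white_noise_channels_uncorrelated(self):
        rec = gen_background(2, 10.0, 6000, slope=0.0, seed=7)
        assert abs(pair_correlation(rec.data[0], rec.data[1])) < 0.05

    def test_channels_centered(self):
        rec = gen_background(4, 5.0, 1200, slope=1.0, seed=3)
        assert np.allclose(rec.data.mean(axis=1), 0, atol=1e-12)

    @pytest.mark.parametrize("slope", [0.0, 1.0, 2.0])
    def test_psd_slope(self, slope):
        # periodogram log-log regression as an independent oracle
        rec = gen_background(1, 30.0, 1200, slope=slope, seed=11)
        f, p = periodogram(rec.data[0], fs=1200)
        sel = (f >= 1) & (f <= 300)
        fit = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert abs(fit - (-slope)) < 0.2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gen_background(2, -1.0, 1200)
        with pytest.raises(ValueError):
            gen_background(2, 1.0, 0)


class TestInjectCoupling:
    def gamma_pair_spec(self, rho, window=(0.0, 3.0)):
        return CouplingSpec(band_by_name("gamma"), frozenset({0, 1}), rho, window)

    def test_zero_coupling_is_identity(self):
        rec = gen_background(3, 3.0, 1200, seed=5)
        out = inject_coupling(rec, self.gamma_pair_spec(0.0), seed=9)
        assert np.array_equal(out.data, rec.data)

    def test_locality_channels(self):
        rec = gen_background(3, 3.0, 1200, seed=5)
        out = inject_coupling(rec, self.gamma_pair_spec(0.8), seed=9)
        assert np.array_equal(out.data[2], rec.data[2])
        assert not np.array_equal(out.data[0], rec.data[0])

    def test_locality_window(self):
        rec = gen_background(2, 6.0, 1200, seed=5)
        out = inject_coupling(rec, self.gamma_pair_spec(0.8, window=(2.0, 5.0)), seed=9)
        s0, s1 = 2 * 1200, 5 * 1200
        assert np.array_equal(out.data[:, :s0], rec.data[:, :s0])
        assert np.array_equal(out.data[:, s1:], rec.data[:, s1:])

    def test_target_correlation_reached(self):
        rec = gen_background(2, 3.0, 6000, seed=5)
        out = inject_coupling(rec, self.gamma_pair_spec(0.8), seed=9)
        band = bandpass_array(out.data, band_by_name("gamma"), 6000)
        r = pair_correlation(band[0], band[1])
        assert r == pytest.approx(0.8, abs=0.1)

    def test_uncoupled_channel_correlation_unchanged(self):
        rec = gen_background(3, 3.0, 6000, seed=5)
        out = inject_coupling(rec, self.gamma_pair_spec(0.8), seed=9)
        band_in = bandpass_array(rec.data, band_by_name("gamma"), 6000)
        band_out = bandpass_array(out.data, band_by_name("gamma"), 6000)
        r_in = pair_correlation(band_in[0], band_in[2])
        r_out = pair_correlation(band_out[0], band_out[2])
        assert abs(r_out - r_in) < 0.1

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_calibration_over_replicates(self, rho):
        # mean recovered in-band correlation within +-0.05 of target at K=18000
        band = band_by_name("gamma")
        vals = []
        for seed in range(50):
            rec = gen_background(2, 3.0, 6000, seed=1000 + seed)
            out = inject_coupling(
                rec, CouplingSpec(band, frozenset({0, 1}), rho, (0.0, 3.0)), seed=seed
            )
            filt = bandpass_array(out.data, band, 6000)
            vals.append(pair_correlation(filt[0], filt[1]))
        assert np.mean(vals) == pytest.approx(rho, abs=0.05)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(band_by_name("gamma"), frozenset({0, 1}), 1.0, (0.0, 1.0))
        with pytest.raises(ValueError):
            CouplingSpec(band_by_name("gamma"), frozenset({0, 1}), -0.1, (0.0, 1.0))

    def test_out_of_range_group_rejected(self):
        rec = gen_background(2, 1.0, 1200, seed=0)
        spec = CouplingSpec(band_by_name("gamma"), frozenset({0, 5}), 0.5, (0.0, 1.0))
        with pytest.raises(ValueError):
            inject_coupling(rec, spec)


class TestSwd:
    def test_cycle_count(self):
        w = gen_swd(SwdSpec(repetition_rate=3.0), 4.0, 1200)
        peaks, _ = find_peaks(w, height=0.9 * SwdSpec().amplitude_ratio)
        assert len(peaks) == 12  # 3 Hz x 4 s

    def test_spectral_peak_at_repetition_rate(self):
        w = gen_swd(SwdSpec(repetition_rate=3.0), 8.0, 1200)
        f, p = periodogram(w, fs=1200)
        sel = (f >= 1) & (f <= 10)
        assert f[sel][np.argmax(p[sel])] == pytest.approx(3.0, abs=0.2)

    def test_pure_wave_when_ratio_zero(self):
        w = gen_swd(SwdSpec(amplitude_ratio=0.0), 2.0, 1200)
        assert np.max(np.abs(w)) == pytest.approx(1.0, abs=1e-6)
        assert np.max(w) <= 1e-9  # wave is a negative deflection

    def test_widths_must_fit_cycle(self):
        with pytest.raises(ValueError):
            SwdSpec(repetition_rate=3.0, spike_width_s=0.2, wave_width_s=0.2)

    def test_smooth_across_cycle_boundary(self):
        # no jump discontinuities (these would leak into high bands)
        w = gen_swd(SwdSpec(), 2.0, 6000)
        assert np.max(np.abs(np.diff(w))) < 0.05


class TestSimulateRecording:
    def test_deterministic(self):
        cfg = gamma_recovery_design(seed=3).seizures[0].config
        a, _ = simulate_recording(cfg)
        b, _ = simulate_recording(cfg)
        assert np.array_equal(a.data, b.data)

    def test_event_attached(self):
        cfg = gamma_recovery_design(seed=3).seizures[0].config
        _, ev = simulate_recording(cfg)
        assert ev is not None and ev.duration_s >= 6.0


class TestStudy:
    def tiny_study(self, n_seizures=3):
        clinical = cae_clinical_table().head(n_seizures).copy()
        seizures = []
        for i, patient in enumerate(clinical["patient"]):
            seizures.append(
                type(gamma_recovery_design(seed=0).seizures[0])(
                    recording_id=f"p{patient:02d}_s1",
                    patient=patient,
                    config=SimulationConfig(
                        n_channels=4, duration_s=10.0, fs=200.0, seed=i, event=(1.0, 8.0)
                    ),
                )
            )
        return StudyConfig(seizures=seizures, clinical=clinical)

    def test_seizure_plan_counts(self):
        plan = seizure_plan(cae_clinical_table())
        assert len(plan) == 22
        assert sum(1 for _, n in plan if n == 1) == 11
        assert sum(1 for _, n in plan if n == 2) == 11
        assert sum(n for _, n in plan) == 33

    def test_event_records_written(self, tmp_path):
        simulate_study(self.tiny_study(), out_dir=tmp_path)
        events = read_events(tmp_path / "events.tsv")
        assert len(events) == 3
        assert (events["offset_s"] - events["onset_s"] >= 6.0).all()

    def test_round_trip(self, tmp_path):
        ds = simulate_study(self.tiny_study(), out_dir=tmp_path)
        back = read_study(tmp_path)
        assert len(back.records) == len(ds.records)
        (rec_id, patient, rec, ev) = back.records[0]
        orig = next(r for r in ds.records if r[0] == rec_id)
        assert np.allclose(rec.data, orig[2].data)
        assert rec.fs == orig[2].fs

    def test_empty_seizure_list(self, tmp_path):
        study = StudyConfig(seizures=[], clinical=cae_clinical_table().head(0))
        ds = simulate_study(study, out_dir=tmp_path)
        assert ds.records == []
        assert len(read_events(tmp_path / "events.tsv")) == 0

    def test_default_region_scheme_covers_all_channels(self):
        scheme = default_region_scheme(30)
        assert len(scheme) == 30
        counts = {r: list(scheme.values()).count(r) for r in set(scheme.values())}
        assert counts["frontal"] == 10
        assert counts["parietal"] + counts["occipital"] == 12
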