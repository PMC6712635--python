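"""Simulator contracts: shapes, determinism, SNR calibration, filtering, montages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvepbench.synthetic_data import (
    NOISE_ONLY,
    ChannelLayout,
    SimulationConfig,
    _trial_components,
    _trial_rng,
    bandpass,
    derive_montage,
    extract_window,
    generate_dataset,
    generate_trial,
    load_dataset,
    parse_montage,
    save_dataset,
)


class TestGeneration:
    def test_default_dataset_matches_benchmark_shape(self):
        ds = generate_dataset(SimulationConfig(seed=0))
        assert len(ds.trials) == 80
        assert ds.n_runs == 20
        assert len(ds.freqs_hz) == 4
        assert ds.trials[0].data.shape == (8, 1000)

    def test_small_dataset_counts(self):
        ds = generate_dataset(SimulationConfig(freqs_hz=(6.0, 8.0), n_runs=2, seed=0))
        assert len(ds.trials) == 4

    def test_trial_determinism(self):
        cfg = SimulationConfig(n_runs=2, seed=3)
        a = generate_trial(cfg, 8.0, 1)
        b = generate_trial(cfg, 8.0, 1)
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seeds_differ_same_shape(self):
        d1 = generate_dataset(SimulationConfig(n_runs=2, seed=1))
        d2 = generate_dataset(SimulationConfig(n_runs=2, seed=2))
        assert d1.trials[0].data.shape == d2.trials[0].data.shape
        assert not np.allclose(d1.trials[0].data, d2.trials[0].data)

    def test_unknown_frequency_rejected(self):
        cfg = SimulationConfig(n_runs=2, seed=0)
        with pytest.raises(ValueError, match="not in configured frequency set"):
            generate_trial(cfg, 7.0, 0)

    def test_oz_spectrum_peaks_at_stimulus_and_harmonic(self):
        cfg = SimulationConfig(n_runs=2, snr_db=60.0, seed=4)
        trial = generate_trial(cfg, 9.0, 0)
        oz = trial.data[trial.layout.index("Oz")]
        spec = np.abs(np.fft.rfft(oz)) ** 2
        freqs = np.fft.rfftfreq(trial.n_samples, 1 / trial.fs)
        order = np.argsort(spec)[::-1]
        top2 = sorted(freqs[order[:2]])
        assert top2 == [9.0, 18.0]

    def test_noise_only_has_no_stimulus_locked_component(self):
        cfg = SimulationConfig(n_runs=2, snr_db=NOISE_ONLY, seed=5)
        sig, noise = _trial_components(cfg, 6.0, 0, _trial_rng(cfg, 6.0, 0))
        assert np.all(sig == 0.0)
        assert np.std(noise) > 0

    def test_snr_calibration_on_reference_channel(self):
        cfg = SimulationConfig(n_runs=2, snr_db=-8.0, seed=6)
        ratios = []
        for run in (0, 1):
            for f in cfg.freqs_hz:
                sig, noise = _trial_components(cfg, f, run, _trial_rng(cfg, f, run))
                oz = cfg.layout.index("Oz")
                ratios.append(10 * np.log10(np.mean(sig[oz] ** 2) / np.mean(noise[oz] ** 2)))
        assert np.max(np.abs(np.asarray(ratios) - (-8.0))) < 0.5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_runs=1)
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(fs=30.0)  # aliases the 10 Hz second harmonic


class TestLayout:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ChannelLayout(names=("Oz", "Oz"), gains=(1.0, 1.0))

    def test_gain_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ChannelLayout(names=("Oz",), gains=(1.0, 0.5))


class TestBandpass:
    def test_passband_tone_preserved(self):
        cfg = SimulationConfig(n_runs=2, seed=0)
        t = np.arange(1000) / 250.0
        tone = np.tile(np.sin(2 * np.pi * 20.0 * t), (8, 1))
        trial = generate_trial(cfg, 6.0, 0).copy_with(tone)
        out = bandpass(trial, 4.0, 45.0)
        core = slice(100, 900)  # trim filter edges
        ratio = np.std(out.data[0, core]) / np.std(tone[0, core])
        assert abs(ratio - 1.0) < 0.01

    def test_stopband_tone_suppressed(self):
        cfg = SimulationConfig(n_runs=2, seed=0)
        t = np.arange(1000) / 250.0
        tone = np.tile(np.sin(2 * np.pi * 1.0 * t), (8, 1))
        trial = generate_trial(cfg, 6.0, 0).copy_with(tone)
        out = bandpass(trial, 4.0, 45.0)
        assert np.sqrt(np.mean(out.data**2)) < 0.05 * np.sqrt(np.mean(tone**2))

    def test_invalid_band_rejected(self):
        cfg = SimulationConfig(n_runs=2, seed=0)
        trial = generate_trial(cfg, 6.0, 0)
        with pytest.raises(ValueError):
            bandpass(trial, 50.0, 40.0)
        with pytest.raises(ValueError):
            bandpass(trial, 4.0, 200.0)


class TestMontage:
    def test_bipolar_of_identical_channels_is_zero(self):
        cfg = SimulationConfig(n_runs=2, seed=7)
        trial = generate_trial(cfg, 6.0, 0)
        data = trial.data.copy()
        data[trial.layout.index("Pz")] = data[trial.layout.index("Oz")]
        out = derive_montage(trial.copy_with(data), [("Oz", "Pz")])
        assert out.data.shape[0] == 1
        np.testing.assert_allclose(out.data, 0.0)

    def test_monopolar_is_identity_row(self):
        cfg = SimulationConfig(n_runs=2, seed=7)
        trial = generate_trial(cfg, 6.0, 0)
        out = derive_montage(trial, [("Oz", None)])
        np.testing.assert_array_equal(out.data[0], trial.data[trial.layout.index("Oz")])

    def test_two_channel_bipolar_spec(self):
        cfg = SimulationConfig(n_runs=2, seed=7)
        trial = generate_trial(cfg, 6.0, 0)
        out = derive_montage(trial, "Oz-Pz,O1-P7")
        assert out.layout.names == ("Oz-Pz", "O1-P7")
        expected = trial.data[trial.layout.index("Oz")] - trial.data[trial.layout.index("Pz")]
        np.testing.assert_array_equal(out.data[0], expected)

    def test_unknown_channel_named_in_error(self):
        cfg = SimulationConfig(n_runs=2, seed=7)
        trial = generate_trial(cfg, 6.0, 0)
        with pytest.raises(KeyError, match="Cz"):
            derive_montage(trial, [("Cz", None)])

    def test_parse_montage(self):
        assert parse_montage("Oz-Pz,O1") == [("Oz", "Pz"), ("O1", None)]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_montage_commutes_with_bandpass(self, seed):
        cfg = SimulationConfig(n_runs=2, seed=seed)
        trial = generate_trial(cfg, 8.0, 0)
        spec = [("Oz", "Pz"), ("O1", None)]
        a = derive_montage(bandpass(trial, 4.0, 45.0), spec)
        b = bandpass(derive_montage(trial, spec), 4.0, 45.0)
        assert np.max(np.abs(a.data - b.data)) < 1e-8


class TestWindowAndSerialization:
    def test_extract_window_is_onset_anchored(self):
        cfg = SimulationConfig(n_runs=2, seed=8)
        trial = generate_trial(cfg, 6.0, 0)
        w = extract_window(trial, 1.0)
        assert w.shape == (8, 250)
        np.testing.assert_array_equal(w, trial.data[:, :250])

    def test_window_longer_than_trial_rejected(self):
        cfg = SimulationConfig(n_runs=2, seed=8)
        trial = generate_trial(cfg, 6.0, 0)
        with pytest.raises(ValueError, match="exceeds trial length"):
            extract_window(trial, 5.0)

    def test_roundtrip_bytes_identical_manifest(self, tmp_path):
        cfg = SimulationConfig(freqs_hz=(6.0, 8.0), n_runs=2, duration_s=1.0, seed=9)
        ds = generate_dataset(cfg)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        save_dataset(ds, d1, cfg=cfg)
        save_dataset(generate_dataset(cfg), d2, cfg=cfg)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_roundtrip_loads_back(self, tmp_path):
        cfg = SimulationConfig(freqs_hz=(6.0, 8.0), n_runs=2, duration_s=1.0, seed=9)
        ds = generate_dataset(cfg)
        save_dataset(ds, tmp_path / "d", cfg=cfg)
        back = load_dataset(tmp_path / "d")
        assert back.freqs_hz == ds.freqs_hz
        assert back.n_runs == ds.n_runs
        for a, b in zip(ds.trials, back.trials):
            assert a.stimulus_hz == b.stimulus_hz
            np.testing.assert_allclose(a.data, b.data, rtol=1e-9, atol=1e-12)
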