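"""Synthetic multichannel SSVEP EEG.

Steady-state visually evoked potentials (SSVEPs) are near-sinusoidal
oscillations at the gazed flicker frequency and its harmonics, strongest over
occipital cortex and embedded in 1/f^alpha background EEG.  This module
generates epoched trials with exactly that structure — harmonic signal with a
per-channel occipital gain profile, spatially correlated colored noise at a
configurable SNR — plus the standard preprocessing steps (zero-phase band-pass
filtering, bipolar/monopolar montage derivation) and a diff-able on-disk
dataset format.

The default configuration mirrors a standard 8-channel benchmark recording:
P7/P3/Pz/P4/P8/O1/Oz/O2 at 250 Hz, 4 s trials, stimulus frequencies
6/8/9/10 Hz, 20 runs x 4 frequencies = 80 trials.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "ChannelLayout",
    "EpochedTrial",
    "Dataset",
    "SimulationConfig",
    "generate_trial",
    "generate_dataset",
    "bandpass",
    "derive_montage",
    "extract_window",
    "save_dataset",
    "load_dataset",
    "parse_montage",
    "NOISE_ONLY",
]

#: snr_db sentinel meaning "no stimulus-locked signal at all" (noise-only trial).
NOISE_ONLY = float("-inf")

DEFAULT_CHANNELS = ("P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2")
# SSVEP amplitude is concentrated occipitally; parietal sites see an attenuated
# volume-conducted copy.
DEFAULT_GAINS = (0.3, 0.3, 0.5, 0.3, 0.3, 0.9, 1.0, 0.9)
#: Channel whose signal/noise power ratio is calibrated to snr_db.
REFERENCE_CHANNEL = "Oz"


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel labels with per-channel SSVEP amplitude gains."""

    names: tuple[str, ...] = DEFAULT_CHANNELS
    gains: tuple[float, ...] = DEFAULT_GAINS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        gains = tuple(float(g) for g in self.gains)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "gains", gains)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if len(gains) != len(names):
            raise ValueError("gains and names must have equal length")
        if any(g < 0 for g in gains):
            raise ValueError("gains must be nonnegative")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label: {name!r}") from None

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass
class EpochedTrial:
    """One labeled EEG segment: channels x samples, plus acquisition metadata."""

    data: np.ndarray
    fs: float
    stimulus_hz: float
    run_index: int
    subject_id: str = "sim"
    layout: ChannelLayout = field(default_factory=ChannelLayout)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a 2-D channels x samples array")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layout names "
                f"{self.layout.n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains NaN or Inf")
        if self.run_index < 0:
            raise ValueError("run_index must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, layout: ChannelLayout | None = None) -> "EpochedTrial":
        return EpochedTrial(
            data=data,
            fs=self.fs,
            stimulus_hz=self.stimulus_hz,
            run_index=self.run_index,
            subject_id=self.subject_id,
            layout=self.layout if layout is None else layout,
        )


@dataclass
class Dataset:
    """A full recording session: trials grouped into runs over a frequency set."""

    trials: list[EpochedTrial]
    layout: ChannelLayout
    freqs_hz: tuple[float, ...]
    n_runs: int

    def __post_init__(self) -> None:
        self.freqs_hz = tuple(float(f) for f in self.freqs_hz)
        if len(set(self.freqs_hz)) != len(self.freqs_hz):
            raise ValueError("stimulus frequencies must be distinct")
        if any(f <= 0 for f in self.freqs_hz):
            raise ValueError("stimulus frequencies must be positive")
        seen = set()
        for t in self.trials:
            key = (t.run_index, t.stimulus_hz)
            if key in seen:
                raise ValueError(f"duplicate (run, frequency) pair: {key}")
            seen.add(key)
        expected = {(r, f) for r in range(self.n_runs) for f in self.freqs_hz}
        if seen != expected:
            raise ValueError("every (run_index, stimulus_hz) pair must appear exactly once")

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    def trials_for_run(self, run_index: int) -> list[EpochedTrial]:
        return [t for t in self.trials if t.run_index == run_index]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the SSVEP simulator.

    snr_db calibrates the per-trial signal/noise power ratio on the reference
    channel (Oz); ``NOISE_ONLY`` (-inf) suppresses the stimulus-locked signal
    entirely.  phase_jitter_rad is the across-run standard deviation of the
    harmonic phases around their per-frequency means; small values model the
    phase-locked responses that MsetCCA/CFA exploit.
    """

    freqs_hz: tuple[float, ...] = (6.0, 8.0, 9.0, 10.0)
    fs: float = 250.0
    duration_s: float = 4.0
    n_runs: int = 20
    n_harmonics_signal: int = 2
    snr_db: float = -8.0
    phase_jitter_rad: float = 0.1
    noise_exponent: float = 1.0
    noise_mixing: float = 0.5
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs_hz", tuple(float(f) for f in self.freqs_hz))
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 (leave-one-run-out needs >= 2 folds)")
        if self.n_harmonics_signal < 1:
            raise ValueError("n_harmonics_signal must be >= 1")
        if math.isnan(self.snr_db) or self.snr_db == float("inf"):
            raise ValueError("snr_db must be finite or -inf (noise-only)")
        top = max(self.freqs_hz) * self.n_harmonics_signal
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest simulated harmonic ({top} Hz)"
            )
        if not 0.0 <= self.noise_mixing <= 1.0:
            raise ValueError("noise_mixing must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _trial_rng(cfg: SimulationConfig, stimulus_hz: float, run_index: int) -> np.random.Generator:
    """Deterministic per-trial stream keyed on (seed, frequency, run)."""
    fi = cfg.freqs_hz.index(stimulus_hz)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1 + fi, 1 + run_index))
    )


def _base_phases(cfg: SimulationConfig, stimulus_hz: float) -> np.ndarray:
    """Per-frequency mean harmonic phases, fixed across runs for a given seed."""
    fi = cfg.freqs_hz.index(stimulus_hz)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, fi)))
    return rng.uniform(0.0, 2 * np.pi, size=cfg.n_harmonics_signal)


def _colored_noise(rng: np.random.Generator, n_samples: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance-ish Gaussian noise with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    pos = freqs > 0
    shaping[pos] = freqs[pos] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * shaping, n=n_samples)
    return out


def _trial_components(
    cfg: SimulationConfig, stimulus_hz: float, run_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Signal and noise parts of one trial, noise already scaled to snr_db.

    Signal per channel c:  gain_c * sum_h (1/h) sin(2*pi*h*f*t + phi_h);
    noise = sqrt(mix)*shared + sqrt(1-mix)*independent colored components,
    globally scaled so that P_signal/P_noise on the reference channel (Oz)
    equals 10^(snr_db/10).
    """
    n = cfg.n_samples
    t = np.arange(1, n + 1) / cfg.fs
    gains = np.asarray(cfg.layout.gains)

    noise_only = cfg.snr_db == NOISE_ONLY
    if noise_only:
        waveform = np.zeros(n)
    else:
        phases = _base_phases(cfg, stimulus_hz)
        jitter = rng.normal(0.0, cfg.phase_jitter_rad, size=cfg.n_harmonics_signal)
        waveform = np.zeros(n)
        for h in range(1, cfg.n_harmonics_signal + 1):
            waveform += (1.0 / h) * np.sin(
                2 * np.pi * h * stimulus_hz * t + phases[h - 1] + jitter[h - 1]
            )
    signal = gains[:, None] * waveform[None, :]

    shared = _colored_noise(rng, n, cfg.fs, cfg.noise_exponent)
    indep = np.stack(
        [_colored_noise(rng, n, cfg.fs, cfg.noise_exponent) for _ in range(cfg.layout.n_channels)]
    )
    noise = np.sqrt(cfg.noise_mixing) * shared[None, :] + np.sqrt(1.0 - cfg.noise_mixing) * indep

    ref = cfg.layout.index(REFERENCE_CHANNEL) if REFERENCE_CHANNEL in cfg.layout.names else 0
    noise_power = float(np.mean(noise[ref] ** 2))
    if noise_only:
        return signal, noise
    signal_power = float(np.mean(signal[ref] ** 2))
    target_ratio = 10.0 ** (cfg.snr_db / 10.0)
    scale = np.sqrt(signal_power / (noise_power * target_ratio))
    return signal, noise * scale


def generate_trial(
    cfg: SimulationConfig,
    stimulus_hz: float,
    run_index: int,
    rng: np.random.Generator | None = None,
) -> EpochedTrial:
    """Simulate one epoched trial at the given stimulus frequency.

    Deterministic: with ``rng=None`` the stream is derived from
    (cfg.seed, stimulus_hz, run_index), so the same arguments always yield
    bit-identical data.
    """
    if stimulus_hz not in cfg.freqs_hz:
        raise ValueError(
            f"stimulus_hz={stimulus_hz} not in configured frequency set {cfg.freqs_hz}"
        )
    if rng is None:
        rng = _trial_rng(cfg, stimulus_hz, run_index)
    sig, noise = _trial_components(cfg, stimulus_hz, run_index, rng)
    return EpochedTrial(
        data=sig + noise,
        fs=cfg.fs,
        stimulus_hz=stimulus_hz,
        run_index=run_index,
        layout=cfg.layout,
    )


def generate_dataset(cfg: SimulationConfig) -> Dataset:
    """Simulate the full session: n_runs x |freqs_hz| trials."""
    trials = [
        generate_trial(cfg, f, r)
        for r in range(cfg.n_runs)
        for f in cfg.freqs_hz
    ]
    return Dataset(trials=trials, layout=cfg.layout, freqs_hz=cfg.freqs_hz, n_runs=cfg.n_runs)


def bandpass(trial: EpochedTrial, low_hz: float, high_hz: float, order: int = 4) -> EpochedTrial:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    nyq = trial.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=trial.fs, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, trial.data, axis=1)
    return trial.copy_with(np.ascontiguousarray(filtered))


def parse_montage(spec: str) -> list[tuple[str, str | None]]:
    """Parse "Oz-Pz,O1-P7" / "O1,Oz" style strings into (anode, cathode) pairs."""
    out: list[tuple[str, str | None]] = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            anode, cathode = (s.strip() for s in part.split("-", 1))
            out.append((anode, cathode))
        else:
            out.append((part, None))
    if not out:
        raise ValueError(f"empty montage spec: {spec!r}")
    return out


def montage_label(montage: list[tuple[str, str | None]]) -> str:
    return ",".join(a if c is None else f"{a}-{c}" for a, c in montage)


def derive_montage(
    trial: EpochedTrial, montage: list[tuple[str, str | None]] | str
) -> EpochedTrial:
    """Re-reference: each output channel is anode - cathode (bipolar) or the
    anode unchanged (monopolar, cathode None)."""
    if isinstance(montage, str):
        montage = parse_montage(montage)
    rows = []
    names = []
    gains = []
    for anode, cathode in montage:
        ia = trial.layout.index(anode)
        if cathode is None:
            rows.append(trial.data[ia])
            names.append(anode)
            gains.append(trial.layout.gains[ia])
        else:
            ic = trial.layout.index(cathode)
            rows.append(trial.data[ia] - trial.data[ic])
            names.append(f"{anode}-{cathode}")
            gains.append(abs(trial.layout.gains[ia] - trial.layout.gains[ic]))
    layout = ChannelLayout(names=tuple(names), gains=tuple(gains))
    return trial.copy_with(np.asarray(rows), layout=layout)


def extract_window(trial: EpochedTrial, window_s: float) -> np.ndarray:
    """First window_s seconds of the trial, samples [0, window_s * fs)."""
    n = int(round(window_s * trial.fs))
    if n <= 0:
        raise ValueError("window_s must be positive")
    if n > trial.n_samples:
        raise ValueError(
            f"window of {window_s} s ({n} samples) exceeds trial length "
            f"({trial.n_samples} samples)"
        )
    return trial.data[:, :n]


# ---------------------------------------------------------------------------
# On-disk dataset format: manifest.json + per-trial CSVs (diff-able, text-only)
# ---------------------------------------------------------------------------

def _freq_tag(f: float) -> str:
    return f"{f:g}".replace(".", "p")


def save_dataset(dataset: Dataset, out_dir: str | Path, cfg: SimulationConfig | None = None) -> Path:
    """Write manifest.json plus one trial_<run>_<freq>Hz.csv per trial."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fs": dataset.fs,
        "freqs_hz": list(dataset.freqs_hz),
        "n_runs": dataset.n_runs,
        "layout": {"names": list(dataset.layout.names), "gains": list(dataset.layout.gains)},
        "subjects": sorted({t.subject_id for t in dataset.trials}),
        "trials": [
            {
                "file": f"trial_{t.run_index}_{_freq_tag(t.stimulus_hz)}Hz.csv",
                "run_index": t.run_index,
                "stimulus_hz": t.stimulus_hz,
                "subject_id": t.subject_id,
            }
            for t in dataset.trials
        ],
    }
    if cfg is not None:
        cfg_echo = dataclasses.asdict(cfg)
        cfg_echo["layout"] = {"names": list(cfg.layout.names), "gains": list(cfg.layout.gains)}
        manifest["config"] = cfg_echo
        manifest["seed"] = cfg.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for t, entry in zip(dataset.trials, manifest["trials"]):
        header = ",".join(str(k) for k in range(t.n_samples))
        np.savetxt(
            out / entry["file"], t.data, delimiter=",", header=header, comments="", fmt="%.10g"
        )
    return out


def load_dataset(in_dir: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    layout = ChannelLayout(
        names=tuple(manifest["layout"]["names"]),
        gains=tuple(manifest["layout"]["gains"]),
    )
    trials = []
    for entry in manifest["trials"]:
        data = np.loadtxt(root / entry["file"], delimiter=",", skiprows=1, ndmin=2)
        trials.append(
            EpochedTrial(
                data=data,
                fs=manifest["fs"],
                stimulus_hz=entry["stimulus_hz"],
                run_index=entry["run_index"],
                subject_id=entry.get("subject_id", "sim"),
                layout=layout,
            )
        )
    return Dataset(
        trials=trials,
        layout=layout,
        freqs_hz=tuple(manifest["freqs_hz"]),
        n_runs=manifest["n_runs"],
    )
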