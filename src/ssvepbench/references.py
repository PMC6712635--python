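"""Sine–cosine harmonic reference signals.

For a stimulus frequency f the reference is the 2N x n matrix with rows
sin(2*pi*f*t), cos(2*pi*f*t), ..., sin(2*pi*N*f*t), cos(2*pi*N*f*t) sampled at
t = 1/Fs, 2/Fs, ..., n/Fs.  These are the templates CCA correlates the EEG
against, the regression dictionary for the LASSO decoder, and the Y matrix
whose projection L1-MCCA optimizes.  An alternate ``square`` shape replaces
each harmonic row by its sign, for the square-wave reading of the stimulus
waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReferenceBank", "build_reference_bank"]


@dataclass(frozen=True)
class ReferenceBank:
    """Per-frequency harmonic reference matrices (each 2*n_harmonics x n_samples)."""

    freqs_hz: tuple[float, ...]
    n_harmonics: int
    fs: float
    n_samples: int
    shape: str = "harmonic"
    matrices: dict[float, np.ndarray] = field(default_factory=dict, repr=False)

    def matrix(self, freq_hz: float) -> np.ndarray:
        return self.matrices[freq_hz]

    def truncated(self, n_samples: int) -> "ReferenceBank":
        """Bank regenerated at a (shorter) window length."""
        if n_samples == self.n_samples:
            return self
        return build_reference_bank(
            self.freqs_hz, self.n_harmonics, n_samples, self.fs, shape=self.shape
        )


def _harmonic_matrix(freq_hz: float, n_harmonics: int, n_samples: int, fs: float) -> np.ndarray:
    t = np.arange(1, n_samples + 1) / fs
    rows = []
    for h in range(1, n_harmonics + 1):
        rows.append(np.sin(2 * np.pi * h * freq_hz * t))
        rows.append(np.cos(2 * np.pi * h * freq_hz * t))
    return np.asarray(rows)


def build_reference_bank(
    freqs_hz,
    n_harmonics: int,
    n_samples: int,
    fs: float,
    shape: str = "harmonic",
) -> ReferenceBank:
    """Build the reference bank for a set of stimulus frequencies.

    Parameters
    ----------
    freqs_hz : iterable of float
        Candidate stimulus frequencies.
    n_harmonics : int
        N, number of harmonics per frequency (2N rows per matrix).
    n_samples : int
        Window length in samples; time axis is t = 1/fs ... n_samples/fs.
    fs : float
        Sampling rate in Hz.
    shape : {"harmonic", "square"}
        "harmonic" gives sine–cosine rows; "square" applies sign() to each row.
    """
    freqs = tuple(float(f) for f in freqs_hz)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if shape not in ("harmonic", "square"):
        raise ValueError(f"unknown reference shape {shape!r}")
    top = max(freqs) * n_harmonics
    if top >= fs / 2.0:
        raise ValueError(
            f"highest harmonic {top} Hz aliases at sampling rate {fs} Hz (Nyquist {fs / 2} Hz)"
        )
    matrices = {}
    for f in freqs:
        m = _harmonic_matrix(f, n_harmonics, n_samples, fs)
        if shape == "square":
            m = np.sign(m)
        matrices[f] = m
    return ReferenceBank(
        freqs_hz=freqs,
        n_harmonics=n_harmonics,
        fs=fs,
        n_samples=n_samples,
        shape=shape,
        matrices=matrices,
    )
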