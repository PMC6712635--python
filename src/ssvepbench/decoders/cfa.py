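"""Common feature analysis decoder.

CFA assumes that all training trials at one stimulus frequency share a common
temporal subspace: each trial factorizes as X_k = A_k_bar B_bar' + A_k_ind
B_k_ind', with B_bar an orthonormal T x C_common basis common to the class
and the remainder trial-specific.  The shared basis is estimated as the
leading right-singular subspace of the per-trial-centered trials stacked
along their channel rows (the best shared low-rank temporal fit, computed by
one deterministic SVD).  A test vector x is assigned to the class whose
common basis captures the most of its energy, argmax_k ||x' B_bar_k||_2;
multichannel windows score each channel row and sum the squared norms.
"""

from __future__ import annotations

import numpy as np

from .base import FrequencyDecoder, center_rows, register_decoder

__all__ = ["cfa_fit_frequency", "cfa_score", "CFADecoder"]


def cfa_fit_frequency(trials: list[np.ndarray], n_common: int = 1) -> np.ndarray:
    """Shared temporal basis B_bar (T x n_common, orthonormal columns).

    ``trials``: >= 2 windows of shape C x T; each is centered in time before
    stacking.  Raises if ``n_common`` exceeds the rank of the stacked data.
    """
    if len(trials) < 2:
        raise ValueError("CFA needs at least 2 training trials per frequency")
    if n_common < 1:
        raise ValueError("n_common must be >= 1")
    stacked = np.vstack([center_rows(t) for t in trials])  # (K*C) x T
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * s[0])) if s.size and s[0] > 0 else 0
    if n_common > rank:
        raise ValueError(f"n_common={n_common} exceeds rank {rank} of the stacked trials")
    return vt[:n_common].T  # T x n_common


def cfa_score(window: np.ndarray, basis: np.ndarray) -> float:
    """sqrt(sum over channel rows of ||x_c' B_bar||^2); reduces to Eq.-style
    ||x' B|| for a single-channel window."""
    window = np.atleast_2d(window)
    if window.shape[1] != basis.shape[0]:
        raise ValueError(
            f"test window has {window.shape[1]} samples but basis expects {basis.shape[0]}"
        )
    proj = center_rows(window) @ basis  # C x n_common
    return float(np.sqrt(np.sum(proj**2)))


@register_decoder
class CFADecoder(FrequencyDecoder):
    """Classification against class-wise common temporal bases."""

    name = "cfa"
    requires_training = True

    def __init__(self, freqs_hz, fs, n_common: int = 1):
        super().__init__(freqs_hz, fs)
        self.n_common = int(n_common)
        self.bases_: dict[float, np.ndarray] = {}

    def _fit(self, trials_by_freq: dict[float, list[np.ndarray]]) -> None:
        self.bases_ = {
            f: cfa_fit_frequency(trials_by_freq[f], self.n_common) for f in self.freqs_hz
        }

    def scores(self, window: np.ndarray) -> np.ndarray:
        return np.array([cfa_score(window, self.bases_[f]) for f in self.freqs_hz])
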