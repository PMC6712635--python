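"""Multiset CCA decoder.

MsetCCA learns one spatial filter per training trial so that the filtered
trials (the canonical variables) are maximally correlated with each other —
the MAXVAR criterion

    max_w  rho = sum_{i != j} w_i' C_ij w_j   s.t.  (1/N) sum_i w_i' C_ii w_i = 1,

with C_ij = X_i X_j' the between-trial covariance.  The stationary points
solve the generalized eigenproblem (R - S) w = rho S w, where R stacks all
C_ij blocks and S is their block diagonal.  The canonical variables of the
leading eigenvector, stacked row-wise, form an optimized data-driven
reference Y_m per stimulus frequency; test windows are scored against it by
canonical correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sp_linalg

from .base import FrequencyDecoder, center_rows, register_decoder
from .cca import cca_correlate

__all__ = ["MsetFreqState", "msetcca_fit_frequency", "MsetCCADecoder"]


@dataclass
class MsetFreqState:
    """Per-trial spatial filters and the stacked optimized reference."""

    filters: np.ndarray  # N x C, row i = w_i
    reference: np.ndarray  # Y_m, N x P stacked canonical variables
    rho: float  # MAXVAR objective at the solution (constraint-normalized)


def _block_matrices(trials: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n_trials = len(trials)
    c = trials[0].shape[0]
    dim = n_trials * c
    R = np.zeros((dim, dim))
    S = np.zeros((dim, dim))
    for i in range(n_trials):
        for j in range(n_trials):
            cij = trials[i] @ trials[j].T
            R[i * c : (i + 1) * c, j * c : (j + 1) * c] = cij
            if i == j:
                S[i * c : (i + 1) * c, j * c : (j + 1) * c] = cij
    return R, S


def msetcca_fit_frequency(trials: list[np.ndarray], ridge_eps: float = 1e-8) -> MsetFreqState:
    """Solve the MAXVAR eigenproblem for one frequency's training trials.

    ``trials``: list of C x P windows (>= 2, identical shapes); rows are
    centered in time here.  A near-singular S (e.g. spatially rank-deficient
    signals) is ridge-regularized on its diagonal blocks with a warning.
    """
    if len(trials) < 2:
        raise ValueError("MsetCCA needs at least 2 training trials")
    shapes = {t.shape for t in trials}
    if len(shapes) != 1:
        raise ValueError(f"all trials must share one shape, got {shapes}")
    centered = [center_rows(t) for t in trials]
    n_trials = len(centered)
    c = centered[0].shape[0]
    R, S = _block_matrices(centered)

    eigs = np.linalg.eigvalsh(S)
    if eigs[0] <= 1e-12 * max(eigs[-1], 1e-300):
        warnings.warn(
            "near-singular within-trial covariance in MsetCCA; ridge-regularizing",
            RuntimeWarning,
            stacklevel=2,
        )
        S = S + ridge_eps * (np.trace(S) / S.shape[0]) * np.eye(S.shape[0])

    vals, vecs = sp_linalg.eigh(R - S, S)
    w = vecs[:, -1]
    # scale to the MAXVAR constraint (1/N) sum_i w_i' C_ii w_i = 1, i.e. w'Sw = N
    quad = float(w @ S @ w)
    w = w * np.sqrt(n_trials / quad)
    rho = float(w @ (R - S) @ w)
    filters = w.reshape(n_trials, c)
    reference = np.stack([filters[i] @ centered[i] for i in range(n_trials)])
    return MsetFreqState(filters=filters, reference=reference, rho=rho)


@register_decoder
class MsetCCADecoder(FrequencyDecoder):
    """CCA against MAXVAR-optimized multi-trial references."""

    name = "msetcca"
    requires_training = True

    def __init__(self, freqs_hz, fs):
        super().__init__(freqs_hz, fs)
        self.states_: dict[float, MsetFreqState] = {}

    def _fit(self, trials_by_freq: dict[float, list[np.ndarray]]) -> None:
        self.states_ = {
            f: msetcca_fit_frequency(trials_by_freq[f]) for f in self.freqs_hz
        }

    def scores(self, window: np.ndarray) -> np.ndarray:
        n = window.shape[1]
        return np.array(
            [
                cca_correlate(window, self.states_[f].reference[:, :n]).rho
                for f in self.freqs_hz
            ]
        )
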