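"""Canonical correlation analysis decoder.

CCA seeks weight vectors w_x, w_y maximizing the correlation between the
projected EEG window w_x'X and the projected harmonic reference w_y'Y; the
candidate frequency whose reference achieves the largest canonical correlation
rho is the recognized target.  Training-free: the references are analytic.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

from ..references import ReferenceBank, build_reference_bank
from .base import FrequencyDecoder, center_rows, register_decoder

__all__ = ["CCAResult", "cca_correlate", "CCADecoder"]

_RCOND = 1e-10


class CCAResult(NamedTuple):
    rho: float
    wx: np.ndarray
    wy: np.ndarray


def _orthobasis(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Orthonormal basis of the row space of x (x: vars x samples), via SVD.

    Returns (U columns spanning sample-space, s, Vt) truncated at rcond, plus
    the retained rank.  Rank-deficient inputs are handled by truncation (the
    pseudoinverse path) with a warning.
    """
    # svd of x.T (samples x vars): x.T = Q S W'; Q columns orthonormal in sample space
    q, s, wt = np.linalg.svd(x.T, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return q[:, :0], s[:0], wt[:0], 0
    rank = int(np.sum(s > _RCOND * s[0]))
    if rank < x.shape[0]:
        warnings.warn(
            "rank-deficient covariance in CCA; using pseudoinverse (truncated SVD) path",
            RuntimeWarning,
            stacklevel=3,
        )
    return q[:, :rank], s[:rank], wt[:rank], rank


def _sign_fix(w: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(w) > 0)
    if nz.size and w[nz[0]] < 0:
        return -w
    return w


def cca_correlate(X: np.ndarray, Y: np.ndarray) -> CCAResult:
    """Largest canonical correlation between row-sets X (C x n) and Y (2N x n).

    Both sets are mean-centered in time internally.  Computed via the
    numerically stable whitening route: rho is the top singular value of
    Qx'Qy where Qx, Qy are orthonormal bases of the centered row spaces.
    """
    X = center_rows(X)
    Y = center_rows(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"sample-count mismatch: X has {X.shape[1]}, Y has {Y.shape[1]}")
    qx, sx, vxt, rx = _orthobasis(X)
    qy, sy, vyt, ry = _orthobasis(Y)
    if rx == 0 or ry == 0:
        return CCAResult(0.0, np.zeros(X.shape[0]), np.zeros(Y.shape[0]))
    u, svals, vt = np.linalg.svd(qx.T @ qy, full_matrices=False)
    rho = float(min(1.0, svals[0]))
    # map canonical directions back to variable weights: wx = Vx diag(1/sx) u1
    wx = vxt.T @ (u[:, 0] / sx)
    wy = vyt.T @ (vt[0, :] / sy)
    return CCAResult(rho, _sign_fix(wx), _sign_fix(wy))


@register_decoder
class CCADecoder(FrequencyDecoder):
    """Standard CCA against sine–cosine references (no training)."""

    name = "cca"
    requires_training = False

    def __init__(self, freqs_hz, fs, n_harmonics: int = 2, reference_shape: str = "harmonic"):
        super().__init__(freqs_hz, fs)
        self.n_harmonics = n_harmonics
        self.reference_shape = reference_shape
        self._banks: dict[int, ReferenceBank] = {}

    def _bank(self, n_samples: int) -> ReferenceBank:
        if n_samples not in self._banks:
            self._banks[n_samples] = build_reference_bank(
                self.freqs_hz, self.n_harmonics, n_samples, self.fs, shape=self.reference_shape
            )
        return self._banks[n_samples]

    def scores(self, window: np.ndarray) -> np.ndarray:
        bank = self._bank(window.shape[1])
        return np.array(
            [cca_correlate(window, bank.matrix(f)).rho for f in self.freqs_hz]
        )
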