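"""Multivariate linear regression decoder.

Each training window is vectorized (channels x samples -> D features) and
mean-centered; with one-of-M label coding Y the discriminative projection is
the least-squares solution

    W = (X_tilde X_tilde')^+  X_tilde  Y',

computed through a rank-truncated Moore-Penrose pseudoinverse.  Test windows
are centered with the training mean, projected by W into the M-dimensional
label space, and classified by majority vote among their 5 nearest projected
training points (Euclidean metric); vote ties resolve to the lowest
frequency.
"""

from __future__ import annotations

import numpy as np

from .base import FrequencyDecoder, register_decoder

__all__ = ["mlr_solve", "MLRDecoder"]


def mlr_solve(features: np.ndarray, labels_onehot: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Projection W (D x M) for centered features (D x N) and one-of-M labels (M x N).

    Singular values below ``rcond * sigma_max`` are truncated in the
    pseudoinverse, which makes the redundant M-column coding harmless.
    """
    # (X X')^+ X = pinv(X)' for any X (shared SVD), so avoid the D x D product
    return np.linalg.pinv(features, rcond=rcond).T @ labels_onehot.T


@register_decoder
class MLRDecoder(FrequencyDecoder):
    """Least-squares subspace projection followed by k-nearest-neighbour voting."""

    name = "mlr"
    requires_training = True

    def __init__(self, freqs_hz, fs, k_neighbors: int = 5):
        super().__init__(freqs_hz, fs)
        if k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        self.k_neighbors = int(k_neighbors)
        self.W_: np.ndarray | None = None
        self.train_mean_: np.ndarray | None = None
        self.train_features_: np.ndarray | None = None  # N x M projected points
        self.train_labels_: np.ndarray | None = None

    def _fit(self, trials_by_freq: dict[float, list[np.ndarray]]) -> None:
        cols = []
        labels = []
        for fi, f in enumerate(self.freqs_hz):
            windows = trials_by_freq[f]
            if not windows:
                raise ValueError(f"no training trials for {f} Hz")
            for w in windows:
                cols.append(np.asarray(w, dtype=float).ravel())
                labels.append(fi)
        X = np.stack(cols, axis=1)  # D x N
        n_train = X.shape[1]
        if n_train < self.k_neighbors:
            raise ValueError(
                f"{n_train} training trials < k_neighbors={self.k_neighbors}"
            )
        self.train_mean_ = X.mean(axis=1, keepdims=True)
        Xc = X - self.train_mean_
        onehot = np.zeros((len(self.freqs_hz), n_train))
        onehot[labels, np.arange(n_train)] = 1.0
        self.W_ = mlr_solve(Xc, onehot)
        self.train_features_ = (self.W_.T @ Xc).T  # N x M
        self.train_labels_ = np.asarray(labels)

    def scores(self, window: np.ndarray) -> np.ndarray:
        x = np.asarray(window, dtype=float).ravel()[:, None] - self.train_mean_
        feat = (self.W_.T @ x).ravel()
        d2 = np.sum((self.train_features_ - feat) ** 2, axis=1)
        nearest = np.argsort(d2, kind="stable")[: self.k_neighbors]
        votes = np.bincount(self.train_labels_[nearest], minlength=len(self.freqs_hz))
        return votes.astype(float)
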