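"""L1-regularized multiway CCA decoder.

For each stimulus frequency the training trials form a three-way tensor
X in R^(I x n x K) (channels x time x trials).  L1-MCCA finds unit-norm
projections w1 (channels), w3 (trials) and v (reference rows) minimizing

    1/2 || X x_1 w1' x_3 w3' - v'Y ||_2^2
        + lam1 ||w1||_1 + lam2 ||v||_1 + lam3 ||w3||_1

by alternating L1-penalized least squares: with any two projections held
fixed the problem in the third is exactly a LASSO.  Because renormalizing a
LASSO iterate back to the unit sphere is not itself a descent step, every
coordinate update is safeguarded: the renormalized LASSO candidate competes
with the exact norm-constrained least-squares minimizer (a trust-region
subproblem solved through its secular equation) and a candidate is accepted
only if it lowers the constrained objective.  Several deterministic-seeded
starts are swept and the lowest-objective solution kept.

The learned v'Y is a subject-adapted reference; at test time the
w1-projected window is scored against it by canonical correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..references import ReferenceBank, build_reference_bank
from .base import FrequencyDecoder, center_rows, register_decoder
from .cca import cca_correlate
from .lasso import lasso_solve

__all__ = ["L1MccaFreqState", "l1mcca_fit_frequency", "L1MccaDecoder"]


@dataclass
class L1MccaFreqState:
    """Converged projections and optimized reference for one frequency."""

    w1: np.ndarray  # channel projection, unit l2 norm
    w3: np.ndarray  # trial projection, unit l2 norm
    v: np.ndarray  # reference-row projection, unit l2 norm
    optimized_reference: np.ndarray  # v' Y, length n
    objective: float
    n_sweeps: int


def _objective(tensor, Y, w1, w3, v, lams):
    s = np.einsum("i,ink,k->n", w1, tensor, w3)
    resid = s - v @ Y
    return 0.5 * float(resid @ resid) + (
        lams[0] * np.abs(w1).sum() + lams[1] * np.abs(v).sum() + lams[2] * np.abs(w3).sum()
    )


def _unit(x: np.ndarray) -> np.ndarray | None:
    nrm = np.linalg.norm(x)
    if nrm == 0.0:
        return None
    return x / nrm


def _sphere_ls(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Exact min of 1/2||Xw - y||^2 subject to ||w|| = 1 (secular equation)."""
    Q = X.T @ X
    c = X.T @ y
    lam, V = np.linalg.eigh(Q)
    z = V.T @ c

    def norm2(mu):
        return float(np.sum((z / (lam + mu)) ** 2))

    mu_lo = -lam[0] + 1e-10 + 1e-10 * abs(lam[0])
    try:
        if norm2(mu_lo) < 1.0:
            # hard case: pad with the minimal-eigenvalue direction
            w = V @ (z / (lam + mu_lo))
            pad = np.sqrt(max(0.0, 1.0 - float(w @ w)))
            return w + pad * V[:, 0]
        mu_hi = mu_lo + 1.0
        while norm2(mu_hi) > 1.0:
            mu_hi = 2.0 * mu_hi + 1.0
        mu = brentq(lambda m: norm2(m) - 1.0, mu_lo, mu_hi, xtol=1e-14)
        return V @ (z / (lam + mu))
    except (ValueError, ZeroDivisionError, FloatingPointError):
        return _unit(np.linalg.lstsq(X, y, rcond=None)[0])


def _sweep_once(tensor, Y, lams, w1, w3, v, obj, warms):
    """One safeguarded coordinate sweep (v, then w1, then w3)."""

    def try_update(cands, assemble):
        nonlocal obj
        for cand in cands:
            if cand is None:
                continue
            new = _objective(tensor, Y, *assemble(cand), lams)
            if new < obj:
                obj = new
                yield cand

    # v-step
    target = np.einsum("i,ink,k->n", w1, tensor, w3)
    for cand in try_update(
        [
            _unit(lasso_solve(target, Y.T, 2.0 * lams[1], warm=warms["v"])),
            _sphere_ls(Y.T, target),
        ],
        lambda c: (w1, w3, c),
    ):
        v = cand
    if np.linalg.norm(v) == 0.0:
        return w1, w3, v, obj, True
    ref = v @ Y
    # w1-step
    Z = np.einsum("ink,k->in", tensor, w3)
    for cand in try_update(
        [
            _unit(lasso_solve(ref, Z.T, 2.0 * lams[0], warm=warms["w1"])),
            _sphere_ls(Z.T, ref),
        ],
        lambda c: (c, w3, v),
    ):
        w1 = cand
    # w3-step
    M = np.einsum("i,ink->nk", w1, tensor)
    for cand in try_update(
        [
            _unit(lasso_solve(ref, M, 2.0 * lams[2], warm=warms["w3"])),
            _sphere_ls(M, ref),
        ],
        lambda c: (w1, c, v),
    ):
        w3 = cand
    return w1, w3, v, obj, False


def l1mcca_fit_frequency(
    tensor: np.ndarray,
    Y: np.ndarray,
    lams: tuple[float, float, float] = (0.02, 0.02, 0.02),
    tol: float = 1e-6,
    max_sweeps: int = 200,
    n_starts: int = 2,
    max_restarts: int = 5,
    rng: np.random.Generator | None = None,
) -> L1MccaFreqState:
    """Safeguarded alternating-LASSO optimization of the three projections.

    ``tensor``: channels x time x trials (I x n x K), rows centered in time;
    ``Y``: 2N x n harmonic reference.  The first start is the deterministic
    uniform 1/sqrt(dim) initialization with v solved first; the remaining
    ``n_starts - 1`` starts draw unit-norm initializations from ``rng`` and
    the lowest-objective solution is returned.  Each start stops when the
    objective decrease over a sweep falls below ``tol`` or after
    ``max_sweeps``.  An all-zero v triggers a fresh randomized start (up to
    ``max_restarts`` extra draws), then an error.
    """
    I, n, K = tensor.shape
    if K < 2:
        raise ValueError("L1-MCCA needs at least 2 training trials per frequency")
    if Y.shape[1] != n:
        raise ValueError("reference length must match tensor time axis")
    if rng is None:
        rng = np.random.default_rng(0)

    best: L1MccaFreqState | None = None
    degenerate_count = 0
    start = 0
    total_starts = n_starts
    while start < total_starts:
        if start == 0:
            w1 = np.full(I, 1.0 / np.sqrt(I))
            w3 = np.full(K, 1.0 / np.sqrt(K))
        else:
            w1 = _unit(rng.standard_normal(I))
            w3 = _unit(rng.standard_normal(K))
        v = np.zeros(Y.shape[0])
        obj = np.inf
        degenerate = False
        warms = {"v": {}, "w1": {}, "w3": {}}
        for sweep in range(1, max_sweeps + 1):
            prev = obj
            w1, w3, v, obj, degenerate = _sweep_once(
                tensor, Y, lams, w1, w3, v, obj, warms
            )
            if degenerate or prev - obj < tol:
                break
        start += 1
        if degenerate or not np.isfinite(obj):
            degenerate_count += 1
            if degenerate_count > max_restarts:
                raise RuntimeError(
                    f"L1-MCCA collapsed to the all-zero solution after {max_restarts} "
                    f"restarts (penalties {lams} may be too large for this data scale)"
                )
            total_starts += 1  # replace the failed start with a fresh draw
            continue
        if best is None or obj < best.objective:
            best = L1MccaFreqState(
                w1=w1, w3=w3, v=v, optimized_reference=v @ Y, objective=obj, n_sweeps=sweep
            )
    assert best is not None
    return best


@register_decoder
class L1MccaDecoder(FrequencyDecoder):
    """CCA with per-frequency references optimized by L1-penalized multiway CCA."""

    name = "l1mcca"
    requires_training = True

    def __init__(
        self,
        freqs_hz,
        fs,
        lam: float = 0.02,
        lams: tuple[float, float, float] | None = None,
        n_harmonics: int = 2,
        seed: int = 0,
    ):
        super().__init__(freqs_hz, fs)
        self.lams = tuple(lams) if lams is not None else (float(lam),) * 3
        self.n_harmonics = n_harmonics
        self.seed = seed
        self.states_: dict[float, L1MccaFreqState] = {}
        self._bank: ReferenceBank | None = None

    def _fit(self, trials_by_freq: dict[float, list[np.ndarray]]) -> None:
        rng = np.random.default_rng(self.seed)
        n = next(iter(trials_by_freq.values()))[0].shape[1]
        self._bank = build_reference_bank(self.freqs_hz, self.n_harmonics, n, self.fs)
        self.states_ = {}
        for f in self.freqs_hz:
            windows = [center_rows(w) for w in trials_by_freq[f]]
            tensor = np.stack(windows, axis=2)  # I x n x K
            self.states_[f] = l1mcca_fit_frequency(
                tensor, self._bank.matrix(f), lams=self.lams, rng=rng
            )

    def scores(self, window: np.ndarray) -> np.ndarray:
        window = center_rows(window)
        n = window.shape[1]
        out = []
        for f in self.freqs_hz:
            st = self.states_[f]
            projected = (st.w1 @ window)[None, :]
            ref = st.optimized_reference[:n][None, :]
            out.append(cca_correlate(projected, ref[:, : projected.shape[1]]).rho)
        return np.array(out)
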