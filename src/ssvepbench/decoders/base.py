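"""Common decoder contract and registry.

Every frequency-recognition method is a :class:`FrequencyDecoder`:
``fit(trials_by_freq)`` consumes training windows grouped by stimulus
frequency (a no-op for training-free methods), ``scores(window)`` returns one
score per candidate frequency, and ``classify(window)`` takes the argmax with
a deterministic tie-break toward the lowest frequency (ties are recorded on
``last_tie``).
"""

from __future__ import annotations

import abc

import numpy as np

__all__ = [
    "FrequencyDecoder",
    "register_decoder",
    "make_decoder",
    "decoder_names",
    "argmax_frequency",
    "center_rows",
]

_REGISTRY: dict[str, type["FrequencyDecoder"]] = {}


def center_rows(x: np.ndarray) -> np.ndarray:
    """Remove each row's temporal mean (correlations assume zero-mean signals)."""
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=1, keepdims=True)


def argmax_frequency(freqs: tuple[float, ...], scores: np.ndarray) -> tuple[float, bool]:
    """Best-scoring frequency; exact score ties resolve to the lowest frequency."""
    scores = np.asarray(scores, dtype=float)
    best = np.max(scores)
    winners = [f for f, s in zip(freqs, scores) if s == best]
    return min(winners), len(winners) > 1


class FrequencyDecoder(abc.ABC):
    """Abstract fit/classify contract shared by all six methods."""

    #: registry key, set by subclasses
    name: str = ""
    #: whether fit() needs training trials
    requires_training: bool = True

    def __init__(self, freqs_hz, fs: float):
        self.freqs_hz = tuple(float(f) for f in freqs_hz)
        self.fs = float(fs)
        self.last_tie: bool = False
        self.fitted_: bool = False

    def fit(self, trials_by_freq: dict[float, list[np.ndarray]]) -> "FrequencyDecoder":
        """Train on windows grouped by frequency; training-free methods ignore it."""
        self._fit(trials_by_freq)
        self.fitted_ = True
        return self

    def _fit(self, trials_by_freq: dict[float, list[np.ndarray]]) -> None:  # noqa: B027
        pass

    @abc.abstractmethod
    def scores(self, window: np.ndarray) -> np.ndarray:
        """One recognition score per candidate frequency (aligned with freqs_hz)."""

    def classify(self, window: np.ndarray) -> float:
        if self.requires_training and not self.fitted_:
            raise RuntimeError(f"{self.name} decoder must be fitted before classify()")
        pred, tie = argmax_frequency(self.freqs_hz, self.scores(np.asarray(window, dtype=float)))
        self.last_tie = tie
        return pred


def register_decoder(cls: type[FrequencyDecoder]) -> type[FrequencyDecoder]:
    if not cls.name:
        raise ValueError("decoder class must define a registry name")
    _REGISTRY[cls.name] = cls
    return cls


def decoder_names() -> list[str]:
    return sorted(_REGISTRY)


def make_decoder(name: str, freqs_hz, fs: float, **hyperparams) -> FrequencyDecoder:
    """Instantiate a registered decoder by name with method hyperparameters."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown decoder {name!r}; available: {decoder_names()}") from None
    return cls(freqs_hz=freqs_hz, fs=fs, **hyperparams)
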