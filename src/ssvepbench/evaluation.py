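"""Leave-one-run-out evaluation of decoders.

Each recording run serves once as the test fold while the remaining runs
train (training-free decoders skip fitting).  Predictions accumulate into an
M x M confusion matrix from which per-class precision Pr = TP/(TP+FP),
sensitivity Se = TP/(TP+FN) and F-score F = 2*Pr*Se/(Pr+Se) are computed; the
headline number per condition is the unweighted macro average of the
per-class F-scores (classes are balanced by design).  Per-trial prediction
records are retained so matched decoder pairs can feed McNemar's test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoders import make_decoder
from .synthetic_data import (
    Dataset,
    EpochedTrial,
    bandpass,
    derive_montage,
    extract_window,
    montage_label,
    parse_montage,
)

__all__ = [
    "ConfusionMatrix",
    "ClassScores",
    "EvaluationReport",
    "TABLE_MONTAGES",
    "loro_splits",
    "f_scores",
    "evaluate",
    "sweep",
]

#: The 16 bipolar/monopolar montages of the 1- and 2-channel analysis.
TABLE_MONTAGES: tuple[str, ...] = (
    "Oz-Pz,O1-P7",
    "Oz-Pz,O1-P8",
    "Oz-Pz,O2-P8",
    "Oz-Pz,O2-P7",
    "Oz-Pz,O1-Pz",
    "Oz-Pz,O2-Pz",
    "Oz-Pz,O1-Oz",
    "Oz-Pz",
    "O1-Pz",
    "O2-Pz",
    "O1,Oz",
    "O2,Oz",
    "O1,O2",
    "Oz",
    "O1",
    "O2",
)


@dataclass
class ConfusionMatrix:
    """M x M counts: rows = true frequency, columns = predicted frequency."""

    counts: np.ndarray
    class_order: tuple[float, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        m = len(self.class_order)
        if self.counts.shape != (m, m):
            raise ValueError("confusion matrix shape must match class order length")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassScores:
    """Per-class precision / sensitivity / F-score with degeneracy flag."""

    freq_hz: float
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f_score: float
    degenerate: bool = False


def f_scores(confusion: ConfusionMatrix) -> tuple[list[ClassScores], float]:
    """Per-class Pr/Se/F and the unweighted macro-F.

    A class with no predicted positives (TP+FP = 0) or no actual positives
    (TP+FN = 0) gets F = 0 and is flagged degenerate.
    """
    c = confusion.counts
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    scores = []
    for i, f in enumerate(confusion.class_order):
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - tp)
        fn = int(c[i, :].sum() - tp)
        degenerate = (tp + fp == 0) or (tp + fn == 0)
        pr = tp / (tp + fp) if tp + fp > 0 else 0.0
        se = tp / (tp + fn) if tp + fn > 0 else 0.0
        fsc = 2 * pr * se / (pr + se) if pr + se > 0 else 0.0
        scores.append(
            ClassScores(
                freq_hz=f, tp=tp, fp=fp, fn=fn,
                precision=pr, sensitivity=se, f_score=fsc, degenerate=degenerate,
            )
        )
    macro = float(np.mean([s.f_score for s in scores]))
    return scores, macro


@dataclass
class EvaluationReport:
    """Cross-validated result for one (decoder, montage, window) condition."""

    decoder: str
    montage: str
    window_s: float
    confusion: ConfusionMatrix
    class_scores: list[ClassScores]
    macro_f: float
    #: one row per test trial: (run_index, true_hz, predicted_hz, tie)
    records: list[tuple[int, float, float, bool]] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion.counts)) / self.confusion.total

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "class_hz": s.freq_hz,
                "TP": s.tp,
                "FP": s.fp,
                "FN": s.fn,
                "precision": s.precision,
                "sensitivity": s.sensitivity,
                "f_score": s.f_score,
            }
            for s in self.class_scores
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "decoder": self.decoder,
            "montage": self.montage,
            "window_s": self.window_s,
            "class_order": list(self.confusion.class_order),
            "confusion": self.confusion.counts.tolist(),
            "class_scores": [
                {
                    "class_hz": s.freq_hz,
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "precision": s.precision,
                    "sensitivity": s.sensitivity,
                    "f_score": s.f_score,
                    "degenerate": s.degenerate,
                }
                for s in self.class_scores
            ],
            "macro_f": self.macro_f,
            "accuracy": self.accuracy,
            "records": [
                {"run": r, "true_hz": t, "predicted_hz": p, "tie": tie}
                for r, t, p, tie in self.records
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        conf = ConfusionMatrix(np.asarray(d["confusion"]), tuple(d["class_order"]))
        scores = [
            ClassScores(
                freq_hz=s["class_hz"], tp=s["tp"], fp=s["fp"], fn=s["fn"],
                precision=s["precision"], sensitivity=s["sensitivity"],
                f_score=s["f_score"], degenerate=s["degenerate"],
            )
            for s in d["class_scores"]
        ]
        records = [
            (r["run"], r["true_hz"], r["predicted_hz"], r["tie"]) for r in d["records"]
        ]
        return cls(
            decoder=d["decoder"], montage=d["montage"], window_s=d["window_s"],
            confusion=conf, class_scores=scores, macro_f=d["macro_f"], records=records,
        )


def loro_splits(dataset: Dataset) -> list[tuple[list[int], int]]:
    """Leave-one-run-out folds: fold i tests run i, trains on all other runs."""
    if dataset.n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    runs = list(range(dataset.n_runs))
    return [([r for r in runs if r != test], test) for test in runs]


def _preprocess(
    trial: EpochedTrial,
    montage: list[tuple[str, str | None]] | None,
    band: tuple[float, float] | None,
) -> EpochedTrial:
    if band is not None:
        trial = bandpass(trial, band[0], band[1])
    if montage is not None:
        trial = derive_montage(trial, montage)
    return trial


def evaluate(
    dataset: Dataset,
    decoder_name: str,
    window_s: float,
    montage_spec: str | list[tuple[str, str | None]] | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
    band: tuple[float, float] | None = (4.0, 45.0),
) -> EvaluationReport:
    """Full leave-one-run-out evaluation of one decoder at one condition.

    Trials are band-pass filtered (default 4–45 Hz), re-referenced to
    ``montage_spec`` if given, and truncated to their first ``window_s``
    seconds for both training and test.  ``seed`` feeds any decoder-internal
    randomness (e.g. L1-MCCA restarts), so reports are reproducible.
    """
    if window_s > dataset.trials[0].duration_s + 1e-9:
        raise ValueError(
            f"window of {window_s} s exceeds trial duration "
            f"{dataset.trials[0].duration_s} s"
        )
    hyperparams = dict(hyperparams or {})
    montage = parse_montage(montage_spec) if isinstance(montage_spec, str) else montage_spec
    label = montage_label(montage) if montage else "all-8"

    processed = [_preprocess(t, montage, band) for t in dataset.trials]
    freqs = dataset.freqs_hz
    fidx = {f: i for i, f in enumerate(freqs)}
    counts = np.zeros((len(freqs), len(freqs)), dtype=int)
    records: list[tuple[int, float, float, bool]] = []

    probe = make_decoder(decoder_name, freqs, dataset.fs, **hyperparams)
    needs_training = probe.requires_training
    if needs_training and "seed" in type(probe).__init__.__code__.co_varnames:
        hyperparams.setdefault("seed", seed)

    for train_runs, test_run in loro_splits(dataset):
        decoder = make_decoder(decoder_name, freqs, dataset.fs, **hyperparams)
        if needs_training:
            train_by_freq: dict[float, list[np.ndarray]] = {f: [] for f in freqs}
            for t in processed:
                if t.run_index in train_runs:
                    train_by_freq[t.stimulus_hz].append(extract_window(t, window_s))
            short = [f for f, ws in train_by_freq.items() if len(ws) < 2]
            if short:
                raise ValueError(
                    f"decoder {decoder_name!r} needs >= 2 training trials per class; "
                    f"classes {short} have fewer in fold testing run {test_run}"
                )
            decoder.fit(train_by_freq)
        for t in sorted(
            (t for t in processed if t.run_index == test_run),
            key=lambda t: t.stimulus_hz,
        ):
            pred = decoder.classify(extract_window(t, window_s))
            counts[fidx[t.stimulus_hz], fidx[pred]] += 1
            records.append((t.run_index, t.stimulus_hz, pred, decoder.last_tie))

    confusion = ConfusionMatrix(counts, freqs)
    scores, macro = f_scores(confusion)
    return EvaluationReport(
        decoder=decoder_name,
        montage=label,
        window_s=window_s,
        confusion=confusion,
        class_scores=scores,
        macro_f=macro,
        records=records,
    )


def sweep(
    dataset: Dataset,
    decoders: list[str],
    windows_s: list[float],
    montages: list[str | None],
    hyperparams: dict[str, dict] | None = None,
    seed: int = 0,
    band: tuple[float, float] | None = (4.0, 45.0),
) -> tuple[pd.DataFrame, list[EvaluationReport]]:
    """Grid over decoders x windows x montages.

    Returns the long-format table (montage, decoder, window_s, macro_f) plus
    the full reports for downstream per-class tables and McNemar comparisons.
    """
    hyperparams = hyperparams or {}
    rows = []
    reports = []
    for montage in montages:
        for name in decoders:
            for w in windows_s:
                rep = evaluate(
                    dataset, name, w, montage_spec=montage,
                    hyperparams=hyperparams.get(name), seed=seed, band=band,
                )
                reports.append(rep)
                rows.append(
                    {
                        "montage": rep.montage,
                        "decoder": name,
                        "window_s": w,
                        "macro_f": rep.macro_f,
                    }
                )
    return pd.DataFrame(rows), reports


def per_class_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Per-class long table: montage, decoder, window_s, class, Pr, Se, F, macro_f."""
    rows = []
    for rep in reports:
        for s in rep.class_scores:
            rows.append(
                {
                    "montage": rep.montage,
                    "decoder": rep.decoder,
                    "window_s": rep.window_s,
                    "class": s.freq_hz,
                    "precision": s.precision,
                    "sensitivity": s.sensitivity,
                    "f_score": s.f_score,
                    "macro_f": rep.macro_f,
                }
            )
    return pd.DataFrame(rows)
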