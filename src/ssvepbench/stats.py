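"""Paired decoder comparison via McNemar's test.

Two decoders evaluated on the same trials are compared through their
discordant outcomes only: b = trials A got right and B got wrong, c = the
reverse.  Under the null both decoders are equally accurate and the
discordant trials split b:c like a fair coin.  With few discordant pairs
(b + c < 25) an exact two-sided binomial test is used; otherwise the
continuity-corrected chi-square statistic (|b - c| - 1)^2 / (b + c) with one
degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .evaluation import EvaluationReport

__all__ = ["McNemarResult", "mcnemar", "pairwise_outperformance"]

#: discordant-pair count below which the exact binomial test is used
EXACT_THRESHOLD = 25


@dataclass
class McNemarResult:
    """Outcome of one paired comparison (labels default to 'A' and 'B')."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    n_pairs: int
    statistic: float | None  # continuity-corrected chi-square, None for exact/degenerate
    p_value: float
    method: str  # "chi2_cc", "exact_binomial" or "degenerate"
    winner: str | None
    label_a: str = "A"
    label_b: str = "B"


def mcnemar(
    preds_a,
    preds_b,
    truth,
    alpha: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
) -> McNemarResult:
    """McNemar's test on matched prediction vectors.

    A winner is declared only when p < ``alpha``; it is the decoder with more
    discordant wins.  b + c = 0 is the degenerate case: p = 1, no statistic,
    no winner.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    truth = np.asarray(truth)
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction and truth vectors must have equal length")
    ok_a = preds_a == truth
    ok_b = preds_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    n = len(truth)

    if b + c == 0:
        return McNemarResult(b, c, n, None, 1.0, "degenerate", None, label_a, label_b)
    if b + c < EXACT_THRESHOLD:
        p = float(sp_stats.binomtest(b, b + c, 0.5).pvalue)
        stat = None
        method = "exact_binomial"
    else:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
        p = float(sp_stats.chi2.sf(stat, df=1))
        method = "chi2_cc"
    winner = None
    if p < alpha and b != c:
        winner = label_a if b > c else label_b
    return McNemarResult(b, c, n, stat, p, method, winner, label_a, label_b)


def _matched_records(rep: EvaluationReport) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    recs = sorted(rep.records, key=lambda r: (r[0], r[1]))  # (run, true) order
    runs = np.array([r[0] for r in recs])
    truth = np.array([r[1] for r in recs])
    preds = np.array([r[2] for r in recs])
    return runs, truth, preds


def pairwise_outperformance(
    reports: list[EvaluationReport], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, int], list[McNemarResult]]:
    """All unordered pairwise McNemar tests over matched evaluation reports.

    All reports must cover the identical (run, true-frequency) trial set.
    Returns a long-format table (decoder_a, decoder_b, b, c, p_value, winner),
    the per-decoder count of significantly won comparisons, and the raw
    results.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    keys = {}
    aligned = {}
    for rep in reports:
        runs, truth, preds = _matched_records(rep)
        key = list(zip(runs.tolist(), truth.tolist()))
        keys[rep.decoder] = key
        aligned[rep.decoder] = (truth, preds)
    ref_key = next(iter(keys.values()))
    for name, key in keys.items():
        if key != ref_key:
            raise ValueError(
                f"report {name!r} covers a different (run, true) trial set; "
                "reports must be matched for McNemar"
            )

    results = []
    wins = {rep.decoder: 0 for rep in reports}
    rows = []
    for rep_a, rep_b in combinations(reports, 2):
        truth, preds_a = aligned[rep_a.decoder]
        _, preds_b = aligned[rep_b.decoder]
        res = mcnemar(
            preds_a, preds_b, truth, alpha=alpha,
            label_a=rep_a.decoder, label_b=rep_b.decoder,
        )
        results.append(res)
        if res.winner is not None:
            wins[res.winner] += 1
        rows.append(
            {
                "decoder_a": rep_a.decoder,
                "decoder_b": rep_b.decoder,
                "b": res.b,
                "c": res.c,
                "method": res.method,
                "p_value": res.p_value,
                "winner": res.winner if res.winner is not None else "none",
            }
        )
    return pd.DataFrame(rows), wins, results
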