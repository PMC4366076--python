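"""Genome-wide error control: Bonferroni thresholds and BH step-up FDR."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BonferroniThreshold:
    alpha: float
    m: int
    per_test: float  # alpha / m
    neg_log10: float


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    """Per-test level alpha/m and its -log10, for m simultaneous tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive test count")
    per_test = alpha / m
    return BonferroniThreshold(
        alpha=alpha, m=m, per_test=per_test, neg_log10=float(-np.log10(per_test))
    )


@dataclass
class MultipleTestingResult:
    method: str
    level: float  # genome-wide alpha or FDR level q
    m: int
    threshold: float  # per-test threshold alpha'
    selected: list = field(default_factory=list)
    n_selected: int = 0
    adjusted: pd.Series | None = None


def bh_select(pvalues, q: float = 0.05) -> MultipleTestingResult:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    ``pvalues`` maps identifiers to p-values (dict or Series).  The largest
    k with ``p_(k) <= k q / m`` fixes the per-test threshold ``p_(k)``; all
    tests with p at or below it are selected, so ties enter together.  BH-
    adjusted p-values (monotone step-up) are attached for convenience.
    """
    p = pd.Series(pvalues, dtype=float).dropna()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = len(p)
    result = MultipleTestingResult(method="benjamini-hochberg", level=q, m=m,
                                   threshold=0.0)
    if m == 0:
        return result
    order = np.argsort(p.to_numpy(), kind="stable")
    sorted_p = p.to_numpy()[order]
    crit = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= crit)
    adj = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = pd.Series(np.clip(adj, 0, 1)[np.argsort(order, kind="stable")],
                         index=p.index)
    result.adjusted = adjusted
    if passing.size:
        threshold = sorted_p[passing[-1]]
        selected = p.index[p.to_numpy() <= threshold]
        result.threshold = float(threshold)
        result.selected = list(selected)
        result.n_selected = len(selected)
    return result


def bonferroni_select(pvalues, alpha: float = 0.05) -> MultipleTestingResult:
    """Select tests with p <= alpha/m (inclusive)."""
    p = pd.Series(pvalues, dtype=float).dropna()
    thr = bonferroni_threshold(alpha, max(len(p), 1)).per_test
    selected = list(p.index[p.to_numpy() <= thr])
    return MultipleTestingResult(
        method="bonferroni", level=alpha, m=len(p), threshold=thr,
        selected=selected, n_selected=len(selected),
    )
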