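"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the mathematical definition, without touching
the package's implementation path, so agreement is meaningful.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def gotoh_global_score(
    seq_a: str,
    seq_b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global alignment score by the full affine-gap DP.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; end gaps
    are penalized like internal ones.  Three-state Gotoh recursion over the
    complete table (no heuristics).
    """
    n, m = len(seq_a), len(seq_b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)  # a[i] aligned to b[j]
    X = np.full((n + 1, m + 1), neg)  # gap in seq_b (a[i] over '-')
    Y = np.full((n + 1, m + 1), neg)  # gap in seq_a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] - gap_open,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open,
                Y[i, j - 1] - gap_extend,
                X[i, j - 1] - gap_open,
            )
    return float(max(M[n, m], X[n, m], Y[n, m]))


def ac_double_loop(values: np.ndarray, lg: int) -> np.ndarray:
    """Naive double-loop auto-covariance of an (l, p) property matrix."""
    values = np.asarray(values, dtype=float)
    l, p = values.shape
    means = [sum(values[i, j] for i in range(l)) / l for j in range(p)]
    out = []
    for lag in range(1, lg + 1):
        for j in range(p):
            total = 0.0
            for i in range(l - lag):
                total += (values[i, j] - means[j]) * (values[i + lag, j] - means[j])
            out.append(total / (l - lag))
    return np.array(out)


def metric_suite_fractions(tp: int, fp: int, tn: int, fn: int) -> dict[str, Fraction]:
    """Exact rational evaluation of the confusion-matrix metric formulas.

    MCC is returned as (numerator, denominator-squared) free form: since
    the denominator involves a square root, MCC is reported as a float via
    exact integer arithmetic under the root.
    """
    total = tp + fp + tn + fn
    out: dict[str, Fraction] = {}
    out["acc"] = Fraction(tp + tn, total)
    out["sen"] = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    out["spe"] = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
    out["pe"] = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
    out["f1"] = (
        Fraction(2 * tp, 2 * tp + fp + fn) if 2 * tp + fp + fn else Fraction(0)
    )
    return out


def mcc_exact(tp: int, fp: int, tn: int, fn: int) -> float:
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    import math

    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def auc_concordance(scores, labels) -> float:
    """AUC by exhaustive concordant/discordant/tied pair counting."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def degree_bin_oracle(degrees: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustively bin a degree map into the nine standard intervals.

    Returns (protein proportions, raw protein counts); intervals are
    (0,10], (10,20], (20,30], (30,50], (50,70], (70,80], (80,100],
    (100,150], (150,inf).
    """
    edges = [(0, 10), (10, 20), (20, 30), (30, 50), (50, 70), (70, 80),
             (80, 100), (100, 150), (150, float("inf"))]
    counts = np.zeros(len(edges))
    for d in degrees.values():
        for i, (lo, hi) in enumerate(edges):
            if lo < d <= hi:
                counts[i] += 1
                break
    return counts / len(degrees), counts
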