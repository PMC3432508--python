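import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_kendalls_w(series: np.ndarray) -> float:
    """Textbook Kendall's W: rank each judge's series, sum ranks per time
    point, and normalize the rank-sum dispersion.  Independent of the
    package implementation (sorting-based ranks, explicit loops)."""
    series = np.asarray(series, dtype=float)
    k, n = series.shape
    ranks = np.zeros_like(series)
    for row_i, row in enumerate(series):
        order = np.argsort(row, kind="stable")
        r = np.empty(n)
        i = 0
        while i < n:  # midranks for tied values
            j = i
            while j + 1 < n and row[order[j + 1]] == row[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        ranks[row_i] = r
    rsum = ranks.sum(axis=0)
    s = np.sum((rsum - rsum.mean()) ** 2)
    return 12.0 * s / (k**2 * (n**3 - n))


def mann_whitney_auc(scores, y_true, positive_class) -> float:
    """AUC as the pairwise rank-sum probability P(s+ > s-) + 0.5 P(s+ = s-),
    by brute force over every (positive, negative) pair."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(y_true) == positive_class]
    neg = scores[np.asarray(y_true) != positive_class]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
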