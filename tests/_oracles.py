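"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values from first principles (interval
enumeration, sums of squares, manual step-up) without touching the library's
own algorithms, so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def oracle_episode_intervals(
    codes, code: int, min_span_ep: int, max_gap_ep: int
) -> list[tuple[int, int]]:
    """All maximal intervals satisfying the episode definition, by enumeration.

    An interval [i, j] qualifies when it starts and ends on epochs of the
    state, every maximal internal run of other states has length at most
    ``max_gap_ep``, and its span is at least ``min_span_ep`` epochs. For each
    admissible start the farthest admissible end is found by a forward scan;
    non-maximal intervals are then discarded.
    """
    codes = list(codes)
    n = len(codes)
    candidates = []
    for i in range(n):
        if codes[i] != code:
            continue
        best_j = None
        run = 0
        for j in range(i, n):
            if codes[j] == code:
                run = 0
                best_j = j
            else:
                run += 1
                if run > max_gap_ep:
                    break
        if best_j is not None and best_j - i + 1 >= min_span_ep:
            candidates.append((i, best_j))
    return [
        (i, j)
        for (i, j) in candidates
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in candidates)
    ]


def oracle_rm_anova(wide: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA F and Greenhouse-Geisser epsilon.

    Textbook sums-of-squares decomposition on a complete n x k matrix, and
    the GG epsilon from the double-centered within-subject covariance.
    """
    y = np.asarray(wide, dtype=float)
    n, k = y.shape
    grand = y.mean()
    subj = y.mean(axis=1, keepdims=True)
    cond = y.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond - grand) ** 2).sum()
    resid = y - subj - cond + grand
    ss_err = (resid ** 2).sum()
    F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    S = np.cov(y, rowvar=False, ddof=1)
    centered = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    eps = np.trace(centered) ** 2 / ((k - 1) * (centered ** 2).sum())
    return float(F), float(eps)


def oracle_bh(pvals: list[float], q: float) -> list[bool]:
    """Benjamini-Hochberg step-up by hand: largest i with p_(i) <= q*i/m."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    cutoff = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= q * rank / m:
            cutoff = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= cutoff:
            reject[idx] = True
    return reject
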