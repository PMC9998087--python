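"""Vigilance-state transition analysis and its paired resampling test.

Every consecutive epoch pair in a window is a *continuation* (same state on
both epochs, the diagonal of the 3x3 table) or a *shift* (state change).
Counts are converted to row percentages -- the share of pairs leaving each
state that go to each destination -- so recordings with different amounts of
each state remain comparable.

Drug-vs-reference comparisons use the canonical paired non-parametric scheme:
the statistic is the mean within-animal difference in a row percentage, and
the null distribution is generated by Monte-Carlo resampling of within-animal
condition-label swaps (independent sign flips of each animal's difference,
default 5000 iterations). One-sided p-values count ties toward the numerator
and are floored at 1/B, never 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import (
    STATES,
    AnalysisWindow,
    CohortDataset,
    EpochSeries,
    ParameterError,
    SomnopharmError,
    slice_window,
    state_code,
)

DEFAULT_ITERATIONS = 5000
SIDES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class TransitionTable:
    """3x3 consecutive-epoch-pair counts and row percentages (W, N, R order)."""

    counts: np.ndarray   # int, counts[from, to]
    row_pct: np.ndarray  # float, rows sum to 100; all-NaN row when no pairs

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def pct(self, from_state: str, to_state: str) -> float:
        return float(self.row_pct[state_code(from_state), state_code(to_state)])


def transition_table(s: EpochSeries, w: AnalysisWindow | None = None) -> TransitionTable:
    """Count epoch-pair transitions/continuations within a window.

    Pairs spanning the window edge are excluded by construction (the window is
    sliced first). Artifact flags are ignored: scored states remain valid, so
    transitions are computed on the full state sequence.
    """
    sub = slice_window(s, w) if w is not None else s
    if len(sub) < 2:
        raise SomnopharmError("transition analysis needs at least two epochs")
    pair_codes = 3 * sub.codes[:-1].astype(np.intp) + sub.codes[1:]
    counts = np.bincount(pair_codes, minlength=9).reshape(3, 3)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = np.where(row_sums > 0, 100.0 * counts / row_sums, np.nan)
    return TransitionTable(counts, row_pct)


@dataclass(frozen=True)
class ResamplingTestResult:
    transition: tuple[str, str]
    observed_diff: float      # mean within-animal (drug - reference) row pct
    p_value: float            # in [1/B, 1]
    B: int
    side: str
    effect_size: float        # paired Cohen's d of the differences (NaN if sd=0)
    n_animals: int
    diffs: tuple[float, ...]  # per-animal differences actually used


def _paired_diffs(
    cohort: CohortDataset,
    transition: tuple[str, str],
    ref: str,
    drug: str,
    w: AnalysisWindow | None,
) -> np.ndarray:
    i, j = state_code(transition[0]), state_code(transition[1])
    diffs = []
    for rec_ref, rec_drug in cohort.paired(ref, drug):
        a = transition_table(rec_drug, w).row_pct[i, j]
        b = transition_table(rec_ref, w).row_pct[i, j]
        if math.isnan(a) or math.isnan(b):
            warnings.warn(
                f"animal {rec_ref.animal_id}: no {STATES[i]}-row pairs in one condition; "
                "excluded from the paired test", stacklevel=3,
            )
            continue
        diffs.append(a - b)
    animals_with_both = {r.animal_id for r, _ in cohort.paired(ref, drug)}
    for a in cohort.animals():
        if a not in animals_with_both:
            warnings.warn(f"animal {a}: missing condition {ref!r} or {drug!r}; excluded",
                          stacklevel=3)
    return np.asarray(diffs, dtype=float)


def paired_resampling_test(
    cohort: CohortDataset,
    transition: tuple[str, str],
    ref: str,
    drug: str,
    B: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator = 0,
    side: str = "greater",
    window: AnalysisWindow | None = None,
) -> ResamplingTestResult:
    """Paired sign-flip resampling test for one transition's row percentage.

    The statistic T is the mean over animals of (drug - reference) row
    percentage. The null resamples T with each animal's difference given an
    independent random sign (a within-animal condition-label swap), B times.
    For ``side='greater'``, p = #{T* >= T_obs} / B, ties counting toward the
    numerator and the result floored at 1/B.
    """
    if B < 1000:
        raise ParameterError(f"B must be at least 1000, got {B}")
    if side not in SIDES:
        raise ParameterError(f"side must be one of {SIDES}")
    diffs = _paired_diffs(cohort, transition, ref, drug, window)
    n = diffs.size
    if n < 3:
        raise SomnopharmError(
            f"paired test needs >=3 animals with both conditions, got {n}"
        )
    t_obs = float(diffs.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(B, n)) * 2 - 1
    t_null = (signs * diffs).mean(axis=1)
    if side == "greater":
        hits = int((t_null >= t_obs).sum())
    elif side == "less":
        hits = int((t_null <= t_obs).sum())
    else:
        hits = int((np.abs(t_null) >= abs(t_obs)).sum())
    p = max(hits / B, 1.0 / B)
    sd = float(diffs.std(ddof=1)) if n > 1 else 0.0
    d = t_obs / sd if sd > 0 else math.nan
    return ResamplingTestResult(
        (STATES[state_code(transition[0])], STATES[state_code(transition[1])]),
        t_obs, p, B, side, d, n, tuple(diffs.tolist()),
    )


def exact_signflip_p(diffs: np.ndarray, side: str = "greater") -> float:
    """Exact sign-flip p over all 2^n label-swap patterns (small n only)."""
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n > 20:
        raise ParameterError("exact enumeration limited to n <= 20")
    t_obs = diffs.mean()
    signs = (((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1) * 2 - 1).astype(float)
    t_all = (signs * diffs).mean(axis=1)
    if side == "greater":
        hits = int((t_all >= t_obs - 1e-12).sum())
    elif side == "less":
        hits = int((t_all <= t_obs + 1e-12).sum())
    else:
        hits = int((np.abs(t_all) >= abs(t_obs) - 1e-12).sum())
    return hits / 2 ** n


def transition_panel(
    cohort: CohortDataset,
    ref: str,
    drug: str,
    B: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    side: str = "greater",
    alpha: float = 0.05,
    window: AnalysisWindow | None = None,
) -> pd.DataFrame:
    """Run the resampling test for all 9 (from, to) pairs.

    Returns a tidy frame with the raw resampling p-value, a significance flag
    at ``alpha``, the paired Cohen's d, and an optional Bonferroni column
    (raw p x 9, capped at 1). Raw p-values carry the inference; no
    family-wise scheme is imposed by default.
    """
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(9)
    k = 0
    for fr in STATES:
        for to in STATES:
            rng = np.random.default_rng(child_seeds[k])
            k += 1
            try:
                res = paired_resampling_test(
                    cohort, (fr, to), ref, drug, B=B, seed=rng, side=side, window=window
                )
            except SomnopharmError as exc:
                raise SomnopharmError(f"transition {fr}->{to}: {exc}") from exc
            rows.append(
                {
                    "from": fr,
                    "to": to,
                    "kind": "continuation" if fr == to else "shift",
                    "observed_diff": res.observed_diff,
                    "p_value": res.p_value,
                    "significant": res.p_value < alpha,
                    "cohens_d": res.effect_size,
                    "p_bonferroni": min(res.p_value * 9, 1.0),
                    "n_animals": res.n_animals,
                }
            )
    return pd.DataFrame(rows)
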