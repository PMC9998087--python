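"""Sleep-architecture metrics: episodes, state allocation, latencies, fragmentation.

An *episode* (bout) of a vigilance state is a maximal interval that starts and
ends on epochs of that state, tolerates internal interruptions by other states
up to a per-state maximum gap, and whose merged span (interruptions included)
reaches a per-state minimum. The standard rodent thresholds are 60 s minimum
span with interruptions of up to 16 s for wake and NREM episodes, and 16 s
minimum span with interruptions of up to 8 s for the much shorter REM
episodes. *Brief awakenings* -- wake intrusions of 1-4 epochs (4-16 s) flanked
by sleep on both sides -- are counted separately as a sleep-fragmentation
marker and expressed per hour of total sleep time (TST = NREM + REM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import (
    EPOCH_S,
    STATES,
    AnalysisWindow,
    CohortDataset,
    CoverageError,
    EpochSeries,
    ParameterError,
    slice_window,
    state_code,
)

#: per-state (min_span_s, max_gap_s) episode thresholds
EPISODE_RULES: dict[str, tuple[float, float]] = {
    "W": (60.0, 16.0),
    "N": (60.0, 16.0),
    "R": (16.0, 8.0),
}


@dataclass(frozen=True)
class Episode:
    """A merged bout of one state. Epoch indices are an inclusive span."""

    state: str
    start_epoch: int
    end_epoch: int
    gaps: tuple[tuple[int, int], ...] = ()  # (start_epoch, length_epochs) per interruption

    @property
    def span_s(self) -> float:
        """Duration including interruptions."""
        return EPOCH_S * (self.end_epoch - self.start_epoch + 1)

    @property
    def net_s(self) -> float:
        """Duration of the episode's own state only."""
        return self.span_s - EPOCH_S * sum(g for _, g in self.gaps)


def _state_runs(codes: np.ndarray, code: int) -> list[tuple[int, int]]:
    """Maximal runs of ``code`` as (start, end_inclusive) pairs."""
    mask = codes == code
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size - 1]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_episodes(
    s: EpochSeries,
    state: str,
    min_span_s: float | None = None,
    max_gap_s: float | None = None,
) -> list[Episode]:
    """Detect episodes of ``state`` in a series.

    Algorithm: (1) find maximal runs of the state; (2) merge consecutive runs
    whenever the intervening run of other states totals at most ``max_gap_s``
    (gap composition is state-agnostic); (3) keep merged intervals whose span,
    interruptions included, is at least ``min_span_s``. Episodes always start
    and end on epochs of the state, so boundary gaps cannot occur.

    Thresholds default to the per-state rules in :data:`EPISODE_RULES`.
    """
    rule = EPISODE_RULES[STATES[state_code(state)]]
    if min_span_s is None:
        min_span_s = rule[0]
    if max_gap_s is None:
        max_gap_s = rule[1]
    for name, v in (("min_span_s", min_span_s), ("max_gap_s", max_gap_s)):
        if v <= 0 or v % EPOCH_S:
            raise ParameterError(f"{name} must be a positive multiple of {EPOCH_S} s, got {v}")
    if min_span_s < EPOCH_S:
        raise ParameterError("min_span_s must be at least one epoch")
    code = state_code(state)
    max_gap_epochs = int(max_gap_s // EPOCH_S)

    runs = _state_runs(s.codes, code)
    episodes: list[Episode] = []
    i = 0
    while i < len(runs):
        start, end = runs[i]
        gaps: list[tuple[int, int]] = []
        j = i + 1
        while j < len(runs):
            gap_len = runs[j][0] - end - 1
            if gap_len > max_gap_epochs:
                break
            gaps.append((end + 1, gap_len))
            end = runs[j][1]
            j += 1
        if EPOCH_S * (end - start + 1) >= min_span_s:
            episodes.append(Episode(STATES[code], start, end, tuple(gaps)))
        i = j
    return episodes


@dataclass(frozen=True)
class StateAllocation:
    """Time-in-state shares of a window, in percent of scored epochs."""

    pct: dict[str, float]          # W/N/R, sums to 100
    rem_pct_tst: float             # 100*R/(N+R); NaN when no sleep
    rem_nrem_ratio: float          # R/N; NaN when no NREM
    n_epochs: int


def time_in_state(s: EpochSeries, w: AnalysisWindow | None = None) -> StateAllocation:
    """Percentage of window time per state, REM as % of TST, and REM/NREM ratio.

    REM%TST is undefined (returned as NaN, never zero) when the window holds
    no sleep at all.
    """
    sub = slice_window(s, w) if w is not None else s
    n = len(sub)
    if n == 0:
        raise CoverageError("cannot allocate states in an empty window")
    counts = np.bincount(sub.codes, minlength=3).astype(float)
    pct = {st: 100.0 * counts[i] / n for i, st in enumerate(STATES)}
    tst = counts[1] + counts[2]
    rem_pct_tst = 100.0 * counts[2] / tst if tst > 0 else math.nan
    ratio = counts[2] / counts[1] if counts[1] > 0 else math.nan
    return StateAllocation(pct, rem_pct_tst, ratio, n)


def timecourse(s: EpochSeries, bin_s: float = 3600.0) -> pd.DataFrame:
    """Per-bin state percentages over consecutive, non-overlapping bins.

    Returns a tidy frame with one row per bin (columns ``bin_start_s``,
    ``pct_W``, ``pct_N``, ``pct_R``, ``rem_pct_tst``).
    """
    if bin_s <= 0 or bin_s % EPOCH_S:
        raise ParameterError(f"bin_s must be a positive multiple of {EPOCH_S} s")
    if bin_s > s.end_s - s.t0_offset:
        raise CoverageError("bin exceeds the recording length")
    rows = []
    start = s.t0_offset
    while start + bin_s <= s.end_s + 1e-9:
        alloc = time_in_state(s, AnalysisWindow(start, start + bin_s))
        rows.append(
            {
                "bin_start_s": start,
                **{f"pct_{st}": alloc.pct[st] for st in STATES},
                "rem_pct_tst": alloc.rem_pct_tst,
            }
        )
        start += bin_s
    return pd.DataFrame(rows)


def nrem_latency(s: EpochSeries) -> float:
    """Seconds from injection (t=0) to the onset of the first NREM episode.

    Sleep onset is the start of the first NREM *episode* under the 60 s /
    16 s rule, not the first isolated NREM epoch. NaN with a warning when the
    series holds no qualifying episode.
    """
    eps = detect_episodes(s, "N")
    if not eps:
        warnings.warn(f"recording {s.key()}: no NREM episode found; latency undefined",
                      stacklevel=2)
        return math.nan
    return s.t0_offset + EPOCH_S * eps[0].start_epoch


def rem_latency_from_sleep_onset(s: EpochSeries) -> float:
    """Seconds from sleep onset (first NREM episode) to the first REM epoch.

    The endpoint is the first single REM epoch at or after sleep onset -- a
    transition into REM -- not a full REM episode. NaN when there is no sleep
    onset or no subsequent REM.
    """
    onset = nrem_latency(s)
    if math.isnan(onset):
        return math.nan
    onset_idx = int(round((onset - s.t0_offset) / EPOCH_S))
    rem = np.flatnonzero(s.codes[onset_idx:] == 2)
    if rem.size == 0:
        warnings.warn(f"recording {s.key()}: no REM sleep after sleep onset", stacklevel=2)
        return math.nan
    return EPOCH_S * float(rem[0])


@dataclass(frozen=True)
class NremBeforeRem:
    minutes: float
    censored: bool  # True when the window contains no REM at all


def nrem_before_first_rem(s: EpochSeries) -> NremBeforeRem:
    """Cumulative NREM sleep (minutes) preceding the first REM epoch.

    When the window contains no REM, the total NREM time is returned and
    flagged censored.
    """
    rem = np.flatnonzero(s.codes == 2)
    if rem.size == 0:
        n_count = int((s.codes == 1).sum())
        return NremBeforeRem(EPOCH_S * n_count / 60.0, censored=True)
    n_count = int((s.codes[: rem[0]] == 1).sum())
    return NremBeforeRem(EPOCH_S * n_count / 60.0, censored=False)


@dataclass(frozen=True)
class BriefAwakenings:
    count: int
    rate_per_h_sleep: float  # NaN when the window holds no sleep
    tst_h: float


def brief_awakenings(s: EpochSeries, w: AnalysisWindow | None = None) -> BriefAwakenings:
    """Count 4-16 s wake intrusions into sleep and their rate per hour of sleep.

    A brief awakening is a maximal wake run of 1-4 epochs immediately preceded
    and followed by sleep (N or R); wake runs touching the window edge are not
    interruptions of sleep and are excluded.
    """
    sub = slice_window(s, w) if w is not None else s
    codes = sub.codes
    count = 0
    for start, end in _state_runs(codes, 0):
        if end - start + 1 > 4:
            continue
        if start == 0 or end == codes.size - 1:
            continue
        if codes[start - 1] != 0 and codes[end + 1] != 0:
            count += 1
    tst_h = EPOCH_S * int(np.isin(codes, (1, 2)).sum()) / 3600.0
    rate = count / tst_h if tst_h > 0 else math.nan
    return BriefAwakenings(count, rate, tst_h)


@dataclass(frozen=True)
class EpisodeStats:
    count: int
    mean_span_s: float  # NaN when count == 0
    max_span_s: float   # NaN when count == 0


def episode_stats(
    episodes: list[Episode], w: AnalysisWindow | None = None, t0_offset: float = 0.0
) -> EpisodeStats:
    """Count / mean span / max span of the episodes starting inside ``w``."""
    if w is not None:
        episodes = [
            e for e in episodes
            if w.start_s <= t0_offset + EPOCH_S * e.start_epoch < w.end_s
        ]
    if not episodes:
        return EpisodeStats(0, math.nan, math.nan)
    spans = [e.span_s for e in episodes]
    return EpisodeStats(len(episodes), float(np.mean(spans)), float(np.max(spans)))


#: metric name -> description, for the tidy output schema
ARCHITECTURE_METRICS = (
    "pct_W", "pct_N", "pct_R", "rem_pct_tst", "rem_nrem_ratio",
    "nrem_latency_s", "rem_latency_s", "nrem_before_rem_min",
    "brief_awakening_rate", "brief_awakening_count",
    "n_episode_count", "n_episode_mean_s", "n_episode_max_s",
    "r_episode_count", "r_episode_mean_s", "r_episode_max_s",
    "w_episode_count", "w_episode_mean_s", "w_episode_max_s",
)


def summarize_recording(
    s: EpochSeries, w: AnalysisWindow,
    rules: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """All architecture metrics of one recording in one window.

    ``rules`` overrides the per-state (min_span_s, max_gap_s) episode
    thresholds; defaults are the standard 60/16 s (W, N) and 16/8 s (R).
    """
    rules = rules or EPISODE_RULES
    sub = slice_window(s, w)
    alloc = time_in_state(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {
            "pct_W": alloc.pct["W"],
            "pct_N": alloc.pct["N"],
            "pct_R": alloc.pct["R"],
            "rem_pct_tst": alloc.rem_pct_tst,
            "rem_nrem_ratio": alloc.rem_nrem_ratio,
            "nrem_latency_s": nrem_latency(sub),
            "rem_latency_s": rem_latency_from_sleep_onset(sub),
            "nrem_before_rem_min": nrem_before_first_rem(sub).minutes,
        }
        ba = brief_awakenings(sub)
    out["brief_awakening_rate"] = ba.rate_per_h_sleep
    out["brief_awakening_count"] = float(ba.count)
    for st in STATES:
        stats = episode_stats(detect_episodes(sub, st, *rules[st]))
        out[f"{st.lower()}_episode_count"] = float(stats.count)
        out[f"{st.lower()}_episode_mean_s"] = stats.mean_span_s
        out[f"{st.lower()}_episode_max_s"] = stats.max_span_s
    return out


def architecture_summary(
    cohort: CohortDataset,
    windows: dict[str, AnalysisWindow] | None = None,
    rules: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Tidy table: one row per (animal, condition, window, metric, value)."""
    from .hypnogram import WINDOWS

    windows = windows or WINDOWS
    rows = []
    for key in sorted(cohort.recordings):
        rec = cohort.recordings[key]
        for wname, w in windows.items():
            metrics = summarize_recording(rec, w, rules)
            for metric, value in metrics.items():
                rows.append(
                    {
                        "animal_id": rec.animal_id,
                        "condition": rec.condition,
                        "window": wname,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
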