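"""Data model and I/O for scored sleep recordings.

A recording is a hypnogram: one vigilance state -- wake (W), NREM sleep (N),
or REM sleep (R) -- per 4 s scoring epoch, together with a parallel artifact
flag per epoch. An artifact flag marks epochs whose EEG is excluded from
spectral averaging; the scored state itself remains valid and is used by all
architecture and transition analyses. Recordings are time-aligned to the
moment of drug injection (t = 0), and analyses operate on half-open
post-injection windows, canonically the acute (0-2 h) and prolonged (0-6 h)
windows.

Epoch timing convention: epoch ``i`` of a series spans
``[t0_offset + 4*i, t0_offset + 4*(i+1))`` seconds post-injection.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

EPOCH_S = 4.0
#: canonical state order; integer codes index into this array
STATES = ("W", "N", "R")
_STATE_CODE = {"W": 0, "N": 1, "R": 2}
_ALIASES = {
    "W": "W", "WAKE": "W", "WAKEFULNESS": "W",
    "N": "N", "NREM": "N", "NR": "N",
    "R": "R", "REM": "R",
}

TABLE_COLUMNS = ("animal_id", "condition", "epoch_index", "state", "artifact")


class SomnopharmError(Exception):
    """Base class for domain errors."""


class FormatError(SomnopharmError):
    """A table is missing required structure (e.g. a named column)."""


class ParseError(SomnopharmError):
    """A cell could not be interpreted; carries the offending file row."""


class IntegrityError(SomnopharmError):
    """Structurally valid input violating a dataset invariant."""


class CoverageError(SomnopharmError):
    """A recording does not cover the requested analysis window."""


class ParameterError(SomnopharmError):
    """An analysis parameter is out of its allowed range."""


def state_code(token: str) -> int:
    """Map a state token (case-insensitive; aliases Wake/NREM/REM) to 0/1/2."""
    try:
        return _STATE_CODE[_ALIASES[str(token).strip().upper()]]
    except KeyError:
        raise ParseError(f"unknown vigilance state token {token!r}") from None


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open post-injection time window [start_s, end_s) in seconds."""

    start_s: float
    end_s: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ParameterError(
                f"window must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_s / EPOCH_S))


#: first 2 h post injection
ACUTE = AnalysisWindow(0.0, 7200.0, "acute")
#: full 6 h observation period
PROLONGED = AnalysisWindow(0.0, 21600.0, "prolonged")
WINDOWS = {"acute": ACUTE, "prolonged": PROLONGED}


@dataclass
class EpochSeries:
    """One scored recording: per-epoch states and artifact flags.

    Parameters
    ----------
    animal_id, condition
        Identity of the recording within the cohort design.
    codes
        int8 array of state codes (0=W, 1=N, 2=R), one per 4 s epoch.
    artifact
        bool array, parallel to ``codes``; True marks epochs whose EEG is
        excluded from spectral averaging (the state stays valid).
    t0_offset
        Seconds from injection to the start of the first stored epoch (>= 0).
    """

    animal_id: str
    condition: str
    codes: np.ndarray
    artifact: np.ndarray
    t0_offset: float = 0.0
    epoch_len: float = EPOCH_S

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.codes.ndim != 1 or self.codes.shape != self.artifact.shape:
            raise IntegrityError("states and artifact flags must be parallel 1-D sequences")
        if self.codes.size and not (0 <= self.codes.min() and self.codes.max() <= 2):
            raise IntegrityError("state codes must be in {0, 1, 2}")
        if self.epoch_len != EPOCH_S:
            raise IntegrityError(f"epoch length is fixed at {EPOCH_S} s")
        if self.t0_offset < 0:
            raise IntegrityError("t0_offset must be >= 0")

    @classmethod
    def from_states(
        cls,
        states: Iterable[str],
        artifact: Iterable[bool] | None = None,
        animal_id: str = "a0",
        condition: str = "saline",
        t0_offset: float = 0.0,
    ) -> "EpochSeries":
        codes = np.array([state_code(s) for s in states], dtype=np.int8)
        art = np.zeros(codes.size, bool) if artifact is None else np.asarray(list(artifact), bool)
        return cls(animal_id, condition, codes, art, t0_offset)

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def states(self) -> np.ndarray:
        """State letters as an array of 'W'/'N'/'R'."""
        return np.array(STATES)[self.codes]

    @property
    def start_times(self) -> np.ndarray:
        """Post-injection start time (s) of each epoch."""
        return self.t0_offset + EPOCH_S * np.arange(len(self))

    @property
    def end_s(self) -> float:
        """Post-injection time at which the last stored epoch ends."""
        return self.t0_offset + EPOCH_S * len(self)

    def covers(self, w: AnalysisWindow) -> bool:
        """Whether every epoch slot of ``w`` is backed by a scored epoch."""
        return self.t0_offset <= w.start_s and self.end_s >= w.end_s

    def key(self) -> tuple[str, str]:
        return (self.animal_id, self.condition)


def slice_window(s: EpochSeries, w: AnalysisWindow) -> EpochSeries:
    """Restrict a series to the epochs whose start time lies in ``w``.

    The series must extend to the end of the window. A late alignment
    (``t0_offset > w.start_s``) is tolerated -- the initial epochs simply do
    not exist -- but is reported with a coverage warning rather than guessed
    around, so partially covered windows are always visible to the caller.
    """
    if s.end_s < w.end_s:
        raise CoverageError(
            f"recording {s.key()} ends at {s.end_s:.0f} s but window "
            f"{w.label} requires coverage to {w.end_s:.0f} s "
            f"(missing span [{s.end_s:.0f}, {w.end_s:.0f}))"
        )
    starts = s.start_times
    mask = (starts >= w.start_s) & (starts < w.end_s)
    idx = np.flatnonzero(mask)
    if s.t0_offset > w.start_s:
        warnings.warn(
            f"recording {s.key()}: first epoch starts {s.t0_offset:.0f} s post-injection; "
            f"window [{w.start_s:.0f}, {w.end_s:.0f}) is only partially covered "
            f"(missing span [{w.start_s:.0f}, {s.t0_offset:.0f}))",
            stacklevel=2,
        )
    if idx.size == 0:
        return replace(s, codes=s.codes[:0], artifact=s.artifact[:0], t0_offset=w.start_s)
    return replace(
        s,
        codes=s.codes[idx[0]: idx[-1] + 1],
        artifact=s.artifact[idx[0]: idx[-1] + 1],
        t0_offset=float(starts[idx[0]]),
    )


@dataclass
class CohortDataset:
    """Within-subject cohort: recordings keyed by (animal_id, condition)."""

    recordings: dict[tuple[str, str], EpochSeries]
    conditions: list[str]
    reference: str = "saline"

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise IntegrityError("a cohort design needs at least two conditions")
        if self.reference not in self.conditions:
            raise IntegrityError(f"reference condition {self.reference!r} not in design")
        for key, rec in self.recordings.items():
            if key != rec.key():
                raise IntegrityError(f"recording stored under {key} but identifies as {rec.key()}")
            if rec.condition not in self.conditions:
                raise IntegrityError(f"recording {key} has condition outside the design")

    @classmethod
    def from_recordings(
        cls, recordings: Iterable[EpochSeries], reference: str = "saline",
        conditions: list[str] | None = None,
    ) -> "CohortDataset":
        recs = {}
        for r in recordings:
            if r.key() in recs:
                raise IntegrityError(f"duplicate recording for {r.key()}")
            recs[r.key()] = r
        if conditions is None:
            conditions = sorted({c for _, c in recs}, key=lambda c: (c != reference, c))
        return cls(recs, list(conditions), reference)

    def animals(self) -> list[str]:
        return sorted({a for a, _ in self.recordings})

    def get(self, animal_id: str, condition: str) -> EpochSeries | None:
        return self.recordings.get((animal_id, condition))

    def paired(self, ref: str, drug: str) -> list[tuple[EpochSeries, EpochSeries]]:
        """Recordings of animals that have both conditions, in animal order."""
        out = []
        for a in self.animals():
            x, y = self.get(a, ref), self.get(a, drug)
            if x is not None and y is not None:
                out.append((x, y))
        return out


# ---------------------------------------------------------------------------
# table I/O (canonical dialect: tab-separated with header)
# ---------------------------------------------------------------------------

def load_hypnogram_table(path, reference: str = "saline", sep: str = "\t") -> CohortDataset:
    """Load a scored-hypnogram table into a validated cohort.

    The canonical dialect is TSV with header columns
    ``animal_id  condition  epoch_index  state  artifact`` (artifact in {0,1};
    states case-insensitive from {W, N, R} with aliases Wake/NREM/REM).
    ``epoch_index`` must be contiguous from 0 within each recording.
    An optional ``t0_offset`` column (constant per recording, seconds) carries
    the injection-to-first-epoch delay.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"hypnogram table is missing required column {col!r}")
    codes = np.empty(len(df), dtype=np.int8)
    for i, tok in enumerate(df["state"].to_numpy()):
        try:
            codes[i] = state_code(tok)
        except ParseError:
            # +2: one for the header line, one for 1-based file rows
            raise ParseError(
                f"unknown vigilance state token {tok!r} at row {i + 2} of {path}"
            ) from None
    df = df.assign(_code=codes)
    recordings = []
    for (animal, cond), grp in df.groupby(["animal_id", "condition"], sort=True):
        idx = grp["epoch_index"].astype(int).to_numpy()
        order = np.argsort(idx)
        idx = idx[order]
        if not np.array_equal(idx, np.arange(len(idx))):
            raise IntegrityError(
                f"recording ({animal!r}, {cond!r}): epoch_index not contiguous from 0"
            )
        art = grp["artifact"].astype(int).to_numpy()[order]
        if not np.isin(art, (0, 1)).all():
            raise ParseError(f"recording ({animal!r}, {cond!r}): artifact flags must be 0/1")
        t0 = 0.0
        if "t0_offset" in grp.columns:
            offs = grp["t0_offset"].astype(float).unique()
            if offs.size > 1:
                raise IntegrityError(
                    f"recording ({animal!r}, {cond!r}): t0_offset must be constant"
                )
            t0 = float(offs[0])
        recordings.append(
            EpochSeries(animal, cond, grp["_code"].to_numpy()[order], art.astype(bool), t0)
        )
    if not recordings:
        raise FormatError("hypnogram table contains no recordings")
    return CohortDataset.from_recordings(recordings, reference=reference)


def save_hypnogram_table(cohort: CohortDataset, path, sep: str = "\t") -> None:
    """Write a cohort in the canonical dialect (byte-stable ordering)."""
    frames = []
    for key in sorted(cohort.recordings):
        rec = cohort.recordings[key]
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": rec.animal_id,
                    "condition": rec.condition,
                    "epoch_index": np.arange(len(rec)),
                    "state": rec.states,
                    "artifact": rec.artifact.astype(int),
                    "t0_offset": rec.t0_offset,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if isinstance(path, io.TextIOBase):
        table.to_csv(path, sep=sep, index=False)
    else:
        with open(path, "w", newline="\n") as fh:
            table.to_csv(fh, sep=sep, index=False)


@dataclass
class CohortReport:
    """Validation report; purely informative, never raises."""

    incomplete_design: dict[str, list[str]] = field(default_factory=dict)
    short_recordings: list[tuple[str, str]] = field(default_factory=list)
    artifact_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    high_artifact: list[tuple[str, str]] = field(default_factory=list)
    late_alignment: list[tuple[str, str]] = field(default_factory=list)

    @property
    def problems(self) -> list[str]:
        out = []
        for animal, missing in self.incomplete_design.items():
            out.append(f"incomplete design: {animal} missing {', '.join(missing)}")
        for key in self.short_recordings:
            out.append(f"short recording: {key} does not cover the prolonged window")
        for key in self.high_artifact:
            out.append(f"high artifact fraction: {key} ({self.artifact_fraction[key]:.1%})")
        for key in self.late_alignment:
            out.append(f"late alignment: {key} starts after injection time 0")
        return out


def validate_cohort(
    cohort: CohortDataset, artifact_threshold: float = 0.2,
    window: AnalysisWindow = PROLONGED,
) -> CohortReport:
    """Report design gaps, short recordings, and artifact load per recording.

    The study design is deliberately unbalanced (not every animal received
    every dose), so missing cells are reported, not rejected.
    """
    report = CohortReport()
    for a in cohort.animals():
        missing = [c for c in cohort.conditions if cohort.get(a, c) is None]
        if missing:
            report.incomplete_design[a] = missing
    for key in sorted(cohort.recordings):
        rec = cohort.recordings[key]
        if not rec.covers(window):
            report.short_recordings.append(key)
        frac = float(rec.artifact.mean()) if len(rec) else 0.0
        report.artifact_fraction[key] = frac
        if frac > artifact_threshold:
            report.high_artifact.append(key)
        if rec.t0_offset > 0:
            report.late_alignment.append(key)
    return report


def read_edf_epochs(path, channel: str, epoch_s: float = EPOCH_S) -> np.ndarray:
    """Read one EEG channel from an EDF file as per-epoch 1024-sample frames.

    Optional plumbing for continuous recordings stored in European Data
    Format at 256 Hz; requires the ``mne`` package (``somnopharm[edf]``).
    Returns an (n_epochs, 1024) array; a trailing partial epoch is dropped.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    if channel not in raw.ch_names:
        raise FormatError(f"channel {channel!r} not found in {path}")
    sfreq = float(raw.info["sfreq"])
    if abs(sfreq - 256.0) > 1e-6:
        raise FormatError(f"expected 256 Hz EDF signals, got {sfreq} Hz")
    sig = raw.get_data(picks=[channel])[0]
    frame = int(round(epoch_s * sfreq))
    n = sig.size // frame
    return sig[: n * frame].reshape(n, frame)
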