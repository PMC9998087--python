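"""Per-epoch EEG spectra, state-conditioned averages, and bin-wise statistics.

Each 4 s epoch of 256 Hz EEG (1024 samples) is reduced to a Hanning-windowed
periodogram with 0.25 Hz resolution, retained on the 0-30 Hz grid (121 bins).
Scaling is power-per-bin with window power correction, so summing the full
spectrum up to the Nyquist frequency recovers the (windowed) time-domain
variance of the frame -- Parseval's identity is the normalization contract.
Statistics operate on the 0.5-30 Hz analysis band (119 bins): the DC and
0.25 Hz bins are dominated by drift and are excluded.

Group testing follows a three-tier scheme on log-transformed state spectra:
a frequency x condition two-way repeated-measures ANOVA screens for an
interaction; only then are per-bin paired two-tailed t-tests run and flagged
at p<0.05 uncorrected, p<0.01 uncorrected, and Benjamini-Hochberg q<0.05.
Neighbouring frequency bins do not vary independently, which is why the
uncorrected tier is reported alongside the FDR tier rather than replaced by
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .hypnogram import (
    AnalysisWindow,
    EpochSeries,
    IntegrityError,
    ParameterError,
    SomnopharmError,
    slice_window,
    state_code,
)

FS = 256.0
FRAME = 1024
N_BINS = 121                       # 0 .. 30 Hz inclusive at 0.25 Hz
FREQS = np.arange(N_BINS) * 0.25   # Hz
DF = 0.25
#: analysis band 0.5-30 Hz inclusive: exactly 119 bins
BAND = (FREQS >= 0.5) & (FREQS <= 30.0)
BAND_FREQS = FREQS[BAND]
SWA_BAND = (FREQS >= 0.5) & (FREQS <= 4.0)


def _periodogram(frames: np.ndarray) -> np.ndarray:
    """Hann periodogram rows over the full 0-128 Hz grid, power-per-bin units."""
    f, pxx = signal.periodogram(
        frames, fs=FS, window="hann", detrend="constant", scaling="density", axis=-1
    )
    return pxx * DF


def epoch_spectrum(frame: np.ndarray, full: bool = False) -> np.ndarray:
    """Power spectrum of one 4 s epoch (1024 samples at 256 Hz).

    Returns the 121 bins covering 0-30 Hz, or the full 513-bin grid to the
    Nyquist frequency when ``full=True`` (used for the Parseval check). The
    sum of the full grid equals the frame's mean-removed, Hann-weighted
    variance ``sum((w*(x - mean(x)))**2) / sum(w**2)``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 1 or frame.size != FRAME:
        raise ParameterError(f"epoch frame must have exactly {FRAME} samples")
    if not np.isfinite(frame).all():
        raise ParameterError("epoch frame contains non-finite values")
    pxx = _periodogram(frame)
    return pxx if full else pxx[:N_BINS]


@dataclass
class EpochSpectra:
    """Per-epoch power matrix (n_epochs x 121 bins on the 0-30 Hz grid)."""

    power: np.ndarray
    freqs: np.ndarray = field(default_factory=lambda: FREQS.copy())

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2 or self.power.shape[1] != N_BINS:
            raise IntegrityError(f"power matrix must have {N_BINS} columns")
        if self.power.size and self.power.min() < 0:
            raise IntegrityError("spectral power must be non-negative")

    def __len__(self) -> int:
        return self.power.shape[0]

    @classmethod
    def from_frames(cls, frames: np.ndarray) -> "EpochSpectra":
        """Batch-analyze an (n_epochs, 1024) array of EEG frames."""
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 2 or frames.shape[1] != FRAME:
            raise ParameterError(f"frames must be (n_epochs, {FRAME})")
        return cls(_periodogram(frames)[:, :N_BINS])


@dataclass(frozen=True)
class StateSpectrum:
    """Mean spectrum over one state's artifact-free epochs in one window."""

    animal_id: str
    condition: str
    state: str
    power: np.ndarray  # 121 bins
    n_epochs: int


def state_spectra(
    spectra: EpochSpectra, s: EpochSeries, state: str, w: AnalysisWindow | None = None
) -> StateSpectrum | None:
    """Average the epoch spectra of one state, excluding artifact epochs.

    ``spectra`` rows must align 1:1 with the epochs of ``s``. Returns None
    with a warning when no epoch qualifies (e.g. animals with too little REM
    sleep are excluded from REM spectral averages).
    """
    if len(spectra) != len(s):
        raise IntegrityError(
            f"spectra rows ({len(spectra)}) do not align with epochs ({len(s)})"
        )
    code = state_code(state)
    if w is not None:
        starts = s.start_times
        in_w = (starts >= w.start_s) & (starts < w.end_s)
    else:
        in_w = np.ones(len(s), bool)
    mask = in_w & (s.codes == code) & ~s.artifact
    n = int(mask.sum())
    if n == 0:
        warnings.warn(
            f"recording {s.key()}: no artifact-free {state} epochs in window; excluded",
            stacklevel=2,
        )
        return None
    return StateSpectrum(s.animal_id, s.condition, state, spectra.power[mask].mean(axis=0), n)


def swa_trace(spectra: EpochSpectra) -> np.ndarray:
    """Slow-wave activity per epoch: mean power over the 0.5-4.0 Hz bins."""
    return spectra.power[:, SWA_BAND].mean(axis=1)


def cohort_state_spectra(rows: list[StateSpectrum]) -> pd.DataFrame:
    """Assemble per-recording state spectra into a (animal, condition) x bin frame.

    The frame has a two-level index (animal_id, condition), one column per
    frequency bin (named by frequency in Hz), plus an ``n_epochs`` column.
    """
    if not rows:
        raise IntegrityError("no state spectra to assemble")
    recs = {}
    for r in rows:
        recs[(r.animal_id, r.condition)] = np.r_[r.power, r.n_epochs]
    df = pd.DataFrame.from_dict(recs, orient="index", columns=[*FREQS, "n_epochs"])
    df.index = pd.MultiIndex.from_tuples(df.index, names=["animal_id", "condition"])
    return df.sort_index()


def relative_spectrum(
    drug: StateSpectrum | np.ndarray, ref: StateSpectrum | np.ndarray
) -> np.ndarray:
    """Per-bin drug power as % of reference over the analysis band (119 values).

    Computed per animal; averaging across animals for display happens after
    this per-animal ratio. Bins with zero reference power are NaN.
    """
    d = drug.power if isinstance(drug, StateSpectrum) else np.asarray(drug, float)
    r = ref.power if isinstance(ref, StateSpectrum) else np.asarray(ref, float)
    if d.shape != (N_BINS,) or r.shape != (N_BINS,):
        raise ParameterError(f"state spectra must have {N_BINS} bins")
    d, r = d[BAND], r[BAND]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(r > 0, 100.0 * (d / r), np.nan)
    return out


@dataclass
class BinTestReport:
    """Outcome of the interaction screen plus the three per-bin flag tiers."""

    interaction_F: float
    interaction_p: float
    tested: bool                  # False when the interaction screen failed
    n_animals: int
    bins: pd.DataFrame | None     # per analysis bin: freq, t, p, flags


def binwise_stats(
    spectra: pd.DataFrame,
    ref: str,
    drug: str,
    alpha: float = 0.05,
    q: float = 0.05,
    log_transform: bool = True,
) -> BinTestReport:
    """Frequency x condition screen and tiered per-bin paired tests.

    ``spectra`` is the frame from :func:`cohort_state_spectra` for one state
    and window. Per-animal spectra are log-transformed (base 10) before
    hypothesis testing; ``log_transform=False`` tests linear power instead
    and is a deliberately distinct option. Animals lacking either condition
    are dropped with a warning. Per-bin t-tests run only when the two-way
    repeated-measures interaction is significant at ``alpha``.
    """
    from scipy import stats as sps

    from .stats import bh_adjust

    power = spectra[list(FREQS)] if "n_epochs" in spectra.columns else spectra
    animals = []
    for a in power.index.get_level_values(0).unique():
        sub = power.loc[a]
        if ref in sub.index and drug in sub.index:
            animals.append(a)
        else:
            warnings.warn(f"animal {a}: missing {ref!r} or {drug!r} spectra; dropped",
                          stacklevel=2)
    if len(animals) < 3:
        raise SomnopharmError(
            f"bin-wise testing needs >=3 paired animals, got {len(animals)}"
        )
    band_cols = [f for f, b in zip(FREQS, BAND) if b]
    x_ref = power.loc[[(a, ref) for a in animals], band_cols].to_numpy()
    x_drug = power.loc[[(a, drug) for a in animals], band_cols].to_numpy()
    if log_transform:
        if (x_ref <= 0).any() or (x_drug <= 0).any():
            raise ParameterError("log transform requires strictly positive band power")
        x_ref, x_drug = np.log10(x_ref), np.log10(x_drug)

    F, p_int = _interaction_screen(x_ref, x_drug, animals, band_cols)
    if not (p_int < alpha):
        return BinTestReport(F, p_int, False, len(animals), None)

    t, p = sps.ttest_rel(x_drug, x_ref, axis=0)
    reject, p_adj = bh_adjust(p, q=q)
    bins = pd.DataFrame(
        {
            "freq": band_cols,
            "t": t,
            "p": p,
            "sig_05": p < 0.05,
            "sig_01": p < 0.01,
            "bh_sig": reject,
            "p_bh": p_adj,
        }
    )
    return BinTestReport(F, p_int, True, len(animals), bins)


def _interaction_screen(x_ref, x_drug, animals, band_cols):
    """Two-way (frequency x condition) repeated-measures interaction F and p.

    Frequency is treated as a repeated factor without sphericity correction:
    this step only screens; the per-bin tests carry the inferential weight.
    """
    import pingouin as pg

    n, m = x_ref.shape
    long = pd.DataFrame(
        {
            "animal": np.repeat(animals, 2 * m),
            "condition": np.tile(np.repeat(["ref", "drug"], m), n),
            "freq": np.tile(band_cols, 2 * n),
            "power": np.concatenate([np.c_[x_ref[i], x_drug[i]].T.ravel() for i in range(n)]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=long, dv="power", within=["condition", "freq"], subject="animal"
        )
    row = aov.loc[aov["Source"] == "condition * freq"].iloc[0]
    return float(row["F"]), float(row["p_unc"])
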