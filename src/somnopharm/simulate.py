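"""Synthetic within-subject sleep cohorts with known drug effects.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised -- and ground-truth drug parameters
recovered -- without any real recordings.

Hypnograms are semi-Markov: each vigilance-state bout draws a geometric dwell
time at 4 s epoch resolution (memoryless at the epoch scale, the simplest
structure that exercises the episode/interruption logic), then exits through
a per-state kernel. REM is entered only from NREM; brief awakenings are an
independent overlay process -- short wake intrusions inserted inside NREM
bouts with a per-epoch hazard -- so their rate is a directly recoverable
ground-truth parameter rather than an emergent property of the kernel.

Drug effects are multiplicative: a factor on the NREM-to-REM exit probability
(REM-entry suppression), on the NREM and REM mean dwell times, on the
brief-awakening hazard, and on 6-30 Hz EEG power during NREM. The identity
drug (all factors 1) is the null condition.

State-conditioned EEG is synthesized in the frequency domain from a target
spectrum (1/f background plus Gaussian peaks: a NREM delta peak, a wake/REM
theta peak) with uniform random phases. Amplitudes are pre-compensated for
the Hanning analysis window's three-bin smoothing kernel, so the mean
spectrum returned by the analyzer matches the target per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded

from .hypnogram import (
    EPOCH_S,
    STATES,
    AnalysisWindow,
    CohortDataset,
    EpochSeries,
    ParameterError,
    slice_window,
    state_code,
)
from .spectral import FRAME, FS, N_BINS, EpochSpectra, cohort_state_spectra, state_spectra

FULL_BINS = FRAME // 2 + 1           # 513 bins, 0-128 Hz
FULL_FREQS = np.arange(FULL_BINS) * 0.25
HI_BAND = (FULL_FREQS >= 6.0) & (FULL_FREQS <= 30.0)


@dataclass(frozen=True)
class SleepDynamicsParams:
    """Baseline semi-Markov dynamics of a mouse in the early light phase.

    Mean bout durations (seconds) parameterize geometric dwell at 4 s
    resolution; exit rows give the next-state probabilities on leaving a
    state. Defaults put roughly a third of time in wake, 60% in NREM and
    7-8% in REM (REM near 11% of total sleep time), with brief-awakening
    intrusions at about ten per hour of sleep.
    """

    mean_bout_s: tuple[float, float, float] = (100.0, 160.0, 64.0)  # W, N, R
    exit_w: tuple[float, float] = (1.0, 0.0)    # -> (N, R); REM entry only from N
    exit_n: tuple[float, float] = (0.7, 0.3)    # -> (W, R)
    exit_r: tuple[float, float] = (0.6, 0.4)    # -> (W, N)
    ba_hazard: float = 0.012                    # intrusion start probability per N epoch
    initial: tuple[float, float, float] = (0.8, 0.2, 0.0)
    artifact_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.mean_bout_s) < EPOCH_S:
            raise ParameterError(f"mean bout durations must be >= {EPOCH_S} s")
        for name, row in (("exit_w", self.exit_w), ("exit_n", self.exit_n),
                          ("exit_r", self.exit_r)):
            if min(row) < 0 or abs(sum(row) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must be non-negative and sum to 1")
        if self.exit_w[1] != 0.0:
            raise ParameterError("REM may only be entered from NREM (exit_w -> R must be 0)")
        if not (0 <= self.ba_hazard < 1):
            raise ParameterError("ba_hazard must lie in [0, 1)")
        if abs(sum(self.initial) - 1.0) > 1e-9 or min(self.initial) < 0:
            raise ParameterError("initial state distribution must be a probability vector")
        if not (0 <= self.artifact_rate < 1):
            raise ParameterError("artifact_rate must lie in [0, 1)")


@dataclass(frozen=True)
class DrugEffectParams:
    """Multiplicative ground-truth drug effects; the identity drug is all ones."""

    rem_entry_mult: float = 1.0       # on the N->R exit probability (<1: REM suppression)
    nrem_dwell_mult: float = 1.0      # on the NREM mean bout duration (>1: longer bouts)
    ba_hazard_mult: float = 1.0       # on the brief-awakening hazard (<1: fewer)
    rem_dwell_mult: float = 1.0       # on the REM mean bout duration
    hi_freq_power_mult: float = 1.0   # on 6-30 Hz NREM EEG power

    def __post_init__(self) -> None:
        if self.rem_entry_mult < 0:
            raise ParameterError("rem_entry_mult must be >= 0")
        for name in ("nrem_dwell_mult", "ba_hazard_mult", "rem_dwell_mult",
                     "hi_freq_power_mult"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


IDENTITY_DRUG = DrugEffectParams()

#: named cohort presets: condition -> drug effects
PRESETS: dict[str, dict[str, DrugEffectParams]] = {
    "null": {"saline": IDENTITY_DRUG, "drug": IDENTITY_DRUG},
    "cno-like": {
        "saline": IDENTITY_DRUG,
        "drug": DrugEffectParams(
            rem_entry_mult=0.5, nrem_dwell_mult=1.5, ba_hazard_mult=0.6,
            rem_dwell_mult=1.0, hi_freq_power_mult=0.85,
        ),
    },
}


def _effective_dynamics(params: SleepDynamicsParams, drug: DrugEffectParams):
    """Dwell exit probabilities per epoch and the 3x2 exit kernels under a drug."""
    mw, mn, mr = params.mean_bout_s
    mn *= drug.nrem_dwell_mult
    mr *= drug.rem_dwell_mult
    p_exit = np.array([EPOCH_S / mw, EPOCH_S / mn, EPOCH_S / mr])
    pnr = params.exit_n[1] * drug.rem_entry_mult
    if pnr > 1:
        raise ParameterError("rem_entry_mult pushes the N->R exit probability above 1")
    exits = {
        0: ((1, 2), (params.exit_w[0], params.exit_w[1])),
        1: ((0, 2), (1.0 - pnr, pnr)),          # wake absorbs the remainder
        2: ((0, 1), (params.exit_r[0], params.exit_r[1])),
    }
    return p_exit, exits


def stationary_occupancy(
    params: SleepDynamicsParams, drug: DrugEffectParams = IDENTITY_DRUG
) -> np.ndarray:
    """Long-run W/N/R time shares of the bout process (no intrusion overlay).

    Computed analytically: the embedded exit chain's stationary distribution,
    weighted by mean dwell times.
    """
    p_exit, exits = _effective_dynamics(params, drug)
    P = np.zeros((3, 3))
    for st, (targets, probs) in exits.items():
        for tg, pr in zip(targets, probs):
            P[st, tg] = pr
    vals, vecs = np.linalg.eig(P.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    pi = pi / pi.sum()
    occ = pi / p_exit  # mean dwell epochs = 1 / p_exit
    return occ / occ.sum()


def simulate_hypnogram(
    params: SleepDynamicsParams,
    drug: DrugEffectParams = IDENTITY_DRUG,
    duration_s: float = 21600.0,
    seed: int | np.random.Generator = 0,
    animal_id: str = "sim",
    condition: str = "saline",
    t0_offset: float = 0.0,
) -> EpochSeries:
    """Draw one scored recording from the semi-Markov model.

    Bouts alternate through the exit kernel with geometric dwells; the drug's
    REM-entry factor rescales the N->R exit probability (wake absorbing the
    remainder) and the dwell factors stretch the NREM/REM means. Brief
    awakenings are then overlaid: each interior NREM epoch starts a 1-4 epoch
    wake intrusion with probability hazard * ba_hazard_mult, provided the
    intrusion stays strictly inside the NREM bout. Reproducible given a seed.
    """
    if duration_s <= 0 or duration_s % EPOCH_S:
        raise ParameterError(f"duration_s must be a positive multiple of {EPOCH_S}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(duration_s // EPOCH_S)
    p_exit, exits = _effective_dynamics(params, drug)

    codes = np.empty(n, dtype=np.int8)
    state = int(rng.choice(3, p=params.initial))
    pos = 0
    while pos < n:
        length = int(rng.geometric(p_exit[state]))
        codes[pos: pos + length] = state
        pos += length
        targets, probs = exits[state]
        state = targets[0] if rng.random() < probs[0] else targets[1]

    hazard = params.ba_hazard * drug.ba_hazard_mult
    if hazard > 0:
        is_n = codes == 1
        starts = np.flatnonzero(is_n & (rng.random(n) < hazard))
        lengths = rng.integers(1, 5, size=starts.size)
        for i, length in zip(starts, lengths):
            j = i + int(length)
            if i == 0 or j >= n:
                continue
            # strictly inside an NREM bout: flanks and body all still NREM
            if codes[i - 1] == 1 and codes[j] == 1 and (codes[i:j] == 1).all():
                codes[i:j] = 0

    artifact = rng.random(n) < params.artifact_rate
    return EpochSeries(animal_id, condition, codes, artifact, t0_offset)


@dataclass(frozen=True)
class InterAnimalVariability:
    """Log-normal between-animal jitter, shared across an animal's conditions."""

    dwell_log_sd: float = 0.15
    hazard_log_sd: float = 0.20

    def __post_init__(self) -> None:
        if self.dwell_log_sd < 0 or self.hazard_log_sd < 0:
            raise ParameterError("variability SDs must be >= 0")


def generate_cohort(
    n_animals: int,
    conditions: dict[str, DrugEffectParams] | str = "cno-like",
    params: SleepDynamicsParams = SleepDynamicsParams(),
    variability: InterAnimalVariability = InterAnimalVariability(),
    duration_s: float = 21600.0,
    seed: int = 0,
    reference: str = "saline",
) -> CohortDataset:
    """Simulate a within-subject cohort: every animal under every condition.

    ``conditions`` maps condition labels to drug effects (or names a preset).
    Each animal draws log-normal random effects on its dwell means and
    brief-awakening hazard once, shared across its conditions; recording
    seeds are spawned deterministically from the master seed, so the same
    seed always reproduces the same cohort.
    """
    if isinstance(conditions, str):
        conditions = PRESETS[conditions]
    if n_animals < 3:
        raise ParameterError("a cohort needs at least 3 animals")
    if reference not in conditions:
        raise ParameterError(f"reference condition {reference!r} not among conditions")
    width = max(2, len(str(n_animals)))
    recs = []
    animal_seeds = np.random.SeedSequence(seed).spawn(n_animals)
    for a_idx, a_seed in enumerate(animal_seeds):
        animal = f"m{a_idx + 1:0{width}d}"
        streams = a_seed.spawn(len(conditions) + 1)
        jit = np.random.default_rng(streams[0])
        dwell_f = np.exp(jit.normal(0.0, variability.dwell_log_sd, size=3))
        hazard_f = float(np.exp(jit.normal(0.0, variability.hazard_log_sd)))
        a_params = replace(
            params,
            mean_bout_s=tuple(m * f for m, f in zip(params.mean_bout_s, dwell_f)),
            ba_hazard=min(params.ba_hazard * hazard_f, 0.99),
        )
        for c_idx, (cond, drug) in enumerate(conditions.items()):
            recs.append(
                simulate_hypnogram(
                    a_params, drug, duration_s,
                    seed=np.random.default_rng(streams[c_idx + 1]),
                    animal_id=animal, condition=cond,
                )
            )
    return CohortDataset.from_recordings(
        recs, reference=reference, conditions=list(conditions)
    )


# ---------------------------------------------------------------------------
# state-conditioned EEG synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralShapeParams:
    """Target EEG spectrum: 1/f background plus Gaussian peaks.

    ``peaks`` is a tuple of (center Hz, width Hz, height) triples; heights
    are in the same arbitrary power units as ``scale``.
    """

    exponent: float = 1.0
    scale: float = 1.0
    peaks: tuple[tuple[float, float, float], ...] = ()

    def target(self, freqs: np.ndarray) -> np.ndarray:
        """Target power on a frequency grid; 0 at DC."""
        with np.errstate(divide="ignore"):
            s = np.where(freqs > 0, self.scale * freqs ** -self.exponent, 0.0)
        for center, width, height in self.peaks:
            s = s + height * np.exp(-0.5 * ((freqs - center) / width) ** 2)
        if (s[1:] <= 0).any():
            raise ParameterError("target spectrum must be positive above DC")
        return s


#: default per-state shapes: NREM has a delta peak near 1.5 Hz and more
#: broadband power; wake and REM carry a theta peak near 7 Hz
STATE_SHAPES: dict[str, SpectralShapeParams] = {
    "W": SpectralShapeParams(1.0, 1.0, ((7.0, 1.0, 0.8),)),
    "N": SpectralShapeParams(1.0, 1.5, ((1.5, 0.75, 3.0),)),
    "R": SpectralShapeParams(1.0, 1.0, ((7.0, 1.0, 2.0),)),
}


def target_spectrum(
    state: str,
    shape: SpectralShapeParams | None = None,
    drug: DrugEffectParams = IDENTITY_DRUG,
    full: bool = False,
) -> np.ndarray:
    """The spectrum the analyzer should recover for a state under a drug.

    The drug's high-frequency factor applies to the 6-30 Hz bins during NREM
    only. Returns the 121-bin analysis grid, or the full 513-bin synthesis
    grid when ``full=True``.
    """
    shape = shape or STATE_SHAPES[STATES[state_code(state)]]
    s = shape.target(FULL_FREQS)
    if state_code(state) == 1 and drug.hi_freq_power_mult != 1.0:
        s = s.copy()
        s[HI_BAND] *= drug.hi_freq_power_mult
    return s if full else s[:N_BINS]


@lru_cache(maxsize=32)
def _synthesis_amplitudes(
    state: str, shape: SpectralShapeParams | None, drug: DrugEffectParams
) -> np.ndarray:
    """rFFT amplitudes whose Hann-analyzed mean spectrum equals the target.

    The Hann periodogram smears power over three bins with weights
    (1, 4, 1)/6; the target is deconvolved through that tridiagonal kernel so
    the generator/analyzer round trip is unbiased even at spectral peaks and
    at the steep low-frequency end of the 1/f background.
    """
    s = target_spectrum(state, shape, drug, full=True)
    m = FULL_BINS - 2  # unknowns: bins 1 .. 511 (DC and Nyquist forced to 0)
    ab = np.zeros((3, m))
    ab[0, 1:] = 1.0 / 6.0
    ab[1, :] = 4.0 / 6.0
    ab[2, :-1] = 1.0 / 6.0
    compensated = solve_banded((1, 1), ab, s[1:-1])
    compensated = np.clip(compensated, 0.0, None)
    amp = np.zeros(FULL_BINS)
    amp[1:-1] = FRAME * np.sqrt(compensated / 2.0)
    return amp


def synthesize_eeg_epochs(
    state: str,
    n_epochs: int,
    rng: np.random.Generator,
    shape: SpectralShapeParams | None = None,
    drug: DrugEffectParams = IDENTITY_DRUG,
    gain: float = 1.0,
) -> np.ndarray:
    """Draw (n_epochs, 1024) EEG frames of one state: random-phase synthesis.

    Each epoch gets independent uniform phases on fixed amplitudes, so epochs
    are independent and the per-bin sampling noise of mean spectra is small.
    ``gain`` scales total power (e.g. per-recording electrode gain jitter).
    """
    amp = _synthesis_amplitudes(STATES[state_code(state)], shape, drug)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(n_epochs, FULL_BINS - 2))
    coeffs = np.zeros((n_epochs, FULL_BINS), dtype=complex)
    coeffs[:, 1:-1] = (math.sqrt(gain) * amp[1:-1]) * np.exp(1j * phases)
    return np.fft.irfft(coeffs, n=FRAME, axis=1)


def synthesize_eeg_epoch(
    state: str,
    shape: SpectralShapeParams | None = None,
    drug: DrugEffectParams = IDENTITY_DRUG,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One 1024-sample EEG frame of the given state (convenience wrapper)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return synthesize_eeg_epochs(state, 1, rng, shape, drug)[0]


def recording_spectra(
    s: EpochSeries,
    drug: DrugEffectParams = IDENTITY_DRUG,
    shapes: dict[str, SpectralShapeParams] | None = None,
    rng: np.random.Generator | int = 0,
    gain: float = 1.0,
) -> EpochSpectra:
    """Synthesize EEG for every epoch of a recording and analyze it.

    Frames are drawn state-conditionally, stacked in epoch order, and run
    through the per-epoch spectral analyzer, giving spectra rows aligned 1:1
    with the hypnogram.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shapes = shapes or STATE_SHAPES
    frames = np.empty((len(s), FRAME))
    for code, st in enumerate(STATES):
        idx = np.flatnonzero(s.codes == code)
        if idx.size:
            frames[idx] = synthesize_eeg_epochs(st, idx.size, rng, shapes[st], drug, gain)
    return EpochSpectra.from_frames(frames)


def cohort_nrem_spectra(
    cohort: CohortDataset,
    conditions: dict[str, DrugEffectParams],
    window: AnalysisWindow,
    seed: int = 0,
    rec_gain_log_sd: float = 0.05,
    shapes: dict[str, SpectralShapeParams] | None = None,
    state: str = "N",
):
    """Per-recording mean NREM spectra for a simulated cohort.

    Synthesizes EEG for each recording's window, applies a log-normal
    per-recording broadband gain (session-to-session electrode impedance
    drift; its SD is in natural-log units), and averages artifact-free
    epochs of ``state``. Returns the (animal, condition) x frequency frame
    consumed by the bin-wise statistics.
    """
    keys = sorted(cohort.recordings)
    streams = np.random.SeedSequence(seed).spawn(len(keys))
    rows = []
    for key, stream in zip(keys, streams):
        rec = slice_window(cohort.recordings[key], window)
        rng = np.random.default_rng(stream)
        gain = float(np.exp(rng.normal(0.0, rec_gain_log_sd)))
        spectra = recording_spectra(rec, conditions[rec.condition], shapes, rng, gain)
        row = state_spectra(spectra, rec, state)
        if row is not None:
            rows.append(row)
    return cohort_state_spectra(rows)
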