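# somnopharm

Quantifying drug effects on mouse sleep from scored EEG/EMG recordings.

Sedatives, antipsychotics, and — less obviously — chemogenetic actuators such
as clozapine-N-oxide (CNO) and compound 21 (C21) can alter sleep in rodents
even without any engineered receptor to act on. Detecting such effects takes
more than comparing time asleep: the sensitive readouts are the *relative*
amount of REM sleep, sleep architecture (episode durations and counts,
latencies), sleep continuity (brief awakenings), vigilance-state stability
(transition probabilities), and the NREM EEG spectrum. `somnopharm`
implements that analysis pipeline for within-subject designs — each animal
recorded under a reference (saline) condition and one or more drug
conditions, hypnograms scored in 4 s epochs as wake (W), NREM (N), or REM
(R), aligned to the injection at t = 0 — together with a synthetic cohort
generator so every stage can be validated against known ground truth.

## What it computes

For each recording and analysis window (acute 0–2 h, prolonged 0–6 h):

- **Time in state** — %W, %N, %R of the window; REM as % of total sleep time
  (REM%TST = 100·R/(N+R)); REM/NREM ratio.
- **Episodes** — merged bouts of one state: W/N episodes require ≥ 60 s span
  tolerating interruptions ≤ 16 s each; REM episodes require ≥ 16 s with
  interruptions ≤ 8 s. Counts, mean and maximum span per state.
- **Latencies** — injection → first NREM episode (sleep onset); sleep onset →
  first REM epoch; cumulative NREM before the first REM epoch.
- **Brief awakenings** — wake intrusions of 4–16 s flanked by sleep, per hour
  of total sleep time (a sleep-fragmentation marker).
- **State transitions** — 3×3 epoch-pair continuation/shift row percentages,
  compared between conditions with a paired sign-flip resampling test
  (B = 5000 iterations; one-sided p = #{T\* ≥ T_obs}/B, ties counted, floored
  at 1/B).
- **Spectra** — per-epoch Hanning periodograms (0–30 Hz, 0.25 Hz bins,
  Parseval-consistent scaling), state-conditioned means over artifact-free
  epochs, drug/reference relative spectra, and tiered bin-wise statistics on
  the 0.5–30 Hz band (119 bins): a frequency × condition repeated-measures
  interaction screen, then per-bin paired t-tests flagged at p<0.05, p<0.01,
  and Benjamini–Hochberg q<0.05.
- **Group statistics** — repeated-measures ANOVA with Greenhouse–Geisser
  corrected (fractional) degrees of freedom, REML mixed-model fallback for
  unbalanced designs, Dunnett-adjusted post hoc comparisons against saline
  gated on a significant main effect, paired Cohen's d = mean(diff)/sd(diff)
  (equivalently t/√n), and noncentral-t power/sample-size for paired tests.

The semi-Markov simulator (`somnopharm.simulate`) draws geometric state
bouts with configurable exit kernels, overlays brief awakenings as an
independent hazard process, synthesizes state-conditioned EEG (1/f
background, NREM delta peak, wake/REM theta peak), and encodes drug effects
as multipliers — REM-entry suppression, NREM-bout elongation, reduced
brief-awakening hazard, 6–30 Hz NREM power suppression — that the pipeline
must recover.

## Worked example

```python
import somnopharm as sp

cfg = sp.StudyConfig(preset="cno-like", n_animals=12, seed=1, spectra=True)
bundle = sp.run_study(cfg)

post = bundle.tables["stats_posthoc"]
row = post[(post.metric == "rem_pct_tst") & (post.window == "prolonged")].iloc[0]
print(f"REM as % of total sleep time (0-6 h): t({int(row.df)}) = {row.t:.3f}, "
      f"p = {row.p_raw:.2e}, Cohen's d = {row.d:.3f}")

panel = bundle.tables["transitions"]
nn = panel[(panel["from"] == "N") & (panel["to"] == "N")].iloc[0]
print(f"NREM>NREM continuation: diff = +{nn.observed_diff:.2f} percentage points, "
      f"resampling p = {nn.p_value:.4f} (B = 5000)")

spec = bundle.tables["spectra"]
flagged = spec.loc[spec.bh_sig, "freq"]
print(f"NREM spectrum: BH-significant suppression in "
      f"{flagged.min():.2f}-{flagged.max():.2f} Hz ({len(flagged)} bins)")

print("smallest n for d=1, one-sided alpha=0.05, power 0.9:",
      sp.paired_t_sample_size(1.0, 0.05, 0.9, "one-sided"))
```

prints

```
REM as % of total sleep time (0-6 h): t(11) = -7.895, p = 7.41e-06, Cohen's d = -2.279
NREM>NREM continuation: diff = +1.58 percentage points, resampling p = 0.0002 (B = 5000)
NREM spectrum: BH-significant suppression in 6.00-30.00 Hz (97 bins)
smallest n for d=1, one-sided alpha=0.05, power 0.9: 11
```

Read top to bottom: the simulated "CNO-like" drug (REM-entry halved, NREM
bouts 1.5× longer, brief-awakening hazard 0.6×, 6–30 Hz NREM power 0.85×)
produces, in a 12-animal within-subject cohort, a large REM%TST reduction, a
significantly increased probability of staying in NREM from one 4 s epoch to
the next, and an FDR-surviving spectral suppression confined exactly to the
manipulated 6–30 Hz band. The last line is the design-stage answer to "how
many animals do I need to detect a large (d = 1) paired effect with 90%
power?" — eleven.

The same pipeline runs on real scored data from a TSV table
(`animal_id condition epoch_index state artifact`, one row per 4 s epoch):

```sh
somnopharm simulate --preset cno-like --n 12 --seed 1 --out cohort.tsv
somnopharm architecture --data cohort.tsv --window prolonged --out arch.csv
somnopharm transitions --data cohort.tsv --drug drug --iters 5000 --seed 1
somnopharm run --config study.yaml
```

## Layout

- `somnopharm.hypnogram` — data model, TSV/EDF I/O, windows, validation
- `somnopharm.architecture` — episodes, allocations, latencies, fragmentation
- `somnopharm.transitions` — transition tables and the resampling test
- `somnopharm.spectral` — periodograms, state spectra, bin-wise statistics
- `somnopharm.stats` — RM-ANOVA/GG, Dunnett, paired t, Cohen's d, BH, power
- `somnopharm.simulate` — semi-Markov hypnograms and EEG synthesis
- `somnopharm.pipeline` / `somnopharm.cli` — study orchestration and CLI

See `docs/methods.md` for the statistical model, simulator assumptions, and
numerical choices.
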