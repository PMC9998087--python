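"""Full-study orchestration: architecture -> transitions -> spectra -> stats.

A study run is driven by a :class:`StudyConfig` (built in code or from YAML)
whose defaults reproduce the canonical analysis parameters: 4 s epochs,
acute (0-2 h) and prolonged (0-6 h) windows, 60 s / 16 s and 16 s / 8 s
episode rules, 5000 resampling iterations, alpha = 0.05, saline reference.
Each stage emits a tidy table; a manifest records the seed, package version,
and a hash of the resolved configuration so any table can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .architecture import EPISODE_RULES, architecture_summary
from .hypnogram import (
    WINDOWS,
    AnalysisWindow,
    CohortDataset,
    SomnopharmError,
    load_hypnogram_table,
    validate_cohort,
)
from .simulate import (
    PRESETS,
    DrugEffectParams,
    InterAnimalVariability,
    SleepDynamicsParams,
    cohort_nrem_spectra,
    generate_cohort,
)
from .spectral import BAND_FREQS, binwise_stats, relative_spectrum
from .stats import dunnett_vs_reference, rm_anova_gg
from .transitions import transition_panel

#: architecture metrics entering group-level testing
STAT_METRICS = (
    "pct_W", "pct_N", "pct_R", "rem_pct_tst", "rem_nrem_ratio",
    "nrem_latency_s", "rem_latency_s", "nrem_before_rem_min",
    "brief_awakening_rate",
    "n_episode_count", "n_episode_mean_s", "n_episode_max_s",
    "r_episode_count", "r_episode_mean_s", "r_episode_max_s",
    "w_episode_count", "w_episode_mean_s", "w_episode_max_s",
)


@dataclass
class StudyConfig:
    """Resolved study parameters; defaults are the canonical analysis values."""

    data: str | None = None                   # hypnogram TSV; exclusive with preset
    preset: str | None = None                 # synthetic preset name (see PRESETS)
    n_animals: int = 12
    duration_s: float = 21600.0
    reference: str = "saline"
    windows: tuple[str, ...] = ("acute", "prolonged")
    episode_rules: dict = field(default_factory=lambda: {
        st: list(rule) for st, rule in EPISODE_RULES.items()
    })
    resampling_iters: int = 5000
    resampling_side: str = "greater"
    transition_window: str = "prolonged"
    spectra: bool = False                     # synthesize + test NREM spectra (preset mode)
    spectra_window: str = "acute"
    rec_gain_log_sd: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SomnopharmError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.windows, list):
            cfg.windows = tuple(cfg.windows)
        return cfg

    def resolved_windows(self) -> dict[str, AnalysisWindow]:
        out = {}
        for name in self.windows:
            if name not in WINDOWS:
                raise SomnopharmError(f"unknown analysis window {name!r}")
            out[name] = WINDOWS[name]
        return out

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyBundle:
    """All output tables of one study run plus its provenance manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict


def build_cohort(config: StudyConfig) -> CohortDataset:
    if (config.data is None) == (config.preset is None):
        raise SomnopharmError("config must name exactly one of 'data' or 'preset'")
    if config.data is not None:
        return load_hypnogram_table(config.data, reference=config.reference)
    if config.preset not in PRESETS:
        raise SomnopharmError(f"unknown preset {config.preset!r}; choose from {list(PRESETS)}")
    return generate_cohort(
        config.n_animals, config.preset, duration_s=config.duration_s,
        seed=config.seed, reference=config.reference,
    )


def group_stats_tables(
    arch: pd.DataFrame, reference: str, alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main-effect and Dunnett post hoc tables over all architecture metrics."""
    main_rows, posthoc_rows = [], []
    for (window, metric), grp in arch.groupby(["window", "metric"], sort=True):
        if metric not in STAT_METRICS:
            continue
        wide = grp.pivot(index="animal_id", columns="condition", values="value")
        cols = [reference] + [c for c in wide.columns if c != reference]
        wide = wide[cols]
        try:
            main = rm_anova_gg(wide)
        except Exception as exc:  # degenerate metrics (all-missing, zero variance)
            main_rows.append({
                "window": window, "metric": metric, "F": float("nan"),
                "df1": float("nan"), "df2": float("nan"), "p": float("nan"),
                "epsilon": float("nan"), "method": "", "n_complete": 0,
                "error": str(exc),
            })
            continue
        main_rows.append({
            "window": window, "metric": metric, "F": main.F, "df1": main.df1,
            "df2": main.df2, "p": main.p, "epsilon": main.epsilon,
            "method": main.method, "n_complete": main.n_complete, "error": "",
        })
        post = dunnett_vs_reference(wide, reference, main_effect=main, alpha=alpha)
        post.insert(0, "metric", metric)
        post.insert(0, "window", window)
        posthoc_rows.append(post)
    main_df = pd.DataFrame(main_rows)
    post_df = (
        pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows else pd.DataFrame()
    )
    return main_df, post_df


def run_study(config: StudyConfig) -> StudyBundle:
    """Execute the configured analysis end to end.

    Stages: cohort validation, per-window architecture metrics, group-level
    main effects with Dunnett post hocs, the 9-transition resampling panel
    per drug condition, and (preset mode with ``spectra=True``) the NREM
    spectral report. Any stage failure aborts with a stage-tagged message.
    """
    cohort = build_cohort(config)
    windows = config.resolved_windows()
    report = validate_cohort(cohort)
    tables: dict[str, pd.DataFrame] = {}
    tables["validation"] = pd.DataFrame({"problem": report.problems})

    try:
        rules = {st: tuple(rule) for st, rule in config.episode_rules.items()}
        arch = architecture_summary(cohort, windows, rules)
    except SomnopharmError as exc:
        raise SomnopharmError(f"[architecture] {exc}") from exc
    tables["architecture"] = arch

    try:
        main_df, post_df = group_stats_tables(arch, cohort.reference, config.alpha)
    except SomnopharmError as exc:
        raise SomnopharmError(f"[stats] {exc}") from exc
    tables["stats_main"] = main_df
    tables["stats_posthoc"] = post_df

    drugs = [c for c in cohort.conditions if c != cohort.reference]
    panel_frames = []
    for i, drug in enumerate(drugs):
        try:
            panel = transition_panel(
                cohort, cohort.reference, drug, B=config.resampling_iters,
                seed=config.seed + 7919 * (i + 1), side=config.resampling_side,
                alpha=config.alpha, window=windows.get(config.transition_window),
            )
        except SomnopharmError as exc:
            raise SomnopharmError(f"[transitions] {exc}") from exc
        panel.insert(0, "condition", drug)
        panel_frames.append(panel)
    tables["transitions"] = pd.concat(panel_frames, ignore_index=True)

    if config.spectra:
        if config.preset is None:
            raise SomnopharmError("[spectra] spectral synthesis requires preset mode")
        conditions = PRESETS[config.preset]
        try:
            spec = cohort_nrem_spectra(
                cohort, conditions, WINDOWS[config.spectra_window],
                seed=config.seed + 104729, rec_gain_log_sd=config.rec_gain_log_sd,
            )
            frames = []
            for drug in drugs:
                rep = binwise_stats(spec, cohort.reference, drug, alpha=config.alpha)
                if rep.bins is not None:
                    bins = rep.bins.copy()
                else:
                    bins = pd.DataFrame({"freq": BAND_FREQS})
                bins.insert(0, "condition", drug)
                bins["interaction_F"] = rep.interaction_F
                bins["interaction_p"] = rep.interaction_p
                bins["tested"] = rep.tested
                power = spec[[c for c in spec.columns if c != "n_epochs"]]
                rel = []
                for a in power.index.get_level_values(0).unique():
                    sub = power.loc[a]
                    if cohort.reference in sub.index and drug in sub.index:
                        rel.append(relative_spectrum(
                            sub.loc[drug].to_numpy(), sub.loc[cohort.reference].to_numpy()
                        ))
                bins["relative_pct"] = pd.DataFrame(rel).mean(axis=0).to_numpy()
                frames.append(bins)
            tables["spectra"] = pd.concat(frames, ignore_index=True)
        except SomnopharmError as exc:
            raise SomnopharmError(f"[spectra] {exc}") from exc

    manifest = {
        "package": "somnopharm",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_animals": len(cohort.animals()),
        "conditions": list(cohort.conditions),
    }
    return StudyBundle(tables, manifest)


def export_tables(bundle: StudyBundle, out_dir, formats: tuple[str, ...] = ("csv",)) -> list[Path]:
    """Write every table (CSV canonical; optional parquet) plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in bundle.tables.items():
        for fmt in formats:
            path = out / f"{name}.{fmt}"
            if fmt == "csv":
                table.to_csv(path, index=False)
            elif fmt == "parquet":
                table.to_parquet(path)
            else:
                raise SomnopharmError(f"unsupported export format {fmt!r}")
            written.append(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
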