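"""One-command experiment reproduction: config, sweep, reporting, manifest.

The zero-argument default configuration reproduces the study setup on the
synthetic cohort: six subjects, 35 trials per class at 256 Hz on the
11-channel sensorimotor montage, 8-30 Hz 2nd-order Butterworth filtering,
2-6 s segmentation, the eight-window scheme, the three decoders and both
validation regimes.  A run writes a tidy results CSV (one row per subject x
classifier x window x regime), a per-duration summary CSV, a trend figure
and a JSON manifest sufficient to re-create the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import CLASSIFIER_NAMES, TrainConfig
from .evaluate import (
    POSITIVE_CLASS,
    REGIMES,
    duration_summary,
    results_frame,
    run_sweep,
)
from .preprocess import bandpass, segment, window_scheme
from .synthdata import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

RESULTS_CSV = "results.csv"
SUMMARY_CSV = "summary_by_duration.csv"
SUMMARY_TXT = "summary_tables.txt"
MANIFEST_JSON = "manifest.json"
TREND_PNG = "duration_trend.png"


@dataclass
class ExperimentConfig:
    """Declarative description of one full experiment."""

    n_subjects: int = 6
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    regimes: tuple[str, ...] = REGIMES
    global_seed: int = 0
    output_dir: str = "mibci_run"
    n_csp_pairs: int = 3
    make_plot: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides

    def __post_init__(self) -> None:
        self.classifiers = tuple(self.classifiers)
        self.regimes = tuple(self.regimes)
        for c in self.classifiers:
            if c not in CLASSIFIER_NAMES:
                raise ValueError(
                    f"classifiers: unknown classifier {c!r}; valid: {CLASSIFIER_NAMES}"
                )
        for r in self.regimes:
            if r not in REGIMES:
                raise ValueError(f"regimes: unknown regime {r!r}; valid: {REGIMES}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def subject_configs(self) -> list[SimulationConfig]:
        """Per-subject simulation configs with seeds derived from the global seed."""
        base = {k: v for k, v in self.simulation.items() if k != "seed"}
        return [
            SimulationConfig(seed=(self.global_seed * 1000 + i) % (2**31), **base)
            for i in range(self.n_subjects)
        ]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from YAML, validating field names."""
    obj = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(obj) - valid
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return ExperimentConfig(**obj)


def prepare_cohort(config: ExperimentConfig) -> tuple[dict, str]:
    """Simulate, band-pass and segment every subject session.

    Returns ``(epoch_sets, task_mode)`` where ``epoch_sets`` maps subject id
    to segmented epochs ready for the sweep.
    """
    sim_configs = config.subject_configs()
    logger.info("simulating %d subject session(s)", len(sim_configs))
    sessions = generate_cohort(sim_configs)
    epoch_sets = {}
    for i, raw in enumerate(sessions):
        epoch_sets[f"S{i + 1:02d}"] = segment(bandpass(raw))
    logger.info(
        "segmented %s trials per subject",
        {k: v.n_trials for k, v in epoch_sets.items()},
    )
    return epoch_sets, sim_configs[0].task_mode


def cv_duration_curves(config: ExperimentConfig) -> pd.DataFrame:
    """Cross-validated accuracy/FPR per classifier and window duration.

    Convenience wrapper: simulate the cohort, sweep the CV regime only, and
    return the per-duration summary — one run of the study's headline curves.
    """
    epoch_sets, task_mode = prepare_cohort(config)
    results = run_sweep(
        epoch_sets,
        classifiers=config.classifiers,
        regimes=("cv_5fold",),
        cfg=TrainConfig(seed=config.global_seed % (2**31), **config.train),
        positive_class=POSITIVE_CLASS[task_mode],
        seed=config.global_seed % (2**31),
        n_csp_pairs=config.n_csp_pairs,
    )
    return duration_summary(results)


def run_experiment(
    config: ExperimentConfig | str | Path, output_dir: str | Path | None = None
) -> Path:
    """Simulate the cohort, run the full sweep, write all artifacts.

    Returns the output directory.  Two runs with identical config produce
    byte-identical results CSVs.
    """
    if not isinstance(config, ExperimentConfig):
        config = load_config(config)
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_configs = config.subject_configs()
    epoch_sets, task_mode = prepare_cohort(config)

    train_cfg = TrainConfig(seed=config.global_seed % (2**31), **config.train)
    results = run_sweep(
        epoch_sets,
        classifiers=config.classifiers,
        regimes=config.regimes,
        cfg=train_cfg,
        positive_class=POSITIVE_CLASS[task_mode],
        seed=config.global_seed % (2**31),
        n_csp_pairs=config.n_csp_pairs,
    )
    df = results_frame(results)
    summary = duration_summary(df)

    df.to_csv(out / RESULTS_CSV, index=False)
    summary.to_csv(out / SUMMARY_CSV, index=False)
    (out / SUMMARY_TXT).write_text(format_report(df))
    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "subject_seeds": [c.seed for c in sim_configs],
        "task_mode": task_mode,
        "positive_class": POSITIVE_CLASS[task_mode],
        "n_results": len(results),
        "windows": [w.name for w in window_scheme()],
    }
    (out / MANIFEST_JSON).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if config.make_plot:
        plot_duration_trend(summary, out / TREND_PNG)
    logger.info("wrote %d results to %s", len(results), out)
    return out


def _config_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["classifiers"] = list(d["classifiers"])
    d["regimes"] = list(d["regimes"])
    return d


def report(results_csv: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Per-classifier x per-duration mean and range tables for both metrics."""
    df = (
        results_csv
        if isinstance(results_csv, pd.DataFrame)
        else pd.read_csv(results_csv)
    )
    required = {"classifier", "regime", "duration_s", "accuracy", "fpr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results file missing column(s): {sorted(missing)}")
    if df.empty:
        raise ValueError("results file contains no rows")
    out = (
        df.groupby(["classifier", "regime", "duration_s"], as_index=False)
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_min=("accuracy", "min"),
            accuracy_max=("accuracy", "max"),
            fpr_mean=("fpr", "mean"),
            fpr_min=("fpr", "min"),
            fpr_max=("fpr", "max"),
        )
        .sort_values(["classifier", "regime", "duration_s"])
        .reset_index(drop=True)
    )
    return out


def format_report(results: pd.DataFrame) -> str:
    """Human-readable summary tables, one block per classifier and regime."""
    tab = report(results)
    lines = []
    for (clf, regime), g in tab.groupby(["classifier", "regime"]):
        lines.append(f"== {clf.upper()} / {regime} ==")
        lines.append(
            f"{'duration':>9} {'acc mean':>9} {'acc range':>15} "
            f"{'fpr mean':>9} {'fpr range':>15}"
        )
        for _, row in g.iterrows():
            lines.append(
                f"{row.duration_s:>8.1f}s {row.accuracy_mean:>9.3f} "
                f"[{row.accuracy_min:.3f}, {row.accuracy_max:.3f}] "
                f"{row.fpr_mean:>9.3f} [{row.fpr_min:.3f}, {row.fpr_max:.3f}]"
            )
        lines.append("")
    return "\n".join(lines)


def plot_duration_trend(summary: pd.DataFrame, path: str | Path) -> None:
    """Accuracy and FPR vs window duration, one line per classifier."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cv = summary[summary["regime"] == "cv_5fold"]
    if cv.empty:
        cv = summary
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for clf, g in cv.groupby("classifier"):
        g = g.sort_values("duration_s")
        axes[0].plot(g["duration_s"], g["accuracy"], "o-", label=clf.upper())
        axes[1].plot(g["duration_s"], g["fpr"], "o-", label=clf.upper())
    axes[0].set_ylabel("CV accuracy")
    axes[1].set_ylabel("CV false-positive ratio")
    for ax in axes:
        ax.set_xlabel("window duration (s)")
        ax.set_xscale("log")
        ax.set_xticks([0.5, 1, 2, 4], ["0.5", "1", "2", "4"])
        ax.grid(alpha=0.3)
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
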