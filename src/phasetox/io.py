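"""File formats and the end-to-end analysis pipeline.

All artifacts are plain text: long-format trace CSV (comma separated,
UTF-8, '.' decimal; time in seconds, phase in degrees), per-cell label
and classification CSVs, a condition-summary TSV shaped like the
published summary table (condition, n_cult, n_cell, mean +/- SEM of
the ID percentage, significance stars), a JSON stats report and a TSV
of cascade predictions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import phasetox
from phasetox import cascade as _cascade
from phasetox.cohortstats import (
    ConditionSummary, DunnettResult, dunnett_vs_control, summarize_condition,
    summarize_culture,
)
from phasetox.synthgen import Cohort, CohortConfig, PhaseTrace, generate_cohort
from phasetox.traceclass import ClassifierThresholds, classify_cohort

TRACE_COLUMNS = ["condition_id", "culture_id", "cell_id", "time_s", "phase_deg"]


# ---------------------------------------------------------------- traces

def write_traces_csv(traces: Sequence[PhaseTrace], path) -> None:
    """Write traces as long-format CSV (one row per sample)."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "condition_id": tr.condition_id,
            "culture_id": tr.culture_id,
            "cell_id": tr.cell_id,
            "time_s": tr.times,
            "phase_deg": tr.phase,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def read_traces_csv(path, stim_onset: float = 0.0,
                    stim_offset: float = 120.0) -> list[PhaseTrace]:
    """Read long-format trace CSV back into PhaseTrace objects.

    Stimulus timing is not stored per sample; it comes from the
    condition metadata (``stim_onset``/``stim_offset``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns {sorted(missing)}")
    traces = []
    for (cond, cult, cell), grp in df.groupby(
            ["condition_id", "culture_id", "cell_id"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(PhaseTrace(grp["time_s"].to_numpy(),
                                 grp["phase_deg"].to_numpy(),
                                 cell_id=str(cell), culture_id=str(cult),
                                 condition_id=str(cond),
                                 stim_onset=stim_onset, stim_offset=stim_offset))
    return traces


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    return pd.read_csv(path)


# ------------------------------------------------------------- summaries

def summary_table(summaries: Sequence[ConditionSummary],
                  dunnett: DunnettResult | None = None,
                  control_id: str | None = None) -> pd.DataFrame:
    """Condition-summary table: mean +/- SEM of the ID percentage + stars."""
    rows = []
    for s in summaries:
        if dunnett is not None and s.condition_id in dunnett.adjusted_p:
            star = dunnett.stars[s.condition_id]
            p_adj = dunnett.adjusted_p[s.condition_id]
        else:
            star = "" if s.condition_id == control_id else "ns"
            p_adj = float("nan")
        rows.append({
            "condition": s.condition_id,
            "n_cult": s.n_cult,
            "n_cell": s.n_cell,
            "pct_ID_mean": round(s.mean_pct_ID, 2),
            "pct_ID_sem": round(s.sem_pct_ID, 2),
            "significance": star,
            "p_adjusted": p_adj,
        })
    return pd.DataFrame(rows)


def write_summary_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4g")


# --------------------------------------------------------------- config

@dataclass(frozen=True)
class ConditionDesign:
    """Simulation design of one condition (class mix and replication)."""

    condition_id: str
    class_probabilities: tuple[float, float, float]
    n_cultures: int = 10
    cells_per_culture: int = 29


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run."""

    out_dir: str = "phasetox_out"
    seed: int = 0
    alpha: float = 0.05
    control_id: str = "control"
    conditions: tuple[ConditionDesign, ...] = (
        ConditionDesign("control", (0.05, 0.29, 0.66), n_cultures=16),
        ConditionDesign("L-Lactate", (0.21, 0.47, 0.32), n_cultures=15),
    )
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    noise_sd: float = 1.0
    sampling_interval: float = 5.0
    baseline_duration: float = 120.0
    stim_duration: float = 120.0
    recording_duration: float = 720.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.control_id not in {c.condition_id for c in self.conditions}:
            raise ValueError(f"control condition {self.control_id!r} not in design")

    def cohort_config(self, design: ConditionDesign, seed: int) -> CohortConfig:
        return CohortConfig(
            n_cultures=design.n_cultures,
            cells_per_culture=design.cells_per_culture,
            class_probabilities=design.class_probabilities,
            sampling_interval=self.sampling_interval,
            baseline_duration=self.baseline_duration,
            stim_duration=self.stim_duration,
            recording_duration=self.recording_duration,
            noise_sd=self.noise_sd,
            seed=seed,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = json.loads(path.read_text())
        if "conditions" in raw:
            raw["conditions"] = tuple(
                ConditionDesign(c["condition_id"],
                                tuple(c["class_probabilities"]),
                                c.get("n_cultures", 10),
                                c.get("cells_per_culture", 29))
                for c in raw["conditions"])
        if "thresholds" in raw:
            raw["thresholds"] = ClassifierThresholds(**raw["thresholds"])
        return cls(**raw)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# --------------------------------------------------------------- pipeline

def simulate(config: RunConfig) -> list[Cohort]:
    """Generate all configured cohorts with per-condition derived seeds."""
    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.conditions))
    return [generate_cohort(self_cfg, condition_id=design.condition_id)
            for design, self_cfg in (
                (d, config.cohort_config(d, int(s) % (2 ** 31)))
                for d, s in zip(config.conditions, seeds))]


def summarize_classifications(classified: pd.DataFrame) -> list[ConditionSummary]:
    """Per-culture then per-condition aggregation of a classification table."""
    summaries = []
    for cond, cond_df in classified.groupby("condition_id", sort=True):
        cultures = [summarize_culture(grp["label"], culture_id=str(cult))
                    for cult, grp in cond_df.groupby("culture_id", sort=True)]
        summaries.append(summarize_condition(cultures, condition_id=str(cond)))
    return summaries


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> classify -> summarize -> stats -> cascade -> report.

    Writes all artifacts under ``config.out_dir`` and returns them
    in-memory.  Output is deterministic for a fixed config (byte
    identical across runs).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohorts = simulate(config)
    traces = [tr for c in cohorts for tr in c.traces]
    labels = pd.concat([c.labels for c in cohorts], ignore_index=True)
    write_traces_csv(traces, out / "traces.csv")
    write_labels_csv(labels, out / "labels.csv")

    classified = classify_cohort(traces, config.thresholds)
    classified.to_csv(out / "classifications.csv", index=False,
                      float_format="%.10g")

    summaries = summarize_classifications(classified)
    by_id = {s.condition_id: s for s in summaries}
    control = by_id[config.control_id]
    treatments = {s.condition_id: list(s.per_culture_pct_ID)
                  for s in summaries if s.condition_id != config.control_id}
    dunnett = None
    if treatments and all(len(v) >= 2 for v in treatments.values()):
        dunnett = dunnett_vs_control(list(control.per_culture_pct_ID),
                                     treatments, alpha=config.alpha,
                                     rng=config.seed)
    table = summary_table(summaries, dunnett, control_id=config.control_id)
    write_summary_tsv(table, out / "condition_summary.tsv")

    panel = _cascade.load_condition_panel()
    predictions = _cascade.predict_table(panel)
    predictions.to_csv(out / "cascade_predictions.tsv", sep="\t", index=False)

    stats_report = {
        "seed": config.seed,
        "alpha": config.alpha,
        "control": config.control_id,
        "n_traces": len(traces),
        "n_cells": int(labels.shape[0]),
        "conditions": {
            s.condition_id: {
                "n_cult": s.n_cult, "n_cell": s.n_cell,
                "mean_pct_ID": s.mean_pct_ID, "sem_pct_ID": s.sem_pct_ID,
                "mean_pct_RD": s.mean_pct_RD, "mean_pct_BP": s.mean_pct_BP,
            } for s in summaries},
        "dunnett": None if dunnett is None else {
            "F": dunnett.f_statistic, "anova_p": dunnett.anova_p,
            "adjusted_p": dict(dunnett.adjusted_p),
            "stars": dict(dunnett.stars)},
        "cascade_matches": int(predictions["match"].sum()),
        "cascade_rows": int(len(predictions)),
    }
    (out / "stats.json").write_text(json.dumps(stats_report, indent=2,
                                               sort_keys=True))
    log = {
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "phasetox_version": phasetox.__version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "n_traces_written": len(traces),
        "n_cells_classified": int(classified.shape[0]),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {"cohorts": cohorts, "classified": classified,
            "summaries": summaries, "dunnett": dunnett,
            "summary_table": table, "cascade_predictions": predictions,
            "stats": stats_report}
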