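"""Morphological classification of QPS responses (BP / RD / ID).

The taxonomy is qualitative in origin -- biphasic recovery with an
overshoot, complete recovery, and irreversible decrease -- so the
classifier operationalises it with explicit thresholds:

1. a *drop* exists when the nadir lies more than ``drop_k`` baseline
   SDs (with an absolute floor, for noiseless traces) below baseline;
2. a dropped trace is **ID** when the recovery fraction at the end of
   the recording is below ``irreversibility_threshold``;
3. a trace that recovered at least ``recovery_threshold`` of its drop
   is **BP** if it also shows an overshoot above baseline exceeding
   ``overshoot_k`` baseline SDs, else **RD**;
4. intermediate recovery fractions are reported as **UNCLASSIFIED**
   and excluded from three-class percentages by default.

All thresholds are relative to the trace's own baseline statistics, so
classification is invariant to constant phase offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from phasetox.synthgen import PhaseTrace

LABELS = ("BP", "RD", "ID", "NONE", "UNCLASSIFIED")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable decision thresholds of the response classifier.

    baseline_window : s
        Pre-stimulus span used to estimate baseline mean and SD
        (default 120 s, the minimum stable-baseline requirement).
    drop_k, drop_floor_deg : -
        A drop is declared when ``|nadir - baseline|`` exceeds
        ``max(drop_k * baseline_sd, drop_floor_deg)``.
    recovery_threshold, irreversibility_threshold : -
        Recovery-fraction cut points separating recovered responses
        (>= 0.8) from irreversible ones (< 0.5).
    overshoot_k, overshoot_floor_deg : -
        BP overshoot must exceed
        ``max(overshoot_k * baseline_sd, overshoot_floor_deg)``.
    overshoot_smooth : samples
        Width of the centred moving average applied when measuring the
        overshoot, so a single noise spike cannot mimic a BP overshoot.
    end_window : s
        Span at the end of the recording whose mean defines the
        recovered level ("irreversible" = still down at that point).
    """

    baseline_window: float = 120.0
    drop_k: float = 3.0
    drop_floor_deg: float = 3.0
    recovery_threshold: float = 0.8
    irreversibility_threshold: float = 0.5
    overshoot_k: float = 3.0
    overshoot_floor_deg: float = 3.0
    overshoot_smooth: int = 3
    end_window: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.irreversibility_threshold < self.recovery_threshold <= 1.5:
            raise ValueError(
                "need 0 <= irreversibility_threshold < recovery_threshold <= 1.5")
        if self.drop_k <= 0 or self.overshoot_k <= 0:
            raise ValueError("drop_k and overshoot_k must be positive")
        if self.baseline_window <= 0 or self.end_window <= 0:
            raise ValueError("windows must be positive")
        if self.overshoot_smooth < 1:
            raise ValueError("overshoot_smooth must be >= 1 sample")


@dataclass(frozen=True)
class TraceFeatures:
    """Morphological features of one trace.

    ``drop_amplitude = nadir - baseline`` (<= 0 for a genuine drop);
    ``recovery_fraction = (end_window_mean - nadir) / (baseline - nadir)``,
    NaN when the trace never left baseline; ``overshoot_amplitude`` is
    the (smoothed) post-nadir maximum minus baseline.
    """

    baseline_mean: float
    baseline_sd: float
    drop_amplitude: float
    nadir_time: float
    recovery_fraction: float
    overshoot_amplitude: float
    end_window_mean: float


@dataclass(frozen=True)
class ResponseClass:
    label: str
    rationale: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def estimate_baseline(trace: PhaseTrace, window: float = 120.0) -> tuple[float, float]:
    """Baseline mean and SD over the pre-stimulus window.

    Uses samples with ``stim_onset - window <= t < stim_onset``; at
    least two are required.
    """
    mask = (trace.times >= trace.stim_onset - window) & (trace.times < trace.stim_onset)
    if mask.sum() < 2:
        raise ValueError("need at least 2 pre-stimulus samples to estimate a baseline")
    pre = trace.phase[mask]
    return float(pre.mean()), float(pre.std(ddof=1))


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or x.size < w:
        return x
    kernel = np.full(w, 1.0 / w)
    return np.convolve(x, kernel, mode="valid")


def extract_features(trace: PhaseTrace,
                     thresholds: ClassifierThresholds | None = None) -> TraceFeatures:
    """Extract baseline, drop, recovery and overshoot features.

    The nadir is the raw post-onset minimum (so printed drop amplitudes
    are reproduced exactly on noiseless traces); the overshoot is read
    from a short moving average of the post-nadir segment.
    """
    thr = thresholds or ClassifierThresholds()
    base_mean, base_sd = estimate_baseline(trace, thr.baseline_window)

    post = trace.times >= trace.stim_onset
    if trace.times[-1] - trace.stim_offset < thr.end_window:
        raise ValueError(
            f"recording ends {trace.times[-1] - trace.stim_offset:.0f} s after the "
            f"stimulus; need >= {thr.end_window:.0f} s for the end window")
    post_phase = trace.phase[post]
    post_times = trace.times[post]
    i_nadir = int(np.argmin(post_phase))
    nadir = float(post_phase[i_nadir])
    nadir_time = float(post_times[i_nadir])
    drop = nadir - base_mean

    end_mask = trace.times >= trace.times[-1] - thr.end_window
    end_mean = float(trace.phase[end_mask].mean())

    after_nadir = post_phase[i_nadir:]
    smoothed = _moving_mean(after_nadir, thr.overshoot_smooth)
    overshoot = float(smoothed.max() - base_mean)

    if nadir < base_mean:
        recovery = float((end_mean - nadir) / (base_mean - nadir))
    else:
        recovery = float("nan")
    return TraceFeatures(baseline_mean=base_mean, baseline_sd=base_sd,
                         drop_amplitude=drop, nadir_time=nadir_time,
                         recovery_fraction=recovery,
                         overshoot_amplitude=overshoot,
                         end_window_mean=end_mean)


def classify_trace(features: TraceFeatures,
                   thresholds: ClassifierThresholds | None = None) -> ResponseClass:
    """Assign BP / RD / ID / NONE / UNCLASSIFIED to extracted features."""
    thr = thresholds or ClassifierThresholds()
    drop_needed = max(thr.drop_k * features.baseline_sd, thr.drop_floor_deg)
    if not np.isfinite(features.recovery_fraction) or -features.drop_amplitude < drop_needed:
        return ResponseClass("NONE", f"|drop| {-features.drop_amplitude:.2f} deg "
                                     f"< detection threshold {drop_needed:.2f} deg")
    rf = features.recovery_fraction
    if rf < thr.irreversibility_threshold:
        return ResponseClass("ID", f"recovery fraction {rf:.2f} < "
                                   f"{thr.irreversibility_threshold}")
    if rf >= thr.recovery_threshold:
        over_needed = max(thr.overshoot_k * features.baseline_sd, thr.overshoot_floor_deg)
        if features.overshoot_amplitude > over_needed:
            return ResponseClass("BP", f"recovered (rf {rf:.2f}) with overshoot "
                                       f"{features.overshoot_amplitude:.2f} deg > "
                                       f"{over_needed:.2f} deg")
        return ResponseClass("RD", f"recovered (rf {rf:.2f}) without overshoot")
    return ResponseClass("UNCLASSIFIED",
                         f"intermediate recovery fraction {rf:.2f}")


def classify(trace: PhaseTrace,
             thresholds: ClassifierThresholds | None = None
             ) -> tuple[TraceFeatures, ResponseClass]:
    """Convenience: features + label for one trace."""
    feats = extract_features(trace, thresholds)
    return feats, classify_trace(feats, thresholds)


def classify_cohort(traces, thresholds: ClassifierThresholds | None = None) -> pd.DataFrame:
    """Classify an iterable of traces into a tidy per-cell table."""
    rows = []
    for tr in traces:
        feats, cls = classify(tr, thresholds)
        rows.append({
            "condition_id": tr.condition_id,
            "culture_id": tr.culture_id,
            "cell_id": tr.cell_id,
            "label": cls.label,
            "drop_amplitude": feats.drop_amplitude,
            "recovery_fraction": feats.recovery_fraction,
            "overshoot_amplitude": feats.overshoot_amplitude,
        })
    return pd.DataFrame(rows, columns=["condition_id", "culture_id", "cell_id",
                                       "label", "drop_amplitude",
                                       "recovery_fraction", "overshoot_amplitude"])
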