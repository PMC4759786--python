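"""Synthetic quantitative-phase-signal (QPS) traces and cohorts.

Traces emulate what a quantitative-phase digital holographic microscope
records from a single neuron during a transient glutamate challenge:
a stable pre-stimulus baseline (phase in degrees, sampled at 0.2 Hz),
an exponential phase drop that develops over the stimulus window (water
influx / swelling), and an exponential return toward baseline whose
completeness depends on the response archetype:

``BP``
    small drop (about -6 deg) with full recovery and a transient
    overshoot above baseline (about +10.8 deg);
``RD``
    larger drop (about -17.6 deg) with complete recovery;
``ID``
    large drop (about -47.5 deg) with little or no recovery -- the
    optical signature of early excitotoxic death;
``NONE``
    no detectable response (flat baseline + noise).

The kinetics are phenomenological piecewise exponentials; exponential
segments are normalised so that the nadir and the end-of-recording
plateau hit their nominal levels exactly, which makes noiseless traces
usable as classifier oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ARCHETYPES = ("BP", "RD", "ID", "NONE")

#: Mean response amplitudes (degrees) of the three archetypes, and the
#: between-cell SDs implied by the reported per-cell standard errors
#: (SD = SEM * sqrt(n_cell)).  Truncation bounds keep every sampled cell
#: inside the morphology that defines its class, so ground-truth labels
#: stay meaningful for arbitrarily unlucky draws.
ARCHETYPE_POPULATIONS: Mapping[str, dict] = {
    "BP": {
        "drop_mean": -6.0,
        "drop_sd": 1.49 * math.sqrt(47),
        "drop_bounds": (-15.0, -4.0),
        "overshoot_mean": 10.8,
        "overshoot_sd": 1.1 * math.sqrt(47),
        "overshoot_bounds": (4.0, 25.0),
        "recovery_mean": 1.0,
        "recovery_sd": 0.05,
        "recovery_bounds": (0.85, 1.0),
    },
    "RD": {
        "drop_mean": -17.6,
        "drop_sd": 1.25 * math.sqrt(121),
        "drop_bounds": (-35.0, -8.0),
        "recovery_mean": 1.0,
        "recovery_sd": 0.05,
        "recovery_bounds": (0.85, 1.0),
    },
    "ID": {
        "drop_mean": -47.5,
        "drop_sd": 3.2 * math.sqrt(63),
        "drop_bounds": (-70.0, -20.0),
        "recovery_mean": 0.05,
        "recovery_sd": 0.10,
        "recovery_bounds": (0.0, 0.30),
    },
}

#: Default probability that a cell of each class stains PI-positive
#: after the insult.  ID cells are overwhelmingly PI-positive (0.86);
#: recovered classes rarely are.  With the control class mix
#: (p_ID = 0.66) these defaults give an overall PI-positive rate near
#: 0.59, and near 0.31 under a protective class mix (p_ID = 0.32),
#: matching the viability counts reported for those conditions.
DEFAULT_PI_GIVEN_CLASS: Mapping[str, float] = {
    "BP": 0.02,
    "RD": 0.05,
    "ID": 0.86,
    "NONE": 0.02,
}


@dataclass(frozen=True)
class ArchetypeParams:
    """Kinetic parameters of one synthetic response trace.

    drop_amplitude is the nadir level relative to baseline (<= 0);
    recovery_fraction is the fraction of the drop that is regained by
    the end of the recording; the overshoot (BP only) is a transient
    Gaussian bump above the recovered level.
    """

    archetype: str
    drop_amplitude: float = 0.0
    drop_time_constant: float = 20.0
    recovery_fraction: float = 0.0
    recovery_time_constant: float = 45.0
    overshoot_amplitude: float = 0.0
    overshoot_duration: float = 120.0
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.drop_amplitude > 0:
            raise ValueError("drop_amplitude must be <= 0 (a phase drop)")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")
        if self.overshoot_amplitude < 0:
            raise ValueError("overshoot_amplitude must be >= 0")
        if self.overshoot_amplitude > 0 and self.archetype != "BP":
            raise ValueError("overshoot is a BP-only feature")
        if self.archetype == "NONE" and self.drop_amplitude != 0:
            raise ValueError("archetype NONE must have zero drop")
        if self.drop_time_constant <= 0 or self.recovery_time_constant <= 0:
            raise ValueError("time constants must be positive")
        if self.overshoot_duration <= 0:
            raise ValueError("overshoot_duration must be positive")


#: Canonical noiseless archetypes at the reported mean amplitudes.
DEFAULT_ARCHETYPES: Mapping[str, ArchetypeParams] = {
    "BP": ArchetypeParams("BP", drop_amplitude=-6.0, recovery_fraction=1.0,
                          overshoot_amplitude=10.8),
    "RD": ArchetypeParams("RD", drop_amplitude=-17.6, recovery_fraction=1.0),
    "ID": ArchetypeParams("ID", drop_amplitude=-47.5, recovery_fraction=0.0),
    "NONE": ArchetypeParams("NONE"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    Defaults follow the experimental design of the glutamate assay:
    holograms at 0.2 Hz (5 s sampling), at least 2 min of stable
    baseline, a 2 min glutamate pulse at t = 0, at least 20 cells per
    culture, and -- for the Mg2+-free control -- class probabilities
    (p_BP, p_RD, p_ID) = (0.05, 0.29, 0.66) over 16 cultures.
    """

    n_cultures: int = 16
    cells_per_culture: int = 29
    class_probabilities: tuple[float, float, float] = (0.05, 0.29, 0.66)
    pi_positive_given_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PI_GIVEN_CLASS))
    sampling_interval: float = 5.0
    baseline_duration: float = 120.0
    stim_duration: float = 120.0
    recording_duration: float = 720.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.class_probabilities
        if len(p) != 3 or any(not 0.0 <= x <= 1.0 for x in p):
            raise ValueError("class_probabilities must be three values in [0, 1]")
        if sum(p) > 1.0 + 1e-12:
            raise ValueError("class probabilities must sum to <= 1")
        for cls, q in self.pi_positive_given_class.items():
            if cls not in ARCHETYPES or not 0.0 <= q <= 1.0:
                raise ValueError(f"invalid PI probability for class {cls!r}")
        if self.n_cultures < 1 or self.cells_per_culture < 1:
            raise ValueError("cohort needs >= 1 culture and >= 1 cell per culture")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.baseline_duration < 2 * self.sampling_interval:
            raise ValueError("baseline must span at least two samples")
        if self.stim_duration <= 0 or self.recording_duration <= 0:
            raise ValueError("durations must be positive")
        if self.recording_duration <= self.baseline_duration + self.stim_duration:
            raise ValueError("recording must extend beyond the stimulus")

    @property
    def p_none(self) -> float:
        return max(0.0, 1.0 - sum(self.class_probabilities))


@dataclass
class PhaseTrace:
    """One cell's QPS time series with stimulus annotation.

    ``times`` is a strictly increasing grid in seconds with the
    glutamate onset at ``stim_onset`` (0 by convention); ``phase`` is
    the quantitative phase in degrees.
    """

    times: np.ndarray
    phase: np.ndarray
    cell_id: str
    culture_id: str = ""
    condition_id: str = ""
    stim_onset: float = 0.0
    stim_offset: float = 120.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.times.shape != self.phase.shape or self.times.ndim != 1:
            raise ValueError("times and phase must be matching 1-D arrays")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite everywhere")
        if not self.stim_onset < self.stim_offset:
            raise ValueError("stim_onset must precede stim_offset")


@dataclass
class Cohort:
    """A generated cohort: traces plus per-cell ground truth."""

    traces: list[PhaseTrace]
    labels: pd.DataFrame  # columns: condition_id, culture_id, cell_id, true_class, pi_positive
    config: CohortConfig
    condition_id: str = "control"


def _ramp(t: np.ndarray, tau: float, span: float) -> np.ndarray:
    """Normalised rising exponential: 0 at t=0, exactly 1 at t=span."""
    out = (1.0 - np.exp(-np.clip(t, 0.0, span) / tau)) / (1.0 - math.exp(-span / tau))
    return np.clip(out, 0.0, 1.0)


def response_waveform(params: ArchetypeParams, times: np.ndarray,
                      stim_onset: float, stim_offset: float) -> np.ndarray:
    """Deterministic (noise-free) phase trajectory for one archetype.

    Piecewise structure: flat baseline before the stimulus; during the
    stimulus an exponential drop that reaches ``drop_amplitude`` exactly
    at ``stim_offset``; afterwards an exponential recovery (over a
    window of four recovery time constants) toward
    ``baseline + (1 - recovery_fraction) * drop_amplitude``; for BP an
    additional Gaussian overshoot bump, centred after the recovery
    completes, whose peak stands ``overshoot_amplitude`` above the
    recovered level.
    """
    t = np.asarray(times, dtype=float)
    base = params.baseline_level
    phase = np.full(t.shape, base)
    if params.archetype == "NONE" or params.drop_amplitude == 0.0:
        return phase

    amp = params.drop_amplitude
    stim_span = stim_offset - stim_onset
    rec_span = 4.0 * params.recovery_time_constant
    final = base + (1.0 - params.recovery_fraction) * amp

    during = (t >= stim_onset) & (t <= stim_offset)
    phase[during] = base + amp * _ramp(t[during] - stim_onset,
                                       params.drop_time_constant, stim_span)
    after = t > stim_offset
    phase[after] = (base + amp) + (final - (base + amp)) * _ramp(
        t[after] - stim_offset, params.recovery_time_constant, rec_span)

    if params.overshoot_amplitude > 0:
        width = params.overshoot_duration / 4.0
        centre = stim_offset + rec_span + params.overshoot_duration / 2.0
        bump = params.overshoot_amplitude * np.exp(-((t - centre) / width) ** 2)
        bump[~after] = 0.0
        phase = phase + bump
    return phase


def generate_trace(params: ArchetypeParams, config: CohortConfig,
                   seed: int | np.random.Generator,
                   cell_id: str = "cell", culture_id: str = "cult",
                   condition_id: str = "cond") -> PhaseTrace:
    """Generate one seeded synthetic QPS trace.

    The time grid starts ``baseline_duration`` seconds before the
    stimulus onset (t = 0) and is spaced exactly
    ``sampling_interval`` apart.  Gaussian noise of SD
    ``config.noise_sd`` degrees is added i.i.d. per sample.  With
    ``noise_sd = 0`` the nadir equals ``baseline + drop_amplitude`` and
    the end-of-recording plateau equals
    ``baseline - (1 - recovery_fraction) * |drop_amplitude|`` exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(config.recording_duration / config.sampling_interval))
    times = np.arange(n) * config.sampling_interval - config.baseline_duration
    stim_onset, stim_offset = 0.0, config.stim_duration
    post_span = times[-1] - stim_offset
    needed = 4.0 * params.recovery_time_constant
    if params.overshoot_amplitude > 0:
        needed += params.overshoot_duration
    if post_span < needed:
        raise ValueError(
            "recording too short: response kinetics need "
            f"{needed:.0f} s after the stimulus, got {post_span:.0f} s")
    phase = response_waveform(params, times, stim_onset, stim_offset)
    if config.noise_sd > 0:
        phase = phase + rng.normal(0.0, config.noise_sd, size=phase.shape)
    return PhaseTrace(times, phase, cell_id=cell_id, culture_id=culture_id,
                      condition_id=condition_id, stim_onset=stim_onset,
                      stim_offset=stim_offset)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_archetype_params(archetype: str, rng: np.random.Generator,
                            baseline_level: float = 0.0) -> ArchetypeParams:
    """Draw per-cell kinetic parameters for one archetype.

    Amplitudes are truncated Gaussians around the archetype means (see
    :data:`ARCHETYPE_POPULATIONS`); NONE cells are flat.
    """
    if archetype == "NONE":
        return ArchetypeParams("NONE", baseline_level=baseline_level)
    pop = ARCHETYPE_POPULATIONS[archetype]
    drop = float(_truncnorm(rng, pop["drop_mean"], pop["drop_sd"],
                            *pop["drop_bounds"], size=1)[0])
    rec = float(_truncnorm(rng, pop["recovery_mean"], pop["recovery_sd"],
                           *pop["recovery_bounds"], size=1)[0])
    overshoot = 0.0
    if archetype == "BP":
        overshoot = float(_truncnorm(rng, pop["overshoot_mean"], pop["overshoot_sd"],
                                     *pop["overshoot_bounds"], size=1)[0])
    return ArchetypeParams(archetype, drop_amplitude=drop, recovery_fraction=rec,
                           overshoot_amplitude=overshoot,
                           baseline_level=baseline_level)


def generate_cohort(config: CohortConfig, condition_id: str = "control",
                    seed: int | np.random.Generator | None = None) -> Cohort:
    """Generate a full cohort of cultures x cells with ground truth.

    Each cell draws a class from ``class_probabilities`` (residual mass
    goes to NONE), per-cell kinetic parameters around the archetype
    means, and a PI-viability label from
    ``pi_positive_given_class[class]``.  Generation is bit-reproducible
    for a fixed config and seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed)
    p_bp, p_rd, p_id = config.class_probabilities
    probs = np.array([p_bp, p_rd, p_id, config.p_none])
    probs = probs / probs.sum()
    classes = np.array(["BP", "RD", "ID", "NONE"])

    traces: list[PhaseTrace] = []
    rows = []
    for c in range(config.n_cultures):
        culture_id = f"{condition_id}_cult{c:02d}"
        for i in range(config.cells_per_culture):
            cell_id = f"{culture_id}_cell{i:03d}"
            cls = str(rng.choice(classes, p=probs))
            baseline = float(rng.normal(60.0, 10.0))
            params = sample_archetype_params(cls, rng, baseline_level=baseline)
            traces.append(generate_trace(params, config, rng, cell_id=cell_id,
                                         culture_id=culture_id,
                                         condition_id=condition_id))
            pi = bool(rng.random() < config.pi_positive_given_class[cls])
            rows.append((condition_id, culture_id, cell_id, cls, pi))
    labels = pd.DataFrame(rows, columns=["condition_id", "culture_id", "cell_id",
                                         "true_class", "pi_positive"])
    return Cohort(traces=traces, labels=labels, config=config,
                  condition_id=condition_id)


def with_class_probabilities(config: CohortConfig,
                             p: Sequence[float], **overrides) -> CohortConfig:
    """Convenience: copy a config with a new (p_BP, p_RD, p_ID) triple."""
    return replace(config, class_probabilities=tuple(float(x) for x in p), **overrides)
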