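"""Feature extraction and BP/RD/ID classification."""

import numpy as np
import pytest

from phasetox.synthgen import (
    ArchetypeParams, CohortConfig, DEFAULT_ARCHETYPES, PhaseTrace, generate_trace,
)
from phasetox.traceclass import (
    ClassifierThresholds, TraceFeatures, classify, classify_trace,
    estimate_baseline, extract_features,
)


def flat_trace(level=0.0, n=144, dt=5.0, noise=None, seed=0):
    times = np.arange(n) * dt - 120.0
    phase = np.full(n, float(level))
    if noise:
        phase = phase + np.random.default_rng(seed).normal(0, noise, n)
    return PhaseTrace(times, phase, cell_id="c", stim_onset=0.0, stim_offset=120.0)


class TestEstimateBaseline:
    def test_constant_baseline(self):
        mean, sd = estimate_baseline(flat_trace(12.0))
        assert (mean, sd) == (12.0, 0.0)

    def test_sd_estimate_is_consistent(self):
        """With 10^4 pre-stimulus samples the SD estimate lands within 5%."""
        times = np.arange(10_001) * 5.0 - 50_000.0
        phase = np.random.default_rng(7).normal(0, 1.0, times.size)
        tr = PhaseTrace(times, phase, cell_id="c", stim_onset=0.0, stim_offset=120.0)
        _, sd = estimate_baseline(tr, window=50_000.0)
        assert abs(sd - 1.0) < 0.05

    def test_trace_starting_at_onset_has_no_baseline(self):
        times = np.arange(100) * 5.0  # starts exactly at stimulus onset
        tr = PhaseTrace(times, np.zeros(100), cell_id="c",
                        stim_onset=0.0, stim_offset=120.0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            estimate_baseline(tr)


class TestExtractFeatures:
    def test_noiseless_rd_archetype(self, noiseless_config, thresholds):
        """Reversible decrease: drop -17.6 deg, full recovery."""
        tr = generate_trace(DEFAULT_ARCHETYPES["RD"], noiseless_config, 0)
        f = extract_features(tr, thresholds)
        assert f.drop_amplitude == pytest.approx(-17.6, abs=1e-9)
        assert f.recovery_fraction == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_id_archetype(self, noiseless_config, thresholds):
        """Irreversible decrease: drop -47.5 deg, zero recovery."""
        tr = generate_trace(DEFAULT_ARCHETYPES["ID"], noiseless_config, 0)
        f = extract_features(tr, thresholds)
        assert f.drop_amplitude == pytest.approx(-47.5, abs=1e-9)
        assert f.recovery_fraction == pytest.approx(0.0, abs=1e-9)

    def test_flat_trace_has_no_drop_and_undefined_recovery(self, thresholds):
        f = extract_features(flat_trace(5.0), thresholds)
        assert f.drop_amplitude == 0.0
        assert np.isnan(f.recovery_fraction)
        assert classify_trace(f, thresholds).label == "NONE"

    def test_recording_too_short_for_end_window(self, thresholds):
        times = np.arange(36) * 5.0 - 120.0  # ends 55 s after onset
        tr = PhaseTrace(times, np.zeros(36), cell_id="c",
                        stim_onset=0.0, stim_offset=120.0)
        with pytest.raises(ValueError, match="end window"):
            extract_features(tr, thresholds)


def features(drop, rf, overshoot, sd=0.0):
    return TraceFeatures(baseline_mean=0.0, baseline_sd=sd, drop_amplitude=drop,
                         nadir_time=120.0, recovery_fraction=rf,
                         overshoot_amplitude=overshoot, end_window_mean=0.0)


class TestClassifyTrace:
    @pytest.mark.parametrize("drop,rf,overshoot,expected", [
        (-47.5, 0.05, -40.0, "ID"),     # pronounced, irreversible
        (-6.0, 1.0, 10.8, "BP"),        # recovered with overshoot
        (-17.6, 0.95, 0.0, "RD"),       # complete recovery, no overshoot
        (-1.0, 1.0, 0.0, "NONE"),       # below detection floor
        (-20.0, 0.65, 0.0, "UNCLASSIFIED"),  # intermediate recovery
    ])
    def test_rule_table(self, drop, rf, overshoot, expected, thresholds):
        assert classify_trace(features(drop, rf, overshoot), thresholds).label == expected

    def test_decreasing_recovery_never_rescues_an_id_call(self, thresholds):
        """Monotonicity: lowering the recovery fraction can only move a label
        toward (never away from) the irreversible class."""
        order = {"ID": 0, "UNCLASSIFIED": 1, "RD": 2, "BP": 2}
        labels = [classify_trace(features(-30.0, rf, 0.0), thresholds).label
                  for rf in np.linspace(1.0, 0.0, 21)]
        ranks = [order[l] for l in labels]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))

    def test_drop_threshold_scales_with_baseline_noise(self, thresholds):
        f = features(-4.0, 0.0, 0.0, sd=2.0)  # needs 6 deg at sd = 2
        assert classify_trace(f, thresholds).label == "NONE"
        assert classify_trace(features(-4.0, 0.0, 0.0, sd=1.0), thresholds).label == "ID"


class TestEndToEnd:
    @pytest.mark.parametrize("archetype", ["BP", "RD", "ID"])
    def test_classification_is_offset_invariant(self, archetype, thresholds):
        """Phase is relative: shifting a whole trace must not change its label."""
        cfg = CohortConfig(noise_sd=1.0)
        tr = generate_trace(DEFAULT_ARCHETYPES[archetype], cfg, seed=5)
        shifted = PhaseTrace(tr.times, tr.phase + 250.0, cell_id="c",
                             stim_onset=tr.stim_onset, stim_offset=tr.stim_offset)
        assert classify(tr, thresholds)[1].label == classify(shifted, thresholds)[1].label

    @pytest.mark.parametrize("archetype", ["BP", "RD", "ID", "NONE"])
    def test_noiseless_archetypes_classify_as_generated(self, archetype,
                                                        noiseless_config, thresholds):
        tr = generate_trace(DEFAULT_ARCHETYPES[archetype], noiseless_config, 0)
        assert classify(tr, thresholds)[1].label == archetype

    def test_moderate_noise_keeps_archetypes_separable(self, thresholds):
        """At 2 deg noise the canonical archetypes still classify correctly."""
        cfg = CohortConfig(noise_sd=2.0)
        hits = 0
        for seed in range(25):
            for archetype in ("BP", "RD", "ID"):
                tr = generate_trace(DEFAULT_ARCHETYPES[archetype], cfg, seed=seed)
                hits += classify(tr, thresholds)[1].label == archetype
        assert hits / 75 >= 0.95
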