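# Methods

## Synthetic trace model

Recorded QPS traces are emulated with phenomenological piecewise-exponential
kinetics; the assay defines the morphology of the three classes but no rate
law, so the generator is built so that its noiseless output is *exactly*
classifiable and its anchor levels are exact:

- **Grid.** Samples every `sampling_interval` (default 5 s, i.e. 0.2 Hz)
  from `-baseline_duration` (default 120 s, the minimum stable-baseline
  requirement) to `recording_duration - baseline_duration` (default total
  720 s). Stimulus onset is t = 0, offset `stim_duration` (default 120 s,
  the 2 min glutamate pulse).
- **Drop.** During the stimulus the phase follows a rising-exponential ramp
  normalised so that it reaches `baseline + drop_amplitude` exactly at the
  stimulus offset (time constant 20 s by default). The normalisation — as
  opposed to a plain `1 - exp(-t/τ)` — is what makes the nadir an exact
  anchor rather than an asymptote.
- **Recovery.** After the offset, an exponential ramp (τ = 45 s, window
  4τ = 180 s) normalised to land exactly on
  `baseline - (1 - recovery_fraction)·|drop|`.
- **Overshoot (BP only).** A Gaussian bump of amplitude
  `overshoot_amplitude` centred after the recovery window completes
  (width `overshoot_duration/4`), so for a fully recovered trace the
  post-recovery maximum is exactly `baseline + overshoot_amplitude`.
- **Noise.** i.i.d. Gaussian per sample, default SD 1°. The instrument's
  axial sensitivity is nanometric, so 1° is a deliberately pessimistic
  single-sample noise level; classification degrades gracefully up to ~2°.

### Cohort generation

Each cell draws its class from `(p_BP, p_RD, p_ID)` with the residual mass
going to a fourth NONE class (flat trace), so mixtures need not sum to 1.
Per-cell amplitudes are truncated Gaussians around the class means
(−6°, −17.6°, −47.5°; overshoot +10.8°) with SDs taken as the reported
per-cell SEM × √n_cell (≈ 10°, 14°, 25° respectively). Truncation bounds
(BP drop ∈ [−15, −4]°, RD ∈ [−35, −8]°, ID ∈ [−70, −20]°; BP overshoot
∈ [4, 25]°; recovery fraction ∈ [0.85, 1] for BP/RD, [0, 0.3] for ID) keep
every sampled cell inside the morphology that defines its label — a cell
labelled BP with a statistically invisible drop would make the ground truth
meaningless. PI positivity is drawn per class: 0.86 for ID (the measured
concordance) and small values (0.02–0.05) for the surviving classes, chosen
so the implied overall PI rates under the control and protective class
mixes (≈ 59% and ≈ 31%) agree with the recorded cross-tabulations.

**What the generator does not emulate:** between-culture heterogeneity of
the class probabilities (per-culture percentages are binomial around a
shared p, so simulated SEMs are smaller than experimental ones), drifting
baselines, correlated noise, cell-to-cell optical cross-talk, and the
timing dependence of drug application. Passing tests therefore demonstrate
the correctness and calibration of the analysis chain under its stated
assumptions, not robustness to every artefact of real recordings.

## Classifier

Thresholds operationalise a qualitative taxonomy; defaults:

| parameter | default | role |
|---|---|---|
| `baseline_window` | 120 s | baseline mean/SD estimation |
| `drop_k` / `drop_floor_deg` | 3 / 3° | drop exists if \|nadir−baseline\| > max(k·σ, floor) |
| `irreversibility_threshold` | 0.5 | recovery fraction below ⇒ ID |
| `recovery_threshold` | 0.8 | recovery fraction above ⇒ recovered (BP/RD) |
| `overshoot_k` / `overshoot_floor_deg` | 3 / 3° | BP requires overshoot > max(k·σ, floor) |
| `overshoot_smooth` | 3 samples | moving mean for the overshoot measurement |
| `end_window` | 60 s | defines the recovered level ("irreversible" = still down here) |

The recovery cut points (0.5 / 0.8) separate "irreversible" from "complete
recovery" with a reported UNCLASSIFIED band between them; UNCLASSIFIED and
NONE cells are excluded from three-class percentage denominators by default.
The nadir is the raw post-onset minimum so that printed drop amplitudes are
reproduced exactly on noiseless traces; the overshoot alone is read from a
3-sample moving mean, because a single-sample maximum over ~100 post-nadir
samples would cross a 3σ threshold by chance alone in ~10% of RD traces at
1° noise, turning them into spurious BP calls. Smoothing only the overshoot
measurement keeps drop amplitudes exact while making BP detection depend on
a sustained (≥ 15 s) elevation. All criteria are relative to each trace's
own baseline statistics, so classification is invariant to constant phase
offsets, and thresholds floor at 3° so noiseless traces are handled.

## Cohort statistics

The culture is the biological replicate: percentages are computed per
culture first and then averaged (mean ± SEM = SD/√n_cult), never pooled
over cells. Group comparisons use one-way ANOVA followed by Dunnett's
two-sided many-to-one comparison against the shared control, evaluated via
the multivariate-t family-wise distribution (scipy's implementation, seeded
for reproducibility; unbalanced designs use the standard unbalanced
correlation structure). Untransformed percentages are the default response
variable; no arcsine or logit transform is applied (an option would be easy
to add, but with ≥ 8 cultures per group the t approximation on percentages
is adequate and matches the reporting convention). Significance stars
follow the convention *** p < 0.005, ** p < 0.01, * p < 0.05.
Report percentages round half-up to the nearest integer.

Degenerate inputs raise: groups need ≥ 2 replicates and nonzero pooled
within-group variance; empty cultures and empty concordance classes are
errors or flagged NaN rather than silent zeros.

## Boolean cascade model

The protective pathway is encoded as a directed acyclic Boolean network:
`Lactate_in → LDH_pyruvate → MPC_transport → mito_ATP → pannexin_release →
ATP_ext → P2_P2Y2 → PI3K → KATP_open → protected`, with AND semantics over
required inputs (the backbone is a chain, so each node simply requires its
upstream neighbour). P2Y1, adenosine (P1) receptors, adenylate
cyclase/cAMP and MAPK are dead-end nodes: stimulating or blocking them
cannot change the outcome, which is exactly what the pharmacology shows.
Interventions: activators drive their target node directly (pyruvate enters
at the mitochondrial carrier, bypassing LDH; UTPγS at the P2Y2 node);
inhibitors clamp their target false; apyrase *degrades* the extracellular
ATP pool, which then stays false unless a hydrolysis-resistant agonist
(ATPγS) sustains it. NMDA-receptor antagonists (APV, MK801) are modelled as
removing the insult itself — a dedicated upstream node — so they yield a
protected outcome without engaging the cascade; consequently the
"adding an inhibitor never creates protection" monotonicity property is
stated over cascade inhibitors only.

Design choices made where the biology is underdetermined: D-glucose is
encoded as not feeding the protective ATP pool (it is metabolisable but
evokes no significant protection; this is a model assumption, configurable
by remapping the agent); quantitative effect sizes, extracellular ATP
concentration thresholds and timing windows (late lactate or delayed
glibenclamide application) are outside a static Boolean model. The
qualitative protected/not-protected readout is the only claim the model
makes; observed ID percentages attached to the packaged panel are fixture
metadata, not model output.

## Problem sizes and numerical choices

- Parameter-recovery checks use the control design (16 cultures × 29
  cells ≈ 464 cells, 1° noise) over 100 seeded replicates; agreement is
  assessed against 3 binomial standard errors at n = 464.
- Family-wise error calibration uses 4 equal groups of 10 cultures and
  2000 null replicates in the test suite (1000 in the acceptance script);
  at 2000 replicates the Monte-Carlo SE of the rate is ≈ 0.005.
- Dose–response simulations use 12 cultures per dose at generating ID
  probabilities (0.66, 0.62, 0.45, 0.32) for (0, 1, 5, 10) mM, 50
  replicates in the test suite and 20 in the acceptance script; under
  binomial culture variability the 1 mM effect (4 percentage points) is
  underpowered and the 5 mM effect (21 points) is reliably detected, so the
  lowest significant dose is 5 mM in the large majority of replicates.
- All simulations derive their randomness from explicit integer seeds or
  `numpy` Generators; pipeline outputs are byte-identical across runs for a
  fixed config.

## Known limitations

- The generator's binomial culture model understates between-culture
  variance relative to the experimental SEMs; simulated Dunnett p-values
  are therefore more significant than experimental ones at the same effect
  size.
- The classifier assumes a single drop-and-recovery episode; oscillating or
  multi-phasic traces outside the BP/RD/ID taxonomy would be forced into
  UNCLASSIFIED or misread.
- The Boolean cascade cannot represent graded, non-significant trends
  (e.g. partial reductions that do not reach significance) — any condition
  is strictly protected or not.
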