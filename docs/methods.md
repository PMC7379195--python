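# Methods

## Scope and data model

The package implements the analysis side of a frequency-MMN experiment with
two equiprobable control conditions (cascade and no-repetition). No raw EEG
is consumed; the working currency is the `EpochSet`
(trials × channels × samples, µV, with one `ToneEvent` per trial). Published
group-level summary statistics serve as worked-example inputs for the
Bayes-factor reproduction; everything upstream of them is exercised on
synthetic data.

## Sequence generation

All blocks use a five-tone ladder (500, 550, 605, 666, 732 Hz), 500-ms SOA,
100-ms tones, 360 analyzed trials per block.

* **Oddball**: 45 deviants (500 Hz) among 550-Hz standards. Gaps between
  deviants (number of intervening standards) are drawn from a discretized
  normal (mean 7, SD 2) truncated to {3..11} and *renormalized* — mass at
  each integer proportional to the normal density there. Deviants are laid
  left to right at cumulative gap positions; if the 45th deviant overruns the
  block, the whole gap vector is redrawn (bounded at 1000 tries). Seven
  warm-up standards precede the block, so the first deviant always has at
  least `7 + gap` standards before it. Event times are nominal
  (`trial_index × SOA`); no jitter.
* **Cascade**: the 8-tone set 500-550-605-666-732-666-605-550 repeated 45
  times; warm-up is one set with the 500-Hz control tone omitted. The
  control tone and the 732-Hz tone each occupy 1/8 of analyzed trials; the
  inner tones 2/8.
* **No-repetition**: each set is a permutation of the cascade multiset,
  rejection-sampled (uniform among valid permutations) so that no two
  consecutive tones are identical within sets, across set boundaries, and at
  the warm-up junction; the warm-up set obeys the same rule.

`sequence_stats` counts adjacent repeats over the *full* event list
(warm-up included) and proportions over analyzed events only; the
interdeviant-gap histogram counts standards between consecutive deviants.

## Synthetic EEG generator

Each trial is a sum of three fixed-latency components plus additive noise;
mastoid-proxy channels receive every component scaled by its own signed
`mastoid_gain` (a single gain per component stands in for a head model —
sufficient for polarity-reversal checks, not for topography).

| component | profile | role |
|---|---|---|
| `baseline_pos` | Gaussian, center 101.5 ms, SD 98.8 ms, +10.0 µV | slow positivity shared by all trials; makes the heavily adapted standard's N1-window mean positive |
| `N1` | dual-width Gaussian at 93 ms: sharp part SD 8 ms (weight 0.0985) + sustained part SD 178.6 ms (weight 0.9015); unadapted peak −25.0 µV | adaptation-scaled negativity |
| `MMN` | Gaussian, center 140 ms, SD 25 ms, −2.304 µV | added on oddball deviant trials only |

The N1's dual-width profile is a deliberate departure from a plain Gaussian.
The published condition means constrain the ratio of the N1's footprint in
the MMN window (115–165 ms) to its footprint in the N1 window (78–108 ms)
to ≈ 0.85 — the standard-vs-control difference persists almost undiminished
into the MMN window — while a visible N1 dip near 93 ms requires local
curvature. A single Gaussian cannot do both; a sharp peak riding on a
sustained negativity, both multiplied by one adaptation gain, can. We read
the sustained part as the adaptation-sensitive portion of the auditory
response that outlasts the N1 peak proper.

**Adaptation.** A tone's N1 gain is `1 − strength · S`, where S is the
recency-weighted mean tonotopic similarity to its predecessors:
`S = Σ_k w_k exp(−Δoct_k²/(2σ²)) / Σ_k w_k`, `w_k = exp(−k/τ)`, over the 8
preceding tones (warm-up tones included, which is what warm-up is for).
Δoct is the log2-frequency distance in octaves. Defaults: strength 0.2537,
σ = 0.1157 oct, τ = 2.091 trials. The functional form is this package's
own; the literature motivates adaptation qualitatively (repetition and
tonotopic proximity reduce the N1) but prescribes no equation. The model
reproduces the qualitative ordering without being told: the deviant
(preceded by near-identical standards) is most adapted, the cascade control
(always immediately preceded by the adjacent 550-Hz tone) intermediate, the
no-repetition control (random non-identical predecessor) least.

**Calibration.** The free parameters (three amplitudes, the slow
component's center/width, the N1 mix, and the three adaptation parameters)
were fitted once by least squares (`scripts/calibrate.py`) so that the
noise-free model reproduces the eight published condition-mean window
amplitudes, with the analysis windows detected from the model's own
waveforms exactly as the pipeline detects them, plus smooth penalties
keeping the standard wave's dip at 93 ms and the difference-wave peak at
140 ms. The frozen defaults achieve a maximum residual of 0.11 µV; the
unadapted N1 amplitude of −25 µV is an effective calibration output (never
observed directly at a 500-ms SOA, where every analyzed tone is preceded by
others within the adaptation window), not a physiological claim.

**Noise and between-subject structure.** Trial noise is AR(1) in time per
channel (default ρ = 0.95, stationary SD 8 µV; white noise available for
unit tests), initialized in its stationary distribution. Per-subject
component amplitudes can be drawn around the group values
(`between_subject_sd`); the published data constrain only group-level CIs,
so the split between trial noise and between-subject variance is a
generator choice, documented rather than claimed. Defaults put the
variability in trial noise, which at 26 subjects and one 360-trial block
per condition yields group-level contrast SEs of the same order as the
published CIs (~0.2–0.35 µV). A per-subject plus-counting error
(|N(1.0, 0.8)|) feeds the behavioral exclusion rule. The ring factor
(one- vs six-letter visual ring) exists only as a balanced metadata label
on blocks. `control_effect_uv` injects a genuine cascade-vs-norep
difference (an MMN-shaped deflection on cascade control trials whose
MMN-window mean equals the requested µV) for recovery studies.

**What the generator does not emulate:** continuous (non-epoched) data,
ocular artifacts, channel-specific topography beyond the mastoid sign flip,
latency jitter, drifts or alpha rhythms. Passing recovery tests therefore
show the *pipeline's* statistical validity under the stated model, not
robustness to every pathology of real recordings.

## ERP pipeline

Baseline correction subtracts each trial/channel's mean over [−100, 0) ms.
Artifact rejection replaces the study's per-subject visual inspection
(unrecoverable from the text) with an automated policy applied blind to
condition: one cutoff per subject from the pooled amplitude ranges
(max − min per trial, maximized over Fz/FCz/Cz), by default the smaller of
the 99th percentile and 200 µV. The N1-absence consensus vote is likewise
replaced by an automated proxy: a subject is flagged when their
standard-trial N1-window mean is more positive than
`max(6 × baseline noise SD, 1.5 µV)` — an absent N1 leaves only the slow
positivity (~+2.8 µV) in the window, while an adapted-but-present N1 keeps
it near +0.7 µV. The behavioral rule (error > mean + 2 SD, strict
inequality, so a zero-SD cohort excludes nobody) and the 70% retention rule
are as published.

Windows are data-driven and derived from oddball trials only, so they
cannot bias the cascade-vs-norep comparison: the N1 window is the negative
peak of the 30-Hz low-passed grand mean of oddball standards (±15 ms,
searched 50–150 ms); the MMN window is the negative peak of the low-passed
deviant-minus-standard grand difference (±25 ms, searched 100–250 ms).
Filtering (4th-order Butterworth, applied forward-backward for zero phase)
is used only for peak finding and display; window means come from
unfiltered averages — whether the original analysis filtered before
extracting means is unstated, and the unfiltered choice keeps the
operations linear. Window bounds are inclusive on the sample grid; peak
ties break to the earliest sample; an extremum on a search-window edge is
flagged as unbracketed. Grand averages across subjects weight subjects
equally (not by trial count).

Contrasts per subject: oddball MMN (deviant − standard), cascade- and
norep-corrected MMNs (deviant − control), the critical condition difference
(norep-corrected − cascade-corrected ≡ cascade − norep, exact by algebra),
and the N1 contrast (cascade − norep). Group CIs use the t critical value
with df = n − 1.

## Bayes engine

Likelihood: t density in θ with df = n − 1, location = observed mean
difference, scale = SE (recovered from a 95% CI as half-width /
t(0.975, df) when not given directly). Priors: uniform (the informed
default), point, normal, half-normal. BF10 is the prior-averaged
likelihood over the likelihood at the null point, by adaptive quadrature
over the prior's support (normal families: location ± 10 scales) with
absolute tolerance well below 1e−8; a uniform prior with equal bounds
degenerates to a point prior, and a point prior at the null gives BF = 1
exactly. Evidence labels follow the conventional scheme (anecdotal 1–3,
moderate 3–10, strong 10–30, very strong 30–100, extreme > 100, applied to
whichever direction exceeds 1).

Sign convention: positive θ means "cascade minus no-repetition" for the N1
test and "(deviant − norep) − (deviant − cascade)" for the MMN test. In
synthetic mode the prior bounds are computed from the same run's observed
quantities (|oddball MMN| for the MMN test; the observed deviant − norep N1
difference for the N1 test, floored at 0.1 µV with a warning when the
noisy observation is non-positive), never from published values.

The reproduction table covers the six final-sample Bayes factors. The
complete-sample values (n = 40) are not reproducible from the published
text alone — their prior bounds (e.g. the complete-sample deviant − norep
N1 difference) are never printed — and are excluded. Reproduction tolerance
is ±5% relative: the printed inputs are rounded to two decimals, and
propagating that rounding spans the residual gap.

## Randomization simulation

"Completely randomized" is read as a uniform permutation of the fixed
multiset (each tone exactly r times), not i.i.d. draws with replacement;
the closed-form expectation m·r·(r−1)/(N·(N−1)) = 12.44% for 8 × 180
matches the published 12.4% (the with-replacement value would be 12.5%).
Adjacent pairs are counted over the N − 1 within-block boundaries; blocks
do not continue into each other.

## Problem sizes and numerical choices

The parameter-recovery suite runs 100 replicates of a 26-subject study at
128 Hz sampling with one 360-trial block per condition and AR(1) noise
(SD 8 µV) — sizes chosen so the full suite runs routinely while keeping
group SEs in the published range. Truth for the bias check is the
noise-free simulation of the same generator (the intrinsic cascade−norep
difference of the calibrated model is ≈ +0.05 µV, matching the published
near-zero difference). The main study grid is 1024 Hz over [−100, 400] ms
(513 samples); epoch grids are defined as samples k/fs for
k in [round(−0.1·fs), round(0.4·fs)], event-relative ms in all interfaces.

## Known limitations

* The calibrated generator matches eight group-mean amplitudes; it is not
  identified by them (other parameter sets could fit equally well), so
  recovered adaptation parameters should not be over-interpreted.
* The exact per-subject rejection cutoffs and the visual N1 consensus of
  the original study are unrecoverable; only their spirit is reproduced,
  and both automated stand-ins are configurable.
* The cascade condition is deterministic, so its window means carry no
  sequence-sampling variance, slightly unbalancing the two control
  conditions' variances — negligible at the calibrated noise level.
* MCMC/posterior estimation, default-Cauchy (JZS) Bayesian t tests and
  multiple-comparison corrections are out of scope; the engine computes
  exactly the summary-statistic Bayes factors described above.
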