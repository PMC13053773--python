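# Methods

This note documents the models, conventions and parameter choices behind
`runcna`, in the spirit of a statistical-software methods appendix: what each
stage assumes, which knobs matter, what the synthetic generators do and do
not emulate, and where the design was genuinely open.

## Signal processing

### vGRF and gait events

The vertical ground-reaction force is low-pass filtered with a zero-phase
(forward–backward) Butterworth filter, order 2, cutoff 50 Hz (`lowpass_vgrf`).
Two passes square the magnitude response, so the gain at the cutoff is
exactly 0.5; the digital design is bilinear with prewarping, so gains away
from the cutoff deviate slightly from the analog prototype (at 100 Hz:
0.0535 rather than 0.0588).

Ground contact is a maximal run of samples strictly above 50 N
(`detect_contacts`). Indices are 0-based with half-open intervals: the onset
sample is the first strictly above threshold, the offset the first subsequent
sample at or below it. Two debounce windows reject chatter near the
threshold: gaps shorter than 20 ms are merged into the surrounding contact,
and contacts shorter than 50 ms are dropped. Both are configurable; the
defaults assume clean laboratory force plates.

The analysed *gait cycle* runs from one contact onset to the next onset of
the instrumented side — one contact time T_c plus one flight time T_f —
because that is the denominator of the stride-frequency definition
SF = 60/(T_c + T_f). This is a step-level cycle, not the two-step anatomical
stride; all per-cycle quantities in this package use it consistently.

Cycle selection (`select_cycles`) takes the first k = 10 valid cycles of the
analysis window. A cycle is invalid when its contact time or total duration
deviates more than 2 trial SDs from the trial median, or when an
EMG-quality flag marks an artefact. This automated rule replaces visual
stride inspection for reproducibility. The deviation test has an absolute
floor of 5 ms: on very regular gait the trial SD collapses to sampling
jitter, and a ±1-sample timing wobble is not a motion artefact. Fewer than k
valid cycles is an error, never a silent shortfall.

### EMG and CNA

EMG is band-passed 20–400 Hz with a zero-phase Butterworth (design order 4
per band edge, configurable), full-wave rectified, and integrated per cycle
with the rectangular rule Σ|xᵢ|·Δt (`iemg_per_cycle`), giving μV·s. The Δt
factor makes iEMG independent of sampling rate and restores the stated
units; absolute magnitudes therefore differ from a bare sample sum by the
constant 1/rate, which is irrelevant to correlations. No amplitude
normalisation (MVC or otherwise) is applied. EMG cycle boundaries are the
GRF cycle boundaries mapped by time (both streams share t = 0 from the
synchronised A/D converter) and rounded to the nearest EMG sample. Cycles
extending past the trace are an error rather than zero-padded.

CNA = mean iEMG per cycle × SF is computed as an exact product and asserted
as an identity on every emitted result. The per-cycle iEMG value is carried
alongside CNA in every output so the stride-frequency-free sensitivity
analysis never needs reprocessing.

### IMTP and isokinetic strength

IMTP onset is the first crossing of baseline mean + 5 baseline SDs that is
sustained for ≥ 10 ms. The baseline is the last 1 s of the quiet-standing
window (the earlier part may contain settling transients); its mean is the
measured body weight, which is deliberately used instead of scale mass × g.
The sustained-crossing requirement guards against single-sample noise
spikes.

RFD(0–w) = (F(anchor + w) − F(anchor))/w for w ∈ {50, 100, 150, 200,
250} ms. The anchor is the last sample at or below the onset threshold — the
threshold crossing itself — one sample before the reported onset index.
Anchoring at the crossing makes RFD exact on ramp fixtures and invariant to
constant force offsets; anchoring one sample later would bias every window by
one sample of rise. Both absolute (N·s⁻¹) and body-mass-relative RFD are
emitted, and an optional fat-free-mass divisor supports the normalisation
sensitivity analysis. Peak force is the maximum after onset; the trial with
the highest PF is selected, ties resolved to the earlier trial.

Isokinetic processing consumes torque values only (dynamometer gravity
compensation is upstream hardware): relative PT = max over repetitions /
body mass.

## Statistics

* **Pearson r** with the exact two-tailed p from t = r√(n−2)/√(1−r²) on n−2
  df (not a normal approximation; n = 23 is small). Pairwise-complete
  deletion with the pair count reported.
* **Shapiro–Wilk** normality is report-only; it does not gate the Pearson
  tests.
* **Benjamini–Hochberg** step-up FDR is applied *within declared families*.
  The default design declares one family per heatmap: joint-matched
  isokinetic strength × muscle CNA (m = 96 across three speeds) and IMTP
  metrics × all muscles (m = 144). The family sizes are logged with every
  run. This is an interpretive choice — any family declaration is defensible
  only if stated, so the package makes it explicit and configurable.
* **Bootstrap 95 % CIs**: percentile method over B = 1999 participant-level
  resamples, seeded per pair from a single study seed (bit-reproducible);
  degenerate resamples (zero variance) are dropped. At n = 23 and ρ = 0.6 the
  percentile interval covers the truth ~93 % of the time — the usual mild
  undercoverage of percentile bootstrap at small n.
* **Effect-size bands** on |r|: trivial < 0.1 ≤ small < 0.3 ≤ moderate
  < 0.5 ≤ large < 0.7 ≤ very large < 0.9 ≤ nearly perfect ≤ 1. Bands are
  half-open on the left so shared endpoints resolve upward.
* **Minimum detectable correlation** (`min_detectable_r`): the smallest ρ at
  which the two-tailed test attains the target power, solved by Brent
  root-finding on the *exact* power function — the sampling density of r
  under a bivariate normal, integrated beyond the critical value. A Fisher-z
  estimate only brackets the root: at n = 23 Fisher-z alone gives 0.556
  where the exact computation gives 0.5456, and the two round differently at
  2 dp. Above |ρ| ≈ 0.999 the hypergeometric density is numerically fragile;
  that bound is treated as the attainability limit.

## Synthetic data

The generators exist to give every pipeline stage a ground-truth oracle, and
they emulate exactly the study conditions: treadmill speeds 10/12/14 km·h⁻¹
with contact times 245/220/200 ms (≤ 250 ms) and flight times 95/115/130 ms,
1000 Hz force and 2000 Hz eight-muscle EMG, IMTP with a 2-s quiet stand and a
5-s pull, and 23-participant cohorts.

* **vGRF**: each stance is a sum of two raised-cosine bumps (impact
  transient at ~12.5 % of stance, active peak mid-stance, peak 2.5 × body
  weight) riding on the 50 N threshold, so the noise-free trace crosses 50 N
  exactly at the stance boundaries and is zero in flight. Any smooth positive
  stance shape would do; raised cosines make the crossings analytic.
* **EMG**: white Gaussian noise band-limited to 20–400 Hz (so the synthetic
  signal survives the pipeline's own band-pass essentially unchanged),
  scaled to unit variance and amplitude-modulated by a per-cycle raised-cosine
  envelope locked to gait phase. For a Gaussian carrier the expected
  rectified amplitude under the envelope is amplitude × √(2/π), giving a
  closed-form expected iEMG per cycle. Default burst phases place quadriceps
  and triceps surae in stance, biceps femoris in late swing, tibialis
  anterior around the swing–contact transition, with plausible un-normalised
  amplitudes (80–140 μV).
* **IMTP**: body weight baseline, then a linear or logistic rise (maximum
  slope = the requested rise rate) to a plateau (default 2.2 × body weight).
  Ground-truth onset and per-window RFD are computed from the noise-free
  trace with the same anchor convention as the analysis.
* **Cohorts**: multivariate-normal draws with a requested (validated PSD)
  correlation matrix. `planted_cohort` builds the full study-shaped table —
  8 isokinetic variables, PF and 5 RFD windows, 8 muscles × 3 speeds of CNA —
  with one planted strength–activation correlation (default ρ = −0.6 between
  eccentric knee-flexor PT and BF CNA at 12 km·h⁻¹, the magnitude of the
  headline effect this kind of study investigates) and everything else
  independent. Strength moments (e.g. K_flex-ecc 2.0 ± 0.35 N·m·kg⁻¹, CNA
  2800 ± 700 μV·s·min⁻¹, stride frequency 176 ± 6 spm) are plausible for
  recreational male runners; no published per-variable moments exist for
  these quantities, so they are package choices, fixed once. Per-cycle iEMG
  columns are derived as CNA / stride frequency so the planted association
  propagates to the sensitivity variant.

The pipeline's simulated mode also generates full signals whose *processed*
metrics carry the planted correlation (a latent activation scale shared
across speeds, correlated with the planted strength variable), so the
end-to-end path — files in, correlation report out — is exercised against
known structure.

What the generators do **not** emulate: motor-unit physiology, signal
nonstationarity within a burst, electrode artefacts and baseline drift,
inter-muscle crosstalk, left/right asymmetry, treadmill-belt speed
fluctuation, or fatigue across a trial. Passing tests therefore demonstrate
correctness of the *computations* under realistic signal geometry and noise,
not robustness to every failure mode of real laboratory data.

## Numerical choices and degenerate inputs

* Zero-phase filtering uses scipy's default reflective padding; traces
  shorter than the padding raise rather than silently truncate.
* A signal that never crosses 50 N yields empty events (not an error); one
  that never drops below yields a single flagged contact spanning the trace.
* Zero variance in either correlation variable, fewer than 3 complete
  pairs, p-values outside (0, 1], non-PSD correlation matrices, and
  self-pairs in a design are all hard errors.
* Pipeline stage seeds fan out deterministically from the single config seed
  (`numpy.random.SeedSequence.spawn`), so reruns are byte-identical and each
  stage is independently reproducible.
* Problem sizes used by the test suite (synthetic trials of 15–40 strides,
  500-replicate bootstrap-coverage and cohort-recovery simulations, 20 000
  power simulations) were chosen as the smallest sizes at which the
  binomial/Monte-Carlo tolerances of the checks are meaningful.

## Known limitations

* CNA integrates activation over whole cycles; it cannot attribute
  activation to stance vs swing phases, and no co-contraction indices are
  computed.
* The BH family declaration materially affects adjusted p-values; results
  are only comparable across studies that declare the same families.
* Percentile bootstrap CIs mildly undercover at n = 23 (~93 % for nominal
  95 %); BCa would narrow the gap at the cost of the simple percentile
  contract.
* The 10-cycle selection takes the *first* ten valid cycles of the analysis
  window; selecting the cleanest ten instead would be a different (and
  slightly optimistic) estimator. The choice is exposed in configuration.
* Vendor device formats (C3D, proprietary EMG exports) are out of scope; the
  readers consume exported CSV channels.
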