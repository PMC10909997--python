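# Methods

This note documents the models, estimators and numerical choices behind
`hrvdt`, and what validation on synthetic data does and does not establish.

## The synthetic study

The generator emulates a within-subject dual-task experiment: three
cognitive-load levels (1-, 2-, 3-back) crossed with three physical-load
levels (none / medium / high), 35 subjects by default, each contributing all
nine cells. Subjects are allocated to three counterbalancing subgroups
(sizes differing by at most one) that rotate the order of the three n-back
runs: (1,2,3), (2,3,1), (3,1,2).

### n-back trials

A trial is 20 letters, 5 of them targets (a letter equal to the one *n*
positions earlier), each letter shown 0.5 s with a 1.5 s inter-stimulus
interval. Target positions are drawn uniformly among eligible positions
(index ≥ *n*); non-target positions are filled avoiding accidental lag-*n*
matches, so the emitted sequence has *exactly* the configured target count —
verified by exhaustive lag scans in the tests. The letter alphabet defaults
to 8 consonants (B C D F G H K L) to avoid vowel-chunking strategies; it is
configurable.

A run is 6 consecutive trials. The protocol's printed component timings
(2 s instruction + 20 × 2 s letters + a post-trial break) do not sum to its
printed 50 s per-trial total; we keep 50 s as the per-trial duration — which
makes a 6-trial run the quoted 5 min — and absorb the 2 s discrepancy into
the inter-trial break (8 s effective). Both values are config-exposed.

### RR series: the IPFM model

RR series come from an integral pulse frequency modulation model. The
modulating rate is

    m(t) = (1/T0) · [1 + a_lf·sin(2π f_lf t + φ1) + a_hf·sin(2π f_hf t + φ2)]

with T0 the mean RR (s), f_lf = 0.10 Hz, f_hf = 0.25 Hz; a beat fires at
each integer crossing of ∫m. The integral is evaluated analytically and
inverted by interpolation on a 1/64 s grid (inversion error ≪ 0.01 ms).
White Gaussian jitter (`jitter_sd`, default 10 ms) is then added per
interval. Defaults: mean RR 800 ms, a_lf = a_hf = 0.04. IPFM is the standard
test bench for HRV spectral estimators because the injected band structure
is known exactly: HF band power must rise monotonically with a_hf, and the
LF/HF balance tracks (a_lf/a_hf)².

Phases φ1, φ2 are drawn from the seeded stream; identical seeds give
bit-identical series.

### Condition effects

An `EffectMap` assigns each design cell multipliers on (mean RR, a_lf, a_hf)
and shifts on (RT location and spread, miss and false-alarm probability, TLX
dimension means). The default map encodes the directions reported for
dual-task load: physical load ↑ ⇒ mean RR ×0.92 (medium) / ×0.85 (high),
a_hf ×0.70 / ×0.55 (vagal withdrawal, raising the LF fraction), small RT and
TLX increases; cognitive load ↑ ⇒ RT location +80/+160 ms, miss probability
+0.07/+0.17, and higher mental/effort/frustration ratings. Subject random
effects — baseline mean RR (SD 50 ms) and RT offset (SD 50 ms) — are shared
across a subject's nine cells, giving the within-subject correlation the
paired tests rely on. An identity map produces exchangeable conditions and
is used for type-I-error checks.

### ECG and behavior

The ECG renderer places a Gaussian-lobe PQRST template (R amplitude 1 mV,
QRS width ≈ 90 ms) at each beat time, sampled at 256 Hz by default, and adds
three noise components: a powerline sinusoid (50 Hz default), band-limited
EMG (zero-phase 4th-order Butterworth-filtered white noise, 20–100 Hz,
scaled to a target RMS), and sub-0.5 Hz baseline wander. Ground-truth beat
times ride along as annotations.

Reaction times are lognormal (median 500 ms, shape σ = 0.25) — the standard
right-skewed family for RT data; responses landing beyond the 2 s response
window (the stimulus cadence) count as misses. TLX ratings are normal draws
around condition-shifted dimension means, rounded and clipped to the
21-point (0–20) scale; each of the 15 pairwise-importance choices picks the
dimension with the larger latent importance, keeping choices consistent with
rating magnitudes.

### What the generator does not emulate

No respiratory-cardiac coupling beyond a fixed-frequency HF sinusoid, no
ectopic-beat morphology (artifact tests inject multiplicative spikes), no
drift of autonomic state within a run, no learning/fatigue dynamics across
runs, and no EEG/eye-movement channels. Passing tests therefore establish
estimator correctness and pipeline sensitivity under band-structured
stationary modulation — not performance on real recordings, where
non-stationarity and morphology variation dominate.

## ECG processing

*Denoising.* Baseline is a 600 ms median filter (wider than the QRS–T span,
so complexes are not flattened) subtracted from the signal; a 20 ms moving
average then attenuates powerline/EMG components (at 256 Hz a ≈5-sample mean
has a spectral null near 50 Hz). Edges are reflected.

*QRS detection.* Difference-threshold detector: first difference → square →
120 ms moving-window integration; the threshold is 0.4 × a running peak of
the integrated signal with a 2 s exponential decay, making detection
invariant to amplitude scaling and robust to slow gain drift. Within each
supra-threshold region the beat is the argmax of the input signal (extended
half an integration window to the left, compensating the integrator delay);
detections closer than the 250 ms refractory period are merged, keeping the
stronger. A flat-line record returns an empty beat list with a warning
rather than an exception.

*RR cleaning.* An interval is an outlier when it deviates from the moving
median of its 11-beat window by more than 3 × 1.4826 × the window's MAD
(the scaled-MAD convention of Matlab-style `filloutliers`, moving variant),
or leaves the 250–2000 ms physiological band. Outliers are repaired by
linear interpolation between surrounding normal intervals and flagged
`outlier_replaced`. The screen-and-repair pass **iterates to convergence**
(at most 5 passes): clustered artifacts inside one window — especially at
the series edges, where the window truncates — inflate the local MAD enough
to mask one another on a single pass, and iteration recovers them. Beat
times are kept as detected; only interval values change, so a repaired
series is marked by its flags rather than by re-synthesized beat times.

Two properties of this rule are worth knowing. It is idempotent — cleaning a
cleaned series changes nothing. And like any small-window MAD screen it has
a non-trivial false-positive rate on smooth-plus-jitter tachograms (an
11-point MAD is a noisy scale estimate), which biases RMSSD downward by a
few percent on *any* series it touches. Injection-recovery is therefore
assessed against an identically-screened uncontaminated reference, which
isolates what the injected artifacts cost after repair (≈1% in RMSSD)
rather than the screen's intrinsic smoothing bias.

## HRV features

Time domain over one window: meanHR is the mean of the instantaneous rate
60000/RR_i (the 60000/mean(RR) convention differs by Jensen's inequality
and is available via config); SDNN uses the sample (n−1) denominator; NN50
counts strict exceedances (>50 ms) of successive differences; pNN50 divides
by the number of successive differences; RMSSD is the RMS of successive
differences.

Frequency domain: the tachogram (interval *i* attributed to its closing
beat time) is cubic-spline interpolated to an even 4 Hz grid and
mean-removed; a Burg autoregressive model of order 16 — a common choice for
5-min windows; AIC selection is available behind a flag — is fitted
(`statsmodels` Burg recursion), and the one-sided AR density
2σ²/fs / |1 − Σ ρ_k e^(−2πifk/fs)|² is evaluated on a 2049-point grid over
[0, 2] Hz. Band powers are trapezoidal integrals with interpolated edge
points over VLF [0.003, 0.040), LF [0.040, 0.150), HF [0.150, 0.400]; Total
is their sum, so power below 0.003 Hz is excluded. nLF + nHF = 1 and
Total-additivity are asserted in the feature constructor. HF = 0 yields a
NaN LF/HF marker, not infinity. A zero-variance input returns an all-zero
spectrum. The Burg estimator was preferred over Yule-Walker for its
stability on short windows; the independent cross-check in the tests is a
Welch periodogram of the same resampled tachogram (agreement within ±10% on
LF and HF at the default settings, typically ±3%).

## Scoring

*NASA-TLX.* Six ratings on the 0–20 scale (a 1–21 storage convention is
config-exposed) and 15 pairwise choices. Dimensions are ranked by selection
count ascending and receive weights 1/21 … 6/21 by rank; tied dimensions
share the mean of the weights their rank positions span (average-rank
convention), so weights always sum to exactly 1 — which makes the total
equal the common rating when all six ratings coincide, a useful invariant.

*Performance.* A hit is a target with an in-window response. CNR = hits /
targets, MNR = 1 − CNR; WNR is responses-to-non-targets over non-target
count (the natural false-alarm base; the source protocol does not define
it). RT statistics are over hit RTs only, SDRT with the (n−1) denominator;
with no hits the RT fields are absent-marked rather than zero.

## Statistics

For each feature × factor, within-subject difference scores are tested for
normality (Shapiro-Wilk, α = 0.05, per pairwise contrast); only if every
contrast passes is the parametric path taken (rmANOVA omnibus + paired t
post-hocs), otherwise Friedman + Wilcoxon signed-rank. Friedman for two
levels (where scipy declines) is computed from within-subject ranks with
tie correction — there it is a monotone function of the sign-test count,
verified in the tests. Wilcoxon drops zero differences and switches from
the exact null to the normal approximation above n = 25. Raw p-values are
reported at α = 0.05 by default; Holm correction over the pairwise
contrasts is available behind a flag. Correlations (Spearman) are computed
within each physical-load stratum, pooling the three cognitive-load levels
within subjects (~3 rows per subject); the repeated subject contributions
are pooled, not modeled — stated in the report header as a limitation.

The analysis report has three stages: workload/performance across cognitive
and physical load; HRV across physical load within each cognitive level;
and HRV × (TLX total, mean RT) correlations per physical-load stratum.

## Validation experiment sizes

The acceptance checks use: 1000 random series for time-domain oracle
equivalence; one 300 s IPFM series (a_lf = a_hf = 0.05, jitter 5 ms) for
AR-vs-Welch agreement and peak recovery plus 5 amplitude levels × 20
replicates for HF monotonicity; 300 s ECGs for detector fidelity (EMG noise
at SNR 10 dB, ±20 ms matching); 10 replicates of 2% spike injection for
cleaning recovery; and 100 replicated studies of 35 subjects each for
direction-recovery power (medium physical load: HF amplitude ×0.70, mean RR
−8%) and for the type-I error under an identity effect map. At these sizes
the full acceptance run takes well under a minute of CPU; the binomial
Monte-Carlo error on the 100-replicate rejection rates is about ±2 points
at the 5% null level.

## Pipeline and reproducibility

The default pipeline generates RR series directly (`via_ecg: false`);
routing through ECG synthesis + QRS detection is a config switch, exercised
separately in the tests, since it adds minutes of detector time across
315 records without changing the statistical content. One global seed fans
out through `numpy` SeedSequence spawning to per-subject, per-condition and
per-stage substreams, so identical configs give byte-identical artifacts
and any stage can be reproduced in isolation. The manifest records a hash
of the resolved configuration; unknown config keys are rejected at load.

## Known limitations

- The IPFM inversion grid (1/64 s) bounds beat-time precision at ~µs scale;
  irrelevant for HRV but not a general-purpose event simulator.
- AR order 16 at 4 Hz resampling is tuned to 5-min windows; much shorter or
  longer windows warrant AIC selection.
- The detector assumes upright R waves (argmax of the signal); inverted-lead
  recordings would need a polarity option.
- Correlation p-values ignore the within-subject dependence of pooled rows.
- The moving-MAD screen's false-positive rate (few %) slightly shrinks
  short-term variability indices on all processed series; comparisons
  between identically-processed conditions are unaffected.
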