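# Methods

This note documents the models, estimators and numerical choices behind
`dastride`, what the synthetic generators do and do not emulate, and the
limitations a user should know before applying the pipeline to real
recordings.

## Spike trains and first-order statistics

A `SpikeTrain` is a strictly increasing series of timestamps (seconds)
with a recording duration.  The mean rate is `(n − 1) / (t_last −
t_first)`, i.e. the rate of the analysed span rather than the nominal
duration, so it remains meaningful on stationary segments; a
configuration flag is not needed because callers pass the segment they
want analysed.  CV is `100 · sd(ISI) / mean(ISI)` with the sample SD
(ddof = 1) and needs ≥ 2 ISIs; skewness and kurtosis are moment-based on
the ISI sample and need ≥ 4 ISIs.  Kurtosis is reported **non-excess**
(a normal distribution scores 3); an `excess_kurtosis` flag switches
conventions.  Statistics that cannot be computed are NaN, never
exceptions — degenerate cells must flow through cohort assembly and be
excluded downstream, not crash it.

The autocorrelation histogram (ACH) bins all pairwise spike-time
differences within ±`max_lag` (default 2 s, bin 10 ms — these defaults
are free choices; pattern classification depends on them, which is why
both are in the configuration) and normalises to a rate: pair count /
(n_spikes · bin width).  A homogeneous Poisson train of rate λ then has
a flat ACH at λ, which makes peak-detectability thresholds easy to state
in rate units.

## Burst and pause detection

Bursts use the classical two-threshold scan for nigral DA neurons: an
ISI strictly below 80 ms opens a burst, ISIs strictly below 160 ms
extend it, anything else closes it.  Strict inequalities follow the
"below 80/160 ms" reading; equality at the cut therefore does not open
or extend.  The closing spike is the spike before the first ISI at or
above the continuation cut, each spike belongs to at most one burst, and
the intraburst frequency of a burst is `1 / mean(intraburst ISIs)`; the
cell-level value is the unweighted mean over bursts and is undefined
(NaN) for cells without bursts.  SFB is the percentage of spikes inside
bursts; `sfb > 5` (strict) calls the cell bursty.

Pauses are ISI outliers above `pthr = q3 + w (q3 − q1)` with `w = 3`,
computed per cell on the analysed segment's ISI distribution with
type-7 (linear-interpolation) quantiles — the estimator is configurable
because small samples shift `pthr` appreciably.  An ISI whose opening
spike is the closing spike of a burst is excluded by default (post-burst
quiescence is plausibly non-synaptic); the exclusion window is exactly
that one interval, not a longer horizon — the narrowest reading of
"pauses after bursts", and the only one that needs no extra free
parameter.  Fewer than 4 ISIs yield an undefined threshold and no pause
statistics.

## Rate stationarity

The multiple-filter test compares, for each window `h` ∈ {25, 50, 100,
150} s and each grid time `t` (1 s steps), the spike counts in
`(t − h, t]` and `(t, t + h]`, studentised by a renewal-process variance
estimate `h (v_l / m_l³ + v_r / m_r³)` built from the empirical ISI mean
and variance in each window.  The global statistic is the maximum over
`t` and `h`.  Its null distribution is simulated: homogeneous Poisson
trains at the observed mean rate, same duration, same windows; the
(1 − α) quantile (α = 0.05, 1000 simulations by default) is the
rejection threshold.  A simulated threshold was chosen over the
asymptotic Gaussian-process limit of the published test because it is
exact at any duration and trivially correct for the window sets users
actually choose; the statistic is studentised and hence nearly pivotal,
so a threshold can be shared across cells of equal duration and similar
rate (the pipeline exploits this).  Change points are the argmax of the
statistic inside each excursion above the threshold, thinned so that no
two lie closer than the largest usable window; segments between change
points partition the recording, and the longest segment containing at
least two spikes is the stationary section passed to the oscillator fit.
Trains shorter than twice the smallest window (or with < 4 spikes) are
returned untested as a single whole-train segment.

By default the whole per-cell variable set — not only the oscillator
parameters — is computed on the stationary segment
(`use_stationary_segment = True`); setting the flag to False computes
everything on the full recording.  Both behaviours are exposed because
either convention is defensible for the non-oscillator statistics.

## The GLO model

Gaussian Locking to a free Oscillator describes a train by four
parameters: mean oscillation period μ (s), period variability s (s),
burst size β (expected spikes per cycle) and locking precision σ₂ (s).
The generative model: hidden beats form a Gaussian random walk with
positive-truncated increments `N(μ, s²)`; each beat emits
`Poisson(β)` spikes (beats may be skipped; a `fixed` law emitting
exactly `round(β)` spikes per beat is available and is what the
synthetic single-spike presets use); each spike is jittered from its
beat by `N(0, σ₂²)`.  The expected rate is β/μ.  This generative
reconstruction is validated by self-consistency — simulate → fit
recovers the parameters — rather than by equality with any particular
legacy implementation.

The model ACH is semi-analytic: per reference spike, companion intensity
`β · N(0, 2σ₂²)` from the same beat (the Poisson pair identity
E[n(n−1)]/E[n] = β) plus `β · N(kμ, ks² + 2σ₂²)` for each beat
separation k ≥ 1, mirrored in lag sign, with Gaussian mass integrated
over each bin so arbitrarily narrow peaks are exact.  The number of
components is chosen in closed form so every Gaussian reaching the lag
window is included; when the variability is so large that thousands of
components would be needed, the cross-beat sum is provably flat at β/μ
and is replaced by that constant.

Fitting minimises the squared difference between the empirical and the
model ACH over (μ, s, β, σ₂) with bounded trust-region least squares.
Initialisation: candidate periods from significant positive-lag ACH
peaks (local maxima above the flat level + 2 SE, after a 3-bin moving
average), β₀ = rate · μ₀, and a small grid of (s, σ₂) splits; the lowest
cost over all starts wins, making the fit deterministic given the train
and configuration.  Trains with no significant off-zero peak are flagged
non-oscillatory and the period variability pinned at its upper bound
(1 s).  σ₂ is floored at 1 ms before taking the natural log, so the LDA
feature log(σ₂) is always finite.  Fits on fewer than 100 spikes are
flagged unconverged.

Pattern taxonomy: bursty iff β > 1.5; oscillatory iff s/μ < 0.35 **and**
the ACH shows ≥ 3 equidistant peaks (near kμ) with non-increasing
amplitude (15% tolerance), each above the flat level + 2 SE.  The 2 × 2
of these flags yields single-spike-oscillatory ("pacemaker"),
single-spike-irregular, bursty-irregular and bursty-oscillatory.  The
thresholds are relative (s/μ), so the labels are invariant under time
rescaling; they were calibrated on synthetic cohorts and sit in the
configuration.  For unconverged fits the label falls back to the ACH
peak-count heuristic and is flagged low-confidence.

Note on "burst size": under the Poisson law, expected spikes per cycle
and expected spikes per burst conditional on bursting coincide for
β ≥ 1; the package reports the unconditional β.

## AP waveform metrics

At least 10 peak-aligned sweeps are averaged pointwise (fewer triggers a
warning, not an error) and re-zeroed to the pre-peak baseline mean.  The
onset of the initial upward component — which the duration definition
needs but no printed rule pins down — is operationalised as the last
sample before the voltage first exceeds baseline mean + 3 baseline SD
ahead of the peak; the multiplier is configurable and the rule was
validated on synthetic templates with exactly known onsets.  AP duration
is onset → post-peak minimum (ms); the relative trough is the trough
voltage after dividing the baseline-subtracted trace by its peak.  A
waveform whose post-peak minimum is not below −2% of the peak is treated
as monophasic and rejected.  Both metrics are invariant under amplitude
scaling and baseline offsets.  The putative-DA screen is
`duration > 1.2 ms` and `1 ≤ rate ≤ 8 Hz`.

## Best-subset LDA

Cells are rows of a 13-variable table: the four GLO parameters (μ, s, β,
log σ₂), mean rate, CV, SFB, ISI skewness and kurtosis, bursts/min,
pauses/min, AP duration, relative trough.  Burst and pause counts enter
as per-minute rates (the raw counts are also exported).  Cells with any
missing variable are excluded from the LDA and logged; intraburst
frequency — undefined for burst-free cells — is deliberately not among
the 13 variables.

For a subset S_j, the cohort is split 1000 times into halves A and B,
stratified per group with the odd member alternating; an LDA trained on
A predicts B and vice versa, and M_j is the mean correct percentage over
both directions and all splits.  The inner classifier is the closed-form
two-class Fisher discriminant: pooled within-class scatter S_w, direction
`w = S_w⁻¹(μ₁ − μ₀)`, equal priors, midpoint threshold — group sizes are
design artifacts, not prevalences.  S_w is regularised with a ridge of
`1e−6 × diag(S_w)`, which is algebraically the identity ridge after
z-scoring each feature by its pooled training SD; the rule is therefore
exactly equivariant under per-feature affine rescaling and no explicit
standardisation (or leakage-prone whole-data scaling) is needed.  The
implementation is vectorised across splits and subsets (batched small
linear solves), which is what makes 8191 subsets × 1000 splits ×
permutations tractable; it agrees with scikit-learn's
`LinearDiscriminantAnalysis(priors=[.5,.5])` to machine precision on
every split, and that agreement is pinned by tests.

The best subset maximises M_j, ties broken toward smaller subsets then
enumeration order.  Significance: the whole maximisation is repeated on
datasets with permuted group labels; `p = (1 + #{permuted M* ≥
observed}) / n_perm` (add-one smoothed, so p ≥ 1/n_perm), with its
Monte-Carlo SE reported.  Full fidelity (1000 permutations × 1000 inner
splits × 8191 subsets) is ~10⁹ discriminant fits; the default is a
scaled-down 200 × 200 run, flagged `scaled_down` in the output, with a
`paper_fidelity` switch for the full setting.  When the best model is
significant the discriminant is retrained on the entire cohort, giving
the full-data accuracy and per-cell correct/incorrect calls.

Under the null, split-half accuracy averages slightly **below** 50%
(cross-validated overfit discriminants are mildly anti-predictive — a
property of CV, more pronounced the larger the subset); the calibration
tests assert the 50 ± 5% band and approximate uniformity of the
permutation p-values.

## FG labelling and anatomy

Intrinsic rule: ROI mean intensity strictly above background mean +
2 SD (background from TH-negative regions, nuclei excluded upstream); a
zero background SD degenerates to a mean comparison with a warning.
Immuno rule: threshold at background mean + 10 SD; "marks" are
8-connected supra-threshold components inside the soma mask with area ≥
2 pixels (the area floor is a noise guard — a single Gaussian-tail pixel
at 10 σ should not count as a punctum); positive iff strictly more than
5 marks.  Population matrices from a region × projection count table:
row-normalised (composition of each region) and column-normalised
(distribution of each projection) percentages; all-zero rows or columns
yield NaN.  Double-label fraction is `100 · n_double / (n_single +
n_double)`.

## Synthetic generators

Generators are pure functions of their specification and seed.  Cohort
presets are named after the study's comparisons (`dls_lsn_vs_msn`,
`msn_ds_vs_lnacc`, `lnacc_vs_mnacc`); effect directions follow the
reported group differences — a high-burstiness lateral DLS-projecting
arm (β = 2.5, Poisson law) against a single-spike medial arm (β = 1,
fixed law); a bursty lNAcc-projecting arm in the mSN; a slower
mNAcc-projecting arm (μ = 0.55 s vs 0.24 s).  Effect sizes are free
parameters of the generator, chosen to give clearly separated but
overlapping groups at the study's sample sizes (9–18 cells per arm,
600 s per cell), and are not claims of fidelity to the real cohorts.

What the generators do **not** emulate: recording noise and spike-sorting
errors (trains are exact); slow drifts in excitability (trains are
stationary by construction unless a step is injected); heavy-tailed ISI
outliers — Gaussian-period single-spike cells essentially never produce
Tukey pauses, so the "longer pauses" aspect of the mNAcc comparison is
not reproduced, only its rate difference; and any correlation structure
between waveform shape and firing pattern beyond the group means.
Passing tests on synthetic cohorts therefore validate the estimators
and the inference machinery, not the biological effect sizes.

## Problem sizes in the checks

The self-validation suite uses 600 s trains throughout (the scale of
real recordings): burst detection is checked exactly against an
exhaustive oracle on 1000 random trains; GLO recovery on a 3 × 3 × 3
parameter grid with 20 simulations each (median period error < 2%,
burst-size error < 10%); stationarity calibration with 500 homogeneous
replicates (type-I 5 ± 2%) and 200 step-change replicates (localisation
within ±10 s in ≥ 90%); LDA calibration on dozens of null cohorts and
50 planted-variable cohorts.  The acceptance script runs reduced-size
versions of the same computations (its `n` fields record the sizes) so a
full from-scratch reproduction stays in the minutes range on one CPU.

## Known limitations

* The GLO fit is an ACH-domain least-squares estimator; it does not use
  spike-level likelihoods and cannot separate s from σ₂ when the train
  is short or the oscillation weak (both then hit their floors/bounds).
* The stationarity null is homogeneous Poisson; for strongly regular
  trains the studentised statistic is slightly conservative.
* The permutation test reuses its scaled-down inner split count for the
  observed statistic when none is supplied, so p-values are consistent
  but coarser than full fidelity.
* `fg_immuno_positive` assumes background statistics are supplied, not
  estimated from the ROI itself.
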