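# Methods

`minf` reimplements, as a tested pipeline, the analysis chain of a
motor-imagery neurofeedback (MI-NF) EEG experiment: two groups of 17
participants each performed kinesthetic motor imagery of a finger-tapping
task over three session blocks, each block consisting of a training run (T)
and two neurofeedback runs (NF1, NF2) of 40 trials (20 per hand). The
neurophysiological outcome is the event-related desynchronization (ERD) of
the sensorimotor mu (8–12 Hz) and beta (13–30 Hz) rhythms, extracted from a
Common-Spatial-Patterns (CSP) projection and compared between runs, blocks
and groups. Because the raw recordings of such studies are rarely deposited,
the package ships a synthetic generator that produces the same data
structure with a *known* ERD, so every stage can be validated by parameter
recovery rather than by eyeballing.

## Synthetic sensorimotor EEG

`minf.simulate` builds a continuous multichannel recording as

    x(t) = A_src · s(t) ⊙ g(t) + M · n(t),

where `s(t)` are four band-limited Gaussian rhythm sources (mu and beta for
a left- and a right-hemisphere sensorimotor source at (∓0.4, 0.05) on a 2-D
cap), `A_src` their Gaussian spatial topographies (spread σ = 0.25),
`n(t)` a bank of 1/f^α noise sources spatially mixed by a random matrix `M`,
and `g(t)` the ERD gain schedule. During each 5-s MI interval the
contralateral source amplitude is scaled by √(1 − d) so that band *power*
drops by exactly `d` (`erd_depth_mu`, `erd_depth_beta`); the ipsilateral
source is scaled by `ipsi_ratio · d`. Gains ramp linearly over 0.25 s at MI
start and end to avoid spectral edge artifacts.

Trial timing follows the emulated protocol: 5-s baseline, 3-s cue, 5-s MI,
inter-trial interval uniform on [0, 4] s; events mark MI onset (time 0 of
every epoch). Hand order is balanced and pseudorandomized with at most three
consecutive same-hand trials (the protocol states only "pseudorandomized";
the run-length cap is this package's reading). Defaults: 64 channels at
500 Hz, 3 blocks × 3 runs × 40 trials, background channel SD ≈ 10 μV,
`erd_depth_mu = 0.4`, `erd_depth_beta = 0.25`, `ipsi_ratio = 0.5`
(ipsilateral ERD about half the contralateral depth, consistent with the
usual lateralization of hand-MI ERD), `snr = 1` (source amplitude at the
topography peak equals the background SD). Depth, SNR and the noise exponent
are free parameters — the emulated study reports no per-band depth — and
are the dials the recovery tests turn.

The electrode layout is a generic equidistant concentric-ring cap, exactly
mirror-symmetric about the midline. Only relative topography matters for
CSP; the symmetry makes the hand-swap invariance testable (swapping all hand
labels is equivalent to relabelling sensors). The innermost 49 channels form
the "central" subset used for CSP, mirroring the original montage's central
channel selection. A 64-channel layout names 6 sensorimotor channels per
hemisphere.

What the generator deliberately does *not* emulate: volume conduction with
realistic head geometry, non-stationary background (drowsiness, alpha
blocking), physiologically detailed EOG/ECG. Blink and EMG artifacts are
threshold-exercising transients (smooth 120 μV frontal bumps; 1–2 s
high-frequency bursts on peripheral channels), sufficient to trip the
rejection rules but not morphologically realistic. Passing tests therefore
demonstrate correctness of the *computations*, not robustness to every
real-world artifact.

## Preprocessing

The offline path mirrors the emulated chain: zero-phase FIR band limitation
(high-pass 8 Hz order 826, low-pass 30 Hz order 220, Hamming windows),
epochs from −7 to 9 s around MI onset (closed-open intervals, windows on the
sample grid), baseline correction over −6 to −4 s. Zero-phase FIR filtering
runs as a single FFT convolution with the filter's autocorrelation after
odd-reflection edge padding — numerically identical (≤ 4 × 10⁻¹⁵) to
forward-backward filtering but much faster for order-826 kernels. The online
(neurofeedback) path uses a causal 4th-order Butterworth 8–30 Hz band-pass;
the original acquisition software exposes a passband-ripple setting with its
Butterworth filter, which a Butterworth design (maximally flat) cannot use,
so the field is carried in `FilterSpec` for provenance but ignored.

Channel QC flags channels whose SD falls outside mean ± 2 SD of the
channel-SD distribution; flagged channels are interpolated from up to six
nearest good neighbours with inverse-distance weights (the layout is a
synthetic 2-D cap, so spherical splines would add nothing) before
common-average referencing. More than 25% bad channels aborts. Trial
rejection implements two rules: the moving-SD rule (flag when a 250-sample
centered moving SD exceeds 2.5× the trial-channel SD — the SD's scope is
per trial and channel, a choice the source protocol leaves open) and an
amplitude criterion (default ±100 μV after band-pass, the conventional
threshold; configurable).

## CSP and the contralateral convention

Class covariances are per-trial trace-normalized, averaged over the 0.5–4.5 s
MI window and shrunk, C ← (1−γ)C + γ·tr(C)/n·I with γ = 0.05. Filters solve
C_L w = λ (C_L + C_R) w; eigenvalues in (0,1) are the left-class variance
fraction. Because MI suppresses the contralateral rhythm, the *left-hand*
filter sits at the low-λ extreme (minimal variance on left-hand trials) and
the right-hand filter at the high end. The original study selected "the most
neurophysiologically plausible" filters by hand; that is automated in two
modes — plain eigenvalue extremes (deterministic, used in tests) and a
scored mode that ranks the three most extreme filters per side by
sensorimotor-cluster energy × spatial smoothness of the pattern. Online, CSP
is fit per run and chained (T calibrates NF1, NF1 calibrates NF2); offline,
one CSP is fit per block over the three runs pooled. Applying a hand's own
filter to that hand's trials gives contralateral activity, the opposite
filter ipsilateral.

## Neurofeedback quantities

Features are log band powers of 1-s bins with 0.9375-s overlap over the MI
(0.5–4.5 s) and baseline (−7 to −3 s) segments — 49 bins each. The 0.0625-s
hop is 31.25 samples at 500 Hz; onsets advance by ⌊i·31.25⌋ samples
(alternating 31/32), so the fractional overlap is realized exactly on
average with integer indexing. Three LDA classifiers (scikit-learn, lsqr
solver with shrinkage 0.05) are trained with 7-fold cross-validation,
stratified by class and *grouped by trial* — overlapping bins of one trial
never straddle folds, a leakage the protocol description leaves open.
Classifier LR separates left- from right-hand MI bins (positive score =
right-hand evidence); BaseL/BaseR separate each hand's MI bins from the same
trials' baseline bins (positive = MI evidence). Each classifier's border is
the 75th percentile (linear interpolation) of its held-out target-class
decision scores; a pooled-score variant is selectable. Ball position is
score/border clipped to [−1, 1] per axis, so left-hand success drives toward
(−1, +1). A caution encoded in the validation suite: fitting CSP outside the
cross-validation loop biases shuffled-label accuracy above chance — the
chance-floor check therefore permutes labels after the (label-independent)
projection.

## ERD

ERD follows the classical power-ratio method: square samples, average across
trials, smooth with a 0.25-s moving average (the source protocol is silent
on smoothing; 0 disables it), then express as percent change against the
mean power R over the −6 to −4 s reference: ERD(t) = (A(t) − R)/R · 100.
Averaging power across trials *before* taking the ratio is load-bearing:
per-trial ratios averaged afterwards weight trials by their reference
fluctuation and differ measurably on heteroscedastic data (asserted in the
tests). Contralateral timecourses of the two hands are averaged pointwise.
Block scalars average the timecourse over the MI window (0.5–4.5 s by
default, matching the feature window; 0–5 s selectable since the source
protocol says only "within the MI interval"); the NF scalar pools NF1+NF2
trials. Baseline power is the mean squared amplitude of the CSP-projected
signal over the reference interval, NF trials pooled — its unit is μV² of
an arbitrarily scaled projection, comparable only within a fitted model.

## Statistics

Paired t (one-sided "training > neurofeedback" on ERD values, i.e. expecting
NF more negative), with d = t/√n and a noncentral-t confidence interval on
d; pooled-variance independent t (df = n₁+n₂−2, not Welch) with d on the
pooled SD and a CI on the mean difference — the two CI conventions match how
the respective published tables report them, verified digit-for-digit.
The mixed repeated-measures ANOVA uses the classical SS decomposition
(between: group, error; within: block, block×group, error); η² divides by
the *total* SS including between-subject variance, which is what reproduces
the small published η² values (partial η² available). Mauchly's W and the
Greenhouse–Geisser ε are computed from the group-mean-centered pooled
within-group covariance projected on orthonormal contrasts; ε-scaled p
accompanies every within term when k > 2 (k = 2 is spherical by
construction). The implementation is cross-checked against pingouin in the
tests, never delegated to it. Holm correction comes in two variants:
standard step-down (with monotonicity enforcement) and a "raw-multiplier"
variant, p·(m − rank + 1) without the monotonicity step, which reproduces
the non-monotone adjusted values printed in the source tables; standard is
the default, and the log flags when the raw-multiplier output is
non-monotone. Shapiro–Wilk and mean-centered Levene checks attach to the
group comparisons.

## Validation scenarios and problem sizes

All simulation-based checks run at desk scale — 16 channels, 20–60 trials
per run, 1–2 blocks, 2–6 subjects per group — since the contracts they
verify (power ratios, eigenstructure, calibration, determinism) do not
depend on the acquisition's full size. Key scenarios:

- **ERD parameter recovery**: depths 0.1–0.4 at high SNR, filter fit on one
  third of trials and ERD measured on the rest (fitting and measuring on the
  same trials lets the filter chase in-sample fluctuations and exaggerates
  ERD by 2–3 points); measured ERD regressed on −100·depth over 20 seeds
  must give slope 1 ± 0.1 and intercept 0 ± 3.
- **Classifier calibration**: the strong-ERD scenario (depth 0.5 both bands,
  SNR 10, 40 trials) yields median CV accuracies ≈ 0.88/0.92/0.93
  (LR/BaseL/BaseR) over 20 seeds; with the default ipsilateral ratio the
  per-bin Bayes limit at depth 0.4 is ≈ 0.78, so depths ≥ 0.5 are what a
  well-separating session looks like in this generator.
- **Test size**: the one-sided paired t at n = 17 holds 5% size within
  ±0.5 points over 10,000 null replicates.
- **Exact oracles**: the diag(4,1)/diag(1,4) CSP toy has eigenvalues
  {0.8, 0.2}; CSP matches an independent dense eigensolver to 10⁻⁶ on ≤ 8
  channels; the k = 2 rmANOVA equals the squared paired t to machine
  precision; identical seeds give byte-identical pipeline outputs.

Published-table reproductions use the embedded summary statistics (group
means, SDs, t values, n = 17) as inputs; per-subject paired differences were
not published, so the paired t statistics themselves are not recomputable —
only their effect sizes and the group comparisons are, and those reproduce
every printed digit.

## Known limitations

Numerical ERD estimates on narrowband signals fluctuate more than intuition
suggests (a 2-s reference from 20 trials of a 4-Hz-wide rhythm has ~10%
power SE), so single-run ERD values carry a few points of Monte-Carlo noise;
the tests average over seeds, hands and bands accordingly. ICA-based
artifact removal and wavelet EMG denoising are out of scope (threshold rules
stand in). The simulation's group difference is zero by default, matching
the emulated study's null result; `group_effect` and `nf_depth_boost`
provide known effects for power studies. Real BrainVision recordings can be
read through MNE, but no claims are made about real-data performance beyond
the correctness of the computations.
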