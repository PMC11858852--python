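# Methods

## The signal model

`equigait` treats straight-line trot as a stride-periodic process observed at
200 Hz. Upper-body vertical displacement of a sound trotting horse is
dominated by a twice-per-stride oscillation: the trunk falls and rises once
per diagonal stance, and the two diagonal stances of a symmetric trot are
interchangeable. Single-limb lameness breaks that interchangeability: the
horse unloads the painful limb, damping the bounce of one half-stride, which
appears in the frequency domain as a once-per-stride (first-harmonic)
component. The simulator makes this mechanism explicit. Each displacement
channel s ∈ {H, W, P} is

    y_s(t) = −A_s·cos(4πf t − π/2) + a_s·sin(2πf t + ψ_s) + ε(t),
    a_s = asymmetry_gain · grade · C[label, s] · A_s,

with ε white Gaussian measurement noise. The fixed phase offsets place the
two displacement minima at the middle of the corresponding reference-limb
stances (RF and LF stance for head/withers, RH and LH stance for the
pelvis), so the left/right half-stride membership of each minimum is
unambiguous even under noise. The sign convention is that a positive
compensation weight C raises the minimum of the *right* limb's stance half;
row signs therefore encode the lame side, and mirroring the label negates
the first-harmonic term exactly.

Limb protraction–retraction angles are θ_l(t) = Θ_l·sin(2πf t + φ_l) with
trot phasing (diagonal limbs in phase, contralateral limbs π apart). The
lame limb's amplitude is reduced by `retraction_deficit_per_grade · grade`,
modeling a propulsion deficit. Stance begins where the angle crosses
mid-range going down and ends at the retraction extremum (most negative
angle); on the sinusoid these events have closed-form times, which the
simulator stores exactly (in seconds) as ground truth.

A two-harmonic model was chosen deliberately: every downstream quantity —
landmarks, asymmetry indices, energy ratio, phase difference — has a closed
form on it, so the entire feature pipeline is checkable against independent
oracles to numerical precision.

## Generator parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `stride_frequency` | 1.4 | Hz | trot cadence |
| `sampling_rate` | 200 | Hz | IMU output rate |
| `n_strides` | 15 | — | strides per trial (a typical straight-line trot-up) |
| `base_amplitude` | H 3.0, W 2.5, P 3.5 | cm | second-harmonic displacement amplitude |
| `asymmetry_gain` | 0.05 | /grade | first-harmonic fraction per grade unit |
| `compensation_matrix` | RF (1, .6, .1); LF mirrored; RH (.4, .2, 1); LH mirrored | — | signed sensor distribution of the asymmetry |
| `retraction_amplitude` | 25 | deg | limb-angle amplitude |
| `retraction_deficit_per_grade` | 0.03 | /grade | lame-limb retraction loss |
| `noise_sd` | 0.05 | cm | displacement measurement noise |
| `angle_noise_sd` | 0.2 | deg | limb-angle measurement noise |
| `amplitude_cv` | 0.10 | — | between-horse amplitude variability (cohorts) |
| `stride_frequency_sd` | 0.08 | Hz | between-horse cadence variability (cohorts) |

The compensation weights encode the clinical sign relations (forelimb
lameness dominates head and withers; hindlimb lameness dominates the pelvis
with ipsilateral head/withers carry-over); their magnitudes are a modeling
choice, configurable, and not a clinical claim. The three variability/noise
parameters beyond the displacement noise (`angle_noise_sd`, `amplitude_cv`,
`stride_frequency_sd`) emulate sensor noise on the angle channels and the
obvious between-horse differences in size and cadence; they were fixed once
at values plausible for clinical trot-ups. Cohort simulation spawns one
independent random stream per horse from the master seed, so any cohort is
reproducible horse-by-horse.

**What the generator does not emulate:** physiological asymmetry of sound
horses, random head tossing, skin-motion artifact and sensor drift, grading
disagreement between observers, multi-limb lameness, circles or soft
surfaces, and between-horse variation in the *compensation pattern* itself.
The last point matters for interpreting results: because every simulated
RF-lame horse shares the same compensation direction, classes are separated
far more cleanly than clinical classes are. Passing tests on synthetic
cohorts therefore demonstrate correctness of the feature definitions and of
the training/validation protocol — not that clinical accuracy would reach
the same level. In particular, a default synthetic cohort often yields *no*
out-of-bag misclassifications at all; when borderline draws do produce
errors, they are fore/hind confusions (shared asymmetry direction, different
sensor distribution) and essentially never lateral ones (opposite signs),
which reproduces the qualitative error structure of clinical reports.

## Stride processing

One stride is one cycle of the designated reference limb (default: right
hind), delimited by successive stance onsets — ground-truth events when
available, otherwise descending mid-range crossings of the reference limb's
angle. Stride frequency is (number of strides)/(elapsed time between first
and last onset). Curves are resampled per stride onto the 0–100 % grid
(101 points — the odd count keeps the 50 % midpoint exact) with a cubic
spline, level-centered (mean removed, discarding slow drift without touching
amplitudes), and averaged pointwise. A stride poorly correlated with the
mean curve (r < 0.5) aborts processing as non-periodic.

Landmarks are read off a band-limited trigonometric interpolant of the mean
curve (FFT of the 100 distinct points, truncated at 10 harmonics by
default — light denoising that is exact for the two-harmonic model), with
each extremum refined by bounded scalar minimization to ~1e-12 in phase.
Requirements and conventions:

* exactly two minima and two maxima per stride (the trot pattern); any other
  count raises an error reporting what was found;
* each minimum/maximum belongs to the half-stride in which the right or left
  reference limb is in stance (fore pair for H and W, hind pair for P),
  using the stance-onset phases measured during segmentation;
* up_X = following local max − min of half X; down_X = preceding local max −
  min of half X; diffTmax_X = half X's local max above the curve's global
  minimum; ROM = global max − global min. The diffTmax definition (altitude
  of each half's maximum over the stride's global minimum) is one of several
  possible readings and is isolated in one function.

Because resampling interpolates, a noise-free symmetric trial does not give
*bitwise* zero asymmetry: the measured floor is ~2e-7 % with cubic
resampling, five to six orders of magnitude below the weakest grade-2
signal (~1 %). Null-property tests assert |AsI| < 1e-5 %.

`displacement_from_acceleration` (drift-removed double integration with
zero-phase 2nd-order Butterworth high-passes, cut-off 0.5 Hz by default) is
optional plumbing for imported raw accelerometer data; the core pipeline
never uses it on synthetic displacement signals, and it recovers amplitudes
only to a few tenths of a percent.

## Features

Five asymmetry indices per upper-body sensor, in two dialects: the
**caption** dialect divides each left-minus-right numerator by the left
side's own amplitude (up/down/diffTmax as appropriate — the only fully
explicit formula set available, hence the default), while the
**ROM-normalized** dialect divides by the stride's range of motion, making
every index exactly antisymmetric under left/right mirroring. Positive
values mean a right-side deficit in both dialects. Every output file records
the dialect used.

ERz and Δφ come from a least-squares fit of
c₀ + c₁cos2πu + s₁sin2πu + c₂cos4πu + s₂sin4πu over the normalized stride;
amplitude_k = √(c_k²+s_k²), phase_k = atan2(s_k, c_k). ERz = 100·A₂²/A₁²
(energy of a harmonic = squared amplitude, reported in percent);
Δφ = phase₁ − phase₂ wrapped into (−180°, 180°], without harmonic-order
rescaling. A perfectly symmetric signal has A₁ = 0 and an unbounded ratio;
ERz is then capped at a configurable ceiling (default 10⁶) and flagged
degenerate. Note a convention consequence: mirroring a trial swaps the
reference limb and therefore shifts the stride start by half a stride, so
Δφ maps to wrap(Δφ + 180°) rather than negating; ERz, ROM and stride
frequency are mirror-invariant.

Retraction asymmetry per limb pair is 100·(left − right)/((left+right)/2),
where each limb's retraction angle is the mean over strides of |θ| at
lift-off (the extremum near each event, refined by local parabolic
interpolation). The symmetric-mean denominator is used because a
contralateral-amplitude denominator is not defined for this feature. In the
27-name feature order the fore pair is listed as `AsI-retraction_W` and the
hind pair as `AsI-retraction_P`, following the reference variable table's
labeling of these rows by body region.

## Classification protocol

* Standardize: per-feature center and unit sample SD (ddof = 1), parameters
  stored and reused; a zero-variance feature raises an error naming it.
* Class weights: w_c = N/(K·n_c) (balanced mode), all 1 (none), or custom.
* SVM: RBF kernel with σ = 0.036 held fixed — this σ is identical to
  scikit-learn's `gamma`, both parameterizing exp(−g‖x−x′‖²) — multiclass by
  one-vs-one voting.
* Cost tuning: bootstrap out-of-bag accuracy over the doubling grid
  0.25…128; each tuning repetition draws one resample and scores *all*
  costs on the same out-of-bag rows (paired comparison, 25 repetitions by
  default); ties resolve to the smallest cost (strongest regularization).
* Validation: 400 repetitions by default; each refits the full pipeline
  (standardize → weights → SVM at the selected cost) on a resample and
  scores the out-of-bag rows; a resample missing a class (or with an empty
  bag) is redrawn and counted. Tuning and validation use independent
  streams spawned from the seed; both are bit-for-bit reproducible.
* Reports: because it is ambiguous whether a published confusion matrix of
  this design is resubstitution or bootstrap-aggregated, `run_pipeline`
  emits both, explicitly labeled (`resubstitution` and `bootstrap_oob`).
* Variable importance: filter importance — per feature and class, the ROC
  AUC of the raw feature separating that class one-vs-rest, folded as
  max(AUC, 1−AUC), then min-max rescaled globally (not per column) to
  0–100, so the matrix always contains a 100 and a 0. A constant feature is
  assigned the scale minimum. This scheme ranks features by marginal
  discrimination; it does not measure joint contribution inside the kernel.

## Problem sizes and numerical choices

The test suite exercises the full default study once (287 horses, 25 tuning
repetitions × 10 costs, 400 validation repetitions) plus a 100-repetition
permutation control, and uses 25-horse cohorts for protocol tests; the
whole suite runs in well under a minute on one core. Chance-level checks
use the band 0.20 ± 3·√(0.2·0.8/287), the sampling error of a chance
classifier on a 287-horse cohort. Oracle-equivalence tests compare against
dense brute-force extremum scans of analytic curves at 1e-9, harmonic
recovery at 1e-6. Seeds below 2³¹ are derived with `numpy.random.
SeedSequence`; identical seeds give byte-identical artifacts.

## Known limitations

* The compensation magnitudes, and hence the relative difficulty of the
  five classes, are modeling choices; synthetic accuracy is near-perfect
  and should not be quoted as an expected clinical accuracy.
* Only single-limb lameness and straight-line trot are modeled.
* The Δφ and ERz conventions (harmonic phase referencing, energy
  definition) follow the definitions above; other conventions exist in the
  kinematics literature and would change the numeric values but not the
  pipeline.
* Trial-level features only: per-stride distributions are averaged away.
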