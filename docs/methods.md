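# Methods

This note documents the models, parameter choices and numerical decisions
behind `ictalkit`, and what the synthetic validation does and does not
establish about real recordings.

## Synthetic EEG model

The generator emulates the statistical structure the analysis assumes in a
4-channel, 250 Hz epidural recording from the left/right anterior/posterior
somatosensory cortices.

**Baseline.** Each channel is independent Gaussian noise with power
spectrum ∝ 1/f^s (default slope s = 1), scaled to a root-mean-square
amplitude of 20 µV. Shaping is done in the frequency domain; a gentle
spectral high-pass below 0.5 Hz emulates the acquisition hardware's DC
rejection and removes the infrared divergence of 1/f noise, without which
window-RMS estimates would drift on the minutes scale. The 1/f form and the
20 µV level are modeling choices — no quantitative description of neonatal
piglet baseline spectra was available — chosen as typical of mammalian
cortical field potentials; the slope is configurable and verified by
periodogram regression (fitted log–log slope within ±0.2 of target over
2–80 Hz).

**Focal bursts** are additive 3 Hz biphasic spike–wave trains (sharp
Gaussian spike followed by a slower negative half-sine per cycle, 5%
amplitude jitter) confined to one channel, with 0.5 s cosine on/off ramps
to avoid edge ringing. The fundamental maps from the requested dominant
band (δ → 3 Hz by default).

**Generalized bursts** are a common source mixed into every channel plus
independent per-channel noise. The source is a 0.8:0.6 variance mixture of
band-limited Gaussian noise (dominant band, default δ) and exact fractional
Gaussian noise at the requested Hurst exponent (default 0.3, i.e.
anti-persistent). The coherence level c maps to a source-to-noise variance
ratio via MSC = (SNR/(1+SNR))², counting the baseline as part of the noise;
when the requested amplitude cannot support the requested coherence the
source takes the whole additive budget and the achieved MSC saturates
below target.

**Amplitude convention.** `amplitude_ratio` r scales the additive burst to
variance (r²−1)·B² so the *total* in-event RMS equals r times the baseline
RMS B. This makes the detector's ratio semantics exact: an event injected
at r = 5 presents an in-window RMS ratio of 5.

**Fractional Gaussian noise** is synthesized by Davies–Harte circulant
embedding, which realizes the exact fGn autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); series length must be a
power of two. The generator is validated against this closed form (3
standard errors over 40 seeds at lags 1–10) before it is used as ground
truth for the Hurst estimator, so the estimator is never tested against
itself.

## Detection

Sliding windows of 2 s with a 1 s hop per channel; a window is flagged when
its RMS is strictly greater than `ratio` (default 3) times that channel's
baseline RMS. Flagged windows separated by gaps ≤ 2 s merge; events shorter
than 2 s are discarded; per-channel events whose intervals overlap with
intersection-over-union ≥ 0.5 fuse into one multi-channel event. The window
and gap defaults resolve the ~3–5 s spike–wave events the classifier
targets while suppressing single-window transients; none of them affect the
threshold location, which the acceptance sweep recovers at 3.000000 ± 1e-6.

The baseline is a designated quiet window (≥ 60 s; the drivers use the
leading 100 s). RMS, spectral entropy and band powers are averaged over
non-overlapping 4 s epochs; coherence and the Hurst exponent are computed
once on the full window because the R/S estimator needs ≥ 1024 samples
(4.1 s at 250 Hz), more than one epoch provides.

## Biomarkers

* **PSD**: Welch, Hann window, 2 s segments, 50% overlap; one-sided
  density. Band powers are trapezoidal integrals over [low, high). The six
  bands deliberately leave a 60–70 Hz gap between slow and fast gamma, so
  the band sum is slightly below total 1–120 Hz power; entropy uses all
  1–120 Hz bins.
* **Spectral entropy**: Shannon entropy (base 2) of the PSD normalized to a
  probability distribution over 1–120 Hz, divided by log₂(bins): 0 for a
  single-bin spectrum, 1 for an exactly flat one.
* **Coherence**: magnitude-squared coherence averaged over 1–120 Hz and
  over all unordered channel pairs. Segment length is 2 s, shrinking to
  n/8 for short windows so at least ~15 overlapped segments are averaged
  (the MSC estimator bias for independent signals is ≈ 1/segments).
* **Hurst**: rescaled-range analysis over logarithmically spaced block
  sizes 16…n/4, with the Anis–Lloyd expected small-sample R/S (Peters
  finite-sample factor); the estimate is 0.5 plus the log–log slope of
  observed over expected R/S. The correction matters: uncorrected R/S is
  biased toward 0.5–0.6 for anti-persistent series at these lengths. Mean
  recovery over 20 seeds at n = 8192 is within ±0.1 at H ∈ {0.3, 0.5, 0.8}.
* **Event windows** shorter than 1024 samples are expanded symmetrically
  (clipped at recording bounds) before feature extraction. Band powers,
  entropy, RMS and Hurst are computed on the event's channels; coherence is
  always computed across *all* recording channels, since cross-channel
  synchrony is the quantity of interest even for single-channel events.

## Classification

Five generalized-favoring criteria, all strict inequalities (a tie with a
reference votes focal, the less severe label): δ/fast-γ ratio > 1.5,
NOT(α/β ratio > 1.2), entropy > baseline mean, coherence > baseline mean,
Hurst < baseline mean. Generalized at ≥ 3 votes.

The α/β criterion is stated as a focal indicator; inside a
generalized-vote tally its *negation* is counted, so that five comparable
generalized-favoring votes exist — otherwise at most four criteria could
ever be "met" and the ≥ 3-of-5 rule would be lopsided. This polarity is a
deliberate, configurable choice (`count_focal_negation`). No
multiple-of-SD margin is applied to the "> baseline" references, as none
is defined for them.

The channel-extent rule is independent of the votes: focal iff the event's
channel set is a singleton. Both calls are always reported; the headline
label defaults to channel extent (the spike–wave convention) and is
switchable per call. Note that a delta-dominant focal spike–wave train
legitimately satisfies the low-frequency vote, so its feature call can be
generalized while its extent call is focal — the two rules measure
different properties of a discharge, and the synthetic archetypes make the
extent rule the ground-truth-aligned one for focal events.

## Burden

Events are binned by onset into half-open 4-h intervals (an onset exactly
on an edge belongs to the later bin). The AUC is the trapezoid of the
count-per-bin curve over bin midpoints: a constant 2 events/bin over
twelve 4-h bins spans 44 h of midpoints and yields 88 events·hours. Mean
duration and onset latency are absent (None), not zero, when no events
exist.

## Puncta quantification

Segmentation is Otsu thresholding plus 8-connected components; per-particle
area and Crofton perimeter are calibrated by the pixel size, and
circularity is 4πA/P² clipped to 1 (discretization can push the raw value
slightly above 1 for small disks). Retention filters use inclusive bounds:
0.05–3 µm² with circularity 0.3–1 for GLAST/synaptophysin; ≥ 1 µm² with no
upper area bound for GFAP. Coverage is 100·Σarea/ROI area; density is
reported per 1000 µm² (a reporting unit choice). Layer I is subdivided
into three equal-depth bands I-1/I-2/I-3 along the laminar axis — equal
thirds by depth, since no anatomical boundary rule is defined for the
sublayers. Particles are assigned to ROIs by centroid membership.

The synthetic image generator places non-overlapping axis-rotated ellipses
(≥ 1 px clearance) with analytically known area and circularity; the
ground-truth table records both the analytic ellipse area (πab) and the
rasterized pixel-count area. On these ideal images segmentation recovers
every particle with pixel-exact area, which validates the measurement
chain but deliberately says nothing about antibody background, overlapping
puncta or out-of-focus light in real confocal fields.

## Regression

Simple linear regression by OLS (statsmodels), reporting slope, intercept,
R² = 1 − SS_res/SS_tot and n per cell of the layer × (predictor, response)
grid; a layer with fewer than 3 usable points contributes no cell (absent,
not zero). Constant predictors are a degenerate-fit error; constant
responses report R² = 0 with a warning. In place of proprietary composite
outlier procedures, an optional flag marks points with |studentized
residual| > 3; flagged points are reported, never removed.

## Problem sizes and limits of the validation

The test suite and acceptance script use 50 seeded recordings of ~6 min
each with 4 archetype events, 20-seed Hurst panels at n = 8192, and
6-animal cohorts — sizes at which every check runs in seconds while the
statistical tolerances stated above are comfortably resolvable. Passing
them establishes that the implementation is faithful to its stated rules
and accurate on data matching its assumptions: stationary 1/f background,
additive bursts, non-overlapping ideal puncta. It does not establish
performance on real neonatal cEEG, which adds artifacts (electrode pops,
movement, drift), non-stationary baselines across temperature phases, and
seizure morphologies beyond the two archetypes; the detector's strict RMS
rule in particular inherits the sensitivity/specificity trade-offs of its
baseline designation on such data.
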