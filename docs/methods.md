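# Methods

`fulm` implements dynamic, super-resolved mapping of stimulus-evoked
cerebral hyperemia (functional hyperemia) from ultrafast contrast-enhanced
ultrasound. This note records the models, the estimators, the numerical
choices and the limits of what the synthetic validation shows.

## Processing model

**Clutter rejection.** Each block of beamformed compound frames
(400 frames at 1 kHz by default) is reshaped into a Casorati matrix
(space × time) and decomposed by SVD without mean-centering; the leading
`n_discard` singular components (10 for contrast blocks, 60 for the
200-frame / 500-Hz Power Doppler blocks) absorb the slowly varying,
spatially coherent tissue signal and are zeroed. Energy is conserved
exactly between the kept and removed subspaces (Parseval over singular
values). A second filter pass cannot reintroduce removed energy, but note
that literal idempotence does not hold on full-rank data — a second pass
removes the *next* `n_discard` components; the removed-subspace property
is what the tests assert.

**Detection and localization.** Microbubble echoes are modelled as
Gaussian spots of σ = 70 µm per axis (FWHM ≈ wavelength × f-number
≈ 165 µm for a ~15-MHz probe). Frames are upsampled by separable
Lanczos-3 interpolation (factor 6, i.e. to pitch/6) and correlated with
the PSF (matched filtering — the optimal detector under white noise, and
position-unbiased for a symmetric spot). Candidates are local maxima
above a robust amplitude floor (median + 5 scaled MAD by default) whose
Pearson correlation with the PSF model exceeds 0.7, restricted to a
vesselness mask (Frangi filter of the temporal-maximum image at scales
{1, 2, 4} pixels, Otsu threshold, dilated by one PSF width; an empty
response warns and passes through). Subpixel positions come from a
least-squares 2D quadratic fit on the 5×5 neighbourhood; the fit falls
back to the integer maximum when the patch is flat, the Hessian is not
negative-definite, or the vertex lands more than one pixel away.
Positions are snapped to the super-resolved grid — coarse pitch / 16,
i.e. 6.875 µm lateral × 6.25 µm axial for the 110 × 100 µm probe grid —
with boundary positions assigned to the higher-index pixel.

Why these choices: a σ = λ/2.355 ≈ 42 µm spot is aliased on a 100-µm
grid (no interpolation recovers subpixel position from it; measured RMSE
≈ 0.24 px even noiseless), whereas the realistic 70-µm echo localizes at
≈ 0.08 px noiseless and ≈ 0.13 px at 20 dB amplitude SNR with the
matched filter. A direct 5×5 vertex fit on the coarse grid is biased
> 0.2 px, which is why the interpolation stage is on by default
(`interp_factor=1` disables it).

**Tracking.** Consecutive-frame detections are paired by minimum total
Euclidean distance (Hungarian assignment with dummy-node padding at the
gate cost); links farther than `max_speed / frame_rate` (100 mm/s →
100 µm at 1 kHz) are forbidden. No gap filling: a missed frame splits the
trajectory. Tracks shorter than 10 successive frames are discarded.
Velocities are finite differences × frame rate (mm/s); the per-step
velocity is attached to the step's first detection and the last detection
repeats the final step. Each track is then rasterized onto the
super-resolved grid by exact gridline-crossing enumeration, so every
pixel crossed — including corner clips — is counted exactly once per
traversal, with a linearly interpolated timestamp; a pixel re-entered in
a later traversal (U-turn) counts again. Track endpoints on a pixel
boundary count in the higher-index pixel (they are actual detections).

**Dynamic maps.** The sliding-window movie M(x, z, t) accumulates
traversal counts (and mean speeds) in centred half-open windows
[t − W/2, t + W/2), W = 5 s, step 1 s by default, giving
Nt = Acq_t / Step_t maps (1400 for 20 patterns of 70 s); windows at the
acquisition edges are truncated, not wrapped. Pattern averaging sums
equivalent phase points across the Nb_pattern repetitions and divides by
W to give a microbubble flux MB_F in MB/s over
Nt_s = Pattern_t / Step_t = 70 phase points; each map then accumulates
W × Nb_pattern = 100 s of data. Because the windows of the first and
last repetition are truncated, a raw sum biases the edge phases low in
every pixel simultaneously — which correlates spuriously with any
mid-pattern stimulus — so MB_F rescales each phase by
n_patterns·W / (effective accumulation time); the raw pattern-summed
counts are kept alongside (`PatternMovie.counts`) and are exactly
conserved against the sliding movie. Pattern speeds are pooled
(count-weighted) means across repetitions, not means of per-repetition
means. A streaming accumulation path produces the pattern movie without
materializing the full (Nz, Nx, Nt) array. Pixels with fewer than five
detections over the whole acquisition are flagged invalid and zero-filled
before activation analysis.

**Drift correction.** Slow positional drift (time scale ≫ cardiac or
respiratory) is estimated by translation-only registration of 10-s count
maps against the first chunk (phase cross-correlation with 1/8-pixel
upsampling, maps lightly smoothed because super-resolved count maps are
sparse) and subtracted from all bubble coordinates of each chunk.

**Activation analysis.** Two estimators on the pattern-averaged movie:

* *Correlation*: per-pixel Pearson correlation between the flux time
  course and the 0/1 stimulation signal A(t); zero-variance pixels map to
  c = 0.
* *SVD*: thin SVD of the (Nz·Nx, Nt_s) Casorati matrix, no
  mean-centering. The stimulus mode maximizes |p_i|, the scalar product
  of the mean-removed, unit-norm A(t) with temporal vector V_i; the pair
  (U, V) is sign-flipped so p > 0. The variation map is
  MB_svd = λ·U·(∫_stim V − ∫_base V) (integrals = sums × Step_t;
  stimulation and baseline windows must have equal duration, defaults
  30–60 s and 0–30 s of the 70-s pattern). The relative map divides by
  the baseline image Σ_{i<i_stim} λ_i U_i ∫_base V_i, masking pixels
  whose denominator is below 10⁻⁹ of the peak; when the stimulus lands
  in the first mode the baseline is undefined and masked with a warning.
  Applied to the raw (non-pattern-summed) movie, the same mode selection
  against the pattern-tiled A(t) yields per-trial variation terms and
  single-trial time courses.

  *Detection* — deciding whether any stimulus-locked mode exists at all
  — cannot rest on a |p| threshold: the overlapping windows make even
  pure shot-noise temporal vectors smooth, and direct simulation of that
  null model (moving-average-windowed white noise) shows max |p_i|
  reaching 0.6–0.8, overlapping every weak real signal. `select_stim_mode`
  therefore keeps only a loose fixed gate (`p_min` = 0.5, flagging
  stimuli essentially orthogonal to the data), and `detect_stim_mode`
  adds the decisive test: the repetitions are split into even and odd
  patterns, each half is analysed independently (best-|p| mode, no
  threshold), and the mode is accepted only when the two halves'
  variation maps — smoothed at the PSF scale (σ = 1.5 super-pixels) so
  incoherent per-pixel loadings average out — correlate with
  ρ ≥ `rho_min` (0.2). Under the null the halves are statistically
  independent and ρ scatters around 0; a stimulus-locked mode reproduces
  across halves. Circular phase shifts of A(t) were evaluated as an
  alternative null calibration and rejected: a 30/70 boxcar correlates
  up to |0.75| with its own shifts, so a genuine signal inflates its own
  threshold.

  The SVD contrast is relative: because the stimulus mode is orthogonal
  to the baseline mode, unmodulated vessels acquire a *negative* loading
  in MB_svd of a globally normalized magnitude — the map localizes
  activation but its zero level is not absolute.

**Vessel quantification.** The vasculature is binarized by Frangi
vesselness + Otsu on the rest-period count map. Compartments: pial
pixels come from a seed mask (manual in practice); remaining vessel
pixels split on mean vertical flow — descending (Vz > 0.5 mm/s,
z grows downward) are penetrating arterioles, ascending venules, the
rest intraparenchymal. Where arterioles and venules overlap, arteriolar
statistics count only downward-flowing bubbles and venular only upward.
Profiles sample an 80-µm flow-normal segment (flow angle from the
two-argument arctangent of (Vx, Vz)); transversal profiles average over
a 50-µm slice centred on the middle of the maximal-count run (plateau
ties would otherwise bias the centre), and the 80-µm window bounds the
measurable vessel width to ≈ 70 µm. The diameter is the width at half
the REST profile maximum for both conditions — amplitude scaling leaves
the rest diameter unchanged; crossings are interpolated linearly, exact
on rectangular profiles and matching the 2.355 σ FWHM closed form on
Gaussian ones within a super-pixel. Longitudinal metrics are smoothed
along depth (200-µm boxcar; diameters median-filtered against
bifurcation outliers; skeleton spurs shorter than 10 super-pixels are
pruned). The perfusion/drainage area is the number of distinct pixels
touched by tracks passing a seed segment × pixel area (set semantics:
monotone, order-invariant). Rest/stim statistics use the two-sided
Wilcoxon signed-rank test on relative variations (paired variant across
depths); spatial resolution is checked by Welch t-tests between the
velocity populations of adjacent super-resolved pixels.

## Synthetic phantom

The generator emulates a coronal plane under continuous contrast
injection: vessel segments (centreline polyline, radius, baseline speed,
baseline arrival rate, compartment, activated flag) through which
bubbles advect. The stimulation protocol is 30 s rest / 30 s stimulation
/ 10 s rest repeated 20 times (1400 s) unless stated. Functional
hyperemia is a trapezoid response (2-s linear rise/fall — the observed
responses are plateau-like, and the trapezoid keeps the closed-form mean
rate exact since its integral per pattern equals the stimulus duration):
arrivals are an inhomogeneous Poisson process at
rate × (1 + (flux_gain − 1)·m(t)) realised by thinning; speeds scale by
the instantaneous 1 + (speed_gain − 1)·m(t); the lateral offset is
uniform within radius × diameter modulation and frozen at arrival so the
per-track speed stays exact (a Poiseuille profile is available behind a
flag). Bubbles are sampled on the global frame clock. The renderer adds
a Gaussian echo per bubble, rank-r tissue clutter (fixed smooth random
spatial patterns × slow sinusoidal weights), white noise, and optional
linear drift plus a cardiac-like axial oscillation; it is intended for
block-scale durations — rendering a full 1400-s acquisition at 1 kHz is
a beamforming-scale job, so the full-acquisition pipeline path feeds
ground-truth tracks directly into tracking-level containers and the
frame path (render → filter → localize → track) is validated end-to-end
on short acquisitions.

Study conditions used by the validation suite (chosen once, from the
regimes the method addresses): six activated plus two control vessels,
each at a 0.4 MB/s baseline arrival rate with flux gain 1.5, for flux
recovery (0.4 MB/s is the reported small-vessel baseline flux; pooling
six independent arrival streams brings the Poisson error of the
recovered rate ratio from ~13 % to ~5 %); a bed of eight thin
5-µm-radius, 0.4 MB/s capillaries at
flux gain 1.2 between 2 MB/s feeders for the repetition-dependence
study — an activated *region*, since a single one-pixel-wide vessel has
too little spatial support for a stable singular mode and its detection
flips with the noise realization; a 17.2-µm-radius arteriole with
diameter gain 1.2 for the diameter study (the 80-µm profile window
bounds measurable diameters to ≈ 70 µm); twenty 10-µm, 0.3 MB/s vessels
with all gains at 1 for null calibration. Simulations run at 500 Hz on
a 12 × 12-coarse-pixel field (192 × 192 super-resolved); these
desk-scale sizes keep the suite in minutes while leaving hundreds of
bubbles per condition. In this regime the weak-activation transition
completes at 12–15 repetitions with detection probability ≈ 2/3 per
realization, so the repetition property is validated as a seed-ensemble
contrast rather than per-realization booleans.

What the phantom does *not* emulate: speckle statistics and realistic
tissue texture, transcranial aberration, bubble-size or amplitude
dispersion, overlapping echoes closer than the PSF, vessel curvature and
branching hierarchies, pulsatile flow. Passing tests therefore show that
the estimators are correct under their own model assumptions, not that
detection performance on animal data matches the reported retention
statistics.

## Numerical choices and degenerate inputs

* Fixed seeds make every stage bit-reproducible; all randomness flows
  from one seed per run.
* Assignment ties are resolved deterministically by the solver; tied
  |p_i| (within 1e-12) pick the smaller mode index with a warning.
* Empty vesselness responses pass through with a warning rather than
  silently dropping all detections; registration with no overlap returns
  zero shift with a warning; empty compartments and all-zero Wilcoxon
  differences are rejected or reported as undefined rather than guessed.
* Spatial comparisons of activation maps against ground truth are made
  after Gaussian smoothing at σ = 1.5 super-pixels (≈ 10 µm, the PSF
  scale): single-pixel flux estimates hold ~10 counts per phase point,
  so per-pixel correlations are shot-noise-limited (~0.4) for any
  estimator.

## Known limitations

* The SVD relative-increase map is undefined where the baseline image is
  zero, and the whole baseline normalization is undefined when the
  stimulus occupies the first mode (reported, not guessed).
* Compartment labelling is purely morphometric/flow-based, as in the
  underlying method; pial arteries and veins are not discriminated.
* The tracker is nearest-neighbour with a hard gate: crossing vessels
  with similar speeds can swap identities; counts are unaffected but
  Lagrangian analyses (perfusion areas) can merge territories.
* Diameters below ~2 super-pixels and above ~70 µm are outside the
  profile estimator's validity.
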