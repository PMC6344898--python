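# Methods

This note documents the models, estimators and numerical choices behind
`oligoquant`, and what the synthetic-data generators do and do not emulate.

## Photon-count calibration

Hybrid detectors in photon-counting mode return discrete counts whose
expectation is linear in fluorophore concentration. Calibration fits an
affine model `counts = slope · c + intercept` by ordinary least squares to a
dilution series (defaults mirror the 0.1–1 µM standards used for the
gymnosis measurements). The fit is affine rather than through the origin:
cellular images carry detector and ambient background even when the
standards are blank-corrected, and the intercept doubles as the background
estimate. Inversion clamps negative concentrations to zero — the clamp count
is reported, never hidden — and flags pixels above the calibrated range as
extrapolated. Accumulated acquisitions (10–15 frames summed to collect
photons from dim structures) are reduced to a per-frame mean before
calibration so the count scale matches the standards.

## Segmentation

Nuclei: three-class Otsu thresholding on the DAPI histogram, implemented as
an exhaustive O(L²) search over ordered pairs of observed grey levels for
the pair minimizing the weighted within-class variance. The middle class is
assigned to background — the rule presumes a genuine three-mode histogram
(background, dim cytosol, bright nuclei); on a two-mode image the upper
threshold falls inside the nuclear mode and erodes the mask, which is why
the synthetic DAPI channel includes a dim cytosolic level. Touching nuclei
are split by watershed on the Gaussian-smoothed distance transform
(σ = 2 px) seeded at h-maxima (h = 2): the h-maxima suppression prevents
shallow plateaus from over-seeding, and the watershed lines play the role of
the dividing lines drawn by shape in the original CellProfiler pipeline,
whose exact settings are not published. Objects outside the 20–150 px
equivalent-diameter gate are discarded (equivalent diameter = diameter of
the circle of equal area; the gate's reference notion of "object diameter"
is not defined more precisely than this). Nuclei touching the image border
are retained by default (`exclude_border` flips this).

Vesicles: bright puncta are detected on the concentration map by a
scale-normalized Laplacian-of-Gaussian response maximized over scales
spanning the expected diameter range, thresholded at `sensitivity` × the
robust spread (1.4826 × MAD) of the response over the cellular area, split
at response peaks by watershed, and finally refined to the bright core
(pixels ≥ 0.8 × the object's background-subtracted maximum). The core
refinement matters quantitatively: the mean over a blurred spot's full
above-threshold support underestimates the plateau concentration by ~25 %,
whereas the 0.8-core recovers it to within ~10 %. The DC level is subtracted
(median) before filtering, which makes offset invariance exact. Nuclear ROIs
for the gymnosis analysis are accepted as external masks, mirroring the
original manually drawn nuclei; the synthetic pipeline uses the generator's
ground-truth nucleus labels in that role.

Intensities are reported as a percentage of the maximal grey value (255 for
8-bit, 4095 for 12-bit) for intensity images, or as plain molar means for
concentration maps.

## Single-cell knockdown

Injected cells are those whose nuclear tracer intensity exceeds a threshold.
The threshold is an explicit analysis input (originally chosen manually from
the tracer/target scatter plot); an automatic suggestion maximizes the
two-class between-class variance over cuts of the sorted per-cell tracer
values and places the threshold mid-gap between the classes — the mid-gap
placement matters because the criterion is flat across a wide separating
region and an edge placement misclassifies under noise. Knockdown is
summarized as mean ± SEM of target intensity per group and the
injected/non-injected ratio; a ratio below 0.5 is >50 % knockdown. The
baseline is the non-injected cells of the same field (per-field baseline;
configurable upstream by pooling records).

## FRAP

Model: `F(t) = a (1 − e^{−t/τ}) + c` on post-bleach frames with t = 0 at the
first post-bleach frame (the single bleach frame is excluded). Derived
quantities: `t½ = τ ln 2`, `D = 0.88 r²/(4 t½)` with the 0.88 prefactor
applied verbatim (its uniform-disk assumption is not re-derived here), and
on prebleach-normalized traces the immobile fraction
`1 − (plateau − F₀)/(1 − F₀)`, plateau = a + c, F₀ = c, clamped to [0, 1]
with clamping reported.

Preprocessing is the classic double normalization
`[(ROI1−ROI3)/(ROI2−ROI3)] · [mean_pre(ROI2−ROI3)/mean_pre(ROI1−ROI3)]`.
By default the background is replaced by its mean and the reference by a
fitted exponential decay before division: both reductions are exact for a
flat background and exponential acquisition bleaching, and they avoid
injecting the reference ROI's frame noise multiplicatively into the
recovery (without this the recovered immobile fraction is biased low by
~0.02–0.03 at SNR 10). Plateau-mode normalization divides by the fitted
asymptote (not a last-frames average). Fits are unweighted least squares —
after normalization the frame noise is approximately homoscedastic — with
the initialization c₀ = first post-bleach value, a₀ = last − c₀, τ₀ = time
to reach the 1 − 1/e level, and restarts over a τ grid on non-convergence.

The generator produces the three ROI traces on the published acquisition
grid (10 prebleach + 70 recovery frames at 97 ms; 2 µm bleach radius in the
nucleus, 5 µm in solution mode). Noise is Gaussian with SD specified at the
prebleach level and scaled with the square root of each sample's expected
signal (shot-noise scaling). Solution-mode recovery (τ ≈ 74 ms) is nearly
complete within one frame interval, so the recovered solution D rests on the
first post-bleach points and is intrinsically noisy; the two-orders-of-
magnitude contrast against nuclear diffusion survives comfortably.

## FCS

Estimators: a multi-tau cascade (m = 16 lags per level, factor-2 binning,
symmetric normalization — each lag's product normalized by the means of its
own head and tail segments) and a direct brute-force estimator evaluating
the definition at every integer lag, used as the oracle in tests. The two
agree exactly at level-0 lags and to within 1 % wherever G is resolved;
beyond the correlation time they differ by their respective sampling noise.

Fit model: `G(τ) = N⁻¹ (1 + τ/τ_D)⁻¹ (1 + T/(1−T) e^{−τ/τ_T})` — the
standard 2D free-diffusion form with a multiplicative triplet factor, τ_T
fixed at 4 µs, T bounded to [0, 0.5]. The first lag is excluded (shot
noise); weights are inverse-variance when replicate spreads are supplied,
else unweighted. The effective volume closing the 2D-model/3D-volume gap is
`V_eff = π^{3/2} w₀³ κ` with a configurable aspect ratio κ (default 5) and
`w₀ = √(4 D_ref τ_D,ref)` from a reference dye of known D; a direct mode
(`V_eff = N_ref/(c_ref N_A)`) is also provided. Concentration is
`c = N/(V_eff N_A)`.

The simulator propagates point emitters by 2D Brownian steps in a periodic
box (default side 8 w₀) and emits Poisson counts with per-bin mean
`brightness · Σᵢ e^{−2rᵢ²/w₀²}`. Three numerical choices deserve note:

1. **Grand-canonical correction.** A closed box with fixed particle number
   has no q = 0 concentration-fluctuation mode; its absence suppresses the
   ACF amplitude and truncates the tail (τ_D biased −18 % even at a 16 w₀
   box). The missing mode is restored by modulating the aggregate intensity
   with an Ornstein–Uhlenbeck factor of relative variance 1/n_particles.
   Its correlation time must sit far above the fit window (so the restored
   mode is flat there) yet far below the trace duration (so the running
   means used in ACF normalization average over it — a slow mode inflicts a
   constant negative bias ≈ 2θ/(T·n) on Ĝ otherwise); the default is
   min(0.3 s, max(0.1 s, 1000 τ_D)). With this correction the analytic
   closed-box ACF fitted by the standard model recovers N and τ_D to
   <0.2 %.
2. **Dynamics stride.** Discrete Brownian sampling is exact at lags that are
   multiples of the propagation step, so positions are advanced on a step of
   up to τ_D/10 (at most 10 emission bins) and held within it; fits use lags
   above twice the step. The step SD is checked against box/10.
3. **Triplet blinking.** With τ_T = 4 µs far below the 10 µs emission bin a
   per-particle telegraph is unresolvable; the dark state is applied at bin
   resolution as equilibrium thinning by (1 − T) plus variance-matched
   occupancy noise (Var f̄ = 2T(1−T)τ_c/Δ, τ_c = τ_T(1−T)), which is
   uncorrelated between bins and therefore visible only at the excluded
   zero-lag region — exactly as in the real measurement at this binning.

Study-scale conditions (`oligoquant.replication`): N = 10, τ_D = 1 ms
(w₀ = 0.25 µm), T = 0.2, 30 s traces at 10 µs bins, 100 replicates; the
reference dye (D = 400 µm²/s, the faster of the two calibration dyes) is
recorded on three 20 s spots at 4 µs bins, with the median fitted τ_D used
for the volume (w₀ errors enter V_eff cubed). Recovered medians land within ~1 % (N) and
~4 % (τ_D) of truth; the concentration round trip through the calibrated
volume is within ~10 % (w₀ errors enter cubed).

## Copy-number budgets

`copies = c · V · N_A` with N_A fixed at the 2019 SI exact value. Default
volumes: cell 2000 fl, nucleus 1180 fl, vesicle 1.014 fl; 52 vesicles per
cell. Headline values are rounded to two significant figures, and the
per-cell endosomal total chains the rounded per-vesicle count
(12 000 × 52 → 620 000) because only round-then-multiply reproduces the
published chain; exact values are always carried alongside. The injected
volume can be derived either from the measured dilution ratio
(0.079 × 2000 fl = 158 fl) or from the concentration ratio
(114/1000 × 2000 fl = 228 fl); both bracket the published "roughly 200 fl"
and neither is privileged.

## What the generators do and do not emulate

The scene generator renders elliptical nuclei, nearest-distance cytosolic
rims, and Gaussian-blurred vesicle disks with Poisson photon statistics at a
configurable gain — sufficient ground truth for calibration, segmentation,
classification and budget arithmetic. It does not model realistic optics
(PSF beyond Gaussian blur), 3D stacks, detector afterpulsing, chromatic
shifts, autofluorescence textures, or cell-to-cell expression variability
beyond the injected/non-injected dichotomy. The vesicle "volume" used in
budgets is the published scalar (1.014 fl), not rendered geometry. Passing
tests therefore demonstrate correctness of the estimators under the stated
noise models, not robustness to every artifact of real microscopy. The
tracer-channel noise model for injected cells is not constrained by the
original description and is exposed as generator parameters (gain,
background) rather than fixed.

## Problem sizes

The replication runners use 200 FRAP traces, 50 + 50 solution/nucleus
traces, 100 FCS traces of 30 s plus three 20 s reference spots, 20
segmentation fields of 30 nuclei, and 3 doses × 100 cells — sizes chosen to
match the study's reported scales while keeping a full reproduction run in
the ten-minute range on one CPU.
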