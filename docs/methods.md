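# Methods

This note records the models behind `htpaint`, the parameters that matter,
the design decisions taken where the workflow left them open, and what the
synthetic-data generator does and does not emulate.

## PAINT simulator (`htpaint.sim`)

**Binding kinetics.** Exchangeable-ligand PAINT is modeled as an M/G/∞
queue on a fixed set of binding sites: new binding events start as a
Poisson process in time (rate = target active count / mean dwell), dwell
times are geometric in frames (discrete memoryless kinetics, the standard
PAINT assumption), and the initial state is drawn from the stationary
distribution, so the expected number of simultaneously active emitters is
constant over the whole acquisition — the defining property of a
replenishing, non-bleaching label. There is deliberately no photobleaching
or dark-state term. Binding sites can be revisited by later events
(exchangeable ligands re-bind the same protein tag).

Default kinetic parameters (no published dwell times or photon budgets
exist for these probes, so these are one-time, order-of-magnitude choices,
not fits): mean on-time 3 frames; 2,000 detected-photon-equivalents per
frame per emitter; uniform background 10 photons/px. Densities follow the
acquisition profiles: 0.109 emitters/µm²/frame for ground-truth imaging,
1.3 for high-density imaging.

**Structures.** Filaments are smooth random-walk curves (vimentin-like),
tubules add a hollow circular cross-section (mitochondria-like), networks
connect random nodes to nearest neighbors (ER-like). Binding sites sit at
fixed arc-length spacing (default 10 nm), at arc positions (k+½)·spacing so
an exact subdivision yields exactly length/spacing sites.

**Camera.** The EMCCD chain per pixel is
Poisson(photons × QE) → Gamma(shape = electrons, scale = EM gain) →
Gaussian read noise → ÷ sensitivity + baseline → clip/quantize to uint16.
Defaults: 157 nm pixels, EM gain 50, preamp 1, QE 0.9, read noise 60 e⁻,
sensitivity 12 e⁻/ADU, baseline 100 ADU. The mean chain response is
photons × QE × gain / sensitivity ADU above baseline, which the
photon-conversion inverse uses.

**What the simulator does not emulate:** 3-D PSFs and astigmatism,
sCMOS-style pixel-dependent noise, triplet/dark-state photophysics, sample
autofluorescence structure, optical aberrations, and axial drift. Tests
passing on this generator therefore demonstrate the correctness and
internal consistency of the computational chain under the stated model, not
performance on real microscope data.

## Localization chain (`htpaint.locfit`)

Spot candidates are local maxima whose net gradient (image gradients
projected toward the candidate over a box, default 7 px) exceeds a
threshold; the threshold is data-scale dependent and exposed as
configuration. Candidate ROIs are fitted by damped Fisher scoring of the
Poisson likelihood of a pixel-integrated 2-D Gaussian with free position,
amplitude, background and per-axis widths; all ROIs are iterated as one
vectorized batch. Localization precision uses the Mortensen MLE formula
with σ_a² = σ² + 1/12 px² and an EMCCD excess-noise factor of 2.

NeNA precision fits the distribution of nearest-neighbor distances between
consecutive-frame localizations with the 2-D correlated-pair density
(d/2σ²)·exp(−d²/4σ²) plus a linear background term. Linking merges
transitive chains within a radius (default 4×NeNA) and a maximum dark time
of 5 frames, using photon-weighted mean positions and inverse-variance
combined precisions (the merge statistic is not standardized anywhere;
photon weighting approximates information weighting). Filtering defaults:
sx, sy ∈ [0.6, 2.0] px, lpx, lpy ≤ 0.3 px.

RCC drift correction renders temporal segments (default 200 frames) at 4×
oversampling, measures all pairwise segment shifts by upsampled phase
correlation, solves the over-determined pairwise system by least squares
and interpolates per frame. Raw-frame drift correction (applied to
high-density stacks before prediction) registers each frame against the
stack mean by phase correlation with mean subtraction.

## Training data (`htpaint.densitydata`)

High-density training patches are sums of k randomly selected (with
replacement) low-density patches; emitter lists concatenate, so counts and
photons are conserved exactly and the mean density multiplies by exactly k.
k = 12 is chosen so 12 × 0.109 ≈ 1.3 emitters/µm² reproduces the
high-density imaging condition. Patches are cut at 17 px and center-cropped
to 16 px at training time. Labels are the *fitted* positions (with their
errors) when built from measured-style data; simulator truth is available
for oracle tests. Background matching applies an additive offset so the
patch median matches the reference high-density (median, MAD); an optional
MAD rescaling exists but is off by default (the offset is the only
mechanism the workflow requires).

## Density-map network (`htpaint.deepdense`)

Architecture: the input frame is bilinearly resized to the upsampled grid
(×16 fixed-cell, ×8 live-cell), then passes 3 encoder blocks (3×3 conv →
batch-norm → ReLU → 2×2 max-pool) and 3 mirrored decoder blocks (2×
nearest-neighbor upsample → conv → BN → ReLU), a final 1×1 convolution and
a **softplus** output. Softplus rather than ReLU keeps the output
nonnegative *with a nonvanishing gradient*: a ReLU head freezes over the
large exact-zero background regions of sparse density maps at
initialization. The network is fully convolutional, so patch-trained
weights predict whole frames. Layers are implemented directly on numpy
arrays (channels-last) with numba kernels for the 3×3 convolutions.

Loss: MSE between Gaussian-blurred prediction and blurred spike map of the
true emitter positions, plus an L1 sparsity penalty on the raw map
(weight 10⁻²). Spikes have amplitude 10; the loss blur is σ = 2 upsampled
px (≈ 0.25 camera px). Both were set once, by overfit probes during
development: amplitude ~10 keeps target peaks within reach of the small
head in few optimization steps, and σ = 2 smooths the objective enough for
the short schedules below to make progress (σ = 1 left training stuck near
the background-only solution).

Two training profiles exist. The *fidelity* profile mirrors the published
workflow: 30,000 patches, batch 256, 100 epochs, 15 % validation split,
initial learning rate 10⁻⁵, upsampling 16 (fixed) / 8 (live). The *desk*
profile is the package's minutes-scale setting used by the evaluation
scripts: 2,000 patches, 20 epochs, upsampling 8, widths (4, 8, 16), batch
16, learning rate 10⁻². The desk batch size and rate are deliberately
aggressive: at fixed patch count and epochs, smaller batches buy more Adam
steps for the same arithmetic, which this small network needs to move past
a flat "structure segmentation" solution it otherwise settles into.
Plateau-based learning-rate reduction (×0.5 after 10 stale epochs, floored
at 1 % of the initial rate) handles the tail.

Prediction standardizes inputs with the stored training mean/std and is
deterministic given the weights. Localization extraction finds *strict*
3×3 local maxima (the center must exceed all eight neighbors — saturated
plateaus of exactly equal values, which a flat network response can
produce, must not emit one localization per pixel), thresholds them, and
computes intensity-weighted centroids over a 3×3 neighborhood (local
averaging); map coordinates convert to camera pixels by division by the
upsampling factor. The threshold is calibrated by bisection so that the
total extracted count matches a reference (ground-truth localizations
scaled by the frame-count ratio, or the known emitter total in
simulations) within ±2 %; counts are non-increasing in the threshold, which
bisection exploits.

## Image quality (`htpaint.imqual`)

The published comparison protocol is followed: 2-px Gaussian blur, min-max
8-bit conversion, optional Otsu + closing structure mask (used for
mitochondria-like data), then PCC, SSIM (11×11 Gaussian window, σ 1.5,
standard constants, dynamic range 255), MS-SSIM (canonical 5-scale weights,
2× average-pool between scales), MAE and PSNR. A perceptual-network metric
is intentionally absent (it would require pretrained third-party weights).

Decorrelation resolution follows the standard algorithm: edge-apodized
image, Fourier transform I and phase-normalized In = I/|I|, correlation
d(r) between I and In masked to |k| < r over 50 radii, repeated for 10
Gaussian high-pass pre-filters; the cutoff is the highest local-maximum
frequency over all curves (the last radius counts when a curve still rises
at Nyquist — the white-noise case), and resolution = 2·pixel/cutoff. In the
end-to-end comparison, resolution is computed on the *float* renders (with
a 1-px render blur), not on the 8-bit preprocessed pair: min-max
quantization injects a flat spectral floor that decorrelation reads as
pixel-scale information, which made an upsampled widefield image appear to
have 39 nm "resolution". The 8-bit pair remains the input to the
similarity metrics, as in the published protocol.

## Live-cell movies (`htpaint.livemovie`)

Windows are [i·step, i·step + window) with window 400 and step 20 by
default; 20 × 50 ms reproduces the 1 s temporal spacing of the published
live-cell video (the workflow's two descriptions — "20 frame overlap"
vs "step size of 20" — conflict; the step reading is adopted because only
it yields the stated 1 s spacing). Each window renders at 8× upsampling,
is clipped at its own 99th percentile, normalized to [0, 1], mean-filtered
(3×3; the size is unstated anywhere, 3×3 is the minimal choice) and
smoothed with a 1.5-px Gaussian. Frames are stitched at 30 fps; when no
MP4 encoder is available the stitcher falls back to a numbered PNG
sequence, with a JSON sidecar carrying the window plan and timestamps
either way.

## Evaluation profile sizes

The desk-scale evaluation (tests and `scripts/acceptance.py`) uses a 48-px
(7.5 µm) field, 5,000 ground-truth frames, 1,000 high-density frames,
2,000 training patches and the desk training profile; drift recovery uses
2,000 frames and fitter efficiency 500 spots. These sizes are the package's
own minutes-scale operating point; the fidelity profile above remains
available for full-scale runs.

## Known limitations

- The desk-profile network is small; its per-frame maps are coarser than a
  fully trained DeepSTORM and its advantage is demonstrated relative to the
  widefield baseline, not to the published full-scale models.
- The MLE fitter is 2-D only and single-emitter; overlapping emitters
  closer than ~5σ are the density-map network's job by design.
- The simulator's noise and kinetics are idealized (see above); none of the
  reported numbers are claims about real microscope data.
- MS-SSIM on small images uses as many of the 5 scales as the image side
  supports, renormalizing the weights.
- On desk-profile prediction maps the distribution of local-maximum
  amplitudes can contain large atoms of bit-identical float32 values (the
  small network saturates over feature-dead regions). Threshold calibration
  then cannot split inside an atom, so the extracted count may deviate from
  the reference by more than the bisection tolerance on such maps; on
  well-separated synthetic maps (and on sharper, fidelity-profile maps) the
  calibrated count matches the reference within the stated 2 %.
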