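# Methods

`pamnet` reconstructs maps of continuous-wave acoustic emission sources
(cavitating microbubbles, in the motivating application) received on a
planar 16×16 matrix array, both with the classical time exposure acoustics
(TEA) beamformer and with a 3D convolutional network trained to emulate it
from raw channel data. Everything below is simulation-based; the package
generates its own data.

## Forward model

Sources are monochromatic point emitters of strength `u·ds` in water
(c = 1500 m/s, ρ = 1000 kg/m³, α = 4.32×10⁻⁴ Np/m). With the complex
wavenumber k = ω/c − jα, the received pressure phasor at distance R is

    p = j k ρ c / (2π) · e^(−jkR) / R · (u·ds),

the single-source form of the Rayleigh–Sommerfeld integral. Receiver
elements are square faces one wavelength across (pitch = element size),
subdivided into a uniform grid of point-like sub-elements (≥ ppwl points
per wavelength per axis, default ppwl = 4); the element signal is the
arithmetic mean over its sub-elements, which keeps units independent of the
subdivision density. Channel data are the real part of the steady-state
phasor rotating at ω, sampled at 40 MHz for 140 µs (5600 samples).
Emission is modeled as eternal CW: absolute onset is irrelevant to a
20 µs integration window, and propagation delay enters through the
e^(−jkR) phase.

A companion particle-velocity expression with a (1 − jkR) bracket is
provided for completeness exactly as it is used in this model family; note
that the classical near-field factor is (1 − j/(kR)). The velocity plays no
role downstream.

Three preset acquisitions pair source frequency with geometry:
256 kHz / 5.8 mm pitch / 6 cm, 612 kHz / 2.48 mm / 4 cm (the default
throughout), and 1 MHz / 1.5 mm / 2 cm. The reconstruction cube is
10×10×10 mm³ at 0.25 mm voxel pitch (41³ voxel centers), centered on the
array axis.

### Noise

Each element draws a target SNR from Normal(−4, 0.3·|−4|) dB — the 0.3
spread emulating receiver-to-receiver sensitivity variation — and white
Gaussian noise is added at the power implied by that element's own signal
power. SNR is defined on the raw broadband record, before filtering.
Profiles are redrawn per frame, so no element has a fixed sensitivity
across a dataset.

## TEA beamforming

Per voxel r, channels are scaled, delayed by the water time of flight, and
summed; the intensity is the integral of the squared beam sum over a 20 µs
window:

    I(r) = ∫₀ᵀ [ Σᵢ wᵢ pᵢ(t + |Rᵢ|/c) ]² dt,   wᵢ = |Rᵢ| (or 1),

discretized as a Riemann sum over round(T·fs) samples with linear
interpolation of fractional sample delays (nearest-sample lookup is kept as
an option for brute-force cross-checks). Trimmed records carry a
`start_time` offset which the beamformer subtracts, making beamforming with
relative delays on trimmed data exactly equal to absolute-delay beamforming
on raw data.

**Distance weighting and the axial ridge.** For a narrowband CW source and
a planar array, the axial point spread function is much longer than the
10 mm cube: the on-axis intensity profile varies by only a few percent
across the full depth range. The unweighted beam sum has a strict maximum
at the true source (all channel phasors align there and the triangle
inequality is otherwise strict), so its argmax localizes single sources to
the voxel level. The |R| weighting, by contrast, up-weights far voxels and
tilts this nearly flat ridge outward by a few voxels — a property of the
weighted functional, not an implementation artifact (the package's tests
verify the vectorized beamformer against an independent closed-form phasor
computation and a brute-force triple loop). Ground-truth volumes default to
the weighted form, which is the standard TEA scaling; beamformer
localization validation uses the unweighted flag, where the
argmax-at-source guarantee actually holds. On the validation geometry the
axial ridge curvature is ~0.1% per voxel, so this check runs at the full
40 MHz rate (the ~0.7% amplitude error of linear interpolation at 8 MHz
would dominate the ridge) and with an integration window of exactly three
carrier periods (a window covering a fractional number of periods leaves a
residual of the 2ω term in the squared beam sum, bounded by 1/(2ωT) — 2.6%
for 5 µs at 612 kHz — which is voxel-phase-dependent and also tips the
ridge). Even so, the guarantee is exact only at the continuous source
position: for sources in the outermost ~1 mm axial shell of the cube the
CW axial peak is flatter than the voxel pitch and asymmetric, and the
*grid* argmax can land two voxels away. An exact continuum phasor
computation reproduces this displacement, and it is insensitive to
sampling rate, interpolation order, and receiver face averaging; with
uniform source placement it affects roughly 4% of single-source frames.
Voxel-exact argmax localization on this grid is therefore a ~96% property
of the physics, not a beamformer defect.

## Conditioning

Channel data are band-pass filtered with a sixth-order Butterworth
(prototype order 6, i.e. `scipy.signal.butter(6, ...)`) centered on the
source frequency with 300 kHz half-bandwidth; for the 256 kHz preset the
lower edge is clamped to 10 kHz. Filtering is a single causal pass applied
identically to all 256 channels; the common group delay cancels in the
relative delays used on trimmed records. Records are trimmed to
[floor(fs·min delay), ceil(fs·(max delay + T))] over all voxel–element
pairs. Network inputs are z-scored per whole frame (jointly over channels,
preserving the inter-channel amplitude ratios that encode spherical
spreading) and fitted to the configured input length by tail zero-padding
or cropping. The network input length is a configuration constant: the
trimmed length for the 612 kHz geometry is ≈1360 samples while the
full-size architecture is defined for 1521, so the trimmed record is
zero-padded up to it. Targets are sqrt(intensity), max-normalized to [0, 1]
(pressure-like units, flattening the dynamic range so side lobes carry
loss weight).

## Reconstruction network

The full-size network maps (1521, 16, 16) single-channel RF to a (41, 41, 41)
volume through 21 convolutional layers in 150,317 trainable parameters:
an opening 9³ convolution, six dense blocks interleaved with five stride-2
time-downsampling convolutions (1521→761→381→191→96→48), one transposed
6³ convolution upsampling 16→48 laterally (stride (1,3,3)), and two final
valid-padded convolutions (5³, 4³) bringing every axis to 41. A dense block
is conv(9,3,3)→BN→(+x)→ReLU→conv(9,3,3)→BN→(+x)→ReLU with channel-
preserving additive skips; dilation (1, 2, 4, 4, 4, 4 across the six
blocks) applies to the time axis. ReLU follows every layer except the
output. A single-filter 1×1×1 projection collapses the 8 channels of the
last tabulated layer to the scalar volume; it is part of the output head
(counted in the parameter budget, not among the 21 convolutional layers).
Outputs are divided by their per-volume maximum, matching the target
scaling. All bare kernel sizes are cubic 3D kernels with TensorFlow-style
`same` padding; this is the unique reading (enumerated over kernel
dimensionality, transpose extent, bias placement, normalization placement
and output head) that reproduces the 150,317-parameter budget, which
adjudicates all residual architecture ambiguity.

The layers are implemented directly in numpy with explicit
backpropagation: stride-1 `same` convolutions with odd effective kernels
(and stride-1 transposed convolutions) are evaluated spectrally on a
zero-padded linear-convolution grid, everything else through slabbed
im2col (forward) and a kernel-tap loop with strided views (backward).
The spectral and direct paths are cross-validated against each other and
against finite differences in the test suite.

### Loss

Training minimizes w_s·(1 − SSIM) + w_l·L1 with w_s : w_l = 0.84 : 0.16
(weights renormalized to sum to one, so (0, 1) degenerates to pure L1).
SSIM uses a 3D Gaussian window, size 11 voxels, σ = 1.5 voxels. Local
moments are computed by normalized zero-padded Gaussian filtering — the
raw zero-padded correlation divided by the local window mass — so border
voxels see a renormalized window and constant volumes have exact means
everywhere (the constant-volume closed form holds to machine precision).
Stabilizers are the conventional C1 = (0.01·D)², C2 = (0.03·D)² with data
range D = 1. The per-voxel SSIM map is averaged over all voxels; its
analytic gradient with respect to the prediction (propagated through the
normalized filtering operator, whose adjoint is correlation of the
mass-normalized co-gradient) is verified against finite differences.

### Optimization

Adam, learning rate 3×10⁻⁴, L2 penalty 10⁻³ added to the gradients of
convolution weights (biases and batch-norm parameters excluded), batch
size 5, 300 epochs, splits 2000/25/500 — the full-scale configuration.
Batch-norm running statistics (momentum 0.9) are used in evaluation mode.
The best-validation parameter state is restored after training when a
validation set is supplied; training aborts on a non-finite loss.

## Evaluation

Per-frame: SSIM; PSNR = 20·log10(I_max/√MSE) (identical volumes report
+∞); NRMSE = √MSE/(I_max − I_min); peak sidelobe ratio (highest intensity
outside the main-lobe component over the global peak); image SNR (peak
over the standard deviation of voxels more than one wavelength from the
main-lobe peak); localization error (distance between argmax voxels, ties
broken at the lowest linear index with a warning); and −3 dB main-lobe
radii along the two lateral (short) axes and the axial (long) axis, with
linear sub-voxel interpolation of the threshold crossing. Source counting
thresholds intensity at max·10^(−3/10) ≈ 0.501·max — the −3 dB cut is
applied on intensity, since the beamformed volumes are intensities — and
labels 26-connected components; the main lobe is the component containing
the global maximum. Aggregates: exact two-sided sign tests on paired
metrics (zeros excluded) and one-vs-rest confusion rates (TPR/FPR/TNR/FNR)
per source count 1–5.

## Desk-scale profile

Full-scale training (2000 frames, 41³ targets, 300 epochs) is far beyond a
single-CPU session, so the package defines a desk profile used by its test
suite: 612 kHz geometry, 21³ grid (0.5 mm pitch), 8 MHz sampling, 50 µs
records, 5 µs integration, input length 168, and a width-reduced network
(15 convolutional layers: channels 2–8, time-only kernels in the
downsampling stages, a (1,8,8) stride-1 transposed convolution realizing
the 16→21 lateral upsampling, two refinement dense blocks at 21³). The desk training run uses 64 training frames, 8 single-source
validation frames, 30 epochs, and learning rate 3×10⁻³, selected by a
small rate sweep on the desk problem — the same procedure the full-scale
configuration prescribes for its optimized rate. At this scale the
composite loss reliably halves the training loss within 30 epochs and
lifts single-source validation SSIM by well over 0.3 from the untrained
model, and a pure-L1 configuration ends with visibly lower validation SSIM
— reproducing, qualitatively, the loss-ablation observation that L1 alone
trains poorly on these sparse, peaked targets.

What desk-scale passing does **not** show: full-scale reconstruction
quality (single-source SSIM ≈ 0.98, PSNR ≈ 39 dB), full-scale confusion
rates (single-source TPR 0.97), sub-millimeter median localization, or any
inference-speed claims. Those require the full 2000-frame GPU-scale
training; the pipeline can emit the corresponding report tables, and the
desk checks stand in for them at this scale.

## Synthetic data: what it emulates, and what not

The generator reproduces the study conditions: 1–5 equal-amplitude CW
sources uniform in the cube, per-element SNR draws, Butterworth
conditioning, TEA targets. It does not model broadband or transient bubble
signatures, inter-source amplitude variation, nonlinear propagation,
aberration, or element directivity beyond face averaging — so passing
tests demonstrate correctness of the pipeline on its own model family, not
performance on experimental cavitation data.

## Numerical choices and degenerate inputs

Float32 network arithmetic with float64 losses/metrics; FFT sizes padded
to `scipy.fft.next_fast_len`; TF-style asymmetric `same` padding (extra
sample trailing); transposed-convolution outputs center-cropped with the
extra sample removed from the trailing side. Zero-variance records,
all-zero volumes, flat reference volumes, empty backgrounds and
mixed-frequency source lists raise errors rather than returning silently;
all-nonpositive network outputs skip max normalization with a warning.
Per-frame seeds derive from the global seed through
`numpy.random.SeedSequence(entropy, spawn_key=(frame,))`, so any frame is
reproducible in isolation.
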