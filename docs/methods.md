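# Methods

## Signal model and phantom

The synthetic head phantom is a piece-wise-regional 3D model: each region
(gray and white matter, CSF ventricles, bilateral caudate, putamen,
globus pallidus and thalamus, and a posterior venous sinus modelled as a
cylinder) carries Gaussian-distributed tissue properties — susceptibility
χ (ppm, self-referenced: air = 0), proton density M0 (GM-normalized) and
T2\* (ms, samples clipped at 1 ms). Defaults sit inside the ranges
reported for healthy adult brain at 3 T (e.g. GP 0.18 ± 0.02 ppm /
T2\* 35 ms; vein 0.45 ± 0.03 ppm / 20 ms; WM −0.03 ppm / 55 ms); a
user-supplied tissue table and an external label volume (e.g. a resampled
anatomical head model) are both accepted, so any published parameter set
can be dropped in.

The total field is the k-space dipole convolution
ΔB_tot = B0·10⁻⁶·FT⁻¹[D(k)·FT(χ)], D(k) = 1/3 − (k·b̂)²/|k|², D(0) = 0,
with DC at the FFT-grid corner and per-axis frequencies scaled by the
reciprocal voxel size. The ground-truth *local* field uses the
reference-scan decomposition: the field re-simulated from the source
distribution restricted to the brain mask with the mask-mean χ removed;
the background field is the remainder, so total = background + local
holds exactly by construction.

Complex data at echo time TE are
S = M0·e^(−TE·R2\*)·e^(i(γΔB_tot·TE + φ0)) with γ = 2π·42.577478518 MHz/T,
five echoes at 3.0/8.4/13.8/19.2/24.6 ms, and independent zero-mean
Gaussian noise of SD 0.07 added to the real and imaginary channels,
regenerated at every echo and repeat. One master seed spawns
deterministic sub-streams for property sampling and for each
(echo, repeat) noise draw, so repeats share ground truth bit-exactly and
differ only in noise — emulating back-to-back scans of one subject.

What the phantom does *not* emulate: flow, χ anisotropy and
microstructure, parallel-imaging (SENSE) spatial noise correlation, and
coil combination. Passing tests therefore demonstrate correctness of the
processing and noise theory on piece-wise-smooth, voxel-wise-independent-
noise data, not robustness to those in-vivo effects.

## Laplacian operators, unwrapping and SHARP

All Laplacian operations use the 7-point stencil (center −6, face
neighbours +1, scaled by the squared voxel size), FFT-diagonalized with
periodic boundaries, so forward and inverse operators are exactly
consistent outside the truncation set. The Laplacian of a *wrapped* phase
is computed through cos φ·∇²(sin φ) − sin φ·∇²(cos φ), which for this
stencil equals Σ_n sin(φ_n − φ) and is insensitive to 2π wraps; its
accuracy degrades with the cube of the per-voxel phase increment, which
is why steep-gradient regions (vein rims) lose content — a real and
intended property of Laplacian-based processing.

Spatial unwrapping inverts the Laplacian with a relative truncation
threshold of 10⁻¹⁰ (effectively only the DC term); the output is set to
zero mean over the mask, since the constant is unobservable.

SHARP applies the same forward operator, restricts the result to the
mask eroded by 5 voxels (3×3×3 cube structuring element applied
iteratively), and deconvolves by truncated inversion. The truncation
threshold (default 0.05) is compared **absolutely** against the
normalized kernel δ − face-neighbour-mean (k-space values O(1),
≈ |k|²h²/6 at low k). This makes the truncation a fixed low-k cutoff of
≈ 0.55 rad/voxel regardless of grid size, which attenuates structures by
their size *in voxels*: a 4-voxel-radius sphere keeps ≈ 47 % of its
interior mean contrast, a 8-voxel sphere almost none. The alternative
convention (threshold relative to the stencil's k-space maximum of 12)
was rejected after measurement: it widens the cutoff ~1.4× and drives
the recovered contrast of the calibration sphere negative, breaking the
correction step entirely. Because background fields are smooth and
low-k, harmonic exterior-source fields are suppressed below 2 % RMS at
either setting.

## Inversion, L-curve and shrinkage correction

The field-to-χ step is closed-form Tikhonov deconvolution
χ = FT⁻¹[D/(D²+α)·FT(ΔB_loc/B0·10⁶)] on the eroded mask, with α chosen
at the maximum-curvature corner of the log-log L-curve (residual norm
vs solution norm over a 30-point grid in [10⁻⁴, 1]). Curvature is
estimated by the Menger (circumcircle) curvature of consecutive
triplets, which locates an exact corner exactly and needs no smoothing
parameter; a degenerate (non-monotone) curve falls back to the grid
midpoint with a warning.

Tikhonov regularization shrinks χ systematically. The correction factor
is calibrated per (grid, α): the noiseless reference-scan local field of
a 1-ppm sphere of 4-voxel radius (the scale of veins and small nuclei)
is inverted at α and the reciprocal of the recovered/true interior
contrast is recorded. The factor (≈ 1.1 at α = 10⁻³, ≈ 3.4 at α = 0.15)
corrects only the inversion stage; size- and shape-dependent attenuation
introduced earlier by the SHARP truncation deliberately remains in the
maps — correcting it per-structure would require knowing the answer, and
residual underestimation is the expected behaviour of this class of
pipeline. The factor is recorded in every output and never applied
implicitly elsewhere.

## Pipelines

All four pipelines share mask, SHARP parameters and inversion settings
and report χ on the SHARP-eroded mask only; regional statistics
intersect ROIs with that mask so all comparisons share support.

* **nlfit** — voxel-wise Gauss–Newton minimization of
  Σ_i |S_i − M_i e^(i(φ0+γΔB·TE_i))|² over (ΔB, φ0), initialized from a
  magnitude²-weighted linear fit of the temporally unwrapped phase
  (≤ 30 iterations, relative-update stop at 10⁻⁶; voxels outside the
  mask are not fitted — background noise has a multimodal likelihood and
  stalls the iteration). The fitted field is passed to SHARP as phase at
  the echo-spacing time, so residual 2π ambiguities from temporal
  unwrapping stay wrapped and are resolved spatially.
* **te-wavg** — per-echo Laplacian unwrapping, then
  ΔB = Σφ_i/(γΣTE_j); φ0 is *not* estimated and biases this estimator by
  n·φ0/(γΣTE) when present.
* **snr-wavg** — per-echo SHARP, R2\* from a bounded (0–2000 s⁻¹)
  vectorized Gauss–Newton monoexponential fit initialized by log-linear
  OLS, then the TE·e^(−TE·R2\*)-weighted average of the background-free
  phase.
* **susc-wavg** — per-echo SHARP and per-echo inversion (one L-curve on
  the middle echo; α shared across echoes), then the M²TE²-weighted χ
  average. Per-echo χ maps from an external tool can be substituted
  (`external_chi`), which is also the hook for iterative single-step
  methods that this package intentionally does not reimplement.

## Noise theory

Per-echo phase noise follows the reciprocal SNR law σ(φ) = c·σ(M)/M with
c ≡ 1 for simulated data; for repeated-scan data, ROI noise is estimated
by the two-scan difference method with the √(R/2) convention (R the net
SENSE factor), which reduces to the textbook difference method at R = 1,
and c(TE) is then estimated from the ROI statistics.

Combined-field noise: the fitted field has the weighted-least-squares
slope-with-intercept variance σ(ΔB) = (1/γ)√(S0/(S0S2−S1²)),
S_p = ΣTE^p/σ²φ — the intercept (φ0) estimation is included because the
fit estimates it. TE- and SNR-weighted averaging have the plain
first-order propagation of their combination formulas (uncorrelated
echoes). All three match 10⁴-draw Monte-Carlo within ~1–3 %. A direct
consequence worth stating: with only five echoes, co-estimating φ0 costs
the fit roughly a factor 1.8 in field-noise SD relative to TE-weighted
averaging, for any realistic σφ(TE) profile — the fit buys accuracy
(no φ0 bias, no Laplacian-unwrapping losses), not raw field precision.

Susceptibility noise: the Tikhonov inversion is linear with impulse
response h = FT⁻¹[D/(D²+α)]; for voxel-wise independent field noise the
variance map propagates as var(χ) = h² ∗ var(ΔB_loc), evaluated in
k-space, scaled by the correction factor, with tiny negative round-trip
values clipped before the root. (A pointwise k-space multiplication of
the variance map by the squared *kernel* would predict σχ ≡ 0 for
uniform input noise and is therefore not what "filtering the variance"
can mean; the h²-convolution form reproduces the Parseval value
σ·√(ΣD̃⁻²/N) exactly and matches 200-repeat full-pipeline Monte-Carlo
within 2–6 %.) Where a pipeline's local-field noise is unknown, the
worst case σ(ΔB_loc) = σ(ΔB_tot) is used. For the χ-averaging pipeline,
first-order propagation covers both the per-echo χ noise (weights² ×
per-echo σχ from the single-echo field noise σφ/(γTE)) and the magnitude
dependence of the weights, with ∂χ/∂M_i = (2M_iTE_i²/Q)(χ_i − χ̄)
evaluated analytically and verified against numerical differentiation.

## Problem sizes and numerical choices

The shipped study runs at 96³ voxels (1 mm isotropic) with six simulated
subjects; noise validation uses a 48³ phantom with 200 Monte-Carlo
repeats and 10⁴ single-voxel draws. L-curve α and the correction factor
are determined on the first subject per pipeline and reused across
subjects of the same protocol. Six subjects is the minimum for which a
two-tailed exact sign test can reach p < 0.05 (p = 2·2⁻⁶ ≈ 0.031 when
all differences agree in sign).

Degenerate inputs are defined throughout: zero-magnitude voxels yield
zero field/offset with NaN residual (fit) or +∞ phase noise; all-zero
weights yield 0 with a flag; erosion to an empty mask raises naming the
radius; a sign test with all-zero differences reports no difference.

## Known limitations

* The SHARP truncation loss is structure-size dependent and uncorrected;
  absolute regional χ values are systematically low (by design, matching
  the behaviour of this pipeline family), so comparisons should be made
  between pipelines or against a matched forward simulation, not against
  literature χ values directly.
* The analytic σχ maps inherit the worst-case σ(ΔB_loc) = σ(ΔB_tot)
  assumption for the fit- and TE-weighted pipelines; SHARP's (small)
  noise reshaping near the mask boundary is not modelled, so line
  profiles should be read in the mask interior.
* The noise model is spatially white; SENSE g-factor structure is
  collapsed into a scalar R.
* Gauss–Newton fits are not protected against the (rare) pathological
  voxel where the complex-fit likelihood is multimodal inside the mask;
  such voxels surface in the residual map rather than being silently
  repaired.
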