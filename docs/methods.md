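# Methods

## The measurement problem

Transparent specimens (etched glass charts, polymer beads, living cells)
modulate the phase of transmitted light but barely its amplitude.
Phase-shifting digital holography recovers that phase quantitatively by
interfering the object wave with a reference wave at several known
reference-phase offsets.  Acquiring the shifted holograms sequentially fails
for moving objects, so the instrument modeled here splits the recombined
beams by polarization onto four cameras that record all four phase steps in
a single exposure: reference-phase offsets 0 (CCD1), π/2 (CCD3), π (CCD2)
and 3π/2 (CCD4).

`quadholo` implements both directions of this experiment in software: a
forward model that generates the four holograms a given phase object would
produce, and the inverse pipeline that turns four recorded holograms back
into phase and thickness maps.

## Forward model

The optical train is a Mach–Zehnder interferometer built from a 45°
linear polarizer and quarter-wave plate in each arm, a polarizing
beamsplitter (PBS) that recombines the arms, and a 45° quarter-wave plate +
second PBS on each output port.  Fields are propagated by 2×2 Jones calculus
(`quadholo.jones`).  The element matrices follow the unnormalized
convention of the system derivation — polarizer `[[1,1],[1,1]]`, PBS
transmit/reflect `½[[1,0],[0,0]]` / `½[[0,0],[0,−1]]` with the half-wave-loss
sign on reflection — because only relative scales between arms matter for
interference and the arctangent retrieval is a ratio.

Two normalization details in `propagate_system` deserve a note.  The raw
45° fast-axis QWP matrix `[[1,−i],[−i,1]]` multiplies 45°-polarized light by
the scalar (1−i); physically this plate leaves that polarization state
unchanged (the unitary-normalized element contributes only a global phase),
so the compensating scalar 1/(1−i) is carried explicitly.  The final PBS is
applied without the ½ amplitude prefactor, which belongs to the single
arm-recombination split, not to each output port.  With these two choices
the chain lands exactly on the closed form

    I_CCD1 = ¼[α²A_O² + A_R² + 2αA_O A_R cos Δφ]
    I_CCD2 = ¼[α²A_O² + A_R² − 2αA_O A_R cos Δφ]
    I_CCD3 = ¼[α²A_O² + A_R² + 2αA_O A_R sin Δφ]
    I_CCD4 = ¼[α²A_O² + A_R² − 2αA_O A_R sin Δφ]

where α·e^{iφ} is the sample's complex transmission and Δφ includes a
global arm offset (φ_o − φ_r).  `closed_form_intensities` evaluates these
expressions directly and the two routes agree to machine precision — the
test suite uses them as mutual oracles, so a bug would have to appear
identically in two independent derivations to go unnoticed.

Diffraction is modeled (optionally) as a hard circular coherent-transfer-
function cutoff at spatial frequency NA/λ applied to the complex field;
the theoretical two-point resolution is γ = λ/(2NA) = 1.064 µm for the
default hardware (λ = 532 nm, NA = 0.25, 10× objective, 3.45 µm camera
pixels → 0.345 µm object-plane sampling).

## Camera realism

The derivation above is noise-free; `corrupt` adds what four real cameras
contribute:

* **Geometry.** Each of CCD2–4 views the field through its own rigid-plus-
  scale transform (translation in pixels, rotation, isotropic scale) applied
  after intensity formation, mirroring four physically distinct cameras.
* **Noise.** Intensities scale to expected photoelectron counts
  (`photon_scale`, default 2048 ≈ half scale of a 12-bit ADC at unit
  intensity), are Poisson-sampled, perturbed by Gaussian read noise
  (default σ = 2 counts), quantized and clipped at saturation.  All noise is
  driven by one seed, so runs are exactly reproducible.

The defaults describe a well-exposed machine-vision CCD; they are the
conditions under which the recovery tests below are run.

## Synthetic samples

Both generators produce pure phase objects (α ≡ 1) with ground-truth phase
and thickness maps that satisfy φ = (2π/λ)(n_s − n_m)·t pointwise.

* **USAF 1951 phase chart** — three-bar elements plus a square pad at the
  standard geometry, line width w(g,e) = 500/2^{g+(e−1)/6} µm, bars w × 5w on
  a 2w pitch, etched to a uniform height on glass (n_s = 1.52 in air).
  Edges are anti-aliased by exact pixel-area fraction so that sub-nanometre
  step-height recovery is not dominated by stair-step artifacts; binary
  edges are available behind a flag for oracle tests.  Element rectangles
  are recorded so measurements can place regions of interest automatically.
* **PMMA beads** — spheres (default 10 µm, n_s = 1.49) in immersion oil
  (n_m = 1.51), with projected thickness t(ρ) = 2√((d/2)² − ρ²).  Because
  n_s < n_m the phase is negative; measurement code reports magnitudes.
  A sequence generator displaces a bead along +y (downward; beads sink)
  at a chosen velocity and frame rate.  The velocity is a free parameter —
  nothing in the modeled system constrains it.

What these generators do **not** emulate: laser speckle and spatial beam
non-uniformity, optical aberrations, defocus of a moving bead, Brownian
motion, extinction-ratio leakage of the polarizers, or inter-camera gain
mismatch beyond what registration and calibration absorb.  Passing the
recovery tests therefore demonstrates the correctness and noise behavior of
the reconstruction chain, not robustness to every artifact a physical bench
produces.

## Reconstruction pipeline

1. **Registration** (`register_channels`).  The four channels record the
   same structure at different points of the fringe cosine, so corresponding
   pixels are related by a *nonlinear but functional* intensity mapping
   (for a two-level object, exactly a curve).  Mean-squared difference and
   cross-correlation are systematically biased (~0.1 px) at feature edges
   under such mappings; the similarity metric used is therefore the
   correlation ratio — the fraction of the moving image's variance explained
   by conditioning on the binned fixed-image intensity — which is invariant
   to any functional mapping.  Optimization is a 3-level multi-resolution
   pyramid with a phase-correlation translation seed (computed on gradient-
   magnitude images, which are contrast-sign invariant) and Powell
   refinement.  Inside the metric the moving image is warped with cubic
   splines and both images are pre-blurred by σ = 0.75 px: bilinear
   resampling smooths most at half-pixel offsets and imprints an
   integer-locking ripple on variance-based metrics.  Transform classes:
   translation, rigid, or rigid + isotropic scale ("affine"); estimated
   transforms are serializable and reused across acquisitions — the cameras
   do not move, so the system needs registration once.  Noise-free recovery
   accuracy is ≲0.1 px and ≲0.01° at 512×512.
2. **Wrapped phase** (`wrapped_phase`).  Δφ = atan2(I₃ − I₄, I₁ − I₂),
   four-quadrant so the full 2π range is recovered (the plain arctangent of
   the ratio would lose the quadrant).  Pixels with no fringe modulation in
   either quadrature (below 10⁻³ of the set's peak modulation) are zeroed
   and flagged in a validity mask.
3. **Calibration subtraction** (`subtract_calibration`).  An empty-field
   acquisition through the identical optics is reconstructed the same way
   and subtracted modulo 2π, removing the arm offset and any system phase
   common to both acquisitions.  Subtraction happens on wrapped maps,
   before unwrapping.
4. **Unwrapping** (`unwrap_phase`).  Unweighted minimum-L2-norm
   (least-squares) unwrapping: the discrete Poisson equation with the
   divergence of the wrapped gradients as source, Neumann boundaries,
   solved by a type-2 DCT.  For residue-free inputs the solution equals the
   truth up to a constant; the residue count is reported as a quality
   metric.  The free constant is pinned by the median wrapped difference
   from the input, keeping the output congruent with the measurement.
5. **Thickness** (`phase_to_thickness`).  Δh = λ·|Δφ| / (2π·|n_s − n_m|).
   Magnitudes are reported: the sign of the index contrast flips the
   measured phase, not the physical height.

## Measurements

* `step_height`: mean thickness over a feature rectangle minus a substrate
  rectangle; rectangles default to the inner 60 % of each feature so edge
  anti-aliasing and interpolation stay outside the average.  `repeat_stats`
  summarizes repeated estimates (mean is the reported value).
* `resolvable`: a profile across a three-bar element resolves the bars if
  three local maxima exist with mean dip-to-peak modulation ≥ 0.2 (the
  threshold is configurable; any fixed value gives the same resolvable /
  unresolvable ordering because modulation falls monotonically with bar
  frequency).
* `bead_peak_phase`: the apex is located on a lightly smoothed copy of the
  map, then estimated by a least-squares paraboloid fit to the raw map
  around that location — unbiased for a smooth dome, noise-averaging, and
  free of the upward bias of a raw windowed maximum and the downward bias
  of smoothing the apex itself.

## Numerical scales used in the validation suite

Recovery tests run at 512×512 with the default noise model, per-channel
misalignments of a few pixels and a fraction of a degree, over five seeds:
the 213.8 nm chart step is recovered within ±5 nm and the 10 µm bead peak
thickness within ±0.1 µm.  Machine-precision identities (Jones chain vs
closed form, arctangent round trip, ramp unwrapping) run at 24²–224².
Registration recovery is verified at 512×512 against injected transforms of
up to 5 px and 1°, to 0.2 px and 0.05°.

## Known limitations

* Misalignment and registration cover rigid + isotropic scale, not shear or
  lens distortion.
* The pupil is an ideal hard cutoff; no apodization or aberrations.
* Least-squares unwrapping is unweighted; in heavy noise it underestimates
  steep slopes (weighted or quality-guided variants are out of scope).
* The calibration acquisition is assumed to share the exact arm offset with
  the sample acquisition (no drift between exposures).
* Bead sequences translate a constant-shape bead; defocus during motion is
  not modeled.
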