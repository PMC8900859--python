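# Methods

This note documents the models, conventions and numerical choices behind
`scatmap`, what the synthetic generators do and do not emulate, and the
limitations a user should keep in mind.

## Scattering geometry

Each detector is modeled as flat and perpendicular to the incident beam
(normal incidence). A pixel at fractional position (row, col) with beam
center (r₀, c₀), pixel pitch *p* (mm) and sample–detector distance *L*
(mm) maps to

    r  = p · ‖(row, col) − (r₀, c₀)‖
    2θ = atan(r / L)
    q  = (4π/λ) · sin θ            [Å⁻¹]
    φ  = atan2(−(row − r₀), col − c₀)   [degrees, (−180, 180]]

φ = 0 points along +columns and increases counter-clockwise when the
image is displayed with row 0 at the top; φ at the beam center is 0 by
convention. The inverse (q → ring radius) is exact and rejects q that
would require 2θ ≥ 90°. Beam centers may lie off the detector — the
normal situation for wide-angle modules mounted beside the direct beam.

Detector tilt, solid-angle and polarization corrections are **not**
applied; tilt is out of scope for this version, and the latter two are
deliberately omitted from the default reduction (a flag slot is reserved
in the reduction configuration, default off). For the ~3 m small-angle
geometry these corrections are well below the per-bin counting noise;
for wide angles they are a recognized limitation.

### Binning conventions

Bin edges are half-open [lo, hi) with the last bin closed, matching the
histogram convention. The (q, φ) map stores the **mean** count of the
contributing pixels per bin (so maps from different exposures are
directly comparable) together with the contributing pixel count, which
preserves sufficiency: totals, count-weighted averages over φ, and
Poisson errors (√(total counts)/n) are all recoverable. The azimuthal
average weights φ bins by their pixel counts and therefore equals the
plain per-pixel mean — the unit tests pin this against a brute-force
per-pixel loop at 1e−10.

## Calibration from powder rings

The calibrant model is a lamellar powder with rings at q_n = 2πn/d;
the silver behenate long period d = 58.380 Å is the built-in default
(configurable). The refinement estimates (L, r₀, c₀) given λ:

1. radial intensity histogram (1 px bins) around the initial center;
   peaks = local maxima above median + 5×MAD, with parabolic sub-bin
   refinement; no peak → calibration failure carrying the detection
   diagnostics;
2. detected peak radii are matched to predicted rings allowing a global
   distance rescale (initial guesses up to ±20 % in L and ±50 px in
   center are tolerated);
3. iterate: intensity-weighted radial centroids of the ring in 36
   azimuthal sectors → linearized least squares for (L, Δrow, Δcol)
   with a soft-L1 loss. The radial window starts wide (50 px) and then
   tracks 4× the measured ring width — a window narrower than the ring
   would anchor the centroid to the current estimate and stall
   convergence. Sectors whose annulus is clipped by a detector edge or
   module gap are discarded (their centroids are biased by several px).

On synthetic calibrant frames over 20 randomized geometries the
recovered distance is within 0.1 % and the center within 0.2 px; the
residual systematic is the slight skew of a Gaussian-in-q ring when
expressed in radius, ≲0.05 %.

## Merging, background, features

* **Inter-detector scale**: median of I_saxs/I_waxs over the overlap
  window (WAXS linearly interpolated onto SAXS bins), robust against
  gap artifacts. Default window = central 80 % of the mutual overlap.
  The merged grid keeps SAXS bins below the window, the count-weighted
  average of both inside, scaled WAXS above.
* **Background**: profiles are normalized by the transmitted monitor
  (the background's brightness tracks the beam that actually traverses
  the sample), subtracted, and rescaled by the sample monitor so the
  output stays on the sample's exposure scale; errors add in
  quadrature. Incident-monitor normalization is available by flag.
* **Smoothing**: rolling median, default width 11 bins, shrinking at
  the edges — removes narrow mineral diffraction spikes while
  attenuating a broad (σ ≈ 10 bins) peak by <1 %.
* **Features**: trapezoidal band integrals over [q_min, q_max] with NaN
  bins skipped and endpoints interpolated; peak areas over
  q_center ± halfwidth with either a linear baseline (straight line
  between the window endpoints — used for the sharp 1.58 Å⁻¹ cellulose
  (200) reflection) or no baseline (the smooth 2.27 Å⁻¹ amorphous
  band). Both baseline choices are linear functionals of the profile,
  which is what qualifies them for tomography. Which baseline was used
  is recorded in the sinogram metadata; the choice for the crystalline
  peak is genuinely open, and both modes are provided.

Gap filling in (q, φ) first mirrors Friedel pairs (φ ± 180°) when the
pattern is declared centrosymmetric, then interpolates linearly along φ
with wrap-around; rows with no support stay NaN. Filled-in bins keep
`counts_per_bin = 0` as a synthetic-data marker so downstream code can
exclude them; the operation is idempotent and never touches measured
bins.

## Raster maps and the on-axis camera

Scan bundles live in one HDF5 file per scan
(`/scan/positions/{x,y}`, `/scan/detectors/<name>/{data,mask}` with the
geometry serialized as a group attribute, `/scan/monitors/{incident,
transmitted}`, root attributes `scan_shape` and `snake`, optional
`/truth`). Snake scans record positions truthfully in acquisition
order; map assembly unscrambles rows, so point order is irrelevant given
correct metadata. A failed per-point reduction produces a NaN cell and
a warning, never an abort.

The camera calibration locates a straight edge as the sub-pixel peak
(parabolic fit) of the gradient magnitude projected along the edge;
scale = |motor step|/|pixel shift| per axis, with the sign mapping image
axes to motor axes. Tiling pastes images at `round(position/mm_per_px)`
with last-writer-wins overlap (no blending or feature registration —
out of scope), recording the canvas offset so that mosaic pixel → motor
conversion is exactly invertible; round trips are pixel-quantized and
therefore accurate to one pixel equivalent.

## Tomography

Attributes entering a sinogram must be linear in the voxel
contributions along the beam path; this is enforced by an explicit
`is_linear` declaration on the attribute callable, and ratio attributes
are constructed as non-linear so that `build_sinogram` rejects them.
The crystallinity-index map is the voxelwise ratio of the reconstructed
crystalline-peak tomogram over the amorphous-band tomogram, restricted
to the support where the denominator exceeds 5 % of its maximum
(default). Absorption uses −ln(transmitted/incident), the line integral
of the attenuation coefficient.

Rotation invariance of scattering attributes is the **user's**
responsibility (valid for randomly oriented structure or a fiber axis
parallel to the rotation axis); the code checks only a weak proxy and
warns when per-projection totals vary by more than 20 %.

Reconstruction is parallel-beam filtered backprojection:

* NaN samples are interpolated along the translation axis first;
* the Ram-Lak filter is built as the DFT of its band-limited **spatial**
  kernel (h(0) = 1/4τ², h(±odd m) = −1/(πmτ)²) rather than as a naive
  |ν| ramp — the naive version under-weights low frequencies on a
  finite grid and reconstructs uniform objects several percent low; an
  optional Hann apodization is available;
* projections are zero-padded to the next power of two ≥ 2× their
  width;
* backprojection uses linear interpolation at t = x·cos θ + y·sin θ,
  per-angle quadrature weights for non-uniform angle sets, an inclusive
  half-turn's duplicated end row dropped, and total angular weight
  capped at π;
* voxels outside the inscribed circle (never covered by every
  projection) are zeroed;
* the rotation-axis offset defaults to an estimate from conjugate
  projection pairs (rows 180° apart, e.g. −90°/+90°): the L2 mismatch
  between one row and the reflection of its conjugate is minimized over
  integer shifts with parabolic sub-pixel refinement, offset = shift/2;
  with no conjugate pair available, a linear fit of the per-projection
  center of mass to A cos θ + B sin θ + C supplies the offset, and a
  flat sinogram returns 0 with a warning.

With these choices, a forward-projected uniform disk (121 angles over
−90°…90° at 1.5°) reconstructs with interior mean accurate to ~0.01 %,
mass conserved to <0.1 %, and full-slice RMS ≈ 4.8 % of the density
(dominated by edge ringing at the discontinuity — interior RMS is
~0.5 %). FBP is linear to machine precision, and reconstruction error
decreases monotonically with the number of angles.

## Synthetic data

Material models are **phenomenological stand-ins**, not physical
fibre-diffraction simulations: I(q) = flat + A·q⁻ᵖ + Σ Gaussians.
Defaults: power-law exponent 3 with amplitude 0.1 (the multi-decade
low-q decay of hierarchical cell-wall tissue); crystalline cellulose =
that decay + a sharp Gaussian at 1.58 Å⁻¹ (σ = 0.03 Å⁻¹) + a smooth
wide-angle hump; amorphous = the decay + a broad hump at 2.27 Å⁻¹
(σ = 0.30 Å⁻¹); blank = a weak flat term + faint low-q tail, ≳10× below
the sample at q = 1 Å⁻¹ (the real blank composition — window plus
residual air — is not quantified, so the blank is shape-only).
Per-material attenuation coefficients (0.15, 0.10, 0.01 mm⁻¹ per unit
weight) are typical soft-matter values at ~12 keV.

Rendering draws Poisson counts around exposure × Σ w·I_m(q) per pixel;
the default exposure (1000) puts a few hundred counts in peak pixels,
matching sub-second exposures of strongly scattering tissue. Noise is
seeded **per grid cell**, so snake and raster traversals of the same
phantom record identical frames and must produce identical maps — a
deliberate property used by the order-invariance tests. Detector
templates reproduce the hybrid-pixel module/gap tiling (5×2 modules of
195×487 px with 17/7 px gaps → 1043×981), including the wide-angle
variant with the center module row removed.

Scan simulation treats the phantom as a thin flat sample (one phantom
pixel = one scan point); tomography simulation line-integrates the
rotated material-weight maps (the same rotate-and-sample transform as
the forward projector) so that per-material path weights, stored as
ground truth, are exact chords. Default tomographic conditions: 5 µm
step and voxel, angles −90°…90° at 1.5° (121 projections).

What the generator does **not** emulate: anisotropic (oriented-fiber)
azimuthal intensity modulation, inter-detector efficiency differences,
beam-profile and motor jitter, detector point-spread, and sample-frame
misalignment. Passing the phantom-recovery suite therefore demonstrates
the correctness of the computation chain, not robustness to every
instrumental artifact of real data; the biological result itself (high
crystallinity index at vascular bundles, low in pith and bark of a real
stem) requires a real sample and is represented here only by its
phantom-based analogue.

## Problem sizes

The validation suite runs the full 121-angle half turn on 64×64 slices
with a 64×64 px wide-angle detector, 20 randomized 1043×981 px
calibration frames, and 20×20 raster maps — sizes chosen so the whole
suite completes in well under a minute per capability while leaving the
statistical tolerances meaningful.

## Transfocator model

δ for beryllium uses the far-from-edge free-electron form
δ = r_e λ² ρ_e/2π with ρ_e from the bulk density (1.848 g/cm³, Z = 4,
A = 9.0122) — accurate to ~2 % over the 7–18 keV operating range (a
warning is issued outside it); no anomalous-dispersion tables. Lenses
are thin and aberration-free: 1/f = Σ 2n_i δ/R_i over in-beam groups;
absorption and effective-aperture effects are omitted (operationally
handled by slits at the instrument). The default stack is 43 lenses of
0.1 mm radius in groups of 1, 2, 4, 8, 16, 12 plus four 0.5 mm lenses;
whether the 0.5 mm lenses switch as one group or individually is not
fixed by the hardware description, so both modes exist
(`split_large_group`), with the single-group default. The configuration
search enumerates all group states exhaustively (2⁷ or 2¹⁰ — trivial),
optionally over a 1 mm grid of transfocator positions within the
0.5–1.5 m travel, breaking ties toward fewer lenses (less absorption).
The imaging layout is fixed at 8 m SSA-to-sample; `BeamlineLayout`
validates only 0 < lens_to_sample < ssa_to_sample so that hypothetical
positions (e.g. the unit-magnification midpoint) remain expressible,
while the travel limits are used by the search.
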