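# Methods

This note records the model, its assumptions, the default parameters and
the numerical choices behind `eixpct`, in the order the data flows
through the toolkit.

## Geometry and units

Transverse lengths are micrometres; the two long distances (system
length, object-to-detector z_od) are entered in centimetres.  The
canonical transverse frame is the **sample-mask plane**; detector-plane
quantities map by the cone magnification M = sdd/(sdd − z_od), which is
always derived from the distances.  For the reference geometry
(70 cm / 15 cm) this gives M = 1.2727; hardware of this class is usually
quoted at the rounded design value 1.25×, and the mask pitch pairs
(48/38 µm, 98/78 µm) are consistent with the rounded value.  The
configuration validator therefore checks the pitch-matching condition in
the sample plane, |p₂/M − p₁| ≤ 1 µm, which both reference mask sets
satisfy with the derived M; `dither_sampling()` accepts an explicit
nominal magnification so that sampling arithmetic can be reported in
design terms (12.5 µm detector pitch ↔ 10 µm sample-plane steps).
Energy enters only through the wavelength, λ[Å] = 12.398/E[keV], at a
single effective energy (19 keV default): the beam is modelled as
monochromatic at the spectrum's effective energy, matching how the
single-shot retrieval treats real polychromatic data.

## Illumination curve

IC(x) is computed **geometrically** — no Fresnel propagation — as the
FFT cross-correlation of the sample-mask aperture train with the
source-blurred detector-mask train on a 0.02 µm grid, normalised so that
fully overlapped apertures under a point source give 1.  The focal spot
(Gaussian, 70 µm FWHM default) enters as a penumbra of FWHM
f·z_od/sdd = 15 µm in the sample plane — standard incoherent-source
projection.  Both mask trains are laid out on the sample-mask period:
the idealised aligned design.  Interpolation is a periodic cubic spline;
IC′ is its analytic derivative.  The maximum-|slope| search uses finite
differences of the tabulated curve rather than the spline (a cubic
overshoots at the kinks of piecewise-linear ICs) and breaks plateau ties
toward the smallest apex offset on the negative flank.  For both
reference configurations the steepest point lands 8.8–9.1 µm from the
apex, so the acquisition default works at s_i = apex − 9 µm, taken as a
sample-mask-plane displacement.

## Phantoms and projection

Phantoms are voxelised δ/β volumes (y = detector rows, x = mask
modulation, z = beam).  Transmission uses T = exp(−∫µ dz) with
µ = 4πβ/λ — β is a dimensionless part of the refractive index and enters
attenuation only through µ.  Refraction is Δθ = ∂ₓ∫δ dz by central
differences; Δx = z_od·Δθ.  Rays are parallel within a slice: at 15 cm
from the detector in a 70 cm system, the cone angle across a mm-scale
phantom is negligible.  Default soft-tissue optical constants
(δ = 7×10⁻⁷, β = 3×10⁻¹⁰ at 19 keV, water-like; adipose and fibrous
variants around it) are configuration values taken from standard
optical-constant tabulations, not constants of the code.  The slanted
resolution edge defaults to an **ideal absorber with δ = 0**: a sharp
opaque interface with a realistic δ would produce a single-voxel
gradient spike (Δx of hundreds of µm) that is an artefact of
differentiating a discontinuity, not physics the edge test probes.
`check_linearity` warns when max |Δx| exceeds half the working-point
offset, the range over which the IC flank is usably linear.

## Forward frame model

One beamlet per illuminated column.  T and Δx are averaged over 7
sub-rays spanning the 12 µm aperture, and the expected counts are
I₀·⟨T·IC(s − Δx)⟩ — aperture-integrated signal.  Cross-talk is a
normalised symmetric kernel applied across detector columns; the default
shape is a Gaussian core plus a 20 % Lorentzian tail of equal FWHM
(emulating scintillator light spread with long tails).  Its width
parameter is the **bare-detector slanted-edge LSF FWHM referred to the
sample plane** (default 100 µm = twice the pixel pitch); the physical
detector-plane kernel is that value × M, which is exactly the
calibration a bare-detector edge scan performs.  The simulated region is
extended by the kernel support so convolution boundaries never touch the
reported columns.  Dithering translates the **sample**, never the masks;
jitter adds per-angle integer-period sample translations recorded in
frame metadata.  Noise is Poisson only, with a mandatory seed;
I₀ defaults to 10⁴ counts/s per used pixel, and exposure scales counts
linearly.

## Correction, recombination, retrieval

Correction is (raw − ⟨dark⟩)/(⟨flat⟩ − ⟨dark⟩) with an ε = 10⁻⁶ floor;
flats are vacuum acquisitions at the working point and carry no row
structure, so a single-row flat broadcasts.  Recombination interleaves
the dithered frames by their true sample coordinates (beamlet position
minus dither offset, known from metadata), so the 10 µm step's slight
overshoot of the 78/8 = 9.75 µm ideal adds no blur; the nominal output
pitch is period/n.

The single-shot filter is D(f) = 1 + i·ξ·f with
ξ = 2π·z_od·γ·R(s_i).  Two readings of the ratio R are implemented;
forward–inverse parameter recovery on a homogeneous cylinder is the
arbiter, and only R = IC/IC′ with γ in inverse length recovers the
input (the matched value is γ = c·r², c = δ/µ, r = IC′/IC — about
1.7 cm⁻¹ for the default tissue at this working point, the same order
as the ~1 cm⁻¹ values used on physical systems of this type).  That mode
is the default; the sign convention is tied to numpy's e^(−2πifx)
transform.  Rows are padded to the next power of two with **edge-value
(constant) continuation**: mirror padding flips the sign of the odd
differential-fringe component, and because the inverse filter's kernel
is a one-sided exponential with decay length ξ/2π (≈ 210 µm at the
matched working point) the reflected images would leak double-digit
relative errors into the field of view; with edge padding the cylinder
round trip is exact to <0.1 % on the system grid.  The unpaired Nyquist
bin is forced real to keep the filter Hermitian.  Retrieval is applied
per projection, before reconstruction.

## Reconstruction

Parallel-beam FBP (scikit-image `iradon`, ramp or Shepp–Logan filter)
stands in for the physical system's cone-beam geometry — at desk scale
the difference is below the other error terms.  Sinogram rows are
aligned so the rotation axis (x = 0) projects to the central column;
CT pipelines use a dither step of exactly period/n so the recombined
grid is uniform for the transform.  µ is recovered in 1/µm by dividing
by the sinogram pitch.  Jitter compensation shifts rows back by the
recorded integer-period offsets with vacuum fill.  Ring suppression is a
generic fixed-pattern detrender: column medians over angle, spike
detection against a 7-column median trend at 5× the median absolute
deviation, repair of flagged columns by interpolation, a local-quadratic
trend refit, and subtraction only at flagged columns — smooth structure,
including steep object boundaries, is left untouched.  It is a simple
substitute for published ring-suppression algorithms, adequate for
column-gain defects, not a reimplementation of any of them.

## Slanted-edge analysis

Per-row edge crossings are mid-level crossings of the row profile (on
coarse grids a gradient centroid and the mid-crossing both carry a
sampling-phase sawtooth of up to ±(period − aperture)/2; the mid
crossing is the better behaved of the two).  A line fit over rows must
reach R² ≥ 0.99 — met by the default geometry of 96 rows at 5°, which
sweeps the edge across ≥ 8 mask periods and averages the sawtooth out of
the fitted line.  All pixels are projected onto the edge normal and
binned at 1/4 of the sampling pitch; smoothing is Savitzky–Golay of
order 3 (window 9 bins); the LSF is the central-difference derivative,
unit-peak normalised.  Fits (Gaussian, or positive Gaussian + Lorentzian
with shared centre) use lmfit with bounded parameters; the FWHM is read
numerically from interpolated half-maximum crossings of the fitted
profile, verified against 2√(2 ln 2)·σ in the pure-Gaussian case.  The
single-peak fit windows default to the central peak (the skipped-mode
LSF has small side replicas at ±78 µm from residual next-column
cross-talk; a single Gaussian is a model of the peak, not of the
replicas).

Two resolution metrics coexist deliberately.  The slanted-edge FWHM
measures the pre-sampling response — it is what the aperture-limited
11.75 µm and the detector-limited 99 µm figures mean.  The per-row
metric (`per_row_edge_fwhm`) differentiates a single recombined
projection on the grid actually sampled and therefore exposes the
sampling limit that dithering removes: it falls monotonically
≈ 175 → 89 → 39 → 20 µm for 1, 2, 4, 8 steps on the skipped set,
plateauing near twice the aperture because the numerical derivative
spans two samples.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: the two mask sets
(48/38 and 98/78 µm pitches, 20/12 µm apertures), 50 µm pixels, 70 µm
FWHM source, 70 cm/15 cm geometry, s_i = 9 µm, 8 dithering steps of
10 µm, a 100 µm bare-detector LSF, an opaque slanted edge, and 30 µm
strand phantoms in soft-tissue disks.  Desk-scale runs use a few hundred
projection angles and mm-scale phantoms — the package's default problem
sizes — rather than the thousands of angles and cm-scale specimens of a
full tissue scan; tissue-image properties are therefore covered by
scaled-down phantom experiments (strand contrast recovery, texture
phantoms), not by reproducing specimen images.  Not modelled: wave
optics and diffraction at the apertures, polychromatic beam hardening,
small-angle scattering (the dark-field channel), detector lag/gain maps,
anatomically realistic breast morphology, and dose.  Passing tests show
the geometric EI model is implemented consistently end to end, not that
these excluded effects are negligible in any particular experiment.

## Known limitations

* The geometric IC underestimates diffraction broadening of real
  beamlets; measured working points and slopes will differ from the
  tabulated ones at the few-µm / few-percent level.
* Multi-frame (2/3-image) Gaussian retrieval of separate absorption,
  refraction and scattering channels is out of scope; only the
  single-image homogeneous-object retrieval is provided.
* γ is a tuning parameter of the retrieval in 1/length units; the
  toolkit does not assert a physical identity between it and δ/β.
* The ring suppressor assumes defects are narrow (≤ 2 adjacent columns)
  relative to true structure; broad fixed-pattern drifts are not
  separated.
* Cone-beam effects, helical/cycloidal trajectories and iterative
  reconstruction are not implemented.
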