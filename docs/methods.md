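# Methods

This note records the physical models, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Materials

Optical constants derive from elemental composition (mass fractions w_i,
density ρ) and photon energy E ∈ [1, 100] keV:

* **δ** = r_e λ² n_e / 2π with the electron density
  n_e = ρ N_A Σ w_i Z_i/A_i.  This is the f1 ≈ Z approximation for the
  atomic scattering factor: valid far from absorption edges, which for
  the supported elements (H, C, N, O) all lie below 1 keV.  CODATA
  constants are used (r_e = 2.8179403×10⁻¹⁵ m, hc = 1.23984198 keV·nm).
* **μ** = ρ Σ w_i (N_A/A_i)(σ_pe + σ_C + σ_R).  The Compton channel is
  the analytic Klein–Nishina total cross section per free electron times
  Z (no binding or Doppler broadening).  The Rayleigh channel is the
  Thomson cross section modulated by squared atomic form factors
  (Cromer–Mann analytic fits, continued as F(2/Å)·(2/s)² beyond the fit
  range), integrated by 256-point Gauss–Legendre quadrature.  The
  photoelectric channel is anchored so the three channels sum to
  standard-reference total mass-attenuation values on the common
  reference energy grid (5–100 keV embedded; power-law extrapolation
  below), and is interpolated log-log between anchors — accurate because
  σ_pe is very nearly a power law in E.  This construction guarantees
  channel consistency (total = sum of channels, used for interaction
  selection) and reproduces reference totals at the anchors exactly;
  water at 25 keV comes out at 0.506 cm⁻¹ (reference 0.507).
* **β** = μλ/4π.

The KN×Z Compton channel overestimates incoherent scattering at low
energy for light elements (no incoherent scattering function); the
derived photoelectric channel absorbs the difference at the anchors, so
channel *ratios* are approximate while totals are accurate.  Mixture
densities are measured inputs, never computed from volume additivity;
the built-in ethanol mixtures use mass fractions 1/3, 1/2, 2/3 with the
measured densities of the validation liquids.  "Air" is N/O only
(Ar omitted) and is used solely as a background medium.

## Phantom geometry

Phantoms are 2D cross-sections in the (x, z) plane (samples are
translation-invariant in y; y is carried through transport as a passive
coordinate).  Regions are circles, convex intersections of half-planes
(slabs, wedges), and *clusters* of many identical circles under a
bounding circle; overlap resolves by explicit integer priority, holes
carrying higher priority than their host.  Ray-boundary intersections
are exact quadratic/linear solutions (no spatial discretization);
intersections closer than 10⁻¹⁰ m are rejected to avoid re-hitting the
surface a photon was just placed on, and photons are nudged 10⁻⁹ m past
each boundary (phase error per crossing ≲ 10⁻⁴ rad).

Clusters are indexed by a uniform grid of square cells (cell size
max(r_bound/8, 3 r_member)); rays inside the bound test only the members
of their current cell and treat cell walls and the bound circle as
pseudo boundaries with no material change (refraction across an
identical-material "boundary" is the identity, so the transport loop
needs no special casing).  This was verified against an all-circles
brute-force oracle and makes the 1176-cylinder dark-field phantom
tractable (~1 s per 3×10⁴ histories).

The dark-field phantom places its microcylinders by dart-throwing
rejection (non-overlapping, fully inside the area), reproducibly from a
seed.  The five-hole liquid phantom's layout dimensions (host 3 mm,
holes 0.8 mm on a 1.8 mm ring) are free parameters: they shape the
image, not the physics under test.

## Sources and coherence

All photons are monochromatic and initialized on the entrance plane.
Coherence is encoded in the joint distribution of position, direction
and initial phase:

* plane wave: uniform x, direction +z, zero phase;
* point source at distance R: position/direction on the fan, initial
  phase −k(x − x_s)²/2R (the paraxial geometric path difference);
* partially coherent source: source point x_s drawn uniform or Gaussian
  (second moment = configured width), target drawn uniform over the
  illuminated region, phase −k(x − x_s)²/2R.

The quadratic initial phase is essential: the transport stage
accumulates only the material-induced phase ∫kδ ds, so source-geometry
phase cannot arise downstream.  With it, photons from one source point
bin to a numerically exact spherical wavefront, and averaging over
source points reproduces partial-coherence visibility loss (tested:
fringe visibility decreases monotonically with source size).  Only
horizontal (x) coherence is modelled.

## Transport

Analog photon Monte Carlo, vectorized over histories: exponential free
paths from the local μ(E), channel selection by cross-section ratio,
Klein–Nishina Compton sampling (rejection on cosθ; energy from the
Compton formula), form-factor Rayleigh sampling (rejection against
(1+cos²θ)F²(q); the element is chosen by coherent share), and Snell
refraction with total external reflection at every boundary — including
for already-scattered photons (the most literal reading of a per-
transition refraction subroutine).  Photoelectric events and photons
falling below the cut-off (default 10 keV for the 25 keV studies;
validity floor 1 keV) deposit locally and terminate; photons crossing
the scoring plane are recorded with position, direction, energy, weight,
accumulated phase and per-channel scatter counts; photons leaving the
bounding box escape.  scored + absorbed + escaped + flagged = emitted,
exactly; a fixed seed reproduces the phase space bitwise.  Weights are
carried but always 1 (no variance reduction).  Secondary electrons are
not transported (imaging observables need none; dose is out of scope).

One seeded counter-based generator (PCG64 via `numpy.random.default_rng`)
drives each run; draws occur in a fixed vectorized order, so determinism
holds for the single-schedule execution this package uses.

## Transition to the wavefront

Within each transverse bin j, photon p contributes
w_p exp(i(−Φ_p + k_p sinθ_p (x_j − x_p))).  The sign pair is chosen so
the binned field of a refracted but unscattered bundle equals the
projection-approximation wavefront exp(−μ̄/2 − i k δ̄) exactly (for a
wedge this identity is algebraic), consistent with the propagation
transfer function e^{−iπλdf²}; the tilt term carries the transverse
phase gradient that per-photon phases alone cannot (it is ON by
default; a phase-only mode exists for ablation).

Three amplitude scales are provided.  The *flux* scale
A_j = S_j/√(n̄ W_j) (coherent sum S, summed weight W, expected
unattenuated count n̄) makes |A|² an unbiased flux estimator — absorption
enters the intensity once, as for a physical wavefront.  The literal
*wave* scale A_j = S_j/n̄ (one unit wave per particle) doubles the
optical depth in |A|², which is why reconstructions from it need a
two-point calibration; it is retained for the transition-formula
contracts.  The imaging pipelines use `split_phase_space`: the coherent
field is built (flux scale) from never-scattered photons only, while
Compton/Rayleigh-scattered photons — whose milliradian deflections
displace their fringe contribution by many analyzer periods — are
carried as ballistic diffuse rays and added to the detector intensity
through the moving analyzer.  Including them in the coherent
normalization would bias the transmission by roughly the in-scatter
fraction (~1% here, i.e. ~9% on reconstructed μ).

## Wave optics

Propagation is the paraxial angular-spectrum method: FFT, multiply by
e^{−iπλdf²}, inverse FFT — unitary, exactly composing over distances,
with an aliasing guard requiring N ≥ λd/dx² and optional zero-padding
guard bands (default 25% per side in the pipelines) against periodic
wrap-around.

Gratings are binary square profiles in two numerical representations.
The default evaluates the Fourier partial sum of the profile truncated
at order ⌊(nbp−6)/2⌋ (nbp = bins per period): the represented field is
then exactly band-limited, the discrete pipeline responds to wavefront
tilts exactly like the continuum (pattern shift d·α), and the harmonics
the retrieval uses (0 and 1) are unaffected by the truncation.  A
point-sampled binary profile at 16 bins/period instead biases the
fringe-shift response by ~+20% through intensity-harmonic aliasing.
The bin-averaged binary profile ("binary") is kept for tests that probe
the literal square profile (unimodularity, power halving, Talbot
revival).  Phase stepping moves G2 in M equidistant steps over one
period (M = 5 in the studies) and box-integrates the intensity over
detector pixels (pixel width must be an integer multiple of the grid
spacing; pixels are whole numbers of analyzer periods in the default
configs, avoiding partial-period edge terms).  Detector response is
deliberately absent.

The projection-approximation forward model integrates δ and μ along
straight rays through the same geometry engine and returns
exp(−μ̄/2 − ikδ̄); it is the baseline the Monte Carlo signal is compared
against in the propagation study.

## Retrieval and reconstruction

Stepping curves are analysed by discrete Fourier transform: a0 (mean),
a1 = |c1| and φ = arg c1 with c1 = (2/M)Σ I_m e^{−2πim/M} — exact to
machine precision for any curve containing only harmonics 0 and 1, for
every M ≥ 3.  Contrasts: T = a0_s/a0_r, dphi = wrap(φ_s − φ_r),
D = (a1/a0)_s/(a1/a0)_r (not clipped; reference-dead pixels are flagged
valid=False and set to neutral values, never NaN).

Sign conventions, fixed package-wide and verified against the analytic
wedge: wavefront phase Φ = −k∫δ dz; deflection toward +x is positive α;
a positive measured fringe phase corresponds to α = −dphi·p2/(2πd), so
the projected decrement is recovered as δ̄ = −Φ/k with dΦ/dx = kα.

Phase profiles are freed of wrap artifacts by local-prediction
modulo-2π de-spiking: each pixel is shifted by the multiple of 2π that
brings it closest to the average of its neighbours.  At a strong edge
(water against air) the fringe shift sweeps past π *inside* one pixel;
the aliased pixel defeats a greedy running unwrap (both entry and exit
differences fall below threshold after wrapping) but is exactly an
isolated ±2π outlier, which the de-spiking restores (verified against
an oracle correction).  Profiles that genuinely exceed π over many
consecutive pixels are outside this scheme — smooth phantoms only.
The integration to Φ is anchored to zero in the sample-free margins on
*both* sides (a linear detrend), enforcing physical closure and
suppressing drift.

Reconstruction is textbook parallel-beam filtered back-projection
(Ram-Lak default, Hann option), delegated to `skimage.transform.iradon`
and rescaled so line integrals are recovered in physical units: −ln T
sinograms give μ in 1/cm, integrated-phase sinograms give δ
(dimensionless), −ln D gives an extinction density (its quantitative
interpretation as a diffusion coefficient is not asserted).  Streak and
ring artifacts in the dark-field and noisy reconstructions are expected
and left uncorrected.  An optional two-point affine calibration helper
exists; raw values are always preserved.  The flat-field reference for
tomography is analytic by default (ideal plane wave through the
interferometer — the infinite-statistics limit of an empty-beam run); a
finite MC reference is available but imprints its per-pixel noise
identically on every projection, i.e. ring artifacts.

## Study configurations (desk scale)

The bundled experiment runners reproduce the three validation studies at
sizes chosen for a single CPU:

* **Propagation imaging** (10 keV, hollow polypropylene cylinder,
  SDD 1.5/3/10 mm): a 0.7 mm window about the inner edge at 0.2 µm
  sampling, 4×10⁵ histories, profiles reported on 3 µm detector pixels
  (a realistic scintillator-microscope resolution; at finer sampling the
  MC/PA comparison at 10 mm is dominated by sub-pixel alignment of the
  near-tangency caustic rather than by the convergence under test).
  The scoring plane sits snug behind the curved sample exit so that
  refracted rays do not accumulate a transverse walk through dead air
  before the wave stage.
* **GI tomography** (25 keV, p1 = 4 µm π grating, p2 = 2 µm opaque
  analyzer at the second Lohmann distance 121 mm, 5 steps, 10 keV
  cut-off): 60 projections × 10⁵ histories, 0.25 µm grid (16 bins per
  p1 period), 8 µm pixels.  The grating periods are free parameters (the
  beamline's are not on record here); the full-scale acquisition
  (1081 projections, 7.4 µm pixels) remains expressible in config.
  Interior means recover δ(water) within ~0.5% and μ within ~2% at this
  scale.
* **Dark-field study** (25 keV, 4 µm pixels): 40 projections × 3×10⁴
  histories over a 0.48 mm field.  Interior extinction of the three
  areas orders with scatterer density (795 > 381 > solid, whose signal
  is confined to its edges), stable across phantom seeds.

## What the synthetic studies do and do not show

The phantoms are mathematically exact cylinders with sharp interfaces
and known compositions: passing tests demonstrates the internal
consistency of the transport–transition–wave–retrieval chain and its
quantitative calibration, not agreement with measured data.  Real
measurements add surface roughness (which broadens edge fringes),
detector response, beam drift, polychromaticity and composition
uncertainty — none of which are modelled.  Dark-field magnitudes depend
on the full sub-pixel microstructure; only orderings and qualitative
behaviour should be read from the reduced-scale runs.

## Known limitations

* 1D transverse wavefronts only (one slice); no 2D unwrapping.
* No electron transport, dose scoring, grating-material scattering,
  polychromatic spectra or partial temporal coherence.
* Cross sections: free-electron Compton and independent-atom form-factor
  Rayleigh; no absorption-edge structure; H/C/N/O only.
* Parallel-beam Lohmann distances; no magnification correction for
  divergent beams.
* The visibility-ratio dark-field estimator uses first harmonics only;
  no higher-harmonic or model-based fits.
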