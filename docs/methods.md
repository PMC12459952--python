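# Methods

## Scope and model

The package analyzes the shape and elastic energetics of a protein–membrane
nanodome: a mechanosensitive trimeric channel (three identical arms of
transmembrane helices, the innermost helix of each arm lining the pore)
that imposes a dome of a few nanometers height on the surrounding bilayer.
The membrane is treated in the Helfrich/Monge picture: a height field
z(x, y) over a reference plane with elastic energy

    E_m = E_b + γ ΔA,       E_b = ∫ 2κ H² dA,

where κ is the bending rigidity (expressed in k_BT; default 25 k_BT with a
20 k_BT variant), γ the membrane tension (mN/m, numerically pN/nm), H the
mean curvature, and ΔA the excess area of the curved surface over its
planar projection.  The protein is modelled as a harmonic spring in the
height-change coordinate Δz: the membrane pulls the dome flat, the protein
resists, and the balance point moves linearly with tension.  Spontaneous
curvature and Gaussian-curvature terms are omitted (slight leaflet
asymmetry; fixed topology).

Thermal energy is fixed at k_BT = 4.2804 pN·nm at the simulation
temperature of 310 K and scaled linearly for other temperatures.

## Midplane reconstruction

Each frame is translated so the channel center of mass (backbone beads of
the three channel-lining helices) sits at the box center; molecules are
re-wrapped whole, by the periodic image of their center of mass.  Leaflets
are assigned per lipid by comparing the head bead's z with the mean z of
the same molecule's tail beads — a local rule that remains correct on
strongly curved membranes and is deterministic; it is exposed for
overriding.  Head beads are binned on an n×n square lattice (half-open
bins, default 25; 17 suits smaller atomistic boxes).  A bin is valid when
both leaflets contribute ≥2 heads; the midplane is the mean of the two
leaflet averages.  Invalid bins are filled iteratively: each pass assigns
an unfilled bin the mean of its already-filled 4-neighbors (periodic at
the box boundary) until none remain.  The continuous evaluator is
bilinear between bin centers with one periodic padding ring.  Whether to
interpolate before or after combining leaflets is not uniquely determined
by the procedure's description; leaflets are combined first, then filled.

## Averaging and symmetrization

Because the protein diffuses rotationally, each frame's shape is rotated
about the channel axis to minimize the summed squared in-plane distance
between its three channel-helix centers of mass and a reference triplet
(the first analyzed frame by default), testing all three cyclic pairings;
ties break toward the smallest non-negative angle.  Each aligned shape
contributes itself plus 120°- and 240°-rotated copies, making the average
exactly threefold symmetric.  Averages live on a square lattice with
lattice constant a = 1 nm (a = 2 nm variant available) over the inscribed
disk of diameter d_m = mean box width — the only region covered by every
rotated conformation.  The relative lipid density ρ(x, y) is the averaged
interpolated head count per bin normalized by its far-field mean (sites
with r > 0.8·d_m/2; the reference procedure states only "far from the
protein", so the radius is a package choice).

## Discretized elastic geometry

Excess area uses forward differences exactly as defined above, summed over
lattice sites in the disk; a site whose forward neighbor leaves the disk
uses the continuous evaluator's boundary value.  Bending energy uses
centered first and second differences in the full (nonlinear) Monge-gauge
mean curvature; sites near the rim evaluate the continuous shape one ring
beyond the disk (for analytic shapes this is the exact function, for data
shapes the extended interpolant).  The conventional finite-difference recipe
this implements contains two evident typographical slips in its source
description — a first derivative written as a mid-value sum and a mean
curvature numerator written unsquared — both restored to the standard
forms, without which a plane would carry nonzero bending energy.  The
per-site energy is weighted by ρ(x, y) so protein-occupied sites do not
contribute membrane bending energy.

Radial profiles average the shape over angles on cell-centered radial bins
(width 1 nm); local quadratic fits over r ± 2 nm give smoothed z'(r) and
z''(r), the axisymmetric mean curvature, and a profile-based bending
energy ∫2κM²·2πr√(1+z'²)dr that cross-checks the lattice energy.  The sign
of M is reported apex-positive (an upward dome has positive M at its
center); the raw Monge-gauge sign is available via a flag.  The area
element √(1+z'²) is included in the revolution integral.

## Inverse-time extrapolation

Trajectories are split into five equal windows; each window's observable
is computed on the shape averaged over all runs' frames in that window,
with across-run errors of the mean.  The last n_fit windows (default 3; 4
reproduces the atomistic worked example — both exposed) are fitted by
ordinary least squares against 1/t, window centers at interval midpoints.
The extrapolated value is the intercept at 1/t = 0 and its uncertainty the
half-width of the 0.5-level prediction band for a new observation there; a
weighted variant exists but the default fit is unweighted.  When the band
is converted to a 1σ error for downstream weighting, the 0.674 normal
quantile is used.

## Elasticity model and its standard errors

Response slopes are fitted on the standard subsets (Δz(γ) for γ ≤ 6 mN/m;
ΔA(Δz) and E_b(Δz) for Δz < 2 nm) by unweighted OLS.  Because these fits
typically have only ~4 points, a residual-based standard error alone is
unreliable (it collapses when points happen to be collinear), and an error
propagated from per-point uncertainties alone is unreliable when those
uncertainties are themselves estimated from 1–2 degrees of freedom; the
reported slope error is therefore the maximum of the two.  Forces are
reported as magnitudes: both membrane terms pull toward flattening.  The
F(Δz) relation is fitted by OLS at the four lowest tensions with constant
global slopes evaluated at the per-tension Δz; since the F values are
*constructed* from fitted slopes, the force-fit residuals are nearly zero
by design, and the standard errors of F₀ and k_F are instead propagated:
F₀ = |dE_b/dΔz|·κ·k_BT inherits the bending-slope error, and k_F, which in
the collinear limit equals |dΔA/dΔz| / (dΔz/dγ), combines the two slope
errors in quadrature.  Δz_free = −F₀/k_F with ratio-propagated error.
The sign conventions make tension-induced flattening positive: z_i =
z(channel) − z(unit-i COM) and Δz(γ) = z₄(0) − z₄(γ), so a force-free
state more curved than the relaxed membrane state has negative Δz_free.

## Protein metrics

TM helix residues protruding from the membrane are trimmed by lipid-tail
contact probability (contact: any residue bead within 0.6 nm of a tail
bead; computed over the last half of the frames by default) — only
consecutive sub-threshold (<10%) stretches at helix ends are removed.
Helix axes are the leading principal component of the backbone beads,
oriented toward +z; the constriction distance is the mean of the three
pairwise distances between the constriction-residue backbone beads.  Both
conventions (PCA axis, mean pairwise distance) are package choices where
the procedure's description says only "axis" and "average distance".

## Synthetic nanodome generator

The generator emulates the statistical structure of coarse-grained
nanodome trajectories on a 50 × 50 nm² periodic patch: a Gaussian dome
(height ~5 nm) with an optional far-field tail (logarithmic, the
small-gradient catenoid expected at zero tension, or screened-exponential
for tensed membranes) and optional threefold perturbation; two leaflets of
head/tail beads Poisson-sampled at 1.5 heads/nm²/leaflet (POPC-like) and
placed ±2 nm along the local surface normal (a vertical-offset mode exists
for closed-form checks); thermal undulations with mode amplitudes
k_BT/(κq⁴ + γq²) up to a 1.5 nm⁻¹ cutoff; a lipid-depleted channel core of
radius 2 nm with pseudo-protein markers (three 8-bead channel-helix
strings at 120°, one constriction bead each, and 3 × 9 unit markers along
spiraling arms at prescribed radii and depths); and per-frame marker
jitter of 0.2 nm.  Surfaces are built symbolically, so quadrature oracles
use exact gradients and Hessians at a 0.05 nm step — 20× finer than the
analysis lattice; refining the step 2× changes the truth values by <0.1%.

Two levels of ground truth are recorded.  *Surface truth* is the fine-grid
quadrature of the continuous surface.  *Observable truth* is the noiseless
measurement: the same reconstruction pipeline applied to an
infinite-density deterministic bead cloud.  The two differ by a few
percent because binning at ~2 nm, bilinear interpolation, and the leaflet
offset geometry deterministically attenuate sharp features; this is a
property of the measurement itself, shared with any bead-based analysis,
so embedded relations are defined in terms of what the analysis measures.

Trajectories embed a harmonic spring: Δz(γ) = (|dΔA/dΔz|/k*)·γ below a
6 mN/m cap, asymptotic excess area ΔA_∞(γ) linear in Δz with the
prescribed slope, per-frame dome heights inverted from ΔA(t) = ΔA_∞ + c/t
through the measured-ΔA table, and the dome width σ root-found once per
parameter set so the measured E_b-vs-Δz slope equals −F₀*/(κ·k_BT)
(calibrations are cached).  Pressures are synthesized to invert
γ = L_z(P_z − (P_x+P_y)/2) exactly.  Seeds derive from one master seed via
a per-(tension, run, frame) counter scheme, making runs independent and
every artifact bit-reproducible.

What the generator does *not* emulate: lipid dynamics and interdiffusion
(frames are independent draws, so there is no autocorrelation), protein
conformational dynamics beyond the prescribed marker motion, solvent,
leaflet compositional asymmetry, and protein–lipid boundary structure.
Passing tests therefore demonstrate the correctness and statistical
calibration of the analysis chain, not the faithfulness of any particular
force field.

## Problem sizes

The statistical suites run at a demonstration scale chosen to keep the
full test suite fast while leaving each estimator's error structure
realistic: end-to-end recovery uses 4 tensions × 3 runs × 15 frames per
replicate (100 replicates), and prediction-band coverage uses 200 direct
replicates of the window-extrapolation model.  Production analyses of
real trajectories would use the native cadence (e.g. 20 ns frames over
4–8 μs runs, ten runs per tension); all sizes are arguments.

## Known limitations

- The undulation contribution to ΔA and E_b of a finite-frame average does
  not extrapolate away in 1/t (it is constant across equal-size windows);
  with few frames per window it inflates both observables, most strongly
  the scale-invariant E_b at low tension.  Averaging over more frames is
  the only remedy, as in the underlying analysis procedure.
- The invalid-bin fill flattens reconstructed features wider than the
  depleted region; with the default 2 nm channel core and 2 nm bins the
  effect is small but nonzero.  At the study's lipid density it is also
  height-dependent — taller domes have steeper, sparser inner slopes and
  hence more invalid bins — so the recovered response slopes dΔA/dΔz and
  dE_b/dΔz (and with them k_F and F₀) read systematically ~10–15% below
  the embedded values even with abundant frames.  This attenuation is a
  property of the binned measurement at finite bead density, shared by
  any analysis of this kind; the recovery tests account for it through
  their standard errors.
- Prediction bands from 1–3 residual degrees of freedom are heavy-tailed;
  downstream fits therefore never rely on a single error estimate (see
  the max rule above).
- GRO/PDB parsing covers the fixed-column coordinate subset only (no
  velocities, no connectivity, no compressed trajectory formats).
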