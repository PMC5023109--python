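# Methods

## Model

The eye imaginal disc is represented as a 2D elliptical domain carrying five
species: the diffusible morphogens Hedgehog (Hh) and Decapentaplegic (Dpp),
the intracellular Dpp-signal transducer pMad, the retinal determination
factor Eya, and the progenitor factor Homothorax (Hth). Each concentration
c_i obeys an advection–reaction–diffusion equation in conservation form,

    dc_i/dt + div(u c_i) = D_i lap(c_i) + R_i ,

where u is the tissue velocity. The reaction terms encode the regulatory
logic: differentiated cells (Phi) produce Hh at a constant rate; furrow
cells (Theta) produce Dpp proportionally to the local Hh concentration;
pMad is produced under Hill activation by Dpp; Eya under activation by
pMad or Hh; and Hth production is repressed by both pMad and Hh
(product of inhibitory Hill terms). All species decay linearly. Cell states
are Heaviside classifications: progenitors Pi where Hth exceeds theta_Hth,
differentiated cells Phi where Hth is below threshold and Hh exceeds
theta_Hh, furrow cells Theta in between. The three indicators always
partition unity.

Hh enters through a flux boundary condition on the posterior 20% of the
AP extent of the boundary; the influx is constant until 10 h, declines
linearly (slope 1 per 2×(t_off−t_on), i.e. to 3/4 at the window midpoint)
and cuts off at 10.5 h. All other species carry zero-flux boundaries.
Initially Hth sits at its unrepressed steady state p_Hth/delta_Hth and all
other species at zero, so every cell is a progenitor.

Growth is modeled as an incompressible Newtonian fluid with a volume
source S = Pi · k0 · exp(−delta_PL · PL), where PL is the posterior length
of the furrow (a surrogate of developmental age). At tissue scales inertia
is negligible (Re ≪ 1), so the momentum balance is solved as quasi-static
Stokes flow with prescribed divergence and a traction-free boundary; the
"−∇ρ" of the printed momentum equation is read as the pressure gradient.
Rigid-body motion is removed by pinning the two translational degrees of
freedom at the node nearest the centroid (rotations are damped by the
pseudo-traction natural boundary condition of the gradient-form operator)
and projecting out any residual mass-weighted translation and rotation.
For a uniform source the discrete solution is the exact isotropic dilation
u = (S/2)(x − x_c), so the growth anisotropy ε = ∂_y u_y / ∂_x u_x equals
1 to solver precision — isotropy is a model rule, not an emergent result.

## Numerics

P1 triangular finite elements, assembled with vectorized numpy and solved
with scipy.sparse. The Stokes problem uses equal-order P1–P1 velocity–
pressure with Brezzi–Pitkäranta stabilization (coefficient 0.1 h_T²/μ).
The mesh is Lagrangian (ALE with mesh velocity equal to tissue velocity):
each step (i) classifies cells, (ii) solves the Stokes problem, (iii)
advects the nodes explicitly, and (iv) advances the species by an implicit
scheme built on the old- and new-mesh mass matrices, which makes the
discrete scheme exactly conservative (with reactions and boundary fluxes
off, total mass is conserved to the linear-solver tolerance per step).
Diffusion is integrated fully implicitly — a trapezoidal diffusion term
undershoots at the sharp furrow front and the clipped undershoots would
break mass conservation — while linear decay uses the trapezoidal rule
(second order), and the nonlinear production terms are explicit. The
maximum step is 250 s. Heaviside indicators are smoothed with a tanh of
width 1% of the corresponding threshold inside the PDE right-hand sides
(discontinuous sources destabilize the implicit solves); sharp
classifications are used for all reporting.

Remeshing is triggered when the minimum element quality
(4√3·area/Σedge², 1 for equilateral) falls below 0.3, or when a step
inverts an element. The boundary polygon is resampled at the target edge
length, the interior refilled with a hexagonal lattice and retriangulated
(Delaunay, degenerate hull slivers dropped), and fields are transferred by
linear interpolation (conserving each species' mass to well under 1% per
event). The furrow position PL is tracked as the anterior-most crossing of
theta_Hth by the linearly interpolated Hth field along the DV midline —
sub-element interpolation, because a pointwise nodal maximum is
mesh-noise sensitive.

## Parameterization

Concentrations are in arbitrary units with the Hth progenitor steady state
fixed at 1 (p_Hth = delta_Hth × 1), so thresholds read as fractions of
maximal Hth. All five species share one production rate. Measured
constants: D_Hh = 0.033 μm²/s and delta_Hth = 6.97e-5 1/s (FRAP);
delta_Hh = 6.7e-4 1/s from the 7 μm Hh gradient length; D_Dpp = 0.1 μm²/s
and delta_Dpp = 2.5e-4 1/s from wing-disc measurements; intracellular
species move with a nominal D = 2.5e-4 μm²/s; delta_PL = 0.0107 1/μm.
delta_pMad (1.8e-4 1/s — dephosphorylation faster than protein turnover)
and delta_Eya (equal to delta_Hth) are model choices.

The remaining constants (Hill constants, thresholds, influx amplitude,
k0, initial semi-axes) were calibrated, at the packaged production
resolution, against the furrow-speed constraint (≈3.4 μm/h), the
qualitative anterior–posterior profile shapes, and the growth trajectory
(anterior length rising to a maximum near mid-development and declining
as the furrow consumes the progenitor pool). Defaults: theta_Hth = 0.35,
theta_Hh = 0.04, K_Hh = 0.01, K_Dpp = 3e-4, K_pMad = 0.2 (all Hill
coefficients 2), eta = 4e-4, k0 = 2.8e-5 1/s, initial semi-axes
55 × 42 μm, target edge length 5 μm (≈2,000–5,000 elements over a run),
dt = 250 s. The wild-type run simulates 80 h.

Mechanistic notes from the calibration, which constrain where the model
can live in parameter space:

* The differentiation front is **Hh-limited**: a half-infinite Hh source
  presents an edge concentration of p_Hh/(2 delta_Hh) ≈ 0.052, and
  theta_Hh must sit below it (with margin for front curvature and growth
  dilution, which both lower the effective edge level) for the
  differentiation wave to advance. The furrow speed is very sensitive to
  this margin, which is why theta_Hh and the Hh production/degradation
  rates dominate the sensitivity analysis.
* The **furrow band** (Theta) exists only while the Hth front runs ahead
  of the Hh differentiation contour. Because Hth kinetics are slow
  (2.76 h half-life), this lead is provided by Dpp/pMad repression
  reaching ahead of the Hh wave; the band and the Dpp/pMad system
  therefore form a positive loop that must be ignited by the margin
  influx and can collapse if pMad repression is too weak (band death) or
  race across the disc if it is too strong. The packaged defaults sit in
  the stable intermediate regime up to roughly 45–50 h of simulated time;
  at later times, with the anterior almost consumed, the band thins below
  the mesh resolution and Dpp production ceases — visible as the decaying
  relic Dpp gradient at 60 h.
* **Growth dilution matters**: with S ≈ k0 ≈ 0.1/h against
  delta_Hth ≈ 0.25/h, the progenitor Hth baseline is p/(delta+S) ≈ 0.7
  early in the run, rising toward 1 as growth attenuates. theta_Hth must
  stay well below this moving baseline.

## Readouts

Furrow speed is the OLS slope of PL(t) on the steady-propagation window —
from shortly after the influx shutdown (the ignition era produces a real,
transient anterior Hth dip that briefly inflates PL) to the time the
furrow reaches 85% of its final excursion. Nonlinearity is the RMSE of
that fit. The sensitivity sweep additionally records the anchored
progression rate (final PL divided by time since initiation): ±1%
perturbations of the Hth-arm parameters act mostly through initiation
timing and front offset, which the anchored rate registers cleanly
(~0.5% responses) while the free slope is at the run-to-run numerical
noise floor (~0.05%); the sign-structure assertions use the anchored
rate. "Final area" readouts are taken at the end of the sweep horizon,
as no canonical readout time exists before full growth termination.

The scaling analysis bins nodal values in a DV band around the midline,
extracts the anterior (furrow-to-pole) Dpp and pMad profiles, rescales
position by the anterior length, and fits a decay length by log-linear
least squares on the 10–90% amplitude segment (robust to near-zero
tails). A constant decay length with a changing anterior length is the
non-scaling signature.

Calibration minimizes the summed squared deviation between simulated and
target furrow-relative profiles (normalized per species to unit maximum,
as units are arbitrary), with an optional furrow-speed penalty; the
forward model defaults to a fast fine-grid 1D solution of the same
network (same ModelParameters object as the 2D engine). Thresholds are
nearly unidentifiable from furrow-anchored normalized profiles alone
(they mostly shift the front, which anchoring removes); the speed penalty
restores identifiability.

## FRAP estimators

Bleach-chase: the unbleached/bleached intensity difference decays as
d(t) = d(0) exp(−delta t); ordinary least squares on ln d(t) gives delta
(slope standard error and R² reported) and the half-life ln 2/delta.
Points with non-positive difference carry no log-information and are
dropped with a warning.

Confocal FRAP: the postbleach profile is fitted as a Gaussian hole; with
the effective radius r_e and nominal ROI radius r_n, the diffusion
coefficient is D = (r_e² + r_n²)/(8 τ_1/2) with τ_1/2 the half recovery
time (linear interpolation between samples; plateau estimated as the mean
of the final 10% of samples, so recordings should extend to near-plateau).
Two Gaussian conventions coexist in the literature: 1 − K exp(−x²/r_e²)
("e1") and 1 − K exp(−2x²/r_e²) ("kang"); the half-time relation above is
derived for the latter (whose 0.86K half-width protocol returns r_e
directly, while the e1 convention's fit-free crossing level is 1 − 1/e of
the depth). Radii differ by √2 between conventions, and feeding an e1
radius into the relation biases D low by ~40%; the end-to-end pipeline
therefore converts to the kang convention before applying it. Both the
nonlinear fit and the fit-free half-width route are reported.

## Synthetic data

Generators are pure functions of their arguments and seed. Fluorescence
noise defaults to multiplicative log-normal (detector physics); additive
Gaussian is available. The bleach-chase generator reproduces the
exponential-difference model exactly before noise, with the 120-min /
5-min-frame sampling as default. The FRAP oracle evolves pure 2D diffusion
of a Gaussian hole by explicit finite differences on a reflecting square
(independent of every estimator it tests). Expression-profile targets are
smooth sigmoid/exponential shapes with the qualitative furrow-relative
anatomy of the pMad, Hth and Eya stainings. The 1D front oracle solves the
full network on a static interval by finite differences with the same
time discretization as the 2D engine; it shares the ModelParameters
object so cross-checks cannot drift apart. None of these emulate imaging
artifacts (bleaching during acquisition, segmentation error, disc
folding), so estimator tests bound algorithmic—not experimental—error.

## Known limitations

* No cell death or survival signaling: mutants that overgrow in the model
  (hh and dpp hypomorphs, hth overexpression) are smaller in reality; the
  discrepancy is expected and documented, not patched.
* The furrow-band/pMad loop is ignition-dependent: furrow initiation is
  kinetics-limited at the packaged influx strength (margin repression is
  saturated), so small influx reductions do not delay initiation; they
  instead widen the igniting furrow band and accelerate the furrow. The
  influx-titration phenotype whose mechanism runs through delayed
  initiation is therefore not reproduced at this calibration.
* Speed and band width are resolution-sensitive near the Hh-edge margin;
  the packaged constants are calibrated at the packaged resolution, and a
  resolution-matched comparison against the 1D oracle is part of the test
  suite.
* Eya has no downstream role in the network; it is simulated and reported
  only.
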