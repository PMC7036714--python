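# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `canaliflow`. The
reaction scheme of the YAP model has its own detailed account in
[MODEL_NOTES.md](MODEL_NOTES.md).

## Zonation and image quantification

Measurements are binned along the straight axis between the CV and PV
landmarks: the relative position p in [0, 1] (voxel-centred coordinates,
anisotropic voxel size honoured) maps to equal-width half-open bins,
open at the CV side so that the exact midpoint of an even zone count
falls into zone n/2 and p = 1 lands in zone n. Diameter profiles use 18
zones and drop zones 1 and 18 (about one cell layer adjacent to each
vein, where vein geometry corrupts the tube statistics); intensity
profiles use 10 zones and keep all of them.

Segmentation of the BC channel is deliberately simple and validated on
phantoms: a global Otsu threshold (which makes the diameter estimate
invariant under intensity rescaling), removal of objects below 64
voxels, a 3D skeleton, and the Euclidean distance transform evaluated at
skeleton voxels as the local tube radius. The per-zone diameter is
twice the *median* skeleton radius: the aggregator is not dictated by
the measurement semantics, and the median is robust against junction
voxels where the distance transform overestimates the radius. Zones
without skeleton voxels are reported missing (NaN), never zero. A
foreground fraction above 50% trips an inverted-contrast error instead
of producing nonsense.

Nuclei are segmented by Otsu thresholding plus a distance-transform
watershed to split touching nuclei; each nucleus contributes the mean
intensity of the second channel over its voxels, assigned to the zone of
its centroid, aggregated as mean +- sem over nuclei. Apical intensity
is the mean marker signal in a 0.56 um shell around the BC mask after
subtracting the background, estimated as the intensity *mode* outside
the dilated mask — the mode is insensitive to bright structures and
makes the measurement exactly invariant under constant offsets.

## Biophysical model of canalicular pressure and tension

The canalicular network of a lobule is collapsed to a serial chain of
zones, each a bundle of parallel tubes with the measured zonal diameter;
only zonal profiles are ever compared to data, so no graph hydraulics is
needed. Actively secreted osmolytes draw water isotonically,
`q_z = J_z / c_osm` (default secretion 1.9e-14 mol/s per zone at 300
mol/m^3, giving canalicular pressures of order 10^2-10^3 Pa), flow
accumulates toward the PV outlet, and the pressure profile follows from
Hagen-Poiseuille resistance per unit length `128 mu / (pi d^4 N)` with
bile viscosity 1.5e-3 Pa s and zone length 15 um. Within a zone the
inflow is uniform, so the flow is piecewise linear and the half-zone
trapezoidal integration used for zone-centre pressures is *exact* — the
solver agrees with the closed-form uniform-channel solution to machine
precision, and the 0.1% test tolerance only covers the discretisation of
randomized heterogeneous cases.

Conventions: tissue pressure defines gauge zero; the outlet (PV/duct)
pressure is a small positive constant calibrated so that the CV-zone
pressure exceeds it 30-fold in the untreated reference (with distributed
inflow, the ratio of the two extreme zone-centre *gauge* pressures
saturates near 22 for 18 zones, so the 30-fold lobular pressure gradient
is implemented as CV-centre absolute pressure over outlet pressure).
Apical cortical tension follows the Laplace law for a cylinder,
T = P d / 2, and strain is the relative diameter change against the
untreated profile.

After a resection of fraction f the bile-salt pool is conserved
(intra-hepatic bile acids are a few percent of it), so secretion per
remnant mass scales by 1/(1-f); f defaults to 0.68 and is exposed as
`--resection-fraction`. Liver mass recovers logistically with halftime
2.5 days and steepness 2/day, bracketing the proliferation peak near two
days and returning the stimulus to baseline within three to five days.
The relative mechanical stimulus handed to the YAP model is the tension
fold-change (evaluated on the strained geometry, since measured
diameters enter the Laplace law); a multiplicative tension x (1+strain)
rule is implemented as an alternative because the two readouts could
plausibly combine, and the default is the pure tension fold.

## Quasi-steady-state fitting

The fitter compares normalized nuclear and total YAP observables —
Y_n and the volume-weighted mean concentration over both compartments,
each divided by its value at stimulus 1 — against long-format tables of
(time, zone, observable, value, sd, n). Residuals are weighted by 1/sd
where a standard deviation is given and by the model value otherwise
(the data are fold-changes, so relative error is the natural scale);
datasets are renormalized to a baseline mean of 1 per observable on
ingest, which makes the objective invariant to a common rescaling of
values and sds. Rows whose parameters admit no steady state contribute
a large finite penalty (1e3 per row) and are logged, keeping the
objective finite everywhere.

Optimization runs in log10-parameter space (rates are positive and
scale-free) with bounds nominal x 10^(+-3), from a seeded Latin
hypercube of starts (default 50; the nominal point is always start 0)
refined by trust-region least squares, with the best start re-polished
at tight tolerance. Identical seeds give bit-identical results.

Individual rate constants are structurally non-identifiable from
normalized steady-state data (see MODEL_NOTES); the well-determined
quantities are the curve itself and its threshold. Parameter-recovery
experiments regenerate the design with fresh seeds, fit each replicate
and report bias and RMSE per free parameter and for the threshold,
flagging relative RMSE above 100% as practically non-identifiable. At
the default design (120 points, 10% lognormal noise) the *mean*
threshold estimate over 20 replicates recovers the generating threshold
to within about 10%, while single-replicate estimates scatter with an
RMSE near 20% — occasional noise realizations have their global optimum
at a visibly shifted curve, which the multi-start optimizer correctly
finds; averaging over replicates is therefore part of the estimator.

The activation threshold of a stimulus-response curve is, by default,
the intersection of the tangent at the inflection point (detected as the
convex-to-concave sign change of the second finite difference with the
largest slope) with the pre-activation baseline level, taken as the
curve value at the low end of the stimulus grid; half-rise and 10%-rise
thresholds are computed alongside. A flat curve or one without an
inflection yields an explicit "no threshold" result. The effective Hill
coefficient is twice the log-log slope of the baseline-subtracted curve
at its half-rise point, which recovers the exponent of a pure Hill
function exactly. The default characterization grid spans 0.25-8.0
(1551 points): wide enough that inflections of strongly perturbed curves
stay on-grid, dense enough that the tangent construction matches a
symbolic oracle within 1%.

## Synthetic-data generator

The phantom emulates the acquisition geometry of the measurements it
stands in for: voxels of 0.28 x 0.28 x 0.3 um (x, y, z), a tube network
rendered around a piecewise-linear random-walk centerline pinned to the
CV and PV landmarks (a Brownian bridge, plus short random side
branches), with the local diameter taken from the zone the centerline
passes through. The tube mask thresholds *exact* sub-voxel distances to
the dense centerline polyline, so the rendered radius carries no
centerline quantization; nuclei are non-overlapping ellipsoids
(semi-axes 2.2/2.8/2.8 um) with intensities assigned by 10-zone
position; the apical channel is a 0.56 um shell around the tubes.
Optics are applied last: Gaussian PSF blur (default sigma 0.2 um), shot
noise approximated as Gaussian with variance proportional to the signal,
and additive read noise. Ground truth (masks, centerline, zonal values)
is recorded before blur and noise.

The YAP table generator evaluates the closed-form quasi-steady state at
the per-(time, zone) stimulus from the biophysical trajectory
(untreated at t = 0), multiplies by lognormal noise of the stated CV
(mean exactly 1), truncates the design to the target count — the default
6 time points (0, 0.8, 1.5, 2, 3, 5 days) x 10 zones x 2 observables x 1
replicate gives exactly 120 points; the decomposition is configurable,
the count is what matters — and renormalizes so the untreated mean is 1
per observable.

What the phantoms do *not* emulate: sinusoids, cell shapes, real BC
surface texture, depth-dependent attenuation, anisotropic PSF tails, or
segmentation-confounding structures. Passing the phantom-truth tests
therefore shows that the measurement semantics are correct and unbiased
at the voxel scale, not that the segmentation would survive arbitrary
real tissue images.

## Problem sizes and tolerances used by the test suite

Phantom-truth comparisons use stacks of 48 x 64 x 520 voxels (about
145 um of CV-PV axis, 18 zones) without blur or noise, and compare
*replicate-mean* profiles over three phantoms against truth at 0.15 um
per zone — profiles in this kind of study are means over a handful of
animals, and the per-phantom voxel-quantization scatter (up to about one
half voxel) averages out the same way. Oracle equivalences run 10
randomized flow networks and 50 random parameter draws (steady state vs
integration to t = 2000 days at rtol 1e-8). Threshold recovery fits 20
replicate noisy datasets with 8 multi-starts each; more starts were
verified not to change the optima. The demo pipeline uses a
32 x 48 x 260 stack and 4 starts. Everything runs in well under a
minute except the recovery and phantom suites (a few seconds each).

## Known limitations

- The serial-zone hydraulic model ignores network topology beyond a
  parallel-channel multiplicity; peristalsis and contractile flow are
  out of scope.
- The isotonic-secretion closure replaces an explicit water-permeability
  law; osmolarity is a fixed set point.
- Normalized steady-state observables cannot identify k_in, k_out,
  k_bind or the absolute concentration scale; claims about those rates
  should not be read off fit results.
- The tangent threshold depends weakly on the stimulus grid through the
  discrete inflection search; the default grid keeps this below the 1%
  oracle tolerance.
- The sensor cooperativity exponent is a structural assumption (see
  MODEL_NOTES): with n = 1 the steady-state curve cannot be sigmoidal,
  so threshold-based analyses require n >= 2.
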