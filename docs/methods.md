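# Methods

## Scope and data flow

`marrowdose` estimates the absorbed dose to the active bone marrow during
Lu-177 radioligand therapy from voxelized inputs: a CT-like HU volume, VOI
label maps (kidneys, lesions, remainder of body), time-activity samples,
and blood counts.  The chain is

CT → material map → skeletal composition map → (kinetics → TIA map) →
voxel Monte Carlo → marrow-localization models → aggregated marrow dose,
with an organ-level S-value computation (SMIRD) alongside as reference.

All volumes share one regular grid (0-based indices, half-open voxel
extents, world = origin + index·spacing, RAS-like axes); single-file
NIfTI-1 is the interchange format, CSV for tables, JSON for configs.

## Materials and skeletal composition

HU → (density, tissue class) uses a piecewise-linear calibration with
anchors at air (−1000 HU, 0.0012 g/cm³), water (0 HU, 1.0 g/cm³) and
cortical bone (+1000 HU, 1.9 g/cm³); the table is an editable input because
published calibrations differ per scanner.  The skeleton is segmented at
HU ≥ 200 with per-slice hole filling (closing marrow cavities enclosed by
cortical bone).  Each skeletal voxel gets a region label 1–13
(skull … femora) and that region's mass fractions (f_BM, f_iaBM, f_HB) of
active marrow, fatty marrow and hard bone.  The bundled fraction table is a
reference-male-style *input*, not an assertion: rows must sum to 1 within
1e-6, and the per-voxel invariant f_BM + f_iaBM + f_HB = 1 is enforced to
1e-9.  Skeletal voxels that fall outside all labeled regions default to a
spine-equivalent composition (configurable, logged) — the behavior of
template-registration gaps had to be decided here because no convention
exists for it.

## Kinetics and TIA

Compartment curves are sums of decaying exponentials with effective rates
(physical decay included), fitted by bounded nonnegative least squares:
mono-exponential fits are seeded by log-linear regression, bi-exponential
fits by curve peeling (slow term from the late half of the samples, fast
term from the early residual); both are deterministic.  Integration is
analytic over [0, ∞) of the fitted curve — the effective rates already
contain physical decay, so no extra decay factor is applied.  Unit chain:
MBq·h → Bq·s via ×3.6e9.

The blood self-dose uses RMBLR = c_ECF/(1 − HCT) with the
extracellular-fluid fraction c_ECF = 0.19 by default (configurable;
c_ECF = 1 − HCT recovers the PRRT convention RMBLR = 1), assuming no
specific binding to marrow or blood cells.  The remainder-of-body TIA comes
from the hybrid SPECT-planar model: a mono-exponential through the
sequential SPECT totals, rescaled to pass through the planar whole-body
activity at 24 h, integrated, with kidney and blood-attributed TIAs
subtracted; a negative remainder is rejected as inconsistent input.
Abdominal-field lesion quantities scale to the whole body by the
total-to-abdominal lesion-volume ratio.

Per-voxel TIA allocation distributes each compartment's TIA over its VOI
proportionally to the 24-h activity image (kidneys, lesions) and uniformly
per unit mass in the ROB; compartment sums are conserved exactly.  A
voxel-wise-fit mode is deliberately not the default: with three time points
per voxel it is noise-dominated, while compartment kinetics × 24-h spatial
shape keeps the spatial resolution of the best-counted time point.

## Monte-Carlo engine

Histories are decays sampled ∝ TIA (inverse-CDF on a fixed cumulative
table).  Per decay: each photon line fires with its yield; one beta
electron draws its energy from the bundled binned spectrum.

*Electrons* deposit locally by default: the CSDA range of Lu-177 betas
(< 2 mm in soft tissue) is below the ≥ 2 mm voxels targeted, which is also
why a 10 keV production threshold is adequate.  The optional CSDA mode
spreads the energy in equal fractions along a straight line of
range length, starting at the voxel center (the sub-voxel emission position
is below the blur scale of interest, and the short-range limit then reduces
exactly to local deposition).

*Photons* are Woodcock-tracked: free paths from the grid-wide majorant
attenuation, virtual collisions rejected by the local-to-majorant ratio.
Interactions are photoelectric absorption (full local deposition) and
incoherent scattering with exact Klein-Nishina sampling
(composition-rejection for the scattered fraction, direction rotated
accordingly); scattered photons below the 1 keV cutoff deposit locally.
Coherent scattering and bremsstrahlung are omitted — sub-percent effects
for Lu-177 energies in tissue, stated here as an accuracy bound rather than
hidden.  Energy is conserved per history to floating tolerance (deposited +
escaped = emitted).

*Scoring.*  Each deposition in a skeletal voxel accumulates raw energy
(bone-mixture dose) and energy × w (active-marrow dose), with w evaluated
per event at the event's energy; photoelectrons and Compton recoils use the
electron stopping-power ratio, sub-cutoff photons the attenuation ratio.
Which coefficient should govern secondary electrons is not fixed by any
convention, so the choice is explicit and a voxel-average-w mode exists for
comparison.  Doses are per-voxel energy / (ρ·V), scaled linearly by
total decays / n_histories; the default 1e6 histories (vs the ~1e9 a
production run would use) trades statistical noise for runtime, and the
per-voxel and aggregate standard errors from 16-batch statistics quantify
exactly what was traded.  Results are bit-reproducible for a fixed (seed,
n_histories, batch count), single-threaded.

*Kernel alternative.*  `kernel_dose` convolves the TIA map with a radial
dose-point kernel (FFT), assuming homogeneous water; it is flagged
approximate in its metadata and scores no marrow weighting.

## Interaction data

Bundled CSVs (versioned inputs; every quantitative test is self-consistent
with them): photon mass attenuation built from the exact free-electron
Klein-Nishina cross-section times electron density plus a power-law
photoelectric term anchored at 20 keV to published attenuation values;
electron collision stopping powers as published-style water values with
per-medium scale factors; Lu-177 photon lines (dominant 113 and 208 keV);
and a 100-bin beta spectrum from allowed-shape theory for the three main
branches with a nonrelativistic screened Fermi correction (table mean
≈ 140 keV).  These parameterizations are accurate to a few percent at
Lu-177 energies — adequate because the marrow dose there is dominated by
locally deposited electrons, and because the weighting factor is a *ratio*
of coefficients, which cancels common scale errors.

## Marrow models and aggregation

MC1 sets per-voxel marrow mass f_BM·ρ·V inside the skeleton.  MC2 zeroes
lesion voxels without redistributing the removed mass — whether displaced
marrow reappears elsewhere is unknowable from the imaging, so no mass
conservation is imposed and totals simply shrink.  gMC3 intersects a
supplied binary marrow VOI with the skeleton (options: include
extra-skeletal VOI voxels with a default composition; weight by image
intensity).  The aggregate marrow dose is the mass-weighted mean of the
per-voxel marrow dose; it uses the patient-specific summed voxel mass (a
reference-mass mode exists for sensitivity).  Aggregate MC standard errors
are formed from the engine's per-batch dose maps under the chosen mass
weights.

## S-value reference dosimetry

D = S(rm←rm)·RMBLR·C_blood·m_rm + Σ_k S(rm←kidney_k)·TIA_k +
S(rm←ROB)·TIA_ROB, linear in every TIA; lesions carry no dedicated channel
and fold into the ROB term.  S values scale from reference to patient mass:
inverse-linear for the self term (electron-dominated Lu-177), a
configurable exponent (default 1, target-mass based; source-mass mode
available) for cross terms — no published formula fixes these, so both the
rule and its sensitivity switches are exposed.  The bundled S-value table
is *illustrative* (structure and masses of a standardized-male table, not
licensed values); absolute SMIRD outputs are therefore not comparable to
clinical results, and nothing in the package asserts them.

## Synthetic patients

The generator emulates the clinical inputs' geometry and bookkeeping: a
body ellipsoid with a 13-region skeleton (open rib and pelvic rings so
per-slice hole filling reproduces the truth skeleton), two kidneys,
spherical bone/soft-tissue lesions, mono-exponential organ kinetics and a
bi-exponential blood curve, the analytic per-voxel TIA they imply, and
noisy measurements at the clinical schedule (SPECT 24/48/72 h, planar 24 h,
five blood samples, 5% multiplicative Gaussian noise).  Defaults: 6 GBq
administered, hematocrit 0.43, per-kidney 2.5% of administered activity
(effective half-life 35 h), lesions 15% (70 h), ROB 45% (45 h), blood
30%/6% with 1.5 h/40 h — effective half-lives of tens of hours typical for
Lu-177 ligands, lesion-to-background concentration contrast of order 100.
`lesion_tia_fraction` rescales the lesion amplitude to a requested share of
total decays (the hotspot configuration uses 0.5).

It does **not** emulate anthropomorphic anatomy, partial-volume or
reconstruction effects, registration error, or count-statistics noise
textures.  Passing tests therefore demonstrate the correctness of the
bookkeeping, physics and statistics under known ground truth — not clinical
accuracy on real images.

## Numerical conventions and degenerate inputs

Log-log interpolation for all coefficient curves (1–600 keV; out-of-range
energies rejected, beta-bin edges clipped at the 1 keV table floor for
scoring).  k-means VOI segmentation is 1-D on intensities within a mask,
fitted on *sorted* values so the labels cannot depend on voxel order,
centroids sorted ascending, distance ties resolved toward the lower
centroid; constant input is rejected.  Integer dose ratios round
half-away-from-zero; dose-per-activity summaries report two significant
figures; the median of 11 values is the 6th order statistic.  Degenerate
cases are explicit: empty skeleton masks warn, an all-zero TIA map yields a
zero dose map with a warning, zero marrow mass makes aggregation an error,
and a marrow VOI that misses the skeleton is rejected with a diagnostic.

On the published 11-cycle cohort table, recomputing the per-cycle integer
dose ratios from the *rounded* printed doses reproduces the published
per-cycle ratios within one unit (the published ratios were formed from
unrounded doses); both the published ratio table and the recomputation are
packaged and reported.

## Known limitations

No coupled electron-photon condensed-history transport, variance reduction,
or coherent/bremsstrahlung physics; photoelectric cross-sections are
power-law fits; transport media are four broad tissue classes; marrow
microstructure (trabecular geometry) is summarized entirely by the
two-factor weighting model, which is a deliberate simplification at
clinical image resolution; non-rigid registration is out of scope (label
maps and marrow VOIs must be supplied pre-registered); planar-image
processing is reduced to a single whole-body scalar at 24 h.
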