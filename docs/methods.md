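# Methods

This note documents the models, estimators and numerical choices behind
`epimech`, and what the synthetic-data generators do and do not emulate.

## Monolayer tessellation and topology

**Preprocessing.** Segmentation masks are consumed as integer label images;
skeletonized boundary images are first Gaussian-filtered (σ = 2 px) to
repair broken boundary connectivity, thresholded, and labelled by
4-connected components of the non-boundary space. A 15 px border is
stripped before measurement (segmentation quality degrades at the frame).
Both constants are pipeline conventions for cellpose-derived masks and are
configurable.

**Per-cell geometry.** Area and perimeter are measured on a sub-pixel
boundary polygon: the region indicator is lightly smoothed (σ = 1 px), the
0.5 iso-contour extracted by marching squares, and the contour simplified
by Douglas–Peucker (tolerance 0.75 px). The smoothed contour runs roughly
midway through the 1-px background gap that skeletonization leaves between
cells, so polygon area and perimeter are nearly unbiased for the underlying
cell: pixel-count areas are biased low by the boundary gap, and pixel-chain
perimeters are biased high by staircase, which matters because the shape
index p = P/√A is compared across conditions at the percent level. On a
rendered honeycomb the pipeline recovers the regular-hexagon value
p = 3.7224 to 0.35%. Nuclear shape descriptors (circularity 4πA/P²,
roundness 4A/(π·major²), aspect ratio) use the same contour with lighter
smoothing (σ = 0.5, tolerance 0.3): nuclei are solid regions without a
skeleton gap, and heavier smoothing erodes sharp corners (a square's
circularity would read 3% high).

**Adjacency.** Two cells are neighbors when their supports come within
Chebyshev distance 2 — equivalently, their radius-1 (8-connectivity)
dilations touch — which bridges the 1–2 px background boundary. The
implementation scans label pairs over all offsets at once; a per-label
dilation serves as an independent oracle in the tests. Edge cells are
those touching the frame, having no neighbors, or whose neighborhood
centroid lies ≥ 30 px away from the cell centroid (a one-sided
neighborhood betrays a border cell). The 30 px bulk criterion is applied
after the border strip, on trimmed coordinates.

**Filters and rescaling.** ⟨A⟩ is the per-image mean area over non-edge
cells before any filtering; the analysis set excludes edge cells, cells
with A/⟨A⟩ > 2 (merged segmentations) and cells with n > 10. Removal only
shrinks the analysis set; surviving cells keep their original neighbor
counts.

**Topology laws.** Lewis and Desch curves are per-integer-n means of the
rescaled area and rescaled perimeter with SEM and count (singleton bins
report a count but no SEM). Perimeters are rescaled by the most probable
perimeter (density peak; a mean-rescaling option exists). For the
Aboav–Weaire statistic b(n) = (n − 6)µ_m(n) − σ_n², σ_n² is the population
(central second moment) variance of the neighbor-count distribution of one
sample, and µ_m(n) averages the neighbor counts of the neighbors of
n-sided cells. Cells on the image frame have truncated neighbor counts, so
they are excluded both as centres and from the µ_m average — their
neighborhood is not defined. b(6) = −σ_n² is then an algebraic identity
and is asserted throughout the test suite. Samples pool across animals
with weights proportional to each animal's total cell count; b(n) is
recomputed from the pooled µ_m and σ² so the identity survives pooling
(for bins present in all animals this equals the weighted mean of b).

**Mode estimation.** The most probable value of a positive, right-skewed
sample (perimeters, stiffnesses) is the argmax of a Gaussian KDE of the
log-transformed data, back-transformed with the Jacobian and shifted by
+h² in log space — the exact correction of the KDE smoothing tilt when the
log-density is locally Gaussian (bandwidth h = 0.5 × sd of the logs). A
histogram peak with quadratic refinement was rejected: it carries an 8–9%
bias at n = 10⁴, whereas this estimator recovers the analytic mode of
lognormal samples to 1–2%.

## Hertz indentation fitting

The contact model is the Hertz sphere-on-half-space law
F = (4/3)·E/(1−ν²)·√R·(δ−δ₀)^{3/2} with F = 0 before contact; units are SI
internally (z in µm at the interface, forces in N, moduli in Pa).

*Basement-membrane protocol* (colloidal AFM probe, R = 3.31 µm, ν = 0.3):
a line is fitted to the non-contact 45% of the approach (fraction
configurable within the 40–50% convention) and subtracted; because
instrument exports disagree on curve orientation, the baseline end is
chosen as the end a line actually fits (`side="auto"`), overridable. The
whole curve is then fitted jointly over (E, δ₀) by bounded
Levenberg–Marquardt-type least squares, initialised from the steepest
force rise (δ₀) and a linearised F^{2/3}-vs-depth regression (E). An
optional depth cap restricts the fit range when the acquisition indents
only a few hundred nanometres.

*Monolayer nanoindentation protocol* (R = 10 µm, ν = 0.5): the contact
point is confined to where the load is ≤ 30% of maximum, the fit covers
0–3 µm of indentation past contact, and fits with R² ≤ 0.95 are flagged
unconverged and excluded from population statistics. Because the depth
window moves with δ₀, the fit proceeds in two stages: a grid search over
admissible contact points (the model is linear in E at fixed δ₀, so each
candidate costs one projection) followed by nonlinear refinement on a
frozen window, re-anchored once. Round-trip recovery on synthetic curves:
exact at zero noise, ~0.4% median error at 1% force noise; at 5% noise the
R² gate itself rejects the curves, which is the gate working as specified.

## Traction and monolayer stress

**PIV.** Each 32-px reference window (50% overlap) is matched as a
template against a search region extended by 8 px in the deformed image
(normalized cross-correlation), with 3-point parabolic subpixel
refinement; windows whose correlation peak is < 1.1 × the second peak are
inpainted from valid neighbors, and the median vector is subtracted as
stage drift (optional). Template matching against a larger search area
avoids the loss-of-pairs bias of same-window circular correlation (~0.1 px
for our bead densities); perfect integer matches (NCC = 1) skip subpixel
refinement, which would only add bias. Measured accuracy on rendered bead
pairs: RMS error ≈ 0.07 px for smooth fields of ±2 px amplitude.

**FTTC.** Traction is recovered from displacement by per-wavevector
Tikhonov inversion of the Boussinesq surface Green tensor
(thick-substrate limit), with the DC component forced to zero — only
net-force-free tractions are observable. λ is chosen by the L-curve corner
by default; a fixed λ (including 0) is available for reproducibility. The
synthetic forward model and the inversion evaluate the same kernel on the
same periodic grid, making the pair exactly consistent: the λ = 0
round-trip on a balanced Gaussian dipole is accurate to ~10⁻⁶ relative L2
and improves monotonically with grid refinement. Wrap-around is controlled
by keeping the pattern compact within the grid (the built-in patterns keep
a wide zero margin); a `pad_factor` knob embeds the field in a larger
periodic box when an isolated scene is wanted, at the cost of exact
forward/inverse consistency from the cropped field of view. The gel
Poisson ratio defaults to 0.5 (incompressible polyacrylamide),
configurable.

**Force balance.** In-plane monolayer stress solves ∂σᵢⱼ/∂xⱼ = Tᵢ/h (T =
traction the cells exert on the substrate, h = monolayer height from live
F-actin profiles) over the image frame with stress-free boundaries, via a
displacement-based Q1 finite-element plane-stress discretization on the
traction grid; rigid-body modes are pinned by Lagrange multipliers, and
stress is evaluated at element centres. The recovered stress is
independent of the assumed sheet modulus; the sheet Poisson ratio defaults
to 0 so that unidirectional balances integrate exactly as the 1-D closed
form (a strip under uniform inward traction T₀ over length L reaches an
average normal stress T₀L/(4h) at the midline; the solver matches within
~2%, dominated by element-centre offset). The readout is the average
normal stress (σxx + σyy)/2 per point with field means of its absolute and
signed values; for an equilibrated field with vanishing traction moments
the mean signed stress is ≲1% of the mean absolute stress. Stress scales
exactly as 1/h.

## Functional quantification

A particle is internalized when its volume centroid (in µm, so voxel
anisotropy is immaterial) lies below the apical reference surface at its
(x, y); a stricter entire-particle rule is available — the choice is ours,
since the original classification is visual inspection of orthogonal
views. Efficiency is the summed projected (xy) area of internalized
particles over that of all particles, each particle's xy support counted
once (per-particle resolution of overlapping projections, matching
particle-analysis semantics); with equal-size particles this equals the
count fraction exactly. A minimum-particle-size filter is exposed with
default 0. Proliferation is the count of EdU⁺ connected components
overlapping DAPI nuclei over the DAPI count, within a central ROI to avoid
edge effects. Eccentricity bins are half-open ([300, 1200), [1200, 2000),
[2000, 3000) µm from the optic nerve; outside → "unassigned"), and ECM
intensities are divided by their per-eye maximum (idempotent; each eye's
maximum is exactly 1).

## Synthetic data: what it emulates, and what it does not

The monolayer generator is the Voronoi diagram of a jittered hexagonal
lattice; `disorder` (jitter SD / lattice pitch) tunes topology from a
perfect honeycomb to a disordered tessellation. The default 0.2 puts the
mean shape index near 3.9, mid-range between the ordered (≈3.8) and
disordered (≈4.0) monolayer states the pipeline is used to distinguish.
Ground truth carries exact polygon areas, perimeters, centroids and
neighbor lists; shared edges shorter than 1 px are not truth neighbors, as
such contacts cannot exist in the rendered mask. Force curves are the
Hertz law plus a linear background and additive Gaussian noise; traction
scenes are force-balanced patterns (Gaussian dipole, contractile disc)
with displacement from the same Green operator the inversion uses; an
equilibrated random-traction generator produces fields whose net force and
first moments vanish, the regime where mean signed stress ≈ 0. Particle
stacks place equal-size spheres by rejection sampling (1000 retries per
particle) with exactly round(n·f) centroids strictly below the reference
surface. All generators are bit-deterministic for a fixed seed.

None of this simulates microscopy physics: no PSF, no photon noise, no
segmentation errors beyond what the raster itself introduces, no
non-Hertzian mechanics (viscoelasticity, finite gel thickness), no 3-D
traction. Passing tests therefore demonstrate that the estimators recover
known ground truth under the stated noise models — not that segmentation
or instrument artefacts on real data are handled.

## Problem sizes

Default test and acceptance-script sizes: 512²–1024² px monolayers with
64–150 cells; 50 curves per (E, noise) cell over E ∈ {0.5, 1.5, 4, 5.5,
18} kPa and noise ∈ {0, 1%, 5%} of maximum force; 32²–128² traction grids;
10–30 particles per stack; 10⁴-sample mode-recovery checks. These sizes
give stable statistics for every check while keeping a full run in
minutes on one CPU.

## Known limitations

- Adjacency at raster resolution cannot decide sub-pixel Voronoi contacts;
  near quadruple points the mask-derived neighbor set can differ from the
  continuum truth (≈1% of interior cells at default disorder, more at
  higher disorder).
- The L-curve corner can over-regularize very smooth, noise-free fields;
  fixed λ is preferred for round-trip studies.
- The force-balance solver assumes a homogeneous, isotropic, linearly
  elastic sheet with stress-free frame boundaries; its equivalence to
  other monolayer-stress formulations is asserted only against the 1-D
  closed form and equilibrium properties.
- `mode_stiffness` requires ≥ 10 accepted fits and is meaningful only for
  unimodal, right-skewed populations.
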