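# Methods

This note documents the models, conventions and numerical choices behind
`neurostereo`, in the spirit of the methods documentation of simulation
packages: what is simulated, what each estimator assumes, which defaults
matter and why, and what the validation suite does and does not show.

## The virtual ganglion

A ganglion is a triaxial ellipsoid (default semi-axes 300 × 200 × 150 µm,
the long axis being the sectioning axis), so the true reference volume has
the closed form V = (4/3)πabc ≈ 3.77 × 10⁷ µm³. Somata are points with
lognormal nucleus radii (neurons ≈ 5 µm, satellite glia ≈ 2 µm). Three
arrangements of neuron somata are generated:

- **regular** — a cubic lattice with pitch (V/N)^(1/3), centred on the
  origin (so a lattice plane passes through each mid-plane), with isotropic
  Gaussian jitter of sd = 5 % of the pitch;
- **random** — a homogeneous Poisson process (count Poisson-distributed
  around the target, positions uniform in the ellipsoid);
- **clustered** — a Thomas process (Poisson parents, isotropic Gaussian
  offspring), restricted to the ellipsoid.

Satellite glia are placed in a thin shell around their parent neuron
(distance ≈ 2 neuron radii plus half-normal noise), with a Poisson number
per neuron (default mean 3). Apoptosis labels are i.i.d. Bernoulli with a
per-group probability.

The default study design has six arms of six animals — control, curcumin,
sleep-deprived (CSD), CSD + curcumin, grid-floor control and grid-floor +
curcumin. Group effects are multiplicative on the control truth: CSD
reduces volume by 31.93 %, neurons by 12.63 % and glia by 26.45 %;
curcumin arms sit at or slightly above control; CSD + curcumin is nearly
restored. The volume multiplier is applied as a cube-root scaling of all
three semi-axes. Apoptosis probabilities (control 0.02, CSD 0.20,
CSD + curcumin 0.08, remaining arms comparable to control) preserve the
ordering CSD ≫ CSD + curcumin ≈ control; the magnitudes are simulator
parameters, not measured quantities. The CSD arm's neurons are generated
as a Poisson (random) arrangement and every other arm as a jittered
lattice (regular), so the spatial classifier has a known target per arm.

The default control neuron number (10 000) is a simulation choice that
gives realistic per-section profile counts at this phantom size; it is not
an anatomical estimate of any real ganglion.

## Virtual sectioning

The microtome advances BA = 25 µm per cut along the long axis, with the
first cut at the tissue pole; a ganglion of extent L yields ceil(L/BA)
sections (24 by default). Axial processing shrinkage compresses each
section to a measured thickness t = 0.92 × BA on average (≈ 23 µm) with
1 % per-section noise, capped at BA. Every cell produces exactly one
counting event — the leading (top) edge of its nucleus sphere entering the
focal plane — assigned to the section containing that edge at a depth
scaled into [0, t]. Cells whose leading edge lies above the first cut face
are kept in section 0, so events are conserved exactly.

Anchoring the cutting grid at the tissue pole (rather than at a uniformly
random phase) keeps the section count deterministic. For the Cavalieri
sum this makes the pipeline a left-Riemann approximation whose residual
bias for the default ellipsoid is ≈ 0.2 % (Euler–Maclaurin term ∝ BA²),
an order of magnitude below the 2 % recovery band the suite enforces; the
systematic *section sampling* start is still uniformly random, as is the
point-grid offset.

Each section records two ellipses: the cut-face ellipse at its top plane
(used for point counting) and the widest profile ellipse reachable within
the slab padded by the largest nucleus radius (used as the observation
window for 2-D pattern extraction, slightly circumscribed so containment
is guaranteed).

## Cavalieri volume

Sections are sampled every k-th with uniform random start, k chosen so
that 8–12 sections are sampled (k = 2 for the default 24); d = k × BA.
One square point grid with a uniform random offset is shared by all
sections of a ganglion, as on a real stage. The default spacing (60 µm,
a(p) = 3600 µm²) yields ~150–250 points per ganglion. A_i = P_i · a(p)
and V = ΣA × d hold exactly (integer-scaled arithmetic).

The CE is the Gundersen–Jensen m = 1 estimator with the standard
point-counting nugget; the profile shape ratio B̄/√Ā is computed from the
sampled cut faces. The covariogram sums C_q = Σ P_i P_{i+q} are plain
(untruncated-length) sums, the form in common use; note that for a
constant count series this leaves a small end term (3n − 4(n−1) + (n−2) =
2), so CE is near but not exactly zero there. Negative SURS variances
(possible in short noisy series) are clamped to zero. The nugget can be
disabled by flag.

## Optical disector

Counting frames (area a/f = 3492 µm², side ≈ 59 µm) sit on a systematic
grid with uniform random phase, default step 120 µm in X and Y — tuned
once so that a default ganglion yields ΣQ⁻ ≈ 400–600, the counting effort
that gives a CE in the mid-4 % range. Only frames lying entirely inside
the section window are applied (partial edge frames would bias the
sampled-volume denominator); with a homogeneous phantom this leaves the
density estimate unbiased. Every applied frame increments ΣP.

The counting rule is the classical unbiased frame: a circular nucleus
profile is counted if it intersects the frame interior and does not touch
the forbidden line — the left edge extended upward to +∞, the bottom edge,
and the right edge extended downward from the bottom-right corner to −∞.
Over a tiling of frames every convex profile is counted exactly once (a
property test asserts this).

Guard zones are fractions of measured thickness — neurons (top 10 %,
bottom 20 %), glia (top 20 %, bottom 10 %) — selectable from the Z-axis
histogram (10 bins of 10 % of t). The z-window is half-open
[guard_top · t, (1 − guard_bottom) · t), so adjacent disectors never
double-count. h = (1 − top − bottom) × t̄. The t̄/BA factor in

    Nv = ΣQ⁻ / (ΣP · (a/f) · h) · (t̄ / BA)

is the only thickness correction applied: with fractional z-windows the
expected count per frame is ρ · (a/f) · BA · (h/t̄), so the correction
makes Nv exactly unbiased for the true density, and no additional
correction by the histogram's included-nucleus fraction is applied
(applying both would double-correct). The `included_nucleus_fraction`
field records the histogram mass inside the window for reporting; with
uniform depths and the neuron guards it is 70 %, and it exceeds 70 % when
depths concentrate mid-section (as real lost-caps histograms do).

## Voronoi classification

Tessellation uses the Delaunay/Voronoi machinery of scipy; polygon areas
use shapely. The default edge policy drops polygons that are unbounded or
touch the window boundary, because truncated edge cells inflate the CV;
the clip-to-window policy (which partitions the window exactly, a property
test checks the areas sum to the window area) is kept for completeness.
CV uses the sample (n − 1) standard deviation. Band boundaries 33 and 64
belong to "random". Per-animal CVs pool polygon areas across the animal's
analysed fields before taking sd/mean. For calibration patterns in a
square window, lattice jitter and Thomas offspring displacements are
wrapped toroidally, which preserves point counts and avoids inhomogeneity
at the edges.

## Apoptotic index and statistics

The apoptotic index defaults to pooled counts over 10 random fields per
animal (Σ apoptotic / Σ total × 100); mean-of-field-percentages is
available and differs only when field totals differ. Body-weight percent
change is (day-21 × 100 / day-1) − 100.

The comparison tree screens each group with a KS test against a normal
with the sample's fitted mean/sd (a conservative screen at these group
sizes) and pools a Levene test; both passing routes to ANOVA + Tukey,
otherwise Kruskal–Wallis + Dunn. Dunn's z-tests use mean ranks with tie
correction and are unadjusted by default (Bonferroni/Holm available).
Volume and cell-number endpoints are compared pairwise with two-tailed
Mann–Whitney U tests; for these, the per-pair p-values are the primary
output and the omnibus "significant" flag is simply min-p < α, which is
anti-conservative across many pairs — calibration checks therefore
evaluate per-pair rates. Degenerate (constant) data short-circuit to
p = 1 with a flag. A `branch` argument can force either arm of the tree,
which is how the type-I calibration of each branch is measured; posthoc
tables can be skipped in large resimulation loops.

## Problem sizes used in validation

The suite validates estimator properties at reduced but statistically
adequate sizes chosen as a deliberate design point: 200 seeded ganglia
for Cavalieri recovery and CE, 100 for disector recovery and CE, 50
patterns per class for the spatial classifier, 1000 resimulations per
branch for type-I calibration, and 12–20 simulated studies for pipeline
nulls. At these sizes the Monte-Carlo standard errors are several times
smaller than the tolerance bands being asserted.

## Known limitations

- Phantoms are spatially homogeneous within the ellipsoid; real ganglia
  have density gradients, vasculature and anisotropic soma shapes, so
  passing recovery tests demonstrates estimator correctness, not
  robustness to biological heterogeneity.
- No optical artefacts are simulated (lost caps beyond guard-zone logic,
  over-projection, staining penetration gradients); the Z histogram of a
  phantom is uniform by construction.
- Shrinkage is axial only and uncorrected in the volume estimate
  (estimates are "apparent" volumes, comparable across groups under the
  equal-shrinkage assumption).
- The TUNEL field simulator counts true labels inside square fields; it
  does not model detection error in label assignment.
- Section windows are analytic ellipses; irregular real section outlines
  enter only through the generic polygon interfaces.
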