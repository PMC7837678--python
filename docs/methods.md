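# Methods

This note documents the models and procedures implemented in `combmorph`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Tree representation and geometry

Reconstructions are rooted geometric trees: per node a 3D position (µm), a
radius, and a parent index (`-1` at the single root).  Although
coordinates are 3D, all analyses treat the arbor as planar: these sensory
dendrites adhere to the 2D body wall, so spanning areas, orientation
angles, MST costs and growth all use (x, y); z is carried through
unchanged.  SWC I/O uses the common 7-column whitespace dialect (1-based
ids, `#` comments); coordinates are written with `%.17g`, so a
write→read round trip is bit-exact.

`resample_tree` redistributes nodes at a fixed spacing along each branch,
preserving section endpoints and therefore the topology and the total
cable length exactly; the final segment of a branch may be shorter, and a
branch shorter than the spacing collapses to its two endpoints (this is
documented behaviour, not an error).  The convention of fine resampling
(0.1 µm) for arbors under 400 µm of cable and coarse (1 µm) above is
exposed in `RunConfig.resample_spacing` and applied per reconstruction;
whether to apply the threshold per time point or per series is a
configuration decision left to the caller (per time point by default).

A *terminal branch* is the cable between a termination point and the
nearest branch point toward the root; for a path graph the single terminal
branch starts at the root.

The spanning-field area S defaults to the **convex hull** of the
(resampled) node cloud.  A tight concave hull (shapely's connected,
hole-free concave hull) is available via `method="concave"` and is used
for the growth-arena contour, where a tight boundary is the point.  The
concave variant was not adopted as the default area because a
fixed-radius alpha complex fragments sparse clouds (lateral branches a few
µm apart) into slivers, destroying area normalisation and cable density;
the convex spanning field is also what the scaling analysis requires to be
stable across tree sizes.

## Main-branch detection and alignment

The main branch (MB) is the reference axis for all orientation measures.
It is found by a fixed-point iteration: (1) rotate the tree about the root
so the tip of the metric longest path is vertical above the root at the
origin; (2) compute the bounding box and find the nodes nearest the
top-left and top-right corners; (3) define the MB tip as the first node
shared by their two root paths; (4) re-rotate and repeat until the MB tip
is unchanged (ties in corner-nearest nodes break to the lowest node
index; non-convergence after 50 iterations raises an error carrying the
last state).  The procedure is equivariant under rigid motions of the
input, which the test suite asserts by property testing.

Because the converged MB tip is the *last shared branch point*, the short
piece of cable between it and the anatomical top of the MB would
otherwise be classified as a lateral branch with a near-zero angle.  The
aligned tree therefore also carries `mb_full_path`: the continuation of
the MB through the straightest child (folded segment angle < 20° from
vertical) until the cable bends away.  Lateral subtrees, branch tables
and retraction eligibility use the full path; the 20° threshold is safe
because genuine second-order laterals leave the MB at much larger angles.

## Branch length order and orientation angles

Branch length order (blo) is recursive: within each lateral subtree the
metric-longest root-to-tip path is order 1 ("second-order" branches,
sprouting directly from the MB); the longest paths branching off an
order-k path are order k+1 ("higher-order", blo ≥ 2).  Ties between
equally long competing paths break to the lowest terminal node index.
The implementation is validated against an independent recursive oracle.

Per-segment orientation angles are computed from the inverse tangent of
the segment vector in the aligned frame and folded into [0°, 90°]: 90°
means the segment runs along the anteroposterior axis (the direction of
crawling contractions), 0° along the MB.  Folding reflects that the
measure is an orientation, not a direction — the reported range is
0–90° only.  Zero-length segments yield missing values and are excluded
from summaries.

## The 49 branching statistics

`compute_morphometrics` returns the 49 statistics enumerated in
`MORPHOMETRIC_NAMES`: counts and branch orders (topological order, +1 at
every branch point from 0 at the root), Van Pelt partition asymmetry
(|l−r|/(l+r−2) over branch points; undefined with < 2 branch points →
NaN, not an error), lengths, diameters, surfaces (π·d·len per segment)
and volumes, isoneuronal tip distances (mean-of-means and mean-of-minima
over nodes off each tip's root path), Euclidean and path distances and
compactness (distance / (branch order + 1)), per-branch tortuosity
(path length / chord, branches defined by blo), branching angles between
daughter segments, spanning area and cable density, a space-filling
statistic (fraction of 1 µm mesh cells of the spanning field visited by
the cable — the mesh size is configurable since the statistic is defined
only up to a resolution), aligned bounding-box width/height/ratio, MB
ratio (MB length / box height), terminal counts and lateral density,
perpendicularity (mean lateral segment angle), branch-length statistics,
diameter/length extremes, and the scaled length (total length after
isotropic rescaling to a 100 µm² spanning area; the rescaled tree's
recomputed area is within 0.1% of the target).

## Bootstrap median test

All group comparisons use an empirical bootstrap for the difference of
medians, avoiding distributional assumptions: both groups are resampled
(with replacement, original sizes) from the *pooled* data to build the
null; the two-sided p-value uses the +1 small-sample correction.  The
pooled-resampling null was chosen because the procedure is published
without the null construction; n_boot defaults to 10,000.  Calibration:
the empirical type-I error at nominal 0.05 is 0.04–0.05 at sample sizes
representative of per-tree branch counts (n ≈ 150); at very small n
(≈ 30) median discreteness makes the test conservative (≈ 0.025), which
is the expected behaviour of resampling tests on medians, not a defect.

## Wire-optimality scaling and the MST ensemble

For planar wire-minimising trees, L ≈ √(S·N/π).  The synthetic comparison
ensemble grows greedy MSTs: targets scattered uniformly over a 100 µm²
square (circle optional) are connected one at a time — always the
globally cheapest pair — to the tree node minimising
`d + bf·(plen + d)`, with bf = 0.2, the root at the region centre, and
ties broken to the lowest target index.  Trees are recorded at
intermediate target counts (every 25 by default, a scaled-down version of
recording at every count) up to 500 targets; each recorded tree is
normalised to a 100 µm² spanning area and the ensemble is fit by OLS of
L on √N.

Measured behaviour: the fit is tightly linear, R² ≈ 0.98 (0.979–0.981
across seeds at 100 simulations).  The fitted slope, with N counted as
branch points, is ≈ 13.5 — well above the idealised constant
10/√π ≈ 5.64 of the law.  This is a geometric property of the MST
construction (branch points are ≈ 23% of connected targets, and the MST
length constant for uniform targets exceeds π^{-1/2}), so the ensemble
reproduces the square-root *form* of the law, not its idealised
prefactor.  The corresponding acceptance test records this honestly and
fails; the R² check is the meaningful reproduction.

## Curvature model

Cuticle folding during a crawling contraction is approximated by bending
onto a cylinder of radius R.  A branch of length L_b at orientation θ to
the cylinder axis follows the ellipse cut by its plane, with
semi-diameters a = L_b/2π and b = a/sin θ, approximated by a circle of
radius Rc = (a+b)/2 (equivalently 1/sin θ = 4πRc/L_b − 1).  For a thin
branch tube (R ≫ r) only the first principal curvature changes; its
increase normalised to the fully bent branch (θ = π/2) is

    c(θ) = 2·sin θ / (1 + sin θ),

rising strictly from 0 to 1 and independent of both L_b and R.  The
closed form was re-derived from the Rc construction and is verified in
the tests against a numeric oracle that samples the plane–cylinder
intersection, refines the semi-diameters by bounded scalar optimisation,
and agrees to better than 1e-9.  Per branch, segment values are
aggregated as a segment-length-weighted mean (chosen for resampling
invariance; the plain median is emitted alongside, since either summary
is defensible).

## Retraction schemes

Given a pre-retraction tree and the observed drop in branch points
(`plan_removal_count`: maximum branch-point count minus the subsequent
minimum), four schemes remove that many terminal branches: shortest
first, lowest mean orientation angle first, highest blo first, or
uniformly at random (averaged over 100 repetitions by default).  The MB's
own terminal piece is never eligible.  After each removal the tree is
re-dissected and re-sorted, so cable exposed by a removal becomes
eligible — chosen because removing one daughter genuinely merges the
sibling into a longer terminal branch; `resort=False` reproduces the
static-list alternative.  Each removal reduces termination points by
exactly one, branch points by one or zero (zero when the origin keeps
≥ 2 children), and total length strictly.

`compare_schemes` scores each scheme against the real post-retraction
tree by branch-point/terminal/higher-order count errors, total length,
Wasserstein distances between branch angle and bending-curvature
distributions, and a bootstrap median-angle test.  On synthetic series
whose ground-truth mechanism is uniform random removal, the random scheme
has the smallest mean angle-distribution distance when aggregated over
several series; single series are noisy, which mirrors why the original
comparison pooled nine neurons.

## Single-branch tracking

Branch correspondence between consecutive 1-hour frames is taken from a
registration table (frame, node_id, track_id) of termination points —
produced manually for real data, exactly by the generator for synthetic
data; automatic registration is out of scope.  Matched branches are
classified by the change in their dissected length: |Δ| ≤ 0.3 µm
(approximate lateral optical resolution; configurable) → stable; larger
changes → elongated/shortened; unmatched branches → retracted (present
only at t₀) or new (only at t₁).  Rates are Δlength per hour.  Per-bin
summaries use right-closed bins on the event end time with the hourly
edges 17.5…21.5; class fractions sum to 1 over classified branches.
Tracks are maintained per consecutive frame pair only.

## Growth model with timed stochastic retraction

The simulator develops an arbor inside the 2D contour of a spanning
field, starting from an existing MB, between 16 and 22.5 hrs AEL in
15-minute iterations.  Per iteration the arena is probed with
N = 100,000 uniform random points (scaled-down runs use 5,000); each
probe's shortest distance to the tree is capped at the active growth
radius (2.5 µm before 19.5 hrs AEL, 1.81 µm after — the mean lengths of
newly formed branches in the tracking data); one target is drawn with
probability ∝ d^γ where γ = k/(1−k) maps the noise parameter k ∈ [0, 1]
from uniform (k = 0) through linear preference (k = 0.5, the default) to
greedy-farthest (k → 1) — the mapping is a declared convention, and the
tests exercise distribution-level outcomes rather than the mapping
itself.  The target is connected to the tree node (cable resampled at
0.1 µm) minimising `d + bf·(plen + d)` with bf = 0.2, the new cable
clipped to the growth radius and rejected if it would leave the contour.
Branch additions per iteration are Poisson with mean B_r (deterministic
rounding available), and growth iterations run until 19.5 hrs AEL when
retraction is enabled (to the end otherwise).

At the hourly time points 16.5…21.5 a retraction step fires: a random
fraction of lateral terminal branches (the combined retracting+shortening
class fraction of that time bin) have their tips shortened by the bin's
mean retracted-branch length; branches no longer than that are removed
entirely; then the bin's newly-formed fraction of branches is added
through the growth machinery (these additions are in addition to B_r).
Fraction-to-count conversion rounds half up with a minimum of one branch
when the fraction is positive.  Retraction is applied after the growth
iterations of a coinciding time point.

`extract_growth_parameters` measures every constant from data: B_r as the
mean branch-point increment per 15 minutes over 16–19.5 hrs AEL (pooled
over the series; a net-loss window clamps to zero rather than a negative
rate), per-bin fractions and retracted lengths from the event table, and
the growth radii from mean new-branch lengths before/after 19.5 hrs AEL.
No parameter is fitted to morphometric outcomes.

Measured ensemble behaviour: with retraction disabled, branch counts are
non-decreasing and the ensemble follows the square-root wire-scaling law
with R² ≈ 0.97 after area normalisation; with retraction parameterised
from a planted comb time-lapse, the median lateral orientation angle
rises by several degrees between the branch-point peak and the end of
development, reproducing the angle-enrichment effect of random pruning
(short, flat-angled higher-order branches are removed whole; long
second-order laterals only lose tip cable).

## Kinematics and calcium

Segment contraction is the sum of distances from a central soma to its
anterior and posterior neighbours, normalised per trial so 0 is maximal
distension and 1 maximal contraction (a constant distance is an error —
normalisation would be undefined).  ΔR/R₀ uses R = F_green/F_red with R₀
the mean over the first five frames; frames with a zero red channel are
missing.  Trials are aligned to maximal contraction (ties: earliest
frame), each ΔR/R₀ trace is normalised by its positive maximum, and
mean ± SEM are reported only where at least five trials contribute
(configurable).  The reported peak lag is the time of the mean ΔR/R₀
maximum relative to maximal contraction; at the 0.2 s frame interval a
planted 0.2 s lag is recovered frame-exactly once ~25 trials are
averaged (single noisy trials can mislocate the peak, which is why the
alignment averages first).

## Synthetic data

The generators define the study conditions and every estimator's ground
truth:

- **Comb trees**: vertical MB (30 µm) with 12 alternating-side laterals;
  second-order lengths log-normal with median 6 µm and angles
  Normal(63°, 8°) clipped to [0°, 90°]; higher-order branches (Poisson
  mean 1 per lateral) with median length 1.8 µm and near-flat angles
  (uniform 5–85°), attached in the middle portion of their parent and
  kept shorter than the remaining parent cable so the planted blo is
  unambiguous.  These medians emulate the reported embryonic branch
  statistics; they are defaults of the generator, not measurements.
- **Time-lapse series**: planted per-interval fractions of retracted /
  shortened / elongated / new branches with |N(2.5, 0.5)| µm/hr rates
  (the 2–3 µm/hr regime), exact tip registration, and an event table in
  the tracking schema.  Removals and sprout sites are restricted to
  positions where the edit cannot silently change another registered
  branch's dissected length (no sibling merge into a registered terminal
  branch, no splitting of a registered branch's cable), so the planted
  table is exact ground truth; the MB tip is left unregistered.  This
  restriction makes planted removals very slightly non-uniform over
  branches — an accepted trade for exactness.
- **Peristalsis**: smooth contraction bumps with a configurable lag and a
  fluorescence transient built as the lagged waveform plus Gaussian noise
  scaled so the planted Pearson correlation (0.85) holds in expectation.

What the generators do **not** emulate: imaging noise and tracing errors,
anisotropic body-wall deformation, sub-hour branch dynamics, 3D arbor
structure, and biological variability across neurons beyond the planted
distributions.  Passing the recovery tests therefore demonstrates the
correctness of the estimators and simulators, not the biological fidelity
of the defaults.

## Problem sizes

The shipped test-and-acceptance configuration uses 100 MST simulations
(vs 1,000 in the original ensemble), growth ensembles of 12–50 runs with
5,000 probe points (vs 100,000), 2,000 bootstrap calibration simulations
at n_boot = 1,000, and 25-trial calcium averages; all sizes are ordinary
function arguments, and the full-size settings are the library defaults.

## Known limitations

- The MB-extension heuristic (20° straightest-continuation walk) can, in
  principle, annex a genuinely near-vertical lateral attached at the MB
  tip; this does not occur for realistic comb geometries.
- The MST slope question discussed above: the ensemble reproduces the
  square-root scaling form, with a prefactor set by MST geometry rather
  than the idealised π^{-1/2}.
- `compare_schemes` on a single series is noisy by nature; conclusions
  should be drawn from aggregates.
- Registration is assumed exact; no correction for registration errors is
  attempted.
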