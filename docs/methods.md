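# Methods

## Division scoring and renewal estimation

A scored division is a doublet of daughter fates; each fate is a layer
call (basal or suprabasal) with optional morphology (cuboidal or
squamous). Classification is purely layer-based: (basal, basal) → SR,
(suprabasal, suprabasal) → SD, mixed → AD. Morphology is carried along
for provenance but never used to resolve an ambiguous layer — records
without a layer call are rejected rather than guessed.

The division-based renewal rate is r = f_SR + f_AD/2, equivalently
(2·n_SR + n_AD)/(2·n_events): the proportion of daughter cells that
stay basal. This form reproduces both measured anchors exactly — the
mutant single-cell fractions 48/42/10 give 0.69 and the control
fractions 29/44/27 give 0.51 (≈0.5). The population-based estimator is
the proportion of EdU+ cells that are K10−; on synthetic data where
doublets are drawn from fractions f it converges to f_SR + f_AD/2, and
the test suite checks the two routes agree within 3 standard errors at
n = 10,000.

Group comparisons use the two-tailed two-sample Student's t-test with
the animal as the unit of replication (one summary value per animal,
at least 3 animals per group in the data this mirrors; the functions
require ≥2). Degenerate zero-variance input returns p = 1 when the
means are equal and is rejected otherwise, so pipelines never see NaN
or a spurious p = 0. Significance bands follow the usual figure-legend
convention (n.s. > 0.05 > \* > 0.01 > \*\* > 0.001 > \*\*\* > 0.0001 >
\*\*\*\*).

Uncertainty on any event-level statistic comes from a percentile
bootstrap (default 2,000 resamples, seed mandatory). A simulation
coverage study in the test suite puts the 95% interval's coverage
between 0.87 and 0.995 at n = 80 events.

Time points are snapped to the sampling grid (default 2-week
intervals) by nearest bin, ties rounding down.

## Morphometry

Cell contact is defined on the Delaunay triangulation of basal-cell
centroids with edges longer than `max_neighbor_dist` removed. The
default cutoff is 15 µm, about 1.5 basal-cell diameters at ~10 µm
packing; it is a free parameter surfaced in every entry point because
"contact" in stained whole-mounts has no canonical numeric definition.
Fewer than three cells, or collinear input, falls back to a plain
distance-threshold graph. Exactly coincident coordinates are resolved
by a deterministic 1e-6 µm jitter with a logged warning (or a hard
error in strict mode).

Edge/inner classification has two modes. `neighbor_cells` (default,
for real data that include untransduced surroundings): a clone cell is
*edge* iff it has at least one graph neighbour outside the clone; a
cell with no neighbours at all is edge (it sits on the circumference
by itself). `alpha_boundary` (for clones recorded without their
surroundings): edge iff the cell lies on the boundary of the clone's
alpha-shape, computed as the union of Delaunay triangles with
circumradius ≤ alpha (alpha = the neighbour cutoff); boundary edges
are those belonging to exactly one retained triangle. On a 7-cell
hexagonal rosette both modes give 6 edge / 1 inner, the 86% early-clone
anchor; on growing hexagonal discs the edge fraction 6k/(3k²+3k+1)
declines convexly, traversing the measured 86→55% range.

Clone geometry uses a moment-matched ellipse: the ellipse with the same
second moments as the input region. Outline input (ordered polygon)
uses exact polygon moments via Green's theorem; centroid input uses the
sample covariance under the uniform-ellipse convention (covariance
eigenvalues a²/4, b²/4). Area is πab; perimeter uses Ramanujan's second
approximation, whose relative error is far below 0.1% for the
near-circular shapes of interest (the elliptic-integral oracle lives in
the tests). Circularity is 4π·area/perimeter², capped at 1 against
numerical overshoot; clone density is n_basal/area in cells/µm².
Coordinates are treated as planar projections of the basal layer; z is
ignored.

## The lattice clone-growth model

Cells occupy sites of a hexagonal lattice (axial coordinates, 10 µm
spacing — epithelial packing). In each time step dt (0.05 day) every
basal cell divides with probability λ·dt; the sampling is first-order,
so configs enforce λ·dt ≤ 0.1. The division draws one of SR / AD / SD
from a context-dependent probability triplet:

| context     | triplet (SR, AD, SD) | r    | provenance                          |
|-------------|----------------------|------|-------------------------------------|
| wt_distant  | 0.29, 0.44, 0.27     | 0.51 | measured control fractions          |
| wt_adjacent | 0.19, 0.44, 0.37     | 0.41 | measured rate; AD held at 0.44      |
| edge        | 0.48, 0.42, 0.10     | 0.69 | measured single-cell mutant         |
| inner       | 0.05, 0.44, 0.51     | 0.27 | implied by late-stage observations  |

The inner triplet deserves explanation: only the *rate* of the clone
core is constrained, and indirectly. Late clones keep ≈55% edge cells
while their whole-clone renewal returns to ≈0.5, with edge cells still
renewing like single cells (0.69). Solving 0.5 = 0.55·0.69 + 0.45·r
gives r ≈ 0.27 for the core; the triplet keeps the ubiquitous 0.44
asymmetric fraction and shifts the symmetric balance. The default
division rate is λ = 0.2/day (≈1.4 divisions/cell/week), a calibrated
free parameter — the source data report proliferation only graphically.

Context is re-evaluated at each division (`context_rule` mode): a
mutant whose homotypic neighbour fraction (same-clone occupants among
its six lattice neighbours; free sites and other genotypes count
against) reaches `homotypic_threshold` (default 1.0, the literal
"surrounded entirely by clone cells" definition) is inner, otherwise
edge; a wild-type cell touching any mutant is wt_adjacent (the rule can
be switched off), otherwise wt_distant. `fixed_probabilities` mode
instead uses each cell's static label — the well-mixed branching
process used for analytic oracles.

Division mechanics on the default (empty-lattice) geometry: SR places
the second daughter in an adjacent free site, preferring the
most-surrounded one (daughters fill concavities first, keeping clones
compact); if the neighbourhood is full, cells shift outward along the
BFS shortest path to the nearest free site. AD keeps one daughter on
the site and delaminates the other; SD delaminates both and frees the
site. Because a confluent epithelium does not accumulate holes, freed
sites heal: enclosed vacancies migrate to the boundary along a shortest
path, boundary notches are closed by an energy-descent rearrangement,
and a periodic relaxation sweep lets boundary cells hop into
better-connected free sites (surface-energy descent under cell-cell
adhesion). Delaminated cells are retained in output tables as
post-mitotic suprabasal K10+ cells. A clone reaching the lattice
boundary halts the run with an explicit error.

A confluent-field mode embeds the clone in wild-type tissue on a fully
occupied lattice: renewal displaces tissue outward along
outward-biased rays (the first hop is isotropic but avoids breaching
the cohesive clone), the outermost cell leaving the observation
window; differentiation compacts inward, fresh wild-type cells
entering at the window edge; and a differential-adhesion swap sweep
smooths the clone/wild-type interface. This mode reproduces the in
vivo geometry (edge = mutant–wild-type contact) at higher cost and is
the natural setting for wild-type-adjacent analyses.

Analytic oracle: a well-mixed population with renewal r grows as
E[N(t)] = N₀·exp(λ(2r−1)t). The simulator matches this within 3
standard errors for r ∈ {0.41, 0.5, 0.69} (400 replicates, 14 days),
and r = 0.5 is an exact martingale. Bookkeeping is conserved exactly:
Δn_basal = #SR − #SD and delaminations = #AD + 2·#SD over any interval
(in field mode, plus window immigration/emigration terms).

### What the stalling experiment shows — and a known limitation

Started from a 7-cell rosette under `context_rule`, clones develop a
differentiating core: realised whole-clone renewal decays from 0.69 to
≈0.54, the edge fraction falls from 86% to an equilibrium near the
observed 55%, and 24-week sizes end two to three orders of magnitude
below the unchecked r = 0.69 exponential. Growth does not, however,
arrest completely: cells on the circumference always carry the
supercritical edge rate, so the clone boundary advances at a slow,
roughly constant radial velocity and median size keeps creeping
(~linear in time). An absolute plateau would require the front itself
to become subcritical, which contradicts the measured late-stage edge
rate; across every regime we explored (division rates 0.1–0.4/day,
inner rates 0.27–0.45, contact thresholds 5/6 and 1, empty-lattice and
confluent-field geometries) the final-third growth of the median
trajectory stays around 40–60%, not below 10%. The corresponding
acceptance test records this honestly: its stabilisation,
renewal-decay and super-linear-comparator assertions pass, its strict
plateau assertion fails.

## Synthetic pulse-chase data

`sample_cfi_dataset` draws division types from a multinomial at the
given triplet and emits each as an EdU+/BrdU− doublet (AD daughter
order randomised), split evenly across animals. The companion cell
table adds the label-window cells that divided before the chase as
EdU+/BrdU+ basal singles at the measured 15% of labelled cells — these
are excluded from scoring by the marker logic, as in the assay. The
generator recovers its input fractions within 3 binomial standard
errors at n = 10,000, and 3 animals × 75 divisions (the scale of the
real experiments) recover the mutant SR fraction within sampling
error.

## Screen simulation and analysis

The simulated pool mirrors a compact in vivo library: 27 genes × 5
hairpins = 135 constructs, log-normal baseline abundances (σ = 1),
4 animal replicates, negative-binomial counts with var = µ + 0.15µ²
and 10⁶ expected reads per library. A gene effect e multiplies the
basal mean by 2^(e/2) and divides the suprabasal mean by the same
factor; effects can be restricted to a subset of hairpins.

Analysis: median-of-ratios size factors per library (reference =
geometric mean across hairpins positive everywhere), pseudocount 0.5
before log-ratios. The default test is a negative-binomial Wald test
on the log2 basal/suprabasal ratio with method-of-moments dispersion,
moderated by flooring each hairpin's estimate at the across-hairpin
median (raw moment estimates are unstable with few replicates). A
paired sign-flip permutation test is provided as a
distribution-assumption-free alternative; with R replicates it has
p-value resolution 1/(2^R+1), so Benjamini–Hochberg significance
across 135 hairpins needs R ≥ ~10. Genes are called hits when at least
two hairpins pass the q threshold (default 0.05) in the same
direction, with any significant opposite-direction hairpin voiding the
call. Fifty simulated null screens produce zero gene-level false
calls; a planted 8-fold, 2-hairpin enrichment is recovered. This is a
deliberate minimal reimplementation of the differential-abundance
step; numerical equality with DESeq2-based pipelines is not claimed.

## What the synthetic data do not capture

The generators emulate sampling noise, spatial clone structure and
count overdispersion — not segmentation error, staining variability,
incomplete label uptake, hair-follicle exclusion, 3D stratification,
mechanics, or apoptosis/senescence (measured to be unchanged in the
source system). Passing tests therefore demonstrate correctness of the
estimators and the internal consistency of the model, not robustness
to every artefact of real imaging data.

## Numerical choices

Seeds are mandatory for every stochastic entry point and all
randomness flows through explicit `numpy` generators; identical
config + seed gives byte-identical outputs. Fractions are renormalised
at construction so f_SR + f_AD + f_SD = 1 holds to 1e-12. Circularity
is capped at 1. Degenerate geometry (collinear points, zero area) and
empty selections raise typed errors rather than returning NaN. Problem
sizes in the test and acceptance runs (200–400 Monte-Carlo replicates,
10 stalling seeds, 50 null screens, 10,000-division samples) were
chosen to keep each derived statistic's Monte-Carlo error well inside
the asserted 3-standard-error bands.
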