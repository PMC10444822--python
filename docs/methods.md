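# Methods

## Inhibitory-cascade morphospace test

Tooth area is crown length × crown width (mm²).  For a triplet ordered along
its developmental cascade (premolars: P4, P3, P2, since the cascade runs
back-to-front from the dP4 locus; molars: M1, M2, M3; mixed: P4, M1, M2) the
ratio coordinates are `x = a2/a1`, `y = a3/a1` ("first-tooth denominator"
convention, the default) or `y = a3/a2` ("adjacent").  The cascade line is
`y = 2x − 1`; `x ≤ 0.5` predicts a non-positive third tooth, read as
"absent".

**Membership region.** Published IC morphospace figures shade the permitted
region as triangles without an algebraic definition, so the package's default
is the parameter-free monotone-ordering region — the middle tooth is
intermediate in size, `(x ≤ 1 ∧ y ≤ x) ∪ (x ≥ 1 ∧ y ≥ x)` under the first
convention — which contains the cascade line and is the weakest claim the
cascade makes.  The region is closed (boundary points count as inside, so the
all-equal triplet satisfies the line exactly), an `eps` tolerance band can
widen the boundaries, and an arbitrary union of half-plane intersections can
be substituted where a specific published polygon is wanted.  Both ratio
conventions reduce to the same ordering test, so membership is
convention-independent for any triplet; the convention is still recorded in
every output because the *coordinates* differ.

**Aggregation.** Replicate measurements of the same crown are averaged on
read (triplicate measurement protocol); individuals and sides of one species
are aggregated by mean area per locus *before* ratios are formed (ratio of
means, not mean of ratios, which avoids the Jensen drift of ratio averaging
and is the selectable default).  Species missing any tooth of a triplet are
excluded and counted.  Occupancy is `100 · n_inside / n_species`; an empty
table after exclusions is an error, never 0%.

## Morphometrics

Relative jaw length is `jaw_length / body_mass^(1/3)` — the cube-root
exponent is the only choice that makes a length/mass ratio unit-free under
isometry; the exponent is configurable for allometric alternatives.
Morphogroups combine tooth counts per side of the lower jaw with a jaw-length
class: (3,3) → 3P3ML/3P3MR split at the "long" cut-point, (2,3) →
2P3MS/2P3MR at the "short" cut-point, (2,2) → 2P2MS, (3,2) → 3P2M flagged
marginal, ≤1 molar → excluded (vampire-like reduced dentitions).  Cut-points
default to dataset tertiles of relative jaw length and are echoed in the
output so a classification is reproducible from its artifacts alone.

Per-locus size variability is the sample CV (sd/mean, ddof=1) of
species-mean areas within a morphogroup; loci with fewer than two species
are reported as missing rather than 0.  Growth profiles are first
differences of canine-to-P4 segment length over Carnegie stages, treated as
equally spaced ordinal units (the rate is per stage, not per day — embryonic
absolute ages are unavailable across species); a profile "has a peak" when
some interval grows strictly faster than the profile's floor.

## Growing-domain reaction–diffusion model

The simulator integrates an activator–inhibitor pair

    ∂u/∂t = D_u ∂²u/∂x² + f(u, v),   ∂v/∂t = D_v ∂²v/∂x² + h(u, v)

with zero-flux boundaries.  The default kinetics are the
activator-depleted-substrate (Schnakenberg) family

    f = γ (a − u + u²v),   h = γ (b − u²v),

steady state `u* = a + b`, `v* = b/(a + b)²`, shipped constants
`a = 0.1, b = 0.9, γ = 1, D_u = 1, D_v = 40` (fastest-growing wavelength
λ_c ≈ 14.9 length units, growth rate σ_max ≈ 0.41 per time unit).  A
Gierer–Meinhardt family is registered as an alternate; the choice of family
is deliberately generic — the scientific claim being tested is that *growth*
modulates a Turing cascade, not a specific reaction mechanism.

**Linear stability.** `linear_stability` locates the instability band from
the roots of `D_u D_v k⁴ − (D_v f_u + D_u h_v) k² + det J` and maximizes the
closed-form dispersion relation inside it (bounded scalar minimization,
xatol 1e-12).  It requires the homogeneous state to be stable to uniform
perturbations; kinetics past the Hopf point are reported as not
Turing-unstable.  The test suite cross-checks the fastest-growing wavenumber
against a dense LAPACK eigenvalue scan with parabolic refinement — an
independent route through the same mathematics.

**Growth.** Apical growth (the default, matching localized proliferation at
the jaw's growing front) appends grid cells at the moving end at the
homogeneous steady-state composition, one cell per Δx of accumulated
elongation; there is no dilution.  Uniform growth stretches the whole domain
(Lagrangian formulation with spacing L/(N−1)) and dilutes both species at
rate L′/L; the node count tracks round(L/Δx)+1 by interpolation.  With zero
growth the two modes reduce to the same integrator and produce bitwise
identical trajectories.  Schedules are piecewise-linear (stage, added length
per stage) pairs mapped to simulation time via `time_per_stage` (25 time
units per Carnegie stage in the shipped configs), clamped at zero.

**Numerics.** Operator splitting: explicit Euler reaction step guarded by a
row-sum bound on the reaction Jacobian (abort with a diagnostic when
`dt · max row sum > 2`), then an unconditionally stable backward-Euler
diffusion step solved as a tridiagonal system (mirror-node Neumann
boundaries).  Shipped discretization Δx = 0.25 (≈ 60 nodes per wavelength),
Δt = 0.05; halving both leaves every shipped configuration's event count
unchanged and moves final peak positions by less than Δx.  Fields are never
clipped; the running minimum of u and v is reported so any negativity is
visible.  NaN/Inf aborts the run.

**Initial condition and cascades.** Each cascade is one independent run: a
Gaussian activator bump (amplitude 0.5, width 5Δx) at the initiating bud
locus (dP4 for premolars, M1 for molars) on a domain of L₀ = 12 ≈ 0.8 λ_c —
short enough to hold exactly one peak — plus uniform noise of amplitude 1e-3
from a seeded generator.  The premolar cascade grows anteriorly and the
molar cascade posteriorly (enforced by default); positions are reported as
cascade coordinates (distance from the bud locus), with lab positions
retained.

**Event detection.** At every recorded frame (0.5 time units) local maxima
of u are located with parabolic sub-grid refinement.  A maximum qualifies as
a peak when its excess over u* exceeds both 50% of the largest excess any
established peak has reached and an absolute floor of 0.2 u* (which silences
initial noise).  A qualifying maximum at distance ≥ 0.8 λ_c from every
established peak must persist for 3 consecutive frames before an insertion
event is emitted (hysteresis against transient shoulder maxima); the event
keeps its first-seen time.  Ordinals map to loci in insertion order
(premolar: dP4, dP3, P2; molar: M1, M2, M3) — a temporal mapping: when a
cascade stops early the *last* ordinal is reported absent, which for
premolars compresses the anatomical detail that the middle locus is the one
lost.  The size proxy is the integrated activator mass over the peak's
inhibitory field (± 0.4 λ_c) a fixed delay (12 time units) after insertion;
windows truncated by a zero-flux boundary are completed by mirror
reflection so boundary peaks are not undercounted.

**Gradients.** An exogenous spatial profile m(x) (linear or exponential in
cascade coordinates, with a floor) multiplies one named kinetic constant;
the special target `"f"` scales the whole activator reaction term.  The
Artibeus configuration depresses the substrate production `b` exponentially
toward the posterior (floor 0.4, length scale 30): later molar peaks are
smaller, and a floor of ~0.3 extinguishes the third insertion — the
reduced-then-lost M3 phenotype.  Deepening the gradient monotonically
shrinks the settled mass of the last peak over floors 0.7 → 0.35 before
suppression; the transient proxy at a short fixed delay is noisier, so the
monotonicity property is stated on settled (end-of-run) masses.

**Calibration of the shipped configurations.** The four growth schedules
were calibrated so that each morphogroup reproduces its observed
premolar/molar insertion phenotype under the shipped kinetics: regular jaw —
steady moderate growth (12 units/stage, total ≈ 2λ_c) giving three strictly
sequential insertions per cascade; long jaw — a brief sharp premolar burst
(70 units/stage for 0.4 stage) that opens space for the 2nd and 3rd
premolars almost at once (their inter-insertion interval is ≈ 0.26 of the
regular-jaw interval); intermediate jaw — reduced premolar growth (total ≈
0.9 λ_c) that never opens a third premolar site; short jaw — flat, slow
premolar growth (no growth peak) and the posterior molar gradient above.
The schedules are phenotype-level calibrations, not fits to the embryonic
µCT series, and no quantitative agreement with any external simulation code
is claimed.  Two regimes of growing-domain Turing dynamics matter here:
when elongation is fast relative to peak drift, new peaks nucleate near the
moving end (sequential outward insertion, the regime of all shipped
configs); when it is much slower, established peaks drift apart and new
peaks intercalate in interior gaps — a real behavior of the equations that
the shipped schedules deliberately avoid because it scrambles the temporal
locus mapping.

## Synthetic data generator

The species-table generator emulates a museum measurement campaign over the
radiation: by default 118 species in five morphogroups (35 3P3MR, 25 3P3ML,
28 2P3MR, 15 2P3MS, 15 2P2MS), jaw lengths ordered long > regular >
intermediate > short (30/22/17/13/12 mm) with heavier short-faced frugivores
(45 g) and light nectarivores (12 g), two individuals per species, both
sides, three replicate measurements per crown.  Premolar and molar triplets
are drawn independently: with probability `ic_conformity_rate` (defaults
0.637 molar, 0.08 premolar — the reported occupancies) the triplet lies
exactly on the cascade line with `a2/a1 ~ U(0.7, 1.25)`; otherwise the
middle tooth is inflated to `max(a1, a3) · U(1.1, 1.6)`, which places the
triplet in the forbidden middle-largest wedge under either convention.
Species-level size scatter is lognormal (CV 0.15) shared across loci, so it
cannot flip membership; extra per-locus variance (default: M3 ×4 in 2P3MS)
models labile loci, and 2P3MS carries a 0.6× reduced M3.  Measurement noise
is multiplicative lognormal applied independently to each recorded length
and width (areas are products, and lognormal noise keeps them positive).
Tooth lengths/widths come from a rectangle model `area = length × width`
with a morphogroup aspect ratio (nectarivore teeth thinner and longer,
AR 2.0; short-faced wider, AR 1.0).

Consequences for interpretation: with zero noise, measured molar occupancy
is exactly the binomial proportion of conforming species, so occupancy
recovery tests are calibrated by the binomial standard error.  On the full
default table the measured molar occupancy sits a few points away from the
nominal rate because the short-jaw M3 reduction and variance inflation move
triplets across the boundary — deliberately so, since the emulated tables
carry the same structure.  The generator draws species independently: it
does not emulate phylogenetic covariance, within-locality structure, or any
crown geometry beyond the rectangle, so passing tests validate the
pipeline's statistics, not comparative-phylogenetic claims.

The embryo-series generator writes piecewise-linear canine-to-P4 lengths
over CS19–CS23 from per-interval rates: a moderate peak for regular and
intermediate jaws (100 µm/stage), a three-fold faster long-jaw peak
(300 µm/stage), and a flat short-jaw series — so the long/intermediate
peak-rate ratio recovered by `growth_rate_profile` is exactly 3.0 by
construction.

## Interfaces and reproducibility

All tabular I/O is plain CSV with units in the column names; readers
validate schema, vocabulary (tooth labels P2…M3, dP3, dP4; sides L/R;
stages CSnn) and value domains, reporting the offending 1-based data row.
Write-then-read is the identity on every validated representation.  Each
pipeline output directory contains exactly one `manifest.json` (tool
version, timestamp, resolved configuration, input digests, seeds, stage
timings); `report.json`/`report.md` contain no timestamps, so identical
configuration and seed reproduce them byte-for-byte.  Every stochastic
component takes an explicit seed, and identical seeds give byte-identical
event CSVs and generated tables.

## Known limitations

- 1-D signaling-center placement only: no 2-D/3-D domains, no cusp
  morphogenesis, no tissue mechanics, no deciduous→permanent replacement
  dynamics.
- The ordinal→locus label mapping is temporal; anatomically the premolar
  cascade loses its *middle* locus, which the mapping does not express.
- The 3P2M morphogroup (molar loss with a long jaw) has no shipped
  configuration; the growth-modulation mechanism alone does not produce it.
- Kinetic constants are generic Schnakenberg values chosen for a clean
  Turing band, not measurements; only insertion-count/order/size phenotypes
  are meaningful, not absolute times or concentrations.
- Uniform-growth mode loses resolution between remeshes on very fast
  schedules; apical mode (the shipped default) has no such limit.
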