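# Methods

## The shedding model

Vesicle release is modeled as a compound Poisson process. A cell property
P — volume (fl), Hb mass (pg), or membrane area (µm²) — starts at P0 and
loses an i.i.d. amount ΔP_i at each shedding event; events arrive at
constant rate f (vesicles/cell/day), so the count by age a is
n(a) ~ Poisson(f·a) and

    P(a) = P0 − Σ_{i=1}^{n(a)} ΔP_i,    E[P(a)] = P0 − f·a·E[ΔP].

Assumptions: the rate and the per-vesicle loss distribution do not depend
on cell age or on the remaining stock (supported by vesicle measurements
from stored blood), and vesicles are spheres, so a radius r maps to volume
(4/3)πr³, area 4πr², and Hb mass (4/3)πr³·c_v for vesicle concentration
c_v. Averaging over a population with mean age ā replaces a by ā. The
analytic expectations are left untruncated (they can go negative, which the
inversion arguments use as an infeasibility signal); simulated sample paths
are instead truncated at the last feasible event and flagged.

When a radius *distribution* is supplied, the per-vesicle mean uses the
appropriate radius moment — E[r³] for volume/Hb, E[r²] for area — not the
moment of the mean radius; for right-skewed size distributions the
difference is material and is covered by a closed-form lognormal-moment
test.

## Rate estimation

Circulating vesicle concentration V obeys dV/dt = f·N − α·V with N the RBC
concentration (cells/µL) and α the first-order clearance rate. At steady
state f = α·V/N. The packaged default α = 1425/day comes from fitting
reinfusion time-courses of the remaining labeled-vesicle fraction with the
bi-exponential

    R(t) = p·exp(−α_r·t) + (1−p)·exp(−α_p·t),

a two-population mixture of RBC-derived (fraction p) and platelet-derived
vesicles. The two-parameter mode fixes p from the reported enrichment
(16.7:1 → p = 16.7/17.7 ≈ 0.944) and fits (α_r, α_p); the three-parameter
mode also fits p ∈ [0, 1]. Fitting is unweighted nonlinear least squares
(`scipy.optimize.least_squares`, rates bounded ≥ 0) from five seeded random
starts, with 95% intervals from the linearized covariance at the optimum.
Clearance fits operate in 1/minute (the time scale of the experiments);
steady-state inversion uses 1/day; the ×1440 bridge is centralized and
tested. The clearance rate is measured in rats and applied to human
steady-state counts — an explicit assumption, not hidden.

Independently, the membrane-area budget bounds the rate: a cell that loses
~130 µm² of area over a 120-day life into vesicles of mean radius 83.5 nm
sheds area/(E[4πr²]·lifespan) ≈ 12 vesicles/day.

## Loss budgets and feasibility

For each subject the observed maturation loss is the difference of paired
reticulocyte and total-population means. Cohort deltas use Student-t
intervals with n−1 df on the per-subject differences (this choice, rather
than normal quantiles, reproduces the reference intervals at printed
precision); percent changes average the per-subject ratios (X−X0)/X0,
signed so losses are negative. Concentrations are stored internally in
pg/fl (1 pg/fl = 100 g/dL).

The fraction-of-loss-explained table evaluates f·ā·v(r)/ΔX per subject at a
fixed 100-nm radius (a deliberately generous, ~90th-percentile choice) and
ā = 50 days, aggregating as mean ± SD (ddof = 1). The vesicle [Hb] used for
the Hb row is the subject's total-population mean [Hb]; "the shedding
cell's concentration" is ambiguous between reticulocyte, total-population,
and trajectory-averaged values, and the total-population reading is adopted
on numerical grounds (it reproduces the reference fractions) and flagged
here. The inverse solvers answer the converse questions: the volume loss of
16.4 fl at the largest empirical rate (f = 8.97) would require ~206-nm
vesicles (twice any reported mean radius), and at the largest reported mean
radius (93 nm) would require f ≈ 97/day — an order of magnitude above any
estimate. The feasibility report checks the empirical box
f ∈ [0.05, 8.97] × r ∈ [53, 93] nm (the membrane-area check uses its own
quoted range f ∈ [4, 13], treated as a configuration default, not a derived
quantity): area is feasible, volume and Hb are not.

## Geometric constraint

Observed fractional area and volume losses are nearly equal
(|ΔS/S₀ − ΔV/V₀| averages 0.9 percentage points on the packaged
two-subject table; "error" is read as the absolute difference in percentage
points, averaged over subjects, with per-subject values also reported). If
fixed-size spherical vesicles carried both losses, ΔS/ΔV = 3/r would have
to equal the cell's S/V. A 100-nm vesicle has S/V = 30 µm⁻¹; RBCs sit near
1.7 µm⁻¹. The verdict is infeasible when the two differ by more than a
configurable factor (default 2 — the physiological gap is ~17×). The
isoperimetric inequality (minimal enclosing area for a volume is the
sphere's, S ≥ 4π(3V/4π)^(2/3)) is enforced on every constructed geometry.

## Dry-mass dynamics

Dry content is Hb plus membrane, with membrane mass and volume proportional
to area:

    M = Hb + ρ_s·v_s·S,    W = Hb/ρ_hb + v_s·S,    D = M/W,

with ρ_s = 1.15 pg/fl, ρ_hb = 1.36 pg/fl. Because ρ_s < ρ_hb, D is a
two-component mixture density strictly inside (ρ_s, ρ_hb). Shedding a
vesicle of radius r and Hb concentration c_v raises D exactly when

    c_v < c* = v_s·s_v·(D − ρ_s) / (v_v·(1 − D/ρ_hb)),

the concentration at which the shed material matches the cell's current dry
density. At physiological states c* is several hundred g/dL (≈700 g/dL at
Hb = 33 pg, S = 140 µm², r = 100 nm), far above the ≤50 g/dL ceiling, so
dry density rises monotonically along every realistic trajectory; the test
suite verifies this path-wise on 10⁴ simulated trajectories per model and
by direct perturbation around c*.

**Membrane volume-per-area (v_s).** The literature-tabulated value of
1.009 fl/µm² would make membrane mass exceed Hb mass, contradicting the
established fact that Hb is ~95–97% of RBC dry mass and the
hundreds-of-g/dL magnitude of the c* bound. We treat that figure as a 10²
scale misprint and default to v_s = 1.009×10⁻² fl/µm², which puts membrane
at ~3–5% of dry mass and reproduces both consistency checks. Both values
are exposed (`v_s_mode` in `RunConfig`).

**The two candidate models.** Initial cells take Hb from a synthetic
reticulocyte cloud and membrane area by volume-matching into a synthetic
(volume, area) reference with S/V = 1.7 (nearest volume; ties to the
smaller area). Both models remove the same observed total Hb (2.9 pg/cell
by default):

- *Model 1* — every vesicle carries the shedding cell's own [Hb], held at
  its initial value (cell volume is not a state variable here, so
  re-deriving [Hb] per event is not attempted). Reaching the Hb target
  requires ~3×10³ vesicles per cell — implied f ≈ 60/day, an order of
  magnitude above any empirical estimate — and more membrane than the cell
  owns, so essentially every cell is flagged infeasible and its trajectory
  truncated at membrane exhaustion, by which point dry density has risen
  far above the narrow measured band.
- *Model 2* — each cell sheds a fixed N = 550 vesicles (the largest
  empirically defensible count; at mean age 50 days this corresponds to
  f = 11/day). The Hb loss is divided among the vesicles *in proportion to
  their volume*, so all of a cell's vesicles share one implied [Hb] (total
  Hb over total volume — the reported quantity; the mean per-vesicle Hb is
  still target/N). Equal division would instead assign small vesicles
  implied concentrations above ρ_hb — a physically impossible per-event
  state that also breaks the monotone-density theorem — so the
  proportional rule is the physically meaningful reading for variable
  vesicle sizes. The density trend stays within the measured band, but the
  implied vesicle [Hb] is ~180 g/dL with the default radius distribution —
  several times past the 50 g/dL ceiling.

Mean-matching aligns simulated initial means to the top-20%-by-mass means
of a reference dry-mass cloud by a multiplicative offset; it shifts the
cloud without changing the mass–density relation (rank structure is
asserted invariant).

## Synthetic data

Generators emulate the statistical shape the analysis assumes, not
instrument physics:

- single-cell (volume, Hb) clouds: bivariate lognormal, moment-matched
  means/CVs (defaults: reticulocytes 104.9 fl / 33.5 pg, total population
  88.8 fl / 30.4 pg — the packaged cohort's means; CVs 13%/12%,
  correlation 0.85);
- vesicle radii: truncated lognormal, mean 83.5 nm, bounds [20, 400] nm.
  The 25% CV is a choice — size spreads of this order are typical of
  extracellular-vesicle data, and the published histograms do not pin the
  width; the bimodal (AFM-like) variant mixes nano (40 nm) and micro
  (120 nm) modes with arbitrary, documented 0.5/0.5 weights;
- clearance curves: the bi-exponential model plus multiplicative lognormal
  noise of stated CV;
- dry-mass clouds: independent lognormal marginals with the measured CVs
  (16.9% mass, 0.3% density), densities resampled into (ρ_s, ρ_hb);
- (volume, area) references: area = 1.7 × volume with multiplicative
  jitter, isoperimetric violations resampled;
- synthetic cohorts: 21 subjects with between-subject spreads matched to
  the packaged table's columns, orderings enforced.

All generators are seed-deterministic (identical seed → identical bytes).
Passing tests on these inputs demonstrates the machinery under the assumed
statistical structure; they cannot certify behavior under real-instrument
artifacts (gating errors, carryover, detection-efficiency drift), which are
out of scope.

## Numerical choices and problem sizes

Tolerances: Monte-Carlo/analytic agreement is asserted within 3 standard
errors; noiseless fit recovery to ≤0.1% relative; monotone-density checks
use a −10⁻¹⁰ slack against float cancellation; isoperimetric checks a 10⁻⁹
relative tolerance. Simulation sizes in the test suite — 10⁴ cells per
dry-mass model, 10⁴ paths in Monte-Carlo population checks, 200 replicates
in the clearance-coverage study, 2×10⁶ samples for radius-moment oracles —
were chosen to keep sampling error well inside those tolerances while the
full suite runs in well under a minute. Cell-population simulations are
vectorized in chunks (512–2048 cells) to bound memory.

## Known limitations

- The clearance rate is a rat-derived constant applied to human counts.
- The model-1 "shedding cell [Hb]" is static at its initial value.
- No age dependence of rate or vesicle size; hooks exist but are untested.
- The non-vesicular loss mechanism is quantified only as a gap, not
  modeled.
- Real dry-mass samples are not packaged; model discrimination is shown
  against synthetic clouds with the measured CVs.
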