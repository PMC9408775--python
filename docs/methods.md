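# Methods

## What is being modeled

The package emulates the measurement layer of a 72 h in-vitro
methamphetamine (METH) dose–response experiment on PC12 catecholamine
cells, at the five doses 0, 10, 100, 500 and 1000 μM. Nothing about METH
pharmacology (transport, vesicular displacement, dopamine oxidation) is
modeled; the generator produces the *measurements* such an experiment
yields — light-microscopy viability and degeneration counts, MitoTracker
densitometry, TEM cell-death assessment, per-mitochondrion ultrastructural
flags and sizes, and immunogold particle counts — with the statistical
structure those assays have, so the downstream operators (scoring,
morphometry, stoichiometry, ANOVA/Scheffè/regression) can be tested
end to end.

## The synthetic cohort

**Units and group sizes.** The analysis unit is the cell (or the
mitochondrion for size/density/stage endpoints), matching the assay
conventions: 300 cells/group for H&E-style survival and dye positivity,
90 for densitometry, 100 for TEM-assessed death, 50 morphometry cells and
150 sampled mitochondria per group, spread over 3 independent experiments
(replicates). Each assay reads the first N cells of the group, split
near-evenly across replicates.

**Distributions.** Binary endpoints (alive, dead-by-TEM, FJB⁺, TB⁺,
damage flags) are Bernoulli; particle and organelle counts are Poisson;
areas and optical densities are log-normal parameterized so the arithmetic
mean equals the configured mean; the matrix/cytosol electron-density ratio
is truncated normal (> 0). Diameters derive from the drawn area via an
ellipse with aspect ratio uniform on [1, 2.5] (d_max·d_min·π/4 = area), so
the recorded triple always satisfies the ellipse plausibility bound —
the joint law of diameters and area is otherwise unspecified in the
source measurements, and this construction keeps it testable.

**Replicate structure.** Each (dose, replicate) carries a multiplicative
N(1, 0.05) random effect on continuous channel means and a beta-distributed
replicate-level rate (concentration κ = 300) for Bernoulli endpoints.
Rates of exactly 0 or 1 stay degenerate, which keeps the control group's
survival at 1 without clipping bias.

**Seeding.** One master seed; the (dose, replicate) substream is
`SeedSequence(master, spawn_key=(dose_index, replicate))`. Identical
(config, seed) pairs reproduce byte-identical CSV output; draw order
inside a replicate is fixed and documented in `cohort.py`.

**Morphometry subset.** Ultrastructure is read on surviving cells: the
first per-replicate share of alive cells carries a full mitochondrion
list; a replicate short of survivors passes its share to later replicates
(the bench equivalent: scanning more grids until N is reached). The
150-mitochondrion sample is drawn round-robin across those cells (first
organelle of each cell, then the second, …) rather than cell-by-cell, so
the sample is not clustered in a handful of cells of one replicate.

**Calibration provenance.** Effect sizes that reproduce a printed value
are listed in `CalibrationConfig.anchored`; every other entry is an
assumed default, enumerable via `assumed_entries()` and logged by the
pipeline. Assumed values were chosen once to preserve the published
orderings: degeneration (FJB/TB) already significant at 10 μM while cell
loss is not; damage probabilities monotone non-decreasing in dose and
maximal at 500–1000 μM; matrix density non-increasing; MTR-G peaking at
100 μM; fission proteins decreasing and Pink1/Parkin increasing, both more
strongly within mitochondria than in cytosol. Two anchors worded as
exceedances ("in excess of 25% of control", "an excess of 200%") are
calibrated strictly above their floors (count fold 1.30, MTR-G fold 2.10).

**Immunogold rates.** The mitochondrial fold of a protein is defined on
the expected per-cell total within mitochondria (the quantity the figures
plot); the per-mitochondrion Poisson rate is that total divided by the
configured count mean at the dose, so the per-cell total scales by exactly
the configured fold even though the organelle count itself changes.

## Rendered patches

Patches are 8-bit grayscale, y-down, pixel-center geometry, no
anti-aliasing (mask areas are exact pixel counts), default 2 nm/px. The
organelle is an axis-aligned ellipse: two dark membrane rings (7 nm)
separated by a light inter-membrane space (8 nm), dark crest bars (6 nm
wide, 40 nm spacing) across the matrix. Damage: dilution brightens the
matrix in seeded disks (SPOTS) or wholesale (WIDESPREAD); broken crests
truncate a seeded contiguous fraction of each bar; ruptured membranes open
the whole envelope over a seeded arc of the perimeter, the opened pixels
reverting to matrix so the organelle area is conserved.

Electron density is inverted gray (density = 255 − mean gray): in TEM,
electron-dense material is dark, and density loss reads as pallor. The
sign convention is a package choice; only orderings across damage levels
are asserted against the source observations, and they are invariant to
global gray rescaling toward white.

## Scoring

A mitochondrion is **altered** iff it shows matrix dilution, broken
crests, or ruptured membranes, alone or in combination; area is excluded
by design (section-plane bias). The **integrity score** is ordinal:
stage 1 ruptured membranes, stage 2 broken crests, stage 3 dilution only,
stage 4 intact. The published rubric names co-occurrence patterns
("broken crests with ruptured membranes and widespread dilution") and does
not cover all 12 feature combinations; off-rubric combinations resolve by
worst-feature precedence (membranes > crests > dilution), consistent with
the rubric's severe-to-slight ordering. In particular, widespread dilution
without other damage is stage 3. The full 12-row decision table is
committed as a test fixture and checked exhaustively. The group score is
the arithmetic mean of per-mitochondrion stages with its SEM ("the
parametric mean of the non-parametric values"); the alternative reading of
the score as a per-group sum is not used, and the choice is recorded here.

An optional adapter (`dilution_from_density`) flags dilution when a
measured density ratio falls below 0.8× the control mean, for use with
rendered patches where dilution is an observation, not a label.

## Statistics

One-way ANOVA (between/within decomposition), Scheffè pairwise contrasts
with critical value (k−1)·F_{α,k−1,N−k}, and simple least-squares
regression with the t test for a non-zero slope are implemented from the
formulas; F and t tail probabilities use the regularized incomplete beta
function and match an independent reference implementation to 1e−10 in
the tests (which also exercise the F = t² and Scheffè-equals-omnibus
identities at k = 2). α = 0.05, configurable. Degenerate inputs: identical
constant groups give F = 0, p = 1; zero within-variance with unequal means
reports the p = 0 boundary with a flag.

The two dose–response regressions (percent cell death vs percent altered
mitochondria; mean area vs percent altered) use the five group-level
summary points, since those are the quantities plotted against dose;
n = 5 is recorded in the result.

`null_calibration()` switches every dose effect off **and** zeroes the
replicate random effect: cell-level ANOVA on replicate-clustered data is
anticonservative, so a size (type-I error) check needs an iid null. The
acceptance suite verifies 5% ± 1.5% rejection over 1000 seeded null
cohorts on the densitometry endpoint.

## What the generator does not emulate

Real micrographs (segmentation of real TEM images is out of scope), time
courses (only the 72 h endpoint), spatial correlation between neighboring
organelles, correlation between a mitochondrion's density ratio and its
categorical dilution label (they are drawn independently), dual-size gold
particle discrimination, and any METH pharmacokinetics. Passing tests
therefore demonstrate that the measurement and inference chain recovers
known ground truth under realistic sampling noise — not that the
biological effect sizes themselves are correct beyond the printed anchors.

## Problem sizes and tolerances

Default runs use the study-scale group sizes above; the convergence test
grows them (~30× cells, 10× experiments) so its 5% relative band is a
\>2σ check against the residual sampling noise. Anchor checks in the run
manifest use ±5 percentage points for population-percentage anchors and
±0.15 for ratio-to-control (fold) anchors; exceedance anchors are checked
one-sidedly. The acceptance script averages three seeded cohorts, the
protocol under which the per-seed binomial noise (±4.8 points on the
TEM-death percentage at N = 100) shrinks below those tolerances.
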