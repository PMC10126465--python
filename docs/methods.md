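# Methods

`sporekit` implements the quantitative layer of a spore-phenotyping study:
single-spore germination kinetics read from phase-contrast time-lapse
recordings, population germination from Tb-DPA fluorescence, viable-count
survival analysis, and a length-based census of Duf421-family proteins.
Because the corresponding wet-lab assays produce no deposited raw data, every
stage is paired with a synthetic generator that knows the ground truth, and
the package's claims are recovery claims on that synthetic data.

## The single-spore intensity model

A dormant spore is phase-bright; germination dims it in stages. We model the
endpoint-normalized intensity of one spore as a continuous piecewise-linear
function of time with four phases:

1. **Lag** (`0 <= t < t_lag`): slow linear decay from 1 with slope
   `leak_slope` (CaDPA leaking out before commitment). The value at `t_lag`
   is `i_lag = 1 - leak_slope * t_lag`.
2. **Rapid CaDPA release** (`t_lag <= t < t_release`): linear drop from
   `i_lag` to `i_release`.
3. **Cortex lysis** (`t_release <= t < t_lys`): linear drop from `i_release`
   to 0.
4. **After lysis**: constant 0.

Non-germinating spores stay at 1. The linear form is a modeling choice: the
assay distinguishes phases, not functional forms, and piecewise linearity
makes the fitting problem exactly solvable, so the fitter can be validated
against brute-force enumeration rather than against itself.

Derived intervals follow the field's definitions: `delta_t_release =
t_release - t_lag` (duration of rapid CaDPA release) and `delta_t_lys =
t_lys - t_release` (duration of cortex lysis). `i_lag` estimates how much
CaDPA leaked during the lag.

## Synthetic data generation

`generate_truth` samples a population: lag times lognormal
(default meanlog `ln 10`, sdlog 0.3, i.e. a right-skewed ~10 min lag),
release durations lognormal around 2 min, lysis durations lognormal around
6 min, leak slopes uniform on [0, 0.008] per min, `i_release` uniform on
[0.25, 0.55]. The lognormal family is a modeling choice — the empirical
distribution of lag times across spores is not established — but the
right-skewed heterogeneity it produces matches what single-spore assays
report. The germinating subpopulation is an exact count
`round(frac_germinating * n)` rather than a Bernoulli draw per spore, so
that population-level expectations (e.g. the fluorescence plateau) are exact
rather than approximate study conditions.

Two constraints keep sampled spores physically and statistically sensible:
`leak_slope * t_lag < 1` (a spore cannot leak more than its content), and
the rapid-release slope is at least twice the lysis slope (capping
`i_release` at `0.95 * i_lag * dt_lys / (dt_lys + 2 dt_rel)`). The second is
an identifiability requirement: if phases 2 and 3 have equal slopes they are
one phase, and no fitting procedure can locate the boundary between them.

`render_stack` draws each spore as a hard disc (radius 4 px) on a uniform
background, with amplitude proportional to the model above, i.i.d. Gaussian
pixel noise, and clipping to the 12-bit range. Frame geometry (1340 x 1024,
12-bit, 1 frame / 15 s) matches the CCD recording conditions of the real
assay. No point-spread function or optics are simulated — detection
difficulty is controlled through the noise level instead — so the rendered
truth stays analytic: with zero noise, the center-pixel trace reproduces the
model to machine precision. Background 150 / amplitude 2400 counts emulate
phase-bright spores on a dim background, so a germinating spore's 20x20
window mean drops by well over half — real traces do the same, which is
what makes the endpoint-drop candidacy rule meaningful. What the generator
does *not* emulate: optical blur, focus drift, illumination gradients,
debris, and spore movement. Passing tests therefore demonstrate correctness
of the analysis pipeline, not robustness to those artifacts.

Plate-reader curves are superpositions of single-spore release schedules
scaled to `total_signal / n`, plus baseline and optional Gaussian noise;
survival tables are Poisson counts with mean
`n0 * 10^(-t/D) * spot_volume * 10^(-dilution)` under first-order
inactivation; protein sets are mutated copies of embedded reference
prototypes at a controlled identity. The prototypes are synthetic
random-residue stand-ins of the correct lengths (231 aa for YetF, 286 aa
for 2Duf), not the biological sequences, which is sufficient because every
census operation depends only on lengths, identities and coverages relative
to a fixed query.

## Trace extraction and normalization

Spores are located in the first frame by Gaussian smoothing (sd 2 px),
thresholding at `median + 5 * MAD * 1.4826` and greedy maximum selection
with a 20 px minimum separation (ties toward the smaller (y, x)). Each
spore's trace is the mean of a 20x20-pixel window, anchored half-open
`[c-10, c+10)` on the integer center. Normalization maps the first frame to
1 and the mean of the last 4 frames to 0; the 4-frame tail (rather than the
single last frame) reduces noise sensitivity and is configurable. A trace
is a *germination candidate* when its relative endpoint drop reaches 0.4;
non-candidates are never force-normalized, because mapping a flat dormant
trace's endpoint to 0 would fabricate a release event. They are retained
for the population germinated fraction. The drop-fraction rule is this
package's operationalization — the original assay does not state how
dormant spores were excluded.

## Breakpoint fitting

For a candidate trace the fitter minimizes SSE over integer breakpoint
triples `b1 < b2 < b3` with knot values fixed at 1 (frame 0) and 0 (from
`b3` on) and free values `v1, v2` at `b1, b2`, under the constraints
`v1 <= 1`, `v2 >= 0`, and a release slope at least `slope_factor` (default
3) times the lag slope — the last prevents the leak phase from absorbing
the release phase on noisy traces. For fixed breakpoints the inner problem
is a 2-variable convex QP solved in closed form (interior solution or the
1-D optimum on one of the three constraint faces); all segment sums reduce
to prefix sums, so a full enumeration costs O(T^3) with small constants.

Traces up to ~60 frames are enumerated exhaustively; longer traces use a
coarse grid (step `ceil((T-1)/60)`) followed by iterated local refinement
(+/- one coarse step, repeated while the SSE improves, at most 10 rounds).
SSE ties resolve to the lexicographically smallest triple. A spore is
called germinated when the piecewise fit improves SSE over the best single
straight line by at least 50% (relative); this rejects flat and purely
linear traces without a separate heuristic. Breakpoints are reported at
frame resolution — no sub-frame interpolation — so one frame interval
(0.25 min at default settings) is the resolution floor of all recovered
times. `i_lag`/`i_release` are the fitted model values at the breakpoints.

## Population germination metrics

Plate-reader curves are baseline-subtracted and smoothed with a centered
moving average (default window 5, which preserves the slope of linear
segments exactly); the germination rate is the maximum centered
finite-difference slope, the plateau is the mean of the final 10% of
timepoints, and the extent is the plateau expressed as a percentage of the
boiled-control (total CaDPA) signal, making it invariant to fluorescence
units. Optimal heat activation is the activation time maximizing the rate,
ties toward the shorter time (less risk of over-activation damage).
Relative CaDPA content per spore is `(boil - blank) / spore_count`, scaled
to 100 for the reference strain.

## Survival analysis

Titers are reconstructed from the largest dilution whose mean spot count
falls in the countable window [3, 30] per 10 uL spot (the bench protocol
counts spots but states no window; the choice is configurable, and the
10-fold dilution arithmetic makes the estimate invariant to which
qualifying dilution is used, in expectation). Outside-window estimates are
flagged; all-zero tables report the detection limit. The decay fit is
ordinary least squares on `log10(titer)` vs time, excluding below-detection
points; `D = -1/slope`, `k = ln(10)/D`. A non-negative slope reports
infinite D (no measurable killing) rather than a negative D. Shoulders and
tailing (Weibull-type models) are deliberately out of scope.

## Homolog census

Candidates are aligned globally (affine gaps, BLOSUM62, open 10 / extend
0.5) against both reference prototypes; the better-scoring query provides
identity and coverage. Identity excludes terminal-gap columns — otherwise
every YetF-like protein aligned to the longer 2Duf query would be
mechanically penalized by ~55 unmatched C-terminal residues. Class is
assigned by length alone: YetF-like 210–253 aa, 2Duf-like 285–290 aa,
otherwise unclassified (ranges configurable per taxon; overlapping ranges
are rejected). Hits pass the filter at query coverage > 85% and, when an
external hit table supplies E-values, E-value < 1e-30; the package never
computes E-values itself (it is not a search engine). Best hit per species
and query defaults to the most significant (smallest) E-value; a literal
largest-E-value rule is selectable. Absolute identity values depend on the
scoring scheme and on the synthetic prototypes, so reproducing any
particular published identity table is explicitly not a goal.

## Problem sizes and numerical choices

The shipped validation suite uses 50 rendered spores (600x400 px frames)
for noise-free recovery, 300 traces at noise sd 0.02 for noisy recovery,
one full-size 1340x1024 frame with 100 spores for detection, 500 spores
for plate-curve consistency, 100 simulated killing experiments for D-value
recovery, and the 36/20/10 protein census — population scales chosen to
match the assays they emulate while keeping a full run in minutes on one
core. Degenerate inputs are handled explicitly: traces shorter than 8
frames and empty frames are errors; zero germinated spores yield a flagged
summary, not an error; exact SSE ties take the lexicographically smallest
breakpoints; `normalized[0] = 1` is exact by construction while the tail
mean is zero to float rounding (~1e-16).

## Known limitations

- Rendered spores are noise-free discs; real phase-contrast blur, drift and
  debris are not modeled, and detection performance on real stacks will be
  worse than the synthetic recall reported here.
- Breakpoint times are frame-quantized; kinetic intervals shorter than ~2
  frames are not resolvable.
- The lag-time distribution family is assumed, not measured.
- The census identity/coverage numbers are scoring-scheme-dependent; only
  the length classification and counting logic are scheme-independent.
- The survival model is strictly log-linear; curved survival data will be
  summarized by a straight line and should be inspected via the per-time
  titers.
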