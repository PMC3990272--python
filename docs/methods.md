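# Methods

## The decision problem

Retinitis Pigmentosa (RP) causes progressive bilateral retinal degeneration;
by the mid-40s most patients are legally blind, retaining at best minimal
light perception. The Argus II epiretinal prosthesis partially restores
visual function. This package implements a cost-utility analysis of
implanting the prosthesis versus care as usual (CAU — nursing care and
rehabilitation), from a healthcare-payer perspective, for a hypothetical
cohort of 1,000 patients aged 46 followed for a 25-year (lifetime) horizon.

## Model structure

A Markov cohort model with annual cycles and four health states ordered by
visual function:

| state | meaning | utility | annual cost (€, 2012) |
|---|---|---|---|
| MLP | minimal light perception (baseline RP) | 0.26 | 11,789 |
| LP (VA+) | light perception | 0.35 | 9,431 (−20%) |
| CF (VA++) | counting fingers | 0.52 | 8,252 (−30%) |
| RL (VA+++) | reading letters | 0.54 | 7,073 (−40%) |

plus a bookkeeping state EXPLANTED for patients whose device was surgically
removed; it carries baseline economics (utility 0.26, cost 11,789 €/yr) so
that explantation can be costed exactly once at incidence.

The CAU cohort stays in MLP for the whole horizon. The implanted cohort is
allocated in cycle 0 to LP/CF/RL with probabilities pVA+/pVA++/pVA+++
(≈0.739/0.205/0.039; see *Working values* below), the small remainder
staying in MLP. From cycle 1 onward patients move up one visual-acuity level
per year with probability 0.10 (LP→CF→RL), and the improved states face an
annual explantation hazard pExplant ≈ 0.017 into the absorbing EXPLANTED
state, applied multiplicatively after the visual-acuity move. Serious
adverse events (SAEs) hit a fraction pSAE = 0.30 of the implanted cohort in
cycle 0 only, costing 1,000 € per event and subtracting a utility decrement
of 0.16 for that year.

There is no death state. This reproduces the source model's implicit
choice — the published 25-year CAU QALY total equals 0.26 × the full 25-term
annuity, which is only consistent with zero mortality — and is recorded here
as a reproduction, not an endorsement.

## Economics

Per cycle, costs are occupancy-weighted annual state costs (stepped as in
the table above, or constant at 11,789 € for the conservative scenario),
plus the device + implantation cost of 90,800 € in cycle 0, per-event SAE
and explantation (2,000 €) costs at incidence, and an annual device-upkeep
cost of 300 € (see *Calibration* for which occupancy carries it). QALYs are
occupancy-weighted state utilities minus the SAE decrement. Both streams
are discounted at 3.5%/year with the first cycle undiscounted — the weight
of cycle t is 1.035^−t — because 0.26 × Σ_{t=0..24} 1.035^−t = 4.435
matches the published 4.44, whereas discounting from t = 1 gives 4.29. No
half-cycle correction, for the same closed-form reason. ICERs are computed
from unrounded totals.

## Working values and the printed parameter table

The published parameter table prints each uncertain parameter's
deterministic value alongside a Beta-PERT range constructed as ±25% of it.
For four transition probabilities the printed deterministic column is
rounded to two decimals while the ranges preserve more digits; inverting
min = 0.75·m and max = 1.25·m recovers the unrounded working values:

| parameter | printed | range | implied |
|---|---|---|---|
| pVA+ | 0.74 | 0.554–0.924 | 0.7389 |
| pVA++ | 0.21 | 0.154–0.257 | 0.2055 |
| pVA+++ | 0.04 | 0.029–0.049 | 0.0389 |
| pExplant | 0.02 | 0.013–0.021 | 0.0171 |

`ParameterSet` stores the printed values and ranges verbatim;
`range_implied_parameters()` recovers the implied working values, and the
calibrated default structure uses them (`mode_policy="range_implied"`). The
policy only touches parameters still exactly at their published defaults —
user overrides and sampled values always pass through. For every other
parameter the implied and printed values coincide to rounding noise.

## Calibration

Every structural reading the source description leaves open is an explicit
field of `StructureConfig`, and `calibrate.enumerate_structures()` builds
the cross-product (128 candidates): allocation semantics, residual-MLP
drift, explantation start cycle (0/1), source states, destination
(absorbing vs recycling to MLP), upkeep-cost coverage, and the working-value
policy. `score_structure` runs all six published scenarios deterministically
and returns the maximum relative deviation over the 42 printed deterministic
cells; `select_structure` picks the minimum and flags the result unresolved
if it exceeds the 1% tolerance (the printed QALYs have only 3 significant
figures, bounding achievable agreement).

The selected structure (frozen as the `StructureConfig` defaults)
reproduces every printed deterministic cell within 0.9%. Two findings are
worth flagging:

* the upkeep cost is attached to the *explanted* occupancy. Covering the
  implanted states instead — the a-priori plausible reading — overshoots
  every cost cell by ≈ €4,400 discounted, and omitting it entirely leaves a
  €400–700 shortfall that the explanted-occupancy stream closes at all
  three horizons. This is most plausibly an artifact of the original
  spreadsheet's cost rows; the package reproduces it because the
  calibration targets demand it, and `others_coverage="implanted"` is one
  switch away.
* only the range-implied working values fit; with the printed 2-dp values
  the best candidate deviates by 3% (and the QALY-increment stream
  identifies pExplant ≈ 0.017 independently of the range inversion).

CAU cells are structure-independent (closed-form annuity) and agree with
the printed values to their printed precision under every candidate.

## Probabilistic sensitivity analysis

Each uncertain parameter is drawn independently from a Beta distribution
rescaled to its published [min, max]. The default parameterization is the
published shape columns, Beta(α₁=5, α₂=5); with symmetric ±25% ranges the
published "Gamma" = 8 classic-PERT variant is *identical* (1 + 8/2 = 5) and
the shape-4 classic PERT is merely wider — all three keep mean = mode, so
the headline PSA results are insensitive to the choice (asserted in tests).
1,000 iterations re-run both arms per draw with a common drawn parameter
set; results are reproducible from the seed.

The three visual-acuity allocation probabilities have wide ranges, and
independent draws exceed a total of 1 in ≈ 39% of iterations. Rejecting or
renormalizing such draws truncates the allocation-mass distribution and
shifts the simulation means well away from the published probabilistic
block (+5–8% on the ICER). Unconstrained sampling — carrying the excess as
a negative MLP residual within the affected draw, exactly what a
spreadsheet remainder cell produces — keeps the means at the deterministic
values and reproduces the published probabilistic results; it is the
default (`on_violation="allow"`, occurrences counted and logged), with
`"normalize"` and `"resample"` selectable for sensitivity analysis. The
stepped cost ordering is likewise not enforced on draws: adjacent state-cost
ranges overlap, and crossing draws are ordinary parameter uncertainty.

Outputs: per-draw CE-plane pairs (ΔC, ΔQ), ratio-of-means probabilistic
ICER (mean-of-ratios also exposed), net monetary benefit, and the
cost-effectiveness acceptability curve over a default WTP grid of
0–50,000 € in 1,000 € steps.

With the published dispersion, ≈ 1.3% of draws have a per-draw ICER above
31,000 €/QALY, so the acceptability curve reaches ≈ 0.985–0.990 there
rather than the 1.00 read off the published figure; the corresponding test
asserts ≥ 0.99 and is expected to sit on that boundary.

## Synthetic parameter sets

`generate_synthetic_parameters(seed)` produces random valid inputs for
property testing: costs log-uniform within a factor of ~3 of the published
values with the stepped ordering enforced, ordered utilities, Dirichlet
visual-acuity probabilities (mass < 1 by construction), ±25% ranges clipped
to [0, 1] for bounded parameters. These exercise the engine's invariants
(mass conservation, path-enumeration oracle, monotone drift) far from the
published inputs; they do not emulate any real RP cohort, so passing
property tests demonstrates engine correctness, not clinical realism.

## Numerical choices and problem sizes

Row-stochasticity is enforced to 1e−9, occupancy conservation to 1e−10;
ties in calibration scores break on enumeration order (stable). The
path-enumeration oracle runs at horizon ≤ 5 where 5^H paths are cheap. The
default test suite runs 1,000-draw PSAs (seconds); the sampling-mean
convergence check uses 10^5 draws of a single parameter. Table rendering
rounds half-up (the printed tables' convention), euros to whole units and
QALYs to two decimals.

## Limitations

* No mortality, so life-years are insensitive to age; QALY gains at long
  horizons are correspondingly optimistic. Inherited from the source model.
* The upkeep-cost-on-explanted finding above means the base-case cost
  streams should be read as a reproduction of the published spreadsheet,
  not as the most defensible economic specification.
* No correlation structure between parameters in the PSA (none is
  described for the source model); no EVPI/EVPPI; no currency conversion
  (the purchasing-power-parity factor behind the 11,789 € baseline cost is
  not published).
* Transition probabilities derive from a 30-patient, two-year device study;
  the 10%/year improvement rate is expert opinion.
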