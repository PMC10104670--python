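# Methods

## Release model

Cumulative release is modelled as three phases with fixed breakpoints:

* burst: 0 → `burst_fraction` over `[0, t_burst]` (default 0.13 by 24 h);
* second phase: linear ramp of `phase2_fraction` over `[t_burst,
  t_phase2_end]` (default 24–96 h; 0.10, 0.15, 0.22 of payload for the
  10.6, 6.5, 3.9 µm classes);
* sustained: zero-order at `sustained_rate` (default 0.004 of payload per
  day) until the `cap` (default 1.0), constant afterwards.

The breakpoints are not free parameters: the assay reports fractions at
exactly 24 h and 96 h, and with eight sampling times freeing them would
cost identifiability for little gain. The intra-burst shape is
unobservable from daily sampling; the default is linear (it reproduces the
printed increments exactly and keeps the PK forcing piecewise constant),
with a first-order saturating alternative (`burst_exponential`, rate
constant 3/t_burst before renormalisation) that agrees at every
breakpoint. Time is carried in hours internally; rates are displayed per
day. Extrapolation beyond the 28-day study continues the zero-order phase
to the cap — a deliberate, conservative choice over inventing a
late-stage erosion model.

## Two-compartment pharmacokinetics

States are drug amounts in synovial fluid and blood; the unreleased depot
enters as a forcing function `R(t) = A_total·f′(t)` rather than a third
state (equivalent for release that does not depend on compartment
concentrations, which is what an in-vitro-derived profile asserts).
Assumptions:

* exchange is unidirectional synovium → blood. The simulated blood
  concentration is 3–4 orders of magnitude below the synovial one, so the
  back-flux term `k_ex,back·C_blood·V_syn` would be negligible;
* elimination acts only on the blood compartment (serum clearance);
  no intra-articular degradation term;
* the system is linear, so trajectories scale exactly with dose — used
  both as a test invariant and for scenario scaling.

### Parameters

| symbol | default | unit | provenance |
|---|---|---|---|
| `V_syn` | 20 | µL | mouse ankle synovial fluid volume |
| `V_dist` | 11 | mL | mouse blood/distribution volume |
| `k_ex` | 0.1 | 1/h | order-of-magnitude synovial permeability |
| `k_el` | ln 2 / 0.75 ≈ 0.924 | 1/h | ~45 min serum half-life of ATRA |
| dose | 2 µg MP at 1.2 wt% | — | a single intra-articular injection |

`k_ex` and `V_dist` were fixed once, inside the stated order-of-magnitude
constraints, such that the default scenario reproduces the three published
model outputs (synovial fluid >6 nM through day 28; blood <20 pM beyond
the burst; blood peak of a few tens of pM). They are calibrated
quantities, not measured ones, and are exposed in the scenario file.

### Solver

Within each output-grid segment the release rate is taken constant at the
value that conserves the released mass over the segment exactly; the
linear system then has a bi-exponential closed form, evaluated with
`expm1`-based helpers so the confluent (`k_ex = k_el`) and near-confluent
cases are exact limits rather than cancellation hazards. For the
piecewise-linear release shape the trajectory is exact; for the
exponential burst the error is the within-segment rate variation (second
order in the grid step over the burst's hourly grid). Eliminated drug is
tracked by per-segment mass bookkeeping, and a post-simulation assertion
enforces the four-pool balance (unreleased + synovial + blood +
eliminated = dose) to 1e-6 relative. An adaptive DOP853 integration of
the same forcing (rtol 1e-12) is available as `method="numeric"` and is
used in tests to cross-check the closed form to 1e-8.

The default output grid is hourly to day 4 and 6-hourly afterwards, with
all release breakpoints inserted (a missing breakpoint in a user grid is
inserted with a warning, since skipping one biases the segment-constant
forcing). Cmax is refined with a parabola through the three grid points
around the discrete maximum; AUC is trapezoidal; threshold crossings are
located by linear interpolation.

## Release-parameter estimation

With breakpoints fixed, the cumulative curve is linear in
(`burst_fraction`, `phase2_fraction`, `sustained_rate`) for both burst
shapes, so the fit is bounded linear least squares (`lsq_linear`, BVLS)
on the cumulative fractions — additive error on the cumulative readout
matches a supernatant-exchange assay where each sample is an independent
concentration read. Identifiability requires ≥4 distinct times spanning
the 96 h breakpoint.

Uncertainty uses a percentile bootstrap, deterministic given a seed.  The
default resamples *residuals* (inflated by √(n/(n−p)) for the three
fitted parameters) onto the fitted curve. A case bootstrap over replicate
curves is available, but with the typical three technical replicates it
has only three exchangeable units and its 95% intervals were measured at
~65–71% coverage on simulated assays, versus ~92–95% for the residual
scheme — hence residual is the default even for replicated data.
Intervals are widened if needed to bracket the point estimate so that
downstream interval logic never sees an inverted bracket.

## Particle sizing

The pipeline mirrors the classic ImageJ recipe: Sobel gradient magnitude
→ threshold (Otsu by default, since manual thresholds are operator
specific) → binary → hole filling → erosion with the 3×3 cross → 8-connected
labelling → area-equivalent diameters `d_px = 2√(area/π) + 2·iterations`
(each cross erosion removes ≈1 px of radius) → scale by µm/px.

Two empirically motivated details:

* **Edge-band compensation.** The thresholded gradient band straddles the
  true boundary, so the filled mask is dilated by ≈1 px of radius. One
  extra erosion (`edge_compensation_px`, default 1) cancels this; it is
  *not* added back by the diameter correction. On rasterized disks this
  reduces the diameter bias from ≈+2.2 px to +0.1–0.4 px; without it,
  10 px-radius disks are oversized by ~10%.
* **Border rejection before erosion.** A particle clipped by the image
  edge loses its outer edge contour, cannot be hole-filled, and its
  remnant is pulled away from the border by erosion; components are
  therefore rejected based on whether their *pre-erosion* component
  touched the border.

"Volume-averaged size" is computed as the De Brouckere mean
D[4,3] = Σd⁴/Σd³, and the polydispersity index as the squared
d³-weighted coefficient of variation of diameter (the dynamic light
scattering analogue). Both definitions are stated prominently because
instrument vendors rarely print theirs; published PDI values should be
compared only qualitatively.

## Synthetic data

The release generator evaluates the model on the in-vitro schedule
(24, 48, 72, 96 h, then days 7/14/21/28) and adds i.i.d. Gaussian noise
per observation, truncated at zero; curves are deliberately not
re-monotonised, since real replicate scatter produces small inversions.
Noise is additive on the cumulative fraction — the simplest model
consistent with the ± scatter reported on increments — with per-class
SDs 0.006/0.002/0.013 used in the recovery tests. Replicates are
independent; any per-timepoint correlation of a real assay is not
emulated, so passing recovery tests show estimator correctness under
independence, not robustness to correlated plate effects.

The micrograph generator places log-normal-diameter disks by rejection
sampling with a minimum edge-to-edge gap, rasterises them with 4×
supersampled coverage (sub-pixel radii are meaningful), and adds Gaussian
background noise. It emulates the geometry of a well-dispersed SEM field
— bright convex particles on a dark background — but not texture,
illumination gradients, charging artefacts or heavy overlap, so sizing
accuracy on it bounds ideal-case, not worst-case, performance.

All generators take mandatory seeds and are pure functions of
(spec, seed).

## Problem sizes in tests

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path with comfortable statistical margins: 100 random
parameter draws for the solver cross-check, 200 simulated assays × 200
bootstrap draws for CI coverage, 500 assays for estimator bias, and
micrographs of ≤60 disks at 1536² px. The whole suite runs in well under
a minute.

## Known limitations

* The PK model has no back-flux, no intra-articular clearance, and no
  tissue binding; it is a deliberate minimal model of a sink-condition
  depot and its calibrated constants are not measured values.
* Polymer erosion and late-stage particle decomposition are not
  modelled; after the release cap the depot simply stops.
* The sizing pipeline does not split strongly overlapping particles
  (erosion is the only separation mechanism, as in the original recipe)
  and excludes border-clipped particles rather than extrapolating them.
* Fitted-parameter CIs assume exchangeable residuals; systematic assay
  drift would not be captured.
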