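# depotpk

Quantitative analysis of an intra-articular sustained-release drug depot:
release kinetics, two-compartment pharmacokinetics, formulation/dose
arithmetic, and micrograph particle sizing for all-trans retinoic acid
(ATRA) encapsulated in PLGA microparticles.

## The problem

Injecting an immunomodulator such as ATRA directly into an arthritic joint
only helps if its concentration in the ~20 µL of synovial fluid stays in
the bioactive (nanomolar) range for weeks, while the rest of the body sees
as little drug as possible. A PLGA microparticle depot achieves this by
releasing its ~1.2 wt% ATRA payload in three phases: a burst of ≈13% of
the payload within 24 h, a size-class-dependent second phase (+10/15/22%
of payload between 24 and 96 h for 10.6/6.5/3.9 µm particles), and a
zero-order tail of ≈0.4% of payload per day that outlasts a 28-day study.

`depotpk` packages the modelling side of that study for reuse:

* **Release model** — cumulative fraction `f(t) ∈ [0,1]` with fixed
  breakpoints at 24 h and 96 h, either piecewise-linear or with a
  first-order saturating burst, and its rate `f′(t)`.
* **Two-compartment PK** — amounts `A_syn` (synovial fluid, volume
  `V_syn`) and `A_blood` (distribution volume `V_dist`) obey

      dA_syn/dt   = R(t) − k_ex · A_syn
      dA_blood/dt = k_ex · A_syn − k_el · A_blood

  with depot source `R(t) = A_total · f′(t)`, unidirectional
  synovium→blood exchange `k_ex`, and first-order elimination `k_el` from
  blood. Solved exactly segment-by-segment (bi-exponential closed form,
  confluent case included), with an adaptive integrator as cross-check.
* **Exposure metrics** — blood Cmax/Tmax/AUC, synovial Cmin over a
  window, time above a bioactivity threshold.
* **Estimation** — bounded least-squares fit of the release parameters to
  cumulative-release assays, with seeded residual-bootstrap confidence
  intervals.
* **Particle sizing** — the edge-detect → mask → fill → erode → label
  pipeline for SEM-style micrographs, with erosion-corrected
  area-equivalent diameters, the De Brouckere mean D[4,3] = Σd⁴/Σd³ and a
  volume-weighted polydispersity index.
* **Synthetic data** — seeded generators for noisy release assays on the
  in-vitro sampling schedule and for disk micrographs with known ground
  truth, so every stage is testable offline.

The calibrated default scenario (2 µg particle dose at 1.2 wt% loading,
`V_syn` = 20 µL, `k_ex` = 0.1 h⁻¹, `k_el` = ln 2 / 0.75 h⁻¹ ≈ 0.924 h⁻¹,
`V_dist` = 11 mL, 6.5 µm release profile) ships as
`depotpk/scenarios/paper_default.yaml`; the elimination constant comes
from the ~45 min serum half-life of ATRA and the exchange constant is an
order-of-magnitude synovial permeability estimate, fixed once so that the
model reproduces the three published outputs (joint >6 nM through day 28,
blood <20 pM after the burst, blood peak of a few tens of pM).

## Worked example

```bash
python examples/03_pk_simulation.py
```

prints, for the calibrated default scenario:

```
min C_syn, day 1-28:   6.66 nM (threshold 6 nM)
time above threshold:  27.0 days
blood Cmax:            38.2 pM at t = 24.0 h
blood max after 48 h:  18.6 pM (<20 pM)
mass balance residual: 3.6e-16 (relative)
```

The joint stays above the 6 nM bioactivity threshold for the entire
day 1–28 window while systemic exposure peaks at tens of picomolar and
settles below 20 pM — roughly a 350-fold joint-to-blood ratio, which is
the rationale for local depot delivery. The other examples cover
formulation arithmetic (`01`), the three release curves (`02`), fitting
noisy assay data with bootstrap CIs (`04`), sizing a synthetic micrograph
(`05`) and the cross-size exposure table (`06`).

A thin CLI wraps the same functions:

```bash
depotpk simulate --out timecourse.csv
depotpk metrics --timecourse timecourse.csv --threshold-nM 6 --window-days 1 28
depotpk synth release --size 6.5um --sd 0.01 --replicates 3 --seed 11 --out release.csv
depotpk fit-release --data release.csv --boot 1000 --seed 7
depotpk synth micrograph --n 50 --d43 6.5 --seed 3 --out img.tif --truth truth.csv
depotpk size-particles --image img.tif --pixel-size 0.05 --erode 2 --out sizes.csv
depotpk run-paper-analysis --outdir out/
```

## Layout

```
src/depotpk/
  formulation.py      feed → loading → dose arithmetic
  release_kinetics.py three-phase release model f(t), f'(t)
  pk_model.py         two-compartment ODE, exact solver, exposure metrics
  estimation.py       least-squares fit + bootstrap CIs
  particle_sizing.py  micrograph segmentation and D[4,3] statistics
  synthetic_data.py   seeded release/micrograph generators
  cli_io.py           scenario configs, CSV I/O, depot-selection workflow
  cli.py              click command-line interface
docs/methods.md       modelling assumptions, parameter provenance, limits
examples/             one narrative script per capability
```
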