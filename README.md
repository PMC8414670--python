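# sptconfine

Single-particle-tracking (SPT) analysis of confined diffusion in rod-shaped
bacteria. The package takes trajectory tables (track id, frame, x, y in
micrometres) as produced by localization/tracking software and answers the
questions a bacterial cell biologist asks of such data: how fast do the
molecules diffuse, how many diffusive subpopulations are there, where and
for how long is motion confined, is the motion Brownian or anomalous, and
how do these behaviours map onto the cell.

## What it computes

* **MSD analysis** — time-averaged and ensemble-averaged mean squared
  displacement; for 2-D Brownian motion `<r^2(t)> = 4 D t`, so the
  five-lag linear fit yields the diffusion coefficient D and its ordinate
  intercept the localization error (`intercept = 4 sigma_loc^2`).
* **Jump-distance decomposition** — pooled single-step displacements
  follow a Rayleigh mixture `p(r) = sum_i A_i r/(2 D_i tau)
  exp(-r^2/(4 D_i tau))`; Levenberg-Marquardt fitting with 1-3 components,
  nested F-tests plus a BIC guard for the component count, and an optional
  simultaneous fit of two datasets with shared D_i and free weights.
* **Confinement** — dwell events (maximal stretches inside a circle of
  radius `R = 2.5 x` mean localization error centred on a trajectory
  node, tolerating one gap or one returning excursion), free/mixed/confined
  verdicts, multi-exponential dwell-time decay `sum A_i exp(-t/tau_i)`,
  and confined/free state-transition counts.
* **Anomalous-diffusion classification** — per trajectory, nested fits of
  `4 K t` versus `4 K_alpha t^alpha` (0 < alpha <= 2) on the first nine
  TAMSD lags, F-test at confidence 0.1; categories Brownian, subdiffusive
  (alpha < 1), superdiffusive (alpha > 1), directed (alpha = 2).
* **Normalized-cell maps** — projection of each cell into a standard
  3 x 1 um rectangle; spot-location heat maps, speed maps (single-step
  `d^2/(4 tau)` over 0.1 um^2 bins), confined/free maps, cell-size
  classes, one-dimensional long-axis profiles.
* **Synthetic data** — a Brownian-mixture simulator (reflecting 1 x 3 um
  cell, 100 sub-steps per frame, 50 nm localization noise,
  photobleaching-limited lifetimes) plus a polar-trap variant with ground
  truth, so every stage is testable without microscopy data.
* **Hydrodynamics** — Stokes-Einstein `D = k_B T/(6 pi eta r_H)` forward
  and inverse, oligomer mass-scaling ratios, and viscosity from
  reference/observed diffusion ratios.

## Worked example

The numbered scripts under `analysis/` form a complete narrative run on
synthetic data; each writes its tables under `results/`.

```
$ python analysis/01_simulate_tracks.py --n-tracks 2000
simulated 2000 tracks (17839 steps) with seed 1
mixture D = (0.08, 0.375, 1.01) um^2/s at (0.1, 0.65, 0.25)

$ python analysis/02_msd_analysis.py
EAMSD 5-lag fit: D = 0.384 um^2/s (R = 0.9995), intercept 0.0153 um^2
mean localization error sigma = 58.1 nm (injected: 50 nm; ...)

$ python analysis/03_jump_distance.py
pooled 16179 jumps; mean 0.1629 um
model selection: k = 2 (p_12 = 1.76e-18, p_23 = 0.582; ...)
  k=2: D_app = [0.43  1.026]  A = [64.7 35.3] %

$ python analysis/04_confinement.py
sigma = 58.1 nm -> R = 145.2 nm
min_steps=5: free/mixed/confined = 517/570/79, 837 events, mean dwell 127.2 ms

$ python analysis/07_hydrodynamics.py
cytoplasmic viscosity: 0.0549 Pa s
hydrodynamic radius of the labelled capsid: 10.468 nm -> tag contribution 2.668 nm
cubic mass-scaling ratio 0.7503 -> predicted D 0.383 um^2/s
```

Reading the numbers: the ensemble D (0.384 um^2/s) sits between the mixture
components because it averages over subpopulations; the TAMSD intercepts
read the injected 50 nm localization noise back as ~58 nm (the estimator
clamps negative intercepts, which biases short-track datasets slightly
high), giving a confinement radius of ~145 nm. At 2,000 tracks the
jump-distance F-test resolves two of the three components — the slowest
population is small (10%) and the 50 nm noise floor pushes all apparent
coefficients up by `sigma^2/tau ~ 0.18 um^2/s`, compressing the component
ratios; the three-way split needs a larger dataset (see
`analysis/06_motion_classes.py` and the acceptance script, which use the
full 50,000-track benchmark). The Stokes-Einstein block converts a
measured 0.51 um^2/s for a 7.8 nm particle into an effective cytoplasmic
viscosity of 0.0549 Pa s, and a 0.38 um^2/s measurement into a 10.468 nm
radius.

The motion census on the full benchmark:

```
$ python analysis/06_motion_classes.py --n-tracks 50000
classified 19374 of 50000 tracks (>= 9 steps)
        brownian:  78.21 %  (n = 15153)
    subdiffusive:  10.07 %  (n = 1951)
  superdiffusive:   5.59 %  (n = 1083)
        directed:   6.13 %  (n = 1187)
```

Brownian motion dominates even though every simulated track is Brownian by
construction: the rejections are the F-test's tail behaviour at nine-lag
resolution, plus genuine wall-induced subdiffusion of the fastest
component in the 1-um-wide cell.

## Layout

```
src/sptconfine/     library: core, msd, jumpdist, confinement, cellmaps,
                    simulate, hydro
analysis/           numbered narrative scripts (01 simulate ... 07 hydro)
tests/              pytest suite, including exhaustive-search oracles
docs/methods.md     model assumptions, estimator choices, limitations
```
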