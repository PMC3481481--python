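# cellshift

Time-course identification of drug-effect dynamics from fluorescent-reporter
cell-shifting assays.

## The problem

Molecularly targeted anticancer agents are more selective than cytotoxic
drugs, so their useful dose is set by *biological effect*, not by toxicity —
which makes single-time-point dose-response readouts inadequate. A
cell-line platform that images a GFP proliferation reporter (e.g. driven by
the MKI67 promoter) hourly across a multiwell dosing plate yields something
richer: for every dose, the time course of the fraction of cells whose
reporter has switched off ("shifted" to the autofluorescence floor).
`cellshift` turns those per-cell intensity tables into estimates of the
*time-varying* drug-effect rate, for preclinical dosing questions like: does
a higher dose change the size of the response, its timing, or both? and
where does the effect saturate?

## The model

Per-cell shifting is switch-like, so each cell at each hour is a Bernoulli
trial and the shifted count in an `N`-cell well is binomial — effectively
Gaussian for the 200–400-cell wells of this design. The drug-well shifted
fraction `ρ₁(t)`, calibrated against pooled drug-free controls
(`ρ(t) = ρ₁(t) − ρ₁c(t)`) and averaged over replicates, follows

    dρ_av/dt = (γ + μ₁)(1 − ρ_av) − (β + μ₂) ρ_av + ν

where `γ(t)` is the drug-effect coefficient (per-hour shift rate of
non-shifted cells), `β(t)` a balancing factor, `μ ~ N(0, Q)` process noise
and `ν ~ N(0, R)` measurement noise. Stacking `w = (γ, β)` as a random walk
observed through `δ(n) = (ρ_av(n+1) − ρ_av(n))/Δt = C(n) w(n) + ν(n)` with
`C(n) = [1 − ρ_av(n), −ρ_av(n)]`, a Kalman filter estimates both rates at
every hour. Traces are then Savitzky–Golay smoothed (span 5, degree 2), the
first 10 h of "commitment time" are discarded, and the plateau of `γ̂` is
located per dose. A seeded Monte Carlo generator reproduces the full plate
design (6 doses 1–32 µM, 6 replicate wells per dose, 36 controls, 48 hourly
timepoints) with known latent rates for validation. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
import numpy as np
from cellshift import CellShiftModel, SimConfig, quantify_plate, simulate_plate
from cellshift.quantify import shift_fraction

cfg = SimConfig(master_seed=1)              # the standard 72-well design
plate = simulate_plate(cfg)
series = quantify_plate(plate)              # calibrated shifted fractions
ctrl = np.vstack([shift_fraction(w) for w in plate.control_wells()])

s = series[32.0]                            # top dose, 32 uM
res = CellShiftModel(s.rho_av, time_h=s.time_grid, dose_uM=32.0,
                     control_rho=ctrl, n_replicates=6).fit()
print(res.summary())
```

```
        Cell-shifting model: Kalman identification
==========================================================
Dose:                32.0 uM
Observations:        48 (steps: 47)
Sampling dt:         1.0 h
Process noise Q:     diag(1e-06, 1e-06)
Measurement noise R: 6.42e-07
----------------------------------------------------------
                    estimate     std err
gamma (final)        0.01442     0.00576
beta  (final)        0.01928     0.01502
----------------------------------------------------------
Converged:           False
Plateau:             level 0.0139, onset 31 h
==========================================================
```

The filtered drug-effect coefficient at hour 47 is 0.014/h ± 0.006; the
smoothed trace plateaus at ~0.014/h from hour 31 ("Converged: False" means
the *raw* estimate is still moving at the default 0.1% tolerance — on noisy
data the smoothed trace is the quantity to read). Averaging the smoothed
trace over the post-burn-in window recovers the latent per-hour shift rate
the plate was generated with:

```python
sm = res.smoothed()
print("post-burn-in mean gamma:", round(sm.gamma_smooth.mean(), 5))
print("latent plateau rate    :", round(cfg.hazard_params.plateau_rate(32.0), 5))
```

```
post-burn-in mean gamma: 0.01116
latent plateau rate    : 0.00985
```

i.e. a 13% relative error at this seed (the 20-seed mean error is ~11%, and
shrinks with more replicate wells). The same pipeline runs from the shell:

```bash
cellshift run-all --seed 1 -o results/      # simulate -> quantify -> identify -> smooth
cellshift report -i results/summary.csv    # per-dose table
```

or stage by stage (`simulate`, `quantify`, `identify`, `smooth`) on CSV
files, including experimental per-cell tables in the documented long format.

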