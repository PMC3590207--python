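# cawave

Stochastic simulation of calcium waves in cardiac myocytes under
**anomalous (space-fractional) subdiffusion**.

Calcium sparks — the elementary release events of clusters of ryanodine
receptors (calcium release units, CRUs) on the sarcoplasmic reticulum —
can chain into propagating calcium waves by calcium-induced calcium
release. Classical Fickian models of sparks predict spatial widths about
half of what confocal linescans measure (the "FWHM paradox"), and they
need unphysiologically large release currents to produce waves. `cawave`
implements the alternative: free calcium spreading by a symmetric Riesz
fractional derivative of order `2 <= beta < 3`,

    dC/dt =  Dx d^b C/d|x|^b + Dy d^b C/d|y|^b
             - J_dye - J_buf - J_pump + J_leak + J_cru ,

with stationary mass-action buffers (fluo-3, calmodulin, troponin, SR and
SL sites), a Hill SERCA pump balanced at rest by a constant leak, and a
lattice of CRUs that fire stochastically with probability
`dt * P_max * C^n / (K^n + C^n)` and inject `I/(2F)` mol/ms for 10 ms,
at most once each. The fractional derivative is discretized with the
right-shifted Gruenwald-Letnikov formula with reflecting walls; diffusion
is advanced by exact per-direction matrix exponentials, reactions by
explicit Euler at `dt = 0.005 ms` on a `0.1 um` grid. At `beta = 2` the
scheme is exactly the classical reflecting-wall Laplacian.

The package encodes the defining experiments as built-in scenarios: a wave ignited by one forced corner spark, a middle-initiated
wave, two colliding waves, and physiological-current (2 pA) protocols in
which one spark dies out but four adjacent sparks ignite a wave. Measured
outputs are wave velocities (from CRU firing-onset regression), wave
amplitude, spark FWHM/FDHM, wall-arrival times and linescan images.

See `docs/methods.md` for the model, numerics, calibration and known
limitations (in particular: with the release source calibrated to the
reported wave *velocities*, developed-wave *amplitudes* run several-fold
above the reported values — a 2-D/3-D geometry effect discussed there).

## Worked example

Run the miniature fixture scenario (4 x 4 um, 3 x 3 CRUs, 20 ms) and then
a corner-initiated wave at `beta = 2.25`:

```
$ cawave simulate --scenario mini_fixture --seed 7 --outdir runs/mini
run complete: 2 CRUs fired; outputs in runs/mini

$ head -4 runs/mini/firing_log.csv
# units: x_um,y_um in um; t_fire_ms,t_close_ms in ms
cru_index,x_um,y_um,t_fire_ms,t_close_ms
4,2.0,2.0,0.0,10.000000000000163
7,3.0,2.0,13.480000000000707,
```

The forced centre spark (opened at t = 0, closed at 10 ms) recruited one
neighbour at 13.5 ms — the elementary fire-diffuse-fire step. `runs/mini`
also contains per-snapshot fields (NPZ), the per-step peak trace, a 16-bit
linescan TIFF + CSV, computed metrics, and a JSON manifest recording every
parameter and the seed needed to reproduce the run bit-for-bit.

From Python, one corner-wave run of the fractional-order sweep:

```python
from cawave import protocols

row = protocols.corner_wave_metrics(beta=2.25, seed=42)
print(row)
# {'beta': 2.25, 'seed': 42, 'vx': 96.9, 'vy': 48.2,
#  'amplitude': 1306.5, 'n_fired': 80}
```

`vx` is the longitudinal wave velocity in um/s — the slope of CRU
first-firing distance versus onset time along the initiation row (first
two onsets excluded), here ~97 um/s as expected for `beta = 2.25`;
`vy` is the (slower) transverse velocity; `amplitude` is the maximum free
calcium (uM) reached anywhere during the run — far above the reported ~110 uM, for the geometry reasons laid out in the methods
note. The full sweep, as a table of seed means +- SD over the four
fractional orders:

```
cawave sweep-beta --betas 2.0,2.05,2.15,2.25 --seeds 8 --outdir runs/sweep
```

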