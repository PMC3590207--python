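# Methods

## The model

`cawave` simulates calcium waves in a two-dimensional sheet of cardiac
cytosol as a stochastic fire-diffuse-fire process under anomalous
(space-fractional) diffusion. Free calcium `C(x, y, t)` obeys

    dC/dt = Dx * d^beta C / d|x|^beta  +  Dy * d^beta C / d|y|^beta
            - J_dye - J_buf - J_pump + J_leak + J_cru

with

* **Fractional diffusion.** `d^beta/d|x|^beta` is the symmetric Riesz
  fractional derivative of order `2 <= beta < 3`, the combination
  `-1/(2 cos(pi beta / 2)) * (D_+^beta + D_-^beta)` of the left- and
  right-sided Riemann-Liouville derivatives. This normalization is the
  unique direction-unbiased choice that reduces exactly to the classical
  Laplacian at `beta = 2`. `Dx = 0.30`, `Dy = 0.15 um^beta/ms` are held
  numerically fixed while `beta` varies. In this convention the
  mean-squared displacement grows as `t^(2/beta)`, so `beta > 2` is
  *subdiffusive*; its Green's function nevertheless has heavy power-law
  tails (`|x|^(-1-beta)`), which is what lets a spark recruit CRUs one or
  two microns away.
* **Buffers.** Five stationary mass-action buffers (fluo-3 dye,
  calmodulin, troponin, SR and SL membrane sites) with the standard rate
  table (`k+` in /uM/s, `k-` in /s, totals in uM). All buffers, the dye
  included, are immobile; only free calcium is transported.
* **Pump and leak.** A Hill-type SERCA pump
  `J_pump = V_max C^n / (K^n + C^n)` (`V_max = 208 uM/s`,
  `K = 0.184 uM`, `n = 3.9`) and a constant SR leak equal to the pump rate
  at the resting concentration `C0 = 0.1 uM`, so the resting state is an
  exact fixed point.
* **CRUs.** Calcium release units on a regular lattice (`lx` by
  `ly = 0.8 um`). A closed CRU at local concentration `C` fires within a
  step `dt` with probability `p = dt * P_max * C^n / (K^n + C^n)`
  (`P_max = 0.3 /ms`, `K = 15 uM`, `n = 1.6`). An open CRU injects calcium
  at the molar rate `sigma = I_cru / (2 F)` at its node for exactly
  `T_open = 10 ms`, then becomes spent and never reopens (horizons of
  200-500 ms are short against the CRU refractory period). Waves are
  started by forcing chosen CRUs open at `t = 0`.

## Discretization

* Grid `dx = dy = 0.1 um`, nodes at `i*dx` with the reflecting walls half a
  cell outside the outermost nodes (the zero-flux placement that conserves
  mass exactly at `beta = 2`); time step `dt = 0.005 ms`.
* The one-sided fractional derivatives use the right-shifted
  Gruenwald-Letnikov weights `g_k = (-1)^k C(beta, k)`, computed by the
  stable recurrence `g_k = g_{k-1} (k - 1 - beta)/k`. Reflecting walls are
  realized by even extension of the field across each wall, truncated after
  one domain width; each row of the assembled operator is then corrected on
  its diagonal so constant fields are annihilated exactly.
* **Time stepping.** The two directional operators act as commuting
  Kronecker factors, so diffusion is advanced exactly by the precomputed
  dense matrix exponentials `e^{dt Lx}`, `e^{dt Ly}` (one matrix product
  per direction per step) — unconditionally stable with no directional
  splitting error. Reactions are integrated with explicit Euler at the
  global `dt` (the fastest buffer rate gives `k*dt < 0.1`); the
  diffusion/reaction order alternates between steps, cancelling the leading
  splitting error over each pair of steps. Each open CRU's per-step deposit
  `dt * sigma / (dx dy depth)` is split around the diffusion solve with
  weights chosen so a constant source reproduces the exact one-step
  response both in total mass and at the source node's own decay rate;
  this removes the leading `dt` sensitivity of the source-node balance
  (halving `dt` moves the deterministic spark amplitude by well under 1%).
* The pump Hill function is evaluated inside the compiled per-node kernel
  from a dense lookup table (spacing 1e-4 uM up to 8 uM, exact power law
  above); interpolation error is below 2e-7 uM/ms. The leak constant is
  evaluated through the same table path, so the resting state is a fixed
  point of the compiled update to machine precision.
* For `beta > 2` the fractional evolution kernel is not positive
  (high-order operators oscillate); near a strong point source small
  negative undershoots appear at sub-micron distances. The stepper clips
  them to zero. The clipped mass is a sub-percent fraction of the released
  calcium and vanishes at `beta = 2`, where mass is conserved to 1e-10
  over 1e4 steps.

## Calibration and study conditions

Two quantities of the source geometry are not fixed by the printed model
and were chosen once:

* **Sheet depth `depth = 0.06 um`** — the thickness used to convert the
  point-source molar rate into a concentration rate (a thin
  sub-sarcolemmal release sheet). Wave dynamics depend on the current and
  depth only through `I_cru / depth`.
* **Pathological CRU current `I_cru = 3.3 pA`** — the elevated current of
  the corner/middle/collision experiments, constrained only to lie between
  the physiological 2 pA and 20 pA. It was calibrated so that the `beta = 2.25` corner wave reproduces
  the ~100 um/s longitudinal wave velocity observed experimentally
  (the same calibration target the reported velocity sweep is anchored to).

With these two numbers fixed, the physiological scenarios (2 pA) reproduce
the reported qualitative behaviour with no further tuning: a single
mid-domain spark dies out, four adjacent sparks form a weak traversing
wave, and halving the longitudinal CRU spacing to 1 um lets a single
2 pA spark form a wave that reaches the left wall near 110 ms.

Background-spark suppression uses a recruitment gate (`C_gate = 0.5 uM`):
a closed CRU may fire only where the wave has raised the local
concentration above the gate. The fractional operator's heavy tails lift
the entire far field a few nanomolar above rest within milliseconds, so a
gate at exactly `C0` would let "spontaneous" sparks seed rogue waves far
ahead of the front — events the modeled experiments explicitly prohibit.
The gate sits far below the 3-5 uM front-skirt level that actually
triggers CRUs.

## Measurement protocols

* **Wave velocity** — least-squares slope of first-firing distance versus
  onset time over the CRUs on the lattice line through the initiation
  site, excluding the first two onsets (the delay from the initiating
  spark to its first triggered neighbour is systematically longer than the
  steady spark-to-spark interval). Onsets are noise-free observables of
  the simulation; a concentration-front-threshold estimator is provided as
  a cross-check.
* **Sweep horizon** — velocity/amplitude sweeps run to 300 ms (stopping
  early once the wave has crossed the domain): the ignition transient of
  the chain occupies the first ~100-150 ms here, and the regression needs
  several steady onsets beyond it. Snapshot schedules are unchanged.
* **Amplitude** — maximum free calcium over all nodes and all steps of the
  run.
* **Wall arrival** — first firing of a CRU on the wall-adjacent lattice
  line.
* **Spark FWHM/FDHM** — measured on the deterministic single-spark
  protocol (stochastic firing disabled, one forced CRU at the domain
  centre). The FWHM is taken on the calcium-bound dye (fluorescence)
  profile through the source at the time of peak central concentration —
  spark widths in the experimental literature are fluorescence widths; the
  free-calcium width is also available and is several-fold narrower.
* **Stochastic metrics** are reported as seed means (+- SD) over a fixed
  list of seeds derived from one master seed; the reproduction script uses
  eight seeds per condition, the test suite four.

## What the scenarios emulate — and what they do not

The scenario module encodes the modeled experiments as data: corner
initiation (2, 0.8); middle initiation (10, 9.6); two-wave collision from
(2, 9.6) and (18, 9.6); and the physiological 2 pA protocols with 1, 4 or
9 initiating sparks at normal and reduced longitudinal spacing. The
corner/middle/collision experiments use a 20 x 10 um sheet; the
physiological protocols use 20 x 20 um so the initiation block sits away
from the reflecting walls (their initiating CRUs extend to y = 11.2 um).
These are idealized sheets with perfectly regular CRU lattices, identical
CRUs, no SR depletion, no rogue RyRs and no mobile dye; passing tests show
the fire-diffuse-fire mechanism and its metrics behave as modeled, not
that real myocytes are quantitatively captured.

## Known limitations

* A two-dimensional sheet with these stationary buffer densities transports
  far-field calcium much more slowly than the three-dimensional geometry
  the standard parameter set was originally fitted in. Consequently, with
  the source calibrated to the reported wave velocities, the *amplitudes*
  (peak free calcium) of developed waves run several-fold above the
  reported 110-135 uM, and their trend with beta is flat rather than
  decreasing; the reported velocity row and amplitude row could not be
  reproduced simultaneously by any admissible source strength. The
  amplitude figures this package reports are therefore expected to exceed
  the published ones, and the ignition transient of the chain is longer
  (which is why the middle-initiation wall arrival runs ~25-40% above the
  reported 120 ms).
* The deterministic Fickian spark's fluorescence FWHM comes out near
  1.6-1.7 um rather than the ~1.0 um quoted for Fickian spark models
  (which are three-dimensional); the free-calcium width is ~0.3 um. The
  beta-ordering (wider at beta = 2.25) is reproduced.
* Orders `beta >= 3` and time-fractional derivatives are out of scope; the
  Riesz normalization is singular at `beta = 3`.
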