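# cardiosim

Headless cardiac electrophysiology simulation for researchers who want
scriptable, reproducible action-potential and tissue-propagation studies:
single-cell current clamp (pacing trains) and voltage clamp (step
protocols), 1D-fiber and 2D-grid monodomain propagation, streaming per-beat
measurement (APD90, amplitude, upstroke velocity, cycle length), and
multi-trial conductance-scaling sensitivity runs — all driven from plain
text files and a small CLI.

## Model

Cellular dynamics follow

    Cm dVm/dt = −Σ I_ion + I_stim

integrated by forward Euler with a three-tier adaptive time step (fine
during the upstroke, coarse in diastole). Tissue couples cells through the
monodomain cable equation with diffusion coefficient `D = d/(4·Ri·Cm)`;
fibers are advanced by the Crank–Nicolson implicit scheme and grids by
Peaceman–Rachford alternating-direction implicit half steps, both with
sealed boundaries. Per-beat properties (minimum, peak, amplitude, 90 %
duration, maximum dVm/dt, cycle length) are measured on the fly with
linearly interpolated crossings. Parameter sensitivity runs scale ion-
channel conductances per trial — fixed, swept, or drawn from normal /
lognormal distributions with reproducible counter-based streams.

A fast two-variable excitable cell (`referenceCell`, rest −85 mV, APD90 ≈
160 ms, CV ≈ 60 cm/s on the default fiber) ships for simulation and
testing; registry entries for four published ionic models carry their
adaptive-timestep configurations. See `docs/methods.md` for the full
numerical story.

## Worked example

Pace the reference cell for three beats and summarize the measured APs:

```sh
$ cat sim.txt
bcl 500
numstims 3
tMax 1500
writeint 0.5

$ cardiosim run --simvars sim.txt --out runs --seed 1
runs/20260930-074307

$ cardiosim summarize runs/20260930-074307
 trial variable  beat         min      peak  amplitude        dur  maxderiv  t_peak    cl
     0       vm     0  -85.000000 24.770189 109.770189 161.837093 89.054596     2.5   NaN
     0       vm     1 -111.472982 24.133665 135.606647 158.239816 70.446946   503.0 500.5
     0       vm     2 -111.471361 24.156787 135.628148 158.359839 68.315656  1003.0 500.0
```

Each row is one completed beat: the diastolic minimum and peak (mV),
amplitude, APD90 (`dur`, ms, from maximum upstroke to 90 % repolarisation),
maximum upstroke velocity (mV/ms, finite-differenced on the 0.5 ms output
grid), time of peak, and the cycle length between successive upstrokes
(ms) — here locked to the 500 ms pacing. The
first beat rises from the −85 mV resting state; later beats start from the
post-repolarisation undershoot, hence the larger amplitude. The run
directory holds the full settings (`simvars.txt`, `pvars.txt`, `dvars.txt`,
`mvars.txt`), the sampled trace (`dt0_dvars.txt`) and the measures
(`dt0_mvars.txt`); `cardiosim run --import <dir> --seed 1` reproduces it
byte-for-byte.

The same engine drives sensitivity sweeps (`--pvars`, e.g.
`kFactor random lognormal 1.0 0.2` with `--trials N`), voltage-clamp steps
(`--mode voltageClamp`), and tissue runs (`--mode grid --geometry <dir>`,
which also writes an activation map). Everything is importable as a
library: `cardiosim.run_trial`, `cardiosim.simulate_fiber`, etc.

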