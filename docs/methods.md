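# Methods

`cardiosim` is a headless simulator for cardiac cellular electrophysiology:
single cells under current or voltage clamp, and 1D/2D monodomain tissue.
This note documents the models, numerical schemes, measurement definitions,
defaults, and the choices made where several designs were defensible.

## Governing equations

A cell's membrane potential obeys

    Cm dVm/dt = -(Σ I_ion) + I_stim

with `Vm` in mV, time in ms, currents Cm-normalised in µA/µF, and a positive
`I_stim` depolarising (the sign convention is stated explicitly because
current-sign conventions differ between labs; here inward/depolarising ionic
currents are negative).

Tissue couples cells through the monodomain cable equation,

    dVm/dt = D ∂²Vm/∂x² - (Σ I_ion - I_stim)/Cm,     D = d / (4 Ri Cm),

with fiber diameter `d` (cm), intracellular resistivity `Ri` (kΩ·cm) and
`Cm` (µF/cm²), giving `D` in cm²/ms. Boundaries are sealed (no-flux) at
fiber ends and grid edges, the standard condition for isolated tissue.

## Cell models

The engine defines a model *contract* (currents, state derivatives,
multiplicative scaling parameters, an adaptive-timestep table) rather than a
fixed equation set. Two fully specified models ship:

**referenceCell** — a two-variable excitable caricature of a ventricular
myocyte built for fast, fully reproducible testing. A cubic FitzHugh–Nagumo
fast variable `u` is mapped affinely to the physiological range
(`Vm = 110·u − 85` mV, rest −85 mV, peak ≈ +25 mV):

    dVm/dt = -(iFast + iRec - Istim)/Cm
    iFast  = -Cm·110·kFactor·k·u(u-a)(1-u)
    iRec   =  Cm·110·w
    dw/dt  = ε(β·u - w)

with k = 8, a = 0.15, ε = 0.005, β = 2. The constants were chosen once,
against explicit physiological requirements, and are not tuning knobs:

* β must place the recovery gate's equilibrium (β·u) above the knee of the
  cubic (≈ 0.93), otherwise the trajectory parks on the depolarised branch
  and the beat never terminates; β = 2 satisfies this with margin.
* ε sets the recovery time constant (1/ε = 200 ms), giving APD90 ≈ 160 ms
  and full 1:1 capture at the default 500 ms pacing cycle length, while
  still producing measurable APD restitution at short diastolic intervals.
* The resulting upstroke velocity (~100 mV/ms), amplitude (~110→135 mV with
  post-repolarisation undershoot) and conduction velocity on a default
  fiber (~60 cm/s) are all in the physiological ballpark for working
  myocardium.

`kFactor` scales the fast (excitatory) conductance and is the model's
sensitivity-analysis hook. `w` is treated as a gate and clipped to [0, 1]
after each explicit step.

**passive** — a reaction-free membrane (zero ionic current) used to exercise
the diffusion solvers against analytic solutions.

Registry entries for four published ionic models (Grandi, TenTusscher,
HundRudy, Kurata) carry only their adaptive-timestep tables as configuration
metadata; their equation sets are not transcribed, and attempting to
integrate one raises a configuration error. The tables include a `Dvdtmax`
column stored verbatim from the published configuration; its meaning is
unresolved (the printed magnitudes, e.g. 5.43e-10 "ms", are inconsistent
with a time step) and it plays no role in the integrator.

## Time integration

Cells advance by explicit forward Euler with a three-tier dynamic step.
With pre-step |dVm/dt| and thresholds from the model's table
(`dtmin ≤ dtmed ≤ dtmax`, `dvcut`):

* |dVm/dt| ≥ dvcut        → dtmin  (upstroke)
* |dVm/dt| ≥ dvcut/10     → dtmed
* otherwise               → dtmax

The tier rule is monotone in |dVm/dt| and uses the *pre-step* derivative
(the cached value from the step that produced the state). Every step is
additionally truncated so the integrator lands exactly on each stimulus
edge, clamp step time, output sample and tMax; output rows therefore sit on
the exact `writetime + n·writeint` grid regardless of dt adaptation, which
makes traces bit-reproducible across dt configurations and is what makes
restart-from-snapshot exact.

Gates are clamped to [0, 1] and concentrations floored at 0 after each
step (explicit Euler can overshoot either bound; Rush–Larsen stepping was
deliberately not adopted, keeping the step definition uniform across
models). Verified behaviour: global error is first order in dt (measured
log-log slope ≈ 1.09 against a dt/64 reference over a 100 ms paced AP — the
horizon covers the upstroke and early repolarisation, where essentially all
of the error accrues).

Under voltage clamp, Vm is externally commanded (a left-closed step
function; before the first step time the model's resting Vm holds), state
variables evolve freely at the clamped potential, and recorded currents are
the model currents at that potential. Since dVm/dt is identically zero the
tier rule selects dtmax; the slow gates of the shipped models are accurate
at that resolution, and the clamp lands exactly on each step time.

## Tissue solvers

Each tissue step is operator-split: ionic currents are evaluated at the
start-of-step (stage) state, non-Vm variables take one explicit Euler step,
then Vm advances through the implicit diffusion solve with the reaction held
at its stage value. The splitting is first order in dt, consistent with the
cell integrator; the diffusion part is unconditionally stable.

* **Fibers** use Crank–Nicolson: `(I − dt/2·L) v⁺ = (I + dt/2·L) v + dt·R`
  with `L` the no-flux discrete Laplacian and `R` the stage reaction.
* **Grids** use Peaceman–Rachford ADI: a row-implicit/column-explicit half
  step followed by the transpose, each advancing dt/2 and carrying half of
  the stage reaction. On a degenerate 1×N grid this is algebraically
  identical to Crank–Nicolson (verified to ~1e-16).

Tridiagonal systems are solved by banded Gaussian elimination (the Thomas
recursion, via LAPACK). Edge conductivities between unlike nodes use the
harmonic mean (series-conductance rule); for homogeneous tissue this reduces
to the nodal value. The tissue time step is the minimum of all member
cells' adaptive selections — a single global step keeps the implicit solve
synchronised across nodes.

Verified behaviour: analytic eigenmode decay to < 1e-3 relative error at
100 nodes (1D) and 40×30 (2D); spatial accuracy slope ≈ 2 under dx
halvings; spatial-mean conservation to ~1e-14 per 1000 steps; activation
maps of symmetric problems symmetric to ~1e-15; conduction velocity ≈ 60
cm/s on the default reference-cell fiber, scaling like 1/√Ri (measured
ratio 0.69 vs the theoretical 0.71 when Ri doubles).

## Beat measurement

Measurement is streaming: samples are consumed as the simulation produces
them and per-beat properties are emitted when each beat completes.

* Between beats, the running minimum and baseline peak track the signal.
  A beat opens when a sample rises above `min + 0.1·(baseline peak − min)`,
  i.e. above the recent baseline.
* Within a beat, the peak and the maximum finite-difference derivative are
  tracked (first attainment wins, with a 1e-9 relative tolerance so float
  noise on an exactly linear upstroke cannot jitter the timing). Beat
  samples are buffered: amplitude-relative quantities are only well defined
  against the final peak.
* The beat closes at the interpolated downward crossing of
  `min + 0.1·amplitude` (90 % recovery). `dur(f)` runs from the
  maximum-derivative time to the interpolated crossing of
  `peak − f·amplitude` (default f = 0.9 gives the conventional APD90:
  activation at maximum upstroke velocity, repolarisation at 90 %
  recovery). For f > 0.9 the level lies beyond the close threshold and the
  crossing is resolved from post-beat samples. `cl` is the spacing between
  successive maximum-derivative times.

Running min and baseline peak reset after each completed beat, so drifting
diastolic baselines are followed. All crossings are linearly interpolated,
making results insensitive to the output interval to first order (halving
`writeint` moves APD90 by less than the coarser interval). The same
machinery serves bulk Ca²⁺ transients; properties beyond min/peak/amplitude
are restricted to the variables each model declares fit for full
measurement. A beat still in progress at the end of a trace is discarded
with a warning, and only beats entirely past `meastime` are reported.

## Sensitivity analysis

Per-trial parameter factors come in three modes: a fixed value (`init`), an
arithmetic sweep `init + i·increment` (`iter`), and independent random draws
(`random`, normal or lognormal). Draws use counter-based streams keyed on
(seed, parameter name, trial index) — CRC32 of the name feeds a
`SeedSequence`, because Python's builtin hash is salted per process. This
makes factor lists reproducible across runs, identical under serial or
concurrent execution, independent across parameters, and stable for early
trials when the trial count changes.

The lognormal is parameterised by its *natural-scale* mean and standard
deviation (what a user scaling conductances around 1.0 expects), converted
internally via µ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²). Negative normal draws
are floored at 0 with a logged warning — a negative conductance factor is
unphysical, and silent clipping would bias sensitivity studies invisibly.

## Files and reproducibility

Every run writes its full configuration (simvars/pvars/dvars/mvars), notes,
per-trial traces (`dt{n}_dvars.txt`) and measures (`dt{n}_mvars.txt`), and
optionally a final-state snapshot (`dss0_cellState.txt`) into a fresh
timestamped directory (ISO-8601 basic, so directories sort lexically).
The settings dialect is `name value(s)` whitespace-delimited UTF-8 text with
`#` comments — defined and documented here as this package's canonical
dialect. Numbers are printed in shortest round-trip decimal form, so
read∘write is exact; that exactness is what makes a snapshot restart
bitwise-identical to an uninterrupted run, and an imported settings
directory plus the original seed reproduce trace files byte-for-byte.

## Defaults

| parameter | default | note |
|---|---|---|
| numstims | 500 | standard long pulse train |
| bcl | 500 ms | 2 Hz pacing |
| stimdur / stimval | 1 ms / 40 µA/µF | ~2× threshold for referenceCell |
| stimt / writetime / meastime | 0 ms | |
| writeint | 0.1 ms | resolves the upstroke |
| tMax | 2500 ms | five default cycles |
| numtrials | 1 | |
| fiber dx / d / Ri / Cm | 0.01 cm / 0.0011 cm / 0.15 kΩ·cm / 1 µF/cm² | textbook ventricular strand values |
| APD fraction | 0.9 | APD90 |
| activation threshold | −20 mV | |

## Known limitations

* The shipped excitable model is a caricature: no ionic concentrations, no
  Ca²⁺ transient, a stylised (deep) post-repolarisation undershoot, and
  restitution far milder than real myocardium. Tests passing against it
  validate the *engine* (integration, schemes, measurement, plumbing), not
  the biophysics of any published ionic model.
* Reaction–diffusion splitting is first order in dt; the second-order
  accuracy of CN/ADI is realised only in the diffusion-dominated limit.
* Anisotropic conductivity tensors, irregular geometries and
  reentry-induction (S1–S2) protocols are out of scope.
* Voltage clamp holds Vm as an ideal source (no series-resistance
  artifact).
* Per-beat measurement assumes beats complete within the trace; signals
  that never recross their takeoff threshold yield no measurements.
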