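"""Single-cell stimulation protocols and the trial runner.

Two protocol kinds are defined here: a current-clamp pulse train (pacing at a
basic cycle length ``bcl`` with ``numstims`` rectangular pulses) and a
five-step voltage clamp.  ``run_trial`` integrates one cell through a
protocol with the adaptive time step, sampling the requested variables on the
exact ``writetime + n*writeint`` grid, and feeding samples past ``meastime``
to the streaming measurers.  ``run_trials`` orchestrates multi-trial runs
whose per-trial parameter factors come from the sensitivity module; results
are bitwise identical whether trials run serially or concurrently.
"""
from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cell_core import (
    CellModel,
    CellState,
    ConfigurationError,
    apply_parameters,
    euler_step,
    select_dt,
)
from .measure import MeasureSpec, Measurer
from .sensitivity import PvarSpec, resolve_pvars

#: protocol kinds selectable from the CLI / simvars files
PROTOCOL_KINDS = ("currentClamp", "voltageClamp", "grid")

_GRID_SNAP = 1e-9  # tolerance (ms) for identifying boundary landings


@dataclass
class CurrentClampProtocol:
    """Pulse-train pacing protocol.

    All times in ms, stimulus amplitude in µA/µF.  ``writetime`` gates when
    trace rows start being written and ``meastime`` gates when beat
    measurement starts; ``writeint`` is the output sampling interval.  The
    default train applies 500 stimuli; ``tMax`` terminates the simulation
    regardless of how many stimuli remain.
    """

    kind = "currentClamp"

    bcl: float = 500.0
    stimdur: float = 1.0
    stimval: float = 40.0
    numstims: int = 500
    stimt: float = 0.0
    tMax: float = 2500.0
    writetime: float = 0.0
    meastime: float = 0.0
    writeint: float = 0.1
    numtrials: int = 1
    paceflag: bool = True

    def __post_init__(self) -> None:
        if not (self.bcl > self.stimdur > 0):
            raise ConfigurationError(
                f"require bcl > stimdur > 0, got bcl={self.bcl}, stimdur={self.stimdur}"
            )
        if self.numstims < 0 or self.stimt < 0:
            raise ConfigurationError("numstims and stimt must be non-negative")
        if not (0 <= self.writetime <= self.tMax and 0 <= self.meastime <= self.tMax):
            raise ConfigurationError("writetime/meastime must lie in [0, tMax]")
        if self.writeint <= 0:
            raise ConfigurationError("writeint must be > 0")
        if self.numtrials < 1:
            raise ConfigurationError("numtrials must be >= 1")


@dataclass
class VoltageClampProtocol:
    """Five-step voltage-clamp schedule: Vm is held at ``v_i`` from ``t_i``
    until the next step time (and at the model's resting Vm before ``t1``)."""

    kind = "voltageClamp"

    t1: float = 50.0
    t2: float = 300.0
    t3: float = 500.0
    t4: float = 800.0
    t5: float = 1000.0
    v1: float = -80.0
    v2: float = -40.0
    v3: float = 0.0
    v4: float = 40.0
    v5: float = -80.0
    tMax: float = 1200.0
    writetime: float = 0.0
    writeint: float = 0.1

    def __post_init__(self) -> None:
        if list(self.times) != sorted(self.times):
            raise ConfigurationError(f"t1..t5 must be non-decreasing, got {self.times}")
        # step times beyond tMax are allowed: those steps are simply never
        # reached and the last attained level holds to the end
        if self.writeint <= 0:
            raise ConfigurationError("writeint must be > 0")

    @property
    def times(self) -> tuple[float, ...]:
        return (self.t1, self.t2, self.t3, self.t4, self.t5)

    @property
    def voltages(self) -> tuple[float, ...]:
        return (self.v1, self.v2, self.v3, self.v4, self.v5)


@dataclass
class TrialResult:
    """Output of one trial: the sampled trace and the per-beat measures."""

    trial: int
    factors: dict[str, float]
    trace: pd.DataFrame
    measures: pd.DataFrame
    error: Exception | None = None
    final_state: CellState | None = None  # supports cell-state snapshots/restart


class TrialError(RuntimeError):
    def __init__(self, trial: int, cause: Exception):
        super().__init__(f"trial {trial} failed: {cause}")
        self.trial = trial
        self.cause = cause


# ---------------------------------------------------------------------------
# Stimulus / clamp schedules
# ---------------------------------------------------------------------------

def stim_current(t: float, p: CurrentClampProtocol) -> float:
    """Pulse-train stimulus at time ``t``: ``stimval`` inside any half-open
    window ``[stimt + k*bcl, stimt + k*bcl + stimdur)`` for k < numstims."""
    if not p.paceflag or p.numstims == 0 or t < p.stimt:
        return 0.0
    k = math.floor((t - p.stimt) / p.bcl)
    if k >= p.numstims:
        return 0.0
    return p.stimval if (t - p.stimt) - k * p.bcl < p.stimdur else 0.0


def clamp_voltage(t: float, p: VoltageClampProtocol, rest_vm: float) -> float:
    """Commanded Vm at time ``t``: the last step at or before ``t`` (left-
    closed), or the model's resting Vm before the first step."""
    vm = rest_vm
    for ti, vi in zip(p.times, p.voltages):
        if t >= ti:
            vm = vi
        else:
            break
    return vm


def sample_times(writetime: float, writeint: float, tMax: float) -> np.ndarray:
    """The exact output grid ``{writetime + n*writeint} ∩ [0, tMax]``."""
    if tMax < writetime:
        return np.empty(0)
    n = int(math.floor((tMax - writetime) / writeint + _GRID_SNAP))
    return writetime + writeint * np.arange(n + 1)


def pulse_edges(p: CurrentClampProtocol) -> list[float]:
    """Every stimulus onset/offset in (0, tMax] — integration boundaries."""
    if not p.paceflag:
        return []
    edges = []
    for k in range(p.numstims):
        on = p.stimt + k * p.bcl
        if on > p.tMax:
            break
        edges.append(on)
        off = on + p.stimdur
        if off <= p.tMax:
            edges.append(off)
    return edges


# ---------------------------------------------------------------------------
# Trial runner
# ---------------------------------------------------------------------------

def _resolve_outputs(model: CellModel, outputs: Iterable[str]) -> list[str]:
    valid = set(model.variable_names()) | set(model.current_names()) | {"t", "vm"}
    cols = ["t", "vm"]  # always recorded
    for name in outputs:
        if name not in valid:
            raise ConfigurationError(
                f"unknown output variable {name!r} for model {model.name!r}; "
                f"valid: {sorted(valid)}"
            )
        if name not in cols:
            cols.append(name)
    return cols


def _make_measurers(model: CellModel, measures: Iterable[MeasureSpec]) -> list[Measurer]:
    out = []
    for spec in measures:
        if spec.variable not in set(model.variable_names()):
            raise ConfigurationError(
                f"cannot measure unknown variable {spec.variable!r} of model {model.name!r}"
            )
        spec.validate_for(model.full_measure_vars)
        out.append(Measurer(spec))
    return out


def _sample_row(state: CellState, model: CellModel, cols: list[str],
                current_cols: set[str]) -> list[float]:
    per_current = {}
    if current_cols:
        per_current, _ = model.currents(state)
    row = []
    for c in cols:
        if c == "t":
            row.append(state.t)
        elif c == "vm":
            row.append(state.vm)
        elif c in state.vars:
            row.append(state.vars[c])
        else:
            row.append(per_current[c])
    return row


def _measures_frame(measurers: list[Measurer]) -> pd.DataFrame:
    records = []
    for m in measurers:
        for beat in m.finish():
            rec = {"variable": m.spec.variable, "beat": beat.beat}
            rec.update(beat.values)
            records.append(rec)
    if not records:
        return pd.DataFrame(columns=["variable", "beat"])
    return pd.DataFrame.from_records(records)


def run_trial(
    model: CellModel,
    protocol,
    outputs: Iterable[str] = (),
    measures: Iterable[MeasureSpec] = (),
    initial_state: CellState | None = None,
) -> TrialResult:
    """Integrate one cell through ``protocol`` and return trace + measures.

    The integrator is forced to land exactly on every stimulus edge, clamp
    step and output sample (boundary truncation of the adaptive dt), so the
    trace grid is independent of dt adaptation.  Time and Vm are always
    recorded.
    """
    if not model.simulatable:
        raise ConfigurationError(
            f"model {model.name!r} ships timestep configuration only and cannot be simulated"
        )
    if protocol.kind == "currentClamp":
        return _run_current_clamp(model, protocol, outputs, measures, initial_state)
    if protocol.kind == "voltageClamp":
        return _run_voltage_clamp(model, protocol, outputs, measures, initial_state)
    raise ConfigurationError(f"run_trial does not handle protocol kind {protocol.kind!r}")


def _empty_result(cols) -> tuple[pd.DataFrame, pd.DataFrame]:
    return (pd.DataFrame(columns=cols), pd.DataFrame(columns=["variable", "beat"]))


def _run_current_clamp(model, p, outputs, measures, initial_state) -> TrialResult:
    cols = _resolve_outputs(model, outputs)
    if p.tMax <= 0:  # degenerate: nothing simulated, nothing reported
        return TrialResult(0, {}, *_empty_result(cols))
    current_cols = set(cols) & set(model.current_names())
    measurers = _make_measurers(model, measures)
    state = (initial_state or model.default_state).copy()

    samples = sample_times(p.writetime, p.writeint, p.tMax)
    samples = samples[samples >= state.t - _GRID_SNAP]
    boundaries = sorted(
        {float(b) for b in samples}
        | {e for e in pulse_edges(p) if e > state.t}
        | {p.tMax}
    )
    rows: list[list[float]] = []

    def record(st: CellState) -> None:
        rows.append(_sample_row(st, model, cols, current_cols))
        if st.t >= p.meastime - _GRID_SNAP:
            for m in measurers:
                val = st.vm if m.spec.variable == "vm" else st.vars[m.spec.variable]
                m.update(st.t, val)

    # exact sample membership: walk the sample array alongside the boundaries
    sample_iter = iter(samples)
    next_sample = next(sample_iter, None)

    if next_sample is not None and abs(state.t - next_sample) < _GRID_SNAP:
        record(state)
        next_sample = next(sample_iter, None)

    for b in boundaries:
        if b <= state.t + _GRID_SNAP:
            continue
        while state.t < b - _GRID_SNAP:
            dt = select_dt(state, model.dt_config, b)
            istim = stim_current(state.t, p)
            state = euler_step(state, model, istim, dt)
        state.t = b  # snap off float drift so the grid is exact
        if next_sample is not None and abs(b - next_sample) < _GRID_SNAP:
            record(state)
            next_sample = next(sample_iter, None)

    trace = pd.DataFrame(rows, columns=cols) if rows else _empty_result(cols)[0]
    return TrialResult(0, {}, trace, _measures_frame(measurers), final_state=state)


def _run_voltage_clamp(model, p, outputs, measures, initial_state) -> TrialResult:
    cols = _resolve_outputs(model, outputs)
    if p.tMax <= 0:
        return TrialResult(0, {}, *_empty_result(cols))
    current_cols = set(cols) & set(model.current_names())
    measurers = _make_measurers(model, measures)
    state = (initial_state or model.default_state).copy()
    rest_vm = model.default_state.vm
    state.vm = clamp_voltage(state.t, p, rest_vm)
    state.dvdt = 0.0

    samples = sample_times(p.writetime, p.writeint, p.tMax)
    samples = samples[samples >= state.t - _GRID_SNAP]
    boundaries = sorted(
        {float(b) for b in samples}
        | {t for t in p.times if t > state.t}
        | {p.tMax}
    )
    rows: list[list[float]] = []

    def record(st: CellState) -> None:
        rows.append(_sample_row(st, model, cols, current_cols))
        for m in measurers:
            val = st.vm if m.spec.variable == "vm" else st.vars[m.spec.variable]
            m.update(st.t, val)

    sample_iter = iter(samples)
    next_sample = next(sample_iter, None)
    if next_sample is not None and abs(state.t - next_sample) < _GRID_SNAP:
        record(state)
        next_sample = next(sample_iter, None)

    for b in boundaries:
        if b <= state.t + _GRID_SNAP:
            continue
        while state.t < b - _GRID_SNAP:
            dt = select_dt(state, model.dt_config, b)
            state = euler_step(state, model, 0.0, dt)
            # Vm is externally commanded: overwrite the integrator's value
            state.vm = clamp_voltage(state.t, p, rest_vm)
            state.dvdt = 0.0
        state.t = b
        state.vm = clamp_voltage(b, p, rest_vm)
        if next_sample is not None and abs(b - next_sample) < _GRID_SNAP:
            record(state)
            next_sample = next(sample_iter, None)

    trace = pd.DataFrame(rows, columns=cols) if rows else _empty_result(cols)[0]
    return TrialResult(0, {}, trace, _measures_frame(measurers), final_state=state)


# ---------------------------------------------------------------------------
# Multi-trial orchestration
# ---------------------------------------------------------------------------

def _one_trial(i, model, protocol, factors, outputs, measures, initial_state):
    try:
        trial_model = apply_parameters(model, factors)
        result = run_trial(trial_model, protocol, outputs, measures, initial_state)
        result.trial = i
        result.factors = factors
        return result
    except Exception as exc:  # report per-trial, never abort siblings
        return TrialResult(i, factors, pd.DataFrame(), pd.DataFrame(), error=TrialError(i, exc))


def run_trials(
    model: CellModel,
    protocol,
    pvars: Sequence[PvarSpec] = (),
    seed: int = 0,
    outputs: Iterable[str] = (),
    measures: Iterable[MeasureSpec] = (),
    numtrials: int | None = None,
    initial_state: CellState | None = None,
    concurrent: bool = False,
    max_workers: int = 4,
) -> list[TrialResult]:
    """Run ``numtrials`` independent trials with per-trial parameter factors.

    Factors come from :func:`cardiosim.sensitivity.resolve_pvars`, keyed on
    (seed, parameter, trial) only, so serial and concurrent execution produce
    bitwise-identical results.
    """
    if numtrials is None:
        numtrials = getattr(protocol, "numtrials", 1)
    factor_list = resolve_pvars(pvars, numtrials, seed)
    args = [
        (i, model, protocol, factor_list[i], list(outputs), list(measures), initial_state)
        for i in range(numtrials)
    ]
    if concurrent and numtrials > 1:
        with ThreadPoolExecutor(max_workers=max_workers) as pool:
            results = list(pool.map(lambda a: _one_trial(*a), args))
    else:
        results = [_one_trial(*a) for a in args]
    return results
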