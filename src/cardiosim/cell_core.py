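"""Cell-model contract, adaptive time-step selection and forward-Euler stepping.

The membrane obeys ``Cm * dVm/dt = -(sum I_ion) + I_stim`` with Vm in mV,
currents in µA/µF (Cm-normalised) and time in ms, so a positive stimulus
current depolarises the cell.  A :class:`CellModel` bundles the current and
state-derivative functions of one ionic model together with its multiplicative
conductance-scaling parameters and its adaptive-timestep configuration.

All integration here is explicit forward Euler with a three-tier dynamic step:
the step shrinks to ``dtmin`` during the fast upstroke (|dVm/dt| above
``dvcut``), uses ``dtmed`` in an intermediate band, and relaxes to ``dtmax``
during slow phases.  Steps are additionally truncated so the integrator lands
exactly on stimulus edges and output-sampling times.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping


class IntegrationError(RuntimeError):
    """Raised when a state derivative becomes non-finite during a step."""


class ConfigurationError(ValueError):
    """Raised for invalid model / protocol configuration (unknown names etc.)."""


@dataclass(frozen=True)
class AdaptiveDtConfig:
    """Three-tier dynamic time-step configuration, all values in ms.

    ``dvdtmax`` is carried verbatim from published per-model tables as
    metadata; it plays no role in step selection.
    """

    dtmin: float
    dtmed: float
    dtmax: float
    dvcut: float  # |dVm/dt| threshold (mV/ms) for the fine step
    dvdtmax: float | None = None  # metadata only

    def __post_init__(self) -> None:
        if not (0.0 < self.dtmin <= self.dtmed <= self.dtmax):
            raise ConfigurationError(
                f"require 0 < dtmin <= dtmed <= dtmax, got "
                f"({self.dtmin}, {self.dtmed}, {self.dtmax})"
            )
        if self.dvcut <= 0.0:
            raise ConfigurationError(f"dvcut must be > 0, got {self.dvcut}")


@dataclass
class CellState:
    """All time-varying quantities of one cell at one instant.

    ``vars`` is an ordered name → value map holding every non-Vm state
    variable (gates are dimensionless in [0, 1], concentrations in mM).
    ``dvdt`` caches dVm/dt (mV/ms) from the step that produced this state and
    drives adaptive-dt selection.
    """

    t: float
    vm: float
    dvdt: float = 0.0
    vars: dict[str, float] = field(default_factory=dict)
    cm: float = 1.0  # µF/cm²

    def copy(self) -> "CellState":
        return CellState(self.t, self.vm, self.dvdt, dict(self.vars), self.cm)


# current_fn(state, parameters) -> (per-current map, total Iion)  [µA/µF]
CurrentFn = Callable[[CellState, Mapping[str, float]], tuple[dict[str, float], float]]
# derivative_fn(state, parameters, istim) -> (dVm/dt, {var: dvar/dt})
DerivativeFn = Callable[
    [CellState, Mapping[str, float], float], tuple[float, dict[str, float]]
]


@dataclass
class CellModel:
    """Contract one ionic model must satisfy to be simulated.

    ``parameters`` are multiplicative scaling factors (default 1.0) on model
    quantities, mostly maximal conductances — the hooks used by parameter
    sensitivity analysis.  ``gates`` lists the state variables clipped to
    [0, 1] after each explicit step; ``concentrations`` are floored at 0.
    """

    name: str
    parameters: dict[str, float]
    default_state: CellState | None
    dt_config: AdaptiveDtConfig
    current_fn: CurrentFn | None = None
    derivative_fn: DerivativeFn | None = None
    gates: frozenset[str] = frozenset()
    concentrations: frozenset[str] = frozenset()
    full_measure_vars: frozenset[str] = frozenset({"vm"})
    metadata: dict = field(default_factory=dict)

    @property
    def simulatable(self) -> bool:
        return self.derivative_fn is not None and self.default_state is not None

    def currents(self, state: CellState) -> tuple[dict[str, float], float]:
        if self.current_fn is None:
            raise ConfigurationError(
                f"model {self.name!r} ships timestep configuration only; "
                "it has no equation set to evaluate"
            )
        return self.current_fn(state, self.parameters)

    def derivatives(self, state: CellState, istim: float) -> tuple[float, dict[str, float]]:
        if self.derivative_fn is None:
            raise ConfigurationError(
                f"model {self.name!r} ships timestep configuration only; "
                "it has no equation set to integrate"
            )
        return self.derivative_fn(state, self.parameters, istim)

    def variable_names(self) -> list[str]:
        if self.default_state is None:
            return []
        return ["vm", *self.default_state.vars.keys()]

    def current_names(self) -> list[str]:
        if self.current_fn is None or self.default_state is None:
            return []
        per_current, _ = self.currents(self.default_state)
        return list(per_current.keys())


def apply_parameters(model: CellModel, factors: Mapping[str, float]) -> CellModel:
    """Return a copy of ``model`` with the given scaling factors applied.

    Unknown parameter names are rejected so a typo in a sensitivity spec
    cannot silently run an unmodified model.
    """
    unknown = sorted(set(factors) - set(model.parameters))
    if unknown:
        raise ConfigurationError(
            f"unknown parameter(s) {unknown} for model {model.name!r}; "
            f"valid names: {sorted(model.parameters)}"
        )
    params = dict(model.parameters)
    params.update({k: float(v) for k, v in factors.items()})
    return replace(model, parameters=params)


def select_dt(state: CellState, cfg: AdaptiveDtConfig, next_boundary: float) -> float:
    """Pick the step for the next forward-Euler advance.

    Tier rule on the pre-step |dVm/dt|: ``dtmin`` at or above ``dvcut``,
    ``dtmed`` at or above ``dvcut/10``, ``dtmax`` otherwise.  The result is
    truncated so the step never crosses ``next_boundary`` (stimulus edge,
    output sample, tMax).
    """
    if next_boundary < state.t:
        raise ValueError(f"next_boundary {next_boundary} precedes t {state.t}")
    adv = abs(state.dvdt)
    if adv >= cfg.dvcut:
        dt = cfg.dtmin
    elif adv >= cfg.dvcut / 10.0:
        dt = cfg.dtmed
    else:
        dt = cfg.dtmax
    return min(dt, next_boundary - state.t)


def euler_step(state: CellState, model: CellModel, istim: float, dt: float) -> CellState:
    """Advance every state variable one explicit-Euler step of size ``dt``.

    Gating variables are clamped to [0, 1] and concentrations floored at 0
    after the update (the explicit scheme can overshoot either bound).  The
    returned state stores the dVm/dt actually used, so the next adaptive-dt
    decision sees the pre-step derivative.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be > 0, got {dt}")
    dvm, dvars = model.derivatives(state, istim)
    if not math.isfinite(dvm):
        raise IntegrationError(f"non-finite dVm/dt at t={state.t} ms")
    new_vars = {}
    for name, value in state.vars.items():
        dx = dvars.get(name, 0.0)
        if not math.isfinite(dx):
            raise IntegrationError(f"non-finite derivative of {name!r} at t={state.t} ms")
        x = value + dt * dx
        if name in model.gates:
            x = min(1.0, max(0.0, x))
        elif name in model.concentrations and x < 0.0:
            x = 0.0
        new_vars[name] = x
    return CellState(state.t + dt, state.vm + dt * dvm, dvm, new_vars, state.cm)


# ---------------------------------------------------------------------------
# Shipped models
# ---------------------------------------------------------------------------

_VM_REST = -85.0  # mV at u = 0
_VM_SPAN = 110.0  # mV per unit of u; peak ≈ +25 mV at u ≈ 1


def _refcell_u(vm: float) -> float:
    return (vm - _VM_REST) / _VM_SPAN


def _refcell_currents(state: CellState, params: Mapping[str, float]):
    k = 8.0 * params["kFactor"]
    a = 0.15
    u = _refcell_u(state.vm)
    w = state.vars["w"]
    # Cm-normalised currents; inward (depolarising) currents are negative.
    i_fast = -state.cm * _VM_SPAN * k * u * (u - a) * (1.0 - u)
    i_rec = state.cm * _VM_SPAN * w
    return {"iFast": i_fast, "iRec": i_rec}, i_fast + i_rec


def _refcell_derivatives(state: CellState, params: Mapping[str, float], istim: float):
    eps, beta = 0.005, 2.0
    u = _refcell_u(state.vm)
    w = state.vars["w"]
    _, i_total = _refcell_currents(state, params)
    dvm = -(i_total - istim) / state.cm
    dw = eps * (beta * u - w)
    return dvm, {"w": dw}


def make_reference_cell() -> CellModel:
    """Two-variable excitable caricature of a ventricular myocyte.

    A cubic FitzHugh–Nagumo-style fast variable mapped affinely onto the
    physiological voltage range (rest −85 mV, peak ≈ +25 mV) plus one slow
    recovery gate ``w``:

        dVm/dt = -(iFast + iRec - Istim)/Cm,
        iFast  = -Cm·110·kFactor·k·u(u-a)(1-u),   u = (Vm+85)/110,
        iRec   =  Cm·110·w,
        dw/dt  = ε(β·u - w),      k=8, a=0.15, ε=0.005, β=2.

    The recovery gain β places w's equilibrium above the knee of the cubic so
    every beat terminates (APD ≈ 160 ms), and the recovery rate ε is set so
    the cell follows 1:1 pacing at a 500 ms cycle length while still showing
    rate-dependent APD restitution at short diastolic intervals.  ``kFactor``
    scales the fast (excitatory) conductance and is the model's single
    sensitivity-analysis parameter.  Intended as a fast, fully specified
    test-fixture model, not a published ionic model.
    """
    return CellModel(
        name="referenceCell",
        parameters={"kFactor": 1.0},
        default_state=CellState(t=0.0, vm=_VM_REST, dvdt=0.0, vars={"w": 0.0}, cm=1.0),
        dt_config=AdaptiveDtConfig(0.005, 0.05, 0.1, dvcut=1.0),
        current_fn=_refcell_currents,
        derivative_fn=_refcell_derivatives,
        gates=frozenset({"w"}),
        full_measure_vars=frozenset({"vm"}),
        metadata={"default_stimval": 40.0, "default_stimdur": 1.0},
    )


def _passive_currents(state: CellState, params: Mapping[str, float]):
    return {}, 0.0


def _passive_derivatives(state: CellState, params: Mapping[str, float], istim: float):
    return istim / state.cm, {}


def make_passive_cell() -> CellModel:
    """Reaction-free membrane (zero ionic current): Vm only moves by stimulus
    or, in tissue, by diffusion.  Used to exercise the PDE solvers against
    analytic pure-diffusion solutions."""
    return CellModel(
        name="passive",
        parameters={},
        default_state=CellState(t=0.0, vm=0.0, dvdt=0.0, vars={}, cm=1.0),
        dt_config=AdaptiveDtConfig(0.005, 0.05, 0.1, dvcut=1.0),
        current_fn=_passive_currents,
        derivative_fn=_passive_derivatives,
    )


def _placeholder(name: str, dtmin: float, dtmed: float, dtmax: float,
                 dvdtmax: float | None) -> CellModel:
    return CellModel(
        name=name,
        parameters={},
        default_state=None,
        dt_config=AdaptiveDtConfig(dtmin, dtmed, dtmax, dvcut=1.0, dvdtmax=dvdtmax),
        metadata={"placeholder": True},
    )


def _registry() -> dict[str, Callable[[], CellModel]]:
    # Published-model entries carry their adaptive-dt tables only; their
    # equation sets are not transcribed here and attempting to integrate one
    # raises ConfigurationError.
    return {
        "referenceCell": make_reference_cell,
        "passive": make_passive_cell,
        "Grandi": lambda: _placeholder("Grandi", 0.005, 0.005, 0.005, 5.43e-10),
        "TenTusscher": lambda: _placeholder("TenTusscher", 0.005, 0.01, 0.1, 7.29e-7),
        "HundRudy": lambda: _placeholder("HundRudy", 0.005, 0.01, 0.1, 5.43e-10),
        "Kurata": lambda: _placeholder("Kurata", 0.005, 0.05, 0.05, None),
    }


MODEL_NAMES = tuple(_registry().keys())


def get_model(name: str) -> CellModel:
    """Look up a registered model by name and return a fresh instance."""
    try:
        factory = _registry()[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None
    return factory()
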