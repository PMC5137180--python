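"""Multicellular propagation: 1D fibers and 2D grids of coupled cells.

The monodomain cable equation

    dVm/dt = D * d²Vm/dx² - (I_ion - I_stim)/Cm,    D = d / (4 * Ri * Cm)

couples the membrane reaction of each node (advanced by the explicit cell
step) to axial diffusion of potential.  Diffusion is integrated implicitly:
Crank–Nicolson on fibers and the Peaceman–Rachford alternating-direction
scheme on grids (row-implicit then column-implicit half steps), both with
sealed (no-flux) boundaries.  Each step is operator-split: ionic currents are
evaluated at the start-of-step state, non-Vm variables advance one explicit
Euler step, and Vm then advances through the implicit diffusion solve with
the reaction held at its stage value.  Tridiagonal systems are solved by
banded Gaussian elimination (the Thomas recursion).

Units: lengths cm, resistivity kΩ·cm, capacitance µF/cm², time ms,
potential mV — giving D in cm²/ms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .cell_core import CellModel, CellState, ConfigurationError, select_dt
from .protocols import CurrentClampProtocol, pulse_edges, sample_times, stim_current

_GRID_SNAP = 1e-9


@dataclass
class Node:
    """One tissue node: a cell model instance, its state, and whether the
    node receives the stimulus and/or is recorded."""

    model: CellModel
    state: CellState
    stimulate: bool = False
    measure: bool = False


def make_node(model: CellModel, stimulate: bool = False, measure: bool = False) -> Node:
    return Node(model, model.default_state.copy(), stimulate, measure)


@dataclass
class FiberGeometry:
    """1D strand of nodes: node length ``dx`` (cm), fiber diameter ``d``
    (cm), intracellular resistivity ``Ri`` (kΩ·cm), capacitance ``cm``."""

    nodes: list[Node]
    dx: float = 0.01
    d: float = 0.0011
    Ri: float = 0.150
    cm: float = 1.0

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ConfigurationError("a fiber needs at least 2 nodes")
        if min(self.dx, self.Ri, self.cm) <= 0 or self.d < 0:
            raise ConfigurationError("dx, Ri, cm must be > 0 and d >= 0")


@dataclass
class GridGeometry:
    """Rectangular rows × cols sheet of nodes."""

    nodes: list[list[Node]]  # nodes[row][col]
    dx: float = 0.01
    dy: float = 0.01
    d: float = 0.0011
    Ri: float = 0.150
    cm: float = 1.0

    def __post_init__(self) -> None:
        if not self.nodes or not self.nodes[0]:
            raise ConfigurationError("grid must have at least one node")
        ncols = len(self.nodes[0])
        if any(len(row) != ncols for row in self.nodes):
            raise ConfigurationError("grid rows must all have the same length")
        if min(self.dx, self.dy, self.Ri, self.cm) <= 0 or self.d < 0:
            raise ConfigurationError("dx, dy, Ri, cm must be > 0 and d >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.nodes), len(self.nodes[0])

    def flat(self) -> list[Node]:
        return [n for row in self.nodes for n in row]


def diffusion_coefficient(g) -> float:
    """Cable diffusion coefficient D = d / (4 * Ri * cm), cm²/ms."""
    return g.d / (4.0 * g.Ri * g.cm)


# ---------------------------------------------------------------------------
# Implicit diffusion machinery
# ---------------------------------------------------------------------------

def _edge_coefficients(nodal_D: np.ndarray) -> np.ndarray:
    """Harmonic-mean conductivity on each edge between adjacent nodes.

    The harmonic mean is the series-conductance rule, the physical choice at
    an interface between unlike cells; for a homogeneous strand it reduces to
    the nodal value.
    """
    a, b = nodal_D[:-1], nodal_D[1:]
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    return h


def _nodal_D(geom, nodes: Sequence[Node]) -> np.ndarray:
    # geometry-level D everywhere; per-node overrides (metadata key
    # "D_scale") support resistive heterogeneity between unlike cells
    base = diffusion_coefficient(geom)
    return np.array(
        [base * nd.model.metadata.get("D_scale", 1.0) for nd in nodes], dtype=float
    )


def _laplacian_apply(v: np.ndarray, edge_D: np.ndarray, dx: float) -> np.ndarray:
    """No-flux variable-coefficient discrete Laplacian, L v.

    ``v`` may be 1D or (n, k) holding k independent strands along axis 0.
    """
    eD = edge_D if v.ndim == 1 else edge_D[:, None]
    flux = eD * (v[1:] - v[:-1]) / dx  # flux on interior edges
    out = np.zeros_like(v)
    out[:-1] += flux
    out[1:] -= flux
    return out / dx


def _solve_implicit(v_rhs: np.ndarray, edge_D: np.ndarray, dx: float,
                    coef: float) -> np.ndarray:
    """Solve (I - coef*L) x = v_rhs with the tridiagonal no-flux Laplacian.

    ``v_rhs`` may be 1D or (n, k) for k independent systems sharing the
    matrix.  Banded Gaussian elimination via LAPACK (Thomas recursion).
    """
    n = v_rhs.shape[0]
    w = coef * edge_D / (dx * dx)
    diag = np.ones(n)
    diag[:-1] += w
    diag[1:] += w
    upper = np.zeros(n)
    lower = np.zeros(n)
    upper[1:] = -w
    lower[:-1] = -w
    ab = np.vstack([upper, diag, lower])
    return solve_banded((1, 1), ab, v_rhs)


def _stage_reaction(nodes: Sequence[Node], dt: float, istim: np.ndarray,
                    cm: float) -> np.ndarray:
    """Evaluate reaction at the stage state and advance non-Vm variables.

    Returns R_i = (istim_i - Iion_i)/cm.  Node states' vars and t advance by
    one explicit Euler step; Vm is left for the implicit diffusion solve.
    """
    R = np.empty(len(nodes))
    for i, node in enumerate(nodes):
        st = node.state
        _, i_total = node.model.currents(st)
        R[i] = (istim[i] - i_total) / cm
        _, dvars = node.model.derivatives(st, istim[i])
        for name, value in st.vars.items():
            x = value + dt * dvars.get(name, 0.0)
            if name in node.model.gates:
                x = min(1.0, max(0.0, x))
            elif name in node.model.concentrations and x < 0.0:
                x = 0.0
            st.vars[name] = x
        st.t += dt
    return R


def cn_step(fiber: FiberGeometry, dt: float, istim: Sequence[float] | None = None) -> np.ndarray:
    """Advance the whole fiber one step of size ``dt`` (Crank–Nicolson).

    Vm solves (I - dt/2·L) v⁺ = (I + dt/2·L) v + dt·R with the reaction R at
    its stage value and no-flux ends.  Node states are updated in place; the
    new Vm vector is returned.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    nodes = fiber.nodes
    n = len(nodes)
    istim_arr = np.zeros(n) if istim is None else np.asarray(istim, dtype=float)
    v = np.array([nd.state.vm for nd in nodes])
    edge_D = _edge_coefficients(_nodal_D(fiber, nodes))
    R = _stage_reaction(nodes, dt, istim_arr, fiber.cm)
    rhs = v + (dt / 2.0) * _laplacian_apply(v, edge_D, fiber.dx) + dt * R
    v_new = _solve_implicit(rhs, edge_D, fiber.dx, dt / 2.0)
    for i, nd in enumerate(nodes):
        nd.state.dvdt = (v_new[i] - nd.state.vm) / dt
        nd.state.vm = float(v_new[i])
    return v_new


def adi_step(grid: GridGeometry, dt: float,
             istim: np.ndarray | None = None) -> np.ndarray:
    """Advance the grid one step of size ``dt`` (Peaceman–Rachford ADI).

    Half step 1 is implicit along x (within each row) and explicit along y;
    half step 2 swaps the roles.  Each half advances dt/2 and carries half of
    the stage reaction, making the scheme identical to Crank–Nicolson on a
    degenerate 1×N grid.  No-flux on all four edges.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    nrows, ncols = grid.shape
    flat = grid.flat()
    istim_arr = (np.zeros((nrows, ncols)) if istim is None
                 else np.asarray(istim, dtype=float).reshape(nrows, ncols))
    v = np.array([[nd.state.vm for nd in row] for row in grid.nodes])
    D = diffusion_coefficient(grid)
    edge_x = np.full(ncols - 1, D) if ncols > 1 else np.zeros(0)
    edge_y = np.full(nrows - 1, D) if nrows > 1 else np.zeros(0)

    R = _stage_reaction(flat, dt, istim_arr.ravel(), grid.cm).reshape(nrows, ncols)

    def lap_x(a: np.ndarray) -> np.ndarray:
        if ncols < 2:
            return np.zeros_like(a)
        return _laplacian_apply(a.T, edge_x, grid.dx).T

    def lap_y(a: np.ndarray) -> np.ndarray:
        if nrows < 2:
            return np.zeros_like(a)
        return _laplacian_apply(a, edge_y, grid.dy)

    half = dt / 2.0
    # half step 1: implicit in x, explicit in y
    rhs1 = v + half * lap_y(v) + half * R
    if ncols > 1:
        v_star = _solve_implicit(rhs1.T, edge_x, grid.dx, half).T
    else:
        v_star = rhs1
    # half step 2: implicit in y, explicit in x
    rhs2 = v_star + half * lap_x(v_star) + half * R
    if nrows > 1:
        v_new = _solve_implicit(rhs2, edge_y, grid.dy, half)
    else:
        v_new = rhs2

    for (r, c), nd in zip(((r, c) for r in range(nrows) for c in range(ncols)), flat):
        nd.state.dvdt = (v_new[r, c] - nd.state.vm) / dt
        nd.state.vm = float(v_new[r, c])
    return v_new


# ---------------------------------------------------------------------------
# Tissue simulation driver
# ---------------------------------------------------------------------------

def tissue_dt(nodes: Sequence[Node], boundary: float) -> float:
    """Global adaptive step: minimum of every member cell's selection, so the
    implicit solve stays synchronized across nodes."""
    return min(select_dt(nd.state, nd.model.dt_config, boundary) for nd in nodes)


def _simulate(step_fn, nodes, geom, protocol: CurrentClampProtocol,
              dt: float | None):
    p = protocol
    stim_mask = np.array([nd.stimulate for nd in nodes], dtype=float)
    samples = sample_times(p.writetime, p.writeint, p.tMax)
    boundaries = sorted({float(b) for b in samples}
                        | {e for e in pulse_edges(p)} | {p.tMax})
    t = min(nd.state.t for nd in nodes)
    times: list[float] = []
    vm_rows: list[np.ndarray] = []

    def record() -> None:
        times.append(t)
        vm_rows.append(np.array([nd.state.vm for nd in nodes]))

    sample_iter = iter(samples)
    next_sample = next(sample_iter, None)
    if next_sample is not None and abs(t - next_sample) < _GRID_SNAP:
        record()
        next_sample = next(sample_iter, None)

    for b in boundaries:
        if b <= t + _GRID_SNAP:
            continue
        while t < b - _GRID_SNAP:
            h = dt if dt is not None else tissue_dt(nodes, b)
            h = min(h, b - t)
            istim = stim_mask * stim_current(t, p)
            step_fn(h, istim)
            t += h
        t = b
        for nd in nodes:
            nd.state.t = t
        if next_sample is not None and abs(b - next_sample) < _GRID_SNAP:
            record()
            next_sample = next(sample_iter, None)

    return np.asarray(times), np.vstack(vm_rows) if vm_rows else np.empty((0, len(nodes)))


def simulate_fiber(fiber: FiberGeometry, protocol: CurrentClampProtocol,
                   dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pace a fiber through a current-clamp protocol; stimulated nodes get
    the pulse train.  Returns (sample times, Vm matrix of shape
    (nsamples, nnodes)).  ``dt`` fixes the step; None selects adaptively."""
    return _simulate(lambda h, istim: cn_step(fiber, h, istim),
                     fiber.nodes, fiber, protocol, dt)


def simulate_grid(grid: GridGeometry, protocol: CurrentClampProtocol,
                  dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Grid counterpart of :func:`simulate_fiber`; Vm matrix columns follow
    row-major node order."""
    return _simulate(lambda h, istim: adi_step(grid, h, istim),
                     grid.flat(), grid, protocol, dt)


# ---------------------------------------------------------------------------
# Conduction analysis
# ---------------------------------------------------------------------------

def activation_map(times: np.ndarray, vm: np.ndarray,
                   threshold: float = -20.0) -> np.ndarray:
    """Per-node activation time: the first upward crossing of ``threshold``,
    linearly interpolated between samples.  NaN marks unactivated nodes."""
    times = np.asarray(times, dtype=float)
    vm = np.asarray(vm, dtype=float)
    nnodes = vm.shape[1]
    act = np.full(nnodes, np.nan)
    for j in range(nnodes):
        y = vm[:, j]
        above = y >= threshold
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            if above.size and above[0]:
                act[j] = times[0]
            continue
        i = idx[0]
        frac = (threshold - y[i]) / (y[i + 1] - y[i])
        act[j] = times[i] + frac * (times[i + 1] - times[i])
    return act


def conduction_velocity(act_times: np.ndarray, dx: float,
                        skip: int = 2) -> float:
    """Planar-wave conduction velocity in cm/ms from a fiber activation map.

    Fits activation time against node position by least squares (discarding
    ``skip`` nodes at each end to avoid stimulus and boundary artifacts);
    CV = 1/slope.
    """
    act = np.asarray(act_times, dtype=float)
    idx = np.arange(act.size)
    sel = slice(skip, act.size - skip if skip else act.size)
    tsel, xsel = act[sel], idx[sel] * dx
    if np.any(np.isnan(tsel)) or tsel.size < 2:
        raise ValueError("fiber not fully activated in the fitted region")
    slope = np.polyfit(xsel, tsel, 1)[0]
    if slope <= 0:
        raise ValueError(f"non-positive activation-time slope {slope}")
    return float(1.0 / slope)
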