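"""Plain-text settings, trace, measurement and cell-state files.

Four settings dialects travel with every run so that output data can always
be cross-referenced with the exact configuration that produced it:

``simvars.txt``
    ``name value`` lines controlling the protocol (bcl, stimdur, tMax, ...)
    plus the protocol kind;
``pvars.txt``
    one parameter-sensitivity spec per line
    (``name init value`` / ``name iter init increment`` /
    ``name random distribution mean sd``);
``dvars.txt``
    one output-variable name per line (t and vm are always written);
``mvars.txt``
    ``variable property...`` lines selecting measured per-beat properties.

All files are whitespace-delimited UTF-8 text with ``#`` comments, LF line
endings, and numbers printed in shortest round-trip decimal form so that
read∘write is exact.  Per-trial outputs are ``dt{trial}_dvars.txt``
(tab-delimited trace) and ``dt{trial}_mvars.txt`` (per-beat measures); a
final-state snapshot is ``dss0_cellState.txt``.  Every run lives in its own
timestamped directory, which ``import_settings`` can later reload to
reproduce the run exactly.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cell_core import CellModel, CellState, ConfigurationError
from .measure import MeasureSpec
from .protocols import CurrentClampProtocol, VoltageClampProtocol
from .sensitivity import PvarSpec

logger = logging.getLogger(__name__)

SIMVARS_FILE = "simvars.txt"
PVARS_FILE = "pvars.txt"
DVARS_FILE = "dvars.txt"
MVARS_FILE = "mvars.txt"
CELLSTATE_FILE = "dss0_cellState.txt"
NOTES_FILE = "notes.txt"
SETTINGS_FILES = (SIMVARS_FILE, PVARS_FILE, DVARS_FILE, MVARS_FILE)


class ParseError(ValueError):
    """Malformed settings file; carries the offending path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _fmt(value) -> str:
    """Shortest round-trip text form (repr for floats, 0/1 for bools)."""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _content_lines(path) -> list[tuple[int, str]]:
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append((lineno, line))
    return out


# ---------------------------------------------------------------------------
# simvars
# ---------------------------------------------------------------------------

_PROTOCOL_CLASSES = {"currentClamp": CurrentClampProtocol,
                     "voltageClamp": VoltageClampProtocol,
                     "grid": CurrentClampProtocol}


def _field_types(kind: str) -> dict[str, type]:
    cls = _PROTOCOL_CLASSES[kind]
    return {f.name: f.type if isinstance(f.type, type) else
            {"float": float, "int": int, "bool": bool}[f.type]
            for f in dataclasses.fields(cls)}


def write_simvars(path, protocol, extra: Mapping[str, object] | None = None) -> None:
    """Write a protocol's parameters as ``name value`` lines."""
    lines = [f"protocol {protocol.kind}"]
    for f in dataclasses.fields(protocol):
        lines.append(f"{f.name} {_fmt(getattr(protocol, f.name))}")
    for k, v in (extra or {}).items():
        lines.append(f"{k} {_fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_simvars(path, kind: str | None = None):
    """Parse a simvars file into a protocol object.

    Missing keys take the protocol defaults (an empty file yields the full
    default protocol, numstims=500 included); unknown keys warn and are
    ignored; a value that does not parse raises :class:`ParseError` with the
    line number.
    """
    entries: dict[str, str] = {}
    linenos: dict[str, int] = {}
    for lineno, line in _content_lines(path):
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 'name value', got {line!r}")
        entries[parts[0]] = parts[1]
        linenos[parts[0]] = lineno
    file_kind = entries.pop("protocol", None)
    kind = kind or file_kind or "currentClamp"
    if kind not in _PROTOCOL_CLASSES:
        raise ParseError(path, linenos.get("protocol", 1),
                         f"unknown protocol kind {kind!r}")
    types = _field_types(kind)
    kwargs = {}
    for name, text in entries.items():
        if name not in types:
            warnings.warn(f"{path}: ignoring unknown simvars key {name!r}")
            continue
        typ = types[name]
        try:
            if typ is bool:
                kwargs[name] = text.lower() in ("1", "true", "yes", "on")
                if text.lower() not in ("0", "1", "true", "false", "yes", "no", "on", "off"):
                    raise ValueError
            elif typ is int:
                kwargs[name] = int(float(text))
            else:
                kwargs[name] = float(text)
        except ValueError:
            raise ParseError(path, linenos[name],
                             f"cannot parse value {text!r} for {name!r}") from None
    return _PROTOCOL_CLASSES[kind](**kwargs)


# ---------------------------------------------------------------------------
# pvars / dvars / mvars
# ---------------------------------------------------------------------------

def write_pvars(path, specs: Iterable[PvarSpec]) -> None:
    lines = []
    for s in specs:
        if s.mode == "init":
            lines.append(f"{s.parameter} init {_fmt(float(s.init_value))}")
        elif s.mode == "iter":
            lines.append(
                f"{s.parameter} iter {_fmt(float(s.init_value))} {_fmt(float(s.increment))}"
            )
        else:
            lines.append(
                f"{s.parameter} random {s.distribution} "
                f"{_fmt(float(s.mean))} {_fmt(float(s.standard_deviation))}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_pvars(path) -> list[PvarSpec]:
    specs = []
    for lineno, line in _content_lines(path):
        parts = line.split()
        try:
            name, mode = parts[0], parts[1]
            if mode == "init":
                specs.append(PvarSpec(name, "init", init_value=float(parts[2])))
            elif mode == "iter":
                specs.append(PvarSpec(name, "iter", init_value=float(parts[2]),
                                      increment=float(parts[3])))
            elif mode == "random":
                specs.append(PvarSpec(name, "random", distribution=parts[2],
                                      mean=float(parts[3]),
                                      standard_deviation=float(parts[4])))
            else:
                raise ParseError(path, lineno, f"unknown pvar mode {mode!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(path, lineno, f"malformed pvar line {line!r}") from None
    return specs


def write_dvars(path, variables: Iterable[str]) -> None:
    names = ["t", "vm"]
    for v in variables:
        if v not in names:
            names.append(v)
    Path(path).write_text("\n".join(names) + "\n")


def read_dvars(path) -> list[str]:
    names = ["t", "vm"]  # always forced on
    for lineno, line in _content_lines(path):
        parts = line.split()
        if len(parts) != 1:
            raise ParseError(path, lineno, f"expected one variable name, got {line!r}")
        if parts[0] not in names:
            names.append(parts[0])
    return names


def write_mvars(path, specs: Iterable[MeasureSpec]) -> None:
    lines = [" ".join([s.variable, *s.properties]) for s in specs]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_mvars(path) -> list[MeasureSpec]:
    specs = []
    for lineno, line in _content_lines(path):
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(path, lineno,
                             f"expected 'variable property...', got {line!r}")
        try:
            specs.append(MeasureSpec(parts[0], tuple(parts[1:])))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return specs


# ---------------------------------------------------------------------------
# traces / measures
# ---------------------------------------------------------------------------

def trace_path(directory, trial: int) -> Path:
    return Path(directory) / f"dt{trial}_dvars.txt"


def measures_path(directory, trial: int) -> Path:
    return Path(directory) / f"dt{trial}_mvars.txt"


def write_trace(path, trace: pd.DataFrame) -> None:
    """Tab-delimited trace with a header row; first columns are t and vm."""
    cols = list(trace.columns)
    if cols[:2] != ["t", "vm"]:
        raise ConfigurationError(f"trace must start with t, vm columns, got {cols[:2]}")
    trace.to_csv(path, sep="\t", index=False, float_format=None)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_measures(path, measures: pd.DataFrame) -> None:
    measures.to_csv(path, sep="\t", index=False)


def read_measures(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cell-state snapshots
# ---------------------------------------------------------------------------

def write_cell_state(path, state: CellState) -> None:
    """Snapshot every state variable (plus t, vm, dvdt, cm) exactly."""
    lines = [f"t {_fmt(float(state.t))}",
             f"vm {_fmt(float(state.vm))}",
             f"dvdt {_fmt(float(state.dvdt))}",
             f"cm {_fmt(float(state.cm))}"]
    lines += [f"{name} {_fmt(float(v))}" for name, v in state.vars.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cell_state(path, model: CellModel) -> CellState:
    """Load a snapshot and validate it covers every variable of ``model``.

    Missing variables are an error naming them; extra entries warn and are
    dropped.
    """
    values: dict[str, float] = {}
    for lineno, line in _content_lines(path):
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 'name value', got {line!r}")
        try:
            values[parts[0]] = float(parts[1])
        except ValueError:
            raise ParseError(path, lineno, f"cannot parse value {parts[1]!r}") from None
    required = ["t", "vm"] + list(model.default_state.vars.keys())
    missing = [n for n in required if n not in values]
    if missing:
        raise ConfigurationError(
            f"cell-state file {path} is missing variable(s) {missing} "
            f"required by model {model.name!r}"
        )
    extra = set(values) - set(required) - {"dvdt", "cm"}
    if extra:
        warnings.warn(f"{path}: ignoring extra cell-state entries {sorted(extra)}")
    return CellState(
        t=values["t"],
        vm=values["vm"],
        dvdt=values.get("dvdt", 0.0),
        vars={n: values[n] for n in model.default_state.vars},
        cm=values.get("cm", model.default_state.cm),
    )


# ---------------------------------------------------------------------------
# run directories
# ---------------------------------------------------------------------------

def create_run_directory(base, when: datetime | None = None) -> Path:
    """Create a timestamped run directory (ISO-8601 basic, sorts lexically)."""
    base = Path(base)
    base.mkdir(parents=True, exist_ok=True)
    stamp = (when or datetime.now()).strftime("%Y%m%d-%H%M%S")
    path = base / stamp
    suffix = 1
    while path.exists():
        suffix += 1
        path = base / f"{stamp}-{suffix}"
    path.mkdir()
    return path


def write_run_settings(directory, protocol, pvars: Sequence[PvarSpec] = (),
                       dvars: Sequence[str] = (), mvars: Sequence[MeasureSpec] = (),
                       notes: str | None = None,
                       extra_simvars: Mapping[str, object] | None = None) -> None:
    directory = Path(directory)
    write_simvars(directory / SIMVARS_FILE, protocol, extra_simvars)
    write_pvars(directory / PVARS_FILE, pvars)
    write_dvars(directory / DVARS_FILE, dvars)
    write_mvars(directory / MVARS_FILE, mvars)
    if notes:
        (directory / NOTES_FILE).write_text(notes + "\n")


# ---------------------------------------------------------------------------
# tissue geometry
# ---------------------------------------------------------------------------

GEOMETRY_FILE = "geometry.txt"
GEOMETRY_STIM_FILE = "geometry_stim.txt"
GEOMETRY_MEASURE_FILE = "geometry_measure.txt"


def write_geometry(directory, grid) -> None:
    """Serialize a grid: one line per row of comma-separated model names,
    plus sidecar lists of stimulated / measured node coordinates
    (``row,col``, 0-based)."""
    directory = Path(directory)
    rows = [",".join(nd.model.name for nd in row) for row in grid.nodes]
    (directory / GEOMETRY_FILE).write_text("\n".join(rows) + "\n")
    stim, meas = [], []
    for r, row in enumerate(grid.nodes):
        for c, nd in enumerate(row):
            if nd.stimulate:
                stim.append(f"{r},{c}")
            if nd.measure:
                meas.append(f"{r},{c}")
    (directory / GEOMETRY_STIM_FILE).write_text("\n".join(stim) + ("\n" if stim else ""))
    (directory / GEOMETRY_MEASURE_FILE).write_text("\n".join(meas) + ("\n" if meas else ""))


def read_geometry(directory, dx: float = 0.01, dy: float = 0.01,
                  d: float = 0.0011, Ri: float = 0.150, cm: float = 1.0):
    """Load a serialized grid geometry; model names resolve via the registry."""
    from .cell_core import get_model
    from .tissue import GridGeometry, make_node

    directory = Path(directory)
    grid_path = directory / GEOMETRY_FILE
    if not grid_path.exists():
        raise ConfigurationError(f"no {GEOMETRY_FILE} in {directory}")
    nodes = []
    for lineno, line in _content_lines(grid_path):
        row = []
        for name in line.split(","):
            model = get_model(name.strip())
            if not model.simulatable:
                raise ParseError(grid_path, lineno,
                                 f"model {name.strip()!r} cannot be simulated")
            row.append(make_node(model))
        nodes.append(row)
    grid = GridGeometry(nodes, dx=dx, dy=dy, d=d, Ri=Ri, cm=cm)

    def _mark(path, attr):
        if not path.exists():
            return
        for lineno, line in _content_lines(path):
            try:
                r, c = (int(x) for x in line.split(","))
                setattr(grid.nodes[r][c], attr, True)
            except (ValueError, IndexError):
                raise ParseError(path, lineno, f"bad node coordinate {line!r}") from None

    _mark(directory / GEOMETRY_STIM_FILE, "stimulate")
    _mark(directory / GEOMETRY_MEASURE_FILE, "measure")
    return grid


def import_settings(source_dir) -> dict:
    """Load whichever of the four settings files a prior run directory holds.

    Returns a dict with any of the keys ``protocol``, ``pvars``, ``dvars``,
    ``mvars``; settings whose file is absent are simply not present, leaving
    the caller's current values untouched.  A directory with none of the
    four is an error.
    """
    source = Path(source_dir)
    found: dict = {}
    if (source / SIMVARS_FILE).exists():
        found["protocol"] = read_simvars(source / SIMVARS_FILE)
    if (source / PVARS_FILE).exists():
        found["pvars"] = read_pvars(source / PVARS_FILE)
    if (source / DVARS_FILE).exists():
        found["dvars"] = read_dvars(source / DVARS_FILE)
    if (source / MVARS_FILE).exists():
        found["mvars"] = read_mvars(source / MVARS_FILE)
    if not found:
        raise ConfigurationError(
            f"{source} contains none of the settings files {SETTINGS_FILES}"
        )
    return found
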