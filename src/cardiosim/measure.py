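"""Streaming per-beat measurement of state-variable properties.

One :class:`Measurer` watches one sampled variable (typically Vm or bulk
intracellular Ca²⁺) and segments it into beats on the fly, reporting per
completed beat: the diastolic minimum, peak, amplitude, time of peak, maximum
upstroke derivative, cycle length and the fractional-repolarization duration
(APD90 by default).

Beat segmentation (identical rule in the array-based test oracle):

* between beats the running minimum and running baseline peak track the
  signal; a beat opens when a sample rises above
  ``min + 0.1 * (baseline_peak - min)`` — i.e. above the recent baseline;
* within a beat the peak and the maximum finite-difference derivative are
  tracked; the beat closes at the downward crossing of
  ``min + 0.1 * amplitude`` (90 % recovery), found by linear interpolation;
* ``dur(f)`` runs from the time of maximum derivative to the interpolated
  downward crossing of ``peak - f * amplitude``;
* ``cl`` is the spacing between successive maximum-derivative times.

Running min and baseline peak reset after each completed beat so drifting
baselines are followed.  All crossing times are linearly interpolated between
samples, making results insensitive to the output sampling interval to first
order.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

logger = logging.getLogger(__name__)

PROPERTIES = ("min", "peak", "amplitude", "dur", "maxderiv", "t_peak", "cl")
#: variables for which the full utility (dur, maxderiv, cl) is supported;
#: peak/min/amplitude work for any state variable.
FULL_MEASURE_PROPS = frozenset({"dur", "maxderiv", "cl"})
TAKEOFF_FRACTION = 0.1  # beat opens/closes at min + 10% of amplitude


@dataclass(frozen=True)
class MeasureSpec:
    """Which properties to measure on which variable."""

    variable: str
    properties: tuple[str, ...] = PROPERTIES
    fraction: float = 0.9  # repolarization fraction for dur

    def __post_init__(self) -> None:
        bad = set(self.properties) - set(PROPERTIES)
        if bad:
            raise ValueError(f"unknown measure properties {sorted(bad)}; valid: {PROPERTIES}")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")

    def validate_for(self, full_measure_vars: frozenset[str]) -> None:
        restricted = set(self.properties) & FULL_MEASURE_PROPS
        if restricted and self.variable not in full_measure_vars:
            raise ValueError(
                f"properties {sorted(restricted)} are only supported for "
                f"{sorted(full_measure_vars)}, not {self.variable!r} "
                "(peak/min/amplitude work for any state variable)"
            )


@dataclass
class BeatMeasurement:
    """Property values of one completed beat (durations in ms, others in the
    units of the measured variable)."""

    beat: int
    values: dict[str, float] = field(default_factory=dict)


class Measurer:
    """Streaming beat segmentation and property measurement for one variable.

    Feed samples in strictly increasing time order with :meth:`update`;
    completed beats accumulate in :attr:`beats`.
    """

    def __init__(self, spec: MeasureSpec):
        self.spec = spec
        self.beats: list[BeatMeasurement] = []
        self._t_prev: float | None = None
        self._y_prev: float | None = None
        self._in_beat = False
        self._base_min = math.inf
        self._base_peak = -math.inf
        # per-beat accumulators
        self._beat_min = math.nan
        self._beat_peak = -math.inf
        self._beat_t_peak = math.nan
        self._beat_maxderiv = -math.inf
        self._beat_t_maxderiv = math.nan
        self._prev_t_maxderiv: float | None = None
        # deep-repolarization target still open after beat close (fraction > 0.9)
        self._pending: dict | None = None

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _cross_down(t0, y0, t1, y1, level):
        """Interpolated time where the segment (t0,y0)->(t1,y1) falls to level."""
        if y0 == y1:
            return t1
        return t0 + (y0 - level) * (t1 - t0) / (y0 - y1)

    def _emit(self, beat_values: dict[str, float]) -> None:
        wanted = {p: beat_values.get(p, math.nan) for p in self.spec.properties}
        self.beats.append(BeatMeasurement(len(self.beats), wanted))

    # -- streaming entry point --------------------------------------------

    def update(self, t: float, value: float, dvalue_dt: float | None = None) -> None:
        """Process one sample; ``dvalue_dt`` defaults to the finite difference
        against the previous sample."""
        if self._t_prev is not None and t <= self._t_prev:
            raise ValueError(f"non-monotone sample time {t} after {self._t_prev}")
        if dvalue_dt is None:
            if self._t_prev is None:
                deriv = 0.0
            else:
                deriv = (value - self._y_prev) / (t - self._t_prev)
        else:
            deriv = dvalue_dt

        if self._pending is not None and self._t_prev is not None:
            p = self._pending
            if self._y_prev >= p["level"] > value:
                t_rep = self._cross_down(self._t_prev, self._y_prev, t, value, p["level"])
                p["values"]["dur"] = t_rep - p["values"]["_t_maxderiv"]
                self._emit(p["values"])
                self._pending = None

        if not self._in_beat:
            threshold = self._base_min + TAKEOFF_FRACTION * (self._base_peak - self._base_min)
            if (self._t_prev is not None and value > threshold
                    and self._base_min < math.inf):
                self._open_beat(t, value, deriv)
            else:
                self._base_min = min(self._base_min, value)
                self._base_peak = max(self._base_peak, value)
        else:
            self._advance_beat(t, value, deriv)

        self._t_prev, self._y_prev = t, value

    def _open_beat(self, t, value, deriv) -> None:
        self._in_beat = True
        self._beat_min = self._base_min
        self._beat_peak = value
        self._beat_t_peak = t
        self._beat_maxderiv = deriv
        self._beat_t_maxderiv = t
        # the beat's samples are buffered until close: amplitude-relative
        # quantities (dur) are only well defined against the final peak
        self._beat_samples: list[tuple[float, float]] = [(t, value)]

    def _advance_beat(self, t, value, deriv) -> None:
        self._beat_samples.append((t, value))
        if value > self._beat_peak:
            self._beat_peak = value
            self._beat_t_peak = t
        # first attainment of the maximum wins: require a relatively
        # significant increase so float noise on equal slopes (e.g. a linear
        # upstroke) cannot jitter the maxderiv time across samples
        if deriv > self._beat_maxderiv + 1e-9 * max(1.0, abs(self._beat_maxderiv)):
            self._beat_maxderiv = deriv
            self._beat_t_maxderiv = t
        amp = self._beat_peak - self._beat_min
        close_level = self._beat_min + TAKEOFF_FRACTION * amp
        if self._y_prev >= close_level > value:
            self._close_beat(t, value)

    def _beat_dur_from_buffer(self, level: float) -> float:
        """First interpolated downward crossing of ``level`` after the peak.

        Repolarization follows the peak by definition; earlier downward
        wiggles (e.g. a blocked-stimulus blip before the true upstroke) must
        not terminate the duration measurement.
        """
        buf = self._beat_samples
        for (t0, y0), (t1, y1) in zip(buf, buf[1:]):
            if t0 < self._beat_t_peak:
                continue
            if y0 >= level > y1:
                return self._cross_down(t0, y0, t1, y1, level) - self._beat_t_maxderiv
        return math.nan

    def _close_beat(self, t, value) -> None:
        self._in_beat = False
        amp = self._beat_peak - self._beat_min
        cl = math.nan
        if self._prev_t_maxderiv is not None:
            cl = self._beat_t_maxderiv - self._prev_t_maxderiv
        self._prev_t_maxderiv = self._beat_t_maxderiv
        dur = self._beat_dur_from_buffer(
            self._beat_peak - self.spec.fraction * amp)
        values = {
            "min": self._beat_min,
            "peak": self._beat_peak,
            "amplitude": amp,
            "t_peak": self._beat_t_peak,
            "maxderiv": self._beat_maxderiv,
            "cl": cl,
            "dur": dur,
            "_t_maxderiv": self._beat_t_maxderiv,
        }
        self._beat_samples = []
        if math.isnan(dur) and self.spec.fraction > 0.9:
            # the requested repolarization level lies below the 90% close
            # threshold; keep scanning post-beat samples for the crossing
            self._pending = {
                "level": self._beat_peak - self.spec.fraction * amp,
                "values": values,
            }
        else:
            self._emit(values)
        self._base_min = math.inf
        self._base_peak = -math.inf

    def finish(self) -> list[BeatMeasurement]:
        """Flush; a beat still open at the end of the trace is discarded."""
        if self._in_beat:
            logger.warning(
                "%s: beat in progress at end of trace never repolarized; discarded",
                self.spec.variable,
            )
            self._in_beat = False
        if self._pending is not None:
            logger.warning(
                "%s: deep repolarization level never reached; dur reported as nan",
                self.spec.variable,
            )
            self._emit(self._pending["values"])
            self._pending = None
        return self.beats


def measure_trace(
    spec: MeasureSpec, t: Sequence[float], y: Sequence[float]
) -> list[BeatMeasurement]:
    """Run the streaming measurer over a stored trace."""
    m = Measurer(spec)
    for ti, yi in zip(t, y):
        m.update(float(ti), float(yi))
    return m.finish()


def restitution(beats: Sequence[BeatMeasurement]) -> list[tuple[float, float]]:
    """Pair each beat's preceding cycle length with its duration.

    Requires at least two completed beats (the first beat has no preceding
    cycle); returns an empty list otherwise.
    """
    pairs = []
    for b in beats:
        cl = b.values.get("cl", math.nan)
        dur = b.values.get("dur", math.nan)
        if not math.isnan(cl):
            pairs.append((cl, dur))
    return pairs
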