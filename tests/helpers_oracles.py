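"""Independent oracles shared across the test suite.

Everything here deliberately avoids the package's streaming/adaptive code
paths: fixed-step integration loops, closed-form signals, and a two-pass
array implementation of the beat-measurement definition.
"""
from __future__ import annotations

import math

import numpy as np

from cardiosim.cell_core import CellModel, CellState, euler_step


def integrate_fixed(model: CellModel, state: CellState, t_end: float, dt: float,
                    istim_fn, sample_every: float | None = None):
    """Fixed-step forward-Euler reference integration.

    Returns (sample times, vm values) on the ``sample_every`` grid (defaults
    to every step).  The stimulus is evaluated at the start of each step.
    """
    s = state.copy()
    times = [s.t]
    vms = [s.vm]
    next_sample = s.t + (sample_every or dt)
    while s.t < t_end - 1e-12:
        h = min(dt, t_end - s.t)
        s = euler_step(s, model, istim_fn(s.t), h)
        if sample_every is None or s.t >= next_sample - 1e-9:
            times.append(s.t)
            vms.append(s.vm)
            if sample_every is not None:
                next_sample += sample_every
    return np.asarray(times), np.asarray(vms), s


def pulse_istim(onset: float, dur: float, amp: float):
    return lambda t: amp if onset <= t < onset + dur else 0.0


# ---------------------------------------------------------------------------
# Beat-measurement oracle: same segmentation definition as the streaming
# measurer, re-derived with full-array operations (argmax/argmin, np.interp).
# ---------------------------------------------------------------------------

TAKEOFF = 0.1


def _interp_cross_down(t0, y0, t1, y1, level):
    if y0 == y1:
        return t1
    return t0 + (y0 - level) * (t1 - t0) / (y0 - y1)


def oracle_measure(t, y, fraction: float = 0.9):
    """Brute-force per-beat properties of a sampled trace.

    Phase 1 scans for beat windows with the takeoff/close threshold rule;
    phase 2 computes each beat's properties from array slices.
    Returns a list of dicts (one per completed beat).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    deriv = np.zeros_like(y)
    deriv[1:] = np.diff(y) / np.diff(t)

    # ---- phase 1: segmentation boundaries -------------------------------
    windows = []  # (open_idx, close_idx, base_min)
    base_min, base_peak = math.inf, -math.inf
    in_beat = False
    open_idx = beat_min = None
    beat_peak = -math.inf
    for i in range(len(y)):
        if not in_beat:
            thr = base_min + TAKEOFF * (base_peak - base_min)
            if i > 0 and base_min < math.inf and y[i] > thr:
                in_beat = True
                open_idx, beat_min, beat_peak = i, base_min, y[i]
            else:
                base_min = min(base_min, y[i])
                base_peak = max(base_peak, y[i])
        else:
            beat_peak = max(beat_peak, y[i])
            close_level = beat_min + TAKEOFF * (beat_peak - beat_min)
            if y[i - 1] >= close_level > y[i]:
                windows.append((open_idx, i, beat_min))
                in_beat = False
                base_min, base_peak = math.inf, -math.inf
    # ---- phase 2: per-beat properties from array slices -----------------
    beats = []
    prev_t_maxderiv = None
    for open_idx, close_idx, bmin in windows:
        seg = slice(open_idx, close_idx + 1)
        ts, ys, ds = t[seg], y[seg], deriv[seg]
        i_peak = int(np.argmax(ys))
        peak = float(ys[i_peak])
        amp = peak - bmin
        i_md = int(np.argmax(ds))
        t_maxderiv = float(ts[i_md])
        # dur: first interpolated downward crossing of peak - f*amp at or
        # after the peak (repolarization follows the peak by definition)
        level = peak - fraction * amp
        dur = math.nan
        j_candidates = np.nonzero((ys[:-1] >= level) & (ys[1:] < level)
                                  & (np.arange(len(ys) - 1) >= i_peak))[0]
        for j in j_candidates:
            t_rep = _interp_cross_down(ts[j], ys[j], ts[j + 1], ys[j + 1], level)
            dur = t_rep - t_maxderiv
            break
        if math.isnan(dur) and fraction > 0.9:
            # deep level lies beyond the close threshold: scan the tail
            tail = slice(close_idx, len(y))
            yt, tt = y[tail], t[tail]
            jj = np.nonzero((yt[:-1] >= level) & (yt[1:] < level))[0]
            if jj.size:
                j = jj[0]
                t_rep = _interp_cross_down(tt[j], yt[j], tt[j + 1], yt[j + 1], level)
                dur = t_rep - t_maxderiv
        cl = math.nan if prev_t_maxderiv is None else t_maxderiv - prev_t_maxderiv
        prev_t_maxderiv = t_maxderiv
        beats.append({
            "min": float(bmin),
            "peak": peak,
            "amplitude": amp,
            "t_peak": float(ts[i_peak]),
            "maxderiv": float(ds[i_md]),
            "dur": dur,
            "cl": cl,
        })
    return beats


# ---------------------------------------------------------------------------
# Synthetic trace generators
# ---------------------------------------------------------------------------

def triangle_trace(baseline=-85.0, peak=25.0, rise=2.0, fall=8.0,
                   onset=20.0, dt=0.1, t_end=60.0, undershoot=0.0):
    """Piecewise-linear single pulse; closed-form properties are trivial."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = np.full_like(t, baseline)
    apex = onset + rise
    end = apex + fall
    rising = (t >= onset) & (t <= apex)
    falling = (t > apex) & (t <= end)
    y[rising] = baseline + (peak - baseline) * (t[rising] - onset) / rise
    y[falling] = peak - (peak - baseline + undershoot) * (t[falling] - apex) / fall
    after = t > end
    y[after] = baseline - undershoot
    return t, y


def random_ap_train(rng: np.random.Generator, n_beats=3, dt=0.25):
    """Smooth randomized AP-like pulse train for oracle-equivalence tests."""
    baseline = -90.0 + 10.0 * rng.random()
    t_end = 150.0 * n_beats + 50.0
    t = np.arange(0.0, t_end, dt)
    y = np.full_like(t, baseline)
    onset = 30.0 + 20.0 * rng.random()
    for _ in range(n_beats):
        amp = 80.0 + 50.0 * rng.random()
        tau_r = 1.0 + 2.0 * rng.random()
        tau_d = 25.0 + 30.0 * rng.random()
        rel = t - onset
        shape = np.where(rel > 0,
                         (1 - np.exp(-np.maximum(rel, 0) / tau_r))
                         * np.exp(-np.maximum(rel, 0) / tau_d), 0.0)
        y = y + amp * shape
        onset += 120.0 + 60.0 * rng.random()
    return t, y
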