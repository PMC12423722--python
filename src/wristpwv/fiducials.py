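"""Morphological landmark detection in PPG cycles and their derivatives.

Within one cycle the systolic peak, dicrotic notch and diastolic peak are
located on the pulse itself; the maximal-slope point is the first local
maximum of the first derivative (FDPPG); and the conventional a-f points
are ordered extrema of the second derivative (SDPPG): a and c are local
maxima, b and d local minima in systole, e the local maximum around the
systole/diastole boundary and f the first local minimum after e.  Wrist
pulses frequently lack a visible diastolic peak; absent landmarks are
reported by name in ``missing`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import PulseCycle

__all__ = ["FiducialSet", "derivative_signal", "locate_ppg_landmarks",
           "locate_max_slope", "locate_sdppg_points", "extract_fiducials"]


@dataclass
class FiducialSet:
    """Cycle-relative landmark positions (samples) and amplitudes."""

    n_sys: int | None = None
    A_sys: float | None = None
    n_notch: int | None = None
    A_notch: float | None = None
    n_dia: int | None = None
    A_dia: float | None = None
    n_ms: int | None = None
    A_ms1: float | None = None  # FDPPG amplitude at the max-slope point
    # SDPPG points: name -> (position, SDPPG amplitude)
    sdppg: dict[str, tuple[int, float]] = field(default_factory=dict)
    n_R: int | None = None
    n_T: int | None = None
    missing: set[str] = field(default_factory=set)

    def sdppg_pos(self, name: str) -> int | None:
        return self.sdppg[name][0] if name in self.sdppg else None

    def sdppg_amp(self, name: str) -> float | None:
        return self.sdppg[name][1] if name in self.sdppg else None


def derivative_signal(cycle: PulseCycle, order: int) -> np.ndarray:
    """Central-difference derivative of the cycle, scaled by 1/Ts per order."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    d = np.gradient(cycle.samples, cycle.Ts)
    if order == 2:
        d = np.gradient(d, cycle.Ts)
    return d


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-sample moving average (edges shrink the window) to kill plateaus."""
    return np.convolve(x, np.ones(3) / 3.0, mode="same")


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict interior local maxima, earliest-first."""
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def _local_minima(x: np.ndarray) -> np.ndarray:
    return np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])) + 1


def locate_ppg_landmarks(cycle: PulseCycle, prominence_frac: float = 0.05) -> FiducialSet:
    """Locate systolic peak, dicrotic notch and diastolic peak on the pulse.

    The systolic peak is the first prominent maximum; the notch is the
    first local minimum after it and the diastolic peak the first local
    maximum after the notch.  Either may be genuinely absent in wrist
    pulses and is then recorded in ``missing``.
    """
    s = _smooth3(cycle.samples)
    rng = float(np.max(s) - np.min(s))
    if rng <= 0:
        raise ValueError("flat cycle has no systolic peak")
    fs_set = FiducialSet()
    maxima = _local_maxima(s)
    prominent = [i for i in maxima if s[i] - np.min(s) >= 0.5 * rng]
    if not prominent:
        raise ValueError("no prominent systolic maximum found")
    n_sys = int(prominent[0])
    fs_set.n_sys = n_sys
    fs_set.A_sys = float(cycle.samples[n_sys])

    minima = _local_minima(s)
    after = [i for i in minima if i > n_sys and i < 0.9 * cycle.M]
    if after:
        n_notch = int(after[0])
        fs_set.n_notch = n_notch
        fs_set.A_notch = float(cycle.samples[n_notch])
        dia = [i for i in maxima if i > n_notch]
        if dia:
            fs_set.n_dia = int(dia[0])
            fs_set.A_dia = float(cycle.samples[fs_set.n_dia])
        else:
            fs_set.missing.add("diastolic")
    else:
        fs_set.missing.update({"notch", "diastolic"})
    return fs_set


def locate_max_slope(cycle: PulseCycle, landmarks: FiducialSet | None = None) -> tuple[int, float]:
    """First local maximum of the FDPPG; must precede the systolic peak."""
    d1 = derivative_signal(cycle, 1)
    sm = _smooth3(d1)
    maxima = _local_maxima(sm)
    if len(maxima) == 0:
        raise ValueError("no rising slope found in cycle")
    n_ms = int(maxima[0])
    if landmarks is not None and landmarks.n_sys is not None and n_ms >= landmarks.n_sys:
        raise ValueError("max-slope point does not precede the systolic peak")
    return n_ms, float(d1[n_ms])


def locate_sdppg_points(
    cycle: PulseCycle,
    landmarks: FiducialSet,
    e_window_frac: float = 0.10,
) -> FiducialSet:
    """Identify SDPPG points a-f and attach them to ``landmarks``.

    a, b, c, d are the first alternating max/min/max/min of the SDPPG in
    the systolic region ([0, n_notch], or [0, 0.4 M] when the notch is
    missing); e is the largest SDPPG local maximum inside a window of
    +/- ``e_window_frac`` * M around the notch estimate, and f the first
    local minimum after e.  Ties break toward the earliest index.
    """
    d2 = derivative_signal(cycle, 2)
    sm = _smooth3(d2)
    M = cycle.M
    sys_end = landmarks.n_notch if landmarks.n_notch is not None else int(0.4 * M)

    maxima = _local_maxima(sm)
    minima = _local_minima(sm)

    def first(cands: np.ndarray, lo: int, hi: int) -> int | None:
        sel = [int(i) for i in cands if lo < i <= hi]
        return sel[0] if sel else None

    n_a = first(maxima, 0, sys_end)
    if n_a is None:
        landmarks.missing.update({"a", "b", "c", "d"})
        landmarks.missing.add("sdppg-unusable")
        return landmarks
    n_b = first(minima, n_a, sys_end)
    if n_b is None:
        landmarks.missing.update({"b", "c", "d"})
        landmarks.sdppg["a"] = (n_a, float(d2[n_a]))
        landmarks.missing.add("sdppg-unusable")
        return landmarks
    landmarks.sdppg["a"] = (n_a, float(d2[n_a]))
    landmarks.sdppg["b"] = (n_b, float(d2[n_b]))
    n_c = first(maxima, n_b, sys_end)
    if n_c is not None:
        landmarks.sdppg["c"] = (n_c, float(d2[n_c]))
        n_d = first(minima, n_c, sys_end)
        if n_d is not None:
            landmarks.sdppg["d"] = (n_d, float(d2[n_d]))
        else:
            landmarks.missing.add("d")
    else:
        landmarks.missing.update({"c", "d"})

    # e: local max around the systole/diastole boundary
    center = landmarks.n_notch if landmarks.n_notch is not None else int(0.4 * M)
    half = int(e_window_frac * M)
    lo_e = max(center - half, landmarks.sdppg.get("d", (n_b, 0.0))[0])
    hi_e = min(center + half, M - 2)
    cand_e = [int(i) for i in maxima if lo_e < i <= hi_e]
    if cand_e:
        n_e = int(cand_e[int(np.argmax(sm[cand_e]))])
        landmarks.sdppg["e"] = (n_e, float(d2[n_e]))
        n_f = first(minima, n_e, M - 1)
        if n_f is not None:
            landmarks.sdppg["f"] = (n_f, float(d2[n_f]))
        else:
            landmarks.missing.add("f")
    else:
        landmarks.missing.update({"e", "f"})
    return landmarks


def extract_fiducials(cycle: PulseCycle) -> FiducialSet:
    """Run the full landmark chain on one cycle; never raises on absence."""
    fset = locate_ppg_landmarks(cycle)
    try:
        n_ms, a_ms = locate_max_slope(cycle, fset)
        fset.n_ms, fset.A_ms1 = n_ms, a_ms
    except ValueError:
        fset.missing.add("max-slope")
    fset = locate_sdppg_points(cycle, fset)
    fset.n_R = cycle.n_r
    fset.n_T = cycle.n_t
    return fset
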