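"""Rule-based driving-scene classification from 1 Hz speed traces.

Road type is not directly observable from the on-board sensors, so the
speed range serves as its proxy.  Each second is assigned one of five
scenes:

* HIGH    — expressway-like driving: within a 1-min block, speeds above
            70 km/h for more than 30 s; a minute also inherits HIGH from
            the preceding minute (hysteresis) until a termination
            condition is met;
* LOW     — premises driving: 1-min blocks with more than 45 s below
            20 km/h, in runs of at least five consecutive such minutes;
* XLOW    — creeping near intersections: speed in (0, 3) km/h while the
            centered 5-s moving-average speed stays below 8 km/h at every
            second of the surrounding +/-10 s (never at speed 0);
* STOPPED — speed exactly 0;
* MEDIUM  — any other second with speed > 0 (ordinary roads).

Per-second precedence: STOPPED > XLOW > LOW > HIGH > MEDIUM.  Minute-level
HIGH/LOW labels are broadcast to their constituent seconds before
precedence resolution.

The carry-over rule as stated has no end; here it terminates at the first
minute that independently qualifies LOW, or has a majority of
STOPPED/XLOW seconds, or whose maximum speed is below 20 km/h (bounded
hysteresis consistent with the rule's intent).
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd


class Scene(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"
    XLOW = "xlow"
    STOPPED = "stopped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: ordering used to break majority ties toward the faster scene
SPEED_ORDER = [Scene.STOPPED, Scene.XLOW, Scene.LOW, Scene.MEDIUM, Scene.HIGH]

HIGH_SPEED_KMH = 70.0
HIGH_SECONDS = 30          # strictly more than this many seconds qualifies
LOW_SPEED_KMH = 20.0
LOW_SECONDS = 45           # strictly more than this many seconds qualifies
LOW_RUN_MINUTES = 5        # "continuing for over 4 min" -> >= 5 minutes
XLOW_SPEED_KMH = 3.0
XLOW_MA_KMH = 8.0
XLOW_MA_WIDTH = 5          # centered moving-average width, s
XLOW_GUARD = 10            # condition must hold over [t-10, t+10]


def _check_grid(t_s: np.ndarray) -> None:
    if len(t_s) > 1 and not np.all(np.diff(t_s) == 1):
        raise ValueError("telemetry must be contiguous at 1 Hz (fill or split first)")


def _xlow_mask(speed: np.ndarray) -> np.ndarray:
    n = len(speed)
    # centered 5-s moving average, shrinking at the edges
    ma = pd.Series(speed).rolling(XLOW_MA_WIDTH, center=True, min_periods=1).mean().to_numpy()
    cond = ma < XLOW_MA_KMH
    mask = np.zeros(n, bool)
    for t in np.nonzero((speed > 0) & (speed < XLOW_SPEED_KMH))[0]:
        lo = max(0, t - XLOW_GUARD)
        hi = min(n, t + XLOW_GUARD + 1)
        if cond[lo:hi].all():
            mask[t] = True
    return mask


def classify_scenes(t_s: np.ndarray, speed_kmh: np.ndarray) -> np.ndarray:
    """Per-second scene labels for a contiguous 1 Hz speed trace.

    Returns an object array of :class:`Scene`, aligned to ``t_s``.
    """
    t_s = np.asarray(t_s)
    speed = np.asarray(speed_kmh, dtype=float)
    _check_grid(t_s)
    n = len(speed)
    if n == 0:
        return np.array([], dtype=object)

    xlow = _xlow_mask(speed)
    stopped = speed == 0.0

    n_min = int(np.ceil(n / 60))
    slices = [slice(m * 60, min((m + 1) * 60, n)) for m in range(n_min)]

    high_base = np.array([(speed[s] > HIGH_SPEED_KMH).sum() > HIGH_SECONDS
                          for s in slices])
    low_qual = np.array([(speed[s] < LOW_SPEED_KMH).sum() > LOW_SECONDS
                         for s in slices])

    # LOW needs >= LOW_RUN_MINUTES consecutive qualifying minutes
    low_minute = np.zeros(n_min, bool)
    run_start = None
    for m in range(n_min + 1):
        if m < n_min and low_qual[m]:
            if run_start is None:
                run_start = m
        else:
            if run_start is not None and m - run_start >= LOW_RUN_MINUTES:
                low_minute[run_start:m] = True
            run_start = None

    # HIGH with carry-over; termination at LOW-qualifying minutes, majority
    # stopped/xlow minutes, or minutes never reaching 20 km/h
    high_minute = np.zeros(n_min, bool)
    for m, s in enumerate(slices):
        if high_base[m]:
            high_minute[m] = True
            continue
        if m > 0 and high_minute[m - 1]:
            n_sec = s.stop - s.start
            terminate = (low_qual[m]
                         or (stopped[s] | xlow[s]).sum() * 2 > n_sec
                         or speed[s].max() < LOW_SPEED_KMH)
            high_minute[m] = not terminate
    # broadcast minute labels to seconds, then resolve precedence
    labels = np.empty(n, dtype=object)
    for m, s in enumerate(slices):
        for t in range(s.start, s.stop):
            if stopped[t]:
                labels[t] = Scene.STOPPED
            elif xlow[t]:
                labels[t] = Scene.XLOW
            elif low_minute[m]:
                labels[t] = Scene.LOW
            elif high_minute[m]:
                labels[t] = Scene.HIGH
            else:
                labels[t] = Scene.MEDIUM
    return labels


def window_scene(labels: np.ndarray) -> Scene:
    """Majority scene of a window of per-second labels; ties break toward
    the faster scene."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty window")
    counts = {s: int((labels == s).sum()) for s in Scene}
    best = max(counts.values())
    # iterate fastest-first so ties resolve toward the faster scene
    for s in reversed(SPEED_ORDER):
        if counts[s] == best:
            return s
    raise AssertionError("unreachable")


def scenes_to_csv(t_s: np.ndarray, labels: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"t_s": t_s, "label": [str(l) for l in labels]}).to_csv(
        path, index=False)
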