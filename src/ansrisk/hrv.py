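"""Windowed autonomic-function indices from beat-to-beat R-R intervals.

The pipeline implemented here turns a tachogram (the series of R-R
intervals, RRI, in ms) into per-window autonomic nerve function (ANF)
indices:

* frequency domain — the tachogram is interpolated to an even 4 Hz grid,
  linearly detrended, fitted with a Burg (maximum-entropy) autoregressive
  model, and the one-sided power spectral density integrated over the LF
  (0.04-0.15 Hz, sympathetic-dominant) and HF (0.15-0.40 Hz,
  parasympathetic) bands;
* age-referenced deviation scores — LF and HF are normalized by the mean
  RRI and standardized against an age-keyed normative table so that the
  reference population has mean 50 and SD 10;
* time domain — AVGHR, SDNN, NN50 and RMSSD on unflagged beats.

Windows in which flagged or abnormal beats exceed 10% of all beats, or
whose average heart rate is physiologically implausible, are excluded
rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import detrend

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: resampling rate for the evenly-gridded tachogram, Hz
RESAMPLE_HZ = 4.0

#: default Burg autoregressive model order for 120-s windows
DEFAULT_AR_ORDER = 16

#: quality-gate defaults: max fraction of bad beats, plausible AVGHR band,
#: plausible RRI range (ms), max relative jump between successive beats
MAX_BAD_FRACTION = 0.10
AVGHR_BAND = (30.0, 150.0)
RRI_RANGE = (300.0, 2000.0)
MAX_RELATIVE_JUMP = 0.20


class QualityError(ValueError):
    pass


@dataclass
class RRISeries:
    """A tachogram: beat timestamps (ms), R-R intervals (ms), artifact flags.

    ``t_ms[i]`` is the time of beat *i*; ``rri_ms[i]`` the interval ending
    at that beat.  ``flag[i]`` marks beats known or suspected to be
    misdetections (merged/split beats, ectopy).
    """

    t_ms: np.ndarray
    rri_ms: np.ndarray
    flag: np.ndarray

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.rri_ms = np.asarray(self.rri_ms, dtype=float)
        self.flag = np.asarray(self.flag, dtype=bool)
        if not (len(self.t_ms) == len(self.rri_ms) == len(self.flag)):
            raise ValueError("t_ms, rri_ms and flag must have equal length")
        if len(self.t_ms) > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("beat timestamps must be strictly increasing")
        if np.any(self.rri_ms <= 0):
            raise ValueError("all R-R intervals must be positive")

    def __len__(self) -> int:
        return len(self.rri_ms)

    @classmethod
    def from_rri(cls, rri_ms: Sequence[float], t0_ms: float = 0.0,
                 flag: Sequence[bool] | None = None) -> "RRISeries":
        """Build a series from intervals alone; timestamps are cumulative."""
        rri = np.asarray(rri_ms, dtype=float)
        t = t0_ms + np.cumsum(rri)
        f = np.zeros(len(rri), bool) if flag is None else np.asarray(flag, bool)
        return cls(t, rri, f)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RRISeries":
        df = pd.read_csv(path)
        flag = df["flag"].to_numpy(bool) if "flag" in df else np.zeros(len(df), bool)
        return cls(df["t_ms"].to_numpy(float), df["rri_ms"].to_numpy(float), flag)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "t_ms": self.t_ms,
            "rri_ms": self.rri_ms,
            "flag": self.flag.astype(int),
        }).to_csv(path, index=False)

    def slice_time(self, start_ms: float, stop_ms: float) -> "RRISeries":
        """Beats with timestamps in the half-open interval [start, stop)."""
        m = (self.t_ms >= start_ms) & (self.t_ms < stop_ms)
        return RRISeries(self.t_ms[m], self.rri_ms[m], self.flag[m])


@dataclass
class NormativeTable:
    """Age-keyed normative means/SDs for RRI-normalized LF and HF.

    Rows give, per integer age, the mean and SD of log(LF/RRI_average)
    (columns ``mu_lf``, ``sigma_lf``) and of HF/RRI_average (``mu_hf``,
    ``sigma_hf``) in a reference population.  Deviation scores computed
    against this table are *relative to the supplied table*: the default
    table shipped with the package is generated from a simulated reference
    population and carries no population-level meaning.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"age", "mu_lf", "sigma_lf", "mu_hf", "sigma_hf"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"normative table missing columns: {sorted(missing)}")
        if (self.table["sigma_lf"] <= 0).any() or (self.table["sigma_hf"] <= 0).any():
            raise ValueError("normative sigmas must be strictly positive")
        ages = np.sort(self.table["age"].to_numpy(int))
        if len(ages) > 1 and np.any(np.diff(ages) != 1):
            raise ValueError("normative table must cover a contiguous age range")
        self.table = self.table.set_index(self.table["age"].astype(int))

    def row(self, age: int) -> pd.Series:
        age = int(age)
        if age not in self.table.index:
            raise KeyError(f"age {age} outside normative table coverage "
                           f"[{self.table.index.min()}, {self.table.index.max()}]")
        return self.table.loc[age]

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormativeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.reset_index(drop=True).to_csv(path, index=False)

    @classmethod
    def synthetic_default(cls, age_min: int = 20, age_max: int = 70,
                          n_ref: int = 400, seed: int = 20210) -> "NormativeTable":
        """Normative table from a simulated reference population (synthetic).

        For each integer age a cohort of ``n_ref`` reference subjects is
        drawn with LF and HF powers that decline gently with age (spectral
        HRV power falls with age), and the per-age mean/SD of the
        normalized quantities are tabulated.  Deterministic for a fixed
        seed; this is a stand-in for unpublished normative data.
        """
        rng = np.random.default_rng(seed)
        rows = []
        for age in range(age_min, age_max + 1):
            # geometric decline of band power with age, ~1.5%/year
            decline = 0.985 ** (age - 40)
            rri_avg = rng.normal(850.0, 80.0, n_ref)
            lf = rng.lognormal(np.log(350.0 * decline), 0.55, n_ref)
            hf = rng.lognormal(np.log(250.0 * decline), 0.60, n_ref)
            log_lf_norm = np.log(lf / rri_avg)
            hf_norm = hf / rri_avg
            rows.append({
                "age": age,
                "mu_lf": log_lf_norm.mean(),
                "sigma_lf": log_lf_norm.std(ddof=1),
                "mu_hf": hf_norm.mean(),
                "sigma_hf": hf_norm.std(ddof=1),
            })
        return cls(pd.DataFrame(rows))


@dataclass
class PSD:
    """One-sided autoregressive power spectral density of a tachogram."""

    freq: np.ndarray      # Hz, spanning [0, RESAMPLE_HZ/2]
    density: np.ndarray   # ms^2/Hz, >= 0
    ar_order: int

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("PSD density must be non-negative")


@dataclass
class ANFWindow:
    """Per-window autonomic indices; index fields are None when quality fails."""

    start_ms: float
    end_ms: float
    quality_pass: bool
    n_beats: int = 0
    avghr: float | None = None
    rri_average: float | None = None
    lf: float | None = None
    hf: float | None = None
    lf_score: float | None = None
    hf_score: float | None = None
    lfhf_ratio: float | None = None
    sdnn: float | None = None
    nn50: int | None = None
    rmssd: float | None = None


def window_rri(rri: RRISeries, width_s: float = 120.0,
               mode: str = "shift") -> list[RRISeries]:
    """Split a tachogram into analysis windows.

    ``mode='shift'`` produces tumbling half-open windows ``[t, t+width)``
    anchored at the first beat's timestamp; only complete windows (the
    series spans the full width) are returned.  ``mode='rest'`` returns the
    single leading 90-s span, the protocol used for the resting eye-closed
    pre/post measurements.
    """
    if width_s <= 0:
        raise ValueError("window width must be positive")
    if len(rri) == 0:
        return []
    # anchor at the recording origin: the start of the first interval
    t0 = rri.t_ms[0] - rri.rri_ms[0]
    span_ms = rri.t_ms[-1] - t0
    if mode == "rest":
        width_ms = 90_000.0
        if span_ms < width_ms:
            return []
        return [rri.slice_time(t0, t0 + width_ms)]
    if mode != "shift":
        raise ValueError(f"unknown windowing mode {mode!r}")
    width_ms = width_s * 1000.0
    n_win = int(span_ms // width_ms)
    out = []
    for k in range(n_win):
        w = rri.slice_time(t0 + k * width_ms, t0 + (k + 1) * width_ms)
        if len(w):
            out.append(w)
    return out


def abnormal_beats(window: RRISeries,
                   rri_range: tuple[float, float] = RRI_RANGE,
                   max_jump: float = MAX_RELATIVE_JUMP) -> np.ndarray:
    """Boolean mask of beats that are physiologically implausible.

    A beat is abnormal when its RRI lies outside ``rri_range`` or jumps by
    more than ``max_jump`` (relative) from the preceding interval.
    """
    rri = window.rri_ms
    bad = (rri < rri_range[0]) | (rri > rri_range[1])
    if len(rri) > 1:
        jump = np.abs(np.diff(rri)) / rri[:-1]
        bad[1:] |= jump > max_jump
    return bad


def assess_window_quality(window: RRISeries,
                          max_bad_fraction: float = MAX_BAD_FRACTION,
                          avghr_band: tuple[float, float] = AVGHR_BAND,
                          rri_range: tuple[float, float] = RRI_RANGE,
                          max_jump: float = MAX_RELATIVE_JUMP) -> bool:
    """Window quality gate.

    Fails iff the fraction of flagged-or-abnormal beats strictly exceeds
    ``max_bad_fraction`` (a window with exactly the threshold fraction
    passes), or the window average heart rate falls outside ``avghr_band``.
    """
    if len(window) == 0:
        raise QualityError("cannot assess an empty window")
    bad = window.flag | abnormal_beats(window, rri_range, max_jump)
    if bad.sum() / len(window) > max_bad_fraction:
        return False
    avghr = 60_000.0 / window.rri_ms.mean()
    return bool(avghr_band[0] <= avghr <= avghr_band[1])


def _burg(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method: AR coefficients ``a`` (A(z)=1+sum a_k z^-k) and the
    driving-noise variance, via the lattice recursion on forward/backward
    prediction errors."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if order >= n:
        raise ValueError("AR order must be below the series length")
    f = x.copy()
    b = x.copy()
    a = np.zeros(order)
    e = float(x @ x) / n
    for m in range(order):
        fm = f[m + 1:n]
        bm = b[m:n - 1]
        den = float(fm @ fm + bm @ bm)
        if den <= 0.0:
            # perfectly predictable remainder (e.g. constant input)
            return a[:m], 0.0
        k = -2.0 * float(fm @ bm) / den
        e *= (1.0 - k * k)
        a[:m] = a[:m] + k * a[:m][::-1]
        a[m] = k
        f_new = fm + k * bm
        b_new = bm + k * fm
        f[m + 1:n] = f_new
        b[m + 1:n] = b_new
    return a, e


def _ar_psd(a: np.ndarray, noise_var: float, fs: float,
            n_freq: int = 1025) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of an AR model on [0, fs/2]; integrates to the process
    variance."""
    freq = np.linspace(0.0, fs / 2.0, n_freq)
    if len(a) == 0 or noise_var <= 0.0:
        return freq, np.full(n_freq, 2.0 * max(noise_var, 0.0) / fs)
    k = np.arange(1, len(a) + 1)
    # A(f) = 1 + sum a_k exp(-2 pi i f k / fs)
    phases = np.exp(-2j * np.pi * np.outer(freq, k) / fs)
    denom = np.abs(1.0 + phases @ a) ** 2
    # keep near-unit-circle poles (noise-free tones) finite
    density = 2.0 * noise_var / fs / np.maximum(denom, 1e-30)
    return freq, density


def mem_psd(window: RRISeries, order: int = DEFAULT_AR_ORDER,
            order_policy: str = "fixed", max_order: int = 30,
            fs: float = RESAMPLE_HZ) -> PSD:
    """Maximum-entropy (Burg AR) power spectral density of a tachogram window.

    The unevenly sampled tachogram is cubic-spline interpolated onto an
    even ``fs`` grid, linearly detrended, and fitted with a Burg AR model
    (fixed order by default; ``order_policy='aic'`` selects the order up to
    ``max_order`` by AIC).  The returned one-sided density integrates over
    [0, fs/2] to the detrended series variance.
    """
    if len(window) < 60:
        raise ValueError("need at least 60 beats for spectral estimation")
    t_s = window.t_ms / 1000.0
    grid = np.arange(t_s[0], t_s[-1], 1.0 / fs)
    tach = CubicSpline(t_s, window.rri_ms)(grid)
    tach = detrend(tach, type="linear")
    if order_policy == "fixed":
        a, e = _burg(tach, min(order, len(tach) // 2 - 1))
    elif order_policy == "aic":
        n = len(tach)
        best = None
        for p in range(2, min(max_order, n // 2 - 1) + 1):
            a_p, e_p = _burg(tach, p)
            if e_p <= 0:
                a, e = a_p, e_p
                break
            aic = n * np.log(e_p) + 2 * p
            if best is None or aic < best[0]:
                best = (aic, a_p, e_p)
        else:
            _, a, e = best
    else:
        raise ValueError(f"unknown order policy {order_policy!r}")
    freq, density = _ar_psd(a, e, fs)
    return PSD(freq, density, len(a))


def band_power(psd: PSD, f_lo: float, f_hi: float) -> float:
    """Trapezoidal integral of the density over the half-open band [f_lo, f_hi)."""
    if not (0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > psd.freq[-1] + 1e-9:
        raise ValueError("band extends beyond the PSD frequency grid")
    # integrate on a refined grid with the band edges included exactly
    mask = (psd.freq > f_lo) & (psd.freq < f_hi)
    f = np.concatenate([[f_lo], psd.freq[mask], [f_hi]])
    d = np.interp(f, psd.freq, psd.density)
    return float(np.trapezoid(d, f))


def deviation_scores(lf: float, hf: float, rri_average: float, age: int,
                     table: NormativeTable,
                     log_hf: bool = False) -> tuple[float, float]:
    """Age-referenced deviation scores of LF and HF (mean 50, SD 10).

    ``LF_score = 10 * (log(LF/RRI_average) - mu_LF(age)) / sigma_LF(age) + 50``;
    the HF score standardizes the *unlogged* normalized power,
    ``HF_score = 10 * (HF/RRI_average - mu_HF(age)) / sigma_HF(age) + 50``
    (set ``log_hf=True`` for a logged variant, in which case the table's HF
    moments must be on the log scale).
    """
    if rri_average <= 0:
        raise ValueError("RRI_average must be positive")
    if lf <= 0:
        raise ValueError("LF must be positive for the log transform")
    if hf < 0:
        raise ValueError("HF must be non-negative")
    row = table.row(age)
    lf_score = 10.0 * (np.log(lf / rri_average) - row["mu_lf"]) / row["sigma_lf"] + 50.0
    hf_in = np.log(hf / rri_average) if log_hf else hf / rri_average
    hf_score = 10.0 * (hf_in - row["mu_hf"]) / row["sigma_hf"] + 50.0
    return float(lf_score), float(hf_score)


def time_domain_features(window: RRISeries) -> tuple[float, float, int, float]:
    """AVGHR, SDNN, NN50 and RMSSD over the window's unflagged beats.

    AVGHR = 60000 / mean(RRI) in beats/min; SDNN is the sample SD (ddof=1);
    NN50 counts successive absolute differences > 50 ms; RMSSD is the root
    mean square of successive differences.
    """
    rri = window.rri_ms[~window.flag]
    if len(rri) < 3:
        raise ValueError("need at least 3 unflagged beats")
    diffs = np.diff(rri)
    avghr = 60_000.0 / rri.mean()
    sdnn = float(rri.std(ddof=1))
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    return float(avghr), sdnn, nn50, rmssd


def compute_anf_series(rri: RRISeries, age: int, table: NormativeTable,
                       mode: str = "shift", width_s: float = 120.0,
                       ar_order: int = DEFAULT_AR_ORDER) -> list[ANFWindow]:
    """Full per-window ANF pipeline: window -> quality -> PSD -> bands ->
    deviation scores -> time domain.  Failed-quality windows are carried
    through with ``quality_pass=False`` and no indices."""
    out: list[ANFWindow] = []
    for w in window_rri(rri, width_s, mode):
        start, end = float(w.t_ms[0]), float(w.t_ms[-1])
        if len(w) < 60 or not assess_window_quality(w):
            out.append(ANFWindow(start, end, quality_pass=False, n_beats=len(w)))
            continue
        try:
            psd = mem_psd(w, order=ar_order)
            lf = band_power(psd, *LF_BAND)
            hf = band_power(psd, *HF_BAND)
            rri_avg = float(w.rri_ms[~w.flag].mean())
            avghr, sdnn, nn50, rmssd = time_domain_features(w)
            lf_s, hf_s = deviation_scores(max(lf, 1e-12), hf, rri_avg, age, table)
            lfhf = lf / hf if hf > 0 else np.nan
        except (ValueError, KeyError):
            out.append(ANFWindow(start, end, quality_pass=False, n_beats=len(w)))
            continue
        out.append(ANFWindow(start, end, True, len(w), avghr, rri_avg, lf, hf,
                             lf_s, hf_s, float(lfhf), sdnn, nn50, rmssd))
    return out


def anf_windows_to_frame(windows: Iterable[ANFWindow]) -> pd.DataFrame:
    """Tabulate ANF windows, one row per window (CSV-ready)."""
    return pd.DataFrame([vars(w) for w in windows])
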