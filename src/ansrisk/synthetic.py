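"""Synthetic driver-shift cohort with planted, recoverable effect sizes.

Fleet telemetry, warning logs and wearable R-R interval recordings from
occupational drivers are proprietary; this module generates a fully
synthetic stand-in cohort in the same formats so that every downstream
stage (HRV features, scene classification, near-miss modeling, quantile
regression, shift comparison) can be exercised and validated end to end.

The generator's world:

* each driver has an age (35-63 y), a baseline heart rate and a stress
  reactivity;
* a shift is 30 min pre-shift rest, a driving/loading mid-shift and
  30 min post-shift rest;
* a latent per-second stress level s(t) in [0, 1] follows a smooth
  mean-reverting drift with occasional event bumps, with a higher
  baseline while driving;
* telemetry is 1 Hz speed (regime means: high ~85, medium ~45, low ~12,
  stopped 0 km/h) with AR(1) noise whose scale grows with stress
  (stressed driving is jerkier) — this is the observable pathway that
  lets a telemetry-only risk model pick up stress-linked hazard;
* near-miss warnings fire per 20-s driving window with probability
  logistic(b0 + b_std*std_speed + b_speed*mean_speed/100 +
  b_stress*mean_stress), so the warning hazard genuinely depends on both
  speed dynamics and the latent stress;
* R-R intervals follow RR(t) = m*(1 + a_LF(s)*sin(2*pi*0.10*t + phi)
  + a_HF(s)*sin(2*pi*0.25*t + psi)) + noise with m = 60000/baseline_hr;
  a_LF increases and a_HF decreases with stress, so stress raises LF/HF
  and lowers NN50/RMSSD;
* beat-detection artifacts (missed beats merged, ectopic splits) are
  injected at configurable rates, conserving elapsed time.

Every stochastic output is a deterministic function of (config, seed),
and each shift carries its ground truth (planted coefficients, phase
boundaries, the stress trace) for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ansrisk.hrv import RRISeries

REGIME_MEANS = {"high": 85.0, "medium": 45.0, "low": 12.0, "stopped": 0.0}


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

@dataclass
class StressParams:
    baseline: float = 0.2
    amplitude: float = 0.08          # stationary SD of the smooth drift
    event_rate: float = 1.0 / 600.0  # bumps per second (~6/h)
    event_height: float = 0.3
    event_tau: float = 60.0          # bump decay time constant, s
    theta: float = 1.0 / 120.0       # drift mean-reversion rate, 1/s
    max_step: float = 0.05           # bound on per-second change

    @property
    def mean(self) -> float:
        """Expected long-run level: baseline + mean event contribution."""
        return self.baseline + self.event_rate * self.event_height * self.event_tau


@dataclass
class RRIParams:
    f_lf: float = 0.10               # Hz, inside the 0.04-0.15 LF band
    f_hf: float = 0.25               # Hz, inside the 0.15-0.40 HF band
    a_lf0: float = 0.030             # LF modulation amplitude at zero stress
    k_lf: float = 1.5                # relative LF amplitude gain per unit stress
    a_hf0: float = 0.055             # HF modulation amplitude at zero stress
    k_hf: float = 0.8                # relative HF amplitude loss per unit stress
    noise_ms: float = 8.0            # white beat-to-beat noise, ms

    def a_lf(self, s: float) -> float:
        return self.a_lf0 * (1.0 + self.k_lf * s)

    def a_hf(self, s: float) -> float:
        return self.a_hf0 * (1.0 - self.k_hf * s)


@dataclass
class HazardParams:
    """Logistic warning hazard per 20-s driving window."""
    intercept: float = -11.0
    b_std_speed: float = 1.2         # per km/h of within-window speed SD
    b_mean_speed: float = 2.0        # per 100 km/h of mean speed
    b_stress: float = 2.5            # per unit latent stress
    min_mean_speed: float = 20.0     # warnings cannot sound at low speeds


@dataclass
class CohortConfig:
    pre_min: float = 30.0
    mid_min: float = 360.0
    post_min: float = 30.0
    #: mid-shift is tiled with segments drawn from this mix
    #: (regime, duration_s, weight)
    scene_mix: tuple = (("high", 600, 0.30), ("medium", 600, 0.45),
                        ("low", 300, 0.15), ("stopped", 120, 0.10))
    speed_noise: float = 2.0         # base AR(1) innovation SD, km/h
    stress_jitter_gain: float = 1.5  # speed-noise multiplier slope in stress
    mid_stress_base: float = 0.35    # driving-phase stress baseline (x reactivity)
    rest_stress_base: float = 0.12
    stress: StressParams = field(default_factory=StressParams)
    rri: RRIParams = field(default_factory=RRIParams)
    hazard: HazardParams = field(default_factory=HazardParams)
    miss_rate: float = 0.02
    ectopic_rate: float = 0.01

    def __post_init__(self):
        if min(self.pre_min, self.mid_min, self.post_min) <= 0:
            raise ConfigError("phase durations must be positive")
        for regime, dur, w in self.scene_mix:
            if regime not in REGIME_MEANS:
                raise ConfigError(f"unknown regime {regime!r}")
            if dur <= 0 or w < 0:
                raise ConfigError("segment durations must be positive, weights >= 0")


@dataclass
class DriverProfile:
    driver_id: str
    age: int
    baseline_hr: float
    stress_reactivity: float

    def __post_init__(self):
        if not 20 <= self.age <= 70:
            raise ConfigError("age outside [20, 70]")
        if not 40 <= self.baseline_hr <= 100:
            raise ConfigError("baseline heart rate outside [40, 100]")
        if self.stress_reactivity < 0:
            raise ConfigError("stress reactivity must be >= 0")


@dataclass
class ShiftData:
    profile: DriverProfile
    telemetry: pd.DataFrame          # t_s, speed_kmh, acc_x_ms2, acc_y_ms2
    warnings: pd.DataFrame           # t_s, source, validated
    rri: RRISeries
    stress: np.ndarray               # per-second latent stress, [0, 1]
    phases: dict                     # phase -> (start_s, end_s)
    ground_truth: dict


# ---------------------------------------------------------------------------
# component generators

def generate_stress_trace(duration_s: int, params: StressParams,
                          seed: int) -> np.ndarray:
    """Latent per-second stress in [0, 1]: mean-reverting smooth drift
    around the baseline plus exponentially decaying event bumps, with the
    per-second change bounded by ``params.max_step``."""
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(duration_s)
    sigma = params.amplitude * np.sqrt(2.0 * params.theta)
    drift = np.zeros(n)
    for t in range(1, n):
        step = (-params.theta * drift[t - 1]
                + sigma * rng.standard_normal())
        drift[t] = drift[t - 1] + np.clip(step, -params.max_step, params.max_step)
    bumps = np.zeros(n)
    events = np.nonzero(rng.random(n) < params.event_rate)[0]
    decay = np.exp(-np.arange(n) / params.event_tau)
    for t0 in events:
        tail = n - t0
        bumps[t0:] += params.event_height * decay[:tail]
    return np.clip(params.baseline + drift + bumps, 0.0, 1.0)


def generate_telemetry(scenario_spec, seed: int,
                       noise_multiplier: np.ndarray | None = None,
                       ar_coeff: float = 0.85) -> pd.DataFrame:
    """1 Hz telemetry from a list of segments.

    ``scenario_spec`` is a list of dicts with keys ``regime`` (high /
    medium / low / stopped), ``duration_s`` and optionally ``mean``
    (km/h) and ``noise`` (innovation SD, km/h).  Speeds follow an AR(1)
    around the regime mean, clipped at zero; stopped segments are exactly
    zero.  Longitudinal acceleration is the per-second speed difference
    converted to m/s^2 plus noise; lateral acceleration is zero-mean
    noise.  ``noise_multiplier`` optionally scales the innovation SD per
    second (stress coupling).
    """
    rng = np.random.default_rng(seed)
    speeds = []
    noises = []
    for seg in scenario_spec:
        regime = seg["regime"]
        if regime not in REGIME_MEANS:
            raise ConfigError(f"unknown regime {regime!r}")
        dur = int(seg["duration_s"])
        if dur <= 0:
            raise ConfigError("segment duration must be positive")
        mean = float(seg.get("mean", REGIME_MEANS[regime]))
        noise = float(seg.get("noise", 0.0 if regime == "stopped" else 2.0))
        speeds.append(np.full(dur, mean))
        noises.append(np.full(dur, noise))
    target = np.concatenate(speeds)
    noise_sd = np.concatenate(noises)
    n = len(target)
    if noise_multiplier is not None:
        noise_sd = noise_sd * np.asarray(noise_multiplier[:n], float)
    speed = np.empty(n)
    speed[0] = target[0]
    eps = rng.standard_normal(n)
    for t in range(1, n):
        speed[t] = (target[t] + ar_coeff * (speed[t - 1] - target[t])
                    + noise_sd[t] * eps[t])
    speed = np.where(target == 0.0, 0.0, np.clip(speed, 0.0, None))
    acc_x = np.zeros(n)
    acc_x[1:] = np.diff(speed) / 3.6
    acc_x += 0.05 * noise_sd * rng.standard_normal(n)
    acc_y = 0.15 * noise_sd * rng.standard_normal(n)
    return pd.DataFrame({
        "t_s": np.arange(n),
        "speed_kmh": speed,
        "acc_x_ms2": acc_x,
        "acc_y_ms2": acc_y,
    })


def generate_rri(profile: DriverProfile, stress: np.ndarray,
                 duration_s: float, params: RRIParams, seed: int,
                 t0_ms: float = 0.0) -> RRISeries:
    """Beat series with stress-modulated LF/HF sinusoidal amplitudes.

    ``RR(t) = m * (1 + a_LF(s(t)) sin(2 pi f_LF t + phi)
                    + a_HF(s(t)) sin(2 pi f_HF t + psi)) + noise``
    with m = 60000/baseline_hr ms.  Raises if parameters would yield a
    non-positive interval.
    """
    if duration_s < 120:
        raise ConfigError("RRI generation needs at least 120 s")
    max_amp = (params.a_lf0 * (1 + max(params.k_lf, 0))
               + params.a_hf0)
    if max_amp >= 0.9:
        raise ConfigError("modulation amplitudes would allow non-positive RRI")
    rng = np.random.default_rng(seed)
    m = 60_000.0 / profile.baseline_hr
    phi, psi = rng.uniform(0, 2 * np.pi, 2)
    t = 0.0
    rri, t_ms = [], []
    n_s = len(stress)
    while t < duration_s:
        s = float(stress[min(int(t), n_s - 1)]) if n_s else 0.0
        rr = m * (1.0
                  + params.a_lf(s) * np.sin(2 * np.pi * params.f_lf * t + phi)
                  + params.a_hf(s) * np.sin(2 * np.pi * params.f_hf * t + psi))
        rr += params.noise_ms * rng.standard_normal()
        if rr <= 0:
            raise ConfigError("generated a non-positive R-R interval")
        t += rr / 1000.0
        rri.append(rr)
        t_ms.append(t0_ms + t * 1000.0)
    return RRISeries(np.array(t_ms), np.array(rri), np.zeros(len(rri), bool))


def generate_warnings(telemetry: pd.DataFrame, stress: np.ndarray,
                      hazard: HazardParams, seed: int) -> pd.DataFrame:
    """Near-miss warnings per 20-s driving window under a logistic hazard.

    A window can fire only when its mean speed is at least
    ``hazard.min_mean_speed`` (forward-collision warnings do not sound at
    low speed); a fired warning gets a uniform timestamp among the
    window's moving seconds, so no warning ever occurs at speed 0.
    """
    rng = np.random.default_rng(seed)
    speed = telemetry["speed_kmh"].to_numpy(float)
    t_s = telemetry["t_s"].to_numpy()
    n_win = len(speed) // 20
    rows = []
    for k in range(n_win):
        sl = slice(k * 20, (k + 1) * 20)
        sp = speed[sl]
        if sp.mean() < hazard.min_mean_speed or not np.any(sp > 0):
            continue
        ms = float(np.mean(stress[sl])) if len(stress) else 0.0
        eta = (hazard.intercept
               + hazard.b_std_speed * (np.std(sp, ddof=1) if len(sp) > 1 else 0.0)
               + hazard.b_mean_speed * sp.mean() / 100.0
               + hazard.b_stress * ms)
        if rng.random() < expit(eta):
            moving = np.nonzero(sp > 0)[0]
            ts = float(t_s[sl][rng.choice(moving)])
            source = "inter_vehicle" if rng.random() < 0.7 else "rear_end"
            rows.append({"t_s": ts, "source": source, "validated": True})
    return pd.DataFrame(rows, columns=["t_s", "source", "validated"])


def inject_artifacts(rri: RRISeries, miss_rate: float, ectopic_rate: float,
                     seed: int) -> RRISeries:
    """Beat-detection artifacts: missed beats merge two adjacent intervals
    into their sum; ectopic beats split one interval into a 40/60 pair.
    Injected beats are flagged and total elapsed time is conserved."""
    if not (0 <= miss_rate < 1 and 0 <= ectopic_rate < 1):
        raise ConfigError("artifact rates must be in [0, 1)")
    if miss_rate + ectopic_rate >= 1:
        raise ConfigError("artifact rates sum to >= 1")
    if miss_rate == 0 and ectopic_rate == 0:
        return rri
    rng = np.random.default_rng(seed)
    n = len(rri)
    u = rng.random(n)
    t0 = rri.t_ms[0] - rri.rri_ms[0]
    new_rri, new_flag = [], []
    i = 0
    while i < n:
        if u[i] < miss_rate and i + 1 < n:
            new_rri.append(rri.rri_ms[i] + rri.rri_ms[i + 1])
            new_flag.append(True)
            i += 2
        elif u[i] < miss_rate + ectopic_rate:
            split = rri.rri_ms[i]
            new_rri.extend([0.4 * split, 0.6 * split])
            new_flag.extend([True, True])
            i += 1
        else:
            new_rri.append(rri.rri_ms[i])
            new_flag.append(bool(rri.flag[i]))
            i += 1
    return RRISeries.from_rri(np.array(new_rri), t0_ms=t0,
                              flag=np.array(new_flag, bool))


# ---------------------------------------------------------------------------
# whole-shift / cohort assembly

def _mid_scenario(mid_s: int, mix, rng) -> list[dict]:
    """Tile the mid-shift with segments drawn from the configured scene mix."""
    regimes = [m[0] for m in mix]
    durs = [m[1] for m in mix]
    weights = np.array([m[2] for m in mix], float)
    weights = weights / weights.sum()
    spec, total = [], 0
    while total < mid_s:
        i = rng.choice(len(regimes), p=weights)
        dur = min(durs[i], mid_s - total)
        spec.append({"regime": regimes[i], "duration_s": dur})
        total += dur
    return spec


def generate_shift(profile: DriverProfile, config: CohortConfig,
                   seed: int) -> ShiftData:
    """One driver-shift: telemetry, warnings, RRI with artifacts, latent
    stress, phase boundaries and the planted ground truth."""
    rng = np.random.default_rng(seed)
    pre_s = int(config.pre_min * 60)
    mid_s = int(config.mid_min * 60)
    post_s = int(config.post_min * 60)
    total_s = pre_s + mid_s + post_s
    phases = {"pre": (0, pre_s), "mid": (pre_s, pre_s + mid_s),
              "post": (pre_s + mid_s, total_s)}

    # latent stress: rest baseline outside driving, elevated while driving
    sp = config.stress
    react = min(profile.stress_reactivity, 2.0)
    drift = generate_stress_trace(
        total_s,
        StressParams(baseline=0.0, amplitude=sp.amplitude,
                     event_rate=sp.event_rate, event_height=sp.event_height,
                     event_tau=sp.event_tau, theta=sp.theta,
                     max_step=sp.max_step),
        seed=int(rng.integers(2 ** 31)))
    base = np.full(total_s, config.rest_stress_base)
    base[pre_s:pre_s + mid_s] = config.mid_stress_base * react
    stress = np.clip(base + drift, 0.0, 1.0)

    # telemetry: rest phases are parked (stopped), mid is the scene mix
    scenario = ([{"regime": "stopped", "duration_s": pre_s}]
                + _mid_scenario(mid_s, config.scene_mix, rng)
                + [{"regime": "stopped", "duration_s": post_s}])
    for seg in scenario:
        if seg["regime"] != "stopped":
            seg["noise"] = config.speed_noise
    noise_mult = 1.0 + config.stress_jitter_gain * stress
    telemetry = generate_telemetry(scenario, seed=int(rng.integers(2 ** 31)),
                                   noise_multiplier=noise_mult)

    warnings = generate_warnings(telemetry, stress, config.hazard,
                                 seed=int(rng.integers(2 ** 31)))

    rri = generate_rri(profile, stress, total_s, config.rri,
                       seed=int(rng.integers(2 ** 31)))
    rri = inject_artifacts(rri, config.miss_rate, config.ectopic_rate,
                           seed=int(rng.integers(2 ** 31)))

    gt = {
        "seed": seed,
        "phases": phases,
        "hazard": asdict(config.hazard),
        "rri_params": asdict(config.rri),
        "stress_mean": float(stress.mean()),
        "driving_start_s": pre_s,
    }
    return ShiftData(profile, telemetry, warnings, rri, stress, phases, gt)


def generate_cohort(n_drivers: int, config: CohortConfig | None = None,
                    seed: int = 0) -> list[ShiftData]:
    """A cohort of synthetic driver-shifts; deterministic in (config, seed)."""
    if n_drivers < 1:
        raise ConfigError("need at least one driver")
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    shifts = []
    for d in range(n_drivers):
        profile = DriverProfile(
            driver_id=f"D{d:03d}",
            age=int(rng.integers(35, 64)),
            baseline_hr=float(np.clip(rng.normal(68.0, 7.0), 50.0, 90.0)),
            stress_reactivity=float(np.clip(rng.lognormal(0.0, 0.25), 0.3, 2.0)),
        )
        shifts.append(generate_shift(profile, config,
                                     seed=int(rng.integers(2 ** 31))))
    return shifts


# ---------------------------------------------------------------------------
# record-level generator for the regression stages

RECORD_EFFECTS = {
    "const": -10.0,
    "lfhf_ratio": 0.30,
    "nn50": -0.05,
    "avghr": -0.02,
    "age": 0.03,
    "mean_speed": 0.10,
}


def simulate_analysis_records(n: int, seed: int,
                              effects: dict | None = None,
                              noise_sd: float = 1.5,
                              bounds=(0.0, 100.0)) -> pd.DataFrame:
    """Analysis-ready 2-min records with planted regression effects.

    Covariates mimic the field ranges (LF/HF around 1-3, NN50 counts,
    deviation scores near 50, speeds 20-100 km/h) with realistic
    correlation inside the sympathetic block (LF_score, LF/HF, SDNN) and
    the parasympathetic block (HF_score, NN50, RMSSD).  The bounded risk
    response is generated from the logistic quantile-regression model
    itself: z = X beta + noise, y = inverse logistic transform of z, so
    every non-intercept coefficient is constant across quantiles and
    recoverable.  The planted coefficients are returned in
    ``frame.attrs['effects']``.
    """
    rng = np.random.default_rng(seed)
    effects = dict(RECORD_EFFECTS if effects is None else effects)

    sns = rng.standard_normal(n)      # latent sympathetic activation
    pns = rng.standard_normal(n)      # latent parasympathetic activity
    df = pd.DataFrame({
        "lfhf_ratio": np.exp(0.45 * sns + 0.15 * rng.standard_normal(n)) * 1.8,
        "lf_score": 50 + 10 * (0.8 * sns + 0.6 * rng.standard_normal(n)),
        "sdnn": np.clip(50 + 15 * (0.7 * sns + 0.7 * rng.standard_normal(n)),
                        5, None),
        "nn50": rng.poisson(15.0 * np.exp(0.45 * pns)),
        "hf_score": 50 + 10 * (0.8 * pns + 0.6 * rng.standard_normal(n)),
        "rmssd": np.clip(30 + 10 * (0.7 * pns + 0.7 * rng.standard_normal(n)),
                         2, None),
        "avghr": rng.normal(75.0, 8.0, n),
        "age": rng.integers(35, 64, n).astype(float),
        "mean_speed": np.clip(rng.normal(60.0, 15.0, n), 20.0, 100.0),
    })
    z = np.full(n, effects.get("const", 0.0))
    for name, beta in effects.items():
        if name != "const":
            z = z + beta * df[name].to_numpy(float)
    z = z + noise_sd * rng.standard_normal(n)
    e = np.exp(np.clip(z, -500, 500))
    df["risk_pct"] = (bounds[1] * e + bounds[0]) / (1.0 + e)
    df["driver_id"] = [f"D{i % 20:03d}" for i in range(n)]
    df.attrs["effects"] = effects
    return df


# ---------------------------------------------------------------------------
# on-disk format

def write_cohort(shifts: list[ShiftData], out_dir: str | Path) -> None:
    """Write the cohort as per-driver CSVs plus a manifest and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    gt = {}
    for s in shifts:
        did = s.profile.driver_id
        s.rri.to_csv(out / f"rri_{did}.csv")
        s.telemetry.to_csv(out / f"telemetry_{did}.csv", index=False)
        s.warnings.to_csv(out / f"warnings_{did}.csv", index=False)
        manifest.append({"driver_id": did, "age": s.profile.age,
                         "baseline_hr": s.profile.baseline_hr,
                         "stress_reactivity": s.profile.stress_reactivity})
        gt[did] = s.ground_truth
    pd.DataFrame(manifest).to_csv(out / "cohort.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, default=str)
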