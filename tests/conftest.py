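import numpy as np
import pandas as pd
import pytest

from ansrisk import hrv, synthetic


@pytest.fixture(scope="session")
def normative_table() -> hrv.NormativeTable:
    return hrv.NormativeTable.synthetic_default()


@pytest.fixture(scope="session")
def toy_normative() -> hrv.NormativeTable:
    """Single-row table with round moments for hand-checkable scores."""
    return hrv.NormativeTable(pd.DataFrame({
        "age": [40], "mu_lf": [3.0], "sigma_lf": [0.5],
        "mu_hf": [1.0], "sigma_hf": [0.2],
    }))


@pytest.fixture(scope="session")
def driver() -> synthetic.DriverProfile:
    return synthetic.DriverProfile("D000", age=50, baseline_hr=70.0,
                                   stress_reactivity=1.0)


@pytest.fixture(scope="session")
def small_cohort() -> list[synthetic.ShiftData]:
    """Eight shifts with a 2-h driving phase; shared across pipeline tests."""
    cfg = synthetic.CohortConfig(mid_min=120.0)
    return synthetic.generate_cohort(8, cfg, seed=3)


@pytest.fixture(scope="session")
def labeled_windows(small_cohort) -> pd.DataFrame:
    from ansrisk import risk

    frames = []
    for s in small_cohort:
        w = risk.build_features(s.telemetry["t_s"].to_numpy(),
                                s.telemetry["speed_kmh"].to_numpy(),
                                s.telemetry["acc_x_ms2"].to_numpy(),
                                s.telemetry["acc_y_ms2"].to_numpy())
        w = risk.label_windows(w, s.warnings["t_s"].to_numpy())
        w["driver_id"] = s.profile.driver_id
        frames.append(w)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def fast_grid() -> dict:
    """Single-point hyperparameter grid to keep CV affordable in tests."""
    return {"n_estimators": [100], "max_depth": [3], "learning_rate": [0.1]}


def clean_rri(n_beats: int = 150, rri_ms: float = 800.0,
              seed: int | None = None) -> hrv.RRISeries:
    if seed is None:
        return hrv.RRISeries.from_rri(np.full(n_beats, rri_ms))
    rng = np.random.default_rng(seed)
    vals = rri_ms + rng.uniform(-40.0, 40.0, n_beats)
    return hrv.RRISeries.from_rri(vals)
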