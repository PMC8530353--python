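"""Construction of the 2-min analysis dataset joining risk and ANF.

The 20-s risk index is resampled to 2-min resolution by averaging (blocks
with any missing 20-s value are dropped), then joined with the 2-min ANF
windows on a shared shift-anchored grid.  A record survives only when

* the driver drove continuously (speed > 0 at every second of the block),
* the 2-min mean speed is at least 20 km/h (the risk index is only
  validated in medium/high-speed driving),
* the ANF window passed the quality gate, and
* the risk block exists.

Risk is expressed in percent so the regression response is bounded in
[0, 100].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ansrisk.hrv import ANFWindow

BLOCK_S = 120
SUB_PER_BLOCK = 6          # six 20-s values per 2-min block
MIN_MEAN_SPEED = 20.0


def resample_risk(risk_20s: pd.DataFrame) -> pd.DataFrame:
    """Average the 20-s risk index into 2-min blocks.

    ``risk_20s`` needs columns ``t_start`` (s, on the 20-s grid) and
    ``risk``.  A block is emitted only when all six of its 20-s values are
    present and non-missing.
    """
    t = risk_20s["t_start"].to_numpy(float)
    r = risk_20s["risk"].to_numpy(float)
    block = np.floor(t / BLOCK_S).astype(int)
    rows = []
    for b in np.unique(block):
        m = block == b
        if m.sum() == SUB_PER_BLOCK and not np.any(np.isnan(r[m])):
            rows.append({"t_start": float(b * BLOCK_S), "risk": float(r[m].mean())})
    return pd.DataFrame(rows, columns=["t_start", "risk"])


def build_analysis_dataset(anf_windows: list[ANFWindow],
                           risk_2min: pd.DataFrame,
                           t_s: np.ndarray, speed_kmh: np.ndarray,
                           driver_id: str, age: int,
                           strict_all_seconds: bool = False,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join quality-passing ANF windows with 2-min risk blocks and filter.

    ``strict_all_seconds=True`` additionally requires every second of the
    block to be at or above 20 km/h (instead of the 2-min mean).  Returns
    ``(records, funnel)`` where ``funnel`` counts records surviving each
    successive filter (concatenated -> continuous driving -> speed).
    """
    t_s = np.asarray(t_s)
    speed = np.asarray(speed_kmh, float)
    t0 = int(t_s[0])

    anf_by_block = {}
    for w in anf_windows:
        b = int(round((w.start_ms / 1000.0) / BLOCK_S))
        anf_by_block[b] = w

    rows, n_concat, n_cont = [], 0, 0
    for _, rk in risk_2min.iterrows():
        b = int(rk["t_start"]) // BLOCK_S
        w = anf_by_block.get(b)
        if w is None or not w.quality_pass:
            continue
        n_concat += 1
        sl = slice(b * BLOCK_S - t0, (b + 1) * BLOCK_S - t0)
        sp = speed[sl]
        if len(sp) < BLOCK_S or np.any(sp <= 0):
            continue
        n_cont += 1
        mean_speed = float(sp.mean())
        speed_ok = (np.all(sp >= MIN_MEAN_SPEED) if strict_all_seconds
                    else mean_speed >= MIN_MEAN_SPEED)
        if not speed_ok:
            continue
        rows.append({
            "driver_id": driver_id,
            "t_start_ms": float(b * BLOCK_S * 1000),
            "risk_pct": float(rk["risk"]) * 100.0,
            "lf_score": w.lf_score, "hf_score": w.hf_score,
            "lfhf_ratio": w.lfhf_ratio,
            "sdnn": w.sdnn, "nn50": w.nn50, "rmssd": w.rmssd,
            "avghr": w.avghr,
            "mean_speed": mean_speed,
            "age": age,
        })
    records = pd.DataFrame(rows)
    funnel = pd.DataFrame({
        "condition": ["concatenated", "continuous_2min_driving", "over_20kmh"],
        "n_records": [n_concat, n_cont, len(records)],
    })
    return records, funnel
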