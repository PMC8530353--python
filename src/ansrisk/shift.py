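"""Shift-phase comparison of autonomic indices (pre / mid / post).

Drivers are measured at rest with eyes closed before and after the shift
(90-s windows) and continuously during it.  The mid-shift representative
value of each index is its mean over the quality-passing 2-min windows in
the first 30 min after driving starts.  Per index, the three phases are
compared all-pairs: when every group passes a Shapiro-Wilk normality test
the parametric Tukey-Kramer procedure is used, otherwise the
nonparametric Steel-Dwass procedure (pairwise rank sums referred to the
studentized-range distribution, with mid-rank tie correction and an exact
enumeration fallback for small samples).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ansrisk.hrv import ANFWindow

#: indices compared across phases (time-domain HRV is unavailable pre/post)
COMPARED_INDICES = ("avghr", "lf_score", "hf_score", "lfhf_ratio")


def representative_mid(anf_windows: list[ANFWindow], driving_start_ms: float,
                       span_min: float = 30.0) -> dict[str, float]:
    """Mean of each ANF index over quality-passing windows starting within
    ``span_min`` minutes of ``driving_start_ms``; the mid-shift
    representative values."""
    span_ms = span_min * 60_000.0
    qual = [w for w in anf_windows
            if w.quality_pass
            and driving_start_ms <= w.start_ms < driving_start_ms + span_ms]
    if not qual:
        raise ValueError("no quality-passing windows in the representative span")
    out = {"n_windows": len(qual)}
    for name in ("avghr", "lf_score", "hf_score", "lfhf_ratio",
                 "sdnn", "nn50", "rmssd"):
        out[name] = float(np.mean([getattr(w, name) for w in qual]))
    return out


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs at least two observations")
    return gs


def tukey_kramer(groups) -> np.ndarray:
    """All-pairs Tukey-Kramer p-values (unequal group sizes allowed).

    Returns a symmetric k x k matrix with NaN on the diagonal.
    """
    gs = _as_groups(groups)
    pooled = np.concatenate([g - g.mean() for g in gs])
    if np.allclose(pooled, 0.0):
        raise ValueError("zero pooled variance")
    res = stats.tukey_hsd(*gs)
    p = np.array(res.pvalue, dtype=float)
    np.fill_diagonal(p, np.nan)
    return p


def _sr_sf(q: float, k: int) -> float:
    """Survival function of the studentized range with infinite df."""
    return float(stats.studentized_range.sf(q, k, np.inf))


def _pair_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Rank-sum statistic for one pair: (W, E[W], Var[W]) with mid-ranks
    and tie correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    r = stats.rankdata(np.concatenate([x, y]))
    w = float(r[:n1].sum())
    e = n1 * (n + 1) / 2.0
    v = n1 * n2 / (n * (n - 1.0)) * (float(np.sum(r ** 2)) - n * (n + 1) ** 2 / 4.0)
    return w, e, v


def _exact_pair_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value of the pairwise rank sum,
    enumerating all C(n1+n2, n1) group assignments."""
    from itertools import combinations as icomb

    n1 = len(x)
    r = stats.rankdata(np.concatenate([x, y]))
    n = len(r)
    e = n1 * (n + 1) / 2.0
    obs = abs(float(r[:n1].sum()) - e)
    hits = total = 0
    for idx in icomb(range(n), n1):
        total += 1
        if abs(float(r[list(idx)].sum()) - e) >= obs - 1e-9:
            hits += 1
    return hits / total


def steel_dwass(groups, exact_max_n: int = 6) -> np.ndarray:
    """All-pairs Steel-Dwass p-values.

    Each pair is jointly mid-ranked; the standardized rank sum t is
    referred to the studentized-range distribution with infinite df via
    q = sqrt(2)*|t|, controlling the family-wise error over the k groups.
    When the smaller group of a pair has at most ``exact_max_n``
    observations the pairwise p-value is computed by exhaustive
    enumeration instead of the normal approximation (and then mapped
    through the same studentized-range adjustment, which is the identity
    at k = 2).
    """
    gs = _as_groups(groups)
    k = len(gs)
    p = np.full((k, k), np.nan)
    for i, j in combinations(range(k), 2):
        x, y = gs[i], gs[j]
        w, e, v = _pair_stat(x, y)
        if v <= 0:
            raise ValueError("all observations tied in a pair")
        from math import comb
        exact_ok = (min(len(x), len(y)) <= exact_max_n
                    and comb(len(x) + len(y), min(len(x), len(y))) <= 50_000)
        if exact_ok:
            p_pair = _exact_pair_p(x, y)
            # map the exact two-sided p through the SR adjustment
            # (identity when k == 2)
            z = stats.norm.isf(min(p_pair, 1.0) / 2.0)
            pij = _sr_sf(np.sqrt(2.0) * max(z, 0.0), k) if np.isfinite(z) else 1.0
            if k == 2:
                pij = p_pair
        else:
            t = (w - e) / np.sqrt(v)
            pij = _sr_sf(np.sqrt(2.0) * abs(t), k)
        p[i, j] = p[j, i] = pij
    return p


def compare_shifts(pre: pd.DataFrame, mid: pd.DataFrame, post: pd.DataFrame,
                   alpha: float = 0.05,
                   indices=COMPARED_INDICES) -> pd.DataFrame:
    """Per-index all-pairs comparison of the three shift phases.

    ``pre``, ``mid`` and ``post`` hold one row per driver and one column
    per ANF index.  For each index, Shapiro-Wilk is run on every phase; if
    all phases look normal (p >= alpha) Tukey-Kramer is used, otherwise
    Steel-Dwass.  Returns a table with the method and the three pairwise
    p-values (mid-pre, post-pre, post-mid).
    """
    rows = []
    for name in indices:
        groups = [pre[name].dropna().to_numpy(float),
                  mid[name].dropna().to_numpy(float),
                  post[name].dropna().to_numpy(float)]
        normal = all(stats.shapiro(g).pvalue >= alpha for g in groups)
        method = "tukey_kramer" if normal else "steel_dwass"
        p = tukey_kramer(groups) if normal else steel_dwass(groups)
        rows.append({
            "index": name,
            "method": method,
            "p_mid_pre": p[0, 1],
            "p_post_pre": p[0, 2],
            "p_post_mid": p[1, 2],
        })
    return pd.DataFrame(rows)
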