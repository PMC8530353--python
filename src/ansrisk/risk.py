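"""Near-miss risk estimation from 20-s vehicle-behavior windows.

Vehicle telemetry (1 Hz speed and longitudinal/lateral acceleration) is
aggregated into tumbling 20-s windows of 15 features (extrema, means and
SDs of each channel, a fine speed-variation component and mean-speed
differences with the neighboring windows).  A window is labeled a
near-miss (1) when a validated forward-collision warning sounded inside
it.  Per driving scene, a gradient-boosted decision-tree classifier is
grid-searched and evaluated with stratified 5-fold cross-validation
(pooled out-of-fold ROC/AUC); its predicted class-1 probability on new
windows is the continuous rear-end collision risk index in [0, 1].

Only the high-speed and medium-speed scenes are modeled: low and
extremely-low-speed driving produced no rear-end near-misses and the
model reports a missing risk there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from ansrisk.scenes import Scene, classify_scenes, window_scene

WINDOW_S = 20

FEATURE_NAMES = [
    "max_speed", "min_speed", "mean_speed",
    "max_acc_x", "min_acc_x", "mean_acc_x",
    "max_acc_y", "min_acc_y", "mean_acc_y",
    "std_speed", "std_acc_x", "std_acc_y",
    "std_diff_speed", "diff_mspeed_bef", "diff_mspeed_aft",
]

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [3, 5],
    "learning_rate": [0.05, 0.1],
}

TRAINED_SCENES = (Scene.HIGH, Scene.MEDIUM)


def _std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def build_features(t_s: np.ndarray, speed_kmh: np.ndarray,
                   acc_x: np.ndarray, acc_y: np.ndarray,
                   scene_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Tumbling 20-s feature windows from contiguous 1 Hz telemetry.

    Returns one row per complete window with the 15 aggregate features, the
    window's majority scene, and a ``complete`` flag that is False for the
    first/last windows whose neighbor-difference features
    (``diff_mspeed_bef``/``diff_mspeed_aft``) had to be zero-filled.
    ``std_diff_speed`` is the 20-s SD of the residual of speed around its
    centered 10-s moving average.
    """
    t_s = np.asarray(t_s)
    speed = np.asarray(speed_kmh, float)
    if len(t_s) > 1 and not np.all(np.diff(t_s) == 1):
        raise ValueError("telemetry must be contiguous at 1 Hz")
    if len(t_s) < 60:
        raise ValueError("need at least 60 s of telemetry")
    acc_x = np.asarray(acc_x, float)
    acc_y = np.asarray(acc_y, float)
    if scene_labels is None:
        scene_labels = classify_scenes(t_s, speed)

    ma10 = pd.Series(speed).rolling(10, center=True, min_periods=1).mean().to_numpy()
    resid = speed - ma10

    n_win = len(t_s) // WINDOW_S
    mean_speed = np.array([speed[k * WINDOW_S:(k + 1) * WINDOW_S].mean()
                           for k in range(n_win)])
    rows = []
    for k in range(n_win):
        sl = slice(k * WINDOW_S, (k + 1) * WINDOW_S)
        sp, ax, ay = speed[sl], acc_x[sl], acc_y[sl]
        complete = 0 < k < n_win - 1
        row = {
            "t_start": float(t_s[sl.start]),
            "max_speed": sp.max(), "min_speed": sp.min(), "mean_speed": sp.mean(),
            "max_acc_x": ax.max(), "min_acc_x": ax.min(), "mean_acc_x": ax.mean(),
            "max_acc_y": ay.max(), "min_acc_y": ay.min(), "mean_acc_y": ay.mean(),
            "std_speed": _std(sp), "std_acc_x": _std(ax), "std_acc_y": _std(ay),
            "std_diff_speed": _std(resid[sl]),
            "diff_mspeed_bef": mean_speed[k] - mean_speed[k - 1] if k > 0 else 0.0,
            "diff_mspeed_aft": mean_speed[k + 1] - mean_speed[k] if k < n_win - 1 else 0.0,
            "scene": window_scene(scene_labels[sl]),
            "complete": complete,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def label_windows(windows: pd.DataFrame, warning_t_s: np.ndarray) -> pd.DataFrame:
    """Attach the near-miss label: 1 iff a validated warning timestamp falls
    in the half-open window [t_start, t_start + 20)."""
    warning_t_s = np.asarray(warning_t_s, float)
    starts = windows["t_start"].to_numpy()
    labels = np.zeros(len(windows), dtype=int)
    for w in warning_t_s:
        hit = (starts <= w) & (w < starts + WINDOW_S)
        labels[hit] = 1
    out = windows.copy()
    out["near_miss"] = labels
    return out


@dataclass
class SceneModelReport:
    """Cross-validation report for one scene's classifier."""

    scene: Scene
    best_params: dict
    auc: float                      # pooled out-of-fold AUC at best_params
    fold_auc: list[float]
    roc: pd.DataFrame               # pooled out-of-fold fpr/tpr/threshold
    importances: pd.Series          # gain-based, normalized to sum to 1


class NearMissModel:
    """Per-scene gradient-boosted near-miss classifiers.

    Statsmodels-style usage: construct from a labeled window table, call
    :meth:`fit`, then :meth:`predict_risk` on new windows.  ``fit`` grid
    searches hyperparameters by mean stratified-5-fold cross-validated AUC
    and keeps a full CV report per scene.
    """

    def __init__(self, windows: pd.DataFrame,
                 grid: dict | None = None, n_splits: int = 5,
                 include_incomplete: bool = False):
        required = set(FEATURE_NAMES) | {"scene", "near_miss"}
        missing = required - set(windows.columns)
        if missing:
            raise ValueError(f"window table missing columns: {sorted(missing)}")
        if not include_incomplete and "complete" in windows.columns:
            windows = windows[windows["complete"]]
        self.windows = windows.reset_index(drop=True)
        self.grid = grid if grid is not None else DEFAULT_GRID
        self.n_splits = n_splits
        self.models_: dict[Scene, GradientBoostingClassifier] = {}
        self.reports_: dict[Scene, SceneModelReport] = {}

    @staticmethod
    def _param_grid(grid: dict) -> list[dict]:
        keys = sorted(grid)
        combos = [{}]
        for k in keys:
            combos = [dict(c, **{k: v}) for c in combos for v in grid[k]]
        return combos

    def fit(self, seed: int = 0) -> "NearMissModel":
        """Train one classifier per scene in {HIGH, MEDIUM}.

        Raises if a trained scene has fewer than two label classes.
        """
        for scene in TRAINED_SCENES:
            sub = self.windows[self.windows["scene"] == scene]
            X = sub[FEATURE_NAMES].to_numpy()
            y = sub["near_miss"].to_numpy()
            if len(np.unique(y)) < 2:
                raise ValueError(f"scene {scene.value!r} has a single class; "
                                 "cannot train a classifier")
            if np.bincount(y).min() < self.n_splits:
                raise ValueError(
                    f"scene {scene.value!r} has fewer minority-class windows "
                    f"({np.bincount(y).min()}) than CV folds "
                    f"({self.n_splits}); provide more data or fewer folds")
            cv = StratifiedKFold(self.n_splits, shuffle=True, random_state=seed)
            folds = list(cv.split(X, y))
            best = None
            for params in self._param_grid(self.grid):
                oof = np.zeros(len(y))
                fold_auc = []
                for tr, te in folds:
                    clf = GradientBoostingClassifier(random_state=seed, **params)
                    clf.fit(X[tr], y[tr])
                    oof[te] = clf.predict_proba(X[te])[:, 1]
                    fold_auc.append(roc_auc_score(y[te], oof[te]))
                mean_auc = float(np.mean(fold_auc))
                if best is None or mean_auc > best[0]:
                    best = (mean_auc, params, oof, fold_auc)
            _, params, oof, fold_auc = best
            fpr, tpr, thr = roc_curve(y, oof)
            final = GradientBoostingClassifier(random_state=seed, **params)
            final.fit(X, y)
            imp = pd.Series(final.feature_importances_, index=FEATURE_NAMES)
            imp = imp / imp.sum()
            self.models_[scene] = final
            self.reports_[scene] = SceneModelReport(
                scene=scene, best_params=params,
                auc=float(roc_auc_score(y, oof)),
                fold_auc=[float(a) for a in fold_auc],
                roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
                importances=imp,
            )
        return self

    def predict_risk(self, windows: pd.DataFrame) -> pd.Series:
        """Per-window near-miss probability in [0, 1].

        Windows in scenes without a trained model (LOW/XLOW/STOPPED) get
        NaN — the risk index is undefined at low speeds.
        """
        if not self.models_:
            raise RuntimeError("model not fitted; call fit() first")
        risk = pd.Series(np.nan, index=windows.index, name="risk")
        for scene, clf in self.models_.items():
            m = windows["scene"] == scene
            if m.any():
                X = windows.loc[m, FEATURE_NAMES].to_numpy()
                risk.loc[m] = clf.predict_proba(X)[:, 1]
        return risk

    def summary(self) -> pd.DataFrame:
        """One row per trained scene: chosen hyperparameters and CV AUC."""
        rows = []
        for scene, rep in self.reports_.items():
            rows.append({"scene": scene.value, "auc": rep.auc,
                         **{f"param_{k}": v for k, v in rep.best_params.items()}})
        return pd.DataFrame(rows)
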