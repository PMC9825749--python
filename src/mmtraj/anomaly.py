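"""Longitudinal anomaly detection on the MMI trajectory, with explanations.

Three detectors, all operating on trajectory residuals (a sample's MMI minus
the reference curve at its time):

* ``interval`` -- outside the trajectory's prediction band;
* ``lowpass`` -- far from a rolling-mean low-pass of the time-ordered
  residual series, in robust-scale units (slow drifts pass the filter,
  spikes do not);
* ``isolation`` -- Isolation Forest on rolling-window summaries
  (residual, rolling mean, rolling SD) of the time-ordered series, flagging
  the top ``contamination`` fraction.

Detected outlier sets are then explained by a gradient-boosted classifier
discriminating outliers from a subsampled background, with cross-validated
AUROC and Shapley-based feature rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, IsolationForest
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .attribution import shapley_values
from .core_io import MicrobiomeDataset
from .trajectory import MMIResult, TrajectoryCurve

_MAD_TO_SD = 1.4826

DEFAULT_WINDOW = 5
DEFAULT_K = 3.0
DEFAULT_CONTAMINATION = 0.05
DEFAULT_SUBSAMPLE_RATIO = 1.0
MAX_BACKGROUND_RATIO = 3.0


@dataclass
class AnomalyReport:
    """Per-sample outlier verdicts from one detector run."""

    frame: pd.DataFrame  # index sample_id; columns method, score, is_outlier
    method: str
    parameters: dict

    @property
    def outlier_ids(self) -> list[str]:
        return self.frame.index[self.frame["is_outlier"]].tolist()

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "method", self.method)
        out.to_csv(path)


@dataclass
class OutlierExplanation:
    """Classifier-based characterization of an outlier set."""

    classifier_name: str
    auroc: float
    feature_ranking: pd.Series  # mean |attribution| per feature, descending
    subsample_ratio: float
    n_outliers: int
    n_background: int


def interval_outliers(mmi: MMIResult, curve: TrajectoryCurve) -> AnomalyReport:
    """Flag samples outside the trajectory's prediction band.

    Score is the residual in units of the local residual scale, so the
    outlier threshold corresponds to the normal quantile of the band level.
    """
    if mmi.interval_kind != "prediction":
        raise ValueError("interval_outliers requires a prediction-interval MMIResult")
    t = mmi.frame["time"].to_numpy()
    scale = np.maximum(curve.residual_scale(t), 1e-12)
    score = np.abs(mmi.frame["residual"].to_numpy()) / scale
    frame = pd.DataFrame(
        {"score": score, "is_outlier": ~mmi.frame["within_interval"].to_numpy()},
        index=mmi.frame.index.copy(),
    )
    return AnomalyReport(
        frame=frame, method="interval",
        parameters={"level": mmi.level, "interval": mmi.interval_kind},
    )


def _centered_rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean whose window shrinks symmetrically at the edges.

    Symmetric shrinkage keeps the filter exact on linear trends everywhere,
    including the first and last points, so a pure drift detrends to zero.
    """
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h: i + h + 1].mean()
    return out


def _rolling_stats(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    half = window // 2
    mean = np.empty(n)
    sd = np.empty(n)
    for i in range(n):
        lo_, hi_ = max(0, i - half), min(n, i + half + 1)
        w = x[lo_:hi_]
        mean[i] = w.mean()
        sd[i] = w.std(ddof=0)
    return mean, sd


def lowpass_outliers(
    mmi: MMIResult,
    ds: MicrobiomeDataset | None = None,
    window: int = DEFAULT_WINDOW,
    k: float = DEFAULT_K,
) -> AnomalyReport:
    """Flag residual spikes that a rolling-average low-pass does not explain.

    Residuals are time-ordered; the rolling mean is the low-pass component
    and the score is the detrended residual in robust-scale units
    (MAD * 1.4826 over the detrended series, standard-deviation fallback
    when the MAD degenerates to zero). When a dataset is supplied, subjects
    with at least ``window`` samples are filtered per subject; everything
    else falls back to the global series.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    frame = mmi.frame
    if len(frame) < window:
        raise ValueError(f"need >= {window} samples")
    scores = pd.Series(0.0, index=frame.index)

    def process(sub: pd.DataFrame) -> None:
        order = sub["time"].argsort(kind="stable").to_numpy()
        ids = sub.index.to_numpy()[order]
        resid = sub["residual"].to_numpy()[order]
        low = _centered_rolling_mean(resid, window)
        det = resid - low
        if np.allclose(det, 0.0, atol=1e-12):
            scores.loc[ids] = 0.0
            return
        mad = np.median(np.abs(det - np.median(det)))
        scale = mad * _MAD_TO_SD
        if scale <= 1e-12:
            scale = det.std(ddof=0)
        scores.loc[ids] = np.abs(det) / scale

    if ds is not None:
        subj = ds.meta["subject_id"].reindex(frame.index)
        big = subj.value_counts()
        big_subjects = set(big.index[big >= window])
        rest_idx = []
        for s, sub_idx in frame.groupby(subj).groups.items():
            if s in big_subjects:
                process(frame.loc[sub_idx])
            else:
                rest_idx.extend(sub_idx)
        if len(rest_idx) >= window:
            process(frame.loc[rest_idx])
        elif rest_idx:
            scores.loc[rest_idx] = 0.0
    else:
        process(frame)

    out = pd.DataFrame(
        {"score": scores, "is_outlier": scores > k}, index=frame.index.copy()
    )
    return AnomalyReport(frame=out, method="lowpass",
                         parameters={"window": window, "k": k})


def isolation_outliers(
    mmi: MMIResult,
    window: int = DEFAULT_WINDOW,
    contamination: float = DEFAULT_CONTAMINATION,
    seed: int = 42,
) -> AnomalyReport:
    """Isolation Forest on rolling-window residual summaries.

    Each sample contributes the vector (residual, rolling mean, rolling SD)
    computed over the time-ordered residual series; the top
    ``ceil(contamination * n)`` samples by anomaly score are flagged.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if not (0.0 < contamination < 0.5):
        raise ValueError("contamination must be in (0, 0.5)")
    frame = mmi.frame
    order = frame["time"].argsort(kind="stable").to_numpy()
    ids = frame.index.to_numpy()[order]
    resid = frame["residual"].to_numpy()[order]
    rmean, rsd = _rolling_stats(resid, window)
    X = np.column_stack([resid, rmean, rsd])
    forest = IsolationForest(n_estimators=200, random_state=seed)
    forest.fit(X)
    score = -forest.score_samples(X)  # larger = more anomalous
    n = len(ids)
    n_flag = int(np.ceil(contamination * n))
    # deterministic flag set: by descending score, ties by series position
    rank = np.lexsort((np.arange(n), -score))
    is_out = np.zeros(n, dtype=bool)
    is_out[rank[:n_flag]] = True
    out = pd.DataFrame({"score": score, "is_outlier": is_out},
                       index=pd.Index(ids, name=frame.index.name))
    out = out.reindex(frame.index)
    return AnomalyReport(
        frame=out, method="isolation",
        parameters={"window": window, "contamination": contamination, "seed": seed},
    )


def explain_outliers(
    ds: MicrobiomeDataset,
    report: AnomalyReport,
    subsample_ratio: float = DEFAULT_SUBSAMPLE_RATIO,
    cv_folds: int = 5,
    seed: int = 42,
    metadata_columns: Sequence[str] = (),
    n_permutations: int = 6,
) -> OutlierExplanation:
    """Characterize an outlier set by what separates it from the rest.

    A gradient-boosted classifier is trained to discriminate outliers from
    a seeded subsample of the non-outliers (``subsample_ratio`` of them,
    floored at the outlier count and capped at three times it to keep
    classes balanced). Reported are the stratified-CV AUROC and features
    ranked by mean absolute Shapley attribution over the outlier samples.
    Metadata columns join the design matrix only when listed explicitly
    (one-hot encoded); subject and time never do.
    """
    if not (0.0 < subsample_ratio <= 1.0):
        raise ValueError("subsample_ratio must be in (0, 1]")
    out_ids = report.outlier_ids
    all_ids = list(ds.table.sample_ids)
    non_ids = [s for s in all_ids if s not in set(out_ids)]
    if len(out_ids) < 5 or len(non_ids) < 5:
        raise ValueError("need >= 5 outliers and >= 5 non-outliers")
    rng = np.random.default_rng(seed)
    n_bg = int(round(subsample_ratio * len(non_ids)))
    n_bg = max(n_bg, len(out_ids))
    n_bg = min(n_bg, int(MAX_BACKGROUND_RATIO * len(out_ids)), len(non_ids))
    bg_ids = list(np.array(non_ids)[rng.choice(len(non_ids), n_bg, replace=False)]) \
        if n_bg < len(non_ids) else non_ids

    design = ds.table.values.loc[out_ids + bg_ids].copy()
    feat_cols = [str(c) for c in design.columns]
    if metadata_columns:
        meta = ds.meta.loc[out_ids + bg_ids]
        banned = {"subject_id", "time"}
        use = [c for c in metadata_columns if c not in banned]
        enc = pd.get_dummies(meta[use], dtype=float)
        design = pd.concat([design, enc], axis=1)
        feat_cols = [str(c) for c in design.columns]
    X = design.to_numpy(dtype=float)
    y = np.array([1] * len(out_ids) + [0] * len(bg_ids))
    if len(set(y)) < 2:
        raise ValueError("degenerate classes")

    clf = GradientBoostingClassifier(random_state=seed)
    n_splits = min(cv_folds, min(np.bincount(y)))
    if n_splits < 2:
        raise ValueError("too few samples per class for cross-validation")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    auroc = float(np.mean(cross_val_score(clf, X, y, cv=cv, scoring="roc_auc")))
    clf.fit(X, y)

    def predict_logit(A: np.ndarray) -> np.ndarray:
        return clf.decision_function(A)

    bg_size = min(25, len(bg_ids))
    bg_idx = len(out_ids) + rng.choice(len(bg_ids), bg_size, replace=False)
    phi, _ = shapley_values(
        predict_logit, X[: len(out_ids)], X[bg_idx],
        n_permutations=n_permutations, seed=seed,
    )
    ranking = pd.Series(np.abs(phi).mean(axis=0), index=feat_cols).sort_values(
        ascending=False
    )
    return OutlierExplanation(
        classifier_name="gradient_boosting",
        auroc=auroc,
        feature_ranking=ranking,
        subsample_ratio=subsample_ratio,
        n_outliers=len(out_ids),
        n_background=len(bg_ids),
    )
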