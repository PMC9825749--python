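"""Microbiome maturation trajectories.

The Microbiome Maturation Index (MMI) of a sample is the time (age) a
regressor predicts from its feature abundances, after training on reference
samples only -- the "microbiota-for-age" convention. The trajectory is a
cubic smoothing spline of MMI against time fitted over the reference
samples, equipped with prediction and confidence bands derived from binned
residual scales. Samples far outside the prediction band are candidate
anomalies; per-feature Shapley attributions explain which taxa drive a
sample's MMI.

The regressor is pluggable through a small named registry; grouped
cross-validation (folds split by subject) is used everywhere so that
repeated samples of one subject never straddle a train/test boundary.
"""

from __future__ import annotations

import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import (
    BaggingRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GroupKFold, cross_val_predict
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .attribution import DEFAULT_BACKGROUND_SIZE, shapley_values
from .core_io import MicrobiomeDataset

logger = logging.getLogger(__name__)

IntervalKind = Literal["confidence", "prediction"]

DEFAULT_REGRESSOR = "bagged_trees"
MIN_CURVE_POINTS = 10
# E[|Z| | |Z| <= 90th percentile of |Z|] for Z~N(0,1): normalizes the
# 10%-upper-trimmed mean of absolute residuals into a standard deviation
_TRIMMED_ABS_MEAN = 0.65735
_TRIM_FRAC = 0.10


def _registry(seed: int) -> dict[str, object]:
    return {
        "linear": LinearRegression(),
        "ridge": Ridge(alpha=1.0),
        "lasso": Lasso(alpha=0.01, max_iter=5000),
        "elasticnet": ElasticNet(alpha=0.01, max_iter=5000),
        "knn": KNeighborsRegressor(n_neighbors=5),
        "svr": SVR(C=10.0),
        "tree": DecisionTreeRegressor(random_state=seed),
        "bagged_trees": BaggingRegressor(
            DecisionTreeRegressor(), n_estimators=50, random_state=seed
        ),
        "random_forest": RandomForestRegressor(n_estimators=100, random_state=seed),
        "gradient_boosting": GradientBoostingRegressor(random_state=seed),
        "hist_gradient_boosting": HistGradientBoostingRegressor(random_state=seed),
        "dummy": DummyRegressor(strategy="mean"),
    }


def list_regressors() -> list[str]:
    return sorted(_registry(0))


def make_regressor(name: str, seed: int = 42):
    reg = _registry(seed)
    if name not in reg:
        raise KeyError(f"unknown regressor {name!r}; registry: {sorted(reg)}")
    return clone(reg[name])


@dataclass
class TrajectoryCurve:
    """Smooth expected-MMI curve with residual-scale bands.

    The curve is a cubic smoothing spline (smoothing by generalized
    cross-validation). ``residual_scale(t)`` is a monotone (shape-preserving)
    interpolation of per-time-bin residual scales, each estimated robustly
    from a trimmed mean of absolute residuals. The
    prediction band is curve +/- z * residual_scale(t); the confidence band
    shrinks the scale by 1/sqrt(n_bin).
    """

    spline: object
    t_range: tuple[float, float]
    bin_centers: np.ndarray
    bin_scales: np.ndarray
    bin_counts: np.ndarray
    interval_kind: IntervalKind = "prediction"
    level: float = 0.95
    _scale_interp: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.bin_centers) >= 2:
            self._scale_interp = PchipInterpolator(
                self.bin_centers, self.bin_scales, extrapolate=False
            )
        else:
            self._scale_interp = None

    def __call__(self, t) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), *self.t_range)
        return np.asarray(self.spline(t), dtype=float)

    def residual_scale(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self._scale_interp is None:
            return np.full(t.shape, float(self.bin_scales[0]))
        tc = np.clip(t, self.bin_centers[0], self.bin_centers[-1])
        return np.asarray(self._scale_interp(tc), dtype=float)

    def _bin_n(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.abs(t[:, None] - self.bin_centers[None, :]).argmin(axis=1)
        return self.bin_counts[idx].astype(float)

    def half_width(
        self, t, kind: IntervalKind | None = None, level: float | None = None
    ) -> np.ndarray:
        kind = kind or self.interval_kind
        level = level if level is not None else self.level
        z = stats.norm.ppf(0.5 + level / 2.0)
        hw = z * self.residual_scale(t)
        if kind == "confidence":
            hw = hw / np.sqrt(np.maximum(self._bin_n(t), 1.0))
        return hw

    def band(self, t, kind: IntervalKind | None = None, level: float | None = None):
        mid = self(t)
        hw = self.half_width(t, kind, level)
        return mid - hw, mid + hw


def fit_trajectory_curve(
    times: Sequence[float],
    mmis: Sequence[float],
    level: float = 0.95,
    interval: IntervalKind = "prediction",
    n_bins: int = 10,
) -> TrajectoryCurve:
    """Fit the smooth MMI-vs-time curve and its residual-scale bands."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(mmis, dtype=float)
    if t.size < MIN_CURVE_POINTS:
        raise ValueError(f"need >= {MIN_CURVE_POINTS} points, got {t.size}")
    if not (0.5 < level < 1.0):
        raise ValueError("level must be in (0.5, 1)")
    spline = _smooth_spline(t, y)
    t_range = (float(t.min()), float(t.max()))
    resid = y - np.asarray(spline(t), dtype=float)
    edges = np.linspace(t_range[0], t_range[1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    centers, scales, counts = [], [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(float(t[mask].mean()))
        scales.append(_robust_scale(resid[mask]))
        counts.append(int(mask.sum()))
    return TrajectoryCurve(
        spline=spline,
        t_range=t_range,
        bin_centers=np.asarray(centers),
        bin_scales=np.asarray(scales),
        bin_counts=np.asarray(counts),
        interval_kind=interval,
        level=level,
    )


def _smooth_spline(t: np.ndarray, y: np.ndarray, lam: float | None = None):
    """GCV cubic smoothing spline over aggregated abscissae.

    Near-coincident time points (within 1/500 of the observed range) are
    merged into weighted means before fitting: jittered longitudinal
    designs otherwise produce abscissa gaps tiny enough to make the GCV
    problem numerically singular. Merging at the weighted mean abscissa is
    exact for data on a straight line. If GCV still fails, a fixed moderate
    smoothing parameter is used; with fewer than 5 distinct abscissae the
    fit degrades to a least-squares line.
    """
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    span = ts[-1] - ts[0]
    tol = span / 500.0 if span > 0 else 0.0
    ux, uy, cnt = _merge_close(ts, ys, tol)
    if ux.size >= 5:
        try:
            return make_smoothing_spline(ux, uy, w=cnt, lam=lam)
        except (ValueError, np.linalg.LinAlgError):
            fallback = float(span**3) / max(ux.size, 1)
            return make_smoothing_spline(ux, uy, w=cnt, lam=fallback)
    coef = np.polyfit(ts, ys, 1)
    return np.poly1d(coef)


def _robust_scale(resid: np.ndarray) -> float:
    """SD estimate from the 10%-upper-trimmed mean of absolute residuals.

    Trimming makes the estimate insensitive to a modest fraction of gross
    outliers -- the very samples the prediction band is meant to expose --
    while keeping near-Gaussian efficiency; the half-normal constant makes
    it consistent for the standard deviation of centred normal residuals.
    """
    a = np.sort(np.abs(np.asarray(resid, dtype=float)))
    keep = max(1, int(np.ceil((1.0 - _TRIM_FRAC) * a.size)))
    return float(a[:keep].mean() / _TRIMMED_ABS_MEAN)


def _select_lam(
    t: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    n_grid: int = 10,
) -> float:
    """Smoothing parameter by interleaved 3-fold CV with the 1-SE rule.

    CV error is accumulated per group (each group is one smooth curve);
    among candidate parameters, the largest one whose total CV error lies
    within one standard error of the minimum wins, which biases the choice
    toward smoothness -- undersmoothed fits make curve-difference statistics
    noise-dominated.
    """
    span = float(np.max(t) - np.min(t))
    if span <= 0:
        return 1.0
    if groups is None:
        groups = np.zeros(len(t), dtype=int)
    lams = span**3 * np.logspace(-6, 1, n_grid)
    fold_sse = np.full((n_grid, 3 * len(np.unique(groups))), np.nan)
    for gi, g in enumerate(np.unique(groups)):
        sel = np.asarray(groups) == g
        order = np.argsort(t[sel], kind="stable")
        ts, ys = t[sel][order], y[sel][order]
        for li, lam in enumerate(lams):
            for fold in range(3):
                test = np.arange(fold, ts.size, 3)
                train = np.setdiff1d(np.arange(ts.size), test)
                if train.size < 4 or test.size == 0:
                    fold_sse[li, 3 * gi + fold] = 0.0
                    continue
                try:
                    sp = _smooth_spline(ts[train], ys[train], lam=float(lam))
                except Exception:
                    fold_sse[li, 3 * gi + fold] = np.inf
                    continue
                pred = np.asarray(sp(np.clip(ts[test], ts[train][0], ts[train][-1])))
                fold_sse[li, 3 * gi + fold] = float(np.sum((pred - ys[test]) ** 2))
    total = fold_sse.sum(axis=1)
    if not np.any(np.isfinite(total)):
        return float(lams[-1])
    best = int(np.nanargmin(total))
    n_folds = fold_sse.shape[1]
    se = float(np.nanstd(fold_sse[best], ddof=1) * np.sqrt(n_folds)) if n_folds > 1 else 0.0
    admissible = np.flatnonzero(total <= total[best] + se)
    return float(lams[admissible.max()])


def _merge_close(ts: np.ndarray, ys: np.ndarray, tol: float):
    """Greedy merge of sorted abscissae closer than tol; weighted means."""
    ux, uy, cnt = [], [], []
    i = 0
    n = ts.size
    while i < n:
        j = i + 1
        while j < n and ts[j] - ts[j - 1] <= tol:
            j += 1
        ux.append(ts[i:j].mean())
        uy.append(ys[i:j].mean())
        cnt.append(float(j - i))
        i = j
    return np.asarray(ux), np.asarray(uy), np.asarray(cnt)


@dataclass
class TrajectoryModel:
    """Fitted MMI regressor plus its reference trajectory curve."""

    regressor: object
    regressor_name: str
    feature_ids_used: list[str]
    curve: TrajectoryCurve
    training_samples: list[str]
    seed: int
    training_X: np.ndarray = field(repr=False, default=None)
    oof_mmi: pd.Series | None = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.regressor.predict(np.asarray(X, dtype=float)), dtype=float)

    def background(self, size: int = DEFAULT_BACKGROUND_SIZE) -> np.ndarray:
        """Seeded subsample of the training matrix for attribution baselines."""
        rng = np.random.default_rng(self.seed)
        n = self.training_X.shape[0]
        if n <= size:
            return self.training_X
        idx = rng.choice(n, size=size, replace=False)
        return self.training_X[idx]


_MODEL_FORMAT_VERSION = 1


def save_model(model: TrajectoryModel, path) -> None:
    """Serialize a fitted model (versioned; includes feature order and seed)."""
    import pickle

    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> TrajectoryModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return payload["model"]


@dataclass
class MMIResult:
    """Per-sample MMI predictions against a trajectory curve."""

    frame: pd.DataFrame  # index sample_id; columns time, mmi, residual, within_interval
    interval_kind: IntervalKind
    level: float

    @property
    def mmi(self) -> pd.Series:
        return self.frame["mmi"]

    @property
    def residual(self) -> pd.Series:
        return self.frame["residual"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def _reference_or_all(ds: MicrobiomeDataset) -> MicrobiomeDataset:
    flags = [m.is_reference for m in ds.metadata]
    if any(f is True for f in flags):
        return ds.reference_subset()
    return ds


def fit_mmi_model(
    ds: MicrobiomeDataset,
    regressor_name: str = DEFAULT_REGRESSOR,
    seed: int = 42,
    level: float = 0.95,
    interval: IntervalKind = "prediction",
    cv_folds: int = 5,
) -> TrajectoryModel:
    """Train the MMI regressor on reference samples and derive the trajectory.

    The regressor learns time from feature abundances. The trajectory curve
    and its residual scales are estimated from grouped out-of-fold
    predictions of the training samples, so the bands reflect generalization
    error rather than in-sample (possibly memorized) fit.
    """
    ref = _reference_or_all(ds)
    if ref.n_samples < MIN_CURVE_POINTS:
        raise ValueError(f"need >= {MIN_CURVE_POINTS} reference samples")
    X = ref.table.values.to_numpy(dtype=float)
    meta = ref.meta
    y = meta["time"].to_numpy()
    groups = meta["subject_id"].to_numpy()
    reg = make_regressor(regressor_name, seed=seed)
    n_splits = min(cv_folds, len(np.unique(groups)))
    oof = cross_val_predict(reg, X, y, groups=groups, cv=GroupKFold(n_splits=n_splits))
    reg.fit(X, y)
    curve = fit_trajectory_curve(y, oof, level=level, interval=interval)
    return TrajectoryModel(
        regressor=reg,
        regressor_name=regressor_name,
        feature_ids_used=[str(f) for f in ref.table.feature_ids],
        curve=curve,
        training_samples=list(ref.table.sample_ids),
        seed=seed,
        training_X=X,
        oof_mmi=pd.Series(oof, index=ref.table.values.index, name="oof_mmi"),
    )


def predict_mmi(
    model: TrajectoryModel,
    ds: MicrobiomeDataset,
    interval: IntervalKind | None = None,
    level: float | None = None,
) -> MMIResult:
    """Predict MMI for every sample and flag interval membership."""
    kind = interval or model.curve.interval_kind
    lvl = level if level is not None else model.curve.level
    have = set(ds.table.feature_ids)
    missing = [f for f in model.feature_ids_used if f not in have]
    if missing:
        raise KeyError(f"dataset lacks model feature(s): {missing}")
    extra = sorted(have - set(model.feature_ids_used))
    if extra:
        logger.warning("ignoring %d feature(s) unknown to the model", len(extra))
    X = ds.table.values[model.feature_ids_used].to_numpy(dtype=float)
    mmi = model.predict(X)
    t = ds.meta["time"].to_numpy()
    mid = model.curve(t)
    resid = mmi - mid
    hw = model.curve.half_width(t, kind, lvl)
    frame = pd.DataFrame(
        {
            "time": t,
            "mmi": mmi,
            "residual": resid,
            "within_interval": np.abs(resid) <= hw + 1e-12,
        },
        index=ds.table.values.index.copy(),
    )
    return MMIResult(frame=frame, interval_kind=kind, level=lvl)


def feature_importance_over_time(
    model: TrajectoryModel,
    ds: MicrobiomeDataset,
    time_windows: Sequence[tuple[float, float]],
    n_permutations: int = 8,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
) -> pd.DataFrame:
    """Mean absolute Shapley attribution per feature within each time window.

    Windows are half-open ``[lo, hi)`` except that the final window also
    admits samples exactly at its right edge (so a partition of the observed
    range covers every sample). Empty windows yield all-NaN rows with a
    warning.
    """
    X = ds.table.values[model.feature_ids_used].to_numpy(dtype=float)
    t = ds.meta["time"].to_numpy()
    phi, _ = shapley_values(
        model.predict, X, model.background(background_size),
        n_permutations=n_permutations, seed=model.seed,
    )
    rows = []
    labels = []
    for w, (lo, hi) in enumerate(time_windows):
        mask = (t >= lo) & (t < hi)
        if w == len(time_windows) - 1:
            mask |= t == hi
        labels.append(f"[{lo:g}, {hi:g})")
        if not mask.any():
            warnings.warn(f"time window [{lo}, {hi}) contains no samples")
            rows.append(np.full(X.shape[1], np.nan))
        else:
            rows.append(np.abs(phi[mask]).mean(axis=0))
    return pd.DataFrame(rows, index=labels, columns=model.feature_ids_used)


def attribute_values(
    model: TrajectoryModel,
    values: pd.DataFrame,
    n_permutations: int = 8,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
) -> pd.DataFrame:
    """Shapley attribution of MMI for rows of a feature-value frame."""
    X = values[model.feature_ids_used].to_numpy(dtype=float)
    phi, _ = shapley_values(
        model.predict, X, model.background(background_size),
        n_permutations=n_permutations, seed=model.seed,
    )
    return pd.DataFrame(phi, index=values.index.copy(), columns=model.feature_ids_used)


def per_sample_attributions(
    model: TrajectoryModel,
    ds: MicrobiomeDataset,
    n_permutations: int = 8,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
) -> pd.DataFrame:
    """Shapley attribution of each sample's MMI, one row per sample."""
    return attribute_values(
        model, ds.table.values, n_permutations=n_permutations,
        background_size=background_size,
    )


@dataclass
class Leaderboard:
    """Cross-validated comparison of candidate MMI regressors."""

    frame: pd.DataFrame  # model, cv_r2_mean, cv_r2_sd, cv_mae_mean, fit_seconds, failed
    fold_hash: str

    def to_csv(self, path) -> None:
        # wall-clock timings are the one non-deterministic column; keeping
        # them out of the export makes identical runs byte-identical
        self.frame.drop(columns=["fit_seconds"]).to_csv(path, index=False)


def compare_models(
    ds: MicrobiomeDataset,
    regressor_names: Sequence[str],
    cv_folds: int = 5,
    seed: int = 42,
) -> Leaderboard:
    """Rank regressors by grouped-CV R^2 with identical folds for all models."""
    if len(regressor_names) < 2:
        raise ValueError("need >= 2 models to compare")
    ref = _reference_or_all(ds)
    X = ref.table.values.to_numpy(dtype=float)
    meta = ref.meta
    y = meta["time"].to_numpy()
    groups = meta["subject_id"].to_numpy()
    n_splits = min(cv_folds, len(np.unique(groups)))
    folds = list(GroupKFold(n_splits=n_splits).split(X, y, groups))
    import hashlib

    fold_hash = hashlib.sha256(
        b"|".join(np.sort(te).tobytes() for _, te in folds)
    ).hexdigest()[:16]
    rows = []
    for name in regressor_names:
        t0 = _time.perf_counter()
        try:
            r2s, maes = [], []
            for tr, te in folds:
                reg = make_regressor(name, seed=seed)
                reg.fit(X[tr], y[tr])
                pred = reg.predict(X[te])
                r2s.append(r2_score(y[te], pred))
                maes.append(mean_absolute_error(y[te], pred))
            rows.append(
                dict(
                    model=name,
                    cv_r2_mean=float(np.mean(r2s)),
                    cv_r2_sd=float(np.std(r2s, ddof=1)),
                    cv_mae_mean=float(np.mean(maes)),
                    fit_seconds=_time.perf_counter() - t0,
                    failed=False,
                )
            )
        except Exception as exc:  # a failing model must not sink the board
            logger.warning("model %s failed: %s", name, exc)
            rows.append(
                dict(
                    model=name, cv_r2_mean=np.nan, cv_r2_sd=np.nan,
                    cv_mae_mean=np.nan, fit_seconds=_time.perf_counter() - t0,
                    failed=True,
                )
            )
    frame = pd.DataFrame(rows).sort_values(
        ["cv_r2_mean", "model"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return Leaderboard(frame=frame, fold_hash=fold_hash)


@dataclass
class GroupComparisonResult:
    """Statistical comparison of two groups' MMI trajectories."""

    method: Literal["linear", "spline_permutation"]
    statistic: float
    p_value: float
    per_group_fit: dict[str, dict[str, float]]
    n_permutations: int = 0


def compare_trajectories(
    ds: MicrobiomeDataset,
    model: TrajectoryModel,
    group_a: str,
    group_b: str,
    method: Literal["linear", "spline_permutation"] = "linear",
    n_permutations: int = 999,
    seed: int = 42,
) -> GroupComparisonResult:
    """Test whether two groups follow the same MMI-vs-time trajectory.

    ``linear`` fits mmi ~ time + group + time:group by least squares and
    reports the F-test of the joint null (no group offset, no slope
    difference). ``spline_permutation`` measures the integrated squared
    difference between per-group smoothing splines on a 201-point grid over
    the shared time range, with a null built by permuting the group
    assignment of whole subjects (all samples of a subject move together).
    """
    meta = ds.meta
    for g in (group_a, group_b):
        if (meta["group"] == g).sum() < MIN_CURVE_POINTS:
            raise ValueError(f"group {g!r} has fewer than {MIN_CURVE_POINTS} samples")
    sub = ds.subset(meta.index[meta["group"].isin([group_a, group_b])].tolist())
    res = predict_mmi(model, sub)
    m = sub.meta
    frame = pd.DataFrame(
        {
            "time": m["time"].to_numpy(),
            "mmi": res.frame["mmi"].to_numpy(),
            "group": m["group"].to_numpy(),
            "subject": m["subject_id"].to_numpy(),
        }
    )
    ta = frame.loc[frame["group"] == group_a, "time"]
    tb = frame.loc[frame["group"] == group_b, "time"]
    lo, hi = max(ta.min(), tb.min()), min(ta.max(), tb.max())
    if lo >= hi:
        raise ValueError("groups cover disjoint time ranges")

    per_group_fit = {}
    for g in (group_a, group_b):
        sel = frame[frame["group"] == g]
        slope, icept = np.polyfit(sel["time"], sel["mmi"], 1)
        per_group_fit[g] = {"slope": float(slope), "intercept": float(icept),
                            "n": int(len(sel))}

    if method == "linear":
        import statsmodels.formula.api as smf

        frame["g"] = (frame["group"] == group_b).astype(float)
        full = smf.ols("mmi ~ time + g + time:g", data=frame).fit()
        restricted = smf.ols("mmi ~ time", data=frame).fit()
        f_stat, p, _ = full.compare_f_test(restricted)
        return GroupComparisonResult(
            method="linear", statistic=float(f_stat), p_value=float(p),
            per_group_fit=per_group_fit, n_permutations=0,
        )
    if method == "spline_permutation":
        if n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        grid = np.linspace(lo, hi, 201)
        # one smoothing parameter, chosen on the observed per-group curves,
        # is reused for every fit so the statistic is identical for observed
        # and null data
        lam = _select_lam(
            frame["time"].to_numpy(), frame["mmi"].to_numpy(),
            groups=frame["group"].to_numpy(),
        )

        def isd(fr: pd.DataFrame, assign: pd.Series) -> float:
            diffs = []
            for g in (group_a, group_b):
                sel = fr[assign == g]
                sp = _smooth_spline(sel["time"].to_numpy(), sel["mmi"].to_numpy(), lam=lam)
                diffs.append(np.asarray(sp(grid), dtype=float))
            return float(np.trapezoid((diffs[0] - diffs[1]) ** 2, grid))

        observed = isd(frame, frame["group"])
        subj_group = frame.groupby("subject")["group"].first()
        subjects = subj_group.index.to_numpy()
        labels = subj_group.to_numpy().copy()
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            rng.shuffle(labels)
            assign = frame["subject"].map(dict(zip(subjects, labels)))
            if isd(frame, assign) >= observed:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        return GroupComparisonResult(
            method="spline_permutation", statistic=observed, p_value=float(p),
            per_group_fit=per_group_fit, n_permutations=n_permutations,
        )
    raise ValueError(f"unknown method {method!r}")
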