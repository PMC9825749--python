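"""Preprocessing for trajectory modelling.

Covers normalization to relative abundances, variance/correlation feature
filtering, the additive log-ratio transform with three denominator-selection
strategies (temporal stability measured as trajectory crossings, extreme
time-association ranking, and downstream model performance under grouped
cross-validation), hybrid feature sets, and reference-group definition
including isolation-based novelty detection.

Compositional data carry only relative information; dividing every feature
by a common denominator and taking logs removes the arbitrary scale, at the
price of choosing that denominator well. A good denominator is temporally
stable relative to the rest of the community -- hence the "fewest crossings"
heuristic -- or is picked directly for downstream predictive performance.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import IsolationForest

from .core_io import FeatureTable, MicrobiomeDataset

logger = logging.getLogger(__name__)

Strategy = Literal["crossings", "ranking_low", "ranking_high", "performance"]

MIN_REFERENCE_SAMPLES = 10
DEFAULT_N_BINS = 10


@dataclass
class DenominatorReport:
    """Outcome of denominator selection for the log-ratio transform."""

    feature_id: str
    strategy: Strategy
    score_per_candidate: dict[str, float]
    ties_broken: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"score": pd.Series(self.score_per_candidate, name="score")}
        )
        df.index.name = "feature_id"
        df["chosen"] = df.index == self.feature_id
        return df


@dataclass
class ReferenceAssignment:
    """Per-sample reference flags plus the mode that produced them."""

    is_reference: dict[str, bool]
    mode: Literal["declared", "group_label", "novelty"]
    novelty_scores: dict[str, float] | None = None


@dataclass
class RemovalLog:
    """Audit trail of filtered features."""

    removed: list[tuple[str, str]] = field(default_factory=list)  # (feature, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["feature_id", "reason"])


def default_pseudocount(table: FeatureTable) -> float:
    """Half the smallest non-zero value in the table (0 if all-positive)."""
    arr = table.values.to_numpy(dtype=float)
    nz = arr[arr > 0]
    if nz.size == 0:
        raise ValueError("table has no positive values")
    if np.all(arr > 0):
        return 0.0
    return float(nz.min() / 2.0)


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Close each sample's counts to proportions summing to 1."""
    if table.value_kind != "counts":
        raise ValueError(f"expected counts, got {table.value_kind}")
    arr = table.values.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        sid = table.values.index[int(np.argmax(zero))]
        raise ValueError(f"sample {sid!r} has zero total count")
    rel = arr / totals[:, None]
    return FeatureTable(
        values=pd.DataFrame(rel, index=table.values.index, columns=table.values.columns),
        value_kind="relative",
    )


def filter_features(
    table: FeatureTable,
    variance_quantile: float = 0.1,
    correlation_threshold: float = 0.95,
) -> tuple[FeatureTable, RemovalLog]:
    """Drop low-variance features, then one member of each highly correlated pair.

    Correlated pairs are scanned by descending \\|Pearson r\\| (ties broken by
    feature-id order) and the lower-variance member is removed greedily, so
    the removal log is deterministic for identical inputs.
    """
    if table.n_features < 2:
        raise ValueError("need at least 2 features to filter")
    log = RemovalLog()
    df = table.values
    variances = df.var(axis=0, ddof=1)
    if variance_quantile > 0:
        cutoff = float(np.quantile(variances.to_numpy(), variance_quantile))
        low = variances[variances < cutoff].index.tolist()
        # constant features always count as low-variance
        low = sorted(set(low) | set(variances[variances == 0].index), key=list(df.columns).index)
        for f in low:
            log.removed.append((str(f), "low_variance"))
        df = df.drop(columns=low)
    if df.shape[1] == 0:
        raise ValueError("variance filtering removed all features")
    if df.shape[1] >= 2:
        corr = df.corr().to_numpy()
        cols = list(df.columns)
        pairs = []
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r = corr[i, j]
                if np.isfinite(r) and abs(r) >= correlation_threshold:
                    pairs.append((abs(r), cols[i], cols[j]))
        pairs.sort(key=lambda p: (-p[0], str(p[1]), str(p[2])))
        dropped: set[str] = set()
        var = df.var(axis=0, ddof=1)
        for _, a, b in pairs:
            if a in dropped or b in dropped:
                continue
            victim = a if var[a] <= var[b] else b
            dropped.add(victim)
            log.removed.append((str(victim), "correlated"))
        df = df.drop(columns=sorted(dropped, key=cols.index))
    if df.shape[1] == 0:
        raise ValueError("correlation filtering removed all features")
    if table.value_kind == "relative":
        # closure of the retained subcomposition keeps rows on the simplex
        df = df.div(df.sum(axis=1), axis=0)
    return FeatureTable(values=df, value_kind=table.value_kind), log


def log_ratio_transform(
    table: FeatureTable, denominator: str, pseudocount: float | None = None
) -> FeatureTable:
    """Additive log-ratio: ln((v_ij + c) / (v_iD + c)); denominator dropped."""
    if table.value_kind not in ("counts", "relative"):
        raise ValueError("log-ratio transform requires counts or relative abundances")
    cols = [str(c) for c in table.values.columns]
    if denominator not in cols:
        near = difflib.get_close_matches(denominator, cols, n=3)
        raise KeyError(f"denominator {denominator!r} not found; close matches: {near}")
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    arr = table.values.to_numpy(dtype=float) + pseudocount
    if np.any(arr <= 0):
        raise ValueError("zeros present; use a positive pseudocount")
    j = cols.index(denominator)
    out = np.log(arr) - np.log(arr[:, [j]])
    out = np.delete(out, j, axis=1)
    keep = [c for c in table.values.columns if str(c) != denominator]
    return FeatureTable(
        values=pd.DataFrame(out, index=table.values.index, columns=keep),
        value_kind="logratio",
    )


def _binned_medians(ds: MicrobiomeDataset, n_bins: int) -> pd.DataFrame:
    """Per-feature median relative abundance per equal-width time bin.

    Rows are bins in time order; bins with no samples are dropped (the
    difference series is compacted).
    """
    table = ds.table
    if table.value_kind == "counts":
        table = to_relative_abundance(table)
    times = ds.meta["time"].to_numpy()
    lo, hi = float(times.min()), float(times.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, n_bins - 1)
    vals = table.values
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        rows.append(vals.iloc[mask].median(axis=0))
    if len(rows) < 2:
        raise ValueError("fewer than 2 non-empty time bins")
    return pd.DataFrame(rows).reset_index(drop=True)


def count_crossings(
    ds: MicrobiomeDataset, candidate: str, n_bins: int = DEFAULT_N_BINS
) -> int:
    """Number of times other features' binned median trajectories cross the candidate's.

    For each other feature, the sign of (median_feature - median_candidate)
    is tracked across adjacent non-empty bins; a sign flip is one crossing.
    Fewer crossings means the candidate is more stable relative to the
    community, which makes it a better log-ratio denominator.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    med = _binned_medians(ds, n_bins)
    if candidate not in med.columns:
        raise KeyError(f"unknown feature {candidate!r}")
    total = 0
    cand = med[candidate].to_numpy()
    for f in med.columns:
        if f == candidate:
            continue
        diff = med[f].to_numpy() - cand
        signs = np.sign(diff)
        signs = signs[signs != 0]  # grazing contact is not a crossing
        if signs.size >= 2:
            total += int(np.sum(signs[1:] * signs[:-1] < 0))
    return total


def differential_ranking(ds: MicrobiomeDataset) -> dict[str, float]:
    """Spearman correlation of each feature's relative abundance with time.

    Strongly time-associated features (rho near +/-1) mark taxa that bloom or
    decline over the study; constant features get 0.
    """
    if len(set(ds.meta["time"])) < 3:
        raise ValueError("need >= 3 distinct time points")
    table = ds.table
    if table.value_kind == "counts":
        table = to_relative_abundance(table)
    times = ds.meta["time"].to_numpy()
    out: dict[str, float] = {}
    for f in table.values.columns:
        x = table.values[f].to_numpy()
        if np.all(x == x[0]):
            out[str(f)] = 0.0
            continue
        rho = stats.spearmanr(x, times).statistic
        out[str(f)] = float(rho) if np.isfinite(rho) else 0.0
    return out


def select_denominator(
    ds: MicrobiomeDataset,
    strategy: Strategy = "crossings",
    model_spec: str | None = None,
    cv_folds: int = 5,
    n_bins: int = DEFAULT_N_BINS,
    pseudocount: float | None = None,
    seed: int = 42,
) -> DenominatorReport:
    """Choose the log-ratio denominator feature under the given strategy.

    ``crossings`` minimizes trajectory crossings; ``ranking_low`` /
    ``ranking_high`` take the extreme time-association; ``performance``
    log-ratio-transforms the reference samples with each candidate in the
    denominator, scores a regressor of time-on-features by grouped CV
    (folds split by subject), and takes the best mean R^2. Ties break
    lexicographically.
    """
    if ds.table.n_features < 2:
        raise ValueError("need >= 2 features")
    features = [str(f) for f in ds.table.feature_ids]
    if strategy == "crossings":
        scores = {f: float(count_crossings(ds, f, n_bins)) for f in features}
        best = min(sorted(scores), key=lambda f: (scores[f], f))
        tie = sum(1 for v in scores.values() if v == scores[best]) > 1
    elif strategy in ("ranking_low", "ranking_high"):
        scores = differential_ranking(ds)
        if strategy == "ranking_low":
            best = min(sorted(scores), key=lambda f: (scores[f], f))
        else:
            best = max(sorted(scores), key=lambda f: (scores[f], f))
        tie = sum(1 for v in scores.values() if v == scores[best]) > 1
    elif strategy == "performance":
        if model_spec is None:
            raise ValueError("strategy='performance' requires model_spec")
        scores = {}
        for f in features:
            scores[f] = _denominator_cv_score(
                ds, f, model_spec, cv_folds, pseudocount, seed
            )
        best = max(sorted(scores), key=lambda f: (scores[f], f))
        tie = sum(1 for v in scores.values() if v == scores[best]) > 1
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return DenominatorReport(
        feature_id=best, strategy=strategy, score_per_candidate=scores, ties_broken=tie
    )


def _denominator_cv_score(
    ds: MicrobiomeDataset,
    denominator: str,
    model_spec: str,
    cv_folds: int,
    pseudocount: float | None,
    seed: int,
) -> float:
    from sklearn.model_selection import GroupKFold, cross_val_score

    from .trajectory import make_regressor

    ref = ds.reference_subset() if any(m.is_reference for m in ds.metadata) else ds
    lr = log_ratio_transform(ref.table, denominator, pseudocount)
    X = lr.values.to_numpy()
    meta = ref.meta
    y = meta["time"].to_numpy()
    groups = meta["subject_id"].to_numpy()
    n_splits = min(cv_folds, len(np.unique(groups)))
    reg = make_regressor(model_spec, seed=seed)
    scores = cross_val_score(
        reg, X, y, groups=groups, cv=GroupKFold(n_splits=n_splits), scoring="r2"
    )
    return float(np.mean(scores))


def build_hybrid_feature_set(
    model_importances: dict[str, float],
    top_k: int,
    domain_features: list[str] | None = None,
) -> list[str]:
    """Union of the top-k model-important features with curated domain features.

    Importance order first, then domain additions in given order, no
    duplicates.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    domain_features = domain_features or []
    unknown = [f for f in domain_features if f not in model_importances]
    if unknown:
        raise KeyError(f"unknown domain feature(s): {unknown}")
    ranked = sorted(model_importances, key=lambda f: (-model_importances[f], f))
    out = ranked[:top_k]
    for f in domain_features:
        if f not in out:
            out.append(f)
    return out


def define_reference(
    ds: MicrobiomeDataset,
    mode: Literal["declared", "group_label", "novelty"] = "declared",
    reference_group: str | None = None,
    novelty_frac: float = 0.05,
    seed: int = 42,
) -> ReferenceAssignment:
    """Decide which samples anchor the reference trajectory.

    ``declared`` passes through metadata flags; ``group_label`` uses group
    membership; ``novelty`` fits an Isolation Forest on the declared/group
    seed set, re-admits non-seed samples whose novelty score falls within
    the seed set's score range, and expels the most anomalous
    ``novelty_frac`` tail of the seed set itself.
    """
    meta = ds.meta
    if mode == "declared":
        flags = meta["is_reference"]
        if flags.isna().any():
            raise ValueError("mode='declared' requires is_reference in metadata")
        result = {s: bool(v) for s, v in flags.items()}
        scores = None
    elif mode == "group_label":
        if reference_group is None:
            raise ValueError("mode='group_label' requires reference_group")
        if reference_group not in set(meta["group"]):
            raise ValueError(
                f"group {reference_group!r} absent; available: {sorted(set(meta['group']))}"
            )
        result = {s: g == reference_group for s, g in meta["group"].items()}
        scores = None
    elif mode == "novelty":
        if not (0.0 < novelty_frac <= 0.5):
            raise ValueError("novelty_frac must be in (0, 0.5]")
        if meta["is_reference"].notna().any() and meta["is_reference"].any():
            seed_mask = meta["is_reference"].fillna(False).astype(bool)
        elif reference_group is not None:
            seed_mask = meta["group"] == reference_group
        else:
            raise ValueError("novelty mode needs declared flags or reference_group")
        X = ds.table.values.to_numpy()
        seed_idx = np.flatnonzero(seed_mask.to_numpy())
        other_idx = np.flatnonzero(~seed_mask.to_numpy())
        forest = IsolationForest(n_estimators=200, random_state=seed)
        forest.fit(X[seed_idx])
        score = forest.score_samples(X)  # higher = more normal
        seed_scores = score[seed_idx]
        cut = np.quantile(seed_scores, novelty_frac)
        # admission band = score range of the retained seed set, i.e. after
        # the most-anomalous novelty_frac tail has been expelled
        hi_band = seed_scores.max()
        result = {}
        ids = list(meta.index)
        for i in seed_idx:
            result[ids[i]] = bool(score[i] > cut)
        for i in other_idx:
            result[ids[i]] = bool(cut <= score[i] <= hi_band)
        scores = {ids[i]: float(-score[i]) for i in range(len(ids))}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_ref = sum(result.values())
    if n_ref < MIN_REFERENCE_SAMPLES:
        raise ValueError(
            f"only {n_ref} reference samples; trajectory fitting needs "
            f">= {MIN_REFERENCE_SAMPLES}"
        )
    return ReferenceAssignment(is_reference=result, mode=mode, novelty_scores=scores)
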