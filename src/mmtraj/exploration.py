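"""Dataset overview: sampling statistics, alpha diversity, embeddings,
embedding-outlier clusters and two-group differential feature analysis.

Alpha diversity uses natural logarithms (nats). The two-group test is a
two-sided Mann-Whitney U per feature with Benjamini-Hochberg q-values across
features: exact enumeration for small untied samples, normal approximation
with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureTable, MicrobiomeDataset


@dataclass
class SamplingSummary:
    """How densely subjects and time bins were sampled."""

    per_subject_counts: dict[str, int]
    per_timebin_counts: dict[str, int]
    time_bins: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": list(self.per_timebin_counts), "count": list(self.per_timebin_counts.values())}
        )


def sampling_statistics(
    ds: MicrobiomeDataset, n_bins: int = 10, binning: Literal["width", "quantile"] = "width"
) -> SamplingSummary:
    """Count samples per subject and per time bin.

    Bins are equal-width half-open ``[lo, hi)`` with the final bin closed on
    the right (quantile binning optional); counts conserve the sample total.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    meta = ds.meta
    per_subject = meta.groupby("subject_id").size().to_dict()
    t = meta["time"].to_numpy()
    if binning == "width":
        edges = np.linspace(t.min(), t.max(), n_bins + 1)
    else:
        edges = np.unique(np.quantile(t, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    bins = [(float(edges[i]), float(edges[i + 1])) for i in range(len(edges) - 1)]
    per_bin: dict[str, int] = {}
    for i, (lo, hi) in enumerate(bins):
        closer = "]" if i == len(bins) - 1 else ")"
        per_bin[f"[{lo:g}, {hi:g}{closer}"] = int(np.sum(idx == i))
    return SamplingSummary(
        per_subject_counts={str(k): int(v) for k, v in per_subject.items()},
        per_timebin_counts=per_bin,
        time_bins=bins,
    )


def alpha_diversity(
    table: FeatureTable, index: Literal["shannon", "simpson"] = "shannon"
) -> pd.Series:
    """Per-sample Shannon entropy (nats) or Gini-Simpson index.

    Counts are closed to proportions first; log-ratio tables are rejected
    because diversity is undefined on signed data.
    """
    if table.value_kind == "logratio":
        raise ValueError("diversity is undefined for log-ratio tables")
    arr = table.values.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total")
    p = arr / totals[:, None]
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=1)
    elif index == "simpson":
        vals = 1.0 - (p**2).sum(axis=1)
    else:
        raise ValueError(f"unknown index {index!r}")
    return pd.Series(vals, index=table.values.index.copy(), name=index)


def embed(
    ds: MicrobiomeDataset,
    method: Literal["pca", "tsne", "umap"] = "pca",
    n_dims: int = 2,
    seed: int = 42,
) -> pd.DataFrame:
    """Low-dimensional embedding of the samples, deterministic given seed.

    PCA coordinates are exact principal-component scores of the centered
    value matrix; t-SNE and UMAP are the usual nonlinear methods.
    """
    X = ds.table.values.to_numpy(dtype=float)
    if n_dims >= X.shape[1]:
        raise ValueError("n_dims must be smaller than the feature count")
    if method == "pca":
        coords = PCA(n_components=n_dims, random_state=seed).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
        coords = TSNE(
            n_components=n_dims, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(X)
    elif method == "umap":
        import umap

        coords = umap.UMAP(
            n_components=n_dims, random_state=seed, n_jobs=1
        ).fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        np.asarray(coords, dtype=float),
        index=ds.table.values.index.copy(),
        columns=[f"dim{i+1}" for i in range(n_dims)],
    )


def two_group_feature_test(
    ds: MicrobiomeDataset, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-feature Mann-Whitney U between two groups, BH-corrected.

    Returns a tidy frame with statistic, p_value, q_value and direction
    (sign of median(group_a) - median(group_b)) per feature.
    """
    meta = ds.meta
    labels = set(meta["group"])
    for g in (group_a, group_b):
        if g not in labels:
            raise ValueError(f"group {g!r} not found; available: {sorted(labels)}")
    a_ids = meta.index[meta["group"] == group_a]
    b_ids = meta.index[meta["group"] == group_b]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("both groups need >= 3 samples")
    A = ds.table.values.loc[a_ids].to_numpy(dtype=float)
    B = ds.table.values.loc[b_ids].to_numpy(dtype=float)
    m = A.shape[1]
    stat = np.empty(m)
    pvals = np.empty(m)
    # exact enumeration where feasible (small untied samples), normal
    # approximation with tie correction otherwise -- decided per feature,
    # since a tie in one feature must not degrade the others
    pooled_small = max(len(a_ids), len(b_ids)) <= 8
    has_ties = np.array(
        [np.unique(np.concatenate([A[:, j], B[:, j]])).size < len(a_ids) + len(b_ids)
         for j in range(m)]
    )
    exact_cols = np.flatnonzero(~has_ties) if pooled_small else np.array([], dtype=int)
    asym_cols = np.setdiff1d(np.arange(m), exact_cols)
    for exact, cols in ((True, exact_cols), (False, asym_cols)):
        if cols.size == 0:
            continue
        res = stats.mannwhitneyu(
            A[:, cols], B[:, cols], axis=0, alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        stat[cols] = np.atleast_1d(res.statistic)
        pvals[cols] = np.minimum(np.atleast_1d(res.pvalue), 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    direction = np.sign(np.median(A, axis=0) - np.median(B, axis=0))
    return pd.DataFrame(
        {
            "feature_id": [str(f) for f in ds.table.feature_ids],
            "statistic": stat,
            "p_value": pvals,
            "q_value": qvals,
            "direction": direction,
        }
    ).sort_values("q_value", kind="stable").reset_index(drop=True)


def embedding_outlier_clusters(
    embedding: pd.DataFrame,
    ds: MicrobiomeDataset,
    min_cluster_frac: float = 0.2,
    min_samples: int = 5,
    eps: float | None = None,
) -> tuple[pd.Series, dict[int, pd.DataFrame]]:
    """Find small off-main clusters in an embedding and what distinguishes them.

    DBSCAN (eps from the k-distance heuristic unless given) partitions the
    embedding; clusters holding less than ``min_cluster_frac`` of the
    samples are outlier clusters, and each is contrasted against the rest
    with the two-group feature test.

    Returns the per-sample cluster labels (-1 = noise) and, per outlier
    cluster, the differential-feature table.
    """
    if not (0.0 < min_cluster_frac < 0.5):
        raise ValueError("min_cluster_frac must be in (0, 0.5)")
    if embedding.shape[0] != ds.n_samples:
        raise ValueError("embedding rows must match dataset samples")
    X = embedding.to_numpy(dtype=float)
    if eps is None:
        # k-distance heuristic, padded so that small tight clusters still
        # form while well-separated groups stay apart
        k = min(min_samples, X.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        dists, _ = nn.kneighbors(X)
        kd = dists[:, -1]
        eps = float(max(2.0 * np.median(kd), 1.5 * np.quantile(kd, 0.95)))
        eps = eps or 1e-6
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
    labels = pd.Series(labels, index=embedding.index.copy(), name="cluster")
    n = len(labels)
    results: dict[int, pd.DataFrame] = {}
    for c in sorted(set(labels) - {-1}):
        frac = (labels == c).sum() / n
        if frac >= min_cluster_frac:
            continue
        in_ids = labels.index[labels == c]
        tmp_meta = ds.meta.copy()
        tag = pd.Series(
            np.where(tmp_meta.index.isin(in_ids), "cluster", "rest"),
            index=tmp_meta.index,
        )
        tagged = _with_groups(ds, tag)
        try:
            results[int(c)] = two_group_feature_test(tagged, "cluster", "rest")
        except ValueError:
            continue  # cluster too small for the test
    return labels, results


def _with_groups(ds: MicrobiomeDataset, groups: pd.Series) -> MicrobiomeDataset:
    from dataclasses import replace

    meta = [replace(m, group=str(groups[m.sample_id])) for m in ds.metadata]
    return MicrobiomeDataset(table=ds.table, metadata=meta, time_unit=ds.time_unit)
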