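"""Model-space intervention simulation.

For an outlier sample, candidate features (chosen explicitly or as the
sample's top Shapley contributors) are reset to the time-local reference
median -- the typical value among reference samples observed near the same
time -- and the MMI is recomputed. If the corrected sample falls back inside
the prediction band, those features are a plausible handle for a real-world
intervention. This is strictly a what-if on the fitted model; no causal or
nutritional claim is implied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomaly import AnomalyReport
from .core_io import MicrobiomeDataset
from .trajectory import (
    TrajectoryModel,
    attribute_values,
    feature_importance_over_time,
    predict_mmi,
)

DEFAULT_K_MAX = 10


@dataclass
class InterventionResult:
    """Outcome of resetting selected features of one sample."""

    sample_id: str
    features_changed: dict[str, tuple[float, float]]  # feature -> (old, new)
    mmi_before: float
    mmi_after: float
    residual_before: float
    residual_after: float
    returned_to_interval: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": self.sample_id, "feature_id": f, "old": o, "new": n}
            for f, (o, n) in self.features_changed.items()
        ]
        return pd.DataFrame(rows, columns=["sample_id", "feature_id", "old", "new"])

    def describe(self) -> str:
        """Human-readable summary of the simulated intervention."""
        lines = [
            f"Intervention on sample {self.sample_id}:",
            f"  MMI {self.mmi_before:+.4f} -> {self.mmi_after:+.4f} "
            f"(residual {self.residual_before:+.4f} -> {self.residual_after:+.4f})",
            "  returned to prediction interval: "
            + ("yes" if self.returned_to_interval else "no"),
        ]
        if self.features_changed:
            lines.append("  features reset to time-local reference medians:")
            for f, (old, new) in self.features_changed.items():
                lines.append(f"    {f}: {old:+.4f} -> {new:+.4f}")
        else:
            lines.append("  no features changed (no-op)")
        return "\n".join(lines)


def timeblock_importance(
    model: TrajectoryModel,
    ds: MicrobiomeDataset,
    block_edges: list[float],
    **kwargs,
) -> dict[str, list[str]]:
    """Ranked feature lists per user-defined time block.

    Blocks are the half-open intervals between consecutive edges; empty
    blocks are skipped with a warning. Ties in mean absolute attribution
    break by feature id.
    """
    if len(block_edges) < 2 or any(
        nxt <= prev for prev, nxt in zip(block_edges[:-1], block_edges[1:])
    ):
        raise ValueError("block_edges must be strictly increasing with >= 2 entries")
    windows = list(zip(block_edges[:-1], block_edges[1:]))
    imp = feature_importance_over_time(model, ds, windows, **kwargs)
    out: dict[str, list[str]] = {}
    for label, row in imp.iterrows():
        if row.isna().all():
            warnings.warn(f"time block {label} is empty; skipped")
            continue
        ranked = sorted(row.index, key=lambda f: (-row[f], f))
        out[label] = list(ranked)
    return out


def reference_profile(
    ds: MicrobiomeDataset, time: float, bandwidth: float
) -> dict[str, tuple[float, float]]:
    """Median and IQR of each feature among reference samples near ``time``.

    Needs at least 5 reference samples within ``time +/- bandwidth``; the
    bandwidth doubles up to three times before giving up.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    ref = ds.reference_subset() if any(m.is_reference for m in ds.metadata) else ds
    times = ref.meta["time"].to_numpy()
    bw = bandwidth
    for _ in range(4):
        mask = np.abs(times - time) <= bw
        if mask.sum() >= 5:
            break
        bw *= 2
    else:
        raise ValueError(
            f"fewer than 5 reference samples within {bandwidth * 8:g} of t={time:g}"
        )
    if mask.sum() < 5:
        raise ValueError(f"fewer than 5 reference samples near t={time:g}")
    sub = ref.table.values.iloc[mask]
    med = sub.median(axis=0)
    iqr = sub.quantile(0.75, axis=0) - sub.quantile(0.25, axis=0)
    return {str(f): (float(med[f]), float(iqr[f])) for f in sub.columns}


def _default_bandwidth(ds: MicrobiomeDataset) -> float:
    t = ds.meta["time"]
    return float((t.max() - t.min()) / 10.0) or 1.0


def simulate_intervention(
    model: TrajectoryModel,
    ds: MicrobiomeDataset,
    sample_id: str,
    features: list[str] | None = None,
    top_k: int | None = None,
    bandwidth: float | None = None,
    k_max: int = DEFAULT_K_MAX,
    level: float | None = None,
) -> InterventionResult:
    """Reset selected features of one sample to reference medians, re-predict.

    Either an explicit feature list or ``top_k`` must be given. In top-k
    mode the sample's features are ranked by absolute Shapley attribution
    and k escalates greedily (1, 2, ...) until the sample returns inside
    the prediction band, up to ``min(top_k, k_max)``; the smallest
    sufficient k wins, otherwise the best-effort largest k is reported.
    Features not selected stay bit-identical.
    """
    if sample_id not in set(ds.table.sample_ids):
        raise KeyError(f"unknown sample {sample_id!r}")
    if (features is None) == (top_k is None):
        raise ValueError("give exactly one of features= or top_k=")
    bandwidth = bandwidth if bandwidth is not None else _default_bandwidth(ds)

    meta = ds.meta
    t = float(meta.loc[sample_id, "time"])
    base = predict_mmi(model, ds, interval="prediction", level=level)
    before = base.frame.loc[sample_id]
    profile = reference_profile(ds, t, bandwidth)

    row = ds.table.values.loc[[sample_id]][model.feature_ids_used]

    def apply(feats: list[str]) -> tuple[float, float, bool, dict]:
        mod = row.copy()
        changed = {}
        for f in feats:
            old = float(mod.iloc[0][f])
            new = profile[f][0]
            mod.iloc[0, mod.columns.get_loc(f)] = new
            changed[f] = (old, new)
        if feats:
            mmi_after = float(model.predict(mod.to_numpy())[0])
        else:
            mmi_after = float(before["mmi"])  # strict no-op
        resid_after = mmi_after - float(model.curve(t))
        hw = float(model.curve.half_width(t, "prediction", level))
        return mmi_after, resid_after, abs(resid_after) <= hw + 1e-12, changed

    if features is not None:
        unknown = [f for f in features if f not in set(model.feature_ids_used)]
        if unknown:
            raise KeyError(f"feature(s) not in model: {unknown}")
        mmi_after, resid_after, inside, changed = apply(list(features))
    else:
        phi = attribute_values(model, ds.table.values.loc[[sample_id]])
        ranked = sorted(phi.columns, key=lambda f: (-abs(phi.iloc[0][f]), f))
        kmax = min(top_k, k_max, len(ranked))
        best = None
        for k in range(1, kmax + 1):
            result = apply(ranked[:k])
            if best is None or abs(result[1]) < abs(best[1]):
                best = result
            if result[2]:
                best = result
                break
        mmi_after, resid_after, inside, changed = best

    return InterventionResult(
        sample_id=sample_id,
        features_changed=changed,
        mmi_before=float(before["mmi"]),
        mmi_after=mmi_after,
        residual_before=float(before["residual"]),
        residual_after=resid_after,
        returned_to_interval=bool(inside),
    )


def shared_outlier_features(
    ds: MicrobiomeDataset,
    report: AnomalyReport,
    model: TrajectoryModel,
    top_k: int = 5,
    seed: int = 42,
) -> pd.DataFrame:
    """How often each feature drives the detected outliers, vs non-outliers.

    Each outlier contributes its ``top_k`` features by absolute Shapley
    attribution; the table reports the fraction of outliers naming each
    feature, alongside the same fraction over an equal-size seeded draw of
    non-outliers (the contrast column).
    """
    out_ids = report.outlier_ids
    if len(out_ids) < 2:
        raise ValueError("need >= 2 outliers")
    all_ids = list(ds.table.sample_ids)
    non_ids = [s for s in all_ids if s not in set(out_ids)]
    rng = np.random.default_rng(seed)
    n_draw = min(len(out_ids), len(non_ids))
    contrast_ids = list(np.array(non_ids)[rng.choice(len(non_ids), n_draw, replace=False)])

    def freq(ids: list[str]) -> pd.Series:
        phi = attribute_values(model, ds.table.values.loc[ids])
        counts = pd.Series(0.0, index=phi.columns)
        for _, row in phi.iterrows():
            top = sorted(row.index, key=lambda f: (-abs(row[f]), f))[:top_k]
            counts[top] += 1
        return counts / len(ids)

    f_out = freq(out_ids)
    f_non = freq(contrast_ids) if contrast_ids else pd.Series(0.0, index=f_out.index)
    out = pd.DataFrame(
        {"outlier_frequency": f_out, "non_outlier_frequency": f_non}
    ).sort_values(["outlier_frequency"], ascending=False)
    out = out[(out["outlier_frequency"] > 0) | (out["non_outlier_frequency"] > 0)]
    out.index.name = "feature_id"
    return out


def intervene_outliers(
    model: TrajectoryModel,
    ds: MicrobiomeDataset,
    report: AnomalyReport,
    top_k: int = DEFAULT_K_MAX,
    bandwidth: float | None = None,
) -> list[InterventionResult]:
    """Run top-k interventions for every detected outlier."""
    return [
        simulate_intervention(model, ds, sid, top_k=top_k, bandwidth=bandwidth)
        for sid in report.outlier_ids
    ]
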