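"""Seeded generator of longitudinal microbiome-like datasets with ground truth.

The generative model is a log-normal composition: each informative feature's
log-abundance drifts linearly in time (alternating signs, so both blooming
and declining taxa exist), non-informative features are stationary noise, and
the exponentiated vector is closed to relative abundances. Subjects are
sampled at equally spaced times with a small jitter, mimicking the repeated
stool-sampling designs of longitudinal cohorts (e.g. mice followed across a
diet switch). A second study arm can be simulated as a maturation offset:
its informative means are evaluated at ``t + group_shift``, so its samples
look like reference samples of a different age.

Everything is deterministic given the spec seed, which makes the generator
usable as a fixture factory for every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import FeatureTable, MicrobiomeDataset, SampleMetadata

_CLOSURE_TOL = 1e-12


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic longitudinal study.

    ``effect_size`` is the per-unit-time slope of informative features'
    mean log-abundance (nats per time unit); ``noise_sd`` the log-scale
    observation noise; ``group_shift`` a maturation-time offset for the
    second arm; ``anomaly_magnitude`` is measured in units of ``noise_sd``.
    Time runs over ``time_range`` in normalized study-duration units.
    """

    n_subjects: int = 40
    samples_per_subject: int = 8
    n_features: int = 30
    n_informative: int = 5
    time_range: tuple[float, float] = (0.0, 1.0)
    effect_size: float = 1.0
    noise_sd: float = 0.3
    group_shift: float = 0.0
    anomaly_frac: float = 0.0
    anomaly_magnitude: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if min(self.n_subjects, self.samples_per_subject, self.n_features) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.anomaly_frac < 0.5):
            raise ValueError("anomaly_frac must be in [0, 0.5)")
        if self.time_range[1] <= self.time_range[0]:
            raise ValueError("time_range must be increasing")


@dataclass
class GroundTruth:
    """What the generator planted: signals, true times, arms, anomalies."""

    informative_feature_ids: list[str]
    true_time: dict[str, float]
    group: dict[str, str]
    anomaly_sample_ids: list[str] = field(default_factory=list)
    anomaly_features: dict[str, str] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)


def generate(spec: SyntheticSpec) -> tuple[MicrobiomeDataset, GroundTruth]:
    """Generate a longitudinal compositional dataset with known signal.

    Returns the dataset (relative abundances) and the planted ground truth.
    When ``group_shift`` is nonzero, the second half of subjects form group
    ``"shifted"``; otherwise every sample is in group ``"reference"``. All
    samples carry ``is_reference=True`` for the reference arm and ``False``
    for the shifted arm.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.time_range
    n_total = spec.n_subjects * spec.samples_per_subject

    feature_ids = [f"taxon_{j:03d}" for j in range(spec.n_features)]
    # alternating signs guarantee both increasing and decreasing taxa
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(spec.n_informative)])
    slopes = np.zeros(spec.n_features)
    slopes[: spec.n_informative] = signs * spec.effect_size

    two_arms = spec.group_shift != 0.0
    n_shifted = spec.n_subjects // 2 if two_arms else 0

    rows = []
    meta: list[SampleMetadata] = []
    truth = GroundTruth(
        informative_feature_ids=feature_ids[: spec.n_informative],
        true_time={},
        group={},
        slopes={fid: float(s) for fid, s in zip(feature_ids, slopes)},
    )
    if spec.samples_per_subject > 1:
        base_times = np.linspace(lo, hi, spec.samples_per_subject)
        spacing = base_times[1] - base_times[0]
    else:
        base_times = np.array([(lo + hi) / 2.0])
        spacing = hi - lo
    for s in range(spec.n_subjects):
        subj = f"subject_{s:03d}"
        shifted = two_arms and s >= spec.n_subjects - n_shifted
        group = "shifted" if shifted else "reference"
        jitter = rng.uniform(-0.05, 0.05, size=spec.samples_per_subject) * spacing
        times = np.clip(base_times + jitter, lo, hi)
        for k, t in enumerate(times):
            t_eff = t + (spec.group_shift if shifted else 0.0)
            mean_log = slopes * t_eff
            logab = rng.normal(mean_log, spec.noise_sd)
            abundance = np.exp(logab)
            rows.append(abundance / abundance.sum())
            sid = f"{subj}_t{k:02d}"
            meta.append(
                SampleMetadata(
                    sample_id=sid,
                    subject_id=subj,
                    time=float(t),
                    group=group,
                    is_reference=not shifted,
                )
            )
            truth.true_time[sid] = float(t)
            truth.group[sid] = group

    values = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index([m.sample_id for m in meta], name="sample_id"),
        columns=feature_ids,
    )
    table = FeatureTable(values=values, value_kind="relative")
    ds = MicrobiomeDataset(table=table, metadata=meta, time_unit="study")
    assert n_total == ds.n_samples
    if spec.anomaly_frac > 0:
        ds, truth = inject_anomalies(ds, truth, spec)
    return ds, truth


def inject_anomalies(
    ds: MicrobiomeDataset, truth: GroundTruth, spec: SyntheticSpec
) -> tuple[MicrobiomeDataset, GroundTruth]:
    """Shift one informative feature's log-abundance in a random sample subset.

    The shift is ``anomaly_magnitude * noise_sd`` on the log scale (a
    multiplicative bump), applied before re-closure, so the perturbed sample
    remains a valid composition. Ground truth records which samples and which
    feature were hit.
    """
    if spec.anomaly_frac <= 0:
        raise ValueError("anomaly_frac must be > 0 to inject anomalies")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = ds.n_samples
    n_anom = int(round(spec.anomaly_frac * n))
    all_ids = list(ds.table.sample_ids)
    chosen = sorted(rng.choice(n, size=n_anom, replace=False).tolist())
    values = ds.table.values.copy()
    informative = truth.informative_feature_ids or list(values.columns[:1])
    new_truth = replace_truth(truth)
    for idx in chosen:
        sid = all_ids[idx]
        fid = informative[int(rng.integers(len(informative)))]
        row = values.loc[sid].to_numpy(dtype=float)
        j = values.columns.get_loc(fid)
        row[j] *= np.exp(spec.anomaly_magnitude * spec.noise_sd)
        values.loc[sid] = row / row.sum()
        new_truth.anomaly_sample_ids.append(sid)
        new_truth.anomaly_features[sid] = fid
    table = FeatureTable(values=values, value_kind="relative")
    out = MicrobiomeDataset(table=table, metadata=ds.metadata, time_unit=ds.time_unit)
    return out, new_truth


def replace_truth(truth: GroundTruth) -> GroundTruth:
    return GroundTruth(
        informative_feature_ids=list(truth.informative_feature_ids),
        true_time=dict(truth.true_time),
        group=dict(truth.group),
        anomaly_sample_ids=list(truth.anomaly_sample_ids),
        anomaly_features=dict(truth.anomaly_features),
        slopes=dict(truth.slopes),
    )
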