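"""Data model for longitudinal microbiome datasets and table/metadata I/O.

The central containers are :class:`FeatureTable` (samples x features abundance
matrix), :class:`SampleMetadata` (one record per sample: subject, time, group,
optional reference flag) and :class:`MicrobiomeDataset`, which ties the two
together and guarantees that their sample-id sets agree.

Supported on-disk formats: CSV/TSV (canonical; first column holds ids, header
row required) and BIOM v2.1 (HDF5) for feature tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ValueKind = Literal["counts", "relative", "logratio"]
Orientation = Literal["samples_as_rows", "features_as_rows"]

_REL_ROWSUM_TOL = 1e-9
_REL_INFER_TOL = 1e-6


class DataValidationError(ValueError):
    """A table or metadata file violates the data-model invariants."""


@dataclass
class FeatureTable:
    """Samples x features abundance matrix.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
        Non-negative for ``counts``/``relative``; unrestricted for
        ``logratio``.
    value_kind
        ``counts`` (raw counts), ``relative`` (rows sum to 1) or
        ``logratio`` (signed, produced by the log-ratio transform).
    """

    values: pd.DataFrame
    value_kind: ValueKind = "counts"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.size == 0:
            raise DataValidationError("feature table is empty")
        dup_s = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_s:
            raise DataValidationError(f"duplicate sample ids: {dup_s}")
        dup_f = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_f:
            raise DataValidationError(f"duplicate feature ids: {dup_f}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise DataValidationError(
                f"non-finite value at sample {self.values.index[i]!r}, "
                f"feature {self.values.columns[j]!r}"
            )
        if self.value_kind in ("counts", "relative") and np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative value at sample {self.values.index[i]!r}, "
                f"feature {self.values.columns[j]!r}"
            )
        if self.value_kind == "relative":
            sums = arr.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_ROWSUM_TOL
            if np.any(bad):
                sid = self.values.index[int(np.argmax(bad))]
                raise DataValidationError(
                    f"relative-abundance row for sample {sid!r} sums to "
                    f"{sums[np.argmax(bad)]:.12g}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, value_kind: ValueKind) -> "FeatureTable":
        return FeatureTable(values=values, value_kind=value_kind)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        df = self.values.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep=sep)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study metadata: who, when, which arm."""

    sample_id: str
    subject_id: str
    time: float
    group: str = "all"
    is_reference: bool | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise DataValidationError(
                f"sample {self.sample_id!r}: time must be finite and >= 0, got {self.time}"
            )


@dataclass
class MicrobiomeDataset:
    """A feature table plus aligned per-sample metadata."""

    table: FeatureTable
    metadata: list[SampleMetadata]
    time_unit: str = ""

    def __post_init__(self) -> None:
        meta_ids = [m.sample_id for m in self.metadata]
        if len(set(meta_ids)) != len(meta_ids):
            raise DataValidationError("duplicate sample ids in metadata")
        if set(meta_ids) != set(self.table.sample_ids):
            missing = set(self.table.sample_ids) ^ set(meta_ids)
            raise DataValidationError(
                f"table/metadata sample-id mismatch: {sorted(missing)[:5]} ..."
            )
        # keep metadata in table order
        order = {s: i for i, s in enumerate(self.table.sample_ids)}
        self.metadata = sorted(self.metadata, key=lambda m: order[m.sample_id])
        times = {m.time for m in self.metadata}
        subjects = {m.subject_id for m in self.metadata}
        if len(times) < 2:
            raise DataValidationError("dataset needs at least 2 distinct time points")
        if len(subjects) < 2:
            raise DataValidationError("dataset needs at least 2 subjects")

    @property
    def meta(self) -> pd.DataFrame:
        """Metadata as a DataFrame indexed by sample_id, in table order."""
        return pd.DataFrame(
            {
                "subject_id": [m.subject_id for m in self.metadata],
                "time": [m.time for m in self.metadata],
                "group": [m.group for m in self.metadata],
                "is_reference": [m.is_reference for m in self.metadata],
            },
            index=pd.Index([m.sample_id for m in self.metadata], name="sample_id"),
        )

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    def subset(self, sample_ids: Sequence[str]) -> "MicrobiomeDataset":
        """Restrict the dataset to the given samples (table order preserved)."""
        keep = [s for s in self.table.sample_ids if s in set(sample_ids)]
        table = FeatureTable(self.table.values.loc[keep], self.table.value_kind)
        meta = [m for m in self.metadata if m.sample_id in set(keep)]
        return MicrobiomeDataset(table=table, metadata=meta, time_unit=self.time_unit)

    def reference_subset(self) -> "MicrobiomeDataset":
        ids = [m.sample_id for m in self.metadata if m.is_reference]
        return self.subset(ids)

    def with_reference_flags(self, flags: dict[str, bool]) -> "MicrobiomeDataset":
        meta = [replace(m, is_reference=flags.get(m.sample_id, m.is_reference))
                for m in self.metadata]
        return MicrobiomeDataset(table=self.table, metadata=meta, time_unit=self.time_unit)


def _infer_value_kind(df: pd.DataFrame) -> ValueKind:
    arr = df.to_numpy(dtype=float)
    if np.allclose(arr, np.round(arr), rtol=0, atol=0):
        return "counts"
    if np.allclose(arr.sum(axis=1), 1.0, rtol=0, atol=_REL_INFER_TOL):
        return "relative"
    return "counts"


def load_feature_table(
    path: str | Path,
    fmt: Literal["csv", "tsv", "biom"] = "csv",
    orientation: Orientation = "samples_as_rows",
    value_kind: ValueKind | None = None,
) -> FeatureTable:
    """Read a feature-abundance table.

    The returned table is always in samples-as-rows orientation. ``value_kind``
    is inferred (integers -> counts; rows summing to 1 within 1e-6 ->
    relative; otherwise counts) unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dup_cols = sorted({c for c in header if header.count(c) > 1})
        if dup_cols:
            raise DataValidationError(
                f"duplicate feature or sample ids in header of {path.name}: {dup_cols}"
            )
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise DataValidationError(f"non-numeric columns: {bad}")
    elif fmt == "biom":
        from ._biom import read_biom

        # BIOM always stores observations (features) x samples; the
        # orientation argument does not apply.
        df = read_biom(path)
        orientation = "features_as_rows"
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if orientation == "features_as_rows":
        df = df.T
    df = df.astype(float)
    df.index.name = "sample_id"
    df.columns.name = None
    kind = value_kind if value_kind is not None else _infer_value_kind(df)
    return FeatureTable(values=df, value_kind=kind)


def load_metadata(path: str | Path, sep: str | None = None) -> list[SampleMetadata]:
    """Read per-sample metadata from CSV/TSV.

    Required columns: sample_id, subject_id, time. Optional: group (defaults
    to ``"all"``) and is_reference (left unset when absent; resolved later by
    the reference-definition step).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "time"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"metadata missing columns: {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise DataValidationError(f"duplicated sample_id in metadata: {dup}")
    records: list[SampleMetadata] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            t = float(d["time"])
        except (TypeError, ValueError):
            raise DataValidationError(
                f"metadata row {row_no}: non-numeric time {d['time']!r}"
            ) from None
        if not math.isfinite(t) or t < 0:
            raise DataValidationError(f"metadata row {row_no}: invalid time {t}")
        ref = d.get("is_reference")
        if ref is not None and not isinstance(ref, bool):
            if pd.isna(ref):
                ref = None
            else:
                ref = str(ref).strip().lower() in ("1", "true", "yes", "t")
        group = d.get("group")
        group = "all" if group is None or pd.isna(group) else str(group)
        records.append(
            SampleMetadata(
                sample_id=str(d["sample_id"]),
                subject_id=str(d["subject_id"]),
                time=t,
                group=group,
                is_reference=ref,
            )
        )
    return records


def save_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "subject_id": [m.subject_id for m in metadata],
            "time": [m.time for m in metadata],
            "group": [m.group for m in metadata],
            "is_reference": [m.is_reference for m in metadata],
        }
    ).to_csv(path, index=False)


def assemble_dataset(
    table: FeatureTable,
    metadata: Sequence[SampleMetadata],
    time_unit: str = "",
) -> MicrobiomeDataset:
    """Join a feature table with metadata on sample id.

    Samples present in only one input are dropped with a logged warning
    (orphan records are common in longitudinal studies); zero overlap is an
    error.
    """
    table_ids = set(table.sample_ids)
    meta_ids = {m.sample_id for m in metadata}
    common = table_ids & meta_ids
    if not common:
        raise DataValidationError("no overlapping samples between table and metadata")
    dropped = len(table_ids ^ meta_ids)
    if dropped:
        logger.warning("%d sample(s) dropped during dataset assembly", dropped)
    keep = [s for s in table.sample_ids if s in common]
    sub = FeatureTable(table.values.loc[keep], table.value_kind)
    meta = [m for m in metadata if m.sample_id in common]
    return MicrobiomeDataset(table=sub, metadata=meta, time_unit=time_unit)
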