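"""Minimal BIOM v2.1 (HDF5) reader/writer built on h5py and scipy.sparse.

Only the pieces of the format the toolbox needs: dense retrieval of the
observation x sample matrix with its id lists, and writing a spec-conformant
file (both CSR groups populated) so round-trips can be tested. Metadata
payloads beyond ids are ignored on read and written empty.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

_FORMAT_URL = "http://biom-format.org"


def read_biom(path: str | Path) -> pd.DataFrame:
    """Return the table as a DataFrame with observations (features) as rows."""
    with h5py.File(path, "r") as f:
        obs_ids = [_decode(x) for x in f["observation/ids"][:]]
        sample_ids = [_decode(x) for x in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    return pd.DataFrame(mat.toarray(), index=obs_ids, columns=sample_ids)


def write_biom(df: pd.DataFrame, path: str | Path, generated_by: str = "mmtraj") -> None:
    """Write an observations-x-samples DataFrame as BIOM v2.1."""
    obs_ids = np.array([str(i) for i in df.index], dtype=object)
    sample_ids = np.array([str(c) for c in df.columns], dtype=object)
    dense = df.to_numpy(dtype=float)
    csr = sparse.csr_matrix(dense)
    csc = sparse.csc_matrix(dense)
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = _FORMAT_URL
        f.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        f.attrs["generated-by"] = generated_by
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = np.array(dense.shape, dtype=np.int64)
        f.attrs["nnz"] = int(csr.nnz)
        strdt = h5py.string_dtype()
        f.create_dataset("observation/ids", data=obs_ids, dtype=strdt)
        f.create_dataset("sample/ids", data=sample_ids, dtype=strdt)
        for name, m in (("observation", csr), ("sample", csc)):
            g = f.create_group(f"{name}/matrix")
            g.create_dataset("data", data=m.data.astype(np.float64))
            g.create_dataset("indices", data=m.indices.astype(np.int32))
            g.create_dataset("indptr", data=m.indptr.astype(np.int32))
        for name in ("observation", "sample"):
            f.create_group(f"{name}/metadata")
            f.create_group(f"{name}/group-metadata")


def _decode(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)
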