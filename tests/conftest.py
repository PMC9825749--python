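import numpy as np
import pandas as pd
import pytest

from mmtraj.core_io import FeatureTable, MicrobiomeDataset, SampleMetadata
from mmtraj.synthetic import SyntheticSpec, generate
from mmtraj.transform import log_ratio_transform, select_denominator
from mmtraj.trajectory import fit_mmi_model


@pytest.fixture(scope="session")
def small_study():
    """Compact longitudinal study with 3 planted informative taxa."""
    spec = SyntheticSpec(
        seed=11, n_subjects=12, samples_per_subject=5, n_features=12, n_informative=3
    )
    return generate(spec)


@pytest.fixture(scope="session")
def fitted_pipeline():
    """Default study run through denominator selection, ALR and MMI fitting."""
    ds, truth = generate(SyntheticSpec(seed=7))
    report = select_denominator(ds, strategy="performance", model_spec="ridge", seed=7)
    lr = log_ratio_transform(ds.table, report.feature_id, pseudocount=0)
    lds = MicrobiomeDataset(table=lr, metadata=ds.metadata, time_unit=ds.time_unit)
    model = fit_mmi_model(lds, regressor_name="ridge", seed=7, level=0.95)
    return ds, lds, model, truth, report


def toy_dataset(values, times=None, groups=None, subjects=None, value_kind="counts"):
    """Hand-rolled tiny dataset builder for unit tests."""
    values = pd.DataFrame(values)
    n = len(values)
    values.index = [f"s{i}" for i in range(n)]
    values.columns = [f"f{j}" for j in range(values.shape[1])]
    times = times if times is not None else [float(i) for i in range(n)]
    subjects = subjects if subjects is not None else [f"subj{i % 2}" for i in range(n)]
    groups = groups if groups is not None else ["all"] * n
    meta = [
        SampleMetadata(f"s{i}", subjects[i], float(times[i]), group=groups[i])
        for i in range(n)
    ]
    return MicrobiomeDataset(
        table=FeatureTable(values, value_kind), metadata=meta, time_unit="d"
    )
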