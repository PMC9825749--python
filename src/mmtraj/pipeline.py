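"""The a-to-e analysis pipeline: explore, prepare, fit, detect, intervene.

Each stage writes tidy CSV/JSON artifacts into the output directory; any
stage can be skipped through the config, and a stage failure aborts the run
with a stage-named error. CSV outputs carry no timestamps so identical
config + seed reruns are byte-identical (timestamps live only in the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anomaly as anomaly_mod
from . import exploration, intervention, transform
from . import trajectory as traj_mod
from .config import save_config
from .core_io import MicrobiomeDataset, assemble_dataset, load_feature_table, load_metadata, save_metadata
from .synthetic import SyntheticSpec, generate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def load_input_dataset(cfg: dict) -> MicrobiomeDataset:
    inp = cfg["input"]
    if not inp["table"] or not inp["metadata"]:
        raise ValueError("config input.table and input.metadata are required")
    table = load_feature_table(inp["table"], fmt=inp["format"], orientation=inp["orientation"])
    meta = load_metadata(inp["metadata"])
    return assemble_dataset(table, meta, time_unit=inp["time_unit"])


def synthetic_dataset(cfg: dict) -> MicrobiomeDataset:
    s = cfg["synthetic"]
    spec = SyntheticSpec(seed=int(cfg["seed"]), **s)
    ds, _ = generate(spec)
    return ds


def run_pipeline(cfg: dict, ds: MicrobiomeDataset | None = None) -> Path:
    """Execute the configured stages; returns the output directory."""
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mmtraj")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        save_config(cfg, outdir / "config.resolved.yaml")
        seed = int(cfg["seed"])
        if ds is None:
            ds = load_input_dataset(cfg)
        ds.table.to_csv(outdir / "dataset_table.csv")
        save_metadata(ds.metadata, outdir / "dataset_metadata.csv")
        stages = cfg["stages"]

        if stages["explore"]:
            _stage_explore(cfg, ds, outdir, seed)
        model = None
        lr_ds = ds
        if stages["transform"]:
            lr_ds = _stage_transform(cfg, ds, outdir, seed)
        if stages["trajectory"]:
            model = _stage_trajectory(cfg, lr_ds, outdir, seed)
        reports = {}
        if stages["anomaly"]:
            if model is None:
                raise StageError("anomaly", ValueError("trajectory stage is required"))
            reports = _stage_anomaly(cfg, lr_ds, model, outdir, seed)
        if stages["intervene"]:
            if model is None or "interval" not in reports:
                raise StageError("intervene", ValueError("anomaly stage is required"))
            _stage_intervene(cfg, lr_ds, model, reports["interval"], outdir)
        logger.info("pipeline finished: %s", outdir)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage_explore(cfg, ds, outdir: Path, seed: int) -> None:
    try:
        ecfg = cfg["exploration"]
        summary = exploration.sampling_statistics(ds, n_bins=ecfg["n_bins"])
        pd.Series(summary.per_subject_counts, name="n_samples").rename_axis(
            "subject_id"
        ).to_csv(outdir / "sampling_per_subject.csv")
        pd.Series(summary.per_timebin_counts, name="n_samples").rename_axis(
            "time_bin"
        ).to_csv(outdir / "sampling_per_timebin.csv")
        div = exploration.alpha_diversity(ds.table, index=ecfg["diversity_index"])
        div.rename_axis("sample_id").to_csv(outdir / "alpha_diversity.csv")
        emb = exploration.embed(ds, method=ecfg["embedding"], n_dims=2, seed=seed)
        emb.rename_axis("sample_id").to_csv(outdir / "embedding.csv")
        labels, cluster_tests = exploration.embedding_outlier_clusters(emb, ds)
        labels.rename_axis("sample_id").to_csv(outdir / "embedding_clusters.csv")
        for c, res in cluster_tests.items():
            res.to_csv(outdir / f"outlier_cluster_{c}_features.csv", index=False)
    except StageError:
        raise
    except Exception as err:
        raise StageError("explore", err) from err


def _stage_transform(cfg, ds, outdir: Path, seed: int) -> MicrobiomeDataset:
    try:
        tcfg = cfg["transform"]
        table = ds.table
        if table.value_kind == "counts":
            table = transform.to_relative_abundance(table)
        table, log = transform.filter_features(
            table,
            variance_quantile=tcfg["variance_quantile"],
            correlation_threshold=tcfg["correlation_threshold"],
        )
        log.to_frame().to_csv(outdir / "feature_removal_log.csv", index=False)
        filtered = MicrobiomeDataset(table=table, metadata=ds.metadata, time_unit=ds.time_unit)
        report = transform.select_denominator(
            filtered,
            strategy=tcfg["denominator_strategy"],
            model_spec=tcfg["model_spec"],
            n_bins=tcfg["n_bins"],
            pseudocount=tcfg["pseudocount"],
            seed=seed,
        )
        report.to_frame().to_csv(outdir / "denominator_report.csv")
        lr = transform.log_ratio_transform(
            table, report.feature_id, pseudocount=tcfg["pseudocount"]
        )
        lr_ds = MicrobiomeDataset(table=lr, metadata=ds.metadata, time_unit=ds.time_unit)
        mode = tcfg["reference_mode"]
        flags = [m.is_reference for m in ds.metadata]
        if mode == "declared" and not any(f is True for f in flags):
            logger.info("no declared reference flags; treating all samples as reference")
        else:
            assign = transform.define_reference(
                lr_ds, mode=mode, reference_group=tcfg["reference_group"], seed=seed
            )
            lr_ds = lr_ds.with_reference_flags(assign.is_reference)
        lr_ds.table.to_csv(outdir / "logratio_table.csv")
        return lr_ds
    except StageError:
        raise
    except Exception as err:
        raise StageError("transform", err) from err


def _stage_trajectory(cfg, lr_ds, outdir: Path, seed: int):
    try:
        tcfg = cfg["trajectory"]
        board = traj_mod.compare_models(
            lr_ds, tcfg["leaderboard"], cv_folds=tcfg["cv_folds"], seed=seed
        )
        board.to_csv(outdir / "leaderboard.csv")
        model = traj_mod.fit_mmi_model(
            lr_ds,
            regressor_name=tcfg["regressor"],
            seed=seed,
            level=tcfg["level"],
            interval=tcfg["interval"],
            cv_folds=tcfg["cv_folds"],
        )
        mmi = traj_mod.predict_mmi(model, lr_ds)
        mmi.to_csv(outdir / "mmi_results.csv")
        groups = sorted(set(lr_ds.meta["group"]))
        if len(groups) == 2:
            cmp_res = traj_mod.compare_trajectories(
                lr_ds, model, groups[0], groups[1], method="linear", seed=seed
            )
            with open(outdir / "group_comparison.json", "w") as fh:
                json.dump(
                    {
                        "method": cmp_res.method,
                        "statistic": cmp_res.statistic,
                        "p_value": cmp_res.p_value,
                        "per_group_fit": cmp_res.per_group_fit,
                    },
                    fh,
                    indent=2,
                )
        return model
    except StageError:
        raise
    except Exception as err:
        raise StageError("trajectory", err) from err


def _stage_anomaly(cfg, lr_ds, model, outdir: Path, seed: int):
    try:
        acfg = cfg["anomaly"]
        mmi = traj_mod.predict_mmi(model, lr_ds, interval="prediction")
        reports = {
            "interval": anomaly_mod.interval_outliers(mmi, model.curve),
            "lowpass": anomaly_mod.lowpass_outliers(
                mmi, lr_ds, window=acfg["window"], k=acfg["k"]
            ),
            "isolation": anomaly_mod.isolation_outliers(
                mmi, window=acfg["window"], contamination=acfg["contamination"], seed=seed
            ),
        }
        for name, rep in reports.items():
            rep.to_csv(outdir / f"anomaly_{name}.csv")
        interval = reports["interval"]
        n_out = len(interval.outlier_ids)
        n_non = lr_ds.n_samples - n_out
        if n_out >= 5 and n_non >= 5:
            expl = anomaly_mod.explain_outliers(
                lr_ds, interval, subsample_ratio=acfg["subsample_ratio"], seed=seed
            )
            expl.feature_ranking.rename("mean_abs_attribution").rename_axis(
                "feature_id"
            ).to_csv(outdir / "outlier_explanation.csv")
            with open(outdir / "outlier_explanation.json", "w") as fh:
                json.dump(
                    {"classifier": expl.classifier_name, "auroc": expl.auroc,
                     "n_outliers": expl.n_outliers, "n_background": expl.n_background},
                    fh, indent=2,
                )
        return reports
    except StageError:
        raise
    except Exception as err:
        raise StageError("anomaly", err) from err


def _stage_intervene(cfg, lr_ds, model, report, outdir: Path) -> None:
    try:
        icfg = cfg["intervention"]
        rows = []
        texts = []
        for sid in report.outlier_ids[: icfg["max_outliers"]]:
            res = intervention.simulate_intervention(
                model, lr_ds, sid, top_k=icfg["k_max"], bandwidth=icfg["bandwidth"]
            )
            texts.append(res.describe())
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "n_features_changed": len(res.features_changed),
                    "features_changed": ";".join(res.features_changed),
                    "mmi_before": res.mmi_before,
                    "mmi_after": res.mmi_after,
                    "residual_before": res.residual_before,
                    "residual_after": res.residual_after,
                    "returned_to_interval": res.returned_to_interval,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "n_features_changed", "features_changed", "mmi_before",
                "mmi_after", "residual_before", "residual_after", "returned_to_interval",
            ],
        ).to_csv(outdir / "intervention_report.csv", index=False)
        (outdir / "intervention_report.txt").write_text(
            "\n\n".join(texts) + ("\n" if texts else "")
        )
        if len(report.outlier_ids) >= 2:
            shared = intervention.shared_outlier_features(
                lr_ds, report, model, top_k=5, seed=int(cfg["seed"])
            )
            shared.to_csv(outdir / "shared_outlier_features.csv")
    except StageError:
        raise
    except Exception as err:
        raise StageError("intervene", err) from err
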