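import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmtraj.core_io import FeatureTable, MicrobiomeDataset, SampleMetadata
from mmtraj.synthetic import SyntheticSpec, generate
from mmtraj.transform import (
    build_hybrid_feature_set,
    count_crossings,
    default_pseudocount,
    define_reference,
    differential_ranking,
    filter_features,
    log_ratio_transform,
    select_denominator,
    to_relative_abundance,
)
from tests.conftest import toy_dataset


class TestRelativeAbundance:
    def test_simple_closure(self):
        t = FeatureTable(pd.DataFrame([[2.0, 2.0], [10.0, 0.0]]), "counts")
        rel = to_relative_abundance(t)
        np.testing.assert_allclose(rel.values.to_numpy(), [[0.5, 0.5], [1.0, 0.0]])
        assert rel.value_kind == "relative"

    def test_zero_total_row_names_sample(self):
        vals = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            to_relative_abundance(FeatureTable(vals, "counts"))

    def test_random_table_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = FeatureTable(pd.DataFrame(rng.integers(1, 100, (50, 30)).astype(float)), "counts")
        rel = to_relative_abundance(t)
        np.testing.assert_allclose(rel.values.sum(axis=1), 1.0, atol=1e-12)


class TestFilterFeatures:
    def test_constant_feature_removed_as_low_variance(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        vals["c"] = 1.0
        out, log = filter_features(FeatureTable(vals, "logratio"), variance_quantile=0.3)
        assert ("c", "low_variance") in log.removed
        assert "c" not in out.values.columns

    def test_perfectly_correlated_pair_drops_lower_variance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        vals = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        out, log = filter_features(
            FeatureTable(vals, "logratio"), variance_quantile=0.0, correlation_threshold=0.99
        )
        assert ("a", "correlated") in log.removed  # var(a) < var(2a)
        assert set(out.values.columns) == {"b", "c"}

    def test_independent_noise_rarely_removed_by_correlation(self):
        kept = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = pd.DataFrame(rng.normal(size=(40, 20)))
            vals.columns = [f"f{j}" for j in range(20)]
            _, log = filter_features(
                FeatureTable(vals, "logratio"), variance_quantile=0.0, correlation_threshold=0.99
            )
            kept += not any(r == "correlated" for _, r in log.removed)
        assert kept >= 95

    def test_deterministic_removal_log(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(25, 8)))
        t = FeatureTable(vals, "logratio")
        _, log1 = filter_features(t, 0.2, 0.9)
        _, log2 = filter_features(t, 0.2, 0.9)
        assert log1.removed == log2.removed


class TestLogRatio:
    def test_feature_equal_to_denominator_gives_zero(self):
        vals = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [4.0, 1.0]})
        lr = log_ratio_transform(FeatureTable(vals, "counts"), "b", pseudocount=0)
        np.testing.assert_allclose(lr.values["a"], 0.0, atol=1e-15)
        assert "b" not in lr.values.columns

    def test_two_feature_example(self):
        vals = pd.DataFrame({"x": [4.0], "y": [2.0]})
        lr = log_ratio_transform(FeatureTable(vals, "counts"), "y", pseudocount=0)
        assert lr.values.loc[0, "x"] == pytest.approx(np.log(2.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=6),
        st.floats(0.1, 1000.0),
    )
    def test_scale_invariance(self, row, scale):
        vals = pd.DataFrame([row, [v * scale for v in row]])
        vals.columns = [f"f{j}" for j in range(len(row))]
        lr = log_ratio_transform(FeatureTable(vals, "counts"), "f0", pseudocount=0)
        np.testing.assert_allclose(
            lr.values.iloc[0].to_numpy(), lr.values.iloc[1].to_numpy(), rtol=1e-9, atol=1e-9
        )

    def test_unknown_denominator_suggests_near_match(self):
        vals = pd.DataFrame({"taxon_a": [1.0], "taxon_b": [2.0]})
        with pytest.raises(KeyError, match="taxon_a"):
            log_ratio_transform(FeatureTable(vals, "counts"), "taxon_aa")

    def test_default_pseudocount_is_half_smallest_nonzero(self):
        vals = pd.DataFrame({"a": [0.0, 0.4], "b": [0.2, 0.6]})
        assert default_pseudocount(FeatureTable(vals, "counts")) == pytest.approx(0.1)


class TestCrossings:
    def test_parallel_trajectories_never_cross(self):
        # candidate constant at 0.5, other feature constant at 0.2
        ds = toy_dataset([[0.5, 0.2]] * 8, times=[0, 0, 1, 1, 2, 2, 3, 3])
        assert count_crossings(ds, "f0", n_bins=4) == 0

    def test_single_intersection_counts_once(self):
        rising = np.linspace(0.2, 0.8, 8)
        vals = [[0.5, r] for r in rising]
        ds = toy_dataset(vals, times=[0, 0, 1, 1, 2, 2, 3, 3])
        assert count_crossings(ds, "f0", n_bins=2) == 1

    def test_matches_brute_force_pairwise_oracle(self):
        ds, _ = generate(SyntheticSpec(seed=9, n_subjects=10, samples_per_subject=6, n_features=10))
        n_bins = 5
        # independent oracle: recompute binned medians and count sign flips
        t = ds.meta["time"].to_numpy()
        edges = np.linspace(t.min(), t.max(), n_bins + 1)
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
        med = ds.table.values.groupby(idx).median()
        for cand in ds.table.feature_ids[:4]:
            expected = 0
            for f in ds.table.feature_ids:
                if f == cand:
                    continue
                d = np.sign((med[f] - med[cand]).to_numpy())
                d = d[d != 0]
                expected += int(np.sum(d[1:] * d[:-1] < 0))
            assert count_crossings(ds, cand, n_bins=n_bins) == expected


class TestDifferentialRanking:
    def test_monotone_features_attain_extremes(self):
        n = 12
        inc = np.linspace(0.1, 0.9, n)
        vals = [[inc[i], 1 - inc[i], 0.5] for i in range(n)]
        ds = toy_dataset(vals, times=list(range(n)))
        ranks = differential_ranking(ds)
        assert ranks["f0"] == pytest.approx(1.0)
        assert ranks["f1"] == pytest.approx(-1.0)

    def test_constant_feature_scores_zero(self):
        # f0 constant in relative-abundance space; f1/f2 exchange mass
        vals = [[0.5, 0.25 + 0.02 * (i % 3), 0.25 - 0.02 * (i % 3)] for i in range(10)]
        ds = toy_dataset(vals, times=list(range(10)), value_kind="relative")
        assert differential_ranking(ds)["f0"] == 0.0

    def test_null_feature_rho_small(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            from scipy.stats import spearmanr

            hits += abs(spearmanr(x, np.arange(200)).statistic) < 0.2
        assert hits >= 95


class TestSelectDenominator:
    def test_crossings_picks_stable_feature(self):
        # a and b swap ranks once, both staying clear of the constant c
        n = 16
        a = np.linspace(0.30, 0.44, n)
        b = np.linspace(0.44, 0.30, n)
        c = np.full(n, 0.26)
        vals = [[a[i], b[i], c[i]] for i in range(n)]
        ds = toy_dataset(vals, times=list(range(n)))
        rep = select_denominator(ds, strategy="crossings", n_bins=4)
        assert rep.feature_id == "f2"
        assert rep.score_per_candidate["f2"] == min(rep.score_per_candidate.values())

    def test_ranking_high_picks_increasing_feature(self):
        n = 12
        inc = np.linspace(0.1, 0.9, n)
        rng = np.random.default_rng(0)
        vals = [[inc[i], 0.5 + rng.normal(0, 0.01), 0.4 - 0.0 * i] for i in range(n)]
        ds = toy_dataset(vals, times=list(range(n)))
        assert select_denominator(ds, strategy="ranking_high").feature_id == "f0"

    def test_performance_matches_exhaustive_oracle(self):
        from sklearn.model_selection import GroupKFold, cross_val_score
        from mmtraj.trajectory import make_regressor

        ds, _ = generate(
            SyntheticSpec(seed=13, n_subjects=10, samples_per_subject=5, n_features=8, n_informative=3)
        )
        rep = select_denominator(ds, strategy="performance", model_spec="ridge", cv_folds=4, seed=13)
        # independent exhaustive search with the same folds and model
        scores = {}
        for f in ds.table.feature_ids:
            lr = log_ratio_transform(ds.table, f, pseudocount=None)
            X = lr.values.to_numpy()
            meta = ds.meta
            scores[f] = float(
                np.mean(
                    cross_val_score(
                        make_regressor("ridge", 13), X, meta["time"].to_numpy(),
                        groups=meta["subject_id"].to_numpy(),
                        cv=GroupKFold(n_splits=4), scoring="r2",
                    )
                )
            )
        best = max(sorted(scores), key=lambda f: (scores[f], f))
        assert rep.feature_id == best
        for f, s in scores.items():
            assert rep.score_per_candidate[f] == pytest.approx(s, abs=1e-9)


class TestHybridFeatureSet:
    def test_union_preserves_importance_order(self):
        imp = {"a": 0.5, "b": 0.3, "c": 0.1}
        assert build_hybrid_feature_set(imp, 2, ["c"]) == ["a", "b", "c"]

    def test_domain_feature_already_present_not_duplicated(self):
        imp = {"a": 0.5, "b": 0.3}
        assert build_hybrid_feature_set(imp, 2, ["a"]) == ["a", "b"]

    def test_empty_domain_is_top_k(self):
        imp = {"a": 0.5, "b": 0.3, "c": 0.1}
        assert build_hybrid_feature_set(imp, 2, []) == ["a", "b"]

    def test_unknown_domain_feature_errors(self):
        with pytest.raises(KeyError):
            build_hybrid_feature_set({"a": 1.0}, 1, ["zzz"])


class TestDefineReference:
    def test_group_label_mode(self, small_study):
        ds, _ = small_study
        # tag half the subjects as control
        from dataclasses import replace

        subs = sorted({m.subject_id for m in ds.metadata})
        ctl = set(subs[:6])
        meta = [replace(m, group="control" if m.subject_id in ctl else "case") for m in ds.metadata]
        ds2 = MicrobiomeDataset(table=ds.table, metadata=meta, time_unit="d")
        assign = define_reference(ds2, mode="group_label", reference_group="control")
        flags = pd.Series(assign.is_reference)
        groups = ds2.meta["group"]
        assert (flags == (groups == "control")).all()

    def test_novelty_admits_duplicates_of_seed(self, small_study):
        ds, _ = small_study
        from dataclasses import replace

        # seed set = all samples; duplicates of the 5 most typical samples
        # (nearest the median composition) as non-seed
        vals = ds.table.values
        dist = ((vals - vals.median(axis=0)) ** 2).sum(axis=1)
        typical = dist.nsmallest(5).index
        dup = vals.loc[typical].copy()
        dup.index = [f"dup{i}" for i in range(5)]
        all_vals = pd.concat([vals, dup])
        meta = [replace(m, is_reference=True) for m in ds.metadata] + [
            SampleMetadata(f"dup{i}", "dupsubj", 0.5, is_reference=False) for i in range(5)
        ]
        ds2 = MicrobiomeDataset(FeatureTable(all_vals, "relative"), meta, "d")
        assign = define_reference(ds2, mode="novelty", novelty_frac=0.05, seed=0)
        assert all(assign.is_reference[f"dup{i}"] for i in range(5))

    def test_novelty_rejects_shifted_samples(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(size=(60, 8))
            shifted = base[:6] + 0.0
            shifted = shifted.copy()
            shifted[:, :5] += 10 * base.std(axis=0)[:5]
            vals = pd.DataFrame(np.vstack([base, shifted]))
            vals.columns = [f"f{j}" for j in range(8)]
            vals.index = [f"s{i}" for i in range(66)]
            meta = [
                SampleMetadata(f"s{i}", f"subj{i % 5}", float(i % 4), is_reference=i < 60)
                for i in range(66)
            ]
            ds = MicrobiomeDataset(FeatureTable(vals, "logratio"), meta, "d")
            assign = define_reference(ds, mode="novelty", novelty_frac=0.05, seed=seed)
            hits += not any(assign.is_reference[f"s{i}"] for i in range(60, 66))
        assert hits >= 48  # >= 95% of runs exclude all shifted samples

    def test_too_few_reference_samples_errors(self):
        vals = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
        vals.index = [f"s{i}" for i in range(6)]
        meta = [
            SampleMetadata(f"s{i}", f"subj{i % 2}", float(i), is_reference=i < 3)
            for i in range(6)
        ]
        ds = MicrobiomeDataset(FeatureTable(vals, "logratio"), meta, "d")
        with pytest.raises(ValueError, match="reference samples"):
            define_reference(ds, mode="declared")
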