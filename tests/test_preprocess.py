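"""Curation, filtering, transforms and imputation."""

import math

import numpy as np
import pytest

from chronomet import SimConfig, build_schedule, inject_outliers, simulate_dataset
from chronomet.errors import ConfigError, DomainError
from chronomet.preprocess import (
    drop_flagged,
    filter_missingness,
    flag_outliers,
    impute_knn,
    impute_linear,
    log2_values,
    transform,
)

from conftest import make_dataset, make_design

U = "a.P.nt-ms"
V = "b.P.nt-ms"


class TestLog2:
    @pytest.mark.parametrize("raw,expected", [(8.0, 3.0), (1.0, 0.0), (0.25, -2.0)])
    def test_values(self, raw, expected):
        ds = make_dataset({(1, 1, U): raw})
        assert log2_values(ds).get(1, 1, U) == expected

    def test_non_positive_rejected(self):
        ds = make_dataset({(1, 1, U): 2.0})
        bad = ds.values.copy()
        bad.at[(1, 1), U] = 0.0
        with pytest.raises(DomainError, match="subject 1"):
            log2_values(ds.with_values(bad, "log2"))  # bypass the raw-positivity gate


class TestFlagOutliers:
    def _ds(self, values, n_tp=2):
        design = make_design(n_tp=n_tp, subjects=tuple(range(1, len(values) + 1)),
                             challenge=False)
        obs = {(s, tp, U): float(v) for s, v in enumerate(values, start=1)
               for tp in design.tp_indices}
        return make_dataset(obs, design=design, transform_tag="log2")

    def test_lone_deviant_among_15_is_never_flagged_by_literal_rule(self):
        # mean 0.667, SD 2.582: |10 - 0.667| = 9.33 < 4*2.582; in fact no
        # single deviant among 15 can exceed (n-1)/sqrt(n) = 3.61 SDs
        ds = self._ds([0.0] * 14 + [10.0])
        report = flag_outliers(ds, sd_scope="timepoint")
        assert report.flagged == []
        grouped = ds.values.groupby(level="tp")
        assert grouped.std(ddof=1).iloc[0, 0] == pytest.approx(2.582, abs=1e-3)

    def test_pooled_scope_flags_gross_deviant(self):
        # pooled over time points, the deviant tp no longer dominates the SD
        design = make_design(n_tp=8, subjects=tuple(range(1, 16)), challenge=False)
        rngv = np.random.default_rng(0)
        obs = {(s, tp, U): float(rngv.normal(0, 1))
               for s in design.subjects for tp in design.tp_indices}
        obs[(1, 5, U)] = 10.0
        ds = make_dataset(obs, design=design, transform_tag="log2")
        flagged = flag_outliers(ds).flagged_keys()
        assert (1, 5, U) in flagged

    def test_exemption_within_30min_of_onset(self):
        # OGTT onset at clock 0: tps at 0 and 30 min are exempt, 60 min is not
        design = make_design(n_tp=8, spacing=30.0, subjects=tuple(range(1, 16)))
        rngv = np.random.default_rng(1)
        obs = {(s, tp, U): float(rngv.normal(0, 1))
               for s in design.subjects for tp in design.tp_indices}
        obs[(2, 2, U)] = 25.0   # clock 30 -> exempt
        obs[(3, 4, U)] = 25.0   # clock 90 -> flagged
        ds = make_dataset(obs, design=design, transform_tag="log2")
        report = flag_outliers(ds)
        assert (2, 2, U) in set(report.exempted)
        assert (3, 4, U) in report.flagged_keys()

    def test_small_or_degenerate_groups_skipped(self):
        design = make_design(n_tp=1, subjects=(1, 2), challenge=False)
        ds = make_dataset({(1, 1, U): 0.0, (2, 1, U): 9.0}, design=design,
                          transform_tag="log2")
        report = flag_outliers(ds)
        assert report.flagged == [] and report.skipped_groups == 1

    def test_recall_on_injected_6sd_outliers(self):
        cfg = SimConfig(n_subjects=15, n_metabolites=10, missing_mcar=0.0,
                        missing_lod_quantile=0.0, seed=8)
        ds, _ = simulate_dataset(cfg)
        log2 = log2_values(ds)
        contaminated, injected = inject_outliers(log2, 0.002, 6.0, seed=10)
        assert len(injected) >= 5
        report = flag_outliers(contaminated)
        exempt = set(report.exempted)
        caught = report.flagged_keys()
        for key in injected:
            assert key in caught or key in exempt

    def test_drop_flagged(self):
        design = make_design(n_tp=8, subjects=tuple(range(1, 16)), challenge=False)
        rngv = np.random.default_rng(2)
        obs = {(s, tp, U): float(rngv.normal(0, 1))
               for s in design.subjects for tp in design.tp_indices}
        obs[(1, 3, U)] = 30.0
        ds = make_dataset(obs, design=design, transform_tag="log2")
        report = flag_outliers(ds)
        cleaned = drop_flagged(ds, report)
        assert cleaned.get(1, 3, U) is None


class TestFilterMissingness:
    def _ds_with_missing(self, n_missing, n_tp=10, subjects=(1, 2, 3)):
        design = make_design(n_tp=n_tp, subjects=subjects, challenge=False)
        keys = [(s, t) for s in subjects for t in design.tp_indices]
        obs = {(s, t, U): 1.0 for s, t in keys[n_missing:]}
        obs.update({(s, t, V): 1.0 for s, t in keys})
        return make_dataset(obs, design=design, uids=[U, V])

    def test_just_below_threshold_retained(self):
        ds = self._ds_with_missing(8)  # 8/30 = 26.7%
        assert U in filter_missingness(ds, 0.30).uids

    def test_exactly_at_threshold_dropped(self):
        ds = self._ds_with_missing(9)  # 9/30 = 30%
        assert U not in filter_missingness(ds, 0.30).uids

    def test_fully_observed_retained(self):
        assert V in filter_missingness(self._ds_with_missing(9), 0.30).uids


class TestTransform:
    def test_zscore_mean_sd(self):
        rngv = np.random.default_rng(3)
        design = make_design(n_tp=6, subjects=(1, 2, 3), challenge=False)
        obs = {(s, t, U): float(rngv.normal(5, 2))
               for s in design.subjects for t in design.tp_indices}
        zs = transform(make_dataset(obs, design=design, transform_tag="log2"), "zscore")
        col = zs.values[U]
        assert col.mean() == pytest.approx(0.0, abs=1e-8)
        assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-8)
        zs.check_invariants()

    def test_zscore_constant_series_becomes_missing(self):
        design = make_design(n_tp=3, subjects=(1, 2), challenge=False)
        obs = {(s, t, U): 5.0 for s in (1, 2) for t in (1, 2, 3)}
        zs = transform(make_dataset(obs, design=design, transform_tag="log2"), "zscore")
        assert zs.n_observations == 0

    def test_log2fc_challenge(self):
        design = make_design(n_tp=4)  # OGTT baseline tp 1
        obs = {(1, 1, U): 3.0, (1, 3, U): 5.0, (1, 4, U): 2.0}
        fc = transform(make_dataset(obs, design=design, transform_tag="log2"),
                       "log2fc_challenge")
        assert fc.get(1, 1, U) == 0.0
        assert fc.get(1, 3, U) == 2.0
        assert fc.get(1, 4, U) == -1.0

    def test_log2fc_challenge_missing_baseline_propagates(self):
        design = make_design(n_tp=3)
        fc = transform(make_dataset({(1, 2, U): 5.0}, design=design,
                                    transform_tag="log2"), "log2fc_challenge")
        assert fc.get(1, 2, U) is None

    def test_log2fc_block_references_first_block_tp(self):
        design = build_schedule("humet56", subjects=[1])
        obs = {(1, 1, U): 2.0, (1, 5, U): 6.0, (1, 29, U): 1.0, (1, 30, U): 4.0}
        fc = transform(make_dataset(obs, design=design, transform_tag="log2"),
                       "log2fc_block")
        assert fc.get(1, 5, U) == 4.0    # vs tp 1 (block 1 first)
        assert fc.get(1, 30, U) == 3.0   # vs tp 29 (block 2 first)

    def test_unknown_mode(self):
        with pytest.raises(ConfigError):
            transform(make_dataset({(1, 1, U): 1.0}, transform_tag="log2"), "nope")


class TestImputeLinear:
    def test_interpolates_against_clock_time(self):
        design = make_design(n_tp=4, spacing=30.0, challenge=False)
        obs = {(1, 1, U): 1.0, (1, 4, U): 4.0}  # clocks 0 and 90; missing 30, 60
        out = impute_linear(make_dataset(obs, design=design, transform_tag="log2"))
        assert out.get(1, 2, U) == pytest.approx(2.0)  # 1 + 3*30/90
        assert out.get(1, 3, U) == pytest.approx(3.0)

    def test_no_extrapolation(self):
        design = make_design(n_tp=3, challenge=False)
        out = impute_linear(make_dataset({(1, 1, U): 1.0, (1, 2, U): 2.0},
                                         design=design, transform_tag="log2"))
        assert out.get(1, 3, U) is None

    def test_does_not_cross_blocks(self):
        design = build_schedule("humet56", subjects=[1])
        obs = {(1, 27, U): 1.0, (1, 30, U): 5.0}
        out = impute_linear(make_dataset(obs, design=design, transform_tag="log2"))
        assert out.get(1, 28, U) is None  # trailing in block 1
        assert out.get(1, 29, U) is None  # leading in block 2

    def test_exact_on_piecewise_linear_signal(self):
        design = make_design(n_tp=10, spacing=15.0, challenge=False, subjects=(1,))
        f = lambda t: 0.5 + 0.02 * t
        obs = {(1, i, U): f(design.tp(i).clock_min) for i in design.tp_indices
               if i not in (3, 4, 7)}
        out = impute_linear(make_dataset(obs, design=design, transform_tag="log2"))
        for i in (3, 4, 7):
            assert out.get(1, i, U) == pytest.approx(f(design.tp(i).clock_min), abs=1e-12)

    def test_observed_values_untouched(self):
        design = make_design(n_tp=4, challenge=False)
        obs = {(1, 1, U): 1.0, (1, 2, U): 7.0, (1, 4, U): 4.0}
        out = impute_linear(make_dataset(obs, design=design, transform_tag="log2"))
        assert out.get(1, 2, U) == 7.0


class TestImputeKnn:
    def _correlated_ds(self, seed=0, n_tp=30, n_subj=3, missing=((1, 5),)):
        rngv = np.random.default_rng(seed)
        design = make_design(n_tp=n_tp, subjects=tuple(range(1, n_subj + 1)),
                             challenge=False)
        uids = [U, V, "c.P.nt-ms", "d.P.nt-ms"]
        base = {k: rngv.normal(0, 1) for k in
                [(s, t) for s in design.subjects for t in design.tp_indices]}
        obs = {}
        for j, u in enumerate(uids):
            for (s, t), b in base.items():
                obs[(s, t, u)] = float(b + 0.1 * rngv.normal())
        for s, t in missing:
            del obs[(s, t, U)]
        return make_dataset(obs, design=design, uids=uids, transform_tag="log2"), obs

    def test_imputes_close_to_truth_for_correlated_neighbors(self):
        ds, obs = self._correlated_ds()
        out = impute_knn(ds, k=3)
        assert out.get(1, 5, U) is not None

    def test_observed_values_untouched(self):
        ds, obs = self._correlated_ds()
        out = impute_knn(ds, k=3)
        for (s, t, u), v in dict(ds.observations()).items():
            assert out.get(s, t, u) == v

    def test_nearest_neighbor_wins_with_k1(self):
        # the candidate sample identical to the query on the predictors must
        # win at k=1 (>= 10 complete pairs needed for the preselection)
        design = make_design(n_tp=12, subjects=(1,), challenge=False)
        uids = [U, V, "c.P.nt-ms"]
        preds = [0.0, 0.0, 9.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 2.5]
        obs = {}
        for t, a in zip(design.tp_indices, preds):
            obs[(1, t, V)] = a
            obs[(1, t, "c.P.nt-ms")] = a
        for t in design.tp_indices[1:]:
            obs[(1, t, U)] = float(10 + t)
        ds = make_dataset(obs, design=design, uids=uids, transform_tag="log2")
        out = impute_knn(ds, k=1, n_preselect=2)
        assert out.get(1, 1, U) == 12.0  # sample at tp 2 matches the query exactly

    def test_all_missing_target_left_missing(self):
        design = make_design(n_tp=5, subjects=(1,), challenge=False)
        obs = {(1, t, V): float(t) for t in range(1, 6)}
        ds = make_dataset(obs, design=design, uids=[U, V], transform_tag="log2")
        out = impute_knn(ds)
        assert all(out.get(1, t, U) is None for t in range(1, 6))
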