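"""Z-score normality, Mann-Whitney concordance, condition stats, curation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, replicate_dataset

from colonyscreen import quality_control as qc
from colonyscreen.iris_io import PlateQuant, build_dataset
from colonyscreen.quality_control import (QCReport, QCThresholds,
                                          condition_level_stats, curate,
                                          mannwhitney_replicates, qc_report,
                                          threshold_curves, zscore_normality,
                                          _replicate_zscores)
from colonyscreen.synthetic_plates import (SimulationConfig, simulate_big,
                                           swap_condition_labels)


class TestZscoreNormality:
    def test_three_spread_replicates_all_normal(self):
        # (2, 4, 6): sample std 2 -> Z = (-1, 0, 1); |Z| > 1 is strict
        ds = replicate_dataset([[2.0], [4.0], [6.0]])
        assert zscore_normality(ds, "cond") == {"A": 100.0, "B": 100.0,
                                                "C": 100.0}

    def test_outliers_and_missing_counted(self):
        # 100 positions; replicate A gets 10 far outliers and 5 missing
        rng = np.random.default_rng(0)
        base = rng.normal(100, 1, 100)
        a, b, c = base.copy(), base.copy(), base.copy()
        a[:10] += 500.0   # |Z| >> 1 for replicate A at those positions
        a[10:15] = np.nan
        ds = replicate_dataset([a, b, c])
        pct = zscore_normality(ds, "cond")
        assert pct["A"] == pytest.approx(85.0)

    def test_constant_replicates_all_normal(self):
        ds = replicate_dataset([[5.0], [5.0], [5.0]])
        assert set(zscore_normality(ds, "cond").values()) == {100.0}

    def test_single_replicate_rejected(self):
        ds = replicate_dataset([[1.0, 2.0]])
        with pytest.raises(ValueError):
            zscore_normality(ds, "cond")

    def test_zscores_standardized(self):
        rng = np.random.default_rng(1)
        block = rng.normal(50, 7, (40, 4))
        z = _replicate_zscores(block)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_invariant_under_common_condition_scaling(self):
        rng = np.random.default_rng(2)
        reps = [rng.lognormal(5, 0.3, 50) for _ in range(3)]
        before = zscore_normality(replicate_dataset(reps), "cond")
        after = zscore_normality(
            replicate_dataset([r * 3.7 for r in reps]), "cond")
        assert before == after


class TestMannWhitneyReplicates:
    def test_identical_replicates_p_one(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(5, 0.3, 60)
        mw = mannwhitney_replicates(replicate_dataset([vals, vals]), "cond")
        assert mw["A"] == 1.0 and mw["B"] == 1.0

    def test_shifted_replicate_scores_lowest(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(5, 0.3, 96)
        b = rng.lognormal(5, 0.3, 96)
        c = a * 1.5
        mw = mannwhitney_replicates(replicate_dataset([a, b, c]), "cond")
        assert mw["C"] < min(mw["A"], mw["B"])

    def test_same_distribution_rarely_flagged(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            reps = [rng.lognormal(5, 0.3, 96) for _ in range(3)]
            mw = mannwhitney_replicates(replicate_dataset(reps), "cond")
            hits += all(v > 0.05 for v in mw.values())
        assert hits >= 90

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(5)
        reps = [rng.lognormal(5, 0.3, 50) for _ in range(3)]
        mw = mannwhitney_replicates(replicate_dataset(reps), "cond")
        permuted = mannwhitney_replicates(
            replicate_dataset([reps[2], reps[0], reps[1]]), "cond")
        assert permuted["A"] == mw["C"]
        assert permuted["B"] == mw["A"]
        assert permuted["C"] == mw["B"]


class TestConditionLevelStats:
    def test_identical_replicates_zero_stats(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(5, 0.3, 40)
        mw_var, colony_var = condition_level_stats(
            replicate_dataset([vals, vals, vals]), "cond")
        assert mw_var == 0.0
        assert colony_var == pytest.approx(0.0, abs=1e-20)

    def test_colony_variance_arithmetic(self):
        # positions (100,100) and (200,400): sample variances 0 and 20000
        ds = replicate_dataset([[100.0, 200.0], [100.0, 400.0]])
        _, colony_var = condition_level_stats(ds, "cond")
        assert colony_var == pytest.approx(10000.0)

    def test_mw_variance_matches_brute_force(self):
        rng = np.random.default_rng(7)
        reps = [rng.lognormal(5, 0.4, 60) for _ in range(3)]
        ds = replicate_dataset(reps)
        mw = mannwhitney_replicates(ds, "cond")
        mw_var, _ = condition_level_stats(ds, "cond")
        assert mw_var == pytest.approx(np.var(list(mw.values()), ddof=1),
                                       rel=1e-12)


def report_from_values(normality, mw=None):
    idx = pd.MultiIndex.from_tuples(
        [("c1", chr(ord("A") + i)) for i in range(len(normality))],
        names=["condition", "replicate"])
    plate_stats = pd.DataFrame({
        "pct_normality": normality,
        "mw_mean_p": mw if mw is not None else [0.5] * len(normality),
    }, index=idx)
    condition_stats = pd.DataFrame(
        {"mw_p_variance": [0.0], "mean_colony_variance": [0.0]},
        index=pd.Index(["c1"], name="condition"))
    return QCReport(plate_stats=plate_stats, condition_stats=condition_stats)


class TestThresholdCurves:
    def test_no_loss_when_all_plates_good(self):
        curves = threshold_curves(report_from_values([90.0] * 4))
        assert (curves["pct_normality"]["pct_plates_lost"] == 0).all()

    def test_half_of_plates_lost_at_eighty(self):
        # replicate normality values as observed in a cold-shock condition
        curves = threshold_curves(
            report_from_values([64.84, 70.53, 90.43, 95.05]))
        at80 = curves["pct_normality"].query("threshold == 80.0")
        assert at80["pct_plates_lost"].iloc[0] == pytest.approx(50.0)

    def test_condition_loss_monotone_in_threshold(self, small_big_sim):
        ds, _ = __import__("colonyscreen").normalize_dataset(
            small_big_sim.dataset())
        curves = threshold_curves(qc_report(ds))
        for name in ("mw_p_variance", "mean_colony_variance"):
            lost = curves[name].sort_values("threshold")["n_conditions_lost"]
            assert (np.diff(lost) <= 0).all()  # fail-HIGH: higher t, fewer lost

    def test_empty_report_rejected(self):
        empty = QCReport(plate_stats=pd.DataFrame(),
                         condition_stats=pd.DataFrame())
        with pytest.raises(ValueError):
            threshold_curves(empty)


class TestCurate:
    def test_normality_threshold_removes_failing_plates(self, quiet_sim):
        ds = quiet_sim.dataset()
        report = qc_report(ds)
        # forge the observed statistics of a four-replicate condition
        cond = ds.conditions[0]
        vals = {("A", 64.84), ("B", 70.53), ("C", 90.43)}
        for rep, v in vals:
            report.plate_stats.loc[(cond, rep), "pct_normality"] = v
        res = curate(ds, report, QCThresholds(normality=80.0),
                     renormalize=False)
        removed = set(res.removed_plates.index)
        assert (cond, "A") in removed and (cond, "B") in removed
        assert (cond, "C") not in removed

    def test_no_thresholds_identity(self, quiet_sim):
        ds = quiet_sim.dataset()
        res = curate(ds, qc_report(ds), QCThresholds())
        pd.testing.assert_frame_equal(res.dataset.values, ds.values)

    def test_removal_count_matches_recount(self, small_big_sim):
        from colonyscreen import normalize_dataset
        ds, _ = normalize_dataset(small_big_sim.dataset())
        report = qc_report(ds)
        t = float(report.plate_stats["pct_normality"].median())
        res = curate(ds, report, QCThresholds(normality=t),
                     renormalize=False)
        expected = int((report.plate_stats["pct_normality"] < t).sum())
        assert len(res.removed_plates) == expected
        assert ds.values.shape[1] - res.dataset.values.shape[1] == expected

    def test_idempotent_with_same_thresholds(self, quiet_sim):
        from colonyscreen import normalize_dataset
        ds, _ = normalize_dataset(quiet_sim.dataset())
        report = qc_report(ds)
        thresholds = QCThresholds(normality=50.0, mw_plate=0.05)
        once = curate(ds, report, thresholds)
        again = curate(once.dataset, qc_report(once.dataset), thresholds)
        assert len(again.removed_plates) == 0
        assert len(again.removed_conditions) == 0

    def test_all_removed_is_error(self, quiet_sim):
        ds = quiet_sim.dataset()
        with pytest.raises(ValueError, match="every plate"):
            curate(ds, qc_report(ds), QCThresholds(normality=101.0))


class TestMislabeledPlateDetection:
    def test_swapped_replicate_attains_minimum_mw_score(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            cfg = SimulationConfig(n_rows=8, n_cols=12, n_conditions=2,
                                   n_replicates=3, edge_multipliers=(1, 1),
                                   plate_scale_cv=0.05, missing_prob=0,
                                   mispin_prob=0, seed=seed)
            sim = simulate_big(cfg)
            # make the two conditions differ by a 1.5x scale, then mislabel
            for p in sim.plates:
                if p.condition == "cond02":
                    p.values *= 1.5
            swapped = swap_condition_labels(
                sim.plates, ("cond01", 1, "B"), ("cond02", 1, "B"))
            ds = build_dataset(swapped, sim.layout)
            mw = mannwhitney_replicates(ds, "cond01")
            hits += min(mw, key=mw.get) == "B"
        assert hits >= 95
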