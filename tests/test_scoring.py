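"""S-score formula, control parameters, IQR scaling, calls, clustering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset

from colonyscreen import normalization, scoring
from colonyscreen.scoring import (CALL_NEGATIVE, CALL_NONE, CALL_POSITIVE,
                                  call_significance, cluster_export,
                                  control_parameters, scale_scores,
                                  sscore_cell, sscore_matrix,
                                  uncentred_correlation_distance)
from colonyscreen.synthetic_plates import SimulationConfig, simulate_big


class TestSScoreCell:
    def test_zero_when_mean_equals_control(self):
        assert sscore_cell([90, 110], 100.0, (10.0, 8), 10.0) == 0.0

    def test_hand_evaluated_formula(self):
        # (190, 210): mu_exp 200 vs control 100, s_exp floored at 10,
        # s_cont 10, n_cont 8 -> 100 / sqrt(100/2 + 100/8) = 12.6491...
        s = sscore_cell([190, 210], 100.0, (10.0, 8), 10.0)
        assert s == pytest.approx(100 / np.sqrt(62.5), rel=1e-12)
        assert s == pytest.approx(12.649110, abs=1e-6)

    def test_all_missing_is_missing(self):
        assert np.isnan(sscore_cell([np.nan, np.nan], 100.0, (10.0, 8), 10.0))

    def test_zero_denominator_is_missing(self):
        assert np.isnan(sscore_cell([100.0], 90.0, (0.0, 8), 0.0))

    def test_floor_applies_to_tight_replicates(self):
        # (190, 210) has replicate std exactly 10, the floor value, so
        # flooring tighter replicates reproduces the same score
        tight = sscore_cell([199.9, 200.1], 100.0, (10.0, 8), 10.0)
        loose = sscore_cell([190, 210], 100.0, (10.0, 8), 10.0)
        assert tight == loose


class TestControlParameters:
    def grid(self, strain_rows, conditions=4, reps=2):
        """Dataset whose row i holds strain_rows[i] at every cell."""
        n = len(strain_rows)
        plates = {}
        for c in range(conditions):
            for r in range(reps):
                plates[(f"c{c}", str(r))] = np.asarray(
                    strain_rows, dtype=float).reshape(n, 1) * np.ones((n, 1))
        return make_dataset(plates, n, 1)

    def test_constant_strain(self):
        rng = np.random.default_rng(0)
        # one constant strain among noisy ones
        cfg = SimulationConfig(n_rows=5, n_cols=5, n_conditions=6,
                               n_replicates=3, edge_multipliers=(1, 1),
                               plate_scale_cv=0.0, missing_prob=0,
                               mispin_prob=0, seed=1)
        ds = simulate_big(cfg).dataset()
        gene = ds.values.index[0]
        ds.values.loc[gene, :] = 100.0
        params = control_parameters(ds)
        rel = params.attrs["median_relative_error"]
        assert params.loc[gene, "mu_cont"] == 100.0
        assert params.loc[gene, "s_cont"] == pytest.approx(100.0 * rel)
        assert params.loc[gene, "n_cont"] == 18

    def test_median_of_values(self):
        vals = np.array([80.0, 100.0, 120.0, 200.0])
        assert np.median(vals) == 110.0  # anchor for the dataset check below
        ds = self.grid([50.0, 60.0, 70.0])
        ds.values.iloc[0, :4] = [80, 100, 120, 200]
        ds.values.iloc[0, 4:] = np.nan
        params = control_parameters(ds)
        assert params["mu_cont"].iloc[0] == 110.0

    def test_s_cont_brute_force_recomputation(self):
        cfg = SimulationConfig(n_rows=5, n_cols=5, n_conditions=5,
                               n_replicates=3, edge_multipliers=(1, 1),
                               missing_prob=0, mispin_prob=0, seed=2)
        ds = simulate_big(cfg).dataset()
        params = control_parameters(ds)
        # brute force: median of per-cell std/mean ratios over all cells
        rels = []
        for condition in ds.conditions:
            block = ds.condition_block(condition).to_numpy()
            for row in block:
                row = row[np.isfinite(row)]
                if row.size >= 2 and row.mean() != 0:
                    rels.append(row.std(ddof=0) / row.mean())
        expected_rel = float(np.median(rels))
        for pos in ds.values.index[:5]:
            mu = float(np.nanmedian(ds.values.loc[pos].to_numpy()))
            assert params.loc[pos, "s_cont"] == pytest.approx(
                mu * expected_rel, rel=1e-12)


class TestScaleScores:
    def matrix(self, arr):
        idx = pd.MultiIndex.from_tuples(
            [(1, i + 1, 1, f"g{i}") for i in range(len(arr))],
            names=["plate", "row", "column", "gene"])
        frame = pd.DataFrame({"c1": np.asarray(arr, dtype=float)}, index=idx)
        return scoring.SScoreMatrix(scores=frame)

    def test_iqr_two_seventy_halves_scores(self):
        m = self.matrix([-2.7, -1.35, 0.0, 1.35, 2.7])  # IQR 2.70
        out = scale_scores(m)
        np.testing.assert_allclose(
            out.scores["c1"], [-1.35, -0.675, 0, 0.675, 1.35])

    def test_already_at_target_unchanged(self):
        m = self.matrix([-1.35, -0.675, 0.0, 0.675, 1.35])  # IQR 1.35
        out = scale_scores(m)
        np.testing.assert_allclose(out.scores["c1"], m.scores["c1"])

    def test_post_scaling_iqr_exact(self):
        rng = np.random.default_rng(3)
        m = self.matrix(rng.normal(0, 3, 200))
        out = scale_scores(m)
        q1, q3 = np.nanpercentile(out.scores["c1"], [25, 75])
        assert q3 - q1 == pytest.approx(1.35, abs=1e-6)

    def test_zero_iqr_group_left_unscaled(self):
        m = self.matrix([1.0, 1.0, 1.0, 1.0])
        out = scale_scores(m)
        np.testing.assert_array_equal(out.scores["c1"], 1.0)


class TestCallSignificance:
    def test_boundaries_are_strict(self):
        idx = pd.MultiIndex.from_tuples(
            [(1, i + 1, 1, f"g{i}") for i in range(4)],
            names=["plate", "row", "column", "gene"])
        m = scoring.SScoreMatrix(
            scores=pd.DataFrame({"c": [-3.0, -3.01, 2.0, 2.5]}, index=idx),
            scaled=True)
        out = call_significance(m)
        assert out.calls["c"].tolist() == [CALL_NONE, CALL_NEGATIVE,
                                           CALL_NONE, CALL_POSITIVE]

    def test_call_counts_match_recount(self, quiet_sim):
        ds, _ = normalization.normalize_dataset(quiet_sim.dataset())
        m = call_significance(scale_scores(sscore_matrix(ds)))
        arr = m.scores.to_numpy()
        assert (m.calls.to_numpy() == CALL_NEGATIVE).sum() == (arr < -3).sum()
        assert (m.calls.to_numpy() == CALL_POSITIVE).sum() == (arr > 2).sum()


class TestLocationSensitivity:
    def test_boost_in_one_condition_raises_that_score(self, quiet_sim):
        ds = quiet_sim.dataset()
        base = sscore_matrix(ds).scores
        boosted = ds.copy()
        pos = boosted.values.index[10]
        cols = [c for c in boosted.values.columns if c[0] == "cond01"]
        boosted.values.loc[pos, cols] *= 1.6
        after = sscore_matrix(boosted).scores
        assert after.loc[pos, "cond01"] > base.loc[pos, "cond01"]


def naive_average_linkage(dist):
    """O(n^3) agglomeration oracle returning merge heights."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return sorted(heights)


class TestClusterExport:
    def toy_matrix(self, rows, conditions=4):
        idx = pd.MultiIndex.from_tuples(
            [(1, i + 1, 1, f"g{i}") for i in range(len(rows))],
            names=["plate", "row", "column", "gene"])
        frame = pd.DataFrame(np.asarray(rows, dtype=float), index=idx,
                             columns=[f"c{j}" for j in range(conditions)])
        return scoring.SScoreMatrix(scores=frame, scaled=True)

    def test_identical_rows_merge_first(self, tmp_path):
        m = self.toy_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [4, -1, 2, 0]])
        files = cluster_export(m, tmp_path / "out")
        first_merge = files["gtr"].read_text().splitlines()[0].split("\t")
        assert {first_merge[1], first_merge[2]} == {"GENE0X", "GENE1X"}
        assert float(first_merge[3]) == pytest.approx(1.0)  # distance 0

    def test_negated_row_is_distance_two(self, tmp_path):
        m = self.toy_matrix([[1, 2, 3, 4], [-1, -2, -3, -4], [1, 2, 3, 4.1]])
        d = uncentred_correlation_distance(m.scores.to_numpy())
        assert d[0, 1] == pytest.approx(2.0)
        files = cluster_export(m, tmp_path / "out")
        # the negated row joins last; its average-linkage height is the mean
        # of its distances to the near-identical pair, i.e. essentially 2
        last = files["gtr"].read_text().splitlines()[-1].split("\t")
        assert "GENE1X" in last
        assert float(last[3]) == pytest.approx(-1.0, abs=1e-3)

    def test_heights_match_naive_oracle(self, tmp_path):
        rng = np.random.default_rng(4)
        m = self.toy_matrix(rng.normal(0, 1, (6, 4)))
        dist = uncentred_correlation_distance(m.scores.to_numpy())
        expected = naive_average_linkage(dist)
        from scipy.cluster.hierarchy import linkage
        got = sorted(linkage(dist[np.triu_indices_from(dist, k=1)],
                             method="average")[:, 2])
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_cdt_contains_all_rows(self, tmp_path):
        rng = np.random.default_rng(5)
        m = self.toy_matrix(rng.normal(0, 1, (6, 4)))
        files = cluster_export(m, tmp_path / "out")
        lines = files["cdt"].read_text().splitlines()
        assert len(lines) == 3 + 6  # header, AID, EWEIGHT + one per gene
        assert files["atr"].exists()
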