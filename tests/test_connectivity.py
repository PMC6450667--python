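"""Background connectivity: event models, denoising, weighted correlations,
Louvain modularity, network density, condition comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mnemonet import connectivity
from mnemonet.connectivity import (
    CollinearityError, ConnectivityMatrix, build_event_model, compare_conditions,
    denoise, louvain_modularity, modularity_q, network_density,
    threshold_matrix, weighted_correlation_matrix,
)
from mnemonet.events import convolved_regressor
from mnemonet.synthgen import ROITimeSeriesSet


def make_ts(data, tr=1.5, nuisance=None, runs=None, labels=None):
    n, r = data.shape
    labels = labels or tuple("N%d" % (i % 2) for i in range(r))
    return ROITimeSeriesSet(
        data=np.asarray(data, float),
        run_ids=np.ones(n, int) if runs is None else runs,
        roi_names=tuple(f"roi{i}" for i in range(r)),
        network_labels=labels,
        tr=tr,
        nuisance=np.zeros((n, 0)) if nuisance is None else nuisance,
        trials=pd.DataFrame(),
    )


def matrix(values, labels):
    n = len(labels)
    return ConnectivityMatrix(np.asarray(values, float),
                              tuple(f"r{i}" for i in range(n)), tuple(labels))


class TestEventModel:
    def test_regressor_peaks_five_to_six_seconds_after_onset(self):
        reg = convolved_regressor(np.array([0.0]), 6.0, np.array([1.0]), 40, 1.0)
        # boxcar-convolved canonical HRF peaks in the 5-9 s window
        assert 5 <= np.argmax(reg) <= 9

    def test_success_modulator_centered_before_convolution(self, scored_trials, small_design):
        sub = scored_trials[scored_trials["subject"] == 1].reset_index(drop=True)
        model = build_event_model(sub, small_design)
        assert abs(model.raw["color_success"].sum()) < 1e-10
        assert abs(model.raw["emotion_memory"].sum()) < 1e-10

    def test_precision_modulator_zero_on_incorrect_trials(self, scored_trials, small_design):
        sub = scored_trials[scored_trials["subject"] == 1].reset_index(drop=True)
        model = build_event_model(sub, small_design)
        incorrect = sub["success_color"].to_numpy() == 0
        assert np.all(model.raw["color_precision"][incorrect] == 0)

    def test_condition_weights_nonnegative_and_normalized(self, scored_trials, small_design):
        sub = scored_trials[scored_trials["subject"] == 1].reset_index(drop=True)
        model = build_event_model(sub, small_design)
        for cond in ("encoding", "remember"):
            w = model.weights[cond]
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0)


class TestDenoise:
    def test_pure_linear_trend_removed(self):
        trend = np.linspace(0, 5, 200)[:, None] * np.array([[1.0, -2.0]])
        out = denoise(make_ts(trend), model=None, include_task=False)
        assert np.abs(out.data).max() < 1e-8

    def test_task_regressor_projected_out(self, one_subject_timeseries, small_design):
        ts = one_subject_timeseries
        model = build_event_model(ts.trials, small_design)
        reg = model.regressors[:, [0]] @ np.ones((1, ts.data.shape[1]))
        out = denoise(make_ts(reg, nuisance=np.zeros((reg.shape[0], 0)),
                              runs=ts.run_ids), model, include_task=True,
                      on_collinear="drop")
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_every_regressor(self, one_subject_timeseries, small_design):
        ts = one_subject_timeseries
        model = build_event_model(ts.trials, small_design)
        out = denoise(ts, model, include_task=True, on_collinear="drop")
        for run, idx in out.run_slices():
            task = model.regressors[model.run_ids == run]
            dots = task.T @ out.data[idx]
            assert np.abs(dots).max() < 1e-6

    def test_duplicated_column_raises_named_error(self):
        rng = np.random.default_rng(40)
        data = rng.standard_normal((100, 2))
        nuis = np.column_stack([np.linspace(-1, 1, 100)] * 2)  # trend duplicated
        with pytest.raises(CollinearityError, match="nuisance"):
            denoise(make_ts(data, nuisance=nuis), model=None, include_task=False)


class TestWeightedCorrelation:
    def test_equal_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(41)
        data = rng.standard_normal((300, 5))
        ts = make_ts(data)
        got = weighted_correlation_matrix(ts, np.ones(300)).values
        expected = np.corrcoef(data.T)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_binary_weights_equal_subset_pearson(self):
        rng = np.random.default_rng(42)
        data = rng.standard_normal((300, 4))
        w = (rng.random(300) < 0.4).astype(float)
        got = weighted_correlation_matrix(make_ts(data), w).values
        expected = np.corrcoef(data[w == 1].T)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(43)
        data = rng.standard_normal((250, 10))
        w = rng.random(250)
        got = weighted_correlation_matrix(make_ts(data), w).values
        wn = w / w.sum()
        for i in range(10):
            for j in range(i + 1, 10):
                x, y = data[:, i], data[:, j]
                xc, yc = x - wn @ x, y - wn @ y
                r = (wn * xc * yc).sum() / np.sqrt((wn * xc**2).sum() * (wn * yc**2).sum())
                assert got[i, j] == pytest.approx(r, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        ts = make_ts(np.random.default_rng(44).standard_normal((50, 3)))
        with pytest.raises(ValueError):
            weighted_correlation_matrix(ts, np.zeros(50))


class TestThreshold:
    def test_everything_below_cut_zeroed(self):
        m = matrix(np.full((4, 4), 0.2), "AABB")
        assert np.all(threshold_matrix(m, 0.25).values == 0)

    def test_cut_minus_one_keeps_offdiagonal(self):
        rng = np.random.default_rng(45)
        vals = np.clip(rng.standard_normal((5, 5)) * 0.3, -1, 1)
        vals = (vals + vals.T) / 2
        m = matrix(vals, "AABBB")
        out = threshold_matrix(m, -1.0)
        np.testing.assert_allclose(out.values, m.values)

    def test_exactly_entries_at_or_above_cut_survive(self):
        vals = np.array([[0, 0.24, 0.25], [0.24, 0, 0.6], [0.25, 0.6, 0]])
        out = threshold_matrix(matrix(vals, "ABC"), 0.25).values
        assert out[0, 1] == 0 and out[0, 2] == 0.25 and out[1, 2] == 0.6


def exhaustive_best_modularity(values):
    """Brute-force max modularity over every partition (Bell-number oracle)."""
    n = values.shape[0]
    best = -np.inf
    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part
    for part in partitions(list(range(n))):
        q = modularity_q(values, [set(c) for c in part])
        best = max(best, q)
    return best


class TestLouvain:
    def test_two_disconnected_cliques_give_half(self):
        block = np.ones((6, 6)) - np.eye(6)
        vals = np.block([[block, np.zeros((6, 6))], [np.zeros((6, 6)), block]])
        q, labels = louvain_modularity(matrix(vals, "A" * 6 + "B" * 6), seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_complete_uniform_graph_near_zero(self):
        vals = np.ones((8, 8)) - np.eye(8)
        q, _ = louvain_modularity(matrix(vals, "A" * 8), seed=0)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_empty_graph_defined_as_zero_with_singletons(self):
        q, labels = louvain_modularity(matrix(np.zeros((5, 5)), "AAABB"), seed=0)
        assert q == 0.0
        assert len(set(labels)) == 5

    def test_planted_blocks_match_exhaustive_oracle_on_nine_nodes(self):
        rng = np.random.default_rng(46)
        labels = np.repeat([0, 1, 2], 3)
        vals = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
        vals += rng.uniform(-0.02, 0.02, vals.shape)
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        q, got = louvain_modularity(matrix(vals, "AAABBBCCC"), seed=1, n_restarts=50)
        assert q == pytest.approx(exhaustive_best_modularity(vals), abs=0.01)
        for grp in (got[:3], got[3:6], got[6:]):
            assert len(set(grp)) == 1
        assert len(set(got[::3])) == 3

    def test_recovers_planted_partition_from_simulated_bold(self, one_subject_timeseries):
        ts = one_subject_timeseries
        clean = denoise(ts, None, include_task=False)
        mat = weighted_correlation_matrix(clean, np.ones(clean.data.shape[0]))
        q, labels = louvain_modularity(threshold_matrix(mat, 0.25), seed=2)
        truth = pd.factorize(np.asarray(ts.network_labels))[0]
        # PM and AT must separate; small hippocampus may join either
        pm = labels[np.asarray(ts.network_labels) == "PM"]
        at = labels[np.asarray(ts.network_labels) == "AT"]
        assert len(set(pm)) == 1 and len(set(at)) == 1 and pm[0] != at[0]

    def test_q_invariant_under_roi_permutation(self):
        rng = np.random.default_rng(47)
        vals = np.abs(rng.standard_normal((10, 10))) * 0.3
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        q1, _ = louvain_modularity(matrix(vals, "A" * 10), seed=3, n_restarts=50)
        perm = rng.permutation(10)
        q2, _ = louvain_modularity(matrix(vals[np.ix_(perm, perm)], "A" * 10),
                                   seed=3, n_restarts=50)
        assert q1 == pytest.approx(q2, abs=1e-9)


class TestDensity:
    def test_forced_within_between_values(self):
        labels = ("A",) * 3 + ("B",) * 3
        same = np.repeat([0, 1], 3)[:, None] == np.repeat([0, 1], 3)[None, :]
        vals = np.where(same, 0.5, 0.1)
        np.fill_diagonal(vals, 0.0)
        dens = network_density(threshold_matrix(matrix(vals, labels), 0.25))
        assert dens["within"] == pytest.approx(0.5)
        assert dens["between"] == pytest.approx(0.0)

    def test_uniform_matrix_gives_equal_densities(self):
        vals = np.full((6, 6), 0.4)
        dens = network_density(threshold_matrix(matrix(vals, "AAABBB"), 0.25))
        assert dens["within"] == pytest.approx(dens["between"])

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(48)
        vals = rng.uniform(0, 0.8, (12, 12))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        labels = ("PM",) * 5 + ("AT",) * 5 + ("HIPP",) * 2
        dens = network_density(matrix(vals, labels))
        within, between = [], []
        for i in range(12):
            for j in range(i + 1, 12):
                (within if labels[i] == labels[j] else between).append(vals[i, j])
        assert dens["within"] == pytest.approx(np.mean(within), abs=1e-12)
        assert dens["between"] == pytest.approx(np.mean(between), abs=1e-12)

    def test_higher_cut_never_increases_density(self):
        rng = np.random.default_rng(49)
        vals = rng.uniform(0, 0.6, (8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        m = matrix(vals, "AAAABBBB")
        prev = network_density(threshold_matrix(m, 0.0))
        for cut in (0.1, 0.2, 0.25, 0.3):
            cur = network_density(threshold_matrix(m, cut))
            assert cur["within"] <= prev["within"] + 1e-12
            assert cur["between"] <= prev["between"] + 1e-12
            prev = cur

    def test_surviving_edges_only_switch(self):
        vals = np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]], float)
        m = matrix(vals, "AAB")
        assert network_density(m, include_zeros=False)["within"] == pytest.approx(0.5)


class TestCompareConditions:
    def metrics(self, rng=None, effect=0.0):
        rng = rng or np.random.default_rng(50)
        n = 12
        base_q = rng.normal(0.4, 0.05, n)
        return pd.DataFrame({
            "Q_encoding": base_q,
            "Q_remember": base_q - effect + rng.normal(0, 0.02, n),
            "within_encoding": rng.normal(0.5, 0.05, n),
            "within_remember": rng.normal(0.5, 0.05, n),
            "between_encoding": rng.normal(0.1, 0.03, n),
            "between_remember": rng.normal(0.1 + effect, 0.03, n),
        })

    def test_identical_conditions_give_zero_stats(self):
        m = self.metrics()
        for col in ("Q", "within", "between"):
            m[f"{col}_remember"] = m[f"{col}_encoding"]
        table = compare_conditions(m).set_index("effect")
        # every task-dependent statistic vanishes; the within-vs-between
        # network main effect legitimately does not
        task_effects = ["modularity_remember_minus_encoding", "density_task_main",
                        "density_interaction_between_vs_within"]
        assert np.allclose(table.loc[task_effects, "value"], 0.0)

    def test_one_df_f_equals_squared_paired_t(self):
        from mnemonet.dependency import group_ttest
        m = self.metrics(effect=0.1)
        table = compare_conditions(m).set_index("effect")
        contrast = (m["between_remember"] - m["between_encoding"]) \
            - (m["within_remember"] - m["within_encoding"])
        t = group_ttest(contrast)["t"]
        assert table.loc["density_interaction_between_vs_within", "value"] \
            == pytest.approx(t ** 2)

    def test_planted_retrieval_effect_detected(self):
        table = compare_conditions(self.metrics(effect=0.15)).set_index("effect")
        assert table.loc["modularity_remember_minus_encoding", "value"] < 0
        assert table.loc["modularity_remember_minus_encoding", "p"] < 0.05
        assert table.loc["density_interaction_between_vs_within", "p"] < 0.05


class TestGroupAverage:
    def test_fisher_z_average_of_identical_matrices_is_identity(self):
        vals = np.array([[0, 0.5], [0.5, 0]], float)
        m = matrix(vals, "AB")
        avg = connectivity.group_average_matrix([m, m, m])
        np.testing.assert_allclose(avg.values, vals, atol=1e-12)
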