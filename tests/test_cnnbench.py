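"""Model construction, training, metrics, the paired t-test and selection."""

import math

import numpy as np
import pytest
from scipy.special import betainc

from neurotoxaug.cnnbench import (
    ConfigurationError,
    GridResult,
    MetricsReport,
    ModelSpec,
    TrainedModel,
    build_model,
    desk_grid,
    evaluate,
    make_grid,
    paired_t_test,
    paper_grid,
    select_best,
    train,
)
from neurotoxaug.datasets import EncodedBatch, one_hot_encode
from neurotoxaug.pepcore import Label, PeptideRecord
from neurotoxaug._nn import softmax


def _spec(**kw) -> ModelSpec:
    base = dict(block_type="conv_pool", n_blocks=1, filters=(4,),
                kernel_size=3, dense_units=8, learning_rate=0.005)
    base.update(kw)
    return ModelSpec(**base)


def _toy_batches(n_per_class=40, length=30, L_max=32):
    """Linearly separable toy data: positives all-C, negatives all-A."""
    pos = [PeptideRecord(id=f"p{i}", sequence="C" * length,
                         label=Label.NEUROTOXIC) for i in range(n_per_class)]
    neg = [PeptideRecord(id=f"n{i}", sequence="A" * length,
                         label=Label.NON_NEUROTOXIC) for i in range(n_per_class)]
    train_batch = one_hot_encode(pos[:30] + neg[:30], L_max)
    val_batch = one_hot_encode(pos[30:] + neg[30:], L_max)
    return train_batch, val_batch


class TestBuildModel:
    def test_repeat_index_does_not_change_parameter_count(self):
        a = build_model(_spec(repeat_index=1), L_max=64)
        b = build_model(_spec(repeat_index=3), L_max=64)
        assert a.n_parameters() == b.n_parameters()

    def test_softmax_head_is_a_probability_vector(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(50, 2)) * 10
        p = softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    def test_conv_conv_pool_depth_four_has_eight_convolutions(self):
        from neurotoxaug._nn import Conv1D

        spec = _spec(block_type="conv_conv_pool", n_blocks=4,
                     filters=(4, 8, 16, 32), kernel_size=3)
        net = build_model(spec, L_max=300)
        assert sum(isinstance(l, Conv1D) for l in net.layers) == 8

    def test_spatial_collapse_raises_at_build_time(self):
        spec = _spec(block_type="conv_conv_pool", n_blocks=4,
                     filters=(4, 8, 16, 32), kernel_size=5)
        with pytest.raises(ConfigurationError):
            build_model(spec, L_max=40)

    @pytest.mark.parametrize("kw", [
        {"block_type": "dense_only"}, {"n_blocks": 5, "filters": (4,) * 5},
        {"filters": (4, 8)}, {"repeat_index": 4},
    ])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            _spec(**kw)


class TestTrain:
    def test_separable_toy_problem_reaches_perfect_validation_f1(self):
        tr, va = _toy_batches()
        spec = _spec()
        net = build_model(spec, L_max=32, seed=0)
        model = train(net, tr, va, spec, seed=0, max_epochs=20, patience=20)
        assert max(h["val_f1"] for h in model.history) == 1.0

    def test_identical_seeds_give_identical_f1_traces(self):
        tr, va = _toy_batches()
        spec = _spec()
        traces = []
        for _ in range(2):
            net = build_model(spec, L_max=32, seed=3)
            model = train(net, tr, va, spec, seed=3, max_epochs=5, patience=5)
            traces.append([h["val_f1"] for h in model.history])
        assert traces[0] == traces[1]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        tr, va = _toy_batches()
        spec = _spec(learning_rate=0.0)
        net = build_model(spec, L_max=32, seed=1)
        before = [p.copy() for p in net.parameters]
        train(net, tr, va, spec, seed=1, max_epochs=1, patience=5)
        # best-epoch restore keeps the (unchanged) initial state
        for b, p in zip(before, net.parameters):
            assert np.array_equal(b, p)


class TestEvaluate:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = MetricsReport.from_counts(tp=50, tn=50, fp=0, fn=0)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_derived_confusion_case(self):
        m = MetricsReport.from_counts(tp=2, fp=1, fn=0, tn=1)
        assert m.precision == pytest.approx(2 / 3, abs=1e-12)
        assert m.recall == pytest.approx(1.0, abs=1e-12)
        assert m.f1 == pytest.approx(0.8, abs=1e-12)
        assert m.accuracy == pytest.approx(0.75, abs=1e-12)

    def test_undefined_metrics_are_flagged_not_zeroed(self):
        m = MetricsReport.from_counts(tp=0, tn=5, fp=0, fn=5)
        assert m.precision is None
        assert "precision" in m.undefined
        assert m.recall == 0.0
        assert m.f1 is None

    def test_all_positive_predictor_on_balanced_batch(self):
        class _AllPos:
            def predict(self, batch):
                return np.ones(batch.tensor.shape[0], dtype=int)

        batch = one_hot_encode(
            [PeptideRecord(id=f"p{i}", sequence="CC",
                           label=Label.NEUROTOXIC) for i in range(5)]
            + [PeptideRecord(id=f"n{i}", sequence="AA",
                             label=Label.NON_NEUROTOXIC) for i in range(5)],
            L_max=4,
        )
        m = evaluate(_AllPos(), batch)
        assert m.accuracy == 0.5
        assert m.recall == 1.0

    def test_metrics_agree_with_independent_formula_implementation(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            tp, tn, fp, fn = rng.integers(1, 40, size=4)
            m = MetricsReport.from_counts(int(tp), int(tn), int(fp), int(fn))
            # independent recomputation straight from the definitions
            assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert m.precision == pytest.approx(p, abs=1e-12)
            assert m.recall == pytest.approx(r, abs=1e-12)
            assert m.f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)


class TestPairedTTest:
    def test_symmetric_differences_give_t_zero_p_one(self):
        res = paired_t_test([2.0, 1.0], [1.0, 2.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_differences_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])

    def test_matches_independent_t_cdf_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            res = paired_t_test(a, b)
            d = a - b
            n = len(d)
            t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            # two-sided p via the regularized incomplete beta function
            df = n - 1
            p = betainc(df / 2.0, 0.5, df / (df + t * t))
            assert res.t_statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)


class TestGrid:
    def test_full_scale_grid_enumerates_864_cells(self):
        grid = paper_grid(n_folds=5)
        assert len(grid) == 864
        archs = {s.architecture_key for s in grid}
        assert len(archs) == 24
        assert {s.learning_rate for s in grid} == {0.005, 0.0001}
        assert len({s.train_source for s in grid}) == 6
        assert {s.repeat_index for s in grid} == {1, 2, 3}

    def test_desk_grid_enumerates_12_cells(self):
        grid = desk_grid(n_folds=5)
        assert len(grid) == 12
        assert len({s.cell_key for s in grid}) == 12

    def test_custom_cardinality_contract(self):
        grid = make_grid(n_folds=2, depths=(1,), base_filters=(8,),
                         learning_rates=(0.005,), repeats=2)
        # (2 folds + aug) sources x 2 block types x 1 x 1 x 2 repeats
        assert len(grid) == 3 * 2 * 2


class TestSelectBest:
    def _result(self, f1, n_params=100, lr=0.005, repeat=1):
        sim = MetricsReport.from_counts(tp=int(f1 * 100), tn=100,
                                        fp=max(1, 100 - int(f1 * 100)), fn=0)
        spec = _spec(learning_rate=lr, repeat_index=repeat)
        return GridResult(spec=spec, model=None, val_f1=f1,
                          test_metrics=sim, sim_metrics=sim,
                          n_parameters=n_params)

    def test_single_row_returns_itself(self):
        r = self._result(0.9)
        assert select_best([r]) is r

    def test_argmax_by_simulation_f1(self):
        lo, hi = self._result(0.5), self._result(0.93)
        assert select_best([lo, hi]) is hi

    def test_agrees_with_exhaustive_scan_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            rows = []
            for _ in range(50):
                tp = int(rng.integers(1, 100))
                fp = int(rng.integers(1, 100))
                fn = int(rng.integers(0, 100))
                m = MetricsReport.from_counts(tp=tp, tn=50, fp=fp, fn=fn)
                rows.append(GridResult(
                    spec=_spec(repeat_index=int(rng.integers(1, 4))),
                    model=None, val_f1=0.0, test_metrics=m, sim_metrics=m,
                    n_parameters=int(rng.integers(50, 500)),
                ))
            best = select_best(rows)
            max_f1 = max(r.sim_metrics.f1 for r in rows)
            assert best.sim_metrics.f1 == max_f1
            ties = [r for r in rows if r.sim_metrics.f1 == max_f1]
            assert best.n_parameters == min(t.n_parameters for t in ties)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_best([])
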