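"""Architecture accounting, forward-math primitives, the numpy engine and
the cross-validation harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brainmr as bm
from brainmr.cnn import (
    ArchitectureSpec,
    DivergenceError,
    LayerSpec,
    Network,
    OPTIMIZER_DEFAULTS,
    TrainConfig,
    batchnorm_forward,
    kfold_split,
    make_optimizer,
    softmax_cross_entropy,
    train_and_evaluate,
)


def tiny_spec(size: int = 12) -> ArchitectureSpec:
    """Smallest graph exercising every layer kind, for cheap engine tests."""
    layers = [
        LayerSpec("conv", kernel=3, stride=2, filters=4),
        LayerSpec("batchnorm"), LayerSpec("softplus"),
        LayerSpec("conv", kernel=3, stride=1, filters=4),
        LayerSpec("batchnorm"),
    ]
    mid = len(layers)
    layers += [
        LayerSpec("softplus"),
        LayerSpec("conv", kernel=1, stride=1, filters=4),
        LayerSpec("batchnorm"), LayerSpec("softplus"),
        LayerSpec("add", skip_from=mid),
        LayerSpec("avgpool", kernel=2, stride=2),
        LayerSpec("gap"), LayerSpec("dense", filters=2), LayerSpec("softmax"),
    ]
    return ArchitectureSpec(input_shape=(size, size, 3), layers=tuple(layers))


class TestShapes:
    @pytest.mark.parametrize("inp,k,s,f,expect", [
        ((224, 224, 3), 5, 2, 32, (110, 110, 32)),
        ((110, 110, 32), 3, 2, 48, (54, 54, 48)),
        ((7, 7, 128), 1, 1, 128, (7, 7, 128)),
    ])
    def test_valid_floor_formula(self, inp, k, s, f, expect):
        assert bm.conv_out_shape(inp, k, s, f) == expect

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            bm.conv_out_shape((4, 4, 1), 5, 1, 8)

    def test_trace_obeys_floor_formula_everywhere(self):
        spec = bm.build_architecture()
        trace = bm.shape_trace(spec)
        cur = trace[0][1]
        for (kind, shape), ly in zip(trace[1:], spec.layers):
            if kind in ("conv", "avgpool"):
                k = ly.kernel
                assert shape[0] == (cur[0] - k) // ly.stride + 1
            cur = shape if len(shape) == 3 else cur


class TestParamCounts:
    @pytest.mark.parametrize("k,cin,cout,expect", [
        (5, 3, 32, 2432),
        (3, 32, 48, 13872),
        (1, 64, 64, 4160),
        (3, 128, 128, 147584),
    ])
    def test_conv_counts(self, k, cin, cout, expect):
        assert bm.conv_param_count(k, cin, cout) == expect

    @pytest.mark.parametrize("c,total", [(32, 128), (48, 192)])
    def test_batchnorm_counts(self, c, total):
        tr, nt = bm.bn_param_count(c)
        assert tr + nt == total and tr == nt

    def test_dense_only_spec(self):
        spec = ArchitectureSpec(input_shape=(1, 1, 128),
                                layers=(LayerSpec("gap"),
                                        LayerSpec("dense", filters=2),
                                        LayerSpec("softmax")))
        assert bm.count_params(spec).total == 128 * 2 + 2 == 258

    def test_breakdown_sums_are_consistent(self):
        pb = bm.count_params(bm.build_architecture())
        assert pb.total == pb.trainable_total + pb.nontrainable_total
        assert pb.total == sum(t + n for _, t, n in pb.per_layer)


class TestPrimitives:
    def test_softplus_closed_form_and_asymptotes(self):
        assert bm.softplus(0.0) == pytest.approx(np.log(2.0))
        assert bm.softplus(-100.0) == pytest.approx(0.0, abs=1e-40)
        assert bm.softplus(100.0) == pytest.approx(100.0, rel=1e-12)

    def test_softplus_derivative_at_zero_is_half(self):
        h = 1e-6
        deriv = (bm.softplus(h) - bm.softplus(-h)) / (2 * h)
        assert deriv == pytest.approx(0.5, abs=1e-6)

    def test_softmax_symmetry_and_closed_form(self):
        assert np.allclose(bm.softmax([0.0, 0.0]), [0.5, 0.5])
        for c in (-3.0, 0.0, 11.0):
            assert np.allclose(bm.softmax([c, c + np.log(3.0)]), [0.25, 0.75])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(-100, 100))
    @settings(max_examples=50, derandomize=True)
    def test_softmax_normalizes_and_is_shift_invariant(self, logits, shift):
        p = bm.softmax(logits)
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(bm.softmax(np.asarray(logits) + shift), p, atol=1e-9)

    def test_batchnorm_constant_batch_outputs_shift(self):
        out = batchnorm_forward(np.full(5, 3.3), gamma=4.0, xi=0.7)
        assert np.allclose(out, 0.7)

    def test_batchnorm_standardized_batch_unchanged(self):
        out = batchnorm_forward(np.array([-1.0, 1.0]), eps=1e-15)
        assert np.allclose(out, [-1.0, 1.0])

    def test_batchnorm_worked_example(self):
        # batch {0,2,4}: mu=2, sigma^2=8/3, F_hat=(-1.2247,0,1.2247);
        # gamma=2, xi=1 -> (-1.44949, 1, 3.44949)
        out = batchnorm_forward(np.array([0.0, 2.0, 4.0]), gamma=2.0, xi=1.0,
                                eps=1e-15)
        assert np.allclose(out, [-1.4494897, 1.0, 3.4494897], atol=1e-6)


class TestEngine:
    def test_gradients_match_finite_differences(self, rng):
        spec = tiny_spec()
        net = Network(spec, seed=1)
        x = rng.random((4, 12, 12, 3)).astype(np.float32)
        y = np.array([0, 1, 0, 1])

        logits = net.forward(x, training=True)
        _, d = softmax_cross_entropy(logits, y)
        net.backward(d)
        params, grads = net.parameters(), net.gradients()
        for pi in range(0, len(params), 3):
            p, g = params[pi], grads[pi]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps, orig = 1e-3, p[idx]
            p[idx] = orig + eps
            lp = softmax_cross_entropy(net.forward(x, training=True), y)[0]
            p[idx] = orig - eps
            lm = softmax_cross_entropy(net.forward(x, training=True), y)[0]
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)

    def test_network_count_matches_analytic_breakdown(self):
        # dual route: counts of actually allocated arrays vs. the analytic
        # accounting from the declarative spec
        for spec in (tiny_spec(), bm.build_architecture(input_size=160)):
            pb = bm.count_params(spec)
            tr, nt = Network(spec, seed=0).num_params()
            assert (tr, nt) == (pb.trainable_total, pb.nontrainable_total)

    def test_bn_layer_matches_algorithmic_oracle(self, rng):
        from brainmr.cnn import _BatchNorm
        bn = _BatchNorm(3)
        bn.gamma[...] = 1.7
        bn.xi[...] = -0.3
        x = rng.random((6, 1, 1, 3)).astype(np.float32)
        out = bn.forward(x, training=True)
        expect = batchnorm_forward(x.reshape(6, 3), gamma=1.7, xi=-0.3,
                                   eps=bn.eps)
        assert np.allclose(out.reshape(6, 3), expect, atol=1e-5)

    def test_nan_loss_raises_divergence_naming_optimizer(self, rng):
        spec = tiny_spec()
        net = Network(spec, seed=0)
        net.parameters()[0][...] = np.nan
        X = rng.random((4, 12, 12, 3)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        from brainmr.cnn import train_network
        with pytest.raises(DivergenceError, match="adam"):
            train_network(net, X, y, TrainConfig(epochs=1, batch_size=4),
                          np.random.default_rng(0))

    def test_save_load_round_trip_preserves_predictions(self, tmp_path, rng):
        net = Network(bm.build_architecture(input_size=160), seed=3)
        x = rng.random((2, 160, 160, 3)).astype(np.float32)
        p1 = net.predict_proba(x)
        path = str(tmp_path / "model.npz")
        net.save(path)
        p2 = Network.load(path).predict_proba(x)
        assert np.allclose(p1, p2)


class TestOptimizers:
    @pytest.mark.parametrize("name", sorted(OPTIMIZER_DEFAULTS))
    def test_each_optimizer_descends_a_quadratic(self, name):
        w = np.array([3.0, -2.0], dtype=np.float32)
        # Adadelta's step is self-scaled by its update RMS, so it takes its
        # conventional unit learning rate; the others use a plain 0.05
        opt = make_optimizer(name, [w], lr=1.0 if name == "adadelta" else 0.05)
        start = float(np.sum(w**2))
        for _ in range(200):
            opt.step([2.0 * w])
        assert float(np.sum(w**2)) < 0.5 * start

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError):
            make_optimizer("lion", [np.zeros(2)])


class TestKFold:
    def test_partition_covers_all_indices_once(self):
        labels = ["normal"] * 4 + ["abnormal"] * 6
        folds = kfold_split(labels, 5, seed=0)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen.tolist()) == list(range(10))
        assert all(len(te) == 2 for _, te in folds)
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(10))
            assert not set(tr) & set(te)

    def test_same_seed_same_folds(self):
        labels = ["normal"] * 9 + ["abnormal"] * 11
        a = kfold_split(labels, 4, seed=5)
        b = kfold_split(labels, 4, seed=5)
        assert all(np.array_equal(x[1], y[1]) for x, y in zip(a, b))

    def test_stratification_within_one_sample_of_global_ratio(self):
        labels = ["normal"] * 60 + ["abnormal"] * 125
        for _, te in kfold_split(labels, 5, seed=2):
            n_norm = sum(labels[i] == "normal" for i in te)
            n_abn = len(te) - n_norm
            assert n_norm == 12 and n_abn == 25

    def test_matches_library_fold_structure(self):
        # scikit-learn's StratifiedKFold as the independent oracle for fold
        # sizes and per-fold class counts
        from sklearn.model_selection import StratifiedKFold
        y = np.array([0] * 13 + [1] * 22)
        ours = kfold_split(["normal"] * 13 + ["abnormal"] * 22, 5, seed=0)
        theirs = list(StratifiedKFold(5, shuffle=True, random_state=0)
                      .split(np.zeros(35), y))
        count = lambda folds: sorted(tuple(np.bincount(y[te], minlength=2))
                                     for _, te in folds)
        assert [len(te) for _, te in ours] == [len(te) for _, te in theirs]
        # the per-fold class-count multiset is identical; fold order is
        # implementation-specific
        assert count(ours) == count(theirs)

    def test_group_members_stay_in_one_fold(self):
        labels = (["normal"] * 6 + ["abnormal"] * 9) * 2
        groups = list(range(15)) * 2
        for tr, te in kfold_split(labels, 3, seed=1, groups=groups):
            te_groups = {groups[i] for i in te}
            tr_groups = {groups[i] for i in tr}
            assert not te_groups & tr_groups


class TestHarness:
    def test_single_class_dataset_rejected(self):
        img = bm.Image2D(np.zeros((8, 8)))
        ds = bm.LabeledDataset(images=[img] * 4, labels=[bm.NORMAL] * 4)
        with pytest.raises(ValueError):
            train_and_evaluate(ds, tiny_spec(), TrainConfig(folds=2))

    def test_reproducible_under_fixed_seed(self, small_dataset):
        cfg = TrainConfig(optimizer="adam", batch_size=4, epochs=2, folds=2,
                          seed=9, input_size=12)
        r1 = train_and_evaluate(small_dataset, tiny_spec(), cfg)
        r2 = train_and_evaluate(small_dataset, tiny_spec(), cfg)
        assert r1.histories == r2.histories
        assert [r.as_dict() for r in r1.fold_reports] == \
            [r.as_dict() for r in r2.fold_reports]

    def test_adadelta_does_not_beat_adam_on_separable_task(self):
        # qualitative optimizer ordering at equal budget: Adadelta's
        # effective step collapses, Adam separates the classes
        ds = bm.make_dataset(10, 14, bm.PhantomConfig(size=(64, 64), seed=2))
        accs = {}
        for name in ("adam", "adadelta"):
            cfg = TrainConfig(optimizer=name, batch_size=8, epochs=2, folds=2,
                              seed=4, input_size=144)
            accs[name] = train_and_evaluate(ds, None, cfg).summary["accuracy"][0]
        assert accs["adadelta"] <= accs["adam"]
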