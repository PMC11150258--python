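import numpy as np
import pytest

from conftest import make_toy_regression
from softsensor.adaptive_ensemble import (
    StackConfig,
    default_stack_config,
    fit_stacking,
    predict_stacking,
    run_mw_stacking,
    window_slice,
)
from softsensor.dataset import ProcessDataset
from softsensor.errors import DataError, WindowExhaustedError
from softsensor.models import ModelConfig, fit_model


def _toy_dataset(n=120, seed=0, noise=0.0):
    X, y = make_toy_regression(n=n, seed=seed, noise=noise)
    return ProcessDataset(X, y, [f"v{i}" for i in range(X.shape[1])])


_FAST = ModelConfig(mode="akbls", m_fourier=60, seed=0)


# ------------------------------------------------------------- window math
def test_window_slice_indexing():
    db = ProcessDataset(
        np.arange(300, dtype=float)[:, None], np.arange(300.0), ["t"]
    )
    w0 = window_slice(db, 0, 100, 10)
    np.testing.assert_array_equal(w0.X[:, 0], np.arange(0, 101))  # rows 0..100
    w2 = window_slice(db, 2, 100, 10)
    np.testing.assert_array_equal(w2.X[:, 0], np.arange(20, 121))  # rows 20..120


def test_window_slice_boundary_and_errors():
    db = ProcessDataset(np.zeros((151, 1)), np.zeros(151), ["t"])
    last = window_slice(db, 5, 100, 10)  # rows 50..150 == size-1
    assert len(last) == 101
    with pytest.raises(WindowExhaustedError):
        window_slice(db, 6, 100, 10)
    with pytest.raises(DataError):
        window_slice(db, -1, 100, 10)
    with pytest.raises(DataError):
        window_slice(db, 0, 0, 10)


# ---------------------------------------------------------------- stacking
def test_stack_config_validation():
    with pytest.raises(DataError):
        StackConfig(base_configs=(_FAST,)).validate()
    with pytest.raises(DataError):
        StackConfig(base_configs=(_FAST, _FAST, _FAST), n_folds=1).validate()
    cfg = default_stack_config(_FAST, seed=5)
    assert len(cfg.base_configs) == 3
    seeds = [b.seed for b in cfg.base_configs]
    assert len(set(seeds)) == 3


@pytest.mark.parametrize("k", [2, 5])
def test_meta_features_no_self_fold_leakage(k):
    data = _toy_dataset(n=100, seed=1)
    cfg = default_stack_config(_FAST, seed=0, n_folds=k, meta="linear")
    model = fit_stacking(data, cfg)
    assert model.meta_features.shape == (100, 3)
    assert np.isfinite(model.meta_features).all()
    # recompute one base's column for one fold from scratch: the fold's
    # meta-features must come from a model that never saw the fold
    fold = 0
    rows = np.flatnonzero(model.fold_of_row == fold)
    others = np.flatnonzero(model.fold_of_row != fold)
    ref = fit_model(data.take(others), cfg.base_configs[0]).predict(data.X[rows])
    np.testing.assert_allclose(model.meta_features[rows, 0], ref, rtol=1e-10)


def test_degenerate_ensemble_matches_single_base():
    data = _toy_dataset(n=90, seed=2, noise=0.05)
    test = _toy_dataset(n=40, seed=3)
    identical = StackConfig(base_configs=(_FAST, _FAST, _FAST), n_folds=3, meta="linear")
    stack = fit_stacking(data, identical)
    single = fit_model(data, _FAST)
    e_stack = np.sqrt(np.mean((stack.predict(test.X) - test.y) ** 2))
    e_single = np.sqrt(np.mean((single.predict(test.X) - test.y) ** 2))
    assert e_stack <= 1.02 * e_single + 1e-9


def test_linear_meta_not_much_worse_than_best_base():
    data = _toy_dataset(n=150, seed=4)
    test = _toy_dataset(n=60, seed=5)
    cfg = default_stack_config(_FAST, seed=1, meta="linear")
    stack = fit_stacking(data, cfg)
    base_rmse = [
        np.sqrt(np.mean((fit_model(data, bc).predict(test.X) - test.y) ** 2))
        for bc in cfg.base_configs
    ]
    ens_rmse = np.sqrt(np.mean((stack.predict(test.X) - test.y) ** 2))
    assert ens_rmse <= 1.1 * min(base_rmse)


def test_predict_stacking_shapes_and_permutation():
    data = _toy_dataset(n=80, seed=6)
    model = fit_stacking(data, default_stack_config(_FAST, seed=0, meta="linear"))
    one = predict_stacking(model, data.X[:1])
    assert one.shape == (1,)
    perm = np.random.default_rng(0).permutation(20)
    batch = predict_stacking(model, data.X[:20])
    np.testing.assert_allclose(predict_stacking(model, data.X[:20][perm]), batch[perm])


def test_gpr_meta_runs():
    data = _toy_dataset(n=80, seed=7, noise=0.05)
    model = fit_stacking(data, default_stack_config(_FAST, seed=0, meta="gpr"))
    assert np.isfinite(model.predict(data.X[:5])).all()


# ----------------------------------------------------------- moving window
def test_mw_degenerate_single_window():
    train = _toy_dataset(n=100, seed=8)
    test = _toy_dataset(n=30, seed=9)
    cfg = default_stack_config(_FAST, seed=0, meta="linear")
    res = run_mw_stacking(train, test, w_m=60, l=30, cfg=cfg, feedback="none")
    assert res.n_windows == 1
    m0 = (100 - 1 - 60) // 30
    static = fit_stacking(window_slice(train, m0, 60, 30), cfg)
    np.testing.assert_allclose(res.predictions, static.predict(test.X), rtol=1e-10)


def test_mw_window_bookkeeping():
    train = _toy_dataset(n=120, seed=10)
    test = _toy_dataset(n=100, seed=11)  # 5 chunks of l=20
    cfg = default_stack_config(_FAST, seed=0, meta="linear")
    res = run_mw_stacking(train, test, w_m=80, l=20, cfg=cfg, feedback="predicted")
    assert res.n_windows == 5
    assert len(res.predictions) == 100
    assert np.isfinite(res.predictions).all()
    assert sum(w["test_rows"] for w in res.windows) == 100


def test_mw_partial_final_chunk():
    train = _toy_dataset(n=120, seed=12)
    test = _toy_dataset(n=50, seed=13)  # 2 full chunks + 10 leftover
    cfg = default_stack_config(_FAST, seed=0, meta="linear")
    res = run_mw_stacking(train, test, w_m=80, l=20, cfg=cfg, feedback="true")
    assert res.n_windows == 2
    assert res.windows[-1]["test_rows"] == 10
    assert res.windows[-1]["refit"] is False


def test_mw_determinism():
    train = _toy_dataset(n=100, seed=14)
    test = _toy_dataset(n=40, seed=15)
    cfg = default_stack_config(_FAST, seed=7, meta="linear")
    a = run_mw_stacking(train, test, 60, 20, cfg, feedback="predicted")
    b = run_mw_stacking(train, test, 60, 20, cfg, feedback="predicted")
    np.testing.assert_array_equal(a.predictions, b.predictions)


def test_mw_validation():
    train = _toy_dataset(n=50)
    test = _toy_dataset(n=20)
    with pytest.raises(DataError, match="window length"):
        run_mw_stacking(train, test, w_m=50, l=10)
    with pytest.raises(DataError, match="feedback"):
        run_mw_stacking(train, test, w_m=30, l=10, feedback="oracle")


def test_mw_adaptivity_mapping_shift():
    # abrupt mean shift in the X->y mapping halfway through the stream:
    # the moving window (with delayed true labels) must beat the static
    # stack on the post-shift half
    rng = np.random.default_rng(0)

    def f(X):
        return np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + X[:, 2]

    names = ["v0", "v1", "v2"]
    Xtr = rng.normal(size=(200, 3))
    train = ProcessDataset(Xtr, f(Xtr), names)
    n = 240
    Xte = rng.normal(size=(n, 3))
    yte = f(Xte)
    yte[n // 2:] += 2.0
    test = ProcessDataset(Xte, yte, names)
    cfg = default_stack_config(ModelConfig(mode="akbls", m_fourier=100, seed=0), seed=0)
    static = fit_stacking(train, cfg).predict(test.X)
    mw = run_mw_stacking(train, test, w_m=n // 4, l=20, cfg=cfg, feedback="true")
    post = slice(n // 2, None)
    err_static = np.sqrt(np.mean((static[post] - yte[post]) ** 2))
    err_mw = np.sqrt(np.mean((mw.predictions[post] - yte[post]) ** 2))
    assert err_mw < err_static
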