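import numpy as np
import pytest

from csarima.clustering import ClusterSet
from csarima.forecaster import (
    ForecastError,
    ModelBundle,
    evaluable_origins,
    pp_target,
    predict_pp,
    prediction_pairs,
    start_pp,
    step,
)
from csarima.io_segmentation import PostprandialPeriod
from csarima.seasonal_models import sarima_forecast
from conftest import T0, ar1_spec, random_walk_spec


def _cluster_set(prototypes):
    prototypes = np.asarray(prototypes, dtype=float)
    return ClusterSet(
        n_clusters=len(prototypes),
        fuzzifier=2.0,
        prototypes=prototypes,
        memberships=np.zeros((0, len(prototypes))),
        objective_history=(),
        validity=0.0,
        seed=0,
    )


def _bundle(prototypes, models):
    return ModelBundle(cluster_set=_cluster_set(prototypes), models=tuple(models))


def _pp(window_fill, observed_length=48, presample_fill=100.0, meal_index=0):
    window = np.full(48, np.nan)
    window[:observed_length] = window_fill[:observed_length]
    return PostprandialPeriod(
        meal_index=meal_index,
        window=window,
        presamples=np.full(5, presample_fill),
        observed_length=observed_length,
        source_span=(T0, T0),
    )


@pytest.fixture()
def single_bundle():
    return _bundle([np.zeros(48)], [ar1_spec(phi=0.6, intercept=40.0)])


@pytest.fixture()
def dual_bundle():
    protos = [np.full(48, 90.0), np.full(48, 110.0)]
    models = [ar1_spec(phi=0.5, intercept=45.0), ar1_spec(phi=0.8, intercept=22.0)]
    return _bundle(protos, models)


# -------------------------------------------------------------------- start_pp


def test_ph_minutes_to_steps(single_bundle):
    state = start_pp(np.full(5, 100.0), single_bundle, ph_minutes=(30, 45, 60, 75))
    assert state.ph_steps == (6, 9, 12, 15)
    assert state.output is None  # fresh state has no output


def test_off_grid_horizon_rejected(single_bundle):
    with pytest.raises(ForecastError):
        start_pp(np.full(5, 100.0), single_bundle, ph_minutes=(7,))


def test_bundle_requires_one_model_per_cluster():
    with pytest.raises(ForecastError):
        ModelBundle(cluster_set=_cluster_set([np.zeros(48)]), models=())


# ------------------------------------------------------------------------ step


def test_no_output_before_third_observed_sample(single_bundle):
    state = start_pp(np.full(5, 100.0), single_bundle)
    for value in (101.0, 102.0):
        state = step(state, value)
        assert state.output is None
    state = step(state, 103.0)
    assert state.output is not None  # 3rd observed sample -> first output


def test_missing_samples_extend_burn_in(single_bundle):
    state = start_pp(np.full(5, 100.0), single_bundle)
    for value in (101.0, np.nan, 102.0):
        state = step(state, value)
        assert state.output is None
    state = step(state, 103.0)
    assert state.output is not None


def test_single_cluster_output_equals_sarima_forecast(single_bundle):
    model = single_bundle.models[0]
    pres = np.full(5, 100.0)
    state = start_pp(pres, single_bundle)
    history = [101.0, 102.0, 103.0, 104.0]
    for value in history:
        state = step(state, value)
    direct = sarima_forecast(model, np.concatenate([pres, history]), max(state.ph_steps))
    for ph, step_n in zip(state.ph_minutes, state.ph_steps):
        assert state.output[ph] == pytest.approx(direct[step_n - 1], rel=1e-12)


def test_equidistant_prefix_averages_local_forecasts(dual_bundle):
    pres = np.full(5, 100.0)
    state = start_pp(pres, dual_bundle)
    for value in (100.0, 100.0, 100.0):  # equidistant from both prototypes
        state = step(state, value)
    np.testing.assert_allclose(state.weights, [0.5, 0.5])
    for ph, step_n in zip(state.ph_minutes, state.ph_steps):
        mean_local = state.local_predictions[:, step_n - 1].mean()
        assert state.output[ph] == pytest.approx(mean_local, rel=1e-12)


def test_output_is_convex_combination(dual_bundle):
    rng = np.random.default_rng(3)
    state = start_pp(np.full(5, 100.0), dual_bundle)
    for value in 100 + rng.normal(0, 15, 12):
        state = step(state, float(value))
        if state.output is None:
            continue
        for ph, step_n in zip(state.ph_minutes, state.ph_steps):
            lo = state.local_predictions[:, step_n - 1].min()
            hi = state.local_predictions[:, step_n - 1].max()
            assert lo - 1e-9 <= state.output[ph] <= hi + 1e-9


def test_weights_frozen_on_missing_sample(dual_bundle):
    state = start_pp(np.full(5, 100.0), dual_bundle)
    for value in (95.0, 96.0, 97.0):
        state = step(state, value)
    frozen = state.weights.copy()
    state = step(state, np.nan)
    np.testing.assert_array_equal(state.weights, frozen)
    assert state.output is not None  # forecasts still produced


def test_stepping_past_window_end_errors(single_bundle):
    state = start_pp(np.full(5, 100.0), single_bundle)
    for _ in range(48):
        state = step(state, 100.0)
    with pytest.raises(ForecastError):
        step(state, 100.0)


def test_cluster_permutation_leaves_output_unchanged(dual_bundle):
    permuted = _bundle(
        dual_bundle.cluster_set.prototypes[::-1].copy(),
        dual_bundle.models[::-1],
    )
    s1 = start_pp(np.full(5, 100.0), dual_bundle)
    s2 = start_pp(np.full(5, 100.0), permuted)
    for value in (96.0, 99.0, 108.0, 104.0):
        s1 = step(s1, value)
        s2 = step(s2, value)
    for ph in s1.ph_minutes:
        assert s1.output[ph] == pytest.approx(s2.output[ph], rel=1e-12)


# ------------------------------------------------------------------ predict_pp


def test_predict_pp_matches_step_replay(dual_bundle):
    rng = np.random.default_rng(11)
    window = 100 + rng.normal(0, 10, 48)
    window[7] = np.nan
    pp = _pp(window, observed_length=30)
    traj = predict_pp(pp, dual_bundle)
    state = start_pp(pp.presamples, dual_bundle)
    outputs = {}
    for t in range(1, pp.observed_length + 1):
        state = step(state, pp.window[t - 1])
        if state.output is not None:
            outputs[t] = dict(state.output)
    for ph, rows in traj.items():
        assert rows, "no predictions produced"
        for t, y_hat, _ in rows:
            assert y_hat == pytest.approx(outputs[t][ph], rel=1e-9)


def test_predict_pp_single_cluster_oracle(single_bundle):
    """With one cluster the whole pipeline is plain SARIMA forecasting."""
    window = np.linspace(100, 150, 48)
    pp = _pp(window)
    traj = predict_pp(pp, single_bundle, ph_minutes=(30,))
    model = single_bundle.models[0]
    for t, y_hat, _ in traj[30]:
        history = np.concatenate([pp.presamples, pp.window[:t]])
        direct = sarima_forecast(model, history, 6)
        assert y_hat == pytest.approx(direct[5], rel=1e-9)


def test_pairing_index_arithmetic(dual_bundle):
    # observed_length 20, PH=75 (15 steps): pairs only for t in [3, 5]
    pp = _pp(np.full(48, 100.0), observed_length=20)
    traj = predict_pp(pp, dual_bundle, ph_minutes=(75,))
    paired_t = [t for t, _, target in traj[75] if not np.isnan(target)]
    assert paired_t == [3, 4, 5]
    # predictions exist beyond t=5 but are unpaired
    assert [t for t, _, _ in traj[75]] == list(range(3, 21))


def test_empty_ph_list_gives_empty_result(dual_bundle):
    pp = _pp(np.full(48, 100.0))
    assert predict_pp(pp, dual_bundle, ph_minutes=()) == {}


def test_random_walk_bundle_predicts_last_value():
    bundle = _bundle([np.full(48, 100.0)], [random_walk_spec()])
    window = np.array([100.0, 104.0, 98.0, 107.0] + [100.0] * 44)
    pp = _pp(window, observed_length=10)
    traj = predict_pp(pp, bundle, ph_minutes=(30,))
    for t, y_hat, _ in traj[30]:
        assert y_hat == pytest.approx(pp.window[t - 1], abs=1e-6)


# ------------------------------------------------------- shared pairing logic


def test_evaluable_origins_skip_burn_in_with_missing():
    window = np.full(48, np.nan)
    window[[0, 2, 4, 5, 6]] = 100.0
    pp = PostprandialPeriod(
        meal_index=0, window=window, presamples=np.full(5, 100.0),
        observed_length=7, source_span=(T0, T0),
    )
    # 3rd observed sample arrives at slot 5
    assert evaluable_origins(pp, burn_in=3) == [5, 6, 7]


def test_pp_target_rules():
    window = np.full(48, np.nan)
    window[:20] = 100.0
    window[10] = np.nan
    pp = _pp(window, observed_length=20)
    assert pp_target(pp, 3, 6) == 100.0
    assert np.isnan(pp_target(pp, 5, 6))  # lands on the missing slot 11
    assert np.isnan(pp_target(pp, 10, 15))  # beyond observed region (padding)


# ------------------------------------------------------------- bundle round-trip


def test_bundle_save_load_roundtrip(tmp_path, dual_bundle):
    path = tmp_path / "bundle.json"
    dual_bundle.save(path)
    back = ModelBundle.load(path)
    np.testing.assert_array_equal(
        back.cluster_set.prototypes, dual_bundle.cluster_set.prototypes
    )
    assert back.models[0].params == dual_bundle.models[0].params
    pp = _pp(np.full(48, 100.0), observed_length=12)
    a = predict_pp(pp, dual_bundle, ph_minutes=(30,))
    b = predict_pp(pp, back, ph_minutes=(30,))
    np.testing.assert_array_equal(np.asarray(a[30]), np.asarray(b[30]))
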