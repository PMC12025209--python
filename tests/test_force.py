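"""Tests for the static and dynamic muscle-force models."""

import numpy as np
import pandas as pd
import pytest

import wristemg as w


def test_printed_model_intercepts_at_zero_mav():
    """At MAV = 0 the published models return their intercepts exactly."""
    assert w.predict_static_force(w.PRINTED_STATIC_MODELS["U"], 0.0) == 4.863
    assert w.predict_static_force(w.PRINTED_STATIC_MODELS["E"], 0.0) == 3.410
    assert w.predict_static_force(w.PRINTED_STATIC_MODELS["F"], 0.0) == 3.615
    assert w.predict_static_force(w.PRINTED_STATIC_MODELS["R"], 0.0) == 1.765


def test_printed_model_prediction_arithmetic():
    model = w.PRINTED_STATIC_MODELS["R"]
    assert w.predict_static_force(model, 10.0) == pytest.approx(9.595)


def test_predict_rejects_negative_mav():
    with pytest.raises(ValueError):
        w.predict_static_force(w.PRINTED_STATIC_MODELS["U"], -1.0)


def exact_table(model, loads=(5.0, 20.0, 35.0, 50.0)):
    rows = [
        {
            "movement": model.movement,
            "load_N": load,
            "rep": 0,
            "MAV": (load - model.intercept) / model.slope,
        }
        for load in loads
    ]
    return w.LoadTrialTable(pd.DataFrame(rows))


def test_fit_recovers_exact_affine_data():
    truth = w.PRINTED_STATIC_MODELS["E"]
    fitted = w.fit_static_model(exact_table(truth), "E")
    assert fitted.slope == pytest.approx(truth.slope, rel=1e-12)
    assert fitted.intercept == pytest.approx(truth.intercept, rel=1e-12)


def test_fit_affine_equivariance():
    """Shifting every MAV by c leaves the slope unchanged and shifts the
    intercept by -slope * c."""
    truth = w.PRINTED_STATIC_MODELS["F"]
    table = exact_table(truth)
    shifted = w.LoadTrialTable(table.frame.assign(MAV=table.frame["MAV"] + 2.5))
    base = w.fit_static_model(table, "F")
    moved = w.fit_static_model(shifted, "F")
    assert moved.slope == pytest.approx(base.slope, rel=1e-10)
    assert moved.intercept == pytest.approx(
        base.intercept - base.slope * 2.5, rel=1e-9
    )


def test_fit_rejects_degenerate_tables():
    truth = w.PRINTED_STATIC_MODELS["E"]
    one_load = exact_table(truth, loads=(10.0,))
    with pytest.raises(ValueError, match="distinct loads"):
        w.fit_static_model(one_load, "E")
    constant = w.LoadTrialTable(
        pd.DataFrame(
            {
                "movement": ["E"] * 3,
                "load_N": [5.0, 10.0, 15.0],
                "rep": [0, 0, 0],
                "MAV": [2.0, 2.0, 2.0],
            }
        )
    )
    with pytest.raises(ValueError, match="singular"):
        w.fit_static_model(constant, "E")


def test_parameter_recovery_over_seeds():
    """Protocol-grid tables (10 loads x 3 reps, 0.5 N noise) recover the
    generating coefficients: slope within 0.05, intercept within 0.8 N,
    in each of 100 seeds."""
    truth = w.PRINTED_STATIC_MODELS["E"]
    for seed in range(100):
        table = w.simulate_load_table(truth, reps=3, noise_sd=0.5, seed=seed)
        fitted = w.fit_static_model(table, "E")
        assert abs(fitted.slope - truth.slope) < 0.05
        assert abs(fitted.intercept - truth.intercept) < 0.8


def test_dynamic_force_limiting_cases():
    accel = np.linspace(-5, 5, 11)
    # m = 0: pure no-load estimate
    params = w.DynamicForceParams(F0=3.0, mass=0.0, angular_acceleration=accel)
    assert np.array_equal(w.dynamic_force(params), np.full(11, 3.0))
    # static limit: a 10 N weight adds exactly 10 N when acceleration is 0
    params = w.DynamicForceParams(
        F0=3.0,
        mass=w.mass_from_weight(10.0),
        angular_acceleration=np.zeros(11),
    )
    assert w.dynamic_force(params) == pytest.approx(np.full(11, 13.0))


def test_dynamic_force_inertial_term():
    mass = w.mass_from_weight(10.0)  # 1.0194 kg
    params = w.DynamicForceParams(
        F0=0.0, mass=mass, angular_acceleration=np.array([10.0])
    )
    inertial = w.dynamic_force(params)[0] - mass * 9.81
    assert inertial == pytest.approx(mass * 0.07 * 10.0, rel=1e-12)
    assert inertial == pytest.approx(0.7136, abs=5e-4)


def test_dynamic_force_rejects_negative_mass():
    with pytest.raises(ValueError):
        w.DynamicForceParams(F0=0.0, mass=-1.0)


def test_estimate_from_constant_recording_is_stable():
    rec = w.generate_recording(
        "U", 10.0, w.GeneratorConfig(duration=6.0, seed=21)
    )
    trace = w.estimate_dynamic_from_semg(
        w.PRINTED_STATIC_MODELS["U"], rec, window_length=1.0
    )
    forces = trace["force_N"].to_numpy()
    assert np.ptp(forces) / forces.mean() < 0.05


def test_estimated_force_tracks_programmed_load_ramp():
    """Recordings at increasing loads give monotonically increasing
    estimated force through the fitted static model."""
    cfg = w.GeneratorConfig(duration=2.0, seed=22, load_gain=0.05)
    means = []
    for load in (0.0, 15.0, 30.0, 45.0):
        rec = w.generate_recording("E-L", load, cfg)
        trace = w.estimate_dynamic_from_semg(
            w.PRINTED_STATIC_MODELS["E"], rec, window_length=0.5
        )
        means.append(trace["force_N"].mean())
    assert all(a < b for a, b in zip(means, means[1:]))


def test_end_to_end_static_fit_from_generated_recordings():
    """Generate recordings over the 5..50 N protocol grid, compute MAVs,
    fit the static model, and predict held-out loads to < 1 N mean
    absolute error."""
    cfg = w.GeneratorConfig(duration=2.0, load_gain=0.05, seed=30)
    rows = []
    channel = 4  # a dominant channel for E-L in the default profile
    for load in w.PROTOCOL_LOADS:
        for rep in range(3):
            rec = w.generate_recording(
                "E-L", load, w.GeneratorConfig(
                    duration=2.0, load_gain=0.05, seed=30 + 100 * rep + int(load)
                )
            )
            rows.append(
                {
                    "movement": "E",
                    "load_N": load,
                    "rep": rep,
                    "MAV": w.mav(rec.samples[channel]),
                }
            )
    frame = pd.DataFrame(rows)
    train = frame[frame["load_N"] % 10 == 0]  # fit on 10,20,...,50
    held = frame[frame["load_N"] % 10 != 0]  # predict 5,15,...,45
    model = w.fit_static_model(w.LoadTrialTable(train), "E")
    held_mean = w.LoadTrialTable(held).mean_mav("E")
    predictions = w.predict_static_force(
        model, held_mean["MAV"].to_numpy()
    )
    mae = np.abs(predictions - held_mean["load_N"].to_numpy()).mean()
    assert mae < 1.0


def test_rmse_oracle_and_identities(rng):
    assert w.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert w.rmse(np.zeros(5) + 2.5, np.zeros(5)) == pytest.approx(2.5)
    for _ in range(10):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        oracle = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 50)
        assert w.rmse(a, b) == pytest.approx(oracle, rel=1e-12)
    with pytest.raises(ValueError):
        w.rmse([1.0], [1.0, 2.0])


def test_load_table_csv_roundtrip(tmp_path):
    table = w.simulate_load_table(w.PRINTED_STATIC_MODELS["U"], seed=3)
    path = tmp_path / "trials.csv"
    table.to_csv(path)
    back = w.LoadTrialTable.from_csv(path)
    assert np.allclose(back.frame["MAV"], table.frame["MAV"])
    refit = w.fit_static_model(back, "U")
    orig = w.fit_static_model(table, "U")
    assert refit.slope == pytest.approx(orig.slope)
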