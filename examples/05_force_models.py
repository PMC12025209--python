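"""Static and dynamic muscle-force estimation.

The static model is an affine map from sEMG amplitude (MAV) to force,
fitted per movement direction from load trials on a 5..50 N grid.  The
dynamic model adds the weight's gravity and the wrist's inertial term
F0 + m*g + m*r*beta_ddot(t) on top of the no-load estimate.
"""

import numpy as np

import wristemg as w

# --- static model: fit from a synthetic load-trial table ---
truth = w.PRINTED_STATIC_MODELS["E"]  # published extension model
table = w.simulate_load_table(truth, loads=w.PROTOCOL_LOADS, reps=3,
                              noise_sd=0.5, seed=1)
fitted = w.fit_static_model(table, "E")
print(f"published:  F_E = {truth.slope:.3f} * MAV + {truth.intercept:.3f}")
print(f"refitted:   F_E = {fitted.slope:.3f} * MAV + {fitted.intercept:.3f}")
# With 0.5 N measurement noise over 10 loads x 3 reps the fit recovers
# the generating coefficients to ~0.01 in slope.

print(f"\nulnar model at MAV=0: "
      f"{w.predict_static_force(w.PRINTED_STATIC_MODELS['U'], 0.0)} N "
      "(the model intercept: baseline muscle tone)")

# --- dynamic model: slow vs fast flexion with a 10 N weight ---
kin_slow = w.generate_kinematics(peak_angle=1.0, duration=4.0, speed_mode="slow")
kin_fast = w.generate_kinematics(peak_angle=1.0, duration=4.0, speed_mode="fast")
mass = w.mass_from_weight(10.0)
for name, kin in (("slow", kin_slow), ("fast", kin_fast)):
    params = w.DynamicForceParams(
        F0=3.0, mass=mass, angular_acceleration=kin.angular_acceleration)
    force = w.dynamic_force(params)
    print(f"{name} flexion: static level {3.0 + mass * 9.81:.2f} N, "
          f"peak dynamic force {force.max():.2f} N")
# Fast movement halves the movement time and quadruples the peak
# angular acceleration, so the inertial excursion is four times larger.

rm = w.rmse(force, np.full_like(force, force.mean()))
print(f"\nRMSE of the fast trace against its own mean: {rm:.2f} N "
      "(the spread the inertial term contributes)")
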