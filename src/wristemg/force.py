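"""EMG-driven muscle force estimation.

Two models link the wrist's sEMG amplitude to the force it exerts:

* the *static* model — for each movement direction, an affine map
  F = slope * MAV + intercept fitted by ordinary least squares of the
  external load (N) on the mean MAV measured under that load; and
* the *dynamic* model — F_dynamic(t) = F0 + m*g + m*r*beta_ddot(t),
  adding the weight's gravity and the inertial term of the wrist
  rotation (lever arm r = 70 mm by default) to the no-load estimate F0.

``PRINTED_STATIC_MODELS`` stores the published coefficient set for the
four directions (flexion, extension, radial, ulnar) as a fixture, so
force traces can be estimated without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import mav
from .synthetic import EMGRecording

GRAVITY = 9.81  # m/s^2
LEVER_ARM = 0.07  # m, wrist rotation centre to the handle load

#: Protocol load grid: 5 N to 50 N in 5 N steps.
PROTOCOL_LOADS: tuple[float, ...] = tuple(float(l) for l in range(5, 55, 5))

FORCE_DIRECTIONS = ("F", "E", "R", "U")


@dataclass(frozen=True)
class StaticForceModel:
    """Affine MAV-to-force map for one movement direction."""

    movement: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.movement not in FORCE_DIRECTIONS:
            raise ValueError(
                f"movement must be one of {FORCE_DIRECTIONS}, "
                f"got {self.movement!r}"
            )
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("slope and intercept must be finite")


#: Published static model coefficients (slope N per MAV unit, intercept N).
PRINTED_STATIC_MODELS: dict[str, StaticForceModel] = {
    "F": StaticForceModel("F", 1.021, 3.615),
    "E": StaticForceModel("E", 1.125, 3.410),
    "R": StaticForceModel("R", 0.783, 1.765),
    "U": StaticForceModel("U", 0.459, 4.863),
}


@dataclass
class LoadTrialTable:
    """Tidy table of load-trial measurements with columns
    ``movement, load_N, rep, MAV``."""

    frame: pd.DataFrame

    REQUIRED = ("movement", "load_N", "rep", "MAV")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.frame["load_N"] < 0).any():
            raise ValueError("loads must be nonnegative")

    def mean_mav(self, movement: str) -> pd.DataFrame:
        """Mean MAV per load for one movement, averaged over reps."""
        sub = self.frame[self.frame["movement"] == movement]
        if sub.empty:
            raise ValueError(f"no rows for movement {movement!r}")
        return (
            sub.groupby("load_N", as_index=False)["MAV"].mean()
            .sort_values("load_N", ignore_index=True)
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LoadTrialTable":
        return cls(pd.read_csv(path))


def fit_static_model(table: LoadTrialTable, movement: str) -> StaticForceModel:
    """Least-squares fit of load (N, response) on mean MAV (predictor)
    for one movement; requires at least two distinct loads and
    non-constant MAV."""
    agg = table.mean_mav(movement)
    if agg["load_N"].nunique() < 2:
        raise ValueError("need at least 2 distinct loads to fit")
    x = agg["MAV"].to_numpy(dtype=float)
    y = agg["load_N"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all MAVs identical: singular fit")
    slope, intercept = np.polyfit(x, y, 1)
    return StaticForceModel(movement, float(slope), float(intercept))


def predict_static_force(model: StaticForceModel, mav_value) -> float:
    """Estimated force (N) from an MAV value through the affine model."""
    arr = np.asarray(mav_value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MAV must be nonnegative")
    out = model.slope * arr + model.intercept
    return float(out) if out.ndim == 0 else out


def simulate_load_table(
    model: StaticForceModel,
    loads: tuple[float, ...] = PROTOCOL_LOADS,
    reps: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> LoadTrialTable:
    """Synthetic load-trial table consistent with an affine MAV-force
    law: for each load L and repetition, MAV = (L + eps - intercept) /
    slope with eps ~ N(0, noise_sd^2) in force units.  Used for
    parameter-recovery checks of ``fit_static_model``."""
    if model.slope == 0:
        raise ValueError("slope must be nonzero to invert the model")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for load in loads:
        for rep in range(reps):
            eps = rng.normal(0.0, noise_sd)
            mav_val = (load + eps - model.intercept) / model.slope
            rows.append(
                {
                    "movement": model.movement,
                    "load_N": load,
                    "rep": rep,
                    "MAV": mav_val,
                }
            )
    return LoadTrialTable(pd.DataFrame(rows))


@dataclass
class DynamicForceParams:
    """Inputs of the dynamic force model: no-load estimate F0 (N), the
    weight's mass (kg), gravity (m/s^2), the wrist lever arm (m), and
    the angular-acceleration trace (rad/s^2)."""

    F0: float
    mass: float
    angular_acceleration: np.ndarray = field(default_factory=lambda: np.zeros(1))
    gravity: float = GRAVITY
    lever_arm: float = LEVER_ARM

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be nonnegative")
        self.angular_acceleration = np.asarray(
            self.angular_acceleration, dtype=float
        )


def mass_from_weight(weight_newtons: float, gravity: float = GRAVITY) -> float:
    """Mass (kg) of a weight specified by its gravitational force (N)."""
    if weight_newtons < 0:
        raise ValueError("weight must be nonnegative")
    return weight_newtons / gravity


def dynamic_force(params: DynamicForceParams) -> np.ndarray:
    """Dynamic force trace F0 + m*g + m*r*beta_ddot(t), elementwise."""
    return (
        params.F0
        + params.mass * params.gravity
        + params.mass * params.lever_arm * params.angular_acceleration
    )


def estimate_dynamic_from_semg(
    model: StaticForceModel,
    recording: EMGRecording,
    window_length: float = 1.0,
    window_step: float | None = None,
    channels: list[int] | None = None,
) -> pd.DataFrame:
    """Estimated force trace from a recording: the per-window MAV
    (averaged across the selected channels) passed through the static
    model.  Returns a frame with columns ``t`` (window centres, s) and
    ``force_N``."""
    if window_step is None:
        window_step = window_length
    win = int(round(window_length * recording.sampling_rate))
    step = int(round(window_step * recording.sampling_rate))
    if win < 1 or step < 1:
        raise ValueError("window too short for the sampling rate")
    if recording.n_samples < win:
        raise ValueError("recording shorter than one window")
    if channels is None:
        channels = list(range(recording.n_channels))
    times, forces = [], []
    n_windows = (recording.n_samples - win) // step + 1
    for w in range(n_windows):
        start = w * step
        seg = recording.samples[channels, start : start + win]
        window_mav = float(np.mean([mav(seg[i]) for i in range(len(channels))]))
        times.append((start + win / 2.0) / recording.sampling_rate)
        forces.append(predict_static_force(model, window_mav))
    return pd.DataFrame({"t": times, "force_N": forces})


def rmse(estimated, reference) -> float:
    """Root-mean-square error between two equal-length force traces (N)."""
    a = np.asarray(estimated, dtype=float).ravel()
    b = np.asarray(reference, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"trace lengths differ: {a.shape} vs {b.shape}"
        )
    return float(np.sqrt(np.mean(np.square(a - b))))
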