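"""Synthetic surface-EMG generator for the wrist-movement pipeline.

Emulates an 8-channel forearm armband recording seven wrist states:
flexion small/large (F-S, F-L), extension small/large (E-S, E-L),
radial deviation (R), ulnar deviation (U), and relaxation (RELAX).

The signal model is deliberately simple: each channel carries zero-mean
band-limited Gaussian noise whose amplitude is movement- and
load-dependent.  A movement is encoded by an *activation profile* — a
row of per-channel amplitude factors — and an external load scales the
amplitude linearly.  For zero-mean Gaussian noise with standard
deviation sigma, E[MAV] = sigma * sqrt(2/pi), so the generator rescales
each channel so that its expected mean-absolute-value equals

    activation_profile[movement, channel] * (base_amplitude + load_gain * load).

This reproduces the two statistical facts the downstream pipeline relies
on: movements are separable in expected-MAV space, and MAV is affine in
the external load (the premise of the static force model).  It does not
model motor units, electrode shift, or fatigue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

#: Canonical movement labels, in the fixed order used throughout the package.
MOVEMENTS: tuple[str, ...] = ("F-S", "F-L", "E-S", "E-L", "R", "U", "RELAX")

#: The designated rest state; it never triggers a robot command.
RELAX = "RELAX"

N_CHANNELS = 8


def validate_movement(movement: str) -> str:
    if movement not in MOVEMENTS:
        raise ValueError(
            f"unknown movement {movement!r}; expected one of {MOVEMENTS}"
        )
    return movement


def default_activation_profile() -> np.ndarray:
    """Default 7x8 movement-by-channel amplitude factors.

    Each non-rest movement has two dominant channels (1.0), two moderate
    (0.5) and four weak (0.15); relaxation is uniformly low (0.05).  The
    dominant pair rotates around the electrode ring so every row is
    distinct, mimicking the channel-specific bursts of a real armband.
    """
    profile = np.full((len(MOVEMENTS), N_CHANNELS), 0.15)
    for j in range(6):  # the six active movements
        profile[j, [j % 8, (j + 1) % 8]] = 1.0
        profile[j, [(j + 2) % 8, (j + 3) % 8]] = 0.5
    profile[6, :] = 0.05  # RELAX
    return profile


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic sEMG generator.

    Amplitudes are in arbitrary but internally consistent signal units;
    the load enters as newtons through ``load_gain`` (units per N).
    """

    sampling_rate: float = 1000.0
    duration: float = 30.0
    seed: int = 0
    activation_profile: np.ndarray = field(
        default_factory=default_activation_profile
    )
    base_amplitude: float = 1.0
    load_gain: float = 0.02
    band: tuple[float, float] = (20.0, 450.0)

    def __post_init__(self) -> None:
        profile = np.asarray(self.activation_profile, dtype=float)
        object.__setattr__(self, "activation_profile", profile)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if profile.shape != (len(MOVEMENTS), N_CHANNELS):
            raise ValueError(
                f"activation_profile must be {len(MOVEMENTS)}x{N_CHANNELS}, "
                f"got {profile.shape}"
            )
        if np.any(profile < 0):
            raise ValueError("activation_profile factors must be nonnegative")
        relax_row = profile[MOVEMENTS.index(RELAX)]
        others = np.delete(profile, MOVEMENTS.index(RELAX), axis=0)
        if not np.all(relax_row < others):
            raise ValueError(
                "RELAX activation must be strictly below every other "
                "movement on every channel"
            )
        for i in range(len(MOVEMENTS)):
            for j in range(i + 1, len(MOVEMENTS)):
                if np.allclose(profile[i], profile[j]):
                    raise ValueError(
                        f"activation_profile rows {MOVEMENTS[i]} and "
                        f"{MOVEMENTS[j]} coincide; classes would be "
                        "inseparable in expectation"
                    )
        if self.load_gain < 0:
            raise ValueError("load_gain must be nonnegative")
        low, high = self.band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError(
                f"degenerate band {self.band}: need 0 < low < high < "
                f"sampling_rate/2 = {self.sampling_rate / 2}"
            )


@dataclass
class EMGRecording:
    """A multichannel sEMG recording: channels x time samples."""

    samples: np.ndarray
    sampling_rate: float
    label: str | None = None
    load: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label is not None:
            validate_movement(self.label)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def to_csv(self, path) -> None:
        """Write as delimited text: a commented metadata preamble, then
        a header row ``t,ch1..chN`` and one sample per row."""
        meta = {
            "sampling_rate": self.sampling_rate,
            "label": self.label,
            "load": self.load,
        }
        t = np.arange(self.n_samples) / self.sampling_rate
        header = "t," + ",".join(f"ch{c + 1}" for c in range(self.n_channels))
        with open(path, "w") as fh:
            fh.write(f"# wristemg-recording {json.dumps(meta)}\n")
            fh.write(header + "\n")
            for i in range(self.n_samples):
                row = ",".join(f"{v:.10g}" for v in self.samples[:, i])
                fh.write(f"{t[i]:.10g},{row}\n")

    @classmethod
    def from_csv(cls, path) -> "EMGRecording":
        meta = {"sampling_rate": None, "label": None, "load": None}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# wristemg-recording"):
                meta.update(json.loads(first.split(None, 2)[2]))
                skip = 1
            else:
                skip = 0
        data = np.loadtxt(path, delimiter=",", skiprows=skip + 1)
        data = np.atleast_2d(data)
        t = data[:, 0]
        samples = data[:, 1:].T
        rate = meta["sampling_rate"]
        if rate is None:
            dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
            rate = 1.0 / dt
        return cls(
            samples=samples,
            sampling_rate=float(rate),
            label=meta["label"],
            load=meta["load"],
        )


@dataclass
class KinematicTrace:
    """Wrist angle trajectory: time (s), angle beta (rad), and angular
    acceleration (rad/s^2), with the acceleration supplied analytically."""

    time: np.ndarray
    angle: np.ndarray
    angular_acceleration: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.angular_acceleration = np.asarray(
            self.angular_acceleration, dtype=float
        )
        if not (
            len(self.time) == len(self.angle) == len(self.angular_acceleration)
        ):
            raise ValueError("time, angle, and acceleration lengths differ")


def _band_limited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    band: tuple[float, float],
    sampling_rate: float,
) -> np.ndarray:
    """White Gaussian noise band-passed and renormalised to unit
    standard deviation per channel (zero-phase filtering, so the
    Gaussianity of the carrier is preserved)."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(
        4, band, btype="bandpass", fs=sampling_rate, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, white, axis=1)
    std = filtered.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return filtered / std


def _generate(
    movement: str, load: float, config: GeneratorConfig, rng: np.random.Generator
) -> EMGRecording:
    n = int(round(config.duration * config.sampling_rate))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    carrier = _band_limited_noise(
        rng, N_CHANNELS, n, config.band, config.sampling_rate
    )
    row = config.activation_profile[MOVEMENTS.index(movement)]
    target_mav = row * (config.base_amplitude + config.load_gain * load)
    # E[|X|] = sigma * sqrt(2/pi) for X ~ N(0, sigma^2)
    sigma = target_mav * np.sqrt(np.pi / 2.0)
    samples = carrier * sigma[:, None]
    return EMGRecording(
        samples=samples,
        sampling_rate=config.sampling_rate,
        label=movement,
        load=load,
    )


def generate_recording(
    movement: str, load: float, config: GeneratorConfig
) -> EMGRecording:
    """Generate one seeded recording of ``movement`` under ``load`` (N).

    Channel ``c`` has expected MAV equal to
    ``activation_profile[movement, c] * (base_amplitude + load_gain * load)``.
    The same (movement, load, config) always yields bit-identical output.
    """
    validate_movement(movement)
    if load < 0:
        raise ValueError(f"load must be nonnegative, got {load}")
    rng = np.random.default_rng(config.seed)
    return _generate(movement, load, config, rng)


def generate_dataset(
    reps_per_movement: int,
    loads: list[float] | None = None,
    config: GeneratorConfig | None = None,
) -> list[EMGRecording]:
    """Balanced labeled dataset: ``reps_per_movement`` recordings for each
    of the seven movements, cycling through ``loads`` across repetitions.

    Each recording draws from an independent child stream of the config
    seed, so no two recordings share a noise realisation, yet the whole
    dataset is deterministic under the seed.
    """
    if reps_per_movement < 1:
        raise ValueError("reps_per_movement must be >= 1")
    if config is None:
        config = GeneratorConfig()
    if loads is None:
        loads = [0.0]
    if any(l < 0 for l in loads):
        raise ValueError("loads must be nonnegative")
    children = np.random.SeedSequence(config.seed).spawn(
        len(MOVEMENTS) * reps_per_movement
    )
    recordings = []
    idx = 0
    for movement in MOVEMENTS:
        for rep in range(reps_per_movement):
            rng = np.random.default_rng(children[idx])
            load = loads[rep % len(loads)]
            recordings.append(_generate(movement, load, config, rng))
            idx += 1
    return recordings


def generate_label_stream(
    truth: list[str], frame_accuracy: float, seed: int
) -> list[str]:
    """Corrupt a ground-truth label stream with iid per-frame errors.

    Each frame is kept with probability ``frame_accuracy``; otherwise it
    is replaced by a label drawn uniformly from the six other movements.
    This is the null model for the majority-vote smoothing experiments.
    """
    if not truth:
        raise ValueError("truth stream must be nonempty")
    if not 0.0 <= frame_accuracy <= 1.0:
        raise ValueError("frame_accuracy must be in [0, 1]")
    for label in set(truth):
        validate_movement(label)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(truth)) < frame_accuracy
    picks = rng.integers(0, len(MOVEMENTS) - 1, size=len(truth))
    out = []
    for i, label in enumerate(truth):
        if keep[i]:
            out.append(label)
        else:
            others = [m for m in MOVEMENTS if m != label]
            out.append(others[picks[i]])
    return out


def _min_jerk(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk unit profile s(tau) on [0,1] and its second
    derivative with respect to tau."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    s2 = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, s2


def generate_kinematics(
    peak_angle: float,
    duration: float,
    speed_mode: str = "slow",
    sampling_rate: float = 1000.0,
) -> KinematicTrace:
    """Smooth out-and-back wrist flexion/extension trajectory.

    The angle rises from 0 to ``peak_angle`` along a minimum-jerk
    profile and returns to 0 the same way.  The movement occupies half
    the trace in slow mode and a quarter in fast mode (centred), so fast
    mode halves the movement time and quadruples the peak angular
    acceleration.  The acceleration is returned analytically.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if speed_mode not in ("slow", "fast"):
        raise ValueError("speed_mode must be 'slow' or 'fast'")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    movement_time = duration / 2.0 if speed_mode == "slow" else duration / 4.0
    half = movement_time / 2.0
    t0 = (duration - movement_time) / 2.0

    angle = np.zeros(n)
    accel = np.zeros(n)

    rising = (t >= t0) & (t < t0 + half)
    tau_r = (t[rising] - t0) / half
    s, s2 = _min_jerk(tau_r)
    angle[rising] = peak_angle * s
    accel[rising] = peak_angle * s2 / half**2

    falling = (t >= t0 + half) & (t <= t0 + movement_time)
    tau_f = 1.0 - (t[falling] - t0 - half) / half
    s, s2 = _min_jerk(tau_f)
    angle[falling] = peak_angle * s
    accel[falling] = peak_angle * s2 / half**2  # chain rule: (d tau/dt)^2

    return KinematicTrace(time=t, angle=angle, angular_acceleration=accel)


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Convenience: a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
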