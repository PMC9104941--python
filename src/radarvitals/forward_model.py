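"""Synthetic FMCW radar forward model for chest-displacement vital signs.

Implements the physics of a 77 GHz frequency-modulated continuous-wave
(FMCW) radar observing a single subject: a chest-displacement scenario
(breathing + heartbeat + optional random body movement), synthesis of the
intermediate-frequency (IF) data cube with the slow-time phase term
4*pi*R(t)/lambda, and a seeded generator of RR-interval cohorts (normal vs
arrhythmic) so every downstream stage is testable without hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import AliasingError, InvalidArgumentError, LengthError

SPEED_OF_LIGHT = 299_792_458.0  # m/s

#: raised-cosine heartbeat pulse occupies this fraction of each beat period
DEFAULT_HEART_DUTY = 0.2


# ---------------------------------------------------------------------------
# configuration / scenario types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChirpConfig:
    """FMCW waveform parameters.

    Defaults follow a 77 GHz radar sweeping 4 GHz in a 50 us chirp with a
    2 Msps ADC and a 20 chirps/s slow axis (512 chirps per 25.6 s
    observation).

    Attributes
    ----------
    fc : chirp start frequency (Hz)
    bandwidth : sweep bandwidth B (Hz)
    chirp_duration : T_C (s)
    fast_sample_interval : ADC sampling period T_f (s)
    slow_sample_interval : chirp repetition period T_s (s)
    n_fast : ADC samples per chirp
    n_chirps : chirps per observation
    tx_amplitude : transmitted amplitude A_T (linear)
    rx_scale : reflection scale beta (dimensionless, >= 0)
    rx_power : received power P_R (linear); IF amplitude is sqrt(P_R)
    antenna_spacing : receive-antenna spacing d_m (m); default lambda/2
    """

    fc: float = 77e9
    bandwidth: float = 4e9
    chirp_duration: float = 50e-6
    fast_sample_interval: float = 0.5e-6
    slow_sample_interval: float = 0.05
    n_fast: int = 100
    n_chirps: int = 512
    tx_amplitude: float = 1.0
    rx_scale: float = 1.0
    rx_power: float = 1.0
    antenna_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.fc <= 0 or self.bandwidth <= 0:
            raise InvalidArgumentError("fc and bandwidth must be positive")
        if self.n_fast < 1 or self.n_chirps < 1:
            raise InvalidArgumentError("sample counts must be >= 1")
        if self.n_fast * self.fast_sample_interval > self.chirp_duration * (1 + 1e-12):
            raise InvalidArgumentError(
                "fast-time sampling window exceeds the chirp duration"
            )
        if self.slow_sample_interval < self.chirp_duration:
            raise InvalidArgumentError(
                "slow_sample_interval must be >= chirp_duration"
            )
        if self.rx_scale < 0:
            raise InvalidArgumentError("rx_scale must be >= 0")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / fc (m)."""
        return SPEED_OF_LIGHT / self.fc

    @property
    def slope(self) -> float:
        """Chirp slope B / T_C (Hz/s)."""
        return self.bandwidth / self.chirp_duration

    @property
    def range_bin_size(self) -> float:
        """Range-FFT bin width c / (2 B) (m)."""
        return SPEED_OF_LIGHT / (2.0 * self.bandwidth)

    @property
    def slow_rate(self) -> float:
        """Slow-time sampling rate 1 / T_s (Hz)."""
        return 1.0 / self.slow_sample_interval

    @property
    def d_m(self) -> float:
        return (
            self.antenna_spacing
            if self.antenna_spacing is not None
            else self.wavelength / 2.0
        )


class RBMEvent(NamedTuple):
    """One random-body-movement burst: Hann-shaped displacement bump."""

    start: float  # s
    duration: float  # s
    amplitude: float  # m


@dataclass(frozen=True)
class DisplacementScenario:
    """Ground-truth chest-displacement scenario.

    Breathing is sinusoidal, the heartbeat a sharp raised-cosine pulse
    train (duty 0.2), and random body movement (RBM) a list of Hann-shaped
    displacement bursts.  ``orientation_gain`` attenuates the vital-sign
    displacement to emulate off-axis (back/left/right) orientations.
    """

    base_range: float = 0.5  # m
    breathing_amplitude: float = 0.004  # m
    breathing_freq: float = 0.3  # Hz (0.1-0.5)
    heart_amplitude: float = 0.0003  # m
    heart_freq: float = 1.2  # Hz (0.8-2)
    angle_of_arrival: float = 0.0  # rad
    phase_noise_sd: float = 0.0  # rad, per-chirp random-walk increment
    rbm_events: tuple[RBMEvent, ...] = ()
    duration: float = 25.6  # s
    orientation_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.base_range <= 0:
            raise InvalidArgumentError("base_range must be positive")
        if self.breathing_amplitude < 0 or self.heart_amplitude < 0:
            raise InvalidArgumentError("amplitudes must be >= 0")
        if not 0 < self.orientation_gain <= 1:
            raise InvalidArgumentError("orientation_gain must lie in (0, 1]")
        object.__setattr__(
            self, "rbm_events", tuple(RBMEvent(*e) for e in self.rbm_events)
        )
        for ev in self.rbm_events:
            if ev.start < 0 or ev.start + ev.duration > self.duration + 1e-12:
                raise InvalidArgumentError(
                    f"RBM event {ev} lies outside [0, duration]"
                )

    def with_(self, **kw) -> "DisplacementScenario":
        return replace(self, **kw)


@dataclass
class IFDataCube:
    """Complex IF samples indexed [chirp l, fast sample k], with provenance."""

    samples: np.ndarray
    config: ChirpConfig
    truth: DisplacementScenario | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        expected = (self.config.n_chirps, self.config.n_fast)
        if self.samples.shape != expected:
            raise LengthError(
                f"cube shape {self.samples.shape} != (n_chirps, n_fast) {expected}"
            )
        if not np.all(np.isfinite(self.samples.view(float))):
            raise InvalidArgumentError("cube contains non-finite samples")


# ---------------------------------------------------------------------------
# displacement synthesis
# ---------------------------------------------------------------------------

def heartbeat_pulse(phase: np.ndarray, duty: float = DEFAULT_HEART_DUTY) -> np.ndarray:
    """Periodic raised-cosine heartbeat pulse of unit peak amplitude.

    ``phase`` is the instantaneous angle 2*pi*f_h*t; within each period the
    pulse occupies the first ``duty`` fraction, peaking at duty/2, and is
    zero elsewhere.  The sharp pulse gives downstream peak detection
    well-defined maxima, unlike a pure sinusoid.
    """
    u = np.mod(np.asarray(phase, dtype=float) / (2.0 * math.pi), 1.0)
    out = np.zeros_like(u)
    inside = u < duty
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * math.pi * u[inside] / duty))
    return out


def _rbm_waveform(t: np.ndarray, events: Sequence[RBMEvent]) -> np.ndarray:
    out = np.zeros_like(t)
    for ev in events:
        if ev.duration <= 0:
            continue
        inside = (t >= ev.start) & (t <= ev.start + ev.duration)
        u = (t[inside] - ev.start) / ev.duration
        out[inside] += ev.amplitude * 0.5 * (1.0 - np.cos(2.0 * math.pi * u))
    return out


def simulate_chest_displacement(
    scenario: DisplacementScenario, rate: float
) -> np.ndarray:
    """Uniformly sampled radar range R(t) in metres.

    R(t) = R0 + g*(b_amp*sin(2 pi f_b t) + h_amp*pulse(2 pi f_h t)) + rbm(t)
    with g the orientation gain and ``pulse`` the raised-cosine heartbeat
    shape.  Length is round(duration * rate).
    """
    if rate <= 0:
        raise InvalidArgumentError("rate must be positive")
    if scenario.heart_amplitude > 0 and not 0 < scenario.heart_freq < rate / 2:
        raise AliasingError(
            f"heart_freq {scenario.heart_freq} Hz outside (0, rate/2)"
        )
    n = int(round(scenario.duration * rate))
    if n < 2:
        raise InvalidArgumentError("duration * rate must be >= 2 samples")
    t = np.arange(n) / rate
    vital = scenario.breathing_amplitude * np.sin(
        2.0 * math.pi * scenario.breathing_freq * t
    )
    vital += scenario.heart_amplitude * heartbeat_pulse(
        2.0 * math.pi * scenario.heart_freq * t
    )
    return (
        scenario.base_range
        + scenario.orientation_gain * vital
        + _rbm_waveform(t, scenario.rbm_events)
    )


def displacement_from_beats(
    beat_times: Sequence[float],
    duration: float,
    rate: float,
    heart_amplitude: float = 0.0003,
    breathing_amplitude: float = 0.004,
    breathing_freq: float = 0.3,
    base_range: float = 0.5,
    duty: float = DEFAULT_HEART_DUTY,
) -> np.ndarray:
    """Chest displacement with heartbeat pulses at explicit beat times.

    Unlike :func:`simulate_chest_displacement` the heartbeat here is
    aperiodic: one raised-cosine pulse per entry of ``beat_times`` whose
    width is ``duty`` times the local inter-beat gap.  Used to turn an
    RR-interval sequence (e.g. an arrhythmic one) into a radar scene.
    """
    beat_times = np.asarray(sorted(beat_times), dtype=float)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    disp = base_range + breathing_amplitude * np.sin(
        2.0 * math.pi * breathing_freq * t
    )
    gaps = np.diff(beat_times)
    for i, bt in enumerate(beat_times):
        if len(gaps) == 0:
            local = 1.0
        else:
            local = gaps[min(i, len(gaps) - 1)]
        width = duty * local
        inside = (t >= bt) & (t <= bt + width)
        disp[inside] += heart_amplitude * 0.5 * (
            1.0 - np.cos(2.0 * math.pi * (t[inside] - bt) / width)
        )
    return disp


# ---------------------------------------------------------------------------
# IF cube synthesis
# ---------------------------------------------------------------------------

def synthesize_if_cube(
    displacement: np.ndarray,
    config: ChirpConfig,
    angle_of_arrival: float = 0.0,
    noise_sd: float = 0.0,
    phase_noise_sd: float = 0.0,
    seed: int | None = None,
    truth: DisplacementScenario | None = None,
) -> IFDataCube:
    """Synthesize the IF data cube from a slow-time range series.

    Each entry is sqrt(P_R) * beta * exp(j*(2 pi f_b k T_f
    + 4 pi R(l T_s)/lambda + 2 pi d_m sin(theta)/lambda)) with the beat
    frequency f_b = slope * 2 R_bar / c held constant across chirps
    (R_bar = mean range; chest motion is orders of magnitude below one
    range bin so the fast-time tone is chirp-invariant).  Optional additive
    complex Gaussian noise of ``noise_sd`` per component, and a slow-time
    phase-noise random walk of per-chirp increment ``phase_noise_sd``.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.ndim != 1 or len(displacement) < config.n_chirps:
        raise LengthError(
            f"displacement length {displacement.shape} shorter than "
            f"n_chirps {config.n_chirps}"
        )
    r = displacement[: config.n_chirps]
    lam = config.wavelength
    f_b = config.slope * 2.0 * float(np.mean(r)) / SPEED_OF_LIGHT
    k = np.arange(config.n_fast)
    fast_phase = 2.0 * math.pi * f_b * k * config.fast_sample_interval
    slow_phase = 4.0 * math.pi * r / lam
    slow_phase = slow_phase + 2.0 * math.pi * config.d_m * math.sin(
        angle_of_arrival
    ) / lam
    rng = np.random.default_rng(seed)
    if phase_noise_sd > 0:
        slow_phase = slow_phase + np.cumsum(
            rng.normal(0.0, phase_noise_sd, size=config.n_chirps)
        )
    amp = math.sqrt(config.rx_power) * config.rx_scale
    cube = amp * np.exp(1j * (slow_phase[:, None] + fast_phase[None, :]))
    if noise_sd > 0:
        cube = cube + rng.normal(0.0, noise_sd, cube.shape) + 1j * rng.normal(
            0.0, noise_sd, cube.shape
        )
    return IFDataCube(samples=cube, config=config, truth=truth)


def simulate_observation(
    scenario: DisplacementScenario,
    config: ChirpConfig | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> IFDataCube:
    """Scenario -> displacement -> IF cube in one seeded call."""
    config = config or ChirpConfig()
    disp = simulate_chest_displacement(scenario, config.slow_rate)
    return synthesize_if_cube(
        disp,
        config,
        angle_of_arrival=scenario.angle_of_arrival,
        noise_sd=noise_sd,
        phase_noise_sd=scenario.phase_noise_sd,
        seed=seed,
        truth=scenario,
    )


# ---------------------------------------------------------------------------
# RR-interval cohort generator
# ---------------------------------------------------------------------------

class CohortSubject(NamedTuple):
    rr_intervals: np.ndarray  # s
    age: int  # yr
    gender_code: int  # male=1, female=0
    label: int  # arrhythmic=1, normal=0


def draw_rr_sequence(
    rng: np.random.Generator,
    arrhythmic: bool,
    n_beats: int = 30,
    mean_rr: float | None = None,
) -> np.ndarray:
    """Draw one RR-interval sequence (seconds).

    Normal subjects: multiplicative Gaussian jitter with sd 3% of the mean
    (coefficient of variation ~0.03).  Arrhythmic subjects: 15% jitter plus
    ectopic-like events at 15% incidence, each a short interval (40-60% of
    the mean) followed by a compensatory long one (140-170%), giving CoV of
    roughly 0.15-0.3.  Intervals are clipped to the physiological
    [0.3, 2.0] s band.
    """
    if arrhythmic:
        mu = mean_rr if mean_rr is not None else rng.uniform(0.6, 1.1)
        rr = mu * (1.0 + 0.15 * rng.standard_normal(n_beats))
        i = 0
        while i < n_beats - 1:
            if rng.uniform() < 0.15:
                rr[i] = mu * rng.uniform(0.4, 0.6)
                rr[i + 1] = mu * rng.uniform(1.4, 1.7)
                i += 2
            else:
                i += 1
    else:
        mu = mean_rr if mean_rr is not None else rng.uniform(0.7, 1.0)
        rr = mu * (1.0 + 0.03 * rng.standard_normal(n_beats))
    return np.clip(rr, 0.3, 2.0)


def simulate_rr_cohort(
    n_subjects: int,
    class_mix: float,
    seed: int,
    n_beats: int = 30,
) -> list[CohortSubject]:
    """Seeded cohort of RR sequences with exact class counts.

    ``round(n_subjects * class_mix)`` subjects are labelled arrhythmic; the
    label order is shuffled deterministically.  Ages span 20-83 years and
    both genders appear, mirroring a mixed screening cohort.
    """
    if n_subjects < 2:
        raise InvalidArgumentError("n_subjects must be >= 2")
    if not 0.0 <= class_mix <= 1.0:
        raise InvalidArgumentError("class_mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_arr = int(round(n_subjects * class_mix))
    labels = np.array([1] * n_arr + [0] * (n_subjects - n_arr))
    rng.shuffle(labels)
    cohort = []
    for lab in labels:
        rr = draw_rr_sequence(rng, arrhythmic=bool(lab), n_beats=n_beats)
        age = int(rng.integers(20, 84))
        gender = int(rng.integers(0, 2))
        cohort.append(CohortSubject(rr, age, gender, int(lab)))
    return cohort


# ---------------------------------------------------------------------------
# delimited-text I/O for cubes and series
# ---------------------------------------------------------------------------

def save_cube_text(cube: IFDataCube, path) -> None:
    """One row per chirp; complex samples as "re,im" pairs separated by tabs."""
    with open(path, "w") as fh:
        for row in cube.samples:
            fh.write(
                "\t".join(f"{v.real:.12g},{v.imag:.12g}" for v in row) + "\n"
            )


def load_cube_text(path, config: ChirpConfig) -> IFDataCube:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            pairs = [p.split(",") for p in line.split("\t")]
            rows.append([complex(float(a), float(b)) for a, b in pairs])
    return IFDataCube(samples=np.asarray(rows), config=config)
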