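"""Synthetic IR-UWB monostatic radar scenes.

An impulse-radio ultra-wideband (IR-UWB) monostatic radar emits short
Gaussian-modulated pulses and samples the returning echo at a fixed fast-time
rate.  One *frame* is the vector of echo amplitudes over fast time: each bin
corresponds to a two-way propagation delay, i.e. a range cell of width
``c * dt / 2``.  A person in the room contributes a handful of dominant point
scatterers (torso, legs, arms) whose range and reflectivity evolve over slow
time according to the activity performed; static surfaces (walls, furniture)
contribute clutter that is shared with a no-target reference frame; indoor
multipath adds delayed, attenuated ghost copies of every target echo.

This module builds such scenes point-scatterer by point-scatterer and renders
frame sequences with the bookkeeping of a real collection campaign: six
activity classes, multiple virtual subjects, a laboratory (empty) and a
lounge (heavily furnished) environment profile, a no-target reference frame
per recording, and one master seed from which every per-recording random
stream is derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Callable, Sequence

import numpy as np

SPEED_OF_LIGHT = 299_792_458.0

#: slow-time key reserved for the no-target reference frame noise stream
_REFERENCE_SLOW_INDEX = 1_000_003

_SEED_MASK = 0x7FFFFFFF


class ActivityLabel(IntEnum):
    """The six monitored activities, integer-coded 1..6.

    ``FALLING`` is the designated positive class for fall detection.
    """

    STANDING_STILL = 1
    FALLING = 2
    LYING_STILL = 3
    STANDING_UP = 4
    WALKING = 5
    JUMPING = 6


N_CLASSES = 6
FALL_CLASS = int(ActivityLabel.FALLING)


@dataclass(frozen=True)
class PulseParams:
    """Radar pulse and fast-time sampling parameters.

    Defaults follow a 4 GHz carrier with 1.7 GHz bandwidth sampled every
    61 ps, 800 range bins starting at 0.9 m — a room extent of about
    0.9–8.2 m with ~0.9 cm range resolution.
    """

    center_frequency: float = 4e9
    bandwidth: float = 1.7e9
    fast_time_step: float = 61e-12
    n_bins: int = 800
    range_offset: float = 0.9

    @property
    def bin_width(self) -> float:
        """Two-way range extent of one fast-time bin, c*dt/2 (meters)."""
        return SPEED_OF_LIGHT * self.fast_time_step / 2.0

    @property
    def extent(self) -> float:
        """Total covered range extent in meters."""
        return self.n_bins * self.bin_width

    @property
    def max_range(self) -> float:
        return self.range_offset + self.extent

    def validate(self) -> None:
        if self.fast_time_step <= 0:
            raise ValueError("fast_time_step must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.center_frequency <= 0 or self.bandwidth <= 0:
            raise ValueError("center_frequency and bandwidth must be positive")

    def with_bins(self, n_bins: int) -> "PulseParams":
        """Return params with ``n_bins`` bins covering the *same* room extent.

        The fast-time step is rescaled so coarser frames still span the full
        0.9–8.2 m room; used for desk-scale experiments.
        """
        scale = self.n_bins / n_bins
        return replace(self, n_bins=n_bins, fast_time_step=self.fast_time_step * scale)


@dataclass
class Scatterer:
    """A point scatterer: range and reflectivity as functions of slow time.

    ``part`` tags the body part ("torso", "legs", "arms") or "clutter";
    furnished environments attenuate leg echoes (furniture blocks low body
    parts) and multipath ghosts attach only to non-clutter scatterers.
    """

    range_fn: Callable[[float], float]
    reflectivity_fn: Callable[[float], float]
    is_static: bool = False
    part: str = "torso"
    meta: dict = field(default_factory=dict)

    @staticmethod
    def static_point(r: float, reflectivity: float, part: str = "clutter") -> "Scatterer":
        return Scatterer(
            range_fn=lambda t, _r=r: _r,
            reflectivity_fn=lambda t, _a=reflectivity: _a,
            is_static=True,
            part=part,
        )


@dataclass
class SceneConfig:
    """A simulated room: pulse, clutter, multipath, noise, and acquisition.

    ``occlusion_attenuation`` scales leg-scatterer reflectivity (1.0 = no
    occlusion, as in an empty lab; ~0.3 emulates furniture blocking legs).
    ``raw_margin_bins`` extends raw frames beyond ``n_bins`` so that the
    window-translation augmentation can slide without running out of data.
    Ghost delays are excess two-way path lengths in meters (0.09-0.73 m,
    i.e. 10-80 bins at full 61 ps resolution) so the multipath geometry is
    independent of the fast-time sampling density.  Identical
    (config, seed) produce bit-identical output.
    """

    pulse: PulseParams = field(default_factory=PulseParams)
    clutter: tuple = ()
    multipath_ghosts: int = 2
    ghost_delay_m: tuple = (0.09, 0.73)
    ghost_attenuation: tuple = (0.1, 0.4)
    noise_sigma: float = 0.02
    occlusion_attenuation: float = 1.0
    frame_rate: float = 5.0
    environment_id: str = "lab"
    rng_seed: int = 0
    raw_margin_bins: int = 40

    def validate(self) -> None:
        self.pulse.validate()
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.occlusion_attenuation <= 1.0):
            raise ValueError("occlusion_attenuation must be in [0, 1]")
        lo, hi = self.ghost_attenuation
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("ghost attenuation factors must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.raw_margin_bins < 0:
            raise ValueError("raw_margin_bins must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """A virtual test subject; diversity emulates a small volunteer panel."""

    height: float = 175.0  # cm
    weight: float = 70.0  # kg
    gait_speed: float = 1.0  # m/s
    reflectivity_scale: float = 0.9  # dimensionless, <= 1

    def validate(self) -> None:
        if min(self.height, self.weight, self.gait_speed, self.reflectivity_scale) <= 0:
            raise ValueError("all subject attributes must be positive")


@dataclass
class RadarFrame:
    """One fast-time amplitude vector at a given slow-time index."""

    amplitudes: np.ndarray
    slow_time_index: int


@dataclass
class RawRecording:
    """An M-frame echo stack with its no-target reference and labels."""

    frames: np.ndarray  # (M, n_bins_raw)
    reference: np.ndarray  # (n_bins_raw,)
    label: ActivityLabel
    subject_id: str
    environment_id: str

    def __post_init__(self) -> None:
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D (M, n_bins) array")
        if self.reference.shape != (self.frames.shape[1],):
            raise ValueError("reference length must match frame length")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_bins_raw(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# pulse template and range geometry


def generate_pulse(params: PulseParams) -> np.ndarray:
    """Gaussian-modulated cosine pulse template sampled over fast time.

    The envelope sigma is set from the -10 dB spectral full width ``B`` via
    the Fourier-width relation ``sigma_t = sqrt(ln 10) / (pi * B)``, so the
    template's -10 dB power-spectrum width equals the configured bandwidth.
    Unit peak amplitude; support truncated at +/-4 sigma (capped at n_bins
    samples so a near-zero-bandwidth limit degenerates to a windowed
    sinusoid rather than an unbounded array).
    """
    params.validate()
    if params.bandwidth >= 2.0 * params.center_frequency:
        raise ValueError("bandwidth must be below twice the center frequency")
    sigma = math.sqrt(math.log(10.0)) / (math.pi * params.bandwidth)
    half = int(round(4.0 * sigma / params.fast_time_step))
    half = min(half, params.n_bins)
    if half < 1:
        raise ValueError("pulse support shorter than one fast-time sample")
    t = np.arange(-half, half + 1, dtype=float) * params.fast_time_step
    p = np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(2.0 * math.pi * params.center_frequency * t)
    return p / np.max(np.abs(p))


def range_to_bin(r: float, params: PulseParams) -> int:
    """Map a two-way range (meters) to its fast-time bin index (0-based)."""
    params.validate()
    if r < params.range_offset - 1e-9 or r > params.max_range + 1e-9:
        raise ValueError(
            f"range {r:.3f} m outside covered extent "
            f"[{params.range_offset:.3f}, {params.max_range:.3f}] m"
        )
    return int(round((r - params.range_offset) / params.bin_width))


def _add_pulse(amp: np.ndarray, template: np.ndarray, center_bin: int, scale: float) -> None:
    half = len(template) // 2
    lo = center_bin - half
    hi = center_bin + half + 1
    s0 = max(0, -lo)
    e0 = len(template) - max(0, hi - len(amp))
    if s0 >= e0:
        return
    amp[max(lo, 0) : min(hi, len(amp))] += scale * template[s0:e0]


# ---------------------------------------------------------------------------
# frame rendering


def simulate_frame(
    scene: SceneConfig,
    scatterers: Sequence[Scatterer],
    t: float,
    *,
    raw: bool = False,
    slow_index: int | None = None,
) -> RadarFrame:
    """Render one echo frame at slow time ``t`` (seconds).

    The frame is the superposition of pulse templates centered at each
    scatterer's range bin (scene clutter included), plus multipath ghost
    copies for every non-clutter scatterer, plus white Gaussian noise.
    Ghost delays/attenuations are drawn once per scatterer from the scene
    seed, so they persist across the frames of a recording; the noise stream
    is keyed by the slow-time index.  ``raw=True`` extends the frame by
    ``raw_margin_bins`` for window augmentation.
    """
    scene.validate()
    pulse = scene.pulse
    n = pulse.n_bins + (scene.raw_margin_bins if raw else 0)
    amp = np.zeros(n, dtype=float)
    template = generate_pulse(pulse)
    seed = int(scene.rng_seed) & _SEED_MASK
    if slow_index is None:
        slow_index = int(round(t * scene.frame_rate))

    all_scatterers = list(scene.clutter) + list(scatterers)
    for idx, sc in enumerate(all_scatterers):
        r = float(np.clip(sc.range_fn(t), pulse.range_offset, pulse.max_range))
        refl = float(np.clip(sc.reflectivity_fn(t), 0.0, 1.0))
        if sc.part == "legs":
            refl *= scene.occlusion_attenuation
        b = range_to_bin(r, pulse)
        _add_pulse(amp, template, b, refl)
        if sc.part != "clutter" and scene.multipath_ghosts > 0:
            grng = np.random.default_rng(np.random.SeedSequence([seed, 7919, idx]))
            lo, hi = scene.ghost_delay_m
            for _ in range(scene.multipath_ghosts):
                delay = max(1, int(round(grng.uniform(lo, hi) / pulse.bin_width)))
                atten = float(grng.uniform(*scene.ghost_attenuation))
                _add_pulse(amp, template, b + delay, refl * atten)

    if scene.noise_sigma > 0:
        nrng = np.random.default_rng(np.random.SeedSequence([seed, int(slow_index)]))
        amp += nrng.normal(0.0, scene.noise_sigma, size=n)
    return RadarFrame(amplitudes=amp, slow_time_index=int(slow_index))


# ---------------------------------------------------------------------------
# activity kinematics


def _smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def activity_trajectory(
    label: ActivityLabel,
    subject: SubjectProfile,
    start_range: float,
    duration: float,
    seed: int,
) -> list[Scatterer]:
    """Build 3 target scatterers (torso, legs, arms) for one activity bout.

    Kinematics per class: standing still = millimetric jitter; falling =
    monotone range/reflectivity transition over 1–2 s then static (the radar
    sits at torso height, so a lying body returns much less energy);
    lying still = static, reduced reflectivity; standing up = reverse
    transition over 2–4 s; walking = linear drift at gait speed with
    periodic leg micro-motion; jumping = periodic oscillation dominated by
    the legs.
    """
    subject.validate()
    label = ActivityLabel(label)  # raises ValueError on unknown labels
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & _SEED_MASK, int(label)]))
    s = subject.reflectivity_scale
    torso_a, legs_a, arms_a = 1.0 * s, 0.6 * s, 0.35 * s
    r0 = float(start_range)

    def const(v: float) -> Callable[[float], float]:
        return lambda t, _v=v: _v

    if label == ActivityLabel.STANDING_STILL:
        ph = rng.uniform(0.0, 2.0 * math.pi, size=3)
        jit = lambda t, p: 0.002 * math.sin(2.0 * math.pi * 0.9 * t + p)
        return [
            Scatterer(lambda t, p=ph[0]: r0 + jit(t, p), const(torso_a), part="torso"),
            Scatterer(lambda t, p=ph[1]: r0 + 0.12 + jit(t, p), const(legs_a), part="legs"),
            Scatterer(lambda t, p=ph[2]: r0 - 0.08 + jit(t, p), const(arms_a), part="arms"),
        ]

    if label == ActivityLabel.LYING_STILL:
        # body horizontal on the floor, below torso height: weak, spread echo
        return [
            Scatterer(const(r0), const(0.35 * s), is_static=True, part="torso"),
            Scatterer(const(r0 + 0.5), const(0.25 * s), is_static=True, part="legs"),
            Scatterer(const(r0 - 0.2), const(0.15 * s), is_static=True, part="arms"),
        ]

    if label in (ActivityLabel.FALLING, ActivityLabel.STANDING_UP):
        if label == ActivityLabel.FALLING:
            tau = float(rng.uniform(1.0, 2.0))
        else:
            tau = float(rng.uniform(2.0, min(4.0, max(2.1, duration - 0.2))))
        t0 = float(rng.uniform(0.1, max(0.11, duration - tau - 0.1)))
        # a standing body pivots roughly one body length into the room
        dr = 0.65 * subject.height / 100.0
        rising = label == ActivityLabel.STANDING_UP  # reflectivity recovers

        def prog(t: float) -> float:
            p = _smoothstep((t - t0) / tau)
            return 1.0 - p if rising else p

        torso = Scatterer(
            lambda t: r0 + dr * prog(t),
            lambda t: s * (1.0 - 0.65 * prog(t)),
            part="torso",
            meta={"transition_s": tau, "onset_s": t0, "range_shift_m": dr},
        )
        legs = Scatterer(
            lambda t: r0 + 0.12 + 0.3 * dr * prog(t),
            lambda t: 0.6 * s * (1.0 - 0.4 * prog(t)),
            part="legs",
        )
        arms = Scatterer(
            lambda t: r0 - 0.08 + 0.6 * dr * prog(t),
            lambda t: 0.35 * s * (1.0 - 0.4 * prog(t)),
            part="arms",
        )
        return [torso, legs, arms]

    if label == ActivityLabel.WALKING:
        v = subject.gait_speed
        ph = rng.uniform(0.0, 2.0 * math.pi, size=2)

        def torso_r(t: float) -> float:
            return r0 + v * t  # direction fixed toward far wall; caller sizes r0

        legs = Scatterer(
            lambda t, p=ph[0]: torso_r(t) + 0.1 + 0.1 * math.sin(2.0 * math.pi * 1.8 * t + p),
            const(legs_a),
            part="legs",
        )
        arms = Scatterer(
            lambda t, p=ph[1]: torso_r(t) - 0.05 + 0.08 * math.sin(2.0 * math.pi * 1.8 * t + p),
            const(arms_a),
            part="arms",
        )
        return [Scatterer(torso_r, const(torso_a), part="torso"), legs, arms]

    # JUMPING: rhythmic bounce; the center of mass rises ~0.2-0.3 m per
    # jump and the tucked legs swing even more, so both the range and the
    # echo amplitude of the merged body return oscillate strongly
    f = 1.6
    ph = rng.uniform(0.0, 2.0 * math.pi)
    torso = Scatterer(
        lambda t: r0 + 0.2 * math.sin(2.0 * math.pi * f * t + ph),
        lambda t: s * (1.0 - 0.25 * abs(math.sin(2.0 * math.pi * f * t + ph))),
        part="torso",
    )
    legs = Scatterer(
        lambda t: r0 + 0.12 + 0.3 * math.sin(2.0 * math.pi * f * t + ph),
        lambda t: 0.6 * s * (1.0 + 0.45 * math.sin(2.0 * math.pi * f * t + ph)),
        part="legs",
    )
    arms = Scatterer(
        lambda t: r0 - 0.08 + 0.15 * math.sin(2.0 * math.pi * f * t + ph),
        const(arms_a),
        part="arms",
    )
    return [torso, legs, arms]


# ---------------------------------------------------------------------------
# scene and dataset factories


def make_scene(
    environment: str = "lab",
    pulse: PulseParams | None = None,
    seed: int = 0,
    noise_sigma: float = 0.02,
) -> SceneConfig:
    """Build a lab (empty) or lounge (heavily furnished) scene profile.

    The lounge has 3x the clutter scatterer count of the lab and an
    occlusion attenuation of 0.3 on leg scatterers (furniture blocks low
    body parts).  Clutter layout is fixed per environment, as a real room's
    walls and furniture would be.
    """
    if environment not in ("lab", "lounge"):
        raise ValueError("environment must be 'lab' or 'lounge'")
    pulse = pulse or PulseParams()
    pulse.validate()
    furnished = environment == "lounge"
    crng = np.random.default_rng(np.random.SeedSequence([int(seed) & _SEED_MASK, 0 if not furnished else 1, 17]))
    n_clutter = 12 if furnished else 4
    lo = pulse.range_offset + 0.2
    hi = pulse.max_range - 0.2
    clutter = tuple(
        Scatterer.static_point(float(crng.uniform(lo, hi)), float(crng.uniform(0.2, 0.6)))
        for _ in range(n_clutter)
    )
    return SceneConfig(
        pulse=pulse,
        clutter=clutter,
        occlusion_attenuation=0.3 if furnished else 1.0,
        noise_sigma=noise_sigma,
        environment_id=environment,
        rng_seed=int(seed) & _SEED_MASK,
    )


def default_subjects(n: int = 5, seed: int = 0) -> list[SubjectProfile]:
    """A diverse panel of n virtual subjects (height/weight/gait spread)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & _SEED_MASK, 23]))
    subjects = []
    for _ in range(n):
        height = float(rng.uniform(158.0, 182.0))
        weight = float(rng.uniform(50.0, 90.0))
        gait = float(rng.uniform(0.8, 1.3))
        refl = float(np.clip(0.7 + (weight - 50.0) / 200.0, 0.7, 1.0))
        subjects.append(SubjectProfile(height=height, weight=weight, gait_speed=gait, reflectivity_scale=refl))
    return subjects


def generate_dataset(
    scene: SceneConfig,
    subjects: Sequence[SubjectProfile],
    samples_per_subject_per_activity: int,
    seed: int,
    duration: float = 4.0,
) -> list[RawRecording]:
    """Generate a balanced labelled dataset of raw recordings.

    Output has ``len(subjects) * 6 * samples_per_subject_per_activity``
    recordings; each carries its own no-target reference frame (same clutter,
    independent noise).  Per-recording random streams are derived from the
    master seed and a running recording counter, so any subset is
    reproducible independently.  Raw frames carry ``raw_margin_bins`` extra
    fast-time bins for window augmentation.
    """
    scene.validate()
    if not subjects:
        raise ValueError("subject list must not be empty")
    if samples_per_subject_per_activity < 1:
        raise ValueError("samples_per_subject_per_activity must be >= 1")
    pulse = scene.pulse
    m_frames = int(round(duration * scene.frame_rate))
    recordings: list[RawRecording] = []
    counter = 0
    for si, subject in enumerate(subjects, start=1):
        subject.validate()
        for label in ActivityLabel:
            for _rep in range(samples_per_subject_per_activity):
                ss = np.random.SeedSequence([int(seed) & _SEED_MASK, counter])
                state = ss.generate_state(2)
                scene_i = replace(scene, rng_seed=int(state[0]) & _SEED_MASK)
                traj_seed = int(state[1]) & _SEED_MASK
                prng = np.random.default_rng(np.random.SeedSequence([int(seed) & _SEED_MASK, counter, 3]))
                if label == ActivityLabel.WALKING:
                    walk_span = subject.gait_speed * duration
                    lo = pulse.range_offset + 0.5
                    hi = max(lo + 0.1, pulse.max_range - walk_span - 0.6)
                elif label in (ActivityLabel.FALLING, ActivityLabel.STANDING_UP):
                    # room for the ~body-length range shift of the transition
                    lo = pulse.range_offset + 0.5
                    hi = max(lo + 0.1, pulse.max_range - 0.65 * subject.height / 100.0 - 0.6)
                else:
                    lo = pulse.range_offset + 0.5
                    hi = max(lo + 0.1, pulse.max_range - 1.0)
                r0 = float(prng.uniform(lo, hi))
                scatterers = activity_trajectory(label, subject, r0, duration, traj_seed)
                frames = np.stack(
                    [
                        simulate_frame(scene_i, scatterers, m / scene.frame_rate, raw=True).amplitudes
                        for m in range(m_frames)
                    ]
                )
                reference = simulate_frame(
                    scene_i, [], 0.0, raw=True, slow_index=_REFERENCE_SLOW_INDEX
                ).amplitudes
                recordings.append(
                    RawRecording(
                        frames=frames,
                        reference=reference,
                        label=label,
                        subject_id=f"S{si}",
                        environment_id=scene.environment_id,
                    )
                )
                counter += 1
    return recordings
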