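"""Synthetic gait recordings with known phase ground truth.

Human walking is modeled as a periodic sequence of cycles, each split into
pre-stance, mid-stance, ter-stance and swing in a fixed order with
configurable duration fractions.  From the resulting 50 Hz phase timeline
the generator derives three mutually consistent streams:

* plantar pressure — heel/sole/toe on-off levels following the foot-switch
  table (swing 000, pre-stance 100, mid-stance rolling 110 -> 111 -> 011,
  ter-stance 001), with bounded additive noise;
* knee angle — a smooth flexion waveform, near-extended through stance with
  a single large flexion peak in swing plus a small loading-response bump;
* sEMG — per muscle, band-limited (20-450 Hz) zero-mean noise whose
  amplitude envelope follows a per-phase activation profile over six
  lower-limb muscles (VM, VL, BF, ST, GA, TA), plus a white-noise floor and
  a 50 Hz power-line component (which the preprocessing notch must remove).

The left-foot pressure channels replay the right-foot schedule shifted by
half a cycle.  All scales are simulator conventions: the generator aims at
the *structure* real recordings share (multi-rate clocks, phase-locked
activations, line interference), not subject-specific realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .errors import ConfigError
from .phase_labeler import N_PHASES, PhaseLabel
from .signal_model import (
    ANGLE_CHANNELS,
    PRESSURE_CHANNELS,
    SEMG_CHANNELS,
    GaitRecording,
    MultiChannelSignal,
)

#: in-cycle phase order: pre-stance, mid-stance, ter-stance, swing
PHASE_ORDER = (
    PhaseLabel.PRE_STANCE,
    PhaseLabel.MID_STANCE,
    PhaseLabel.TER_STANCE,
    PhaseLabel.SWING,
)

#: walking-speed presets: km/h -> cycle duration in seconds (simulator
#: convention: slower gait, longer cycle)
SPEED_CYCLE_S = {1.0: 2.2, 2.0: 1.6, 3.0: 1.3}

LOW_RATE_HZ = 50.0
DEFAULT_RATIO = 30  # 1500 Hz sEMG over the 50 Hz A/D clock


@dataclass
class GaitScheduleConfig:
    """Cycle timing of the simulated gait.

    ``phase_fractions`` are the (pre-stance, mid-stance, ter-stance, swing)
    shares of one cycle; the default is a stance-dominated cycle
    (70% stance / 30% swing).
    """

    cycle_duration_s: float = 1.6
    n_cycles: int = 20
    phase_fractions: tuple[float, float, float, float] = (0.15, 0.40, 0.15, 0.30)
    seed: int = 0

    def validate(self) -> None:
        if self.cycle_duration_s <= 0 or self.n_cycles < 1:
            raise ConfigError("cycle_duration_s must be > 0 and n_cycles >= 1")
        f = np.asarray(self.phase_fractions, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ConfigError("phase_fractions must be 4 positive values summing to 1")


@dataclass
class MusclePhaseProfile:
    """Activation amplitude of each muscle in each gait sub-phase.

    ``amplitudes[phase_code, muscle]`` scales band-limited noise for that
    muscle while the gait is in that phase; muscles are ordered as
    ``SEMG_CHANNELS`` (VM, VL, BF, ST, GA, TA), phase codes as
    :class:`~gaitfuse.phase_labeler.PhaseLabel`.  ``noise_floor`` is a
    phase-independent white-noise level and ``line_amp`` the amplitude of
    the 50 Hz power-line interference.
    """

    amplitudes: np.ndarray = field(default_factory=lambda: _default_amplitudes())
    noise_floor: float = 0.05
    line_amp: float = 0.2

    def validate(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        if a.shape != (N_PHASES, len(SEMG_CHANNELS)):
            raise ConfigError(
                f"amplitudes must have shape ({N_PHASES}, {len(SEMG_CHANNELS)})"
            )
        if np.any(a < 0) or self.noise_floor < 0 or self.line_amp < 0:
            raise ConfigError("all amplitudes must be nonnegative")
        if np.all(a.max(axis=0) - a.min(axis=0) == 0):
            raise ConfigError("at least one muscle must differ across phases")


def _default_amplitudes() -> np.ndarray:
    """Phase-locked activation pattern, rows = (swing, pre, mid, ter).

    Qualitative gait physiology: quadriceps (VM, VL) peak at loading,
    plantar-flexor (GA) builds through stance to push-off, dorsiflexor (TA)
    and hamstrings (BF, ST) are swing/heel-strike muscles.  Swing and
    pre-stance deliberately share elevated flexor activity, so the knee
    angle carries genuinely complementary information.
    """
    #                  VM    VL    BF    ST    GA    TA
    return np.array([
        [0.20, 0.20, 0.50, 0.50, 0.10, 0.90],   # swing
        [1.00, 1.00, 0.60, 0.60, 0.10, 0.80],   # pre-stance
        [0.50, 0.50, 0.20, 0.20, 0.80, 0.10],   # mid-stance
        [0.20, 0.20, 0.20, 0.30, 1.20, 0.10],   # ter-stance
    ])


def make_phase_timeline(cfg: GaitScheduleConfig, rate_hz: float = LOW_RATE_HZ,
                        phase_offset: float = 0.0) -> np.ndarray:
    """Phase code of every sample of a uniformly sampled gait schedule.

    Sample ``i`` at time ``i / rate_hz`` is assigned the phase whose
    cumulative-fraction interval contains its in-cycle position.
    ``phase_offset`` (fraction of a cycle) shifts the schedule, e.g. 0.5 for
    the contralateral foot.  Returns ``round(total duration * rate)`` codes.
    """
    cfg.validate()
    n = int(round(cfg.cycle_duration_s * cfg.n_cycles * rate_hz))
    if n < 1:
        raise ConfigError("timeline would be empty at this rate/duration")
    u = (np.arange(n) / (cfg.cycle_duration_s * rate_hz) + phase_offset) % 1.0
    edges = np.cumsum(cfg.phase_fractions)[:-1]
    seg = np.searchsorted(edges, u, side="right")
    codes = np.array([int(p) for p in PHASE_ORDER], dtype=np.int64)
    return codes[seg]


# foot-switch (heel, sole, toe) levels per phase; mid-stance rolls through
# three sub-states (heel+sole, full foot, sole+toe) in equal thirds
_STATIC_STATES = {
    int(PhaseLabel.SWING): (0, 0, 0),
    int(PhaseLabel.PRE_STANCE): (1, 0, 0),
    int(PhaseLabel.TER_STANCE): (0, 0, 1),
}
_MID_SEQUENCE = ((1, 1, 0), (1, 1, 1), (0, 1, 1))


def _runs(labels: np.ndarray):
    """Yield (start, stop, code) for maximal constant runs."""
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield start, i, int(labels[start])
            start = i


def ideal_switch_states(timeline: np.ndarray) -> np.ndarray:
    """Noise-free (heel, sole, toe) on/off levels for a phase timeline."""
    timeline = np.asarray(timeline, dtype=np.int64)
    out = np.zeros((timeline.size, 3), dtype=float)
    for start, stop, code in _runs(timeline):
        if code == int(PhaseLabel.MID_STANCE):
            length = stop - start
            for k, state in enumerate(_MID_SEQUENCE):
                a = start + (k * length) // 3
                b = start + ((k + 1) * length) // 3
                out[a:b] = state
        else:
            out[start:stop] = _STATIC_STATES[code]
    return out


def synth_pressure(timeline: np.ndarray, noise: float = 0.02, seed: int = 0,
                   rate_hz: float = LOW_RATE_HZ, on_level: float = 1.0) -> MultiChannelSignal:
    """Three-channel (heel, sole, toe) foot-switch pressure trace.

    "On" samples sit at ``on_level`` and "off" samples at 0, plus uniform
    noise bounded by ``noise`` — so for any ``noise < on_level/2`` a
    mid-level threshold recovers the scheduled states exactly.
    """
    timeline = np.asarray(timeline)
    if timeline.size == 0:
        raise ConfigError("timeline must be nonempty")
    rng = np.random.default_rng(seed)
    vals = ideal_switch_states(timeline) * on_level
    vals = vals + rng.uniform(-noise, noise, size=vals.shape)
    return MultiChannelSignal(["heel", "sole", "toe"], rate_hz, 0.0, vals)


def synth_angle(timeline: np.ndarray, amplitude_deg: float = 60.0,
                seed: int = 0, noise_deg: float = 0.5,
                rate_hz: float = LOW_RATE_HZ,
                stance_flexion_frac: float = 0.15,
                baseline_deg: float = 5.0) -> MultiChannelSignal:
    """Smooth knee-flexion waveform phase-locked to the gait schedule.

    Each swing run carries a single raised-sine flexion peak of
    ``amplitude_deg``; each stance stretch a small loading-response bump
    (``stance_flexion_frac`` of the amplitude).  The sin^2 bumps have zero
    value and slope at run boundaries, so the waveform is continuous across
    phase transitions.
    """
    timeline = np.asarray(timeline)
    if timeline.size == 0:
        raise ConfigError("timeline must be nonempty")
    rng = np.random.default_rng(seed)
    n = timeline.size
    angle = np.full(n, baseline_deg, dtype=float)
    swing = timeline == int(PhaseLabel.SWING)
    for start, stop, is_swing in _runs(swing.astype(np.int64)):
        length = stop - start
        x = (np.arange(length) + 0.5) / length
        bump = np.sin(np.pi * x) ** 2
        if is_swing:
            angle[start:stop] += amplitude_deg * bump
        else:
            angle[start:stop] += stance_flexion_frac * amplitude_deg * bump
    angle += rng.normal(0.0, noise_deg, size=n)
    return MultiChannelSignal(list(ANGLE_CHANNELS), rate_hz, 0.0, angle[:, None])


def synth_semg(timeline: np.ndarray, profile: MusclePhaseProfile | None = None,
               ratio: int = DEFAULT_RATIO, seed: int = 0,
               base_rate_hz: float = LOW_RATE_HZ) -> MultiChannelSignal:
    """Six-channel sEMG stream at ``ratio`` times the timeline rate.

    Each channel is unit-variance 20-450 Hz band-limited noise scaled by the
    muscle's activation amplitude for the instantaneous phase, plus a white
    noise floor and a 50 Hz line-interference sinusoid.
    """
    timeline = np.asarray(timeline, dtype=np.int64)
    if timeline.size == 0:
        raise ConfigError("timeline must be nonempty")
    if ratio < 1:
        raise ConfigError("ratio must be >= 1")
    profile = profile or MusclePhaseProfile()
    profile.validate()
    rng = np.random.default_rng(seed)
    rate = ratio * base_rate_hz
    n_hi = ratio * timeline.size
    carrier = rng.standard_normal((n_hi, len(SEMG_CHANNELS)))
    sig = MultiChannelSignal(list(SEMG_CHANNELS), rate, 0.0, carrier)
    carrier = preprocess.bandpass(sig).values
    std = carrier.std(axis=0, keepdims=True)
    carrier = carrier / np.where(std > 0, std, 1.0)
    envelope = np.asarray(profile.amplitudes)[np.repeat(timeline, ratio)]
    values = envelope * carrier
    if profile.noise_floor > 0:
        values = values + profile.noise_floor * rng.standard_normal(values.shape)
    if profile.line_amp > 0:
        t = np.arange(n_hi) / rate
        values = values + profile.line_amp * np.sin(2 * np.pi * 50.0 * t)[:, None]
    return MultiChannelSignal(list(SEMG_CHANNELS), rate, 0.0, values)


@dataclass
class AngleParams:
    amplitude_deg: float = 60.0
    noise_deg: float = 0.5
    stance_flexion_frac: float = 0.15
    baseline_deg: float = 5.0


def generate_recording(cfg: GaitScheduleConfig | None = None,
                       profile: MusclePhaseProfile | None = None,
                       angle_params: AngleParams | None = None,
                       seed: int | None = None,
                       pressure_noise: float = 0.02,
                       ratio: int = DEFAULT_RATIO,
                       meta: dict | None = None
                       ) -> tuple[GaitRecording, np.ndarray]:
    """Full synthetic recording plus its ground-truth 50 Hz phase sequence.

    Right-foot pressure follows the generating schedule (which is also the
    returned ground truth); left-foot channels replay it shifted by half a
    cycle.  Sub-stream seeds are spawned from one master seed, so a fixed
    seed reproduces the recording bit-for-bit and different seeds give
    independent noise realizations.
    """
    cfg = cfg or GaitScheduleConfig()
    if seed is None:
        seed = cfg.seed
    cfg.validate()
    profile = profile or MusclePhaseProfile()
    ap = angle_params or AngleParams()
    seeds = np.random.SeedSequence(seed).generate_state(4)
    timeline = make_phase_timeline(cfg, LOW_RATE_HZ)
    timeline_left = make_phase_timeline(cfg, LOW_RATE_HZ, phase_offset=0.5)
    right = synth_pressure(timeline, pressure_noise, int(seeds[0]))
    left = synth_pressure(timeline_left, pressure_noise, int(seeds[1]))
    pressure = MultiChannelSignal(
        list(PRESSURE_CHANNELS), LOW_RATE_HZ, 0.0,
        np.hstack([right.values, left.values]),
    )
    angle = synth_angle(timeline, ap.amplitude_deg, int(seeds[2]), ap.noise_deg,
                        stance_flexion_frac=ap.stance_flexion_frac,
                        baseline_deg=ap.baseline_deg)
    semg = synth_semg(timeline, profile, ratio, int(seeds[3]))
    rec_meta = {"subject": "synthetic", "speed_km_h": None, "foot": "right",
                "seed": int(seed), "cycle_duration_s": cfg.cycle_duration_s,
                "n_cycles": cfg.n_cycles}
    if meta:
        rec_meta.update(meta)
    rec = GaitRecording(semg, angle, pressure, rec_meta)
    return rec, timeline


def speed_to_cycle_s(speed_km_h: float) -> float:
    """Walking-speed preset -> cycle duration (simulator convention)."""
    try:
        return SPEED_CYCLE_S[float(speed_km_h)]
    except KeyError:
        raise ConfigError(
            f"no cycle-duration preset for {speed_km_h} km/h; "
            f"presets: {sorted(SPEED_CYCLE_S)}"
        ) from None
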