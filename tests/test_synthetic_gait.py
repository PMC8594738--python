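import numpy as np
import pytest

from gaitfuse.errors import ConfigError
from gaitfuse.phase_labeler import PhaseLabel
from gaitfuse.synthetic_gait import (
    PHASE_ORDER,
    GaitScheduleConfig,
    MusclePhaseProfile,
    generate_recording,
    make_phase_timeline,
    speed_to_cycle_s,
    synth_angle,
    synth_pressure,
    synth_semg,
)

#: allowed foot-switch rows per phase: swing 000, pre 100, mid {110,111,010,011}, ter 001
ALLOWED_STATES = {
    int(PhaseLabel.SWING): {(0, 0, 0)},
    int(PhaseLabel.PRE_STANCE): {(1, 0, 0)},
    int(PhaseLabel.MID_STANCE): {(1, 1, 0), (1, 1, 1), (0, 1, 0), (0, 1, 1)},
    int(PhaseLabel.TER_STANCE): {(0, 0, 1)},
}


def _runs_of(timeline):
    change = np.flatnonzero(np.diff(timeline)) + 1
    return np.split(timeline, change)


def test_equal_fractions_give_equal_phase_counts():
    cfg = GaitScheduleConfig(cycle_duration_s=2.0, n_cycles=1,
                             phase_fractions=(0.25, 0.25, 0.25, 0.25))
    tl = make_phase_timeline(cfg, 50.0)
    assert tl.size == 100
    counts = np.bincount(tl, minlength=4)
    assert np.all(counts == 25)


def test_each_phase_has_one_contiguous_run_per_cycle():
    cfg = GaitScheduleConfig(cycle_duration_s=1.6, n_cycles=3)
    tl = make_phase_timeline(cfg, 50.0)
    runs = _runs_of(tl)
    for phase in PHASE_ORDER:
        n_runs = sum(1 for r in runs if r[0] == int(phase))
        assert n_runs == 3


def test_all_four_phases_present_and_ordered():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=2), 50.0)
    assert set(np.unique(tl)) == {0, 1, 2, 3}
    # within each cycle: pre -> mid -> ter -> swing
    runs = [r[0] for r in _runs_of(tl)]
    order = [int(p) for p in PHASE_ORDER]
    assert runs == order * 2


def test_invalid_fractions_rejected():
    with pytest.raises(ConfigError):
        make_phase_timeline(GaitScheduleConfig(phase_fractions=(0.5, 0.5, 0.1, 0.1)))
    with pytest.raises(ConfigError):
        make_phase_timeline(GaitScheduleConfig(cycle_duration_s=0.0))


def test_pressure_states_follow_foot_switch_table():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=4), 50.0)
    sig = synth_pressure(tl, noise=0.05, seed=1)
    states = (sig.values > 0.5).astype(int)
    for code in range(4):
        rows = {tuple(s) for s in states[tl == code]}
        assert rows <= ALLOWED_STATES[code], f"phase {code}: {rows}"


def test_pressure_levels_separated_from_noise():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=2), 50.0)
    sig = synth_pressure(tl, noise=0.05, seed=0)
    on = sig.values[sig.values > 0.5]
    off = sig.values[sig.values <= 0.5]
    assert on.min() >= 0.95 and off.max() <= 0.05


def test_angle_swing_peak_dominates_stance():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=3), 50.0)
    ang = synth_angle(tl, amplitude_deg=60.0, seed=0, noise_deg=0.0)
    vals = ang.values[:, 0]
    swing = tl == int(PhaseLabel.SWING)
    assert vals[swing].max() > vals[~swing].max()
    assert vals[swing].max() == pytest.approx(65.0, abs=2.0)  # baseline 5 + 60


def test_angle_zero_amplitude_is_constant():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=1), 50.0)
    ang = synth_angle(tl, amplitude_deg=0.0, seed=0, noise_deg=0.0,
                      stance_flexion_frac=0.0)
    assert np.ptp(ang.values) == 0.0


def test_angle_deterministic_under_seed():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=1), 50.0)
    a = synth_angle(tl, seed=7)
    b = synth_angle(tl, seed=7)
    np.testing.assert_array_equal(a.values, b.values)


def test_semg_zero_envelope_channel_is_zero_over_phase():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=2), 50.0)
    amps = MusclePhaseProfile().amplitudes.copy()
    amps[int(PhaseLabel.SWING), 0] = 0.0  # VM silent in swing
    prof = MusclePhaseProfile(amplitudes=amps, noise_floor=0.0, line_amp=0.0)
    sig = synth_semg(tl, prof, ratio=30, seed=0)
    hi_mask = np.repeat(tl == int(PhaseLabel.SWING), 30)
    assert np.all(sig.values[hi_mask, 0] == 0.0)
    assert np.any(sig.values[~hi_mask, 0] != 0.0)


def test_semg_rms_scales_linearly_with_amplitude():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=4), 50.0)
    base = np.full((4, 6), 0.5)
    base[0, 0] = 1.0  # keep profile phase-distinguishable
    prof_a = MusclePhaseProfile(amplitudes=base, noise_floor=0.0, line_amp=0.0)
    prof_2a = MusclePhaseProfile(amplitudes=2 * base, noise_floor=0.0, line_amp=0.0)
    sig_a = synth_semg(tl, prof_a, ratio=30, seed=3)
    sig_2a = synth_semg(tl, prof_2a, ratio=30, seed=3)
    rms = lambda v: np.sqrt(np.mean(v ** 2))
    ratio = rms(sig_2a.values[:, 1]) / rms(sig_a.values[:, 1])
    assert ratio == pytest.approx(2.0, rel=1e-9)


def test_semg_deterministic_and_length_contract():
    tl = make_phase_timeline(GaitScheduleConfig(n_cycles=1), 50.0)
    a = synth_semg(tl, ratio=30, seed=5)
    b = synth_semg(tl, ratio=30, seed=5)
    np.testing.assert_array_equal(a.values, b.values)
    assert a.n_samples == 30 * tl.size
    assert a.rate_hz == 1500.0


def test_generate_recording_sample_arithmetic():
    cfg = GaitScheduleConfig(cycle_duration_s=1.2, n_cycles=3)
    rec, truth = generate_recording(cfg, seed=0)
    assert truth.size == 180           # 3 * 1.2 s * 50 Hz
    assert rec.angle.n_samples == 180
    assert rec.semg.n_samples == 5400  # R = 30
    assert rec.pressure.n_channels == 6


def test_generate_recording_seed_contract():
    cfg = GaitScheduleConfig(n_cycles=2)
    rec_a, _ = generate_recording(cfg, seed=1)
    rec_b, _ = generate_recording(cfg, seed=1)
    rec_c, _ = generate_recording(cfg, seed=2)
    np.testing.assert_array_equal(rec_a.semg.values, rec_b.semg.values)
    assert not np.array_equal(rec_a.semg.values, rec_c.semg.values)


def test_left_foot_shifted_half_cycle():
    cfg = GaitScheduleConfig(cycle_duration_s=2.0, n_cycles=4,
                             phase_fractions=(0.25, 0.25, 0.25, 0.25))
    rec, truth = generate_recording(cfg, seed=0, pressure_noise=0.0)
    right_heel = rec.pressure.channel("R_heel") > 0.5
    left_heel = rec.pressure.channel("L_heel") > 0.5
    half = 50  # half of a 2 s cycle at 50 Hz
    np.testing.assert_array_equal(right_heel[:-half], left_heel[half:])


def test_speed_presets():
    assert speed_to_cycle_s(1.0) == 2.2
    assert speed_to_cycle_s(3.0) == 1.3
    with pytest.raises(ConfigError):
        speed_to_cycle_s(7.5)
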