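"""Gait sub-phase labeling from plantar-pressure foot switches.

Each of the three study-foot pressure channels (heel, sole, toe) is
binarized with a Schmitt trigger; the resulting 3-bit foot-switch state maps
to one of four gait sub-phases:

    heel sole toe   phase
    0    0    0     swing
    1    0    0     pre-stance   (heel strike, heel only)
    1    1    0     mid-stance   (heel-to-toe rollover, sole loaded)
    1    1    1     mid-stance
    0    1    0     mid-stance
    0    1    1     mid-stance
    0    0    1     ter-stance   (push-off, toe only)

State 101 (heel+toe, no sole) is not part of the standard mapping; it can
only arise transiently during rollover and is assigned to mid-stance so the
mapping is total over all 8 states (a debug log line flags it).
"""

from __future__ import annotations

import logging
from enum import IntEnum

import numpy as np

from .errors import ChannelError, ConfigError
from .signal_model import GaitRecording, MultiChannelSignal

log = logging.getLogger(__name__)


class PhaseLabel(IntEnum):
    """Gait sub-phase with package-wide stable integer codes."""

    SWING = 0
    PRE_STANCE = 1
    MID_STANCE = 2
    TER_STANCE = 3

    @property
    def label(self) -> str:
        return _PHASE_NAMES[int(self)]


_PHASE_NAMES = {0: "swing", 1: "pre_stance", 2: "mid_stance", 3: "ter_stance"}

N_PHASES = 4

#: total mapping from (heel, sole, toe) foot-switch state to phase
STATE_TO_PHASE = {
    (0, 0, 0): PhaseLabel.SWING,
    (1, 0, 0): PhaseLabel.PRE_STANCE,
    (1, 1, 0): PhaseLabel.MID_STANCE,
    (1, 1, 1): PhaseLabel.MID_STANCE,
    (0, 1, 0): PhaseLabel.MID_STANCE,
    (0, 1, 1): PhaseLabel.MID_STANCE,
    (0, 0, 1): PhaseLabel.TER_STANCE,
    (1, 0, 1): PhaseLabel.MID_STANCE,  # outside the standard table; see module docstring
}


def state_to_phase(state: tuple[int, int, int]) -> PhaseLabel:
    """Map one (heel, sole, toe) foot-switch state to its gait sub-phase."""
    key = tuple(int(v) for v in state)
    if any(v not in (0, 1) for v in key) or len(key) != 3:
        raise ValueError(f"foot-switch state must be three binary flags, got {state!r}")
    if key == (1, 0, 1):
        log.debug("foot-switch state 101 (heel+toe) observed; mapped to mid-stance")
    return STATE_TO_PHASE[key]


def binarize(pressure: MultiChannelSignal, threshold_frac: float = 0.3,
             hysteresis_frac: float = 0.05) -> np.ndarray:
    """Schmitt-trigger binarization of a 3-channel (heel, sole, toe) block.

    Per channel, baseline is the 5th percentile and range the 95th minus 5th
    percentile; the switch turns on at baseline + (threshold+hysteresis)*range
    and off at baseline + (threshold-hysteresis)*range, which suppresses
    chattering when the trace dwells near a single threshold.

    Returns an (n_samples, 3) uint8 array.  A constant (zero-range) channel
    is held off, with a warning.
    """
    if pressure.n_channels != 3:
        raise ChannelError(f"binarize expects 3 channels, got {pressure.n_channels}")
    if not (0.0 < threshold_frac < 1.0) or hysteresis_frac < 0 \
            or threshold_frac <= hysteresis_frac:
        raise ConfigError("need 0 < threshold_frac < 1 and 0 <= hysteresis_frac < threshold_frac")
    vals = pressure.values
    n = vals.shape[0]
    out = np.zeros((n, 3), dtype=np.uint8)
    for j in range(3):
        x = vals[:, j]
        base, top = np.percentile(x, [5.0, 95.0])
        rng = top - base
        if rng <= 1e-12:
            log.warning("pressure channel %s has zero range; held off",
                        pressure.channel_names[j])
            continue
        hi = base + (threshold_frac + hysteresis_frac) * rng
        lo = base + (threshold_frac - hysteresis_frac) * rng
        state = 1 if x[0] >= base + threshold_frac * rng else 0
        col = out[:, j]
        for i in range(n):
            if state == 0 and x[i] >= hi:
                state = 1
            elif state == 1 and x[i] <= lo:
                state = 0
            col[i] = state
    return out


def smooth_labels(labels: np.ndarray, smoothing_len: int) -> np.ndarray:
    """Majority vote over a centered window of odd length (1 = off).

    Window is clipped at the edges; ties resolve to the lowest phase code.
    """
    if smoothing_len < 1 or smoothing_len % 2 == 0:
        raise ConfigError("smoothing_len must be a positive odd integer")
    if smoothing_len == 1:
        return np.asarray(labels, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    half = smoothing_len // 2
    n = labels.size
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        w = labels[max(0, i - half): min(n, i + half + 1)]
        out[i] = np.bincount(w, minlength=N_PHASES).argmax()
    return out


def label_recording(rec: GaitRecording, foot: str = "right",
                    smoothing_len: int = 1, threshold_frac: float = 0.3,
                    hysteresis_frac: float = 0.05) -> np.ndarray:
    """Label every low-rate sample of a recording with its gait sub-phase.

    The study foot's three pressure channels are binarized and mapped
    through the foot-switch table; optional majority-vote smoothing removes
    isolated glitches.  Returns an int array of phase codes at the low rate.
    """
    if foot not in ("left", "right"):
        raise ConfigError(f"foot must be 'left' or 'right', got {foot!r}")
    prefix = "R" if foot == "right" else "L"
    names = [f"{prefix}_heel", f"{prefix}_sole", f"{prefix}_toe"]
    missing = [n for n in names if n not in rec.pressure.channel_names]
    if missing:
        raise ChannelError(f"recording lacks pressure channels {missing}")
    states = binarize(rec.pressure.select(names), threshold_frac, hysteresis_frac)
    lut = np.empty(8, dtype=np.int64)
    for (h, s, t), phase in STATE_TO_PHASE.items():
        lut[(h << 2) | (s << 1) | t] = int(phase)
    codes = (states[:, 0].astype(np.int64) << 2) | (states[:, 1] << 1) | states[:, 2]
    return smooth_labels(lut[codes], smoothing_len)
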