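"""Adapting A1-like inputs to the competition network.

Primary auditory cortex responds to triplet tone sequences with
onset-plateau responses that adapt rapidly: over the first 2-3 triplets the
overall response amplitude decays and the tonotopic (DF) dependence of the
responses emerges, both on a shared timescale of 500 ms.  At stimulus onset
the responses are therefore large and broadly tuned — effectively driven by
a small DF — which is what biases the downstream competition toward the
integrated percept.  After a silent pause this fast adaptation recovers
quickly (100 ms timescale), so the post-pause inputs again resemble onset
inputs.

This module turns a :class:`~streamseg.paradigm.StimulusTimeline` into the
three per-unit input time series I_A(t), I_AB(t), I_B(t).  The downstream
units pool A1 activity at tonotopic centers A, B and their semitone midpoint
(A+B)/2; a tone at semitone position p contributes a rectangular pulse to
unit k with Gaussian tonotopic weight exp(-d^2 / (2 w^2)), where d is the
distance from unit k's center to the tone's *effective* position: positions
compress toward the stimulus midpoint by the effective-DF fraction
f(t) in (0, 1] (small at onset, so both tones drive the midpoint region and
the integration unit receives the largest input; 1 when adapted, restoring
the full tonotopic separation).

Non-triplet events (distractor and deviant tones) follow three extra rules:
their amplitude is boosted to the unadapted level (a novel event in a
window where silence or a standard tone was expected), their contribution at
the A center is attenuated by forward masking (the event immediately follows
an A-tone offset), and — under the gating hypothesis — they are excluded
from the input to the AB (integration) unit entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .paradigm import StimulusTimeline, ToneEvent, hz_to_st

__all__ = [
    "A1Params",
    "AdaptationState",
    "A1InputTrace",
    "tonotopic_weight",
    "effective_df",
    "recover_during_silence",
    "distractor_response",
    "compute_input_trace",
    "unit_centers_st",
]

UNIT_NAMES = ("A", "AB", "B")


@dataclass
class A1Params:
    """Input-stage parameters.

    Times are ms.  ``amp_onset_gain`` is the unadapted response amplitude
    relative to the adapted steady state; ``df_onset_frac`` is the
    effective-DF fraction at onset.  ``input_gain`` sets the adapted pulse
    amplitude in the competition stage's drive units.  Calibrated defaults;
    see docs/methods.md.
    """

    tau_a1: float = 500.0          # fast adaptation timescale
    tau_rec: float = 100.0         # recovery timescale during silence
    tuning_width_st: float = 2.5   # Gaussian tonotopic tuning width
    amp_onset_gain: float = 5.0    # unadapted / adapted amplitude ratio (> 1)
    df_onset_frac: float = 0.25    # effective-DF fraction at onset, in (0, 1)
    masking_factor: float = 0.5    # A-center attenuation of non-triplet events
    input_gain: float = 0.12       # adapted pulse amplitude (drive units)
    boost_to_unadapted: bool = True
    gate_non_triplet_from_ab: bool = False
    adapting: bool = True          # False = "input static" mode
    recovery_grace_ms: float = 100.0  # silence within the triplet grammar

    def validate(self) -> "A1Params":
        for name in ("tau_a1", "tau_rec", "tuning_width_st", "input_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.amp_onset_gain < 1:
            raise ValueError(f"amp_onset_gain must be >= 1, got {self.amp_onset_gain}")
        if not 0 < self.df_onset_frac <= 1:
            raise ValueError(
                f"df_onset_frac must be in (0, 1], got {self.df_onset_frac}"
            )
        if not 0 <= self.masking_factor <= 1:
            raise ValueError(
                f"masking_factor must be in [0, 1], got {self.masking_factor}"
            )
        return self


@dataclass(frozen=True)
class AdaptationState:
    """Current fast-adaptation level of the A1 responses.

    ``amp_state`` is the current amplitude gain, relaxing from
    ``amp_onset_gain`` (unadapted) down to 1 (adapted) during stimulation.
    ``df_state`` is the current effective-DF fraction, rising from
    ``df_onset_frac`` to 1.  ``last_tone_offset_ms`` tracks the end of the
    most recent stimulation.
    """

    amp_state: float
    df_state: float
    last_tone_offset_ms: Optional[int] = None

    @classmethod
    def unadapted(cls, params: A1Params) -> "AdaptationState":
        return cls(amp_state=params.amp_onset_gain, df_state=params.df_onset_frac)

    @classmethod
    def adapted(cls) -> "AdaptationState":
        return cls(amp_state=1.0, df_state=1.0)

    def stimulated(self, duration_ms: float, params: A1Params) -> "AdaptationState":
        """Advance adaptation through ``duration_ms`` of stimulation."""
        decay = math.exp(-duration_ms / params.tau_a1)
        return replace(
            self,
            amp_state=1.0 + (self.amp_state - 1.0) * decay,
            df_state=1.0 - (1.0 - self.df_state) * decay,
        )


def tonotopic_weight(tone_freq_st: float, unit_center_st: float, width: float) -> float:
    """Gaussian tonotopic weight exp(-d^2 / (2 width^2)), d in semitones."""
    if width <= 0:
        raise ValueError(f"width must be > 0, got {width}")
    d = tone_freq_st - unit_center_st
    return math.exp(-(d * d) / (2.0 * width * width))


def effective_df(
    t_since_onset: float,
    df_nominal: float,
    params: A1Params,
    state: Optional[AdaptationState] = None,
) -> float:
    """Effective DF after ``t_since_onset`` ms of uninterrupted stimulation.

    Rises exponentially from ``df_onset_frac * df_nominal`` toward
    ``df_nominal`` with timescale ``tau_a1``.  With a ``state``, relaxation
    starts from the state's current effective-DF fraction.
    """
    if df_nominal <= 0:
        raise ValueError(f"df_nominal must be > 0, got {df_nominal}")
    f0 = state.df_state if state is not None else params.df_onset_frac
    f = 1.0 - (1.0 - f0) * math.exp(-t_since_onset / params.tau_a1)
    return df_nominal * f


def recover_during_silence(
    state: AdaptationState, silence_ms: float, params: A1Params
) -> AdaptationState:
    """Relax adaptation back toward onset values during ``silence_ms`` of silence.

    Pure exponential recovery with timescale ``tau_rec``: zero silence is the
    identity, and silence >= 2 * tau_rec brings the state within e^-2 of a
    full reset.  (The input-trace builder applies this only to silence in
    excess of the grammar's nominal inter-triplet gap; see
    :func:`compute_input_trace`.)
    """
    if silence_ms < 0:
        raise ValueError(f"silence_ms must be >= 0, got {silence_ms}")
    if silence_ms == 0:
        return state
    decay = math.exp(-silence_ms / params.tau_rec)
    return replace(
        state,
        amp_state=params.amp_onset_gain + (state.amp_state - params.amp_onset_gain) * decay,
        df_state=params.df_onset_frac + (state.df_state - params.df_onset_frac) * decay,
    )


def unit_centers_st(df_st: float) -> np.ndarray:
    """Tonotopic centers of units (A, AB, B) in semitones above the A tone."""
    return np.array([0.0, df_st / 2.0, df_st])


def effective_position_st(pos_st: float, mid_st: float, df_frac: float) -> float:
    """Effective tonotopic position of a tone under partial DF adaptation.

    While the DF dependence of the responses is still emerging, the stimulus
    drives A1 as if its tones were separated by the (smaller) effective DF.
    A stimulus with that separation is symmetric about the same midpoint, so
    tone positions compress toward the midpoint by the effective-DF fraction:
    p_eff = mid + f (p - mid).  At onset (small f) both tones therefore
    drive the region around (A+B)/2 — the broad, barely tone-specific onset
    response that biases the integration unit — and as f -> 1 the full
    tonotopic separation emerges.
    """
    return mid_st + df_frac * (pos_st - mid_st)


def _standard_amps(
    pos_st: float, centers: np.ndarray, state: AdaptationState, params: A1Params,
    mid_st: float,
) -> np.ndarray:
    p_eff = effective_position_st(pos_st, mid_st, state.df_state)
    d = p_eff - centers
    w2 = params.tuning_width_st**2
    return params.input_gain * state.amp_state * np.exp(-(d * d) / (2.0 * w2))


def distractor_response(
    event: ToneEvent,
    state: AdaptationState,
    params: A1Params,
    base_freq_hz: float,
    df_st: float,
) -> np.ndarray:
    """Per-unit pulse amplitudes (A, AB, B) for a non-triplet event.

    Amplitude uses the unadapted gain when ``boost_to_unadapted`` is set (the
    event is detected as novel); the A-center contribution is attenuated by
    ``masking_factor`` (the event follows an A-tone offset); under
    ``gate_non_triplet_from_ab`` the AB contribution is zero.  With masking
    off, boost off and gating off this reduces exactly to the standard-tone
    rule.
    """
    if event.label not in ("distractor", "deviant"):
        raise ValueError(
            f"distractor_response requires a non-triplet event, got label "
            f"{event.label!r}"
        )
    centers = unit_centers_st(df_st)
    eff_state = (
        replace(state, amp_state=params.amp_onset_gain)
        if params.boost_to_unadapted
        else state
    )
    pos = hz_to_st(event.freq_hz, base_freq_hz)
    amps = _standard_amps(pos, centers, eff_state, params, df_st / 2.0)
    amps[0] *= params.masking_factor
    if params.gate_non_triplet_from_ab:
        amps[1] = 0.0
    return amps


@dataclass
class A1InputTrace:
    """Per-unit input time series on a uniform grid.

    ``I`` has shape (n_samples, 3) with columns (I_A, I_AB, I_B); ``t`` is in
    ms with uniform step ``dt``.  ``provenance`` logs every event's
    contribution (which tone drove which unit with what weight).
    """

    t: np.ndarray
    I: np.ndarray
    dt: float
    df_st: float
    base_freq_hz: float
    provenance: list = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.t) - 1

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_ms": self.t, "I_A": self.I[:, 0], "I_AB": self.I[:, 1],
             "I_B": self.I[:, 2]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_input_trace(
    timeline: StimulusTimeline, params: A1Params, dt: float = 5.0
) -> A1InputTrace:
    """Convert a stimulus timeline into adapted per-unit input pulses.

    Each tone contributes a rectangular pulse for its duration, scaled by the
    tonotopic weight at the current effective DF and by the current amplitude
    gain; both adaptation components are evaluated at tone onset and advance
    during the tone on the shared ``tau_a1`` timescale.  Silence beyond the
    grammar's nominal 100 ms inter-triplet gap lets the adaptation recover
    with ``tau_rec``.  In static mode (``adapting=False``) the responses are
    the fully adapted ones from the first triplet on, giving a strictly
    periodic trace.

    Non-triplet events are routed through :func:`distractor_response` and
    advance the shared adaptation clock like any other stimulation.
    """
    params.validate()
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    total = timeline.total_ms
    n_steps = total / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"dt={dt} does not divide the timeline duration {total} ms")
    n_steps = int(round(n_steps))
    t = np.arange(n_steps + 1) * dt
    I = np.zeros((n_steps + 1, 3))
    provenance: list[dict] = []

    centers = unit_centers_st(timeline.df_st)
    state = (
        AdaptationState.unadapted(params) if params.adapting else AdaptationState.adapted()
    )
    for ev in timeline.events:
        for edge in (ev.onset_ms, ev.offset_ms):
            if abs(edge / dt - round(edge / dt)) > 1e-9:
                raise ValueError(
                    f"event edge at {edge} ms does not fall on the dt={dt} ms grid"
                )
        if params.adapting and state.last_tone_offset_ms is not None:
            gap = ev.onset_ms - state.last_tone_offset_ms
            excess = max(0.0, gap - params.recovery_grace_ms)
            if excess > 0:
                state = recover_during_silence(state, excess, params)
        if ev.label in ("distractor", "deviant"):
            amps = distractor_response(
                ev, state, params, timeline.base_freq_hz, timeline.df_st
            )
        else:
            pos = hz_to_st(ev.freq_hz, timeline.base_freq_hz)
            amps = _standard_amps(pos, centers, state, params, timeline.df_st / 2.0)
        i0 = int(round(ev.onset_ms / dt))
        i1 = int(round(ev.offset_ms / dt))
        I[i0:i1] += amps  # pulse active on [onset, offset)
        provenance.append(
            {
                "onset_ms": ev.onset_ms,
                "label": ev.label,
                "freq_hz": ev.freq_hz,
                "amp_state": state.amp_state,
                "df_state": state.df_state,
                "amps": amps.tolist(),
            }
        )
        if params.adapting:
            state = replace(
                state.stimulated(ev.duration_ms, params),
                last_tone_offset_ms=ev.offset_ms,
            )
    return A1InputTrace(
        t=t,
        I=I,
        dt=dt,
        df_st=timeline.df_st,
        base_freq_hz=timeline.base_freq_hz,
        provenance=provenance,
    )
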