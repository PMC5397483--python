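"""ABA_ triplet stimulus construction.

The streaming paradigm interleaves low A tones and high B tones in a
repeating ABA_ pattern: within every 400 ms triplet, an A tone plays at
0 ms, a B tone at 100 ms, a second A tone at 200 ms, and the final 100 ms
("_") is silent.  All tones are 100 ms pure tones; the B tone sits DF
semitones above the A tone.  This module builds such timelines, applies the
three perturbation types studied with them (stimulus pauses, distractor
tones inserted in the inter-triplet gap, deviant replacements of a B tone),
enumerates the factorial experimental designs, and can synthesize audio.

All frequency arithmetic is 12-tone equal temperament: a step of ``s``
semitones multiplies frequency by ``2**(s/12)``.  The frequency midpoint
between A and B, written (A+B)/2, is the *semitone* (log-frequency)
midpoint, i.e. the geometric mean in Hz — tonotopy is logarithmic, and the
model's integration unit is centered there.

Times are integer milliseconds internally: every duration in the paradigm
is a multiple of 1 ms, and integer timing keeps design arithmetic exact.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TONE_MS",
    "TRIPLET_MS",
    "GAP_MS",
    "ToneEvent",
    "Perturbation",
    "StimulusTimeline",
    "TrialCondition",
    "DesignTable",
    "st_to_hz",
    "hz_to_st",
    "resolve_freq_spec",
    "make_triplet_sequence",
    "apply_pause",
    "apply_distractor",
    "apply_deviant",
    "rove_base_frequency",
    "rove_ladder_hz",
    "pause_experiment_design",
    "perturbation_experiment_design",
    "build_timeline",
    "synthesize_waveform",
    "write_wav",
]

TONE_MS = 100       # duration of each pure tone
TRIPLET_MS = 400    # A + B + A + silence
GAP_MS = 100        # the trailing "_" silence of each triplet

ROVE_MIN_HZ = 420.0
ROVE_MAX_HZ = 1060.0
ROVE_STEP_ST = 4.0

DEFAULT_BASE_HZ = 500.0


def st_to_hz(base_hz: float, st: float) -> float:
    """Frequency ``st`` semitones above ``base_hz`` (12-TET)."""
    return base_hz * 2.0 ** (st / 12.0)


def hz_to_st(freq_hz: float, base_hz: float) -> float:
    """Signed semitone distance of ``freq_hz`` above ``base_hz``."""
    return 12.0 * math.log2(freq_hz / base_hz)


@dataclass(frozen=True)
class ToneEvent:
    """A single pure tone in a timeline."""

    onset_ms: int
    duration_ms: int
    freq_hz: float
    label: str  # "A" | "B" | "distractor" | "deviant"

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.freq_hz <= 0:
            raise ValueError(f"freq_hz must be > 0, got {self.freq_hz}")
        if self.label not in ("A", "B", "distractor", "deviant"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def offset_ms(self) -> int:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class Perturbation:
    """Descriptor for the (at most one) perturbation carried by a timeline."""

    kind: str = "none"  # none | pause | distractor | deviant
    pause_ms: int = 0
    after_triplet: int = 0   # pause / distractor location (1-based)
    freq_spec: str = ""      # distractor frequency spec, e.g. "B+2", "(A+B)/2"
    dur_ms: int = 0          # distractor duration
    offset_st: float = 0.0   # deviant frequency offset
    in_triplet: int = 0      # deviant location (1-based)

    def describe(self) -> str:
        if self.kind == "none":
            return "none"
        if self.kind == "pause":
            return f"pause{self.pause_ms}@{self.after_triplet}"
        if self.kind == "distractor":
            return f"distractor:{self.freq_spec}@{self.after_triplet}"
        return f"deviant:{self.offset_st:+g}@{self.in_triplet}"


@dataclass(frozen=True)
class StimulusTimeline:
    """Ordered tone events plus the metadata that generated them.

    The single source of truth for what is played: tone onsets/durations/
    frequencies, the nominal DF and base (A) frequency, and the perturbation
    descriptor.  Invariant: events are sorted by onset and non-overlapping.
    """

    events: tuple[ToneEvent, ...]
    total_ms: int
    df_st: float
    base_freq_hz: float
    perturbation: Perturbation = field(default_factory=Perturbation)

    def __post_init__(self) -> None:
        prev_end = 0
        for ev in self.events:
            if ev.onset_ms < prev_end:
                raise ValueError(
                    f"events overlap or are unsorted at onset {ev.onset_ms} ms"
                )
            prev_end = ev.offset_ms
        if self.events and self.events[-1].offset_ms > self.total_ms:
            raise ValueError("total_ms shorter than last event offset")

    # -- derived geometry ---------------------------------------------------

    @property
    def freq_a(self) -> float:
        return self.base_freq_hz

    @property
    def freq_b(self) -> float:
        return st_to_hz(self.base_freq_hz, self.df_st)

    @property
    def n_triplets(self) -> int:
        return sum(1 for ev in self.events if ev.label in ("A",)) // 2

    def triplet_start_ms(self, i: int) -> int:
        """Start time of 1-based triplet ``i`` (accounts for a pause)."""
        if not 1 <= i <= self.n_triplets:
            raise ValueError(f"triplet index {i} outside 1..{self.n_triplets}")
        start = TRIPLET_MS * (i - 1)
        p = self.perturbation
        if p.kind == "pause" and i > p.after_triplet:
            start += p.pause_ms
        return start

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "df_st": self.df_st,
            "base_freq_hz": self.base_freq_hz,
            "total_ms": self.total_ms,
            "perturbation": vars(self.perturbation).copy(),
            "events": [
                {
                    "onset_ms": ev.onset_ms,
                    "duration_ms": ev.duration_ms,
                    "freq_hz": ev.freq_hz,
                    "label": ev.label,
                }
                for ev in self.events
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusTimeline":
        return cls(
            events=tuple(ToneEvent(**ev) for ev in d["events"]),
            total_ms=d["total_ms"],
            df_st=d["df_st"],
            base_freq_hz=d["base_freq_hz"],
            perturbation=Perturbation(**d.get("perturbation", {})),
        )

    @classmethod
    def from_json(cls, text_or_path: str) -> "StimulusTimeline":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def make_triplet_sequence(
    n_triplets: int,
    df_st: float,
    base_freq_hz: float = DEFAULT_BASE_HZ,
) -> StimulusTimeline:
    """Build an unperturbed ABA_ sequence of ``n_triplets`` triplets.

    The final triplet includes its trailing 100 ms silence, so the total
    duration is exactly ``400 * n_triplets`` ms.
    """
    if n_triplets < 1:
        raise ValueError(f"n_triplets must be >= 1, got {n_triplets}")
    if df_st <= 0:
        raise ValueError(f"df_st must be > 0, got {df_st}")
    if base_freq_hz <= 0:
        raise ValueError(f"base_freq_hz must be > 0, got {base_freq_hz}")
    freq_b = st_to_hz(base_freq_hz, df_st)
    events = []
    for i in range(n_triplets):
        t0 = TRIPLET_MS * i
        events.append(ToneEvent(t0, TONE_MS, base_freq_hz, "A"))
        events.append(ToneEvent(t0 + 100, TONE_MS, freq_b, "B"))
        events.append(ToneEvent(t0 + 200, TONE_MS, base_freq_hz, "A"))
    return StimulusTimeline(
        events=tuple(events),
        total_ms=TRIPLET_MS * n_triplets,
        df_st=df_st,
        base_freq_hz=base_freq_hz,
    )


def _require_unperturbed(timeline: StimulusTimeline, op: str) -> None:
    if timeline.perturbation.kind != "none":
        raise ValueError(
            f"{op}: timeline already carries perturbation "
            f"{timeline.perturbation.describe()!r}; one perturbation per timeline"
        )


def apply_pause(
    timeline: StimulusTimeline, pause_ms: int, after_triplet: int
) -> StimulusTimeline:
    """Insert a silent pause after 1-based triplet ``after_triplet``.

    Every event from the following triplet onward is shifted by ``pause_ms``;
    ``pause_ms = 0`` returns the timeline unchanged.
    """
    if pause_ms < 0:
        raise ValueError(f"pause_ms must be >= 0, got {pause_ms}")
    if pause_ms == 0:
        return timeline
    n = timeline.n_triplets
    if not 1 <= after_triplet < n:
        raise ValueError(
            f"after_triplet must be in 1..{n - 1} for a {n}-triplet sequence, "
            f"got {after_triplet}"
        )
    _require_unperturbed(timeline, "apply_pause")
    boundary = TRIPLET_MS * after_triplet
    events = tuple(
        replace(ev, onset_ms=ev.onset_ms + pause_ms) if ev.onset_ms >= boundary else ev
        for ev in timeline.events
    )
    return replace(
        timeline,
        events=events,
        total_ms=timeline.total_ms + pause_ms,
        perturbation=Perturbation(
            kind="pause", pause_ms=pause_ms, after_triplet=after_triplet
        ),
    )


def resolve_freq_spec(spec: str, freq_a_hz: float, freq_b_hz: float) -> float:
    """Resolve a semitone-relative frequency spec against the A/B tones.

    Accepted forms: ``"A"``, ``"B"``, ``"A+2"``, ``"A-2"``, ``"B+8"``, ...,
    and ``"(A+B)/2"`` (alias ``"AB"``) for the semitone midpoint, i.e. the
    geometric mean of the A and B frequencies.
    """
    s = spec.strip().replace(" ", "")
    if s in ("(A+B)/2", "AB"):
        return math.sqrt(freq_a_hz * freq_b_hz)
    if not s or s[0] not in "AB":
        raise ValueError(f"cannot parse frequency spec {spec!r}")
    ref = freq_a_hz if s[0] == "A" else freq_b_hz
    rest = s[1:]
    if not rest:
        return ref
    try:
        offset = float(rest)
    except ValueError:
        raise ValueError(f"cannot parse frequency spec {spec!r}") from None
    return st_to_hz(ref, offset)


def apply_distractor(
    timeline: StimulusTimeline,
    freq_spec: str,
    after_triplet: int,
    dur_ms: int = 50,
) -> StimulusTimeline:
    """Insert a distractor tone, centered in the inter-triplet silent gap.

    The gap after triplet ``after_triplet`` is the 100 ms "_" of that
    triplet; a 50 ms distractor leaves 25 ms of silence on either side.  No
    existing event moves.
    """
    n = timeline.n_triplets
    if not 1 <= after_triplet < n:
        raise ValueError(
            f"after_triplet must be in 1..{n - 1} for a {n}-triplet sequence, "
            f"got {after_triplet}"
        )
    _require_unperturbed(timeline, "apply_distractor")
    gap_start = TRIPLET_MS * after_triplet - GAP_MS
    if dur_ms <= 0 or dur_ms > GAP_MS:
        raise ValueError(
            f"dur_ms must be in 1..{GAP_MS} (the inter-triplet gap), got {dur_ms}"
        )
    if (GAP_MS - dur_ms) % 2:
        raise ValueError(
            f"dur_ms must leave an even number of silent ms in the {GAP_MS} ms gap"
        )
    freq = resolve_freq_spec(freq_spec, timeline.freq_a, timeline.freq_b)
    onset = gap_start + (GAP_MS - dur_ms) // 2
    new_event = ToneEvent(onset, dur_ms, freq, "distractor")
    events = tuple(sorted(timeline.events + (new_event,), key=lambda e: e.onset_ms))
    return replace(
        timeline,
        events=events,
        perturbation=Perturbation(
            kind="distractor",
            freq_spec=freq_spec,
            after_triplet=after_triplet,
            dur_ms=dur_ms,
        ),
    )


def apply_deviant(
    timeline: StimulusTimeline, offset_st: float, in_triplet: int
) -> StimulusTimeline:
    """Shift the B tone of 1-based triplet ``in_triplet`` by ``offset_st`` st.

    Only that one event changes: its frequency becomes ``freq_B * 2^(offset/12)``
    and its label becomes "deviant".  Timing and all other events are
    untouched (contrast with a distractor, which adds an event).
    """
    n = timeline.n_triplets
    if not 1 <= in_triplet <= n:
        raise ValueError(
            f"in_triplet must be in 1..{n} for a {n}-triplet sequence, got {in_triplet}"
        )
    _require_unperturbed(timeline, "apply_deviant")
    b_seen = 0
    events = []
    for ev in timeline.events:
        if ev.label == "B":
            b_seen += 1
            if b_seen == in_triplet:
                ev = replace(
                    ev, freq_hz=st_to_hz(ev.freq_hz, offset_st), label="deviant"
                )
        events.append(ev)
    return replace(
        timeline,
        events=tuple(events),
        perturbation=Perturbation(
            kind="deviant", offset_st=offset_st, in_triplet=in_triplet
        ),
    )


def rove_ladder_hz() -> np.ndarray:
    """The fixed ladder of base (A) frequencies between 420 and 1060 Hz.

    Five values equally spaced in log frequency with both endpoints
    included; successive members are separated by (nominally) 4 semitones,
    so the highest B tone at DF = 10 st reaches 1060 * 2^(10/12) ~ 1888 Hz.
    """
    n = int(round(hz_to_st(ROVE_MAX_HZ, ROVE_MIN_HZ) / ROVE_STEP_ST)) + 1
    return np.geomspace(ROVE_MIN_HZ, ROVE_MAX_HZ, n)


def rove_base_frequency(rng_seed) -> float:
    """Draw one base frequency uniformly from the roving ladder.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    Roving the base frequency between trials avoids carry-over adaptation.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ladder = rove_ladder_hz()
    return float(rng.choice(ladder))


# ---------------------------------------------------------------------------
# Experimental designs
# ---------------------------------------------------------------------------

DF_CONDITIONS = (4.0, 7.0, 10.0)


@dataclass(frozen=True)
class TrialCondition:
    """One cell-instance of a factorial design."""

    df_st: float
    n_context_triplets: int
    n_test_triplets: int
    perturbation: Perturbation
    repetition: int

    def __post_init__(self) -> None:
        if self.n_context_triplets < 0 or self.n_test_triplets < 0:
            raise ValueError("triplet counts must be >= 0")

    @property
    def n_triplets(self) -> int:
        return self.n_context_triplets + self.n_test_triplets


@dataclass(frozen=True)
class DesignTable:
    """Enumerated trial conditions of one experiment."""

    rows: tuple[TrialCondition, ...]
    experiment_name: str

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self, master_seed: int | None = None):
        """Tabulate the design; with a seed, assign roved base freqs + trial seeds."""
        import pandas as pd

        records = []
        for i, row in enumerate(self.rows):
            rec = {
                "experiment": self.experiment_name,
                "df_st": row.df_st,
                "n_triplets": row.n_triplets,
                "perturbation": row.perturbation.describe(),
                "repetition": row.repetition,
            }
            if master_seed is not None:
                rng = np.random.default_rng(
                    np.random.SeedSequence(master_seed, spawn_key=(i,))
                )
                rec["base_freq_hz"] = round(rove_base_frequency(rng), 2)
                rec["seed"] = int(rng.integers(0, 2**31 - 1))
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path, master_seed: int | None = None) -> None:
        self.to_frame(master_seed).to_csv(path, index=False)


def pause_experiment_design(repetitions: int = 20) -> DesignTable:
    """The pause experiment: 3 DF x 5 length/pause cells x repetitions.

    Cells: 3-triplet, 7-triplet and 10-triplet controls, and 7 context
    triplets + pause (300 or 600 ms) + 3 test triplets.  With the standard
    20 repetitions this is 15 conditions and 300 trials.
    """
    if repetitions < 1:
        raise ValueError(f"repetitions must be >= 1, got {repetitions}")
    cells = [
        (0, 3, Perturbation()),
        (4, 3, Perturbation()),
        (7, 3, Perturbation()),
        (7, 3, Perturbation(kind="pause", pause_ms=300, after_triplet=7)),
        (7, 3, Perturbation(kind="pause", pause_ms=600, after_triplet=7)),
    ]
    rows = [
        TrialCondition(df, ctx, test, pert, rep)
        for df in DF_CONDITIONS
        for (ctx, test, pert) in cells
        for rep in range(1, repetitions + 1)
    ]
    return DesignTable(tuple(rows), "pause")


def perturbation_experiment_design(
    perturbation_cells: Sequence[str], repetitions: int = 20
) -> DesignTable:
    """The distractor/deviant experiment: 3 DF x (2 controls + cells) x reps.

    Controls are 3- and 6-triplet unperturbed sequences.  Each cell names a
    distractor frequency spec ("distractor:B+2") or deviant offset
    ("deviant:+2"); distractors go in the gap after triplet 3 of 6, deviants
    in triplet 3 of 6.
    """
    if repetitions < 1:
        raise ValueError(f"repetitions must be >= 1, got {repetitions}")
    if not perturbation_cells:
        warnings.warn("no perturbation cells given; design has controls only")
    cells: list[tuple[int, int, Perturbation]] = [
        (0, 3, Perturbation()),
        (3, 3, Perturbation()),
    ]
    for cell in perturbation_cells:
        kind, _, arg = cell.partition(":")
        if kind == "distractor":
            pert = Perturbation(
                kind="distractor", freq_spec=arg, after_triplet=3, dur_ms=50
            )
        elif kind == "deviant":
            pert = Perturbation(kind="deviant", offset_st=float(arg), in_triplet=3)
        else:
            raise ValueError(
                f"cell {cell!r} must look like 'distractor:B+2' or 'deviant:+2'"
            )
        cells.append((3, 3, pert))
    rows = [
        TrialCondition(df, ctx, test, pert, rep)
        for df in DF_CONDITIONS
        for (ctx, test, pert) in cells
        for rep in range(1, repetitions + 1)
    ]
    return DesignTable(tuple(rows), "perturbation")


def build_timeline(
    cond: TrialCondition, base_freq_hz: float = DEFAULT_BASE_HZ
) -> StimulusTimeline:
    """Materialize a TrialCondition into a StimulusTimeline."""
    tl = make_triplet_sequence(cond.n_triplets, cond.df_st, base_freq_hz)
    p = cond.perturbation
    if p.kind == "pause":
        tl = apply_pause(tl, p.pause_ms, p.after_triplet)
    elif p.kind == "distractor":
        tl = apply_distractor(tl, p.freq_spec, p.after_triplet, p.dur_ms)
    elif p.kind == "deviant":
        tl = apply_deviant(tl, p.offset_st, p.in_triplet)
    return tl


# ---------------------------------------------------------------------------
# Audio synthesis
# ---------------------------------------------------------------------------


def synthesize_waveform(
    timeline: StimulusTimeline,
    sample_rate: int = 44100,
    ramp_ms: float = 10.0,
    level_db: float = 65.0,
) -> np.ndarray:
    """Render the timeline as a float waveform.

    Each tone is a pure sinusoid with linear on/off ramps of ``ramp_ms``;
    everything else is exact silence.  ``level_db`` is a digital full-scale
    convention, not calibrated SPL: the nominal presentation level of 65 dB
    maps to a peak amplitude of 0.5, and other levels scale relative to it.
    """
    if sample_rate < 8000:
        raise ValueError(f"sample_rate must be >= 8000, got {sample_rate}")
    peak = 0.5 * 10.0 ** ((level_db - 65.0) / 20.0)
    n_total = int(round(timeline.total_ms * sample_rate / 1000.0))
    out = np.zeros(n_total, dtype=np.float64)
    for ev in timeline.events:
        if 2 * ramp_ms > ev.duration_ms:
            raise ValueError(
                f"ramp_ms={ramp_ms} too long for a {ev.duration_ms} ms tone"
            )
        i0 = int(round(ev.onset_ms * sample_rate / 1000.0))
        n = int(round(ev.duration_ms * sample_rate / 1000.0))
        t = np.arange(n) / sample_rate
        tone = np.sin(2.0 * np.pi * ev.freq_hz * t)
        n_ramp = int(round(ramp_ms * sample_rate / 1000.0))
        env = np.ones(n)
        if n_ramp > 0:
            ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
            env[:n_ramp] = ramp
            env[n - n_ramp :] = ramp[::-1]
        out[i0 : i0 + n] += peak * tone * env
    return out


def write_wav(path, waveform: np.ndarray, sample_rate: int, fmt: str = "float32"):
    """Write a waveform as WAV (``fmt``: "float32" or "pcm16")."""
    from scipy.io import wavfile

    if fmt == "float32":
        wavfile.write(path, sample_rate, waveform.astype(np.float32))
    elif fmt == "pcm16":
        scaled = np.clip(waveform, -1.0, 1.0) * 32767.0
        wavfile.write(path, sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError(f"fmt must be 'float32' or 'pcm16', got {fmt!r}")
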