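"""Scaling of human walking-gait muscle traces to mouse ex vivo commands.

Human musculoskeletal walking simulations provide, for one gait cycle, the
time-varying fiber length, excitation and force of soleus and EDL.  To replay
that cycle on an isolated mouse muscle mounted on a servomotor, fiber length
is first normalized by the human optimal fiber length,

    L~(t) = L_human(t) / Lo_human,

and the normalized trajectory is then re-expressed as a signed length change
about the mouse optimal length,

    dL_mouse(t) = L~(t) * Lo_mouse - Lo_mouse,

which drives the lever arm.  Excitation is mapped to stimulator voltage over a
configurable range and the stimulus train is synchronized with the length
command at the command sample rate (222 Hz by default).

Units package-wide: lengths mm, forces mN (human simulation forces in N),
voltages V, times s, frequencies Hz.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Muscle",
    "MuscleArchitecture",
    "HumanGaitTrace",
    "NormalizedTrace",
    "CommandWaveform",
    "EccentricSpec",
    "EventKind",
    "TimelineEvent",
    "ProtocolTimeline",
    "DEFAULT_COMMAND_RATE_HZ",
    "DEFAULT_VOLTAGE_RANGE",
    "ESCALATED_VOLTAGE_RANGE",
    "FORCE_FREQUENCY_STEPS_HZ",
    "normalize_length",
    "scale_to_mouse",
    "normalize_force",
    "build_eccentric_command",
    "build_gait_cycle_command",
    "build_timeline",
]

#: Command/stimulus synchronization rate for gait cycling (Hz).
DEFAULT_COMMAND_RATE_HZ = 222.0
#: Initial stimulator voltage range for excitation mapping (V).
DEFAULT_VOLTAGE_RANGE = (0.0, 20.0)
#: Escalated range used when the initial range cannot reach the target force.
ESCALATED_VOLTAGE_RANGE = (0.0, 80.0)
#: Stimulation frequencies of the force-frequency block, twitch (1 Hz) to 180 Hz.
FORCE_FREQUENCY_STEPS_HZ = (1, 10, 20, 40, 60, 80, 100, 120, 150, 180)


class Muscle(str, enum.Enum):
    SOLEUS = "soleus"
    EDL = "EDL"

    @classmethod
    def coerce(cls, value: "Muscle | str") -> "Muscle":
        if isinstance(value, cls):
            return value
        for m in cls:
            if m.value.lower() == str(value).lower():
                return m
        raise ValueError(f"unknown muscle {value!r}; expected one of "
                         f"{[m.value for m in cls]}")


class InvalidArchitectureError(ValueError):
    """A muscle-architecture constant is missing or non-positive."""


@dataclass(frozen=True)
class MuscleArchitecture:
    """Species-paired architecture constants for one muscle.

    Parameters
    ----------
    muscle : Muscle
        Which muscle the constants describe (soleus or EDL).
    lo_mouse_mm : float
        Optimal length of the mouse muscle (mm).
    lo_human_mm : float
        Optimal fiber length of the human muscle in the lower-limb model (mm).
    fmax_human_n : float
        Maximum isometric force of the human muscle in the model (N).
    fmax_mouse_mn : float, optional
        Measured maximum isometric force of the mouse muscle (mN).  Unknown
        until a pre-protocol force-frequency record has been collected.
    """

    muscle: Muscle
    lo_mouse_mm: float
    lo_human_mm: float
    fmax_human_n: float
    fmax_mouse_mn: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "muscle", Muscle.coerce(self.muscle))
        for name in ("lo_mouse_mm", "lo_human_mm", "fmax_human_n"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidArchitectureError(f"{name} must be finite and > 0, got {v}")
        if self.fmax_mouse_mn is not None and not self.fmax_mouse_mn > 0:
            raise InvalidArchitectureError(
                f"fmax_mouse_mn must be > 0 when present, got {self.fmax_mouse_mn}")


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass(frozen=True)
class HumanGaitTrace:
    """One gait cycle of a human muscle from a walking simulation.

    ``time_s`` spans one cycle and is strictly increasing; ``fiber_length_mm``
    is in the same units as ``lo_human_mm``; ``excitation`` lies in [0, 1];
    ``force_n`` is non-negative (Newtons, the human-model scale).
    """

    time_s: np.ndarray
    fiber_length_mm: np.ndarray
    excitation: np.ndarray
    force_n: np.ndarray

    def __post_init__(self) -> None:
        t = _as_1d(self.time_s, "time_s")
        ln = _as_1d(self.fiber_length_mm, "fiber_length_mm")
        ex = _as_1d(self.excitation, "excitation")
        f = _as_1d(self.force_n, "force_n")
        if not (len(t) == len(ln) == len(ex) == len(f)):
            raise ValueError("all trace arrays must have equal length")
        if len(t) < 2:
            raise ValueError("a gait trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")
        if ex.min() < 0 or ex.max() > 1:
            raise ValueError("excitation must lie in [0, 1]")
        if f.min() < 0:
            raise ValueError("force_n must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "fiber_length_mm", ln)
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "force_n", f)

    @property
    def cycle_duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class NormalizedTrace:
    """A dimensionless signal on the time grid of its source trace."""

    time_s: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = _as_1d(self.time_s, "time_s")
        v = _as_1d(self.value, "value")
        if len(t) != len(v):
            raise ValueError("time_s and value must have equal length")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "value", v)


#: Relative tolerance on command-grid uniformity (one part in 10^6).
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class CommandWaveform:
    """Time-stamped length-change and voltage commands for the apparatus.

    ``delta_length_mm`` is signed, relative to the mouse optimal length;
    ``voltage_v`` is the stimulation envelope amplitude.  The grid is uniform
    at ``1 / sample_rate_hz``.  ``stim_freq_hz`` records the pulse frequency
    carried by the envelope where a single frequency applies (eccentric and
    tetanic commands); gait commands synchronize pulses at the sample rate.
    """

    time_s: np.ndarray
    delta_length_mm: np.ndarray
    voltage_v: np.ndarray
    sample_rate_hz: float
    stim_freq_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = _as_1d(self.time_s, "time_s")
        d = _as_1d(self.delta_length_mm, "delta_length_mm")
        v = _as_1d(self.voltage_v, "voltage_v")
        if not (len(t) == len(d) == len(v)):
            raise ValueError("command arrays must have equal length")
        if len(t) == 0:
            raise ValueError("empty command waveform")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        dt = 1.0 / self.sample_rate_hz
        if len(t) > 1 and np.max(np.abs(np.diff(t) - dt)) > _GRID_RTOL * dt:
            raise ValueError("command time grid is not uniform at 1/sample_rate")
        if v.min() < 0:
            raise ValueError("voltage must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "delta_length_mm", d)
        object.__setattr__(self, "voltage_v", v)

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    def concat(self, other: "CommandWaveform") -> "CommandWaveform":
        """Append ``other`` directly after this waveform (half-open cycles)."""
        if not math.isclose(self.sample_rate_hz, other.sample_rate_hz):
            raise ValueError("sample rates differ")
        dt = 1.0 / self.sample_rate_hz
        t0 = self.time_s[-1] + dt
        return CommandWaveform(
            np.concatenate([self.time_s, other.time_s - other.time_s[0] + t0]),
            np.concatenate([self.delta_length_mm, other.delta_length_mm]),
            np.concatenate([self.voltage_v, other.voltage_v]),
            self.sample_rate_hz,
            self.stim_freq_hz,
            {**self.meta, **other.meta},
        )


def normalize_length(trace: HumanGaitTrace, arch: MuscleArchitecture) -> NormalizedTrace:
    """Normalize human fiber length by the human optimal fiber length.

    Returns L~(t) = L_human(t) / Lo_human on the same time grid.
    """
    if arch.lo_human_mm <= 0:
        raise InvalidArchitectureError("lo_human_mm must be > 0")
    return NormalizedTrace(trace.time_s, trace.fiber_length_mm / arch.lo_human_mm)


def _resample_halfopen(time: np.ndarray, value: np.ndarray, sample_rate: float,
                       duration: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Shape-preserving (PCHIP) resampling onto a uniform half-open grid.

    The grid holds ``round(duration * sample_rate)`` samples starting at the
    trace start; the cycle end is exclusive so concatenated cycles never
    duplicate the boundary sample.
    """
    if duration is None:
        duration = float(time[-1] - time[0])
    n = int(round(duration * sample_rate))
    if n < 1:
        raise ValueError("duration too short for the command sample rate")
    t = np.arange(n) / sample_rate
    # map command times onto the source grid (with optional time warp)
    src_span = float(time[-1] - time[0])
    src_t = time[0] + t * (src_span / duration)
    interp = PchipInterpolator(time, value)
    return t, interp(src_t)


def scale_to_mouse(norm: NormalizedTrace, arch: MuscleArchitecture,
                   sample_rate_hz: float = DEFAULT_COMMAND_RATE_HZ) -> CommandWaveform:
    """Convert a normalized length trajectory into a mouse length-change command.

    dL_mouse(t) = L~(t) * Lo_mouse - Lo_mouse, resampled to the command rate.
    The voltage channel is zeroed; excitation mapping happens in
    :func:`build_gait_cycle_command`.
    """
    if len(norm.time_s) == 0:
        raise ValueError("empty normalized trace")
    if arch.lo_mouse_mm <= 0:
        raise InvalidArchitectureError("lo_mouse_mm must be > 0")
    t, v = _resample_halfopen(norm.time_s, norm.value, sample_rate_hz)
    delta = v * arch.lo_mouse_mm - arch.lo_mouse_mm
    return CommandWaveform(t, delta, np.zeros_like(t), sample_rate_hz,
                           meta={"muscle": arch.muscle.value})


def normalize_force(force: Sequence[float], fmax: float,
                    time_s: Sequence[float] | None = None) -> NormalizedTrace:
    """Normalize a force trace by its muscle's maximum isometric force.

    Human forces are divided by the model Fmax, mouse forces by the measured
    pre-force-frequency maximum; both must be supplied in the same units as
    their reference.
    """
    if fmax is None or fmax <= 0:
        raise ValueError(f"invalid reference force fmax={fmax}; must be > 0")
    f = _as_1d(force, "force")
    if f.min() < 0:
        raise ValueError("force must be non-negative")
    t = _as_1d(time_s, "time_s") if time_s is not None else np.arange(len(f), dtype=float)
    return NormalizedTrace(t, f / fmax)


@dataclass(frozen=True)
class EccentricSpec:
    """Parameters of one eccentric-contraction protocol.

    The muscle is stimulated at ``stim_freq_hz`` for an isometric hold, then
    lengthened at ``strain_rate_lo_per_s`` until the commanded displacement
    reaches ``strain`` of the mouse optimal length (10/20/30% in the study
    conditions; ramp durations 200/400/600 ms at 0.5 Lo/s).
    """

    strain: float
    strain_rate_lo_per_s: float = 0.5
    isometric_hold_s: float = 0.5
    stim_freq_hz: float = 80.0
    n_reps: int = 5
    inter_rep_rest_s: float = 240.0
    recovery_times_min: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0)

    def __post_init__(self) -> None:
        if self.strain < 0:
            raise ValueError("strain must be >= 0")
        if self.strain_rate_lo_per_s <= 0:
            raise ValueError("strain_rate must be > 0")
        if self.isometric_hold_s < 0 or self.stim_freq_hz <= 0:
            raise ValueError("invalid hold duration or stimulation frequency")
        if self.n_reps < 1 or self.inter_rep_rest_s < 0:
            raise ValueError("invalid repetition schedule")

    @property
    def ramp_duration_s(self) -> float:
        return self.strain / self.strain_rate_lo_per_s


def build_eccentric_command(spec: EccentricSpec, arch: MuscleArchitecture,
                            sample_rate_hz: float = 1000.0,
                            stim_amplitude_v: float = 30.0) -> CommandWaveform:
    """Build one eccentric repetition: isometric hold then constant-rate ramp.

    The ramp sample count is ``round(ramp_duration * sample_rate)`` and the
    commanded endpoint is recomputed so the final sample equals
    ``strain * Lo_mouse`` exactly — endpoint fidelity is preferred over exact
    rate when the duration is not representable on the grid.  The voltage
    channel carries a constant stimulation envelope over hold + ramp, with
    the pulse frequency recorded in ``stim_freq_hz``.
    """
    fs = float(sample_rate_hz)
    if fs <= 0:
        raise ValueError("sample_rate_hz must be > 0")
    n_hold = int(round(spec.isometric_hold_s * fs))
    n_ramp = int(round(spec.ramp_duration_s * fs))
    final = spec.strain * arch.lo_mouse_mm
    hold = np.zeros(max(n_hold, 1))
    if n_ramp > 0:
        # endpoint honored exactly at the last sample of the realized ramp
        ramp = final * np.arange(1, n_ramp + 1) / n_ramp
    else:
        ramp = np.empty(0)
    delta = np.concatenate([hold, ramp])
    t = np.arange(len(delta)) / fs
    volts = np.full_like(delta, float(stim_amplitude_v))
    return CommandWaveform(
        t, delta, volts, fs, stim_freq_hz=spec.stim_freq_hz,
        meta={"muscle": arch.muscle.value, "strain": spec.strain,
              "strain_rate_lo_per_s": spec.strain_rate_lo_per_s,
              "realized_ramp_s": n_ramp / fs},
    )


def map_excitation_to_voltage(excitation: np.ndarray, voltage_scale: float,
                              voltage_range: tuple[float, float] = DEFAULT_VOLTAGE_RANGE,
                              ) -> np.ndarray:
    """Linear map of excitation in [0, 1] onto the active voltage range,
    multiplied by the calibration scale factor."""
    if voltage_scale < 0:
        raise ValueError("voltage_scale must be >= 0")
    lo, hi = voltage_range
    if not hi > lo:
        raise ValueError("voltage_range must satisfy lo < hi")
    return voltage_scale * (lo + np.asarray(excitation, float) * (hi - lo))


def build_gait_cycle_command(trace: HumanGaitTrace, arch: MuscleArchitecture,
                             voltage_scale: float = 1.0,
                             cycle_rate_hz: float = 1.0,
                             sample_rate_hz: float = DEFAULT_COMMAND_RATE_HZ,
                             voltage_range: tuple[float, float] = DEFAULT_VOLTAGE_RANGE,
                             n_cycles: int = 1) -> CommandWaveform:
    """Build gait-mimicking cycling commands from one human gait trace.

    The human cycle is time-warped to ``1 / cycle_rate_hz`` (1 s at the study
    cadence), the length channel scaled through the normalization/rescaling
    chain, and excitation mapped to voltage.  One 1-s cycle at 222 Hz holds
    exactly 222 samples (half-open; concatenated cycles share no boundary
    sample).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if cycle_rate_hz <= 0:
        raise ValueError("cycle_rate_hz must be > 0")
    duration = 1.0 / cycle_rate_hz
    norm = normalize_length(trace, arch)
    t, v = _resample_halfopen(norm.time_s, norm.value, sample_rate_hz, duration)
    delta = v * arch.lo_mouse_mm - arch.lo_mouse_mm
    _, exc = _resample_halfopen(trace.time_s, trace.excitation, sample_rate_hz, duration)
    exc = np.clip(exc, 0.0, 1.0)
    volts = map_excitation_to_voltage(exc, voltage_scale, voltage_range)
    if n_cycles > 1:
        delta = np.tile(delta, n_cycles)
        volts = np.tile(volts, n_cycles)
        t = np.arange(len(delta)) / sample_rate_hz
    return CommandWaveform(
        t, delta, volts, sample_rate_hz,
        meta={"muscle": arch.muscle.value, "voltage_scale": voltage_scale,
              "voltage_range": list(voltage_range), "n_cycles": n_cycles},
    )


# ---------------------------------------------------------------------------
# Protocol timelines
# ---------------------------------------------------------------------------

class EventKind(str, enum.Enum):
    TWITCH = "twitch"
    TETANUS = "tetanus"
    FORCE_FREQUENCY_STEP = "force_frequency_step"
    REST = "rest"
    GAIT_CYCLE = "gait_cycle"
    ECCENTRIC_REP = "eccentric_rep"
    VOLTAGE_OPTIMIZATION = "voltage_optimization"


@dataclass(frozen=True)
class TimelineEvent:
    kind: EventKind
    start_s: float
    duration_s: float
    attrs: dict = field(default_factory=dict)

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered, non-overlapping timed events of one ex vivo protocol."""

    protocol: str
    events: tuple[TimelineEvent, ...]

    def __post_init__(self) -> None:
        ev = tuple(self.events)
        for a, b in zip(ev, ev[1:]):
            if b.start_s < a.start_s:
                raise ValueError("events must be sorted by start time")
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(
                    f"events overlap: {a.kind.value}@{a.start_s} and "
                    f"{b.kind.value}@{b.start_s}")
        object.__setattr__(self, "events", ev)

    def count(self, kind: EventKind, **attrs) -> int:
        n = 0
        for e in self.events:
            if e.kind is kind and all(e.attrs.get(k) == v for k, v in attrs.items()):
                n += 1
        return n

    @property
    def total_span_s(self) -> float:
        return self.events[-1].end_s if self.events else 0.0

    def to_records(self) -> list[dict]:
        return [{"kind": e.kind.value, "start_s": e.start_s,
                 "duration_s": e.duration_s, **e.attrs} for e in self.events]


_TWITCH_S = 0.1          # single-pulse response window
_TETANUS_S = 0.5         # stimulus train duration of one tetanus
_FF_STEP_S = 0.5
_EVENT_SPACING_S = 60.0  # 1 min between pre-contractions / force-frequency steps
_QUIESCENCE_S = 600.0    # 10 min quiescence blocks


class _Builder:
    def __init__(self) -> None:
        self.events: list[TimelineEvent] = []
        self.cursor = 0.0

    def add(self, kind: EventKind, duration: float, gap_before: float = 0.0, **attrs):
        start = self.cursor + gap_before
        self.events.append(TimelineEvent(kind, start, duration, attrs))
        self.cursor = start + duration
        return self.events[-1]


def _force_frequency(b: _Builder, phase: str, gap_before: float) -> None:
    first = True
    for f in FORCE_FREQUENCY_STEPS_HZ:
        b.add(EventKind.FORCE_FREQUENCY_STEP, _FF_STEP_S,
              gap_before=gap_before if first else _EVENT_SPACING_S - _FF_STEP_S,
              freq_hz=f, phase=phase)
        first = False


def build_timeline(protocol: str, spec: EccentricSpec | None = None,
                   arch: MuscleArchitecture | None = None) -> ProtocolTimeline:
    """Build the timed event list of one of the three protocols.

    ``protocol`` is one of ``eccentric``, ``cycling25`` or ``cycling200``.
    An :class:`EccentricSpec` is required exactly for the eccentric protocol.
    All protocols begin with the pre-contraction block (3 twitches, 3 tetani at
    150 Hz, 1 min apart) and the pre-force-frequency (1–180 Hz, 1 min between
    steps).  The cycling protocols add voltage optimization, the cycle sets
    (25 cycles per set, 1 cycle/s, 1-min inter-set rests), viability tetani at
    120 Hz (after cycle 100 in the 200-cycle protocol, and 1 min after the last
    cycle), and the post-force-frequency after 10 min of rest.  The eccentric
    protocol adds 5 stretch repetitions with 4-min quiescence and 80-Hz
    recovery tetani at 5/10/15/30 min after the final stretch.
    """
    protocol = str(protocol)
    if protocol == "eccentric":
        if spec is None:
            raise ValueError("eccentric timeline requires an EccentricSpec")
        n_cycles = 0
    elif protocol == "cycling25":
        if spec is not None:
            raise ValueError("spec is only accepted for the eccentric protocol")
        n_cycles = 25
    elif protocol == "cycling200":
        if spec is not None:
            raise ValueError("spec is only accepted for the eccentric protocol")
        n_cycles = 200
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    b = _Builder()
    # pre-contractions: onsets 1 min apart
    for i in range(3):
        b.add(EventKind.TWITCH, _TWITCH_S,
              gap_before=0.0 if i == 0 else _EVENT_SPACING_S - _TWITCH_S, index=i)
    for i in range(3):
        gap = _EVENT_SPACING_S - (_TWITCH_S if i == 0 else _TETANUS_S)
        b.add(EventKind.TETANUS, _TETANUS_S, gap_before=gap,
              freq_hz=150, phase="pre_contraction", index=i)
    # 10 min quiescence then pre-force-frequency
    _force_frequency(b, "pre", gap_before=_QUIESCENCE_S)

    if n_cycles:
        # voltage optimization, then 5 min rest before cycling
        b.add(EventKind.VOLTAGE_OPTIMIZATION, 60.0, gap_before=_EVENT_SPACING_S)
        b.cursor += 300.0
        cycle_s = 1.0
        set_size = 25
        n_sets = n_cycles // set_size
        cycle_idx = 0
        for s in range(n_sets):
            if s > 0:
                # 1-min rest between sets; after the 100th cycle of the
                # 200-cycle protocol a 120-Hz viability tetanus sits 1 s into
                # that rest and the rest event covers the remainder.
                if n_cycles == 200 and cycle_idx == 100:
                    b.add(EventKind.TETANUS, _TETANUS_S, gap_before=1.0,
                          freq_hz=120, phase="mid_protocol", after_cycle=cycle_idx)
                    b.add(EventKind.REST, _EVENT_SPACING_S - 1.0 - _TETANUS_S,
                          between_sets=True)
                else:
                    b.add(EventKind.REST, _EVENT_SPACING_S, between_sets=True)
            for _ in range(set_size):
                b.add(EventKind.GAIT_CYCLE, cycle_s, set_index=s,
                      cycle_index=cycle_idx)
                cycle_idx += 1
        # 1 min after the final cycle: 120-Hz tetanus, then 10 min rest, post-FF
        b.add(EventKind.TETANUS, _TETANUS_S, gap_before=_EVENT_SPACING_S,
              freq_hz=120, phase="post_protocol", after_cycle=cycle_idx)
        _force_frequency(b, "post", gap_before=_QUIESCENCE_S)
        tl = ProtocolTimeline(protocol, tuple(b.events))
        if tl.total_span_s > 5400.0:
            raise AssertionError("cycling timeline exceeds the 1.5-hour budget")
        return tl

    # eccentric protocol
    rep_dur = spec.isometric_hold_s + spec.ramp_duration_s
    for r in range(spec.n_reps):
        b.add(EventKind.ECCENTRIC_REP, rep_dur,
              gap_before=_QUIESCENCE_S if r == 0 else spec.inter_rep_rest_s,
              rep_index=r, strain=spec.strain, stim_freq_hz=spec.stim_freq_hz)
    final_stretch_end = b.cursor
    for m in spec.recovery_times_min:
        start = final_stretch_end + m * 60.0
        b.events.append(TimelineEvent(EventKind.TETANUS, start, _TETANUS_S,
                                      {"freq_hz": spec.stim_freq_hz,
                                       "phase": "recovery",
                                       "recovery_min": m}))
    b.events.sort(key=lambda e: e.start_s)
    return ProtocolTimeline(protocol, tuple(b.events))
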