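"""Protocol-faithful synthetic EEG, facial EMG bursts, and contaminated mixtures.

Emulates a facial-contraction recording session: five facial muscles
(Frontalis, Masseter, Orbicularis Oculi, Orbicularis Oris, Zygomatic), each
contracted 15 times per eye condition in three timing patterns — long (3 s),
medium (1 s) and short (0.5 s), five repetitions of each in seeded random
order — with a 2 s neutral period after every contraction, an open-eyes block
followed by a closed-eyes block, and elevated alpha power while eyes are
closed.  The EMG channel is band-limited Gaussian noise gated by a
trapezoidal burst envelope; the mixture is scaled so the in-burst
EEG-to-EMG power ratio matches a requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .types import ContaminationMask, TimeSeries

__all__ = [
    "Muscle",
    "DurationClass",
    "EyeCondition",
    "ProtocolEvent",
    "ProtocolTimeline",
    "SynthParams",
    "generate_protocol",
    "synthesize_eeg",
    "synthesize_emg",
    "mix",
    "EEG_BANDS",
]


class Muscle(str, Enum):
    FRONTALIS = "Frontalis"
    MASSETER = "Masseter"
    ORBICULARIS_OCULI = "OrbicularisOculi"
    ORBICULARIS_ORIS = "OrbicularisOris"
    ZYGOMATIC = "Zygomatic"


class DurationClass(float, Enum):
    LONG = 3.0
    MEDIUM = 1.0
    SHORT = 0.5


class EyeCondition(str, Enum):
    OPEN = "open"
    CLOSED = "closed"


#: Canonical EEG rhythm bands (Hz): closed on the left, open on the right.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "Delta": (0.5, 4.0),
    "Theta": (4.0, 7.0),
    "Alpha": (7.0, 13.0),
    "Beta": (13.0, 30.0),
    "Gamma": (30.0, 70.0),
}

#: Neutral period after every contraction (s).
NEUTRAL_GAP_S = 2.0

#: Repetitions of each duration class per muscle per eye condition.
REPS_PER_CLASS = 5


@dataclass(frozen=True)
class ProtocolEvent:
    """One muscle contraction within the session."""

    muscle: Muscle
    duration_class: DurationClass
    onset_s: float
    eye_condition: EyeCondition
    participant: int = 0

    @property
    def duration_s(self) -> float:
        return float(self.duration_class.value)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered contraction events for one or more participants."""

    events: tuple[ProtocolEvent, ...]
    n_participants: int
    fs: float

    @property
    def duration_s(self) -> float:
        """Record length: last contraction end plus the trailing neutral gap."""
        if not self.events:
            return NEUTRAL_GAP_S
        return self.events[-1].end_s + NEUTRAL_GAP_S

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def total_contaminated_s(self) -> float:
        return sum(e.duration_s for e in self.events)

    def closed_eyes_intervals(self) -> list[tuple[float, float]]:
        """Contiguous closed-eyes blocks, in seconds.

        Each participant's closed-eyes block runs from the midpoint between
        their last open-eyes event and first closed-eyes event to the end of
        their portion of the record.
        """
        out = []
        for p in range(self.n_participants):
            ev = [e for e in self.events if e.participant == p]
            closed = [e for e in ev if e.eye_condition is EyeCondition.CLOSED]
            if not closed:
                continue
            open_ = [e for e in ev if e.eye_condition is EyeCondition.OPEN]
            first_closed = min(e.onset_s for e in closed)
            if open_:
                last_open_end = max(e.end_s for e in open_)
                start = 0.5 * (last_open_end + first_closed)
            else:
                start = min(e.onset_s for e in ev) - NEUTRAL_GAP_S
            end = max(e.end_s for e in ev) + NEUTRAL_GAP_S
            out.append((start, end))
        return out


@dataclass(frozen=True)
class SynthParams:
    """Generator settings for the synthetic EEG/EMG channels.

    Band variances are in µV²; their defaults give a ~7 µV RMS background
    EEG with the usual low-frequency dominance.  ``alpha_closed_gain``
    multiplies the alpha-band *variance* during closed-eyes blocks
    (Berger effect); 4 is a typical eyes-closed posterior enhancement.
    ``emg_band`` covers the surface-EMG bandwidth within the acquisition
    band.  ``snr_db`` is the in-burst EEG-to-EMG power ratio; facial-EMG
    contamination of scalp EEG commonly sits at −10 dB and below.
    """

    fs: float = 5000.0
    eeg_band_powers: dict = field(
        default_factory=lambda: {
            "Delta": 25.0,
            "Theta": 9.0,
            "Alpha": 16.0,
            "Beta": 4.0,
            "Gamma": 1.0,
        }
    )
    alpha_closed_gain: float = 4.0
    emg_band: tuple[float, float] = (20.0, 450.0)
    snr_db: float = -10.0
    envelope_rise_ms: float = 50.0
    baseline_db: float = -40.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.emg_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(
                f"emg_band must satisfy 0 < low < high < fs/2, got {self.emg_band} at fs={self.fs}"
            )
        if self.alpha_closed_gain < 1:
            raise ValueError("alpha_closed_gain must be >= 1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_protocol(
    n_participants: int,
    seed: int,
    fs: float = 5000.0,
    muscles: Sequence[Muscle] | None = None,
    eye_conditions: Sequence[EyeCondition] | None = None,
) -> ProtocolTimeline:
    """Build the contraction timeline for ``n_participants`` sessions.

    The full protocol (default ``muscles``/``eye_conditions``) yields 150
    contractions per participant: 5 muscles × 2 eye conditions × (5 long +
    5 medium + 5 short), the duration-class order shuffled within each
    muscle block.  ``muscles``/``eye_conditions`` subsets exist for
    shorter records; the per-block structure is unchanged.
    """
    if n_participants < 1:
        raise ValueError(f"n_participants must be >= 1, got {n_participants}")
    muscles = tuple(muscles) if muscles is not None else tuple(Muscle)
    conditions = (
        tuple(eye_conditions) if eye_conditions is not None else tuple(EyeCondition)
    )
    rng = _rng(seed, 1)
    events: list[ProtocolEvent] = []
    t = 0.0
    for p in range(n_participants):
        t += NEUTRAL_GAP_S  # lead-in noise period for each session
        for cond in conditions:
            for muscle in muscles:
                classes = [d for d in DurationClass for _ in range(REPS_PER_CLASS)]
                order = rng.permutation(len(classes))
                for i in order:
                    d = classes[i]
                    events.append(
                        ProtocolEvent(
                            muscle=muscle,
                            duration_class=d,
                            onset_s=t,
                            eye_condition=cond,
                            participant=p,
                        )
                    )
                    t += d.value + NEUTRAL_GAP_S
    return ProtocolTimeline(events=tuple(events), n_participants=n_participants, fs=fs)


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    nyq = fs / 2
    if high >= nyq:
        high = 0.999 * nyq
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def synthesize_eeg(timeline: ProtocolTimeline, params: SynthParams) -> TimeSeries:
    """Background EEG as a superposition of band-limited noise oscillations.

    Each canonical band contributes independent filtered noise scaled to its
    configured variance; the alpha contribution is amplified by
    ``sqrt(alpha_closed_gain)`` over closed-eyes blocks.
    """
    n = timeline.n_samples
    fs = params.fs
    rng = _rng(params.seed, 2)
    total = np.zeros(n)
    closed = np.zeros(n, dtype=bool)
    for start_s, end_s in timeline.closed_eyes_intervals():
        i0 = max(0, int(round(start_s * fs)))
        i1 = min(n, int(round(end_s * fs)))
        closed[i0:i1] = True
    for band, (low, high) in EEG_BANDS.items():
        var = params.eeg_band_powers.get(band, 0.0)
        if var <= 0:
            continue
        x = _band_noise(rng, n, fs, low, high) * np.sqrt(var)
        if band == "Alpha" and params.alpha_closed_gain != 1.0:
            gain = np.where(closed, np.sqrt(params.alpha_closed_gain), 1.0)
            x = x * gain
        total += x
    return TimeSeries(total, fs)


def _trapezoid_envelope(timeline: ProtocolTimeline, params: SynthParams) -> np.ndarray:
    """Per-sample burst envelope: 1 inside contractions, ramped edges, 0 outside.

    The rise/fall ramps live *inside* each event so the envelope support is
    exactly the event support.
    """
    n = timeline.n_samples
    fs = params.fs
    env = np.zeros(n)
    rise = params.envelope_rise_ms / 1000.0
    for e in timeline.events:
        i0 = int(round(e.onset_s * fs))
        i1 = min(n, int(round(e.end_s * fs)))
        m = i1 - i0
        if m <= 0:
            continue
        r = min(int(round(rise * fs)), m // 2)
        seg = np.ones(m)
        if r > 0:
            ramp = np.linspace(0, 1, r + 2)[1:-1]  # strictly positive inside
            seg[:r] = ramp
            seg[m - r:] = ramp[::-1]
        env[i0:i1] = seg
    return env


def synthesize_emg(
    timeline: ProtocolTimeline, params: SynthParams
) -> tuple[TimeSeries, ContaminationMask]:
    """EMG channel: band-limited noise gated by the burst envelope.

    A small always-on baseline (``baseline_db`` relative to the burst level)
    gives the channel a realistic noise floor.  The returned mask is high
    exactly where the burst envelope is nonzero.
    """
    n = timeline.n_samples
    fs = params.fs
    rng = _rng(params.seed, 3)
    carrier = _band_noise(rng, n, fs, *params.emg_band)
    env = _trapezoid_envelope(timeline, params)
    baseline = 10.0 ** (params.baseline_db / 20.0)
    emg = carrier * (env + baseline)
    mask = ContaminationMask(env > 0, fs)
    return TimeSeries(emg, fs), mask


def mix(
    eeg: TimeSeries,
    emg: TimeSeries,
    mask: ContaminationMask,
    snr_db: float,
) -> TimeSeries:
    """Contaminated channel ``eeg + g*emg`` with in-burst SNR fixed to ``snr_db``.

    The gain g is solved from the mask-high sample powers, so
    10·log10(P_eeg / P_{g·emg}) over the bursts equals ``snr_db`` exactly
    (up to float rounding).
    """
    if eeg.n != emg.n or eeg.fs != emg.fs:
        raise ValueError("eeg and emg must share length and sampling rate")
    if mask.n != eeg.n:
        raise ValueError("mask length must match the signals")
    if mask.n_high == 0:
        raise ValueError("mask has no high samples; in-burst SNR is undefined")
    p_eeg = np.mean(mask.high_samples_of(eeg.samples) ** 2)
    p_emg = np.mean(mask.high_samples_of(emg.samples) ** 2)
    if p_emg == 0:
        raise ValueError("EMG power over the mask is zero; gain is undefined")
    g = np.sqrt(p_eeg / (p_emg * 10.0 ** (snr_db / 10.0)))
    return TimeSeries(eeg.samples + g * emg.samples, eeg.fs)
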