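"""Core domain objects shared across the pipeline.

Everything downstream (detection, energy, statistics) operates on these
containers: an :class:`EEGRecording` holds the multichannel time series plus
its annotations, a :class:`Segment` is a state-labelled window cut out of a
recording, :class:`Band` defines the three analysis bands, and
:class:`HFOEvent` is a single oscillatory burst (injected or detected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CHANNELS_1020",
    "LOBE_MAP",
    "Annotation",
    "Band",
    "BANDS",
    "EEGRecording",
    "HFOEvent",
    "Segment",
    "band_of_freq",
    "lobe_of",
]

#: The 19 scalp electrodes of the International 10-20 system, canonical order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Electrode -> lobe. F7/F8 follow the anterior-temporal convention.
LOBE_MAP: dict[str, str] = {
    **{ch: "frontal" for ch in ("Fp1", "Fp2", "F3", "F4", "Fz")},
    **{ch: "temporal" for ch in ("F7", "F8", "T3", "T4", "T5", "T6")},
    **{ch: "central" for ch in ("C3", "C4", "Cz")},
    **{ch: "parietal" for ch in ("P3", "P4", "Pz")},
    **{ch: "occipital" for ch in ("O1", "O2")},
}


def lobe_of(channel: str) -> str:
    """Map a 10-20 electrode label to its lobe.

    Raises
    ------
    KeyError
        If ``channel`` is not a recognized 10-20 label.
    """
    try:
        return LOBE_MAP[channel]
    except KeyError:
        raise KeyError(
            f"unknown 10-20 channel {channel!r}; known: {sorted(LOBE_MAP)}"
        ) from None


@dataclass(frozen=True)
class Band:
    """A frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: need low < high, got {self.low}, {self.high}")

    def contains(self, freq_hz: float) -> bool:
        return self.low <= freq_hz < self.high


GAMMA = Band("gamma", 40.0, 80.0)
RIPPLE = Band("ripple", 80.0, 200.0)
FAST_RIPPLE = Band("fast_ripple", 200.0, 300.0)

#: The three analysis bands, by name.
BANDS: dict[str, Band] = {b.name: b for b in (GAMMA, RIPPLE, FAST_RIPPLE)}


def band_of_freq(freq_hz: float) -> str:
    """Band label for a frequency; 'out_of_band' outside 40-300 Hz.

    The upper edge 300 Hz belongs to fast_ripple (closed at the top of the
    analysed range).
    """
    for band in BANDS.values():
        if band.contains(freq_hz):
            return band.name
    if freq_hz == FAST_RIPPLE.high:
        return FAST_RIPPLE.name
    return "out_of_band"


@dataclass(frozen=True)
class Annotation:
    """A labelled time window; ``channel`` is an electrode label or 'all'."""

    label: str
    onset: float
    duration: float
    channel: str = "all"

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class HFOEvent:
    """One oscillatory burst on one channel.

    ``regularity`` is the max/min ratio of inter-peak intervals (1.0 for a
    perfectly regular train, undefined/1.0 when fewer than 3 peaks).
    """

    channel: str
    band: str
    onset: float
    offset: float
    n_cycles: int
    peak_amp: float
    regularity: float = 1.0

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("HFOEvent requires offset > onset")
        if self.regularity < 1.0:
            raise ValueError("regularity is max/min interval, must be >= 1")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EEGRecording:
    """Multichannel scalp EEG in microvolts.

    ``data`` has shape (n_channels, n_samples); row order matches
    ``channel_names``.
    """

    channel_names: list[str]
    fs: float
    data: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in recording (have {self.channel_names})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def annotate(self, label: str, onset: float, duration: float, channel: str = "all") -> None:
        if onset < 0 or onset + duration > self.duration + 1e-9:
            raise ValueError(
                f"annotation [{onset}, {onset + duration}] outside record of {self.duration} s"
            )
        self.annotations.append(Annotation(label, onset, duration, channel))

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            list(self.channel_names), self.fs, self.data.copy(), list(self.annotations)
        )


@dataclass
class Segment:
    """A state-labelled window of a recording.

    ``state`` is one of WNED/SNED/WED/SED/PreS/S/PostS (or the generic
    wake/sleep used by synthetic cohorts). Subject/group metadata ride along
    so energy tables can be built without a lookup.
    """

    recording: EEGRecording
    state: str
    onset: float
    subject: str | None = None
    group: str | None = None

    @property
    def fs(self) -> float:
        return self.recording.fs

    @property
    def duration(self) -> float:
        return self.recording.duration

    def with_recording(self, recording: EEGRecording) -> "Segment":
        return replace(self, recording=recording)
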