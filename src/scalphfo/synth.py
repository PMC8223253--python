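"""Synthetic annotated scalp-EEG cohorts.

No raw clinical recordings are available, so every downstream stage is
exercised on generated data with known ground truth: 1/f Gaussian background,
Hann-windowed oscillatory bursts in the gamma/ripple/fast-ripple bands,
sleep spindles, spike + slow-wave discharge complexes, and configurable
multiplicative (group, state, band) energy factors. Factors act on signal
amplitude as sqrt(factor) so the expected band energy scales linearly with
the factor.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    BANDS,
    CHANNELS_1020,
    Annotation,
    EEGRecording,
    HFOEvent,
    Segment,
    band_of_freq,
)
from .eeg_io import write_edf

__all__ = [
    "ICTAL_STATES",
    "CohortConfig",
    "GroundTruth",
    "generate_background",
    "generate_cohort",
    "inject_burst",
    "inject_discharges",
    "write_cohort",
]

#: 2-s peri-spasm stages; everything else is a 5-min interictal stage.
ICTAL_STATES = frozenset({"PreS", "S", "PostS"})

_DEFAULT_STATES = {"NC": ("wake", "sleep"), "IS": ("wake", "sleep", "PreS", "S", "PostS")}


@dataclass
class CohortConfig:
    """Design of a synthetic cohort.

    ``band_effects`` maps (group, state, band) to a multiplicative energy
    factor; missing keys default to 1. ``event_rate`` is injected bursts per
    channel per band per 5 minutes.
    """

    n_subjects_per_group: int = 5
    groups: tuple[str, ...] = ("IS", "NC")
    states_per_group: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_STATES)
    )
    fs: float = 1000.0
    interictal_duration_s: float = 300.0
    ictal_duration_s: float = 2.0
    channels: tuple[str, ...] = CHANNELS_1020
    band_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    event_rate: float = 10.0
    event_amplitude_uv: float = 25.0
    background_amplitude: float = 20.0
    band_noise_rms_ratio: float = 0.75
    discharge_rate_per_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 0:
            raise ValueError("n_subjects_per_group must be >= 0")
        if self.fs <= 0 or self.interictal_duration_s <= 0 or self.ictal_duration_s <= 0:
            raise ValueError("fs and durations must be positive")
        if self.fs < 2 * max(b.high for b in BANDS.values()):
            raise ValueError("fs below Nyquist for the injected bands")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if any(f <= 0 for f in self.band_effects.values()):
            raise ValueError("all band-effect factors must be > 0")
        for group in self.groups:
            if group not in self.states_per_group:
                raise ValueError(f"no states configured for group {group!r}")

    def factor(self, group: str, state: str, band: str) -> float:
        return self.band_effects.get((group, state, band), 1.0)

    def duration_of(self, state: str) -> float:
        return self.ictal_duration_s if state in ICTAL_STATES else self.interictal_duration_s


@dataclass
class GroundTruth:
    """Everything injected into a cohort, keyed for parameter-recovery tests."""

    injected_events: list[tuple[str, str, HFOEvent]] = field(default_factory=list)
    energy_factors: dict[tuple[str, str, str], float] = field(default_factory=dict)
    discharge_annotations: list[tuple[str, str, Annotation]] = field(default_factory=list)

    def events_for(self, subject: str, state: str) -> list[HFOEvent]:
        return [ev for s, st, ev in self.injected_events if s == subject and st == state]


def generate_background(
    duration_s: float,
    fs: float,
    channels: list[str] | tuple[str, ...],
    amplitude_rms: float,
    seed: int | np.random.Generator,
) -> EEGRecording:
    """1/f-shaped Gaussian noise, each channel scaled to exactly
    ``amplitude_rms`` microvolts RMS.

    Power is proportional to 1/f above 1 Hz (flat below), giving a log-log
    Welch slope near -1 over the analysed 1-300 Hz range.
    """
    if duration_s <= 0 or fs <= 0 or amplitude_rms <= 0:
        raise ValueError("duration_s, fs and amplitude_rms must all be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # amplitude ~ f^-1/2 => power ~ 1/f; clamp below 1 Hz and zero out DC
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** -0.5
    shape[0] = 0.0

    data = np.empty((len(channels), n))
    for i in range(len(channels)):
        spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
        x = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(x**2))
        data[i] = x * (amplitude_rms / rms)
    return EEGRecording(list(channels), fs, data)


def inject_burst(
    recording: EEGRecording,
    channel: str,
    t0: float,
    freq_hz: float,
    n_cycles: int,
    amplitude_uv: float,
) -> tuple[EEGRecording, HFOEvent]:
    """Add a Hann-windowed sinusoidal burst in place and return its event.

    The burst spans ``n_cycles / freq_hz`` seconds starting at ``t0``; its
    band label comes from ``freq_hz`` (gamma 40-80, ripple 80-200,
    fast_ripple 200-300, else 'out_of_band' — still injected).
    """
    if freq_hz >= recording.fs / 2:
        raise ValueError(f"burst frequency {freq_hz} Hz at/above Nyquist {recording.fs / 2}")
    duration = n_cycles / freq_hz
    if t0 < 0 or t0 + duration > recording.duration + 1e-9:
        raise ValueError(
            f"burst [{t0:.3f}, {t0 + duration:.3f}] s exceeds record of {recording.duration} s"
        )
    idx = recording.channel_index(channel)
    i0 = int(round(t0 * recording.fs))
    n = int(round(duration * recording.fs))
    t = np.arange(n) / recording.fs
    window = np.hanning(n) if n > 1 else np.ones(n)
    burst = amplitude_uv * window * np.sin(2 * np.pi * freq_hz * t)
    recording.data[idx, i0: i0 + n] += burst

    band = band_of_freq(freq_hz)
    event = HFOEvent(
        channel=channel,
        band=band,
        onset=i0 / recording.fs,
        offset=(i0 + n) / recording.fs,
        n_cycles=n_cycles,
        peak_amp=float(amplitude_uv),
        regularity=1.0,
    )
    recording.annotate(f"hfo_{band}", event.onset, event.duration, channel)
    return recording, event


def _spike_wave(fs: float, spike_ms: float, wave_ms: float, spike_amp: float, wave_amp: float) -> np.ndarray:
    """Biphasic spike followed by a half-sine slow wave."""
    n_spike = max(int(round(spike_ms / 1000 * fs)), 4)
    n_wave = max(int(round(wave_ms / 1000 * fs)), 4)
    t = np.linspace(0, 1, n_spike, endpoint=False)
    spike = spike_amp * np.sin(2 * np.pi * t) * np.hanning(n_spike)
    wave = wave_amp * np.sin(np.pi * np.linspace(0, 1, n_wave, endpoint=False))
    return np.concatenate([spike, -wave])


def inject_discharges(
    recording: EEGRecording,
    channels: list[str],
    rate_per_s: float,
    spike_amp_uv: float,
    slow_amp_uv: float,
    seed: int | np.random.Generator,
) -> tuple[EEGRecording, list[Annotation]]:
    """Add spike + slow-wave complexes at Poisson times on ``channels``.

    Each complex produces one annotation labelled 'discharge' whose channel
    field is 'all' or a comma-joined channel list. Deterministic given seed.
    """
    if rate_per_s < 0 or spike_amp_uv < 0 or slow_amp_uv < 0:
        raise ValueError("rate and amplitudes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    annotations: list[Annotation] = []
    if rate_per_s == 0:
        return recording, annotations

    n_events = rng.poisson(rate_per_s * recording.duration)
    max_len_s = 0.07 + 0.5
    onsets = np.sort(rng.uniform(0, max(recording.duration - max_len_s, 0), size=n_events))
    idxs = [recording.channel_index(ch) for ch in channels]
    chan_field = "all" if set(channels) == set(recording.channel_names) else ",".join(channels)

    for onset in onsets:
        spike_ms = rng.uniform(20, 70)
        wave_ms = rng.uniform(200, 500)
        template = _spike_wave(recording.fs, spike_ms, wave_ms, spike_amp_uv, slow_amp_uv)
        i0 = int(round(onset * recording.fs))
        seg = slice(i0, i0 + len(template))
        for ci in idxs:
            recording.data[ci, seg] += template[: recording.n_samples - i0]
        duration = len(template) / recording.fs
        ann = Annotation("discharge", i0 / recording.fs, duration, chan_field)
        annotations.append(ann)
        recording.annotations.append(ann)
    return recording, annotations


def _add_band_noise(
    rng: np.random.Generator, data: np.ndarray, fs: float, low: float, high: float, rms: float
) -> None:
    """Add band-limited Gaussian noise of the given per-channel RMS in place."""
    n = data.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        return
    for i in range(data.shape[0]):
        spec = np.zeros(len(freqs), dtype=complex)
        spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
        x = np.fft.irfft(spec, n=n)
        data[i] += x * (rms / np.sqrt(np.mean(x**2)))


def _add_spindles(rng: np.random.Generator, rec: EEGRecording, amplitude_uv: float) -> None:
    """Sleep spindles: 11-14 Hz bursts of ~1 s every ~10 s on all channels."""
    n_spindles = max(int(rec.duration / 10), 1)
    for _ in range(n_spindles):
        freq = rng.uniform(11, 14)
        dur = rng.uniform(0.5, 1.5)
        t0 = rng.uniform(0, rec.duration - dur)
        n = int(round(dur * rec.fs))
        i0 = int(round(t0 * rec.fs))
        t = np.arange(n) / rec.fs
        burst = amplitude_uv * np.hanning(n) * np.sin(2 * np.pi * freq * t)
        rec.data[:, i0: i0 + n] += burst[None, :]
        rec.annotations.append(Annotation("spindle", t0, dur, "all"))


def _subject_state_rng(seed: int, group: str, subject_i: int, state: str) -> np.random.Generator:
    # crc32 rather than hash(): stable across processes regardless of PYTHONHASHSEED
    key = zlib.crc32(f"{group}/{state}".encode())
    return np.random.default_rng([seed, key, subject_i])


def generate_cohort(config: CohortConfig) -> tuple[list[Segment], GroundTruth]:
    """Build one recording per subject x state with ground truth attached.

    Band energy in each (group, state, band) cell is driven toward the
    configured factor two ways: injected burst amplitudes and a continuous
    in-band noise floor are both scaled by sqrt(factor), so the recovered
    average band energy is approximately proportional to the factor.
    """
    segments: list[Segment] = []
    truth = GroundTruth()
    for group in config.groups:
        for si in range(config.n_subjects_per_group):
            subject = f"{group}{si:03d}"
            for state in config.states_per_group[group]:
                rng = _subject_state_rng(config.seed, group, si, state)
                duration = config.duration_of(state)
                rec = generate_background(
                    duration, config.fs, config.channels, config.background_amplitude, rng
                )
                rec.annotations.append(Annotation(state, 0.0, duration, "all"))

                for band in BANDS.values():
                    factor = config.factor(group, state, band.name)
                    truth.energy_factors[(subject, state, band.name)] = factor
                    scale = np.sqrt(factor)
                    _add_band_noise(
                        rng,
                        rec.data,
                        config.fs,
                        band.low,
                        band.high,
                        config.band_noise_rms_ratio * config.background_amplitude * scale,
                    )
                    n_events = rng.poisson(config.event_rate * duration / 300.0 * len(config.channels))
                    for _ in range(n_events):
                        freq = rng.uniform(band.low, min(band.high, config.fs / 2 - 1))
                        n_cycles = int(rng.integers(6, 11))
                        burst_dur = n_cycles / freq
                        if burst_dur >= duration:
                            continue
                        channel = str(rng.choice(config.channels))
                        t0 = rng.uniform(0, duration - burst_dur)
                        _, event = inject_burst(
                            rec, channel, t0, freq, n_cycles, config.event_amplitude_uv * scale
                        )
                        truth.injected_events.append((subject, state, event))

                if state == "sleep":
                    _add_spindles(rng, rec, amplitude_uv=30.0)
                    if group == "IS":
                        _, anns = inject_discharges(
                            rec,
                            list(config.channels),
                            config.discharge_rate_per_s,
                            spike_amp_uv=100.0,
                            slow_amp_uv=150.0,
                            seed=rng,
                        )
                        truth.discharge_annotations.extend((subject, state, a) for a in anns)

                segments.append(
                    Segment(rec, state=state, onset=0.0, subject=subject, group=group)
                )
    return segments, truth


def write_cohort(segments: list[Segment], truth: GroundTruth, out_dir: str | Path) -> None:
    """Write one EDF (+ sidecar) per segment and the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for seg in segments:
        name = f"{seg.subject}_{seg.state}.edf"
        write_edf(seg.recording, out / name)
    payload = {
        "injected_events": [
            {"subject": s, "state": st, **vars(ev)} for s, st, ev in truth.injected_events
        ],
        "energy_factors": [
            {"subject": k[0], "state": k[1], "band": k[2], "factor": v}
            for k, v in truth.energy_factors.items()
        ],
        "discharge_annotations": [
            {"subject": s, "state": st, "onset": a.onset, "duration": a.duration, "channel": a.channel}
            for s, st, a in truth.discharge_annotations
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
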