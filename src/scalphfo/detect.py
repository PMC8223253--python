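"""HFO event detection.

An event is a run of at least four consecutive, regular oscillations that
stand out from the surrounding background in both amplitude and frequency.
The marking rule is operationalized as:

1. band-pass the channel to the target band (zero-phase Butterworth);
2. take the analytic (Hilbert) envelope;
3. background level = mean + ``amp_factor`` * SD of the envelope, refined by
   one re-estimation pass that excludes above-threshold samples (padded by
   one band period) before recomputing the statistics;
4. candidate = a maximal run with envelope above the background level that
   persists for at least 3 cycles of the band's upper frequency, extended
   outward while the envelope stays above its background mean (overlapping
   extensions merge);
5. within the candidate, find oscillation peaks (local maxima of the
   band-passed signal at or above mean + 2 SD) and keep the longest chain
   of consecutive peaks whose inter-peak intervals lie within the band's
   period range [1/high, 1/low] (one sample of slack for quantization);
   accept iff the chain has >= 4 peaks, the max/min interval ratio is
   <= ``regularity_max``, and the run's peak envelope reaches
   ``prominence_factor`` times the background level (amplitude clearly
   above, not merely at, threshold);
6. merge accepted events closer than ``merge_gap``; return sorted by onset.

Interictal recordings additionally apply the rate rule: a channel's events
only count if they recur at least ``min_rate`` times per 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import BANDS, Band, EEGRecording, HFOEvent, Segment
from .eeg_io import bandpass

__all__ = ["DetectorParams", "apply_rate_rule", "detect_events", "detect_events_channel"]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable marking thresholds (declared operationalizations, not
    published values)."""

    amp_factor: float = 3.0
    regularity_max: float = 1.5
    merge_gap: float = 0.01
    min_rate: float = 2.0
    prominence_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.amp_factor <= 0:
            raise ValueError("amp_factor must be > 0")
        if self.prominence_factor < 1:
            raise ValueError("prominence_factor must be >= 1")
        if self.regularity_max < 1:
            raise ValueError("regularity_max must be >= 1")
        if self.min_rate < 0:
            raise ValueError("min_rate must be >= 0")


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts.tolist(), stops.tolist()))


def envelope_thresholds(
    envelope: np.ndarray, amp_factor: float, pad: int
) -> tuple[float, float, float]:
    """(high, mid, low) background thresholds with one exclusion pass.

    The first pass uses all samples; samples above the first-pass high
    threshold (padded by ``pad`` samples on each side) are excluded and the
    statistics recomputed once. High = mean + amp_factor*SD gates candidate
    cores, mid = mean + 2 SD gates counted oscillation peaks, low = the
    mean itself bounds the candidate extension.
    """
    mu, sd = float(envelope.mean()), float(envelope.std())
    thr = mu + amp_factor * sd
    exclude = envelope > thr
    if exclude.any() and pad > 0:
        idx = np.flatnonzero(exclude)
        mask = np.zeros(len(envelope), dtype=bool)
        for i in idx:
            mask[max(i - pad, 0): i + pad + 1] = True
        exclude = mask
    keep = ~exclude
    if keep.sum() >= 16:
        mu, sd = float(envelope[keep].mean()), float(envelope[keep].std())
    return mu + amp_factor * sd, mu + 2 * sd, mu


def _longest_regular_chain(
    peak_idx: np.ndarray, fs: float, band: Band, regularity_max: float
) -> tuple[int, int, float]:
    """Longest run of consecutive peaks with in-band intervals.

    Returns (start position in peak_idx, chain length in peaks, regularity).
    Intervals must lie in [1/high - 1/fs, 1/low + 1/fs] seconds and the
    chain's max/min interval ratio must stay <= regularity_max.
    """
    if len(peak_idx) == 0:
        return 0, 0, 1.0
    lo = 1.0 / band.high - 1.0 / fs
    hi = 1.0 / band.low + 1.0 / fs
    intervals = np.diff(peak_idx) / fs
    ok = (intervals >= lo) & (intervals <= hi)

    best = (0, 1, 1.0)
    i = 0
    while i < len(intervals):
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < len(intervals) and ok[j]:
            j += 1
        # peaks i .. j inclusive; shrink window until regularity holds
        for s in range(i, j):
            for e in range(j, s, -1):
                seg = intervals[s:e]
                reg = float(seg.max() / seg.min())
                if reg <= regularity_max:
                    length = e - s + 1
                    if length > best[1]:
                        best = (s, length, reg)
                    break
        i = j
    return best


def detect_events_channel(
    x: np.ndarray,
    fs: float,
    band: Band | str,
    params: DetectorParams = DetectorParams(),
    channel: str = "ch",
) -> list[HFOEvent]:
    """Detect events on one channel. Returns non-overlapping, onset-sorted
    events."""
    if isinstance(band, str):
        band = BANDS[band]
    x = np.asarray(x, dtype=np.float64)
    if len(x) / fs < 8.0 / band.low:
        raise ValueError(
            f"segment of {len(x) / fs:.3f} s too short for band {band.name} "
            f"(need >= {8.0 / band.low:.3f} s)"
        )
    if not x.any():
        return []

    xb = bandpass(x, band, fs)
    env = np.abs(hilbert(xb))
    pad = int(round(fs / band.low))
    thr_hi, thr_mid, thr_lo = envelope_thresholds(env, params.amp_factor, pad)
    min_core = int(np.ceil(3.0 * fs / band.high))  # core must persist >= 3 cycles
    cores = [(c0, c1) for c0, c1 in _runs_above(env > thr_hi) if c1 - c0 >= min_core]
    if not cores:
        return []
    lo_runs = _runs_above(env > thr_lo)

    # extend each core to its enclosing low-threshold run; dedupe
    extended: list[tuple[int, int]] = []
    for c0, c1 in cores:
        enclosing = next(((l0, l1) for l0, l1 in lo_runs if l0 <= c0 and l1 >= c1), (c0, c1))
        if not extended or enclosing[0] > extended[-1][1]:
            extended.append(enclosing)
        else:
            extended[-1] = (extended[-1][0], max(extended[-1][1], enclosing[1]))

    events: list[HFOEvent] = []
    for r0, r1 in extended:
        seg = xb[r0:r1]
        if len(seg) < 3:
            continue
        interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]) & (seg[1:-1] >= thr_mid)
        peak_idx = np.flatnonzero(interior) + 1 + r0
        start, length, regularity = _longest_regular_chain(
            peak_idx, fs, band, params.regularity_max
        )
        if length >= 4 and env[r0:r1].max() >= params.prominence_factor * thr_hi:
            events.append(
                HFOEvent(
                    channel=channel,
                    band=band.name,
                    onset=r0 / fs,
                    offset=r1 / fs,
                    n_cycles=length,
                    peak_amp=float(np.max(np.abs(seg))),
                    regularity=max(regularity, 1.0),
                )
            )

    # merge events separated by < merge_gap
    merged: list[HFOEvent] = []
    for ev in sorted(events, key=lambda e: e.onset):
        if merged and ev.onset - merged[-1].offset < params.merge_gap:
            prev = merged[-1]
            merged[-1] = HFOEvent(
                channel=channel,
                band=band.name,
                onset=prev.onset,
                offset=max(prev.offset, ev.offset),
                n_cycles=prev.n_cycles + ev.n_cycles,
                peak_amp=max(prev.peak_amp, ev.peak_amp),
                regularity=max(prev.regularity, ev.regularity),
            )
        else:
            merged.append(ev)
    return merged


def detect_events(
    segment: Segment | EEGRecording,
    band: Band | str,
    params: DetectorParams = DetectorParams(),
) -> list[HFOEvent]:
    """Detect events on every channel of a segment; sorted by onset."""
    rec = segment.recording if isinstance(segment, Segment) else segment
    events: list[HFOEvent] = []
    for name in rec.channel_names:
        events.extend(detect_events_channel(rec.channel(name), rec.fs, band, params, name))
    return sorted(events, key=lambda e: (e.onset, e.channel))


def apply_rate_rule(
    events: list[HFOEvent], segment_duration_s: float, min_rate: float = 2.0
) -> list[HFOEvent]:
    """Keep the events only if they recur at >= ``min_rate`` per 5 minutes.

    The count is scaled to a 5-minute window, so short ictal segments are
    not auto-excluded (and the rule is typically skipped for them with
    min_rate=0).
    """
    if segment_duration_s <= 0:
        raise ValueError("segment_duration_s must be positive")
    rate = len(events) * 300.0 / segment_duration_s
    return list(events) if rate >= min_rate else []
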