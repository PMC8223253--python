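"""Morlet wavelet time-frequency energy.

Each frequency is analysed with a complex Morlet wavelet of ``omega0``
(default 6) cycles. Wavelets are amplitude-calibrated: the coefficient
magnitude of a unit-amplitude sinusoid at the wavelet's centre frequency is
1 regardless of frequency, so power |W|^2 is in squared signal units (uV^2)
and a sinusoid of amplitude a yields peak power a^2.

The scalar used throughout the analysis is the *average* band energy: the
mean of |W|^2 over all grid points inside the band and time window, with
samples within one wavelet half-length of the segment edges excluded
(reflect padding is used for the convolution itself).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import BANDS, CHANNELS_1020, Band, Segment, lobe_of
from .eeg_io import average_reference

__all__ = [
    "LeadSummary",
    "TFMap",
    "average_band_energy",
    "band_energy",
    "band_freq_grid",
    "channel_band_energies",
    "morlet_tfr",
    "responsible_leads",
]

#: Frequency grid steps per band (Hz): fine for the narrow gamma band.
_GRID_STEP = {"gamma": 2.0, "ripple": 5.0, "fast_ripple": 5.0}


def band_freq_grid(band: Band | str) -> np.ndarray:
    """Analysis frequencies for a band: [low, high) at the band's grid step."""
    if isinstance(band, str):
        band = BANDS[band]
    step = _GRID_STEP.get(band.name, 5.0)
    return np.arange(band.low, band.high, step)


@dataclass
class TFMap:
    """Time-frequency power map: power[i, j] = |W(freqs[i], times[j])|^2."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    halfwidths: np.ndarray  # per-frequency wavelet half-length, seconds

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or (len(self.times) > 1 and np.any(np.diff(self.times) <= 0)):
            raise ValueError("freqs and times must be strictly increasing")
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValueError("power shape must be (n_freqs, n_times)")


def _morlet_kernel(freq: float, fs: float, omega0: float) -> tuple[np.ndarray, int]:
    """Amplitude-calibrated complex Morlet wavelet and its half-length."""
    sigma_t = omega0 / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2 * sigma_t**2))
    kernel = gauss * np.exp(2j * np.pi * freq * t)
    # calibrate: response amplitude to a unit sinusoid at `freq` becomes 1
    kernel *= 2.0 / gauss.sum()
    return kernel, half


def morlet_tfr(
    signal: np.ndarray, fs: float, freqs: np.ndarray, omega0: float = 6.0
) -> TFMap:
    """Complex-Morlet power decomposition of a 1-D signal.

    Parameters
    ----------
    freqs
        Strictly increasing analysis frequencies, all below Nyquist.
    omega0
        Wavelet width in cycles (>= 5 for an analytic wavelet).
    """
    signal = np.asarray(signal, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.max() >= fs / 2:
        raise ValueError(f"max analysis frequency {freqs.max()} Hz >= Nyquist {fs / 2} Hz")
    if omega0 < 5:
        raise ValueError("omega0 must be >= 5 for a usable analytic Morlet wavelet")
    n = len(signal)
    power = np.empty((len(freqs), n))
    halfwidths = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        kernel, half = _morlet_kernel(f, fs, omega0)
        halfwidths[i] = half / fs
        pad = min(half, n - 1)
        padded = np.concatenate([signal[pad:0:-1], signal, signal[-2: -2 - pad: -1]])
        coef = fftconvolve(padded, np.conj(kernel[::-1]), mode="same")[pad: pad + n]
        power[i] = np.abs(coef) ** 2
    return TFMap(freqs=freqs, times=np.arange(n) / fs, power=power, halfwidths=halfwidths)


def average_band_energy(
    tfmap: TFMap, band: Band | str, time_window: tuple[float, float] | None = None
) -> float:
    """Mean power over f in [band.low, band.high) and t in ``time_window``,
    excluding edge samples within one wavelet half-length of the boundaries.
    """
    if isinstance(band, str):
        band = BANDS[band]
    fmask = (tfmap.freqs >= band.low) & (tfmap.freqs < band.high)
    if not fmask.any():
        raise ValueError(f"no analysis frequencies inside band {band.name}")
    t0 = tfmap.times[0] if time_window is None else time_window[0]
    t1 = tfmap.times[-1] if time_window is None else time_window[1]

    total, count = 0.0, 0
    for i in np.flatnonzero(fmask):
        lo = max(t0, tfmap.times[0] + tfmap.halfwidths[i])
        hi = min(t1, tfmap.times[-1] - tfmap.halfwidths[i])
        tmask = (tfmap.times >= lo) & (tfmap.times <= hi)
        if tmask.any():
            total += tfmap.power[i, tmask].sum()
            count += int(tmask.sum())
    if count == 0:
        raise ValueError("empty band/time selection (segment shorter than the wavelet?)")
    return total / count


def band_energy(
    signal: np.ndarray, fs: float, band: Band | str, omega0: float = 6.0
) -> float:
    """Average band energy of a 1-D signal on the band's default grid."""
    if isinstance(band, str):
        band = BANDS[band]
    tfmap = morlet_tfr(signal, fs, band_freq_grid(band), omega0)
    return average_band_energy(tfmap, band)


def channel_band_energies(
    segments: list[Segment],
    bands: list[Band | str] | None = None,
    omega0: float = 6.0,
    reference: str = "average",
) -> pd.DataFrame:
    """Average band energy per subject x channel x state x band.

    Signals are re-referenced to the common average first (the montage used
    for the high-frequency analysis). Returns a tidy frame with columns
    subject, group, channel, state, band, avg_energy.
    """
    band_objs = [BANDS[b] if isinstance(b, str) else b for b in (bands or list(BANDS.values()))]
    rows = []
    for seg in segments:
        if seg.subject is None or seg.group is None:
            raise ValueError("segments must carry subject and group metadata")
        rec = average_reference(seg.recording) if reference == "average" else seg.recording
        grids = {b.name: band_freq_grid(b) for b in band_objs}
        for name in rec.channel_names:
            x = rec.channel(name)
            for b in band_objs:
                tfmap = morlet_tfr(x, rec.fs, grids[b.name], omega0)
                rows.append(
                    {
                        "subject": seg.subject,
                        "group": seg.group,
                        "channel": name,
                        "state": seg.state,
                        "band": b.name,
                        "avg_energy": average_band_energy(tfmap, b),
                    }
                )
    return pd.DataFrame(
        rows, columns=["subject", "group", "channel", "state", "band", "avg_energy"]
    )


@dataclass
class LeadSummary:
    """Responsible leads per subject plus cohort-level lobe counts."""

    per_subject: dict[str, list[tuple[str, str]]]  # subject -> [(channel, lobe)]
    lobe_counts: Counter = field(default_factory=Counter)
    ties: set[str] = field(default_factory=set)


def responsible_leads(table: pd.DataFrame, top_k: int = 1) -> LeadSummary:
    """Rank channels by average energy per subject; the top channel is the
    responsible lead.

    Energy is pooled (mean) over whatever states/bands are present in the
    table. Exact ties are broken by canonical 10-20 channel order and the
    subject is flagged in ``ties``.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if table.empty:
        raise ValueError("empty energy table")
    order = {ch: i for i, ch in enumerate(CHANNELS_1020)}
    summary = LeadSummary(per_subject={})
    for subject, sub in table.groupby("subject"):
        pooled = sub.groupby("channel")["avg_energy"].mean()
        ranked = sorted(
            pooled.items(), key=lambda kv: (-kv[1], order.get(kv[0], len(order)), kv[0])
        )
        top = ranked[:top_k]
        if len(ranked) > top_k and any(
            np.isclose(ranked[top_k - 1][1], v) for _, v in ranked[top_k:]
        ):
            summary.ties.add(str(subject))
        leads = [(ch, lobe_of(ch)) for ch, _ in top]
        summary.per_subject[str(subject)] = leads
        summary.lobe_counts.update(lobe for _, lobe in leads)
    return summary
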