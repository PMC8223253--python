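"""Recording I/O, montages, band filters and segment extraction.

EDF carries the signals; annotations travel in a tab-separated sidecar
(`<file>.annotations.tsv`, columns label/onset_s/duration_s/channel) so the
deliverable stays plain-text friendly and round trips exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import BANDS, Annotation, Band, EEGRecording, Segment
from .edf import EDFFormatError, read_edf_raw, write_edf_raw

__all__ = [
    "BIPOLAR_CHAINS",
    "EDFFormatError",
    "Montage",
    "apply_montage",
    "average_reference",
    "bandpass",
    "extract_segment",
    "longitudinal_bipolar",
    "read_annotations",
    "read_edf",
    "write_annotations",
    "write_edf",
]

#: Longitudinal bipolar ("double banana") derivation chains over 10-20 labels.
BIPOLAR_CHAINS: tuple[tuple[str, ...], ...] = (
    ("Fp1", "F7", "T3", "T5", "O1"),
    ("Fp2", "F8", "T4", "T6", "O2"),
    ("Fp1", "F3", "C3", "P3", "O1"),
    ("Fp2", "F4", "C4", "P4", "O2"),
    ("Fz", "Cz", "Pz"),
)


@dataclass(frozen=True)
class Montage:
    """A referencing scheme.

    ``kind`` is ``average_reference`` (each channel minus the all-channel
    mean) or ``longitudinal_bipolar`` (chained differences along
    :data:`BIPOLAR_CHAINS`). ``derivations`` maps output label to an
    (anode, cathode) pair, where cathode ``"average"`` means the common
    average.
    """

    kind: str
    derivations: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)

    @staticmethod
    def average(channels: list[str]) -> "Montage":
        return Montage(
            "average_reference",
            tuple((ch, ch, "average") for ch in channels),
        )

    @staticmethod
    def bipolar(channels: list[str] | None = None) -> "Montage":
        derivs = []
        for chain in BIPOLAR_CHAINS:
            for a, b in zip(chain[:-1], chain[1:]):
                if channels is None or (a in channels and b in channels):
                    derivs.append((f"{a}-{b}", a, b))
        return Montage("longitudinal_bipolar", tuple(derivs))


def average_reference(recording: EEGRecording) -> EEGRecording:
    """Subtract the all-channel mean from every channel at every sample."""
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return EEGRecording(
        list(recording.channel_names), recording.fs, data, list(recording.annotations)
    )


def longitudinal_bipolar(recording: EEGRecording) -> EEGRecording:
    """Re-derive the recording as longitudinal bipolar channel differences."""
    montage = Montage.bipolar(recording.channel_names)
    return apply_montage(recording, montage)


def apply_montage(recording: EEGRecording, montage: Montage) -> EEGRecording:
    if montage.kind == "average_reference" and not montage.derivations:
        return average_reference(recording)
    missing = sorted(
        {src for _, a, b in montage.derivations for src in (a, b)}
        - set(recording.channel_names)
        - {"average"}
    )
    if missing:
        raise KeyError(f"montage references missing channel(s): {missing}")
    if not montage.derivations:
        raise ValueError("montage has no derivations")

    avg = recording.data.mean(axis=0)
    rows, labels = [], []
    for label, anode, cathode in montage.derivations:
        a = recording.channel(anode)
        b = avg if cathode == "average" else recording.channel(cathode)
        rows.append(a - b)
        labels.append(label)
    return EEGRecording(labels, recording.fs, np.vstack(rows), list(recording.annotations))


def _band_sos(band: Band, fs: float) -> np.ndarray:
    if band.high >= fs / 2:
        raise ValueError(f"band {band.name} upper edge {band.high} Hz >= Nyquist {fs / 2} Hz")
    return sps.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, band: Band | str, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward).

    Accepts a :class:`Band` or one of the names in :data:`scalphfo.core.BANDS`.
    Works on 1-D signals or (channels, samples) arrays.
    """
    if isinstance(band, str):
        band = BANDS[band]
    sos = _band_sos(band, fs)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def extract_segment(
    recording: EEGRecording,
    state_label: str,
    duration_s: float,
    subject: str | None = None,
    group: str | None = None,
) -> Segment:
    """Cut the first annotated window labelled ``state_label`` of at least
    ``duration_s`` seconds out of the recording.

    The returned segment's recording keeps every annotation overlapping the
    window, with onsets re-expressed relative to the segment start
    (half-open window [onset, onset + duration)).
    """
    candidates = [
        ann
        for ann in sorted(recording.annotations, key=lambda a: a.onset)
        if ann.label == state_label and ann.duration >= duration_s - 1e-9
    ]
    if not candidates:
        available = sorted({a.label for a in recording.annotations})
        raise LookupError(
            f"no window labelled {state_label!r} of >= {duration_s} s; "
            f"available labels: {available}"
        )
    ann = candidates[0]
    i0 = int(round(ann.onset * recording.fs))
    i1 = i0 + int(round(duration_s * recording.fs))
    window = (ann.onset, ann.onset + duration_s)

    kept = []
    for other in recording.annotations:
        if other.onset < window[1] and other.offset > window[0]:
            kept.append(
                Annotation(
                    other.label,
                    other.onset - window[0],
                    other.duration,
                    other.channel,
                )
            )
    seg_rec = EEGRecording(
        list(recording.channel_names), recording.fs, recording.data[:, i0:i1], kept
    )
    return Segment(seg_rec, state=state_label, onset=ann.onset, subject=subject, group=group)


# ---------------------------------------------------------------------------
# File I/O


def _sidecar_path(edf_path: str | os.PathLike) -> Path:
    p = Path(edf_path)
    return p.with_suffix(p.suffix + ".annotations.tsv") if p.suffix != ".edf" \
        else p.with_suffix(".annotations.tsv")


def write_annotations(annotations: list[Annotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("label\tonset_s\tduration_s\tchannel\n")
        for ann in annotations:
            fh.write(f"{ann.label}\t{ann.onset!r}\t{ann.duration!r}\t{ann.channel}\n")


def read_annotations(path: str | os.PathLike) -> list[Annotation]:
    anns = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["label", "onset_s", "duration_s", "channel"]:
            raise ValueError(f"unexpected annotation sidecar header: {header}")
        for line in fh:
            if not line.strip():
                continue
            label, onset, duration, channel = line.rstrip("\n").split("\t")
            anns.append(Annotation(label, float(onset), float(duration), channel))
    return anns


def write_edf(recording: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as 16-bit EDF plus a `.annotations.tsv` sidecar."""
    if recording.n_channels == 0 or recording.n_samples == 0:
        raise EDFFormatError("refusing to write an empty recording")
    write_edf_raw(path, list(recording.channel_names), recording.fs, recording.data)
    write_annotations(recording.annotations, _sidecar_path(path))


def read_edf(path: str | os.PathLike) -> EEGRecording:
    """Read an EDF file (and its annotation sidecar, if present)."""
    raw = read_edf_raw(path)
    sidecar = _sidecar_path(path)
    annotations = read_annotations(sidecar) if sidecar.exists() else []
    return EEGRecording(raw.labels, raw.fs, raw.data, annotations)
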