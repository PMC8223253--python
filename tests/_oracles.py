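"""Independent brute-force oracles used by the test suite.

These mirror the *documented rules*, not the implementations: naive Python
loops, exhaustive chain enumeration, and the literal step-down formula.
Shared signal primitives (band-pass filter, Hilbert transform) and the
threshold statistics are definitional and reused; everything downstream of
them is re-derived from scratch here.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import hilbert

from scalphfo.core import BANDS, Band
from scalphfo.eeg_io import bandpass


def oracle_thresholds(env: np.ndarray, amp_factor: float, pad: int) -> tuple[float, float, float]:
    mu = float(env.mean())
    sd = float(env.std())
    thr = mu + amp_factor * sd
    excluded = [False] * len(env)
    hits = [i for i, v in enumerate(env) if v > thr]
    if hits and pad > 0:
        for i in hits:
            for j in range(max(i - pad, 0), min(i + pad + 1, len(env))):
                excluded[j] = True
    else:
        for i in hits:
            excluded[i] = True
    kept = np.array([v for v, ex in zip(env, excluded) if not ex])
    if len(kept) >= 16:
        mu, sd = float(kept.mean()), float(kept.std())
    return mu + amp_factor * sd, mu + 2 * sd, mu


def _naive_runs(flags: list[bool]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def oracle_detect(
    x: np.ndarray,
    fs: float,
    band: Band | str,
    amp_factor: float = 3.0,
    regularity_max: float = 1.5,
    merge_gap: float = 0.01,
    prominence_factor: float = 1.5,
) -> list[tuple[int, int, int]]:
    """Brute-force scan. Returns (onset_sample, offset_sample, n_cycles)
    triples for every accepted event, merged and sorted."""
    if isinstance(band, str):
        band = BANDS[band]
    x = np.asarray(x, dtype=np.float64)
    if not x.any():
        return []
    xb = bandpass(x, band, fs)
    env = np.abs(hilbert(xb))
    pad = int(round(fs / band.low))
    thr_hi, thr_mid, thr_lo = oracle_thresholds(env, amp_factor, pad)
    min_core = math.ceil(3.0 * fs / band.high)

    cores = [
        (a, b) for a, b in _naive_runs([v > thr_hi for v in env]) if b - a >= min_core
    ]
    if not cores:
        return []
    lo_runs = _naive_runs([v > thr_lo for v in env])

    windows: list[tuple[int, int]] = []
    for c0, c1 in cores:
        enclosing = (c0, c1)
        for l0, l1 in lo_runs:
            if l0 <= c0 and l1 >= c1:
                enclosing = (l0, l1)
                break
        if not windows or enclosing[0] > windows[-1][1]:
            windows.append(enclosing)
        else:
            windows[-1] = (windows[-1][0], max(windows[-1][1], enclosing[1]))

    lo_int = 1.0 / band.high - 1.0 / fs
    hi_int = 1.0 / band.low + 1.0 / fs
    accepted: list[tuple[int, int, int]] = []
    for r0, r1 in windows:
        seg = xb[r0:r1]
        if len(seg) < 3:
            continue
        peaks = [
            i + 1
            for i in range(len(seg) - 2)
            if seg[i + 1] > seg[i] and seg[i + 1] >= seg[i + 2] and seg[i + 1] >= thr_mid
        ]
        # exhaustive: every contiguous peak window, longest first per start
        best_len = 0
        for s in range(len(peaks)):
            for e in range(len(peaks) - 1, s, -1):
                ivals = [(peaks[k + 1] - peaks[k]) / fs for k in range(s, e)]
                if all(lo_int <= v <= hi_int for v in ivals) and max(ivals) / min(ivals) <= regularity_max:
                    if e - s + 1 > best_len:
                        best_len = e - s + 1
                    break
        if best_len >= 4 and max(env[r0:r1]) >= prominence_factor * thr_hi:
            accepted.append((r0, r1, best_len))

    merged: list[tuple[int, int, int]] = []
    for ev in sorted(accepted):
        if merged and (ev[0] - merged[-1][1]) / fs < merge_gap:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], ev[1]), prev[2] + ev[2])
        else:
            merged.append(ev)
    return merged


def oracle_holm(pvals) -> np.ndarray:
    """Literal step-down: sort ascending, cumulative max of (m-j+1)p_(j)
    capped at 1, mapped back to input order."""
    p = np.asarray(pvals, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = []
    for j, idx in enumerate(order):
        adj_sorted.append(min(1.0, (m - j) * p[idx]))
    out = np.empty(m)
    best = 0.0
    for j, idx in enumerate(order):
        best = max(best, adj_sorted[j])
        out[idx] = best
    return out
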