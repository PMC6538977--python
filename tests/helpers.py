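"""Independent brute-force oracles and synthetic fixtures for the tests.

Everything here is deliberately naive (explicit loops, O(n^2) scans) and
kept independent of the package implementation it checks.
"""

from __future__ import annotations

import math
import struct
from pathlib import Path

import numpy as np


def brute_envelope(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of |x| with shrinking edge windows (loop)."""
    n = len(x)
    a = np.abs(x)
    out = np.empty(n)
    left = (window - 1) // 2
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i - left + window)
        out[i] = a[lo:hi].mean()
    return out


def brute_sampen(x: np.ndarray, m: int = 2, r: float | None = None, tau: int = 1) -> float:
    """Sample entropy by explicit pairwise template counting."""
    x = np.asarray(x, dtype=float)[::tau]
    n = len(x)
    if r is None:
        r = 0.2 * float(x.std())
    n_templates = n - m
    b = 0
    a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return -math.log(a / b)


def brute_negative_peaks(x: np.ndarray, k_sd: float = 5.0) -> list[int]:
    """O(n^2) scan for negative deflections: local minima below -k*SD whose
    topographic prominence on the inverted trace exceeds half the peak."""
    y = -np.asarray(x, dtype=float)
    sd = x.std()
    n = len(y)
    out = []
    for i in range(1, n - 1):
        if not (y[i] > y[i - 1] and y[i] >= y[i + 1]):
            continue
        if y[i] <= k_sd * sd:
            continue
        # prominence: walk out to the nearest higher point on each side,
        # track the minimum in between; prominence = peak - max(left_min, right_min)
        left_min = y[i]
        j = i - 1
        while j >= 0 and y[j] <= y[i]:
            left_min = min(left_min, y[j])
            j -= 1
        if j < 0:
            left_min = y[:i].min()
        right_min = y[i]
        j = i + 1
        while j < n and y[j] <= y[i]:
            right_min = min(right_min, y[j])
            j += 1
        if j >= n:
            right_min = y[i + 1:].min() if i + 1 < n else y[i]
        prom = y[i] - max(left_min, right_min)
        if prom > 0.5 * y[i]:
            out.append(i)
    return out


def brute_rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (average ranks for ties)."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def brute_band_integral(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral over [lo, hi] by explicit summation."""
    total = 0.0
    for i in range(len(freqs) - 1):
        f0, f1 = freqs[i], freqs[i + 1]
        if f0 >= lo and f1 <= hi:
            total += 0.5 * (power[i] + power[i + 1]) * (f1 - f0)
    return total


def brute_ppc(phases: np.ndarray) -> float:
    """Mean cosine of the absolute angular distance over all pairs (loop)."""
    n = len(phases)
    s = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = phases[i] - phases[j]
            d = abs(math.atan2(math.sin(d), math.cos(d)))
            s += math.cos(d)
    return s / (n * (n - 1) / 2)


def write_minimal_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: float,
    labels: list[str],
) -> None:
    """Write a minimal valid EDF file (synthetic test fixture).

    One data record per second, 16-bit little-endian samples, physical
    range +/-3276.8 uV mapped to digital +/-32767.
    """
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    ns, n = data_uv.shape
    assert len(labels) == ns
    spr = int(round(fs))  # samples per record (1-s records)
    n_records = n // spr
    phys_min, phys_max = -3276.8, 3276.8
    dig_min, dig_max = -32767, 32767

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),                      # version
            pad("X X X X", 80),               # patient id
            pad("Startdate X X X X", 80),     # recording id
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),      # header bytes
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),                      # record duration (s)
            pad(str(ns), 4),
        ]
    )
    fields = [
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(str(phys_min), 8) for _ in labels),
        b"".join(pad(str(phys_max), 8) for _ in labels),
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(spr), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    body = bytearray()
    for rec_i in range(n_records):
        for c in range(ns):
            seg = data_uv[c, rec_i * spr: (rec_i + 1) * spr]
            dig = np.clip(np.round((seg - phys_min) * scale + dig_min), dig_min, dig_max)
            body += struct.pack(f"<{spr}h", *dig.astype(np.int16))
    Path(path).write_bytes(header + b"".join(fields) + bytes(body))
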