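"""Grip-force target: cleaning, session z-scoring, movement detection, and
alignment to the 10 Hz feature clock.

Cleaning removes slow baseline drift with a causal rolling-percentile
baseline (two passes of trailing-window 10th-percentile subtraction — the
second pass removes the drift-proportional lag bias of the first) followed by
half-wave rectification, so rest segments sit at ~0 and ramps keep their
shape. The cleaned trace is z-scored over the whole session (the study's
convention; an option restricts scaling statistics to a training index set
for strictly leak-free label scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class MovementStats:
    onsets: np.ndarray  # sample indices
    peak_amplitudes: np.ndarray
    peak_velocities: np.ndarray
    variability: float  # sample variance of peak amplitudes

    @property
    def n_movements(self) -> int:
        return int(self.onsets.size)


def _trailing_percentile_baseline(
    x: np.ndarray, fs: float, window_s: float, q: float, step_s: float = 0.1,
    subsample: int = 10,
) -> np.ndarray:
    """Causal baseline: q-th percentile of the trailing ``window_s`` window,
    evaluated every ``step_s`` and held (zero-order) until the next anchor.
    The window is subsampled for speed; at force bandwidths this is loss-free.
    """
    n = x.size
    step = max(1, int(round(step_s * fs)))
    w = int(round(window_s * fs))
    anchors = np.arange(step - 1, n, step)
    vals = np.empty(anchors.size)
    for i, t in enumerate(anchors):
        lo = max(0, t - w + 1)
        vals[i] = np.percentile(x[lo : t + 1 : subsample], q)
    baseline = np.empty(n)
    baseline[: anchors[0] + 1] = vals[0]
    for i in range(1, anchors.size):
        baseline[anchors[i - 1] + 1 : anchors[i] + 1] = vals[i]
    baseline[anchors[-1] + 1 :] = vals[-1]
    return baseline


def clean_force(
    raw: np.ndarray, fs: float = 1000.0, window_s: float = 15.0, percentile: float = 10.0
) -> np.ndarray:
    """Remove slow baseline drift and rectify; rest segments end up at ~0."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("force trace contains non-finite samples")
    if raw.size == 0:
        return raw.copy()
    if np.ptp(raw) == 0:
        warnings.warn("clean_force: constant force input, returning zeros")
        return np.zeros_like(raw)
    x = raw - _trailing_percentile_baseline(raw, fs, window_s, percentile)
    x = x - _trailing_percentile_baseline(x, fs, window_s, percentile)
    return np.maximum(x, 0.0)


def zscore_session(
    cleaned: np.ndarray, train_index: Optional[np.ndarray] = None
) -> np.ndarray:
    """(x - mean) / sd. With ``train_index`` the statistics come from those
    samples only (leak-free variant); default is whole-session scaling."""
    cleaned = np.asarray(cleaned, dtype=float)
    ref = cleaned if train_index is None else cleaned[train_index]
    sd = ref.std()
    if sd == 0:
        raise ValueError("zscore_session: zero standard deviation")
    return (cleaned - ref.mean()) / sd


def detect_movements(
    cleaned: np.ndarray,
    fs: float = 1000.0,
    threshold_frac: float = 0.1,
    min_hold_s: float = 0.1,
    refractory_s: float = 0.5,
    backtrack_frac: float = 0.02,
) -> MovementStats:
    """Threshold-crossing movement detection on the cleaned force.

    A movement starts where force crosses ``threshold_frac`` of the session
    maximum and stays above for ``min_hold_s``; the onset is then backtracked
    to the last sample at or below ``backtrack_frac`` of the maximum, which
    lands near the true ramp foot. Variability is the sample (n-1) variance
    of peak amplitudes.
    """
    x = np.asarray(cleaned, dtype=float)
    if x.size == 0 or x.max() <= 0:
        empty = np.array([])
        return MovementStats(np.array([], dtype=int), empty, empty, 0.0)
    thr = threshold_frac * x.max()
    low = backtrack_frac * x.max()
    hold = int(round(min_hold_s * fs))
    refr = int(round(refractory_s * fs))
    above = x > thr
    onsets: list[int] = []
    peaks: list[float] = []
    velocities: list[float] = []
    i, n = 0, x.size
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            if i + hold <= n and above[i : i + hold].all():
                # movement extent: until force drops below threshold again
                j = i
                while j < n and x[j] > thr:
                    j += 1
                # backtrack to the ramp foot
                k = i
                lo = max(0, i - refr)
                while k > lo and x[k - 1] > low:
                    k -= 1
                if not onsets or k - onsets[-1] >= refr:
                    onsets.append(k)
                    seg = x[k:j]
                    peaks.append(float(seg.max()))
                    velocities.append(float(np.diff(seg).max() * fs) if seg.size > 1 else 0.0)
                i = j + refr
                continue
        i += 1
    onsets_arr = np.asarray(onsets, dtype=int)
    peaks_arr = np.asarray(peaks)
    variability = float(np.var(peaks_arr, ddof=1)) if peaks_arr.size > 1 else 0.0
    return MovementStats(onsets_arr, peaks_arr, np.asarray(velocities), variability)


def align_to_features(z: np.ndarray, t_end: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Label per feature row = force sample at the packet end (last-sample
    convention): row with t_end seconds maps to sample round(t_end*fs) - 1."""
    z = np.asarray(z, dtype=float)
    idx = np.round(np.asarray(t_end) * fs).astype(int) - 1
    if idx.size and (idx[-1] >= z.size or idx[0] < 0):
        raise ValueError(
            f"feature clock extends to sample {idx[-1]} but force has {z.size} samples"
        )
    return z[idx]


@dataclass
class ForceTarget:
    """The decoding label bundle for one session."""

    raw: np.ndarray
    cleaned: np.ndarray
    z: np.ndarray
    y10: np.ndarray
    movements: MovementStats
    fs: float = 1000.0

    @classmethod
    def from_raw(
        cls, raw: np.ndarray, t_end: np.ndarray, fs: float = 1000.0, **detect_kwargs
    ) -> "ForceTarget":
        cleaned = clean_force(raw, fs)
        z = zscore_session(cleaned)
        return cls(
            raw=np.asarray(raw, dtype=float),
            cleaned=cleaned,
            z=z,
            y10=align_to_features(z, t_end, fs),
            movements=detect_movements(cleaned, fs, **detect_kwargs),
            fs=fs,
        )

    @property
    def onset_times_s(self) -> np.ndarray:
        return self.movements.onsets / self.fs
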