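"""Beta-burst detection on the 10 Hz feature series and time-in-burst
statistics around movement onsets.

A burst is a maximal run of consecutive feature samples strictly above a
threshold — the 75th percentile of the rest-period feature distribution —
lasting at least 100 ms (one feature sample). "Time spent in burst" is the
summed burst duration intersected with an analysis window around each
movement onset: motor preparation (-1, 0) s and movement execution (0, 1) s.
Computed per channel on the normalized beta / low-beta / high-beta feature
series of the main pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import CorrelationReport, correlation

WINDOWS: dict[str, tuple[float, float]] = {"prep": (-1.0, 0.0), "move": (0.0, 1.0)}


@dataclass
class BurstSet:
    bursts: list[tuple[float, float]]  # (start_s, end_s), sorted, non-overlapping
    threshold: float
    rate_hz: float = 10.0
    channel: Optional[str] = None
    band: Optional[str] = None

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.bursts])

    @property
    def total_time_s(self) -> float:
        return float(self.durations.sum()) if self.bursts else 0.0


def rest_mask(
    t: np.ndarray,
    onset_times_s: np.ndarray,
    burn_in: Optional[np.ndarray] = None,
    pre_s: float = 1.0,
    post_s: float = 2.0,
) -> np.ndarray:
    """Rest = outside (-pre, +post) s around any movement onset, non-burn-in."""
    t = np.asarray(t, dtype=float)
    mask = np.ones(t.size, dtype=bool)
    for o in np.asarray(onset_times_s, dtype=float):
        mask &= ~((t > o - pre_s) & (t < o + post_s))
    if burn_in is not None:
        mask &= ~np.asarray(burn_in, dtype=bool)
    return mask


def burst_threshold(values: np.ndarray, rest: np.ndarray) -> float:
    """75th percentile (linear interpolation) of feature values at rest."""
    values = np.asarray(values, dtype=float)
    rest = np.asarray(rest, dtype=bool)
    if not rest.any():
        raise ValueError("rest mask selects no samples")
    return float(np.percentile(values[rest], 75))


def detect_bursts(
    values: np.ndarray,
    threshold: float,
    rate_hz: float = 10.0,
    min_dur_s: float = 0.1,
    channel: Optional[str] = None,
    band: Optional[str] = None,
) -> BurstSet:
    """Maximal runs of samples strictly above threshold, kept if their
    duration (k samples = k/rate s) reaches ``min_dur_s``. A single
    supra-threshold sample at 10 Hz is a 100 ms burst and is kept."""
    values = np.asarray(values, dtype=float)
    above = values > threshold
    bursts: list[tuple[float, float]] = []
    i, n = 0, values.size
    step = 1.0 / rate_hz
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            dur = (j - i) * step
            if dur >= min_dur_s - 1e-12:
                bursts.append((i * step, j * step))
            i = j
        else:
            i += 1
    return BurstSet(bursts=bursts, threshold=threshold, rate_hz=rate_hz, channel=channel, band=band)


def time_in_burst(
    burst_set: BurstSet,
    onset_times_s: np.ndarray,
    windows: Optional[dict[str, tuple[float, float]]] = None,
) -> dict[str, float]:
    """Mean per-movement time spent in burst within each window.

    Burst intervals are intersected with (onset + w0, onset + w1) per
    movement and summed; the aggregate is the mean across movements. Returns
    {} when there are no movements.
    """
    onsets = np.asarray(onset_times_s, dtype=float)
    windows = WINDOWS if windows is None else windows
    if onsets.size == 0:
        return {}
    out: dict[str, float] = {}
    for name, (w0, w1) in windows.items():
        per_movement = np.zeros(onsets.size)
        for k, o in enumerate(onsets):
            lo, hi = o + w0, o + w1
            for s, e in burst_set.bursts:
                per_movement[k] += max(0.0, min(e, hi) - max(s, lo))
        out[name] = float(per_movement.mean())
    return out


def burst_score_correlation(
    time_in_burst_per_subject: Sequence[float],
    scores: Sequence[float],
    seed: int = 0,
    n_perm: int = 5000,
) -> CorrelationReport:
    """Spearman correlation (Monte-Carlo p) of burst time with a per-subject
    score, e.g. a clinical motor scale."""
    return correlation(
        np.asarray(time_in_burst_per_subject, dtype=float),
        np.asarray(scores, dtype=float),
        method="spearman",
        seed=seed,
        n_perm=n_perm,
    )
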