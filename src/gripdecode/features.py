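"""Causal band-power feature extraction at the 10 Hz feature rate.

Eight oscillatory bands are tracked per neural channel: theta (4-8 Hz),
alpha (8-12 Hz), beta (13-35 Hz), low beta (13-20 Hz), high beta (20-35 Hz),
low gamma (60-80 Hz), HFA (90-200 Hz), and all gamma (60-200 Hz). Each band
is estimated as the variance of the causally band-pass-filtered signal over a
band-specific trailing window (1000 ms for theta, 500 ms for alpha/beta
bands, 100 ms for gamma/HFA bands), evaluated every 100 ms, i.e. once per
virtual packet. Features are normalized against the sliding median of the
past 10 s (current sample included) and clipped to [-2, 2] as artifact
rejection. Every step uses only past samples, so the whole chain is
real-time compatible: truncating the recording at time t leaves all feature
rows up to t bit-identical.

Filters are order-4 Butterworth IIR applied forward-only (``sosfilt``); the
frequency response of each filter is exposed via :func:`band_filter_response`
so tests can check pass/stop-band behaviour against an explicit oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .io import ECOG, LFP, RawRecording

FEATURE_RATE_HZ = 10.0
PACKET_SAMPLES = 100  # at 1 kHz
NORMALIZATION_MEMORY_S = 10.0
CLIP_BOUND = 2.0
BURN_IN_S = 10.0


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float
    window_ms: int

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high <= 200):
            raise ValueError(f"band {self.name}: edges must satisfy 0 < low < high <= 200 Hz")
        if self.window_ms not in (100, 500, 1000):
            raise ValueError(f"band {self.name}: window_ms must be one of 100/500/1000")

    def sos(self, fs: float = 1000.0) -> np.ndarray:
        return signal.butter(4, (self.f_low, self.f_high), btype="bandpass", fs=fs, output="sos")


def default_bands() -> list[BandDefinition]:
    """The eight-band set with its per-band variance windows."""
    return [
        BandDefinition("theta", 4, 8, 1000),
        BandDefinition("alpha", 8, 12, 500),
        BandDefinition("beta", 13, 35, 500),
        BandDefinition("low_beta", 13, 20, 500),
        BandDefinition("high_beta", 20, 35, 500),
        BandDefinition("low_gamma", 60, 80, 100),
        BandDefinition("hfa", 90, 200, 100),
        BandDefinition("gamma", 60, 200, 100),
    ]


def band_filter_response(band: BandDefinition, freqs: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """|H(f)| of the causal band filter — the pass/stop-band oracle."""
    _, h = signal.sosfreqz(band.sos(fs), worN=2 * np.pi * freqs / fs)
    return np.abs(h)


@dataclass
class FeatureSeries:
    """Feature table on the 10 Hz packet clock.

    ``values`` is time x channel x feature; the feature axis is the band axis
    (8 wide) before lag concatenation and band-major lag blocks
    (band, lag0..lagJ) after it. ``t_end[k]`` is the packet-end time of row k.
    """

    values: np.ndarray
    t_end: np.ndarray
    channel_labels: list[str]
    bands: list[BandDefinition]
    lags_ms: list[int]
    burn_in: np.ndarray  # bool mask, rows to exclude from any fit
    normalized: bool
    clip_bound: float = CLIP_BOUND
    rate_hz: float = FEATURE_RATE_HZ

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def feature_names(self, channel: str) -> list[str]:
        return [
            f"{channel}_{b.name}_lag{k}" for b in self.bands for k in range(len(self.lags_ms))
        ]

    def channel_matrix(self, label: str) -> np.ndarray:
        """(time, features) block for one channel."""
        return self.values[:, self.channel_labels.index(label), :]


def band_power_feature(history: np.ndarray, band: BandDefinition, fs: float = 1000.0) -> float:
    """Variance of the causally filtered trailing ``band.window_ms`` window.

    ``history`` is the full available past of one channel (most recent sample
    last); the filter runs over all of it so its state matches streaming
    operation. Raises if the history is shorter than the band window.
    """
    history = np.asarray(history, dtype=float)
    w = int(band.window_ms * fs / 1000.0)
    if history.size < w:
        raise ValueError(
            f"band {band.name}: need >= {w} samples of history, got {history.size}"
        )
    filtered = signal.sosfilt(band.sos(fs), history)
    return float(np.var(filtered[-w:]))


def normalize_and_clip(
    raw: np.ndarray,
    rate_hz: float = FEATURE_RATE_HZ,
    memory_s: float = NORMALIZATION_MEMORY_S,
    clip_bound: float = CLIP_BOUND,
) -> np.ndarray:
    """Sliding-median normalization with clipping, strictly causal.

    ``v_norm(t) = clip((v(t) - med) / (med + eps), -c, c)`` where ``med`` is
    the median over the trailing ``memory_s`` seconds including the current
    sample (100 values at 10 Hz once warm). ``eps = 1e-12 * (1 + |med|)``
    guards the zero-median case. Works on (T,) or (T, ...) arrays
    column-wise along axis 0.
    """
    raw = np.asarray(raw, dtype=float)
    squeeze = raw.ndim == 1
    x = raw.reshape(raw.shape[0], -1)
    T, K = x.shape
    m = int(round(memory_s * rate_hz))
    med = np.empty_like(x)
    warm = min(m, T)
    for t in range(warm - 1):  # warm-up: median over whatever history exists
        med[t] = np.median(x[: t + 1], axis=0)
    if T >= m:
        for k in range(K):  # column-wise keeps the windowed view small
            windows = np.lib.stride_tricks.sliding_window_view(x[:, k], m)
            med[m - 1 :, k] = np.median(windows, axis=-1)
    elif T >= 1:
        med[T - 1] = np.median(x, axis=0)
    eps = 1e-12 * (1.0 + np.abs(med))
    out = np.clip((x - med) / (med + eps), -clip_bound, clip_bound)
    return out[:, 0] if squeeze else out.reshape(raw.shape)


def extract_feature_series(
    rec: RawRecording,
    bands: Optional[Sequence[BandDefinition]] = None,
    normalize: bool = True,
) -> FeatureSeries:
    """Extract the full causal feature table from a re-referenced recording.

    One row per 100 ms packet; per row, every band for every neural
    (ECoG/LFP) channel. Rows with packet-end time <= 10 s are flagged as
    burn-in (the normalization median is not yet warm there) and must be
    excluded from any downstream fit.
    """
    if rec.fs != 1000:
        raise ValueError("extract_feature_series requires a 1 kHz recording")
    bands = list(bands) if bands is not None else default_bands()
    neural = [i for i, c in enumerate(rec.channels) if c.kind in (ECOG, LFP)]
    longest = max(b.window_ms for b in bands)
    if rec.n_samples < longest:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the longest band window ({longest} ms)"
        )
    n_rows = rec.n_samples // PACKET_SAMPLES
    ends = (np.arange(1, n_rows + 1) * PACKET_SAMPLES)  # exclusive end sample of each packet
    values = np.empty((n_rows, len(neural), len(bands)))
    for ci, ch in enumerate(neural):
        x = rec.samples[ch]
        for bi, band in enumerate(bands):
            filtered = signal.sosfilt(band.sos(rec.fs), x)
            w = int(band.window_ms)
            # trailing-window variance at each packet end, vectorized via
            # cumulative sums: var = E[x^2] - E[x]^2 over the last w samples
            c1 = np.concatenate(([0.0], np.cumsum(filtered)))
            c2 = np.concatenate(([0.0], np.cumsum(filtered**2)))
            starts = np.maximum(ends - w, 0)
            cnt = ends - starts
            s1 = c1[ends] - c1[starts]
            s2 = c2[ends] - c2[starts]
            values[:, ci, bi] = s2 / cnt - (s1 / cnt) ** 2
    np.maximum(values, 0.0, out=values)  # clamp negative round-off
    t_end = ends / rec.fs
    if normalize:
        values = normalize_and_clip(values)
    burn_in = t_end <= BURN_IN_S
    return FeatureSeries(
        values=values,
        t_end=t_end,
        channel_labels=[rec.channels[i].label for i in neural],
        bands=bands,
        lags_ms=[0],
        burn_in=burn_in,
        normalized=normalize,
    )


def concatenate_lags(fs: FeatureSeries, n_lags: int = 5) -> FeatureSeries:
    """Append the ``n_lags - 1`` preceding packets to every feature row.

    Row t then holds each band at t, t-100 ms, ..., t-(n_lags-1)*100 ms
    (band-major, lag-minor ordering), i.e. 8 bands x 5 lags = 40 features per
    channel at the default. Initial rows without full lag history are
    dropped rather than zero-padded.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if len(fs.lags_ms) != 1:
        raise ValueError("series already has lags concatenated")
    T, C, B = fs.values.shape
    if n_lags > T:
        raise ValueError(f"n_lags={n_lags} exceeds series length {T}")
    out = np.empty((T - n_lags + 1, C, B * n_lags))
    for j in range(n_lags):
        sl = fs.values[n_lags - 1 - j : T - j]  # lag j = j packets in the past
        out[:, :, j::n_lags] = sl
    return replace(
        fs,
        values=out,
        t_end=fs.t_end[n_lags - 1 :],
        lags_ms=[-100 * j for j in range(n_lags)],
        burn_in=fs.burn_in[n_lags - 1 :],
    )
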