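"""Synthetic intracranial recordings, grip-force traces, burst series, and
point-cloud connectomes with planted ground truth.

The recording generator emulates the phenomenology of movement decoding data
rather than biophysics: every channel carries 1/f background plus band-limited
oscillators (white noise band-pass filtered per band and amplitude-modulated).
Around each movement the beta (13-35 Hz) oscillator desynchronises (amplitude
drop ``beta_desync``) and the gamma/HFA (60-200 Hz) oscillator synchronises
proportionally to instantaneous force (``gamma_coupling``), both stronger on
the hemisphere contralateral to the moved hand (``contra_gain``). Pre-movement
beta bursts can be injected at ``burst_rate`` during the motor-preparation
second. The force trace is a sum of raised-cosine ramps with randomised peak
amplitude, slow drift, and white sensor noise.

Every generator takes an explicit seed; identical seed + config gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

from .io import ECOG, FORCE, LFP, ChannelMeta, RawRecording

BETA_BAND = (13.0, 35.0)
GAMMA_BAND = (60.0, 200.0)


@dataclass
class SimulationConfig:
    """Stated world for one synthetic session.

    Defaults emulate an intraoperative grip-force session: ~1 movement every
    8 s, clear beta desynchronisation, force-proportional gamma coupling that
    is twice as strong contralaterally, and mild force drift/noise.
    """

    duration_s: float = 300.0
    fs: float = 1000.0
    n_ecog: int = 4  # split half contralateral / half ipsilateral
    n_lfp: int = 4  # contacts on one (contralateral) DBS lead -> 3 bipolar
    n_movements: int = 36
    gamma_coupling: float = 1.0
    beta_desync: float = 0.7
    contra_gain: float = 2.0
    burst_rate: float = 0.3  # bursts/s during the motor-preparation second
    drift_amp: float = 0.5  # force units
    noise_sd: float = 0.05  # force units
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "duration_s", "fs", "gamma_coupling", "beta_desync",
            "contra_gain", "burst_rate", "drift_amp", "noise_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"SimulationConfig.{name} must be finite, got {v!r}")
        if not self.duration_s > 0:
            raise ValueError("SimulationConfig.duration_s must be > 0")
        if not self.fs > 2 * GAMMA_BAND[1]:
            raise ValueError("SimulationConfig.fs must exceed twice the highest band edge (200 Hz)")
        if self.n_movements < 0:
            raise ValueError("SimulationConfig.n_movements must be >= 0")
        if not 0 <= self.beta_desync <= 1:
            raise ValueError("SimulationConfig.beta_desync must lie in [0, 1]")
        if self.gamma_coupling < 0:
            raise ValueError("SimulationConfig.gamma_coupling must be >= 0")
        if self.contra_gain < 1:
            raise ValueError("SimulationConfig.contra_gain must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: onsets, per-channel coupling, injected bursts."""

    movement_onsets: np.ndarray  # sample indices, strictly increasing
    force_clean: np.ndarray  # ramps-only force (no drift, no noise)
    peak_amplitudes: np.ndarray
    channel_gains: dict[str, dict[str, float]]  # label -> {beta_desync, gamma_gain}
    burst_intervals: dict[str, list[tuple[float, float]]]  # label -> (start_s, end_s)
    hub_location: Optional[np.ndarray] = None


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude background via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def _band_oscillator(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited noise (order-4 Butterworth on white noise)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _raised_cosine_ramp(t: np.ndarray, rise_s: float = 0.25) -> np.ndarray:
    """0 -> 1 raised-cosine transition over ``rise_s`` seconds."""
    y = np.clip(t / rise_s, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * y))


def _force_trace(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Clean ramps, onsets, peaks; plateau 1-2 s, 250 ms raised-cosine edges."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    force = np.zeros(n)
    if cfg.n_movements == 0:
        return force, np.array([], dtype=int), np.array([]), t
    # quasi-periodic onsets with jitter, leaving 12 s lead-in for burn-in/baseline
    lead_in, tail = 12.0, 4.0
    usable = cfg.duration_s - lead_in - tail
    if usable <= 0:
        raise ValueError("duration_s too short for the requested movements")
    spacing = usable / cfg.n_movements
    onsets_s = lead_in + spacing * np.arange(cfg.n_movements) + rng.uniform(
        0, 0.4 * spacing, cfg.n_movements
    )
    peaks = rng.uniform(0.8, 1.2, cfg.n_movements)
    rise = 0.25
    for start, peak in zip(onsets_s, peaks):
        plateau = rng.uniform(1.0, 2.0)
        seg = (t >= start) & (t < start + rise + plateau + rise)
        ts = t[seg] - start
        up = _raised_cosine_ramp(ts, rise)
        down = _raised_cosine_ramp(rise + plateau + rise - ts, rise)
        force[seg] += peak * np.minimum(up, down)
    onsets = np.round(onsets_s * cfg.fs).astype(int)
    return force, onsets, peaks, t


def generate_recording(
    config: SimulationConfig,
) -> tuple[RawRecording, np.ndarray, GroundTruth]:
    """Synthesize one session.

    Returns the recording (neural channels + FORCE channel), the raw force
    trace (ramps + drift + noise, same as the FORCE channel), and the planted
    ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    force_clean, onsets, peaks, _ = _force_trace(config, rng)
    drift = config.drift_amp * 0.5 * (
        1 + np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
    )
    force_raw = force_clean + drift + config.noise_sd * rng.standard_normal(n)

    # movement-locked beta suppression envelope support: 1 during movement
    moving = np.zeros(n)
    for s in onsets:
        e = min(n, s + int(1.5 * config.fs))
        moving[s:e] = 1.0
    # smooth the gate with a 200 ms Hann window (no sharp spectral edges)
    win = signal.windows.hann(int(0.2 * config.fs) + 1)
    moving = signal.fftconvolve(moving, win / win.sum(), mode="same")
    moving = np.clip(moving, 0.0, 1.0)

    n_contra = (config.n_ecog + 1) // 2
    channels: list[ChannelMeta] = []
    rows: list[np.ndarray] = []
    gains: dict[str, dict[str, float]] = {}
    bursts: dict[str, list[tuple[float, float]]] = {}

    def synth_channel(label: str, contra: bool) -> np.ndarray:
        side_gain = config.contra_gain if contra else 1.0
        desync = min(1.0, config.beta_desync * (side_gain / config.contra_gain)) \
            if config.contra_gain > 0 else config.beta_desync
        gamma_gain = config.gamma_coupling * side_gain
        beta_env = 1.0 - desync * moving
        # injected pre-movement bursts: beta amplitude x3 for 200-400 ms
        intervals: list[tuple[float, float]] = []
        for s in onsets:
            prep_start = s / config.fs - 1.0
            n_b = rng.poisson(config.burst_rate * 1.0)
            for _ in range(n_b):
                dur = rng.uniform(0.2, 0.4)
                start = rng.uniform(prep_start, max(prep_start, s / config.fs - dur))
                if intervals and start < intervals[-1][1]:
                    continue  # keep per-channel intervals non-overlapping
                intervals.append((start, start + dur))
        burst_env = np.zeros(n)
        for s0, s1 in intervals:
            burst_env[int(s0 * config.fs) : int(s1 * config.fs)] = 2.0
        beta_env = beta_env * (1.0 + burst_env)
        gamma_env = 1.0 + gamma_gain * force_clean
        x = (
            8.0 * _pink_noise(rng, n, config.fs)
            + 4.0 * beta_env * _band_oscillator(rng, n, config.fs, BETA_BAND)
            + 1.5 * gamma_env * _band_oscillator(rng, n, config.fs, GAMMA_BAND)
        )
        gains[label] = dict(beta_desync=desync, gamma_gain=gamma_gain)
        bursts[label] = intervals
        return x

    for i in range(config.n_ecog):
        contra = i < n_contra
        hemi = "L" if contra else "R"
        label = f"ECOG_{hemi}_{i}"
        channels.append(
            ChannelMeta(
                label=label, kind=ECOG, electrode_group=f"strip_{hemi}",
                contact_index=i, hemisphere=hemi,
                coordinate=(float(-40 if hemi == 'L' else 40), float(-20 + 8 * i), 60.0),
                laterality="contra" if contra else "ipsi",
            )
        )
        rows.append(synth_channel(label, contra))

    for i in range(config.n_lfp):
        label = f"LFP_L_{i}"
        channels.append(
            ChannelMeta(
                label=label, kind=LFP, electrode_group="lead_L",
                contact_index=i, hemisphere="L",
                coordinate=(-12.0, -13.0, -6.0 + 2.0 * i),
                laterality="contra",
            )
        )
        rows.append(synth_channel(label, contra=True))

    channels.append(ChannelMeta(label="FORCE", kind=FORCE, electrode_group="analog"))
    rows.append(force_raw)

    rec = RawRecording(np.vstack(rows), config.fs, channels, session_id=f"sim-{config.seed}")
    truth = GroundTruth(
        movement_onsets=onsets,
        force_clean=force_clean,
        peak_amplitudes=peaks,
        channel_gains=gains,
        burst_intervals=bursts,
    )
    return rec, force_raw, truth


def generate_burst_series(
    bursts: list[tuple[float, float]],
    threshold: float,
    baseline: float = 0.0,
    rate_hz: float = 10.0,
    duration_s: Optional[float] = None,
) -> np.ndarray:
    """Feature-rate series equal to ``baseline`` except inside the requested
    ``(start_s, dur_s)`` intervals, where it exceeds ``threshold``.

    Durations must sit on the 0.1 s feature grid; intervals must not overlap.
    """
    step = 1.0 / rate_hz
    iv = sorted((float(s), float(d)) for s, d in bursts)
    for s, d in iv:
        if abs(round(d / step) - d / step) > 1e-9 or d <= 0:
            raise ValueError(f"burst duration {d} s is not a positive multiple of {step} s")
    for (s0, d0), (s1, _) in zip(iv[:-1], iv[1:]):
        if s1 < s0 + d0 - 1e-12:
            raise ValueError(f"burst intervals overlap at {s1} s")
    if duration_s is None:
        duration_s = (iv[-1][0] + iv[-1][1] + 1.0) if iv else 1.0
    n = int(round(duration_s * rate_hz))
    out = np.full(n, float(baseline))
    high = threshold + max(1.0, abs(threshold))
    for s, d in iv:
        i0 = int(round(s * rate_hz))
        i1 = i0 + int(round(d * rate_hz))
        out[i0:i1] = high
    return out


def write_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar for a simulated recording (onsets, gains, bursts)."""
    import json
    from pathlib import Path

    payload = dict(
        movement_onsets=[int(s) for s in truth.movement_onsets],
        peak_amplitudes=[float(a) for a in truth.peak_amplitudes],
        channel_gains=truth.channel_gains,
        burst_intervals={
            ch: [[float(a), float(b)] for a, b in iv]
            for ch, iv in truth.burst_intervals.items()
        },
    )
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# point-cloud connectome fixtures


@dataclass
class ConnectomeFixture:
    """Recording sites + streamlines + fingerprints with a planted hub.

    Performance at each site is a linear function (slope ``slope_a``) of its
    normalized structural connectivity to the hub plus Gaussian noise,
    truncated to [0, 1].
    """

    site_coords: np.ndarray  # (S, 3) mm
    site_subjects: np.ndarray  # (S,) subject index
    performance: np.ndarray  # (S,) in [0, 1]
    fibers: list[np.ndarray]  # list of (P, 3) polylines
    hub_location: np.ndarray  # (3,)
    hub_fiber_mask: np.ndarray  # (F,) bool, fibers routed through the hub
    hub_connectivity: np.ndarray  # (S,) normalized connectivity to hub fibers
    fingerprints: np.ndarray  # (S, nx, ny, nz) smoothed fiber density
    grid_origin: np.ndarray
    grid_spacing: float


def _bezier_through(p0: np.ndarray, mid: np.ndarray, p2: np.ndarray, n_pts: int) -> np.ndarray:
    """Quadratic Bezier from p0 to p2 passing through ``mid`` at u=0.5."""
    ctrl = 2.0 * mid - 0.5 * (p0 + p2)
    u = np.linspace(0.0, 1.0, n_pts)[:, None]
    return (1 - u) ** 2 * p0 + 2 * u * (1 - u) * ctrl + u**2 * p2


def generate_connectome(
    n_sites: int = 60,
    n_fibers: int = 400,
    slope_a: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    hub_fraction: float = 0.5,
    box_mm: float = 100.0,
    radius_mm: float = 5.0,
    grid_spacing_mm: float = 4.0,
    smooth_fwhm_mm: float = 8.0,
    sites_per_subject: int = 4,
) -> ConnectomeFixture:
    """Build a synthetic connectome with a designated hub.

    A fraction ``hub_fraction`` of fibers is routed through the hub; sites are
    placed near fiber paths (a hub-proximal cluster plus on-fiber sites), the
    way recording strips overlie white-matter tracts, so that hub fibers pass
    the downstream >20 %-of-sites inclusion filter.
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    if n_fibers < 10:
        raise ValueError("n_fibers must be >= 10")
    if box_mm <= 0:
        raise ValueError("degenerate bounding box")
    rng = np.random.default_rng(seed)
    hub = rng.uniform(0.4 * box_mm, 0.6 * box_mm, 3)

    def boundary_point() -> np.ndarray:
        p = rng.uniform(0, box_mm, 3)
        axis = rng.integers(0, 3)
        p[axis] = rng.choice([0.0, box_mm])
        return p

    fibers: list[np.ndarray] = []
    hub_mask = np.zeros(n_fibers, dtype=bool)
    n_hub = int(round(hub_fraction * n_fibers))
    for f in range(n_fibers):
        a, b = boundary_point(), boundary_point()
        if f < n_hub:
            mid = hub + rng.normal(0, 1.0, 3)
            hub_mask[f] = True
        else:
            mid = rng.uniform(0, box_mm, 3)
            while np.linalg.norm(mid - hub) < 4 * radius_mm:
                mid = rng.uniform(0, box_mm, 3)
        poly = _bezier_through(a, mid, b, n_pts=15) + rng.normal(0, 0.3, (15, 3))
        fibers.append(poly)

    # sites: hub-proximal cluster + points scattered along fiber paths
    n_hub_sites = max(2, int(round(0.4 * n_sites)))
    coords = np.empty((n_sites, 3))
    for s in range(n_sites):
        if s < n_hub_sites:
            coords[s] = hub + rng.normal(0, 0.6 * radius_mm, 3)
        else:
            poly = fibers[rng.integers(0, n_fibers)]
            vertex = poly[rng.integers(2, len(poly) - 2)]
            coords[s] = vertex + rng.normal(0, 0.6 * radius_mm, 3)
    coords = np.clip(coords, 0.0, box_mm)

    from .connectomics import fiber_connectivity  # local import avoids a cycle

    conn, _kept = fiber_connectivity(coords, fibers, radius_mm=radius_mm, min_fraction=0.0)
    hub_counts = conn[:, hub_mask].sum(axis=1).astype(float)
    hub_conn = hub_counts / max(1.0, hub_counts.max())
    performance = np.clip(
        slope_a * hub_conn + rng.normal(0.0, noise_sd, n_sites), 0.0, 1.0
    )

    # per-site voxel fingerprint: smoothed density of its connected fibers
    dims = int(np.ceil(box_mm / grid_spacing_mm)) + 1
    sigma_vox = smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid_spacing_mm
    all_vertices = [np.clip((f / grid_spacing_mm), 0, dims - 1).astype(int) for f in fibers]
    fingerprints = np.zeros((n_sites, dims, dims, dims), dtype=np.float32)
    for s in range(n_sites):
        density = np.zeros((dims, dims, dims))
        for f_idx in np.nonzero(conn[s])[0]:
            vx = all_vertices[f_idx]
            np.add.at(density, (vx[:, 0], vx[:, 1], vx[:, 2]), 1.0)
        fingerprints[s] = gaussian_filter(density, sigma=sigma_vox)

    subjects = np.arange(n_sites) // sites_per_subject
    return ConnectomeFixture(
        site_coords=coords,
        site_subjects=subjects,
        performance=performance,
        fibers=fibers,
        hub_location=hub,
        hub_fiber_mask=hub_mask,
        hub_connectivity=hub_conn,
        fingerprints=fingerprints,
        grid_origin=np.zeros(3),
        grid_spacing=grid_spacing_mm,
    )
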