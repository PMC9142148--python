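"""Recording containers, disk IO, virtual streaming, and montage referencing.

Recordings are multichannel intracranial signals (ECoG strips, DBS-lead LFP
contacts) plus an analog grip-force channel, all at a common sampling rate.
Streaming emulates the online acquisition loop: non-overlapping 100 ms packets
in time order, so any consumer is strictly causal by construction.

On disk a recording is a directory in a BIDS-iEEG-flavoured fallback layout:
``samples.dat`` (float32 little-endian, channels x samples, C order),
``channels.tsv`` (label/type/group/contact/hemisphere/coordinates/laterality),
``recording.json`` (rate, session, array shape) and an optional ``events.tsv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

ECOG = "ECOG"
LFP = "LFP"
FORCE = "FORCE"

PACKET_S = 0.1  #: virtual packet length in seconds


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one recorded channel.

    ``contact_index`` counts contacts within an electrode (DBS convention:
    contact 0 is the lowest). ``laterality`` is relative to the moved hand
    ("contra" / "ipsi") when known.
    """

    label: str
    kind: str  # ECOG | LFP | FORCE
    electrode_group: str = ""
    contact_index: int = 0
    hemisphere: str = ""  # "L" | "R" | ""
    coordinate: Optional[tuple[float, float, float]] = None
    laterality: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (ECOG, LFP, FORCE):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.coordinate is not None:
            coord = np.asarray(self.coordinate, dtype=float)
            if coord.shape != (3,) or not np.all(np.isfinite(coord)):
                raise ValueError(f"channel {self.label}: coordinate must be a finite 3-vector")


@dataclass
class RawRecording:
    """channels x samples matrix with per-channel metadata."""

    samples: np.ndarray
    fs: float
    channels: list[ChannelMeta]
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but {len(self.channels)} channel entries"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")

    def pick(self, kinds: Sequence[str]) -> "RawRecording":
        """Sub-recording restricted to the given channel kinds (order kept)."""
        idx = [i for i, c in enumerate(self.channels) if c.kind in kinds]
        return RawRecording(
            self.samples[idx].copy(),
            self.fs,
            [self.channels[i] for i in idx],
            self.session_id,
        )


@dataclass(frozen=True)
class StreamPacket:
    samples: np.ndarray  # channels x block
    t_end: float  # time of the last sample (s), end-inclusive convention
    packet_index: int


def stream_packets(rec: RawRecording) -> Iterator[StreamPacket]:
    """Emulate the online stream: contiguous 100 ms packets at 1 kHz.

    The final partial packet (if any) is discarded, mirroring an online
    system that only ever acts on complete packets. Each packet holds a copy,
    so later mutation of the source array cannot rewrite emitted packets.
    """
    if rec.fs != 1000:
        raise ValueError("stream_packets requires fs=1000 Hz; resample_to_1khz first")
    block = int(round(PACKET_S * rec.fs))
    n_packets = rec.n_samples // block
    for k in range(n_packets):
        sl = rec.samples[:, k * block : (k + 1) * block].copy()
        yield StreamPacket(sl, t_end=(k + 1) * block / rec.fs, packet_index=k)


def rereference(rec: RawRecording) -> RawRecording:
    """Montage referencing: bipolar LFP, per-hemisphere common-average ECoG.

    Every 4-contact (or n-contact) LFP electrode yields n-1 bipolar channels
    ``contact_i - contact_{i+1}`` (adjacent pairs 0-1, 1-2, 2-3). ECoG channels
    have the common average of all ECoG channels of the same hemisphere
    subtracted, leaving the channel count unchanged. Force channels pass
    through untouched. Output order: ECoG, bipolar LFP, force.
    """
    ecog_idx = [i for i, c in enumerate(rec.channels) if c.kind == ECOG]
    out_samples: list[np.ndarray] = []
    out_meta: list[ChannelMeta] = []

    # ECoG: common average reference per hemisphere
    by_hemi: dict[str, list[int]] = {}
    for i in ecog_idx:
        by_hemi.setdefault(rec.channels[i].hemisphere, []).append(i)
    for hemi, idx in by_hemi.items():
        if len(idx) < 2:
            raise ValueError(f"need >=2 ECoG channels in hemisphere {hemi!r} for CAR")
    for i in ecog_idx:
        hemi_idx = by_hemi[rec.channels[i].hemisphere]
        car = rec.samples[hemi_idx].mean(axis=0)
        out_samples.append(rec.samples[i] - car)
        out_meta.append(rec.channels[i])

    # LFP: adjacent bipolar pairs per electrode group
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(rec.channels):
        if c.kind == LFP:
            groups.setdefault(c.electrode_group, []).append(i)
    for group, idx in groups.items():
        idx = sorted(idx, key=lambda i: rec.channels[i].contact_index)
        if len(idx) < 2:
            raise ValueError(f"LFP electrode {group!r} has a single contact; cannot re-reference")
        for a, b in zip(idx[:-1], idx[1:]):
            ca, cb = rec.channels[a], rec.channels[b]
            out_samples.append(rec.samples[a] - rec.samples[b])
            out_meta.append(
                ChannelMeta(
                    label=f"{group}_{ca.contact_index}-{cb.contact_index}",
                    kind=LFP,
                    electrode_group=group,
                    contact_index=ca.contact_index,
                    hemisphere=ca.hemisphere,
                    coordinate=(
                        tuple((np.asarray(ca.coordinate) + np.asarray(cb.coordinate)) / 2.0)
                        if ca.coordinate is not None and cb.coordinate is not None
                        else None
                    ),
                    laterality=ca.laterality,
                )
            )

    for i, c in enumerate(rec.channels):
        if c.kind == FORCE:
            out_samples.append(rec.samples[i].copy())
            out_meta.append(c)

    return RawRecording(np.vstack(out_samples), rec.fs, out_meta, rec.session_id)


def resample_to_1khz(rec: RawRecording) -> RawRecording:
    """Anti-aliased polyphase resampling down to the 1 kHz analysis rate."""
    if rec.fs < 1000:
        raise ValueError(f"fs={rec.fs} Hz < 1000 Hz: upsampling is not supported")
    if rec.fs == 1000:
        return replace(rec, samples=rec.samples.copy())
    frac = Fraction(1000, int(round(rec.fs))) if float(rec.fs).is_integer() else Fraction(
        1000 / rec.fs
    ).limit_denominator(10_000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return RawRecording(out, 1000.0, list(rec.channels), rec.session_id)


# ---------------------------------------------------------------------------
# disk layout


def write_recording(rec: RawRecording, path: str | Path, events: Optional[pd.DataFrame] = None) -> Path:
    """Write the fallback BIDS-iEEG-style directory layout (see module docs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec.samples.astype("<f4").tofile(path / "samples.dat")
    rows = []
    for c in rec.channels:
        coord = c.coordinate if c.coordinate is not None else (np.nan, np.nan, np.nan)
        rows.append(
            dict(
                label=c.label, type=c.kind, group=c.electrode_group,
                contact=c.contact_index, hemisphere=c.hemisphere,
                x=coord[0], y=coord[1], z=coord[2],
                laterality=c.laterality if c.laterality is not None else "n/a",
            )
        )
    pd.DataFrame(rows).to_csv(path / "channels.tsv", sep="\t", index=False)
    header = dict(
        fs=rec.fs, session_id=rec.session_id,
        n_channels=rec.samples.shape[0], n_samples=rec.samples.shape[1],
        dtype="float32", byte_order="little",
        reference_convention="bipolar contact_i - contact_{i+1}; CAR per hemisphere",
    )
    (path / "recording.json").write_text(json.dumps(header, indent=2))
    if events is not None:
        events.to_csv(path / "events.tsv", sep="\t", index=False)
    return path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    try:
        header = json.loads((path / "recording.json").read_text())
    except FileNotFoundError as e:
        raise ValueError(f"{path}: missing recording.json header") from e
    tsv = pd.read_csv(path / "channels.tsv", sep="\t")
    if tsv["label"].duplicated().any():
        dupes = tsv.loc[tsv["label"].duplicated(), "label"].tolist()
        raise ValueError(f"{path / 'channels.tsv'}: duplicate channel label(s) {dupes}")
    if len(tsv) != header["n_channels"]:
        raise ValueError(
            f"{path}: channels.tsv lists {len(tsv)} channels, header says {header['n_channels']}"
        )
    data = np.fromfile(path / "samples.dat", dtype="<f4")
    expect = header["n_channels"] * header["n_samples"]
    if data.size != expect:
        raise ValueError(f"{path / 'samples.dat'}: {data.size} values, expected {expect}")
    samples = data.reshape(header["n_channels"], header["n_samples"]).astype(float)
    channels = []
    for _, row in tsv.iterrows():
        coord = (row["x"], row["y"], row["z"])
        coord = None if any(pd.isna(v) for v in coord) else tuple(float(v) for v in coord)
        lat = None if (pd.isna(row["laterality"]) or row["laterality"] == "n/a") else row["laterality"]
        channels.append(
            ChannelMeta(
                label=str(row["label"]), kind=str(row["type"]),
                electrode_group="" if pd.isna(row["group"]) else str(row["group"]),
                contact_index=int(row["contact"]),
                hemisphere="" if pd.isna(row["hemisphere"]) else str(row["hemisphere"]),
                coordinate=coord, laterality=lat,
            )
        )
    return RawRecording(samples, float(header["fs"]), channels, header["session_id"])
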