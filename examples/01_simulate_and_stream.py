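"""Simulate an intraoperative grip-force session and replay it as a
real-time packet stream.

Builds a 2-minute synthetic recording (ECoG + STN-LFP + force channel at
1 kHz), writes/reads it through the disk layout, re-references it (bipolar
LFP, per-hemisphere common average ECoG), and streams 100 ms packets the way
an online decoder would receive them.
"""

import tempfile
from pathlib import Path

import gripdecode as gd

cfg = gd.SimulationConfig(duration_s=120.0, n_movements=13, seed=7)
rec, force, truth = gd.generate_recording(cfg)
print(f"simulated {rec.duration_s:.0f} s, channels: {[c.label for c in rec.channels]}")
print(f"planted movements: {len(truth.movement_onsets)} "
      f"(first onset at {truth.movement_onsets[0] / 1000:.2f} s)")

with tempfile.TemporaryDirectory() as tmp:
    path = gd.write_recording(rec, Path(tmp) / "sub-01_ses-01_ieeg")
    gd.simulate.write_ground_truth(truth, path / "ground_truth.json")
    back = gd.read_recording(path)
    print(f"disk round trip: max sample error {abs(back.samples - rec.samples).max():.2e} uV")

ref = gd.rereference(rec)
print(f"after referencing: {[c.label for c in ref.channels]}")
# 4-contact LFP lead -> 3 bipolar channels; ECoG count unchanged (CAR)

n_packets = 0
for packet in gd.stream_packets(ref):
    n_packets += 1  # an online consumer would update features here
print(f"streamed {n_packets} packets of 100 ms ({n_packets / 10:.0f} s of data)")
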