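"""Beta-burst statistics around movement onset.

Detects bursts on the normalized low-beta feature series (threshold = 75th
percentile of rest periods, minimum duration 100 ms) and measures the time
spent in burst during motor preparation (-1 to 0 s) and movement execution
(0 to 1 s). On a cohort of synthetic subjects with a planted monotone
relation, burst time correlates with an external severity score — the
pattern reported for subthalamic low-beta bursts and motor impairment.
"""

import numpy as np

import gripdecode as gd
from gripdecode import bursts as bu

rng = np.random.default_rng(0)
prep_times, scores = [], []
for subject in range(12):
    cfg = gd.SimulationConfig(
        duration_s=150.0, n_movements=17,
        burst_rate=0.1 + 0.04 * subject,  # planted monotone burst gradient
        seed=300 + subject,
    )
    rec, force, _ = gd.generate_recording(cfg)
    fs = gd.extract_feature_series(gd.rereference(rec))
    tgt = gd.ForceTarget.from_raw(force, fs.t_end)
    bi = [b.name for b in fs.bands].index("low_beta")
    series = fs.values[:, 0, bi]  # contralateral ECoG channel
    rest = bu.rest_mask(fs.t_end, tgt.onset_times_s, fs.burn_in)
    thr = bu.burst_threshold(series, rest)
    bset = bu.detect_bursts(series, thr, band="low_beta")
    tib = bu.time_in_burst(bset, tgt.onset_times_s)
    prep_times.append(tib["prep"])
    scores.append(20 + 25 * (0.1 + 0.04 * subject) + rng.normal(0, 1.0))
    if subject < 3:
        print(f"subject {subject}: threshold {thr:.3f}, {bset.n_bursts} bursts, "
              f"prep {tib['prep']:.3f} s, move {tib['move']:.3f} s")

rep = bu.burst_score_correlation(prep_times, scores, seed=0, n_perm=5000)
print(f"\nburst time (prep) vs severity score across {rep.n} subjects: "
      f"Spearman rho = {rep.rho:.2f}, permutation p = {rep.p:.4f}")
print("positive rho recovers the planted burst-severity relation")
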