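"""Widefield cytometry on a synthetic field: correction, detection, gating.

Builds a 2D field of disc-shaped nuclei under an uneven illumination
gradient where 30% of cells carry a bright S-phase signal, then runs the
QIBC chain: polynomial illumination correction, adaptive-Otsu nucleus
detection with the 6-40 px diameter gate, per-nucleus integrated
intensities and fixed-threshold gating. Ends with the two unit-conversion
utilities used when relating imaging to fibre assays.
"""

import numpy as np

from spark3d.qibc import (fold_efficiency, gate_positive,
                          illumination_correct, integrate_intensities,
                          robust_signal, segment_nuclei_2d, tract_to_kb)

rng = np.random.default_rng(7)
size = 512
yy, xx = np.mgrid[:size, :size]
dapi = np.full((size, size), 10.0)
signal = np.full((size, size), 2.0)

centres, n_positive = [], 0
while len(centres) < 40:
    cy, cx = rng.integers(30, size - 30, 2)
    if all((cy - a) ** 2 + (cx - b) ** 2 > 45 ** 2 for a, b in centres):
        centres.append((cy, cx))
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= 10 ** 2
        dapi[disc] = 100.0
        if rng.random() < 0.30:  # planted S-phase fraction
            signal[disc] = 50.0
            n_positive += 1

gradient = 1.0 + 0.5 * xx / size  # uneven illumination
dapi = illumination_correct(dapi * gradient)
signal = illumination_correct(signal * gradient)

labels = segment_nuclei_2d(dapi)
records = integrate_intensities(labels, {"dapi": dapi, "edu": signal})
records, pct = gate_positive(records, "edu", threshold=5000.0)
values = [r.channel_integrated["edu"] for r in records]

print(f"planted nuclei: {len(centres)} ({n_positive} signal-positive)")
print(f"detected nuclei: {labels.max()}")
print(f"gated positive: {pct:.1f}% "
      f"(planted fraction {100 * n_positive / len(centres):.1f}%)")
print(f"robust population signal (p95 - p5): {robust_signal(values):.0f} a.u.")

print(f"\n6 µm fibre tract -> {tract_to_kb(6.0):.2f} kb of nascent DNA")
print("15 min @ 10 µM vs 240 min @ 100 µM -> "
      f"{fold_efficiency(15, 10, 240, 100):.0f}-fold incorporation efficiency")
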