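"""Classify hand-built overlap graphs into the replication-event taxonomy.

Shows the two-step logic on toy label volumes: (1) inter-channel overlaps
are scored relative to each focus's largest overlap and only those above
20% of that maximum are kept; (2) connected components of the kept-edge
bipartite graph map onto single-colour / ongoing / initiation / termination
/ crowded events.
"""

import numpy as np

from spark3d.events import (build_components, classify_component,
                            compute_overlaps, select_overlaps)
from spark3d.segment import LabelVolume

# two EdU foci and three dUTP foci on a toy grid (0.04 µm voxels)
edu = np.zeros((1, 8, 30), dtype=np.int32)
dutp = np.zeros_like(edu)
edu[0, 2:6, 1:7] = 1      # EdU 1
dutp[0, 2:6, 5:11] = 1    # dUTP 1 overlaps EdU 1 (ongoing pair)
edu[0, 2:6, 14:20] = 2    # EdU 2
dutp[0, 2:6, 18:24] = 2   # dUTP 2 overlaps EdU 2 strongly ...
dutp[0, 5:6, 19:21] = 3   # dUTP 3 carves a sliver out of the same region

records = compute_overlaps(LabelVolume(edu, 0.04, "edu"),
                           LabelVolume(dutp, 0.04, "dutp"))
print("raw overlaps (EdU label, dUTP label, voxels):")
for r in records:
    print(f"  ({r.focus_a}, {r.focus_b}): {r.overlap_voxels}")

selected = select_overlaps(records)
print("\nafter the >20%-of-maximum rule:")
for r in selected:
    print(f"  ({r.focus_a}, {r.focus_b}): rel scores "
          f"{r.rel_score_a:.2f}/{r.rel_score_b:.2f} -> "
          f"{'kept' if r.kept else 'dropped'}")

print("\nconnected components and their event types:")
for edu_set, dutp_set, edges in build_components([1, 2], [1, 2, 3], selected):
    etype = classify_component(edu_set, dutp_set, edges)
    print(f"  EdU {sorted(edu_set)} + dUTP {sorted(dutp_set)} -> {etype}")
print("\n(an isolated focus is a single-colour event; one EdU with one dUTP "
      "is an ongoing fork; weak overlaps never join a component)")
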