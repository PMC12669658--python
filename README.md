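# spark3d

Quantification of DNA-replication nanostructures in dual-channel 3D
super-resolution image stacks.

## The problem

During S phase, nascent DNA can be labelled with two sequential pulses —
a clickable thymidine analogue (EdU, detected post-fixation with an
azide dye) followed by a directly fluorescent dUTP delivered by a
nucleoside-triphosphate transporter. Imaged in 3D at ~100 nm resolution,
each replication site appears as a pair (or triplet) of nanoscale foci
whose colour pattern encodes its replication history:

| pattern | event type | interpretation |
|---|---|---|
| 1 EdU ↔ 1 dUTP | **ongoing** | a single fork synthesising through both pulses |
| 1 EdU ↔ 2 dUTP | **initiation** | bidirectional firing within the pulse window |
| 2 EdU ↔ 1 dUTP | **termination** | converging forks merging |
| isolated focus | single-colour | labelled in one pulse only |
| anything else (>3 foci) | crowded | concatenated clusters, excluded from kinetics |

`spark3d` implements the full analysis chain for such stacks and — because
real microscopy data is bulky and scarce — a synthetic-nucleus simulator
with planted ground truth, so every stage is testable at desk scale:

1. **simulate** — elliptical nuclei with hundreds of Gaussian-blob foci
   arranged as planted events on an anisotropic voxel grid, with Poisson +
   Gaussian noise (`spark3d.simulate`).
2. **segment** — anisotropy correction (linear z resampling to isotropic
   voxels), Voronoi-Otsu labelling (blur → LoG spot detection → Otsu →
   marker watershed), 2D nuclear masking, and the <50-voxel size cutoff
   (`spark3d.segment`).
3. **classify** — inter-channel overlap graph, pruning of overlaps ≤20% of
   each focus's maximum overlap, and component classification into the
   taxonomy above (`spark3d.events`).
4. **measure** — centroid distances of ongoing events, volume-overlap
   ratios (intersection / union of member foci), initiation angles
   (arccos of the centre→flank centroid vectors), nearest-neighbour and
   nuclear-periphery distance distributions, per-nucleus summaries, and
   Mann–Whitney U comparisons with Bonferroni correction
   (`spark3d.metrics`).
5. **qibc** — widefield quantitative image-based cytometry: polynomial
   illumination correction, adaptive-Otsu nucleus detection (6–40 px),
   per-nucleus integrated intensities, fixed-threshold S-phase gating and
   the robust p95−p5 population signal (`spark3d.qibc`).

## A worked example

`examples/01_simulate_and_analyze.py` plants 40 events in a small nucleus,
runs the full chain, and scores the recovery:

```
simulated 40 events on a (16, 256, 256) grid, voxel spacing (0.1, 0.04, 0.04) µm

detected events by type:
   single_colour: 8
         ongoing: 20
      initiation: 7
     termination: 2
         crowded: 3
dual-colour relative frequencies (initiation/ongoing/termination): 0.24 / 0.69 / 0.07
focus retention in dual events: 0.77

planted-type recovery accuracy: 0.97
centroid-distance MAE: 2.0 nm (measured vs planted separation of ongoing events)
initiation-angle MAE: 1.0 degrees
```

The per-type counts come from the classified overlap graph; "retention" is
the fraction of detected foci that end up in dual-colour events (the part
of the data usable for kinetics inference); the two MAE lines compare
measured geometry against the planted ground truth. The other examples
walk through the overlap-pruning/classification rules on toy label images
(`02_event_classification.py`) and the widefield cytometry chain
(`03_qibc_gating.py`).

A thin CLI wraps the same functions:

```bash
spark3d simulate --out scene/           # stack.tif + mask.tif + ground truth
spark3d analyze --stack scene/stack.tif --mask scene/mask.tif --out results/
spark3d qibc --fields fields/ --threshold 5000 --out cells.csv
```

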