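# Methods

## Conventions

Arrays are (z, y, x); 0-based voxel indices; the physical coordinate of
voxel *i* along an axis of spacing *d* is (i + 0.5)·d µm (voxel centres).
All distances are µm, volumes µm³, angles degrees. Nuclear masks are 2D
(drawn on, or simulated as, maximum-intensity projections) and apply to
every z plane.

## Synthetic nuclei

The simulator emulates an early-S-phase nucleus as seen by 3D structured
illumination: an elliptical nuclear footprint, hundreds of nascent-DNA foci
rendered as isotropic 3D Gaussian blobs in physical coordinates and sampled
onto an anisotropic grid (z step ≫ xy pixel), Poisson shot noise on
signal + background and additive Gaussian read noise. Rendering in physical
coordinates before sampling means the anisotropy-correction step is
genuinely exercised, not a no-op.

Planted event geometries follow the dual-pulse taxonomy: ongoing events are
one EdU + one dUTP blob at a configurable centroid separation; initiation
(termination) events are one EdU (dUTP) blob flanked by two dUTP (EdU)
blobs at the same separation with a configurable inter-flank angle; crowded
events are a chain of four alternating-channel blobs. Crowded events are
chains rather than balls: blobs of the *same* channel packed into a ball
would sit closer than the rendered point-spread scale and fuse into a
single focus at segmentation, so the planted ">3 foci" structure would be
unrecoverable by construction; a gently bending chain keeps same-channel
blobs about twice the separation apart while every adjacent inter-channel
pair still overlaps.

Placement is bounded rejection sampling: blob centres must fall inside the
footprint (with a 3σ margin) and the z slab, and blobs of distinct events
must be ≥ `min_event_gap` apart; after 10·n_events failed draws a
`PlacementError` is raised rather than silently truncating the scene.
Identical configs (including seed) give bit-identical stacks.

Default study conditions and why:

| parameter | default | rationale |
|---|---|---|
| voxel spacing | (0.10, 0.04, 0.04) µm | typical reconstructed 3D-SIM sampling; z ≫ xy |
| focus_sigma | 0.09 µm | rendered foci ≈ 100 voxels after correction, comfortably above the 50-voxel cutoff |
| separation mean ± sd | 0.135 ± 0.02 µm | the measured EdU↔dUTP nearest-neighbour distance of ~135 nm; draws truncated to [0.3, 1.55]× the mean so pairs stay renderable on the grid |
| angle distribution | uniform(120°, 180°) | flank pairs below ~110° sit closer than the imaging PSF at this separation and are unresolvable in principle; the planted range keeps the ground truth recoverable |
| amplitude / background / read sd | 100 / 10 / 2 photons | peak SNR ≈ 9, bright well-exposed foci |
| min_event_gap | 0.5 µm | ≈ 6·focus_sigma, so neighbouring events never merge |
| event mixture | 0.10/0.10 singles, 0.56/0.07/0.07 ongoing/init/term, 0.10 crowded | dual-event ratio 1:8:1 with roughly half of foci in curated dual events, as in real early-S nuclei |

What the simulator does **not** model: the SIM optical transfer function and
reconstruction artefacts, depth-dependent aberrations, chromatic shifts,
intensity variation between foci of one event, and the dense concatenated
foci of late-S nuclei. Passing recovery tests therefore demonstrates that
the analysis chain is correct and unbiased on well-formed anisotropic data
at realistic SNR — not that it is robust to reconstruction artefacts.

## Segmentation

Anisotropy correction resamples z by f = z_spacing / xy_spacing with 1-D
linear interpolation (f < 1 downsamples by the same formula). The resampler
is written directly on the voxel-centre convention — output plane *j*
samples input position (j + 0.5)/f − 0.5 — because generic zoom routines
rescale by (n−1)/(m−1), which would introduce a systematic z-scale error of
a few percent and bias every physical distance.

Foci are segmented per channel with a Voronoi-Otsu labelling workflow:
Gaussian blur (`blur_sigma`, default 1 voxel) → Otsu threshold on the
blurred volume → spot detection at `spot_sigma` scale → marker-based
watershed of the thresholded foreground on a constant image, i.e. geodesic
Voronoi expansion from the seeds. Spot detection uses maxima of the
Laplacian-of-Gaussian response at `spot_sigma` (default 1 voxel) rather
than maxima of the plain blur: the LoG is the standard band-pass spot
detector and resolves same-channel blob pairs down to ≈2σ of the effective
PSF, where plain blurred maxima already fuse. This matters for initiation
and termination events, whose two flanking foci are the closest structures
in the data. Otsu is computed once on the whole blurred volume (no
per-nucleus local thresholding); an all-constant volume yields zero labels.

Foci are assigned to nuclei by their centroid pixel (deterministic for foci
straddling the mask edge); foci whose centroid falls outside every nucleus
are discarded, then foci below `min_voxels = 50` voxels are removed
(strict less-than). Labels are recompacted after every filtering step, in
raster order of first occurrence, so ids are dense and runs reproducible.
Centroids are intensity-unweighted voxel-coordinate means converted to µm;
volume is voxel count × spacing³.

## Event classification

Every inter-channel label pair sharing ≥1 voxel is an overlap. For each
focus the largest of its overlaps defines a maximum, and an overlap is kept
only if strictly greater than 20% of that maximum (`overlap_rel_threshold`).
The rule is evaluated from both endpoints' perspectives and joined with AND
by default: the symmetric rule is order-independent and makes channel-swap
antisymmetry (initiation ↔ termination under relabelling of the channels)
exact on any input; the asymmetric OR variant is available via
`AnalysisConfig(overlap_rule="or")`. Ties for the maximum score 1 and are
kept.

Connected components of the kept-edge bipartite graph are classified:
singletons are single-colour; (1 EdU, 1 dUTP, 1 edge) ongoing; (1 EdU,
2 dUTP, 2-edge star) initiation; the mirror star termination; everything
else — including any component of more than `max_foci_per_event = 3` foci —
crowded. Exclusivity in the star definitions is enforced on the kept-edge
graph (pruning happens before classification). Retention is the fraction
of detected foci landing in dual-colour events, reported per nucleus.

## Geometry and statistics

* Ongoing-event centroid distance: Euclidean distance of the two member
  centroids in µm.
* Overlap ratio: intersection of the event's EdU and dUTP voxels divided by
  the union of all member-foci voxels ("total event volume" read as union,
  which avoids double counting). Event volume is the union count × voxel
  volume.
* Initiation angle: arccos of the normalised dot product of the two
  centre→flank centroid vectors, cosine clamped to [−1, 1]; termination is
  handled symmetrically from the dUTP centroid.
* Nearest-neighbour distances use a k-d tree, reported separately for the
  A→B and B→A directions; within-channel mode excludes self.
* Periphery distances: 2D Euclidean distance transform of each focus's own
  nucleus mask, sampled at the centroid pixel, in µm. 2D (not 3D) because
  the masks themselves are 2D projections.
* Group comparisons: two-sided Mann–Whitney U, exact null distribution for
  tie-free samples with both n ≤ 8, otherwise the normal approximation with
  tie correction; Bonferroni adjustment p_adj = min(1, p·n_tests).
* Colocalisation: Pearson R over masked pixels of two 2D projections, with
  no intensity threshold.

## QIBC

Illumination correction fits a 2nd-order 2D polynomial surface
(CellProfiler's "Fit Polynomial" convention, order config-exposed) and
divides by it, rescaling to preserve the input mean (subtraction available
per config); a constant image is returned unchanged, which also makes the
correction idempotent. Nucleus detection uses tiled (adaptive) Otsu
thresholds — tile size 4× the maximum object diameter, tiles without
meaningful contrast falling back to the global Otsu — interpolated to full
resolution, followed by hole filling and an equivalent-diameter gate of
[6, 40] px. Gating is strict: positive iff integrated intensity >
threshold; the threshold value is dataset-specific and always user input.
The robust population signal is p95 − p5 under the linear-interpolation
percentile convention (stated explicitly because the value differs across
conventions).

## Numerical/edge-case choices

Blank or constant volumes segment to zero labels (not an error); an empty
nuclear mask yields empty outputs with a warning; an initiation angle is
undefined (error) for coincident centroids; placement failure and missing
spacing metadata are explicit errors, never silent defaults. Separation
draws are truncated Gaussian as noted above. All randomness flows from the
single config seed through one `numpy` generator.

## Problem sizes

The test suite and the acceptance script validate recovery on single nuclei
of up to 500 planted events on a (24, 512, 512) grid — a few hundred
dual-colour events per nucleus, the same order as a real early-S cell — and
smaller grids elsewhere; statistical laws (triangular periphery-distance
density, multinomial mixture recovery) are checked at n = 1000–2000 points.

## Known limitations

Flank pairs closer than ≈2σ of the effective PSF are physically
unresolvable and classify as ongoing; with the default separation and angle
distributions this affects a few percent of three-focus events (visible as
the initiation→ongoing entries in recovery confusion tables). Otsu on a
whole volume assumes foci occupy a small but non-negligible intensity tail;
extremely sparse or empty channels may threshold noise (the size filter
removes the debris). The QIBC nucleus detector has no declumping step, so
touching nuclei merge and are usually rejected by the diameter gate.
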