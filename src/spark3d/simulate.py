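"""Synthetic dual-channel 3D nuclei with planted, ground-truth replication events.

The simulator emulates an early-S-phase nucleus imaged as an anisotropic
3D stack: hundreds of diffraction-scale nascent-DNA foci, rendered as
isotropic 3D Gaussian blobs in *physical* coordinates and sampled onto a
grid whose z step is much larger than the xy pixel, with Poisson shot noise
on signal-plus-background and additive Gaussian read noise. Events are
planted with the canonical dual-pulse geometries:

* ``single_a`` / ``single_b`` — one focus in the first (EdU) or second
  (dUTP) channel only.
* ``ongoing`` — one EdU focus and one dUTP focus, centroids separated by a
  configurable distance (a single fork synthesising through both pulses).
* ``initiation`` — one EdU focus flanked by two dUTP foci at the same
  separation, with a configurable angle between the two EdU→dUTP vectors
  (bidirectional firing within the pulse window).
* ``termination`` — the mirror image: two EdU foci and one dUTP focus
  (converging forks).
* ``crowded`` — a chain of four alternating-channel foci; such components
  have more than three nanofoci and are excluded from kinetics inference
  downstream.

Because every planted blob centre, separation and angle is recorded, the
full segmentation → classification → geometry chain can be validated by
planted-parameter recovery at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ChannelStack, NuclearMask, write_stack, write_mask

__all__ = [
    "SimulationConfig",
    "PlantedEvent",
    "GroundTruth",
    "PlacementError",
    "simulate_nucleus",
    "plant_single",
    "plant_ongoing",
    "plant_initiation",
    "plant_termination",
    "plant_crowded",
    "render_events",
    "write_ground_truth",
    "CHANNEL_EDU",
    "CHANNEL_DUTP",
    "EVENT_TYPES",
]

CHANNEL_EDU = "edu"
CHANNEL_DUTP = "dutp"
EVENT_TYPES = ("single_a", "single_b", "ongoing", "initiation", "termination", "crowded")


class PlacementError(RuntimeError):
    """Nucleus too small to place the requested events at min_event_gap."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic nucleus.

    All spatial parameters are in µm; the grid is (z, y, x).

    ``nucleus_semiaxes`` is ``(sz, sy, sx)``: the nuclear mask is an ellipse
    with semi-axes (sy, sx) in the image plane, and planted blob centres are
    confined to a slab of half-thickness sz around the mid-plane in z.

    ``event_mixture`` must sum to 1 over the keys of :data:`EVENT_TYPES`.
    ``angle_range`` is the uniform distribution (degrees) of the inter-dUTP
    angle of initiation (and, mirrored, termination) events.
    """

    grid_shape: tuple = (24, 512, 512)
    voxel_spacing: tuple = (0.10, 0.04, 0.04)
    nucleus_semiaxes: tuple = (0.7, 8.5, 9.5)
    n_events: int = 300
    event_mixture: dict = field(default_factory=lambda: {
        "single_a": 0.10, "single_b": 0.10,
        "ongoing": 0.56, "initiation": 0.07, "termination": 0.07,
        "crowded": 0.10,
    })
    separation_mean: float = 0.135
    separation_sd: float = 0.02
    angle_range: tuple = (120.0, 180.0)
    focus_sigma: float = 0.09
    amplitude: float = 100.0
    background: float = 10.0
    gaussian_read_noise_sd: float = 2.0
    min_event_gap: float = 0.5
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        probs = np.array([self.event_mixture.get(t, 0.0) for t in EVENT_TYPES])
        unknown = set(self.event_mixture) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types in mixture: {sorted(unknown)}")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"event_mixture probabilities must be >=0 and sum to 1, got {probs.sum()}"
            )
        for name in ("separation_mean", "focus_sigma", "min_event_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(s <= 0 for s in self.voxel_spacing) or any(s <= 0 for s in self.nucleus_semiaxes):
            raise ValueError("spacing and semi-axes must be > 0")
        if self.separation_sd < 0 or self.amplitude <= 0 or self.background < 0:
            raise ValueError("invalid intensity/noise parameters")
        lo, hi = self.angle_range
        if not (0 < lo <= hi <= 180):
            raise ValueError("angle_range must satisfy 0 < lo <= hi <= 180 degrees")


@dataclass
class PlantedEvent:
    """One ground-truth event: true type and the physical blob centres."""

    event_id: int
    true_type: str
    #: list of (channel, z, y, x) with coordinates in µm
    blob_centres: list
    true_separation: float | None = None
    true_angle: float | None = None

    def centres_of(self, channel: str) -> np.ndarray:
        pts = [c[1:] for c in self.blob_centres if c[0] == channel]
        return np.array(pts, dtype=float).reshape(-1, 3)

    @property
    def centre(self) -> np.ndarray:
        return np.mean([c[1:] for c in self.blob_centres], axis=0)


@dataclass
class GroundTruth:
    planted_events: list
    nuclear_mask: NuclearMask
    config: SimulationConfig

    def __post_init__(self):
        ids = [e.event_id for e in self.planted_events]
        if len(ids) != len(set(ids)):
            raise ValueError("planted event ids must be unique")
        if not (self.nuclear_mask.labels > 0).any():
            raise ValueError("nuclear mask is empty")


# ---------------------------------------------------------------------------
# event geometry builders


def plant_single(centre, channel: str, event_id: int = 0) -> PlantedEvent:
    t = "single_a" if channel == CHANNEL_EDU else "single_b"
    return PlantedEvent(event_id, t, [(channel, *np.asarray(centre, float))])


def plant_ongoing(centre, separation: float, direction=None,
                  event_id: int = 0) -> PlantedEvent:
    """One EdU and one dUTP blob, centroids `separation` µm apart."""
    if separation <= 0:
        raise ValueError("separation must be > 0")
    u = _unit(direction if direction is not None else (0.0, 0.0, 1.0))
    c = np.asarray(centre, float)
    a = c - 0.5 * separation * u
    b = c + 0.5 * separation * u
    return PlantedEvent(event_id, "ongoing",
                        [(CHANNEL_EDU, *a), (CHANNEL_DUTP, *b)],
                        true_separation=separation)


def plant_initiation(centre, separation: float, angle: float, basis=None,
                     event_id: int = 0) -> PlantedEvent:
    """One EdU blob at `centre`, two dUTP blobs at distance `separation`.

    ``angle`` (degrees, in (0, 180]) is the angle between the two
    EdU→dUTP vectors. ``basis`` optionally fixes the event plane as two
    orthonormal 3-vectors ``(e1, e2)``; the default plane is (y, x).
    """
    if separation <= 0:
        raise ValueError("separation must be > 0")
    if not 0 < angle <= 180:
        raise ValueError(f"angle must lie in (0, 180] degrees, got {angle}")
    e1, e2 = _orthonormal_basis(basis)
    half = math.radians(angle) / 2.0
    c = np.asarray(centre, float)
    v1 = separation * (math.cos(half) * e1 + math.sin(half) * e2)
    v2 = separation * (math.cos(half) * e1 - math.sin(half) * e2)
    return PlantedEvent(event_id, "initiation",
                        [(CHANNEL_EDU, *c),
                         (CHANNEL_DUTP, *(c + v1)),
                         (CHANNEL_DUTP, *(c + v2))],
                        true_separation=separation, true_angle=float(angle))


def plant_termination(centre, separation: float, angle: float, basis=None,
                      event_id: int = 0) -> PlantedEvent:
    """Mirror of initiation: one dUTP blob flanked by two EdU blobs."""
    init = plant_initiation(centre, separation, angle, basis=basis)
    swapped = [(CHANNEL_DUTP if ch == CHANNEL_EDU else CHANNEL_EDU, z, y, x)
               for ch, z, y, x in init.blob_centres]
    return PlantedEvent(event_id, "termination", swapped,
                        true_separation=separation, true_angle=float(angle))


def plant_crowded(centre, separation: float, rng: np.random.Generator,
                  event_id: int = 0) -> PlantedEvent:
    """Chain of 4 alternating-channel blobs (a >3-nanofoci component).

    Adjacent blobs (different channels) sit `separation` apart so each
    inter-channel pair overlaps once rendered; small random turns keep the
    chain compact while same-channel blobs stay ~2× separation apart so
    they remain individually resolvable.
    """
    c = np.asarray(centre, float)
    u = _random_unit(rng)
    pts = [c - 1.5 * separation * u]
    direction = u
    for _ in range(3):
        # bend by <=25 degrees around a random axis
        direction = _rotate_slightly(direction, rng, max_deg=25.0)
        pts.append(pts[-1] + separation * direction)
    chain_centre = np.mean(pts, axis=0)
    pts = [p + (c - chain_centre) for p in pts]
    chans = [CHANNEL_EDU, CHANNEL_DUTP, CHANNEL_EDU, CHANNEL_DUTP]
    return PlantedEvent(event_id, "crowded",
                        [(ch, *p) for ch, p in zip(chans, pts)],
                        true_separation=separation)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    while np.linalg.norm(v) < 1e-12:
        v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_slightly(u, rng, max_deg=25.0) -> np.ndarray:
    perp = np.cross(u, _random_unit(rng))
    n = np.linalg.norm(perp)
    if n < 1e-9:
        return u
    perp /= n
    theta = math.radians(rng.uniform(0.0, max_deg))
    return math.cos(theta) * u + math.sin(theta) * perp


def _orthonormal_basis(basis):
    if basis is None:
        e1 = np.array([0.0, 1.0, 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        return e1, e2
    e1 = _unit(basis[0])
    e2 = np.asarray(basis[1], float)
    e2 = e2 - np.dot(e2, e1) * e1
    return e1, _unit(e2)


def _random_basis(rng):
    e1 = _random_unit(rng)
    e2 = _random_unit(rng)
    e2 = e2 - np.dot(e2, e1) * e1
    while np.linalg.norm(e2) < 1e-9:
        e2 = _random_unit(rng)
        e2 = e2 - np.dot(e2, e1) * e1
    return e1, e2 / np.linalg.norm(e2)


# ---------------------------------------------------------------------------
# placement and rendering


def draw_event_types(rng: np.random.Generator, n: int, mixture: dict) -> list:
    """Draw n event types i.i.d. from the configured mixture."""
    types = list(EVENT_TYPES)
    probs = np.array([mixture.get(t, 0.0) for t in types], float)
    probs = probs / probs.sum()
    return [types[i] for i in rng.choice(len(types), size=n, p=probs)]


def make_nuclear_mask(config: SimulationConfig) -> NuclearMask:
    """Elliptical nucleus footprint centred in the (y, x) plane."""
    _, ny, nx = config.grid_shape
    _, dy, dx = config.voxel_spacing
    _, sy, sx = config.nucleus_semiaxes
    yy = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
    xx = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    inside = (Y / sy) ** 2 + (X / sx) ** 2 <= 1.0
    return NuclearMask(inside.astype(np.uint16), (dy, dx))


def _build_event(true_type, centre, config, rng, event_id) -> PlantedEvent:
    sep = float(np.clip(rng.normal(config.separation_mean, config.separation_sd),
                        0.3 * config.separation_mean, 1.55 * config.separation_mean)) \
        if config.separation_sd > 0 else config.separation_mean
    if true_type == "single_a":
        return plant_single(centre, CHANNEL_EDU, event_id)
    if true_type == "single_b":
        return plant_single(centre, CHANNEL_DUTP, event_id)
    if true_type == "ongoing":
        return plant_ongoing(centre, sep, _random_unit(rng), event_id)
    if true_type in ("initiation", "termination"):
        angle = float(rng.uniform(*config.angle_range))
        basis = _random_basis(rng)
        fn = plant_initiation if true_type == "initiation" else plant_termination
        return fn(centre, sep, angle, basis=basis, event_id=event_id)
    if true_type == "crowded":
        return plant_crowded(centre, sep, rng, event_id)
    raise ValueError(f"unknown event type {true_type}")


def place_events(config: SimulationConfig, rng: np.random.Generator) -> list:
    """Plant events by bounded rejection sampling.

    Every blob centre must lie inside the nuclear footprint (with a 3-sigma
    margin) and within the z slab, and all blobs of distinct events must be
    at least ``min_event_gap`` apart. After ``10 * n_events`` failed
    attempts a :class:`PlacementError` is raised rather than silently
    truncating the scene.
    """
    nz, ny, nx = config.grid_shape
    dz, dy, dx = config.voxel_spacing
    sz, sy, sx = config.nucleus_semiaxes
    z0 = nz * dz / 2.0
    y0 = ny * dy / 2.0
    x0 = nx * dx / 2.0
    margin = 3.0 * config.focus_sigma
    sy_in, sx_in = sy - margin, sx - margin
    if sy_in <= 0 or sx_in <= 0:
        raise PlacementError("nucleus semi-axes smaller than the blob margin")
    zlo = max(z0 - sz, margin)
    zhi = min(z0 + sz, nz * dz - margin)
    if zhi <= zlo:
        raise PlacementError("z slab thinner than the blob margin")

    types = draw_event_types(rng, config.n_events, config.event_mixture)
    events: list[PlantedEvent] = []
    occupied: list[np.ndarray] = []
    occ_arr = np.empty((0, 3))
    attempts_left = 10 * config.n_events
    for i, t in enumerate(types):
        placed = False
        while attempts_left > 0:
            attempts_left -= 1
            # uniform point in the eroded ellipse footprint
            while True:
                y = rng.uniform(-sy_in, sy_in)
                x = rng.uniform(-sx_in, sx_in)
                if (y / sy_in) ** 2 + (x / sx_in) ** 2 <= 1.0:
                    break
            z = rng.uniform(zlo, zhi)
            ev = _build_event(t, (z, y0 + y, x0 + x), config, rng, event_id=i)
            pts = np.array([c[1:] for c in ev.blob_centres])
            if not _inside(pts, z0, y0, x0, sz, sy_in, sx_in, zlo, zhi):
                continue
            if len(occ_arr) and np.min(
                np.linalg.norm(occ_arr[:, None, :] - pts[None, :, :], axis=2)
            ) < config.min_event_gap:
                continue
            events.append(ev)
            occupied.extend(pts)
            occ_arr = np.asarray(occupied)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place event {i + 1}/{config.n_events} within "
                f"{10 * config.n_events} total attempts; nucleus too small for "
                f"n_events at min_event_gap={config.min_event_gap} µm"
            )
    return events


def _inside(pts, z0, y0, x0, sz, sy_in, sx_in, zlo, zhi) -> bool:
    ok_z = (pts[:, 0] >= zlo) & (pts[:, 0] <= zhi)
    ok_plane = (((pts[:, 1] - y0) / sy_in) ** 2 + ((pts[:, 2] - x0) / sx_in) ** 2) <= 1.0
    return bool(np.all(ok_z & ok_plane))


def render_events(config: SimulationConfig, events: Sequence[PlantedEvent]) -> dict:
    """Render noise-free per-channel volumes (signal only, no background).

    Each blob is an isotropic 3D Gaussian of SD ``focus_sigma`` µm evaluated
    at the physical voxel centres of the anisotropic grid, truncated at 5
    sigma. Returns float64 arrays keyed by channel name.
    """
    nz, ny, nx = config.grid_shape
    dz, dy, dx = config.voxel_spacing
    sig = config.focus_sigma
    reach = 5.0 * sig
    out = {CHANNEL_EDU: np.zeros(config.grid_shape),
           CHANNEL_DUTP: np.zeros(config.grid_shape)}
    for ev in events:
        for ch, cz, cy, cx in ev.blob_centres:
            iz0 = max(int(math.floor((cz - reach) / dz - 0.5)), 0)
            iz1 = min(int(math.ceil((cz + reach) / dz - 0.5)) + 1, nz)
            iy0 = max(int(math.floor((cy - reach) / dy - 0.5)), 0)
            iy1 = min(int(math.ceil((cy + reach) / dy - 0.5)) + 1, ny)
            ix0 = max(int(math.floor((cx - reach) / dx - 0.5)), 0)
            ix1 = min(int(math.ceil((cx + reach) / dx - 0.5)) + 1, nx)
            if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
                continue
            zz = ((np.arange(iz0, iz1) + 0.5) * dz - cz) ** 2
            yy = ((np.arange(iy0, iy1) + 0.5) * dy - cy) ** 2
            xx = ((np.arange(ix0, ix1) + 0.5) * dx - cx) ** 2
            r2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
            out[ch][iz0:iz1, iy0:iy1, ix0:ix1] += (
                config.amplitude * np.exp(-r2 / (2.0 * sig ** 2))
            )
    return out


def simulate_nucleus(config: SimulationConfig):
    """Simulate one nucleus.

    Returns ``(stack, mask, ground_truth)`` where the stack holds the two
    noisy channel volumes. Identical configs (including seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    mask = make_nuclear_mask(config)
    events = place_events(config, rng) if config.n_events > 0 else []
    clean = render_events(config, events)
    channels = {}
    for ch in (CHANNEL_EDU, CHANNEL_DUTP):
        expected = clean[ch] + config.background
        img = rng.poisson(expected).astype(np.float64) if config.shot_noise \
            else expected
        if config.gaussian_read_noise_sd > 0:
            img = img + rng.normal(0.0, config.gaussian_read_noise_sd,
                                   size=img.shape)
        channels[ch] = img.astype(np.float32)
    stack = ChannelStack(channels, config.voxel_spacing)
    return stack, mask, GroundTruth(events, mask, config)


# ---------------------------------------------------------------------------
# on-disk ground truth


def ground_truth_frames(gt: GroundTruth) -> tuple:
    """Ground truth as (blobs, events) DataFrames, one row per blob/event."""
    blob_rows, event_rows = [], []
    for ev in gt.planted_events:
        event_rows.append({
            "event_id": ev.event_id, "true_type": ev.true_type,
            "true_separation_um": ev.true_separation,
            "true_angle_deg": ev.true_angle,
        })
        for ch, z, y, x in ev.blob_centres:
            blob_rows.append({"event_id": ev.event_id, "channel": ch,
                              "z_um": z, "y_um": y, "x_um": x})
    blob_cols = ["event_id", "channel", "z_um", "y_um", "x_um"]
    ev_cols = ["event_id", "true_type", "true_separation_um", "true_angle_deg"]
    return (pd.DataFrame(blob_rows, columns=blob_cols),
            pd.DataFrame(event_rows, columns=ev_cols))


def write_ground_truth(gt: GroundTruth, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blobs, events = ground_truth_frames(gt)
    paths = {"blobs": out_dir / "true_blobs.csv",
             "events": out_dir / "true_events.csv"}
    blobs.to_csv(paths["blobs"], index=False)
    events.to_csv(paths["events"], index=False)
    return paths
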