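"""Reading and writing of stacks, masks, tables and analysis configuration.

Conventions used throughout the package:

* 3D arrays are ordered ``(z, y, x)``; 2D arrays ``(y, x)``.
* Voxel/pixel indices are 0-based; the physical coordinate of voxel ``i``
  along an axis with spacing ``d`` is ``(i + 0.5) * d`` micrometres
  (voxel centres).
* All physical quantities are in micrometres (µm) unless stated otherwise.

Stacks are stored as multi-page TIFF with axes ``(C, Z, Y, X)`` plus a JSON
sidecar holding the voxel spacing and channel names — spacing is always an
explicit input, never a silent default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ChannelStack",
    "NuclearMask",
    "AnalysisConfig",
    "MetadataError",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_tables",
    "read_tables",
    "load_analysis_config",
    "save_analysis_config",
]


class MetadataError(ValueError):
    """Raised when required spacing/channel metadata is missing or invalid."""


@dataclass
class ChannelStack:
    """Per-channel 3D intensity volumes with physical voxel spacing.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"edu"``, ``"dutp"``) to a 3D
        ``(z, y, x)`` intensity array. All channels must share one shape.
    voxel_spacing
        Physical voxel size ``(z, y, x)`` in µm; strictly positive.
    source
        Optional path the stack was read from.
    """

    channels: dict
    voxel_spacing: tuple
    source: str | None = None

    def __post_init__(self):
        shapes = {ch: np.asarray(v).shape for ch, v in self.channels.items()}
        uniq = set(shapes.values())
        if len(uniq) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for s in uniq:
            if len(s) != 3:
                raise ValueError(f"channels must be 3D (z,y,x), got shape {s}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise MetadataError(
                f"voxel_spacing must be three positive values, got {self.voxel_spacing}"
            )

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self):
        return list(self.channels.keys())


@dataclass
class NuclearMask:
    """2D nucleus label image: 0 = background, k > 0 = nucleus k.

    Masks are drawn on (or simulated as) maximum-intensity projections and
    applied to every z plane of the corresponding stack.
    """

    labels: np.ndarray
    pixel_spacing: tuple  # (y, x) µm

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("nuclear mask must be 2D (y,x)")
        if self.labels.min() < 0:
            raise ValueError("mask labels must be non-negative integers")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise MetadataError("pixel_spacing must be two positive values")

    @property
    def nucleus_ids(self):
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    Defaults are the published constants of the workflow: foci below 50
    voxels are discarded, inter-channel overlaps are kept only when larger
    than 20% of the focus's maximum overlap, components of more than 3 foci
    are "crowded", and stretched-fibre lengths convert to DNA length at
    2.59 kbp/µm.
    """

    min_voxels: int = 50
    overlap_rel_threshold: float = 0.20
    max_foci_per_event: int = 3
    #: Gaussian outline-blur sigma in µm; None means 1 isotropic voxel.
    blur_sigma_um: float | None = None
    #: Spot-detection blur sigma in µm; None means 1 isotropic voxel.
    spot_sigma_um: float | None = None
    channel_edu: str = "edu"
    channel_dutp: str = "dutp"
    #: Join rule for the >20% overlap selection across the two endpoints.
    overlap_rule: str = "and"  # "and" (symmetric, default) or "or"
    periphery_mode: str = "2d"
    fibre_rate_kbp_per_um: float = 2.59
    illumination_poly_order: int = 2
    illumination_mode: str = "divide"

    def __post_init__(self):
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if not 0 < self.overlap_rel_threshold < 1:
            raise ValueError("overlap_rel_threshold must lie in (0, 1)")
        if self.overlap_rule not in ("and", "or"):
            raise ValueError("overlap_rule must be 'and' or 'or'")
        if self.max_foci_per_event < 1:
            raise ValueError("max_foci_per_event must be >= 1")


# ---------------------------------------------------------------------------
# stacks


def write_stack(stack: ChannelStack, path, sidecar=None) -> tuple:
    """Write a ChannelStack as a (C, Z, Y, X) TIFF plus a JSON sidecar.

    Returns the (tiff_path, sidecar_path) written.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    names = stack.channel_names
    data = np.stack([np.asarray(stack.channels[ch]) for ch in names])
    tifffile.imwrite(path, data)
    meta = {"spacing_um": list(stack.voxel_spacing), "channels": names}
    sidecar.write_text(json.dumps(meta, indent=2))
    return path, sidecar


def read_stack(path, sidecar=None) -> ChannelStack:
    """Read a multi-channel TIFF stack; spacing must come from the sidecar.

    Raises
    ------
    MetadataError
        If the sidecar is absent or lacks spacing/channel entries.
    ValueError
        If channel shapes are inconsistent with the metadata.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sidecar.exists():
        raise MetadataError(
            f"no spacing metadata: sidecar {sidecar} not found "
            "(voxel spacing is required, never defaulted)"
        )
    meta = json.loads(sidecar.read_text())
    if "spacing_um" not in meta or "channels" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks 'spacing_um'/'channels'")
    data = tifffile.imread(path)
    names = list(meta["channels"])
    if data.ndim == 3 and len(names) == 1:
        data = data[None]
    elif data.ndim == 3 and data.shape[0] % len(names) == 0:
        # pages flattened on disk; the sidecar channel count restores (C,Z,Y,X)
        data = data.reshape(len(names), -1, *data.shape[1:])
    if data.shape[0] != len(names):
        raise ValueError(
            f"TIFF has {data.shape[0]} channels but sidecar lists {len(names)}"
        )
    channels = {ch: data[i] for i, ch in enumerate(names)}
    return ChannelStack(channels, tuple(meta["spacing_um"]), source=str(path))


def write_mask(mask: NuclearMask, path, sidecar=None) -> tuple:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    sidecar.write_text(json.dumps({"pixel_spacing_um": list(mask.pixel_spacing)}))
    return path, sidecar


def read_mask(path, sidecar=None) -> NuclearMask:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sidecar.exists():
        raise MetadataError(f"no pixel spacing metadata for mask: {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    if "pixel_spacing_um" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks 'pixel_spacing_um'")
    return NuclearMask(tifffile.imread(path), tuple(meta["pixel_spacing_um"]))


# ---------------------------------------------------------------------------
# tables

FOCI_COLUMNS = [
    "focus_id", "channel", "nucleus_id", "voxel_count", "volume_um3",
    "centroid_z_um", "centroid_y_um", "centroid_x_um",
    "integrated_intensity", "mean_intensity",
]
EVENT_COLUMNS = ["event_id", "nucleus_id", "type", "edu_focus_ids", "dutp_focus_ids"]


def write_tables(foci: pd.DataFrame, events: pd.DataFrame,
                 summaries: pd.DataFrame, out_dir) -> dict:
    """Write foci/events/nucleus-summary CSVs with a stable column order.

    Numeric round-trip is lossless: floats are written with shortest
    round-trip repr (pandas default) and integers exactly.

    Raises
    ------
    ValueError
        If an event references a focus id absent from the foci table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(events):
        known = set(foci["focus_id"].tolist())
        for col in ("edu_focus_ids", "dutp_focus_ids"):
            for ids in events[col]:
                for fid in _parse_id_list(ids):
                    if fid not in known:
                        raise ValueError(f"event references unknown focus id {fid}")
    paths = {}
    for name, df, cols in (
        ("foci", foci, FOCI_COLUMNS),
        ("events", events, EVENT_COLUMNS),
        ("summaries", summaries, None),
    ):
        p = out_dir / f"{name}.csv"
        out = df.copy()
        if cols is not None:
            for c in cols:
                if c not in out.columns:
                    out[c] = pd.Series(dtype=object)
            out = out[cols]
        out.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_tables(out_dir) -> dict:
    out_dir = Path(out_dir)
    return {name: pd.read_csv(out_dir / f"{name}.csv",
                              float_precision="round_trip")
            for name in ("foci", "events", "summaries")}


def _parse_id_list(value) -> list:
    """Parse a semicolon-joined focus-id list as written to the events CSV."""
    if isinstance(value, (list, tuple)):
        return [int(v) for v in value]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    if not s:
        return []
    return [int(tok) for tok in s.split(";")]


def format_id_list(ids: Sequence[int]) -> str:
    return ";".join(str(int(i)) for i in ids)


# ---------------------------------------------------------------------------
# config files


def save_analysis_config(config: AnalysisConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(asdict(config), sort_keys=False))
    return path


def load_analysis_config(path) -> AnalysisConfig:
    """Load a YAML analysis config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
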