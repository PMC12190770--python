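"""Volume and manifest I/O.

Defines the in-memory containers shared by every pipeline stage — a
multi-channel 3D :class:`ChannelVolume` and the per-sample metadata row
:class:`SampleMeta` — together with OME-TIFF readers/writers and the
manifest CSV schema.

Coordinate convention: arrays are 0-based and ordered ``(channel, z, y, x)``
with z index 0 at the top of the stack.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ChannelVolume",
    "SampleMeta",
    "read_volume",
    "write_volume",
    "load_manifest",
    "save_manifest",
    "MANIFEST_COLUMNS",
]

#: Channel names required by the quantification pipeline.
REQUIRED_CHANNELS = ("DAPI", "GFP", "EFFECTOR")

#: Required manifest columns (``manual_flags`` and ``path`` are optional).
MANIFEST_COLUMNS = ("sample_id", "tool", "condition", "axis_value", "bio_replicate")


@dataclass
class ChannelVolume:
    """A named multi-channel 3D voxel array with physical voxel size.

    Parameters
    ----------
    voxels
        Intensity array ordered ``(channel, z, y, x)``, non-negative AU.
    channel_names
        One unique label per channel, same order as ``voxels``.
    voxel_size_um
        Physical voxel size ``(z, y, x)`` in micrometres.
    bit_depth
        8 or 16; intensities must lie in ``[0, 2**bit_depth - 1]``.
    """

    voxels: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size_um: tuple[float, float, float] = (9.0, 5.0, 5.0)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4D (c, z, y, x), got {self.voxels.ndim}D")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.voxels.size and (
            self.voxels.min() < 0 or self.voxels.max() > self.max_intensity
        ):
            raise ValueError(
                f"intensities must lie in [0, {self.max_intensity}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (z, y, x) array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in volume (have {list(self.channel_names)})"
            ) from None
        return self.voxels[idx]

    def require_channels(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(
                f"volume is missing required channel(s) {missing}; "
                f"present: {list(self.channel_names)}"
            )


@dataclass
class SampleMeta:
    """One manifest row: identity and experimental condition of a sample."""

    sample_id: str
    tool: str
    condition: str
    axis_value: float
    bio_replicate: str
    manual_flags: frozenset[str] = field(default_factory=frozenset)
    path: str | None = None

    def __post_init__(self) -> None:
        self.axis_value = float(self.axis_value)
        if self.axis_value < 0:
            raise ValueError(f"axis_value must be >= 0, got {self.axis_value}")
        self.manual_flags = frozenset(self.manual_flags)
        self.bio_replicate = str(self.bio_replicate)


def write_volume(path: str | Path, volume: ChannelVolume) -> Path:
    """Write a volume as OME-TIFF with named channels and voxel sizes."""
    path = Path(path)
    dtype = np.uint8 if volume.bit_depth == 8 else np.uint16
    data = np.asarray(np.round(volume.voxels), dtype=dtype)
    z_um, y_um, x_um = volume.voxel_size_um
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(volume.channel_names)},
            "PhysicalSizeZ": z_um,
            "PhysicalSizeY": y_um,
            "PhysicalSizeX": x_um,
        },
    )
    return path


def _ome_channel_names(ome_xml: str) -> list[str]:
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    names = []
    for ch in root.iter(f"{{{ns['ome']}}}Channel"):
        names.append(ch.get("Name") or f"C{len(names)}")
    return names


def _ome_voxel_size(ome_xml: str) -> tuple[float, float, float] | None:
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0].strip("{")
    px = next(root.iter(f"{{{ns}}}Pixels"), None)
    if px is None:
        return None
    try:
        return (
            float(px.get("PhysicalSizeZ")),
            float(px.get("PhysicalSizeY")),
            float(px.get("PhysicalSizeX")),
        )
    except (TypeError, ValueError):
        return None


def read_volume(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    required_channels: Sequence[str] | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> ChannelVolume:
    """Read an OME-TIFF (or plain multi-page TIFF) volume.

    For OME-TIFF, channel names and voxel size come from the embedded
    metadata; ``channel_names`` overrides them.  Plain TIFFs without
    channel metadata require an explicit ``channel_names`` list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome_xml = tf.ome_metadata
    if data.ndim == 3:  # single channel stack
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"cannot interpret {path} as (c, z, y, x); shape {data.shape}")

    names: Sequence[str] | None = channel_names
    meta_size = None
    if ome_xml:
        meta_size = _ome_voxel_size(ome_xml)
        if names is None:
            parsed = _ome_channel_names(ome_xml)
            if len(parsed) == data.shape[0]:
                names = parsed
    if names is None:
        raise ValueError(
            f"{path} carries no channel metadata; pass channel_names explicitly"
        )
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{len(names)} channel names for {data.shape[0]} channels in {path}"
        )
    bit_depth = 8 if data.dtype == np.uint8 else 16
    vol = ChannelVolume(
        voxels=data,
        channel_names=tuple(names),
        voxel_size_um=voxel_size_um or meta_size or (9.0, 5.0, 5.0),
        bit_depth=bit_depth,
    )
    if required_channels:
        vol.require_channels(required_channels)
    return vol


def _parse_flags(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return frozenset()
    return frozenset(part.strip() for part in str(raw).split(";") if part.strip())


def load_manifest(path: str | Path) -> list[SampleMeta]:
    """Load and validate a manifest CSV into :class:`SampleMeta` rows.

    Required columns: sample_id, tool, condition, axis_value, bio_replicate.
    Optional: manual_flags (semicolon-separated), path.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "bio_replicate": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing column(s) {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"manifest {path} has duplicate sample_id(s) {sorted(set(dupes))}")
    records = []
    for i, row in df.iterrows():
        try:
            axis_value = float(row["axis_value"])
        except (TypeError, ValueError):
            raise ValueError(
                f"manifest row {i} (sample_id={row['sample_id']!r}): "
                f"non-numeric axis_value {row['axis_value']!r}"
            ) from None
        records.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                tool=str(row["tool"]),
                condition=str(row["condition"]),
                axis_value=axis_value,
                bio_replicate=str(row["bio_replicate"]),
                manual_flags=_parse_flags(row.get("manual_flags")),
                path=str(row["path"]) if "path" in df.columns and pd.notna(row["path"]) else None,
            )
        )
    return records


def save_manifest(path: str | Path, records: Sequence[SampleMeta]) -> Path:
    """Write SampleMeta rows to a manifest CSV (inverse of load_manifest)."""
    path = Path(path)
    rows = [
        {
            "sample_id": r.sample_id,
            "tool": r.tool,
            "condition": r.condition,
            "axis_value": r.axis_value,
            "bio_replicate": r.bio_replicate,
            "manual_flags": ";".join(sorted(r.manual_flags)),
            "path": r.path or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
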