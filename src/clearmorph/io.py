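"""Image and table I/O plus the core in-memory data model.

The package represents a single-channel multiphoton z-stack as an
:class:`ImageStack`: a 3-D array of non-negative intensities indexed
``(z, y, x)`` together with the physical voxel extent per axis in
micrometres.  Voxels are generally anisotropic (the z step of the
acquisition is coarser than the in-plane pixel spacing), so every
physical measurement downstream goes through ``voxel_size``.

Stacks are exchanged as multi-page TIFF (one page per z-slice).  Voxel
size and sample metadata are recorded both in the TIFF ImageJ metadata
and in a JSON sidecar written next to the image; the sidecar is the
authoritative copy on re-read.  All coordinates are voxel-centre based,
0-based, and reported in micrometres.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SEXES",
    "CONDITIONS",
    "SIDES",
    "TISSUES",
    "SampleMetadata",
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]

SEXES = ("male", "female")
CONDITIONS = ("SNI", "sham")
SIDES = ("ipsilateral", "contralateral")
TISSUES = ("DRG", "ScN_proximal", "ScN_distal")


@dataclass(frozen=True)
class SampleMetadata:
    """Identity of one imaged sample (one tissue from one side of one animal)."""

    sample_id: str
    sex: str
    condition: str
    side: str
    tissue: str
    animal_id: str = ""

    def __post_init__(self) -> None:
        for value, allowed, name in (
            (self.sex, SEXES, "sex"),
            (self.condition, CONDITIONS, "condition"),
            (self.side, SIDES, "side"),
            (self.tissue, TISSUES, "tissue"),
        ):
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SampleMetadata":
        keys = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in keys})


@dataclass
class ImageStack:
    """A 3-D single-channel intensity grid with physical voxel dimensions.

    Parameters
    ----------
    data
        Intensities indexed ``(z, y, x)``; finite and non-negative.
    voxel_size
        Physical extent of one voxel per axis ``(z, y, x)`` in µm.
    metadata
        Optional sample identity.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    metadata: SampleMetadata | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3-D (z, y, x); got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive extents in µm; got {self.voxel_size}")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("stack intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.voxel_size))

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return ImageStack(data=data, voxel_size=self.voxel_size, metadata=self.metadata, name=self.name)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON sidecar.

    Intensities are stored as their native dtype if integral, otherwise
    float32.  The sidecar records voxel size and sample metadata and is
    what :func:`read_stack` trusts on the way back in.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.data
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    # ImageJ convention: spacing = z step, resolution = pixels per µm in x/y
    tifffile.imwrite(
        path,
        data,
        imagej=np.issubdtype(data.dtype, np.integer) or data.dtype == np.float32,
        resolution=(1.0 / stack.voxel_size[2], 1.0 / stack.voxel_size[1]),
        metadata={"spacing": stack.voxel_size[0], "unit": "um", "axes": "ZYX"},
    )
    sidecar = {
        "voxel_size_um": list(stack.voxel_size),
        "name": stack.name,
        "metadata": stack.metadata.to_dict() if stack.metadata else None,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    z is page order.  Voxel size comes from the JSON sidecar if present,
    else from ImageJ TIFF metadata; ``voxel_size_override`` wins over
    both.  A stack with no discoverable voxel size and no override is an
    error, because every downstream measurement is physical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise ValueError(f"pages of {path} have differing shapes: {sorted(shapes)}")
        data = tf.asarray()
        ij = tf.imagej_metadata or {}
        tags = tf.pages[0].tags
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel z-stack, got shape {data.shape}")

    voxel_size = None
    metadata = None
    name = path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        voxel_size = tuple(info["voxel_size_um"])
        name = info.get("name") or name
        if info.get("metadata"):
            metadata = SampleMetadata.from_dict(info["metadata"])
    elif "spacing" in ij and "XResolution" in tags:
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
        voxel_size = (
            float(ij["spacing"]),
            yres[1] / yres[0],
            xres[1] / xres[0],
        )
    if voxel_size_override is not None:
        voxel_size = tuple(float(v) for v in voxel_size_override)
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel size in metadata; pass voxel_size_override=(z, y, x) in µm"
        )
    return ImageStack(data=data, voxel_size=voxel_size, metadata=metadata, name=name)


#: Fixed column order of the per-object morphometry table.
RECORD_COLUMNS = [
    "object_id",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "n_voxels",
    "volume_um3",
    "area_um2",
    "axis_a_um",
    "axis_b_um",
    "axis_c_um",
    "sphericity",
    "e_prolate",
    "e_oblate",
    "phenotype",
    "flags",
]


def write_records(records, path: str | Path) -> Path:
    """Write morphometry records as CSV with the documented column order.

    Accepts a sequence of ``MorphometryRecord`` or a DataFrame already in
    record form.  Floats are written at full repr precision so a write →
    read round trip is bit-stable.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.to_dict() for r in records])
    if df.empty:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
    df = df.reindex(columns=RECORD_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a morphometry CSV back into a DataFrame (documented columns)."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} is not a morphometry table; missing columns {sorted(missing)}")
    df["flags"] = df["flags"].fillna("")
    df["phenotype"] = df["phenotype"].fillna("")
    return df
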