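"""Image and table I/O with explicit physical metadata.

Everything in the pipeline is indexed (z, y, x) and all physical lengths are
micrometres. Voxel size is a *mandatory* input carried on every container —
the headline quantities downstream (centroid positions, inter-nuclear edge
distances, nuclear volumes) are physical distances, so a missing pixel size
is an error, never a silent assumption of 1 µm.

Masks and intensity stacks travel as TIFF; tabular results as CSV with units
embedded in the column names; configuration as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "IntensityStack",
    "RunConfig",
    "read_mask",
    "write_mask",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
]


def _coerce_voxel_size(voxel_size_um) -> tuple[float, float, float]:
    """Validate a (z, y, x) voxel size in µm.

    A 2-vector is interpreted as (y, x) for single-slice data and lifted to
    (1.0, y, x); the z pitch of a one-slice grid never enters any distance.
    """
    vs = tuple(float(v) for v in np.atleast_1d(voxel_size_um))
    if len(vs) == 2:
        vs = (1.0,) + vs
    if len(vs) != 3:
        raise ValueError(f"voxel_size_um must have 2 or 3 components, got {voxel_size_um!r}")
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size_um components must be > 0, got {vs}")
    return vs


def _lift_to_3d(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D or 3D grid, got shape {arr.shape}")
    return arr


@dataclass
class LabelMask:
    """Integer-labelled voxel grid with physical voxel size.

    Each nucleus occupies the voxels sharing one unique positive label;
    0 is reserved for background. This is the segmentation the pipeline
    consumes — producing it is upstream of this package.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    replicate_id: str = "R1"
    image_id: str = "image"

    def __post_init__(self) -> None:
        arr = _lift_to_3d(np.asarray(self.voxels))
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(
                f"label mask must have an integer dtype, got {arr.dtype}; "
                "floating-point masks are rejected rather than rounded"
            )
        if arr.size and arr.min() < 0:
            raise ValueError("label mask contains negative labels")
        self.voxels = arr
        self.voxel_size_um = _coerce_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the mask."""
        u = np.unique(self.voxels)
        return u[u > 0]


@dataclass
class IntensityStack:
    """Named co-registered intensity channels, congruent with a mask."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxel_size_um = _coerce_voxel_size(self.voxel_size_um)
        fixed: dict[str, np.ndarray] = {}
        shape = None
        for name, arr in self.channels.items():
            a = _lift_to_3d(np.asarray(arr, dtype=float))
            if a.size and a.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError(
                    f"channel {name!r} shape {a.shape} differs from {shape}"
                )
            fixed[name] = a
        self.channels = fixed

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def check_congruent(self, mask: LabelMask) -> None:
        if self.shape != mask.shape:
            raise ValueError(
                f"stack shape {self.shape} does not match mask shape {mask.shape}"
            )


@dataclass
class RunConfig:
    """Analysis-stage parameters.

    ``radius_um`` is the neighbour-retention radius applied to centroid
    distances (default 40 µm). ``thresholds`` maps replicate -> channel ->
    intensity threshold; thresholds are constant within a biological
    replicate. ``subsample_n`` optionally fixes the number of edge distances
    fed to the density estimate, for comparability across samples.
    """

    radius_um: float = 40.0
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    density_grid_points: int = 512
    bandwidth_rule: str | float = "silverman"
    subsample_n: int | None = None
    seed: int = 0
    border_policy: str = "include"

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.subsample_n is not None and self.subsample_n < 2:
            raise ValueError("subsample_n must be >= 2 or None")
        if self.border_policy not in ("include", "exclude"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if self.density_grid_points < 8:
            raise ValueError("density_grid_points must be >= 8")

    def threshold_for(self, replicate_id: str, channel: str) -> float:
        try:
            return float(self.thresholds[replicate_id][channel])
        except KeyError as exc:
            raise KeyError(
                f"no threshold configured for replicate {replicate_id!r}, "
                f"channel {channel!r}"
            ) from exc

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# TIFF I/O


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def read_mask(
    path,
    voxel_size_um=None,
    replicate_id: str | None = None,
    image_id: str | None = None,
) -> LabelMask:
    """Read a label mask from TIFF.

    Voxel size is taken from the explicit argument, or else from a JSON
    sidecar written by :func:`write_mask`. If neither is available the read
    fails: physical calibration must come from the caller, not a guess.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    meta: dict = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    if voxel_size_um is None:
        voxel_size_um = meta.get("voxel_size_um")
    if voxel_size_um is None:
        raise ValueError(
            f"no voxel size for {path}: pass voxel_size_um or provide a "
            "JSON sidecar; a 1 µm default is never assumed"
        )
    return LabelMask(
        voxels=arr,
        voxel_size_um=voxel_size_um,
        replicate_id=replicate_id or meta.get("replicate_id", "R1"),
        image_id=image_id or meta.get("image_id", path.stem),
    )


def write_mask(mask: LabelMask, path) -> Path:
    """Write a mask as TIFF plus a JSON sidecar carrying voxel size (µm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.voxels, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "voxel_size_um": list(mask.voxel_size_um),
                "replicate_id": mask.replicate_id,
                "image_id": mask.image_id,
                "axes": "zyx",
            },
            indent=2,
        )
    )
    return path


def read_stack(
    paths,
    channel_names: Sequence[str],
    voxel_size_um,
    mask: LabelMask | None = None,
) -> IntensityStack:
    """Read one or more intensity channels.

    ``paths`` is either a list of single-channel TIFFs (one per name) or a
    single TIFF whose leading axis enumerates channels. Shape congruence is
    enforced against ``mask`` when one is supplied.
    """
    channel_names = list(channel_names)
    if isinstance(paths, (str, Path)):
        data = tifffile.imread(paths)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim == 3 and len(channel_names) == 1:
            data = data[np.newaxis]
        if data.shape[0] != len(channel_names):
            raise ValueError(
                f"{paths} holds {data.shape[0]} channels but "
                f"{len(channel_names)} names were given"
            )
        arrays = [data[i] for i in range(data.shape[0])]
    else:
        paths = [Path(p) for p in paths]
        if len(paths) != len(channel_names):
            raise ValueError(
                f"{len(paths)} channel files but {len(channel_names)} names"
            )
        arrays = [tifffile.imread(p) for p in paths]
    stack = IntensityStack(
        channels=dict(zip(channel_names, arrays)), voxel_size_um=voxel_size_um
    )
    if mask is not None:
        stack.check_congruent(mask)
    return stack


def write_stack(stack: IntensityStack, directory, prefix: str = "channel") -> dict[str, Path]:
    """Write each channel as ``<prefix>_<name>.tif`` with one shared sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for name, arr in stack.channels.items():
        p = directory / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32), photometric="minisblack")
        out[name] = p
    (directory / f"{prefix}_channels.json").write_text(
        json.dumps(
            {"voxel_size_um": list(stack.voxel_size_um), "channels": stack.channel_names},
            indent=2,
        )
    )
    return out


# ---------------------------------------------------------------------------
# Tables


def write_table(records, path, columns: Sequence[str] | None = None) -> Path:
    """Write records to CSV with a deterministic column order.

    ``records`` may be a DataFrame, a list of dicts, or a list of
    dataclasses. An empty list with ``columns`` yields a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        if not rows:
            if columns is None:
                raise ValueError("empty record list requires explicit columns")
            df = pd.DataFrame(columns=list(columns))
        else:
            df = pd.DataFrame(rows)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
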