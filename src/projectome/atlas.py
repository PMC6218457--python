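"""Anatomical reference frame: label volume, region ontology, midline.

A :class:`LabelVolume` is a 3D grid of non-negative integer region ids
(0 is background / unlabeled) with voxel size and origin in micrometers.
Voxel ``(i, j, k)`` occupies the half-open physical box
``[origin + i*d, origin + (i+1)*d)`` per axis, so a point exactly on an
interior voxel boundary belongs to the higher-index voxel.

The :class:`RegionOntology` is a parent-linked region table (id, acronym,
name, parent, hemisphere, layer, fiber-tract flag) rooted at a whole-brain
region; it supports ancestor queries used to aggregate leaf regions (for
example cortical layer leaves) up to area level.

Volumes serialize to NRRD (a small reader/writer for the raw and ascii
encodings lives here) and ontologies to CSV or JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import BadFactor, IoFailure, UnknownRegion

__all__ = [
    "LabelVolume",
    "RegionOntology",
    "MidlinePlane",
    "Side",
    "region_at",
    "region_at_points",
    "hemisphere_of",
    "downsample_labels",
    "ancestors",
    "read_nrrd",
    "write_nrrd",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class Side(Enum):
    LEFT = "left"
    RIGHT = "right"
    ON_MIDLINE = "on_midline"


@dataclass(frozen=True)
class MidlinePlane:
    """An axis-aligned plane splitting the volume into hemispheres."""

    axis: str  # 'x', 'y' or 'z'
    coordinate: float  # μm

    def __post_init__(self):
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of x/y/z, got {self.axis!r}")

    @property
    def axis_index(self) -> int:
        return _AXES[self.axis]


@dataclass
class LabelVolume:
    """Voxelized region ids with physical geometry (μm)."""

    labels: np.ndarray  # (nx, ny, nz) non-negative integers
    voxel_size: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if any(s < 1 for s in self.labels.shape):
            raise ValueError("all volume dimensions must be >= 1")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent(self) -> Tuple[Tuple[float, float], ...]:
        """Physical [min, max) interval per axis, μm."""
        return tuple(
            (self.origin[a], self.origin[a] + self.labels.shape[a] * self.voxel_size[a])
            for a in range(3)
        )


def region_at_points(vol: LabelVolume, points: np.ndarray) -> np.ndarray:
    """Region ids for an (N, 3) array of μm points; 0 outside the volume."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = np.floor(
        (pts - np.asarray(vol.origin)) / np.asarray(vol.voxel_size)
    ).astype(np.int64)
    shape = np.asarray(vol.labels.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(pts), dtype=vol.labels.dtype)
    if inside.any():
        ii = idx[inside]
        out[inside] = vol.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def region_at(vol: LabelVolume, p: Sequence[float]) -> int:
    """Region id of the voxel containing ``p`` (half-open intervals); 0 outside."""
    return int(region_at_points(vol, np.asarray(p, dtype=float)[None, :])[0])


def hemisphere_of(p: Sequence[float], mid: MidlinePlane) -> Side:
    c = float(p[mid.axis_index])
    if c < mid.coordinate:
        return Side.LEFT
    if c > mid.coordinate:
        return Side.RIGHT
    return Side.ON_MIDLINE


def downsample_labels(vol: LabelVolume, factors: Tuple[int, int, int]) -> LabelVolume:
    """Majority-label block downsampling; ties break to the smallest id.

    Edge blocks may be partial.  ``voxel_size`` is multiplied by the
    factors; the origin is unchanged.
    """
    f = tuple(int(v) for v in factors)
    if any(v < 1 for v in f):
        raise BadFactor(factors)
    labels = vol.labels
    out_shape = tuple(-(-labels.shape[a] // f[a]) for a in range(3))
    pad = tuple(out_shape[a] * f[a] - labels.shape[a] for a in range(3))
    # -1 marks padding so it never wins a majority vote.
    padded = np.pad(labels, [(0, p) for p in pad], constant_values=-1)
    blocks = padded.reshape(
        out_shape[0], f[0], out_shape[1], f[1], out_shape[2], f[2]
    ).transpose(0, 2, 4, 1, 3, 5).reshape(*out_shape, -1)
    flat = blocks.reshape(-1, blocks.shape[-1])
    out = np.empty(flat.shape[0], dtype=labels.dtype)
    for i in range(flat.shape[0]):
        block = flat[i]
        block = block[block >= 0]
        vals, counts = np.unique(block, return_counts=True)
        out[i] = vals[np.argmax(counts)]  # first argmax -> smallest id on tie
    return LabelVolume(
        labels=out.reshape(out_shape),
        voxel_size=tuple(vol.voxel_size[a] * f[a] for a in range(3)),
        origin=vol.origin,
    )


# ---------------------------------------------------------------------------
# Region ontology
# ---------------------------------------------------------------------------

_ONT_COLUMNS = ["region_id", "acronym", "name", "parent_id", "hemisphere", "layer", "is_fiber_tract"]


class RegionOntology:
    """Parent-linked region table rooted at a whole-brain region.

    ``parent_id == -1`` marks the root.  ``layer`` is '' for non-layer
    regions and one of '1', '2/3', '5' for cortical layer leaves;
    ``hemisphere`` is 'left', 'right', 'bilateral' or 'na'.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        for col, default in (("hemisphere", "na"), ("layer", ""), ("is_fiber_tract", False)):
            if col not in df.columns:
                df[col] = default
        df = df[_ONT_COLUMNS].reset_index(drop=True)
        df["region_id"] = df["region_id"].astype(int)
        df["parent_id"] = df["parent_id"].astype(int)
        df["layer"] = df["layer"].fillna("").astype(str)
        df["is_fiber_tract"] = df["is_fiber_tract"].astype(bool)
        if df["region_id"].duplicated().any():
            raise ValueError("duplicate region ids in ontology")
        if df["acronym"].duplicated().any():
            raise ValueError("duplicate acronyms in ontology")
        self.table = df
        self._parent: Dict[int, int] = dict(zip(df["region_id"], df["parent_id"]))
        self._acr: Dict[int, str] = dict(zip(df["region_id"], df["acronym"]))
        self._id: Dict[str, int] = dict(zip(df["acronym"], df["region_id"]))
        self._layer: Dict[int, str] = dict(zip(df["region_id"], df["layer"]))
        # acyclicity check doubles as a parent-existence check
        for rid in self._parent:
            self.ancestors(rid)

    def __contains__(self, region_id: int) -> bool:
        return int(region_id) in self._parent

    def acronym(self, region_id: int) -> str:
        if region_id not in self:
            raise UnknownRegion(region_id)
        return self._acr[int(region_id)]

    def id_of(self, acronym: str) -> int:
        if acronym not in self._id:
            raise UnknownRegion(acronym)
        return self._id[acronym]

    def parent(self, region_id: int) -> int:
        if region_id not in self:
            raise UnknownRegion(region_id)
        return self._parent[int(region_id)]

    def ancestors(self, region_id: int) -> List[int]:
        """Ancestor ids ordered leaf→root, excluding ``region_id`` itself."""
        if region_id not in self:
            raise UnknownRegion(region_id)
        out: List[int] = []
        cur = self._parent[int(region_id)]
        seen = {int(region_id)}
        while cur != -1:
            if cur not in self._parent:
                raise UnknownRegion(cur)
            if cur in seen:
                raise ValueError(f"cycle in ontology at region {cur}")
            seen.add(cur)
            out.append(cur)
            cur = self._parent[cur]
        return out

    def layer_of(self, region_id: int) -> str:
        """Layer tag of the region or its nearest layer-typed ancestor.

        Returns '1', '2/3', '5' or 'unknown'.
        """
        if region_id not in self:
            raise UnknownRegion(region_id)
        for rid in [int(region_id)] + self.ancestors(region_id):
            if self._layer.get(rid):
                return self._layer[rid]
        return "unknown"

    def region_ids(self) -> List[int]:
        """Ids in ontology (table) order."""
        return list(self.table["region_id"])

    def map_to_level(self, region_id: int, level_ids: Sequence[int]) -> int:
        """First self-or-ancestor id contained in ``level_ids``, else 0.

        Background (0) always maps to 0.
        """
        if region_id == 0:
            return 0
        level = set(int(i) for i in level_ids)
        for rid in [int(region_id)] + self.ancestors(region_id):
            if rid in level:
                return rid
        return 0

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: Union[str, os.PathLike]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, os.PathLike]) -> "RegionOntology":
        return cls(pd.read_csv(path, keep_default_na=False, na_values=[]))

    def to_json(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            json.dump(self.table.to_dict(orient="records"), fh, indent=1)

    @classmethod
    def from_json(cls, path: Union[str, os.PathLike]) -> "RegionOntology":
        with open(path) as fh:
            return cls(pd.DataFrame(json.load(fh)))

    def __eq__(self, other):
        if not isinstance(other, RegionOntology):
            return NotImplemented
        return self.table.equals(other.table)


def ancestors(ont: RegionOntology, region_id: int) -> List[int]:
    """Module-level alias for :meth:`RegionOntology.ancestors`."""
    return ont.ancestors(region_id)


# ---------------------------------------------------------------------------
# Minimal NRRD io (raw and ascii encodings, 3D integer volumes)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "int32": np.int32,
    "int64": np.int64,
    "uint32": np.uint32,
    "int16": np.int16,
    "uint16": np.uint16,
    "uint8": np.uint8,
    "int8": np.int8,
}


def write_nrrd(vol: LabelVolume, path: Union[str, os.PathLike], encoding: str = "raw") -> None:
    """Write a label volume as NRRD with geometry in the header.

    NRRD stores the first axis fastest, so data are emitted in Fortran
    order.  ``encoding`` is 'raw' (little-endian binary) or 'ascii'.
    """
    if encoding not in ("raw", "ascii"):
        raise IoFailure(f"unsupported NRRD encoding {encoding!r}")
    arr = np.ascontiguousarray(vol.labels.astype(np.int32))
    dx, dy, dz = vol.voxel_size
    ox, oy, oz = vol.origin
    header = (
        "NRRD0004\n"
        "# label volume\n"
        "type: int32\n"
        "dimension: 3\n"
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}\n"
        f"encoding: {encoding}\n"
        "endian: little\n"
        "space dimension: 3\n"
        f"space directions: ({dx:.17g},0,0) (0,{dy:.17g},0) (0,0,{dz:.17g})\n"
        f"space origin: ({ox:.17g},{oy:.17g},{oz:.17g})\n"
        "\n"
    )
    flat = arr.flatten(order="F")
    try:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            if encoding == "raw":
                fh.write(flat.astype("<i4").tobytes())
            else:
                fh.write(" ".join(str(int(v)) for v in flat).encode("ascii"))
    except OSError as exc:
        raise IoFailure(str(exc)) from exc


def _parse_vector(text: str) -> Tuple[float, ...]:
    return tuple(float(v) for v in text.strip().lstrip("(").rstrip(")").split(","))


def read_nrrd(path: Union[str, os.PathLike]) -> LabelVolume:
    """Read a volume written by :func:`write_nrrd` (raw/ascii, 3D ints)."""
    try:
        with open(path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise IoFailure(str(exc)) from exc
    sep = data.find(b"\n\n")
    if not data.startswith(b"NRRD") or sep < 0:
        raise IoFailure(f"{path} is not a supported NRRD file")
    fields: Dict[str, str] = {}
    for line in data[:sep].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, value = line.split(":", 1)
        fields[key.strip()] = value.strip()
    sizes = tuple(int(v) for v in fields["sizes"].split())
    dtype = _NRRD_TYPES.get(fields.get("type", "int32"))
    if dtype is None:
        raise IoFailure(f"unsupported NRRD type {fields.get('type')!r}")
    encoding = fields.get("encoding", "raw")
    payload = data[sep + 2:]
    n = int(np.prod(sizes))
    if encoding == "raw":
        flat = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"), count=n)
    elif encoding in ("ascii", "text", "txt"):
        flat = np.array(payload.split(), dtype=dtype)
    else:
        raise IoFailure(f"unsupported NRRD encoding {encoding!r}")
    labels = flat.reshape(sizes, order="F")
    dirs = fields.get("space directions", "(1,0,0) (0,1,0) (0,0,1)").split(") ")
    voxel = tuple(_parse_vector(d)[a] for a, d in enumerate(dirs))
    origin = _parse_vector(fields.get("space origin", "(0,0,0)"))
    return LabelVolume(labels=labels.astype(np.int32), voxel_size=voxel, origin=origin)
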