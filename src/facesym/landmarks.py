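"""The 32-landmark facial schema and file I/O (landmark CSV/JSON, OBJ/PLY).

The canonical schema covers the soft-tissue landmarks routinely digitized in
craniofacial anthropometry, split into facial thirds (upper/middle/lower with
4/17/11 landmarks) and by laterality (10 midline landmarks plus 11 bilateral
pairs).  Coordinates are millimetres in the natural-head-position frame:
the Frankfort horizontal plane lies in the XZ plane and the facial sagittal
plane nominally in the YZ plane (x lateral, y vertical, z anterior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh as _trimesh


class Region(str, Enum):
    UPPER = "upper"
    MIDDLE = "middle"
    LOWER = "lower"


class Laterality(str, Enum):
    MIDLINE = "midline"
    LEFT = "left"
    RIGHT = "right"


class LandmarkParseError(ValueError):
    """Malformed landmark file (duplicate names, missing coordinates...)."""


class SchemaError(ValueError):
    """A landmark set does not satisfy the canonical 32-landmark schema."""


@dataclass(frozen=True)
class LandmarkDefinition:
    name: str
    region: Optional[Region] = None
    laterality: Optional[Laterality] = None
    pair_name: Optional[str] = None


# (base name, region) for the 10 midline landmarks, cranial to caudal.
_MIDLINE = [
    ("trichion", Region.UPPER),
    ("glabella", Region.UPPER),
    ("nasion", Region.MIDDLE),
    ("pronasale", Region.MIDDLE),
    ("subnasale", Region.MIDDLE),
    ("labiale_superius", Region.LOWER),
    ("labiale_inferius", Region.LOWER),
    ("sublabiale", Region.LOWER),
    ("pogonion", Region.LOWER),
    ("gnathion", Region.LOWER),
]

# (base name, region) for the 11 bilateral pairs; each contributes a
# *_right and *_left landmark.
_BILATERAL = [
    ("superciliary_ridge", Region.UPPER),
    ("endocanthion", Region.MIDDLE),
    ("exocanthion", Region.MIDDLE),
    ("pupil", Region.MIDDLE),
    ("alare", Region.MIDDLE),
    ("subalare", Region.MIDDLE),
    ("zygion", Region.MIDDLE),
    ("tragion", Region.MIDDLE),
    ("cheilion", Region.LOWER),
    ("gonion", Region.LOWER),
    ("crista_philtri", Region.LOWER),
]

# Alternate spellings accepted on read and normalized to the canonical key.
NAME_ALIASES = {"crista_philtre": "crista_philtri"}


def canonical_schema() -> tuple[LandmarkDefinition, ...]:
    """The 32 canonical landmark definitions in fixed order.

    Order: midline landmarks first (cranial to caudal), then bilateral
    pairs as right/left consecutive entries.  Counts: 10 midline + 11 pairs,
    regions 4 (upper) / 17 (middle) / 11 (lower).
    """
    defs: list[LandmarkDefinition] = [
        LandmarkDefinition(name, region, Laterality.MIDLINE)
        for name, region in _MIDLINE
    ]
    for base, region in _BILATERAL:
        right, left = f"{base}_right", f"{base}_left"
        defs.append(LandmarkDefinition(right, region, Laterality.RIGHT, pair_name=left))
        defs.append(LandmarkDefinition(left, region, Laterality.LEFT, pair_name=right))
    return tuple(defs)


CANONICAL_NAMES = tuple(d.name for d in canonical_schema())


def _normalize_name(name: str) -> str:
    key = name.strip().lower().replace(" ", "_")
    for alias, canon in NAME_ALIASES.items():
        if key.startswith(alias):
            key = key.replace(alias, canon, 1)
    return key


class LandmarkSet:
    """Ordered collection of named 3D landmarks (positions in mm).

    Canonical sets carry the 32-landmark schema; arbitrary named sets are
    allowed for generic geometry work (``definitions`` then typically have
    no region/laterality).
    """

    def __init__(self, definitions: Sequence[LandmarkDefinition], positions):
        self.definitions = tuple(definitions)
        pos = np.asarray(positions, dtype=float)
        if pos.shape != (len(self.definitions), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.definitions)} definitions"
            )
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            raise LandmarkParseError("duplicate landmark names")
        self.positions = pos.copy()
        self._index = {n: i for i, n in enumerate(names)}

    # -- basic access -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.definitions)

    def __len__(self) -> int:
        return len(self.definitions)

    def position_of(self, name: str) -> np.ndarray:
        return self.positions[self._index[name]]

    def with_positions(self, positions) -> "LandmarkSet":
        return LandmarkSet(self.definitions, positions)

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        idx = [self._index[n] for n in names]
        return LandmarkSet([self.definitions[i] for i in idx], self.positions[idx])

    # -- canonical schema ---------------------------------------------
    @classmethod
    def from_named_positions(cls, mapping: dict, strict: bool = True) -> "LandmarkSet":
        """Build a canonical-schema set from a {name: xyz} mapping."""
        normalized = {_normalize_name(k): v for k, v in mapping.items()}
        missing = [n for n in CANONICAL_NAMES if n not in normalized]
        if missing:
            raise SchemaError(f"missing canonical landmarks: {', '.join(missing)}")
        extra = set(normalized) - set(CANONICAL_NAMES)
        if strict and extra:
            raise SchemaError(f"unknown landmarks under strict schema: {sorted(extra)}")
        positions = [normalized[n] for n in CANONICAL_NAMES]
        return cls(canonical_schema(), positions)

    def is_canonical(self) -> bool:
        return self.names == CANONICAL_NAMES

    def require_canonical(self) -> None:
        if not self.is_canonical():
            raise SchemaError("operation requires the canonical 32-landmark schema")

    def partition(self, region: Region | str) -> "LandmarkSet":
        """Subset of one facial third (upper=4, middle=17, lower=11)."""
        self.require_canonical()
        region = Region(region)
        keep = [i for i, d in enumerate(self.definitions) if d.region == region]
        return LandmarkSet([self.definitions[i] for i in keep], self.positions[keep])

    def midline(self) -> "LandmarkSet":
        self.require_canonical()
        keep = [i for i, d in enumerate(self.definitions)
                if d.laterality == Laterality.MIDLINE]
        return LandmarkSet([self.definitions[i] for i in keep], self.positions[keep])

    def bilateral_pairs(self) -> list[tuple[str, str]]:
        """(right_name, left_name) for the 11 bilateral pairs, in order."""
        self.require_canonical()
        return [(f"{b}_right", f"{b}_left") for b, _ in _BILATERAL]


def read_landmarks(path, format: Optional[str] = None, strict: bool = False) -> LandmarkSet:
    """Read landmarks from CSV (name,x,y,z header) or JSON.

    With ``strict=True`` the file must contain exactly the canonical schema
    (aliases accepted); otherwise a generic named set is returned, with
    canonical definitions attached when all names match.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise LandmarkParseError(f"CSV must have columns name,x,y,z; got {list(df.columns)}")
        if df[["x", "y", "z"]].isna().any().any():
            bad = df.index[df[["x", "y", "z"]].isna().any(axis=1)][0]
            raise LandmarkParseError(f"missing coordinate in row {bad} ({df.loc[bad, 'name']!r})")
        names = [str(n) for n in df["name"]]
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    elif fmt == "json":
        records = json.loads(path.read_text())
        names, coords_list = [], []
        for i, rec in enumerate(records):
            if "name" not in rec or "xyz" not in rec or len(rec["xyz"]) != 3:
                raise LandmarkParseError(f"record {i} must have 'name' and 3-element 'xyz'")
            names.append(str(rec["name"]))
            coords_list.append([float(v) for v in rec["xyz"]])
        coords = np.asarray(coords_list, dtype=float)
    else:
        raise ValueError(f"unsupported landmark format {fmt!r}")

    norm = [_normalize_name(n) for n in names]
    if len(set(norm)) != len(norm):
        dupes = sorted({n for n in norm if norm.count(n) > 1})
        raise LandmarkParseError(f"duplicate landmark names: {dupes}")
    if strict or set(norm) == set(CANONICAL_NAMES):
        return LandmarkSet.from_named_positions(dict(zip(norm, coords)), strict=strict)
    defs = [LandmarkDefinition(n) for n in norm]
    return LandmarkSet(defs, coords)


def write_landmarks(lms: LandmarkSet, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.DataFrame({
            "name": list(lms.names),
            "x": lms.positions[:, 0],
            "y": lms.positions[:, 1],
            "z": lms.positions[:, 2],
        })
        df.to_csv(path, index=False, float_format="%.9f")
    elif fmt == "json":
        records = [{"name": n, "xyz": [float(v) for v in p]}
                   for n, p in zip(lms.names, lms.positions)]
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unsupported landmark format {fmt!r}")


# ---------------------------------------------------------------------------
# Triangle meshes


class MeshParseError(ValueError):
    pass


@dataclass(frozen=True, eq=False)
class TriMesh:
    """Triangle surface mesh: vertices (N×3 mm) and faces (M×3, 0-based)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be N×3")
        if f.size and (f.ndim != 2 or f.shape[1] != 3):
            raise ValueError("faces must be M×3 triangles")
        f = f.reshape(-1, 3)
        if f.size:
            if f.min() < 0 or f.max() >= len(v):
                raise MeshParseError("face index out of range")
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise MeshParseError("degenerate face with repeated vertex index")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def with_vertices(self, vertices) -> "TriMesh":
        return TriMesh(vertices, self.faces)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def read_mesh(path) -> TriMesh:
    """Read an OBJ or PLY surface (normals/texture ignored; faces triangulated)."""
    path = Path(path)
    try:
        loaded = _trimesh.load(str(path), process=False, maintain_order=True,
                               force="mesh")
    except Exception as exc:  # loader errors become parse errors
        raise MeshParseError(f"cannot read mesh {path.name}: {exc}") from exc
    return TriMesh(np.asarray(loaded.vertices, dtype=float),
                   np.asarray(loaded.faces, dtype=np.int64))


def write_mesh(mesh: TriMesh, path) -> None:
    path = Path(path)
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if path.suffix.lower() == ".ply" else {}
    tm.export(str(path), **kwargs)
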