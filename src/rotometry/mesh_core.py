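"""Triangle-mesh data model, STL I/O, and tooth-submesh extraction.

Arch models travel as STL (ASCII or little-endian binary); per-vertex tooth
labels and landmark points travel in sidecar JSON because STL itself carries
no attributes.  All coordinates are millimetres in a right-handed frame.
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    InvalidInputError,
    InvalidSegmentationError,
    MeshFormatError,
    NotFoundError,
)

#: Welding tolerance for duplicate STL vertices, in mm.
WELD_TOL_MM = 1e-6

#: The seven crown types handled by the landmark scheme.
TOOTH_TYPES = (
    "central_incisor",
    "lateral_incisor",
    "canine",
    "first_premolar",
    "second_premolar",
    "first_molar",
    "second_molar",
)

#: FDI second digit -> tooth type.
_FDI_DIGIT_TO_TYPE = {i + 1: t for i, t in enumerate(TOOTH_TYPES)}

#: Ordered landmark roles (vector tail, vector head) per tooth type.
LANDMARK_ROLES = {
    "central_incisor": ("mesial-point", "distal-point"),
    "lateral_incisor": ("mesial-point", "distal-point"),
    "canine": ("mesial-point", "distal-point"),
    "first_premolar": ("buccal-cusp", "lingual-cusp"),
    "second_premolar": ("buccal-cusp", "lingual-cusp"),
    "first_molar": ("disto-vestibular-cusp", "mesio-lingual-cusp"),
    "second_molar": ("disto-vestibular-cusp", "mesio-lingual-cusp"),
}


def tooth_type_for_fdi(fdi: int) -> str:
    """Return the tooth type implied by an FDI code (e.g. 36 -> first_molar)."""
    if not (11 <= fdi <= 48) or not (1 <= fdi % 10 <= 7) or not (1 <= fdi // 10 <= 4):
        raise InvalidInputError(f"FDI code {fdi} outside the supported 11-47 range")
    return _FDI_DIGIT_TO_TYPE[fdi % 10]


@dataclass
class TriangleMesh:
    """An indexed triangle surface: ``vertices`` (n, 3) float64, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 3:
            raise InvalidInputError("mesh needs at least 3 vertices of dimension 3")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) < 1:
            raise InvalidInputError("mesh needs at least one triangular face")
        if not np.isfinite(v).all():
            raise InvalidInputError("mesh has non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise InvalidInputError("face index out of vertex range")
        if (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise InvalidInputError("face with repeated vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class ToothLabelMap:
    """Vertex -> FDI assignment plus the FDI -> tooth-type table.

    ``assignments`` maps each labeled FDI code to the array of vertex indices
    carrying that label; unlisted vertices are background.
    """

    assignments: dict[int, np.ndarray]
    tooth_type: dict[int, str]

    def __post_init__(self):
        self.assignments = {
            int(k): np.asarray(v, dtype=np.int64) for k, v in self.assignments.items()
        }
        self.tooth_type = {int(k): str(v) for k, v in self.tooth_type.items()}
        for fdi in self.assignments:
            expected = tooth_type_for_fdi(fdi)
            declared = self.tooth_type.get(fdi)
            if declared is None:
                raise InvalidInputError(f"tooth {fdi} has labels but no tooth type")
            if declared != expected:
                raise InvalidInputError(
                    f"tooth {fdi} declared {declared!r}, FDI digit implies {expected!r}"
                )

    @property
    def teeth(self) -> list[int]:
        return sorted(self.assignments)

    def check_against(self, mesh: TriangleMesh) -> None:
        for fdi, idx in self.assignments.items():
            if len(idx) and idx.max() >= mesh.n_vertices:
                raise InvalidInputError(
                    f"label for tooth {fdi} references vertex {idx.max()} "
                    f"beyond mesh size {mesh.n_vertices}"
                )

    def to_json_dict(self) -> dict:
        return {
            "tooth_labels": {str(k): v.tolist() for k, v in self.assignments.items()},
            "tooth_types": {str(k): v for k, v in self.tooth_type.items()},
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ToothLabelMap":
        return cls(
            assignments={int(k): np.asarray(v) for k, v in d["tooth_labels"].items()},
            tooth_type={int(k): v for k, v in d["tooth_types"].items()},
        )


@dataclass
class Landmark:
    """A named point on a tooth crown at one timepoint."""

    tooth: int
    role: str
    position: np.ndarray
    frame: str = "T0"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.position.shape != (3,) or not np.isfinite(self.position).all():
            raise InvalidInputError("landmark position must be a finite 3-vector")
        admissible = LANDMARK_ROLES[tooth_type_for_fdi(self.tooth)]
        if self.role not in admissible:
            raise InvalidInputError(
                f"role {self.role!r} not admissible for tooth {self.tooth} "
                f"(expected one of {admissible})"
            )


def landmarks_to_json(landmarks: Iterable[Landmark]) -> list[dict]:
    return [
        {"tooth": lm.tooth, "role": lm.role, "xyz": lm.position.tolist(), "frame": lm.frame}
        for lm in landmarks
    ]


def landmarks_from_json(items: Iterable[Mapping]) -> list[Landmark]:
    return [
        Landmark(int(d["tooth"]), d["role"], np.asarray(d["xyz"]), d.get("frame", "T0"))
        for d in items
    ]


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

_ASCII_FLOAT = r"[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?"
_VERTEX_RE = re.compile(
    rf"vertex\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})\s+({_ASCII_FLOAT})"
)


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices that coincide within ``tol``; keep first-occurrence order.

    Degenerate faces produced by the merge are dropped.
    """
    keys = np.round(np.asarray(vertices, dtype=np.float64) / tol).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    # Renumber unique groups by first occurrence so vertex order is stable.
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    new_vertices = vertices[first[order]]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[keep]


def _read_stl_binary(raw: bytes, path: Path) -> TriangleMesh:
    if len(raw) < 84:
        raise MeshFormatError(
            f"{path}: binary STL truncated at byte {len(raw)} (header needs 84 bytes)"
        )
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) != expected:
        raise MeshFormatError(
            f"{path}: facet count {count} implies {expected} bytes, file has "
            f"{len(raw)} (mismatch at byte offset {min(len(raw), expected)})"
        )
    if count == 0:
        raise InvalidInputError(f"{path}: STL contains no facets")
    rec = np.frombuffer(
        raw,
        dtype=np.dtype(
            [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        ),
        count=count,
        offset=84,
    )
    tri = rec["v"].astype(np.float64).reshape(-1, 3)
    faces = np.arange(len(tri), dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(*weld_vertices(tri, faces))


def _read_stl_ascii(text: str, path: Path) -> TriangleMesh:
    if "endsolid" not in text:
        raise MeshFormatError(f"{path}: ASCII STL missing 'endsolid' terminator")
    n_facets = text.count("facet normal")
    coords = _VERTEX_RE.findall(text)
    if len(coords) != 3 * n_facets:
        raise MeshFormatError(
            f"{path}: {n_facets} facets declared but {len(coords)} vertex lines found "
            f"(expected {3 * n_facets})"
        )
    if n_facets == 0:
        raise InvalidInputError(f"{path}: STL contains no facets")
    tri = np.array(coords, dtype=np.float64)
    faces = np.arange(len(tri), dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(*weld_vertices(tri, faces))


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file, welding duplicate vertices."""
    path = Path(path)
    if not path.exists():
        raise NotFoundError(f"STL file not found: {path}")
    raw = path.read_bytes()
    if len(raw) == 0:
        raise MeshFormatError(f"{path}: empty file")
    # ASCII files start with 'solid' AND contain textual facet records; some
    # binary exporters also start with 'solid', so require both.
    head = raw[:512].lstrip()
    if head.startswith(b"solid"):
        try:
            text = raw.decode("ascii")
        except UnicodeDecodeError:
            text = None
        if text is not None and ("facet" in text or "endsolid" in text):
            return _read_stl_ascii(text, path)
    return _read_stl_binary(raw, path)


def write_stl(mesh: TriangleMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` to ``path``; normals are recomputed from vertex winding."""
    mesh.validate()
    path = Path(path)
    tri = mesh.triangles()
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    if mode == "binary":
        rec = np.zeros(
            mesh.n_faces,
            dtype=np.dtype(
                [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            ),
        )
        rec["normal"] = normals.astype(np.float32)
        rec["v"] = tri.astype(np.float32)
        with open(path, "wb") as fh:
            fh.write(b"rotometry binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(rec.tobytes())
    elif mode == "ascii":
        lines = ["solid rotometry"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid rotometry\n")
        path.write_text("\n".join(lines))
    else:
        raise InvalidInputError(f"unknown STL mode {mode!r} (use 'ascii' or 'binary')")


# ---------------------------------------------------------------------------
# Submesh extraction
# ---------------------------------------------------------------------------


def extract_tooth_submesh(
    mesh: TriangleMesh, labels: ToothLabelMap, tooth: int
) -> TriangleMesh:
    """Return the reindexed submesh of faces fully labeled with ``tooth``.

    Faces with mixed labels are excluded (conservative boundary handling);
    vertex positions are carried over unchanged from the parent mesh.
    """
    if tooth not in labels.assignments:
        raise NotFoundError(f"tooth {tooth} not present in label map")
    labels.check_against(mesh)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[labels.assignments[tooth]] = True
    face_mask = mask[mesh.faces].all(axis=1)
    if not face_mask.any():
        raise InvalidSegmentationError(f"tooth {tooth} label yields an empty submesh")
    faces = mesh.faces[face_mask]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces])


def tooth_vertex_indices(labels: ToothLabelMap, tooth: int) -> np.ndarray:
    """Parent-mesh vertex indices labeled with ``tooth``."""
    if tooth not in labels.assignments:
        raise NotFoundError(f"tooth {tooth} not present in label map")
    return labels.assignments[tooth]


def save_labels(labels: ToothLabelMap, path) -> None:
    Path(path).write_text(json.dumps(labels.to_json_dict()))


def load_labels(path) -> ToothLabelMap:
    return ToothLabelMap.from_json_dict(json.loads(Path(path).read_text()))
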