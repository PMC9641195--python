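"""Triangle-mesh data model, STL input/output and validity diagnostics.

Chamber surfaces travel as STL (stereolithography) files: an unstructured
list of triangles, each stored with its own three vertex coordinates and a
facet normal.  Both the ASCII and the little-endian binary dialect are
supported.  On read, identical vertex positions are merged into a shared,
indexed vertex table so that topological diagnostics (watertightness,
orientation consistency) are meaningful; stored facet normals are discarded
because the signed-volume convention used downstream derives orientation
solely from the vertex winding.

Coordinates are interpreted as millimetres throughout the package.
"""

from __future__ import annotations

import io
import os
import struct
from dataclasses import dataclass
from typing import BinaryIO, Union

import numpy as np

__all__ = [
    "TriangleMesh",
    "MeshDiagnostics",
    "STLParseError",
    "read_stl",
    "write_stl",
    "diagnose",
]

_BINARY_RECORD_DTYPE = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


class STLParseError(ValueError):
    """Malformed STL input (truncated record, bad token, count mismatch)."""


@dataclass(frozen=True)
class MeshDiagnostics:
    """Topological validity flags for a triangle mesh.

    A mesh that is both watertight (every edge shared by exactly two faces)
    and orientation-consistent (the two faces sharing an edge traverse it in
    opposite directions) bounds a region of space and has a well-defined
    signed volume.
    """

    is_watertight: bool
    is_orientation_consistent: bool
    n_degenerate_faces: int
    n_duplicate_vertices: int

    @property
    def is_closed(self) -> bool:
        """True when the enclosed signed volume is well defined."""
        return self.is_watertight and self.is_orientation_consistent

    def as_dict(self) -> dict:
        return {
            "is_watertight": bool(self.is_watertight),
            "is_orientation_consistent": bool(self.is_orientation_consistent),
            "n_degenerate_faces": int(self.n_degenerate_faces),
            "n_duplicate_vertices": int(self.n_duplicate_vertices),
        }


class TriangleMesh:
    """Indexed triangle surface in millimetre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Vertex index triples.  The winding order is significant: it defines
        the facet orientation used for signed-volume computation.
    name : str
        Free-text label (carried into STL headers).
    """

    def __init__(self, vertices, faces, name: str = ""):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {vertices.shape}")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {faces.shape}")
        if not np.all(np.isfinite(vertices)):
            raise ValueError("vertex coordinates must be finite")
        if faces.size:
            if faces.min() < 0 or faces.max() >= len(vertices):
                raise ValueError("face index out of range")
            if (
                (faces[:, 0] == faces[:, 1])
                | (faces[:, 1] == faces[:, 2])
                | (faces[:, 0] == faces[:, 2])
            ).any():
                raise ValueError("face repeats a vertex index")
        self.vertices = vertices
        self.faces = faces
        self.name = name

    # -- basic geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of per-face vertex coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, unit: bool = True) -> np.ndarray:
        """Facet normals recomputed from winding (right-hand rule)."""
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if unit:
            norms = np.linalg.norm(n, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                n = np.where(norms[:, None] > 0, n / norms[:, None], 0.0)
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(unit=False), axis=1)

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces, self.name)

    def scaled(self, s: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * float(s), self.faces, self.name)

    def flipped(self) -> "TriangleMesh":
        """Reverse the winding of every face (negates the signed volume)."""
        return TriangleMesh(self.vertices, self.faces[:, ::-1], self.name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TriangleMesh(n_vertices={self.n_vertices}, n_faces={self.n_faces}, "
            f"name={self.name!r})"
        )


# ---------------------------------------------------------------------------
# STL reading
# ---------------------------------------------------------------------------


def _merge_vertices(tri_vertices: np.ndarray, tolerance: float | None):
    """Collapse the triangle-soup vertex stream into an indexed table.

    Positions are merged by exact bitwise equality by default, or within
    ``tolerance`` when given (coordinates quantised to the tolerance grid).
    The vertex order is the order of first occurrence in the facet stream.
    """
    flat = tri_vertices.reshape(-1, 3)
    if tolerance is not None and tolerance > 0:
        keys = np.round(flat / tolerance).astype(np.int64)
    else:
        keys = flat
    _, first_idx, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    # np.unique sorts; remap so vertices appear in first-occurrence order
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = flat[first_idx[order]]
    faces = rank[inverse].reshape(-1, 3)
    return vertices, faces


def _parse_binary(data: bytes, name: str, tolerance):
    if len(data) < 84:
        raise STLParseError(
            f"truncated binary STL: header+count need 84 bytes, file has {len(data)}"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) < expected:
        n_complete = (len(data) - 84) // 50
        raise STLParseError(
            f"binary STL declares {count} facets but ends at byte {len(data)} "
            f"(expected {expected}; only {n_complete} complete 50-byte records)"
        )
    records = np.frombuffer(data, dtype=_BINARY_RECORD_DTYPE, count=count, offset=84)
    tri = records["vertices"].astype(np.float64)
    if not np.all(np.isfinite(tri)):
        raise STLParseError("binary STL contains non-finite vertex coordinates")
    header = data[:80].split(b"\x00", 1)[0].decode("ascii", errors="replace").strip()
    vertices, faces = _merge_vertices(tri, tolerance)
    return TriangleMesh(vertices, faces, name or header)


def _parse_ascii(text: str, name: str, tolerance):
    tri_rows: list[list[float]] = []
    solid_name = ""
    saw_solid = saw_endsolid = False
    pending: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        kw = tokens[0].lower()
        if kw == "solid":
            saw_solid = True
            solid_name = " ".join(tokens[1:])
        elif kw == "vertex":
            if len(tokens) != 4:
                raise STLParseError(
                    f"line {lineno}: vertex needs 3 coordinates, got {len(tokens) - 1}"
                )
            try:
                pending.extend(float(t) for t in tokens[1:])
            except ValueError as exc:
                raise STLParseError(
                    f"line {lineno}: non-numeric ASCII token in {raw.strip()!r}"
                ) from exc
        elif kw == "endfacet":
            if len(pending) != 9:
                raise STLParseError(
                    f"line {lineno}: facet closed with {len(pending) // 3} vertices, "
                    "expected 3"
                )
            tri_rows.append(pending)
            pending = []
        elif kw == "endsolid":
            saw_endsolid = True
        elif kw in ("facet", "outer", "endloop"):
            continue
        else:
            raise STLParseError(f"line {lineno}: unexpected token {tokens[0]!r}")
    if not saw_solid:
        raise STLParseError("ASCII STL missing 'solid' header")
    if not saw_endsolid:
        raise STLParseError("ASCII STL missing 'endsolid' (truncated file?)")
    if pending:
        raise STLParseError("ASCII STL ends inside an open facet")
    tri = np.array(tri_rows, dtype=np.float64).reshape(-1, 3, 3) if tri_rows else np.zeros((0, 3, 3))
    vertices, faces = _merge_vertices(tri, tolerance) if len(tri) else (np.zeros((0, 3)), np.zeros((0, 3), int))
    return TriangleMesh(vertices, faces, name or solid_name)


def _looks_ascii(data: bytes) -> bool:
    head = data[:512].lstrip()
    if not head.startswith(b"solid"):
        return False
    # A binary file may also start with "solid"; a genuine ASCII body must
    # contain a "facet" keyword (or be an empty solid with "endsolid").
    try:
        probe = data.decode("ascii")
    except UnicodeDecodeError:
        return False
    return "endsolid" in probe


def read_stl(
    source: Union[str, os.PathLike, bytes, BinaryIO],
    dialect: str = "auto",
    merge_tolerance: float | None = None,
) -> TriangleMesh:
    """Read an STL file (ASCII or binary) into a :class:`TriangleMesh`.

    Parameters
    ----------
    source
        File path, raw bytes, or a binary file object.
    dialect
        ``"auto"`` (default) inspects the content: a file starting with a
        valid ASCII ``solid`` structure is parsed as ASCII, anything else as
        little-endian binary.  ``"ascii"``/``"binary"`` force a dialect.
    merge_tolerance
        Optional epsilon for vertex merging.  By default positions are merged
        only on exact bitwise equality; STL stores each triangle's vertices
        independently, and shared topology is needed only for diagnostics,
        not for volume computation.

    Raises
    ------
    STLParseError
        On truncated binary records, facet-count mismatch, or non-numeric
        ASCII tokens; the message names the offending byte or line offset.
    """
    name = ""
    if isinstance(source, bytes):
        data = source
    elif hasattr(source, "read"):
        data = source.read()
    else:
        name = os.path.splitext(os.path.basename(os.fspath(source)))[0]
        with open(source, "rb") as fh:
            data = fh.read()

    if dialect == "auto":
        dialect = "ascii" if _looks_ascii(data) else "binary"
    if dialect == "ascii":
        try:
            text = data.decode("ascii")
        except UnicodeDecodeError as exc:
            raise STLParseError(f"not ASCII STL: undecodable byte at offset {exc.start}") from exc
        return _parse_ascii(text, name, merge_tolerance)
    if dialect == "binary":
        return _parse_binary(data, name, merge_tolerance)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# STL writing
# ---------------------------------------------------------------------------


def write_stl(
    mesh: TriangleMesh,
    target: Union[str, os.PathLike, BinaryIO],
    dialect: str = "binary",
) -> None:
    """Write *mesh* to *target* in the requested STL dialect.

    Facet normals are recomputed from the vertex winding (unit length, zero
    for degenerate triangles).  A binary file is exactly
    ``80 + 4 + 50 * n_faces`` bytes.
    """
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    tri = mesh.triangles()
    normals = mesh.face_normals(unit=True)

    if dialect == "binary":
        records = np.zeros(mesh.n_faces, dtype=_BINARY_RECORD_DTYPE)
        records["normal"] = normals.astype(np.float32)
        records["vertices"] = tri.astype(np.float32)
        header = (mesh.name or "ventrivol").encode("ascii", errors="replace")[:80]
        payload = header.ljust(80, b"\x00") + struct.pack("<I", mesh.n_faces) + records.tobytes()
        _write_bytes(target, payload)
        return

    buf = io.StringIO()
    solid = mesh.name or "ventrivol"
    buf.write(f"solid {solid}\n")
    for n, t in zip(normals, tri):
        buf.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
        buf.write("    outer loop\n")
        for v in t:
            buf.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
        buf.write("    endloop\n")
        buf.write("  endfacet\n")
    buf.write(f"endsolid {solid}\n")
    _write_bytes(target, buf.getvalue().encode("ascii"))


def _write_bytes(target, payload: bytes) -> None:
    if hasattr(target, "write"):
        target.write(payload)
    else:
        with open(target, "wb") as fh:
            fh.write(payload)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def diagnose(mesh: TriangleMesh, merge_tolerance: float | None = None) -> MeshDiagnostics:
    """Compute topological validity flags for *mesh*.

    Watertight means every undirected edge is shared by exactly two faces.
    Orientation-consistent means no directed edge is traversed twice in the
    same direction, i.e. the two faces sharing an edge wind it oppositely.
    Both flags together guarantee a well-defined signed volume.

    The result is invariant under vertex renumbering and face reordering.
    """
    faces = mesh.faces
    if len(faces) == 0:
        return MeshDiagnostics(False, True, 0, _count_duplicates(mesh.vertices, merge_tolerance))

    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    undirected = np.sort(directed, axis=1)
    _, und_counts = np.unique(undirected, axis=0, return_counts=True)
    is_watertight = bool(np.all(und_counts == 2))
    _, dir_counts = np.unique(directed, axis=0, return_counts=True)
    # every directed edge unique and no undirected edge shared >2 times
    is_consistent = bool(np.all(dir_counts == 1) and np.all(und_counts <= 2))

    areas = mesh.face_areas()
    scale = float(np.abs(mesh.vertices).max()) if mesh.n_vertices else 1.0
    n_degenerate = int(np.sum(areas <= 1e-12 * max(scale, 1.0) ** 2))

    return MeshDiagnostics(
        is_watertight=is_watertight,
        is_orientation_consistent=is_consistent,
        n_degenerate_faces=n_degenerate,
        n_duplicate_vertices=_count_duplicates(mesh.vertices, merge_tolerance),
    )


def _count_duplicates(vertices: np.ndarray, tolerance: float | None) -> int:
    if len(vertices) == 0:
        return 0
    if tolerance is not None and tolerance > 0:
        keys = np.round(vertices / tolerance).astype(np.int64)
    else:
        keys = vertices
    n_unique = len(np.unique(keys, axis=0))
    return int(len(vertices) - n_unique)
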