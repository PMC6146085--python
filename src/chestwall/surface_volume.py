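"""Chest-wall surface construction and divergence-theorem volumes.

The anterior marker grid is triangulated row by row and closed onto a
horizontal bed plane (supine acquisition: only the anterior surface is
measured, so absolute volumes are convention-dependent while volume
*variations* — the physiologically meaningful quantity — are not).  The
volume enclosed by a closed, consistently oriented triangle mesh follows
from the divergence theorem:

    V = (1/6) * sum over faces of  v0 . (v1 x v2)

Three chest-wall compartments are delimited by transverse marker rows:
pulmonary ribcage (clavicles to xiphisternum), abdominal ribcage
(xiphisternum to lower costal margin) and abdomen (costal margin to pubis).
Each compartment is closed by vertical cut surfaces through its boundary
rows, so the three compartment volumes sum to the total chest-wall volume
exactly (shared cut walls cancel in the sum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError, TopologyError
from .marker_model import MarkerLayout, TrajectorySet

__all__ = [
    "SurfaceModel",
    "CompartmentSeries",
    "build_surface",
    "enclosed_volume",
    "compartment_volumes",
    "export_obj",
]

M3_TO_L = 1000.0

COMPARTMENTS = ("pulmonary_ribcage", "abdominal_ribcage", "abdomen")


@dataclass
class SurfaceModel:
    """Closed triangle mesh with per-face compartment tags.

    ``vertices`` is (n, 3) in meters; ``faces`` is (m, 3) vertex indices with
    consistent outward winding; ``compartment_tag`` labels each face as one
    of the three compartments (anterior faces) or ``"closure"`` (bed panel,
    skirt and cut walls).
    """

    vertices: np.ndarray
    faces: np.ndarray
    compartment_tag: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.faces = np.asarray(self.faces, int)
        self.compartment_tag = np.asarray(self.compartment_tag, object)
        if self.faces.shape[0] != self.compartment_tag.shape[0]:
            raise ValueError("one tag per face required")

    def euler_characteristic(self) -> int:
        edges = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        n_edges = len(np.unique(edges, axis=0))
        n_verts = len(np.unique(self.faces))
        return n_verts - n_edges + len(self.faces)

    def is_closed(self) -> bool:
        """True iff every undirected edge is used by exactly two faces, once
        in each direction (closed, consistently oriented)."""
        directed = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        und, counts = np.unique(np.sort(directed, axis=1), axis=0, return_counts=True)
        if not (counts == 2).all():
            return False
        # consistent orientation: no directed edge repeats
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        return bool((dcounts == 1).all())


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------


def _grid_positions(frame: np.ndarray, layout: MarkerLayout) -> np.ndarray:
    """(rows, cols, 3) marker positions ordered by the layout grid."""
    idx = layout.grid_indices()
    if (idx < 0).any():
        raise GeometryError("layout grid has empty cells")
    P = np.asarray(frame, float)[idx]
    if not np.isfinite(P).all():
        raise GeometryError("invalid (NaN) marker positions in frame")
    return P


def _check_geometry(P: np.ndarray) -> None:
    rows, cols, _ = P.shape
    flat = P.reshape(-1, 3)
    d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        raise GeometryError("degenerate geometry: coincident marker positions")
    row_y = P[:, :, 1].mean(axis=1)
    if not (np.diff(row_y) < 0).all():
        raise GeometryError(
            "non-monotonic row ordering: rows must run cranio-caudally "
            "(decreasing longitudinal coordinate)"
        )


def _band_faces(
    P: np.ndarray,
    idx_top: np.ndarray,
    r0: int,
    r1: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate one grid band (rows r0..r1) and its bed closure.

    Returns (anterior_faces, closure_faces) as index triples into the
    vertex array [anterior markers, projected markers] where projected
    marker i has index i + n_markers.
    """
    rows, cols, _ = P.shape
    n = rows * cols
    idx_bot = idx_top + n
    anterior: list[tuple[int, int, int]] = []
    closure: list[tuple[int, int, int]] = []
    for r in range(r0, r1):
        for c in range(cols - 1):
            a, b = idx_top[r, c], idx_top[r, c + 1]
            cc, d = idx_top[r + 1, c], idx_top[r + 1, c + 1]
            # shorter diagonal; tie -> cranial-left diagonal (a--d)
            l_ad = np.linalg.norm(P.reshape(-1, 3)[a] - P.reshape(-1, 3)[d % n])
            l_bc = np.linalg.norm(P.reshape(-1, 3)[b] - P.reshape(-1, 3)[cc % n])
            if l_ad <= l_bc:
                tris = [(a, cc, d), (a, d, b)]
            else:
                tris = [(a, cc, b), (b, cc, d)]
            anterior.extend(tris)
            # mirrored bed panel, reversed winding
            for t0, t1, t2 in tris:
                closure.append((t0 + n, t2 + n, t1 + n))
    # boundary loop of the band, counter-clockwise viewed from +z:
    # caudal row left->right, right column caudal->cranial,
    # cranial row right->left, left column cranial->caudal.
    loop: list[int] = []
    loop += [idx_top[r1, c] for c in range(cols)]            # caudal edge, +x
    loop += [idx_top[r, cols - 1] for r in range(r1 - 1, r0 - 1, -1)]
    loop += [idx_top[r0, c] for c in range(cols - 2, -1, -1)]
    loop += [idx_top[r, 0] for r in range(r0 + 1, r1)]
    for u, v in zip(loop, loop[1:] + loop[:1]):
        closure.append((v, u, u + n))
        closure.append((v, u + n, v + n))
    return np.array(anterior, int), np.array(closure, int)


def _band_bounds(layout: MarkerLayout) -> dict[str, tuple[int, int]]:
    xiph = layout.row_index("xiphisternal_row")
    costal = layout.row_index("lower_costal_row")
    last = layout.n_rows - 1
    return {
        "pulmonary_ribcage": (0, xiph),
        "abdominal_ribcage": (xiph, costal),
        "abdomen": (costal, last),
    }


def build_surface(
    frame: np.ndarray,
    layout: MarkerLayout,
    closure: str = "bed_plane",
    bed_offset: float = 0.01,
    bed_z: float | None = None,
) -> SurfaceModel:
    """Build the closed chest-wall surface for one frame.

    The anterior grid is triangulated quad by quad using the shorter
    diagonal (ties toward the cranial-left diagonal), then closed by
    projecting every marker onto the bed plane (``min z - bed_offset``
    unless *bed_z* is given) and triangulating the bed panel and the
    perimeter skirt.  Faces are wound outward; if the signed volume comes
    out negative all faces are flipped.
    """
    if closure != "bed_plane":
        raise ValueError(f"unknown closure strategy {closure!r}")
    P = _grid_positions(frame, layout)
    _check_geometry(P)
    rows, cols, _ = P.shape
    n = rows * cols
    z0 = float(P[:, :, 2].min() - bed_offset) if bed_z is None else float(bed_z)
    proj = P.reshape(-1, 3).copy()
    proj[:, 2] = z0
    vertices = np.vstack([P.reshape(-1, 3), proj])
    idx_top = np.arange(n).reshape(rows, cols)
    bounds = _band_bounds(layout)

    faces: list[np.ndarray] = []
    tags: list[np.ndarray] = []
    # anterior faces per compartment band, closure from the full-grid band
    for comp in COMPARTMENTS:
        r0, r1 = bounds[comp]
        ant, _ = _band_faces(P, idx_top, r0, r1)
        faces.append(ant)
        tags.append(np.full(len(ant), comp, object))
    _, clos = _band_faces(P, idx_top, 0, rows - 1)
    faces.append(clos)
    tags.append(np.full(len(clos), "closure", object))
    F = np.vstack(faces)
    T = np.concatenate(tags)
    model = SurfaceModel(vertices, F, T)
    if _signed_volume_m3(vertices, F) < 0:
        model.faces = F[:, ::-1]
    return model


def _signed_volume_m3(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)


def enclosed_volume(s: SurfaceModel) -> float:
    """Volume enclosed by a closed oriented mesh, in liters.

    Divergence theorem: V = (1/6) sum_faces v0 . (v1 x v2), positive for
    outward orientation.  Raises :class:`TopologyError` on open meshes.
    """
    if not s.is_closed():
        raise TopologyError("mesh is not closed/consistently oriented")
    return _signed_volume_m3(s.vertices, s.faces) * M3_TO_L


# ---------------------------------------------------------------------------
# Compartment volume series
# ---------------------------------------------------------------------------


@dataclass
class CompartmentSeries:
    """Per-frame chest-wall and compartment volumes (liters)."""

    time: np.ndarray
    v_cw: np.ndarray
    v_rcp: np.ndarray
    v_rca: np.ndarray
    v_ab: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        for name in ("time", "v_cw", "v_rcp", "v_rca", "v_ab"):
            setattr(self, name, np.asarray(getattr(self, name), float))

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "V_cw": self.v_cw,
                "V_rcp": self.v_rcp,
                "V_rca": self.v_rca,
                "V_ab": self.v_ab,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compartment_volumes(
    t: TrajectorySet,
    layout: MarkerLayout,
    bed_offset: float = 0.01,
) -> CompartmentSeries:
    """Chest-wall and compartment volume time series by the divergence theorem.

    The bed plane is static (minimum anterior z over the whole recording
    minus *bed_offset*).  Mesh topology (quad diagonal choice) is fixed from
    the time-mean geometry so the same triangulation applies to every frame;
    volumes are then evaluated vectorized across frames.  Frames with
    invalid markers raise a :class:`GeometryError` naming the first bad
    frame — run gap filling first.
    """
    if tuple(t.marker_ids) != tuple(layout.marker_ids):
        raise GeometryError("trajectory marker set does not match layout")
    if not t.gap_mask.all():
        bad = int(np.flatnonzero(~t.gap_mask.all(axis=1))[0])
        raise GeometryError(
            f"invalid marker samples at frame {bad}; fill gaps before computing volumes"
        )
    mean_frame = t.positions.mean(axis=0)
    P = _grid_positions(mean_frame, layout)
    _check_geometry(P)
    rows, cols, _ = P.shape
    n = rows * cols
    idx_top = layout.grid_indices()  # marker index per (row, col)
    # reorder positions into grid order once
    order = idx_top.reshape(-1)
    pos = t.positions[:, order, :]  # (F, n, 3) grid-ordered
    z_bed = float(pos[:, :, 2].min() - bed_offset)
    proj = pos.copy()
    proj[:, :, 2] = z_bed
    verts = np.concatenate([pos, proj], axis=1)  # (F, 2n, 3)

    grid_idx = np.arange(n).reshape(rows, cols)
    bounds = dict(_band_bounds(layout))
    bounds["chest_wall"] = (0, rows - 1)
    volumes: dict[str, np.ndarray] = {}
    for comp, (r0, r1) in bounds.items():
        ant, clos = _band_faces(P, grid_idx, r0, r1)
        faces = np.vstack([ant, clos])
        v0 = verts[:, faces[:, 0], :]
        v1 = verts[:, faces[:, 1], :]
        v2 = verts[:, faces[:, 2], :]
        vol = np.einsum("fij,fij->f", v0, np.cross(v1, v2)) / 6.0
        volumes[comp] = vol * M3_TO_L
    sign = 1.0 if volumes["chest_wall"][0] >= 0 else -1.0
    return CompartmentSeries(
        time=t.time,
        v_cw=sign * volumes["chest_wall"],
        v_rcp=sign * volumes["pulmonary_ribcage"],
        v_rca=sign * volumes["abdominal_ribcage"],
        v_ab=sign * volumes["abdomen"],
        sample_rate=t.sample_rate,
    )


def export_obj(s: SurfaceModel, path: str | Path) -> None:
    """Write the mesh as Wavefront OBJ for visual inspection."""
    with open(path, "w") as fh:
        for v in s.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in s.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
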