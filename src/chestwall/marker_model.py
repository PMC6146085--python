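"""Marker layout and trajectory data model.

Optoelectronic plethysmography (OEP) records the 3D positions of passive
reflective markers placed on the anterior trunk surface of a supine subject,
from the clavicles to the pubis.  This module defines the marker-grid layout
(:class:`MarkerLayout`), the time-indexed trajectories
(:class:`TrajectorySet`), the laboratory axis convention, file I/O for the
tabular trajectory dialect, short-gap repair, and layout validation.

Axis convention (fixed for the whole package): ``+x`` points from the
subject's left toward the right, ``+y`` from caudal to cranial, ``+z`` from
the bed toward the anterior surface.  The frontal view is therefore the x-y
plane by construction.  All distances are in meters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import FormatError, LayoutMismatchError, UnsupportedFormatError

__all__ = [
    "AxisConvention",
    "MarkerLayout",
    "TrajectorySet",
    "ValidationReport",
    "default_layout",
    "load_trajectories",
    "save_trajectories",
    "fill_gaps",
    "validate_layout",
    "layout_from_yaml",
    "layout_to_yaml",
]

#: Landmark roles that must map to a single marker.
PAIR_ROLES = (
    "axillary_sternal_left",
    "axillary_sternal_right",
    "costal10_left",
    "costal10_right",
)
#: Landmark roles that name a whole transverse marker row.
ROW_ROLES = ("clavicular_row", "xiphisternal_row", "lower_costal_row", "pubic_row")

REQUIRED_ROLES = PAIR_ROLES + ROW_ROLES


@dataclass(frozen=True)
class AxisConvention:
    """Orthonormal laboratory axes.

    ``lateral`` points from the subject's left to the right, ``longitudinal``
    from caudal to cranial, ``anteroposterior`` from the bed toward the
    anterior surface.
    """

    lateral: tuple[float, float, float] = (1.0, 0.0, 0.0)
    longitudinal: tuple[float, float, float] = (0.0, 1.0, 0.0)
    anteroposterior: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        m = np.array([self.lateral, self.longitudinal, self.anteroposterior], float)
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be mutually orthogonal unit vectors")

    @property
    def right_handed(self) -> bool:
        m = np.array([self.lateral, self.longitudinal, self.anteroposterior], float)
        return float(np.linalg.det(m)) > 0

    def matrix(self) -> np.ndarray:
        return np.array([self.lateral, self.longitudinal, self.anteroposterior], float)


@dataclass(frozen=True)
class MarkerLayout:
    """Names, grid topology and anatomical landmark roles of the trunk grid.

    Parameters
    ----------
    marker_ids
        Ordered marker names; the order defines the column order of
        trajectory arrays and files.
    grid
        Mapping of marker id to ``(row, column)``.  Row 0 is the most cranial
        (clavicular) row; rows increase caudally.  Column 0 is the subject's
        left-most column.
    landmarks
        Mapping of semantic role to a marker id (for left/right pairs) or to
        a tuple of marker ids (for whole-row roles).
    """

    marker_ids: tuple[str, ...]
    grid: Mapping[str, tuple[int, int]]
    landmarks: Mapping[str, str | tuple[str, ...]]

    def __post_init__(self) -> None:
        ids = self.marker_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in layout")
        if set(self.grid) != set(ids):
            raise ValueError("grid keys must match marker_ids exactly")
        cells = list(self.grid.values())
        if len(set(cells)) != len(cells):
            raise ValueError("grid positions must be unique")
        missing = [r for r in REQUIRED_ROLES if r not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmark roles: {missing}")
        for role in PAIR_ROLES:
            m = self.landmarks[role]
            if not isinstance(m, str) or m not in self.grid:
                raise ValueError(f"landmark role {role!r} must map to one marker id")
        for left, right in (PAIR_ROLES[:2], PAIR_ROLES[2:]):
            if self.landmarks[left] == self.landmarks[right]:
                raise ValueError(f"{left}/{right} must map to distinct markers")
        for role in ROW_ROLES:
            row_ids = self.landmarks[role]
            if isinstance(row_ids, str):
                row_ids = (row_ids,)
            rows = {self.grid[m][0] for m in row_ids if m in self.grid}
            if len(rows) != 1 or any(m not in self.grid for m in row_ids):
                raise ValueError(f"row role {role!r} must map to markers of one row")
        order = [self.row_index(r) for r in ROW_ROLES]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError("landmark rows must be ordered cranio-caudally")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_rows(self) -> int:
        return 1 + max(r for r, _ in self.grid.values())

    @property
    def n_cols(self) -> int:
        return 1 + max(c for _, c in self.grid.values())

    def row_index(self, role: str) -> int:
        """Grid row of a row role (or of the marker a pair role names)."""
        m = self.landmarks[role]
        if isinstance(m, str):
            return self.grid[m][0]
        return self.grid[m[0]][0]

    def index_of(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def grid_indices(self) -> np.ndarray:
        """(n_rows, n_cols) array of marker indices, or -1 for empty cells."""
        out = np.full((self.n_rows, self.n_cols), -1, dtype=int)
        for i, m in enumerate(self.marker_ids):
            r, c = self.grid[m]
            out[r, c] = i
        return out


def default_layout(rows: int = 6, cols: int = 6) -> MarkerLayout:
    """The default 36-marker anterior-trunk grid.

    Six transverse rows from clavicles to pubis: clavicular, sternal-angle,
    nipple, xiphisternal, 10th-costal-cartilage and umbilical/pubic; six
    columns from the subject's left anterior axillary line to the right one.
    The anterior-axillary landmarks sit at the lateral extremes of the
    sternal-angle row; the 10th-costal landmarks at the extremes of the
    lower costal row.
    """
    if rows < 4 or cols < 2:
        raise ValueError("grid needs at least 4 rows and 2 columns")
    ids = tuple(f"r{r}c{c}" for r in range(rows) for c in range(cols))
    grid = {f"r{r}c{c}": (r, c) for r in range(rows) for c in range(cols)}
    sternal_row = 1
    xiph_row = rows - 3
    costal_row = rows - 2
    landmarks: dict[str, str | tuple[str, ...]] = {
        "axillary_sternal_left": f"r{sternal_row}c0",
        "axillary_sternal_right": f"r{sternal_row}c{cols - 1}",
        "costal10_left": f"r{costal_row}c0",
        "costal10_right": f"r{costal_row}c{cols - 1}",
        "clavicular_row": tuple(f"r0c{c}" for c in range(cols)),
        "xiphisternal_row": tuple(f"r{xiph_row}c{c}" for c in range(cols)),
        "lower_costal_row": tuple(f"r{costal_row}c{c}" for c in range(cols)),
        "pubic_row": tuple(f"r{rows - 1}c{c}" for c in range(cols)),
    }
    return MarkerLayout(marker_ids=ids, grid=grid, landmarks=landmarks)


@dataclass
class TrajectorySet:
    """Time-indexed 3D marker positions.

    ``positions`` has shape ``(n_frames, n_markers, 3)`` in meters;
    ``gap_mask`` is True where a sample is valid.  Positions at invalid
    samples are NaN.
    """

    positions: np.ndarray
    sample_rate: float
    marker_ids: tuple[str, ...]
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.marker_ids):
            raise ValueError("positions second axis must match marker_ids")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.isfinite(self.positions).all(axis=2)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.positions.shape[:2]:
            raise ValueError("gap_mask must have shape (frames, markers)")
        if not np.isfinite(self.positions[self.gap_mask]).all():
            raise ValueError("positions must be finite wherever gap_mask is valid")
        self.marker_ids = tuple(self.marker_ids)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate

    def index_of(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            self.positions.copy(), self.sample_rate, self.marker_ids, self.gap_mask.copy()
        )


# ---------------------------------------------------------------------------
# File I/O — tabular dialect
#
# One row per frame; header row mandatory; columns "<marker>_x,<marker>_y,
# <marker>_z" comma-separated; missing samples are empty fields.  A leading
# comment line "# sample_rate_hz: <fs>" carries the sampling rate.
# ---------------------------------------------------------------------------


def save_trajectories(t: TrajectorySet, path: str | Path) -> None:
    """Write the tabular CSV dialect (lossless float round-trip)."""
    path = Path(path)
    cols = [f"{m}_{ax}" for m in t.marker_ids for ax in "xyz"]
    flat = t.positions.reshape(t.n_frames, -1)
    with io.StringIO() as buf:
        buf.write(f"# sample_rate_hz: {t.sample_rate!r}\n")
        buf.write(",".join(cols) + "\n")
        for row in flat:
            buf.write(",".join("" if not np.isfinite(v) else f"{v:.17g}" for v in row))
            buf.write("\n")
        path.write_text(buf.getvalue())


def load_trajectories(
    path: str | Path,
    format: str = "tabular",
    sample_rate: float | None = None,
    layout: MarkerLayout | None = None,
) -> TrajectorySet:
    """Read marker trajectories from *path*.

    Only the tabular CSV dialect is supported; convert C3D acquisitions to
    this dialect upstream.  If *layout* is given, the file's marker set must
    match it exactly, otherwise a :class:`LayoutMismatchError` is raised.
    Missing/occluded samples (empty fields) are flagged in ``gap_mask``.
    """
    if format == "c3d":
        raise UnsupportedFormatError(
            "C3D reading is not supported; export the point data to the "
            "tabular CSV dialect first"
        )
    if format != "tabular":
        raise UnsupportedFormatError(f"unknown trajectory format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        lines = path.read_text().splitlines()
    except OSError as e:  # pragma: no cover - OS dependent
        raise FormatError(str(e)) from e
    i = 0
    fs = sample_rate
    while i < len(lines) and lines[i].startswith("#"):
        key, _, val = lines[i][1:].partition(":")
        if key.strip() == "sample_rate_hz":
            fs = float(val)
        i += 1
    if i >= len(lines) or not lines[i].strip():
        raise FormatError(f"{path}: missing header row")
    header = [h.strip() for h in lines[i].split(",")]
    i += 1
    markers: list[str] = []
    for j in range(0, len(header), 3):
        triple = header[j : j + 3]
        if len(triple) != 3 or not all(
            h.endswith(f"_{ax}") for h, ax in zip(triple, "xyz")
        ):
            raise FormatError(f"{path}: header must be <marker>_x,_y,_z triples")
        names = {h.rsplit("_", 1)[0] for h in triple}
        if len(names) != 1:
            raise FormatError(f"{path}: inconsistent marker name in columns {triple}")
        markers.append(names.pop())
    if fs is None:
        raise FormatError(
            f"{path}: sampling rate not in file; pass sample_rate= explicitly"
        )
    rows = [ln for ln in lines[i:] if ln.strip()]
    data = np.full((len(rows), len(markers) * 3), np.nan)
    for k, ln in enumerate(rows):
        cells = ln.split(",")
        if len(cells) != len(header):
            raise FormatError(f"{path}: row {k} has {len(cells)} fields, "
                              f"expected {len(header)}")
        for j, cell in enumerate(cells):
            if cell.strip():
                data[k, j] = float(cell)
    positions = data.reshape(len(rows), len(markers), 3)
    gap_mask = np.isfinite(positions).all(axis=2)
    positions[~gap_mask] = np.nan
    if layout is not None and tuple(markers) != tuple(layout.marker_ids):
        missing = set(layout.marker_ids) - set(markers)
        extra = set(markers) - set(layout.marker_ids)
        raise LayoutMismatchError(
            f"{path}: marker set does not match layout "
            f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
        )
    return TrajectorySet(positions, float(fs), tuple(markers), gap_mask)


# ---------------------------------------------------------------------------
# Gap repair
# ---------------------------------------------------------------------------


def fill_gaps(t: TrajectorySet, max_gap_s: float) -> TrajectorySet:
    """Fill short occlusion gaps by per-coordinate linear interpolation.

    Interior gaps of duration <= ``max_gap_s`` are interpolated linearly per
    coordinate; longer gaps and gaps touching the start or end of the
    recording remain flagged invalid.  Valid samples are never altered.
    """
    if max_gap_s < 0:
        raise ValueError("max_gap_s must be >= 0")
    out = t.copy()
    max_len = int(np.floor(max_gap_s * t.sample_rate + 1e-9))
    if max_len == 0:
        return out
    frames = np.arange(t.n_frames)
    for m in range(t.n_markers):
        valid = out.gap_mask[:, m]
        if valid.all() or not valid.any():
            continue
        invalid_idx = np.flatnonzero(~valid)
        # contiguous runs of invalid frames
        splits = np.flatnonzero(np.diff(invalid_idx) > 1) + 1
        for run in np.split(invalid_idx, splits):
            if run[0] == 0 or run[-1] == t.n_frames - 1 or len(run) > max_len:
                continue
            lo, hi = run[0] - 1, run[-1] + 1
            for ax in range(3):
                out.positions[run, m, ax] = np.interp(
                    frames[run], [lo, hi], [out.positions[lo, m, ax],
                                            out.positions[hi, m, ax]]
                )
            out.gap_mask[run, m] = True
    return out


# ---------------------------------------------------------------------------
# Layout validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only outcome of :func:`validate_layout`."""

    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_layout(t: TrajectorySet, layout: MarkerLayout) -> ValidationReport:
    """Check a trajectory set against a layout (report-only, never raises).

    Flags markers missing from the file, duplicated ids, landmark roles that
    point at absent markers, and left/right swaps detected from the sign of
    the mean lateral coordinate at the landmark pairs (left landmarks must
    lie at smaller ``x`` than right ones).
    """
    issues: list[str] = []
    file_ids = list(t.marker_ids)
    seen: set[str] = set()
    for m in file_ids:
        if m in seen:
            issues.append(f"duplicated marker id in file: {m}")
        seen.add(m)
    for m in layout.marker_ids:
        if m not in seen:
            issues.append(f"marker missing from file: {m}")
    for role in REQUIRED_ROLES:
        ids = layout.landmarks.get(role)
        if ids is None:
            issues.append(f"landmark role missing from layout: {role}")
            continue
        for mid in (ids,) if isinstance(ids, str) else ids:
            if mid not in seen:
                issues.append(f"landmark role {role} points at absent marker {mid}")
    for left_role, right_role in (PAIR_ROLES[:2], PAIR_ROLES[2:]):
        lid = layout.landmarks.get(left_role)
        rid = layout.landmarks.get(right_role)
        if not (isinstance(lid, str) and isinstance(rid, str)):
            continue
        if lid in seen and rid in seen:
            li, ri = file_ids.index(lid), file_ids.index(rid)
            both = t.gap_mask[:, li] & t.gap_mask[:, ri]
            if both.any():
                xl = float(np.nanmean(t.positions[both, li, 0]))
                xr = float(np.nanmean(t.positions[both, ri, 0]))
                if xl > xr:
                    issues.append(
                        f"left/right swap suspected for {left_role}/{right_role}: "
                        f"mean lateral coordinate of {lid} ({xl:.3f}) exceeds "
                        f"{rid} ({xr:.3f})"
                    )
    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# Layout files
# ---------------------------------------------------------------------------


def layout_to_yaml(layout: MarkerLayout, path: str | Path) -> None:
    doc = {
        "markers": {m: list(layout.grid[m]) for m in layout.marker_ids},
        "landmarks": {
            k: (v if isinstance(v, str) else list(v))
            for k, v in layout.landmarks.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def layout_from_yaml(path: str | Path) -> MarkerLayout:
    """Read a layout document: marker → [row, col] plus role → marker(s)."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
        markers = doc["markers"]
        landmarks = doc["landmarks"]
    except (OSError, yaml.YAMLError, KeyError, TypeError) as e:
        raise FormatError(f"cannot parse layout file {path}: {e}") from e
    grid = {m: (int(rc[0]), int(rc[1])) for m, rc in markers.items()}
    lm = {k: (v if isinstance(v, str) else tuple(v)) for k, v in landmarks.items()}
    return MarkerLayout(tuple(markers), grid, lm)
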