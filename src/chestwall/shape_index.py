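"""Bell-shaped chest index and ribcage shape classification.

The bell-shaped chest index is the ratio between two frontal-view
distances: the distance between the two anterior-axillary-line markers at
the sternal angle (of Louis), and the distance between the right and left
10th costal cartilages, where the costal margin reaches its lowest level.
An index well below 1 indicates a bell-shaped chest (apex narrower than
base, typical of ribcage-muscle weakness), an index near 1 a rectangular
chest, and an index well above 1 an inverted-triangle chest.

The index needs only two distances, so alongside the marker-based
computation a "tape-measure mode" (:func:`shape_from_distances`) accepts
two manually measured lengths.  The radiograph-based upper-to-lower ribcage
ratio (longest transverse line of the 2nd rib over that of the 9th rib) is
implemented as plain ratio arithmetic on two given lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .marker_model import AxisConvention, MarkerLayout, TrajectorySet

__all__ = [
    "ShapeResult",
    "frontal_projection",
    "bell_shape_index",
    "classify_shape",
    "upper_lower_ratio",
    "shape_from_distances",
    "DEFAULT_SHAPE_THRESHOLDS",
]

#: (low, high) bounds separating bell / rectangular / inverted-triangle.
#: The qualitative definition ("well below 1" / "close to 1" / "well above
#: 1") is operationalised by these configurable defaults.
DEFAULT_SHAPE_THRESHOLDS = (0.85, 1.15)

SHAPE_CLASSES = ("bell", "rectangular", "inverted_triangle")


@dataclass(frozen=True)
class ShapeResult:
    """Bell-shaped chest index with its two landmark distances."""

    d_upper: float          # m, anterior axillary lines at sternal angle
    d_lower: float          # m, right/left 10th costal cartilage
    bell_index: float
    shape_class: str
    frames_used: str
    thresholds: tuple[float, float] = DEFAULT_SHAPE_THRESHOLDS

    def to_dict(self) -> dict:
        return {
            "d_upper_m": self.d_upper,
            "d_lower_m": self.d_lower,
            "bell_index": self.bell_index,
            "shape_class": self.shape_class,
            "frames_used": self.frames_used,
            "thresholds": list(self.thresholds),
        }


def frontal_projection(
    points: np.ndarray, axes: AxisConvention | None = None
) -> np.ndarray:
    """Project 3D points onto the frontal (lateral, longitudinal) plane.

    The anteroposterior coordinate is dropped; with the default axis
    convention this is simply ``(x, y)``.
    """
    axes = axes or AxisConvention()
    pts = np.asarray(points, float)
    if not np.isfinite(pts).all():
        raise GeometryError("cannot project invalid (NaN) points")
    return np.stack(
        [pts @ np.asarray(axes.lateral), pts @ np.asarray(axes.longitudinal)],
        axis=-1,
    )


def _landmark_indices(layout: MarkerLayout) -> dict[str, int]:
    roles = (
        "axillary_sternal_left",
        "axillary_sternal_right",
        "costal10_left",
        "costal10_right",
    )
    out = {}
    for role in roles:
        mid = layout.landmarks.get(role)
        if not isinstance(mid, str) or mid not in layout.marker_ids:
            raise GeometryError(f"landmark role {role!r} missing from layout")
        out[role] = layout.index_of(mid)
    return out


def bell_shape_index(
    t: TrajectorySet,
    layout: MarkerLayout,
    window: tuple[float, float] | None = None,
    end_expiratory_times: np.ndarray | None = None,
    thresholds: tuple[float, float] = DEFAULT_SHAPE_THRESHOLDS,
    axes: AxisConvention | None = None,
) -> ShapeResult:
    """Bell-shaped chest index from marker trajectories.

    Per-frame frontal-projection Euclidean distances between the two
    landmark pairs are averaged at the end-expiratory instants (if
    *end_expiratory_times* is given, e.g. breath start times from the
    segmentation), restricted to *window*; the index is
    ``mean(d_upper) / mean(d_lower)``.  Without end-expiratory instants the
    mean over all valid frames is used and a warning is emitted.
    """
    idx = _landmark_indices(layout)
    cols = [idx[r] for r in (
        "axillary_sternal_left", "axillary_sternal_right",
        "costal10_left", "costal10_right",
    )]
    valid = t.gap_mask[:, cols].all(axis=1)
    time = t.time
    if window is not None:
        valid &= (time >= window[0] - 1e-9) & (time <= window[1] + 1e-9)
    if end_expiratory_times is not None and len(end_expiratory_times) > 0:
        frames = np.unique(
            np.clip(
                np.round(np.asarray(end_expiratory_times) * t.sample_rate), 0,
                t.n_frames - 1,
            ).astype(int)
        )
        frames = frames[valid[frames]]
        frames_used = f"{len(frames)} end-expiratory frames"
    else:
        frames = np.flatnonzero(valid)
        frames_used = f"all {len(frames)} valid frames"
        if end_expiratory_times is not None:
            warnings.warn(
                "no end-expiratory instants available; falling back to the "
                "all-frame mean",
                stacklevel=2,
            )
    if len(frames) == 0:
        raise GeometryError("no frames with all four shape landmarks valid")
    P = t.positions[frames]
    proj = frontal_projection(P[:, cols, :], axes)
    d_upper = float(np.linalg.norm(proj[:, 0] - proj[:, 1], axis=1).mean())
    d_lower = float(np.linalg.norm(proj[:, 2] - proj[:, 3], axis=1).mean())
    index = d_upper / d_lower
    return ShapeResult(
        d_upper=d_upper,
        d_lower=d_lower,
        bell_index=index,
        shape_class=classify_shape(index, thresholds),
        frames_used=frames_used,
        thresholds=thresholds,
    )


def classify_shape(
    index: float, thresholds: tuple[float, float] = DEFAULT_SHAPE_THRESHOLDS
) -> str:
    """'bell' below the low threshold, 'inverted_triangle' above the high
    one, 'rectangular' in between (inclusive)."""
    if not index > 0:
        raise ValueError(f"shape index must be positive, got {index}")
    low, high = thresholds
    if not 0 < low <= high:
        raise ValueError("thresholds must satisfy 0 < low <= high")
    if index < low:
        return "bell"
    if index > high:
        return "inverted_triangle"
    return "rectangular"


def upper_lower_ratio(d_rib2: float, d_rib9: float) -> float:
    """Radiographic upper-to-lower ribcage ratio.

    Ratio of the longest transverse line of the 2nd rib to that of the 9th
    rib, both measured manually on an antero-posterior radiograph (any
    consistent unit).
    """
    if not (d_rib2 > 0 and d_rib9 > 0):
        raise ValueError("both diameters must be positive")
    return d_rib2 / d_rib9


def shape_from_distances(
    d_upper: float,
    d_lower: float,
    thresholds: tuple[float, float] = DEFAULT_SHAPE_THRESHOLDS,
) -> ShapeResult:
    """Tape-measure mode: index and class from two measured distances."""
    if not (d_upper > 0 and d_lower > 0):
        raise ValueError("both distances must be positive")
    index = d_upper / d_lower
    return ShapeResult(
        d_upper=float(d_upper),
        d_lower=float(d_lower),
        bell_index=index,
        shape_class=classify_shape(index, thresholds),
        frames_used="manual measurement",
        thresholds=thresholds,
    )
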