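"""Synthetic torso and breathing-motion generator with known ground truth.

Emulates a supine quiet-breathing acquisition of the 36-marker anterior
trunk grid: a tapered torso with programmable upper/lower width ratio (the
ground-truth bell-shaped chest index), and breathing applied as
anteroposterior displacement fields with smooth row-wise weighting per
compartment.  The three field amplitudes are calibrated against the actual
volume pipeline so that the programmed compartment contribution split
(p_rcp, p_rca, p_ab) to the programmed tidal volume is met exactly on the
noise-free signal — the chest-wall volume response is linear in the
anteroposterior marker displacements for the bed-plane closure, so the
calibration is a 3x3 linear solve, not an approximation.

A negative p_rcp (with the others compensating so the split sums to 1)
produces inspiratory inward motion of the pulmonary ribcage, i.e.
paradoxical breathing.  Breath periods are drawn with a programmable
coefficient of variation, Gaussian marker noise is additive, and every
draw is reproducible from the seed.

The default cohort groups are loosely inspired by published severity
profiles of spinal muscular atrophy (bell indices from ~0.73 to ~0.92,
pulmonary-ribcage contributions from about -5% to +20%); they are
illustrative scenarios, not reproductions of any patient data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError
from .marker_model import MarkerLayout, TrajectorySet, default_layout, save_trajectories
from .surface_volume import compartment_volumes

__all__ = [
    "TorsoSpec",
    "BreathSpec",
    "GroupSpec",
    "CohortSpec",
    "make_torso",
    "simulate_breathing",
    "simulate_cohort",
    "default_cohort",
]


@dataclass(frozen=True)
class TorsoSpec:
    """Static torso geometry.

    ``upper_width`` is the frontal distance between the anterior-axillary
    markers at the sternal-angle row; ``lower_width`` the distance between
    the 10th-costal markers.  The grid width tapers linearly through these
    two rows (extrapolated beyond them), so the ground-truth bell index is
    exactly ``upper_width / lower_width``.  ``anterior_heights`` is the
    per-row sagittal elevation above the bed plane (z = 0).  Defaults are
    child-sized (trunk ~0.35 m, chest width ~0.18 m).
    """

    upper_width: float = 0.165
    lower_width: float = 0.18
    trunk_length: float = 0.35
    anterior_heights: tuple[float, ...] | None = None
    rows: int = 6
    cols: int = 6

    def __post_init__(self) -> None:
        if not (self.upper_width > 0 and self.lower_width > 0 and self.trunk_length > 0):
            raise ValueError("widths and trunk length must be positive")
        if self.rows < 4 or self.cols < 2:
            raise ValueError("grid needs at least 4 rows and 2 columns")
        if self.anterior_heights is not None and len(self.anterior_heights) != self.rows:
            raise ValueError("anterior_heights must have one entry per row")

    @property
    def bell_index(self) -> float:
        return self.upper_width / self.lower_width

    def heights(self) -> np.ndarray:
        if self.anterior_heights is not None:
            h = np.asarray(self.anterior_heights, float)
        else:
            base = np.array([0.055, 0.07, 0.08, 0.08, 0.07, 0.05])
            h = np.interp(
                np.linspace(0, 1, self.rows), np.linspace(0, 1, len(base)), base
            )
        if not (h > 0).all():
            raise ValueError("anterior heights must be positive")
        return h


@dataclass(frozen=True)
class BreathSpec:
    """Programmed breathing: rate, tidal volume, compartment split, noise.

    ``split`` is (p_rcp, p_rca, p_ab) and must sum to 1; p_rcp may be
    negative (paradox) with the others compensating.  ``phases`` are
    per-compartment offsets in fractions of a breath cycle.  ``rate_cv`` is
    the coefficient of variation of the breath period; ``noise_sigma`` the
    standard deviation (m) of additive Gaussian marker noise on every
    coordinate.
    """

    rr: float = 30.0              # breaths/min
    v_t: float = 0.2              # L
    split: tuple[float, float, float] = (0.20, 0.10, 0.70)
    phases: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rate_cv: float = 0.0
    noise_sigma: float = 0.0      # m
    duration_s: float = 60.0
    sample_rate: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rr > 0 and self.v_t > 0):
            raise ValueError("rr and v_t must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("contribution split must sum to 1")
        if self.rate_cv < 0 or self.noise_sigma < 0:
            raise ValueError("rate_cv and noise_sigma must be >= 0")
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")


def make_torso(spec: TorsoSpec) -> tuple[np.ndarray, MarkerLayout]:
    """Static marker frame (n_markers, 3) and matching layout.

    The frontal-projection landmark distances equal the spec widths exactly.
    """
    layout = default_layout(spec.rows, spec.cols)
    sternal_row = layout.grid[layout.landmarks["axillary_sternal_left"]][0]
    costal_row = layout.row_index("lower_costal_row")
    r = np.arange(spec.rows)
    widths = spec.upper_width + (spec.lower_width - spec.upper_width) * (
        (r - sternal_row) / (costal_row - sternal_row)
    )
    if not (widths > 0).all():
        raise ValueError("width taper extrapolates to non-positive widths")
    h = spec.heights()
    frame = np.empty((spec.rows * spec.cols, 3))
    for m, (rr_, cc) in ((layout.index_of(mid), layout.grid[mid])
                         for mid in layout.marker_ids):
        frac = cc / (spec.cols - 1) - 0.5
        frame[m] = (
            widths[rr_] * frac,
            spec.trunk_length * (1.0 - rr_ / (spec.rows - 1)),
            h[rr_],
        )
    return frame, layout


# ---------------------------------------------------------------------------
# Breathing motion
# ---------------------------------------------------------------------------


def _weight_fields(layout: MarkerLayout) -> np.ndarray:
    """(3, n_rows) row weights of the compartment displacement fields."""
    xiph = layout.row_index("xiphisternal_row")
    costal = layout.row_index("lower_costal_row")
    last = layout.n_rows - 1
    w = np.zeros((3, layout.n_rows))
    w[0, 0] = 0.5
    w[0, 1:xiph] = 1.0
    w[1, xiph : costal + 1] = 1.0
    w[2, costal + 1 : last + 1] = 1.0
    return w


def _volume_sensitivity(
    base: np.ndarray, layout: MarkerLayout, w: np.ndarray
) -> np.ndarray:
    """3x3 matrix: compartment volume change (L) per unit field amplitude.

    Exact because compartment volumes are linear in anteroposterior marker
    displacement under the bed-plane closure with fixed topology.
    """
    rows_of = np.array([layout.grid[m][0] for m in layout.marker_ids])
    n = len(layout.marker_ids)
    frames = [base]
    for j in range(3):
        f = base.copy()
        f[:, 2] += w[j, rows_of]
        frames.append(f)
    traj = TrajectorySet(np.stack(frames), 1.0, layout.marker_ids)
    s = compartment_volumes(traj, layout)
    v = np.stack([s.v_rcp, s.v_rca, s.v_ab])  # (3 comps, 4 frames)
    return v[:, 1:] - v[:, [0]]               # M[c, j]


def _breath_periods(
    rng: np.random.Generator, rr: float, cv: float, duration_s: float
) -> np.ndarray:
    t0 = 60.0 / rr
    periods = []
    total = 0.0
    while total < duration_s + t0:
        p = t0 * float(np.clip(1.0 + cv * rng.standard_normal(), 0.5, 1.5))
        periods.append(p)
        total += p
    return np.asarray(periods)


def simulate_breathing(
    torso: TorsoSpec | tuple[np.ndarray, MarkerLayout],
    spec: BreathSpec,
) -> tuple[TrajectorySet, dict]:
    """Marker trajectories for a breathing torso, plus the ground truth.

    Returns the trajectory set and a record of every programmed quantity
    (bell index, RR, V_T, contribution split, noise, seed).
    """
    if isinstance(torso, TorsoSpec):
        base, layout = make_torso(torso)
        gt_index = torso.bell_index
    else:
        base, layout = torso
        from .shape_index import frontal_projection  # local to avoid cycle

        idx = [layout.index_of(layout.landmarks[r]) for r in (
            "axillary_sternal_left", "axillary_sternal_right",
            "costal10_left", "costal10_right")]
        p = frontal_projection(base[idx])
        gt_index = float(
            np.linalg.norm(p[0] - p[1]) / np.linalg.norm(p[2] - p[3])
        )
    rng = np.random.default_rng(spec.seed)
    w = _weight_fields(layout)
    M = _volume_sensitivity(base, layout, w)
    targets = np.asarray(spec.split) * spec.v_t  # L per compartment
    alpha = np.linalg.solve(M, targets)          # field amplitudes, m

    periods = _breath_periods(rng, spec.rr, spec.rate_cv, spec.duration_s)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    n_frames = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n_frames) / spec.sample_rate
    k = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(periods) - 1)
    tau = (t - starts[k]) / periods[k]

    rows_of = np.array([layout.grid[m][0] for m in layout.marker_ids])
    disp = np.zeros((n_frames, len(layout.marker_ids)))
    for c in range(3):
        u = 0.5 * (1.0 - np.cos(2.0 * np.pi * (tau - spec.phases[c])))
        disp += alpha[c] * np.outer(u, w[c, rows_of])
    z = base[None, :, 2] + disp
    trunk_scale = float(np.ptp(base[:, 1]))
    if z.min() < 0.003 or np.abs(disp).max() > 0.5 * trunk_scale:
        raise GeometryError(
            "infeasible contribution split: displacement amplitudes exceed the "
            "torso geometry (markers would cross the bed plane or move by a "
            "large fraction of the trunk length)"
        )
    positions = np.empty((n_frames, len(layout.marker_ids), 3))
    positions[:, :, 0] = base[None, :, 0]
    positions[:, :, 1] = base[None, :, 1]
    positions[:, :, 2] = z
    if spec.noise_sigma > 0:
        positions = positions + rng.normal(0.0, spec.noise_sigma, positions.shape)
    traj = TrajectorySet(positions, spec.sample_rate, layout.marker_ids)
    ground_truth = {
        "bell_index": gt_index,
        "rr": spec.rr,
        "v_t": spec.v_t,
        "p_rcp": spec.split[0],
        "p_rca": spec.split[1],
        "p_ab": spec.split[2],
        "pct_rcp": 100.0 * spec.split[0],
        "pct_ab": 100.0 * spec.split[2],
        "rate_cv": spec.rate_cv,
        "noise_sigma": spec.noise_sigma,
        "duration_s": spec.duration_s,
        "sample_rate": spec.sample_rate,
        "seed": spec.seed,
    }
    return traj, ground_truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Per-group parameter distributions (normal, clipped to valid ranges)."""

    n: int = 10
    index_mean: float = 0.9
    index_sd: float = 0.03
    p_rcp_mean: float = 0.2
    p_rcp_sd: float = 0.02
    p_rca: float = 0.10
    rr_mean: float = 25.0
    rr_sd: float = 2.0
    v_t_mean: float = 0.18
    v_t_sd: float = 0.02
    rate_cv: float = 0.05
    noise_sigma: float = 2e-4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: dict[str, GroupSpec] = field(default_factory=dict)
    seed: int = 0
    duration_s: float = 60.0
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")


def default_cohort(n_per_group: int = 10, seed: int = 0) -> CohortSpec:
    """Five illustrative severity groups with jointly decreasing bell index
    and pulmonary-ribcage contribution (healthy-like down to severe-like,
    the most severe with paradoxical breathing)."""
    g = {
        "HC": GroupSpec(n=n_per_group, index_mean=0.92, p_rcp_mean=0.20,
                        rr_mean=22, v_t_mean=0.20),
        "SMA3": GroupSpec(n=n_per_group, index_mean=0.91, p_rcp_mean=0.18,
                          rr_mean=24, v_t_mean=0.18),
        "SMA2": GroupSpec(n=n_per_group, index_mean=0.81, p_rcp_mean=0.126,
                          rr_mean=30, v_t_mean=0.14),
        "SMA2px": GroupSpec(n=n_per_group, index_mean=0.74, p_rcp_mean=-0.049,
                            rr_mean=35, v_t_mean=0.10, v_t_sd=0.015),
        "SMA1": GroupSpec(n=n_per_group, index_mean=0.73, p_rcp_mean=-0.08,
                          rr_mean=45, rr_sd=4.0, v_t_mean=0.07, v_t_sd=0.01),
    }
    return CohortSpec(groups=g, seed=seed)


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, list[TrajectorySet]]:
    """Simulate every subject of a cohort.

    Returns the ground-truth manifest (one row per subject) and the
    trajectory sets in the same order.  If *out_dir* is given, one tabular
    trajectory file per subject plus ``manifest.csv`` are written there.
    """
    master = np.random.default_rng(spec.seed)
    rows = []
    trajs: list[TrajectorySet] = []
    for group, g in spec.groups.items():
        for k in range(g.n):
            sid = f"{group}_{k:02d}"
            index = float(np.clip(master.normal(g.index_mean, g.index_sd), 0.4, 2.0))
            p_rcp = float(np.clip(master.normal(g.p_rcp_mean, g.p_rcp_sd), -0.3, 0.6))
            rr = float(np.clip(master.normal(g.rr_mean, g.rr_sd), 8.0, 110.0))
            v_t = float(np.clip(master.normal(g.v_t_mean, g.v_t_sd), 0.03, 1.0))
            sub_seed = int(master.integers(0, 2**31 - 1))
            torso = TorsoSpec(upper_width=0.18 * index, lower_width=0.18)
            bspec = BreathSpec(
                rr=rr,
                v_t=v_t,
                split=(p_rcp, g.p_rca, 1.0 - p_rcp - g.p_rca),
                rate_cv=g.rate_cv,
                noise_sigma=g.noise_sigma,
                duration_s=spec.duration_s,
                sample_rate=spec.sample_rate,
                seed=sub_seed,
            )
            traj, gt = simulate_breathing(torso, bspec)
            trajs.append(traj)
            row = {"subject_id": sid, "group": group, **gt}
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                fname = f"{sid}.csv"
                save_trajectories(traj, out_dir / fname)
                row["file"] = fname
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest, trajs
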