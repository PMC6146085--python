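"""Breath segmentation and breathing-pattern computation.

From the chest-wall volume trace, a stable window of quiet breathing (at
least 40 s by default) is selected, breaths are segmented between
end-expiratory troughs, and per-breath tidal volume and signed compartmental
contributions are computed.  The breathing pattern summarises the table:
respiratory rate RR = 60 / mean(T_tot), tidal volume V_T, minute ventilation
V_E = RR * V_T, rapid and shallow breathing index RSBi = RR / V_T, and the
mean percentage contributions of pulmonary ribcage and abdomen to V_T.

Paradoxical breathing — inspiratory inward motion of the pulmonary ribcage
while the chest wall expands — is flagged when the mean pulmonary-ribcage
percentage contribution is negative.

Detection details: extrema are found on a zero-phase low-pass filtered copy
of the trace (Butterworth, 2 Hz cutoff by default, covering respiratory
rates below 120 breaths/min), with a minimum prominence of 25% of the
window's median breath excursion and a minimum breath duration of 0.5 s.
Tidal quantities are read from the unfiltered series at the detected
instants, so filter attenuation never biases V_T; because the compartment
series sum to the chest-wall series sample by sample, the signed
contributions of a breath sum to exactly 100% of V_T.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientBreathsError, InsufficientDataError
from .surface_volume import CompartmentSeries

__all__ = [
    "BreathTable",
    "BreathingPattern",
    "select_stable_window",
    "segment_breaths",
    "breathing_pattern",
    "classify_paradox",
]

BREATH_COLUMNS = (
    "t_start",
    "t_peak",
    "t_end",
    "t_tot",
    "v_t",
    "dv_rcp",
    "dv_rca",
    "dv_ab",
    "pct_rcp",
    "pct_rca",
    "pct_ab",
)


@dataclass
class BreathTable:
    """Per-breath timings, tidal volume and compartment contributions.

    One row per breath, trough-to-trough.  ``v_t`` is the chest-wall volume
    excursion from the end-expiratory trough to the end-inspiratory peak;
    ``dv_*`` are the signed compartment changes over the same interval and
    ``pct_*`` their percentage of V_T (they sum to 100 by construction).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BREATH_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"breath table missing columns {missing}")

    @property
    def n_breaths(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class BreathingPattern:
    """Subject-level breathing-pattern summary."""

    rr: float            # breaths/min
    v_t: float           # L
    v_e: float           # L/min
    rsbi: float          # breaths/min/L
    pct_rcp: float       # mean % contribution of pulmonary ribcage
    pct_rca: float
    pct_ab: float
    paradox: bool
    n_breaths: int

    def to_dict(self) -> dict:
        return {
            "RR_per_min": self.rr,
            "V_T_L": self.v_t,
            "V_E_L_per_min": self.v_e,
            "RSBi_per_min_per_L": self.rsbi,
            "dV_RCp_pct_VT": self.pct_rcp,
            "dV_RCa_pct_VT": self.pct_rca,
            "dV_AB_pct_VT": self.pct_ab,
            "paradox": self.paradox,
            "n_breaths": self.n_breaths,
        }


# ---------------------------------------------------------------------------
# Extremum detection
# ---------------------------------------------------------------------------


def lowpass(v: np.ndarray, fs: float, cutoff_hz: float = 2.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    nyq = fs / 2.0
    if cutoff_hz >= 0.95 * nyq:
        return np.asarray(v, float).copy()
    b, a = signal.butter(4, cutoff_hz / nyq)
    return signal.filtfilt(b, a, np.asarray(v, float))


def _detect_extrema(
    vs: np.ndarray,
    fs: float,
    min_breath_s: float,
    prominence_frac: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Peaks and troughs of a smoothed trace.

    The prominence threshold is ``prominence_frac`` times the window's
    median breath excursion, estimated robustly as the difference between
    the median detected peak height and the median detected trough height
    in a first distance-only pass.
    """
    dist = max(1, int(round(min_breath_s * fs)))
    p0, _ = signal.find_peaks(vs, distance=dist)
    t0, _ = signal.find_peaks(-vs, distance=dist)
    if len(p0) == 0 or len(t0) == 0:
        return np.array([], int), np.array([], int), 0.0
    excursion = float(np.median(vs[p0]) - np.median(vs[t0]))
    if excursion <= 1e-9:  # below any physiological tidal excursion (L)
        return np.array([], int), np.array([], int), 0.0
    prom = prominence_frac * excursion
    peaks, _ = signal.find_peaks(vs, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-vs, distance=dist, prominence=prom)
    return peaks, troughs, prom


# ---------------------------------------------------------------------------
# Stable-window selection
# ---------------------------------------------------------------------------


def select_stable_window(
    series: CompartmentSeries,
    min_duration_s: float = 40.0,
    cutoff_hz: float = 2.0,
    min_breath_s: float = 0.5,
    prominence_frac: float = 0.25,
) -> tuple[float, float]:
    """Most regular contiguous window of at least *min_duration_s* seconds.

    Breaths are segmented provisionally over the whole recording; among all
    contiguous runs of breaths spanning at least *min_duration_s*, the one
    minimising the coefficient of variation of breath duration is returned
    (ties resolved toward the earliest window).  Deterministic for fixed
    input.
    """
    if series.duration < min_duration_s:
        raise InsufficientDataError(
            f"recording lasts {series.duration:.1f} s, "
            f"need at least {min_duration_s:.1f} s"
        )
    vs = lowpass(series.v_cw, series.sample_rate, cutoff_hz)
    peaks, troughs, _ = _detect_extrema(
        vs, series.sample_rate, min_breath_s, prominence_frac
    )
    starts, durations = _breath_bounds(series.time, peaks, troughs)
    n = len(durations)
    best: tuple[float, int, int] | None = None  # (cv, i, j) inclusive
    for i in range(n):
        for j in range(i + 1, n):
            span = starts[j] + durations[j] - starts[i]
            if span < min_duration_s:
                continue
            d = durations[i : j + 1]
            cv = float(np.std(d) / np.mean(d))
            if best is None or cv < best[0] - 1e-15:
                best = (cv, i, j)
    if best is None:
        raise InsufficientDataError(
            f"no contiguous run of breaths spans {min_duration_s:.1f} s"
        )
    _, i, j = best
    return float(starts[i]), float(starts[j] + durations[j])


def _breath_bounds(
    time: np.ndarray, peaks: np.ndarray, troughs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Start times and durations of trough-to-trough breaths containing a peak."""
    starts, durs = [], []
    for a, b in zip(troughs[:-1], troughs[1:]):
        if ((peaks > a) & (peaks < b)).any():
            starts.append(time[a])
            durs.append(time[b] - time[a])
    return np.asarray(starts), np.asarray(durs)


# ---------------------------------------------------------------------------
# Breath segmentation
# ---------------------------------------------------------------------------


def segment_breaths(
    series: CompartmentSeries,
    window: tuple[float, float] | None = None,
    cutoff_hz: float = 2.0,
    min_breath_s: float = 0.5,
    prominence_frac: float = 0.25,
    min_breaths: int = 3,
) -> BreathTable:
    """Segment the chest-wall trace into breaths within *window*.

    End-expiratory troughs and end-inspiratory peaks are identified on the
    low-pass filtered trace; each breath spans trough to trough and must
    contain a peak (the highest, if several).  V_T and the signed
    compartment changes are evaluated on the raw series between the trough
    and peak instants, so contributions sum to exactly 100% of V_T.
    """
    t = series.time
    if window is None:
        sel = np.ones(series.n_frames, bool)
    else:
        w0, w1 = window
        if w0 < t[0] - 1e-9 or w1 > t[-1] + 1.0 / series.sample_rate + 1e-9:
            raise InsufficientDataError(
                f"window ({w0:.2f}, {w1:.2f}) s outside recording "
                f"({t[0]:.2f}, {t[-1]:.2f}) s"
            )
        sel = (t >= w0 - 1e-9) & (t <= w1 + 1e-9)
    offset = int(np.flatnonzero(sel)[0])
    v = series.v_cw[sel]
    vs = lowpass(v, series.sample_rate, cutoff_hz)
    peaks, troughs, _ = _detect_extrema(
        vs, series.sample_rate, min_breath_s, prominence_frac
    )
    rows = []
    for a, b in zip(troughs[:-1], troughs[1:]):
        inside = peaks[(peaks > a) & (peaks < b)]
        if len(inside) == 0:
            continue
        p = inside[np.argmax(vs[inside])]
        ia, ip, ib = offset + a, offset + p, offset + b
        v_t = series.v_cw[ip] - series.v_cw[ia]
        if v_t <= 0:
            continue
        dv_rcp = series.v_rcp[ip] - series.v_rcp[ia]
        dv_rca = series.v_rca[ip] - series.v_rca[ia]
        dv_ab = series.v_ab[ip] - series.v_ab[ia]
        rows.append(
            {
                "t_start": t[ia],
                "t_peak": t[ip],
                "t_end": t[ib],
                "t_tot": t[ib] - t[ia],
                "v_t": v_t,
                "dv_rcp": dv_rcp,
                "dv_rca": dv_rca,
                "dv_ab": dv_ab,
                "pct_rcp": 100.0 * dv_rcp / v_t,
                "pct_rca": 100.0 * dv_rca / v_t,
                "pct_ab": 100.0 * dv_ab / v_t,
            }
        )
    if len(rows) < min_breaths:
        raise InsufficientBreathsError(
            f"found {len(rows)} complete breaths, need at least {min_breaths}"
        )
    return BreathTable(pd.DataFrame(rows, columns=list(BREATH_COLUMNS)))


# ---------------------------------------------------------------------------
# Pattern summary and paradox classification
# ---------------------------------------------------------------------------


def breathing_pattern(b: BreathTable) -> BreathingPattern:
    """RR, V_T, V_E, RSBi and mean contributions from a breath table."""
    if b.n_breaths == 0:
        raise InsufficientBreathsError("empty breath table")
    f = b.frame
    rr = 60.0 / float(f["t_tot"].mean())
    v_t = float(f["v_t"].mean())
    pct_rcp = float(f["pct_rcp"].mean())
    return BreathingPattern(
        rr=rr,
        v_t=v_t,
        v_e=rr * v_t,
        rsbi=rr / v_t,
        pct_rcp=pct_rcp,
        pct_rca=float(f["pct_rca"].mean()),
        pct_ab=float(f["pct_ab"].mean()),
        paradox=pct_rcp < 0.0,
        n_breaths=b.n_breaths,
    )


def classify_paradox(b: BreathTable) -> tuple[str, float]:
    """Classify paradoxical breathing from the mean pulmonary-ribcage
    percentage contribution: 'paradox' iff it is negative."""
    if b.n_breaths == 0:
        raise InsufficientBreathsError("empty breath table")
    mean_pct = float(b.frame["pct_rcp"].mean())
    return ("paradox" if mean_pct < 0.0 else "no_paradox", mean_pct)
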