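"""Tensile-test feature extraction for soft hydrated scaffolds.

Raw traction logs (time, actuator displacement, load-cell force) are
converted to engineering stress–strain curves: the zero-strain reference
is the first sample at which the force reaches the pre-tension load
(3 g by default, the regimen used for hydrated scaffold testing), stress
is force over the nominal initial cross-section pi*d^2/4, and strain is
displacement change over the gauge length.

The J-shaped curve is then segmented into toe / linear / yield regions
and a failure point, and three scalar features are extracted: the
viscoelastic modulus (least-squares slope of the linear region, per unit
strain), the maximum tensile strength, and the elongation at break.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import StressStrainCurve

__all__ = [
    "TractionLog",
    "MechanicalSummary",
    "InvalidTestError",
    "GRAVITY_M_PER_S2",
    "force_to_stress_kPa",
    "to_stress_strain",
    "segment_regions",
    "extract_summary",
    "analyze_log",
]

GRAVITY_M_PER_S2 = 9.80665


class InvalidTestError(ValueError):
    """The log never reaches pre-tension; no valid test occurred."""


@dataclass
class TractionLog:
    """Raw acquisition from the traction rig plus specimen geometry."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_N: np.ndarray
    gauge_length_mm: float
    diameter_mm: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=np.float64)
        self.force_N = np.asarray(self.force_N, dtype=np.float64)
        if not (len(self.time_s) == len(self.displacement_mm) == len(self.force_N)):
            raise ValueError("time, displacement and force must align")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.gauge_length_mm <= 0 or self.diameter_mm <= 0:
            raise ValueError("specimen geometry must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, gauge_length_mm: float,
                   diameter_mm: float, labels: dict | None = None) -> "TractionLog":
        return cls(df["time_s"].to_numpy(), df["displacement_mm"].to_numpy(),
                   df["force_N"].to_numpy(), gauge_length_mm=gauge_length_mm,
                   diameter_mm=diameter_mm, labels=dict(labels or {}))


@dataclass
class MechanicalSummary:
    modulus_kPa: float
    uts_kPa: float
    elongation_break_pct: float
    fit_r2: float
    labels: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def force_to_stress_kPa(force_N: float | np.ndarray,
                        diameter_mm: float) -> float | np.ndarray:
    """Engineering stress over the nominal circular cross-section pi d^2/4."""
    area_m2 = math.pi * (diameter_mm * 1e-3) ** 2 / 4.0
    return force_N / area_m2 / 1e3


def to_stress_strain(log: TractionLog, pretension_g: float = 3.0) -> StressStrainCurve:
    """Convert a traction log to an engineering stress–strain curve.

    Stress uses the nominal initial cross-section (no area tracking is
    possible on hydrated scaffolds in a PBS bath); strain is percent of
    the gauge length.  Both are referenced to the pre-tensioned state:
    the first sample at which the load reaches the pre-tension
    weight-equivalent defines zero strain, its force is the stress
    baseline, and earlier samples are discarded.
    """
    f_pre = pretension_g * 1e-3 * GRAVITY_M_PER_S2
    reached = np.nonzero(log.force_N >= f_pre)[0]
    if reached.size == 0:
        raise InvalidTestError(
            f"force never reached the {pretension_g} g pre-tension "
            f"({f_pre:.4g} N); invalid test")
    i0 = int(reached[0])
    strain = (log.displacement_mm[i0:] - log.displacement_mm[i0]) / log.gauge_length_mm * 100.0
    stress = force_to_stress_kPa(log.force_N[i0:] - f_pre, log.diameter_mm)
    return StressStrainCurve(
        strain_pct=strain,
        stress_kPa=stress,
        meta={"pretension_g": pretension_g, "start_index": i0,
              "gauge_length_mm": log.gauge_length_mm,
              "diameter_mm": log.diameter_mm, "labels": dict(log.labels)},
    )


def _smooth_stress(s: np.ndarray, win: int) -> np.ndarray:
    """Savitzky–Golay smoothing (cubic, edges fitted, not padded).

    Exact on piecewise-cubic noise-free curves away from the region
    joints, including the terminal sample, so smoothing never biases the
    peak of a clean curve; under noise it attenuates the running-max
    inflation that a raw maximum would suffer.
    """
    win = min(win if win % 2 == 1 else win + 1, s.size if s.size % 2 == 1 else s.size - 1)
    if win < 5:
        return s
    return signal.savgol_filter(s, win, polyorder=3, mode="interp")


def _rolling_linfit(x: np.ndarray, y: np.ndarray, win: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Slope and R² of y~x over every window [i, i+win); NaN when undefined."""
    n = x.size - win + 1
    z = np.zeros(1)

    def w(arr):
        s_ = np.concatenate([z, np.cumsum(arr)])
        return s_[win:win + n] - s_[:n]

    Sx, Sy, Sxx, Syy, Sxy = w(x), w(y), w(x * x), w(y * y), w(x * y)
    vxx = win * Sxx - Sx * Sx
    vyy = win * Syy - Sy * Sy
    vxy = win * Sxy - Sx * Sy
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(vxx > 0, vxy / np.where(vxx > 0, vxx, 1.0), np.nan)
        r2 = np.where((vxx > 0) & (vyy > 0),
                      vxy**2 / np.where(vxx * vyy > 0, vxx * vyy, 1.0), np.nan)
    r2 = np.where(np.isfinite(slope) & (vyy <= 0), 1.0, r2)  # flat y: perfect fit
    return slope, np.clip(r2, 0.0, 1.0)


def segment_regions(curve: StressStrainCurve, window_pct: float | None = None,
                    *, slope_tol: float = 0.02, r2_min: float = 0.99,
                    slope_quantile: float = 0.75,
                    failure_fraction: float = 0.30) -> dict:
    """Locate toe / linear / yield boundaries and the failure point.

    The linear region is found in two passes.  Detection: the longest
    contiguous run of sliding strain windows (width ``window_pct``,
    default one eighth of the observed span) whose local slope is within
    ``slope_tol`` of a reference plateau slope and whose local R² is at
    least ``r2_min``; the reference is the ``slope_quantile`` quantile of
    all window slopes, which equals the plateau slope on a clean curve
    but, unlike the maximum, is not inflated by noise.  Refinement: a
    line is fitted to the run's core and the boundaries are walked
    outward while the smoothed stress stays within a small
    deviation-from-linearity tolerance (tied to the fitted span and to
    the noise level via a robust MAD estimate), which locates the onset
    of toe and yield curvature to well under a window width.

    Toe runs from zero strain to the linear start; yield from the linear
    end to the stress peak.  Failure is the first sample where the
    smoothed stress drops more than ``failure_fraction`` below its
    running peak; if it never does, the last sample is taken as a
    censored end-of-course failure.

    Returns the boundaries in percent strain plus index bookkeeping and
    warning flags; results are attached to ``curve.regions``/``meta``.
    """
    e = np.asarray(curve.strain_pct, dtype=np.float64)
    s = np.asarray(curve.stress_kPa, dtype=np.float64)
    if e.size < 50:
        raise ValueError("need at least 50 samples to segment regions")
    flags: list[str] = []

    step = float(np.median(np.diff(e)))
    if window_pct is None:
        window_pct = float(e[-1] - e[0]) / 8.0
    win = max(int(round(window_pct / step)), 5)
    smooth = _smooth_stress(s, win)

    # failure: fractional drop from the running peak of the smoothed
    # trace; drops are only meaningful once the specimen has carried an
    # appreciable load (a quarter of the global peak), otherwise noise
    # around zero stress at the start of the test would qualify
    run_peak = np.maximum.accumulate(smooth)
    armed = run_peak > 0.25 * float(smooth.max())
    dropped = np.nonzero(armed & (smooth < (1.0 - failure_fraction) * run_peak))[0]
    if dropped.size:
        i_fail = int(dropped[0])
    else:
        i_fail = e.size - 1
        flags.append("end_of_course")

    ee, ss = e[: i_fail + 1], smooth[: i_fail + 1]
    n = ee.size
    win_eff = min(win, n - 1)
    slopes, r2s = _rolling_linfit(ee, ss, win_eff)

    valid = np.isfinite(slopes)
    if valid.any():
        m_ref = float(np.nanquantile(slopes[valid], slope_quantile))
        ok = valid & (slopes >= (1.0 - slope_tol) * m_ref) & (r2s >= r2_min)
    else:
        ok = np.zeros(slopes.size, dtype=bool)

    if ok.any():
        # longest contiguous run of qualifying window starts
        idx = np.nonzero(ok)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        j = int(np.argmax(ends - starts))
        r0 = int(idx[starts[j]])
        r1 = min(int(idx[ends[j]]) + win_eff - 1, n - 1)
        # refinement: trim half a window (curvature bleeds that far into
        # the run), fit the core, walk boundaries out to the onset of
        # systematic deviation from the fitted line
        tr = win_eff // 2
        i_lin0, i_lin1 = r0 + tr, r1 - tr
        if i_lin1 - i_lin0 < 5:
            i_lin0, i_lin1 = r0, r1
        a, b = np.polyfit(ee[i_lin0:i_lin1 + 1], ss[i_lin0:i_lin1 + 1], 1)
        dev = np.abs(ss - (a * ee + b))
        dcore = dev[i_lin0:i_lin1 + 1]
        mad = 1.4826 * float(np.median(np.abs(dcore - np.median(dcore))))
        theta = max(1.5e-3 * abs(a * (ee[i_lin1] - ee[i_lin0])),
                    4.0 * mad, 1e-12)
        while i_lin0 > 0 and dev[i_lin0 - 1] < theta:
            i_lin0 -= 1
        while i_lin1 < n - 1 and dev[i_lin1 + 1] < theta:
            i_lin1 += 1
    else:
        flags.append("no_plateau_fixed_window")
        warnings.warn("no linear plateau found; falling back to the fixed "
                      "3-6% strain window", stacklevel=2)
        i_lin0 = min(int(np.searchsorted(ee, 3.0)), max(n - 6, 0))
        i_lin1 = min(max(int(np.searchsorted(ee, 6.0)), i_lin0 + 5), n - 1)

    i_peak = int(np.argmax(ss))
    regions = {
        "toe_end": float(ee[i_lin0]),
        "linear_end": float(ee[i_lin1]),
        "yield_end": float(ee[i_peak]),
        "failure": float(e[i_fail]),
    }
    info = {
        **regions,
        "linear_slice": (i_lin0, i_lin1),
        "failure_index": i_fail,
        "peak_index": i_peak,
        "flags": flags,
        "smoothed_stress": smooth,
    }
    curve.regions = regions
    curve.meta["segmentation"] = info
    return info


def extract_summary(curve: StressStrainCurve,
                    segmentation: dict | None = None) -> MechanicalSummary:
    """Modulus, maximum tensile strength and elongation at break.

    Modulus is the least-squares slope of stress vs strain over the
    linear region, expressed per unit strain (fraction), so a curve
    gaining 10 kPa per percent strain reports 1000 kPa.
    """
    seg = segmentation or curve.meta.get("segmentation")
    if seg is None:
        raise ValueError("segment_regions must run before extract_summary")
    i0, i1 = seg["linear_slice"]
    if i1 - i0 < 5:
        raise ValueError("fewer than 5 samples in the linear region")
    e = np.asarray(curve.strain_pct, dtype=np.float64)
    s = np.asarray(curve.stress_kPa, dtype=np.float64)
    x = e[i0:i1 + 1] / 100.0  # strain as fraction
    y = s[i0:i1 + 1]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    i_fail = seg["failure_index"]
    s_eval = np.asarray(seg.get("smoothed_stress", s))
    return MechanicalSummary(
        modulus_kPa=float(slope),
        uts_kPa=float(s_eval[: i_fail + 1].max()),
        elongation_break_pct=float(e[i_fail]),
        fit_r2=float(min(max(r2, 0.0), 1.0)),
        labels=dict(curve.meta.get("labels", {})),
        flags=list(seg.get("flags", [])),
    )


def analyze_log(log: TractionLog, *, pretension_g: float = 3.0,
                window_pct: float = 1.0, failure_fraction: float = 0.30
                ) -> tuple[StressStrainCurve, MechanicalSummary]:
    """Full mechanics pipeline: log -> curve -> regions -> summary."""
    curve = to_stress_strain(log, pretension_g=pretension_g)
    seg = segment_regions(curve, window_pct=window_pct,
                          failure_fraction=failure_fraction)
    return curve, extract_summary(curve, seg)
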