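"""Verification of freeze-casting temperature logs against the nominal
profile (linear cooling ramp followed by an isothermal hold).

The ramp/hold split is taken from the *nominal* profile timing, not from
change-point detection on the noisy log, so jitter cannot move the
segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RampSpec

__all__ = ["RampReport", "verify_ramp"]


@dataclass
class RampReport:
    fitted_rate_C_per_min: float
    hold_mean_C: float
    hold_sd_C: float
    max_abs_deviation_C: float
    n_ramp: int
    n_hold: int
    passed: bool
    diagnostics: list = field(default_factory=list)


def verify_ramp(log: pd.DataFrame, nominal: RampSpec,
                tolerance_C: float = 1.0) -> RampReport:
    """Check a logged thermal profile against its nominal spec.

    Fits the cooling rate by least squares on the nominal ramp window,
    summarizes the hold plateau, and reports the maximum absolute
    deviation from the nominal profile.  Fails (with diagnostics) when
    that deviation exceeds ``tolerance_C``.
    """
    if len(log) < 2:
        raise ValueError("ramp log must contain at least 2 samples")
    t = log["time_s"].to_numpy(dtype=np.float64)
    temp = log["temp_C"].to_numpy(dtype=np.float64)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    ramp_s = nominal.ramp_duration_s
    in_ramp = t <= ramp_s
    in_hold = ~in_ramp
    diagnostics: list[str] = []
    if in_ramp.sum() >= 2:
        slope = np.polyfit(t[in_ramp], temp[in_ramp], 1)[0]
        fitted_rate = float(slope * 60.0)
    else:
        fitted_rate = float("nan")
        diagnostics.append("ramp segment too short to fit")
    if in_hold.any():
        hold_mean = float(temp[in_hold].mean())
        hold_sd = (float(temp[in_hold].std(ddof=1))
                   if in_hold.sum() > 1 else 0.0)
    else:
        hold_mean, hold_sd = float("nan"), float("nan")
        diagnostics.append("no hold segment in log")
    nominal_profile = np.where(
        in_ramp,
        nominal.start_temp_C + nominal.ramp_rate_C_per_min / 60.0 * t,
        nominal.hold_temp_C,
    )
    max_dev = float(np.abs(temp - nominal_profile).max())
    passed = max_dev <= tolerance_C
    if not passed:
        if in_hold.any() and abs(hold_mean - nominal.hold_temp_C) > tolerance_C:
            diagnostics.append(
                f"hold plateau offset: mean {hold_mean:.2f} C vs nominal "
                f"{nominal.hold_temp_C:.2f} C")
        diagnostics.append(
            f"max deviation {max_dev:.2f} C exceeds tolerance {tolerance_C} C")
    return RampReport(
        fitted_rate_C_per_min=fitted_rate,
        hold_mean_C=hold_mean,
        hold_sd_C=hold_sd,
        max_abs_deviation_C=max_dev,
        n_ramp=int(in_ramp.sum()),
        n_hold=int(in_hold.sum()),
        passed=passed,
        diagnostics=diagnostics,
    )
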