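"""Seeded synthetic fixtures with ground truth for every analysis stage.

Freeze-cast scaffolds are characterized from three kinds of raw data:
SEM micrographs of transversal cuts (lamellar, ovoid pores), SEM
micrographs of longitudinal cuts (aligned micro-channels), and traction
logs from tensile testing of hydrated specimens.  The generators here
emulate the statistical structure of each — log-normal pore areas with a
controlled bounding-box aspect ratio, periodic stripe textures at a known
angle, J-shaped stress–strain curves with toe/linear/yield regions, and
the freeze-casting temperature ramp — so that every downstream stage can
be validated against known truth without any acquired data.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PoreFieldSpec",
    "ChannelFieldSpec",
    "CurveSpec",
    "RampSpec",
    "PackingError",
    "InconsistentCurveSpec",
    "gen_pore_field",
    "gen_channel_field",
    "gen_stress_strain",
    "gen_temperature_log",
    "sample_curve_specs",
    "draw_pore_geometry",
    "rasterize_truth",
    "curve_to_traction_log",
]

# 8-bit intensity levels for the two phases of a noise-free micrograph.
_PORE_LEVEL = 40
_MATRIX_LEVEL = 220


class PackingError(RuntimeError):
    """Non-overlapping pore placement failed within the attempt budget."""


class InconsistentCurveSpec(ValueError):
    """Stress–strain spec whose target strength is unreachable."""


# ---------------------------------------------------------------------------
# Pore fields (transversal cuts)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoreFieldSpec:
    """Parameters of a synthetic transversal-cut pore field.

    Pores are rendered as ellipses (the real lamellar pores are ovoid).
    Areas are drawn log-normal with parameters ``area_mu``/``area_sigma``
    on the log scale of µm²; the bounding-box aspect ratio (width/height)
    is drawn normal and truncated to stay positive.  ``orientation_deg``
    rotates the major axis (90° = vertical, matching the lamellae of a
    bottom-up freeze; aspect ratios below 1 then mean taller-than-wide
    pores, as observed on real scaffolds with mean ratio ~0.67).
    """

    image_size: tuple[int, int] = (512, 512)  # (height, width) px
    pixel_scale: float = 2.0                  # µm / pixel
    n_pores: int = 80
    area_mu: float = 7.5                      # log µm² (median ~1800 µm²)
    area_sigma: float = 0.6
    aspect_mean: float = 0.67                 # bbox width / height
    aspect_sd: float = 0.2
    orientation_deg: float = 90.0             # major-axis angle
    allow_overlap: bool = False
    noise_sd: float = 0.0                     # intensity noise (8-bit units)
    dark_pores: bool = True
    seed: int = 0

    margin_px: int = 2          # dilation margin separating pores
    max_attempts: int = 10_000  # placement attempts per pore

    def validate(self) -> None:
        h, w = self.image_size
        if h < 2 or w < 2:
            raise ValueError("image_size must be at least 2x2")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.n_pores < 0:
            raise ValueError("n_pores must be non-negative")
        if self.area_sigma < 0 or self.aspect_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def draw_pore_geometry(spec: PoreFieldSpec) -> pd.DataFrame:
    """Draw per-pore analytic geometry (no rasterization, no placement).

    Returns a frame with the log-normal areas (µm²), truncated-normal
    aspect ratios and the ellipse semi-axes in pixels.  Used internally
    by :func:`gen_pore_field` and directly for distributional checks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    area_um2 = rng.lognormal(spec.area_mu, spec.area_sigma, size=spec.n_pores)
    aspect = rng.normal(spec.aspect_mean, spec.aspect_sd, size=spec.n_pores)
    # truncate: redraw non-positive ratios (rare for realistic params)
    bad = aspect <= 0.05
    while bad.any():
        aspect[bad] = rng.normal(spec.aspect_mean, spec.aspect_sd, size=int(bad.sum()))
        bad = aspect <= 0.05
    area_px = area_um2 / spec.pixel_scale**2
    # ellipse with semi-axes a (major) and b: area = pi*a*b; at orientation
    # 90 deg the bbox is 2b wide x 2a tall so aspect = b/a
    theta = math.radians(spec.orientation_deg)
    # solve semi-axes from area and *bbox* aspect at angle theta:
    #   half-width  W = sqrt(a^2 cos^2 t + b^2 sin^2 t) with t = angle of
    #   the major axis from vertical... use the closed form below.
    ct2 = math.cos(theta) ** 2
    st2 = math.sin(theta) ** 2
    # bbox half extents for semi-axes (a along theta, b perpendicular):
    #   W^2 = a^2 ct2 + b^2 st2,  H^2 = a^2 st2 + b^2 ct2
    # choose b = k*a; aspect r = W/H -> r^2 = (ct2 + k^2 st2)/(st2 + k^2 ct2)
    r2 = aspect**2
    denom = r2 * ct2 - st2
    num = ct2 - r2 * st2
    with np.errstate(divide="ignore", invalid="ignore"):
        k2 = np.where(np.abs(denom) > 1e-12, num / denom, np.nan)
    # infeasible aspect at this angle (k^2 <= 0): fall back to axis-aligned
    k2 = np.where((k2 > 0) & np.isfinite(k2), k2, aspect**2)
    k = np.sqrt(k2)
    a = np.sqrt(area_px / (math.pi * k))
    b = k * a
    return pd.DataFrame(
        {
            "area_um2": area_um2,
            "aspect_ratio": aspect,
            "semi_major_px": a,
            "semi_minor_px": b,
            "theta_deg": np.full(spec.n_pores, spec.orientation_deg),
        }
    )


def _ellipse_patch(h: int, w: int, cy: float, cx: float, a: float, b: float,
                   theta_deg: float, pad: int = 0
                   ) -> tuple[int, int, np.ndarray]:
    """Ellipse raster restricted to its bounding patch (plus ``pad``).

    Returns ``(r0, c0, submask)``; pixel centers inside the boundary are
    true.  ``theta_deg`` is the major-axis angle in the analysis
    convention (0° horizontal, 90° vertical, y pointing up).
    """
    r = max(a, b) + pad + 1.0
    r0 = max(int(math.floor(cy - r)), 0)
    r1 = min(int(math.ceil(cy + r)) + 1, h)
    c0 = max(int(math.floor(cx - r)), 0)
    c1 = min(int(math.ceil(cx + r)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return 0, 0, np.zeros((0, 0), dtype=bool)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    t = math.radians(theta_deg)
    dx = xx - cx
    dy = -(yy - cy)  # flip rows so angles follow the y-up convention
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return r0, c0, (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _ellipse_mask(h: int, w: int, cy: float, cx: float, a: float, b: float,
                  theta_deg: float) -> np.ndarray:
    """Full-frame boolean raster of the ellipse (pixel-center inclusion)."""
    out = np.zeros((h, w), dtype=bool)
    r0, c0, sub = _ellipse_patch(h, w, cy, cx, a, b, theta_deg)
    if sub.size:
        out[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]] = sub
    return out


def rasterize_truth(truth: pd.DataFrame, image_size: tuple[int, int]) -> np.ndarray:
    """Re-render the foreground mask from a ground-truth table.

    Uses the identical pixel-center inclusion rule as the generator, so
    for non-overlapping noise-free fields the result equals the image's
    pore mask exactly.
    """
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    for row in truth.itertuples():
        mask |= _ellipse_mask(h, w, row.center_row, row.center_col,
                              row.semi_major_px, row.semi_minor_px, row.theta_deg)
    return mask


def gen_pore_field(spec: PoreFieldSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a grayscale pore-field image plus its ground-truth table.

    Returns ``(image, truth)`` where image is uint8 (dark pores on a
    bright matrix by default) and truth holds one row per pore with both
    the analytic draw (``area_um2``, ``aspect_ratio``) and the rasterized
    geometry (``area_px``, pixel bounding box, ``bbox_aspect``).

    Raises
    ------
    PackingError
        if ``allow_overlap`` is false and a pore cannot be placed within
        ``max_attempts`` random positions.
    """
    spec.validate()
    h, w = spec.image_size
    geom = draw_pore_geometry(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    occupied = np.zeros((h, w), dtype=bool)
    mask = np.zeros((h, w), dtype=bool)
    rows = []
    struct = ndimage.generate_binary_structure(2, 2)  # 8-connected margin
    for i, g in enumerate(geom.itertuples()):
        placed = False
        for _ in range(spec.max_attempts):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            r0, c0, sub = _ellipse_patch(h, w, cy, cx, g.semi_major_px,
                                         g.semi_minor_px, g.theta_deg,
                                         pad=spec.margin_px)
            if not sub.any():
                continue  # fell entirely outside the frame
            if not spec.allow_overlap:
                grown = ndimage.binary_dilation(sub, structure=struct,
                                                iterations=spec.margin_px)
                occ = occupied[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]]
                if (grown & occ).any():
                    continue
                occ |= grown
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place pore {i + 1}/{spec.n_pores} after "
                f"{spec.max_attempts} attempts; reduce n_pores or areas"
            )
        m = np.zeros((h, w), dtype=bool)
        m[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]] = sub
        mask |= m
        ys, xs = np.nonzero(m)
        bw = int(xs.max() - xs.min() + 1)
        bh = int(ys.max() - ys.min() + 1)
        rows.append(
            {
                "pore_id": i + 1,
                "center_row": cy,
                "center_col": cx,
                "semi_major_px": g.semi_major_px,
                "semi_minor_px": g.semi_minor_px,
                "theta_deg": g.theta_deg,
                "area_um2": g.area_um2,
                "aspect_ratio": g.aspect_ratio,
                "area_px": int(m.sum()),
                "area_raster_um2": float(m.sum()) * spec.pixel_scale**2,
                "bbox_w_px": bw,
                "bbox_h_px": bh,
                "bbox_aspect": bw / bh,
                "touches_border": bool(
                    ys.min() == 0 or xs.min() == 0
                    or ys.max() == h - 1 or xs.max() == w - 1
                ),
            }
        )

    columns = ["pore_id", "center_row", "center_col", "semi_major_px",
               "semi_minor_px", "theta_deg", "area_um2", "aspect_ratio",
               "area_px", "area_raster_um2", "bbox_w_px", "bbox_h_px",
               "bbox_aspect", "touches_border"]
    truth = pd.DataFrame(rows, columns=columns)

    pore_level, matrix_level = (
        (_PORE_LEVEL, _MATRIX_LEVEL) if spec.dark_pores
        else (_MATRIX_LEVEL, _PORE_LEVEL)
    )
    img = np.where(mask, pore_level, matrix_level).astype(np.float64)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


# ---------------------------------------------------------------------------
# Channel fields (longitudinal cuts)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelFieldSpec:
    """Periodic stripe texture emulating aligned micro-channels.

    ``stripe_angle_deg`` is the direction of the stripes on the 0–180°
    scale used throughout (90° = vertical channels, 0°/180° = horizontal).
    Stripe edges are anti-aliased over ~1.5 px so angled stripes do not
    produce staircase gradients.
    """

    image_size: tuple[int, int] = (256, 256)
    stripe_angle_deg: float = 90.0
    stripe_period: float = 16.0   # px
    duty_cycle: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0
    edge_width: float = 1.5       # px, anti-aliasing ramp

    def validate(self) -> None:
        if not (0.0 <= self.stripe_angle_deg < 180.0):
            raise ValueError("stripe_angle_deg must lie in [0, 180)")
        if self.stripe_period < 2:
            raise ValueError("stripe_period must be at least 2 px")
        if not (0.0 < self.duty_cycle < 1.0):
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_channel_field(spec: ChannelFieldSpec) -> np.ndarray:
    """Generate a uint8 stripe texture at the requested angle."""
    spec.validate()
    h, w = spec.image_size
    t = math.radians(spec.stripe_angle_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    # coordinate perpendicular to the stripes (y up so 90 deg = vertical)
    u = -xx * math.sin(t) + (-yy) * math.cos(t)
    phase = np.mod(u, spec.stripe_period)
    half = spec.duty_cycle * spec.stripe_period
    # signed distance (px) to the nearest stripe edge, >0 inside a stripe
    d = np.minimum(phase, half - phase)
    d = np.where(phase <= half, np.minimum(phase, half - phase),
                 -np.minimum(phase - half, spec.stripe_period - phase))
    level = np.clip(0.5 + d / spec.edge_width, 0.0, 1.0)
    img = _PORE_LEVEL + level * (_MATRIX_LEVEL - _PORE_LEVEL)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stress–strain curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveSpec:
    """Parameters of a synthetic J-shaped tensile curve.

    The curve has the canonical soft-tissue layout: a convex toe region
    where the slope ramps quadratically up to the modulus, a linear
    elastic region at constant slope, and a yield region where the slope
    decays (defibrillation) until the stress peaks at ``uts_kPa`` at the
    break strain, where the test ends.  Strains are engineering strain in
    percent; the modulus is expressed per unit strain (fraction), the
    convention in which a 1000 kPa modulus gives 10 kPa per % strain.
    """

    modulus_kPa: float = 2000.0
    uts_kPa: float = 100.0
    break_strain_pct: float = 8.0
    toe_end_pct: float = 3.0
    linear_end_pct: float = 6.0
    yield_end_pct: float = 7.0
    sample_rate_hz: float = 100.0
    strain_rate_pct_per_s: float = 1.0
    noise_sd_kPa: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.toe_end_pct < self.linear_end_pct
                < self.yield_end_pct <= self.break_strain_pct):
            raise ValueError("region boundaries must satisfy "
                             "0 < toe < linear < yield <= break")
        if self.modulus_kPa <= 0 or self.uts_kPa <= 0:
            raise ValueError("modulus and uts must be positive")
        if self.sample_rate_hz <= 0 or self.strain_rate_pct_per_s <= 0:
            raise ValueError("rates must be positive")
        if self.noise_sd_kPa < 0:
            raise ValueError("noise_sd_kPa must be non-negative")


@dataclass
class StressStrainCurve:
    """Engineering stress–strain series with annotated region boundaries.

    ``regions`` maps ``toe_end``/``linear_end``/``yield_end``/``failure``
    to strains in percent.  ``meta`` carries provenance (specimen labels,
    flags such as censored end-of-course failures).
    """

    strain_pct: np.ndarray
    stress_kPa: np.ndarray
    regions: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain_pct": self.strain_pct,
                             "stress_kPa": self.stress_kPa})


def _curve_stress(strain_pct: np.ndarray, spec: CurveSpec) -> tuple[np.ndarray, float]:
    """Noise-free stress (kPa) at the given strains, plus the yield-slope.

    Slope profile m(e) (kPa per % strain), with E = modulus/100:
      toe   [0, t]:   m = E (e/t)^2          (convex, continuous at t)
      lin   [t, l]:   m = E
      yield [l, y]:   m falls linearly E -> m_y
      tail  [y, B]:   m = m_y (constant)
    m_y is solved so the stress reaches uts exactly at B.
    """
    t, l, y, B = (spec.toe_end_pct, spec.linear_end_pct,
                  spec.yield_end_pct, spec.break_strain_pct)
    E = spec.modulus_kPa / 100.0  # kPa per % strain
    s_t = E * t / 3.0
    s_l = s_t + E * (l - t)
    gain = spec.uts_kPa - s_l
    denom = (y - l) / 2.0 + (B - y)
    if denom > 0:
        m_y = (gain - E * (y - l) / 2.0) / denom
    else:  # y == B: slope ramps linearly from E to m_y over [l, B]
        m_y = 2.0 * gain / (B - l) - E
    if m_y < -1e-12 or m_y > E * (1 + 1e-12):
        raise InconsistentCurveSpec(
            f"uts {spec.uts_kPa} kPa unreachable with modulus "
            f"{spec.modulus_kPa} kPa and the given region boundaries "
            f"(implied yield-end slope {m_y * 100:.1f} kPa)"
        )
    m_y = min(max(m_y, 0.0), E)

    e = np.asarray(strain_pct, dtype=np.float64)
    stress = np.empty_like(e)
    # piecewise integrals of the slope profile
    in_toe = e <= t
    stress[in_toe] = E * e[in_toe] ** 3 / (3 * t**2)
    in_lin = (e > t) & (e <= l)
    stress[in_lin] = s_t + E * (e[in_lin] - t)
    in_yld = (e > l) & (e <= y)
    d = e[in_yld] - l
    stress[in_yld] = s_l + E * d - (E - m_y) * d**2 / (2 * (y - l))
    s_y = s_l + (E + m_y) * (y - l) / 2.0
    in_tail = e > y
    stress[in_tail] = s_y + m_y * (e[in_tail] - y)
    return stress, m_y * 100.0


def gen_stress_strain(spec: CurveSpec) -> StressStrainCurve:
    """Generate a sampled synthetic tensile curve with truth annotations."""
    spec.validate()
    step = spec.strain_rate_pct_per_s / spec.sample_rate_hz
    n = int(round(spec.break_strain_pct / step))
    strain = np.arange(n + 1) * step
    stress, tail_slope = _curve_stress(strain, spec)
    if spec.noise_sd_kPa > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sd_kPa, size=stress.shape)
    return StressStrainCurve(
        strain_pct=strain,
        stress_kPa=stress,
        regions={
            "toe_end": spec.toe_end_pct,
            "linear_end": spec.linear_end_pct,
            "yield_end": spec.yield_end_pct,
            "failure": spec.break_strain_pct,
        },
        meta={"source": "synthetic", "spec": spec, "tail_slope_kPa": tail_slope},
    )


def sample_curve_specs(n: int, seed: int, *,
                       modulus_range_kPa: tuple[float, float] = (500.0, 4000.0),
                       uts_range_kPa: tuple[float, float] = (50.0, 150.0),
                       noise_frac_max: float = 0.05) -> list[CurveSpec]:
    """Draw ``n`` mutually consistent curve specs spanning the given ranges.

    Modulus and strength are drawn independently and uniformly; because
    an arbitrary (modulus, uts) pair is not reachable under a fixed
    region layout, the canonical layout (toe 0–3%, linear 3–6%, yield
    6–7%, break 8%) is scaled geometrically by c = uts / (5 E) with E in
    kPa per % strain, which places the strength at the midpoint of the
    feasible band for every draw.  Stress noise SD is uniform on
    [0, noise_frac_max * uts].
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        e_mod = rng.uniform(*modulus_range_kPa)
        uts = rng.uniform(*uts_range_kPa)
        c = uts / (5.0 * e_mod / 100.0)
        specs.append(CurveSpec(
            modulus_kPa=e_mod,
            uts_kPa=uts,
            toe_end_pct=3.0 * c,
            linear_end_pct=6.0 * c,
            yield_end_pct=7.0 * c,
            break_strain_pct=8.0 * c,
            noise_sd_kPa=rng.uniform(0.0, noise_frac_max * uts),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs


def curve_to_traction_log(curve: StressStrainCurve, *, gauge_length_mm: float,
                          diameter_mm: float, pretension_g: float = 3.0,
                          pretension_rate_g_per_s: float = 1.0,
                          sample_rate_hz: float = 100.0) -> pd.DataFrame:
    """Fabricate a raw traction log (time, displacement, force) from a curve.

    Prepends the pre-tension phase (force ramp at ``pretension_rate_g_per_s``
    with no net strain) so the log exercises the same zero-reference logic
    as an acquired one.  Inverse of the stress–strain conversion: feeding
    the result back recovers the curve to numerical precision.
    """
    g = 9.80665
    area_m2 = math.pi * (diameter_mm * 1e-3) ** 2 / 4.0
    f_pre = pretension_g * 1e-3 * g
    n_pre = int(round(pretension_g / pretension_rate_g_per_s * sample_rate_hz))
    t_pre = np.arange(n_pre) / sample_rate_hz
    f_ramp = (t_pre / t_pre[-1] if n_pre > 1 else np.ones(n_pre)) * f_pre * (
        1 - 1e-9)  # stay just under the trigger until the test proper
    force_curve = curve.stress_kPa * 1e3 * area_m2 + f_pre
    disp_curve = curve.strain_pct / 100.0 * gauge_length_mm
    t_curve = t_pre[-1] + 1.0 / sample_rate_hz + np.arange(len(disp_curve)) / sample_rate_hz if n_pre else np.arange(len(disp_curve)) / sample_rate_hz
    return pd.DataFrame(
        {
            "time_s": np.concatenate([t_pre, t_curve]),
            "displacement_mm": np.concatenate([np.zeros(n_pre), disp_curve]),
            "force_N": np.concatenate([f_ramp, force_curve]),
        }
    )


# ---------------------------------------------------------------------------
# Freeze-casting temperature ramps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RampSpec:
    """Nominal freeze-casting thermal profile.

    Default is the process used for the scaffolds: a −1 °C/min ramp from
    room temperature down to −40 °C, held for 90 min, logged at 10 Hz by
    the mold-base RTD probe.
    """

    start_temp_C: float = 20.0
    ramp_rate_C_per_min: float = -1.0
    hold_temp_C: float = -40.0
    hold_min: float = 90.0
    log_rate_hz: float = 10.0
    control_noise_sd_C: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.ramp_rate_C_per_min >= 0:
            raise ValueError("ramp_rate_C_per_min must be negative")
        if self.hold_temp_C >= self.start_temp_C:
            raise ValueError("hold_temp_C must be below start_temp_C")
        if self.log_rate_hz <= 0:
            raise ValueError("log_rate_hz must be positive")
        if self.hold_min < 0 or self.control_noise_sd_C < 0:
            raise ValueError("hold_min and noise must be non-negative")

    @property
    def ramp_duration_s(self) -> float:
        return (self.hold_temp_C - self.start_temp_C) / (
            self.ramp_rate_C_per_min / 60.0)


def gen_temperature_log(spec: RampSpec) -> pd.DataFrame:
    """Generate a (time_s, temp_C) log for the nominal profile + jitter."""
    spec.validate()
    ramp_s = spec.ramp_duration_s
    total_s = ramp_s + spec.hold_min * 60.0
    n = int(round(total_s * spec.log_rate_hz))
    t = np.arange(n + 1) / spec.log_rate_hz
    temp = np.where(
        t <= ramp_s,
        spec.start_temp_C + spec.ramp_rate_C_per_min / 60.0 * t,
        spec.hold_temp_C,
    )
    if spec.control_noise_sd_C > 0:
        rng = np.random.default_rng(spec.seed)
        temp = temp + rng.normal(0.0, spec.control_noise_sd_C, size=temp.shape)
    return pd.DataFrame({"time_s": t, "temp_C": temp})
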