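"""Surface-displacement reconstruction from 8x8 time-of-flight frames.

Two multi-zone ToF sensors flank the indenter tip, each tilted 12 degrees
to the observation plane with 35.1 mm standoff and a 63-degree diagonal
field of view.  The fifth zone row (from the anterior) of each sensor gives
eight measuring points per side in the transverse plane.  After discarding
points inside 0.9 of the tip radius, each side is described by a cubic fit
``v(x)`` anchored at the indenter tip and supported by three base points on
the reference plane, whose position ``x_B`` is selected by minimizing the
cost ``Theta(x_B) = RMSE(v) + Q`` (``Q`` rewards fits that return to the
reference plane close to the indenter).  The region mean surface
displacement ``u(x)`` is a cubic over both (mirrored) sides with
intersection bounds ``x_min`` (indenter tip) and ``x_max`` (reference
plane), completed by the tip profile and the undeformed plane into a
continuous profile on ``0 <= x <= r_C = 110 mm``.

Coordinates: ``x`` is the radial distance from the indenter axis (mm), the
``z`` axis points up, the undeformed skin surface (reference plane) is at
``z = 0`` and indentation displaces in ``-z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq

__all__ = [
    "R_TIP",
    "R_CYL",
    "SensorGeometry",
    "ToFFrame",
    "TransversePoints",
    "SideProfileFit",
    "MeanSurfaceDisplacement",
    "IndenterTipProfile",
    "tip_profile_z",
    "preprocess_frames",
    "to_transverse_points",
    "side_profile_fit",
    "mean_surface_displacement",
    "compose_full_profile",
]

R_TIP = 10.0  # indenter tip radius, mm
R_CYL = 110.0  # lateral extent of the evaluation domain (r_t + 100), mm
DISCARD_FACTOR = 0.9  # raw points within 0.9*r_t of the axis are distorted
BASE_INTERVAL = 8.0  # mm, span of the three reference-plane base points
SWEEP_STEP = 5.0  # mm, base-point sweep step
PENALTY_NO_ROOT = 10.0
PENALTY_WEIGHT = 0.75


@dataclass(frozen=True)
class SensorGeometry:
    """Pose and optics of one ToF sensor (shared with the synthetic renderer).

    The sensor sits ``standoff_mm`` above the reference plane, laterally
    offset from the indenter axis, and is tilted ``tilt_deg`` outward about
    the anterior (y) axis.  The 8x8 zone grid subdivides the frustum
    uniformly in angle; the diagonal field of view is 63 degrees, i.e.
    ``63 / sqrt(2)`` per axis.  Zone rows run along the anterior axis and
    the fifth row (index 4) is used for transverse profiles.
    """

    side: str  # "left" | "right"
    tilt_deg: float = 12.0
    standoff_mm: float = 35.1
    fov_diag_deg: float = 63.0
    lateral_offset_mm: float = 10.0
    n_zones: int = 8
    rate_hz: float = 15.0
    profile_row: int = 4

    @property
    def sign(self) -> float:
        return -1.0 if self.side == "left" else 1.0

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.sign * self.lateral_offset_mm, 0.0, self.standoff_mm])

    def zone_directions(self) -> np.ndarray:
        """Unit ray directions, shape (rows, cols, 3), world coordinates."""
        per_axis = np.deg2rad(self.fov_diag_deg / np.sqrt(2.0))
        centers = (np.arange(self.n_zones) - (self.n_zones - 1) / 2.0) * (
            per_axis / self.n_zones
        )
        th_x, th_y = np.meshgrid(centers, centers, indexing="xy")  # [row, col]
        d = np.stack([np.tan(th_x), np.tan(th_y), -np.ones_like(th_x)], axis=-1)
        d /= np.linalg.norm(d, axis=-1, keepdims=True)
        t = -self.sign * np.deg2rad(self.tilt_deg)  # boresight tilts outward
        rot = np.array(
            [[np.cos(t), 0.0, np.sin(t)], [0.0, 1.0, 0.0], [-np.sin(t), 0.0, np.cos(t)]]
        )
        return d @ rot.T


@dataclass(frozen=True)
class ToFFrame:
    """One 8x8 distance frame of a sensor."""

    sensor_side: str
    timestamp: float  # s
    distances: np.ndarray  # (8, 8), mm
    rate: float = 15.0  # Hz, nominal

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (8, 8):
            raise ValueError("distances must be an 8x8 array")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("distances must be positive and finite")
        object.__setattr__(self, "distances", d)


@dataclass(frozen=True)
class TransversePoints:
    """Row-5 measuring points of one side in the transverse plane."""

    side: str
    x: np.ndarray  # mm, radial distance from the indenter axis, increasing
    z: np.ndarray  # mm, displacement relative to the reference plane
    delta_i: float = float("nan")

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class SideProfileFit:
    """Cubic side profile selected by the base-point cost function."""

    side: str
    delta_i: float
    coefficients: tuple  # cubic, descending powers
    x_b: float  # chosen base-point anchor, mm
    theta: float  # cost value
    x_xmax: float | None  # intersection with the reference plane, if any
    x_inner: float  # anchor abscissa (innermost support)
    penalized: bool = False  # no real root below r_C

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


@dataclass(frozen=True)
class MeanSurfaceDisplacement:
    """Region-mean cubic displacement profile at one indentation depth."""

    region_id: str
    delta_i: float
    coefficients: tuple  # u_1..u_4, descending
    x_min: float  # intersection with the indenter tip, mm
    x_max: float  # positive root on the reference plane, mm
    f_star: float  # reference indentation force, N

    def __call__(self, x):
        return np.polyval(self.coefficients, x)


@dataclass(frozen=True)
class IndenterTipProfile:
    """Hemispherical tip (radius 10 mm) with 20 mm cylindrical extension."""

    r_t: float = R_TIP
    cylinder_extension: float = 20.0
    delta: float = 0.0

    def z(self, x):
        return tip_profile_z(x, self.delta, self.r_t)


def tip_profile_z(x, delta: float, r_t: float = R_TIP):
    """Height of the indenter tip surface at radius ``|x| <= r_t``.

    ``z(x) = -delta + (r_t - sqrt(r_t^2 - x^2))``; the deepest point is the
    apex, ``z(0) = -delta``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > r_t + 1e-9):
        raise ValueError("tip profile defined only for |x| <= r_t")
    out = -delta + (r_t - np.sqrt(np.maximum(r_t**2 - x**2, 0.0)))
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------- frames
def preprocess_frames(frames: Sequence[ToFFrame], grid_dt: float = 0.1):
    """Smooth zone values and resample the stream to a uniform 0.1 s grid.

    Each zone value is replaced by the mean over a length-5 sliding window
    along its zone row, then every zone is linearly interpolated in time to
    a common ``grid_dt`` grid.  Raises on gaps longer than 1 s.
    """
    frames = sorted(frames, key=lambda f: f.timestamp)
    if not frames:
        raise ValueError("no frames")
    t = np.array([f.timestamp for f in frames])
    if np.any(np.diff(t) > 1.0):
        raise ValueError("gap longer than 1 s in the frame stream")
    side = frames[0].sensor_side
    data = np.stack([f.distances for f in frames])  # (nt, 8, 8)
    data = uniform_filter1d(data, size=5, axis=2, mode="nearest")
    if len(frames) == 1:
        return [ToFFrame(side, float(t[0]), data[0], frames[0].rate)]
    t_new = np.arange(t[0], t[-1] + 1e-9, grid_dt)
    interp = interp1d(t, data, axis=0)
    out = interp(np.clip(t_new, t[0], t[-1]))
    return [
        ToFFrame(side, float(tn), out[k], frames[0].rate) for k, tn in enumerate(t_new)
    ]


def _frame_points(frame: ToFFrame, geometry: SensorGeometry):
    """Row-5 world points (radial distance, z) of a frame."""
    dirs = geometry.zone_directions()[geometry.profile_row]  # (8, 3)
    d = frame.distances[geometry.profile_row][:, None]
    pts = geometry.origin[None, :] + d * dirs
    x = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(x)
    return x[order], pts[order, 2]


def to_transverse_points(
    frame: ToFFrame,
    geometry: SensorGeometry,
    reference_frame: ToFFrame,
    delta_i: float = float("nan"),
) -> TransversePoints:
    """Convert a row-5 frame into transverse ``(x, z)`` displacement points.

    ``z`` is measured relative to the reference (zero-position) frame,
    interpolated to the current points' radial positions, so a frame equal
    to the reference maps to ``z = 0`` everywhere.
    """
    if reference_frame is None:
        raise ValueError("a reference frame at the zero position is required")
    x, z = _frame_points(frame, geometry)
    x_ref, z_ref = _frame_points(reference_frame, geometry)
    ref = interp1d(x_ref, z_ref, fill_value="extrapolate")
    return TransversePoints(side=frame.sensor_side, x=x, z=z - ref(x), delta_i=delta_i)


# ----------------------------------------------------- side profile fitting
def _anchor_points(left: TransversePoints, right: TransversePoints, delta_i: float):
    """Intersections of the inner-point chord with the tip profile.

    The straight line joining the innermost remaining left and right points
    (left side mirrored to negative x) is intersected with the indenter tip
    profile at depth ``delta_i``, yielding one anchor per side (returned
    with positive radial abscissae).
    """
    xl, zl = -left.x[0], left.z[0]
    xr, zr = right.x[0], right.z[0]
    slope = (zr - zl) / (xr - xl)
    inter = zl - slope * xl

    def g(x):
        return slope * x + inter - tip_profile_z(x, delta_i)

    anchors = {}
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        lo, hi = min(1e-6 * sgn, sgn * R_TIP), max(1e-6 * sgn, sgn * R_TIP)
        if g(lo) * g(hi) <= 0:
            root = brentq(g, lo, hi)
        else:
            root = sgn * R_TIP  # chord passes above the equator: anchor at the wall
        anchors[side] = (abs(root), slope * root + inter)
    return anchors


def side_profile_fit(
    points: TransversePoints,
    delta_i: float,
    opposite: TransversePoints | None = None,
) -> SideProfileFit:
    """Select the cubic side profile minimizing ``Theta(x_B) = RMSE + Q``.

    Points with ``x <= 0.9 r_t`` are discarded; the anchor on the indenter
    tip comes from the chord through the innermost left/right points (the
    side itself is mirrored when no opposite side is given).  For every
    candidate ``x_B`` (swept in 5 mm steps from the outermost point,
    inclusive, to ``r_C``) a cubic is fitted through the anchor, the
    measuring points and three equally spaced base points at ``z = 0``
    within an 8 mm interval ending at ``x_B``.  The RMSE is evaluated over
    the measuring points only; ``Q = 0.75 x_xmax / r_C`` when the cubic
    returns to the reference plane within ``r_C``, else 10.  Ties prefer
    the smaller ``x_B`` (most compact deformation).
    """
    keep = points.x > DISCARD_FACTOR * R_TIP
    x, z = points.x[keep], points.z[keep]
    if x.size < 3:
        raise ValueError("fewer than 3 points outside the discard zone")
    trimmed = TransversePoints(points.side, x, z, delta_i)
    if opposite is not None:
        ok = opposite.x > DISCARD_FACTOR * R_TIP
        other = TransversePoints(opposite.side, opposite.x[ok], opposite.z[ok], delta_i)
    else:
        mirror = "left" if trimmed.side == "right" else "right"
        other = TransversePoints(mirror, x, z, delta_i)
    pair = {trimmed.side: trimmed, other.side: other}
    if set(pair) != {"left", "right"}:
        raise ValueError("need one 'left' and one 'right' side")
    anchors = _anchor_points(pair["left"], pair["right"], delta_i)
    ax, az = anchors[trimmed.side]

    best = None
    x_b = float(x.max())
    while x_b <= R_CYL + 1e-9:
        bases = np.array([x_b - BASE_INTERVAL, x_b - BASE_INTERVAL / 2.0, x_b])
        fx = np.concatenate([[ax], x, bases])
        fz = np.concatenate([[az], z, np.zeros(3)])
        coeffs = np.polyfit(fx, fz, 3)
        resid = np.polyval(coeffs, x) - z
        rmse = float(np.sqrt(np.mean(resid**2)))
        root = _plane_crossing(coeffs, ax, R_CYL)
        if root is None:
            q, penalized = PENALTY_NO_ROOT, True
        else:
            q, penalized = PENALTY_WEIGHT * root / R_CYL, False
        theta = rmse + q
        cand = SideProfileFit(
            side=trimmed.side,
            delta_i=delta_i,
            coefficients=tuple(coeffs),
            x_b=x_b,
            theta=theta,
            x_xmax=root,
            x_inner=ax,
            penalized=penalized,
        )
        if best is None or theta < best.theta - 1e-12:
            best = cand
        x_b += SWEEP_STEP
    return best


def _plane_crossing(coeffs, x_lo: float, x_hi: float) -> float | None:
    """Smallest real root of the cubic above ``x_lo`` and within ``x_hi``."""
    roots = np.roots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
    real = real[(real > x_lo) & (real <= x_hi)]
    return float(real[0]) if real.size else None


# ------------------------------------------------------------ region means
def mean_surface_displacement(
    fits: Iterable[SideProfileFit],
    delta_i: float,
    f_star: float,
    region_id: str = "",
    sample_step: float = 0.5,
) -> MeanSurfaceDisplacement:
    """Cubic mean displacement over all side fits (left side mirrored).

    Each side fit is sampled between its tip anchor and its crossing with
    the reference plane (or its base anchor when penalized); one cubic is
    fitted over the pooled samples.  ``x_min`` is the intersection with the
    indenter tip profile (falling back to the shank wall at ``x = r_t``),
    ``x_max`` the positive root on the reference plane.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no side fits")
    xs, zs = [], []
    for fit in fits:
        hi = fit.x_xmax if fit.x_xmax is not None else fit.x_b
        grid = np.arange(fit.x_inner, hi + 1e-9, sample_step)
        xs.append(grid)
        zs.append(np.polyval(fit.coefficients, grid))
    x = np.concatenate(xs)
    z = np.concatenate(zs)
    coeffs = tuple(np.polyfit(x, z, 3))

    # intersection with the hemisphere; the cubic may pass above the
    # equator, in which case the profile attaches to the cylindrical wall
    def g(xx):
        return np.polyval(coeffs, xx) - tip_profile_z(xx, delta_i)

    if g(1e-6) * g(R_TIP) <= 0:
        x_min = float(brentq(g, 1e-6, R_TIP))
    else:
        x_min = R_TIP

    x_max = _reference_plane_root(coeffs, x_min)
    if x_max is None:
        raise ValueError("mean cubic does not return to the reference plane")
    return MeanSurfaceDisplacement(
        region_id=region_id,
        delta_i=delta_i,
        coefficients=coeffs,
        x_min=x_min,
        x_max=x_max,
        f_star=f_star,
    )


def _reference_plane_root(coeffs, x_min: float) -> float | None:
    """Root of the cubic on the reference plane in ``(x_min, r_C]``.

    Among real roots in range, the smallest with positive slope (the
    displacement recovers toward zero there); with none qualifying, the
    largest in-range root.
    """
    roots = np.roots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
    real = real[(real > x_min) & (real <= R_CYL)]
    if real.size == 0:
        return None
    deriv = np.polyder(np.poly1d(coeffs))
    rising = real[deriv(real) > 0]
    return float(rising[0]) if rising.size else float(real[-1])


def compose_full_profile(
    msd: MeanSurfaceDisplacement, blend_mm: float = 5.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous displacement profile on ``[0, r_C]``.

    Indenter tip for ``x < x_min``, the mean cubic on ``[x_min, x_max]``,
    the reference plane beyond.  Transitions are smoothed over at most
    ``blend_mm`` on each side of the junctions by dropping cubic samples
    next to them and bridging with a monotone C1 interpolant (PCHIP),
    keeping the apex value ``-delta_I`` at ``x = 0`` and exact zeros from
    ``x_max`` outward.
    """
    d, x_min, x_max = msd.delta_i, msd.x_min, msd.x_max
    w = min(blend_mm, (x_max - x_min) / 4.0)
    x_tip = np.linspace(0.0, x_min, max(int(x_min / 0.25), 4), endpoint=True)
    z_tip = tip_profile_z(np.minimum(x_tip, R_TIP), d)
    x_mid = np.arange(x_min + w, x_max - w, 0.25)
    z_mid = np.polyval(msd.coefficients, x_mid)
    x_out = np.arange(x_max, R_CYL + 1e-9, 2.0)
    z_out = np.zeros_like(x_out)
    xx = np.concatenate([x_tip, x_mid, x_out, [R_CYL]])
    zz = np.concatenate([z_tip, z_mid, z_out, [0.0]])
    xx, idx = np.unique(np.round(xx, 9), return_index=True)
    interp = PchipInterpolator(xx, zz[idx])

    def profile(x):
        x = np.clip(np.asarray(x, dtype=float), 0.0, R_CYL)
        return interp(x)

    return profile
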