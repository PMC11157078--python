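"""Inverse identification of Ogden parameters by objective-surface grid search.

For every parameter set ``p = (c, m)`` on the grid ``P = C x M`` the forward
model is compared with the region's reference data at the four indentation
depths ``delta_I``:

* force residual            ``F_f = (f_sim - f_ref)^2 / f_ref^2``
* surface residual          ``F_u = sum_i w_i (u_i_sim - u_i_ref)^2 / u_i_ref^2``
  over the top-edge nodes with ``x_min <= x_i <= x_Trim``, with weights
  inversely proportional to the initial radii (normalized to sum 1)
* combined objective        ``F_fu = eta F_f + (1 - eta) F_u``
* total objective           ``F_fu_tot = (1/4) sum_I F_fu(p; delta_I)``

``x_Trim`` is where the reference displacement magnitude falls to the trim
factor ``delta_Trim``, which cuts off the blow-up of relative errors as the
displacement approaches zero.  The minimizer of ``F_fu_tot`` is the
identified set ``p_res``; per-depth minimizers are the ``p_I``.

Because ``kappa = 2000 c`` makes the displacement field independent of
``c`` (and the reaction exactly proportional to it), one forward solve per
``m`` column serves the entire ``c`` axis, and consecutive ``m`` columns
are warm-started from each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label
from scipy.optimize import brentq

from indentfit.curves import PolyFit, evaluate_fit
from indentfit.fem.mesh import MeshSpec
from indentfit.fem.ogden import OgdenParams
from indentfit.fem.solver import FEModel, NonConvergenceError
from indentfit.tof_surface import MeanSurfaceDisplacement

__all__ = [
    "ReferenceSet",
    "ObjectiveSurface",
    "TrimEvaluation",
    "force_residual",
    "node_weights",
    "x_trim_position",
    "surface_residual",
    "combined_objective",
    "total_objective",
    "grid_search",
    "select_trim_factor",
]

DEFAULT_C_GRID = np.arange(1.0, 61.0, 1.0)  # kPa
DEFAULT_M_GRID = np.arange(4.0, 126.0, 1.0)
SUBLEVEL_THRESHOLD = 1.5  # objective level used by the trim-factor shape metrics


@dataclass(frozen=True)
class ReferenceSet:
    """Experimental reference data of one region for the inverse analysis."""

    region_id: str
    force_fit: PolyFit
    surfaces: tuple  # four MeanSurfaceDisplacement, ascending delta_I
    delta_levels: tuple  # four equally spaced delta_I, mm
    delta_max_star: float  # largest delta_I, mm
    delta_trim: float  # mm
    eta: float = 0.5

    def __post_init__(self):
        if len(self.delta_levels) != 4 or len(self.surfaces) != 4:
            raise ValueError("four indentation depths are required")
        steps = np.diff(self.delta_levels)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("delta_I must be equally spaced")
        if abs(self.delta_levels[-1] - self.delta_max_star) > 1e-9:
            raise ValueError("delta_I=4 must equal delta_max_star")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def f_ref(self, delta: float) -> float:
        return float(evaluate_fit(self.force_fit, delta))


@dataclass
class ObjectiveSurface:
    """Objective values over the parameter grid ``P = C x M``."""

    region_id: str
    c_values: np.ndarray  # kPa
    m_values: np.ndarray
    eta: float
    delta_trim: float
    F_fu: np.ndarray  # (n_c, n_m, 4)
    F_tot: np.ndarray  # (n_c, n_m); non-converged cells are +inf
    failures: np.ndarray  # (n_c, n_m) bool
    p_I: list  # four (c, m) per-depth minimizers
    p_res: tuple  # (c, m) global minimizer
    min_F_tot: float
    raw: dict = field(default_factory=dict)  # m -> {delta: (f_hat_1kPa, r, uz)}

    def sublevel_mask(self, level: float = SUBLEVEL_THRESHOLD) -> np.ndarray:
        return np.isfinite(self.F_tot) & (self.F_tot <= level)


@dataclass
class TrimEvaluation:
    """Outcome of the six-criterion trim-factor sweep for one region."""

    candidates: np.ndarray  # mm
    series: dict  # criterion name -> array over candidates
    targets: dict  # criterion name -> individually selected delta_Trim, mm
    selected: float  # rounded mean of the individual targets, mm


# ----------------------------------------------------------- residual terms
def force_residual(f_sim: float, f_ref: float) -> float:
    """Normalized squared force error ``(f_sim - f_ref)^2 / f_ref^2``."""
    if f_ref == 0:
        raise ValueError("reference force must be nonzero (stay above the toe region)")
    return float((f_sim - f_ref) ** 2 / f_ref**2)


def node_weights(radii) -> np.ndarray:
    """Weights inversely proportional to the initial radii, summing to 1."""
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValueError("empty node set")
    if np.any(r <= 0):
        raise ValueError("radii must be positive (axis nodes are excluded)")
    inv = 1.0 / r
    return inv / inv.sum()


def x_trim_position(msd: MeanSurfaceDisplacement, delta_trim: float) -> float:
    """Lateral position where the reference displacement magnitude equals
    ``delta_trim`` (root of ``u(x) = -delta_trim`` next to ``x_max``)."""

    def g(x):
        return np.polyval(msd.coefficients, x) + delta_trim

    lo, hi = msd.x_min, msd.x_max
    if g(lo) * g(hi) > 0:
        raise ValueError("trim level outside the displacement range of the profile")
    return float(brentq(g, lo, hi))


def surface_residual(
    sim_r,
    sim_uz,
    msd: MeanSurfaceDisplacement,
    delta_trim: float,
) -> float:
    """Weighted relative surface-displacement error ``F_u``.

    The reference cubic is interpolated to the simulation nodes' initial
    radii; only nodes with ``x_min <= r <= x_Trim`` enter.
    """
    x_trim = x_trim_position(msd, delta_trim)
    r = np.asarray(sim_r, dtype=float)
    uz = np.asarray(sim_uz, dtype=float)
    sel = (r >= msd.x_min) & (r <= x_trim)
    if not np.any(sel):
        raise ValueError("no simulation node in the evaluation window")
    r, uz = r[sel], uz[sel]
    u_ref = np.polyval(msd.coefficients, r)
    w = node_weights(r)
    return float(np.sum(w * (uz - u_ref) ** 2 / u_ref**2))


def combined_objective(F_f: float, F_u: float, eta: float) -> float:
    """Convex combination ``F_fu = eta F_f + (1 - eta) F_u``."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    return eta * F_f + (1.0 - eta) * F_u


def total_objective(F_fu_per_depth) -> float:
    """Arithmetic mean of the combined objective over the four depths."""
    v = np.asarray(F_fu_per_depth, dtype=float)
    if v.size != 4:
        raise ValueError("four depth values are required")
    return float(v.mean())


# --------------------------------------------------------------- grid search
def _forward_columns(
    reference: ReferenceSet,
    m_values,
    mesh_N: int = 3,
    n_steps: int = 8,
    model: FEModel | None = None,
    progress=None,
):
    """Forward solutions per ``m`` at c = 1 kPa for all four depths.

    Consecutive ``m`` values are warm-started from each other per depth
    (with adaptive bisection in ``m`` on failure); the first column walks
    the full indentation path.  Returns ``{m: {delta: (f_hat, r, uz)}}``
    with ``f_hat`` the reaction at c = 1 kPa.
    """
    m_values = [float(m) for m in m_values]
    depths = list(reference.delta_levels)
    if model is None:
        model = FEModel(MeshSpec(N=mesh_N))
    out = {}
    states = None  # {delta: state} of the previously solved m
    prev_m = None
    for m in sorted(m_values):
        column, new_states = _solve_column(model, depths, m, prev_m, states, n_steps)
        if column is not None:
            out[m] = column
            states, prev_m = new_states, m
        if progress:
            progress(m, column is not None)
    return out


def _solve_column(model, depths, m, prev_m, states, n_steps):
    params = OgdenParams(1.0, m)
    try:
        if states is None:
            sol = model.solve(params, depths[-1], n_steps=n_steps, snapshots=depths)
            snaps = {d: sol.snapshot(d) for d in depths}
        else:
            snaps = {}
            for d in depths:
                snaps[d] = _equilibrate_chain(model, d, prev_m, states[d], m)
    except NonConvergenceError:
        return None, None
    column = {
        d: (s["reaction"], s["r"].copy(), s["uz"].copy()) for d, s in snaps.items()
    }
    new_states = {d: s["state"] for d, s in snaps.items()}
    return column, new_states


def _equilibrate_chain(model, delta, m_from, state, m_to, dm_min=0.05):
    """Adaptive warm continuation in m at one depth."""
    m = float(m_from)
    dm = float(m_to - m_from)
    snap = None
    while abs(m - m_to) > 1e-12:
        step = dm if abs(dm) <= abs(m_to - m) else m_to - m
        trial = m + step
        try:
            snap = model.equilibrate(OgdenParams(1.0, trial), delta, state)
        except NonConvergenceError:
            dm *= 0.5
            if abs(dm) < dm_min:
                raise
            continue
        m, state = trial, snap["state"]
        dm *= 1.5
    if snap is None:
        snap = model.equilibrate(OgdenParams(1.0, m_to), delta, state)
    return snap


def grid_search(
    reference: ReferenceSet,
    c_values=DEFAULT_C_GRID,
    m_values=DEFAULT_M_GRID,
    eta: float | None = None,
    delta_trim: float | None = None,
    mesh_N: int = 3,
    n_steps: int = 8,
    raw_columns: dict | None = None,
    max_failure_fraction: float = 0.2,
    progress=None,
) -> ObjectiveSurface:
    """Exhaustive objective-surface evaluation over ``P = C x M``.

    One forward solve per ``m`` column (c-scaling serves the ``c`` axis);
    per-depth minima ``p_I`` and the global minimizer ``p_res`` are
    reported, with ties broken toward smaller ``c`` then smaller ``m``.
    Pre-computed forward columns can be passed in (``raw_columns``) to
    re-evaluate the surface for other ``eta``/``delta_trim`` without new
    simulations.  Aborts if more than ``max_failure_fraction`` of the grid
    fails to converge.
    """
    c_values = np.asarray(sorted(c_values), dtype=float)
    m_values = np.asarray(sorted(m_values), dtype=float)
    eta = reference.eta if eta is None else float(eta)
    delta_trim = reference.delta_trim if delta_trim is None else float(delta_trim)
    depths = list(reference.delta_levels)
    if raw_columns is None:
        raw_columns = _forward_columns(
            reference, m_values, mesh_N=mesh_N, n_steps=n_steps, progress=progress
        )

    n_c, n_m = len(c_values), len(m_values)
    F_fu = np.full((n_c, n_m, 4), np.inf)
    failures = np.zeros((n_c, n_m), dtype=bool)
    f_ref = np.array([reference.f_ref(d) for d in depths])
    for j, m in enumerate(m_values):
        col = raw_columns.get(float(m))
        if col is None:
            failures[:, j] = True
            continue
        # F_u is independent of c; F_f scales exactly with c
        Fu = np.empty(4)
        fhat = np.empty(4)
        for k, d in enumerate(depths):
            f1, r, uz = col[d]
            fhat[k] = f1
            Fu[k] = surface_residual(r, uz, reference.surfaces[k], delta_trim)
        f_sim = c_values[:, None] * fhat[None, :]  # (n_c, 4)
        Ff = (f_sim - f_ref[None, :]) ** 2 / f_ref[None, :] ** 2
        F_fu[:, j, :] = eta * Ff + (1 - eta) * Fu[None, :]

    if failures.mean() > max_failure_fraction:
        raise NonConvergenceError(
            f"{failures.mean():.0%} of the parameter grid failed to converge"
        )
    F_tot = F_fu.mean(axis=2)
    F_tot[failures] = np.inf

    def _argmin(a):
        idx = np.unravel_index(np.argmin(a), a.shape)
        return (float(c_values[idx[0]]), float(m_values[idx[1]]))

    p_I = [_argmin(np.where(failures, np.inf, F_fu[:, :, k])) for k in range(4)]
    p_res = _argmin(F_tot)
    return ObjectiveSurface(
        region_id=reference.region_id,
        c_values=c_values,
        m_values=m_values,
        eta=eta,
        delta_trim=delta_trim,
        F_fu=F_fu,
        F_tot=F_tot,
        failures=failures,
        p_I=p_I,
        p_res=p_res,
        min_F_tot=float(np.min(F_tot)),
        raw=raw_columns,
    )


# ------------------------------------------------------- trim-factor sweep
def _circularity(mask: np.ndarray, dc: float, dm: float) -> float:
    """``4 pi A / P^2`` of the largest connected sublevel component.

    Computed on the nondimensionalized grid (axes scaled by the respective
    maxima), with area as cell count times cell area and perimeter as the
    total length of exposed cell edges.
    """
    lab, n = label(mask)
    if n == 0:
        return 0.0
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    comp = lab == largest
    area = comp.sum() * dc * dm
    pad = np.pad(comp, 1)
    perim = (
        (pad[1:-1, 1:-1] & ~pad[:-2, 1:-1]).sum() * dm
        + (pad[1:-1, 1:-1] & ~pad[2:, 1:-1]).sum() * dm
        + (pad[1:-1, 1:-1] & ~pad[1:-1, :-2]).sum() * dc
        + (pad[1:-1, 1:-1] & ~pad[1:-1, 2:]).sum() * dc
    )
    if perim == 0:
        return 1.0
    return float(4 * np.pi * area / perim**2)


def _first_converged(candidates, series, tol):
    """First candidate whose relative change from its predecessor is < tol."""
    s = np.asarray(series, dtype=float)
    for k in range(1, len(s)):
        denom = max(abs(s[k - 1]), 1e-12)
        if np.isfinite(s[k]) and abs(s[k] - s[k - 1]) / denom < tol:
            # stable already at the earlier of the pair
            return float(candidates[k - 1])
    return float(candidates[-1])


def select_trim_factor(
    reference: ReferenceSet,
    c_values=DEFAULT_C_GRID,
    m_values=DEFAULT_M_GRID,
    candidates=None,
    mesh_N: int = 3,
    raw_columns: dict | None = None,
) -> TrimEvaluation:
    """Six-criterion trim-factor selection over candidates 0.1-1.2 mm.

    Per candidate ``delta_Trim`` the objective surface is re-evaluated
    (forward solutions are shared across candidates) and six series are
    tracked: (1) the SD of the distances between ``F_fu_tot`` and the four
    per-depth objectives, (2) the fraction of the nondimensionalized grid
    with ``F_fu_tot > 1.5``, (3) the circularity of the sublevel region
    ``F_fu_tot <= 1.5``, (4) the force/surface balance (closest to 0.5 at
    the lowest feasible candidate), (5)-(6) the relative change of the
    resulting ``c`` and ``m``.  Convergence targets: < 2 % for (1)-(3),
    < 1 % for (5)-(6).  The selected trim factor is the rounded mean of
    the six individual targets.
    """
    if candidates is None:
        candidates = np.round(np.arange(0.1, 1.2001, 0.1), 10)
    candidates = np.asarray(candidates, dtype=float)
    if raw_columns is None:
        raw_columns = _forward_columns(reference, m_values, mesh_N=mesh_N)

    c_values = np.asarray(sorted(c_values), dtype=float)
    m_values = np.asarray(sorted(m_values), dtype=float)
    dc = (c_values[1] - c_values[0]) / c_values.max() if len(c_values) > 1 else 1.0
    dm = (m_values[1] - m_values[0]) / m_values.max() if len(m_values) > 1 else 1.0

    names = ("depth_sd", "high_fraction", "circularity", "balance", "c_res", "m_res")
    series = {n: [] for n in names}
    f_ref = np.array([reference.f_ref(d) for d in reference.delta_levels])
    for cand in candidates:
        try:
            surf = grid_search(
                reference, c_values, m_values,
                delta_trim=float(cand), raw_columns=raw_columns,
            )
        except ValueError:
            for n in names:
                series[n].append(np.nan)
            continue
        ok = ~surf.failures
        dist = np.abs(surf.F_fu[ok] - surf.F_tot[ok][:, None])
        series["depth_sd"].append(float(np.mean(np.std(dist, axis=1))))
        series["high_fraction"].append(
            float(np.mean(surf.F_tot[ok] > SUBLEVEL_THRESHOLD))
        )
        series["circularity"].append(_circularity(surf.sublevel_mask(), dc, dm))
        # mean force share of the combined objective
        Ff_list, Fu_list = [], []
        for m in m_values:
            col = surf.raw.get(float(m))
            if col is None:
                continue
            for k, d in enumerate(reference.delta_levels):
                f1, r, uz = col[d]
                Ff_list.append(
                    np.mean((c_values * f1 - f_ref[k]) ** 2 / f_ref[k] ** 2)
                )
                Fu_list.append(
                    surface_residual(r, uz, reference.surfaces[k], float(cand))
                )
        mean_ff, mean_fu = float(np.mean(Ff_list)), float(np.mean(Fu_list))
        series["balance"].append(mean_ff / (mean_ff + mean_fu))
        series["c_res"].append(surf.p_res[0])
        series["m_res"].append(surf.p_res[1])

    targets = {
        "depth_sd": _first_converged(candidates, series["depth_sd"], 0.02),
        "high_fraction": _first_converged(candidates, series["high_fraction"], 0.02),
        "circularity": _first_converged(candidates, series["circularity"], 0.02),
        "c_res": _first_converged(candidates, series["c_res"], 0.01),
        "m_res": _first_converged(candidates, series["m_res"], 0.01),
    }
    balance = np.asarray(series["balance"], dtype=float)
    if np.all(np.isnan(balance)):
        targets["balance"] = float(candidates[0])
    else:
        targets["balance"] = float(candidates[np.nanargmin(np.abs(balance - 0.5))])
    selected = round(float(np.mean(list(targets.values()))), 1)
    return TrimEvaluation(
        candidates=candidates,
        series={k: np.asarray(v, dtype=float) for k, v in series.items()},
        targets=targets,
        selected=selected,
    )
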