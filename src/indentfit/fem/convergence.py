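"""Mesh-convergence metrics for the indentation forward model.

For a mesh refinement factor ``N`` against a fine reference ``N_ref``
(nominally 6), evaluated at a common indentation depth:

* force error  ``E_F(N) = |(F(N) - F(ref)) / F(ref)| * 100 %`` with ``F``
  the indentation reaction at the evaluation depth, and
* surface error ``E_u(N) = (1/Nn) * sum_i |(u_i(N) - u_ref(r_i)) / u_ref(r_i)| * 100 %``

over the top-edge nodes outside the indenter footprint (``r >= r_t``), with
the reference displacements interpolated to the coarse-node radii by a
monotone cubic (PCHIP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from indentfit.fem.mesh import MeshSpec
from indentfit.fem.ogden import OgdenParams
from indentfit.fem.solver import (
    FEModel,
    NonConvergenceError,
    R_TIP,
    continue_in_m,
    interpolate_state,
    surface_profile,
)

__all__ = ["ConvergenceReport", "mesh_convergence", "DEFAULT_MATERIAL_SETS"]

#: Material sets spanning the identified parameter space: compliant,
#: mid-range and stiff (c kPa, m).
DEFAULT_MATERIAL_SETS = (
    OgdenParams(1.0, 4.0),
    OgdenParams(45.0, 30.0),
    OgdenParams(140.0, 60.0),
)


@dataclass
class ConvergenceReport:
    N_values: tuple
    reference_N: int
    delta: float
    material_sets: tuple
    E_F: dict = field(default_factory=dict)  # (N, set_idx) -> %
    E_u: dict = field(default_factory=dict)  # (N, set_idx) -> %

    def max_errors(self, N: int) -> tuple[float, float]:
        """Maximum (E_F, E_u) over material sets at refinement N."""
        ef = max(v for (n, _), v in self.E_F.items() if n == N)
        eu = max(v for (n, _), v in self.E_u.items() if n == N)
        return ef, eu


def force_error(f_coarse: float, f_ref: float) -> float:
    """Relative force error in percent."""
    return abs((f_coarse - f_ref) / f_ref) * 100.0


def surface_error(r_coarse, u_coarse, r_ref, u_ref, r_min: float = R_TIP) -> float:
    """Mean relative nodal displacement error in percent.

    Reference displacements are interpolated to the coarse radii with a
    monotone cubic; only nodes with ``r >= r_min`` (outside the indenter
    footprint) enter.
    """
    interp = PchipInterpolator(r_ref, u_ref)
    sel = r_coarse >= r_min - 1e-9
    rc, uc = np.asarray(r_coarse)[sel], np.asarray(u_coarse)[sel]
    uref = interp(rc)
    return float(np.mean(np.abs((uc - uref) / uref)) * 100.0)


def mesh_convergence(
    N_values=(1, 2, 3),
    reference_N: int = 6,
    material_sets=DEFAULT_MATERIAL_SETS,
    delta: float = 20.0,
    n_steps: int = 20,
    **solve_kwargs,
) -> ConvergenceReport:
    """Run the convergence study and tabulate E_F / E_u against the reference.

    For each material set the refinement levels are solved as a ladder: the
    coarsest level walks the full indentation path, every finer level (and
    the reference) re-equilibrates at the evaluation depth from the previous
    level's interpolated state.  The converged states are mesh-exact; the
    warm start only saves the redundant path walk.
    """
    material_sets = tuple(material_sets)
    ladder = sorted(set(N_values) | {reference_N})
    report = ConvergenceReport(
        N_values=tuple(N_values),
        reference_N=reference_N,
        delta=delta,
        material_sets=material_sets,
    )
    models = {N: FEModel(MeshSpec(N=N)) for N in ladder}

    # Displacement fields (and hence both error metrics) are independent of
    # c, so each refinement level needs one anchor solve plus continuation
    # chains in m to the requested material sets.
    anchor_m = 12.0
    anchor_c = 1.0
    anchor_states = {}
    N0 = ladder[0]
    sol = models[N0].solve(
        OgdenParams(anchor_c, anchor_m), delta,
        n_steps=n_steps, snapshots=[delta], **solve_kwargs,
    )
    anchor_states[N0] = sol.snapshot(delta)["state"]
    for N_prev, N in zip(ladder, ladder[1:]):
        u0 = interpolate_state(models[N_prev].mesh, anchor_states[N_prev], models[N].mesh)
        try:
            snap = models[N].equilibrate(OgdenParams(anchor_c, anchor_m), delta, u0)
        except NonConvergenceError:
            snap = models[N].solve(
                OgdenParams(anchor_c, anchor_m), delta,
                n_steps=n_steps, snapshots=[delta],
                initial_states={delta: u0}, **solve_kwargs,
            ).snapshot(delta)
        anchor_states[N] = snap["state"]

    results = {}  # (N, set index) -> (reaction, r, uz)
    for N in ladder:
        for k, p in enumerate(material_sets):
            try:
                snap = continue_in_m(
                    models[N], delta, anchor_m, anchor_states[N], p.m, c_kpa=anchor_c
                )
            except NonConvergenceError:
                snap = models[N].solve(
                    OgdenParams(anchor_c, p.m), delta,
                    n_steps=n_steps, snapshots=[delta], **solve_kwargs,
                ).snapshot(delta)
            scale = p.c_kpa / anchor_c
            results[(N, k)] = (scale * snap["reaction"], snap["r"], snap["uz"])

    for N in N_values:
        for k in range(len(material_sets)):
            f_ref, r_ref, u_ref = results[(reference_N, k)]
            f, r, u = results[(N, k)]
            report.E_F[(N, k)] = force_error(f, f_ref)
            report.E_u[(N, k)] = surface_error(r, u, r_ref, u_ref)
    return report
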