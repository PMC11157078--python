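"""Bundled region-mean reference data from the in vivo abdominal study.

Twelve measurement configurations are covered: six abdominal regions, each
with fully relaxed (``R1``-``R6``) and controlled activated (``A1``-``A6``)
trunk musculature.  For every region the study provides

* a mean force-displacement polynomial (through the origin, descending
  powers, valid on ``0 <= delta <= delta_max``),
* four mean surface-displacement cubics ``u(x)`` at the equally spaced
  indentation depths ``delta_I`` (``I = 1..4``, the last being
  ``delta_max_star``), each with intersection bounds ``x_min``/``x_max`` and
  the reference force ``f_star``,
* the identified first-order Ogden parameter set ``p_res = (c, m)`` with the
  trim factor used and the simulated reaction at ``delta_max_star``.

These tables are the experimental inputs of the inverse identification; the
package treats them as data, not as results to be asserted.

.. note::
   The published A2 force-fit coefficients do not reproduce the published
   ``f_max`` for that region (the row appears to carry typographical errors);
   they are stored verbatim and should not be used for value-level checks.
"""

from __future__ import annotations

from indentfit.curves import PolyFit

#: Indenter tip radius, mm.
R_TIP = 10.0

#: Radius of the modelled tissue cylinder (= tip radius + 100 mm), mm.
R_CYL = 110.0

REGIONS = (
    "R1", "R2", "R3", "R4", "R5", "R6",
    "A1", "A2", "A3", "A4", "A5", "A6",
)

# region -> (delta_max mm, f_max N, degree, descending coefficients, rmse)
_FORCE_ROWS = {
    "R1": (25.0, 11.85, 2, (8.684e-03, 2.462e-01, 0.0), 1.256),
    "R2": (30.0, 13.33, 4, (-2.937e-06, 2.590e-04, 2.479e-03, 2.163e-01, 0.0), 0.963),
    "R3": (30.0, 11.52, 2, (8.604e-03, 1.260e-01, 0.0), 0.512),
    "R4": (30.0, 10.33, 2, (5.279e-03, 1.859e-01, 0.0), 0.660),
    "R5": (25.0, 11.41, 4, (5.359e-06, 1.710e-04, 3.677e-03, 1.740e-01, 0.0), 1.025),
    "R6": (20.0, 32.25, 4, (-2.765e-05, 2.665e-03, 2.231e-02, 3.214e-01, 0.0), 2.639),
    "A1": (20.0, 20.94, 2, (3.456e-02, 3.556e-01, 0.0), 2.913),
    "A2": (25.0, 29.51, 5, (-1.119e-05, -6.415e-04, 4.969e-02, 5.176e-02, 4.619e-01, 0.0), 3.320),
    "A3": (25.0, 27.01, 5, (9.067e-06, -5.547e-04, 1.047e-02, -2.882e-02, 3.835e-01, 0.0), 3.922),
    "A4": (25.0, 22.44, 3, (-3.641e-04, 2.890e-02, 4.072e-01, 0.0), 4.682),
    "A5": (24.0, 23.86, 2, (2.864e-02, 3.068e-01, 0.0), 4.037),
    "A6": (14.0, 55.98, 4, (-3.118e-04, -3.885e-03, 3.465e-01, 7.624e-01, 0.0), 10.959),
}

# region -> list of rows (delta_I, f_star, x_min, x_max, (u1, u2, u3, u4))
# u(x) is the cubic fit of the mean surface displacement (z positive up,
# displacements negative), valid on x_min <= x <= x_max.
_SURFACE_ROWS = {
    "R1": [
        (5.0, 1.45, 6.089, 42.859, (-1.065e-04, 6.927e-03, -3.190e-02, -2.971)),
        (10.0, 3.33, 7.831, 53.080, (-4.762e-05, 3.425e-03, 8.567e-02, -7.078)),
        (15.0, 5.65, 8.837, 62.945, (-4.873e-05, 4.178e-03, 1.030e-01, -10.89)),
        (20.0, 8.40, 9.671, 66.729, (-6.188e-05, 5.926e-03, 8.836e-02, -13.9)),
    ],
    "R2": [
        (6.25, 1.51, 7.342, 37.005, (-1.993e-04, 1.256e-02, -1.166e-01, -2.782)),
        (12.5, 5.53, 8.943, 45.946, (-1.246e-04, 8.224e-03, 6.108e-02, -8.087)),
        (18.75, 6.27, 9.756, 57.187, (-5.454e-05, 3.227e-03, 2.287e-01, -13.43)),
        (25.0, 9.86, 10.000, 65.213, (-5.666e-05, 4.188e-03, 2.368e-01, -17.54)),
    ],
    "R3": [
        (6.25, 1.12, 7.566, 35.484, (-2.180e-04, 1.351e-02, -1.365e-01, -2.433)),
        (12.5, 2.92, 9.293, 42.561, (-1.745e-04, 1.119e-02, 5.990e-03, -7.075)),
        (18.75, 5.39, 9.942, 52.568, (-6.188e-05, 3.089e-03, 2.467e-01, -12.52)),
        (25.0, 8.53, 10.000, 60.609, (-6.175e-05, 4.191e-03, 2.418e-01, -16.31)),
    ],
    "R4": [
        (6.25, 1.37, 7.348, 36.761, (-1.688e-04, 1.022e-02, -6.487e-02, -3.037)),
        (12.5, 3.15, 9.026, 49.639, (-3.117e-05, 3.522e-04, 2.401e-01, -8.972)),
        (18.75, 5.34, 9.831, 61.055, (-1.742e-05, -5.439e-04, 3.221e-01, -13.67)),
        (25.0, 7.94, 10.000, 67.845, (-1.813e-05, -4.167e-04, 3.827e-01, -18.39)),
    ],
    "R5": [
        (6.25, 1.28, 7.331, 39.196, (-1.194e-04, 7.065e-03, -8.779e-03, -3.318)),
        (12.5, 3.21, 8.955, 43.200, (-1.068e-04, 5.409e-03, 1.698e-01, -8.818)),
        (18.75, 6.34, 9.697, 52.244, (-4.996e-05, 1.204e-03, 3.545e-01, -14.68)),
        (25.0, 11.41, 9.990, 61.790, (-5.988e-05, 3.226e-03, 3.379e-01, -19.07)),
    ],
    "R6": [
        (4.0, 1.81, 6.811, 43.314, (6.69e-07, -4.281e-04, 5.611e-02, -1.682)),
        (8.0, 5.25, 8.518, 45.484, (-4.42e-05, 2.257e-03, 7.747e-02, -4.033)),
        (12.0, 11.10, 9.272, 51.617, (2.646e-07, -2.121e-03, 2.639e-01, -8.007)),
        (16.0, 19.96, 9.865, 57.954, (8.678e-06, -3.241e-03, 3.435e-01, -10.71)),
    ],
    "A1": [
        (4.0, 1.98, 6.425, 45.758, (-7.288e-06, 1.786e-04, 5.058e-02, -1.99)),
        (8.0, 5.06, 8.082, 45.302, (-6.09e-05, 3.765e-03, 5.473e-02, -4.543)),
        (12.0, 9.24, 8.921, 49.949, (-8.825e-05, 6.103e-03, 6.618e-02, -3.34)),
        (16.0, 14.54, 9.463, 55.936, (-5.966e-05, 4.297e-03, 1.412e-01, -10.9)),
    ],
    "A2": [
        (5.0, 3.52, 7.095, 46.183, (-1.724e-05, 5.926e-04, 6.401e-02, -2.522)),
        (10.0, 9.04, 8.513, 50.939, (-3.94e-05, 2.501e-03, 9.710e-02, -6.23)),
        (15.0, 15.84, 9.315, 57.370, (-4.751e-05, 3.453e-03, 1.354e-01, -10.16)),
        (20.0, 23.02, 9.878, 65.679, (-3.791e-05, 2.684e-03, 1.961e-01, -13.72)),
    ],
    "A3": [
        (5.0, 2.19, 7.553, 39.789, (1.582e-06, -3.823e-04, 6.318e-02, -2.008)),
        (10.0, 6.77, 9.309, 47.862, (-2.645e-05, 1.298e-03, 9.510e-02, -4.625)),
        (15.0, 13.42, 9.795, 56.835, (-2.952e-05, 1.614e-03, 1.561e-01, -8.663)),
        (20.0, 20.12, 10.000, 65.710, (-2.59e-05, 1.704e-03, 1.772e-01, -11.65)),
    ],
    "A4": [
        (5.0, 2.74, 7.252, 49.359, (5.653e-06, -9.252e-04, 8.103e-02, -2.425)),
        (10.0, 6.66, 8.761, 49.564, (-8.992e-06, -9.275e-04, 1.988e-01, -6.479)),
        (15.0, 11.44, 9.584, 57.680, (-7.473e-06, -1.211e-03, 2.744e-01, -10.36)),
        (20.0, 16.80, 9.981, 63.514, (-1.605e-05, -1.236e-04, 2.837e-01, -13.41)),
    ],
    "A5": [
        (5.0, 2.25, 6.772, 47.663, (7.959e-06, -1.075e-03, 9.514e-02, -2.954)),
        (10.0, 5.93, 8.856, 53.956, (2.45e-05, -3.237e-03, 2.213e-01, -6.363)),
        (15.0, 11.04, 9.616, 54.403, (1.31e-05, -3.276e-03, 3.356e-01, -10.67)),
        (20.0, 17.59, 9.969, 59.772, (7.236e-06, -3.051e-03, 3.979e-01, -14.43)),
    ],
    "A6": [
        (3.25, 5.97, 6.440, 52.595, (1.001e-05, -9.623e-04, 4.477e-02, -1.149)),
        (6.5, 17.97, 8.652, 54.386, (3.466e-05, -3.406e-03, 1.263e-01, -2.373)),
        (9.75, 33.95, 9.422, 61.089, (3.14e-05, -3.384e-03, 1.605e-01, -4.337)),
        (13.0, 51.03, 9.817, 67.835, (3.628e-05, -4.454e-03, 2.358e-01, -6.824)),
    ],
}

# region -> (delta_max_star mm, delta_trim mm, f_sim N, c kPa, m,
#            (c_lo, c_hi), (m_lo, m_hi), min F_fu_tot)
_IDENTIFIED = {
    "R1": (20.0, 0.5, 10.78, 5.0, 30.0, (5, 8), (24, 60), 0.43),
    "R2": (25.0, 0.6, 13.11, 7.0, 17.0, (6, 7), (15, 39), 0.33),
    "R3": (25.0, 0.5, 9.62, 7.0, 12.0, (6, 7), (11, 32), 0.38),
    "R4": (25.0, 0.5, 11.24, 6.0, 17.0, (5, 7), (15, 35), 0.31),
    "R5": (25.0, 0.6, 12.46, 8.0, 14.0, (6, 8), (13, 38), 0.35),
    "R6": (16.0, 0.6, 19.60, 25.0, 19.0, (20, 29), (16, 39), 0.12),
    "A1": (16.0, 0.6, 17.08, 18.0, 25.0, (17, 18), (21, 59), 0.26),
    "A2": (20.0, 0.5, 30.37, 19.0, 24.0, (17, 24), (20, 44), 0.29),
    "A3": (20.0, 0.5, 23.91, 20.0, 18.0, (18, 22), (17, 29), 0.13),
    "A4": (20.0, 0.5, 21.07, 16.0, 20.0, (15, 19), (17, 44), 0.26),
    "A5": (20.0, 0.6, 21.07, 16.0, 20.0, (12, 16), (16, 60), 0.33),
    "A6": (13.0, 0.4, 59.48, 100.0, 23.0, (78, 126), (16, 44), 0.34),
}


def force_fit(region: str) -> PolyFit:
    """Mean force-displacement fit for ``region`` as a :class:`PolyFit`."""
    dmax, _fmax, degree, coeffs, rmse = _FORCE_ROWS[region]
    return PolyFit(
        coefficients=tuple(coeffs),
        degree=degree,
        delta_max=dmax,
        rmse=rmse,
        r_squared=float("nan"),
    )


def f_max(region: str) -> float:
    """Published mean indentation force at ``delta_max``, N."""
    return _FORCE_ROWS[region][1]


def surface_rows(region: str):
    """List of ``(delta_I, f_star, x_min, x_max, coefficients)`` tuples."""
    return list(_SURFACE_ROWS[region])


def surface_displacement(region: str, delta_i: float):
    """Mean surface displacement row for one indentation depth.

    Returns a :class:`indentfit.tof_surface.MeanSurfaceDisplacement` carrying
    the bundled cubic, bounds and reference force.
    """
    from indentfit.tof_surface import MeanSurfaceDisplacement

    for d, f_star, x_min, x_max, coeffs in _SURFACE_ROWS[region]:
        if abs(d - delta_i) < 1e-9:
            return MeanSurfaceDisplacement(
                region_id=region,
                delta_i=d,
                coefficients=tuple(coeffs),
                x_min=x_min,
                x_max=x_max,
                f_star=f_star,
            )
    raise KeyError(f"no surface row for {region} at delta_I={delta_i}")


def delta_levels(region: str) -> tuple[float, float, float, float]:
    """The four equally spaced indentation depths ``delta_I`` of a region."""
    return tuple(row[0] for row in _SURFACE_ROWS[region])


def delta_max_star(region: str) -> float:
    """Largest simulated indentation depth ``delta_I=4`` of a region."""
    return _IDENTIFIED[region][0]


def identified_params(region: str) -> dict:
    """Identified Ogden set and inverse-analysis metadata for a region."""
    dms, dtrim, f_sim, c, m, c_range, m_range, fmin = _IDENTIFIED[region]
    return {
        "delta_max_star": dms,
        "delta_trim": dtrim,
        "f_sim": f_sim,
        "c_kpa": c,
        "m": m,
        "c_range": c_range,
        "m_range": m_range,
        "min_F_fu_tot": fmin,
    }


def reference_set(region: str, delta_trim: float | None = None):
    """Assemble the full inverse-analysis reference set for a region."""
    from indentfit.inverse_id import ReferenceSet

    levels = delta_levels(region)
    if delta_trim is None:
        delta_trim = _IDENTIFIED[region][1]
    return ReferenceSet(
        region_id=region,
        force_fit=force_fit(region),
        surfaces=tuple(surface_displacement(region, d) for d in levels),
        delta_levels=levels,
        delta_max_star=delta_max_star(region),
        delta_trim=delta_trim,
    )
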