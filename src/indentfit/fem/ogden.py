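"""Uncoupled first-order Ogden hyperelasticity.

Strain energy density in terms of the deviatoric principal stretches
``lam_tilde_i = J**(-1/3) * lam_i`` and the volume ratio ``J = det F``::

    Psi = (c / m**2) * sum_i (lam_tilde_i**m - 1) + (kappa / 2) * (ln J)**2

with a stress-like parameter ``c`` (kPa), a dimensionless nonlinearity
exponent ``m`` and a bulk-like modulus ``kappa`` that defaults to
``2000 * c`` for near-incompressibility.  The deviatoric term scales
linearly in ``c``: at fixed ``m`` the whole stress response (and with it
any displacement-driven equilibrium solution) is proportional to ``c``.

Internally the solver works in MPa/mm/N units; the public dataclass keeps
kPa for readability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OgdenParams",
    "principal_kirchhoff",
    "pk2_voigt",
    "strain_energy_voigt",
    "strain_energy_density",
    "ogden_stress",
    "small_strain_moduli",
]

KAPPA_RATIO = 2000.0  # kappa / c for nearly isochoric response


@dataclass(frozen=True)
class OgdenParams:
    """First-order Ogden parameter set ``p = (c, m)`` with bulk modulus kappa."""

    c_kpa: float
    m: float
    kappa_kpa: float | None = None

    def __post_init__(self):
        if self.c_kpa <= 0:
            raise ValueError("c must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.kappa_kpa is None:
            object.__setattr__(self, "kappa_kpa", KAPPA_RATIO * self.c_kpa)

    @property
    def c_mpa(self) -> float:
        return self.c_kpa * 1e-3

    @property
    def kappa_mpa(self) -> float:
        return self.kappa_kpa * 1e-3


def principal_kirchhoff(lam1, lam2, lam3, c, m, kappa):
    """Principal Kirchhoff stresses ``tau_i = lam_i dPsi/dlam_i`` (array-safe).

    ``c``/``kappa`` in any consistent stress unit; returns the same unit.
    """
    J = lam1 * lam2 * lam3
    lnJ = np.log(J)
    Jm13 = J ** (-1.0 / 3.0)
    a1 = (Jm13 * lam1) ** m
    a2 = (Jm13 * lam2) ** m
    a3 = (Jm13 * lam3) ** m
    mean3 = (a1 + a2 + a3) / 3.0
    cm = c / m
    vol = kappa * lnJ
    return cm * (a1 - mean3) + vol, cm * (a2 - mean3) + vol, cm * (a3 - mean3) + vol


def _principal_2x2(C11, C22, C12):
    """Eigenvalues and rotation of a symmetric 2x2 (batched)."""
    mid = 0.5 * (C11 + C22)
    dif = 0.5 * (C11 - C22)
    rad = np.sqrt(dif * dif + C12 * C12)
    lam_a = mid + rad
    lam_b = mid - rad
    theta = 0.5 * np.arctan2(2.0 * C12, C11 - C22)
    return lam_a, lam_b, np.cos(theta), np.sin(theta)


def pk2_voigt(C11, C22, C12, Cth, c, m, kappa):
    """Second Piola-Kirchhoff stress components for the axisymmetric state.

    Input: right Cauchy-Green components (in-plane ``C11, C22, C12`` and the
    hoop component ``Cth``).  Output: ``(S11, S22, S12, Sth)`` conjugate to
    the Green-Lagrange strain components ``(E11, E22, 2 E12, Eth)``.
    Raises ``FloatingPointError`` via NaN downstream if ``det C <= 0``; the
    solver treats non-finite results as a diverged state.
    """
    l1s, l2s, ct, st = _principal_2x2(C11, C22, C12)
    l1s = np.maximum(l1s, 1e-12)
    l2s = np.maximum(l2s, 1e-12)
    Cth = np.maximum(Cth, 1e-12)
    lam1 = np.sqrt(l1s)
    lam2 = np.sqrt(l2s)
    lam3 = np.sqrt(Cth)
    t1, t2, t3 = principal_kirchhoff(lam1, lam2, lam3, c, m, kappa)
    S1 = t1 / l1s
    S2 = t2 / l2s
    S11 = S1 * ct * ct + S2 * st * st
    S22 = S1 * st * st + S2 * ct * ct
    S12 = (S1 - S2) * ct * st
    Sth = t3 / Cth
    return S11, S22, S12, Sth


def strain_energy_voigt(C11, C22, C12, Cth, c, m, kappa):
    """Strain energy density from right Cauchy-Green components."""
    l1s, l2s, _, _ = _principal_2x2(C11, C22, C12)
    lam1 = np.sqrt(np.maximum(l1s, 1e-12))
    lam2 = np.sqrt(np.maximum(l2s, 1e-12))
    lam3 = np.sqrt(np.maximum(Cth, 1e-12))
    J = lam1 * lam2 * lam3
    lnJ = np.log(J)
    Jm13 = J ** (-1.0 / 3.0)
    dev = (Jm13 * lam1) ** m + (Jm13 * lam2) ** m + (Jm13 * lam3) ** m - 3.0
    return (c / m**2) * dev + 0.5 * kappa * lnJ**2


def strain_energy_density(params: OgdenParams, F: np.ndarray) -> float:
    """Energy density (MPa) for a full 3x3 deformation gradient."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("det F must be positive")
    lam = np.sqrt(np.linalg.eigvalsh(F.T @ F))
    lnJ = np.log(J)
    lt = lam * J ** (-1.0 / 3.0)
    c, m, kappa = params.c_mpa, params.m, params.kappa_mpa
    return float((c / m**2) * (np.sum(lt**m) - 3.0) + 0.5 * kappa * lnJ**2)


def ogden_stress(params: OgdenParams, F: np.ndarray, tangent: bool = False):
    """Cauchy stress (MPa) for a 3x3 deformation gradient.

    With ``tangent=True`` additionally returns the material tangent
    ``dS/dC`` (fourth-order, minor-symmetric, via central differences on C),
    accurate enough for quadratic Newton convergence in practice.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("det F must be positive")
    C = F.T @ F
    c, m, kappa = params.c_mpa, params.m, params.kappa_mpa

    def _pk2(Cmat):
        w, V = np.linalg.eigh(Cmat)
        w = np.maximum(w, 1e-12)
        lam = np.sqrt(w)
        taus = principal_kirchhoff(lam[0], lam[1], lam[2], c, m, kappa)
        S = sum((tau / w[i]) * np.outer(V[:, i], V[:, i]) for i, tau in enumerate(taus))
        return S

    S = _pk2(C)
    sigma = (F @ S @ F.T) / J
    if not tangent:
        return sigma

    h = 1e-7 * max(1.0, float(np.abs(C).max()))
    D = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for l in range(k, 3):
            dC = np.zeros((3, 3))
            dC[k, l] = dC[l, k] = h
            dS = (_pk2(C + dC) - _pk2(C - dC)) / (2 * h)
            D[:, :, k, l] = dS
            D[:, :, l, k] = dS
    return sigma, D


def small_strain_moduli(params: OgdenParams, gamma: float = 1e-5) -> dict:
    """Numerically measured small-strain moduli of the model.

    The shear modulus is extracted from the energy of a simple-shear state,
    ``mu = 2 Psi(gamma) / gamma**2``; Poisson ratio, Young's and
    plane-contact moduli follow from ``mu`` and ``kappa``.  Values in MPa.
    """
    F = np.eye(3)
    F[0, 1] = gamma
    mu = 2.0 * strain_energy_density(params, F) / gamma**2
    kappa = params.kappa_mpa
    nu = (3 * kappa - 2 * mu) / (2 * (3 * kappa + mu))
    E = 2 * mu * (1 + nu)
    return {"mu": mu, "nu": nu, "E": E, "E_star": E / (1 - nu**2)}
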