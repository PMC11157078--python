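"""Indenter force-displacement processing.

Raw indenter records (displacement ``delta`` in mm, force ``F`` in N) are
cleaned of the pre-contact prefix, over-stroke samples and recording
outliers, then described by through-origin polynomial fits of the least
possible degree.  Region means are fitted on the pooled records of all
participants, and the pooled data additionally yields conforming upper/lower
range envelopes.  For relaxed-muscle curves a two-segment secant stiffness
summary splits the curve at ``0.45 * delta_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ForceDisplacementRecord",
    "PolyFit",
    "RangeBoundary",
    "UnusableTrialError",
    "clean_record",
    "fit_force_displacement",
    "evaluate_fit",
    "range_boundaries",
    "segment_stiffness",
]

#: Force threshold defining "detectable contact", N.  Below the load-cell
#: noise scale implied by the rig calibration (RMSE ~ 0.4 N).
CONTACT_THRESHOLD_N = 0.1

#: Outlier rule: drop samples deviating more than this many MADs from a
#: centered rolling median.
OUTLIER_K_MAD = 5.0
OUTLIER_WINDOW = 11


class UnusableTrialError(ValueError):
    """Raised when cleaning leaves no usable samples in a trial."""


@dataclass(frozen=True)
class ForceDisplacementRecord:
    """One indentation trial: ordered ``(delta mm, force N)`` samples."""

    region_id: str
    participant_id: str
    trial_id: str
    delta: np.ndarray  # mm, non-negative, non-decreasing
    force: np.ndarray  # N

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("need >= 2 paired (delta, force) samples")
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite force samples")
        if np.any(d < 0):
            raise ValueError("negative displacements")
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "force", f)

    @property
    def n_samples(self) -> int:
        return self.delta.size


@dataclass(frozen=True)
class PolyFit:
    """Through-origin polynomial ``f(delta)`` with descending coefficients.

    ``coefficients[k]`` multiplies ``delta**(degree - k)``; the trailing
    constant term is zero by construction.  The fit is valid only on
    ``0 <= delta <= delta_max``.
    """

    coefficients: tuple[float, ...]
    degree: int
    delta_max: float
    rmse: float
    r_squared: float = float("nan")

    def __post_init__(self):
        if not (1 <= self.degree <= 5):
            raise ValueError("degree must be in 1..5")
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count must equal degree + 1")
        if self.coefficients[-1] != 0.0:
            raise ValueError("fit must pass through the origin")
        if not all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")

    def __call__(self, delta):
        return evaluate_fit(self, delta)


@dataclass(frozen=True)
class RangeBoundary:
    """Upper and lower envelope fits of a region's pooled test range."""

    region_id: str
    upper: PolyFit
    lower: PolyFit


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(view, axis=1)


def clean_record(record: ForceDisplacementRecord) -> ForceDisplacementRecord:
    """Drop pre-contact, over-stroke and outlier samples from a trial.

    Leading samples with force below the contact threshold are removed, as
    are samples recorded past the maximum stroke (detected as the point of
    maximum displacement; retraction data after it is discarded).  Remaining
    samples farther than ``OUTLIER_K_MAD`` scaled MADs from a centered
    rolling median of the force are treated as recording outliers.
    """
    d, f = record.delta, record.force

    # pre-contact prefix
    above = np.nonzero(f > CONTACT_THRESHOLD_N)[0]
    if above.size == 0:
        raise UnusableTrialError(f"trial {record.trial_id}: no contact force detected")
    start = above[0]

    # past maximum stroke (end of the loading ramp)
    stop = int(np.argmax(d)) + 1
    if stop <= start + 1:
        raise UnusableTrialError(f"trial {record.trial_id}: empty after cleaning")
    d, f = d[start:stop], f[start:stop]

    # recording-related outliers on the force channel
    if d.size >= OUTLIER_WINDOW:
        med = _rolling_median(f, OUTLIER_WINDOW)
        resid = f - med
        mad = np.median(np.abs(resid))
        scale = 1.4826 * mad
        if scale > 0:
            keep = np.abs(resid) <= OUTLIER_K_MAD * scale
            d, f = d[keep], f[keep]

    if d.size < 2:
        raise UnusableTrialError(f"trial {record.trial_id}: empty after cleaning")
    return replace(record, delta=d, force=f)


def _through_origin_lstsq(d: np.ndarray, f: np.ndarray, degree: int):
    """Least-squares through-origin fit; returns (coefficients, rmse, r2)."""
    powers = np.arange(degree, 0, -1)
    design = d[:, None] ** powers[None, :]
    sol, *_ = np.linalg.lstsq(design, f, rcond=None)
    pred = design @ sol
    resid = f - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    coeffs = tuple(float(c) for c in sol) + (0.0,)
    return coeffs, rmse, r2


def fit_force_displacement(
    records: ForceDisplacementRecord | Iterable[ForceDisplacementRecord],
    max_degree: int = 5,
    rmse_tolerance: float = 1.01,
) -> PolyFit:
    """Fit the pooled samples with the least-degree through-origin polynomial.

    Degrees ``1..max_degree`` are fitted; the smallest degree whose RMSE is
    within ``rmse_tolerance`` (default 1 %) of the global minimum RMSE over
    all candidate degrees is selected, mirroring the "least possible degree
    with minimum RMSE" rule.  ``delta_max`` is the largest pooled
    displacement.
    """
    if isinstance(records, ForceDisplacementRecord):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("no records to fit")
    d = np.concatenate([r.delta for r in records])
    f = np.concatenate([r.force for r in records])
    order = np.argsort(d)
    d, f = d[order], f[order]

    max_degree = int(min(max_degree, 5, max(1, d.size - 1)))
    candidates = []
    for degree in range(1, max_degree + 1):
        coeffs, rmse, r2 = _through_origin_lstsq(d, f, degree)
        if not all(np.isfinite(coeffs)):
            raise ValueError(f"non-finite coefficients at degree {degree}")
        candidates.append((degree, coeffs, rmse, r2))

    best_rmse = min(c[2] for c in candidates)
    threshold = rmse_tolerance * best_rmse + 1e-15
    degree, coeffs, rmse, r2 = next(c for c in candidates if c[2] <= threshold)
    return PolyFit(
        coefficients=coeffs,
        degree=degree,
        delta_max=float(d.max()),
        rmse=rmse,
        r_squared=r2,
    )


def evaluate_fit(fit: PolyFit, delta) -> np.ndarray | float:
    """Horner evaluation of ``fit`` at ``delta`` (no extrapolation)."""
    d = np.asarray(delta, dtype=float)
    if np.any(d < -1e-12) or np.any(d > fit.delta_max * (1 + 1e-12)):
        raise ValueError(
            f"delta outside the fit's validity range [0, {fit.delta_max}] mm"
        )
    out = np.zeros_like(d)
    for c in fit.coefficients:
        out = out * d + c
    return float(out) if np.isscalar(delta) or d.ndim == 0 else out


def range_boundaries(
    records: Sequence[ForceDisplacementRecord],
    max_degree: int = 5,
    n_bins: int = 40,
) -> RangeBoundary:
    """Fit upper/lower envelopes of the pooled data of one region.

    The pooled samples are binned along displacement; the per-bin maxima
    (minima) are fitted with a through-origin polynomial selected by the same
    least-degree rule as the mean fit.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    region = records[0].region_id
    d = np.concatenate([r.delta for r in records])
    f = np.concatenate([r.force for r in records])

    edges = np.linspace(0.0, d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    d_hi, f_hi, d_lo, f_lo = [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        k_hi = np.argmax(f[sel])
        k_lo = np.argmin(f[sel])
        d_hi.append(d[sel][k_hi])
        f_hi.append(f[sel][k_hi])
        d_lo.append(d[sel][k_lo])
        f_lo.append(f[sel][k_lo])

    def _envelope_fit(dd, ff):
        rec = ForceDisplacementRecord(
            region_id=region,
            participant_id="<pooled>",
            trial_id="<envelope>",
            delta=np.asarray(dd),
            force=np.asarray(ff),
        )
        fit = fit_force_displacement(rec, max_degree=max_degree)
        # envelopes share the pooled validity range
        return replace(fit, delta_max=float(d.max()))

    return RangeBoundary(
        region_id=region,
        upper=_envelope_fit(d_hi, f_hi),
        lower=_envelope_fit(d_lo, f_lo),
    )


def segment_stiffness(fit: PolyFit, split_fraction: float = 0.45) -> tuple[float, float]:
    """Two-segment secant stiffnesses of a relaxed-muscle mean curve.

    The curve is split at ``s * delta_max``.  The first-segment stiffness is
    the secant slope from the origin, ``f(s*dmax) / (s*dmax)``; the second is
    the secant over the remaining segment.
    """
    if fit.delta_max <= 0:
        raise ValueError("delta_max must be positive")
    s = float(split_fraction)
    d_split = s * fit.delta_max
    f_split = evaluate_fit(fit, d_split)
    f_end = evaluate_fit(fit, fit.delta_max)
    k1 = f_split / d_split
    k2 = (f_end - f_split) / (fit.delta_max - d_split)
    return float(k1), float(k2)
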