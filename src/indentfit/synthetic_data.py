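"""Synthetic experiments: forward-model ground truth wrapped in sensor noise.

Every pipeline stage can be exercised without the human study: the FE
forward model provides the ground-truth reaction curve and deformed
surface, which are turned into a noisy indenter force stream (5 mm/s feed),
ray-cast 8x8 ToF frames from both tilted sensors (additive noise with an
RMSE target of ~0.8 mm, clipped to +-1.6 mm), and band-limited sEMG traces
with 50 Hz mains contamination.  Identical seeds reproduce identical
streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from indentfit.curves import ForceDisplacementRecord
from indentfit.tof_surface import R_CYL, SensorGeometry, ToFFrame

__all__ = [
    "NoiseSpec",
    "SyntheticExperiment",
    "generate_force_stream",
    "surface_function_from_profile",
    "render_tof_frames",
    "generate_semg",
    "build_experiment_suite",
]

FEED_RATE = 5.0  # mm/s indenter feed
FORCE_SAMPLE_HZ = 100.0


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise levels (zero-mean Gaussian, ToF clipped)."""

    force_sd: float = 0.4  # N, load-cell scale implied by rig calibration
    tof_rmse: float = 0.805  # mm, target aggregate deviation
    tof_bound: float = 1.6  # mm, clip for absolute deviations
    semg_baseline_uv: float = 6.8  # resting amplitude
    seed: int = 0

    def __post_init__(self):
        if self.tof_bound < 0 or self.tof_rmse < 0 or self.force_sd < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class SyntheticExperiment:
    """One generated experiment with its ground truth."""

    region_id: str
    c_kpa: float
    m: float
    delta_max: float
    noise: NoiseSpec
    force_record: ForceDisplacementRecord
    time_s: np.ndarray
    tof_frames: dict  # side -> list[ToFFrame]
    tof_reference: dict  # side -> ToFFrame at the zero position
    semg: dict  # channel -> np.ndarray (µV)


def generate_force_stream(
    reaction_curve,
    delta_max: float,
    noise: NoiseSpec,
    seed: int,
    region_id: str = "SYN",
    participant_id: str = "P00",
    trial_id: str = "T00",
    pre_contact_s: float = 0.5,
):
    """Noisy indenter stream: 5 mm/s ramp sampled at 100 Hz.

    ``reaction_curve`` maps displacement (mm) to force (N).  A pre-contact
    prefix of zero displacement with noise-only force exercises the
    cleaning stage.  Returns ``(record, time_s)``.
    """
    rng = np.random.default_rng(seed)
    n_pre = int(pre_contact_s * FORCE_SAMPLE_HZ)
    t_ramp = np.arange(0.0, delta_max / FEED_RATE + 1e-9, 1.0 / FORCE_SAMPLE_HZ)
    delta = np.concatenate([np.zeros(n_pre), FEED_RATE * t_ramp])
    t = np.arange(delta.size) / FORCE_SAMPLE_HZ
    force = np.asarray([float(reaction_curve(d)) for d in delta])
    force = force + rng.normal(0.0, noise.force_sd, size=force.size)
    record = ForceDisplacementRecord(
        region_id=region_id,
        participant_id=participant_id,
        trial_id=trial_id,
        delta=delta,
        force=force,
    )
    return record, t


def surface_function_from_profile(r, uz):
    """Axisymmetric surface ``z = s(radius)`` from sampled (r, u_z) pairs."""
    r = np.asarray(r, dtype=float)
    uz = np.asarray(uz, dtype=float)
    interp = PchipInterpolator(r, uz)

    def s(rad):
        rad = np.asarray(rad, dtype=float)
        out = interp(np.clip(rad, r[0], r[-1]))
        return np.where(rad > r[-1], 0.0, out)

    return s


def _ray_cast(origin, direction, surface, t_max=300.0, step=2.0):
    """Distance along a ray to the axisymmetric surface ``z = s(radius)``."""

    def h(t):
        p = origin + t * direction
        return p[2] - surface(np.hypot(p[0], p[1]))

    t_lo = 0.0
    h_lo = h(t_lo)
    t = step
    while t <= t_max:
        h_t = h(t)
        if h_lo > 0 and h_t <= 0:
            return brentq(h, t_lo, t, xtol=1e-10)
        t_lo, h_lo = t, h_t
        t += step
    return None


def render_tof_frames(
    surface,
    geometry: SensorGeometry,
    noise: NoiseSpec,
    seed: int,
    timestamps=None,
):
    """Ray-cast 8x8 distance frames of one sensor over ``timestamps``.

    ``surface`` is either a single ``z = s(radius)`` callable (static
    scene) or a mapping ``t -> callable``.  Noise is additive Gaussian with
    SD ``tof_rmse``, clipped to ``+-tof_bound``; zones whose ray misses the
    surface are flagged invalid (distance NaN is not allowed in frames, so
    they are set to the frustum limit and reported).
    """
    rng = np.random.default_rng(seed)
    if timestamps is None:
        timestamps = [0.0]
    dirs = geometry.zone_directions()
    frames = []
    for ts in timestamps:
        surf = surface(ts) if callable(surface) and _takes_time(surface) else surface
        dist = np.empty((geometry.n_zones, geometry.n_zones))
        for i in range(geometry.n_zones):
            for j in range(geometry.n_zones):
                d = _ray_cast(geometry.origin, dirs[i, j], surf)
                dist[i, j] = d if d is not None else 300.0
        if noise.tof_rmse > 0:
            eps = rng.normal(0.0, noise.tof_rmse, size=dist.shape)
            dist = dist + np.clip(eps, -noise.tof_bound, noise.tof_bound)
        frames.append(
            ToFFrame(geometry.side, float(ts), dist, rate=geometry.rate_hz)
        )
    return frames


def _takes_time(fn) -> bool:
    # a mapping t -> surface is passed as a function of one scalar returning
    # a callable; a plain surface returns array values
    try:
        probe = fn(0.0)
    except Exception:
        return False
    return callable(probe)


def generate_semg(
    activity_pct,
    channel: str,
    seed: int,
    fs: float = 1024.0,
    duration_s: float = 4.0,
    mvc_amplitude_uv: float = 235.4,
    baseline_uv: float = 6.8,
    mains_fraction: float = 0.5,
):
    """Band-limited Gaussian sEMG with activity-dependent amplitude.

    The RMS amplitude is ``baseline + activity/100 * (mvc - baseline)``
    (``activity_pct`` may be a scalar or a callable of time); a 50 Hz mains
    tone of ``mains_fraction * baseline`` amplitude is superimposed to
    exercise the notch filter.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    white = rng.standard_normal(n)
    sos = signal.butter(4, (45.0, 500.0), btype="bandpass", fs=fs, output="sos")
    band = signal.sosfilt(sos, white)
    band /= np.sqrt(np.mean(band**2))
    act = activity_pct(t) if callable(activity_pct) else float(activity_pct)
    rms = baseline_uv + np.asarray(act) / 100.0 * (mvc_amplitude_uv - baseline_uv)
    x = band * rms + mains_fraction * baseline_uv * np.sin(2 * np.pi * 50.0 * t)
    return x


def build_experiment_suite(
    solutions,
    noise: NoiseSpec,
    seed: int,
    out_dir,
    activity_pct: float = 5.0,
):
    """Write CSV fixtures plus a ground-truth manifest for test assertions.

    ``solutions`` maps an experiment name to a forward
    :class:`~indentfit.fem.solver.IndentationSolution` (its final snapshot
    provides the deformed surface; its reaction history the force curve).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "noise": asdict(noise), "experiments": {}}
    for k, (name, sol) in enumerate(sorted(solutions.items())):
        exp_seed = seed + 1000 * (k + 1)
        exp = _build_experiment(name, sol, noise, exp_seed)
        edir = out / name
        edir.mkdir(exist_ok=True)
        _write_force_csv(edir / "force.csv", exp)
        for side, frames in exp.tof_frames.items():
            _write_tof_csv(edir / f"tof_{side}.csv", frames, exp.tof_reference[side])
        _write_semg_csv(edir / "semg.csv", exp)
        manifest["experiments"][name] = {
            "c_kpa": exp.c_kpa,
            "m": exp.m,
            "delta_max_mm": exp.delta_max,
            "seed": exp_seed,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _build_experiment(name, sol, noise, exp_seed) -> SyntheticExperiment:
    delta_max = float(sol.delta_history[-1])

    def reaction_curve(d):
        return np.interp(d, sol.delta_history, sol.reaction_history)

    record, t = generate_force_stream(reaction_curve, delta_max, noise, exp_seed)
    snap = sol.snapshots[max(sol.snapshots)]
    deformed = surface_function_from_profile(snap["r"], snap["uz"])
    flat = surface_function_from_profile([0.0, R_CYL], [0.0, 0.0])
    frames, refs = {}, {}
    for s_idx, side in enumerate(("left", "right")):
        geom = SensorGeometry(side=side)
        refs[side] = render_tof_frames(flat, geom, noise, exp_seed + 7 + s_idx)[0]
        frames[side] = render_tof_frames(
            deformed, geom, noise, exp_seed + 17 + s_idx
        )
    semg = {
        ch: generate_semg(5.0, ch, exp_seed + 31 + i)
        for i, ch in enumerate(("E1", "E2", "E3"))
    }
    return SyntheticExperiment(
        region_id=name,
        c_kpa=sol.params.c_kpa,
        m=sol.params.m,
        delta_max=delta_max,
        noise=noise,
        force_record=record,
        time_s=t,
        tof_frames=frames,
        tof_reference=refs,
        semg=semg,
    )


def _write_force_csv(path, exp):
    rec = exp.force_record
    with open(path, "w") as fh:
        fh.write("time_s,displacement_mm,force_N\n")
        for t, d, f in zip(exp.time_s, rec.delta, rec.force):
            fh.write(f"{t:.4f},{d:.6f},{f:.6f}\n")


def _write_tof_csv(path, frames, reference):
    with open(path, "w") as fh:
        cols = ",".join(f"z{k}" for k in range(64))
        fh.write(f"kind,t_s,{cols}\n")
        vals = ",".join(f"{v:.4f}" for v in reference.distances.ravel())
        fh.write(f"reference,{reference.timestamp:.3f},{vals}\n")
        for fr in frames:
            vals = ",".join(f"{v:.4f}" for v in fr.distances.ravel())
            fh.write(f"frame,{fr.timestamp:.3f},{vals}\n")


def _write_semg_csv(path, exp):
    chans = sorted(exp.semg)
    n = len(exp.semg[chans[0]])
    fs = 1024.0
    with open(path, "w") as fh:
        fh.write("t_s," + ",".join(chans) + "\n")
        for i in range(n):
            row = ",".join(f"{exp.semg[ch][i]:.4f}" for ch in chans)
            fh.write(f"{i / fs:.6f},{row}\n")
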