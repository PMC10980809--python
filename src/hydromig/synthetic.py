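"""Seeded generators for every input the analysis pipeline consumes.

All generators are pure functions of their configuration: the random number
generator is numpy's default PCG64 seeded explicitly, so outputs are
bit-reproducible for a given seed on a given numpy version.

The trajectory generator is both a fixture source and a pipeline stage in
its own right (model-verification simulations are compared against measured
MSD and velocity-orientation profiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .indentation import DEFAULT_POISSON, ForceCurve, hertz_force
from .microstructure import LabeledVolume
from .tracks import Track, TrackSet

__all__ = [
    "SimulationConfig",
    "VolumeConfig",
    "simulate_aprw_tracks",
    "generate_bicontinuous_volume",
    "generate_outgrowth_mask",
    "generate_infiltration_depths",
    "generate_hertz_curves",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the anisotropic persistent-random-walk simulator.

    Speeds in um/hr, times in hours, positional noise sd ``sigma`` in um per
    coordinate.  ``internal_dt`` is the integration step; it defaults to a
    twentieth of the shortest persistence time (rounded down so the sampling
    interval is an integer multiple of it).
    """

    S_p: float = 38.47
    P_p: float = 0.56
    S_np: float = 27.9
    P_np: float = 0.56
    sigma: float = 0.5
    n_tracks: int = 200
    duration: float = 40.0
    sample_dt: float = 0.1
    internal_dt: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.P_p, self.P_np) <= 0 or self.sample_dt <= 0 or self.duration <= 0:
            raise ValueError("persistence times, sample_dt and duration must be positive")
        if min(self.S_p, self.S_np) < 0 or self.sigma < 0:
            raise ValueError("speeds and sigma must be non-negative")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.internal_dt is not None:
            p_min = min(self.P_p, self.P_np)
            if self.internal_dt > p_min / 10 + 1e-12:
                raise ValueError("internal_dt must be <= min(P)/10")
            ratio = self.sample_dt / self.internal_dt
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError("sample_dt must be an integer multiple of internal_dt")

    @property
    def resolved_internal_dt(self) -> float:
        if self.internal_dt is not None:
            return self.internal_dt
        target = min(self.P_p, self.P_np) / 20.0
        n_sub = max(1, math.ceil(self.sample_dt / target))
        return self.sample_dt / n_sub


@dataclass(frozen=True)
class VolumeConfig:
    """Parameters of the thresholded-random-field volume generator."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 1.0  # um, isotropic
    length_scale: float = 8.0  # um, Gaussian smoothing scale
    fill_fraction: float = 0.5  # target phase-1 (GR) volume fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.shape):
            raise ValueError("shape must be >= 2 along every axis")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.length_scale < self.voxel_size:
            raise ValueError("length_scale must be >= one voxel")
        if not 0 < self.fill_fraction < 1:
            raise ValueError("fill_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# APRW trajectories


def _ou_step_coeffs(S: float, P: float, dt: float) -> tuple[float, float, np.ndarray]:
    """Exact one-step update of the integrated Ornstein-Uhlenbeck process.

    The velocity follows an OU process with stationary variance S^2/2 and
    correlation time P; the position is its time integral.  Over a step dt
    the pair (position increment, new velocity) is jointly Gaussian:

        v'  = a v + eta_v,          a = exp(-dt/P)
        dx  = P (1 - a) v + eta_x

    with Var(eta_v) = q (1 - a^2), Cov(eta_x, eta_v) = q P (1 - a)^2 and
    Var(eta_x) = q P^2 (2 dt/P - 3 + 4a - a^2), q = S^2/2.  Being the exact
    transition kernel, the simulated positions follow the continuum law at
    the sample times for any step size, and the ensemble per-axis MSD equals
    S^2 P^2 (exp(-tau/P) + tau/P - 1) exactly.

    Returns ``(a, drift_coeff, chol)`` where chol is the 2x2 Cholesky factor
    of the (eta_x, eta_v) covariance.
    """
    a = math.exp(-dt / P)
    q = S * S / 2.0
    c_vv = q * (1.0 - a * a)
    c_xv = q * P * (1.0 - a) ** 2
    c_xx = q * P * P * (2.0 * dt / P - 3.0 + 4.0 * a - a * a)
    cov = np.array([[c_xx, c_xv], [c_xv, c_vv]])
    if S == 0.0:
        chol = np.zeros((2, 2))
    else:
        chol = np.linalg.cholesky(cov + 1e-300 * np.eye(2))
    return a, P * (1.0 - a), chol


def _simulate_axis(rng: np.random.Generator, S: float, P: float, dt: float,
                   n_steps: int, n_tracks: int) -> np.ndarray:
    """Positions (n_tracks, n_steps + 1) of one migration axis, starting at 0."""
    a, drift, chol = _ou_step_coeffs(S, P, dt)
    v = rng.normal(0.0, S / math.sqrt(2.0) if S > 0 else 0.0, size=n_tracks)
    x = np.zeros((n_tracks, n_steps + 1))
    z = rng.standard_normal((n_steps, n_tracks, 2))
    for i in range(n_steps):
        eta = z[i] @ chol.T  # (n_tracks, 2): (eta_x, eta_v)
        x[:, i + 1] = x[:, i] + drift * v + eta[:, 0]
        v = a * v + eta[:, 1]
    return x


def simulate_aprw_tracks(cfg: SimulationConfig) -> TrackSet:
    """Simulate 2D APRW trajectories with per-track random axis orientation.

    Each track carries independent OU velocity processes along its primary
    and non-primary axes (speeds S_p, S_np; persistence times P_p, P_np),
    initialised from the stationary distribution so the process is
    stationary from the first sample.  Positions are integrated with the
    exact transition kernel at ``internal_dt`` and kept every ``sample_dt``;
    each track's axis frame is rotated by an independent uniform angle, and
    independent Gaussian positional noise (sd ``sigma``) is added per
    coordinate, emulating localisation error of the tracker.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.resolved_internal_dt
    n_sub = int(round(cfg.sample_dt / dt))
    n_samples = int(math.floor(cfg.duration / cfg.sample_dt + 1e-9)) + 1
    n_steps = (n_samples - 1) * n_sub

    x_p = _simulate_axis(rng, cfg.S_p, cfg.P_p, dt, n_steps, cfg.n_tracks)
    x_np = _simulate_axis(rng, cfg.S_np, cfg.P_np, dt, n_steps, cfg.n_tracks)
    x_p = x_p[:, ::n_sub]
    x_np = x_np[:, ::n_sub]

    theta = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_tracks)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    x = cos_t[:, None] * x_p - sin_t[:, None] * x_np
    y = sin_t[:, None] * x_p + cos_t[:, None] * x_np
    if cfg.sigma > 0:
        x = x + rng.normal(0.0, cfg.sigma, size=x.shape)
        y = y + rng.normal(0.0, cfg.sigma, size=y.shape)

    times = np.arange(n_samples) * cfg.sample_dt
    tracks = tuple(
        Track(f"sim{i:04d}", times, np.column_stack([x[i], y[i]]))
        for i in range(cfg.n_tracks)
    )
    return TrackSet(tracks, dt=cfg.sample_dt, ndim=2)


# ---------------------------------------------------------------------------
# two-phase volumes


def generate_bicontinuous_volume(cfg: VolumeConfig) -> LabeledVolume:
    """Two-phase volume from a smoothed, thresholded Gaussian random field.

    Seeded white noise is Gaussian-smoothed at ``length_scale`` (converted
    to voxels) and thresholded at the ``1 - fill_fraction`` quantile, so the
    phase-1 volume fraction equals ``fill_fraction`` to within one voxel.
    Near 50% fill both phases percolate (bicontinuous morphology); low fill
    yields isolated phase-1 blobs in a connected phase-0 matrix.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(cfg.shape)
    sigma_vox = cfg.length_scale / cfg.voxel_size
    feld = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    thr = np.quantile(feld, 1.0 - cfg.fill_fraction)
    labels = (feld > thr).astype(np.uint8)
    vs = cfg.voxel_size
    return LabeledVolume(labels, (vs, vs, vs))


# ---------------------------------------------------------------------------
# outgrowth masks


def generate_outgrowth_mask(
    center: tuple[float, float],
    spheroid_radius: float,
    per_ray_truth: np.ndarray | list[float],
    image_shape: tuple[int, int],
    pixel_size: float = 1.0,
    arm_halfwidth_px: float = 2.0,
    start_angle_deg: float = 0.0,
    jitter_px: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary spheroid-plus-arms mask with known per-ray ground truth.

    A filled disk of ``spheroid_radius`` (um) is drawn at ``center`` (row,
    col pixels) with one straight arm per entry of ``per_ray_truth``
    extending to the given radial distance (um), equally spaced in angle
    starting at ``start_angle_deg``.  Optional seeded jitter perturbs the
    arm boundary pixels.  Returns ``(mask, truth)`` where truth echoes the
    per-ray distances actually drawn.
    """
    truth = np.asarray(per_ray_truth, dtype=float)
    if np.any(truth < 0):
        raise ValueError("per_ray_truth must be >= 0")
    rng = np.random.default_rng(seed)
    if jitter_px > 0:
        truth = np.maximum(truth + rng.normal(0.0, jitter_px * pixel_size, truth.size), 0.0)
    mask = np.zeros(image_shape, dtype=bool)
    r0, c0 = center
    rows, cols = np.mgrid[0: image_shape[0], 0: image_shape[1]]
    rad_px = np.hypot(rows - r0, cols - c0)
    mask |= rad_px <= spheroid_radius / pixel_size

    n_rays = truth.size
    angles = np.deg2rad(start_angle_deg + 360.0 * np.arange(n_rays) / n_rays)
    for ang, dist in zip(angles, truth):
        # perpendicular distance of each pixel to the ray line
        dr, dc = -(rows - r0), cols - c0  # image rows grow downwards
        along = dc * np.cos(ang) + dr * np.sin(ang)
        perp = np.abs(-dc * np.sin(ang) + dr * np.cos(ang))
        mask |= (perp <= arm_halfwidth_px) & (along >= 0) & (along <= dist / pixel_size)
    return mask, truth


# ---------------------------------------------------------------------------
# infiltration depths


def generate_infiltration_depths(
    n: int, distribution: str = "exponential", seed: int = 0, **params: float
) -> np.ndarray:
    """Depths (um) of infiltrating cells from a named distribution family.

    Families: ``point`` (value), ``uniform`` (low, high), ``exponential``
    (scale, the mean depth).  Depths are non-negative by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "point":
        return np.full(n, float(params.get("value", 0.0)))
    if distribution == "uniform":
        return rng.uniform(params.get("low", 0.0), params.get("high", 100.0), n)
    if distribution == "exponential":
        return rng.exponential(params.get("scale", 30.0), n)
    raise ValueError(f"unknown distribution {distribution!r}")


# ---------------------------------------------------------------------------
# indentation curves


def generate_hertz_curves(
    E_true: float,
    probe_radius: float = 5.0,
    poisson: float = DEFAULT_POISSON,
    noise_sd: float = 0.0,
    n_points: int = 100,
    max_depth: float = 2.0,
    n_curves: int = 1,
    seed: int = 0,
) -> list[ForceCurve]:
    """Forward-model Hertz loading curves with additive Gaussian force noise.

    ``E_true`` in kPa, probe radius and depths in um, noise in nN.  With
    ``noise_sd = 0`` a refit recovers ``E_true`` exactly.
    """
    if E_true < 0 or noise_sd < 0 or max_depth <= 0 or n_points < 2:
        raise ValueError("invalid Hertz generator parameters")
    rng = np.random.default_rng(seed)
    depth = np.linspace(0.0, max_depth, n_points)
    clean = hertz_force(depth, E_true, probe_radius, poisson)
    curves = []
    for _ in range(n_curves):
        force = clean + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
        curves.append(ForceCurve(depth, force, probe_radius, poisson))
    return curves
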