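"""Anisotropic persistent random walk (APRW) trajectory statistics.

The APRW model describes 3D cell migration, after projection to 2D, as two
independent persistent random walks along a cell-specific primary axis p and
the orthogonal non-primary axis np.  The inference chain implemented here:

1. time-averaged mean squared displacement (MSD) per track and population,
2. angular displacement distributions between consecutive steps,
3. per-cell migration axes by singular value decomposition (SVD) of the
   velocity matrix,
4. per-axis MSDs fitted jointly to the APRW forms

   MSD_p(tau)  = S_p^2  P_p^2  (exp(-tau/P_p)  + tau/P_p  - 1) + 2 sigma^2
   MSD_np(tau) = S_np^2 P_np^2 (exp(-tau/P_np) + tau/P_np - 1) + 2 sigma^2

   with a shared positional-noise variance sigma^2,
5. diffusivities D = S^2 P / 4 per axis, total diffusivity D_t = D_p + D_np,
   and the anisotropy index phi = D_p / D_np.

Speeds are um/hr, persistence times hours, diffusivities um^2/hr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .tracks import Track, TrackSet

__all__ = [
    "MSDCurve",
    "AngularDistribution",
    "AxisDecomposition",
    "APRWFit",
    "MotilityMetrics",
    "OrientationProfile",
    "AlphaFit",
    "aprw_msd",
    "track_msd",
    "population_msd",
    "fit_alpha",
    "angular_displacements",
    "svd_axes",
    "axis_msds",
    "fit_aprw",
    "fit_trackset",
    "motility_metrics",
    "orientation_profile",
    "population_summary",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD: lags (hours), values (um^2), pair counts per lag."""

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (lags.shape == values.shape == n_pairs.shape):
            raise ValueError("lags, values and n_pairs must have equal length")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must be positive and strictly increasing")
        if np.any(values < -1e-12) or np.any(n_pairs < 1):
            raise ValueError("MSD values must be >= 0 and pair counts >= 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_pairs", n_pairs)


@dataclass(frozen=True)
class AngularDistribution:
    """Histogram density of angular displacements d(theta) on [0, 180] deg."""

    lag: float
    bin_edges: np.ndarray
    density: np.ndarray  # per-degree probability density
    n_pairs: int
    n_skipped: int  # zero-magnitude velocity pairs excluded


@dataclass(frozen=True)
class AxisDecomposition:
    """Per-cell migration axes from SVD of the (non-centred) velocity matrix."""

    p_axis: np.ndarray
    np_axis: np.ndarray
    singular_values: np.ndarray  # (s1, s2), s1 >= s2
    rotated_velocities: np.ndarray  # (n_steps, 2): components along (p, np)


@dataclass(frozen=True)
class APRWFit:
    """Fitted APRW parameters for one cell."""

    S_p: float  # primary-axis speed, um/hr
    P_p: float  # primary-axis persistence time, hr
    S_np: float
    P_np: float
    sigma2: float  # positional-noise variance, um^2
    rss: float
    converged: bool
    swapped: bool = False  # axes exchanged to enforce D_p >= D_np


@dataclass(frozen=True)
class MotilityMetrics:
    """Diffusivities and anisotropy derived from an APRW fit."""

    D_p: float
    D_np: float
    D_t: float
    phi: float  # D_p / D_np; nan when D_np == 0


@dataclass(frozen=True)
class OrientationProfile:
    """Mean velocity magnitude per orientation bin relative to each cell's p axis."""

    angle_bins: np.ndarray  # bin edges, degrees on [0, 360]
    mean_speed: np.ndarray  # um/hr per bin (nan where empty)
    n_steps: np.ndarray


@dataclass(frozen=True)
class AlphaFit:
    """Power-law exponent of MSD ~ tau^alpha over a lag range."""

    alpha: float
    prefactor: float
    lag_range: tuple[float, float]
    n_lags: int


# ---------------------------------------------------------------------------
# model


def aprw_msd(tau: np.ndarray, S: float, P: float, sigma2: float = 0.0) -> np.ndarray:
    """Single-axis persistent-random-walk MSD with positional-noise floor.

    ``S^2 P^2 (exp(-tau/P) + tau/P - 1) + 2 sigma^2``; the long-lag slope is
    S^2 P and the corresponding diffusivity is S^2 P / 4.
    """
    tau = np.asarray(tau, dtype=float)
    if P <= 0:
        return np.full_like(tau, 2.0 * sigma2)
    x = tau / P
    return S**2 * P**2 * (np.exp(-x) + x - 1.0) + 2.0 * sigma2


# ---------------------------------------------------------------------------
# MSD estimation


def _uniform_dt(track: Track) -> float:
    steps = np.diff(track.times)
    if steps.size == 0:
        raise ValueError(f"track {track.id!r}: too short for MSD")
    if np.any(np.abs(steps - steps[0]) > 1e-6):
        raise ValueError(f"track {track.id!r}: non-uniform sampling")
    return float(steps[0])


def _msd_1d_or_nd(pos: np.ndarray, dt: float, max_lag_fraction: float) -> MSDCurve:
    n = pos.shape[0]
    kmax = int(np.floor(max_lag_fraction * (n - 1)))
    kmax = max(kmax, 1)
    lags = np.arange(1, kmax + 1) * dt
    values = np.empty(kmax)
    n_pairs = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        disp = pos[k:] - pos[:-k]
        sq = np.sum(disp * disp, axis=-1) if disp.ndim > 1 else disp * disp
        values[k - 1] = sq.mean()
        n_pairs[k - 1] = sq.shape[0]
    return MSDCurve(lags, values, n_pairs)


def track_msd(track: Track, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Time-averaged MSD of one track over all overlapping pairs.

    At lag ``k dt`` the estimate averages ``|r(t + k dt) - r(t)|^2`` over all
    n - k start times.  Lags run to ``floor(max_lag_fraction (n-1))`` steps;
    long lags have few pairs and high variance, hence the default cap at half
    the track duration.
    """
    if track.n_samples < 3:
        raise ValueError(f"track {track.id!r}: need >= 3 samples for MSD")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    dt = _uniform_dt(track)
    return _msd_1d_or_nd(track.positions, dt, max_lag_fraction)


def population_msd(ts: TrackSet, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Population-averaged MSD: unweighted mean of per-track MSDs per lag.

    Tracks contribute at a lag only if they are long enough to estimate it.
    """
    if len(ts) == 0:
        raise ValueError("empty TrackSet")
    curves = [track_msd(tr, max_lag_fraction) for tr in ts if tr.n_samples >= 3]
    if not curves:
        raise ValueError("no track has >= 3 samples")
    kmax = max(c.lags.size for c in curves)
    acc = np.zeros(kmax)
    cnt = np.zeros(kmax, dtype=int)
    for c in curves:
        m = c.lags.size
        acc[:m] += c.values
        cnt[:m] += 1
    lags = np.arange(1, kmax + 1) * ts.dt
    return MSDCurve(lags, acc / cnt, cnt)


def fit_alpha(msd: MSDCurve, lag_range: tuple[float, float]) -> AlphaFit:
    """Least-squares line fit of log MSD against log lag over ``lag_range``.

    The slope is the anomalous-diffusion exponent alpha: 1 for Brownian
    motion, 2 for ballistic, < 1 for sub-diffusion.
    """
    lo, hi = lag_range
    sel = (msd.lags >= lo) & (msd.lags <= hi)
    if int(sel.sum()) < 3:
        raise ValueError("need >= 3 lags inside lag_range")
    if np.any(msd.values[sel] <= 0):
        raise ValueError("zero MSD values in lag_range: log-log fit undefined")
    slope, intercept = np.polyfit(np.log(msd.lags[sel]), np.log(msd.values[sel]), 1)
    return AlphaFit(float(slope), float(np.exp(intercept)), (lo, hi), int(sel.sum()))


# ---------------------------------------------------------------------------
# angular displacements


def angular_displacements(ts: TrackSet, lag: float, n_bins: int = 36) -> AngularDistribution:
    """Distribution of angles between velocity pairs separated by ``lag``.

    d(theta) = arccos( v_t . v_{t+lag} / (|v_t| |v_{t+lag}|) ), pooled over
    all tracks and start times; pairs with a zero-magnitude velocity are
    skipped and counted.  Density is per degree on [0, 180].
    """
    k = int(round(lag / ts.dt))
    if abs(k * ts.dt - lag) > 1e-6 or k < 1:
        raise ValueError(f"lag must be a positive multiple of dt={ts.dt}")
    angles: list[np.ndarray] = []
    n_skipped = 0
    for tr in ts:
        if tr.n_samples < k + 2:
            continue
        v = tr.velocities(ts.dt)
        v1, v2 = v[:-k], v[k:]
        m1 = np.linalg.norm(v1, axis=1)
        m2 = np.linalg.norm(v2, axis=1)
        ok = (m1 > 0) & (m2 > 0)
        n_skipped += int((~ok).sum())
        cosang = np.sum(v1[ok] * v2[ok], axis=1) / (m1[ok] * m2[ok])
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if not angles:
        raise ValueError(f"lag {lag} h too large for every track")
    pooled = np.concatenate(angles)
    if pooled.size == 0:
        raise ValueError("no velocity pair with non-zero magnitudes at this lag")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    return AngularDistribution(lag, edges, density, pooled.size, n_skipped)


# ---------------------------------------------------------------------------
# migration axes


def svd_axes(track: Track, dt: float | None = None) -> AxisDecomposition:
    """Primary / non-primary migration axes of one 2D track.

    The velocity matrix (rows = steps, columns = x, y) is decomposed by SVD
    *without* mean-centring, so a net drift contributes to the primary axis.
    The right singular vector of the larger singular value is the primary
    axis p; velocities are returned rotated into the (p, np) frame.
    """
    if track.ndim != 2:
        raise ValueError("svd_axes requires a 2D track (project first)")
    if track.n_samples < 3:
        raise ValueError(f"track {track.id!r}: need >= 3 samples")
    dt = _uniform_dt(track) if dt is None else dt
    v = track.velocities(dt)
    if np.allclose(v, 0.0):
        raise ValueError(f"track {track.id!r}: all velocities zero, axes degenerate")
    _, s, vt = np.linalg.svd(v, full_matrices=False)
    p_axis, np_axis = vt[0], vt[1]
    # fix handedness so (p, np) is a right-handed frame
    if p_axis[0] * np_axis[1] - p_axis[1] * np_axis[0] < 0:
        np_axis = -np_axis
    rotated = v @ np.column_stack([p_axis, np_axis])
    return AxisDecomposition(p_axis, np_axis, s[:2], rotated)


def axis_msds(
    track: Track, axes: AxisDecomposition, max_lag_fraction: float = 0.5
) -> tuple[MSDCurve, MSDCurve]:
    """1D MSDs of the track coordinates projected on the p and np axes.

    Their sum equals the 2D MSD at every lag (orthonormality of the axes).
    """
    dt = _uniform_dt(track)
    coord_p = track.positions @ axes.p_axis
    coord_np = track.positions @ axes.np_axis
    return (
        _msd_1d_or_nd(coord_p, dt, max_lag_fraction),
        _msd_1d_or_nd(coord_np, dt, max_lag_fraction),
    )


# ---------------------------------------------------------------------------
# APRW fitting


_LOG_EPS = 1e-12


def _aprw_residuals(theta: np.ndarray, lags: np.ndarray, y_p: np.ndarray,
                    y_np: np.ndarray, log_space: bool) -> np.ndarray:
    s_p, p_p, s_np, p_np, sig2 = theta
    m_p = aprw_msd(lags, s_p, p_p, sig2)
    m_np = aprw_msd(lags, s_np, p_np, sig2)
    if log_space:
        return np.concatenate([
            np.log(m_p + _LOG_EPS) - np.log(y_p + _LOG_EPS),
            np.log(m_np + _LOG_EPS) - np.log(y_np + _LOG_EPS),
        ])
    return np.concatenate([m_p - y_p, m_np - y_np])


def fit_aprw(msd_p: MSDCurve, msd_np: MSDCurve, n_starts: int = 5,
             residuals: str = "log") -> APRWFit:
    """Joint nonlinear least squares of the two per-axis MSD curves.

    One positional-noise variance sigma^2 is shared between the two axes
    (both model equations carry the same 2 sigma^2 offset).  Residuals are
    taken in log space by default: MSD values span orders of magnitude and
    their fluctuations are roughly multiplicative, so a linear-space fit is
    dominated by the largest (and most uncertain) lags and can run away to a
    spurious ballistic solution on single-cell curves.  ``residuals =
    "linear"`` selects plain unweighted residuals instead.

    Persistence times are bounded above by the largest fitted lag — a
    correlation time longer than the observation window is not identifiable
    from the curve.  Multi-start: persistence-time guesses log-spaced
    between the first lag and half the window, speeds from the long-lag
    slope S^2 P.  If the fitted primary axis turns out slower-diffusing
    than the non-primary one, the axes are swapped so that D_p >= D_np by
    convention.
    """
    if msd_p.lags.size != msd_np.lags.size or not np.allclose(msd_p.lags, msd_np.lags):
        raise ValueError("the two MSD curves must share identical lags")
    if residuals not in ("log", "linear"):
        raise ValueError("residuals must be 'log' or 'linear'")
    lags, y_p, y_np = msd_p.lags, msd_p.values, msd_np.values
    if lags.size < 5:
        raise ValueError("need >= 5 lags for the APRW fit")

    dt = lags[0]
    p_max = lags[-1]
    # long-lag slope estimates S^2 P per axis
    half = lags.size // 2
    slope_p = max(np.polyfit(lags[half:], y_p[half:], 1)[0], 1e-12)
    slope_np = max(np.polyfit(lags[half:], y_np[half:], 1)[0], 1e-12)
    sig2_0 = max(min(y_p[0], y_np[0]) / 2.0, 1e-9)

    # the noise floor 2 sigma^2 cannot exceed the observed first-lag MSD;
    # capping sigma^2 removes a degenerate optimum in which one axis's whole
    # curve is absorbed into an absurdly large noise term
    sig2_cap = max(min(y_p[0], y_np[0]), 1e-9)
    lower = np.zeros(5)
    upper = np.array([np.inf, p_max, np.inf, p_max, sig2_cap])
    p_guesses = np.geomspace(dt, max(p_max / 2.0, dt * 1.01), n_starts)
    best = None
    for p0 in p_guesses:
        theta0 = np.array([
            np.sqrt(slope_p / p0), p0,
            np.sqrt(slope_np / p0), p0,
            sig2_0,
        ])
        try:
            res = optimize.least_squares(
                _aprw_residuals, theta0,
                bounds=(lower, upper),
                args=(lags, y_p, y_np, residuals == "log"),
                x_scale=np.maximum(theta0, 1e-6),
                method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return APRWFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)

    s_p, p_p, s_np, p_np, sig2 = best.x
    swapped = False
    if s_p**2 * p_p < s_np**2 * p_np:
        s_p, p_p, s_np, p_np = s_np, p_np, s_p, p_p
        swapped = True
    return APRWFit(
        float(s_p), float(p_p), float(s_np), float(p_np), float(sig2),
        rss=float(2.0 * best.cost), converged=bool(best.status > 0),
        swapped=swapped,
    )


def motility_metrics(fit: APRWFit) -> MotilityMetrics:
    """Diffusivities D = S^2 P / 4 per axis, total D_t, anisotropy phi.

    phi is flagged undefined (nan) when the non-primary diffusivity is zero
    to numerical precision — the ratio is unmeasurable for such a cell.
    """
    d_p = fit.S_p**2 * fit.P_p / 4.0
    d_np = fit.S_np**2 * fit.P_np / 4.0
    resolvable = d_np > 1e-9 * max(d_p, 1.0)
    phi = d_p / d_np if resolvable else float("nan")
    return MotilityMetrics(d_p, d_np, d_p + d_np, phi)


def fit_trackset(ts: TrackSet, fit_lag_fraction: float = 0.1,
                 residuals: str = "log",
                 fit_window: float | None = None) -> list[APRWFit]:
    """Per-cell APRW fits for every track in the set.

    ``fit_lag_fraction`` caps the lags entering the per-cell fit at that
    fraction of each track's duration (default one tenth).  Single-track
    time-averaged MSDs at longer lags average very few displacement pairs
    and their scatter grows steeply with lag, so a short window gives
    markedly lower-variance parameter estimates; the cap is an estimator
    choice, independent of the (longer) window used for population MSDs.
    ``fit_window`` (hours) overrides the fractional cap with an absolute
    one — useful for very long tracks, where the information about (S, P)
    saturates a few persistence times past the ballistic-diffusive corner
    while the noise keeps growing with lag.  Tracks whose axes are
    degenerate or that are too short are skipped.
    """
    fits = []
    for tr in ts:
        frac = fit_lag_fraction
        if fit_window is not None and tr.n_samples > 1:
            span = tr.times[-1] - tr.times[0]
            frac = min(frac, fit_window / span) if span > 0 else frac
        try:
            axes = svd_axes(tr, ts.dt)
            msd_p, msd_np = axis_msds(tr, axes, frac)
            fits.append(fit_aprw(msd_p, msd_np, residuals=residuals))
        except ValueError:
            continue
    return fits


# ---------------------------------------------------------------------------
# population-level summaries


def orientation_profile(ts: TrackSet, n_bins: int = 24) -> OrientationProfile:
    """Mean velocity magnitude per orientation bin, relative to each cell's p axis.

    Each track's steps are rotated into its own (p, np) frame before pooling,
    so anisotropic migration shows up as maxima at 0 and 180 degrees.
    """
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    speeds: list[np.ndarray] = []
    angs: list[np.ndarray] = []
    for tr in ts:
        try:
            axes = svd_axes(tr, ts.dt)
        except ValueError:
            continue
        v = axes.rotated_velocities
        mag = np.linalg.norm(v, axis=1)
        ok = mag > 0
        speeds.append(mag[ok])
        angs.append(np.degrees(np.arctan2(v[ok, 1], v[ok, 0])) % 360.0)
    if not speeds:
        raise ValueError("no track yields migration axes")
    spd = np.concatenate(speeds)
    ang = np.concatenate(angs)
    idx = np.clip(np.digitize(ang, edges) - 1, 0, n_bins - 1)
    mean_speed = np.full(n_bins, np.nan)
    n_steps = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        n_steps[b] = int(sel.sum())
        if n_steps[b]:
            mean_speed[b] = float(spd[sel].mean())
    return OrientationProfile(edges, mean_speed, n_steps)


def population_summary(fits: Iterable[APRWFit]) -> dict[str, float]:
    """Arithmetic means of per-cell APRW parameters and derived metrics.

    Metrics (diffusivities, phi) are computed per cell and then averaged;
    the mean of per-cell ratios differs in general from the ratio of means,
    so ``phi_of_means`` is reported alongside for comparison.  Non-converged
    fits are excluded and counted.
    """
    fits = list(fits)
    good = [f for f in fits if f.converged and np.isfinite(f.S_p)]
    if not good:
        raise ValueError("no converged fits to summarise")
    metrics = [motility_metrics(f) for f in good]
    phis = np.array([m.phi for m in metrics])
    d_p = np.array([m.D_p for m in metrics])
    d_np = np.array([m.D_np for m in metrics])
    return {
        "n_cells": len(good),
        "n_excluded": len(fits) - len(good),
        "S_p": float(np.mean([f.S_p for f in good])),
        "P_p": float(np.mean([f.P_p for f in good])),
        "S_np": float(np.mean([f.S_np for f in good])),
        "P_np": float(np.mean([f.P_np for f in good])),
        "sigma2": float(np.mean([f.sigma2 for f in good])),
        "D_p": float(d_p.mean()),
        "D_np": float(d_np.mean()),
        "D_t": float((d_p + d_np).mean()),
        "phi": float(np.nanmean(phis)),
        "phi_of_means": float(d_p.mean() / d_np.mean()) if d_np.mean() > 0 else float("nan"),
    }
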