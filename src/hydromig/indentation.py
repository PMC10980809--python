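"""Hertz spherical-indentation fitting and force-map statistics.

AFM nanoindentation with a spherical probe on a soft gel is summarised by an
effective indentation modulus E_ind obtained from the Hertz contact relation

    F = (4/3) * E_ind / (1 - nu^2) * sqrt(R) * delta^(3/2)

with F the force (nN), delta the indentation depth (um), R the probe radius
(um) and nu the Poisson ratio (0.49 for highly swollen hydrogels).  With
these units E_ind comes out in kPa directly.  Grids of fitted moduli (force
maps) are summarised after interquartile-range (IQR) outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ForceCurve",
    "IndentationResult",
    "ForceMap",
    "hertz_force",
    "fit_hertz",
    "iqr_mask",
    "map_stats",
    "DEFAULT_POISSON",
]

DEFAULT_POISSON = 0.49  # highly swollen hydrogel


@dataclass(frozen=True)
class ForceCurve:
    """Loading portion of one indentation: depth (um) and force (nN)."""

    depth: np.ndarray
    force: np.ndarray
    probe_radius: float  # um
    poisson: float = DEFAULT_POISSON

    def __post_init__(self) -> None:
        d = np.asarray(self.depth, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("depth and force must be 1D arrays of equal length")
        if np.any(d < 0) or np.any(np.diff(d) < 0):
            raise ValueError("depth must be non-negative and non-decreasing")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        object.__setattr__(self, "depth", d)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class IndentationResult:
    """Fitted effective indentation modulus for one curve."""

    E_ind: float  # kPa
    contact_offset: float  # um (0 unless fitted)
    rss: float  # nN^2


@dataclass(frozen=True)
class ForceMap:
    """Rectangular grid of fitted moduli (kPa) over stage positions."""

    moduli: np.ndarray  # 2D, kPa; nan = failed curve
    pitch: tuple[float, float] = (15.0, 15.0)  # um between grid nodes


def hertz_force(delta: np.ndarray, E_ind: float, probe_radius: float,
                poisson: float = DEFAULT_POISSON) -> np.ndarray:
    """Spherical-indenter Hertz force (nN) at depth delta (um), E_ind in kPa."""
    delta = np.asarray(delta, dtype=float)
    return (4.0 / 3.0) * (E_ind / (1.0 - poisson**2)) * np.sqrt(probe_radius) * delta**1.5


def fit_hertz(curve: ForceCurve, fit_offset: bool = False) -> IndentationResult:
    """Least-squares Hertz fit of the entire loading portion of one curve.

    The model is linear in E_ind, so with the contact point taken at
    delta = 0 (curves pre-zeroed at contact, the default) the fit is the
    non-negative closed-form projection.  With ``fit_offset`` a contact
    offset delta_0 is fitted jointly for curves that were not zeroed:
    F = k E (delta - delta_0)_+^{3/2}.
    """
    if curve.depth.size < 5:
        raise ValueError("need >= 5 points to fit")
    k = (4.0 / 3.0) / (1.0 - curve.poisson**2) * np.sqrt(curve.probe_radius)
    if not fit_offset:
        basis = k * curve.depth**1.5
        denom = float(basis @ basis)
        e = max(float(basis @ curve.force) / denom, 0.0) if denom > 0 else 0.0
        resid = curve.force - e * basis
        return IndentationResult(e, 0.0, float(resid @ resid))

    def resid(theta: np.ndarray) -> np.ndarray:
        e, d0 = theta
        eff = np.clip(curve.depth - d0, 0.0, None)
        return k * e * eff**1.5 - curve.force

    e0 = max(fit_hertz(curve, fit_offset=False).E_ind, 1e-6)
    res = optimize.least_squares(
        resid, np.array([e0, 0.0]),
        bounds=([0.0, 0.0], [np.inf, float(curve.depth[-1])]),
    )
    if not res.success:
        raise RuntimeError(f"Hertz fit failed: {res.message}")
    return IndentationResult(float(res.x[0]), float(res.x[1]), float(2.0 * res.cost))


def iqr_mask(values: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Boolean mask of entries inside [Q1 - factor*IQR, Q3 + factor*IQR].

    Quartiles by linear interpolation; nan entries are always masked out.
    Idempotent in the sense that re-masking the survivors with their own
    quartiles is not applied — the rule is a single pass, as conventional.
    """
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    q1, q3 = np.percentile(vals[finite], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return finite & (vals >= lo) & (vals <= hi)


def map_stats(fmap: ForceMap, iqr_factor: float = 1.5) -> dict[str, float]:
    """Mean modulus, coefficient of variation and outlier count of a force map.

    Entries outside the IQR fence are removed before the mean and CV
    (std/mean) are computed; removed entries are counted, never silently
    dropped from the report.
    """
    vals = np.asarray(fmap.moduli, dtype=float).ravel()
    if np.isfinite(vals).sum() < 4:
        raise ValueError("need >= 4 valid grid entries")
    keep = iqr_mask(vals, iqr_factor)
    survivors = vals[keep]
    if survivors.size == 0:
        raise ValueError("all entries removed as outliers")
    mean = float(survivors.mean())
    cv = float(survivors.std() / mean) if mean != 0 else float("nan")
    return {
        "mean_kpa": mean,
        "cv": cv,
        "n_outliers": int(np.isfinite(vals).sum() - survivors.size),
        "n_used": int(survivors.size),
    }
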