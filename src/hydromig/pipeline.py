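"""End-to-end pipeline runs: tracks -> APRW summary, volume -> morphometrics.

Every run returns (and optionally writes) a JSON-serialisable summary with a
provenance block (configuration echo, seed, package version) sufficient to
reproduce it bit-for-bit.  Filtering stages log input/output counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from . import aprw
from .microstructure import LabeledVolume, structure_metrics
from .tracks import (
    TrackSet,
    filter_short_tracks,
    project_to_2d,
    read_tracks,
    speed_vs_time,
    truncate_tracks,
)

logger = logging.getLogger("hydromig")

__all__ = ["TracksPipelineConfig", "run_tracks_pipeline", "run_volume_pipeline", "make_report"]


@dataclass(frozen=True)
class TracksPipelineConfig:
    """Analysis settings for the trajectory pipeline.

    Defaults follow the study conventions: 30 um minimum track path length,
    analysis gated to t >= 30 h (set ``t_start = 0`` for simulated data that
    is stationary from the first frame), MSD lags capped at half the track
    duration.
    """

    min_path_length: float = 30.0  # um
    t_start: float = 30.0  # hours
    max_lag_fraction: float = 0.5  # population MSD window
    fit_lag_fraction: float = 0.1  # per-cell fit window (see aprw.fit_trackset)
    alpha_lag_range: tuple[float, float] | None = None  # default: [2, 20] x dt-scale
    angular_lags: tuple[float, ...] = ()  # hours; empty = skip
    n_orientation_bins: int = 24


def run_tracks_pipeline(
    ts: TrackSet | str | Path,
    cfg: TracksPipelineConfig = TracksPipelineConfig(),
    out: str | Path | None = None,
) -> dict[str, Any]:
    """Full trajectory analysis: filter, project, truncate, fit, summarise."""
    if not isinstance(ts, TrackSet):
        ts = read_tracks(ts)
    n0 = len(ts)
    ts = filter_short_tracks(ts, cfg.min_path_length)
    logger.info("path-length filter (>= %g um): %d -> %d tracks", cfg.min_path_length, n0, len(ts))
    if ts.ndim == 3:
        ts = project_to_2d(ts)
    n1 = len(ts)
    if cfg.t_start > 0:
        ts = truncate_tracks(ts, cfg.t_start)
        logger.info("time gate (t >= %g h): %d -> %d tracks", cfg.t_start, n1, len(ts))
    if len(ts) == 0:
        raise ValueError("no tracks remain after filtering")

    pop_msd = aprw.population_msd(ts, cfg.max_lag_fraction)
    lag_range = cfg.alpha_lag_range or (
        max(2.0, 2 * ts.dt), min(20.0, pop_msd.lags[-1])
    )
    alpha = aprw.fit_alpha(pop_msd, lag_range)
    fits = aprw.fit_trackset(ts, cfg.fit_lag_fraction)
    summary = aprw.population_summary(fits)
    profile = aprw.orientation_profile(ts, cfg.n_orientation_bins)

    result: dict[str, Any] = {
        "n_tracks_input": n0,
        "n_tracks_analysed": len(ts),
        "alpha": alpha.alpha,
        "alpha_lag_range_h": list(alpha.lag_range),
        "population": summary,
        "population_msd": {
            "lags_h": pop_msd.lags.tolist(),
            "msd_um2": pop_msd.values.tolist(),
        },
        "orientation_profile": {
            "bin_edges_deg": profile.angle_bins.tolist(),
            "mean_speed_um_hr": [None if np.isnan(v) else v for v in profile.mean_speed],
        },
        "provenance": {"config": asdict(cfg), "version": __version__},
    }
    for lag in cfg.angular_lags:
        dist = aprw.angular_displacements(ts, lag)
        result.setdefault("angular_displacements", {})[f"lag_{lag}_h"] = {
            "bin_edges_deg": dist.bin_edges.tolist(),
            "density_per_deg": dist.density.tolist(),
        }
    if out is not None:
        Path(out).write_text(json.dumps(result, indent=2))
    return result


def run_volume_pipeline(
    vol: LabeledVolume,
    neighborhood: int = 26,
    out: str | Path | None = None,
) -> dict[str, Any]:
    """Morphometrics of one labelled volume as a JSON-serialisable summary."""
    metrics = structure_metrics(vol, neighborhood)
    result = {
        **metrics.to_dict(),
        "provenance": {
            "neighborhood": neighborhood,
            "shape": list(vol.labels.shape),
            "voxel_size_um": list(vol.voxel_size),
            "version": __version__,
        },
    }
    if out is not None:
        Path(out).write_text(json.dumps(result, indent=2))
    return result


def make_report(results: list[str | Path]) -> str:
    """Render one or more JSON result files as a human-readable text report."""
    lines = [f"hydromig report (v{__version__})", "=" * 40]
    for path in results:
        path = Path(path)
        data = json.loads(path.read_text())
        lines.append(f"\n[{path.name}]")
        lines.extend(_render(data, indent=2))
    return "\n".join(lines) + "\n"


def _render(obj: Any, indent: int) -> list[str]:
    pad = " " * indent
    lines = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)) and k not in ("provenance",):
                if isinstance(v, list) and len(v) > 8:
                    lines.append(f"{pad}{k}: [{len(v)} values]")
                else:
                    lines.append(f"{pad}{k}:")
                    lines.extend(_render(v, indent + 2))
            elif k == "provenance":
                lines.append(f"{pad}provenance: {json.dumps(v, sort_keys=True)}")
            else:
                lines.append(f"{pad}{k}: {_fmt(v)}")
    elif isinstance(obj, list):
        for v in obj:
            lines.append(f"{pad}- {_fmt(v)}")
    else:
        lines.append(f"{pad}{_fmt(obj)}")
    return lines


def _fmt(v: Any) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)
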