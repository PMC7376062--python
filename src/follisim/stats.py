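"""Emergent migration statistics: speed, meandering index, motility
coefficient and stromal scanning rate.

These are the four quantities the optimization objectives are built from:
three are calibrated against experimental B-cell migration data (speed,
meandering index, motility coefficient) and the fourth (scanning rate)
quantifies how efficiently agents survey distinct stromal cells.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import BCellTrack


@dataclass
class MigrationSummary:
    """Per-run medians over cells; units in field notation.

    speed µm·min⁻¹; meandering index in [0,1] (net displacement over path
    length); motility coefficient µm²·min⁻¹ (MSD slope / 2·dim); scanning
    rate in unique stromal nodes per cell per hour.
    """

    speed: float
    meandering_index: float
    motility_coefficient: float
    scanning_rate: float
    n_tracks: int
    n_excluded: int = 0

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.speed, self.meandering_index,
             self.motility_coefficient, self.scanning_rate]
        )

    METRIC_NAMES = ("speed", "meandering_index", "motility_coefficient",
                    "scanning_rate")


def _resample(track: BCellTrack, dt_sample: float) -> np.ndarray:
    """Positions at dt_sample cadence (nearest-sample decimation)."""
    t = track.times
    if len(t) < 2:
        return track.positions
    stride = max(int(round(dt_sample / (t[1] - t[0]))), 1)
    return track.positions[::stride]


def msd_curve(positions: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD at lags 1..max_lag (single track)."""
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = positions[k:] - positions[:-k]
        out[k - 1] = float((d**2).sum(axis=1).mean())
    return out


def motility_coefficient(
    positions: np.ndarray, dt: float, dim: int = 3, lag_fraction: float = 0.25
) -> float:
    """Effective diffusivity from an origin-constrained OLS fit of MSD vs time.

    The fit uses lags up to ``lag_fraction`` of the track length, where the
    time-averaged MSD is least biased.
    """
    n = len(positions)
    max_lag = max(int(lag_fraction * (n - 1)), 1)
    msd = msd_curve(positions, max_lag)
    taus = np.arange(1, max_lag + 1) * dt
    slope = float((taus @ msd) / (taus @ taus))  # OLS through the origin
    return max(slope / (2 * dim), 0.0)


def summarize(
    tracks: list[BCellTrack],
    dt_sample: float = 30.0,
    duration: float | None = None,
    dim: int = 3,
) -> MigrationSummary:
    """Median per-cell migration statistics for one simulation run."""
    speeds, meanders, motilities, scans = [], [], [], []
    excluded = 0
    total_h = None
    for tr in tracks:
        p = _resample(tr, dt_sample)
        if len(p) < 2:
            excluded += 1
            continue
        stride = max(int(round(dt_sample / (tr.times[1] - tr.times[0]))), 1)
        dt_eff = (tr.times[1] - tr.times[0]) * stride
        steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
        path = float(steps.sum())
        speeds.append(steps.mean() / dt_eff * 60.0)  # µm/min
        net_disp = float(np.linalg.norm(p[-1] - p[0]))
        meanders.append(net_disp / path if path > 0 else 0.0)
        motilities.append(motility_coefficient(p, dt_eff, dim=dim) * 60.0)  # µm²/min
        total_h = (tr.times[-1] - tr.times[0]) / 3600.0 if duration is None \
            else duration / 3600.0
        scans.append(len(tr.contacts) / total_h if total_h > 0 else 0.0)
    if not speeds:
        raise ValueError("no track has >= 2 samples at this dt_sample")
    return MigrationSummary(
        speed=float(np.median(speeds)),
        meandering_index=float(np.median(meanders)),
        motility_coefficient=float(np.median(motilities)),
        scanning_rate=float(np.median(scans)),
        n_tracks=len(speeds),
        n_excluded=excluded,
    )
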