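"""Stationary-interval selection and normalized distributions.

Microsecond trajectories of a membrane-anchored protein start from a
prepared configuration, so an initial non-stationary portion (here declared
by the user, e.g. t < 1 μs) is excluded before computing distributions.
Intervals are half-open, ``t0 <= t < t1``, so consecutive windows partition
a trajectory without double counting.  Histograms are density-normalized
(they integrate to 1 over the binned range).

Angles on [0°, 180°] are summarized with plain linear statistics — the
deviation angle is a polar angle against a fixed axis, not a periodic
variable, so circular statistics would be wrong here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigError, SelectionError
from .series import AngleSeries, TimeSeries

__all__ = [
    "DistributionResult",
    "SummaryStats",
    "select_interval",
    "histogram",
    "summarize",
    "DEFAULT_BIN_WIDTHS",
]

#: default bin widths per observable kind (degrees, Å, Å)
DEFAULT_BIN_WIDTHS = {"angle": 2.5, "z": 1.0, "rg": 0.5}


@dataclass
class DistributionResult:
    """Density-normalized histogram over a stated time interval."""

    bin_edges: np.ndarray
    densities: np.ndarray
    interval: tuple[float, float]
    n_frames: int
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.densities = np.asarray(self.densities, dtype=np.float64)
        if len(self.bin_edges) != len(self.densities) + 1:
            raise ConfigError("need len(bin_edges) == len(densities) + 1")
        if (self.densities < 0).any():
            raise ConfigError("densities must be non-negative")
        if self.n_frames < 1:
            raise ConfigError("a distribution needs at least one frame")
        total = float(self.densities @ np.diff(self.bin_edges))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"histogram integrates to {total}, not 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


class SummaryStats(NamedTuple):
    mean: float
    mode_bin: tuple[float, float]
    width: float  # standard deviation around the mean


def select_interval(series: TimeSeries, t0: float, t1: float) -> TimeSeries:
    """Frames with ``t0 <= t < t1`` (order preserved)."""
    if not t0 < t1:
        raise ConfigError(f"need t0 < t1, got [{t0}, {t1})")
    mask = (series.times >= t0) & (series.times < t1)
    if not mask.any():
        raise SelectionError(
            f"interval [{t0}, {t1}) μs contains no frames "
            f"(series spans [{series.times[0]:g}, {series.times[-1]:g}] μs)"
        )
    cls = type(series)
    return cls(series.times[mask], series.values[mask], series.label)


def histogram(
    series: TimeSeries | np.ndarray,
    bin_width: float | None = None,
    edges: np.ndarray | None = None,
    interval: tuple[float, float] | None = None,
) -> DistributionResult:
    """Density-normalized histogram of a series (optionally restricted to a
    half-open time interval first).

    Exactly one of ``bin_width`` or ``edges`` must be given.  With a bin
    width, edges are anchored at integer multiples of the width so binning
    is deterministic and comparable across intervals.
    """
    label = ""
    if isinstance(series, TimeSeries):
        if interval is not None:
            series = select_interval(series, *interval)
        values = series.values
        label = series.label
        interval = (float(series.times[0]), float(series.times[-1]))
    else:
        values = np.asarray(series, dtype=np.float64)
        if interval is None:
            interval = (0.0, float(max(values.size, 1)))
    if values.size == 0:
        raise SelectionError("cannot histogram an empty series")
    if not np.isfinite(values).all():
        bad = np.nonzero(~np.isfinite(values))[0]
        raise ConfigError(f"non-finite values at frames {bad.tolist()[:10]}")
    if (bin_width is None) == (edges is None):
        raise ConfigError("give exactly one of bin_width or edges")
    if edges is None:
        if bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = lo + bin_width * np.arange(round((hi - lo) / bin_width) + 1)
    densities, edges = np.histogram(values, bins=np.asarray(edges), density=True)
    return DistributionResult(
        bin_edges=edges,
        densities=densities,
        interval=interval,
        n_frames=int(values.size),
        label=label,
    )


def summarize(dist: DistributionResult) -> SummaryStats:
    """Mean, mode bin and standard deviation of a binned distribution."""
    widths = np.diff(dist.bin_edges)
    weights = dist.densities * widths
    centers = dist.bin_centers
    mean = float(weights @ centers)
    k = int(np.argmax(dist.densities))
    var = float(weights @ (centers - mean) ** 2)
    return SummaryStats(
        mean=mean,
        mode_bin=(float(dist.bin_edges[k]), float(dist.bin_edges[k + 1])),
        width=float(np.sqrt(max(var, 0.0))),
    )
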