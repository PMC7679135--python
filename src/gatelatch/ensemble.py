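"""Replicate handling and the statistical toolkit for MD ensembles.

Distributions pool frames, subunits and (when requested) repeats; scalar
summaries quoted with an error bar are computed per repeat first and the
standard error is taken over repeats.  Welch tests and Pearson correlations
are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .structure import Trajectory

__all__ = [
    "DistanceDistribution",
    "trim_equilibration",
    "distance_distribution",
    "repeat_mean_sem",
    "welch_two_sided",
    "pearson",
    "contact_auc",
]

DEFAULT_EQUILIBRATION_NS = 100.0
DEFAULT_DISTANCE_BIN = 0.2  # Å


@dataclass
class DistanceDistribution:
    """Normalized histogram p(d) over distance bins (Å)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int
    source_label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probabilities.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total})")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def trim_equilibration(traj: Trajectory, t_eq: float = DEFAULT_EQUILIBRATION_NS) -> Trajectory:
    """Drop the equilibration window: frames with time ≤ ``t_eq`` ns.

    Frame spacing is preserved and retained frames keep their absolute times.
    """
    if t_eq < 0:
        raise ValueError("t_eq must be non-negative")
    duration = traj.times[-1]
    if t_eq >= duration:
        raise ValueError(
            f"t_eq = {t_eq} ns is not shorter than the trajectory ({duration} ns)"
        )
    keep = traj.times > t_eq
    n_removed = int(np.sum(~keep))
    return Trajectory(
        topology=traj.topology,
        coords=traj.coords[keep],
        frame_spacing=traj.frame_spacing,
        repeat_id=traj.repeat_id,
        time_offset=traj.time_offset + n_removed * traj.frame_spacing,
    )


def distance_distribution(
    samples: np.ndarray | Sequence[float],
    bin_width: float = DEFAULT_DISTANCE_BIN,
    source_label: str = "",
    bin_range: tuple[float, float] | None = None,
) -> DistanceDistribution:
    """Normalized histogram of pooled distance samples.

    ``samples`` may be any array (e.g. the (frames × subunits) values of a
    :class:`~gatelatch.geometry.DistanceSeries`, or several repeats
    concatenated); it is flattened before binning.  Bin edges are aligned to
    integer multiples of ``bin_width`` so distributions from disjoint sample
    sets share edges.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot build a distribution from zero samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("distance samples must be finite")
    if bin_range is None:
        lo = np.floor(x.min() / bin_width) * bin_width
        hi = np.ceil(x.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = bin_range
    nbins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return DistanceDistribution(
        bin_edges=edges,
        probabilities=counts / counts.sum(),
        n_samples=int(x.size),
        source_label=source_label,
    )


def repeat_mean_sem(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and standard error over simulation repeats.

    SEM is the sample standard deviation (ddof=1) divided by √n.  With a
    single repeat the mean is returned with SEM ``None`` (undefined, never a
    silent zero); an empty input is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no repeats supplied")
    mean = float(x.mean())
    if x.size == 1:
        return mean, None
    return mean, float(x.std(ddof=1) / np.sqrt(x.size))


def welch_two_sided(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch's t-test (unequal variances); returns ``(t, p)``.

    Degenerate case: both groups with zero variance and equal means gives
    ``(0, 1)`` by convention; zero variance in both with unequal means is an
    error (the statistic is unbounded).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch test needs at least 2 samples per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("both groups have zero variance but unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if xv.var() == 0 or yv.var() == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(xv, yv).statistic)


def contact_auc(dist: DistanceDistribution, cutoff: float = 7.0) -> float:
    """Probability mass below ``cutoff`` Å (fraction in [0, 1]).

    Bins entirely below the cutoff contribute fully; the straddling bin
    contributes pro rata (mass is treated as uniform within a bin).
    """
    edges = dist.bin_edges
    p = dist.probabilities
    mass = 0.0
    for i in range(len(p)):
        lo, hi = edges[i], edges[i + 1]
        if hi <= cutoff:
            mass += p[i]
        elif lo < cutoff:
            mass += p[i] * (cutoff - lo) / (hi - lo)
    return float(min(1.0, max(0.0, mass)))
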