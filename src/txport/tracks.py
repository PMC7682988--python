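"""Tiling-array signal tracks: MA-loess normalization, replicate
combination, and Gaussian smoothing onto a 10-bp grid.

A :class:`ProbeSignalTrack` holds per-probe values on one contig, either
as two positive channels (IP and input intensities) or as a log2 IP/input
ratio. Two-channel tracks are normalized in MA space — M = log2(IP/input)
against A = mean log2 intensity — by subtracting a robust locally weighted
regression of M on A, removing intensity-dependent dye bias. Normalized
replicate tracks are averaged probe-wise, then smoothed once with a
Gaussian kernel (default sd 100 bp) evaluated on a regular grid (default
10 bp step) to give a :class:`SmoothedTrack`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError


@dataclass
class ProbeSignalTrack:
    """Probe-level signal on one contig; positions are 0-based probe
    centers, strictly increasing. Exactly one of (ip, inp) / log2_ratio
    is set."""

    contig: str
    positions: np.ndarray
    ip: np.ndarray | None = None
    inp: np.ndarray | None = None
    log2_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size == 0:
            raise ValidationError("empty probe track")
        if not np.all(np.diff(self.positions) > 0):
            raise ValidationError("probe positions must be strictly increasing")
        two_channel = self.ip is not None or self.inp is not None
        if two_channel:
            if self.ip is None or self.inp is None or self.log2_ratio is not None:
                raise ValidationError(
                    "a track is either two-channel (ip+inp) or a log2 ratio")
            self.ip = np.asarray(self.ip, dtype=float)
            self.inp = np.asarray(self.inp, dtype=float)
            if self.ip.shape != self.positions.shape or \
                    self.inp.shape != self.positions.shape:
                raise ValidationError("channel/position length mismatch")
            if (self.ip <= 0).any() or (self.inp <= 0).any():
                raise ValidationError("channel intensities must be positive")
        else:
            if self.log2_ratio is None:
                raise ValidationError("track carries no values")
            self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
            if self.log2_ratio.shape != self.positions.shape:
                raise ValidationError("ratio/position length mismatch")

    @property
    def is_two_channel(self) -> bool:
        return self.ip is not None

    def ma_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(M, A) per probe for a two-channel track."""
        if not self.is_two_channel:
            raise ValidationError("MA values require a two-channel track")
        m = np.log2(self.ip / self.inp)
        a = 0.5 * np.log2(self.ip * self.inp)
        return m, a


@dataclass
class SmoothedTrack:
    """Signal resampled on a regular grid; NaN marks grid points with no
    probe support."""

    contig: str
    start: int
    step: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValidationError("grid step must be >= 1")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def grid_positions(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.values.size)

    def value_at(self, position: int) -> float:
        """Value of the grid point covering ``position`` (NaN outside)."""
        i = (position - self.start) // self.step
        if i < 0 or i >= self.values.size:
            return float("nan")
        return float(self.values[i])

    def values_in(self, start: int, end: int) -> np.ndarray:
        """Grid values for grid points in [start, end) (half-open)."""
        lo = -(-(start - self.start) // self.step)  # ceil division
        hi = -(-(end - self.start) // self.step)
        lo = max(lo, 0)
        hi = min(hi, self.values.size)
        if hi <= lo:
            return np.empty(0)
        return self.values[lo:hi]


def ma_loess_normalize(track: ProbeSignalTrack, span: float = 0.3,
                       iterations: int = 2) -> ProbeSignalTrack:
    """Remove intensity-dependent dye bias by loess regression in MA space.

    Fits a robust locally weighted regression of M on A (``span`` fraction
    of the data per local fit, ``iterations`` robustifying reweights) and
    returns the residual M as a log2-ratio track, as in limma-style
    within-array loess normalization of two-color arrays.
    """
    m, a = track.ma_values()
    fitted = lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return ProbeSignalTrack(contig=track.contig, positions=track.positions,
                            log2_ratio=m - fitted)


def combine_replicates(tracks: Sequence[ProbeSignalTrack]) -> ProbeSignalTrack:
    """Probe-wise unweighted mean of replicate log2-ratio tracks.

    All replicates must share the probe grid; probes that are NaN in some
    replicates take the mean of the available values.
    """
    if not tracks:
        raise ValidationError("no replicate tracks given")
    first = tracks[0]
    for t in tracks[1:]:
        if t.contig != first.contig or \
                not np.array_equal(t.positions, first.positions):
            raise ValidationError("replicates must share an identical probe grid")
        if t.is_two_channel:
            raise ValidationError("combine normalized log2-ratio tracks")
    if first.is_two_channel:
        raise ValidationError("combine normalized log2-ratio tracks")
    stack = np.vstack([t.log2_ratio for t in tracks])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return ProbeSignalTrack(contig=first.contig, positions=first.positions,
                            log2_ratio=mean)


def gaussian_smooth(track: ProbeSignalTrack, sd: float = 100.0,
                    step: int = 10, truncate: float = 4.0) -> SmoothedTrack:
    """One pass of Gaussian kernel smoothing onto a regular grid.

    The value at grid point g is the kernel-weighted mean of probe values
    within ``truncate`` standard deviations, with weights renormalized
    over the probes actually present (so edges and gaps do not shrink the
    signal). Grid points with no probe in the kernel support are NaN.
    Probe spacing may be irregular.
    """
    if sd <= 0:
        raise ValidationError("kernel sd must be positive")
    if step < 1:
        raise ValidationError("grid step must be >= 1")
    if track.is_two_channel:
        raise ValidationError("smooth a log2-ratio track (normalize first)")
    pos = track.positions
    val = track.log2_ratio
    ok = np.isfinite(val)
    pos, val = pos[ok], val[ok]
    if pos.size == 0:
        raise ValidationError("track has no finite values")
    start = int(np.floor(pos[0] / step) * step)
    stop = int(np.ceil(pos[-1] / step) * step)
    n_grid = (stop - start) // step + 1
    grid = start + step * np.arange(n_grid)
    radius = truncate * sd
    num = np.zeros(n_grid)
    den = np.zeros(n_grid)
    # accumulate each probe's kernel footprint over the grid
    lo = np.searchsorted(grid, pos - radius, side="left")
    hi = np.searchsorted(grid, pos + radius, side="right")
    for p, v, i, j in zip(pos, val, lo, hi):
        g = grid[i:j]
        w = np.exp(-((g - p) ** 2) / (2.0 * sd * sd))
        num[i:j] += w * v
        den[i:j] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    return SmoothedTrack(contig=track.contig, start=start, step=step,
                         values=values)
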