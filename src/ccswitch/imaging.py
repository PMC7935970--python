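"""Confocal z-stack quantitation of membrane-localized fluorescence.

Re-implements the z-analyzer macro logic for supported-lipid-bilayer (SLB)
experiments: each z-slice of a confocal stack is collapsed to its mean
intensity, giving a z-profile whose peak marks the membrane plane; the peak
intensity per time point yields the membrane-bound kinetic trace, and the
baseline-subtracted peak area quantifies membrane binding above the
bulk-solution background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .kinetics import TimeCourse


@dataclass
class ZStackSeries:
    """Confocal intensity data indexed (time, channel, z[, y, x]).

    ``data`` may be a full 5-D pixel array or a pre-collapsed 3-D array of
    per-slice means; ``z_spacing_um`` is the uniform slice spacing.
    """

    data: np.ndarray
    z_spacing_um: float
    channels: tuple
    times_min: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 5):
            raise ValueError("data must be (t, c, z) or (t, c, z, y, x)")
        if np.any(self.data < 0):
            raise ValueError("negative intensities")
        if self.z_spacing_um <= 0:
            raise ValueError("z spacing must be positive")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match channel axis")
        if self.times_min is None:
            self.times_min = np.arange(self.data.shape[0], dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.times_min.size != self.data.shape[0]:
            raise ValueError("times length mismatch")

    @property
    def n_slices(self):
        return self.data.shape[2]

    @property
    def z_positions_um(self):
        return np.arange(self.n_slices) * self.z_spacing_um

    def channel_index(self, channel):
        if isinstance(channel, str):
            try:
                return self.channels.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channels}"
                ) from None
        return int(channel)


@dataclass
class ZProfile:
    """Mean intensity per z-slice at one time point, one channel."""

    z_um: np.ndarray
    intensity: np.ndarray
    channel: str = ""
    time_min: float = 0.0

    def __post_init__(self):
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.z_um.shape != self.intensity.shape:
            raise ValueError("z grid and intensity differ in length")

    @property
    def spacing(self):
        return float(np.median(np.diff(self.z_um)))

    @property
    def peak_index(self):
        return int(np.argmax(self.intensity))


def z_profile(stack: ZStackSeries, channel, time_index: int = 0) -> ZProfile:
    """Collapse one time point of one channel to its z-profile of
    (y, x)-mean intensities."""
    c = stack.channel_index(channel)
    frame = stack.data[time_index, c]
    if frame.ndim == 3:
        if frame.shape[1] == 0 or frame.shape[2] == 0:
            raise ValueError("empty slice dimension")
        prof = frame.mean(axis=(1, 2))
    else:
        prof = frame
    return ZProfile(
        z_um=stack.z_positions_um,
        intensity=prof,
        channel=str(stack.channels[c]),
        time_min=float(stack.times_min[time_index]),
    )


def peak_intensity_timecourse(stack: ZStackSeries, channel) -> TimeCourse:
    """Peak z-profile intensity versus time for one channel (the
    membrane-localized signal)."""
    peaks = [
        float(z_profile(stack, channel, i).intensity.max())
        for i in range(stack.data.shape[0])
    ]
    return TimeCourse(
        stack.times_min,
        {"peak_intensity": np.asarray(peaks)},
        meta=dict(channel=str(channel), mode="slb_peak"),
    )


def peak_area(
    profile: ZProfile,
    window: tuple = None,
    flank: int = 3,
) -> float:
    """Baseline-subtracted trapezoidal peak area (intensity * um).

    ``window`` is an inclusive (lo, hi) slice-index pair; defaults to
    +/-3 slices around the profile maximum.  The baseline is a straight
    line through the medians of ``flank`` slices on each side of the
    window, standing in for a manual bulk-solution subtraction; negative
    areas are possible and reported as such.
    """
    y = profile.intensity
    z = profile.z_um
    if window is None:
        i = profile.peak_index
        window = (max(i - 3, 0), min(i + 3, y.size - 1))
    lo, hi = int(window[0]), int(window[1])
    if lo < 0 or hi >= y.size or hi - lo + 1 < 3:
        raise ValueError("window must lie within the profile and span >= 3 points")
    left = y[max(lo - flank, 0):lo]
    right = y[hi + 1:hi + 1 + flank]
    if left.size == 0 and right.size == 0:
        warnings.warn("window touches both profile edges; baseline set to zero")
        base = np.zeros(hi - lo + 1)
    else:
        if left.size == 0 or right.size == 0:
            warnings.warn("window touches a profile edge; one-sided baseline")
            med = np.median(left if left.size else right)
            base = np.full(hi - lo + 1, med)
        else:
            zl = np.mean(z[max(lo - flank, 0):lo])
            zr = np.mean(z[hi + 1:hi + 1 + flank])
            ml, mr = np.median(left), np.median(right)
            slope = (mr - ml) / (zr - zl)
            base = ml + slope * (z[lo:hi + 1] - zl)
    return float(np.trapezoid(y[lo:hi + 1] - base, z[lo:hi + 1]))


def colocalization_check(profiles, tolerance_um: float = None):
    """Pairwise |peak-position| differences between channels, in um.

    Returns (deltas dict keyed by channel-label pair, colocalized verdict);
    the default tolerance is one slice spacing.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    grid = profiles[0].z_um
    for p in profiles[1:]:
        if p.z_um.shape != grid.shape or not np.allclose(p.z_um, grid):
            raise ValueError("profiles are on mismatched z grids")
    tol = profiles[0].spacing if tolerance_um is None else tolerance_um
    deltas = {}
    for i, p in enumerate(profiles):
        for q in profiles[i + 1:]:
            key = (p.channel or f"ch{i}", q.channel)
            deltas[key] = abs(grid[p.peak_index] - grid[q.peak_index])
    return deltas, all(d <= tol + 1e-12 for d in deltas.values())


def read_tiff_series(path, axes: str, z_spacing_um: float, channels,
                     times_min=None) -> ZStackSeries:
    """Read a multi-page TIFF into a ZStackSeries.

    ``axes`` declares the on-disk axis order using characters from
    ``tczyx`` (e.g. ``"tczyx"`` or ``"tcz"``); the array is transposed to
    the canonical (t, c, z[, y, x]) order.
    """
    arr = tifffile.imread(str(path))
    axes = axes.lower()
    if arr.ndim != len(axes) or set(axes) - set("tczyx"):
        raise ValueError(f"axes {axes!r} do not describe a {arr.ndim}-D array")
    want = "tczyx" if arr.ndim == 5 else "tcz"
    arr = np.transpose(arr, [axes.index(ax) for ax in want])
    return ZStackSeries(arr, z_spacing_um, tuple(channels), times_min)


def write_tiff_series(stack: ZStackSeries, path) -> None:
    tifffile.imwrite(str(path), stack.data.astype(np.float32))
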