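"""Quantitative measurements on reconstructed phase and thickness maps.

Covers the instrument-characterization measurements: USAF 1951 line-width
bookkeeping, three-bar resolvability from a line profile, step height between
a feature region and the substrate (with repeated-measurement statistics),
and bead peak-phase extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .reconstruct import PhaseMap, ThicknessMap
from .samples import usaf_linewidth_um

__all__ = [
    "ROI",
    "MeasurementSeries",
    "usaf_linewidth",
    "resolvable",
    "step_height",
    "repeat_stats",
    "bead_peak_phase",
    "line_profile",
    "inner_roi",
]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle on the map grid: (row0, col0, rows, cols)."""

    row0: int
    col0: int
    rows: int
    cols: int

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("ROI must be non-empty")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI must lie within image bounds")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.rows), slice(self.col0, self.col0 + self.cols))

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.row0 + self.rows <= other.row0
            or other.row0 + other.rows <= self.row0
            or self.col0 + self.cols <= other.col0
            or other.col0 + other.cols <= self.col0
        )

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row0 + self.rows > shape[0] or self.col0 + self.cols > shape[1]:
            raise ValueError(f"ROI {self} exceeds image bounds {shape}")


def inner_roi(roi: ROI | tuple, fraction: float = 0.6) -> ROI:
    """Shrink a rectangle to its central ``fraction`` (per side), >= 1 pixel.

    Measurement rectangles default to the inner 60% of a feature so that
    edge anti-aliasing and interpolation artifacts stay outside the average.
    """
    if not isinstance(roi, ROI):
        roi = ROI(*roi)
    dr = int(round(roi.rows * (1 - fraction) / 2))
    dc = int(round(roi.cols * (1 - fraction) / 2))
    return ROI(roi.row0 + dr, roi.col0 + dc, max(roi.rows - 2 * dr, 1), max(roi.cols - 2 * dc, 1))


@dataclass(frozen=True)
class MeasurementSeries:
    """Repeated scalar estimates summarized by mean, sample sd and n."""

    estimates: tuple[float, ...]
    mean: float
    sd: float
    n: int


def usaf_linewidth(group: int, element: int) -> float:
    """USAF 1951 line width in um: ``500 / 2**(group + (element-1)/6)``."""
    return usaf_linewidth_um(group, element)


def resolvable(
    profile: np.ndarray, min_contrast: float = 0.2
) -> tuple[bool, float]:
    """Decide whether a profile across a three-bar element resolves the bars.

    The profile is baseline-shifted to its minimum; the element is resolved
    if three local maxima are found and the mean dip-to-peak modulation
    ``(mean(peaks) - mean(dips)) / mean(peaks)`` reaches ``min_contrast``.
    Returns ``(resolved, modulation)``; fewer than three detectable peaks
    gives ``(False, 0.0)``.
    """
    p = np.asarray(profile, dtype=float)
    p = p - p.min()
    if p.max() == 0:
        return False, 0.0
    peaks, props = scipy.signal.find_peaks(p, prominence=0.02 * p.max(), plateau_size=1)
    if len(peaks) < 3:
        return False, 0.0
    if len(peaks) > 3:  # keep the three most prominent
        order = np.argsort(props["prominences"])[::-1][:3]
        peaks = np.sort(peaks[order])
    peak_vals = p[peaks]
    dips = [p[peaks[i] : peaks[i + 1] + 1].min() for i in range(2)]
    contrast = float((peak_vals.mean() - np.mean(dips)) / peak_vals.mean())
    return bool(contrast >= min_contrast), contrast


def step_height(thickness: ThicknessMap, feature: ROI | tuple, substrate: ROI | tuple) -> float:
    """Mean thickness over the feature rectangle minus the substrate rectangle."""
    if not isinstance(feature, ROI):
        feature = ROI(*feature)
    if not isinstance(substrate, ROI):
        substrate = ROI(*substrate)
    feature.validate_within(thickness.values.shape)
    substrate.validate_within(thickness.values.shape)
    if feature.overlaps(substrate):
        raise ValueError("feature and substrate rectangles overlap")
    return float(
        thickness.values[feature.slices].mean() - thickness.values[substrate.slices].mean()
    )


def repeat_stats(estimates: list[float]) -> MeasurementSeries:
    """Summarize repeated estimates; the mean is the reported measurement."""
    if len(estimates) == 0:
        raise ValueError("no estimates given")
    arr = np.asarray(estimates, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MeasurementSeries(tuple(arr.tolist()), float(arr.mean()), sd, int(arr.size))


def bead_peak_phase(
    phase: PhaseMap,
    center_hint: tuple[int, int],
    window: int = 31,
    smooth_sigma: float = 1.0,
) -> float:
    """Peak |phase| of a bead near ``center_hint`` (row, col), in radians.

    The apex is located on a lightly Gaussian-smoothed copy of the map (so a
    single noisy pixel cannot win), then its value is estimated by a local
    least-squares paraboloid fit to the raw map around that location: a bead
    apex is a smooth dome, for which the quadratic model is unbiased, and the
    fit averages pixel noise without the downward bias that smoothing the
    apex itself would introduce.  Raises if the window does not intersect the
    image.
    """
    r, c = center_hint
    h = window // 2
    raw = np.abs(phase.values)
    vals = scipy.ndimage.gaussian_filter(raw, smooth_sigma) if smooth_sigma > 0 else raw
    r0, r1 = max(r - h, 0), min(r + h + 1, vals.shape[0])
    c0, c1 = max(c - h, 0), min(c + h + 1, vals.shape[1])
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"window around {center_hint} lies outside the image")
    pr, pc = np.unravel_index(np.argmax(vals[r0:r1, c0:c1]), (r1 - r0, c1 - c0))
    pr += r0
    pc += c0
    k = 3  # half-size of the quadratic-fit patch
    fr0, fr1 = max(pr - k, 0), min(pr + k + 1, raw.shape[0])
    fc0, fc1 = max(pc - k, 0), min(pc + k + 1, raw.shape[1])
    patch = raw[fr0:fr1, fc0:fc1]
    yy, xx = np.mgrid[fr0:fr1, fc0:fc1]
    yy = (yy - pr).ravel().astype(float)
    xx = (xx - pc).ravel().astype(float)
    a = np.column_stack([np.ones_like(xx), xx, yy, xx * xx, xx * yy, yy * yy])
    coef, *_ = np.linalg.lstsq(a, patch.ravel(), rcond=None)
    c0_, cx, cy, cxx, cxy, cyy = coef
    hess = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
    # evaluate the fit at its stationary point when it is a maximum nearby
    try:
        off = np.linalg.solve(hess, [-cx, -cy])
    except np.linalg.LinAlgError:
        off = np.zeros(2)
    if np.all(np.linalg.eigvalsh(hess) < 0) and np.all(np.abs(off) <= k):
        x0, y0 = off
        return float(c0_ + cx * x0 + cy * y0 + cxx * x0**2 + cxy * x0 * y0 + cyy * y0**2)
    return float(c0_)


def line_profile(
    values: np.ndarray, start: tuple[float, float], end: tuple[float, float], n: int = 200
) -> np.ndarray:
    """Sample ``values`` along the segment start->end (row, col) with bilinear
    interpolation; used for bar-pattern and bead cross-section plots."""
    rr = np.linspace(start[0], end[0], n)
    cc = np.linspace(start[1], end[1], n)
    return scipy.ndimage.map_coordinates(values, [rr, cc], order=1)
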