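"""Synthetic transparent phase objects with known ground truth.

Generators for the two sample classes used to characterize the instrument:
a phase-only USAF 1951 resolution target (bars and square pads etched to a
uniform height on a glass substrate) and spherical PMMA beads immersed in an
index-matching oil.  Both are pure phase objects: the complex transmission is
``alpha(x,y) * exp(j*phi(x,y))`` with ``alpha == 1`` everywhere, and the phase
carries the optical path difference

    phi = (2*pi/lambda) * (n_s - n_m) * thickness,

so the ground-truth phase and thickness maps are mutually consistent by
construction.  All lengths are in micrometres; phase is in radians.

The image grid is row-major with the origin at the top-left pixel center and
y increasing downward, so gravity (beads sinking) maps to the +row direction.
Phase is signed by (n_s - n_m): beads in a higher-index oil carry negative
phase, and measurement code reports magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleField",
    "BeadSpec",
    "usaf_phase_target",
    "usaf_linewidth_um",
    "bead_field",
    "moving_bead_sequence",
    "uniform_field",
]


@dataclass
class SampleField:
    """A phase object on a pixel grid with its ground truth.

    Attributes
    ----------
    transmission : complex 2-D array, ``alpha * exp(j*phi)``
    pixel_size : object-plane pixel size in micrometres
    truth_phase : phase map in radians (signed by ``n_s - n_m``)
    truth_thickness : physical thickness map in micrometres (non-negative)
    n_s, n_m : sample and medium refractive indices
    wavelength : vacuum wavelength in micrometres used to bind phase to thickness
    features : optional geometry bookkeeping, e.g. USAF element rectangles
        in pixel coordinates ``(row0, col0, rows, cols)``
    """

    transmission: np.ndarray
    pixel_size: float
    truth_phase: np.ndarray
    truth_thickness: np.ndarray
    n_s: float
    n_m: float
    wavelength: float
    features: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission.shape


@dataclass(frozen=True)
class BeadSpec:
    """A spherical bead: diameter (um), center (x, y) in um, refractive index."""

    diameter: float
    center: tuple[float, float]
    n_s: float = 1.49

    def __post_init__(self):
        if self.diameter <= 0 and self.diameter != 0.0:
            raise ValueError("bead diameter must be positive")


def usaf_linewidth_um(group: int, element: int) -> float:
    """Line width of USAF 1951 element (g, e): ``500 / 2**(g + (e-1)/6)`` um."""
    return 500.0 / 2.0 ** (group + (element - 1) / 6.0)


def _phase_per_um(wavelength: float, n_s: float, n_m: float) -> float:
    return 2.0 * np.pi * (n_s - n_m) / wavelength


def _rect_coverage(
    shape: tuple[int, int],
    pixel_size: float,
    x0: float,
    x1: float,
    y0: float,
    y1: float,
    antialias: bool,
) -> np.ndarray:
    """Per-pixel area fraction covered by the axis-aligned rectangle [x0,x1]x[y0,y1] (um).

    Pixel (i, j) spans ``[j*p - p/2, j*p + p/2] x [i*p - p/2, i*p + p/2]``.
    With ``antialias=False`` a pixel is inside iff its center is inside.
    """
    h, w = shape
    p = pixel_size
    xc = np.arange(w) * p
    yc = np.arange(h) * p
    if not antialias:
        inx = (xc >= x0) & (xc < x1)
        iny = (yc >= y0) & (yc < y1)
        return np.outer(iny, inx).astype(float)
    ox = np.clip(np.minimum(x1, xc + p / 2) - np.maximum(x0, xc - p / 2), 0.0, p) / p
    oy = np.clip(np.minimum(y1, yc + p / 2) - np.maximum(y0, yc - p / 2), 0.0, p) / p
    return np.outer(oy, ox)


def _rect_to_roi(pixel_size: float, x0: float, x1: float, y0: float, y1: float) -> tuple:
    r0 = int(np.ceil(y0 / pixel_size))
    c0 = int(np.ceil(x0 / pixel_size))
    r1 = int(np.floor(y1 / pixel_size))
    c1 = int(np.floor(x1 / pixel_size))
    return (r0, c0, max(r1 - r0, 1), max(c1 - c0, 1))


def usaf_phase_target(
    groups: list[tuple[int, int]],
    height: float,
    n_s: float = 1.52,
    n_m: float = 1.0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.345,
    wavelength: float = 0.532,
    antialias: bool = True,
) -> SampleField:
    """Phase-only USAF 1951 target: three-bar elements plus a square pad.

    Each requested (group, element) is laid out as a square pad of side 5w, a
    block of three vertical bars and a block of three horizontal bars, where
    w is the standard line width ``500/2**(g+(e-1)/6)`` um; bars are w wide,
    5w long, on a 2w pitch.  Feature pixels carry the phase of a uniform etch
    of the given ``height`` (um); the substrate carries zero phase.  Edges are
    anti-aliased by pixel-area fraction unless ``antialias=False``.

    The returned field records, per element, pixel rectangles for the square
    pad, bar blocks and a nearby substrate patch under
    ``features[(g, e)]`` — used downstream for step-height regions of interest.

    Raises
    ------
    ValueError
        If an element's footprint does not fit on the grid, or height < 0.
    """
    if height < 0:
        raise ValueError("etch height must be non-negative")
    h, w_px = shape
    grid_w = w_px * pixel_size
    grid_h = h * pixel_size
    phase = np.zeros(shape, dtype=float)
    features: dict = {}

    margin = 6 * pixel_size
    y_cursor = margin
    for g, e in groups:
        w = usaf_linewidth_um(g, e)
        bar_len = 5.0 * w
        cell_h = bar_len
        # square pad | gap | vertical bars | gap | horizontal bars
        cell_w = bar_len + 2 * w + bar_len + 2 * w + bar_len
        if margin + cell_w > grid_w or y_cursor + cell_h + margin > grid_h:
            raise ValueError(
                f"USAF element group {g} element {e} (cell {cell_w:.1f} x {cell_h:.1f} um) "
                f"does not fit on the {grid_w:.1f} x {grid_h:.1f} um grid"
            )
        x = margin
        cov = np.zeros(shape, dtype=float)
        # square pad
        cov += _rect_coverage(shape, pixel_size, x, x + bar_len, y_cursor, y_cursor + bar_len, antialias)
        square_roi = _rect_to_roi(pixel_size, x, x + bar_len, y_cursor, y_cursor + bar_len)
        x += bar_len + 2 * w
        # vertical bars: three bars w wide, 5w tall, pitch 2w
        vx0 = x
        for k in range(3):
            bx = x + 2 * w * k
            cov += _rect_coverage(shape, pixel_size, bx, bx + w, y_cursor, y_cursor + bar_len, antialias)
        vbars_roi = _rect_to_roi(pixel_size, vx0, vx0 + 5 * w, y_cursor, y_cursor + bar_len)
        x += bar_len + 2 * w
        # horizontal bars
        hx0 = x
        for k in range(3):
            by = y_cursor + 2 * w * k
            cov += _rect_coverage(shape, pixel_size, x, x + bar_len, by, by + w, antialias)
        hbars_roi = _rect_to_roi(pixel_size, hx0, hx0 + 5 * w, y_cursor, y_cursor + bar_len)
        # substrate reference patch to the right of the element
        sx0 = x + bar_len + 3 * w
        sx1 = min(sx0 + bar_len, grid_w - margin)
        if sx1 <= sx0 + pixel_size:  # fall back below the element
            sx0, sx1 = margin, margin + bar_len
            sy0 = y_cursor + cell_h + 3 * w
            sy1 = sy0 + bar_len
        else:
            sy0, sy1 = y_cursor, y_cursor + bar_len
        substrate_roi = _rect_to_roi(pixel_size, sx0, sx1, sy0, sy1)
        features[(g, e)] = {
            "linewidth_um": w,
            "square": square_roi,
            "vbars": vbars_roi,
            "hbars": hbars_roi,
            "substrate": substrate_roi,
        }
        phase = np.maximum(phase, cov)  # features never overlap; guard double counting
        y_cursor += cell_h + 4 * w + margin

    feature_phase = _phase_per_um(wavelength, n_s, n_m) * height
    truth_phase = phase * feature_phase
    truth_thickness = phase * height
    transmission = np.exp(1j * truth_phase)
    return SampleField(
        transmission=transmission,
        pixel_size=pixel_size,
        truth_phase=truth_phase,
        truth_thickness=truth_thickness,
        n_s=n_s,
        n_m=n_m,
        wavelength=wavelength,
        features=features,
    )


def bead_field(
    beads: list[BeadSpec],
    n_m: float = 1.51,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.345,
    wavelength: float = 0.532,
) -> SampleField:
    """Projected-thickness phase field of spherical beads.

    A sphere of diameter d centered at (cx, cy) contributes projected
    thickness ``t(rho) = 2*sqrt((d/2)**2 - rho**2)`` for in-plane radius
    rho < d/2, zero outside.  Overlapping beads add thickness.  Phase per bead
    is ``(2*pi/lambda)*(n_s - n_m)*t`` with that bead's index, so beads denser
    in oil (n_s < n_m) produce negative phase.
    """
    h, w = shape
    yc = np.arange(h)[:, None] * pixel_size
    xc = np.arange(w)[None, :] * pixel_size
    thickness = np.zeros(shape, dtype=float)
    phase = np.zeros(shape, dtype=float)
    n_s = beads[0].n_s if beads else n_m
    for b in beads:
        r = b.diameter / 2.0
        rho2 = (xc - b.center[0]) ** 2 + (yc - b.center[1]) ** 2
        t = 2.0 * np.sqrt(np.clip(r * r - rho2, 0.0, None))
        thickness += t
        phase += _phase_per_um(wavelength, b.n_s, n_m) * t
    return SampleField(
        transmission=np.exp(1j * phase),
        pixel_size=pixel_size,
        truth_phase=phase,
        truth_thickness=thickness,
        n_s=n_s,
        n_m=n_m,
        wavelength=wavelength,
        features={"beads": [(b.center, b.diameter) for b in beads]},
    )


def moving_bead_sequence(
    bead: BeadSpec,
    velocity: float,
    fps: float,
    n_frames: int,
    n_m: float = 1.51,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.345,
    wavelength: float = 0.532,
) -> list[SampleField]:
    """Frames of a bead sinking at ``velocity`` um/s imaged at ``fps`` frames/s.

    Frame k displaces the bead center by ``velocity * k / fps`` along +y
    (downward).  A bead leaving the grid raises a warning but the truncated
    frame is still produced.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = []
    grid_h = shape[0] * pixel_size
    for k in range(n_frames):
        cy = bead.center[1] + velocity * k / fps
        if cy - bead.diameter / 2 > grid_h or cy + bead.diameter / 2 < 0:
            warnings.warn(f"bead exited the grid at frame {k} (center y={cy:.2f} um)")
        moved = BeadSpec(bead.diameter, (bead.center[0], cy), bead.n_s)
        frames.append(bead_field([moved], n_m=n_m, shape=shape, pixel_size=pixel_size, wavelength=wavelength))
    return frames


def uniform_field(
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.345,
    wavelength: float = 0.532,
    n_m: float = 1.0,
) -> SampleField:
    """Empty field (alpha=1, phi=0): the calibration acquisition without a sample."""
    z = np.zeros(shape, dtype=float)
    return SampleField(
        transmission=np.ones(shape, dtype=complex),
        pixel_size=pixel_size,
        truth_phase=z,
        truth_thickness=z.copy(),
        n_s=n_m,
        n_m=n_m,
        wavelength=wavelength,
    )
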