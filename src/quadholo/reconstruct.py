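"""Phase and thickness reconstruction from four phase-shifted holograms.

The pipeline mirrors the instrument's workflow: register the four camera
channels once (see :mod:`quadholo.registration`), retrieve the wrapped phase
by the four-step arctangent formula

    dphi = atan2(I_CCD3 - I_CCD4, I_CCD1 - I_CCD2),

subtract a calibration phase recorded without the sample (removing the arm
offset and system aberrations), unwrap by the unweighted minimum-L2-norm
(least-squares) method solved with discrete cosine transforms, and convert
phase to physical thickness through the optical path difference

    dh = lambda * dphi / (2*pi*(n_s - n_m)).

The arctangent is evaluated four-quadrant so the full 2*pi range is
recovered; a two-argument ratio alone would lose the quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "PhaseMap",
    "ThicknessMap",
    "wrap",
    "wrapped_phase",
    "subtract_calibration",
    "unwrap_phase",
    "count_residues",
    "phase_to_thickness",
    "theoretical_resolution",
]


@dataclass
class PhaseMap:
    """A 2-D phase field in radians.

    ``wrapped=True`` means values lie in (-pi, pi].  ``valid`` optionally
    masks pixels with measurable fringe modulation; invalid pixels hold 0.
    """

    values: np.ndarray
    wrapped: bool = True
    pixel_size: float | None = None
    valid: np.ndarray | None = None


@dataclass
class ThicknessMap:
    """Physical thickness in micrometres with the constants used to obtain it."""

    values: np.ndarray
    n_s: float
    n_m: float
    wavelength: float
    pixel_size: float | None = None


def wrap(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x, dtype=float)))


def wrapped_phase(holos, modulation_threshold: float = 1e-3) -> PhaseMap:
    """Four-step arctangent phase retrieval.

    Requires pixelwise-corresponding channels (register first).  Pixels where
    both quadrature differences fall below ``modulation_threshold`` times the
    set's peak modulation carry no fringe information; they are zeroed and
    flagged in the validity mask.
    """
    num = holos.images[3] - holos.images[4]  # sin quadrature
    den = holos.images[1] - holos.images[2]  # cos quadrature
    max_mod = max(np.abs(num).max(), np.abs(den).max())
    if max_mod == 0:
        valid = np.zeros(num.shape, dtype=bool)
    else:
        thr = modulation_threshold * max_mod
        valid = (np.abs(num) >= thr) | (np.abs(den) >= thr)
    phase = np.arctan2(num, den)
    phase[~valid] = 0.0
    return PhaseMap(phase, wrapped=True, pixel_size=holos.pixel_size, valid=valid)


def subtract_calibration(phase: PhaseMap, calib: PhaseMap) -> PhaseMap:
    """Subtract the empty-field calibration phase, rewrapped to (-pi, pi].

    Removes the arm phase offset and any system aberration common to sample
    and calibration acquisitions.
    """
    if phase.values.shape != calib.values.shape:
        raise ValueError(
            f"phase {phase.values.shape} and calibration {calib.values.shape} dims differ"
        )
    out = wrap(phase.values - calib.values)
    valid = None
    if phase.valid is not None or calib.valid is not None:
        valid = np.ones(out.shape, dtype=bool)
        if phase.valid is not None:
            valid &= phase.valid
        if calib.valid is not None:
            valid &= calib.valid
    return PhaseMap(out, wrapped=True, pixel_size=phase.pixel_size, valid=valid)


def _wrapped_gradients(psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dy = wrap(np.diff(psi, axis=0))
    dx = wrap(np.diff(psi, axis=1))
    return dy, dx


def count_residues(phase: np.ndarray) -> int:
    """Number of phase residues: 2x2 loops whose wrapped gradients do not close.

    Zero residues means the wrapped gradient field is conservative and
    least-squares unwrapping is exact up to a constant.
    """
    dy, dx = _wrapped_gradients(phase)
    loop = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
    return int(np.count_nonzero(np.abs(loop) > np.pi))


def unwrap_phase(phase: PhaseMap) -> PhaseMap:
    """Unweighted minimum-norm (least-squares) phase unwrapping.

    Solves the discrete Poisson equation whose source is the divergence of
    the wrapped phase gradients, under Neumann boundary conditions, via a
    type-2 discrete cosine transform.  The solution minimizes the L2 mismatch
    between its gradients and the wrapped gradients; for residue-free inputs
    it equals the true phase up to an additive constant.  Always returns; the
    residue count is available via :func:`count_residues` as a quality metric.
    """
    psi = phase.values
    dy, dx = _wrapped_gradients(psi)
    rho = np.zeros_like(psi)
    rho[:-1, :] += dy
    rho[1:, :] -= dy
    rho[:, :-1] += dx
    rho[:, 1:] -= dx

    m, n = psi.shape
    dct = scipy.fft.dctn(rho, type=2, norm="ortho")
    ii = np.arange(m)[:, None]
    jj = np.arange(n)[None, :]
    denom = 2.0 * (np.cos(np.pi * ii / m) - 1.0) + 2.0 * (np.cos(np.pi * jj / n) - 1.0)
    denom[0, 0] = 1.0  # DC is the free additive constant
    sol = dct / denom
    sol[0, 0] = 0.0
    out = scipy.fft.idctn(sol, type=2, norm="ortho")
    # pin the additive constant so the output stays congruent with the input
    out += np.median(wrap(psi - out))
    return PhaseMap(out, wrapped=False, pixel_size=phase.pixel_size, valid=phase.valid)


def phase_to_thickness(
    phase: PhaseMap, wavelength: float, n_s: float, n_m: float
) -> ThicknessMap:
    """Convert unwrapped phase to thickness: dh = lambda*dphi / (2*pi*(n_s-n_m)).

    The reported map is a magnitude (|n_s - n_m| in the denominator and |phase|
    in the numerator): the sign of the index contrast only flips the sign of
    the measured phase, not the physical height.
    """
    if n_s == n_m:
        raise ValueError("thickness is undefined for n_s == n_m (no index contrast)")
    values = wavelength * np.abs(phase.values) / (2.0 * np.pi * abs(n_s - n_m))
    return ThicknessMap(values, n_s=n_s, n_m=n_m, wavelength=wavelength, pixel_size=phase.pixel_size)


def theoretical_resolution(wavelength: float, na: float) -> float:
    """Diffraction-limited transverse resolution gamma = lambda / (2 NA)."""
    if na <= 0:
        raise ValueError("NA must be positive")
    return wavelength / (2.0 * na)
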