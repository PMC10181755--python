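"""2x2 Jones-calculus algebra for the polarization elements of the interferometer.

A fully polarized field is a two-component complex vector (Ex, Ey) with the
x basis vector parallel to the p-polarized vibration direction and y parallel
to the s-polarized direction.  Optical elements (linear polarizer, quarter-wave
plates, polarizing beamsplitter cube) act as 2x2 complex matrices.

Matrix conventions
------------------
The element matrices follow the unnormalized convention used in the system
derivation, not the energy-normalized textbook forms: the 45-degree polarizer
is ``[[1, 1], [1, 1]]`` (no 1/2), and the polarizing-beamsplitter transmit /
reflect matrices carry an explicit scalar 1/2 amplitude prefactor, with the
reflect branch picking up a half-wave-loss sign (the -1 entry).  This
convention makes the closed-form 1/4 intensity coefficients of the four-camera
model come out exactly (see :mod:`quadholo.forward`); a global intensity scale
is irrelevant to arctangent phase retrieval, which is a ratio.

Both components of a :class:`JonesVector` may be numpy arrays of identical
shape, so a whole 2-D field propagates through an element in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Number

import numpy as np

__all__ = [
    "JonesVector",
    "JonesMatrix",
    "UnsupportedElementError",
    "apply",
    "element_matrix",
    "intensity",
    "POLARIZER_45",
    "QWP_FAST_X",
    "QWP_FAST_45",
    "QWP_SLOW_45",
    "PBS_TRANSMIT",
    "PBS_REFLECT",
]


class UnsupportedElementError(ValueError):
    """Raised when an (element kind, orientation) pair is not part of the system."""


@dataclass(frozen=True)
class JonesVector:
    """Complex field amplitudes along x (p-pol) and y (s-pol).

    ``ex`` and ``ey`` may be complex scalars or equally shaped complex arrays.
    """

    ex: complex | np.ndarray
    ey: complex | np.ndarray

    def __add__(self, other: "JonesVector") -> "JonesVector":
        return JonesVector(self.ex + other.ex, self.ey + other.ey)

    def __mul__(self, scalar) -> "JonesVector":
        return JonesVector(self.ex * scalar, self.ey * scalar)

    __rmul__ = __mul__

    def intensity(self) -> np.ndarray | float:
        return intensity(self)


@dataclass(frozen=True)
class JonesMatrix:
    """A 2x2 complex element operator with a human-readable label."""

    m: np.ndarray
    label: str = "generic"

    def __post_init__(self):
        arr = np.asarray(self.m, dtype=complex)
        if arr.shape != (2, 2):
            raise ValueError(f"Jones matrix must be 2x2, got shape {arr.shape}")
        object.__setattr__(self, "m", arr)

    def __mul__(self, scalar) -> "JonesMatrix":
        if not isinstance(scalar, Number):
            return NotImplemented
        return JonesMatrix(self.m * scalar, self.label)

    __rmul__ = __mul__

    def __call__(self, v: JonesVector) -> JonesVector:
        return apply(self, v)


def apply(m: JonesMatrix, v: JonesVector) -> JonesVector:
    """Matrix-vector product ``m @ v``, elementwise over array-valued fields."""
    a = m.m
    return JonesVector(
        a[0, 0] * v.ex + a[0, 1] * v.ey,
        a[1, 0] * v.ex + a[1, 1] * v.ey,
    )


def intensity(v: JonesVector) -> np.ndarray | float:
    """Detected intensity |Ex|^2 + |Ey|^2 (squared modulus of the field)."""
    return (np.abs(v.ex) ** 2 + np.abs(v.ey) ** 2).real


# Element constants, as the system derivation prints them.
POLARIZER_45 = JonesMatrix([[1, 1], [1, 1]], "polarizer@45")
QWP_FAST_X = JonesMatrix([[1, 0], [0, 1j]], "qwp fast-axis || x")
QWP_FAST_45 = JonesMatrix([[1, -1j], [-1j, 1]], "qwp fast-axis @45")
QWP_SLOW_45 = JonesMatrix([[1, 1j], [1j, 1]], "qwp slow-axis @45")
PBS_TRANSMIT = JonesMatrix(np.array([[1, 0], [0, 0]]) * 0.5, "pbs transmit (p)")
PBS_REFLECT = JonesMatrix(np.array([[0, 0], [0, -1]]) * 0.5, "pbs reflect (s, half-wave loss)")

_ELEMENTS: dict[tuple[str, float | None], JonesMatrix] = {
    ("polarizer", 45.0): POLARIZER_45,
    ("qwp", 0.0): QWP_FAST_X,
    ("qwp", 45.0): QWP_FAST_45,
    ("qwp_slow", 45.0): QWP_SLOW_45,
    ("pbs_transmit", None): PBS_TRANSMIT,
    ("pbs_reflect", None): PBS_REFLECT,
}


def element_matrix(kind: str, orientation_deg: float | None = None) -> JonesMatrix:
    """Return the Jones matrix of a system element.

    Supported combinations are exactly the ones the four-camera interferometer
    uses: ``("polarizer", 45)``, ``("qwp", 0)`` (fast axis along x),
    ``("qwp", 45)`` (fast axis at 45 deg), ``("qwp_slow", 45)`` (slow axis at
    45 deg), and orientation-free ``("pbs_transmit", None)`` /
    ``("pbs_reflect", None)``, the latter including the half-wave-loss sign.
    The beamsplitter matrices carry their scalar 1/2 amplitude prefactor.

    Raises
    ------
    UnsupportedElementError
        For any other (kind, orientation) combination.
    """
    key = (kind, None if orientation_deg is None else float(orientation_deg))
    try:
        return _ELEMENTS[key]
    except KeyError:
        raise UnsupportedElementError(
            f"no element matrix for kind={kind!r} at orientation {orientation_deg!r}; "
            f"supported: {sorted(str(k) for k in _ELEMENTS)}"
        ) from None
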