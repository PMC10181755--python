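"""Forward model: four simultaneously recorded phase-shifted holograms.

The interferometer splits a collimated beam into an object arm (through the
sample) and a reference arm; both pass a 45-degree linear polarizer and a
quarter-wave plate (fast axis at 45 deg on the object arm, where it leaves
the 45-degree polarization unchanged; fast axis along x on the reference arm,
producing circular polarization).  The arms recombine in a polarizing
beamsplitter, whose two outputs each traverse a 45-degree quarter-wave plate
and a second polarizing beamsplitter, yielding four cameras that record the
same interference pattern with reference-phase offsets of 0, pi/2, pi and
3*pi/2:

    I_CCD1 = 1/4 [a^2 A_O^2 + A_R^2 + 2 a A_O A_R cos(dphi)]
    I_CCD2 = 1/4 [a^2 A_O^2 + A_R^2 - 2 a A_O A_R cos(dphi)]
    I_CCD3 = 1/4 [a^2 A_O^2 + A_R^2 + 2 a A_O A_R sin(dphi)]
    I_CCD4 = 1/4 [a^2 A_O^2 + A_R^2 - 2 a A_O A_R sin(dphi)]

with a, phi the sample's amplitude/phase modulation and dphi the total
object-reference phase difference.  Two routes produce these intensities:
:func:`closed_form_intensities` evaluates the expressions above directly,
while :func:`propagate_system` pushes the field through the explicit Jones
chain; they agree to machine precision and serve as mutual oracles.

Camera realism (photon shot noise, read noise, quantization) and per-camera
geometric misalignment are applied afterwards by :func:`corrupt`, mirroring
four physically distinct cameras viewing the same optical field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.ndimage

from . import jones
from .jones import JonesVector
from .samples import SampleField

__all__ = [
    "OpticalConfig",
    "NoiseModel",
    "ChannelTransform",
    "MisalignmentModel",
    "HologramSet",
    "PHASE_SHIFTS",
    "closed_form_intensities",
    "propagate_system",
    "apply_pupil",
    "corrupt",
    "warp_channel",
]

# Reference-phase offset recorded by each camera.
PHASE_SHIFTS = {1: 0.0, 3: np.pi / 2, 2: np.pi, 4: 3 * np.pi / 2}


@dataclass
class OpticalConfig:
    """Optical system parameters.  Lengths in micrometres.

    ``arm_phase_offset`` is the global phase difference (phi_o - phi_r)
    between the arms with no sample present; calibration subtraction removes
    it during reconstruction.
    """

    wavelength: float = 0.532
    a_o: float = 1.0
    a_r: float = 1.0
    na: float = 0.25
    magnification: float = 10.0
    pixel_pitch: float = 3.45
    shape: tuple[int, int] = (512, 512)
    bit_depth: int = 12
    coherent_cutoff_enabled: bool = False
    arm_phase_offset: float = 0.0

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.na <= 1):
            raise ValueError("NA must lie in (0, 1]")
        if self.a_o < 0 or self.a_r < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def object_pixel_size(self) -> float:
        """Object-plane sampling: camera pixel pitch / magnification (um)."""
        return self.pixel_pitch / self.magnification


@dataclass
class NoiseModel:
    """Camera noise: Poisson shot noise, Gaussian read noise, quantization.

    ``photon_scale`` is the expected photoelectron count at unit optical
    intensity; the default 2048 puts a unit-intensity fringe peak at half
    scale of a 12-bit ADC (1 count per DN).
    """

    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    photon_scale: float = 2048.0
    bit_depth: int = 12
    seed: int | None = None

    def __post_init__(self):
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")


@dataclass(frozen=True)
class ChannelTransform:
    """Rigid-plus-scale misalignment of one camera: applied about image center.

    ``translation`` is (drow, dcol) in pixels; positive values move image
    content down/right.  ``rotation_deg`` is counterclockwise in the array
    sense; ``scale`` is isotropic.
    """

    translation: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    scale: float = 1.0

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.translation[0]) < tol
            and abs(self.translation[1]) < tol
            and abs(self.rotation_deg) < tol
            and abs(self.scale - 1.0) < tol
        )

    def inverse(self) -> "ChannelTransform":
        th = np.deg2rad(-self.rotation_deg)
        s = 1.0 / self.scale
        r, c = self.translation
        # inverse of (rotate, scale, translate): translate back then unrotate
        rr = s * (np.cos(th) * (-r) - np.sin(th) * (-c))
        cc = s * (np.sin(th) * (-r) + np.cos(th) * (-c))
        return ChannelTransform((rr, cc), -self.rotation_deg, s)


@dataclass
class MisalignmentModel:
    """Per-camera geometric transforms of CCD2-CCD4 relative to CCD1."""

    per_channel: dict[int, ChannelTransform] = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "MisalignmentModel":
        return cls({})

    def get(self, ccd: int) -> ChannelTransform:
        return self.per_channel.get(ccd, ChannelTransform())


@dataclass
class HologramSet:
    """Four real-valued intensity images keyed by camera id (1..4).

    ``phase_shift_of`` maps camera id to its reference-phase offset
    (CCD1 -> 0, CCD3 -> pi/2, CCD2 -> pi, CCD4 -> 3*pi/2).  For noise-free,
    aligned sets the channel sum is conserved: I1 + I2 == I3 + I4 pointwise.
    """

    images: dict[int, np.ndarray]
    phase_shift_of: dict[int, float] = field(default_factory=lambda: dict(PHASE_SHIFTS))
    background: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self):
        if sorted(self.images) != [1, 2, 3, 4]:
            raise ValueError(f"hologram set needs cameras 1..4, got {sorted(self.images)}")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel dimensions differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[1].shape

    def copy(self) -> "HologramSet":
        return HologramSet(
            {k: v.copy() for k, v in self.images.items()},
            dict(self.phase_shift_of),
            None if self.background is None else self.background.copy(),
            self.pixel_size,
        )


def _check_dims(sample: SampleField, cfg: OpticalConfig) -> None:
    if sample.shape != tuple(cfg.shape):
        raise ValueError(f"sample grid {sample.shape} does not match camera dims {tuple(cfg.shape)}")


def closed_form_intensities(sample: SampleField, cfg: OpticalConfig) -> HologramSet:
    """Noise-free, perfectly aligned four-channel intensities (closed form)."""
    _check_dims(sample, cfg)
    t = sample.transmission
    if cfg.coherent_cutoff_enabled:
        t = apply_pupil(sample, cfg).transmission
    # interference term: a*exp(j*dphi) with dphi = phi_sample + arm offset
    cross = t * np.exp(1j * cfg.arm_phase_offset)
    dc = (np.abs(t) ** 2) * cfg.a_o**2 + cfg.a_r**2
    mod = 2.0 * cfg.a_o * cfg.a_r
    i1 = 0.25 * (dc + mod * cross.real)
    i2 = 0.25 * (dc - mod * cross.real)
    i3 = 0.25 * (dc + mod * cross.imag)
    i4 = 0.25 * (dc - mod * cross.imag)
    return HologramSet(
        {1: i1, 2: i2, 3: i3, 4: i4},
        background=0.25 * dc,
        pixel_size=sample.pixel_size,
    )


def propagate_system(sample: SampleField, cfg: OpticalConfig) -> HologramSet:
    """Explicit Jones-chain propagation through the element sequence.

    The printed element matrices drop unimodular global scalars; the only one
    that matters for channel balance is the 45-degree quarter-wave plate on
    the object arm, whose raw matrix multiplies 45-degree-polarized light by
    (1 - j).  Since this plate leaves that polarization state physically
    unchanged (a pure global phase for the unitary-normalized element), the
    compensating scalar 1/(1 - j) is carried explicitly so the chain lands on
    exactly the closed-form 1/4 coefficients.  The final beamsplitter is
    applied without the amplitude 1/2 prefactor for the same reason: it acts
    once per output port, not once per arm.
    """
    _check_dims(sample, cfg)
    t = sample.transmission
    if cfg.coherent_cutoff_enabled:
        t = apply_pupil(sample, cfg).transmission

    # Object arm: source -> sample -> polarizer@45 -> QWP fast@45
    e_obj = JonesVector(cfg.a_o * np.exp(1j * cfg.arm_phase_offset) * t, np.zeros_like(t))
    e_obj = jones.apply(jones.POLARIZER_45, e_obj)
    e_obj = jones.apply(jones.QWP_FAST_45, e_obj) * (1.0 / (1.0 - 1j))

    # Reference arm: source -> polarizer@45 -> QWP fast axis || x (-> circular)
    ones = np.ones_like(t)
    e_ref = JonesVector(cfg.a_r * ones, np.zeros_like(t))
    e_ref = jones.apply(jones.POLARIZER_45, e_ref)
    e_ref = jones.apply(jones.QWP_FAST_X, e_ref)

    # First PBS (amplitude 1/2 per port): split each arm into p and s components
    e_obj_par = jones.apply(jones.PBS_TRANSMIT, e_obj)
    e_obj_perp = jones.apply(jones.PBS_REFLECT, e_obj)
    e_ref_par = jones.apply(jones.PBS_TRANSMIT, e_ref)
    e_ref_perp = jones.apply(jones.PBS_REFLECT, e_ref)

    m0 = e_obj_par + e_ref_perp
    m1 = e_obj_perp + e_ref_par

    # QWP slow-axis @45 on both mixed outputs -> mixed circular light
    m0 = jones.apply(jones.QWP_SLOW_45, m0)
    m1 = jones.apply(jones.QWP_SLOW_45, m1)

    # Final PBS separates quadratures onto the four cameras (no 1/2 prefactor)
    pbs_t = 2.0 * jones.PBS_TRANSMIT
    pbs_r = 2.0 * jones.PBS_REFLECT
    i1 = jones.intensity(jones.apply(pbs_t, m0))
    i2 = jones.intensity(jones.apply(pbs_r, m0))
    i3 = jones.intensity(jones.apply(pbs_t, m1))
    i4 = jones.intensity(jones.apply(pbs_r, m1))
    return HologramSet({1: i1, 2: i2, 3: i3, 4: i4}, pixel_size=sample.pixel_size)


def apply_pupil(sample: SampleField, cfg: OpticalConfig) -> SampleField:
    """Low-pass the complex field with the coherent transfer function.

    A diffraction-limited coherent system passes spatial frequencies up to
    NA/lambda (cycles/um); the pupil is a hard circular cutoff at that radius.
    Ground-truth maps are left untouched — the pupil degrades the image, not
    the object.
    """
    t = sample.transmission
    h, w = t.shape
    fy = scipy.fft.fftfreq(h, d=sample.pixel_size)
    fx = scipy.fft.fftfreq(w, d=sample.pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    cutoff = cfg.na / cfg.wavelength
    mask = f2 <= cutoff**2
    filtered = scipy.fft.ifft2(scipy.fft.fft2(t) * mask)
    return SampleField(
        transmission=filtered,
        pixel_size=sample.pixel_size,
        truth_phase=sample.truth_phase,
        truth_thickness=sample.truth_thickness,
        n_s=sample.n_s,
        n_m=sample.n_m,
        wavelength=sample.wavelength,
        features=sample.features,
    )


def warp_channel(img: np.ndarray, tr: ChannelTransform, order: int = 1) -> np.ndarray:
    """Apply a ChannelTransform to image content (rotation/scale about center,
    then translation), with bilinear interpolation and edge replication."""
    if tr.is_identity():
        return img.copy()
    h, w = img.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(tr.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    # output[o] = input( (1/s) * R^-1 @ (o - c - t) + c )
    m = rot.T / tr.scale
    t = np.asarray(tr.translation, dtype=float)
    offset = c - m @ (c + t)
    return scipy.ndimage.affine_transform(img, m, offset=offset, order=order, mode="nearest")


def corrupt(
    holos: HologramSet,
    noise: NoiseModel | None = None,
    mis: MisalignmentModel | None = None,
) -> HologramSet:
    """Degrade an ideal hologram set with camera misalignment and noise.

    Per channel: warp CCD2-4 by their misalignment transform (the cameras view
    the same optical field through different geometric mappings), scale to
    expected photoelectron counts, Poisson-sample, add Gaussian read noise,
    quantize to the ADC bit depth and clip at saturation.  Images come back on
    the input intensity scale (counts / photon_scale).  Deterministic for a
    fixed ``NoiseModel.seed``.  With ``noise=None`` and identity transforms the
    input is returned unchanged.
    """
    out = {}
    rng = np.random.default_rng(noise.seed if noise is not None else None)
    for ccd, img in holos.images.items():
        x = img
        if mis is not None and ccd != 1:
            x = warp_channel(x, mis.get(ccd))
        if noise is not None:
            counts = np.clip(x, 0.0, None) * noise.photon_scale
            if noise.shot_noise:
                counts = rng.poisson(counts).astype(float)
            if noise.read_noise_sigma > 0:
                counts = counts + rng.normal(0.0, noise.read_noise_sigma, counts.shape)
            full = 2**noise.bit_depth - 1
            counts = np.clip(np.round(counts), 0, full)
            x = counts / noise.photon_scale
        elif mis is None or ccd == 1:
            x = x.copy()
        out[ccd] = x
    return HologramSet(out, dict(holos.phase_shift_of), pixel_size=holos.pixel_size)
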