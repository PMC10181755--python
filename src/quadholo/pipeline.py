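"""End-to-end workflows chaining simulation, registration and reconstruction.

The reconstruction order mirrors the instrument workflow: align the four
channels (registration computed once and reusable), retrieve wrapped phase by
the four-step arctangent, subtract the wrapped calibration phase recorded
without a sample, then unwrap and convert to thickness.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .config import RunConfig
from .forward import HologramSet, closed_form_intensities, corrupt
from .reconstruct import (
    PhaseMap,
    count_residues,
    phase_to_thickness,
    subtract_calibration,
    unwrap_phase,
    wrapped_phase,
)
from .registration import RegistrationResult, apply_registration, register_channels
from .samples import SampleField, uniform_field

log = logging.getLogger(__name__)

__all__ = ["simulate_acquisition", "reconstruct_maps"]

# offset added to the run seed for the calibration exposure, so sample and
# calibration acquisitions see independent noise from the same run seed
_CALIB_SEED_OFFSET = 1


def simulate_acquisition(cfg: RunConfig, with_calibration: bool = True):
    """Simulate one acquisition: sample holograms plus an empty-field
    calibration set recorded through the identical optics and misalignment.

    Returns ``(sample_field, holograms, calibration_holograms)``; the
    calibration set is ``None`` if not requested.  Deterministic in
    ``cfg.seed``: the sample exposure uses the run seed and the calibration
    exposure a fixed offset from it.
    """
    sample = cfg.build_sample()
    holos = closed_form_intensities(sample, cfg.optics)
    noise = cfg.noise
    if noise is not None:
        noise = dataclasses.replace(noise, seed=cfg.seed, bit_depth=cfg.optics.bit_depth)
    holos = corrupt(holos, noise, cfg.misalignment)
    calib = None
    if with_calibration:
        empty = uniform_field(
            shape=tuple(cfg.optics.shape),
            pixel_size=cfg.optics.object_pixel_size,
            wavelength=cfg.optics.wavelength,
        )
        calib = closed_form_intensities(empty, cfg.optics)
        cnoise = None
        if noise is not None:
            cnoise = dataclasses.replace(noise, seed=cfg.seed + _CALIB_SEED_OFFSET)
        calib = corrupt(calib, cnoise, cfg.misalignment)
    return sample, holos, calib


def reconstruct_maps(
    holos: HologramSet,
    calib: HologramSet | None = None,
    registration_cfg: dict | None = None,
    cached_registration: RegistrationResult | None = None,
    wavelength: float = 0.532,
    n_s: float = 1.52,
    n_m: float = 1.0,
) -> dict:
    """Full reconstruction of one hologram set.

    Registration is estimated from the sample holograms unless a cached
    result is supplied (the cameras do not move between acquisitions, so one
    estimate serves all); the same transforms align the calibration set.
    Returns a dict with the registration result, wrapped / compensated /
    unwrapped phase maps, the thickness map and quality diagnostics
    (registration scores, residue count).
    """
    reg_cfg = {"model": "rigid", "reference": 1, "pyramid": (4, 2, 1)}
    if registration_cfg:
        reg_cfg.update(registration_cfg)
    if cached_registration is not None:
        reg = cached_registration
        log.info("reusing cached registration transforms")
    else:
        reg = register_channels(
            holos,
            reference=int(reg_cfg["reference"]),
            model=str(reg_cfg["model"]),
            pyramid=tuple(reg_cfg["pyramid"]),
        )
        log.info("registration scores: %s", reg.scores)
    aligned = apply_registration(holos, reg)
    wrapped = wrapped_phase(aligned)

    compensated = wrapped
    if calib is not None:
        calib_aligned = apply_registration(calib, reg)
        calib_wrapped = wrapped_phase(calib_aligned)
        compensated = subtract_calibration(wrapped, calib_wrapped)
    else:
        log.warning("no calibration set supplied; phase compensation skipped")

    residues = count_residues(compensated.values)
    unwrapped = unwrap_phase(compensated)
    thickness = phase_to_thickness(unwrapped, wavelength=wavelength, n_s=n_s, n_m=n_m)
    return {
        "registration": reg,
        "wrapped": wrapped,
        "compensated": compensated,
        "unwrapped": unwrapped,
        "thickness": thickness,
        "residues": residues,
    }
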