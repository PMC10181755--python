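"""Run configuration: everything needed to reproduce a simulation or
reconstruction from one YAML/JSON document plus a seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .forward import ChannelTransform, MisalignmentModel, NoiseModel, OpticalConfig
from .samples import (
    BeadSpec,
    SampleField,
    bead_field,
    uniform_field,
    usaf_phase_target,
)

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Complete, explicit run description.

    ``sample`` is a kind-tagged mapping: ``{"kind": "usaf", "groups": [[6, 1]],
    "height_um": 0.2138, "n_s": 1.52, "n_m": 1.0}`` or ``{"kind": "beads",
    "beads": [{"diameter_um": 10, "center_um": [80, 80], "n_s": 1.49}],
    "n_m": 1.51}``.  All lengths in micrometres.  Round-trips losslessly
    through YAML.
    """

    seed: int = 0
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    misalignment: MisalignmentModel = field(default_factory=MisalignmentModel)
    sample: dict = field(default_factory=lambda: {"kind": "usaf", "groups": [[6, 1]], "height_um": 0.2138, "n_s": 1.52, "n_m": 1.0})
    registration: dict = field(default_factory=lambda: {"model": "rigid", "reference": 1, "pyramid": [4, 2, 1]})
    measure: dict = field(default_factory=lambda: {"contrast_threshold": 0.2})

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "optics": asdict(self.optics),
            "noise": None if self.noise is None else asdict(self.noise),
            "misalignment": {
                str(c): asdict(t) for c, t in self.misalignment.per_channel.items()
            },
            "sample": self.sample,
            "registration": self.registration,
            "measure": self.measure,
        }
        d["optics"]["shape"] = list(self.optics.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            optics_d = dict(d.get("optics", {}))
            if "shape" in optics_d:
                optics_d["shape"] = tuple(optics_d["shape"])
            optics = OpticalConfig(**optics_d)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"optics: {e}") from e
        noise_d = d.get("noise", "default")
        try:
            if noise_d is None:
                noise = None
            elif noise_d == "default":
                noise = NoiseModel()
            else:
                noise = NoiseModel(**noise_d)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"noise: {e}") from e
        try:
            mis = MisalignmentModel(
                {
                    int(c): ChannelTransform(
                        tuple(t.get("translation", (0.0, 0.0))),
                        float(t.get("rotation_deg", 0.0)),
                        float(t.get("scale", 1.0)),
                    )
                    for c, t in (d.get("misalignment") or {}).items()
                }
            )
        except (TypeError, ValueError) as e:
            raise ConfigError(f"misalignment: {e}") from e
        sample = d.get("sample", cls().sample)
        if sample.get("kind") not in ("usaf", "beads", "empty"):
            raise ConfigError(f"sample.kind: must be 'usaf', 'beads' or 'empty', got {sample.get('kind')!r}")
        cfg = cls(
            seed=int(d.get("seed", 0)),
            optics=optics,
            noise=noise,
            misalignment=mis,
            sample=sample,
            registration=dict(d.get("registration", cls().registration)),
            measure=dict(d.get("measure", cls().measure)),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    # -- construction --------------------------------------------------
    def build_sample(self) -> SampleField:
        """Instantiate the SampleField described by ``sample`` on the camera grid."""
        s = self.sample
        shape = tuple(self.optics.shape)
        px = self.optics.object_pixel_size
        lam = self.optics.wavelength
        kind = s["kind"]
        if kind == "usaf":
            return usaf_phase_target(
                [tuple(g) for g in s.get("groups", [[6, 1]])],
                height=float(s.get("height_um", 0.2138)),
                n_s=float(s.get("n_s", 1.52)),
                n_m=float(s.get("n_m", 1.0)),
                shape=shape,
                pixel_size=px,
                wavelength=lam,
                antialias=bool(s.get("antialias", True)),
            )
        if kind == "beads":
            beads = [
                BeadSpec(
                    float(b.get("diameter_um", 10.0)),
                    tuple(b.get("center_um", (shape[1] * px / 2, shape[0] * px / 2))),
                    float(b.get("n_s", 1.49)),
                )
                for b in s.get("beads", [{}])
            ]
            return bead_field(beads, n_m=float(s.get("n_m", 1.51)), shape=shape, pixel_size=px, wavelength=lam)
        return uniform_field(shape=shape, pixel_size=px, wavelength=lam, n_m=float(s.get("n_m", 1.0)))

    def sample_indices(self) -> tuple[float, float]:
        """(n_s, n_m) of the described sample, for thickness conversion."""
        s = self.sample
        if s["kind"] == "beads":
            beads = s.get("beads", [{}])
            return float(beads[0].get("n_s", 1.49)), float(s.get("n_m", 1.51))
        return float(s.get("n_s", 1.52)), float(s.get("n_m", 1.0))
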