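"""One-time intensity-based registration of the four camera channels.

Each camera views the interference field through its own geometric mapping;
before the arctangent formula can be applied the four holograms must be in
pixelwise correspondence.  Registration estimates, for each moving channel,
the transform that maximizes intensity similarity with the reference channel,
using a multi-resolution pyramid with a cross-correlation translation seed and
Powell refinement at each level.  The similarity metric is the correlation
ratio (minimum conditional variance of the moving intensities given the fixed
intensities): the four cameras see the same structure through different
points of the fringe cosine, so corresponding pixels are related by a
nonlinear but functional intensity mapping, which the correlation ratio is
invariant to while plain cross-correlation or mean-squared difference is
systematically biased at feature edges.  The estimate is a :class:`~quadholo.forward.ChannelTransform`
describing the camera's misalignment itself, so applying its inverse aligns
the channel.  Transforms are computed once and reusable across acquisitions
made with the same cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import downscale_local_mean

from .forward import ChannelTransform, HologramSet, warp_channel

__all__ = ["RegistrationResult", "register_channels", "apply_registration"]

_MODELS = ("translation", "rigid", "affine")


@dataclass
class RegistrationResult:
    """Estimated per-channel misalignment transforms and diagnostics.

    ``transforms[ccd]`` is the estimated misalignment of that camera relative
    to the reference (reference channel maps to the identity).  ``scores``
    holds the final normalized mean-squared difference per channel and
    ``converged`` flags optimizer success; a non-converged channel still
    carries its best-so-far transform.
    """

    reference: int
    model: str
    transforms: dict[int, ChannelTransform] = field(default_factory=dict)
    scores: dict[int, float] = field(default_factory=dict)
    converged: dict[int, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "model": self.model,
            "transforms": {
                str(c): {
                    "translation": list(t.translation),
                    "rotation_deg": t.rotation_deg,
                    "scale": t.scale,
                }
                for c, t in self.transforms.items()
            },
            "scores": {str(c): float(s) for c, s in self.scores.items()},
            "converged": {str(c): bool(v) for c, v in self.converged.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationResult":
        res = cls(reference=int(d["reference"]), model=d["model"])
        for c, t in d["transforms"].items():
            res.transforms[int(c)] = ChannelTransform(
                tuple(t["translation"]), t["rotation_deg"], t["scale"]
            )
        res.scores = {int(c): float(s) for c, s in d.get("scores", {}).items()}
        res.converged = {int(c): bool(v) for c, v in d.get("converged", {}).items()}
        return res


def _normalize(img: np.ndarray) -> np.ndarray:
    s = img.std()
    return (img - img.mean()) / (s if s > 0 else 1.0)


def _edge_image(img: np.ndarray) -> np.ndarray:
    # The four cameras record the same structure at different reference-phase
    # offsets, so their fringe contrasts differ in sign and magnitude; the
    # gradient magnitude is invariant to that and shared across channels.
    return _normalize(scipy.ndimage.gaussian_gradient_magnitude(img, sigma=1.0))


def _params_to_transform(p: np.ndarray, model: str) -> ChannelTransform:
    if model == "translation":
        return ChannelTransform((p[0], p[1]))
    if model == "rigid":
        return ChannelTransform((p[0], p[1]), p[2])
    return ChannelTransform((p[0], p[1]), p[2], p[3])


def _transform_to_params(t: ChannelTransform, model: str) -> np.ndarray:
    if model == "translation":
        return np.array([*t.translation])
    if model == "rigid":
        return np.array([*t.translation, t.rotation_deg])
    return np.array([*t.translation, t.rotation_deg, t.scale])


def _corr_ratio_cost(
    fixed: np.ndarray, moving: np.ndarray, tr: ChannelTransform, crop: int, nbins: int = 64
) -> float:
    """1 - eta^2: normalized conditional variance of moving given binned fixed.

    Cubic-spline warping is used inside the metric: bilinear resampling
    smooths most at half-pixel offsets, which imprints a spurious
    integer-locking ripple on any variance-based similarity measure.
    """
    aligned = warp_channel(moving, tr.inverse(), order=3)
    m = aligned[crop:-crop, crop:-crop].ravel()
    f = fixed[crop:-crop, crop:-crop].ravel()
    span = np.ptp(f)
    if span == 0 or m.var() == 0:
        return 1.0
    bins = np.clip(((f - f.min()) / span * nbins).astype(int), 0, nbins - 1)
    n = np.bincount(bins, minlength=nbins)
    s1 = np.bincount(bins, weights=m, minlength=nbins)
    s2 = np.bincount(bins, weights=m * m, minlength=nbins)
    good = n > 0
    cond_var = float((s2[good] - s1[good] ** 2 / n[good]).sum()) / m.size
    return cond_var / float(m.var())


def _register_one(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: str,
    pyramid: tuple[int, ...],
) -> tuple[ChannelTransform, float, bool]:
    fixed_edges = _edge_image(fixed)
    moving_edges = _edge_image(moving)
    # mild pre-blur further suppresses resampling-induced metric ripple
    fixed = scipy.ndimage.gaussian_filter(_normalize(fixed), 0.75)
    moving = scipy.ndimage.gaussian_filter(_normalize(moving), 0.75)
    estimate = ChannelTransform()
    ok = True
    score = np.inf
    for i, level in enumerate(pyramid):
        if level > 1:
            f = downscale_local_mean(fixed, (level, level))
            m = downscale_local_mean(moving, (level, level))
        else:
            f, m = fixed, moving
        crop = max(4, int(8 / level))
        if i == 0:
            # seed from the edge images, whose texture is shared across
            # channels regardless of fringe contrast sign; the shift needed
            # to register moving onto fixed is minus the content displacement
            fe = downscale_local_mean(fixed_edges, (level, level)) if level > 1 else fixed_edges
            me = downscale_local_mean(moving_edges, (level, level)) if level > 1 else moving_edges
            shift, *_ = phase_cross_correlation(fe, me, upsample_factor=10)
            estimate = ChannelTransform(
                (-float(shift[0]) * level, -float(shift[1]) * level),
                estimate.rotation_deg,
                estimate.scale,
            )

        def cost(p, _f=f, _m=m, _lvl=level, _crop=crop):
            tr = _params_to_transform(p, model)
            scaled = ChannelTransform(
                (tr.translation[0] / _lvl, tr.translation[1] / _lvl),
                tr.rotation_deg,
                tr.scale,
            )
            return _corr_ratio_cost(_f, _m, scaled, _crop)

        p0 = _transform_to_params(estimate, model)
        res = scipy.optimize.minimize(
            cost, p0, method="Powell", options={"xtol": 1e-5, "ftol": 1e-10, "maxiter": 200}
        )
        ok = ok and bool(res.success)
        estimate = _params_to_transform(res.x, model)
        score = float(res.fun)
    return estimate, score, ok


def register_channels(
    holos: HologramSet,
    reference: int = 1,
    model: str = "rigid",
    pyramid: tuple[int, ...] = (4, 2, 1),
) -> RegistrationResult:
    """Estimate the misalignment of CCD2-4 relative to the reference channel.

    ``model`` selects the transform class: pure ``translation``, ``rigid``
    (translation + rotation), or ``affine`` (rigid + isotropic scale).
    Non-convergence of the optimizer on a channel is flagged in
    ``converged`` with the best-so-far transform retained.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    if reference not in holos.images:
        raise ValueError(f"reference channel {reference} not in hologram set")
    result = RegistrationResult(reference=reference, model=model)
    fixed = holos.images[reference]
    for ccd, img in holos.images.items():
        if ccd == reference:
            result.transforms[ccd] = ChannelTransform()
            result.scores[ccd] = 0.0
            result.converged[ccd] = True
            continue
        tr, score, ok = _register_one(fixed, img, model, pyramid)
        result.transforms[ccd] = tr
        result.scores[ccd] = score
        result.converged[ccd] = ok
    return result


def apply_registration(holos: HologramSet, result: RegistrationResult) -> HologramSet:
    """Warp each moving channel by the inverse of its estimated misalignment."""
    out = {}
    for ccd, img in holos.images.items():
        tr = result.transforms.get(ccd, ChannelTransform())
        out[ccd] = img.copy() if tr.is_identity() else warp_channel(img, tr.inverse())
    return HologramSet(out, dict(holos.phase_shift_of), pixel_size=holos.pixel_size)
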