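"""Gaussian-sphere heatmap targets and sampling priors.

The regression target for a volume is a single-channel heatmap containing
one isotropic Gaussian sphere per landmark, evaluated in voxel units with a
shared sigma (default 3 voxels; identical to mm on 1 mm isotropic data) and
peak-normalized to 1. Overlapping spheres combine by voxelwise maximum so
the peak normalization survives landmark proximity. The sampling prior is
the same construction centered on the *template* landmarks, renormalized to
sum 1 so it can drive weighted patch sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import FiducialSet, Volume

__all__ = ["HeatmapSpec", "make_target_heatmap", "make_sampling_prior", "LandmarkOutOfBounds"]


class LandmarkOutOfBounds(ValueError):
    """A landmark maps outside the volume bounds."""


@dataclass
class HeatmapSpec:
    """Parameters of the Gaussian-sphere target.

    sigma is in voxels; peak_value is the post-normalization maximum.
    Gaussians are evaluated at every voxel (no truncation radius): at
    sigma=3 the tails are numerically negligible beyond ~15 voxels.
    """

    sigma: float = 3.0
    peak_value: float = 1.0
    combine_rule: str = "max"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.combine_rule != "max":
            raise ValueError(f"unsupported combine rule {self.combine_rule!r}")


def _landmark_voxels(landmarks: FiducialSet, shape, affine) -> list[tuple[str, np.ndarray]]:
    inv = np.linalg.inv(affine)
    out = []
    for label, pos in landmarks.points:
        vox = inv[:3, :3] @ pos + inv[:3, 3]
        if np.any(vox < -0.5) or np.any(vox > np.asarray(shape) - 0.5):
            raise LandmarkOutOfBounds(
                f"landmark {label!r} maps to voxel {np.round(vox, 2)} outside shape {tuple(shape)}"
            )
        out.append((label, vox))
    return out


def _gaussian_spheres(shape, centers_vox: list[np.ndarray], sigma: float) -> np.ndarray:
    """Voxelwise max of unit-peak Gaussians centered at fractional voxel indices."""
    gx = np.arange(shape[0], dtype=float)
    gy = np.arange(shape[1], dtype=float)
    gz = np.arange(shape[2], dtype=float)
    out = np.zeros(shape, dtype=float)
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for c in centers_vox:
        d2 = (
            ((gx - c[0]) ** 2)[:, None, None]
            + ((gy - c[1]) ** 2)[None, :, None]
            + ((gz - c[2]) ** 2)[None, None, :]
        )
        np.maximum(out, np.exp(-d2 * inv2s2), out=out)
    return out


def make_target_heatmap(shape, landmarks: FiducialSet, affine, spec: HeatmapSpec | None = None) -> Volume:
    """Build the Gaussian-sphere regression target for a volume.

    Value at voxel v is ``max over landmarks l of exp(-|v - l_vox|^2 / (2 sigma^2))``,
    scaled by ``spec.peak_value``; the returned Volume shares the source
    affine so the heatmap overlays the image in external viewers.
    """
    spec = spec or HeatmapSpec()
    affine = np.asarray(affine, dtype=float)
    centers = [vox for _, vox in _landmark_voxels(landmarks, shape, affine)]
    data = _gaussian_spheres(tuple(shape), centers, spec.sigma) * spec.peak_value
    return Volume(data=data, affine=affine)


def make_sampling_prior(
    template_landmarks: FiducialSet, shape, affine, spec: HeatmapSpec | None = None
) -> Volume:
    """Gaussian-sphere map centered on the template landmarks, normalized to sum 1.

    Usable directly as a sampling probability density for weighted patch
    sampling, and doubles as the static error map of the regression
    framework (no iterative updating).
    """
    hm = make_target_heatmap(shape, template_landmarks, affine, spec)
    total = float(hm.data.sum())
    if total <= 0:
        raise ValueError("sampling prior is identically zero (template outside volume?)")
    return Volume(data=hm.data / total, affine=hm.affine)
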