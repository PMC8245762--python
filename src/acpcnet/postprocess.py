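"""Extract labeled AC/PC coordinates from a predicted heatmap volume.

Because the input volumes are rigidly pre-aligned to a template with known
AC/PC locations, the true landmarks must lie close to the template pair.
The extraction pipeline exploits this: a binary region-of-interest mask
around the template landmarks removes false-positive peaks elsewhere, a
Gaussian filter smooths the spheres, the two strongest sufficiently
separated maxima are taken as the landmark peaks, each peak is refined to
sub-voxel precision by a local intensity-weighted centroid, and the more
anterior refined point (greater RAS y) is labeled AC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .synthetic_phantom import default_template
from .volumes_io import FiducialSet, Volume

__all__ = [
    "ExtractConfig",
    "MissingLandmarkError",
    "DegenerateHeatmapError",
    "apply_roi_mask",
    "extract_landmarks",
]


class MissingLandmarkError(RuntimeError):
    """Fewer than two credible peaks: one commissure was not detected."""


class DegenerateHeatmapError(RuntimeError):
    """The two detected peaks are not separated by min_separation_mm."""


@dataclass
class ExtractConfig:
    """Post-processing parameters.

    roi_radius_mm: radius of the spherical ROI around each template
    landmark. smooth_sigma_vox: Gaussian smoothing applied before peak
    picking. min_separation_mm: suppression radius around the first peak
    before searching for the second. subvoxel_window_vox: odd cube edge of
    the intensity-weighted centroid refinement.
    """

    roi_radius_mm: float = 15.0
    smooth_sigma_vox: float = 1.0
    min_separation_mm: float = 8.0
    subvoxel_method: str = "parabolic"
    subvoxel_window_vox: int = 5
    template_landmarks: FiducialSet = field(default_factory=default_template)

    def __post_init__(self) -> None:
        if self.roi_radius_mm <= 0 or self.min_separation_mm <= 0:
            raise ValueError("radii must be positive")
        if self.smooth_sigma_vox < 0:
            raise ValueError("smooth_sigma_vox must be nonnegative")
        if self.subvoxel_window_vox % 2 != 1 or self.subvoxel_window_vox < 1:
            raise ValueError("subvoxel_window_vox must be a positive odd count")
        if self.subvoxel_method not in ("parabolic", "centroid"):
            raise ValueError(f"unknown subvoxel_method {self.subvoxel_method!r}")
        pts = self.template_landmarks.positions()
        if len(pts) >= 2:
            span = float(np.linalg.norm(pts[0] - pts[1]))
            if self.min_separation_mm >= 2 * self.roi_radius_mm + span:
                raise ValueError(
                    "min_separation_mm exceeds the reachable peak separation "
                    "(2*roi_radius_mm + template landmark distance)"
                )


def _world_grid_distances(h: Volume, targets: np.ndarray) -> np.ndarray:
    """Min distance (mm) from every voxel center to any of the target points."""
    idx = np.indices(h.shape, dtype=float).reshape(3, -1).T
    world = idx @ h.affine[:3, :3].T + h.affine[:3, 3]
    d = np.full(world.shape[0], np.inf)
    for t in targets:
        d = np.minimum(d, np.linalg.norm(world - t, axis=1))
    return d.reshape(h.shape)


def apply_roi_mask(h: Volume, cfg: ExtractConfig | None = None) -> Volume:
    """Zero voxels farther than roi_radius_mm from both template landmarks."""
    cfg = cfg or ExtractConfig()
    d = _world_grid_distances(h, cfg.template_landmarks.positions())
    data = np.where(d <= cfg.roi_radius_mm, h.data, 0.0)
    return Volume(data=data, affine=h.affine)


def _refine_centroid(data: np.ndarray, peak_idx: np.ndarray, half: int) -> np.ndarray:
    """Intensity-weighted centroid over a (2*half+1)^3 neighborhood.

    Pulls toward the window center when the peak is flat relative to the
    window (wide sigma), so the parabolic refinement is the default.
    """
    lo = np.maximum(peak_idx - half, 0)
    hi = np.minimum(peak_idx + half + 1, np.asarray(data.shape))
    sub = np.clip(data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]], 0.0, None)
    total = float(sub.sum())
    if total <= 0:
        return peak_idx.astype(float)
    grids = np.meshgrid(*(np.arange(a, b, dtype=float) for a, b in zip(lo, hi)), indexing="ij")
    return np.array([float((g * sub).sum() / total) for g in grids])


def _refine_parabolic(data: np.ndarray, peak_idx: np.ndarray) -> np.ndarray:
    """Per-axis log-parabola peak interpolation.

    log intensity of a Gaussian sphere is exactly quadratic, so the vertex
    of the parabola through the peak voxel and its two axis neighbors
    recovers the fractional center exactly (including the half-voxel tie
    case, where argmax lands on the lower of two equal voxels).
    """
    eps = 1e-300
    out = peak_idx.astype(float)
    for ax in range(3):
        i = int(peak_idx[ax])
        if i == 0 or i == data.shape[ax] - 1:
            continue
        sel = list(peak_idx)
        vals = []
        for j in (i - 1, i, i + 1):
            sel[ax] = j
            vals.append(max(float(data[tuple(sel)]), eps))
        lm, l0, lp = (np.log(v) for v in vals)
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            out[ax] = i + float(np.clip(0.5 * (lm - lp) / denom, -1.0, 1.0))
    return out


def extract_landmarks(h: Volume, cfg: ExtractConfig | None = None) -> FiducialSet:
    """Heatmap -> labeled AC/PC positions in RAS mm.

    Pipeline: ROI mask -> Gaussian smoothing -> strongest peak -> suppress a
    min_separation_mm ball -> second peak (must reach 10% of the first) ->
    sub-voxel refinement (log-parabolic peak interpolation by default, or a
    local intensity-weighted centroid) -> anterior point labeled AC. Ties in
    the anterior ordering break by peak amplitude, then lexicographic voxel
    index, so the result is deterministic.
    """
    cfg = cfg or ExtractConfig()
    masked = apply_roi_mask(h, cfg)
    data = masked.data.astype(float)
    if cfg.smooth_sigma_vox > 0:
        data = gaussian_filter(data, cfg.smooth_sigma_vox)

    peak1 = np.array(np.unravel_index(int(np.argmax(data)), data.shape))
    val1 = float(data[tuple(peak1)])
    if val1 <= 0:
        raise MissingLandmarkError("heatmap contains no positive signal inside the ROI")

    # voxel size along each axis for the suppression ball in mm
    world1 = h.affine[:3, :3] @ peak1 + h.affine[:3, 3]
    d = _world_grid_distances(Volume(data=data, affine=h.affine), world1[None, :])
    suppressed = np.where(d > cfg.min_separation_mm, data, -np.inf)
    peak2 = np.array(np.unravel_index(int(np.argmax(suppressed)), data.shape))
    val2 = float(data[tuple(peak2)])
    if not np.isfinite(suppressed[tuple(peak2)]) or val2 < 0.1 * val1:
        raise MissingLandmarkError(
            f"second peak ({val2:.3g}) below 10% of the first ({val1:.3g}); "
            "one commissure not detected"
        )
    world2 = h.affine[:3, :3] @ peak2 + h.affine[:3, 3]
    if np.linalg.norm(world2 - world1) < cfg.min_separation_mm:
        raise DegenerateHeatmapError("detected peaks closer than min_separation_mm")

    half = cfg.subvoxel_window_vox // 2
    refined = []
    for pk, val in ((peak1, val1), (peak2, val2)):
        if cfg.subvoxel_method == "parabolic":
            vox = _refine_parabolic(data, pk)
        else:
            vox = _refine_centroid(data, pk, half)
        world = h.affine[:3, :3] @ vox + h.affine[:3, 3]
        refined.append((world, val, tuple(int(i) for i in pk)))

    # anterior = greater RAS y; ties by amplitude, then voxel index
    refined.sort(key=lambda r: (-r[0][1], -r[1], r[2]))
    return FiducialSet(points=[("AC", refined[0][0]), ("PC", refined[1][0])])
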