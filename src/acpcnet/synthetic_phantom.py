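"""Procedural brain phantoms with known AC/PC ground truth.

Real pipelines of this kind consume T1-weighted MRI volumes rigidly
pre-aligned to a template, with the anterior and posterior commissures
(AC/PC) annotated in RAS millimeters. This module emulates those inputs
procedurally: a head/brain ellipsoid with ventricle-like hypointensities and
midline structure, two compact hyperintense blobs at the AC and PC
locations (so the landmarks are predictable from image intensity alone),
residual rigid jitter standing in for imperfect registration, multiplicative
intensity inhomogeneity (bias field), and additive noise. Realistic MR
physics is a non-goal; image-predictability of the landmarks is the
requirement.

The canonical (unjittered) AC/PC positions double as the *template*
landmarks used by the sampling prior and the post-processing region of
interest, exactly as a registration template's known AC/PC would.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .heatmap_targets import HeatmapSpec, make_target_heatmap
from .volumes_io import FiducialSet, Volume

__all__ = [
    "PhantomParams",
    "default_template",
    "center_affine",
    "generate_phantom",
    "generate_cohort",
    "cohort_seeds",
    "estimate_head_mask",
    "simulate_prediction_heatmap",
    "simulate_annotators",
]

# Intensity model (arbitrary T1-like units in [0, 1] before bias/noise)
_SCALP = 0.25
_BRAIN = 0.55
_CSF = 0.12
_MIDLINE = 0.35
_BLOB_AMPLITUDE = 0.5
_BLOB_SIGMA_MM = 2.0


@dataclass
class PhantomParams:
    """Knobs of the phantom generator.

    shape: voxel grid (default 64x64x48 desk scale; 256x256x150 emulates the
    full acquisition geometry). acpc_distance_mm: anterior-axis separation of
    the two landmarks (default 26 mm, adult anatomy). jitter_mm: scale of the
    residual rigid misalignment left over after template registration.
    noise_sigma: additive Gaussian noise, in intensity units. bias_field:
    smooth multiplicative inhomogeneity on/off.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    acpc_distance_mm: float = 26.0
    jitter_mm: float = 2.0
    noise_sigma: float = 0.03
    bias_field: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acpc_distance_mm <= 0:
            raise ValueError("acpc_distance_mm must be positive")
        if min(self.shape) < 24:
            raise ValueError(
                f"shape {self.shape} too small to contain the phantom geometry (min extent 24)"
            )
        if self.acpc_distance_mm > 0.6 * self.shape[1]:
            raise ValueError("acpc_distance_mm does not fit inside the head along y")


def center_affine(shape) -> np.ndarray:
    """1 mm isotropic affine placing the world origin at the grid center."""
    affine = np.eye(4)
    affine[:3, 3] = -(np.asarray(shape, dtype=float) - 1.0) / 2.0
    return affine


def default_template(acpc_distance_mm: float = 26.0) -> FiducialSet:
    """Template AC/PC pair: on the midline, symmetric about the origin.

    AC is anterior of PC (greater RAS y).
    """
    half = acpc_distance_mm / 2.0
    return FiducialSet(
        points=[("AC", np.array([0.0, half, 0.0])), ("PC", np.array([0.0, -half, 0.0]))]
    )


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _ellipsoid(q: np.ndarray, center, radii) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid evaluated at points q (..., 3)."""
    r = (q - np.asarray(center, dtype=np.float32)) / np.asarray(radii, dtype=np.float32)
    return np.einsum("...i,...i->...", r, r) < 1.0


def generate_phantom(p: PhantomParams) -> tuple[Volume, FiducialSet]:
    """Generate one phantom volume and its ground-truth AC/PC fiducials.

    Deterministic given ``p.seed``. With jitter_mm = 0 the landmarks sit at
    the template positions and their anterior-axis separation equals
    ``acpc_distance_mm`` exactly.
    """
    rng = np.random.default_rng(p.seed)
    shape = tuple(int(s) for s in p.shape)
    affine = center_affine(shape)

    # Residual rigid misalignment: small rotation + translation of the scene.
    if p.jitter_mm > 0:
        t = rng.normal(0.0, p.jitter_mm / np.sqrt(3.0), size=3)
        angles = rng.normal(0.0, np.deg2rad(0.5 * p.jitter_mm), size=3)
    else:
        t = np.zeros(3)
        angles = np.zeros(3)
    rot = _rotation_matrix(angles)

    # World coordinates of every voxel, pulled back to canonical scene coords.
    grids = np.meshgrid(
        *(np.arange(s, dtype=np.float32) for s in shape), indexing="ij", copy=False
    )
    world = np.stack(grids, axis=-1) + affine[:3, 3].astype(np.float32)
    q = (world - t.astype(np.float32)) @ rot.astype(np.float32)  # R^T (x - t)

    ext = np.asarray(shape, dtype=float)
    head_radii = 0.44 * ext
    brain_radii = 0.87 * head_radii

    data = np.zeros(shape, dtype=np.float32)
    head = _ellipsoid(q, (0, 0, 0), head_radii)
    data[head] = _SCALP
    brain = _ellipsoid(q, (0, 0, 0), brain_radii)
    data[brain] = _BRAIN
    # Lateral-ventricle-like hypointensities, superior and slightly anterior.
    vent_z = 0.28 * brain_radii[2]
    for sx in (-1.0, 1.0):
        vent = _ellipsoid(
            q,
            (sx * 0.16 * brain_radii[0], 0.12 * brain_radii[1], vent_z),
            (0.14 * brain_radii[0], 0.45 * brain_radii[1], 0.28 * brain_radii[2]),
        )
        data[vent & brain] = _CSF
    # Interhemispheric midline: thin darker sagittal slab.
    mid = np.abs(q[..., 0]) < 1.0
    data[mid & brain] = np.minimum(data[mid & brain], _MIDLINE)

    # Landmarks: canonical template positions moved by the rigid jitter.
    template = default_template(p.acpc_distance_mm)
    ac = rot @ template["AC"] + t
    pc = rot @ template["PC"] + t

    # Compact hyperintense blobs make both landmarks image-predictable.
    inv2s2 = np.float32(1.0 / (2.0 * _BLOB_SIGMA_MM**2))
    for lm in (ac, pc):
        d2 = np.einsum("...i,...i->...", world - lm.astype(np.float32), world - lm.astype(np.float32))
        data += np.float32(_BLOB_AMPLITUDE) * np.exp(-d2 * inv2s2)

    if p.bias_field:
        # Smooth multiplicative inhomogeneity: low-order random polynomial.
        u = world / ext.astype(np.float32)  # roughly [-0.5, 0.5] per axis
        coeffs = rng.normal(0.0, 0.12, size=9).astype(np.float32)
        field = (
            1.0
            + coeffs[0] * u[..., 0] + coeffs[1] * u[..., 1] + coeffs[2] * u[..., 2]
            + coeffs[3] * u[..., 0] * u[..., 1]
            + coeffs[4] * u[..., 1] * u[..., 2]
            + coeffs[5] * u[..., 0] * u[..., 2]
            + coeffs[6] * u[..., 0] ** 2 + coeffs[7] * u[..., 1] ** 2 + coeffs[8] * u[..., 2] ** 2
        )
        data *= np.clip(field, 0.7, 1.3)

    if p.noise_sigma > 0:
        data += rng.normal(0.0, p.noise_sigma, size=shape).astype(np.float32)

    truth = FiducialSet(points=[("AC", ac), ("PC", pc)])
    return Volume(data=data, affine=affine), truth


def cohort_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-phantom seeds derived from a cohort seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def generate_cohort(n: int, p: PhantomParams) -> list[tuple[Volume, FiducialSet]]:
    """Generate ``n`` phantoms with per-phantom seeds derived from ``p.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(replace(p, seed=s)) for s in cohort_seeds(p.seed, n)]


def estimate_head_mask(v: Volume, threshold: float = 0.15) -> np.ndarray:
    """Boolean head mask from smoothed intensity; oracle for in-head checks."""
    return gaussian_filter(np.asarray(v.data, dtype=float), 2.0) > threshold


def simulate_prediction_heatmap(
    truth: FiducialSet,
    spec: HeatmapSpec,
    noise_sigma: float,
    spurious_peaks: int,
    seed: int,
    shape=(64, 64, 48),
    affine=None,
    roi_clearance_mm: float = 25.0,
) -> Volume:
    """Emulate a network's predicted heatmap for post-processing tests.

    Ideal Gaussian-sphere heatmap at the true landmarks, plus the requested
    number of spurious Gaussian peaks placed strictly farther than
    ``roi_clearance_mm`` from both landmarks (outside any region of
    interest anchored on them), plus additive Gaussian noise. With
    noise_sigma = 0 and spurious_peaks = 0 the output equals the ideal
    target heatmap exactly.
    """
    if "AC" not in truth or "PC" not in truth:
        raise ValueError("truth must contain AC and PC")
    affine = center_affine(shape) if affine is None else np.asarray(affine, dtype=float)
    hm = make_target_heatmap(shape, truth, affine, spec)
    data = hm.data.copy()
    rng = np.random.default_rng(seed)

    if spurious_peaks > 0:
        margin = 5  # keep full peaks inside the grid
        lo = affine[:3, :3] @ np.full(3, margin) + affine[:3, 3]
        hi = affine[:3, :3] @ (np.asarray(shape) - 1.0 - margin) + affine[:3, 3]
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < spurious_peaks:
            attempts += 1
            if attempts > 10000:
                raise ValueError(
                    "cannot place spurious peaks outside the ROI clearance; "
                    "volume too small for roi_clearance_mm"
                )
            cand = rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi))
            if min(np.linalg.norm(cand - truth["AC"]), np.linalg.norm(cand - truth["PC"])) <= roi_clearance_mm:
                continue
            if any(np.linalg.norm(cand - q) < 6.0 * spec.sigma for q in placed):
                continue
            placed.append(cand)
        fake = FiducialSet(points=[(f"spur{i}", q) for i, q in enumerate(placed)])
        spur = make_target_heatmap(shape, fake, affine, spec)
        np.maximum(data, 0.9 * spur.data, out=data)

    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return Volume(data=data, affine=affine)


def simulate_annotators(
    truth: FiducialSet, k: int, label_noise_mm: float, seed: int
) -> list[FiducialSet]:
    """k independent annotators: isotropic Gaussian perturbation per landmark."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(k):
        pts = [
            (label, pos + rng.normal(0.0, label_noise_mm, size=3))
            for label, pos in truth.points
        ]
        out.append(FiducialSet(points=pts))
    return out
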