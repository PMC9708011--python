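"""Cine preprocessing: z-score standardization, landmark-based rigid
registration to a cohort reference pose, elliptical heart masking, and
anti-aliased downsampling.

Pipeline order is fixed — standardize, register, mask, downsample — and the
z-score statistics are always computed on the full pre-mask array so that the
per-subject intensity scale is removed before any spatial operation.

Coordinate convention: 0-based (row, col) with the pixel-centre at integer
coordinates, everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from skimage.transform import resize_local_mean

from .synthetic import CineStudy, LANDMARK_LABELS

ALLOWED_SIZES = (32, 64, 128, 256)


@dataclass
class ReferenceFrame:
    """Canonical pose of one view: mean landmark configuration plus the
    elliptical heart mask fitted around it."""

    view: str
    reference_landmarks: np.ndarray  # 3 x 2, (row, col), label order of LANDMARK_LABELS
    mask_center: np.ndarray  # (row, col)
    mask_semi_axes: np.ndarray  # (a_row, a_col), pixels
    mask_angle: float = 0.0  # radians

    def __post_init__(self):
        pts = np.asarray(self.reference_landmarks, dtype=float)
        if pts.shape != (3, 2):
            raise ValueError("reference needs exactly 3 (row, col) landmarks")
        if _collinear(pts):
            raise ValueError("reference landmarks are collinear")
        if np.any(np.asarray(self.mask_semi_axes) <= 0):
            raise ValueError("mask semi-axes must be positive")
        self.reference_landmarks = pts


@dataclass
class PreprocessedTensor:
    subject_id: str
    view: str
    tensor: np.ndarray  # S x S x T, z-units
    angle: float  # recovered rotation, radians
    translation: tuple  # recovered (d_row, d_col), pixels
    scale: float = 1.0
    mask_fraction: float = 1.0
    target_size: int | None = None


def _collinear(pts, tol=1e-9):
    a, b, c = np.asarray(pts, dtype=float)
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    scale = max(np.abs(pts).max(), 1.0)
    return abs(cross) < tol * scale**2


def landmark_matrix(landmarks: dict, view: str) -> np.ndarray:
    """Landmarks as a 3x2 array in the view's fixed label order."""
    labels = LANDMARK_LABELS[view]
    missing = set(labels) - set(landmarks)
    if missing:
        raise ValueError(f"missing landmark labels for view {view}: {sorted(missing)}")
    return np.array([landmarks[l] for l in labels], dtype=float)


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

def zscore_standardize(tensor: np.ndarray) -> np.ndarray:
    """Standardize one subject's full H x W x T array to mean 0, SD 1."""
    tensor = np.asarray(tensor, dtype=float)
    sd = tensor.std()
    if sd == 0:
        raise ValueError("constant tensor: z-score undefined (SD = 0)")
    return (tensor - tensor.mean()) / sd


# ---------------------------------------------------------------------------
# rigid alignment (2D Kabsch / Procrustes)
# ---------------------------------------------------------------------------

def rigid_align(source: np.ndarray, target: np.ndarray, allow_scale: bool = False):
    """Least-squares rigid (optionally similarity) transform mapping the
    source points onto the target points.

    Returns (R, t, s) with ``aligned = s * R @ source_i + t``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    src_c, tgt_c = src.mean(axis=0), tgt.mean(axis=0)
    A, B = src - src_c, tgt - tgt_c
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        s = (S * np.diag(D)).sum() / (A**2).sum()
    else:
        s = 1.0
    t = tgt_c - s * R @ src_c
    return R, t, s


def _apply_rigid(points, R, t, s=1.0):
    return (s * (np.asarray(points, dtype=float) @ R.T)) + t


def fit_reference(
    landmark_sets: list[np.ndarray],
    view: str,
    mask_expansion: float = 2.5,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ReferenceFrame:
    """Generalized-Procrustes mean landmark configuration.

    Iteratively aligns every subject's 3-point set to the running mean and
    re-averages until the mean moves by less than ``tol``.  Orientation is
    anchored to the first subject so the result is deterministic.  The
    elliptical mask is centred on the mean-landmark centroid with semi-axes
    ``mask_expansion`` times the per-axis landmark spread.
    """
    sets = []
    for i, pts in enumerate(landmark_sets):
        pts = np.asarray(pts, dtype=float)
        if pts.shape != (3, 2):
            raise ValueError(f"subject {i}: expected 3x2 landmark array, got {pts.shape}")
        if _collinear(pts):
            raise ValueError(f"subject {i}: collinear landmarks {pts.tolist()}")
        sets.append(pts)
    if len(sets) < 2:
        raise ValueError("need at least 2 subjects to fit a reference")

    mean = sets[0].copy()
    for _ in range(max_iter):
        aligned = []
        for pts in sets:
            R, t, _ = rigid_align(pts, mean)
            aligned.append(_apply_rigid(pts, R, t))
        new_mean = np.mean(aligned, axis=0)
        shift = np.abs(new_mean - mean).max()
        mean = new_mean
        if shift < tol:
            break

    centroid = mean.mean(axis=0)
    spread = mean.std(axis=0, ddof=0)
    semi = mask_expansion * np.maximum(spread, 1.0)
    return ReferenceFrame(
        view=view, reference_landmarks=mean, mask_center=centroid,
        mask_semi_axes=semi, mask_angle=0.0,
    )


def register_to_reference(
    study: CineStudy, ref: ReferenceFrame, allow_scale: bool = False
) -> PreprocessedTensor:
    """Rigidly register one study's tensor into the reference pose.

    The least-squares rigid transform mapping the study's landmarks onto the
    reference landmarks is applied identically to every frame (bilinear
    interpolation, zero fill outside the field of view).
    """
    if study.view != ref.view:
        raise ValueError(f"view mismatch: study {study.view} vs reference {ref.view}")
    src = landmark_matrix(study.landmarks, study.view)
    R, t, s = rigid_align(src, ref.reference_landmarks, allow_scale=allow_scale)
    # forward map: y = s R x + t  =>  pull-back x = R^T (y - t) / s
    inv_mat = R.T / s
    offset = -inv_mat @ t
    tensor = np.asarray(study.tensor, dtype=float)
    out = np.empty_like(tensor)
    for f in range(tensor.shape[2]):
        out[:, :, f] = affine_transform(tensor[:, :, f], inv_mat, offset=offset, order=1, cval=0.0)
    angle = float(np.arctan2(R[1, 0], R[0, 0]))
    return PreprocessedTensor(
        subject_id=study.subject_id, view=study.view, tensor=out,
        angle=angle, translation=(float(t[0]), float(t[1])), scale=float(s),
    )


# ---------------------------------------------------------------------------
# masking and downsampling
# ---------------------------------------------------------------------------

def elliptical_mask(shape, ref: ReferenceFrame) -> np.ndarray:
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr, dc = r - ref.mask_center[0], c - ref.mask_center[1]
    ca, sa = np.cos(ref.mask_angle), np.sin(ref.mask_angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    a, b = ref.mask_semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def apply_elliptical_mask(tensor: np.ndarray, ref: ReferenceFrame):
    """Zero out voxels outside the in-plane ellipse in every frame.

    Returns (masked tensor, retained-voxel fraction).
    """
    mask = elliptical_mask(tensor.shape[:2], ref)
    if not mask.any():
        raise ValueError("elliptical mask covers zero voxels")
    out = np.where(mask[:, :, None], tensor, 0.0)
    return out, float(mask.mean())


def downsample(tensor: np.ndarray, target_size: int) -> np.ndarray:
    """Local-mean (anti-aliased) resize of every frame to target x target."""
    if target_size not in ALLOWED_SIZES:
        raise ValueError(f"target_size must be one of {ALLOWED_SIZES}")
    H, W, T = tensor.shape
    if target_size > min(H, W):
        raise ValueError("target_size exceeds source size")
    if target_size == H == W:
        return tensor.copy()
    out = np.empty((target_size, target_size, T))
    for f in range(T):
        out[:, :, f] = resize_local_mean(tensor[:, :, f], (target_size, target_size))
    return out


def preprocess_study(
    study: CineStudy,
    ref: ReferenceFrame,
    target_size: int,
    allow_scale: bool = False,
) -> PreprocessedTensor:
    """Full chain: z-score -> register -> mask -> downsample."""
    std = zscore_standardize(study.tensor)
    reg = register_to_reference(
        CineStudy(
            subject_id=study.subject_id, view=study.view, tensor=std,
            landmarks=study.landmarks, covariates=study.covariates,
            survival_time=study.survival_time, event=study.event,
            latent_risk=study.latent_risk, metadata=study.metadata,
        ),
        ref,
        allow_scale=allow_scale,
    )
    masked, frac = apply_elliptical_mask(reg.tensor, ref)
    small = downsample(masked, target_size)
    reg.tensor = small
    reg.mask_fraction = frac
    reg.target_size = target_size
    return reg
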