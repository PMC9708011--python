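"""Multilinear principal component analysis for 3rd-order image tensors.

MPCA projects H x W x T arrays through one orthonormal basis per mode
(rows, columns, frames), preserving the spatial-temporal structure that
vectorized PCA destroys.  Fitting centres the sample by its mean tensor and,
per mode, eigendecomposes the mode-n total scatter matrix

    Phi_n = sum_m  X_m_(n)  X_m_(n)^T

of the (partially projected) mode-n unfoldings, retaining the smallest
number of leading eigenvectors whose cumulative eigenvalue fraction reaches
the requested variance level.  One alternating sweep over the modes is the
default; further sweeps refine the bases on the projections of the other
modes.

Features are the entries of the projected core tensor, vectorized and
ordered by descending training variance.  Reconstruction back-contracts a
core with the transposed bases and adds the mean; with square bases
(``variance_kept=1``) project/reconstruct is an exact round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MPCAModel:
    mean_tensor: np.ndarray  # S x S x T
    mode_bases: list  # per mode n: (dim_n, P_n) orthonormal columns
    feature_variances: np.ndarray  # variance per vectorized core entry, canonical order
    feature_order: np.ndarray  # permutation sorting canonical entries by descending variance
    variance_kept: float
    n_iterations: int = 1

    @property
    def core_shape(self):
        return tuple(b.shape[1] for b in self.mode_bases)

    @property
    def n_features(self):
        return int(np.prod(self.core_shape))

    def canonical_index(self, ordered_index):
        """Map position(s) in the variance-ordered feature vector back to the
        canonical (row-major core) index."""
        return self.feature_order[ordered_index]


def _mode_unfold(tensors, mode):
    """Stack mode-n unfoldings of a batch (N, d0, d1, d2) into one matrix
    (d_mode, N * prod(other))."""
    moved = np.moveaxis(tensors, 1 + mode, 1)
    return moved.reshape(tensors.shape[0], moved.shape[1], -1)


def _fix_signs(basis):
    """Deterministic sign: largest-|component| of each column made positive."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return basis * signs


def _multilinear_project(batch, bases, skip=None):
    """Contract a batch (N, d0, d1, d2) with basis transposes on every mode
    except ``skip``."""
    out = batch
    for mode, B in enumerate(bases):
        if mode == skip or B is None:
            continue
        out = np.moveaxis(np.tensordot(out, B, axes=([1 + mode], [0])), -1, 1 + mode)
    return out


def fit_mpca(
    tensors, variance_kept: float = 0.97, n_iterations: int = 1
) -> MPCAModel:
    """Fit an MPCA model to a list/array of same-shape 3rd-order tensors."""
    if not 0.0 < variance_kept <= 1.0:
        raise ValueError("variance_kept must lie in (0, 1]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    arrs = [np.asarray(t, dtype=float) for t in tensors]
    if len(arrs) < 2:
        raise ValueError("need at least 2 tensors")
    shape = arrs[0].shape
    if len(shape) != 3:
        raise ValueError("expected 3rd-order tensors")
    for i, a in enumerate(arrs):
        if a.shape != shape:
            raise ValueError(f"tensor {i} shape {a.shape} != {shape}")
    batch = np.stack(arrs, axis=0)
    mean = batch.mean(axis=0)
    centered = batch - mean

    bases: list = [None, None, None]
    total_var = float((centered**2).sum())
    for _ in range(n_iterations):
        for mode in range(3):
            partial = _multilinear_project(centered, bases, skip=mode)
            unf = _mode_unfold(partial, mode)  # (N, d_mode, rest)
            flat = np.concatenate([u for u in unf], axis=1)
            scatter = flat @ flat.T
            evals, evecs = np.linalg.eigh(scatter)
            order = np.argsort(-evals, kind="stable")
            evals, evecs = evals[order], evecs[:, order]
            evals = np.clip(evals, 0.0, None)
            total = evals.sum()
            if total <= 0:
                p = 1
            else:
                cum = np.cumsum(evals) / total
                p = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
            bases[mode] = _fix_signs(evecs[:, :p])

    cores = _multilinear_project(centered, bases)
    flat_cores = cores.reshape(cores.shape[0], -1)
    variances = flat_cores.var(axis=0, ddof=0)
    order = np.argsort(-variances, kind="stable")
    model = MPCAModel(
        mean_tensor=mean,
        mode_bases=bases,
        feature_variances=variances,
        feature_order=order,
        variance_kept=variance_kept,
        n_iterations=n_iterations,
    )
    for B in model.mode_bases:
        gram = B.T @ B
        if np.abs(gram - np.eye(B.shape[1])).max() >= 1e-8:
            raise RuntimeError("mode basis lost orthonormality")
    if variances.sum() > total_var / len(arrs) + 1e-6 * max(total_var, 1.0):
        raise RuntimeError("captured variance exceeds total data variance")
    return model


def project(model: MPCAModel, tensor, ordered: bool = True) -> np.ndarray:
    """Project one tensor to its feature vector (variance-ordered by default)."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != model.mean_tensor.shape:
        raise ValueError(f"shape {tensor.shape} != model shape {model.mean_tensor.shape}")
    core = _multilinear_project((tensor - model.mean_tensor)[None], model.mode_bases)[0]
    flat = core.reshape(-1)
    return flat[model.feature_order] if ordered else flat


def project_batch(model: MPCAModel, tensors, ordered: bool = True) -> np.ndarray:
    batch = np.stack([np.asarray(t, dtype=float) for t in tensors], axis=0)
    if batch.shape[1:] != model.mean_tensor.shape:
        raise ValueError("tensor shape mismatch")
    cores = _multilinear_project(batch - model.mean_tensor, model.mode_bases)
    flat = cores.reshape(batch.shape[0], -1)
    return flat[:, model.feature_order] if ordered else flat


def reconstruct(model: MPCAModel, features, ordered: bool = True, add_mean: bool = True):
    """Back-project a feature vector to voxel space."""
    features = np.asarray(features, dtype=float)
    if features.shape != (model.n_features,):
        raise ValueError(f"expected {model.n_features} features, got {features.shape}")
    flat = features
    if ordered:
        flat = np.empty_like(features)
        flat[model.feature_order] = features
    core = flat.reshape(model.core_shape)
    out = core[None]
    for mode, B in enumerate(model.mode_bases):
        out = np.moveaxis(np.tensordot(out, B.T, axes=([1 + mode], [0])), -1, 1 + mode)
    out = out[0]
    return out + model.mean_tensor if add_mean else out
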