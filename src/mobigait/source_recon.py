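"""eLORETA source reconstruction, dipole collapse, and ROI extraction.

eLORETA (exact low-resolution electromagnetic tomography) is the weighted
minimum-norm inverse whose source weights are chosen self-consistently so
that point sources are localized with zero error in the noiseless case.  The
weights solve the fixed point

    W_v = ( K_v^T (K W^-1 K^T + alpha H)^+ K_v )^{1/2}

per source ``v``, with ``K`` the average-referenced lead field, ``H`` the
average-reference (centering) operator, and the 3x3 matrix square root taken
symmetrically.  The inverse operator is then ``W_v^-1 K_v^T M`` with
``M = (K W^-1 K^T + alpha H)^+``.

The 3-D dipole time course at each voxel is collapsed to one representative
signal by PCA (first principal component), as is the set of voxel signals
inside a 6-mm ROI sphere.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .synthetic import LeadField

ROI_NAMES = ("M1", "THAL", "PMC", "PPC", "CER")


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


@dataclasses.dataclass
class InverseOperator:
    weights: np.ndarray      # (n_sources, 3, n_channels)
    alpha: float
    method: str = "eLORETA"
    n_iter: int = 0
    residual: float = np.inf


@dataclasses.dataclass
class RoiSpec:
    """A spherical region of interest on the source grid."""

    name: str
    hemisphere: str          # "left" or "right"
    center_mm: np.ndarray
    radius_mm: float = 6.0

    def __post_init__(self):
        if self.name not in ROI_NAMES:
            raise ValueError(f"ROI name must be one of {ROI_NAMES}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        self.center_mm = np.asarray(self.center_mm, float)


def _sym_sqrt(A: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(A)
    w = np.maximum(w, 0.0)
    return (V * np.sqrt(w)) @ V.T


def _sym_inv(A: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(A)
    wi = np.where(w > rcond * w.max(), 1.0 / np.maximum(w, 1e-300), 0.0)
    return (V * wi) @ V.T


def eloreta_fit(leadfield: LeadField, alpha: float | None = None,
                tol: float = 1e-6, max_iter: int = 100) -> InverseOperator:
    """Compute the eLORETA inverse operator for a lead field.

    ``alpha`` defaults to 1e-3 times the mean eigenvalue of the gain Gram
    matrix.  The gain is average-referenced internally.  Raises
    :class:`ConvergenceError` (carrying the last residual) if the weight
    fixed point has not converged within ``max_iter`` iterations.
    """
    K = np.asarray(leadfield.gain, float)
    n_ch, n_src, _ = K.shape
    K = K - K.mean(axis=0, keepdims=True)

    # non-degenerate orientation space per source
    sv = np.linalg.svd(K.transpose(1, 0, 2), compute_uv=False)  # (n_src, 3)
    if np.any(sv[:, 2] < 1e-10 * sv[:, 0]):
        bad = int(np.argmin(sv[:, 2] / sv[:, 0]))
        raise ValueError(f"rank-deficient gain block at source {bad}")

    H = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch
    Kf = K.reshape(n_ch, n_src * 3)
    if alpha is None:
        gram = Kf @ Kf.T
        alpha = 1e-3 * np.trace(gram) / n_ch
    Winv = np.tile(np.eye(3), (n_src, 1, 1))
    residual = np.inf
    for it in range(1, max_iter + 1):
        # S = sum_v K_v W_v^-1 K_v^T
        S = np.einsum("cvi,vij,dvj->cd", K, Winv, K, optimize=True)
        M = np.linalg.pinv(S + alpha * H, hermitian=True)
        KtMK = np.einsum("cvi,cd,dvj->vij", K, M, K, optimize=True)
        W_new = np.stack([_sym_sqrt(KtMK[v]) for v in range(n_src)])
        Winv_new = np.stack([_sym_inv(W_new[v]) for v in range(n_src)])
        prev = np.stack([_sym_inv(Winv[v]) for v in range(n_src)])
        num = np.linalg.norm(W_new - prev, axis=(1, 2))
        den = np.maximum(np.linalg.norm(prev, axis=(1, 2)), 1e-300)
        residual = float(np.max(num / den))
        Winv = Winv_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"eLORETA did not converge in {max_iter} iterations "
            f"(residual {residual:.3g})", residual=residual)
    weights = np.einsum("vij,cvj,cd->vid", Winv, K, M, optimize=True)
    return InverseOperator(weights=weights, alpha=float(alpha),
                           n_iter=it, residual=residual)


def apply_inverse(op: InverseOperator, eeg) -> np.ndarray:
    """Project channel data to source dipole time courses (n_src, 3, T).

    ``eeg`` may be a SensorStream or a (n_channels, T) array.  The mapping
    is exactly linear in the data.
    """
    data = eeg.data if hasattr(eeg, "data") else np.asarray(eeg, float)
    if data.shape[0] != op.weights.shape[2]:
        raise ValueError(
            f"channel mismatch: operator expects {op.weights.shape[2]}, "
            f"data has {data.shape[0]}")
    return np.einsum("vic,ct->vit", op.weights, data, optimize=True)


def _pc1(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of rows-as-variables data.

    Returns (scores, loading, explained_fraction) with the deterministic
    sign rule: loading sum positive, ties broken by a positive first
    non-zero element.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    u = U[:, 0]
    total = float(np.sum(s ** 2))
    if abs(u.sum()) > 1e-12:
        sign = np.sign(u.sum())
    else:
        nz = u[np.abs(u) > 1e-12]
        sign = np.sign(nz[0]) if nz.size else 1.0
    scores = sign * s[0] * Vt[0]
    frac = float(s[0] ** 2 / total) if total > 0 else 0.0
    return scores, sign * u, frac


def collapse_dipole(source_xyz: np.ndarray) -> np.ndarray:
    """Collapse a (3, T) dipole signal to its first principal component."""
    source_xyz = np.asarray(source_xyz, float)
    if source_xyz.ndim != 2 or source_xyz.shape[0] != 3:
        raise ValueError("expected a (3, n_times) dipole signal")
    if source_xyz.shape[1] < 2:
        raise ValueError("need at least 2 time samples")
    if np.all(source_xyz == 0):
        import logging
        logging.getLogger(__name__).warning("all-zero dipole signal")
        return np.zeros(source_xyz.shape[1])
    scores, _, _ = _pc1(source_xyz)
    return scores


def collapse_all(dipoles: np.ndarray) -> np.ndarray:
    """Collapse (n_src, 3, T) dipole signals to (n_src, T) voxel signals."""
    return np.stack([collapse_dipole(d) for d in dipoles])


def extract_roi(voxel_signals: np.ndarray, spec: RoiSpec,
                grid_mm: np.ndarray) -> np.ndarray:
    """First principal component of the voxel signals inside the ROI sphere."""
    grid_mm = np.asarray(grid_mm, float)
    d = np.linalg.norm(grid_mm - spec.center_mm[None, :], axis=1)
    inside = np.flatnonzero(d <= spec.radius_mm)
    if inside.size == 0:
        raise ValueError(
            f"ROI {spec.name}/{spec.hemisphere}: no voxel within "
            f"{spec.radius_mm} mm (nearest at {d.min():.1f} mm)")
    X = np.asarray(voxel_signals, float)[inside]
    if inside.size == 1:
        return X[0]
    scores, _, _ = _pc1(X)
    return scores
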