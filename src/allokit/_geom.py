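"""Rigid-body superposition and pairwise-RMSD kernels.

All coordinates are in Å. Rotations are found by the Kabsch algorithm
(SVD of the 3x3 covariance with a proper-rotation determinant fix).
"""

from __future__ import annotations

import numpy as np


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix R such that mobile @ R best fits target.

    Both inputs must already be centered (mean-free), shape (n, 3).
    """
    cov = mobile.T @ target
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def superpose(mobile: np.ndarray, target: np.ndarray,
              mobile_fit: np.ndarray | None = None,
              target_fit: np.ndarray | None = None) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target``.

    The rotation/translation is determined on the fit selections
    (defaults: the full coordinate sets) and applied to all of ``mobile``.
    """
    if mobile_fit is None:
        mobile_fit = mobile
    if target_fit is None:
        target_fit = target
    cm = mobile_fit.mean(axis=0)
    ct = target_fit.mean(axis=0)
    rot = kabsch_rotation(mobile_fit - cm, target_fit - ct)
    return (mobile - cm) @ rot + ct


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between matched coordinate sets, no fitting."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fitted_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between a and b over rigid motions."""
    return rmsd(superpose(a, b), b)


def pairwise_rmsd_matrix(frames: np.ndarray, chunk: int = 256) -> np.ndarray:
    """All-vs-all minimum (fitted) RMSD over a stack of frames.

    frames: (n_frames, n_atoms, 3). Uses the closed form
    rmsd^2 = (Ta + Tb - 2*(s1 + s2 +/- s3)) / n_atoms with batched
    3x3 SVDs of the cross-covariances, chunked to bound memory.
    """
    n_frames, n_atoms, _ = frames.shape
    x = frames - frames.mean(axis=1, keepdims=True)
    norms = np.einsum("fai,fai->f", x, x)
    out = np.zeros((n_frames, n_frames))
    for i0 in range(0, n_frames, chunk):
        i1 = min(i0 + chunk, n_frames)
        for j0 in range(i0, n_frames, chunk):
            j1 = min(j0 + chunk, n_frames)
            # cross covariances for the block: (bi, bj, 3, 3)
            cov = np.einsum("iak,jal->ijkl", x[i0:i1], x[j0:j1])
            u, s, vt = np.linalg.svd(cov)
            det = np.linalg.det(u @ vt)
            tr = s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]
            sq = (norms[i0:i1, None] + norms[None, j0:j1] - 2.0 * tr) / n_atoms
            block = np.sqrt(np.maximum(sq, 0.0))
            out[i0:i1, j0:j1] = block
            out[j0:j1, i0:i1] = block.T
    np.fill_diagonal(out, 0.0)
    return out
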