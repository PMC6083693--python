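"""Rigid-body alignment helpers (Kabsch superposition, random rotations)."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_align", "aligned_displacements", "random_rotation"]


def kabsch_align(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of point set ``P`` onto ``Q``.

    Returns ``P`` transformed by the least-squares rotation + translation
    (no scaling, proper rotation only).  Degenerate cases (1 or 2 points,
    collinear sets) are handled by the SVD naturally; distances between the
    transformed and target points are then the residual displacements.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError("point sets must have equal shapes")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (P - pc) @ R.T + qc


def aligned_displacements(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Per-point residual distances after Kabsch alignment of P onto Q."""
    aligned = kabsch_align(P, Q)
    return np.linalg.norm(aligned - np.asarray(Q, dtype=float).reshape(-1, 3), axis=1)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (via unit quaternion)."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()
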