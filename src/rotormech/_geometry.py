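"""Shared rigid-body geometry primitives (Kabsch superposition, batched RMSD)."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target : (n, 3) arrays
        Paired coordinates, n >= 3 and not all collinear for a unique rotation.

    Returns
    -------
    R : (3, 3) proper rotation matrix
    t : (3,) translation
        such that ``mobile @ R.T + t`` optimally superposes onto ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch expects two (n, 3) coordinate arrays of equal shape")
    if mobile.shape[0] < 3:
        raise ValueError(
            f"kabsch needs at least 3 paired atoms, got {mobile.shape[0]}: "
            "rotation is underdetermined"
        )
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def superpose_coords(mobile: np.ndarray, target: np.ndarray,
                     apply_to: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Superpose ``mobile`` onto ``target``; optionally transform ``apply_to``.

    Returns the transformed coordinates and the RMSD over the fit atoms.
    """
    R, t = kabsch(mobile, target)
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    if apply_to is None:
        return fitted, rmsd
    return apply_to @ R.T + t, rmsd


def rmsd_after_fit(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    fitted, rmsd = superpose_coords(a, b)
    return rmsd


def batch_rmsd_to_template(frags: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Minimum RMSD of many small fragments against one template, batched.

    Uses the closed form rmsd^2 = (E0 - 2 * sum_i s_i) / n where s_i are the
    singular values of the cross-covariance with the smallest one
    sign-flipped when the fit requires an improper rotation.

    Parameters
    ----------
    frags : (N, n, 3)
    template : (n, 3)
    """
    frags = np.asarray(frags, dtype=float)
    template = np.asarray(template, dtype=float)
    n = template.shape[0]
    fc = frags - frags.mean(axis=1, keepdims=True)
    tc = template - template.mean(axis=0)
    E0 = np.sum(fc ** 2, axis=(1, 2)) + np.sum(tc ** 2)
    H = np.einsum("nij,ik->njk", fc, tc)  # (N, 3, 3)
    s = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    trace = s.sum(axis=1) - 2.0 * s[:, -1] * (det < 0)
    msd = np.maximum(E0 - 2.0 * trace, 0.0) / n
    return np.sqrt(msd)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis has near-zero norm")
    k = axis / norm
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a near-zero vector")
    return v / n


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )
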