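"""Rigid-body geometry: least-squares superposition, rotations, sphere grids.

The superposition engine restricts itself to proper rotations (det = +1) so
that chirality is never inverted by a fit.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target : (n, 3) arrays
        Paired point sets, n >= 3 recommended (n >= 1 accepted).

    Returns
    -------
    rotation : (3, 3) proper rotation matrix
    translation : (3,) vector
    rmsd : float
        Root-mean-square deviation of ``rotation @ mobile + translation``
        from ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    c_m = mobile.mean(axis=0)
    c_t = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - c_t, mobile - c_m)
    r = rot.as_matrix()
    t = c_t - r @ c_m
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return r, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply ``x -> R x + t`` to an (n, 3) coordinate array."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)


def rmsd_fixed(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two paired point sets without superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def unit(v: np.ndarray) -> np.ndarray:
    """Unit vector along v."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic for a given n; used as the Shrake-Rupley sampling grid.
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )
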