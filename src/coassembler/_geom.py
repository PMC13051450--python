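"""Internal geometry helpers: internal-coordinate atom placement and rigid fits."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C with bond |C-D|, angle B-C-D and
    torsion A-B-C-D (NeRF construction)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear reference: pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, ref)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits `reference`, with the
    rotation constrained to be proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    p = mobile - mu_m
    q = reference - mu_r
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    moved = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_rigid(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def pairwise_min_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance between two coordinate sets."""
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((d ** 2).sum(axis=2).min()))
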