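"""Small geometry kernels: Kabsch superposition, internal-coordinate (NeRF)
atom placement, dihedrals and plane reflections."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t) such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``target``. The rotation is proper (det +1); reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch expects two (n, 3) arrays of equal shape")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - mu_m @ R.T
    return R, t


def superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal proper-rotation superposition."""
    R, t = kabsch(mobile, target)
    moved = mobile @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 formed by p0-p1-p2, in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = length, angle(b,c,d) = angle, torsion
    (a,b,c,d) = torsion. Natural-extension-of-reference-frame construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("colinear reference atoms for internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(chi),
        -length * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def reflect_through_plane(points: np.ndarray, p0, p1, p2) -> np.ndarray:
    """Mirror ``points`` through the plane containing p0, p1, p2."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    n = np.cross(p1 - p0, p2 - p0)
    n /= np.linalg.norm(n)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = (pts - p0) @ n
    return pts - 2.0 * d[:, None] * n


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + 5.0 ** 0.5)
    theta = golden * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])
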