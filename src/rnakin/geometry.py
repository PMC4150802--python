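"""Low-level rigid-geometry primitives shared across the package.

All angles are radians unless a function name says otherwise.  Points are
numpy arrays of shape (3,) or (N, 3).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, TWO_PI) - np.pi)
    return w if w.ndim else float(w)


def unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def cross3(a, b):
    """Cross product of two 3-vectors (faster than np.cross for scalars)."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in radians."""
    u, v = unit(a - b), unit(c - b)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 (IUPAC right-handed), radians in (-pi, pi].

    Raises ValueError when three consecutive atoms are collinear, which leaves
    the torsion undefined.
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = cross3(b0, b1)
    n2 = cross3(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined dihedral: collinear atoms")
    m1 = cross3(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(wrap_angle(np.arctan2(y, x)))


def rotation_matrix(axis, angle) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis vector."""
    axis = unit(np.asarray(axis, dtype=float))
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def rotate_about_line(points, origin, axis, angle) -> np.ndarray:
    """Rotate points about the line through `origin` along `axis`."""
    R = rotation_matrix(axis, angle)
    return (np.asarray(points) - origin) @ R.T + origin


class Frame:
    """Right-handed orthonormal frame: origin plus rotation columns."""

    __slots__ = ("R", "o")

    def __init__(self, R: np.ndarray, o: np.ndarray):
        self.R = R
        self.o = o

    @classmethod
    def from_points(cls, a, b, c) -> "Frame":
        """Frame with origin at b, x along b->c, a fixing the xy half-plane."""
        x = unit(c - b)
        w = a - b
        y = w - np.dot(w, x) * x
        y = unit(y)
        z = cross3(x, y)
        return cls(np.column_stack([x, y, z]), np.asarray(b, dtype=float))

    def to_local(self, pts):
        return (np.asarray(pts) - self.o) @ self.R

    def to_world(self, pts):
        return np.asarray(pts) @ self.R.T + self.o


def transform_between(src: Frame, dst: Frame):
    """Rigid map (R, t) taking world points expressed near `src` onto `dst`.

    Applying ``p @ R.T + t`` moves a point rigidly so its coordinates in
    `dst` equal its former coordinates in `src`.
    """
    R = dst.R @ src.R.T
    t = dst.o - src.o @ R.T
    return R, t


def nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with |cd|=bond, angle(b,c,d) and
    dihedral(a,b,c,d) given (natural-extension reference frame)."""
    bc = unit(c - b)
    n = unit(cross3(b - a, bc))
    m = cross3(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            -np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(P, Q):
    """Optimal rotation/translation superposing P onto Q (least squares).

    Returns (R, t, rmsd) with ``P @ R.T + t`` the superposed copy.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - cp @ R.T
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superposed_rmsd(P, Q) -> float:
    """RMSD after optimal superposition."""
    return kabsch(P, Q)[2]


def circular_variance(angles) -> float:
    """1 - |mean resultant| of a sample of angles (radians); 0 for constant."""
    a = np.asarray(angles, dtype=float)
    return float(1.0 - np.abs(np.mean(np.exp(1j * a))))
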