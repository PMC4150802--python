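"""Ribose pucker as a single differentiable coordinate (tau).

The five-membered sugar ring is treated as a rigid body whose internal
geometry is a smooth function of one pucker coordinate tau (degrees).  tau is
an affine recoding of the Altona-Sundaralingam pseudorotation phase P,
calibrated so that tau = -154 deg corresponds to C3'-endo (P ~ 18 deg) and
tau = +44.7 deg to C2'-endo (P ~ 162 deg).  The map is continuous and
monotone on the branch tau in (-180, 180]; the phase window not covered by
that branch (far "west" puckers) is outside the sampler's reach and is folded
back on measurement.

Ring coordinates are generated by an exact-closure embedding: the five ring
atoms sit on a circle of phase-adjusted radius with out-of-plane
displacements z_j = A cos(phi + 4 pi j / 5), the classic pseudorotation
displacement pattern.  Closure is exact by construction; bond lengths stay
within ~0.01 A of the target 1.46 A.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import Frame, dihedral, nerf, unit

RING_ORDER = ["O4'", "C1'", "C2'", "C3'", "C4'"]

# tau <-> P calibration anchors
_TAU_C3, _P_C3 = -154.0, 18.0
_TAU_C2, _P_C2 = 44.7, 162.0
_SLOPE = (_P_C2 - _P_C3) / (_TAU_C2 - _TAU_C3)
_OFFSET = _P_C3 - _SLOPE * _TAU_C3

_RING_BOND = 1.46      # effective endocyclic bond length, Angstrom
_Z_AMP = 0.235         # out-of-plane amplitude; gives nu_max close to 39 deg
_SIN36 = np.sin(np.radians(36.0))
_SIN72 = np.sin(np.radians(72.0))

# exocyclic substituents: ring atom -> ((up_name, up_len), (down_name, down_len))
# "up" is the base (beta) face.  NGLY / C5' / O3' are attachment anchors for
# atoms that belong to neighboring rigid bodies.
EXO_SUBSTITUENTS = {
    "C1'": (("NGLY", 1.47), ("H1'", 1.09)),
    "C2'": (("H2'", 1.09), ("O2'", 1.41)),
    "C3'": (("H3'", 1.09), ("O3'", 1.42)),
    "C4'": (("C5'", 1.51), ("H4'", 1.09)),
}
_TETRA_HALF = np.radians(54.75)


def tau_to_phase(tau_deg: float) -> float:
    """Pseudorotation phase P (degrees) for a pucker coordinate tau.

    tau is treated as a real-valued coordinate (not an angle on the circle):
    the affine slope differs from one, so wrapping tau by 360 would jump the
    phase.  The embedding only consumes the phase modulo 360.
    """
    return _SLOPE * float(tau_deg) + _OFFSET


def phase_to_tau(p_deg: float) -> float:
    """Inverse of :func:`tau_to_phase`.

    The phase is folded into the branch window centered on the canonical
    tau interval; values just past the tau = +-180 edge are reported as a
    continuous overshoot rather than being wrapped to the other end, so
    that measure/set round trips stay consistent near the branch cut.
    """
    lo = _SLOPE * (-180.0) + _OFFSET
    width = _SLOPE * 360.0
    p = (p_deg - lo) % 360.0 + lo
    if p > lo + width:           # outside the covered branch; fold back
        p -= 360.0
    return (p - _OFFSET) / _SLOPE


def wrap_deg(a):
    return -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)


def pseudorotation(ring_coords) -> tuple[float, float]:
    """Altona-Sundaralingam phase P and amplitude nu_max (degrees).

    `ring_coords` is a (5, 3) array in RING_ORDER.
    """
    r = np.asarray(ring_coords, dtype=float)
    idx = [(4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0), (3, 4, 0, 1)]
    nu = np.array([np.degrees(dihedral(r[a], r[b], r[c], r[d]))
                   for a, b, c, d in idx])
    y = (nu[4] + nu[1]) - (nu[3] + nu[0])
    x = 2.0 * nu[2] * (_SIN36 + _SIN72)
    p = np.degrees(np.arctan2(y, x))
    numax = nu[2] / np.cos(np.radians(p))
    if numax < 0:
        numax, p = -numax, p + 180.0
    return float(wrap_deg(p) % 360.0), float(numax)


def _raw_ring(phi_deg: float) -> np.ndarray:
    """Embedded ring for internal phase phi; order RING_ORDER; exact closure."""
    j = np.arange(5)
    z = _Z_AMP * np.cos(np.radians(phi_deg) + 4.0 * np.pi * j / 5.0)
    dz2 = np.mean(np.diff(np.concatenate([z, z[:1]])) ** 2)
    r_eff = np.sqrt(max(_RING_BOND**2 - dz2, 0.25)) / (2.0 * _SIN36)
    # winding chosen so the beta (base) face is +z for D-ribose chirality
    ang = 2.0 * np.pi * j / 5.0
    ring = np.column_stack([r_eff * np.cos(ang), r_eff * np.sin(ang), z])
    return ring - ring.mean(axis=0)


@lru_cache(maxsize=1)
def _phase_calibration() -> tuple[float, float]:
    """(sign, offset) with measured P ~ sign * phi + offset."""
    p0, _ = pseudorotation(_raw_ring(0.0))
    p1, _ = pseudorotation(_raw_ring(25.0))
    d = wrap_deg(p1 - p0)
    sign = 1.0 if d > 0 else -1.0
    return sign, p0


def ring_local_coords(p_deg: float) -> np.ndarray:
    """(5, 3) ring coordinates whose A-S pseudorotation phase is ~p_deg."""
    sign, off = _phase_calibration()
    return _raw_ring(sign * (p_deg - off))


def fit_phase(ring_coords) -> tuple[float, float]:
    """Exact numerical inverse of the embedding: phase P (deg) and fit RMSD.

    Finds the phase whose embedded ring best superposes (Kabsch) onto the
    given ring coordinates; accurate for embedded rings, robust for real ones.
    """
    from .geometry import superposed_rmsd

    p0, _ = pseudorotation(ring_coords)

    def cost(p):
        return superposed_rmsd(ring_local_coords(p), ring_coords)

    res = minimize_scalar(cost, bracket=(p0 - 12.0, p0, p0 + 12.0),
                          options={"xtol": 1e-10})
    return float(res.x % 360.0), float(res.fun)


def measure_tau(ring_coords) -> float:
    """Pucker coordinate tau (degrees) from ring coordinates."""
    p, _ = fit_phase(ring_coords)
    return phase_to_tau(p)


def classify_pucker(tau_deg: float) -> str:
    """'C3-endo', 'C2-endo' or 'other' from the pseudorotation phase."""
    p = tau_to_phase(tau_deg) % 360.0
    if -18.0 <= wrap_deg(p) <= 54.0:
        return "C3-endo"
    if 126.0 <= p <= 198.0:
        return "C2-endo"
    return "other"


def exo_direction(ring, j, up: bool) -> np.ndarray:
    """Unit direction of an exocyclic substituent at ring atom j.

    Tetrahedral placement: in the plane spanned by the external bisector of
    the two endocyclic bonds and the local ring normal.
    """
    r = ring[j]
    u1 = unit(ring[(j - 1) % 5] - r)
    u2 = unit(ring[(j + 1) % 5] - r)
    bis = unit(u1 + u2)
    n = np.cross(u1, u2)
    n = unit(n)
    if np.dot(n, np.array([0.0, 0.0, 1.0])) < 0 and abs(n[2]) > 1e-8:
        n = -n                       # keep "up" on the +z (beta) side
    s = 1.0 if up else -1.0
    return unit(-bis * np.cos(_TETRA_HALF) + s * n * np.sin(_TETRA_HALF))


_TEMPLATE_MEMO: dict = {}


def ribose_template(tau_deg: float) -> dict:
    """Local ribose geometry for a given tau: ring atoms, hydrogens, the
    2'-OH group, and the attachment anchors NGLY (glycosidic nitrogen),
    C5' and O3'.  Returns a dict name -> (3,) array.
    """
    key = round(float(tau_deg), 9)
    if key in _TEMPLATE_MEMO:
        return _TEMPLATE_MEMO[key]
    ring = ring_local_coords(tau_to_phase(tau_deg))
    out = {name: ring[i] for i, name in enumerate(RING_ORDER)}
    for j, name in enumerate(RING_ORDER):
        if name not in EXO_SUBSTITUENTS:
            continue
        (up_name, up_len), (dn_name, dn_len) = EXO_SUBSTITUENTS[name]
        out[up_name] = ring[j] + up_len * exo_direction(ring, j, True)
        out[dn_name] = ring[j] + dn_len * exo_direction(ring, j, False)
    # 2'-OH hydrogen, anti to C3' about the C2'-O2' bond
    out["HO2'"] = nerf(out["C3'"], out["C2'"], out["O2'"],
                       0.96, np.radians(109.5), np.pi)
    if len(_TEMPLATE_MEMO) < 4096:
        _TEMPLATE_MEMO[key] = out
    return out


def ribose_anchor_frame(template: dict, a: str, b: str, c: str) -> Frame:
    return Frame.from_points(template[a], template[b], template[c])
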