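"""Synthetic fixtures: idealized A-form RNA hairpins and RDC mixtures.

The hairpin builder constructs a WC-paired stem by stacking base-pair frames
along a helix whose parameters (twist, rise, displacement, inclination,
glycosidic placement angles and the chi/gamma/beta torsions) are calibrated
numerically so that consecutive residues connect through near-ideal O3'-P
junctions with A-form epsilon/zeta/alpha crossing torsions.  The loop is
grown by natural-extension (NeRF) chaining and re-closed onto the 3' stem
with damped pseudoinverse iterations -- the same numerical idea the sampler
uses for rebuild moves.

Everything is generated from internal idealized geometry; no external
coordinate files are needed.  The geometry is self-consistent rather than a
fiber-diffraction average.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import chem, pucker
from .geometry import dihedral, nerf, rotation_matrix, unit, wrap_angle
from .structure_io import WCPair, read_pdb

# A-form target torsions (degrees)
AFORM = {"alpha": -68.0, "beta": 178.0, "gamma": 54.0, "epsilon": -153.0,
         "zeta": -71.0, "chi": -158.0}
TAU_C3_ENDO = -154.0

# ideal backbone internals (Angstrom / degrees)
_B = {
    "O3'-P": 1.60, "P-O5'": 1.59, "O5'-C5'": 1.42,
    "C3'-O3'-P": 119.7, "O3'-P-O5'": 104.0, "P-O5'-C5'": 120.9,
    "C4'-C5'-O5'": 110.2, "C5'-C4'": 1.51,
}

_HB_TARGET = 2.10        # donor-H ... acceptor distance in stem pairs
# common C1' off-axis height in the pair frame; between the natural purine
# (1.06 A) and pyrimidine (0.73 A) exterior-bisector heights
_Y_C1 = 0.89
# central WC atoms per base: (glycosidic N, central hbond heavy atom)
_HB_ATOM = {"A": "N1", "U": "N3", "G": "N1", "C": "N3"}
_DONOR = {"AU": "U", "GC": "G", "UA": "U", "CG": "G"}


@dataclass
class HairpinSpec:
    stem: int = 4
    loop: int = 4
    sequence: str | None = None
    noise_sigma: float = 0.0            # degrees, applied to loop torsions
    tau: float = TAU_C3_ENDO
    torsions: dict = field(default_factory=lambda: dict(AFORM))

    def __post_init__(self):
        if self.stem < 1:
            raise ValueError("stem must have at least one base pair")
        if self.loop < 3:
            raise ValueError("loop must have at least three nucleotides")
        if self.sequence is None:
            stem1 = ("GC" * self.stem)[: self.stem]
            loop = ("GAAA" * ((self.loop + 3) // 4))[: self.loop]
            stem2 = "".join(chem.WC_PARTNER[b] for b in reversed(stem1))
            self.sequence = stem1 + loop + stem2
        n = 2 * self.stem + self.loop
        if len(self.sequence) != n:
            raise ValueError(f"sequence length {len(self.sequence)} != {n}")
        for i in range(self.stem):
            a, b = self.sequence[i], self.sequence[n - 1 - i]
            if chem.WC_PARTNER[a] != b:
                raise ValueError(f"stem positions {i + 1}/{n - i} not WC")

    @property
    def length(self):
        return 2 * self.stem + self.loop

    def pair_list(self):
        n = self.length
        return [WCPair(i + 1, n - i,
                       "AU" if {self.sequence[i]} <= {"A", "U"} else "GC")
                for i in range(self.stem)]


@dataclass
class HairpinResult:
    spec: HairpinSpec
    topology: object
    coords: np.ndarray
    pairs: list
    pdb_text: str
    achieved: dict                      # calibrated parameter values


# ---------------------------------------------------------------------------
# base placement in the pair frame

# In-plane mirror applied to pyrimidine templates so that, once the pair is
# assembled with colinear hydrogen bonds, the IUPAC chi reference atoms of
# both bases fall on the same side of the glycosidic axis and the attached
# sugars share one backbone orientation.  A planar base is achiral, so this
# is a convention, fixed empirically against the purine construction.
_MIRROR_PYRIMIDINE = True


def _oriented_base(letter):
    """Base coords with the central WC atom at the origin and the glycosidic
    N -> WC-atom direction along +x (both atoms on the x axis)."""
    raw = chem.ideal_base_coords(letter)
    if letter in chem.PYRIMIDINES and _MIRROR_PYRIMIDINE:
        raw = {nm: p * np.array([1.0, -1.0, 1.0]) for nm, p in raw.items()}
    hb = raw[_HB_ATOM[letter]]
    gn = raw[chem.GLYCOSIDIC_N[letter]]
    d = unit(hb - gn)
    ang = np.arctan2(d[1], d[0])
    R = rotation_matrix([0.0, 0.0, 1.0], -ang)
    return {nm: (p - hb) @ R.T for nm, p in raw.items()}


_FLIP = rotation_matrix([0.0, 1.0, 0.0], np.pi)     # strand-2 dyad flip


def _pair_coords(b1, b2, y_c1=_Y_C1):
    """Coordinates of a WC pair in the pair frame.

    Strand-1 base extends toward -x, strand-2 (flipped about the y axis)
    toward +x; hydrogen bonds run along x.  Each C1' is placed at the
    glycosidic bond length from its nitrogen, as close to the base's radial
    direction as possible subject to a common off-axis height `y_c1` -- this
    puts both C1' atoms at equal y, so base pairs stack into one helical
    lattice regardless of which strand holds the purine.
    """
    c1 = _oriented_base(b1)
    c2 = {nm: p @ _FLIP.T for nm, p in _oriented_base(b2).items()}
    # translate strand-2 base along +x until the donor H ... acceptor
    # distance equals the target
    donor = _DONOR[b1 + b2]
    hname = "H3" if donor == "U" else "H1"
    if donor == b1:
        hpos, acc = c1[hname], None
        # acceptor on strand 2, currently at origin after flip
        t = _solve_sep(lambda t: np.linalg.norm(
            hpos - np.array([t, 0.0, 0.0])))
    else:
        hpos = c2[hname]
        t = _solve_sep(lambda t: np.linalg.norm(
            hpos + np.array([t, 0.0, 0.0])))
    for nm in c2:
        c2[nm] = c2[nm] + np.array([t, 0.0, 0.0])
    # glycosidic C1' attachments: as close to the exterior ring bisector as
    # the common height y_c1 allows (keeps C1'-N-C ring angles near ideal)
    sy = np.clip(y_c1 / chem._C1P_N, -0.95, 0.95)
    for cc, base in ((c1, b1), (c2, b2)):
        nn = cc[chem.GLYCOSIDIC_N[base]]
        nb1, nb2 = chem.GLYC_RING_NEIGHBORS[base]
        bis = -unit(unit(cc[nb1] - nn) + unit(cc[nb2] - nn))
        psi = np.arcsin(sy) if bis[0] > 0 else np.pi - np.arcsin(sy)
        cc["C1'"] = nn + chem._C1P_N * np.array(
            [np.cos(psi), np.sin(psi), 0.0])
    # anchor the frame at the C1'-C1' midpoint so purine/pyrimidine strand
    # assignments share one helix lattice
    center = 0.5 * (c1["C1'"] + c2["C1'"])
    c1 = {nm: p - center for nm, p in c1.items()}
    c2 = {nm: p - center for nm, p in c2.items()}
    return c1, c2


def _solve_sep(dist_of_t):
    from scipy.optimize import brentq
    f = lambda t: dist_of_t(t) - _HB_TARGET
    return brentq(f, 0.5, 8.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# residue construction from a placed base

def _ribose_on_base(base_world, letter, chi_deg, tau_deg):
    """Attach an ideal ribose to a placed base, honoring chi."""
    tpl = pucker.ribose_template(tau_deg)
    n_name = chem.GLYCOSIDIC_N[letter]
    c1_w, n_w = base_world["C1'"], base_world[n_name]
    # rigid placement: template C1' -> world C1', template C1'->NGLY direction
    # -> world C1'->N direction (rotation about their cross axis)
    d_t = unit(tpl["NGLY"] - tpl["C1'"])
    d_w = unit(n_w - c1_w)
    axis = np.cross(d_t, d_w)
    if np.linalg.norm(axis) < 1e-10:
        R0 = np.eye(3) if np.dot(d_t, d_w) > 0 else rotation_matrix(
            _any_perp(d_t), np.pi)
    else:
        R0 = rotation_matrix(axis, np.arccos(np.clip(np.dot(d_t, d_w),
                                                     -1.0, 1.0)))
    placed = {nm: (p - tpl["C1'"]) @ R0.T + c1_w for nm, p in tpl.items()}
    # rotate about the glycosidic axis to the requested chi
    ref = base_world[chem.CHI_REF_ATOM[letter]]
    cur = np.degrees(dihedral(placed["O4'"], placed["C1'"], n_w, ref))
    Rc = rotation_matrix(n_w - c1_w, np.radians(chi_deg - cur))
    placed = {nm: (p - c1_w) @ Rc.T + c1_w for nm, p in placed.items()}
    return placed


def _any_perp(v):
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, a))


def _build_residue(base_world, letter, p, first=False):
    """All atom positions for one residue; `p` holds torsion parameters."""
    out = {nm: base_world[nm] for nm in chem.base_atom_names(letter)}
    sugar = _ribose_on_base(base_world, letter, p["chi"], p["tau"])
    for nm in ("C1'", "C2'", "C3'", "C4'", "O4'", "H1'", "H2'", "H3'",
               "H4'", "O2'", "HO2'", "C5'", "O3'"):
        out[nm] = sugar[nm]
    g = np.radians(p["gamma"])
    out["O5'"] = nerf(out["C3'"], out["C4'"], out["C5'"], _B["O5'-C5'"],
                      np.radians(_B["C4'-C5'-O5'"]), g)
    for nm, off in (("H5'", 2.0 * np.pi / 3.0), ("H5''", -2.0 * np.pi / 3.0)):
        out[nm] = nerf(out["C3'"], out["C4'"], out["C5'"], 1.09,
                       np.radians(109.5), g + off)
    if first:
        out["HO5'"] = nerf(out["C4'"], out["C5'"], out["O5'"], 0.96,
                           np.radians(108.0), np.pi)
    else:
        b = np.radians(p["beta"])
        out["P"] = nerf(out["C4'"], out["C5'"], out["O5'"], _B["P-O5'"],
                        np.radians(_B["P-O5'-C5'"]), b)
        a = np.radians(p["alpha"])
        for nm, off in (("OP1", 2.0 * np.pi / 3.0),
                        ("OP2", -2.0 * np.pi / 3.0)):
            out[nm] = nerf(out["C5'"], out["O5'"], out["P"], 1.48,
                           np.radians(109.0), a + off)
    return out


def _junction_residual(prev, cur, p):
    """9-vector: where residue `cur`'s P/O5'/C5' sit versus ideal extension
    of residue `prev`'s C4'-C3'-O3' frame with A-form crossing torsions."""
    P_t = nerf(prev["C4'"], prev["C3'"], prev["O3'"], _B["O3'-P"],
               np.radians(_B["C3'-O3'-P"]), np.radians(p["epsilon"]))
    O5_t = nerf(prev["C3'"], prev["O3'"], P_t, _B["P-O5'"],
                np.radians(_B["O3'-P-O5'"]), np.radians(p["zeta"]))
    C5_t = nerf(prev["O3'"], P_t, O5_t,
                np.linalg.norm(cur["C5'"] - cur["O5'"]),
                np.radians(_B["P-O5'-C5'"]), np.radians(p["alpha"]))
    return np.concatenate([cur["P"] - P_t, cur["O5'"] - O5_t,
                           cur["C5'"] - C5_t])


# ---------------------------------------------------------------------------
# helix calibration

_PARAM_NAMES = ["twist", "rise", "dx", "incl", "chi", "gamma", "beta", "tau"]
_PARAM_X0 = np.array([32.7, 2.81, -4.4, 17.0, -158.0, 54.0, 178.0,
                      TAU_C3_ENDO])
# box bounds keeping the calibration in chemically sane territory
# (anti glycosidic angles, north-ish puckers, non-degenerate rise)
_PARAM_LO = np.array([-60.0, -7.0, -8.0, -45.0, -200.0, -110.0, 100.0,
                      -168.0])
_PARAM_HI = np.array([60.0, 7.0, 8.0, 45.0, -100.0, 110.0, 260.0, -115.0])
_CAL_STARTS = [
    np.array([32.7, 2.81, -4.4, 17.0, -158.0, 54.0, 178.0, TAU_C3_ENDO]),
    np.array([-32.7, -2.81, -4.4, 17.0, -158.0, 54.0, 178.0, TAU_C3_ENDO]),
    np.array([-23.0, 5.0, 0.0, 0.0, -130.0, -59.0, 171.0, -160.0]),
]


def _stem_residues(seq, stem, params):
    """Place the stem residues of both strands; returns dict chain_pos ->
    (letter, atom dict).  chain positions are 0-based."""
    n = len(seq)
    tw = np.radians(params["twist"])
    rise = params["rise"]
    Q = rotation_matrix([1.0, 0.0, 0.0], np.radians(params["incl"]))
    shift = np.array([params["dx"], 0.0, 0.0])
    out = {}
    tor = {"chi": params["chi"], "gamma": params["gamma"],
           "beta": params["beta"], "alpha": AFORM["alpha"],
           "tau": params.get("tau", TAU_C3_ENDO)}
    for j in range(stem):
        b1, b2 = seq[j], seq[n - 1 - j]
        c1, c2 = _pair_coords(b1, b2, params.get("y_c1", _Y_C1))
        Rz = rotation_matrix([0.0, 0.0, 1.0], j * tw)
        t = np.array([0.0, 0.0, j * rise])
        for side, cc, pos in ((1, c1, j), (2, c2, n - 1 - j)):
            world = {nm: ((p + shift) @ Q.T) @ Rz.T + t
                     for nm, p in cc.items()}
            res = _build_residue(world, seq[pos], tor, first=(pos == 0))
            out[pos] = (seq[pos], res)
    return out


def _junction_quality(prev, cur):
    """(O3'-P bond error A, zeta deviation deg, alpha deviation deg)."""
    P, O3 = cur["P"], prev["O3'"]
    zet = np.degrees(dihedral(prev["C3'"], O3, P, cur["O5'"]))
    alp = np.degrees(dihedral(O3, P, cur["O5'"], cur["C5'"]))
    wd = lambda v, t: float(np.degrees(wrap_angle(np.radians(v - t))))
    return (float(np.linalg.norm(P - O3) - _B["O3'-P"]),
            wd(zet, AFORM["zeta"]), wd(alp, AFORM["alpha"]))


def _junction_cost(prev, cur):
    """Weighted residual: hard bond geometry, soft crossing torsions.

    The O3'-P bond length and flanking angles are weighted heavily; the
    zeta/alpha crossing torsions are pulled toward A-form values; epsilon is
    left nearly free (it is the compliant degree of freedom absorbing the
    idealized covalent geometry).
    """
    from .geometry import bond_angle

    P, O3 = cur["P"], prev["O3'"]
    out = [25.0 * (np.linalg.norm(P - O3) - _B["O3'-P"])]
    out.append(0.3 * (np.degrees(bond_angle(prev["C3'"], O3, P)) -
                      _B["C3'-O3'-P"]))
    out.append(0.3 * (np.degrees(bond_angle(O3, P, cur["O5'"])) -
                      _B["O3'-P-O5'"]))
    eps = np.degrees(dihedral(prev["C4'"], prev["C3'"], O3, P))
    zet = np.degrees(dihedral(prev["C3'"], O3, P, cur["O5'"]))
    alp = np.degrees(dihedral(O3, P, cur["O5'"], cur["C5'"]))
    wd = lambda v, t: np.degrees(wrap_angle(np.radians(v - t)))
    out.append(0.05 * wd(eps, AFORM["epsilon"]))
    out.append(0.8 * wd(zet, AFORM["zeta"]))
    out.append(0.8 * wd(alp, AFORM["alpha"]))
    return np.asarray(out)


def _stem_junction_pairs(seq, stem, placed):
    n = len(seq)
    out = []
    for j in range(stem - 1):
        # strand 1: chain position j+1 follows j; strand 2 runs antiparallel,
        # so chain position n-1-j (level j) follows n-2-j (level j+1)
        out.append((placed[j][1], placed[j + 1][1]))
        out.append((placed[n - 2 - j][1], placed[n - 1 - j][1]))
    return out


_CAL_MEMO: dict = {}


def calibrate_helix(seq, stem, max_levels=4):
    """Fit the pair-stacking parameters so consecutive stem residues connect
    through a near-ideal O3'-P bond with A-form-like zeta/alpha crossing
    torsions.  Deterministic; memoized per stem sequence.

    Returns (params dict, worst junction quality tuple).
    """
    levels = min(stem, max_levels)
    n = len(seq)
    window = seq[:levels] + seq[n - levels:]
    key = (window, levels)
    if key in _CAL_MEMO:
        return _CAL_MEMO[key]
    if levels < 2:
        params = dict(zip(_PARAM_NAMES, _PARAM_X0))
        out = (params, (0.0, 0.0, 0.0))
        _CAL_MEMO[key] = out
        return out

    def resid(x):
        params = dict(zip(_PARAM_NAMES, x))
        try:
            placed = _stem_residues(window, levels, params)
            rs = [_junction_cost(p, c)
                  for p, c in _stem_junction_pairs(window, levels, placed)]
        except ValueError:
            return np.full(6 * 2 * (levels - 1) + 4, 1e3)
        # weak priors: near-A-form rise magnitude, anti chi, north pucker,
        # and a barrier against degenerate (overlapping) stacking
        prior = np.array([0.3 * (abs(x[1]) - 2.81),
                          0.05 * (x[4] + 158.0),
                          0.05 * (x[7] + 154.0),
                          5.0 * max(0.0, 2.0 - abs(x[1]))])
        return np.concatenate(rs + [prior])

    best = None
    for x0 in _CAL_STARTS:
        sol = least_squares(resid, x0, bounds=(_PARAM_LO, _PARAM_HI),
                            method="trf", xtol=1e-12, ftol=1e-12,
                            max_nfev=2500)
        cost = float(np.linalg.norm(sol.fun))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
        if cost < 4.0:          # a junction-closing basin; stop searching
            break
    params = dict(zip(_PARAM_NAMES, best[1]))
    placed = _stem_residues(window, levels, params)
    quals = [_junction_quality(p, c)
             for p, c in _stem_junction_pairs(window, levels, placed)]
    worst = tuple(float(np.max(np.abs([q[i] for q in quals])))
                  for i in range(3))
    out = (params, worst)
    _CAL_MEMO[key] = out
    return out


# ---------------------------------------------------------------------------
# loop construction and closure

_LOOP_BONDS = [("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"), ("C3'", "O3'")]


def _grow_loop(prev_res, letters, torsion_draw):
    """NeRF-grow loop residues 5'->3' from the last strand-1 stem residue."""
    residues = []
    prev = prev_res
    for letter in letters:
        t = torsion_draw()
        P = nerf(prev["C4'"], prev["C3'"], prev["O3'"], _B["O3'-P"],
                 np.radians(_B["C3'-O3'-P"]), np.radians(t["epsilon"]))
        O5 = nerf(prev["C3'"], prev["O3'"], P, _B["P-O5'"],
                  np.radians(_B["O3'-P-O5'"]), np.radians(t["zeta"]))
        C5 = nerf(prev["O3'"], P, O5, _B["O5'-C5'"],
                  np.radians(_B["P-O5'-C5'"]), np.radians(t["alpha"]))
        C4 = nerf(P, O5, C5, _B["C5'-C4'"],
                  np.radians(_B["C4'-C5'-O5'"]), np.radians(t["beta"]))
        # place the ribose so its C4'/C5' anchors match, honoring gamma
        res = _loop_residue(letter, P, O5, C5, C4, t)
        residues.append((letter, res))
        prev = res
    return residues


def _loop_residue(letter, P, O5, C5, C4, t):
    tpl = pucker.ribose_template(t["tau"])
    # rigidly place the template: C4' -> C4, C4'->C5' direction -> C4->C5
    d_t = unit(tpl["C5'"] - tpl["C4'"])
    d_w = unit(C5 - C4)
    axis = np.cross(d_t, d_w)
    if np.linalg.norm(axis) < 1e-10:
        R0 = np.eye(3)
    else:
        R0 = rotation_matrix(axis, np.arccos(np.clip(np.dot(d_t, d_w),
                                                     -1.0, 1.0)))
    placed = {nm: (p - tpl["C4'"]) @ R0.T + C4 for nm, p in tpl.items()}
    cur = np.degrees(dihedral(O5, C5, C4, placed["C3'"]))
    Rg = rotation_matrix(C4 - C5, np.radians(t["gamma"] - cur))
    placed = {nm: (p - C4) @ Rg.T + C4 for nm, p in placed.items()}

    out = {"P": P, "O5'": O5, "C5'": C5}
    for nm in ("C1'", "C2'", "C3'", "C4'", "O4'", "H1'", "H2'", "H3'",
               "H4'", "O2'", "HO2'", "O3'"):
        out[nm] = placed[nm]
    for nm, off in (("OP1", 2.0 * np.pi / 3.0), ("OP2", -2.0 * np.pi / 3.0)):
        out[nm] = nerf(C5, O5, P, 1.48, np.radians(109.0),
                       np.radians(t["alpha"]) + off)
    for nm, off in (("H5'", 2.0 * np.pi / 3.0), ("H5''", -2.0 * np.pi / 3.0)):
        out[nm] = nerf(out["C3'"], C4, C5, 1.09, np.radians(109.5),
                       np.radians(t["gamma"]) + off)
    # base via chi about the glycosidic bond
    base = _base_on_sugar(letter, placed, t["chi"])
    out.update(base)
    return out


def _base_on_sugar(letter, sugar, chi_deg):
    raw = chem.ideal_base_coords(letter)
    n_name = chem.GLYCOSIDIC_N[letter]
    nn = raw[n_name]
    nb1, nb2 = chem.GLYC_RING_NEIGHBORS[letter]
    bis = -unit(unit(raw[nb1] - nn) + unit(raw[nb2] - nn))
    c1_t = nn + chem._C1P_N * bis
    d_t = unit(raw[n_name] - c1_t)
    c1_w = sugar["C1'"]
    d_w = unit(sugar["NGLY"] - c1_w)
    axis = np.cross(d_t, d_w)
    if np.linalg.norm(axis) < 1e-10:
        R0 = np.eye(3)
    else:
        R0 = rotation_matrix(axis, np.arccos(np.clip(np.dot(d_t, d_w),
                                                     -1.0, 1.0)))
    placed = {nm: (p - c1_t) @ R0.T + c1_w for nm, p in raw.items()}
    ref = placed[chem.CHI_REF_ATOM[letter]]
    cur = np.degrees(dihedral(sugar["O4'"], c1_w, placed[n_name], ref))
    Rc = rotation_matrix(placed[n_name] - c1_w, np.radians(chi_deg - cur))
    return {nm: (p - c1_w) @ Rc.T + c1_w
            for nm, p in placed.items() if nm != "C1'"}


def _close_loop(loop_residues, last_stem1, p_target, tol=0.01, max_iter=200):
    """Adjust loop backbone torsions so the chain delivers its outgoing P
    onto `p_target`.  Damped pseudoinverse iteration; returns True on
    success (mutates loop_residues in place)."""
    last = loop_residues[-1][1]
    phat = nerf(last["C4'"], last["C3'"], last["O3'"], _B["O3'-P"],
                np.radians(_B["C3'-O3'-P"]), np.radians(AFORM["epsilon"]))

    bonds = []
    for ri in range(len(loop_residues)):
        for bond in _LOOP_BONDS:
            bonds.append((ri, bond))
        if ri + 1 < len(loop_residues):
            bonds.append((ri, ("O3'", "P+")))

    lam = 0.5
    r = p_target - phat
    for _ in range(max_iter):
        if np.linalg.norm(r) < tol:
            return True
        J = np.zeros((3, len(bonds)))
        for k, (ri, bond) in enumerate(bonds):
            res = loop_residues[ri][1]
            if bond == ("O3'", "P+"):
                o, ax = res["O3'"], loop_residues[ri + 1][1]["P"] - res["O3'"]
            else:
                o, ax = res[bond[0]], res[bond[1]] - res[bond[0]]
            J[:, k] = np.cross(unit(ax), phat - o)
        dphi = lam * np.linalg.pinv(J, rcond=1e-8) @ r
        np.clip(dphi, -0.3, 0.3, out=dphi)
        phat_new, backup = _apply_loop_rotations(loop_residues, bonds, dphi,
                                                 phat)
        r_new = p_target - phat_new
        if np.linalg.norm(r_new) <= np.linalg.norm(r) + 1e-12:
            phat, r = phat_new, r_new
            lam = min(1.0, lam * 1.5)
        else:
            for (ri, nm), pos in backup.items():
                loop_residues[ri][1][nm] = pos
            lam *= 0.5
            if lam < 1e-4:
                return False
    return np.linalg.norm(r) < tol


def _apply_loop_rotations(loop_residues, bonds, dphi, phat):
    backup = {}
    for k, (ri, bond) in enumerate(bonds):
        if abs(dphi[k]) < 1e-14:
            continue
        res = loop_residues[ri][1]
        if bond == ("O3'", "P+"):
            o, ax = res["O3'"], loop_residues[ri + 1][1]["P"] - res["O3'"]
            moved = [(rj, nm) for rj in range(ri + 1, len(loop_residues))
                     for nm in loop_residues[rj][1]]
        else:
            o, ax = res[bond[0]], res[bond[1]] - res[bond[0]]
            moved = _movable_cache(loop_residues, ri, bond)
        R = rotation_matrix(ax, dphi[k])
        for rj, nm in moved:
            key = (rj, nm)
            if key not in backup:
                backup[key] = loop_residues[rj][1][nm].copy()
            loop_residues[rj][1][nm] = \
                (loop_residues[rj][1][nm] - o) @ R.T + o
        phat = (phat - o) @ R.T + o
    return phat, backup


def _movable_cache(loop_residues, ri, bond):
    skip_first = {"P": {"P", "OP1", "OP2"},
                  "O5'": {"P", "OP1", "OP2", "O5'"},
                  "C5'": {"P", "OP1", "OP2", "O5'", "C5'", "H5'", "H5''"}}
    a, _bname = bond
    moved = []
    if a == "C3'":
        moved.append((ri, "O3'"))
    else:
        for nm in loop_residues[ri][1]:
            if nm not in skip_first[a]:
                moved.append((ri, nm))
    for rj in range(ri + 1, len(loop_residues)):
        for nm in loop_residues[rj][1]:
            moved.append((rj, nm))
    return moved


# ---------------------------------------------------------------------------
# assembly

def _fix_phosphate_oxygens(residues):
    """Re-place OP1/OP2 tetrahedrally from the final O3'(i-1)-P-O5' geometry.

    During loop growth and reclosure the incoming O3' direction changes, so
    the free phosphate oxygens are rebuilt once the backbone is final.
    """
    for i in range(1, len(residues)):
        res = residues[i][1]
        prev = residues[i - 1][1]
        if "P" not in res:
            continue
        P = res["P"]
        u1 = unit(res["O5'"] - P)
        u2 = unit(prev["O3'"] - P)
        b = -unit(u1 + u2)
        nn = unit(np.cross(u1, u2))
        phi = np.radians(59.9)
        res["OP1"] = P + 1.48 * (b * np.cos(phi) + nn * np.sin(phi))
        res["OP2"] = P + 1.48 * (b * np.cos(phi) - nn * np.sin(phi))


_CHI_SWEEP = np.arange(-180.0, 180.0, 7.5)


def _declash_loop_bases(residues, loop_lo, loop_hi, vdw_scale=0.5,
                        passes=3):
    """Rotate loop bases about their glycosidic bonds to relieve overlaps.

    Loop chi angles are free parameters of the fixture; each loop base is
    swept over chi candidates and set to the least-clashing orientation.
    Deterministic.  Mutates `residues` in place.
    """
    def radius(nm):
        return chem.VDW_RADII["H" if nm.startswith("H") else nm[0]]

    def overlap_count(ri, base_names, coords_map):
        cnt = 0
        own_sugar_ok = {"C1'", "H1'", "O4'", "C2'", "H2'", "C3'"}
        for nm in base_names:
            p = coords_map[nm]
            r1 = radius(nm)
            for rj, (_l2, res2) in enumerate(residues):
                for nm2, p2 in res2.items():
                    if rj == ri and (nm2 in own_sugar_ok or
                                     nm2 in base_names):
                        continue
                    if rj == ri and nm2 == "C1'":
                        continue
                    thr = vdw_scale * (r1 + radius(nm2))
                    d = p - p2
                    if abs(d[0]) < thr and d @ d < thr * thr:
                        cnt += 1
        return cnt

    for _ in range(passes):
        changed = False
        for ri in range(loop_lo, loop_hi):
            letter, res = residues[ri]
            base_names = chem.base_atom_names(letter)
            cur = overlap_count(ri, base_names, res)
            if cur == 0:
                continue
            sugar = {nm: res[nm] for nm in res if nm not in base_names}
            sugar["NGLY"] = res[chem.GLYCOSIDIC_N[letter]]
            best = (cur, None)
            for chi in _CHI_SWEEP:
                cand = _base_on_sugar(letter, sugar, float(chi))
                cand_full = dict(sugar)
                cand_full.update(cand)
                score = overlap_count(ri, base_names, cand_full)
                if score < best[0]:
                    best = (score, cand)
                    if score == 0:
                        break
            if best[1] is not None:
                res.update(best[1])
                changed = True
        if not changed:
            break


def _pdb_text(seq, residues):
    """Hand-formatted single-model PDB text in template atom order."""
    lines = []
    serial = 1
    nres = len(seq)
    for ri, (letter, res) in enumerate(residues, start=1):
        names = [nm for nm, _el in chem.SUGAR_ATOMS if nm in res]
        if "HO5'" in res:
            names.append("HO5'")
        if "HO3'" in res:
            names.append("HO3'")
        names += [nm for nm in chem.base_atom_names(letter)]
        for nm in names:
            x, y, z = res[nm]
            el = "H" if nm.startswith("H") else nm[0]
            name_f = nm if len(nm) >= 4 else f" {nm:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_f:<4s} {letter:>3s} A{ri:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_hairpin(spec: HairpinSpec | None = None, rng=None,
                 max_attempts: int = 60) -> HairpinResult:
    """Build an idealized WC-paired hairpin; deterministic under a seed."""
    spec = spec or HairpinSpec()
    if not hasattr(rng, "normal"):
        rng = np.random.default_rng(rng)
    seq, stem, loop = spec.sequence, spec.stem, spec.loop
    n = spec.length

    params, junc_q = calibrate_helix(seq, stem)
    placed = _stem_residues(seq, stem, params)

    # loop torsions start from A-form values and the requested pucker
    base_t = {"epsilon": AFORM["epsilon"], "zeta": AFORM["zeta"],
              "alpha": AFORM["alpha"], "beta": AFORM["beta"],
              "gamma": AFORM["gamma"], "chi": AFORM["chi"],
              "tau": spec.tau}
    # 3' stem entry point: P of the first strand-2 residue (chain pos n-stem)
    p_target = placed[n - stem][1]["P"]

    loop_letters = list(seq[stem:stem + loop])
    last_ok = None
    for attempt in range(max_attempts):
        def draw():
            t = dict(base_t)
            sigma = max(spec.noise_sigma, 45.0 * attempt / max_attempts)
            if attempt or spec.noise_sigma:
                for k in ("epsilon", "zeta", "alpha", "beta", "gamma", "chi"):
                    t[k] = t[k] + rng.normal(0.0, max(sigma, 1e-9))
            return t

        loop_res = _grow_loop(placed[stem - 1][1], loop_letters, draw)
        if _close_loop(loop_res, placed[stem - 1][1], p_target):
            residues = []
            for i in range(n):
                if stem <= i < stem + loop:
                    residues.append(loop_res[i - stem])
                else:
                    residues.append((seq[i], dict(placed[i][1])))
            _fix_phosphate_oxygens(residues)
            _declash_loop_bases(residues, stem, stem + loop)
            # terminal hydrogens
            r_last = residues[-1][1]
            r_last["HO3'"] = nerf(r_last["C4'"], r_last["C3'"],
                                  r_last["O3'"], 0.96, np.radians(108.0),
                                  np.pi)
            text = _pdb_text(seq, residues)
            with tempfile.NamedTemporaryFile("w", suffix=".pdb",
                                             delete=False) as fh:
                fh.write(text)
                path = fh.name
            topo, coords = read_pdb(path)
            from .sampler import clash_check
            clash, _pair = clash_check(topo, coords)
            if not clash:
                achieved = dict(params)
                achieved["junction_bond_err"] = junc_q[0]
                achieved["junction_zeta_err"] = junc_q[1]
                achieved["junction_alpha_err"] = junc_q[2]
                return HairpinResult(spec, topo, coords, spec.pair_list(),
                                     text, achieved)
            last_ok = "clash"
        else:
            last_ok = "closure"
    raise RuntimeError(f"hairpin generation failed ({last_ok}) after "
                       f"{max_attempts} attempts")


# ---------------------------------------------------------------------------
# RDC fixtures

def make_rdc_fixture(n_candidates=100, k_bonds=12, true_weights=(0.4, 0.5),
                     noise_sigma=0.0, rng=None, spread=3.0):
    """Synthetic candidate RDC rows plus a (noisy) mixture observation.

    Back-calculated RDC sets from one molecule share a dominant alignment
    signature, with conformer-to-conformer deviations smaller than the
    couplings themselves; the fixture mimics this as a common mean pattern
    (sd 10 Hz) plus per-candidate deviations of sd `spread` Hz.  Returns
    (observed (k,), candidates (s, k), labels, true weight vector).
    """
    rng = np.random.default_rng(rng) if not hasattr(rng, "normal") else rng
    w = np.zeros(n_candidates)
    tw = np.asarray(true_weights, dtype=float)
    if tw.sum() > 1.0 + 1e-9:
        raise ValueError("true weights must sum to at most 1")
    w[: len(tw)] = tw
    mean_pattern = rng.normal(0.0, 10.0, size=k_bonds)
    cand = mean_pattern + rng.normal(0.0, spread,
                                     size=(n_candidates, k_bonds))
    obs = w @ cand + rng.normal(0.0, noise_sigma, size=k_bonds)
    labels = [(30 + i // 2, "C1'" if i % 2 == 0 else "C8", "H1'" if i % 2 == 0
               else "H8") for i in range(k_bonds)]
    return obs, cand, labels, w
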