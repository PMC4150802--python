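"""Hydrogen-bond closure constraints: cycle Jacobian and null-space moves.

Each Watson-Crick pair contributes one kinematic cycle with six constraint
rows: the instantaneous position of the donor hydrogen and of the acceptor
atom, each expressed as the difference between the motion transmitted along
the two tree branches of the cycle.  Because both constrained endpoints lie
on the hydrogen-bond axis, rotation of one branch about that axis survives,
so a generic cycle removes five degrees of freedom and the null space has
dimension n - 5m.

A null-space move projects a trial torsion vector with N N^T (N from the
SVD of J), caps the largest component, applies the move, and then *verifies*
that the relative displacement of the constrained endpoints stayed below a
closure tolerance -- the linearization guarantee is checked, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .geometry import kabsch, unit
from .kinematics import Conformation, KinematicTree, deform_ribose

_FD_TAU_STEP = 1e-5      # radians, central difference for tau columns


class ClosureViolationError(RuntimeError):
    """A move displaced a constrained hydrogen-bond endpoint too far."""

    def __init__(self, drift):
        super().__init__(f"hydrogen-bond closure violated: drift {drift:.4f} A")
        self.drift = drift


@dataclass
class Cycle:
    pair: object
    donor: int
    hydrogen: int
    acceptor: int
    h_body: int
    a_body: int
    s_edge: np.ndarray          # +1 h-branch, -1 a-branch, 0 otherwise
    tau_exit: dict              # tau dof_index -> (exit_edge_h, exit_edge_a)


class CycleSet(list):
    """List of cycles; keeps the tree it was built against."""

    def __init__(self, cycles, tree):
        super().__init__(cycles)
        self.tree = tree


def _root_path(tree: KinematicTree, body: int):
    """Edges from `body` up to the root, nearest first."""
    parent_edge = getattr(tree, "_parent_edge", None)
    if parent_edge is None:
        parent_edge = {e.child_body: e for e in tree.edges}
        tree._parent_edge = parent_edge
    path = []
    while body != tree.root:
        e = parent_edge[body]
        path.append(e)
        body = e.parent_body
    return path


def build_cycles(tree: KinematicTree, pairs) -> CycleSet:
    """One kinematic cycle per WC pair (donor-H and acceptor endpoints)."""
    topo = tree.topology
    cycles = []
    for pair in pairs:
        for d_idx, h_idx, a_idx in pair.resolve(topo):
            hb = int(tree.body_of[h_idx])
            ab = int(tree.body_of[a_idx])
            path_h = _root_path(tree, hb)
            path_a = _root_path(tree, ab)
            set_h = {e.dof_index for e in path_h}
            set_a = {e.dof_index for e in path_a}
            s = np.zeros(tree.n_edges)
            for k in set_h - set_a:
                s[k] = 1.0
            for k in set_a - set_h:
                s[k] = -1.0
            tau_exit = {}
            for t in tree.tau_dofs:
                eh = next((e for e in path_h if e.parent_body == t.body), None)
                ea = next((e for e in path_a if e.parent_body == t.body), None)
                if eh is not None or ea is not None:
                    tau_exit[t.dof_index] = (eh, ea)
            cycles.append(Cycle(pair, d_idx, h_idx, a_idx, hb, ab, s, tau_exit))
    return CycleSet(cycles, tree)


def compute_jacobian(tree: KinematicTree, conformation: Conformation,
                     cycles) -> np.ndarray:
    """6m x n cycle Jacobian at the current conformation.

    Edge-torsion columns are analytic (axis cross lever-arm, signed by
    branch); tau columns use central finite differences of the local ribose
    re-embedding, the documented fallback for the pucker chain rule.
    """
    from . import pucker

    coords = conformation.coords
    n = tree.n
    J = np.zeros((6 * len(cycles), n))
    tau_by_dof = {t.dof_index: t for t in tree.tau_dofs}
    step_deg = np.degrees(_FD_TAU_STEP)
    tf_cache = {}

    taus = conformation.taus()
    tau_order = {t.dof_index: i for i, t in enumerate(tree.tau_dofs)}

    def tau_tf(t):
        if t.dof_index not in tf_cache:
            cur = float(taus[tau_order[t.dof_index]])
            plus = deform_ribose(coords, t, cur + step_deg, cur_tau_deg=cur)[2]
            minus = deform_ribose(coords, t, cur - step_deg,
                                  cur_tau_deg=cur)[2]
            tf_cache[t.dof_index] = (plus, minus)
        return tf_cache[t.dof_index]

    def tau_deriv(t, edge, point):
        plus, minus = tau_tf(t)
        Rp, tp = plus[edge.dof_index]
        Rm, tm = minus[edge.dof_index]
        return ((point @ Rp.T + tp) - (point @ Rm.T + tm)) / \
            (2.0 * _FD_TAU_STEP)

    for ci, cyc in enumerate(cycles):
        h = coords[cyc.hydrogen]
        a = coords[cyc.acceptor]
        rows = slice(6 * ci, 6 * ci + 6)
        for e in tree.edges:
            s = cyc.s_edge[e.dof_index]
            if s == 0.0:
                continue
            # a +d change of the IUPAC dihedral rotates the subtree by -d
            # about the bond axis
            axis = unit(coords[e.ca] - coords[e.pa]) * (-e.sign)
            J[rows.start:rows.start + 3, e.dof_index] = \
                s * np.cross(axis, h - coords[e.pa])
            J[rows.start + 3:rows.stop, e.dof_index] = \
                -s * np.cross(axis, a - coords[e.pa])
        for k, (eh, ea) in cyc.tau_exit.items():
            t = tau_by_dof[k]
            # c_h = h - M_a(h_ref); c_a = a - M_h(a_ref)
            dh = tau_deriv(t, eh, h) if eh is not None else 0.0
            dh_via_a = tau_deriv(t, ea, h) if ea is not None else 0.0
            da = tau_deriv(t, ea, a) if ea is not None else 0.0
            da_via_h = tau_deriv(t, eh, a) if eh is not None else 0.0
            J[rows.start:rows.start + 3, k] = dh - dh_via_a
            J[rows.start + 3:rows.stop, k] = da - da_via_h
    return J


def nullspace_basis(J: np.ndarray, sv_tol: float = 1e-6) -> np.ndarray:
    """Orthonormal null-space basis N (n x d) from the right singular
    vectors of J; JN ~ 0 and N^T N = I."""
    n = J.shape[1]
    if J.shape[0] == 0 or not np.any(J):
        return np.eye(n)
    U, S, Vt = scipy.linalg.svd(J, full_matrices=True)
    smax = S[0] if len(S) else 0.0
    rank = int(np.sum(S > sv_tol * max(smax, 1.0)))
    return Vt[rank:].T


def body_transform(tree, ref_coords, new_coords, body: int):
    """Best-fit rigid transform of one body between two conformations."""
    idx = sorted(tree.bodies[body].atom_indices)
    if len(idx) < 3:
        # extend with bonded neighbors to make the frame well defined
        topo = tree.topology
        extra = sorted({nb for i in idx for nb in topo.neighbors[i]})
        idx = sorted(set(idx) | set(extra))
    R, t, _ = kabsch(ref_coords[idx], new_coords[idx])
    return R, t


def closure_drift(ref: Conformation, new: Conformation, cycles) -> float:
    """Largest relative endpoint displacement over all cycles, Angstrom.

    For each cycle the donor hydrogen is re-expressed in the acceptor body's
    moving frame (and vice versa); a perfectly maintained hydrogen bond
    yields zero.
    """
    tree = ref.tree
    worst = 0.0
    for cyc in cycles:
        Ra, ta = body_transform(tree, ref.coords, new.coords, cyc.a_body)
        Rh, th = body_transform(tree, ref.coords, new.coords, cyc.h_body)
        c_h = new.coords[cyc.hydrogen] - (ref.coords[cyc.hydrogen] @ Ra.T + ta)
        c_a = new.coords[cyc.acceptor] - (ref.coords[cyc.acceptor] @ Rh.T + th)
        worst = max(worst, float(np.linalg.norm(c_h)),
                    float(np.linalg.norm(c_a)))
    return worst


def nullspace_perturb(conformation: Conformation, cycles, trial,
                      max_step: float = 0.1, eps_closure: float = 0.05,
                      sv_tol: float = 1e-6,
                      basis: np.ndarray | None = None) -> Conformation:
    """Apply a null-space-projected torsion move and verify closure.

    The projected move is rescaled so its largest component does not exceed
    `max_step` radians.  Raises :class:`ClosureViolationError` when any
    constrained endpoint drifts more than `eps_closure` Angstrom.
    """
    tree = conformation.tree
    trial = np.asarray(trial, dtype=float)
    if trial.shape != (tree.n,):
        raise ValueError(f"trial vector must have length {tree.n}")
    if basis is None:
        cached = getattr(conformation, "_ns_cache", None)
        key = (id(cycles), sv_tol)
        if cached is not None and cached[0] == key:
            basis = cached[1]
        else:
            J = compute_jacobian(tree, conformation, cycles)
            basis = nullspace_basis(J, sv_tol)
            conformation._ns_cache = (key, basis)
    delta = basis @ (basis.T @ trial)
    peak = np.max(np.abs(delta)) if delta.size else 0.0
    if peak > max_step:
        delta = delta * (max_step / peak)
    new = conformation.apply(delta)
    if len(cycles):
        drift = closure_drift(conformation, new, cycles)
        if drift > eps_closure:
            raise ClosureViolationError(drift)
    return new
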