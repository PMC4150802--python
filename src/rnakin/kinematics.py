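"""Rigid-body spanning tree and torsional forward kinematics.

The molecule is partitioned into rigid bodies (largest subunits without
internal rotatable bonds); a rooted directed spanning tree over the bodies
carries one torsional degree of freedom per edge, plus one pucker coordinate
tau per ribose.  Hydrogen bonds are *not* tree edges; they close kinematic
cycles handled in :mod:`rnakin.constraints`.

Conformations are coordinate-primary: a Conformation owns Cartesian
coordinates, and degrees of freedom are measured from them.  Moves are
applied incrementally (rotations about current bond axes, ribose re-embedding
for tau), which keeps the model well-defined even when a rebuilt backbone
carries a little residual strain at the resealed O3'-P junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import chem, pucker
from .geometry import (Frame, dihedral, rotate_about_line, transform_between,
                       wrap_angle)
from .structure_io import Topology

TORSION_LABELS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


@dataclass
class RigidBody:
    body_id: int
    atom_indices: frozenset


@dataclass
class Edge:
    dof_index: int
    parent_body: int
    child_body: int
    pa: int                 # bond atom on the parent side
    ca: int                 # bond atom on the child side
    label: str | None
    quad: tuple             # 4 atom indices; dihedral convention atoms
    sign: float             # +1 if quad middle == (pa, ca), else -1
    subtree: np.ndarray = None  # atom indices moved by this DOF


@dataclass
class TauDof:
    dof_index: int
    residue: int
    body: int
    ring: tuple             # atom indices in pucker.RING_ORDER order
    sub_anchor: dict        # non-ring body atom -> ring position (0..4)
    child_edges: list       # Edge objects leaving the ribose body
    in_edge: "Edge | None"


def build_rigid_bodies(topology: Topology):
    """Union-find merge over non-rotatable bonds and single-neighbor atoms."""
    n = len(topology.atoms)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for b in topology.bonds:
        if not b.rotatable:
            union(b.i, b.j)
    for i in range(n):
        if len(topology.neighbors[i]) == 1:
            union(i, topology.neighbors[i][0])

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    bodies = []
    for bid, root in enumerate(sorted(groups)):
        bodies.append(RigidBody(bid, frozenset(groups[root])))
    return bodies


class KinematicTree:
    """Rooted directed spanning tree of rigid bodies with torsional DOFs."""

    def __init__(self, bodies, topology: Topology, root_choice="5p"):
        self.topology = topology
        self.bodies = bodies
        natoms = len(topology.atoms)
        self.body_of = np.empty(natoms, dtype=int)
        for b in bodies:
            for i in b.atom_indices:
                self.body_of[i] = b.body_id

        # body graph over rotatable bonds that actually join two bodies
        G = nx.Graph()
        G.add_nodes_from(b.body_id for b in bodies)
        bond_for = {}
        for bd in topology.rotatable_bonds():
            bi, bj = self.body_of[bd.i], self.body_of[bd.j]
            if bi == bj:
                continue            # degenerate DOF (e.g. bare terminal O3')
            key = (min(bi, bj), max(bi, bj))
            if key not in bond_for:
                bond_for[key] = bd
                G.add_edge(bi, bj)
        if not nx.is_connected(G):
            raise ValueError("rigid-body graph is disconnected")

        self.root = self._root_body(root_choice)
        self.edges: list[Edge] = []
        self.children = {b.body_id: [] for b in bodies}
        order = nx.bfs_edges(G, self.root,
                             sort_neighbors=lambda nbrs: sorted(nbrs))
        for k, (pb, cb) in enumerate(order):
            bd = bond_for[(min(pb, cb), max(pb, cb))]
            pa, ca = bd.i, bd.j
            if self.body_of[pa] != pb:
                pa, ca = ca, pa
            e = Edge(k, pb, cb, pa, ca, bd.label, None, 1.0)
            self.edges.append(e)
            self.children[pb].append(e)

        self._compute_subtrees()
        for e in self.edges:
            e.quad, e.sign = self._resolve_quad(e)
        self.tau_dofs = self._find_riboses()
        self.n_edges = len(self.edges)
        self.n = self.n_edges + len(self.tau_dofs)
        self.dof_labels = [e.label or "bond" for e in self.edges] + \
                          ["tau"] * len(self.tau_dofs)
        self.dof_residue = [topology.residue_of(e.ca) for e in self.edges] + \
                           [t.residue for t in self.tau_dofs]

    # ------------------------------------------------------------------
    def _root_body(self, root_choice):
        topo = self.topology
        if root_choice == "5p":
            return int(self.body_of[0])
        if root_choice == "3p":
            return int(self.body_of[topo.atom_index(topo.n_residues, "O3'")])
        return int(root_choice)

    def _compute_subtrees(self):
        body_atoms = {b.body_id: sorted(b.atom_indices) for b in self.bodies}
        # edges are in BFS order, so reversed order is bottom-up
        for e in reversed(self.edges):
            sub_atoms = list(body_atoms[e.child_body])
            for ce in self.children[e.child_body]:
                sub_atoms.extend(ce.subtree.tolist())
            e.subtree = np.array(sorted(sub_atoms), dtype=int)

    def _resolve_quad(self, e: Edge):
        topo = self.topology
        sub = set(e.subtree.tolist())
        if e.label in chem.TORSION_DEFS or e.label == "chi":
            if e.label == "chi":
                c1 = e.pa if topo.atoms[e.pa].name == "C1'" else e.ca
                owner = topo.residue_of(c1)
                base = topo.base(owner)
                spec = ((0, "O4'"), (0, "C1'"), (0, chem.GLYCOSIDIC_N[base]),
                        (0, chem.CHI_REF_ATOM[base]))
            else:
                spec = chem.TORSION_DEFS[e.label]
                nm1 = spec[1][1]
                owner = topo.residue_of(
                    e.pa if topo.atoms[e.pa].name == nm1 else e.ca)
            idx = []
            for off, nm in spec:
                r = owner + off
                if 1 <= r <= topo.n_residues and topo.has_atom(r, nm):
                    idx.append(topo.atom_index(r, nm))
                else:
                    idx = None
                    break
            if idx and {idx[1], idx[2]} == {e.pa, e.ca} and \
                    idx[0] not in sub and idx[3] in sub:
                sign = 1.0 if (idx[1], idx[2]) == (e.pa, e.ca) else -1.0
                return tuple(idx), sign
        # generic fallback: any stator-side neighbor of pa, rotor-side of ca
        g = h = None
        for nb in sorted(self.topology.neighbors[e.pa]):
            if nb != e.ca and nb not in sub:
                g = nb
                break
        for nb in sorted(self.topology.neighbors[e.ca]):
            if nb != e.pa and nb in sub:
                h = nb
                break
        if g is None or h is None:
            raise ValueError(f"cannot build torsion quadruple for edge {e}")
        return (g, e.pa, e.ca, h), 1.0

    def _find_riboses(self):
        topo = self.topology
        out = []
        by_atom_edge = {}
        for e in self.edges:
            by_atom_edge.setdefault(e.parent_body, []).append(e)
        in_edge_of = {e.child_body: e for e in self.edges}
        for r in topo.residues:
            try:
                ring = tuple(topo.atom_index(r.index, nm)
                             for nm in pucker.RING_ORDER)
            except Exception:
                continue
            body = self.body_of[ring[0]]
            if any(self.body_of[a] != body for a in ring):
                continue            # ring split across bodies; no tau DOF
            body_atoms = self.bodies[body].atom_indices
            # anchor each non-ring body atom to the nearest ring atom by bonds
            sub_anchor = {}
            ring_set = set(ring)
            frontier = {a: ring.index(a) for a in ring}
            queue = list(ring)
            while queue:
                cur = queue.pop(0)
                for nb in topo.neighbors[cur]:
                    if nb in body_atoms and nb not in frontier:
                        frontier[nb] = frontier[cur]
                        queue.append(nb)
            for a, anchor in frontier.items():
                if a not in ring_set:
                    sub_anchor[a] = anchor
            child_edges = [e for e in self.children[body]]
            dof_index = len(self.edges) + len(out)
            out.append(TauDof(dof_index, r.index, int(body), ring,
                              sub_anchor, child_edges,
                              in_edge_of.get(int(body))))
        return out

    # ------------------------------------------------------------------
    def measure_dofs(self, coords) -> np.ndarray:
        """All DOF values in radians (edge torsions, then tau per ribose)."""
        vals = np.empty(self.n)
        for e in self.edges:
            a, b, c, d = e.quad
            vals[e.dof_index] = dihedral(coords[a], coords[b],
                                         coords[c], coords[d])
        for t in self.tau_dofs:
            ring = coords[list(t.ring)]
            vals[t.dof_index] = np.radians(pucker.measure_tau(ring))
        return vals

    def ring_coords(self, coords, residue):
        for t in self.tau_dofs:
            if t.residue == residue:
                return coords[list(t.ring)]
        raise ValueError(f"residue {residue} has no complete ribose ring")


# ---------------------------------------------------------------------------

def build_tree(bodies, topology, root_choice="5p") -> KinematicTree:
    return KinematicTree(bodies, topology, root_choice)


def make_tree(topology, root_choice="5p") -> KinematicTree:
    return build_tree(build_rigid_bodies(topology), topology, root_choice)


# ---------------------------------------------------------------------------

def _ring_cyc(i, d):
    return (i + d) % 5


def _place_embedding(coords, tau_dof: TauDof, emb):
    """Rigidly place an ideal ring embedding into the lab frame, anchored to
    the ribose's parent attachment (or least-squares for a root ribose)."""
    ring_idx = list(tau_dof.ring)
    ring_old = coords[ring_idx]
    e_in = tau_dof.in_edge
    if e_in is not None:
        pa, ca = e_in.pa, e_in.ca
        ca_pos = ring_idx.index(ca)
        # reference ring atom: the subtree-side quad atom if it is on the ring
        rr = e_in.quad[3] if e_in.quad[2] == ca else e_in.quad[0]
        if rr not in ring_idx:
            rr = ring_idx[_ring_cyc(ca_pos, -1)]
        rr_pos = ring_idx.index(rr)
        # transplant the parent atom into the embedding's local geometry
        Lo = Frame.from_points(ring_old[_ring_cyc(ca_pos, -1)],
                               ring_old[ca_pos],
                               ring_old[_ring_cyc(ca_pos, 1)])
        Ln = Frame.from_points(emb[_ring_cyc(ca_pos, -1)],
                               emb[ca_pos],
                               emb[_ring_cyc(ca_pos, 1)])
        pa_local = Ln.to_world(Lo.to_local(coords[pa]))
        Fw = Frame.from_points(coords[pa], ring_old[ca_pos], ring_old[rr_pos])
        fn = Frame.from_points(pa_local, emb[ca_pos], emb[rr_pos])
        return Fw.to_world(fn.to_local(emb))
    from .geometry import kabsch
    R, t, _ = kabsch(emb, ring_old)
    return emb @ R.T + t


def deform_ribose(coords, tau_dof: TauDof, new_tau_deg, cur_tau_deg=None):
    """Geometry update for one ribose moved to a new tau.

    The update is *relative*: ideal embeddings at the current and the new tau
    are both placed on the parent anchor, and atoms follow the map between
    them.  As new -> current the deformation tends to the identity, so small
    deviations of the actual ring from ideal geometry (e.g. PDB coordinate
    quantization) are carried along instead of being snapped away.

    Returns (new ring coords (5, 3), substituent updates {atom: pos},
    child-subtree transforms {edge.dof_index: (R, t)}).  No mutation.
    """
    ring_idx = list(tau_dof.ring)
    ring_old = coords[ring_idx]
    if cur_tau_deg is None:
        cur_tau_deg = pucker.measure_tau(ring_old)
    emb_cur = pucker.ring_local_coords(pucker.tau_to_phase(cur_tau_deg))
    emb_new = pucker.ring_local_coords(pucker.tau_to_phase(new_tau_deg))
    world_cur = _place_embedding(coords, tau_dof, emb_cur)
    world_new = _place_embedding(coords, tau_dof, emb_new)
    # ideal update plus carried-over deviation of the actual ring
    ring_new = world_new + (ring_old - world_cur)

    sub_updates = {}
    anchor_frames = {}
    for atom, anchor in tau_dof.sub_anchor.items():
        if anchor not in anchor_frames:
            Fo = Frame.from_points(world_cur[_ring_cyc(anchor, -1)],
                                   world_cur[anchor],
                                   world_cur[_ring_cyc(anchor, 1)])
            Fn = Frame.from_points(world_new[_ring_cyc(anchor, -1)],
                                   world_new[anchor],
                                   world_new[_ring_cyc(anchor, 1)])
            anchor_frames[anchor] = (Fo, Fn)
        Fo, Fn = anchor_frames[anchor]
        sub_updates[atom] = Fn.to_world(Fo.to_local(coords[atom]))

    child_tf = {}
    for ce in tau_dof.child_edges:
        ra = ce.pa                      # ring-side atom of the child bond
        ra_pos = ring_idx.index(ra)
        g = ce.quad[0] if ce.quad[1] == ra else ce.quad[3]
        if g in ring_idx:
            gp = ring_idx.index(g)
        else:
            gp = _ring_cyc(ra_pos, -1)
        third = _ring_cyc(ra_pos, 1)
        if third == gp:
            third = _ring_cyc(ra_pos, -1)
        Fo = Frame.from_points(world_cur[third], world_cur[ra_pos],
                               world_cur[gp])
        Fn = Frame.from_points(world_new[third], world_new[ra_pos],
                               world_new[gp])
        child_tf[ce.dof_index] = transform_between(Fo, Fn)
    return ring_new, sub_updates, child_tf


class Conformation:
    """Cartesian coordinates bound to a kinematic tree.

    Immutable in practice: :meth:`apply` returns a new instance.  DOF values
    are measured from coordinates on first access and cached.
    """

    def __init__(self, tree: KinematicTree, coords):
        self.tree = tree
        self.coords = np.asarray(coords, dtype=float)
        self._dofs = None
        self._taus = None               # degrees, tree.tau_dofs order

    @property
    def topology(self):
        return self.tree.topology

    def taus(self) -> np.ndarray:
        """Pucker coordinates (degrees) for all riboses, cached.

        Measured from coordinates once; carried arithmetically through
        :meth:`apply`, which sets the embedding to the requested value.
        """
        if self._taus is None:
            self._taus = np.array(
                [pucker.measure_tau(self.coords[list(t.ring)])
                 for t in self.tree.tau_dofs])
        return self._taus

    def dofs(self) -> np.ndarray:
        if self._dofs is None:
            vals = np.empty(self.tree.n)
            for e in self.tree.edges:
                a, b, c, d = e.quad
                vals[e.dof_index] = dihedral(self.coords[a], self.coords[b],
                                             self.coords[c], self.coords[d])
            vals[self.tree.n_edges:] = np.radians(self.taus())
            self._dofs = vals
        return self._dofs.copy()

    @property
    def theta(self) -> np.ndarray:
        return self.dofs()

    def tau(self, residue: int) -> float:
        """Pucker coordinate of one residue, degrees."""
        for i, t in enumerate(self.tree.tau_dofs):
            if t.residue == residue:
                return float(self.taus()[i])
        raise ValueError(f"residue {residue} has no complete ribose ring")

    def c4_coords(self) -> np.ndarray:
        return self.coords[self.topology.c4_indices()]

    def copy(self) -> "Conformation":
        c = Conformation(self.tree, self.coords.copy())
        c._dofs = None if self._dofs is None else self._dofs.copy()
        c._taus = None if self._taus is None else self._taus.copy()
        return c

    # ------------------------------------------------------------------
    def apply(self, delta, tol=1e-12) -> "Conformation":
        """Apply DOF increments (radians, length n) and return the result."""
        delta = np.asarray(delta, dtype=float)
        tree = self.tree
        if delta.shape != (tree.n,):
            raise ValueError(f"delta must have length {tree.n}")
        coords = self.coords.copy()
        taus = self.taus()
        tau_pos = {t.dof_index: i for i, t in enumerate(tree.tau_dofs)}
        tau_by_body = {t.body: t for t in tree.tau_dofs}

        def visit(body):
            t = tau_by_body.get(body)
            if t is not None and abs(delta[t.dof_index]) > tol:
                cur = float(taus[tau_pos[t.dof_index]])
                new_tau = cur + np.degrees(delta[t.dof_index])
                ring_new, subs, child_tf = deform_ribose(coords, t, new_tau,
                                                         cur_tau_deg=cur)
                coords[list(t.ring)] = ring_new
                for a, p in subs.items():
                    coords[a] = p
                for ce in t.child_edges:
                    R, tr = child_tf[ce.dof_index]
                    coords[ce.subtree] = coords[ce.subtree] @ R.T + tr
            for e in tree.children[body]:
                d = delta[e.dof_index]
                if abs(d) > tol:
                    origin = coords[e.pa]
                    axis = coords[e.ca] - origin
                    # IUPAC dihedrals grow under right-handed rotation about
                    # the reversed bond axis
                    coords[e.subtree] = rotate_about_line(
                        coords[e.subtree], origin, axis, -e.sign * d)
                visit(e.child_body)

        visit(tree.root)
        out = Conformation(tree, coords)
        out._taus = taus + np.degrees(
            delta[[t.dof_index for t in tree.tau_dofs]]) \
            if len(tree.tau_dofs) else taus.copy()
        if self._dofs is not None:
            upd = self._dofs + delta
            ne = tree.n_edges
            upd[:ne] = wrap_angle(upd[:ne])     # tau entries stay unwrapped
            out._dofs = upd
            # ribose deformation perturbs adjacent torsions at strain level;
            # refresh those entries exactly
            touched = [e.dof_index for t in tree.tau_dofs
                       if abs(delta[t.dof_index]) > tol
                       for e in ([t.in_edge] if t.in_edge else []) +
                       t.child_edges]
            for k in touched:
                e = tree.edges[k]
                a, b, c, d = e.quad
                out._dofs[k] = dihedral(coords[a], coords[b],
                                        coords[c], coords[d])
        return out

    def with_dofs(self, theta_target) -> "Conformation":
        """Conformation whose DOF vector equals `theta_target` (radians)."""
        return self.apply(wrap_angle(np.asarray(theta_target) - self.dofs()))


def forward_kinematics(tree: KinematicTree, theta) -> Conformation:
    """Coordinates for an absolute DOF vector, built from the reference
    coordinates stored on the topology (root body pinned to the input)."""
    base = Conformation(tree, tree.topology.ref_coords.copy())
    return base.with_dofs(theta)


def set_ribose_tau(conformation: Conformation, residue: int,
                   tau_value_deg: float) -> Conformation:
    """Return a conformation with one ribose set to the given tau (degrees)."""
    tree = conformation.tree
    for i, t in enumerate(tree.tau_dofs):
        if t.residue == residue:
            cur = float(conformation.taus()[i])
            delta = np.zeros(tree.n)
            # plain difference: tau is not 360-periodic (see pucker module)
            delta[t.dof_index] = np.radians(tau_value_deg - cur)
            return conformation.apply(delta)
    raise ValueError(f"residue {residue} has no complete ribose ring")


def measure_torsions(coords, tree: KinematicTree) -> pd.DataFrame:
    """Per-residue table of backbone/glycosidic torsions and tau, degrees."""
    topo = tree.topology
    rows = []
    by_key = {}
    for e in tree.edges:
        if e.label:
            res = topo.residue_of(e.quad[1])
            by_key[(res, e.label)] = np.degrees(
                dihedral(*[coords[i] for i in e.quad]))
    taus = {t.residue: pucker.measure_tau(coords[list(t.ring)])
            for t in tree.tau_dofs}
    for r in topo.residues:
        row = {"residue": r.index, "base": r.base}
        for lab in TORSION_LABELS:
            if lab == "delta":
                try:
                    row[lab] = np.degrees(dihedral(
                        coords[topo.atom_index(r.index, "C5'")],
                        coords[topo.atom_index(r.index, "C4'")],
                        coords[topo.atom_index(r.index, "C3'")],
                        coords[topo.atom_index(r.index, "O3'")]))
                except Exception:
                    row[lab] = np.nan
            else:
                row[lab] = by_key.get((r.index, lab), np.nan)
        row["tau"] = taus.get(r.index, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
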