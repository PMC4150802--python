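"""Rebuild perturbations: resample free segments and reclose the backbone.

A rebuild picks a run of one or two nucleotides that are free of base
pairing, conceptually breaks the O3'-P bond at the segment's 3' end, draws a
fresh ribose pucker for each residue from a bimodal distribution over tau
(C3'-endo and C2'-endo modes), resamples each glycosidic angle uniformly,
and then restores the broken bond by damped Moore-Penrose pseudoinverse
iterations over the segment's non-ribose backbone torsions.  Atoms outside
the segment do not move at all: the downstream chain keeps its coordinates
and the small residual (below `close_tol`) is absorbed as junction strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import rotate_about_line, unit
from .kinematics import Conformation

# printed mixture weights 0.6/0.5 are normalized internally (6/11, 5/11)
_DEFAULT_WEIGHTS = (0.6, 0.5)
_DEFAULT_MEANS = (-154.0, 44.7)
_DEFAULT_SDS = (11.5, 17.2)


class NoFreeSegmentError(RuntimeError):
    """Every nucleotide participates in a WC pair; rebuilds are impossible."""


class RebuildFailure(RuntimeError):
    """Reclosure did not converge within the iteration budget."""


@dataclass
class PuckerDistribution:
    """Two-component normal mixture over the pucker coordinate tau (deg).

    `shift` (degrees) moves the second (C2'-endo) component's mean, used to
    oversample non-helical riboses.
    """

    weights: tuple = _DEFAULT_WEIGHTS
    means: tuple = _DEFAULT_MEANS
    sds: tuple = _DEFAULT_SDS
    shift: float = 0.0

    def __post_init__(self):
        if any(s <= 0 for s in self.sds):
            raise ValueError("component standard deviations must be positive")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, not all zero")
        self._p = w / w.sum()

    def component_means(self):
        return (self.means[0], self.means[1] + self.shift)

    def sample(self, rng) -> float:
        k = int(rng.random() >= self._p[0])
        mu = self.component_means()[k]
        # tau is a real-valued coordinate (slope != 1 against the
        # pseudorotation phase), so tails are not wrapped
        return float(rng.normal(mu, self.sds[k]))


def sample_tau(distribution: PuckerDistribution, rng) -> float:
    """One draw of tau (degrees) from the mixture."""
    return distribution.sample(rng)


@dataclass
class Segment:
    residues: tuple             # 1 or 2 consecutive residue indices
    has_downstream: bool        # False only at the 3' end of the chain

    def __post_init__(self):
        if not 1 <= len(self.residues) <= 2:
            raise ValueError("segment must span 1 or 2 nucleotides")


def free_residues(topology, pairs, exclude=()):
    paired = {p.residue_i for p in pairs} | {p.residue_j for p in pairs}
    paired |= set(exclude)
    return [r.index for r in topology.residues if r.index not in paired]


def eligible_segments(topology, pairs, exclude=(), lengths=(1, 2)):
    free = set(free_residues(topology, pairs, exclude))
    segs = []
    if 1 in lengths:
        segs += [(r,) for r in sorted(free)]
    if 2 in lengths:
        segs += [(r, r + 1) for r in sorted(free) if r + 1 in free]
    return segs


def select_segment(topology, pairs, rng, exclude=(),
                   lengths=(1, 2)) -> Segment:
    """Uniformly random contiguous run of free nucleotides.

    `lengths` restricts the allowed segment sizes; the sampling procedure
    prefers two-nucleotide segments (whose reclosure has enough backbone
    torsions to be almost always solvable), falling back to single
    nucleotides when no adjacent free pair exists.
    """
    segs = eligible_segments(topology, pairs, exclude, lengths)
    if not segs and lengths != (1, 2):
        segs = eligible_segments(topology, pairs, exclude)
    if not segs:
        raise NoFreeSegmentError("no unpaired nucleotides available")
    ress = segs[int(rng.integers(len(segs)))]
    return Segment(tuple(ress), ress[-1] < topology.n_residues)


# ---------------------------------------------------------------------------

def _segment_machinery(conf: Conformation, segment: Segment):
    """Adjustable torsion bonds, segment atoms and closure target."""
    topo = conf.topology
    tree = conf.tree
    res_set = set(segment.residues)
    last = segment.residues[-1]

    seg_atoms = []
    for r in segment.residues:
        seg_atoms.extend(topo.residues[r - 1].atom_indices.values())
    seg_atoms = np.array(sorted(seg_atoms), dtype=int)

    # adjustable: alpha/beta/gamma/epsilon bonds of segment residues plus any
    # zeta bond internal to the segment; chi and ring bonds excluded; the
    # zeta across the break does not move the target and is left alone
    bonds = []
    chi_edges = []
    tau_dofs = []
    for e in tree.edges:
        ri = topo.residue_of(e.pa)
        rj = topo.residue_of(e.ca)
        if e.label in ("alpha", "beta", "gamma", "epsilon") and ri in res_set:
            bonds.append(e)
        elif e.label == "zeta" and ri in res_set and rj in res_set:
            bonds.append(e)
        elif e.label == "chi" and ri in res_set:
            chi_edges.append(e)
    for t in tree.tau_dofs:
        if t.residue in res_set:
            tau_dofs.append(t)

    target = None
    if segment.has_downstream:
        p_next = topo.atom_index(last + 1, "P")
        target = conf.coords[p_next].copy()
    else:
        p_next = None
    return seg_atoms, bonds, chi_edges, tau_dofs, p_next, target


def rebuild_segment(conf: Conformation, segment: Segment,
                    distribution: PuckerDistribution, rng,
                    close_tol: float = 0.01, max_iter: int = 100,
                    lam0: float = 0.5) -> Conformation:
    """Resample a free segment and reseal its 3' O3'-P bond.

    Returns a new conformation; atoms outside the segment are bitwise
    unchanged.  Raises :class:`RebuildFailure` on non-convergence.
    """
    tree = conf.tree
    seg_atoms, bonds, chi_edges, tau_dofs, p_next, target = \
        _segment_machinery(conf, segment)

    # 1) resample pucker and glycosidic angles on a trial copy
    delta = np.zeros(tree.n)
    all_taus = conf.taus()
    tau_order = {t.dof_index: i for i, t in enumerate(tree.tau_dofs)}
    for t in tau_dofs:
        cur = float(all_taus[tau_order[t.dof_index]])
        delta[t.dof_index] = np.radians(distribution.sample(rng) - cur)
    for e in chi_edges:
        delta[e.dof_index] = rng.uniform(-np.pi, np.pi)
    trial = conf.apply(delta)

    if target is None:
        # chain 3' end: nothing to reclose
        return _commit(conf, trial, seg_atoms, delta)

    # 2) damped pseudoinverse reclosure over segment backbone torsions;
    # when the residual stalls in a local minimum of the nonlinear map,
    # the segment torsions are re-seeded at random and iteration resumes
    # (all within the same iteration budget)
    coords = trial.coords
    lam = lam0
    r = target - coords[p_next]
    best = (np.linalg.norm(r), coords)
    for _ in range(max_iter):
        if np.linalg.norm(r) < close_tol:
            return _commit(conf, Conformation(tree, coords), seg_atoms,
                           delta)
        J = np.zeros((3, len(bonds)))
        p_cur = coords[p_next]
        for k, e in enumerate(bonds):
            axis = unit(coords[e.ca] - coords[e.pa])
            J[:, k] = np.cross(axis, p_cur - coords[e.pa])
        step = lam * (np.linalg.pinv(J, rcond=1e-8) @ r)
        np.clip(step, -0.5, 0.5, out=step)
        new_coords = _rotate_bonds(coords, bonds, step)
        r_new = target - new_coords[p_next]
        if np.linalg.norm(r_new) <= np.linalg.norm(r) + 1e-12:
            coords, r = new_coords, r_new
            if np.linalg.norm(r) < best[0]:
                best = (np.linalg.norm(r), coords)
            lam = min(1.0, 1.5 * lam)
        else:
            lam *= 0.5
            if lam < 1e-5:
                coords = _rotate_bonds(
                    coords, bonds, rng.uniform(-np.pi, np.pi, len(bonds)))
                r = target - coords[p_next]
                lam = lam0
    raise RebuildFailure(
        f"reclosure stalled at residual {best[0]:.4f} A")


def _rotate_bonds(coords, bonds, step):
    out = coords.copy()
    for k, e in enumerate(bonds):
        if abs(step[k]) < 1e-15:
            continue
        origin = out[e.pa]
        axis = out[e.ca] - origin
        out[e.subtree] = rotate_about_line(out[e.subtree], origin, axis,
                                           step[k])
    return out


def _commit(original: Conformation, moved: Conformation, seg_atoms,
            tau_delta=None):
    """Copy only the segment atoms; everything else stays untouched."""
    coords = original.coords.copy()
    coords[seg_atoms] = moved.coords[seg_atoms]
    out = Conformation(original.tree, coords)
    if tau_delta is not None:
        idx = [t.dof_index for t in original.tree.tau_dofs]
        out._taus = original.taus() + np.degrees(tau_delta[idx])
    return out
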