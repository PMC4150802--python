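"""Pool-growing conformational sampler.

The pool starts from the input structure.  Each iteration selects a seed by
the shell rule (a fully random torsion vector picks the nearest pool member
inside a random-radius shell around the start, which biases seeds toward
sparsely populated regions), perturbs it with a rebuild or a null-space move
at a 10/90 rate, and accepts the candidate if it is clash-free and keeps
every Watson-Crick hydrogen bond closed.  All randomness flows through one
numpy Generator, so a (structure, pairs, config, seed) tuple reproduces the
pool exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constraints, rebuild as rebuild_mod
from .geometry import superposed_rmsd, wrap_angle
from .kinematics import Conformation, make_tree


# ---------------------------------------------------------------------------
# clash detection

@dataclass
class ClashGrid:
    """Spatial hash over atoms: cubic cells at least twice the largest scaled
    radius, so any clashing pair falls in the same or adjacent cells."""

    cell: float
    buckets: dict
    coords: np.ndarray

    @classmethod
    def build(cls, coords, radii, vdw_scale):
        cell = max(2.0 * vdw_scale * float(np.max(radii)), 1e-6)
        keys = np.floor(coords / cell).astype(np.int64)
        buckets = {}
        for i, k in enumerate(map(tuple, keys)):
            buckets.setdefault(k, []).append(i)
        return cls(cell, buckets, coords)

    def neighbor_candidates(self, i):
        k = tuple(np.floor(self.coords[i] / self.cell).astype(np.int64))
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.extend(self.buckets.get(
                        (k[0] + dx, k[1] + dy, k[2] + dz), ()))
        return out


def _excluded_pairs(topology, bodies=None):
    """1-2, 1-3 and same-rigid-body pairs, as a set of packed ints."""
    n = len(topology.atoms)
    excl = set()
    for i, j in topology.pairs_12_13():
        excl.add(i * n + j)
    if bodies is not None:
        for b in bodies:
            idx = sorted(b.atom_indices)
            for x in range(len(idx)):
                for y in range(x + 1, len(idx)):
                    excl.add(idx[x] * n + idx[y])
    return excl


def clash_check(topology, coords, vdw_scale: float = 0.5, bodies=None,
                excluded=None, return_all=False):
    """Hard-sphere clash test with scaled van der Waals radii.

    A clash is any non-excluded pair closer than
    ``vdw_scale * (r_i + r_j)``.  Returns (bool, first offending pair).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(topology.atoms)
    radii = np.array([a.vdw_radius for a in topology.atoms])
    if excluded is None:
        key = ("_clash_excl", bodies is not None)
        excluded = getattr(topology, "_clash_cache", {}).get(key)
        if excluded is None:
            excluded = _excluded_pairs(topology, bodies)
            cache = getattr(topology, "_clash_cache", None)
            if cache is None:
                cache = {}
                topology._clash_cache = cache
            cache[key] = excluded
    grid = ClashGrid.build(coords, radii, vdw_scale)
    hits = []
    for i in range(n):
        cand = [j for j in grid.neighbor_candidates(i) if j > i]
        if not cand:
            continue
        cand = np.asarray(cand)
        d = np.linalg.norm(coords[cand] - coords[i], axis=1)
        thr = vdw_scale * (radii[cand] + radii[i])
        bad = cand[d < thr]
        for j in bad:
            if i * n + int(j) not in excluded:
                if not return_all:
                    return True, (i, int(j))
                hits.append((i, int(j)))
    if return_all:
        return (len(hits) > 0), hits
    return False, None


def clash_check_bruteforce(topology, coords, vdw_scale=0.5, bodies=None):
    """O(N^2) oracle used to validate the grid (and in tests)."""
    coords = np.asarray(coords, dtype=float)
    n = len(topology.atoms)
    radii = np.array([a.vdw_radius for a in topology.atoms])
    excluded = _excluded_pairs(topology, bodies)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    thr = vdw_scale * (radii[:, None] + radii[None, :])
    ii, jj = np.where(d < thr)
    for i, j in zip(ii, jj):
        if i < j and i * n + j not in excluded:
            return True, (int(i), int(j))
    return False, None


# ---------------------------------------------------------------------------
# pairing bias (Metropolis)

@dataclass
class PairingBias:
    """Bias toward generic pairing of target residue pairs: d sums, over the
    target pairs, the smallest deviation of any candidate H...acceptor vector
    from the 2 Angstrom target length."""

    target_pairs: list                  # [(res_i, res_j)]
    target_length: float = 2.0

    def candidate_sets(self, topology):
        out = []
        for ri, rj in self.target_pairs:
            hs_i, acc_i = _polar_atoms(topology, ri)
            hs_j, acc_j = _polar_atoms(topology, rj)
            out.append((hs_i, acc_j, hs_j, acc_i))
        return out

    def d_value(self, topology, coords):
        total = 0.0
        for hs_i, acc_j, hs_j, acc_i in self.candidate_sets(topology):
            best = np.inf
            for hs, acc in ((hs_i, acc_j), (hs_j, acc_i)):
                for h in hs:
                    for a in acc:
                        L = float(np.linalg.norm(coords[h] - coords[a]))
                        best = min(best, abs(self.target_length - L))
            total += best
        return total


def _polar_atoms(topology, residue):
    """(charged hydrogens, acceptor N/O) among the base atoms of a residue."""
    from . import chem

    base = topology.base(residue)
    names = chem.base_atom_names(base)
    hs, acc = [], []
    for nm in names:
        idx = topology.atom_index(residue, nm)
        at = topology.atoms[idx]
        if at.element == "H":
            nb = topology.neighbors[idx]
            if nb and topology.atoms[nb[0]].element in ("N", "O"):
                hs.append(idx)
        elif at.element in ("N", "O"):
            bonded_h = [j for j in topology.neighbors[idx]
                        if topology.atoms[j].element == "H"]
            if not bonded_h:
                acc.append(idx)
    return hs, acc


def metropolis_accept(seed_conf, new_conf, bias: PairingBias, rng) -> bool:
    """Accept with probability min(1, exp(-(d_new - d_seed)))."""
    topo = seed_conf.topology
    d_seed = bias.d_value(topo, seed_conf.coords)
    d_new = bias.d_value(topo, new_conf.coords)
    if d_new <= d_seed:
        return True
    return bool(rng.random() < np.exp(-(d_new - d_seed)))


# ---------------------------------------------------------------------------
# pool

@dataclass
class SamplePool:
    topology: object
    tree: object
    r_init: float
    conformations: list = field(default_factory=list)
    provenance: list = field(default_factory=list)
    rmsd_to_init: list = field(default_factory=list)
    attempts: list = field(default_factory=list)

    @property
    def init(self):
        return self.conformations[0]

    def add(self, conf, **prov):
        self.conformations.append(conf)
        self.provenance.append(prov)
        self.rmsd_to_init.append(
            superposed_rmsd(conf.c4_coords(), self.init.c4_coords())
            if self.conformations[:-1] else 0.0)

    def provenance_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.provenance)
        df["c4_rmsd_to_init"] = self.rmsd_to_init
        return df

    def attempts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attempts)


def select_seed(pool: SamplePool, rng, r_init=None):
    """Shell rule: pick the pool member nearest (in torsion space) to a
    fully random conformation, among members whose C4' RMSD to the start
    falls in a random shell of width r_init/100."""
    if not pool.conformations:
        raise ValueError("pool is empty")
    r_init = pool.r_init if r_init is None else r_init
    n = pool.tree.n
    rmsds = np.asarray(pool.rmsd_to_init)
    eligible = rmsds <= r_init
    width = r_init / 100.0
    for _ in range(50):
        theta_random = rng.uniform(-np.pi, np.pi, size=n)
        radius = rng.uniform(0.0, r_init)
        inside = np.where(eligible & (rmsds >= radius) &
                          (rmsds <= radius + width))[0]
        if len(inside):
            dists = [np.linalg.norm(wrap_angle(
                pool.conformations[i].dofs() - theta_random))
                for i in inside]
            return int(inside[int(np.argmin(dists))])
    # fall back to the member nearest the last drawn shell
    idx = np.where(eligible)[0]
    return int(idx[int(np.argmin(np.abs(rmsds[idx] - radius)))])


DEFAULTS = dict(rebuild_rate=0.1, max_step=0.1, eps_closure=0.05,
                vdw_scale=0.5, sv_tol=1e-6, tau_shift=0.0,
                stall_limit=10_000, root="5p")


def run(topology, pairs, r_init, n_struct, rng, options=None,
        coords=None, bias=None) -> SamplePool:
    """Grow a pool of `n_struct` accepted samples beyond the start."""
    opts = dict(DEFAULTS)
    opts.update(options or {})
    if not hasattr(rng, "normal"):
        rng = np.random.default_rng(rng)
    if n_struct < 1:
        raise ValueError("n_struct must be >= 1")

    tree = make_tree(topology, opts["root"])
    start = Conformation(tree, topology.ref_coords.copy()
                         if coords is None else np.asarray(coords))
    cycles = constraints.build_cycles(tree, pairs)
    dist = rebuild_mod.PuckerDistribution(shift=opts["tau_shift"])

    clash0, pair0 = clash_check(topology, start.coords, opts["vdw_scale"],
                                bodies=tree.bodies)
    if clash0:
        raise ValueError(f"input structure has a clash at scaled vdW radii: "
                         f"atom pair {pair0}")

    pool = SamplePool(topology, tree, r_init)
    pool.add(start, move="init", seed=-1, iteration=0)

    consecutive_rejects = 0
    iteration = 0
    while len(pool.conformations) - 1 < n_struct:
        iteration += 1
        if consecutive_rejects > opts["stall_limit"]:
            raise RuntimeError(
                f"sampler stalled: {consecutive_rejects} consecutive "
                f"rejections after {iteration} attempts; "
                f"{len(pool.conformations) - 1} samples accepted")
        seed_idx = select_seed(pool, rng)
        seed = pool.conformations[seed_idx]
        want_rebuild = rng.random() < opts["rebuild_rate"]
        move = "rebuild" if want_rebuild else "nullspace"
        reason = None
        new = None
        try:
            if want_rebuild:
                try:
                    seg = rebuild_mod.select_segment(topology, pairs, rng,
                                                     lengths=(2,))
                    new = rebuild_mod.rebuild_segment(seed, seg, dist, rng)
                except rebuild_mod.NoFreeSegmentError:
                    move = "nullspace"
                    new = constraints.nullspace_perturb(
                        seed, cycles, rng.standard_normal(tree.n),
                        opts["max_step"], opts["eps_closure"], opts["sv_tol"])
            else:
                new = constraints.nullspace_perturb(
                    seed, cycles, rng.standard_normal(tree.n),
                    opts["max_step"], opts["eps_closure"], opts["sv_tol"])
        except constraints.ClosureViolationError:
            reason = "closure"
        except rebuild_mod.RebuildFailure:
            reason = "rebuild_failed"

        if new is not None and reason is None:
            clash, _ = clash_check(topology, new.coords, opts["vdw_scale"],
                                   bodies=tree.bodies)
            if clash:
                reason = "clash"
            elif len(cycles) and constraints.closure_drift(
                    pool.init, new, cycles) > opts["eps_closure"]:
                reason = "closure_cumulative"
            elif bias is not None and not metropolis_accept(seed, new, bias,
                                                            rng):
                reason = "metropolis"

        accepted = reason is None and new is not None
        pool.attempts.append(dict(iteration=iteration, move=move,
                                  seed=seed_idx, accepted=accepted,
                                  reason=reason or "accepted"))
        if accepted:
            pool.add(new, move=move, seed=seed_idx, iteration=iteration)
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
    return pool
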