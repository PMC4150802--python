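import numpy as np
import pytest
from scipy.optimize import brentq

from rnakin import constraints, kinematics, sampler
from rnakin.sampler import (PairingBias, SamplePool, clash_check,
                            clash_check_bruteforce, metropolis_accept, run,
                            select_seed)
from rnakin.structure_io import Atom, Bond, Topology


def _two_atom_topology(d):
    atoms = [Atom(1, "C1'", "C", 1, np.array([0.0, 0.0, 0.0]), 1.70),
             Atom(2, "C1'", "C", 2, np.array([d, 0.0, 0.0]), 1.70)]
    return Topology(atoms, [], [], ref_coords=np.array([a.coords
                                                        for a in atoms]))


@pytest.mark.parametrize("d,expected", [(1.71, False), (1.69, True)])
def test_carbon_pair_threshold(d, expected):
    topo = _two_atom_topology(d)
    clash, _ = clash_check(topo, topo.ref_coords, vdw_scale=0.5)
    assert clash is expected


def test_bisection_recovers_scale_factor():
    def verdict(d):
        topo = _two_atom_topology(d)
        clash, _ = clash_check(topo, topo.ref_coords, vdw_scale=0.5)
        return -1.0 if clash else 1.0

    boundary = brentq(verdict, 0.5, 3.0, xtol=1e-6)
    assert abs(boundary / (1.70 + 1.70) - 0.5) < 1e-3


def test_grid_matches_bruteforce_on_random_conformations(hairpin, hp_tree):
    conf0 = kinematics.Conformation(hp_tree, hairpin.coords.copy())
    rng = np.random.default_rng(8)
    disagreements = 0
    for _ in range(60):
        conf = conf0.apply(rng.normal(0.0, 0.25, hp_tree.n))
        a, _ = clash_check(hairpin.topology, conf.coords,
                           bodies=hp_tree.bodies)
        b, _ = clash_check_bruteforce(hairpin.topology, conf.coords,
                                      bodies=hp_tree.bodies)
        disagreements += int(a != b)
    assert disagreements == 0


def test_excluded_pairs_do_not_clash(hairpin, hp_tree):
    # bonded and angle-linked atoms are closer than scaled radii by design
    clash, pair = clash_check(hairpin.topology, hairpin.coords,
                              bodies=hp_tree.bodies)
    assert not clash


# ---------------------------------------------------------------------------

def test_seed_from_singleton_pool(hairpin, hp_tree):
    conf = kinematics.Conformation(hp_tree, hairpin.coords.copy())
    pool = SamplePool(hairpin.topology, hp_tree, 3.0)
    pool.add(conf, move="init", seed=-1, iteration=0)
    assert select_seed(pool, np.random.default_rng(0)) == 0


def test_seed_shell_picks_matching_member(hairpin, hp_tree):
    conf = kinematics.Conformation(hp_tree, hairpin.coords.copy())
    pool = SamplePool(hairpin.topology, hp_tree, 3.0)
    pool.add(conf, move="init", seed=-1, iteration=0)
    d = np.zeros(hp_tree.n)
    d[20] = 0.6                       # a loop torsion; ~1 A C4' RMSD
    far = conf.apply(d)
    pool.add(far, move="x", seed=0, iteration=1)
    assert 0.2 < pool.rmsd_to_init[1] < 3.0   # inside the exploration radius
    rng = np.random.default_rng(1)
    picks = {select_seed(pool, rng) for _ in range(300)}
    assert picks == {0, 1}      # both shells are visited


def test_sampler_determinism(hairpin):
    kw = dict(r_init=3.0, n_struct=8, coords=hairpin.coords)
    p1 = run(hairpin.topology, hairpin.pairs, rng=np.random.default_rng(7),
             **kw)
    p2 = run(hairpin.topology, hairpin.pairs, rng=np.random.default_rng(7),
             **kw)
    assert len(p1.conformations) == len(p2.conformations)
    for a, b in zip(p1.conformations, p2.conformations):
        assert np.array_equal(a.coords, b.coords)
    assert p1.provenance == p2.provenance


def test_pool_members_clash_free_and_closed(hairpin, hp_tree):
    pool = run(hairpin.topology, hairpin.pairs, r_init=3.0, n_struct=15,
               rng=np.random.default_rng(3), coords=hairpin.coords)
    cycles = constraints.build_cycles(pool.tree, hairpin.pairs)
    for conf in pool.conformations:
        clash, _ = clash_check(hairpin.topology, conf.coords,
                               bodies=pool.tree.bodies)
        assert not clash
        drift = constraints.closure_drift(pool.init, conf, cycles)
        assert drift <= 0.05 + 1e-9


def test_run_requires_positive_count(hairpin):
    with pytest.raises(ValueError):
        run(hairpin.topology, hairpin.pairs, 3.0, 0,
            np.random.default_rng(0), coords=hairpin.coords)


# ---------------------------------------------------------------------------

def test_metropolis_always_accepts_equal_d(hairpin, hp_tree):
    conf = kinematics.Conformation(hp_tree, hairpin.coords.copy())
    bias = PairingBias([(1, hairpin.topology.n_residues)])
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert metropolis_accept(conf, conf, bias, rng)


def test_ideal_hbond_contributes_zero(hairpin):
    # the stem pairs hold 2.1 A central hydrogen bonds; with a 2.1 A target
    # length the per-pair term vanishes
    bias = PairingBias([(1, hairpin.topology.n_residues)],
                       target_length=2.1)
    d = bias.d_value(hairpin.topology, hairpin.coords)
    assert d < 1e-3


def test_candidate_distance_arithmetic(hairpin):
    # d equals |target - L| of the closest-to-target candidate vector,
    # verified against an exhaustive search over the candidate sets
    topo = hairpin.topology
    pair = (1, topo.n_residues)
    bias = PairingBias([pair], target_length=3.2)
    hs1, acc1 = sampler._polar_atoms(topo, pair[0])
    hs2, acc2 = sampler._polar_atoms(topo, pair[1])
    best = min(abs(3.2 - np.linalg.norm(hairpin.coords[h] -
                                        hairpin.coords[a]))
               for hs, accs in ((hs1, acc2), (hs2, acc1))
               for h in hs for a in accs)
    assert bias.d_value(topo, hairpin.coords) == pytest.approx(best)


def test_metropolis_rate_matches_boltzmann(hairpin, hp_tree):
    conf = kinematics.Conformation(hp_tree, hairpin.coords.copy())
    worse = kinematics.Conformation(hp_tree, hairpin.coords.copy())

    class FixedBias(PairingBias):
        def d_value(self, topo, coords):
            return 0.0 if coords is conf.coords else 1.2

    bias = FixedBias([(1, 2)])
    rng = np.random.default_rng(11)
    acc = sum(metropolis_accept(conf, worse, bias, rng) for _ in range(4000))
    assert abs(acc / 4000 - np.exp(-1.2)) < 0.03
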