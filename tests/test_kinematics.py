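import numpy as np
import pytest

from rnakin import chem, kinematics, pucker
from rnakin.geometry import wrap_angle
from rnakin.kinematics import (Conformation, build_rigid_bodies,
                               forward_kinematics, make_tree,
                               measure_torsions, set_ribose_tau)


def test_bodies_partition_atoms(hairpin):
    bodies = build_rigid_bodies(hairpin.topology)
    total = sum(len(b.atom_indices) for b in bodies)
    assert total == len(hairpin.topology.atoms)
    seen = set()
    for b in bodies:
        assert not (seen & b.atom_indices)
        seen |= b.atom_indices


def test_merging_rules(hairpin, hp_tree):
    topo = hairpin.topology
    body_of = hp_tree.body_of
    # a purine base is one rigid body including its hydrogens
    g = topo.residues[0]
    base_atoms = [topo.atom_index(1, nm) for nm in chem.base_atom_names("G")]
    assert len({body_of[i] for i in base_atoms}) == 1
    # single-neighbor atoms merge with their neighbor (terminal hydroxyl H)
    ho3 = topo.atom_index(topo.n_residues, "HO3'")
    o3 = topo.atom_index(topo.n_residues, "O3'")
    assert body_of[ho3] == body_of[o3]
    # a rotatable bond never joins two atoms of one body
    for b in topo.rotatable_bonds():
        e_edges = [e for e in hp_tree.edges
                   if {e.pa, e.ca} == {b.i, b.j}]
        if e_edges:
            assert body_of[b.i] != body_of[b.j]
    # O5'-C5' rotatable: different bodies
    assert body_of[topo.atom_index(2, "O5'")] != \
        body_of[topo.atom_index(2, "C5'")]


def test_dof_count_formula(hairpin, hairpin_single):
    # 5 per residue (beta gamma epsilon chi tau) + 2 per junction
    for hp in (hairpin, hairpin_single):
        tree = make_tree(hp.topology)
        L = hp.topology.n_residues
        assert tree.n == 7 * L - 2


def test_tree_acyclic_single_parent(hp_tree):
    seen = {}
    for e in hp_tree.edges:
        assert e.child_body not in seen
        seen[e.child_body] = e.parent_body
    assert len(seen) == len(hp_tree.edges)
    assert hp_tree.root not in seen


def test_root_choice_preserves_dof_count(hairpin):
    t5 = make_tree(hairpin.topology, "5p")
    t3 = make_tree(hairpin.topology, "3p")
    assert t5.n == t3.n
    assert t5.root != t3.root


def test_forward_kinematics_identity(hp_conf, hp_tree):
    again = forward_kinematics(hp_tree, hp_conf.dofs())
    assert np.abs(again.coords - hp_conf.coords).max() < 1e-9


def test_single_chi_moves_only_distal_base(hp_conf, hp_tree):
    chi = [e for e in hp_tree.edges if e.label == "chi"][-1]
    d = np.zeros(hp_tree.n)
    d[chi.dof_index] = 0.4
    new = hp_conf.apply(d)
    moved = np.linalg.norm(new.coords - hp_conf.coords, axis=1)
    assert set(np.where(moved > 1e-9)[0]) <= set(chi.subtree.tolist())


def test_rigid_bodies_stay_rigid_under_random_moves(hp_conf, hp_tree):
    rng = np.random.default_rng(4)
    new = hp_conf.apply(rng.normal(0.0, 0.2, hp_tree.n))
    ribose_bodies = {t.body for t in hp_tree.tau_dofs}
    for body in hp_tree.bodies:
        idx = sorted(body.atom_indices)
        if len(idx) < 2:
            continue
        a = hp_conf.coords[idx]
        b = new.coords[idx]
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        if body.body_id in ribose_bodies:
            # riboses deform internally: that is the pucker DOF working
            assert np.abs(da - db).max() < 1.0
        else:
            assert np.abs(da - db).max() < 1e-9


def test_apply_matches_requested_dof_change(hp_conf, hp_tree):
    rng = np.random.default_rng(5)
    d = rng.normal(0.0, 0.1, hp_tree.n)
    new = hp_conf.apply(d)
    got = wrap_angle(new.tree.measure_dofs(new.coords) -
                     hp_tree.measure_dofs(hp_conf.coords))
    # edge torsions move by exactly the requested increment
    ne = hp_tree.n_edges
    assert np.abs(wrap_angle(got[:ne] - d[:ne])).max() < 2e-3
    # pucker coordinates too (via the embedding)
    assert np.abs(got[ne:] - d[ne:]).max() < 1e-3


def test_displacement_matches_finite_difference_direction(hp_conf, hp_tree):
    # analytic instantaneous displacement = axis x lever for an edge DOF
    e = [x for x in hp_tree.edges if x.label == "beta"][2]
    h = 1e-6
    d = np.zeros(hp_tree.n)
    d[e.dof_index] = h
    num = (hp_conf.apply(d).coords - hp_conf.apply(-d).coords) / (2 * h)
    axis = hp_conf.coords[e.ca] - hp_conf.coords[e.pa]
    axis = -axis / np.linalg.norm(axis) * e.sign
    for atom in e.subtree[:10]:
        ana = np.cross(axis, hp_conf.coords[atom] - hp_conf.coords[e.pa])
        assert np.abs(num[atom] - ana).max() < 1e-6
    outside = [i for i in range(len(hp_conf.coords)) if i not in e.subtree]
    assert np.abs(num[outside]).max() < 1e-9


def test_measure_set_round_trip(hp_conf, hp_tree):
    rng = np.random.default_rng(6)
    target = hp_conf.dofs() + rng.normal(0.0, 0.3, hp_tree.n)
    new = hp_conf.with_dofs(target)
    ne = hp_tree.n_edges
    err = wrap_angle(new.tree.measure_dofs(new.coords)[:ne] - target[:ne])
    assert np.abs(err).max() < 2e-3
    # setting a conformation to its own DOF vector is the exact identity
    again = new.with_dofs(new.dofs())
    assert np.abs(again.coords - new.coords).max() < 1e-12


def test_measured_torsions_match_construction(hairpin, hp_tree):
    df = measure_torsions(hairpin.coords, hp_tree)
    stem = hairpin.spec.stem
    L = hairpin.spec.length
    # intra-stem junctions carry the A-form crossing torsions
    intra_alpha = list(range(2, stem + 1)) + list(range(L - stem + 2, L + 1))
    intra_zeta = list(range(1, stem)) + list(range(L - stem + 1, L))
    for r in intra_alpha:
        assert abs(df.loc[df.residue == r, "alpha"].iloc[0] - (-68.0)) < 5.0
    for r in intra_zeta:
        assert abs(df.loc[df.residue == r, "zeta"].iloc[0] - (-71.0)) < 5.0


# ---------------------------------------------------------------------------

def test_set_ribose_tau_classification(hp_conf):
    res = hp_conf.topology.n_residues // 2   # a loop residue
    for tau, klass in ((-154.0, "C3-endo"), (44.7, "C2-endo")):
        new = set_ribose_tau(hp_conf, res, tau)
        assert abs(new.tau(res) - tau) < 1e-9
        measured = pucker.measure_tau(
            new.tree.ring_coords(new.coords, res))
        # independent re-measurement; small bias from carried-over strain
        assert abs(measured - tau) < 0.2
        assert pucker.classify_pucker(measured) == klass
        # ring closure preserved
        ring = new.tree.ring_coords(new.coords, res)
        d = np.linalg.norm(np.roll(ring, -1, axis=0) - ring, axis=1)
        assert d.max() < 1.56 and d.min() > 1.36


def test_set_ribose_tau_idempotent(hp_conf):
    res = 6
    a = set_ribose_tau(hp_conf, res, 44.7)
    b = set_ribose_tau(a, res, 44.7)
    assert np.abs(b.coords - a.coords).max() < 1e-9


def test_set_ribose_tau_moves_exocyclic_with_ring(hp_conf):
    res = 6
    topo = hp_conf.topology
    new = set_ribose_tau(hp_conf, res, 44.7)
    # bond lengths from ring atoms to substituents preserved
    for pair in (("C2'", "O2'"), ("C1'", "H1'"), ("C3'", "O3'"),
                 ("C4'", "C5'")):
        i, j = (topo.atom_index(res, nm) for nm in pair)
        before = np.linalg.norm(hp_conf.coords[i] - hp_conf.coords[j])
        after = np.linalg.norm(new.coords[i] - new.coords[j])
        assert abs(before - after) < 2e-3


def test_set_ribose_tau_requires_ring(hp_conf):
    with pytest.raises(ValueError):
        set_ribose_tau(hp_conf, 999, -154.0)
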