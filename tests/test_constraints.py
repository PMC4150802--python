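import numpy as np
import pytest

from rnakin import constraints, kinematics
from rnakin.constraints import (ClosureViolationError, build_cycles,
                                closure_drift, compute_jacobian,
                                nullspace_basis, nullspace_perturb)

SV_TOL = 1e-6


def test_six_rows_per_cycle(hp_conf, hp_tree, hp_cycles, hairpin):
    J = compute_jacobian(hp_tree, hp_conf, hp_cycles)
    assert J.shape == (6 * len(hairpin.pairs), hp_tree.n)
    assert len(hp_cycles) == len(hairpin.pairs)


def test_columns_vanish_off_cycle(hp_conf, hp_tree, hp_cycles):
    J = compute_jacobian(hp_tree, hp_conf, hp_cycles)
    on_path = set()
    for cyc in hp_cycles:
        on_path |= set(np.where(cyc.s_edge != 0)[0].tolist())
        on_path |= set(cyc.tau_exit.keys())
    off = [k for k in range(hp_tree.n) if k not in on_path]
    assert np.abs(J[:, off]).max() < 1e-12


def test_jacobian_matches_finite_differences(hp_conf, hp_cycles, hp_tree,
                                             oracles):
    J = compute_jacobian(hp_tree, hp_conf, hp_cycles)
    Jfd = oracles["fd_jacobian"](hp_conf, hp_cycles)
    assert np.abs(J - Jfd).max() < 1e-6 * max(1.0, np.abs(J).max())


def test_empty_cycles_give_full_nullspace(hp_conf, hp_tree):
    J = compute_jacobian(hp_tree, hp_conf, [])
    N = nullspace_basis(J, SV_TOL)
    assert N.shape == (hp_tree.n, hp_tree.n)
    assert np.allclose(N, np.eye(hp_tree.n))


@pytest.mark.parametrize("fixture,m", [("hairpin_single", 1),
                                       ("hairpin_double", 2)])
def test_rank_law_on_random_generic_fixtures(request, fixture, m, oracles):
    """rank(J) = 5m, null-space dimension n - 5m, across many randomly
    perturbed (generic-geometry) single- and double-cycle structures."""
    hp = request.getfixturevalue(fixture)
    tree = kinematics.make_tree(hp.topology)
    base = kinematics.Conformation(tree, hp.coords.copy())
    cycles = build_cycles(tree, hp.pairs)
    rng = np.random.default_rng(42)
    checked_fd = 0
    for trial in range(25):
        conf = oracles["randomized"](base, rng)
        J = compute_jacobian(tree, conf, cycles)
        sv = np.linalg.svd(J, compute_uv=False)
        rank = int(np.sum(sv > SV_TOL * sv[0]))
        assert rank == 5 * m
        N = nullspace_basis(J, SV_TOL)
        assert N.shape[1] == tree.n - 5 * m
        assert np.abs(J @ N).max() < 1e-8 * max(1.0, np.abs(J).max())
        if trial % 8 == 0:      # spot-check against the independent oracle
            Jfd = oracles["fd_jacobian"](conf, cycles)
            assert np.abs(J - Jfd).max() < 1e-5 * max(1.0, np.abs(J).max())
            checked_fd += 1
    assert checked_fd >= 3


def test_basis_orthonormal_and_projection_idempotent(hp_conf, hp_tree,
                                                     hp_cycles):
    J = compute_jacobian(hp_tree, hp_conf, hp_cycles)
    N = nullspace_basis(J, SV_TOL)
    assert np.abs(N.T @ N - np.eye(N.shape[1])).max() < 1e-10
    P = N @ N.T
    assert np.abs(P @ P - P).max() < 1e-10


def test_zero_trial_leaves_conformation_unchanged(hp_conf, hp_cycles):
    new = nullspace_perturb(hp_conf, hp_cycles, np.zeros(hp_conf.tree.n),
                            sv_tol=SV_TOL)
    assert np.abs(new.coords - hp_conf.coords).max() < 1e-12


def test_unconstrained_projection_is_identity(hairpin, hp_tree):
    conf = kinematics.Conformation(hp_tree, hairpin.coords.copy())
    trial = np.zeros(hp_tree.n)
    trial[10] = 5.0
    new = nullspace_perturb(conf, build_cycles(hp_tree, []), trial,
                            max_step=0.1)
    change = np.abs(kinematics.wrap_angle(new.dofs() - conf.dofs()))
    assert abs(change[10] - 0.1) < 1e-6      # capped single-torsion move
    assert np.abs(np.delete(change, 10)).max() < 1e-6


def test_step_cap_enforced(hp_conf, hp_cycles):
    rng = np.random.default_rng(0)
    for _ in range(5):
        trial = 10.0 * rng.standard_normal(hp_conf.tree.n)
        try:
            new = nullspace_perturb(hp_conf, hp_cycles, trial, max_step=0.1,
                                    sv_tol=SV_TOL)
        except ClosureViolationError:
            continue
        change = kinematics.wrap_angle(new.dofs() - hp_conf.dofs())
        assert np.abs(change).max() <= 0.1 + 1e-6


def test_closure_drift_quadratic_in_step(hp_conf, hp_cycles, hp_tree):
    J = compute_jacobian(hp_tree, hp_conf, hp_cycles)
    N = nullspace_basis(J, SV_TOL)
    rng = np.random.default_rng(9)
    ratios = []
    for _ in range(5):
        d = N @ (N.T @ rng.standard_normal(hp_tree.n))
        d *= 0.1 / np.abs(d).max()
        drifts = [closure_drift(hp_conf, hp_conf.apply(d * s), hp_cycles)
                  for s in (1.0, 0.5, 0.25)]
        ratios.append(drifts[0] / drifts[1])
        ratios.append(drifts[1] / drifts[2])
        assert drifts[0] > drifts[1] > drifts[2]
    # halving the step shrinks the drift about fourfold (linearization)
    assert np.mean(ratios) > 3.0


def test_violating_move_is_rejected(hp_conf, hp_cycles):
    # a huge unprojected-trial cannot sneak through the closure gate:
    # force a violation by applying a raw (unprojected) move instead
    rng = np.random.default_rng(3)
    rejected = 0
    for _ in range(20):
        try:
            nullspace_perturb(hp_conf, hp_cycles,
                              rng.standard_normal(hp_conf.tree.n),
                              max_step=0.1, eps_closure=0.005,
                              sv_tol=SV_TOL)
        except ClosureViolationError as e:
            assert e.drift > 0.005
            rejected += 1
    assert rejected > 0
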