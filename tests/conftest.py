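import numpy as np
import pytest

from rnakin import constraints, kinematics, synthetic


@pytest.fixture(scope="session")
def hairpin():
    """4-bp stem / 4-nt loop hairpin, the main fixture."""
    return synthetic.make_hairpin(synthetic.HairpinSpec(stem=4, loop=4),
                                  np.random.default_rng(1))


@pytest.fixture(scope="session")
def hairpin_double():
    """2-bp stem hairpin: two nested hydrogen-bond cycles."""
    return synthetic.make_hairpin(synthetic.HairpinSpec(stem=2, loop=4),
                                  np.random.default_rng(3))


@pytest.fixture(scope="session")
def hairpin_single():
    """Single WC pair hairpin: one kinematic cycle."""
    return synthetic.make_hairpin(synthetic.HairpinSpec(stem=1, loop=4),
                                  np.random.default_rng(2))


@pytest.fixture(scope="session")
def hp_tree(hairpin):
    return kinematics.make_tree(hairpin.topology)


@pytest.fixture()
def hp_conf(hairpin, hp_tree):
    return kinematics.Conformation(hp_tree, hairpin.coords.copy())


@pytest.fixture(scope="session")
def hp_cycles(hairpin, hp_tree):
    return constraints.build_cycles(hp_tree, hairpin.pairs)


def constraint_values(ref, new, cycles):
    """Stacked 6m relative endpoint displacements between two conformations
    (the quantity whose derivative the cycle Jacobian is)."""
    tree = ref.tree
    out = []
    for cyc in cycles:
        Ra, ta = constraints.body_transform(tree, ref.coords, new.coords,
                                            cyc.a_body)
        Rh, th = constraints.body_transform(tree, ref.coords, new.coords,
                                            cyc.h_body)
        out.append(new.coords[cyc.hydrogen] -
                   (ref.coords[cyc.hydrogen] @ Ra.T + ta))
        out.append(new.coords[cyc.acceptor] -
                   (ref.coords[cyc.acceptor] @ Rh.T + th))
    return np.concatenate(out)


def finite_difference_jacobian(conf, cycles, h=1e-6):
    """Independent central-difference oracle for the cycle Jacobian."""
    n = conf.tree.n
    J = np.zeros((6 * len(cycles), n))
    for k in range(n):
        d = np.zeros(n)
        d[k] = h
        J[:, k] = (constraint_values(conf, conf.apply(d), cycles) -
                   constraint_values(conf, conf.apply(-d), cycles)) / (2 * h)
    return J


def randomized(conf, rng, scale=0.15):
    """Generic-geometry variant: random perturbation of every DOF."""
    return conf.apply(rng.normal(0.0, scale, size=conf.tree.n))


@pytest.fixture(scope="session")
def oracles():
    return {
        "constraint_values": constraint_values,
        "fd_jacobian": finite_difference_jacobian,
        "randomized": randomized,
    }
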