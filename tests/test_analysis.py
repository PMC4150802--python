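import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rnakin import analysis, kinematics
from rnakin.analysis import (ShiftHistogram, c4_rmsd, dof_variance_profile,
                             kl_divergence, rmsd_cs, shift_kl, tag_regions)
from rnakin.geometry import rotation_matrix


def test_c4_rmsd_identity_and_rigid_motion(hp_conf):
    assert c4_rmsd(hp_conf, hp_conf) == pytest.approx(0.0, abs=1e-9)
    R = rotation_matrix([1.0, 1.0, 0.0], 1.2)
    moved = hp_conf.c4_coords() @ R.T + np.array([5.0, -3.0, 2.0])
    assert c4_rmsd(hp_conf, moved) == pytest.approx(0.0, abs=1e-9)


def test_c4_rmsd_three_point_hand_value():
    # equilateral triangle vs the same triangle with one vertex pushed out
    # along its median: optimal superposition reduces to centroid alignment
    # because the perturbation is purely radial
    A = np.array([[1.0, 0.0, 0.0],
                  [-0.5, np.sqrt(3) / 2, 0.0],
                  [-0.5, -np.sqrt(3) / 2, 0.0]])
    B = A.copy()
    B[0] = [1.3, 0.0, 0.0]
    # centroid shift 0.1 along x; residuals (0.2, -0.1, -0.1) on x
    expected = np.sqrt((0.2 ** 2 + 0.1 ** 2 + 0.1 ** 2) / 3.0)
    assert c4_rmsd(A, B) == pytest.approx(expected, abs=1e-6)


def test_c4_rmsd_shape_mismatch():
    with pytest.raises(ValueError):
        c4_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def test_dof_variance_zero_for_identical_pool(hp_conf):
    df = dof_variance_profile([hp_conf] * 5)
    assert np.allclose(df["circular_variance"], 0.0)


def test_dof_variance_ranks_perturbed_dof_first(hp_conf, hp_tree):
    k = 17
    pool = []
    for x in (-0.4, -0.2, 0.2, 0.4):
        d = np.zeros(hp_tree.n)
        d[k] = x
        pool.append(hp_conf.apply(d))
    df = dof_variance_profile(pool)
    assert df["circular_variance"].idxmax() == k


def test_loop_dofs_more_variable_than_stem(hairpin, hp_tree):
    from rnakin import sampler

    pool = sampler.run(hairpin.topology, hairpin.pairs, 3.0, 40,
                       np.random.default_rng(17), coords=hairpin.coords)
    df = dof_variance_profile(pool.conformations)
    stem_res = set(range(1, hairpin.spec.stem + 1)) | \
        set(range(hairpin.spec.length - hairpin.spec.stem + 1,
                  hairpin.spec.length + 1))
    loop = df[~df.residue.isin(stem_res)]["circular_variance"].mean()
    stem = df[df.residue.isin(stem_res)]["circular_variance"].mean()
    assert loop > stem


# ---------------------------------------------------------------------------

def test_kl_hand_computed_two_bin_example():
    # 0.5*(0.8 ln 1.6 + 0.2 ln 0.4 + 0.5 ln 0.625 + 0.5 ln 2.5)
    hand = 0.5 * (0.8 * np.log(1.6) + 0.2 * np.log(0.4) +
                  0.5 * np.log(0.625) + 0.5 * np.log(2.5))
    got = kl_divergence(np.array([0.8, 0.2]), np.array([0.5, 0.5]))
    assert got == pytest.approx(hand, abs=1e-12)
    assert got == pytest.approx(0.2079441542, abs=1e-6)


def test_kl_zero_iff_equal():
    p = np.array([0.3, 0.5, 0.2])
    assert kl_divergence(p, p) == 0.0
    q = np.array([0.25, 0.5, 0.25])
    assert kl_divergence(p, q) > 0.0


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=30),
       st.lists(st.floats(0.01, 10.0), min_size=2, max_size=30))
def test_kl_symmetric_and_nonnegative(pa, qa):
    n = min(len(pa), len(qa))
    p = np.array(pa[:n]) / np.sum(pa[:n])
    q = np.array(qa[:n]) / np.sum(qa[:n])
    d1 = kl_divergence(p, q)
    d2 = kl_divergence(q, p)
    assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)
    assert d1 >= -1e-12


def test_histogram_thirty_bins_pseudocounts_and_sum():
    vals = np.r_[np.full(50, 1.0), np.full(50, 2.0)]
    h = ShiftHistogram.from_values(vals, mu=1.5, sigma=0.25)
    assert len(h.probs) == 30
    assert len(h.edges) == 31
    assert np.all(h.probs > 0)
    assert abs(h.probs.sum() - 1.0) < 1e-12
    assert h.edges[0] == pytest.approx(0.5) and h.edges[-1] == \
        pytest.approx(2.5)


def test_shift_kl_uses_predicted_stats():
    rng = np.random.default_rng(0)
    pred = rng.normal(7.5, 0.3, 400)
    meas = rng.normal(7.5, 0.3, 400)
    close = shift_kl(meas, pred)
    far = shift_kl(meas + 0.6, pred)
    assert close < far


def test_kl_rejects_mismatched_bins():
    a = ShiftHistogram.from_values(np.random.default_rng(0).normal(size=50))
    b = ShiftHistogram.from_values(
        np.random.default_rng(1).normal(5.0, 1.0, 50))
    with pytest.raises(ValueError):
        kl_divergence(a, b)


# ---------------------------------------------------------------------------

def _table(rows):
    return pd.DataFrame(rows, columns=["residue", "proton", "ppm"])


def test_rmsd_cs_identity_and_single_offset():
    t = _table([(1, "H1'", 5.5), (2, "H8", 7.9)])
    assert rmsd_cs(t, t)[0] == pytest.approx(0.0)
    t2 = _table([(1, "H1'", 5.8), (2, "H8", 7.9)])
    val, unmatched = rmsd_cs(t, t2)
    assert unmatched == []
    assert val == pytest.approx(np.sqrt(0.3 ** 2 / 2.0))


def test_rmsd_cs_four_record_hand_value():
    m = _table([(1, "H1'", 5.0), (2, "H8", 8.0), (3, "H6", 7.5),
                (4, "H2", 7.0)])
    p = _table([(1, "H1'", 5.1), (2, "H8", 7.8), (3, "H6", 7.5),
                (4, "H2", 7.4)])
    val, _ = rmsd_cs(m, p)
    assert val == pytest.approx(
        np.sqrt((0.1 ** 2 + 0.2 ** 2 + 0.0 + 0.4 ** 2) / 4.0))


def test_rmsd_cs_reports_unmatched():
    m = _table([(1, "H1'", 5.0), (2, "H8", 8.0)])
    p = _table([(1, "H1'", 5.1), (3, "H6", 7.2)])
    val, unmatched = rmsd_cs(m, p)
    assert val == pytest.approx(0.1)
    assert set(unmatched) == {(2, "H8"), (3, "H6")}


def test_region_tagging(hairpin):
    df = _table([(1, "H1'", 5.0), (6, "H8", 8.0)])
    tagged = tag_regions(df, hairpin.pairs)
    assert tagged.loc[tagged.residue == 1, "region"].iloc[0] == "helical"
    assert tagged.loc[tagged.residue == 6, "region"].iloc[0] == "non-helical"


def test_shift_table_round_trip(tmp_path):
    df = _table([(1, "H1'", 5.123), (2, "H5", 5.456)])
    p = tmp_path / "shifts.tsv"
    analysis.write_shift_table(df, p)
    df2 = analysis.read_shift_table(p)
    assert np.allclose(df2["ppm"], df["ppm"])
    bad = tmp_path / "bad.tsv"
    bad.write_text("1\tH99\t5.0\n")
    with pytest.raises(ValueError, match="H99"):
        analysis.read_shift_table(bad)
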