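import numpy as np
import pytest
from scipy.optimize import minimize

from rnakin import rdcfit, synthetic
from rnakin.rdcfit import (EnsembleWeights, RDCDataset, fit_report,
                           fit_weights, load_dataset, read_rdc_table,
                           verify_kkt, write_rdc_table)


def _dataset(rng_seed=0, s=50, k=12):
    # shared alignment signature plus per-candidate deviations, as in
    # back-calculated RDC sets of one molecule
    rng = np.random.default_rng(rng_seed)
    cand = rng.normal(0.0, 10.0, k) + rng.normal(0.0, 3.0, (s, k))
    labels = [(30 + i, "C1'", "H1'") for i in range(k)]
    return cand, labels


def test_exact_candidate_recovered():
    cand, labels = _dataset()
    ds = RDCDataset(cand[3], cand, labels)
    w, resid = fit_weights(ds)
    assert resid < 1e-9
    assert list(w.support) == [3]
    assert abs(w.w[3] - 1.0) < 1e-9


def test_constructed_mixture_recovered():
    cand, labels = _dataset(1)
    obs = 0.4 * cand[1] + 0.5 * cand[2]
    w, resid = fit_weights(RDCDataset(obs, cand, labels))
    assert np.abs(w.w[[1, 2]] - [0.4, 0.5]).max() < 1e-6
    assert w.w.sum() < 0.9 + 1e-9


@pytest.mark.parametrize("j", [1, 2, 3, 5])
def test_parsimony_support_equals_mixture_size(j):
    # enough couplings that the sparse mixture is identifiable
    rng = np.random.default_rng(j)
    cand, labels = _dataset(j + 10, s=100, k=30)
    true = rng.dirichlet(np.ones(j)) * 0.95
    obs = true @ cand[:j]
    w, resid = fit_weights(RDCDataset(obs, cand, labels))
    assert len(w.support) == j
    assert np.abs(w.w[:j] - true).max() < 1e-5
    assert resid < 1e-8


def test_row_order_invariance():
    cand, labels = _dataset(4)
    obs = 0.3 * cand[0] + 0.6 * cand[7]
    w1, _ = fit_weights(RDCDataset(obs, cand, labels))
    perm = np.random.default_rng(0).permutation(len(cand))
    w2, _ = fit_weights(RDCDataset(obs, cand[perm], labels))
    assert np.abs(w1.w[perm] - w2.w).max() < 1e-9


def test_sum_constraint_modes():
    cand, labels = _dataset(5, s=30)
    obs = 3.0 * cand[2]            # pulls toward weights > 1
    w_le, _ = fit_weights(RDCDataset(obs, cand, labels), "le")
    assert w_le.w.sum() <= 1.0 + 1e-9
    w_eq, _ = fit_weights(RDCDataset(obs, cand, labels), "eq")
    assert abs(w_eq.w.sum() - 1.0) < 1e-9


def test_global_optimality_against_convex_oracle():
    rng = np.random.default_rng(9)
    cand, labels = _dataset(9, s=200)
    true = np.zeros(200)
    true[[3, 50, 120]] = (0.3, 0.35, 0.2)
    obs = true @ cand + rng.normal(0.0, 1.0, cand.shape[1])
    ds = RDCDataset(obs, cand, labels)
    w, _ = fit_weights(ds)

    def obj(x):
        return np.sum((obs - x @ cand) ** 2)

    r = minimize(obj, np.full(200, 1.0 / 400), method="SLSQP",
                 bounds=[(0.0, None)] * 200,
                 constraints=[{"type": "ineq",
                               "fun": lambda x: 1.0 - np.sum(x)}],
                 options={"maxiter": 800, "ftol": 1e-14})
    assert obj(w.w) <= r.fun + 1e-8
    ok, msg = verify_kkt(ds, w.w, "le")
    assert ok, msg


def test_random_feasible_points_never_beat_solution():
    rng = np.random.default_rng(2)
    cand, labels = _dataset(2, s=40)
    obs = 0.5 * cand[0] + 0.4 * cand[1] + rng.normal(0, 0.5, cand.shape[1])
    ds = RDCDataset(obs, cand, labels)
    w, _ = fit_weights(ds)
    best = np.sum((obs - w.w @ cand) ** 2)
    for _ in range(10_000):
        x = rng.dirichlet(np.ones(40)) * rng.uniform(0.0, 1.0)
        assert np.sum((obs - x @ cand) ** 2) >= best - 1e-10


def test_empty_candidates_and_bad_mode_rejected():
    ds = RDCDataset(np.array([1.0]), np.empty((0, 1)), [(1, "C", "H")])
    with pytest.raises(ValueError):
        fit_weights(ds)
    cand, labels = _dataset()
    with pytest.raises(ValueError):
        fit_weights(RDCDataset(cand[0], cand, labels), "bogus")


# ---------------------------------------------------------------------------

def test_report_perfect_fit_and_zero_weights():
    cand, labels = _dataset(3)
    ds = RDCDataset(cand[5], cand, labels)
    w, _ = fit_weights(ds)
    rep = fit_report(ds, w)
    assert rep["r2"] == pytest.approx(1.0)
    assert rep["rmsd_hz"] == pytest.approx(0.0, abs=1e-9)
    zero = EnsembleWeights(np.zeros(len(cand)))
    rep0 = fit_report(ds, zero)
    k = len(ds.observed)
    assert rep0["rmsd_hz"] == pytest.approx(
        np.linalg.norm(ds.observed) / np.sqrt(k))


def test_noisy_mixture_rmsd_tracks_noise():
    obs, cand, labels, w_true = synthetic.make_rdc_fixture(
        100, 40, (0.5, 0.4), noise_sigma=1.0, rng=7)
    ds = RDCDataset(obs, cand, labels)
    w, _ = fit_weights(ds)
    rep = fit_report(ds, w)
    assert 0.4 < rep["rmsd_hz"] < 1.3


def test_table_round_trip(tmp_path):
    labels = [(30, "C1'", "H1'"), (31, "C8", "H8")]
    values = np.array([12.345678, -3.2])
    p = tmp_path / "rdc.tsv"
    write_rdc_table(labels, values, p)
    l2, v2 = read_rdc_table(p)
    assert l2 == labels
    assert np.allclose(v2, values)


def test_pales_style_rows(tmp_path):
    p = tmp_path / "pales.tab"
    p.write_text(
        "REMARK back-calculated\n"
        "VARS RESID_I RESNAME_I ATOMNAME_I RESID_J RESNAME_J ATOMNAME_J D\n"
        "FORMAT %d %s %s %d %s %s %f\n"
        "30 G C8 30 G H8 12.50\n"
        "31 U C1' 31 U H1' -4.75\n")
    labels, values = read_rdc_table(p)
    assert labels == [(30, "C8", "H8"), (31, "C1'", "H1'")]
    assert np.allclose(values, [12.50, -4.75])


def test_misaligned_candidate_raises(tmp_path):
    obs = tmp_path / "obs.tsv"
    obs.write_text("30\tC8\tH8\t1.0\n31\tC1'\tH1'\t2.0\n")
    bad = tmp_path / "cand.tsv"
    bad.write_text("30\tC8\tH8\t1.0\n")
    with pytest.raises(ValueError, match="align"):
        load_dataset(obs, [bad])
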