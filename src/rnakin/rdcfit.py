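"""Sparse ensemble weights from residual dipolar couplings.

Solves the convex quadratic program

    min_w || D_obs - sum_i w_i D_calc,i ||^2
    s.t.  w_i >= 0,  0 <= sum_i w_i <= 1

with an active-set method built on non-negative least squares.  The solver
is deterministic and reaches the global optimum of the convex program; the
support of w simultaneously selects the ensemble members and their weights.
A flag switches the sum constraint to strict equality (weights summing to
unity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

SUPPORT_TOL = 1e-6


@dataclass
class RDCDataset:
    observed: np.ndarray            # (k,) Hz
    candidates: np.ndarray          # (s, k) Hz, one row per conformation
    labels: list                    # k tuples (resid, atom1, atom2)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.candidates = np.atleast_2d(
            np.asarray(self.candidates, dtype=float))
        if self.observed.ndim != 1:
            raise ValueError("observed must be a vector")
        k = len(self.observed)
        if k < 1:
            raise ValueError("need at least one coupling")
        if self.candidates.shape[1] != k:
            raise ValueError("candidate rows must match observed length")
        if len(self.labels) != k:
            raise ValueError("labels must match observed length")
        if not (np.all(np.isfinite(self.observed)) and
                np.all(np.isfinite(self.candidates))):
            raise ValueError("non-finite RDC values")

    @property
    def n_candidates(self):
        return self.candidates.shape[0]


@dataclass
class EnsembleWeights:
    w: np.ndarray
    support_tol: float = SUPPORT_TOL
    residual: float = 0.0

    @property
    def support(self):
        return np.where(self.w > self.support_tol)[0]

    def __post_init__(self):
        if np.any(self.w < -1e-9):
            raise ValueError("weights must be non-negative")
        if self.w.sum() > 1.0 + 1e-9:
            raise ValueError("weights must sum to at most 1")


# ---------------------------------------------------------------------------
# solver

def _ecls_on_support(A, b, F):
    """min ||A_F x - b||^2 s.t. sum(x) = 1 via the KKT system."""
    AF = A[:, F]
    G = AF.T @ AF
    k = len(F)
    KKT = np.zeros((k + 1, k + 1))
    KKT[:k, :k] = 2.0 * G
    KKT[:k, k] = 1.0
    KKT[k, :k] = 1.0
    rhs = np.concatenate([2.0 * AF.T @ b, [1.0]])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
    return sol[:k], sol[k]


def _nnls_sum_one(A, b, max_iter=None):
    """Active-set solve of min ||Aw-b||^2, w >= 0, sum w = 1."""
    s = A.shape[1]
    max_iter = max_iter or 20 * (s + 1)
    # start from the single best column
    obj = [np.sum((A[:, i] - b) ** 2) for i in range(s)]
    F = [int(np.argmin(obj))]
    w = np.zeros(s)
    w[F[0]] = 1.0
    lam = 0.0
    for _ in range(max_iter):
        x, lam = _ecls_on_support(A, b, F)
        if np.min(x) < -1e-12:
            # step from current feasible w toward x, stop at the first bound
            wF = w[F]
            alphas = [wF[i] / (wF[i] - x[i]) for i in range(len(F))
                      if x[i] < 0]
            alpha = min(alphas)
            wF = wF + alpha * (x - wF)
            drop = [F[i] for i in range(len(F)) if wF[i] <= 1e-12]
            for i, fi in enumerate(F):
                w[fi] = max(wF[i], 0.0)
            for fi in drop:
                w[fi] = 0.0
                F.remove(fi)
            continue
        w[:] = 0.0
        for i, fi in enumerate(F):
            w[fi] = x[i]
        # bound-constraint optimality: grad_i + lam >= 0 for i not in F
        g = -2.0 * A.T @ (b - A @ w)
        viol = g + lam
        viol[F] = np.inf
        j = int(np.argmin(viol))
        if viol[j] >= -1e-10 * max(1.0, np.abs(g).max()):
            return w
        F.append(j)
    warnings.warn("active-set iteration limit reached; returning best iterate")
    return w


def fit_weights(dataset: RDCDataset, sum_constraint_mode: str = "le",
                support_tol: float = SUPPORT_TOL):
    """Global minimizer of the constrained quadratic program.

    `sum_constraint_mode`: "le" (sum of weights at most one, the default)
    or "eq" (weights sum to unity).  Returns (EnsembleWeights, residual
    norm in Hz).
    """
    if dataset.n_candidates == 0:
        raise ValueError("empty candidate set")
    A = dataset.candidates.T            # k x s
    b = dataset.observed
    if sum_constraint_mode not in ("le", "eq"):
        raise ValueError("sum_constraint_mode must be 'le' or 'eq'")
    if sum_constraint_mode == "le":
        w, _ = scipy.optimize.nnls(A, b)
        if w.sum() > 1.0:
            w = _nnls_sum_one(A, b)
    else:
        w = _nnls_sum_one(A, b)
    w = np.where(w < 0, 0.0, w)
    resid = float(np.linalg.norm(b - A @ w))
    ew = EnsembleWeights(w, support_tol, resid)
    ok, msg = verify_kkt(dataset, w, sum_constraint_mode)
    if not ok:
        warnings.warn(f"KKT verification flagged the solution: {msg}")
    return ew, resid


def verify_kkt(dataset, w, mode, tol=1e-6):
    """Post-hoc check of the first-order optimality conditions."""
    A = dataset.candidates.T
    b = dataset.observed
    g = -2.0 * A.T @ (b - A @ w)
    scale = max(1.0, float(np.abs(g).max()))
    ssum = w.sum()
    support = w > SUPPORT_TOL
    if mode == "le" and ssum < 1.0 - 1e-9:
        mu = 0.0
    else:
        mu = float(-np.mean(g[support])) if support.any() else 0.0
        if mode == "le" and mu < -tol * scale:
            return False, f"multiplier for the sum constraint negative ({mu:g})"
    if support.any() and np.max(np.abs(g[support] + mu)) > tol * scale:
        return False, "gradient not stationary on the support"
    if np.min(g + mu) < -tol * scale:
        return False, "descent direction remains on a zero weight"
    return True, "ok"


# ---------------------------------------------------------------------------
# tables

def read_rdc_table(path):
    """Read one RDC table.

    Two dialects: a TSV with columns (resid, atom1, atom2, D_Hz), or a
    PALES-style whitespace table whose data rows start with an integer
    residue number, contain atom-name tokens, and whose first numeric token
    after the names is taken as the coupling in Hz.  Returns (labels,
    values).
    """
    labels, values = [], []
    with open(path) as fh:
        for line in fh:
            t = line.split()
            if not t or t[0].upper() in ("REMARK", "DATA", "VARS", "FORMAT",
                                         "#"):
                continue
            if line.lstrip().startswith("#"):
                continue
            try:
                resid = int(t[0])
            except ValueError:
                continue
            names = [x for x in t[1:] if any(c.isalpha() for c in x)
                     and not _is_number(x)]
            nums = [x for x in t[1:] if _is_number(x)]
            if len(names) < 2 or not nums:
                continue
            atoms = [nm for nm in names if nm[0] in "HCNOP"][:2]
            if len(atoms) < 2:
                continue
            # drop duplicated residue-number tokens in PALES rows
            d = None
            for x in t[1:]:
                if _is_number(x) and "." in x:
                    d = float(x)
                    break
            if d is None:
                d = float(nums[-1])
            labels.append((resid, atoms[0], atoms[1]))
            values.append(d)
    return labels, np.asarray(values, dtype=float)


def _is_number(x):
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_rdc_table(labels, values, path):
    with open(path, "w") as fh:
        for (resid, a1, a2), v in zip(labels, values):
            fh.write(f"{resid}\t{a1}\t{a2}\t{v:.6f}\n")


def load_dataset(observed_path, candidate_paths) -> RDCDataset:
    """Assemble a dataset from an observed table plus candidate tables.

    Label mismatches raise a ValueError listing the offending bonds.
    """
    labels, obs = read_rdc_table(observed_path)
    rows = []
    for p in candidate_paths:
        cl, cv = read_rdc_table(p)
        if cl != labels:
            missing = [l for l in labels if l not in cl]
            extra = [l for l in cl if l not in labels]
            raise ValueError(
                f"candidate table {p} does not align with observed: "
                f"missing {missing}, unexpected {extra}")
        rows.append(cv)
    return RDCDataset(obs, np.array(rows), labels)


def fit_report(dataset: RDCDataset, weights: EnsembleWeights) -> dict:
    """R^2, RMSD (Hz), ensemble size and a per-bond comparison table."""
    pred = weights.w @ dataset.candidates
    resid = dataset.observed - pred
    k = len(dataset.observed)
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((dataset.observed - dataset.observed.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    table = pd.DataFrame({
        "resid": [l[0] for l in dataset.labels],
        "atom1": [l[1] for l in dataset.labels],
        "atom2": [l[2] for l in dataset.labels],
        "observed_Hz": dataset.observed,
        "predicted_Hz": pred,
    })
    return {"r2": r2, "rmsd_hz": rmsd,
            "ensemble_size": int(len(weights.support)),
            "weights_sum": float(weights.w.sum()),
            "table": table}
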