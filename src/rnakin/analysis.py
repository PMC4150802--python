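"""Ensemble analysis metrics.

C4' RMSD between conformations (after optimal superposition), per-DOF
circular variance profiles across a pool, symmetric Kullback-Leibler
divergence between binned proton chemical-shift distributions, and the RMSD
between measured and predicted shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import circular_variance, superposed_rmsd

PROTON_TYPES = ("H1'", "H2", "H5", "H6", "H8")
N_BINS = 30
PSEUDOCOUNT = 1e-6


def _c4(x):
    if hasattr(x, "c4_coords"):
        return x.c4_coords()
    return np.asarray(x, dtype=float)


def c4_rmsd(conf_a, conf_b) -> float:
    """C4' RMSD in Angstrom after least-squares superposition.

    Accepts Conformation objects or raw (n, 3) C4' coordinate arrays.
    """
    A, B = _c4(conf_a), _c4(conf_b)
    if A.shape != B.shape:
        raise ValueError("conformations have different residue counts")
    return superposed_rmsd(A, B)


def dof_variance_profile(pool) -> pd.DataFrame:
    """Circular variance of every degree of freedom across a pool."""
    confs = getattr(pool, "conformations", pool)
    tree = confs[0].tree
    thetas = np.array([c.dofs() for c in confs])
    var = [circular_variance(thetas[:, k]) for k in range(tree.n)]
    return pd.DataFrame({
        "dof": np.arange(tree.n),
        "label": tree.dof_labels,
        "residue": tree.dof_residue,
        "circular_variance": var,
    })


# ---------------------------------------------------------------------------
# chemical shifts

@dataclass
class ShiftHistogram:
    """30-bin histogram over [mu - 4 sigma, mu + 4 sigma] with pseudocounts
    in empty bins and renormalization, so the divergence is finite."""

    probs: np.ndarray
    edges: np.ndarray

    @classmethod
    def from_values(cls, values, mu=None, sigma=None, n_bins=N_BINS):
        values = np.asarray(values, dtype=float)
        if mu is None:
            mu = float(values.mean())
        if sigma is None:
            sigma = float(values.std(ddof=0))
        if sigma <= 0:
            sigma = 1e-3
        edges = np.linspace(mu - 4.0 * sigma, mu + 4.0 * sigma, n_bins + 1)
        counts, _ = np.histogram(values, bins=edges)
        probs = counts.astype(float)
        probs[probs == 0.0] = PSEUDOCOUNT
        probs /= probs.sum()
        return cls(probs, edges)


def kl_divergence(p, q) -> float:
    """Symmetric Kullback-Leibler divergence (natural log).

    D = (D'(P||Q) + D'(Q||P)) / 2 with D'(P||Q) = sum_i ln(P_i/Q_i) P_i.
    Accepts probability vectors or ShiftHistogram objects on identical bins.
    """
    if isinstance(p, ShiftHistogram) and isinstance(q, ShiftHistogram):
        if not np.allclose(p.edges, q.edges):
            raise ValueError("histograms are binned on different edges")
        P, Q = p.probs, q.probs
    else:
        P = np.asarray(getattr(p, "probs", p), dtype=float)
        Q = np.asarray(getattr(q, "probs", q), dtype=float)
    if P.shape != Q.shape:
        raise ValueError("distributions differ in length")
    if np.any(P <= 0) or np.any(Q <= 0):
        raise ValueError("zero bins; apply pseudocounts first")
    d_pq = float(np.sum(np.log(P / Q) * P))
    d_qp = float(np.sum(np.log(Q / P) * Q))
    return 0.5 * (d_pq + d_qp)


def shift_kl(measured_values, predicted_values, n_bins=N_BINS) -> float:
    """Symmetric KL between measured and predicted shift sets, binned over
    the predicted mean +- 4 predicted standard deviations."""
    pv = np.asarray(predicted_values, dtype=float)
    mu, sigma = float(pv.mean()), float(pv.std(ddof=0))
    P = ShiftHistogram.from_values(measured_values, mu, sigma, n_bins)
    Q = ShiftHistogram.from_values(predicted_values, mu, sigma, n_bins)
    return kl_divergence(P, Q)


def read_shift_table(path) -> pd.DataFrame:
    """TSV with columns residue, proton, ppm (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["residue", "proton", "ppm"])
    if df.iloc[0]["proton"] == "proton":   # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df["residue"] = df["residue"].astype(int)
    df["ppm"] = df["ppm"].astype(float)
    bad = ~df["proton"].isin(PROTON_TYPES)
    if bad.any():
        raise ValueError(
            f"unknown proton types: {sorted(df.loc[bad, 'proton'].unique())}")
    return df


def write_shift_table(df: pd.DataFrame, path):
    df[["residue", "proton", "ppm"]].to_csv(path, sep="\t", header=False,
                                            index=False)


def tag_regions(df: pd.DataFrame, pairs) -> pd.DataFrame:
    """Add a region column: residues in a WC pair are helical."""
    helical = {p.residue_i for p in pairs} | {p.residue_j for p in pairs}
    out = df.copy()
    out["region"] = np.where(out["residue"].isin(helical),
                             "helical", "non-helical")
    return out


def rmsd_cs(measured: pd.DataFrame, predicted: pd.DataFrame):
    """RMSD (ppm) over (residue, proton) records present in both tables.

    Returns (rmsd, unmatched) where unmatched lists records found in only
    one of the tables.
    """
    m = measured.set_index(["residue", "proton"])["ppm"]
    p = predicted.set_index(["residue", "proton"])["ppm"]
    common = m.index.intersection(p.index)
    unmatched = sorted(set(m.index.symmetric_difference(p.index)))
    if len(common) == 0:
        raise ValueError("no records in common")
    diff = (m.loc[common] - p.loc[common]).to_numpy(dtype=float)
    return float(np.sqrt(np.mean(diff ** 2))), unmatched
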