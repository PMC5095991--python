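"""Hand-constructable toy objects and brute-force oracles shared by the tests.

The oracles here are intentionally naive (dense matrices, exhaustive loops)
and independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from seqblup import BreedSpec, GenotypeDataset, PhenotypeTable


def make_toy_dataset(
    dosages,
    positions_bp,
    breed_of,
    *,
    chromosome="1",
    on_array=None,
    info=None,
    sire_of=None,
    age_rank=None,
    breed_specs=None,
):
    """A GenotypeDataset from explicit arrays (one chromosome by default)."""
    dosages = np.asarray(dosages, dtype=np.float32)
    n, p = dosages.shape
    positions_bp = np.asarray(positions_bp, dtype=np.int64)
    breed_of = np.asarray(breed_of, dtype=object)
    chrom = np.repeat(chromosome, p) if np.isscalar(chromosome) else np.asarray(chromosome, dtype=object)

    markers = pd.DataFrame(
        {
            "variant_id": [f"v{c}_{q}" for c, q in zip(chrom, positions_bp)],
            "chromosome": chrom,
            "position_bp": positions_bp,
            "on_array": np.ones(p, dtype=bool) if on_array is None else np.asarray(on_array, dtype=bool),
            "info_score": np.ones(p) if info is None else np.asarray(info, dtype=float),
        }
    )
    breeds_here = list(dict.fromkeys(breed_of))
    pooled = dosages.mean(axis=0) / 2.0
    for b in breeds_here:
        rows = np.flatnonzero(breed_of == b)
        f = dosages[rows].mean(axis=0) / 2.0
        markers[f"maf_{b}"] = np.minimum(f, 1.0 - f)
    markers["maf"] = np.minimum(pooled, 1.0 - pooled)

    if sire_of is None:
        sire_of = [f"{b}_S0" for b in breed_of]
    animals = pd.DataFrame(
        {
            "animal_id": [f"an{i:03d}" for i in range(n)],
            "breed": breed_of,
            "sire_id": list(sire_of),
            "age_rank": np.arange(1, n + 1) if age_rank is None else np.asarray(age_rank),
        }
    )
    if breed_specs is None:
        breed_specs = [
            BreedSpec(b, max(int((breed_of == b).sum()), 1), 0, 0.0, 1000) for b in breeds_here
        ]
    return GenotypeDataset(dosages=dosages, markers=markers, animals=animals, breeds=breed_specs)


def make_toy_phenos(dataset, drp, tbv=None, reliability=0.9, trait="yield"):
    tab = dataset.animals.copy()
    tab["tbv"] = np.zeros(len(tab)) if tbv is None else np.asarray(tbv, dtype=float)
    tab["drp"] = np.asarray(drp, dtype=float)
    tab["drp_reliability"] = reliability
    return PhenotypeTable(tab, trait=trait)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def gls_oracle(X, y, V):
    """Dense generalized least squares: beta, se and Wald p for the last column."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Vi = np.linalg.inv(V)
    A = np.linalg.inv(X.T @ Vi @ X)
    beta = A @ (X.T @ Vi @ y)
    se = np.sqrt(np.diag(A))
    z = beta[-1] / se[-1]
    return beta[-1], se[-1], 2.0 * norm.sf(abs(z))


def sire_covariance(sire_ids, s2s, s2e):
    """Dense V = s2s * ZZ' + s2e * I over a list of sire labels."""
    sire_ids = np.asarray(sire_ids)
    same = sire_ids[:, None] == sire_ids[None, :]
    return s2s * same.astype(float) + s2e * np.eye(len(sire_ids))


def prune_oracle(cand: pd.DataFrame, G: np.ndarray, r2_max: float) -> pd.DataFrame:
    """Exhaustive greedy LD pruning: ascending p, every kept pair compared."""
    order = cand.sort_values(["p_value", "chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
    Gc = np.asarray(G, dtype=float)
    Gc = Gc - Gc.mean(axis=0)
    kept = []
    for i in range(len(order)):
        gi = Gc[:, i]
        if gi @ gi == 0:
            continue
        ok = True
        for j in kept:
            gj = Gc[:, j]
            r2 = (gi @ gj) ** 2 / ((gi @ gi) * (gj @ gj))
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    return order.iloc[kept].reset_index(drop=True)


def interval_oracle(cand: pd.DataFrame, n: int, w: float, p_max=None) -> set:
    """Brute-force peak-interval walk; returns the selected variant ids."""
    pool = cand.copy()
    selected = set()
    while len(pool):
        pool = pool.sort_values(["p_value", "chromosome", "position_bp"], kind="mergesort")
        peak = pool.iloc[0]
        if p_max is not None and peak["p_value"] >= p_max:
            break
        inside = pool[
            (pool["chromosome"] == peak["chromosome"])
            & (abs(pool["position_bp"] - peak["position_bp"]) <= w * 1e6 / 2)
        ]
        selected |= set(inside.iloc[:n]["variant_id"])
        pool = pool.drop(inside.index)
    return selected


def ridge_oracle(Z, y, lam):
    """Mixed-model-equation / ridge solution with an unpenalized intercept."""
    n, p = Z.shape
    X = np.hstack([np.ones((n, 1)), Z])
    D = np.eye(p + 1) * lam
    D[0, 0] = 0.0
    coef = np.linalg.solve(X.T @ X + D, X.T @ y)
    return Z @ coef[1:], coef
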