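"""Single-marker association scans with a random sire effect.

The scans regress deregressed proofs (DRP) on allele dose one variant at a
time, accounting for paternal half-sib covariance through a random sire
effect: ``y = mu + s + beta * g + e`` within a population, and
``y = mu + s + b_breed + beta * g + e`` when populations are pooled, with a
fixed breed effect absorbing between-breed mean differences.

The sire and residual variances are estimated once per population on the
no-marker null model (EM-REML) and then held fixed for every marker; each
marker effect is a generalized-least-squares estimate under that covariance,
tested with a two-sided Wald test against the standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .simdata import GenotypeDataset, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "SireModelFit",
    "AssociationTable",
    "estimate_sire_variance",
    "scan_within_breed",
    "scan_multi_breed",
    "preselect_for_multibreed",
]

#: default marker filters for the sequence-level scans
SCAN_MAF_MIN = 0.005
SCAN_INFO_MIN = 0.60


@dataclass
class SireModelFit:
    """Variance components of the null model ``y = mu + s + e`` for one population."""

    sire_variance: float
    residual_variance: float
    n_sires: int
    converged: bool
    population: str = ""

    @property
    def ratio(self) -> float:
        """sigma2_s / sigma2_e (0 when the sire variance is 0)."""
        return self.sire_variance / self.residual_variance if self.residual_variance > 0 else 0.0


@dataclass
class AssociationTable:
    """Per-variant scan output for one scope (a breed, or ``"multi-breed"``).

    ``records`` columns: ``variant_id chromosome position_bp beta se p_value
    n_used``, sorted by genomic position.
    """

    records: pd.DataFrame
    scope: str
    trait: str = "yield"
    filters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        out = self.records.rename(
            columns={"chromosome": "chrom", "position_bp": "pos", "p_value": "p", "n_used": "n"}
        ).copy()
        out["scope"] = self.scope
        out["trait"] = self.trait
        out[["variant_id", "chrom", "pos", "beta", "se", "p", "n", "scope", "trait"]].to_csv(
            path, sep="\t", index=False
        )
        return path

    @classmethod
    def from_tsv(cls, path) -> "AssociationTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
        scope = str(df["scope"].iloc[0]) if len(df) else ""
        trait = str(df["trait"].iloc[0]) if len(df) else "yield"
        records = df.rename(
            columns={"chrom": "chromosome", "pos": "position_bp", "p": "p_value", "n": "n_used"}
        )[["variant_id", "chromosome", "position_bp", "beta", "se", "p_value", "n_used"]]
        return cls(records=records, scope=scope, trait=trait)


# ---------------------------------------------------------------------------
# sire variance (EM-REML on the null model)
# ---------------------------------------------------------------------------


def estimate_sire_variance(
    phenos: PhenotypeTable,
    population: str,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> SireModelFit:
    """EM-REML estimates of sire and residual variance under ``y = mu + s + e``.

    Deterministic given the data.  When the design is confounded (fewer than
    two sires, or no sire with at least two offspring) the fit falls back to
    a residual-only model with ``converged=False`` and a logged warning.
    """
    sub = phenos.for_breed(population)
    if len(sub) == 0:
        raise ValueError(f"no animals for population {population!r}")
    y = sub["drp"].to_numpy(dtype=float)
    sires, sire_idx = np.unique(sub["sire_id"].to_numpy(), return_inverse=True)
    n, k = y.size, sires.size
    counts = np.bincount(sire_idx, minlength=k).astype(float)

    if k < 2 or counts.max() < 2:
        logger.warning(
            "sire effect confounded for %s (%d sires, max family %d); residual-only fit",
            population, k, int(counts.max()),
        )
        return SireModelFit(0.0, float(np.var(y, ddof=1)), k, False, population)

    var_y = float(np.var(y, ddof=1))
    s2s, s2e = 0.25 * var_y, 0.75 * var_y
    group_sums = np.bincount(sire_idx, weights=y, minlength=k)
    converged = False
    for _ in range(max_iter):
        # GLS intercept under the current variances
        w = 1.0 / (s2e + counts * s2s)
        mu = float(np.sum(w * group_sums) / np.sum(w * counts))
        # sire BLUP and prediction-error variance
        shrink = counts * s2s / (s2e + counts * s2s)
        s_hat = shrink * (group_sums / counts - mu)
        pev = s2s * s2e / (s2e + counts * s2s)
        resid = y - mu - s_hat[sire_idx]
        s2s_new = float((s_hat @ s_hat + pev.sum()) / k)
        s2e_new = float((resid @ y - 0.0) / (n - 1))
        s2e_new = max(s2e_new, 1e-12)
        s2s_new = max(s2s_new, 0.0)
        if s2s_new < 1e-6 * s2e_new:  # boundary: sire variance vanishes
            s2s, s2e = s2s_new, s2e_new
            converged = True
            break
        if abs(s2s_new - s2s) < tol * (1 + s2s) and abs(s2e_new - s2e) < tol * (1 + s2e):
            s2s, s2e = s2s_new, s2e_new
            converged = True
            break
        s2s, s2e = s2s_new, s2e_new
    return SireModelFit(s2s, s2e, k, converged, population)


# ---------------------------------------------------------------------------
# GLS machinery (block-diagonal sire covariance)
# ---------------------------------------------------------------------------


class _SireGLS:
    """Weighted inner products under ``V = sigma2_s * ZZ' + sigma2_e * I``.

    ``V`` is block diagonal over sire families, so ``x' V^-1 y`` reduces to
    ``(x'y - sum_k c_k S_k(x) S_k(y)) / sigma2_e`` with per-family constants
    ``c_k = sigma2_s / (sigma2_e + n_k sigma2_s)`` and family sums ``S_k``.
    ``sigma2_s`` and ``sigma2_e`` may vary by family (nesting within breed).
    """

    def __init__(self, sire_idx: np.ndarray, s2s_per_family: np.ndarray, s2e: float):
        self.sire_idx = sire_idx
        self.k = int(sire_idx.max()) + 1 if sire_idx.size else 0
        self.counts = np.bincount(sire_idx, minlength=self.k).astype(float)
        self.s2e = float(s2e)
        self.c = s2s_per_family / (self.s2e + self.counts * s2s_per_family)

    def group_sums(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 1:
            return np.bincount(self.sire_idx, weights=x, minlength=self.k)
        out = np.zeros((self.k, x.shape[1]))
        np.add.at(out, self.sire_idx, x)
        return out

    def inner(self, x, y, sx=None, sy=None):
        """x' V^-1 y; x and y may be 1-D or (n, m) with matching group sums."""
        sx = self.group_sums(x) if sx is None else sx
        sy = self.group_sums(y) if sy is None else sy
        if x.ndim == 1 and y.ndim == 1:
            return (x @ y - np.sum(self.c * sx * sy)) / self.s2e
        if x.ndim == 1:
            return (x @ y - (self.c * sx) @ sy) / self.s2e
        if y.ndim == 1:
            return (x.T @ y - sx.T @ (self.c * sy)) / self.s2e
        return (x.T @ y - sx.T @ (self.c[:, None] * sy)) / self.s2e


def _wald(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(beta / se)
    return 2.0 * norm.sf(z)


def _marker_filter(dataset: GenotypeDataset, maf: np.ndarray, maf_min: float, info_min: float):
    info = dataset.markers["info_score"].to_numpy(dtype=float)
    return (maf >= maf_min) & (maf > 0.0) & (info >= info_min)


def scan_within_breed(
    dataset: GenotypeDataset,
    phenos: PhenotypeTable,
    population: str,
    fit: SireModelFit,
    maf_min: float = SCAN_MAF_MIN,
    info_min: float = SCAN_INFO_MIN,
) -> AssociationTable:
    """GLS single-marker scan within one population.

    Variants with within-population MAF below ``maf_min`` or INFO score below
    ``info_min`` are excluded before testing; zero-variance (monomorphic)
    markers among the survivors are dropped with a logged reason.
    """
    if fit.population and fit.population != population:
        raise ValueError(f"fit is for {fit.population!r}, not {population!r}")
    sub = phenos.for_breed(population)
    rows = dataset.breed_rows(population)
    geno_ids = dataset.animals["animal_id"].to_numpy()[rows]
    sub = sub.set_index("animal_id").reindex(geno_ids).dropna(subset=["drp"]).reset_index()
    keep_rows = rows[np.isin(geno_ids, sub["animal_id"].to_numpy())]
    y = sub["drp"].to_numpy(dtype=float)

    G = dataset.dosages[keep_rows].astype(np.float64)
    f = G.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    mask = _marker_filter(dataset, maf, maf_min, info_min)

    _, sire_idx = np.unique(sub["sire_id"].to_numpy(), return_inverse=True)
    gls = _SireGLS(sire_idx, np.full(int(sire_idx.max()) + 1, fit.sire_variance), fit.residual_variance)

    ones = np.ones(y.size)
    records = _scan_core(gls, ones[:, None], y, G, mask, dataset)
    return AssociationTable(
        records=records,
        scope=population,
        trait=phenos.trait,
        filters={"maf_min": maf_min, "info_min": info_min},
    )


def _scan_core(gls: _SireGLS, W: np.ndarray, y: np.ndarray, G: np.ndarray, mask: np.ndarray,
               dataset: GenotypeDataset) -> pd.DataFrame:
    """GLS effect of each masked column of G, adjusting for fixed covariates W."""
    n = y.size
    sW, sy = gls.group_sums(W), gls.group_sums(y)
    A = gls.inner(W, W, sW, sW)          # (p, p)
    Wy = gls.inner(W, y, sW, sy)         # (p,)
    Ainv = np.linalg.inv(np.atleast_2d(A))

    cols = np.flatnonzero(mask)
    Gm = G[:, cols]
    sG = gls.group_sums(Gm)
    WG = gls.inner(W, Gm, sW, sG)        # (p, m)
    gy = gls.inner(Gm, y, sG, sy).ravel()  # (m,)
    gg = (np.einsum("ij,ij->j", Gm, Gm) - np.einsum("kj,kj->j", sG, gls.c[:, None] * sG)) / gls.s2e

    adj = np.einsum("pm,pq,qm->m", WG, Ainv, WG)
    denom = gg - adj
    good = denom > 1e-10
    if not np.all(good):
        logger.info("dropping %d zero-variance markers after covariate adjustment", int((~good).sum()))
    beta = np.full(cols.size, np.nan)
    se = np.full(cols.size, np.nan)
    num = gy - WG.T @ (Ainv @ Wy)
    beta[good] = num[good] / denom[good]
    se[good] = np.sqrt(1.0 / denom[good])
    p = _wald(beta, se)

    m = dataset.markers
    rec = pd.DataFrame(
        {
            "variant_id": m["variant_id"].to_numpy()[cols],
            "chromosome": m["chromosome"].to_numpy()[cols],
            "position_bp": m["position_bp"].to_numpy()[cols],
            "beta": beta,
            "se": se,
            "p_value": p,
            "n_used": n,
        }
    )
    rec = rec.loc[np.isfinite(rec["beta"])].reset_index(drop=True)
    return rec.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)


def scan_multi_breed(
    datasets,
    phenos: PhenotypeTable,
    candidate_variants,
    fits,
    maf_min: float = SCAN_MAF_MIN,
    info_min: float = SCAN_INFO_MIN,
) -> AssociationTable:
    """Pooled scan across populations with a fixed breed effect.

    ``datasets`` is either one :class:`GenotypeDataset` holding all breeds or
    a mapping ``breed -> GenotypeDataset``; ``fits`` maps breed to its
    :class:`SireModelFit`.  Breed enters as a reference-coded fixed effect,
    sires are nested within breed with each population's estimated sire
    variance, and the residual variance is pooled (animal-weighted mean of
    the per-population estimates).  A single population reduces exactly to
    :func:`scan_within_breed`.
    """
    from .simdata import GenotypeDataset as _GD

    if isinstance(datasets, _GD):
        per_breed = {b: datasets for b in pd.unique(phenos.table["breed"])}
    else:
        per_breed = dict(datasets)
    breeds = [b for b in per_breed if b in set(phenos.table["breed"])]
    if not breeds:
        raise ValueError("no overlapping breeds between datasets and phenotypes")
    candidate_variants = list(candidate_variants)

    blocks, ys, sire_labels, breed_labels = [], [], [], []
    info_rows = None
    for b in breeds:
        ds = per_breed[b]
        sub = phenos.for_breed(b)
        rows = ds.breed_rows(b)
        geno_ids = ds.animals["animal_id"].to_numpy()[rows]
        sub = sub.set_index("animal_id").reindex(geno_ids).dropna(subset=["drp"]).reset_index()
        keep = rows[np.isin(geno_ids, sub["animal_id"].to_numpy())]
        cols = ds.marker_indices(candidate_variants)
        blocks.append(ds.dosages[np.ix_(keep, cols)].astype(np.float64))
        ys.append(sub["drp"].to_numpy(dtype=float))
        sire_labels.append(sub["sire_id"].astype(str).to_numpy())
        breed_labels.append(np.repeat(b, len(sub)))
        if info_rows is None:
            mm = ds.markers.iloc[cols]
            info_rows = mm

    G = np.vstack(blocks)
    y = np.concatenate(ys)
    breed_arr = np.concatenate(breed_labels)
    sire_arr = np.array([f"{b}:{s}" for b, s in zip(breed_arr, np.concatenate(sire_labels))])

    # pooled residual, per-family (breed-specific) sire variance
    n_per = np.array([len(v) for v in ys], dtype=float)
    s2e = float(sum(fits[b].residual_variance * n for b, n in zip(breeds, n_per)) / n_per.sum())
    uniq_sires, sire_idx = np.unique(sire_arr, return_inverse=True)
    fam_breed = np.array([s.split(":", 1)[0] for s in uniq_sires])
    s2s_fam = np.array([fits[b].sire_variance for b in fam_breed])
    gls = _SireGLS(sire_idx, s2s_fam, s2e)

    # reference-coded breed dummies
    W = np.ones((y.size, 1))
    for b in breeds[1:]:
        W = np.hstack([W, (breed_arr == b).astype(float)[:, None]])

    f = G.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    info = info_rows["info_score"].to_numpy(dtype=float)
    mask = (maf >= maf_min) & (maf > 0.0) & (info >= info_min)
    if not mask.all():
        logger.info("multi-breed scan: %d candidates dropped by MAF/INFO/monomorphism", int((~mask).sum()))

    sub_ds = GenotypeDatasetView(info_rows)
    records = _scan_core(gls, W, y, G, mask, sub_ds)
    return AssociationTable(
        records=records,
        scope="multi-breed",
        trait=phenos.trait,
        filters={"maf_min": maf_min, "info_min": info_min},
    )


class GenotypeDatasetView:
    """Minimal marker-table adapter used by the shared scan core."""

    def __init__(self, markers: pd.DataFrame):
        self.markers = markers.reset_index(drop=True)


def preselect_for_multibreed(
    within_tables,
    holstein_threshold: float = 1e-5,
    other_threshold: float = 1e-3,
    holstein_breeds=(),
) -> list:
    """Candidate variants for the pooled scan.

    Takes within-population scan tables (possibly several traits per
    population) and returns the union of variants with ``p`` strictly below
    the population-specific threshold in at least one table: the stricter
    threshold for populations named in ``holstein_breeds``, the looser one
    for the rest.  Sorted by (chromosome, position) for determinism.
    """
    holstein = set(holstein_breeds)
    hits = []
    for tab in within_tables:
        thr = holstein_threshold if tab.scope in holstein else other_threshold
        rec = tab.records
        sel = rec.loc[rec["p_value"] < thr, ["variant_id", "chromosome", "position_bp"]]
        hits.append(sel)
    if not hits:
        return []
    allhits = pd.concat(hits, ignore_index=True).drop_duplicates("variant_id")
    allhits = allhits.sort_values(["chromosome", "position_bp"], kind="mergesort")
    return allhits["variant_id"].tolist()
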