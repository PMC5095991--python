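"""Synthetic multi-breed genotype and phenotype data.

The generator emulates the statistical structure that GWAS-based variant
preselection and multi-breed genomic prediction rest on:

* several populations diverged from a common ancestral gene pool by
  breed-specific amounts of drift (a Balding–Nichols frequency model
  parameterized by per-breed FST);
* within-breed linkage disequilibrium that decays with map distance, while
  LD phase agreement between breeds decays faster the more diverged the
  breeds are — so LD persists over shorter ranges across breeds than within;
* paternal half-sib family structure with genotypes transmitted from
  genotyped sires (recombination at ~1 crossover per 100 Mb);
* a trait controlled by a set of causative QTL whose allele-substitution
  effects are correlated across breeds, plus a polygenic remainder
  transmitted through the sire families;
* deregressed proofs (DRP) = true breeding value + independent noise, with
  the noise variance set so the squared accuracy of DRP equals a target
  reliability, standardized to mean 0 / variance 1 within breed.

Dosages are stored on the 0–2 scale.  Every draw is reproducible from the
seed passed to the generating function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "BreedSpec",
    "MarkerMeta",
    "GenotypeDataset",
    "TraitArchitecture",
    "PhenotypeTable",
    "SimulationConfig",
    "default_breeds",
    "make_marker_map",
    "simulate_breed_frequencies",
    "simulate_genotypes",
    "simulate_architecture",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

#: recombination rate used for paternal gametes, crossovers per Mb (~1 Morgan / 100 Mb)
RECOMB_PER_MB = 0.01


@dataclass(frozen=True)
class BreedSpec:
    """One population: its size, divergence from the ancestral pool and family structure.

    Parameters
    ----------
    name
        Breed label, used throughout as the population identifier.
    n_training, n_validation
        Number of phenotyped animals in the training and validation sets.
    fst_from_ancestral
        Wright's FST between this breed and the common ancestral population;
        0 means no drift.  Two breeds with small FST values are nearly
        identical populations; large values give distantly related breeds.
    sire_family_size
        Average paternal half-sib family size; the number of sires is
        ``ceil(n_animals / sire_family_size)``.
    holstein_like
        Marks the large, well-powered populations whose GWAS results are
        held to stricter preselection thresholds.
    """

    name: str
    n_training: int
    n_validation: int
    fst_from_ancestral: float
    sire_family_size: int = 20
    holstein_like: bool = False

    def __post_init__(self) -> None:
        if self.n_training <= 0:
            raise ValueError(f"n_training must be > 0 for breed {self.name}")
        if self.n_validation < 0:
            raise ValueError(f"n_validation must be >= 0 for breed {self.name}")
        if not (0.0 <= self.fst_from_ancestral < 1.0):
            raise ValueError(f"fst_from_ancestral must be in [0, 1) for breed {self.name}")
        if self.sire_family_size < 1:
            raise ValueError("sire_family_size must be >= 1")

    @property
    def n_animals(self) -> int:
        return self.n_training + self.n_validation


@dataclass(frozen=True)
class MarkerMeta:
    """Metadata for a single variant."""

    variant_id: str
    chromosome: str
    position_bp: int
    on_array: bool
    maf_per_breed: dict
    info_score: float


@dataclass
class GenotypeDataset:
    """Dosage genotypes plus marker and animal metadata for several breeds.

    Attributes
    ----------
    dosages
        ``(n_animals, n_markers)`` array of allele doses in [0, 2].
    markers
        One row per variant: ``variant_id chromosome position_bp on_array
        info_score maf`` plus one ``maf_<breed>`` column per breed.
    animals
        One row per animal: ``animal_id breed sire_id age_rank``.  Higher
        ``age_rank`` means younger.  ``sire_id`` may refer to a founder that
        is not itself in the table.
    breeds
        The :class:`BreedSpec` list the data were generated under (or
        reconstructed from on reading).
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    animals: pd.DataFrame
    breeds: list

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.animals), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animals)} animals x {len(self.markers)} markers"
            )

    @property
    def breed_names(self) -> list:
        return [b.name for b in self.breeds]

    def breed_spec(self, name: str) -> BreedSpec:
        for b in self.breeds:
            if b.name == name:
                return b
        raise KeyError(f"unknown breed {name!r}")

    def breed_rows(self, name: str) -> np.ndarray:
        """Row indices of animals belonging to ``name``."""
        return np.flatnonzero((self.animals["breed"] == name).to_numpy())

    def marker_indices(self, variant_ids) -> np.ndarray:
        """Column indices for the given variant ids; raises on a missing id."""
        lookup = pd.Index(self.markers["variant_id"])
        idx = lookup.get_indexer(list(variant_ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(variant_ids, idx) if i < 0]
            raise KeyError(f"variants not in dataset: {missing[:5]}")
        return idx

    def dosage_for(self, variant_ids, animal_rows=None) -> np.ndarray:
        cols = self.marker_indices(variant_ids)
        sub = self.dosages[:, cols] if animal_rows is None else self.dosages[np.ix_(animal_rows, cols)]
        return np.asarray(sub, dtype=np.float64)

    def marker_meta(self, variant_id: str) -> MarkerMeta:
        row = self.markers.loc[self.markers["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        r = row.iloc[0]
        maf = {b: float(r[f"maf_{b}"]) for b in self.breed_names if f"maf_{b}" in row.columns}
        return MarkerMeta(
            variant_id=str(r["variant_id"]),
            chromosome=str(r["chromosome"]),
            position_bp=int(r["position_bp"]),
            on_array=bool(r["on_array"]),
            maf_per_breed=maf,
            info_score=float(r["info_score"]),
        )


@dataclass
class TraitArchitecture:
    """The causal truth: QTL positions and breed-specific substitution effects.

    ``effects_per_breed`` is ``(n_qtl, n_breeds)`` in trait units per allele
    dose, columns ordered as ``breed_names``.  ``polygenic_variance`` is the
    per-breed variance of the polygenic remainder (trait units squared).
    """

    qtl_variant_ids: list
    effects_per_breed: np.ndarray
    breed_names: list
    cross_breed_corr: np.ndarray
    polygenic_variance: float
    trait: str = "yield"

    def __post_init__(self) -> None:
        c = np.asarray(self.cross_breed_corr, dtype=float)
        if c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
            raise ValueError("cross_breed_corr must be square symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("cross_breed_corr must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("cross_breed_corr must be positive semidefinite")


@dataclass
class PhenotypeTable:
    """Per-animal phenotypes: truth (TBV) plus deregressed proofs (DRP).

    ``table`` columns: ``animal_id breed sire_id age_rank tbv drp
    drp_reliability``.  DRP are standardized to mean 0 / variance 1 within
    each breed; TBV are kept on the raw trait scale for testing.
    """

    table: pd.DataFrame
    trait: str = "yield"

    def for_breed(self, breed: str) -> pd.DataFrame:
        return self.table.loc[self.table["breed"] == breed]

    def subset(self, animal_ids) -> "PhenotypeTable":
        mask = self.table["animal_id"].isin(set(animal_ids))
        return PhenotypeTable(self.table.loc[mask].reset_index(drop=True), trait=self.trait)


# ---------------------------------------------------------------------------
# frequency and genotype generation
# ---------------------------------------------------------------------------


def simulate_breed_frequencies(ancestral_freqs, breeds, seed: int) -> np.ndarray:
    """Draw per-breed allele frequencies around the ancestral frequencies.

    Uses the Balding–Nichols model: for ancestral frequency ``p`` and breed
    divergence ``F``, the breed frequency is Beta distributed with mean ``p``
    and variance ``F p (1 - p)``.  ``F = 0`` returns the ancestral
    frequencies unchanged; fixed ancestral alleles (p of 0 or 1) stay fixed.

    Returns an ``(n_breeds, n_loci)`` array.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("ancestral frequencies must be finite and in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.empty((len(breeds), p.size))
    for j, b in enumerate(breeds):
        f = b.fst_from_ancestral
        if f == 0.0:
            out[j] = p
            continue
        scale = (1.0 - f) / f
        interior = (p > 0.0) & (p < 1.0)
        row = p.copy()
        pi = p[interior]
        row[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
        out[j] = row
    return out


def make_marker_map(
    n_markers: int, chrom_length_mb: float = 100.0, n_chromosomes: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Random (sorted, distinct) marker positions on ``n_chromosomes`` chromosomes."""
    rng = np.random.default_rng(seed)
    per = [n_markers // n_chromosomes] * n_chromosomes
    per[-1] += n_markers - sum(per)
    frames = []
    for c, n in enumerate(per, start=1):
        pos = np.sort(rng.choice(int(chrom_length_mb * 1e6), size=n, replace=False)) + 1
        frames.append(pd.DataFrame({"chromosome": str(c), "position_bp": pos.astype(np.int64)}))
    return pd.concat(frames, ignore_index=True)


def _gaussian_threshold(freq: np.ndarray) -> np.ndarray:
    # allele "1" carried when latent z < Phi^-1(freq); +-inf handles fixed loci
    with np.errstate(divide="ignore"):
        return norm.ppf(np.clip(freq, 0.0, 1.0))


def _ar1_haplotypes(n_hap, tau, r_adj, signs, rng):
    """Binary haplotypes from a Gaussian-copula AR(1) along the marker map.

    ``tau`` are per-marker thresholds, ``r_adj`` the latent correlation with
    the previous marker (0 at chromosome starts), ``signs`` the per-interval
    LD phase (+-1).  Marginal frequencies are exact; adjacent-marker LD is
    controlled by ``r_adj``.
    """
    n_markers = tau.size
    haps = np.empty((n_hap, n_markers), dtype=np.uint8)
    z = rng.standard_normal(n_hap)
    haps[:, 0] = z < tau[0]
    for m in range(1, n_markers):
        r = r_adj[m] * signs[m]
        z = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n_hap)
        haps[:, m] = z < tau[m]
    return haps


def _transmit_paternal(sire_haps, sire_of, d_mb, new_chrom, rng):
    """Gametes from genotyped sires: mosaic of each sire's two haplotypes."""
    n_off = sire_of.size
    n_markers = d_mb.size
    p_switch = np.clip(d_mb * RECOMB_PER_MB, 0.0, 0.5)
    switches = rng.random((n_off, n_markers)) < p_switch[None, :]
    # independent chromosome start -> resample the carried haplotype
    switches[:, new_chrom] = rng.integers(0, 2, size=(n_off, int(new_chrom.sum()))).astype(bool)
    which = np.logical_xor.accumulate(switches, axis=1)
    hap_a = sire_haps[2 * sire_of]
    hap_b = sire_haps[2 * sire_of + 1]
    return np.where(which, hap_b, hap_a)


def simulate_genotypes(
    freqs: np.ndarray,
    marker_map: pd.DataFrame,
    ld_decay: float,
    breeds,
    seed: int,
    *,
    phase_divergence_scale: float = 3.0,
    array_spacing: int = 50,
    array_min_maf: float = 0.15,
    info_beta: tuple | None = None,
) -> GenotypeDataset:
    """Generate dosage genotypes for all breeds.

    Haplotypes follow a first-order Gaussian-copula process along the map:
    the latent correlation between markers ``d`` Mb apart is
    ``ld_decay ** d``, so within-breed LD decays smoothly with distance.
    Each adjacent-marker interval carries an LD phase sign; breeds flip the
    ancestral phase independently with probability
    ``min(1, phase_divergence_scale * fst)``, so the more diverged two breeds
    are, the faster their LD phase agreement — and hence across-breed LD —
    decays with distance.  Dosage = paternal + maternal haplotype; paternal
    haplotypes are recombined copies of a genotyped sire's pair, maternal
    haplotypes are fresh draws from the breed's process.

    ``array_spacing`` controls the simulated 50K-style panel: roughly one of
    every ``array_spacing`` common variants (mean-frequency MAF above
    ``array_min_maf``) is flagged ``on_array``.  ``info_beta`` optionally
    draws imputation INFO scores from a Beta(a, b); the default is a point
    mass at 1.0.
    """
    if not (0.0 <= ld_decay < 1.0):
        raise ValueError("ld_decay must be in [0, 1)")
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (len(breeds), len(marker_map)):
        raise ValueError("freqs must be (n_breeds, n_markers)")

    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    same_chrom = np.concatenate([[False], chrom[1:] == chrom[:-1]])
    if np.any((np.diff(pos) <= 0) & same_chrom[1:]):
        raise ValueError("positions must be strictly increasing within chromosome")
    d_mb = np.zeros(len(marker_map))
    d_mb[1:] = np.where(same_chrom[1:], np.diff(pos) / 1e6, np.inf)
    d_mb[0] = np.inf
    new_chrom = ~same_chrom
    with np.errstate(over="ignore"):
        r_adj = np.where(np.isfinite(d_mb), ld_decay ** d_mb, 0.0) if ld_decay > 0 else np.zeros_like(d_mb)

    rng = np.random.default_rng(seed)
    n_markers = len(marker_map)
    anc_signs = np.where(rng.random(n_markers) < 0.5, 1.0, -1.0)

    dosage_blocks = []
    animal_frames = []
    for j, b in enumerate(breeds):
        phi = min(1.0, phase_divergence_scale * b.fst_from_ancestral)
        flip = rng.random(n_markers) < phi
        signs = np.where(flip, np.where(rng.random(n_markers) < 0.5, 1.0, -1.0), anc_signs)
        tau = _gaussian_threshold(freqs[j])

        n_sires = max(1, int(np.ceil(b.n_animals / b.sire_family_size)))
        sire_haps = _ar1_haplotypes(2 * n_sires, tau, r_adj, signs, rng)
        maternal = _ar1_haplotypes(b.n_animals, tau, r_adj, signs, rng)
        sire_of = np.arange(b.n_animals) % n_sires
        paternal = _transmit_paternal(sire_haps, sire_of, d_mb, new_chrom, rng)
        dosage_blocks.append((paternal + maternal).astype(np.float32))

        animal_frames.append(
            pd.DataFrame(
                {
                    "animal_id": [f"{b.name}_{i:05d}" for i in range(b.n_animals)],
                    "breed": b.name,
                    "sire_id": [f"{b.name}_S{s:04d}" for s in sire_of],
                    "age_rank": np.arange(1, b.n_animals + 1),
                }
            )
        )

    dosages = np.vstack(dosage_blocks)
    animals = pd.concat(animal_frames, ignore_index=True)

    markers = marker_map.copy().reset_index(drop=True)
    markers.insert(0, "variant_id", [f"var_{c}_{p}" for c, p in zip(chrom, pos)])

    mean_freq = freqs.mean(axis=0)
    mean_maf = np.minimum(mean_freq, 1.0 - mean_freq)
    on_array = np.zeros(n_markers, dtype=bool)
    common = np.flatnonzero(mean_maf >= array_min_maf)
    if common.size:
        target = max(1, n_markers // array_spacing)
        picks = common[np.linspace(0, common.size - 1, min(target, common.size)).round().astype(int)]
        on_array[np.unique(picks)] = True
    markers["on_array"] = on_array
    if info_beta is None:
        markers["info_score"] = 1.0
    else:
        a, b_ = info_beta
        markers["info_score"] = rng.beta(a, b_, size=n_markers)

    # realized per-breed and pooled MAF from the stored dosages
    row0 = 0
    pooled = dosages.mean(axis=0) / 2.0
    for b in breeds:
        block = dosages[row0 : row0 + b.n_animals]
        f = block.mean(axis=0) / 2.0
        markers[f"maf_{b.name}"] = np.minimum(f, 1.0 - f)
        row0 += b.n_animals
    markers["maf"] = np.minimum(pooled, 1.0 - pooled)

    return GenotypeDataset(dosages=dosages, markers=markers, animals=animals, breeds=list(breeds))


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------


def simulate_architecture(
    dataset: GenotypeDataset,
    n_qtl: int,
    cross_breed_corr: np.ndarray,
    qtl_variance_fraction: float,
    seed: int,
    *,
    exclude_array: bool = True,
    min_maf: float = 0.05,
    genetic_variance: float = 1.0,
    trait: str = "yield",
) -> TraitArchitecture:
    """Sample causative QTL and their breed-correlated substitution effects.

    QTL are drawn among sequence variants (off-array by default, so the
    simulated chip does not tag them directly) with pooled MAF at least
    ``min_maf``.  Per-breed effect vectors are multivariate normal with the
    target cross-breed correlation, then rescaled per breed so the realized
    QTL genic variance equals ``qtl_variance_fraction * genetic_variance``
    (column scaling leaves the correlation untouched); the polygenic
    remainder gets the rest.
    """
    if not (0.0 <= qtl_variance_fraction <= 1.0):
        raise ValueError("qtl_variance_fraction must be in [0, 1]")
    corr = np.atleast_2d(np.asarray(cross_breed_corr, dtype=float))
    n_breeds = len(dataset.breeds)
    if corr.shape != (n_breeds, n_breeds):
        raise ValueError(f"cross_breed_corr must be {n_breeds}x{n_breeds}")
    eig = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    if eig.min() < -1e-8:
        raise ValueError("cross_breed_corr is not positive semidefinite")

    rng = np.random.default_rng(seed)
    m = dataset.markers
    eligible = m["maf"].to_numpy() >= min_maf
    if exclude_array:
        eligible &= ~m["on_array"].to_numpy()
    candidates = np.flatnonzero(eligible)
    if n_qtl > candidates.size:
        raise ValueError(f"requested {n_qtl} QTL but only {candidates.size} eligible variants")

    qtl_idx = np.sort(rng.choice(candidates, size=n_qtl, replace=False))
    qtl_ids = m["variant_id"].to_numpy()[qtl_idx].tolist()

    if n_qtl == 0 or qtl_variance_fraction == 0.0:
        effects = np.zeros((n_qtl, n_breeds))
        return TraitArchitecture(qtl_ids, effects, dataset.breed_names, corr, genetic_variance, trait)

    # PSD-safe factor (eigen decomposition instead of Cholesky)
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    effects = rng.standard_normal((n_qtl, n_breeds)) @ factor.T

    target_var = qtl_variance_fraction * genetic_variance
    for j, name in enumerate(dataset.breed_names):
        rows = dataset.breed_rows(name)
        g = dataset.dosages[np.ix_(rows, qtl_idx)].astype(np.float64)
        realized = float(np.var(g @ effects[:, j]))
        if realized <= 0:
            raise ValueError(f"QTL genic variance is zero in breed {name}; increase min_maf or n_qtl")
        effects[:, j] *= np.sqrt(target_var / realized)

    polygenic = genetic_variance * (1.0 - qtl_variance_fraction)
    return TraitArchitecture(qtl_ids, effects, dataset.breed_names, corr, polygenic, trait)


def simulate_phenotypes(
    dataset: GenotypeDataset,
    arch: TraitArchitecture,
    target_drp_reliability: float,
    seed: int,
) -> PhenotypeTable:
    """True breeding values and deregressed proofs.

    TBV = QTL genic value (breed-specific effects) + polygenic term, the
    latter transmitted through sire families (half the sire's polygenic
    value plus a Mendelian-sampling deviation).  DRP add independent noise
    with variance ``var(TBV) * (1 - rel) / rel`` so that the squared
    correlation between TBV and DRP equals the target reliability, then are
    standardized within breed.  ``target_drp_reliability = 1`` gives DRP
    exactly equal to the standardized TBV.
    """
    if not (0.0 < target_drp_reliability <= 1.0):
        raise ValueError("target_drp_reliability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    animals = dataset.animals
    qtl_idx = dataset.marker_indices(arch.qtl_variant_ids) if arch.qtl_variant_ids else np.array([], dtype=int)

    tbv = np.zeros(len(animals))
    drp = np.zeros(len(animals))
    for j, name in enumerate(dataset.breed_names):
        rows = dataset.breed_rows(name)
        if qtl_idx.size:
            g = dataset.dosages[np.ix_(rows, qtl_idx)].astype(np.float64)
            genic = g @ arch.effects_per_breed[:, j]
        else:
            genic = np.zeros(rows.size)

        sires = animals["sire_id"].to_numpy()[rows]
        uniq, inv = np.unique(sires, return_inverse=True)
        s_poly = rng.standard_normal(uniq.size) * np.sqrt(arch.polygenic_variance)
        mend = rng.standard_normal(rows.size) * np.sqrt(0.75 * arch.polygenic_variance)
        poly = 0.5 * s_poly[inv] + mend

        bv = genic + poly
        tbv[rows] = bv
        var_bv = float(np.var(bv))
        if target_drp_reliability == 1.0 or var_bv == 0.0:
            raw = bv.copy()
        else:
            noise_var = var_bv * (1.0 - target_drp_reliability) / target_drp_reliability
            raw = bv + rng.standard_normal(rows.size) * np.sqrt(noise_var)
        sd = raw.std()
        drp[rows] = (raw - raw.mean()) / (sd if sd > 0 else 1.0)

    table = animals.copy()
    table["tbv"] = tbv
    table["drp"] = drp
    table["drp_reliability"] = target_drp_reliability
    return PhenotypeTable(table, trait=arch.trait)


# ---------------------------------------------------------------------------
# configuration and one-call generation
# ---------------------------------------------------------------------------


def default_breeds() -> list:
    """Scaled-down analogues of two near-identical Holstein-like populations,
    a moderately related red-breed population and a distant Jersey-like one."""
    return [
        BreedSpec("HOL1", 1000, 250, 0.010, 20, holstein_like=True),
        BreedSpec("HOL2", 1000, 250, 0.015, 20, holstein_like=True),
        BreedSpec("RED", 750, 190, 0.050, 15),
        BreedSpec("JER", 500, 125, 0.150, 15),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The defaults give one 100-Mb chromosome with ~10,000 sequence variants,
    ~200 of them flagged as array (chip) markers, 50 off-array QTL whose
    effects correlate 0.8 across breeds and explain one third of the genetic
    variance (~30% of phenotypic variance at DRP reliability 0.9).
    """

    breeds: list = field(default_factory=default_breeds)
    n_markers: int = 10_000
    n_chromosomes: int = 1
    chrom_length_mb: float = 100.0
    ld_decay: float = 0.01
    phase_divergence_scale: float = 3.0
    array_spacing: int = 50
    array_min_maf: float = 0.15
    info_beta: tuple | None = None
    n_qtl: int = 50
    cross_breed_effect_corr: float = 0.8
    qtl_variance_fraction: float = 1.0 / 3.0
    genetic_variance: float = 1.0
    drp_reliability: float = 0.9
    ancestral_maf_min: float = 0.05
    trait: str = "yield"


def simulate_dataset(config: SimulationConfig, seed: int):
    """Run the whole generator: map → frequencies → genotypes → architecture → phenotypes.

    Returns ``(dataset, architecture, phenotypes)``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=5)
    marker_map = make_marker_map(
        config.n_markers, config.chrom_length_mb, config.n_chromosomes, seed=int(sub[0])
    )
    anc = np.random.default_rng(int(sub[1])).uniform(
        config.ancestral_maf_min, 1.0 - config.ancestral_maf_min, size=config.n_markers
    )
    freqs = simulate_breed_frequencies(anc, config.breeds, seed=int(sub[2]))
    dataset = simulate_genotypes(
        freqs,
        marker_map,
        config.ld_decay,
        config.breeds,
        seed=int(sub[3]),
        phase_divergence_scale=config.phase_divergence_scale,
        array_spacing=config.array_spacing,
        array_min_maf=config.array_min_maf,
        info_beta=config.info_beta,
    )
    n_breeds = len(config.breeds)
    corr = np.full((n_breeds, n_breeds), config.cross_breed_effect_corr)
    np.fill_diagonal(corr, 1.0)
    arch = simulate_architecture(
        dataset,
        config.n_qtl,
        corr,
        config.qtl_variance_fraction,
        seed=int(sub[4]),
        genetic_variance=config.genetic_variance,
        trait=config.trait,
    )
    phenos = simulate_phenotypes(dataset, arch, config.drp_reliability, seed=int(sub[4]) + 1)
    return dataset, arch, phenos


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

_PHENO_COLS = ["animal_id", "breed", "sire_id", "age_rank", "drp", "drp_reliability", "trait"]


def write_dataset(dataset: GenotypeDataset, phenos: PhenotypeTable, out_prefix) -> dict:
    """Write genotypes as VCF (per-sample DS dosages), phenotypes as TSV.

    Produces ``<prefix>.vcf`` (INFO keys ``INFO`` for imputation quality and
    ``ARRAY`` for chip membership), ``<prefix>.phenotypes.tsv`` with the
    pedigree/phenotype columns, ``<prefix>.tbv.tsv`` with the simulation
    truth, and ``<prefix>.breeds.json`` describing the populations.
    Dosages are written with three decimals.
    """
    import pysam

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ids_geno = dataset.animals["animal_id"].tolist()
    ids_pheno = phenos.table["animal_id"].tolist()
    if set(ids_geno) != set(ids_pheno):
        raise ValueError("genotype and phenotype tables refer to different animal sets")

    header = pysam.VariantHeader()
    for c in pd.unique(dataset.markers["chromosome"]):
        sub = dataset.markers.loc[dataset.markers["chromosome"] == c, "position_bp"]
        header.contigs.add(str(c), length=int(sub.max()) + 1)
    header.info.add("INFO", 1, "Float", "Imputation INFO score")
    header.info.add("ARRAY", 0, "Flag", "Variant is on the genotyping array panel")
    header.formats.add("DS", 1, "Float", "Estimated allele dosage")
    for a in ids_geno:
        header.add_sample(a)

    vcf_path = out_prefix.with_suffix(".vcf")
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        dos = np.round(dataset.dosages.astype(np.float64), 3)
        for i, row in enumerate(dataset.markers.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(row.chromosome),
                start=int(row.position_bp) - 1,
                alleles=("A", "C"),
                id=str(row.variant_id),
            )
            rec.info["INFO"] = float(row.info_score)
            if bool(row.on_array):
                rec.info["ARRAY"] = True
            col = dos[:, i]
            for s, sample in enumerate(rec.samples.values()):
                sample["DS"] = float(col[s])
            vcf.write(rec)

    pheno_path = Path(str(out_prefix) + ".phenotypes.tsv")
    ptab = phenos.table.copy()
    ptab["trait"] = phenos.trait
    ptab[_PHENO_COLS].to_csv(pheno_path, sep="\t", index=False)
    tbv_path = Path(str(out_prefix) + ".tbv.tsv")
    ptab[["animal_id", "tbv"]].to_csv(tbv_path, sep="\t", index=False)

    breeds_path = Path(str(out_prefix) + ".breeds.json")
    breeds_path.write_text(json.dumps([asdict(b) for b in dataset.breeds], indent=1))
    return {"vcf": vcf_path, "phenotypes": pheno_path, "tbv": tbv_path, "breeds": breeds_path}


def read_dataset(out_prefix):
    """Read back a dataset written by :func:`write_dataset`.

    Returns ``(GenotypeDataset, PhenotypeTable)``; marker metadata round-trips
    exactly, dosages to the printed precision (3 decimals).
    """
    import pysam

    out_prefix = Path(out_prefix)
    breeds = [BreedSpec(**d) for d in json.loads(Path(str(out_prefix) + ".breeds.json").read_text())]
    ptab = pd.read_csv(Path(str(out_prefix) + ".phenotypes.tsv"), sep="\t", dtype={"animal_id": str, "sire_id": str})
    tbv = pd.read_csv(Path(str(out_prefix) + ".tbv.tsv"), sep="\t", dtype={"animal_id": str})
    trait = str(ptab["trait"].iloc[0]) if len(ptab) else "yield"
    ptab = ptab.merge(tbv, on="animal_id", how="left")

    rows = []
    dosage_cols = []
    with pysam.VariantFile(str(out_prefix.with_suffix(".vcf"))) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            rows.append(
                {
                    "variant_id": rec.id,
                    "chromosome": str(rec.contig),
                    "position_bp": rec.pos,
                    "on_array": "ARRAY" in rec.info,
                    "info_score": float(rec.info["INFO"]),
                }
            )
            dosage_cols.append([rec.samples[s]["DS"] for s in samples])
    markers = pd.DataFrame(rows)
    dosages = np.asarray(dosage_cols, dtype=np.float32).T

    # realign animals to the VCF sample order
    ptab = ptab.set_index("animal_id").loc[samples].reset_index()
    animals = ptab[["animal_id", "breed", "sire_id", "age_rank"]].copy()
    animals["age_rank"] = animals["age_rank"].astype(int)

    pooled = dosages.mean(axis=0) / 2.0
    for b in breeds:
        rows_b = np.flatnonzero((animals["breed"] == b.name).to_numpy())
        f = dosages[rows_b].mean(axis=0) / 2.0
        markers[f"maf_{b.name}"] = np.minimum(f, 1.0 - f)
    markers["maf"] = np.minimum(pooled, 1.0 - pooled)

    dataset = GenotypeDataset(dosages=dosages, markers=markers, animals=animals, breeds=breeds)
    pheno_cols = ["animal_id", "breed", "sire_id", "age_rank", "tbv", "drp", "drp_reliability"]
    phenos = PhenotypeTable(ptab[pheno_cols].copy(), trait=trait)
    return dataset, phenos
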