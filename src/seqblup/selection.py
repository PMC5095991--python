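"""From GWAS results to prediction-marker components.

The selection chain turns an association table into the two disjoint marker
sets of a two-component SNP-BLUP model:

1. :func:`filter_base_panel` — the array ("50K") component: chip variants
   with MAF above 0.01 and INFO score of at least 0.9;
2. :func:`threshold_select` — candidate QTL variants with p below ``10**-t``
   (the same MAF/INFO eligibility applies to prediction markers);
3. :func:`ld_prune` — greedy LD pruning at squared-correlation 0.95,
   keeping the more significant variant of each correlated pair;
4. :func:`limit_per_interval` — peak-anchored windows of ``w`` Mb keeping at
   most the ``n`` lowest-p variants each;
5. :func:`assemble_components` — any variant entering the QTL component is
   excluded from the array component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import AssociationTable
from .scenarios import ScenarioSpec
from .simdata import GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerComponents",
    "filter_base_panel",
    "threshold_select",
    "ld_prune",
    "limit_per_interval",
    "assemble_components",
]

#: base-panel eligibility thresholds (strict MAF, inclusive INFO)
PANEL_MAF_MIN = 0.01
PANEL_INFO_MIN = 0.9
#: LD-pruning defaults
PRUNE_R2_MAX = 0.95
PRUNE_WINDOW_MB = 1.0


@dataclass
class MarkerComponents:
    """The resolved marker sets of one scenario: array component + QTL component.

    Disjoint by construction: a variant selected into the QTL component is
    removed from the array component.
    """

    array_component: list
    qtl_component: list
    scenario: ScenarioSpec

    def __post_init__(self) -> None:
        overlap = set(self.array_component) & set(self.qtl_component)
        if overlap:
            raise ValueError(f"components overlap: {sorted(overlap)[:5]}")

    def to_frame(self, dataset: GenotypeDataset | None = None) -> pd.DataFrame:
        """Tidy listing ``variant_id chrom pos component`` for writing."""
        parts = []
        for comp, ids in (("50K", self.array_component), ("QTL", self.qtl_component)):
            df = pd.DataFrame({"variant_id": ids, "component": comp})
            parts.append(df)
        out = pd.concat(parts, ignore_index=True)
        if dataset is not None:
            meta = dataset.markers[["variant_id", "chromosome", "position_bp"]]
            out = out.merge(meta, on="variant_id", how="left")
            out = out[["variant_id", "chromosome", "position_bp", "component"]]
        return out


def filter_base_panel(
    dataset: GenotypeDataset,
    maf_min: float = PANEL_MAF_MIN,
    info_min: float = PANEL_INFO_MIN,
) -> list:
    """Array variants passing the base filter: MAF strictly above ``maf_min``
    (pooled across breeds) and INFO score at least ``info_min``."""
    m = dataset.markers
    mask = (
        m["on_array"].to_numpy()
        & (m["maf"].to_numpy() > maf_min)
        & (m["info_score"].to_numpy() >= info_min)
    )
    ids = m["variant_id"].to_numpy()[mask].tolist()
    if not ids:
        warnings.warn("base panel is empty after MAF/INFO filtering", stacklevel=2)
    return ids


def threshold_select(
    assoc: AssociationTable,
    t: float,
    dataset: GenotypeDataset | None = None,
    maf_min: float = PANEL_MAF_MIN,
    info_min: float = PANEL_INFO_MIN,
) -> pd.DataFrame:
    """Candidates with p strictly below ``10**-t``, sorted by ascending p.

    When ``dataset`` is given, prediction-marker eligibility (pooled MAF
    strictly above ``maf_min``, INFO at least ``info_min``) is enforced too.
    Ties on p break by (chromosome, position).  Returns a frame with columns
    ``variant_id chromosome position_bp p_value``.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    rec = assoc.records
    sel = rec.loc[rec["p_value"] < 10.0 ** (-t), ["variant_id", "chromosome", "position_bp", "p_value"]].copy()
    if dataset is not None and len(sel):
        meta = dataset.markers.set_index("variant_id")
        ok = [
            (meta.at[v, "maf"] > maf_min) and (meta.at[v, "info_score"] >= info_min)
            for v in sel["variant_id"]
        ]
        sel = sel.loc[ok]
    sel = sel.sort_values(["p_value", "chromosome", "position_bp"], kind="mergesort")
    return sel.reset_index(drop=True)


def _pooled_dosages(datasets, variant_ids, animal_ids=None) -> np.ndarray:
    from .simdata import GenotypeDataset as _GD

    if isinstance(datasets, _GD):
        datasets = [datasets]
    blocks = []
    for ds in datasets:
        rows = None
        if animal_ids is not None:
            keep = ds.animals["animal_id"].isin(set(animal_ids)).to_numpy()
            rows = np.flatnonzero(keep)
        blocks.append(ds.dosage_for(variant_ids, rows))
    return np.vstack(blocks)


def ld_prune(
    candidates: pd.DataFrame,
    datasets,
    r2_max: float = PRUNE_R2_MAX,
    window_mb: float = PRUNE_WINDOW_MB,
    animal_ids=None,
) -> pd.DataFrame:
    """Greedy LD pruning, most significant candidate first.

    A candidate is kept iff its squared dosage correlation with every
    already-kept variant on the same chromosome within ``window_mb`` Mb is
    at most ``r2_max``.  Correlations are computed on the pooled genotypes
    of the supplied dataset(s), optionally restricted to ``animal_ids``
    (typically the training animals of the scan's source populations).
    Zero-variance candidates in the pooled set are dropped as duplicates.
    """
    if len(candidates) == 0:
        return candidates.copy()
    cand = candidates.sort_values(["p_value", "chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
    G = _pooled_dosages(datasets, cand["variant_id"], animal_ids)
    G = G - G.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", G, G))

    chrom = cand["chromosome"].to_numpy()
    pos = cand["position_bp"].to_numpy(dtype=float)
    window_bp = window_mb * 1e6

    kept: list[int] = []
    for i in range(len(cand)):
        if norms[i] == 0.0:
            logger.info("ld_prune: dropping zero-variance candidate %s", cand["variant_id"].iloc[i])
            continue
        ok = True
        for j in kept:
            if chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp:
                r = float(G[:, i] @ G[:, j]) / (norms[i] * norms[j])
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            kept.append(i)
    return cand.iloc[kept].reset_index(drop=True)


def limit_per_interval(pruned: pd.DataFrame, n: int, w: float, p_max: float | None = None) -> pd.DataFrame:
    """Peak-anchored per-interval cap.

    Repeatedly takes the most significant remaining variant as a peak,
    defines the interval as peak position ± ``w``/2 Mb on the peak's
    chromosome, retains the up-to-``n`` lowest-p variants inside it and
    removes the whole interval from the pool, until no remaining variant has
    p below ``p_max`` (by construction every input candidate already passed
    the threshold, so ``p_max=None`` exhausts the pool).  Ties on p break by
    (chromosome, position).  Output sorted by genomic position.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if w <= 0:
        raise ValueError("w must be > 0")
    pool = pruned.sort_values(["p_value", "chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
    half = w * 1e6 / 2.0
    selected = []
    while len(pool):
        peak = pool.iloc[0]
        if p_max is not None and peak["p_value"] >= p_max:
            break
        in_iv = (pool["chromosome"] == peak["chromosome"]) & (
            (pool["position_bp"] - peak["position_bp"]).abs() <= half
        )
        interval = pool.loc[in_iv]
        selected.append(interval.iloc[:n])
        pool = pool.loc[~in_iv].reset_index(drop=True)
    if not selected:
        return pruned.iloc[0:0].copy()
    out = pd.concat(selected, ignore_index=True)
    return out.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)


def assemble_components(base_panel, qtl_set, scenario: ScenarioSpec) -> MarkerComponents:
    """Disjoint {array, QTL} components: QTL variants leave the array set."""
    base = list(base_panel)
    if not base:
        raise ValueError("base panel is empty")
    qtl = list(dict.fromkeys(qtl_set))  # dedupe, keep order
    qtl_s = set(qtl)
    array = [v for v in base if v not in qtl_s]
    return MarkerComponents(array_component=array, qtl_component=qtl, scenario=scenario)
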