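"""Training/validation splitting and scenario evaluation statistics.

Validation reliability is the squared correlation between DRP and GEBV in
the validation set divided by the mean DRP reliability of that set; bias is
the regression slope of DRP on GEBV (below 1 flags inflated predictions);
the QTL heritability is the share of phenotypic variance attributed to the
QTL component, ``sigma2_QTL / (sigma2_50K + sigma2_QTL + sigma2_e)``, with
the component variances taken as posterior means of the across-animal
variances of each component's genetic values.  A genomic correlation is
flagged significant when its absolute posterior mean exceeds twice its
posterior standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import PhenotypeTable

__all__ = [
    "ValidationSplit",
    "EvaluationReport",
    "split_train_validation",
    "reliability",
    "bias_regression",
    "qtl_heritability",
    "genomic_correlation_summary",
]


@dataclass
class ValidationSplit:
    """Per-breed training/validation animal ids.

    Validation animals are the youngest of each breed; any training animal
    that sired a validation animal is removed from training.
    """

    training_ids: dict
    validation_ids: dict

    def all_training(self) -> list:
        return [a for ids in self.training_ids.values() for a in ids]

    def all_validation(self) -> list:
        return [a for ids in self.validation_ids.values() for a in ids]


@dataclass
class EvaluationReport:
    """Evaluation of one scenario for one breed and trait."""

    scenario: str
    breed: str
    trait: str
    reliability: float
    bias_slope: float
    h2_qtl: float
    n_validation: int
    n_qtl_markers: int
    genomic_correlations: dict = field(default_factory=dict)
    degenerate_to_50k: bool = False

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "breed": self.breed,
            "trait": self.trait,
            "reliability": self.reliability,
            "bias_slope": self.bias_slope,
            "h2_qtl": self.h2_qtl,
            "n_validation": self.n_validation,
            "n_qtl_markers": self.n_qtl_markers,
            "degenerate_to_50k": self.degenerate_to_50k,
        }
        for pair, (mean, sd, sig) in self.genomic_correlations.items():
            row[f"corr_{pair}"] = mean
            row[f"corr_{pair}_sd"] = sd
            row[f"corr_{pair}_significant"] = sig
        return row


def split_train_validation(phenos: PhenotypeTable, validation_fraction) -> ValidationSplit:
    """Youngest animals per breed go to validation; their sires leave training.

    ``validation_fraction`` is a single fraction in [0, 1) or a mapping
    ``breed -> fraction``.  Age is carried by ``age_rank`` (higher =
    younger).  Raises if a breed's training set ends up empty.
    """
    tab = phenos.table
    training, validation = {}, {}
    for breed, sub in tab.groupby("breed", sort=False):
        frac = validation_fraction.get(breed) if isinstance(validation_fraction, dict) else validation_fraction
        frac = float(frac)
        if not (0.0 <= frac < 1.0):
            raise ValueError(f"validation fraction for {breed} must be in [0, 1)")
        n_val = int(round(frac * len(sub)))
        ordered = sub.sort_values(["age_rank", "animal_id"], ascending=[False, True], kind="mergesort")
        val = ordered.iloc[:n_val]
        rest = ordered.iloc[n_val:]
        val_sires = set(val["sire_id"])
        train = rest.loc[~rest["animal_id"].isin(val_sires)]
        if len(train) == 0:
            raise ValueError(f"no training animals left for breed {breed}")
        training[breed] = train["animal_id"].tolist()
        validation[breed] = val["animal_id"].tolist()
    return ValidationSplit(training_ids=training, validation_ids=validation)


def _check_pair(drp, gebv):
    drp = np.asarray(drp, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if drp.shape != gebv.shape or drp.ndim != 1:
        raise ValueError("drp and gebv must be aligned 1-D vectors")
    if drp.size < 3:
        raise ValueError("need at least 3 animals")
    return drp, gebv


def reliability(drp, gebv, mean_drp_reliability: float) -> float:
    """Validation reliability: cor(DRP, GEBV)^2 / mean DRP reliability."""
    drp, gebv = _check_pair(drp, gebv)
    if not (0.0 < mean_drp_reliability <= 1.0):
        raise ValueError("mean_drp_reliability must be in (0, 1]")
    if drp.std() == 0.0 or gebv.std() == 0.0:
        raise ValueError("reliability undefined for constant DRP or GEBV")
    r = float(np.corrcoef(drp, gebv)[0, 1])
    return r * r / mean_drp_reliability


def bias_regression(drp, gebv) -> float:
    """Least-squares slope of DRP on GEBV; below 1 means inflated GEBV."""
    drp, gebv = _check_pair(drp, gebv)
    var = float(np.var(gebv))
    if var == 0.0:
        raise ValueError("bias slope undefined for constant GEBV")
    cov = float(np.cov(gebv, drp, ddof=0)[0, 1])
    return cov / var


def qtl_heritability(var_Za_chain, var_Zq_chain, sigma2_e_chain) -> float:
    """Share of phenotypic variance attributed to the QTL component.

    Plugs the chain means into
    ``sigma2_QTL / (sigma2_50K + sigma2_QTL + sigma2_e)``.
    """
    chains = [np.asarray(c, dtype=float) for c in (var_Za_chain, var_Zq_chain, sigma2_e_chain)]
    if any(c.size == 0 for c in chains):
        raise ValueError("empty chain")
    if len({c.size for c in chains}) != 1:
        raise ValueError("chains must be aligned")
    s50, sq, se = (float(c.mean()) for c in chains)
    denom = s50 + sq + se
    if denom <= 0.0:
        raise ValueError("total variance is zero")
    return sq / denom


def genomic_correlation_summary(correlation_chain) -> tuple:
    """Posterior mean, posterior SD and the |mean| > 2*SD significance flag."""
    chain = np.asarray(correlation_chain, dtype=float)
    if chain.size == 0:
        raise ValueError("empty chain")
    mean = float(chain.mean())
    sd = float(chain.std(ddof=1)) if chain.size > 1 else 0.0
    return mean, sd, bool(abs(mean) > 2.0 * sd)


def reports_to_frame(reports) -> pd.DataFrame:
    """Tidy table, one row per scenario x breed x trait."""
    return pd.DataFrame([r.to_row() for r in reports])
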