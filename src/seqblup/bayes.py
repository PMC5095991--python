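"""Gibbs samplers for single- and two-component Bayesian SNP-BLUP.

All models regress within-breed-standardized DRP on marker dosages with
normally distributed effects and flat (uniform, non-informative) priors on
every variance component:

* **WB** — within-breed: ``y = mu + Z_a a + Z_q q + e`` on one population;
* **MB** — multi-breed: a fixed breed effect is added and all populations
  are pooled with common marker effects;
* **MT** — multi-trait: the same trait in different breeds is treated as
  correlated traits; each marker carries one effect per breed, drawn from a
  multivariate normal whose across-breed covariance matrices (one for the
  array component, one for the QTL component) are themselves sampled.

Scalar variances are sampled from their scaled inverse-chi-squared full
conditionals with the flat-prior degrees of freedom ``m - 2`` for a
component of ``m`` effects and ``n - 2`` for residuals; the multi-trait
effect covariances come from inverse-Wishart conditionals with ``m``
degrees of freedom (the flat-prior data degrees of freedom plus the minimal
``B + 1``).  Per iteration the sampler also records the across-animal
variances var(Za) and var(Zq) of the two genetic components, whose chain
means are the component variance estimates used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from . import _kernels
from .scenarios import ScenarioSpec
from .selection import MarkerComponents
from .simdata import GenotypeDataset, PhenotypeTable

__all__ = [
    "MCMCConfig",
    "DesignMatrices",
    "PosteriorSummary",
    "GibbsDivergenceError",
    "build_design",
    "gibbs_single_trait",
    "gibbs_multi_trait",
    "compute_gebv",
    "summarize_posterior",
]


class GibbsDivergenceError(RuntimeError):
    """A variance draw diverged or a conditional covariance lost positive
    definiteness; carries a state snapshot for diagnosis."""

    def __init__(self, message: str, state: dict):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length, burn-in, seed and thinning for the variance chains.

    The desk-scale default is 5,000 iterations with 1,000 burn-in; the
    full-length setting used for the chain-agreement check is 50,000 with
    10,000 burn-in.
    """

    n_iter: int = 5000
    n_burnin: int = 1000
    seed: int = 0
    store_every: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.store_every < 1:
            raise ValueError("store_every must be >= 1")


@dataclass
class DesignMatrices:
    """Centered dosage design matrices for the two components, restricted to
    one animal set and sorted by (breed, animal id) for reproducibility.

    Columns are centered on the training-set mean dosage (stored in
    ``array_means``/``qtl_means``), which decouples the intercept from the
    marker effects; GEBV are therefore expressed as deviations and are
    defined up to a constant, which none of the evaluation statistics
    depend on.
    """

    Z_array: np.ndarray
    Z_qtl: np.ndarray
    array_ids: list
    qtl_ids: list
    array_means: np.ndarray
    qtl_means: np.ndarray
    animal_ids: np.ndarray
    breed_labels: np.ndarray
    breed_names: list
    breed_starts: np.ndarray  # block boundaries, length n_breeds + 1

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)


@dataclass
class PosteriorSummary:
    """Output of one chain: posterior-mean effects, variance chains and GEBV.

    ``effect_means_*`` are per-marker posterior means, shape ``(p,)`` for
    single-trait models and ``(p, n_breeds)`` for MT.  ``chains`` holds the
    stored post-burn-in draws: scalar variance chains as 1-D arrays,
    per-breed quantities as ``(T, n_breeds)``, and for MT the derived
    genomic-correlation chains under keys ``corr_<comp>_<j>_<k>``.
    ``var_Za_chain``/``var_Zq_chain`` are the per-iteration across-animal
    variances of each component's genetic values.  ``gebv`` are the training
    animals' genetic values under the posterior-mean effects.
    """

    model: str
    breed_names: list
    array_ids: list
    qtl_ids: list
    array_means: np.ndarray
    qtl_means: np.ndarray
    mu: np.ndarray
    breed_effects: np.ndarray
    effect_means_array: np.ndarray
    effect_means_qtl: np.ndarray
    chains: dict
    var_Za_chain: np.ndarray
    var_Zq_chain: np.ndarray
    gebv: pd.Series
    config: MCMCConfig = field(default_factory=MCMCConfig)

    @property
    def n_stored(self) -> int:
        return len(self.var_Za_chain)


def build_design(dataset: GenotypeDataset, components: MarkerComponents, animal_ids) -> DesignMatrices:
    """Extract the two dosage design matrices for the given animals.

    Rows are sorted by (breed, animal id) — in the dataset's breed order —
    so the result, and therefore every chain run on it, is invariant to the
    order animals are passed in.  A component variant missing from the
    dataset raises a ``KeyError`` naming it.
    """
    wanted = set(animal_ids)
    an = dataset.animals.reset_index(drop=True)
    present = an["animal_id"].isin(wanted)
    if present.sum() != len(wanted):
        missing = wanted - set(an["animal_id"])
        raise KeyError(f"animals not in dataset: {sorted(missing)[:5]}")
    sub = an.loc[present].copy()
    order_key = {b: i for i, b in enumerate(dataset.breed_names)}
    sub = sub.sort_values(["breed", "animal_id"], key=lambda s: s.map(order_key) if s.name == "breed" else s,
                          kind="mergesort")
    rows = sub.index.to_numpy()

    Za = dataset.dosage_for(components.array_component, rows)
    Zq = dataset.dosage_for(components.qtl_component, rows) if components.qtl_component \
        else np.zeros((len(rows), 0))
    a_means = Za.mean(axis=0) if Za.shape[1] else np.zeros(0)
    q_means = Zq.mean(axis=0) if Zq.shape[1] else np.zeros(0)
    Za = np.asfortranarray(Za - a_means)
    Zq = np.asfortranarray(Zq - q_means)

    breeds_here = [b for b in dataset.breed_names if b in set(sub["breed"])]
    labels = sub["breed"].to_numpy()
    starts = [0]
    for b in breeds_here:
        starts.append(starts[-1] + int((labels == b).sum()))
    return DesignMatrices(
        Z_array=Za,
        Z_qtl=Zq,
        array_ids=list(components.array_component),
        qtl_ids=list(components.qtl_component),
        array_means=a_means,
        qtl_means=q_means,
        animal_ids=sub["animal_id"].to_numpy(),
        breed_labels=labels,
        breed_names=breeds_here,
        breed_starts=np.asarray(starts, dtype=np.int64),
    )


def _aligned_response(designs: DesignMatrices, phenos: PhenotypeTable) -> np.ndarray:
    tab = phenos.table.set_index("animal_id")
    y = tab.reindex(designs.animal_ids)["drp"]
    if y.isna().any():
        missing = designs.animal_ids[y.isna().to_numpy()]
        raise KeyError(f"animals without phenotypes: {list(missing[:5])}")
    return y.to_numpy(dtype=float)


def _flat_df(m: int) -> float:
    # flat-prior scaled inverse-chi-squared degrees of freedom; floor keeps
    # tiny components proper
    return float(max(m - 2, 1))


def _check_finite(name, value, state):
    if not np.all(np.isfinite(value)):
        raise GibbsDivergenceError(f"non-finite draw for {name}", state)


def gibbs_single_trait(
    designs: DesignMatrices,
    phenos: PhenotypeTable,
    scenario: ScenarioSpec,
    config: MCMCConfig,
    fixed_variances: dict | None = None,
) -> PosteriorSummary:
    """Gibbs chain for the WB and MB model families.

    Per iteration, in order: intercept (and reference-coded breed effects
    for MB) from their flat-prior normal conditionals; every marker effect
    of the array then the QTL component from its normal full conditional;
    each component variance and the residual variance from scaled
    inverse-chi-squared conditionals.  ``fixed_variances`` (keys
    ``sigma2_array``, ``sigma2_qtl``, ``sigma2_e``) disables the variance
    updates — the sampler then converges to the closed-form ridge/BLUP
    solution, which is used as an oracle in the tests.
    """
    if scenario.model not in {"WB", "MB"}:
        raise ValueError(f"scenario {scenario.name} is not a single-trait family")
    y = _aligned_response(designs, phenos)
    n = y.size
    Za, Zq = designs.Z_array, designs.Z_qtl
    M, N = Za.shape[1], Zq.shape[1]
    zsq_a = np.einsum("ij,ij->j", Za, Za)
    zsq_q = np.einsum("ij,ij->j", Zq, Zq) if N else np.zeros(0)

    rng = np.random.default_rng(config.seed)
    _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))

    fixed = fixed_variances or {}
    floor = 1e-12
    s2a = max(float(fixed.get("sigma2_array", np.var(y) / max(M, 1))), floor)
    s2q = max(float(fixed.get("sigma2_qtl", np.var(y) / max(N, 1))), floor) if N else 0.0
    s2e = max(float(fixed.get("sigma2_e", 0.5 * np.var(y))), floor)

    use_breed = scenario.model == "MB" and len(designs.breed_names) > 1
    nb = len(designs.breed_names)
    starts = designs.breed_starts
    mu = 0.0
    b_eff = np.zeros(nb)  # b_eff[0] fixed at 0 (reference breed)

    a = np.zeros(M)
    q = np.zeros(N)
    ua = np.zeros(n)
    uq = np.zeros(n)
    e = y.copy()

    sum_a = np.zeros(M)
    sum_q = np.zeros(N)
    n_avg = 0
    ch_s2a, ch_s2q, ch_s2e, ch_vza, ch_vzq = [], [], [], [], []

    for it in range(1, config.n_iter + 1):
        # location parameters (flat priors)
        new_mu = mu + e.mean() + rng.standard_normal() * np.sqrt(s2e / n)
        e -= new_mu - mu
        mu = new_mu
        if use_breed:
            for j in range(1, nb):
                s, t = starts[j], starts[j + 1]
                nj = t - s
                new_b = b_eff[j] + e[s:t].mean() + rng.standard_normal() * np.sqrt(s2e / nj)
                e[s:t] -= new_b - b_eff[j]
                b_eff[j] = new_b

        _kernels.sweep_component(Za, zsq_a, e, a, ua, s2a, s2e)
        if N:
            _kernels.sweep_component(Zq, zsq_q, e, q, uq, s2q, s2e)

        if fixed_variances is None:
            s2a = max(float((a @ a) / rng.chisquare(_flat_df(M))), floor)
            if N:
                s2q = max(float((q @ q) / rng.chisquare(_flat_df(N))), floor)
            s2e = max(float((e @ e) / rng.chisquare(_flat_df(n))), floor)
            if not (np.isfinite(s2a) and np.isfinite(s2q) and np.isfinite(s2e)):
                raise GibbsDivergenceError(
                    "variance draw diverged",
                    {"iteration": it, "sigma2_array": s2a, "sigma2_qtl": s2q, "sigma2_e": s2e,
                     "max_abs_effect": float(np.abs(a).max(initial=0.0))},
                )

        if it > config.n_burnin:
            sum_a += a
            if N:
                sum_q += q
            n_avg += 1
            if (it - config.n_burnin - 1) % config.store_every == 0:
                ch_s2a.append(s2a)
                ch_s2q.append(s2q)
                ch_s2e.append(s2e)
                ch_vza.append(float(np.var(ua)))
                ch_vzq.append(float(np.var(uq)) if N else 0.0)

    mean_a = sum_a / n_avg
    mean_q = sum_q / n_avg if N else sum_q
    gebv = Za @ mean_a + (Zq @ mean_q if N else 0.0)

    return PosteriorSummary(
        model=scenario.model,
        breed_names=designs.breed_names,
        array_ids=designs.array_ids,
        qtl_ids=designs.qtl_ids,
        array_means=designs.array_means,
        qtl_means=designs.qtl_means,
        mu=np.array([mu]),
        breed_effects=b_eff,
        effect_means_array=mean_a,
        effect_means_qtl=mean_q,
        chains={
            "sigma2_array": np.array(ch_s2a),
            "sigma2_qtl": np.array(ch_s2q),
            "sigma2_e": np.array(ch_s2e),
        },
        var_Za_chain=np.array(ch_vza),
        var_Zq_chain=np.array(ch_vzq),
        gebv=pd.Series(np.asarray(gebv), index=designs.animal_ids, name="gebv"),
        config=config,
    )


def _sample_invwishart(rng, scale, df, state):
    jitter = 1e-8 * np.eye(scale.shape[0])
    for attempt in range(2):
        try:
            draw = invwishart.rvs(df=df, scale=scale + (10.0**attempt) * jitter, random_state=rng)
            draw = np.atleast_2d(draw)
            np.linalg.cholesky(draw)
            return draw
        except np.linalg.LinAlgError:
            continue
    raise GibbsDivergenceError("covariance draw not positive definite after jitter retry", state)


def gibbs_multi_trait(
    designs: DesignMatrices,
    phenos: PhenotypeTable,
    scenario: ScenarioSpec,
    config: MCMCConfig,
    fixed_covariances: dict | None = None,
) -> PosteriorSummary:
    """Gibbs chain for the MT family (correlated effects across breeds).

    Each animal carries the trait of exactly one breed; residuals are
    independent between breeds (no residual covariance).  Per marker the
    vector of per-breed effects is sampled jointly given the current
    across-breed effect covariance; the covariance matrices of the array and
    QTL components are sampled from inverse-Wishart conditionals, and the
    per-breed residual variances independently.  Genomic correlations are
    derived per stored draw as ``sigma_jk / sqrt(sigma_jj * sigma_kk)``.

    ``fixed_covariances`` (keys ``array``, ``qtl``: (B, B) matrices;
    ``sigma2_e``: length-B vector) disables the covariance updates; with
    diagonal matrices the model then decouples into independent per-breed
    chains, which the tests exploit as an oracle.
    """
    if scenario.model != "MT":
        raise ValueError(f"scenario {scenario.name} is not the multi-trait family")
    y = _aligned_response(designs, phenos)
    n = y.size
    Za, Zq = designs.Z_array, designs.Z_qtl
    M, N = Za.shape[1], Zq.shape[1]
    nb = len(designs.breed_names)
    starts = designs.breed_starts
    n_per = np.diff(starts)

    # per-breed column sums of squares
    def _zsq_b(Z):
        out = np.zeros((nb, Z.shape[1]))
        for j in range(nb):
            s, t = starts[j], starts[j + 1]
            out[j] = np.einsum("ij,ij->j", Z[s:t], Z[s:t])
        return out

    zsq_a, zsq_q = _zsq_b(Za), _zsq_b(Zq) if N else np.zeros((nb, 0))

    rng = np.random.default_rng(config.seed)
    _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))

    fixed = fixed_covariances or {}
    floor = 1e-12
    var_y = np.maximum(np.array([np.var(y[starts[j]:starts[j + 1]]) for j in range(nb)]), floor)
    sig_a = np.atleast_2d(fixed.get("array", np.diag(var_y / max(M, 1))))
    sig_q = np.atleast_2d(fixed.get("qtl", np.diag(var_y / max(N, 1)))) if N else np.eye(nb)
    s2e = np.maximum(np.asarray(fixed.get("sigma2_e", 0.5 * var_y), dtype=float), floor)

    mu = np.zeros(nb)
    A = np.zeros((M, nb))
    Q = np.zeros((N, nb))
    ua = np.zeros(n)
    uq = np.zeros(n)
    e = y.copy()

    sum_A = np.zeros((M, nb))
    sum_Q = np.zeros((N, nb))
    n_avg = 0
    ch = {"sigma2_e": [], "sigma_array": [], "sigma_qtl": [], "var_Za": [], "var_Zq": []}

    for it in range(1, config.n_iter + 1):
        for j in range(nb):
            s, t = starts[j], starts[j + 1]
            new_mu = mu[j] + e[s:t].mean() + rng.standard_normal() * np.sqrt(s2e[j] / n_per[j])
            e[s:t] -= new_mu - mu[j]
            mu[j] = new_mu

        state = {"iteration": it, "sigma_array": sig_a, "sigma_qtl": sig_q, "sigma2_e": s2e}
        ok = _kernels.sweep_component_mt(Za, zsq_a, e, A, ua, np.linalg.inv(sig_a), s2e, starts)
        if ok == 0:
            raise GibbsDivergenceError("array-component conditional precision not PD", state)
        if N:
            ok = _kernels.sweep_component_mt(Zq, zsq_q, e, Q, uq, np.linalg.inv(sig_q), s2e, starts)
            if ok == 0:
                raise GibbsDivergenceError("QTL-component conditional precision not PD", state)

        if fixed_covariances is None:
            sig_a = _sample_invwishart(rng, A.T @ A, max(M, nb + 1), state)
            if N:
                sig_q = _sample_invwishart(rng, Q.T @ Q, max(N, nb + 1), state)
            for j in range(nb):
                s, t = starts[j], starts[j + 1]
                ss = float(e[s:t] @ e[s:t])
                s2e[j] = max(ss / rng.chisquare(_flat_df(n_per[j])), floor)
            _check_finite("sigma2_e", s2e, state)

        if it > config.n_burnin:
            sum_A += A
            if N:
                sum_Q += Q
            n_avg += 1
            if (it - config.n_burnin - 1) % config.store_every == 0:
                ch["sigma2_e"].append(s2e.copy())
                ch["sigma_array"].append(sig_a.copy())
                ch["sigma_qtl"].append(sig_q.copy() if N else np.zeros((nb, nb)))
                ch["var_Za"].append([float(np.var(ua[starts[j]:starts[j + 1]])) for j in range(nb)])
                ch["var_Zq"].append(
                    [float(np.var(uq[starts[j]:starts[j + 1]])) if N else 0.0 for j in range(nb)]
                )

    mean_A = sum_A / n_avg
    mean_Q = sum_Q / n_avg if N else sum_Q
    gebv = np.zeros(n)
    for j in range(nb):
        s, t = starts[j], starts[j + 1]
        gebv[s:t] = Za[s:t] @ mean_A[:, j] + (Zq[s:t] @ mean_Q[:, j] if N else 0.0)

    chains = {
        "sigma2_e": np.asarray(ch["sigma2_e"]),
        "sigma_array": np.asarray(ch["sigma_array"]),
        "sigma_qtl": np.asarray(ch["sigma_qtl"]),
    }
    for comp, key in (("array", "sigma_array"), ("qtl", "sigma_qtl")):
        if comp == "qtl" and not N:
            continue
        mats = chains[key]
        for j in range(nb):
            for k in range(j + 1, nb):
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = mats[:, j, k] / np.sqrt(mats[:, j, j] * mats[:, k, k])
                chains[f"corr_{comp}_{designs.breed_names[j]}_{designs.breed_names[k]}"] = corr

    return PosteriorSummary(
        model="MT",
        breed_names=designs.breed_names,
        array_ids=designs.array_ids,
        qtl_ids=designs.qtl_ids,
        array_means=designs.array_means,
        qtl_means=designs.qtl_means,
        mu=mu,
        breed_effects=np.zeros(nb),
        effect_means_array=mean_A,
        effect_means_qtl=mean_Q,
        chains=chains,
        var_Za_chain=np.asarray(ch["var_Za"]),
        var_Zq_chain=np.asarray(ch["var_Zq"]),
        gebv=pd.Series(gebv, index=designs.animal_ids, name="gebv"),
        config=config,
    )


def compute_gebv(dataset: GenotypeDataset, summary: PosteriorSummary, animal_ids) -> pd.Series:
    """GEBV for arbitrary (e.g. validation) animals under posterior-mean effects.

    ``GEBV = Z_array @ mean(a) + Z_qtl @ mean(q)``; for MT models each
    animal uses its own breed's effect column.  Missing genotypes raise.
    """
    animal_ids = list(animal_ids)
    an = dataset.animals.set_index("animal_id")
    missing = [a for a in animal_ids if a not in an.index]
    if missing:
        raise KeyError(f"animals not genotyped: {missing[:5]}")
    rows = dataset.animals["animal_id"].isin(set(animal_ids))
    rows = np.flatnonzero(rows.to_numpy())
    ids_here = dataset.animals["animal_id"].to_numpy()[rows]

    Za = dataset.dosage_for(summary.array_ids, rows) - summary.array_means
    Zq = dataset.dosage_for(summary.qtl_ids, rows) - summary.qtl_means if summary.qtl_ids else None

    if summary.model == "MT":
        breed_of = dataset.animals["breed"].to_numpy()[rows]
        col = np.array([summary.breed_names.index(b) for b in breed_of])
        g = np.einsum("ij,ji->i", Za, summary.effect_means_array[:, col])
        if Zq is not None and Zq.shape[1]:
            g += np.einsum("ij,ji->i", Zq, summary.effect_means_qtl[:, col])
    else:
        g = Za @ summary.effect_means_array
        if Zq is not None and Zq.shape[1]:
            g += Zq @ summary.effect_means_qtl
    out = pd.Series(g, index=ids_here, name="gebv")
    return out.reindex(animal_ids)


def summarize_posterior(summary: PosteriorSummary) -> pd.DataFrame:
    """Posterior means and SDs of the variance components and genomic correlations.

    The component variances are the chain means of the across-animal
    variances var(Za) and var(Zq).  Genomic-correlation rows carry a
    ``significant`` flag: |mean| greater than twice the posterior SD.
    """
    if summary.n_stored == 0:
        raise ValueError("no stored draws")
    rows = []

    def add(name, chain, significance=False):
        chain = np.asarray(chain, dtype=float)
        mean = float(chain.mean())
        sd = float(chain.std(ddof=1)) if chain.size > 1 else 0.0
        row = {"quantity": name, "mean": mean, "sd": sd}
        if significance:
            row["significant"] = bool(abs(mean) > 2.0 * sd)
        rows.append(row)

    vza = np.atleast_2d(summary.var_Za_chain.T).T
    vzq = np.atleast_2d(summary.var_Zq_chain.T).T
    if summary.model == "MT":
        for j, b in enumerate(summary.breed_names):
            add(f"sigma2_50K[{b}]", vza[:, j])
            if summary.qtl_ids:
                add(f"sigma2_QTL[{b}]", vzq[:, j])
            add(f"sigma2_e[{b}]", summary.chains["sigma2_e"][:, j])
        for key, chain in summary.chains.items():
            if key.startswith("corr_"):
                add(key, chain, significance=True)
    else:
        add("sigma2_50K", summary.var_Za_chain)
        if summary.qtl_ids:
            add("sigma2_QTL", summary.var_Zq_chain)
        add("sigma2_e", summary.chains["sigma2_e"])
    return pd.DataFrame(rows)
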