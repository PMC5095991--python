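"""End-to-end orchestration: simulate → GWAS → select → predict → evaluate.

A :class:`RunConfig` bundles the synthetic-data settings, the scenario list
(in the acronym grammar of :mod:`seqblup.scenarios`), MCMC settings and the
master seed.  :func:`run_scenario` executes one scenario and returns a tidy
report; :func:`run_grid` runs the whole list, sharing cached GWAS and
selection artifacts between scenarios (many scenarios differ only in their
prediction model or per-interval cap, so scans and pruning are computed
once and reused).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import selection
from .bayes import MCMCConfig, build_design, compute_gebv, gibbs_multi_trait, gibbs_single_trait
from .evaluate import (
    EvaluationReport,
    genomic_correlation_summary,
    bias_regression,
    qtl_heritability,
    reliability,
    split_train_validation,
)
from .gwas import estimate_sire_variance, preselect_for_multibreed, scan_multi_breed, scan_within_breed
from .scenarios import ScenarioSpec, parse_scenario
from .simdata import BreedSpec, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineContext", "run_scenario", "run_grid", "parse_scenario"]


@dataclass
class RunConfig:
    """Everything one run needs: data, scenarios, chains, seeds, thresholds."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scenarios: list = field(default_factory=lambda: ["WB-50K", "WB-50K+MBQTL6-10/2"])
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    seed: int = 0
    holstein_threshold: float = 1e-5
    other_threshold: float = 1e-3
    prune_r2_max: float = selection.PRUNE_R2_MAX
    prune_window_mb: float = selection.PRUNE_WINDOW_MB
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in self.scenarios:
            parse_scenario(name)  # fail early on malformed names

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = dict(raw.get("simulation", {}))
        if "breeds" in sim_raw:
            sim_raw["breeds"] = [BreedSpec(**b) for b in sim_raw["breeds"]]
        if "info_beta" in sim_raw and sim_raw["info_beta"] is not None:
            sim_raw["info_beta"] = tuple(sim_raw["info_beta"])
        kwargs = {k: v for k, v in raw.items() if k not in {"simulation", "mcmc"}}
        return cls(
            simulation=SimulationConfig(**sim_raw),
            mcmc=MCMCConfig(**raw.get("mcmc", {})),
            **kwargs,
        )

    def to_yaml(self, path) -> Path:
        raw = {
            "simulation": asdict(self.simulation),
            "mcmc": asdict(self.mcmc),
            "scenarios": list(self.scenarios),
            "seed": self.seed,
            "holstein_threshold": self.holstein_threshold,
            "other_threshold": self.other_threshold,
            "prune_r2_max": self.prune_r2_max,
            "prune_window_mb": self.prune_window_mb,
            "out_dir": self.out_dir,
        }
        if raw["simulation"].get("info_beta") is not None:
            raw["simulation"]["info_beta"] = list(raw["simulation"]["info_beta"])
        path = Path(path)
        path.write_text(yaml.safe_dump(raw, sort_keys=False))
        return path


class PipelineContext:
    """Shared state between scenarios of one grid: data and cached artifacts."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.cache: dict = {}
        self.failures: dict = {}

    def get(self, key, builder):
        if key not in self.cache:
            logger.info("computing %s", key)
            self.cache[key] = builder()
        return self.cache[key]

    # -- cached stages -----------------------------------------------------

    def data(self):
        return self.get("data", lambda: simulate_dataset(self.config.simulation, self.config.seed))

    def split(self):
        def build():
            _, _, phenos = self.data()
            frac = {
                b.name: b.n_validation / b.n_animals for b in self.config.simulation.breeds
            }
            return split_train_validation(phenos, frac)

        return self.get("split", build)

    def training_phenos(self):
        def build():
            _, _, phenos = self.data()
            return phenos.subset(self.split().all_training())

        return self.get("training_phenos", build)

    def sire_fits(self):
        def build():
            phenos = self.training_phenos()
            return {b.name: estimate_sire_variance(phenos, b.name) for b in self.config.simulation.breeds}

        return self.get("sire_fits", build)

    def within_table(self, breed: str):
        def build():
            dataset, _, _ = self.data()
            return scan_within_breed(dataset, self.training_phenos(), breed, self.sire_fits()[breed])

        return self.get(f"within_table:{breed}", build)

    def multibreed_table(self):
        def build():
            dataset, _, _ = self.data()
            tables = [self.within_table(b.name) for b in self.config.simulation.breeds]
            holstein = [b.name for b in self.config.simulation.breeds if b.holstein_like]
            candidates = preselect_for_multibreed(
                tables,
                holstein_threshold=self.config.holstein_threshold,
                other_threshold=self.config.other_threshold,
                holstein_breeds=holstein,
            )
            return scan_multi_breed(dataset, self.training_phenos(), candidates, self.sire_fits())

        return self.get("multibreed_table", build)

    def base_panel(self):
        def build():
            dataset, _, _ = self.data()
            return selection.filter_base_panel(dataset)

        return self.get("base_panel", build)

    def qtl_set(self, spec: ScenarioSpec, breed: str | None):
        """Threshold → prune → per-interval cap for one scenario (cached)."""
        key = f"qtl_set:{spec.qtl_source}:{spec.t}:{spec.n}:{spec.w}:{breed if spec.qtl_source == 'WB' else '*'}"

        def build():
            dataset, _, _ = self.data()
            if spec.qtl_source == "WB":
                assoc = self.within_table(breed)
                animal_ids = self.split().training_ids[breed]
            else:
                assoc = self.multibreed_table()
                animal_ids = self.split().all_training()
            cand = selection.threshold_select(assoc, spec.t, dataset)
            pruned = selection.ld_prune(
                cand,
                dataset,
                r2_max=self.config.prune_r2_max,
                window_mb=self.config.prune_window_mb,
                animal_ids=animal_ids,
            )
            if spec.n is not None:
                pruned = selection.limit_per_interval(pruned, spec.n, spec.w)
            return pruned["variant_id"].tolist()

        return self.get(key, build)


def _evaluate_breed(spec, summary, dataset, phenos, split, breed) -> EvaluationReport:
    val_ids = split.validation_ids[breed]
    sub = phenos.table.set_index("animal_id").loc[val_ids]
    gebv = compute_gebv(dataset, summary, val_ids)
    rel = reliability(sub["drp"].to_numpy(), gebv.to_numpy(), float(sub["drp_reliability"].mean()))
    slope = bias_regression(sub["drp"].to_numpy(), gebv.to_numpy())

    if summary.model == "MT":
        j = summary.breed_names.index(breed)
        vza = summary.var_Za_chain[:, j]
        vzq = summary.var_Zq_chain[:, j]
        s2e = summary.chains["sigma2_e"][:, j]
    else:
        vza, vzq, s2e = summary.var_Za_chain, summary.var_Zq_chain, summary.chains["sigma2_e"]
    h2 = qtl_heritability(vza, vzq, s2e) if summary.qtl_ids else 0.0

    corrs = {}
    for key, chain in summary.chains.items():
        if key.startswith("corr_"):
            corrs[key.removeprefix("corr_")] = genomic_correlation_summary(chain)

    return EvaluationReport(
        scenario=spec.name,
        breed=breed,
        trait=phenos.trait,
        reliability=rel,
        bias_slope=slope,
        h2_qtl=h2,
        n_validation=len(val_ids),
        n_qtl_markers=len(summary.qtl_ids),
        genomic_correlations=corrs,
        degenerate_to_50k=spec.has_qtl_component and not summary.qtl_ids,
    )


def run_scenario(config: RunConfig, scenario, context: PipelineContext | None = None) -> pd.DataFrame:
    """Execute one scenario end to end; returns one report row per breed.

    ``scenario`` is a :class:`ScenarioSpec` or an acronym string.  A scenario
    whose selection chain yields no QTL variant still runs, flagged
    ``degenerate_to_50k`` (it is then the array-only model).
    """
    spec = scenario if isinstance(scenario, ScenarioSpec) else parse_scenario(scenario)
    ctx = context if context is not None else PipelineContext(config)
    dataset, _, phenos = ctx.data()
    split = ctx.split()

    reports = []
    if spec.model == "WB":
        for b in config.simulation.breeds:
            qtl = ctx.qtl_set(spec, b.name) if spec.has_qtl_component else []
            if spec.has_qtl_component and not qtl:
                logger.warning("scenario %s: empty QTL selection for %s; degenerates to 50K-only",
                               spec.name, b.name)
            comps = selection.assemble_components(ctx.base_panel(), qtl, spec)
            designs = build_design(dataset, comps, split.training_ids[b.name])
            summary = gibbs_single_trait(designs, ctx.training_phenos(), spec, config.mcmc)
            reports.append(_evaluate_breed(spec, summary, dataset, phenos, split, b.name))
    else:
        qtl = ctx.qtl_set(spec, None) if spec.has_qtl_component else []
        if spec.has_qtl_component and not qtl:
            logger.warning("scenario %s: empty QTL selection; degenerates to 50K-only", spec.name)
        comps = selection.assemble_components(ctx.base_panel(), qtl, spec)
        designs = build_design(dataset, comps, split.all_training())
        if spec.model == "MB":
            summary = gibbs_single_trait(designs, ctx.training_phenos(), spec, config.mcmc)
        else:
            summary = gibbs_multi_trait(designs, ctx.training_phenos(), spec, config.mcmc)
        for b in config.simulation.breeds:
            reports.append(_evaluate_breed(spec, summary, dataset, phenos, split, b.name))

    frame = pd.DataFrame([r.to_row() for r in reports])
    frame.insert(0, "seed", config.seed)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / f"report_{spec.name.replace('/', '-')}.tsv", sep="\t", index=False)
    return frame


def run_grid(config: RunConfig, context: PipelineContext | None = None) -> pd.DataFrame:
    """Run every configured scenario with shared caches.

    Failing scenarios are recorded in ``context.failures`` (scenario name →
    exception) and the grid continues; the combined tidy report of the
    successful scenarios is returned.
    """
    ctx = context if context is not None else PipelineContext(config)
    frames = []
    for name in config.scenarios:
        try:
            frames.append(run_scenario(config, name, ctx))
        except Exception as exc:  # noqa: BLE001 - grid keeps going, failure recorded
            logger.error("scenario %s failed: %s", name, exc)
            ctx.failures[name] = exc
    if not frames:
        return pd.DataFrame()
    combined = pd.concat(frames, ignore_index=True)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        combined.to_csv(out / "report_grid.tsv", sep="\t", index=False)
    return combined
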