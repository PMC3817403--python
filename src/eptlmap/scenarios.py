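"""End-to-end scenario runners: candidate validation, pleiotropy, power.

Each scenario is fully determined by a :class:`ScenarioConfig` (loadable
from YAML) and an integer seed, simulates its own inputs through
:mod:`eptlmap.synthetic`, runs the relevant statistics, and returns a tidy
DataFrame report. The CLI's ``scenario`` subcommand is a thin wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cytometry import sample_stats
from .synthetic import PopulationParams, SporePanel, simulate_spore_panel
from .variability import classify_candidates, linkage_test, mannwhitney

logger = logging.getLogger(__name__)

SCENARIOS = ("validate_candidates", "pleiotropy", "lineage_power")


@dataclass
class ScenarioConfig:
    """One reproducible scenario run.

    ``candidate_effects`` maps locus labels to planted CV gains (zero means
    a spurious candidate); ``population`` sets the base generator
    parameters shared by all spores.
    """

    scenario: str = "validate_candidates"
    seed: int = 0
    alpha: float = 0.05
    n_spores: int = 40
    n_cells_per_spore: int = 10_000
    candidate_effects: dict[str, float] = field(
        default_factory=lambda: {"ePTL8": 0.018, "null_locus": 0.0}
    )
    # lineage_power grid
    effect_grid: tuple[float, ...] = (0.005, 0.01, 0.02)
    n_spores_grid: tuple[int, ...] = (20, 40, 80)
    n_replicates: int = 100
    # pleiotropy: planted effect of the locus on the second reporter
    pleiotropic_effect: float = 0.0
    population: PopulationParams = field(default_factory=PopulationParams)

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_spores < 3:
            raise ValueError("n_spores must be >= 3")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pop = PopulationParams(**raw.pop("population", {}))
        cfg = cls(population=pop, **raw)
        cfg.validate()
        return cfg


def _panel_linkage(panel: SporePanel):
    stats = [sample_stats(t) for t in panel.tables]
    return stats, linkage_test(stats, panel.genotypes)


def run_validate_candidates(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate one spore panel per candidate locus and test linkage.

    Mirrors the validation step of introgression mapping: the introgressed
    strain is crossed back to the recipient, random spores are phenotyped
    and genotyped at the candidate, and conditioned CV residuals are
    compared between genotype groups.
    """
    config.validate()
    pop = replace(config.population, n_cells=config.n_cells_per_spore)
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.candidate_effects))
    rows = []
    for (locus, effect), child in zip(config.candidate_effects.items(), seeds):
        panel = simulate_spore_panel(
            pop, effect, config.n_spores, seed=child.generate_state(1)[0]
        )
        _, result = _panel_linkage(panel)
        rows.append(
            {
                "locus": locus,
                "planted_cv_gain": effect,
                "n_spores": len(panel),
                "U": result.u_statistic,
                "p_value": result.p_value,
                "median_residual_difference": result.median_difference,
            }
        )
    report = pd.DataFrame(rows)
    report["validated"] = classify_candidates(report["p_value"], config.alpha)
    return report


def run_pleiotropy(config: ScenarioConfig) -> pd.DataFrame:
    """Test a locus against a second, unrelated reporter.

    A specific locus should show no linkage with the second reporter's CV
    (or mean); a pleiotropic one (ura3- or dst1-like) affects both
    reporters. ``pleiotropic_effect`` plants the locus effect on the second
    reporter; the scenario runs both that design and the zero-effect null.
    """
    config.validate()
    pop = replace(config.population, n_cells=config.n_cells_per_spore)
    designs = {"specific_null": 0.0, "pleiotropic": config.pleiotropic_effect}
    seeds = np.random.SeedSequence(config.seed).spawn(len(designs))
    rows = []
    for (design, effect), child in zip(designs.items(), seeds):
        panel = simulate_spore_panel(
            pop, effect, config.n_spores, seed=child.generate_state(1)[0]
        )
        stats, cv_result = _panel_linkage(panel)
        means = np.array([s.mean for s in stats])
        is_donor = np.array([g == "donor" for g in panel.genotypes])
        _, mean_p, _ = mannwhitney(means[is_donor], means[~is_donor])
        rows.append(
            {
                "design": design,
                "planted_cv_gain": effect,
                "cv_linkage_p": cv_result.p_value,
                "mean_linkage_p": mean_p,
                "cv_linked": cv_result.p_value < config.alpha,
                "mean_linked": mean_p < config.alpha,
            }
        )
    return pd.DataFrame(rows)


def run_lineage_power(config: ScenarioConfig) -> pd.DataFrame:
    """Empirical power of the linkage test over an effect x panel-size grid."""
    config.validate()
    pop = replace(config.population, n_cells=config.n_cells_per_spore)
    rows = []
    grid = [(e, n) for e in config.effect_grid for n in config.n_spores_grid]
    seeds = np.random.SeedSequence(config.seed).spawn(len(grid))
    for (effect, n_spores), cell_seed in zip(grid, seeds):
        rep_seeds = cell_seed.spawn(config.n_replicates)
        hits = 0
        for rs in rep_seeds:
            panel = simulate_spore_panel(
                pop, effect, n_spores, seed=rs.generate_state(1)[0]
            )
            try:
                _, result = _panel_linkage(panel)
            except ValueError:  # all spores drew the same genotype
                continue
            hits += result.p_value < config.alpha
        rows.append(
            {
                "cv_gain_effect": effect,
                "n_spores": n_spores,
                "n_replicates": config.n_replicates,
                "power": hits / config.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig) -> pd.DataFrame:
    """Dispatch on ``config.scenario``; logs config and row counts."""
    config.validate()
    logger.info("scenario=%s seed=%d", config.scenario, config.seed)
    runner = {
        "validate_candidates": run_validate_candidates,
        "pleiotropy": run_pleiotropy,
        "lineage_power": run_lineage_power,
    }[config.scenario]
    report = runner(config)
    logger.info("scenario %s produced %d rows", config.scenario, len(report))
    return report
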