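"""Synthetic cytometry, spore-panel, pileup and genotype-track generators.

The original raw flow-cytometry acquisitions and resequencing reads behind
the BY/RM introgression design were never deposited, so every input of the
pipeline can be generated here with known ground truth:

* per-cell tables (FSC, SSC, FL1) with lognormal size, size-coupled
  fluorescence, a declining CV~mean baseline and planted CV-gain (ePTL) or
  mean-shift (eQTL) effects;
* a repressive methionine dose-response of mean expression (decreasing
  Hill function) over the standard 0-200 uM induction series;
* backcross spore panels with Mendelian 1:1 segregation at a single locus;
* per-SNP pileup allele counts emulating ~45x whole-genome resequencing.

Single-cell expression is lognormal, parameterised by target mean and
target CV via moment matching; FL1 adds a linear log-FSC size term on top,
so the linear size conditioning in :mod:`eptlmap.cytometry` removes it
exactly in expectation. All generators take an explicit integer seed and
never touch global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cytometry import CELL_COLUMNS
from .variability import DONOR, RECIPIENT

#: Methionine induction series (uM) used throughout: full induction at 0,
#: moderate activation up to 200 uM. The repressive pre-culture condition
#: is 1000 uM (1 mM).
DEFAULT_CONCENTRATIONS_UM = (0.0, 5.0, 20.0, 50.0, 100.0, 150.0, 200.0)
REPRESSIVE_UM = 1000.0


@dataclass
class PopulationParams:
    """Ground-truth parameters of one simulated cell population.

    The target CV of the expression component at mean ``m`` is
    ``baseline_cv_intercept + baseline_cv_slope * m + cv_gain_effect``;
    ``mean_shift_effect`` shifts the target mean (an eQTL-like effect)
    while ``cv_gain_effect`` adds variability at fixed mean (an ePTL-like
    effect). ``size_coupling`` adds ``size_coupling * (log FSC - fsc_log_mean)``
    to FL1 on the linear scale.
    """

    mean_expression: float = 100.0  # a.u.
    baseline_cv_intercept: float = 0.25
    baseline_cv_slope: float = -0.001  # per a.u.
    cv_gain_effect: float = 0.0
    mean_shift_effect: float = 0.0  # a.u.
    size_coupling: float = 20.0  # a.u. per log-FSC unit
    fsc_log_mean: float = 5.5
    fsc_log_sd: float = 0.25
    ssc_log_mean: float = 5.0
    ssc_log_sd: float = 0.35
    n_cells: int = 10_000
    sample_id: str = "sample"
    strain: str = "BY"
    methionine_uM: float = 50.0

    @property
    def target_mean(self) -> float:
        return self.mean_expression + self.mean_shift_effect

    @property
    def target_cv(self) -> float:
        return (
            self.baseline_cv_intercept
            + self.baseline_cv_slope * self.target_mean
            + self.cv_gain_effect
        )

    def validate(self) -> None:
        values = [
            self.mean_expression,
            self.baseline_cv_intercept,
            self.baseline_cv_slope,
            self.cv_gain_effect,
            self.mean_shift_effect,
            self.size_coupling,
            self.fsc_log_mean,
            self.fsc_log_sd,
            self.ssc_log_mean,
            self.ssc_log_sd,
        ]
        if not all(np.isfinite(values)):
            raise ValueError("non-finite population parameter")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.fsc_log_sd < 0 or self.ssc_log_sd < 0:
            raise ValueError("scatter log-s.d. must be >= 0")
        if self.target_mean <= 0:
            raise ValueError("target mean expression must be > 0")
        if self.target_cv < 0:
            raise ValueError(
                f"target CV {self.target_cv:.4g} < 0 at mean "
                f"{self.target_mean:.4g}: rejected, not clipped"
            )


@dataclass
class DoseResponse:
    """Decreasing Hill response of mean expression to methionine.

    ``mean(c) = floor_mean + (max_mean - floor_mean) / (1 + (c / hill_k)**hill_n)``
    — full induction ``max_mean`` at c = 0, asymptote ``floor_mean`` under
    strong repression.
    """

    max_mean: float = 150.0  # a.u.
    hill_k: float = 50.0  # uM, half-repression concentration
    hill_n: float = 1.5
    floor_mean: float = 10.0  # a.u.

    def validate(self) -> None:
        if not self.max_mean > self.floor_mean >= 0:
            raise ValueError("require max_mean > floor_mean >= 0")
        if self.hill_k <= 0 or self.hill_n <= 0:
            raise ValueError("hill_k and hill_n must be > 0")

    def mean_at(self, concentration_uM) -> np.ndarray:
        c = np.asarray(concentration_uM, dtype=float)
        if (c < 0).any():
            raise ValueError("concentrations must be >= 0")
        self.validate()
        return self.floor_mean + (self.max_mean - self.floor_mean) / (
            1.0 + (c / self.hill_k) ** self.hill_n
        )


@dataclass
class TruthTrack:
    """Ground-truth per-SNP genotypes and the donor regions planted in them.

    ``sites`` has columns chrom, pos (1-based, strictly increasing per
    chromosome) and genotype (donor/recipient); ``regions`` lists the
    planted donor intervals as (chrom, start, end) in the same coordinates.
    """

    sites: pd.DataFrame
    regions: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, group in self.sites.groupby("chrom", sort=False):
            pos = group["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        for chrom, start, end in self.regions:
            mask = (
                (self.sites["chrom"] == chrom)
                & (self.sites["pos"] >= start)
                & (self.sites["pos"] <= end)
            )
            if not mask.any():
                raise ValueError(f"planted region {chrom}:{start}-{end} covers no SNP")


@dataclass
class SporePanel:
    """Spore genotypes at one locus plus the per-spore cell tables."""

    genotypes: list[str]
    tables: list[pd.DataFrame]

    def __len__(self) -> int:
        return len(self.genotypes)


def _lognormal_expression(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> np.ndarray:
    """Lognormal draws with the requested mean and CV (moment-matched)."""
    if cv == 0.0:
        return np.full(n, mean, dtype=float)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def simulate_cells(params: PopulationParams, seed: int) -> pd.DataFrame:
    """Simulate one acquisition sample of ``params.n_cells`` cells.

    FSC and SSC are lognormal; FL1 is the lognormal expression component
    (target mean ``params.target_mean``, target CV ``params.target_cv``)
    plus the linear size term ``size_coupling * (log FSC - fsc_log_mean)``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_cells
    log_fsc = rng.normal(params.fsc_log_mean, params.fsc_log_sd, size=n)
    log_ssc = rng.normal(params.ssc_log_mean, params.ssc_log_sd, size=n)
    expression = _lognormal_expression(rng, params.target_mean, params.target_cv, n)
    fl1 = expression + params.size_coupling * (log_fsc - params.fsc_log_mean)
    return pd.DataFrame(
        {
            "sample_id": params.sample_id,
            "strain": params.strain,
            "methionine_uM": params.methionine_uM,
            "FSC": np.exp(log_fsc),
            "SSC": np.exp(log_ssc),
            "FL1": fl1,
        },
        columns=CELL_COLUMNS,
    )


def methionine_series(
    params: PopulationParams,
    dose: DoseResponse,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_UM,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """One simulated sample per methionine concentration.

    The planted mean at concentration c follows the Hill dose-response;
    the planted CV follows the baseline CV~mean law at that mean plus any
    planted gain. Each concentration gets an independent child seed.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValueError("empty concentration list")
    dose.validate()
    seeds = np.random.SeedSequence(seed).spawn(len(concentrations))
    tables = []
    for c, child in zip(concentrations, seeds):
        mean_c = float(dose.mean_at(c))
        p = replace(
            params,
            mean_expression=mean_c,
            methionine_uM=float(c),
            sample_id=f"{params.sample_id}_met{c:g}",
        )
        tables.append(simulate_cells(p, seed=child.generate_state(1)[0]))
    return tables


def simulate_spore_panel(
    params: PopulationParams,
    cv_gain_effect: float,
    n_spores: int,
    seed: int,
    mean_shift_effect: float = 0.0,
) -> SporePanel:
    """Backcross spore panel segregating 1:1 at one locus.

    Each spore is donor or recipient with probability 1/2 independently;
    donor spores receive the planted CV gain (and optional mean shift) on
    top of the baseline population parameters.
    """
    if n_spores < 2:
        raise ValueError("need >= 2 spores")
    rng = np.random.default_rng(seed)
    genotypes = [DONOR if rng.random() < 0.5 else RECIPIENT for _ in range(n_spores)]
    seeds = np.random.SeedSequence(rng.integers(2**31)).spawn(n_spores)
    tables = []
    for i, (g, child) in enumerate(zip(genotypes, seeds)):
        extra_cv = cv_gain_effect if g == DONOR else 0.0
        extra_mean = mean_shift_effect if g == DONOR else 0.0
        p = replace(
            params,
            cv_gain_effect=params.cv_gain_effect + extra_cv,
            mean_shift_effect=params.mean_shift_effect + extra_mean,
            sample_id=f"spore{i:04d}",
            strain=g,
        )
        tables.append(simulate_cells(p, seed=child.generate_state(1)[0]))
    return SporePanel(genotypes=genotypes, tables=tables)


def make_truth_track(
    regions: Sequence[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    snp_spacing: int = 300,
    flipped_sites: Sequence[tuple[str, int]] = (),
) -> TruthTrack:
    """Build a ground-truth SNP track with planted donor regions.

    SNPs are placed every ``snp_spacing`` bp along each chromosome (the
    BY/RM pair carries ~42,800 SNPs over a ~12 Mb genome, i.e. one SNP per
    ~280 bp). Sites inside a planted region are donor, all others
    recipient; ``flipped_sites`` inverts the truth at single positions to
    emulate isolated miscalls or private mutations.
    """
    rows = []
    flipped = set(flipped_sites)
    for chrom, length in chrom_lengths.items():
        positions = np.arange(snp_spacing, length + 1, snp_spacing, dtype=int)
        genotype = np.full(len(positions), RECIPIENT, dtype=object)
        for r_chrom, start, end in regions:
            if r_chrom == chrom:
                genotype[(positions >= start) & (positions <= end)] = DONOR
        for i, pos in enumerate(positions):
            g = genotype[i]
            if (chrom, int(pos)) in flipped:
                g = DONOR if g == RECIPIENT else RECIPIENT
            rows.append((chrom, int(pos), g))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "genotype"])
    track = TruthTrack(sites=sites, regions=list(regions))
    track.validate()
    return track


def simulate_pileup(
    truth: TruthTrack, coverage: float, error_rate: float, seed: int
) -> pd.DataFrame:
    """Per-SNP allele counts emulating short-read resequencing.

    Depth at each site is Poisson(``coverage``); each read reports the true
    allele with probability ``1 - error_rate`` and the other allele
    otherwise (symmetric error). Returns a table with columns chrom, pos,
    donor_count, recipient_count.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    truth.validate()
    rng = np.random.default_rng(seed)
    sites = truth.sites
    depth = rng.poisson(coverage, size=len(sites))
    p_donor = np.where(
        sites["genotype"].to_numpy() == DONOR, 1.0 - error_rate, error_rate
    )
    donor_count = rng.binomial(depth, p_donor)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "donor_count": donor_count,
            "recipient_count": depth - donor_count,
        }
    )
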