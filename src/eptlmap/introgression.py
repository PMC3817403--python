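"""Forward simulation of backcross introgression with phenotypic selection.

A donor genome (RM-like) is introgressed into a recipient background
(BY-like) by repeated backcrossing: at every generation spores are drawn by
meiosis, phenotyped (simulated CV gain and mean shift), and the spore with
the highest CV gain among those with near-recipient mean is carried
forward. Without selection the expected donor genome fraction halves each
generation, reaching 2^-7 (~0.8%) after seven generations; selection at k
unlinked loci retains those loci plus linkage drag around them.

Crossovers follow the Haldane model: per chromosome the crossover count is
Poisson(length_cM / 100) with positions uniform along the chromosome (no
interference). Genomes are haploid segment lists in genetic-map (cM)
coordinates; bp coordinates are proportional within each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variability import DONOR, RECIPIENT

logger = logging.getLogger(__name__)

#: S288c nuclear chromosome sizes in bp (chromosomes I-XVI).
S288C_CHROM_BP = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}

#: Genome-average recombination rate used for the default map (cM per kb).
DEFAULT_CM_PER_KB = 0.36


@dataclass(frozen=True)
class GeneticMap:
    """Chromosome lengths in cM and bp; cM <-> bp proportional per chromosome."""

    lengths_cM: dict[str, float]
    lengths_bp: dict[str, int]

    def __post_init__(self):
        if set(self.lengths_cM) != set(self.lengths_bp):
            raise ValueError("cM and bp maps must cover the same chromosomes")
        for chrom in self.lengths_cM:
            if self.lengths_cM[chrom] <= 0 or self.lengths_bp[chrom] <= 0:
                raise ValueError(f"non-positive length for {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths_cM)

    @property
    def total_cM(self) -> float:
        return float(sum(self.lengths_cM.values()))

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths_bp.values()))

    def bp_to_cM(self, chrom: str, pos_bp: float) -> float:
        return pos_bp / self.lengths_bp[chrom] * self.lengths_cM[chrom]

    @classmethod
    def yeast_default(cls, cm_per_kb: float = DEFAULT_CM_PER_KB) -> "GeneticMap":
        """16-chromosome map with S288c bp sizes and a uniform cM/kb rate."""
        return cls(
            lengths_cM={c: bp / 1000.0 * cm_per_kb for c, bp in S288C_CHROM_BP.items()},
            lengths_bp=dict(S288C_CHROM_BP),
        )


@dataclass
class HaplotypeGenome:
    """Haploid genome as per-chromosome lists of labeled cM intervals.

    ``segments[chrom]`` is an ordered list of ``(start_cM, end_cM, label)``
    half-open intervals tiling the chromosome exactly; adjacent intervals
    carry distinct labels after :meth:`normalize`.
    """

    segments: dict[str, list[tuple[float, float, str]]]

    @classmethod
    def uniform(cls, genetic_map: GeneticMap, label: str) -> "HaplotypeGenome":
        return cls(
            {
                chrom: [(0.0, genetic_map.lengths_cM[chrom], label)]
                for chrom in genetic_map.chromosomes
            }
        )

    def normalize(self) -> "HaplotypeGenome":
        """Merge adjacent same-label intervals in place; returns self."""
        for chrom, segs in self.segments.items():
            merged: list[tuple[float, float, str]] = []
            for start, end, label in segs:
                if merged and merged[-1][2] == label and merged[-1][1] == start:
                    merged[-1] = (merged[-1][0], end, label)
                else:
                    merged.append((start, end, label))
            self.segments[chrom] = merged
        return self

    def check_tiling(self, genetic_map: GeneticMap, tol: float = 1e-9) -> None:
        for chrom in genetic_map.chromosomes:
            segs = self.segments[chrom]
            if abs(segs[0][0]) > tol or abs(segs[-1][1] - genetic_map.lengths_cM[chrom]) > tol:
                raise ValueError(f"{chrom}: segments do not span the chromosome")
            for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
                if abs(e0 - s1) > tol or e0 <= s0 or e1 <= s1:
                    raise ValueError(f"{chrom}: gap, overlap or empty interval")

    def genotype_at(self, chrom: str, pos_cM: float) -> str:
        """Label of the interval containing ``pos_cM`` (right-closed at the end)."""
        segs = self.segments[chrom]
        for start, end, label in segs:
            if start <= pos_cM < end:
                return label
        if pos_cM == segs[-1][1]:
            return segs[-1][2]
        raise ValueError(f"position {pos_cM} cM outside {chrom}")

    def label_length(self, label: str) -> float:
        return sum(
            end - start
            for segs in self.segments.values()
            for start, end, seg_label in segs
            if seg_label == label
        )


def donor_fraction(
    genome: HaplotypeGenome, genetic_map: GeneticMap, scale: str = "cM"
) -> float:
    """Fraction of the genome carrying the donor label, in cM or bp."""
    if scale not in ("cM", "bp"):
        raise ValueError("scale must be 'cM' or 'bp'")
    if scale == "cM":
        return genome.label_length(DONOR) / genetic_map.total_cM
    total = 0.0
    for chrom, segs in genome.segments.items():
        bp_per_cM = genetic_map.lengths_bp[chrom] / genetic_map.lengths_cM[chrom]
        total += sum((end - start) * bp_per_cM for start, end, lab in segs if lab == DONOR)
    return total / genetic_map.total_bp


def meiosis(
    mother: HaplotypeGenome,
    father: HaplotypeGenome,
    genetic_map: GeneticMap,
    seed: int | np.random.Generator,
) -> HaplotypeGenome:
    """One gamete from the diploid formed by two haploid parents.

    Per chromosome: crossover count ~ Poisson(L/100), positions uniform on
    (0, L); the gamete copies alternating parental haplotypes between
    crossovers, starting from a fair-coin choice of parent.
    """
    if set(mother.segments) != set(father.segments) or set(mother.segments) != set(
        genetic_map.chromosomes
    ):
        raise ValueError("parents and map must cover the same chromosomes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamete: dict[str, list[tuple[float, float, str]]] = {}
    for chrom in genetic_map.chromosomes:
        length = genetic_map.lengths_cM[chrom]
        n_co = rng.poisson(length / 100.0)
        breaks = np.sort(rng.uniform(0.0, length, size=n_co))
        bounds = np.concatenate([[0.0], breaks, [length]])
        current = int(rng.integers(2))  # 0 = mother, 1 = father
        parents = (mother, father)
        segs: list[tuple[float, float, str]] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            segs.extend(_slice(parents[current].segments[chrom], lo, hi))
            current = 1 - current
        gamete[chrom] = segs
    return HaplotypeGenome(gamete).normalize()


def _slice(
    segs: Sequence[tuple[float, float, str]], lo: float, hi: float
) -> list[tuple[float, float, str]]:
    out = []
    for start, end, label in segs:
        s, e = max(start, lo), min(end, hi)
        if e > s:
            out.append((s, e, label))
    return out


@dataclass
class LocusEffect:
    """Phenotypic effect of a donor allele at one map position."""

    chrom: str
    pos_cM: float
    cv_gain: float = 0.0
    mean_shift: float = 0.0


@dataclass
class LineageConfig:
    """Design of one introgression lineage.

    Defaults mirror the published design: seven generations, one spore
    chosen among ~40 per generation, selection for high CV gain among
    spores whose mean expression stays within ``mean_tolerance`` of the
    recipient's.
    """

    generations: int = 7
    n_spores_per_generation: int = 40
    target_loci: list[LocusEffect] = field(default_factory=list)
    cv_noise_sd: float = 0.005
    mean_noise_sd: float = 2.0
    mean_tolerance: float = 10.0
    genetic_map: GeneticMap = field(default_factory=GeneticMap.yeast_default)

    def validate(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_spores_per_generation < 2:
            raise ValueError("n_spores_per_generation must be >= 2")
        for locus in self.target_loci:
            if locus.chrom not in self.genetic_map.lengths_cM:
                raise ValueError(f"target locus chromosome {locus.chrom} not on map")
            if not 0.0 <= locus.pos_cM <= self.genetic_map.lengths_cM[locus.chrom]:
                raise ValueError(f"target locus {locus.pos_cM} cM off {locus.chrom}")


def spore_phenotype(
    genome: HaplotypeGenome, config: LineageConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Simulated (cv_gain, mean_shift) of a spore: locus effects plus noise."""
    cv = 0.0
    mean = 0.0
    for locus in config.target_loci:
        if genome.genotype_at(locus.chrom, locus.pos_cM) == DONOR:
            cv += locus.cv_gain
            mean += locus.mean_shift
    cv += rng.normal(0.0, config.cv_noise_sd)
    mean += rng.normal(0.0, config.mean_noise_sd)
    return cv, mean


def backcross_generation(
    current: HaplotypeGenome,
    config: LineageConfig,
    seed: int | np.random.Generator,
    recipient: HaplotypeGenome | None = None,
) -> HaplotypeGenome:
    """Cross the current spore to the recipient and select one offspring spore.

    Phenotypic selection: among spores whose |mean shift| is within the
    tolerance, pick the maximum simulated CV gain. If no spore passes the
    mean filter, the spore with the smallest |mean shift| is taken instead
    (with a warning), mirroring selection pressure that cannot be relaxed
    mid-experiment.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if recipient is None:
        recipient = HaplotypeGenome.uniform(config.genetic_map, RECIPIENT)
    spores = [
        meiosis(current, recipient, config.genetic_map, rng)
        for _ in range(config.n_spores_per_generation)
    ]
    phenos = [spore_phenotype(s, config, rng) for s in spores]
    passing = [i for i, (_, m) in enumerate(phenos) if abs(m) <= config.mean_tolerance]
    if not passing:
        logger.warning("no spore within mean tolerance; taking nearest-mean spore")
        best = min(range(len(spores)), key=lambda i: abs(phenos[i][1]))
    else:
        best = max(passing, key=lambda i: phenos[i][0])
    return spores[best]


@dataclass
class LineageResult:
    """Final genome and per-generation log of one simulated lineage."""

    genome: HaplotypeGenome
    donor_fraction_cM: float
    donor_fraction_bp: float
    loci_retained: list[bool]
    generation_log: list[dict]


def run_lineage(config: LineageConfig, seed: int) -> LineageResult:
    """Run one introgression lineage of ``config.generations`` generations.

    Generation 1 sporulates the fully heterozygous F1 (donor x recipient),
    so the selected spore carries half the donor genome in expectation;
    each subsequent generation backcrosses the selected spore to the
    recipient, halving the expectation again. Without selection the
    expected donor fraction after g generations is 2^-g.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    gmap = config.genetic_map
    recipient = HaplotypeGenome.uniform(gmap, RECIPIENT)
    current = HaplotypeGenome.uniform(gmap, DONOR)  # haploid donor parent of the F1
    log = []
    for gen in range(1, config.generations + 1):
        current = backcross_generation(current, config, rng, recipient=recipient)
        log.append(
            {
                "generation": gen,
                "donor_fraction_cM": donor_fraction(current, gmap, "cM"),
                "donor_fraction_bp": donor_fraction(current, gmap, "bp"),
            }
        )
    retained = [
        current.genotype_at(l.chrom, l.pos_cM) == DONOR for l in config.target_loci
    ]
    return LineageResult(
        genome=current,
        donor_fraction_cM=log[-1]["donor_fraction_cM"],
        donor_fraction_bp=log[-1]["donor_fraction_bp"],
        loci_retained=retained,
        generation_log=log,
    )


def retention_prob(k: int) -> float:
    """Probability that one spore carries the donor allele at k unlinked loci.

    Each heterozygous locus segregates independently 1:1, so the
    probability is 2^-k (e.g. 1/64 for six loci).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    return 0.5**k


def haldane_recombination_fraction(distance_cM: float) -> float:
    """Haldane map function r = (1 - exp(-2d/100)) / 2."""
    if distance_cM < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * distance_cM / 100.0))


def genome_to_bed(
    genome: HaplotypeGenome, genetic_map: GeneticMap, label: str = DONOR
) -> list[tuple[str, int, int]]:
    """Segments carrying ``label`` as 0-based half-open bp intervals (BED)."""
    rows = []
    for chrom, segs in genome.segments.items():
        bp_per_cM = genetic_map.lengths_bp[chrom] / genetic_map.lengths_cM[chrom]
        for start, end, seg_label in segs:
            if seg_label == label:
                rows.append((chrom, int(round(start * bp_per_cM)), int(round(end * bp_per_cM))))
    return rows
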