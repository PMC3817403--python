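"""Double-marker recombinant screens and perfect-discriminator fine mapping.

A candidate region flanked by two selectable genes (e.g. *THR1* and *COX6*
around the chrVIII variability locus) permits a powerful screen: in a
diploid heterozygous across the region, with one null marker on each
haplotype, only spores that recombined between the flanks survive double
selection. Genotyping the survivors at markers spanning the region and
asking which marker's genotype exactly partitions the low- from
high-variability spores localises the causal polymorphism to the interval
between the nearest non-discriminating flanking markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .introgression import GeneticMap, HaplotypeGenome
from .variability import DONOR, RECIPIENT

LOW = "low-CV"
HIGH = "high-CV"


@dataclass
class RecombinantPanel:
    """Recombinant strains x ordered markers, with a phenotype class each.

    ``genotypes`` is a strains-by-markers DataFrame of donor/recipient
    calls whose columns are 1-based marker positions (bp, strictly
    increasing); ``phenotypes`` holds one class label per strain.
    """

    genotypes: pd.DataFrame
    phenotypes: list[str]

    def __post_init__(self):
        positions = list(self.genotypes.columns)
        if positions != sorted(positions):
            raise ValueError("marker positions must be strictly increasing")
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate marker positions")
        if len(self.phenotypes) != len(self.genotypes):
            raise ValueError("one phenotype per strain required")
        if self.genotypes.isna().any().any():
            raise ValueError("missing genotype calls in panel")

    @property
    def marker_positions(self) -> list[int]:
        return list(self.genotypes.columns)


def select_recombinants(
    spores: Sequence[HaplotypeGenome],
    genetic_map: GeneticMap,
    chrom: str,
    left_marker_bp: int,
    right_marker_bp: int,
) -> list[HaplotypeGenome]:
    """Keep spores with donor genotype at the left flank and recipient at the right.

    This is the viability-selected class of a double-marker screen: every
    surviving spore is necessarily recombinant within the interval. Both
    markers must be on the same chromosome with left < right.
    """
    if left_marker_bp >= right_marker_bp:
        raise ValueError("left marker must precede right marker")
    if chrom not in genetic_map.lengths_bp:
        raise ValueError(f"unknown chromosome {chrom}")
    left_cM = genetic_map.bp_to_cM(chrom, left_marker_bp)
    right_cM = genetic_map.bp_to_cM(chrom, right_marker_bp)
    return [
        s
        for s in spores
        if s.genotype_at(chrom, left_cM) == DONOR
        and s.genotype_at(chrom, right_cM) == RECIPIENT
    ]


def panel_from_genomes(
    spores: Sequence[HaplotypeGenome],
    genetic_map: GeneticMap,
    chrom: str,
    marker_positions_bp: Sequence[int],
    phenotypes: Sequence[str],
) -> RecombinantPanel:
    """Genotype a set of spores at ordered markers to build a panel."""
    rows = []
    for spore in spores:
        rows.append(
            [
                spore.genotype_at(chrom, genetic_map.bp_to_cM(chrom, pos))
                for pos in marker_positions_bp
            ]
        )
    genotypes = pd.DataFrame(rows, columns=list(marker_positions_bp))
    return RecombinantPanel(genotypes=genotypes, phenotypes=list(phenotypes))


def classify_gains(gains: Sequence[float]) -> list[str]:
    """Split quantitative CV gains into low/high classes by 1-D 2-means.

    Exact over sorted split points: the boundary minimising total
    within-class sum of squares. Strains below the boundary are LOW.
    """
    arr = np.asarray(list(gains), dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 gains to classify")
    order = np.argsort(arr)
    sorted_arr = arr[order]
    best_split, best_cost = 1, np.inf
    for k in range(1, arr.size):
        lo, hi = sorted_arr[:k], sorted_arr[k:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_split = cost, k
    threshold = sorted_arr[best_split - 1]
    return [LOW if g <= threshold else HIGH for g in arr]


@dataclass
class DiscriminatorResult:
    """Markers perfectly co-segregating with phenotype, and their interval."""

    markers: list[int]
    interval: tuple[int, int] | None  # half-open bp candidate region


def perfect_discriminator(panel: RecombinantPanel) -> DiscriminatorResult:
    """Find markers whose genotype exactly partitions the phenotype classes.

    A marker is a perfect discriminator when its donor/recipient split
    equals the low/high phenotype split (either polarity, zero
    misclassification). The candidate interval spans from the nearest
    non-discriminating marker on the left to the nearest one on the right
    of the perfect block; when the block reaches the panel edge, the edge
    marker position bounds the interval. Invariant to strain order and to
    which allele is labeled donor.
    """
    classes = set(panel.phenotypes)
    if len(classes) < 2:
        raise ValueError("both phenotype classes must be present")
    pheno = np.asarray(panel.phenotypes)
    pheno_low = pheno == sorted(classes)[1]  # boolean partition; polarity-free below
    perfect = []
    positions = panel.marker_positions
    for pos in positions:
        geno_donor = panel.genotypes[pos].to_numpy() == DONOR
        if (geno_donor == pheno_low).all() or (geno_donor == ~pheno_low).all():
            perfect.append(pos)
    if not perfect:
        return DiscriminatorResult(markers=[], interval=None)
    leftmost, rightmost = min(perfect), max(perfect)
    non_perfect_left = [p for p in positions if p < leftmost and p not in perfect]
    non_perfect_right = [p for p in positions if p > rightmost and p not in perfect]
    left_bound = max(non_perfect_left) if non_perfect_left else positions[0]
    right_bound = min(non_perfect_right) if non_perfect_right else positions[-1]
    return DiscriminatorResult(markers=perfect, interval=(left_bound, right_bound))


def interval_span_kb(left_pos: int, right_pos: int, rounded: bool = False) -> float:
    """Span of a marker interval in kb, optionally rounded to the nearest kb."""
    if left_pos >= right_pos:
        raise ValueError("left position must be < right position")
    kb = (right_pos - left_pos) / 1000.0
    return float(round(kb)) if rounded else kb
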