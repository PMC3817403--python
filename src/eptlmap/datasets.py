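"""Published reference values from the BY/RM introgression of P_met17-GFP
cell-to-cell variability.

The raw cytometry and sequencing data of that experiment were never
deposited; what survives in print is the table of introgressed regions
found in the three seventh-generation strains (W7, X7, Z7), the linkage
validation P-values at each region's marker, and the headline CV-gain
effect sizes. They are embedded here so the pipeline's region-filtering
and candidate-classification logic can be exercised against the published
outcome, and so the synthetic generators can plant realistic effects.
"""

from __future__ import annotations

import pandas as pd

from .regions import Region

# Introgressed regions detected at ~45x in the three lineages. Positions are
# 1-based S288c coordinates of the outermost donor (RM-genotype) SNPs.
# Single-SNP rows (chrVII:1,026,099 and chrXII:5,741) have no marker or
# validation P: they were treated as probable sequencing errors.
_REGION_ROWS = [
    # strain, chrom, from, to, marker_pos, validation_p, id
    ("W7", "chrIX", 193_200, 203_412, 199_365, 0.299, None),
    ("W7", "chrXIII", 13_365, 41_051, 40_087, 0.00928, "ePTL13"),
    ("X7", "chrI", 27_811, 67_477, 47_045, 0.0388, "ePTL1"),
    ("X7", "chrV", 191_817, 211_558, 203_237, 0.161, None),
    ("X7", "chrVII", 577_844, 745_593, 599_377, 6.66e-05, "ePTL7"),
    ("X7", "chrVII", 1_026_099, 1_026_099, None, None, None),
    ("X7", "chrXIII", 799_196, 807_742, 807_167, 0.554, None),
    ("Z7", "chrVI", 256_480, 270_099, 263_987, 0.242, None),
    ("Z7", "chrVIII", 160_589, 212_237, 160_869, 2.41e-11, "ePTL8"),
    ("Z7", "chrXII", 5_741, 5_741, None, None, None),
    ("Z7", "chrXV", 563_573, 703_057, 625_582, 0.4, None),
]

#: Published single-locus CV gains of the four validated ePTLs.
EPTL_CV_GAINS = {"ePTL1": 0.003, "ePTL7": 0.014, "ePTL8": 0.018, "ePTL13": 0.019}

#: CV gain of the strain cumulating ePTL7 + ePTL8 + ePTL13.
COMBINED_CV_GAIN = 0.049

#: BY/RM CV difference after removing the artificial ura3 effect.
BY_RM_CV_DIFFERENCE = 0.031

#: Number of donor/recipient SNPs distinguishing the two backgrounds.
N_REFERENCE_SNPS = 42_794

# Fine mapping of ePTL8 on chrVIII: eight-marker recombinant screen between
# the thr1/cox6 selection flanks. The marker at 175,005 perfectly
# discriminated low- from high-variability recombinants, delimiting a 6-kb
# variability interval (171,530-177,601, containing only ERC1) and a larger
# mean-expression interval (177,601-209,170).
FINE_MAPPING_MARKERS_BP = (171_530, 175_005, 177_601, 186_650, 191_000, 197_000, 203_000, 209_170)
VARIABILITY_INTERVAL_BP = (171_530, 177_601)
MEAN_INTERVAL_BP = (177_601, 209_170)


def known_regions_table() -> pd.DataFrame:
    """The published introgressed-region table as a DataFrame."""
    return pd.DataFrame(
        _REGION_ROWS,
        columns=["strain", "chrom", "from", "to", "marker_pos", "validation_p", "id"],
    )


def known_regions() -> list[Region]:
    """The published regions as :class:`~eptlmap.regions.Region` objects."""
    out = []
    for strain, chrom, start, end, _marker, p, rid in _REGION_ROWS:
        out.append(
            Region(
                chrom=chrom,
                start=start,
                end=end,
                n_snps=1 if start == end else 2,  # lower bound; >= 2 for true regions
                strain=strain,
                validation_p=p,
                region_id=rid,
            )
        )
    return out


def validation_p_values() -> list[float]:
    """Linkage-validation P-values of the nine multi-SNP candidate regions."""
    return [p for *_, p, _rid in _REGION_ROWS if p is not None]
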