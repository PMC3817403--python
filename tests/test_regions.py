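"""Genotype calling, region segmentation and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import eptlmap as e
from eptlmap.datasets import known_regions, known_regions_table, validation_p_values
from eptlmap.introgression import S288C_CHROM_BP
from eptlmap.regions import regions_to_bed, regions_to_frame


def pileup_row(chrom, pos, donor, recipient):
    return {"chrom": chrom, "pos": pos, "donor_count": donor, "recipient_count": recipient}


class TestCallGenotypes:
    @pytest.mark.parametrize(
        "donor, recipient, expected",
        [
            (45, 0, "donor"),  # clean donor site
            (0, 0, "ambiguous"),  # zero depth
            (44, 1, "donor"),  # 44/45 = 0.978 >= 0.9
            (0, 45, "recipient"),
            (25, 20, "ambiguous"),  # 0.56 < 0.9 both ways
            (4, 0, "ambiguous"),  # below min_depth 5
        ],
    )
    def test_threshold_logic(self, donor, recipient, expected):
        pileup = pd.DataFrame([pileup_row("chrI", 100, donor, recipient)])
        track = e.call_genotypes(pileup, min_depth=5, donor_freq_threshold=0.9)
        assert track["call"].iloc[0] == expected

    def test_invalid_threshold_rejected(self):
        pileup = pd.DataFrame([pileup_row("chrI", 100, 10, 0)])
        with pytest.raises(ValueError):
            e.call_genotypes(pileup, donor_freq_threshold=0.4)
        with pytest.raises(ValueError):
            e.call_genotypes(pileup, min_depth=0)


def track_from_calls(calls, chrom="chrI", spacing=100):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, len(calls) + 1) * spacing,
            "call": calls,
        }
    )


class TestSegmentRegions:
    def test_all_recipient_no_regions(self):
        assert e.segment_regions(track_from_calls(["recipient"] * 10)) == []

    def test_all_donor_single_region(self):
        regions = e.segment_regions(track_from_calls(["donor"] * 10))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end, regions[0].n_snps) == (100, 1000, 10)

    def test_recipient_call_splits_without_bridging(self):
        calls = ["donor"] * 3 + ["recipient"] + ["donor"] * 3
        regions = e.segment_regions(track_from_calls(calls))
        assert [(r.start, r.end) for r in regions] == [(100, 300), (500, 700)]

    def test_max_bridge_merges_across_recipient_calls(self):
        calls = ["donor"] * 3 + ["recipient"] + ["donor"] * 3
        regions = e.segment_regions(track_from_calls(calls), max_bridge=1)
        assert [(r.start, r.end, r.n_snps) for r in regions] == [(100, 700, 6)]

    def test_ambiguous_calls_bridged_inside_runs(self):
        calls = ["donor", "ambiguous", "ambiguous", "donor"]
        regions = e.segment_regions(track_from_calls(calls))
        assert [(r.start, r.end, r.n_snps) for r in regions] == [(100, 400, 2)]

    def test_unsorted_track_rejected(self):
        track = track_from_calls(["donor"] * 3)
        track.loc[1, "pos"] = 1  # break ordering
        with pytest.raises(ValueError, match="not sorted"):
            e.segment_regions(track)

    def test_boundaries_are_outermost_donor_positions(self):
        calls = ["recipient", "ambiguous", "donor", "donor", "ambiguous", "recipient"]
        regions = e.segment_regions(track_from_calls(calls))
        assert [(r.start, r.end) for r in regions] == [(300, 400)]


class TestFilterRegions:
    def test_min_snps_one_is_identity(self):
        regions = e.segment_regions(track_from_calls(["donor", "recipient", "donor"]))
        assert e.filter_regions(regions, min_snps=1) == regions

    def test_single_snp_regions_dropped(self):
        calls = ["donor", "recipient", "donor", "donor"]
        regions = e.segment_regions(track_from_calls(calls))
        kept = e.filter_regions(regions, min_snps=2)
        assert len(regions) == 2 and len(kept) == 1
        assert kept[0].n_snps == 2

    def test_empty_input(self):
        assert e.filter_regions([], min_snps=2) == []

    def test_idempotent_and_order_preserving(self):
        calls = ["donor"] * 2 + ["recipient"] + ["donor"] * 4 + ["recipient", "donor"]
        regions = e.segment_regions(track_from_calls(calls))
        once = e.filter_regions(regions, min_snps=2)
        assert e.filter_regions(once, min_snps=2) == once
        starts = [r.start for r in once]
        assert starts == sorted(starts)


class TestRegionLength:
    def test_published_region_sizes(self):
        table = known_regions_table()
        z7_viii = table[(table.strain == "Z7") & (table.chrom == "chrVIII")].iloc[0]
        r = e.Region(chrom="chrVIII", start=int(z7_viii["from"]), end=int(z7_viii["to"]), n_snps=2)
        assert e.region_length_kb(r) == pytest.approx(51.648)
        assert e.region_length_kb(r) > 50
        x7_vii = table[(table.strain == "X7") & (table["from"] == 577_844)].iloc[0]
        r2 = e.Region(chrom="chrVII", start=int(x7_vii["from"]), end=int(x7_vii["to"]), n_snps=2)
        assert e.region_length_kb(r2, rounded=True) == 168

    def test_single_snp_region_zero_length(self):
        r = e.Region(chrom="chrXII", start=5741, end=5741, n_snps=1)
        assert e.region_length_kb(r) == 0.0

    def test_region_invariants(self):
        with pytest.raises(ValueError):
            e.Region(chrom="chrI", start=10, end=5, n_snps=2)
        with pytest.raises(ValueError):
            e.Region(chrom="chrI", start=10, end=10, n_snps=2)


class TestPublishedTableReconstruction:
    def test_planted_published_regions_recovered_boundary_exact(self):
        """Planting the 11 published donor intervals in synthetic truth tracks,
        simulating error-free 45x pileups, calling genotypes and segmenting
        recovers all 11 regions with exact boundaries; filtering single-SNP
        regions leaves the 9 candidates."""
        table = known_regions_table()
        all_regions = []
        for strain, group in table.groupby("strain"):
            planted = [
                (chrom, int(a), int(b))
                for chrom, a, b in group[["chrom", "from", "to"]].itertuples(
                    index=False, name=None
                )
            ]
            # SNP grid plus the published boundary positions themselves, so
            # boundary-exact recovery is possible
            rows = []
            for chrom, length in S288C_CHROM_BP.items():
                grid = set(range(997, length + 1, 997))
                grid |= {a for c, a, _ in planted if c == chrom}
                grid |= {b for c, _, b in planted if c == chrom}
                for pos in sorted(grid):
                    genotype = "recipient"
                    for c, a, b in planted:
                        if c == chrom and a <= pos <= b:
                            genotype = "donor"
                            break
                    rows.append({"chrom": chrom, "pos": pos, "genotype": genotype})
            track = e.TruthTrack(sites=pd.DataFrame(rows), regions=planted)
            track.validate()
            pileup = e.simulate_pileup(track, coverage=45.0, error_rate=0.0, seed=21)
            calls = e.call_genotypes(pileup)
            found = e.segment_regions(calls, strain=strain)
            all_regions.extend(found)
            for chrom, a, b in planted:
                match = [r for r in found if r.chrom == chrom and r.start == a and r.end == b]
                assert match, f"{strain} {chrom}:{a}-{b} not recovered exactly"
        assert len(all_regions) == 11
        kept = e.filter_regions(all_regions, min_snps=2)
        assert len(kept) == 9

    def test_validation_pvalues_classify_four_eptls(self):
        flags = e.classify_candidates(validation_p_values(), alpha=0.05)
        assert sum(flags) == 4

    def test_known_regions_objects_match_table(self):
        regions = known_regions()
        assert len(regions) == 11
        singles = [r for r in regions if r.n_snps == 1]
        assert {(r.chrom, r.start) for r in singles} == {
            ("chrVII", 1_026_099),
            ("chrXII", 5_741),
        }


class TestErrorModel:
    def test_isolated_errors_make_only_single_snp_regions(self):
        """At 45x with 1% per-base error, miscalls are isolated, produce only
        single-SNP regions, and min_snps=2 removes them all."""
        lengths = {"chrI": 1_500_000, "chrII": 1_500_000}
        planted = [("chrI", 400_000, 500_000)]
        track = e.make_truth_track(planted, lengths, snp_spacing=300)
        pileup = e.simulate_pileup(track, coverage=45.0, error_rate=0.01, seed=22)
        calls = e.call_genotypes(pileup, min_depth=5, donor_freq_threshold=0.9)
        found = e.segment_regions(calls)
        spurious = [
            r for r in found if not (r.chrom == "chrI" and r.start >= 400_000 and r.end <= 500_000)
        ]
        assert all(r.n_snps == 1 for r in spurious)
        kept = e.filter_regions(found, min_snps=2)
        assert len(kept) == 1
        assert kept[0].chrom == "chrI"
        # planted boundaries are SNP-grid positions inside [400k, 500k]
        assert 400_000 <= kept[0].start <= kept[0].end <= 500_000

    def test_flipped_truth_site_yields_removable_single_snp_region(self):
        lengths = {"chrI": 100_000}
        track = e.make_truth_track([], lengths, snp_spacing=500, flipped_sites=[("chrI", 50_000)])
        pileup = e.simulate_pileup(track, coverage=45.0, error_rate=0.0, seed=23)
        calls = e.call_genotypes(pileup)
        found = e.segment_regions(calls)
        assert [(r.start, r.end, r.n_snps) for r in found] == [(50_000, 50_000, 1)]
        assert e.filter_regions(found, min_snps=2) == []


def test_frame_and_bed_export():
    regions = [
        e.Region(chrom="chrVIII", start=160_589, end=212_237, n_snps=50, strain="Z7"),
        e.Region(chrom="chrXII", start=5_741, end=5_741, n_snps=1, strain="Z7"),
    ]
    frame = regions_to_frame(regions)
    assert list(frame.columns[:5]) == ["strain", "chrom", "from", "to", "n_snps"]
    bed = regions_to_bed(regions)
    # BED is 0-based half-open: start shifts by 1, inclusive end is kept
    assert bed.iloc[0]["start"] == 160_588 and bed.iloc[0]["end"] == 212_237
    assert bed.iloc[1]["end"] - bed.iloc[1]["start"] == 1


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    calls=st.lists(
        st.sampled_from(["donor", "recipient", "ambiguous"]), min_size=1, max_size=40
    ),
    min_snps=st.integers(1, 4),
)
def test_segmentation_properties(calls, min_snps):
    """Segmented regions are disjoint, ordered, bounded by donor calls, and
    jointly cover every donor call exactly once."""
    track = track_from_calls(calls)
    regions = e.segment_regions(track)
    donor_positions = set(track.loc[track["call"] == "donor", "pos"])
    covered = set()
    prev_end = -1
    for r in regions:
        assert r.start in donor_positions and r.end in donor_positions
        assert r.start > prev_end
        prev_end = r.end
        covered |= {p for p in donor_positions if r.start <= p <= r.end}
    assert covered == donor_positions
    kept = e.filter_regions(regions, min_snps=min_snps)
    assert all(r.n_snps >= min_snps for r in kept)
    assert e.filter_regions(kept, min_snps=min_snps) == kept
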