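"""Site model: PAM matching, cut prediction, single and composite scans."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dualcut.site_model import (
    CANONICAL_SPACING,
    ENZYMES,
    NMCAS9,
    SACAS9,
    SPCAS9,
    GuideSite,
    SiteModelError,
    classify_orientation,
    compare_targeting_range,
    enumerate_composite_sites,
    enumerate_guide_sites,
    match_pam,
    predict_cut_junction,
    revcomp,
)

import oracle_utils as orc


class TestMatchPam:
    @pytest.mark.parametrize("window,pattern,expected", [
        ("AGG", "NGG", True),
        ("GAAT", "GRRT", True),
        ("GCGT", "GRRT", False),
        ("TGG", "NGG", True),
        ("TCG", "NGG", False),
        ("GATT", "GATT", True),
        ("NGG", "NGG", False),   # genome N matches nothing, not even N
        ("AGN", "NGN", False),
    ])
    def test_iupac_semantics(self, window, pattern, expected):
        assert match_pam(window, pattern) is expected

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(SiteModelError):
            match_pam("AG", "NGG")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=8))
    def test_n_pattern_matches_every_unambiguous_window(self, window):
        assert match_pam(window, "N" * len(window))


class TestCutPrediction:
    @pytest.mark.parametrize("enzyme,proto,pam,strand,expected", [
        (SPCAS9, (100, 120), (120, 123), "+", 117),
        (SPCAS9, (100, 120), (97, 100), "-", 103),
        (SACAS9, (200, 221), (221, 227), "+", 218),
        (NMCAS9, (300, 324), (292, 300), "-", 303),
    ])
    def test_blunt_cut_three_bp_from_pam(self, enzyme, proto, pam, strand, expected):
        site = GuideSite(enzyme, "chr", proto[0], proto[1], pam[0], pam[1], strand)
        assert predict_cut_junction(site) == expected

    @pytest.mark.parametrize("enzyme", [SPCAS9, SACAS9, NMCAS9])
    @pytest.mark.parametrize("strand", "+-")
    def test_cut_distance_to_pam_proximal_edge_equals_offset(self, enzyme, strand):
        P, Q = enzyme.protospacer_length, enzyme.pam_length
        if strand == "+":
            site = GuideSite(enzyme, "c", 50, 50 + P, 50 + P, 50 + P + Q, "+")
            assert site.protospacer_end - site.cut_junction == enzyme.cut_offset
        else:
            site = GuideSite(enzyme, "c", 50 + Q, 50 + Q + P, 50, 50 + Q, "-")
            assert site.cut_junction - site.protospacer_start == enzyme.cut_offset

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(SiteModelError):
            GuideSite(SPCAS9, "c", 100, 120, 121, 124, "+")  # PAM not adjacent


class TestGuideSiteEnumeration:
    def test_poly_a_has_no_ngg_sites(self):
        assert enumerate_guide_sites({"c": "A" * 200}, SPCAS9, {"NGG"}) == []

    def test_single_planted_site_matches_brute_force(self, rng):
        seq = "".join(rng.choice(list("ACT"), 30))  # G-free background
        seq = seq[:2] + "".join(rng.choice(list("ACGT"), 20)) + "AGG" + seq[25:]
        sites = enumerate_guide_sites({"c": seq}, SPCAS9, {"NGG"})
        brute = orc.brute_guide_sites(seq, "SpCas9", ["NGG"])
        assert {(s.full_start, s.strand) for s in sites} == brute

    def test_n_bases_void_sites(self):
        seq = "A" * 20 + "AGG" + "A" * 5
        with_n = seq.replace("AGG", "NGG")
        assert len(enumerate_guide_sites({"c": seq}, SPCAS9, {"NGG"})) == 1
        assert enumerate_guide_sites({"c": with_n}, SPCAS9, {"NGG"}) == []

    @pytest.mark.parametrize("enzyme", [SPCAS9, SACAS9, NMCAS9])
    def test_counts_invariant_under_reverse_complement(self, enzyme, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        fwd = enumerate_guide_sites({"c": seq}, enzyme)
        rev = enumerate_guide_sites({"c": revcomp(seq)}, enzyme)
        assert len(fwd) == len(rev)

    def test_expanded_patterns_deduplicate_double_matches(self, rng):
        # an NGG PAM matches both NNG and NGN; the site must be unique
        seq = "".join(rng.choice(list("ACT"), 25)) + "AGG" + "TTTT"
        seq = "".join(np.random.default_rng(5).choice(list("ACGT"), 20)) + seq[20:]
        sites = enumerate_guide_sites({"c": seq}, SPCAS9, {"NNG", "NGN"})
        keys = [(s.full_start, s.strand) for s in sites]
        assert len(keys) == len(set(keys))

    def test_brute_force_agreement_on_random_contig(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        for enzyme, pats in ((SPCAS9, ["NGG"]), (SPCAS9, ["NNG", "NGN"]),
                             (SACAS9, ["GRRT"]), (NMCAS9, ["GATT"])):
            sites = enumerate_guide_sites({"c": seq}, enzyme, pats)
            assert ({(s.full_start, s.strand) for s in sites}
                    == orc.brute_guide_sites(seq, enzyme.name, pats))


def _planted_pair(spacing: int) -> str:
    """80-nt contig: SpCas9 site, then spacing nt, then an SaCas9 site (D1)."""
    rng = np.random.default_rng(17)
    sp = "".join(rng.choice(list("ACGT"), 20)) + "TGG"
    sa = "".join(rng.choice(list("ACGT"), 21)) + "CTGAAT"
    filler = "T" * (80 - len(sp) - spacing - len(sa))
    return sp + "A" * spacing + sa + filler


class TestCompositeEnumeration:
    def test_planted_pair_found_with_expected_spacing(self):
        genome = {"c": _planted_pair(15)}
        hits = enumerate_composite_sites(genome, SACAS9, "canonical")
        brute = orc.brute_composites(genome["c"], "SaCas9", ["NGG"], ["GRRT"],
                                     10, 30)
        assert orc.composite_keys(hits) == brute
        assert any(c.spacing_x == 15 and c.orientation == "D1" for c in hits)

    def test_spacing_range_excludes_planted_pair(self):
        hits = enumerate_composite_sites({"c": _planted_pair(15)}, SACAS9,
                                         "canonical", spacing_range=(20, 30))
        assert all(c.spacing_x >= 20 for c in hits)
        assert not any(c.spacing_x == 15 for c in hits)

    @pytest.mark.parametrize("partner", [SACAS9, NMCAS9])
    def test_expanded_mode_is_a_superset_of_canonical(self, partner, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        canonical = orc.composite_keys(
            enumerate_composite_sites({"c": seq}, partner, "canonical"))
        expanded = orc.composite_keys(
            enumerate_composite_sites({"c": seq}, partner, "expanded"))
        assert canonical <= expanded

    def test_counts_invariant_under_reverse_complement(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        fwd = enumerate_composite_sites({"c": seq}, SACAS9, "canonical")
        rev = enumerate_composite_sites({"c": revcomp(seq)}, SACAS9, "canonical")
        assert len(fwd) == len(rev)
        assert sorted(c.orientation for c in fwd) == sorted(c.orientation for c in rev)

    def test_brute_force_agreement_all_orientations(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 4000))
        hits = enumerate_composite_sites({"c": seq}, SACAS9, "canonical",
                                         orientations=("D1", "D2", "D3", "D4"))
        brute = orc.brute_composites(seq, "SaCas9", ["NGG"], ["GRRT"], 10, 30,
                                     orientations=("D1", "D2", "D3", "D4"))
        assert orc.composite_keys(hits) == brute

    def test_unknown_orientation_label_rejected(self):
        with pytest.raises(SiteModelError):
            enumerate_composite_sites({"c": "A" * 100}, SACAS9, "canonical",
                                      orientations=("D1", "D9"))

    def test_widening_spacing_never_removes_sites(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 4000))
        narrow = orc.composite_keys(enumerate_composite_sites(
            {"c": seq}, SACAS9, "canonical", spacing_range=(10, 20)))
        wide = orc.composite_keys(enumerate_composite_sites(
            {"c": seq}, SACAS9, "canonical", spacing_range=(10, 40)))
        assert narrow <= wide


class TestTargetingRange:
    def test_poly_a_genome_counts_zero_ratios_undefined(self):
        summary = compare_targeting_range({"c": "A" * 500}, SACAS9)
        assert summary["n_sp_only_NGG"] == 0
        assert summary["n_composite_canonical"] == 0
        assert summary["ratio_canonical"] is None
        assert summary["ratio_expanded"] is None

    def test_expanded_count_at_least_canonical(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 8000))
        summary = compare_targeting_range({"c": seq}, SACAS9)
        assert summary["n_composite_expanded"] >= summary["n_composite_canonical"]
        assert summary["ratio_expanded"] >= summary["ratio_canonical"]

    def test_counts_equal_brute_force(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        summary = compare_targeting_range({"c": seq}, NMCAS9)
        assert summary["n_sp_only_NGG"] == len(
            orc.brute_guide_sites(seq, "SpCas9", ["NGG"]))
        assert summary["n_composite_canonical"] == len(
            orc.brute_composites(seq, "NmCas9", ["NGG"], ["GATT"], 10, 30))
        assert summary["n_composite_expanded"] == len(
            orc.brute_composites(seq, "NmCas9", ["NNG", "NGN"], ["GATT"], 10, 100))
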