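"""Cas9 target-site models and composite dual-PAM site enumeration.

A Cas9 ribonucleoprotein recognizes a *protospacer* abutting a short
protospacer-adjacent motif (PAM) and leaves a blunt double-strand break a
fixed number of bases 5' of the PAM (three for the enzymes modeled here).
A dual-Cas9 nuclease (an SpCas9 fused to an orthogonal SaCas9 or NmCas9)
needs a *composite* target: one site per Cas9 domain, in a permitted relative
orientation (labels D1-D4) and with a bounded number of intervening
nucleotides between the site edges.

This module provides the site arithmetic (PAM matching over IUPAC codes,
blunt-cut prediction) and genome-wide enumeration of single and composite
sites under either the stringent "canonical" parameter set (SpCas9 NGG PAM,
10-30 bp spacing) or the relaxed "expanded" set (SpCas9 NNG/NGN PAMs,
10-100 bp spacing).  Coordinates are 0-based, half-open throughout; cut
junctions are integer split points (the number of contig bases retained to
the left of the blunt cut).
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "SiteModelError",
    "Enzyme",
    "SPCAS9",
    "SACAS9",
    "NMCAS9",
    "ENZYMES",
    "GuideSite",
    "CompositeSite",
    "ORIENTATION_LABELS",
    "DEFAULT_ORIENTATION_MAP",
    "CANONICAL_SPACING",
    "EXPANDED_SPACING",
    "FUNCTIONAL_WINDOW_DEFAULT",
    "revcomp",
    "match_pam",
    "predict_cut_junction",
    "classify_orientation",
    "enumerate_guide_sites",
    "enumerate_composite_sites",
    "compare_targeting_range",
]


class SiteModelError(ValueError):
    """Raised for invalid site-model inputs or configuration."""


#: IUPAC nucleotide classes.  A genome 'N' base is deliberately absent from
#: every class (including the class of the pattern symbol N), so ambiguous
#: assembly bases never support a site.
IUPAC_CLASSES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_iupac(pattern: str, what: str) -> None:
    bad = set(pattern.upper()) - set(IUPAC_CLASSES)
    if bad:
        raise SiteModelError(f"{what} {pattern!r} contains non-IUPAC symbols {sorted(bad)}")


@dataclass(frozen=True)
class Enzyme:
    """A Cas9 species: protospacer/PAM geometry and blunt-cut offset.

    ``pam_search_core`` is the informative, suffix-aligned sub-pattern of the
    canonical PAM that genome scans enforce (leading N positions are
    unconstrained beyond being unambiguous sequence).  ``pam_expanded`` lists
    alternative core patterns usable in relaxed scans (SpCas9 only).
    ``cut_offset`` is measured in nucleotides from the PAM-proximal end of
    the protospacer; the break is modeled as blunt.
    """

    name: str
    protospacer_length: int
    pam_length: int
    pam_canonical: str
    pam_search_core: str
    pam_expanded: Tuple[str, ...] = ()
    cut_offset: int = 3

    def __post_init__(self) -> None:
        _check_iupac(self.pam_canonical, "canonical PAM")
        _check_iupac(self.pam_search_core, "PAM search core")
        for pat in self.pam_expanded:
            _check_iupac(pat, "expanded PAM")
        if not 0 < self.cut_offset < self.protospacer_length:
            raise SiteModelError("cut_offset must fall inside the protospacer")
        if len(self.pam_canonical) != self.pam_length:
            raise SiteModelError("canonical PAM length disagrees with pam_length")
        core = self.pam_search_core.upper()
        if len(core) > self.pam_length:
            raise SiteModelError("PAM search core longer than the PAM")
        # suffix alignment: each core symbol class must be a subset of the
        # class of the corresponding canonical suffix symbol
        suffix = self.pam_canonical.upper()[self.pam_length - len(core):]
        for c_core, c_canon in zip(core, suffix):
            if not set(IUPAC_CLASSES[c_core]) <= set(IUPAC_CLASSES[c_canon]):
                raise SiteModelError(
                    f"search core {core!r} is not a suffix-aligned sub-pattern "
                    f"of canonical PAM {self.pam_canonical!r}")

    @property
    def site_length(self) -> int:
        return self.protospacer_length + self.pam_length


SPCAS9 = Enzyme("SpCas9", 20, 3, "NGG", "NGG", ("NNG", "NGN"))
SACAS9 = Enzyme("SaCas9", 21, 6, "NNGRRT", "GRRT")
NMCAS9 = Enzyme("NmCas9", 24, 8, "NNNNGATT", "GATT")

ENZYMES: Dict[str, Enzyme] = {e.name.lower(): e for e in (SPCAS9, SACAS9, NMCAS9)}


def match_pam(window: str, pattern: str) -> bool:
    """True iff every base of ``window`` lies in the IUPAC class of the
    corresponding ``pattern`` symbol.  An 'N' genome base matches nothing."""
    if len(window) != len(pattern):
        raise SiteModelError(
            f"window length {len(window)} != pattern length {len(pattern)}")
    for base, sym in zip(window.upper(), pattern.upper()):
        try:
            cls = IUPAC_CLASSES[sym]
        except KeyError:
            raise SiteModelError(f"invalid IUPAC symbol {sym!r} in pattern") from None
        if base not in cls:
            return False
    return True


@dataclass(frozen=True)
class GuideSite:
    """One protospacer+PAM occurrence on a contig.

    On the + strand the PAM interval immediately follows the protospacer; on
    the - strand it immediately precedes it (both in reference coordinates).
    """

    enzyme: Enzyme
    contig: str
    protospacer_start: int
    protospacer_end: int
    pam_start: int
    pam_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SiteModelError(f"invalid strand {self.strand!r}")
        if self.protospacer_end - self.protospacer_start != self.enzyme.protospacer_length:
            raise SiteModelError("protospacer interval length disagrees with enzyme")
        if self.pam_end - self.pam_start != self.enzyme.pam_length:
            raise SiteModelError("PAM interval length disagrees with enzyme")
        adjacent = (self.pam_start == self.protospacer_end if self.strand == "+"
                    else self.pam_end == self.protospacer_start)
        if not adjacent:
            raise SiteModelError("PAM must abut the protospacer on the correct side")

    @property
    def full_start(self) -> int:
        return min(self.protospacer_start, self.pam_start)

    @property
    def full_end(self) -> int:
        return max(self.protospacer_end, self.pam_end)

    @property
    def cut_junction(self) -> int:
        return predict_cut_junction(self)


def predict_cut_junction(site: GuideSite) -> int:
    """Blunt-cut split point: ``cut_offset`` nt 5' of the PAM on the
    protospacer strand, returned as the count of contig bases left of the cut."""
    if site.strand == "+":
        return site.protospacer_end - site.enzyme.cut_offset
    return site.protospacer_start + site.enzyme.cut_offset


# ---------------------------------------------------------------------------
# single-site enumeration

def _pattern_regex(pattern: str) -> str:
    return "".join(f"[{IUPAC_CLASSES[c]}]" for c in pattern.upper())


def _scan_forward(seq: str, enzyme: Enzyme, patterns: Iterable[str]) -> Set[int]:
    """Full-site start offsets where protospacer+PAM matches on this strand.

    Every base of the site must be A/C/G/T; each pattern is suffix-aligned
    within the PAM, with the leading PAM positions unconstrained.
    """
    starts: Set[int] = set()
    for pat in patterns:
        lead = enzyme.pam_length - len(pat)
        if lead < 0:
            raise SiteModelError(f"pattern {pat!r} longer than the {enzyme.name} PAM")
        rx = re.compile(
            "(?=[ACGT]{%d}%s)" % (enzyme.protospacer_length + lead, _pattern_regex(pat)))
        starts.update(m.start() for m in rx.finditer(seq))
    return starts


def enumerate_guide_sites(
    genome: Mapping[str, str],
    enzyme: Enzyme,
    pam_set: Optional[Iterable[str]] = None,
) -> List[GuideSite]:
    """All positions on both strands where a full site fits inside the contig
    and the PAM core matches some pattern; deduplicated and sorted by
    (contig, full-site start, strand)."""
    patterns = sorted(set(pam_set)) if pam_set is not None else [enzyme.pam_search_core]
    found: Dict[Tuple[str, int, str], GuideSite] = {}
    P, Q = enzyme.protospacer_length, enzyme.pam_length
    for contig in sorted(genome):
        seq = genome[contig].upper()
        L = len(seq)
        for i in _scan_forward(seq, enzyme, patterns):
            site = GuideSite(enzyme, contig, i, i + P, i + P, i + P + Q, "+")
            found[(contig, site.full_start, "+")] = site
        for j in _scan_forward(revcomp(seq), enzyme, patterns):
            s = L - j - (P + Q)  # genome start of the full site
            site = GuideSite(enzyme, contig, s + Q, s + Q + P, s, s + Q, "-")
            found[(contig, site.full_start, "-")] = site
    return [found[k] for k in sorted(found)]


# ---------------------------------------------------------------------------
# composite sites

ORIENTATION_LABELS: Tuple[str, ...] = ("D1", "D2", "D3", "D4")

#: label -> (site order read along the SpCas9 protospacer strand,
#:           relative strand of the partner site).  The mapping is a
#: convention and can be remapped by callers.
DEFAULT_ORIENTATION_MAP: Dict[str, Tuple[str, str]] = {
    "D1": ("sp_first", "same"),
    "D2": ("sp_first", "opposite"),
    "D3": ("partner_first", "same"),
    "D4": ("partner_first", "opposite"),
}

CANONICAL_SPACING: Tuple[int, int] = (10, 30)
EXPANDED_SPACING: Tuple[int, int] = (10, 100)
FUNCTIONAL_WINDOW_DEFAULT = 200


def classify_orientation(
    sp_site: GuideSite,
    partner_site: GuideSite,
    orientation_map: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> Optional[str]:
    """Orientation label of a non-overlapping site pair, or None if the
    configuration is not in the map.

    Order is read along the SpCas9 protospacer strand, so labels are
    invariant under reverse complementation of the contig.
    """
    omap = orientation_map or DEFAULT_ORIENTATION_MAP
    if sp_site.strand == "+":
        sp_first = partner_site.full_start >= sp_site.full_end
    else:
        sp_first = partner_site.full_end <= sp_site.full_start
    relative = "same" if sp_site.strand == partner_site.strand else "opposite"
    key = ("sp_first" if sp_first else "partner_first", relative)
    for label, value in omap.items():
        if tuple(value) == key:
            return label
    return None


@dataclass(frozen=True)
class CompositeSite:
    """A paired SpCas9 + partner-Cas9 target with orientation and spacing.

    ``spacing_x`` counts the nucleotides between the nearest edges of the two
    full sites (protospacer + PAM).  ``within_functional_window`` annotates
    whether the two predicted cuts fall within the empirical distance over
    which fused nucleases act synergistically; it never filters results.
    """

    sp_site: GuideSite
    partner_site: GuideSite
    orientation: str
    spacing_x: int
    cut_separation: int
    within_functional_window: bool

    def __post_init__(self) -> None:
        if self.spacing_x < 0:
            raise SiteModelError("composite sites must not overlap")

    @property
    def key(self) -> Tuple[str, int, str, int, str, str]:
        """Coordinate tuple identifying this composite (used for set comparisons)."""
        return (self.sp_site.contig, self.sp_site.full_start, self.sp_site.strand,
                self.partner_site.full_start, self.partner_site.strand, self.orientation)

    @property
    def span(self) -> Tuple[int, int]:
        return (min(self.sp_site.full_start, self.partner_site.full_start),
                max(self.sp_site.full_end, self.partner_site.full_end))


def _make_composite(sp: GuideSite, partner: GuideSite, spacing: int,
                    orientation: str, functional_window: int) -> CompositeSite:
    cut_sep = abs(partner.cut_junction - sp.cut_junction)
    return CompositeSite(sp, partner, orientation, spacing, cut_sep,
                         cut_sep < functional_window)


def _sp_patterns(mode: str) -> List[str]:
    if mode == "canonical":
        return [SPCAS9.pam_search_core]
    if mode == "expanded":
        return sorted(SPCAS9.pam_expanded)
    raise SiteModelError(f"unknown mode {mode!r} (expected 'canonical' or 'expanded')")


def enumerate_composite_sites(
    genome: Mapping[str, str],
    partner: Enzyme,
    mode: str = "canonical",
    spacing_range: Optional[Tuple[int, int]] = None,
    orientations: Iterable[str] = ("D1", "D2"),
    functional_window: int = FUNCTIONAL_WINDOW_DEFAULT,
    orientation_map: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> List[CompositeSite]:
    """All (SpCas9 site, partner site) pairs with non-overlapping intervals,
    edge spacing inside ``spacing_range`` (inclusive) and an allowed
    orientation; each composite reported once, deterministically ordered."""
    if partner.name == SPCAS9.name:
        raise SiteModelError("partner enzyme must be orthogonal to SpCas9")
    orientations = list(orientations)
    for lab in orientations:
        if lab not in ORIENTATION_LABELS:
            raise SiteModelError(f"unknown orientation label {lab!r}")
    smin, smax = spacing_range if spacing_range is not None else (
        CANONICAL_SPACING if mode == "canonical" else EXPANDED_SPACING)
    if smin < 0 or smax < smin:
        raise SiteModelError(f"invalid spacing range ({smin}, {smax})")

    sp_sites = enumerate_guide_sites(genome, SPCAS9, _sp_patterns(mode))
    partner_sites = enumerate_guide_sites(genome, partner)
    by_contig: Dict[str, List[GuideSite]] = {}
    for site in partner_sites:
        by_contig.setdefault(site.contig, []).append(site)

    out: List[CompositeSite] = []
    wanted = set(orientations)
    for contig, plist in by_contig.items():
        by_start = sorted(plist, key=lambda s: s.full_start)
        starts = [s.full_start for s in by_start]
        by_end = sorted(plist, key=lambda s: s.full_end)
        ends = [s.full_end for s in by_end]
        for sp in sp_sites:
            if sp.contig != contig:
                continue
            # partner entirely to the right of the SpCas9 site
            lo = bisect_left(starts, sp.full_end + smin)
            hi = bisect_right(starts, sp.full_end + smax)
            for p in by_start[lo:hi]:
                label = classify_orientation(sp, p, orientation_map)
                if label in wanted:
                    out.append(_make_composite(sp, p, p.full_start - sp.full_end,
                                               label, functional_window))
            # partner entirely to the left
            lo = bisect_left(ends, sp.full_start - smax)
            hi = bisect_right(ends, sp.full_start - smin)
            for p in by_end[lo:hi]:
                label = classify_orientation(sp, p, orientation_map)
                if label in wanted:
                    out.append(_make_composite(sp, p, sp.full_start - p.full_end,
                                               label, functional_window))
    out.sort(key=lambda c: c.key)
    return out


def compare_targeting_range(
    genome: Mapping[str, str],
    partner: Enzyme,
    functional_window: int = FUNCTIONAL_WINDOW_DEFAULT,
) -> Dict[str, object]:
    """Compare composite-site density under both parameter sets with the
    density of plain SpCas9 NGG sites.  Ratios are None when the genome has
    no SpCas9 site (undefined, not a division error)."""
    if not genome:
        raise SiteModelError("empty genome")
    n_sp = len(enumerate_guide_sites(genome, SPCAS9, {"NGG"}))
    n_can = len(enumerate_composite_sites(genome, partner, "canonical",
                                          functional_window=functional_window))
    n_exp = len(enumerate_composite_sites(genome, partner, "expanded",
                                          functional_window=functional_window))
    return {
        "partner": partner.name,
        "n_sp_only_NGG": n_sp,
        "n_composite_canonical": n_can,
        "n_composite_expanded": n_exp,
        "ratio_canonical": (n_can / n_sp) if n_sp else None,
        "ratio_expanded": (n_exp / n_sp) if n_sp else None,
    }
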