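"""Independent reference implementations used as test oracles.

These deliberately avoid the package's scan/alignment code paths: site
discovery is a per-offset loop over every position and strand, pairing is
exhaustive over all site pairs, and the aligner is a textbook Gotoh
dynamic program.  They are quadratic and slow by design.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence, Set, Tuple

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_ENZYME_GEOMETRY = {
    # name -> (protospacer length, PAM length, cut offset)
    "SpCas9": (20, 3, 3),
    "SaCas9": (21, 6, 3),
    "NmCas9": (24, 8, 3),
}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def iupac_match(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(window, pattern))


def brute_guide_sites(seq: str, enzyme_name: str,
                      patterns: Sequence[str]) -> Set[Tuple[int, str]]:
    """(full-site start, strand) of every site, by scanning every offset."""
    P, Q, _ = _ENZYME_GEOMETRY[enzyme_name]
    W = P + Q
    out: Set[Tuple[int, str]] = set()
    for i in range(len(seq) - W + 1):
        window = seq[i:i + W]
        if any(b not in "ACGT" for b in window):
            continue
        if any(iupac_match(window[W - len(p):], p) for p in patterns):
            out.add((i, "+"))
        rcw = rc(window)
        if any(iupac_match(rcw[W - len(p):], p) for p in patterns):
            out.add((i, "-"))
    return out


_LABELS = {
    ("sp_first", "same"): "D1",
    ("sp_first", "opposite"): "D2",
    ("partner_first", "same"): "D3",
    ("partner_first", "opposite"): "D4",
}


def brute_composites(
    seq: str,
    partner_name: str,
    sp_patterns: Sequence[str],
    partner_patterns: Sequence[str],
    smin: int,
    smax: int,
    orientations: Iterable[str] = ("D1", "D2"),
) -> Set[Tuple[int, str, int, str, str]]:
    """All (sp start, sp strand, partner start, partner strand, label)
    composites, by pairing every SpCas9 site with every partner site."""
    sp_w = sum(_ENZYME_GEOMETRY["SpCas9"][:2])
    pa_w = sum(_ENZYME_GEOMETRY[partner_name][:2])
    sp_sites = sorted(brute_guide_sites(seq, "SpCas9", sp_patterns))
    pa_sites = sorted(brute_guide_sites(seq, partner_name, partner_patterns))
    wanted = set(orientations)
    out: Set[Tuple[int, str, int, str, str]] = set()
    for s_start, s_strand in sp_sites:
        for p_start, p_strand in pa_sites:
            if p_start >= s_start + sp_w:
                spacing, sp_left = p_start - (s_start + sp_w), True
            elif s_start >= p_start + pa_w:
                spacing, sp_left = s_start - (p_start + pa_w), False
            else:
                continue  # overlapping
            if not smin <= spacing <= smax:
                continue
            sp_first = sp_left if s_strand == "+" else not sp_left
            relative = "same" if s_strand == p_strand else "opposite"
            label = _LABELS[("sp_first" if sp_first else "partner_first", relative)]
            if label in wanted:
                out.add((s_start, s_strand, p_start, p_strand, label))
    return out


def composite_keys(composites) -> Set[Tuple[int, str, int, str, str]]:
    """Project package CompositeSite objects onto the oracle's key tuples."""
    return {(c.sp_site.full_start, c.sp_site.strand,
             c.partner_site.full_start, c.partner_site.strand, c.orientation)
            for c in composites}


def gotoh_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                gap_open: float = -5.0, gap_extend: float = -1.0) -> float:
    """Global affine-gap score; a length-L gap costs gap_open + L*gap_extend."""
    neg = float("-inf")
    go = gap_open + gap_extend  # first gap base
    ge = gap_extend
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Iy[0][j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + go, Ix[i - 1][j] + ge, Iy[i - 1][j] + go)
            Iy[i][j] = max(M[i][j - 1] + go, Iy[i][j - 1] + ge, Ix[i][j - 1] + go)
    return max(M[n][m], Ix[n][m], Iy[n][m])
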