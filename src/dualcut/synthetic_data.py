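"""Synthetic amplicon libraries and genomes with known ground truth.

Every pipeline stage is testable without external downloads: this module
fabricates (a) amplicon molecules drawn from a configurable mixture over the
seven repair-outcome classes, optionally UMI-tagged and PCR-duplicated into
FASTQ-ready reads, and (b) genome sequence with composite dual-Cas9 target
sites planted at recorded coordinates and the background scrubbed of
accidental composites.  All outputs are pure functions of (config, seed).

Ground truth is kept honest by construction rather than by re-running the
classifier: indel placements are resampled whenever an equivalent-scoring
alignment could slide the event outside the attribution window, or whenever
the planned lesion's score margin would let the wrong candidate reference
win under the default scoring.  The closure property (error-free molecules
classify back to their true class) therefore holds by design, not by luck.

Substitution errors are applied once per template molecule — the molecule a
UMI tags before amplification — so all PCR copies of a molecule share its
errors; an independent ``read_error_rate`` (default 0) adds per-copy
sequencing noise on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lesion_classifier import AmpliconReference
from .quantification import CLASS_SCHEMA, UNEDITED
from .read_processing import ReadRecord
from .site_model import (
    CANONICAL_SPACING,
    DEFAULT_ORIENTATION_MAP,
    EXPANDED_SPACING,
    FUNCTIONAL_WINDOW_DEFAULT,
    IUPAC_CLASSES,
    SACAS9,
    SPCAS9,
    CompositeSite,
    Enzyme,
    GuideSite,
    enumerate_composite_sites,
    revcomp,
)

__all__ = [
    "SimulationError",
    "ReferenceSpec",
    "SimulationConfig",
    "DEFAULT_MIXTURE",
    "LibraryResult",
    "GenomeSimulation",
    "simulate_reference",
    "simulate_molecule",
    "simulate_molecules",
    "simulate_library",
    "simulate_genome_with_sites",
]

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for infeasible or invalid simulation configurations."""


#: class mixture used throughout: a strongly active dual nuclease whose
#: lesions are dominated by precise deletions, over an unedited background
DEFAULT_MIXTURE: Dict[str, float] = {
    "UNEDITED": 0.20,
    "PRECISE_DELETION": 0.60,
    "IMPRECISE_DELETION": 0.05,
    "SP_INDEL": 0.05,
    "PARTNER_INDEL": 0.05,
    "BOTH_INDEL": 0.025,
    "INVERSION": 0.025,
}


@dataclass(frozen=True)
class ReferenceSpec:
    """Random amplicon layout: length, GC content and the two cut junctions."""

    length: int = 200
    gc: float = 0.5
    cut_a: int = 80
    cut_b: int = 140

    def __post_init__(self) -> None:
        if not 0 < self.cut_a < self.cut_b < self.length:
            raise SimulationError("cuts must satisfy 0 < cut_a < cut_b < length")
        if not 0.0 <= self.gc <= 1.0:
            raise SimulationError("GC fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated amplicon library.

    ``substitution_rate`` is the per-base template error rate (applied once
    per molecule); ``read_error_rate`` is per base of every PCR copy.
    ``copy_range`` is the inclusive uniform range of PCR copies per molecule.
    """

    reference: ReferenceSpec = ReferenceSpec()
    mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    n_molecules: int = 1000
    substitution_rate: float = 0.001
    read_error_rate: float = 0.0
    indel_geom_p: float = 0.35
    indel_max: int = 20
    imprecise_offset_max: int = 10
    window: int = 5
    copy_range: Tuple[int, int] = (1, 30)
    umi_length: int = 10
    quality: int = 37

    def __post_init__(self) -> None:
        unknown = set(self.mixture) - set(CLASS_SCHEMA)
        if unknown:
            raise SimulationError(f"unknown classes in mixture: {sorted(unknown)}")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise SimulationError("mixture probabilities must sum to 1")
        if any(p < 0 for p in self.mixture.values()):
            raise SimulationError("mixture probabilities must be non-negative")
        for name in ("substitution_rate", "read_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.n_molecules < 0 or self.umi_length < 1 or self.quality < 0:
            raise SimulationError("invalid library parameters")
        lo, hi = self.copy_range
        if not 1 <= lo <= hi:
            raise SimulationError("copy_range must satisfy 1 <= lo <= hi")
        if not 0.0 < self.indel_geom_p <= 1.0 or not 1 <= self.indel_max:
            raise SimulationError("invalid indel length distribution")


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    at, cg = (1.0 - gc) / 2.0, gc / 2.0
    return "".join(rng.choice(_BASES, size=n, p=[at, cg, cg, at]))


def _apply_substitutions(seq: str, rate: float,
                         rng: np.random.Generator) -> Tuple[str, int]:
    """Independent per-base substitutions to a uniformly chosen *other* base."""
    if rate <= 0.0 or not seq:
        return seq, 0
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, 0
    out = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out), int(hits.size)


def simulate_reference(spec: ReferenceSpec = ReferenceSpec(),
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> AmpliconReference:
    """Random amplicon with annotated cuts, deterministic under the seed.

    The inter-cut segment is regenerated in the rare case that it equals its
    own reverse complement, so an inversion is always distinguishable from
    the wild type.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = _random_dna(rng, spec.length, spec.gc)
        segment = seq[spec.cut_a:spec.cut_b]
        if revcomp(segment) != segment:
            return AmpliconReference("sim_amplicon", seq, spec.cut_a, spec.cut_b)
    raise SimulationError("could not draw a non-palindromic inter-cut segment")


# ---------------------------------------------------------------------------
# indel placement guards
#
# An indel in a repetitive context has several equivalent optimal alignments;
# the reported event can sit anywhere in that slide range.  Placements are
# accepted only when every equivalent position still obeys the truth-class
# window convention.

def _deletion_slide(seq: str, start: int, end: int, cap: int = 64) -> Tuple[int, int]:
    """Shift range [kmin, kmax] over which deleting seq[start:end) is
    sequence-equivalent to deleting seq[start+k:end+k)."""
    right = 0
    while right < cap and end + right < len(seq) and seq[start + right] == seq[end + right]:
        right += 1
    left = 0
    while left < cap and start - left - 1 >= 0 and seq[start - left - 1] == seq[end - left - 1]:
        left += 1
    return -left, right


def _insertion_slide(seq: str, pos: int, ins: str, cap: int = 64) -> Tuple[int, int]:
    """Equivalent insertion-point range [pmin, pmax] for inserting ``ins``
    before seq[pos]."""
    t = list(ins)
    right = 0
    while right < cap and pos + right < len(seq) and t[0] == seq[pos + right]:
        t = t[1:] + [t[0]]
        right += 1
    t = list(ins)
    left = 0
    while left < cap and pos - left - 1 >= 0 and t[-1] == seq[pos - left - 1]:
        t = [seq[pos - left - 1]] + t[:-1]
        left += 1
    return pos - left, pos + right


def _geom_length(rng: np.random.Generator, p: float, cap: int) -> int:
    return int(min(rng.geometric(p), cap))


def _window_hits(lo: int, hi_excl: int, cut: int, window: int) -> bool:
    """Does the half-open interval [lo, hi_excl) touch positions [cut-w, cut+w)?"""
    return lo < cut + window and hi_excl > cut - window


def _simulate_cut_indel(wt: str, cut: int, other_cut: int, rng: np.random.Generator,
                        window: int, geom_p: float, indel_max: int,
                        cut_separation: int) -> Tuple[str, int, Tuple[str, int, int]]:
    """One indel confined to ±window of ``cut``; returns (new segment pieces
    applied later) as (sequence, net length change, event tuple)."""
    a, b = sorted((cut, other_cut))
    for _ in range(200):
        length = _geom_length(rng, geom_p, indel_max)
        if rng.random() < 0.5:
            # deletion containing the junction
            start = cut - int(rng.integers(0, length + 1))
            end = start + length
            if start < 1 or end > len(wt) - 1:
                continue
            # the wrong candidate must never outscore WT under default scoring
            if 3 * cut_separation <= 4 * length:
                continue
            kmin, kmax = _deletion_slide(wt, start, end)
            placements_ok = all(
                _window_hits(start + k, end + k, cut, window)
                and not _window_hits(start + k, end + k, other_cut, window)
                and not (start + k <= a and end + k >= b)
                for k in range(kmin, kmax + 1))
            if not placements_ok:
                continue
            return wt[:start] + wt[end:], -length, ("deletion", start, length)
        ins = _random_dna(rng, length)
        pmin, pmax = _insertion_slide(wt, cut, ins)
        if pmin < cut - window or pmax > cut + window:
            continue
        if _window_hits(pmin, pmax + 1, other_cut, window):
            continue
        return wt[:cut] + ins + wt[cut:], length, ("insertion", cut, length)
    raise SimulationError(
        "could not place an unambiguous indel at the cut site; the cut "
        "separation is too small for the configured indel lengths")


def simulate_molecule(
    lesion_class: str,
    ref: AmpliconReference,
    rng: np.random.Generator,
    window: int = 5,
    indel_geom_p: float = 0.35,
    indel_max: int = 20,
    imprecise_offset_max: int = 10,
) -> Tuple[str, Dict[str, object]]:
    """One error-free molecule of the requested class, with its truth detail.

    Precise deletions join the two cuts exactly; imprecise deletions offset
    one or both junction ends by ±1..imprecise_offset_max nt (net length
    change never zero, so the lesion is always distinguishable from a precise
    junction plus substitutions); cut-site indels are geometric-length
    (truncated) insertions or deletions confined to the attribution window;
    inversions flip the inter-cut segment exactly.
    """
    wt, a, b = ref.sequence, ref.cut_a, ref.cut_b
    d = b - a
    detail: Dict[str, object] = {"class": lesion_class, "events": ()}

    if lesion_class == UNEDITED:
        return wt, detail
    if lesion_class == "PRECISE_DELETION":
        detail["events"] = (("deletion", a, d),)
        return wt[:a] + wt[b:], detail
    if lesion_class == "INVERSION":
        detail["events"] = (("inversion", a, d),)
        return wt[:a] + revcomp(wt[a:b]) + wt[b:], detail
    if lesion_class == "IMPRECISE_DELETION":
        m = imprecise_offset_max
        for _ in range(500):
            oa = int(rng.integers(-m, m + 1))  # positive widens leftward
            ob = int(rng.integers(-m, m + 1))  # positive widens rightward
            if (oa, ob) == (0, 0) or oa + ob == 0:
                continue
            start, end = a - oa, b + ob
            if not (1 <= start < end <= len(wt) - 1):
                continue
            shrink = max(0, -oa) + max(0, -ob)
            if d <= 4 * shrink + 5:  # wrong-candidate score-margin guard
                continue
            detail["events"] = (("deletion", start, end - start),)
            detail["junction_offsets"] = (oa, ob)
            return wt[:start] + wt[end:], detail
        raise SimulationError("could not draw a valid imprecise junction")
    if lesion_class == "SP_INDEL":
        seq, _, event = _simulate_cut_indel(wt, a, b, rng, window, indel_geom_p,
                                            indel_max, d)
        detail["events"] = (event,)
        return seq, detail
    if lesion_class == "PARTNER_INDEL":
        seq, _, event = _simulate_cut_indel(wt, b, a, rng, window, indel_geom_p,
                                            indel_max, d)
        detail["events"] = (event,)
        return seq, detail
    if lesion_class == "BOTH_INDEL":
        for _ in range(200):
            # place at the downstream cut first so upstream coordinates are stable
            seq_b, delta_b, event_b = _simulate_cut_indel(
                wt, b, a, rng, window, indel_geom_p, indel_max, d)
            seq_ab, _, event_a = _simulate_cut_indel(
                seq_b, a, b + delta_b, rng, window, indel_geom_p, indel_max,
                d + delta_b)
            len_a = event_a[2] if event_a[0] == "deletion" else 0
            len_b = event_b[2] if event_b[0] == "deletion" else 0
            if 3 * d <= 4 * (len_a + len_b) - 5:  # joint deletion margin
                continue
            detail["events"] = (event_a, event_b)
            return seq_ab, detail
        raise SimulationError("could not place indels at both cut sites")
    raise SimulationError(f"unknown lesion class {lesion_class!r}")


def _draw_molecules(config: SimulationConfig,
                    rng: np.random.Generator) -> Tuple[AmpliconReference,
                                                       List[Tuple[str, str]],
                                                       List[Dict[str, object]]]:
    ref = simulate_reference(config.reference, rng=rng)
    names = sorted(config.mixture)
    probs = np.array([config.mixture[n] for n in names])
    probs = probs / probs.sum()
    classes = rng.choice(names, size=config.n_molecules, p=probs)
    molecules: List[Tuple[str, str]] = []
    truth: List[Dict[str, object]] = []
    for i, cls in enumerate(classes):
        seq, detail = simulate_molecule(
            str(cls), ref, rng, window=config.window,
            indel_geom_p=config.indel_geom_p, indel_max=config.indel_max,
            imprecise_offset_max=config.imprecise_offset_max)
        seq, n_err = _apply_substitutions(seq, config.substitution_rate, rng)
        mol_id = f"mol{i:06d}"
        molecules.append((mol_id, seq))
        truth.append({
            "molecule_id": mol_id,
            "true_class": str(cls),
            "n_template_errors": n_err,
            "events": ";".join(f"{k}:{p}:{n}" for k, p, n in detail["events"]),
        })
    return ref, molecules, truth


def simulate_molecules(
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame, AmpliconReference]:
    """Template molecules straight from the mixture (no UMIs or copies)."""
    rng = np.random.default_rng(seed)
    ref, molecules, truth = _draw_molecules(config, rng)
    return molecules, pd.DataFrame(truth), ref


@dataclass(frozen=True)
class LibraryResult:
    """A simulated UMI library: reads, per-molecule truth, and the reference."""

    reads: Tuple[ReadRecord, ...]
    truth: pd.DataFrame
    reference: AmpliconReference


def simulate_library(config: SimulationConfig,
                     seed: Optional[int] = None) -> LibraryResult:
    """UMI-tagged, PCR-duplicated library over the molecule mixture.

    Each molecule gets a uniform-random UMI (collisions allowed and visible
    in the truth table) prepended 5' of the payload, and a uniform copy
    count from ``copy_range``; every copy is emitted as a constant-quality
    read.
    """
    rng = np.random.default_rng(seed)
    ref, molecules, truth = _draw_molecules(config, rng)
    reads: List[ReadRecord] = []
    for row, (mol_id, seq) in zip(truth, molecules):
        umi = _random_dna(rng, config.umi_length)
        copies = int(rng.integers(config.copy_range[0], config.copy_range[1] + 1))
        row["umi"] = umi
        row["copies"] = copies
        row["sequence"] = seq
        for c in range(copies):
            read_seq = umi + seq
            if config.read_error_rate > 0:
                read_seq, _ = _apply_substitutions(read_seq,
                                                   config.read_error_rate, rng)
            reads.append(ReadRecord(f"{mol_id}/{c}", read_seq,
                                    (config.quality,) * len(read_seq)))
    return LibraryResult(tuple(reads), pd.DataFrame(truth), ref)


# ---------------------------------------------------------------------------
# genomes with planted composite sites

@dataclass(frozen=True)
class GenomeSimulation:
    """A synthetic contig plus the composite sites planted in it."""

    genome: Dict[str, str]
    truth: Tuple[CompositeSite, ...]
    contig: str
    partner: Enzyme
    mode: str
    spacing_range: Tuple[int, int]


def _concrete_pam(enzyme: Enzyme, rng: np.random.Generator) -> str:
    """A concrete canonical PAM whose core cannot re-match at shifted offsets
    (SaCas9 GRRT is instantiated as GAAT; SpCas9 NGG gets a non-G lead)."""
    if enzyme is SPCAS9 or enzyme.name == "SpCas9":
        return "ACT"[int(rng.integers(3))] + "GG"
    if enzyme.name == "SaCas9":
        return _random_dna(rng, 2) + "GAAT"
    if enzyme.name == "NmCas9":
        return _random_dna(rng, 4) + "GATT"
    raise SimulationError(f"no concrete PAM rule for {enzyme.name}")


def _site_text(enzyme: Enzyme, rng: np.random.Generator) -> str:
    return _random_dna(rng, enzyme.protospacer_length) + _concrete_pam(enzyme, rng)


def _non_g(rng: np.random.Generator) -> str:
    return "ACT"[int(rng.integers(3))]


def _build_guide_site(enzyme: Enzyme, contig: str, full_start: int,
                      strand: str) -> GuideSite:
    P, Q = enzyme.protospacer_length, enzyme.pam_length
    if strand == "+":
        return GuideSite(enzyme, contig, full_start, full_start + P,
                         full_start + P, full_start + P + Q, "+")
    return GuideSite(enzyme, contig, full_start + Q, full_start + Q + P,
                     full_start, full_start + Q, "-")


def _core_break_options(site: GuideSite, patterns: Sequence[str],
                        protected: frozenset) -> List[Tuple[int, str]]:
    """Mutable (genome position, allowed replacement bases) pairs that weaken
    the site's PAM core, honouring protected planted positions."""
    options: List[Tuple[int, str]] = []
    for pat in patterns:
        k = len(pat)
        for i, sym in enumerate(pat.upper()):
            cls = IUPAC_CLASSES[sym]
            if cls == "ACGT":
                continue
            if site.strand == "+":
                pos = site.pam_end - k + i
                forbidden = set(cls)
            else:
                pos = site.pam_start + k - 1 - i
                forbidden = {revcomp(b) for b in cls}
            if pos in protected:
                continue
            allowed = "".join(b for b in "ACGT" if b not in forbidden)
            if allowed:
                options.append((pos, allowed))
    return options


def simulate_genome_with_sites(
    n_composites: int,
    partner: Enzyme = SACAS9,
    mode: str = "canonical",
    orientations: Sequence[str] = ("D1", "D2"),
    spacing_range: Optional[Tuple[int, int]] = None,
    background_length: int = 20000,
    gc: float = 0.5,
    seed: Optional[int] = None,
    functional_window: int = FUNCTIONAL_WINDOW_DEFAULT,
    contig: str = "chrSim",
) -> GenomeSimulation:
    """A contig with ``n_composites`` composite sites at recorded coordinates
    and a background scrubbed of accidental composites within the queried
    parameter window.

    Scrubbing mutates one PAM-core base of each accidental composite (never
    touching planted cores) and rescans until enumeration returns exactly
    the planted truth.  Exact-truth planting is supported for canonical-mode
    queries; expanded-mode SpCas9 PAMs (NNG/NGN) make single-base-shifted
    variants of any planted site legitimate matches, so expanded planting
    raises an error instead of silently returning an unreachable truth.
    """
    if mode not in ("canonical", "expanded"):
        raise SimulationError(f"unknown mode {mode!r}")
    if mode == "expanded" and n_composites > 0:
        raise SimulationError(
            "exact-truth planting is only supported for canonical-mode queries")
    rng = np.random.default_rng(seed)
    smin, smax = spacing_range if spacing_range is not None else (
        CANONICAL_SPACING if mode == "canonical" else EXPANDED_SPACING)

    pieces: List[str] = []
    pos = 0
    planted: List[Dict[str, object]] = []

    def emit(text: str) -> int:
        nonlocal pos
        pieces.append(text)
        start = pos
        pos += len(text)
        return start

    emit(_random_dna(rng, int(rng.integers(150, 300)), gc))
    for _ in range(n_composites):
        label = orientations[int(rng.integers(len(orientations)))]
        order, relative = DEFAULT_ORIENTATION_MAP[label]
        spacing = int(rng.integers(smin, smax + 1))
        sp_text = _site_text(SPCAS9, rng)
        partner_plus = _site_text(partner, rng)
        partner_frame_strand = "+" if relative == "same" else "-"
        partner_text = (partner_plus if partner_frame_strand == "+"
                        else revcomp(partner_plus))
        spacer = _non_g(rng) + _random_dna(rng, spacing - 1, gc)
        if order == "sp_first":
            frame = sp_text + spacer + partner_text
            sp_off, partner_off = 0, len(sp_text) + spacing
        else:
            frame = partner_text + spacer + sp_text + _non_g(rng)
            sp_off, partner_off = len(partner_text) + spacing, 0
        sp_strand, p_strand = "+", partner_frame_strand
        if rng.random() < 0.5:  # flip the whole composite; label is invariant
            sp_off = len(frame) - sp_off - SPCAS9.site_length
            partner_off = len(frame) - partner_off - partner.site_length
            frame = revcomp(frame)
            sp_strand = "-"
            p_strand = "+" if p_strand == "-" else "-"
        start = emit(frame)
        planted.append({
            "label": label, "spacing": spacing,
            "sp_start": start + sp_off, "sp_strand": sp_strand,
            "partner_start": start + partner_off, "partner_strand": p_strand,
        })
        emit(_random_dna(rng, int(rng.integers(300, 600)), gc))

    if pos > background_length:
        raise SimulationError(
            f"cannot pack {n_composites} composites into {background_length} bp")
    emit(_random_dna(rng, background_length - pos, gc))
    sequence = "".join(pieces)

    truth: List[CompositeSite] = []
    protected: set = set()
    for rec in planted:
        sp = _build_guide_site(SPCAS9, contig, int(rec["sp_start"]), str(rec["sp_strand"]))
        ps = _build_guide_site(partner, contig, int(rec["partner_start"]),
                               str(rec["partner_strand"]))
        cut_sep = abs(ps.cut_junction - sp.cut_junction)
        truth.append(CompositeSite(sp, ps, str(rec["label"]), int(rec["spacing"]),
                                   cut_sep, cut_sep < functional_window))
        protected.update(range(sp.pam_start, sp.pam_end))
        protected.update(range(ps.pam_start, ps.pam_end))
    truth.sort(key=lambda c: c.key)
    truth_keys = {c.key for c in truth}
    protected_frozen = frozenset(protected)

    sp_patterns = ([SPCAS9.pam_search_core] if mode == "canonical"
                   else sorted(SPCAS9.pam_expanded))
    genome = {contig: sequence}
    for _ in range(400):
        found = enumerate_composite_sites(
            genome, partner, mode, spacing_range=(smin, smax),
            orientations=orientations, functional_window=functional_window)
        found_keys = {c.key for c in found}
        if truth_keys - found_keys:
            raise SimulationError("planted composite lost during scrubbing")
        extras = [c for c in found if c.key not in truth_keys]
        if not extras:
            return GenomeSimulation(genome, tuple(truth), contig, partner,
                                    mode, (smin, smax))
        seq_list = list(genome[contig])
        mutated = False
        for extra in extras:
            for site, patterns in ((extra.partner_site, [partner.pam_search_core]),
                                   (extra.sp_site, sp_patterns)):
                options = _core_break_options(site, patterns, protected_frozen)
                if options:
                    p, allowed = options[0]
                    seq_list[p] = allowed[int(rng.integers(len(allowed)))]
                    mutated = True
                    break
        if not mutated:
            raise SimulationError(
                "accidental composite overlaps planted cores and cannot be scrubbed")
        genome = {contig: "".join(seq_list)}
    raise SimulationError("background scrubbing did not converge")
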