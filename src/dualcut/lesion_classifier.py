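"""Seven-class repair-outcome classification of amplicon molecules.

Two synchronous blunt double-strand breaks at a composite target leave one
of seven outcomes: unedited sequence, small indels at the SpCas9 cut, at the
partner-Cas9 cut, or at both, precise deletion of the intervening segment
(an exact cut-to-cut junction), imprecise deletion, or inversion of the
segment.  Each consolidated molecule is globally aligned (affine gaps)
against three candidate references derived from the wild-type amplicon and
its two predicted cut junctions:

* ``WT``        — the unedited amplicon,
* ``PRECISE``   — wild type with the inter-cut segment excised,
* ``INVERSION`` — wild type with the segment reverse-complemented in place,

and the winning candidate plus the indel events of that alignment decide the
class.  Indels are attributed to a cut when they fall within ``window``
(default ±5 bp) of its junction; substitution-only differences are never
lesions.  Molecules below the identity floor are reported UNCLASSIFIED and
tallied separately rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import Align

from .quantification import (
    CLASS_SCHEMA,
    LESION_CLASSES,
    UNCLASSIFIED,
    UNEDITED,
    LesionCountTable,
)
from .read_processing import MoleculeConsensus
from .site_model import revcomp

__all__ = [
    "ScoringScheme",
    "DEFAULT_SCORING",
    "GapEvent",
    "AlignmentResult",
    "AmpliconReference",
    "CandidateReferences",
    "LesionCall",
    "ClassificationResult",
    "align_global",
    "build_candidate_references",
    "classify_molecule",
    "classify_sample",
]

CANDIDATE_ORDER: Tuple[str, ...] = ("WT", "PRECISE", "INVERSION")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a gap of length L costs gap_open + L*gap_extend."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open > 0 or self.gap_extend >= 0:
            raise ValueError("scoring scheme must reward matches and penalize differences")


DEFAULT_SCORING = ScoringScheme()

_ALIGNERS: Dict[ScoringScheme, Align.PairwiseAligner] = {}


def _aligner_for(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = _ALIGNERS.get(scoring)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        # biopython charges open_gap_score for the first gap base
        aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
        aligner.extend_gap_score = scoring.gap_extend
        _ALIGNERS[scoring] = aligner
    return aligner


@dataclass(frozen=True)
class GapEvent:
    """One indel in reference coordinates.

    A deletion removes reference bases [position, position+length); an
    insertion adds ``length`` query bases immediately before reference
    position ``position``.
    """

    kind: str  # "insertion" | "deletion"
    position: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.position + (self.length if self.kind == "deletion" else 0)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one global alignment of a molecule to a candidate."""

    candidate: Optional[str]
    score: float
    normalized_identity: float
    gap_events: Tuple[GapEvent, ...]


def align_global(query: str, reference: str,
                 scoring: ScoringScheme = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal global alignment of ``query`` against ``reference`` under
    affine-gap scoring, with gap events reported in reference coordinates.

    Identity is gap-exclusive: identities over aligned base pairs.  Gaps are
    evidence of lesions and are judged through the score and the reported
    gap events, so a genuine deletion molecule keeps a high identity while a
    random or chimeric sequence (whose aligned bases agree only by chance,
    ~0.7 here) stays far below typical identity floors.  The traceback is
    the aligner's first optimal path and is deterministic for fixed inputs.
    """
    if not query or not reference:
        raise ValueError("alignment requires non-empty sequences")
    if query == reference:
        return AlignmentResult(None, scoring.match * len(query), 1.0, ())
    aln = _aligner_for(scoring).align(reference, query)[0]
    ref_blocks, query_blocks = aln.aligned

    events: List[GapEvent] = []
    first_ref, first_query = ref_blocks[0], query_blocks[0]
    if first_ref[0] > 0:
        events.append(GapEvent("deletion", 0, int(first_ref[0])))
    if first_query[0] > 0:
        events.append(GapEvent("insertion", int(first_ref[0]), int(first_query[0])))
    for k in range(len(ref_blocks) - 1):
        d_ref = int(ref_blocks[k + 1][0] - ref_blocks[k][1])
        d_query = int(query_blocks[k + 1][0] - query_blocks[k][1])
        if d_ref > 0:
            events.append(GapEvent("deletion", int(ref_blocks[k][1]), d_ref))
        if d_query > 0:
            events.append(GapEvent("insertion", int(ref_blocks[k + 1][0]), d_query))
    if ref_blocks[-1][1] < len(reference):
        events.append(GapEvent("deletion", int(ref_blocks[-1][1]),
                               len(reference) - int(ref_blocks[-1][1])))
    if query_blocks[-1][1] < len(query):
        events.append(GapEvent("insertion", len(reference),
                               len(query) - int(query_blocks[-1][1])))

    counts = aln.counts()
    aligned_pairs = counts.identities + counts.mismatches
    identity = counts.identities / aligned_pairs if aligned_pairs else 0.0
    events.sort(key=lambda e: (e.position, e.kind, e.length))
    return AlignmentResult(None, float(aln.score), identity, tuple(events))


# ---------------------------------------------------------------------------
# candidate references

@dataclass(frozen=True)
class AmpliconReference:
    """Wild-type amplicon with the two predicted cut junctions annotated.

    ``cut_a`` is the SpCas9 junction, ``cut_b`` the partner-Cas9 junction;
    each is the number of reference bases retained left of the blunt cut.
    """

    ref_id: str
    sequence: str
    cut_a: int
    cut_b: int

    def __post_init__(self) -> None:
        if not 0 < self.cut_a < self.cut_b < len(self.sequence):
            raise ValueError(
                f"{self.ref_id}: cut junctions must satisfy 0 < cut_a < cut_b < length "
                f"(got {self.cut_a}, {self.cut_b}, length {len(self.sequence)})")


@dataclass(frozen=True)
class CandidateReferences:
    wild_type: str
    precise_deletion: str
    inversion: str


def build_candidate_references(ref: AmpliconReference) -> CandidateReferences:
    """The three alignment candidates implied by two blunt cuts."""
    wt = ref.sequence
    a, b = ref.cut_a, ref.cut_b
    return CandidateReferences(
        wild_type=wt,
        precise_deletion=wt[:a] + wt[b:],
        inversion=wt[:a] + revcomp(wt[a:b]) + wt[b:],
    )


@dataclass(frozen=True)
class LesionCall:
    """Class assignment for one molecule with its supporting alignment."""

    molecule_id: str
    lesion_class: str
    evidence: AlignmentResult
    indel_detail: Tuple[GapEvent, ...] = ()


def _event_in_window(event: GapEvent, cut: int, window: int) -> bool:
    if event.kind == "deletion":
        return event.position < cut + window and event.ref_end > cut - window
    return cut - window <= event.position <= cut + window


def classify_molecule(
    molecule: str,
    ref: AmpliconReference,
    candidates: Optional[CandidateReferences] = None,
    window: int = 5,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_identity: float = 0.9,
    unedited_identity_min: float = 0.9,
    large_deletion_mode: bool = False,
    molecule_id: str = "molecule",
) -> LesionCall:
    """Assign one molecule to a repair class.

    Decision procedure: align to all three candidates and keep the best
    score (ties resolve WT > PRECISE > INVERSION, biasing away from lesion
    calls).  A PRECISE-best alignment without indels is a precise deletion;
    with indels, imprecise.  An INVERSION-best alignment is an inversion.  A
    WT-best alignment is imprecise when one deletion spans both junctions,
    otherwise indels are attributed to the cut windows they touch; with no
    window indels the molecule is unedited provided it clears
    ``unedited_identity_min``.  Below the identity floor (skipped in
    ``large_deletion_mode``) the molecule is UNCLASSIFIED.
    """
    if candidates is None:
        candidates = build_candidate_references(ref)
    sequences = {
        "WT": candidates.wild_type,
        "PRECISE": candidates.precise_deletion,
        "INVERSION": candidates.inversion,
    }
    alignments: Dict[str, AlignmentResult] = {}
    for name in CANDIDATE_ORDER:
        result = align_global(molecule, sequences[name], scoring)
        alignments[name] = AlignmentResult(name, result.score,
                                           result.normalized_identity,
                                           result.gap_events)
    best_name = max(CANDIDATE_ORDER, key=lambda n: alignments[n].score)
    best = alignments[best_name]

    if not large_deletion_mode and best.normalized_identity < min_identity:
        return LesionCall(molecule_id, UNCLASSIFIED, best)

    if best_name == "PRECISE":
        cls = "PRECISE_DELETION" if not best.gap_events else "IMPRECISE_DELETION"
        return LesionCall(molecule_id, cls, best, best.gap_events)
    if best_name == "INVERSION":
        return LesionCall(molecule_id, "INVERSION", best, best.gap_events)

    # WT-best
    a, b = ref.cut_a, ref.cut_b
    spanning = tuple(
        e for e in best.gap_events
        if e.kind == "deletion" and e.position <= a and e.ref_end >= b)
    if spanning:
        return LesionCall(molecule_id, "IMPRECISE_DELETION", best, spanning)
    in_a = tuple(e for e in best.gap_events if _event_in_window(e, a, window))
    in_b = tuple(e for e in best.gap_events if _event_in_window(e, b, window))
    if in_a and in_b:
        return LesionCall(molecule_id, "BOTH_INDEL", best, tuple(sorted(
            set(in_a + in_b), key=lambda e: (e.position, e.kind, e.length))))
    if in_a:
        return LesionCall(molecule_id, "SP_INDEL", best, in_a)
    if in_b:
        return LesionCall(molecule_id, "PARTNER_INDEL", best, in_b)
    if best.normalized_identity >= unedited_identity_min:
        return LesionCall(molecule_id, UNEDITED, best)
    return LesionCall(molecule_id, UNCLASSIFIED, best)


@dataclass(frozen=True)
class ClassificationResult:
    """Sample-level classification: counts, per-molecule calls, indel catalog."""

    table: LesionCountTable
    calls: Tuple[LesionCall, ...]
    catalog: pd.DataFrame


MoleculeInput = Union[MoleculeConsensus, Tuple[str, str]]


def _molecule_id_seq(molecule: MoleculeInput, index: int) -> Tuple[str, str]:
    if isinstance(molecule, MoleculeConsensus):
        return f"umi:{molecule.umi}", molecule.sequence
    mol_id, seq = molecule
    return str(mol_id), seq


def classify_sample(
    molecules: Iterable[MoleculeInput],
    ref: AmpliconReference,
    window: int = 5,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_identity: float = 0.9,
    unedited_identity_min: float = 0.9,
    large_deletion_mode: bool = False,
    sample_id: str = "sample",
) -> ClassificationResult:
    """Classify every molecule of a sample.

    Counts (seven classes + UNCLASSIFIED) sum to the number of input
    molecules.  The catalog retains each attributed indel as one row of
    (frame, kind, position, length, count, frequency) — frequency on the
    whole-sample molecule denominator — for positional background
    subtraction.  Identical sequences are classified once and cached, so
    heavily duplicated samples stay cheap.
    """
    candidates = build_candidate_references(ref)
    cache: Dict[str, LesionCall] = {}
    calls: List[LesionCall] = []
    counts = {cls: 0 for cls in CLASS_SCHEMA}
    unclassified = 0
    for i, molecule in enumerate(molecules):
        mol_id, seq = _molecule_id_seq(molecule, i)
        cached = cache.get(seq)
        if cached is None:
            cached = classify_molecule(
                seq, ref, candidates, window=window, scoring=scoring,
                min_identity=min_identity,
                unedited_identity_min=unedited_identity_min,
                large_deletion_mode=large_deletion_mode, molecule_id=mol_id)
            cache[seq] = cached
        call = LesionCall(mol_id, cached.lesion_class, cached.evidence,
                          cached.indel_detail)
        calls.append(call)
        if call.lesion_class == UNCLASSIFIED:
            unclassified += 1
        else:
            counts[call.lesion_class] += 1

    total = len(calls)
    rows = []
    agg: Dict[Tuple[str, str, int, int], int] = {}
    for call in calls:
        frame = call.evidence.candidate or "WT"
        for event in call.indel_detail:
            key = (frame, event.kind, event.position, event.length)
            agg[key] = agg.get(key, 0) + 1
    for (frame, kind, position, length), n in sorted(agg.items()):
        rows.append({"frame": frame, "kind": kind, "position": position,
                     "length": length, "count": n,
                     "frequency": n / total if total else 0.0})
    catalog = pd.DataFrame(rows, columns=["frame", "kind", "position",
                                          "length", "count", "frequency"])
    table = LesionCountTable(sample_id, counts, unclassified)
    return ClassificationResult(table, tuple(calls), catalog)
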