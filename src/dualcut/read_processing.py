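"""Quality filtering, UMI extraction and molecule consolidation.

Amplicon libraries built by linear amplification-mediated PCR carry a unique
molecular identifier (UMI) on one end of every read, so PCR duplicates of
one template molecule can be collapsed to a single consensus.  The rule used
here is deliberately conservative: a UMI group yields a molecule only when
at least ``min_support`` (default 4) *identical* copies of one payload
sequence are present, which suppresses both sequencing errors in the UMI and
low-copy artifacts.  Groups that never reach the threshold are discarded and
tallied, never guessed at.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "ReadRecord",
    "UmiRead",
    "UmiGroup",
    "MoleculeConsensus",
    "quality_filter",
    "extract_umi",
    "extract_umis",
    "group_by_umi",
    "consolidate_umi_group",
    "consolidate",
    "alignment_score_filter",
]


@dataclass(frozen=True)
class ReadRecord:
    """A merged read: sequence plus per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.read_id}: negative Phred score")


@dataclass(frozen=True)
class UmiRead:
    """A read with its UMI split off; ``payload`` is the locus sequence."""

    umi: str
    payload: ReadRecord


@dataclass(frozen=True)
class UmiGroup:
    """All reads sharing one exact UMI string, with a payload-sequence tally."""

    umi: str
    members: Tuple[UmiRead, ...]
    sequence_tally: Tuple[Tuple[str, int], ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MoleculeConsensus:
    """One consolidated template molecule and its identical-read support."""

    umi: str
    sequence: str
    support: int


def quality_filter(
    reads: Iterable[ReadRecord],
    mean_min: float = 30.0,
    base_min: float = 24.0,
) -> List[ReadRecord]:
    """Keep reads whose mean Phred is strictly above ``mean_min`` and whose
    minimum per-base Phred is strictly above ``base_min``; order preserved.

    Both thresholds are strict ("above"), so a read whose mean is exactly 30
    or that carries a single Q24 base is dropped.
    """
    if mean_min < 0 or base_min < 0:
        raise ValueError("quality thresholds must be non-negative")
    kept = []
    for read in reads:
        if not read.qualities:
            continue
        if min(read.qualities) > base_min and sum(read.qualities) / len(read.qualities) > mean_min:
            kept.append(read)
    return kept


def extract_umi(
    raw: ReadRecord,
    umi_length: int = 10,
    umi_end: str = "5prime",
) -> Optional[UmiRead]:
    """Split the UMI off the configured read end; None (a counted skip) when
    the read is too short to leave a non-empty payload."""
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    if umi_end not in ("5prime", "3prime"):
        raise ValueError(f"invalid umi_end {umi_end!r}")
    if len(raw.sequence) <= umi_length:
        return None
    if umi_end == "5prime":
        umi = raw.sequence[:umi_length]
        payload = ReadRecord(raw.read_id, raw.sequence[umi_length:],
                             raw.qualities[umi_length:])
    else:
        umi = raw.sequence[-umi_length:]
        payload = ReadRecord(raw.read_id, raw.sequence[:-umi_length],
                             raw.qualities[:-umi_length])
    return UmiRead(umi, payload)


def extract_umis(
    reads: Iterable[ReadRecord],
    umi_length: int = 10,
    umi_end: str = "5prime",
) -> Tuple[List[UmiRead], int]:
    """Vector form of :func:`extract_umi`; returns (umi reads, skipped count)."""
    out: List[UmiRead] = []
    skipped = 0
    for read in reads:
        rec = extract_umi(read, umi_length, umi_end)
        if rec is None:
            skipped += 1
        else:
            out.append(rec)
    return out, skipped


def group_by_umi(reads: Iterable[UmiRead]) -> List[UmiGroup]:
    """One group per distinct UMI (exact string match), sorted by UMI."""
    buckets: Dict[str, List[UmiRead]] = {}
    for read in reads:
        buckets.setdefault(read.umi, []).append(read)
    groups = []
    for umi in sorted(buckets):
        members = tuple(buckets[umi])
        tally = Counter(m.payload.sequence for m in members)
        groups.append(UmiGroup(umi, members, tuple(sorted(tally.items()))))
    return groups


def consolidate_umi_group(
    group: UmiGroup,
    min_support: int = 4,
) -> Optional[MoleculeConsensus]:
    """Emit the plurality payload sequence iff its exact-identity count
    reaches ``min_support``; at most one molecule per UMI.

    Ties on count resolve to the lexicographically smallest sequence so the
    result is order-independent.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not group.sequence_tally:
        return None
    seq, count = min(group.sequence_tally, key=lambda kv: (-kv[1], kv[0]))
    if count >= min_support:
        return MoleculeConsensus(group.umi, seq, count)
    return None


def consolidate(
    groups: Iterable[UmiGroup],
    min_support: int = 4,
) -> Tuple[List[MoleculeConsensus], int]:
    """Consolidate every group; returns (molecules, rejected-group count)."""
    molecules: List[MoleculeConsensus] = []
    rejected = 0
    for group in groups:
        mol = consolidate_umi_group(group, min_support)
        if mol is None:
            rejected += 1
        else:
            molecules.append(mol)
    return molecules, rejected


def alignment_score_filter(
    calls: Sequence[Tuple[object, object]],
    min_identity: float = 0.9,
    large_deletion_mode: bool = False,
) -> List[Tuple[object, object]]:
    """Drop molecules whose best-candidate normalized alignment identity is
    below ``min_identity``.

    ``large_deletion_mode`` bypasses the filter entirely: molecules carrying
    deletions much longer than the amplicon flanks align poorly to every
    candidate, so score filtering would discard exactly the reads of
    interest.  ``calls`` pairs each molecule with its best
    :class:`~dualcut.lesion_classifier.AlignmentResult`.
    """
    if large_deletion_mode:
        return list(calls)
    return [c for c in calls if c[1].normalized_identity >= min_identity]
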