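"""File input/output: FASTA/FASTQ via Bio.SeqIO, BED-like site tables, TSVs.

All writers emit deterministic text (sorted keys, fixed float formatting,
``\\n`` line endings) so identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantification import CLASS_SCHEMA, LesionCountTable, RateTable
from .read_processing import MoleculeConsensus, ReadRecord
from .site_model import CompositeSite, GuideSite

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_molecules_fasta",
    "write_guide_sites_bed",
    "write_composite_sites_bed",
    "read_composite_sites_bed",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_rates_tsv",
    "read_specificity_table",
]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Multi-contig FASTA as an ordered {identifier: uppercase sequence} map."""
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    return contigs


def write_fasta(contigs: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: PathLike) -> List[ReadRecord]:
    """Merged reads from a Phred+33 FASTQ file."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(ReadRecord(rec.id, str(rec.seq).upper(),
                                tuple(rec.letter_annotations["phred_quality"])))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: PathLike) -> None:
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(read.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_molecules_fasta(molecules: Iterable[MoleculeConsensus],
                          path: PathLike) -> None:
    """Consolidated molecules as FASTA, identical-read support in the header."""
    records = [SeqRecord(Seq(m.sequence), id=f"umi:{m.umi}",
                         description=f"support={m.support}")
               for m in molecules]
    SeqIO.write(records, str(path), "fasta")


def read_molecules_fasta(path: PathLike) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# site tables

def write_guide_sites_bed(sites: Iterable[GuideSite], path: PathLike) -> None:
    """BED6 over the full site (protospacer+PAM); name carries enzyme and PAM."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.enzyme.name}|{s.enzyme.pam_canonical}"
            fh.write(f"{s.contig}\t{s.full_start}\t{s.full_end}\t{name}\t0\t{s.strand}\n")


_COMPOSITE_COLUMNS = [
    "contig", "start", "end", "name", "score", "sp_strand",
    "sp_start", "sp_end", "partner", "partner_start", "partner_end",
    "partner_strand", "orientation", "spacing_x", "cut_separation",
    "within_functional_window", "mode",
]


def write_composite_sites_bed(composites: Iterable[CompositeSite],
                              path: PathLike, mode: str = "canonical") -> None:
    """BED6 over the composite span plus partner coordinates, orientation,
    spacing, cut separation and search mode as extra columns."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COMPOSITE_COLUMNS) + "\n")
        for c in composites:
            start, end = c.span
            name = f"SpCas9-{c.partner_site.enzyme.name}"
            fields = [
                c.sp_site.contig, start, end, name, 0, c.sp_site.strand,
                c.sp_site.full_start, c.sp_site.full_end,
                c.partner_site.enzyme.name, c.partner_site.full_start,
                c.partner_site.full_end, c.partner_site.strand,
                c.orientation, c.spacing_x, c.cut_separation,
                int(c.within_functional_window), mode,
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_composite_sites_bed(path: PathLike) -> pd.DataFrame:
    """Composite-site BED back as a DataFrame (coordinates round-trip exactly)."""
    return pd.read_csv(path, sep="\t", header=0, names=_COMPOSITE_COLUMNS,
                       comment=None).rename(columns=lambda c: c.lstrip("#"))


# ---------------------------------------------------------------------------
# count / rate tables

def write_counts_tsv(table: LesionCountTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\tcount\n")
        for cls in CLASS_SCHEMA:
            fh.write(f"{table.sample_id}\t{cls}\t{table.count(cls)}\n")
        fh.write(f"{table.sample_id}\tUNCLASSIFIED\t{table.unclassified}\n")


def read_counts_tsv(path: PathLike) -> LesionCountTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "class", "count"):
        if col not in df.columns:
            raise ValueError(f"counts table {path} is missing column {col!r}")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError(f"counts table {path} must describe exactly one sample")
    by_class = dict(zip(df["class"], df["count"].astype(int)))
    unclassified = int(by_class.pop("UNCLASSIFIED", 0))
    return LesionCountTable(str(sample_ids[0]), by_class, unclassified)


def write_rates_tsv(rates: Sequence[RateTable], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\tpercent\tcorrected\n")
        for rt in rates:
            flag = int(rt.corrected)
            for cls in CLASS_SCHEMA:
                fh.write(f"{rt.sample_id}\t{cls}\t{rt.rate(cls):.6f}\t{flag}\n")
            fh.write(f"{rt.sample_id}\tUNCLASSIFIED\t{rt.unclassified_rate:.6f}\t{flag}\n")
            fh.write(f"{rt.sample_id}\tTOTAL_LESIONS\t{rt.total_lesion_rate:.6f}\t{flag}\n")


def read_specificity_table(path: PathLike) -> pd.DataFrame:
    """GUIDE-seq site/count TSV with columns site_id, is_on_target,
    unique_reads (+ optional nuclease)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"site_id", "is_on_target", "unique_reads"} - set(df.columns)
    if missing:
        raise ValueError(f"specificity table {path} is missing {sorted(missing)}")
    return df
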