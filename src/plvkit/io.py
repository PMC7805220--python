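"""Data model and readers/writers for the pipeline's formats.

All coordinates are 0-based half-open internally.  SAM's 1-based closed
convention is converted at the boundary and never leaks inward.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Contig:
    """A nucleotide sequence: the unit of classification."""

    id: str
    seq: str
    source_sample: str = "assembly"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """A peptide sequence: the unit of homology search."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneCall:
    """A predicted coding region on a contig and its peptide."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    peptide: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class AlignmentRecord:
    """One read's placement on a contig, with mate linkage."""

    read_id: str
    mate_index: int
    contig_id: str
    start: int
    end: int
    strand: str
    mate_contig_id: Optional[str] = None
    mate_start: Optional[int] = None
    is_proper_pair: bool = True
    sample: str = "viral"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.mate_index not in (1, 2):
            raise ValueError(f"read {self.read_id!r}: mate_index must be 1 or 2")


@dataclass
class HomologyHit:
    """Query->subject local alignment; the edge type of the pipeline."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    aln_len: int
    pct_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity must be within [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: Union[str, os.PathLike], kind: str = "nucleotide"):
    """Read a FASTA file into Contig or ProteinRecord objects.

    Record ids are the header up to the first whitespace; sequences are
    uppercased; input order is preserved.  ``kind`` selects the returned
    type: ``nucleotide`` -> Contig, ``protein`` -> ProteinRecord.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"unknown FASTA kind {kind!r}")
    cls = Contig if kind == "nucleotide" else ProteinRecord
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not rec.id:
            raise ValueError(f"{path}: record {i}: empty header")
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id!r}): empty sequence")
        out.append(cls(id=rec.id, seq=seq))
    return out


def write_fasta(records, path: Union[str, os.PathLike], width: int = 70) -> None:
    """Write Contig/ProteinRecord objects as FASTA (wrapped at ``width``)."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Gene tables

GENE_TABLE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand", "peptide"]


def write_gene_table(genes, path: Union[str, os.PathLike]) -> None:
    """Write GeneCalls as a TSV with a fixed, deterministic column order."""
    df = pd.DataFrame(
        [
            (g.gene_id, g.contig_id, g.start, g.end, g.strand, g.peptide)
            for g in genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: Union[str, os.PathLike]):
    """Read a gene TSV written by :func:`write_gene_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str}, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    return [
        GeneCall(
            gene_id=str(r.gene_id),
            contig_id=str(r.contig_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            peptide=str(r.peptide),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Alignments

ALIGNMENT_COLUMNS = [
    "read_id",
    "mate_index",
    "contig_id",
    "start",
    "end",
    "strand",
    "mate_contig_id",
    "mate_start",
    "proper_pair",
    "sample",
]


def read_alignments(
    path: Union[str, os.PathLike],
    dialect: str = "tsv",
    sample: Optional[str] = None,
    contig_lengths: Optional[dict] = None,
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from SAM or the pipeline's 10-column TSV.

    Unmapped records are skipped.  SAM coordinates (1-based closed) are
    converted to 0-based half-open.  ``sample`` overrides the fraction
    label (required for SAM, which carries none).  When ``contig_lengths``
    is given, records extending past the contig raise a record-level error
    naming the line.
    """
    if dialect == "tsv":
        yield from _read_alignments_tsv(path, sample, contig_lengths)
    elif dialect == "sam":
        yield from _read_alignments_sam(path, sample, contig_lengths)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


def _check_bounds(rec: AlignmentRecord, contig_lengths, where: str) -> None:
    if contig_lengths is None:
        return
    clen = contig_lengths.get(rec.contig_id)
    if clen is not None and rec.end > clen:
        raise ValueError(
            f"{where}: read {rec.read_id!r} extends to {rec.end} beyond "
            f"contig {rec.contig_id!r} length {clen}"
        )


def _read_alignments_tsv(path, sample, contig_lengths):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: alignment TSV missing columns {sorted(missing)}")
    for i, r in enumerate(df.itertuples()):
        mate_contig = str(r.mate_contig_id) if str(r.mate_contig_id) else None
        mate_start = int(r.mate_start) if str(r.mate_start) not in ("", "-1") else None
        rec = AlignmentRecord(
            read_id=str(r.read_id),
            mate_index=int(r.mate_index),
            contig_id=str(r.contig_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            mate_contig_id=mate_contig,
            mate_start=mate_start,
            is_proper_pair=_parse_bool(r.proper_pair),
            sample=sample if sample is not None else str(r.sample),
        )
        _check_bounds(rec, contig_lengths, f"{path} line {i + 2}")
        yield rec


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("1", "true", "yes")


def _read_alignments_sam(path, sample, contig_lengths):
    import pysam

    if sample is None:
        sample = "viral"
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, aln in enumerate(fh):
            if aln.is_unmapped:
                continue
            end = aln.reference_end
            if end is None:
                continue
            mate_contig = None
            mate_start = None
            if aln.is_paired and not aln.mate_is_unmapped:
                try:
                    mate_contig = aln.next_reference_name
                except ValueError:
                    mate_contig = None
                if aln.next_reference_start is not None and aln.next_reference_start >= 0:
                    mate_start = aln.next_reference_start
            rec = AlignmentRecord(
                read_id=aln.query_name,
                mate_index=2 if aln.is_read2 else 1,
                contig_id=aln.reference_name,
                start=aln.reference_start,
                end=end,
                strand="-" if aln.is_reverse else "+",
                mate_contig_id=mate_contig,
                mate_start=mate_start,
                is_proper_pair=aln.is_proper_pair,
                sample=sample,
            )
            _check_bounds(rec, contig_lengths, f"{path} record {i}")
            yield rec


def alignments_to_frame(records) -> pd.DataFrame:
    """Collect AlignmentRecords into the canonical DataFrame layout."""
    rows = [
        (
            r.read_id,
            r.mate_index,
            r.contig_id,
            r.start,
            r.end,
            r.strand,
            r.mate_contig_id if r.mate_contig_id is not None else "",
            r.mate_start if r.mate_start is not None else -1,
            r.is_proper_pair,
            r.sample,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_alignments(df: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    """Write an alignment DataFrame in the pipeline's TSV dialect."""
    df.to_csv(path, sep="\t", index=False)


def load_alignment_frame(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Fast path: load a truth-alignment TSV directly into a DataFrame."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: alignment TSV missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Homology hit tables (BLAST outfmt-6 compatible)

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


def write_hit_table(hits, path: Union[str, os.PathLike]) -> None:
    """Write HomologyHits as 12-column outfmt-6-style TSV (no header).

    mismatch/gap-open columns are filled with 0 placeholders; coordinates
    stay 0-based half-open (documented deviation from BLAST's 1-based)."""
    rows = [
        (
            h.query_id,
            h.subject_id,
            round(h.pct_identity, 3),
            h.aln_len,
            0,
            0,
            h.q_start,
            h.q_end,
            h.s_start,
            h.s_end,
            f"{h.evalue:.3g}",
            round(h.bitscore, 1),
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )
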