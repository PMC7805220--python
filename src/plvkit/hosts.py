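"""Eukaryotic host linkage via capsid genes in transcriptomes.

A transcript that encodes a long stretch of a known PLV major capsid
protein is evidence that the corresponding virus infects (or integrates
into) that eukaryote.  Each transcript is translated in all six frames
and aligned against the MCP database; the best hit is kept when it
passes both the E-value cutoff (1e-10) and the aligned-length rule
(>= 200 aa), and inherits the subject MCP's virus-group label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import homology as hom
from .homology import ScoringScheme, DEFAULT_SCHEME
from .io import Contig, GeneCall


@dataclass
class HostLink:
    transcript_id: str
    host_taxon: str
    mcp_subject_id: str
    aligned_aa: int
    evalue: float
    frame: str  # +1..+3 / -1..-3
    assigned_group: str


def transcriptome_search(
    transcripts: Sequence[Contig],
    mcp_db: Sequence,  # ProteinRecord or (id, seq); group labels via mcp_groups
    mcp_groups: Optional[Dict[str, str]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_cutoff: float = 1e-10,
    min_aa: int = 200,
) -> List[HostLink]:
    """Six-frame translated search of transcripts against MCP proteins.

    Keeps the best hit per transcript with E <= cutoff and aligned length
    >= min_aa (the length rule dominates: a strong but short hit is
    rejected).  E-values use m = frame length, n = total database
    residues."""
    pairs = [(p.id, p.seq) if hasattr(p, "id") else (p[0], p[1]) for p in mcp_db]
    if not pairs:
        raise ValueError("MCP database must be non-empty")
    n_db = sum(len(s) for _, s in pairs)
    mcp_groups = mcp_groups or {}
    links: List[HostLink] = []
    for tr in transcripts:
        if tr.length < 3:
            continue
        best: Optional[HostLink] = None
        for frame, pep in hom.translate_six_frames(tr.seq):
            if not pep:
                continue
            for sid, sseq in pairs:
                hit = hom.local_align(
                    pep, sseq, scheme, query_id=tr.id, subject_id=sid,
                    m=len(pep), n=n_db,
                )
                if hit is None or hit.evalue > e_cutoff or hit.aln_len < min_aa:
                    continue
                cand = HostLink(
                    transcript_id=tr.id,
                    host_taxon=tr.source_sample,
                    mcp_subject_id=sid,
                    aligned_aa=hit.aln_len,
                    evalue=hit.evalue,
                    frame=frame,
                    assigned_group=mcp_groups.get(sid, "unassigned"),
                )
                if best is None or cand.evalue < best.evalue:
                    best = cand
        if best is not None:
            links.append(best)
    return links


_STOPS = {"TAA", "TAG", "TGA"}


def call_orfs(contig: Contig, min_aa: int = 100) -> List[GeneCall]:
    """All maximal start-to-stop ORFs on both strands, longest first.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next stop codon (stop excluded from the peptide, included in the
    coordinates).  Coordinates are reported on the forward axis."""
    seq = contig.seq
    L = len(seq)
    out: List[Tuple[int, int, str, str]] = []  # start, end, strand, peptide
    for strand in ("+", "-"):
        s = seq if strand == "+" else hom.revcomp(seq)
        for off in range(3):
            i = off
            orf_start = None
            while i + 3 <= L:
                codon = s[i : i + 3]
                if orf_start is None and codon == "ATG":
                    orf_start = i
                elif codon in _STOPS and orf_start is not None:
                    aa_len = (i - orf_start) // 3
                    if aa_len >= min_aa:
                        pep = hom.translate(s[orf_start:i])
                        if strand == "+":
                            out.append((orf_start, i + 3, "+", pep))
                        else:
                            out.append((L - (i + 3), L - orf_start, "-", pep))
                    orf_start = None
                elif codon in _STOPS:
                    orf_start = None
                i += 3
    out.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    return [
        GeneCall(
            gene_id=f"{contig.id}_orf{k + 1:03d}",
            contig_id=contig.id,
            start=s0,
            end=e0,
            strand=st,
            peptide=pep,
        )
        for k, (s0, e0, st, pep) in enumerate(out)
    ]


def hostlink_table(links: Sequence[HostLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                transcript_id=l.transcript_id,
                host_taxon=l.host_taxon,
                mcp_subject_id=l.mcp_subject_id,
                aligned_aa=l.aligned_aa,
                evalue=l.evalue,
                frame=l.frame,
                assigned_group=l.assigned_group,
            )
            for l in links
        ]
    )
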