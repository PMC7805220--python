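"""Gene-sharing network analysis.

Protein clusters (PCs) are connected components of the all-vs-all protein
similarity graph at an E-value cutoff; genomes are then connected by
edges weighted by the significance of their shared PC content (the
-log10 upper-tail hypergeometric probability of sharing at least k PCs
given the two profile sizes and the PC universe).  Virus clusters (VCs)
are connected components of the thresholded genome graph; genomes that
share PCs but never reach the weight threshold are *outliers*, genomes
sharing no PC with anyone are *singletons*.

This is a deliberately deterministic, oracle-testable simplification of
the vConTACT-style computation (components instead of Markov/ClusterONE
clustering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from . import homology as hom
from .homology import ScoringScheme, DEFAULT_SCHEME
from .io import HomologyHit


@dataclass
class ProteinCluster:
    pc_id: str
    members: List[str]
    annotation: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class VirusCluster:
    vc_id: str
    members: List[str]
    category: str  # VC | pair | outlier | singleton


def cluster_proteins(
    proteins: Sequence,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_cutoff: float = 1e-4,
    hits: Optional[Sequence[HomologyHit]] = None,
) -> List[ProteinCluster]:
    """Protein clusters as connected components at E <= cutoff.

    ``proteins`` are ProteinRecords or (id, seq) pairs; ``hits`` may carry
    precomputed all-vs-all hits (self-hits ignored), otherwise they are
    computed here.  PC ids are assigned by descending size, then by the
    lexicographically smallest member, as PC_0000, PC_0001, ...
    """
    pairs = [(p.id, p.seq) if hasattr(p, "id") else (p[0], p[1]) for p in proteins]
    ids = [i for i, _ in pairs]
    if hits is None:
        hits = search_all_vs_all(pairs, scheme, e_cutoff)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for h in hits:
        if h.query_id != h.subject_id and h.evalue <= e_cutoff:
            g.add_edge(h.query_id, h.subject_id)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [
        ProteinCluster(pc_id=f"PC_{i:04d}", members=c) for i, c in enumerate(comps)
    ]


def search_all_vs_all(
    proteins: Sequence[Tuple[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_cutoff: float = 1e-4,
) -> List[HomologyHit]:
    """Symmetric all-vs-all search (each unordered pair scored once).

    E-values use the database-wide search space (n = total residues in
    the set), as an all-vs-all BLAST would: with N sequences there are
    ~N^2/2 chances for a spurious pair, and only the database-size
    correction keeps the expected number of chance edges near the
    nominal cutoff."""
    enc = [hom.encode_peptide(s) for _, s in proteins]
    n_db = sum(len(s) for _, s in proteins)
    hits: List[HomologyHit] = []
    n = len(proteins)
    for i in range(n):
        qid, qseq = proteins[i]
        for j in range(i + 1, n):
            sid, sseq = proteins[j]
            score = hom.local_score(enc[i], enc[j], scheme)
            if score <= 0.0:
                continue
            bits = hom.bitscore(score, scheme)
            e = hom.evalue(bits, len(qseq), n_db)
            if e <= e_cutoff:
                hits.append(
                    HomologyHit(
                        query_id=qid, subject_id=sid, bitscore=bits, evalue=e,
                        aln_len=1, pct_identity=0.0,
                        q_start=0, q_end=1, s_start=0, s_end=1,
                    )
                )
    return hits


def pc_membership(
    clusters: Sequence[ProteinCluster],
    gene_to_genome: Dict[str, str],
) -> Dict[str, Set[str]]:
    """Genome -> set of PC ids (via each genome's clustered genes)."""
    profiles: Dict[str, Set[str]] = {}
    for pc in clusters:
        for gid in pc.members:
            genome = gene_to_genome.get(gid)
            if genome is not None:
                profiles.setdefault(genome, set()).add(pc.pc_id)
    return profiles


def genome_edge_weight(
    profile1: Set[str],
    profile2: Set[str],
    universe: int,
) -> float:
    """-log10 hypergeometric upper-tail P(shared >= k); 0 when k == 0."""
    n1, n2 = len(profile1), len(profile2)
    if universe < max(n1, n2):
        raise ValueError("universe smaller than a profile")
    k = len(profile1 & profile2)
    if k == 0:
        return 0.0
    # P(X >= k), X ~ Hypergeom(universe, n1, n2)
    p = float(hypergeom.sf(k - 1, universe, n1, n2))
    if p <= 0.0:
        return 300.0  # beyond double precision
    import math

    return -math.log10(p)


def genome_edges(
    profiles: Dict[str, Set[str]],
    universe: int,
) -> pd.DataFrame:
    """Weights for all genome pairs sharing at least one PC."""
    rows = []
    names = sorted(profiles)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = len(profiles[a] & profiles[b])
            if shared == 0:
                continue
            w = genome_edge_weight(profiles[a], profiles[b], universe)
            rows.append((a, b, shared, w))
    return pd.DataFrame(rows, columns=["genome1", "genome2", "shared_pcs", "weight"])


def make_virus_clusters(
    edges: pd.DataFrame,
    genomes: Sequence[str],
    weight_threshold: float = 1.0,
) -> List[VirusCluster]:
    """Thresholded connected components with size-class labeling.

    Genomes appearing in ``edges`` (they share PCs with someone) but in no
    supra-threshold component of size >= 2 are outliers; genomes absent
    from ``edges`` are singletons."""
    has_shared: Set[str] = set(edges["genome1"]) | set(edges["genome2"])
    g = nx.Graph()
    g.add_nodes_from(has_shared)
    strong = edges[edges["weight"] >= weight_threshold]
    for r in strong.itertuples():
        g.add_edge(r.genome1, r.genome2)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    out: List[VirusCluster] = []
    clustered: Set[str] = set()
    for i, c in enumerate(comps):
        out.append(
            VirusCluster(
                vc_id=f"VC_{i:03d}",
                members=c,
                category="VC" if len(c) >= 3 else "pair",
            )
        )
        clustered.update(c)
    n_out = 0
    for gname in sorted(genomes):
        if gname in clustered:
            continue
        if gname in has_shared:
            out.append(VirusCluster(f"OUT_{n_out:03d}", [gname], "outlier"))
        else:
            out.append(VirusCluster(f"SING_{n_out:03d}", [gname], "singleton"))
        n_out += 1
    return out


def assign_mcp_group(
    genomes: Sequence[str],
    mcp_gene_by_genome: Dict[str, str],
    clusters: Sequence[ProteinCluster],
) -> Dict[str, str]:
    """Group label = the PC containing the genome's MCP gene; 'unassigned'
    for genomes lacking an identified MCP."""
    gene_to_pc = {gid: pc.pc_id for pc in clusters for gid in pc.members}
    out = {}
    for g in genomes:
        mcp = mcp_gene_by_genome.get(g)
        out[g] = gene_to_pc.get(mcp, "unassigned") if mcp else "unassigned"
    return out


def pc_table(clusters: Sequence[ProteinCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(pc_id=pc.pc_id, size=pc.size, members=",".join(pc.members),
                 annotation=pc.annotation)
            for pc in clusters
        ]
    )


def vc_table(vcs: Sequence[VirusCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(vc_id=vc.vc_id, category=vc.category, size=len(vc.members),
                 members=",".join(vc.members))
            for vc in vcs
        ]
    )


def to_graphml(edges: pd.DataFrame, path, weight_threshold: float = 0.0) -> None:
    g = nx.Graph()
    for r in edges.itertuples():
        if r.weight >= weight_threshold:
            g.add_edge(r.genome1, r.genome2, weight=float(r.weight),
                       shared_pcs=int(r.shared_pcs))
    nx.write_graphml(g, path)
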