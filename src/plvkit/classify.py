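"""Contig classification: virophages, putative and confirmed PLVs.

The decision procedure mirrors the discovery workflow:

* a contig is a *virophage* when any of its genes hits the virophage-type
  MCP database;
* a contig is a *putative PLV* when (1) at least 20% of its predicted
  genes hit the bait database, (2) it is 10-45 kb long, and (3) no
  virophage MCP was detected;
* a putative PLV is *confirmed* when additionally it is 10-41 kb long and
  an MCP gene is identified (here: a hit to an MCP profile model, or a
  direct hit to an already-confirmed MCP gene);
* a putative PLV with no detectable MCP but with both an mCP and an
  ATPase is carried forward as putative (``fallback_core``), never
  confirmed;
* detection is expanded iteratively: genes of confirmed contigs join the
  bait database and the search repeats until a fixed point.

Fraction and length thresholds are inclusive; the 20% criterion counts
distinct genes with at least one hit, not hit multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import homology as hom
from .homology import ProfileModel, ScoringScheme, DEFAULT_SCHEME, encode_peptide
from .io import Contig, GeneCall, HomologyHit


@dataclass
class ClassifierConfig:
    hit_fraction: float = 0.20
    putative_len: Tuple[int, int] = (10000, 45000)
    confirmed_len: Tuple[int, int] = (10000, 41000)
    blast_e: float = 1e-5
    profile_e: float = 1e-5
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.hit_fraction <= 1.0):
            raise ValueError("hit_fraction must be in (0, 1]")
        p_lo, p_hi = self.putative_len
        c_lo, c_hi = self.confirmed_len
        if p_lo > p_hi or c_lo > c_hi:
            raise ValueError("length intervals must be non-empty")
        if not (p_lo <= c_lo and c_hi <= p_hi):
            raise ValueError("confirmed_len must be contained in putative_len")


@dataclass
class ClassificationResult:
    contig_id: str
    label: str  # virophage | putative_PLV | confirmed_PLV | rejected
    hit_fraction_observed: float = 0.0
    n_genes: int = 0
    n_hit_genes: int = 0
    mcp_gene_id: Optional[str] = None
    mcp_method: str = "none"  # blast | profile | none
    fallback_core: bool = False
    iteration_found: int = 0
    reason: str = ""


def flag_virophage(genes: Sequence[GeneCall], gene_hits: Sequence[HomologyHit]) -> bool:
    """True iff at least one of the contig's genes hits the virophage MCP db."""
    gene_ids = {g.gene_id for g in genes}
    return any(h.query_id in gene_ids for h in gene_hits)


def flag_putative_plv(
    contig: Contig,
    genes: Sequence[GeneCall],
    hits: Sequence[HomologyHit],
    virophage_mcp_found: bool,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassificationResult:
    """Apply the three putative-PLV criteria; all inclusive boundaries."""
    gene_ids = {g.gene_id for g in genes}
    n_genes = len(gene_ids)
    hit_genes = {h.query_id for h in hits if h.query_id in gene_ids}
    n_hit = len(hit_genes)
    if n_genes == 0:
        return ClassificationResult(
            contig.id, "rejected", n_genes=0, reason="no genes"
        )
    frac = n_hit / n_genes
    res = ClassificationResult(
        contig.id, "rejected",
        hit_fraction_observed=frac, n_genes=n_genes, n_hit_genes=n_hit,
    )
    lo, hi = cfg.putative_len
    if virophage_mcp_found:
        res.reason = "virophage MCP detected"
        return res
    if frac < cfg.hit_fraction:
        res.reason = f"hit fraction {frac:.3f} < {cfg.hit_fraction}"
        return res
    if not (lo <= contig.length <= hi):
        res.reason = f"length {contig.length} outside [{lo}, {hi}]"
        return res
    res.label = "putative_PLV"
    res.reason = ""
    return res


def confirm_plv(
    result: ClassificationResult,
    contig: Contig,
    mcp_hit: Optional[Tuple[str, str]] = None,  # (gene_id, method)
    cfg: ClassifierConfig = ClassifierConfig(),
    has_mcp_minor: bool = False,
    has_atpase: bool = False,
) -> ClassificationResult:
    """Promote a putative PLV to confirmed, or record the core-gene fallback."""
    if result.label != "putative_PLV":
        raise ValueError("confirm_plv requires a putative_PLV result")
    out = ClassificationResult(**vars(result))
    lo, hi = cfg.confirmed_len
    if mcp_hit is not None:
        out.mcp_gene_id, out.mcp_method = mcp_hit
    if result.hit_fraction_observed < cfg.hit_fraction:
        out.reason = "hit fraction below threshold"
        return out
    if not (lo <= contig.length <= hi):
        out.reason = f"length {contig.length} outside [{lo}, {hi}]"
        return out
    if mcp_hit is None:
        if has_mcp_minor and has_atpase:
            out.fallback_core = True
            out.reason = "no MCP; carried forward on mCP+ATPase"
        else:
            out.reason = "no MCP gene found"
        return out
    out.label = "confirmed_PLV"
    out.reason = ""
    return out


# ---------------------------------------------------------------------------
# iterative bait expansion


class _GeneScanState:
    """Per-gene incremental scan over a growing bait database."""

    __slots__ = ("hit", "scanned")

    def __init__(self) -> None:
        self.hit = False
        self.scanned = 0


@dataclass
class BaitExpansion:
    results: Dict[str, ClassificationResult]
    bait_db: List[Tuple[str, str]]
    iterations: int
    converged: bool


def bait_expand(
    contigs: Sequence[Contig],
    genes: Sequence[GeneCall],
    seed_db: Sequence,
    virophage_mcp_db: Sequence,
    profile_lib: Sequence[ProfileModel],
    cfg: ClassifierConfig = ClassifierConfig(),
    scheme: ScoringScheme = DEFAULT_SCHEME,
    mcp_minor_db: Sequence = (),
    atpase_db: Sequence = (),
) -> BaitExpansion:
    """Iterative search-flag-confirm-expand loop to a fixed point.

    Genes of detected virophages are pooled into the bait database before
    the first PLV pass; genes of each iteration's confirmed PLVs are
    appended afterwards (between full passes, so the result is independent
    of contig processing order).  MCP genes of confirmed contigs also
    become direct search baits (``mcp_method='blast'``) alongside the
    profile library (``mcp_method='profile'``).
    """
    if not seed_db:
        raise ValueError("seed bait database must be non-empty")
    contigs = sorted(contigs, key=lambda c: c.id)
    genes_by_contig: Dict[str, List[GeneCall]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    enc: Dict[str, np.ndarray] = {}
    for g in genes:
        if g.peptide:
            enc[g.gene_id] = encode_peptide(g.peptide)

    def _pairs(db):
        return [(r.id, r.seq) if hasattr(r, "id") else (r[0], r[1]) for r in db]

    bait: List[Tuple[str, str]] = list(_pairs(seed_db))
    bait_enc: List[np.ndarray] = [encode_peptide(s) for _, s in bait]
    viro_mcp = _pairs(virophage_mcp_db)
    viro_mcp_enc = [encode_peptide(s) for _, s in viro_mcp]
    minor_enc = [encode_peptide(s) for _, s in _pairs(mcp_minor_db)]
    atp_enc = [encode_peptide(s) for _, s in _pairs(atpase_db)]
    mcp_baits: List[Tuple[str, str]] = []  # confirmed MCP genes
    mcp_bait_enc: List[np.ndarray] = []

    scan_state: Dict[str, _GeneScanState] = {g.gene_id: _GeneScanState() for g in genes}
    results: Dict[str, ClassificationResult] = {}

    def _gene_hits_db(gene: GeneCall, db_enc, e_cutoff) -> bool:
        if not gene.peptide:
            return False
        q = enc[gene.gene_id]
        return hom.scan_first_hit(q, len(gene.peptide), db_enc, scheme, e_cutoff) >= 0

    # pre-pass: virophage detection (static database)
    viro_ids = set()
    for c in contigs:
        cg = genes_by_contig.get(c.id, [])
        if any(_gene_hits_db(g, viro_mcp_enc, cfg.blast_e) for g in cg):
            viro_ids.add(c.id)
            results[c.id] = ClassificationResult(
                c.id, "virophage", n_genes=len(cg), iteration_found=1,
                mcp_method="blast",
            )
    for cid in sorted(viro_ids):
        for g in genes_by_contig.get(cid, []):
            if g.peptide:
                bait.append((g.gene_id, g.peptide))
                bait_enc.append(enc[g.gene_id])

    def _hit_fraction(cg: List[GeneCall]) -> Tuple[int, int]:
        n_hit = 0
        for g in cg:
            st = scan_state[g.gene_id]
            if not st.hit and st.scanned < len(bait_enc) and g.peptide:
                k = hom.scan_first_hit(
                    enc[g.gene_id], len(g.peptide), bait_enc, scheme,
                    cfg.blast_e, start=st.scanned,
                )
                st.scanned = len(bait_enc)
                st.hit = k >= 0
            if st.hit:
                n_hit += 1
        return n_hit, len(cg)

    def _find_mcp(cg: List[GeneCall]) -> Optional[Tuple[str, str]]:
        best: Optional[Tuple[float, str, str]] = None
        for g in cg:
            if not g.peptide:
                continue
            if mcp_bait_enc and hom.scan_first_hit(
                enc[g.gene_id], len(g.peptide), mcp_bait_enc, scheme, cfg.blast_e
            ) >= 0:
                cand = (0.0, g.gene_id, "blast")
                if best is None or cand < best:
                    best = cand
                continue
            for prof in profile_lib:
                hits = hom.profile_search(prof, [(g.gene_id, g.peptide)], cfg.profile_e)
                if hits:
                    cand = (hits[0].evalue, g.gene_id, "profile")
                    if best is None or cand < best:
                        best = cand
                    break
        if best is None:
            return None
        return best[1], best[2]

    converged = False
    iteration = 0
    confirmed_ids = set()
    while iteration < cfg.max_iterations:
        iteration += 1
        newly_confirmed: List[str] = []
        for c in contigs:
            if c.id in viro_ids or c.id in confirmed_ids:
                continue
            cg = genes_by_contig.get(c.id, [])
            n_hit, n_genes = _hit_fraction(cg)
            res = _flag_with_counts(c, n_hit, n_genes, False, cfg)
            if res.label == "putative_PLV":
                mcp = _find_mcp(cg)
                has_minor = any(_gene_hits_db(g, minor_enc, cfg.blast_e) for g in cg) if minor_enc else False
                has_atp = any(_gene_hits_db(g, atp_enc, cfg.blast_e) for g in cg) if atp_enc else False
                res = confirm_plv(res, c, mcp, cfg, has_minor, has_atp)
            if res.label == "confirmed_PLV":
                res.iteration_found = iteration
                confirmed_ids.add(c.id)
                newly_confirmed.append(c.id)
            results[c.id] = res
        for cid in newly_confirmed:
            for g in genes_by_contig.get(cid, []):
                if not g.peptide:
                    continue
                bait.append((g.gene_id, g.peptide))
                bait_enc.append(enc[g.gene_id])
                if results[cid].mcp_gene_id == g.gene_id:
                    mcp_baits.append((g.gene_id, g.peptide))
                    mcp_bait_enc.append(enc[g.gene_id])
        if not newly_confirmed:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"bait expansion did not converge in {cfg.max_iterations} iterations;"
            " returning partial results"
        )
    return BaitExpansion(
        results=results, bait_db=bait, iterations=iteration, converged=converged
    )


def _flag_with_counts(
    contig: Contig, n_hit: int, n_genes: int, viro: bool, cfg: ClassifierConfig
) -> ClassificationResult:
    if n_genes == 0:
        return ClassificationResult(contig.id, "rejected", reason="no genes")
    frac = n_hit / n_genes
    res = ClassificationResult(
        contig.id, "rejected",
        hit_fraction_observed=frac, n_genes=n_genes, n_hit_genes=n_hit,
    )
    lo, hi = cfg.putative_len
    if viro:
        res.reason = "virophage MCP detected"
    elif frac < cfg.hit_fraction:
        res.reason = f"hit fraction {frac:.3f} < {cfg.hit_fraction}"
    elif not (lo <= contig.length <= hi):
        res.reason = f"length {contig.length} outside [{lo}, {hi}]"
    else:
        res.label = "putative_PLV"
        res.reason = ""
    return res


# ---------------------------------------------------------------------------
# dereplication


DEFAULT_DEREP_ROUNDS = [
    (0.9, 0.2, True),   # local identity, >=20% coverage of the longer
    (0.7, None, True),  # global identity over the longer sequence
]


def _round_identity(member: Contig, rep: Contig, circular_aware: bool):
    """(identity_local, identity_global, coverage) of member vs representative."""
    import edlib

    short, long_ = (member, rep) if member.length <= rep.length else (rep, member)
    target = long_.seq + long_.seq if circular_aware else long_.seq
    r = edlib.align(short.seq, target, mode="HW", task="distance")
    d = max(0, r["editDistance"])
    ident_local = (short.length - d) / short.length
    ident_global = (short.length - d) / long_.length
    coverage = short.length / long_.length
    return ident_local, ident_global, coverage


def dereplicate(
    genomes: Sequence[Contig],
    rounds: Optional[List[Tuple[float, Optional[float], bool]]] = None,
):
    """Greedy length-sorted clustering, optionally rotation-aware.

    ``rounds`` is a list of (identity, coverage_of_longer, circular_aware):
    coverage None means global identity (matched bases over the longer
    sequence); otherwise local identity with the given minimum coverage of
    the longer sequence.  Each round clusters the previous round's
    representatives; cluster membership is transitive across rounds.

    Returns (clusters, representatives): clusters maps representative id to
    member ids (including itself).
    """
    if not genomes:
        raise ValueError("no genomes to dereplicate")
    if rounds is None:
        rounds = DEFAULT_DEREP_ROUNDS
    assign: Dict[str, str] = {c.id: c.id for c in genomes}
    current = list(genomes)
    for identity, coverage, circular_aware in rounds:
        current.sort(key=lambda c: (-c.length, c.id))
        reps: List[Contig] = []
        for c in current:
            placed = False
            for rep in reps:
                il, ig, cov = _round_identity(c, rep, circular_aware)
                if coverage is None:
                    ok = ig >= identity
                else:
                    ok = il >= identity and cov >= coverage
                if ok:
                    assign[c.id] = rep.id
                    placed = True
                    break
            if not placed:
                reps.append(c)
        current = reps
    # resolve transitive assignments
    def root(x: str) -> str:
        while assign[x] != x:
            x = assign[x]
        return x

    clusters: Dict[str, List[str]] = {}
    for c in genomes:
        clusters.setdefault(root(c.id), []).append(c.id)
    representatives = sorted(clusters)
    return clusters, representatives
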