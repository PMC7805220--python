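"""Stage drivers composing the library modules into the full workflow.

Each ``run_*`` function consumes a CommunityBundle (or the equivalent
files loaded through :mod:`plvkit.io`) and returns in-memory results plus
tidy tables, so the CLI, the analysis scripts and the test-suite all
execute the same code paths.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import classify, completeness, enrichment, homology, hosts, network
from .classify import BaitExpansion, ClassifierConfig
from .homology import ProfileModel, ScoringScheme, DEFAULT_SCHEME, build_profile
from .io import Contig, GeneCall, ProteinRecord
from .synth import CommunityBundle, make_transcriptome


def build_mcp_profiles(mcp_refs: Dict[str, Sequence], alpha: float = 1.0) -> List[ProfileModel]:
    """One profile model per known MCP family from its reference alignment."""
    profiles = []
    for group in sorted(mcp_refs):
        refs = mcp_refs[group]
        seqs = [r.seq if hasattr(r, "seq") else r[1] for r in refs]
        profiles.append(build_profile(seqs, alpha=alpha, name=f"MCP_{group}"))
    return profiles


def run_detection(
    bundle: CommunityBundle,
    cfg: ClassifierConfig = ClassifierConfig(),
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> BaitExpansion:
    """Classify every contig by iterative bait expansion."""
    profiles = build_mcp_profiles(bundle.baits.mcp_refs)
    return classify.bait_expand(
        bundle.contigs,
        bundle.genes,
        seed_db=bundle.baits.virophage_genes,
        virophage_mcp_db=bundle.baits.virophage_mcps,
        profile_lib=profiles,
        cfg=cfg,
        scheme=scheme,
        mcp_minor_db=bundle.baits.mcp_minor_refs,
        atpase_db=bundle.baits.atpase_refs,
    )


def classification_table(expansion: BaitExpansion) -> pd.DataFrame:
    rows = []
    for cid in sorted(expansion.results):
        r = expansion.results[cid]
        rows.append(
            dict(
                contig_id=r.contig_id,
                label=r.label,
                hit_fraction=round(r.hit_fraction_observed, 4),
                n_genes=r.n_genes,
                n_hit_genes=r.n_hit_genes,
                mcp_gene_id=r.mcp_gene_id or "",
                mcp_method=r.mcp_method,
                fallback_core=r.fallback_core,
                iteration_found=r.iteration_found,
                reason=r.reason,
            )
        )
    return pd.DataFrame(rows)


def run_completeness(
    bundle: CommunityBundle,
    fraction: str = "viral",
    contig_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Completeness calls from the virus-fraction read mapping."""
    aln = bundle.alignments[fraction]
    calls = []
    for c in bundle.contigs:
        if contig_ids is not None and c.id not in contig_ids:
            continue
        calls.append(completeness.call_completeness(c, aln))
    return completeness.completeness_table(calls)


def run_enrichment(
    bundle: CommunityBundle,
    contig_ids: Optional[Sequence[str]] = None,
    share_threshold: float = 0.95,
):
    """Per-contig enrichment profiles and the population summary."""
    va = bundle.alignments["viral"]
    ma = bundle.alignments["microbial"]
    gv = bundle.metagenome_gb["viral"]
    gm = bundle.metagenome_gb["microbial"]
    profiles = []
    for c in bundle.contigs:
        if contig_ids is not None and c.id not in contig_ids:
            continue
        profiles.append(
            enrichment.fold_enrichment(c.id, c.length, va, ma, gv, gm)
        )
    summary = enrichment.summarize_population(profiles, share_threshold)
    return profiles, summary


def run_network(
    bundle: CommunityBundle,
    expansion: BaitExpansion,
    e_cutoff: float = 1e-4,
    weight_threshold: float = 1.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
):
    """Protein clusters, genome edges, virus clusters, MCP group labels
    over all contigs classified as viruses."""
    virus_ids = {
        cid
        for cid, r in expansion.results.items()
        if r.label in ("confirmed_PLV", "virophage")
    }
    proteins = [
        (g.gene_id, g.peptide)
        for g in bundle.genes
        if g.contig_id in virus_ids and g.peptide
    ]
    gene_to_genome = {g.gene_id: g.contig_id for g in bundle.genes}
    pcs = network.cluster_proteins(proteins, scheme, e_cutoff)
    profiles = network.pc_membership(pcs, gene_to_genome)
    edges = network.genome_edges(profiles, universe=len(pcs))
    vcs = network.make_virus_clusters(edges, sorted(virus_ids), weight_threshold)
    mcp_by_genome = {
        cid: r.mcp_gene_id
        for cid, r in expansion.results.items()
        if r.mcp_gene_id
    }
    groups = network.assign_mcp_group(sorted(virus_ids), mcp_by_genome, pcs)
    return pcs, edges, vcs, groups


def run_hosts(
    bundle: CommunityBundle,
    expansion: BaitExpansion,
    seed: int = 0,
    n_decoys: int = 10,
    e_cutoff: float = 1e-10,
    min_aa: int = 200,
):
    """Mock-transcriptome screen with the confirmed MCP genes as the db."""
    peptides = {g.gene_id: g.peptide for g in bundle.genes}
    truth_groups = dict(zip(bundle.truth.genes.gene_id, bundle.truth.genes.group))
    mcp_db = []
    mcp_groups = {}
    for cid, r in sorted(expansion.results.items()):
        if r.label == "confirmed_PLV" and r.mcp_gene_id and r.mcp_gene_id in peptides:
            mcp_db.append(ProteinRecord(id=r.mcp_gene_id, seq=peptides[r.mcp_gene_id]))
            mcp_groups[r.mcp_gene_id] = truth_groups.get(r.mcp_gene_id, "unassigned")
    rng = np.random.default_rng(seed)
    planted = [
        (rec.id, mcp_groups[rec.id], rec.seq) for rec in mcp_db[: min(12, len(mcp_db))]
    ]
    transcripts, truth = make_transcriptome(planted, rng, n_decoys=n_decoys)
    links = hosts.transcriptome_search(
        transcripts, mcp_db, mcp_groups, e_cutoff=e_cutoff, min_aa=min_aa
    )
    return transcripts, truth, links


# ---------------------------------------------------------------------------
# evaluation against planted truth


def detection_metrics(expansion: BaitExpansion, truth_contigs: pd.DataFrame) -> dict:
    """Precision/recall of confirmed_PLV and virophage calls vs truth."""
    truth = dict(zip(truth_contigs.contig_id, truth_contigs.truth_class))
    out = {}
    for label, truth_class in (("confirmed_PLV", "PLV"), ("virophage", "virophage")):
        called = {cid for cid, r in expansion.results.items() if r.label == label}
        actual = {cid for cid, cls in truth.items() if cls == truth_class}
        tp = len(called & actual)
        out[f"{label}_precision"] = tp / len(called) if called else 1.0
        out[f"{label}_recall"] = tp / len(actual) if actual else 1.0
        out[f"{label}_called"] = len(called)
        out[f"{label}_truth"] = len(actual)
    return out


def completeness_metrics(table: pd.DataFrame, truth_contigs: pd.DataFrame) -> dict:
    merged = table.merge(
        truth_contigs[["contig_id", "topology", "truth_class"]], on="contig_id"
    )
    genomes = merged[merged.truth_class.isin(["PLV", "virophage"])]
    circ = genomes[genomes.topology == "circular"]
    lin = genomes[genomes.topology == "linear"]
    tirs = genomes[genomes.topology == "linear_TIR"]
    return {
        "circular_recall": float((circ.status == "circular").mean()) if len(circ) else 1.0,
        "linear_false_circular_rate": float((lin.status == "circular").mean()) if len(lin) else 0.0,
        "tir_recall": float((tirs.status == "terminal_repeat").mean()) if len(tirs) else 1.0,
        "n_circular_truth": int(len(circ)),
        "n_linear_truth": int(len(lin)),
        "n_tir_truth": int(len(tirs)),
    }
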