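"""Synthetic community generator with planted ground truth.

Emulates the study system end to end: groups of Polinton-like virus (PLV)
genomes (10-41 kb) each carrying a group-specific major capsid protein
(MCP) family plus minor capsid protein (mCP), packaging ATPase and
accessory genes; virophage genomes defined by the virophage-type MCP;
background (cellular) contigs; elements integrated into large host contigs
with terminal inverted repeats (TIRs) and 5-7 bp target-site duplications
(TSDs); and paired 2x150 bp read placements from a virus-enriched and a
microbial size fraction with per-genome fold enrichment.

Reads are emitted as truth alignments (the pipeline's TSV dialect), so no
external mapper is required; FASTQ export is available for end-to-end runs
with a real mapper.  One seed determines every byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .homology import AA20, revcomp
from .io import AlignmentRecord, Contig, GeneCall, ProteinRecord

NT = "ACGT"

# deterministic codon choice tables (stop codons excluded)
_CODONS_BY_AA: Dict[str, List[str]] = {}


def _codons_by_aa() -> Dict[str, List[str]]:
    global _CODONS_BY_AA
    if not _CODONS_BY_AA:
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[1]
        d: Dict[str, List[str]] = {}
        for codon, aa in sorted(tbl.forward_table.items()):
            d.setdefault(aa, []).append(codon)
        _CODONS_BY_AA = d
    return _CODONS_BY_AA


@dataclass
class CommunitySpec:
    """All conditions of a synthetic community.

    Core geometry follows the study system: genomes 10-41 kb, 2x150 bp
    paired reads, insert sizes bounded at 800 bp, TSDs of 5-7 bp.
    ``mcp_divergence`` is the expected *pairwise* fraction of substituted
    residues within a group's capsid family (each genome is mutated from
    the family ancestor at half that rate).
    """

    n_groups: int = 8
    genomes_per_group: int = 5
    genome_length_range: Tuple[int, int] = (10000, 41000)
    mcp_divergence: float = 0.3
    n_virophages: int = 5
    n_background: int = 20
    n_integrations: int = 3
    tir_length: int = 250
    tsd_length: int = 6
    fraction_abundances: Optional[Dict[str, Tuple[float, float]]] = None
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 50
    max_insert: int = 800
    error_rate: float = 0.002
    seed: int = 42

    # community composition conditions
    viral_copies: float = 100.0
    fold_range: Tuple[float, float] = (1.0, 2816.0)
    depth_per_copy: float = 0.25
    accessory_range: Tuple[int, int] = (5, 20)
    shared_accessory_prob: float = 0.5
    n_shared_accessory_families: int = 30
    n_private_accessory_families: int = 10
    cross_group_core: bool = True
    n_reference_mcps: int = 4
    n_reference_virophages: int = 5
    mcp_len: int = 300
    mcp_minor_len: int = 170
    atpase_len: int = 160
    accessory_len_range: Tuple[int, int] = (100, 180)
    background_length_range: Tuple[int, int] = (5000, 44000)
    integration_host_length_range: Tuple[int, int] = (48000, 70000)
    background_viral_copies: float = 2.0
    background_microbial_copies: float = 100.0
    topology_weights: Tuple[float, float, float] = (0.4, 0.3, 0.3)

    def __post_init__(self) -> None:
        for name in ("n_groups", "genomes_per_group", "n_virophages",
                     "n_background", "n_integrations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_integrations and not (5 <= self.tsd_length <= 7):
            raise ValueError("tsd_length must be within [5, 7]")
        if self.max_insert < self.insert_mean:
            raise ValueError("max_insert must be >= insert_mean")
        lo, hi = self.genome_length_range
        if not (1000 <= lo <= hi <= 10**6):
            raise ValueError("genome_length_range must lie within [1000, 1e6]")
        if not (0.0 <= self.mcp_divergence < 0.95):
            raise ValueError(
                "mcp_divergence >= 0.95 rejected: family structure unrecoverable"
            )


@dataclass
class TruthTable:
    """Planted truth: one row per contig, per gene family, per integration."""

    contigs: pd.DataFrame
    genes: pd.DataFrame
    integrations: pd.DataFrame

    def save(self, outdir) -> None:
        self.contigs.to_csv(os.path.join(outdir, "truth_contigs.tsv"), sep="\t", index=False)
        self.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
        self.integrations.to_csv(
            os.path.join(outdir, "truth_integrations.tsv"), sep="\t", index=False
        )

    @classmethod
    def load(cls, outdir) -> "TruthTable":
        read = lambda n: pd.read_csv(os.path.join(outdir, n), sep="\t", keep_default_na=False)
        return cls(
            contigs=read("truth_contigs.tsv"),
            genes=read("truth_genes.tsv"),
            integrations=read("truth_integrations.tsv"),
        )


@dataclass
class Baits:
    """The 'known sequence' side of the study: reference databases.

    Emulates public resources (virophage gene databases, known capsid
    families from the literature) that seed the detection procedure."""

    virophage_genes: List[ProteinRecord]
    virophage_mcps: List[ProteinRecord]
    mcp_refs: Dict[str, List[ProteinRecord]]  # group -> aligned reference MCPs
    mcp_minor_refs: List[ProteinRecord]
    atpase_refs: List[ProteinRecord]


@dataclass
class CommunityBundle:
    spec: CommunitySpec
    contigs: List[Contig]
    genes: List[GeneCall]
    truth: TruthTable
    alignments: Dict[str, pd.DataFrame]
    fragment_log: Dict[str, Dict[str, dict]]
    baits: Baits
    metagenome_gb: Dict[str, float]

    def genes_for(self, contig_id: str) -> List[GeneCall]:
        return [g for g in self.genes if g.contig_id == contig_id]


# ---------------------------------------------------------------------------
# sequence primitives

_AA_LIST = list(AA20)
_NT_LIST = list(NT)


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_LIST, size=length))


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT_LIST, size=length))


def mutate_peptide(pep: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate`` (to a different one)."""
    if rate <= 0:
        return pep
    chars = list(pep)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        choices = [a for a in _AA_LIST if a != chars[i]]
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def reverse_translate(pep: str, rng: np.random.Generator) -> str:
    table = _codons_by_aa()
    return "".join(
        table[aa][rng.integers(0, len(table[aa]))] for aa in pep
    )


# ---------------------------------------------------------------------------
# gene pools


@dataclass
class GenePools:
    """Family ancestors the community is mutated from."""

    virophage_mcp: str
    group_mcp: Dict[str, str]
    mcp_minor: Dict[str, str]  # keyed by group, or {"*": seq} when shared
    atpase: Dict[str, str]
    shared_accessory: List[Tuple[str, str]]  # (family_id, peptide)
    private_accessory: Dict[str, List[Tuple[str, str]]]
    virophage_accessory: List[Tuple[str, str]]

    def core_for(self, group: str) -> Tuple[str, str]:
        key = "*" if "*" in self.mcp_minor else group
        return self.mcp_minor[key], self.atpase[key]


def make_gene_pools(spec: CommunitySpec, rng: np.random.Generator) -> GenePools:
    groups = [f"G{g + 1:02d}" for g in range(spec.n_groups)]
    lo, hi = spec.accessory_len_range
    shared = [
        (f"ACC{j:03d}", random_peptide(rng, int(rng.integers(lo, hi + 1))))
        for j in range(spec.n_shared_accessory_families)
    ]
    if spec.cross_group_core:
        mcp_minor = {"*": random_peptide(rng, spec.mcp_minor_len)}
        atpase = {"*": random_peptide(rng, spec.atpase_len)}
    else:
        mcp_minor = {g: random_peptide(rng, spec.mcp_minor_len) for g in groups + ["VIRO"]}
        atpase = {g: random_peptide(rng, spec.atpase_len) for g in groups + ["VIRO"]}
    return GenePools(
        virophage_mcp=random_peptide(rng, spec.mcp_len),
        group_mcp={g: random_peptide(rng, spec.mcp_len) for g in groups},
        mcp_minor=mcp_minor,
        atpase=atpase,
        shared_accessory=shared,
        private_accessory={
            g: [
                (f"{g}_PRIV{j:02d}", random_peptide(rng, int(rng.integers(lo, hi + 1))))
                for j in range(spec.n_private_accessory_families)
            ]
            for g in groups
        },
        virophage_accessory=[
            (f"VACC{j:02d}", random_peptide(rng, int(rng.integers(lo, hi + 1))))
            for j in range(5)
        ],
    )


def _draw_gene_inventory(
    kind: str,
    group: str,
    pools: GenePools,
    spec: CommunitySpec,
    rng: np.random.Generator,
) -> List[Tuple[str, str, str]]:
    """(family_id, role, ancestor_peptide) list for one genome."""
    inv: List[Tuple[str, str, str]] = []
    mcp_minor, atpase = pools.core_for(group if kind == "PLV" else "VIRO")
    if kind == "PLV":
        inv.append((f"MCP_{group}", "mcp", pools.group_mcp[group]))
    else:
        inv.append(("MCP_VIRO", "mcp", pools.virophage_mcp))
    inv.append(("MCP_MINOR" if "*" in pools.mcp_minor else f"MCP_MINOR_{group}",
                "mcp_minor", mcp_minor))
    inv.append(("ATPASE" if "*" in pools.atpase else f"ATPASE_{group}",
                "atpase", atpase))
    lo, hi = spec.accessory_range
    n_acc = int(rng.integers(lo, hi + 1))
    if kind == "PLV":
        n_shared = max(2, int(rng.binomial(n_acc, spec.shared_accessory_prob)))
        n_shared = min(n_shared, n_acc, len(pools.shared_accessory))
        n_priv = min(n_acc - n_shared, len(pools.private_accessory[group]))
        shared_idx = rng.choice(len(pools.shared_accessory), size=n_shared, replace=False)
        priv_idx = rng.choice(
            len(pools.private_accessory[group]), size=n_priv, replace=False
        )
        for i in sorted(shared_idx):
            fid, pep = pools.shared_accessory[i]
            inv.append((fid, "accessory", pep))
        for i in sorted(priv_idx):
            fid, pep = pools.private_accessory[group][i]
            inv.append((fid, "accessory", pep))
    else:  # virophage: mostly the shared pool, plus virophage-private families
        n_shared = min(max(1, int(rng.binomial(n_acc, 0.8))), len(pools.shared_accessory))
        n_priv = min(n_acc - n_shared, len(pools.virophage_accessory))
        shared_idx = rng.choice(len(pools.shared_accessory), size=n_shared, replace=False)
        priv_idx = rng.choice(len(pools.virophage_accessory), size=max(0, n_priv), replace=False)
        for i in sorted(shared_idx):
            fid, pep = pools.shared_accessory[i]
            inv.append((fid, "accessory", pep))
        for i in sorted(priv_idx):
            fid, pep = pools.virophage_accessory[i]
            inv.append((fid, "accessory", pep))
    return inv


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class PlantedGenome:
    contig: Contig
    genes: List[GeneCall]
    gene_families: List[Tuple[str, str, str]]  # (gene_id, family_id, role)
    topology: str  # circular | linear | linear_TIR
    group: str
    kind: str  # PLV | virophage


def _assemble(
    contig_id: str,
    peptides: List[Tuple[str, str, str]],  # (family_id, role, mutated peptide)
    target_len: int,
    topology: str,
    tir_length: int,
    rng: np.random.Generator,
) -> Tuple[str, List[GeneCall], List[Tuple[str, str, str]]]:
    coding = sum(3 * len(p) for _, _, p in peptides)
    n = len(peptides)
    min_spacer = 20
    tir = tir_length if topology == "linear_TIR" else 0
    core_target = max(target_len - 2 * tir, coding + (n + 1) * min_spacer)
    spare = core_target - coding - (n + 1) * min_spacer
    extra = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1)))
    parts: List[str] = []
    genes: List[GeneCall] = []
    fams: List[Tuple[str, str, str]] = []
    pos = 0
    for k, (fam, role, pep) in enumerate(peptides):
        spacer = random_nt(rng, min_spacer + int(extra[k]))
        parts.append(spacer)
        pos += len(spacer)
        cds = reverse_translate(pep, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(cds if strand == "+" else revcomp(cds))
        gid = f"{contig_id}_g{k + 1:03d}"
        genes.append(
            GeneCall(
                gene_id=gid, contig_id=contig_id,
                start=pos + tir, end=pos + tir + len(cds),
                strand=strand, peptide=pep,
            )
        )
        fams.append((gid, fam, role))
        pos += len(cds)
    parts.append(random_nt(rng, min_spacer + int(extra[n])))
    core = "".join(parts)
    if topology == "linear_TIR":
        t = random_nt(rng, tir_length)
        # keep the planted repeat maximal: the base just inside each end of
        # the core must not extend the inverted repeat by chance
        bad = revcomp(core[-1])
        if core[0] == bad:
            repl = next(b for b in NT if b != bad)
            core = repl + core[1:]
        seq = t + core + revcomp(t)
    else:
        seq = core
    return seq, genes, fams


def generate_genome(
    group: str,
    spec: CommunitySpec,
    rng: np.random.Generator,
    pools: GenePools,
    contig_id: Optional[str] = None,
    kind: str = "PLV",
    topology: Optional[str] = None,
) -> PlantedGenome:
    """One planted genome: >=3 core genes plus accessory genes.

    Each family member is mutated from its ancestor at half the pairwise
    divergence, so two members differ at ~``mcp_divergence``."""
    if not (0.0 <= spec.mcp_divergence < 0.95):
        raise ValueError("divergence >= 0.95 rejected")
    if contig_id is None:
        contig_id = f"{kind}_{group}"
    rate = spec.mcp_divergence / 2.0
    inventory = _draw_gene_inventory(kind, group, pools, spec, rng)
    peptides = [(fam, role, mutate_peptide(pep, rate, rng)) for fam, role, pep in inventory]
    lo, hi = spec.genome_length_range
    target = int(rng.integers(lo, hi + 1))
    if topology is None:
        topology = ["circular", "linear", "linear_TIR"][
            int(rng.choice(3, p=np.asarray(spec.topology_weights) / sum(spec.topology_weights)))
        ]
    if spec.tir_length <= 0 and topology == "linear_TIR":
        topology = "linear"
    seq, genes, fams = _assemble(
        contig_id, peptides, target, topology, spec.tir_length, rng
    )
    return PlantedGenome(
        contig=Contig(id=contig_id, seq=seq),
        genes=genes,
        gene_families=fams,
        topology=topology,
        group=group,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# integration


def plant_integration(
    host: Contig,
    virus: Contig,
    spec: CommunitySpec,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> Tuple[Contig, dict]:
    """Insert ``virus`` (flanked by TIRs and a duplicated target-site motif)
    into the interior of ``host``.

    Product layout: host[:pos+k] + TIR + virus + rc(TIR) + host[pos:], i.e.
    the k-bp host motif at [pos, pos+k) appears on both flanks of the
    element.  The site is re-drawn until the planted TSD is maximal (no
    accidental longer duplication), so detection recovers exactly k.
    """
    k = spec.tsd_length
    tirlen = spec.tir_length
    if host.length < virus.length + 2 * k + 200:
        raise ValueError("host too short for integration")
    tir = random_nt(rng, tirlen) if tirlen > 0 else ""
    vseq = virus.seq
    if tirlen > 0 and vseq[0] == revcomp(vseq[-1]):
        # keep the planted TIR maximal (first interior base must not extend it)
        vseq = next(b for b in NT if b != revcomp(vseq[-1])) + vseq[1:]
    element = tir + vseq + revcomp(tir)
    for _ in range(max_tries):
        pos = int(rng.integers(100, host.length - 100 - k))
        motif = host.seq[pos : pos + k]
        new_seq = host.seq[: pos + k] + element + host.seq[pos:]
        elem_start = pos + k
        elem_end = elem_start + len(element)
        # maximality: no duplication longer than k at this site
        ok = True
        for j in range(k + 1, 8):
            if new_seq[elem_start - j : elem_start] == new_seq[elem_end : elem_end + j]:
                ok = False
                break
        if ok:
            out = Contig(id=host.id, seq=new_seq, source_sample=host.source_sample)
            row = {
                "host_contig_id": host.id,
                "virus_contig_id": virus.id,
                "elem_start": elem_start,
                "elem_end": elem_end,
                "tir_length": tirlen,
                "tsd": motif if k > 0 else "",
                "tsd_len": k,
                "topology": "linear_TIR" if tirlen > 0 else "linear",
            }
            return out, row
    raise RuntimeError("could not place integration with a maximal TSD")


def excise(contig_seq: str, row: dict) -> str:
    """Inverse of plant_integration: remove element plus one TSD copy."""
    s, e, k = row["elem_start"], row["elem_end"], row["tsd_len"]
    return contig_seq[:s] + contig_seq[e + k :]


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    entries: Sequence[Tuple[str, int, str, float]],
    spec: CommunitySpec,
    rng: np.random.Generator,
    fraction: str,
) -> Tuple[pd.DataFrame, Dict[str, dict]]:
    """Paired-read truth placements for one size fraction.

    ``entries``: (contig_id, length, topology, depth).  Fragment count per
    contig is depth * length / (2 * read_length); circular contigs wrap
    fragments across the origin and those pairs are emitted with the
    discordant mate placements a mapper would report.
    """
    rl = spec.read_length
    rows = []
    log: Dict[str, dict] = {}
    for cid, L, topology, depth in entries:
        if depth <= 0 or L <= 0:
            log[cid] = {"n_fragments": 0, "n_wrap": 0, "bases": 0}
            continue
        if spec.insert_mean > L:
            raise ValueError(f"insert_mean exceeds length of {cid}")
        n_frag = int(round(depth * L / (2.0 * rl)))
        if n_frag == 0:
            log[cid] = {"n_fragments": 0, "n_wrap": 0, "bases": 0}
            continue
        ins = np.clip(
            np.round(rng.normal(spec.insert_mean, spec.insert_sd, size=n_frag)),
            2 * rl,
            min(spec.max_insert, L),
        ).astype(np.int64)
        if topology == "circular":
            start = rng.integers(0, L, size=n_frag)
            # A read individually straddling the origin would be clipped by a
            # mapper; snap such fragments so the junction falls between the
            # mates, preserving the expected wrap fraction ~ insert/length.
            h = start + ins - L
            near = (h > 0) & (h < rl)  # R2 would straddle: push it past 0
            start = np.where(near, start + (rl - h), start)
            h = start + ins - L
            far = h > ins - rl  # R1 would straddle: pull it back to the end
            start = np.where(far, L - ins + (ins - rl), start)
            h = start + ins - L
            wrap = h > 0
            r2s = np.where(wrap, h - rl, start + ins - rl)
        else:
            start = np.array(
                [int(rng.integers(0, L - i + 1)) for i in ins], dtype=np.int64
            )
            r2s = start + ins - rl
            wrap = np.zeros(n_frag, dtype=bool)
        for i in range(n_frag):
            rid = f"{cid}|{fraction}|{i}"
            proper = not bool(wrap[i])
            s1, s2 = int(start[i]), int(r2s[i])
            rows.append((rid, 1, cid, s1, s1 + rl, "+", cid, s2, proper, fraction))
            rows.append((rid, 2, cid, s2, s2 + rl, "-", cid, s1, proper, fraction))
        log[cid] = {
            "n_fragments": n_frag,
            "n_wrap": int(wrap.sum()),
            "bases": 2 * rl * n_frag,
        }
    df = pd.DataFrame(rows, columns=pio.ALIGNMENT_COLUMNS)
    return df, log


# ---------------------------------------------------------------------------
# community assembly


def _align_refs(peps: List[str]) -> List[str]:
    # substitution-only mutation keeps family members pre-aligned
    return peps


def build_community(spec: CommunitySpec) -> CommunityBundle:
    """Generate the full community in memory."""
    rng = np.random.default_rng(spec.seed)
    pools = make_gene_pools(spec, rng)
    groups = [f"G{g + 1:02d}" for g in range(spec.n_groups)]
    rate = spec.mcp_divergence / 2.0

    contigs: List[Contig] = []
    genes: List[GeneCall] = []
    contig_rows = []
    gene_rows = []

    planted: List[PlantedGenome] = []
    for g in groups:
        for i in range(spec.genomes_per_group):
            pg = generate_genome(
                g, spec, rng, pools, contig_id=f"PLV_{g}_{i + 1:03d}", kind="PLV"
            )
            planted.append(pg)
    for i in range(spec.n_virophages):
        pg = generate_genome(
            "VIRO", spec, rng, pools, contig_id=f"VIRO_{i + 1:03d}", kind="virophage"
        )
        planted.append(pg)

    folds = {}
    for pg in planted:
        contigs.append(pg.contig)
        genes.extend(pg.genes)
        lo, hi = spec.fold_range
        fold = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if spec.fraction_abundances and pg.contig.id in spec.fraction_abundances:
            vc, mc = spec.fraction_abundances[pg.contig.id]
        else:
            vc = spec.viral_copies
            mc = vc / fold
        folds[pg.contig.id] = (vc, mc)
        contig_rows.append(
            dict(
                contig_id=pg.contig.id,
                truth_class=pg.kind if pg.kind == "PLV" else "virophage",
                group=pg.group,
                topology=pg.topology,
                length=pg.contig.length,
                viral_copies=vc,
                microbial_copies=mc,
            )
        )
        for gid, fam, role in pg.gene_families:
            gene_rows.append(dict(gene_id=gid, contig_id=pg.contig.id,
                                  family=fam, role=role, group=pg.group))

    # background contigs: random composition, private random genes
    for i in range(spec.n_background):
        lo, hi = spec.background_length_range
        L = int(rng.integers(lo, hi + 1))
        cid = f"BG_{i + 1:03d}"
        n_genes = max(1, L // 2000)
        peps = [
            (f"bg_{cid}_{k}", "background", random_peptide(rng, int(rng.integers(80, 250))))
            for k in range(n_genes)
        ]
        seq, gcalls, fams = _assemble(cid, peps, L, "linear", 0, rng)
        contig = Contig(id=cid, seq=seq)
        contigs.append(contig)
        genes.extend(gcalls)
        if spec.fraction_abundances and cid in spec.fraction_abundances:
            vc, mc = spec.fraction_abundances[cid]
        else:
            vc, mc = spec.background_viral_copies, spec.background_microbial_copies
        folds[cid] = (vc, mc)
        contig_rows.append(
            dict(contig_id=cid, truth_class="background", group="",
                 topology="linear", length=contig.length,
                 viral_copies=vc, microbial_copies=mc)
        )
        for gid, fam, role in fams:
            gene_rows.append(dict(gene_id=gid, contig_id=cid, family=fam,
                                  role=role, group=""))

    # integrated elements in large host contigs
    integration_rows = []
    for i in range(spec.n_integrations):
        lo, hi = spec.integration_host_length_range
        L = int(rng.integers(lo, hi + 1))
        cid = f"HOST_{i + 1:03d}"
        n_genes = max(1, L // 2000)
        peps = [
            (f"bg_{cid}_{k}", "background", random_peptide(rng, int(rng.integers(80, 250))))
            for k in range(n_genes)
        ]
        host_seq, host_genes, host_fams = _assemble(cid, peps, L, "linear", 0, rng)
        host = Contig(id=cid, seq=host_seq)
        grp = groups[i % len(groups)] if groups else "G01"
        virus = generate_genome(
            grp, spec, rng, pools, contig_id=f"ELEM_{i + 1:03d}", kind="PLV",
            topology="linear",
        )
        merged, row = plant_integration(host, virus.contig, spec, rng)
        # shift the element's gene calls into host coordinates
        offset = row["elem_start"] + spec.tir_length
        elem_genes = [
            GeneCall(
                gene_id=g.gene_id.replace("ELEM", "HOST"),
                contig_id=cid,
                start=g.start + offset,
                end=g.end + offset,
                strand=g.strand,
                peptide=g.peptide,
            )
            for g in virus.genes
        ]
        # host genes downstream of the site shift by the inserted length
        ins_len = (row["elem_end"] - row["elem_start"]) + row["tsd_len"]
        adj_host_genes = []
        for g in host_genes:
            if g.start >= row["elem_start"]:
                g = GeneCall(g.gene_id, cid, g.start + ins_len, g.end + ins_len,
                             g.strand, g.peptide)
            elif g.end > row["elem_start"] - row["tsd_len"]:
                continue  # drop genes straddling the insertion site
            adj_host_genes.append(g)
        contigs.append(merged)
        genes.extend(adj_host_genes + elem_genes)
        if spec.fraction_abundances and cid in spec.fraction_abundances:
            vc, mc = spec.fraction_abundances[cid]
        else:
            vc, mc = spec.background_viral_copies, spec.background_microbial_copies
        folds[cid] = (vc, mc)
        contig_rows.append(
            dict(contig_id=cid, truth_class="integrated_host", group=grp,
                 topology="linear", length=merged.length,
                 viral_copies=vc, microbial_copies=mc)
        )
        for g in adj_host_genes:
            gene_rows.append(dict(gene_id=g.gene_id, contig_id=cid,
                                  family=f"bg_{g.gene_id}", role="background", group=""))
        for gcall, (gid, fam, role) in zip(virus.genes, virus.gene_families):
            gene_rows.append(
                dict(gene_id=gid.replace("ELEM", "HOST"), contig_id=cid,
                     family=fam, role=role, group=grp)
            )
        integration_rows.append(row | {"host_contig_id": cid})

    # reference databases ("known" sequences)
    viro_genes: List[ProteinRecord] = []
    viro_mcps: List[ProteinRecord] = []
    for r in range(spec.n_reference_virophages):
        inv = _draw_gene_inventory("virophage", "VIRO", pools, spec, rng)
        for k, (fam, role, pep) in enumerate(inv):
            mutated = mutate_peptide(pep, rate, rng)
            rec = ProteinRecord(id=f"RVIRO_{r + 1:02d}_g{k + 1:03d}", seq=mutated)
            viro_genes.append(rec)
            if role == "mcp":
                viro_mcps.append(rec)
    mcp_refs = {
        g: [
            ProteinRecord(
                id=f"REF_MCP_{g}_{j + 1:02d}",
                seq=mutate_peptide(pools.group_mcp[g], rate, rng),
            )
            for j in range(spec.n_reference_mcps)
        ]
        for g in groups
    }
    mcp_minor_refs = [
        ProteinRecord(id=f"REF_MCPMINOR_{key}_{j + 1:02d}", seq=mutate_peptide(anc, rate, rng))
        for key, anc in sorted(pools.mcp_minor.items())
        for j in range(3)
    ]
    atpase_refs = [
        ProteinRecord(id=f"REF_ATPASE_{key}_{j + 1:02d}", seq=mutate_peptide(anc, rate, rng))
        for key, anc in sorted(pools.atpase.items())
        for j in range(3)
    ]

    # reads
    meta = {c["contig_id"]: c for c in contig_rows}
    align: Dict[str, pd.DataFrame] = {}
    flog: Dict[str, Dict[str, dict]] = {}
    sizes: Dict[str, float] = {}
    for fraction, copies_col in (("viral", "viral_copies"), ("microbial", "microbial_copies")):
        entries = [
            (
                c["contig_id"],
                c["length"],
                c["topology"],
                c[copies_col] * spec.depth_per_copy,
            )
            for c in contig_rows
        ]
        df, log = simulate_reads(entries, spec, rng, fraction)
        align[fraction] = df
        flog[fraction] = log
        sizes[fraction] = sum(v["bases"] for v in log.values()) / 1e9

    # planted normalized fold enrichment (per-Gb scale, as estimated downstream)
    for c in contig_rows:
        v = c["viral_copies"] / sizes["viral"] if sizes["viral"] > 0 else 0.0
        m = c["microbial_copies"] / sizes["microbial"] if sizes["microbial"] > 0 else 0.0
        c["planted_fold_norm"] = v / m if m > 0 else float("inf")

    truth = TruthTable(
        contigs=pd.DataFrame(contig_rows),
        genes=pd.DataFrame(gene_rows),
        integrations=pd.DataFrame(
            integration_rows,
            columns=[
                "host_contig_id", "virus_contig_id", "elem_start", "elem_end",
                "tir_length", "tsd", "tsd_len", "topology",
            ],
        ),
    )
    return CommunityBundle(
        spec=spec,
        contigs=contigs,
        genes=genes,
        truth=truth,
        alignments=align,
        fragment_log=flog,
        baits=Baits(
            virophage_genes=viro_genes,
            virophage_mcps=viro_mcps,
            mcp_refs=mcp_refs,
            mcp_minor_refs=mcp_minor_refs,
            atpase_refs=atpase_refs,
        ),
        metagenome_gb=sizes,
    )


def emit_community(
    spec: CommunitySpec,
    outdir,
    export_fastq: bool = False,
) -> CommunityBundle:
    """Write the community to a directory; identical seed -> identical bytes."""
    bundle = build_community(spec)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    baitdir = os.path.join(outdir, "baits")
    os.makedirs(baitdir, exist_ok=True)

    pio.write_fasta(bundle.contigs, os.path.join(outdir, "contigs.fna"))
    pio.write_gene_table(bundle.genes, os.path.join(outdir, "genes.tsv"))
    pio.write_fasta(
        [ProteinRecord(id=g.gene_id, seq=g.peptide) for g in bundle.genes if g.peptide],
        os.path.join(outdir, "proteins.faa"),
    )
    for fraction, df in bundle.alignments.items():
        pio.write_alignments(df, os.path.join(outdir, f"alignments_{fraction}.tsv"))
    bundle.truth.save(outdir)

    pio.write_fasta(bundle.baits.virophage_genes, os.path.join(baitdir, "virophage_genes.faa"))
    pio.write_fasta(bundle.baits.virophage_mcps, os.path.join(baitdir, "virophage_mcp.faa"))
    pio.write_fasta(bundle.baits.mcp_minor_refs, os.path.join(baitdir, "mcp_minor_refs.faa"))
    pio.write_fasta(bundle.baits.atpase_refs, os.path.join(baitdir, "atpase_refs.faa"))
    for g, refs in sorted(bundle.baits.mcp_refs.items()):
        pio.write_fasta(refs, os.path.join(baitdir, f"mcp_refs_{g}.afa"))

    manifest = {
        "spec": dataclasses.asdict(bundle.spec),
        "metagenome_gb": bundle.metagenome_gb,
        "fragment_log": bundle.fragment_log,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    if export_fastq:
        _export_fastq(bundle, outdir)
    return bundle


def _export_fastq(bundle: CommunityBundle, outdir: str) -> None:
    """Phred+33 FASTQ (constant quality) reconstructed from truth placements."""
    rng = np.random.default_rng(bundle.spec.seed + 10**6)
    seqs = {c.id: c.seq for c in bundle.contigs}
    rl = bundle.spec.read_length
    qual = "I" * rl
    for fraction, df in bundle.alignments.items():
        for mate in (1, 2):
            path = os.path.join(outdir, f"reads_{fraction}_R{mate}.fastq")
            with open(path, "w") as fh:
                sub = df[df["mate_index"] == mate]
                for r in sub.itertuples():
                    s = seqs[r.contig_id][r.start : r.end]
                    if r.strand == "-":
                        s = revcomp(s)
                    s = _apply_errors(s, bundle.spec.error_rate, rng)
                    fh.write(f"@{r.read_id}/{mate}\n{s}\n+\n{qual}\n")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        alt = [b for b in NT if b != chars[i]]
        chars[i] = alt[rng.integers(0, 3)]
    return "".join(chars)


def load_community(outdir) -> CommunityBundle:
    """Reload a community directory written by :func:`emit_community`."""
    outdir = str(outdir)
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    sd = manifest["spec"]
    hints = {f.name: f for f in dataclasses.fields(CommunitySpec)}
    kwargs = {}
    for k, v in sd.items():
        if k not in hints:
            continue
        if isinstance(v, list):
            v = tuple(v)
        if k == "fraction_abundances" and v in ("None", None):
            v = None
        kwargs[k] = v
    spec = CommunitySpec(**kwargs)
    contigs = pio.read_fasta(os.path.join(outdir, "contigs.fna"))
    genes = pio.read_gene_table(os.path.join(outdir, "genes.tsv"))
    truth = TruthTable.load(outdir)
    align = {
        f: pio.load_alignment_frame(os.path.join(outdir, f"alignments_{f}.tsv"))
        for f in ("viral", "microbial")
    }
    baitdir = os.path.join(outdir, "baits")
    mcp_refs = {}
    for name in sorted(os.listdir(baitdir)):
        if name.startswith("mcp_refs_") and name.endswith(".afa"):
            group = name[len("mcp_refs_") : -len(".afa")]
            mcp_refs[group] = pio.read_fasta(os.path.join(baitdir, name), kind="protein")
    baits = Baits(
        virophage_genes=pio.read_fasta(os.path.join(baitdir, "virophage_genes.faa"), kind="protein"),
        virophage_mcps=pio.read_fasta(os.path.join(baitdir, "virophage_mcp.faa"), kind="protein"),
        mcp_refs=mcp_refs,
        mcp_minor_refs=pio.read_fasta(os.path.join(baitdir, "mcp_minor_refs.faa"), kind="protein"),
        atpase_refs=pio.read_fasta(os.path.join(baitdir, "atpase_refs.faa"), kind="protein"),
    )
    return CommunityBundle(
        spec=spec,
        contigs=contigs,
        genes=genes,
        truth=truth,
        alignments=align,
        fragment_log=manifest.get("fragment_log", {}),
        baits=baits,
        metagenome_gb={k: float(v) for k, v in manifest["metagenome_gb"].items()},
    )


# ---------------------------------------------------------------------------
# mock transcriptomes


def make_transcriptome(
    mcp_records: Sequence[Tuple[str, str, str]],  # (mcp_id, group, peptide)
    rng: np.random.Generator,
    n_decoys: int = 10,
    utr_range: Tuple[int, int] = (100, 400),
    decoy_len_range: Tuple[int, int] = (600, 1500),
) -> Tuple[List[Contig], pd.DataFrame]:
    """Transcript contigs embedding full MCP ORFs, plus decoys.

    ORFs are planted cycling through all six frames (strand x offset) so
    frame-completeness of downstream searches is exercised.  Returns the
    transcripts and a truth table (transcript_id, mcp_id, group, strand,
    frame_offset)."""
    frames = [("+", 0), ("+", 1), ("+", 2), ("-", 0), ("-", 1), ("-", 2)]
    transcripts: List[Contig] = []
    rows = []
    for i, (mcp_id, group, pep) in enumerate(mcp_records):
        strand, off = frames[i % 6]
        orf = "ATG" + reverse_translate(pep, rng) + "TAA"
        lo, hi = utr_range
        # UTR lengths congruent to the target offset mod 3, so the planted
        # ORF lands in a known reading frame on either strand
        nleft = int(rng.integers(lo, hi + 1))
        nright = int(rng.integers(lo, hi + 1))
        left = random_nt(rng, nleft - nleft % 3 + off)
        right = random_nt(rng, nright - nright % 3 + off)
        seq = left + orf + right
        if strand == "-":
            seq = revcomp(seq)
        tid = f"TR_{i + 1:03d}"
        transcripts.append(Contig(id=tid, seq=seq, source_sample="transcriptome"))
        rows.append(dict(transcript_id=tid, mcp_id=mcp_id, group=group,
                         strand=strand, frame_offset=off))
    for j in range(n_decoys):
        lo, hi = decoy_len_range
        tid = f"DECOY_{j + 1:03d}"
        transcripts.append(
            Contig(id=tid, seq=random_nt(rng, int(rng.integers(lo, hi + 1))),
                   source_sample="transcriptome")
        )
    return transcripts, pd.DataFrame(rows)
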