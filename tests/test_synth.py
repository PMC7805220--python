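import hashlib
import os

import numpy as np
import pandas as pd
import pytest

from plvkit.homology import revcomp
from plvkit.io import Contig
from plvkit.synth import (
    CommunitySpec,
    build_community,
    emit_community,
    excise,
    generate_genome,
    load_community,
    make_gene_pools,
    make_transcriptome,
    mutate_peptide,
    plant_integration,
    random_nt,
    random_peptide,
    simulate_reads,
)

TINY = dict(
    n_groups=2, genomes_per_group=2, n_virophages=1, n_background=2,
    n_integrations=1, genome_length_range=(10000, 15000),
    background_length_range=(5000, 12000), viral_copies=20.0,
    background_microbial_copies=20.0,
)


def _dir_checksums(path):
    out = {}
    for root, _, files in os.walk(path):
        for f in sorted(files):
            p = os.path.join(root, f)
            out[os.path.relpath(p, path)] = hashlib.sha256(
                open(p, "rb").read()
            ).hexdigest()
    return out


class TestSpecValidation:
    def test_tsd_length_bounds(self):
        with pytest.raises(ValueError, match="tsd"):
            CommunitySpec(tsd_length=4)

    def test_divergence_bound(self):
        with pytest.raises(ValueError, match="divergence"):
            CommunitySpec(mcp_divergence=0.96)

    def test_insert_bound(self):
        with pytest.raises(ValueError):
            CommunitySpec(insert_mean=900, max_insert=800)

    def test_genome_length_bounds(self):
        with pytest.raises(ValueError):
            CommunitySpec(genome_length_range=(500, 2000))


class TestGenerateGenome:
    def test_zero_divergence_gives_identical_family_mcps(self):
        spec = CommunitySpec(mcp_divergence=0.0, **{k: v for k, v in TINY.items() if k != "n_integrations"}, n_integrations=0)
        rng = np.random.default_rng(1)
        pools = make_gene_pools(spec, rng)
        mcps = []
        for i in range(3):
            g = generate_genome("G01", spec, rng, pools, contig_id=f"c{i}")
            mcp = next(p for gid, fam, role in g.gene_families if role == "mcp"
                       for p in [dict((x.gene_id, x.peptide) for x in g.genes)[gid]])
            mcps.append(mcp)
        assert mcps[0] == mcps[1] == mcps[2]

    def test_same_seed_same_genome(self):
        spec = CommunitySpec(**TINY)
        pools = make_gene_pools(spec, np.random.default_rng(3))
        g1 = generate_genome("G01", spec, np.random.default_rng(7), pools)
        g2 = generate_genome("G01", spec, np.random.default_rng(7), pools)
        assert g1.contig.seq == g2.contig.seq

    def test_core_genes_present_and_length_in_range(self):
        spec = CommunitySpec(**TINY)
        rng = np.random.default_rng(5)
        pools = make_gene_pools(spec, rng)
        g = generate_genome("G02", spec, rng, pools)
        roles = {r for _, _, r in g.gene_families}
        assert {"mcp", "mcp_minor", "atpase"} <= roles
        n_acc = sum(1 for _, _, r in g.gene_families if r == "accessory")
        assert 5 <= n_acc <= 20
        lo, hi = spec.genome_length_range
        assert lo <= g.contig.length <= hi

    def test_pairwise_mcp_identity_tracks_divergence(self, default_bundle):
        peps = {g.gene_id: g.peptide for g in default_bundle.genes}
        truth = default_bundle.truth.genes
        idents = []
        for grp in ("G01", "G02", "G03"):
            fam = [peps[g] for g in truth.query("role=='mcp' and group==@grp").gene_id
                   if g in peps]
            for i in range(len(fam)):
                for j in range(i + 1, len(fam)):
                    idents.append(np.mean([a == b for a, b in zip(fam[i], fam[j])]))
        assert abs(float(np.mean(idents)) - 0.70) < 0.05


class TestIntegration:
    def _setup(self, tsd_len=6, tir=250):
        spec = CommunitySpec(tsd_length=tsd_len, tir_length=tir, **{k: v for k, v in TINY.items() if k not in ("n_integrations",)}, n_integrations=1)
        rng = np.random.default_rng(9)
        host = Contig(id="h", seq=random_nt(rng, 30000))
        virus = Contig(id="v", seq=random_nt(rng, 12000))
        merged, row = plant_integration(host, virus, spec, rng)
        return host, virus, merged, row

    @pytest.mark.parametrize("tsd_len", [5, 6, 7])
    def test_tsd_duplicated_on_both_flanks(self, tsd_len):
        host, virus, merged, row = self._setup(tsd_len=tsd_len)
        s, e, k = row["elem_start"], row["elem_end"], row["tsd_len"]
        assert k == tsd_len
        assert merged.seq[s - k : s] == merged.seq[e : e + k] == row["tsd"]

    def test_zero_tir_yields_linear_topology(self):
        host, virus, merged, row = self._setup(tir=0)
        assert row["topology"] == "linear"
        assert row["elem_end"] - row["elem_start"] == virus.length

    def test_excision_restores_host(self):
        host, virus, merged, row = self._setup()
        assert excise(merged.seq, row) == host.seq

    def test_host_too_short_rejected(self):
        spec = CommunitySpec(**TINY)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="host too short"):
            plant_integration(
                Contig(id="h", seq=random_nt(rng, 1000)),
                Contig(id="v", seq=random_nt(rng, 5000)),
                spec, rng,
            )


class TestSimulateReads:
    def test_zero_copies_zero_records(self):
        spec = CommunitySpec(**TINY)
        df, log = simulate_reads(
            [("c1", 20000, "linear", 0.0)], spec, np.random.default_rng(0), "microbial"
        )
        assert len(df) == 0
        assert log["c1"]["n_fragments"] == 0

    def test_record_conservation_two_per_fragment(self, default_bundle):
        for fraction, df in default_bundle.alignments.items():
            n_frag = sum(
                v["n_fragments"] for v in default_bundle.fragment_log[fraction].values()
            )
            assert len(df) == 2 * n_frag

    def test_wrap_pair_fraction_matches_insert_over_length(self):
        spec = CommunitySpec(**TINY)
        L = 17800
        df, log = simulate_reads(
            [("c", L, "circular", 50.0)], spec, np.random.default_rng(4), "viral"
        )
        n, nw = log["c"]["n_fragments"], log["c"]["n_wrap"]
        expect = n * spec.insert_mean / L
        sd = np.sqrt(expect)
        assert abs(nw - expect) < 5 * sd
        # wrap pairs put mates near opposite ends, discordant
        wrap = df[~df.proper_pair]
        assert len(wrap) == 2 * nw
        r1 = wrap[wrap.mate_index == 1]
        assert (r1.start > L - 1000).all()
        assert (r1.mate_start < 1000).all()

    def test_insert_longer_than_genome_rejected(self):
        spec = CommunitySpec(**TINY)
        with pytest.raises(ValueError, match="insert_mean"):
            simulate_reads([("c", 200, "linear", 5.0)], spec, np.random.default_rng(0), "viral")

    def test_reads_stay_within_contig(self, default_bundle):
        lens = dict(zip(default_bundle.truth.contigs.contig_id,
                        default_bundle.truth.contigs.length))
        for df in default_bundle.alignments.values():
            ends = df.groupby("contig_id")["end"].max()
            for cid, e in ends.items():
                assert e <= lens[cid]
            assert (df.start >= 0).all()


class TestEmitCommunity:
    def test_truth_bookkeeping_and_determinism(self, tmp_path):
        spec = CommunitySpec(**TINY, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        b = emit_community(spec, d1)
        emit_community(spec, d2)
        n_expected = (
            spec.n_groups * spec.genomes_per_group + spec.n_virophages
            + spec.n_background + spec.n_integrations
        )
        assert len(b.truth.contigs) == n_expected == len(b.contigs)
        assert _dir_checksums(d1) == _dir_checksums(d2)

    def test_integration_truth_rows_have_tsds(self, tmp_path):
        spec = CommunitySpec(**TINY, seed=6)
        b = emit_community(spec, tmp_path / "c")
        assert len(b.truth.integrations) == spec.n_integrations
        assert (b.truth.integrations.tsd.str.len() == spec.tsd_length).all()

    def test_load_roundtrip(self, tmp_path):
        spec = CommunitySpec(**TINY, seed=7)
        b = emit_community(spec, tmp_path / "c")
        back = load_community(tmp_path / "c")
        assert [c.id for c in back.contigs] == [c.id for c in b.contigs]
        assert back.metagenome_gb == pytest.approx(b.metagenome_gb)
        assert len(back.genes) == len(b.genes)
        pd.testing.assert_frame_equal(
            back.alignments["viral"], b.alignments["viral"], check_dtype=False
        )

    def test_fastq_export_matches_truth_counts(self, tmp_path):
        spec = CommunitySpec(**TINY, seed=8, error_rate=0.0)
        b = emit_community(spec, tmp_path / "c", export_fastq=True)
        n_r1 = sum(
            1 for line in open(tmp_path / "c" / "reads_viral_R1.fastq")
            if line.startswith("@")
        )
        assert n_r1 == (b.alignments["viral"].mate_index == 1).sum()


class TestTranscriptome:
    def test_planted_orfs_cover_all_six_frames(self):
        rng = np.random.default_rng(2)
        mcps = [(f"m{i}", "G", random_peptide(rng, 250)) for i in range(6)]
        transcripts, truth = make_transcriptome(mcps, rng, n_decoys=0)
        assert sorted(zip(truth.strand, truth.frame_offset)) == [
            ("+", 0), ("+", 1), ("+", 2), ("-", 0), ("-", 1), ("-", 2)
        ]
        # the planted peptide is recoverable from the stated frame
        from plvkit.homology import translate, revcomp as rc

        for tr, row in zip(transcripts, truth.itertuples()):
            seq = tr.seq if row.strand == "+" else rc(tr.seq)
            pep = translate(seq, row.frame_offset)
            assert mcps[int(row.Index)][2] in pep
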