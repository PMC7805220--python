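import numpy as np
import pytest

from plvkit import classify
from plvkit.classify import (
    ClassifierConfig,
    bait_expand,
    confirm_plv,
    dereplicate,
    flag_putative_plv,
    flag_virophage,
)
from plvkit.homology import build_profile
from plvkit.io import Contig, GeneCall, HomologyHit
from plvkit.synth import mutate_peptide, random_nt, random_peptide


def _contig(length, cid="c"):
    return Contig(id=cid, seq="A" * length)


def _genes(n, cid="c"):
    return [GeneCall(f"{cid}_g{i}", cid, 10 * i, 10 * i + 9, "+", "") for i in range(n)]


def _hits(genes, n_hit):
    return [
        HomologyHit(g.gene_id, "bait", 50.0, 1e-10, 100, 80.0, 0, 100, 0, 100)
        for g in genes[:n_hit]
    ]


CFG = ClassifierConfig()


class TestPutativeBoundaries:
    """The documented decision matrix for the three putative criteria."""

    @pytest.mark.parametrize(
        "n_hit,n_genes,length,mcp,expected",
        [
            # hit-fraction boundary at 20% (inclusive)
            (19, 100, 20000, False, "rejected"),
            (20, 100, 20000, False, "putative_PLV"),
            (21, 100, 20000, False, "putative_PLV"),
            (4, 21, 20000, False, "rejected"),    # 0.190
            (5, 20, 20000, False, "putative_PLV"),  # 0.25
            # length boundaries, inclusive [10000, 45000]
            (10, 20, 9999, False, "rejected"),
            (10, 20, 10000, False, "putative_PLV"),
            (10, 20, 45000, False, "putative_PLV"),
            (10, 20, 45001, False, "rejected"),
            (10, 20, 41000, False, "putative_PLV"),
            (10, 20, 41001, False, "putative_PLV"),  # putative allows up to 45 kb
            # virophage MCP presence vetoes
            (10, 20, 20000, True, "rejected"),
            (20, 20, 45000, True, "rejected"),
        ],
    )
    def test_matrix(self, n_hit, n_genes, length, mcp, expected):
        genes = _genes(n_genes)
        res = flag_putative_plv(_contig(length), genes, _hits(genes, n_hit), mcp, CFG)
        assert res.label == expected
        assert res.hit_fraction_observed == pytest.approx(n_hit / n_genes)

    def test_zero_genes_rejected_without_division(self):
        res = flag_putative_plv(_contig(20000), [], [], False, CFG)
        assert res.label == "rejected"
        assert res.reason == "no genes"


class TestConfirmBoundaries:
    def _putative(self, length, frac=0.5):
        genes = _genes(20)
        return flag_putative_plv(
            _contig(length), genes, _hits(genes, int(frac * 20)), False, CFG
        )

    @pytest.mark.parametrize(
        "length,mcp,expected",
        [
            (43000, ("g", "profile"), "putative_PLV"),  # > 41 kb: never confirmed
            (41000, ("g", "profile"), "confirmed_PLV"),
            (41001, ("g", "profile"), "putative_PLV"),
            (10000, ("g", "profile"), "confirmed_PLV"),
            (9999, None, "rejected"),  # not putative in the first place
            (20000, None, "putative_PLV"),
        ],
    )
    def test_matrix(self, length, mcp, expected):
        if expected == "rejected":
            res = self._putative(length)
            assert res.label == "rejected"
            return
        res = confirm_plv(self._putative(length), _contig(length), mcp, CFG)
        assert res.label == expected

    def test_mcp_profile_hit_confirms(self):
        res = confirm_plv(self._putative(20000), _contig(20000), ("gX", "profile"), CFG)
        assert res.label == "confirmed_PLV"
        assert res.mcp_gene_id == "gX"
        assert res.mcp_method == "profile"

    def test_core_fallback_stays_putative(self):
        res = confirm_plv(
            self._putative(20000), _contig(20000), None, CFG,
            has_mcp_minor=True, has_atpase=True,
        )
        assert res.label == "putative_PLV"
        assert res.fallback_core is True

    def test_without_fallback_reason_recorded(self):
        res = confirm_plv(self._putative(20000), _contig(20000), None, CFG)
        assert res.label == "putative_PLV"
        assert res.fallback_core is False
        assert "no MCP" in res.reason

    def test_requires_putative_input(self):
        genes = _genes(20)
        rejected = flag_putative_plv(_contig(5000), genes, _hits(genes, 10), False, CFG)
        with pytest.raises(ValueError):
            confirm_plv(rejected, _contig(5000), None, CFG)


class TestFlagVirophage:
    def test_hit_and_no_hit(self):
        genes = _genes(5)
        assert flag_virophage(genes, _hits(genes, 1)) is True
        assert flag_virophage(genes, []) is False
        assert flag_virophage([], _hits(_genes(5), 2)) is False


class TestConfigValidation:
    def test_confirmed_must_be_subset_of_putative(self):
        with pytest.raises(ValueError):
            ClassifierConfig(putative_len=(10000, 45000), confirmed_len=(9000, 41000))

    def test_hit_fraction_bounds(self):
        with pytest.raises(ValueError):
            ClassifierConfig(hit_fraction=0.0)


def _two_hop_community(seed=0):
    """Group A hits the seed db directly; group B shares genes only with A."""
    rng = np.random.default_rng(seed)
    seed_fams = [random_peptide(rng, 150) for _ in range(10)]
    a_priv = [random_peptide(rng, 150) for _ in range(7)]
    b_priv = [random_peptide(rng, 150) for _ in range(7)]
    mcp_a = random_peptide(rng, 250)
    mcp_b = random_peptide(rng, 250)

    def contig(cid, peptides):
        genes = [
            GeneCall(f"{cid}_g{i}", cid, 300 * i, 300 * i + 3 * len(p), "+", p)
            for i, p in enumerate(peptides)
        ]
        return Contig(id=cid, seq=random_nt(rng, 15000)), genes

    ca, genes_a = contig("A", [mcp_a] + [mutate_peptide(p, 0.1, rng) for p in seed_fams[:3]] + a_priv[:6])
    cb, genes_b = contig("B", [mcp_b] + [mutate_peptide(p, 0.1, rng) for p in a_priv[:5]] + b_priv[:4])
    seed_db = [(f"seed{i}", p) for i, p in enumerate(seed_fams)]
    viro_mcp_db = [("viro_mcp", random_peptide(rng, 250))]
    profiles = [
        build_profile([mutate_peptide(mcp_a, 0.1, rng) for _ in range(3)], name="MCP_A"),
        build_profile([mutate_peptide(mcp_b, 0.1, rng) for _ in range(3)], name="MCP_B"),
    ]
    return [ca, cb], genes_a + genes_b, seed_db, viro_mcp_db, profiles


class TestBaitExpand:
    def test_two_hop_chain_found_in_second_iteration(self):
        contigs, genes, seed_db, viro_db, profiles = _two_hop_community()
        out = bait_expand(contigs, genes, seed_db, viro_db, profiles)
        assert out.results["A"].label == "confirmed_PLV"
        assert out.results["A"].iteration_found == 1
        assert out.results["B"].label == "confirmed_PLV"
        assert out.results["B"].iteration_found >= 2
        assert out.converged

    def test_fixed_point_when_seed_covers_everything(self):
        contigs, genes, seed_db, viro_db, profiles = _two_hop_community()
        # seed the bait with every gene: nothing new can be added after pass 1
        full_seed = seed_db + [(g.gene_id + "_bait", g.peptide) for g in genes]
        out = bait_expand(contigs, genes, full_seed, viro_db, profiles)
        assert out.converged
        assert out.iterations == 2  # second pass finds nothing new
        assert all(r.iteration_found == 1 for r in out.results.values()
                   if r.label == "confirmed_PLV")

    def test_empty_assemblies_give_empty_results(self):
        _, _, seed_db, viro_db, profiles = _two_hop_community()
        out = bait_expand([], [], seed_db, viro_db, profiles)
        assert out.results == {}

    def test_empty_seed_db_rejected(self):
        contigs, genes, _, viro_db, profiles = _two_hop_community()
        with pytest.raises(ValueError):
            bait_expand(contigs, genes, [], viro_db, profiles)

    def test_order_invariance(self):
        contigs, genes, seed_db, viro_db, profiles = _two_hop_community()
        out1 = bait_expand(contigs, genes, seed_db, viro_db, profiles)
        out2 = bait_expand(
            list(reversed(contigs)), list(reversed(genes)), seed_db, viro_db, profiles
        )
        assert {k: v.label for k, v in out1.results.items()} == {
            k: v.label for k, v in out2.results.items()
        }


class TestDereplicate:
    def test_exact_duplicate_collapses(self):
        rng = np.random.default_rng(1)
        seq = random_nt(rng, 15000)
        a, b = Contig(id="a", seq=seq), Contig(id="b", seq=seq)
        clusters, reps = dereplicate([a, b], rounds=[(0.9, None, False)])
        assert reps == ["a"]
        assert sorted(clusters["a"]) == ["a", "b"]

    def test_rotation_needs_circular_awareness(self):
        rng = np.random.default_rng(2)
        seq = random_nt(rng, 20000)
        rot = seq[5000:] + seq[:5000]
        a, b = Contig(id="a", seq=seq), Contig(id="b", seq=rot)
        clusters, reps = dereplicate([a, b], rounds=[(0.9, None, True)])
        assert len(reps) == 1
        clusters, reps = dereplicate([a, b], rounds=[(0.9, None, False)])
        assert len(reps) == 2

    def test_eighty_percent_mutants_merge_only_at_07(self):
        rng = np.random.default_rng(3)
        seq = random_nt(rng, 12000)
        chars = list(seq)
        for i in np.flatnonzero(rng.random(len(chars)) < 0.2):
            chars[i] = "ACGT"[(("ACGT".index(chars[i])) + 1) % 4]
        mut = "".join(chars)
        a, b = Contig(id="a", seq=seq), Contig(id="b", seq=mut)
        _, reps07 = dereplicate([a, b], rounds=[(0.7, None, True)])
        _, reps09 = dereplicate([a, b], rounds=[(0.9, None, True)])
        assert len(reps07) == 1
        assert len(reps09) == 2

    def test_two_round_defaults_cluster_fragments_then_relatives(self):
        rng = np.random.default_rng(4)
        seq = random_nt(rng, 30000)
        frag = Contig(id="frag", seq=seq[2000:12000])  # 33% of the full genome
        full = Contig(id="full", seq=seq)
        other = Contig(id="other", seq=random_nt(rng, 30000))
        clusters, reps = dereplicate([full, frag, other])
        assert sorted(clusters["full"]) == ["frag", "full"]
        assert "other" in reps

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dereplicate([])
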