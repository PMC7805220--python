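import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plvkit import homology as hom
from plvkit.homology import (
    DEFAULT_SCHEME,
    ScoringScheme,
    build_profile,
    evalue,
    bitscore,
    local_align,
    local_score,
    encode_peptide,
    profile_search,
    search_db,
    translate_six_frames,
    ProfileModel,
)
from plvkit.synth import mutate_peptide, random_peptide

AA = "ACDEFGHIKLMNPQRSTVWY"
peptides = st.text(alphabet=AA, min_size=1, max_size=8)


class TestLocalAlign:
    def test_identity_alignment_scores_diagonal_sum(self):
        pep = "ACDEFGHIKW"
        hit = local_align(pep, pep)
        enc = encode_peptide(pep)
        raw = sum(DEFAULT_SCHEME.matrix[i, i] for i in enc)
        assert hit.bitscore == pytest.approx(bitscore(raw))
        assert hit.pct_identity == 100.0
        assert (hit.q_start, hit.q_end, hit.s_start, hit.s_end) == (0, 10, 0, 10)

    def test_no_positive_pair_score_gives_empty_alignment(self):
        # A vs C scores 0 in BLOSUM62: no positive local alignment exists
        assert local_align("AAAA", "CCCC") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACD")

    def test_x_is_neutral(self):
        hit = local_align("MKVXXLW", "MKVAALW")
        assert hit is not None
        assert hit.aln_len == 7

    def test_matches_brute_force_on_random_panel(self, oracle_score):
        rng = np.random.default_rng(5)
        for _ in range(150):
            q = "".join(rng.choice(list(AA), rng.integers(1, 9)))
            s = "".join(rng.choice(list(AA), rng.integers(1, 9)))
            got = local_score(encode_peptide(q), encode_peptide(s))
            assert got == pytest.approx(oracle_score(q, s)), (q, s)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(q=peptides, s=peptides)
    def test_score_symmetric_for_symmetric_matrix(self, q, s):
        assert local_score(encode_peptide(q), encode_peptide(s)) == pytest.approx(
            local_score(encode_peptide(s), encode_peptide(q))
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(q=peptides, s=peptides, t=peptides)
    def test_score_monotone_under_subject_extension(self, q, s, t):
        # a local alignment within s remains valid within s + t
        base = local_score(encode_peptide(q), encode_peptide(s))
        ext = local_score(encode_peptide(q), encode_peptide(s + t))
        assert ext >= base - 1e-9


class TestEvalue:
    def test_unit_evalue_identity(self):
        # bitscore b with 2**-b * m * n == 1  =>  E == 1
        m, n = 300, 500
        b = math.log2(m * n)
        assert evalue(b, m, n) == pytest.approx(1.0)

    def test_linear_in_database_size(self):
        assert evalue(30.0, 100, 2000) == pytest.approx(2 * evalue(30.0, 100, 1000))

    def test_bits_and_raw_forms_agree(self):
        lam, K = 0.267, 0.041
        S, m, n = 100.0, 300, 300
        via_bits = evalue(bitscore(S), m, n)
        raw = K * m * n * math.exp(-lam * S)
        assert via_bits == pytest.approx(raw, rel=1e-9)

    def test_monotone_in_bitscore_and_search_space(self):
        assert evalue(31.0, 100, 100) < evalue(30.0, 100, 100)
        assert evalue(30.0, 100, 100) < evalue(30.0, 200, 100)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            evalue(30.0, 0, 10)


class TestSearchDb:
    def test_self_hit_has_lowest_evalue(self):
        rng = np.random.default_rng(0)
        db = [(f"p{i}", random_peptide(rng, 120)) for i in range(5)]
        hits = search_db([db[2]], db, e_cutoff=1e-3)
        assert hits[0].subject_id == "p2"
        assert all(hits[0].evalue <= h.evalue for h in hits)

    def test_zero_cutoff_empty(self):
        rng = np.random.default_rng(0)
        db = [("p", random_peptide(rng, 50))]
        assert search_db(db, db, e_cutoff=0.0) == []

    def test_empty_db_empty(self):
        assert search_db([("q", "MKV")], [], e_cutoff=1.0) == []

    def test_planted_family_recovered_without_decoy_hits(self):
        rng = np.random.default_rng(3)
        anc = random_peptide(rng, 200)
        fam = [(f"fam{i}", mutate_peptide(anc, 0.15, rng)) for i in range(6)]
        decoys = [(f"dec{i}", random_peptide(rng, 200)) for i in range(20)]
        hits = search_db([fam[0]], fam + decoys, e_cutoff=1e-5)
        subjects = {h.subject_id for h in hits}
        assert {f"fam{i}" for i in range(6)} <= subjects
        assert not any(s.startswith("dec") for s in subjects)

    def test_deterministic_order(self):
        rng = np.random.default_rng(1)
        anc = random_peptide(rng, 100)
        db = [(f"s{i}", mutate_peptide(anc, 0.1, rng)) for i in range(4)]
        hits1 = search_db([("q", anc)], db, e_cutoff=1e-3)
        hits2 = search_db([("q", anc)], list(reversed(db)), e_cutoff=1e-3)
        assert [h.subject_id for h in hits1] == [h.subject_id for h in hits2]


class TestProfile:
    def test_single_residue_column_alpha_limit(self):
        msa = ["A", "A", "A"]
        prof = build_profile(msa, alpha=1e-9)
        # log-odds of the observed residue -> 2*log2(1/bg); others floored
        assert prof.scores[0, 0] == pytest.approx(2 * math.log2(20.0), abs=1e-4)
        assert prof.scores[0, 5] == pytest.approx(-20.0)

    def test_uniform_column_scores_zero(self):
        msa = list(AA)  # one sequence per residue, single column
        prof = build_profile(msa, alpha=1.0)
        assert np.allclose(prof.scores[0, :20], 0.0)

    def test_gappy_columns_masked(self):
        msa = ["A-C", "A-C", "AAC"]
        prof = build_profile(msa)
        assert prof.ncols == 2
        assert prof.kept_columns == [0, 2]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["AC", "ACD"])

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(0)
        msa = [mutate_peptide(random_peptide(rng, 30), 0.2, rng) for _ in range(4)]
        prof = build_profile(msa, name="fam")
        back = ProfileModel.from_text(prof.to_text())
        assert back.name == "fam"
        assert np.allclose(back.scores, prof.scores, atol=1e-3)

    def test_training_sequence_recovered_at_default_cutoff(self):
        rng = np.random.default_rng(2)
        anc = random_peptide(rng, 150)
        msa = [mutate_peptide(anc, 0.15, rng) for _ in range(5)]
        prof = build_profile(msa, name="fam")
        hits = profile_search(prof, [("t0", msa[0])], e_cutoff=1e-5)
        assert [h.subject_id for h in hits] == ["t0"]

    def test_empty_db(self):
        prof = build_profile(["ACD", "ACD"])
        assert profile_search(prof, []) == []

    def test_profile_recovers_member_single_search_misses(self):
        # raise family divergence until a single-sequence query misses a
        # member at E <= 1e-5, then the profile from the found members must
        # recover every member at the same cutoff with no decoy hits
        for divergence in np.arange(0.5, 0.95, 0.05):
            rng = np.random.default_rng(11)
            anc = random_peptide(rng, 120)
            fam = [(f"fam{i}", mutate_peptide(anc, divergence / 2, rng)) for i in range(6)]
            decoys = [(f"dec{i}", random_peptide(rng, 120)) for i in range(20)]
            db = fam + decoys
            found = {h.subject_id for h in search_db([fam[0]], db, e_cutoff=1e-5)}
            missed = [fid for fid, _ in fam if fid not in found]
            if not missed:
                continue
            train = [seq for fid, seq in fam if fid not in missed]
            prof = build_profile(train, name="fam")
            phits = {h.subject_id for h in profile_search(prof, db, e_cutoff=1e-5)}
            assert {fid for fid, _ in fam} <= phits
            assert not any(s.startswith("dec") for s in phits)
            return
        pytest.fail("no divergence produced a single-search miss")


class TestTranslation:
    def test_first_frame(self):
        assert dict(translate_six_frames("ATGGCC"))["+1"] == "MA"

    def test_reverse_complement_swaps_frame_sets(self):
        nt = "ATGGCCTTAGACCTG"
        fwd = dict(translate_six_frames(nt))
        rev = dict(translate_six_frames(hom.revcomp(nt)))
        assert {fwd[f"+{i}"] for i in (1, 2, 3)} == {rev[f"-{i}"] for i in (1, 2, 3)}
        assert {fwd[f"-{i}"] for i in (1, 2, 3)} == {rev[f"+{i}"] for i in (1, 2, 3)}

    def test_frame_lengths(self):
        rng = np.random.default_rng(0)
        nt = "".join(rng.choice(list("ACGT"), 300))
        for frame, pep in translate_six_frames(nt):
            off = int(frame[1]) - 1
            assert len(pep) == (300 - off) // 3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate_six_frames("AT")

    def test_stops_rendered_as_star(self):
        assert dict(translate_six_frames("TAATAG"))["+1"] == "**"


class TestScoringScheme:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1)
        with pytest.raises(ValueError):
            ScoringScheme(lam=0.0)
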