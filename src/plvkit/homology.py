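"""Self-contained protein similarity search.

Pairwise Smith-Waterman local alignment with affine gaps, Karlin-Altschul
E-values, position-specific profile models built from alignments, and
six-frame translation.  This is the engine behind every similarity-based
decision in the pipeline (bait searches, capsid confirmation, protein
clustering, transcriptome screening).

Conventions
-----------
* Scores use BLOSUM62 with gap cost ``open + g * extend`` for a gap of
  length ``g`` (the "11/1" convention); ``X`` and ``*`` score 0 against
  everything.
* E = K * m * n * exp(-lambda * S), with the published gapped BLOSUM62
  parameters lambda = 0.267, K = 0.041.  Bit score b = (lambda*S - ln K)/ln 2,
  so E = m * n * 2**-b.
* Profile models are per-column log-odds scores in half-bit units
  (2 * log2(p/background)); they reuse the same lambda/K uncalibrated,
  which is adequate because profile E-values are used only as ranked
  thresholds.
* Traceback tie-breaks: the end cell is the first maximum in row-major
  order (smallest query end, then subject end) and the path prefers
  diagonal over up over left, so coordinates are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .io import HomologyHit, ProteinRecord

# Published gapped BLOSUM62 (open 11, extend 1) Karlin-Altschul parameters.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA20 = ALPHABET[:20]
_X_INDEX = ALPHABET.index("X")

_ENCODE = np.full(128, _X_INDEX, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i

_ENCODE21 = np.full(128, 20, dtype=np.int8)
for _i, _c in enumerate(AA20):
    _ENCODE21[ord(_c)] = _i


def encode_peptide(seq: str) -> np.ndarray:
    """Encode a peptide over the BLOSUM62 alphabet; unknowns map to X."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE[arr]


def _encode21(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE21[arr]


def _default_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    assert str(blosum.alphabet) == ALPHABET
    m = np.array(blosum, dtype=np.float64)
    # X and the stop symbol are wildcards here: score 0 against everything.
    for sym in ("X", "*"):
        i = ALPHABET.index(sym)
        m[i, :] = 0.0
        m[:, i] = 0.0
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value parameters."""

    matrix: np.ndarray = field(default_factory=_default_matrix)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = GAPPED_LAMBDA
    K: float = GAPPED_K

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_SCHEME = ScoringScheme()

_NEG = -1e30


@njit(cache=True)
def _affine_local_score(S, go, ge):
    """Best Smith-Waterman score for a precomputed cell-score matrix S."""
    n, m = S.shape
    H = np.zeros(m + 1)
    F = np.full(m + 1, _NEG)
    best = 0.0
    for i in range(1, n + 1):
        diag = 0.0
        E = _NEG
        for j in range(1, m + 1):
            E = max(E - ge, H[j - 1] - go - ge)
            F[j] = max(F[j] - ge, H[j] - go - ge)
            h = diag + S[i - 1, j - 1]
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _affine_local_full(S, go, ge):
    """Full H/E/F matrices for traceback."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            F[i, j] = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


def _traceback(S, H, E, F, go, ge):
    """Recover the optimal local path.

    Returns (score, q_start, q_end, s_start, s_end, columns) where columns
    is a list of (i, j) aligned pairs with -1 marking a gap on that side.
    End cell: first maximum in row-major order; ties prefer diag > up > left.
    """
    best = H.max()
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, []
    idx = np.argwhere(H == best)
    # row-major argwhere is already sorted by (i, j)
    i, j = int(idx[0][0]), int(idx[0][1])
    q_end, s_end = i, j
    cols: List[Tuple[int, int]] = []
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "F":
            cols.append((i - 1, -1))
            if F[i, j] == H[i - 1, j] - go - ge:
                i -= 1
                state = "H"
            else:
                i -= 1
        else:  # E
            cols.append((-1, j - 1))
            if E[i, j] == H[i, j - 1] - go - ge:
                j -= 1
                state = "H"
            else:
                j -= 1
    cols.reverse()
    return float(best), i, q_end, j, s_end, cols


def bitscore(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Normalized score in bits: (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    """Expected chance hits: E = m * n * 2**(-bitscore)."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    return float(m) * float(n) * math.pow(2.0, -bits)


def _as_pairs(seqs) -> List[Tuple[str, str]]:
    out = []
    for s in seqs:
        if isinstance(s, (ProteinRecord,)):
            out.append((s.id, s.seq))
        elif isinstance(s, tuple):
            out.append((s[0], s[1]))
        else:
            raise TypeError(f"expected ProteinRecord or (id, seq), got {type(s)}")
    return out


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    m: Optional[int] = None,
    n: Optional[int] = None,
) -> Optional[HomologyHit]:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns None when no positive-scoring local alignment exists (the
    empty alignment).  E-values default to the pairwise search space
    m = |query|, n = |subject| unless overridden.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    q = encode_peptide(query)
    s = encode_peptide(subject)
    S = scheme.matrix[q[:, None], s[None, :]]
    H, E, F = _affine_local_full(S, scheme.gap_open, scheme.gap_extend)
    score, qs, qe, ss, se, cols = _traceback(S, H, E, F, scheme.gap_open, scheme.gap_extend)
    if score <= 0.0 or not cols:
        return None
    matches = sum(
        1 for (ci, cj) in cols if ci >= 0 and cj >= 0 and query[ci] == subject[cj]
    )
    bits = bitscore(score, scheme)
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        bitscore=bits,
        evalue=evalue(bits, m if m is not None else len(query), n if n is not None else len(subject)),
        aln_len=len(cols),
        pct_identity=100.0 * matches / len(cols),
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
    )


def local_score(query_enc: np.ndarray, subject_enc: np.ndarray,
                scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Score-only Smith-Waterman on pre-encoded peptides (fast path)."""
    S = scheme.matrix[query_enc[:, None], subject_enc[None, :]]
    return float(_affine_local_score(S, scheme.gap_open, scheme.gap_extend))


def search_db(
    queries,
    db,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_cutoff: float = 1e-5,
) -> List[HomologyHit]:
    """All query-subject pairs with E <= cutoff.

    The E-value search space is m = query length, n = total database
    residues (BLAST-like).  Output order: query input order, then
    ascending E, then subject id.
    """
    qpairs = _as_pairs(queries)
    dpairs = _as_pairs(db)
    if not dpairs:
        return []
    n_db = sum(len(s) for _, s in dpairs)
    d_enc = [encode_peptide(s) for _, s in dpairs]
    hits: List[HomologyHit] = []
    for qi, (qid, qseq) in enumerate(qpairs):
        q_enc = encode_peptide(qseq)
        qhits = []
        for (sid, sseq), s_enc in zip(dpairs, d_enc):
            score = local_score(q_enc, s_enc, scheme)
            if score <= 0.0:
                continue
            e = evalue(bitscore(score, scheme), len(qseq), n_db)
            if e <= e_cutoff:
                hit = local_align(
                    qseq, sseq, scheme, query_id=qid, subject_id=sid,
                    m=len(qseq), n=n_db,
                )
                if hit is not None:
                    qhits.append(hit)
        qhits.sort(key=lambda h: (h.evalue, h.subject_id))
        hits.extend(qhits)
    return hits


def scan_first_hit(
    query_enc: np.ndarray,
    query_len: int,
    db_enc: Sequence[np.ndarray],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    e_cutoff: float = 1e-5,
    start: int = 0,
) -> int:
    """Index of the first database entry (>= start) the query hits, else -1.

    Uses the pairwise search space (m = query, n = subject), which keeps a
    hit decision independent of later database growth -- required so that
    iterative bait expansion is monotone.
    """
    for k in range(start, len(db_enc)):
        s_enc = db_enc[k]
        score = local_score(query_enc, s_enc, scheme)
        if score <= 0.0:
            continue
        e = evalue(bitscore(score, scheme), query_len, len(s_enc))
        if e <= e_cutoff:
            return k
    return -1


# ---------------------------------------------------------------------------
# Profile models


@dataclass
class ProfileModel:
    """Position-specific log-odds scoring model built from an alignment.

    ``scores`` has shape (ncols, 21): 20 residue columns in AA20 order in
    half-bit units plus a final zero column for unknown residues.  Columns
    with more than ``max_gap_frac`` gaps in the source alignment were
    masked out; ``kept_columns`` maps back to source alignment columns.
    """

    scores: np.ndarray
    background: np.ndarray
    alpha: float
    name: str = "profile"
    kept_columns: Optional[List[int]] = None

    @property
    def ncols(self) -> int:
        return int(self.scores.shape[0])

    def consensus(self) -> str:
        return "".join(AA20[int(i)] for i in np.argmax(self.scores[:, :20], axis=1))

    def to_text(self) -> str:
        lines = [
            f"# plvkit profile v1 name={self.name} ncols={self.ncols} alpha={self.alpha}",
            "# background\t" + "\t".join(f"{b:.6g}" for b in self.background),
            "col\t" + "\t".join(AA20),
        ]
        for i in range(self.ncols):
            lines.append(
                f"{i}\t" + "\t".join(f"{v:.4f}" for v in self.scores[i, :20])
            )
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "ProfileModel":
        lines = [l for l in text.splitlines() if l.strip()]
        head = lines[0]
        if not head.startswith("# plvkit profile v1"):
            raise ValueError("not a plvkit profile file")
        meta = dict(tok.split("=", 1) for tok in head.split()[4:])
        bg = np.array([float(x) for x in lines[1].split("\t")[1:]])
        rows = []
        for line in lines[3:]:
            rows.append([float(x) for x in line.split("\t")[1:]])
        scores20 = np.array(rows)
        scores = np.zeros((scores20.shape[0], 21))
        scores[:, :20] = scores20
        return cls(
            scores=scores,
            background=bg,
            alpha=float(meta.get("alpha", 1.0)),
            name=meta.get("name", "profile"),
        )

    @classmethod
    def load(cls, path) -> "ProfileModel":
        with open(path) as fh:
            return cls.from_text(fh.read())


GAP_CHARS = set("-.")


def build_profile(
    msa: Sequence[str],
    alpha: float = 1.0,
    background: Optional[np.ndarray] = None,
    max_gap_frac: float = 0.5,
    score_floor: float = -20.0,
    name: str = "profile",
) -> ProfileModel:
    """Log-odds profile from an aligned set of peptides.

    Columns with more than ``max_gap_frac`` gap characters are masked.
    Per-column residue probabilities are pseudocount-smoothed toward the
    background (weight ``alpha``); scores are 2*log2(p/background), floored
    at ``score_floor``.  Background defaults to uniform 1/20.
    """
    if len(msa) < 2:
        raise ValueError("profile needs at least 2 aligned sequences")
    width = len(msa[0])
    if any(len(s) != width for s in msa):
        raise ValueError("ragged alignment")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)

    cols = []
    kept = []
    for j in range(width):
        column = [s[j].upper() for s in msa]
        gap_frac = sum(1 for c in column if c in GAP_CHARS) / len(column)
        if gap_frac > max_gap_frac:
            continue
        counts = np.zeros(20)
        for c in column:
            k = AA20.find(c)
            if k >= 0:
                counts[k] += 1.0
        nobs = counts.sum()
        probs = (counts + alpha * background) / (nobs + alpha)
        with np.errstate(divide="ignore"):
            sc = 2.0 * np.log2(probs / background)
        sc = np.maximum(sc, score_floor)
        cols.append(sc)
        kept.append(j)
    if not cols:
        raise ValueError("all columns masked")
    scores = np.zeros((len(cols), 21))
    scores[:, :20] = np.vstack(cols)
    return ProfileModel(
        scores=scores, background=background, alpha=alpha, name=name,
        kept_columns=kept,
    )


def profile_score(profile: ProfileModel, seq: str,
                  gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Best local profile-to-sequence score with affine gaps."""
    enc = _encode21(seq)
    S = profile.scores[:, enc]
    return float(_affine_local_score(S, gap_open, gap_extend))


def profile_search(
    profile: ProfileModel,
    db,
    e_cutoff: float = 1e-5,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    lam: float = GAPPED_LAMBDA,
    K: float = GAPPED_K,
) -> List[HomologyHit]:
    """Best local profile score per subject; hits with E <= cutoff.

    E-values reuse the pairwise-alignment Karlin-Altschul parameters
    uncalibrated for profile scores (ranked-threshold use only), with
    m = profile columns, n = total database residues.
    """
    dpairs = _as_pairs(db)
    if not dpairs:
        return []
    n_db = sum(len(s) for _, s in dpairs)
    consensus = profile.consensus()
    hits = []
    for sid, sseq in dpairs:
        enc = _encode21(sseq)
        S = profile.scores[:, enc]
        score = float(_affine_local_score(S, gap_open, gap_extend))
        if score <= 0.0:
            continue
        bits = (lam * score - math.log(K)) / math.log(2.0)
        e = evalue(bits, profile.ncols, n_db)
        if e > e_cutoff:
            continue
        H, E, F = _affine_local_full(S, gap_open, gap_extend)
        _, qs, qe, ss, se, cols = _traceback(S, H, E, F, gap_open, gap_extend)
        matches = sum(
            1
            for (ci, cj) in cols
            if ci >= 0 and cj >= 0 and consensus[ci] == sseq[cj].upper()
        )
        hits.append(
            HomologyHit(
                query_id=profile.name,
                subject_id=sid,
                bitscore=bits,
                evalue=e,
                aln_len=max(1, len(cols)),
                pct_identity=100.0 * matches / max(1, len(cols)),
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# Translation

_STANDARD_TABLE = None


def _codon_table():
    global _STANDARD_TABLE
    if _STANDARD_TABLE is None:
        from Bio.Data import CodonTable

        tbl = CodonTable.unambiguous_dna_by_id[1]
        d = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            d[stop] = "*"
        _STANDARD_TABLE = d
    return _STANDARD_TABLE


def translate(nt: str, frame_offset: int = 0) -> str:
    """Translate one forward frame; stops as '*', ambiguous codons as 'X'."""
    table = _codon_table()
    s = nt.upper()
    out = []
    for i in range(frame_offset, len(s) - 2, 3):
        out.append(table.get(s[i : i + 3], "X"))
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(nt: str) -> str:
    return nt.upper().translate(_COMPLEMENT)[::-1]


def translate_six_frames(nt: str) -> List[Tuple[str, str]]:
    """All six reading frames as (frame_label, peptide).

    Labels +1..+3 are forward offsets 0..2; -1..-3 are the same offsets on
    the reverse complement.
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = nt.upper()
    rev = revcomp(fwd)
    out = []
    for off in range(3):
        out.append((f"+{off + 1}", translate(fwd, off)))
    for off in range(3):
        out.append((f"-{off + 1}", translate(rev, off)))
    return out
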