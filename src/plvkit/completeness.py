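"""Genome completeness calls.

A contig is flagged complete when read mapping shows it to be circular
(mate pairs linking the two termini in wrap-around orientation) or when
its ends carry terminal direct/inverted repeats.  Integrated elements are
additionally checked for the short target-site duplication (TSD) a
transposition or integration event leaves on both flanks.

The circularity rule: among contigs of at least ``min_len``, collect
non-properly-paired reads whose mate lands in the opposite terminal
window (default 1000 bp); the contig is called circular when the coverage
depth of that evidence within the terminal windows exceeds 10% of the
mean contig coverage (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd

from .homology import revcomp
from .io import Contig


@dataclass
class CompletenessCall:
    contig_id: str
    status: str  # circular | terminal_repeat | linear
    repeat_kind: str = "none"  # inverted | direct | none
    repeat_coords: Optional[Tuple[Tuple[int, int], Tuple[int, int]]] = None
    support_pairs: int = 0
    support_depth: float = 0.0
    mean_coverage: float = 0.0
    tsd: Optional[str] = None
    reason: str = ""


def mean_coverage(contig_length: int, alignments: pd.DataFrame) -> float:
    """Mean read depth: total aligned bases / contig length."""
    if contig_length <= 0:
        raise ValueError("zero-length contig")
    if len(alignments) == 0:
        return 0.0
    return float((alignments["end"] - alignments["start"]).sum()) / contig_length


def _window_overlap(starts, ends, lo, hi):
    """Aligned bases of each record falling inside [lo, hi)."""
    import numpy as np

    s = np.maximum(starts, lo)
    e = np.minimum(ends, hi)
    return np.maximum(e - s, 0)


def detect_circular(
    contig_id: str,
    contig_length: int,
    alignments: pd.DataFrame,
    window: int = 1000,
    depth_frac: float = 0.10,
    min_len: int = 10000,
) -> CompletenessCall:
    """Circularity from end-linking discordant mate pairs.

    Evidence reads are non-proper pairs with the read in one terminal
    window and its mate in the opposite one.  Their coverage depth over
    the two windows (aligned bases / 2*window) must exceed
    ``depth_frac`` x mean contig coverage -- strictly -- for a circular
    call.  Wrap-around orientation (forward read at the right end, its
    reverse mate at the left end) distinguishes a circular genome from
    same-orientation terminal-repeat artifacts.
    """
    aln = alignments[alignments["contig_id"] == contig_id]
    mc = mean_coverage(contig_length, aln) if contig_length > 0 else 0.0
    if contig_length < min_len:
        return CompletenessCall(
            contig_id, "linear", mean_coverage=mc,
            reason=f"below min_len {min_len}",
        )
    if len(aln) == 0:
        return CompletenessCall(contig_id, "linear", mean_coverage=0.0, reason="no reads")
    left_lo, left_hi = 0, window
    right_lo, right_hi = contig_length - window, contig_length

    cand = aln[(~aln["proper_pair"].astype(bool)) & (aln["mate_contig_id"] == contig_id)]
    if len(cand) == 0:
        return CompletenessCall(contig_id, "linear", mean_coverage=mc,
                                reason="no end-linking pairs")
    in_left = (cand["start"] >= left_lo) & (cand["start"] < left_hi)
    in_right = (cand["end"] > right_lo) & (cand["end"] <= right_hi)
    mate_left = (cand["mate_start"] >= left_lo) & (cand["mate_start"] < left_hi)
    mate_right = (cand["mate_start"] >= right_lo) & (cand["mate_start"] < right_hi)
    linking = (in_left & mate_right) | (in_right & mate_left)
    ev = cand[linking]
    if len(ev) == 0:
        return CompletenessCall(contig_id, "linear", mean_coverage=mc,
                                reason="no end-linking pairs")
    bases = (
        _window_overlap(ev["start"].to_numpy(), ev["end"].to_numpy(), left_lo, left_hi)
        + _window_overlap(ev["start"].to_numpy(), ev["end"].to_numpy(), right_lo, right_hi)
    ).sum()
    support_depth = float(bases) / (2.0 * window)
    n_pairs = ev["read_id"].nunique()
    if support_depth > depth_frac * mc:
        # orientation: wrap-around means the right-end read is on '+' with
        # its mate at the left end, or the left-end read is on '-'
        right_fwd = ev[(ev["end"] > right_lo) & (ev["strand"] == "+")]
        left_rev = ev[(ev["start"] < left_hi) & (ev["strand"] == "-")]
        wrap_like = len(right_fwd) + len(left_rev)
        status = "circular" if wrap_like >= max(1, len(ev) // 2) else "terminal_repeat"
        kind = "none" if status == "circular" else "direct"
        return CompletenessCall(
            contig_id, status, repeat_kind=kind,
            support_pairs=int(n_pairs), support_depth=support_depth,
            mean_coverage=mc,
        )
    return CompletenessCall(
        contig_id, "linear", support_pairs=int(n_pairs),
        support_depth=support_depth, mean_coverage=mc,
        reason="end-linking depth at or below threshold",
    )


def detect_terminal_repeats(
    contig: Contig,
    min_len: int = 20,
    min_identity: float = 95.0,
    max_scan: int = 2000,
) -> CompletenessCall:
    """Terminal direct/inverted repeats by sequence self-comparison.

    Compares the first T bp against the last T bp (direct) and against
    the reverse complement of the last T bp (inverted), T = min(max_scan,
    length // 2).  Reports the longest terminal repeat of at least
    ``min_len`` bp at >= ``min_identity`` % matches, preferring inverted
    on ties.
    """
    L = contig.length
    if L < 2 * min_len:
        return CompletenessCall(contig.id, "linear", reason="too short for repeats")
    T = min(max_scan, L // 2)
    head = contig.seq[:T]
    tail = contig.seq[L - T :]

    def longest_direct() -> int:
        # a direct repeat pairs seq[i] with seq[L-k+i]: the alignment
        # depends on k, so scan k downward and accept the first length
        # whose shifted comparison meets the identity bar
        import numpy as np

        arr = np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
        for k in range(T, min_len - 1, -1):
            ident = float((arr[:k] == arr[L - k :]).mean())
            if ident * 100.0 >= min_identity:
                return k
        return 0

    def longest(a: str, b: str, anchor_run: int = 10) -> int:
        # anchored at the termini: longest k with identity >= min_identity
        # that also ends in >= anchor_run consecutive matches, so the
        # reported end is never padded out by chance matches in the
        # identity budget
        best = 0
        mism = 0
        run = 0
        for k in range(1, len(a) + 1):
            if a[k - 1] != b[k - 1]:
                mism += 1
                run = 0
            else:
                run += 1
            if (
                k >= min_len
                and (k - mism) * 100.0 >= min_identity * k
                and run >= min(anchor_run, k)
            ):
                best = k
        return best

    # the inverted pairing seq[i] <-> revcomp(seq)[i] is k-independent, so a
    # single anchored scan suffices; the direct pairing is k-dependent
    inv = longest(head, revcomp(tail))
    direct = longest_direct()
    if inv == 0 and direct == 0:
        return CompletenessCall(contig.id, "linear", reason="no terminal repeat")
    if inv >= direct:
        k, kind = inv, "inverted"
    else:
        k, kind = direct, "direct"
    return CompletenessCall(
        contig.id,
        "terminal_repeat",
        repeat_kind=kind,
        repeat_coords=((0, k), (L - k, L)),
    )


def detect_tsd(
    host: Contig,
    insertion: Tuple[int, int],
    len_range: Tuple[int, int] = (5, 7),
) -> Optional[str]:
    """Target-site duplication flanking an insertion, exact match only.

    Tries the largest k in ``len_range`` first and returns the duplicated
    motif host[start-k:start] == host[end:end+k], or None.
    """
    start, end = insertion
    lo, hi = len_range
    if start - hi < 0 or end + hi > host.length:
        raise ValueError("insertion too close to contig edge")
    for k in range(hi, lo - 1, -1):
        left = host.seq[start - k : start]
        right = host.seq[end : end + k]
        if left == right:
            return left
    return None


def call_completeness(
    contig: Contig,
    alignments: pd.DataFrame,
    window: int = 1000,
    depth_frac: float = 0.10,
    min_len: int = 10000,
    repeat_min_len: int = 20,
    repeat_min_identity: float = 95.0,
) -> CompletenessCall:
    """Combined call: circular (read evidence) wins over terminal repeats
    (sequence evidence); otherwise linear."""
    circ = detect_circular(
        contig.id, contig.length, alignments,
        window=window, depth_frac=depth_frac, min_len=min_len,
    )
    rep = detect_terminal_repeats(
        contig, min_len=repeat_min_len, min_identity=repeat_min_identity
    )
    if circ.status == "circular":
        return circ
    if rep.status == "terminal_repeat":
        rep.support_pairs = circ.support_pairs
        rep.support_depth = circ.support_depth
        rep.mean_coverage = circ.mean_coverage
        return rep
    if circ.status == "terminal_repeat":
        return circ
    circ.reason = circ.reason or rep.reason
    return circ


def completeness_table(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        coords = c.repeat_coords
        rows.append(
            dict(
                contig_id=c.contig_id,
                status=c.status,
                repeat_kind=c.repeat_kind,
                repeat_left_start=coords[0][0] if coords else -1,
                repeat_left_end=coords[0][1] if coords else -1,
                repeat_right_start=coords[1][0] if coords else -1,
                repeat_right_end=coords[1][1] if coords else -1,
                support_pairs=c.support_pairs,
                support_depth=round(c.support_depth, 4),
                mean_coverage=round(c.mean_coverage, 4),
                tsd=c.tsd or "",
                reason=c.reason,
            )
        )
    return pd.DataFrame(rows)
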