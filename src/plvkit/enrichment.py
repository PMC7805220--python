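"""Size-fraction read recruitment and enrichment statistics.

Recruitment is measured as coverage depth normalized by metagenome size
(coverage per Gb), so abundances are comparable across metagenomes of
different sizes.  Fold enrichment is the ratio of normalized coverage in
the virus-size fraction over the microbial fraction; genomes recruiting
reads only from the viral fraction are flagged ``viral_only`` and are
excluded from median-fold summaries (they cannot be ranked) but counted
separately.

"Reads recruited" is computed from aligned bases (depth) by default; a
read-count mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class EnrichmentProfile:
    contig_id: str
    cov_per_gb_viral: float
    cov_per_gb_microbial: float
    fold_enrichment: Optional[float]  # None when viral_only or undetected
    viral_only: bool
    viral_read_share: Optional[float]
    recruited_mb_per_gb_viral: float
    recruited_mb_per_gb_microbial: float
    defined: bool  # False when no reads in either fraction


def aligned_bases(contig_id: str, alignments: pd.DataFrame) -> float:
    sub = alignments[alignments["contig_id"] == contig_id]
    if len(sub) == 0:
        return 0.0
    return float((sub["end"] - sub["start"]).sum())


def normalized_coverage(
    contig_id: str,
    contig_length: int,
    alignments: pd.DataFrame,
    metagenome_gb: float,
    mode: str = "depth",
) -> float:
    """Coverage per Gb: (aligned bases / contig length) / metagenome size.

    ``mode='reads'`` uses read counts per contig kb instead of depth."""
    if metagenome_gb <= 0:
        raise ValueError("metagenome size must be positive")
    if contig_length <= 0:
        raise ValueError("contig length must be positive")
    sub = alignments[alignments["contig_id"] == contig_id]
    if len(sub) == 0:
        return 0.0
    if mode == "depth":
        depth = float((sub["end"] - sub["start"]).sum()) / contig_length
    elif mode == "reads":
        depth = len(sub) / (contig_length / 1000.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return depth / metagenome_gb


def fold_enrichment(
    contig_id: str,
    contig_length: int,
    viral_alignments: pd.DataFrame,
    microbial_alignments: pd.DataFrame,
    viral_gb: float,
    microbial_gb: float,
    mode: str = "depth",
) -> EnrichmentProfile:
    """Per-genome enrichment profile across the two size fractions."""
    cov_v = normalized_coverage(contig_id, contig_length, viral_alignments, viral_gb, mode)
    cov_m = normalized_coverage(contig_id, contig_length, microbial_alignments, microbial_gb, mode)
    mb_v = aligned_bases(contig_id, viral_alignments) / 1e6 / viral_gb
    mb_m = aligned_bases(contig_id, microbial_alignments) / 1e6 / microbial_gb
    if cov_v == 0.0 and cov_m == 0.0:
        return EnrichmentProfile(
            contig_id, 0.0, 0.0, None, False, None, 0.0, 0.0, defined=False
        )
    if cov_m == 0.0:
        return EnrichmentProfile(
            contig_id, cov_v, 0.0, None, True, 1.0, mb_v, 0.0, defined=True
        )
    return EnrichmentProfile(
        contig_id,
        cov_v,
        cov_m,
        cov_v / cov_m,
        False,
        cov_v / (cov_v + cov_m),
        mb_v,
        mb_m,
        defined=True,
    )


def summarize_population(
    profiles: Sequence[EnrichmentProfile],
    share_threshold: float = 0.95,
) -> dict:
    """Median/range of defined folds, viral-only counts, share statistics."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    folds = [p.fold_enrichment for p in profiles if p.fold_enrichment is not None]
    shares = [p.viral_read_share for p in profiles if p.viral_read_share is not None]
    n_detected = sum(1 for p in profiles if p.defined)
    out = {
        "n_genomes": len(profiles),
        "n_detected": n_detected,
        "n_viral_only": sum(1 for p in profiles if p.viral_only),
        "n_undetected": sum(1 for p in profiles if not p.defined),
        "median_fold": float(np.median(folds)) if folds else None,
        "min_fold": float(np.min(folds)) if folds else None,
        "max_fold": float(np.max(folds)) if folds else None,
        "pct_share_ge_threshold": (
            100.0 * sum(1 for s in shares if s >= share_threshold) / len(shares)
            if shares
            else None
        ),
        "share_threshold": share_threshold,
    }
    return out


def group_recruitment(
    member_ids: Sequence[str],
    alignments: pd.DataFrame,
    metagenome_gb: float,
) -> float:
    """Group-level recruitment in Mb of aligned bases per Gb of metagenome."""
    if not member_ids:
        raise ValueError("group is empty")
    if metagenome_gb <= 0:
        raise ValueError("metagenome size must be positive")
    sub = alignments[alignments["contig_id"].isin(set(member_ids))]
    if len(sub) == 0:
        return 0.0
    return float((sub["end"] - sub["start"]).sum()) / 1e6 / metagenome_gb


def enrichment_table(profiles: Sequence[EnrichmentProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                contig_id=p.contig_id,
                cov_per_gb_viral=p.cov_per_gb_viral,
                cov_per_gb_microbial=p.cov_per_gb_microbial,
                fold_enrichment=p.fold_enrichment if p.fold_enrichment is not None else "",
                viral_only=p.viral_only,
                viral_read_share=p.viral_read_share if p.viral_read_share is not None else "",
                recruited_mb_per_gb_viral=p.recruited_mb_per_gb_viral,
                recruited_mb_per_gb_microbial=p.recruited_mb_per_gb_microbial,
                defined=p.defined,
            )
            for p in profiles
        ]
    )
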