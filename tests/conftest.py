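"""Shared fixtures: planted communities and independent scoring oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from plvkit import pipeline
from plvkit.homology import DEFAULT_SCHEME, encode_peptide
from plvkit.synth import CommunitySpec, build_community


def brute_local_score(q: str, s: str, scheme=DEFAULT_SCHEME) -> float:
    """Exhaustive local-alignment score oracle.

    Enumerates every local alignment as a pair of equal-length strictly
    increasing index subsequences of query and subject (gaps between
    consecutive aligned pairs are grouped, which is optimal under affine
    costs), scores them all, and returns the maximum (or 0).  Independent
    of the dynamic-programming implementation it checks.
    """
    qe, se = encode_peptide(q), encode_peptide(s)
    n, m = len(qe), len(se)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = scheme.matrix
    best = 0.0
    for k in range(1, min(n, m) + 1):
        qc = np.array(list(combinations(range(n), k)))
        sc = np.array(list(combinations(range(m), k)))
        sub = M[qe[qc][:, None, :], se[sc][None, :, :]].sum(-1)
        if k > 1:
            gq = np.diff(qc, axis=1) - 1
            gs = np.diff(sc, axis=1) - 1
            costq = np.where(gq > 0, go + ge * gq, 0.0).sum(-1)
            costs = np.where(gs > 0, go + ge * gs, 0.0).sum(-1)
            sub = sub - costq[:, None] - costs[None, :]
        best = max(best, float(sub.max()))
    return max(best, 0.0)


def hypergeom_tail_oracle(k: int, universe: int, n1: int, n2: int) -> float:
    """Exact upper-tail P(X >= k) by direct summation of the pmf."""
    import math

    total = 0.0
    denom = math.comb(universe, n2)
    for i in range(k, min(n1, n2) + 1):
        total += math.comb(n1, i) * math.comb(universe - n1, n2 - i) / denom
    return total


@pytest.fixture(scope="session")
def oracle_score():
    return brute_local_score


@pytest.fixture(scope="session")
def hypergeom_oracle():
    return hypergeom_tail_oracle


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted community: 8 groups x 5 PLVs, 5 virophages,
    20 background contigs, 3 integrations, divergence 0.3, seed 42."""
    return build_community(CommunitySpec())


@pytest.fixture(scope="session")
def default_expansion(default_bundle):
    """Full iterative detection on the default community (shared: slow)."""
    return pipeline.run_detection(default_bundle)


@pytest.fixture(scope="session")
def grouping_bundle():
    """Low cross-group-sharing community for gene-sharing-network recovery:
    intra-group PC overlap high, inter-group overlap <= a few percent."""
    spec = CommunitySpec(
        n_groups=8,
        genomes_per_group=4,
        n_virophages=0,
        n_background=0,
        n_integrations=0,
        cross_group_core=False,
        shared_accessory_prob=0.05,
        seed=42,
    )
    return build_community(spec)


@pytest.fixture(scope="session")
def grouping_pcs(grouping_bundle):
    from plvkit import network

    proteins = [(g.gene_id, g.peptide) for g in grouping_bundle.genes if g.peptide]
    return network.cluster_proteins(proteins, e_cutoff=1e-4)
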