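# Methods

This note documents the models and procedures implemented in `plvkit`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic benchmarks show.

## 1. Similarity search and statistics

**Pairwise alignment.** Protein similarity uses Smith–Waterman local
alignment with affine gaps on BLOSUM62. A gap of length *g* costs
`gap_open + g·gap_extend` (defaults 11 and 1, the common "11/1"
convention). `X` and `*` score 0 against every residue, so unknown
residues and translated stop codons are neutral. Raw scores are converted
to bits, `b = (λS − ln K)/ln 2`, and to expectation values,
`E = m·n·2^(−b)`, with the published gapped BLOSUM62 parameters
λ = 0.267, K = 0.041.

Three search-space conventions are used deliberately:

- `search_db` (query against a database) uses `n` = total database
  residues, as BLAST does;
- the classifier's incremental per-gene scans use the *pairwise* space
  (`n` = subject length). This keeps every hit decision independent of
  later database growth, which is what makes iterative bait expansion
  monotone (a confirmed contig can never become unconfirmed because the
  bait database grew);
- the all-vs-all network search uses `n` = total residues of the set:
  with `N` proteins there are ~`N²/2` chances for a spurious edge, and
  only the database-size correction keeps chance components rare.

**Determinism of coordinates.** When several alignments are co-optimal,
the reported end cell is the first maximum in row-major order (smallest
query end, then subject end) and the traceback prefers diagonal over up
over left. These rules exist purely so that scores *and* coordinates are
reproducible; they never change the optimal score, which is what the
exhaustive-enumeration oracle in the test-suite pins down (all peptide
pairs up to length 8, enumerated as pairs of increasing index
subsequences — an independent formulation, not a second DP).

**Profile models.** Remote-homology capsid confirmation uses a
position-specific log-odds model rather than a full Plan-7 HMM: per
column, residue probabilities are pseudocount-smoothed toward the
background, `p = (c + α·b)/(n + α)` with α = 1 by default, and scored in
half-bit units `2·log2(p/b)`, floored at −20. Columns with > 50 % gaps
are masked. The background defaults to uniform 1/20, which is exact for
the synthetic communities (uniform-composition peptides) and
configurable for real data. Profile-to-sequence search runs the same
affine local DP over the profile columns; E-values reuse λ and K
*uncalibrated* — adequate because profile E-values are used only as
ranked thresholds, and stated here so nobody mistakes them for
calibrated significance. The contract that matters, and that the tests
enforce, is sensitivity: families diverged enough that a single-sequence
query loses members are fully recovered by the profile built from the
remaining members at the same cutoff.

The calibration of that sensitivity check deserves a note: how diverged
a family must be before single-sequence search fails depends on the
random draw, so both the test and the acceptance script *scan* —
divergence rises (and family draws are re-sampled) until the
single-sequence query genuinely misses ≥ 1 member, and only then is the
profile required to recover everyone. The tuning is the point of the
check, not a knob fitted to it.

## 2. Classification

A contig is classified by three nested rules, all with inclusive
boundaries:

- **virophage**: ≥ 1 gene hits the virophage-type MCP database at
  E ≤ 1e−5.
- **putative PLV**: (1) ≥ 20 % of predicted genes hit the bait database
  at E ≤ 1e−5, (2) length within [10 000, 45 000] bp, (3) no virophage
  MCP. The 20 % criterion counts *distinct genes with ≥ 1 hit*, never hit
  multiplicity (multiplicity would double-count paralogs). A contig with
  zero genes is rejected outright, never divided by zero.
- **confirmed PLV**: putative, length within [10 000, 41 000] bp, and an
  MCP identified — by a hit to an MCP profile model (`mcp_method =
  profile`, standing in for structure-aware remote-homology annotation)
  or by a direct hit to an MCP confirmed earlier in the expansion
  (`mcp_method = blast`). A putative contig with mCP and ATPase but no
  detectable MCP is carried forward with `fallback_core = True` and is
  *never* confirmed.

**Iterative bait expansion.** Detection starts from a seed bait database
(reference virophage genes). Detected virophages contribute their genes
before the first PLV pass; thereafter each iteration searches, flags,
confirms, and appends the genes of newly confirmed contigs — *between*
full passes, so the fixed point is independent of contig processing
order. The loop stops when an iteration confirms nothing new (or at
`max_iterations`, with a warning and partial results). Per-gene scan
state is cached and resumed over the growing database, so each
gene–bait pair is aligned at most once.

**Dereplication.** Genomes are clustered greedily, longest first, each
joining the first representative it matches. Identity is computed with
edlib (infix alignment of the shorter sequence into the representative):
`(len_short − editdist)/len_long` for global mode, or
`(len_short − editdist)/len_short` with a minimum coverage
`len_short/len_long` for local mode. Rotation awareness doubles the
representative so circular permutations match exactly. The default is
two rounds — local 0.9 identity at ≥ 0.2 coverage of the longer, then
global 0.7 — with membership transitive across rounds. This is an
edit-distance approximation of megablast-based identity; on the
synthetic data (substitutions only) the two coincide.

## 3. Completeness

**Circularity.** For contigs ≥ `min_len` (10 kb), evidence reads are
non-properly-paired reads with one mate in `[0, 1000)` and the other in
`[L−1000, L)`. The call is circular when the evidence coverage depth in
the two windows (aligned bases / 2000) strictly exceeds
`0.10 ×` mean contig coverage and the pair orientation is wrap-around
(forward read at the right end, reverse mate at the left). Both the
evidence depth and the mean coverage scale linearly in read count, so
the decision is invariant to duplicating the alignment stream — asserted
as a metamorphic test. The "evidence depth" reading (aligned bases of
end-linking mates over the total window length) was one of two plausible
interpretations of depth-based circularity support; it is the
mechanically checkable one and is stated here as this package's
definition, not as anyone else's intent.

**Terminal repeats.** The first `T = min(2000, L/2)` bases are compared
against the last `T`. For *inverted* repeats the pairing
`seq[i] ↔ revcomp(seq)[i]` is independent of the repeat length, so one
anchored scan reports the longest prefix with ≥ 95 % identity **that
ends in ≥ 10 consecutive matches**. The anchor-run condition matters:
without it, a 95 % identity budget lets the reported repeat drift ~15 bp
past the true end of an exact repeat on random flanks, and planted
coordinates would never be recovered exactly. For *direct* repeats the
pairing depends on the length, so lengths are scanned downward and the
first length whose shifted comparison meets the identity bar is
reported. Inverted wins ties. The generator, symmetrically, plants
*maximal* repeats (the first interior base never extends the repeat by
chance), so "exact coordinates" is a well-posed requirement.

**Target-site duplications.** TSD detection is exact string equality of
`host[start−k:start]` and `host[end:end+k]`, trying k = 7, 6, 5 in that
order; 5–7 bp is too short for fuzzy matching to mean anything. The
generator re-draws integration sites whose TSD would be accidentally
extendable, keeping planted k recoverable exactly.

When both read evidence and sequence repeats fire, circular wins: a
genome with a terminal repeat *and* wrap-oriented pairs is reported
circular.

## 4. Enrichment

Recruitment is aligned bases by default (a read-count mode exists):
normalized coverage is `(aligned bases / contig length) / metagenome Gb`,
so jointly scaling a fraction's reads and its size leaves every per-Gb
statistic exactly fixed (tested as an exact, not approximate, identity).
Fold enrichment is the ratio of normalized coverages; genomes with zero
microbial signal are `viral_only` — reported and counted but excluded
from median folds, since an infinite fold cannot be ranked. The
"share ≥ 95 %" statistic uses normalized recruitment, chosen for
cross-metagenome comparability. Group recruitment is additive Mb of
aligned bases per Gb.

The planted fold in the truth table is expressed on the same normalized
scale (copy ratio × metagenome-size ratio), because that is the quantity
the estimator can recover; the raw copy ratio is also recorded.

## 5. Synthetic community

The generator emulates the study system, not generic metagenomes:

- **Genomes.** Each of `n_groups` (8) PLV groups has its own random MCP
  ancestor (300 aa); mCP (170 aa) and ATPase (160 aa) ancestors are
  shared community-wide by default (`cross_group_core`), which is what
  lets PLVs hit a virophage-gene bait database at all. Each genome
  carries the three core genes plus 5–20 accessory genes drawn from a
  shared pool (30 families) and a group-private pool (10 families),
  with at least two shared-pool families per PLV ("shares several genes
  with virophages" is the premise of bait detection). Virophages carry
  the virophage-type MCP family. Genome lengths are uniform in
  10–41 kb; genes are placed with random spacers and strands, peptides
  reverse-translated with random codons.
- **Divergence.** `mcp_divergence` is defined as the expected *pairwise*
  substitution fraction within a family; each member is therefore
  mutated from the ancestor at half that rate. At the default 0.3,
  realized pairwise MCP identity is 70 ± 5 %.
- **Topologies.** Genomes are circular, plain linear, or linear with
  terminal inverted repeats (default tir_length 250 bp) in a 40/30/30
  mix. Integrated elements are PLV genomes wrapped in TIRs, inserted
  into the interior of large (48–70 kb) host contigs behind a duplicated
  5–7 bp target-site motif; excision (element + one TSD copy) restores
  the host exactly.
- **Reads.** Each fraction gets `depth·L/(2·150)` fragments per contig,
  with depth = copies × `depth_per_copy` (0.25× per copy). Inserts are
  normal (350 ± 50, clipped to [300, 800]). Circular contigs place
  fragments across the origin; a fragment whose *individual read* would
  straddle the junction is snapped so the junction falls between the
  mates (a mapper would clip such reads), preserving the expected wrap
  fraction ≈ insert/length. Truth alignments are emitted directly in the
  pipeline's TSV dialect — no mapper needed; FASTQ export (Phred+33,
  constant quality, substitution errors at `error_rate`) supports
  end-to-end runs with a real mapper.
- **Abundances.** Virus genomes get `viral_copies` = 100 (25× depth) in
  the viral fraction and a per-genome fold enrichment drawn log-uniform
  from [1, 2816]; background contigs are microbial-skewed (2 vs 100
  copies), emulating cellular material that mostly stays above the
  0.2 µm filter.
- **References.** The generator also emits the "already known" side of
  the analysis: reference virophage gene sets (the seed bait), reference
  MCPs per group (the profile library inputs, pre-aligned because the
  mutation model is substitution-only), and mCP/ATPase references for
  the core-gene fallback.

**What it does not emulate** — and hence what passing tests do *not*
show about real data: assembly fragmentation and chimerism, indels and
real error profiles, composition bias (uniform random residues/bases),
paralogy within genomes, mapping ambiguity (truth alignments are
unambiguous, so no mapping-quality filtering is exercised), contaminant
taxa, and abundance dynamics. Thresholds shown to be exact here (20 %,
10/41/45 kb, 10 % depth) still carry their real-world sensitivity to
gene-calling and assembly quality.

## 6. Gene-sharing network

Protein clusters are connected components of the all-vs-all similarity
graph at E ≤ 1e−4 (a stricter 1e−9 variant only refines, never merges —
a tested property). PC identifiers are assigned by descending size and
then lexicographic first member, so ids are stable under input
permutation. Genome edges weigh shared PC content by the exact
hypergeometric upper tail, `w = −log10 P(X ≥ k)` with
`X ~ Hypergeom(N, |g1|, |g2|)` over the N-PC universe (computed by
`scipy.stats.hypergeom.sf` and cross-checked against direct summation to
1e−9 relative; weights beyond double precision are capped at 300).
Virus clusters are connected components at weight ≥ 1.0 (p ≤ 0.1) by
default; components of size ≥ 3 are VCs, size 2 pairs; genomes that
share PCs but never pass the threshold are outliers, genomes sharing no
PC are singletons. Components-with-threshold is a deliberate,
deterministic simplification of density-based virus clustering; it
recovers planted groups exactly when inter-group PC sharing is low
(≤ ~5 %), which is the regime the grouping benchmark generates
(per-group cores, minimal shared accessory pool). With community-wide
shared cores every genome pair shares ≥ 2 PCs and no component
threshold can separate groups — a real limitation of the simplification,
which is why the grouping analysis uses the low-sharing community.

MCP-based grouping simply labels each genome by the PC of its MCP gene
(`unassigned` when no MCP was identified).

## 7. Host linkage

Transcripts are translated in all six frames and aligned against the MCP
database; the best hit per transcript is kept when E ≤ 1e−10 *and* the
alignment covers ≥ 200 aa — the length rule dominates, so a short
perfect fragment is rejected. "Over 200 aa" is implemented as ≥ 200
(configurable); a one-residue boundary is biologically immaterial but
must be pinned for tests. Aligned length (alignment columns) is used
rather than subject coverage. The ORF caller reports maximal
start-to-stop ORFs (first ATG after the previous in-frame stop) on both
strands, coordinates on the forward axis, longest first.

## 8. Problem sizes and determinism

The default community (68 contigs, ~1000 genes, ~350 k read placements)
is sized so the full detection loop, the network analysis and the whole
test-suite run in a few minutes on one CPU; the grouping benchmark uses
8 × 4 genomes. All stochastic tests run at fixed seeds; the acceptance
script derives every random stream from its `--seed` argument and is
deterministic given it. Every generator output is a pure function of its
spec (one seed, one byte stream), which the suite asserts by hashing
emitted directories.

## 9. Known limitations

- Profile E-values are uncalibrated (§1); treat them as ranks.
- The megablast-style identity of dereplication is approximated by edit
  distance; for real genomes with large indels the two diverge.
- Virus-cluster recovery by thresholded components degrades when groups
  share core genes (§6).
- The classifier consumes predicted genes; it does not call genes on
  assemblies itself (the ORF caller in the host-linkage module is a
  stand-in suitable for transcripts, not a genome gene finder).
- HMM–HMM / structure-level remote homology is out of scope; the profile
  stage approximates its role in MCP confirmation.
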