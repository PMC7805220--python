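# plvkit

Discovery and characterization of **Polinton-like viruses (PLVs)** and
**virophages** in size-fractionated aquatic metagenomes.

PLVs are small (10–41 kb) dsDNA viruses of unicellular eukaryotes related
to Polinton transposons and virophages (*Lavidaviridae*). Because their
genes rarely resemble anything in reference databases, they are found not
by annotation but by *gene sharing*: a contig that shares a substantial
fraction of its genes with known virophages, falls in the right size
range, and carries a double jelly-roll major capsid protein (MCP) is a
PLV candidate. `plvkit` implements that decision procedure end to end as
a tested library, together with everything needed to exercise it without
any external data: a synthetic community generator that plants genomes,
integrated elements and size-fractionated reads with known ground truth.

The package is aimed at viromics researchers who want a transparent,
deterministic re-implementation of this detection logic — to study its
behavior, calibrate thresholds, or run it on their own assemblies — and
at methods developers who need planted-truth benchmarks for capsid-bait
detection pipelines.

## What is implemented

- **Homology engine** (`plvkit.homology`): Smith–Waterman local alignment
  with affine gaps (gap of length *g* costs 11 + *g*), BLOSUM62, and
  Karlin–Altschul statistics `E = K·m·n·e^(−λS)` with the published
  gapped parameters λ = 0.267, K = 0.041; position-specific log-odds
  profile models (half-bit scores `2·log2(p/b)`, pseudocount-smoothed,
  gappy columns masked) for remote-homology capsid searches; six-frame
  translation.
- **Classification** (`plvkit.classify`): a contig is a *putative PLV*
  when (1) ≥ 20 % of its predicted genes hit the virophage/PLV bait
  database at E ≤ 1e−5, (2) its length is within [10, 45] kb, and
  (3) no virophage-type MCP is present; it is *confirmed* when it is
  additionally within [10, 41] kb and an MCP is identified (profile hit
  or direct hit to an already-confirmed MCP). Contigs with mCP + ATPase
  but no MCP are carried forward as putative (`fallback_core`). Detection
  expands iteratively: genes of confirmed contigs join the bait database
  until a fixed point. Greedy, rotation-aware dereplication (edlib
  edit-distance identity against a doubled representative) removes
  redundant genomes.
- **Completeness** (`plvkit.completeness`): a contig ≥ 10 kb is
  *circular* when discordant mate pairs link its two terminal 1-kb
  windows in wrap-around orientation and their coverage depth in those
  windows exceeds 10 % of the mean contig coverage (strict); terminal
  inverted/direct repeats come from anchored sequence self-comparison;
  target-site duplications (5–7 bp, exact) are checked at integration
  flanks.
- **Enrichment** (`plvkit.enrichment`): per-genome normalized coverage
  (depth per Gb of metagenome), viral/microbial fold enrichment, the
  share of recruitment from the viral fraction, and group-level Mb Gb⁻¹.
- **Gene-sharing network** (`plvkit.network`): protein clusters (PCs) as
  connected components of the all-vs-all similarity graph; genome edges
  weighted by `−log10 P(X ≥ k)` with `X ~ Hypergeom(N, |g1|, |g2|)` over
  the PC universe; thresholded components give virus clusters (VCs) with
  pair/outlier/singleton classes; genomes group by their MCP's PC.
- **Host linkage** (`plvkit.hosts`): six-frame translated search of
  transcriptome contigs against MCP databases (E < 1e−10, ≥ 200 aa), plus
  a simple maximal-ORF caller.
- **Synthetic community** (`plvkit.synth`): planted PLV groups with
  group-specific MCP families at configurable divergence, virophages,
  background contigs, integrated elements with TIRs and 5–7 bp TSDs,
  circular genomes, and paired 2×150 bp read placements from two size
  fractions with per-genome fold enrichment. One seed determines every
  output byte.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
planted community (seed 42):

```sh
python analysis/01_simulate_community.py     # writes results/community/
python analysis/02_detect_viruses.py
python analysis/03_genome_completeness.py
python analysis/04_fraction_enrichment.py
python analysis/05_gene_sharing_network.py
python analysis/06_host_linkage.py
```

Output of the detection and completeness stages:

```
classification written to results/classification.tsv
  labels: {'confirmed_PLV': 40, 'rejected': 23, 'virophage': 5}
  bait expansion converged in 2 iterations
  confirmed-PLV precision=1.000 recall=1.000 (40 called / 40 planted)
  virophage precision=1.000 recall=1.000
completeness written to results/completeness.tsv
  circular recall=1.000 (11 planted), false-circular on linear=0.000
  TIR genomes recalled: 1.000 of 17
  TSDs recovered exactly: 3/3
```

All 40 planted PLVs are confirmed with no false positives (the 23
rejected contigs are the planted background and the > 45 kb host contigs
carrying integrated elements); every circular genome is recognized from
its wrap-around mate pairs, and every planted terminal repeat and
target-site duplication is recovered at exact coordinates. Enrichment
and network stages report, for the same run:

```
  median fold = 24.2 (range 0.80-2074)
  55.6% of genomes recruit >=95% of normalized reads from the viral fraction
  planted folds recovered within factor 2: 17/17 (genomes with >=100 pairs in both fractions)
397 proteins -> 130 protein clusters (ARI vs planted families: 1.000)
32 genomes -> 8 virus clusters (ARI vs planted groups: 1.000)
```

The same stages are available as a CLI (`plvkit simulate|detect|complete|
enrich|net|hosts|report`) with a YAML config; see `plvkit --help`.

## Documentation

`docs/methods.md` describes the model and procedure, all tunable
parameters with units and defaults, what the synthetic generator does and
does not emulate, and the numerical conventions (tie-breaking, score
floors, boundary semantics).
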