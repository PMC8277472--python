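# Methods

## Scope and model

`hgtscreen` implements a multi-evidence inference for horizontal gene
transfer (HGT) into animal genomes. No single line of evidence is decisive:
a strong similarity to non-metazoan sequences can come from a genuine
ancient transfer or from contaminating DNA co-assembled with the host
genome. The pipeline therefore joins five independent analyses per gene and
reports them side by side rather than collapsing them prematurely.

### Weighted HGT index

The index contrasts the best similarity score against non-metazoan
subjects with the best against metazoan subjects. Design choices:

* **Coverage weighting.** Raw bit scores are multiplied by
  `min(1, aln_length / query_length)`. Bit scores grow roughly linearly in
  alignment length, so a short fragment with high per-column score can
  otherwise outrank a full-length homologue; the weight makes group maxima
  comparable at equal coverage. The weighting function is pluggable
  (`weight_fn`) for users who prefer, e.g., a coverage power.
* **Threshold.** Default 30 bits, the customary cutoff for
  bit-score-difference alien indices; configurable. At 30 bits the implied
  likelihood-ratio margin is ~2^30, conservative for full-length proteins.
* **Lineage exclusion.** Hits whose taxon is marked excluded (the query's
  own lineage and its sister groups) are removed before taking maxima, so
  the index dates transfers relative to that split. In the synthetic data
  the transferred genes are shared with the excluded sister lineage:
  without exclusion their index drops to ~9 bits and they would be missed —
  this is tested behaviour, not an accident.
* **Empty groups** contribute a maximum of 0 rather than ±infinity, keeping
  h finite and comparable; a gene with no usable hit at all has undefined h
  and verdict `ambiguous`.
* **Paralogy check.** A family of candidates passes when every member's
  best non-self within-genome bit score among the family strictly exceeds
  its best cross-species score (ties fail, deliberately strict).

### Contamination screen

Two hard criteria — multi-exon gene structure (prokaryotic donors lack
spliceosomal introns) and a < 80% nucleotide-identity ceiling to
non-metazoan homologues (near-identity indicates recent material, i.e.
contamination, not an ancient transfer) — and two supporting ones:

* **Depth.** Ratio of scaffold mean depth to the length-weighted median
  over all scaffolds must lie in [0.5, 2.0]. The length-weighted median is
  robust to many short aberrant contigs; the fence width is configurable
  for haploid/diploid coverage peaks.
* **Synteny.** Up to 5 genes on each side of the candidate are mapped
  through reciprocal-best-hit pairs; the gene passes if ≥ 2 partners lie on
  one reference scaffold within a window of the same size around each other.
  Strict collinearity is *not* required — conserved neighbourhoods survive
  local rearrangement — and a single-gene contig can never pass (no
  neighbours).
* **Aggregation.** Failing a hard criterion ⇒ `suspect_contaminant`; both
  hard criteria plus a quorum (default 1) of available supporting criteria ⇒
  `intrinsic`; otherwise `insufficient_evidence`. The quorum default
  acknowledges that some assemblies lack either a depth table or a usable
  reference (transcriptome-only species have neither).
* The identity ceiling considers only hits with `aln_length ≥ 100` bp;
  shorter nucleotide hits are uninformative about gene-level identity.

### 4DTv

Scored codon columns require (i) no gap in either codon, (ii) identical
first two bases across the pair, and (iii) that prefix fourfold-degenerate
(CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN). This is the conservative
convention that guarantees third-position changes are synonymous; columns
violating any condition are excluded from the denominator. Gaps are legal
only in whole-codon units — alignments with frame-breaking gaps are
rejected at construction because 4DTv is undefined across frameshifts.
The raw proportion is reported without model-based correction. `n_sites = 0`
yields an explicitly undefined value, distinct from 0.

One-to-one orthologues are reciprocal best hits with a strict tie rule: a
tie for either top score disqualifies the gene. The background confidence
interval is the empirical [α/2, 1−α/2] percentile interval (default
α = 0.05) over defined background values; a normal-approximation interval
is available but not the default, as 4DTv distributions are bounded and
often skewed.

### Indel signatures

Only gap-state (presence/absence) signatures are scanned; residue-identity
signatures would need a substitution model and are out of scope. A column
is diagnostic when the focal-clade state reaches prevalence ≥ `p_in`
(default 0.9) inside and ≤ `p_out` (default 0.1) outside; maximal
same-kind runs of ≥ `min_width` (default 2) columns become blocks. The
tolerance `p_out > 0` allows partial presence in near outgroups. A block's
reported `prevalence_in` is the *minimum* over its columns (and
`prevalence_out` the maximum), so the block invariants are re-checkable
post hoc. A candidate row carries a block only when it shows the clade
state at every column of the (short) block, and is a clade member when it
carries ≥ 80% of blocks by count.

### Enrichment

Fisher's exact test, two-sided by the point-probability criterion, with
the sample odds ratio (a·d)/(b·c) (+∞ when b·c = 0 with a·d > 0; the 0/0
case is NaN). The implementation delegates the p-value to
`scipy.stats.fisher_exact`; the test suite verifies it against an
independent full hypergeometric enumeration. The default gene universe in
the pipeline is every gene not screened out as a suspect contaminant —
contaminants are not part of the host gene complement, so including them
would distort both margins. A chi-squared variant exists for very large
tables.

## Synthetic data: what it emulates, and what it does not

The generator plants a complete ground truth (default: 100 native, 20
transferred, 30 contaminant genes; all parameters in `SimulationConfig`):

* **Bit scores** are linear in alignment length and divergence,
  `B = max(0, L·(s₀ − slope·d) + ε)`, ε ~ Normal(0, 5 bits), with s₀ = 2
  bits/column and slope 1 bit/column per substitution/site. This is the
  simplest model reproducing the monotone similarity structure the index
  assumes. Native genes are closest to metazoans (d = 0.1), transferred
  and contaminant genes to a donor clade (d = 0.15 and d ≈ 0.012
  respectively); transferred genes are also close to the excluded sister
  lineage (shared transfer). Percent identity decays exponentially with
  divergence (rate 0.75 for protein, 2.5 for nucleotide — nucleotide
  identity saturates faster, which is what makes the 80% ceiling separate
  ancient transfers from contaminants).
* **Codon pairs** evolve under a discrete two-parameter (Kimura-type)
  process applied only at third positions of fourfold codons, calibrated so
  expected substitutions/site equals the requested divergence with
  transition:transversion ratio κ (default 2). First two codon positions
  never change, so amino acids are fixed and 4DTv is cleanly neutral. The
  saturation limit of the transversion-difference probability is ½.
* **Contaminants** are single-exon by construction (prokaryote-derived
  sequences lack introns), ≥ 97% nucleotide identity to the donor, on
  dedicated contigs whose depth is drawn at 5× the host mean (300× vs 60×,
  sd 30 vs 6) — far outside the [0.5, 2] fence.
* **Gene order**: host genes sit 10 per scaffold; a synteny reference
  mirrors the native gene order (transferred genes absent, as expected for
  a lineage-specific acquisition — they pass synteny through their anchored
  neighbours). A close sister strain provides orthologues of every host
  gene at nucleotide divergence 0.2 for the 4DTv background.
* **DE flags** are Bernoulli with p = 0.5 for transferred and p = 0.3 for
  native genes — a population odds ratio of ≈ 2.33, the effect-size regime
  the method is meant to detect; contaminants are never expressed.
* All randomness flows through numpy's PCG64 `default_rng` keyed by
  `(seed, stream)` pairs, one stream per generator, so outputs are
  byte-identical across runs and platforms.

Not emulated: read-level data (no FASTQ), indels within CDS pairs
(gap-free by construction), amino-acid substitution processes, GC/k-mer
composition signals, assembly chimerism, and divergence-dependent hit
drop-out beyond a hard detectability cut. Passing tests therefore
demonstrate the *logic* of the inference under its own assumptions — clean
margins, correctly labelled taxa — not robustness to misassembly,
annotation error or database mislabelling in real data.

## Numerical and engineering choices

* Coordinates are 0-based half-open internally, converted at GFF3
  boundaries; round-tripping is the identity (tested).
* Taxon mapping is exact-match first, then longest-prefix, so per-sequence
  entries override accession-prefix entries.
* The screen and the scan are deterministic and order-independent in their
  inputs; reports are written with fixed float formatting (`%.6g`) and
  sorted keys so identical runs are byte-identical.
* Genes with several transcripts use the longest coding transcript.
* Degenerate inputs fail loudly: ragged alignments, non-binary DE flags,
  duplicate ids, unresolvable subjects, zero median depth and frame-breaking
  gaps all raise typed errors with file/line context where applicable.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
deliberately modest sizes — 150-gene genomes (1,250 for the enrichment
cohort), 500-pair 4DTv backgrounds over 10–20 seeds, 2,000 permutation
replicates — chosen so the full suite completes in well under a minute
while keeping every calibration band (CI coverage 95% ± 3%, type-I error
0.05 ± 0.02, 4DTv saturation 0.5 ± 0.02) statistically meaningful at those
sizes.

## Known limitations

* The index threshold (30 bits) and the screen fences are conventions, not
  fitted quantities; on real data they should be examined against the
  genome-wide h distribution and coverage histogram.
* Synteny anchoring needs a reasonably complete reference gene order;
  fragmented references inflate `insufficient_evidence`.
* The enrichment test answers association, not causation; its universe
  choice (all credible genes vs expressed genes) materially changes the
  margins and is exposed as an option.
* 4DTv without correction compresses at high divergence; the CI membership
  test is meaningful only for closely related pairs, which is its intended
  use (strain-level orthology confirmation).
* Candidate rows for the signature scan must be pre-aligned into the
  reference alignment coordinate system; profile alignment is out of scope.
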