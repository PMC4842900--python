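# popscan — methods

popscan re-implements, as a reusable library, the analysis path used to
study natural bacterial populations through metagenome-assembled genomes
(MAGs): recruit metagenomic reads to a population-bin genome, summarize the
population's presence in a sample (ANI, breadth, depth, abundance), and
test which reference genes are absent from the in-situ population using a
coverage-based skew-normal null. A synthetic-community generator with full
ground truth makes the whole path testable without sequencing data.

## The synthetic community model

The generator produces four linked objects:

1. **Reference genome** — a single contig of i.i.d. nucleotides with a
   configurable GC fraction (default 0.5). Genes are placed uniformly at
   random without overlap (longest first; 100 attempts per gene, then an
   explicit failure — never silent truncation). Gene lengths follow a Beta
   distribution rescaled to `(min, max)` with its mean pinned to the
   requested mean (concentration 4), default (200, 1200, 700) bp. The
   non-overlap placement model cannot reach the gene density of real
   bacterial genomes (~88%); defaults keep density near 55%, which is
   irrelevant to the statistics being tested but worth knowing. Each gene
   carries a broad functional label (regulation, carbohydrate/amino-acid/
   nutrient transport and metabolism, hypothetical) so absence calls can be
   summarized by category.
2. **In-situ population** — the reference with (a) independent per-base
   substitutions at rate `1 − ANI/100` (substituted base always differs)
   and (b) a chosen set of genes excised outright. Deletion is excision,
   not masking: the population genuinely lacks the sequence, and the
   manifest records each junction position so read truth can flag
   junction-spanning reads.
3. **Reads** — single-end, uniform start positions, equiprobable strands,
   independent substitution errors (default 1%). The read count is Poisson
   with mean `depth × genome / read_length` (Lander–Waterman). The default
   250 bp read models merged 2×150 bp pairs; merged reads behave as single
   alignments downstream, which is why a single-end model suffices. The
   200 bp floor of the abundance-counting preset is only satisfiable with
   merged-scale reads.
4. **Background** — a share of reads (default 30%) drawn from an unrelated
   random genome. Real off-target communities contain *relatives* of the
   target at 70–85% identity; an i.i.d. background shares nothing
   alignable, so it exercises the reject path but not the low-identity
   histogram. Tests that need a low-identity peak build one explicitly by
   diverging a second population at 80% ANI.

Everything is a pure function of (inputs, `rng_seed`); sub-generators
derive fixed offsets from the one seed, and fixtures round-trip through
FASTA/FASTQ/BED/TSV byte-identically.

What the generator deliberately does **not** model: indels (substitution-
only keeps identity arithmetic exact and the recruiter's ungapped model
lossless), platform-specific error profiles, paired-end insert sizes,
strain mixtures beyond one population plus one background, and repeats.
Passing tests therefore demonstrate correctness of the statistics under
the stated model, not robustness to gapped alignment or repeat-rich
genomes — gapped alignments can still be ingested from standard 12-column
tables produced by external search tools.

## Read recruitment

The recruiter is an exact ungapped seed-and-extend search: 16 bp exact
k-mer seeds (sorted-array index) propose diagonals on both strands, and
each diagonal is scored by its maximum-scoring contiguous segment under
+1/−1 (computed exactly; equal to the Smith–Waterman optimum whenever the
optimum is ungapped, with the same stop-at-zero tie-breaking). A full
Smith–Waterman with linear gap penalties is implemented alongside as the
testing oracle.

Two reporting semantics coexist, on purpose:

- **Reads** are mapped: the best-scoring diagonal places the read, and the
  emitted record covers the read's full extent on that diagonal (clipped at
  contig ends), end mismatches included. Local end-trimming would inflate
  per-read identity (≈ +0.1 identity point at 150 bp and 4% divergence),
  biasing genome-derived ANI; full-extent reporting makes read-set ANI an
  unbiased estimator of population divergence and makes coverage
  accounting exact. With `best_hit_only` (default) a multi-mapping read
  contributes coverage exactly once; ties break to the lexicographically
  smallest subject, then smallest start.
- **Contigs** (`augment_bins`) keep the local segment: an unbinned contig
  joins a bin when it *shares a block* of ≥ 2 kbp at ≥ 99.7% identity, and
  diluting that block over the whole contig would be wrong.

Seeding with exact 16-mers cannot miss a read whose substitutions leave one
clean 16 bp window; at the divergences the analysis targets (≤ 5%,
typically ≤ 1%) the miss probability is negligible for ≥ 100 bp reads.

Filter presets carry the published cutoffs: plot retention ≥ 70 bp &
≥ 60% identity; abundance counting ≥ 200 bp & ≥ 98%; cross-site abundance
≥ 90 bp & ≥ 98%; re-assembly read selection ≥ 100 bp & ≥ 98%. All filter
comparisons are inclusive (≥).

Internal coordinates are 0-based half-open; the tabular dialect's 1-based
inclusive coordinates, with subject start > end encoding the reverse
strand, are converted only at the I/O boundary.

## Coverage profiles and population summaries

A recruitment profile holds per-base depth split at 95% identity (the
boundary between a sequence-discrete population and lower-identity
relatives), the identity histogram of recruited base-positions per 1% bin,
mean coverage per consecutive 500 bp segment (final partial segments kept
at their true length), and a 1 kbp-windowed display track. Conservation is
exact on every input: summed depth over both classes equals summed
alignment length, because each record deposits exactly `alignment_length`
bases from its subject start.

- **ANI** — length-weighted mean identity of records passing ≥ 70 bp &
  ≥ 60% (length-weighting makes each aligned base count equally; an
  unweighted per-record mean is available). Zero qualifying records raise
  an explicit no-recruitment error instead of returning 0.
- **Breadth and depth** use the high-identity class only, so diverged
  relatives cannot satisfy "genome representation" on behalf of the target
  population. This identity floor is a design choice, configurable.
- **Detection gates** — ANI > 95 and breadth > 0.90 strictly; depth ≥ 3
  inclusively (the depth bound is approximate in origin). The refusal
  reason names the first failing gate.
- **Relative abundance** — reads recruited under the abundance preset
  divided by total metagenome reads.
- **Sequence-discreteness** — the fraction of recruited base-positions at
  ≥ 95% identity, flagged discrete when ≥ 0.8 *and* the histogram mass in
  [90, 95) is less than half the mass in [95, 100] (a valley check).

## The gene-absence test

Null hypothesis: the gene is present in the in-situ population, so its
coverage is exchangeable with the rest of the genome. The genome is tiled
into 500 bp segments; a skew-normal density
`f(x) = (2/ω) φ((x−ξ)/ω) Φ(α(x−ξ)/ω)` is fit to segment mean depths by
maximum likelihood (scipy), initialized by method of moments with sample
skewness clamped to 99% of the attainable skew-normal bound; the fit is
deterministic and refuses < 50 or constant values. The skew normal, unlike
the normal, absorbs the right-skew that uneven recruitment produces.

Per gene: mean high-identity coverage over the gene body → left-tail
`raw_p = F(coverage)` under the fitted null → length adjustment
`p = raw_p^(L/500)` because 500 bp segments are treated as independent
tests (longer genes must be low-covered over more independent segments, so
they are assessed more stringently; genes shorter than 500 bp get an
exponent < 1, which *raises* their p — the formula's literal behavior) →
Benjamini–Hochberg across the candidate family → absent when the adjusted
p falls below α = 0.025.

Design choices that the procedure's verbal description leaves open:

- **Candidate gate.** The test targets genes of "zero or near-zero"
  coverage. Taken without a gate, the length exponent would flag long genes
  of ordinary coverage (raw_p ≈ 0.5 becomes 0.5^10 ≈ 10⁻³ for a 5 kbp
  gene). Default: only genes with mean coverage below
  `min(1.0, 0.25 × median segment coverage)` enter the test; non-candidates
  carry p = 1 and stay out of the FDR family. Configurable.
- **FDR family** — candidate genes of one (bin × metagenome) comparison,
  matching per-comparison reporting.
- **Zero segments** are included when fitting the null (configurable).
  With deletions at the few-percent scale this leaves P(X ≤ 0) under the
  fitted null around 10⁻³–10⁻², small enough for full power on ≥ 500 bp
  deletions; excluding them sharpens the null when contamination is heavy.
- **Coverage class** — the test uses high-identity (≥ 95%) coverage only,
  so a diverged relative recruiting across the deletion cannot mask it.
- The test refuses to run (naming the gate) when the population fails the
  detection gates: absence calls are only meaningful for a population that
  is actually present at ~3x or more.

Calibration and power under the study conditions (500 kbp, 400 genes, 5x,
1% error) are checked end-to-end in the test suite: planted deletions
≥ 500 bp are recovered with sensitivity ≥ 0.95 and ≤ 2 false calls, and
with nothing deleted the absent-call fraction stays within α across seeded
replicates. `scripts/acceptance.py` recomputes both.

## Pipeline

`run_pipeline` chains simulate → recruit → profile → absence → report from
a sectioned `key = value` config (unknown keys rejected), writes every
intermediate artifact plus plot-ready report series (windowed coverage by
identity class, per-read position × identity points, identity histogram),
and records a manifest with the config hash, seed, package version, every
threshold in effect, and stage timings. Identical configs reproduce
byte-identical artifacts; the manifest's config hash excludes the output
location. A stage failure halts the run naming the stage.

## Numerical notes and problem sizes

- Percent identity is stored at 2-decimal precision (the tabular format's
  own precision), so table round-trips are lossless.
- The identity histogram bins by floor(identity); bin 100 holds exact
  matches.
- BH adjustment is the standard step-up (`q(i) = min_{j≥i} m·p(j)/j`,
  capped at 1, input order restored); it is cross-checked in tests against
  the brute-force definition and statsmodels.
- The Smith–Waterman row recurrence resolves the in-row gap dependency
  with a running-maximum transform, so each row is vectorized; the oracle
  comfortably handles the ≤ 80 bp × ≤ 2 kbp validation pairs.
- Simulations in the test suite and acceptance script use 100–500 kbp
  genomes and 10⁴–2.5×10⁴ reads — large enough for the binomial and
  Lander–Waterman expectations they are checked against to have small
  relative error, while one full run of everything stays in minutes.

## Known limitations

- Substitution-only alignment: indel-bearing reads must come in through
  external alignment tables; the internal aligner will place them but may
  split them across diagonals.
- The single-background model understates the low-identity recruitment a
  real soil metagenome produces; the 60% identity retention floor and the
  95% class split are exercised with an explicit diverged relative instead.
- ANI from recruited reads conflates population divergence with sequencing
  error (as any read-recruitment ANI does); with the default 1% error the
  reported ANI sits ≈ 1 point below the genomic ANI.
- A population at exactly the 3x depth gate may fall on either side of it
  after sampling noise; gate boundaries are exact, sampling is not.
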