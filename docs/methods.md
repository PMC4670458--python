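# Methods

## Canonical site model

A mature miRNA's seed is its nucleotides 2–8 (1-based). Matching is done on
the UTR strand (mRNA sense, DNA alphabet) read 5'→3'. With `core6` the
reverse complement of miRNA positions 2–7 and `m8` the complement of
position 8, the three canonical site types are the strings `m8·core6·A`
(8mer), `m8·core6` (7mer-m8) and `core6·A` (7mer-A1). The `A` opposite
miRNA position 1 must be a literal adenosine in the target regardless of
the miRNA's first nucleotide. Only these three canonical types are
predicted: no 6mers, no 3'-supplementary or non-canonical pairing, no
conservation filtering and no context scoring. Scope is deliberate — the
canonical set is fully specifiable and is what the site-density statistic
consumes.

Each UTR position is classified with priority 8mer > 7mer-m8 > 7mer-A1,
and overlaps for one miRNA are resolved greedily left to right: once a
site is accepted the scan resumes at its end. This makes the per-UTR count
deterministic and prevents one locus contributing twice. An 8mer whose
final `A` falls outside the scanned region degrades to a 7mer-m8, exactly
as it would if the region were a free-standing sequence. Coordinates are
0-based half-open; IUPAC ambiguity codes never match; inputs are
normalised (miRNAs to ACGU, UTRs to ACGT) before matching.

Site density is `1000 · count / UTR length` (sites per kilobase).

### Window counting for the null

The resampling null evaluates millions of windows, so it uses a
precomputed index of pattern-occurrence positions per background UTR
(`SiteCandidateIndex`) instead of re-scanning each extracted window.
Counting walks the candidate positions inside the window and reproduces
the scanner's classification and greedy rule; a property test asserts
exact agreement with `find_sites` on the extracted substring, including
the window-edge cases.

## Differential expression

Per gene, with two groups of log2 intensities (A = reference, B =
contrast): `log2fc = mean(B) − mean(A)`, linear fold change `2^log2fc`
(geometric, i.e. computed from log-scale means — raw-scale means are not
used), a two-sided pooled-variance Student's t test (Welch available as an
option), and Benjamini–Hochberg step-up adjustment across all genes. BH is
the adjustment used because the screening context is a standard array
experiment; it is an explicit option, not hard-wired. A gene is called
up if fold change > 2.0 (strictly) and p < 0.05 (strictly), down
symmetrically at fold change < 0.5; the thresholds are parameters. A gene
at exactly the fold-change cutoff is non-DE. Degenerate rows in which both
groups are constant return p = 1.0 when the means agree (p = 0.0
otherwise) so that pipelines stay total instead of propagating NaN.

The qPCR utility implements global-mean ΔCt normalisation: for each
sample, a target miRNA's Ct minus the mean Ct of all assayed miRNAs in
that sample, centred across samples and negated, so one PCR cycle equals
one log2 unit. A generic Pearson r² helper supports level-versus-age
correlation analyses.

## Enrichment test

For gene set S (n UTRs, lengths L1..Ln), miRNA m, background pool = the
UTRs of genes called non-DE:

* **M_obs** — median over S of the per-UTR site density; the median of an
  even-length list is the mean of the two central values.
* **Null** — B replicates (default 1000). Per replicate, for each Li: a
  background UTR of length ≥ Li is chosen uniformly among those eligible,
  a start position is chosen uniformly, the contiguous window of exactly
  Li nt is extracted and its site density recorded; the replicate keeps
  the median of the n window densities. Windows (rather than whole
  background UTRs) are the default because they honour "regions of
  matching length" literally; a whole-UTR mode (uniform choice among the
  k = 25 background UTRs nearest in length, whole-UTR density substituted)
  is available behind a flag for sensitivity analysis.
* **Empirical p** — `p_left = #{null < M_obs}/B`,
  `p_right = #{null > M_obs}/B`, strict inequalities, no pseudocount. Ties
  count toward neither side (a mid-p option assigns them half weight).
  Both sides are always reported; the caller decides which side a given
  panel interprets. Note the consequence probed by the acceptance suite:
  an observed median beyond the entire null yields exactly p = 0.

### RNG protocol

Each (miRNA × set) cell gets its own `numpy` generator seeded by a
SeedSequence over (master seed, CRC32 of the miRNA name, CRC32 of the set
label), so adding a miRNA or a set never perturbs other cells. Within a
cell the generator is consumed gene by gene in set order: first the B
background-UTR draws (`integers(0, n_eligible, size=B)`, indexing the
background sorted by (length, id)), then the B start draws
(`integers(0, length − Li + 1)` elementwise). The protocol is fixed and
documented so an independent re-simulation can replay it; results are
bit-reproducible from the master seed.

### Length fallback

If some Li exceeds every background UTR length the default is an error.
The `longest` fallback substitutes the whole-UTR density of the longest
background UTR for that gene (drawing no random numbers, so other genes'
streams stay aligned). The fallback exists because a uniformly drawn gene
set can legitimately contain the pool's longest UTR — as happens in the
calibration simulations — while a curated background can simply be
extended instead.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

* **True calls** — each gene is up / down / non-DE with configured
  fractions (defaults 0.10 / 0.05 of 2000 genes).
* **UTR lengths** — log-normal, median 1000 nt, log-sd 0.6, truncated
  below at 50 nt; `sigma = 0` gives constant lengths. These defaults give
  the realistic right-skewed spread of mammalian 3'UTR annotations at a
  scale (10³–10⁴ genes) that exercises the statistic.
* **Sequence background** — i.i.d. nucleotides at GC fraction 0.42. Every
  spontaneous canonical match for any panel miRNA is then scrubbed (one
  base of the offending window redrawn until clean), so planted sites are
  the *only* sites and the emitted truth table is exactly recoverable by
  re-scanning — the generator's own acceptance test. The cost is a
  background composition that is not perfectly i.i.d. in the scrubbed
  windows; at the spontaneous match rate of roughly 0.1–0.2 windows/kb
  this perturbation is negligible for the statistic under study.
* **Site planting** — per (gene, miRNA), the planted count is Poisson with
  mean `density · ratio · (L − 7)/1000`, i.e. a homogeneous rate over the
  L − 7 valid start positions; `ratio` is the per-miRNA enrichment factor
  for the gene's true call (1.0 = no effect). Planted sites are 8mers at
  uniform non-overlapping positions; an insertion is redrawn (up to 100
  times, then an error) if it would overlap an existing site or create any
  unintended canonical match near the junctions. Two modelling points
  matter for calibration and were chosen deliberately: the rate scales
  with L − 7 rather than L, and sites exclude only their own footprint
  (adjacent sites are allowed). Either a per-length rate mismatch or a
  wider keep-out makes whole-UTR site counts statistically different from
  the counts in length-matched windows cut from longer UTRs — measurably
  biasing the resampling test away from uniform p-values even though both
  effects are invisible at the level of mean counts. Poisson draws are
  truncated to a packing capacity of L // 16 sites per miRNA (unreachable
  at realistic densities).
* **Expression** — per-gene log2 baseline ~ Uniform(4, 12); true up/down
  genes offset by ± planted log2fc (default 2.0) in the contrast group;
  i.i.d. Gaussian noise, sd 0.2, per cell; 3 replicates per group. These
  defaults reproduce the design point of a 3-vs-3 array screen with a
  fold-change-4 planted effect.
* **Scenario** — the default two-miRNA dataset plants miR-181a sites
  enriched (ratio 3.0) in true-up genes and depleted (0.2) in true-down
  genes, and miR-34a the opposite, with the expression layer sharing the
  same truth calls; the panel uses the real mature sequences of
  rno-miR-34a-5p and rno-miR-181a-5p.

What passing tests on these data do **not** show: behaviour under real
UTR base composition (dinucleotide structure, repeats), 6mer/non-canonical
sites, conservation filtering, heteroscedastic or correlated array noise,
or annotation errors. The generator is a statistical emulator, not a
genome.

## Numerical and design choices

* Ties in the empirical p are excluded by construction (strict
  inequalities); with a near-degenerate null (e.g. constant-length pools,
  where the discrete null medians collapse to one value) both one-sided
  p-values approach 0 and the test is uninformative — length spread in the
  pool is what makes the null continuous enough to calibrate.
* Background sorted by (length, id) before sampling, making eligibility a
  contiguous suffix and the draw protocol well defined.
* The model surface (`TargetEnrichment.fit() → TargetEnrichmentResults`)
  follows the estimator/results convention; the pipeline stages
  (simulation, DE selection, site scanning) are plain functions since
  nothing in them is fitted.
* Problem sizes in the test and acceptance simulations (pools of
  1200–2000 genes, 100–200 trials or runs, B = 500–1000) were chosen as
  the smallest sizes at which the binomial tolerance bands of the
  statistical checks are meaningful.
* Empty gene sets, unresolvable gene ids, background/set overlap,
  missing expression values and group sizes < 2 are hard errors, raised
  with the offending identifier where applicable.

## Known limitations

* The scanner implements the canonical TargetScan-style site set only; it
  is not a reimplementation of any full prediction pipeline (no context
  scores, no conservation, no ORF/5'UTR sites).
* The null resamples windows independently across replicates from a
  finite background pool; with very small backgrounds the null medians
  are correlated across replicates and the empirical p loses resolution.
* Whole-UTR mode with `nearest_k` is a sensitivity tool; its k = 25 is a
  convention, not an inference.
* The DE module assumes pre-normalised log2 intensities; platform
  normalisation and moderated/paired statistics are out of scope.
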