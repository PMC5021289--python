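# Methods

This note documents the models, parameter choices and numerical
conventions behind `rdnaquant`, and what the synthetic experiments do and
do not demonstrate.

## Copy-number estimators

**Genome proportion (NGS).**  The estimator is the three-step chain
GP% = 100·mapped/total → GP(Mb) = GP%·G/100 → copies = GP(Mb)/L_ref.
Full precision is carried between steps; rounding is applied only when a
report is rendered (GP and GP(Mb) to two decimals, copies to the nearest
50).  This matters: the published-style value 1.93 Mb for a 480 Mb genome
is only reachable from the unrounded GP (0.40 rounded × 480 gives 1.92).
`L_ref` is a parameter, not a constant: ~0.003 Mb for a 26S gene, the
whole-unit length otherwise (0.0112 Mb for an 11.2 kb unit; synthetic
runs use the generated unit's exact length).

The estimator assumes reads sample the genome uniformly and that a read
maps if and only if it originates from the array.  Both assumptions are
exactly true in the simulator up to two documented distortions: reads
spanning the junction between adjacent copies are kept only if their
larger piece covers ≥ 80% of the read, and reads spanning the
array/background boundary behave likewise.  The resulting downward bias
is bounded by one read length per unit copy (read_len/unit_len ≈ 1.7% at
100 nt / 6 kb) and the acceptance tests compare against an analytic
enumeration of accepting start positions rather than the raw copy count.

**qPCR (ΔCt).**  copies/1C = 2^(ct_ref − ct_sample) · ref_copies ·
(1C_sample/1C_ref), with the calibrator defaulting to *A. thaliana*
(570 copies/1C, 157 Mb).  The default exponent sign follows amplification
physics — more template crosses threshold at a *lower* ct — because the
opposite, occasionally printed convention halves instead of doubling per
cycle; that printed convention remains available via
`printed_exponent=True`.  Replicate ct standard deviations propagate as
sd(copies) = copies·ln2·√(sd_s² + sd_r²).  Amplification efficiency
other than perfect doubling is out of scope.  The simulator's
`simulate_qpcr` is the exact inverse of the estimator at zero noise;
a property test verifies the round-trip to 1e−6 relative.

## Read QC

Trimming follows the two-sided running-sum (modified-Mott) rule: each
base contributes `limit − 10^(−Q/10)` with limit 0.05, and the kept
segment is the maximal-scoring contiguous stretch (computed as the
maximal-scoring substring; longest, then leftmost, on ties).  Reads
shorter than 90 nt after trimming, or still containing an N, are removed.
The choice of the substring formulation over two independent end scans is
a design decision; the two agree on all reads whose quality profile is
high–low only at the ends, which is what the two-valued simulator
produces.

## Mapping model

Alignment is semi-global against a single unit: match +1 (fixed — the
cost model names only penalties, and +1 is the convention of the
reference-mapping toolchain this parameterisation mirrors), mismatch 2,
insertion 3, deletion 3, both strands evaluated, read bases overhanging a
reference end soft-clipped at no cost.  A read is accepted when its
best-scoring alignment has aligned-read fraction ≥ 0.8 and similarity
(matches/alignment columns) ≥ 0.8.  Ties on score are broken by leftmost
reference start, then + strand, then smallest reference end; within a
path, traceback prefers substitution over insertion over deletion.
N and IUPAC ambiguity codes never match anything, including themselves.

Mapping against the single unit (not a doubled unit) is deliberate:
junction reads then probe the clipping semantics, and the induced GP bias
is the bounded quantity discussed above.

### Exact fast paths

`map_reads(mode="auto")` is engineered so that accept/reject decisions are
identical to the full dynamic program:

1. *Gapless candidates.*  Eight contiguous read parts are seeded by their
   leading 11-mers against a unit k-mer index.  If the best gapless
   (possibly end-clipped) candidate has penalty 3·mismatches + clipped
   bases ≤ ⌊0.2·L⌋, the read is accepted outright: any optimal alignment
   under the 2/3/3 costs then has at most ⌊0.2·L⌋ penalty, hence clip
   ≤ 0.2·L (length fraction holds) and at most ⌊0.2·L⌋/3 non-match
   columns over ≥ 0.8·L columns (similarity ≥ 11/12).  Enumeration is
   complete for ≤ 4 mismatches.  The emitted *placement* is the best
   enumerated gapless candidate; a hypothetical higher-scoring gapped
   alignment elsewhere would require a near-duplicated region inside the
   unit and would affect only the pileup position, never the decision.
2. *Infix-distance screen.*  Any read with an acceptable alignment has
   edlib HW (infix) edit distance to the unit ≤ 0.25·(L−C) + C maximised
   over clip C ≤ ⌊0.2·L⌋ (40 for L = 100); reads beyond the bound on both
   strands are rejected without a DP.  Random background sits at distance
   ≈ 0.42·L, so ~92% of background reads stop here.
3. *Score screen.*  Any acceptable alignment scores ≥ (4·sf − 3)·⌈lf·L⌉
   (16 for L = 100); survivors below that after a score-only DP are
   rejected; the rest get the full DP with traceback.

`mode="exact"` disables all three and runs the full DP per read; a test
asserts that both modes produce identical decisions *and* pileups on
mixed read sets, and the mapper is checked read-for-read against a
brute-force full-matrix DP oracle on 500 reads.

## Pileup, consensus, coverage

The pileup counts A/C/G/T/deletion per unit position; insertions are
keyed to the preceding reference position.  Coverage is the sum of all
five rows (a deleting read still covers the position).  Consensus takes
the majority base (alphabetical on ties), N at zero coverage, removes
positions where deletions hold a strict majority, and includes insertions
observed in a strict majority of covering reads.  Region coverage reports
each subregion's mean depth and its ratio to the median of the per-region
means; ratios > 10 are flagged as anomalies (the signature of
subregion-related sequences dispersed outside the array, as seen for
ITS2 in some mosses).

## Variant calling

Calls are threshold-based on the pileup: coverage ≥ 100, allele count
≥ 10, frequency = count/coverage ≥ 0.10 ("high-frequency" variants —
on the order of a hundred carriers in a ~thousand-copy family).  This
deterministic filter deliberately replaces the probabilistic caller of
the original toolchain: only threshold-filtered outputs are comparable,
and at ≥ 10% frequency the thresholds dominate any genotype-likelihood
model.  "Countable reads" are all accepted mapped reads covering the
position; no additional base-quality masking is applied.  Frequencies are
compared as count/coverage so exact-boundary alleles (20/200 at 10%)
pass.

Adjacent substitution calls whose frequencies agree pairwise within 0.05
merge into an MNV (count = min of members, frequency = that count over
the max coverage) — a pileup-level surrogate for read-backed phasing,
since per-read phase is not retained by default.  Runs break at
multi-allelic positions.  Multi-base deletions appear as one DEL call per
deleted position.  Indels are counted in a pooled "indel" category and
excluded from SNP-set tallies by default.  Between-sample heterogeneity
is reported as the fold difference in call totals, per kind and overall.

## Divergence

Assembled units are aligned globally (match +1, mismatch −2, gap −3 per
base, terminal gaps penalised; traceback prefers substitution, then gap
in the first sequence).  The p-distance counts mismatches over
*overlapping* columns only — columns with a base in both sequences; gaps
never count as differences, so inserting shared gap columns leaves p
unchanged.  Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) is defined
for p < 0.75 and errors at saturation.  Per-subregion distances take the
column's position in the first sequence of the pair — a deterministic
convention, since the pair's coordinate systems differ.  Pairwise (not
multiple) alignment is used throughout.

## Synthetic data

`build_rdna_genome` concatenates a uniformly random background with a
head-to-tail tandem array.  Each variant is applied to exactly
round(fraction × copies) copies, chosen as the first so-many entries of
an independent seed-shuffled copy order per variant, so realized carrier
fractions are exact.  `simulate_reads` draws unpaired reads with uniform
starts, i.i.d. substitution errors (never silent), N replacement at a
small rate (emitted at Q2), and two-valued qualities; defaults
(read_len 100, error 0.5%, Q37/Q12, n_rate 0.001, forward-only) describe
an unpaired short-read archive of the study era.  Output is
byte-identical under a fixed seed.

What the simulator does *not* model: indel sequencing errors, GC and
coverage bias, quality-profile structure along the read, paired ends, and
real IGS/array substructure.  Passing tests therefore demonstrate the
correctness of the estimators and filters under their stated sampling
assumptions, not robustness to real-data artefacts.

## Experiment sizing in the tests

* Copy-number recovery: 6 kb unit, 150 kb background, 5/20/100 copies at
  50× depth; the assertion compares the estimate against the exact
  enumeration of accepting read-start positions within 3 binomial SE, and
  that enumeration against the true copy number within the junction-loss
  bound.
* Variant recovery: 1 kb unit × 20 copies, no background, nine SNVs at
  fractions {0.15, 0.3, 0.5}, 0.5% error, 100 replicates at ~800× unit
  pileup depth.  The depth honours the "≥ 300×" recovery condition with
  headroom chosen from the binomial arithmetic: at 300× the ±0.05
  frequency band is only ~1.7σ at fraction 0.5 and the 10% call threshold
  is ~2.8σ below fraction 0.15, so "always called, within band in ≥ 95%"
  is not a stable property at 300× and becomes one at ~800×.
* Heterogeneity ratio: two synthetic samples with 60 vs 20 variants at
  ~300× yield a 3-fold ratio within [2.5, 3.5].
* Mapper correctness: 500 mixed reads ≤ 80 nt against ≤ 600 nt units,
  checked score-for-score and decision-for-decision against a brute-force
  DP written independently in the test suite.

## Known limitations

* The mapper is exact but desk-scale: full-archive SRA runs (10⁷⁺ reads)
  would need hours, not minutes.  Heuristic indexing for that scale is an
  explicit non-goal.
* The gapless fast path's placement (not decision) assumes the unit
  contains no near-duplicate of itself; `mode="exact"` removes the
  assumption.
* MNV grouping is a frequency-concordance surrogate, not read-backed
  phasing.
* qPCR modelling stops at perfect doubling; efficiency calibration and
  degraded-template diagnostics are treated as upstream QC.
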