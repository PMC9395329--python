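# Methods

This note documents the models, estimators, and design choices behind
`dogbiome`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not show.

## The abundance estimator

### Unique best-hit mapping

Reads are assigned by ungapped, full-containment alignment against every
position of every SGB representative on both strands, scored by mismatch
count. A read is **unique** when exactly one (SGB, position, strand) attains
the minimum mismatch count within the budget; ties make it **ambiguous** and
it is discarded; reads whose best alignment exceeds the budget are
**unmapped**. Discarding ambiguous reads trades sensitivity for specificity:
window counts never receive reads that could belong to another catalog
genome.

The built-in mapper is seed-and-extend: non-overlapping exact k-mer seeds
(k = 31) taken along the read, candidate positions looked up in a hash index
of all catalog k-mers, and each candidate scored over the full read. The
mismatch budget is deliberately tied to the seed layout:

    budget = floor(read_length / k) − 1

By pigeonhole, any alignment with at most `budget` mismatches must contain
at least one error-free seed, so the candidate set provably contains every
acceptable alignment and the heuristic returns *exactly* the assignments of
an exhaustive all-position scan (the test suite checks this equivalence on
thousands of random reads, including planted shared segments that force
ambiguity). For 100-bp reads the budget is 2 mismatches; at the default
0.5 % base error ~98.6 % of error-bearing reads still qualify, and the reads
lost to the budget are lost uniformly across genomes, which the relative
normalization cancels. SAM input from a full aligner (e.g. bowtie2) is
accepted as an alternative front end, with uniqueness decided on the best
alignment score (AS, falling back to −NM, then MAPQ).

### Windows, dense mean cover, and genome-size normalization

Each genome is tiled into fixed 1-kb windows (0-based, half-open; terminal
window possibly shorter; 1 kb is a package default, not a literature value —
the estimator's properties are checked at 500/1000/5000 bp). Unique reads are
tallied by leftmost base. Window counts become per-base densities
`count × read_length / window_length`, and the per-SGB cover is the
two-sided **trimmed mean** (default 25 % per side) of the sorted densities.
The trimmed mean estimates the coverage of the *densely covered core* of the
genome: it shrugs off both uncovered/deleted regions (bottom tail) and
repetitive or conserved hotspots (top tail). `trim_fraction = 0` recovers
the plain mean exactly. Because densities are per base, genome-size
normalization is built in; a config flag optionally divides again by total
genome length for users who prefer that convention (the two differ by a
per-SGB constant only).

Known small-sample behavior: for a low-abundance SGB whose windows hold
Poisson counts with mean ≲ 4, the integer-valued trimmed mean is biased
slightly low (a few percent) relative to the true mean density. This is
visible in the synthetic benchmark only for species within a factor of a few
of the detection cap and is dominated there by binomial sampling noise.

### Existence and relative abundance

An SGB is concluded to exist in a sample when (i) its cover is positive,
(ii) at least `min_reads = 10` unique reads support it, and (iii) at least
`min_nonzero_window_fraction = 5 %` of its windows are nonzero — criterion
(iii) rejects "abundance" manufactured by a single promiscuous region.
Both thresholds are package defaults declared in `ExistenceConfig`.
Relative abundance divides each existing SGB's cover by the summed covers of
existing SGBs (so the vector sums to 1 over existing SGBs), is invariant to
any global rescaling of covers, and is therefore also invariant in
expectation to sequencing depth.

### Detection cap

Abundances are capped at τ = 10⁻⁴ in one of two modes. **floor** (default)
raises every entry below τ — zeros included — to τ: all samples become
comparable on a log scale, at the cost of the vector no longer summing to 1
(recorded in the cap state). **zero** zeroes sub-τ entries and renormalizes
survivors, preserving the simplex. Richness is always computed against the
*pre-floor* abundances (p ≥ τ), since after flooring every species would
trivially count as present. Species columns of the assembled feature table
are floor-capped by default (`cap_species=False` disables), so downstream
statistics see the log-friendly representation.

## Read processing

Edge trimming scans inward from each end and stops at the first base whose
quality reaches the threshold — the simplest rule consistent with trimming
"low-quality read edges", with no sliding window. A read is dropped when it
contains any configured adapter substring, when its trimmed length falls
below `min_length_after_trim` (50 bp), or when its trimmed mean quality is
below `min_mean_quality` (20). These thresholds are package defaults exposed
in `QCConfig`; the filter is idempotent by construction.

The built-in host screen removes a read when ≥ 50 % of its strand-canonical
31-mers occur in the host genome's k-mer set. This is intentionally not a
full aligner: at desk scale it is exact enough (a clean 100-bp host read
shares 100 % of k-mers; one sequencing error still leaves ≥ 56 %), and an
external reads-vs-host SAM is accepted where bowtie-level sensitivity is
wanted. Consequence of the 50 % rule: host reads carrying ≥ 2 errors can
slip through (~9 % of host reads at 0.5 % base error). Escaped host reads
are random with respect to the catalog and end up unmapped, so they do not
bias abundances; the host-clearance test therefore uses a 0.1 % error
simulation where escape is < 2 %.

Subsampling is uniform without replacement, deterministic under its seed,
order-preserving, and defaults to 10⁷ reads; a shortfall keeps all reads and
warns rather than failing.

## Synthetic data: what it emulates, and what it does not

The generator is the package's ground-truth instrument, not a fixture.

* **Community truths.** True profiles are symmetric Dirichlet(α = 0.5)
  draws — a realistic steep rank-abundance curve whose tail dips below the
  10⁻⁴ cap. Per-dog profiles add N(0, σ = 1) noise to the cohort's mean
  log-profile and renormalize (softmax), giving log-normal-like spread.
* **Reads.** A read is host with probability `host_fraction` (default 0.1),
  junk with probability `junk_fraction` (0.05; half carry a fixed known
  33-mer adapter, half are uniformly low-quality), otherwise drawn from an
  SGB with probability ∝ abundance × genome length — so per-base coverage,
  which the estimator measures, is proportional to abundance. Bases flip
  independently at 0.5 %. Every read records its true origin; qualities of
  non-junk reads are constant (Q37).
* **Cohort.** Demographics follow a working-dog program's marginals
  (Malinois-dominant breeds, ~12 % puppies, ~11 % sterilized, ~10 % GI
  issues; BCS ≈ N(5, 0.6) on the 1–9 scale). The eight behavior scores
  discretize latent standard Gaussians at quintiles into 1–5. A planted
  effect shifts the affected SGBs' log-abundances by `effect_size` latent
  SDs in dogs at or above the trait's binarization threshold (default 3,
  matching the median rule for quintile scores), before renormalization.
  With no effects, abundances are independent of all metadata by
  construction.

Not emulated: realistic genome content (GC skew, repeats, shared gene
families between species), paired-end structure and insert sizes,
position-dependent quality, PCR duplicates, strain-level mixtures, and
compositional correlation structure beyond what softmax closure induces.
Passing the synthetic benchmark therefore shows the *estimator and
statistics are correct under their stated model*; it does not certify
performance on real stool sequencing, where inter-genome homology makes the
unique-mapping fraction, and hence effective depth, substantially lower.

Closure is worth a word: because profiles renormalize, a planted increase in
two species slightly depresses every other species in high-trait dogs. Rank
tests legitimately detect these induced associations; the association
example shows this, and it mirrors real compositional data.

## Statistics

Rank scans use two-sided Mann–Whitney (exact enumeration when both groups
≤ 8 and untied, otherwise the tie-corrected normal approximation with
continuity correction — verified within 0.02 of exhaustive enumeration) and
Kruskal–Wallis beyond two groups. Pearson p-values come from the t transform
with n−2 df. Demographic cross-tables use Fisher's exact test
(point-probability two-sided rule) for sparse 2×2 tables (any expected count
< 5) and the chi-squared test without continuity correction otherwise.

One scan — one phenotype against all features — is one multiple-testing
family; this is the least surprising family definition and is recorded on
every record. Both Bonferroni (level 0.15) and Benjamini–Hochberg FDR
(levels 0.15 and 0.05 in different figure-level uses) are implemented, and
the correction method is a required argument rather than a default, because
the two conventions coexist in this analysis style. Type-I control and power
are verified empirically: on 20 null cohorts (n = 100, 50 species) the mean
BH-significant fraction at 0.15 stays within budget and raw p-values are
KS-uniform; a 2-latent-SD effect on two species is detected in ≥ 80 % of
replicates.

## Prediction

Traits binarize at the rounded-up median score (⌈median⌉, so 1–5 scores with
median 2.5 split at 3), with explicit per-trait thresholds honored and
binary flags passed through; dogs under 1 year are excluded first, and an
emptied group is an error naming the trait and threshold. The classifier is
XGBoost with declared defaults (200 trees, depth 3, learning rate 0.1,
subsample 0.8 — conventional small-n settings, not tuned), evaluated in
stratified k-fold cross-validation; stratification is used because small
cohorts with skewed score distributions otherwise produce single-class
folds. Both k = 3 (AUC-oriented) and k = 5 (accuracy-oriented) are
first-class presets, since both protocols are standard in this analysis
style; per-fold ROC AUC (trapezoidal) and accuracy at 0.5 are reported with
mean and SD. Folds and booster are deterministic under the seed, and scores
are only ever produced for held-out folds.

## Numerical and procedural choices

* Shannon diversity uses natural log (nats).
* The Bacteroidetes phylum label is read verbatim from the taxonomy table,
  so both the "Bacteroidetes" and "Bacteroides" spellings work; a zero
  denominator makes F/B missing (NaN), never infinite.
* PCoA double-centers −½D², symmetrizes before `eigh`, reports the full
  eigenvalue spectrum in decreasing order, and drops negative-eigenvalue
  axes (coordinates scale eigenvectors by √λ). Axes are defined up to sign.
* The 13-column summary block is configurable via a manifest; the default is
  richness, Shannon, butyrate sum, acetate sum, F/B ratio, plus eight taxon
  aggregates filled from phylum then family labels in sorted order. The
  precise feature block of any given study is a reporting convention, so it
  is an input, not a constant.
* The pipeline manifest stores the config, seed, and SHA-256 of every
  artifact; reruns at the same config+seed are byte-identical (tested), and
  all TSVs are written with a fixed float format to keep this true.

## Problem sizes

The test and acceptance workloads are sized for a single CPU: the deep
recovery benchmark uses 30 SGBs × 50 kb and 200,000 × 100 bp reads (~1
minute), mapper/oracle equivalence uses thousands of reads on ≤ 2 kb
genomes, statistical suites use 10–20 replicates of n = 100–120 cohorts with
50 features, and the end-to-end determinism run uses 12 dogs × 2,000 reads.
These sizes were chosen so the full validation cycle stays in the minutes
range while every contract is exercised at meaningful statistical power.

## Known limitations

* The exact-match-seeded mapper has no gapped alignment; indels in reads
  (absent from the simulator) would be unmapped rather than softly penalized.
* The trimmed-mean cover's small-λ bias (above) slightly deflates species
  near the cap.
* The host screen's k-mer rule is error-sensitive as analyzed above; use the
  SAM mode with a real aligner for contamination-critical work.
* Association scans are univariate by design; confounder-adjusted
  multivariate modeling is out of scope at these cohort sizes.
* The synthetic cohort's demographic marginals are presets, not estimates of
  any particular population.
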