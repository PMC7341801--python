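# Methods notes

This note records the models, defaults, numerical choices and limitations
behind `svclade`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and formats

Variants are held as `SVRecord` (1-based inclusive coordinates; `svlen` is
the positive length magnitude) and genotypes as a variants × individuals
dosage matrix over {0, 1, 2, MISSING}. MISSING is first-class: it is never
imputed at ingest, because the clade filter's error accounting depends on
distinguishing dropout from discordance. Multi-allelic VCF records are
rejected (split upstream); the analyses are biallelic throughout. Breakend
and duplication records are outside the closed {INS, DEL, INV} type set
and are skipped with a tallied count — this also realises the removal of
translocation calls at ingest.

VCF dialect: the writer emits symbolic ALT alleles with `SVTYPE`, `SVLEN`
(negative for deletions), `END = POS + SVLEN` for DEL/INV, and the allele
sequence in an INFO `SEQ` key; the reader inverts this exactly and also
accepts sequence-resolved ALT/REF alleles. INS length comes from |SVLEN|
with the allele sequence as fallback; DEL/INV length from END − POS with
|SVLEN| as fallback — caller dialects disagree, so the precedence is
fixed. Half-calls ("./1") and "./." map to MISSING. BED output is 0-based
half-open.

## Synthetic cohort generator

The generator's defaults are the study conditions of the analyses:

- 8 diploids in clade A (two populations) and 24 in clade B (three
  populations), mirroring a small-outgroup / large-ingroup design.
- Class mix tandem 0.215 / LTR 0.236 / LINE-CR1 0.023 / no-match 0.526 —
  the composition of a long-read avian SV call set renormalised over the
  four modelled classes.
- Clade-private variants: minor-allele count drawn ∝ 1/i (the neutral
  folded spectrum) for interspersed and unannotated classes; the
  hypermutable tandem class draws its frequency from a symmetric
  Beta(2, 2), conditioned on segregating, to reproduce the shift toward
  intermediate frequencies.
- Lengths: log-normal backgrounds per class, with the LTR class drawn
  from a three-component Gaussian mixture at 0.9 / 2.4 / 6.5 kb
  (weights 0.45/0.35/0.20, sd 10% of the mean) — the characteristic
  full-length retrotransposon family peaks. Minimum length 51 bp.
- Cross-clade false positives (default rate 5%): genotyped at
  intermediate frequency (Beta(5, 5)) in *both* clades with an
  excess-heterozygosity floor of ⌈n/3⌉ heterozygotes per clade. This is
  the signature of the collapsed-paralog/hypermutable artifacts the
  clade filter targets, and it guarantees that with zero genotyping
  error every injected FP violates both clade screens — making exact
  truth-recovery a well-defined property rather than a probabilistic one.
  FP loci are placed preferentially (90%) within the outer 5% of a
  chromosome, emulating the enrichment of unreliable calls near
  repeat-dense chromosome ends.
- Genotyping error: each call independently flips with rate ε to one of
  the other two dosage states uniformly (no error model is implied by the
  analysis itself; this is the simplest symmetric choice). ε defaults to
  0 and is swept explicitly in tests.
- Missingness: per-call masking at `missing_rate`, default 0. The default
  emulates a force-genotyped consensus call set in which every variant is
  re-genotyped in every individual, so complete rows are the realistic
  baseline; missingness is exercised explicitly where it matters.

Randomness is one integer seed fanned out through `SeedSequence.spawn`
into named substreams (classes, origins, lengths, positions, genotypes,
errors, missing, repeats, support), so adding a stage never perturbs
another stage's draws and all outputs are byte-reproducible.

What the generator does **not** emulate: linkage and recombination
(variants are exchangeable draws, not a coalescent), population structure
within clades beyond labels (all members of a clade share one frequency
draw), reference bias, length-dependent genotyping difficulty, and
sequence-level read evidence. Passing tests therefore demonstrate the
correctness and calibration of the estimators and filters under their own
model assumptions — not performance on real alignments.

The default karyotype is a reduced avian-like table (12 chromosomes,
~725 Mb) including a microchromosome at ~1.4% of the genome so that
enrichment arithmetic has a realistic denominator.

## Consensus merging

Single-linkage clustering per chromosome (and per type when type matching
is on) with breakpoint distance |pos_i − pos_j| ≤ 1 kb, measured on start
coordinates only. Chaining is transitive, so a cluster can span more than
1 kb end to end — accepted deliberately to match the behaviour of the
standard merging tool. Both published parameter sets ship as presets:
`lr` = (1 kb, 1 caller, type match, min size 50 bp) and `sr` = (1 kb,
2 callers, type match, no size floor). The cluster representative is the
member whose length is closest to the cluster median (ties → leftmost
start, then id); the tool's own representative rule is undocumented, so
this is this package's fixed choice. Support/length filtering keeps
5 ≤ support ≤ 60 and length ≤ 100 kb (all bounds inclusive). Low-MQ
masking drops a call when its [pos, end] span shares ≥1 bp with a masked
interval; adjacency is not overlap; chromosomes absent from the track are
unmasked with a warning.

## Clade-exclusivity filter

The clade-A analysis screens the clade-B outgroup in `homref_outgroup`
mode with clade B's tolerance (default 4); the clade-B analysis screens
clade A in `fixed_outgroup` mode with clade A's tolerance (default 2).
Defaults scale with outgroup size (4 above 16 diploids, else 2) and are
overridable per clade. Decisions that were genuinely open:

- Missing outgroup calls are excluded from error counts (dropout is not
  discordance); a `count_missing_as_error` switch exposes the other
  reading.
- The majority-state tie in `fixed_outgroup` resolves to reference —
  deterministic and conservative.
- A variant retained for either clade enters the retained union; with
  ε > 0 the tolerances deliberately let a few variants appear in both
  clades, which the tests assert as a property rather than suppress.

Raising a tolerance can only grow the retained set (monotonicity, tested
as a property).

## Population-genetic summaries

- Folded AFS: per variant, minor count min(k, 2N′−k) over non-missing
  diploids; monomorphic variants contribute nothing, so spectrum mass
  equals the segregating count by construction.
- F_ST: the two-level variance-component estimator with unequal sample
  sizes; individuals with missing calls are dropped variant-wise (not
  list-wise) to maximise data use. θ̂ is kept as-is when negative and
  enters the percentile ranking; monomorphic variants are flagged
  undefined and excluded from outlier scans. Sample configurations with
  an average of ≤1 diploid per population leave the within-population
  mean square without degrees of freedom and are likewise flagged
  undefined. The implementation is cross-checked against an
  independently coded ANOVA mean-squares evaluation to 1e-10.
- Outliers: linear-interpolation quantile, strict `>` comparison.
- Window densities: 1-Mb tiling windows; with the non-overlapping
  convention, same-type records whose spans intersect collapse into one
  cluster before counting; a record/cluster belongs to the window
  containing its start. Both behaviours are exposed.
- PCA: per-variant mean imputation of MISSING, per-variant centring,
  eigendecomposition of the individual × individual covariance.
  Components are ordered by decreasing eigenvalue; the sign convention
  makes each component's largest-magnitude loading positive; coordinates
  are eigenvectors scaled by √eigenvalue.

## Repeat assignment

Best match per variant by overlap bp (equivalent to overlap fraction
within a variant), ties by higher score then lexicographic name — the tie
chain is fixed explicitly because only the primary criterion is standard.
Class taxonomy rolls simple/low-complexity/satellite/rRNA/tRNA/
macrosatellite into *tandem* and keeps LTR, LINE/CR1, SINE and DNA as
interspersed classes; superfamily prefixes take precedence over keyword
matches (SINE/tRNA is a SINE).

## LTR dating

t = k / (2 μ L) with μ defaulting to 0.0158 substitutions per site per
Myr. Difference counting: mismatched non-gap columns plus isolated 1-bp
gap events; gap runs ≥ 2 bp are excluded from both k and the effective L
(only single-base indels are treated as countable point events; the
treatment of longer gaps is otherwise undefined, and excluding them is
the conservative reading). The estimate is an upper bound — differences
still segregating in the population inflate k. Saturation is not
modelled; the paired-repeat simulator refuses parameter combinations
whose expected difference count exceeds L. Unaligned input pairs are
aligned globally (match 1, mismatch −1, gap open −4, extend −1) before
counting.

## Association

p in all information criteria counts every mean parameter, the intercept
and the residual variance — the convention must be fixed for ΔAICc values
to be reproducible, and this is the one used. ΔAICc = AICc(baseline) −
AICc(candidate), candidate selected iff ΔAICc ≥ 2; the BIC difference is
reported alongside and may point the other way (the comparison object
says whether the criteria agree). Fits being compared must share the
response subset (equal n; listwise deletion of individuals with missing
genotype or phenotype happens before fitting). The baseline design is
intercept-only plus the stated covariates; no additional covariates are
assumed.

## Pipeline

Stages hand off through plain VCF/TSV/YAML/JSON files so each stage is
independently runnable and inspectable; the manifest stores per-stage
record counts and relative output paths, and identical config + seed
gives byte-identical outputs. The pipeline's merge stage exercises the
consensus step by emitting jittered pseudo-caller replicates of the
simulated call set (Gaussian breakpoint jitter, per-record dropout);
real multi-caller inputs enter through the `merge` subcommand.

## Problem sizes

Default problem sizes were chosen so the full suite and the acceptance
script each run in seconds on a single core while keeping Monte-Carlo
standard errors small: 10,000-variant cohorts for truth-recovery and
calibration checks, 20,000 variants for spectrum goodness-of-fit, 1,000
replicates for the dating round trip, and 200 replicates for
model-selection power. These sizes are the package's own test design
points; all estimators are O(m) in the variant count and scale to larger
cohorts unchanged.

## Known limitations

- The filter cannot distinguish genuinely hypermutable recurrent variants
  from genotyping artifacts; both violate clade exclusivity and are
  excluded together.
- The merge representative rule and the single-linkage chaining are one
  fixed reading of under-specified tool behaviour.
- The dating estimator ignores polymorphism among the repeat differences
  and multi-base indel events.
- The generator's independence assumptions (no LD, exchangeable variants)
  mean calibration results transfer to real data only insofar as those
  assumptions hold.
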