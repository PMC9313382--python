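# Methods

This note documents the models, decision rules and numerical choices behind
`mmct`, in the order the pipeline applies them, and what the bundled
simulator does and does not emulate.

## Data model and conventions

A cohort is keyed by `(patient_id, sample_index)`.  Each patient contributes
a designated *(first, paired)* sample pair — by default the two earliest
samples, overridable with a `paired` flag in the clinical table; every
statistic is computed on that pair, and additional samples are carried but
never rescue or penalize a variant.  Variant coordinates are 1-based (VCF
convention), copy-number segments 0-based half-open (BED convention), with
explicit tested converters.  Tabular files are UTF-8 TSV with `.` for
missing; VCF input requires per-sample `AD`/`DP` and sample IDs of the form
`<patient>_<index>`.  Multi-allelic sites are split into independent
records — an assumption, since panel data rarely contain them.

Annotations join variants on `(chrom, pos, ref, alt)`.  A variant without an
annotation row is retained with an all-missing annotation (and logged), so
that absence of external evidence is always visible rather than silently
fatal.  Gene-symbol conflicts resolve in favor of the annotation file.

## Variant inclusion cascade

Four stages in order, each a pure per-variant predicate:

1. **Population AF** — every *non-missing* database AF (1000 Genomes,
   gnomAD, ESP) must be `< 0.01`, strictly.  A variant absent from all three
   databases passes: absence from population catalogues is itself evidence
   of rarity.
2. **Read support** — `VAF >= 0.10` *and* `alt_reads >= 5` in at least one
   member of the pair, boundaries inclusive.
3. **Predictor consensus** — pathogenic verdicts in `>= 2` of the six
   predictors; for genes recurrently mutated in MM, one pathogenic verdict
   among the cancer-specific subset (CRAVAT, CHASM, FATHMM Cancer, CScape)
   suffices.  Missing verdicts count as non-pathogenic — the conservative
   reading where a predictor that did not cover a site casts no vote.
4. **Curated-class rejection** — variants labeled benign or likely benign
   are rejected unless whitelisted; the default whitelist is the single pair
   (*KMT2C*, c.1173C>A).  A missing curated class is retained: rejection
   requires affirmative benign evidence.

The stage counts form a `FilterReport` whose retention is monotone by
construction; a brute-force one-pass re-evaluation of all four criteria is
kept as the test oracle.

## Trajectory classification

Presence at a timepoint requires `alt_reads >= 3` and `VAF >= 0.02`.
The data themselves do not define "disappeared": at ~267× depth a single
stray read is common, and without a floor sequencing noise converts stable
variants into spurious branching calls.  The floor is configurable.

Presence pairs map to classes directly — (absent, present) → acquired,
(present, absent) → lost.  For variants present at both timepoints,
*expanded*/*declined* requires **both**:

* a two-sided two-proportion z-test on `(alt_reads, depth)` rejecting at
  α = 0.05 (statsmodels `proportions_ztest`), and
* an absolute VAF difference `>= 0.10`.

A pure significance rule would over-call at panel depth (at 267×, a VAF
shift of ~0.06 is already "significant"); a pure effect-size rule would
over-call at shallow depth.  Everything else is *stable*.

Clonality is a VAF threshold: `>= 0.40` ≈ clonal under the diploid
heterozygous model at high purity.  No copy-number or purity correction is
applied by default — the data model carries purity so a CCF-aware adjustment
can be slotted in, but the default mirrors a VAF-threshold convention.

Patient patterns follow from acquired/lost counts alone: branching
(both ≥ 1), acquisition, loss, stable.  Parallel evolution flags a gene with
two independent variant keys present in the same sample; whether both must
be *acquired* is genuinely ambiguous in practice, so co-presence is the
default and acquisition-only a config flag (`parallel_requires_acquired`).

## CNV events

A region's copy state is the length-weighted mean log2 ratio of the
segments intersecting it; a region with less than 50% of its length covered
is *missing*, never guessed (`min_region_overlap = 0.5` prevents calls from
a sliver of coverage).  Thresholds: loss `<= -0.25`, gain `>= +0.20`,
amplification `>= +0.30` — near CNVkit's conventional cutoffs, fully
configurable, since purity-adjusted panels differ.

The seven region windows (1p12, 1p22.1, 1p32.3, 1q21, 17p13.1, 13q14,
14q32) ship as an editable BED file with GRCh38 cytoband boundaries; these
windows are assumptions, as is representing "del17p / 17 monosomy" by
17p13.1 alone.  del1p is the three-valued OR of its three sub-regions.
Translocations come only from FISH flags — a capture panel cannot call IGH
breakpoints — and missing FISH propagates as missing.

A **biallelic event** is `VAF >= 0.80` in at least one sample at a locus
whose log2 is below the amplification threshold there (an amplified allele
can inflate VAF without a second hit); an uncovered locus counts as not
amplified.  **Double/triple hits** count distinct lesions among
{del17p, gain1q21, del1p, t(4;14), t(14;16)}; a TP53 double hit is del17p
co-occurring with a retained TP53 mutation.

## Staging and survival

ISS: I iff β2M < 3.5 mg/L and albumin ≥ 3.5 g/dL; III iff β2M ≥ 5.5; else
II.  R-ISS: I iff ISS I, no high-risk cytogenetics (del17p, t(4;14),
t(14;16)) and normal LDH; III iff ISS III with high-risk cytogenetics or
high LDH; else II.  Missing LDH or cytogenetics yield *not_reported* only
when the stage actually depends on them (ISS II is R-ISS II regardless);
not-reported patients are excluded from the affected analyses rather than
imputed.  An exhaustive grid against an independently written lookup oracle
is part of the test suite.

Survival uses lifelines: Kaplan–Meier with Greenwood confidence intervals,
median defined as the first time the estimate drops to ≤ 0.5; the log-rank
test across groups; and for two groups a single-covariate Cox model with
the Efron tie convention and a Wald 95% CI on the log hazard ratio.  A group
without events leaves the HR and median undefined, reported as such.  No
multiple-testing correction is applied; all tests are two-sided at 0.05.
The pattern-vs-response association dichotomizes response at ≥ VGPR and uses
the two-sided Fisher exact test (scipy), checked against a hypergeometric
enumeration oracle to 1e-12 on all 2×2 tables with n ≤ 40.

## The simulator

Defaults encode the study conditions the pipeline targets: 30 patients,
negative-binomial depth with mean 267× (dispersion 30, so depth sd ≈ 51 —
wide enough to stress the presence floor), purity U(0.82, 0.98) per sample,
pattern probabilities 8:11:7:4, variants per patient lognormal with median 5
clipped to [2, 33].

Per patient: the pattern fixes required classes (branching gets ≥ 1 acquired
and ≥ 1 lost, …); remaining variants are extra acquisitions/losses where the
pattern allows, else shared variants in the 25:29:46 expanded/declined/stable
mix.  True CCFs: present-timepoint CCF U(0.30, 1.00); expansion/decline
magnitude U(0.30, 0.60).  The lower bounds keep true VAFs comfortably above
the filter and presence floors (0.82 × 0.30 / 2 ≈ 0.12), so recovery failures
measure noise, not construction artifacts.  Observed VAF = purity × CCF/2
(diploid heterozygous); read counts are binomial.  Copy-number-aware VAF
coupling is deliberately omitted; biallelic fixtures instead override the
VAF to U(0.85, 0.95) directly, a stand-in for copy-neutral LOH that makes
the ≥ 80% rule testable.

Decoys: common-SNP contaminants (one database AF forced into [0.01, 0.30];
VAF 0.5 at both samples) and curated-benign variants that pass the earlier
stages, plus exactly one whitelisted *KMT2C* c.1173C>A likely-benign variant
per cohort.  Ground-truth patterns are defined over the core somatic set
only, so filter leakage or over-removal shows up directly as recovery loss.
Predictor sensitivity 0.90 / specificity 0.95 per predictor.

CNV: one segment per region window per sample, log2 = N(shift, 0.10) with
shift −0.5 for losses and +0.4 for gains, plus neutral background segments.
With these separations, per-call accuracy is ~97.7% (gain, 2σ from the
threshold) to ~99.4% (loss, 2.5σ), which is what makes the ≥ 98% pooled
recovery floor meaningful rather than trivial.

Clinical: albumin lognormal(log 3.8, 0.15) g/dL, β2M lognormal(log 4.0,
0.5) mg/L, LDH high with probability 0.25 and missing with 0.05; FISH
translocations persist between timepoints (they are clonal early events);
the del17p FISH flag tracks the true CNV state.  Response is drawn
pattern-dependently (P(≥VGPR) = 0.7 loss, 0.1 acquisition, 0.4 otherwise) so
the pattern–response association is recoverable.  Survival is exponential
per true R-ISS″ group — medians 11/21/53 months (PFS/OS″/OS′) for I–II
versus 3/9/37 for III — with independent uniform censoring `C ~ U(0, u)`,
where `u` is solved per group (Brent) so the expected censored fraction is
exactly the configured 20%.  OS′ = OS″ + the between-sample gap
U(6, 36) months, preserving OS′ ≥ OS″.

Randomness: one global seed; each patient's generator is
`SeedSequence(seed, spawn_key=(patient_index,))`, so adding patients never
reshuffles existing ones and a fixed seed reproduces byte-identical files.

### What passing tests do and do not show

The simulator realizes the pipeline's own assumptions: independent binomial
reads, one-segment-per-region CNVs, exponential survival, annotations whose
errors are independent across predictors.  Recovery floors (≥ 95% variant
classes and patient patterns, ≥ 98% CNV events at n = 200 patients, fixed
seed) therefore demonstrate internal correctness and noise robustness — not
performance on real data, where alignment artifacts, subclonal copy-number
changes, purity mis-estimates and correlated predictor errors all violate
these assumptions.  Genes are assigned uniformly from a 39-gene catalogue,
which over-produces same-gene collisions relative to a real panel, so
simulated parallel-evolution counts run high; the detector's logic, not its
prevalence, is what the tests establish.

## Problem sizes

Default test-suite scales: 200 simulated patients for recovery checks,
n = 2000 per arm for Cox recovery (log-HR SE ≈ 0.035), n = 2000–5000 for KM
medians, 40 replicates for CI coverage, and full enumeration of all 134,030
2×2 tables with n ≤ 40 for the Fisher oracle.  These sizes make the
stochastic assertions comfortably stable under their fixed seeds.

## Known limitations

* Tumor-only design: no germline subtraction; high-VAF variants may be
  germline in real data (the filter's population-AF stage is the only
  guard).
* No subclone deconvolution or phylogeny — variants are classified
  individually, so two variants of one clone are counted twice.
* Clonality and biallelic rules use raw VAF, not CCF; purity and local copy
  number are available in the data model but unused by default.
* The CNV caller consumes segments; it inherits whatever bias the upstream
  segmentation had, and region windows are fixed, not data-driven.
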