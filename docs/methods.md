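# Methods

## Study design being modelled

A single progenitor plant (G0) founds six lineages propagated by
single-seed descent for ten generations, three on control and three on
saline soil. Genomic resequencing covers the progenitor and three
tenth-generation (G10) siblings per lineage; whole-genome bisulfite
sequencing covers two first-generation (G1) plants — the "parental"
reference methylomes — one G10 plant per lineage, and one selfed
offspring (G11) of the first lineage of each treatment.

## Mutation accumulation under selfing

New mutations arise per generation as Poisson events per class
(transition, transversion, insertion, deletion) and are heterozygous with
probability τ/(μ+τ) (default 1: all heterozygous, the worst case for
detection). Each heterozygous mutation segregates per selfing generation
1/4 homozygous-mutant : 1/2 heterozygous : 1/4 lost, so the probability
that a heterozygote born t generations ago is now fixed is
(1/2)(1−(1/2)^t).

The rate estimator is m = (n/lines)/g. The accumulation model compares
the expected accumulated homozygous count g(μ + τ/2) with the expected
identified count gμ + (g−2)τ/2; at g = 10 and μ = 0 the identified count
is 8/10 of the accumulated count, a 20% underestimate. The closed form
drops a geometric tail of size 2^−g relative to (g−2)/2, so it agrees
with the exact per-birth-generation Markov-chain sum to <0.03% at g = 10
and the agreement improves with g; below roughly ten generations the
closed form is materially coarser than the exact sum, which is why the
package exposes `fixation_probability` for exact work.

G10 sibling plants are modelled as children of the G9 germline
individual: each sibling independently resolves the G9 heterozygotes and
adds its own private G10 events. Mutations shared by siblings of one
lineage are therefore expected and are counted once per lineage by the
caller.

## Variant filtering

A candidate is called a de novo homozygous mutation iff:

1. progenitor depth ≥ the class minimum (8 SBS / 5 indel) — otherwise
   absence cannot be verified;
2. progenitor alternate-allele fraction ≤ 0.05;
3. at least one derived sample is a valid carrier: alternate fraction
   > 0.95 with depth within class bounds (8–75 for SBS, ≥5 for indels);
4. no adequately covered sample shows an alternate fraction in the
   heterozygous band [0.20, 0.80];
5. all carriers belong to one lineage (cross-lineage sharing indicates an
   ancestral variant or systematic artefact; within-lineage sharing is
   genuine inheritance and is counted once per lineage).

Filtering its own output is a no-op (idempotence), which the tests
enforce.

The normalised Ti/Tv ratio collapses the twelve directed substitutions
onto six strand-symmetric classes, divides each class count by the number
of source-pair sites (G:C sites = gc·L, A:T sites = (1−gc)·L with
gc = 0.36 by default) and forms (transition-rate sum)/(transversion-rate
sum). A spectrum with no transversions raises an explicit
undefined-ratio error rather than returning infinity.

## Methylome calling

Fisher exact tests are two-sided, computed by direct hypergeometric
enumeration with the conventional 1 + 1e-7 tie tolerance (validated
against scipy on random tables) and memoised on the four cell counts,
which makes genome-wide scans cheap because count tables recur heavily.

- **Site status.** A position is evaluable in a sample at depth 3–200 and
  methylated at ≥3 methylated reads; failing depth is "not evaluable",
  distinct from "unmethylated".
- **Universe.** Evaluable in *every* parental and derived sample, and
  methylated in at least one ("analyzable").
- **Parental removal.** Positions where the two G1 parents differ at a
  BH FDR of 10% (per-site Fisher between parents) are removed before any
  generational comparison.
- **DMPs.** Per (position, derived sample): Fisher versus each parent,
  take the maximum of the two p-values (the call must hold against
  both), multiply by the per-site family size 2 × (number of derived
  samples) (Bonferroni; 12 tests with six derived samples), cap at 1,
  then BH at 5% across all (position, sample) units. A significant unit
  is a DMP only if the derived methylation proportion lies strictly on
  one side of both parental proportions; that side is the direction
  (gain/loss). Degenerate identical tables give p = 1. Strands are kept
  separate; symmetric CG pairs are not merged (positions are counted per
  cytosine).
- **DMRs.** Per sample, DMPs are chained while consecutive positions are
  <50 bp apart (a 49 bp gap chains, 50 breaks); runs with <5 DMPs or a
  span (end − start + 1) <10 bp are ignored. Each surviving run is
  re-tested on member-DMP counts aggregated by the arithmetic mean
  rounded half-up (summation is available via
  `MethylationCallPolicy.region_aggregate="sum"`; Fisher on sums is
  scale-equivalent), with the same Bonferroni-then-BH scheme at 5%.
- **Retention.** A carrier DMP is retained when the offspring is itself
  DMP-significant versus both parents at that position with the same
  direction (default); a plain methylated/unmethylated status match is
  available behind `retention_requires_significance=False`. Positions
  not evaluable in the offspring leave the denominator.
- **Clustering.** Up to 20,000 DMP positions (seeded uniform draw;
  fewer uses all, with a log note) are summarised as per-sample
  methylation proportions and clustered with Euclidean distance and
  average linkage; the dendrogram exports to newick.

The Bonferroni family is a modelling choice: the per-site pairwise-test
family (2 × derived samples) followed by BH over (position, sample) units.
An alternative — BH per position on a combined statistic — was considered
and rejected because the per-sample unit is what the downstream
per-sample DMP sets and DMR chaining consume.

## Genomic distribution

Positions are assigned to exactly one category by the fixed priority
CDS > UTR > intron > ncRNA > pseudogene > TE > intergenic; "genic" is
{CDS, UTR, intron, ncRNA} (configurable). Regional incidence is DMPs per
methylated site within each category, reported as NaN (not zero) for an
empty category. The G-test is the log-likelihood-ratio chi-square,
G = 2·Σ O·ln(O/E), 1 df, no continuity correction and no Williams
correction. Chromosome profiles bin positions (default bin =
chromosome length/50, since no natural bin size exists at desk scale)
and normalise each class to its per-chromosome maximum.

## Synthetic-data generator

The generator is the package's study stand-in, not a fixture: a
two-chromosome 1 Mb-per-chromosome genome replaces the ~120 Mb original,
and the per-site per-generation mutation rates fold in that scale factor
so a default run accumulates realistic per-genome event counts
(control: ≈0.33 transitions, ≈0.16 transversions, ≈0.09 indels per genome
per generation — about 52 mutations per arm across nine G10 plants over
ten generations; saline doubles each class). Indel lengths are geometric
(p = 0.5) truncated at 226 bp.

Methylomes: every cytosine is enumerated with its CG/CHG/CHH context;
progenitor states are Bernoulli per context (CG 0.24, CHG 0.10,
CHH 0.03), and methylated sites emit reads at a per-site Beta level
(CG Beta(20,2), CHG Beta(5,5), CHH Beta(2,8)) held fixed across samples,
so Fisher tests face realistic dispersion and CG changes are easier to
detect than CHG/CHH — mirroring the observed CG overrepresentation among
DMPs. Per generation, unmethylated sites gain and methylated sites lose
methylation at context-specific rates (CG 1e-4/3e-4 gain/loss per site
per generation, chosen so desk-scale DMP counts land in the hundreds
with a balanced gain/loss split; absolute per-generation epimutation
rates are not published, so these are calibrated to the relative
contrasts only). Genic sites use 2× rates; saline lineages multiply CG
rates by 1.45. Rare regional events flip a ~120 bp window of CG sites
together (3e-8 per site per generation), the source of DMR-scale
signal. Methylation is inherited clonally through selfing — epiallele
segregation is deliberately not modelled.

Offspring (G11) methylomes inherit each accumulated epimutation with
probability 0.76 (the retention probability is exposed directly rather
than derived from a per-generation loss rate, because a rate consistent
with the slow accumulation dynamics cannot produce ~24% single-generation
reversion; retention is treated as its own observable).

Sequencing emulation is count-level only: per-site depth is
Poisson(75×) for bisulfite and Poisson(22×) for genomic data;
methylated-read counts are Binomial(depth, level) with a 0.004
non-conversion floor (plus an unmethylated lambda-phage-style spike-in
table for conversion-rate estimation); variant support is
Binomial(depth, 1−ε), Binomial(depth, 1/2) or Binomial(depth, ε) for
homozygous/heterozygous/absent, with sparse false candidates injected at
low allele fractions. No reads, no alignment.

### What passing synthetic tests does not show

The generator draws i.i.d. sequence (no repeats or mappability
structure), makes initial methylation independent of feature category,
applies the same genic enrichment to both arms (so the treatment × genic
interaction the G-test targets is not emulated — the test itself is
validated on constructed tables), and omits PCR/strand biases and
context-dependent non-conversion. Recovery results on synthetic data
therefore validate the statistical machinery, not robustness to real
alignment artefacts.

## Numerical and engineering choices

- Wide count tables (two columns per sample) in pandas; 1-based
  positions in reports, 0-based half-open in BED exports.
- BH via statsmodels `multipletests`; linkage via scipy.
- Welch t-tests on per-lineage rates; two identical zero-variance groups
  report t = 0, p = 1 by convention.
- All simulation stages draw from generators seeded as (seed, stage), so
  fixture generation and the pipeline are byte-reproducible; identical
  runs hash identically, which the tests assert.
- Desk-scale problem sizes used by the test suite (50–350 kb per
  chromosome, 10⁴ analyzable CG sites for error-control checks, 10⁴
  Monte-Carlo replicates for segregation dynamics) were chosen so the
  whole suite runs in well under a minute while keeping 3-standard-error
  bands tight around the quantities checked.

## Known limitations

- Multi-allelic variant records are rejected, not decomposed.
- The DMR significance family (Bonferroni factor 2 × derived samples) is
  a convention; region counts are small enough at desk scale that the
  choice is rarely load-bearing.
- `compare_rates` assumes per-lineage rates are approximately normal;
  with three lineages per arm the t-test is descriptive rather than
  powerful.
- The generator's saline multiplier applies uniformly along the genome;
  chromosomal-position effects on the stress excess are not modelled.
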