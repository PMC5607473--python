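# Methods

## Model and procedure

The pipeline treats DNM discovery as a two-stage problem: a deliberately
permissive rule-based candidate extraction, followed by a statistical
classifier calibrated on an internal, genome-wide labelling signal —
transmission consistency in three-generation families.

### Candidate extraction

Allelic balance (AB) is alt reads over ref+alt reads. The filter set, with
defaults in `RunConfig`:

| rule | default | notes |
| --- | --- | --- |
| proband carries alt | — | hom-alt calls allowed ≤ 1 ref read |
| proband depth | ≥ 12 | |
| proband AB | ≥ 0.15 | inclusive boundary |
| parent depth | ≥ 12 | father ≥ 6 at X sites of male probands |
| parent alt reads | ≤ 1 | |
| parent AB | ≤ 0.05 | applies independently of the count rule, so 1 alt read in 15 (AB 0.067) rejects |
| outside carriers | ≤ 10 possible, ≤ 3 likely | beyond descendants of the parent pair |
| site soft-clip | ≤ 10% | proband's mean over covering reads |

Likely carriers use strict inequalities (depth > 12, |AB−0.5| < 0.25,
GQ > 20) while the proband depth rule is inclusive (≥ 12); the two
phrasings are kept deliberately as two distinct rules rather than
harmonized. Probands are restricted to > 20× genome-wide mean coverage, and
probands with > 10% mean soft-clipping, > 1.5% mean N fraction, or > 300
candidates are removed wholesale.

"Descendants of the parent pair" is implemented as the set of individuals
with **both** members of the couple among their ancestors. For ordinary
pedigrees this equals "children of the couple and everything below them";
under inbreeding the both-ancestors definition is the one the carrier
exclusion logically wants (anyone who could have inherited the allele from
the couple), and it is what the brute-force oracle in the test suite
verifies.

### Transmission assay

A candidate in a three-generation proband is evaluable when at least two
offspring with non-missing calls cover *both* proband haplotypes at the
site. Offspring calls are missing below 10× depth, and alt-carrying calls
additionally require ≥ 2 alt reads and AB ≥ 0.1 — this avoids labelling a
true DNM inconsistent off the back of one noisy grandchild genotype. The
label is consistent iff some proband haplotype H exists such that exactly
the offspring inheriting H carry the allele. On the X, a male offspring
carrying the allele heterozygously is biologically impossible for a
germline variant and forces the inconsistent label.

### Classifier

`TransmissionGam` is a binomial additive model on the logit scale with
penalized cubic B-spline smooths (10 basis functions each) on proband
allelic balance, FoxoG and Trio-NPOSS, and a linear binary GATK-filter
term; it is built on statsmodels' GLMGam. Design choices:

* **Penalty selection** is per-smooth 5-fold cross-validation on a small
  log-spaced grid (0.1, 10, 1000), with deterministic (seeded) folds so a
  refit on identical data reproduces identical predictions. Any reasonable
  roughness penalty yields the same classifications on well-separated data;
  the grid keeps the search cheap and reproducible.
* **Degenerate covariates** (fewer distinct values than basis functions,
  e.g. Trio-NPOSS when almost all counts are 0–3) automatically fall back
  to linear terms — a spline basis cannot be anchored on them.
* **Near-separable training sets** can make weakly penalized IRLS diverge;
  the fit escalates the penalty ×100 (up to four times) until it
  stabilizes.
* **Scoring outside the training hull**: covariates are clamped to the
  training range (constant extrapolation of each smooth) and such rows are
  flagged `extrapolated`. The response cutoff is strict: a response exactly
  equal to 0.8 is not high quality.
* **FoxoG** is the fraction of orientation-resolved alt read pairs in the
  damage-prone orientation — F2R1 for C>A, F1R2 for G>T (the
  reverse-complement case is treated equivalently, since 8-oxoG damage on
  the opposite strand presents as G>T). All other substitutions and indels
  score 0, as do sites with no orientation-resolved pairs.
* **Trio-NPOSS** uses *possible* carriers (genotype-based), untransformed.
* The model is trained on the evaluable labels and then scores every
  candidate, including the training ones; unevaluable candidates
  contribute nothing to training.

### Phasing

Three-generation phasing counts per-offspring votes (carrier on the
proband's paternal haplotype → paternal; non-carrier on it → maternal;
symmetrically for the maternal haplotype), restricted to IBD segments of
≥ 0.8 cM with ≥ 200 consecutive panel markers; conflicting votes leave the
DNM unphased rather than majority-voting. Read-pair phasing sums
alt-allele-bearing pairs over phased markers within 1,000 bp (the order of
a sequencing fragment; read pairs cannot link farther) and requires
single-sided support — at least one pair for one parent and exactly zero
for the other. Ref-allele pairs never assign origin: only the DNM allele's
chromosome is informative. Pairs supporting a third haplotype or
inconsistent with every biallelic combination never contribute. The
consensus keeps agreements, carries one-sided information through, and
excludes (but counts) both-phased disagreements. The summary table
satisfies the identity `consensus = three_gen + read_pair − both −
discordant` by construction, and `summarize_phasing` asserts it against the
actual call set.

### Validation reports

Twin concordance treats twin calls as missing below 10× depth and twin het
calls as missing without ≥ 2 alt reads and AB ≥ 0.1; a verifiable twin call
lacking the allele is discordant, hom-alt presence counts as concordant.
Discordance is reported both pooled (count-weighted) and as the mean of
per-pair fractions, since either convention is defensible. The variant
summary stratifies counts by SNP/indel × biallelic/non-biallelic with
GATK-pass, phase-score > 0.8 and imputation-info > 0.8 columns; totals are
sums over the type rows.

The imputation informativeness is the ratio of the observed (population,
divide-by-n) variance of imputed expected allele counts to p(1−p), computed
per haplotype. For dosages attenuated toward the frequency by a factor a
(d = p + a(θ−p)) the measure converges to a²; values above 1 are clipped
and flagged.

## Simulator

The simulator defines the study conditions the tests and the acceptance
script run under.

* **Toy genome**: two 10 Mb autosomes (optional 10 Mb X), uniform 1 cM/Mb,
  one panel marker per 10 kb — large enough to hold the 0.8 cM/200-marker
  segments phasing requires, small enough for seconds-scale runs.
* **Meiosis**: crossover count ~ Poisson(map length in Morgans), positions
  uniform, no interference (Haldane). MZ twins share the proband's gamete
  mosaics exactly. Males are hemizygous for X (single maternal haplotype).
* **Coverage 34×** (Poisson per site; halved for male X), true het alt
  reads ~ Binomial(depth, 0.5), sequencing error 0.002.
* **DNM load**: total per proband ~ Poisson(2 × 8 per gamete), paternal
  with probability 0.75 — a simulator default chosen to exercise phasing
  with an asymmetric origin, not an empirical claim. ~10% indels; GATK pass
  probability 0.99.
* **Artifacts**: ~ Poisson(24) per proband; AB ~ Beta(4, 16) (mean 0.2);
  half are oxoG-type C>A/G>T with 95:5 orientation skew; GATK fail
  probability 0.3; Poisson(2) recurrent carriers planted in unrelated
  individuals so Trio-NPOSS carries signal. The DNM and artifact loads are
  set so the two classes contribute roughly equal numbers of *extracted*
  candidates (artifacts are planted more heavily because the AB filter
  removes more of them).
* **Read-pair linkage**: 60% of sites get a phased het marker within
  100–900 bp; traversing pairs ~ Poisson(6); the marker allele on each pair
  is flipped with the tracing error rate (default 0.002). Artifact sites
  link their alt pairs to either marker allele at random, which the
  single-sided support rule correctly refuses to phase.
* **Post-twinning fraction 0.03**: each DNM of a twin proband is private
  (somatic, absent from the co-twin) with this probability.
* Lane metrics, IBD summaries (shared fraction ~1 for genuine parent-child
  pairs, <0.05 for planted swaps), QC-failing lanes and bad probands are
  planted on demand; defaults plant none.

What the simulator does **not** emulate: realistic mutation spectra and
clustering, indel realignment artifacts, mapping bias, population
demography or relatedness beyond the simulated families, imputation-panel
errors (marker phase is exact up to the tracing error), and
coverage/GC structure along the genome. Passing tests therefore demonstrate
the correctness and internal calibration of the machinery under its own
assumptions — not performance on real cohort data, whose artifact modes are
richer.

## Numerical and format choices

* Fractional fields (soft-clip, N fraction, segment cM, annotations) are
  carried at 4 decimal places in memory and on disk so a VCF/TSV round trip
  is exact.
* Multi-allelic sites are represented as dichotomized biallelic records
  with an INFO `MULTI` flag; the non-biallelic column of the variant
  summary counts these.
* Lane-rule inequalities are strict exactly as printed (mean base quality
  < 25 fails, 25.0 passes; duplicate percent > 50 fails, 50.0 passes), and
  a missing metric raises rather than passing silently.
* Zero denominators (no informative reads, no chip bases, no het pairs,
  p ∈ {0,1}) raise typed errors; they are never silently treated as passes.
* The pipeline is a pure function of (dataset, config): reruns produce
  byte-identical outputs. Within the simulator one `numpy` generator seeded
  from `SimConfig.seed` drives everything.

## Problem sizes

Unit tests run on 3–10 family simulations (seconds); the acceptance-scale
cohort is 70 families / ~10 twin pairs, yielding ≈ 2,300 candidates with
≈ 45% artifacts, ≈ 1,100 phased DNMs and ≈ 300 verifiable twin genotypes —
enough for the AUC, leakage, accuracy and binomial-recovery margins to be
stable across seeds while the whole suite stays under ten seconds.

## Known limitations

* Inheritance assignments and IBD segments are inputs (produced here by the
  simulator); the package does not detect IBD from genotypes.
* The GAM's effective degrees of freedom are not exposed per smooth beyond
  the statsmodels summary; coefficients are not interpreted, only the
  classification behaviour is tested.
* X-chromosome handling covers hemizygous males and the male-carrier
  constraint; pseudo-autosomal regions are out of scope.
* Sample-swap handling excludes the child side of unconfirmed parent-child
  pairs; it does not attempt to identify which member of a pair was
  swapped.
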