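# Methods

This note documents the models, conventions and tunable parameters behind
each stage of the pipeline, what the synthetic cohort does and does not
emulate, and the design choices made where more than one reasonable
convention exists.

## Quantification models

### Culture

The colony-count conversion is pure protocol arithmetic. With swab uptake
*u* = 150 µl, transport-medium volume *m* = 1050 µl and plated volume
*p* = 50 µl (all configurable in `CultureProtocolParams`):

    dilution = (u + m) / u = 8
    plating  = 1000 / p   = 20
    cfu/ml   = colonies × dilution × plating = colonies × 160

Zero colonies is reported as the left-censored value "<160" (the culture
detection limit) and an uncountable plate (">100" colonies) as ">1.6 × 10⁴".
Reporting categories use edges 160 / 1600 / 8000 / 16 000 cfu/ml; the
moderate bin (50–100 colonies, 0.8–1.6 × 10⁴) is closed at the top because
100 colonies is still countable, so "abundant" is strictly > 1.6 × 10⁴.
Censoring is always carried in a typed `CensoredValue`, never as a sentinel
number.

### qPCR

The standard curve is the usual log-linear model Ct = m·log₁₀(copies per
reaction) + b. The built-in calibration (`calibration_curve`) reflects the
assay's genomic-DNA standard: a fluorometric measurement of 38.3 ng/µl and a
genome of 2,096,423 bp give 1.69 × 10⁷ genomes/µl via an average
double-stranded base-pair mass of 650 g/mol; the ten-fold dilution series of
that stock is linear down to 1.69 genomes/µl, i.e. with 2 µl of template and
4 rRNA operons per genome ≈ 13.52 (≈ 14) target copies per reaction, at
Ct 34.17. The curve is anchored at that point with the ideal 100%-efficiency
slope −1/log₁₀2 = −3.3219. Two deliberate conventions:

- The stock concentration enters at the printed 3-significant-figure value
  (1.69 × 10⁷), not the unrounded 1.6926 × 10⁷, so the censoring limit works
  out to the round figure 2816 genomes/ml (3.38 genomes/reaction × the 1:833
  sample dilution). The unrounded value would shift every number by ~0.15%.
- The 1:833 overall dilution of sample material through collection and DNA
  extraction is a protocol constant that already folds in the template
  volume: genomes/ml = genomes/reaction × 833.

`fit_standard_curve` fits mean Ct on log₁₀(copies) by least squares over the
longest run of dilution steps, starting from the most concentrated, whose
per-step residuals all stay within a tolerance (default 0.5 Ct). Steps that
plateau below the linear range — the stochastic regime under ~14 copies per
reaction — are thereby excluded, and the lowest retained step defines both
the LoQ Ct and the censoring threshold. At least three linear steps are
required. Per-run drift is handled by `run_adjustment`: the offset is
mean(observed standard Ct) − predicted Ct at the standard's known copy
number, and shifts every subsequent prediction and inversion of that run.
Ct values beyond the (offset-adjusted) LoQ Ct, and no-amplification
reactions, are reported "<LoQ". The limit is treated as a limit of
*quantification*: detections beyond it are censored, not discarded.

## Read processing

Pairs are merged by scanning every R1-suffix/R2-reverse-complement-prefix
overlap of length ≥ `min_overlap` (default 20 nt) and keeping the candidate
with the lowest mismatch fraction, requiring ≤ `max_mismatch_frac` (default
0.1); disagreeing overlap bases take the higher-quality call, R1 winning
ties. Unmergeable pairs are discarded (not rescued as single reads) and
counted in the stage report. The merger parameters are not dictated by any
protocol constant and are config-exposed. Merged sequences shorter than
300 nt are removed; the synthetic amplicons are ~410–430 nt precisely so
that correctly merged reads pass this filter and truncated artifacts do not.

## OTU inference

Clustering is greedy abundance-sorted centroid clustering: dereplicate,
visit unique sequences in order of decreasing read count (first occurrence
breaks ties), join the first existing centroid with identity ≥ 0.99, else
found a new OTU. Identity is matches / alignment columns with terminal gaps
excluded from the denominator ("end-gap-free"), computed from edlib's global
alignment; this convention suits amplicons of near-equal length and makes
thresholds like "3 mismatches in 400 nt = 0.9925" exact. Clustering is per
sample, and the sum of OTU sizes always equals the number of input reads.
OTUs with fewer than 50 members are rejected after clustering.

Chimera flagging uses a two-parent splice test. For each OTU, candidate
parents are same-sample OTUs with ≥ 2× its abundance. The OTU is flagged
when some left/right splice of two distinct parents (a) explains its
centroid nearly perfectly — at most 1% of positions mismatched
(`max_splice_divergence`), (b) beats the best single parent by ≥ 2
mismatches, and (c) takes ≥ 20% of the centroid from each parent.
Requirement (a) matters: without it, any sufficiently divergent
low-abundance OTU would be flagged, because the optimal splice of two
arbitrary parents always beats one parent by chance. With it, true PCR
splices (which the model explains exactly) are caught and legitimate rare
taxa are not. All four parameters are config-exposed.

## Taxonomy

Identification follows a clinical decision ladder on the ranked hit list
against the reference collection: top identity ≥ 99.0% with a margin
> 0.8% to the best *other* species (extra references of the same species are
skipped) gives an unambiguous species call; ≥ 99.0% with a smaller margin
reports the runner-up in parentheses; two or more species at the *identical*
top score produce a slash group; 97–99% gives a genus call; below 97% the
OTU is retained as "unclassified" (no rule exists for that band, and
discarding would silently bias composition). Identities are compared at
4-decimal precision, both for tie detection and for the margin, so that
floating-point noise cannot flip a call at the 0.8% boundary. Boundary
conventions: ≥ 0.990 inclusive, margin strictly > 0.008, genus band
[0.97, 0.990).

## Decontamination

The decontamination model assumes reagent background is (i) shared between
samples and extraction controls and (ii) led by a stable set of canonical
contaminant taxa. The rules, in order:

1. **Pooling** — the union of identifications across all negative and
   spiked controls (spike organism excluded) is the contaminant set.
2. **Sample-specific cutoff** — the largest within-sample relative abundance
   among canonical contaminants present in that sample. An identification in
   the contaminant set is removed iff its relative abundance does not exceed
   this cutoff. Rationale for using within-sample relative abundance (rather
   than absolute reads or qPCR-scaled abundance): control and sample
   libraries have unrelated sequencing depths, so only composition is
   comparable. The in-control reading of the cutoff is selectable via
   `DecontaminationConfig.cutoff_source`.
3. **Culture rescue** — species cultured from the same patient are always
   accepted; by default either segment's culture rescues both of the
   patient's profiles (selectable to per-sample). Matching is slash-group
   aware: a cultured *S. epidermidis* rescues the
   "S. capitis/epidermidis" sequencing label, and a bare genus name in the
   canonical list ("Aquabacterium") matches any species of that genus.
4. **Cross-sample singleton removal** — identifications present in fewer
   than 2 samples cohort-wide are removed everywhere.
5. **Blocklist** — "biologically unexpected" labels, removed
   unconditionally. It ships empty: that judgement is discretionary and
   belongs to the user.

Every removal is logged with (sample, species, reads, reason), and reads are
conserved: removed + retained = input, per sample.

## Cohort analysis

Results from a patient's two segments are merged as a presence union;
per-segment counts are retained for rank aggregation. Prevalence is the
fraction of patients carrying an identification; the core microbiota at
threshold *t* contains identifications with prevalence strictly greater
than *t* ("more than 30%/50%" is read literally). Patient-level quantity
categories take the bin of the most microbe-rich segment, culture and
molecular modalities handled separately; censored values order by their
knowable magnitude ("<x" just below x, ">x" just above). Genus/phylum
aggregation resolves slash groups through the lineage table when all members
agree at the requested rank, else buckets them as "unresolved".
Culture-vs-sequencing concordance counts identifications found by both,
culture only, and sequencing only, with membership-aware matching.

## Synthetic cohort

What the generator emulates, and the defaults:

- **Design**: 60 patients × 2 segments, 10 negative + 10 spiked controls.
- **Communities**: per-sample richness ~ Poisson(3) drawn from the
  non-contaminant reference species; log-concentration = 5.0 + patient
  effect (sd 1.0, shared by both segments) + within-sample noise
  (sd √(3² − 1²)), in ln genomes/ml. These values were calibrated once so
  that ~40% of patient-level maxima (and ~60% of individual segments) fall
  below the 2816 genomes/ml LoQ while a heavy tail reaches 10⁵–10⁶
  genomes/ml — the load structure such surgical cohorts show.
- **Contaminant background**: a fixed composition over the canonical
  contaminants, mixed into each library with weight w = C₀/(C₀ + total
  load), C₀ = 2 × 10³ genomes/ml equivalent, so sterile samples yield pure
  background and heavy samples dilute it. A sterile sample with *no*
  configured background yields an empty library.
- **Reads**: 2 × 300 nt pairs from ~420 nt amplicons (guaranteed overlap
  window ≥ 180 nt), i.i.d. substitution errors at 0.002/base, chimera
  probability 0.01 per pair (two distinct source amplicons spliced at a
  uniform point in the middle 20–80%). Depth defaults to 3000 pairs/sample —
  a deliberately scaled-down library size; depth is a free design parameter.
  Read headers carry only the sample id; ground truth lives in a sidecar
  table so no label can leak into the pipeline.
- **Reference collection**: curated lineages (phylum→genus) for ~35 real
  oral/intestinal and contaminant taxa plus synthesized filler species. By
  construction it contains one identical-sequence pair (S. capitis /
  S. epidermidis — exercising slash groups, and realizing the canonical
  staphylococcal contaminant group) and one near-identical pair
  (S. mitis / S. oralis, 2 substitutions ≈ 0.48% < 0.8% — exercising
  parenthetical alternatives). Cultivability is a per-species coin flip
  (~50%), the spike organism fixed non-cultivable; this reproduces
  culture/sequencing discordance without modelling growth media.
- **Controls**: negatives are pure background; spiked controls add
  *Legionella pneumophila* at 1.5 × 10⁵ cells in the 1.2 ml collection
  volume (1.25 × 10⁵ genomes/ml), which dominates the default background.
- **Culture**: per cultivable species, colonies ~ Poisson(concentration /
  160); plates over 100 colonies report ">100".
- **qPCR**: Ct = curve prediction at (total load / 833 × 4 operons) copies
  plus Gaussian noise (default sd 0.2 Ct); zero load gives a
  no-amplification sentinel, and sub-linear-range copies never report below
  the LoQ Ct.

What it does **not** emulate: indels and quality-score miscalibration, PCR
amplification bias and primer chemistry, 16S copy-number variation between
taxa (a fixed 4 operons/genome), batch effects between extraction sets, and
any diet/antibiotic influence on the communities. Passing tests on this
cohort therefore demonstrate the correctness of the pipeline's logic and
arithmetic under the stated statistical structure, not robustness to every
artifact of real MiSeq data.

## Numerical choices and degenerate inputs

- Identity ties in clustering resolve to the earlier (more abundant,
  first-seen) centroid; OTU output is sorted by size then id.
- Empty hit lists annotate as "unclassified" with absent identities; empty
  read sets, empty cohorts and zero-read profiles flow through every stage
  as empty outputs rather than errors, except where a contract forbids them
  (e.g. pooling zero controls).
- `fit_standard_curve` requires ≥ 3 linear steps and ignores
  no-amplification replicates within a step.
- Loads at or above 10⁶ genomes/ml fall into the highest reporting bin with
  a warning (the reporting scheme was built for a cohort that shows none).
- All generators and the pipeline are deterministic for a fixed seed; there
  is no hidden global RNG state.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use scaled-down problem sizes
chosen as the package's own verification conditions: a 10-patient
contaminant-free, error-free cohort at 3000 pairs/sample for exact
end-to-end truth recovery (with the singleton rule disabled, since a species
genuinely present in one sample would otherwise be removed by design);
200 simulated patients for the load-calibration check; 200 qPCR replicates
at 10⁴ genomes/ml with Ct noise sd 0.2 for parameter recovery (median
absolute relative error ≈ 10%, well under the 25% target); and profile-level
simulation of the default 60-patient design for decontamination
sensitivity/specificity.
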