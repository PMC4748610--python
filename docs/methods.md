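# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices made where the design was genuinely open, and what the
synthetic cohorts do and do not emulate.

## Alignment cleaning

Input CPR alignments are per-line haplotypes over {A,C,G,T,N} (lines are
homozygous, so one haplotype per line). Cleaning applies, to a fixed point:

1. lines with any heterozygous call in the CPR are removed;
2. alleles below the minor-allele-frequency threshold (default 1 %) are
   masked to N in the carrying lines — the *allele* is excluded, not the
   site, preserving the remaining variation at that position;
3. a site where every determined line carries one base is treated as fixed
   for that base (Ns filled in);
4. lines that are N at a site that remains polymorphic are excluded from
   that CPR;
5. a CPR retaining fewer than 20 usable lines is excluded.

Steps 2–4 interact (masking can expose fixed sites; exclusions can change
frequencies), so they are iterated until stable, which also makes the
operation idempotent. π uses pairwise deletion per site with an adjusted
denominator; Tajima's D uses the per-CPR retained line count for its
constants. Whether the original analyses used pairwise or complete deletion
is not documented for this pipeline's ancestry; pairwise deletion is the
default because it maximizes data use, and after the cleaning rules above no
N remains in practice.

## Diversity statistics and the coalescent null

S, π (per site), θ_w = S/(a₁L) and Tajima's D follow the standard
definitions; D is undefined (reported missing, never zero) for S = 0 or
n < 4. The null distribution of D is obtained by simulating n = 29
haplotypes of L = 160 bp under a demographic model and applying the *same*
statistic implementation to each replicate; S = 0 replicates are excluded
from the null (D's domain) and counted separately.

Simulation is delegated to msprime with haploid samples, continuous genome
coordinates (exact infinite-sites mutations) and mutation/recombination
rates of 1.45×10⁻⁹ /bp/generation and 5.0×10⁻⁷ cM/bp (1 cM = 0.01
crossovers, so 5×10⁻⁹ crossovers/bp/generation). Because msprime's pairwise
coalescence rate with ploidy 1 is 1/size, deme sizes are passed as
2·N_ref·(scaled size), keeping the diploid convention θ = 4·N_ref·μ
(E[T₂] = 2·N_ref generations); this is verified against E[S] = θ·a_{n−1}
and E[π·L] = θ in the test suite.

The demographic structure supported is a set of demes with piecewise
exponential sizes plus discrete founding and admixture events (backwards in
time each lineage of an admixed deme independently picks a source with the
stated proportions). The bottleneck/growth/admixture history appropriate to
the emulated North-American panel has published *estimated* parameters that
are not reproduced here; `toy_admixture_model()` is an explicitly labelled
structural placeholder, and any real analysis must supply its own parameter
values (YAML/config input). Tests and the acceptance script use the
constant-size neutral null, whose analytics are known exactly.

Empirical P values are +1-corrected two-tailed:
P = min(1, 2·min(p_upper, p_lower)) with p_upper = (#{D_sim ≥ d} + 1)/(R+1).
The +1 avoids P = 0 from finite simulation; doubling the smaller tail is the
two-tailed convention chosen since no formula was prescribed. Verdicts:
P < 0.01 above the null median → balancing candidate, below → sweep /
purifying candidate.

## Expression model

Seq is the full-CPR haplotype class (lines with identical cleaned promoter
sequence share an allele label, ordered by descending frequency, so the
majority haplotype is always allele "a"). The model
Y = μ + Seq + Sex + Seq×Sex + ε is fitted per transcript by OLS with
Type II sums of squares for the per-term F tests — robust to the mild
imbalance produced by per-CPR line exclusions; the choice is switchable by
fitting through `statsmodels` directly. BH adjustment is applied per term
family (Seq, Sex, Seq×Sex) across transcripts at FDR 5 %, because candidate
counts are reported per term. Transcripts outside the broad-sense
heritability window [0.3, 1.0] are dropped before modelling; heritability is
an input column, not something the package estimates. Degenerate designs
(single allele class, single sex, zero residual variance) return missing
statistics with a diagnostic rather than failing.

## Motif analysis

PSSM cells are log₂ of the pseudocount-smoothed motif probability over a
uniform background; the pseudocount default is 0.5 per cell (avoids −∞
log-odds; the choice only matters for near-zero counts). The balanced
threshold is taken from the exact joint score distribution under the
background and the motif's own distribution, computed by position-wise
convolution: for widths ≤ 10 the DP keeps exact score keys (it matches
exhaustive k-mer enumeration bit-for-bit, which the tests exercise for
widths 4–8), beyond that scores are binned at 0.01 bits. The threshold is
the achievable score whose FNR/FPR is closest to the target ratio (1000 by
default) on the log scale, ties resolved upward. Binding calls use
score ≥ threshold − 10⁻⁹ so that float summation order cannot flip a call
exactly at the threshold.

Scanning covers both strands (the minus-strand score at offset i is the
score of the reverse complement of the window starting at i); windows
containing N score missing rather than worst-case, mirroring the
exclude-undetermined-data policy of the cleaning rules. A change event is a
(motif, window, strand) at which at least one allele is bound and one
unbound; a CPR's "# TFBSs" counts *motifs* with ≥ 1 event, not windows.
For minimal mutation-set search all 2^k combinations of the k candidate
SNPs are applied (capped at k = 12) and, per event, subsets that flip the
call with no flipping proper subset are reported. Patterns: I — a single
SNP flips exactly that one event; II — a flipping single SNP flips ≥ 2
events; III — every minimal subset has ≥ 2 SNPs.

The bundled motif set (`toy_motif_set`) is a synthetic stand-in: four
sharply peaked width-6 matrices shaped after core-promoter consensi, one of
them palindromic so both-strand (pattern II) flips are constructible. Real
analyses should load JASPAR POLII count matrices through `read_jaspar`,
which accepts both JASPAR count dialects via Biopython.

## Linkage disambiguation

LD is counted directly from phase-known haplotypes (inbred lines). Blocks
follow the Gabriel confidence-interval rule with the constants its tool
family popularized — strong LD when the |D′| CI has lower bound ≥ 0.70 and
upper bound ≥ 0.98, recombination evidence when the upper bound < 0.90,
blocks where strong pairs outnumber recombination pairs ≥ 19:1 — since only
the concept, not the constants, was prescribed. CIs come from a
nonparametric bootstrap over lines (default 1000 resamples) rather than
likelihood intervals: simple and adequate for phase-known data. Flank
associations regress per-line expression means (mean within line × sex,
then across sexes, so unbalanced replication cannot tilt a line toward one
sex) on allele code, SNP by SNP, with BH at FDR 1 % within the ±5000 bp
window. The verdict is Y when a significant flanking SNP shares a block
with a CPR SNP or has r² ≥ 0.8 with one — the r² fallback covers pairs that
the block rule leaves ambiguous and is switchable.

## Duplication screen

Reads are prefiltered by dropping any read with ≥ 80 % of its (pre-trim)
bases below Q20 and truncating the maximal 3′ suffix of bases below Q10;
the two criteria are evaluated independently on the original read, and the
trim is a truncation (not windowed) because the rule removes "3′ end
regions". A (line, CPR) is flagged when mean depth over CPR ± 200 bp is at
least twice the unweighted mean of per-gene mean depths on the same
chromosome for the same line; the per-line interpretation follows the
allele-specific question being asked. Read mapping itself is out of scope —
depth tables are inputs.

## Allele phylogenies

Pairwise distances default to a composite TN93: base composition is pooled
across the whole alignment (the composite element), transition/transversion
proportions are per pair; JC and K2P closed forms are available for
degenerate data. Neighbor joining uses the standard Q criterion with
deterministic tie-breaking (lexicographic order of the joined clusters'
smallest leaf names), clamps negative branch lengths to zero moving the
deficit to the sibling, and roots on the midpoint of the outgroup's pendant
edge when an outgroup is given (rooting does not change unrooted
bipartitions). Bootstrap supports resample alignment columns, re-run the
same distance + NJ path, and report the percentage of replicates containing
each original bipartition; replicates with undefined distances are skipped
but stay in the denominator. Newick output annotates supports above a
display threshold (60 % by convention).

## Synthetic cohorts

`generate_cohort` emulates the study conditions: 29 homozygous lines,
160 bp CPRs, θ = 0.006 per site (matching the promoter-scale diversity of
the population emulated), broad-sense heritability 0.6 by default with
expression decomposing as line effect + sex effect + interaction + N(0,1)
residual, two replicates per line × sex (the replicate count is a free
parameter of the emulated design), ±5000 bp flanks, and per-line depth
tracks. Notable design choices:

* **Planted selection signatures are fully constructed.** A CPR planted as
  "balancing" consists of two haplogroups (15/14 split) differing at
  `selection_strength` sites (default 8) on a monomorphic background; a
  "sweep" CPR carries that many singletons on distinct lines. The strengths
  place the planted D (≈ +3.0 / −2.2) clearly beyond the neutral null's
  1 % two-tailed critical values (≈ +2.3 / −1.9 at θ_locus ≈ 1), so a
  planted positive is an outlier by construction for any seed, while
  neutral CPRs carry ordinary coalescent variation. The sign-only property
  (balancing → D > 0, sweep → D < 0 in ≥ 95 % of draws at strength ≥ 6)
  also holds on coalescent backgrounds.
* **Planted expression effects are the line effect.** For a transcript with
  a planted promoter effect, the allele class is the genetic cause: no
  additional per-line genetic noise is layered on top. Unplanted
  transcripts get Gaussian line effects scaled to the configured
  heritability (recovered within ±0.05 by variance components in the
  tests).
* **Flank LD is a two-state copying chain.** Linked flanks copy each line's
  derived/ancestral haplogroup label outward with per-bp switch probability
  `ld_decay` (closed-form flip probability per distance), giving direct
  control of r² to the promoter split; `ld_decay = 0` yields perfect LD and
  "independent" flanks are drawn at random MAF 0.2–0.5.
* **Depth tracks are noise-free.** Tracks sit at expected coverage
  (30× default) so a planted duplication is exactly 2× and the ≥ 2 ratio
  rule is exact; with sampling noise a true 2× duplication straddles the
  threshold by construction, a calibration question the generator does not
  try to answer. Gene intervals for the normalizer are placed outside
  CPR ± 250 bp so the duplication cannot inflate its own baseline.
* **TFBS plants are verified constructions.** The derived haplogroup carries
  a motif consensus and the ancestral carries it broken at 1 (patterns
  I/II) or 2 (pattern III) positions; every placement is re-scanned and the
  construction retried until the full motif set reproduces exactly the
  declared pattern, or fails explicitly.

What the generator does **not** emulate: microarray probe structure and
normalization, alternative splicing, X-vs-autosome dosage, LD decay shaped
by real recombination maps, GC-dependent or mapping-dependent depth
variation, and genuine selective genealogies (planted signatures are
patterns, not population histories). Tests passing on these cohorts show
the machinery is correct under its stated assumptions, not that real data
meet them.

## Problem sizes

Defaults are chosen for desk-scale reproduction: 10,000-replicate nulls in
tests and the acceptance script (the 100,000-replicate default of
`build_null` remains available), 150-CPR diversity summaries, 51-CPR
end-to-end runs, 300–1000 bootstrap resamples for block CIs and trees.
The acceptance script (`scripts/acceptance.py --seed N --out f.json`)
derives every random stream from its seed and completes in about a minute.

## Known limitations

* The demographic null ships with placeholder admixture parameters; outlier
  calls on real data are only as good as the supplied demographic model.
* Empirical P values are bounded below by 1/(R+1); at R = 10⁴ the smallest
  attainable two-tailed P is 2×10⁻⁴.
* The Gabriel-rule constants and the r² ≥ 0.8 fallback are conventions, not
  estimates; dense SNP windows with many uninformative pairs can produce
  conservative (absent) blocks with 29 lines.
* `minimal_mutation_sets` is exponential in the SNP count (capped at 12).
* The Welch-test criterion linking TFBS events to expression differences
  (p < 0.05 on bound vs unbound line means) is a pragmatic screen chosen
  for the final-report filter; it is not multiplicity-corrected across
  events within a CPR.
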