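# Methods

## Variant acceptance rule

Each observation is a per-site, per-sample pileup summary with
strand-split alt counts. The rule is a deterministic threshold filter,
not a genotype-likelihood model:

* frequency *f* = alt_depth / depth; accepted only if *f* ≥
  `min_frequency` (default 0.10, inclusive — "at least 10%");
* if *f* < `high_frequency_cutoff` (default 0.80, strict — "less than
  80%"), the strand bias must satisfy bias < `max_strand_bias`
  (default 0.70, strict).

Strand bias is `max(alt_fwd, alt_rev) / alt_depth`, the share of the
majority strand among supporting reads; it lies in [0.5, 1] and is the
simplest statistic consistent with "strand bias limited to less than
70%". No formula is standard for this phrase; alternatives (e.g. Fisher
strand tests) need per-strand reference counts the input schema does not
carry. `fail_reason` reports the first violated clause
(`below_min_frequency`, then `strand_biased`). Sites with depth 0 are
errors for the single-observation operations and simply non-passing in
the batch screen.

A consequence worth knowing: under a fair strand split the majority
share of *n* supporting reads exceeds 0.7 with probability ≈ 0.15–0.34
for *n* ≈ 8–14, so genuinely real variants at ~20% frequency and ~63×
coverage are rejected by the bias clause ~20% of the time. The filter's
sensitivity (measured by the test suite on planted truth, balanced
strands, Poisson(63) depth, 100 seeds) is ≈ 0.78 at frequency 0.2,
≥ 0.95 from 0.4 upward, and ≈ 1 above 0.7. Near-fixed variants — the
regime the classifier cares about — are essentially never lost.

## Cross-sample classification

Passing calls are grouped by variant key (position, ref, alt). Labels,
evaluated in this order so every key gets exactly one:

1. `shared_all` — passing in every sample; when all descendants of one
   published reference share a deviation, the parsimonious reading is an
   error in the reference assembly;
2. `emergent` — passing only in designated later samples (e.g. a biofilm
   sampled after ~100 h of selection), the signature of a suppressor
   rising within the experiment;
3. `strain_unique` — passing calls confined to samples of exactly one
   strain;
4. `other` — everything else, including keys with no passing call.

The batch report adds a `near_fixed` flag: maximum passing frequency ≥
0.90, the operational reading of "at or near 100% frequency"
(configurable). Strain-unique *and* near-fixed is the partition used
when counting fixed lineage-specific mutations; raw `strain_unique`
additionally includes occasional borderline noise calls at 10–15%
frequency.

## Codon consequence annotation

Equal-length substitutions only (SNVs and MNVs such as GC→CT); indels
are refused explicitly rather than silently dropped. Residue index is
⌈cds_position/3⌉; an MNV spanning a codon boundary yields one record per
affected codon. Translation uses the bacterial/archaeal code (NCBI
table 11) via Biopython. All external coordinates are 1-based inclusive.
Minus-strand CDS are handled by reverse-complementing the joined
segments before offset computation, and genomic alleles (given on the
plus strand, VCF-style) are re-oriented accordingly. Variants spanning a
segment boundary of a multi-segment CDS are refused.

## PROSITE matcher

`parse_prosite_pattern` implements the standard syntax (`-`-separated
elements; `x`, `[..]`, `{..}`; `(n)`/`(n,m)` repeats; `<`/`>` anchors)
with parse errors that carry the character position. Scanning tries
every offset and, for variable-length patterns, every feasible span, so
overlapping hits and multiple spans per offset are all reported —
matching how repeat positions are tabulated for RTX proteins. This is
O(length × span-range) with a small NFA per window; proteome-scale
inputs here are a few thousand residues, where exhaustive enumeration is
both fast and trivially checkable against a brute-force oracle. The
PS00330 Ca-binding signature ships as an editable config datum
(`data/ps00330.txt`) so it can track PROSITE releases; the nonamer
`G-G-x-G-x-D-x-x-x` constrains only positions 1, 2, 4 (Gly) and 6 (Asp).

## Isoelectric point

Net charge is the sum of Henderson–Hasselbalch terms over ionizable side
chains (D, E, C, Y acidic; H, K, R basic) plus the chain termini; pI is
found by bisection on [0, 14] to |Q| < 1e-4 (≈ 50 iterations; the charge
function is strictly decreasing in pH). Two pKa tables are bundled:

* `bjellqvist` (default) — Expasy-style values including
  residue-specific N-terminal and C-terminal (D/E) adjustments;
* `emboss` — the EMBOSS `iep` defaults, no terminal adjustments.

Printed pI values in the literature depend on which table produced them;
differences of ~0.1–0.4 pH between tables are normal, which is why the
set is a named, selectable parameter. A subtlety the tests respect: with
the Bjellqvist terminal adjustments, appending Asp replaces a strong
terminal acid (3.55) with a weaker one (4.55) while adding a 4.05 side
chain, so pI monotonicity under residue appending is only guaranteed for
tables without terminal adjustments.

## Cargo screen

A protein is a candidate iff all of: length ≥ `min_length` (default
1000 aa — known cargo exceed 2400 aa while typical proteins are far
smaller); pI ≤ `max_pI` (default 4.5); cysteines ≤ `max_cysteines`
(default 3); PS00330 present (switchable); and ≥ `min_nonamers` nonamer
hits starting within the final `c_term_window` fraction of the sequence
(default 0.25 — real repeats sit in the final ~6%, so a quarter is a
deliberately permissive operationalisation of "near the C terminus").
Gly/Ala-rich segments (windows of `glyala_window` = 30 aa with G+A
fraction ≥ 0.4, merged) are reported as a descriptive feature but do not
gate the verdict, since the decisive export signal is the Ca-binding
repeat region. Every failed criterion is listed, so relaxing exactly the
failing one flips the verdict — a property the tests exercise. A von
Willebrand factor A domain search is deliberately out of scope (it
distinguishes cargo families but is not an export requirement).

## Founder back-calculation

Deterministic chain with every intermediate reported:
area = vessel + n_slides × slide (defaults 231 + 7 × 15 = 336 cm²);
total cells = areal protein × area × 10⁹ / protein-per-cell (default
278 fg/cell, a literature value for a related *Desulfovibrio*);
producers = total × (1 − non-producer fraction); doublings =
elapsed/generation rounded to nearest (default; `floor` and
`continuous` provided — nearest is what turns 120 h / 6.8 h = 17.65
into 18); founders = producers / 2^doublings. Elapsed time is total
residence including the batch lead (24 h) before continuous flow.
Inputs below the detection limit (1.3 µg/cm²) are refused, not imputed.
Counts are reported both as floats and as 2-significant-figure strings,
the precision at which such estimates are meaningful. The estimate is a
lower bound: it assumes no producer loss in the effluent.

Dilution utilities: D = flow × 60 / volume (ml/min, ml, 1/h) and its
inverse; an advisory washout flag when D > ln 2 / generation time
(biofilm retention, not planktonic growth, then sustains the community).
The growth-rate fit regresses ln OD on time, by default over the
contiguous window (≥ 3 usable points) maximising R² — an automatic
exponential-phase detector that ignores lag and stationary phases — and
returns ln 2 / slope.

## Synthetic data

What the generators emulate, and what they do not:

* **Pileups.** Depth per site is Poisson(mean 63) by default (fixed
  depth available) — the standard shotgun approximation when only
  average coverage is known. Supporting reads are Binomial(depth,
  true_frequency), strand-split Binomial(alt, strand_skew). Every
  planted site is reported for every sample (non-carriers with zero alt
  reads) so the classifier sees the full frequency matrix. Noise
  variants model caller artifacts: per-site probability `noise_rate`
  over a 3.57-Mb genome, true frequency Uniform(0.01, 0.08) — below the
  10% rule, exercising the rejection path — and artifact-like strand
  skew Uniform(0, 1). Not modelled: read-level errors, mapping quality,
  indels, correlated coverage dips. Passing tests therefore show the
  rule and classifier are correct on their stated inputs, not that any
  upstream aligner is.
* **Study scenario** (`strain_divergence_plan`): three samples
  (MT-batch; MO-batch; MO-biofilm as the designated later sample), the
  twelve known MO-lineage mutations planted at frequency 0.98 in the two
  MO samples, 29 shared deviations at 0.99 in all samples, noise_rate
  2 × 10⁻⁶ (~7 spurious sites per sample; the artifact rate of the
  original caller is unknown, so this is a free knob chosen to exercise
  rejection without dominating the report).
* **Proteomes.** Planted cargo are built from a D- and C-free background
  (Glu supplies acidity) so the requested nonamer and cysteine counts
  are exact by construction and verified by an independent scan;
  composition is iteratively nudged (E↔Q swaps) into the target pI band,
  with an error after bounded attempts if the band is infeasible. Decoys
  alternate between shuffles of the non-overlapping dipeptide tiling of
  planted cargo (realistic length/composition, motifs destroyed) and
  short random-composition proteins; each decoy is screened and re-drawn
  if it would pass, so planted truth is exact. Real proteomes have
  domain structure and homology these decoys do not.
* **Reactor.** Deterministic exponential doubling, areal protein capped
  at a carrying capacity of 400 µg/cm² by default (the order of observed
  steady-state biofilms; configurable), censoring at 1.3 µg/cm² — sub-
  detection observations are emitted at the detection limit with a
  censored flag, never as quantified values. No attachment/detachment
  kinetics or measurement noise: the model is the exact inverse of the
  back-calculation, which is what makes the round-trip test exact.

All generators are deterministic given their seed; identical plans and
seeds give byte-identical outputs.

## Problem sizes in the test suite

The suite runs planted-truth recovery at 100 seeds × 9 frequencies for
filter sensitivity, 100 decoys + 2 cargo for the proteome screen, 1,000
random sequences (≤ 100 aa) for the PROSITE-vs-oracle equivalence, 50
random 30-mers against a 0.001-step pH grid for the pI solver, and the
exhaustive filter truth table for all pileups with depth ≤ 30 — sizes at
which the oracles are exact and the whole suite completes in well under
a minute on one CPU.

## Known limitations

* The variant screen takes depth as given; any mapping-quality filtering
  upstream of the pileup summary is the caller's business.
* The strand-bias statistic intentionally mirrors the published
  threshold wording; as noted above it costs sensitivity below ~30%
  frequency. Use `FilterThresholds(max_strand_bias=...)` to trade
  specificity for sensitivity.
* pI values are table-dependent; expect ~0.1–0.4 pH differences from
  tools using other pKa sets, and compare like with like.
* The founder estimate inherits every constant in the chain linearly
  (protein per cell, area) and exponentially (generation time, elapsed
  time); it is a scale estimate, reported to 2 significant figures.
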