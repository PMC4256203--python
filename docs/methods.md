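# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `sialoseq`.

## Read quality control

A read is end-trimmed: bases are removed from the 5′ and 3′ ends while
their Phred quality is below `end_q` (default 10). The trimmed read is
rejected when its mean quality is below `mean_q` (default 20) or when fewer
than 25 bases remain (the seed length — anything shorter cannot be mapped).
Rejection is a return state, not an error, and every input read ends up in
exactly one of three tallies: rejected, unmapped, or mapped.

## Read-to-CDS assignment

Mapping is exact-k-mer seeding plus banded extension, not a BLAST
reimplementation. The index stores every 25-mer of both strands of every
CDS. A read is probed at non-overlapping 25-mer windows (plus one final
window flush with the read end); each seed hit proposes a (CDS, strand,
diagonal) candidate, which is scored:

* match +1, mismatch −2, gap opening −3, each additional gap base −1;
* at most one gap opening, of at most 3 bases (configurable);
* the read must lie fully within the CDS (no overhangs, no clipping);
* identity = matches / read length, and alignments under the identity
  threshold (default 0.96) are discarded.

All CDS tying at the maximum score are returned in lexicographic id order,
capped at `max_ties` (default 5); beyond the cap the read is discarded
entirely rather than arbitrarily resolved, which keeps counts independent
of input order. A tied read adds 1 to each tied CDS by default, so the
library total R = Σ per-CDS counts can exceed the distinct-read count
(`tie_mode="fractional"` splits the read 1/k instead). The rationale for
seeding: at ≥96% identity over reads of 100–300 bases, a true alignment
contains an exact 25-mer unless errors are pathologically evenly spaced
(a read of length L with e edits always contains an exact run of at least
(L−e)/(e+1) bases), so the contract is agreement with an exhaustive
alignment oracle on realistic error loads, which the test suite checks
directly.

## Expression statistics

* RPKM = count · 10⁹ / (length_nt · total_mapped), with total_mapped the
  per-library R. Multi-library ("overall") RPKM pools counts and totals
  before applying the formula rather than averaging per-library RPKMs.
* The normalized fold-change ratio r₁R₂/[R₁(r₂+1)] is computed in both
  directions; the +1 pseudocount keeps it finite, at the cost of shrinking
  ratios when the opposite count is small (a CDS with true fold 10 and an
  opposite-group expectation of ~2 reads estimates below 10 — visible in
  the recovery tests as the dominant source of misses).
* Per-CDS testing is Pearson's χ² with 1 df and no continuity correction on
  the 2×2 table [[r₁, R₁−r₁], [r₂, R₂−r₂]]. Degenerate tables (a zero
  margin) return χ² = 0, p = 1 and are excluded from the testing family.
* Significance defaults to α = 0.05 with Bonferroni correction over the CDS
  actually tested in a contrast (r₁+r₂ > 0). With ~10⁴ tests an
  uncorrected 0.05 would be anti-conservative; `mtc=None` exposes the
  uncorrected behaviour for comparability with analyses that used none.
* An over-expression call requires both the normalized ratio ≥ fold
  (default 10) and the adjusted p < α. The fold statistic is the
  normalized ratio, not a raw RPKM ratio.
* Heat-map display normalization divides each row by its own mean after
  dropping rows with overall RPKM below 20 (row means are then exactly 1);
  row Z-scoring is available as an alternative.

## Polymorphism statistics

SNPs are accepted at depth ≥ 20 and quality ≥ 13, both boundaries
inclusive. Classification substitutes the alternate base into the
reference codon (frame 0 from base 1; CDS whose length is not divisible by
3 are rejected at load) and compares translations under the standard
genetic code — appropriate for insect nuclear genes. Stop↔sense changes
are non-synonymous; stop↔stop changes are synonymous. Multiple SNPs in one
codon are classified independently against the reference codon, the same
convention as per-site callers; haplotype-aware classification is out of
scope. Codons containing N are excluded from both the codon denominator
and the counts (such SNPs are "unset"; conservation S + NS + unset = number
of filtered SNPs is asserted in tests).

Rates are per 100 codons. Class tables average per-CDS rates with equal
weight per CDS (not length-weighted), restricted to CDS with at least one
accepted SNP; SE = sd/√n, blank for single-CDS classes; NS/S is the ratio
of the class means, not the mean of per-CDS ratios. Per-library
comparisons restrict every library to the same shared polymorphic CDS set
(the union over libraries) so the bars share a denominator.

## Functional classification

The vocabulary is an ordered list of (keyword, class, subfamily) entries
matched as case-insensitive substrings, first match wins. The bundled list
(~85 entries) covers the families prominent in triatomine saliva —
lipocalins (triabin, pallidipin, procalin, nitrophorin), trialysin,
apyrase/5′-nucleotidase, Kazal and pacifastin inhibitors, antigen 5,
odorant-binding proteins, antimicrobial peptides — plus housekeeping,
transposable-element and viral terms; it is an approximation assembled for
this package and is user-replaceable via TSV. Transposable-element
keywords only fire when the supplied TE-evidence flag is set (standing in
for a significant repeat-database profile hit); with no keyword hit, a
signal-peptide flag yields Secreted, otherwise Unknown. Both flags are
inputs: signal-peptide prediction and repeat-database searches are
external tools by design.

## Alignment summaries

A column is variable when it holds more than one distinct symbol among
{A,C,G,T,−}; ambiguity codes are missing data and never create
variability. Variable columns split exclusively: any gap makes the column
"gapped"; gap-free variable columns are substitutions, further split into
parsimony-informative (≥2 distinct bases each in ≥2 sequences) and
singleton. These identities (variable = substitution + gapped;
substitution = P-info + singleton) are enforced by construction and
asserted on every summary. Percentages are 100·count/columns at 2
decimals. One published ITS-2 figure (10 gapped positions out of 481
printed as 2.05%) does not reproduce — 10/481 = 2.08% — and is treated as
a typo; the package reports the recomputed value.

## Synthetic-data model

The generator's defaults are the study conditions: 2,000 CDS, 10 libraries
(2 stages × 5 regions), 50,000 reads per library, 300-base reads.

* **Classes** are apportioned by largest remainder to hit the configured
  proportions exactly (defaults ≈ 20% Secreted, 65% Housekeeping, 5% TE,
  0.4% Viral, 9.6% Unknown), then shuffled.
* **Lengths** are log-normal in nt (median 1,170, σ_log 0.35, clipped to
  [450, 9,000] and rounded to whole codons), giving a mean protein length
  within a few percent of ~400 amino acids. Every sequence is a valid ORF
  (ATG start, single terminal stop, no internal in-frame stop).
* **Expression** is a per-CDS log-normal baseline (σ_log = 1); 5% of CDS
  receive a multiplicative stage or region effect with fold drawn
  log-uniformly from [10, 1000], matching the magnitude range of the
  over-expressed transcripts the analysis is meant to find. Reads are
  multinomial per library with probabilities ∝ baseline × length × effect,
  positions uniform along the CDS, either strand.
* **Qualities** follow a two-component model: good reads draw Q35–40 with
  0–6 low-quality (Q2–9) bases at each end so end-trimming has work to do;
  a configurable fraction (default 5%) draws Q2–12 throughout and must
  fail the mean-Q20 filter. This is a contract-testing device, not an
  instrument error profile.
* **Errors** are independent per-base substitutions (default 0.1%).
* **SNPs** per CDS are planted at the configured class rates per 100
  codons by stochastic rounding (floor plus Bernoulli remainder) of
  rate × codons/100 — the deterministic-plus-remainder law concentrates
  class totals tightly, which is what a ground-truth generator is for,
  while per-CDS counts remain honest rates. Positions and alternate bases
  are drawn only from substitutions whose effect is provable from the
  genetic code (verified at generation time), at most one SNP per codon.
  A configurable fraction of calls (default 10%) is pushed strictly below
  the depth-20 or quality-13 threshold to exercise filtering. Default
  rates give NS/S ≈ 2.07 for Secreted, ≈ 1.0 for Housekeeping, with TE,
  Viral and Unknown intermediate-to-high.
* An optional `paralog_families` knob duplicates CDS at 97% identity to
  exercise the tied-match rule (triatomine lipocalins are an expanded,
  highly similar family); off by default.

All three generators are byte-deterministic under a fixed seed, each from
its own child generator of (seed, stage-tag), so one stage's output does
not depend on whether the others ran.

What the simulation does **not** emulate: platform-specific error and
quality profiles, coverage unevenness along transcripts, isoforms,
assembly artefacts, biological replicates (the emulated design has none),
and linkage between planted SNPs. Passing recovery tests therefore shows
the pipeline's arithmetic and decision rules are correct under clean
sampling noise, not that the study design has power against real
biological overdispersion.

## Recovery criteria and sizes

The recovery run used by the tests and the acceptance script is the full
default design (2,000 CDS × 10 libraries × 50k reads, ~55 s on one CPU).
A planted CDS counts as recovered when any contrast calls it in either
direction; false positives are calls on CDS with no planted effect.
Expected behaviour, stable across seeds: sensitivity ≈ 0.96–0.99 (misses
concentrate in planted folds near the 10× call boundary, shrunk below it
by the +1 pseudocount), FDR ≈ 0–0.01, class NS/S recovered within ~2–8%
(the Viral class, 8 CDS at these proportions, dominates the error).

## Numerical and design choices

* Coordinates are 1-based inclusive on disk (VCF convention), 0-based
  half-open internally; conversion lives only in the I/O module.
* CDS are sense-strand by construction; reads map to either strand.
* Alignment scoring constants are package choices, configurable, and
  stated above; tie-breaking is lexicographic everywhere.
* χ² via `scipy.stats.chi2_contingency(correction=False)` in the scalar
  API; the vectorized DE table uses the algebraically identical closed
  form, and tests pin both against an independent oracle to 1e-9.
* SE is always sample sd/√n across CDS.
* Haplotype labels are assigned by first appearance (numbers for ITS-2,
  letters for ITS-1, composite "CH" + number + letter); biological names
  can be supplied as a rename map.
* VCF QUAL is treated as site quality (the usual pileup-caller output);
  genotype-level fields are out of scope.

## Limitations

* The mapper is contract-equivalent to, not bitwise-identical with, a
  blastn-based counter; word statistics (E-values) are not computed.
* NS/S here is a raw per-100-codon count ratio, not a codon-model dN/dS;
  it is not corrected for the number of synonymous/non-synonymous sites
  per codon and should not be compared with ω estimates.
* The DE model is the χ²-on-totals test of the emulated study; it has no
  dispersion parameter and inherits that study's no-replicates caveat.
  For replicated designs use a count-model package instead.
* Classification quality is bounded by the keyword vocabulary; the bundled
  list recovers the generator's own descriptions exactly but is only an
  approximation to any curator's vocabulary.
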