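# Methods

## Coordinate model

All coordinates are 1-based inclusive, matching GenBank flat files and
every published mitogenome locus table (a locus at 858–868 with unit A
and 11 repeats satisfies `end − start + 1 = unit × repeats`).
Mitogenomes are circular; `circular_substring` wraps past the
linearization origin on circular records and raises (carrying the
truncated string) on linear ones. Features may wrap the origin
(`end < start`). When annotations overlap, gene assignment prefers
coding/structural features (PCG, tRNA, rRNA) over the control region;
positions covered by nothing are "Intergenic".

## SSR detection

A locus is a maximal perfect tandem run of a primitive unit (one that is
not itself a whole-number tandem of a shorter unit), reported at its
leftmost phase over whole units only. Tiers follow the organelle-SSR
convention of the source inventories:

| tier      | unit length | floor                  | default |
|-----------|------------|-------------------------|---------|
| normal    | 1–4 bp     | total run ≥ 10 bp       | `min_total_normal = 10` |
| potential | 5–6 bp     | ≥ 2 repeats             | `min_repeats_long = 2` |
| extended  | 7–10 bp    | ≥ 2 repeats             | `min_repeats_long = 2` |

The 10 bp floor is **inclusive**: the published inventories list 10 bp
loci (A×10, AT×5) as normal SSRs, so "≥ 10" is the operative rule even
though prose descriptions sometimes say "exceeds". No published example
fixes the hepta–deca repeat floor; 2 is used by analogy with penta/hexa
and is configurable. Units are reported exactly as read on the forward
strand (TA and AT are distinct loci, as in the published tables); no
canonical rotation or strand normalization is applied. Overlapping loci
with different primitive units are all retained. Scanning across the
circular origin is off by default — the published inventories are
consistent with a linear scan of the deposited rotation — and available
via `circular_scan`; an origin-spanning run then subsumes its truncated
head/tail pieces. Only perfect repeats are reported; compound or
interrupted repeats are out of scope.

The scanner is verified against an independent brute-force enumerator
(direct string comparison at every start/unit-length pair) on hundreds
of random sequences; equivalence is exact.

## SSR grouping

Loci from different genomes describe "the same" locus when their
flanking context matches. Each locus is extended to a probe of up to
60 bp of flank on each side (wrapping on circular sequences, truncating
on linear ones; flanks are capped so a probe never exceeds the genome).
Probes are compared by optimal local alignment (match +1, mismatch −2,
gap open −5, extend −2; Smith–Waterman via Biopython) and the score is
converted to a Karlin–Altschul e-value `E = K·m·n·e^(−λS)`. λ solves
`Σ pᵢpⱼ e^(λ sᵢⱼ) = 1` by root-finding and K is computed by the standard
lattice series (relative entropy H plus the random-walk correction term
σ obtained by convolving the per-column score distribution), both under
uniform base composition and cached per scheme. For the (+1, −2) scheme
this yields λ ≈ 1.333, K ≈ 0.621 — the familiar ungapped nucleotide
values. Uniform rather than genome composition keeps the statistic
deterministic across inputs; at a 1×10⁻¹⁰ cutoff on ≤ 130 bp probes the
pass/fail decision is far from the boundary for both near-identical and
unrelated flank pairs, so this choice does not move groupings.

Edges additionally require an identical repeat unit — published groups
always share the unit, and the requirement prevents chaining unrelated
homopolymer loci through AT-rich flanks (configurable). Single-linkage
connected components form groups; if a component acquires two loci from
one genome, the locus with the better best-edge e-value stays and the
other is re-seeded as a singleton. Orientation is not searched: probes
are compared as read, so reverse-complement flank matches are out of
scope. Group ids are positional (multi-member groups by leftmost member,
then singletons); published ids are not recoverable, so cross-referencing
is by membership.

## Pairwise variant calling

Intraspecific mitogenome pairs are ≥ 99% identical, so the global
affine-gap alignment (match +1, mismatch −2, open −6, extend −1, where
"open" is the cost of the first gapped base) is computed inside a
diagonal band of width `2·|len(a) − len(b)| + 200`. If the optimal
traceback touches the band edge the band is doubled and the alignment
recomputed (up to 3 retries) — on near-identical input the first band
always suffices; the retry exists for pathological input, and an
external aligned-FASTA (e.g. MAFFT output) can be supplied instead. The
band recurrence is JIT-compiled (numba); small cases are verified
against Biopython's unbanded global aligner score-for-score.

SNPs are columns where both rows carry differing unambiguous residues;
N and other ambiguity codes never produce calls, and gap-bearing columns
are excluded (they belong to INDEL regions). An INDEL region is a
maximal run of gap-bearing columns counted as one event regardless of
length; by default the run stays one region even if the gaps switch rows
mid-run ("continuous INDEL bases" is the operative rule), with
`split_by_row` providing the per-row alternative. Coding effects
translate the affected codon under translation table 5 (invertebrate
mitochondrial), honoring strand; stop gain/loss is nonsynonymous;
positions outside PCGs are noncoding; a PCG whose span is not a codon
multiple (and not flagged as an incomplete-stop record) yields NA.
Effect annotation uses the first genome's annotations — the comparison
is intraspecific, and positions are reported in both frames.

## Skew statistics

GC-skew `(G−C)/(G+C)` and AT-skew `(A−T)/(A+T)` on the reported strand —
the orientation that gives insect mitogenome reference strands their
negative GC-skew and positive AT-skew. Ambiguity codes are excluded from
numerator and denominator; an empty denominator yields NaN, never 0.
Counts over a partition of the genome sum to the whole-genome counts,
and both skews negate under reverse complement (tested properties).

## Heteroplasmy scan

A site is a heteroplasmy candidate when (i) depth ≥ 50, (ii) the minor
allele fraction (minor / (major + minor), N excluded) is ≥ 0.10, and
(iii) the one-sided binomial tail `P[X ≥ minor | n = depth, p = error/3]`
survives Bonferroni correction over all tested columns at α = 0.05. The
error rate defaults to 1% and is divided by 3 because a specific wrong
base is tested. The thresholds are package choices — the original
observation was confirmed by PCR and Sanger sequencing rather than by a
numeric rule — picked so that a ~50/50 site at thousands-fold depth is
an overwhelming call while error-rate noise is suppressed
genome-wide; all are exposed on the CLI. At depth 1,000 and true minor
fraction 0.5 the binomial power is ≈ 1, and error-only simulations over
a 16.6 kb genome yield zero calls in ≥ 19/20 replicates (both asserted
in the test suite). Annotation reports per-allele coding effects and
whether either allele creates or destroys an SSR within ±60 bp. Inputs
are count tables, so strand-bias and base-quality filters are not
possible here — a documented limitation — and the scan cannot
distinguish true within-individual heteroplasmy from pooled-individual
polymorphism; that requires sequencing individuals.

## Synthetic data

The generator emulates the study system's gross features: a ~16.6 kb
circular genome at 23.8% GC overall containing a 2,219 bp control region
at 17.5% GC (the non-CR background compensates so the genome-wide GC
lands on target), an A>T excess within the AT pool (+0.095) and C>G
within the GC pool (−0.14) to mirror the observed skews, planted SSRs
spliced in with one-base disruptors on each side so the planted run is
maximal exactly as specified, derived haplotypes with planted SNPs
(~60% inside PCG annotations) and INDELs of 1–42 bp (the longest placed
in the control region, the most variable part of real mitogenomes), and
multinomial pileups with per-base error and planted het sites.

The background is i.i.d. — no dinucleotide structure, no codon bias, no
real gene content (the dummy PCGs are random in-frame spans). Passing
tests therefore demonstrate algorithmic correctness on data with
realistic composition and scale, not performance on biological sequence
idiosyncrasies such as heteroplasmic length variants or repeat-rich
control-region structure beyond what is planted. Planted edits keep
≥ 20 bp separation, which makes the optimal alignment unique so truth
recovery is asserted exactly rather than statistically. All generators
are pure functions of (parameters, seed).

## Numerical and degenerate-input choices

* Ambiguity codes other than N are accepted on input with a warning,
  excluded from SSR units, and scored as mismatches in alignments.
* Tie-breaks: equal-count bases in a pileup rank alphabetically; group
  candidate edges are evaluated in a canonical (genome, position) order
  so results are independent of input order.
* The Karlin–Altschul σ series is truncated when a term falls below
  1e−9 (geometric decay guarantees convergence for valid schemes);
  schemes with non-negative expected score are rejected.
* Banded alignment stores scores as int64; the sentinel −10⁹ with
  half-sentinel guards prevents overflow from propagating.

## Problem sizes in tests and the acceptance script

Oracle equivalence runs 200 random sequences of ≤ 2 kb; heteroplasmy
power uses 100 replicates of a 300 bp genome at depth 1,000 and
specificity 20 error-only replicates of a 16,613 bp genome; variant
truth recovery uses full-scale 16.6 kb pairs. These sizes exercise every
code path at the scale of the real data while keeping the whole suite in
the minutes range.

## Known limitations

* No imperfect/approximate repeat detection and no repeat-evolution
  model.
* Grouping does not search reverse-complement orientation.
* The variant caller has no multi-sample VCF semantics, phasing, or
  population statistics beyond pairwise counts.
* The GenBank reader covers the feature types present in mitogenome
  records (CDS, tRNA, rRNA, D-loop, misc_feature); exotic location
  operators beyond origin-wrapping joins are not handled.
* Whether the published grouping engine's e-values derive from a full
  gapped BLAST parameterization is not documented upstream; the group
  counts reproduced here are therefore checked with a small tolerance
  (±2) while membership of non-common groups is checked exactly.
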