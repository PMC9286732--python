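# Methods

This note documents the models, parameters and design choices behind
`alleletx`, in the order data flows through the package.

## The measurement model

Each nascent-RNA read is treated as two coordinates on a haploid reference
(allele 1): the 5′ end (where Pol II initiated) and the 3′ end (the Pol II
active site), with strand, an allele tag ∈ {A1, A2, untagged} and sample
labels (organ, reciprocal cross, replicate).  Cross labels name the mother
first: in cross `A1xA2`, allele 1 is maternal.  All intervals are 0-based
half-open internally; GTF-like 1-based input is converted at the readers.
"Downstream" is always strand-aware: offset +d means position +d on the
plus strand and −d on the minus strand, and sequence context is read from
the transcribed strand (reverse-complemented on minus).

## Synthetic diploid genomes

`GenomePair` holds both haplotypes plus a variant table (SNPs and
left-anchored indels, non-overlapping, sorted).  Applying the variants to
allele 1 reproduces allele 2 exactly, and a segment-based monotone
coordinate map projects positions between haplotypes; projection is exact
outside indel footprints and clamps to the last aligned base inside them
(the vectorized form is used when projecting whole read tables).

The generator works in two phases sharing one deterministic per-locus
blueprint (a dedicated child stream of the run seed): phase one writes
promoter cassettes into random sequence — initiator dinucleotides at each
member TSS, a 10 bp G-run ending in C at the planned pause offset, forced
allelic initiator/pause SNPs and TSS-to-pause indels — and adds background
heterozygosity (defaults: SNPs 5×10⁻³/bp, 1–5 bp indels 3×10⁻⁴/bp, roughly
the divergence of two distant inbred mouse strains) outside protected
promoter cores; phase two *re-reads the finished sequences* to derive the
truth, so planted rates and pause positions are a function of the DNA
exactly as the generative model claims:

* **initiation rate** per TSS and allele:
  `base · w[dinucleotide at (−1,0)] · exp(α · AT fraction of ±5 bp,
  positions −1/0 excluded)`, with default initiator weights
  CA 1.0, TA 0.5, TG 0.25, CG 0.1 (free parameters — the qualitative
  ordering is the modeled claim, the magnitudes are not published),
  `w_other = 0.05` for non-YR initiators and α = 0.5;
* **pause position** per allele, from that allele's own sequence in local
  coordinates: the smallest-offset argmax over 20–60 bp of
  `w_C · [base = C] + w_G · (#G in the 10 bp upstream)` (defaults 2.0 and
  0.25).  Three anchoring modes: `energy` (global argmax — purely
  sequence-anchored), `pic` (fixed TSS offset), and `constrained` (argmax
  within ±2 bp of a PIC-set offset — distance anchoring dominates, the
  sequence picks the exact base).  The constrained mode is the default for
  pause-determinant studies because it reproduces both observed behaviors
  at once: an active-site C→D SNP moves the pause a base or two, while a
  TSS-to-pause indel shifts the reference-projected pause by its full
  length (regression slope ≈ 1).

Effect classes are assigned proportionally (deterministic counts, shuffled):
`none`, `abundance` (3:1 allele-1 fold by default), `shape_single` (one
secondary TSS ×4 on one allele), `shape_multi` (three secondary TSSs ×2,
split one-vs-two across the alleles — a same-direction uniform boost
renormalizes away into a single-TSS change, and direction patterns that
alternate at adjacent positions cancel in the ECDF, so neither would be a
genuinely multi-TSS shape change), `termination` (the short allele's unit
20–45 % shorter; half of these also gain a long-allele-only novel 3′ exon
and a 3× allelic stability shift), and `imprinted` (4:1 maternal fold,
applied by cross direction; strain effects are allele-linked instead —
this reciprocal-cross asymmetry is what the domain classifier exploits).

Reads: per sample and locus, TSS×allele counts are Poisson around a fixed
per-locus total (40 tagged reads per TSC per sample by default; optional
gamma-Poisson overdispersion), each read tagged with probability 0.5.
Promoter-proximal reads keep the capped 5′ end at the TSS and a 3′ end at
the allele's pause plus a symmetric geometric jitter truncated at ±4 bp; a
configurable fraction are gene-body run-on fragments with a uniform 3′ end
along the allele's own unit and a 5′ end an insert length (20–60 bp)
upstream — these carry the allelic-termination signal and the gene-body
counts.  mRNA is simulated per gene×allele×exon as Poisson with mean
(transcription rate × stability multiplier × exon kb × depth); novel 3′
exons emit only from the long allele.

What the generator does **not** emulate: mappability and alignment bias,
ligation bias, enhancer grammar, overlapping genes, polymerase pileups at
termination sites, and chromosome-scale variation in variant density.
Passing tests therefore demonstrate correctness of the analysis logic under
the stated generative model, not robustness to every artifact of real
libraries.

## Calling and testing

TSSs are bases with ≥ 5 pooled reads inside a candidate region; TSCs chain
TSSs ≤ 60 bp apart (within one region, so every TSC has exactly one parent
TSR); all tied maxima are kept as the maxTSS set, with the 5′-most used
where a single representative is needed.  maxPause is the modal allelic
3′-end base in a region (≥ 5 allelic reads; 5′-most on ties — whether the
original analysis broke ties the same way is not stated, so this is a
documented convention, not a claim).  TSS–pause pairs are valid when the
strand-aware distance is 10–50 bp on both alleles.

Abundance: exact binomial against 0.5 on summed tagged counts (replicates
and crosses pooled), BH within the analysis family, discovery FDR 0.10 and
confident-background FDR > 0.90.  Shape: two-sample KS on weighted
positions.  Because these supports are tiny and heavily tied, the
asymptotic KS p-value is very conservative; the package adds an exact
permutation mode (full split enumeration when the pooled multiset is
small, otherwise 2000 seeded Monte-Carlo label shuffles with a +1/+1
correction) and uses it for initiation- and pause-shape analyses.
Significant TSCs are classified single- vs multi-TSS by masking the member
with the largest absolute allelic difference (5′-most on ties) and
re-testing against the highest nominal p that survived the first-pass FDR;
masking that starves an allele below 5 observations means the change was
removable by construction → single.  Mislabeling is asymmetric: residual
multi-TSS signal is weaker than the full signal, so underpowered multi
events drift toward "single"; the planted-truth experiments quantify this.

The block caller is a re-implementation of the AlleleHMM idea: three
states (balanced p=0.5, A1-biased p=ρ, A2-biased p=1−ρ; ρ fixed at 0.9),
binomial emissions at informative positions (≥ 1 tagged read — the
emission model is undefined at zero coverage), symmetric switch
probability τ (grid 10⁻⁵…10⁻², selected by sensitivity+specificity against
labeled reference units, ties toward smaller τ), initial distribution
(1−2τ, τ, τ) so τ→0 forbids biased states entirely, Viterbi decoding, and
an exact binomial block p-value on summed counts.  It is validated against
exhaustive path search on small instances and against planted truth, not
against the original software, whose exact parameterization is outside
this codebase.  Domains: blocks kept when same-direction replicate
p-values Fisher-combine to ≤ 0.05 (no multiplicity correction across
blocks at this step, by design), classified strain-effect vs imprinted by
reciprocal-cross direction, then overlapping same-class calls merged
across organs.  Domain merging requires the same direction on the
strain/parent axis.

Determinant analyses always compare a significant test set against the
FDR > 0.9 ascertainment-matched control set, never against genome-wide
expectation: SNP profiles (5 bp profile bins, Fisher tests on 10 bp merged
bins, BH at 0.05), AT/base composition (initiator positions −1/0 masked),
TATA scoring (max log2-odds of a bundled PWM — a degenerate AT-rich and a
strict TATAAA-like matrix, both synthetic stand-ins and user-replaceable —
against a first-order Markov background fitted to allele 1, window −35…−20,
threshold 3, Pearson correlation of Δscore vs Δusage), and the shooting
gallery (candidate YR initiators within ±20 bp, low/high-allele ratio with
a 0.5 pseudocount, central maxTSS excluded).  The "ratio of allelic bias"
for the hierarchy is log2(reads on the stronger-initiator allele / reads on
the other), zero-count sites excluded — the exact orientation used in the
original figure is not printed, so this is a documented choice.

Pause explanations tag each same-maxTSS/different-maxPause pair by variant
classes around the short-allele pause: active site (offset 0), transcription
bubble (−10…−1), downstream (+1…+10), TSS-to-pause indel; more than one
class → "multiple", none → "unexplained".  These windows mirror the context
blocks (−20…−11 / −10…−1 / +1…+10) used for the G/C analysis; they are an
interpretation, since no exclusive partition is published.  The signed
indel convention is positive = deletion carried by the (projected) short
allele; under distance anchoring the allele missing sequence always
projects long, so planted deletions appear with negative sign — the
regressions use magnitudes.

AT windows intersect transcription units with same-strand blocks under
three rules (block starts inside the unit; ends in the strand-aware final
10 % or beyond; intersection ≤ 50 % of the unit), one window per unit
(union of qualifying intersections).  Structure change = any mRNA-level
block between 10 kb strand-aware upstream of the window and its end.
Stability = exonic mRNA / nascent gene-body counts, requiring ≥ 10
allele-specific nascent reads per allele; zero-mRNA alleles give stability
0 and are excluded from log-ratios with a flag.  The one-sided KS for
stability coupling is run per organ.

## Numerical and degenerate-input conventions

Tests that cannot run return NaN sentinels (zero totals, empty groups,
under-threshold coverage) rather than raising.  Fisher's combination clips
p = 0 to the smallest positive float with a warning.  The Fisher 2×2
odds ratio is the sample estimate ad/bc.  BH refuses NaN inputs.  All
randomness flows from explicit `numpy` Generators derived from the run
seed; there is no global RNG state, so identical (seed, config) runs are
byte-identical.

## Validation experiment sizes

The planted-truth experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 500-TSC cohorts × 10 seeds for type-I and
abundance recovery at the default 40 tagged reads/TSC/sample; 60-locus
cohorts × 5 seeds at 200 tagged reads/TSC with promoter-concentrated
libraries for shape classification (shape dissection interrogates
well-covered clusters); 400 loci for the initiator hierarchy; 30 planted
block instances plus 3 × 60-locus reciprocal-cross cohorts for HMM
validation; 300 constrained-mode loci for pause determinants; 40-locus
cohorts at ≥ 0.5 reads/bp for AT windows and 200-gene cohorts × 10 seeds
for stability coupling.  Statistical functions are checked against
independent pure-Python enumeration oracles on 1000 random instances of
≤ 12 observations per test family.

## Known limitations

Single-contig simulations; no multi-organ τ heterogeneity; the HMM uses a
fixed ρ rather than estimating it; pause-shape and initiation-shape tests
share the permutation machinery and therefore its Monte-Carlo resolution
(≥ 1/2001); the adjacency analyses take the neighbor relation as given
rather than deriving it from an annotation graph; and the stability index
ignores exon-length normalization differences between alleles except
through the simulated length factor.
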