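# Methods

## The model

A type IIB restriction endonuclease cleaves on both sides of its
recognition sequence, releasing a constant-length fragment. For *Bsa*XI
the recognition motif is `ACNNNNNCTCC` (equivalently `GGAGNNNNNGT` read
from the other strand); the excised fragment is 33 nt — 12 nt upstream of
the plus-form motif and 10 nt downstream (flanks swapped for minus-form
occurrences) — with 3-nt 3′ overhangs at both ends. Each recognition site
therefore defines exactly one sequencing locus ("tag") whose position and
sequence are computable from the reference genome; classical type IIP RAD
enzymes (*Eco*RI, *Sbf*I, *Hin*dIII) instead produce two variable-length
tags per site. All coordinates in the package are 0-based half-open (BED
convention).

Because a 33-bp fragment ligates the two adapters in either orientation,
a locus is sequenced from either strand with roughly equal probability.
Both orientations are reduced to one canonical key by reverse-complementing
any tag carrying `GGAG` at offset 10 and `GT` at offset 19 into the
`AC…CTCC` form (`AC` at offset 12, `CTCC` at offset 19). Canonicalization
is idempotent, and a tag and its reverse complement map to the same key.

## Scanning and window simulations

Motif scanning expands IUPAC codes to character classes and uses a
zero-width regex lookahead so overlapping occurrences are all reported.
Genome `N` bases never match any code: gapped assemblies must not produce
phantom sites. Self-complementary motifs are counted once per occurrence
on the provided strand; for *Bsa*XI both degenerate forms are scanned and
the orientation recorded. On i.i.d. uniform sequence the expected site
density is 2·(1/4)⁶ per position (two forms, six fixed bases each), which
the test suite verifies on a 10-Mb seeded sequence.

The window simulation tiles each sequence into non-overlapping 4000-bp
windows (the average spacing of *Eco*RI sites, i.e. one expected RAD site
per window), discarding trailing partial windows so the occupancy classes
stay comparable; a site belongs to the window containing its motif start.
Classes are 0 / 1 / ≥2 sites = no anchoring / unoriented anchoring /
oriented placement of a scaffold of that size.

## Library construct and barcode design

The stored construct sequences are the printed ones: adapter-1 common arm
(33 nt, the 3′ end of the 58-nt multiplexing PCR primer 1.0), adapter-2
top strand (34 nt, reverse complement of the 3′ 34 nt of the 64-nt index
primer). The amplicon is 58 + b + 33 + 64 bp for a b-nt barcode, hence
160–164 bp across the 5–9-nt barcode range. A 50-bp single-end read is
barcode + tag + adapter-2 read-through (12 nt with the shortest barcode).

Barcode validity means: length 5–9; every pair ≥ 2 apart by Levenshtein
distance (Hamming is ill-defined across unequal lengths); prefix-free (an
inline, variable-length barcode must have an unambiguous boundary); and no
*Bsa*XI site contained or recreated in the ligated context for *any*
completion of the degenerate 3-nt overhang — the context checked is
adapter-1 arm + barcode + overhang + a fully degenerate insert, a match
counting only when every fixed motif base lands on a concrete base. The
designer greedily extends the set with seeded random candidates, cycling
through the requested lengths and preferring the candidate that minimizes
per-position base-composition imbalance (color balance on the sequencer).
The objective is a heuristic; the constraints are hard. A distance-2
packing bound (4^(L−1) codewords per length) rejects impossible requests
immediately.

Overhang-targeting fractions are computed by exhaustive enumeration of all
4^(2L) ordered overhang pairs, a spec matching both ends: one fixed base
per end (`NNF`) keeps (4²/4³)² = 1/16 of *Bsa*XI fragments, and `NF` keeps
(4/4²)² = 1/16 of *Alf*I fragments.

## The two-step read filter

Step 1 assigns a read to a sample by its barcode prefix: an exact match
wins; otherwise a *unique* barcode at Hamming distance 1 wins; zero or
several candidates at the best tier leave the read unassigned (ambiguity
is discarded rather than guessed). A barcode is only tested when the read
retains a full 33-mer after trimming it. Because validated sets have
pairwise distance ≥ 2, one sequencing error can never silently reassign a
read to the wrong sample — it either still matches uniquely or becomes
ambiguous.

Step 2 accepts a trimmed read iff its first 33 bases contain no `N` and
match either positional fragment form; only the six fixed bases of a form
(`AC`+`CTCC` or `GGAG`+`GT`) are constrained, the degenerate positions may
be any concrete base. Survivors are canonicalized; the remainder of the
read (adapter read-through) is discarded. Quality scores play no role —
the filter is purely sequence-based. With per-base error e, the expected
site-filter rejection rate among barcode-matched reads is
1 − (1 − e)⁶, which the suite checks against simulation.

Rejected-but-barcode-matched reads can be classified against a genome by
exact lookup of their leading 33-mer on either strand; a hit is consistent
with a between-site fragment that survived size selection (the dominant
real-world contaminant), as opposed to sequencing noise. Exact matching is
a documented simplification of mismatch-tolerant alignment.

## Coverage accounting

The expected site universe is the reference's in-silico digestion. Sample
tags are assigned to reference tags exactly or, optionally, tolerating one
substitution with a uniqueness requirement (a tag hitting several sites is
discarded, mirroring unique-mapping alignment; an option splits such tags
fractionally instead). Coverage rate = sites with ≥ 1 assigned read ÷
total expected sites; depth = assigned reads ÷ total expected sites — the
denominator is deliberately the *total*, not the covered subset, because
both conventions exist and the saturation tables use this one. Under
uniform Poisson depth λ the expected coverage is 1 − e^(−λ), the
closed form the acceptance suite checks at λ ∈ {1, 5, 10, 20}; saturation
curves subsample assigned reads without replacement under a fixed seed.

## Genotyping

Loci are anchored to reference tag sites rather than assembled de novo —
the principal simplification relative to catalog-based stack assembly, and
a natural one here because the simulator always provides the reference.
Two consequences are handled explicitly:

- **Anchoring tolerance.** A parent allele may differ from the reference
  tag by up to two substitutions (the catalog-merge tolerance), so
  genotyping observations are anchored at Hamming distance ≤ 2 using
  pigeonhole banding (three 11-nt bands; any 2-mismatch neighbour shares a
  band exactly). Distance ties and repeated reference tags leave a read
  unanchored.
- **Error-read absorption.** Sequences seen fewer than 2 times at a locus
  do not form alleles; they are merged into the closest real allele within
  2 substitutions and otherwise dropped — the minimum-coverage
  primary/secondary-read rule of standard stack assembly. Without this,
  a single passing error read (expected in ~35 % of depth-20 stacks at
  e = 10⁻³ · 22 degenerate positions) would turn a homozygous stack into a
  spurious heterozygote.

A sample call at a locus is: missing below total depth 2; otherwise with
f = frequency of the second allele, hom(top) when f < 0.010, het(top two)
when f > 0.011, and missing in the deliberately uncallable band between
(the band replaces automated call correction). aa × bb markers are sites
where both parents are hom for different alleles ≤ 2 substitutions apart;
progeny genotypes map hom(parent-A) → aa, hom(parent-B) → bb, het with
exactly the parental pair → ab, anything else → missing. Markers with
missing rate ≥ 0.20 are dropped; survivors are tested against 1:2:1 with
the asymptotic χ² (df = 2, no continuity correction, expectations from
non-missing counts only) and dropped at p < 0.01. At F2 sample sizes of a
dozen the exact multinomial tail is a step function whose jumps reach
~0.07, so the asymptotic p-value tracks the exact (mid-p) tail within 0.02
only in the rejection-relevant region p < 0.1 — which is where the filter
decides — and within the discreteness bound elsewhere; the suite tests
exactly that.

## The synthetic-data generator

The generator emulates the study design it is meant to exercise: an F2
cross between two homozygous parents, 12-plex inline-barcoded libraries,
single-end 50-bp reads. Defaults are the study conditions: 277 progeny,
per-site Poisson depth 10, per-base substitution error 10⁻³, a fair
strand-choice coin per read, and between-site contaminant fragments making
up 25 % of reads (from the published accounting: ~30 % of barcode-matched
reads fail the site filter and ~86 % of those map to the genome).
Contaminants are generated as *additional* library molecules so the
configured λ remains the true per-site depth. Tests and examples scale the
genome, site count and progeny number down to desk scale; the package
chooses sizes so that each statistical assertion retains its power (e.g.
~600 markers × 200 progeny for parameter recovery).

Specifics worth knowing:

- Genomes are i.i.d. uniform A/C/G/T; planted sites are written at evenly
  spaced jittered positions, alternating motif forms, and the site truth
  is the full rescan of the finished sequence (background occurrences
  included).
- Parent B's substitutions are placed only inside tag footprints, never on
  fixed motif bases, and are rejected if they would create or destroy any
  motif occurrence in the local context — both parents digest
  identically, so allele dropout through site destruction is off by
  default.
- F2 genotypes segregate independently at (¼, ½, ¼) by default; an
  optional linked mode forms gametes per chromosome with
  Poisson-distributed crossovers over a configurable map length.
- Errors are substitution-only (an indel would shift the fixed-offset
  filter and behave as read loss, which is how the real filter treats it);
  quality strings are constant because the filter ignores them.
- Everything is bit-reproducible given the seed; per-read truth records
  sample, site, strand, error count and contaminant status.

What passing on this generator does *not* show about real data: no PCR
duplicates, no GC or restriction-efficiency bias, no quality-correlated
error profile, no indels, no reference/sample divergence beyond the
planted SNPs, and uniform rather than empirically dispersed depth. The
closure results (≥ 99 % genotype recovery at λ = 20) are therefore a
correctness statement about the pipeline's logic, not a performance claim
about any real library.

## Numerical and design choices

- Overlapping motif occurrences are all counted; orientation ties at one
  position are impossible (the two forms differ at fixed bases).
- Tag uniqueness defaults to exact-duplicate detection; the
  mismatch-tolerant mode (all-pairs, Hamming ≤ 2) is an explicit opt-in
  for desk-scale genomes.
- *Alf*I participates in site counting and overhang arithmetic only; its
  tag geometry is not modeled.
- Barcode design, subsampling and all simulator draws funnel through
  seeded generators; the CLI exposes a single `--seed`.
- Degenerate inputs raise configuration errors (zero window size, empty
  barcode set, zero expected sites, out-of-range rates) rather than
  returning sentinel values; rejections inside the read filter are data,
  not errors, and carry reasons.
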