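# Methods

`almirna` re-implements, as a tested library, the computational chain used
to identify miRNAs in barley small-RNA libraries from an Al-stress
experiment contrasting the Al-tolerant Tibetan wild accession XZ29 with the
Al-sensitive cultivar Golden Promise (GP): read preprocessing and
contaminant subtraction, hairpin-criteria classification into known / new
member / candidate miRNAs, counts-per-million normalisation with log2
fold-change responsiveness rules, complementarity-based target prediction,
and degradome (PARE) validation of cleavage sites.  Because the original
sequencing libraries are not publicly deposited, a first-class synthetic
experiment generator defines the study conditions and provides ground truth
for every downstream stage.

## Preprocessing

Raw 50-bp single-end reads carry the small-RNA 3' adapter.  Trimming takes
the insert before the leftmost full adapter occurrence, or before the
longest adapter prefix (>= 6 nt by default) at the read end.  Reads then
pass a fixed bin precedence — adapter failure, length (valid inserts are
18–25 nt), junk/low complexity, Rfam-style ncRNA, mRNA, repeats, valid —
and every read lands in exactly one bin, so the accounting table reconciles
raw = valid + removed exactly per library.  Junk is defined operationally
(the source tooling leaves it undefined): any N, a single base at >= 80% of
the length, or a 2-periodic repeat covering >= 80%.  Contaminant
subtraction is exact substring matching against each reference class on
both strands, in the precedence order above; exactness keeps the stage
deterministic and oracle-checkable, at the cost of missing inexact
contaminant copies (a real aligner-based chain tolerates mismatches).

## Folding engine and hairpin criteria

Secondary structures are predicted by a Nussinov-style minimum-energy
dynamic program over nested structures with AU/GC/GU pairs, a minimum
hairpin loop of 3 nt, and the energy model

    E(S) = sum e_pair + sum e_stack + LOOP_PENALTY * (non-stacked closing pairs)

with `e_pair` = −2.0 (GC), −1.1 (AU), −0.5 (GU) kcal/mol, a stacking bonus
of −0.3·(w(p)+w(q)) with w = 2.0/1.0/0.5 for GC/AU/GU, and a flat loop
initiation penalty of +3.0 kcal/mol charged to every helix-closing pair not
stacked on an inner pair (hairpin, bulge, internal and multibranch loops
are penalised uniformly).  This model is intentionally small: it is not the
Turner free-energy set, but every constant is documented and the DP optimum
is verified against exhaustive enumeration of all nested structures for
short sequences (the test suite checks 500 random sequences up to 28 nt).
Ties in energy are resolved toward more base pairs — encoded exactly in an
integer-scaled DP objective — with remaining ties fixed by a deterministic
leftmost-pairing traceback.  Because the table depends only on unordered
pair types, the model is symmetric under sequence reversal (reverse
*complementation* is not an energy symmetry once G:U wobbles are admitted:
complementing a G:U pair yields the unpairable A:C).

MFE-derived metrics follow the standard definitions: AMFE = MFE/length×100
and MFEI = |AMFE|/GC%, the usual discriminator of genuine pre-miRNAs.

Candidate precursors must satisfy ten structure criteria: (1) <= 12 nt in
any one stem bulge, (2) >= 16 stem pairs, (3) MFE <= −15 kcal/mol,
(4) hairpin length strictly between 50 and 200 nt, (5) <= 4 nt in any one
bulge in the mature region, (6) <= 2 biased errors in one mature bulge,
(7) <= 2 biased bulges in the mature region, (8) <= 4 errors (unpaired
bases) in the mature region, (9) >= 12 base pairs in the mature region,
(10) >= 80% of the mature sequence inside the stem.  Terms the criteria
leave undefined are fixed here as conventions: the *stem* is every paired
position outside the terminal loop; a *bulge* is a maximal unpaired run
between consecutive stem pairs on one strand; an *error* is an unpaired
mature position; a bulge is *biased* when its two strand-side runs differ
in length, its biased-error count being that difference.  Structures that
are not a single stem-loop are rejected before criteria evaluation.

## Classification

Tags matching a mature reference end-gap-free with <= 2 internal
substitutions and <= 3 nt of 5'/3' length variation are *known* miRNAs and
inherit the reference name.  Tags failing that but lying on one arm of a
reference precursor (substitutions only, <= 4 nt protrusion into the
terminal loop; arms come from folding the precursor) are *new members*.
Remaining tags with an exact genome hit (multi-hit cap 20) seed candidate
discovery: the 120-nt flank windows (5'-extended, 3'-extended, full) around
the hit are folded and the candidate is accepted if any excised stem-loop
around the mature site passes all ten criteria.  Excision — testing every
enclosing single-terminal-loop helix level around the mature site — is
necessary because genuine hairpin loci sit in genomic context: folding the
whole 260-nt window almost always adds incidental helices in the flanks, so
a naive single-stem-loop requirement on the full window would reject
essentially every true locus.  Precedence is known > new member >
candidate; candidates are named PC-miR&lt;k&gt; over lexicographically
sorted tags so numbering is input-order independent.

## Expression and responsiveness

Counts are globally normalised to counts-per-million of valid reads per
library; replicates are averaged after scaling.  The per-genotype fold
change is log2(Al/control) on condition means.  Zeros are not
pseudocounted: exactly one zero yields an EXCLUSIVE sentinel
(treatment-exclusive presence), two zeros yield ABSENT — this preserves the
genotype-exclusivity concept (a miRNA absent from one genotype is counted
as *exclusive*, not *unchanged*, in that genotype's column, which is also
how the packaged published table reconciles its printed 0.00 entries).
Regulation thresholds are inclusive: up iff fc >= 0.5, down iff
fc <= −0.5, else unchanged.  A miRNA is Al-responsive iff (1) its maximum
normalised value over the four genotype × treatment conditions exceeds 100
reads, (2) for newly found (candidate) miRNAs the precursor MFEI exceeds
0.85, and (3) it is up, down or treatment-exclusive in >= 1 genotype.  No
replicate-aware significance testing is performed — the procedure being
reproduced uses thresholds only, so there is nothing to correct for
multiple testing.

## Target prediction and degradome validation

Targets are scored with the standard plant complementarity penalty scheme:
mismatch 1.0, G:U wobble 0.5, bulged nucleotide 1.0, all doubled at miRNA
positions 2–13 (5' end = 1), at most one single-nucleotide bulge, cutoff
4.0.  The transcriptome scan is vectorised over window starts with numpy
prefix sums and agrees with the explicit single-duplex scorer, which is in
turn checked against exhaustive alignment enumeration.  The predicted
cleavage site is the target base paired to miRNA position 10 (position 11
when 10 itself is bulged).

Degradome reads are anchored by their first 20 nt with exact sense-strand
matching; multi-mapping reads count 1/n.  The signal at a predicted
cleavage site is ranked 0–4 against its transcript profile (0: unique
maximum with > 1 read; 1: shared maximum above the transcript mean; 4:
exactly one raw read; 2: above the mean; 3: non-zero), evaluated in that
order; Y requires category <= 2 by default.  The mean is taken over all
transcript positions.  These category definitions follow the widely used
degradome convention; the threshold and anchor length are configurable.

## Synthetic experiment generator

The generator emulates the study design: 2 genotypes × 2 treatments × 2
replicates (8 libraries) plus one pooled degradome library.  Defaults,
chosen once as the study conditions:

- 20 planted loci — 10 known, 5 new-member, 5 candidate — with mature
  lengths dominated by 21 nt (known/new) and 24 nt (candidates); each
  precursor is a perfect-stem hairpin (6-nt extensions, 8-nt weakly pairing
  loop) verified at generation time to pass all ten criteria with
  MFEI > 0.85, embedded in a 100-kb random genome with >= 240 nt between
  loci so flank windows never span two loci.
- Library depth 1e6 reads; read = insert + adapter padded to 50 nt.
  Contaminant budget fractions mirror the bins of a typical small-RNA run:
  adapter-less 20%, sub-18-nt fragments 5%, junk 1%, Rfam 12%, mRNA 20%,
  repeats 0.2%; the remainder is valid, with filler genome fragments
  absorbing the per-library difference so every library has the same
  expected valid total (this keeps true fold changes equal to log2 of the
  planted effect factor after CPM normalisation).
- Counts per tag per library are negative binomial with dispersion 0.1
  (variance m + 0.1 m²), a standard overdispersed model for sequencing
  counts; dispersion 0 emits exact expected counts (the deterministic
  limit used by exact-recovery tests).
- Effect factors: strong responders at 4.0 or 0.25 (|log2 fc| = 2), two
  high-expression unchanged known miRNAs at 1.0, remaining unchanged loci
  at low expression (below the 100-CPM responsiveness floor, as most
  detected miRNAs in a real run are), and three genotype-exclusive
  candidates (factor 0 in the absent genotype) mirroring the
  wild-accession-exclusive candidates the design anticipates.  At
  dispersion 0.1 with two replicates the sampling sd of log2 fc is ~0.46,
  so a high-expression truly-unchanged miRNA is falsely called responsive
  roughly half the time; with two such loci planted the responsive-set
  Jaccard against truth averages ~0.94 over seeds, and the recovery check
  is therefore defined on the 10-seed mean.
- Degradome: per true target, signal reads start exactly at the cleavage
  site (opposite miRNA positions 10–11) at fraction 0.5 of 1000 reads per
  transcript; background reads cover *other* positions uniformly, so a
  zero-signal simulation yields N for every pair exactly.

What the generator does **not** emulate: real barley genome composition and
repeat structure, sequencing errors (off by default; a substitution rate is
available), quality-score variation, isomiR end heterogeneity, and
inexact contaminant copies.  Passing recovery tests therefore demonstrate
the correctness of the analysis chain under its stated assumptions, not
performance on real libraries.

## Numerical choices and degenerate inputs

Energies are integer centi-kcal internally; the DP tie-break uses an exact
integer combined objective (energy × 1024 − pairs).  Folding accepts 1–300
nt; zero-GC sequences make MFEI undefined (an error).  Zero-total libraries
are a named error in normalisation.  All randomness flows through numpy
Generators seeded from the run seed; identical configuration reproduces
byte-identical artifacts, and the run manifest records SHA-256 digests per
stage to make this checkable.

## Known limitations

The energy model ranks structures plausibly but its absolute energies are
not calibrated to experiment; criteria (3) and the MFEI threshold therefore
bind against this model's scale, not RNAfold's (planted hairpins clear both
with wide margin, so conclusions about the pipeline logic are unaffected).
Candidate discovery requires an exact genome hit; isomiRs of a candidate
with untemplated ends would be missed.  Degradome mapping is exact and
sense-only.  The published-table reproduction exercises the regulation-call
rules on printed fold changes; the upstream read-level quantities of the
original study are not reproducible without its unreleased libraries.
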