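# Methods

This note documents the models and conventions behind `curesmir`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Read cleanup and library statistics

Reads are unified to the RNA alphabet internally (T→U); output preserves the
input alphabet. Cleanup removes, in order: non-nucleotide sequences, reads
shorter than `min_len` (default 15 nt, the lower edge of the usable sRNA size
range), and — the *singleton rule* — unique sequences whose summed count
across all libraries is 1, i.e. detected only once, in a single library. We
deliberately do **not** drop sequences with count 1 in one library but >0 in
another: shared sequences are informative regardless of their per-library
count, and the alternative reading would deplete the shared partition.
Cleanup is idempotent.

Comparison statistics partition unique sequences of two libraries into shared
(count > 0 in both) and specific. Denominators: unique percentages use the
size of the unique-sequence union; total-read percentages use the grand total
over both libraries. Mean frequency is reads per unique sequence, per library
for the shared partition. Percentages print half-up at two decimals — the
convention of published library tables; note that a partition rounded this
way can sum to 99.99 or 100.01.

TPM uses the library's clean-read total as denominator (not mapped reads):
normalization happens library-wide, before any mapping step, so TPM values of
residual subsets remain comparable across stages.

Annotation assignment is exact substring containment in class sequence sets,
first match in priority order tRNA > rRNA > snRNA > snoRNA > mRNA; unmatched
reads form the "others" residual that feeds discovery. No mismatches are
allowed — annotation classes are abundant housekeeping RNAs for which exact
fragments dominate.

## Homology search

The comparison between a read and a reference mature is an ungapped sliding
alignment: at each relative offset, the distance is the Hamming distance over
the overlap plus every position of the longer footprint left unmatched
(so a length difference of *d* costs at least *d*, and shifting two
equal-length sequences costs the shift). The minimum over offsets is the
reported mismatch count; the default acceptance threshold is 3. Indels are
not modeled: plant mature miRNAs are 19–24 nt and conserved families differ
by substitutions and end-shifts, both of which this distance captures. G:U is
a **mismatch** here — sequence identity, not structure, defines family
membership. Ties between references at equal distance break
lexicographically by reference id, making candidate annotation deterministic.

## Precursor folding and validation

Windows of ±300 nt around a transcript hit are folded at minimum free energy
with ViennaRNA. Known kilobase-precursor families (default: miR858, whose
precursors run from roughly 1.5 kb upward) use ±4000 nt directly; all other
candidates retry at the wide flank if the standard window fails validation,
so unusually long precursors of novel families are still found. Windows
longer than 700 nt are folded with a 700-nt maximum base-pair span: miRNA
hairpins are local structures, and the cap keeps kilobase windows tractable
without affecting the duplex.

A hairpin is accepted when

1. the mature lies entirely on one stem arm (no partner inside the mature
   span, all partners on one side — otherwise "loop overlap");
2. a star span can be derived on the opposite arm: the region pairing the
   mature, shifted +2 nt to produce the canonical 2-nt 3′ overhangs on both
   duplex ends (unpaired mature ends are bridged from the nearest paired
   position, so bulged duplexes keep a full-length star);
3. duplex mismatches ≤ 5 (default): mature positions not paired into the
   duplex, excluding the 2-nt overhang; G:U wobbles count as *paired* here —
   structure, unlike family membership, tolerates wobbles;
4. asymmetric bulges within the duplex ≤ 3 nt.

The ceilings leave margin above the 4-mismatch duplexes observed in real
conserved families while rejecting random foldbacks: dinucleotide-shuffled
precursors fail validation in >90 % of trials (enforced by test). The
reported precursor is trimmed to the minimal stem-loop containing mature and
star plus 10 nt flanks. Star detection status distinguishes stars seen in
this experiment's libraries, in supplementary libraries, or not at all.

## Genome localization, promoters, cis-elements

Locus finding assumes precursors near-identical to the genome (same species,
possibly a different cultivar): exact 20-mer seeds tiled along the precursor,
each seed hit extended to a full-length ungapped comparison, accepted at
≥95 % identity (default), both strands, coordinates projected onto the
forward strand. This finds diverged paralogous copies down to ~95 % without a
general aligner; a copy whose every 20-mer tile is mutated would be missed,
which at ≥95 % identity is unlikely for precursors ≥100 nt.

Promoters are the 2000 nt upstream of the precursor's 5′ end on its strand
(reverse-complemented for minus-strand loci), clipped and flagged at
chromosome ends. Cis-element motifs are plain IUPAC strings from a
user-supplied table (a small demo catalogue ships in
`curesmir.genome.DEMO_MOTIFS`); scanning is exact under IUPAC expansion, both
strands, overlapping hits included, positions reported relative to the
feature start (−1 = the base just upstream). Proprietary promoter-database
matrices are out of scope.

## Degradome target calling

Target alignment slides the reverse complement of the miRNA along the
transcript, ungapped (published plant duplexes are length-preserving);
miRNA position *i* (5′→3′) faces transcript position `window_end − i + 1`.
Per-position states are match / G-U wobble / mismatch; wobbles never count
toward the mismatch total, whose default ceiling of 6 admits the weakest
printed duplexes.

Degradome tags are mapped by exact sense-strand occurrence; each occurrence
contributes its count at its 5′ position. Abundance is TP10M
(count / library size × 10⁷). The cleavage window is the three transcript
positions facing miRNA positions 9–11; the call is the window maximum, ties
resolving to the position facing miRNA position 10 (the canonical slicing
site), then to the smaller coordinate. Categories are computed over
transcript positions holding ≥1 raw tag — including zero-coverage positions
would pin the median at 0 for nearly every transcript and inflate Category
II. Category I requires the site to equal the transcript-wide maximum *and*
that maximum to exceed the occupied-position median: on a flat profile the
"maximum" is everywhere and carries no evidence, so such calls fall to
Category III. Category II is strict (`median < peak < maximum`); a peak
exactly at the median is III. Multiple degradome libraries are analyzed
independently and merged only in the summary, which reports per-library
categories, the best (lowest) category, and a representative alignment
chosen by fewest mismatches, then fewest wobbles, then miRNA id.

## Expression quantification

Fold change is the plain TPM ratio treatment/control — sRNA differential
expression here involves one library per condition, so no dispersion
modeling. log₂FC is kept at full precision internally and reported half-up
at two decimals. Zero control TPM raises an error unless a pseudocount
(customarily 0.5) is supplied; the quantified panels this mirrors contain no
zeros, so the degenerate case is surfaced rather than silently patched.

2^−ΔΔCt: technical replicates are averaged within each biological replicate
first; ΔCt = gene mean Ct − reference-gene mean Ct per biological replicate,
averaged per sample; ΔΔCt is taken against a calibrator sample, whose
relative expression is exactly 1 by construction. Dispersion is the SD of
per-replicate relative expression. Heatmap export uses −ΔΔCt (calibrator
column exactly 0); missing gene/sample combinations are flagged, never
imputed. Amplification-efficiency correction is out of scope.

## Synthetic-data generator

The generator plants exact ground truth and emulates the statistical shape of
a two-condition leaf sRNA experiment:

* **Hairpins** are built constructively: stem = mature opposite a modified
  reverse complement, loop drawn from {A, C} so it cannot pair internally,
  random pads to the requested precursor length (defaults 80–160 nt, plus
  one kilobase-scale precursor of 1600 nt mirroring the miR858 situation).
  Designed duplex defects sit ≥3 nt apart away from the duplex ends:
  mismatches use bases that can neither Watson–Crick nor wobble pair;
  designed wobbles are G:U-compatible substitutions, exercising the separate
  wobble accounting. Because random pads occasionally offer competing
  pairings, each construct is folded once with the discovery-stage window and
  parameters and the pads/loop are re-drawn (seeded, deterministic) until the
  realized duplex matches the design — construction with verification, so
  truth coordinates are exact under MFE folding rather than merely likely.
* **Star geometry**: the planted star is the duplex-geometry span (+2 shift),
  so a correct `derive_star` recovers it byte-for-byte.
* **sRNA libraries**: design counts for matures (log-uniform ~80–3000 with
  per-condition fold changes of ±2.5 log₂ units), stars at 2–10 % of their
  mature, ~1500 background unique reads with the canonical 21/24-nt-dominant
  length structure over 15–44 nt, a designed shared fraction (default 0.27)
  in which shared reads carry much higher counts than specific ones,
  annotation-derived fragments, degradation fragments, and planted
  cross-library singletons (always emitted with count exactly 1). Emitted
  counts are multinomial draws at the requested depth (default 120,000 reads
  per library — scaled to keep the full pipeline fast while leaving every
  per-read expectation ≥2); `NoiseSettings.off()` emits the design verbatim
  for exact-recovery checks.
* **Degradome**: per-transcript position weights place the designed fraction
  of a target transcript's tags at the cleavage position (Category I: 0.5),
  an off-site dominant peak for Category II designs, and a raised background
  whose occupied-position median exceeds the site signal for Category III;
  non-target transcripts get uniform background. Tags are 20-nt transcript
  subsequences; sampling is multinomial (default depth 100,000) with a
  deterministic expected-count mode for exact recovery.
* **qPCR**: Ct = base + ΔCt + Gaussian noise per technical replicate, 3
  biological × 3 technical by default, with a reference gene at ΔCt 0, so
  designed 2^−ΔΔCt values are recovered exactly at zero noise.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: sequencing error and adapter artifacts, expression-
versus-GC biases, multi-mapping reads between paralogous precursors,
transcript isoforms and splice variants, degradome tags from non-miRNA decay
pathways, and amplification-efficiency differences between qPCR assays. The
synthetic validation demonstrates algorithmic correctness (exact recovery of
planted structure under the stated models), not robustness to every
real-world artifact.

## Numerical conventions

* Rounding for report columns: half-up (away from zero) at two decimals.
* All coordinates 1-based inclusive; minus-strand genomic loci are projected
  onto the forward strand and store the reverse-complemented mature.
* Ties: homology references lexicographic; cleavage calls to the position
  facing miRNA 10, then smaller coordinate; representative alignments by
  (mismatches, wobbles, id).
* Folding is deterministic for a fixed ViennaRNA version; the 700-nt pairing
  span cap applies only to windows longer than 700 nt.
* Empty inputs: zero-depth library requests warn and return empty; empty
  annotation warns and classes everything "others"; an empty degradome
  profile is an error for categorization.

## Problem sizes

The default test and demo configuration uses 5 planted miRNA families (one
with a 1600-nt precursor), 3 × 20-kb chromosomes, one diverged paralog per
precursor where paralogy is exercised, ~1700 unique reads per library at
120,000 reads depth, 100,000 degradome tags, and 3 × 3 qPCR replicates —
small enough for the whole suite to run in about a minute on one CPU while
every statistical check retains 4σ headroom.

## Known limitations

* Homology search is substitution/shift-based; a family diverged by true
  indels inside the mature would score poorly.
* Locus finding requires one exact 20-mer; heavily diverged (<95 %) or
  rearranged loci are out of reach by design.
* Annotation filtering is exact-match; a read overlapping an rRNA fragment
  with one sequencing error lands in "others".
* Category assignment depends on the occupied-position median, which is
  sensitive at very low degradome coverage; calls on transcripts with only a
  handful of tagged positions should be treated with caution.
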