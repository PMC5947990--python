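# Methods

## Problem and approach

Knock-in of short epitope tags (V5, 3XFLAG, HA, Myc) at a protein's
C-terminus by Cas9-stimulated homology-directed repair works best when the
double-strand break falls just downstream of the stop codon — close enough
for efficient HDR, but inside the 3'UTR so that the inevitable NHEJ indels
at the cut site cannot disrupt the reading frame. `epitag` automates the
resulting design task: pick guides by cut-to-stop distance, efficiency and
specificity, and assemble a single-stranded donor (≤200 nt, the practical
ceiling for commercial ultramer synthesis) that inserts the tag in frame
immediately 5' of the stop codon and cannot be re-cut after integration.

## Coordinates and the design region

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
inclusive) is converted at the parsing boundary. The design region is a
stop-codon-centred window of **spliced transcript sequence on the coding
strand**: `window_nt // 2` bases before the first stop base and the
remainder (stop codon included) after, truncated with a warning where the
transcript ends. The default window is 200 nt and the floor is 46 nt (one
23-nt Cas9 site on each side of the stop). Each region base carries its
genomic coordinate, so designs round-trip exactly to the genome even when
the window crosses a splice junction (a warning notes the divergence).

Two GTF dialects disagree on whether the CDS includes the stop codon. An
explicit `stop_codon` feature is authoritative; otherwise the last three CDS
bases are tested against {TAA, TAG, TGA}, and failing that the three exonic
bases after the CDS are tried. Transcripts with no locatable stop, a CDS not
divisible by three, a stop codon split across exons, or no 3'UTR are skipped
with a logged warning — for C-terminal tagging there is nothing to design
downstream of such stops, and guessing coordinates silently would be worse
than refusing.

## Guide model

Candidates are every N20-NGG match on either strand of the region; windows
containing N are rejected. The cut site is the blunt break 3 nt 5' of the
PAM (between protospacer positions 17|18) — the standard SpCas9 geometry.
The **cut-to-stop distance** is defined bond-to-base: `cut_offset − (stop_offset
+ 3)`, so 0 means the cut bond abuts the last stop base, positive values are
3'UTR-side, negative values cut inside or upstream of the stop. This
convention is recorded in the run metadata because "distance from the stop
codon" is otherwise ambiguous by ±3 nt.

Ranking uses three hard filters and a tiered sort:

- hard: the cut base must be labelled 3'UTR; aggregate specificity ≥ 50
  (configurable floor); in batch mode, distance ≤ 30 nt;
- tier 1: distance within the preferred 8–15 nt window; then descending
  on-target score; ties broken by ascending distance, then protospacer
  lexicographic order (a total order — input permutation cannot change the
  output);
- the top 2 survivors are returned (configurable `top_k`).

Treating the preferred window as a strict first-tier key, the on-target
score as the within-tier key and specificity as a floor rather than a sort
key is a design choice: proximity is the dominant predictor of tagging
success, predicted efficiency is noisy, and specificity is a veto-style
criterion ("do not order this guide") rather than a preference. All three
knobs are exposed in `DesignConfig`.

Guides whose protospacer overlaps the CDS are allowed as long as the cut is
in the UTR; only the cut position threatens the reading frame.

## On-target score

The Rule Set 2 featurization of the 30-nt context (4 nt upstream +
protospacer + PAM + 3 nt downstream) is implemented in full — position-
specific nucleotide and adjacent-dinucleotide indicators, position-
independent mono/dinucleotide counts, protospacer GC count with low/high
indicators, and the NGGN PAM-variant block — with stable feature names so an
externally trained linear model can be supplied (`--model weights.tsv`,
columns `feature`, `weight`, optional `intercept` row). The trained
gradient-boosted weights of the published model are not bundled; they are an
external artefact, and shipping a re-trained approximation would invite
silent disagreement with it.

Without a model the pipeline uses a deterministic fallback:
`0.5·gc_term + 0.5·run_term`, where `gc_term = max(0, 1 − |GC20 − 10|/10)`
and `run_term` is 0 if the protospacer contains a homonucleotide run ≥ 5,
else 1. This keeps the score in [0, 1], rewards the same gross features the
trained model rewards (balanced GC, no homopolymers), is self-contained and
exactly testable — but it is a heuristic, not a validated efficiency
predictor, and ranking between guides with similar distance tiers should be
read accordingly.

## Off-target search and specificity

The scanner reports every 20-mer on either strand of the genome within
Hamming distance ≤ 3 of the protospacer whose adjacent PAM is NGG or NAG.
It is an exhaustive, numpy-vectorised sliding comparison — equivalent to
(and tested against) a literal per-position loop — rather than a seed-based
aligner search, so it cannot miss mismatch placements that defeat seeded
heuristics; it is strictly at least as sensitive as a 3-mismatch short-read
aligner run. N in the genome never matches. The on-target locus itself is
reported but flagged `is_self` and excluded from aggregation. Desk-scale
genomes (≤ a few Mb) scan in seconds; whole mammalian builds are supported
but not required by the test suite.

Specificity follows the MIT scheme with the Hsu et al. (2013) position
weights (position 1 PAM-distal … 20 PAM-proximal):

- single hit, m ≥ 1: `100 · ∏(1−W_p) · [((19−d̄)/19)·4 + 1]⁻¹ · m⁻²`;
- d̄ is the mean gap between consecutive mismatch positions (the behaviour
  of the original web implementation), with d̄ = 19 when m = 1 so the
  distance term is 1;
- m = 0 scores 100 by convention;
- aggregate: `100·100 / (100 + Σ single-hit scores)` over non-self hits.

NAG hits are weighted identically to NGG in the aggregate (the PAM class is
reported per hit so users can post-filter); the published scheme defines no
NAG penalty and inventing one here would change ranking invisibly.

## Donor design

Arms are symmetric: `arm = ⌊(cap − tag)/2⌋` with the stop codon budgeted
inside the 3' arm — the only convention under which the catalogue arm table
(66→67, 42→79, 30→85, 27→86 under a 200 cap) is internally consistent; odd
remainders leave one nt of the cap unused (HA: 199 nt total). Arms below 30
nt ("insufficient homology") are an error; regions too short for the
nominal arms truncate both arms symmetrically with a warning.

PAM blocking is decided in this order:

1. **none_needed** — the insertion point falls strictly inside the
   protospacer+PAM span, so the integrated allele no longer contains the
   site. Skipping the edit keeps the donor maximally faithful to the
   reference; `always_block` forces an edit anyway for users who prefer
   belt-and-braces.
2. **PAM_NGG_to_NGC / NGT** — both PAM G bases lie in the 3'UTR: the
   PAM-proximal G is substituted (NGC default; NGT offered since both are
   standard practice). Neither NGC nor NGT is cleavage-licensing.
3. **silent_CDS** — a PAM G is coding: the alphabetically first synonymous
   codon alternative that both breaks the site and does not recreate an
   NGG/NAG at the register.
4. **conservative_CDS** — no synonymous option (Trp/Met codons): the
   single-base substitution minimising, lexicographically,
   |Δ Kyte–Doolittle hydropathy| then charge-class change (D/E negative,
   K/R/H positive, others neutral) of the altered residue. The hydropathy
   scale and charge classes are recorded in the run metadata.

The stop codon itself is never edited. After assembly the donor is
re-checked for an intact protospacer+NGG at the original register
(`residual_protospacer_match`); a surviving site is a hard error. The oligo
is emitted on the PAM strand (the guide's strand) by default, with a
`nonpam` flag because complementary-strand donors are also effective and
occasionally synthesise better.

## Batch mode and plate layout

Targets fill wells row-major A1→A12→B1→…→H12, spilling onto further plates
past 96; control wells (well → transcript map) are reserved on every plate
before targets are placed. Row-major order is a convention choice exposed in
the plate map output. Design failures (no guide within the batch cap, no
assemblable donor) are **rows with machine-readable reasons**, not process
errors; only I/O and validation faults exit non-zero. Genotyping amplicon
prediction is pure arithmetic — knock-in size = wild-type size + tag length
— with a warning outside the 400–600 bp range convenient for agarose
resolution of the two alleles.

## Synthetic fixtures: what they do and do not show

`epitag.fixtures` generates seeded, byte-reproducible genomes and GTFs with
planted truth. Background sequence is drawn from {A, T} and planted
protospacers from {A, C, T} with no CC dinucleotide, so **every** NGG/NAG
site and every ≤3-mismatch neighbour in the fixture genome is planted and
recorded: candidate enumeration, ranking, off-target recovery and donor
edits can be verified against exact expectations, on both transcript
strands. Decoy off-target loci are written at exact Hamming distances with
chosen PAM classes on a separate chromosome.

This design is deliberately adversarial to false positives but not
representative of real genomes: fixtures have no GC-rich regions, repeats,
pseudogenes, overlapping sites, realistic PAM densities or multi-exon
UTRs (splice handling is covered by hand-built multi-exon toys in the unit
tests). Passing the suite therefore demonstrates the correctness of the
coordinate arithmetic, filters, scores and assembly — not the biological
hit-rate of the heuristic on-target score, which only external trained
weights can provide. Planted sites must sit ≥23 nt apart (site spans would
otherwise collide); the generator refuses overlapping plants rather than
silently shifting them.

## Numerical and degenerate-input choices

- IUPAC ambiguity codes other than N are normalised to N on genome load;
  non-IUPAC characters are an error with position. N poisons any overlapping
  candidate window and never matches in the off-target scan.
- Ranking ties end at protospacer lexicographic order, making every output
  list a pure function of the input set.
- The crRNA ordering oligo is protospacer (T→U) + a configurable 16-nt
  repeat (canonical SpCas9 repeat prefix by default; commercial two-part
  systems use proprietary variants of the same length, so only the 20+16=36
  geometry is contractual). The 67-nt tracrRNA constant is metadata.
- Scores are clipped: model predictions to [0, 1]; MIT scores are bounded in
  [0, 100] by construction.

## Known limitations

- The fallback on-target score is a stand-in ranking heuristic; supply
  trained weights for efficiency-critical designs.
- Off-target search is mismatch-only (no DNA/RNA bulges) and NGG/NAG-only.
- Transcripts whose stop codon spans a splice junction are rejected, not
  designed.
- Tags are inserted only at the C-terminus, immediately before the stop;
  linkers, N-terminal and internal insertions are out of scope.
- Problem sizes in the test suite (fixture genomes up to ~100 kb, 50–97
  transcript batches) were chosen as comfortably desk-scale; all operations
  scale linearly in genome length.
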