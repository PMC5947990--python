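# epitag

Design tool for CRISPR/Cas9 **C-terminal epitope-tag knock-in**: given a
genome, a transcript annotation and an epitope tag (V5, 3XFLAG, HA, Myc or a
custom in-frame sequence), `epitag` selects stop-codon-proximal SpCas9 guides
and builds matched single-stranded oligodeoxynucleotide (ssODN) repair
templates, in single-target and 96-well batch modes. It is aimed at groups
doing selection-free HDR tagging in mammalian cell lines, where the design
bottleneck is picking a guide that cuts just downstream of the stop codon and
ordering a ≤200-mer donor that cannot be re-cut after integration.

## What it computes

For a transcript with stop codon at offset *s* in a 200-nt stop-centred
window of spliced coding-strand sequence:

- **Candidate guides** are all N₂₀NGG matches on either strand. The cut site
  is the blunt break 3 nt 5′ of the PAM; the cut-to-stop distance is
  `cut_offset − (s + 3)` (0 = cut bond abutting the last stop base).
- **On-target efficiency** uses the full Rule Set 2 featurization of the
  30-nt context (4 nt + protospacer + NGG + 3 nt) with a pluggable linear
  model; without external weights, a documented deterministic fallback
  (GC-balance + homopolymer-run penalty) keeps scores in [0, 1].
- **Specificity** is the MIT aggregate score `100·100/(100 + Σ single-hit)`
  over an exhaustive genome scan for ≤3-mismatch matches adjacent to NGG or
  NAG PAMs; single hits score
  `100·∏(1−W_p) · [((19−d̄)/19)·4+1]⁻¹ · m⁻²` with the Hsu et al. (2013)
  position weights *W*.
- **Ranking**: cut in the 3′UTR and specificity ≥ 50 are hard filters;
  guides cutting 8–15 nt after the stop form the first tier, then higher
  on-target score wins; batch mode caps the distance at 30 nt and the top
  two guides are emitted, each with a 36-nt crRNA ordering oligo
  (protospacer + 16-nt repeat; the constant tracrRNA is a 67-mer).
- **ssODN donors** insert the tag immediately 5′ of the stop codon between
  symmetric homology arms of `⌊(200 − tag)/2⌋` nt (stop codon budgeted in
  the 3′ arm): 67/79/85/86 nt for the 66/42/30/27-nt catalogue tags. A
  PAM-blocking mutation (NGG→NGC in the UTR, a synonymous — or failing that,
  hydropathy/charge-conservative — codon change in CDS) prevents re-cutting;
  no edit is made when the insertion itself splits the target site. Donors
  are emitted on the PAM strand.

## Worked example

No external downloads are needed: the package generates deterministic
synthetic fixtures with planted, truth-recorded design sites.

```sh
cat > fixspec.json <<'EOF'
{"seed": 3, "n_transcripts": 4, "cut_distances": [[5, 28], [12, 40]],
 "offtargets": [{"tx_index": 0, "guide_index": 0, "mm": 2, "pam_class": "NGG"}]}
EOF
epitag fixtures --spec fixspec.json -o fix
epitag design --genome fix/genome.fa --annotation fix/annotation.gtf \
              --transcript TX001 --tag V5 -o out
```

prints

```
wrote 5 chromosomes, 9 truth rows to fix
TX001: 2 guide(s) designed
```

and `out/design.tsv` contains one row per guide, e.g. (columns abridged):

| rank | cut_to_stop | ontarget | specificity | ssodn_len | arm5_len | mutation_plan |
|------|-------------|----------|-------------|-----------|----------|----------------|
| 1    | 28          | 0.80     | 100.00      | 200       | 79       | 136:G>C:PAM_NGG_to_NGC |
| 2    | 5           | 0.75     | 93.25       | 200       | 79       | none_needed    |

Neither planted site on TX001 cuts inside the preferred 8–15 nt window, so
the tier falls back to on-target score: the distance-28 guide ranks first
and its UTR PAM is changed NGG→NGC in the donor. The rank-2 guide cuts 5 nt
after the stop — the tag insertion itself splits its target site, so its
donor needs no blocking edit; its specificity of 93.25 reflects the one
planted 2-mismatch decoy. Both V5 donors are exactly 200 nt with 79-nt
arms. `out/oligos.fa` holds the ssODN and the 36-nt crRNA ordering oligo for
each guide; `out/guides.bed` has the genomic site intervals.

Batch mode takes a target list and emits a plate map (row-major A1…H12,
spilling to further plates past 96 targets, with repeatable control wells):

```sh
epitag batch --genome fix/genome.fa --annotation fix/annotation.gtf \
             --targets targets.tsv --tag V5 --control A1:TX004 -o plate
```

## Scope

`epitag` designs C-terminal tag knock-ins only (tag immediately before the
stop codon, guides cutting in the 3′UTR). It does not design primers
(genotyping amplicon sizes are predicted from user-supplied primer
coordinates), long dsDNA/plasmid donors, N-terminal or internal insertions,
or guides for non-NGG nucleases. See `docs/methods.md` for the model
conventions, parameter defaults and limitations.
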