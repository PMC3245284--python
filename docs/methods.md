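# Methods

## The inference problem

A genomic segment containing a gene can reach a new locus by three routes
that leave different sequence signatures. A **direct DNA copy** preserves
segment order and intron content. A **circular DNA intermediate** — the
segment is excised, circularized, re-linearized at a new cut point and
inserted — preserves intron content but cyclically rotates the segment
order: if the ancestral footprint is A…D with internal points B (= the cut)
and C, the duplicate reads [B…D][A…B], i.e. the downstream half precedes the
upstream half. A **retrocopy** (reverse transcription of the spliced mRNA)
loses every intron. `circdup` classifies a candidate duplicate by reading
exactly these signatures from the sequences.

## Anchors and synteny blocks

`find_anchors` reports every maximal exact match (MEM) of length ≥
`min_len` on both strands. Matches are seeded with a `min_len`-mer hash of
the source, extended greedily in both directions, and de-duplicated per
diagonal; `N` never matches anything. Default `min_len` = 20: at the 0.5–1%
per-site divergence the analysis is designed for, exact-match runs between
copies average 100–200 bp, so 20-mers tile every homologous segment
densely while 20-mer chance hits between unrelated sequence of the tens-of-
kilobase scale used here are ≪ 1 per comparison.

`chain_blocks` performs greedy highest-score chaining (score = summed
anchor length, ties broken by leftmost target start): consecutive members
must be co-strand with source gap, target gap and diagonal drift each ≤
`max_gap` (default 2000 bp, an order of magnitude above the expected
anchor spacing at 1% divergence). Blocks are the hulls of their chains;
blocks with target span < `min_block_len` are dropped (default 500 bp for
end-user runs; the ground-truth recovery harness uses 50 bp so rotations
whose cut falls near the excision edge still produce two blocks). A
best-first overlap filter keeps blocks from stacking on the target.

Maximal exact matches rather than unique matches were chosen because
duplicated genes make uniqueness brittle; chaining resolves the ambiguity.
Greedy chaining rather than a full weighted LIS is sufficient because
blocks in this problem are few and long.

## Mechanism classification

`order_signature` sorts blocks by target start and records the permutation
π of source-order ranks plus per-block strands and inter-block gaps.
`classify_mechanism` then decides in fixed order:

1. **retrocopy** if an intron report from the spliced mapping shows every
   intron absent — intron loss is decisive and overrides block order.
2. **single_block** if only one block exists: one dotplot box cannot
   distinguish a direct copy from a circular intermediate (and a rotation
   by 0 is *definitionally* a direct copy — the documented degeneracy), so
   the package refuses to guess.
3. **circular_intermediate** if all strands are `+`, target gaps are within
   `tgt_slack` (default 1 kb — the duplicate footprint must be contiguous)
   and π is a non-identity cyclic rotation. A two-block co-oriented swap
   [1,0] counts: with consistent strands it cannot arise from an inversion.
   A strand-inconsistent swap is excluded (reversal guard) and falls to
   `complex`.
4. **direct** for the identity rotation with a contiguous target footprint.
5. **complex** otherwise.

Source gaps may exceed target gaps by up to `max_src_gap` (default 50 kb)
before forcing `complex`: sequence inserted into the **source** after the
duplication sits inside the ancestral footprint without touching the
duplicate, and a note records when this tolerance was used. Consequently a
plain direct event is reported `single_block`, while a direct event whose
source footprint was later interrupted by an insertion shows ≥ 2
identity-ordered blocks and is called `direct`; the recovery harness
simulates direct events with such an insertion for exactly this reason.

**Circle length.** For a rotation, the blocks lie on exactly two diagonals
(source start − target start); the difference of the two diagonals equals
the length of the circularized segment. This estimator is exact at zero
mutation rate and insensitive to the ±few-bp jitter that chance
micro-homology puts on block ends, which a span-sum estimator is not. Any
positive source gap at the rotation junction (post-duplication insertion at
the cut) is subtracted. Direct calls use the contiguous target footprint.

**Breakpoints.** Block-hull boundaries are refined by ungapped X-drop
extension along the block diagonal (match +1, mismatch −3, stop when the
running score drops 12 below its maximum; the boundary is placed at the
score argmax). This recovers breakpoints to within a few bases at 0.5–1%
divergence. Exact recovery is information-theoretically impossible when
bases flanking the true breakpoint coincide by chance (probability 1/4 per
base, geometric tail), so recovered breakpoints carry an inherent ±few-bp
ambiguity even on unmutated copies.

## Breakpoint neighborhoods

Flanks default to 100 bp per side. Inverted/direct repeat search
enumerates, per diagonal of the (a, revcomp b) comparison, all maximal
windows with at most `max_mismatch` mismatches and length ≥ `min_len`
(default 8, mismatch 0); `min_len` < 4 is rejected as noise (two random
100-mers already yield ~0.13 chance 8 bp hits). Motif scanning honors IUPAC
codes and reports overlapping and minus-strand occurrences; the default
panel is {GCAAAC, CAGGG}, user-extensible. Repeat annotation is homology to
a user-supplied library via the anchor/chain machinery (12 bp anchors,
fragments reported at ≥ 80% identity over ≥ 30 bp); de novo repeat
discovery is out of scope. At 10% fragment divergence the exact-match
anchors thin out and a planted fragment may be missed, but it is never
mislabelled — the failure mode is silence, not error.

## Spliced mapping and ORF diagnostics

`splice_map` anchors the mRNA to the locus (18 bp minimum anchor), selects
the best collinear chain by dynamic programming, and converts diagonal
jumps ≥ 4 bp into introns. The exon boundary at each junction is placed at
the GT..AG-consistent split nearest the anchor junction, searched within
±10 bp; the GT..AG structure itself eliminates ±1-shifted candidates (the
shifted donor would have to start with the intron's own T/G), which is what
makes the round trip on simulator genes exact. A junction admitting no
GT..AG split is still reported as an intron but logged as a splice-site
warning rather than an error, since pseudogene copies degrade their sites.
Diagonal losses < 4 bp are absorbed as small indels within the exon, so an
exon's genomic and mRNA lengths may differ and frame bookkeeping sees the
difference. Intron length 0 encodes exons that are genomically adjacent
without an intron. Exon calls cover the full mRNA including UTRs; ORF
checks use only the CDS span.

`check_orf` translates the mapped CDS, records cumulative frame per exon
(mapped exon length vs mRNA exon length, mod 3) and every internal stop
with its exon and codon offset; a mapping is intact iff it has no internal
stop and ends with a stop codon. `exon_skip_rescue` exhaustively re-splices
and re-translates every subset of internal coding exons up to `max_skip`
(default 2) and returns the minimal subsets restoring an intact ORF —
reporting the rescue possibilities without deciding whether a damaged copy
is a pseudogene or a short-isoform template, which sequence alone cannot
settle.

## Synonymous divergence and dating

`ng86_sites` counts expected synonymous sites per codon over the nine
single-nucleotide neighbors, excluding stop-codon neighbors from the
denominator at their position, so S + N = 3 per codon exactly.
Multi-difference codons are averaged over all minimal mutational pathways,
excluding pathways through stop codons (all pathways are used only if every
one is blocked). Observed proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)p), defined for p < 3/4; saturation is flagged, not
thrown. Codon pairs come from a protein-level global alignment (match 1,
mismatch 0, gap −1, deterministic tie-break) back-mapped to codons, with
gapped and stop-containing columns dropped.

Dating uses T = Ks / r by default with r = 5.5×10⁻⁹ synonymous
substitutions per site per year. This per-pair convention reproduces the
reference arithmetic this package is calibrated against (0.0152 / 5.5×10⁻⁹
= 2.76 My); the textbook per-lineage convention T = Ks / 2r is available by
flag. Whether a published rate is meant per lineage or per pair is often
ambiguous — both conventions are exposed so the choice is always explicit.

## The simulator and what it does (not) show

`make_gene_locus` builds a locus with a multi-exon gene: default 24 exons
with translation starting inside exon 2 and stopping inside exon 23 (22
coding exons, UTR on the first and last), GT..AG introns, a spliced CDS
that starts with ATG, contains no internal stop and has codon-multiple
length. Default exon lengths 80–200 bp and introns 400–800 bp put the gene
span near 17 kb so that 20–30 kb excisions — the scale of the events the
analysis targets — fit inside an 8 kb-flanked source locus.
`simulate_duplication` copies (direct), rotates (circular, by a uniform cut
unless specified) or splices (retrocopy) the segment into a target locus,
mutating the inserted copy only, i.i.d. substitutions at the configured
rate (an indel rate is accepted but defaults to 0 so anchor recovery has a
clean accuracy surface). Decoy insertions into the source, flanking motif
copies, inverted-repeat pairs at the excision boundaries and labelled
repeat fragments are planted with full ground-truth records.

Background sequence is i.i.d. uniform A/C/G/T. The simulator therefore does
**not** emulate compositional bias, tandem repeats, segmental duplications
in the background, sequencing or assembly error, or indel-rich divergence.
Passing recovery tests show the inference is correct when homology is
unambiguous and divergence is substitution-dominated at ≤ ~1%; they do not
certify performance on repeat-dense real assemblies, where anchor
uniqueness — not the permutation logic — becomes the binding constraint.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; GFF3 output alone is
  1-based.
- All randomness flows from integer seeds through `numpy` generators;
  identical seeds give byte-identical outputs, including pipeline reports
  (timestamps are excluded by design).
- Chaining tolerates 50 bp of member overlap (maximal matches around a
  substitution overlap by construction).
- The duplicate is inserted on the + strand by default; a
  reverse-complement flag exists but co-oriented events are the default
  study condition.
- Recovery conditions: excision 20–30 kb uniform, circle cut uniform over
  the excised segment, mutation rate uniform in 0.5–1%, 50 seeded events
  per mechanism. The residual 0–4% failure rate in circular recovery is
  the documented edge degeneracy: a cut within ~50 bp of the excision
  boundary leaves the second block below the chaining floor, and the event
  is (correctly, from the evidence) reported `single_block`.

## Known limitations

- Inversions and translocations inside the duplicated footprint are lumped
  into `complex`; no probabilistic scoring of mechanisms is attempted.
- Spliced mapping assumes the gene is co-oriented with the mRNA (+ strand).
- NG86 with Jukes–Cantor is the classical counting estimator; no
  maximum-likelihood codon models, rate heterogeneity or confidence
  intervals beyond the simulation-based calibration check.
- Repeat annotation requires a library; fragments below ~70% identity to
  their library entry are usually invisible to exact-match anchoring.
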