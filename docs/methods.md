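# Methods

This note records the model, parameter conventions and numerical choices
behind `plastovar`. Units are base pairs (bp) unless stated; rates are
expected events **per site per unit branch length**.

## Quadripartite structure detection

The inverted repeat is found directly from the sequence, with no
annotation input:

1. **Seeding.** All exact k-mer matches (k = 25) between the genome and
   its reverse complement are collected. A match between position `i`
   (forward) and `j` (reverse strand) votes for the anti-diagonal
   `i + j`; a genuine inverted repeat places all its seeds on one
   anti-diagonal.
2. **Clustering.** Votes are grouped into clusters along the
   anti-diagonal axis (gap tolerance 1 000 bp); the largest cluster is
   taken as the IR candidate.
3. **X-drop extension.** The candidate is extended outwards base by
   base with match +1 / mismatch −3, stopping when the running score
   falls 20 below its maximum; the boundary is the last scoring
   maximum. This lets the detected repeat tolerate isolated mismatches
   without being dragged past the true junction.
4. **Acceptance.** The repeat must be at least `min_ir` (default
   1 000 bp) long with at most `max(2, 0.01 × length)` internal
   mismatches; otherwise `StructureNotFound` is raised (CLI exit
   code 4).

The four junctions JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and JLA
(IRa/LSC) follow from the detected arms. IR symmetry is expressed by a
*mirror diagonal*: position `x` in one arm pairs with
`mirror_diag − x` in the other, which is also how a gene spanning JSA
projects a truncated, reverse-complemented **pseudo-copy** onto the IRb
side (pseudo-*ycf1* overlapping *ndhF*).

Note one boundary subtlety: the only junction-adjacent base pair an
X-drop extension can test by chance is (first SSC base, last SSC base);
the LSC-side partner index falls outside the genome. A single
complementary pair there extends the *true maximal repeat* by 1 bp —
the detector is reporting the genome's actual maximal inverted repeat,
not an error.

## Junction report conventions

For each junction the nearest gene on each side is reported with its
distance (0 = abuts the junction; negative = the gene crosses it) and a
`spans` flag with the bp extent on either side. Distances are computed
in modular (circular) coordinates.

## Region extraction

Regions are extracted with one IR copy dropped (default IRb) so
duplicated content is counted once:

- **CDS** exons are spliced (multi-exon genes contribute one spliced
  sequence; the trans-spliced *rps12* is split into `rps12-5p` and
  `rps12-3p` because its exons are not co-linear).
- **Introns** are named `<gene>-intron` (or `-intron1/2`).
- **Intergenic spacers (IGS)** are named `<left>-<right>` from the base
  gene symbols (anticodons stripped); a second occurrence of the same
  pair gets an `@2` suffix. The spacer wrapping the circular origin is
  kept as one region of two intervals.

Homologous regions are grouped across taxa by name; an IGS observed in
the opposite orientation in some taxon (after an inversion) is
flip-renamed and reverse-complemented into the reference orientation.
Groups missing from any taxon are flagged incomplete and excluded from
variability summaries.

## Alignment

Pairwise alignment is an affine-gap Gotoh 3-state dynamic program:
match +1, mismatch −1, gap open −4 (charged on the first gap base), gap
extend −1. Multiple alignment is progressive: a guide tree from 8-mer
count distances (UPGMA via `scipy.cluster.hierarchy.linkage`), then
profile–profile merges. Group merges use **free end gaps**: terminal
gaps are charged extend-only (−1/bp) rather than fully free — fully
free terminal gaps admit degenerate staircase alignments between
diverged profiles, while extend-only keeps ends cheap but anchored.
Pairwise scores were validated exactly against Biopython's
`PairwiseAligner` under the same scoring scheme.

## Variability statistics

Counting follows the DnaSP conventions for gapped alignments:

- Columns containing a gap are excluded from the site tallies
  (invariable / variable / parsimony-informative).
- A gap-free column with `k` distinct bases contributes `k − 1`
  substitutions; it is **parsimony-informative** if at least two states
  each occur in at least two rows.
- An **indel event** is a distinct gap interval `(start, end)` observed
  in any row — shared gaps count once.
- `SV% = (subs + indel_events) / (subs + indel_events + invariable) ×
  100`; `PIS% = PIS / (sites excluding gap columns) × 100`. Zero
  denominators yield 0.0 with a warning.

Class summaries aggregate raw counts over all regions of a class before
forming percentages (not averages of percentages). The
substitution:indel ratio is `subs / indel_events` (∞ when no indels).
Distance trees use uncorrected p-distances (gap-containing columns
skipped per pair) and scikit-bio neighbor joining.

## Simulator

The simulator is the package's ground-truth generator, not a biological
sequence evolution model. Its design goals are (a) realistic plastome
*structure* and (b) an exactly replayable mutation log.

**Ancestor.** A genome is built from an ordered list of *segments*
tiling the IR-masked circle: gene exons and introns from a bundled gene
map (113 unique genes by default — 79 protein-coding, 30 tRNA, 4 rRNA,
with the classic motifs: trans-spliced *rps12*, *ndhF* reaching 56 bp
into IRb, *ycf1* spanning JSA with a pseudo-copy at IRb, *rps19* fully
duplicated in the IR), separated by random spacers (≥ `min_igs`,
default 120 bp) drawn to hit the configured partition lengths
(defaults: LSC 85 000, IR 27 000, SSC 17 000). Background GC is set per
partition (LSC 0.355, SSC 0.313, IR 0.426). IRb is never stored: it is
always rebuilt as the reverse complement of IRa, so the two IRs
co-mutate and `ir_mismatches` is 0 by construction. One base adjacent
to the SSC junctions is adjusted, if needed, so the planted IR is
*exactly* the maximal inverted repeat (see the boundary subtlety
above). The assembled SSC is `ssc_len − 56` because *ndhF*'s 56-bp
overhang lives in the IR arm.

**Evolution.** On each branch, per segment: indel count ~
Poisson(rate × branch length × length), each indel a 50:50
insertion/deletion with geometric length (mean 3, cap 50); then
substitution count ~ Poisson(·), uniform over the three alternative
bases, placed outside freshly inserted ranges so the event log maps
cleanly to ancestral positions. Default per-class rates (subs / indels):
CDS 0.032 / 0.0004, IGS 0.092 / 0.023, intron 0.0448 / 0.01375, other
0.012 / 0.0006 — ordering IGS > intron > CDS, with CDS substitutions
strongly dominating CDS indels. Per-region multipliers, planted
gene-block inversions (with edge-spacer renaming) and LSC→IR boundary
shifts can be assigned to named branches; a shift moves bases from the
terminal LSC spacer into the IR (both copies, via the mirror) and must
fit inside that spacer — a larger request is rejected rather than
silently truncated, since gene capture by the IR is not modelled.

**Truth.** Every event is logged with ancestral-position ids. Any tip
can be replayed base-for-base from the log (`replay`), and expected
per-region alignment statistics are computed from the log
(`truth_expected_stats`) with an `exact` flag that is true when no two
events collide on the same ancestral positions; for such regions the
full pipeline (extract → group → align → classify) is expected to
reproduce the truth counts exactly, and in measured runs does so for
≥ 96 % of exact-flagged regions (the residual being equally-scoring
alternative gap placements).

**What the simulator does not model.** No rate heterogeneity beyond
class and per-region multipliers (no Γ across sites), no
transition/transversion bias, no codon or selection model, no base
composition drift, no tandem-repeat slippage, no IR loss, and no
independent evolution of the two IR copies (co-mutation is structural;
IR boundary dynamics are studied via the explicit `ir_boundary_shift`
mechanism instead). Gene lengths are typical magnitudes, not any
accession's. Simulated variability levels are set by the default rates
above; empirical claims about real taxa require real data.

## Configuration and reproducibility

All randomness flows from a single integer seed through
`numpy.random.default_rng` / `SeedSequence`; identical seeds give
byte-identical outputs (tested). The `compare` pipeline's knobs (IR
detection threshold, dropped IR copy, alignment scores, ranking metric,
top-N) live in a validated YAML config; unknown keys and type
mismatches are rejected with every offending key named (CLI exit
code 2).
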