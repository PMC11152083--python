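# Methods

## The comparative ΔSNP scan

The scan targets lineage-specific divergence in a focal genome given a
multiple alignment with *k* ≥ 3 related species. Divergence between the
focal species and any single relative mixes changes on the focal branch
with changes on the relative's branch; contrasting each focal comparison
against comparisons *among* the non-focal species cancels the shared
component. The procedure:

1. **Windowing.** The focal (reference) genome is tiled with
   nonoverlapping windows of `window_size` (default 10,000 bp; a trailing
   partial window is kept). Window ids are `scaffold:index`.
2. **Counting.** For each species pair, every reference position carrying
   an unambiguous A/C/G/T is an *aligned base* of the pair when the
   partner row also has an unambiguous base in that alignment column, and
   a *SNP* when the two bases differ. Soft-masked lowercase counts as its
   base (masking steers the aligner, not the count); IUPAC ambiguity codes
   other than A/C/G/T behave like N (not aligned). Control pairs (neither
   member the reference) are counted in the same columns and assigned to
   reference coordinates, so every comparison lives on one window grid.
   Reference positions covered by more than one block are counted once —
   first block wins, multiplicity is logged. This single-counting rule is
   a deliberate, reproducible contract; alignment tools differ in how they
   expose duplicated alignments, and the choice is surfaced rather than
   inherited silently.
3. **Filtering.** Windows need at least `min_aligned` aligned bases
   (default 3,000 bp ≈ the least-aligned 1% at 10-kb windows) in **every**
   analyzed pair; requiring all pairs keeps a single window set common to
   all comparisons. Whether a zero-aligned window is "missing" or merely
   "thin" is irrelevant under this rule: anything below the floor is out.
   The W chromosome and scaffolds classed `exclude` are dropped;
   autosomes and the Z chromosome are analyzed as separate strata
   throughout, because the avian Z evolves measurably faster than the
   autosomes (fast-Z) and a pooled Z-transformation would let Z windows
   crowd the tail.
4. **Standardization.** SNP proportions are Z-transformed (sample sd,
   n−1) within each (pair × chromosome class) stratum over filtered
   windows only. A stratum with fewer than two values or zero variance is
   an error, not a silent pass-through.
5. **Contrast.** ΔSNP(w, f) = z_f(w) − max_c z_c(w) per focal comparison
   *f*. The orientation matters: the statistic as sometimes written
   ("subtract focal from the control maximum") would make focal-specific
   divergence *negative*; selecting high focal-specific divergence with a
   top-quantile rule requires focal − max(control), which is what the
   selected-window ΔSNP ranges reported in comparable scans (all
   positive) imply. We adopt focal − max(control) and flag the ambiguity
   here.
6. **Selection.** Per focal comparison and class, the threshold is the
   empirical `quantile` (default 0.99) of defined ΔSNP values under
   linear interpolation (`numpy.quantile` default); windows with
   ΔSNP ≥ threshold are selected, so threshold ties are included and the
   argmax window is always selected. Quantile definition and tie handling
   are not standardized across tools; both are fixed here for determinism
   and echoed in the run metadata. Windows lacking a defined ΔSNP in any
   entering comparison cannot be selected (the restriction is applied
   before the quantile is taken).
7. **Intersection.** The final set is the intersection of the per-focal
   selections — a window must look like an outlier against *every*
   relative to survive.

## Genic enrichment (permutation test)

Observed statistic: total bp of intersection between the union of the
selected windows and the union of the genic intervals. Null: each window
is re-placed independently and uniformly at random among all positions
where it fits (`scope="genome"`, the default; `scope="chromosome"`
restricts each window to its own scaffold), lengths preserved, overlaps
among shuffled windows permitted; the null statistic is the summed
per-window overlap. Placement weights are proportional to the number of
valid starts per scaffold, which makes every placement genome-wide
equally likely — on a single scaffold of length G with window length w
there are G − w + 1 placements, and the exact null mean is enumerable
(the package ships `expected_overlap_exhaustive` for that check).
Reported: null mean and sd, z = (obs − mean)/sd (undefined when sd = 0),
and both one-sided empirical p-values with the +1 correction
p = (1 + #{null ≥ obs})/(1 + n_perm). Published reshuffling tools do not
document their placement constraints; this null is the simplest fully
reproducible one, and the scope switch covers the main alternative.

## Start-codon proximity

A gene is a putative regulatory target of a selected window when its
strand-aware 5′ end (interval start on `+`, end − 1 on `−`; the proxy for
the annotated start codon) lies in [window.start − D, window.end + D) on
the same scaffold, D = 250,000 bp by default — the upper end of reported
enhancer–target distances. Distance is 0 inside the window, otherwise the
gap to the nearest window edge; genes hit by several windows keep the
minimum. With D = 0 the rule degenerates to start-codon-in-window
membership.

## Inversion detection

The screening practice this formalizes is visual: scan a dot plot 20 Mb
at a time and flag reverse-diagonal segments > 50 kb. The algorithmic
version, per (reference scaffold, query scaffold) pairing:

- drop alignment blocks with `block_len` < `min_block` (default 5,000 bp)
  or mapq < `min_mapq` (default 30) — small repeat-driven blocks are the
  main false-positive source;
- define the local *direct* orientation per `screen_len` (default 20 Mb)
  window as the strand carrying more aligned bp (so a query scaffold that
  is entirely reverse-complemented — an assembly orientation artifact —
  produces no calls);
- merge maximal runs of opposite-strand blocks whose inter-block
  reference gaps are ≤ `merge_gap` (default 100 kb);
- emit runs spanning > `min_len` (default 50 kb) of the reference.

Only the 50-kb floor and the 20-Mb screen come from established practice;
`min_block`, `merge_gap` and `min_mapq` are engineering defaults of this
implementation and are always echoed in output metadata. Calls report
query coordinates and supporting block counts; no breakpoint refinement
is attempted, so boundary accuracy is limited by block granularity
(within `merge_gap` on the synthetic truth).

## The simulator

`SimConfig` defines the validation conditions:

- **Tree.** Four taxa, ((focal, sister), near, far), branch lengths in
  substitutions/site chosen so *observed* focal-vs-other divergences are
  0.030 / 0.038 / 0.039 after Jukes–Cantor multiple-hit correction
  (t = −(3/4)·ln(1 − 4p/3)) — the divergence regime of congeneric
  swallow comparisons.
- **Evolution.** Ancestral sequence i.i.d. from `base_composition`
  (default 43% GC, avian-like); each branch applies the exact JC
  transition: a site changes to a uniformly chosen other base with
  probability (3/4)(1 − e^(−4t/3)). No indels inside aligned tracts —
  indel realism adds nothing to windowed count logic; unaligned reference
  tracts (`gap_fraction`, default 0.08 in 0.5–5-kb tracts) model
  alignment gaps instead, and each aligned tract becomes one MAF block.
- **Planted windows.** On the focal terminal branch only, listed windows
  multiply the branch length by `rate_multiplier` (default 5×). This
  elevates divergence in all focal comparisons and none of the controls —
  exactly the alternative hypothesis of the scan. Default: 20 ten-kb
  windows, 15 autosomal + 5 on Z.
- **Genome sizing.** Four scaffolds (three autosomes + Z) of 6 Mb → 2,400
  windows. The sizing is constrained by the selection budget: a top-1%
  rule can select ~18 autosomal and ~6 Z windows per comparison, so the
  planted 15 + 5 fit inside the budget with headroom; on a materially
  smaller genome the planted fraction would exceed 1% and full recovery
  would be arithmetically impossible regardless of signal strength.
- **Inversions.** Listed segments are reverse-complemented in the named
  query assembly, and a truth PAF against the focal reference is emitted
  (blocks of ≤ 500 kb, '−' inside planted segments, exact base-identity
  match counts, so PAF divergence estimates recover the realized
  divergence). Defaults: 40 kb / 60 kb / 500 kb in the sister species —
  one below the call floor, two above. The MAF is emitted from the
  pre-inversion sequences; sequence scan and inversion scan consume
  different inputs (MAF vs PAF) by design.
- **Determinism.** All randomness flows from `seed` (gene placement from
  an offset stream); identical configs produce byte-identical files.

What passing synthetic tests does **not** show: robustness to real
alignment pathology (paralogy, repeat-driven mis-alignment, indel-rich
regions, reference bias of single-genome coordinates), to
non-substitution divergence, or to incomplete lineage sorting, which can
make single-locus histories deviate from the species tree and inflate
control-pair divergence locally. The planted 5× signal is strong; recovery
of weaker or smaller-than-window signals degrades and is not certified.

## Other numerical choices

- All in-memory coordinates are 0-based half-open; GFF3 converts at the
  boundary, MAF minus-strand rows are flipped to forward coordinates at
  parse time.
- Assembly stats follow the common assembly-QC convention: scaffolds
  strictly longer than `min_len` (default 500 bp) enter; N50 is the
  largest L with scaffolds ≥ L covering ≥ half the filtered total; GC%
  over A/C/G/T only (case-insensitive); N% over the filtered length.
- Neighbor joining is delegated to scikit-bio (Saitou–Nei), with taxa
  sorted by name beforehand for deterministic tie-breaking and negative
  branch lengths clamped to zero; two taxa yield a single edge split
  evenly. Guide-tree construction is a standard step, and the tests hold
  it to the 3-taxon closed form and exact recovery of additive matrices.
- PAF divergence = 1 − Σ matches / Σ block length over records passing
  the mapq filter (default 0) — the quick estimator used to seed guide
  trees, not a substitution-model distance.
- The pipeline writes every stage as TSV/BED/JSON with a parameter echo
  sufficient to reconstruct the run; reruns with identical config and
  inputs are byte-identical.

## Known limitations

- Window counts keep one `bool` per reference position to enforce
  single counting; fine up to bird-genome scale, wasteful beyond.
- The permutation null treats windows independently; it does not
  condition on the observed non-overlap of selected windows.
- Inversion calls assume a mostly collinear backbone within each
  screening window; heavily shuffled genomes would need synteny-chain
  preprocessing first.
- `read_fasta` reports invalid symbols by record id and offset, not file
  line number (Biopython does not expose line numbers).
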