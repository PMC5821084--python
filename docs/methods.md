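# Methods

## Data model and conventions

All intervals are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the boundary, and insertion "plot" files are one row per
base (row *i* = base *i* in internal coordinates). A *unique insertion* is
a distinct base position with read evidence in either transposon
orientation; a base supported by both orientations counts once. Orientation
counts are kept separately for bias flagging. The 9-bp target-site
duplication of Tn5 is not collapsed: sites are scored at their reported
positions. Genes that overlap are each scored independently over their own
intervals; no sharing rule is applied.

## Insertion-index classification

The insertion index of a CDS is `x = unique_insertions / length_bp`,
always in [0, 1]. Its genome-wide distribution is bimodal, and the two
modes are modelled separately rather than by EM over unlabeled data:

- **Histogram**: Freedman–Diaconis bin width `w = 2·IQR·n^(−1/3)` with
  edges covering [0, max(x)]. A degenerate IQR of 0 falls back to Sturges'
  rule with a warning. At least two bins are always produced.
- **Trough**: the histogram is smoothed with an edge-aware 3-bin moving
  average; the two highest local maxima are located and the trough is the
  centre of the minimum-count raw bin strictly between them, ties broken
  toward the lower index. A unimodal histogram raises an error instructing
  a manual override — the split is a judgment call the tool must surface,
  not silently invent.
- **Fits** (on raw indices, not binned counts): exponential MLE
  `λ = 1/mean` on `x < trough`; gamma MLE (scipy, location fixed at 0) on
  `x ≥ trough`. When the left mode is entirely zero, the mean is
  substituted with `1/(2·Lmax)` (Lmax = longest annotated gene, 10 kb cap
  when unknown) so λ stays finite; zero-index genes are clamp-dominated
  regardless, so the substitute does not influence calls.
- **Score**: `log2(f_exp(x)/f_gamma(x))`, densities floored at 1e−300 and
  scores clamped to ±1000. Density ratio (not tail probability or
  normalized posterior) is the established practice for this statistic;
  with a 12-fold threshold it yields the familiar ±3.6 unclear band.
- **Calls**: essential iff score ≥ log2(12); nonessential iff
  score ≤ −log2(12); unclear in the open band between. Positive score =
  essential-mode support. Genes shorter than `min_length` (default 45 bp,
  the shortest annotated gene the method can plausibly resolve) are scored
  but flagged `short_gene`, since index resolution degrades below the
  detection length.

## Insertion-free-region statistics

Insertion placement is modelled per site: N noncoincident insertions over
G sites give per-site probability ρ = N/G, and a given stretch of L sites
is empty with probability `(1−ρ)^L` (geometric tail, computed in log
space). The continuous Poissonian `exp(−x/f)` is retained only as a
comparison baseline; at ρ ≈ 0.195 it overstates the tail several-fold.

Scanning corrections are simulated under the null model:

- **Genome context**: N distinct sites sampled uniformly without
  replacement (Floyd-style sampling); all maximal gaps between consecutive
  sites are tabulated, including the two terminal gaps (linear genomes) or
  the single wrap-around gap (circular; default linear — the end-gap
  choice affects p_genome only at O(1/N)).
- **Gene context**: independent Bernoulli(ρ) occupancy over g = 1,000
  sites. For a 1-kb window of a multi-Mb genome the
  hypergeometric/Bernoulli difference is below Monte-Carlo noise, and the
  Bernoulli model admits an exact oracle: the longest-run-of-failures
  distribution computed by the recurrence
  `a_j = a_{j−1} − ρ(1−ρ)^L·a_{j−L−1}` (probability of *no* run ≥ L in j
  sites). Simulated curves are validated against it at every L.

Tables map L = 1..(max observed gap + 10) to the expected number of IFRs
≥ L and the probability of at least one; `critical_length(table, α)`
returns the smallest L at or below α. At the full library scale
(G = 4,631,469, N = 901,383, ρ = 0.1946) the analytic first-order form
`1 − exp(−(N+1)(1−ρ)^L)` places the genome-corrected α = 0.05 crossing at
L = 78 (P(77) ≈ 0.051), and the exact gene-context DP places the
crossings at 38 (α = 0.05) and 49 (α = 0.005); simulations agree within
Monte-Carlo noise. Simulation sizes (2,000 genome instances, 1e5 gene
instances in acceptance runs) keep the binomial standard error at those
crossings to ≈0.005 and ≈0.0007 respectively.

`scan_ifrs` emits every genome-wide maximal insertion-free run (with the
single-region P and p_genome) plus, per gene, its longest intra-CDS run.
The per-gene record carries both the g = 1,000 table's p_gene — faithful
to the fixed-model-gene convention — and `p_gene_exact`, the DP
probability evaluated at the gene's own length; both are reported, neither
silently replaces the other. Gap length counts the empty bases strictly
between insertions (exclusive of both flanking sites); published critical
lengths carry convention-level slack of a few bp, which is why acceptance
checks use ±3 bp bands.

## Synthetic library generator

The generator is first-class, tested code: it defines the study conditions
under which everything else is validated.

- **Scales.** Desk preset: G = 500,000, 450 genes, N = 97,500
  (ρ = 0.195), gene lengths uniform on [200, 1700] bp (mean 950 bp ≈ the
  *E. coli* average CDS; ~85% coding density). Full-scale preset:
  G = 4,631,469, 4,200 genes, N = 901,383.
- **Placement.** Genes are packed left to right with ≥1-bp random spacers
  (multinomial slack); classes assigned by largest-remainder apportionment
  of the configured fractions, shuffled per seed.
- **Classes.** Desk default: 10% essential, 80% nonessential, 3%/2%
  5′/3′ domain-essential (essential span 35–60% of the CDS), 2%
  orientation-restricted, 2% fitness-cost (density ×0.1, the severe end of
  growth-defect genes), 1% internal 66-bp insertion-free windows. The
  full-scale preset omits the thinning classes (orientation, fitness)
  because its N is the *measured* unique-site count of a real library;
  site conservation then holds exactly and the realized density equals
  N/G.
- **Library draw.** N distinct sites uniform over permitted bases
  (essential CDSs, essential spans and internal windows excluded — planted
  essential regions are insertion-free by construction, a hard
  constraint); orientation Bernoulli(1/2) per site, suppressed (not
  redrawn) on the disallowed strand of orientation-restricted genes; read
  counts geometric with mean 9 (≈ the reads-per-site ratio of a saturated
  MiSeq library). Read counts are decorative: unique sites drive every
  statistic.
- **Terminus dip**: an optional flat thinning factor over a window, a
  stand-in for the replication-terminus density dip; real dips are
  gradients, and no shape model is attempted.

What the generator does **not** emulate: sequencing noise, PCR/mapping
bias, operon structure and polar lethality (orientation restriction
reproduces the observable signature without modelling transcription), or
overdispersion of per-gene insertion counts beyond sampling noise. Real
nonessential-mode index distributions are wider than the generator's
binomial spread, so passing recovery tests demonstrates correctness of the
machinery under the stated null, not field performance on noisy libraries.

## Numerical and degenerate-input choices

- Densities floored at 1e−300 and scores clamped at ±1000 keep the ratio
  finite at x = 0 (gamma density 0 for shape > 1 → call clamps essential).
- Probability table lookups return 1 below the table and 0 beyond its end
  (an observed gap longer than any simulated gap is rarer than 1/instances).
- Ties: trough minimum toward the lower index; per-gene longest run toward
  the leftmost; report rows ordered by (start, gene_id) with a stable sort.
- All simulations take named integer seeds and are bit-reproducible;
  pipeline outputs contain no timestamps, so reruns are byte-identical.
- Duplicate GFF3 IDs are suffixed `_2`, `_3`, … with a warning, never
  dropped (pseudogene/prophage annotations collide in practice).

## Known limitations

- p_gene from the fixed 1-kb model gene under- or over-corrects for genes
  much longer or shorter than 1 kb; `p_gene_exact` addresses this but the
  Bernoulli approximation itself ignores the without-replacement
  constraint (negligible at g ≪ G).
- The null model assumes spatially uniform insertion propensity; real
  libraries show structure (e.g. a terminus dip) that inflates apparent
  IFR significance locally. No positional correction is applied.
- The trough detector assumes a genuinely bimodal index histogram; sparse
  annotations (few hundred genes or fewer) may need a manual trough.
- Fitness-cost genes land between the modes and, depending on the fitted
  gamma width, may be called essential or nonessential; the model cannot
  separate "essential" from "severe growth defect" — by design, matching
  how the index statistic behaves on real libraries.
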