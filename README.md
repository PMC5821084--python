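# tradistat

Essentiality calling and insertion-free-region statistics for saturated
transposon-insertion libraries (TraDIS / Tn-seq).

## The problem

Transposon-directed insertion site sequencing builds a dense pool of
insertion mutants and maps every transposon–genome junction. Genes whose
disruption kills the cell (or cripples growth) are recovered with few or no
insertions, so a saturated library — on the order of one unique insertion
site every ~5 bp — turns essentiality into a statistical question about
per-gene insertion counts and about stretches of the genome that no
insertion ever hits.

`tradistat` implements the two analyses such a library supports, for
bacterial genome annotations (GFF3) and per-base insertion evidence ("plot"
files, one row per base, forward/reverse read counts):

1. **Insertion-index classification.** Each CDS gets an insertion index
   score `x = (unique insertion sites in CDS) / (CDS length in bp)`. Across
   a genome the distribution of `x` is bimodal: a spike near zero
   (essential or severely costly genes) and a broad mode near the genomic
   density ρ. An exponential density `f(x; λ)` is fitted to the low mode
   and a gamma density `f(x; k, θ)` to the high mode, split at the trough
   of a Freedman–Diaconis histogram. Each gene is scored by

   `loglik = log2[ f_exp(x; λ) / f_gamma(x; k, θ) ]`

   and called *essential* if `loglik ≥ log2 12 ≈ 3.6` (the gene is at least
   12× more likely under the essential mode), *nonessential* if
   `loglik ≤ −log2 12`, and *unclear* in the open band between.

2. **Insertion-free region (IFR) significance.** With N noncoincident
   insertions over G sites (per-site probability ρ = N/G), the chance that
   one *given* stretch of L sites is empty is the geometric tail
   `(1 − ρ)^L` — the discrete replacement for the continuous Poissonian
   `exp(−x/f)`. Because a gene (length g) or a genome (length G) offers
   many places for an empty stretch to occur, the package also computes the
   multiplicity-corrected `p_gene(L)` and `p_genome(L)` — the probability
   of at least one IFR of length ≥ L anywhere in a model gene / the whole
   genome — by Monte-Carlo simulation of the random-insertion null model,
   cross-checked against an exact dynamic-programming computation of the
   longest-failure-run distribution. `critical_length` inverts these tables
   (e.g. the smallest L with `p_genome ≤ 0.05`). This separates genes that
   merely *look* sparse from genes harbouring spans too long to be empty by
   chance — including essential domains inside otherwise tolerant genes,
   which index-only classification systematically misses.

A synthetic-library generator plants all the archetypes a real library
exhibits (fully essential genes, 5′/3′ essential domains, internal
insertion-free windows, orientation-restricted genes, fitness-cost genes)
so the whole pipeline is testable without sequencing data.

## Worked example

```python
from tradistat import (
    default_preset, generate_annotation, simulate_library,
    compute_gene_stats, genome_density, NullModelConfig,
    simulate_gene_null, critical_length, scan_ifrs, score_and_classify,
)
from tradistat import essentiality_model as em

cfg = default_preset(seed=42)              # 500 kb, 450 genes, ~97,500 sites
annotation, truth = generate_annotation(cfg)
profile = simulate_library(annotation, truth, cfg)
print(profile.unique_sites, round(genome_density(profile), 4))
# 94325 0.1887

stats = compute_gene_stats(profile, annotation)
fit = em.fit_insertion_indices(
    [s.insertion_index for s in stats],
    max_gene_length=max(g.length for g in annotation.genes),
)
print(round(fit.trough, 4), round(fit.gamma_shape, 2))
# 0.0109 11.11
calls = score_and_classify(stats, fit)
print(sum(c.call == "essential" for c in calls))
# 45

null = simulate_gene_null(NullModelConfig(
    G=cfg.G, N=profile.unique_sites, n_gene_instances=50_000, seed=42))
print(critical_length(null, 0.05))
# 40
records = scan_ifrs(profile, annotation, null_gene=null)
flagged = [r for r in records if r.gene_id and r.p_gene < 0.05]
print(len(flagged))
# 94
```

The 45 essential calls recover exactly the 45 planted essential genes
(insertion index 0 clamps the likelihood ratio in favour of the essential
mode), while the IFR scan additionally flags the planted 5′/3′ essential
domains and internal windows — genes whose overall index looks healthy and
which the index classifier alone would wave through as nonessential. The
gene-corrected critical length of 40 bp at this library's realized density
(ρ ≈ 0.189) means any intra-gene insertion-free run of ≥ 40 bp is
significant at α = 0.05.

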