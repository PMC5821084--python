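"""Null models and P-values for insertion-free regions (IFRs).

A genome of G sites carrying N noncoincident insertions has per-site
insertion probability rho = N/G.  Under independent insertion the chance
that a *given* stretch of L sites is insertion-free is the geometric tail

    P = sum_{k>=L} rho (1 - rho)^k = (1 - rho)^L,

which replaces the continuous Poissonian approximation exp(-x/f).  That
single-region P value is anticonservative for scanning: a gene of length g
(or a genome of length G) offers many effectively independent places for an
IFR to occur.  The corrected quantities

    p_gene(L)   = P(>=1 IFR of length >= L anywhere in a model gene of g sites)
    p_genome(L) = P(>=1 IFR of length >= L anywhere in the genome)

are estimated here by Monte-Carlo simulation of the null model (N distinct
sites placed uniformly for the genome; independent Bernoulli(rho) occupancy
for the short-gene approximation), and p_gene is additionally available
exactly through a dynamic-programming computation of the distribution of
the longest failure run in Bernoulli trials.  ``critical_length`` inverts a
simulated table to recover, e.g., the smallest L with p_genome(L) <= 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomeAnnotation, InsertionProfile
from .gene_metrics import longest_zero_run

__all__ = [
    "NullModelConfig",
    "NullModelResult",
    "IFRRecord",
    "TableRangeError",
    "geometric_tail_p",
    "poisson_tail_p",
    "longest_run_survival",
    "longest_run_survival_curve",
    "simulate_genome_null",
    "simulate_gene_null",
    "critical_length",
    "scan_ifrs",
    "ifr_table",
    "write_null_table",
    "read_null_table",
]

#: extra table rows kept beyond the largest simulated gap
_L_MARGIN = 10


class TableRangeError(ValueError):
    """Requested alpha lies below the smallest probability in the table."""


@dataclass(frozen=True)
class NullModelConfig:
    """Parameters of the random noncoincident insertion null model."""

    G: int
    N: int
    g: int = 1000
    n_genome_instances: int = 100
    n_gene_instances: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.N <= self.G:
            raise ValueError(f"need 0 < N <= G, got N={self.N}, G={self.G}")
        if self.g < 1:
            raise ValueError("model gene length g must be >= 1")

    @property
    def rho(self) -> float:
        return self.N / self.G


@dataclass
class NullModelResult:
    """Simulated table mapping L -> (expected IFR count >= L, P(any IFR >= L))."""

    context: str  # {"gene", "genome"}
    L: np.ndarray
    expected_count: np.ndarray
    probability: np.ndarray
    config: NullModelConfig

    def probability_at(self, L: int) -> float:
        """P(any IFR >= L); 1 below the table, 0 beyond its end."""
        if L <= 0:
            return 1.0
        L0 = int(self.L[0])
        if L < L0:
            return 1.0
        if L > int(self.L[-1]):
            return 0.0
        return float(self.probability[L - L0])

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame(
            {
                "L": self.L,
                "expected_count": self.expected_count,
                "probability": self.probability,
                "context": self.context,
                "G_or_g": cfg.G if self.context == "genome" else cfg.g,
                "N_or_rho": cfg.N if self.context == "genome" else cfg.rho,
                "instances": (
                    cfg.n_genome_instances
                    if self.context == "genome"
                    else cfg.n_gene_instances
                ),
                "seed": cfg.seed,
            }
        )


@dataclass(frozen=True)
class IFRRecord:
    """A maximal insertion-free run with attached null-model probabilities."""

    start: int
    end: int
    p_single: float
    p_genome: float = math.nan
    p_gene: float = math.nan
    p_gene_exact: float = math.nan
    gene_id: str | None = None

    @property
    def L(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Closed forms


def geometric_tail_p(L: int, rho: float) -> float:
    """P(a given stretch of L sites is insertion-free) = (1 - rho)^L.

    Computed in log space so large L does not underflow prematurely.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if L < 0:
        raise ValueError("L must be >= 0")
    if L == 0:
        return 1.0
    if rho == 1.0:
        return 0.0
    return math.exp(L * math.log1p(-rho))


def poisson_tail_p(x: float, f: float) -> float:
    """Continuous Poissonian baseline exp(-x/f), f = inverse insertion density.

    Kept only for comparison against the discrete geometric model.
    """
    if f <= 0:
        raise ValueError("f must be positive")
    return math.exp(-x / f)


# ---------------------------------------------------------------------------
# Exact longest-run distribution (dynamic programming)


def longest_run_survival(n_sites: int, rho: float, L: int) -> float:
    """Exact P(longest insertion-free run >= L) in n independent Bernoulli sites.

    Uses the standard recurrence for the probability a_j that the first j
    sites contain no failure run of length L:

        a_j = a_{j-1} - rho * (1-rho)^L * a_{j-L-1},   a_j = 1 for j < L,
        a_L = 1 - (1-rho)^L.
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if L <= 0:
        return 1.0
    if L > n_sites:
        return 0.0
    q_L = math.exp(L * math.log1p(-rho)) if rho < 1.0 else 0.0
    a = [1.0] * (n_sites + 1)
    a[L] = 1.0 - q_L
    coeff = rho * q_L
    for j in range(L + 1, n_sites + 1):
        a[j] = a[j - 1] - coeff * a[j - L - 1]
    return 1.0 - a[n_sites]


def longest_run_survival_curve(
    n_sites: int, rho: float, L_values: Sequence[int]
) -> np.ndarray:
    """Vector of exact P(max run >= L) over an L grid."""
    return np.array([longest_run_survival(n_sites, rho, int(L)) for L in L_values])


# ---------------------------------------------------------------------------
# Monte-Carlo simulations


def _table_from_gaps(
    gap_hist: np.ndarray, max_hist: np.ndarray, n_instances: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (L, expected_count, probability) from accumulated gap histograms.

    ``gap_hist[l]`` counts maximal gaps of exactly l bases pooled over all
    instances; ``max_hist[m]`` counts instances whose largest gap was m.
    """
    max_gap = max(gap_hist.size, max_hist.size) - 1
    Lmax = max(max_gap, 0) + _L_MARGIN
    L = np.arange(1, Lmax + 1)
    gh = np.zeros(Lmax + 1)
    gh[: gap_hist.size] = gap_hist
    expected = gh[::-1].cumsum()[::-1][1:] / n_instances
    mh = np.zeros(Lmax + 1)
    mh[: max_hist.size] = max_hist
    probability = mh[::-1].cumsum()[::-1][1:] / n_instances
    return L, expected, probability


def simulate_genome_null(
    config: NullModelConfig, circular: bool = False
) -> NullModelResult:
    """Monte-Carlo null for whole-genome IFRs.

    Each instance places N *distinct* sites uniformly among G positions
    (sampling without replacement — noncoincident insertions) and records
    every maximal gap of empty sites between consecutive occupied ones.
    Linear genomes include the two terminal gaps; circular genomes merge
    them into a single wrap-around gap.
    """
    rng = np.random.default_rng(config.seed)
    G, N = config.G, config.N
    gap_hist = np.zeros(1, dtype=np.int64)
    max_hist = np.zeros(1, dtype=np.int64)
    for _ in range(config.n_genome_instances):
        sites = np.sort(rng.choice(G, size=N, replace=False, shuffle=False))
        internal = np.diff(sites) - 1
        if circular:
            wrap = (G - 1 - sites[-1]) + sites[0]
            gaps = np.append(internal, wrap)
        else:
            gaps = np.concatenate(([sites[0]], internal, [G - 1 - sites[-1]]))
        gaps = gaps[gaps > 0]
        if gaps.size:
            h = np.bincount(gaps)
            if h.size > gap_hist.size:
                gap_hist = np.pad(gap_hist, (0, h.size - gap_hist.size))
            gap_hist[: h.size] += h
            m = int(gaps.max())
        else:
            m = 0
        if m + 1 > max_hist.size:
            max_hist = np.pad(max_hist, (0, m + 1 - max_hist.size))
        max_hist[m] += 1
    L, expected, probability = _table_from_gaps(
        gap_hist, max_hist, config.n_genome_instances
    )
    return NullModelResult("genome", L, expected, probability, config)


def simulate_gene_null(config: NullModelConfig, chunk: int = 20_000) -> NullModelResult:
    """Monte-Carlo null for IFRs inside a model gene of g sites.

    Occupancy is independent Bernoulli(rho) per site — the local
    approximation to sampling without replacement, accurate when g << G.
    Tables record, per L, the mean number of maximal insertion-free runs of
    length >= L per gene and the probability that at least one occurs.
    """
    rng = np.random.default_rng(config.seed)
    g, rho, n = config.g, config.rho, config.n_gene_instances
    gap_hist = np.zeros(1, dtype=np.int64)
    max_hist = np.zeros(1, dtype=np.int64)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        occ = np.ones((m, g + 1), dtype=bool)  # sentinel column ends each row
        occ[:, :g] = rng.random((m, g)) < rho
        flat = occ.ravel()
        ones_idx = np.flatnonzero(flat)
        runs = np.empty(ones_idx.size, dtype=np.int64)
        runs[0] = ones_idx[0]
        runs[1:] = np.diff(ones_idx) - 1
        starts = np.empty_like(runs)
        starts[0] = 0
        starts[1:] = ones_idx[:-1] + 1
        rows = starts // (g + 1)
        keep = runs > 0
        runs_k, rows_k = runs[keep], rows[keep]
        if runs_k.size:
            h = np.bincount(runs_k)
            if h.size > gap_hist.size:
                gap_hist = np.pad(gap_hist, (0, h.size - gap_hist.size))
            gap_hist[: h.size] += h
        row_max = np.zeros(m, dtype=np.int64)
        np.maximum.at(row_max, rows_k, runs_k)
        mh = np.bincount(row_max)
        if mh.size > max_hist.size:
            max_hist = np.pad(max_hist, (0, mh.size - max_hist.size))
        max_hist[: mh.size] += mh
        done += m
    L, expected, probability = _table_from_gaps(gap_hist, max_hist, n)
    return NullModelResult("gene", L, expected, probability, config)


def critical_length(result: NullModelResult, alpha: float) -> int:
    """Smallest L with P(any IFR >= L) <= alpha in a simulated table."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    mask = result.probability <= alpha
    if not mask.any():
        raise TableRangeError(
            f"alpha={alpha} below the table's minimum probability "
            f"({result.probability.min():.3g}); extend the simulation"
        )
    return int(result.L[mask][0])


# ---------------------------------------------------------------------------
# Scanning


def _maximal_zero_runs(occ: np.ndarray, offset: int = 0) -> list[tuple[int, int]]:
    """Half-open (start, end) of every maximal run of False values."""
    ones = np.flatnonzero(occ)
    n = occ.shape[0]
    if ones.size == 0:
        return [(offset, offset + n)] if n else []
    runs: list[tuple[int, int]] = []
    if ones[0] > 0:
        runs.append((offset, offset + int(ones[0])))
    if ones.size > 1:
        gap_sizes = np.diff(ones) - 1
        for k in np.flatnonzero(gap_sizes > 0):
            runs.append((offset + int(ones[k]) + 1, offset + int(ones[k + 1])))
    if ones[-1] < n - 1:
        runs.append((offset + int(ones[-1]) + 1, offset + n))
    return runs


def scan_ifrs(
    profile: InsertionProfile,
    annotation: GenomeAnnotation,
    null_gene: NullModelResult | None = None,
    null_genome: NullModelResult | None = None,
    exact_gene_p: bool = True,
) -> list[IFRRecord]:
    """Report every genome-wide maximal IFR plus each gene's longest IFR.

    Genome-wide records carry the single-region geometric P and, when a
    genome null table is supplied, p_genome.  Per-gene records carry the
    g=1000 table's p_gene for the gene's longest intra-CDS run and, when
    ``exact_gene_p`` is set, the exact longest-run probability evaluated at
    the gene's own length (column ``p_gene_exact``).
    """
    G = profile.genome_length
    occ = profile.occupancy
    sites = profile.unique_sites
    rho = sites / G if sites else None
    records: list[IFRRecord] = []

    def p_single(L: int) -> float:
        return geometric_tail_p(L, rho) if rho else math.nan

    for start, end in _maximal_zero_runs(occ):
        L = end - start
        records.append(
            IFRRecord(
                start=start,
                end=end,
                p_single=p_single(L),
                p_genome=(
                    null_genome.probability_at(L) if null_genome is not None else math.nan
                ),
            )
        )
    for gene in annotation.genes:
        sub = occ[gene.start : gene.end]
        runs = _maximal_zero_runs(sub, offset=gene.start)
        if not runs:
            continue
        start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        L = end - start
        records.append(
            IFRRecord(
                start=start,
                end=end,
                p_single=p_single(L),
                p_gene=(
                    null_gene.probability_at(L) if null_gene is not None else math.nan
                ),
                p_gene_exact=(
                    longest_run_survival(gene.length, rho, L)
                    if (exact_gene_p and rho)
                    else math.nan
                ),
                gene_id=gene.gene_id,
            )
        )
    records.sort(key=lambda r: (r.start, r.end, r.gene_id or ""))
    return records


def ifr_table(records: Sequence[IFRRecord], annotation: GenomeAnnotation) -> pd.DataFrame:
    """BED-like frame of IFR records with overlapping gene ids attached."""
    starts = np.array([g.start for g in annotation.genes])
    ends = np.array([g.end for g in annotation.genes])
    ids = [g.gene_id for g in annotation.genes]
    rows = []
    for r in records:
        overlap = [
            ids[k]
            for k in np.flatnonzero((starts < r.end) & (ends > r.start))
        ]
        rows.append(
            {
                "start": r.start,
                "end": r.end,
                "L": r.L,
                "kind": "gene" if r.gene_id else "genome",
                "gene_id": r.gene_id or "",
                "p_single": r.p_single,
                "p_gene": r.p_gene,
                "p_gene_exact": r.p_gene_exact,
                "p_genome": r.p_genome,
                "overlapping_gene_ids": ",".join(overlap),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "start",
            "end",
            "L",
            "kind",
            "gene_id",
            "p_single",
            "p_gene",
            "p_gene_exact",
            "p_genome",
            "overlapping_gene_ids",
        ],
    )


def write_null_table(result: NullModelResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_null_table(path: str | Path) -> NullModelResult:
    df = pd.read_csv(path, sep="\t")
    context = str(df["context"].iloc[0])
    inst = int(df["instances"].iloc[0])
    seed = int(df["seed"].iloc[0])
    if context == "genome":
        G = int(df["G_or_g"].iloc[0])
        N = int(df["N_or_rho"].iloc[0])
        cfg = NullModelConfig(G=G, N=N, n_genome_instances=inst, seed=seed)
    else:
        g = int(df["G_or_g"].iloc[0])
        rho = float(df["N_or_rho"].iloc[0])
        # reconstruct an (N, G) pair with the stored density
        G = 10_000_000
        cfg = NullModelConfig(
            G=G, N=round(rho * G), g=g, n_gene_instances=inst, seed=seed
        )
    return NullModelResult(
        context,
        df["L"].to_numpy(dtype=np.int64),
        df["expected_count"].to_numpy(dtype=float),
        df["probability"].to_numpy(dtype=float),
        cfg,
    )
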