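"""Per-gene and regional insertion statistics.

The central per-gene quantity is the *insertion index score*: the number of
distinct bases within a CDS carrying any insertion evidence, divided by the
CDS length in bases.  A base counts once no matter how many reads or
orientations support it; orientation-resolved counts are kept separately so
one-sided (polar) insertion patterns can be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GenomeAnnotation, InsertionProfile

__all__ = [
    "GeneStats",
    "compute_gene_stats",
    "genome_density",
    "mean_site_spacing",
    "local_density",
    "orientation_bias",
    "longest_zero_run",
]


@dataclass(frozen=True)
class GeneStats:
    gene_id: str
    length_bp: int
    unique_insertions: int
    insertion_index: float
    fwd_insertions: int
    rev_insertions: int
    max_ifr_bp: int


def longest_zero_run(occupied: np.ndarray) -> int:
    """Length of the longest run of False values (runs truncated at ends)."""
    occupied = np.asarray(occupied, dtype=bool)
    n = occupied.shape[0]
    ones = np.flatnonzero(occupied)
    if ones.size == 0:
        return n
    best = max(int(ones[0]), int(n - 1 - ones[-1]))
    if ones.size > 1:
        gaps = np.diff(ones) - 1
        best = max(best, int(gaps.max()))
    return best


def compute_gene_stats(
    profile: InsertionProfile, annotation: GenomeAnnotation
) -> list[GeneStats]:
    """One :class:`GeneStats` per gene, scored over its own interval.

    Overlapping genes are each scored independently.  ``max_ifr_bp`` is the
    longest run of insertion-free bases strictly inside the CDS; a gene with
    no insertions has ``max_ifr_bp`` equal to its length.
    """
    G = profile.genome_length
    if annotation.genome_length != G:
        raise ValueError(
            f"annotation length {annotation.genome_length} != profile length {G}"
        )
    occ = profile.occupancy
    fwd_occ = profile.fwd_counts > 0
    rev_occ = profile.rev_counts > 0
    out: list[GeneStats] = []
    for g in annotation.genes:
        if g.start < 0 or g.end > G:
            raise ValueError(f"gene {g.gene_id!r} outside genome bounds")
        sl = slice(g.start, g.end)
        unique = int(occ[sl].sum())
        out.append(
            GeneStats(
                gene_id=g.gene_id,
                length_bp=g.length,
                unique_insertions=unique,
                insertion_index=unique / g.length,
                fwd_insertions=int(fwd_occ[sl].sum()),
                rev_insertions=int(rev_occ[sl].sum()),
                max_ifr_bp=longest_zero_run(occ[sl]),
            )
        )
    return out


def genome_density(profile: InsertionProfile) -> float:
    """Genome-wide unique-site density rho-hat = unique_sites / G."""
    if profile.genome_length == 0:
        raise ValueError("empty profile")
    return profile.unique_sites / profile.genome_length


def mean_site_spacing(profile: InsertionProfile) -> float:
    """Average number of bases per unique insertion site (G / sites)."""
    if profile.unique_sites == 0:
        raise ValueError("mean spacing undefined: profile has no insertion sites")
    return profile.genome_length / profile.unique_sites


def local_density(
    profile: InsertionProfile, center: int, window: int, circular: bool = False
) -> float:
    """Unique-site density in a window of ``window`` bases centred on ``center``.

    Linear genomes clip the window at the ends and divide by the bases
    actually covered; circular genomes wrap around instead.
    """
    G = profile.genome_length
    if not 0 <= center < G:
        raise ValueError(f"center {center} outside [0, {G})")
    if window < 1:
        raise ValueError("window must be >= 1")
    start = center - window // 2
    end = start + window
    occ = profile.occupancy
    if circular:
        idx = np.arange(start, end) % G
        return float(occ[idx].sum()) / window
    start = max(start, 0)
    end = min(end, G)
    return float(occ[start:end].sum()) / (end - start)


def orientation_bias(
    stats: GeneStats, min_sites: int = 10, bias_fraction: float = 0.9
) -> str:
    """Flag one-sided insertion patterns.

    Returns one of ``none``, ``fwd_only``, ``rev_only``, ``fwd_biased``,
    ``rev_biased``.  Genes with fewer than ``min_sites`` unique insertions
    are never flagged.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if not 0.5 < bias_fraction <= 1.0:
        raise ValueError("bias_fraction must be in (0.5, 1]")
    if stats.unique_insertions < min_sites:
        return "none"
    fwd, rev = stats.fwd_insertions, stats.rev_insertions
    total = fwd + rev
    if total == 0:
        return "none"
    if rev == 0:
        return "fwd_only"
    if fwd == 0:
        return "rev_only"
    if fwd / total >= bias_fraction:
        return "fwd_biased"
    if rev / total >= bias_fraction:
        return "rev_biased"
    return "none"
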