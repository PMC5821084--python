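"""Synthetic transposon libraries with planted ground truth.

The generator emulates a saturated mini-Tn5 library: N noncoincident
insertion sites placed uniformly over a genome of G bases, with each site
assigned one of the two transposon orientations with probability 1/2 and a
read count drawn from a geometric distribution.  Planted gene classes
reproduce every insertion-profile archetype a dense library exhibits:

``essential``                 zero insertions over the whole CDS
``domain_essential_5prime``   an insertion-free essential span at the 5' end
``domain_essential_3prime``   same at the 3' end
``orientation_restricted``    only one transposon orientation recovered
``fitness_cost``              insertion density thinned by a multiplier
``internal_ifr``              a short internal insertion-free window
``nonessential``              unconstrained

Read counts are decorative for the downstream statistics (unique sites
drive everything); they exist so emitted plot files look like real ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .formats_io import FormatError, GeneRecord, GenomeAnnotation, InsertionProfile

__all__ = [
    "TRUE_CLASSES",
    "TruthRecord",
    "SynthConfig",
    "CapacityError",
    "default_preset",
    "full_scale_preset",
    "generate_annotation",
    "simulate_library",
    "write_truth",
    "read_truth",
    "write_manifest",
]

TRUE_CLASSES = (
    "essential",
    "nonessential",
    "domain_essential_5prime",
    "domain_essential_3prime",
    "orientation_restricted",
    "fitness_cost",
    "internal_ifr",
)

#: fraction of each class in a default library; the essential share mirrors
#: the ~8% of E. coli genes called essential, the rest are small planted
#: archetype classes
DEFAULT_CLASS_FRACTIONS: Mapping[str, float] = {
    "essential": 0.10,
    "nonessential": 0.80,
    "domain_essential_5prime": 0.03,
    "domain_essential_3prime": 0.02,
    "orientation_restricted": 0.02,
    "fitness_cost": 0.02,
    "internal_ifr": 0.01,
}


#: full-scale preset fractions: N is the *measured* number of unique sites in
#: a real library, so the full-scale preset plants only classes that do not
#: thin sites away (site conservation holds exactly and density == N/G)
FULL_SCALE_CLASS_FRACTIONS: Mapping[str, float] = {
    "essential": 0.08,
    "nonessential": 0.86,
    "domain_essential_5prime": 0.03,
    "domain_essential_3prime": 0.02,
    "internal_ifr": 0.01,
}


class CapacityError(ValueError):
    """Requested genes or insertions do not fit the genome."""


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    true_class: str
    essential_span: tuple[int, int] | None = None  # gene-relative, half-open
    allowed_orientation: str | None = None  # {"fwd", "rev"}
    density_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.true_class not in TRUE_CLASSES:
            raise FormatError(f"unknown true_class {self.true_class!r}")
        if not 0.0 <= self.density_multiplier <= 1.0:
            raise FormatError("density_multiplier must be in [0, 1]")
        if self.allowed_orientation is not None and self.true_class != "orientation_restricted":
            raise FormatError("allowed_orientation is only for orientation_restricted")


@dataclass(frozen=True)
class SynthConfig:
    G: int = 500_000
    n_genes: int = 450
    gene_length_range: tuple[int, int] = (200, 1700)
    N_insertions: int = 97_500
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    terminus_dip: tuple[int, int, float] | None = None  # (center, window, factor)
    seed: int = 0
    read_count_mean: float = 9.0  # ~8,279,309 reads / 901,383 sites
    span_fraction_range: tuple[float, float] = (0.35, 0.6)
    internal_ifr_length: int = 66
    fitness_multiplier: float = 0.1

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(TRUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in fractions: {sorted(unknown)}")


def default_preset(seed: int = 0) -> SynthConfig:
    """Desk-scale library: G=500 kb, ~450 genes, rho = 0.195."""
    return SynthConfig(seed=seed)


def full_scale_preset(seed: int = 0) -> SynthConfig:
    """Full-scale library: G=4,631,469 bases, N=901,383 insertion sites."""
    return SynthConfig(
        G=4_631_469,
        n_genes=4_200,
        N_insertions=901_383,
        class_fractions=dict(FULL_SCALE_CLASS_FRACTIONS),
        seed=seed,
    )


def _class_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the classes."""
    counts = {c: int(np.floor(fractions.get(c, 0.0) * n)) for c in TRUE_CLASSES}
    rem = n - sum(counts.values())
    leftovers = sorted(
        TRUE_CLASSES,
        key=lambda c: (fractions.get(c, 0.0) * n) - counts[c],
        reverse=True,
    )
    for c in leftovers[:rem]:
        counts[c] += 1
    return counts


def generate_annotation(config: SynthConfig) -> tuple[GenomeAnnotation, list[TruthRecord]]:
    """Place non-overlapping genes left to right with random spacers.

    Deterministic per seed.  Every pair of adjacent genes is separated by
    at least one intergenic base.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    if n == 0:
        return GenomeAnnotation(genome_length=config.G), []
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    total = int(lengths.sum()) + (n + 1)  # minimum 1-bp spacers
    if total > config.G:
        raise CapacityError(
            f"cannot pack {n} genes (span {total}) into {config.G} bases"
        )
    slack = config.G - total
    spacers = 1 + rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    labels: list[str] = []
    for cls, cnt in _class_counts(config.class_fractions, n).items():
        labels.extend([cls] * cnt)
    labels = list(np.array(labels)[rng.permutation(n)])
    genes: list[GeneRecord] = []
    truth: list[TruthRecord] = []
    pos = 0
    f_lo, f_hi = config.span_fraction_range
    for i in range(n):
        pos += int(spacers[i])
        length = int(lengths[i])
        start, end = pos, pos + length
        pos = end
        gid = f"g{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        cls = labels[i]
        span = None
        orient = None
        mult = 1.0
        if cls in ("domain_essential_5prime", "domain_essential_3prime"):
            frac = rng.uniform(f_lo, f_hi)
            s = max(1, int(round(frac * length)))
            span = (0, s) if cls == "domain_essential_5prime" else (length - s, length)
        elif cls == "internal_ifr":
            w = config.internal_ifr_length
            margin = 20
            if length < w + 2 * margin:
                raise CapacityError(
                    f"gene length {length} too short for a {w}-bp internal window"
                )
            off = int(rng.integers(margin, length - w - margin + 1))
            span = (off, off + w)
        elif cls == "orientation_restricted":
            orient = "fwd" if rng.random() < 0.5 else "rev"
        elif cls == "fitness_cost":
            mult = config.fitness_multiplier
        genes.append(GeneRecord(gene_id=gid, start=start, end=end, strand=strand))
        truth.append(
            TruthRecord(
                gene_id=gid,
                true_class=cls,
                essential_span=span,
                allowed_orientation=orient,
                density_multiplier=mult,
            )
        )
    return GenomeAnnotation(genome_length=config.G, genes=genes), truth


def simulate_library(
    annotation: GenomeAnnotation,
    truth: Sequence[TruthRecord],
    config: SynthConfig,
) -> InsertionProfile:
    """Draw an insertion profile honouring the planted truth.

    N distinct sites are placed uniformly over the *permitted* bases (the
    complement of essential CDSs, essential spans, and internal IFR
    windows).  Orientations are Bernoulli(1/2) per site; the disallowed
    orientation inside orientation-restricted genes is suppressed (sites
    dropped, not redrawn), fitness-cost genes and the terminus dip thin
    their sites by their factors, so realized unique sites can fall
    slightly below N.  Read counts per retained site are geometric.
    """
    rng = np.random.default_rng(config.seed + 1)  # decouple from annotation draw
    G = annotation.genome_length
    by_id = {g.gene_id: g for g in annotation.genes}
    permitted = np.ones(G, dtype=bool)
    for t in truth:
        g = by_id[t.gene_id]
        if t.true_class == "essential":
            permitted[g.start : g.end] = False
        elif t.essential_span is not None:
            s, e = t.essential_span
            permitted[g.start + s : g.start + e] = False
    candidates = np.flatnonzero(permitted)
    if candidates.size < config.N_insertions:
        raise CapacityError(
            f"permitted region ({candidates.size} bases) smaller than "
            f"N={config.N_insertions}"
        )
    sites = rng.choice(candidates, size=config.N_insertions, replace=False, shuffle=False)
    sites.sort()
    is_fwd = rng.random(sites.size) < 0.5
    keep = np.ones(sites.size, dtype=bool)
    for t in truth:
        g = by_id[t.gene_id]
        in_gene = (sites >= g.start) & (sites < g.end)
        if t.true_class == "orientation_restricted":
            want_fwd = t.allowed_orientation == "fwd"
            keep &= ~(in_gene & (is_fwd != want_fwd))
        elif t.density_multiplier < 1.0:
            thin = rng.random(sites.size) >= t.density_multiplier
            keep &= ~(in_gene & thin)
    if config.terminus_dip is not None:
        center, window, factor = config.terminus_dip
        lo, hi = center - window // 2, center + (window - window // 2)
        in_dip = (sites >= lo) & (sites < hi)
        thin = rng.random(sites.size) >= factor
        keep &= ~(in_dip & thin)
    sites, is_fwd = sites[keep], is_fwd[keep]
    reads = rng.geometric(1.0 / config.read_count_mean, size=sites.size)
    fwd = np.zeros(G, dtype=np.int64)
    rev = np.zeros(G, dtype=np.int64)
    fwd[sites[is_fwd]] = reads[is_fwd]
    rev[sites[~is_fwd]] = reads[~is_fwd]
    return InsertionProfile(fwd, rev)


# ---------------------------------------------------------------------------
# Truth-table I/O

_TRUTH_COLUMNS = [
    "gene_id",
    "true_class",
    "span_start",
    "span_end",
    "allowed_orientation",
    "density_multiplier",
]


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truth:
        s, e = t.essential_span if t.essential_span is not None else ("", "")
        rows.append(
            {
                "gene_id": t.gene_id,
                "true_class": t.true_class,
                "span_start": s,
                "span_end": e,
                "allowed_orientation": t.allowed_orientation or "",
                "density_multiplier": t.density_multiplier,
            }
        )
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in _TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: truth table missing columns {missing}")
    out: list[TruthRecord] = []
    for _, row in df.iterrows():
        cls = row["true_class"]
        if cls not in TRUE_CLASSES:
            raise FormatError(f"{path}: unknown class label {cls!r}")
        span = None
        if row["span_start"] != "" and row["span_end"] != "":
            span = (int(row["span_start"]), int(row["span_end"]))
        out.append(
            TruthRecord(
                gene_id=row["gene_id"],
                true_class=cls,
                essential_span=span,
                allowed_orientation=row["allowed_orientation"] or None,
                density_multiplier=float(row["density_multiplier"]),
            )
        )
    return out


def write_manifest(config: SynthConfig, path: str | Path) -> None:
    """YAML record of the generator configuration and seed."""
    data = {
        "G": config.G,
        "n_genes": config.n_genes,
        "gene_length_range": list(config.gene_length_range),
        "N_insertions": config.N_insertions,
        "class_fractions": dict(config.class_fractions),
        "terminus_dip": list(config.terminus_dip) if config.terminus_dip else None,
        "seed": config.seed,
        "read_count_mean": config.read_count_mean,
        "span_fraction_range": list(config.span_fraction_range),
        "internal_ifr_length": config.internal_ifr_length,
        "fitness_multiplier": config.fitness_multiplier,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
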