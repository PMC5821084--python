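"""End-to-end orchestration and gene-list set comparison."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from . import essentiality_model as em
from . import formats_io as fio
from . import gene_metrics as gm
from . import ifr_stats as ifr

__all__ = ["RunConfig", "run_pipeline", "compare_gene_lists"]


@dataclass
class RunConfig:
    gff: str
    plot: str
    out_dir: str
    feature_types: tuple[str, ...] = ("CDS",)
    circular: bool = False
    genome_length: int | None = None
    fold_threshold: float = 12.0
    trough: float | None = None
    min_gene_length: int = 45
    genome_instances: int = 100
    gene_instances: int = 100_000
    model_gene_length: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")

    def digest(self) -> str:
        payload = yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """read -> stats -> fit -> classify -> null-sim -> scan -> report.

    Writes gene_report.tsv, ifr_report.tsv, null_gene.tsv, null_genome.tsv,
    fit.yaml and run.log into ``out_dir``.  Outputs are deterministic for a
    given config (no timestamps), so a rerun is byte-identical.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"tradistat {__version__} run, seed={config.seed}, config={config.digest()}"
    ]

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    annotation = _stage("read_gff3")(
        fio.read_gff3,
        config.gff,
        feature_types=config.feature_types,
        genome_length=config.genome_length,
        circular=config.circular,
    )
    profile = _stage("read_plot")(fio.read_plot, config.plot, annotation.genome_length)
    log_lines.append(
        f"genome_length={profile.genome_length} unique_sites={profile.unique_sites} "
        f"density={gm.genome_density(profile):.6f}"
    )
    stats = _stage("compute_gene_stats")(gm.compute_gene_stats, profile, annotation)
    indices = np.array([s.insertion_index for s in stats])
    max_len = max((g.length for g in annotation.genes), default=None)
    trough = config.trough
    if trough is not None:
        log_lines.append(f"WARN trough overridden to {trough}")
    fit = _stage("fit_modes")(
        em.fit_insertion_indices, indices, trough=trough, max_gene_length=max_len
    )
    calls = _stage("score_and_classify")(
        em.score_and_classify,
        stats,
        fit,
        fold_threshold=config.fold_threshold,
        min_length=config.min_gene_length,
    )
    for c in calls:
        if c.short_gene:
            log_lines.append(f"WARN short_gene {c.gene_id} (< {config.min_gene_length} bp)")
    null_cfg = ifr.NullModelConfig(
        G=profile.genome_length,
        N=max(profile.unique_sites, 1),
        g=config.model_gene_length,
        n_genome_instances=config.genome_instances,
        n_gene_instances=config.gene_instances,
        seed=config.seed,
    )
    null_genome = _stage("simulate_genome_null")(
        ifr.simulate_genome_null, null_cfg, circular=config.circular
    )
    null_gene = _stage("simulate_gene_null")(ifr.simulate_gene_null, null_cfg)
    records = _stage("scan_ifrs")(
        ifr.scan_ifrs, profile, annotation, null_gene=null_gene, null_genome=null_genome
    )
    gene_p = {r.gene_id: r.p_gene for r in records if r.gene_id is not None}
    table = fio.build_gene_table(annotation, stats, calls, gene_p=gene_p)
    fio.write_gene_report(table, out / "gene_report.tsv")
    ifr.ifr_table(records, annotation).to_csv(
        out / "ifr_report.tsv", sep="\t", index=False, lineterminator="\n"
    )
    ifr.write_null_table(null_gene, out / "null_gene.tsv")
    ifr.write_null_table(null_genome, out / "null_genome.tsv")
    counts = {
        k: int(sum(c.call == k for c in calls))
        for k in ("essential", "unclear", "nonessential")
    }
    sidecar = {
        "lambda_ess": fit.lambda_ess,
        "gamma_shape": fit.gamma_shape,
        "gamma_scale": fit.gamma_scale,
        "trough": fit.trough,
        "n_left": fit.n_left,
        "n_right": fit.n_right,
        "fold_threshold": config.fold_threshold,
        "alpha": config.alpha,
        "seed": config.seed,
        "config_hash": config.digest(),
        "version": __version__,
        "counts": counts,
    }
    with open(out / "fit.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    log_lines.append(
        "counts essential={essential} unclear={unclear} nonessential={nonessential}".format(
            **counts
        )
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "counts": counts,
        "fit": fit,
        "out_dir": str(out),
        "n_genes": len(stats),
        "critical_L_genome": _safe_critical(null_genome, config.alpha),
        "critical_L_gene": _safe_critical(null_gene, config.alpha),
    }


def _safe_critical(result: ifr.NullModelResult, alpha: float) -> int | None:
    try:
        return ifr.critical_length(result, alpha)
    except ifr.TableRangeError:
        return None


def compare_gene_lists(
    list_a: Iterable[str],
    list_b: Iterable[str],
    list_c: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> dict:
    """Three-way set comparison: counts and memberships of all 7 Venn regions.

    ``aliases`` maps alternative gene names onto canonical ids before
    comparison (reference essential-gene lists often use older names).
    """

    def canon(ids: Iterable[str]) -> set[str]:
        al = aliases or {}
        return {al.get(i, i) for i in ids}

    a, b, c = canon(list_a), canon(list_b), canon(list_c)
    members = {
        "abc": a & b & c,
        "ab": (a & b) - c,
        "ac": (a & c) - b,
        "bc": (b & c) - a,
        "a": a - b - c,
        "b": b - a - c,
        "c": c - a - b,
    }
    return {
        "counts": {k: len(v) for k, v in members.items()},
        "members": {k: sorted(v) for k, v in members.items()},
    }
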