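"""Bimodal classification of insertion index scores.

In a saturated transposon library the per-gene insertion index scores fall
into two modes: a spike at or near zero (genes whose disruption is lethal or
near-lethal) and a broad mode around the genomic insertion density
(dispensable genes).  Following established TraDIS practice, an exponential
distribution is fitted to the low (essential) mode and a gamma distribution
to the high (nonessential) mode, split at the trough of the histogram.  Each
gene is then scored by

    loglik_score = log2( f_exp(x; lambda) / f_gamma(x; k, theta) )

at its insertion index x.  Positive scores favour the essential mode.  With
the default 12-fold threshold a gene is *essential* when the score is at
least log2(12) = 3.585, *nonessential* when it is at most -log2(12), and
*unclear* in between.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .gene_metrics import GeneStats

__all__ = [
    "BimodalFit",
    "EssentialityCall",
    "InsufficientDataError",
    "NoTroughError",
    "InsufficientModeError",
    "histogram_bins",
    "find_trough",
    "fit_modes",
    "score_and_classify",
    "fit_insertion_indices",
]

#: floor applied to both mode densities before taking the ratio
_DENSITY_FLOOR = 1e-300
#: symmetric clamp on log2 scores
_SCORE_CLAMP = 1000.0
#: fallback gene-length cap used by the zero-mean substitution rule when the
#: caller does not supply the longest annotated gene length
_DEFAULT_MAX_GENE_LENGTH = 10_000


class InsufficientDataError(ValueError):
    """Fewer insertion index values than the histogram rule needs."""


class NoTroughError(ValueError):
    """The histogram has no interior minimum between two modes."""


class InsufficientModeError(ValueError):
    """One side of the trough has too few genes to fit a distribution."""


@dataclass(frozen=True)
class BimodalFit:
    """Fitted parameters of the two-mode model plus the trough that split it."""

    lambda_ess: float
    gamma_shape: float
    gamma_scale: float
    trough: float
    n_left: int
    n_right: int


@dataclass(frozen=True)
class EssentialityCall:
    gene_id: str
    loglik_score: float
    call: str  # {essential, unclear, nonessential}
    short_gene: bool = False


def histogram_bins(indices: Sequence[float]) -> tuple[float, np.ndarray]:
    """Freedman-Diaconis bin width and edges covering [0, max(indices)].

    width = 2 * IQR * n^(-1/3).  A degenerate IQR of zero falls back to
    Sturges' rule with a warning.  At least two bins are always returned.
    """
    x = np.asarray(indices, dtype=float)
    n = x.size
    if n < 10:
        raise InsufficientDataError(f"need >= 10 values, got {n}")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    xmax = float(x.max())
    if iqr > 0:
        width = 2.0 * iqr * n ** (-1.0 / 3.0)
    else:
        warnings.warn(
            "IQR is zero; falling back to Sturges' rule for bin width",
            stacklevel=2,
        )
        k = int(np.ceil(np.log2(n))) + 1
        width = (xmax / k) if xmax > 0 else 1.0
    edges = np.arange(0.0, xmax + width, width)
    if edges.size and edges[-1] < xmax:  # guard against float shortfall
        edges = np.append(edges, edges[-1] + width)
    while edges.size < 3:  # enforce >= 2 bins
        edges = np.append(edges, (edges[-1] if edges.size else 0.0) + width)
    return width, edges


def find_trough(counts: Sequence[float], edges: Sequence[float]) -> float:
    """Locate the trough between the two dominant modes of a histogram.

    The histogram is smoothed with an edge-aware 3-bin moving average; the
    two highest local maxima of the smoothed counts are found and the trough
    is the centre of the minimum-count (raw) bin strictly between them, ties
    broken toward the lower index.  Raises :class:`NoTroughError` when no
    two modes exist (the caller may then override with an explicit value).
    """
    c = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if c.size < 3:
        raise NoTroughError("histogram too small to contain two modes")
    kernel = np.ones(3)
    sm = np.convolve(c, kernel, mode="same") / np.convolve(
        np.ones_like(c), kernel, mode="same"
    )
    maxima = []
    for i in range(c.size):
        left_ok = i == 0 or sm[i] > sm[i - 1]
        right_ok = i == c.size - 1 or sm[i] >= sm[i + 1]
        if left_ok and right_ok:
            maxima.append(i)
    if len(maxima) < 2:
        raise NoTroughError(
            "histogram appears unimodal; supply an explicit trough override"
        )
    maxima.sort(key=lambda i: (-sm[i], i))
    i1, i2 = sorted(maxima[:2])
    if i2 - i1 < 2:
        raise NoTroughError(
            "no interior bin between the two modes; supply an explicit trough"
        )
    interior = c[i1 + 1 : i2]
    j = i1 + 1 + int(np.argmin(interior))  # argmin takes the first (lower) tie
    return float((edges[j] + edges[j + 1]) / 2.0)


def fit_modes(
    indices: Sequence[float],
    trough: float,
    max_gene_length: int | None = None,
) -> BimodalFit:
    """Maximum-likelihood fits on the raw indices either side of the trough.

    Exponential rate on ``x < trough`` is the closed form 1/mean; when the
    left mode is entirely zero the mean is substituted with
    ``1 / (2 * max_gene_length)`` so the rate stays finite (zero-index genes
    are clamp-dominated regardless).  The gamma fit on ``x >= trough`` uses
    MLE with location fixed at zero.
    """
    x = np.asarray(indices, dtype=float)
    left = x[x < trough]
    right = x[x >= trough]
    if left.size < 5 or right.size < 5:
        raise InsufficientModeError(
            f"need >= 5 genes per mode, got {left.size} left / {right.size} right"
        )
    mean_left = float(left.mean())
    if mean_left == 0.0:
        cap = max_gene_length if max_gene_length else _DEFAULT_MAX_GENE_LENGTH
        mean_left = 1.0 / (2.0 * cap)
    lambda_ess = 1.0 / mean_left
    shape, _, scale = sps.gamma.fit(right, floc=0)
    return BimodalFit(
        lambda_ess=float(lambda_ess),
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        trough=float(trough),
        n_left=int(left.size),
        n_right=int(right.size),
    )


def _scores(x: np.ndarray, fit: BimodalFit) -> np.ndarray:
    f_ess = sps.expon.pdf(x, scale=1.0 / fit.lambda_ess)
    f_non = sps.gamma.pdf(x, fit.gamma_shape, scale=fit.gamma_scale)
    f_ess = np.maximum(f_ess, _DENSITY_FLOOR)
    f_non = np.maximum(f_non, _DENSITY_FLOOR)
    return np.clip(np.log2(f_ess) - np.log2(f_non), -_SCORE_CLAMP, _SCORE_CLAMP)


def score_and_classify(
    stats: Sequence[GeneStats],
    fit: BimodalFit,
    fold_threshold: float = 12.0,
    min_length: int = 45,
) -> list[EssentialityCall]:
    """Score every gene and assign essential / unclear / nonessential.

    ``call == essential`` iff score >= log2(fold_threshold);
    ``call == nonessential`` iff score <= -log2(fold_threshold); unclear
    otherwise.  Genes shorter than ``min_length`` (default 45 bp, the
    smallest annotated gene the model can resolve) are scored normally but
    carry ``short_gene=True``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    thr = np.log2(fold_threshold)
    x = np.array([s.insertion_index for s in stats], dtype=float)
    scores = _scores(x, fit)
    out: list[EssentialityCall] = []
    for s, score in zip(stats, scores):
        if score >= thr:
            call = "essential"
        elif score <= -thr:
            call = "nonessential"
        else:
            call = "unclear"
        out.append(
            EssentialityCall(
                gene_id=s.gene_id,
                loglik_score=float(score),
                call=call,
                short_gene=s.length_bp < min_length,
            )
        )
    return out


def fit_insertion_indices(
    indices: Sequence[float],
    trough: float | None = None,
    max_gene_length: int | None = None,
) -> BimodalFit:
    """Convenience: histogram, trough detection (unless overridden), fits."""
    x = np.asarray(indices, dtype=float)
    if trough is None:
        _, edges = histogram_bins(x)
        counts, _ = np.histogram(x, bins=edges)
        trough = find_trough(counts, edges)
    return fit_modes(x, trough, max_gene_length=max_gene_length)
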