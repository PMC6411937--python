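"""Gene-level expression QC for ribosome profiling.

Counts deduplicated unique footprints on trimmed CDS (excluding the
initiation and termination peaks), filters weakly covered genes,
normalizes with median-of-ratios size factors and a log2 transform,
and provides the sample-level diagnostics that expose batch structure:
pairwise Pearson correlation, PCA on the most variable genes, and a
hypergeometric gene-set overlap test.

The log transform here is size-factor normalization followed by
log2(x + pseudocount) — a deliberately simple, documented stand-in for
a regularized log: absolute values differ, but the correlation and PCA
structure this module exists to diagnose is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA

from .align import Footprint
from .qc import psite_of
from .transcripts import TranscriptModel

__all__ = [
    "OverlapTestResult",
    "PCAResult",
    "count_cds",
    "filter_low",
    "size_factors_median_of_ratios",
    "normalize_log",
    "pca_top_variable",
    "pairwise_correlation",
    "hypergeom_overlap",
]


def count_cds(
    samples: Mapping[str, Iterable[Footprint]],
    transcripts: Sequence[TranscriptModel],
    trim: int = 30,
    psite_offsets: int | Mapping[int, int] = 12,
) -> pd.DataFrame:
    """Per-gene counts of unique footprints with a P-site in the trimmed CDS.

    One representative transcript per gene; the first and last ``trim``
    nt of the CDS are excluded to avoid initiation/termination peaks.
    Genes whose trimmed CDS is empty are excluded (with a warning).
    Returns a genes x samples integer DataFrame.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    windows = {}
    excluded = []
    for t in transcripts:
        lo, hi = t.utr5_end + trim, t.cds_end - trim
        if hi > lo:
            windows[t.id] = (lo, hi)
        else:
            excluded.append(t.id)
    if excluded:
        warnings.warn(
            f"{len(excluded)} gene(s) with trimmed CDS length <= 0 excluded: "
            + ", ".join(excluded[:5])
            + ("..." if len(excluded) > 5 else "")
        )
    genes = [t.id for t in transcripts if t.id in windows]
    columns = {}
    for sample, footprints in samples.items():
        acc: dict[str, int] = {}
        for f in footprints:
            if f.category != "unique" or f.reference not in windows:
                continue
            lo, hi = windows[f.reference]
            if lo <= psite_of(f, psite_offsets) < hi:
                acc[f.reference] = acc.get(f.reference, 0) + 1
        columns[sample] = [acc.get(g, 0) for g in genes]
    return pd.DataFrame(columns, index=pd.Index(genes, name="gene"))


def filter_low(counts: pd.DataFrame, min_mean: float = 5.0) -> pd.DataFrame:
    """Keep genes with mean count across all samples >= ``min_mean``."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    return counts.loc[counts.mean(axis=1) >= min_mean]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The reference is the per-gene geometric mean over samples, restricted
    to genes with nonzero counts in every sample; each sample's factor is
    the median of its count/reference ratios.  Falls back to total-count
    factors (scaled to geometric mean 1) when no gene is nonzero
    everywhere.
    """
    x = counts.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn("no gene is nonzero in every sample; using total-count size factors")
        totals = x.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total counts")
        sf = totals / stats.gmean(totals)
        return pd.Series(sf, index=counts.columns, name="size_factor")
    ref = stats.gmean(x[all_nonzero], axis=1)
    sf = np.median(x[all_nonzero] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_log(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Size-factor-normalized log2 counts: log2(count/sf + pseudocount).

    Size factors are attached as ``result.attrs['size_factors']``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sf = size_factors_median_of_ratios(counts)
    out = np.log2(counts / sf + pseudocount)
    out.attrs["size_factors"] = sf
    return out


@dataclass(frozen=True)
class PCAResult:
    """Sample scores and per-component variance fractions."""

    scores: pd.DataFrame  # samples x PCs
    variance_ratio: np.ndarray
    genes: list[str]  # the top-variable genes used
    degenerate: bool = False


def pca_top_variable(matrix: pd.DataFrame, n_top: int = 1000, scale: bool = False) -> PCAResult:
    """PCA of samples on the ``n_top`` most variable genes.

    Matches the R ``prcomp`` convention: samples are observations, genes
    are centered variables, no unit-variance scaling by default (set
    ``scale=True`` for the scaled variant).  Returns scores (samples x
    components) and variance-explained fractions over all components.
    """
    if n_top > matrix.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds gene count {matrix.shape[0]}")
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    variances = matrix.var(axis=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    X = matrix.loc[top].to_numpy(dtype=float).T  # samples x genes
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    total_var = X.var(axis=0, ddof=1).sum()
    degenerate = total_var == 0
    if degenerate:
        warnings.warn("samples are identical on the selected genes; PCA is degenerate")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    with np.errstate(invalid="ignore", divide="ignore"):  # degenerate input
        scores = pca.fit_transform(X)
    ratio = (
        np.zeros(n_comp) if degenerate else pca.explained_variance_ / total_var
    )
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(n_comp)]
        ),
        variance_ratio=ratio,
        genes=list(top),
        degenerate=degenerate,
    )


def pairwise_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of (transformed) expression."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    return matrix.corr(method="pearson")


@dataclass(frozen=True)
class OverlapTestResult:
    """Upper-tail hypergeometric overlap between two gene sets.

    ``p_value`` may underflow to 0 for extreme overlaps; ``log_p_value``
    (natural log) is always finite and exact to numerical precision.
    """

    overlap: int
    n_a: int
    n_b: int
    universe: int
    p_value: float
    log_p_value: float

    def __post_init__(self) -> None:
        if not self.overlap <= min(self.n_a, self.n_b) <= self.universe:
            raise ValueError("require overlap <= min(set sizes) <= universe size")


def hypergeom_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapTestResult:
    """P(X >= k) for the overlap k of two gene sets drawn from a universe.

    X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|); the upper tail is
    accumulated in log space (log-sum-exp over the log pmf), so
    vanishingly small P values (e.g. 1e-43) remain accurate and their
    logarithm never underflows.
    """
    U = set(universe)
    A, B = set(set_a), set(set_b)
    if not A <= U or not B <= U:
        raise ValueError("gene sets must be subsets of the universe")
    k = len(A & B)
    N, K, n = len(U), len(A), len(B)
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:  # k exceeds the support only if inputs are inconsistent
        raise ValueError("overlap exceeds the smaller set")
    logp = special.logsumexp(stats.hypergeom.logpmf(support, N, K, n))
    return OverlapTestResult(
        overlap=k, n_a=K, n_b=n, universe=N,
        p_value=float(min(np.exp(logp), 1.0)), log_p_value=float(min(logp, 0.0)),
    )
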