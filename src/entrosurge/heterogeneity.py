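"""Cell-to-cell heterogeneity via binned Shannon entropy.

For each gene at each time-point, expression values across cells are
histogrammed into N = floor(n_cells / 2) equal-width bins over the observed
range and the Shannon entropy  E = -sum_k p_k log2 p_k  is computed.  A gene
expressed identically in all cells has zero entropy; a gene filling all bins
uniformly attains the maximum log2(N).  Entropy differences between
time-points are assessed by a (paired, by default) Wilcoxon test across
genes, with cell subsampling to establish robustness.  Pseudo-population
averaging (random cell groups averaged per time-point) emulates bulk
measurements from single-cell data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MoleculeMatrix

__all__ = [
    "EntropyTable",
    "gene_entropy",
    "entropy_table",
    "entropy_shift_significance",
    "pseudo_populations",
]

logger = logging.getLogger("entrosurge")


def gene_entropy(values, n_bins: int) -> float:
    """Shannon entropy (bits) of an equal-width histogram over [min, max].

    Probabilities are bin counts over the number of values; ``0 log 0 = 0``.
    A constant vector has zero entropy.  Requires >= 2 values and
    ``n_bins >= 1``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need >= 2 values to estimate entropy")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts / v.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass
class EntropyTable:
    """Per-gene, per-time entropies with consecutive-time differences."""

    entropy: pd.DataFrame  # genes x time-points (bits)
    n_bins: dict  # time-point -> bin count used
    delta: pd.DataFrame  # genes x consecutive pairs ("t1->t2")
    scale: str = "counts"
    significance: dict = field(default_factory=dict)  # "t1->t2" -> percent significant

    def mean_profile(self) -> pd.Series:
        """Mean entropy over genes at each time-point."""
        return self.entropy.mean(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.entropy.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def _bins_for(n_cells: int) -> int:
    return max(1, n_cells // 2)


def entropy_table(matrix: MoleculeMatrix, scale: str = "counts") -> EntropyTable:
    """Entropy of every gene at every time-point, plus delta-entropy.

    Bin count is floor(n_cells/2) per time-point.  ``scale='log'`` computes
    entropies on ln(m+1) values instead of raw counts (equal-width binning
    is not scale-invariant, so the choice is explicit).  Time-points with
    fewer than 2 cells are excluded with a warning.
    """
    if scale not in ("counts", "log"):
        raise ValueError("scale must be 'counts' or 'log'")
    times = []
    n_bins = {}
    for t in matrix.times:
        if matrix.n_cells_at(t) < 2:
            warnings.warn(f"time-point {t:g} h has < 2 cells; excluded from entropy table")
            continue
        times.append(t)
        n_bins[t] = _bins_for(matrix.n_cells_at(t))
    ent = pd.DataFrame(index=matrix.genes, columns=times, dtype=float)
    for t in times:
        sub = matrix.at_time(t)
        if scale == "log":
            sub = np.log1p(sub)
        for gene in matrix.genes:
            ent.loc[gene, t] = gene_entropy(sub[gene].to_numpy(), n_bins[t])
    pairs = {}
    for t1, t2 in zip(times, times[1:]):
        pairs[f"{t1:g}->{t2:g}"] = ent[t2] - ent[t1]
    delta = pd.DataFrame(pairs, index=ent.index)
    return EntropyTable(entropy=ent, n_bins=n_bins, delta=delta, scale=scale)


def _wilcoxon_p(e1: np.ndarray, e2: np.ndarray, paired: bool) -> float:
    d = e1 - e2
    try:
        if paired:
            if np.allclose(d, 0):
                return 1.0
            return float(stats.wilcoxon(e1, e2, zero_method="wilcox").pvalue)
        return float(stats.mannwhitneyu(e1, e2, alternative="two-sided").pvalue)
    except ValueError:
        return 1.0


def entropy_shift_significance(
    matrix: MoleculeMatrix,
    t1: float,
    t2: float,
    n_iter: int = 1000,
    subsample_frac: float = 0.85,
    seed: int = 0,
    alpha: float = 0.05,
    paired: bool = True,
    scale: str = "counts",
) -> float:
    """Percent of subsampling iterations with a significant entropy shift.

    Each iteration subsamples ``floor(frac * n_cells)`` cells per time-point
    without replacement, recomputes per-gene entropies (bins floor(n/2) of
    the subsample) and runs a Wilcoxon test across genes between the two
    time-points (paired signed-rank by default; rank-sum with
    ``paired=False``).  Returns the percentage of iterations with
    ``p < alpha``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    for t in (t1, t2):
        if t not in matrix.times:
            raise ValueError(f"time-point {t!r} not present")
    sub1 = matrix.at_time(t1)
    sub2 = matrix.at_time(t2)
    if scale == "log":
        sub1, sub2 = np.log1p(sub1), np.log1p(sub2)
    x1, x2 = sub1.to_numpy(), sub2.to_numpy()
    n1 = max(2, int(np.floor(subsample_frac * x1.shape[0])))
    n2 = max(2, int(np.floor(subsample_frac * x2.shape[0])))
    b1, b2 = _bins_for(n1), _bins_for(n2)
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_genes = x1.shape[1]
    for _ in range(n_iter):
        idx1 = rng.choice(x1.shape[0], size=n1, replace=False)
        # one subsample per time label: comparing a time-point with itself
        # uses identical cells and is never "significant"
        idx2 = idx1 if t1 == t2 else rng.choice(x2.shape[0], size=n2, replace=False)
        e1 = np.empty(n_genes)
        e2 = np.empty(n_genes)
        for g in range(n_genes):
            e1[g] = gene_entropy(x1[idx1, g], b1)
            e2[g] = gene_entropy(x2[idx2, g], b2)
        if _wilcoxon_p(e1, e2, paired) < alpha:
            n_sig += 1
    return 100.0 * n_sig / n_iter


def pseudo_populations(matrix: MoleculeMatrix, k: int, seed: int = 0) -> MoleculeMatrix:
    """Average random cell groups into ``k`` pseudo-bulk samples per time-point.

    Cells at each time-point are randomly partitioned into ``k`` groups with
    sizes differing by at most one; each pseudo-population is the per-gene
    mean of its cells (missing entries ignored).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    rows, ids, times = [], [], []
    for t in matrix.times:
        sub = matrix.at_time(t)
        if k > len(sub):
            raise ValueError(f"k={k} exceeds the {len(sub)} cells at time {t:g}")
        perm = rng.permutation(len(sub))
        for j, grp in enumerate(np.array_split(perm, k)):
            rows.append(sub.iloc[grp].mean(axis=0, skipna=True))
            ids.append(f"t{t:g}_p{j}")
            times.append(t)
    values = pd.DataFrame(rows, index=ids)
    return MoleculeMatrix(values, pd.Series(times, index=ids), truth_labels=dict(matrix.truth_labels))
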