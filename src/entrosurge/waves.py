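"""Early expression waves and gene-set enrichment.

A gene belongs to the wave at time T if a significant expression change is
detected between T and at least one earlier time-point, and the gene does
not already belong to an earlier wave.  Detection uses a two-sided
Mann-Whitney U test repeated over bootstrap resamples of cells (with
replacement, within each time-point); a change counts only if the test is
positive (p < alpha) in more than ``support_threshold`` of the bootstrap
replicates.  Enrichment of a wave gene set in a functional category is
quantified with the exact hypergeometric law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MoleculeMatrix

__all__ = [
    "WaveTable",
    "bootstrap_mw_support",
    "assign_waves",
    "waves_from_supports",
    "hypergeom_enrichment",
]


@dataclass
class WaveTable:
    """Per-gene wave assignment with bootstrap support."""

    table: pd.DataFrame  # index gene; columns wave_time (NaN = none), best_support
    supports: dict  # (gene, ta, tb) -> support fraction
    params: dict = field(default_factory=dict)

    def genes_in_wave(self, t: float) -> list[str]:
        sel = self.table["wave_time"] == t
        return sorted(self.table.index[sel])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", na_rep="NA")


def _mw_p_single(x: np.ndarray, y: np.ndarray) -> float:
    allv = np.concatenate([x, y])
    if np.all(allv == allv[0]):
        return 1.0  # fully tied data: no detectable shift, by convention
    try:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)
    except ValueError:
        return 1.0


def _mw_pvalues_boot(x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Two-sided Mann-Whitney p-values over bootstrap resamples.

    Small groups (both sizes <= 8) use the exact/auto scipy test per
    replicate; larger groups use the normal approximation with midranks,
    tie correction and continuity correction, vectorised over replicates.
    """
    n1, n2 = x.size, y.size
    if n1 <= 8 and n2 <= 8:
        ps = np.empty(n_boot)
        for b_i in range(n_boot):
            ps[b_i] = _mw_p_single(x[rng.integers(0, n1, n1)], y[rng.integers(0, n2, n2)])
        return ps
    xb = x[rng.integers(0, n1, (n_boot, n1))]
    yb = y[rng.integers(0, n2, (n_boot, n2))]
    comb = np.concatenate([xb, yb], axis=1)
    ranks = stats.rankdata(comb, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = np.empty(n_boot)
    for b_i in range(n_boot):
        _, counts = np.unique(comb[b_i], return_counts=True)
        tie_term[b_i] = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    ps = np.ones(n_boot)
    ok = var > 0
    z = (np.abs(u1[ok] - mu) - 0.5) / np.sqrt(var[ok])
    ps[ok] = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    return ps


def bootstrap_mw_support(
    matrix: MoleculeMatrix,
    gene: str,
    ta: float,
    tb: float,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of bootstrap replicates detecting a shift for one gene.

    Cells are resampled with replacement within each time-point (original
    group sizes); each replicate runs a two-sided Mann-Whitney test between
    the two time-points.  Fully tied data yields p = 1 (support 0).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    for t in (ta, tb):
        if t not in matrix.times:
            raise ValueError(f"time-point {t!r} not present")
    x = matrix.at_time(ta)[gene].dropna().to_numpy()
    y = matrix.at_time(tb)[gene].dropna().to_numpy()
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 cells per time-point")
    rng = np.random.default_rng(seed)
    ps = _mw_pvalues_boot(x, y, n_boot, rng)
    return float(np.mean(ps < alpha))


def waves_from_supports(
    supports: dict,
    genes,
    times,
    support_threshold: float = 0.9,
) -> pd.DataFrame:
    """Assign waves from a precomputed support table.

    Scanning times in order, a gene joins the wave at time T if its support
    against at least one earlier time-point *strictly* exceeds the
    threshold, and the gene is not already in an earlier wave.
    """
    times = list(times)
    rows = {}
    for gene in genes:
        wave = np.nan
        best = 0.0
        for ti, t in enumerate(times[1:], start=1):
            cands = [supports[(gene, ta, t)] for ta in times[:ti] if (gene, ta, t) in supports]
            if cands and max(cands) > support_threshold:
                wave = t
                best = max(cands)
                break
        rows[gene] = {"wave_time": wave, "best_support": best}
    return pd.DataFrame.from_dict(rows, orient="index")[["wave_time", "best_support"]]


def assign_waves(
    matrix: MoleculeMatrix,
    times=None,
    n_boot: int = 1000,
    support_threshold: float = 0.9,
    alpha: float = 0.05,
    seed: int = 0,
) -> WaveTable:
    """Wave assignment for every gene over ordered time-points.

    For each gene and each time T, bootstrap Mann-Whitney support is
    computed against every earlier time-point; the first T with support
    above the threshold fixes the gene's wave.  Re-running with the same
    seed reproduces the table exactly.
    """
    if times is None:
        times = matrix.times
    times = [float(t) for t in times]
    if len(times) < 2:
        raise ValueError("need >= 2 ordered time-points")
    if sorted(set(times)) != times:
        raise ValueError("time labels must be strictly increasing and unique")
    for t in times:
        if t not in matrix.times:
            raise ValueError(f"time-point {t!r} not present in matrix")
    genes = matrix.genes
    supports = {}
    for gi, gene in enumerate(genes):
        for tj, tb in enumerate(times[1:], start=1):
            for ti, ta in enumerate(times[:tj]):
                pair_seed = np.random.SeedSequence([seed, gi, ti, tj])
                rng = np.random.default_rng(pair_seed)
                x = matrix.at_time(ta)[gene].dropna().to_numpy()
                y = matrix.at_time(tb)[gene].dropna().to_numpy()
                if x.size < 3 or y.size < 3:
                    raise ValueError(f"need >= 3 cells at {ta:g} and {tb:g} for gene {gene}")
                ps = _mw_pvalues_boot(x, y, n_boot, rng)
                supports[(gene, ta, tb)] = float(np.mean(ps < alpha))
    table = waves_from_supports(supports, genes, times, support_threshold)
    params = {
        "n_boot": n_boot,
        "support_threshold": support_threshold,
        "alpha": alpha,
        "seed": seed,
        "times": times,
    }
    return WaveTable(table=table, supports=supports, params=params)


def hypergeom_enrichment(k: int, n_draws: int, K: int, N: int, tail: str = "pmf") -> float:
    """Exact hypergeometric probability via big-integer combinatorics.

    ``pmf``: probability of exactly ``k`` category members among
    ``n_draws`` draws from a universe of ``N`` with ``K`` category members;
    ``upper``: P(X >= k).  Impossible configurations (k > K or more
    non-members required than exist) have probability 0.
    """
    if tail not in ("pmf", "upper"):
        raise ValueError("tail must be 'pmf' or 'upper'")
    if not (0 <= K <= N and 0 <= n_draws <= N and k >= 0):
        raise ValueError(f"inconsistent arguments k={k}, n={n_draws}, K={K}, N={N}")
    if k > n_draws:
        raise ValueError(f"k={k} exceeds the number of draws {n_draws}")

    def pmf(j: int) -> Fraction:
        if j > K or n_draws - j > N - K:
            return Fraction(0)
        return Fraction(math.comb(K, j) * math.comb(N - K, n_draws - j), math.comb(N, n_draws))

    if tail == "pmf":
        return float(pmf(k))
    return float(sum(pmf(j) for j in range(k, min(n_draws, K) + 1)))
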