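"""Gene-gene correlation networks per time-point.

Pairwise Spearman (default) or Pearson correlations across cells at one
time-point, Bonferroni-controlled over the G(G-1)/2 tests, made robust by
repeated subsampling of cells: an edge survives only if it is significant
with a constant sign in every iteration.  Additional views: edge/hub
summaries, correlation variation between consecutive time-points, and the
four-block bulk/single-cell cross-correlation structure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import MoleculeMatrix

__all__ = [
    "CorrelationGraph",
    "CorrelationDelta",
    "correlation_matrix",
    "robust_network",
    "network_summary",
    "correlation_delta",
    "cross_correlation_structure",
]

logger = logging.getLogger("entrosurge")


@dataclass
class CorrelationGraph:
    """Subsampling-robust correlation network at one time-point."""

    time: float
    graph: nx.Graph  # nodes = genes; edge attrs: rho, p_adj
    method: str
    frac: float
    n_iter: int
    alpha: float

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "rho": d["rho"], "p_adj": d["p_adj"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p_adj"])

    def to_tsv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class CorrelationDelta:
    """Correlation variation between two time-points."""

    delta: pd.DataFrame  # genes x genes, rho(t2) - rho(t1)
    band: float
    n_increasing: int = field(init=False)
    n_decreasing: int = field(init=False)

    def __post_init__(self):
        v = self.delta.to_numpy()
        iu = np.triu_indices(v.shape[0], k=1)
        off = v[iu]
        off = off[~np.isnan(off)]
        self.n_increasing = int((off > self.band).sum())
        self.n_decreasing = int((off < -self.band).sum())


def _pearson_with_p(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix and two-sided p-values (t approximation)."""
    n = x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(x, rowvar=False)
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(rho)] = np.nan
    return rho, p


def correlation_matrix(
    matrix: MoleculeMatrix, t: float, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise gene correlations at a time-point with Bonferroni-adjusted p.

    Ties are handled by midranks (Spearman); p-values come from the
    t-approximation and are multiplied by the number of tests G(G-1)/2
    (capped at 1).  Zero-variance genes yield NA rows/columns.  Requires
    >= 4 cells.
    """
    sub = matrix.at_time(t)
    return _correlation_frame(sub, method)


def _correlation_frame(
    sub: pd.DataFrame, method: str, bonferroni: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = sub.to_numpy(dtype=float)
    n, g = x.shape
    if n < 4:
        raise ValueError(f"need >= 4 cells, got {n}")
    if method == "spearman":
        # Spearman = Pearson on midranks; p from the same t-approximation
        x = stats.rankdata(x, axis=0)
    rho, p = _pearson_with_p(x)
    zero_var = np.nanstd(x, axis=0) == 0
    rho[zero_var, :] = np.nan
    rho[:, zero_var] = np.nan
    p[zero_var, :] = np.nan
    p[:, zero_var] = np.nan
    n_tests = g * (g - 1) // 2
    p_adj = np.minimum(p * n_tests, 1.0) if bonferroni else p
    np.fill_diagonal(rho, np.where(zero_var, np.nan, 1.0))
    np.fill_diagonal(p_adj, np.nan)
    genes = sub.columns
    return (
        pd.DataFrame(rho, index=genes, columns=genes),
        pd.DataFrame(p_adj, index=genes, columns=genes),
    )


def robust_network(
    matrix: MoleculeMatrix,
    t: float,
    frac: float = 0.85,
    n_iter: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "spearman",
    bonferroni: bool = True,
) -> CorrelationGraph:
    """Subsampling-robust correlation network at one time-point.

    Each iteration subsamples ``floor(frac * n_cells)`` cells without
    replacement; an edge survives iff its (Bonferroni-adjusted, unless
    disabled) p-value is below ``alpha`` with the same correlation sign in
    *every* iteration.  Edge weights are the full-data correlations.  With
    ``frac=1, n_iter=1`` this reduces exactly to thresholding the plain
    correlation matrix.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sub = matrix.at_time(t)
    n_cells = len(sub)
    n_take = int(np.floor(frac * n_cells))
    if n_take < 4:
        raise ValueError(f"floor(frac * n_cells) = {n_take} < 4: too few cells per subsample")
    genes = list(sub.columns)
    g = len(genes)
    rho_full, p_full = _correlation_frame(sub, method, bonferroni=bonferroni)
    rng = np.random.default_rng(seed)
    alive = np.ones((g, g), dtype=bool)
    sign_ref = np.zeros((g, g), dtype=np.int8)
    x = sub.to_numpy(dtype=float)
    n_tests = g * (g - 1) // 2
    for _ in range(n_iter):
        idx = rng.choice(n_cells, size=n_take, replace=False) if n_take < n_cells else np.arange(n_cells)
        frame = pd.DataFrame(x[idx], columns=genes)
        rho_i, p_i = _correlation_frame(frame, method, bonferroni=bonferroni)
        p_use = p_i.to_numpy()
        sig = (p_use < alpha) & ~np.isnan(p_use)
        s = np.sign(rho_i.to_numpy()).astype(np.int8)
        first = sign_ref == 0
        sign_ref[first] = s[first]
        alive &= sig & (s == sign_ref)
        if not alive.any():
            break
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for i, j in itertools.combinations(range(g), 2):
        if alive[i, j] and alive[j, i]:
            graph.add_edge(
                genes[i],
                genes[j],
                rho=float(rho_full.iat[i, j]),
                p_adj=float(p_full.iat[i, j]),
            )
    logger.info(
        "robust network at t=%g h: %d/%d edges survive %d iterations (frac=%.2f)",
        t, graph.number_of_edges(), n_tests, n_iter, frac,
    )
    return CorrelationGraph(time=t, graph=graph, method=method, frac=frac, n_iter=n_iter, alpha=alpha)


def network_summary(graph: CorrelationGraph, top_k: int = 3) -> tuple[int, list[tuple[str, int]]]:
    """Edge count and the ``top_k`` highest-degree genes (ties by name)."""
    degrees = dict(graph.graph.degree())
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [(gene, int(deg)) for gene, deg in ranked[:top_k] if deg > 0]
    return graph.n_edges, top


def correlation_delta(rho_t1: pd.DataFrame, rho_t2: pd.DataFrame, band: float = 0.4) -> CorrelationDelta:
    """Per-pair correlation change rho(t2) - rho(t1), with counts beyond +/- band."""
    if list(rho_t1.columns) != list(rho_t2.columns) or list(rho_t1.index) != list(rho_t2.index):
        raise ValueError("correlation matrices must share the same gene set and order")
    return CorrelationDelta(delta=rho_t2 - rho_t1, band=band)


def cross_correlation_structure(bulk: pd.DataFrame, sc: MoleculeMatrix) -> dict[str, pd.DataFrame]:
    """Four-block correlation structure between bulk and single-cell data.

    ``bulk`` is samples x genes with time labels as index; the single-cell
    matrix is aggregated to per-time-point means matched to the bulk
    samples for the between-dataset block.  Returns Pearson blocks
    ``within_bulk``, ``within_sc`` and ``between`` (bulk genes x sc genes).
    """
    shared = [gene for gene in bulk.columns if gene in set(sc.genes)]
    if not shared:
        raise ValueError("no shared genes between bulk and single-cell data")
    b = bulk[shared].astype(float)
    within_bulk = b.corr(method="pearson")
    sc_vals = sc.values[shared]
    within_sc = sc_vals.corr(method="pearson")
    sc_means = sc_vals.groupby(sc.time_h).mean()
    sc_means = sc_means.reindex(b.index)
    if sc_means.isna().all(axis=None):
        raise ValueError("no single-cell time-points match the bulk sample labels")
    between = pd.DataFrame(index=shared, columns=shared, dtype=float)
    for gb in shared:
        for gs in shared:
            xb = b[gb].to_numpy()
            xs = sc_means[gs].to_numpy()
            ok = ~np.isnan(xb) & ~np.isnan(xs)
            if ok.sum() >= 3 and np.std(xb[ok]) > 0 and np.std(xs[ok]) > 0:
                between.loc[gb, gs] = float(np.corrcoef(xb[ok], xs[ok])[0, 1])
    return {"within_bulk": within_bulk, "within_sc": within_sc, "between": between}
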