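"""Dynamical network biomarker (DNB) analysis.

A DNB is a gene subset D whose rising variability (CV), rising internal
correlation (PCCin) and falling external correlation (PCCout) signal an
approaching critical transition.  The aggregate statistic is

    I = CV * PCCin / PCCout

with, over n genes of which n_D are in D,

    CV     = (1/n_D)       * sum_{i in D} CV_i
    PCCin  = (1/n_D^2)     * sum_{i,j in D} C_ij          (diagonal included)
    PCCout = (1/(n_D(n-n_D))) * sum_{i in D, j notin D} C_ij

where CV_i is the coefficient of variation of gene i across cells and C_ij
a Pearson correlation coefficient.  Defaults evaluate the sums exactly as
written (signed correlations, self-terms included); ``absolute=True`` and
``include_diagonal=False`` expose the variants common in the DNB
literature.  Candidate genes are screened between two time-points: member
of at least one pair whose correlation rises by a threshold, with a rising
CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MoleculeMatrix

__all__ = [
    "DNBResult",
    "select_dnb_candidates",
    "i_score",
    "i_score_from_components",
    "dnb_profile",
]


@dataclass
class DNBResult:
    """DNB gene set with its per-time-point score components."""

    genes: tuple[str, ...]
    n_total: int
    table: pd.DataFrame  # index: time; columns: CV, PCCin, PCCout, I

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "time_h"
        out.to_csv(path, sep="\t")


def _cv(sub: pd.DataFrame) -> pd.Series:
    """Per-gene coefficient of variation (sample SD / mean) across cells."""
    mean = sub.mean(axis=0, skipna=True)
    sd = sub.std(axis=0, ddof=1, skipna=True)
    return sd / mean


def _corr(sub: pd.DataFrame, method: str) -> pd.DataFrame:
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    return sub.corr(method=method)


def select_dnb_candidates(
    matrix: MoleculeMatrix,
    t0: float,
    t1: float,
    corr_threshold: float = 0.5,
    method: str = "spearman",
) -> set[str]:
    """Two-stage candidate screen between two time-points.

    A gene qualifies iff (1) it participates in at least one pair whose
    correlation increases by at least ``corr_threshold`` from t0 to t1 and
    (2) its CV increases from t0 to t1.  An empty set is a valid outcome.
    """
    for t in (t0, t1):
        if t not in matrix.times:
            raise ValueError(f"time-point {t!r} not present")
    sub0, sub1 = matrix.at_time(t0), matrix.at_time(t1)
    rho0 = _corr(sub0, method)
    rho1 = _corr(sub1, method)
    inc = (rho1 - rho0) >= corr_threshold
    np.fill_diagonal(inc.values, False)
    in_rising_pair = inc.any(axis=1)
    cv_rising = _cv(sub1) > _cv(sub0)
    return set(in_rising_pair.index[in_rising_pair & cv_rising])


def i_score_from_components(
    corr: pd.DataFrame,
    cvs: pd.Series,
    D,
    include_diagonal: bool = True,
    absolute: bool = False,
) -> dict:
    """Evaluate the I-score formulas from a correlation matrix and CVs.

    Returns a dict with CV, PCCin, PCCout, I (NaN when PCCout is 0, i.e.
    undefined), n_D and n.  NaN correlations (zero-variance genes) are
    excluded from the block means.
    """
    genes = list(corr.columns)
    D = [g for g in genes if g in set(D)]
    n, n_d = len(genes), len(D)
    if not 0 < n_d < n:
        raise ValueError(f"need 0 < |D| < n, got |D|={n_d}, n={n}")
    out = [g for g in genes if g not in set(D)]
    c = corr.to_numpy(dtype=float)
    if absolute:
        c = np.abs(c)
    di = [genes.index(g) for g in D]
    oi = [genes.index(g) for g in out]
    block_in = c[np.ix_(di, di)].copy()
    if not include_diagonal:
        np.fill_diagonal(block_in, np.nan)
    block_out = c[np.ix_(di, oi)]
    pcc_in = float(np.nanmean(block_in))
    pcc_out = float(np.nanmean(block_out))
    cv = float(np.mean([cvs[g] for g in D]))
    i_val = cv * pcc_in / pcc_out if pcc_out != 0 else float("nan")
    return {"CV": cv, "PCCin": pcc_in, "PCCout": pcc_out, "I": i_val, "n_D": n_d, "n": n}


def i_score(
    matrix: MoleculeMatrix,
    D,
    t: float,
    method: str = "pearson",
    absolute: bool = False,
    include_diagonal: bool = True,
) -> dict:
    """I-score components for gene set D at one time-point.

    Requires >= 4 cells at ``t``.  A zero-mean gene in D makes its CV
    undefined and is an error naming the gene; PCCout = 0 yields an
    undefined (NaN) I rather than an error.
    """
    sub = matrix.at_time(t)
    if len(sub) < 4:
        raise ValueError(f"need >= 4 cells at t={t!r}")
    cvs = _cv(sub)
    for g in set(D):
        if g not in sub.columns:
            raise ValueError(f"gene {g!r} not in matrix")
        mean_g = sub[g].mean(skipna=True)
        sd_g = sub[g].std(ddof=1, skipna=True)
        if mean_g == 0 or sd_g == 0 or np.isnan(cvs[g]) or np.isinf(cvs[g]):
            raise ValueError(f"CV undefined for gene {g!r} at t={t!r} (zero mean or zero spread)")
    corr = _corr(sub, method)
    return i_score_from_components(corr, cvs, D, include_diagonal=include_diagonal, absolute=absolute)


def dnb_profile(
    matrix: MoleculeMatrix,
    D,
    method: str = "pearson",
    absolute: bool = False,
    include_diagonal: bool = True,
) -> DNBResult:
    """CV, PCCin, PCCout and I for gene set D at every time-point."""
    rows = {}
    for t in matrix.times:
        comp = i_score(
            matrix, D, t, method=method, absolute=absolute, include_diagonal=include_diagonal
        )
        rows[t] = {k: comp[k] for k in ("CV", "PCCin", "PCCout", "I")}
    table = pd.DataFrame(rows).T
    return DNBResult(genes=tuple(sorted(set(D))), n_total=len(matrix.genes), table=table)
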