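"""Low-level single-cell RT-qPCR processing: from raw Cq values to molecules.

The chain mirrors a microfluidic-chip (BioMark-style) workflow:

1. parse the long-format Cq export (``UD`` = quality-control failure,
   ``999`` = no detection within the cycle limit),
2. primer-efficiency screening from serial-dilution curves,
3. cell filtering (valid spikes; empty-well outlier rule),
4. per-cell spike normalisation  ``Cq_ij = Cq^_ij - (Cqbar_i - Cqbar_0)``,
5. conversion to absolute molecule numbers
   ``m_ij = W * S * 2^(max_cq - preamp - Cq_ij)`` (defaults 96 x 45 x 2^(30-22-Cq)),
6. optional ``ln(m+1)`` transform for linear analyses,
7. Poisson-Beta replacement of missing values, fit per gene per time-point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MoleculeMatrix
from .two_state import EstimatorFailure, PoissonBetaParams, fit_poisson_beta_moments

__all__ = [
    "AssayConstants",
    "CqDataset",
    "SpikeSummary",
    "EfficiencyRecord",
    "CODE_NODETECT",
    "parse_cq_csv",
    "primer_efficiency",
    "select_valid_cells",
    "normalize_cq",
    "cq_to_molecules",
    "log1_transform",
    "impute_missing",
    "technical_span_summary",
]

logger = logging.getLogger("entrosurge")

#: Cq code meaning "no detection within the cycle limit"
CODE_NODETECT = 999.0

_CSV_COLUMNS = ["cell_id", "time_h", "target", "target_type", "cq", "status"]


@dataclass(frozen=True)
class AssayConstants:
    """Assay geometry entering the molecule-count formula.

    ``plate_wells``: dilution of one cell extract over the plate;
    ``pcr_sampling``: 1/fraction of the well sampled by the PCR;
    ``preamp_cycles``: pre-amplification cycles; ``max_cq``: Cq at which a
    single molecule is measured (detection limit).
    """

    plate_wells: int = 96
    pcr_sampling: int = 45
    preamp_cycles: int = 22
    max_cq: float = 30.0


@dataclass(frozen=True)
class SpikeSummary:
    """Per-cell mean spike Cq and the global reference used to normalise."""

    per_cell: pd.Series  # mean spike Cq per retained cell
    n_valid: pd.Series  # number of valid spike measurements per cell
    global_mean: float  # mean over all valid spike measurements (Cqbar_0)


@dataclass(frozen=True)
class EfficiencyRecord:
    """Primer-pair PCR efficiency from a serial-dilution curve."""

    slope: float
    efficiency: float
    percent: float
    keep: bool


class CqDataset:
    """Long-format per-(cell, target) Cq records with status codes.

    The backing frame has columns ``cell_id, time_h, target, target_type,
    cq, status``.  ``status`` is ``OK`` or ``UD``; for UD records ``cq`` is
    NaN; ``cq == 999`` encodes no detection.  ``target_type`` is ``gene`` or
    ``spike``.
    """

    def __init__(self, df: pd.DataFrame, constants: AssayConstants = AssayConstants()):
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CqDataset frame missing columns: {missing}")
        df = df.copy()
        df["cq"] = df["cq"].astype(float)
        df["time_h"] = df["time_h"].astype(float)
        bad_status = set(df["status"]) - {"OK", "UD"}
        if bad_status:
            raise ValueError(f"invalid status values: {sorted(bad_status)}")
        bad_type = set(df["target_type"]) - {"gene", "spike"}
        if bad_type:
            raise ValueError(f"invalid target_type values: {sorted(bad_type)}")
        ud = df["status"] == "UD"
        if df.loc[ud, "cq"].notna().any():
            raise ValueError("UD records must not carry a numeric Cq")
        if df.loc[~ud, "cq"].isna().any():
            raise ValueError("OK records must carry a numeric Cq (or 999)")
        numeric = (~ud) & (df["cq"] != CODE_NODETECT)
        vals = df.loc[numeric, "cq"]
        if ((vals <= 0) | (vals > constants.max_cq)).any():
            raise ValueError(f"numeric Cq values must lie in (0, {constants.max_cq}]")
        if df.duplicated(["cell_id", "target"]).any():
            dup = df[df.duplicated(["cell_id", "target"], keep=False)].iloc[0]
            raise ValueError(f"duplicate record for cell {dup.cell_id!r} target {dup.target!r}")
        self.df = df.reset_index(drop=True)
        self.constants = constants
        self.spike_summary: SpikeSummary | None = None
        self.removal_log: dict = {}

    # -- accessors ---------------------------------------------------------

    @property
    def cells(self) -> list[str]:
        return list(pd.unique(self.df["cell_id"]))

    @property
    def genes(self) -> list[str]:
        return sorted(self.df.loc[self.df.target_type == "gene", "target"].unique())

    @property
    def spikes(self) -> list[str]:
        return sorted(self.df.loc[self.df.target_type == "spike", "target"].unique())

    def _valid(self) -> pd.Series:
        """Boolean mask of records with a usable numeric Cq."""
        return (self.df["status"] == "OK") & (self.df["cq"] != CODE_NODETECT)

    def copy(self) -> "CqDataset":
        out = CqDataset(self.df.copy(), self.constants)
        out.spike_summary = self.spike_summary
        out.removal_log = dict(self.removal_log)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CqDataset({len(self.cells)} cells, {len(self.genes)} genes, "
            f"{len(self.spikes)} spikes)"
        )

    # -- I/O ---------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        out = self.df.loc[:, _CSV_COLUMNS].copy()
        out["cq"] = out["cq"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        out.to_csv(path, index=False)


def parse_cq_csv(path: str | Path, constants: AssayConstants = AssayConstants()) -> CqDataset:
    """Parse the long-format Cq CSV written by the generator / exporter.

    Malformed rows are rejected with their line number; duplicate
    (cell, target) records are an error.  An empty file (header only) yields
    an empty dataset.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _CSV_COLUMNS:
        raise ValueError(f"bad header in {path}: expected {_CSV_COLUMNS}, got {list(df.columns)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        status = row.status
        raw_cq = row.cq.strip()
        if status not in ("OK", "UD"):
            raise ValueError(f"{path}:{i}: invalid status {status!r}")
        if row.target_type not in ("gene", "spike"):
            raise ValueError(f"{path}:{i}: invalid target_type {row.target_type!r}")
        if status == "UD":
            if raw_cq not in ("", "UD"):
                raise ValueError(f"{path}:{i}: UD record must not carry a Cq value")
            cq = np.nan
        else:
            try:
                cq = float(raw_cq)
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: unparseable Cq {raw_cq!r}") from exc
        try:
            time_h = float(row.time_h)
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: unparseable time_h {row.time_h!r}") from exc
        records.append((row.cell_id, time_h, row.target, row.target_type, cq, status))
    frame = pd.DataFrame(records, columns=_CSV_COLUMNS)
    return CqDataset(frame, constants)


def primer_efficiency(dilution_cqs) -> EfficiencyRecord:
    """PCR efficiency from a serial dilution: ``E = 10^(-1/slope)``.

    ``dilution_cqs`` is a sequence of (log10 dilution, Cq) pairs; the slope
    is the least-squares regression of Cq on log10 dilution.  The primer is
    kept iff the efficiency percentage ``(E - 1) * 100`` lies in [80, 120].
    """
    pts = np.asarray(list(dilution_cqs), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (log10 dilution, Cq) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero-variance dilution series")
    slope = float(np.polyfit(x, y, 1)[0])
    if slope == 0:
        raise ValueError("flat dilution curve: efficiency undefined")
    eff = 10.0 ** (-1.0 / slope)
    percent = (eff - 1.0) * 100.0
    return EfficiencyRecord(slope=slope, efficiency=eff, percent=percent, keep=80.0 <= percent <= 120.0)


def _undetected_gene_counts(data: CqDataset) -> pd.Series:
    """Per-cell count of gene records that are UD or undetected (999)."""
    g = data.df[data.df.target_type == "gene"]
    bad = (g["status"] == "UD") | (g["cq"] == CODE_NODETECT)
    return bad.groupby(g["cell_id"]).sum().reindex(data.cells, fill_value=0)


def select_valid_cells(
    data: CqDataset, low_expr_mad_k: float = 3.0, max_undetected_frac: float = 0.9
) -> CqDataset:
    """Remove cells without any valid spike, then empty-well outliers.

    A cell survives stage one iff it has >= 1 spike record with a numeric Cq
    (not UD, not 999).  Stage two removes cells whose number of
    undetected/UD genes exceeds ``median + k * MAD`` across the remaining
    cells (a robust screen for wells with no or a dying cell), or whose
    undetected fraction exceeds ``max_undetected_frac`` outright (the
    relative rule is blind when most wells are empty).
    """
    spikes = data.df[data.df.target_type == "spike"]
    valid_spike = (spikes["status"] == "OK") & (spikes["cq"] != CODE_NODETECT)
    n_valid = valid_spike.groupby(spikes["cell_id"]).sum().reindex(data.cells, fill_value=0)
    keep1 = set(n_valid[n_valid >= 1].index)
    removed_no_spike = [c for c in data.cells if c not in keep1]

    stage1 = data.df[data.df.cell_id.isin(keep1)]
    if stage1.empty:
        raise ValueError("all cells removed (no valid spikes); inspect the input dataset")
    d1 = CqDataset(stage1, data.constants)

    counts = _undetected_gene_counts(d1)
    med = float(counts.median())
    mad = float((counts - med).abs().median())
    # MAD floor of one count: with (near-)zero dropout the MAD degenerates
    # to 0 and a single undetected gene must not condemn a cell
    threshold = med + low_expr_mad_k * max(mad, 1.0)
    n_genes = len(d1.genes)
    abs_limit = max_undetected_frac * n_genes
    keep2 = set(counts[(counts <= threshold) & (counts <= abs_limit)].index)
    removed_low_expr = sorted(set(d1.cells) - keep2)
    stage2 = d1.df[d1.df.cell_id.isin(keep2)]
    if stage2.empty:
        raise ValueError("all cells removed by the low-expression filter; inspect thresholds")
    out = CqDataset(stage2, data.constants)
    out.removal_log = {
        "no_valid_spike": sorted(removed_no_spike),
        "low_expression": removed_low_expr,
        "undetected_threshold": threshold,
        "n_retained": len(out.cells),
    }
    logger.info(
        "cell filtering: %d removed (no valid spike), %d removed (empty-well rule), %d retained",
        len(removed_no_spike), len(removed_low_expr), len(out.cells),
    )
    return out


def spike_summary(data: CqDataset) -> SpikeSummary:
    """Per-cell mean spike Cq and the global reference Cqbar_0.

    The global reference is the mean over *all* valid spike measurements of
    the retained cells (cells without any valid spike must have been removed
    beforehand).
    """
    spikes = data.df[data.df.target_type == "spike"]
    valid = spikes[(spikes["status"] == "OK") & (spikes["cq"] != CODE_NODETECT)]
    if valid.empty:
        raise ValueError("no valid spike measurements; run select_valid_cells first")
    per_cell = valid.groupby("cell_id")["cq"].mean().reindex(data.cells)
    n_valid = valid.groupby("cell_id")["cq"].size().reindex(data.cells, fill_value=0)
    if per_cell.isna().any():
        missing = per_cell[per_cell.isna()].index.tolist()
        raise ValueError(f"cells without valid spikes present: {missing}; run select_valid_cells")
    return SpikeSummary(per_cell=per_cell, n_valid=n_valid, global_mean=float(valid["cq"].mean()))


def normalize_cq(data: CqDataset) -> CqDataset:
    """Spike-normalise every numeric Cq: ``Cq_ij = Cq^_ij - (Cqbar_i - Cqbar_0)``.

    The per-cell shift (mean spike Cq minus the global spike mean) captures
    reverse-transcription efficiency, the dominant technical noise source;
    subtracting it is exactly corrective for an additive per-cell offset.
    UD and 999 codes pass through unchanged; raw values are kept in a
    ``cq_raw`` column for audit.
    """
    summ = spike_summary(data)
    df = data.df.copy()
    df["cq_raw"] = df["cq"]
    shift = df["cell_id"].map(summ.per_cell - summ.global_mean)
    numeric = (df["status"] == "OK") & (df["cq"] != CODE_NODETECT)
    df.loc[numeric, "cq"] = df.loc[numeric, "cq"] - shift[numeric]
    out = CqDataset.__new__(CqDataset)  # skip range re-validation: shifts may exceed max_cq
    out.df = df.reset_index(drop=True)
    out.constants = data.constants
    out.spike_summary = summ
    out.removal_log = dict(data.removal_log)
    return out


def cq_to_molecules(data: CqDataset) -> MoleculeMatrix:
    """Convert normalised gene Cqs to absolute molecule numbers.

    ``m_ij = W * S * 2^(max_cq - preamp - Cq_ij)`` with the dataset's assay
    constants; ``Cq = 999 -> m = 0``; ``UD -> missing``.
    """
    k = data.constants
    g = data.df[data.df.target_type == "gene"].copy()
    scale = k.plate_wells * k.pcr_sampling
    expo = k.max_cq - k.preamp_cycles - g["cq"]
    m = scale * np.power(2.0, expo)
    m[g["cq"] == CODE_NODETECT] = 0.0
    m[g["status"] == "UD"] = np.nan
    g["m"] = m
    values = g.pivot(index="cell_id", columns="target", values="m")
    values = values.reindex(index=pd.unique(g["cell_id"]))
    time_h = g.drop_duplicates("cell_id").set_index("cell_id")["time_h"].reindex(values.index)
    values.columns.name = None
    return MoleculeMatrix(values, time_h)


def log1_transform(matrix: MoleculeMatrix) -> MoleculeMatrix:
    """Elementwise ``ln(m + 1)``; missing entries preserved."""
    vals = matrix.values.to_numpy()
    if vals.size and np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("negative molecule counts cannot be log-transformed")
    out = matrix.copy()
    out.values = np.log1p(matrix.values)
    return out


def impute_missing(
    matrix: MoleculeMatrix,
    min_valid_cells: int = 20,
    seed: int = 0,
    with_poisson: bool = False,
) -> tuple[MoleculeMatrix, list[dict], dict]:
    """Replace missing entries with Poisson-Beta draws fit per gene x time.

    For each gene and time-point with missing entries, (a, b, c) are fit by
    moments on the observed cells and each missing value is replaced by an
    independent draw from ``c * Beta(a, b)`` (molecule numbers are large and
    effectively continuous, so the Poisson layer is skipped by default;
    ``with_poisson=True`` adds it for sensitivity analysis).  A gene whose
    observed-cell count falls below ``min_valid_cells`` at a time-point
    requiring imputation, or whose moment fit degenerates, is deleted and
    reported rather than silently imputed.

    Returns
    -------
    (imputed matrix, deletion report, fitted parameters keyed by (gene, time))
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    imputed_mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    deleted: list[dict] = []
    params: dict[tuple[str, float], PoissonBetaParams] = {}
    times = matrix.times
    for gene in list(values.columns):
        fits: dict[float, PoissonBetaParams] = {}
        reason = None
        for t in times:
            col = values.loc[matrix.time_h == t, gene]
            n_missing = int(col.isna().sum())
            if n_missing == 0:
                continue
            obs = col.dropna().to_numpy()
            if obs.size < min_valid_cells:
                reason = f"only {obs.size} valid cells at t={t:g} (< {min_valid_cells})"
                break
            try:
                fits[t] = fit_poisson_beta_moments(obs)
            except EstimatorFailure as exc:
                reason = f"moment fit failed at t={t:g}: {exc}"
                break
        if reason is not None:
            deleted.append({"gene": gene, "reason": reason})
            values = values.drop(columns=gene)
            imputed_mask = imputed_mask.drop(columns=gene)
            continue
        for t, p in fits.items():
            sel = (matrix.time_h == t) & values[gene].isna()
            n = int(sel.sum())
            draws = p.c * rng.beta(p.a, p.b, size=n)
            if with_poisson:
                draws = rng.poisson(draws).astype(float)
            values.loc[sel, gene] = draws
            imputed_mask.loc[sel, gene] = True
            params[(gene, t)] = p
    if deleted:
        logger.info("imputation deleted %d gene(s): %s", len(deleted), [d["gene"] for d in deleted])
    out = MoleculeMatrix(
        values,
        matrix.time_h.copy(),
        truth_labels=dict(matrix.truth_labels),
        imputed=imputed_mask,
        cell_meta=matrix.cell_meta,
    )
    return out, deleted, params


def technical_span_summary(data: CqDataset) -> tuple[float, float]:
    """Mean per-target Cq range (max - min) for spikes and for genes.

    Contrasting the spike span (technical-only variation) with the gene span
    (technical + biological) summarises technical reproducibility.
    """
    valid = data.df[data._valid()]
    spans = {}
    for ttype in ("spike", "gene"):
        sub = valid[valid.target_type == ttype]
        per_target = sub.groupby("target")["cq"].agg(lambda v: v.max() - v.min() if len(v) >= 2 else np.nan)
        per_target = per_target.dropna()
        if per_target.empty:
            raise ValueError(f"no {ttype} target with >= 2 numeric Cq values")
        spans[ttype] = float(per_target.mean())
    return spans["spike"], spans["gene"]
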