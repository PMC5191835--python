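"""Shared in-memory containers for the pipeline.

The central object is :class:`MoleculeMatrix`: a cells x genes table of
estimated mRNA molecule counts with per-cell time-point labels and an
explicit missing mask (``NaN`` entries).  It is produced either by the
synthetic generator, by the Cq-level preprocessing pipeline, or by the
two-state simulator, and consumed by every downstream analysis stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MoleculeMatrix"]


class MoleculeMatrix:
    """Cells x genes molecule-count matrix with time labels.

    Parameters
    ----------
    values
        DataFrame indexed by cell id, one column per gene.  ``NaN`` marks a
        missing (quality-failed) measurement; all defined entries must be
        ``>= 0``.
    time_h
        Per-cell time-point labels in hours, aligned with ``values.index``.
    truth_labels
        Optional per-gene ground-truth tags carried over from a synthetic
        schedule (``{gene: {"wave_time": 4.0, ...}}``).
    imputed
        Optional boolean audit mask marking entries filled in by imputation.
    cell_meta
        Optional per-cell metadata (e.g. differentiation lags in an
        asynchronous simulation).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        time_h: pd.Series,
        truth_labels: dict | None = None,
        imputed: pd.DataFrame | None = None,
        cell_meta: pd.DataFrame | None = None,
    ):
        values = values.astype(float)
        time_h = pd.Series(np.asarray(time_h, dtype=float), index=values.index)
        defined = values.to_numpy()[~np.isnan(values.to_numpy())]
        if defined.size and (defined < 0).any():
            raise ValueError("molecule counts must be >= 0 wherever defined")
        if imputed is not None:
            imputed = imputed.reindex(index=values.index, columns=values.columns).fillna(False)
        self.values = values
        self.time_h = time_h
        self.truth_labels = truth_labels or {}
        self.imputed = imputed
        self.cell_meta = cell_meta

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cells(self) -> list[str]:
        return list(self.values.index)

    @property
    def times(self) -> list[float]:
        """Sorted unique time-point labels."""
        return sorted(set(self.time_h))

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def n_cells_at(self, t: float) -> int:
        return int((self.time_h == t).sum())

    def at_time(self, t: float) -> pd.DataFrame:
        """Sub-matrix of cells measured at time-point ``t``."""
        return self.values.loc[self.time_h == t]

    def copy(self) -> "MoleculeMatrix":
        return MoleculeMatrix(
            self.values.copy(),
            self.time_h.copy(),
            truth_labels=dict(self.truth_labels),
            imputed=None if self.imputed is None else self.imputed.copy(),
            cell_meta=None if self.cell_meta is None else self.cell_meta.copy(),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MoleculeMatrix({len(self.cells)} cells x {len(self.genes)} genes, "
            f"times={self.times})"
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: columns ``cell_id, time_h, <genes...>``; NA = missing."""
        out = self.values.copy()
        out.insert(0, "time_h", self.time_h)
        out.index.name = "cell_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MoleculeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell_id", na_values=["NA"])
        time_h = df.pop("time_h")
        return cls(df, time_h)

    def truth_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth_labels, indent=2, sort_keys=True))
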