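"""End-to-end orchestration: preprocess -> entropy -> networks -> DNB -> waves.

Every artifact is written to a run directory together with a
machine-readable manifest (content digests, per-stage seeds) so that a
re-run with the identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dnb as dnb_mod
from . import heterogeneity, networks, preprocessing, waves as waves_mod
from .config import PipelineConfig
from .containers import MoleculeMatrix

__all__ = ["run_pipeline"]

logger = logging.getLogger("entrosurge")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(path: Path, doc) -> None:
    path.write_text(json.dumps(_jsonable(doc), indent=2, sort_keys=True) + "\n")


def _load_matrix(config: PipelineConfig, outdir: Path) -> tuple[MoleculeMatrix, dict]:
    """Preprocess a Cq CSV, or load an already-converted molecule TSV."""
    audit: dict = {}
    if config.input_cq_csv:
        data = preprocessing.parse_cq_csv(config.input_cq_csv, config.constants)
        data = preprocessing.select_valid_cells(data, config.preprocess.low_expr_mad_k)
        audit["cell_filtering"] = data.removal_log
        data = preprocessing.normalize_cq(data)
        spike_span, gene_span = preprocessing.technical_span_summary(data)
        audit["technical_span"] = {"spike_span_cq": spike_span, "gene_span_cq": gene_span}
        matrix = preprocessing.cq_to_molecules(data)
    elif config.input_molecules_tsv:
        matrix = MoleculeMatrix.from_tsv(config.input_molecules_tsv)
    else:
        raise ValueError("config must set input_cq_csv or input_molecules_tsv")
    matrix, deleted, params = preprocessing.impute_missing(
        matrix,
        min_valid_cells=config.preprocess.min_valid_cells,
        seed=config.seed_for("impute"),
        with_poisson=config.preprocess.impute_with_poisson,
    )
    audit["imputation"] = {
        "deleted_genes": deleted,
        "n_imputed": int(matrix.imputed.to_numpy().sum()) if matrix.imputed is not None else 0,
        "fits": {f"{g}@{t:g}h": {"a": p.a, "b": p.b, "c": p.c} for (g, t), p in params.items()},
    }
    matrix.to_tsv(outdir / "molecules.tsv")
    _write_json(outdir / "preprocess_audit.json", audit)
    return matrix, audit


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the run manifest.

    Writes, under ``outdir``: the imputed molecule matrix, entropy tables
    and shift significances, per-time robust networks (edge TSV + GraphML)
    and correlation deltas, the DNB candidate profile, the wave table, a
    human-readable summary and a digest manifest.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, audit = _load_matrix(config, outdir)
    times = matrix.times
    summary_lines = [
        f"cells: {len(matrix.cells)}  genes: {len(matrix.genes)}  time-points: "
        + ", ".join(f"{t:g}h" for t in times)
    ]

    # -- entropy -----------------------------------------------------------
    etab = heterogeneity.entropy_table(matrix, scale=config.entropy.scale)
    for t1, t2 in zip(times, times[1:]):
        etab.significance[f"{t1:g}->{t2:g}"] = heterogeneity.entropy_shift_significance(
            matrix, t1, t2,
            n_iter=config.entropy.n_iter,
            subsample_frac=config.entropy.frac,
            seed=config.seed_for(f"entropy:{t1:g}->{t2:g}"),
            alpha=config.entropy.alpha,
            paired=config.entropy.paired,
            scale=config.entropy.scale,
        )
    etab.to_tsv(outdir / "entropy.tsv")
    profile = etab.mean_profile()
    peak_t = float(profile.idxmax())
    interior_peak = times[0] < peak_t < times[-1]
    _write_json(outdir / "entropy_summary.json", {
        "mean_entropy": {f"{t:g}": profile[t] for t in times},
        "delta_entropy_mean": {c: float(etab.delta[c].mean()) for c in etab.delta.columns},
        "significance_percent": etab.significance,
        "peak_time_h": peak_t,
        "interior_peak": bool(interior_peak),
    })
    summary_lines.append(
        f"entropy: peak of mean entropy at {peak_t:g} h ({'interior' if interior_peak else 'boundary'})"
    )

    # -- networks ----------------------------------------------------------
    log_matrix = preprocessing.log1_transform(matrix)
    graphs = {}
    rhos = {}
    net_summary = {}
    for t in times:
        g = networks.robust_network(
            log_matrix, t,
            frac=config.network.frac,
            n_iter=config.network.n_iter,
            alpha=config.network.alpha,
            seed=config.seed_for(f"network:{t:g}"),
            method=config.network.method,
            bonferroni=config.network.bonferroni,
        )
        graphs[t] = g
        rhos[t], _ = networks.correlation_matrix(log_matrix, t, method=config.network.method)
        g.to_tsv(outdir / f"network_t{t:g}.tsv")
        g.to_graphml(outdir / f"network_t{t:g}.graphml")
        n_edges, hubs = networks.network_summary(g, top_k=config.network.top_k)
        net_summary[f"{t:g}"] = {"n_edges": n_edges, "hubs": hubs}
    deltas = {}
    for t1, t2 in zip(times, times[1:]):
        d = networks.correlation_delta(rhos[t1], rhos[t2], band=config.network.delta_band)
        deltas[f"{t1:g}->{t2:g}"] = {
            "n_increasing": d.n_increasing,
            "n_decreasing": d.n_decreasing,
        }
        d.delta.to_csv(outdir / f"correlation_delta_{t1:g}_{t2:g}.tsv", sep="\t")
    _write_json(outdir / "network_summary.json", {"per_time": net_summary, "deltas": deltas})
    summary_lines.append(
        "network edges per time-point: "
        + ", ".join(f"{t:g}h={net_summary[f'{t:g}']['n_edges']}" for t in times)
    )

    # -- DNB ---------------------------------------------------------------
    t0 = config.dnb.t0 if config.dnb.t0 is not None else times[0]
    t1 = config.dnb.t1 if config.dnb.t1 is not None else times[1]
    candidates = dnb_mod.select_dnb_candidates(
        matrix, t0, t1,
        corr_threshold=config.dnb.corr_threshold,
        method=config.dnb.select_method,
    )
    dnb_doc: dict = {"t0": t0, "t1": t1, "candidates": sorted(candidates)}
    if 0 < len(candidates) < len(matrix.genes):
        profile_dnb = dnb_mod.dnb_profile(
            matrix, candidates,
            method=config.dnb.score_method,
            absolute=config.dnb.absolute,
            include_diagonal=config.dnb.include_diagonal,
        )
        profile_dnb.to_tsv(outdir / "dnb_profile.tsv")
        dnb_doc["profile"] = {
            f"{t:g}": {k: profile_dnb.table.loc[t, k] for k in ("CV", "PCCin", "PCCout", "I")}
            for t in profile_dnb.table.index
        }
        summary_lines.append(f"DNB: {len(candidates)} candidate genes between {t0:g} and {t1:g} h")
    else:
        summary_lines.append(f"DNB: no usable candidate set ({len(candidates)} genes selected)")
    _write_json(outdir / "dnb.json", dnb_doc)

    # -- waves -------------------------------------------------------------
    if config.waves.enabled:
        wt = waves_mod.assign_waves(
            matrix,
            times=times,
            n_boot=config.waves.n_boot,
            support_threshold=config.waves.support_threshold,
            alpha=config.waves.alpha,
            seed=config.seed_for("waves"),
        )
        wt.to_tsv(outdir / "waves.tsv")
        assigned = wt.table.dropna(subset=["wave_time"])
        wave_counts = assigned.groupby("wave_time").size().to_dict()
        _write_json(outdir / "waves.json", {
            "params": wt.params,
            "wave_counts": {f"{k:g}": int(v) for k, v in wave_counts.items()},
        })
        summary_lines.append(
            "waves: " + (", ".join(f"{int(v)} gene(s) at {k:g}h" for k, v in sorted(wave_counts.items())) or "none")
        )

    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")

    artifacts = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "artifacts": {p.name: _digest(p) for p in artifacts},
    }
    _write_json(outdir / "manifest.json", manifest)
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest
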