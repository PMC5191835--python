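"""Ground-truthed synthetic single-cell RT-qPCR experiments.

The generator works top-down through the same layers the real assay
traverses, so every downstream stage can be tested against known truth:

1. a :class:`KineticSchedule` assigns each gene time-varying two-state
   rates (kon, koff, s0, d0) at anchor time-points, plus truth tags
   (wave membership, variability-surge flag, biomarker-set membership);
2. :func:`sample_snapshots` turns the schedule into molecule-count
   snapshots, either from the stationary Poisson-Beta law or by full
   Gillespie simulation;
3. :func:`degrade_to_cq` inverts the molecule-count formula back to Cq
   space and applies per-cell technical shifts, spike channels, detection
   limits (999), quality failures (UD) and empty wells.

Scenario defaults emulate a ~90-gene, 6-time-point differentiation
experiment: an early two-gene then five-gene wave of expression shifts, a
mid-course burst-size surge producing an interior entropy peak, and a
correlated biomarker gene set whose variability and internal correlation
jump at the second time-point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from . import two_state
from .containers import MoleculeMatrix
from .preprocessing import AssayConstants, CODE_NODETECT, CqDataset

__all__ = [
    "KineticSchedule",
    "Coupling",
    "SpikeModel",
    "DropoutModel",
    "SCENARIOS",
    "make_schedule",
    "sample_snapshots",
    "degrade_to_cq",
]

SCENARIOS = ("constant", "entropy_surge", "waves", "dnb")

#: default anchor times (hours) for the six-time-point design
DEFAULT_ANCHORS = (0.0, 8.0, 24.0, 33.0, 48.0, 72.0)
#: default anchors for the early-wave design
WAVE_ANCHORS = (0.0, 2.0, 4.0, 8.0)


@dataclass
class Coupling:
    """Gaussian-copula correlation structure for stationary snapshots.

    All genes share a weak global factor (``global_rho``; a cell-state /
    cell-size proxy), and the genes in ``set_genes`` share an additional
    factor whose strength ``set_rho[t]`` varies by anchor time.
    """

    global_rho: float = 0.0
    set_genes: tuple[str, ...] = ()
    set_rho: dict[float, float] = field(default_factory=dict)

    def rho_at(self, t: float) -> float:
        return max(self.set_rho.get(t, self.global_rho), self.global_rho)


@dataclass
class KineticSchedule:
    """Per-gene, per-anchor two-state rates with optional truth tags."""

    genes: list[str]
    anchor_times: tuple[float, ...]
    rates: np.ndarray  # shape (n_genes, n_anchors, 4): kon, koff, s0, d0
    truth_labels: dict[str, dict] = field(default_factory=dict)
    coupling: Coupling | None = None

    def __post_init__(self):
        self.anchor_times = tuple(float(t) for t in self.anchor_times)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.anchor_times) < 2:
            raise ValueError("need >= 2 anchor times")
        if any(b <= a for a, b in zip(self.anchor_times, self.anchor_times[1:])):
            raise ValueError("anchor times must be strictly increasing")
        if self.rates.shape != (len(self.genes), len(self.anchor_times), 4):
            raise ValueError(
                f"rates shape {self.rates.shape} != ({len(self.genes)}, {len(self.anchor_times)}, 4)"
            )
        if (self.rates < 0).any():
            raise ValueError("all rates must be >= 0")
        if (self.rates[:, :, 3] <= 0).any():
            raise ValueError("d0 must be > 0 for every gene at every anchor")

    def rates_for(self, gene: str) -> np.ndarray:
        return self.rates[self.genes.index(gene)]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "genes": self.genes,
            "anchor_times": list(self.anchor_times),
            "rates": self.rates.tolist(),
            "truth_labels": self.truth_labels,
            "coupling": None
            if self.coupling is None
            else {
                "global_rho": self.coupling.global_rho,
                "set_genes": list(self.coupling.set_genes),
                "set_rho": {str(k): v for k, v in self.coupling.set_rho.items()},
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticSchedule":
        doc = json.loads(Path(path).read_text())
        coupling = None
        if doc.get("coupling"):
            c = doc["coupling"]
            coupling = Coupling(
                global_rho=c["global_rho"],
                set_genes=tuple(c["set_genes"]),
                set_rho={float(k): v for k, v in c["set_rho"].items()},
            )
        return cls(
            genes=list(doc["genes"]),
            anchor_times=tuple(doc["anchor_times"]),
            rates=np.asarray(doc["rates"], dtype=float),
            truth_labels=doc.get("truth_labels", {}),
            coupling=coupling,
        )


@dataclass(frozen=True)
class SpikeModel:
    """Exogenous spike-in channels: purely technical Cq variation.

    The per-cell effect (reverse-transcription efficiency) is additive in Cq
    space and shared by all spikes and genes of a cell, which is what makes
    spike normalisation exactly corrective in expectation.
    """

    n_spikes: int = 2
    base_cq: float = 13.0
    cell_effect_sd: float = 0.5
    residual_sd: float = 0.1
    fail_prob: float = 0.02

    def __post_init__(self):
        if self.cell_effect_sd < 0 or self.residual_sd < 0:
            raise ValueError("spike noise SDs must be >= 0")
        if not 0 <= self.fail_prob < 1:
            raise ValueError("fail_prob must be in [0, 1)")


@dataclass(frozen=True)
class DropoutModel:
    """Detection limit and quality-failure model for gene channels."""

    detection_limit_cq: float = 30.0
    ud_prob: float = 0.03
    bad_cell_prob: float = 0.02

    def __post_init__(self):
        for p in (self.ud_prob, self.bad_cell_prob):
            if not 0 <= p < 1:
                raise ValueError("probabilities must be in [0, 1)")


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

# Multiplicative changes defining the scenarios.  The wave shift is a
# sustained 4-fold change in synthesis rate (differentiation-responsive
# genes shift severalfold).  The surge scenario moves genes from an
# OFF-dominated bursty baseline (mass concentrated at low counts: low
# shape entropy under equal-width binning) to balanced promoter switching
# (a = b = 1: near-uniform occupancy of the expression range, close to the
# maximal binned entropy) and back.  The biomarker scenario reduces kon
# (fewer, larger bursts), raising the coefficient of variation.
_WAVE_FOLD = 4.0
_SURGE_S0_FACTOR = 1.5
_DNB_KON_FACTOR = 0.25
_GLOBAL_RHO = 0.15
_DNB_RHO_PROFILE = (0.15, 0.85, 0.3, 0.2, 0.15, 0.15)  # per anchor index


def _base_rates(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Realistic per-gene base kinetics: a, b ~ 1-6, c ~ 150-800 molecules."""
    kon = rng.uniform(0.5, 2.0, n_genes)
    koff = rng.uniform(0.5, 2.0, n_genes)
    s0 = rng.uniform(80.0, 300.0, n_genes)
    d0 = rng.uniform(0.3, 0.7, n_genes)
    return np.stack([kon, koff, s0, d0], axis=1)


def make_schedule(
    scenario: str,
    n_genes: int = 90,
    anchor_times=None,
    seed: int = 0,
) -> KineticSchedule:
    """Build a ground-truthed kinetic schedule for a named scenario.

    Scenarios
    ---------
    ``constant``
        Identical rates at every anchor; no truth labels.
    ``entropy_surge``
        ~80% of genes switch to fewer/larger bursts at the second and third
        anchors (default 8 h and 24 h) and revert afterwards, producing an
        interior peak of cell-to-cell entropy; tagged ``entropy_surge``.
    ``waves``
        Anchors default to (0, 2, 4, 8) h; exactly 2 genes shift their
        synthesis rate first at the second anchor and 5 more first at the
        third, sustained afterwards; tagged ``wave_time``.
    ``dnb``
        A 12-gene set (fewer for small panels) whose burst variability rises
        at the second anchor while its internal copula correlation jumps,
        then both relax; all genes share a weak global correlation; tagged
        ``dnb_member``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if anchor_times is None:
        anchor_times = WAVE_ANCHORS if scenario == "waves" else DEFAULT_ANCHORS
    anchor_times = tuple(float(t) for t in anchor_times)
    if len(anchor_times) < 2:
        raise ValueError("need >= 2 anchor times")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    base = _base_rates(n_genes, rng)
    A = len(anchor_times)
    rates = np.repeat(base[:, None, :], A, axis=1)
    truth: dict[str, dict] = {}
    coupling = None

    if scenario == "constant":
        pass

    elif scenario == "entropy_surge":
        surge_idx = rng.choice(n_genes, size=max(1, int(round(0.8 * n_genes))), replace=False)
        surge_anchors = [1]  # single interior anchor: rates ramp up to and away from it
        for gi in surge_idx:
            d0 = rates[gi, 0, 3]
            # bursty OFF-dominated baseline at every anchor ...
            rates[gi, :, 0] = rng.uniform(0.15, 0.3) * d0 / 0.5
            rates[gi, :, 1] = rng.uniform(0.8, 1.6) * d0 / 0.5
            rates[gi, :, 2] = rng.uniform(150.0, 400.0) * d0 / 0.5
            # ... switching to balanced occupancy (a = b = 1) at the surge
            for ai in surge_anchors:
                rates[gi, ai, 0] = d0
                rates[gi, ai, 1] = d0
                rates[gi, ai, 2] = rates[gi, 0, 2] * _SURGE_S0_FACTOR
            truth[genes[gi]] = {"entropy_surge": True}

    elif scenario == "waves":
        if A < 3:
            raise ValueError("waves scenario needs >= 3 anchor times")
        if n_genes < 8:
            raise ValueError("waves scenario needs >= 8 genes")
        chosen = rng.choice(n_genes, size=7, replace=False)
        wave1, wave2 = chosen[:2], chosen[2:]
        for rank, (members, ai) in enumerate([(wave1, 1), (wave2, 2)]):
            for j, gi in enumerate(members):
                fold = _WAVE_FOLD if j % 2 == 0 else 1.0 / _WAVE_FOLD
                rates[gi, ai:, 2] *= fold
                truth[genes[gi]] = {"wave_time": anchor_times[ai]}

    elif scenario == "dnb":
        n_members = min(12, max(2, n_genes // 3))
        members = rng.choice(n_genes, size=n_members, replace=False)
        for gi in members:
            rates[gi, 1, 0] *= _DNB_KON_FACTOR
            truth[genes[gi]] = {"dnb_member": True}
        set_rho = {
            t: _DNB_RHO_PROFILE[min(i, len(_DNB_RHO_PROFILE) - 1)]
            for i, t in enumerate(anchor_times)
        }
        coupling = Coupling(
            global_rho=_GLOBAL_RHO,
            set_genes=tuple(genes[gi] for gi in members),
            set_rho=set_rho,
        )

    return KineticSchedule(
        genes=genes,
        anchor_times=anchor_times,
        rates=rates,
        truth_labels=truth,
        coupling=coupling,
    )


# ---------------------------------------------------------------------------
# Snapshots
# ---------------------------------------------------------------------------


def _stationary_z(a, b, n_cells, gene_is_member, rho_g, rho_m, rng):
    """Beta-distributed promoter activities, optionally copula-coupled."""
    G = a.size
    z = np.empty((n_cells, G))
    if rho_g <= 0 and rho_m <= 0:
        u = rng.random((n_cells, G))
    else:
        f0 = rng.standard_normal((n_cells, 1))
        f1 = rng.standard_normal((n_cells, 1))
        eps = rng.standard_normal((n_cells, G))
        load0 = np.sqrt(rho_g)
        extra = np.where(gene_is_member, max(rho_m - rho_g, 0.0), 0.0)
        load1 = np.sqrt(extra)
        tot = np.clip(1.0 - rho_g - extra, 0.0, 1.0)
        zz = load0 * f0 + load1 * f1 + np.sqrt(tot) * eps
        u = stats.norm.cdf(zz)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    for g in range(G):
        if a[g] <= 0:
            z[:, g] = 0.0  # promoter never switches on
        elif b[g] <= 0:
            z[:, g] = 1.0  # promoter never switches off
        else:
            z[:, g] = special.betaincinv(a[g], b[g], u[:, g])
    return z


def sample_snapshots(
    schedule: KineticSchedule,
    n_cells_per_time: int,
    mode: str = "stationary",
    seed: int = 0,
) -> MoleculeMatrix:
    """Draw molecule-count snapshots for every anchor time of a schedule.

    ``stationary`` mode draws each cell independently from the Poisson-Beta
    law D(kon/d0, koff/d0, s0/d0) at that anchor (with the schedule's copula
    coupling, if any); ``gillespie`` mode runs full synchronous trajectories
    through :func:`entrosurge.two_state.simulate_population` (coupling does
    not apply there).
    """
    if n_cells_per_time < 2:
        raise ValueError("n_cells_per_time must be >= 2")
    if mode not in ("stationary", "gillespie"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "gillespie":
        cfg = two_state.TrajectoryConfig(
            record_times=schedule.anchor_times, n_cells=n_cells_per_time
        )
        return two_state.simulate_population(schedule, cfg, "synchronous", seed)

    rng = np.random.default_rng(seed)
    genes = schedule.genes
    coupling = schedule.coupling or Coupling()
    member = np.array([g in set(coupling.set_genes) for g in genes])
    frames = []
    times = []
    ids = []
    for ai, t in enumerate(schedule.anchor_times):
        r = schedule.rates[:, ai, :]
        a = r[:, 0] / r[:, 3]
        b = r[:, 1] / r[:, 3]
        c = r[:, 2] / r[:, 3]
        z = _stationary_z(a, b, n_cells_per_time, member, coupling.global_rho, coupling.rho_at(t), rng)
        counts = rng.poisson(c[None, :] * z)
        frames.append(counts)
        times.extend([t] * n_cells_per_time)
        ids.extend(f"t{t:g}_c{i:03d}" for i in range(n_cells_per_time))
    values = pd.DataFrame(np.concatenate(frames, axis=0).astype(float), index=ids, columns=genes)
    return MoleculeMatrix(
        values, pd.Series(times, index=ids), truth_labels=dict(schedule.truth_labels)
    )


# ---------------------------------------------------------------------------
# Degradation to Cq level
# ---------------------------------------------------------------------------


def degrade_to_cq(
    matrix: MoleculeMatrix,
    spikes: SpikeModel = SpikeModel(),
    dropout: DropoutModel = DropoutModel(),
    seed: int = 0,
    constants: AssayConstants = AssayConstants(),
    gene_noise_sd: float = 0.0,
) -> CqDataset:
    """Degrade a molecule matrix into a raw Cq-level dataset.

    Inverts the molecule-count formula
    ``Cq = max_cq - preamp - log2(m / (W * S))``, then applies, per cell, an
    additive technical shift shared by genes and spikes, optional extra gene
    measurement noise (``gene_noise_sd`` cycles), the detection limit
    (counts of 0 or Cq beyond the limit become 999), random quality
    failures (UD), empty wells (``bad_cell_prob``: most genes undetected),
    and the spike channels.  Missing entries of the input matrix become UD.
    """
    rng = np.random.default_rng(seed)
    k = constants
    scale = k.plate_wells * k.pcr_sampling
    records = []
    cells = matrix.cells
    shifts = rng.normal(0.0, spikes.cell_effect_sd, size=len(cells))
    bad_cell = rng.random(len(cells)) < dropout.bad_cell_prob
    for ci, cell in enumerate(cells):
        t = float(matrix.time_h.loc[cell])
        # spike channels first: technical-only, no detection issues
        for s in range(spikes.n_spikes):
            if rng.random() < spikes.fail_prob:
                records.append((cell, t, f"spike{s + 1}", "spike", np.nan, "UD"))
            else:
                cq = spikes.base_cq + shifts[ci] + rng.normal(0.0, spikes.residual_sd)
                records.append((cell, t, f"spike{s + 1}", "spike", cq, "OK"))
        for gene in matrix.genes:
            m = matrix.values.at[cell, gene]
            if np.isnan(m):
                records.append((cell, t, gene, "gene", np.nan, "UD"))
                continue
            if bad_cell[ci]:  # empty well: spikes read fine, no cellular mRNA
                records.append((cell, t, gene, "gene", CODE_NODETECT, "OK"))
                continue
            if rng.random() < dropout.ud_prob:
                records.append((cell, t, gene, "gene", np.nan, "UD"))
                continue
            if m <= 0:
                records.append((cell, t, gene, "gene", CODE_NODETECT, "OK"))
                continue
            cq = k.max_cq - k.preamp_cycles - np.log2(m / scale) + shifts[ci]
            if gene_noise_sd > 0:
                cq += rng.normal(0.0, gene_noise_sd)
            if cq > dropout.detection_limit_cq:
                records.append((cell, t, gene, "gene", CODE_NODETECT, "OK"))
            else:
                records.append((cell, t, gene, "gene", max(cq, 1e-6), "OK"))
    df = pd.DataFrame(
        records, columns=["cell_id", "time_h", "target", "target_type", "cq", "status"]
    )
    return CqDataset(df, constants)
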