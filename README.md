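# entrosurge

Analysis toolkit for **cell-to-cell variability in single-cell RT-qPCR time
courses**, built around the observation that differentiating cell
populations can pass through a transient burst of molecular heterogeneity
before committing irreversibly to their new fate.

The package takes raw quantification-cycle (Cq) tables from
microfluidic-chip RT-qPCR experiments (tens of genes, tens of cells per
time-point, spike-in control channels) and carries them through a complete,
reproducible analysis:

1. **Preprocessing** — primer-efficiency screening
   (`E = 10^(-1/slope)`, keep 80–120 %), cell filtering (valid spikes,
   empty-well outlier rule), per-cell spike normalisation
   `Cq_ij = Ĉq_ij − (C̄q_i − C̄q_0)`, and conversion to absolute molecule
   numbers `m_ij = 96 × 45 × 2^(30−22−Cq_ij)` (999 → 0 molecules, UD →
   missing).
2. **Poisson-Beta imputation** — each gene × time-point marginal is fit to
   the stationary law of the two-state (telegraph) model of transcription,
   `Z ~ Beta(a, b), X ~ Poisson(cZ)` with `a = kon/d0`, `b = koff/d0`,
   `c = s0/d0`, by closed-form moment estimators; missing values are
   replaced by draws from `c·Beta(a, b)`.
3. **Entropy heterogeneity** — per gene and time-point, the Shannon entropy
   `E = −Σ p_k log2 p_k` of an equal-width histogram with `N = ⌊n_cells/2⌋`
   bins, with Δ-entropy between consecutive time-points and
   subsampling + Wilcoxon significance of entropy shifts.
4. **Robust correlation networks** — Spearman correlations per time-point
   with Bonferroni control; edges must stay significant with a constant
   sign in every one of the (default 10 000) 85 %-subsampling iterations.
5. **DNB I-score** — for a candidate gene set `D` (members of pairs whose
   correlation rises ≥ 0.5 between two time-points, with rising CV),
   `I = CV · PCCin / PCCout` per time-point.
6. **Expression waves** — earliest time at which each gene's distribution
   differs from any earlier time, by two-sided Mann-Whitney tests required
   to hold in > 90 % of 1 000 bootstrap resamples; hypergeometric
   enrichment of wave genes in functional categories by exact big-integer
   combinatorics.
7. **Two-state simulation** — exact Gillespie trajectories under
   time-varying rates (linear interpolation between anchor time-points,
   piecewise-constant on a 0.1 h grid), with synchronous vs asynchronous
   (Uniform(0, 24 h) onset lags) differentiation of whole populations.

A first-class **synthetic-data generator** emulates the full experimental
design — kinetic schedules with ground-truth labels, stationary or
simulated snapshots, degradation back to Cq space with spike channels,
detection limits (999), quality failures (UD) and empty wells — so every
stage is testable without access to laboratory data.

## Worked example

```python
from entrosurge import synthetic_data as sd, heterogeneity as het

schedule = sd.make_schedule("entropy_surge", n_genes=30, seed=1)
matrix = sd.sample_snapshots(schedule, n_cells_per_time=60, seed=2)
table = het.entropy_table(matrix)
print(table.mean_profile().round(3))
pct = het.entropy_shift_significance(matrix, 0.0, 8.0, n_iter=200, seed=5)
print(f"0h -> 8h entropy shift significant in {pct:.0f}% of subsampling iterations")
```

prints

```
0.0     3.753
8.0     4.485
24.0    3.721
33.0    3.764
48.0    3.780
72.0    3.713
dtype: float64
0h -> 8h entropy shift significant in 100% of subsampling iterations
```

The mean per-gene entropy rises by ~0.7 bits at the interior 8 h
time-point and falls back — the transient heterogeneity surge the scenario
encodes — and the rise is detected in every subsampling iteration of the
paired Wilcoxon test across genes.

The same analysis runs from the shell:

```sh
entrosurge simulate --scenario entropy_surge --n-genes 30 --n-cells 60 --seed 1 --out sim/
entrosurge run --cq-csv sim/cq.csv --seed 1 --out run/
entrosurge report run/
```

`run/` then contains the imputed molecule matrix, entropy tables, per-time
network edge lists (TSV + GraphML), the DNB profile, the wave table, and a
manifest of content digests; re-running with the same seed reproduces every
artifact byte for byte.

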