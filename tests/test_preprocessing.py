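"""Cq-level pipeline: parsing, QC, normalisation, conversion, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from entrosurge import preprocessing as pp
from entrosurge import synthetic_data as sd
from entrosurge.two_state import PoissonBetaParams, poisson_beta_sample
from conftest import make_matrix


def _long(records):
    return pd.DataFrame(
        records, columns=["cell_id", "time_h", "target", "target_type", "cq", "status"]
    )


def small_dataset():
    """Two cells, two spikes, two genes; cell c2's spike mean 1 cycle higher."""
    rows = []
    for cell, shift in (("c1", 0.0), ("c2", 1.0)):
        rows.append((cell, 0.0, "spike1", "spike", 13.0 + shift, "OK"))
        rows.append((cell, 0.0, "spike2", "spike", 13.0 + shift, "OK"))
        rows.append((cell, 0.0, "gA", "gene", 10.0 + shift, "OK"))
        rows.append((cell, 0.0, "gB", "gene", 20.0 + shift, "OK"))
    return pp.CqDataset(_long(rows))


class TestParsing:
    def test_write_parse_roundtrip_is_identity(self, tmp_path):
        data = small_dataset()
        data.write_csv(tmp_path / "x.csv")
        back = pp.parse_cq_csv(tmp_path / "x.csv")
        pd.testing.assert_frame_equal(data.df, back.df)

    def test_empty_file_after_header_is_empty_dataset(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("cell_id,time_h,target,target_type,cq,status\n")
        data = pp.parse_cq_csv(p)
        assert data.cells == [] and data.genes == []

    def test_malformed_row_names_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "cell_id,time_h,target,target_type,cq,status\n"
            "c1,0,gA,gene,12.5,OK\n"
            "c1,0,gB,gene,oops,OK\n"
        )
        with pytest.raises(ValueError, match=":3:"):
            pp.parse_cq_csv(p)

    def test_ud_rows_parse_to_missing_cq(self, tmp_path):
        p = tmp_path / "ud.csv"
        p.write_text(
            "cell_id,time_h,target,target_type,cq,status\nc1,0,gA,gene,,UD\n"
        )
        data = pp.parse_cq_csv(p)
        assert data.df.status.iloc[0] == "UD" and np.isnan(data.df.cq.iloc[0])

    def test_duplicate_cell_target_rejected(self):
        rows = [("c1", 0.0, "gA", "gene", 10.0, "OK"), ("c1", 0.0, "gA", "gene", 11.0, "OK")]
        with pytest.raises(ValueError, match="duplicate"):
            pp.CqDataset(_long(rows))

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("cell,time,gene\n")
        with pytest.raises(ValueError, match="header"):
            pp.parse_cq_csv(p)


class TestPrimerEfficiency:
    def test_perfect_doubling_series_gives_efficiency_two(self):
        slope = -1.0 / np.log10(2.0)  # ~ -3.3219 cycles per decade
        pts = [(x, 30.0 + slope * x) for x in (0.0, -1.0, -2.0, -3.0)]
        rec = pp.primer_efficiency(pts)
        assert rec.efficiency == pytest.approx(2.0, abs=1e-9)
        assert rec.percent == pytest.approx(100.0, abs=1e-6)
        assert rec.keep

    def test_slope_minus_two_rejected(self):
        pts = [(x, 30.0 - 2.0 * x) for x in (0.0, -1.0, -2.0)]
        rec = pp.primer_efficiency(pts)
        assert rec.efficiency == pytest.approx(10.0**0.5, rel=1e-12)
        assert rec.percent > 120 and not rec.keep

    def test_point_order_does_not_matter(self):
        slope = -1.0 / np.log10(2.0)
        pts = [(x, 30.0 + slope * x) for x in (0.0, -1.0, -2.0, -3.0)]
        rec1 = pp.primer_efficiency(pts)
        rec2 = pp.primer_efficiency(list(reversed(pts)))
        assert rec1.efficiency == pytest.approx(rec2.efficiency, rel=1e-12)

    def test_zero_variance_dilutions_rejected(self):
        with pytest.raises(ValueError):
            pp.primer_efficiency([(0.0, 30.0), (0.0, 29.0), (0.0, 28.0)])


class TestCellFiltering:
    def test_cell_with_all_spikes_invalid_is_removed(self):
        rows = [
            ("c1", 0.0, "spike1", "spike", 13.0, "OK"),
            ("c1", 0.0, "gA", "gene", 10.0, "OK"),
            ("c2", 0.0, "spike1", "spike", np.nan, "UD"),
            ("c2", 0.0, "gA", "gene", 10.0, "OK"),
        ]
        out = pp.select_valid_cells(pp.CqDataset(_long(rows)))
        assert out.cells == ["c1"]
        assert out.removal_log["no_valid_spike"] == ["c2"]

    def test_cell_with_one_valid_spike_is_retained_and_normalized_by_it(self):
        rows = [
            ("c1", 0.0, "spike1", "spike", 12.0, "OK"),
            ("c1", 0.0, "spike2", "spike", 14.0, "OK"),
            ("c1", 0.0, "gA", "gene", 10.0, "OK"),
            ("c2", 0.0, "spike1", "spike", 15.0, "OK"),
            ("c2", 0.0, "spike2", "spike", np.nan, "UD"),
            ("c2", 0.0, "gA", "gene", 10.0, "OK"),
        ]
        out = pp.normalize_cq(pp.select_valid_cells(pp.CqDataset(_long(rows))))
        assert set(out.df.cell_id) == {"c1", "c2"}
        # c2's only valid spike (15) defines its shift: 15 - mean(12,14,15)
        shift = 15.0 - np.mean([12.0, 14.0, 15.0])
        got = out.df[(out.df.cell_id == "c2") & (out.df.target == "gA")].cq.iloc[0]
        assert got == pytest.approx(10.0 - shift)

    def test_outlier_undetected_cell_removed_under_mad_rule(self):
        rng = np.random.default_rng(0)
        rows = []
        n_genes = 40
        for ci in range(10):
            cell = f"c{ci}"
            rows.append((cell, 0.0, "spike1", "spike", 13.0, "OK"))
            # ~20% undetected for normal cells, 95% for the last cell
            frac = 0.95 if ci == 9 else 0.2
            bad = rng.random(n_genes) < frac
            for gi in range(n_genes):
                cq = pp.CODE_NODETECT if bad[gi] else 15.0 + rng.normal(0, 0.5)
                rows.append((cell, 0.0, f"g{gi}", "gene", cq, "OK"))
        out = pp.select_valid_cells(pp.CqDataset(_long(rows)), low_expr_mad_k=3.0)
        assert "c9" not in out.cells
        assert len(out.cells) == 9


class TestNormalization:
    def test_cell_at_global_mean_is_unchanged(self):
        data = small_dataset()
        out = pp.normalize_cq(data)
        # global spike mean is 13.5; c1 spike mean 13.0 -> shift -0.5
        ga_c1 = out.df[(out.df.cell_id == "c1") & (out.df.target == "gA")].cq.iloc[0]
        assert ga_c1 == pytest.approx(10.5)

    def test_one_cycle_spike_excess_shifts_genes_down_by_one(self):
        data = small_dataset()
        out = pp.normalize_cq(data)
        # c2 sits 1 cycle above c1; after normalisation both agree exactly
        ga_c1 = out.df[(out.df.cell_id == "c1") & (out.df.target == "gA")].cq.iloc[0]
        ga_c2 = out.df[(out.df.cell_id == "c2") & (out.df.target == "gA")].cq.iloc[0]
        assert ga_c2 == pytest.approx(ga_c1)

    def test_spike_means_center_on_global_mean_after_normalization(self):
        data = small_dataset()
        out = pp.normalize_cq(data)
        spikes = out.df[out.df.target_type == "spike"]
        per_cell = spikes.groupby("cell_id").cq.mean()
        assert np.allclose(per_cell, out.spike_summary.global_mean)

    def test_codes_pass_through_unchanged(self):
        rows = [
            ("c1", 0.0, "spike1", "spike", 13.0, "OK"),
            ("c1", 0.0, "gA", "gene", pp.CODE_NODETECT, "OK"),
            ("c1", 0.0, "gB", "gene", np.nan, "UD"),
        ]
        out = pp.normalize_cq(pp.CqDataset(_long(rows)))
        assert out.df[out.df.target == "gA"].cq.iloc[0] == pp.CODE_NODETECT
        assert out.df[out.df.target == "gB"].status.iloc[0] == "UD"

    def test_relative_cell_shifts_removed_exactly(self, noise_free_models):
        # zero-mean per-cell shifts: normalised output equals the shift-free one
        sch = sd.make_schedule("constant", n_genes=5, seed=0)
        m = sd.sample_snapshots(sch, 6, seed=1)
        spikes, dropout = noise_free_models
        base = sd.degrade_to_cq(m, spikes, dropout, seed=2)
        shifted = base.copy()
        shifts = {cell: (1.0 if i % 2 == 0 else -1.0) for i, cell in enumerate(shifted.cells)}
        numeric = (shifted.df.status == "OK") & (shifted.df.cq != pp.CODE_NODETECT)
        shifted.df.loc[numeric, "cq"] += shifted.df.loc[numeric, "cell_id"].map(shifts)
        out_base = pp.normalize_cq(pp.select_valid_cells(base))
        out_shift = pp.normalize_cq(pp.select_valid_cells(shifted))
        g0 = out_base.df[out_base.df.target_type == "gene"].cq.to_numpy()
        g1 = out_shift.df[out_shift.df.target_type == "gene"].cq.to_numpy()
        assert np.allclose(g0, g1)


class TestMoleculeConversion:
    def test_printed_constants_map_cq8_to_4320(self):
        rows = [
            ("c1", 0.0, "spike1", "spike", 13.0, "OK"),
            ("c1", 0.0, "gA", "gene", 8.0, "OK"),
            ("c1", 0.0, "gB", "gene", pp.CODE_NODETECT, "OK"),
            ("c1", 0.0, "gC", "gene", np.nan, "UD"),
        ]
        m = pp.cq_to_molecules(pp.CqDataset(_long(rows)))
        assert m.values.at["c1", "gA"] == pytest.approx(96 * 45 * 2.0**0)
        assert m.values.at["c1", "gB"] == 0.0
        assert np.isnan(m.values.at["c1", "gC"])

    def test_each_cycle_halves_molecule_count(self):
        rows = [("c1", 0.0, "spike1", "spike", 13.0, "OK")] + [
            ("c1", 0.0, f"g{i}", "gene", float(5 + i), "OK") for i in range(6)
        ]
        m = pp.cq_to_molecules(pp.CqDataset(_long(rows)))
        vals = m.values.loc["c1", [f"g{i}" for i in range(6)]].to_numpy()
        assert np.allclose(vals[:-1] / vals[1:], 2.0)

    def test_custom_constants_respected(self):
        k = pp.AssayConstants(plate_wells=10, pcr_sampling=10, preamp_cycles=5, max_cq=20)
        rows = [("c1", 0.0, "gA", "gene", 15.0, "OK")]
        m = pp.cq_to_molecules(pp.CqDataset(_long(rows), k))
        assert m.values.at["c1", "gA"] == pytest.approx(100.0)


class TestLogTransform:
    def test_analytic_values_and_missing_preserved(self):
        m = make_matrix([[0.0, np.e - 1.0], [np.nan, 3.0]], [0.0, 0.0])
        out = pp.log1_transform(m)
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == pytest.approx(1.0)
        assert np.isnan(out.values.iloc[1, 0])

    def test_rank_preserving(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1000, size=(20, 3))
        out = pp.log1_transform(make_matrix(v, [0.0] * 20))
        for c in range(3):
            assert (np.argsort(v[:, c]) == np.argsort(out.values.iloc[:, c].to_numpy())).all()


class TestImputation:
    def test_no_missing_returns_unchanged(self, constant_matrix):
        out, deleted, params = pp.impute_missing(constant_matrix, seed=0)
        assert deleted == [] and params == {}
        pd.testing.assert_frame_equal(out.values, constant_matrix.values)

    def test_observed_entries_never_altered_and_masks_cover(self):
        p = PoissonBetaParams(1.0, 2.0, 200.0)
        vals = poisson_beta_sample(p, 50 * 2, seed=0).reshape(50, 2).astype(float)
        m = make_matrix(vals, [0.0] * 50)
        miss = np.zeros_like(vals, dtype=bool)
        miss[::4, 0] = True
        m.values[miss] = np.nan
        out, deleted, params = pp.impute_missing(m, seed=1)
        assert not deleted
        obs = ~miss
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
        assert (out.imputed.to_numpy() == miss).all()
        assert not out.values.isna().any().any()

    def test_imputed_values_lie_in_beta_support(self):
        p = PoissonBetaParams(1.0, 2.0, 200.0)
        vals = poisson_beta_sample(p, 60, seed=2).reshape(60, 1).astype(float)
        m = make_matrix(vals, [0.0] * 60)
        m.values.iloc[::3, 0] = np.nan
        out, _, params = pp.impute_missing(m, seed=3)
        c_fit = params[(m.genes[0], 0.0)].c
        imputed_vals = out.values.to_numpy()[out.imputed.to_numpy()]
        assert ((imputed_vals >= 0) & (imputed_vals <= c_fit)).all()

    def test_imputed_distribution_matches_observed(self):
        # 30% missing under a known law: imputed vs observed pass a KS test
        p = PoissonBetaParams(1.0, 2.0, 300.0)
        ok = 0
        for seed in range(10):
            vals = poisson_beta_sample(p, 200, seed=seed).reshape(200, 1).astype(float)
            m = make_matrix(vals, [0.0] * 200)
            miss = np.random.default_rng(seed + 100).random(200) < 0.3
            m.values.iloc[miss, 0] = np.nan
            out, _, _ = pp.impute_missing(m, seed=seed + 200)
            imput = out.values.to_numpy()[miss.reshape(-1, 1) & np.ones((200, 1), bool)]
            obs = vals[~miss, 0]
            if stats.ks_2samp(imput, obs).pvalue > 0.01:
                ok += 1
        assert ok >= 9

    def test_gene_with_too_few_valid_cells_deleted(self):
        vals = np.abs(np.random.default_rng(0).normal(100, 30, size=(25, 2)))
        m = make_matrix(vals, [0.0] * 25)
        m.values.iloc[:10, 0] = np.nan  # 15 valid < 20
        out, deleted, _ = pp.impute_missing(m, min_valid_cells=20, seed=0)
        assert [d["gene"] for d in deleted] == [m.genes[0]]
        assert out.genes == [m.genes[1]]


class TestTechnicalSpans:
    def test_constant_spike_channel_has_zero_span(self):
        rows = [("c%d" % i, 0.0, "spike1", "spike", 13.0, "OK") for i in range(4)]
        rows += [("c%d" % i, 0.0, "gA", "gene", 10.0 + i, "OK") for i in range(4)]
        spike_span, gene_span = pp.technical_span_summary(pp.CqDataset(_long(rows)))
        assert spike_span == 0.0
        assert gene_span == pytest.approx(3.0)

    def test_mean_of_per_target_ranges(self):
        rows = []
        for i, cq in enumerate([10.0, 14.0]):  # spike1 range 4
            rows.append((f"c{i}", 0.0, "spike1", "spike", cq, "OK"))
        for i, cq in enumerate([10.0, 16.0]):  # spike2 range 6
            rows.append((f"c{i}", 0.0, "spike2", "spike", cq, "OK"))
        for i, cq in enumerate([8.0, 9.0]):
            rows.append((f"c{i}", 0.0, "gA", "gene", cq, "OK"))
        spike_span, gene_span = pp.technical_span_summary(pp.CqDataset(_long(rows)))
        assert spike_span == pytest.approx(5.0)
        assert gene_span == pytest.approx(1.0)

    def test_span_invariant_under_cell_reordering(self):
        data = small_dataset()
        shuffled = pp.CqDataset(data.df.iloc[::-1].reset_index(drop=True), data.constants)
        assert pp.technical_span_summary(data) == pp.technical_span_summary(shuffled)
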