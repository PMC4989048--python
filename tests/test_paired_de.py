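"""Paired NB differential expression: normalisation, factors, test, calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenosubnet import paired_de as de
from phenosubnet.synthio import SimConfig, simulate_paired_counts

from conftest import toy_de_table


def paired_meta(n_patients):
    rows = []
    for i in range(n_patients):
        p = f"P{i + 1:02d}"
        rows += [(f"{p}_PLC", p, "PLC", "A"), (f"{p}_DMC", p, "DMC", "A")]
    return pd.DataFrame(
        {"patient": [r[1] for r in rows], "site": [r[2] for r in rows],
         "batch": [r[3] for r in rows]},
        index=[r[0] for r in rows],
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]},
                              index=["g1", "g2", "g3"])
        sf = de.size_factors_median_of_ratios(counts)
        assert np.allclose(sf.factors, 1.0)

    def test_hand_computed_two_gene_case(self):
        counts = pd.DataFrame({"s1": [2, 8], "s2": [4, 16]}, index=["g1", "g2"])
        sf = de.size_factors_median_of_ratios(counts)
        assert np.allclose(sf.factors, [2**-0.5, 2**0.5], atol=1e-3)

    def test_scaling_one_column_scales_its_factor(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(5, 200, size=(40, 4)),
                              columns=list("abcd"))
        sf1 = de.size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["b"] = counts["b"] * 3
        sf2 = de.size_factors_median_of_ratios(scaled)
        ratio = sf2.factors / sf1.factors
        # the shared geometric-mean reference moves by 3**(1/4)
        ref_shift = 3 ** (1 / 4)
        assert np.isclose(ratio["b"], 3 / ref_shift, rtol=1e-9)
        assert np.allclose(ratio[["a", "c", "d"]], 1 / ref_shift, rtol=1e-9)

    def test_unestimable_without_allpositive_gene(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]})
        with pytest.raises(ValueError):
            de.size_factors_median_of_ratios(counts)


class TestFiltering:
    def test_zero_threshold_is_identity(self, small_counts):
        counts, meta, _ = small_counts
        out = de.filter_low_expression(counts, meta, 0.0)
        assert list(out.index) == list(counts.index)

    def test_all_zero_gene_removed_and_hand_count(self):
        meta = paired_meta(2)
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(50, 100, size=(10, 4)),
                              index=[f"g{i}" for i in range(10)],
                              columns=meta.index)
        counts.iloc[0] = 0          # all-zero: mean 0
        counts.iloc[1] = [1, 0, 0, 0]
        counts.iloc[2] = [0, 1, 1, 0]
        counts.iloc[3] = [2, 1, 0, 1]
        out = de.filter_low_expression(counts, meta, 5.0)
        assert len(out) == 6
        assert "g0" not in out.index

    def test_negative_threshold_rejected(self, small_counts):
        counts, meta, _ = small_counts
        with pytest.raises(ValueError):
            de.filter_low_expression(counts, meta, -1.0)


class TestControlGenes:
    def test_counts_and_determinism(self):
        rows = [(f"g{i}", 0.0, p) for i, p in enumerate(
            [0.5, 0.01, 0.3, 0.02, 0.9, 0.03, 0.7, 0.8, 0.6, 0.4])]
        result = toy_de_table(rows)
        result.table["pvalue"] = [r[2] for r in rows]
        controls = de.select_control_genes(result, 3)
        assert len(controls) == 7
        assert set(controls) == {f"g{i}" for i in (0, 2, 4, 6, 7, 8, 9)}
        assert de.select_control_genes(result, 0) == [f"g{i}" for i in range(10)]

    def test_exclude_everything_rejected(self):
        result = toy_de_table([("g1", 0.0, 0.5), ("g2", 0.0, 0.6)])
        with pytest.raises(ValueError):
            de.select_control_genes(result, 2)


class TestUnwantedFactors:
    def test_recovers_planted_rank_one_pattern(self):
        rng = np.random.default_rng(0)
        n_genes, n_samples = 60, 8
        pattern = np.array([1, 1, 1, 1, -1, -1, -1, -1], float)
        loadings = rng.normal(0, 1, n_genes)
        log_mu = 5 + 0.5 * np.outer(loadings, pattern)
        counts = pd.DataFrame(np.round(np.exp(log_mu)).astype(int),
                              index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{j}" for j in range(n_samples)])
        sf = de.SizeFactors(pd.Series(1.0, index=counts.columns))
        uf = de.estimate_unwanted_factors(counts, sf, list(counts.index), k=2)
        r = np.corrcoef(uf.scores["W1"], pattern)[0, 1]
        assert abs(r) > 0.99
        # rank-1 structure: second factor carries almost nothing
        norms = np.linalg.norm(uf.scores, axis=0)
        assert norms[1] < 0.1 * norms[0]

    def test_constant_controls_give_zero_scores(self):
        counts = pd.DataFrame(7, index=["g1", "g2", "g3"], columns=["a", "b", "c"])
        sf = de.SizeFactors(pd.Series(1.0, index=counts.columns))
        uf = de.estimate_unwanted_factors(counts, sf, ["g1", "g2", "g3"], k=1)
        assert np.allclose(uf.scores, 0.0, atol=1e-12)

    def test_k_bounds_enforced(self, small_counts):
        counts, _, _ = small_counts
        sf = de.size_factors_median_of_ratios(counts)
        with pytest.raises(ValueError):
            de.estimate_unwanted_factors(counts, sf, list(counts.index[:3]), k=4)
        with pytest.raises(ValueError):
            de.estimate_unwanted_factors(counts, sf, [], k=1)


class TestNbWald:
    def test_null_type_one_error_calibrated(self):
        cfg = SimConfig(n_genes=2000, de_fraction=0.0, batch_gene_fraction=0.0,
                        seed=11)
        counts, meta, _ = simulate_paired_counts(cfg)
        res = de.nb_wald_paired_test(counts, meta)
        frac = (res.table["pvalue"].dropna() < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_two_fold_gene(self):
        # a gene at log2FC = 2 with 8 pairs should nearly always be called
        hits = 0
        for rep in range(50):
            cfg = SimConfig(n_genes=150, de_fraction=0.0, de_log2fc_mean=2.0,
                            dispersion_range=(0.05, 0.15),  # moderate dispersion
                            batch_gene_fraction=0.0, seed=500 + rep)
            counts, meta, _ = simulate_paired_counts(cfg, de_genes={"G0050": 1.0})
            res = de.nb_wald_paired_test(counts, meta)
            if res.table.loc["G0050", "padj"] <= 0.1:
                hits += 1
        assert hits >= 48  # >= 95% of 50 replicates

    def test_no_signal_gene_flat(self):
        meta = paired_meta(4)
        counts = pd.DataFrame(
            {s: [100, 50, 300] for s in meta.index},
            index=["g1", "g2", "g3"],
        )
        res = de.nb_wald_paired_test(counts, meta)
        assert abs(res.table.loc["g1", "log2FoldChange"]) < 1e-6
        assert res.table.loc["g1", "pvalue"] > 0.5

    def test_all_zero_gene_reported_missing(self):
        meta = paired_meta(3)
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(20, 80, size=(5, 6)),
                              index=[f"g{i}" for i in range(5)],
                              columns=meta.index)
        counts.iloc[2] = 0
        res = de.nb_wald_paired_test(counts, meta)
        assert np.isnan(res.table.loc["g2", "pvalue"])
        assert np.isnan(res.table.loc["g2", "log2FoldChange"])

    def test_library_scaling_leaves_log2fc_invariant(self):
        # noiseless fixture: counts follow the multiplicative model exactly,
        # so size factors absorb a library rescale without residual error
        meta = paired_meta(3)
        rng = np.random.default_rng(5)
        base = 2 ** rng.integers(3, 9, size=20)  # powers of two stay integral
        lfc = rng.choice([-1, 0, 1], size=20)
        cols = {}
        for s in meta.index:
            vals = base * np.where(meta.loc[s, "site"] == "DMC", 2.0 ** lfc, 1.0)
            cols[s] = vals.astype(int)
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(20)])
        scaled = counts.copy()
        scaled.iloc[:, 0] = counts.iloc[:, 0] * 4  # integer rescale of one library
        r1 = de.nb_wald_paired_test(counts, meta)
        r2 = de.nb_wald_paired_test(scaled, meta)
        assert np.allclose(r1.table["log2FoldChange"], r2.table["log2FoldChange"],
                           atol=1e-6)

    def test_unpaired_metadata_rejected(self):
        meta = paired_meta(2).iloc[:-1]  # drop one DMC sample
        counts = pd.DataFrame(10, index=["g1"], columns=meta.index)
        with pytest.raises(ValueError):
            de.nb_wald_paired_test(counts, meta)

    def test_ruv_correction_reduces_confounded_inflation(self):
        cfg = SimConfig(n_genes=1200, de_fraction=0.0, batch_confounding=0.6,
                        batch_log2_shift=1.5, seed=21)
        counts, meta, _ = simulate_paired_counts(cfg)
        sf = de.size_factors_median_of_ratios(counts)
        raw = de.nb_wald_paired_test(counts, meta, sf=sf)
        controls = de.select_control_genes(raw, 120)
        uf = de.estimate_unwanted_factors(counts, sf, controls, k=1)
        corrected = de.nb_wald_paired_test(counts, meta, sf=sf, uf=uf)
        f_raw = (raw.table["pvalue"].dropna() < 0.05).mean()
        f_corr = (corrected.table["pvalue"].dropna() < 0.05).mean()
        assert f_corr < f_raw


class TestBhAdjust:
    def test_equal_inputs_unchanged(self):
        assert np.allclose(de.bh_adjust([0.2] * 5), 0.2)

    def test_hand_evaluated_step_up(self):
        q = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_definition(self, pvals):
        p = np.array(pvals)
        q = de.bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        for rank_pos, i in enumerate(order):
            js = np.arange(rank_pos, m)
            brute[i] = min(1.0, np.min(m * p[order][js] / (js + 1)))
        assert np.allclose(q, brute, atol=1e-12)
        assert np.all(q >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])


class TestCallDegs:
    def test_empty_result(self):
        up, down = de.call_degs(toy_de_table([]))
        assert up == [] and down == []

    def test_inclusive_boundaries(self):
        lfc = np.log2(1.5)
        result = toy_de_table([("up_edge", lfc, 0.1), ("down_edge", -lfc, 0.1),
                               ("too_weak", lfc * 0.99, 0.1),
                               ("not_sig", lfc, 0.11)])
        up, down = de.call_degs(result, fc_threshold=1.5, alpha=0.1)
        assert up == ["up_edge"] and down == ["down_edge"]

    def test_hand_filtered_toy(self):
        result = toy_de_table([
            ("a", 1.0, 0.01), ("b", 0.7, 0.05), ("c", -0.9, 0.02),
            ("d", 0.2, 0.01), ("e", 1.5, 0.5), ("f", -0.1, 0.9),
        ])
        up, down = de.call_degs(result, 1.5, 0.1)
        assert (len(up), len(down)) == (2, 1)

    def test_sub_unity_fold_threshold_rejected(self):
        with pytest.raises(ValueError):
            de.call_degs(toy_de_table([]), fc_threshold=0.5)


class TestSummaryUnits:
    def test_headline_arithmetic(self):
        s = de.deg_summary(["g"] * 830, ["g"] * 745, 17160)
        assert s["n_total"] == 1575
        assert s["pct_up"] == 4.8
        assert s["pct_down"] == 4.3

    def test_empty_and_exact_percentages(self):
        s = de.deg_summary([], [], 100)
        assert (s["n_total"], s["pct_up"], s["pct_down"]) == (0, 0.0, 0.0)
        s = de.deg_summary(["a"] * 5, ["b"] * 5, 100)
        assert s["pct_up"] == s["pct_down"] == 5.0

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            de.deg_summary([], [], 0)

    def test_fpkm_unit_case_and_scaling(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["g1", "g2"])
        counts.loc["filler"] = [1_000_000 - 100]
        lengths = pd.Series([1000, 500, 1000], index=["g1", "g2", "filler"])
        out = de.fpkm(counts, lengths)
        assert out.loc["g1", "s1"] == pytest.approx(100.0)
        assert out.loc["g2", "s1"] == 0.0
        doubled = counts * 2
        out2 = de.fpkm(doubled, lengths)
        assert out2.loc["g1", "s1"] == pytest.approx(out.loc["g1", "s1"])
        with pytest.raises(ValueError):
            de.fpkm(counts, pd.Series([0, 1, 1], index=counts.index))

    def test_ddct_reference_averaging(self):
        flat = de.ddct_relative_expression(
            {"DMC": 24.0, "PLC": 24.0}, {"DMC": (20, 22), "PLC": (20, 22)})
        assert flat.relative_expression["fold"] == pytest.approx(1.0)
        one_cycle = de.ddct_relative_expression(
            {"DMC": 23.0, "PLC": 24.0}, {"DMC": (20, 20), "PLC": (20, 20)})
        assert one_cycle.relative_expression["fold"] == pytest.approx(2.0)
        averaged = de.ddct_relative_expression(
            {"DMC": 24.0, "PLC": 25.0}, {"DMC": (20, 22), "PLC": (20, 22)})
        assert averaged.relative_expression["fold"] == pytest.approx(2.0)
        with pytest.raises(ValueError):
            de.ddct_relative_expression({"DMC": 24.0}, {"DMC": (20, 22)})
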