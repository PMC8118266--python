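import numpy as np
import pandas as pd
import pytest

from crinet import (
    ConsensusConfig,
    ExpressionMatrix,
    InteractionTable,
    abundance_filter,
    compute_effective_regulation,
    compute_interaction_regulation,
    expression_correlation_filter,
    filter_genes_by_effective_regulation,
)
from crinet.regulation import (
    bootstrap_counts,
    bootstrap_row_correlations,
    interpolated_percentile,
    row_correlations,
)

from conftest import random_toy_instance


# ---------------------------------------------------------------------------
# independent brute-force oracles (explicit per-sample loops)
# ---------------------------------------------------------------------------

def ir_bruteforce(table, mirnas, genes):
    """Literal per-record, per-sample evaluation of the IR statistic."""
    recs = list(zip(table.data["regulator"], table.data["target"],
                    table.data["norm_weight"]))
    out = {}
    for r, t, w in recs:
        vals = []
        for s in genes.sample_ids:
            er = mirnas.data.loc[r, s]
            et = genes.data.loc[t, s]
            num = er * et * w
            den1 = sum(genes.data.loc[tj, s] * wj
                       for rj, tj, wj in recs if rj == r)
            den2 = sum(mirnas.data.loc[rj, s] * wj
                       for rj, tj, wj in recs if tj == t)
            f1 = num / den1 if den1 > 0 else 0.0
            f2 = num / den2 if den2 > 0 else 0.0
            vals.append(f1 * f2)
        out[(r, t)] = np.array(vals)
    return out


def er_bruteforce(table, mirnas):
    """Literal double-loop evaluation of the ER statistic."""
    recs = list(zip(table.data["regulator"], table.data["target"],
                    table.data["norm_weight"]))
    out = {}
    for t in sorted({tt for _, tt, _ in recs}):
        vals = []
        for s in mirnas.sample_ids:
            total = 0.0
            for r, tt, w in recs:
                if tt != t:
                    continue
                score_sum = sum(wj for rj, _, wj in recs if rj == r)
                total += mirnas.data.loc[r, s] * w / score_sum
            vals.append(total)
        out[t] = np.array(vals)
    return out


# ---------------------------------------------------------------------------
# interaction regulation
# ---------------------------------------------------------------------------

class TestInteractionRegulation:
    def test_single_edge_collapses_to_expression_product(self):
        genes = ExpressionMatrix(pd.DataFrame([[3.0, 5.0]], index=["g"],
                                              columns=["s1", "s2"]))
        mirnas = ExpressionMatrix(pd.DataFrame([[2.0, 7.0]], index=["m"],
                                               columns=["s1", "s2"]))
        table = InteractionTable(pd.DataFrame(
            {"regulator": ["m"], "target": ["g"], "raw_score": [-0.5],
             "rna_class": ["mRNA"], "norm_weight": [1.0]}))
        reg = compute_interaction_regulation(table, mirnas, genes)
        # both fractions collapse, leaving Exp(r) * Exp(t) exactly
        np.testing.assert_array_equal(reg.ir_for("m", "g"), [6.0, 35.0])

    def test_zero_regulator_expression_gives_zero_ir(self):
        genes = ExpressionMatrix(pd.DataFrame([[3.0, 5.0]], index=["g"],
                                              columns=["s1", "s2"]))
        mirnas = ExpressionMatrix(pd.DataFrame([[0.0, 7.0]], index=["m"],
                                               columns=["s1", "s2"]))
        table = InteractionTable(pd.DataFrame(
            {"regulator": ["m"], "target": ["g"], "raw_score": [-0.5],
             "rna_class": ["mRNA"], "norm_weight": [1.0]}))
        reg = compute_interaction_regulation(table, mirnas, genes)
        assert reg.ir_for("m", "g")[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        genes, mirnas, table = random_toy_instance(rng)
        reg = compute_interaction_regulation(table, mirnas, genes)
        oracle = ir_bruteforce(table, mirnas, genes)
        for key, expected in oracle.items():
            np.testing.assert_allclose(reg.ir_for(*key), expected, atol=1e-10)

    def test_nonnegative_everywhere(self, rng):
        genes, mirnas, table = random_toy_instance(rng)
        reg = compute_interaction_regulation(table, mirnas, genes)
        assert (reg.ir.to_numpy() >= 0).all()


class TestEffectiveRegulation:
    def test_single_edge_collapses_to_regulator_expression(self):
        mirnas = ExpressionMatrix(pd.DataFrame([[2.0, 7.0]], index=["m"],
                                               columns=["s1", "s2"]))
        table = InteractionTable(pd.DataFrame(
            {"regulator": ["m"], "target": ["g"], "raw_score": [-0.5],
             "rna_class": ["mRNA"], "norm_weight": [0.4]}))
        reg = compute_effective_regulation(table, mirnas)
        np.testing.assert_array_equal(reg.er_for("g"), [2.0, 7.0])

    def test_equal_split_between_two_targets(self):
        mirnas = ExpressionMatrix(pd.DataFrame([[4.0, 8.0]], index=["m"],
                                               columns=["s1", "s2"]))
        table = InteractionTable(pd.DataFrame(
            {"regulator": ["m", "m"], "target": ["t1", "t2"],
             "raw_score": [-0.5, -0.4], "rna_class": ["mRNA"] * 2,
             "norm_weight": [0.5, 0.5]}))
        reg = compute_effective_regulation(table, mirnas)
        np.testing.assert_allclose(reg.er_for("t1"), [2.0, 4.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_toys(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes, mirnas, table = random_toy_instance(rng)
        reg = compute_effective_regulation(table, mirnas, genes)
        oracle = er_bruteforce(table, mirnas)
        for gene, expected in oracle.items():
            np.testing.assert_allclose(reg.er_for(gene), expected, atol=1e-10)

    def test_er_invariant_to_scaling_one_mirnas_weights(self, rng):
        """The inner weight ratio makes ER scale-free per regulator."""
        genes, mirnas, table = random_toy_instance(rng, n_genes=6, n_mirnas=3)
        df = table.data.copy()
        scaled = df.copy()
        m0 = scaled["regulator"].iloc[0]
        scaled.loc[scaled["regulator"] == m0, "norm_weight"] *= 7.3
        reg_a = compute_effective_regulation(InteractionTable(df), mirnas, genes)
        reg_b = compute_effective_regulation(InteractionTable(scaled), mirnas, genes)
        np.testing.assert_allclose(reg_a.er.to_numpy(), reg_b.er.to_numpy(),
                                   atol=1e-10)


# ---------------------------------------------------------------------------
# abundance filter
# ---------------------------------------------------------------------------

class TestAbundanceFilter:
    def _reg_with_constant_ir(self, table, value, n_samples=6):
        import crinet.regulation as R

        index = pd.MultiIndex.from_arrays(
            [table.data["regulator"], table.data["target"]])
        ir = pd.DataFrame(np.full((len(table), n_samples), value), index=index,
                          columns=[f"s{i}" for i in range(n_samples)])
        return R.RegulationVectors(ir=ir)

    def _one_record_table(self):
        return InteractionTable(pd.DataFrame(
            {"regulator": ["m"], "target": ["g"], "raw_score": [-0.5],
             "rna_class": ["mRNA"], "norm_weight": [1.0]}))

    def test_constant_above_threshold_kept(self):
        t = self._one_record_table()
        out = abundance_filter(t, self._reg_with_constant_ir(t, np.exp(-4)))
        assert len(out) == 1

    def test_constant_below_threshold_removed(self):
        t = self._one_record_table()
        out = abundance_filter(t, self._reg_with_constant_ir(t, np.exp(-5)))
        assert len(out) == 0

    def test_interpolated_percentile_formula(self):
        # 10 samples, log IR = (-5 x8, -1 x2): h = 9*0.8 = 7.2 (0-based)
        # -> -5 + 0.2 * 4 = -4.2, which clears the -4.89 cut
        v = np.array([-5.0] * 8 + [-1.0] * 2)
        assert interpolated_percentile(v, 0.8) == pytest.approx(-4.2)
        t = self._one_record_table()
        import crinet.regulation as R

        index = pd.MultiIndex.from_arrays([["m"], ["g"]])
        ir = pd.DataFrame([np.exp(v)], index=index,
                          columns=[f"s{i}" for i in range(10)])
        out = abundance_filter(t, R.RegulationVectors(ir=ir))
        assert len(out) == 1

    def test_percentile_with_zero_ir_is_minus_inf(self):
        v = np.array([0.0, 0.0, 0.0, 1.0])
        with np.errstate(divide="ignore"):
            assert interpolated_percentile(np.log(v), 0.5) == -np.inf


# ---------------------------------------------------------------------------
# correlation filters + consensus
# ---------------------------------------------------------------------------

def _pair_matrices(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(10, 3, n)
    return x


class TestExpressionCorrelationFilter:
    def _build(self, mirna_row, gene_row):
        n = len(mirna_row)
        cols = [f"s{i}" for i in range(n)]
        mirnas = ExpressionMatrix(pd.DataFrame([mirna_row], index=["m"], columns=cols))
        genes = ExpressionMatrix(pd.DataFrame([gene_row], index=["g"], columns=cols))
        table = InteractionTable(pd.DataFrame(
            {"regulator": ["m"], "target": ["g"], "raw_score": [-0.5],
             "rna_class": ["mRNA"], "norm_weight": [1.0]}))
        return table, mirnas, genes

    def test_perfect_anticorrelation_kept(self):
        x = np.linspace(1, 10, 30)
        table, mirnas, genes = self._build(x, 20 - x)
        out = expression_correlation_filter(
            table, mirnas, genes, consensus=ConsensusConfig(n_resamples=200, seed=1))
        assert len(out) == 1
        assert out.data["corr"].iloc[0] == pytest.approx(-1.0)

    def test_constant_regulator_dropped(self):
        table, mirnas, genes = self._build([2.0] * 10, list(range(10)))
        out = expression_correlation_filter(table, mirnas, genes)
        assert len(out) == 0

    def test_weak_anticorrelation_dropped_and_fraction_reproducible(self):
        rng = np.random.default_rng(42)
        x = rng.normal(10, 3, 60)
        y = -0.05 * x + rng.normal(10, 3, 60)  # sample corr near -0.05
        table, mirnas, genes = self._build(x, y)
        cfg = ConsensusConfig(n_resamples=300, seed=7)
        out = expression_correlation_filter(table, mirnas, genes, consensus=cfg)
        assert len(out) == 0

        # independent seeded re-run of the consensus fraction
        X = mirnas.values - mirnas.values.mean(axis=1, keepdims=True)
        Y = genes.values - genes.values.mean(axis=1, keepdims=True)
        counts = np.random.default_rng(7).multinomial(
            60, np.full(60, 1 / 60), size=300).T.astype(float)
        frac_pkg = (bootstrap_row_correlations(X, Y, counts) < -0.1).mean()
        manual = []
        for b in range(300):
            idx = np.repeat(np.arange(60), counts[:, b].astype(int))
            manual.append(np.corrcoef(x[idx], y[idx])[0, 1] < -0.1)
        assert frac_pkg == pytest.approx(np.mean(manual), abs=1e-12)

    def test_filter_idempotent(self):
        x = np.linspace(1, 10, 30)
        table, mirnas, genes = self._build(x, 20 - x + 0.01 * x**2)
        cfg = ConsensusConfig(n_resamples=100, seed=3)
        once = expression_correlation_filter(table, mirnas, genes, consensus=cfg)
        twice = expression_correlation_filter(once, mirnas, genes, consensus=cfg)
        assert len(once) == len(twice)
        assert set(zip(twice.data["regulator"], twice.data["target"])) <= \
            set(zip(table.data["regulator"], table.data["target"]))


class TestEffectiveRegulationFilter:
    def _setup(self, er_rows, expr_rows):
        import crinet.regulation as R

        n = len(next(iter(expr_rows.values())))
        cols = [f"s{i}" for i in range(n)]
        genes = ExpressionMatrix(pd.DataFrame(expr_rows, index=cols).T)
        er = pd.DataFrame(er_rows, index=cols).T
        return genes, R.RegulationVectors(er=er)

    def test_exact_negative_linear_kept_constant_er_excluded(self):
        x = np.linspace(1, 5, 20)
        genes, reg = self._setup(
            {"good": -x + 10, "flat": [3.0] * 20},
            {"good": x, "flat": x},
        )
        kept = filter_genes_by_effective_regulation(
            genes, reg, consensus=ConsensusConfig(n_resamples=100, seed=5))
        assert kept == {"good"}

    def test_empty_candidate_set_raises(self):
        x = np.linspace(1, 5, 20)
        genes, reg = self._setup({"g": x + 1}, {"g": x})  # positive corr
        with pytest.raises(ValueError, match="no gene"):
            filter_genes_by_effective_regulation(genes, reg)

    def test_borderline_gene_excluded_with_low_consensus_fraction(self):
        rng = np.random.default_rng(11)
        x = rng.normal(10, 2, 80)
        er_borderline = -0.005 * x + rng.normal(5, 2, 80)
        good = np.linspace(1, 5, 80)
        genes, reg = self._setup(
            {"borderline": er_borderline, "good": -good + 9},
            {"borderline": x, "good": good},
        )
        cfg = ConsensusConfig(n_resamples=200, seed=13)
        kept, stats = filter_genes_by_effective_regulation(
            genes, reg, consensus=cfg, return_stats=True)
        assert kept == {"good"}
        frac = stats.set_index("gene").loc["borderline", "consensus_frac"]
        assert frac < 0.99
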