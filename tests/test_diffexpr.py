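"""Differential expression: filtering, normalization, testing, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import tmecausal as tc
from tmecausal.diffexpr import DEResult, filter_low_counts, size_factors

from .oracles import bh_adjust_brute


def _labels(counts, n_high):
    return pd.Series(
        ["high"] * n_high + ["low"] * (counts.shape[1] - n_high),
        index=counts.columns,
    )


class TestFilter:
    def test_uniformly_low_gene_removed(self):
        counts = pd.DataFrame({f"s{i}": [4, 100] for i in range(10)},
                              index=["low", "ok"])
        kept = filter_low_counts(counts)
        assert list(kept.index) == ["ok"]  # 4 < 10/2 everywhere

    def test_single_large_count_retains(self):
        row = [0] * 9 + [100]
        counts = pd.DataFrame([row, [9] * 10],
                              index=["spike", "steady"],
                              columns=[f"s{i}" for i in range(10)])
        kept = filter_low_counts(counts)
        assert set(kept.index) == {"spike", "steady"}

    def test_matches_bruteforce_rule(self, toy_counts):
        kept = filter_low_counts(toy_counts)
        half = toy_counts.shape[1] / 2
        expected = [
            g for g in toy_counts.index
            if not (toy_counts.loc[g] < half).all()
        ]
        assert list(kept.index) == expected

    def test_alternative_rules(self, toy_counts):
        total = filter_low_counts(toy_counts, "total_below_half_n")
        assert set(total.index) == {
            g for g in toy_counts.index
            if toy_counts.loc[g].sum() >= toy_counts.shape[1] / 2}
        with pytest.raises(ValueError):
            filter_low_counts(toy_counts, "bogus")


class TestSizeFactors:
    def test_proportional_columns_recover_constants(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=40).astype(float)
        scale = np.array([0.5, 1.0, 2.0, 4.0])
        counts = pd.DataFrame(
            np.round(base[:, None] * scale[None, :]),
            columns=list("abcd"))
        sf = size_factors(counts)
        expected = scale / np.exp(np.mean(np.log(scale)))
        # up to rounding of the counts
        assert np.allclose(sf.values, expected, rtol=0.02)

    def test_all_zero_gene_handled(self):
        counts = pd.DataFrame({"a": [0, 5, 10], "b": [0, 5, 10]})
        sf = size_factors(counts)
        assert np.allclose(sf.values, [1.0, 1.0])


class TestBH:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=20))
    def test_bh_matches_bruteforce(self, pvals):
        ours = multipletests(pvals, method="fdr_bh")[1]
        brute = bh_adjust_brute(np.array(pvals))
        assert np.allclose(ours, brute, atol=1e-12)


class TestWald:
    def test_identical_columns_give_zero_lfc(self):
        col = np.array([5, 50, 500, 17, 120])
        counts = pd.DataFrame({"a": col, "b": col},
                              index=[f"g{i}" for i in range(5)])
        res = tc.nb_wald_test(counts, _labels(counts, 1))
        assert all(r.log2_fc == pytest.approx(0.0, abs=1e-8) for r in res)

    def test_null_simulation_calibrated(self):
        rng = np.random.default_rng(8)
        n_genes, n = 600, 60
        mu = 2.0 ** rng.uniform(3, 9, n_genes)
        r = 1 / 0.2
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, n)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n)])
        res = tc.nb_wald_test(filter_low_counts(counts), _labels(counts, 30))
        raw = np.mean([x.p_value < 0.05 for x in res])
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert raw <= 0.05 + 3 * se
        assert np.mean([x.fdr < 0.05 for x in res]) <= 0.05 + 3 * se

    def test_fourfold_change_recovered(self):
        rng = np.random.default_rng(9)
        n_genes, per = 200, 50
        mu = 2.0 ** rng.uniform(4, 9, n_genes)
        r = 1 / 0.2
        counts = rng.negative_binomial(r, r / (r + mu[:, None]),
                                       size=(n_genes, 2 * per))
        counts[0, :per] = rng.negative_binomial(
            r, r / (r + 4 * mu[0]), size=per)
        counts = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(2 * per)])
        res = tc.nb_wald_test(counts, _labels(counts, per))
        hit = next(x for x in res if x.gene == "g0")
        assert hit.log2_fc == pytest.approx(2.0, abs=0.3)
        assert hit.fdr < 0.05

    def test_log2fc_agrees_with_reference_implementation(self):
        """Fold-change estimates track an independent NB DE implementation."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(1)
        n_genes, per = 120, 30
        mu = 2.0 ** rng.uniform(4, 9, n_genes)
        r = 1 / 0.2
        counts = rng.negative_binomial(r, r / (r + mu[:, None]),
                                       size=(n_genes, 2 * per))
        for i in range(10):
            counts[i, :per] = rng.negative_binomial(
                r, r / (r + (2 ** (1 + i % 3)) * mu[i]), size=per)
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(2 * per)]
        labels = ["high"] * per + ["low"] * per
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=pd.DataFrame(counts.T, columns=genes),
                metadata=pd.DataFrame({"group": labels}),
                design="~group", quiet=True)
            dds.deseq2()
            stat = DeseqStats(dds, contrast=["group", "high", "low"],
                              quiet=True)
            stat.summary()
        ref = stat.results_df["log2FoldChange"]
        ours = tc.nb_wald_test(
            pd.DataFrame(counts, index=genes, columns=samples),
            pd.Series(labels, index=samples))
        lfc = pd.Series({x.gene: x.log2_fc for x in ours})
        assert np.corrcoef(lfc[ref.index], ref)[0, 1] > 0.99
        spiked = [f"g{i}" for i in range(10)]
        assert np.allclose(lfc[spiked], ref[spiked], atol=0.1)

    def test_bad_labels_rejected(self, toy_counts):
        labels = pd.Series(["x"] * toy_counts.shape[1], index=toy_counts.columns)
        with pytest.raises(ValueError, match="high"):
            tc.nb_wald_test(toy_counts, labels)


class TestSelection:
    def _r(self, gene, lfc, fdr):
        return DEResult(gene, 10.0, lfc, fdr / 2, fdr)

    @pytest.mark.parametrize("lfc,fdr,kept,direction", [
        (1.6, 0.01, True, "up"),
        (1.4, 0.001, False, None),
        (-2.0, 0.04, True, "down"),
        (1.6, 0.06, False, None),
    ])
    def test_cutoffs(self, lfc, fdr, kept, direction):
        selected = tc.select_degs([self._r("g", lfc, fdr)])
        assert bool(selected) == kept
        if kept:
            assert selected[0].direction == direction

    def test_shared_requires_concordance(self):
        imm = [self._r("a", 2.0, 0.01), self._r("b", 2.0, 0.01),
               self._r("c", -2.0, 0.01)]
        stro = [self._r("a", 1.8, 0.01), self._r("b", -1.8, 0.01),
                self._r("c", -2.5, 0.01)]
        shared = tc.shared_degs(imm, stro)
        assert sorted(r.gene for r in shared) == ["a", "c"]

    def test_shared_matches_set_algebra(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        imm = [self._r(g, rng.choice([-2.0, 2.0]), 0.01)
               for g in rng.choice(genes, 20, replace=False)]
        stro = [self._r(g, rng.choice([-2.0, 2.0]), 0.01)
                for g in rng.choice(genes, 20, replace=False)]
        up_i = {r.gene for r in imm if r.direction == "up"}
        dn_i = {r.gene for r in imm if r.direction == "down"}
        up_s = {r.gene for r in stro if r.direction == "up"}
        dn_s = {r.gene for r in stro if r.direction == "down"}
        expected = (up_i & up_s) | (dn_i & dn_s)
        assert {r.gene for r in tc.shared_degs(imm, stro)} == expected
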