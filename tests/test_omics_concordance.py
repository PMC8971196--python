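"""FDR classification, Fisher exact test, peak and promoter summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from myoph.omics_concordance import (
    ContingencyTable2x2,
    bh_adjust,
    classify_features,
    concordance_table,
    fisher_exact_2x2,
    percent_rounded,
    promoter_overlap_fraction,
    spike_in_scale_factor,
    summarize_peak_presence,
)
from myoph.synthetic_data import OmicsTableSpec, generate_omics_tables


def bh_literal(p):
    """Independent step-up oracle: padj_i = min_{j >= rank_i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(1.0, running)
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_step_up_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_fuzz_equals_literal_definition(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, n)
            if rng.random() < 0.3:  # inject ties and extremes
                p[rng.integers(0, n)] = rng.choice([0.0, 1.0, 0.5])
            np.testing.assert_allclose(bh_adjust(p), bh_literal(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClassification:
    def test_toy_table(self):
        table = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "log2fc": [1.0, -1.0, -2.0],
                "pvalue": [0.5, 0.5, 0.5],
                "padj": [0.01, 0.2, 0.04],
            }
        )
        down, up = classify_features(table)
        assert up == {"a"} and down == {"c"}

    def test_empty_table(self):
        down, up = classify_features(pd.DataFrame())
        assert down == set() and up == set()

    def test_alpha_zero_returns_nothing(self):
        table = pd.DataFrame(
            {"id": ["a"], "log2fc": [2.0], "pvalue": [0.0], "padj": [0.0]}
        )
        down, up = classify_features(table, alpha=0.0)
        assert down == set() and up == set()

    def test_alpha_one_returns_all_directional_features(self):
        table = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "log2fc": [2.0, -1.0, 0.0],
                "pvalue": [0.2, 0.4, 0.1],
                "padj": [0.6, 0.8, 0.3],
            }
        )
        with pytest.warns(UserWarning, match="log2FC == 0"):
            down, up = classify_features(table, alpha=1.0)
        assert down == {"b"} and up == {"a"}  # zero-fold-change feature excluded


class TestConcordance:
    def test_all_same_direction_infinite_odds(self):
        t, odds, _ = concordance_table({"g1", "g2"}, {"g3"}, ["g1", "g2"], ["g3"])
        assert t.b == 0 and t.c == 0
        assert math.isinf(odds)

    def test_hand_counted_table(self):
        gene_down = {f"d{i}" for i in range(10)}
        gene_up = {f"u{i}" for i in range(10)}
        prot_down = [f"d{i}" for i in range(8)] + ["u0"]
        prot_up = ["d8", "d9"] + [f"u{i}" for i in range(1, 10)]
        t, odds, pairs = concordance_table(gene_down, gene_up, prot_down, prot_up)
        assert (t.a, t.b, t.c, t.d) == (8, 2, 1, 9)
        assert odds == pytest.approx(36.0)
        assert len(pairs) == 20

    def test_duplicate_protein_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            concordance_table({"a"}, set(), ["a"], ["a"])

    def test_generator_concordance_detected_across_seeds(self):
        # with 90% direction concordance over ~100 matched pairs the Fisher
        # test should call the association significant essentially always
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = OmicsTableSpec(
                n_genes=500, frac_down=0.12, frac_up=0.12,
                n_matched_proteins=100, concordance_prob=0.9,
                n_background_peaks=10, seed=1000 + seed,
            )
            deg, dap, _, _ = generate_omics_tables(spec)
            g_down, g_up = classify_features(deg)
            p_down, p_up = classify_features(dap)
            t, _, _ = concordance_table(g_down, g_up, p_down, p_up)
            if fisher_exact_2x2(t) < 0.05:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestFisher:
    def test_enumerated_example(self):
        assert fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(
            34.0 / 70.0, abs=1e-12
        )

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 25, 4)
            if a + b + c + d == 0:
                continue
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            ours = fisher_exact_2x2(t)
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestPeakPresence:
    def _table(self, flags, conds=("A", "B")):
        n = len(flags)
        df = pd.DataFrame(
            {"chrom": ["chr1"] * n, "start": range(0, 100 * n, 100),
             "end": range(50, 100 * n, 100)}
        )
        for j, c in enumerate(conds):
            df[c] = [row[j] for row in flags]
        return df

    def test_single_condition_all_present(self):
        df = self._table([(True,), (True,), (True,)], conds=("A",))
        res = summarize_peak_presence(df)
        assert res["union"] == 3
        assert res["conditions"]["A"]["percent"] == 100

    def test_counts_match_independent_tally(self):
        rng = np.random.default_rng(17)
        flags = []
        while len(flags) < 400:
            row = tuple(rng.random(3) < [0.8, 0.6, 0.4])
            if any(row):
                flags.append(row)
        df = self._table(flags, conds=("A", "B", "C"))
        res = summarize_peak_presence(df)
        for j, c in enumerate(("A", "B", "C")):
            brute = sum(1 for row in flags if row[j])
            assert res["conditions"][c]["count"] == brute
            assert res["conditions"][c]["percent"] <= 100

    def test_max_count_gives_max_percent(self):
        rng = np.random.default_rng(2)
        flags = []
        while len(flags) < 200:
            row = tuple(rng.random(3) < [0.9, 0.5, 0.3])
            if any(row):
                flags.append(row)
        res = summarize_peak_presence(self._table(flags, conds=("A", "B", "C")))
        counts = {c: v["count"] for c, v in res["conditions"].items()}
        pcts = {c: v["percent"] for c, v in res["conditions"].items()}
        assert max(pcts, key=pcts.get) == max(counts, key=counts.get)

    def test_row_absent_everywhere_rejected(self):
        df = self._table([(True, False), (False, False)])
        with pytest.raises(ValueError, match="union"):
            summarize_peak_presence(df)

    def test_rounding_ties_away_from_zero(self):
        assert percent_rounded(1, 8) == 13  # 12.5 -> 13
        assert percent_rounded(0, 8) == 0
        assert percent_rounded(8, 8) == 100


class TestPromoterOverlap:
    def _tss(self, positions):
        return pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(len(positions))],
                "chrom": "chr1",
                "tss": positions,
                "strand": "+",
            }
        )

    def _peaks(self, intervals, present=True):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * len(intervals),
                "start": [s for s, _ in intervals],
                "end": [e for _, e in intervals],
                "cond": [present] * len(intervals),
            }
        )

    def test_no_peaks_gives_zero(self):
        frac, _ = promoter_overlap_fraction(
            self._tss([1000]), self._peaks([]), window_bp=500
        )
        assert frac == 0.0

    def test_hand_interval_check(self):
        tss = self._tss([1000, 5000, 9000])
        peaks = self._peaks([(900, 1100), (8000, 8400)])
        frac, flags = promoter_overlap_fraction(tss, peaks, window_bp=500)
        assert frac == pytest.approx(1.0 / 3.0)
        assert flags["promoter_has_peak"].tolist() == [True, False, False]

    def test_invariant_to_row_order_and_peak_splitting(self):
        tss = self._tss([1000, 5000, 9000, 20000])
        peaks = self._peaks([(900, 1100), (4500, 5600), (30000, 30100)])
        frac1, _ = promoter_overlap_fraction(tss, peaks, window_bp=500)
        shuffled = peaks.sample(frac=1.0, random_state=1).reset_index(drop=True)
        frac2, _ = promoter_overlap_fraction(tss, shuffled, window_bp=500)
        split = self._peaks(
            [(900, 1000), (1000, 1100), (4500, 5000), (5000, 5600), (30000, 30100)]
        )
        frac3, _ = promoter_overlap_fraction(tss, split, window_bp=500)
        assert frac1 == frac2 == frac3

    def test_condition_restriction(self):
        tss = self._tss([1000])
        peaks = self._peaks([(900, 1100)], present=False)
        frac_any, _ = promoter_overlap_fraction(tss, peaks, window_bp=500)
        frac_cond, _ = promoter_overlap_fraction(
            tss, peaks, window_bp=500, condition="cond"
        )
        assert frac_any == 1.0 and frac_cond == 0.0

    def test_binomial_recovery_from_generator(self):
        spec = OmicsTableSpec(
            n_genes=3000, promoter_overlap_prob=2.0 / 3.0,
            n_background_peaks=500, seed=19,
        )
        _, _, peaks, tss = generate_omics_tables(spec)
        frac, _ = promoter_overlap_fraction(tss, peaks, window_bp=2000)
        assert frac == pytest.approx(2.0 / 3.0, abs=0.03)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            promoter_overlap_fraction(self._tss([]), self._peaks([(0, 10)]))


class TestSpikeIn:
    def test_equal_ratios_give_unity(self):
        assert spike_in_scale_factor(10, 40, 5, 20) == pytest.approx(1.0)

    def test_hand_example(self):
        # input dm6:rn6 = 1:10, IP dm6:rn6 = 1:5 -> 0.1 / 0.2 = 0.5
        assert spike_in_scale_factor(1, 5, 1, 10) == pytest.approx(0.5)

    def test_depth_invariance(self):
        f1 = spike_in_scale_factor(100, 400, 50, 600)
        f2 = spike_in_scale_factor(200, 800, 100, 1200)
        assert f1 == pytest.approx(f2)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            spike_in_scale_factor(0, 1, 1, 1)
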