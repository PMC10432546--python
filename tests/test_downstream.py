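"""Differential accessibility, sharing categorization and Fisher enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacsep.downstream import (
    categorize_sharing,
    differential_ocr,
    fisher_enrichment,
    planted_signal_groups,
    _rank_sum_p,
)


class TestDifferentialOcr:
    def test_identical_groups_yield_nothing(self):
        rng = np.random.default_rng(0)
        g = rng.random((8, 50))
        table = differential_ocr(g, g.copy())
        assert not table["significant"].any()

    def test_defaults_follow_the_published_thresholds(self):
        import inspect

        sig = inspect.signature(differential_ocr)
        assert sig.parameters["alpha"].default == 0.05
        assert sig.parameters["fc_min"].default == 0.5

    def test_planted_signal_recovered_exactly(self):
        A, B, shifted = planted_signal_groups(
            n_per_group=10, n_ocr=200, n_shifted=20, shift_factor=4.0, seed=1
        )
        table = differential_ocr(A, B)
        called = np.flatnonzero(table["significant"].to_numpy())
        assert np.array_equal(called, shifted)
        assert (table.loc[called, "direction"] == "up").all()

    def test_adjusted_p_never_below_raw(self):
        A, B, _ = planted_signal_groups(seed=2)
        table = differential_ocr(A, B)
        assert (table["p_adj"] >= table["p_value"] - 1e-12).all()

    def test_overlapping_sample_ids_rejected(self):
        g = np.random.default_rng(3).random((4, 10))
        with pytest.raises(ValueError, match="share sample ids"):
            differential_ocr(
                g, g, sample_ids_a=["a", "b", "c", "d"], sample_ids_b=["d", "e", "f", "g"]
            )

    def test_type_i_error_under_the_dual_threshold(self):
        """Null simulations: both groups drawn from the same distribution;
        the fraction of OCRs called significant stays below 1e-3."""
        rng = np.random.default_rng(4)
        n_sig = 0
        n_total = 0
        for _ in range(60):
            A = rng.lognormal(0, 0.3, size=(10, 200))
            B = rng.lognormal(0, 0.3, size=(10, 200))
            table = differential_ocr(A, B)
            n_sig += int(table["significant"].sum())
            n_total += 200
        assert n_sig / n_total < 1e-3


class TestRankSumExactness:
    @pytest.mark.parametrize("na,nb", [(4, 4), (5, 7), (8, 6)])
    def test_agrees_with_exhaustive_enumeration(self, na, nb):
        """Small tie-free groups: the p value matches the exact permutation
        distribution of the rank sum enumerated by brute force."""
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.normal(0, 1, na)
        b = rng.normal(0.8, 1, nb)
        p_impl = _rank_sum_p(a, b)

        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs = ranks[:na].sum()
        mean = na * (na + len(pooled) - na + 1) / 2.0  # na*(n+1)/2
        stat_obs = abs(obs - mean)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), na):
            w = ranks[list(combo)].sum()
            if abs(w - mean) >= stat_obs - 1e-9:
                count += 1
            total += 1
        assert p_impl == pytest.approx(count / total, abs=1e-10)


class TestBenjaminiHochberg:
    def test_agrees_with_step_up_reference(self):
        """statsmodels BH (as used in the tables) vs a hand-rolled step-up."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.random(47)
            ours = multipletests(p, method="fdr_bh")[1]

            m = len(p)
            order = np.argsort(p)
            ranked = p[order] * m / (np.arange(m) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            ref = np.empty(m)
            ref[order] = np.minimum(ranked, 1.0)
            assert np.max(np.abs(ours - ref)) < 1e-12


class TestSharing:
    @staticmethod
    def _table(peak_ids, sig_ids, direction="up"):
        return pd.DataFrame(
            {
                "peak_id": peak_ids,
                "significant": [p in sig_ids for p in peak_ids],
                "direction": [direction] * len(peak_ids),
            }
        )

    def test_categories_and_counts(self):
        peaks = [f"p{i}" for i in range(12)]
        exc_only = {"p0", "p1", "p2", "p3", "p4"}
        mic_only = {"p5", "p6", "p7"}
        shared = {"p8", "p9"}
        tables = {
            "EXC": self._table(peaks, exc_only | shared),
            "MIC": self._table(peaks, mic_only | shared),
        }
        summary = categorize_sharing(tables)
        assert summary.categories[frozenset({"EXC"})] == 5
        assert summary.categories[frozenset({"MIC"})] == 3
        assert summary.categories[frozenset({"EXC", "MIC"})] == 2
        assert summary.n_significant == 10
        assert sum(summary.categories.values()) == summary.n_significant

    def test_inconsistent_universe_rejected(self):
        t1 = self._table(["p1", "p2"], {"p1"})
        t2 = self._table(["p1", "p3"], {"p1"})
        with pytest.raises(ValueError, match="universe"):
            categorize_sharing({"A": t1, "B": t2})


class TestFisher:
    def test_two_sided_p_matches_hypergeometric_enumeration(self):
        """Table (10, 10, 10, 970): sum hypergeometric point masses <= the
        observed one (the two-sided exact convention)."""
        a, b, c, d = 10, 10, 10, 970
        df = fisher_enrichment(
            hit_genes=set(range(20)),
            trait_gene_sets={"s": set(range(10)) | set(range(20, 30))},
            universe=set(range(1000)),
        )
        n_hit, n_trait, N = a + b, a + c, a + b + c + d
        rv = stats.hypergeom(N, n_trait, n_hit)
        p_obs = rv.pmf(a)
        p_ref = sum(
            rv.pmf(k)
            for k in range(max(0, n_hit + n_trait - N), min(n_hit, n_trait) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert df["p_value"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_everything_overlaps(self):
        genes = set(range(10))
        df = fisher_enrichment(genes, {"s": genes}, genes)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_sets_deplete(self):
        universe = set(range(1000))
        df = fisher_enrichment(
            set(range(100)), {"s": set(range(100, 200))}, universe
        )
        assert df["odds_ratio"].iloc[0] < 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(set(), {"s": set()}, set())
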