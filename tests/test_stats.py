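import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cargoscreen import (
    CountMatrix,
    call_hits,
    dedupe_gene_sets,
    median_ratio_normalize,
    rra_gene_pvalues,
    rra_rho,
    sgrna_test,
)
from cargoscreen.stats import fit_dispersion, nb_tail, ranked_hits


def brute_force_rho(u_sorted, k_prime=None):
    """Independent oracle: direct binomial-tail summation."""
    k = len(u_sorted)
    kp = k if k_prime is None else k_prime
    best = math.inf
    for j in range(1, kp + 1):
        u = u_sorted[j - 1]
        tail = sum(math.comb(k, m) * u**m * (1 - u) ** (k - m)
                   for m in range(j, k + 1))
        best = min(best, tail)
    return best


class TestNormalization:
    def test_depth_rescaling_invariance(self, tiny_counts):
        """Rescaling per-sample depths leaves the normalized profile
        unchanged up to one common scalar (the absolute count scale is
        not identifiable from relative abundances)."""
        norm1 = median_ratio_normalize(tiny_counts)
        scaled = tiny_counts.counts.copy()
        for i, col in enumerate(scaled.columns):
            scaled[col] = scaled[col] * (i + 2)  # distinct per-sample depths
        norm2 = median_ratio_normalize(
            CountMatrix(scaled, tiny_counts.genes, tiny_counts.samples))
        ratio = (norm2.counts / norm1.counts).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])

    def test_one_sample_double_of_other(self, tiny_library):
        c = pd.DataFrame({"s1": [10, 20, 30, 40, 50, 60]},
                         index=tiny_library.guide_ids)
        c["s2"] = c["s1"] * 2
        genes = pd.Series(tiny_library.table["gene_id"].to_numpy(),
                          index=c.index)
        norm = median_ratio_normalize(CountMatrix(c, genes))
        pd.testing.assert_series_equal(norm.counts["s1"], norm.counts["s2"],
                                       check_names=False)

    def test_identical_samples_equal_factors(self, tiny_library):
        c = pd.DataFrame({"s1": [5, 5, 5, 5, 5, 5],
                          "s2": [5, 5, 5, 5, 5, 5]},
                         index=tiny_library.guide_ids)
        genes = pd.Series(tiny_library.table["gene_id"].to_numpy(),
                          index=c.index)
        norm = median_ratio_normalize(CountMatrix(c, genes))
        pd.testing.assert_frame_equal(norm.counts, c.astype(float))

    def test_five_guide_hand_computation(self):
        # direct evaluation of the size-factor formula on 5 guides
        c = pd.DataFrame({"s1": [10, 20, 30, 40, 50],
                          "s2": [20, 40, 60, 80, 100]},
                         index=[f"g{i}" for i in range(5)])
        g = np.exp(np.log(c.to_numpy()).mean(axis=1))
        factors = np.median(c.to_numpy() / g[:, None], axis=0)
        factors = factors / np.exp(np.log(factors).mean())
        genes = pd.Series(["A"] * 5, index=c.index)
        norm = median_ratio_normalize(CountMatrix(c, genes))
        expected = c.to_numpy() / factors
        np.testing.assert_allclose(norm.counts.to_numpy(), expected)

    def test_zero_guides_fall_back_to_totals(self, tiny_library):
        c = pd.DataFrame({"s1": [0, 1, 0, 2, 0, 3],
                          "s2": [1, 0, 2, 0, 3, 0]},
                         index=tiny_library.guide_ids)
        genes = pd.Series(tiny_library.table["gene_id"].to_numpy(),
                          index=c.index)
        norm = median_ratio_normalize(CountMatrix(c, genes))  # warns, works
        assert np.isfinite(norm.counts.to_numpy()).all()


class TestSgrnaTest:
    def test_poisson_tail_matches_brute_force(self):
        # phi=0 reduces to a Poisson tail; oracle: direct summation
        mu, x = 5.0, 10
        expected = 1 - sum(math.exp(-mu) * mu**i / math.factorial(i)
                           for i in range(x))
        assert nb_tail(x, mu, 0.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.03182805730620475)

    def test_nb_tail_matches_moment_parameterization(self):
        # variance check: mean mu, var mu + phi mu^2
        mu, phi = 50.0, 0.1
        r = 1 / phi
        d = sps.nbinom(r, r / (r + mu))
        assert d.mean() == pytest.approx(mu)
        assert d.var() == pytest.approx(mu + phi * mu**2)

    def test_zero_treatment_gives_p_near_one(self, tiny_counts):
        counts = tiny_counts.counts.copy()
        counts.loc["A1", ["low_r1", "low_r2"]] = 0
        cm = CountMatrix(counts, tiny_counts.genes, tiny_counts.samples)
        stats = sgrna_test(median_ratio_normalize(cm))
        assert stats.loc["A1", "p"] == pytest.approx(1.0)

    def test_ranks_are_permutation(self, tiny_counts):
        stats = sgrna_test(median_ratio_normalize(tiny_counts))
        M = len(stats)
        assert sorted(stats["rank"]) == list(range(1, M + 1))
        assert sorted(stats["u"]) == pytest.approx(
            [i / M for i in range(1, M + 1)])

    def test_guide_order_invariance(self, tiny_counts):
        stats1 = sgrna_test(median_ratio_normalize(tiny_counts))
        shuffled = CountMatrix(tiny_counts.counts.iloc[::-1],
                               tiny_counts.genes.iloc[::-1],
                               tiny_counts.samples)
        stats2 = sgrna_test(median_ratio_normalize(shuffled))
        pd.testing.assert_frame_equal(stats1, stats2.sort_index()
                                      .reindex(stats1.index))

    def test_dispersion_fit_recovers_planted_phi(self, default_screen):
        _, cm, _ = default_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        assert stats.attrs["dispersion"] == pytest.approx(0.05, abs=0.03)

    def test_single_control_uses_prior(self, tiny_counts):
        samples = tiny_counts.samples[
            tiny_counts.samples["sample"] != "high_r2"]
        cm = CountMatrix(tiny_counts.counts.drop(columns="high_r2"),
                         tiny_counts.genes, samples)
        stats = sgrna_test(median_ratio_normalize(cm), prior_dispersion=0.07)
        assert stats.attrs["dispersion"] == 0.07


class TestRraRho:
    def test_single_guide_identity(self):
        assert rra_rho([0.2]) == pytest.approx(0.2)

    def test_three_guide_example(self):
        # P = (1-0.99^3, 0.5, 0.729); rho = 0.029701
        rho = rra_rho([0.01, 0.5, 0.9], 3)
        assert rho == pytest.approx(0.029701, rel=1e-9)

    def test_matches_brute_force_on_grid_k_le_5(self):
        """rho equals the exhaustive binomial-tail oracle for all k <= 5
        over the 1/20 rank grid."""
        grid = [i / 20 for i in range(1, 21)]
        rng = np.random.default_rng(0)
        for k in range(1, 6):
            for _ in range(60):
                u = np.sort(rng.choice(grid, size=k, replace=True))
                for kp in range(1, k + 1):
                    assert rra_rho(u, kp) == pytest.approx(
                        brute_force_rho(list(u), kp), rel=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=6),
           st.integers(0, 5), st.data())
    def test_monotone_in_ranks(self, u, idx, data):
        """Decreasing any u_(j) cannot increase rho."""
        u = sorted(u)
        i = idx % len(u)
        smaller = u.copy()
        smaller[i] = data.draw(st.floats(0.0005, u[i]))
        smaller = sorted(smaller)
        assert rra_rho(smaller) <= rra_rho(u) + 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rra_rho([0.5, 0.2])  # not ascending
        with pytest.raises(ValueError):
            rra_rho([0.0, 0.5])  # rank must be > 0
        with pytest.raises(ValueError):
            rra_rho([0.5], k_prime=2)


@pytest.fixture(scope="module")
def gene_table(default_screen):
    library, cm, _ = default_screen
    stats = sgrna_test(median_ratio_normalize(cm))
    return rra_gene_pvalues(stats, library, alpha=0.05, B=2000, seed=5)


class TestRraGenePvalues:
    def test_p_floor_and_range(self, gene_table):
        assert (gene_table["p"] >= 1 / 2001).all()
        assert (gene_table["p"] <= 1).all()
        assert ((gene_table["rho"] > 0) & (gene_table["rho"] <= 1)).all()

    def test_guides_near_rank_one_give_p_near_one(self, default_screen):
        library, cm, _ = default_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        # worst-ranked gene set: all u near 1
        worst = (stats.groupby(stats["gene"])["u"].min()).idxmax()
        table = rra_gene_pvalues(stats, library, alpha=0.05, B=500, seed=1)
        sub = table[table["gene"] == worst]
        assert (sub["p"] > 0.5).all()

    def test_unknown_gene_raises(self, default_screen, tiny_library):
        library, cm, _ = default_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        with pytest.raises(KeyError, match="absent"):
            rra_gene_pvalues(stats, tiny_library, B=200)

    def test_bh_preserves_p_ordering(self, gene_table):
        t = gene_table.sort_values("p")
        assert t["q"].is_monotonic_increasing
        assert (t["q"] >= t["p"] - 1e-12).all()

    def test_permutation_count_consistency(self, default_screen):
        """p-values agree within 3 Monte-Carlo SEs across B."""
        library, cm, _ = default_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        t1 = rra_gene_pvalues(stats, library, B=1000, seed=1)
        t2 = rra_gene_pvalues(stats, library, B=8000, seed=2)
        m = t1.merge(t2, on=["gene", "guide_set"], suffixes=("_1", "_2"))
        p = m["p_2"]
        se = np.sqrt(p * (1 - p) / 1000) + 1e-3
        frac_ok = (np.abs(m["p_1"] - m["p_2"]) <= 3 * se).mean()
        assert frac_ok > 0.95

    def test_permutation_p_uniform_under_null(self, null_screen):
        library, cm, _ = null_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        table = rra_gene_pvalues(stats, library, alpha=1.0, B=1000, seed=3)
        ks = sps.kstest(table["p"], "uniform").statistic
        assert ks < 0.05


class TestDedupeAndHits:
    def _table(self):
        return pd.DataFrame({
            "gene": ["TP53", "TP53", "KRAS"],
            "guide_set": ["set1", "set2", "set1"],
            "k": [5, 5, 5], "k_prime": [3, 1, 2],
            "rho": [1e-4, 0.3, 0.01],
            "p": [0.001, 0.2, 0.05],
            "q": [0.01, 0.4, 0.1],
            "rank": [1, 3, 2],
        })

    def test_higher_ranking_set_kept(self):
        out = dedupe_gene_sets(self._table())
        assert len(out) == 2
        tp53 = out[out["gene"] == "TP53"].iloc[0]
        assert tp53["p"] == 0.001 and tp53["guide_set"] == "set1"

    def test_single_set_gene_unchanged(self):
        out = dedupe_gene_sets(self._table())
        kras = out[out["gene"] == "KRAS"].iloc[0]
        assert kras["p"] == 0.05

    def test_tie_broken_by_rho_then_set_tag(self):
        t = self._table()
        t.loc[1, "p"] = 0.001  # tie on p
        out = dedupe_gene_sets(t)
        assert out[out["gene"] == "TP53"].iloc[0]["guide_set"] == "set1"

    def test_one_row_per_gene_on_synthetic_library(self, default_screen):
        library, cm, _ = default_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        table = rra_gene_pvalues(stats, library, B=300, seed=2)
        assert len(table) > len(library.genes)  # second sets present
        out = dedupe_gene_sets(table)
        assert len(out) == len(library.genes)
        assert out["gene"].is_unique

    def test_hit_threshold_one_returns_all(self):
        out = dedupe_gene_sets(self._table())
        assert call_hits(out, 1.0) == {"TP53", "KRAS"}

    def test_threshold_below_floor_empty(self, gene_table):
        out = dedupe_gene_sets(gene_table)
        assert call_hits(out, 1 / 5000) == set()

    def test_hit_sets_monotone_in_threshold(self, gene_table):
        out = dedupe_gene_sets(gene_table)
        prev = set()
        for thr in (0.001, 0.01, 0.05, 0.2, 1.0):
            cur = call_hits(out, thr)
            assert prev <= cur
            prev = cur

    def test_ranked_export_has_neg_log10(self):
        out = ranked_hits(dedupe_gene_sets(self._table()), 0.06)
        assert list(out["gene"]) == ["TP53", "KRAS"]
        assert out["neg_log10_p"].iloc[0] == pytest.approx(3.0)


class TestRecovery:
    def test_planted_genes_recovered(self, default_screen):
        """On the default scenario, hit calling at p<0.01 attains
        sensitivity >= 0.8 for the planted required genes."""
        library, cm, truth = default_screen
        stats = sgrna_test(median_ratio_normalize(cm))
        table = dedupe_gene_sets(
            rra_gene_pvalues(stats, library, alpha=0.05, B=2000, seed=7))
        hits = call_hits(table, 0.01)
        required = set(truth.required_genes)
        sensitivity = len(hits & required) / len(required)
        assert sensitivity >= 0.8
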