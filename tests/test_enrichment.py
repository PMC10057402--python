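"""Gene-set analysis: hand-walked running sums, exhaustive ES oracle,
combinatorial ORA checks, activation z-score formula, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from toxpotency.datatypes import GeneSetCollection
from toxpotency.enrichment import (
    activation_z,
    gsea_es,
    gsea_nes,
    ora_fisher,
    rank_genes,
    surface_area_correlation,
)


def es_oracle(scores, hits, weight=1.0):
    """Straightforward running-sum walk (independent of the library
    vectorization)."""
    nh = hits.sum()
    w = np.abs(scores) ** weight
    tot = w[hits].sum()
    if tot <= 0:
        w = np.ones_like(w)
        tot = float(nh)
    run, best = 0.0, 0.0
    for s, h, wi in zip(scores, hits, w):
        run += wi / tot if h else -1.0 / (len(scores) - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestRankGenes:
    def _table(self, stats_, dirs, ps=None):
        genes = [f"g{i}" for i in range(len(stats_))]
        return pd.DataFrame(
            {
                "stat": stats_,
                "direction": dirs,
                "p": ps if ps is not None else np.linspace(0.01, 0.5, len(stats_)),
                "fold_change": np.asarray(dirs, float) * 2.0,
            },
            index=genes,
        )

    def test_strict_ordering(self):
        t = self._table([3.0, 1.0, 2.0], [1, -1, 1])
        ranked = rank_genes(t)
        assert list(ranked.index) == ["g0", "g2", "g1"]
        assert ranked.iloc[-1] < 0

    def test_tie_break_by_gene_id_stable(self):
        t = self._table([2.0, 2.0, 2.0], [1, 1, 1])
        r1, r2 = rank_genes(t), rank_genes(t.iloc[::-1])
        assert list(r1.index) == list(r2.index) == ["g0", "g1", "g2"]

    def test_signed_logp_rank_equivalent_on_monotone_p(self):
        """When p decreases monotonically with |stat|, both metrics give
        the same ordering."""
        stats_ = [5.0, 4.0, 3.0, 2.0, 1.0]
        ps = [0.001, 0.01, 0.05, 0.2, 0.5]
        t = self._table(stats_, [1, 1, -1, -1, 1], ps)
        assert list(rank_genes(t, "signed_stat").index) == list(
            rank_genes(t, "signed_logp").index
        )

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rank_genes(pd.DataFrame({"stat": [1.0]}, index=["g"]))


class TestGseaEs:
    def _ranked(self, n=10):
        return pd.Series(np.linspace(3.0, 0.5, n), index=[f"g{i}" for i in range(n)])

    def test_top_block_maximal(self):
        es, _ = gsea_es(self._ranked(), ["g0", "g1"])
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_bottom_block_symmetric_to_reversed(self):
        ranked = self._ranked()
        es_bottom, _ = gsea_es(ranked, ["g8", "g9"])
        rev = ranked.iloc[::-1]
        es_rev, _ = gsea_es(rev.sort_values(ascending=False), ["g8", "g9"])
        assert es_bottom < 0

    def test_hand_walked_running_sum(self):
        """3-gene set at ranks 2, 5, 9 of a 10-gene list: compare every
        step of the running sum with a hand-built table."""
        scores = np.array([5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.8, 0.5, 0.2])
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(10)])
        members = ["g1", "g4", "g8"]  # ranks 2, 5, 9 (1-based)
        es, rs = gsea_es(ranked, members)
        tot = 4.0 + 2.0 + 0.5
        expect, run = [], 0.0
        for i in range(10):
            if f"g{i}" in members:
                run += scores[i] / tot
            else:
                run -= 1.0 / 7.0
            expect.append(run)
        assert np.allclose(rs, expect, atol=1e-12)
        assert es == pytest.approx(expect[np.argmax(np.abs(expect))])

    def test_set_equal_universe_rejected(self):
        with pytest.raises(ValueError):
            gsea_es(self._ranked(3), ["g0", "g1", "g2"])

    def test_reversing_list_negates_es(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.normal(0, 1, 12))[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(12)])
        flipped = pd.Series(-scores[::-1], index=ranked.index[::-1])
        for members in (["g0", "g3"], ["g5", "g6", "g11"]):
            es1, _ = gsea_es(ranked, members)
            es2, _ = gsea_es(flipped, members)
            assert es1 == pytest.approx(-es2, abs=1e-12)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_walk_oracle_exhaustively(self, data):
        n = data.draw(st.integers(3, 12))
        scores = np.array(
            data.draw(st.lists(st.floats(0.01, 5), min_size=n, max_size=n))
        )
        scores = np.sort(scores)[::-1]
        m = data.draw(st.integers(1, min(4, n - 1)))
        members = data.draw(
            st.lists(st.integers(0, n - 1), min_size=m, max_size=m, unique=True)
        )
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(n)])
        hits = np.zeros(n, bool)
        hits[members] = True
        es, _ = gsea_es(ranked, [f"g{i}" for i in members])
        assert es == pytest.approx(es_oracle(scores, hits), abs=1e-12)


class TestGseaNes:
    def _null_ranked(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, n)
        return pd.Series(
            np.sort(scores)[::-1], index=[f"g{i}" for i in range(n)]
        )

    def test_nes_sign_matches_es_sign(self):
        ranked = self._null_ranked(200, 1)
        sets = {f"s{i}": [f"g{j}" for j in range(i * 7, i * 7 + 6)] for i in range(10)}
        res = gsea_nes(ranked, sets, nperm=200, seed=3)
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()

    def test_type_i_error_near_nominal(self):
        """Null scores, 200 random sets: the p <= 0.05 fraction lands
        near 0.05."""
        rng = np.random.default_rng(7)
        ranked = self._null_ranked(800, 5)
        genes = list(ranked.index)
        sets = {
            f"s{i}": list(rng.choice(genes, size=rng.integers(8, 25), replace=False))
            for i in range(200)
        }
        res = gsea_nes(ranked, sets, nperm=1000, seed=11)
        rate = float((res["p"] <= 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_planted_top_set_positive_and_significant(self):
        hits = 0
        for seed in range(30):
            ranked = self._null_ranked(300, 100 + seed)
            members = list(ranked.index[:12])  # top-loaded set
            res = gsea_nes(ranked, {"planted": members}, nperm=300, seed=seed)
            hits += bool(res.loc["planted", "nes"] > 0 and res.loc["planted", "p"] <= 0.05)
        assert hits >= 29

    def test_small_sets_skipped(self):
        ranked = self._null_ranked(50, 2)
        res = gsea_nes(ranked, {"tiny": ["g0", "g1"]}, nperm=100, seed=0)
        assert len(res) == 0


class TestOraFisher:
    def test_zero_overlap_not_perturbed(self):
        uni = [f"u{i}" for i in range(20)]
        r = ora_fisher(uni[:5], uni, uni[10:15])
        assert r["overlap"] == 0 and not r["perturbed"]

    def test_full_overlap_combinatorial_oracle(self):
        uni = [f"u{i}" for i in range(20)]
        r = ora_fisher(uni[:5], uni, uni[:5])
        assert r["p"] == pytest.approx(1.0 / 15504.0)
        assert not r["perturbed"]  # overlap 5 is not > 5

    def test_boundary_rule_conventions(self):
        # overlap 6 with -log10 p >= 1.3 -> perturbed
        uni = [f"u{i}" for i in range(40)]
        r = ora_fisher(uni[:8], uni, uni[:10])
        assert r["overlap"] == 8
        if r["neglog10p"] >= 1.3:
            assert r["perturbed"]

    def test_matches_exact_enumeration(self):
        """Hypergeometric tail vs explicit pmf summation for every
        overlap in a small universe."""
        rng = np.random.default_rng(3)
        uni = [f"u{i}" for i in range(25)]
        for _ in range(20):
            k_set = rng.integers(1, 12)
            k_deg = rng.integers(1, 12)
            members = list(rng.choice(uni, size=k_set, replace=False))
            degs = list(rng.choice(uni, size=k_deg, replace=False))
            r = ora_fisher(degs, uni, members)
            from math import comb

            n, K, nd = 25, k_set, k_deg
            exact = sum(
                comb(K, x) * comb(n - K, nd - x) / comb(n, nd)
                for x in range(r["overlap"], min(K, nd) + 1)
            )
            assert r["p"] == pytest.approx(exact, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_fisher([], [], ["a"])


class TestActivationZ:
    def test_all_concordant(self):
        degs = {f"g{i}": 1 for i in range(16)}
        r = activation_z(degs, {f"g{i}": 1 for i in range(16)})
        assert r["z"] == pytest.approx(4.0) and r["state"] == "activated"

    def test_balanced_zero(self):
        degs = {f"g{i}": (1 if i < 8 else -1) for i in range(16)}
        r = activation_z(degs, {f"g{i}": 1 for i in range(16)})
        assert r["z"] == pytest.approx(0.0) and r["state"] == "no_call"

    def test_formula_oracle(self):
        degs = {f"g{i}": (1 if i < 10 else -1) for i in range(12)}
        r = activation_z(degs, {f"g{i}": 1 for i in range(12)})
        assert r["z"] == pytest.approx(8.0 / np.sqrt(12.0))
        assert r["state"] == "activated"

    def test_no_overlap_no_activity_pattern(self):
        r = activation_z({"a": 1}, {"b": 1})
        assert r["z"] is None and r["state"] == "no_activity_pattern"


class TestSurfaceAreaCorrelation:
    def _frame(self, values):
        rows = []
        for (e, d), v in values.items():
            rows.append({"exposure": e, "dose": d, "value": v})
        return pd.DataFrame(rows)

    def test_monotone_in_deposited_area_gives_rho_one(self):
        bet = {"A": 100.0, "B": 400.0}
        vals = {("A", 6): 1.0, ("A", 18): 2.0, ("A", 54): 4.0, ("B", 6): 3.0, ("B", 18): 5.0, ("B", 54): 6.0}
        rho, _ = surface_area_correlation(self._frame(vals), bet)
        assert rho == pytest.approx(1.0)

    def test_ties_match_midrank_formula(self):
        bet = {"A": 10.0}
        vals = {("A", 1): 1.0, ("A", 2): 2.0, ("A", 3): 2.0, ("A", 4): 3.0, ("A", 5): 5.0}
        rho, _ = surface_area_correlation(self._frame(vals), bet)
        x = np.array([10, 20, 30, 40, 50], float)
        y = np.array([1, 2, 2, 3, 5], float)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual, rel=1e-12)

    def test_null_p_uniform_over_seeds(self):
        bet = {"A": 50.0, "B": 200.0}
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            vals = {
                (e, d): rng.normal() for e in "AB" for d in (6.0, 18.0, 54.0)
            }
            _, p = surface_area_correlation(self._frame(vals), bet)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_bet_rejected(self):
        with pytest.raises(ValueError, match="BET"):
            surface_area_correlation(self._frame({("A", 6): 1.0, ("A", 18): 2.0, ("A", 54): 3.0}), {})
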