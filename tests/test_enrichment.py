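"""Ranking metric, GSEA enrichment score and permutation null, signatures."""

import math

import numpy as np
import pandas as pd
import pytest

from chemreprog.enrichment import (build_signature, enrichment_score,
                                   gsea_preranked, rank_genes, ranking_metric,
                                   read_gmt, signature_association,
                                   signature_correlation, write_gmt)
from chemreprog.errors import ValidationError


def oracle_es(metrics, hit_mask, weight=1.0):
    """Literal position-by-position running sum (the textbook definition)."""
    n = len(metrics)
    m = hit_mask.sum()
    w = np.abs(metrics) ** weight if weight != 0 else np.ones(n)
    nr = w[hit_mask].sum()
    running, best = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            running += (w[i] / nr) if nr > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best


class TestRankingMetric:
    def test_positive_lfc(self):
        assert ranking_metric(0.001, 2.0) == pytest.approx(3.0)

    def test_zero_lfc_gives_zero(self):
        assert ranking_metric(1e-10, 0.0) == pytest.approx(0.0)

    def test_negative_lfc(self):
        assert ranking_metric(0.05, -1.0) == pytest.approx(-1.3010, abs=1e-4)

    def test_floor_keeps_metric_finite(self):
        assert math.isfinite(ranking_metric(1e-320, 1.0))

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValidationError):
            ranking_metric(0.0, 1.0)


def test_rank_genes_descending_with_id_tiebreak():
    de = pd.DataFrame({"pv": [0.01, 0.01, 0.5], "lfc": [1.0, 1.0, -2.0]},
                      index=["b", "a", "c"])
    ranked = rank_genes(de)
    assert list(ranked.index) == ["a", "b", "c"]  # ties by identifier
    assert ranked.is_monotonic_decreasing


class TestEnrichmentScore:
    def test_set_on_top_with_positive_metrics_gives_one(self):
        metrics = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        hits = np.array([True, True, True, False, False, False])
        assert enrichment_score(metrics, hits) == pytest.approx(1.0)

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 50))
            metrics = np.sort(rng.normal(0, 2, n))[::-1]
            m = int(rng.integers(2, n - 1))
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, m, replace=False)] = True
            assert enrichment_score(metrics, hits) == \
                pytest.approx(oracle_es(metrics, hits), abs=1e-12)

    def test_invariant_under_positive_rescaling(self, rng):
        n = 30
        metrics = np.sort(rng.normal(0, 1, n))[::-1]
        hits = np.zeros(n, dtype=bool)
        hits[[2, 7, 11, 20]] = True
        assert enrichment_score(metrics * 7.3, hits) == \
            pytest.approx(enrichment_score(metrics, hits), abs=1e-12)

    def test_negating_and_reversing_negates_es(self, rng):
        n = 30
        metrics = np.sort(rng.normal(0, 1, n))[::-1]
        hits = np.zeros(n, dtype=bool)
        hits[[1, 5, 12, 18, 25]] = True
        forward = enrichment_score(metrics, hits)
        backward = enrichment_score(-metrics[::-1], hits[::-1])
        assert backward == pytest.approx(-forward, abs=1e-12)

    def test_weight_zero_equals_ks_statistic(self, rng):
        n = 40
        metrics = np.sort(rng.normal(0, 1, n))[::-1]
        m = 8
        hits = np.zeros(n, dtype=bool)
        hits[rng.choice(n, m, replace=False)] = True
        es = enrichment_score(metrics, hits, weight=0.0)
        # KS oracle: max signed difference between the hit and miss ECDFs
        hit_pos = np.flatnonzero(hits)
        diffs = []
        running = 0.0
        for i in range(n):
            running += 1.0 / m if hits[i] else -1.0 / (n - m)
            diffs.append(running)
        oracle = diffs[int(np.argmax(np.abs(diffs)))]
        assert es == pytest.approx(oracle, abs=1e-12)


class TestGseaPreranked:
    @staticmethod
    def _ranked(n=40, seed=2):
        rng = np.random.default_rng(seed)
        metrics = np.sort(rng.normal(0, 2, n))[::-1]
        return pd.Series(metrics, index=[f"g{i:03d}" for i in range(n)])

    def test_bit_identical_under_fixed_seed(self):
        ranked = self._ranked()
        sets = {"top": set(ranked.index[:8]), "mid": set(ranked.index[15:25])}
        a = gsea_preranked(ranked, sets, n_perm=500, seed=42)
        b = gsea_preranked(ranked, sets, n_perm=500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_self_enriched_set_is_significant(self):
        ranked = self._ranked()
        res = gsea_preranked(ranked, {"top": set(ranked.index[:8])},
                             n_perm=1000, seed=1)
        row = res.iloc[0]
        assert row["es"] == pytest.approx(1.0)
        assert row["nes"] > 1.0
        assert row["p_value"] < 0.01

    def test_nes_sign_matches_es_sign(self):
        ranked = self._ranked(60)
        sets = {f"s{i}": set(ranked.index[i * 6:(i + 1) * 6 + 3])
                for i in range(8)}
        res = gsea_preranked(ranked, sets, n_perm=300, seed=3)
        ok = res["es"].notna()
        assert np.all(np.sign(res.loc[ok, "nes"]) == np.sign(res.loc[ok, "es"]))

    def test_disjoint_set_gets_error_record(self):
        ranked = self._ranked()
        res = gsea_preranked(ranked, {"alien": {"x", "y", "z"},
                                      "top": set(ranked.index[:8])},
                             n_perm=200, seed=1)
        alien = res[res["set"] == "alien"].iloc[0]
        assert alien["error"] != "" and math.isnan(alien["es"])
        assert res[res["set"] == "top"].iloc[0]["error"] == ""

    def test_permutation_p_stable_across_seeds(self):
        ranked = self._ranked(200, seed=8)
        target = set(ranked.index[8:40:2])
        ps = [gsea_preranked(ranked, {"s": target}, n_perm=2000,
                             seed=s).iloc[0]["p_value"] for s in range(5)]
        pbar = float(np.mean(ps))
        se = math.sqrt(max(pbar * (1 - pbar), 1e-6) / 2000)
        assert max(abs(p - pbar) for p in ps) <= 3 * se + 1e-3


class TestSignatures:
    def test_fewer_significant_than_n(self):
        de = pd.DataFrame({"lfc": [2.0, -1.0, 0.5], "pv": [0.001] * 3,
                           "fdr": [0.01, 0.01, 0.8]}, index=list("abc"))
        assert build_signature(de, n=500) == {"a", "b"}

    def test_top_n_by_absolute_lfc(self, rng):
        n_genes = 1000
        de = pd.DataFrame({
            "lfc": rng.normal(0, 2, n_genes),
            "pv": np.full(n_genes, 1e-4),
            "fdr": np.full(n_genes, 1e-3),
        }, index=[f"g{i:04d}" for i in range(n_genes)])
        sig = build_signature(de, n=500)
        assert len(sig) == 500
        cut = de.loc[list(sig), "lfc"].abs().min()
        excluded = de.drop(index=list(sig))
        assert (excluded["lfc"].abs() <= cut + 1e-12).all()

    def test_no_significant_genes_empty(self):
        de = pd.DataFrame({"lfc": [1.0], "pv": [0.5], "fdr": [0.9]}, index=["a"])
        assert build_signature(de) == set()

    def test_split_partitions_by_sign(self):
        de = pd.DataFrame({"lfc": [2.0, -3.0], "pv": [1e-3] * 2,
                           "fdr": [1e-2] * 2}, index=["up1", "dn1"])
        up, down = build_signature(de, split=True)
        assert up == {"up1"} and down == {"dn1"}


class TestSignatureCorrelation:
    @staticmethod
    def _de(rng, n=300):
        return pd.DataFrame({"lfc": rng.normal(0, 1, n),
                             "pv": rng.uniform(0, 1, n)},
                            index=[f"g{i:04d}" for i in range(n)])

    def test_self_correlation_is_one(self, rng):
        de = self._de(rng)
        assert signature_correlation(de, de, n=100) == pytest.approx(1.0)

    def test_negated_lfc_gives_minus_one(self, rng):
        de = self._de(rng)
        neg = de.copy()
        neg["lfc"] = -neg["lfc"]
        assert signature_correlation(de, neg, n=100) == pytest.approx(-1.0)

    def test_matches_explicit_union_oracle(self, rng):
        from scipy import stats as sps
        a, b = self._de(rng), self._de(rng)
        n = 80
        top_a = a["pv"].nsmallest(n).index
        top_b = b["pv"].nsmallest(n).index
        union = sorted(set(top_a) | set(top_b))
        oracle = sps.spearmanr(a.loc[union, "lfc"], b.loc[union, "lfc"]).statistic
        assert signature_correlation(a, b, n=n) == pytest.approx(oracle, rel=1e-10)


def test_signature_association_self_enrichment(rng):
    n = 400
    de = pd.DataFrame({"lfc": rng.normal(0, 1, n), "pv": rng.uniform(0, 1, n)},
                      index=[f"g{i:04d}" for i in range(n)])
    # inject a strongly up-regulated block
    up_genes = de.index[:30]
    de.loc[up_genes, "lfc"] = 2.0
    de.loc[up_genes, "pv"] = 1e-6
    de["fdr"] = de["pv"]
    res = signature_association({"cond": de}, {"injected": set(up_genes)},
                                n_perm=500, seed=4)
    row = res.iloc[0]
    assert row["nes"] > 0 and row["fdr"] < 0.05 and row["stars"] != ""


def test_gmt_roundtrip(tmp_path):
    sets = {"alpha": {"g1", "g2"}, "beta": {"g3", "g4", "g5"}}
    p = tmp_path / "sets.gmt"
    write_gmt(sets, p)
    assert read_gmt(p) == sets
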