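"""Enrichment score, corGSEA permutation machinery, and over-representation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from coexpr.errors import AnalysisError, GmtError
from coexpr.gsea import (
    GeneSetCollection,
    corgsea,
    enrichment_score,
    over_representation,
    read_gmt,
)
from coexpr.store import CorrelationVector


def ks_oracle(is_hit):
    """Classic unweighted KS statistic: signed extremum of P_hit - P_miss.

    Exact ties in magnitude keep the earliest position (the tolerance guards
    against rounding noise promoting a mathematically tied later value).
    """
    N, m = len(is_hit), int(sum(is_hit))
    best, hits = 0.0, 0
    for i in range(N):
        hits += is_hit[i]
        dev = hits / m - (i + 1 - hits) / (N - m)
        if abs(dev) > abs(best) + 1e-12:
            best = dev
    return best


def running_sum_oracle(scores, is_hit, p):
    """Literal enumeration of the weighted running sum; first-extremum ties."""
    N, m = len(scores), int(sum(is_hit))
    tot = sum(abs(scores[i]) ** p for i in range(N) if is_hit[i])
    run, best = 0.0, 0.0
    for i in range(N):
        if is_hit[i]:
            run += abs(scores[i]) ** p / tot
        else:
            run -= 1.0 / (N - m)
        if abs(run) > abs(best) + 1e-12:
            best = run
    return best


class TestEnrichmentScore:
    def test_top_block_and_interleaved_placements(self):
        # members at ranks 1..m with equal scores peak at exactly 1
        scores = np.linspace(1.0, 1.0, 10)
        hit = np.zeros(10, dtype=bool)
        hit[:2] = True
        assert enrichment_score(scores, hit)[0] == pytest.approx(1.0)
        # one miss between consecutive hits: peak 1 - (m-1)/(N-m) = 0.875
        hit = np.zeros(10, dtype=bool)
        hit[[0, 2]] = True
        assert enrichment_score(scores, hit)[0] == pytest.approx(0.875)

    def test_matches_ks_oracle_at_exponent_zero(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 51))
            m = int(rng.integers(1, min(10, N - 1) + 1))
            scores = np.sort(rng.normal(size=N))[::-1]
            hit = np.zeros(N, dtype=bool)
            hit[rng.choice(N, size=m, replace=False)] = True
            es, _ = enrichment_score(scores, hit, weight_exponent=0.0)
            assert es == pytest.approx(ks_oracle(hit.tolist()), abs=1e-12)

    def test_matches_running_sum_enumeration_at_exponent_one(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 51))
            m = int(rng.integers(1, min(10, N - 1) + 1))
            scores = np.sort(rng.normal(size=N))[::-1]
            hit = np.zeros(N, dtype=bool)
            hit[rng.choice(N, size=m, replace=False)] = True
            es, _ = enrichment_score(scores, hit, weight_exponent=1.0)
            assert es == pytest.approx(
                running_sum_oracle(scores.tolist(), hit.tolist(), 1.0), abs=1e-12
            )

    def test_monotone_transform_invariance_unweighted(self, rng):
        scores = np.sort(rng.normal(size=40))[::-1]
        hit = np.zeros(40, dtype=bool)
        hit[rng.choice(40, size=8, replace=False)] = True
        es1, _ = enrichment_score(scores, hit, weight_exponent=0.0)
        es2, _ = enrichment_score(np.exp(scores), hit, weight_exponent=0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_random_placement_centers_near_zero(self, rng):
        scores = np.sort(rng.normal(size=30))[::-1]
        vals = []
        for _ in range(2000):
            hit = np.zeros(30, dtype=bool)
            hit[rng.choice(30, size=5, replace=False)] = True
            vals.append(enrichment_score(scores, hit, weight_exponent=0.0)[0])
        assert abs(np.mean(vals)) < 0.05

    def test_whole_universe_set_rejected(self):
        with pytest.raises(AnalysisError, match="whole ranking"):
            enrichment_score(np.array([2.0, 1.0]), np.array([True, True]))

    def test_leading_edge_side(self):
        scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        hit = np.array([True, True, False, False, False, False])
        es, le = enrichment_score(scores, hit)
        assert es > 0 and list(le) == [0, 1]
        hit = np.array([False, False, False, False, True, True])
        es, le = enrichment_score(scores, hit)
        assert es < 0 and list(le) == [4, 5]


def make_vector(r, genes=None, query="QRY", n=60):
    genes = genes if genes is not None else np.array([f"G{i:04d}" for i in range(len(r))])
    return CorrelationVector(
        query_gene=query,
        tissue="bone",
        disease="cancer",
        genes=np.asarray(genes),
        r=np.asarray(r, dtype=float),
        p=np.zeros(len(r)),
        n=n,
    )


class TestCorgsea:
    def test_top_correlates_set_attains_minimum_p(self, strong_store, strong_truth):
        gene = strong_truth["modules"]["M01"]["genes"][0]
        vec = strong_store.get_vector(gene, ("bone", "cancer"))
        genes, _ = vec.ranked(drop_query=True)
        col = GeneSetCollection.from_dict({"TOP50": genes[:50]})
        out = corgsea(vec, col, n_perm=1000, seed=2)
        assert out["NES"].iloc[0] > 0
        assert out["pval"].iloc[0] == pytest.approx(1 / 1001)
        assert set(out["leading_edge"].iloc[0].split(",")) <= set(genes[:50])

    def test_mirrored_set_flips_sign(self, rng):
        r = np.sort(rng.normal(scale=0.3, size=501))[::-1]
        genes = np.array([f"G{i:04d}" for i in range(501)])
        vec = make_vector(r, genes, query=genes[250])
        top = genes[:30]
        bottom = genes[-30:]
        col = GeneSetCollection.from_dict({"TOP": top, "BOTTOM": bottom})
        out = corgsea(vec, col, n_perm=500, seed=4).set_index("set")
        assert out.loc["TOP", "ES"] > 0 > out.loc["BOTTOM", "ES"]
        assert abs(out.loc["TOP", "NES"]) == pytest.approx(
            abs(out.loc["BOTTOM", "NES"]), rel=0.5
        )

    def test_seed_determinism_and_no_zero_pvalues(self, strong_store):
        vec = strong_store.get_vector("G0100", ("bone", "normal"))
        genes, _ = vec.ranked(drop_query=True)
        col = GeneSetCollection.from_dict(
            {f"S{i}": genes[i * 20 : i * 20 + 20] for i in range(8)}
        )
        a = corgsea(vec, col, n_perm=300, seed=9)
        b = corgsea(vec, col, n_perm=300, seed=9)
        assert a.equals(b)
        assert (a["pval"] > 0).all()

    def test_bh_adjustment_monotone(self, strong_store):
        vec = strong_store.get_vector("G0200", ("bone", "normal"))
        genes, _ = vec.ranked(drop_query=True)
        col = GeneSetCollection.from_dict(
            {f"S{i}": genes[i * 25 : i * 25 + 25] for i in range(10)}
        )
        out = corgsea(vec, col, n_perm=200, seed=1).sort_values("pval")
        assert (out["padj"] >= out["pval"] - 1e-12).all()
        assert (np.diff(out["padj"]) >= -1e-12).all()

    def test_small_universe_rejected(self):
        vec = make_vector(np.linspace(1, -1, 50))
        with pytest.raises(AnalysisError, match=">= 100"):
            corgsea(vec, GeneSetCollection.from_dict({"S": ["G0001"]}))

    def test_out_of_bounds_sets_skipped_not_raised(self, strong_store):
        vec = strong_store.get_vector("G0300", ("bone", "normal"))
        col = GeneSetCollection.from_dict({"TINY": ["G0001", "G0002"]})
        with pytest.warns(UserWarning, match="size bounds"):
            out = corgsea(vec, col, n_perm=100, seed=0)
        assert len(out) == 0
        assert out.attrs["skipped"][0][0] == "TINY"


class TestOverRepresentation:
    def test_textbook_configuration(self):
        universe = [f"U{i}" for i in range(20)]
        col = GeneSetCollection.from_dict({"S": universe[:5]})
        query = universe[1:5] + [universe[10]]  # overlap 4 of 5
        out = over_representation(query, col, universe)
        assert out["overlap"].iloc[0] == 4
        assert out["pval"].iloc[0] == pytest.approx(76 / 15504, abs=1e-12)
        assert out["padj"].iloc[0] == out["pval"].iloc[0]  # single set: BH identity

    def test_query_equals_universe(self):
        universe = [f"U{i}" for i in range(8)]
        col = GeneSetCollection.from_dict({"S": universe})
        out = over_representation(universe, col, universe)
        assert out["overlap"].iloc[0] == 8
        assert out["pval"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            M = int(rng.integers(5, 26))
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            universe = [f"U{i}" for i in range(M)]
            s = list(rng.choice(universe, size=K, replace=False))
            q = list(rng.choice(universe, size=n, replace=False))
            x = len(set(s) & set(q))
            expected = sum(
                math.comb(K, i) * math.comb(M - K, n - i) / math.comb(M, n)
                for i in range(x, min(K, n) + 1)
            )
            out = over_representation(q, GeneSetCollection.from_dict({"S": s}), universe)
            assert out["pval"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_empty_query_after_intersection(self):
        with pytest.raises(AnalysisError, match="empty"):
            over_representation(["X"], GeneSetCollection.from_dict({"S": ["A"]}), ["A", "B"])


class TestGmt:
    def test_parse_and_dedup(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SETA\tdesc\ttp53\tBRCA1\tTP53\nSETB\t\tA\tB\tC\n")
        col = read_gmt(path)
        assert col.sets["SETA"] == frozenset({"TP53", "BRCA1"})
        assert len(col.sets["SETA"]) == 2
        assert col.descriptions["SETA"] == "desc"

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SETA\tdesc\tA\nONLY_NAME\n")
        with pytest.raises(GmtError, match=":2:"):
            read_gmt(path)

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S\td\tA\tB\nS\td\tC\tD\n")
        with pytest.raises(GmtError, match="duplicate"):
            read_gmt(path)


class TestCrossCheck:
    def test_es_agrees_with_independent_gsea_implementation(self):
        """Cross-check the weighted statistic against gseapy's prerank ES."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(42)
        genes = [f"G{i:03d}" for i in range(150)]
        scores = np.sort(rng.normal(size=150))[::-1]
        members = [genes[i] for i in rng.choice(150, size=20, replace=False)]
        import pandas as pd

        rnk = pd.DataFrame({"gene": genes, "score": scores}).set_index("gene")
        res = gseapy.prerank(
            rnk=rnk,
            gene_sets={"SET": members},
            permutation_num=5,
            min_size=2,
            max_size=500,
            weight=1.0,
            seed=1,
            threads=1,
            outdir=None,
            no_plot=True,
        ).res2d
        hit = np.isin(genes, members)
        ours, _ = enrichment_score(scores, hit, weight_exponent=1.0)
        assert ours == pytest.approx(float(res["ES"].iloc[0]), abs=1e-6)
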