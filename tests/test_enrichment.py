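"""Fisher over-representation, BH correction, and duplicate-ORF rules."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qhtcp.enrichment import (
    AnnotationSet,
    bh_correct,
    build_background,
    enrich_clusters,
    fisher_enrichment,
    report_enrichment,
    resolve_cluster_members,
)


def hypergeom_tail_oracle(a, n_bg, term_size, cluster_size):
    """Exact upper-tail P(X >= a) by rational hypergeometric summation."""
    total = comb(n_bg, cluster_size)
    s = sum(
        comb(term_size, i) * comb(n_bg - term_size, cluster_size - i)
        for i in range(a, min(term_size, cluster_size) + 1)
    )
    return float(Fraction(s, total))


def bh_stepup_oracle(p):
    """Direct q_i = min_{j>=i} p_(j) * m / j implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q = np.array([min(ps[j] * m / (j + 1) for j in range(i, m)) for i in range(m)])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def test_build_background_collapses_duplicates():
    assert build_background(["RAD9", "RAD9", "XRS2"]) == {"RAD9", "XRS2"}


def test_resolve_cluster_members_duplicate_rules():
    assignment = {
        "RAD9@arr01:1.1": 3,
        "RAD9@arr02:4.7": 7,     # same gene in a second cluster
        "XRS2@arr01:1.2": 3,
        "XRS2@arr01:9.9": 3,     # duplicated within one cluster
        "MRE11@arr01:2.2": 0,    # outside any cluster -> ignored
    }
    clusters = resolve_cluster_members(assignment)
    assert clusters[3] == {"RAD9", "XRS2"}
    assert clusters[7] == {"RAD9"}
    assert all("MRE11" not in genes for genes in clusters.values())


def test_fisher_matches_hypergeometric_oracle():
    """One-sided Fisher p equals the exact hypergeometric tail to 1e-10."""
    rng = np.random.default_rng(0)
    genes = [f"G{i:04d}" for i in range(2000)]
    for _ in range(150):
        n_bg = int(rng.integers(20, 2001))
        bg_genes = genes[:n_bg]
        term_size = int(rng.integers(1, n_bg + 1))
        cluster_size = int(rng.integers(1, min(n_bg, 60) + 1))
        a = int(rng.integers(0, min(term_size, cluster_size) + 1))
        term = set(bg_genes[:term_size])
        cluster = set(bg_genes[:a]) | set(bg_genes[term_size : term_size + cluster_size - a])
        res = fisher_enrichment(
            cluster, set(bg_genes), AnnotationSet(terms={"T": term}), min_term_size=1
        )
        a_eff = len(cluster & term)
        expected = hypergeom_tail_oracle(a_eff, n_bg, term_size, len(cluster))
        assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-10)


def test_fisher_trivial_tables():
    bg = {f"G{i}" for i in range(1000)}
    ordered = sorted(bg)
    ann = AnnotationSet(terms={"T": set(ordered[:20])})
    # term absent from cluster -> p = 1
    res = fisher_enrichment(set(ordered[100:110]), bg, ann)
    assert res["p"].iloc[0] == 1.0
    # cluster = background -> no enrichment possible
    res = fisher_enrichment(bg, bg, ann)
    assert res["p"].iloc[0] == 1.0
    # stated example: a=5 of cluster 10 vs term 20 in background 1000
    cluster = set(ordered[:5]) | set(ordered[500:505])
    res = fisher_enrichment(cluster, bg, ann)
    assert res["p"].iloc[0] == pytest.approx(
        hypergeom_tail_oracle(5, 1000, 20, 10), abs=1e-10
    )


def test_fisher_cluster_outside_background_named():
    bg = {"AAA", "BBB"}
    with pytest.raises(ValueError, match="ZZZ"):
        fisher_enrichment({"ZZZ"}, bg, AnnotationSet(terms={"T": {"AAA", "BBB"}}))


def test_bh_known_values():
    assert bh_correct([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_correct([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_array_equal(bh_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        bh_correct([0.5, 1.5])


def test_bh_matches_stepup_oracle_exactly():
    for i in range(200):
        rng = np.random.default_rng(i)
        p = rng.random(int(rng.integers(1, 80)))
        np.testing.assert_array_equal(bh_correct(p), bh_stepup_oracle(p))


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_monotone_in_p_rank(p):
    q = bh_correct(np.array(p))
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-15)
    assert np.all((q >= 0) & (q <= 1))


def test_report_enrichment_threshold_and_representative():
    results = pd.DataFrame(
        {
            "cluster": [1, 1, 1, 2],
            "term_id": ["T2", "T1", "T3", "T9"],
            "p": [1e-6, 1e-6, 0.5, 0.9],
            "q": [1e-4, 1e-4, 0.9, 0.9],
        }
    )
    reported = report_enrichment(results, q_threshold=0.005)
    assert set(reported["cluster"]) == {1}          # cluster 2 has nothing to report
    rep = reported[reported["representative"]]
    assert list(rep["term_id"]) == ["T1"]           # q tie -> alphabetical term id
    everything = report_enrichment(results, q_threshold=1.1)
    assert len(everything) == 4


def test_enrich_clusters_scopes():
    genes = [f"G{i:03d}" for i in range(200)]
    bg = set(genes)
    ann = AnnotationSet(
        terms={"T1": set(genes[:30]), "T2": set(genes[50:90]), "T3": set(genes[::7])}
    )
    clusters = {1: set(genes[:25]), 2: set(genes[100:120])}
    per = enrich_clusters(clusters, bg, ann, scope="per_cluster")
    glob = enrich_clusters(clusters, bg, ann, scope="global")
    assert set(per.columns) == set(glob.columns)
    pd.testing.assert_series_equal(per["p"], glob["p"])  # p unchanged by scope
    # planted overlap: T1 should dominate cluster 1
    top = per[per["cluster"] == 1].sort_values("q").iloc[0]
    assert top["term_id"] == "T1" and top["q"] < 1e-10
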