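"""Per-cluster GO-term over-representation testing.

Each cluster's gene list is tested against the screen background (the
unique gene deletions with high-quality data) with a one-sided Fisher's
exact test per term, followed by Benjamini-Hochberg false-discovery
control. The q < 0.005 reporting threshold and the duplicate-ORF rules
follow screen practice: duplicate deletions collapse to a single
background entry; a gene duplicated across clusters contributes to each
cluster's test list; within one cluster it counts once; duplicates outside
any cluster are ignored.

BH is applied per cluster by default (each cluster's tested terms form one
family, matching per-cluster reporting); a global family is available via
``scope="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

DEFAULT_Q_THRESHOLD = 0.005
MIN_TERM_SIZE = 2


@dataclass
class AnnotationSet:
    """term_id -> set of (uppercase) gene symbols, with optional metadata."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {
            t: {g.upper() for g in genes} for t, genes in self.terms.items() if genes
        }

    @classmethod
    def from_tsv(cls, path: str | Path, names_path: str | Path | None = None) -> "AnnotationSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"term_id", "gene"} <= set(df.columns):
            raise ValueError("annotation table needs columns term_id, gene")
        terms: dict[str, set[str]] = {}
        for t, g in zip(df["term_id"], df["gene"]):
            terms.setdefault(str(t), set()).add(str(g).upper())
        names = {}
        if names_path is not None:
            meta = pd.read_csv(names_path, sep="\t", comment="#")
            names = dict(zip(meta["term_id"].astype(str), meta["name"].astype(str)))
        return cls(terms=terms, names=names)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(t, g) for t in sorted(self.terms) for g in sorted(self.terms[t])]
        pd.DataFrame(rows, columns=["term_id", "gene"]).to_csv(path, sep="\t", index=False)


def build_background(entries: Iterable[str]) -> set[str]:
    """Unique gene symbols; duplicate ORF entries collapse to one member."""
    return {str(e).upper() for e in entries}


def resolve_cluster_members(
    assignment: Mapping[str, int] | pd.Series, entry_to_gene: Mapping[str, str] | None = None
) -> dict[int, set[str]]:
    """Per-cluster gene test lists applying the duplicate-ORF rules.

    ``assignment`` maps entries (spot lineages) to cluster labels;
    ``entry_to_gene`` maps entries to gene symbols (identity with an
    ``@``-suffix strip by default). A gene in several clusters is tested in
    each; within one cluster it counts once; entries without a cluster
    (label <= 0 or NaN) are ignored.
    """
    if isinstance(assignment, pd.Series):
        assignment = assignment.to_dict()
    clusters: dict[int, set[str]] = {}
    for entry, label in assignment.items():
        if label is None or (isinstance(label, float) and np.isnan(label)) or int(label) <= 0:
            continue
        gene = (
            entry_to_gene[entry]
            if entry_to_gene is not None
            else str(entry).split("@", 1)[0]
        )
        clusters.setdefault(int(label), set()).add(gene.upper())
    return clusters


def fisher_enrichment(
    cluster_genes: set[str],
    background: set[str],
    annotations: AnnotationSet,
    min_term_size: int = MIN_TERM_SIZE,
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided Fisher exact tests of a cluster against every term.

    The 2x2 table for a term is (a, b; c, d) with a = |cluster & term|,
    b = |cluster - term|, c = |(background & term) - cluster|, d the
    remainder. The one-sided (over-representation) p-value is the
    hypergeometric upper tail P(X >= a). Terms annotated to fewer than
    ``min_term_size`` background genes are skipped.
    """
    stray = cluster_genes - background
    if stray:
        raise ValueError(f"cluster gene(s) outside background: {sorted(stray)[:5]}")
    n_bg = len(background)
    n_cl = len(cluster_genes)
    rows = []
    for term_id in sorted(annotations.terms):
        term_bg = annotations.terms[term_id] & background
        m = len(term_bg)
        if m < min_term_size:
            continue
        a = len(cluster_genes & term_bg)
        b = n_cl - a
        c = m - a
        d = n_bg - n_cl - c
        if alternative == "greater":
            p = float(hypergeom.sf(a - 1, n_bg, m, n_cl))
        else:
            from scipy.stats import fisher_exact

            p = float(fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "term_id": term_id,
                "a": a,
                "cluster_size": n_cl,
                "term_size": m,
                "background_size": n_bg,
                "odds_ratio": odds,
                "p": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def bh_correct(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to [0, 1]; output in the
    input order, monotone non-decreasing in p-rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def enrich_clusters(
    clusters: Mapping[int, set[str]],
    background: set[str],
    annotations: AnnotationSet,
    scope: str = "per_cluster",
    min_term_size: int = MIN_TERM_SIZE,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher tests for every cluster with BH correction.

    ``scope`` ``"per_cluster"`` adjusts within each cluster's tested terms;
    ``"global"`` adjusts across all (cluster, term) tests jointly.
    """
    if scope not in ("per_cluster", "global"):
        raise ValueError("scope must be 'per_cluster' or 'global'")
    frames = []
    for label in sorted(clusters):
        res = fisher_enrichment(
            clusters[label], background, annotations, min_term_size, alternative
        )
        if res.empty:
            continue
        res.insert(0, "cluster", label)
        if scope == "per_cluster":
            res["q"] = bh_correct(res["p"].to_numpy())
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "term_id", "a", "cluster_size", "term_size",
                     "background_size", "odds_ratio", "p", "q"]
        )
    out = pd.concat(frames, ignore_index=True)
    if scope == "global":
        out["q"] = bh_correct(out["p"].to_numpy())
    return out


def report_enrichment(
    results: pd.DataFrame, q_threshold: float = DEFAULT_Q_THRESHOLD
) -> pd.DataFrame:
    """Reported subset: per cluster, terms with q < threshold, flagging the
    lowest-q term as the cluster's representative (ties alphabetical)."""
    if results.empty:
        out = results.copy()
        out["reported"] = pd.Series(dtype=bool)
        out["representative"] = pd.Series(dtype=bool)
        return out
    keep = results[results["q"] < q_threshold].copy()
    keep["reported"] = True
    keep["representative"] = False
    for label, grp in keep.groupby("cluster"):
        best = grp.sort_values(["q", "term_id"], kind="mergesort").index[0]
        keep.loc[best, "representative"] = True
    return keep.sort_values(["cluster", "q", "term_id"]).reset_index(drop=True)
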