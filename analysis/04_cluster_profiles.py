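#!/usr/bin/env python
"""Cluster interaction profiles and cut the tree at the BIC optimum.

Ward/Euclidean agglomeration over (adjK2, adjK3, adjL2, adjL3), scored
for k = 1..60 with the hard-assignment Gaussian BIC. Writes
results/clusters.tsv, results/bic_curve.tsv and results/cluster_report.tsv.
"""

from pathlib import Path

import numpy as np

from qhtcp import plate_io
from qhtcp.clustering import (
    bic_cut,
    build_profile_matrix,
    cluster_report,
    hierarchical_cluster,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = plate_io.read_table(ROOT / "interactions.tsv")
    matrix = build_profile_matrix(table)
    tree = hierarchical_cluster(matrix)
    assignment = bic_cut(tree, matrix)

    plate_io.write_table(
        assignment.labels.rename_axis("entry").reset_index(), ROOT / "clusters.tsv"
    )
    plate_io.write_table(assignment.bic_curve, ROOT / "bic_curve.tsv")
    report = cluster_report(assignment, matrix)
    plate_io.write_table(report, ROOT / "cluster_report.tsv")
    np.savetxt(ROOT / "tree.txt", assignment.tree, header="scipy linkage matrix")

    print(f"clustered {len(assignment.labels)} profiles "
          f"({len(matrix.dropped)} dropped for missingness)")
    print(f"BIC-optimal number of clusters: k = {assignment.k}")
    print("\nper-cluster summary (tendency from mean adjusted L at 20 ug/mL):")
    cols = ["cluster", "size", "tendency", "mean_adjK3", "mean_adjL3"]
    print(report[cols].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
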