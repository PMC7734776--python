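"""Meta-structure of the cluster centres: non-metric MDS + grouping.

The RMSD submatrix over the top cluster centres is embedded into two
dimensions by non-metric MDS (Kruskal stress-1 with isotonic
disparities); centres whose conformations are similar land close
together.  Single-linkage components at a distance threshold replace the
by-eye circling of nearby centres, and the per-system residence time in
each meta-cluster is accounted, including an explicit "unassigned"
remainder for frames outside the embedded top clusters.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from loopconf.cluster import Cluster, Clustering
from loopconf.ordination import group_metaclusters, metacluster_occupancy, nonmetric_mds

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 1234
TOP_K = 25
THRESHOLD = 0.45   # embedding distance units (~nm after scale matching)


def main() -> None:
    matrix = np.loadtxt(OUT / "rmsd_matrix.csv", delimiter=",")
    payload = json.loads((OUT / "clustering.json").read_text())
    clustering = Clustering(
        clusters=tuple(Cluster(c["center_frame"], tuple(c["members"]))
                       for c in payload["clusters"]),
        cutoff=payload["cutoff_nm"], total_frames=payload["total_frames"])
    labels = pd.read_csv(OUT / "membership.csv")["system"].tolist()

    k = min(TOP_K, clustering.n_clusters)
    centers = [c.center_frame for c in clustering.clusters[:k]]
    embedding = nonmetric_mds(matrix[np.ix_(centers, centers)], seed=SEED)
    meta = group_metaclusters(embedding, THRESHOLD)
    pd.DataFrame({
        "cluster": np.arange(k),
        "center_frame": centers,
        "x": embedding.points[:, 0],
        "y": embedding.points[:, 1],
        "metacluster": meta.assignment,
        "size": [clustering.clusters[i].size for i in range(k)],
    }).to_csv(OUT / "embedding.csv", index=False, float_format="%.6f",
              lineterminator="\n")

    occ = metacluster_occupancy(meta, clustering, labels)
    occ.to_csv(OUT / "metacluster_occupancy.csv", float_format="%.6f",
               lineterminator="\n")
    print(f"stress {embedding.stress:.2e} over {k} centres "
          f"({embedding.iterations} iterations, seed {SEED})")
    print(f"{meta.n_metaclusters} meta-clusters at threshold {THRESHOLD}")
    print("per-system residence (fraction of time):")
    print(occ.round(3).to_string())


if __name__ == "__main__":
    main()
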