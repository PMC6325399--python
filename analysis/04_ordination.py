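"""Community-structure ordination: HCA dendrogram and PCA.

Euclidean distances between standardized profiles feed a
complete-linkage dendrogram (written as Newick); a PCA of the profiles
(bins as variables, centered, unscaled) summarizes the variance
structure, analogous to asking whether samples group by diet or by
species.
"""

import sys
from pathlib import Path

import pandas as pd

from rumenprof import io as rio
from rumenprof import SimConfig, complete_linkage, euclidean_distances, pca, simulate_study, trflp_chain

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260927
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = simulate_study(SimConfig(), seed=SEED)
    _, matrix = trflp_chain(study.peak_tables)

    dist = euclidean_distances(matrix)
    tree = complete_linkage(dist)
    rio.write_newick(tree.to_newick(), OUT / "dendrogram.nwk")

    result = pca(matrix)
    rio.write_table(result.scores_frame(), OUT / "pca_scores.tsv")
    variance = pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(len(result.component_variance))],
            "variance": result.component_variance,
            "variance_explained_percent": result.variance_explained_percent,
        }
    )
    rio.write_table(variance, OUT / "pca_variance.tsv")
    pc1, pc2 = result.variance_explained_percent[:2]
    print(f"dendrogram: {len(tree.leaf_ids)} leaves, merge heights "
          f"{tree.heights.min():.3f}..{tree.heights.max():.3f}")
    print(f"PC1 explains {pc1:.1f}% and PC2 {pc2:.1f}% of the variance")


if __name__ == "__main__":
    main()
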