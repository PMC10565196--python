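"""Relatedness as covariance: trees, classifications, and the combined model.

Shows the Brownian-motion covariance of a small tree, the shared-level
covariance of a hierarchical classification, and how spatial and
phylogenetic components combine into one phylospatial covariance.
"""

import numpy as np
import pandas as pd

from phylospatial import (
    GeoTable,
    KernelSpec,
    combine_covariances,
    distance_matrix,
    phylo_covariance,
    spatial_covariance,
)

ids = ["A", "B", "C"]
tree_cov = phylo_covariance("((A:1,B:1):1,C:2);", ids)
print("Brownian covariance of ((A:1,B:1):1,C:2); :")
print(pd.DataFrame(tree_cov.values, index=ids, columns=ids))
print("A and B share one unit of history; C shares none.\n")

classification = pd.DataFrame(
    {"taxon": ids, "family": ["f1", "f1", "f2"], "genus": ["g1", "g2", "g3"]}
)
cls_cov = phylo_covariance(classification, ids)
print("shared-level covariance from a 2-level classification:")
print(pd.DataFrame(cls_cov.values, index=ids, columns=ids))

table = GeoTable(pd.DataFrame({"id": ids, "lon": [0.0, 3.0, 100.0], "lat": [0.0, 2.0, 40.0]}))
sp_cov = spatial_covariance(distance_matrix(table), KernelSpec(sigma2=1.0, rho=2000.0))
combined = combine_covariances(sp_cov, tree_cov, sigma2_s=0.6, sigma2_p=0.3, tau2=0.1)
print("\nphylospatial covariance 0.6*K_space + 0.3*K_phylo + 0.1*I:")
print(pd.DataFrame(np.round(combined.values, 3), index=ids, columns=ids))
print(
    "\nThe variance components say how much trait similarity to attribute to"
    "\nproximity vs descent vs neither; the spatial GLMM estimates them."
)
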