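"""Summarize cluster proximity as distances from a reference centroid.

Uses a toy 2-D embedding; in practice this is a PCA embedding and the
reference is a cluster of interest (e.g. the neoplastic cells).
"""

import numpy as np
import pandas as pd

from apamirnet import ClusterAssignment, centroid_distances

rng = np.random.default_rng(0)
centers = {"ref": (0, 0), "near": (3, 0), "far": (10, 10)}
cells, labels, coords = [], {}, []
for name, (cx, cy) in centers.items():
    for i in range(50):
        cid = f"{name}{i}"
        cells.append(cid)
        labels[cid] = name
        coords.append(rng.normal((cx, cy), 1.0))

embedding = pd.DataFrame(coords, index=cells, columns=["PC1", "PC2"])
clusters = ClusterAssignment(pd.Series(labels))
out = centroid_distances(embedding, clusters, "ref")
print(out.to_string(index=False))
# mean_distance is the average Euclidean distance from the reference
# centroid to each cell of the target cluster; sd is the population SD.
# 'near' should sit around 3, 'far' around sqrt(200) ~ 14.
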