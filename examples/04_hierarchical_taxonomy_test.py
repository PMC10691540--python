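"""Hierarchical differential PA testing over a cell-type taxonomy.

Cells carry leaf labels from a small taxonomy (neurons/non-neurons at the
top, excitatory/inhibitory below); each non-root node is tested against
the remaining cells of its parent, so a PA difference between deep
siblings is reported once, at the node where it occurs.
"""

import numpy as np
import pandas as pd
from scipy import sparse

from apamix.differential import TaxonomyTree, hierarchical_tests
from apamix.quantify import PeakCellMatrix, QCSummary
from apamix.simulate import simulate_gene_counts

rng = np.random.default_rng(41)
tree = TaxonomyTree.from_edges([
    ("root", "neuron"), ("root", "nonneuron"),
    ("neuron", "excitatory"), ("neuron", "inhibitory"),
])

# one gene with two peaks; the shift exists only between the two neuron
# subtypes, nonneurons sit in between
leaf_alphas = {"excitatory": (8.0, 2.0), "inhibitory": (2.0, 8.0),
               "nonneuron": (5.0, 5.0)}
blocks, barcodes, labels = [], [], []
for leaf, alpha in leaf_alphas.items():
    counts, _ = simulate_gene_counts({leaf: alpha}, 120, 15.0, 10.0, rng)
    blocks.append(counts)
    barcodes += [f"{leaf}-{i}" for i in range(120)]
    labels += [leaf] * 120

peaks_meta = pd.DataFrame([
    {"peak_id": "gX:P1", "gene_id": "gX", "chrom": "chrT", "strand": "+",
     "start": 0, "end": 100, "mu": 50.0, "sigma": 30.0},
    {"peak_id": "gX:P2", "gene_id": "gX", "chrom": "chrT", "strand": "+",
     "start": 400, "end": 500, "mu": 450.0, "sigma": 30.0},
])
pcm = PeakCellMatrix(sparse.csr_matrix(np.vstack(blocks).T), peaks_meta,
                     barcodes, QCSummary())

results = hierarchical_tests(pcm, pd.Series(labels, index=barcodes), tree)
print(results[["node", "level", "gene_id", "p_adj", "mpro",
               "significant"]].to_string(index=False))
print()
print("The excitatory-vs-rest-of-neurons and inhibitory-vs-rest-of-neurons "
      "comparisons carry the signal (opposite MPRO signs);")
print("the neuron-vs-nonneuron comparison pools the two subtypes and shows "
      "no net proportion shift, so it is not called.")
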