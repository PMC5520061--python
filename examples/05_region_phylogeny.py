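"""Neighbor-joining phylogeny of tumor regions from binary mutation profiles.

Each region becomes a 0/1 vector over all exonic mutation sites; the matched
germline is an all-zero outgroup (somatic mutations are absent from it by
definition). Pairwise Hamming counts feed the canonical neighbor-joining
algorithm, and the tree is rooted on the germline. Regions dominated by the
same subclones end up as neighbors.
"""

import trunkscope as ts
from trunkscope.phylogeny import ascii_tree

ds = ts.generate_dataset(ts.SimParams(seed=7))
kept, _ = ts.filter_callset(ds.callset)
matrix = ts.build_presence_matrix(kept, ts.EXONIC)

tree = ts.region_tree(matrix, metric="count")
print("newick:", ts.write_newick(tree))
print("\nrooted tree (indentation = depth, ':x' = branch length in mutations):")
print(ascii_tree(tree))
print("\nbranch lengths count mutation-profile differences; the long edge to "
      "the germline reflects the shared trunk burden of all regions")
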