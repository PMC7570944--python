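"""Agglomerative hierarchy on the bundled closeness matrix.

The indegree x outdegree affinity works directly on the asymmetric W;
the minimum-affinity (most bonded) pair merges first and heights read
as dissimilarities.
"""

import herdsocial as hs

W = hs.load_cattle_closeness()
dend = hs.ahc_build(W)

print("Merge sequence (most bonded first):")
for (left, right), height in zip(dend.merge_members(), dend.merges[:, 2]):
    print(f"  {{{','.join(left)}}} + {{{','.join(right)}}}  at {height:.4f}")

newick = hs.dendrogram_to_newick(dend)
print(f"\nNewick: {newick}")
print("\nThe first merge {8,10} at 9.1494 = 3.06 x 2.99 is the smallest")
print("mutual rank product - the most strongly bonded pair in the group.")
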