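"""Project descriptor dissimilarities to 2-D with classical MDS.

Prints each descriptor's coordinates under the embedding-based metric;
descriptors from the same planted semantic group land close together.
"""

import numpy as np

import odorlex as ox

cat, spectra, emb, truth = ox.generate_worked_fixture()
dm = ox.cosine_dissimilarity(cat.descriptor_names, emb)
coords = ox.mds_embed(dm, 2)

print("descriptor   group   x        y")
for d, (x, y) in zip(dm.labels, coords):
    print(f"{d:10s}   {truth.member_map[d]}      {x:+.3f}   {y:+.3f}")

# The floral group (rose, lily, violet) and the dairy group (milk, cheese,
# butter) separate along the first axis; within-group spread is set by the
# small noise on each word vector.
d_within = np.linalg.norm(coords[0] - coords[1])
d_between = np.linalg.norm(coords[0] - coords[3])
print(f"\nrose-lily distance {d_within:.3f} << rose-milk distance {d_between:.3f}")
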