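"""Cluster odor descriptors two ways and compare what each metric sees.

Builds a synthetic catalog in which semantically similar descriptors are
used mutually exclusively, then clusters the descriptors (a) by catalog
column correlation and (b) by word-embedding cosine distance.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import odorlex as ox

cfg = ox.SyntheticConfig(n_chemicals=200, n_groups=4, seed=0)
cat, spectra, emb, truth = ox.generate_world(cfg)
print(f"catalog: {cat.n_chemicals} chemicals x {cat.n_descriptors} descriptors, "
      f"sparsity {ox.sparsity(cat):.3f}")

true_labels = [truth.member_map[d] for d in cat.descriptor_names]
for name, dm in (
    ("correlation", ox.correlation_dissimilarity(cat)),
    ("cosine/word2vec", ox.cosine_dissimilarity(cat.descriptor_names, emb)),
):
    asg = ox.cut_to_k(ox.upgma(dm), cfg.n_groups)
    got = [asg.member_map[d] for d in cat.descriptor_names]
    ari = adjusted_rand_score(true_labels, got)
    print(f"{name:16s}: ARI vs planted groups = {ari:.3f}")

# An ARI of 1.0 means the cut recovered the planted semantic groups exactly;
# the correlation metric scores far lower because exclusive annotation makes
# within-group correlations vanish even for near-synonymous descriptors.
r = np.corrcoef(cat.matrix.T.astype(float))
group = np.array(true_labels)
same = (group[:, None] == group[None, :]) & ~np.eye(len(group), dtype=bool)
print(f"mean within-group column correlation: {r[same].mean():+.3f} "
      "(near zero despite shared meaning)")
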