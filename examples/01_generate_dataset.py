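"""Generate a synthetic miRNA-disease dataset with planted low-rank structure.

Every downstream capability of the package can be exercised on data like
this: a binary association matrix whose links follow latent factors, plus
four similarity views (two per entity class) correlated with the same
factors.
"""

import numpy as np

import hypermda as h

dataset = h.make_dataset(n_m=60, n_d=40, rank=4, density=0.10, noise_sd=0.1, seed=1)
assoc = dataset.associations

print(f"association matrix: {assoc.n_mirna} miRNAs x {assoc.n_disease} diseases")
print(f"known associations: {assoc.n_positive} "
      f"(density {assoc.n_positive / (assoc.n_mirna * assoc.n_disease):.3f})")

# the planted signal: linked pairs have larger factor inner products
scores = dataset.truth.mirna_factors @ dataset.truth.disease_factors.T
linked = scores[assoc.values == 1].mean()
unlinked = scores[assoc.values == 0].mean()
print(f"mean factor inner product, linked pairs:   {linked:.3f}")
print(f"mean factor inner product, unlinked pairs: {unlinked:.3f}")
print("-> the gap between these two numbers is what the model must recover")

view = dataset.mirna_views["functional"]
print(f"functional view: symmetric={np.allclose(view.values, view.values.T)}, "
      f"diag=1, range [{view.values.min():.2f}, {view.values.max():.2f}]")
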