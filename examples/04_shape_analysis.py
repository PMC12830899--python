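"""Shape analysis: bounding boxes, flatness, and regional similarity.

Asks the questions the structure module answers about a fitted (here:
simulated) conformation — how anisotropic is it, is it genuinely
three-dimensional, and do two regions fold alike?
"""

import numpy as np

import ecdna3d as e
from ecdna3d.evaluate import bounding_box, permutation_similarity
from ecdna3d.matrix import ContactMatrix, ice_normalize_generalized

cfg = e.SimConfig(ne=60, k=1, alpha=-1.2, beta=8.0, seed=2)
truth = e.add_local_folds(e.simulate_base_structure(cfg))

# Minimum bounding box: rotating calipers vs the PCA frame.
cal = bounding_box(truth.coords, method="calipers")
pca = bounding_box(truth.coords, method="pca")
print(f"calipers box edges {np.round(cal['edges'], 3)} "
      f"ratio {cal['ratio']:.3f} volume {cal['volume']:.3f}")
print(f"PCA box      edges {np.round(pca['edges'], 3)} "
      f"ratio {pca['ratio']:.3f} volume {pca['volume']:.3f}")
assert cal["volume"] <= pca["volume"] + 1e-9

# Flatness: refit with beta fixed while squeezing the first axis.  A truly
# 3D fold pays a likelihood price once the bound drops below its extent.
E = e.sample_hic(truth.coords, cfg.alpha, cfg.beta, seed=3)
binmap = e.binmap_from_duplication_regions(cfg.ne, ())
C = ContactMatrix(E, kind="collapsed", state="raw", resolution=5000,
                  binmap=binmap)
N, _ = ice_normalize_generalized(C, binmap)
res = e.flatness_test(N.values, binmap, beta_fixed=cfg.beta,
                      axis_limits=(1.0, 0.5, 0.15), n_repeats=3, seed=0)
for limit, objs in res.items():
    print(f"axis limit {limit}: median objective {np.median(objs):.1f}")

# Permutation test: is region 5-15 folded like region 35-45?
perm = permutation_similarity(truth.coords, (5, 10), (35, 10),
                              n_perm=500, seed=1)
print(f"regions 5-15 vs 35-45: RMSD {perm['rmsd']:.3f} "
      f"(p={perm['p_rmsd']:.3f}), PCC {perm['pcc']:.3f} "
      f"(p={perm['p_pcc']:.3f})")
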