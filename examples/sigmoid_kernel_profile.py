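"""How the SWRF* sigmoid scale factor shapes neighbour weights.

On class-independent SNP data the pairwise Hamming distances concentrate
around their mean t with standard deviation u.  The sigmoid kernel
f(d) = 2 / (1 + exp(-(t - d) / (u / scale))) - 1 assigns "full" weight
(|f| > 0.95) only to pairs far enough from t; the scale factor sets how
far.  Small scales behave like a ramp (almost no pair saturates), large
scales harden into the SURF* step function.
"""

import numpy as np

from morf import distance_stats, pairwise_distances, random_snp_dataset

dataset = random_snp_dataset(n_samples=400, n_snps=1000, seed=5)
D = pairwise_distances(dataset)
t, u = distance_stats(D)
upper = D[np.triu_indices(dataset.n_samples, k=1)].astype(float)
print(f"pairwise Hamming distances: mean t = {t:.1f}, sd u = {u:.2f} "
      f"({upper.size} pairs)")

print("\nscale  full-weight pairs  onset (sd from mean)")
for scale in (1, 2, 4, 8, 16):
    f = 2.0 / (1.0 + np.exp(-(t - upper) / (u / scale))) - 1.0
    full = np.abs(f) > 0.95
    onset = np.log(39) / scale  # |t-d|/u where |f| crosses 0.95
    print(f"{scale:>5}  {100 * full.mean():>16.2f}%  {onset:>8.3f}")
print("\nAt the default scale 4 an intermediate share of pairs (~a third) is "
      "saturated,\nwith full weight starting ~0.92 sd from the mean distance; "
      "at scale 1 almost\nno pair reaches full weight and the kernel degrades "
      "into a ramp.")
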