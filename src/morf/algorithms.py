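"""Named Relief-family algorithms as MoRF instantiations.

``run_algorithm`` dispatches on the algorithm name, resolves data-dependent
kernel parameters (the SURF/SWRF* threshold ``t`` is the mean pairwise
distance, the sigmoid width ``u`` the pairwise-distance standard deviation,
ReliefF thresholds come from k-nearest hit/miss radii with the field-standard
default k=10), and hands over to the generic engine.  ``relief_original``
implements the classic single-nearest-hit/miss update separately, since its
normalisation (divide by the number of visited samples) predates the
kernel-mass normaliser of the framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ConfigError,
    DataError,
    GenotypeDataset,
    NeighborKernel,
    WeightVector,
    morf_weights,
    pairwise_distances,
)

__all__ = ["AlgorithmConfig", "ALGORITHMS", "relief_original", "run_algorithm"]

ALGORITHMS = ("relief", "relieff", "surf", "surf_star", "swrf_star")


@dataclass
class AlgorithmConfig:
    """Parameters shared by all algorithms.

    ``sample_fraction`` < 1 visits a random subset of samples in the outer
    loop (a classic Relief option for large n) and then requires ``seed``.
    """

    name: str = "swrf_star"
    k: int = 10
    scale: float = 4.0
    metric: str = "hamming"
    diff_model: str = "allelic"
    seed: Optional[int] = None
    sample_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHMS:
            raise ConfigError(
                f"unknown algorithm {self.name!r}; expected one of {ALGORITHMS}"
            )
        if not 0 < self.sample_fraction <= 1:
            raise ConfigError(
                f"sample_fraction must be in (0, 1], got {self.sample_fraction!r}"
            )
        if self.sample_fraction < 1 and self.seed is None:
            raise ConfigError("sample_fraction < 1 requires an explicit seed")


def _sample_set(config: AlgorithmConfig, n: int) -> Optional[np.ndarray]:
    if config.sample_fraction >= 1:
        return None
    rng = np.random.default_rng(config.seed)
    size = max(1, round(config.sample_fraction * n))
    return rng.choice(n, size=size, replace=False)


def relief_original(
    dataset: GenotypeDataset, config: Optional[AlgorithmConfig] = None
) -> WeightVector:
    """The original Relief update: one nearest hit and one nearest miss.

    For each visited sample the update is ``diff(a, s_i, miss) - diff(a, s_i,
    hit)``; the accumulated weights are divided by the number of visited
    samples, so the output lies in [-1, 1].  Nearest-neighbour ties are
    broken by the lowest sample index, which makes the full pass
    deterministic.
    """
    config = config or AlgorithmConfig(name="relief")
    if len(np.unique(dataset.labels)) < 2:
        raise DataError("relief requires both classes to be present")
    if dataset.n_samples < 3:
        raise DataError("relief requires at least 3 samples")

    D = pairwise_distances(dataset, config.metric)
    from .core import _collapse  # shared genotype recoding

    X = _collapse(dataset.genotypes, config.diff_model)
    y = dataset.labels
    n, a = X.shape
    indices = _sample_set(config, n)
    if indices is None:
        indices = np.arange(n)

    W = np.zeros(a)
    order = np.arange(n)
    for i in indices:
        d = D[i].astype(float).copy()
        d[i] = np.inf
        same = y == y[i]
        # np.argmin on the masked arrays returns the first (lowest-index) tie
        hit_pool = np.where(same & (order != i))[0]
        miss_pool = np.where(~same)[0]
        hit = hit_pool[np.argmin(d[hit_pool])]
        miss = miss_pool[np.argmin(d[miss_pool])]
        W += (X[i] != X[miss]).astype(float) - (X[i] != X[hit]).astype(float)
    W /= len(indices)
    return WeightVector(W, dataset.attribute_names)


def run_algorithm(dataset: GenotypeDataset, config: AlgorithmConfig) -> WeightVector:
    """Dispatch to the named algorithm with its standard kernel defaults."""
    if config.name == "relief":
        return relief_original(dataset, config)
    kernel = NeighborKernel(kind=config.name, k=config.k, scale=config.scale)
    return morf_weights(
        dataset,
        kernel,
        diff_model=config.diff_model,
        metric=config.metric,
        sample_set=_sample_set(config, dataset.n_samples),
    )
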