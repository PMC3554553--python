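"""Core of the Modular Relief Framework (MoRF).

Relief-family algorithms estimate a per-attribute weight in [-1, 1] that
measures how strongly an attribute (here, a SNP coded as minor-allele count)
discriminates between classes, using nearest-neighbour structure rather than
univariate association.  MoRF decomposes the family into four interchangeable
component functions:

* a **class comparator** ``c(s_i, s_j)`` (+1 for a miss, -1 for a hit),
* a **local difference** ``diff(a, s_i, s_j)`` along a single attribute,
* a **global distance** ``dist_ij`` (Hamming or taxicab on genotype vectors),
* a **neighbour weighting kernel** ``f(dist_ij)`` in [-1, 1] that decides how
  much each neighbour contributes.

The weight update for attribute ``a`` driven by sample ``s_i`` is

    dW_i[a] = sum_{j != i} c(s_i, s_j) * diff(a, s_i, s_j) * f(dist_ij)
              / sum_{j != i} |f(dist_ij)|

and the final weight is the average of ``dW_i[a]`` over the visited samples.
The absolute value in the normaliser keeps every weight in [-1, 1] even for
kernels that take negative values (the "star" kernels); a sample whose
normaliser is zero contributes a neutral update of 0.

Choosing the kernel recovers the published algorithms: a per-sample k-nearest
step gives ReliefF, a global step at threshold ``t`` gives SURF, a signed step
gives SURF*, and a sigmoid centred at ``t`` with width ``u/scale`` gives
SWRF* (Sigmoid Weighted ReliefF Star).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "GenotypeDataset",
    "WeightVector",
    "NeighborKernel",
    "DataError",
    "ConfigError",
    "class_comparator",
    "diff_allelic",
    "diff_genetic_model",
    "hamming_distance",
    "taxicab_distance",
    "pairwise_distances",
    "distance_stats",
    "kernel_relieff",
    "kernel_surf",
    "kernel_surf_star",
    "kernel_swrf_star",
    "morf_weights",
    "relieff_thresholds",
    "GENETIC_MODELS",
]

GENOTYPE_VALUES = (0, 1, 2)
GENETIC_MODELS = ("allelic", "dominant", "recessive", "heterozygote")

DiffModel = Literal["allelic", "dominant", "recessive", "heterozygote"]
Metric = Literal["hamming", "taxicab"]


class DataError(ValueError):
    """Invalid genotype data: out-of-domain values, shape mismatches, etc."""


class ConfigError(ValueError):
    """Invalid algorithm or kernel configuration."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """A case-control SNP dataset.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_attributes)`` integer matrix of minor-allele counts,
        every entry in {0, 1, 2}.
    labels
        Length-``n_samples`` vector of binary class labels in {0, 1}
        (1 = case / diseased by convention).
    attribute_names
        Unique identifier per attribute.  Defaults to ``SNP1..SNPa``.
    metadata
        Free-form annotations.  The simulator stores the names of the
        functional (disease-causing) attributes under ``"functional"``.
    """

    genotypes: np.ndarray
    labels: np.ndarray
    attribute_names: Optional[Sequence[str]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.labels = np.asarray(self.labels)
        if self.genotypes.ndim != 2:
            raise DataError("genotypes must be a 2-D matrix (samples x attributes)")
        n, a = self.genotypes.shape
        if n < 2 or a < 1:
            raise DataError(f"need at least 2 samples and 1 attribute, got {n}x{a}")
        if not np.isin(self.genotypes, GENOTYPE_VALUES).all():
            bad = np.argwhere(~np.isin(self.genotypes, GENOTYPE_VALUES))[0]
            raise DataError(
                f"genotype at sample {bad[0]}, attribute {bad[1]} is "
                f"{self.genotypes[bad[0], bad[1]]!r}; must be 0, 1 or 2"
            )
        if self.labels.shape != (n,):
            raise DataError(
                f"labels must have length {n}, got shape {self.labels.shape}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            bad_i = int(np.argwhere(~np.isin(self.labels, (0, 1)))[0][0])
            raise DataError(
                f"class label of sample {bad_i} is {self.labels[bad_i]!r}; must be 0 or 1"
            )
        self.genotypes = self.genotypes.astype(np.int8, copy=False)
        self.labels = self.labels.astype(np.int8, copy=False)
        if self.attribute_names is None:
            self.attribute_names = [f"SNP{i + 1}" for i in range(a)]
        else:
            self.attribute_names = list(self.attribute_names)
        if len(self.attribute_names) != a:
            raise DataError(
                f"{len(self.attribute_names)} attribute names for {a} attributes"
            )
        if len(set(self.attribute_names)) != a:
            raise DataError("attribute names must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.genotypes.shape[1]

    def attribute_index(self, name: str) -> int:
        try:
            return self.attribute_names.index(name)
        except ValueError:
            raise DataError(f"unknown attribute {name!r}") from None


@dataclass
class WeightVector:
    """Per-attribute Relief weights, aligned with ``attribute_names``."""

    weights: np.ndarray
    attribute_names: Sequence[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.attribute_names = list(self.attribute_names)
        if self.weights.ndim != 1 or len(self.weights) != len(self.attribute_names):
            raise DataError("weights and attribute names must align")
        # allow a hair of floating-point slack at the boundaries
        if np.any(np.abs(self.weights) > 1 + 1e-9):
            raise DataError("attribute weights must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, name: str) -> float:
        return float(self.weights[list(self.attribute_names).index(name)])


# ---------------------------------------------------------------------------
# Component functions
# ---------------------------------------------------------------------------


def class_comparator(label_i: int, label_j: int) -> int:
    """Return -1 for a hit (equal classes) and +1 for a miss."""
    if label_i not in (0, 1) or label_j not in (0, 1):
        raise DataError(f"class labels must be 0 or 1, got {label_i!r}, {label_j!r}")
    return -1 if label_i == label_j else 1

def _check_genotype(value: int) -> None:
    if value not in GENOTYPE_VALUES:
        raise DataError(f"genotype value must be 0, 1 or 2, got {value!r}")


def diff_allelic(value_i: int, value_j: int) -> int:
    """Match/mismatch difference on raw minor-allele counts: 0 iff equal."""
    _check_genotype(value_i)
    _check_genotype(value_j)
    return int(value_i != value_j)


def _carrier_status(values: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return np.asarray(values) >= 1
    if model == "recessive":
        return np.asarray(values) == 2
    if model == "heterozygote":
        return np.asarray(values) == 1
    raise ConfigError(
        f"unknown genetic model {model!r}; expected one of {GENETIC_MODELS[1:]}"
    )


def diff_genetic_model(value_i: int, value_j: int, model: str) -> int:
    """Difference after collapsing genotypes to carrier status under a
    dominant, recessive or heterozygote single-locus model."""
    _check_genotype(value_i)
    _check_genotype(value_j)
    si, sj = _carrier_status(np.array([value_i, value_j]), model)
    return int(si != sj)


def _collapse(genotypes: np.ndarray, diff_model: str) -> np.ndarray:
    """Recode the genotype matrix so that the allelic match/mismatch diff on
    the recoded values reproduces the requested diff model."""
    if diff_model == "allelic":
        return genotypes
    return _carrier_status(genotypes, diff_model).astype(np.int8)


def hamming_distance(sample_i: Sequence[int], sample_j: Sequence[int]) -> int:
    """Number of attributes at which two genotype vectors differ."""
    x, y = np.asarray(sample_i), np.asarray(sample_j)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    return int(np.count_nonzero(x != y))


def taxicab_distance(sample_i: Sequence[int], sample_j: Sequence[int]) -> int:
    """Sum of absolute allele-count differences (L1 on genotype vectors)."""
    x, y = np.asarray(sample_i, dtype=int), np.asarray(sample_j, dtype=int)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    for v in (x, y):
        if not np.isin(v, GENOTYPE_VALUES).all():
            raise DataError("genotype values must be 0, 1 or 2")
    return int(np.abs(x - y).sum())


def pairwise_distances(dataset: GenotypeDataset, metric: Metric = "hamming") -> np.ndarray:
    """Full ``n x n`` sample-distance matrix (symmetric, zero diagonal)."""
    X = dataset.genotypes.astype(np.int16)
    if metric == "hamming":
        # one-hot trick: Hamming = a - sum_g <I[x=g], I[y=g]>
        n, a = X.shape
        D = np.full((n, n), a, dtype=np.int32)
        for g in GENOTYPE_VALUES:
            Ig = (X == g).astype(np.int32)
            D -= Ig @ Ig.T
    elif metric == "taxicab":
        # |x-y| = x + y - 2*min(x,y); min decomposes over thresholds 1 and 2
        ge1 = (X >= 1).astype(np.int32)
        ge2 = (X >= 2).astype(np.int32)
        sums = X.sum(axis=1, dtype=np.int32)
        D = sums[:, None] + sums[None, :] - 2 * (ge1 @ ge1.T + ge2 @ ge2.T)
    else:
        raise ConfigError(f"unknown metric {metric!r}; expected 'hamming' or 'taxicab'")
    np.fill_diagonal(D, 0)
    return D


def distance_stats(distances: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation of the pairwise distances.

    Computed over the ``n(n-1)/2`` unordered distinct pairs, excluding the
    zero diagonal.  These are the defaults for the SURF/SURF* threshold ``t``
    and the SWRF* sigmoid width ``u``.
    """
    D = np.asarray(distances)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise DataError("distance matrix must be square")
    if n < 2:
        raise DataError("need at least 2 samples for distance statistics")
    upper = D[np.triu_indices(n, k=1)]
    return float(upper.mean()), float(upper.std())


# ---------------------------------------------------------------------------
# Neighbour weighting kernels
# ---------------------------------------------------------------------------


def _check_dist(dist: float) -> None:
    if dist < 0:
        raise DataError(f"distances are non-negative, got {dist!r}")


def kernel_relieff(dist: float, is_hit: bool, t_hit: float, t_miss: float) -> float:
    """ReliefF per-sample step kernel: 1 within the k-nearest radius of the
    matching category (hit or miss), else 0."""
    _check_dist(dist)
    threshold = t_hit if is_hit else t_miss
    return 1.0 if dist <= threshold else 0.0


def kernel_surf(dist: float, t: float) -> float:
    """SURF global step kernel: 1 for neighbours within threshold ``t``."""
    _check_dist(dist)
    return 1.0 if dist <= t else 0.0


def kernel_surf_star(dist: float, t: float) -> float:
    """SURF* signed step kernel: +1 within ``t``, -1 beyond it."""
    _check_dist(dist)
    return 1.0 if dist <= t else -1.0


def kernel_swrf_star(dist: float, t: float, u: float, scale: float = 4.0) -> float:
    """SWRF* sigmoid kernel ``2 / (1 + exp(-(t - d)/(u/scale))) - 1``.

    Strictly decreasing in ``dist``, zero at ``dist == t``, approaching +1
    for nearby and -1 for distant neighbours.  The default ``scale`` of 4
    makes the transition region roughly two pairwise-distance standard
    deviations wide, so that about a third of sample pairs receive nearly
    full weight (|f| > 0.95) while pairs near the mean distance contribute
    little.
    """
    if u <= 0 or scale <= 0:
        raise ConfigError(f"sigmoid width u={u!r} and scale={scale!r} must be positive")
    _check_dist(dist)
    with np.errstate(over="ignore"):  # saturates cleanly to -1
        return float(2.0 / (1.0 + np.exp(-(t - dist) / (u / scale))) - 1.0)


def relieff_thresholds(
    distances: np.ndarray, labels: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample k-th nearest hit and miss distances (self excluded).

    If a sample has fewer than ``k`` hits or misses available, the radius of
    the farthest available neighbour of that category is used and a warning
    is emitted.  A sample with no neighbour at all in a category gets a
    threshold of -1, which excludes the (empty) category.
    """
    if k < 1:
        raise ConfigError(f"k must be a positive integer, got {k!r}")
    D = np.asarray(distances)
    labels = np.asarray(labels)
    n = len(labels)
    t_hit = np.full(n, -1.0)
    t_miss = np.full(n, -1.0)
    clamped = False
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        for thresholds, mask in ((t_hit, same), (t_miss, ~same & (np.arange(n) != i))):
            d = np.sort(D[i][mask])
            if len(d) == 0:
                continue
            if len(d) < k:
                clamped = True
                thresholds[i] = d[-1]
            else:
                thresholds[i] = d[k - 1]
    if clamped:
        warnings.warn(
            f"fewer than k={k} hits or misses available for some samples; "
            "using all available neighbours of that category",
            stacklevel=2,
        )
    return t_hit, t_miss


@dataclass
class NeighborKernel:
    """Specification of a neighbour weighting function.

    ``kind`` selects the family; unset parameters (``t``, ``u``, ReliefF
    per-sample thresholds) are resolved from the dataset's pairwise-distance
    distribution by :func:`morf_weights`.
    """

    kind: Literal["relieff", "surf", "surf_star", "swrf_star"]
    t: Optional[float] = None
    u: Optional[float] = None
    k: int = 10
    scale: float = 4.0
    t_hit: Optional[np.ndarray] = None   # per-sample, kind="relieff" only
    t_miss: Optional[np.ndarray] = None

    KINDS = ("relieff", "surf", "surf_star", "swrf_star")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ConfigError(
                f"unknown kernel kind {self.kind!r}; expected one of {self.KINDS}"
            )
        if self.kind == "relieff" and self.k < 1:
            raise ConfigError(f"relieff requires k >= 1, got {self.k!r}")
        if self.kind == "swrf_star":
            if self.scale <= 0:
                raise ConfigError(f"scale must be positive, got {self.scale!r}")
            if self.u is not None and self.u <= 0:
                raise ConfigError(f"sigmoid width u must be positive, got {self.u!r}")

    def resolve(self, distances: np.ndarray, labels: np.ndarray) -> "NeighborKernel":
        """Fill unset parameters from the data: ``t``/``u`` from the pairwise
        distance mean and standard deviation, ReliefF thresholds from the
        k-nearest hit/miss radii."""
        kernel = NeighborKernel(
            self.kind, self.t, self.u, self.k, self.scale, self.t_hit, self.t_miss
        )
        if kernel.kind == "relieff":
            if kernel.t_hit is None or kernel.t_miss is None:
                kernel.t_hit, kernel.t_miss = relieff_thresholds(
                    distances, labels, kernel.k
                )
        else:
            if kernel.t is None or (kernel.kind == "swrf_star" and kernel.u is None):
                t, u = distance_stats(distances)
                if kernel.t is None:
                    kernel.t = t
                if kernel.u is None:
                    if u == 0 and kernel.kind == "swrf_star":
                        raise ConfigError(
                            "all pairwise distances are equal; sigmoid width "
                            "u=0 is invalid — supply u explicitly"
                        )
                    kernel.u = u
        return kernel

    def weight_matrix(self, distances: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Evaluate ``f(dist_ij)`` for every ordered pair; zero diagonal.

        Requires a fully resolved kernel (see :meth:`resolve`).
        """
        D = np.asarray(distances, dtype=float)
        if self.kind == "relieff":
            if self.t_hit is None or self.t_miss is None:
                raise ConfigError("relieff kernel needs per-sample thresholds")
            labels = np.asarray(labels)
            same = labels[:, None] == labels[None, :]
            F = np.where(
                same,
                D <= np.asarray(self.t_hit)[:, None],
                D <= np.asarray(self.t_miss)[:, None],
            ).astype(float)
        elif self.kind == "surf":
            if self.t is None:
                raise ConfigError("surf kernel needs a threshold t")
            F = (D <= self.t).astype(float)
        elif self.kind == "surf_star":
            if self.t is None:
                raise ConfigError("surf_star kernel needs a threshold t")
            F = np.where(D <= self.t, 1.0, -1.0)
        else:  # swrf_star
            if self.t is None or self.u is None:
                raise ConfigError("swrf_star kernel needs t and u")
            if self.u <= 0 or self.scale <= 0:
                raise ConfigError("swrf_star requires u > 0 and scale > 0")
            with np.errstate(over="ignore"):  # distant pairs saturate to -1
                F = 2.0 / (1.0 + np.exp(-(self.t - D) / (self.u / self.scale))) - 1.0
        np.fill_diagonal(F, 0.0)
        return F


# ---------------------------------------------------------------------------
# The generic weight-update engine
# ---------------------------------------------------------------------------


def morf_weights(
    dataset: GenotypeDataset,
    kernel: NeighborKernel,
    diff_model: DiffModel = "allelic",
    metric: Metric = "hamming",
    sample_set: Optional[Sequence[int]] = None,
) -> WeightVector:
    """Run the MoRF weight-update engine with the given component functions.

    For every sample ``i`` in ``sample_set`` (default: all samples) the
    per-sample update is the kernel-weighted, class-signed average attribute
    mismatch over all other samples, normalised by the total absolute kernel
    mass so each update — and hence the averaged weight — lies in [-1, 1].
    A sample with zero kernel mass contributes a neutral update.
    """
    if sample_set is not None:
        sample_set = np.asarray(sample_set, dtype=int)
        if sample_set.size == 0:
            raise ConfigError("sample_set must not be empty")
    if len(np.unique(dataset.labels)) < 2:
        warnings.warn(
            "dataset contains a single class; hit/miss structure is degenerate",
            stacklevel=2,
        )

    D = pairwise_distances(dataset, metric)
    resolved = kernel.resolve(D, dataset.labels)
    F = resolved.weight_matrix(D, dataset.labels)

    X = _collapse(dataset.genotypes, diff_model)
    y = dataset.labels
    c = np.where(y[:, None] == y[None, :], -1.0, 1.0)
    signed = c * F
    denom = np.abs(F).sum(axis=1)

    indices = np.arange(dataset.n_samples) if sample_set is None else sample_set
    W = np.zeros(dataset.n_attributes)
    for i in indices:
        if denom[i] == 0:
            continue
        mismatch = (X != X[i]).astype(float)
        W += signed[i] @ mismatch / denom[i]
    W /= len(indices)
    return WeightVector(np.clip(W, -1.0, 1.0), dataset.attribute_names)
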