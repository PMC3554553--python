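"""Power evaluation protocol for SNP attribute-ranking algorithms.

An algorithm run on one replicate dataset yields a weight per SNP; the run
is a *success* at a given percentile cutoff if **both** functional SNPs rank
inside the examined top fraction (e.g. the top 50 of 1000 SNPs at the 95th
percentile).  Power is the proportion of successes over replicate datasets;
a power curve traces it over cutoffs from the 100th down to the 50th
percentile.  Two algorithms' success counts at a fixed cutoff are compared
with Fisher's exact test, Bonferroni-corrected over the number of
comparisons performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import scipy.stats

from .core import ConfigError, DataError, WeightVector

__all__ = [
    "PowerCurve",
    "FisherComparison",
    "rank_attributes",
    "cutoff_count",
    "success",
    "power",
    "power_curve",
    "fisher_exact_2x2",
    "compare_algorithms",
]

DEFAULT_CUTOFFS = tuple(range(100, 49, -1))


def rank_attributes(weights: WeightVector) -> np.ndarray:
    """Attribute indices ordered by weight, best first.

    Ties are broken by ascending attribute index so rankings are
    deterministic and stable under re-runs.
    """
    w = np.asarray(weights.weights)
    if w.size == 0:
        raise DataError("cannot rank an empty weight vector")
    return np.argsort(-w, kind="stable")


def cutoff_count(n_attrs: int, percentile: float) -> int:
    """Number of top-ranked attributes examined at a percentile cutoff.

    ``round(n_attrs * (100 - percentile) / 100)`` with halves rounded away
    from zero, so the 95th percentile of 1000 SNPs examines exactly 50.
    """
    if n_attrs < 1:
        raise ConfigError(f"n_attrs must be positive, got {n_attrs!r}")
    if not 0 <= percentile <= 100:
        raise ConfigError(f"percentile must be in [0, 100], got {percentile!r}")
    x = n_attrs * (100 - percentile) / 100
    return int(np.floor(x + 0.5))


def _as_indices(
    weights: WeightVector, functional_ids: Sequence[Union[int, str]]
) -> list[int]:
    names = list(weights.attribute_names)
    out = []
    for fid in functional_ids:
        if isinstance(fid, str):
            if fid not in names:
                raise ConfigError(f"unknown functional attribute {fid!r}")
            out.append(names.index(fid))
        else:
            if not 0 <= int(fid) < len(names):
                raise ConfigError(f"functional attribute index {fid!r} out of range")
            out.append(int(fid))
    return out


def success(
    weights: WeightVector,
    functional_ids: Sequence[Union[int, str]],
    percentile: float,
) -> bool:
    """True iff every functional SNP ranks inside the examined top fraction."""
    idx = _as_indices(weights, functional_ids)
    top = rank_attributes(weights)[: cutoff_count(len(weights), percentile)]
    return bool(np.isin(idx, top).all())


def power(success_flags: Sequence[bool]) -> float:
    """Proportion of replicate datasets flagged as successes."""
    flags = np.asarray(success_flags, dtype=bool)
    if flags.size == 0:
        raise ConfigError("power needs at least one replicate")
    return float(flags.mean())


@dataclass
class PowerCurve:
    """Success proportion per percentile cutoff (100 down to 50)."""

    cutoffs: np.ndarray
    success_rate: np.ndarray
    n_datasets: int

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"cutoff": self.cutoffs, "success_rate": self.success_rate}
        )


def power_curve(
    weight_vectors: Sequence[WeightVector],
    functional_ids: Sequence[Sequence[Union[int, str]]],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> PowerCurve:
    """Power at each percentile cutoff over a set of replicate datasets.

    ``functional_ids[i]`` names the functional SNPs of dataset ``i``.  The
    curve is monotone: lowering the cutoff examines more SNPs, so successes
    can only accumulate.
    """
    if len(weight_vectors) == 0:
        raise ConfigError("power_curve needs at least one dataset")
    if len(functional_ids) != len(weight_vectors):
        raise DataError(
            f"{len(weight_vectors)} weight vectors but "
            f"{len(functional_ids)} functional-id records"
        )
    # worst (largest) rank of the functional pair per dataset, computed once
    worst_ranks = np.empty(len(weight_vectors), dtype=int)
    n_attrs = np.empty(len(weight_vectors), dtype=int)
    for i, (wv, fids) in enumerate(zip(weight_vectors, functional_ids)):
        order = rank_attributes(wv)
        pos = np.empty(len(order), dtype=int)
        pos[order] = np.arange(len(order))
        worst_ranks[i] = max(pos[j] for j in _as_indices(wv, fids)) + 1
        n_attrs[i] = len(wv)
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    rates = np.array(
        [
            np.mean(
                [
                    worst_ranks[i] <= cutoff_count(int(n_attrs[i]), c)
                    for i in range(len(worst_ranks))
                ]
            )
            for c in cutoffs
        ]
    )
    return PowerCurve(cutoffs, rates, n_datasets=len(weight_vectors))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Uses the probability-mass convention: conditional on the margins, sum
    the hypergeometric probabilities of all tables at most as probable as
    the observed one (with a small relative tolerance guarding float ties).
    """
    counts = np.array([[a, b], [c, d]])
    if (counts < 0).any():
        raise ConfigError("cell counts must be non-negative")
    if counts.sum() == 0:
        raise ConfigError("Fisher test undefined for an all-zero table")
    return float(scipy.stats.fisher_exact(counts, alternative="two-sided").pvalue)


@dataclass
class FisherComparison:
    """Fisher's exact comparison of two algorithms' success counts."""

    successes_a: int
    successes_b: int
    n_a: int
    n_b: int
    p_value: float
    n_tests: int
    significant: bool


def compare_algorithms(
    successes_a: int, successes_b: int, n: int, n_tests: int = 1
) -> FisherComparison:
    """Compare success counts out of ``n`` datasets per arm.

    Builds the 2x2 success/failure table, computes the two-sided Fisher
    exact p-value and flags significance at the Bonferroni-corrected level
    ``0.05 / n_tests``.
    """
    if n <= 0:
        raise ConfigError(f"n must be positive, got {n!r}")
    if n_tests < 1:
        raise ConfigError(f"n_tests must be >= 1, got {n_tests!r}")
    for s in (successes_a, successes_b):
        if not 0 <= s <= n:
            raise ConfigError(f"success count {s!r} outside [0, {n}]")
    p = fisher_exact_2x2(successes_a, n - successes_a, successes_b, n - successes_b)
    return FisherComparison(
        successes_a=successes_a,
        successes_b=successes_b,
        n_a=n,
        n_b=n,
        p_value=p,
        n_tests=n_tests,
        significant=p < 0.05 / n_tests,
    )
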