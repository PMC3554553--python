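"""Synthetic two-locus epistasis data generator.

Emulates the classic benchmark collections used to evaluate Relief-family
algorithms on SNP data: pairs of interacting ("functional") SNPs whose joint
genotype determines disease risk through a 3x3 penetrance table with little
or no marginal effect at either locus, embedded among hundreds of
class-independent noise SNPs.

A :class:`PenetranceModel` holds the penetrance table ``f_gh`` = P(disease |
g copies of the minor allele at locus A, h copies at locus B), together with
the two minor allele frequencies.  Genotypes follow Hardy-Weinberg
proportions with linkage equilibrium between the loci, so the prevalence is
``K = sum_gh P(g) P(h) f_gh`` and the (broad-sense, observed-scale)
heritability is the penetrance variance over the Bernoulli phenotype
variance::

    h2 = sum_gh P(g) P(h) (f_gh - K)^2 / (K (1 - K))

``find_model`` searches for purely epistatic tables with a prescribed
heritability: random tables are projected onto the zero-marginal-effect
subspace and affinely rescaled about ``K`` to hit the target ``h2`` exactly,
rejecting candidates whose cells leave [0, 1].

``generate_design`` enumerates a full factorial study — heritability grid x
MAF x models x replicates x sample sizes — with reproducible per-dataset
seeds and a manifest recording every model table and the functional SNP
positions, which the power evaluation needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, DataError, GenotypeDataset

__all__ = [
    "PenetranceModel",
    "SimulationDesign",
    "genotype_distribution",
    "heritability",
    "marginal_effects",
    "find_model",
    "sample_case_control",
    "add_noise_snps",
    "random_snp_dataset",
    "generate_design",
    "iter_design",
]

#: heritability grid of the classic benchmark (Methods-style listing)
DEFAULT_HERITABILITIES = (0.01, 0.025, 0.05, 0.10, 0.20, 0.30, 0.40)


def genotype_distribution(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    if not 0 < maf <= 0.5:
        raise ConfigError(f"minor allele frequency must be in (0, 0.5], got {maf!r}")
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


@dataclass
class PenetranceModel:
    """A two-locus disease model: 3x3 penetrance table + allele frequencies."""

    table: np.ndarray
    maf_a: float
    maf_b: float

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise DataError(f"penetrance table must be 3x3, got {self.table.shape}")
        if self.table.min() < 0 or self.table.max() > 1:
            raise DataError("penetrance values must lie in [0, 1]")
        genotype_distribution(self.maf_a)
        genotype_distribution(self.maf_b)

    @property
    def joint_genotype_probs(self) -> np.ndarray:
        """3x3 cell probabilities under HWE and linkage equilibrium."""
        return np.outer(
            genotype_distribution(self.maf_a), genotype_distribution(self.maf_b)
        )

    @property
    def prevalence(self) -> float:
        """Population disease probability K."""
        return float((self.joint_genotype_probs * self.table).sum())


def heritability(model: PenetranceModel) -> float:
    """Variance-explained heritability on the observed (penetrance) scale."""
    P = model.joint_genotype_probs
    K = model.prevalence
    if K <= 0 or K >= 1:
        raise DataError(f"degenerate model: prevalence K={K} must be in (0, 1)")
    return float((P * (model.table - K) ** 2).sum() / (K * (1 - K)))


def marginal_effects(model: PenetranceModel) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-locus marginal penetrances and the main-effect score.

    The marginal penetrance at locus A is ``m_A(g) = sum_h P(h) f_gh``; the
    score is the larger of the two marginal ranges (max - min).  A purely
    epistatic model has score 0: neither locus carries any univariate signal.
    """
    pa = genotype_distribution(model.maf_a)
    pb = genotype_distribution(model.maf_b)
    m_a = model.table @ pb
    m_b = model.table.T @ pa
    score = float(max(np.ptp(m_a), np.ptp(m_b)))
    return m_a, m_b, score


class ModelSearchError(RuntimeError):
    """No acceptable penetrance table found within the iteration budget."""


def find_model(
    target_h2: float,
    maf: float,
    seed: int,
    main_effect_tol: float = 0.01,
    max_iter: int = 10_000,
) -> PenetranceModel:
    """Search for a purely epistatic model with the target heritability.

    Each candidate starts as a uniform random 3x3 table, is centred so both
    marginal penetrances are constant (zero main effect), and is rescaled
    about the prevalence so the recomputed heritability equals ``target_h2``
    up to floating point.  Candidates with any cell outside [0, 1] are
    rejected.  All-or-none (0/1) candidate tables, which carry the maximal
    heritability of 1, are interleaved so that near-unity targets remain
    reachable (the fully penetrant XOR table is one such candidate).
    Reproducible given ``seed``.
    """
    if not 0 < target_h2 <= 1:
        raise ConfigError(f"target heritability must be in (0, 1], got {target_h2!r}")
    pa = genotype_distribution(maf)
    P = np.outer(pa, pa)
    rng = np.random.default_rng(seed)
    best_err = np.inf

    def accept(table: np.ndarray) -> Optional[PenetranceModel]:
        nonlocal best_err
        if table.min() < 0 or table.max() > 1:
            return None
        model = PenetranceModel(table, maf, maf)
        if not 0 < model.prevalence < 1:
            return None
        _, _, score = marginal_effects(model)
        if score > main_effect_tol:
            return None
        err = abs(heritability(model) - target_h2)
        best_err = min(best_err, err)
        return model if err <= 0.01 * target_h2 else None

    for _ in range(max_iter):
        f = rng.random((3, 3))
        K = float((P * f).sum())
        m_a = f @ pa
        m_b = f.T @ pa
        # remove both marginal effects; the cell mean under P stays K
        f0 = f - m_a[:, None] - m_b[None, :] + 2 * K
        var = float((P * (f0 - K) ** 2).sum())
        if var > 0 and 0 < K < 1:
            alpha = np.sqrt(target_h2 * K * (1 - K) / var)
            model = accept(K + alpha * (f0 - K))
            if model is not None:
                return model
        # all-or-none candidate: h2 = 1 exactly, so shrinking the table
        # about its prevalence by sqrt(target_h2) lands on the target
        fb = rng.integers(0, 2, size=(3, 3)).astype(float)
        Kb = float((P * fb).sum())
        if 0 < Kb < 1:
            model = accept(Kb + np.sqrt(target_h2) * (fb - Kb))
            if model is not None:
                return model
    raise ModelSearchError(
        f"no model with h2={target_h2} (maf={maf}) within {max_iter} draws; "
        f"best candidate missed by {best_err:.3g}"
    )


def _draw_genotypes(probs: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised draws from a 3-category genotype distribution."""
    return np.searchsorted(np.cumsum(probs), rng.random(size)).astype(np.int8)


def sample_case_control(
    model: PenetranceModel, n: int, seed: int
) -> GenotypeDataset:
    """Draw a balanced case-control sample at the two functional loci.

    Genotype pairs are drawn under HWE and linkage equilibrium; disease
    status is Bernoulli with the cell penetrance; rejection sampling fills
    the two class quotas of ``n/2`` each.  Attributes are named ``SNP1`` and
    ``SNP2`` and recorded as functional in the dataset metadata.
    """
    if n < 2 or n % 2:
        raise ConfigError(f"sample size must be a positive even number, got {n!r}")
    K = model.prevalence
    if K <= 0 or K >= 1:
        raise DataError(
            "penetrance table cannot fill both classes (prevalence 0 or 1)"
        )
    rng = np.random.default_rng(seed)
    pa = genotype_distribution(model.maf_a)
    pb = genotype_distribution(model.maf_b)
    quota = {0: n // 2, 1: n // 2}
    chunks: dict[int, list[np.ndarray]] = {0: [], 1: []}
    # expected draws needed per accepted sample in the rarer class
    batch = int(n / min(K, 1 - K)) + 16
    while quota[0] > 0 or quota[1] > 0:
        g = _draw_genotypes(pa, batch, rng)
        h = _draw_genotypes(pb, batch, rng)
        disease = (rng.random(batch) < model.table[g, h]).astype(np.int8)
        for cls in (0, 1):
            take = np.flatnonzero(disease == cls)[: quota[cls]]
            if take.size:
                chunks[cls].append(np.column_stack([g[take], h[take]]))
                quota[cls] -= take.size
    genotypes = np.vstack(
        [np.vstack(chunks[0]), np.vstack(chunks[1])]
    )
    labels = np.repeat([0, 1], n // 2).astype(np.int8)
    return GenotypeDataset(
        genotypes,
        labels,
        attribute_names=["SNP1", "SNP2"],
        metadata={"functional": ["SNP1", "SNP2"]},
    )


def _noise_matrix(
    n_samples: int, n_snps: int, rng: np.random.Generator, mode: str
) -> np.ndarray:
    if mode == "hwe":
        maf = rng.uniform(0.05, 0.5, n_snps)
        p0 = (1 - maf) ** 2
        p01 = p0 + 2 * maf * (1 - maf)
        u = rng.random((n_samples, n_snps))
        return ((u > p0).astype(np.int8) + (u > p01).astype(np.int8))
    if mode == "uniform":
        return rng.integers(0, 3, size=(n_samples, n_snps), dtype=np.int8)
    raise ConfigError(f"unknown noise mode {mode!r}; expected 'hwe' or 'uniform'")


def add_noise_snps(
    dataset: GenotypeDataset, n_noise: int, seed: int, mode: str = "hwe"
) -> GenotypeDataset:
    """Append class-independent noise SNPs to a dataset.

    By default each noise SNP gets its own minor allele frequency drawn
    uniformly from [0.05, 0.5] and Hardy-Weinberg genotypes; ``mode=
    "uniform"`` instead draws genotypes uniformly from {0, 1, 2}.  Class
    labels and existing attributes are untouched; the functional-attribute
    record in the metadata is preserved.
    """
    if n_noise < 0:
        raise ConfigError(f"n_noise must be non-negative, got {n_noise!r}")
    if n_noise == 0:
        return dataset
    rng = np.random.default_rng(seed)
    noise = _noise_matrix(dataset.n_samples, n_noise, rng, mode)
    names = list(dataset.attribute_names) + [
        f"N{i + 1}" for i in range(n_noise)
    ]
    metadata = dict(dataset.metadata)
    metadata.setdefault("functional", list(dataset.metadata.get("functional", [])))
    return GenotypeDataset(
        np.hstack([dataset.genotypes, noise]),
        dataset.labels,
        attribute_names=names,
        metadata=metadata,
    )


def random_snp_dataset(
    n_samples: int, n_snps: int, seed: int, mode: str = "hwe"
) -> GenotypeDataset:
    """A dataset of purely class-independent SNPs with balanced labels.

    Useful for studying the pairwise-distance distribution itself (e.g. the
    behaviour of neighbour weighting kernels) without any genetic signal.
    """
    if n_samples < 2 or n_snps < 1:
        raise ConfigError("need at least 2 samples and 1 SNP")
    rng = np.random.default_rng(seed)
    genotypes = _noise_matrix(n_samples, n_snps, rng, mode)
    labels = np.zeros(n_samples, dtype=np.int8)
    labels[n_samples // 2 :] = 1
    return GenotypeDataset(genotypes, labels, metadata={"functional": []})


# ---------------------------------------------------------------------------
# Factorial study designs
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """A factorial simulation study.

    Defaults mirror the classic benchmark: seven heritabilities, MAFs 0.2
    and 0.4, five models per setting, 100 replicates per model, four sample
    sizes and 998 appended noise SNPs.
    """

    heritabilities: Sequence[float] = DEFAULT_HERITABILITIES
    mafs: Sequence[float] = (0.2, 0.4)
    sample_sizes: Sequence[int] = (200, 400, 800, 1600)
    models_per_setting: int = 5
    replicates_per_model: int = 100
    n_noise: int = 998
    seed: int = 0
    noise_mode: str = "hwe"
    main_effect_tol: float = 0.01

    @property
    def n_datasets(self) -> int:
        return (
            len(self.heritabilities)
            * len(self.mafs)
            * self.models_per_setting
            * self.replicates_per_model
            * len(self.sample_sizes)
        )


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def iter_design(
    design: SimulationDesign,
) -> Iterator[tuple[dict, GenotypeDataset]]:
    """Generate every dataset of the design, yielding (manifest row, dataset).

    Model searches and per-dataset sampling seeds all derive from
    ``design.seed``, so the same design yields the same stream of datasets.
    """
    rng = np.random.default_rng(design.seed)
    for h2 in design.heritabilities:
        for maf in design.mafs:
            for m in range(design.models_per_setting):
                model = find_model(
                    h2, maf, seed=_spawn_seed(rng),
                    main_effect_tol=design.main_effect_tol,
                )
                model_id = f"h{h2:g}_maf{maf:g}_m{m + 1}"
                for size in design.sample_sizes:
                    for rep in range(design.replicates_per_model):
                        cc_seed = _spawn_seed(rng)
                        noise_seed = _spawn_seed(rng)
                        dataset = sample_case_control(model, size, cc_seed)
                        dataset = add_noise_snps(
                            dataset, design.n_noise, noise_seed, design.noise_mode
                        )
                        row = {
                            "dataset_id": f"{model_id}_n{size}_r{rep + 1}",
                            "model_id": model_id,
                            "heritability": h2,
                            "maf": maf,
                            "sample_size": size,
                            "replicate": rep + 1,
                            "cc_seed": cc_seed,
                            "noise_seed": noise_seed,
                            "functional": ",".join(
                                dataset.metadata["functional"]
                            ),
                            "penetrance_table": json.dumps(
                                np.round(model.table, 12).tolist()
                            ),
                        }
                        yield row, dataset


def generate_design(
    design: SimulationDesign, out_dir: Optional[str | Path] = None
) -> pd.DataFrame:
    """Run the full design; optionally write every dataset plus a manifest.

    With ``out_dir`` set, each dataset is written as a tab-delimited genotype
    table and the manifest (model tables, seeds, functional SNP positions,
    file paths) as ``manifest.tsv`` in that directory.  Returns the manifest.
    """
    from .io import write_dataset  # avoid an import cycle at module load

    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for row, dataset in iter_design(design):
        if out_path is not None:
            rel = f"{row['dataset_id']}.txt"
            write_dataset(dataset, out_path / rel)
            row["path"] = rel
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.tsv", sep="\t", index=False)
    return manifest
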