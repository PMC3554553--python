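"""Readers and writers for the tab-delimited genotype-table dialect.

The on-disk format is a UTF-8, LF-terminated, tab-delimited table: a header
of SNP names followed by a class column (named ``Class`` by default, always
written last), then one row per sample with genotypes coded 0/1/2 and class
0/1.  Weight tables, power curves and comparison summaries are written as
plain tab-delimited text as well; no binary formats are used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import DataError, GenotypeDataset, WeightVector
from .evaluation import FisherComparison, PowerCurve, rank_attributes

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_weights",
    "read_weights",
    "write_power_curve",
    "write_comparison",
]


def read_dataset(
    path: Union[str, Path], class_column: str = "Class"
) -> GenotypeDataset:
    """Parse a tab-delimited genotype table into a :class:`GenotypeDataset`.

    Validation errors report the offending row and column: genotypes must be
    integers in {0, 1, 2}, class labels in {0, 1}, and all rows must have
    the same number of fields as the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip() != ""]
    if not lines:
        raise DataError(f"{path}: file is empty")
    header = lines[0].split("\t")
    if class_column not in header:
        raise DataError(
            f"{path}: missing class column {class_column!r} in header"
        )
    if len(lines) < 2:
        raise DataError(f"{path}: header only, no sample rows")
    class_idx = header.index(class_column)
    attr_names = [h for i, h in enumerate(header) if i != class_idx]
    genotypes = np.empty((len(lines) - 1, len(attr_names)), dtype=np.int8)
    labels = np.empty(len(lines) - 1, dtype=np.int8)
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise DataError(
                f"{path}: line {r} has {len(fields)} fields, expected {len(header)}"
            )
        col = 0
        for cidx, (name, raw) in enumerate(zip(header, fields)):
            try:
                value = int(raw)
            except ValueError:
                raise DataError(
                    f"{path}: line {r}, column {name!r}: non-integer value {raw!r}"
                ) from None
            if cidx == class_idx:
                if value not in (0, 1):
                    raise DataError(
                        f"{path}: line {r}, column {name!r}: class {value} not in {{0,1}}"
                    )
                labels[r - 2] = value
            else:
                if value not in (0, 1, 2):
                    raise DataError(
                        f"{path}: line {r}, column {name!r}: genotype {value} "
                        "not in {0,1,2}"
                    )
                genotypes[r - 2, col] = value
                col += 1
    return GenotypeDataset(genotypes, labels, attribute_names=attr_names)


def write_dataset(dataset: GenotypeDataset, path: Union[str, Path]) -> Path:
    """Write a dataset in the tab-delimited dialect (class column last)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([*dataset.attribute_names, "Class"]) + "\n")
        for row, label in zip(dataset.genotypes, dataset.labels):
            fh.write("\t".join(map(str, row)) + f"\t{label}\n")
    return path


def write_weights(
    weights: WeightVector, path: Union[str, Path],
    names: Sequence[str] | None = None,
) -> Path:
    """Write (attribute, weight, rank) rows at full float precision."""
    names = list(names) if names is not None else list(weights.attribute_names)
    if len(names) != len(weights):
        raise DataError(
            f"{len(names)} names for {len(weights)} weights"
        )
    order = rank_attributes(weights)
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("attribute\tweight\trank\n")
        for name, w, r in zip(names, weights.weights, rank):
            fh.write(f"{name}\t{float(w)!r}\t{r}\n")
    return path


def read_weights(path: Union[str, Path]) -> WeightVector:
    """Read a weight table written by :func:`write_weights`."""
    df = pd.read_csv(path, sep="\t")
    return WeightVector(df["weight"].to_numpy(float), df["attribute"].astype(str))


def write_power_curve(
    curves: dict[str, PowerCurve], path: Union[str, Path]
) -> Path:
    """Write one or more power curves as a (cutoff, rate per algorithm) table."""
    if not curves:
        raise DataError("no power curves to write")
    first = next(iter(curves.values()))
    out = pd.DataFrame({"cutoff": first.cutoffs.astype(int)})
    for name, curve in curves.items():
        if not np.array_equal(curve.cutoffs, first.cutoffs):
            raise DataError("power curves use different cutoff grids")
        out[name] = curve.success_rate
    path = Path(path)
    out.to_csv(path, sep="\t", index=False)
    return path


def write_comparison(result: FisherComparison, path: Union[str, Path]) -> Path:
    """Write a Fisher comparison as a one-row tab-delimited summary."""
    path = Path(path)
    pd.DataFrame(
        [
            {
                "successes_a": result.successes_a,
                "successes_b": result.successes_b,
                "n_a": result.n_a,
                "n_b": result.n_b,
                "p_value": result.p_value,
                "n_tests": result.n_tests,
                "alpha_corrected": 0.05 / result.n_tests,
                "significant": result.significant,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
    return path
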