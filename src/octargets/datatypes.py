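"""Core in-memory containers shared by the pipeline stages.

The central container is :class:`ExpressionDataset`, a genes x samples
matrix of log2-scale expression values with per-sample condition
(``cancer`` / ``control``) and batch labels.  Stages exchange plain
pandas objects otherwise (probe tables, DE tables, edge lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputFormatError

CONDITIONS = ("cancer", "control")


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with sample condition and batch labels.

    Parameters
    ----------
    values
        genes x samples DataFrame; the index holds unique gene (or probe)
        identifiers and the columns hold unique sample identifiers.
    condition
        Per-sample label, one of ``cancer`` or ``control``, indexed by sample.
    batch
        Per-sample batch (source-study) label, indexed by sample.
    """

    values: pd.DataFrame
    condition: pd.Series
    batch: pd.Series

    def __post_init__(self):
        samples = list(self.values.columns)
        self.condition = self.condition.reindex(samples)
        self.batch = self.batch.reindex(samples)
        if self.condition.isna().any() or self.batch.isna().any():
            raise InputFormatError("every sample needs a condition and batch label")
        if not self.values.index.is_unique:
            raise InputFormatError("gene identifiers must be unique")
        if not self.values.columns.is_unique:
            raise InputFormatError("sample identifiers must be unique")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise InputFormatError(f"unknown condition labels: {sorted(bad)}")
        if np.asarray(self.values, dtype=float).size and not np.isfinite(
            self.values.to_numpy(dtype=float)
        ).all():
            raise InputFormatError("expression matrix contains missing values")

    # -- convenience -------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_condition(self, condition: str) -> "ExpressionDataset":
        """Return the dataset restricted to samples of one condition."""
        keep = self.condition[self.condition == condition].index
        return ExpressionDataset(
            self.values[keep], self.condition[keep], self.batch[keep]
        )

    def sample_map(self) -> pd.DataFrame:
        """Condition/batch labels as a sample-indexed frame."""
        return pd.DataFrame({"condition": self.condition, "batch": self.batch})

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, expr_path, samplemap_path) -> None:
        write_expression_tsv(self.values, expr_path)
        sm = self.sample_map().reset_index(names="sample")
        sm.to_csv(samplemap_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path, samplemap_path) -> "ExpressionDataset":
        values = read_expression_tsv(expr_path)
        sm = read_sample_map(samplemap_path)
        return cls(values, sm["condition"], sm["batch"])


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="id", float_format="%.6f")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_sample_map(path) -> pd.DataFrame:
    sm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "batch"}
    if not required.issubset(sm.columns):
        raise InputFormatError(
            f"sample map needs columns {sorted(required)}, got {list(sm.columns)}"
        )
    return sm.set_index("sample")


@dataclass
class BatchAssessment:
    """Quality read-out of a batch-corrected dataset.

    ``mixing_score`` is the mean silhouette coefficient of the batch labels
    on the first two principal components: values near 0 (or below) mean
    the batches are well mixed, values near 1 mean they separate cleanly.
    ``power`` holds per-gene two-sample t-test power at the stated effect
    size and level.
    """

    pc_scores: pd.DataFrame  # samples x 2, columns PC1/PC2
    mixing_score: float
    power: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    delta: float = 1.0
    alpha: float = 0.05

    @property
    def frac_powered(self) -> float:
        """Fraction of genes with power >= 0.8."""
        if len(self.power) == 0:
            return float("nan")
        return float((self.power >= 0.8).mean())
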