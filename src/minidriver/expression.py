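"""Expression matrix input, validation, low-expression filtering and condition splits.

Expression values are RPKM-scale non-negative reals on a genes-by-samples
grid.  Correlations downstream are computed on these values as-is (no log
transform), so this module deliberately performs no normalisation beyond the
rank-based low-expression cut.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "filter_low_expression",
    "split_by_condition",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique gene symbols, columns by unique sample ids.
    condition : pandas.Series, optional
        Sample id -> condition label (e.g. ``"normal"`` / ``"tumour"``).
        May cover only the samples present in ``data``.
    """

    data: pd.DataFrame
    condition: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.condition is not None:
            missing = self.data.columns.difference(self.condition.index)
            if len(missing) > 0:
                raise ValueError(
                    f"samples missing from condition map: {list(missing[:5])}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_expression_matrix(
    path, condition_map=None, *, sep: str = "\t"
) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (gene symbols in the first column).

    Duplicate gene rows are collapsed by summation (exon-level aggregation
    artefacts) and logged.  ``condition_map`` is an optional two-column TSV
    (sample_id, label) without a header.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression values ({exc})") from exc
    if df.index.has_duplicates:
        n_dupes = int(df.index.duplicated().sum())
        logger.warning(
            "%s: collapsing %d duplicate gene row(s) by summation", path, n_dupes
        )
        df = df.groupby(level=0, sort=False).sum()

    condition = None
    if condition_map is not None:
        cond_df = pd.read_csv(
            condition_map, sep=sep, header=None, names=["sample_id", "label"]
        )
        condition = pd.Series(
            cond_df["label"].astype(str).to_numpy(),
            index=cond_df["sample_id"].astype(str),
            name="condition",
        )
    return ExpressionMatrix(df, condition)


def filter_low_expression(
    m: ExpressionMatrix, percentile: float = 40.0
) -> ExpressionMatrix:
    """Discard the lowest ``floor(percentile/100 * G)`` genes by summed expression.

    The cut is rank-based: genes are ordered by total expression across all
    samples and the bottom fraction removed, keeping the remainder in their
    original row order.  Ties are broken stably so that, among equal sums,
    earlier-listed genes are preferred for retention.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    n_genes = m.data.shape[0]
    n_drop = math.floor(percentile / 100.0 * n_genes)
    if n_drop == 0:
        return ExpressionMatrix(m.data.copy(), m.condition)
    sums = m.data.sum(axis=1).to_numpy()
    # descending by sum, stable: ties keep original order, so the first
    # G - n_drop positions are the retained genes
    order = np.argsort(-sums, kind="stable")
    keep = np.sort(order[: n_genes - n_drop])
    return ExpressionMatrix(m.data.iloc[keep], m.condition)


def split_by_condition(m: ExpressionMatrix, label: str) -> ExpressionMatrix:
    """Return the sub-matrix of samples whose condition equals ``label``."""
    if m.condition is None:
        raise ValueError("expression matrix has no condition map")
    labels = m.condition.reindex(m.data.columns)
    cols = m.data.columns[(labels == label).to_numpy()]
    if len(cols) == 0:
        raise ValueError(f"no samples with condition label {label!r}")
    return ExpressionMatrix(m.data[cols], m.condition)
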