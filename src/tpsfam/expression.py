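"""RPKM expression summaries: abundance categories, tissue specificity, heatmap prep.

Abundance categories follow the heatmap anchor values of the source data
(white ≈ 0.1-0.5 RPKM, saturated red at 60 RPKM), interpolated into four
bands: not_detected (< 0.1), low (0.1-0.5), moderate (0.5-60, exclusive)
and high (>= 60). A gene is tissue-specific when exactly one tissue exceeds
the detection threshold (0.5 RPKM).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

NOT_DETECTED_BELOW = 0.1
LOW_UPPER = 0.5
HIGH_AT = 60.0
DETECT_THRESHOLD = 0.5

CATEGORIES = ("not_detected", "low", "moderate", "high")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with gene ids in the first column and tissue labels as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def validate_expression(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative RPKM values")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids")


def expression_category(value: float) -> str:
    """Map one RPKM value to its abundance band."""
    if value < 0:
        raise ValueError(f"negative RPKM {value}")
    if value < NOT_DETECTED_BELOW:
        return "not_detected"
    if value <= LOW_UPPER:
        return "low"
    if value < HIGH_AT:
        return "moderate"
    return "high"


def category_table(matrix: pd.DataFrame) -> pd.DataFrame:
    validate_expression(matrix)
    return matrix.map(expression_category)


def tissue_specific(
    row: Mapping[str, float] | pd.Series, detect_threshold: float = DETECT_THRESHOLD
) -> str | None:
    """The single tissue above the detection threshold, or None.

    Specificity requires value(T) > threshold in exactly one tissue and
    <= threshold everywhere else; invariant under tissue permutation.
    """
    row = pd.Series(row, dtype=float)
    if len(row) < 2:
        raise ValueError("need at least 2 tissues for a specificity call")
    detected = row[row > detect_threshold]
    return str(detected.index[0]) if len(detected) == 1 else None


def tissue_specificity_table(
    matrix: pd.DataFrame, detect_threshold: float = DETECT_THRESHOLD
) -> pd.Series:
    validate_expression(matrix)
    return pd.Series(
        {g: tissue_specific(matrix.loc[g], detect_threshold) for g in matrix.index},
        name="specific_tissue",
    )


def heatmap_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """log2(x+1)-transformed matrix with rows ordered by hierarchical clustering.

    Average linkage on correlation distance; a constant row has undefined
    correlation and gets distance 1 to every other row (with a warning).
    Rows are pre-sorted by id so ties and the whole ordering are
    deterministic.
    """
    validate_expression(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 genes")
    matrix = matrix.sort_index()
    transformed = np.log2(matrix + 1.0)
    values = transformed.to_numpy()
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): correlation distance set to 1"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = pdist(values, metric="correlation")
    dist = np.where(np.isnan(dist), 1.0, dist)
    dist = np.clip(dist, 0.0, None)
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    row_order = [str(transformed.index[i]) for i in order]
    return transformed.loc[row_order], row_order
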