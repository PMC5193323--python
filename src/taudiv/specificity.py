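"""Tissue-specificity index tau and tissue-specific gene calling.

tau = sum_i (1 - x_i / max_i x_i) / (n - 1) over n >= 2 tissues, computed
on log2 expression after flooring linear values below 1 at 1 (so
sub-1-RPKM expression counts as absent).  tau is 0 for uniformly expressed
genes and 1 for genes expressed in a single tissue; it is undefined when
no retained tissue reaches 1 RPKM.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError, StateError
from .io_tables import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.8
DEFAULT_TESTIS_LABEL = "testis"

TAU_COLUMNS = (
    "tau",
    "max_tissue",
    "max_expression",
    "n_tissues_used",
    "defined",
    "is_specific",
    "testis_forced",
)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 with floor-at-1: v -> log2(max(v, 1)).

    Values below 1 RPKM map to 0 so that noise-level expression is treated
    as absence.  Raises StateError if the matrix is already log scale.
    """
    if matrix.is_log:
        raise StateError("matrix is already log-transformed")
    values = np.log2(np.clip(matrix.data.to_numpy(dtype=float), 1.0, None))
    data = pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(matrix.species_id, matrix.dataset_id, data, is_log=True)


def compute_tau(log_profile) -> float:
    """tau for one gene from its vector of log-expression values.

    Returns NaN (undefined) when the maximum is 0, i.e. the gene is not
    expressed above the floor in any tissue.
    """
    x = np.asarray(log_profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DimensionError(f"tau needs >= 2 tissues, got shape {x.shape}")
    if (x < 0).any():
        raise ValueError("log-expression values must be >= 0 (apply the floored log first)")
    mx = x.max()
    if mx == 0:
        return float("nan")
    return float((1.0 - x / mx).sum() / (x.size - 1))


def _tau_rows(log_values: np.ndarray) -> np.ndarray:
    """Vectorised tau over the rows of a gene x tissue log matrix."""
    n = log_values.shape[1]
    mx = log_values.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - log_values / mx[:, None]).sum(axis=1) / (n - 1)
    tau[mx == 0] = np.nan
    return tau


def build_tau_table(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    excluded_tissues: Iterable[str] = (),
    testis_override: bool = False,
    testis_label: str = DEFAULT_TESTIS_LABEL,
) -> pd.DataFrame:
    """Per-gene tau, main tissue and specificity call.

    The matrix must be on linear scale: tau is computed on the floored log2
    values of the retained tissues, while the main tissue and its
    ``max_expression`` are taken on the linear scale.  Ties for the main
    tissue are broken by tissue-column order (first wins, tie count logged).

    ``is_specific`` is ``defined and tau >= threshold``; with
    ``testis_override`` every defined gene whose main tissue is the testis
    is additionally called specific regardless of tau (flag
    ``testis_forced``).
    """
    if matrix.is_log:
        raise StateError("build_tau_table expects linear-scale expression")
    if not 0 < threshold <= 1:
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    excluded = set(excluded_tissues)
    unknown = excluded - set(matrix.tissues)
    if unknown:
        raise ConfigError(f"excluded tissues {sorted(unknown)} not in matrix")
    retained = [t for t in matrix.tissues if t not in excluded]
    if len(retained) < 2:
        raise DimensionError(
            f"tissue exclusion leaves {len(retained)} tissue(s); tau needs >= 2"
        )
    if testis_override and testis_label not in retained:
        raise ConfigError(
            f"testis_override requested but {testis_label!r} not among retained tissues"
        )

    lin = matrix.data.loc[:, retained]
    logv = np.log2(np.clip(lin.to_numpy(dtype=float), 1.0, None))
    tau = _tau_rows(logv)
    defined = ~np.isnan(tau)

    max_tissue = lin.idxmax(axis=1)  # ties: first column in tissue order
    n_ties = int((lin.eq(lin.max(axis=1), axis=0).sum(axis=1) > 1).sum())
    if n_ties:
        logger.info("build_tau_table: %d genes with tied main tissue (first column kept)", n_ties)
    max_expression = lin.max(axis=1)

    is_specific = defined & (tau >= threshold)
    testis_forced = np.zeros(len(lin), dtype=bool)
    if testis_override:
        testis_forced = defined & (max_tissue == testis_label).to_numpy() & ~is_specific
        is_specific = is_specific | testis_forced

    table = pd.DataFrame(
        {
            "tau": tau,
            "max_tissue": max_tissue,
            "max_expression": max_expression,
            "n_tissues_used": len(retained),
            "defined": defined,
            "is_specific": is_specific,
            "testis_forced": testis_forced,
        },
        index=lin.index,
    )
    table.index.name = "gene_id"
    table.attrs["excluded_tissues"] = sorted(excluded)
    table.attrs["threshold"] = threshold
    logger.info(
        "build_tau_table: %s/%s %d genes, %d defined, %d specific (threshold %.2f)",
        matrix.species_id, matrix.dataset_id, len(table),
        int(defined.sum()), int(is_specific.sum()), threshold,
    )
    return table


def leave_one_tissue_out(
    matrix: ExpressionMatrix,
    tissue_label: str,
    threshold: float = DEFAULT_THRESHOLD,
    **kwargs,
) -> pd.DataFrame:
    """Recompute the tau table with one tissue removed (robustness control)."""
    if tissue_label not in matrix.tissues:
        raise ConfigError(f"tissue {tissue_label!r} not present in matrix")
    return build_tau_table(
        matrix, threshold=threshold, excluded_tissues={tissue_label}, **kwargs
    )


def write_tau_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def read_tau_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("defined", "is_specific", "testis_forced"):
        if col in table.columns:
            table[col] = table[col].astype(bool)
    return table
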