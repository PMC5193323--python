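"""Readers, writers and configuration objects for all tabular inputs.

All files are UTF-8, tab-separated, '.' decimal, with a mandatory header
row; gzip-compressed files are read transparently.  Missing values are an
error everywhere — no imputation is attempted.  Gene identifiers are
treated as opaque strings.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CalibrationLookupError,
    DimensionError,
    EmptyResultError,
    FormatError,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

#: Relation strings accepted in homology tables.
RELATIONS = ("one2one_ortholog", "within_species_paralog", "one2two_outgroup")

HOMOLOGY_COLUMNS = (
    "gene_a",
    "species_a",
    "gene_b",
    "species_b",
    "relation",
    "node_label",
    "family_id",
)


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x tissue expression values for one species/dataset.

    ``data`` is a DataFrame indexed by gene identifier with one column per
    tissue; values are linear-scale RPKM/FPKM-like abundances unless
    ``is_log`` is set (log2 scale after floor-at-1).
    """

    species_id: str
    dataset_id: str
    data: pd.DataFrame
    is_log: bool = False

    def __post_init__(self):
        if self.data.shape[1] < 2:
            raise DimensionError(
                f"{self.dataset_id}: expression matrix needs >= 2 tissue "
                f"columns, got {self.data.shape[1]}"
            )
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate tissue labels {dups}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if np.isnan(values).any():
            raise FormatError("missing expression values are not allowed")
        if not np.isfinite(values).all():
            raise FormatError("non-finite expression values")
        if not self.is_log and (values < 0).any():
            raise FormatError("negative expression values on linear scale")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_tissues(self) -> int:
        return self.data.shape[1]


def read_expression(path, species_id: str, dataset_id: str) -> ExpressionMatrix:
    """Read a TSV expression table (first column: gene id, rest: tissues)."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 3:
        raise DimensionError(f"{path}: fewer than 2 tissue columns")
    tissues = header[1:]
    if len(set(tissues)) != len(tissues):
        raise FormatError(f"{path}: duplicate tissue labels in header")
    df = pd.read_csv(path, sep="\t", header=0, names=header, dtype={header[0]: str})
    df = df.set_index(header[0])
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    matrix = ExpressionMatrix(species_id, dataset_id, df)
    logger.info(
        "read_expression: %s/%s %d genes x %d tissues",
        species_id, dataset_id, len(matrix.genes), matrix.n_tissues,
    )
    return matrix


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Gene filters
# ---------------------------------------------------------------------------


@dataclass
class GeneFilter:
    """Restriction applied to an expression matrix before analysis.

    mode 'keep_biotype' keeps genes whose metadata biotype is in payload
    (e.g. {'protein_coding'}); 'drop_chromosomes' removes genes on the
    listed chromosomes (e.g. sex chromosomes {'X', 'Y'}); 'drop_genes'
    removes listed gene identifiers.
    """

    mode: str
    payload: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.mode not in ("keep_biotype", "drop_chromosomes", "drop_genes"):
            raise FormatError(f"unknown gene filter mode {self.mode!r}")
        self.payload = frozenset(self.payload)
        if not self.payload:
            raise FormatError("gene filter payload must be non-empty")


def apply_gene_filter(
    matrix: ExpressionMatrix,
    gene_filter: GeneFilter,
    metadata: Mapping[str, Mapping[str, str]] | pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Return the matrix restricted to genes passing the filter.

    ``metadata`` maps gene id -> attributes ('biotype', 'chromosome'); it is
    required for the biotype/chromosome modes and must cover all genes.
    Gene order of survivors is preserved.  Idempotent.
    """
    genes = matrix.data.index
    if gene_filter.mode == "drop_genes":
        keep = ~genes.isin(gene_filter.payload)
    else:
        if metadata is None:
            raise FormatError(f"mode {gene_filter.mode!r} requires gene metadata")
        if isinstance(metadata, pd.DataFrame):
            meta = metadata
        else:
            meta = pd.DataFrame.from_dict(dict(metadata), orient="index")
        missing = genes.difference(meta.index)
        if len(missing):
            raise FormatError(
                f"metadata missing for {len(missing)} genes (e.g. {list(missing[:3])})"
            )
        attr = "biotype" if gene_filter.mode == "keep_biotype" else "chromosome"
        if attr not in meta.columns:
            raise FormatError(f"gene metadata lacks column {attr!r}")
        values = meta.loc[genes, attr]
        if gene_filter.mode == "keep_biotype":
            keep = values.isin(gene_filter.payload).to_numpy()
        else:
            keep = ~values.isin(gene_filter.payload).to_numpy()
    if not keep.any():
        raise EmptyResultError(f"gene filter {gene_filter.mode} removed every gene")
    logger.info(
        "apply_gene_filter: %s kept %d/%d genes",
        gene_filter.mode, int(keep.sum()), len(genes),
    )
    return ExpressionMatrix(
        matrix.species_id, matrix.dataset_id, matrix.data.loc[keep], matrix.is_log
    )


# ---------------------------------------------------------------------------
# Homology pairs
# ---------------------------------------------------------------------------


def validate_homology(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HOMOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"homology table missing columns {missing}")
    df = df.loc[:, list(HOMOLOGY_COLUMNS)].astype(str)
    bad = sorted(set(df["relation"]) - set(RELATIONS))
    if bad:
        raise FormatError(f"unknown relation strings {bad}; expected one of {RELATIONS}")
    if (df["gene_a"] == df["gene_b"]).any():
        raise FormatError("homology rows with gene_a == gene_b")
    paralog = df["relation"] == "within_species_paralog"
    if (df.loc[paralog, "species_a"] != df.loc[paralog, "species_b"]).any():
        raise FormatError("within_species_paralog rows must have matching species")
    ortho = df["relation"] == "one2one_ortholog"
    if (df.loc[ortho, "species_a"] == df.loc[ortho, "species_b"]).any():
        raise FormatError("one2one_ortholog rows must link different species")
    return df.reset_index(drop=True)


def read_homology(path) -> pd.DataFrame:
    """Read a homology pair table (Ensembl-Compara-style TSV export)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = validate_homology(df)
    logger.info("read_homology: %d rows", len(df))
    return df


def write_homology(df: pd.DataFrame, path) -> None:
    validate_homology(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Age calibration
# ---------------------------------------------------------------------------


class AgeCalibration:
    """Mapping from taxonomic node label to an absolute age in million years."""

    def __init__(self, ages: Mapping[str, float]):
        clean: dict[str, float] = {}
        for label, age in ages.items():
            age = float(age)
            if not np.isfinite(age) or age <= 0:
                raise FormatError(f"calibration age for {label!r} must be positive, got {age}")
            if label in clean:
                raise FormatError(f"duplicate node label {label!r} in calibration")
            clean[str(label)] = age
        self._ages = clean

    def age(self, node_label: str) -> float:
        try:
            return self._ages[node_label]
        except KeyError:
            raise CalibrationLookupError(node_label) from None

    def __contains__(self, node_label: str) -> bool:
        return node_label in self._ages

    def __len__(self) -> int:
        return len(self._ages)

    def items(self):
        return self._ages.items()


def read_calibration(path) -> AgeCalibration:
    df = pd.read_csv(path, sep="\t", dtype={"node_label": str})
    for col in ("node_label", "age_my"):
        if col not in df.columns:
            raise FormatError(f"calibration table missing column {col!r}")
    if df["node_label"].duplicated().any():
        raise FormatError("duplicate node labels in calibration table")
    return AgeCalibration(dict(zip(df["node_label"], df["age_my"])))


def write_calibration(calibration: AgeCalibration, path) -> None:
    rows = sorted(calibration.items(), key=lambda kv: (kv[1], kv[0]))
    pd.DataFrame(rows, columns=["node_label", "age_my"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# Tissue map
# ---------------------------------------------------------------------------


class TissueMap:
    """Maps (species, local tissue label) to a canonical tissue label.

    Only needed where tissues are compared *across* species (same-tissue
    analysis); tau itself never requires tissue matching.
    """

    def __init__(self, mapping: Mapping[tuple[str, str], str]):
        self._map: dict[tuple[str, str], str] = {}
        for key, canonical in mapping.items():
            if key in self._map and self._map[key] != canonical:
                raise FormatError(
                    f"tissue {key} mapped to both {self._map[key]!r} and {canonical!r}"
                )
            self._map[(str(key[0]), str(key[1]))] = str(canonical)

    def canonical(self, species_id: str, local_label: str) -> str | None:
        """Canonical label, or None (logged) when the tissue is unmapped."""
        hit = self._map.get((species_id, local_label))
        if hit is None:
            logger.warning("tissue %r of species %r is unmapped", local_label, species_id)
        return hit

    def canonical_labels(self) -> set[str]:
        return set(self._map.values())

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def read_tissue_map(path) -> TissueMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("species_id", "local_tissue", "canonical_tissue"):
        if col not in df.columns:
            raise FormatError(f"tissue map missing column {col!r}")
    keyed = df.set_index(["species_id", "local_tissue"])["canonical_tissue"]
    dup = keyed.index.duplicated(keep=False)
    if dup.any() and keyed[dup].groupby(level=[0, 1]).nunique().gt(1).any():
        raise FormatError("a local tissue label maps to two canonical labels")
    return TissueMap(dict(keyed.items()))


def write_tissue_map(tissue_map: TissueMap, path) -> None:
    rows = sorted((sp, loc, can) for (sp, loc), can in tissue_map.items())
    pd.DataFrame(rows, columns=["species_id", "local_tissue", "canonical_tissue"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path) -> frozenset:
    """One gene identifier per line; blank lines and '#' comments ignored."""
    genes = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return frozenset(genes)
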