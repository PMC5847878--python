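"""Expression-matrix / sample-sheet I/O and gene filtering.

The expression matrix is a plain :class:`pandas.DataFrame` of log2
intensities with gene identifiers on the rows and sample identifiers on
the columns; the sample sheet is a :class:`pandas.Series` mapping sample
id to one of the four dietary groups.  Filtering implements the two
expression-detection rules used before differential testing: a minimum
interquartile range computed over the whole dataset (all groups pooled)
and a minimum linear-scale intensity reached on a minimum number of
arrays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = frozenset({"C", "CR", "CR-MF", "MF"})


class DatasetError(ValueError):
    """Raised for malformed expression matrices or sample sheets."""


def load_expression(path) -> pd.DataFrame:
    """Read a tab-separated log2 expression matrix.

    The first column must be named ``gene_id``; the header row carries
    sample ids.  Duplicate gene or sample ids and non-numeric cells are
    rejected with the offending location named.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene_id":
        raise DatasetError(
            f"{path}: first column must be 'gene_id', found "
            f"{header[0] if header else None!r}"
        )
    samples = pd.Index(header[1:], dtype=str)
    dup = samples[samples.duplicated()]
    if len(dup):
        raise DatasetError(f"{path}: duplicated sample id(s): {sorted(set(dup))}")
    raw = pd.read_csv(path, sep="\t", dtype=str, skiprows=1, header=None)
    if raw.shape[1] != len(header):
        raise DatasetError(f"{path}: ragged rows (header has {len(header)} columns)")
    genes = raw.iloc[:, 0].astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise DatasetError(f"{path}: duplicated gene id(s): {sorted(set(dup))}")
    values = raw.iloc[:, 1:].copy()
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DatasetError(
            f"{path}: non-numeric value {values.iat[r, c]!r} at gene "
            f"{genes.iat[r]!r}, sample {samples[c]!r}"
        )
    if numeric.isna().to_numpy().any() or not np.isfinite(numeric.to_numpy()).all():
        raise DatasetError(f"{path}: matrix contains missing or non-finite values")
    matrix = numeric.astype(float)
    matrix.index = pd.Index(genes, name="gene_id")
    matrix.columns = samples
    return matrix


def load_sample_sheet(path) -> pd.Series:
    """Read a tab-separated sample sheet with columns sample_id, group."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise DatasetError(f"{path}: sample sheet must have a {col!r} column")
    ids = sheet["sample_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise DatasetError(f"{path}: duplicated sample id(s): {sorted(set(dup))}")
    unknown = sorted(set(sheet["group"]) - VALID_GROUPS)
    if unknown:
        raise DatasetError(
            f"{path}: unknown group label(s) {unknown}; expected one of "
            f"{sorted(VALID_GROUPS)}"
        )
    return pd.Series(
        sheet["group"].to_numpy(), index=pd.Index(ids, name="sample_id"), name="group"
    )


def load_dataset(matrix_path, sheet_path) -> tuple[pd.DataFrame, pd.Series]:
    """Load and cross-validate an expression matrix and its sample sheet.

    Samples present on only one side are reported with a warning and the
    returned objects are restricted to the common samples.
    """
    matrix = load_expression(matrix_path)
    sheet = load_sample_sheet(sheet_path)
    only_matrix = matrix.columns.difference(sheet.index)
    only_sheet = sheet.index.difference(matrix.columns)
    if len(only_matrix):
        warnings.warn(
            f"samples in matrix but not in sheet: {list(only_matrix)}", stacklevel=2
        )
    if len(only_sheet):
        warnings.warn(
            f"samples in sheet but not in matrix: {list(only_sheet)}", stacklevel=2
        )
    common = [s for s in matrix.columns if s in set(sheet.index)]
    if not common:
        raise DatasetError("matrix and sample sheet share no samples")
    return matrix[common], sheet.loc[common]


@dataclass(frozen=True)
class FilterParams:
    """Detection-filter thresholds.

    iqr_min
        Minimum interquartile range of a gene's log2 values across the
        entire dataset (all groups pooled); genes must exceed it strictly.
    intensity_min
        Minimum intensity a gene must exceed (strictly) on at least
        ``min_arrays`` arrays.  Interpreted on the linear scale by
        default, i.e. a gene counts on an array when ``2**x >
        intensity_min``; set ``intensity_scale="log2"`` to compare the
        stored log2 value directly.
    """

    iqr_min: float = 0.1
    intensity_min: float = 20.0
    min_arrays: int = 5
    intensity_scale: str = "linear"

    def __post_init__(self):
        if self.iqr_min < 0:
            raise ValueError("iqr_min must be >= 0")
        if self.intensity_min <= 0:
            raise ValueError("intensity_min must be > 0")
        if self.min_arrays < 1:
            raise ValueError("min_arrays must be >= 1")
        if self.intensity_scale not in ("linear", "log2"):
            raise ValueError("intensity_scale must be 'linear' or 'log2'")


@dataclass
class FilterResult:
    """Filtered matrix plus per-rule removal accounting."""

    matrix: pd.DataFrame
    n_input: int
    n_retained: int
    n_failed_iqr: int
    n_failed_intensity: int
    params: FilterParams
    quantile_convention: str = field(default="linear interpolation (numpy default)")


def filter_genes(matrix: pd.DataFrame, params: FilterParams | None = None) -> FilterResult:
    """Keep genes passing both detection rules; order is preserved.

    A gene is retained iff (1) the IQR of its full row is strictly
    greater than ``iqr_min`` and (2) strictly more than
    ``intensity_min`` intensity is reached on at least ``min_arrays``
    arrays.  Removal counts are reported per rule (a gene failing both
    rules counts in both).
    """
    if params is None:
        params = FilterParams()
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise DatasetError("cannot filter an empty matrix")
    values = matrix.to_numpy(dtype=float)
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    iqr_pass = (q75 - q25) > params.iqr_min
    if params.intensity_scale == "linear":
        log2_cut = math.log2(params.intensity_min)
    else:
        log2_cut = params.intensity_min
    intensity_pass = (values > log2_cut).sum(axis=1) >= params.min_arrays
    keep = iqr_pass & intensity_pass
    return FilterResult(
        matrix=matrix.loc[keep],
        n_input=len(matrix),
        n_retained=int(keep.sum()),
        n_failed_iqr=int((~iqr_pass).sum()),
        n_failed_intensity=int((~intensity_pass).sum()),
        params=params,
    )


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write an expression matrix in the package's TSV dialect."""
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(sheet: pd.Series, path) -> None:
    """Write a sample sheet TSV with columns sample_id, group."""
    sheet.rename("group").to_csv(path, sep="\t", index_label="sample_id")
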